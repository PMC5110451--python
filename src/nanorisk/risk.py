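"""The 4-step risk-characterization pipeline.

hazard identification → dose-response → exposure → risk characterization.

Dose-response derives an occupational exposure limit (OEL) from a point of
departure (NOAEL or LOAEL) by dividing out uncertainty factors; exposure is
the network posterior over airborne-concentration bins; risk is summarized
by the hazard quotient

    HQ = exposure concentration / OEL  (× 100, in %),

reported as a full discrete distribution with its mean and equal-tailed 90%
credible interval, and mapped to a control band. The acceptable ↔
potential-risk inflection sits exactly at HQ = 100% (ratio 1), exceeded
strictly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NanoriskError
from .materials import CONCENTRATION, OEL
from .network import NetworkSpec, bin_representatives
from .inference import posterior_marginals

#: Control bands on mean HQ in %: the 100% inflection separates acceptable
#: from potential risk; 10% and 1000% are reporting conventions
#: subdividing the acceptable and unacceptable ranges.
BANDS = (
    ("negligible", 10.0),
    ("caution", 100.0),
    ("potential risk", 1000.0),
    ("high risk", float("inf")),
)


# ---------------------------------------------------------------------------
# dose-response


@dataclass(frozen=True)
class DoseResponseConfig:
    """Dose-response settings deriving the OEL from a point of departure.

    Parameters
    ----------
    point_of_departure:
        NOAEL or LOAEL in μg/m³ (animal study derived), > 0.
    pod_kind:
        ``"NOAEL"`` or ``"LOAEL"``; a LOAEL incurs an extra divisor
        (``loael_factor``, default 10) because the true no-effect level
        lies below it.
    uncertainty_factor:
        Inter-/intra-species safety factor, default 100.
    cmr:
        Carcinogenic/mutagenic/reprotoxic flag; switches the default mode
        to linear.
    mode:
        ``"threshold"`` (non-carcinogenic) or ``"linear"`` (carcinogenic
        low-dose extrapolation); default inferred from ``cmr``.
    linear_extrapolation_factor:
        Extra divisor (default 10) standing in for linear low-dose
        extrapolation to the acceptable-risk level.
    """

    point_of_departure: float
    pod_kind: str = "NOAEL"
    uncertainty_factor: float = 100.0
    cmr: bool = False
    mode: str | None = None
    loael_factor: float = 10.0
    linear_extrapolation_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.point_of_departure <= 0:
            raise ValueError("point_of_departure must be > 0")
        if self.uncertainty_factor < 1:
            raise ValueError("uncertainty_factor must be >= 1")
        if self.pod_kind not in ("NOAEL", "LOAEL"):
            raise ValueError(f"pod_kind must be NOAEL or LOAEL, got {self.pod_kind!r}")
        if self.mode not in (None, "threshold", "linear"):
            raise ValueError(f"mode must be threshold or linear, got {self.mode!r}")

    @property
    def effective_mode(self) -> str:
        if self.mode is not None:
            return self.mode
        return "linear" if self.cmr else "threshold"


def derive_oel(cfg: DoseResponseConfig) -> float:
    """OEL in μg/m³ from the point of departure and uncertainty factors.

    Threshold mode: POD / UF (the usual UF is 100), with a further /10 for
    a LOAEL point of departure. Linear (carcinogenic) mode applies one more
    documented divisor in place of a full slope-factor integration.
    """
    oel = cfg.point_of_departure / cfg.uncertainty_factor
    if cfg.pod_kind == "LOAEL":
        oel /= cfg.loael_factor
    if cfg.effective_mode == "linear":
        oel /= cfg.linear_extrapolation_factor
    return oel


# ---------------------------------------------------------------------------
# discrete distributions on positive scales


@dataclass(frozen=True)
class DiscreteDistribution:
    """Finite distribution over representative values (atoms)."""

    values: tuple[float, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        p = np.asarray(self.probs, dtype=float)
        if v.shape != p.shape or v.ndim != 1 or v.size == 0:
            raise ValueError("values and probs must be equal-length 1-D")
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be a probability vector (sum 1 within 1e-9)")
        object.__setattr__(self, "values", tuple(float(x) for x in v))
        object.__setattr__(self, "probs", tuple(float(x) for x in np.clip(p, 0, None)))

    @classmethod
    def point(cls, value: float) -> "DiscreteDistribution":
        return cls((float(value),), (1.0,))

    @classmethod
    def from_bins(cls, edges, probs) -> "DiscreteDistribution":
        """Bin distribution collapsed onto per-bin representatives
        (geometric midpoints; arithmetic when the bin touches zero)."""
        return cls(tuple(bin_representatives(edges)), tuple(np.asarray(probs, float)))

    @property
    def mean(self) -> float:
        return float(np.dot(self.values, self.probs))

    def quantile(self, q: float) -> float:
        """Smallest atom whose CDF reaches q (atoms sorted ascending)."""
        order = np.argsort(self.values, kind="stable")
        v = np.asarray(self.values)[order]
        cdf = np.cumsum(np.asarray(self.probs)[order])
        k = int(np.searchsorted(cdf, q - 1e-12, side="left"))
        return float(v[min(k, v.size - 1)])

    def interval(self, level: float = 0.90) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        return self.quantile(a), self.quantile(1.0 - a)


# ---------------------------------------------------------------------------
# hazard quotient


@dataclass
class HQForecast:
    """Hazard-quotient forecast: distribution, summaries and control band.

    ``hq_distribution`` is the ratio distribution re-binned onto
    ``hq_bin_edges`` (HQ in %); the mean and the equal-tailed 90% interval
    are computed on the un-binned ratio atoms. Concentration and OEL means
    and 90% intervals (μg/m³) are carried for heat-map coordinates.
    """

    hq_bin_edges: tuple[float, ...]
    hq_distribution: tuple[float, ...]
    mean_hq: float
    interval_90: tuple[float, float]
    band: str
    mean_concentration: float
    mean_oel: float
    concentration_interval_90: tuple[float, float]
    oel_interval_90: tuple[float, float]
    hq_atoms: tuple[tuple[float, float], ...] = field(default=(), repr=False)

    def to_dict(self) -> dict:
        return {
            "mean_hq_percent": self.mean_hq,
            "hq_interval_90_percent": list(self.interval_90),
            "band": self.band,
            "mean_concentration_ugm3": self.mean_concentration,
            "concentration_interval_90_ugm3": list(self.concentration_interval_90),
            "mean_oel_ugm3": self.mean_oel,
            "oel_interval_90_ugm3": list(self.oel_interval_90),
            "hq_bin_edges_percent": list(self.hq_bin_edges),
            "hq_distribution": list(self.hq_distribution),
        }


def _default_hq_grid(atoms: np.ndarray) -> np.ndarray:
    lo = max(min(atoms.min() * 0.999, 0.1), 1e-6)
    hi = max(atoms.max() * 1.001, lo * 10)
    return np.geomspace(lo, hi, 41)


def classify_risk(forecast: "HQForecast | float") -> str:
    """Control band for a forecast (by its mean HQ) or a bare HQ in %.

    Bands: negligible (< 10%), caution (10–100%), potential risk
    (> 100%, ≤ 1000%), high risk (> 1000%). The potential-risk threshold
    is strictly above 100%: HQ of exactly 100% is still acceptable.
    """
    hq = forecast.mean_hq if isinstance(forecast, HQForecast) else float(forecast)
    if hq < 0:
        raise ValueError("HQ cannot be negative")
    if hq < 10.0:
        return "negligible"
    if hq <= 100.0:
        return "caution"
    if hq <= 1000.0:
        return "potential risk"
    return "high risk"


def hazard_quotient(
    exposure: DiscreteDistribution,
    oel: DiscreteDistribution,
    hq_bin_edges=None,
) -> HQForecast:
    """Forecast HQ = concentration / OEL from two discrete distributions.

    The exposure and OEL distributions are combined as independent (their
    evidence paths are separate once the physicochemical evidence and CMR
    are instantiated — an approximation documented in the methods note):
    every pairwise ratio c_i/o_j gets weight p_i·q_j. The mean and
    equal-tailed 5%/95% quantiles are taken on this atom set; the reported
    distribution is re-binned onto an HQ grid (geometric by default).
    """
    if any(v <= 0 for v in oel.values):
        raise NanoriskError("OEL distribution has mass on a non-positive value")
    c = np.asarray(exposure.values)
    o = np.asarray(oel.values)
    pc = np.asarray(exposure.probs)
    po = np.asarray(oel.probs)

    ratios = (c[:, None] / o[None, :]).ravel() * 100.0  # %
    weights = (pc[:, None] * po[None, :]).ravel()
    keep = weights > 0
    ratios, weights = ratios[keep], weights[keep]
    order = np.argsort(ratios, kind="stable")
    ratios, weights = ratios[order], weights[order]

    mean_hq = float(np.dot(ratios, weights))
    cdf = np.cumsum(weights)
    lo = float(ratios[np.searchsorted(cdf, 0.05 - 1e-12, side="left")])
    hi = float(ratios[min(np.searchsorted(cdf, 0.95 - 1e-12, side="left"), ratios.size - 1)])

    if hq_bin_edges is None:
        edges = _default_hq_grid(ratios)
    else:
        edges = np.asarray(hq_bin_edges, dtype=float)
    # clamp outliers into the end bins
    clipped = np.clip(ratios, edges[0], edges[-1])
    idx = np.clip(np.searchsorted(edges, clipped, side="right") - 1, 0, len(edges) - 2)
    dist = np.zeros(len(edges) - 1)
    np.add.at(dist, idx, weights)
    dist /= dist.sum()

    return HQForecast(
        hq_bin_edges=tuple(float(e) for e in edges),
        hq_distribution=tuple(float(p) for p in dist),
        mean_hq=mean_hq,
        interval_90=(lo, hi),
        band=classify_risk(mean_hq),
        mean_concentration=exposure.mean,
        mean_oel=oel.mean,
        concentration_interval_90=exposure.interval(0.90),
        oel_interval_90=oel.interval(0.90),
        hq_atoms=tuple(zip((float(r) for r in ratios), (float(w) for w in weights))),
    )


# ---------------------------------------------------------------------------
# exposure


def exposure_posterior(
    net: NetworkSpec, evidence=None, variable: str = CONCENTRATION
) -> np.ndarray:
    """Posterior over airborne-concentration bins given evidence."""
    if variable not in net.names:
        raise NanoriskError(f"network has no variable {variable!r}")
    return posterior_marginals(net, evidence)[variable]


def concentration_distribution(
    net: NetworkSpec, evidence=None, variable: str = CONCENTRATION
) -> DiscreteDistribution:
    """Exposure posterior collapsed onto bin representatives (μg/m³)."""
    var = net.variable(variable)
    if var.bin_edges is None:
        raise NanoriskError(f"{variable!r} carries no bin edges")
    return DiscreteDistribution.from_bins(
        var.bin_edges, exposure_posterior(net, evidence, variable)
    )


def oel_distribution(
    net: NetworkSpec, evidence=None, variable: str = OEL
) -> DiscreteDistribution:
    """Network OEL posterior collapsed onto bin representatives (μg/m³)."""
    var = net.variable(variable)
    if var.bin_edges is None:
        raise NanoriskError(f"{variable!r} carries no bin edges")
    return DiscreteDistribution.from_bins(
        var.bin_edges, posterior_marginals(net, evidence)[variable]
    )


# ---------------------------------------------------------------------------
# heat-map coordinates


@dataclass(frozen=True)
class HeatmapPoint:
    """One material's position on the control-banding heat map.

    x is the mean OEL, y the mean airborne concentration (both μg/m³, the
    estimated mean values); the interval fields are the 90% credible
    endpoints drawn as dashed (OEL) and solid (concentration) lines.
    """

    x_mean_oel: float
    y_mean_concentration: float
    band: str
    x_interval_90: tuple[float, float]
    y_interval_90: tuple[float, float]
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "x_mean_oel_ugm3": self.x_mean_oel,
            "y_mean_concentration_ugm3": self.y_mean_concentration,
            "band": self.band,
            "x_interval_90_ugm3": list(self.x_interval_90),
            "y_interval_90_ugm3": list(self.y_interval_90),
        }


def heatmap_point(forecast: HQForecast, label: str = "") -> HeatmapPoint:
    """Heat-map coordinates of a forecast: mean OEL vs mean concentration."""
    return HeatmapPoint(
        x_mean_oel=forecast.mean_oel,
        y_mean_concentration=forecast.mean_concentration,
        band=forecast.band,
        x_interval_90=forecast.oel_interval_90,
        y_interval_90=forecast.concentration_interval_90,
        label=label,
    )


def render_heatmap(points: list[HeatmapPoint], path: str) -> None:
    """Render control-banding heat map to a PNG: log-log OEL vs
    concentration plane shaded by HQ band, one point per material with its
    90% interval lines (dashed for OEL, solid for concentration)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    xs = [p.x_mean_oel for p in points] or [1.0]
    ys = [p.y_mean_concentration for p in points] or [1.0]
    lo = min(min(xs), min(ys)) / 30
    hi = max(max(xs), max(ys)) * 30
    grid = np.geomspace(lo, hi, 200)
    ox, cy = np.meshgrid(grid, grid)
    hq = cy / ox * 100.0
    levels = [0, 10, 100, 1000, max(1e9, float(hq.max()) * 2)]
    colors = ["#2d8a43", "#cbd152", "#e08a2e", "#b3272d"]
    ax.contourf(ox, cy, hq, levels=levels, colors=colors, alpha=0.35)
    for p in points:
        ax.plot([p.x_interval_90[0], p.x_interval_90[1]], [p.y_mean_concentration] * 2,
                linestyle="--", color="k", lw=1)
        ax.plot([p.x_mean_oel] * 2, [p.y_interval_90[0], p.y_interval_90[1]],
                linestyle="-", color="k", lw=1)
        ax.scatter([p.x_mean_oel], [p.y_mean_concentration], zorder=5)
        if p.label:
            ax.annotate(p.label, (p.x_mean_oel, p.y_mean_concentration),
                        textcoords="offset points", xytext=(5, 5))
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("OEL (μg/m³), dashed = 90% interval")
    ax.set_ylabel("NM concentration in air (μg/m³), solid = 90% interval")
    ax.set_title("Control-banding heat map (HQ bands)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
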