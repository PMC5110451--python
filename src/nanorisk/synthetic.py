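"""Ground-truth networks and NIOSH-like synthetic case tables.

The real case tables behind the default networks were assembled from
occupational-exposure reports and project databases that cannot be
redistributed; this module generates statistical stand-ins: ancestral
samples from a fully known ground-truth network, masked completely at
random to emulate the heavy missingness of literature-derived rows. The
default fixture sizes mirror the real collections (46 CNT, 39 Ag and 55
TiO₂ rows) at a default missing rate of 0.30. Everything downstream —
EM learning, experience updating, risk forecasting, out-of-sample
calibration — is exercised end-to-end on these fixtures with no external
input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, NetworkError, ZeroProbabilityError
from .inference import Evidence, eliminate
from .materials import CONCENTRATION, MATERIALS, build_material_network
from .network import NetworkSpec, validate_network

#: Row counts of the literature-derived collections the fixtures emulate.
DEFAULT_ROWS = {"CNT": 46, "Ag": 39, "TiO2": 55}

DEFAULT_MISSING_RATE = 0.30


@dataclass
class FixtureSpec:
    """Recipe for one synthetic case table.

    ``column_weights`` optionally skews missingness across variables
    (relative weights, rescaled so the mean cell-masking probability stays
    ``missing_rate``); by default every cell is masked independently with
    probability ``missing_rate`` (MCAR).
    """

    material: str = "CNT"
    n_rows: int | None = None
    missing_rate: float = DEFAULT_MISSING_RATE
    seed: int = 0
    truth: NetworkSpec | None = None
    column_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rows is None:
            self.n_rows = DEFAULT_ROWS.get(self.material, 50)
        if self.n_rows < 1:
            raise DataError("n_rows must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise DataError("missing_rate must be in [0, 1)")
        if self.truth is None:
            self.truth = truth_network(self.material)


def truth_network(material: str) -> NetworkSpec:
    """Fully parameterized ground-truth network for a material.

    The three materials share one structure and differ only in CPT
    parameterization (see :mod:`nanorisk.materials`)."""
    if material not in MATERIALS:
        raise KeyError(f"unknown material {material!r}; expected one of {MATERIALS}")
    return build_material_network(material)


def sample_cases(
    net: NetworkSpec, n_rows: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Forward (ancestral) sampling of complete cases, topological order."""
    net = validate_network(net)
    order = net.topological_order()
    cards = net.cards
    drawn: dict[str, np.ndarray] = {}
    for name in order:
        cpt = net.cpts[name]
        if cpt.parents:
            pcards = [cards[p] for p in cpt.parents]
            cfg = np.ravel_multi_index(
                tuple(drawn[p] for p in cpt.parents), pcards
            )
        else:
            cfg = np.zeros(n_rows, dtype=int)
        u = rng.random(n_rows)
        cum = np.cumsum(cpt.table, axis=1)
        idx = (u[:, None] > cum[cfg]).sum(axis=1)
        drawn[name] = np.minimum(idx, cards[name] - 1)
    data = {
        name: [net.variable(name).states[i] for i in drawn[name]]
        for name in net.names
    }
    return pd.DataFrame(data, columns=net.names)


def generate_cases(fix: FixtureSpec) -> pd.DataFrame:
    """Sample a case table from the fixture's truth and mask cells MCAR.

    Deterministic: identical ``FixtureSpec`` (including seed) gives a
    byte-identical table.
    """
    rng = np.random.default_rng(fix.seed)
    net = validate_network(fix.truth)
    table = sample_cases(net, fix.n_rows, rng)
    if fix.missing_rate > 0:
        names = list(table.columns)
        w = np.array([fix.column_weights.get(n, 1.0) for n in names], dtype=float)
        if np.any(w < 0):
            raise DataError("column weights must be non-negative")
        rates = np.clip(fix.missing_rate * w * len(names) / w.sum(), 0.0, 0.999)
        mask = rng.random(table.shape) < rates[None, :]
        table = table.mask(pd.DataFrame(mask, columns=names), other=np.nan)
    return table


# ---------------------------------------------------------------------------
# predictive sets and out-of-sample calibration


def predictive_set(probs: np.ndarray, level: float = 0.90) -> list[int]:
    """Smallest set of states whose posterior mass reaches ``level``.

    States are added in decreasing posterior probability (ties broken by
    index), so the set is the discrete highest-mass credible set; because
    mass comes in lumps the attained level is ≥ the nominal one —
    conservative coverage.
    """
    probs = np.asarray(probs, dtype=float)
    order = np.lexsort((np.arange(probs.size), -probs))
    cum = 0.0
    chosen: list[int] = []
    for k in order:
        chosen.append(int(k))
        cum += probs[k]
        if cum >= level - 1e-12:
            break
    return sorted(chosen)


@dataclass(frozen=True)
class CoverageReport:
    """Empirical calibration of nominal-90% predictive concentration sets."""

    n_test: int
    coverage: float  # fraction of cases whose true bin was in the set
    mean_set_size: float
    nominal_level: float

    @property
    def coverage_percent(self) -> float:
        return 100.0 * self.coverage


def out_of_sample_check(
    truth: NetworkSpec,
    fitted: NetworkSpec,
    n_test: int,
    seed: int,
    target: str = CONCENTRATION,
    level: float = 0.90,
) -> CoverageReport:
    """Out-of-sample calibration of the fitted model's credible sets.

    Samples ``n_test`` fresh complete cases from ``truth``, hides the
    target (concentration) value of each, conditions the *fitted* network
    on every other cell, and checks whether the true bin falls in the
    fitted model's smallest ≥``level`` posterior-mass set.
    """
    if n_test < 1:
        raise DataError("n_test must be >= 1")
    truth = validate_network(truth)
    fitted = validate_network(fitted)
    if truth.names != fitted.names or sorted(truth.edges) != sorted(fitted.edges):
        raise NetworkError("truth and fitted networks must share structure")
    if target not in truth.names:
        raise NetworkError(f"no target variable {target!r}")

    rng = np.random.default_rng(seed)
    cases = sample_cases(truth, n_test, rng)
    var = fitted.variable(target)
    hits = 0
    sizes = 0
    for _, row in cases.iterrows():
        true_state = row[target]
        evidence = {k: v for k, v in row.items() if k != target}
        ev_idx = Evidence(evidence).to_indices(fitted)
        f = eliminate(fitted, ev_idx, {target})
        vec = f.align((target,))
        z = float(vec.sum())
        if z <= 0.0:
            raise ZeroProbabilityError(
                "a truth-sampled case has probability zero under the fitted model"
            )
        chosen = predictive_set(vec / z, level)
        sizes += len(chosen)
        if var.states.index(true_state) in chosen:
            hits += 1
    return CoverageReport(
        n_test=n_test,
        coverage=hits / n_test,
        mean_set_size=sizes / n_test,
        nominal_level=level,
    )
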