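"""Default CNT / Ag / TiO₂ networks.

Each network shares one expert-elicited skeleton: twelve physicochemical
characteristics (particle size, surface area, chemical reactivity, surface
charge, solubility, morphology, coating, degree of
aggregation/agglomeration, dispersibility, pH, contamination and CMR
classification), an airborne-concentration exposure node, and an
occupational-exposure-limit (OEL) node driven by the CMR flag. The three
materials differ only in CPT parameterization: priors for solubility,
morphology and CMR, and the scale of the airborne-concentration model,
chosen so that mean hazard quotients under empty evidence follow
``MATERIAL_RISK_ORDER``.

The structure encodes the causal story: coating and pH set the surface
charge; charge controls agglomeration (near-neutral particles aggregate);
aggregation grows the effective particle size and, with coating, sets
dispersibility; size and morphology determine specific surface area;
coating and contamination drive chemical reactivity; dispersibility and
solubility drive how much material becomes airborne; the CMR flag switches
the OEL between a strict (carcinogen) and a lenient regime. Edge and CPT
choices beyond this are editable defaults, not measured facts: load,
modify and re-save the JSON to encode your own elicitation.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .network import (
    CPT,
    NetworkSpec,
    VariableSpec,
    bin_representatives,
    interval_state_labels,
    make_concentration_bins,
    validate_network,
)

CONCENTRATION = "NMs Concentration in Air"
OEL = "OEL"

#: Materials ordered by increasing mean hazard quotient of their default
#: networks under empty evidence (a fixture convention, configurable here).
MATERIAL_RISK_ORDER: tuple[str, ...] = ("CNT", "Ag", "TiO2")

#: Default airborne-concentration discretization: 0–1000 μg/m³, 8 bins,
#: widths doubling left to right (finest resolution over the 1–50 μg/m³
#: range where recommended nanomaterial OELs live).
CONCENTRATION_EDGES = make_concentration_bins(0.0, 1000.0, 8, growth=2.0)

OEL_EDGES = (1.0, 5.0, 25.0, 100.0, 1000.0)

PARTICLE_SIZE_EDGES = (1.0, 50.0, 150.0, 1000.0)

# Material-specific parameterization. conc_median_base is the median
# airborne concentration (μg/m³) at the reference parent configuration.
_MATERIAL_PARAMS = {
    "CNT": dict(
        conc_median_base=3.0,
        cmr_prior=0.5,
        solubility_prior=(0.80, 0.15, 0.05),
        morphology_prior=(0.05, 0.85, 0.10),
    ),
    "Ag": dict(
        conc_median_base=20.0,
        cmr_prior=0.5,
        solubility_prior=(0.20, 0.40, 0.40),
        morphology_prior=(0.70, 0.05, 0.25),
    ),
    "TiO2": dict(
        conc_median_base=140.0,
        cmr_prior=0.5,
        solubility_prior=(0.70, 0.20, 0.10),
        morphology_prior=(0.55, 0.05, 0.40),
    ),
}

MATERIALS = tuple(_MATERIAL_PARAMS)


def graded_row(n_states: int, loc: float, concentration: float = 6.0) -> np.ndarray:
    """Probability vector over ordered states peaked near fractional
    position ``loc`` in [0, 1]; higher ``concentration`` sharpens the peak."""
    pos = np.arange(n_states) / max(n_states - 1, 1)
    p = np.exp(-concentration * (pos - loc) ** 2)
    return p / p.sum()


def lognormal_bin_probs(
    edges: tuple[float, ...], median: float, sigma: float
) -> np.ndarray:
    """Probabilities of a lognormal(median, sigma) truncated to the binned
    range, one mass per bin. A zero left edge is treated as CDF 0."""
    e = np.asarray(edges, dtype=float)
    cdf = np.where(e > 0, norm.cdf((np.log(np.where(e > 0, e, 1.0)) - np.log(median)) / sigma), 0.0)
    p = np.diff(cdf)
    total = p.sum()
    if total <= 0:
        raise ValueError("lognormal mass entirely outside the binned range")
    return p / total


def _variables() -> list[VariableSpec]:
    pc = "physicochemical"
    return [
        VariableSpec("Coating", ("uncoated", "coated"), tag=pc),
        VariableSpec("pH", ("acidic", "neutral", "basic"), tag=pc),
        VariableSpec("Contamination", ("low", "high"), tag=pc),
        VariableSpec("Morphology", ("spherical", "elongated", "irregular"), tag=pc),
        VariableSpec("CMR", ("no", "yes"), tag=pc),
        VariableSpec("Solubility", ("low", "medium", "high"), tag=pc),
        VariableSpec("Surface Charge", ("negative", "neutral", "positive"), tag=pc),
        VariableSpec("Degree of Aggregation", ("low", "medium", "high"), tag=pc),
        VariableSpec(
            "Particle Size",
            interval_state_labels(PARTICLE_SIZE_EDGES, "nm"),
            kind="discretized-continuous",
            bin_edges=PARTICLE_SIZE_EDGES,
            tag=pc,
        ),
        VariableSpec("Surface Area", ("low", "medium", "high"), tag=pc),
        VariableSpec("Chemical Reactivity", ("low", "medium", "high"), tag=pc),
        VariableSpec("Dispersibility", ("low", "high"), tag=pc),
        VariableSpec(
            CONCENTRATION,
            interval_state_labels(CONCENTRATION_EDGES, "ug/m3"),
            kind="discretized-continuous",
            bin_edges=CONCENTRATION_EDGES,
            tag="exposure",
        ),
        VariableSpec(
            OEL,
            interval_state_labels(OEL_EDGES, "ug/m3"),
            kind="discretized-continuous",
            bin_edges=OEL_EDGES,
            tag="dose-response",
        ),
    ]


EDGES: list[tuple[str, str]] = [
    ("Coating", "Surface Charge"),
    ("pH", "Surface Charge"),
    ("Coating", "Chemical Reactivity"),
    ("Contamination", "Chemical Reactivity"),
    ("Surface Charge", "Degree of Aggregation"),
    ("Degree of Aggregation", "Particle Size"),
    ("Coating", "Dispersibility"),
    ("Degree of Aggregation", "Dispersibility"),
    ("Particle Size", "Surface Area"),
    ("Morphology", "Surface Area"),
    ("Dispersibility", CONCENTRATION),
    ("Solubility", CONCENTRATION),
    ("CMR", OEL),
]


def _rows(parent_cards: tuple[int, ...], fn) -> np.ndarray:
    """Stack CPT rows produced by fn(parent_state_indices) in row-major
    parent-configuration order."""
    if not parent_cards:
        return np.asarray(fn(()))[None, :]
    rows = []
    for flat in range(int(np.prod(parent_cards))):
        idx = np.unravel_index(flat, parent_cards)
        rows.append(fn(tuple(int(i) for i in idx)))
    return np.asarray(rows)


def build_material_network(material: str) -> NetworkSpec:
    """Fully parameterized default network for CNT, Ag or TiO2."""
    if material not in _MATERIAL_PARAMS:
        raise KeyError(
            f"unknown material {material!r}; expected one of {MATERIALS}"
        )
    prm = _MATERIAL_PARAMS[material]
    cpts: dict[str, CPT] = {}

    # material-specific priors (marginal nodes with explicit CPTs)
    cpts["Morphology"] = CPT("Morphology", (), np.array(prm["morphology_prior"]))
    cpts["CMR"] = CPT("CMR", (), np.array([1 - prm["cmr_prior"], prm["cmr_prior"]]))
    cpts["Solubility"] = CPT("Solubility", (), np.array(prm["solubility_prior"]))
    # Coating, pH, Contamination: no CPT -> validate_network fills uniform.

    # Surface Charge | Coating, pH — acidic pH pushes charge positive,
    # basic negative; a coating damps the spread toward neutral.
    ph_loc = {0: 0.9, 1: 0.5, 2: 0.1}
    cpts["Surface Charge"] = CPT(
        "Surface Charge",
        ("Coating", "pH"),
        _rows((2, 3), lambda i: graded_row(3, ph_loc[i[1]], 5.0 if i[0] == 0 else 2.0)),
    )

    # Chemical Reactivity | Coating, Contamination
    cpts["Chemical Reactivity"] = CPT(
        "Chemical Reactivity",
        ("Coating", "Contamination"),
        _rows(
            (2, 2),
            lambda i: graded_row(3, 0.15 + 0.45 * (i[0] == 0) + 0.30 * i[1], 5.0),
        ),
    )

    # Degree of Aggregation | Surface Charge — near-neutral particles lack
    # electrostatic repulsion and agglomerate.
    agg_loc = {0: 0.25, 1: 0.85, 2: 0.25}
    cpts["Degree of Aggregation"] = CPT(
        "Degree of Aggregation",
        ("Surface Charge",),
        _rows((3,), lambda i: graded_row(3, agg_loc[i[0]], 5.0)),
    )

    # Particle Size | Degree of Aggregation — more aggregation, larger
    # effective size.
    cpts["Particle Size"] = CPT(
        "Particle Size",
        ("Degree of Aggregation",),
        _rows((3,), lambda i: graded_row(3, 0.2 + 0.325 * i[0], 5.0)),
    )

    # Dispersibility | Coating, Degree of Aggregation
    def disp_row(i):
        p_high = (0.75 if i[0] == 1 else 0.45) + {0: 0.15, 1: 0.0, 2: -0.25}[i[1]]
        p_high = float(np.clip(p_high, 0.05, 0.95))
        return np.array([1 - p_high, p_high])

    cpts["Dispersibility"] = CPT(
        "Dispersibility", ("Coating", "Degree of Aggregation"), _rows((2, 3), disp_row)
    )

    # Surface Area | Particle Size, Morphology — small and elongated
    # particles expose more specific surface.
    cpts["Surface Area"] = CPT(
        "Surface Area",
        ("Particle Size", "Morphology"),
        _rows(
            (3, 3),
            lambda i: graded_row(3, 0.85 - 0.325 * i[0] + 0.10 * (i[1] == 1), 5.0),
        ),
    )

    # Airborne concentration | Dispersibility, Solubility — lognormal over
    # the growing bins; readily dispersed material raises the median,
    # soluble material lowers it (dissolves rather than staying airborne).
    disp_mult = {0: 0.5, 1: 2.0}
    sol_mult = {0: 1.3, 1: 1.0, 2: 0.6}

    def conc_row(i):
        median = prm["conc_median_base"] * disp_mult[i[0]] * sol_mult[i[1]]
        return lognormal_bin_probs(CONCENTRATION_EDGES, median, sigma=1.0)

    cpts[CONCENTRATION] = CPT(
        CONCENTRATION, ("Dispersibility", "Solubility"), _rows((2, 3), conc_row)
    )

    # OEL | CMR — carcinogens draw a strict limit regime.
    def oel_row(i):
        median = 8.0 if i[0] == 1 else 80.0
        return lognormal_bin_probs(OEL_EDGES, median, sigma=0.7)

    cpts[OEL] = CPT(OEL, ("CMR",), _rows((2,), oel_row))

    spec = NetworkSpec(
        name=f"{material} default network",
        variables=_variables(),
        edges=list(EDGES),
        cpts=cpts,
    )
    return validate_network(spec)


def concentration_representatives() -> np.ndarray:
    return bin_representatives(CONCENTRATION_EDGES)


def oel_representatives() -> np.ndarray:
    return bin_representatives(OEL_EDGES)
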