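"""Discrete Bayesian-network definition, validation and discretization.

A network is a DAG of discrete variables. Continuous quantities (airborne
concentration in μg/m³, particle size in nm, the occupational exposure
limit) enter as *discretized-continuous* variables carrying explicit bin
edges; everything else is categorical. Each non-root variable carries a
conditional probability table (CPT) with one probability vector over its
states per joint parent configuration; root ("marginal") variables carry a
single prior row. Parent configurations are indexed row-major in the CPT's
declared parent order (first parent varies slowest).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .errors import CPTError, CycleError, NetworkError

ROW_TOL = 1e-9

KINDS = ("categorical", "discretized-continuous")
TAGS = ("physicochemical", "exposure", "dose-response", "risk")


@dataclass(frozen=True)
class VariableSpec:
    """A single discrete variable.

    Parameters
    ----------
    name:
        Unique identifier.
    states:
        Ordered, unique state labels. For discretized-continuous variables
        state ``k`` denotes the half-open interval
        ``[bin_edges[k], bin_edges[k+1])`` (last bin closed on the right).
    kind:
        ``"categorical"`` or ``"discretized-continuous"``.
    bin_edges:
        Strictly increasing edges, length ``len(states) + 1``; required iff
        the variable is discretized-continuous. Units are whatever the
        variable declares (μg/m³ for airborne concentration and OEL, nm for
        particle size).
    tag:
        Role in the risk pipeline: physicochemical characteristic, exposure,
        dose-response or risk.
    is_marginal:
        True iff the variable has no parents in its network; set during
        validation.
    """

    name: str
    states: tuple[str, ...]
    kind: str = "categorical"
    bin_edges: tuple[float, ...] | None = None
    tag: str = "physicochemical"
    is_marginal: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise NetworkError("variable name must be non-empty")
        if not self.states:
            raise NetworkError(f"variable {self.name!r}: states must be non-empty")
        if len(set(self.states)) != len(self.states):
            raise NetworkError(f"variable {self.name!r}: duplicate state labels")
        if self.kind not in KINDS:
            raise NetworkError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        if self.tag not in TAGS:
            raise NetworkError(f"variable {self.name!r}: unknown tag {self.tag!r}")
        if self.kind == "discretized-continuous":
            if self.bin_edges is None:
                raise NetworkError(
                    f"variable {self.name!r}: discretized-continuous requires bin_edges"
                )
            edges = tuple(float(e) for e in self.bin_edges)
            if len(edges) != len(self.states) + 1:
                raise NetworkError(
                    f"variable {self.name!r}: need {len(self.states) + 1} bin edges, "
                    f"got {len(edges)}"
                )
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise NetworkError(
                    f"variable {self.name!r}: bin edges must be strictly increasing"
                )
            object.__setattr__(self, "bin_edges", edges)
        elif self.bin_edges is not None:
            raise NetworkError(
                f"variable {self.name!r}: bin_edges only valid for "
                "discretized-continuous variables"
            )
        object.__setattr__(self, "states", tuple(self.states))

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def state_index(self, label: str) -> int:
        """Index of an exact (case-sensitive) state label."""
        try:
            return self.states.index(label)
        except ValueError:
            raise NetworkError(
                f"variable {self.name!r}: unknown state label {label!r}"
            ) from None


@dataclass
class CPT:
    """Conditional probability table for one variable.

    ``table`` has shape ``(n_parent_configs, n_child_states)``; the parent
    configuration index is ``np.ravel_multi_index(parent_state_indices,
    parent_cardinalities)`` in the declared parent order.
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim == 1:
            self.table = self.table[None, :]
        if self.table.ndim != 2:
            raise CPTError(f"CPT for {self.child!r}: table must be 2-D")

    @property
    def n_configs(self) -> int:
        return self.table.shape[0]

    def validate(self, cards: dict[str, int]) -> None:
        if self.child not in cards:
            raise CPTError(f"CPT child {self.child!r} is not a network variable")
        for p in self.parents:
            if p not in cards:
                raise CPTError(
                    f"CPT for {self.child!r}: parent {p!r} is not a network variable"
                )
        expected_rows = int(np.prod([cards[p] for p in self.parents], dtype=int)) if self.parents else 1
        if self.table.shape != (expected_rows, cards[self.child]):
            raise CPTError(
                f"CPT for {self.child!r}: expected shape "
                f"({expected_rows}, {cards[self.child]}), got {self.table.shape}"
            )
        if np.any(self.table < -ROW_TOL) or np.any(self.table > 1 + ROW_TOL):
            raise CPTError(f"CPT for {self.child!r}: entries outside [0, 1]")
        sums = self.table.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > ROW_TOL)
        if bad.size:
            raise CPTError(
                f"CPT for {self.child!r}: row {bad[0]} sums to {sums[bad[0]]!r}, "
                "not 1 within 1e-9"
            )

    def copy(self) -> "CPT":
        return CPT(self.child, self.parents, self.table.copy())


@dataclass
class NetworkSpec:
    """A discrete Bayesian network: variables, edges and CPTs.

    ``experience`` optionally carries, per variable, a non-negative
    equivalent-sample count per parent configuration (see the learning
    module); it travels with the network through serialization.
    """

    name: str
    variables: list[VariableSpec]
    edges: list[tuple[str, str]]
    cpts: dict[str, CPT] = field(default_factory=dict)
    experience: dict[str, np.ndarray] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise NetworkError(f"unknown variable {name!r}")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def cards(self) -> dict[str, int]:
        return {v.name: v.cardinality for v in self.variables}

    def parents(self, name: str) -> tuple[str, ...]:
        if name in self.cpts:
            return self.cpts[name].parents
        return tuple(p for p, c in self.edges if c == name)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        g.add_edges_from(self.edges)
        return g

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph()))

    def state_space_size(self) -> int:
        return int(np.prod([v.cardinality for v in self.variables], dtype=object))

    def copy(self) -> "NetworkSpec":
        return NetworkSpec(
            name=self.name,
            variables=list(self.variables),
            edges=list(self.edges),
            cpts={k: c.copy() for k, c in self.cpts.items()},
            experience={k: np.asarray(v, dtype=float).copy() for k, v in self.experience.items()},
        )

    def parent_config_index(self, child: str, parent_states: dict[str, int]) -> int:
        """Row index in ``cpts[child].table`` for given parent state indices."""
        parents = self.parents(child)
        if not parents:
            return 0
        cards = self.cards
        idx = tuple(parent_states[p] for p in parents)
        return int(np.ravel_multi_index(idx, [cards[p] for p in parents]))


def validate_network(spec: NetworkSpec) -> NetworkSpec:
    """Validate a network and return a normalized copy.

    Checks acyclicity, exact agreement between the edge list and every
    CPT's parent list, row normalization within 1e-9, and fills marginal
    (parentless) variables that lack an explicit CPT with uniform priors —
    the convention for unbiased parameterization when knowledge is lacking.
    Idempotent: validating a validated network is a no-op.
    """
    names = [v.name for v in spec.variables]
    if len(set(names)) != len(names):
        raise NetworkError("duplicate variable names")
    known = set(names)
    for p, c in spec.edges:
        if p not in known or c not in known:
            raise NetworkError(f"edge ({p!r}, {c!r}) references unknown variable")
    if len(set(spec.edges)) != len(spec.edges):
        raise NetworkError("duplicate edges")

    g = nx.DiGraph()
    g.add_nodes_from(names)
    g.add_edges_from(spec.edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise CycleError(f"network contains a directed cycle: {cycle}")

    cards = {v.name: v.cardinality for v in spec.variables}
    edge_parents = {n: tuple(sorted(p for p, c in spec.edges if c == n)) for n in names}

    cpts: dict[str, CPT] = {}
    for name in names:
        if name in spec.cpts:
            cpt = spec.cpts[name].copy()
            if tuple(sorted(cpt.parents)) != edge_parents[name]:
                raise NetworkError(
                    f"CPT for {name!r} declares parents {cpt.parents}, but the edge "
                    f"list implies {edge_parents[name]}"
                )
            cpt.validate(cards)
            # renormalize within-tolerance rows; skip already-exact ones so
            # validation is idempotent to the last bit
            cpt.table = np.clip(cpt.table, 0.0, None)
            sums = cpt.table.sum(axis=1, keepdims=True)
            off = np.abs(sums - 1.0)[:, 0] > 1e-12
            cpt.table[off] /= sums[off]
            cpts[name] = cpt
        else:
            if edge_parents[name]:
                raise NetworkError(f"non-marginal variable {name!r} lacks a CPT")
            cpts[name] = CPT(name, (), np.full((1, cards[name]), 1.0 / cards[name]))

    variables = [
        replace(v, is_marginal=not edge_parents[v.name]) for v in spec.variables
    ]

    experience: dict[str, np.ndarray] = {}
    for name, counts in spec.experience.items():
        if name not in known:
            raise NetworkError(f"experience table references unknown variable {name!r}")
        arr = np.asarray(counts, dtype=float)
        if arr.shape != (cpts[name].n_configs,):
            raise NetworkError(
                f"experience for {name!r}: expected {cpts[name].n_configs} counts, "
                f"got shape {arr.shape}"
            )
        if np.any(arr < 0):
            raise NetworkError(f"experience for {name!r}: negative counts")
        experience[name] = arr.copy()

    return NetworkSpec(spec.name, variables, list(spec.edges), cpts, experience)


# -- discretization helpers ---------------------------------------------


def make_concentration_bins(
    lower: float, upper: float, n_bins: int, growth: float = 2.0
) -> tuple[float, ...]:
    """Bin edges whose widths grow geometrically from the left tail.

    Successive bin widths multiply by ``growth``; with ``growth > 1``
    granularity concentrates at low values, where airborne-concentration
    observations are most likely. ``growth = 1`` gives equal widths.

    Returns ``n_bins + 1`` strictly increasing edges spanning exactly
    ``[lower, upper]``.
    """
    if not upper > lower:
        raise ValueError(f"need lower < upper, got [{lower}, {upper}]")
    if n_bins < 2:
        raise ValueError(f"need n_bins >= 2, got {n_bins}")
    if growth < 1:
        raise ValueError(f"need growth >= 1, got {growth}")
    span = upper - lower
    if growth == 1:
        widths = np.full(n_bins, span / n_bins)
    else:
        w0 = span * (growth - 1.0) / (growth**n_bins - 1.0)
        widths = w0 * growth ** np.arange(n_bins)
    edges = lower + np.concatenate([[0.0], np.cumsum(widths)])
    edges[-1] = upper  # kill accumulation error
    return tuple(float(e) for e in edges)


def assign_bin(value: float, edges: tuple[float, ...] | list[float]) -> int:
    """Bin index for a value: half-open ``[lo, hi)`` bins, last bin closed.

    ``value == edges[0]`` maps to bin 0; ``value == edges[-1]`` maps to the
    last bin; anything outside ``[edges[0], edges[-1]]`` is an error.
    """
    edges = np.asarray(edges, dtype=float)
    if value < edges[0] or value > edges[-1]:
        raise ValueError(
            f"value {value} outside the binned range [{edges[0]}, {edges[-1]}]"
        )
    if value == edges[-1]:
        return len(edges) - 2
    return int(np.searchsorted(edges, value, side="right") - 1)


def bin_representatives(edges: tuple[float, ...] | list[float]) -> np.ndarray:
    """One representative value per bin for expectation and ratio arithmetic.

    Geometric midpoint √(lo·hi) for strictly positive bins — the natural
    choice for width-growing bins, reducing bias in ratio quantities — and
    the arithmetic midpoint when the bin touches zero (or is non-positive).
    """
    edges = np.asarray(edges, dtype=float)
    lo, hi = edges[:-1], edges[1:]
    reps = np.where(lo > 0, np.sqrt(np.clip(lo, 0, None) * hi), (lo + hi) / 2.0)
    return reps


def interval_state_labels(edges: tuple[float, ...], unit: str = "") -> tuple[str, ...]:
    """Human-readable state labels like ``"[0, 3.92)"`` for binned variables."""

    def fmt(x: float) -> str:
        if x == int(x) and abs(x) < 1e15:
            return str(int(x))
        return f"{x:.4g}"

    labels = []
    n = len(edges) - 1
    for k in range(n):
        close = "]" if k == n - 1 else ")"
        suffix = f" {unit}" if unit else ""
        labels.append(f"[{fmt(edges[k])}, {fmt(edges[k + 1])}{close}{suffix}")
    return tuple(labels)


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats of a probability vector (0 log 0 := 0)."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum()) if nz.size else 0.0
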