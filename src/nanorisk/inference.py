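"""Exact posterior inference on discrete networks.

Two routes compute the same marginals: ``posterior_marginals`` runs
variable elimination (min-fill ordering, lexicographic tie-break) and is
the production path; ``joint_enumeration`` materializes the full joint
table and is retained purely as a brute-force correctness oracle for
small networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EvidenceError, ZeroProbabilityError
from .network import NetworkSpec


@dataclass(frozen=True)
class Evidence:
    """Observed variable states: a map from variable name to state label."""

    assignments: dict[str, str]

    def to_indices(self, net: NetworkSpec) -> dict[str, int]:
        out = {}
        for name, label in self.assignments.items():
            try:
                var = net.variable(name)
            except Exception:
                raise EvidenceError(f"evidence names unknown variable {name!r}") from None
            if label not in var.states:
                raise EvidenceError(
                    f"evidence {name!r}={label!r}: not one of {var.states}"
                )
            out[name] = var.states.index(label)
        return out


def _as_evidence_indices(net: NetworkSpec, evidence) -> dict[str, int]:
    if evidence is None:
        return {}
    if isinstance(evidence, Evidence):
        return evidence.to_indices(net)
    if isinstance(evidence, dict):
        return Evidence(dict(evidence)).to_indices(net)
    raise EvidenceError(f"unsupported evidence object: {type(evidence)!r}")


class Factor:
    """A non-negative table over a tuple of named discrete variables."""

    __slots__ = ("vars", "values")

    def __init__(self, variables: tuple[str, ...], values: np.ndarray):
        self.vars = tuple(variables)
        self.values = np.asarray(values, dtype=float)
        assert self.values.ndim == len(self.vars)

    def _expand(self, union: tuple[str, ...]) -> np.ndarray:
        src = {v: i for i, v in enumerate(self.vars)}
        present = [v for v in union if v in src]
        arr = np.transpose(self.values, [src[v] for v in present])
        shape_iter = iter(arr.shape)
        shape = tuple(next(shape_iter) if v in src else 1 for v in union)
        return arr.reshape(shape)

    def __mul__(self, other: "Factor") -> "Factor":
        union = self.vars + tuple(v for v in other.vars if v not in self.vars)
        return Factor(union, self._expand(union) * other._expand(union))

    def sum_out(self, var: str) -> "Factor":
        i = self.vars.index(var)
        return Factor(self.vars[:i] + self.vars[i + 1 :], self.values.sum(axis=i))

    def reduce(self, var: str, state: int) -> "Factor":
        if var not in self.vars:
            return self
        i = self.vars.index(var)
        return Factor(
            self.vars[:i] + self.vars[i + 1 :], np.take(self.values, state, axis=i)
        )

    def align(self, order: tuple[str, ...]) -> np.ndarray:
        """Values transposed into the given variable order (must be a permutation)."""
        assert set(order) == set(self.vars)
        src = {v: i for i, v in enumerate(self.vars)}
        return np.transpose(self.values, [src[v] for v in order])


def cpt_factor(net: NetworkSpec, name: str) -> Factor:
    cpt = net.cpts[name]
    cards = net.cards
    shape = tuple(cards[p] for p in cpt.parents) + (cards[name],)
    return Factor(cpt.parents + (name,), cpt.table.reshape(shape))


def _min_fill_order(factor_scopes: list[set[str]], elim: set[str]) -> list[str]:
    """Elimination order by the min-fill heuristic, ties broken by name."""
    neighbors: dict[str, set[str]] = {v: set() for s in factor_scopes for v in s}
    for scope in factor_scopes:
        for v in scope:
            neighbors[v] |= scope - {v}
    order = []
    remaining = set(elim)
    while remaining:
        best = None
        best_fill = None
        for v in sorted(remaining):
            nbrs = neighbors[v] & (set(neighbors) - {v})
            fill = sum(
                1
                for a in nbrs
                for b in nbrs
                if a < b and b not in neighbors[a]
            )
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        order.append(best)
        remaining.discard(best)
        nbrs = neighbors.pop(best)
        for a in nbrs:
            neighbors[a] |= nbrs - {a}
            neighbors[a].discard(best)
    return order


def eliminate(
    net: NetworkSpec, evidence_idx: dict[str, int], keep: set[str]
) -> Factor:
    """Unnormalized factor over ``keep`` after observing evidence.

    The factor's total mass equals P(evidence); keep = ∅ yields a scalar
    factor carrying exactly that normalizer.
    """
    factors = []
    for name in net.names:
        f = cpt_factor(net, name)
        for ev_var, ev_state in evidence_idx.items():
            f = f.reduce(ev_var, ev_state)
        factors.append(f)

    elim = {v for f in factors for v in f.vars} - set(keep)
    order = _min_fill_order([set(f.vars) for f in factors], elim)

    for var in order:
        related = [f for f in factors if var in f.vars]
        factors = [f for f in factors if var not in f.vars]
        prod = related[0]
        for f in related[1:]:
            prod = prod * f
        factors.append(prod.sum_out(var))

    result = Factor((), np.array(1.0))
    for f in factors:
        result = result * f
    return result


def posterior_marginals(net: NetworkSpec, evidence=None) -> dict[str, np.ndarray]:
    """Posterior marginal of every variable given evidence, by variable
    elimination.

    Observed variables get a point mass on their observed state. Raises
    :class:`ZeroProbabilityError` if the evidence is impossible under the
    network.
    """
    ev = _as_evidence_indices(net, evidence)
    cards = net.cards
    out: dict[str, np.ndarray] = {}
    z = None
    for name in net.names:
        if name in ev:
            vec = np.zeros(cards[name])
            vec[ev[name]] = 1.0
            out[name] = vec
            continue
        f = eliminate(net, ev, {name})
        vec = f.align((name,))
        z = float(vec.sum())
        if not np.isfinite(z):
            raise FloatingPointError("non-finite normalizer in variable elimination")
        if z <= 0.0:
            raise ZeroProbabilityError(
                f"evidence {evidence!r} has probability zero under network "
                f"{net.name!r}"
            )
        out[name] = vec / z
    if z is None and ev:  # all variables observed: check consistency
        z = float(eliminate(net, ev, set()).values)
        if z <= 0.0:
            raise ZeroProbabilityError(
                f"evidence {evidence!r} has probability zero under network "
                f"{net.name!r}"
            )
    return out


def log_evidence(net: NetworkSpec, evidence=None) -> float:
    """log P(evidence) under the network."""
    ev = _as_evidence_indices(net, evidence)
    z = float(eliminate(net, ev, set()).values)
    if z <= 0.0:
        raise ZeroProbabilityError(f"evidence {evidence!r} has probability zero")
    return float(np.log(z))


MAX_ENUMERATION_CONFIGS = 1_000_000


def joint_enumeration(net: NetworkSpec, evidence=None) -> dict[str, np.ndarray]:
    """Brute-force oracle: marginals by summing the materialized joint.

    Only valid for networks with at most ``MAX_ENUMERATION_CONFIGS`` joint
    configurations; used in tests to certify variable elimination.
    """
    if net.state_space_size() > MAX_ENUMERATION_CONFIGS:
        raise ValueError(
            f"state space {net.state_space_size()} exceeds enumeration limit"
        )
    ev = _as_evidence_indices(net, evidence)
    joint = Factor((), np.array(1.0))
    for name in net.names:
        joint = joint * cpt_factor(net, name)
    for var, state in ev.items():
        joint = joint.reduce(var, state)
    z = float(joint.values.sum())
    if z <= 0.0:
        raise ZeroProbabilityError(f"evidence {evidence!r} has probability zero")
    cards = net.cards
    out: dict[str, np.ndarray] = {}
    for name in net.names:
        if name in ev:
            vec = np.zeros(cards[name])
            vec[ev[name]] = 1.0
            out[name] = vec
        else:
            f = joint
            for other in joint.vars:
                if other != name:
                    f = f.sum_out(other)
            out[name] = f.align((name,)) / z
    return out
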