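"""Parameter learning from incomplete case tables.

Two learning modes:

* :func:`em_fit` — batch expectation–maximization. The E-step runs exact
  inference per case (conditioning on that case's observed cells,
  missingness assumed MCAR) to obtain expected family counts; the M-step
  re-estimates every CPT row from (expected counts + Dirichlet
  pseudo-counts). With complete data and zero prior this reduces exactly to
  the relative-frequency MLE.

* :func:`update_with_cases` — experience-weighted sequential updating. The
  current CPT rows scaled by their *experience* (equivalent-sample) counts
  act as Dirichlet pseudo-counts; a new batch of cases adds its (expected)
  counts and the experience grows by the number of cases absorbed, so the
  sway of new data shrinks as experience accumulates. Partially observed
  cases contribute fractionally, spreading their posterior mass across
  parent configurations.

Case tables are pandas DataFrames whose columns are network variable names
and whose cells hold state labels; empty cells / NaN mean missing. The
CSV convention is a header row of variable names with empty fields for
missing cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ZeroProbabilityError
from .inference import cpt_factor, eliminate
from .network import NetworkSpec, validate_network

#: State-space size up to which the E-step materializes the full joint
#: table once per iteration (fast path; ≲ 40 MB at the limit) instead of
#: running variable elimination per case pattern.
JOINT_TABLE_LIMIT = 5_000_000


# ---------------------------------------------------------------------------
# case-table encoding


def encode_cases(net: NetworkSpec, cases: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Encode a case table as an int matrix over all network variables.

    Returns ``(codes, columns)`` where ``codes`` has one column per network
    variable in network order, entries are state indices and -1 means
    missing (including variables absent from the table). All-missing
    columns are reported with a warning and treated as absent.
    """
    if cases.shape[0] < 1:
        raise DataError("case table has no rows")
    unknown = [c for c in cases.columns if c not in net.names]
    if unknown:
        raise DataError(f"case-table columns not in the network: {unknown}")

    codes = np.full((len(cases), len(net.names)), -1, dtype=np.int64)
    any_observed = False
    for j, name in enumerate(net.names):
        if name not in cases.columns:
            continue
        col = cases[name]
        var = net.variable(name)
        lut = {s: i for i, s in enumerate(var.states)}
        vals = np.full(len(cases), -1, dtype=np.int64)
        observed_any = False
        for i, cell in enumerate(col.tolist()):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
                continue
            if not isinstance(cell, str):
                cell = str(cell)
            if cell not in lut:
                raise DataError(
                    f"row {i}, column {name!r}: {cell!r} is not a valid state label"
                )
            vals[i] = lut[cell]
            observed_any = True
        if not observed_any:
            warnings.warn(
                f"column {name!r} is entirely missing; ignored", stacklevel=2
            )
            continue
        codes[:, j] = vals
        any_observed = True
    if not any_observed:
        raise DataError("case table contains no observed cells")
    return codes, list(net.names)


def _dedupe(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(codes, axis=0, return_counts=True)
    return patterns, counts.astype(float)


# ---------------------------------------------------------------------------
# exact E-step


class _EStep:
    """Expected family counts and log-likelihood under the current CPTs."""

    def __init__(self, net: NetworkSpec):
        self.net = net
        self.names = net.names
        self.cards = [net.cards[n] for n in self.names]
        self.pos = {n: i for i, n in enumerate(self.names)}
        self.families = {
            n: net.cpts[n].parents + (n,) for n in self.names
        }
        self.use_joint = net.state_space_size() <= JOINT_TABLE_LIMIT
        if self.use_joint:
            joint = None
            for n in self.names:
                f = cpt_factor(net, n)
                joint = f if joint is None else joint * f
            self.joint = joint.align(tuple(self.names))

    def _family_marginal(self, pattern: np.ndarray, fam: tuple[str, ...]):
        """Unnormalized marginal over the *hidden* members of ``fam`` given
        the observed cells of ``pattern``, axes in network order."""
        hidden_fam = [v for v in fam if pattern[self.pos[v]] < 0]
        if self.use_joint:
            indexer = tuple(
                int(s) if s >= 0 else slice(None) for s in pattern
            )
            sub = self.joint[indexer]  # axes = hidden vars in net order
            hidden_all = [n for n, s in zip(self.names, pattern) if s < 0]
            drop = tuple(
                ax for ax, v in enumerate(hidden_all) if v not in fam
            )
            marg = sub.sum(axis=drop) if drop else sub
            order = [v for v in hidden_all if v in fam]
        else:
            ev = {
                n: int(s)
                for n, s in zip(self.names, pattern)
                if s >= 0
            }
            f = eliminate(self.net, ev, set(hidden_fam))
            order = sorted(hidden_fam, key=self.pos.__getitem__)
            marg = f.align(tuple(order)) if hidden_fam else np.asarray(f.values)
        return marg, order

    def run(
        self, patterns: np.ndarray, weights: np.ndarray
    ) -> tuple[dict[str, np.ndarray], float]:
        counts = {
            n: np.zeros_like(self.net.cpts[n].table) for n in self.names
        }
        loglik = 0.0
        for pattern, w in zip(patterns, weights):
            if np.all(pattern >= 0):
                # complete case: sufficient statistics need no inference,
                # and zero model probability must not block counting
                logp = 0.0
                for name in self.names:
                    cpt = self.net.cpts[name]
                    cfg = self.net.parent_config_index(
                        name, {p: int(pattern[self.pos[p]]) for p in cpt.parents}
                    )
                    s = int(pattern[self.pos[name]])
                    counts[name][cfg, s] += w
                    p = cpt.table[cfg, s]
                    logp += np.log(p) if p > 0 else -np.inf
                loglik += float(w) * logp
                continue
            z = None
            for name in self.names:
                fam = self.families[name]
                marg, order = self._family_marginal(pattern, fam)
                mass = float(marg.sum())
                if z is None:
                    z = mass
                    if z <= 0.0:
                        raise ZeroProbabilityError(
                            f"case pattern {pattern.tolist()} has probability "
                            "zero under the current parameters"
                        )
                # embed into the full family array (parents..., child)
                fam_cards = tuple(self.cards[self.pos[v]] for v in fam)
                target = np.zeros(fam_cards)
                indexer = tuple(
                    int(pattern[self.pos[v]]) if pattern[self.pos[v]] >= 0 else slice(None)
                    for v in fam
                )
                if order:
                    perm = [order.index(v) for v in fam if pattern[self.pos[v]] < 0]
                    target[indexer] = np.transpose(marg, perm) / z
                else:
                    target[indexer] = mass / z
                counts[name] += w * target.reshape(counts[name].shape)
            loglik += float(w) * float(np.log(z))
        return counts, loglik


# ---------------------------------------------------------------------------
# EM


@dataclass
class FitResult:
    """Outcome of an EM run.

    ``loglik_trace`` records, per iteration, the objective EM ascends:
    the observed-data log-likelihood, plus the Dirichlet log-prior term
    when ``prior_strength > 0`` (at prior strength zero it is the pure
    log-likelihood). The trace is non-decreasing within numerical
    tolerance — the EM guarantee.
    """

    network: NetworkSpec
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def _log_prior(net: NetworkSpec, prior_strength: float) -> float:
    if prior_strength <= 0:
        return 0.0
    total = 0.0
    for name in net.names:
        table = net.cpts[name].table
        total += prior_strength * float(np.log(np.clip(table, 1e-300, None)).sum())
    return total


def em_fit(
    net: NetworkSpec,
    cases: pd.DataFrame,
    prior_strength: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
) -> FitResult:
    """Fit CPTs to an incomplete case table by expectation–maximization.

    Parameters
    ----------
    net:
        Starting network; its current CPTs initialize EM. Rows that are
        exactly uniform receive a seeded jitter of magnitude 0.01 to break
        symmetry.
    cases:
        Case table; empty/NaN cells are missing (MCAR assumed).
    prior_strength:
        Per-cell Dirichlet pseudo-count added in every M-step (default 1,
        add-one smoothing; keeps cells away from the absorbing zero state).
        Set to 0 for the pure maximum-likelihood estimate.
    tol:
        Stop when the relative change of the objective falls below this.
    max_iter:
        Iteration cap.
    seed:
        Seeds the symmetry-breaking jitter only; EM itself is deterministic.
    """
    if prior_strength < 0:
        raise ValueError("prior_strength must be >= 0")
    net = validate_network(net)
    codes, _ = encode_cases(net, cases)
    patterns, weights = _dedupe(codes)

    rng = np.random.default_rng(seed)
    for name in net.names:
        table = net.cpts[name].table
        uniform = np.all(np.abs(table - 1.0 / table.shape[1]) < 1e-12, axis=1)
        if uniform.any():
            jitter = rng.uniform(0, 0.01, size=table.shape)
            table[uniform] += jitter[uniform]
            table /= table.sum(axis=1, keepdims=True)

    result = FitResult(network=net)
    prev_obj = -np.inf
    for it in range(1, max_iter + 1):
        estep = _EStep(net)
        counts, loglik = estep.run(patterns, weights)
        obj = loglik + _log_prior(net, prior_strength)
        result.loglik_trace.append(obj)
        result.n_iter = it
        if np.isfinite(prev_obj) and np.isfinite(obj):
            denom = max(abs(prev_obj), 1.0)
            if (obj - prev_obj) / denom < tol:
                result.converged = True
                break
        elif obj == prev_obj:  # e.g. both -inf: nothing EM can improve
            result.converged = True
            break
        prev_obj = obj

        for name in net.names:
            table = net.cpts[name].table
            new = counts[name] + prior_strength
            totals = new.sum(axis=1, keepdims=True)
            visited = totals[:, 0] > 0
            table[visited] = new[visited] / totals[visited]
    result.network = net
    return result


# ---------------------------------------------------------------------------
# experience-weighted sequential updating


@dataclass
class ExperienceTable:
    """Equivalent-sample counts per variable and parent configuration.

    The count attached to a CPT row measures the confidence in that row:
    after updating on case data it coincides with the (expected) number of
    cases observed in that parent configuration.
    """

    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for name, arr in self.counts.items():
            arr = np.asarray(arr, dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"experience for {name!r}: negative counts")
            clean[name] = arr
        self.counts = clean

    @classmethod
    def zeros(cls, net: NetworkSpec) -> "ExperienceTable":
        return cls({n: np.zeros(net.cpts[n].n_configs) for n in net.names})

    def total(self, name: str) -> float:
        return float(self.counts[name].sum())

    def copy(self) -> "ExperienceTable":
        return ExperienceTable({n: a.copy() for n, a in self.counts.items()})


def update_with_cases(
    net: NetworkSpec,
    exp: ExperienceTable | None,
    cases: pd.DataFrame,
) -> tuple[NetworkSpec, ExperienceTable]:
    """Absorb a batch of cases into the network, weighted by experience.

    Current CPT rows times their experience counts act as Dirichlet
    pseudo-counts; the batch contributes expected counts computed by one
    exact E-pass under the current parameters (complete cases contribute
    exactly one count each). Returns the updated network and the grown
    experience table; with complete data, sequential batches commute with
    concatenation.
    """
    net = validate_network(net)
    if exp is None:
        exp = ExperienceTable.zeros(net)
    if len(cases) == 0:  # nothing to absorb
        return net.copy(), exp.copy()
    for name in net.names:
        if name not in exp.counts:
            raise ValueError(f"experience table lacks variable {name!r}")
        if exp.counts[name].shape != (net.cpts[name].n_configs,):
            raise ValueError(f"experience for {name!r} has the wrong shape")

    codes, _ = encode_cases(net, cases)
    patterns, weights = _dedupe(codes)
    counts, _ = _EStep(net).run(patterns, weights)

    new_net = net.copy()
    new_exp = exp.copy()
    for name in net.names:
        table = new_net.cpts[name].table
        e = exp.counts[name][:, None]
        batch = counts[name]
        n_cfg = batch.sum(axis=1, keepdims=True)
        denom = e + n_cfg
        touched = denom[:, 0] > 0
        table[touched] = (table[touched] * e[touched] + batch[touched]) / denom[touched]
        new_exp.counts[name] = exp.counts[name] + n_cfg[:, 0]
    new_net.experience = {n: new_exp.counts[n].copy() for n in net.names}
    return new_net, new_exp
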