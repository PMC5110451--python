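import numpy as np
import pytest

from nanorisk import CPT, NetworkSpec, VariableSpec, build_material_network, validate_network


@pytest.fixture(scope="session")
def cnt_net():
    return build_material_network("CNT")


def random_network(seed: int, max_nodes: int = 8, max_card: int = 3) -> NetworkSpec:
    """A random small DAG with Dirichlet CPTs, for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_nodes + 1))
    names = [f"X{i}" for i in range(n)]
    cards = rng.integers(2, max_card + 1, size=n)
    variables = [
        VariableSpec(names[i], tuple(f"s{k}" for k in range(cards[i])))
        for i in range(n)
    ]
    edges = []
    parents: dict[str, list[str]] = {nm: [] for nm in names}
    for j in range(1, n):
        k = int(rng.integers(0, min(j, 2) + 1))
        for p in rng.choice(j, size=k, replace=False):
            parents[names[j]].append(names[int(p)])
            edges.append((names[int(p)], names[j]))
    cpts = {}
    for i, nm in enumerate(names):
        ps = tuple(parents[nm])
        n_cfg = int(np.prod([cards[names.index(p)] for p in ps])) if ps else 1
        table = rng.dirichlet(np.full(cards[i], 2.0), size=n_cfg)
        cpts[nm] = CPT(nm, ps, table)
    return validate_network(NetworkSpec(f"random-{seed}", variables, edges, cpts))


def random_evidence(net: NetworkSpec, seed: int, p_observe: float = 0.4) -> dict:
    rng = np.random.default_rng(seed + 1)
    ev = {}
    for v in net.variables:
        if rng.random() < p_observe:
            ev[v.name] = v.states[int(rng.integers(v.cardinality))]
    return ev


def recovery_truth(seed: int = 42) -> NetworkSpec:
    """Six-node ground truth for parameter-recovery experiments.

    Single-parent edges and CPT entries bounded away from 0/1 keep every
    parent configuration well populated at moderate sample sizes.
    """
    rng = np.random.default_rng(seed)
    spec = [
        ("A", 2, ()),
        ("B", 3, ("A",)),
        ("C", 2, ("B",)),
        ("D", 3, ("C",)),
        ("E", 2, ("A",)),
        ("F", 2, ("E",)),
    ]
    cards = {nm: c for nm, c, _ in spec}
    variables = [VariableSpec(nm, tuple(f"s{k}" for k in range(c))) for nm, c, _ in spec]
    edges = [(p, nm) for nm, _, ps in spec for p in ps]
    cpts = {}
    for nm, c, ps in spec:
        n_cfg = int(np.prod([cards[p] for p in ps])) if ps else 1
        table = 0.2 + 0.6 * rng.dirichlet(np.full(c, 5.0), size=n_cfg)
        table /= table.sum(axis=1, keepdims=True)
        cpts[nm] = CPT(nm, tuple(ps), table)
    return validate_network(NetworkSpec("recovery-truth", variables, edges, cpts))
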