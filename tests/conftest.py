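import numpy as np
import pytest

from chemomodules import synthetic_data as sd


@pytest.fixture(scope="session")
def planted_adata():
    """5 modules x 6 genes + 40 background genes, 2100 cells, loading 0.8."""
    spec = sd.ModulePlantSpec(
        module_assignments=sd.make_module_assignments(5, 6, 40),
        loading=0.8,
        n_cells_per_patient=100,
        n_patients=21,
        seed=1,
    )
    return sd.generate_modular_expression(spec)


@pytest.fixture(scope="session")
def toy_rl_map():
    from chemomodules.rl_permutation import RLMap

    pairs = {
        ("CXCL8", "CXCR1"),
        ("CXCL8", "CXCR2"),
        ("CXCL1", "CXCR2"),
        ("CCL19", "CCR7"),
        ("CCL21", "CCR7"),
        ("CCL5", "CCR5"),
    }
    return RLMap(pairs=frozenset(pairs))


def brute_force_rand_index(a, b) -> float:
    """Pair-enumeration Rand index, independent of sklearn."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    agree = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if (a[i] == a[j]) == (b[i] == b[j]):
                agree += 1
    return agree / total


def average_linkage_flat_oracle(profiles: np.ndarray, cut: float) -> np.ndarray:
    """Brute-force average-linkage agglomeration (Lance-Williams recurrence)
    with a flat cut at cophenetic distance <= ``cut``.

    Independent oracle for the scipy linkage/fcluster path: average linkage
    is monotone, so the flat clusters are exactly the unions of all merges
    performed at height <= cut.
    """
    n = profiles.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    d: dict[tuple[int, int], float] = {
        (i, j): float(np.linalg.norm(profiles[i] - profiles[j]))
        for i in range(n)
        for j in range(i + 1, n)
    }

    def dist(a: int, b: int) -> float:
        return d[(a, b) if a < b else (b, a)]

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        (a, b), h = min(
            (
                ((x, y), dist(x, y))
                for i, x in enumerate(keys)
                for y in keys[i + 1 :]
            ),
            key=lambda kv: kv[1],
        )
        na, nb = len(clusters[a]), len(clusters[b])
        for c in clusters:
            if c in (a, b):
                continue
            d[(min(c, next_id), max(c, next_id))] = (
                na * dist(a, c) + nb * dist(b, c)
            ) / (na + nb)
        if h <= cut:
            ra, rb = find(clusters[a][0]), find(clusters[b][0])
            parent[rb] = ra
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1

    roots = [find(i) for i in range(n)]
    _, labels = np.unique(roots, return_inverse=True)
    return labels
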