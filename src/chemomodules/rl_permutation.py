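"""Permutation test for receptor-ligand interactions between modules.

An RL interaction between a chemokine module and a receptor module is a known
ligand -> receptor pairing with the ligand in the chemokine module and the
receptor in the receptor module.  The null shuffles gene -> module labels
within each module set (chemokines and receptors independently), preserving
module sizes; the empirical p for a module pair is the plain proportion of
shuffles whose interaction count is greater than or equal to the observed
count.  An exhaustive enumerator over all distinguishable assignments serves
as the exact oracle for small configurations.
"""

from __future__ import annotations

import importlib.resources
import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RLMap",
    "PermutationResult",
    "load_default_rl_map",
    "count_interactions",
    "permutation_test",
    "exhaustive_null",
]


@dataclass(frozen=True)
class RLMap:
    """A set of (ligand, receptor) pairings with per-pair provenance."""

    pairs: frozenset[tuple[str, str]]
    sources: dict[tuple[str, str], str] | None = None

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RLMap":
        required = {"ligand", "receptor"}
        if not required.issubset(df.columns):
            raise ValueError("RL map needs 'ligand' and 'receptor' columns")
        pairs = frozenset(zip(df["ligand"], df["receptor"]))
        sources = None
        if "source" in df.columns:
            sources = {
                (l, r): s
                for l, r, s in zip(df["ligand"], df["receptor"], df["source"])
            }
        return cls(pairs=pairs, sources=sources)

    @classmethod
    def from_tsv(cls, path) -> "RLMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class PermutationResult:
    """Observed count, null distribution, and empirical p for a module pair."""

    chem_module: str
    rec_module: str
    observed: int
    null_counts: np.ndarray
    p: float
    n_iter: int
    seed: int


def load_default_rl_map() -> RLMap:
    """The curated chemokine -> receptor pairing table shipped with the
    package (data/chemokine_receptor_pairs.tsv); fully user-replaceable."""
    ref = importlib.resources.files("chemomodules") / "data" / "chemokine_receptor_pairs.tsv"
    with importlib.resources.as_file(ref) as path:
        return RLMap.from_tsv(path)


def count_interactions(
    chem_module: set[str], rec_module: set[str], rl_map: RLMap
) -> int:
    """Number of map pairs with ligand in the chemokine module and receptor
    in the receptor module."""
    return sum(
        1 for (l, r) in rl_map.pairs if l in chem_module and r in rec_module
    )


def _module_arrays(modules: dict[str, set[str]]):
    """Flatten a module set into (gene list, module-index array, id list)."""
    mod_ids = sorted(modules)
    genes: list[str] = []
    labels: list[int] = []
    for mi, m in enumerate(mod_ids):
        for g in sorted(modules[m]):
            genes.append(g)
            labels.append(mi)
    return genes, np.asarray(labels, dtype=np.int64), mod_ids


def _observed_matrix(chem_modules, rec_modules, rl_map) -> np.ndarray:
    chem_ids = sorted(chem_modules)
    rec_ids = sorted(rec_modules)
    obs = np.zeros((len(chem_ids), len(rec_ids)), dtype=np.int64)
    for i, cm in enumerate(chem_ids):
        for j, rm in enumerate(rec_ids):
            obs[i, j] = count_interactions(
                chem_modules[cm], rec_modules[rm], rl_map
            )
    return obs


def permutation_test(
    chem_modules: dict[str, set[str]],
    rec_modules: dict[str, set[str]],
    rl_map: RLMap,
    n_iter: int = 10_000,
    seed: int = 0,
    pseudo: bool = False,
) -> list[PermutationResult]:
    """Shuffle-based enrichment test for every chemokine x receptor module pair.

    Each null iteration independently permutes the gene -> module assignment
    within the chemokine module set and within the receptor module set
    (module sizes preserved; genes outside any module are excluded from the
    shuffle universe), recounts interactions for all pairs from the same
    shuffle (joint null), and p = (# null >= observed) / n_iter.  With
    ``pseudo=True`` the (k+1)/(n+1) estimator is used instead.
    """
    if not chem_modules or not rec_modules:
        raise ValueError("both module sets must be non-empty")
    if n_iter < 100:
        warnings.warn(
            f"n_iter={n_iter} gives coarse p resolution (1/{n_iter})",
            stacklevel=2,
        )
    chem_genes, chem_labels, chem_ids = _module_arrays(chem_modules)
    rec_genes, rec_labels, rec_ids = _module_arrays(rec_modules)
    n_cm, n_rm = len(chem_ids), len(rec_ids)

    # map pairs restricted to genes in the shuffle universe
    chem_pos = {g: i for i, g in enumerate(chem_genes)}
    rec_pos = {g: i for i, g in enumerate(rec_genes)}
    pair_idx = np.asarray(
        [
            (chem_pos[l], rec_pos[r])
            for (l, r) in sorted(rl_map.pairs)
            if l in chem_pos and r in rec_pos
        ],
        dtype=np.int64,
    ).reshape(-1, 2)

    obs = _observed_matrix(chem_modules, rec_modules, rl_map)

    rng = np.random.default_rng(seed)
    # one permutation of each label vector per iteration
    chem_perm = np.argsort(
        rng.random((n_iter, len(chem_genes))), axis=1, kind="stable"
    )
    rec_perm = np.argsort(
        rng.random((n_iter, len(rec_genes))), axis=1, kind="stable"
    )
    chem_null_labels = chem_labels[chem_perm]  # (n_iter, n_chem_genes)
    rec_null_labels = rec_labels[rec_perm]

    null = np.zeros((n_iter, n_cm * n_rm), dtype=np.int64)
    iters = np.arange(n_iter)
    for l_idx, r_idx in pair_idx:
        flat = chem_null_labels[:, l_idx] * n_rm + rec_null_labels[:, r_idx]
        null[iters, flat] += 1
    null = null.reshape(n_iter, n_cm, n_rm)

    results = []
    for i, cm in enumerate(chem_ids):
        for j, rm in enumerate(rec_ids):
            ge = int((null[:, i, j] >= obs[i, j]).sum())
            p = (ge + 1) / (n_iter + 1) if pseudo else ge / n_iter
            results.append(
                PermutationResult(
                    chem_module=cm,
                    rec_module=rm,
                    observed=int(obs[i, j]),
                    null_counts=null[:, i, j].copy(),
                    p=float(p),
                    n_iter=n_iter,
                    seed=seed,
                )
            )
    return results


def _distinct_assignments(labels: np.ndarray):
    """All distinguishable gene -> module-label assignments (multiset perms)."""
    seen = set()
    for perm in itertools.permutations(labels.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm, dtype=np.int64)


def n_distinct_assignments(modules: dict[str, set[str]]) -> int:
    sizes = [len(v) for v in modules.values()]
    n = sum(sizes)
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(s)
    return total


def exhaustive_null(
    chem_modules: dict[str, set[str]],
    rec_modules: dict[str, set[str]],
    rl_map: RLMap,
    max_assignments: int = 1_000_000,
) -> pd.DataFrame:
    """Exact tail probabilities by full enumeration of the shuffle null.

    Enumerates every distinguishable chemokine assignment x receptor
    assignment (refusing above ``max_assignments`` combinations) and returns
    a frame with exact p per module pair.  Oracle for
    :func:`permutation_test`.
    """
    total = n_distinct_assignments(chem_modules) * n_distinct_assignments(
        rec_modules
    )
    if total > max_assignments:
        raise ValueError(
            f"{total} distinguishable assignments exceed the "
            f"{max_assignments} enumeration bound"
        )
    chem_genes, chem_labels, chem_ids = _module_arrays(chem_modules)
    rec_genes, rec_labels, rec_ids = _module_arrays(rec_modules)
    n_cm, n_rm = len(chem_ids), len(rec_ids)
    chem_pos = {g: i for i, g in enumerate(chem_genes)}
    rec_pos = {g: i for i, g in enumerate(rec_genes)}
    pairs = [
        (chem_pos[l], rec_pos[r])
        for (l, r) in sorted(rl_map.pairs)
        if l in chem_pos and r in rec_pos
    ]
    obs = _observed_matrix(chem_modules, rec_modules, rl_map)

    chem_assignments = list(_distinct_assignments(chem_labels))
    rec_assignments = list(_distinct_assignments(rec_labels))
    ge = np.zeros((n_cm, n_rm), dtype=np.int64)
    for ca in chem_assignments:
        for ra in rec_assignments:
            counts = np.zeros((n_cm, n_rm), dtype=np.int64)
            for l_idx, r_idx in pairs:
                counts[ca[l_idx], ra[r_idx]] += 1
            ge += counts >= obs
    denom = len(chem_assignments) * len(rec_assignments)
    rows = []
    for i, cm in enumerate(chem_ids):
        for j, rm in enumerate(rec_ids):
            rows.append(
                {
                    "chem_module": cm,
                    "rec_module": rm,
                    "observed": int(obs[i, j]),
                    "p_exact": ge[i, j] / denom,
                    "n_assignments": denom,
                }
            )
    return pd.DataFrame(rows)
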