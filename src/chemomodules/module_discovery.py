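"""Chemokine / chemokine-receptor co-expression module discovery.

A module is a flat cluster of the gene-gene Spearman-correlation profile
vectors (average-linkage agglomerative clustering of Euclidean distances
between correlation rows, cut at a fixed cophenetic distance — 1.65 for
chemokines in cancer cells, 1.5 for receptors in leukocytes) whose mean
within-cluster pairwise Spearman r exceeds 0.15.  Robustness is assessed by a
leave-one-patient-out co-clustering frequency, and modules are scored per
patient as the mean expression of their genes, which can then be correlated
with immune-infiltration fractions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "ModuleSet",
    "spearman_panel",
    "extract_modules",
    "leave_one_out_stability",
    "score_modules_per_patient",
    "infiltration_from_labels",
    "correlate_modules_with_infiltration",
    "spearman_with_p",
]


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman coefficients over a gene panel.

    ``zero_variance`` flags genes constant in the analyzed population;
    their correlations are set to 0 against all other genes.
    """

    genes: list[str]
    r: np.ndarray
    zero_variance: list[str] = field(default_factory=list)


@dataclass
class ModuleSet:
    """Disjoint gene modules passing the flat-cluster + mean-r criterion."""

    modules: dict[str, set[str]]
    linkage_distance: float
    min_mean_r: float
    unassigned: set[str] = field(default_factory=set)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "module": m}
            for m, genes in sorted(self.modules.items())
            for g in sorted(genes)
        ]
        rows += [{"gene": g, "module": "unassigned"} for g in sorted(self.unassigned)]
        return pd.DataFrame(rows, columns=["gene", "module"])


def _population_mask(adata: AnnData, population) -> np.ndarray:
    """Resolve a population selector to a boolean cell mask.

    ``population`` may be None (all cells), a boolean mask, or a
    ``(obs_column, value)`` tuple such as ``("cell_type", "cancer")``.
    """
    if population is None:
        return np.ones(adata.n_obs, dtype=bool)
    if isinstance(population, tuple) and len(population) == 2:
        col, val = population
        return np.asarray(adata.obs[col] == val)
    mask = np.asarray(population, dtype=bool)
    if mask.shape != (adata.n_obs,):
        raise ValueError("boolean population mask has wrong length")
    return mask


def spearman_panel(
    adata: AnnData, panel: list[str], population=None
) -> CorrelationMatrix:
    """Pairwise Spearman correlation (midrank ties) over a gene panel.

    Computed across the cells of the selected population.  Genes with zero
    variance in that population get r = 0 against all others and are flagged.
    """
    missing = [g for g in panel if g not in adata.var_names]
    if missing:
        raise KeyError(f"panel genes absent from the matrix: {missing}")
    mask = _population_mask(adata, population)
    if mask.sum() < 3:
        raise ValueError("need at least 3 cells in the population")

    sub = adata[mask, panel]
    x = sub.X
    x = np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)

    variances = x.var(axis=0)
    varying = variances > 0
    r = np.zeros((len(panel), len(panel)))
    np.fill_diagonal(r, 1.0)
    if varying.sum() >= 2:
        sub_r = stats.spearmanr(x[:, varying], axis=0).statistic
        sub_r = np.atleast_2d(sub_r)
        idx = np.flatnonzero(varying)
        r[np.ix_(idx, idx)] = sub_r
        r[idx, idx] = 1.0
    zero_var = [panel[i] for i in np.flatnonzero(~varying)]
    if zero_var:
        logger.info("zero-variance genes in population: %s", zero_var)
    return CorrelationMatrix(genes=list(panel), r=r, zero_variance=zero_var)


def extract_modules(
    corr: CorrelationMatrix,
    linkage_distance: float,
    min_mean_r: float = 0.15,
) -> ModuleSet:
    """Flat-cluster the correlation profiles and keep qualifying modules.

    Each gene's row of correlation coefficients is its profile vector;
    Euclidean distances between profiles are clustered with average linkage
    and cut at ``linkage_distance`` (distance criterion).  Clusters of size
    >= 2 whose mean within-cluster pairwise Spearman r exceeds
    ``min_mean_r`` become modules; all other genes are unassigned.
    Zero-variance genes are excluded from clustering and reported
    unassigned.
    """
    keep = [g for g in corr.genes if g not in set(corr.zero_variance)]
    idx = [corr.genes.index(g) for g in keep]
    unassigned: set[str] = set(corr.zero_variance)
    modules: dict[str, set[str]] = {}

    if len(keep) >= 2:
        profiles = corr.r[np.ix_(idx, idx)]
        z = linkage(pdist(profiles, metric="euclidean"), method="average")
        flat = fcluster(z, t=linkage_distance, criterion="distance")
        next_id = 1
        # deterministic module numbering: by first gene position in the panel
        cluster_order = sorted(
            set(flat), key=lambda c: int(np.flatnonzero(flat == c)[0])
        )
        for c in cluster_order:
            members = [keep[i] for i in np.flatnonzero(flat == c)]
            if len(members) < 2:
                unassigned.update(members)
                continue
            mi = [corr.genes.index(g) for g in members]
            block = corr.r[np.ix_(mi, mi)]
            iu = np.triu_indices(len(members), k=1)
            if block[iu].mean() > min_mean_r:
                modules[f"M{next_id}"] = set(members)
                next_id += 1
            else:
                unassigned.update(members)
    else:
        unassigned.update(keep)

    if not modules:
        logger.info("no cluster passed the mean-r criterion; all unassigned")
    return ModuleSet(
        modules=modules,
        linkage_distance=linkage_distance,
        min_mean_r=min_mean_r,
        unassigned=unassigned,
    )


def leave_one_out_stability(
    adata: AnnData,
    panel: list[str],
    population,
    patient_key: str = "patient",
    linkage_distance: float = 1.65,
    min_mean_r: float = 0.15,
) -> pd.DataFrame:
    """Co-clustering frequency of gene pairs across leave-one-patient-out runs.

    For each patient, the Spearman panel and module extraction are recomputed
    on the remaining cells; the (gene, gene) frequency is the fraction of
    iterations in which both genes share a module (unassigned genes count as
    not co-clustered).  Iterations with fewer than 3 cells are skipped with
    the denominator adjusted.
    """
    patients = sorted(adata.obs[patient_key].unique())
    if len(patients) < 3:
        raise ValueError("need at least 3 patients for leave-one-out")
    base_mask = _population_mask(adata, population)

    counts = np.zeros((len(panel), len(panel)))
    n_used = 0
    gene_pos = {g: i for i, g in enumerate(panel)}
    for held_out in patients:
        mask = base_mask & np.asarray(adata.obs[patient_key] != held_out)
        if mask.sum() < 3:
            logger.warning("skipping iteration without patient %s: <3 cells", held_out)
            continue
        corr = spearman_panel(adata, panel, population=mask)
        mods = extract_modules(corr, linkage_distance, min_mean_r)
        n_used += 1
        for genes in mods.modules.values():
            gi = [gene_pos[g] for g in genes]
            for a, b in itertools.combinations(gi, 2):
                counts[a, b] += 1
                counts[b, a] += 1
    if n_used == 0:
        raise ValueError("no usable leave-one-out iterations")
    freq = counts / n_used
    np.fill_diagonal(freq, 1.0)
    return pd.DataFrame(freq, index=panel, columns=panel)


def score_modules_per_patient(
    adata: AnnData,
    modules: ModuleSet,
    population=None,
    patient_key: str = "patient",
    expression_threshold: float | None = None,
    n_null: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient mean module expression, with a binary "expressed" flag.

    The score for (patient, module) is the mean expression of the module's
    genes over that patient's population cells.  A module counts as
    expressed in a patient when the score exceeds ``expression_threshold``;
    when that is None the threshold defaults per module to the 75th
    percentile of a null built by re-drawing same-sized random gene sets
    from the full gene panel (scale-free across modules).

    Returns (scores, expressed_flags); patients without population cells
    get NaN scores and are never flagged.
    """
    if not modules.modules:
        raise ValueError("module set is empty")
    mask = _population_mask(adata, population)
    sub = adata[mask]
    x = sub.X
    x = np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)
    patients = sorted(adata.obs[patient_key].unique())
    mod_ids = sorted(modules.modules)
    gene_pos = {g: i for i, g in enumerate(sub.var_names)}

    scores = pd.DataFrame(index=patients, columns=mod_ids, dtype=float)
    pat_arr = np.asarray(sub.obs[patient_key])
    for p in patients:
        rows = pat_arr == p
        if not rows.any():
            continue
        for m in mod_ids:
            cols = [gene_pos[g] for g in modules.modules[m] if g in gene_pos]
            if cols:
                scores.loc[p, m] = float(x[np.ix_(rows, cols)].mean())

    if expression_threshold is None:
        rng = np.random.default_rng(seed)
        pool = [g for g in sub.var_names if g in gene_pos]
        thresholds = {}
        for m in mod_ids:
            size = len(modules.modules[m])
            null_scores = np.empty(n_null)
            for it in range(n_null):
                cols = [gene_pos[g] for g in rng.choice(pool, size, replace=False)]
                null_scores[it] = x[:, cols].mean()
            thresholds[m] = float(np.percentile(null_scores, 75))
    else:
        thresholds = {m: expression_threshold for m in mod_ids}

    expressed = pd.DataFrame(index=patients, columns=mod_ids, dtype=bool)
    for m in mod_ids:
        expressed[m] = scores[m] > thresholds[m]
    expressed = expressed.fillna(False)
    return scores, expressed


def infiltration_from_labels(
    adata: AnnData,
    leukocyte_types: list[str],
    patient_key: str = "patient",
    cell_type_key: str = "cell_type",
) -> pd.DataFrame:
    """Per-patient immune-cell abundance as percent of leukocytes.

    Rows are patients, columns the given leukocyte types; each row sums to
    100 over patients with at least one leukocyte.
    """
    obs = adata.obs
    is_leuk = obs[cell_type_key].isin(leukocyte_types)
    tab = (
        obs.loc[is_leuk]
        .groupby([patient_key, cell_type_key], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=leukocyte_types, fill_value=0)
    )
    totals = tab.sum(axis=1)
    return tab.div(totals.replace(0, np.nan), axis=0) * 100.0


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p for Spearman r at small n."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = stats.pearsonr(rx, ry[list(perm)]).statistic
        total += 1
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    return count / total


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman r with a two-sided p: exact permutation for n <= 8,
    t-approximation otherwise.  Returns (nan, nan) on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan, math.nan
    n = len(x)
    res = stats.spearmanr(x, y)
    r = float(res.statistic)
    if n <= 8:
        p = _exact_spearman_p(x, y, r)
    else:
        p = float(res.pvalue)
    return r, p


def correlate_modules_with_infiltration(
    scores: pd.DataFrame, infiltration: pd.DataFrame
) -> pd.DataFrame:
    """Spearman r and two-sided p for each (module, immune cell type) pair.

    Patients missing either value are pairwise-deleted; pairs with fewer
    than 5 complete patients, or a constant column, are reported with
    missing r/p rather than zero.
    """
    rows = []
    for m in scores.columns:
        for ct in infiltration.columns:
            joined = pd.concat(
                [scores[m], infiltration[ct]], axis=1, join="inner"
            ).dropna()
            if len(joined) < 5:
                r, p = math.nan, math.nan
            else:
                r, p = spearman_with_p(
                    joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
                )
            rows.append(
                {
                    "module": m,
                    "cell_type": ct,
                    "spearman_r": r,
                    "p_value": p,
                    "n_patients": len(joined),
                }
            )
    return pd.DataFrame(rows)
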