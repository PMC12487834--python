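"""Synthetic inputs with planted ground truth for every pipeline stage.

Four generators mirror the four data modalities the pipeline consumes:

* :func:`generate_modular_expression` — log-normalized single-cell expression
  with planted correlated gene modules (latent-factor Gaussian model).
* :func:`generate_survival_data` — clonogenic surviving fractions under the
  linear-quadratic model with lognormal replicate noise.
* :func:`generate_cell_images` — paired DAPI / bright-field images with known
  total and SA-beta-Gal-positive cell counts.
* :func:`generate_cytokine_panel` — SASP-factor fold-change tables with
  lognormal replicate noise.

All randomness flows from a single integer seed per call; no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

__all__ = [
    "ModulePlantSpec",
    "SurvivalSimSpec",
    "ImageSimSpec",
    "SASP_FACTORS",
    "make_module_assignments",
    "generate_modular_expression",
    "generate_survival_data",
    "generate_cell_images",
    "generate_cytokine_panel",
]

#: The ten established SASP factors used for the SASP factor score.
SASP_FACTORS = (
    "CCL2", "CCL4", "CCL5", "CXCL1", "CXCL8",
    "CXCL10", "ICAM1", "IL1a", "IL6", "TNFa",
)

BACKGROUND = "background"


@dataclass
class ModulePlantSpec:
    """Plan for an expression matrix with planted co-expression modules.

    Parameters
    ----------
    module_assignments
        Map gene-id -> module-id, or :data:`BACKGROUND` for independent
        noise genes.  Modules are disjoint by construction of the map.
    loading
        Latent-factor loading in (0, 1].  Within-module Pearson correlation
        of the underlying Gaussian is ``loading**2`` when ``noise_sd == 1``.
    n_cells_per_patient, n_patients
        Positive counts; total cells = product.
    noise_sd
        Standard deviation of the idiosyncratic noise term (1.0 recovers
        the analytic loading**2 correlation).
    module_activity
        Optional map module-id -> set of patient ids in which the module's
        latent factor is active; inactive patients receive pure noise for
        those genes.  ``None`` means active in all patients.
    activity_mean
        Mean of the latent factor in active patients when
        ``module_activity`` is given (module expression is both correlated
        and elevated there); ignored when ``module_activity`` is None.
    """

    module_assignments: dict[str, str]
    loading: float = 0.8
    n_cells_per_patient: int = 100
    n_patients: int = 21
    noise_sd: float = 1.0
    seed: int = 0
    module_activity: dict[str, set[str]] | None = None
    activity_mean: float = 1.0
    cell_type: str = "cancer"

    def __post_init__(self) -> None:
        if not (0.0 < self.loading <= 1.0):
            raise ValueError(f"loading must be in (0, 1], got {self.loading}")
        if self.n_cells_per_patient <= 0 or self.n_patients <= 0:
            raise ValueError("cell and patient counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(set(self.module_assignments)) != len(self.module_assignments):
            raise ValueError("duplicate gene ids in module assignments")


@dataclass
class SurvivalSimSpec:
    """Linear-quadratic survival curve simulation: SF = exp(-aD - bD^2)."""

    alpha: float  # 1/Gy
    beta: float  # 1/Gy^2
    doses: list[float] = field(default_factory=lambda: [0, 1, 2, 4, 6, 8])
    n_replicates: int = 3
    lognormal_sd: float = 0.1
    seed: int = 0
    radiation_type: str = "photon"

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")


@dataclass
class ImageSimSpec:
    """Paired DAPI / bright-field fixture with known stain-positive cells."""

    n_cells: int = 80
    fraction_positive: float = 0.3
    image_size: int = 384
    nucleus_radius: float = 6.0
    stain_intensity: float = 80.0  # 8-bit units of blue dominance
    background_sd: float = 60.0  # 16-bit DAPI background noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_positive <= 1.0):
            raise ValueError("fraction_positive must be in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.nucleus_radius <= 0 or self.image_size <= 0:
            raise ValueError("geometry parameters must be positive")


def make_module_assignments(
    n_modules: int, genes_per_module: int, n_background: int
) -> dict[str, str]:
    """Build a disjoint gene -> module map with synthetic gene ids."""
    assignments: dict[str, str] = {}
    g = 0
    for m in range(1, n_modules + 1):
        for _ in range(genes_per_module):
            assignments[f"G{g:04d}"] = f"M{m}"
            g += 1
    for _ in range(n_background):
        assignments[f"G{g:04d}"] = BACKGROUND
        g += 1
    return assignments


def generate_modular_expression(spec: ModulePlantSpec) -> AnnData:
    """Simulate a cells x genes log-normalized matrix with planted modules.

    Each module's genes share a per-cell latent factor:
    ``g = loading * factor + sqrt(1 - loading^2) * noise``, then shifted by
    +3 marginal SD and clipped at zero to mimic non-negative log-normalized
    expression.  Background genes are independent noise on the same scale.
    Ground truth lands in ``adata.var["true_module"]`` and
    ``adata.uns["true_modules"]``.
    """
    genes = list(spec.module_assignments)
    modules = sorted(
        {m for m in spec.module_assignments.values() if m != BACKGROUND}
    )
    rng = np.random.default_rng(spec.seed)
    n_cells = spec.n_cells_per_patient * spec.n_patients

    patients = np.array(
        [f"P{i % spec.n_patients:02d}" for i in range(n_cells)]
    )

    factors = rng.standard_normal((n_cells, len(modules)))
    if spec.module_activity is not None:
        for j, m in enumerate(modules):
            active = spec.module_activity.get(m)
            if active is not None:
                is_active = np.isin(patients, sorted(active))
                factors[is_active, j] += spec.activity_mean
                factors[~is_active, j] = 0.0

    lam = spec.loading
    resid = math.sqrt(1.0 - lam * lam)
    module_index = {m: j for j, m in enumerate(modules)}
    x = np.empty((n_cells, len(genes)))
    for gi, gene in enumerate(genes):
        m = spec.module_assignments[gene]
        noise = rng.standard_normal(n_cells) * spec.noise_sd
        if m == BACKGROUND:
            x[:, gi] = noise
        else:
            x[:, gi] = lam * factors[:, module_index[m]] + resid * noise

    # shift by +3 marginal SD, clip at zero: distributional approximation
    # of non-negative log-normalized expression
    sd = math.sqrt(lam * lam + resid * resid * spec.noise_sd**2)
    x = np.clip(x + 3.0 * max(sd, spec.noise_sd, 1e-12), 0.0, None)

    obs = pd.DataFrame(
        {
            "patient": patients,
            "cell_type": spec.cell_type,
            "treatment": "irradiated",
        },
        index=[f"cell{i}" for i in range(n_cells)],
    )
    var = pd.DataFrame(
        {"true_module": [spec.module_assignments[g] for g in genes]},
        index=genes,
    )
    adata = AnnData(X=x, obs=obs, var=var)
    adata.uns["true_modules"] = {
        m: sorted(g for g, mm in spec.module_assignments.items() if mm == m)
        for m in modules
    }
    return adata


def generate_survival_data(spec: SurvivalSimSpec) -> pd.DataFrame:
    """Simulate surviving fractions under the LQ model.

    Returns a tidy frame with columns ``radiation_type, dose_gy, replicate,
    surviving_fraction``.  Noise is multiplicative lognormal,
    ``SF = exp(-aD - bD^2) * exp(eps)`` with ``eps ~ N(0, lognormal_sd^2)``;
    dose 0 has SF 1 before noise.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for dose in spec.doses:
        sf_true = math.exp(-spec.alpha * dose - spec.beta * dose * dose)
        for rep in range(spec.n_replicates):
            eps = rng.normal(0.0, spec.lognormal_sd) if spec.lognormal_sd else 0.0
            rows.append(
                {
                    "radiation_type": spec.radiation_type,
                    "dose_gy": float(dose),
                    "replicate": rep,
                    "surviving_fraction": sf_true * math.exp(eps),
                }
            )
    return pd.DataFrame(rows)


def _place_centers(
    rng: np.random.Generator,
    n: int,
    size: int,
    min_sep: float,
    margin: float,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample non-overlapping centers at a minimum separation."""
    centers: list[tuple[float, float]] = []
    tries = 0
    min_sep2 = min_sep * min_sep
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} cells at separation {min_sep:.1f} "
                f"in a {size}x{size} frame after {max_tries} tries"
            )
        r = rng.uniform(margin, size - margin)
        c = rng.uniform(margin, size - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep2 for r0, c0 in centers):
            centers.append((r, c))
    return np.array(centers).reshape(n, 2)


def generate_cell_images(spec: ImageSimSpec):
    """Render a DAPI (16-bit) / bright-field (8-bit RGB) image pair.

    DAPI: Gaussian-profile nuclei on a dark noisy background.  Bright-field:
    uniform light background with a blue-dominant perinuclear stain disc
    around each designated positive cell.

    Returns
    -------
    dapi : (H, W) uint16 array
    brightfield : (H, W, 3) uint8 array
    truth : dict with ``total_cells``, ``positive_cells``, ``centers``
        (n x 2 array of row/col coordinates, 0-based) and ``positive_mask``.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    r_nuc = spec.nucleus_radius
    n_pos = int(round(spec.n_cells * spec.fraction_positive))

    dapi = rng.normal(300.0, spec.background_sd, (size, size))
    bf = np.full((size, size, 3), 225.0)
    bf += rng.normal(0.0, 2.0, bf.shape)

    if spec.n_cells > 0:
        # perinuclear cytoplasmic stain: tight disc around the nucleus
        stain_radius = 1.8 * r_nuc
        margin = 2.5 * r_nuc + 3.0
        centers = _place_centers(rng, spec.n_cells, size, 2.5 * r_nuc, margin)
        positive_mask = np.zeros(spec.n_cells, dtype=bool)
        positive_mask[rng.permutation(spec.n_cells)[:n_pos]] = True

        yy, xx = np.mgrid[0:size, 0:size]
        for i, (cr, cc) in enumerate(centers):
            d2 = (yy - cr) ** 2 + (xx - cc) ** 2
            # Gaussian nucleus, sigma = radius/2 so FWHM ~ 1.2 radii
            dapi += 4000.0 * np.exp(-d2 / (2.0 * (r_nuc / 2.0) ** 2))
            if positive_mask[i]:
                disc = d2 <= stain_radius**2
                # SA-beta-Gal blue: suppress red/green, keep blue high
                bf[disc, 0] -= spec.stain_intensity
                bf[disc, 1] -= spec.stain_intensity
                bf[disc, 2] -= 0.15 * spec.stain_intensity
    else:
        centers = np.zeros((0, 2))
        positive_mask = np.zeros(0, dtype=bool)

    dapi16 = np.clip(dapi, 0, 65535).astype(np.uint16)
    bf8 = np.clip(bf, 0, 255).astype(np.uint8)
    truth = {
        "total_cells": spec.n_cells,
        "positive_cells": int(n_pos),
        "centers": centers,
        "positive_mask": positive_mask,
    }
    return dapi16, bf8, truth


def generate_cytokine_panel(
    n_analytes: int = 10,
    fold_change_vector=None,
    replicate_sd: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a fold-change table (analyte, replicate, fold_change).

    Analyte names come from the SASP factor list; lognormal replicate noise
    multiplies the specified fold changes.
    """
    if n_analytes > len(SASP_FACTORS):
        raise ValueError(
            f"at most {len(SASP_FACTORS)} SASP analytes available"
        )
    if fold_change_vector is None:
        fold_change_vector = np.ones(n_analytes)
    fold_change_vector = np.asarray(fold_change_vector, dtype=float)
    if len(fold_change_vector) != n_analytes:
        raise ValueError("fold_change_vector length must equal n_analytes")
    if np.any(fold_change_vector <= 0):
        raise ValueError("fold changes must be positive")
    if replicate_sd < 0:
        raise ValueError("replicate_sd must be non-negative")

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        for analyte, fc in zip(SASP_FACTORS[:n_analytes], fold_change_vector):
            noise = math.exp(rng.normal(0.0, replicate_sd)) if replicate_sd else 1.0
            rows.append(
                {"analyte": analyte, "replicate": rep, "fold_change": fc * noise}
            )
    return pd.DataFrame(rows)
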