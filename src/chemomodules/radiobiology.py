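"""Quantitative assay statistics: clonogenic-survival linear-quadratic fits,
relative biological effectiveness at 10% survival, SASP factor scores, and
Boyden-chamber migration indices.

The linear-quadratic model ``S(D) = exp(-alpha*D - beta*D^2)`` is fit by
least squares in log-survival space with non-negativity constraints on alpha
[1/Gy] and beta [1/Gy^2]; replicates are pooled rather than averaged first.
RBE_s = D_s(reference) / D_s(test) with D_s the iso-survival dose at level s
(s = 0.10 for RBE10).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from chemomodules.synthetic_data import SASP_FACTORS

logger = logging.getLogger(__name__)

__all__ = [
    "LQFit",
    "RBEResult",
    "surviving_fraction",
    "fit_lq",
    "iso_survival_dose",
    "compute_rbe",
    "sasp_score",
    "migration_index",
]

MIGRATION_SUBSETS = ("CD4 T", "CD8 T", "NKT", "CD56dim NK", "CD56bright NK")


@dataclass
class LQFit:
    """Fitted linear-quadratic survival parameters.

    ``d10`` is the dose at 10% survival, the positive root of
    ``alpha*D + beta*D^2 = ln 10``.  ``constrained`` flags a fit where the
    non-negativity bound on alpha or beta is active.
    """

    alpha: float  # 1/Gy
    beta: float  # 1/Gy^2
    covariance: np.ndarray | None = None
    d10: float = math.nan
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    constrained: bool = False


@dataclass
class RBEResult:
    reference: LQFit
    test: LQFit
    survival_level: float
    rbe: float


def surviving_fraction(counts: pd.DataFrame) -> pd.DataFrame:
    """Surviving fractions from colony counts.

    Expects columns ``radiation_type, dose_gy, colonies, seeded, replicate``
    (optionally ``condition``).  Per (condition, radiation_type, replicate),
    plating efficiency PE = colonies0/seeded0 from the dose-0 record and
    SF(D) = (colonies_D/seeded_D)/PE.  Replicates are kept separate.
    """
    group_keys = [
        k for k in ("condition", "radiation_type", "replicate") if k in counts.columns
    ]
    out = []
    for keys, grp in counts.groupby(group_keys) if group_keys else [((), counts)]:
        zero = grp[grp["dose_gy"] == 0]
        if zero.empty:
            raise ValueError(f"no dose-0 record for group {keys}")
        pe = float(zero["colonies"].sum()) / float(zero["seeded"].sum())
        if pe == 0:
            raise ValueError(f"plating efficiency is zero for group {keys}")
        g = grp.copy()
        g["surviving_fraction"] = (g["colonies"] / g["seeded"]) / pe
        out.append(g)
    return pd.concat(out, ignore_index=True)


def iso_survival_dose(alpha: float, beta: float, s: float) -> float:
    """Dose achieving surviving fraction ``s``: positive root of
    ``alpha*D + beta*D^2 = -ln s``."""
    if not (0.0 < s < 1.0):
        raise ValueError("survival level must be in (0, 1)")
    target = -math.log(s)
    if alpha == 0 and beta == 0:
        return math.inf
    # stable quadratic root: avoids cancellation when beta -> 0
    return 2.0 * target / (alpha + math.sqrt(alpha * alpha + 4.0 * beta * target))


def fit_lq(sf_data: pd.DataFrame, weights: np.ndarray | None = None) -> LQFit:
    """Least-squares LQ fit of ln SF = -alpha*D - beta*D^2, alpha, beta >= 0.

    ``sf_data`` needs columns ``dose_gy`` and ``surviving_fraction``;
    replicates are fit jointly (pooled).  With the constraints inactive this
    is the ordinary linear least-squares solution; an active constraint is
    flagged.  Equal weights by default; optional per-point weights.
    """
    doses = np.asarray(sf_data["dose_gy"], dtype=float)
    sf = np.asarray(sf_data["surviving_fraction"], dtype=float)
    if np.any(sf <= 0):
        raise ValueError("surviving fractions must be positive for a log fit")
    if len(np.unique(doses)) < 3:
        raise ValueError("need at least 3 distinct doses to identify alpha and beta")

    y = -np.log(sf)
    a = np.column_stack([doses, doses**2])
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        a = a * w[:, None]
        y = y * w

    # non-negative least squares: exact constrained solution
    params, _ = optimize.nnls(a, y)
    alpha, beta = float(params[0]), float(params[1])
    constrained = bool(np.any(np.isclose(params, 0.0)))

    resid = y - a @ params
    dof = max(len(y) - 2, 1)
    sigma2 = float(resid @ resid) / dof
    try:
        cov = sigma2 * np.linalg.inv(a.T @ a)
    except np.linalg.LinAlgError:
        cov = None
    d10 = iso_survival_dose(alpha, beta, 0.10)
    if constrained:
        logger.info("LQ fit constraint active: alpha=%.4g beta=%.4g", alpha, beta)
    return LQFit(
        alpha=alpha,
        beta=beta,
        covariance=cov,
        d10=d10,
        residuals=resid,
        constrained=constrained,
    )


def compute_rbe(reference: LQFit, test: LQFit, s: float = 0.10) -> RBEResult:
    """Relative biological effectiveness at survival level ``s``:
    ratio of reference (photon) to test (particle) iso-survival dose."""
    if not (0.0 < s < 1.0):
        raise ValueError("survival level must be in (0, 1)")
    d_ref = iso_survival_dose(reference.alpha, reference.beta, s)
    d_test = iso_survival_dose(test.alpha, test.beta, s)
    if not (d_test > 0):
        raise ValueError("test iso-survival dose is not positive")
    return RBEResult(reference=reference, test=test, survival_level=s, rbe=d_ref / d_test)


def sasp_score(
    panel: pd.DataFrame, factors: tuple[str, ...] = SASP_FACTORS
) -> tuple[float, float, pd.Series]:
    """SASP factor score: mean fold change of the established SASP factors.

    ``panel`` has columns ``analyte, replicate, fold_change`` with fold
    changes relative to the unirradiated control.  Per replicate the score is
    the mean fold change over the listed factors present; missing factors are
    logged.  Returns (mean score, SD across replicates, per-replicate
    scores).
    """
    present = panel[panel["analyte"].isin(factors)]
    if present.empty:
        raise ValueError("none of the SASP factors are present in the panel")
    if np.any(present["fold_change"] <= 0):
        raise ValueError("fold changes must be positive")
    missing = sorted(set(factors) - set(present["analyte"]))
    if missing:
        logger.info("SASP factors missing from panel: %s", missing)
    per_rep = present.groupby("replicate")["fold_change"].mean()
    sd = float(per_rep.std(ddof=1)) if len(per_rep) > 1 else 0.0
    return float(per_rep.mean()), sd, per_rep


def migration_index(counts: pd.DataFrame) -> pd.DataFrame:
    """Migration index per immune subset from bead-normalized counts.

    ``counts`` has columns ``sample, subset, count, beads, is_control``.
    Counts are first normalized to acquired beads
    (count * ref_beads / sample_beads, with the maximum bead count as the
    fixed reference — any fixed reference cancels in the ratio), then the
    index is normalized test / normalized control per subset.  Subsets with
    a zero control count are reported missing.
    """
    if np.any(counts["beads"] <= 0):
        raise ValueError("bead counts must be positive")
    ctrl = counts[counts["is_control"]]
    if ctrl.empty:
        raise ValueError("no control sample present")
    ref_beads = float(counts["beads"].max())
    norm = counts.copy()
    norm["normalized"] = norm["count"] * ref_beads / norm["beads"]
    ctrl_norm = (
        norm[norm["is_control"]].set_index("subset")["normalized"]
    )
    rows = []
    for (sample, subset), grp in norm[~norm["is_control"]].groupby(
        ["sample", "subset"], observed=True
    ):
        c = ctrl_norm.get(subset)
        if c is None or c == 0:
            idx = math.nan
        else:
            idx = float(grp["normalized"].iloc[0] / c)
        rows.append({"sample": sample, "subset": subset, "migration_index": idx})
    return pd.DataFrame(rows)
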