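"""Grouped local false discovery rates for the pair-level p-values.

The screen tests every (target, biomarker) pair, so the p-value collection
is huge and heterogeneous: some biomarker genes carry real signal, most do
not. Following the independent-hypothesis-weighting idea, p-values are
partitioned by the mutated gene and each group receives its own null model:

    lfdr(p) = pi0 * f0(p) / f(p),    f0 = U(0,1) density = 1,

where pi0 is the group's estimated proportion of true nulls (Storey's
lambda-grid estimator with spline smoothing) and f is the group's p-value
mixture density, estimated by a Gaussian kernel on the probit scale.
Groups too small for stable density estimation fall back to the pooled
all-pairs density with pi0 fixed at 1 (conservative), so every tested pair
receives an lfdr and rankings are total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: clamp for p-values before the probit transform
P_EPS = 1e-8
#: Storey's lambda grid
LAMBDA_GRID = np.round(np.arange(0.05, 0.9001, 0.05), 2)


@dataclass
class GroupFdrModel:
    """Audit record of one biomarker group's null model."""

    biomarker: str
    n_tests: int
    pi0: float
    fallback_used: bool


def estimate_pi0(
    pvalues: np.ndarray,
    lambdas: np.ndarray = LAMBDA_GRID,
    min_pi0: float = 0.0,
) -> float:
    """Storey's smoothed estimate of the proportion of true nulls.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) is computed on the
    lambda grid, smoothed by a cubic least-squares fit, evaluated at the
    largest lambda, and clamped to [min_pi0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    lambdas = np.sort(np.asarray(lambdas, dtype=float))
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas[-1]))
    return float(np.clip(pi0, min_pi0, 1.0))


def lfdr_from_pvalues(
    pvalues: np.ndarray, pi0: float, eps: float = P_EPS
) -> tuple[np.ndarray, bool]:
    """Local FDR per p-value given pi0, with a uniform null density.

    The mixture density f is estimated by Gaussian KDE (Silverman
    bandwidth) on the probit scale x = Phi^-1(p), back-transformed by the
    normal density Jacobian, then lfdr = min(1, pi0/f) is regularized to be
    non-decreasing in p (running maximum in p order). Returns the lfdr
    array (input order) and a degeneracy flag set when all p-values
    coincide, in which case every lfdr is min(1, pi0).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    pc = np.clip(p, eps, 1.0 - eps)
    if np.unique(pc).size == 1:
        return np.full(p.shape, min(1.0, pi0)), True
    x = stats.norm.ppf(pc)
    kde = stats.gaussian_kde(x, bw_method="silverman")
    h = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 4 * h, x.max() + 4 * h, 1024)
    fx_grid = kde(grid)
    fx = np.interp(x, grid, fx_grid)
    f = fx / stats.norm.pdf(x)
    with np.errstate(divide="ignore"):
        raw = np.minimum(1.0, pi0 / f)
    order = np.argsort(pc, kind="stable")
    mono = np.empty_like(raw)
    mono[order] = np.maximum.accumulate(raw[order])
    return np.minimum(mono, 1.0), False


def grouped_lfdr(
    pairs: pd.DataFrame,
    min_group_size: int = 50,
    p_col: str = "p_value",
    group_col: str = "biomarker",
) -> tuple[pd.DataFrame, list[GroupFdrModel]]:
    """Per-biomarker local FDR over a frame of tested pairs.

    Groups with at least ``min_group_size`` p-values get their own
    (pi0, density); smaller groups are scored by the pooled all-pairs
    density with pi0 forced to 1 and flagged ``fallback_used``. Returns the
    input frame with ``lfdr`` and ``fallback_used`` columns appended, plus
    the per-group audit models.
    """
    if pairs.empty:
        raise ValueError("no tested pairs")
    out = pairs.copy()
    out["lfdr"] = np.nan
    out["fallback_used"] = False
    models: list[GroupFdrModel] = []

    sizes = out.groupby(group_col, sort=False)[p_col].size()
    small = sizes.index[sizes < min_group_size]
    if len(small):
        pooled_lfdr, _ = lfdr_from_pvalues(out[p_col].to_numpy(), pi0=1.0)
        mask = out[group_col].isin(small).to_numpy()
        out.loc[mask, "lfdr"] = pooled_lfdr[mask]
        out.loc[mask, "fallback_used"] = True
        for g in small:
            models.append(
                GroupFdrModel(
                    biomarker=g, n_tests=int(sizes[g]), pi0=1.0, fallback_used=True
                )
            )
    for g in sizes.index[sizes >= min_group_size]:
        mask = (out[group_col] == g).to_numpy()
        p = out.loc[mask, p_col].to_numpy()
        pi0 = estimate_pi0(p)
        lf, degenerate = lfdr_from_pvalues(p, pi0)
        if degenerate:
            logger.warning("degenerate p-value distribution in group %s", g)
        out.loc[mask, "lfdr"] = lf
        models.append(
            GroupFdrModel(biomarker=g, n_tests=int(mask.sum()), pi0=pi0, fallback_used=False)
        )
    return out, models


def models_to_frame(models: list[GroupFdrModel]) -> pd.DataFrame:
    """Audit table (biomarker, n_tests, pi0, fallback flag) for export."""
    return pd.DataFrame(
        [
            {
                "biomarker": m.biomarker,
                "n_tests": m.n_tests,
                "pi0": m.pi0,
                "fallback_used": m.fallback_used,
            }
            for m in models
        ]
    )
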