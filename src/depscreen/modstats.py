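"""Moderated two-group t-tests with empirical-Bayes variance shrinkage.

For one biomarker gene the cohort splits into mutant (MUT) and wild-type
(WT) lines; each RNAi target's essentiality difference

    delta_ess = mean(MUT) - mean(WT)

is tested against H0: the score distribution is identical in MUT and WT.
Negative delta_ess means mutant lines are *sensitive* to knocking down the
target. Because cohorts are small (n' ~ 20), per-target residual variances
s2 are shrunk toward a prior (d0, s0^2) estimated across all targets tested
against the same biomarker design, and the moderated statistic

    t = delta_ess / sqrt(s2_post * (1/n_mut + 1/n_wt)),
    s2_post = (d0 * s0^2 + df * s2) / (d0 + df),   df = n' - 2,

is referred to Student's t with d0 + df degrees of freedom (standard normal
when d0 is infinite). d0 = 0 recovers the ordinary pooled two-sample
t-test; the prior (d0, s0^2) comes from a method-of-moments fit of a scaled
F distribution to the observed s2 (digamma/trigamma matching on log s2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)


@dataclass
class TwoGroupFits:
    """Per-target two-group fits for one biomarker design (vectorized)."""

    targets: np.ndarray  # object array of target symbols
    delta_ess: np.ndarray
    s2: np.ndarray
    df_residual: int
    n_mut: int
    n_wt: int


@dataclass
class VariancePrior:
    """Empirical-Bayes prior: d0 pseudo-degrees of freedom at variance s0_sq."""

    d0: float  # may be +inf
    s0_sq: float

    def __post_init__(self) -> None:
        # d0 = 0 is allowed as the no-shrinkage limit (ordinary pooled t-test)
        if not (self.d0 >= 0):
            raise ValueError("d0 must be non-negative (possibly inf)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def fit_two_group(
    cohort_essentiality: pd.DataFrame,
    mutation_status: np.ndarray | pd.Series,
    min_group: int = 2,
) -> TwoGroupFits:
    """Fit the two-group model for every target against one mutation vector.

    ``mutation_status`` is the 0/1 vector over the cohort columns. Raises
    ``GroupTooSmall`` when either group has fewer than ``min_group`` lines.
    """
    m = np.asarray(mutation_status).astype(bool)
    E = cohort_essentiality.to_numpy(dtype=float)
    if m.shape[0] != E.shape[1]:
        raise ValueError("mutation vector length does not match cohort size")
    if np.isnan(E).any():
        raise ValueError("cohort essentiality contains missing values")
    n_mut = int(m.sum())
    n_wt = int((~m).sum())
    if min(n_mut, n_wt) < min_group:
        raise GroupTooSmall(
            f"group too small: n_mut={n_mut}, n_wt={n_wt} (minimum {min_group})"
        )
    if min_group < 2:
        logger.warning("min_group < 2: single-observation groups give no spread")
    mut_mean = E[:, m].mean(axis=1)
    wt_mean = E[:, ~m].mean(axis=1)
    ss_mut = ((E[:, m] - mut_mean[:, None]) ** 2).sum(axis=1)
    ss_wt = ((E[:, ~m] - wt_mean[:, None]) ** 2).sum(axis=1)
    df = n_mut + n_wt - 2
    return TwoGroupFits(
        targets=np.asarray(cohort_essentiality.index, dtype=object),
        delta_ess=mut_mean - wt_mean,
        s2=(ss_mut + ss_wt) / df,
        df_residual=df,
        n_mut=n_mut,
        n_wt=n_wt,
    )


class GroupTooSmall(ValueError):
    """A mutation group is below the estimable minimum for this pair."""


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def estimate_variance_prior(
    s2: np.ndarray, df: int | np.ndarray
) -> VariancePrior:
    """Method-of-moments fit of the scaled-F prior to observed variances.

    Models s2 ~ s0^2 * chi2_df/df * F-mixing with prior degrees of freedom
    d0; matches the mean and spread of log s2 using digamma/trigamma
    moments. When the spread of log s2 does not exceed what equal true
    variances would produce, d0 is infinite and s0^2 is the common variance
    on the log scale.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 >= 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValueError("need at least 2 finite variances to estimate a prior")
    if (s2 == 0).all():
        raise ValueError("all residual variances are zero: degenerate data")
    if (s2 == 0).any():
        offset = s2[s2 > 0].min() * 1e-6
        logger.warning(
            "%d zero variances offset by %.3g for prior estimation",
            int((s2 == 0).sum()),
            offset,
        )
        s2 = np.where(s2 == 0, offset, s2)

    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def moderated_t_test(
    fits: TwoGroupFits, prior: VariancePrior, biomarker: str | None = None
) -> pd.DataFrame:
    """Moderated t statistics and two-sided p-values for one biomarker design.

    Returns a frame with columns target, biomarker, n_mut, n_wt, delta_ess,
    s2_post, t, df_total, p_value and a degenerate flag for zero posterior
    variance (p forced to 0, or 1 when delta_ess is also 0).
    """
    d0, s0 = prior.d0, prior.s0_sq
    df = float(fits.df_residual)
    if np.isinf(d0):
        s2_post = np.full_like(fits.s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df * fits.s2) / (d0 + df)
        df_total = d0 + df
    scale = 1.0 / fits.n_mut + 1.0 / fits.n_wt
    degenerate = s2_post == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits.delta_ess / np.sqrt(s2_post * scale)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    if degenerate.any():
        null_degenerate = degenerate & (fits.delta_ess == 0)
        t = np.where(degenerate, np.sign(fits.delta_ess) * np.inf, t)
        t = np.where(null_degenerate, 0.0, t)
        p = np.where(degenerate, 0.0, p)
        p = np.where(null_degenerate, 1.0, p)
    out = pd.DataFrame(
        {
            "target": fits.targets,
            "biomarker": biomarker,
            "n_mut": fits.n_mut,
            "n_wt": fits.n_wt,
            "delta_ess": fits.delta_ess,
            "s2_post": s2_post,
            "t": t,
            "df_total": df_total,
            "p_value": p,
            "degenerate": degenerate,
        }
    )
    return out


def test_all_pairs(
    cohort_essentiality: pd.DataFrame,
    cohort_mutations: pd.DataFrame,
    min_group: int = 2,
    prior_scope: str = "per_biomarker",
) -> tuple[pd.DataFrame, list[dict]]:
    """Test every (target, biomarker) pair over the cohort.

    For each biomarker row in the cohort mutation matrix the two-group model
    is fitted for all targets at once and one variance prior is estimated
    across targets within that biomarker design (``prior_scope =
    "per_biomarker"``) or one prior is shared across all biomarkers
    (``"global"``). Biomarkers with a group below ``min_group`` are skipped
    and reported in the second return value.
    """
    if prior_scope not in ("per_biomarker", "global"):
        raise ValueError("prior_scope must be 'per_biomarker' or 'global'")
    results: list[pd.DataFrame] = []
    skipped: list[dict] = []
    fits_by_biomarker: list[tuple[str, TwoGroupFits]] = []
    for biomarker, row in cohort_mutations.iterrows():
        try:
            fits = fit_two_group(cohort_essentiality, row.to_numpy(), min_group)
        except GroupTooSmall as exc:
            skipped.append({"biomarker": biomarker, "reason": str(exc)})
            continue
        fits_by_biomarker.append((biomarker, fits))

    if not fits_by_biomarker:
        return (
            pd.DataFrame(
                columns=[
                    "target", "biomarker", "n_mut", "n_wt", "delta_ess",
                    "s2_post", "t", "df_total", "p_value", "degenerate",
                ]
            ),
            skipped,
        )

    if prior_scope == "global":
        all_s2 = np.concatenate([f.s2 for _, f in fits_by_biomarker])
        all_df = np.concatenate(
            [np.full_like(f.s2, f.df_residual) for _, f in fits_by_biomarker]
        )
        if all_s2.size < 2:
            shared_prior = VariancePrior(d0=0.0, s0_sq=max(float(all_s2[0]), 1e-300))
        else:
            shared_prior = estimate_variance_prior(all_s2, all_df)
    for biomarker, fits in fits_by_biomarker:
        if prior_scope == "global":
            prior = shared_prior
        elif fits.s2.size < 2:
            # a single target gives no ensemble: no shrinkage (ordinary t)
            prior = VariancePrior(d0=0.0, s0_sq=max(float(fits.s2[0]), 1e-300))
            logger.warning(
                "biomarker %s: only one target; using unmoderated t", biomarker
            )
        else:
            prior = estimate_variance_prior(fits.s2, fits.df_residual)
        results.append(moderated_t_test(fits, prior, biomarker=biomarker))
    return pd.concat(results, ignore_index=True), skipped
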