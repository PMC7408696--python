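"""Cohort selection and the three-way target pre-filter.

A screen runs inside one tumor cohort (the n' cell lines of the queried
tumor type) against the rest of the panel. Before any pair is tested, a
candidate drug target must be

1. *prevalently essential* in the cohort: score below the essentiality
   cutoff (default -2) in more than ``min_cohort_essential_fraction``
   (default 20%) of cohort lines;
2. *cohort specific*: essential-vs-cohort odds ratio above 1 and essential
   in at most ``max_other_essential_fraction`` (default 20%) of the other
   panel lines;
3. *expressed*: at least ``min_tpm`` (default 1 TPM) in more than
   ``min_expressed_fraction`` (default 75%) of cohort lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class Cohort:
    """An ordered cohort of cell lines and its complement within the panel."""

    name: str
    member_ids: list[str]
    complement_ids: list[str]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("cohort has no members")
        overlap = set(self.member_ids) & set(self.complement_ids)
        if overlap:
            raise ValueError(f"cohort and complement overlap: {sorted(overlap)}")

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class FilterParams:
    """Thresholds of the target pre-filter.

    Strictness follows the filter definitions: essentiality is strict
    (score < cutoff), cohort prevalence and expression prevalence are strict
    (>), the other-lines essentiality cap is inclusive (<=), and TPM itself
    is inclusive (>= min_tpm).
    """

    essentiality_cutoff: float = -2.0
    min_cohort_essential_fraction: float = 0.20
    max_other_essential_fraction: float = 0.20
    require_odds_ratio_gt: float = 1.0
    min_tpm: float = 1.0
    min_expressed_fraction: float = 0.75

    def __post_init__(self) -> None:
        for name in (
            "min_cohort_essential_fraction",
            "max_other_essential_fraction",
            "min_expressed_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not np.isfinite(self.essentiality_cutoff):
            raise ValueError("essentiality_cutoff must be finite")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterParams":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


def select_cohort(
    annotation: pd.Series,
    tumor_type: str | None = None,
    id_list: Sequence[str] | None = None,
    name: str | None = None,
) -> Cohort:
    """Build a cohort from a tumor-type label or an explicit id list."""
    panel = list(annotation.index)
    if (tumor_type is None) == (id_list is None):
        raise ValueError("provide exactly one of tumor_type or id_list")
    if tumor_type is not None:
        members = [c for c in panel if annotation[c] == tumor_type]
        if not members:
            raise ValueError(f"no cell lines annotated with tumor type {tumor_type!r}")
        name = name or tumor_type
    else:
        missing = [c for c in id_list if c not in annotation.index]
        if missing:
            raise ValueError(f"cell lines not in panel: {missing}")
        members = list(id_list)
        if not members:
            raise ValueError("empty cohort id list")
        name = name or "custom"
    member_set = set(members)
    complement = [c for c in panel if c not in member_set]
    return Cohort(name=name, member_ids=members, complement_ids=complement)


def essential_fraction(scores: np.ndarray, cutoff: float) -> float:
    """Fraction of scores strictly below the essentiality cutoff."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if np.isnan(scores).any():
        raise ValueError("missing values in score vector (impute first)")
    return float((scores < cutoff).mean())


def specificity_stats(
    target_scores: pd.Series | np.ndarray,
    cohort: Cohort,
    cutoff: float,
    celllines: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Odds ratio of cohort-vs-other essentiality and the other-lines fraction.

    From the 2x2 table (a = cohort essential, b = cohort non-essential,
    c = other essential, d = other non-essential) the odds ratio is
    (a*d)/(b*c), with the Haldane-Anscombe +0.5 correction applied to every
    cell iff any cell is zero.
    """
    if isinstance(target_scores, pd.Series):
        ser = target_scores
    else:
        if celllines is None:
            raise ValueError("celllines required for a bare array")
        ser = pd.Series(np.asarray(target_scores, dtype=float), index=list(celllines))
    if not cohort.complement_ids:
        raise ValueError("cohort complement is empty")
    inside = ser.loc[cohort.member_ids].to_numpy(dtype=float)
    outside = ser.loc[cohort.complement_ids].to_numpy(dtype=float)
    a = float((inside < cutoff).sum())
    b = float(inside.size - a)
    c = float((outside < cutoff).sum())
    d = float(outside.size - c)
    other_fraction = c / (c + d)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c), other_fraction


def expressed_fraction(tpm: np.ndarray, min_tpm: float) -> float:
    """Fraction of cohort lines expressing the gene at >= min_tpm."""
    tpm = np.asarray(tpm, dtype=float)
    if tpm.size == 0:
        raise ValueError("empty TPM vector")
    return float((tpm >= min_tpm).mean())


def target_prefilter(
    essentiality: pd.DataFrame,
    expression: pd.DataFrame,
    cohort: Cohort,
    params: FilterParams | None = None,
) -> pd.DataFrame:
    """Evaluate the three-criterion pre-filter for every target.

    Returns one row per target with the measured fractions, the odds ratio,
    per-criterion pass flags and the overall conjunction. Targets without an
    expression row fail the expression criterion (logged).
    """
    params = params or FilterParams()
    cutoff = params.essentiality_cutoff
    members = cohort.member_ids

    E_in = essentiality[members].to_numpy(dtype=float)
    if np.isnan(E_in).any() or np.isnan(essentiality.to_numpy()).any():
        raise ValueError("essentiality matrix contains missing values; impute first")
    E_out = essentiality[cohort.complement_ids].to_numpy(dtype=float)

    a = (E_in < cutoff).sum(axis=1).astype(float)
    b = E_in.shape[1] - a
    c = (E_out < cutoff).sum(axis=1).astype(float)
    d = E_out.shape[1] - c
    cohort_fraction = a / E_in.shape[1]
    other_fraction = c / E_out.shape[1]
    zero = np.minimum.reduce([a, b, c, d]) == 0
    a2, b2, c2, d2 = (x + np.where(zero, 0.5, 0.0) for x in (a, b, c, d))
    with np.errstate(divide="ignore", invalid="ignore"):
        odds_ratio = (a2 * d2) / (b2 * c2)

    expr_frac = np.full(essentiality.shape[0], np.nan)
    in_X = essentiality.index.isin(expression.index)
    if (~in_X).any():
        logger.warning(
            "%d targets absent from the expression matrix fail the expression filter",
            int((~in_X).sum()),
        )
    if in_X.any():
        X_in = expression.loc[essentiality.index[in_X], members].to_numpy(dtype=float)
        expr_frac[in_X] = (X_in >= params.min_tpm).mean(axis=1)

    pass_essential = cohort_fraction > params.min_cohort_essential_fraction
    pass_specific = (odds_ratio > params.require_odds_ratio_gt) & (
        other_fraction <= params.max_other_essential_fraction
    )
    pass_expressed = in_X & (np.nan_to_num(expr_frac, nan=-1.0) > params.min_expressed_fraction)

    return pd.DataFrame(
        {
            "cohort_essential_fraction": cohort_fraction,
            "other_essential_fraction": other_fraction,
            "odds_ratio": odds_ratio,
            "expressed_fraction": expr_frac,
            "pass_essential": pass_essential,
            "pass_specific": pass_specific,
            "pass_expressed": pass_expressed,
            "pass": pass_essential & pass_specific & pass_expressed,
        },
        index=essentiality.index,
    )
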