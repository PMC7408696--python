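"""End-to-end screen: ranked target-biomarker-drug hypotheses for a cohort.

The pipeline for one tumor cohort:

1. pre-filter targets (prevalently essential, cohort specific, expressed);
2. moderated two-group tests of every surviving target against every
   biomarker gene with estimable groups;
3. grouped local FDR over *all* tested pairs (grouping by biomarker), so
   the null model never depends on the user's query;
4. restriction to the queried targets / drugs / mutations, thresholding by
   lfdr and |delta_ess|, drug attachment and interaction annotation;
5. total-order sort: lfdr, then p-value, then |delta_ess| descending, then
   (target, biomarker) lexicographic — identical inputs give byte-identical
   output tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import Cohort, FilterParams, target_prefilter
from .fdr import GroupFdrModel, grouped_lfdr, models_to_frame
from .io import AlignedBundle
from .modstats import GroupTooSmall, fit_two_group, estimate_variance_prior, moderated_t_test, test_all_pairs

logger = logging.getLogger(__name__)

RANK_COLUMNS = [
    "target", "biomarker", "delta_ess", "p_value", "lfdr",
    "n_mut", "n_wt", "direction", "drugs", "interaction_supported",
]


@dataclass
class ScreenQuery:
    """One of the four query scenarios: a set of targets, a set of drugs, a
    set of mutations, or the whole panel ("all") — always with a cohort."""

    mode: str  # {"targets", "drugs", "mutations", "all"}
    cohort: Cohort
    items: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("targets", "drugs", "mutations", "all"):
            raise ValueError(f"unknown query mode {self.mode!r}")
        if (self.mode == "all") != (len(self.items) == 0):
            raise ValueError("items must be empty iff mode='all'")


@dataclass
class ScreenParams:
    """Everything tunable about a screen run."""

    filters: FilterParams = field(default_factory=FilterParams)
    max_lfdr: float = 0.5
    min_abs_delta_ess: float = 2.0
    require_interaction: bool = False
    min_group: int = 2
    fdr_min_group_size: int = 50
    prior_scope: str = "per_biomarker"
    best_per_target: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.max_lfdr <= 1):
            raise ValueError("max_lfdr must be in (0, 1]")
        if self.min_abs_delta_ess < 0:
            raise ValueError("min_abs_delta_ess must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScreenResult:
    """Ranked pairs plus everything needed to audit the run."""

    ranked: pd.DataFrame
    all_pairs: pd.DataFrame
    prefilter_report: pd.DataFrame
    group_models: list[GroupFdrModel]
    skipped_biomarkers: list[dict]
    manifest: dict


def map_targets_to_drugs(
    targets: Sequence[str], dti: pd.DataFrame | None
) -> dict[str, list[str]]:
    """Deduplicated, sorted drug lists per target (empty when undrugged)."""
    mapping: dict[str, list[str]] = {t: [] for t in targets}
    if dti is not None and len(dti):
        grouped = dti.groupby("target")["drug_id"].agg(lambda s: sorted(set(s)))
        for t in targets:
            if t in grouped.index:
                mapping[t] = list(grouped.loc[t])
    return mapping


def interaction_filter(
    pairs: pd.DataFrame,
    interactions: set[frozenset] | None,
    require_interaction: bool = False,
) -> pd.DataFrame:
    """Annotate (and optionally require) a known gene-gene interaction
    between target and biomarker; membership is unordered."""
    inter = interactions or set()
    supported = np.array(
        [frozenset((t, b)) in inter for t, b in zip(pairs["target"], pairs["biomarker"])],
        dtype=bool,
    )
    out = pairs.copy()
    out["interaction_supported"] = supported
    if require_interaction:
        out = out[supported].reset_index(drop=True)
    return out


def _sorted_ranked(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["_absdelta"] = df["delta_ess"].abs()
    df = df.sort_values(
        by=["lfdr", "p_value", "_absdelta", "target", "biomarker"],
        ascending=[True, True, False, True, True],
        kind="mergesort",
    ).drop(columns="_absdelta")
    return df.reset_index(drop=True)


def _tested_pairs(
    bundle: AlignedBundle, cohort: Cohort, params: ScreenParams
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Prefilter targets, then test every surviving target against every
    biomarker with estimable groups. Returns (pairs, prefilter report,
    skipped biomarkers)."""
    report = target_prefilter(
        bundle.essentiality, bundle.expression, cohort, params.filters
    )
    passed = report.index[report["pass"]]
    if len(passed) == 0:
        return pd.DataFrame(), report, []
    E_cohort = bundle.essentiality.loc[passed, cohort.member_ids]
    M_cohort = bundle.mutations[cohort.member_ids]
    pairs, skipped = test_all_pairs(
        E_cohort, M_cohort, min_group=params.min_group, prior_scope=params.prior_scope
    )
    return pairs, report, skipped


def run_screen(
    bundle: AlignedBundle,
    query: ScreenQuery,
    params: ScreenParams | None = None,
    seed: int | None = None,
) -> ScreenResult:
    """Run the full screen for one query and return the ranked table.

    The pipeline is deterministic; ``seed`` is only recorded in the run
    manifest (no step draws random numbers).
    """
    params = params or ScreenParams()
    cohort = query.cohort

    # resolve the query restriction up front so bad items fail fast
    target_restrict: set[str] | None = None
    biomarker_restrict: set[str] | None = None
    if query.mode == "targets":
        missing = [t for t in query.items if t not in bundle.essentiality.index]
        if missing:
            raise ValueError(f"queried targets not in essentiality matrix: {missing}")
        target_restrict = set(query.items)
    elif query.mode == "drugs":
        if bundle.dti is None or not len(bundle.dti):
            raise ValueError("drug query requires a DTI table")
        known = set(bundle.dti["drug_id"])
        missing = [d for d in query.items if d not in known]
        if missing:
            raise ValueError(f"queried drugs not in DTI table: {missing}")
        target_restrict = set(
            bundle.dti.loc[bundle.dti["drug_id"].isin(query.items), "target"]
        )
    elif query.mode == "mutations":
        missing = [b for b in query.items if b not in bundle.mutations.index]
        if missing:
            raise ValueError(f"queried mutations not in mutation matrix: {missing}")
        biomarker_restrict = set(query.items)

    pairs, report, skipped = _tested_pairs(bundle, cohort, params)
    models: list[GroupFdrModel] = []
    if pairs.empty:
        warnings.warn("no testable (target, biomarker) pairs; empty result")
        ranked = pd.DataFrame(columns=RANK_COLUMNS)
        all_pairs = pairs
    else:
        all_pairs, models = grouped_lfdr(pairs, min_group_size=params.fdr_min_group_size)
        sel = all_pairs
        if target_restrict is not None:
            sel = sel[sel["target"].isin(target_restrict)]
        if biomarker_restrict is not None:
            sel = sel[sel["biomarker"].isin(biomarker_restrict)]
        sel = sel[
            (sel["lfdr"] <= params.max_lfdr)
            & (sel["delta_ess"].abs() >= params.min_abs_delta_ess)
        ].reset_index(drop=True)

        drug_map = map_targets_to_drugs(sorted(set(sel["target"])), bundle.dti)
        sel = sel.assign(
            direction=np.where(sel["delta_ess"] < 0, "mutant-sensitive", "mutant-resistant"),
            drugs=[";".join(drug_map[t]) for t in sel["target"]],
        )
        sel = interaction_filter(sel, bundle.interactions, params.require_interaction)
        ranked = _sorted_ranked(sel)
        if params.best_per_target:
            ranked = ranked.drop_duplicates(subset="target", keep="first").reset_index(
                drop=True
            )
        ranked = ranked[RANK_COLUMNS]

    manifest = {
        "cohort": cohort.name,
        "cohort_size": cohort.size,
        "panel_size": cohort.size + len(cohort.complement_ids),
        "query_mode": query.mode,
        "query_items": list(query.items),
        "params": params.to_dict(),
        "seed": seed,
        "n_targets_prefiltered": int(report["pass"].sum()) if len(report) else 0,
        "n_pairs_tested": int(len(pairs)),
        "n_pairs_reported": int(len(ranked)),
        "skipped_biomarkers": skipped,
    }
    return ScreenResult(
        ranked=ranked,
        all_pairs=all_pairs if not pairs.empty else pairs,
        prefilter_report=report,
        group_models=models,
        skipped_biomarkers=skipped,
        manifest=manifest,
    )


def test_pair(
    bundle: AlignedBundle,
    cohort: Cohort,
    target: str,
    biomarker: str,
    params: ScreenParams | None = None,
) -> pd.Series:
    """Case-by-case test of one pair, bypassing the pre-filter battery.

    Statistics are computed exactly as in :func:`run_screen`; the lfdr
    comes from the full-screen grouped model so that a pair that also
    survives the screen reports identical numbers. A pair whose target
    failed the pre-filter is appended to the tested collection before the
    grouped model is fitted.
    """
    params = params or ScreenParams()
    if target not in bundle.essentiality.index:
        raise ValueError(f"target {target!r} not in essentiality matrix")
    if biomarker not in bundle.mutations.index:
        raise ValueError(f"biomarker {biomarker!r} not in mutation matrix")

    pairs, _report, _skipped = _tested_pairs(bundle, cohort, params)
    in_set = (
        not pairs.empty
        and ((pairs["target"] == target) & (pairs["biomarker"] == biomarker)).any()
    )
    if not in_set:
        E_cohort = bundle.essentiality.loc[[target], cohort.member_ids]
        m = bundle.mutations.loc[biomarker, cohort.member_ids].to_numpy()
        fits = fit_two_group(E_cohort, m, min_group=params.min_group)  # GroupTooSmall propagates
        same_group = (
            pairs[pairs["biomarker"] == biomarker] if not pairs.empty else pd.DataFrame()
        )
        if len(same_group):
            # reuse the screen's variance prior for this biomarker design
            E_all = bundle.essentiality.loc[same_group["target"], cohort.member_ids]
            prior = estimate_variance_prior(
                fit_two_group(E_all, m, min_group=params.min_group).s2,
                fits.df_residual,
            )
        else:
            prior = estimate_variance_prior(
                np.append(fits.s2, fits.s2), fits.df_residual
            )
        extra = moderated_t_test(fits, prior, biomarker=biomarker)
        pairs = pd.concat([pairs, extra], ignore_index=True) if not pairs.empty else extra
    scored, _models = grouped_lfdr(pairs, min_group_size=params.fdr_min_group_size)
    row = scored[(scored["target"] == target) & (scored["biomarker"] == biomarker)].iloc[0]
    row = row.copy()
    row["direction"] = "mutant-sensitive" if row["delta_ess"] < 0 else "mutant-resistant"
    return row


def mutation_cooccurrence(
    cohort_mutations: pd.DataFrame, gene: str, haldane: bool = True
) -> pd.DataFrame:
    """Co-occurrence of one gene's mutations with every other gene.

    For each other gene, the 2x2 mutant/wild-type cross-table against
    ``gene`` over the cohort, its odds ratio (Haldane +0.5 correction iff a
    cell is zero) and the two-sided Fisher exact p-value, sorted by p.
    """
    if gene not in cohort_mutations.index:
        raise ValueError(f"gene {gene!r} not in mutation matrix")
    if cohort_mutations.shape[1] < 4:
        raise ValueError("need at least 4 cell lines for co-occurrence")
    g = cohort_mutations.loc[gene].to_numpy().astype(bool)
    rows = []
    for other, vals in cohort_mutations.iterrows():
        if other == gene:
            continue
        o = vals.to_numpy().astype(bool)
        n11 = int((g & o).sum())
        n10 = int((g & ~o).sum())
        n01 = int((~g & o).sum())
        n00 = int((~g & ~o).sum())
        _or_unused, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
        a, b, c, d = float(n11), float(n10), float(n01), float(n00)
        if haldane and min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        rows.append(
            {
                "gene": other,
                "n_both": n11,
                "n_gene_only": n10,
                "n_other_only": n01,
                "n_neither": n00,
                "odds_ratio": (a * d) / (b * c),
                "fisher_p": float(p),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene", "n_both", "n_gene_only", "n_other_only", "n_neither", "odds_ratio", "fisher_p"],
    )
    return out.sort_values(["fisher_p", "gene"], kind="mergesort").reset_index(drop=True)
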