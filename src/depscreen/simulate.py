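"""Synthetic cell-line panels with known ground truth.

Emulates the shapes of a real essentiality screen — a DEMETER-like score
matrix over a few hundred cell lines, a binary mutation matrix, a TPM
expression matrix, tumor-type annotation, a drug-target table and a
gene-gene interaction set — at a reduced scale, with effects planted where
the caller says. Scores are Gaussian around a per-target baseline; planted
(target, biomarker) pairs shift the mutant lines' scores by a chosen delta,
and "commonly essential" background targets shift a fraction of the whole
panel so that the specificity filter has something to reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AlignedBundle


@dataclass
class PlantedEffect:
    """One planted (target, biomarker) association.

    ``delta`` is added to the essentiality score of mutant lines (within
    the cohort only when ``cohort_only``); negative delta plants a
    mutant-sensitive pair. ``n_mut_cohort`` optionally forces an exact
    number of mutant lines inside the cohort (chosen at random), making
    recovery conditions reproducible.
    """

    target: str
    biomarker: str
    delta: float
    cohort_only: bool = True
    n_mut_cohort: int | None = None


@dataclass
class BackgroundEssential:
    """A pan-essential distractor: ``shift`` applied to a random fraction of
    the whole panel, so it is essential inside and outside any cohort."""

    target: str
    shift: float
    fraction: float


@dataclass
class SyntheticConfig:
    """Panel dimensions, noise levels and planted truth for one bundle."""

    n_panel: int = 400
    n_cohort: int = 22
    n_targets: int = 500
    n_biomarkers: int = 40
    mutation_freq_range: tuple[float, float] = (0.05, 0.5)
    base_score_mean: float = 0.0
    noise_sd: float = 1.0
    target_effect_sd: float = 1.0
    line_effect_sd: float = 0.0
    planted: list[PlantedEffect] = field(default_factory=list)
    essential_background: list[BackgroundEssential] = field(default_factory=list)
    missing_rate: float = 0.0
    low_tpm_target_fraction: float = 0.10
    cohort_label: str = "cohort"
    other_label: str = "other"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohort > self.n_panel:
            raise ValueError("n_cohort cannot exceed n_panel")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.mutation_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("mutation_freq_range must satisfy 0 < low <= high < 1")
        targets = {f"T{i:04d}" for i in range(self.n_targets)}
        biomarkers = {f"B{i:04d}" for i in range(self.n_biomarkers)}
        for pe in self.planted:
            if pe.target not in targets:
                raise ValueError(f"planted target {pe.target!r} outside T0000..T{self.n_targets - 1:04d}")
            if pe.biomarker not in biomarkers:
                raise ValueError(f"planted biomarker {pe.biomarker!r} outside B0000..B{self.n_biomarkers - 1:04d}")
            if pe.n_mut_cohort is not None and not (0 <= pe.n_mut_cohort <= self.n_cohort):
                raise ValueError("n_mut_cohort outside [0, n_cohort]")
        for bg in self.essential_background:
            if bg.target not in targets:
                raise ValueError(f"background target {bg.target!r} out of range")
            if not (0 <= bg.fraction <= 1):
                raise ValueError("background fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Realized truth of a generated bundle: planted pairs with their
    realized mutant counts and realized delta_ess, plus per-biomarker
    configured and realized mutation frequencies."""

    planted: pd.DataFrame
    mutation_freqs: pd.DataFrame
    cohort_ids: list[str]


def generate_bundle(config: SyntheticConfig) -> tuple[AlignedBundle, GroundTruth]:
    """Draw one fully aligned synthetic bundle from the configuration."""
    rng = np.random.default_rng(config.seed)
    targets = [f"T{i:04d}" for i in range(config.n_targets)]
    biomarkers = [f"B{i:04d}" for i in range(config.n_biomarkers)]
    lines = [f"CL{i:04d}" for i in range(config.n_panel)]

    cohort_idx = np.sort(rng.choice(config.n_panel, size=config.n_cohort, replace=False))
    cohort_ids = [lines[i] for i in cohort_idx]
    annotation = pd.Series(config.other_label, index=pd.Index(lines))
    annotation.iloc[cohort_idx] = config.cohort_label

    # mutations: one Bernoulli frequency per biomarker gene
    freqs = rng.uniform(*config.mutation_freq_range, size=config.n_biomarkers)
    M = (rng.random((config.n_biomarkers, config.n_panel)) < freqs[:, None]).astype(np.int8)
    M = pd.DataFrame(M, index=pd.Index(biomarkers), columns=pd.Index(lines))
    for pe in config.planted:
        if pe.n_mut_cohort is not None:
            chosen = rng.choice(config.n_cohort, size=pe.n_mut_cohort, replace=False)
            M.loc[pe.biomarker, cohort_ids] = 0
            M.loc[pe.biomarker, [cohort_ids[i] for i in chosen]] = 1

    # essentiality: per-target baseline + planted/background shifts + noise.
    # Planted targets get a neutral baseline so the planted delta alone
    # defines their ground truth (the baseline draw must not be able to
    # push a planted target past the prevalence/specificity filters).
    target_base = config.base_score_mean + rng.normal(
        0.0, config.target_effect_sd, size=config.n_targets
    )
    planted_targets = {pe.target for pe in config.planted}
    for t in planted_targets:
        target_base[targets.index(t)] = config.base_score_mean
    line_eff = (
        rng.normal(0.0, config.line_effect_sd, size=config.n_panel)
        if config.line_effect_sd > 0
        else np.zeros(config.n_panel)
    )
    E = (
        target_base[:, None]
        + line_eff[None, :]
        + rng.normal(0.0, config.noise_sd, size=(config.n_targets, config.n_panel))
    )
    E = pd.DataFrame(E, index=pd.Index(targets), columns=pd.Index(lines))
    for bg in config.essential_background:
        n_hit = int(round(bg.fraction * config.n_panel))
        hit = rng.choice(config.n_panel, size=n_hit, replace=False)
        E.iloc[E.index.get_loc(bg.target), hit] += bg.shift
    for pe in config.planted:
        mut = M.loc[pe.biomarker].to_numpy().astype(bool)
        if pe.cohort_only:
            scope = np.zeros(config.n_panel, dtype=bool)
            scope[cohort_idx] = True
            mut = mut & scope
        E.iloc[E.index.get_loc(pe.target), mut] += pe.delta

    # realized truth before masking
    planted_rows = []
    for pe in config.planted:
        mut = M.loc[pe.biomarker, cohort_ids].to_numpy().astype(bool)
        e_row = E.loc[pe.target, cohort_ids].to_numpy()
        realized = (
            float(e_row[mut].mean() - e_row[~mut].mean())
            if 0 < mut.sum() < mut.size
            else np.nan
        )
        planted_rows.append(
            {
                "target": pe.target,
                "biomarker": pe.biomarker,
                "delta": pe.delta,
                "cohort_only": pe.cohort_only,
                "n_mut_cohort": int(mut.sum()),
                "n_mut_panel": int(M.loc[pe.biomarker].sum()),
                "realized_delta_ess": realized,
            }
        )
    truth = GroundTruth(
        planted=pd.DataFrame(
            planted_rows,
            columns=[
                "target", "biomarker", "delta", "cohort_only",
                "n_mut_cohort", "n_mut_panel", "realized_delta_ess",
            ],
        ),
        mutation_freqs=pd.DataFrame(
            {
                "biomarker": biomarkers,
                "configured_freq": freqs,
                "realized_freq": M.to_numpy().mean(axis=1),
            }
        ),
        cohort_ids=cohort_ids,
    )

    # expression: lognormal TPM; a slice of targets forced low in the cohort
    gene_base = rng.lognormal(mean=2.0, sigma=1.0, size=config.n_targets)
    X = gene_base[:, None] * rng.lognormal(0.0, 0.5, size=(config.n_targets, config.n_panel))
    X = pd.DataFrame(X, index=pd.Index(targets), columns=pd.Index(lines))
    n_low = int(round(config.low_tpm_target_fraction * config.n_targets))
    if n_low:
        eligible = np.array(
            [i for i, t in enumerate(targets) if t not in planted_targets]
        )
        n_low = min(n_low, eligible.size)
        low_targets = eligible[
            rng.choice(eligible.size, size=n_low, replace=False)
        ]
        n_low_lines = max(1, int(np.ceil(0.30 * config.n_cohort)))
        for ti in low_targets:
            hit_lines = rng.choice(config.n_cohort, size=n_low_lines, replace=False)
            X.iloc[ti, cohort_idx[hit_lines]] = rng.uniform(0.0, 0.9, size=n_low_lines)

    if config.missing_rate > 0:
        mask = rng.random(E.shape) < config.missing_rate
        # keep every row imputable: at least 2 observed values
        for i in np.where((~mask).sum(axis=1) < 2)[0]:
            keep = rng.choice(config.n_panel, size=2, replace=False)
            mask[i, keep] = False
        E = E.mask(mask)

    # fictitious drugs: 0-3 per target, mixed assay-backed and curated rows
    dti_rows = []
    n_drugs = rng.integers(0, 4, size=config.n_targets)
    for ti, t in enumerate(targets):
        for di in range(n_drugs[ti]):
            kind = rng.choice(["IC50", "Ki", "none"], p=[0.45, 0.25, 0.30])
            potency = float(rng.lognormal(-1.0, 1.0)) if kind != "none" else np.nan
            dti_rows.append(
                {
                    "drug_id": f"DRUG_{t}_{di}",
                    "target": t,
                    "potency_uM": potency,
                    "potency_kind": kind,
                    "source": "synthetic",
                }
            )
    dti = pd.DataFrame(
        dti_rows, columns=["drug_id", "target", "potency_uM", "potency_kind", "source"]
    )

    interactions = {frozenset((pe.target, pe.biomarker)) for pe in config.planted}
    n_decoys = 2 * len(config.planted) + 20
    for _ in range(n_decoys):
        t = targets[rng.integers(config.n_targets)]
        b = biomarkers[rng.integers(config.n_biomarkers)]
        interactions.add(frozenset((t, b)))

    bundle = AlignedBundle(
        essentiality=E,
        mutations=M,
        expression=X,
        annotation=annotation,
        dti=dti,
        interactions=interactions,
    )
    return bundle, truth


def write_bundle(bundle: AlignedBundle, directory) -> dict[str, Path]:
    """Write a bundle in the exact dialects the readers consume.

    Emits TSV matrices (``NA`` for missing essentiality), a MAF-like
    variant table derived from the mutation matrix (one Missense record per
    mutant entry), and annotation/DTI/interaction TSVs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "essentiality": directory / "essentiality.tsv",
        "mutations": directory / "mutations.tsv",
        "variants": directory / "variants.maf",
        "expression": directory / "expression.tsv",
        "annotation": directory / "annotation.tsv",
        "dti": directory / "dti.tsv",
        "interactions": directory / "interactions.tsv",
    }
    bundle.essentiality.to_csv(paths["essentiality"], sep="\t", na_rep="NA")
    bundle.mutations.to_csv(paths["mutations"], sep="\t")
    bundle.expression.to_csv(paths["expression"], sep="\t")

    genes, cells = np.where(bundle.mutations.to_numpy() == 1)
    maf = pd.DataFrame(
        {
            "Hugo_Symbol": bundle.mutations.index[genes],
            "Tumor_Sample_Barcode": bundle.mutations.columns[cells],
            "Variant_Classification": "Missense_Mutation",
            "t_alt_count": 40,
            "t_ref_count": 60,
        }
    )
    maf.to_csv(paths["variants"], sep="\t", index=False)

    ann = pd.DataFrame(
        {"cellline": bundle.annotation.index, "tumor_type": bundle.annotation.to_numpy()}
    )
    ann.to_csv(paths["annotation"], sep="\t", index=False)

    dti = bundle.dti if bundle.dti is not None else pd.DataFrame(
        columns=["drug_id", "target", "potency_uM", "potency_kind", "source"]
    )
    dti.to_csv(paths["dti"], sep="\t", index=False)

    inter = bundle.interactions or set()
    rows = sorted(tuple(sorted(pair)) for pair in inter)
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(
        paths["interactions"], sep="\t", index=False
    )
    return paths
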