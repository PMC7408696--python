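"""Reading, validation and alignment of the input tables.

The screen consumes five tables:

* an essentiality matrix (RNAi targets x cell lines, DEMETER-like scores,
  more negative = more essential; missing cells allowed),
* a mutation matrix (genes x cell lines, strictly 0/1) or a MAF-like variant
  table that is dichotomized into one,
* an expression matrix (genes x cell lines, TPM),
* a cell-line annotation (cell line -> tumor type),
* a drug-target interaction (DTI) table with optional potencies in uM.

Matrices are held as :class:`pandas.DataFrame` with row identifiers in the
index and cell-line identifiers as columns; ``NaN`` marks a missing
essentiality score.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Variant classes excluded by default when dichotomizing a variant table:
#: silent and non-coding records do not count as a mutation.
DEFAULT_EXCLUDED_CLASSES = frozenset(
    {"Silent", "Intron", "3'UTR", "5'UTR", "5'Flank", "IGR", "RNA"}
)

MATRIX_KINDS = ("essentiality", "mutation", "expression")


@dataclass
class AlignedBundle:
    """All inputs restricted to one common, canonically ordered cell-line set."""

    essentiality: pd.DataFrame
    mutations: pd.DataFrame
    expression: pd.DataFrame
    annotation: pd.Series
    dti: pd.DataFrame | None = None
    interactions: set[frozenset] | None = None
    dropped: dict[str, list[str]] = field(default_factory=dict)

    @property
    def celllines(self) -> list[str]:
        return list(self.essentiality.columns)


def _sniff_sep(path: Path, declared: str | None) -> str:
    if declared is not None:
        return declared
    with open(path, newline="") as fh:
        head = fh.readline()
    if not head.strip():
        raise ValueError(f"{path}: empty file")
    try:
        return csv.Sniffer().sniff(head, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def _check_unique(labels: pd.Index, what: str, path) -> None:
    if labels.has_duplicates:
        dups = sorted(labels[labels.duplicated()].unique().tolist())
        raise ValueError(f"{path}: duplicate {what} identifiers: {dups}")
    if len(labels) == 0:
        raise ValueError(f"{path}: no {what} identifiers")


def read_matrix(path, kind: str, sep: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV matrix (row ids in first column, cell-line header).

    Parameters
    ----------
    path
        File to read; delimiter is sniffed unless ``sep`` is given.
    kind
        One of ``"essentiality"`` (empty/"NA" cells become NaN),
        ``"mutation"`` (strictly 0/1, missing values rejected) or
        ``"expression"`` (non-negative; missing cells become 0 with a
        warning).
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}; expected one of {MATRIX_KINDS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    sep = _sniff_sep(path, sep)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    # pandas mangles duplicate header names, so check the raw header first
    _check_unique(pd.Index(header[1:]), "column", path)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""], dtype=str)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no data columns")
    _check_unique(df.index, "row", path)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if kind == "mutation":
        if df.isna().any().any():
            r, c = np.argwhere(df.isna().to_numpy())[0]
            raise ValueError(
                f"{path}: missing value in mutation matrix at "
                f"row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        values = df.to_numpy()
        bad = ~np.isin(values, ["0", "1", "0.0", "1.0"])
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"{path}: non-binary value {values[r, c]!r} at "
                f"row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        return df.astype(float).astype(np.int8)

    out = df.astype(float)
    if kind == "expression":
        n_missing = int(out.isna().sum().sum())
        if n_missing:
            logger.warning("%s: %d missing expression cells set to 0", path, n_missing)
            out = out.fillna(0.0)
        if (out.to_numpy() < 0).any():
            raise ValueError(f"{path}: negative expression values")
    else:  # essentiality: NaN = missing, otherwise finite
        vals = out.to_numpy()
        if np.isinf(vals).any():
            raise ValueError(f"{path}: non-finite essentiality scores")
    return out


def read_annotation(path, sep: str | None = None) -> pd.Series:
    """Read a two-column cell line -> tumor type table."""
    path = Path(path)
    sep = _sniff_sep(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation needs (cellline, tumor_type) columns")
    ser = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
    _check_unique(ser.index, "cell-line", path)
    return ser


def read_dti(path, sep: str | None = None) -> pd.DataFrame:
    """Read a drug-target interaction table.

    Expected columns: ``drug_id``, ``target``, optionally ``potency_uM``,
    ``potency_kind`` (IC50 / Ki / none) and ``source``. Duplicate
    (drug_id, target) rows are dropped keeping the first occurrence.
    """
    path = Path(path)
    sep = _sniff_sep(path, sep)
    df = pd.read_csv(path, sep=sep)
    for col in ("drug_id", "target"):
        if col not in df.columns:
            raise ValueError(f"{path}: DTI table lacks required column {col!r}")
    if "potency_uM" not in df.columns:
        df["potency_uM"] = np.nan
    if "potency_kind" not in df.columns:
        df["potency_kind"] = "none"
    df["potency_kind"] = df["potency_kind"].fillna("none")
    if (df["potency_uM"].dropna() <= 0).any():
        raise ValueError(f"{path}: potency_uM must be positive where present")
    df = df.drop_duplicates(subset=["drug_id", "target"], keep="first")
    return df.reset_index(drop=True)


def read_interactions(path, sep: str | None = None) -> set[frozenset]:
    """Read gene-gene interaction pairs (two symbol columns) as an unordered set."""
    path = Path(path)
    sep = _sniff_sep(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: interaction table needs two symbol columns")
    return {frozenset((a, b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]) if a != b}


def read_maf(path, sep: str | None = None) -> pd.DataFrame:
    """Read a MAF-like variant table into a record frame.

    Requires ``Hugo_Symbol``, ``Tumor_Sample_Barcode`` and
    ``Variant_Classification``; when ``t_alt_count``/``t_ref_count`` are
    present the allele fraction alt/(alt+ref) is computed, otherwise it is
    left absent.
    """
    path = Path(path)
    sep = _sniff_sep(path, sep)
    df = pd.read_csv(path, sep=sep, comment="#")
    required = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: MAF lacks required columns {missing}")
    records = pd.DataFrame(
        {
            "gene": df["Hugo_Symbol"].astype(str),
            "cellline": df["Tumor_Sample_Barcode"].astype(str),
            "variant_classification": df["Variant_Classification"].astype(str),
        }
    )
    if "t_alt_count" in df.columns and "t_ref_count" in df.columns:
        alt = pd.to_numeric(df["t_alt_count"], errors="coerce")
        ref = pd.to_numeric(df["t_ref_count"], errors="coerce")
        records["allele_fraction"] = (alt / (alt + ref)).to_numpy()
    else:
        records["allele_fraction"] = np.nan
    return records


def dichotomize_mutations(
    records: pd.DataFrame,
    celllines: Sequence[str],
    excluded_classes: Iterable[str] = DEFAULT_EXCLUDED_CLASSES,
    min_allele_fraction: float | None = None,
) -> pd.DataFrame:
    """Collapse variant records into a binary gene x cell-line matrix.

    An entry is 1 iff at least one record for that gene and cell line
    survives the variant-class and allele-fraction filters; a cell line with
    no surviving record is wild-type (0). Records for cell lines outside
    ``celllines`` are logged and skipped. Genes whose rows end up all zero
    are retained.
    """
    if len(celllines) == 0:
        raise ValueError("celllines must be non-empty")
    celllines = [str(c) for c in celllines]
    excluded = set(excluded_classes)

    rec = records.copy()
    rec["gene"] = rec["gene"].astype(str)
    rec["cellline"] = rec["cellline"].astype(str)
    if (rec["gene"] == "").any() or (rec["cellline"] == "").any():
        raise ValueError("variant records with empty gene or cell-line identifiers")
    af = rec.get("allele_fraction")
    if af is not None:
        bad = af.dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError("allele fractions outside [0, 1]")

    unknown = ~rec["cellline"].isin(celllines)
    if unknown.any():
        logger.warning(
            "skipping %d variant records for %d cell lines outside the panel",
            int(unknown.sum()),
            rec.loc[unknown, "cellline"].nunique(),
        )
        rec = rec[~unknown]

    keep = ~rec["variant_classification"].isin(excluded)
    if min_allele_fraction is not None and "allele_fraction" in rec.columns:
        # records without an allele fraction are kept (filter cannot apply)
        keep &= ~(rec["allele_fraction"] < min_allele_fraction)
    rec = rec[keep]

    genes = pd.Index(pd.unique(records["gene"].astype(str)))
    M = pd.DataFrame(0, index=genes, columns=pd.Index(celllines), dtype=np.int8)
    if len(rec):
        hits = rec[["gene", "cellline"]].drop_duplicates()
        M.values[
            genes.get_indexer(hits["gene"]), M.columns.get_indexer(hits["cellline"])
        ] = 1
    return M


def align_panel(
    essentiality: pd.DataFrame,
    mutations: pd.DataFrame,
    expression: pd.DataFrame,
    annotation: pd.Series,
    dti: pd.DataFrame | None = None,
    interactions: set[frozenset] | None = None,
    min_lines: int = 3,
) -> AlignedBundle:
    """Restrict all matrices to the common cell-line set, in one order.

    The canonical order is the essentiality matrix's column order restricted
    to the intersection. The bundle records which lines each source lost.
    """
    sources = {
        "essentiality": list(essentiality.columns),
        "mutation": list(mutations.columns),
        "expression": list(expression.columns),
        "annotation": list(annotation.index),
    }
    common = set(sources["essentiality"])
    for cols in sources.values():
        common &= set(cols)
    shared = [c for c in essentiality.columns if c in common]
    if len(shared) < min_lines:
        raise ValueError(
            f"only {len(shared)} cell lines shared by all inputs "
            f"(minimum {min_lines}): {shared}"
        )
    dropped = {
        name: [c for c in cols if c not in common] for name, cols in sources.items()
    }
    return AlignedBundle(
        essentiality=essentiality[shared],
        mutations=mutations[shared],
        expression=expression[shared],
        annotation=annotation.loc[shared],
        dti=dti,
        interactions=interactions,
        dropped=dropped,
    )


def impute_knn(essentiality: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing scores by nearest-neighbor averaging over target rows.

    For each missing entry e_ij the imputed value is the mean, over the k
    target rows nearest to row i, of their scores in cell line j. Distance
    between two rows is the mean squared difference over the coordinates
    observed in both (so rows with different missingness patterns remain
    comparable); only rows observed at column j are candidate donors. Ties
    in distance are broken by row order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= essentiality.shape[0]:
        raise ValueError(
            f"k={k} must be smaller than the number of target rows "
            f"({essentiality.shape[0]})"
        )
    V = essentiality.to_numpy(dtype=float, copy=True)
    obs = ~np.isnan(V)
    n_obs_row = obs.sum(axis=1)
    if (n_obs_row == 0).any():
        missing_targets = essentiality.index[n_obs_row == 0].tolist()
        raise ValueError(f"rows entirely missing, cannot impute: {missing_targets}")
    if (n_obs_row < 2).any():
        few = essentiality.index[n_obs_row < 2].tolist()
        raise ValueError(f"rows with fewer than 2 observed values: {few}")
    if obs.all():
        return essentiality.copy()

    Vz = np.where(obs, V, 0.0)
    # pairwise mean squared difference over mutually observed coordinates
    shared = obs.astype(float) @ obs.T.astype(float)
    sq = (Vz**2) @ obs.T.astype(float)
    cross = Vz @ Vz.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = (sq + sq.T - 2.0 * cross) / shared
    dist[shared == 0] = np.inf
    np.fill_diagonal(dist, np.inf)

    out = V.copy()
    for i, j in zip(*np.where(~obs)):
        donors = np.where(obs[:, j] & np.isfinite(dist[:, i]))[0]
        if donors.size == 0:
            raise ValueError(
                f"no donor rows observed at column {essentiality.columns[j]!r} "
                f"for target {essentiality.index[i]!r}"
            )
        # stable sort on distance -> ties broken by row order
        order = donors[np.argsort(dist[donors, i], kind="stable")]
        out[i, j] = V[order[:k], j].mean()
    return pd.DataFrame(out, index=essentiality.index, columns=essentiality.columns)


def filter_dti_potency(dti: pd.DataFrame, threshold_uM: float = 1.0) -> pd.DataFrame:
    """Keep assay-backed interactions with potency strictly below threshold.

    Rows whose ``potency_kind`` is IC50 or Ki survive iff
    ``potency_uM < threshold_uM``; curated mechanism-of-action rows
    (``potency_kind`` = none) are always kept.
    """
    if threshold_uM <= 0:
        raise ValueError("threshold_uM must be positive")
    kind = dti["potency_kind"].fillna("none")
    assayed = kind.isin(["IC50", "Ki"])
    keep = ~assayed | (dti["potency_uM"] < threshold_uM)
    return dti[keep].reset_index(drop=True)
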