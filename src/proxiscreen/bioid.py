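"""Peptide-to-protein quantification, normalization and QC for proximity labeling.

Input is a peptide-level label-free quantification table (one row per
(protein, peptide), one intensity column per sample) plus a sample
annotation table.  Peptides are aggregated to proteins by summation, and the
protein matrix can be column-normalized by one of the schemes used for
streptavidin-capture proteomics:

``robust_mean``
    Trimmed mean of log-intensities per sample, re-exponentiated — a robust
    total-signal size factor.
``carboxylase``
    Mean intensity of endogenously biotinylated carboxylases, which enter the
    streptavidin pull-down independently of the bait and therefore track
    capture efficiency.
``bira``
    Mean intensity of the BirA* ligase itself, tracking ligase expression.
``none``
    Identity.

Technical noise is summarized as the per-protein percent coefficient of
variation across repeated injections of a QC pool (an equal mixture of all
samples), reported for all proteins and for the >=2-peptide subset.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProteinQuantMatrix",
    "NormalizationSpec",
    "QcReport",
    "read_peptides",
    "read_samples",
    "validate_annotation",
    "aggregate_peptides",
    "normalize",
    "qc_cv",
]

ID_COLS = ("protein_id", "peptide_id")


class InputError(ValueError):
    """Raised for malformed quantification or annotation tables."""


@dataclass
class ProteinQuantMatrix:
    """Protein x sample intensity matrix with peptide support counts.

    values : DataFrame indexed by protein id, one column per sample.
    n_peptides : number of distinct peptides observed per protein.
    normalization : tag recording the applied scheme ("raw" before any).
    size_factors : per-sample factors applied by the last normalization.
    """

    values: pd.DataFrame
    n_peptides: pd.Series
    normalization: str = "raw"
    size_factors: pd.Series | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# normalization: {self.normalization}\n")
            out = self.values.copy()
            out.insert(0, "n_peptides", self.n_peptides)
            out.to_csv(fh, sep="\t", index_label="protein_id")

    @classmethod
    def from_tsv(cls, path) -> "ProteinQuantMatrix":
        with open(path) as fh:
            first = fh.readline()
            tag = "raw"
            if first.startswith("#"):
                tag = first.split(":", 1)[1].strip()
                body = fh.read()
            else:
                body = first + fh.read()
        df = pd.read_csv(io.StringIO(body), sep="\t", index_col="protein_id")
        n_pep = df.pop("n_peptides").astype(int)
        return cls(values=df, n_peptides=n_pep, normalization=tag)


@dataclass
class NormalizationSpec:
    """Normalization scheme plus the reference ids it needs (if any)."""

    method: str = "robust_mean"
    reference_ids: Sequence[str] = field(default_factory=tuple)
    trim: float = 0.2

    def __post_init__(self) -> None:
        if self.method not in ("robust_mean", "carboxylase", "bira", "none"):
            raise InputError(f"unknown normalization method {self.method!r}")
        if self.method in ("carboxylase", "bira") and not self.reference_ids:
            raise InputError(f"method {self.method!r} requires reference_ids")


@dataclass
class QcReport:
    per_protein: pd.Series  # %CV across QC-pool samples
    mean_all: float
    mean_multi_peptide: float
    n_qc_samples: int


def read_peptides(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ID_COLS if c not in df.columns]
    if missing:
        raise InputError(f"peptide table missing columns {missing}")
    return df


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise InputError("annotation table missing 'sample_id'")
    if "is_qc" in df.columns:
        df["is_qc"] = df["is_qc"].astype(bool)
    else:
        df["is_qc"] = False
    return df


def validate_annotation(peptides: pd.DataFrame, samples: pd.DataFrame) -> list[str]:
    """Check sample ids are unique and every quant column is annotated once."""
    if samples.sample_id.duplicated().any():
        dups = samples.sample_id[samples.sample_id.duplicated()].tolist()
        raise InputError(f"duplicate sample ids in annotation: {dups}")
    quant_cols = [c for c in peptides.columns if c not in ID_COLS]
    unannotated = [c for c in quant_cols if c not in set(samples.sample_id)]
    if unannotated:
        raise InputError(f"quant columns without annotation: {unannotated}")
    return quant_cols


def aggregate_peptides(peptides: pd.DataFrame) -> ProteinQuantMatrix:
    """Sum peptide intensities to one row per protein.

    The protein expression value is the aggregate (sum) of its peptides'
    intensities per sample; ``n_peptides`` counts distinct peptides.
    Duplicate (protein, peptide) rows are rejected.
    """
    if peptides.empty:
        raise InputError("peptide table is empty")
    dup = peptides.duplicated(subset=list(ID_COLS))
    if dup.any():
        pairs = peptides.loc[dup, list(ID_COLS)].values.tolist()
        raise InputError(f"duplicate (protein, peptide) entries: {pairs[:5]}")
    quant_cols = [c for c in peptides.columns if c not in ID_COLS]
    vals = peptides[quant_cols]
    if (vals.values < 0).any():
        raise InputError("negative intensities in peptide table")
    grouped = peptides.groupby("protein_id", sort=True)
    values = grouped[quant_cols].sum()
    n_pep = grouped["peptide_id"].nunique()
    return ProteinQuantMatrix(values=values, n_peptides=n_pep, normalization="raw")


def _size_factors(matrix: ProteinQuantMatrix, spec: NormalizationSpec) -> pd.Series:
    vals = matrix.values
    if spec.method == "none":
        raw = pd.Series(1.0, index=vals.columns)
    elif spec.method == "robust_mean":
        raw = {}
        for s in vals.columns:
            col = vals[s].values
            pos = col[col > 0]
            if pos.size == 0:
                raise InputError(f"sample {s!r} has no positive intensities")
            raw[s] = float(np.exp(stats.trim_mean(np.log(pos), spec.trim)))
        raw = pd.Series(raw)
    else:  # carboxylase / bira: mean intensity of the reference set
        missing = [r for r in spec.reference_ids if r not in vals.index]
        if missing:
            raise InputError(f"reference proteins absent from matrix: {missing}")
        ref = vals.loc[list(spec.reference_ids)]
        raw = ref.mean(axis=0)
        zero = raw[raw <= 0]
        if not zero.empty:
            raise InputError(
                f"reference set has zero intensity in sample(s) {list(zero.index)}"
            )
    return raw


def normalize(matrix: ProteinQuantMatrix, spec: NormalizationSpec) -> ProteinQuantMatrix:
    """Divide each sample column by its scheme size factor.

    Factors are rescaled so their geometric mean is 1, which preserves the
    overall intensity scale; for reference-based schemes the reference-set
    mean becomes identical across samples.
    """
    raw = _size_factors(matrix, spec)
    factors = raw / stats.gmean(raw.values)
    values = matrix.values.div(factors, axis=1)
    return ProteinQuantMatrix(
        values=values,
        n_peptides=matrix.n_peptides.copy(),
        normalization=spec.method,
        size_factors=factors,
    )


def qc_cv(matrix: ProteinQuantMatrix, samples: pd.DataFrame) -> QcReport:
    """Percent CV per protein across QC-pool injections.

    %CV = 100 * sd / mean over the QC columns; the summary is the mean over
    proteins with nonzero mean, reported for all proteins and for those
    quantified by two or more peptides.
    """
    qc_ids = samples.loc[samples.is_qc, "sample_id"].tolist()
    qc_ids = [s for s in qc_ids if s in matrix.values.columns]
    if len(qc_ids) < 2:
        raise InputError("need at least 2 annotated QC-pool samples")
    sub = matrix.values[qc_ids]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    cv = cv.where(mean > 0)
    multi = matrix.n_peptides >= 2
    return QcReport(
        per_protein=cv,
        mean_all=float(cv.mean()),
        mean_multi_peptide=float(cv[multi].mean()),
        n_qc_samples=len(qc_ids),
    )
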