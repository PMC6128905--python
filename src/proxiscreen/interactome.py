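"""Per-isoform interactome calling from normalized protein matrices.

A protein belongs to a bait's interactome when its labeling is enriched over
the ligase-only control: fold change of replicate means at least a
calibrated threshold, a Student's t test on log2 intensities below alpha,
and support by at least two distinct peptides.  The fold threshold is
calibrated from known positive controls (the RAF kinases, direct RAS
effectors): the least recovered control sets the stringency, floored at
2-fold.  Passing proteins are summarized as per-bait sets with the disjoint
Venn partition, and as a z-scored, hierarchically clustered matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .bioid import ProteinQuantMatrix

__all__ = [
    "StringencyCalibration",
    "CalibrationResult",
    "InteractomeSet",
    "ClusterResult",
    "pseudo_intensity",
    "compute_enrichment",
    "calibrate_threshold",
    "call_interactome",
    "venn_partition",
    "zscore_and_cluster",
    "adjust_bh",
]

DEFAULT_POSITIVE_CONTROLS = ("ARAF", "BRAF", "RAF1")


class CalibrationError(ValueError):
    """Raised when a positive control fails the significance requirement."""


@dataclass
class StringencyCalibration:
    """Positive-control-driven stringency for interactome membership."""

    positive_controls: Sequence[str] = DEFAULT_POSITIVE_CONTROLS
    alpha: float = 0.05
    floor: float = 2.0


@dataclass
class CalibrationResult:
    derived: float          # min fold over positive controls
    applied: float          # max(derived, floor)
    control_folds: pd.Series
    log: dict = field(default_factory=dict)


@dataclass
class InteractomeSet:
    """Per-bait passing sets, their union and disjoint Venn partition."""

    members: dict[str, frozenset]
    union: frozenset
    venn: dict[str, int]
    records: pd.DataFrame | None = None


@dataclass
class ClusterResult:
    zscores: pd.DataFrame
    row_order: list
    col_order: list
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    zero_sd_proteins: list


def pseudo_intensity(values: pd.DataFrame) -> float:
    """Half the smallest nonzero intensity — substituted for exact zeros."""
    arr = values.values
    pos = arr[arr > 0]
    if pos.size == 0:
        raise ValueError("matrix has no positive intensities")
    return float(pos.min() / 2.0)


def _log2_with_pseudo(values: pd.DataFrame, pseudo: float) -> pd.DataFrame:
    return np.log2(values.where(values > 0, pseudo))


def _bait_columns(samples: pd.DataFrame, bait: str, condition: str | None) -> list[str]:
    sel = (samples.bait == bait) & (~samples.is_qc)
    if condition is not None and "condition" in samples.columns:
        sel &= samples.condition == condition
    return samples.loc[sel, "sample_id"].tolist()


def compute_enrichment(
    matrix: ProteinQuantMatrix,
    samples: pd.DataFrame,
    bait: str,
    control_bait: str = "control",
    alpha: float = 0.05,
    condition: str | None = None,
    pseudo: float | None = None,
) -> pd.DataFrame:
    """Fold change and t-test p-value of each protein for one bait.

    fold_change is the ratio of bait to control replicate means on the
    (pseudo-substituted) normalized intensities; the p-value comes from a
    two-sample pooled-variance Student's t test on log2 intensities.
    Degenerate zero-variance proteins get p = 1 when the means are equal and
    p = 0 otherwise, so constant noise-free tables stay interpretable.
    """
    bait_cols = _bait_columns(samples, bait, condition)
    ctl_cols = _bait_columns(samples, control_bait, condition)
    if len(bait_cols) < 2:
        raise ValueError(f"bait {bait!r} needs >=2 replicate samples, found {len(bait_cols)}")
    if len(ctl_cols) < 2:
        raise ValueError(
            f"control bait {control_bait!r} needs >=2 replicate samples, found {len(ctl_cols)}"
        )
    if pseudo is None:
        pseudo = pseudo_intensity(matrix.values)
    vals = matrix.values.where(matrix.values > 0, pseudo)
    b = vals[bait_cols].values
    c = vals[ctl_cols].values
    fold = b.mean(axis=1) / c.mean(axis=1)

    lb, lc = np.log2(b), np.log2(c)
    with warnings.catch_warnings():
        # degenerate zero-variance rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(lb, lc, axis=1, equal_var=True)
    pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = (lb.std(axis=1) == 0) & (lc.std(axis=1) == 0)
    equal_means = np.isclose(lb.mean(axis=1), lc.mean(axis=1))
    pvals = np.where(degenerate, np.where(equal_means, 1.0, 0.0), pvals)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    all_zero = (matrix.values[bait_cols + ctl_cols].values == 0).all(axis=1)
    return pd.DataFrame(
        {
            "protein_id": matrix.values.index,
            "bait": bait,
            "fold_change": fold,
            "p_value": pvals,
            "n_peptides": matrix.n_peptides.values,
            "all_zero": all_zero,
        }
    ).reset_index(drop=True)


def calibrate_threshold(
    records: pd.DataFrame, calibration: StringencyCalibration
) -> CalibrationResult:
    """Derive the fold threshold from the least recovered positive control.

    Every (control, bait) record must be significant at ``alpha``; each
    control's fold is the geometric mean of its per-bait folds; the derived
    threshold is the minimum over controls, floored at ``floor``.
    """
    folds = {}
    for pid in calibration.positive_controls:
        sub = records[records.protein_id == pid]
        if sub.empty:
            raise CalibrationError(f"positive control {pid!r} has no enrichment record")
        bad = sub[sub.p_value >= calibration.alpha]
        if not bad.empty:
            baits = bad.bait.tolist()
            raise CalibrationError(
                f"positive control {pid!r} not significant (p >= {calibration.alpha}) "
                f"for bait(s) {baits}"
            )
        folds[pid] = float(stats.gmean(sub.fold_change.values))
    control_folds = pd.Series(folds)
    derived = float(control_folds.min())
    applied = max(derived, calibration.floor)
    log = {
        "positive_controls": list(calibration.positive_controls),
        "control_folds": {k: float(v) for k, v in control_folds.items()},
        "derived_threshold": derived,
        "floor": calibration.floor,
        "applied_threshold": applied,
        "alpha": calibration.alpha,
    }
    return CalibrationResult(derived=derived, applied=applied, control_folds=control_folds, log=log)


def venn_partition(sets: Mapping[str, frozenset | set]) -> dict[str, int]:
    """Disjoint region counts for any number of named sets.

    Region keys join member names with ``&`` in the order given; counts sum
    to the union size.
    """
    names = list(sets)
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(set(sets[n]) for n in combo))
            outside = set.union(set(), *(set(sets[n]) for n in names if n not in combo))
            regions["&".join(combo)] = len(inside - outside)
    return regions


def call_interactome(
    records: pd.DataFrame, threshold: float, alpha: float = 0.05
) -> InteractomeSet:
    """Apply the fold / significance / >=2-peptide rule and partition baits.

    A record passes iff fold_change >= threshold, p_value < alpha and
    n_peptides >= 2.  Returns per-bait passing sets with the disjoint Venn
    partition over all baits present in ``records``.
    """
    rec = records.copy()
    rec["passes"] = (
        (rec.fold_change >= threshold)
        & (rec.p_value < alpha)
        & (rec.n_peptides >= 2)
    )
    members = {
        bait: frozenset(rec.loc[(rec.bait == bait) & rec.passes, "protein_id"])
        for bait in rec.bait.unique()
    }
    union = frozenset(set().union(*members.values())) if members else frozenset()
    venn = venn_partition(members)
    return InteractomeSet(members=members, union=union, venn=venn, records=rec)


def zscore_and_cluster(
    matrix: ProteinQuantMatrix,
    proteins: Sequence[str] | None = None,
    pseudo: float | None = None,
) -> ClusterResult:
    """Row-wise z-scores of log2 intensities with hierarchical clustering.

    z = (log2 value - row mean) / row sd per protein; rows with zero sd are
    set to 0 and flagged.  Samples and proteins are clustered with
    correlation distance (1 - Pearson) and average linkage; the emitted
    orders are the dendrogram leaf orders.
    """
    vals = matrix.values if proteins is None else matrix.values.loc[list(proteins)]
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 samples to z-score")
    if pseudo is None:
        pseudo = pseudo_intensity(vals if (vals.values > 0).any() else matrix.values)
    log2 = _log2_with_pseudo(vals, pseudo)
    mean = log2.mean(axis=1)
    sd = log2.std(axis=1, ddof=1)
    zero_sd = sd == 0
    z = log2.sub(mean, axis=0).div(sd.where(~zero_sd, 1.0), axis=0)
    z.loc[zero_sd] = 0.0

    def _linkage_order(data: np.ndarray, labels: list) -> tuple[np.ndarray | None, list]:
        if data.shape[0] < 2:
            return None, list(labels)
        d = pdist(data, metric="correlation")
        d = np.nan_to_num(d, nan=1.0)  # constant rows: treat as uncorrelated
        d = np.clip(d, 0.0, None)      # guard tiny negative rounding
        link = hierarchy.linkage(d, method="average")
        order = hierarchy.leaves_list(link)
        return link, [labels[i] for i in order]

    row_link, row_order = _linkage_order(z.values, list(z.index))
    col_link, col_order = _linkage_order(z.values.T, list(z.columns))
    return ClusterResult(
        zscores=z,
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
        zero_sd_proteins=list(z.index[zero_sd]),
    )


def adjust_bh(records: pd.DataFrame) -> pd.DataFrame:
    """Optional Benjamini–Hochberg adjustment (off by default downstream)."""
    rec = records.copy()
    rec["p_adjusted"] = stats.false_discovery_control(rec.p_value.values, method="bh")
    return rec
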