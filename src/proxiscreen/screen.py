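"""Pooled CRISPR dropout-screen scoring.

Guide counts are normalized to reads-per-million frequencies; each guide
gets a depletion metric, the replicate-averaged log2 change in frequency
from the first to the second post-selection timepoint within one genetic
background; the enrichment score of a guide in a RAS-transformed background
is its depletion metric minus the metric in the empty-vector background, so
selective dropout is negative.  Guides collapse to genes by the mean of the
three most extreme of five guides per direction; genes are classified
against a threshold tau (default 0.4 in log2 units, the enrichment of the
RAS effector BRAF) and percentile-ranked with top-1% flags per direction.

T0 (the post-infection library) is not part of the depletion metric; it is
summarized for representation QC (Gini coefficient).
"""

from __future__ import annotations

import math
from math import ceil

import numpy as np
import pandas as pd

__all__ = [
    "normalize_counts",
    "depletion_metric",
    "depletion_metrics_all",
    "enrichment_scores",
    "collapse_genes",
    "classify_genes",
    "class_fractions",
    "rank_percentiles",
    "gini",
    "library_representation",
]

CLASSES = ("positive", "negative", "both", "unaltered")


class ScreenError(ValueError):
    pass


def _count_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    if "guide_id" in counts.columns:
        counts = counts.set_index("guide_id")
    return counts


def normalize_counts(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Reads-per-million guide frequencies.

    freq = (count + pseudocount) / column_total * 1e6, where the column total
    is of the raw counts; each column therefore sums to
    1e6 * (1 + n_guides * pseudocount / total).
    """
    mat = _count_matrix(counts)
    totals = mat.sum(axis=0)
    empty = totals[totals <= 0]
    if not empty.empty:
        raise ScreenError(f"empty count column(s): {list(empty.index)}")
    return (mat + pseudocount).div(totals, axis=1) * 1e6


def _tp_columns(samples: pd.DataFrame, background: str, timepoint: str) -> pd.Series:
    sel = (samples.background == background) & (samples.timepoint == timepoint)
    sub = samples.loc[sel].set_index("replicate")["sample_id"]
    if sub.empty:
        raise ScreenError(f"no samples for background {background!r} timepoint {timepoint!r}")
    return sub


def depletion_metric(
    freq: pd.DataFrame,
    samples: pd.DataFrame,
    background: str,
    t1: str = "T1",
    t2: str = "T2",
) -> pd.Series:
    """Per-guide log2(freq@T2 / freq@T1), averaged over replicate pairs.

    Replicates are paired by replicate index and log-ratios averaged after
    the per-replicate ratio, so depletion comes out negative.
    """
    c1 = _tp_columns(samples, background, t1)
    c2 = _tp_columns(samples, background, t2)
    shared = sorted(set(c1.index) & set(c2.index))
    if not shared:
        raise ScreenError(f"no replicate pairs for {background!r} between {t1} and {t2}")
    ratios = [np.log2(freq[c2[r]] / freq[c1[r]]) for r in shared]
    out = pd.concat(ratios, axis=1).mean(axis=1)
    out.name = background
    return out


def depletion_metrics_all(freq: pd.DataFrame, samples: pd.DataFrame, **kw) -> pd.DataFrame:
    backgrounds = list(dict.fromkeys(samples.background))
    return pd.concat(
        [depletion_metric(freq, samples, b, **kw) for b in backgrounds], axis=1
    )


def enrichment_scores(metrics: pd.DataFrame, vector: str = "vector") -> pd.DataFrame:
    """Per-guide score per background: metric(background) - metric(vector).

    The vector column itself is identically 0 by construction.
    """
    if vector not in metrics.columns:
        raise ScreenError(f"vector background {vector!r} not scored")
    return metrics.sub(metrics[vector], axis=0)


def _topk_mean(scores: pd.DataFrame, k: int, largest: bool) -> float:
    """Mean of the k most extreme guide scores, ties broken by guide id.

    Uses an exactly rounded sum, so the result is independent of guide order.
    """
    ordered = scores.sort_values(["score", "guide_id"], ascending=[not largest, True])
    return math.fsum(ordered.head(k)["score"]) / k


def collapse_genes(
    scores: pd.DataFrame,
    library: pd.DataFrame,
    k: int = 3,
    include_classes: tuple[str, ...] = ("target", "ribosomal_control"),
) -> pd.DataFrame:
    """Collapse guide enrichment scores to gene level, best k per direction.

    pos_score is the mean of the k largest guide scores of the gene,
    neg_score the mean of the k smallest ("three best of five" in each
    direction).  Genes with fewer than k guides are collapsed over all their
    guides and flagged.  Ties in the top-k selection break on guide id.

    ``scores`` is a guide x background frame (index guide_id); output is
    long-form with one row per (gene, background).
    """
    lib = library.set_index("guide_id")
    unknown = [g for g in scores.index if g not in lib.index]
    if unknown:
        raise ScreenError(f"guides absent from library: {unknown[:5]}")
    lib = lib.loc[scores.index]
    keep = lib["class"].isin(include_classes)
    rows = []
    for background in scores.columns:
        df = pd.DataFrame(
            {
                "guide_id": scores.index[keep],
                "gene": lib.loc[keep, "gene"].values,
                "score": scores.loc[keep, background].values,
            }
        )
        for gene, sub in df.groupby("gene", sort=True):
            kk = min(k, len(sub))
            rows.append(
                {
                    "gene": gene,
                    "background": background,
                    "pos_score": _topk_mean(sub, kk, largest=True),
                    "neg_score": _topk_mean(sub, kk, largest=False),
                    "n_guides": len(sub),
                    "underpowered": len(sub) < k,
                }
            )
    return pd.DataFrame(rows)


def classify_genes(
    gene_scores: pd.DataFrame,
    tau: float = 0.4,
    benchmark: str | None = None,
) -> pd.DataFrame:
    """Four-way classification per (gene, background).

    positive iff pos_score >= +tau, negative iff neg_score <= -tau, both iff
    both hold, unaltered otherwise.  With ``benchmark`` given, tau is
    recalibrated per background to |neg_score(benchmark)| in that
    background (the BRAF-style rule).
    """
    out = gene_scores.copy()
    if benchmark is not None:
        bench = out[out.gene == benchmark].set_index("background")["neg_score"]
        if bench.empty:
            raise ScreenError(f"benchmark gene {benchmark!r} missing from gene scores")
        tau_by_bkg = bench.abs()
        out["tau"] = out.background.map(tau_by_bkg)
        if out["tau"].isna().any():
            missing = out.loc[out["tau"].isna(), "background"].unique().tolist()
            raise ScreenError(f"benchmark gene {benchmark!r} unscored in {missing}")
    else:
        out["tau"] = tau
    pos = out.pos_score >= out.tau
    neg = out.neg_score <= -out.tau
    out["class"] = np.select(
        [pos & neg, pos, neg], ["both", "positive", "negative"], default="unaltered"
    )
    return out


def class_fractions(classified: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per-background fractions of the four classes (sum to 1)."""
    result: dict[str, dict[str, float]] = {}
    for background, sub in classified.groupby("background"):
        n = len(sub)
        counts = sub["class"].value_counts()
        result[background] = {c: float(counts.get(c, 0)) / n for c in CLASSES}
    return result


def rank_percentiles(gene_scores: pd.DataFrame, top_fraction: float = 0.01) -> pd.DataFrame:
    """Percentile ranks and top-1% flags per direction, waterfall-sorted.

    Flags the ceil(top_fraction * n) genes with the largest pos_score
    (top_positive) and the smallest neg_score (top_negative) within each
    background; rows come back sorted by descending pos_score within
    background (waterfall order).
    """
    out = gene_scores.copy()
    pieces = []
    for _background, sub in out.groupby("background", sort=False):
        sub = sub.copy()
        n = len(sub)
        n_top = ceil(top_fraction * n)
        sub["pos_percentile"] = sub.pos_score.rank(pct=True, method="average") * 100
        sub["neg_percentile"] = sub.neg_score.rank(pct=True, method="average") * 100
        top_pos = sub.sort_values(["pos_score", "gene"], ascending=[False, True]).head(n_top)
        top_neg = sub.sort_values(["neg_score", "gene"], ascending=[True, True]).head(n_top)
        sub["top_positive"] = sub.gene.isin(top_pos.gene).values
        sub["top_negative"] = sub.gene.isin(top_neg.gene).values
        pieces.append(sub.sort_values(["pos_score", "gene"], ascending=[False, True]))
    return pd.concat(pieces).reset_index(drop=True)


def gini(x: np.ndarray) -> float:
    """Gini coefficient of a non-negative vector (0 = perfectly even)."""
    x = np.sort(np.asarray(x, dtype=float))
    if x.sum() == 0:
        return 0.0
    n = x.size
    cum = np.cumsum(x)
    return float((n + 1 - 2 * (cum / cum[-1]).sum()) / n)


def library_representation(
    counts: pd.DataFrame, samples: pd.DataFrame, timepoint: str = "T0"
) -> pd.DataFrame:
    """Per-sample representation QC at the library timepoint."""
    mat = _count_matrix(counts)
    sel = samples[samples.timepoint == timepoint]
    rows = []
    for _, s in sel.iterrows():
        col = mat[s.sample_id].values
        rows.append(
            {
                "sample_id": s.sample_id,
                "background": s.background,
                "total_reads": int(col.sum()),
                "zero_guides": int((col == 0).sum()),
                "gini": gini(col),
            }
        )
    return pd.DataFrame(rows)
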