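"""Joining the labeling and dropout arms into vulnerability calls.

The terminal product is a table of dual-assay records: per entity, the
labeling fold change per bait and the collapsed negative screen score per
background, with reference-benchmarked hit flags — an entity is a dual hit
for an isoform when it is enriched at least half as well as the reference
gene in both assays (labeling fold at least half the reference's fold, and
neg_score at least half as depleted as the reference's).  Also here:
knockout-dependent differential interactomes (delta = 0.1 log2 rule,
benchmarked to the reference protein's own reduction), hypergeometric
(one-sided Fisher) over-representation of gene sets, and the plate-assay
percent-viability formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bioid import ProteinQuantMatrix
from .interactome import pseudo_intensity

__all__ = [
    "join_assays",
    "dual_hit_call",
    "differential_labeling",
    "DifferentialResult",
    "overrepresentation",
    "read_gmt",
    "percent_viability",
]


class IntegrationError(ValueError):
    pass


def join_assays(
    interactome_records: pd.DataFrame,
    gene_scores: pd.DataFrame,
    id_map: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Join labeling records to screen gene scores through an id map.

    ``interactome_records`` is the long enrichment table (protein_id, bait,
    fold_change, optionally passes); ``gene_scores`` the collapsed screen
    table (gene, background, pos_score, neg_score); ``id_map`` has columns
    protein_id, gene.  Many-to-many mappings are rejected; entities present
    in only one arm go to the sidecar report, one joined record per mappable
    entity comes back wide (labeling_<bait>, passes_<bait>, neg_<background>,
    pos_<background>).
    """
    for col in ("protein_id", "gene"):
        if col not in id_map.columns:
            raise IntegrationError(f"id map missing column {col!r}")
    dup_p = id_map.protein_id[id_map.protein_id.duplicated()].unique().tolist()
    dup_g = id_map.gene[id_map.gene.duplicated()].unique().tolist()
    if dup_p or dup_g:
        raise IntegrationError(
            f"ambiguous id map; duplicated proteins {dup_p[:5]}, genes {dup_g[:5]}"
        )

    lab = interactome_records.pivot(index="protein_id", columns="bait", values="fold_change")
    lab.columns = [f"labeling_{b}" for b in lab.columns]
    if "passes" in interactome_records.columns:
        mem = interactome_records.pivot(index="protein_id", columns="bait", values="passes")
        mem.columns = [f"passes_{b}" for b in mem.columns]
        lab = lab.join(mem)

    neg = gene_scores.pivot(index="gene", columns="background", values="neg_score")
    neg.columns = [f"neg_{b}" for b in neg.columns]
    pos = gene_scores.pivot(index="gene", columns="background", values="pos_score")
    pos.columns = [f"pos_{b}" for b in pos.columns]
    scr = neg.join(pos)

    mapping = id_map.set_index("protein_id")["gene"]
    mappable = lab.index.intersection(mapping.index)
    joined = lab.loc[mappable].copy()
    joined["gene"] = mapping.loc[mappable].values
    joined = joined[joined.gene.isin(scr.index)]
    joined = joined.join(scr, on="gene")
    joined.index.name = "entity_id"
    joined = joined.reset_index()

    sidecar = {
        "proteins_without_mapping": sorted(set(lab.index) - set(mapping.index)),
        "proteins_without_screen_scores": sorted(
            set(mappable) - set(joined.entity_id)
        ),
        "genes_without_labeling": sorted(set(scr.index) - set(joined.gene)),
    }
    return joined, sidecar


def dual_hit_call(
    records: pd.DataFrame,
    reference: str,
    isoform: str,
    require_membership: bool = True,
) -> pd.DataFrame:
    """Flag entities enriched at least half as well as the reference.

    For the given isoform: labeling_<isoform> >= 0.5 * reference labeling
    and neg_<isoform> <= 0.5 * reference neg_score (neg scores are negative,
    so "half as well" means at least half as depleted).  The reference must
    itself have positive labeling and a negative neg_score in the isoform,
    and always flags.  When membership columns (passes_<isoform>) are
    present and ``require_membership`` is set, candidates are additionally
    restricted to the isoform's called interactome.
    """
    lab_col, neg_col = f"labeling_{isoform}", f"neg_{isoform}"
    for col in (lab_col, neg_col):
        if col not in records.columns:
            raise IntegrationError(f"records missing column {col!r}")
    ref_rows = records[records.entity_id == reference]
    if ref_rows.empty:
        raise IntegrationError(f"reference {reference!r} absent from records")
    ref_lab = float(ref_rows[lab_col].iloc[0])
    ref_neg = float(ref_rows[neg_col].iloc[0])
    if not ref_lab > 0:
        raise IntegrationError(
            f"reference {reference!r} has non-positive labeling in {isoform}"
        )
    if not ref_neg < 0:
        raise IntegrationError(
            f"reference {reference!r} has non-negative neg_score in {isoform} "
            f"({ref_neg:.3g})"
        )
    out = records.copy()
    flag = (out[lab_col] >= 0.5 * ref_lab) & (out[neg_col] <= 0.5 * ref_neg)
    flag |= out.entity_id == reference  # the reference trivially meets its own rule
    mem_col = f"passes_{isoform}"
    if require_membership and mem_col in out.columns:
        flag &= out[mem_col].fillna(False).astype(bool)
    out[f"dual_hit_{isoform}"] = flag.fillna(False)
    return out


@dataclass
class DifferentialResult:
    """Knockout-vs-vector differential labeling table and its benchmark."""

    records: pd.DataFrame  # protein_id, fold_difference, direction, per-line columns
    benchmark: float       # the reference protein's own fold difference
    summary: dict = field(default_factory=dict)


def differential_labeling(
    matrix_vector: ProteinQuantMatrix,
    matrix_ko: ProteinQuantMatrix | Mapping[str, ProteinQuantMatrix],
    reference: str,
    delta: float = 0.1,
    pseudo: float | None = None,
) -> DifferentialResult:
    """Log2 fold difference of labeling between knockout and vector samples.

    fold_difference = mean log2(ko) - mean log2(vector) per protein, where
    the knockout mean weights each knockout line equally (lines passed as a
    mapping line -> matrix; a single matrix is one line).  Direction is
    enriched (>= +delta), depleted (<= -delta) or unchanged, and the
    reference protein's own fold difference is reported as the benchmark.
    Both matrices must carry the same normalization.
    """
    lines = (
        dict(matrix_ko) if isinstance(matrix_ko, Mapping) else {"ko": matrix_ko}
    )
    for name, m in lines.items():
        if m.normalization != matrix_vector.normalization:
            raise IntegrationError(
                f"knockout line {name!r} normalized as {m.normalization!r} but vector "
                f"matrix as {matrix_vector.normalization!r}"
            )
    shared = matrix_vector.values.index
    for m in lines.values():
        shared = shared.intersection(m.values.index)
    if reference not in shared:
        raise IntegrationError(f"reference protein {reference!r} absent from both matrices")
    if pseudo is None:
        pool = [matrix_vector.values.loc[shared]] + [
            m.values.loc[shared] for m in lines.values()
        ]
        pseudo = pseudo_intensity(pd.concat(pool, axis=1))

    def _mean_log2(values: pd.DataFrame) -> pd.Series:
        return np.log2(values.where(values > 0, pseudo)).mean(axis=1)

    vec = _mean_log2(matrix_vector.values.loc[shared])
    per_line = {
        name: _mean_log2(m.values.loc[shared]) - vec for name, m in lines.items()
    }
    line_df = pd.DataFrame(per_line)
    fold_diff = line_df.mean(axis=1)
    direction = np.select(
        [fold_diff >= delta, fold_diff <= -delta],
        ["enriched", "depleted"],
        default="unchanged",
    )
    records = pd.DataFrame({"protein_id": shared, "fold_difference": fold_diff.values})
    for name in per_line:
        records[f"diff_{name}"] = line_df[name].values
    records["direction"] = direction
    benchmark = float(fold_diff.loc[reference])
    summary = {
        "delta": delta,
        "n_enriched": int((direction == "enriched").sum()),
        "n_depleted": int((direction == "depleted").sum()),
        "n_unchanged": int((direction == "unchanged").sum()),
        "benchmark_protein": reference,
        "benchmark_fold_difference": benchmark,
        "knockout_lines": list(lines),
    }
    return DifferentialResult(records=records, benchmark=benchmark, summary=summary)


def overrepresentation(
    hits: set,
    gene_sets: Mapping[str, set],
    background: set,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation sets in a hit list.

    One-sided Fisher exact p toward enrichment by default (``alternative``
    may be "two-sided"); fold enrichment is (overlap/hits) / (set/background).
    Annotation sets are intersected with the background; hits must be a
    subset of the background.
    """
    if not background:
        raise IntegrationError("background set is empty")
    stray = set(hits) - set(background)
    if stray:
        raise IntegrationError(f"hits outside background: {sorted(stray)[:5]}")
    N, n = len(background), len(hits)
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & set(background)
        K = len(inset)
        k = len(inset & set(hits))
        if alternative == "greater":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            table = [[k, K - k], [n - k, (N - K) - (n - k)]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        fold = (k / n) / (K / N) if n > 0 and K > 0 else np.nan
        rows.append(
            {
                "set_id": name,
                "overlap": k,
                "set_size": K,
                "hit_list_size": n,
                "background_size": N,
                "p_value": p,
                "fold_enrichment": fold,
            }
        )
    return pd.DataFrame(rows)


def read_gmt(path) -> dict[str, set]:
    """Read gene sets from a GMT file (set id, description, members...)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets


def percent_viability(treated, blank, negative_control):
    """Plate-reader viability: 100 * (treated - blank) / (negative - blank).

    May exceed 100 or go negative; reported as-is.  Scalars or arrays.
    """
    treated = np.asarray(treated, dtype=float)
    blank = np.asarray(blank, dtype=float)
    negative_control = np.asarray(negative_control, dtype=float)
    if np.any(negative_control <= blank):
        raise IntegrationError("negative control must exceed blank absorbance")
    out = 100.0 * (treated - blank) / (negative_control - blank)
    return float(out) if out.ndim == 0 else out
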