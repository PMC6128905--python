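"""Calibration and parameter-recovery studies on the synthetic assays.

Each study runs one simulator configuration through the corresponding
analysis stages and reports the quantities that characterize the method:
technical %CV recovery, null false-positive calibration, spike-in recall
and false-discovery proportion, threshold calibration accuracy, screen
control behaviour, and the end-to-end dual-hit headline.  They are used by
the acceptance script and exercised directly in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bioid, interactome, pipeline, screen, simulate

__all__ = [
    "qc_cv_study",
    "null_calibration_study",
    "bioid_recovery_study",
    "screen_recovery_study",
    "end_to_end_study",
]


def _aggregate_and_normalize(sim: simulate.BioidSim, config: simulate.BioidSimConfig):
    matrix = bioid.aggregate_peptides(sim.peptides.copy())
    spec = bioid.NormalizationSpec(
        method="carboxylase", reference_ids=config.reference_proteins.carboxylase
    )
    return bioid.normalize(matrix, spec)


def qc_cv_study(seed: int = 0, cv: float = 0.08, n_proteins: int = 1500) -> dict:
    """Recover the configured technical CV from the QC-pool injections."""
    config = simulate.BioidSimConfig(
        n_proteins=n_proteins,
        n_true_per_bait={},
        spiked={},
        replicate_cv=cv,
        n_qc_samples=4,
        seed=seed,
    )
    sim = simulate.simulate_bioid(config)
    matrix = _aggregate_and_normalize(sim, config)
    report = bioid.qc_cv(matrix, sim.samples)
    return {
        "configured_cv_pct": 100.0 * cv,
        "qc_mean_cv_pct": report.mean_all,
        "qc_mean_cv_pct_multi_peptide": report.mean_multi_peptide,
        "n_proteins": len(matrix.values),
    }


def null_calibration_study(seed: int = 0, n_proteins: int = 2000) -> dict:
    """All true folds 1: the t-test should be uniform and the filter silent.

    Runs on unnormalized intensities: empirical size factors are shared
    across proteins, which leaves each test valid but correlates them all,
    so the per-protein calibration of the t-test is checked in isolation.
    """
    config = simulate.BioidSimConfig(
        n_proteins=n_proteins,
        n_true_per_bait={},
        spiked={},
        reference_proteins=simulate.ReferenceProteins(raf={}),
        seed=seed,
    )
    sim = simulate.simulate_bioid(config)
    matrix = bioid.aggregate_peptides(sim.peptides.copy())
    records = interactome.compute_enrichment(matrix, sim.samples, "KRAS")
    inter = interactome.call_interactome(records, threshold=2.0, alpha=0.05)
    frac_sig = float((records.p_value < 0.05).mean())
    pass_rate = float(inter.records.passes.mean())
    return {
        "n_proteins": len(records),
        "fraction_p_below_05": frac_sig,
        "pass_rate_at_2fold": pass_rate,
    }


def bioid_recovery_study(seed: int = 0, n_proteins: int = 2000, n_spiked: int = 100) -> dict:
    """Spike-in recovery: recall, FDP and calibrated-threshold accuracy.

    100 interactors at fold 4 (cv 0.10) among 2000 proteins for one bait;
    RAF-like controls planted at folds {4.0, 3.0, 2.5} so the calibrated
    stringency should land near the least recovered control (2.5).
    """
    config = simulate.BioidSimConfig(
        n_proteins=n_proteins,
        n_true_per_bait={"KRAS": n_spiked},
        shared_interactor_fraction=0.0,
        true_fold=4.0,
        replicate_cv=0.10,
        spiked={},
        seed=seed,
    )
    sim = simulate.simulate_bioid(config)
    matrix = _aggregate_and_normalize(sim, config)
    records = pd.concat(
        [
            interactome.compute_enrichment(matrix, sim.samples, b)
            for b in ("KRAS", "NRAS", "HRAS")
        ],
        ignore_index=True,
    )
    calib = interactome.calibrate_threshold(records, interactome.StringencyCalibration())
    inter = interactome.call_interactome(
        records[records.bait == "KRAS"], calib.applied, alpha=0.05
    )
    called = set(inter.members["KRAS"])
    truth = sim.truth.set_index("entity_id")
    spiked = set(truth.index[truth.kind == "interactor"])
    null_ids = set(truth.index[truth.fold_KRAS == 1.0])
    recall = len(called & spiked) / len(spiked)
    fdp = len(called & null_ids) / max(len(called), 1)
    return {
        "n_proteins": n_proteins,
        "n_spiked": len(spiked),
        "recall": recall,
        "false_discovery_proportion": fdp,
        "derived_threshold": calib.derived,
        "applied_threshold": calib.applied,
        "injected_min_control_fold": min(config.reference_proteins.raf.values()),
    }


def screen_recovery_study(seed: int = 0, n_genes: int = 500) -> dict:
    """Default screen: planted gene, ribosomal controls, non-targeting null."""
    config = simulate.ScreenSimConfig(n_genes=n_genes, seed=seed)
    sim = simulate.simulate_screen(config)
    freq = screen.normalize_counts(sim.counts)
    metrics = screen.depletion_metrics_all(freq, sim.samples)
    scores = screen.enrichment_scores(metrics, vector=config.backgrounds[0])
    gene_scores = screen.classify_genes(screen.collapse_genes(scores, sim.library))
    gene_scores = screen.rank_percentiles(gene_scores)

    ras = [b for b in config.backgrounds if b != config.backgrounds[0]]
    targets = gene_scores[
        gene_scores.gene.isin(sim.library.loc[sim.library["class"] == "target", "gene"])
    ]
    planted_rank = {}
    planted_class = {}
    for b in ras:
        sub = targets[targets.background == b].sort_values(["neg_score", "gene"])
        planted_rank[b] = int(np.flatnonzero(sub.gene.values == "PIP5K1A")[0]) + 1
        cls = gene_scores[(gene_scores.gene == "PIP5K1A") & (gene_scores.background == b)]
        planted_class[b] = cls["class"].iloc[0]

    ribo_genes = sim.library.loc[sim.library["class"] == "ribosomal_control", "gene"].unique()
    ribo = gene_scores[gene_scores.gene.isin(ribo_genes) & gene_scores.background.isin(ras)]
    ribo_negative_fraction = float((ribo["class"] == "negative").mean())

    nt_guides = sim.library.loc[sim.library["class"] == "nontargeting", "guide_id"]
    nt_scores = scores.loc[nt_guides, ras]
    nontargeting_mean = float(nt_scores.values.mean())

    return {
        "n_genes": n_genes,
        "planted_gene_rank_by_background": planted_rank,
        "planted_gene_class_by_background": planted_class,
        "planted_rank_kras": planted_rank["KRAS"],
        "planted_negative_only_kras": (
            planted_class["KRAS"] == "negative"
            and all(planted_class[b] != "negative" for b in ras if b != "KRAS")
        ),
        "ribosomal_negative_fraction": ribo_negative_fraction,
        "nontargeting_mean_enrichment": nontargeting_mean,
        "n_nontargeting_guides": int(len(nt_guides)),
    }


def end_to_end_study(seed: int = 0) -> dict:
    """Full dual-assay run; the headline is the reference's dual-hit pattern."""
    result = pipeline.run_end_to_end(seed=seed)
    dual_kras = result.dual_records.get("dual_hit_KRAS")
    n_dual_kras = int(dual_kras.sum()) if dual_kras is not None else 0
    return {
        "n_proteins": len(result.matrix.values),
        "reference_dual_hit_isoforms": result.dual_hit_isoforms,
        "n_dual_hit_isoforms": len(result.dual_hit_isoforms),
        "n_dual_hits_kras": n_dual_kras,
        "interactome_union_size": len(result.interactome_set.union),
        "applied_fold_threshold": result.calibration.applied,
        "differential_benchmark": (
            result.differential.benchmark if result.differential else None
        ),
        "metadata": result.metadata,
    }
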