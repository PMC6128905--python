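"""Dual-assay joins, reference-benchmarked hits, differential labeling,
over-representation and viability arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from proxiscreen.bioid import ProteinQuantMatrix
from proxiscreen.integrate import (
    IntegrationError,
    differential_labeling,
    dual_hit_call,
    join_assays,
    overrepresentation,
    percent_viability,
)


def interactome_records(entries):
    return pd.DataFrame(entries, columns=["protein_id", "bait", "fold_change", "passes"])


def gene_scores(entries):
    return pd.DataFrame(entries, columns=["gene", "background", "pos_score", "neg_score"])


class TestJoin:
    def setup_method(self):
        self.records = interactome_records(
            [("P1", "KRAS", 8.0, True), ("P2", "KRAS", 4.0, True), ("P3", "KRAS", 3.0, True)]
        )
        self.scores = gene_scores(
            [("g1", "KRAS", 0.1, -1.2), ("g2", "KRAS", 0.0, -0.6)]
        )
        self.id_map = pd.DataFrame(
            {"protein_id": ["P1", "P2"], "gene": ["g1", "g2"]}
        )

    def test_joined_and_sidecar(self):
        joined, sidecar = join_assays(self.records, self.scores, self.id_map)
        assert set(joined.entity_id) == {"P1", "P2"}
        assert sidecar["proteins_without_mapping"] == ["P3"]
        row = joined.set_index("entity_id").loc["P1"]
        assert row["labeling_KRAS"] == 8.0
        assert row["neg_KRAS"] == -1.2

    def test_matches_dictionary_merge_oracle(self):
        rng = np.random.default_rng(10)
        n = 100
        prots = [f"P{i}" for i in range(n)]
        genes = [f"g{i}" for i in range(n)]
        rec = interactome_records(
            [(p, "KRAS", float(rng.uniform(1, 10)), True) for p in prots]
        )
        keep = rng.random(n) < 0.7
        sc = gene_scores(
            [(g, "KRAS", 0.0, float(rng.normal())) for g, k in zip(genes, keep) if k]
        )
        id_map = pd.DataFrame({"protein_id": prots, "gene": genes})
        joined, _ = join_assays(rec, sc, id_map)
        oracle = {}
        folds = {r[0]: r[2] for r in rec.itertuples(index=False)}
        negs = {r[0]: r[3] for r in sc.itertuples(index=False)}
        for p, g in zip(prots, genes):
            if p in folds and g in negs:
                oracle[p] = (folds[p], negs[g])
        assert set(joined.entity_id) == set(oracle)
        sub = joined.set_index("entity_id")
        for p, (fold, neg) in oracle.items():
            assert sub.loc[p, "labeling_KRAS"] == fold
            assert sub.loc[p, "neg_KRAS"] == neg

    def test_ambiguous_mapping_rejected(self):
        bad = pd.DataFrame({"protein_id": ["P1", "P1"], "gene": ["g1", "g2"]})
        with pytest.raises(IntegrationError, match="P1"):
            join_assays(self.records, self.scores, bad)


def dual_records(entries):
    return pd.DataFrame(entries, columns=["entity_id", "labeling_KRAS", "neg_KRAS"])


class TestDualHit:
    def test_exact_boundary_is_a_hit(self):
        rec = dual_records([("REF", 8.0, -1.2), ("C", 4.0, -0.6)])
        out = dual_hit_call(rec, "REF", "KRAS").set_index("entity_id")
        assert out.loc["C", "dual_hit_KRAS"]
        assert out.loc["REF", "dual_hit_KRAS"]

    def test_just_below_boundary_is_not(self):
        rec = dual_records([("REF", 8.0, -1.2), ("C", 4.0, -0.5)])
        out = dual_hit_call(rec, "REF", "KRAS").set_index("entity_id")
        assert not out.loc["C", "dual_hit_KRAS"]

    def test_reference_preconditions(self):
        with pytest.raises(IntegrationError, match="non-negative"):
            dual_hit_call(dual_records([("REF", 8.0, 0.1)]), "REF", "KRAS")
        with pytest.raises(IntegrationError, match="absent"):
            dual_hit_call(dual_records([("X", 8.0, -1.0)]), "REF", "KRAS")

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, lab_scale, neg_scale):
        """Rescaling all labeling or all neg scores never changes the calls."""
        rec = dual_records(
            [("REF", 8.0, -1.2), ("A", 4.1, -0.7), ("B", 3.9, -0.7), ("C", 5.0, -0.55)]
        )
        base = dual_hit_call(rec, "REF", "KRAS")["dual_hit_KRAS"]
        scaled = rec.copy()
        scaled["labeling_KRAS"] *= lab_scale
        scaled["neg_KRAS"] *= neg_scale
        out = dual_hit_call(scaled, "REF", "KRAS")["dual_hit_KRAS"]
        assert (out == base).all()

    def test_membership_gating(self):
        rec = dual_records([("REF", 8.0, -1.2), ("C", 4.0, -0.6)])
        rec["passes_KRAS"] = [True, False]
        out = dual_hit_call(rec, "REF", "KRAS").set_index("entity_id")
        assert not out.loc["C", "dual_hit_KRAS"]

    def test_planted_dual_effect_genes_recovered(self):
        """Genes planted at >=60% of the reference effect in both assays are
        flagged under default assay noise."""
        from proxiscreen import bioid as bq
        from proxiscreen import screen as scr
        from proxiscreen import simulate

        frac = 0.7
        planted = {f"D{i:02d}": {"KRAS": 4.0 * frac} for i in range(20)}
        planted["REF"] = {"KRAS": 4.0}
        config = simulate.BioidSimConfig(
            n_proteins=300, n_true_per_bait={}, spiked=planted, seed=3
        )
        sim = simulate.simulate_bioid(config)
        matrix = bq.aggregate_peptides(sim.peptides.copy())
        from proxiscreen.interactome import compute_enrichment

        rec = compute_enrichment(matrix, sim.samples, "KRAS")

        planted_genes = sorted(planted)
        genes = planted_genes + [f"N{i:03d}" for i in range(80)]  # neutral filler
        fitness = {g: {"KRAS": -0.8 * frac} for g in planted_genes}
        fitness["REF"] = {"KRAS": -0.8}
        sconfig = simulate.ScreenSimConfig(
            genes=genes, fitness=fitness, n_ribosomal_controls=5,
            n_nontargeting=10, seed=4,
        )
        ssim = simulate.simulate_screen(sconfig)
        freq = scr.normalize_counts(ssim.counts)
        metrics = scr.depletion_metrics_all(freq, ssim.samples)
        scores = scr.enrichment_scores(metrics)
        gsc = scr.collapse_genes(scores, ssim.library)

        id_map = pd.DataFrame({"protein_id": genes, "gene": genes})
        joined, _ = join_assays(rec, gsc, id_map)
        out = dual_hit_call(joined, "REF", "KRAS", require_membership=False)
        flagged = out.set_index("entity_id")["dual_hit_KRAS"]
        assert flagged[[f"D{i:02d}" for i in range(20)]].sum() >= 18


class TestDifferential:
    def matrix(self, values, tag="bira"):
        df = pd.DataFrame(values).T
        df.columns = [f"s{i}" for i in range(df.shape[1])]
        return ProteinQuantMatrix(df, pd.Series(2, index=df.index), normalization=tag)

    def test_self_comparison_is_exactly_zero(self):
        m = self.matrix({"REF": [4.0, 5.0], "A": [1.0, 2.0]})
        out = differential_labeling(m, m, reference="REF")
        assert (out.records.fold_difference == 0).all()
        assert (out.records.direction == "unchanged").all()

    def test_doubling_is_plus_one_enriched(self):
        vec = self.matrix({"REF": [4.0, 4.0], "A": [3.0, 3.0]})
        ko = self.matrix({"REF": [4.0, 4.0], "A": [6.0, 6.0]})
        out = differential_labeling(vec, ko, reference="REF")
        rec = out.records.set_index("protein_id")
        assert np.isclose(rec.loc["A", "fold_difference"], 1.0)
        assert rec.loc["A", "direction"] == "enriched"

    def test_benchmark_is_line_mixture_mean(self):
        """Reference reduced 8-fold in one line, 2-fold in two: the benchmark
        is the equal-weight mean of the per-line log2 reductions."""
        vec = self.matrix({"REF": [8.0, 8.0], "A": [1.0, 1.0]})
        lines = {
            "l1": self.matrix({"REF": [4.0, 4.0], "A": [1.0, 1.0]}),
            "l2": self.matrix({"REF": [4.0, 4.0], "A": [1.0, 1.0]}),
            "l3": self.matrix({"REF": [1.0, 1.0], "A": [1.0, 1.0]}),
        }
        out = differential_labeling(vec, lines, reference="REF")
        assert np.isclose(out.benchmark, (-1.0 - 1.0 - 3.0) / 3)
        assert out.summary["n_depleted"] == 1

    def test_mismatched_normalization_rejected(self):
        vec = self.matrix({"REF": [1.0, 1.0]}, tag="bira")
        ko = self.matrix({"REF": [1.0, 1.0]}, tag="carboxylase")
        with pytest.raises(IntegrationError, match="normalized"):
            differential_labeling(vec, ko, reference="REF")


class TestOverrepresentation:
    def test_closed_form_full_overlap(self):
        """background 10, set 5, hits 5, overlap 5: p = 1/C(10,5)."""
        background = set(range(10))
        out = overrepresentation({0, 1, 2, 3, 4}, {"s": {0, 1, 2, 3, 4}}, background)
        assert np.isclose(out.p_value[0], 1 / math.comb(10, 5), rtol=1e-12)
        assert out.overlap[0] == 5

    def test_proportional_overlap_fold_one(self):
        background = set(range(100))
        hits = set(range(20))            # 20% of background
        gene_set = set(range(0, 100, 10))  # overlap 2 of 10 = 20% of hits
        out = overrepresentation(hits, {"s": gene_set}, background)
        assert np.isclose(out.fold_enrichment[0], 1.0)

    def test_matches_hypergeometric_tail_oracle(self):
        """p equals the explicit hypergeometric tail sum to 1e-12."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            N = int(rng.integers(20, 80))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            background = set(range(N))
            gene_set = set(range(K))
            hits = set(rng.choice(N, size=n, replace=False).tolist())
            out = overrepresentation(hits, {"s": gene_set}, background)
            k = len(hits & gene_set)
            tail = sum(
                math.comb(K, j) * math.comb(N - K, n - j)
                for j in range(k, min(K, n) + 1)
                if n - j <= N - K
            ) / math.comb(N, n)
            assert np.isclose(out.p_value[0], tail, rtol=1e-12, atol=1e-300)

    def test_pvalues_uniform_at_support_points(self):
        """Under random hit sets the attained p-values match their own
        exceedance probabilities (discreteness-tolerant uniformity)."""
        rng = np.random.default_rng(11)
        N, K, n = 500, 100, 50
        background = set(range(N))
        gene_set = set(range(K))
        pvals = np.array(
            [
                overrepresentation(
                    set(rng.choice(N, size=n, replace=False).tolist()),
                    {"s": gene_set},
                    background,
                ).p_value[0]
                for _ in range(1000)
            ]
        )
        for k in range(5, 16):
            q = float(stats.hypergeom.sf(k - 1, N, K, n))
            frac = float((pvals <= q).mean())
            tol = 3 * np.sqrt(q * (1 - q) / 1000) + 0.01
            assert abs(frac - q) < tol

    def test_errors(self):
        with pytest.raises(IntegrationError, match="background"):
            overrepresentation(set(), {"s": {1}}, set())
        with pytest.raises(IntegrationError, match="outside"):
            overrepresentation({99}, {"s": {1}}, {1, 2})


class TestViability:
    def test_formula_endpoints_and_midpoint(self):
        assert percent_viability(1.1, 0.1, 1.1) == 100.0
        assert percent_viability(0.1, 0.1, 1.1) == 0.0
        assert np.isclose(percent_viability(0.6, 0.1, 1.1), 50.0)

    def test_can_exceed_range(self):
        assert percent_viability(2.1, 0.1, 1.1) > 100
        assert percent_viability(0.0, 0.1, 1.1) < 0

    def test_invalid_controls(self):
        with pytest.raises(IntegrationError):
            percent_viability(0.5, 1.0, 0.9)
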