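import numpy as np
import pandas as pd
import pytest
from scipy import stats

from florachip.errors import InputError
from florachip.synthio import SimConfig, generate_bundle
from florachip.targets import (
    EnrichmentRow,
    ExpressionRecord,
    TermAnnotation,
    classify_direction,
    direct_target_report,
    fisher_enrichment,
    hypergeom_upper_tail,
    intersect_gene_sets,
    read_de_table,
)
from oracles import hypergeom_tail_float_oracle


class TestHypergeomTail:
    def test_worked_example_is_exact_rational(self):
        # N=20 genes, term size 5, selected 6, overlap 4:
        # (C(5,4)C(15,2) + C(5,5)C(15,1)) / C(20,6) = 540/38760
        assert hypergeom_upper_tail(4, 20, 5, 6) == 540 / 38760

    def test_k_zero_and_impossible_k(self):
        assert hypergeom_upper_tail(0, 20, 5, 6) == 1.0
        assert hypergeom_upper_tail(6, 20, 5, 6) == 0.0

    def test_matches_scipy_fisher_exact(self, rng):
        for _ in range(50):
            N = int(rng.integers(10, 60))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(0, min(K, n) + 1))
            table = [[k, K - k], [n - k, N - K - n + k]]
            if min(min(row) for row in table) < 0:
                continue
            _, p_fisher = stats.fisher_exact(table, alternative="greater")
            assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(
                p_fisher, rel=1e-9)


class TestFisherEnrichment:
    TERMS = [
        TermAnnotation("T1", "planted", frozenset({"g1", "g2", "g3", "g4", "g5"})),
        TermAnnotation("T2", "other", frozenset({"g6", "g7"})),
        TermAnnotation("T0", "unpopulated", frozenset({"absent"})),
    ]
    UNIVERSE = [f"g{i}" for i in range(1, 21)]

    def test_unpopulated_terms_excluded_from_m(self):
        rows = fisher_enrichment({"g1", "g2", "g3", "g4", "g6", "g8"},
                                 self.TERMS, self.UNIVERSE)
        assert [r.term_id for r in rows] == ["T1", "T2"]  # sorted by p
        top = rows[0]
        assert (top.k, top.K, top.n_sel, top.N) == (4, 5, 6, 20)
        assert top.p_value == 540 / 38760
        assert top.p_bonferroni == 2 * top.p_value  # m = 2 populated terms

    def test_selection_equal_to_universe_gives_p_one(self):
        rows = fisher_enrichment(set(self.UNIVERSE), self.TERMS, self.UNIVERSE)
        assert all(r.k == r.K and r.p_value == 1.0 for r in rows)

    def test_bonferroni_caps_at_one(self):
        terms = [TermAnnotation(f"T{i}", "t", frozenset({"g1"}))
                 for i in range(10)]
        rows = fisher_enrichment({"g2"}, terms, self.UNIVERSE)
        assert all(r.p_bonferroni == 1.0 for r in rows)

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(InputError, match="gX"):
            fisher_enrichment({"gX"}, self.TERMS, self.UNIVERSE)

    def test_random_configurations_match_float_tail_oracle(self, rng):
        for _ in range(300):
            N = int(rng.integers(5, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, K + n - N), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(
                hypergeom_tail_float_oracle(k, N, K, n), rel=1e-12)


class TestIntersect:
    def test_simple_overlap(self):
        de = {"loss_mutant": [ExpressionRecord(g, 1.0, "loss_mutant")
                              for g in ("g3", "g4", "g6")]}
        out = intersect_gene_sets({"g1", "g2", "g3", "g4", "g5"}, de)
        assert out["n_bound_and_loss_mutant"] == 2
        assert out["bound_and_loss_mutant"] == ["g3", "g4"]

    def test_disjoint_sets(self):
        de = {"induction": [ExpressionRecord("x", 1.0, "induction")]}
        out = intersect_gene_sets({"g1"}, de)
        assert out["n_bound_and_induction"] == 0
        assert out["n_bound_and_all"] == 0

    def test_duplicate_rows_deduplicated_with_warning(self, tmp_path):
        p = tmp_path / "de.tsv"
        p.write_text("gene_id\tlog2fc\ng1\t1.0\ng1\t-2.0\ng2\t0.5\n")
        with pytest.warns(UserWarning, match="duplicate"):
            records = read_de_table(p, "loss_mutant")
        assert [(r.gene_id, r.log2fc) for r in records] == [("g1", 1.0),
                                                            ("g2", 0.5)]

    def test_counts_bounded_and_order_invariant(self, rng):
        bound = {f"g{i}" for i in rng.integers(0, 50, size=25)}
        recs = [ExpressionRecord(f"g{i}", 1.0, "loss_mutant")
                for i in rng.integers(0, 50, size=30)]
        out_fwd = intersect_gene_sets(bound, {"loss_mutant": recs})
        out_rev = intersect_gene_sets(bound, {"loss_mutant": recs[::-1]})
        assert out_fwd == out_rev
        assert out_fwd["n_bound_and_loss_mutant"] <= min(
            len(bound), out_fwd["n_loss_mutant"])

    def test_planted_overlap_expectation(self):
        # with de_overlap_frac = 0.8 the bound∩DE count should sit within
        # binomial noise of 0.8 x (number of B-bound genes), pooled over seeds
        total, expected = 0, 0.0
        for seed in range(20):
            cfg = SimConfig(seed=seed)
            bundle = generate_bundle(cfg)
            bound = set(bundle.b_bound_genes())
            de = {
                label: [ExpressionRecord(r.gene_id, r.log2fc, label)
                        for r in df.itertuples()]
                for label, df in bundle.de_tables.items()
            }
            out = intersect_gene_sets(bound, de)
            total += out["n_bound_and_loss_mutant"]
            expected += cfg.de_overlap_frac * len(bound)
        se = np.sqrt(expected * (1 - 0.8))
        assert abs(total - expected) <= 4 * se


class TestDirection:
    def test_loss_up_induction_down_is_opposite(self):
        records = [ExpressionRecord("g", 1.25, "loss_mutant"),
                   ExpressionRecord("g", -0.541, "induction_4h"),
                   ExpressionRecord("g", -0.477, "induction_8h")]
        assert classify_direction("g", records) == "opposite"

    def test_loss_only_is_single_dataset(self):
        records = [ExpressionRecord("g", -0.59, "loss_mutant")]
        assert classify_direction("g", records) == "single_dataset"

    def test_equal_signs_are_concordant(self):
        records = [ExpressionRecord("g", 0.5, "loss_mutant"),
                   ExpressionRecord("g", 0.5, "induction_4h")]
        assert classify_direction("g", records) == "concordant"

    def test_disagreeing_induction_timepoints_are_ambiguous(self):
        records = [ExpressionRecord("g", 1.0, "loss_mutant"),
                   ExpressionRecord("g", 0.4, "induction_4h"),
                   ExpressionRecord("g", -0.4, "induction_8h")]
        assert classify_direction("g", records) == "ambiguous"

    def test_zero_log2fc_carries_no_direction(self):
        records = [ExpressionRecord("g", 0.0, "loss_mutant"),
                   ExpressionRecord("g", 0.4, "induction_4h")]
        with pytest.warns(UserWarning, match="no direction"):
            assert classify_direction("g", records) == "single_dataset"

    def test_unknown_gene_rejected(self):
        with pytest.raises(InputError):
            classify_direction("g", [ExpressionRecord("other", 1.0, "x")])


class TestDirectTargetReport:
    def test_empty_inputs_give_header_only(self):
        df = direct_target_report([], [], {})
        assert len(df) == 0 and "top_tier" in df.columns

    def test_opposite_gene_flagged_top_tier(self):
        de = {
            "loss_mutant": [ExpressionRecord("g1", 1.2, "loss_mutant"),
                            ExpressionRecord("g2", 0.9, "loss_mutant")],
            "induction": [ExpressionRecord("g1", -0.8, "induction"),
                          ExpressionRecord("g2", 0.7, "induction")],
        }
        df = direct_target_report([], ["g1", "g2"], de)
        by_gene = df.set_index("gene")
        assert bool(by_gene.loc["g1", "top_tier"]) is True
        assert by_gene.loc["g2", "direction"] == "concordant"

    def test_recovers_planted_opposite_genes(self, rng):
        # over seeds, bound genes placed in both DE tables with opposite signs
        # must come back as top-tier candidates
        recovered, planted = 0, 0
        for seed in range(10):
            bundle = generate_bundle(SimConfig(seed=100 + seed))
            bound = bundle.b_bound_genes()
            de = {
                label: [ExpressionRecord(r.gene_id, r.log2fc, label)
                        for r in df.itertuples()]
                for label, df in bundle.de_tables.items()
            }
            truth = set()
            loss = {r.gene_id: r.log2fc for r in de["loss_mutant"]}
            ind = {r.gene_id: r.log2fc for r in de["induction"]}
            for g in bound:
                if g in loss and g in ind and loss[g] * ind[g] < 0:
                    truth.add(g)
            df = direct_target_report([], bound, de)
            top = set(df.loc[df["top_tier"], "gene"]) if len(df) else set()
            planted += len(truth)
            recovered += len(truth & top)
        assert planted > 0
        assert recovered / planted >= 0.8
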