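import math

import numpy as np
import pandas as pd
import pytest

from ovodiverge import enrichment as enr
from ovodiverge import synthetic_data as synth
from conftest import toy_counts


def fisher_tail_oracle(a, b, c, d):
    """One-sided (greater) Fisher p by direct hypergeometric summation."""
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, k)
    p = 0.0
    for x in range(a, min(r1, k) + 1):
        if k - x <= r2:
            p += math.comb(r1, x) * math.comb(r2, k - x) / denom
    return p


def hypergeom_tail_oracle(k, N, K, n):
    denom = math.comb(N, n)
    return sum(math.comb(K, x) * math.comb(N - K, n - x) / denom
               for x in range(k, min(K, n) + 1))


@pytest.fixture(scope="module")
def motif_cohort():
    truth = synth.SimulationTruth(rng_seed=6)
    return synth.simulate_motif_cohort(truth, seed=6)


@pytest.fixture(scope="module")
def motif_list(motif_cohort):
    return enr.read_meme_motifs(motif_cohort.meme_text)


class TestScan:
    def test_planted_consensus_hit_at_offset(self, motif_list):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, 200))
        planted_at = 77
        seq = seq[:planted_at] + "TGACGTCA" + seq[planted_at + 8:]
        planted = next(m for m in motif_list if m.name == "PLANTED")
        offsets = enr.motif_hit_offsets(seq, planted)
        assert planted_at in offsets

    def test_sequence_shorter_than_motif_skipped(self, motif_list):
        hits = enr.scan_motifs({"tiny": "ACG"}, motif_list)
        assert not hits.loc["tiny"].any()

    def test_strand_symmetry(self, motif_cohort, motif_list):
        comp = str.maketrans("ACGT", "TGCA")
        sub = dict(list(motif_cohort.foreground.items())[:40])
        rc = {k: v.translate(comp)[::-1] for k, v in sub.items()}
        a = enr.scan_motifs(sub, motif_list)
        b = enr.scan_motifs(rc, motif_list)
        assert (a.sum() == b.sum()).all()

    def test_background_hit_rate_calibrated(self, motif_list):
        """Empirical per-window false-positive rate matches the exact
        enumeration over all 8-mers and never exceeds 3x the target.

        The discretized score distribution has large atoms for a sharply
        peaked PWM, so the calibrated threshold is conservative: the exact
        attainable rate sits at or below the requested probability.
        """
        import itertools
        from Bio.Seq import Seq

        planted = next(m for m in motif_list if m.name == "PLANTED")
        bg = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
        pssm = planted.counts.normalize(pseudocounts=0.01).log_odds(bg)
        threshold = pssm.distribution(background=bg, precision=10 ** 3
                                      ).threshold_fpr(1e-4)
        exact = np.mean([
            float(pssm.calculate(Seq("".join(w)))) > threshold
            for w in itertools.product("ACGT", repeat=8)
        ])
        assert 0 < exact <= 1e-4

        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        seqs = {f"r{i}": "".join(rng.choice(bases, 1000)) for i in range(300)}
        counts = enr.scan_motifs(seqs, [planted], per_position_p=1e-4,
                                 return_counts=True)
        windows = 300 * (1000 - 8 + 1) * 2
        rate = counts["PLANTED"].sum() / windows
        assert rate < 3e-4
        assert exact / 3 < rate < 3 * exact


class TestMotifEnrichment:
    def test_fisher_matches_direct_summation(self):
        fg = pd.DataFrame({"m": [True] * 8 + [False] * 2},
                          index=[f"f{i}" for i in range(10)])
        bg = pd.DataFrame({"m": [True] * 10 + [False] * 90},
                          index=[f"b{i}" for i in range(100)])
        (res,) = enr.motif_enrichment(fg, bg)
        assert res.p_value == pytest.approx(fisher_tail_oracle(8, 2, 10, 90),
                                            abs=1e-10)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 30, 4)
            fg = pd.DataFrame({"m": [True] * a + [False] * b},
                              index=[f"f{i}" for i in range(a + b)])
            bg = pd.DataFrame({"m": [True] * c + [False] * d},
                              index=[f"b{i}" for i in range(c + d)])
            if fg.empty:
                continue
            (res,) = enr.motif_enrichment(fg, bg)
            assert res.p_value == pytest.approx(
                fisher_tail_oracle(int(a), int(b), int(c), int(d)), abs=1e-10)

    def test_equal_rates_not_enriched(self):
        fg = pd.DataFrame({"m": [True] * 5 + [False] * 5},
                          index=[f"f{i}" for i in range(10)])
        bg = pd.DataFrame({"m": [True] * 5 + [False] * 5},
                          index=[f"b{i}" for i in range(10)])
        (res,) = enr.motif_enrichment(fg, bg)
        assert res.odds_ratio == pytest.approx(1.0)
        assert not res.enriched

    def test_overlapping_sets_rejected(self):
        df = pd.DataFrame({"m": [True]}, index=["x"])
        with pytest.raises(ValueError, match="disjoint"):
            enr.motif_enrichment(df, df)

    def test_planted_motif_ranks_first(self, motif_cohort, motif_list):
        fg = enr.scan_motifs(motif_cohort.foreground, motif_list)
        bg = enr.scan_motifs(motif_cohort.background, motif_list)
        results = enr.motif_enrichment(fg, bg)
        assert results[0].motif_id == "PLANTED" and results[0].enriched
        assert not any(r.enriched and r.p_value < results[0].p_value
                       for r in results[1:])


class TestIntersectSets:
    def test_exclusive_cells(self):
        df = enr.intersect_sets({"A": {"x", "y"}, "B": {"y", "z"}})
        cells = dict(zip(df["sets"], df["members"]))
        assert cells == {"A&B": "y", "A": "x", "B": "z"}

    def test_identical_sets_single_cell(self):
        df = enr.intersect_sets({f"S{i}": {"a", "b"} for i in range(5)})
        assert len(df) == 1 and df["count"].iloc[0] == 2

    def test_counts_sum_to_union_bitmask_oracle(self):
        rng = np.random.default_rng(3)
        universe = [f"e{i}" for i in range(1000)]
        sets = {f"S{j}": set(rng.choice(universe, 200, replace=False))
                for j in range(5)}
        df = enr.intersect_sets(sets)
        union = set().union(*sets.values())
        assert df["count"].sum() == len(union)
        # bitmask oracle
        masks = {}
        for x in union:
            key = tuple(sorted(n for n in sets if x in sets[n]))
            masks[key] = masks.get(key, 0) + 1
        got = {tuple(sorted(s.split("&"))): c
               for s, c in zip(df["sets"], df["count"])}
        assert got == masks


class TestTfFilters:
    def test_nesting_invariant_and_planted_recovery(self):
        truth = synth.SimulationTruth(rng_seed=8)
        cohort = synth.simulate_tf_filter_cohort(truth, seed=8)
        rep = enr.tf_filters(cohort.enriched, cohort.expression,
                             cohort.metadata, cohort.tf_to_gene,
                             reference="human")
        assert rep.conserved <= rep.expressed <= rep.shared
        assert rep.shared == cohort.expected_shared
        assert rep.expressed == cohort.expected_expressed
        assert rep.conserved == cohort.expected_conserved

    def test_zero_threshold_keeps_all_detected(self):
        truth = synth.SimulationTruth(rng_seed=8)
        cohort = synth.simulate_tf_filter_cohort(truth, seed=8)
        rep = enr.tf_filters(cohort.enriched, cohort.expression,
                             cohort.metadata, cohort.tf_to_gene,
                             reference="human", expression_min=0.0)
        detected = {tf for tf in rep.shared
                    if rep.mean_expression.loc[tf, "human"] > 0}
        assert rep.expressed == detected

    def test_empty_intersection_no_error(self):
        truth = synth.SimulationTruth(rng_seed=8)
        cohort = synth.simulate_tf_filter_cohort(truth, seed=8)
        enriched = dict(cohort.enriched)
        enriched["rabbit"] = {"TFZZZ"}
        rep = enr.tf_filters(enriched, cohort.expression, cohort.metadata,
                             cohort.tf_to_gene, reference="human")
        assert rep.shared == set() and rep.conserved == set()


class TestWilcoxonDe:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(5.0, (50, 20))
        counts = np.concatenate([base, base], axis=1)
        cm, _ = toy_counts(counts)
        import pandas as pd
        from ovodiverge.core_io import CellMetadata
        meta = CellMetadata(pd.DataFrame({
            "cell_id": cm.cell_ids, "species": "s1",
            "cell_type": ["A"] * 20 + ["B"] * 20, "library_id": "l",
        }))
        de = enr.wilcoxon_de(cm, meta, "A", "B")
        assert (de["q_value"] > 0.9).all()
        np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-12)

    def test_separated_groups_match_exact_enumeration(self):
        # gene 0 fully separates the groups with 20 distinct normalized
        # values (gene 1 is a constant filler fixing per-cell depth)
        counts = np.zeros((2, 20), dtype=int)
        counts[0] = [100 + i for i in range(10)] + list(range(1, 11))
        counts[1] = 1000
        cm, _ = toy_counts(counts)
        from ovodiverge.core_io import CellMetadata
        meta = CellMetadata(pd.DataFrame({
            "cell_id": cm.cell_ids, "species": "s1",
            "cell_type": ["A"] * 10 + ["B"] * 10, "library_id": "l",
        }))
        de = enr.wilcoxon_de(cm, meta, "A", "B")
        # most extreme of C(20,10) equally likely rank splits, two-sided
        p0 = float(de.loc[de["gene"] == "g0", "p_value"].iloc[0])
        assert p0 == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_absent_group_rejected(self):
        cm, meta = toy_counts(np.ones((5, 6), dtype=int))
        with pytest.raises(ValueError, match="absent or too small"):
            enr.wilcoxon_de(cm, meta, "TC", "XX")

    def test_marker_genes_lead_by_effect_size(self, expression_cohort):
        de = enr.wilcoxon_de(expression_cohort.counts["human"],
                             expression_cohort.metadata["human"], "TC", "GC")
        # TC marker block: genes 50-74 of the generator layout; many genes
        # saturate the rank-sum p, so rank the significant ones by effect
        sig = de[de["q_value"] < 0.05]
        top = set(sig.nlargest(25, "log2fc")["gene"])
        markers = {f"human_g{i:05d}" for i in range(50, 75)}
        assert len(top & markers) >= 20


class TestBenjaminiHochberg:
    def test_closed_form(self):
        from statsmodels.stats.multitest import multipletests
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])


class TestOra:
    def test_full_set_closed_form(self):
        universe = [f"g{i}" for i in range(100)]
        gene_sets = {"S": set(universe[:10])}
        df = enr.ora(universe[:10], universe, gene_sets)
        assert df["p_value"].iloc[0] == pytest.approx(
            1 / math.comb(100, 10), rel=1e-9)

    def test_disjoint_list_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        df = enr.ora(universe[40:], universe, {"S": set(universe[:10])})
        assert df["p_value"].iloc[0] == pytest.approx(1.0)

    def test_random_cases_match_direct_summation(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(60)]
        for _ in range(50):
            K, n = int(rng.integers(1, 30)), int(rng.integers(1, 30))
            members = set(rng.choice(universe, K, replace=False))
            query = set(rng.choice(universe, n, replace=False))
            df = enr.ora(query, universe, {"S": members})
            k = len(members & query)
            assert df["p_value"].iloc[0] == pytest.approx(
                hypergeom_tail_oracle(k, 60, K, n), abs=1e-10)

    def test_planted_marker_set_ranks_first(self, expression_cohort):
        de = enr.wilcoxon_de(expression_cohort.counts["human"],
                             expression_cohort.metadata["human"], "TC", "GC")
        universe = list(expression_cohort.counts["human"].feature_ids)
        sets = {
            "GC_markers": set(universe[0:25]),
            "SC_markers": set(universe[25:50]),
            "TC_markers": set(universe[50:75]),
        }
        sig = de[(de["q_value"] < 0.05) & (de["log2fc"] > 0)]
        top = list(sig.nlargest(40, "log2fc")["gene"])
        df = enr.ora(top, universe, sets)
        assert df["set"].iloc[0] == "TC_markers"

    def test_list_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            enr.ora(["x"], ["a", "b"], {"S": {"a"}})
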