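import numpy as np
import pandas as pd
import pytest

from ovodiverge import ightr as ig
from ovodiverge.core_io import (
    Chain,
    ChainBlock,
    ChainMap,
    GeneModel,
    GenomicInterval,
    PipelineConfig,
)


def reads_frame(starts, length=100, flags=None, chrom="chr1"):
    starts = list(starts)
    flags = flags if flags is not None else [0] * len(starts)
    df = pd.DataFrame({
        "chrom": chrom, "start": starts,
        "end": [s + length for s in starts],
        "flag": flags, "barcode": "bc1",
    })
    return df.sort_values("start", kind="stable").reset_index(drop=True)


def cluster_reads(start, n, span, length=100):
    return np.round(np.linspace(start, start + span - length, n)).astype(int)


class TestFilterDuplicates:
    def test_flag_bit_semantics(self):
        df = reads_frame([0, 300, 600, 900], flags=[0, 1024, 1040, 16])
        out = ig.filter_duplicates(df)
        assert out["flag"].tolist() == [0, 16]

    def test_all_duplicates_empty(self):
        df = reads_frame([0, 300], flags=[1024, 1024])
        assert ig.filter_duplicates(df).empty

    def test_generator_duplicate_count_exact(self, read_sim):
        for sp, df in read_sim.reads.items():
            out = ig.filter_duplicates(df)
            assert len(df) - len(out) == read_sim.n_duplicates[sp]


class TestCompose:
    def test_precedence_exon_over_repeat(self):
        span = GenomicInterval("chr1", 0, 2000, "+")
        gene = GeneModel("g", "g", "protein_coding", "+", 0,
                         (GenomicInterval("chr1", 0, 500, "+"),
                          GenomicInterval("chr1", 1500, 2000, "+")), span)
        repeats = [GenomicInterval("chr1", 100, 600)]
        df = reads_frame([150])  # midpoint 200: exon AND repeat -> exon
        comp = ig.compose_transcriptome(df, [gene], repeats)
        assert comp["exon"] == 1.0

    def test_unannotated_midpoint_is_intergenic(self):
        df = reads_frame([50_000])
        comp = ig.compose_transcriptome(df, [], [])
        assert comp["intergenic"] == 1.0
        assert comp.sum() == pytest.approx(1.0)

    def test_planted_proportions_recovered(self, read_sim, annotations,
                                           truth):
        for sp in ("human", "rat"):
            ann = annotations[sp]
            reads = ig.filter_duplicates(read_sim.reads[sp])
            comp = ig.compose_transcriptome(reads, ann.genes, ann.repeats)
            for cat, want in truth.read_category_props.items():
                assert comp[cat] == pytest.approx(want, abs=0.02)
            assert comp.sum() == pytest.approx(1.0, abs=1e-12)


class TestCaller:
    def test_gap_149_merges_into_one_region(self, config):
        starts = []
        pos = 1000
        for _ in range(12):
            starts.append(pos)
            pos += 100 + 149  # end-to-start gap exactly 149
        regions = ig.call_ightrs(reads_frame(starts), [], [], config)
        assert len(regions) == 1
        assert regions[0].read_count == 12
        assert (regions[0].interval.start, regions[0].interval.end) == \
            (1000, starts[-1] + 100)

    def test_gap_150_splits_and_count_rule_drops(self, config):
        # 12 reads, one internal gap of exactly 150 -> two clusters of 6
        left = cluster_reads(1000, 6, 300)
        right = cluster_reads(int(left[-1]) + 100 + 150, 6, 300)
        regions = ig.call_ightrs(reads_frame(list(left) + list(right)),
                                 [], [], config)
        assert regions == []

    def test_eleven_pass_ten_fail(self, config):
        eleven = ig.call_ightrs(reads_frame(cluster_reads(0, 11, 600)),
                                [], [], config)
        ten = ig.call_ightrs(reads_frame(cluster_reads(5000, 10, 600)),
                             [], [], config)
        assert len(eleven) == 1 and eleven[0].read_count == 11
        assert ten == []
        # the inclusive reading of the count rule admits the 10-read cluster
        inclusive = PipelineConfig(ightr_count_inclusive=True)
        assert len(ig.call_ightrs(reads_frame(cluster_reads(5000, 10, 600)),
                                  [], [], inclusive)) == 1

    def test_reads_per_kb(self, config):
        regions = ig.call_ightrs(reads_frame(cluster_reads(0, 12, 500)),
                                 [], [], config)
        assert regions[0].reads_per_kb == pytest.approx(12 / 0.5)

    def test_recall_is_idempotent(self, config):
        regions = ig.call_ightrs(reads_frame(cluster_reads(0, 15, 700)),
                                 [], [], config)
        (r,) = regions
        member = reads_frame(cluster_reads(0, 15, 700))
        again = ig.call_ightrs(member, [], [], config)
        assert len(again) == 1
        assert again[0].interval == r.interval
        assert again[0].read_count == r.read_count

    def test_unsorted_input_rejected(self, config):
        df = reads_frame([100, 50])
        df = df.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            ig.call_ightrs(df, [], [], config)

    def test_unfiltered_duplicates_rejected(self, config):
        df = reads_frame([0, 300], flags=[0, 1024])
        with pytest.raises(ValueError, match="duplicate"):
            ig.call_ightrs(df, [], [], config)

    @pytest.mark.parametrize("mode", ["end_to_start", "start_to_start"])
    def test_matches_brute_force_oracle(self, mode):
        cfg = PipelineConfig(ightr_gap_mode=mode)
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(5, 60))
            starts = np.sort(rng.integers(0, 6000, n))
            lengths = rng.integers(60, 140, n)
            df = pd.DataFrame({"chrom": "chr1", "start": starts,
                               "end": starts + lengths, "flag": 0,
                               "barcode": "b"})
            a = ig.call_ightrs(df, [], [], cfg)
            b = ig.brute_force_ightrs(df, [], [], cfg)
            assert [(r.interval, r.read_count) for r in a] == \
                [(r.interval, r.read_count) for r in b]

    def test_planted_recovered_decoys_rejected(self, read_sim, annotations,
                                               config):
        for sp in ("human", "rabbit"):
            ann = annotations[sp]
            reads = ig.filter_duplicates(read_sim.reads[sp])
            regions = ig.call_ightrs(reads, ann.genes, ann.repeats, config)
            called = {(r.interval.start, r.interval.end) for r in regions}
            planted = {(iv.start, iv.end) for iv in ann.ightrs}
            assert called == planted
            for r in regions:
                assert r.read_count > config.ightr_min_reads

    def test_zero_intergenic_reads_empty(self, config):
        span = GenomicInterval("chr1", 0, 10_000, "+")
        gene = GeneModel("g", "g", "protein_coding", "+", 0, (span,), span)
        df = reads_frame(cluster_reads(100, 20, 800))
        assert ig.call_ightrs(df, [gene], [], config) == []


class TestTssDistance:
    def _gene(self, tss):
        span = GenomicInterval("chr1", tss, tss + 1000, "+")
        return GeneModel(f"g{tss}", f"g{tss}", "protein_coding", "+", tss,
                         (span,), span)

    def _region(self, start, end):
        return ig.IgHTRRegion(GenomicInterval("chr1", start, end), 12, 1.0)

    def test_bin_assignment(self):
        genes = [self._gene(100_000)]
        regions = [self._region(104_800, 105_200),   # midpoint 5 kb away
                   self._region(99_800, 100_200)]    # midpoint at the TSS
        annotated, hist = ig.tss_distance(regions, genes)
        assert annotated[0].distance_to_tss == 5000
        assert annotated[1].distance_to_tss == 0
        assert hist["(1000, 10000]"] == 1
        assert hist["(0, 1000]"] == 1

    def test_nearest_tss_matches_all_pairs_scan(self, annotations, read_sim,
                                                config):
        ann = annotations["monkey"]
        reads = ig.filter_duplicates(read_sim.reads["monkey"])
        regions = ig.call_ightrs(reads, ann.genes, ann.repeats, config)
        annotated, _ = ig.tss_distance(regions, ann.genes)
        tss = [g.tss for g in ann.genes]
        for r in annotated:
            want = min(abs(t - r.interval.midpoint) for t in tss)
            assert r.distance_to_tss == want

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ig.tss_distance([], [self._gene(0)])
        with pytest.raises(ValueError, match="genes"):
            ig.tss_distance([self._region(0, 100)], [])


class TestAccessibilityProfile:
    def test_uniform_coverage_gives_flat_equal_tracks(self):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.integers(0, 200_000, 30_000))
        frags = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + 200, "barcode": "b"})
        regions = [GenomicInterval("chr1", 50_000 + i * 5000,
                                   50_000 + i * 5000 + 500)
                   for i in range(10)]
        space = [GenomicInterval("chr1", 120_000, 180_000)]
        prof = ig.accessibility_profile(regions, frags, space,
                                        control_seed=1)
        ratio = prof.region_track.mean() / prof.control_track.mean()
        assert 0.8 < ratio < 1.2

    def test_zero_fragments_all_zero(self):
        frags = pd.DataFrame(columns=["chrom", "start", "end", "barcode"])
        regions = [GenomicInterval("chr1", 5000, 5500)]
        space = [GenomicInterval("chr1", 20_000, 40_000)]
        prof = ig.accessibility_profile(regions, frags, space, control_seed=2)
        assert prof.region_track.sum() == 0
        assert prof.control_track.sum() == 0

    def test_planted_enrichment_recovered(self, read_sim, annotations,
                                          config, truth):
        ann = annotations["human"]
        reads = ig.filter_duplicates(read_sim.reads["human"])
        regions = ig.call_ightrs(reads, ann.genes, ann.repeats, config)
        prof = ig.accessibility_profile([r.interval for r in regions],
                                        read_sim.fragments["human"],
                                        ann.control_zones, control_seed=3)
        body = [i for i, b in enumerate(prof.bin_labels)
                if b.startswith("body")]
        ratio = prof.region_track[body].mean() / prof.control_track[body].mean()
        assert ratio >= 2.0

    def test_flank_below_bin_width_rejected(self):
        with pytest.raises(ValueError, match="flank"):
            ig.accessibility_profile([], pd.DataFrame(columns=[
                "chrom", "start", "end", "barcode"]), [], flank=50,
                flank_bin=100)


class TestIghtrConservation:
    def test_empty_chain_not_conserved(self):
        r = ig.IgHTRRegion(GenomicInterval("chr1", 0, 500), 12, 1.0)
        out = ig.classify_ightr_conservation([r], ChainMap([]), [])
        assert out[0].conservation == "NOT_CONSERVED"

    def test_bookended_is_conserved_not_ightr(self):
        cm = ChainMap([Chain(10, "chr1", 100_000, "+", 0, 50_000,
                             "chrH", 100_000, "+", 0, 50_000, 1,
                             (ChainBlock(50_000, 0, 0),))])
        r = ig.IgHTRRegion(GenomicInterval("chr1", 1000, 1500), 12, 1.0)
        ref = [ig.IgHTRRegion(GenomicInterval("chrH", 1500, 2000), 12, 1.0)]
        out = ig.classify_ightr_conservation([r], cm, ref)
        assert out[0].conservation == "CONSERVED_NOT_IGHTR"
        ref2 = [ig.IgHTRRegion(GenomicInterval("chrH", 1499, 2000), 12, 1.0)]
        assert ig.classify_ightr_conservation([r], cm, ref2)[0].conservation \
            == "CONSERVED"

    def test_planted_tri_fractions_recovered(self, read_sim, annotations,
                                             config):
        called = {}
        for sp, ann in annotations.items():
            reads = ig.filter_duplicates(read_sim.reads[sp])
            called[sp] = ig.call_ightrs(reads, ann.genes, ann.repeats, config)
        for sp in ("monkey", "mouse"):
            out = ig.classify_ightr_conservation(
                called[sp], annotations[sp].chain_to_ref, called["human"])
            got = {c: sum(1 for r in out if r.conservation == c)
                   for c in ig.IGHTR_CONSERVATION}
            want = {c: annotations[sp].ightr_classes.count(c)
                    for c in ig.IGHTR_CONSERVATION}
            assert got == want
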