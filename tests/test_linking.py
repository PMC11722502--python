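import numpy as np
import pytest

from v2g.fragments import (
    FragmentMap,
    RestrictionFragment,
    VariantBinAssignment,
    make_bins,
)
from v2g.linking import (
    CLASS_100KB_1MB,
    CLASS_GT_1MB,
    CLASS_LT_100KB,
    CLASS_OVERLAP,
    CcvPlacement,
    InteractionLoop,
    MECH_LOOP,
    MECH_PROMOTER_OVERLAP,
    classify_distance,
    flag_alternative_promoter,
    link_variants_to_genes,
    load_interactions,
    summarize_signals,
)
from v2g.promoters import PromoterRegion, TranscriptModel


def simple_fmap(n_frags=12, frag_len=1000, k=2, chrom="chr1"):
    frags = [
        RestrictionFragment(i + 1, chrom, i * frag_len, (i + 1) * frag_len)
        for i in range(n_frags)
    ]
    return FragmentMap(frags, make_bins(frags, k=k))


def placement(vid, sid, chrom, pos, fmap, adjacent=()):
    primary = fmap.bin_at(chrom, pos - 1).bin_id
    return CcvPlacement(
        vid, sid, chrom, pos, VariantBinAssignment(vid, primary, tuple(adjacent))
    )


def promoter(chrom, start, end, gene, tid="T", source="global"):
    return PromoterRegion(
        chrom, start, end, source=source, gene_ids={gene}, transcript_ids={tid}
    )


class TestLoadInteractions:
    def _write(self, path, rows):
        header = (
            "bait_chr\tbait_start\tbait_end\tbait_name\totherEnd_chr\t"
            "otherEnd_start\totherEnd_end\totherEnd_name\tN_reads\tscore\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")

    def test_score_boundary(self, tmp_path):
        fmap = simple_fmap()
        p = tmp_path / "x.ibed"
        rows = [
            ("chr1", 1, 2000, "a", "chr1", 4001, 6000, "g", 10, 5.0),
            ("chr1", 1, 2000, "b", "chr1", 4001, 6000, "g", 10, 4.99),
            ("chr1", 1, 2000, "c", "chr1", 6001, 8000, "g", 10, 7.5),
        ]
        self._write(p, rows)
        loops = load_interactions(str(p), fmap)
        assert len(loops) == 2
        assert {lp.score for lp in loops} == {5.0, 7.5}

    def test_trans_dropped(self, tmp_path):
        fmap = simple_fmap()
        p = tmp_path / "x.ibed"
        self._write(p, [("chr1", 1, 2000, "a", "chr2", 1, 2000, "g", 10, 9.0)])
        assert load_interactions(str(p), fmap) == []

    def test_bin_resolution(self, tmp_path):
        fmap = simple_fmap()
        p = tmp_path / "x.ibed"
        self._write(p, [("chr1", 2001, 4000, "a", "chr1", 8001, 10000, "g", 10, 6.0)])
        (lp,) = load_interactions(str(p), fmap)
        assert lp.bait_bin_id == 2 and lp.other_end_bin_id == 5


class TestLinkVariants:
    def test_loop_link(self):
        fmap = simple_fmap()
        ccv = placement("v", 1, "chr1", 500, fmap)
        loop = InteractionLoop("L", 1, 3, 6.0)  # bin1 [0,2000) <-> bin3 [4000,6000)
        prom = promoter("chr1", 4500, 5500, "G")
        links = link_variants_to_genes([ccv], [loop], [prom], fmap,
                                       [TranscriptModel("G", "G", "T", "chr1", "+", 5000)])
        assert len(links) == 1
        assert links[0].mechanism == MECH_LOOP
        assert links[0].gene_id == "G"

    def test_loop_links_in_both_directions(self):
        # the CCV may sit at either loop end
        fmap = simple_fmap()
        prom = promoter("chr1", 500, 1500, "G")
        tx = [TranscriptModel("G", "G", "T", "chr1", "+", 1000)]
        ccv = placement("v", 1, "chr1", 4500, fmap)  # bin 3
        for loop in (InteractionLoop("L", 3, 1, 6.0), InteractionLoop("L", 1, 3, 6.0)):
            links = link_variants_to_genes([ccv], [loop], [prom], fmap, tx)
            assert [lk.gene_id for lk in links] == ["G"]

    def test_promoter_overlap_link(self):
        fmap = simple_fmap()
        ccv = placement("v", 1, "chr1", 1200, fmap)
        prom = promoter("chr1", 1000, 1500, "G")
        links = link_variants_to_genes([ccv], [], [prom], fmap, [])
        assert len(links) == 1
        assert links[0].mechanism == MECH_PROMOTER_OVERLAP
        assert links[0].distance_class == CLASS_OVERLAP

    def test_no_loop_no_promoter_no_links(self):
        fmap = simple_fmap()
        ccv = placement("v", 1, "chr1", 500, fmap)
        assert link_variants_to_genes([ccv], [], [], fmap, []) == []

    def test_adjacent_bin_loops_used(self):
        fmap = simple_fmap()
        ccv = placement("v", 1, "chr1", 1990, fmap, adjacent=(2,))
        loop = InteractionLoop("L", 2, 5, 6.0)
        prom = promoter("chr1", 8500, 9500, "G")
        links = link_variants_to_genes([ccv], [loop], [prom], fmap,
                                       [TranscriptModel("G", "G", "T", "chr1", "+", 9000)])
        assert [lk.gene_id for lk in links] == ["G"]

    def test_brute_force_oracle(self):
        # <= 50-fragment random universes vs a triple loop over
        # (variant, loop, promoter)
        rng = np.random.default_rng(5)
        for trial in range(20):
            n = int(rng.integers(4, 50))
            frag_len = 500
            frags = [
                RestrictionFragment(i + 1, "chr1", i * frag_len, (i + 1) * frag_len)
                for i in range(n)
            ]
            k = int(rng.integers(1, 5))
            fmap = FragmentMap(frags, make_bins(frags, k=k))
            L = n * frag_len
            n_bins = len(fmap.bins)
            ccvs = [
                placement(f"v{i}", 1, "chr1", int(rng.integers(1, L + 1)), fmap)
                for i in range(3)
            ]
            loops = [
                InteractionLoop(
                    f"L{j}",
                    int(rng.integers(1, n_bins + 1)),
                    int(rng.integers(1, n_bins + 1)),
                    6.0,
                )
                for j in range(4)
            ]
            proms = []
            for g in range(3):
                s = int(rng.integers(1, L - 100))
                proms.append(promoter("chr1", s, s + int(rng.integers(50, 2000)), f"G{g}"))
            links = link_variants_to_genes(ccvs, loops, proms, fmap, [])
            got = {(lk.variant_id, lk.gene_id, lk.mechanism) for lk in links}
            expected = set()
            for ccv in ccvs:
                for lp in loops:
                    for b in ccv.assignment.bin_ids:
                        if lp.touches(b):
                            other = fmap.bin(lp.other(b))
                            for p in proms:
                                if p.start <= other.end and p.end >= other.start + 1:
                                    expected.add(
                                        (ccv.variant_id, next(iter(p.gene_ids)), MECH_LOOP)
                                    )
                for p in proms:
                    if p.start <= ccv.pos <= p.end:
                        expected.add(
                            (ccv.variant_id, next(iter(p.gene_ids)), MECH_PROMOTER_OVERLAP)
                        )
            assert got == expected, f"trial {trial}"


class TestAlternativePromoter:
    def _links(self, sep):
        fmap = simple_fmap(n_frags=60, frag_len=1000, k=2)
        # variant inside promoter A of gene G; loop to promoter B, `sep` away
        prom_a = promoter("chr1", 1000, 1500, "G", source="global")
        b_start = 1500 + sep
        prom_b = promoter("chr1", b_start, b_start + 500, "G", source="melanocyte")
        ccv = placement("v", 1, "chr1", 1200, fmap)
        target_bin = fmap.bin_at("chr1", b_start + 100).bin_id
        loop = InteractionLoop("L", ccv.assignment.primary_bin_id, target_bin, 6.0)
        links = link_variants_to_genes(
            [ccv], [loop], [prom_a, prom_b], fmap,
            [TranscriptModel("G", "G", "T", "chr1", "+", 1200)],
        )
        return flag_alternative_promoter(links)

    def test_separation_15kb_flagged(self):
        links = self._links(15_000)
        loop_links = [lk for lk in links if lk.mechanism == MECH_LOOP]
        assert any(lk.alt_promoter for lk in loop_links)

    def test_separation_8kb_not_flagged(self):
        links = self._links(8_000)
        assert not any(lk.alt_promoter for lk in links)

    def test_different_gene_never_flagged(self):
        fmap = simple_fmap(n_frags=60, frag_len=1000, k=2)
        prom_a = promoter("chr1", 1000, 1500, "G1")
        prom_b = promoter("chr1", 40_000, 40_500, "G2")
        ccv = placement("v", 1, "chr1", 1200, fmap)
        loop = InteractionLoop(
            "L", ccv.assignment.primary_bin_id, fmap.bin_at("chr1", 40_100).bin_id, 6.0
        )
        links = link_variants_to_genes([ccv], [loop], [prom_a, prom_b], fmap, [])
        links = flag_alternative_promoter(links)
        assert not any(lk.alt_promoter for lk in links)


class TestClassifyDistance:
    def test_550kb_mid_band(self):
        assert classify_distance(550_000) == CLASS_100KB_1MB

    def test_1_1mb_long_range(self):
        assert classify_distance(1_100_000) == CLASS_GT_1MB

    def test_overlap_mechanism(self):
        assert classify_distance(0, MECH_PROMOTER_OVERLAP) == CLASS_OVERLAP

    def test_boundaries(self):
        assert classify_distance(99_999) == CLASS_LT_100KB
        assert classify_distance(100_000) == CLASS_100KB_1MB
        assert classify_distance(1_000_000) == CLASS_100KB_1MB
        assert classify_distance(1_000_001) == CLASS_GT_1MB


class TestSummaries:
    def _mk_link(self, sid, gene, vid="v"):
        from v2g.linking import VariantGeneLink

        return VariantGeneLink(vid, sid, gene, MECH_LOOP)

    def test_median_five(self):
        links = []
        for sid, n in ((1, 1), (2, 5), (3, 9)):
            links += [self._mk_link(sid, f"G{sid}_{i}", f"v{sid}") for i in range(n)]
        df, medians = summarize_signals(links)
        assert medians["median_genes_per_signal"] == 5.0

    def test_zero_link_signal_listed(self):
        df, medians = summarize_signals(
            [self._mk_link(1, "G")], all_signal_ids=[1, 2]
        )
        assert set(df.signal_id) == {1, 2}
        assert int(df.loc[df.signal_id == 2, "n_genes"].iloc[0]) == 0
        assert medians["n_signals_no_nomination"] == 1

    def test_planted_counts(self, noise_free_bundle):
        # summary on the planted universe equals the ledger
        truth = noise_free_bundle.truth
        assert len(truth.true_links) == 10
        assert len({g for _, g in truth.true_links}) == 10
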