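"""Motif scanning, binned annotations, anchored profiles and enrichment."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import recombimorph as rm
from recombimorph.features import (PRDM9_MOTIF, AnchorSet, MotifHit,
                                   anchored_profile, bed_coverage_tracks,
                                   gc_cpg_tracks, motif_positions,
                                   overlap_enrichment, partition_by_motif,
                                   reverse_complement, scan_motif,
                                   select_spaced_anchors)
from recombimorph.map_core import GenomeLayout, GeneticMap, IntervalPartition

_IUPAC_SETS = {"A": "A", "C": "C", "G": "G", "T": "T", "N": "ACGT",
               "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
               "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG"}


def _brute_force_scan(seq, pattern):
    """Position-by-position IUPAC matcher on both strands (independent oracle)."""
    hits = []
    for pat, strand in ((pattern, "+"), (reverse_complement(pattern), "-")):
        for i in range(len(seq) - len(pat) + 1):
            if all(seq[i + k] in _IUPAC_SETS[c] for k, c in enumerate(pat)):
                hits.append((i, strand))
    return sorted(hits)


class TestMotifScan:
    def test_pattern_instance_at_origin(self):
        hits = scan_motif({"chr1": "CCACCATAACCAC"})
        assert MotifHit("chr1", 0, "+") in hits

    def test_all_a_sequence_empty(self):
        assert scan_motif({"chr1": "A" * 200}) == []

    def test_reverse_strand_hit(self):
        rc = reverse_complement("CCACCATAACCAC")  # concrete motif instance
        hits = scan_motif({"chr1": "TT" + rc + "AA"})
        assert MotifHit("chr1", 2, "-") in hits

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            scan_motif({"chr1": "ACGT"}, pattern="CCXCC")

    def test_matches_brute_force_on_random_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 50_000))
        # implant a few exact instances so the comparison is not vacuous
        inst = "CCACCATAACCAC"
        seq = inst + seq[len(inst):25_000] + reverse_complement(inst) + seq[25_013:]
        hits = sorted((h.start, h.strand) for h in scan_motif({"chr1": seq}))
        assert hits == _brute_force_scan(seq, PRDM9_MOTIF)
        assert len(hits) >= 2


class TestBinnedAnnotations:
    def test_full_exon_bin(self):
        genome = GenomeLayout((("chr1", 3000),))
        cov = bed_coverage_tracks(genome, [("chr1", 1000, 2000)])["chr1"].values
        assert cov.tolist() == [0.0, 1.0, 0.0]

    def test_gc_content_of_acgt_repeat(self):
        genome = GenomeLayout((("chr1", 2000),))
        gc, cpg = gc_cpg_tracks(genome, {"chr1": "ACGT" * 500})
        assert gc["chr1"].values == pytest.approx([0.5, 0.5])
        # "ACGT"*n has one CG dinucleotide per 4-mer
        assert cpg["chr1"].values == pytest.approx([0.25, 0.25])

    def test_out_of_bounds_record_rejected_with_count(self):
        genome = GenomeLayout((("chr1", 1000),))
        with pytest.warns(UserWarning, match="rejected 1"):
            cov = bed_coverage_tracks(genome, [("chr1", 0, 100), ("chr1", 900, 2000)])
        assert cov["chr1"].values[0] == pytest.approx(0.1)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 9_000), st.integers(1, 3_000)),
                    max_size=20))
    def test_coverage_matches_base_by_base(self, raw):
        genome = GenomeLayout((("chr1", 10_000),))
        records = [("chr1", s, min(s + w, 10_000)) for s, w in raw]
        cov = bed_coverage_tracks(genome, records, bin_size=1000)["chr1"].values
        base = np.zeros(10_000, dtype=bool)
        for _, s, e in records:
            base[s:e] = True
        brute = base.reshape(10, 1000).mean(axis=1)
        assert cov == pytest.approx(brute)


def _uniform_map(rate=2.0, length=200_000):
    part = IntervalPartition({"chr1": [0, length]})
    return GeneticMap(part, [rate])


class TestAnchoredProfile:
    def test_uniform_map_flat_profile(self):
        anchors = AnchorSet([("chr1", p) for p in range(60_000, 140_000, 10_000)])
        prof = anchored_profile(_uniform_map(), anchors, half_width=5000)
        assert prof.mean == pytest.approx(2.0)
        assert prof.n.min() == len(anchors)

    def test_single_anchor_equals_local_slice(self):
        part = IntervalPartition({"chr1": [0, 50_000, 51_000, 200_000]})
        gmap = GeneticMap(part, [1.0, 30.0, 1.0])
        prof = anchored_profile(gmap, AnchorSet([("chr1", 50_500)]), half_width=3000)
        # offset bin [0, 1000) covers [50500, 51500): half hot, half background
        centre = prof.mean[prof.offsets == 0][0]
        assert centre == pytest.approx(0.5 * 30.0 + 0.5 * 1.0)

    def test_peak_at_implanted_hotspot_centres(self, cohort, genome):
        truth = cohort.truth
        centres = [(h.chrom, h.centre) for h in truth.hotspots if h.intensity_f > 0]
        prof = anchored_profile(cohort.refined["F"].to_map(), AnchorSet(centres),
                                half_width=20_000)
        # hotspots are ~1 kb wide, so the peak sits in the bins nearest offset 0
        near = np.abs(prof.offsets + 500) <= 1000
        assert prof.mean[near].max() == prof.mean.max()
        assert prof.mean.max() > 3 * np.median(prof.mean)

    def test_translation_equivariance(self):
        part_a = IntervalPartition({"chr1": [0, 50_000, 51_000, 200_000]})
        part_b = IntervalPartition({"chr1": [7000, 57_000, 58_000, 207_000]})
        a = GeneticMap(part_a, [1.0, 9.0, 1.0])
        b = GeneticMap(part_b, [1.0, 9.0, 1.0])
        pa = anchored_profile(a, AnchorSet([("chr1", 50_500)]), half_width=4000)
        pb = anchored_profile(b, AnchorSet([("chr1", 57_500)]), half_width=4000)
        assert pa.mean == pytest.approx(pb.mean)

    def test_strand_flip(self):
        part = IntervalPartition({"chr1": [0, 50_000, 51_000, 200_000]})
        gmap = GeneticMap(part, [1.0, 9.0, 1.0])
        fwd = anchored_profile(gmap, AnchorSet([("chr1", 49_000, "+")]), half_width=4000)
        rev = anchored_profile(gmap, AnchorSet([("chr1", 49_000, "-")]), half_width=4000)
        assert fwd.mean == pytest.approx(rev.mean[::-1])

    def test_sex_dimorphic_profile_pattern(self, cohort):
        """Female-specific anchors show a female peak and a flat male profile."""
        centres = [(h.chrom, h.centre) for h in cohort.truth.hotspots if h.kind == "F"]
        f = anchored_profile(cohort.refined["F"].to_map(), AnchorSet(centres), 20_000)
        m = anchored_profile(cohort.refined["M"].to_map(), AnchorSet(centres), 20_000)
        near = np.abs(f.offsets + 500) <= 1000
        assert f.mean[near].max() > 5 * np.median(f.mean)
        assert m.mean[near].max() < 3.0  # no male elevation at these anchors


class TestSpacedAnchors:
    def test_already_spaced_all_kept(self):
        anchors = AnchorSet([("chr1", p) for p in (0, 10_000, 20_000)])
        out = select_spaced_anchors(anchors, 5000, seed=0)
        assert len(out) == 3

    def test_close_pair_keeps_exactly_one(self):
        anchors = AnchorSet([("chr1", 1000), ("chr1", 2000)])
        out = select_spaced_anchors(anchors, 5000, seed=0)
        assert len(out) == 1

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.integers(0, 100_000), min_size=1, max_size=60),
           st.integers(0, 5))
    def test_output_always_satisfies_spacing(self, positions, seed):
        out = select_spaced_anchors(AnchorSet([("chr1", p) for p in positions]),
                                    5000, seed=seed)
        pos = sorted(p for _, p, _ in out.anchors)
        assert all(b - a >= 5000 for a, b in zip(pos, pos[1:]))


class TestPartitionByMotif:
    def test_within_boundary_inclusive(self):
        hits = {"chr1": np.array([15_000])}
        anchors = AnchorSet([("chr1", 10_001), ("chr1", 9_999), ("chr1", 20_000)])
        with_m, without = partition_by_motif(anchors, hits, within=5000)
        assert [p for _, p, _ in with_m.anchors] == [10_001, 20_000]
        assert [p for _, p, _ in without.anchors] == [9_999]

    def test_partition_exhaustive_and_disjoint(self, rng):
        anchors = AnchorSet([("chr1", int(p)) for p in rng.choice(10**6, 50)])
        hits = {"chr1": np.sort(rng.choice(10**6, 20))}
        with_m, without = partition_by_motif(anchors, hits)
        assert len(with_m) + len(without) == len(anchors)
        assert not (set((c, p) for c, p, _ in with_m.anchors)
                    & set((c, p) for c, p, _ in without.anchors))


class TestOverlapEnrichment:
    GENOME = GenomeLayout((("chr1", 1_000_000),))

    def test_anchors_on_peaks_fully_observed(self):
        peaks = [("chr1", p, p + 200) for p in range(10_000, 500_000, 20_000)]
        anchors = AnchorSet([("chr1", p + 100) for p, *_ in
                             [(s,) for _, s, _ in peaks]])
        res = overlap_enrichment(anchors, peaks, self.GENOME, n_rand=50, seed=0)
        assert res.observed == 1.0

    def test_expected_matches_analytic_coverage(self, rng):
        # peaks + 1 kb margin cover a known fraction; random anchors match it
        peaks = [("chr1", s, s + 2000) for s in range(10_000, 990_000, 10_000)]
        anchors = AnchorSet([("chr1", int(p)) for p in rng.integers(0, 10**6, 400)])
        res = overlap_enrichment(anchors, peaks, self.GENOME, within=1000,
                                 n_rand=200, seed=1)
        covered = 98 * 4001  # 98 peaks, each effective span 2000 + 2*1000 + 1
        assert res.expected == pytest.approx(covered / 1e6, abs=0.02)
        assert res.ci_lo <= res.expected <= res.ci_hi

    def test_constructed_depletion_detected(self):
        peaks = [("chr1", s, s + 1000) for s in range(0, 500_000, 5000)]
        anchors = AnchorSet([("chr1", p) for p in range(502_500, 998_000, 5000)])
        res = overlap_enrichment(anchors, peaks, self.GENOME, within=1000,
                                 n_rand=200, seed=2)
        assert res.observed == 0.0
        assert res.observed < res.ci_lo

    def test_mask_too_small_rejected(self):
        genome = GenomeLayout((("chr1", 100),))
        anchors = AnchorSet([("chr1", p) for p in range(90)])
        with pytest.raises(ValueError, match="too small"):
            overlap_enrichment(anchors, [("chr1", 0, 10)], genome,
                               mask=[("chr1", 0, 60)], n_rand=5, seed=0)


class TestMotifPositions:
    def test_both_strand_hit_counted_once(self):
        hits = [MotifHit("chr1", 100, "+"), MotifHit("chr1", 100, "-"),
                MotifHit("chr1", 300, "+")]
        pos = motif_positions(hits, pattern_length=13)
        assert pos["chr1"].tolist() == [106, 306]
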