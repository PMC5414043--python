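"""Interval partitions, ML maps, binning, correlation and summary statistics."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import recombimorph as rm
from recombimorph.map_core import (BinnedTrack, CrossoverEvent, EventSet,
                                   GenomeLayout, GeneticMap, IntervalPartition)


def _events(spans, sex="F", chrom="chr1", n_meioses=100):
    evs = [CrossoverEvent(f"m{i}", sex, chrom, s, e) for i, (s, e) in enumerate(spans)]
    return EventSet(evs, {sex: n_meioses})


GENOME = GenomeLayout((("chr1", 1_000_000),))


class TestPartition:
    def test_union_of_endpoints(self):
        part = rm.build_partition(_events([(100, 500), (300, 900)]), GENOME)
        assert part.boundaries["chr1"].tolist() == [100, 300, 500, 900]
        assert part.lengths.tolist() == [200, 200, 400]

    def test_single_span_identity(self):
        part = rm.build_partition(_events([(0, 10)]), GENOME)
        assert part.boundaries["chr1"].tolist() == [0, 10]

    def test_rejects_unknown_chromosome_and_empty_span(self):
        with pytest.raises(ValueError, match="chrMissing"):
            rm.build_partition(_events([(0, 10)], chrom="chrMissing"), GENOME)
        with pytest.raises(ValueError):
            CrossoverEvent("m", "F", "chr1", 5, 5)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 9_999), st.integers(1, 2_000)),
                    min_size=1, max_size=60))
    def test_every_span_is_union_of_candidate_intervals(self, raw):
        spans = [(s, s + w) for s, w in raw]
        events = _events(spans)
        part = rm.build_partition(events, GENOME)
        for s, e in spans:
            lo, hi = part.interval_range("chr1", s, e)
            b = part.boundaries["chr1"]
            off = part._offset["chr1"]
            covered = list(zip(b[lo - off:hi - off], b[lo - off + 1:hi - off + 1]))
            assert covered[0][0] == s and covered[-1][1] == e
            assert all(x[1] == y[0] for x, y in zip(covered, covered[1:]))


class TestMLMap:
    def test_single_interval_event(self):
        events = _events([(0, 10_000)])
        part = rm.build_partition(events, GENOME)
        gmap = rm.ml_rate_map(events, part, "F")
        # 1 event / 100 meioses = 1 cM of genetic length over 0.01 Mb
        assert gmap.rates[0] == pytest.approx(100.0)
        assert gmap.total_cm == pytest.approx(1.0)

    def test_length_proportional_apportionment_gives_uniform_rate(self):
        events = _events([(0, 1000), (0, 4000), (1000, 4000)])
        part = rm.build_partition(events, GENOME)
        gmap = rm.ml_rate_map(EventSet([CrossoverEvent("m", "F", "chr1", 0, 4000)],
                                       {"F": 100}), part, "F")
        # one event over 1 kb + 3 kb intervals: rate uniform at 250 cM/Mb
        assert gmap.rates == pytest.approx([250.0, 250.0])

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 9_999), st.integers(1, 3_000)),
                    min_size=1, max_size=50),
           st.integers(1, 500))
    def test_mass_conservation(self, raw, m):
        spans = [(s, s + w) for s, w in raw]
        events = _events(spans, n_meioses=m)
        part = rm.build_partition(events, GENOME)
        gmap = rm.ml_rate_map(events, part, "F")
        assert gmap.total_cm == pytest.approx(100.0 * len(spans) / m, rel=1e-9)

    def test_zero_meioses_rejected(self):
        events = _events([(0, 10)])
        part = rm.build_partition(events, GENOME)
        with pytest.raises(ValueError):
            rm.ml_rate_map(events, part, "M")


class TestSexAveraged:
    def test_average_and_identity(self):
        part = IntervalPartition({"chr1": [0, 1000, 2000]})
        f = GeneticMap(part, [2.0, 4.0], sex="F")
        m = GeneticMap(part, [1.0, 4.0], sex="M")
        avg = rm.sex_averaged_map(f, m)
        assert avg.rates.tolist() == [1.5, 4.0]
        assert avg.sex == "avg"
        assert rm.sex_averaged_map(f, f).rates.tolist() == f.rates.tolist()

    def test_averaging_commutes_with_genetic_length(self, rng):
        part = IntervalPartition({"chr1": np.sort(rng.choice(10**6, 40, replace=False))})
        f = GeneticMap(part, rng.gamma(1, 2, part.n_intervals))
        m = GeneticMap(part, rng.gamma(1, 2, part.n_intervals))
        avg = rm.sex_averaged_map(f, m)
        assert avg.total_cm == pytest.approx((f.total_cm + m.total_cm) / 2, rel=1e-12)

    def test_partition_mismatch_rejected(self):
        f = GeneticMap(IntervalPartition({"chr1": [0, 1000]}), [1.0])
        m = GeneticMap(IntervalPartition({"chr1": [0, 2000]}), [1.0])
        with pytest.raises(ValueError):
            rm.sex_averaged_map(f, m)


class TestBinning:
    def test_uniform_interval_fills_bins(self):
        part = IntervalPartition({"chr1": [0, 2000]})
        gmap = GeneticMap(part, [3.0])
        tracks = rm.interpolate_bins(gmap, GenomeLayout((("chr1", 2000),)))
        assert tracks["chr1"].values.tolist() == [3.0, 3.0]

    def test_long_interval_masked(self):
        part = IntervalPartition({"chr1": [0, 60_000, 61_000]})
        gmap = GeneticMap(part, [1.0, 2.0])
        tracks = rm.interpolate_bins(gmap, GenomeLayout((("chr1", 61_000),)))
        assert np.isnan(tracks["chr1"].values[:60]).all()  # >50 kb rule
        assert tracks["chr1"].values[60] == pytest.approx(2.0)

    def test_weighted_mean_across_boundary(self):
        part = IntervalPartition({"chr1": [0, 400, 1000]})
        gmap = GeneticMap(part, [2.0, 6.0])
        tracks = rm.interpolate_bins(gmap, GenomeLayout((("chr1", 1000),)))
        assert tracks["chr1"].values[0] == pytest.approx(0.4 * 2 + 0.6 * 6)

    def test_gap_and_centromere_masked(self):
        part = IntervalPartition({"chr1": [0, 10_000]})
        gmap = GeneticMap(part, [1.0])
        genome = GenomeLayout((("chr1", 10_000),), gaps=(("chr1", 2000, 3000),),
                              centromeres=(("chr1", 5000, 5500),))
        v = rm.interpolate_bins(gmap, genome)["chr1"].values
        assert np.isnan(v[2]) and np.isnan(v[5])
        assert np.isfinite(v[[0, 1, 3, 4, 6, 7, 8, 9]]).all()

    def test_binning_conserves_genetic_length(self, rng):
        b = np.sort(rng.choice(np.arange(0, 100_001, 50), 30, replace=False))
        part = IntervalPartition({"chr1": b})
        gmap = GeneticMap(part, rng.gamma(1, 2, part.n_intervals))
        tracks = rm.interpolate_bins(gmap, GenomeLayout((("chr1", 100_000),)),
                                     bin_size=50, max_interval=10**9)
        v = tracks["chr1"].values
        mapped = slice(int(b[0] // 50), int(b[-1] // 50))
        assert np.nansum(v[mapped]) * 50 * 1e-6 == pytest.approx(gmap.total_cm, rel=1e-6)


class TestMapCorrelation:
    def _random_map(self, rng, n=400):
        b = np.arange(n + 1) * 1000
        part = IntervalPartition({"chr1": b})
        return GeneticMap(part, rng.gamma(1.0, 2.0, n))

    def test_self_correlation_is_one(self, rng):
        gmap = self._random_map(rng)
        for scale in (2000, 10_000, 50_000):
            assert rm.map_correlation(gmap, gmap, scale) == pytest.approx(1.0)

    def test_permutation_null(self, rng):
        gmap = self._random_map(rng, n=4000)
        perm = GeneticMap(gmap.partition, rng.permutation(gmap.rates))
        r2 = rm.map_correlation(gmap, perm, 1000)
        assert r2 < (3 / np.sqrt(4000)) ** 2 * 9  # r ~ N(0, 1/sqrt(n))

    def test_noise_degrades_correlation(self, rng):
        gmap = self._random_map(rng, n=2000)
        r2 = []
        for sd in (0.5, 2.0, 8.0):
            noisy = GeneticMap(gmap.partition,
                               np.abs(gmap.rates + rng.normal(0, sd, 2000)))
            r2.append(rm.map_correlation(gmap, noisy, 1000))
        assert r2[0] > r2[1] > r2[2]

    def test_insufficient_windows(self):
        part = IntervalPartition({"chr1": [0, 1000]})
        gmap = GeneticMap(part, [1.0])
        with pytest.raises(ValueError, match="insufficient"):
            rm.map_correlation(gmap, gmap, 1000)


class TestConcentration:
    def test_known_fraction(self):
        part = IntervalPartition({"chr1": [0, 1000, 2000, 3000]})
        gmap = GeneticMap(part, [80.0, 10.0, 10.0])  # genetic lengths 8:1:1
        assert rm.sequence_fraction_for(gmap, 0.8) == pytest.approx(1 / 3)

    def test_uniform_map_is_diagonal(self):
        part = IntervalPartition({"chr1": np.arange(0, 11_000, 1000)})
        gmap = GeneticMap(part, np.full(10, 2.0))
        phys, gen = rm.concentration_curve(gmap)
        assert phys == pytest.approx(gen)
        assert rm.sequence_fraction_for(gmap, 0.8) == pytest.approx(0.8)

    def test_curve_properties(self, rng):
        part = IntervalPartition({"chr1": np.sort(rng.choice(10**6, 100, replace=False))})
        gmap = GeneticMap(part, rng.gamma(0.5, 3.0, part.n_intervals))
        phys, gen = rm.concentration_curve(gmap)
        assert phys[0] == gen[0] == 0 and phys[-1] == pytest.approx(1) and gen[-1] == pytest.approx(1)
        assert np.all(np.diff(gen) >= -1e-12)
        # concavity: slopes (rates) are nonincreasing
        slopes = np.diff(gen) / np.diff(phys)
        assert np.all(np.diff(slopes) <= 1e-9)

    def test_sharpening_hotspot_concentrates(self):
        part = IntervalPartition({"chr1": np.arange(0, 11_000, 1000)})
        mild = GeneticMap(part, [5.0] + [1.0] * 9)
        sharp = GeneticMap(part, [50.0] + [1.0] * 9)
        assert (rm.sequence_fraction_for(sharp, 0.8)
                <= rm.sequence_fraction_for(mild, 0.8))

    def test_zero_map_rejected(self):
        part = IntervalPartition({"chr1": [0, 1000]})
        with pytest.raises(ValueError):
            rm.concentration_curve(GeneticMap(part, [0.0]))


class TestResolutionStats:
    def test_median_and_fraction(self):
        events = _events([(0, 10_000), (0, 30_000), (0, 50_000)])
        med, frac = rm.event_resolution_stats(events)
        assert med == 30_000 and frac == pytest.approx(1 / 3)

    def test_all_small(self):
        events = _events([(0, 5000)] * 4)
        med, frac = rm.event_resolution_stats(events)
        assert med == 5000 and frac == 1.0

    def test_refined_never_coarser_than_spans(self, cohort):
        spans = np.array([e.span_length for e in cohort.data.events.of_sex("F")])
        assert np.all(cohort.refined["F"].expected_resolution <= spans + 1e-9)


class TestIO:
    def test_event_tsv_roundtrip(self, tmp_path):
        events = _events([(0, 500), (100, 900)])
        rm.write_events_tsv(events, tmp_path / "ev.tsv")
        back = rm.read_events_tsv(tmp_path / "ev.tsv", n_meioses={"F": 100})
        assert [(e.chrom, e.start, e.end, e.sex) for e in back.events] == \
               [(e.chrom, e.start, e.end, e.sex) for e in events.events]

    def test_map_tsv_roundtrip_with_ci(self, tmp_path):
        part = IntervalPartition({"chr1": [0, 1000, 3000]})
        gmap = GeneticMap(part, [1.0, 2.0], sex="F",
                          ci={0.99: ([0.5, 1.0], [2.0, 4.0])})
        rm.write_map_tsv(gmap, tmp_path / "map.tsv", level=0.99)
        back = rm.read_map_tsv(tmp_path / "map.tsv", ci_level=0.99)
        assert back.rates == pytest.approx(gmap.rates)
        assert back.ci[0.99][1] == pytest.approx([2.0, 4.0])
        assert back.partition.same_as(part)
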