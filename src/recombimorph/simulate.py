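"""Synthetic meiosis simulator: sex-specific hotspot-structured truth maps,
Poisson crossovers per meiosis, and event observation as flanking
informative-SNP intervals.

The generator emulates the structure of pedigree crossover data: most
hotspots are shared between the sexes with correlated (but not identical)
magnitudes, a minority are specific to one sex; the female genome-wide total
exceeds the male total by a configurable factor (default 1.6); both sexes
share a smooth broad-scale background trend, with male background
additionally elevated towards the telomeres.  Crossovers per meiosis per
chromosome are Poisson (no interference), placed by inverse-CDF of the
cumulative genetic map, and observed only up to the nearest informative SNP
on each side.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .map_core import (FEMALE, MALE, BinnedTrack, CrossoverEvent, EventSet,
                       GeneticMap, GenomeLayout, IntervalPartition)


@dataclass
class HotspotSpec:
    """Hotspot architecture of the synthetic truth maps.

    Intensities are the genetic length (cM) each hotspot contributes in the
    female map; male intensities use the same gamma marginal scaled by
    1/female_male_ratio so that shared hotspots are commensurate between
    the sexes.
    """

    density_per_mb: float = 0.75
    width_mean_bp: float = 1200.0
    intensity_shape: float = 6.0
    intensity_scale_cm: float = 0.15
    shared_fraction: float = 0.4
    sex_specific_fraction: float = 0.25   # per sex
    magnitude_correlation: float = 0.8    # Gaussian-copula rho for shared hotspots

    def __post_init__(self):
        for frac in (self.shared_fraction, self.sex_specific_fraction,
                     self.magnitude_correlation):
            if not 0 <= frac <= 1:
                raise ValueError("fractions/correlation must lie in [0, 1]")
        if self.shared_fraction + 2 * self.sex_specific_fraction > 1 + 1e-9:
            raise ValueError("shared + 2*sex-specific fractions exceed 1")
        if self.density_per_mb <= 0 or self.width_mean_bp <= 0:
            raise ValueError("density and width must be positive")


@dataclass
class Hotspot:
    chrom: str
    centre: int
    width: int
    kind: str          # 'shared', 'F', or 'M'
    intensity_f: float  # cM
    intensity_m: float


@dataclass
class TruthMap:
    """Per-sex piecewise-constant true rate functions (cM/Mb), stored as
    breakpoints, plus the implanted hotspot list."""

    breakpoints: dict   # sex -> {chrom: np.ndarray of bp, 0..L}
    rates: dict         # sex -> {chrom: np.ndarray, len(breakpoints)-1}
    hotspots: list = field(default_factory=list)

    def total_cm(self, sex: str) -> float:
        return sum(float(np.sum(r * np.diff(b) * 1e-6))
                   for b, r in zip(self.breakpoints[sex].values(), self.rates[sex].values()))

    def cumulative(self, sex: str, chrom: str) -> tuple:
        b = self.breakpoints[sex][chrom]
        g = self.rates[sex][chrom] * np.diff(b) * 1e-6
        return b, np.concatenate([[0.0], np.cumsum(g)])

    def binned(self, sex: str, genome: GenomeLayout, bin_size: int = 1000) -> dict:
        tracks = {}
        for chrom, clen in genome.chromosomes:
            n = -(-clen // bin_size)
            edges = np.minimum(np.arange(n + 1, dtype=np.int64) * bin_size, clen)
            b, cum = self.cumulative(sex, chrom)
            G = np.interp(edges, b, cum)
            tracks[chrom] = BinnedTrack(chrom, bin_size,
                                        (G[1:] - G[:-1]) / ((edges[1:] - edges[:-1]) * 1e-6))
        return tracks

    def project(self, sex: str, partition: IntervalPartition) -> GeneticMap:
        """Length-weighted mean true rate per partition interval."""
        rates = np.empty(partition.n_intervals)
        for chrom in partition.chroms:
            b, cum = self.cumulative(sex, chrom)
            bounds = partition.boundaries[chrom]
            G = np.interp(bounds, b, cum)
            sl = partition.chrom_slice(chrom)
            rates[sl] = np.diff(G) / (np.diff(bounds) * 1e-6)
        return GeneticMap(partition, rates, sex=sex)

    def sex_specific_centres(self, sex: str) -> list:
        return [(h.chrom, h.centre) for h in self.hotspots if h.kind == sex]


@dataclass
class SimConfig:
    """Study-design parameters of one simulated cohort."""

    genome: GenomeLayout
    n_female: int = 2000
    n_male: int = 2000
    snp_density_per_kb: float = 1.0
    p_informative: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_female < 1 or self.n_male < 1:
            raise ValueError("need at least one meiosis per sex")
        if not (self.snp_density_per_kb > 0 and 0 < self.p_informative <= 1):
            raise ValueError("SNP density must be positive and p_informative in (0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class SimulatedDataset:
    truth: TruthMap
    events: EventSet
    snps: dict          # chrom -> sorted SNP positions
    config: SimConfig
    n_dropped: int = 0  # crossovers without a flanking informative SNP


def default_genome(total_mb: int = 20, n_chroms: int = 2) -> GenomeLayout:
    """The documented default simulation genome: 20 Mb over two chromosomes."""
    size = total_mb * 1_000_000 // n_chroms
    return GenomeLayout(tuple((f"chr{i + 1}", size) for i in range(n_chroms)))


# ---------------------------------------------------------------------------
# Truth-map construction
# ---------------------------------------------------------------------------

def make_truth_maps(spec: HotspotSpec, genome: GenomeLayout, seed: int,
                    female_male_ratio: float = 1.6,
                    female_background_cm_per_mb: float = 0.1,
                    male_background_cm_per_mb: float = 0.05,
                    trend_amplitude: float = 0.5, trend_components: int = 3,
                    telomere_amplitude: float = 3.0,
                    telomere_tau_bp: float = 2e6,
                    background_grid_bp: int = 50_000) -> TruthMap:
    """Build correlated female/male piecewise-constant truth maps.

    Hotspot centres are Poisson-placed; shared hotspots get gamma intensities
    coupled through a Gaussian copula (rho = magnitude_correlation).
    Backgrounds share a smooth random trend; the male background is a near-zero
    level (male recombination is mostly hotspot-concentrated) further
    multiplied by a distance-to-telomere elevation factor.  A global scale on
    male hotspot intensities is solved so that the genome-wide female/male
    total equals ``female_male_ratio`` exactly.
    """
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    total_mb = sum(lengths.values()) * 1e-6

    hotspots: list = []
    for chrom, clen in genome.chromosomes:
        n_hot = rng.poisson(spec.density_per_mb * clen * 1e-6)
        centres = np.sort(rng.integers(0, clen, size=n_hot))
        widths = np.maximum(rng.gamma(4.0, spec.width_mean_bp / 4.0, size=n_hot), 200.0)
        u = rng.random(n_hot)
        kinds = np.where(u < spec.shared_fraction, "shared",
                         np.where(u < spec.shared_fraction + spec.sex_specific_fraction, FEMALE,
                                  np.where(u < spec.shared_fraction + 2 * spec.sex_specific_fraction,
                                           MALE, "none")))
        rho = spec.magnitude_correlation
        for c, w, kind in zip(centres, widths, kinds):
            if kind == "none":
                continue
            z1, z2 = rng.standard_normal(2)
            gf = stats.gamma.ppf(stats.norm.cdf(z1), spec.intensity_shape,
                                 scale=spec.intensity_scale_cm)
            zc = rho * z1 + np.sqrt(max(1.0 - rho * rho, 0.0)) * z2
            gm = stats.gamma.ppf(stats.norm.cdf(zc), spec.intensity_shape,
                                 scale=spec.intensity_scale_cm)
            if kind == FEMALE:
                i_f, i_m = gf, 0.0
            elif kind == MALE:
                i_f, i_m = 0.0, gm
            else:
                i_f, i_m = gf, gm
            hotspots.append(Hotspot(chrom, int(c), int(round(w)), kind,
                                    float(i_f), float(i_m)))

    hot_f_cm = sum(h.intensity_f for h in hotspots)
    hot_m_raw = sum(h.intensity_m for h in hotspots)
    female_total = female_background_cm_per_mb * total_mb + hot_f_cm
    bg_m_total = male_background_cm_per_mb * total_mb
    male_scale = (female_total / female_male_ratio - bg_m_total) / hot_m_raw \
        if hot_m_raw > 0 else 0.0
    if hot_m_raw > 0 and male_scale <= 0:
        raise ValueError("male background exceeds the target male total; "
                         "reduce male_background_cm_per_mb or the ratio")
    for h in hotspots:
        h.intensity_m *= male_scale

    # background profiles on a coarse grid, shared trend + male telomere factor
    trend_phase = rng.random(trend_components) * 2 * np.pi
    trend_freq = rng.integers(1, 4, size=trend_components)

    def _trend(x, L):
        s = sum(np.cos(2 * np.pi * k * x / L + ph)
                for k, ph in zip(trend_freq, trend_phase)) / max(trend_components, 1)
        return np.maximum(1.0 + trend_amplitude * s, 0.05)

    bg_profiles = {FEMALE: {}, MALE: {}}
    for chrom, clen in genome.chromosomes:
        grid = np.arange(0, clen, background_grid_bp, dtype=np.int64)
        edges = np.concatenate([grid, [clen]])
        mids = (edges[:-1] + edges[1:]) / 2.0
        t = _trend(mids, clen)
        d_tel = np.minimum(mids, clen - mids)
        tel = 1.0 + telomere_amplitude * np.exp(-d_tel / telomere_tau_bp)
        seg_mb = np.diff(edges) * 1e-6
        bg_profiles[FEMALE][chrom] = (edges, t, seg_mb)
        bg_profiles[MALE][chrom] = (edges, t * tel, seg_mb)

    # normalize each sex's background profile to its target genome-wide total
    targets = {FEMALE: female_background_cm_per_mb * total_mb, MALE: bg_m_total}
    breakpoints = {FEMALE: {}, MALE: {}}
    rates = {FEMALE: {}, MALE: {}}
    for sex in (FEMALE, MALE):
        norm = sum(float(np.sum(prof * seg_mb))
                   for _, prof, seg_mb in bg_profiles[sex].values())
        scale = targets[sex] / norm
        for chrom, clen in genome.chromosomes:
            edges, prof, _ = bg_profiles[sex][chrom]
            bg_rate = prof * scale
            # merge background segments with hotspot bumps
            cuts = set(edges.tolist())
            for h in hotspots:
                if h.chrom == chrom:
                    cuts.add(max(h.centre - h.width // 2, 0))
                    cuts.add(min(h.centre + h.width - h.width // 2, clen))
            b = np.array(sorted(cuts), dtype=np.int64)
            mid = (b[:-1] + b[1:]) / 2.0
            r = bg_rate[np.clip(np.searchsorted(edges, mid, side="right") - 1,
                                0, bg_rate.size - 1)].astype(float)
            for h in hotspots:
                if h.chrom != chrom:
                    continue
                intensity = h.intensity_f if sex == FEMALE else h.intensity_m
                if intensity <= 0:
                    continue
                s = max(h.centre - h.width // 2, 0)
                e = min(h.centre + h.width - h.width // 2, clen)
                if e <= s:
                    continue
                r[(mid > s) & (mid < e)] += intensity / ((e - s) * 1e-6)
            breakpoints[sex][chrom] = b
            rates[sex][chrom] = r
    return TruthMap(breakpoints, rates, hotspots)


# ---------------------------------------------------------------------------
# Meiosis simulation
# ---------------------------------------------------------------------------

def simulate_meioses(truth: TruthMap, config: SimConfig) -> SimulatedDataset:
    """Poisson crossovers per meiosis, localized to flanking informative SNPs.

    SNPs are Poisson-placed once per dataset; each SNP is informative in a
    given meiosis independently with probability ``p_informative``.  Crossovers
    lacking an informative SNP on either side are dropped (counted).
    """
    rng = np.random.default_rng(config.seed)
    lengths = config.genome.lengths
    snps = {}
    for chrom, clen in config.genome.chromosomes:
        n = rng.poisson(config.snp_density_per_kb * clen / 1000.0)
        snps[chrom] = np.sort(rng.choice(clen, size=min(n, clen), replace=False)) \
            if n else np.empty(0, dtype=np.int64)

    events: list = []
    dropped = 0
    n_by_sex = {FEMALE: config.n_female, MALE: config.n_male}
    for sex in (FEMALE, MALE):
        n_meioses = n_by_sex[sex]
        for chrom, clen in config.genome.chromosomes:
            b, cum = truth.cumulative(sex, chrom)
            total_cm = cum[-1]
            if total_cm <= 0:
                warnings.warn(f"chromosome {chrom} has zero {sex} genetic length")
                continue
            counts = rng.poisson(total_cm / 100.0, size=n_meioses)
            chrom_snps = snps[chrom]
            for m in np.nonzero(counts)[0]:
                u = rng.random(counts[m]) * total_cm
                xo = np.interp(u, cum, b)
                informative = chrom_snps[rng.random(chrom_snps.size) < config.p_informative]
                for pos in xo:
                    i = int(np.searchsorted(informative, pos))
                    if i == 0 or i == informative.size:
                        dropped += 1
                        continue
                    left, right = int(informative[i - 1]), int(informative[i])
                    if left == right:
                        dropped += 1
                        continue
                    events.append(CrossoverEvent(f"{sex}{m}", sex, chrom, left, right))

    event_set = EventSet(events, {FEMALE: config.n_female, MALE: config.n_male},
                         provenance=f"simulated seed={config.seed}")
    return SimulatedDataset(truth, event_set, snps, config, n_dropped=dropped)


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    r_refined: float
    r_unrefined: float
    sensitivity: float
    precision: float
    median_resolution_bp: float
    n_bins: int


def _binned_rates(gmap: GeneticMap, genome: GenomeLayout, bin_size: int) -> np.ndarray:
    from .map_core import interpolate_bins
    tracks = interpolate_bins(gmap, genome, bin_size=bin_size, max_interval=10 ** 9)
    return np.concatenate([tracks[c].values for c, _ in genome.chromosomes])


def _truth_binned(truth: TruthMap, sex: str, genome: GenomeLayout, bin_size: int) -> np.ndarray:
    tracks = truth.binned(sex, genome, bin_size)
    return np.concatenate([tracks[c].values for c, _ in genome.chromosomes])


def _predicted_hot_runs(gmap: GeneticMap, threshold: float) -> list:
    """Maximal runs of adjacent partition intervals with rate > threshold."""
    runs = []
    for chrom in gmap.partition.chroms:
        starts, ends = gmap.partition.interval_bounds(chrom)
        hot = gmap.chrom_rates(chrom) > threshold
        k = 0
        while k < hot.size:
            if hot[k]:
                j = k
                while j + 1 < hot.size and hot[j + 1]:
                    j += 1
                runs.append((chrom, int(starts[k]), int(ends[j])))
                k = j + 1
            else:
                k += 1
    return runs


def hotspot_detection(gmap: GeneticMap, centres, threshold: float = 10.0,
                      tol_bp: int = 2000) -> tuple:
    """(sensitivity, precision): a truth hotspot is detected when the map rate
    exceeds ``threshold`` within ±``tol_bp`` of its centre; a predicted hot run
    is true when it lies within ``tol_bp`` of some truth centre."""
    detected = sum(
        1 for chrom, c in centres
        if np.isfinite(gmap.max_rate(chrom, max(c - tol_bp, 0), c + tol_bp))
        and gmap.max_rate(chrom, max(c - tol_bp, 0), c + tol_bp) > threshold
    )
    sensitivity = detected / len(centres) if centres else float("nan")
    runs = _predicted_hot_runs(gmap, threshold)
    true_runs = sum(
        1 for chrom, s, e in runs
        if any(c == chrom and s - tol_bp <= p <= e + tol_bp for c, p in centres)
    )
    precision = true_runs / len(runs) if runs else float("nan")
    return sensitivity, precision


def recovery_metrics(refined, unrefined: GeneticMap, truth: TruthMap, sex: str,
                     genome: GenomeLayout, bin_size: int = 10_000,
                     hotspot_threshold: float = 10.0, tol_bp: int = 2000) -> RecoveryReport:
    """Parameter-recovery report: Pearson r of each map against the truth at
    ``bin_size`` resolution, hotspot sensitivity/precision of the refined map
    against all implanted hotspots active in this sex, and the median
    posterior-expected event resolution."""
    refined_map = refined.to_map() if hasattr(refined, "to_map") else refined
    t = _truth_binned(truth, sex, genome, bin_size)
    r1 = _binned_rates(refined_map, genome, bin_size)
    r0 = _binned_rates(unrefined, genome, bin_size)
    ok = np.isfinite(t) & np.isfinite(r1) & np.isfinite(r0)
    rr = float(stats.pearsonr(r1[ok], t[ok])[0])
    ru = float(stats.pearsonr(r0[ok], t[ok])[0])
    active = [(h.chrom, h.centre) for h in truth.hotspots
              if (h.intensity_f if sex == FEMALE else h.intensity_m) > 0]
    sens, prec = hotspot_detection(refined_map, active, hotspot_threshold, tol_bp)
    med = float(np.median(refined.expected_resolution)) \
        if hasattr(refined, "expected_resolution") else float("nan")
    return RecoveryReport(rr, ru, sens, prec, med, int(ok.sum()))


# ---------------------------------------------------------------------------
# Standard recovery experiment (one simulated cohort, both sexes refined)
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    """One simulated cohort taken through partitioning, ML mapping and
    Gibbs refinement of both sexes."""

    truth: TruthMap
    data: SimulatedDataset
    partition: IntervalPartition
    ml: dict        # sex -> GeneticMap (unrefined)
    refined: dict   # sex -> PosteriorSummary


def run_cohort(truth_seed: int, sim_seed: int, mcmc_seed: int,
               genome: GenomeLayout | None = None,
               spec: HotspotSpec | None = None,
               n_meioses: int = 2000, **truth_kwargs) -> CohortResult:
    """Simulate one cohort under the default study conditions and refine both
    sex-specific maps with the desk MCMC schedule (10k iterations)."""
    from .map_core import build_partition, ml_rate_map
    from .refine import desk_config, gibbs_refine

    genome = genome if genome is not None else default_genome()
    spec = spec if spec is not None else HotspotSpec()
    truth = make_truth_maps(spec, genome, truth_seed, **truth_kwargs)
    data = simulate_meioses(truth, SimConfig(genome, n_female=n_meioses,
                                             n_male=n_meioses, seed=sim_seed))
    part = build_partition(data.events, genome)
    ml = {s: ml_rate_map(data.events, part, s) for s in (FEMALE, MALE)}
    refined = {
        s: gibbs_refine(data.events, part, s,
                        config=desk_config(seed=mcmc_seed + k))
        for k, s in enumerate((FEMALE, MALE))
    }
    return CohortResult(truth, data, part, ml, refined)


def recover_sex_specific_hotspots(cohort: CohortResult, tol_bp: int = 2000,
                                  level: float = 0.99) -> dict:
    """Run the dimorphic caller on a cohort and score recovery of the
    implanted sex-specific hotspots (a truth hotspot counts as recovered when
    a called hotspot of the matching sex lies within ``tol_bp`` of its
    centre; a call counts as true under the mirror-image rule)."""
    from .dimorphic import (build_regions, call_dimorphic_intervals,
                            classify_sex_specific, filter_intervals)

    f, m = cohort.refined[FEMALE], cohort.refined[MALE]
    ivs = call_dimorphic_intervals(f, m, level=level)
    regions = build_regions(filter_intervals(ivs), cohort.data.config.genome,
                            f, m, all_intervals=ivs)
    hotspots = classify_sex_specific(regions, f, m)
    n_true = n_found = n_calls = n_calls_true = 0
    for sex in (FEMALE, MALE):
        centres = cohort.truth.sex_specific_centres(sex)
        calls = [(h.region.chrom, h.region.start, h.region.end)
                 for h in hotspots if h.hot_sex == sex]
        n_true += len(centres)
        n_found += sum(1 for c, p in centres
                       if any(cc == c and s - tol_bp <= p <= e + tol_bp
                              for cc, s, e in calls))
        n_calls += len(calls)
        n_calls_true += sum(1 for cc, s, e in calls
                            if any(c == cc and s - tol_bp <= p <= e + tol_bp
                                   for c, p in centres))
    return {
        "regions": regions, "hotspots": hotspots,
        "n_true": n_true, "n_found": n_found,
        "n_calls": n_calls, "n_calls_true": n_calls_true,
        "recall": n_found / n_true if n_true else float("nan"),
        "precision": n_calls_true / n_calls if n_calls else float("nan"),
    }
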