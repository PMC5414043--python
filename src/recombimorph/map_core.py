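"""Genome layout, crossover events, interval partitions and genetic maps.

The coordinate system of every map in this package is the *inter-SNP interval
partition*: the sorted union, per chromosome, of the endpoints of all observed
crossover-event uncertainty spans.  Each event then covers a contiguous run of
intervals and a map assigns a recombination rate (cM/Mb) to every interval.

Coordinates are 0-based half-open throughout; BED conventions on disk.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FEMALE = "F"
MALE = "M"
SEX_AVERAGED = "avg"

#: chromosomes carried by one sex only (male rates are undefined / NA there)
FEMALE_ONLY_CHROMS = ("X", "chrX")


def expected_crossovers(rate_cm_per_mb, length_bp, n_meioses=1):
    """Expected crossover count in an interval: rate[cM/Mb] * L[bp] * 1e-8 per meiosis.

    This is the single place where cM/Mb rates are converted to per-meiosis
    crossover expectations (1 cM = 1% crossover probability, 1 Mb = 1e6 bp).
    """
    return np.asarray(rate_cm_per_mb, dtype=float) * np.asarray(length_bp, dtype=float) * 1e-8 * n_meioses


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes plus assembly gaps and centromere spans (0-based half-open)."""

    chromosomes: tuple  # of (name, length)
    gaps: tuple = ()  # of (chrom, start, end)
    centromeres: tuple = ()

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome layout")
        lengths = dict(self.chromosomes)
        for label, spans in (("gap", self.gaps), ("centromere", self.centromeres)):
            for chrom, start, end in spans:
                if chrom not in lengths:
                    raise ValueError(f"{label} span on unknown chromosome {chrom!r}")
                if not (0 <= start < end <= lengths[chrom]):
                    raise ValueError(f"{label} span {chrom}:{start}-{end} outside chromosome bounds")

    @property
    def lengths(self) -> dict:
        return dict(self.chromosomes)

    def masked_spans(self, chrom: str) -> list:
        """Gap plus centromere spans on one chromosome, merged where overlapping."""
        spans = sorted(
            [(s, e) for c, s, e in tuple(self.gaps) + tuple(self.centromeres) if c == chrom]
        )
        merged: list = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    @classmethod
    def from_files(cls, chrom_sizes, gaps_bed=None, centromeres_bed=None) -> "GenomeLayout":
        sizes = pd.read_csv(chrom_sizes, sep="\t", header=None, comment="#",
                            names=["chrom", "length"], usecols=[0, 1])
        chroms = tuple((str(r.chrom), int(r.length)) for r in sizes.itertuples())

        def _bed(path):
            if path is None:
                return ()
            df = pd.read_csv(path, sep="\t", header=None, comment="#",
                             usecols=[0, 1, 2], names=["chrom", "start", "end"])
            return tuple((str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples())

        return cls(chroms, _bed(gaps_bed), _bed(centromeres_bed))


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

@dataclass
class CrossoverEvent:
    """One observed recombination event localized to an uncertainty span."""

    meiosis_id: str
    sex: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"sex must be {FEMALE!r} or {MALE!r}, got {self.sex!r}")
        if not self.start < self.end:
            raise ValueError(f"zero- or negative-length event span {self.chrom}:{self.start}-{self.end}")

    @property
    def span_length(self) -> int:
        return self.end - self.start


@dataclass
class EventSet:
    """A collection of crossover events plus the number of informative meioses per sex."""

    events: list
    n_meioses: dict  # sex -> int
    provenance: str = ""

    def __post_init__(self):
        sexes = {e.sex for e in self.events}
        for s in sexes:
            if self.n_meioses.get(s, 0) < 1:
                raise ValueError(f"events present for sex {s!r} but n_meioses[{s!r}] < 1")

    def of_sex(self, sex: str) -> list:
        return [e for e in self.events if e.sex == sex]

    def __len__(self) -> int:
        return len(self.events)


def read_events_tsv(path, n_meioses: Mapping[str, int] | None = None,
                    one_based: bool = False, provenance: str = "") -> EventSet:
    """Read an event table (columns meiosis_id, sex, chrom, start, end; header required).

    If ``n_meioses`` is not given, the number of distinct meiosis ids per sex is
    used — appropriate only when every meiosis yielded at least one event.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"meiosis_id": str, "chrom": str})
    required = {"meiosis_id", "sex", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"event TSV must have columns {sorted(required)}")
    off = 1 if one_based else 0
    events = [
        CrossoverEvent(str(r.meiosis_id), str(r.sex), str(r.chrom), int(r.start) - off, int(r.end))
        for r in df.itertuples()
    ]
    if n_meioses is None:
        n_meioses = df.groupby("sex")["meiosis_id"].nunique().to_dict()
    return EventSet(events, dict(n_meioses), provenance=provenance or str(path))


def write_events_tsv(events: EventSet, path) -> None:
    df = pd.DataFrame(
        [(e.meiosis_id, e.sex, e.chrom, e.start, e.end) for e in events.events],
        columns=["meiosis_id", "sex", "chrom", "start", "end"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interval partition
# ---------------------------------------------------------------------------

class IntervalPartition:
    """Per-chromosome strictly increasing boundaries; intervals are [b_{k-1}, b_k).

    Intervals from all chromosomes are additionally exposed as one flat,
    globally indexed array (chromosome blocks are contiguous), which is the
    indexing used by rate arrays and by the Gibbs sampler.
    """

    def __init__(self, boundaries: Mapping[str, Sequence[int]]):
        self.boundaries: dict = {}
        self.chroms: list = []
        self._offset: dict = {}
        lengths = []
        off = 0
        for chrom, b in boundaries.items():
            b = np.asarray(b, dtype=np.int64)
            if b.size < 2 or np.any(np.diff(b) <= 0):
                raise ValueError(f"boundaries for {chrom} must be strictly increasing with >= 2 entries")
            self.boundaries[chrom] = b
            self.chroms.append(chrom)
            self._offset[chrom] = off
            lengths.append(np.diff(b))
            off += b.size - 1
        self.lengths: np.ndarray = np.concatenate(lengths) if lengths else np.empty(0, dtype=np.int64)
        self.n_intervals: int = int(self.lengths.size)

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offset[chrom]
        return slice(off, off + self.boundaries[chrom].size - 1)

    def interval_range(self, chrom: str, start: int, end: int) -> tuple:
        """Global (lo, hi) index range of the intervals exactly tiling [start, end)."""
        b = self.boundaries.get(chrom)
        if b is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        lo = int(np.searchsorted(b, start))
        hi = int(np.searchsorted(b, end))
        if lo >= b.size or b[lo] != start or hi >= b.size or b[hi] != end:
            raise ValueError(f"span {chrom}:{start}-{end} is not aligned to partition boundaries")
        off = self._offset[chrom]
        return off + lo, off + hi

    def overlap_range(self, chrom: str, start: int, end: int) -> tuple:
        """Global (lo, hi) index range of intervals intersecting [start, end)."""
        b = self.boundaries[chrom]
        lo = int(np.searchsorted(b, start, side="right")) - 1
        hi = int(np.searchsorted(b, end, side="left"))
        lo = max(lo, 0)
        hi = min(hi, b.size - 1)
        off = self._offset[chrom]
        return off + lo, off + max(hi, lo)

    def interval_bounds(self, chrom: str) -> tuple:
        """(starts, ends) arrays for one chromosome's intervals."""
        b = self.boundaries[chrom]
        return b[:-1], b[1:]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chroms:
            s, e = self.interval_bounds(chrom)
            rows.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
        return pd.concat(rows, ignore_index=True)

    def same_as(self, other: "IntervalPartition") -> bool:
        return self.chroms == other.chroms and all(
            np.array_equal(self.boundaries[c], other.boundaries[c]) for c in self.chroms
        )


def build_partition(events: EventSet, genome: GenomeLayout) -> IntervalPartition:
    """Boundaries per chromosome = sorted union of all event span endpoints."""
    lengths = genome.lengths
    per_chrom: dict = {}
    for ev in events.events:
        if ev.chrom not in lengths:
            raise ValueError(f"event on unknown chromosome {ev.chrom!r}")
        if not (0 <= ev.start < ev.end <= lengths[ev.chrom]):
            raise ValueError(f"event span {ev.chrom}:{ev.start}-{ev.end} outside chromosome bounds")
        per_chrom.setdefault(ev.chrom, set()).update((ev.start, ev.end))
    ordered = {c: np.array(sorted(per_chrom[c]), dtype=np.int64)
               for c in sorted(per_chrom, key=lambda c: list(lengths).index(c))}
    return IntervalPartition(ordered)


# ---------------------------------------------------------------------------
# Genetic maps
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Per-interval recombination rates (cM/Mb) on an IntervalPartition.

    ``ci`` optionally maps a credible level (e.g. 0.99) to a (lower, upper)
    pair of rate arrays.
    """

    partition: IntervalPartition
    rates: np.ndarray
    sex: str = SEX_AVERAGED
    n_meioses: int | None = None
    ci: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.size != self.partition.n_intervals:
            raise ValueError("rate array length does not match partition")
        finite = np.isfinite(self.rates)
        if np.any(self.rates[finite] < 0):
            raise ValueError("negative recombination rate")
        for level, (lo, hi) in self.ci.items():
            self.ci[level] = (np.asarray(lo, dtype=float), np.asarray(hi, dtype=float))

    @property
    def genetic_lengths(self) -> np.ndarray:
        """Genetic length of each interval in cM."""
        return self.rates * self.partition.lengths * 1e-6

    @property
    def total_cm(self) -> float:
        return float(np.nansum(self.genetic_lengths))

    def cumulative(self, chrom: str) -> tuple:
        """(boundary positions, cumulative cM at each boundary) for one chromosome."""
        sl = self.chrom_rates(chrom)
        g = np.nan_to_num(sl) * self.partition.lengths[self.partition.chrom_slice(chrom)] * 1e-6
        return self.partition.boundaries[chrom], np.concatenate([[0.0], np.cumsum(g)])

    def chrom_rates(self, chrom: str) -> np.ndarray:
        return self.rates[self.partition.chrom_slice(chrom)]

    def mean_rate(self, chrom: str, start: int, end: int) -> float:
        """Physical-length-weighted mean rate over [start, end) (overlap-weighted)."""
        lo, hi = self.partition.overlap_range(chrom, start, end)
        if hi <= lo:
            return float("nan")
        off = self.partition._offset[chrom]
        s, e = self.partition.interval_bounds(chrom)
        s, e = s[lo - off:hi - off], e[lo - off:hi - off]
        w = np.minimum(e, end) - np.maximum(s, start)
        r = self.rates[lo:hi]
        ok = (w > 0) & np.isfinite(r)
        if not np.any(ok):
            return float("nan")
        return float(np.sum(w[ok] * r[ok]) / np.sum(w[ok]))

    def max_rate(self, chrom: str, start: int, end: int) -> float:
        """Maximum interval rate among intervals intersecting [start, end)."""
        lo, hi = self.partition.overlap_range(chrom, start, end)
        r = self.rates[lo:hi]
        r = r[np.isfinite(r)]
        return float(np.max(r)) if r.size else float("nan")


def ml_rate_map(events: EventSet, partition: IntervalPartition, sex: str,
                female_only_chroms: Iterable[str] = FEMALE_ONLY_CHROMS) -> GeneticMap:
    """Unrefined maximum-likelihood map: each event's unit mass is apportioned to
    its candidate intervals proportionally to physical length (the ML solution of
    the uniform-placement model); rate_i = (mass_i / M) * 100 / (L_i * 1e-6).
    """
    M = events.n_meioses.get(sex, 0)
    if M <= 0:
        raise ValueError(f"no meioses recorded for sex {sex!r}")
    mass = np.zeros(partition.n_intervals)
    for ev in events.of_sex(sex):
        lo, hi = partition.interval_range(ev.chrom, ev.start, ev.end)
        L = partition.lengths[lo:hi].astype(float)
        mass[lo:hi] += L / L.sum()
    rates = (mass / M) * 100.0 / (partition.lengths * 1e-6)
    if sex == MALE:
        for chrom in partition.chroms:
            if chrom in tuple(female_only_chroms):
                rates[partition.chrom_slice(chrom)] = np.nan
    return GeneticMap(partition, rates, sex=sex, n_meioses=M)


def sex_averaged_map(f: GeneticMap, m: GeneticMap) -> GeneticMap:
    if not f.partition.same_as(m.partition):
        raise ValueError("female and male maps are on different partitions")
    return GeneticMap(f.partition, (f.rates + m.rates) / 2.0, sex=SEX_AVERAGED)


# ---------------------------------------------------------------------------
# Binned tracks
# ---------------------------------------------------------------------------

@dataclass
class BinnedTrack:
    """Fixed-width binned values along one chromosome; NaN marks NA bins."""

    chrom: str
    bin_size: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_bins(self) -> int:
        return self.values.size


def _mask_bins(mask: np.ndarray, start: int, end: int, bin_size: int) -> None:
    lo = int(start) // bin_size
    hi = -(-int(end) // bin_size)  # ceil
    mask[max(lo, 0):min(hi, mask.size)] = True


def interpolate_bins(gmap: GeneticMap, genome: GenomeLayout, bin_size: int = 1000,
                     max_interval: int = 50_000) -> dict:
    """Interpolate a map into fixed 1 kb (default) bins per chromosome.

    Bin value = physical-length-weighted mean rate of the overlapping intervals.
    A bin is NA when it overlaps an assembly gap, a centromere, a low-resolution
    interval (> ``max_interval`` bp), or lies partly outside the mapped region.
    """
    tracks: dict = {}
    lengths = genome.lengths
    for chrom, clen in genome.chromosomes:
        n_bins = -(-clen // bin_size)
        if chrom not in gmap.partition.boundaries:
            tracks[chrom] = BinnedTrack(chrom, bin_size, np.full(n_bins, np.nan))
            continue
        edges = np.minimum(np.arange(n_bins + 1, dtype=np.int64) * bin_size, clen)
        b, cum = gmap.cumulative(chrom)
        G = np.interp(edges, b, cum)
        widths = (edges[1:] - edges[:-1]) * 1e-6
        vals = (G[1:] - G[:-1]) / widths
        na = np.zeros(n_bins, dtype=bool)
        na |= edges[:-1] < b[0]
        na |= edges[1:] > b[-1]
        for s, e in genome.masked_spans(chrom):
            _mask_bins(na, s, e, bin_size)
        sl = gmap.partition.chrom_slice(chrom)
        rates = gmap.rates[sl]
        starts, ends = gmap.partition.interval_bounds(chrom)
        long_or_nan = (ends - starts > max_interval) | ~np.isfinite(rates)
        for s, e in zip(starts[long_or_nan], ends[long_or_nan]):
            _mask_bins(na, s, e, bin_size)
        vals[na] = np.nan
        tracks[chrom] = BinnedTrack(chrom, bin_size, vals)
    return tracks


# ---------------------------------------------------------------------------
# Map comparison and summary statistics
# ---------------------------------------------------------------------------

def _window_genetic_distances(x, scale_bp: int) -> dict:
    """Per-chromosome arrays of genetic distance (cM) in non-overlapping windows
    anchored at position 0; NaN-contaminated windows are NaN; terminal partial
    windows are dropped.
    """
    out: dict = {}
    if isinstance(x, GeneticMap):
        for chrom in x.partition.chroms:
            b, cum = x.cumulative(chrom)
            n_win = int(b[-1]) // scale_bp
            if n_win == 0:
                continue
            edges = np.arange(n_win + 1, dtype=np.int64) * scale_bp
            G = np.interp(edges, b, cum)
            w = G[1:] - G[:-1]
            w[edges[:-1] < b[0]] = np.nan
            rates = x.chrom_rates(chrom)
            if np.any(~np.isfinite(rates)):
                starts, ends = x.partition.interval_bounds(chrom)
                for s, e in zip(starts[~np.isfinite(rates)], ends[~np.isfinite(rates)]):
                    w[max(s // scale_bp, 0):min(-(-e // scale_bp), n_win)] = np.nan
            out[chrom] = w
    elif isinstance(x, Mapping):
        for chrom, track in x.items():
            if scale_bp % track.bin_size:
                raise ValueError("scale must be a multiple of the track bin size")
            bpw = scale_bp // track.bin_size
            n_win = track.n_bins // bpw
            if n_win == 0:
                continue
            v = track.values[: n_win * bpw].reshape(n_win, bpw)
            out[chrom] = v.sum(axis=1) * track.bin_size * 1e-6  # cM per window
    else:
        raise TypeError("expected a GeneticMap or a dict of BinnedTrack")
    return out


def map_correlation(a, b, scale_bp: int) -> float:
    """Squared Pearson correlation of per-window genetic distances at one scale."""
    wa, wb = _window_genetic_distances(a, scale_bp), _window_genetic_distances(b, scale_bp)
    xs, ys = [], []
    for chrom in set(wa) & set(wb):
        n = min(wa[chrom].size, wb[chrom].size)
        xs.append(wa[chrom][:n])
        ys.append(wb[chrom][:n])
    if not xs:
        raise ValueError("insufficient windows")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("insufficient windows")
    r, _ = stats.pearsonr(x[ok], y[ok])
    return float(r * r)


def concentration_curve(gmap: GeneticMap) -> tuple:
    """Cumulative genetic proportion versus cumulative physical proportion with
    intervals taken hottest-first.  Returns (physical, genetic) arrays starting
    at (0, 0) and ending at (1, 1).
    """
    g = gmap.genetic_lengths
    L = gmap.partition.lengths.astype(float)
    ok = np.isfinite(g)
    g, L = g[ok], L[ok]
    if g.sum() <= 0:
        raise ValueError("map has zero total genetic length")
    order = np.argsort(-(g / (L * 1e-6)), kind="stable")
    phys = np.concatenate([[0.0], np.cumsum(L[order]) / L.sum()])
    gen = np.concatenate([[0.0], np.cumsum(g[order]) / g.sum()])
    return phys, gen


def sequence_fraction_for(gmap: GeneticMap, q: float) -> float:
    """Smallest physical-sequence proportion capturing at least ``q`` of the
    total genetic length (e.g. q=0.8: how concentrated is recombination)."""
    phys, gen = concentration_curve(gmap)
    return float(phys[np.searchsorted(gen, q - 1e-9)])


def event_resolution_stats(x, threshold_bp: int = 10_000) -> tuple:
    """(median resolution in bp, fraction of events resolved to <= threshold).

    For an :class:`EventSet`, resolution is the raw span length; for a refined
    posterior (anything exposing ``expected_resolution``), it is the
    posterior-expected assigned-interval length.
    """
    if hasattr(x, "expected_resolution"):
        res = np.asarray(x.expected_resolution, dtype=float)
    elif isinstance(x, EventSet):
        res = np.array([e.span_length for e in x.events], dtype=float)
    else:
        res = np.asarray(x, dtype=float)
    if res.size == 0:
        raise ValueError("no events")
    return float(np.median(res)), float(np.mean(res <= threshold_bp))


# ---------------------------------------------------------------------------
# Map TSV I/O
# ---------------------------------------------------------------------------

def write_map_tsv(gmap: GeneticMap, path, level: float | None = None, header_lines=()) -> None:
    """Write chrom/start/end/rate (+ ci_lo, ci_hi for one level) as a BED-like TSV."""
    df = gmap.partition.to_frame()
    df["rate_cM_per_Mb"] = gmap.rates
    if level is None and gmap.ci:
        level = max(gmap.ci)
    if level is not None and level in gmap.ci:
        lo, hi = gmap.ci[level]
        df["ci_lo"], df["ci_hi"] = lo, hi
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"# sex={gmap.sex} n_meioses={gmap.n_meioses}"
                 + (f" ci_level={level}" if level is not None and level in gmap.ci else "") + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_map_tsv(path, sex: str = SEX_AVERAGED, ci_level: float | None = None) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    boundaries: dict = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        b = np.concatenate([grp["start"].to_numpy(), [grp["end"].iloc[-1]]])
        if not np.array_equal(b[1:-1], grp["end"].to_numpy()[:-1]):
            raise ValueError(f"map intervals on {chrom} are not contiguous")
        boundaries[chrom] = b
    part = IntervalPartition(boundaries)
    ci = {}
    if "ci_lo" in df.columns and "ci_hi" in df.columns:
        ci[ci_level if ci_level is not None else 0.95] = (
            df["ci_lo"].to_numpy(float), df["ci_hi"].to_numpy(float))
    return GeneticMap(part, df["rate_cM_per_Mb"].to_numpy(float), sex=sex, ci=ci)
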