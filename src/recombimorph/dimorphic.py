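"""Calling sexually dimorphic intervals/regions and sex-specific hotspots.

An interval is dimorphic at level gamma when the female and male posterior
credible intervals at that level do not overlap.  Well-localized dimorphic
intervals (100 bp — 10 kb after merging adjacent ones) seed 10 kb windows;
windows failing direction purity, overlapping assembly gaps, or with a
between-sex rate difference below 2 cM/Mb are discarded, and among mutually
overlapping windows the one with the largest |Delta| is kept.  A region is a
sex-specific hotspot when its length-weighted mean rate exceeds 10 cM/Mb in
one sex while every interval rate in the other sex stays below 1 cM/Mb.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .map_core import FEMALE, MALE, GeneticMap, GenomeLayout

FEMALE_HIGHER = "female_higher"
MALE_HIGHER = "male_higher"


@dataclass
class DimorphicInterval:
    chrom: str
    start: int
    end: int
    direction: str
    f_rate: float
    m_rate: float
    level: float

    @property
    def delta(self) -> float:
        return abs(self.f_rate - self.m_rate)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DimorphicRegion:
    chrom: str
    start: int
    end: int
    direction: str
    delta: float                 # |window mean f − window mean m|, cM/Mb
    max_interval_delta: float    # largest member-interval |Δ|
    members: list = field(default_factory=list)
    clipped: bool = False

    def overlaps(self, other: "DimorphicRegion") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class SexSpecificHotspot:
    region: DimorphicRegion
    hot_sex: str       # FEMALE or MALE
    hot_mean: float    # length-weighted mean rate in the hot sex, cM/Mb
    cold_max: float    # maximum interval rate in the other sex, cM/Mb


def _rates_and_ci(x, level: float):
    """(rates, ci_lo, ci_hi) from a PosteriorSummary or a GeneticMap with CIs."""
    rates = x.mean if hasattr(x, "mean") and not isinstance(x, GeneticMap) else x.rates
    if level not in x.ci:
        raise ValueError(f"no credible interval stored at level {level}")
    lo, hi = x.ci[level]
    return np.asarray(rates, float), np.asarray(lo, float), np.asarray(hi, float)


def call_dimorphic_intervals(f, m, level: float = 0.99) -> list:
    """Flag intervals whose female and male CIs at ``level`` do not overlap."""
    if not f.partition.same_as(m.partition):
        raise ValueError("female and male summaries are on different partitions")
    fr, flo, fhi = _rates_and_ci(f, level)
    mr, mlo, mhi = _rates_and_ci(m, level)
    out = []
    part = f.partition
    for chrom in part.chroms:
        sl = part.chrom_slice(chrom)
        starts, ends = part.interval_bounds(chrom)
        for k in range(starts.size):
            i = sl.start + k
            if not (np.isfinite(flo[i]) and np.isfinite(mhi[i])
                    and np.isfinite(mlo[i]) and np.isfinite(fhi[i])):
                continue
            if flo[i] > mhi[i]:
                direction = FEMALE_HIGHER
            elif mlo[i] > fhi[i]:
                direction = MALE_HIGHER
            else:
                continue
            out.append(DimorphicInterval(chrom, int(starts[k]), int(ends[k]),
                                         direction, float(fr[i]), float(mr[i]), level))
    return out


def filter_intervals(intervals, min_len: int = 100, max_len: int = 10_000) -> list:
    """Drop poorly localized intervals: shorter than ``min_len`` or longer than
    ``max_len`` (strict exclusion; the boundary lengths themselves are kept)."""
    return [iv for iv in intervals if min_len <= iv.length <= max_len]


def merge_adjacent(intervals, slack: int = 0) -> list:
    """Merge same-direction intervals whose gap is <= ``slack`` bp (default:
    touching) into larger dimorphic intervals; rates merged length-weighted."""
    merged: list = []
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start)):
        if (merged and iv.chrom == merged[-1].chrom
                and iv.direction == merged[-1].direction
                and iv.start - merged[-1].end <= slack):
            prev = merged[-1]
            w1, w2 = prev.length, iv.length
            merged[-1] = DimorphicInterval(
                prev.chrom, prev.start, iv.end, prev.direction,
                (prev.f_rate * w1 + iv.f_rate * w2) / (w1 + w2),
                (prev.m_rate * w1 + iv.m_rate * w2) / (w1 + w2),
                prev.level,
            )
        else:
            merged.append(DimorphicInterval(iv.chrom, iv.start, iv.end, iv.direction,
                                            iv.f_rate, iv.m_rate, iv.level))
    return merged


def build_regions(intervals, genome: GenomeLayout, f_map, m_map,
                  window: int = 10_000, min_diff: float = 2.0,
                  all_intervals=None, merge_slack: int = 0) -> list:
    """Dimorphic regions: 10 kb windows centred on (merged) dimorphic intervals.

    ``f_map``/``m_map`` may be GeneticMaps or PosteriorSummaries (their mean
    rates are used for window-level Delta).  ``all_intervals`` (default: the
    input) is the significant set used for the direction-purity check.
    """
    f_map = f_map.to_map() if hasattr(f_map, "to_map") else f_map
    m_map = m_map.to_map() if hasattr(m_map, "to_map") else m_map
    if all_intervals is None:
        all_intervals = intervals
    lengths = genome.lengths
    merged = merge_adjacent(intervals, slack=merge_slack)

    candidates: list = []
    for iv in merged:
        mid = (iv.start + iv.end) // 2
        start, end = mid - window // 2, mid + window - window // 2
        clen = lengths[iv.chrom]
        clipped = start < 0 or end > clen
        start, end = max(start, 0), min(end, clen)
        # direction purity: any overlapping significant interval of the other direction kills it
        if any(ov.chrom == iv.chrom and ov.direction != iv.direction
               and ov.start < end and start < ov.end for ov in all_intervals):
            continue
        if any(gc == iv.chrom and gs < end and start < ge
               for gc, gs, ge in genome.gaps):
            continue
        members = [ov for ov in all_intervals
                   if ov.chrom == iv.chrom and ov.start < end and start < ov.end]
        fmean = f_map.mean_rate(iv.chrom, start, end)
        mmean = m_map.mean_rate(iv.chrom, start, end)
        delta = abs(fmean - mmean)
        if not np.isfinite(delta) or delta < min_diff:
            continue
        max_iv_delta = max((ov.delta for ov in members), default=iv.delta)
        candidates.append(DimorphicRegion(iv.chrom, start, end, iv.direction,
                                          float(delta), float(max_iv_delta),
                                          members=members, clipped=clipped))

    # among mutually overlapping windows keep the one with the largest |Δ|
    kept: list = []
    for reg in sorted(candidates, key=lambda r: -r.delta):
        if not any(reg.overlaps(k) for k in kept):
            kept.append(reg)
    kept.sort(key=lambda r: (r.chrom, r.start))
    return kept


def classify_sex_specific(regions, f_map, m_map,
                          hot_mean: float = 10.0, cold_max: float = 1.0) -> list:
    """Sex-specific hotspots: window mean > ``hot_mean`` in one sex and maximum
    interval rate < ``cold_max`` in the other."""
    f_map = f_map.to_map() if hasattr(f_map, "to_map") else f_map
    m_map = m_map.to_map() if hasattr(m_map, "to_map") else m_map
    out = []
    for reg in regions:
        fmean = f_map.mean_rate(reg.chrom, reg.start, reg.end)
        mmean = m_map.mean_rate(reg.chrom, reg.start, reg.end)
        fmax = f_map.max_rate(reg.chrom, reg.start, reg.end)
        mmax = m_map.max_rate(reg.chrom, reg.start, reg.end)
        if fmean > hot_mean and mmax < cold_max:
            out.append(SexSpecificHotspot(reg, FEMALE, float(fmean), float(mmax)))
        elif mmean > hot_mean and fmax < cold_max:
            out.append(SexSpecificHotspot(reg, MALE, float(mmean), float(fmax)))
    return out


def regions_to_frame(regions, hotspots=()) -> pd.DataFrame:
    """BED6+ output: chrom, start, end, name(direction), score(|Δ|×100, capped
    1000), strand('.'), f/m window means and class."""
    by_region = {id(h.region): h for h in hotspots}
    rows = []
    for reg in regions:
        h = by_region.get(id(reg))
        cls = f"{'female' if h.hot_sex == FEMALE else 'male'}_specific_hotspot" if h else "dimorphic"
        rows.append((reg.chrom, reg.start, reg.end, reg.direction,
                     min(int(round(reg.delta * 100)), 1000), ".",
                     reg.delta, reg.max_interval_delta, cls))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                       "strand", "delta", "max_interval_delta", "class"])
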