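"""Annotation tracks, degenerate-motif scanning, anchored rate profiles and
randomized overlap-enrichment tests.

The motif of main interest is the degenerate 13-mer PRDM9 binding motif
CCNCCNTNNCCNC; scanning covers both strands (the reverse complement of the
pattern is searched on the forward sequence) and reports every overlapping
match.
"""
from __future__ import annotations

import re
import warnings
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .map_core import BinnedTrack, GeneticMap, GenomeLayout

PRDM9_MOTIF = "CCNCCNTNNCCNC"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(pattern: str) -> str:
    return pattern.upper().translate(_COMPLEMENT)[::-1]


def _iupac_regex(pattern: str) -> str:
    try:
        return "".join(_IUPAC[c] for c in pattern.upper())
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r} in motif pattern") from None


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int   # 0-based start of the match on the forward sequence
    strand: str  # '+' or '-'


def _sequences(source) -> Mapping[str, str]:
    if isinstance(source, Mapping):
        return source
    try:
        from pyfaidx import Fasta
    except ImportError:  # pragma: no cover
        raise ImportError("reading FASTA paths requires pyfaidx")
    fa = Fasta(str(source), as_raw=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def scan_motif(source, pattern: str = PRDM9_MOTIF) -> list:
    """All (possibly overlapping) matches of an IUPAC pattern on both strands.

    ``source`` is a chrom -> sequence mapping or a FASTA path.  A hit's start
    is always the leftmost base of the matched window on the forward strand.
    """
    fwd = re.compile(f"(?=({_iupac_regex(pattern)}))")
    rc_pat = reverse_complement(pattern)
    rev = None if rc_pat == pattern.upper() else re.compile(f"(?=({_iupac_regex(rc_pat)}))")
    hits = []
    for chrom, seq in _sequences(source).items():
        s = seq.upper()
        hits.extend(MotifHit(chrom, m.start(), "+") for m in fwd.finditer(s))
        if rev is not None:
            hits.extend(MotifHit(chrom, m.start(), "-") for m in rev.finditer(s))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def motif_positions(hits, pattern_length: int = len(PRDM9_MOTIF)) -> dict:
    """Per-chromosome sorted arrays of motif-hit centres, counting a position
    once even when hit on both strands."""
    per: dict = {}
    for h in hits:
        per.setdefault(h.chrom, set()).add(h.start + pattern_length // 2)
    return {c: np.array(sorted(p), dtype=np.int64) for c, p in per.items()}


# ---------------------------------------------------------------------------
# Binned annotations
# ---------------------------------------------------------------------------

def _merge_spans(spans) -> list:
    spans = sorted(spans)
    out: list = []
    for s, e in spans:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _bin_extents(clen: int, bin_size: int) -> np.ndarray:
    n = -(-clen // bin_size)
    edges = np.minimum(np.arange(n + 1, dtype=np.int64) * bin_size, clen)
    return (edges[1:] - edges[:-1]).astype(float)


def bed_coverage_tracks(genome: GenomeLayout, records, bin_size: int = 1000) -> dict:
    """Fraction of each bin covered by the union of BED records.

    ``records`` is an iterable of (chrom, start, end) or a BED path.  Records
    extending past the chromosome end are rejected (counted in a warning).
    """
    if isinstance(records, (str, bytes)) or hasattr(records, "read"):
        df = pd.read_csv(records, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        records = [(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()]
    lengths = genome.lengths
    per: dict = {}
    rejected = 0
    for chrom, s, e in records:
        if chrom not in lengths or s < 0 or e > lengths[chrom] or s >= e:
            rejected += 1
            continue
        per.setdefault(chrom, []).append((int(s), int(e)))
    if rejected:
        warnings.warn(f"rejected {rejected} BED records outside chromosome bounds")
    tracks = {}
    for chrom, clen in genome.chromosomes:
        extents = _bin_extents(clen, bin_size)
        cov = np.zeros(extents.size)
        for s, e in _merge_spans(per.get(chrom, [])):
            first, last = s // bin_size, (e - 1) // bin_size
            if first == last:
                cov[first] += e - s
            else:
                cov[first] += (first + 1) * bin_size - s
                cov[last] += e - last * bin_size
                cov[first + 1:last] += bin_size
        tracks[chrom] = BinnedTrack(chrom, bin_size, cov / extents)
    return tracks


def gc_cpg_tracks(genome: GenomeLayout, sequences, bin_size: int = 1000) -> tuple:
    """(GC fraction, CpG density) per bin.  GC is G+C over called (non-N)
    bases; CpG is CG-dinucleotide starts per bin divided by the bin extent."""
    seqs = _sequences(sequences)
    gc_tracks, cpg_tracks = {}, {}
    for chrom, clen in genome.chromosomes:
        extents = _bin_extents(clen, bin_size)
        n_bins = extents.size
        seq = seqs.get(chrom, "")
        arr = np.frombuffer(seq.upper().encode(), dtype="S1")
        edges = np.minimum(np.arange(n_bins, dtype=np.int64) * bin_size, arr.size)
        gc = ((arr == b"G") | (arr == b"C")).astype(float)
        called = np.isin(arr, [b"A", b"C", b"G", b"T"]).astype(float)
        if arr.size:
            gc_sum = np.add.reduceat(gc, edges)
            called_sum = np.add.reduceat(called, edges)
            with np.errstate(invalid="ignore"):
                gc_frac = np.where(called_sum > 0, gc_sum / called_sum, np.nan)
        else:
            gc_frac = np.full(n_bins, np.nan)
        cg = np.zeros(arr.size, dtype=float)
        if arr.size > 1:
            cg[:-1] = (arr[:-1] == b"C") & (arr[1:] == b"G")
            cpg = np.add.reduceat(cg, edges) / extents
        else:
            cpg = np.zeros(n_bins)
        gc_tracks[chrom] = BinnedTrack(chrom, bin_size, gc_frac)
        cpg_tracks[chrom] = BinnedTrack(chrom, bin_size, cpg)
    return gc_tracks, cpg_tracks


def motif_density_tracks(genome: GenomeLayout, hits, bin_size: int = 1000) -> dict:
    """Motif-hit starts per bin (a hit on either strand counts once)."""
    starts: dict = {}
    for h in hits:
        starts.setdefault(h.chrom, set()).add(h.start)
    tracks = {}
    for chrom, clen in genome.chromosomes:
        n_bins = -(-clen // bin_size)
        counts = np.zeros(n_bins)
        for s in starts.get(chrom, ()):
            if 0 <= s < clen:
                counts[s // bin_size] += 1
        tracks[chrom] = BinnedTrack(chrom, bin_size, counts)
    return tracks


def binned_annotations(genome: GenomeLayout, fasta=None, beds: Mapping | None = None,
                       motif_hits=None, bin_size: int = 1000) -> dict:
    """Standard annotation-track set: GC/CpG from sequence, coverage fraction
    per BED input, motif density; keyed by annotation name."""
    out: dict = {}
    if fasta is not None:
        gc, cpg = gc_cpg_tracks(genome, fasta, bin_size)
        out["gc"], out["cpg"] = gc, cpg
    for name, recs in (beds or {}).items():
        out[name] = bed_coverage_tracks(genome, recs, bin_size)
    if motif_hits is not None:
        out["motif"] = motif_density_tracks(genome, motif_hits, bin_size)
    return out


# ---------------------------------------------------------------------------
# Anchored profiles
# ---------------------------------------------------------------------------

@dataclass
class AnchorSet:
    """Genomic anchor points (TSS, hotspot centres, peak midpoints, ...)."""

    anchors: list  # of (chrom, position) or (chrom, position, strand)
    name: str = ""

    def __post_init__(self):
        self.anchors = [a if len(a) == 3 else (a[0], a[1], None) for a in self.anchors]

    def __len__(self) -> int:
        return len(self.anchors)

    def positions(self, chrom: str) -> np.ndarray:
        return np.array(sorted(p for c, p, _ in self.anchors if c == chrom), dtype=np.int64)


@dataclass
class ProfileResult:
    """Mean rate per offset bin around a set of anchors, with 95% CI of the mean."""

    offsets: np.ndarray  # bin start offsets relative to the anchor, bp
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n: np.ndarray        # anchors contributing per offset
    n_anchors_used: int = 0
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean,
                             "lo": self.ci_lo, "hi": self.ci_hi, "n": self.n})


def anchored_profile(gmap: GeneticMap, anchors: AnchorSet, half_width: int = 50_000,
                     bin: int = 1000, genome: GenomeLayout | None = None) -> ProfileResult:
    """Average map rate in 1 kb offset bins around anchors.

    Per anchor, the rate in offset bin [pos+o, pos+o+bin) is the length-weighted
    map rate over that window (exact, via the cumulative genetic map); bins
    falling outside the mapped region — or over gaps/centromeres when a genome
    is supplied — are NA and excluded per anchor.  Stranded anchors on '-' are
    flipped so that positive offsets point downstream.
    """
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    n_off = 2 * (half_width // bin)
    offs = (np.arange(n_off + 1, dtype=np.int64) - n_off // 2) * bin
    rows = []
    excluded = 0
    for chrom in gmap.partition.chroms:
        b, cum = gmap.cumulative(chrom)
        mask_spans = genome.masked_spans(chrom) if genome is not None else []
        for c, pos, strand in anchors.anchors:
            if c != chrom:
                continue
            edges = pos + offs
            G = np.interp(edges, b, cum)
            vals = (G[1:] - G[:-1]) / (bin * 1e-6)
            bad = (edges[:-1] < b[0]) | (edges[1:] > b[-1])
            for s, e in mask_spans:
                bad |= (edges[:-1] < e) & (edges[1:] > s)
            vals[bad] = np.nan
            if strand == "-":
                vals = vals[::-1]
            if np.all(np.isnan(vals)):
                excluded += 1
                continue
            rows.append(vals)
    if not rows:
        raise ValueError("no anchors with usable windows")
    mat = np.vstack(rows)
    n = np.sum(np.isfinite(mat), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return ProfileResult(offs[:-1], mean, mean - 1.96 * sem, mean + 1.96 * sem,
                         n, n_anchors_used=mat.shape[0], n_excluded=excluded)


def select_spaced_anchors(anchors: AnchorSet, min_spacing: int = 5000,
                          seed: int | None = None, rng=None) -> AnchorSet:
    """Seeded random subset in which all same-chromosome anchors are
    >= ``min_spacing`` apart (random shuffle, then greedy accept-if-spaced)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    order = rng.permutation(len(anchors.anchors))
    accepted_pos: dict = {}
    accepted = []
    for i in order:
        chrom, pos, strand = anchors.anchors[i]
        kept = accepted_pos.setdefault(chrom, [])
        j = bisect_left(kept, pos)
        if (j > 0 and pos - kept[j - 1] < min_spacing) or \
           (j < len(kept) and kept[j] - pos < min_spacing):
            continue
        insort(kept, pos)
        accepted.append((chrom, pos, strand))
    accepted.sort(key=lambda a: (a[0], a[1]))
    return AnchorSet(accepted, name=anchors.name)


def partition_by_motif(anchors: AnchorSet, hits, within: int = 5000,
                       pattern_length: int = len(PRDM9_MOTIF)) -> tuple:
    """Split anchors into (with, without) a motif-hit centre within ±``within``
    bp (inclusive)."""
    centres = hits if isinstance(hits, dict) else motif_positions(hits, pattern_length)
    with_m, without = [], []
    for chrom, pos, strand in anchors.anchors:
        pts = centres.get(chrom)
        near = False
        if pts is not None and pts.size:
            j = int(np.searchsorted(pts, pos))
            for k in (j - 1, j):
                if 0 <= k < pts.size and abs(int(pts[k]) - pos) <= within:
                    near = True
        (with_m if near else without).append((chrom, pos, strand))
    return (AnchorSet(with_m, name=f"{anchors.name}_with_motif"),
            AnchorSet(without, name=f"{anchors.name}_without_motif"))


# ---------------------------------------------------------------------------
# Overlap enrichment
# ---------------------------------------------------------------------------

@dataclass
class OverlapEnrichment:
    observed: float
    expected: float
    ci_lo: float
    ci_hi: float
    n_rand: int
    seed: int | None = None


def _overlap_fraction(positions_by_chrom: dict, peaks_by_chrom: dict, within: int) -> float:
    hit = total = 0
    for chrom, pos in positions_by_chrom.items():
        total += len(pos)
        peaks = peaks_by_chrom.get(chrom)
        if peaks is None or not len(peaks[0]):
            continue
        starts, ends = peaks
        pos = np.asarray(pos)
        # candidate peaks: last with start <= pos, and the next one
        j = np.searchsorted(starts, pos, side="right") - 1
        jc = np.clip(j, 0, starts.size - 1)
        inside = (j >= 0) & (starts[jc] <= pos) & (pos < ends[jc])
        d_prev = np.where(j >= 0, pos - (ends[jc] - 1), np.iinfo(np.int64).max)
        jn = np.clip(j + 1, 0, starts.size - 1)
        d_next = np.where(j + 1 < starts.size, starts[jn] - pos, np.iinfo(np.int64).max)
        near = inside | (d_prev <= within) | (d_next <= within)
        hit += int(near.sum())
    return hit / total if total else float("nan")


def overlap_enrichment(anchors: AnchorSet, peaks, genome: GenomeLayout,
                       within: int = 1000, n_rand: int = 1000,
                       mask=None, seed: int = 0) -> OverlapEnrichment:
    """Observed fraction of anchors within ±``within`` bp of a peak, versus the
    null distribution from ``n_rand`` uniform placements of the same number of
    anchors on unmasked sequence of the same chromosome (seeded)."""
    peaks_by_chrom: dict = {}
    for chrom, s, e in peaks:
        peaks_by_chrom.setdefault(chrom, []).append((int(s), int(e)))
    for chrom in peaks_by_chrom:
        merged = _merge_spans(peaks_by_chrom[chrom])
        peaks_by_chrom[chrom] = (np.array([s for s, _ in merged], dtype=np.int64),
                                 np.array([e for _, e in merged], dtype=np.int64))

    pos_by_chrom = {}
    for chrom, _ in genome.chromosomes:
        p = anchors.positions(chrom)
        if p.size:
            pos_by_chrom[chrom] = p
    observed = _overlap_fraction(pos_by_chrom, peaks_by_chrom, within)

    # allowed (unmasked) segments per chromosome
    allowed: dict = {}
    lengths = genome.lengths
    for chrom in pos_by_chrom:
        masked = _merge_spans(list(genome.masked_spans(chrom)) +
                              [(s, e) for c, s, e in (mask or ()) if c == chrom])
        segs, cursor = [], 0
        for s, e in masked:
            if s > cursor:
                segs.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < lengths[chrom]:
            segs.append((cursor, lengths[chrom]))
        tot = sum(e - s for s, e in segs)
        if tot < pos_by_chrom[chrom].size:
            raise ValueError(f"unmasked sequence on {chrom} too small for randomization")
        allowed[chrom] = (segs, tot)

    rng = np.random.default_rng(seed)
    fractions = np.empty(n_rand)
    for r in range(n_rand):
        rand_pos = {}
        for chrom, p in pos_by_chrom.items():
            segs, tot = allowed[chrom]
            u = rng.random(p.size) * tot
            seg_len = np.array([e - s for s, e in segs], dtype=float)
            cum = np.concatenate([[0.0], np.cumsum(seg_len)])
            k = np.searchsorted(cum, u, side="right") - 1
            k = np.clip(k, 0, len(segs) - 1)
            starts = np.array([s for s, _ in segs], dtype=float)
            rand_pos[chrom] = (starts[k] + (u - cum[k])).astype(np.int64)
        fractions[r] = _overlap_fraction(rand_pos, peaks_by_chrom, within)

    lo, hi = np.percentile(fractions, [2.5, 97.5])
    return OverlapEnrichment(float(observed), float(fractions.mean()),
                             float(lo), float(hi), n_rand, seed)
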