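"""Haar discrete wavelet transform of binned genomic signals.

Signals (1 kb-binned log10 rates or annotations) are NA-padded to the next
power of two and decomposed with the orthonormal Haar pyramid

    s_j[k] = (s_{j-1}[2k] + s_{j-1}[2k+1]) / sqrt(2)
    d_j[k] = (s_{j-1}[2k] - s_{j-1}[2k+1]) / sqrt(2),     s_0 = signal.

Any coefficient whose support contains an NA bin is NA (NaN propagates through
the pyramid), so edge effects from padding are automatically excluded.  The
level-j coefficients describe variation at scale bin_size * 2^j.  On NA-free
signals the transform is orthonormal (Parseval: detail + final-smooth energy
equals signal energy).

Genome-wide statistics pool per-chromosome coefficients at each level;
chromosomes are never concatenated, so no coefficient straddles two
chromosomes.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .map_core import BinnedTrack


def log_transform(track: BinnedTrack, epsilon: float = 1e-3) -> BinnedTrack:
    """log10(value + epsilon) per bin, NA preserved; negative input is an error."""
    v = track.values
    if np.any(v[np.isfinite(v)] < 0):
        raise ValueError("negative values cannot be log-transformed")
    return BinnedTrack(track.chrom, track.bin_size, np.log10(v + epsilon))


def next_pow2(n: int) -> int:
    return 1 << max(n - 1, 0).bit_length()


@dataclass
class DyadicSignal:
    """A binned signal NA-padded to a power-of-two length."""

    values: np.ndarray
    chrom: str = ""
    bin_size: int = 1000
    n_orig: int = 0

    @classmethod
    def from_track(cls, track: BinnedTrack) -> "DyadicSignal":
        n = track.n_bins
        padded = np.full(next_pow2(n), np.nan)
        padded[:n] = track.values
        return cls(padded, chrom=track.chrom, bin_size=track.bin_size, n_orig=n)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size & (self.values.size - 1):
            raise ValueError("DyadicSignal length must be a power of two")
        if not self.n_orig:
            self.n_orig = self.values.size


@dataclass
class WaveletLevels:
    """Per-level Haar detail (d) and smoothing (s) coefficients, NA-masked."""

    details: list      # details[j-1] has length n / 2^j
    smooths: list
    bin_size: int = 1000
    chrom: str = ""

    @property
    def n_levels(self) -> int:
        return len(self.details)

    def scale_bp(self, level: int) -> int:
        return self.bin_size * 2 ** level


def haar_dwt(signal, max_level: int | None = None) -> WaveletLevels:
    """Orthonormal Haar pyramid down to ``max_level`` (default: full depth)."""
    if isinstance(signal, BinnedTrack):
        signal = DyadicSignal.from_track(signal)
    if isinstance(signal, DyadicSignal):
        s = signal.values.astype(float)
        bin_size, chrom = signal.bin_size, signal.chrom
    else:
        s = np.asarray(signal, dtype=float)
        bin_size, chrom = 1000, ""
    n = s.size
    full = int(math.log2(n)) if n else 0
    J = full if max_level is None else max_level
    if J > full:
        raise ValueError(f"max_level {J} too deep for signal of length {n}")
    details, smooths = [], []
    sqrt2 = math.sqrt(2.0)
    for _ in range(J):
        a, b = s[0::2], s[1::2]
        details.append((a - b) / sqrt2)
        s = (a + b) / sqrt2
        smooths.append(s.copy())
    return WaveletLevels(details, smooths, bin_size=bin_size, chrom=chrom)


def _as_list(x) -> list:
    return list(x) if isinstance(x, (list, tuple)) else [x]


def power_spectrum(levels) -> pd.DataFrame:
    """Fraction of detail-coefficient energy per scale (sums to 1 over levels).

    ``levels`` may be one WaveletLevels or a list (genome-wide: coefficients are
    pooled across chromosomes before normalizing).
    """
    pool = _as_list(levels)
    J = min(w.n_levels for w in pool)
    energy = np.zeros(J)
    for w in pool:
        for j in range(J):
            d = w.details[j]
            energy[j] += np.nansum(d * d)
    total = energy.sum()
    if total <= 0:
        raise ValueError("all detail coefficients are NA or zero")
    bin_size = pool[0].bin_size
    return pd.DataFrame({
        "level": np.arange(1, J + 1),
        "scale_bp": [bin_size * 2 ** j for j in range(1, J + 1)],
        "fraction": energy / total,
    })


def _coef_correlation(a, b, which: str) -> pd.DataFrame:
    pa, pb = _as_list(a), _as_list(b)
    if len(pa) != len(pb):
        raise ValueError("mismatched number of chromosomes")
    J = min(min(w.n_levels for w in pa), min(w.n_levels for w in pb))
    rows = []
    for j in range(J):
        xs, ys = [], []
        for wa, wb in zip(pa, pb):
            x = getattr(wa, which)[j]
            y = getattr(wb, which)[j]
            if x.size != y.size:
                raise ValueError("wavelet geometries differ")
            xs.append(x)
            ys.append(y)
        x, y = np.concatenate(xs), np.concatenate(ys)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            rows.append((j + 1, pa[0].bin_size * 2 ** (j + 1), np.nan, np.nan, int(ok.sum())))
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append((j + 1, pa[0].bin_size * 2 ** (j + 1), r * r, p, int(ok.sum())))
    return pd.DataFrame(rows, columns=["level", "scale_bp", "r2", "p", "n"])


def detail_correlation(a, b) -> pd.DataFrame:
    """Per-scale squared Pearson correlation of detail coefficients (pooled
    genome-wide), with two-sided p-values."""
    return _coef_correlation(a, b, "details")


def smooth_correlation(a, b) -> pd.DataFrame:
    """As :func:`detail_correlation` but on the smoothing coefficients."""
    return _coef_correlation(a, b, "smooths")


def wavelet_regression(response, predictors, names=None) -> pd.DataFrame:
    """Scale-by-scale OLS of response detail coefficients on predictor details.

    ``response``/each predictor may be a WaveletLevels or a per-chromosome list.
    Returns one row per (level, predictor): coefficient, standard error,
    two-sided t-test p-value, n complete cases and the design condition number.
    Exactly collinear predictors are dropped with a warning at that scale.
    """
    resp = _as_list(response)
    preds = [_as_list(p) for p in predictors]
    if names is None:
        names = [f"x{k}" for k in range(len(preds))]
    J = min(w.n_levels for group in [resp] + preds for w in group)
    rows = []
    for j in range(J):
        y = np.concatenate([w.details[j] for w in resp])
        X = np.column_stack([np.concatenate([w.details[j] for w in p]) for p in preds])
        ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
        yj, Xj = y[ok], X[ok]
        keep = list(range(len(preds)))
        if yj.size >= len(keep) + 2:
            design = np.column_stack([np.ones(yj.size), Xj])
            rank = np.linalg.matrix_rank(design)
            if rank < design.shape[1]:
                warnings.warn(f"collinear predictors at level {j + 1}; dropping redundant columns")
                keep = []
                cols = [np.ones(yj.size)]
                for k in range(Xj.shape[1]):
                    trial = np.column_stack(cols + [Xj[:, k]])
                    if np.linalg.matrix_rank(trial) == trial.shape[1]:
                        cols.append(Xj[:, k])
                        keep.append(k)
                Xj = Xj[:, keep]
        if yj.size < len(keep) + 2 or not keep:
            for k, name in enumerate(names):
                rows.append((j + 1, resp[0].bin_size * 2 ** (j + 1), name,
                             np.nan, np.nan, np.nan, int(yj.size), np.nan))
            continue
        fit = sm.OLS(yj, sm.add_constant(Xj)).fit()
        cond = float(fit.condition_number)
        for k, name in enumerate(names):
            if k in keep:
                col = keep.index(k) + 1  # +1 for intercept
                rows.append((j + 1, resp[0].bin_size * 2 ** (j + 1), name,
                             float(fit.params[col]), float(fit.bse[col]),
                             float(fit.pvalues[col]), int(yj.size), cond))
            else:
                rows.append((j + 1, resp[0].bin_size * 2 ** (j + 1), name,
                             np.nan, np.nan, np.nan, int(yj.size), cond))
    return pd.DataFrame(rows, columns=["level", "scale_bp", "predictor", "coef",
                                       "se", "pvalue", "n", "cond"])


def coefficients_frame(levels) -> pd.DataFrame:
    """Dump of coefficients: chrom, level, index, d, s, na_flag (TSV-ready)."""
    rows = []
    for w in _as_list(levels):
        for j in range(w.n_levels):
            d, s = w.details[j], w.smooths[j]
            for k in range(d.size):
                rows.append((w.chrom, j + 1, k, d[k], s[k],
                             int(not (np.isfinite(d[k]) and np.isfinite(s[k])))))
    return pd.DataFrame(rows, columns=["chrom", "level", "index", "d", "s", "na_flag"])
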