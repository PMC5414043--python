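"""Bayesian Gibbs refinement of crossover localization and per-interval rates.

Model
-----
Within each inter-SNP interval i (length L_i bp), crossover counts across M
meioses of one sex are Poisson with mean M * r_i * L_i * 1e-8, where r_i is
the rate in cM/Mb.  Rates are a priori independent Gamma(alpha, beta)
(beta is a rate parameter, in units of 1/(cM/Mb)).  Each observed event is
known only to lie somewhere in its uncertainty span; the sampler alternates

* an assignment step — each event's interval is resampled within its span with
  probability proportional to r_i * L_i (the Poisson-process placement rule);
* a rate step — given the assigned counts c_i, the conjugate update draws
  r_i ~ Gamma(alpha + c_i, beta + M * L_i * 1e-8) independently per interval.

Posterior means, equal-tailed credible intervals, per-event assignment
posteriors and posterior-expected event resolutions are reported from the
thinned post-burn-in samples.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .map_core import (FEMALE_ONLY_CHROMS, EventSet, GeneticMap,
                       IntervalPartition, ml_rate_map)

_MIN_RATE = 1e-300  # guards log/weight arithmetic against exact-zero gamma draws


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, rate) prior on per-interval rates in cM/Mb."""

    shape: float
    rate: float

    def __post_init__(self):
        if not (self.shape > 0 and np.isfinite(self.shape)
                and self.rate > 0 and np.isfinite(self.rate)):
            raise ValueError("gamma prior parameters must be strictly positive and finite")

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def sd(self) -> float:
        return self.shape ** 0.5 / self.rate


@dataclass
class MCMCConfig:
    """Sampler schedule.  The default is the full production schedule
    (1.3M iterations, 300k burn-in, thinning 100 -> 10,000 retained samples);
    :func:`desk_config` gives a small-problem schedule."""

    n_iter: int = 1_300_000
    burn_in: int = 300_000
    thin: int = 100
    ci_levels: tuple = (0.95, 0.99)
    seed: int = 0

    def __post_init__(self):
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if (self.n_iter - self.burn_in) % self.thin:
            raise ValueError("(n_iter - burn_in) must be divisible by thin")

    @property
    def n_samples(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def desk_config(seed: int = 0, ci_levels=(0.95, 0.99)) -> MCMCConfig:
    """Schedule suited to small simulated problems: 10k iterations, 2k burn-in,
    thinning 10 (800 retained samples)."""
    return MCMCConfig(n_iter=10_000, burn_in=2_000, thin=10, ci_levels=tuple(ci_levels), seed=seed)


def fit_prior_from_unrefined(unrefined: GeneticMap) -> GammaPrior:
    """Method-of-moments gamma fit to the length-weighted unrefined rates.

    shape = mean^2 / variance, rate = mean / variance; both clamped to >= 1e-6.
    A zero-variance (constant) map falls back to shape 1 with the prior mean
    matched to the map mean, with a warning.
    """
    r = unrefined.rates
    w = unrefined.partition.lengths.astype(float)
    ok = np.isfinite(r)
    r, w = r[ok], w[ok]
    if r.size < 2:
        raise ValueError("need at least 2 intervals with finite rates")
    mean = float(np.average(r, weights=w))
    var = float(np.average((r - mean) ** 2, weights=w))
    if var <= 0:
        warnings.warn("unrefined map has zero rate variance; falling back to shape=1 prior")
        return GammaPrior(1.0, max(1.0 / mean if mean > 0 else 1.0, 1e-6))
    return GammaPrior(max(mean * mean / var, 1e-6), max(mean / var, 1e-6))


# ---------------------------------------------------------------------------
# Sampler state and steps
# ---------------------------------------------------------------------------

@dataclass
class GibbsProblem:
    """Precomputed arrays for one sex's refinement problem (global interval index)."""

    lengths: np.ndarray     # interval lengths, bp
    exposures: np.ndarray   # M * L_i * 1e-8 per interval
    cand_lo: np.ndarray     # per-event first candidate interval (inclusive)
    cand_hi: np.ndarray     # per-event last candidate interval (exclusive)

    @property
    def n_intervals(self) -> int:
        return self.lengths.size

    @property
    def n_events(self) -> int:
        return self.cand_lo.size


@dataclass
class AssignmentState:
    """Current event-to-interval assignments, interval counts and rates."""

    assignments: np.ndarray
    counts: np.ndarray
    rates: np.ndarray

    def check(self, problem: GibbsProblem) -> None:
        assert int(self.counts.sum()) == problem.n_events
        assert np.all((self.assignments >= problem.cand_lo)
                      & (self.assignments < problem.cand_hi))
        assert np.all(self.rates > 0)


def build_problem(events: EventSet, partition: IntervalPartition, sex: str) -> tuple:
    """(GibbsProblem, events-of-sex) for one sex; M taken from the EventSet."""
    evs = events.of_sex(sex)
    M = events.n_meioses.get(sex, 0)
    if M <= 0:
        raise ValueError(f"no meioses recorded for sex {sex!r}")
    lo = np.empty(len(evs), dtype=np.int64)
    hi = np.empty(len(evs), dtype=np.int64)
    for k, ev in enumerate(evs):
        lo[k], hi[k] = partition.interval_range(ev.chrom, ev.start, ev.end)
    L = partition.lengths.astype(float)
    return GibbsProblem(L, L * M * 1e-8, lo, hi), evs


def initial_state(problem: GibbsProblem, prior: GammaPrior, rng) -> AssignmentState:
    rates = np.full(problem.n_intervals, max(prior.mean, _MIN_RATE))
    state = AssignmentState(
        assignments=np.zeros(problem.n_events, dtype=np.int64),
        counts=np.zeros(problem.n_intervals, dtype=np.int64),
        rates=rates,
    )
    assignment_step(state, problem, rng)
    return state


def assignment_step(state: AssignmentState, problem: GibbsProblem, rng) -> AssignmentState:
    """Resample every event's interval with probability prop. to r_i * L_i
    within its candidate range (vectorized categorical draw via the cumulative
    weight function)."""
    w = state.rates * problem.lengths
    cw = np.concatenate([[0.0], np.cumsum(w)])
    lo, hi = problem.cand_lo, problem.cand_hi
    tot = cw[hi] - cw[lo]
    assert np.all(tot > 0), "all candidate weights zero — rates must stay positive"
    u = cw[lo] + rng.random(lo.size) * tot
    idx = np.searchsorted(cw, u, side="right") - 1
    np.clip(idx, lo, hi - 1, out=idx)
    state.assignments = idx
    state.counts = np.bincount(idx, minlength=problem.n_intervals)
    return state


def rate_step(state: AssignmentState, problem: GibbsProblem, prior: GammaPrior, rng) -> AssignmentState:
    """Conjugate Gamma update: r_i ~ Gamma(alpha + c_i, beta + M L_i 1e-8)."""
    shape = prior.shape + state.counts
    scale = 1.0 / (prior.rate + problem.exposures)
    state.rates = np.maximum(rng.gamma(shape, scale), _MIN_RATE)
    return state


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def summarize_samples(samples: np.ndarray, levels=(0.95, 0.99)) -> tuple:
    """(posterior mean, {level: (lo, hi)}) with equal-tailed quantile CIs."""
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] < 100:
        raise ValueError("need at least 100 samples to summarize")
    if np.any(np.isnan(samples)):
        raise ValueError("NaN in posterior samples")
    mean = samples.mean(axis=0)
    ci = {}
    for g in levels:
        lo, hi = np.quantile(samples, [(1 - g) / 2, 1 - (1 - g) / 2], axis=0)
        ci[g] = (lo, hi)
    return mean, ci


@dataclass
class PosteriorSummary:
    """Posterior over per-interval rates and per-event assignments for one sex."""

    partition: IntervalPartition
    sex: str
    n_meioses: int
    mean: np.ndarray
    ci: dict                       # level -> (lo, hi) rate arrays
    assignment_probs: list         # per event, probs over its candidate intervals
    expected_resolution: np.ndarray  # per event, sum_i P(i) * L_i (bp)
    n_samples: int
    prior: GammaPrior
    config: MCMCConfig

    def to_map(self) -> GeneticMap:
        return GeneticMap(self.partition, self.mean.copy(), sex=self.sex,
                          n_meioses=self.n_meioses,
                          ci={g: (lo.copy(), hi.copy()) for g, (lo, hi) in self.ci.items()})


def gibbs_refine(events: EventSet, partition: IntervalPartition, sex: str,
                 prior: GammaPrior | None = None,
                 config: MCMCConfig | None = None) -> PosteriorSummary:
    """Run the Gibbs sampler for one sex and summarize the posterior.

    ``prior`` defaults to a method-of-moments fit to the unrefined ML map;
    ``config`` defaults to the full production schedule — pass
    :func:`desk_config` for small problems.  Fully reproducible from
    ``config.seed``.
    """
    if len(events) == 0:
        raise ValueError("empty EventSet")
    if prior is None:
        prior = fit_prior_from_unrefined(ml_rate_map(events, partition, sex))
    if config is None:
        config = MCMCConfig()
    problem, evs = build_problem(events, partition, sex)
    if problem.n_events == 0:
        raise ValueError(f"no events for sex {sex!r}")

    covered = np.zeros(partition.n_intervals, dtype=bool)
    for lo, hi in zip(problem.cand_lo, problem.cand_hi):
        covered[lo:hi] = True
    for chrom in partition.chroms:
        if not covered[partition.chrom_slice(chrom)].any():
            warnings.warn(f"chromosome {chrom} has no {sex} events; its rates are prior draws")

    rng = np.random.default_rng(config.seed)
    state = initial_state(problem, prior, rng)

    n_keep = config.n_samples
    samples = np.empty((n_keep, problem.n_intervals))
    # per-event assignment tallies, flattened over candidate ranges
    widths = problem.cand_hi - problem.cand_lo
    ptr = np.concatenate([[0], np.cumsum(widths)])
    tallies = np.zeros(int(ptr[-1]), dtype=np.int64)

    kept = 0
    for it in range(config.n_iter):
        assignment_step(state, problem, rng)
        rate_step(state, problem, prior, rng)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            samples[kept] = state.rates
            np.add.at(tallies, ptr[:-1] + (state.assignments - problem.cand_lo), 1)
            kept += 1
    assert kept == n_keep

    mean, ci = summarize_samples(samples, config.ci_levels)
    probs = [tallies[ptr[k]:ptr[k + 1]] / n_keep for k in range(problem.n_events)]
    expected_res = np.array(
        [float(np.dot(p, problem.lengths[lo:hi]))
         for p, lo, hi in zip(probs, problem.cand_lo, problem.cand_hi)]
    )

    if sex == "M":
        for chrom in partition.chroms:
            if chrom in FEMALE_ONLY_CHROMS:
                sl = partition.chrom_slice(chrom)
                mean[sl] = np.nan
                for g in ci:
                    ci[g][0][sl] = np.nan
                    ci[g][1][sl] = np.nan

    return PosteriorSummary(
        partition=partition, sex=sex, n_meioses=events.n_meioses[sex],
        mean=mean, ci=ci, assignment_probs=probs,
        expected_resolution=expected_res, n_samples=n_keep,
        prior=prior, config=config,
    )
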