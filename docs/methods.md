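# Methods

## Coordinate system and units

All coordinates are 0-based half-open internally; BED conventions on disk
(1-based event TSVs are accepted via a flag). Rates are cM/Mb everywhere. The
single unit conversion — expected crossovers per meiosis in an interval equals
`rate · L · 1e-8` (1 cM = 1% crossover probability, 1 Mb = 1e6 bp) — lives in
`map_core.expected_crossovers` and is used consistently by the likelihood,
the sampler and the simulator.

The interval partition per chromosome is the sorted union of all event-span
endpoints, so every event covers an exactly contiguous run of intervals. The
X chromosome is treated as female-only: male maps there are emitted as NA.

## Unrefined maximum-likelihood map

Each event distributes one unit of crossover mass across its candidate
intervals proportionally to physical length — the maximum-likelihood solution
of the uniform-placement model, and equivalent to assuming no rate
information within a span. `rate_i = (mass_i / M) · 100 / (L_i · 1e-6)`.
This conserves mass exactly: the map's total genetic length is
`100 · n_events / M` cM. An EM-style iterative reweighting is deliberately
not implemented; the Gibbs refinement supersedes it.

## Gibbs refinement

Per-interval counts are modelled Poisson with mean `M · r_i · L_i · 1e-8`;
the Bernoulli-per-meiosis exactness is ignored because per-interval rates are
small. Intervals are a priori independent Gamma(α, β) (β is a rate
parameter, units 1/(cM/Mb)); there is no spatial smoothing and no crossover
interference. The prior is fitted by length-weighted method of moments on the
unrefined map (`α = m²/v`, `β = m/v`, clamped at 1e-6; a zero-variance map
falls back to shape 1 with matched mean, with a warning); both parameters can
be overridden from the CLI.

The sampler alternates exact conditional draws:

* assignments ∝ `r_i · L_i` within each event's span — the posterior-correct
  rule for the Poisson-process placement model (the alternative ∝ `r_i` alone
  would correspond to a single-point placement model and is not used);
* rates from the conjugate `Gamma(α + c_i, β + M·L_i·1e-8)`.

Both steps are vectorized (cumulative-weight categorical sampling;
`numpy.random.Generator.gamma`), so a 10k-iteration chain on a
thousand-interval problem runs in a couple of seconds. Credible intervals are
equal-tailed sample quantiles (not HPD). Per-event assignment posteriors are
tallied at the retained iterations; the expected resolution of an event is
`Σ_i P(assign = i) · L_i`, which is by construction never coarser than the
span. Summaries require ≥100 retained samples and reject NaN. Everything is
reproducible from a single integer seed through one `numpy` Generator.

Schedules: the documented production schedule is 1.3M iterations / 300k
burn-in / thin 100 (10,000 retained samples); `desk_config()` (10k / 2k /
10, 800 samples) is used for the simulated studies in the tests and the
acceptance script, whose problems have a few hundred intervals rather than
hundreds of thousands.

## Dimorphic regions and sex-specific hotspots

An interval is dimorphic at level γ when the two sexes' γ credible intervals
are disjoint. Intervals shorter than 100 bp or longer than 10 kb are excluded
(strict exclusion, matching the wording "smaller than"/"larger than").
Adjacent (touching; configurable slack, default 0) same-direction intervals
are merged *before* windowing — the alternative order (window first) is a
documented convention choice. Each merged interval seeds a 10 kb window on
its midpoint; windows are discarded when they contain an opposite-direction
significant interval, overlap an assembly gap, or show a length-weighted
window-level |Δ| below 2 cM/Mb; among mutually overlapping windows the
largest |Δ| wins. |Δ| is defined at window level (the per-interval maximum is
recorded alongside). Windows clipped at chromosome ends are retained and
flagged. Classification thresholds: window mean >10 cM/Mb in the hot sex and
maximum interval rate <1 cM/Mb in the cold sex.

A small-cohort caveat the synthetic experiments make explicit: intervals with
no assigned events revert to the prior mean (the genome-average rate), so the
cold-sex "max < 1 cM/Mb" rule is only attainable when the cold sex's average
rate is comfortably below 1 — at very large meiosis counts the exposure term
dominates and this ceases to matter.

## Wavelet analysis

Maps are interpolated into 1 kb bins (length-weighted mean rate per bin); a
bin is NA when it overlaps an assembly gap, a centromere, or an interval
longer than 50 kb (low map resolution), or falls outside the mapped region.
Rates are log10-transformed with ε = 1e-3 cM/Mb (posterior-mean maps are
strictly positive, so ε matters only for synthetic truth maps containing
exact zeros). Signals are NA-padded to the next power of two and decomposed
with the orthonormal Haar pyramid (1/√2 normalization, Parseval exact); NaN
propagates through the pyramid, so any coefficient whose support touches an
NA bin — including all padding — is automatically excluded. Level j describes
scale `bin_size · 2^j`; the default 14 levels on 1 kb bins span 2 kb–16.4 Mb
(the level count is a flag).

The power spectrum normalizes over detail energies only (the final smooth is
excluded), so reported fractions are shares of the analyzed scale range.
Genome-wide statistics pool per-chromosome coefficients at each level;
chromosomes are never concatenated. Per-scale cross-sex correlations are
Pearson r² over complete coefficient pairs (≥3 required, else NA); the
regression is ordinary least squares with intercept on detail coefficients,
with marginal two-sided t-tests. Exactly collinear predictors are dropped
with a warning and the design's condition number is reported.

In the synthetic recovery experiment the cross-sex comparison bins the
posterior-mean maps *without* the 50 kb low-resolution mask: at desk-scale
event counts most of a 20 Mb genome sits in >50 kb intervals, and NA
propagation would leave zero complete coefficients at ≥256 kb. The mask
remains the default for real-data binning.

## Sequence features

Motif scanning compiles IUPAC patterns (full code set; anything else is an
error) to regex look-aheads, so overlapping matches are all reported; the
reverse complement of the pattern is scanned on the forward sequence and
reported as '−' strand hits. A hit present on both strands at one position
counts once in density tracks. "Within 5 kb" of an anchor is measured
centre-to-anchor, inclusive. Anchored profiles read the map through its
cumulative genetic-length function, so per-offset values are exact
length-weighted means (and the profile is translation-equivariant); the 95%
CI of the mean is ±1.96·SEM. Spaced-anchor selection is a seeded random
shuffle with greedy accept-if-spaced. Overlap enrichment randomizes anchor
positions uniformly over unmasked sequence of the same chromosome (gaps and
centromeres excluded) and reports the 2.5/97.5 percentiles of the
randomized overlap fractions.

## Synthetic data generator

The generator emulates the structure of multi-cohort pedigree crossover data;
its defaults define the study conditions used throughout the tests and the
acceptance script (a 20 Mb genome in two chromosomes, 2,000 meioses per sex):

* **Hotspots** — Poisson-placed at 0.75 per Mb; widths Gamma(4, mean 1.2 kb,
  floor 200 bp), matching the 1–2 kb width of real hotspots; intensities
  (cM contributed per hotspot) Gamma(6, 0.15) — mean 0.9 cM, CV 0.41. 40% of
  hotspots are shared between the sexes with Gamma intensities coupled by a
  Gaussian copula (ρ = 0.8), and 25% per sex are sex-specific. The
  sex-specific fraction is deliberately enriched relative to the
  mostly-shared regime of real genomes so the recovery experiment has a
  usable number of true positives; the realistic regime is one parameter
  away (`shared_fraction`).
* **Backgrounds** — both sexes share a smooth random trend (3 long-wavelength
  cosines, amplitude 0.5); female background 0.1 cM/Mb, male 0.05 cM/Mb
  additionally multiplied by a subtelomeric elevation factor
  (1 + 3·exp(−d/2 Mb), normalized to mean 1). The male hotspot-intensity
  scale is solved so the genome-wide female/male total equals the configured
  1.6 exactly. The resulting averages (~0.6 cM/Mb female, ~0.37 male)
  represent a modestly recombining region; they are intentionally below
  1 cM/Mb so that the cold-sex hotspot criterion is attainable at a
  2,000-meiosis cohort (see the caveat above).
* **Observation** — crossovers per meiosis per chromosome are Poisson in the
  map's total Morgans (no interference, consistent with the likelihood);
  positions by inverse CDF of the cumulative map; SNPs Poisson-placed at
  1 per kb, each informative per meiosis independently with probability 0.3
  (i.i.d. thinning emulating heterozygosity/phase filtering, without
  modelling genotypes). An event's span is the flanking informative-SNP
  pair; crossovers lacking a flank are dropped and counted. Median spans are
  ~5–7 kb — a dense-genotyping cohort; these choices were fixed by a power
  analysis of the dimorphic caller at the 2,000-meiosis design before the
  test suite was frozen.

What passing the synthetic suite does **not** show: performance under
genotyping error, phasing artifacts, crossover interference, population
structure across merged cohorts, or the much larger interval counts
(hundreds of thousands) of real genome-wide data.

## Numerical choices and degenerate inputs

Gamma draws are floored at 1e-300 to keep assignment weights strictly
positive; posterior quantiles from 800 desk-schedule samples make extreme
(99.5%) bounds noticeably noisy, which the tolerance of the enumeration
oracle accounts for. Concentration curves sort intervals hottest-first with a
stable sort; `sequence_fraction_for` subtracts 1e-9 from the quantile before
the search to absorb cumulative-sum round-off. Degenerate cases are explicit
errors (empty event sets, zero meioses, all-NA signals, all-zero maps,
constant-signal correlations → NA) rather than silent NaN arithmetic.

## Known limitations

* No joint female–male hierarchical model; chains per sex are independent.
* No multi-chain convergence diagnostics beyond seed-reproducible traces.
* Assignment sampling assumes the Poisson-process placement rule; the
  single-point alternative (∝ r only) is noted but not implemented.
* The profile normalization used in some published figures ("normalized
  recombination rates") is not specified in accessible sources; profiles
  here report raw means with CIs.
* Map comparison across genome assemblies (liftover) and crossover detection
  from raw genotypes are out of scope; events are taken as given.
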