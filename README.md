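# recombimorph

Sex-specific genetic maps from pedigree crossover events — Bayesian refinement
of event localization, calling of sexually dimorphic regions and sex-specific
hotspots, and wavelet-based characterization of the genomic scales at which
female and male recombination differ.

## The problem

Human recombination is sexually dimorphic: genome-wide, female crossover rates
are ~1.6-fold higher than male rates, male rates are elevated near telomeres,
and the two sexes differ further at fine scale. Pedigree studies observe each
crossover only as an *uncertainty span* between the two flanking informative
SNPs of a meiosis, so naive per-interval rate estimates are blurred by tens of
kilobases. This package is for statistical geneticists who have crossover
event tables (one row per event: meiosis, parental sex, chromosome, span) and
want fine-scale sex-specific rate maps plus downstream dimorphism analyses.

## The model

The boundaries of all event spans cut each chromosome into inter-SNP
intervals, the atomic units of every map. For one sex with M informative
meioses, the crossover count in interval *i* (length *L_i* bp, rate *r_i* in
cM/Mb) is Poisson with mean `M · r_i · L_i · 1e-8`, with independent
Gamma(α, β) priors on the rates (α, β fitted by length-weighted method of
moments to the unrefined maximum-likelihood map). Because each event is only
known to lie somewhere in its span, a Gibbs sampler alternates

1. **assignment step** — each event's interval is resampled within its span
   with probability ∝ `r_i · L_i`;
2. **rate step** — the conjugate update `r_i ~ Gamma(α + c_i, β + M·L_i·1e-8)`
   given the assigned counts `c_i`.

Posterior means and equal-tailed credible intervals come from the thinned
post-burn-in samples (default schedule 1.3M iterations, 300k burn-in, thin
100 → 10,000 samples; a desk schedule of 10k/2k/10 is provided for small
problems). Downstream:

* **dimorphic intervals** — female and male 99% CIs disjoint; well-localized
  ones (100 bp–10 kb) seed 10 kb regions filtered for direction purity, gap
  overlap and a ≥2 cM/Mb sex difference; *sex-specific hotspots* are regions
  with mean rate >10 cM/Mb in one sex and every interval <1 cM/Mb in the other.
* **wavelet analysis** — 1 kb-binned log10 rates are NA-padded to a power of
  two and decomposed with the orthonormal Haar DWT; detail-coefficient power
  spectra, cross-sex per-scale correlations, and scale-by-scale OLS against
  genomic annotations (GC, exon/repeat coverage, PRDM9-motif density).
* **sequence features** — IUPAC scanning for the degenerate 13-mer PRDM9
  motif `CCNCCNTNNCCNC`, anchored rate profiles around TSS/peak anchors, and
  randomization tests of anchor/peak overlap.
* **simulator** — hotspot-structured sex-specific truth maps (shared hotspots
  with correlated magnitudes, sex-specific hotspots, male subtelomeric
  elevation, configurable female/male ratio), Poisson crossovers per meiosis,
  and span observation through informative-SNP thinning — ground truth for
  parameter-recovery experiments.

## Worked example

```python
import recombimorph as rm
from recombimorph.simulate import run_cohort, recover_sex_specific_hotspots

cohort = run_cohort(truth_seed=11, sim_seed=12, mcmc_seed=1)
events = cohort.data.events
print(f"events: {len(events)}  (F={len(events.of_sex('F'))}, M={len(events.of_sex('M'))})")
print(f"inter-SNP intervals: {cohort.partition.n_intervals}")
med_r, frac10 = rm.event_resolution_stats(cohort.refined['F'])
rep = rm.recovery_metrics(cohort.refined['F'], cohort.ml['F'], cohort.truth, 'F',
                          cohort.data.config.genome)
rec = recover_sex_specific_hotspots(cohort)
```

prints

```
events: 264  (F=156, M=108)
inter-SNP intervals: 239
female event resolution: 6.6 kb unrefined -> 2.4 kb refined (96.2% within 10 kb)
truth correlation at 10 kb: refined r=0.982, unrefined r=0.948
sex-specific hotspots: 4 called, 4/6 implanted ones recovered
```

— a cohort of 2,000 meioses per sex on a 20 Mb two-chromosome genome; the
Gibbs refinement sharpens the median female event localization from 6.6 kb to
2.4 kb, tracks the simulated truth better than the unrefined ML map, and the
dimorphic caller recovers four of the six implanted sex-specific hotspots
with no false calls.

A command-line interface mirrors the library (`recombimorph simulate | mlmap |
refine | binmap | mapcorr | concentration | dimorphic | wavelet | wavereg |
motifscan | profile | enrich`); run `recombimorph --help` for the file
formats (events TSV, BED-like map TSV, chrom.sizes, BED annotations).

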