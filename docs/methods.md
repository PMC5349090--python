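# Methods

This note records the models implemented in `poolseg`, the defaults and
why they were chosen, the numerical details, and the limits of what the
synthetic tests demonstrate.

## Synthetic cross

**Marker map.** Two marker classes segregate in the cross: *induced*
SNPs private to the mutagenized superior parent (default 900, matching
the ~815–967 mutations accumulated by iterated EMS treatment of a
haploid strain) and *background* SNPs distinguishing the two unrelated
parents (default 30,000 — a typical density for unrelated
*S. cerevisiae* strains; the true count for any given cross is unknown
and configurable). Markers are placed uniformly at random,
per-chromosome counts proportional to physical length, on a packaged
16-chromosome genome model approximating the S288c reference
(~12.07 Mb). All markers are polarized so that the "variant" allele is
the superior parent's allele; in real data this corresponds to flipping
background SNPs called against the reference so that frequency is
always linkage-to-the-superior-parent.

**Meiosis.** Crossovers per chromosome are Poisson with mean equal to
the chromosome's genetic length in Morgans at a uniform 0.4 cM/kb (the
yeast genome-wide average), positions uniform, no interference
(Haldane model), one product chromatid kept per meiosis. The two-point
recombinant fraction therefore follows Haldane's map function
r = ½(1 − e^(−2d)), which the tests verify directly. Mitochondrial
status is an independent Bernoulli draw; the default probability of
functional mitochondria is 1.0 because all viable segregants analyzed
in the reference cross had regained respiration (the mutagenized parent
itself had lost it).

**Trait model.** Phenotype (mg/L ethyl acetate after 96 h) is

```
y = (b_sup + b_inf)/2 + Σ_j a_j · 1[conditions_j satisfied] + ε,
ε ~ N(0, σ²)
```

with baselines b_sup = 13.9 and b_inf = 49.8 mg/L (the measured parent
means), residual σ = 1.5 mg/L (typical replicate sd of the printed
segregant table), and three default loci echoing the mapped
architecture:

| locus | effect (mg/L) | class | condition |
|---|---|---|---|
| chrII (~490 kb) | −16 | background | none (background allele on the superior parent's side) |
| chrVII (~482 kb) | −5 | induced | none |
| chrV (~278 kb) | −3 | induced | functional mitochondria AND hidden induced partner allele (chrXIII) |

Effects are attached to the nearest simulated marker of the matching
class. The conditional locus reproduces the key epistasis phenomenon:
silent in the mutagenized parent (defective mitochondria), expressed in
segregants that regain respiration and co-inherit the partner allele,
and therefore mappable only through the segregant pool. Setting
`mito_prob = 0` masks it entirely — the phenotype distribution is then
identical in law to the model without the locus, which the tests check.

**Pooled reads.** Each pool member contributes equally (the study
equalized cells by OD₆₀₀; no growth-bias model). Depth per marker is
Poisson(mean 40× for pools, 60× for parents); each read reports a
uniformly chosen member's allele flipped with probability 0.005
(symmetric per-read error, no quality-score simulation — synthetic
site qualities are constant and the quality filter is pass-through on
synthetic data). Equivalently the variant count is
Binomial(depth, f(1−e) + (1−f)e).

## Filters and the frequency statistic

Markers need ≥ 25 reads at site quality ≥ 10 (both inclusive). Parent
genotypes are called homozygous when ≥ 90% of reads agree; the 90% rule
applies to parents only — a pooled sample is expected near 50% and
cannot satisfy it. A marker is informative when the parents are called
opposite homozygotes and the marker passes filters in both pools.
Frequency is the exact ratio variant/depth; indels are excluded
(SNP-only marker set). Coordinates are 1-based VCF convention
throughout; I/O is VCF 4.2 with per-sample AD fields, one pseudo-sample
per pool or parent.

## Smoothing

Raw frequencies are smoothed per chromosome with a penalized cubic
B-spline: interior knots at marker-count quantiles, one per 25 markers,
clipped to [8, 40] knots per chromosome (resolution comparable to the
~150–175 kb QTL regions of interest); second-order difference penalty;
observation weights proportional to read depth. The penalty is treated
as a random-effect precision in a linear mixed model and the smoothing
parameter λ is chosen by REML. After Demmler–Reinsch diagonalization
(A = BᵀWB = RᵀR, R⁻ᵀPR⁻¹ = U diag(s) Uᵀ) the criterion minimized over
log λ is

```
(n − p₀)·log RSS_pen(λ) + Σ_{s_i>0} log(1 + λ s_i) − (K − p₀)·log λ,
```

with p₀ = 2 the penalty null-space dimension and
σ̂² = RSS_pen/(n − p₀). This implementation was checked against an
independent REML smoother during development and agrees to ~2×10⁻³
RMS on binomial-noise test data. The pointwise band is the Bayesian
Wald band ±z·SE from σ̂²(A + λP)⁻¹. Fits are clamped to [0,1] after
fitting; the band is clipped and re-bracketed around the estimate.
Chromosomes with fewer than 12 markers fall back to a weighted mean
with a logged warning. Spline fits have inflated variance within a few
knot spacings of chromosome ends; peak positions at the extreme ends of
chromosomes should be read with that in mind.

## QTL calling

A QTL is a maximal run of consecutive markers whose smoothed frequency
exceeds 70% (superior-linked) or falls below 30% (inferior-linked),
spanning ≥ 10 markers; same-direction runs separated by < 5
sub-threshold markers are merged. Calls are ranked by |peak − 50%| and
reported with the random pool's smoothed value at the peak; a call is
flagged *selection-independent* when the random pool also crosses a
threshold there. Thresholds apply to the point estimate, not the band
(the reference analysis states them on the frequency itself); the band
is reported for display. Reported linkage percentages are **peak**
smoothed values (the alternative, region means, is not used; the choice
is deliberate and documented here because published linkage percentages
do not specify it).

### Calibration limits of the 30/70% thresholds

With pools of only 41 segregants the pool allele fraction at any locus
has binomial sd √(0.25/41) ≈ 0.078 *before* sequencing, and this
segregant-sampling noise is spatially correlated over ~½ Morgan
(~125 kb at 0.4 cM/kb). Depth-weighted smoothing removes read noise but
correctly tracks this drift, so the 30/70% thresholds sit only ~2.6
drift-sd from 50% while the genome contains on the order of 100
quasi-independent recombination blocks. A null cross (no causative
loci) therefore typically shows 1–5 drift excursions past the
thresholds per genome; at this pool size the scan over-calls, and the
exact-binomial fine-mapping stage is what separates real loci from
drift. This mirrors the reference analysis itself, where two
inferior-linked regions were discounted on biological grounds and two
more failed the fine-mapping significance line. Users wanting a
calibrated genome-wide scan should increase pool size (drift sd scales
as 1/√n) rather than move the thresholds.

## Fine-mapping

The selected pool is re-thresholded with a stricter cutoff, default
16.3 mg/L — the highest ethyl acetate value measured for the superior
parent. (The reference methods text mentions 16.8 mg/L in one place and
16.3 in another; the package defaults to 16.3 and exposes the cutoff in
config.) Both phenotype cutoffs are strict (<). Marker genotypes of the
refined segregants (scored in up to 15 evenly spaced markers per called
region by default) are tested against 1:1 with the two-sided exact
binomial test using the **minimum-likelihood convention**: p = Σ over
outcomes j with pmf(j) ≤ pmf(k). Conventions for two-sided exact tests
differ, so this is stated explicitly; for p₀ = ½ the tail sum is
computed in exact integer arithmetic (so p(23, 23) = 2⁻²² exactly) and
it is symmetric in k ↔ n−k. Markers with zero scored segregants after
missingness are dropped, not assigned p = 1. No multiple-testing
correction by default (a fixed α = 0.01 line, as in the reference
analysis); a Bonferroni flag is available.

## Segregant-table statistics

Ranking is a stable ascending sort on phenotype mean with ties broken
by id. `crosstab_top(k, loci)` counts, among the k lowest producers,
carriers of the superior allele at *all* listed loci. Group comparisons
use a pooled-variance two-sided Student t-test (Welch by flag) for two
groups and one-way ANOVA with Tukey HSD post-hoc for more; the
two-group path satisfies F = t². `enrichment_test` formalizes the
top-of-table argument as a Fisher exact test on the 2×2 allele ×
below/above-cutoff table; it is an added formalization, not part of the
original analysis. The packaged fixture stores the printed 44-segregant
means and replicate sds verbatim; replicate-level measurements were not
published and are not fabricated.

## What the synthetic tests do and do not show

The simulator reproduces the statistical structure the analysis relies
on — Mendelian 50% expectation, Haldane linkage decay, selection-driven
frequency displacement, depth-limited read sampling, epistatic masking —
so passing tests demonstrate that the pipeline recovers planted loci
under the study's design (386 segregants, 41-segregant pools, 40×).
They do not demonstrate robustness to features of real data that are
deliberately out of scope: alignment and variant-calling artifacts,
repetitive regions and copy-number variation, segregation distortion
from spore-viability selection, growth competition within pools,
indels, or non-uniform recombination (hot/cold spots). Problem sizes in
tests and in `scripts/acceptance.py` are the study's own (20 seeded
replicates of the full design); nothing was scaled down.

## Determinism

Every stochastic stage takes a seed or NumPy `Generator`; the pipeline
derives per-stage substreams from the single config seed via
`SeedSequence.spawn`, so identical seeds give bit-identical segregants,
counts and reports.
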