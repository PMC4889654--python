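# Methods

This note documents the statistical procedures, the synthetic-data model and
its limits, and the numerical choices made where the design was open.

## Filtering cascade

Order matters and is fixed: (1) per-genotype depth mask — genotypes with
DP ≤ 7 become missing (the bound is exclusive: DP > 7 is kept); (2) site
filters — biallelic SNPs only, call rate ≥ 0.80, missing fraction < 0.30,
MAF > 0.05 computed over non-missing calls (both bounds strict where
stated); (3) sample filter — individuals with call rate < 0.80 removed;
(4) site re-filter — sites no longer polymorphic among the kept samples are
dropped. The depth filter masks genotypes rather than dropping sites, so a
site's call rate is re-evaluated after masking; this is one of two
defensible readings of "depth filter" and is the package's choice, applied
consistently. Half-calls (`0/.`) are treated as missing. The site filters
are idempotent (property-tested).

## Diversity statistics

* **π** per non-overlapping window: Σ over SNPs of 2p̂(1−p̂)·n/(n−1)
  divided by window length, with n the site's non-missing allele count —
  the unbiased per-site estimator aggregated per window. Windows are
  half-open on 1-based coordinates (position 1000 falls in the first
  1000-bp window).
* **Tajima's D** per window from the 1989 constants (a₁, a₂, b₁, b₂, c₁,
  c₂, e₁, e₂), with θ̂π the windowed pairwise-diversity sum and θ̂W = S/a₁.
  Genotypes are treated as 2N sequences (random union of gametes); with
  missing data, the constants use the median non-missing allele count over
  the window's segregating sites, which is exact for complete data and a
  documented approximation otherwise. Windows with S = 0 are reported
  undefined; they contribute 0 to the "all windows" average and are
  excluded from the "SNP windows" average — the two averages a windowed
  genome scan typically quotes.
* **HWE** exact test: the probability of each heterozygote count compatible
  with the observed allele counts (same parity) is computed from
  log-factorials; the p-value sums configurations no more probable than the
  observed one (with a 1+1e-12 tolerance against ties lost to rounding).
  Bonferroni and BH flags at 0.05 come from statsmodels.
* **Weir–Cockerham Fst** with the 1984 a/b/c variance components for
  diploids and unequal sample sizes, using per-site non-missing counts.
  Two summaries: mean of per-site a/(a+b+c) over sites with positive
  denominator, and the sample-size-corrected "weighted" form Σa/Σ(a+b+c).
  Pairwise matrices put the mean above and the weighted value below the
  diagonal.

## LD decay

r² is the squared Pearson correlation of unphased ALT dosages over samples
with both genotypes called (genotype r²; the data this pipeline targets are
unphased). Pairs need n_obs ≥ 5; zero-variance pairs are dropped. Pairs are
binned by physical distance with floor(d/width), width 50 bp, half-open
bins, empty bins retained.

The decay curve is a count-weighted loess of bin mean r² on bin midpoint:
tricube kernel over the nearest `span` fraction of bins (default span 0.3),
kernel weights multiplied by per-bin pair counts, **local quadratic** fit.
Degree 2 matters: local linear smoothing of a convex decreasing curve
carries a curvature/boundary bias that flattens the fitted maximum and
inflates the half-decay distance by ~18% on a noiseless exponential at
span 0.3, versus ~4% for the quadratic. r²_max is the maximum of the fitted
curve (a raw-bin-mean option exists), and d_half is the first crossing of
r²_max/2 at or after the argmax, by linear interpolation between grid
points. Two residual biases remain and are accepted: the curve is evaluated
at bin midpoints, so r²_max is read at d = 25 bp rather than 0 (≈ +3–4% on
d_half for a 600–700-bp decay scale), and the sampling floor of r̂²
(≈ 1/n_samples) lifts the far tail. Measured recovery on synthetic panels
(200 haplotypes, 4×10-kb contigs) is within 10–20% of the closed-form
truth; analyses here use span 0.2, appropriate for ~200 bins of 50 bp
against a sub-kilobase decay scale.

Per-population curves rerun the pipeline on each population's sample
subset; populations under 5 samples are skipped with a warning.

## Beta-distribution LD outlier test

Within each distance bin, scaled values ((x−0.5)·θ)+0.5 with θ = 0.999 map
[0,1] into (0,1) without jitter, preserving order and invertibility. A Beta
law is fitted per bin by maximum likelihood (scipy, location 0 / scale 1
fixed), initialized at the method-of-moments estimate and falling back to
it (flagged `converged=False`) if optimization fails. Bins with fewer than
10 pairs are merged with the next bin upward before fitting (Beta MLE is
unstable on tiny samples); a trailing undersized group merges downward.
Each pair's p_raw = 1 − CDF(scaled r²) is evaluated under its own bin's
fit, with the pair's own value included in that fit (no leave-one-out).
BH correction is applied globally across all retained pairs by default —
matching a single genome-wide flagged count — with a per-bin mode
available; flagged means adjusted p ≤ 0.01. Under a true Beta null the raw
tail probabilities are uniform (KS-tested at n = 10⁴) and ~1% fall below
the 0.01 raw threshold.

## Selection screen

The per-SNP scan table (BayeScan `_fst.txt` dialect) is mapped to sites by
row order; a row-count mismatch is a hard error rather than a silent
reindex. The top fraction keeps SNPs with alpha ≥ the k-th largest value,
k = ⌈fraction·m⌉, ties at the cutoff all included; ranking uses signed
alpha by default (absolute-value mode available). Candidates are top-ranked
SNPs belonging to ≥ 1 flagged pair, annotated with their smallest-p_adj
partner. Gene proximity uses the signed gap between the SNP position and
the gene interval — 0 inside the gene, positive if the gene starts
downstream, negative if it ends upstream — inclusive at exactly the window
width (default 1000 bp); strand never affects distance. Shared outliers
intersect labelled candidate sets by scaffold:position.

## Synthetic-data model

The generator exists to give every downstream stage a known truth, not to
model any real population.

* **LD**: each haplotype carries a latent uniform along the contig,
  retained from the previous site with probability ρ^d (ρ =
  `retention_per_bp`, d = inter-site gap) and redrawn otherwise; the allele
  is the indicator u < p_site. Sites sharing the uniform are comonotone, so
  at frequency-0.5 sites E[r²](d) = ρ^{2d} and the half-decay distance is
  exactly ln 2 / (2 ln(1/ρ)) — e.g. ρ = 0.99943 → ≈ 608 bp. Persisting the
  *generating uniform* rather than the allele is essential: copying alleles
  directly makes each site's marginal frequency a smoothed average of its
  neighbours' population frequencies, which collapses between-population
  differentiation (measured Fst fell from a 0.2 target to ~0.007 under the
  allele-copying variant). At unequal site frequencies the comonotone
  coupling bounds r² below 1, so realized r²_max is well under 1 —
  mirroring the frequency-dependence of r² in real data.
* **Structure**: Balding–Nichols — per-population frequencies drawn
  Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral frequencies that are
  uniform on a MAF-respecting band; measured weighted Weir–Cockerham Fst at
  F = 0.2, 5000 sites, 50 diploids per population lands within 0.02.
* **Planted signals**: spiked pairs duplicate a mid-frequency donor's
  alleles onto a site 2–8 kb away with 1% independent flips — near-1 r² at
  a distance where background LD has decayed, i.e. genuinely
  distance-abnormal LD (a duplicate at an adjacent site would be
  indistinguishable from background and is correctly not flagged).
  Mid-frequency donors (0.15–0.85) ensure planted pairs survive the MAF
  filter. Spiked differentiation sites get near-fixed opposite frequencies
  in alternating populations. Both kinds receive top-rank alphas in the
  mock scan table, and one gene is planted 300 bp downstream of every
  spiked site.
* **Nuisance**: depth ~ Poisson(depth_mean, default 40×) written for every
  genotype including those the DP filter must remove; missingness is
  i.i.d. Bernoulli; genotypes pair haplotypes 2i, 2i+1.

What the generator does **not** emulate: demographic history, recombination
hotspots, sequencing error, allele dropout typical of ddRAD, multi-allelic
sites and indels, or linked selection. Passing tests therefore demonstrate
the estimators' correctness and calibration under a clean, analytically
tractable null — not robustness to every artifact of real libraries.

Determinism: all stages are seeded; the same seed and configuration produce
byte-identical output trees (tested). Substreams are derived from the root
seed per stage (positions/frequencies, structure, spiking, emission), so
changing one stage's draws does not perturb the others.

## Default parameters

| parameter | default | unit | note |
|---|---|---|---|
| min_genotype_depth | 7 | reads | exclusive (DP > 7 kept) |
| max_site_missing_frac | 0.30 | fraction | strict (< 0.30) |
| min_site_call_rate / min_sample_call_rate | 0.80 | fraction | inclusive |
| maf_min | 0.05 | frequency | exclusive (MAF > 0.05) |
| LD bin width | 50 | bp | |
| loess span / degree | 0.3 / 2 | — | span 0.2 used in the bundled analyses |
| θ (scaling) | 0.999 | — | |
| outlier alpha | 0.01 | — | BH-adjusted, global scope |
| min bin occupancy | 10 | pairs | merged upward |
| top alpha fraction | 0.10 | — | 0.05 also supported |
| gene window | 1000 | bp | inclusive boundary |
| Tajima/π window | 1000 | bp | 5000 bp for WGS-style runs |
| retention_per_bp | 0.99943 | per bp | true d_half ≈ 608 bp |
| fst_target | 0.10 | — | generator default |

## Problem sizes used in the bundled analyses

The test suite and `scripts/acceptance.py` run the decay analysis on one
population of 100 diploids (200 haplotypes) over four 10-kb contigs
(~780 sites, ~75k pairs), Fst calibration on 2×50 diploids at ~5000 sites,
the Beta-null calibration at 10⁴ pairs, and the end-to-end screen on the
generator's default cohort (3×18 diploids). These sizes keep every
quantity's Monte-Carlo error comfortably inside the tolerances asserted in
the tests while the whole suite runs in well under a minute.

## Known limitations

* d_half carries the +3–20% upward bias discussed above at these problem
  sizes; it shrinks with narrower bins, smaller span, and more samples.
* Tajima's D windowed averages depend on how undefined windows are treated;
  both conventions are reported, and the choice is the caller's.
* The Beta fit includes each pair's own value (no leave-one-out), slightly
  conservative for small bins.
* The HWE test assumes a single panmictic sample per test; applying it
  across structured cohorts detects the Wahlund effect, not genotyping
  error — per-population application is the caller's responsibility.
* The EM haplotype-frequency r² (`pairwise_r2(..., method="em")`) assumes
  HWE when resolving double-heterozygote phase; genotype r² (the default)
  makes no phase assumption and is the estimator used throughout the
  bundled analyses.
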