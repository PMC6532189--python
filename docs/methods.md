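# Methods

`spec2gwas` implements a phenotyping-to-association pipeline for seed
biochemical traits: raw spectroradiometer frames are calibrated to
reflectance, an exhaustive two-band index search extracts a spectral proxy
for the measured trait, and both the proxy and the measured trait are
scanned with a Q+K mixed linear model. A synthetic-data module generates
genotypes, traits and raw spectra with planted ground truth so that every
stage is testable without external data. This note records the models,
the parameter choices, and the limits of what the synthetic experiments
demonstrate.

## Reflectance calibration and preprocessing

Raw intensity is converted to reflectance band-by-band with the
white-reference/dark-current formula

    I_cal = (I_raw − I_dark) / (I_white − I_dark),

with the dark current treated as a per-band vector (modern instruments
report banded dark). Bands below 400 nm and above 2450 nm are trimmed
(low signal-to-noise at the grid edges), and the instrument's three
automatic repeats per sample are averaged arithmetically. Calibration,
trimming and replicate averaging commute, so their order does not affect
results; the pipeline uses calibrate → trim → average. Calibrated
reflectance slightly above 1 is allowed (real instruments overshoot on
bright targets); |I_cal| > 10 is rejected as a frame mix-up.

## Trait screening

Each trait is summarized by min/max/mean/SD and the coefficient of
variation CV = SD/mean. Following the study design this emulates, the CV
flag (≥ 0.15, applied to the value rounded to two decimals, so a raw CV
of 0.1486 is flagged) is advisory; the hard gate is distributional: a
Shapiro–Wilk test at α = 0.05 (the standard small-n choice; the screening
rule itself does not name a test). A trait that fails normality is
excluded; a trait whose best spectral index explains less than R² = 0.6
stays at the correlation stage and is not scanned.

## Two-band index search

Three index families are evaluated at every admissible wavelength pair of
the trimmed grid: SRI = R_a/R_b, NDSI = (R_a−R_b)/(R_a+R_b), and
DSI = R_a−R_b. NDSI and DSI only change sign under pair exchange, so they
are searched over unordered pairs in the canonical form λ_a > λ_b; SRI is
not correlation-invariant under inversion and is searched in both orders.
Each candidate is scored by the squared Pearson correlation with the
trait (pairwise-complete over samples where a division guard produced a
missing value); the family+pair with the highest R² becomes the
"hyperspectral trait". Ties break deterministically: smaller λ_b, then
smaller λ_a, then family order NDSI, DSI, SRI. The scan is vectorized
per-λ_a (about 2.1 M pairs on the 2051-band 1 nm grid, a few seconds per
family on one core) and is verified exactly against a naive triple-loop
reference on small grids. A `stride` option coarsens the grid for quick
runs; the full R² surface can be retained on request.

## Genotypes and population structure

* **Variant filtration.** Three positional rules, evaluated simultaneously
  on the original set with the union of removals applied: SNP pairs at
  distance ≤ 5 bp (both removed); SNPs within ≤ 5 bp of an indel (the SNP
  removed, the indel kept — the rule screens SNPs, not indels); indel
  pairs at distance < 10 bp (both removed). The deliberate asymmetry
  between "≤ 5" and "< 10" follows the stated filtering protocol to the
  letter. The filter is idempotent.
* **MAF screen.** Markers with minor-allele frequency below 0.05
  (computed on non-missing calls; threshold inclusive) are dropped.
* **Kinship.** VanRaden-style centered cross-product of per-marker
  standardized dosages, K = ZZᵀ/m, after mean imputation; the estimator is
  tagged in the output and pluggable. This is the standard G-matrix for
  mixed-model association.
* **Structure covariates.** Top-q principal components of the same
  standardized dosage matrix (default q = k−1 for k assumed
  subpopulations), with a deterministic sign convention (largest-|loading|
  element positive). A user-supplied ancestry-fraction table may be used
  instead.
* **LD decay.** r² is the squared Pearson correlation of dosage vectors
  for same-chromosome pairs within a 1000 kb window; the decay curve is
  the mean r² per distance bin (5 kb default), smoothed by a 5-bin running
  median. LD50 is the smallest bin center at which the smoothed curve
  falls to half its global maximum. Finer bins (2 kb) are used in the
  recovery experiments because the bin-center convention quantizes the
  estimate.
* **NJ tree.** p-distance = fraction of mutually called markers whose
  dosages differ (no phasing assumed); neighbor-joining agglomeration;
  bootstrap over marker columns with support per internal bipartition.

## The mixed linear model

For each marker x the association model is

    y = xα + Qβ + u + e,  u ~ N(0, σ²g K),  e ~ N(0, σ²e I).

Variance components are profiled by REML over δ = σ²e/σ²g in the
eigenbasis of K (K rescaled to mean diagonal 1; eigenvalues clipped at 0;
grid scan over log δ ∈ [−10, 10] followed by bounded Brent refinement,
tolerance 1e-6). The default scan fixes δ from the null (no-marker) fit
for every marker — the P3D/EMMAX strategy — and tests each marker by
generalized least squares via a weighted Frisch–Waugh projection, fully
vectorized across markers; `mode="exact"` re-estimates δ per marker. The
Wald statistic uses the Gaussian reference by default (the large-panel
mixed-model convention; in our calibration experiments it is also the
best-calibrated choice once variance-component estimation noise is
accounted for), with `use_t=True` available for small panels. With
K = identity the REML profile over δ is flat — this is detected and
flagged — and the scan reduces exactly to OLS, which the tests verify to
1e-10.

P3D agrees closely with per-marker REML for polygenic signals (median
deviation in −log10 p under 10% in our tests) but is conservative at a
marker that carries a visible share of the heritability, because the null
fit absorbs that marker's effect into σ²g; this known EMMAX property is
measured, not hidden, by the test suite. A leave-one-chromosome-out
(LOCO) option rebuilds K and the null fit per chromosome from the other
chromosomes, removing the tested markers' own contribution to the random
effect; the scan default is no LOCO, but the end-to-end pipeline enables
it, because with two strong causal loci at n = 80 proximal contamination
otherwise leaves lead p-values hovering at the Bonferroni line.

Genome-wide thresholds are Bonferroni: significant P = 0.01/n and
suggestive P = 0.1/n with n the number of markers tested (an effective
marker count may be supplied; no attempt is made to estimate one). Locus
intervals around each significant lead marker (visited in order of
increasing p) cover every marker within the window with r² ≥ 0.6 to the
lead; overlapping intervals merge. QQ diagnostics report the genomic
inflation factor λ = median(χ²₁)/0.4549.

## Gene lookup and trait comparison

Genes overlap a locus interval if their 1-based inclusive spans share at
least 1 bp (abutting is not overlap; no promoter extension). Two scans
from the same marker panel are compared by significant SNP positions and
by located gene ids, yielding Venn counts and a superset verdict
("does the proxy trait cover everything the measured trait found?").
Database-backed functional annotation is out of scope; gene models come
from a user-supplied GFF3/BED file (or the synthetic gene-model builder).

## The synthetic data model

Every generator is a pure function of (configuration, seed).

* **Genotypes** follow a Balding–Nichols model: ancestral frequency
  p ~ Uniform(maf_low, maf_high); subpopulation frequency
  ~ Beta(p(1−F)/F, (1−p)(1−F)/F); genotypes Binomial(2, p_subpop);
  2000 SNPs uniformly spaced over 12 chromosomes, 80 samples in 6
  subpopulations, F = 0.2 by default. This reproduces tunable realized
  Fst (checked against a Hudson-estimator oracle) and realistic PCA/
  kinship structure.
* **Trait**: y = Σ g_i b_i + e with Normal effect draws rescaled so the
  genetic share of variance equals h², then affinely rescaled to mean
  8.62 and SD 0.77 (the seed protein-content moments in percent that the
  pipeline emulates; the affine map preserves h² exactly). Defaults plant
  2 causal loci at h² = 0.7 among markers with realized MAF ≥ 0.2 —
  strong, common loci, consistent with a study in which the lead
  associations reach p ≈ 1e-12…1e-34 at n = 80. Because the emulated
  study only admits traits that pass the normality screen, the generator
  redraws the effect/noise vectors (up to 50 attempts) until Shapiro–Wilk
  accepts the trait; `require_normal_trait=False` disables this.
* **Spectra**: true reflectance = smooth baseline (wide Gaussians plus
  trait-independent water-absorption dips at 1450/1940 nm), modulated per
  sample by a multiplicative scale, a tilt, and two Gaussian-process-like
  deviation fields (rough, length 14 nm; mid-scale, length 45 nm), minus
  an absorption Gaussian at λ_a = 1227 nm (σ = 18 nm) whose depth is
  affine in the standardized trait. Raw frames are constructed as
  I_raw = I_dark + (R_true + noise)·(I_white − I_dark) over three
  replicates, so calibration inverts the construction exactly in the
  noiseless case. All noise sources are shaped by a wavelength-dependent
  envelope: noisy near the water bands, the grid edges and the detector
  junction around 1090 nm, and *quiet* in two narrow instrument windows
  centered on the planted pair (1227, 1177) nm. The envelope is what
  makes the planted pair the unique population-level optimum of the index
  search: without it, dip-flank pairs, the mirror-image reference near
  1277 nm, or arbitrary distant references score equally well, and the
  recovered pair would be an arbitrary member of a near-tie set. The
  deviation amplitudes were chosen once, by a small numerical design
  study balancing flank cancellation against reference-distance penalties,
  and then frozen.
* **Filter fixture**: a variant table with planted rule violations (SNP
  clusters at 3 and 5 bp, SNPs 2 and 5 bp from indels, an indel pair at
  9 bp) and boundary survivors (6 bp SNP pair, 10 bp indel pair), with the
  expected removal set recorded as truth.
* **LD panel**: haplotypes from a Markov copying chain with per-step copy
  probability exp(−ln2·Δ/(2·LD50)), so dosage r² decays as
  exp(−ln2·d/LD50) and the planted half-distance is exact in expectation.

**What passing these tests does and does not show.** The synthetic spectra
are engineered so the planted band pair is identifiable — real seed
spectra need not put their information in a unique pair, real replicate
noise is not white, and real baselines vary with grain packing in ways no
two-scale field captures. Recovery therefore demonstrates that the search
and the pipeline are correct, not that two bands suffice for any real
trait. Similarly, the Balding–Nichols panel has no linkage disequilibrium
between markers (each marker is drawn independently), so locus intervals
on it are typically single markers; the LD-decay experiments use the
separate Markov-chain panel.

## Experiment sizes

The acceptance experiments are sized for a single core: structured-null
calibration uses 8–12 replicates of an n = 200, 2000-marker panel;
heritability recovery uses n = 300 with 1500 markers on a family-like
panel (30 subpopulations at F = 0.5 — many small related groups give REML
enough contrasts for a ±0.15 recovery; a panel of near-unrelated samples
at n = 300 cannot estimate h² that precisely); power uses 8–10 replicates
at n = 300 with a single causal marker explaining ≈20% of variance; the
end-to-end run uses the full default configuration including the complete
1 nm index search.

## Known limitations

* The exhaustive search is O(B²·n) in time; the optional full surface is
  O(B²) in memory (~34 MB at 2051 bands) and off by default.
* The mixed model assumes a single Gaussian random effect; dominance,
  epistasis and multi-trait models are out of scope, as are FDR
  procedures (Bonferroni only).
* p-values for markers collinear with the covariates are reported missing
  rather than dropped silently.
* The Gaussian Wald reference is slightly anticonservative in very small
  panels; `use_t=True` gives the exact-OLS small-sample behavior.
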