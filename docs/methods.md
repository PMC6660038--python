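# Methods

`wrinkleqtl` re-creates, end to end on synthetic data, the analysis chain of
a facial-wrinkle QTL mapping study in a Chinese indigenous pig herd: genotype
quality control, GRM-based heritability, mixed-model association scans for
two correlated wrinkle phenotypes, a two-trait meta-analysis, an LD-aware
gene-based test, sliding-window selection statistics contrasting the domestic
herd against wild boars, and bootstrap neighbor-joining trees of the swept
haplotypes.  This note records the models, the calibration of the simulator,
and the numerical choices made where the design was genuinely open.

## The synthetic herd

No genotype data are bundled; every analysis runs on the output of
`wrinkleqtl.simdata`, which emulates the study design the pipeline targets:

* **332 domestic pigs** (168 castrated males, 164 females) and **21 wild
  boars**, genotyped on a medium-density chip;
* a **6 Mb focal segment** standing in for SSC7 32–38 Mb, carrying a selective
  sweep at position 34,835,986 (the top-SNP position, offset 2,835,986 within
  the segment), plus **three neutral 6 Mb background chromosomes**;
* two wrinkle phenotypes — *wrinkle pixel ratio* (`wpr`) and *wrinkle score*
  (`score`) — with a shared major QTL at the swept SNP and a polygenic
  background.

### Founders: block coalescent

Each chromosome is cut into 50 kb blocks.  Within a block, founder haplotypes
(2 × 500) are drawn from a single-population Kingman coalescent without
recombination: exponential waiting times between coalescences, mutations
Poisson on the genealogy under infinite sites.  The per-block mutation rate
is calibrated so the expected number of segregating sites per chromosome
equals `target_snp_count` (3,000).  Within a block this yields the neutral
site-frequency spectrum (counts ∝ 1/i) and coalescent LD; LD decays across
block boundaries because blocks are independent.  Blocks are a deliberate
simplification — the package needs genuine haplotype structure for EHH-type
statistics, not a demographically calibrated pig genome (see Limitations).

### Forward phase: Wright–Fisher with selection, recombination and mutation

The founder pool is copied into a domestic and a wild population (500
diploids each) which then evolve independently for `split_generations` (60)
generations of random mating.  Each generation one set of diploid parents is
drawn for the whole genome; chromosomes assort independently and recombine
uniformly at 1 cM/Mb.  New mutations enter at the rate implied by the founder
theta (θ/4N per gamete per chromosome), which keeps the site-frequency
spectrum at mutation–drift equilibrium — without this influx the forward
phase bleeds rare variants and Tajima's D drifts strongly positive even
without selection.  Sites born in one population are private to it (zero
columns in the other), as in real data.

**The sweep.**  In the domestic population only, genic selection
(fitness 1, 1+s, (1+s)² with s = 0.1) acts on a favored allele ("G") planted
at the focal position at initial frequency 0.05.  The allele is modelled as a
*single recent mutation* that drifted to 5%: all carriers descend from one
founder haplotype, so each carrier's local background is copied from a
template over an exponential IBD tract (mean 2 Mb per side, ≈ 1/(rT) for an
allele on the order of fifty generations old at 1 cM/Mb).  Without this
shared descent the allele would sit on ~50 unrelated haplotypes and sweep
softly, leaving no haplotype signature; with it, 60 generations of s = 0.1
carry the allele to a mean frequency ≈ 0.9 (deterministic logistic 0.94) and
produce the full hard-sweep signature at the focal window: Tajima's D ≤ −1
in the domestic sample but not the wild one, elevated window FST, large
standardized XPEHH, and favored-allele haplotypes collapsing into one NJ
clade.  If the favored allele is lost the simulation retries with a fresh
stream (cap 20), then fails loudly.

**Why background chromosomes.**  The GRM of the real study is genome-wide;
a GRM built only from the sweep segment is dominated by sweep-induced local
relatedness, and the polygenic model then absorbs the QTL (no association
power, deflated heritability, miscalibrated λ).  Three neutral chromosomes
put the focal segment at ~25% of the GRM — far more than the real ~0.2%, but
enough to restore calibration (null λ ≈ 0.95–1.05) at an affordable cost.

### Phenotypes

For each trait, with σ the trait's target SD and g the focal-SNP dosage:

    y = μ + sex + batch + a·(g − ḡ) + u + e
    a chosen so Var(a·g) = q σ²    (q = QTL variance fraction)
    u ~ N(0, K (h² − q) σ²),  e ~ N(0, I (1 − h²) σ²)

K is the standardized GRM of the sample's *common* variants (MAF ≥ 1%),
rescaled to unit mean diagonal — the same variant class the analysis GRM
uses, so the fitted heritability estimates the simulated one.  Calibration:
`wpr` mean 0.09, SD 0.027, h² 0.681, q 0.218; `score` mean 3.20, SD 1.04,
h² 0.737, q 0.313; both QTL effects positive on the favored G dosage
(negative per A allele).  Sex effects (+0.01 / +0.29 in females) and two
batches with small effects (±5% of an SD) enter as fixed effects.  The
polygenic and residual draws of the two traits share one cross-trait
correlation ρ solved so the total phenotypic correlation equals 0.777 given
the QTL and fixed-effect contributions; an infeasible target raises an error.

### What the generator does not emulate

Chip ascertainment bias (sites are drawn from the neutral SFS, then
MAF-filtered by QC), genotyping error and missingness (none by default; the
QC paths are exercised with synthetic defects in the tests), a real pig
recombination map, the 9-sire/52-dam pedigree (relatedness arises from the
small forward-phase population instead), X-chromosome transmission (the
X-male coding is tested on constructed data), and sequence-level (WGS) data.
Passing tests therefore show the *methods* are implemented correctly and
recover what this generator plants — not that the pipeline is robust to chip
artifacts or demographic confounding in real herds.

## Analysis chain

**QC** (`genio`): SNPs with call rate < 90% are removed, then SNPs with
MAF < 1% (computed over non-missing calls), then individuals with
missingness > 10% — strict inequalities, in that fixed order (the order
changes the counts, so it is pinned and reported).  Mendelian-error filtering
is not applied: no pedigree is modelled; the report records this.  Male
X-chromosome heterozygous calls are genotyping anomalies and are set to
missing (counted); valid male X calls keep the homozygous 0/2 coding.

**Heritability** (`polygenic`): standardized GRM
z = (g − 2p)/√(2p(1−p)), K = ZZᵀ/m, with mean substitution for missing
dosages (configurable to pairwise-complete).  The single-component animal
model y = Xβ + g + e, Var = K·VA + I·VR, is fitted by maximum likelihood
(matching the GenABEL `polygenic` default; REML behind a flag): on the
eigenbasis of K the fixed effects and total variance are profiled in closed
form, leaving a 1-D search over h² ∈ [0, 0.999] (41-point grid bracket, then
bounded Brent to 10⁻⁶; the upper bound keeps Σ invertible).  The reported
log-likelihood is the standard Gaussian form −½[log|Σ| + rᵀΣ⁻¹r + n log 2π];
maximizing the *positive* of the bracketed expression would be degenerate.

**Association** (`gwas`): GRAMMAR/mmscore two-stage scan — the polygenic
model is fitted once; each SNP is score-tested against the GLS residuals
with W = Σ̂⁻¹ (applied through the stored eigendecomposition):
U = g̃ᵀWr, V = g̃ᵀWg̃, z = U/√V, with g̃ centered on its W-weighted mean and
effect = U/V.  Per-SNP exact mixed-model refits are out of scope and would
differ slightly.  Individuals missing a SNP are dropped for that SNP (the
covariance is re-inverted on the sub-block); SNPs with one genotype class
are emitted flagged with p = 1, never silently skipped.  Thresholds are
Bonferroni 0.05/N and suggestive 1/N.  λ is median(z²)/0.4549 (the estimator
is not uniquely defined elsewhere; the median form is robust and standard).
The top-locus confidence interval takes the contiguous run of SNPs within 2
units of −log₁₀(p) of the peak ("2-LOD": for 1-df tests LOD and −log₁₀ p
coincide up to a near-unity factor); ties break to the smallest position.
Variance explained by the top SNP uses the three-OLS-model mean-square
formula var% = (MS_sex+batch − MS_full)/MS_mean-only × 100 with
MS = SS_resid/(n − p) — residual degrees of freedom, since the denominator
convention changes the value and is otherwise unspecified.

**Meta-analysis** (`meta`): per SNP, χ² = tᵀV⁻¹t with t the two signed
statistics and V the 2×2 correlation matrix of the signed statistics over
all scanned SNPs (phenotypic correlation available as an option); the 2-df
tail is exp(−χ²/2).  At n = 332 the t-versus-normal distinction is
negligible, so the mmscore z-scores serve as the signed statistics.  A
degenerate V (|r| ≥ 1) is clamped to 0.999 with a warning.

**Gene test** (`genetest`): BED genes (0-based half-open, converted to
1-based inclusive) collect the SNPs inside their body — no flanking window.
T = Σz² has null distribution Σλᵢχ²₁ with λ the eigenvalues of the gene's
genotype-correlation matrix (ridge 10⁻⁶); the tail uses Satterthwaite moment
matching (scale Σλ²/Σλ, df (Σλ)²/Σλ²), with a Monte-Carlo exact tail behind
a flag for small p.  This is a principled stand-in for what "taking LD into
account" minimally requires, not a reproduction of MAGMA's internals, so the
study's top-gene lists are not reproduction targets.

**Selection scans** (`selscan`): 200 kb windows advancing by 100 kb; windows
with < 5 SNPs are masked (reported absent, not zero, to keep coordinates
aligned).  Tajima's D follows the 1989 constants with n = number of
sequences (2 × individuals for unphased input, π from allele frequencies
with the n/(n−1) factor); D is undefined (absent) when no site segregates.
FST is the Weir–Cockerham (1984) per-SNP θ̂ averaged within the window
(ratio-of-sums offered as an option); the window mean is restricted to SNPs
with pooled MAF ≥ 5% — a chip-like common-variant set — because the per-SNP
estimator is extremely noisy on the many population-private rare variants
the simulator produces, and their near-zero values swamp the mean.  Small
negative θ̂ values are legal and preserved.  XPEHH integrates EHH (pairwise
haplotype homozygosity extending from the core) by trapezoid over physical
distance — no genetic map is shipped — stopping where the pooled-sample EHH
drops below 0.05 or at a 500 kb cap; the bounds come from the pooled sample,
which makes raw XPEHH = ln(iHH₁/iHH₂) exactly antisymmetric under swapping
populations.  Scores are z-standardized genome-wide (raw scores are also
emitted; whether the study standardized is unstated).

**Haplotype trees** (`haplo`): the target region is phased by
partition-ligation EM (blocks ≤ 6 SNPs, exhaustive haplotype enumeration,
EM to 10⁻⁶ with 5 random restarts, top-8 haplotypes retained per ligation),
or taken from the simulator's truth phase / an external phased VCF, so the
trees do not depend on the EM stand-in's accuracy — Bayesian coalescent
phasing is deliberately not reimplemented.  Unique haplotypes (with
multiplicities — whether the study deduplicated is unstated, and
multiplicities preserve the information) are compared by Hamming distance
and joined by Saitou–Nei NJ with deterministic first-minimum tie-breaks;
negative branch lengths are clamped to zero and counted.  Bootstrap support
per internal edge is the bipartition frequency over SNP-column resamples
(default 1,000; 100 in the desk profile).  Newick is written with supports
as internal labels; serialization round-trips through scikit-bio.

**Phenotype tools** (`phenotools`): the pixel ratio is traced-wrinkle pixels
over facial-contour pixels (the manual tracing protocol itself is not
automated); the consensus score accepts the mean of three scores on the
1–5 half-point grid when their range is ≤ 1 and flags the sample for
rescoring otherwise.  The sex comparison uses a Welch t-test — the study
does not name its test, so these P-values are descriptive only.

**Pipeline** (`cli`): subcommands per stage plus `run`, driven by a
schema-validated YAML config (unknown keys rejected).  Each run writes TSV/
JSON outputs and a manifest (seed, input checksums, per-stage wall time);
identical config + seed reproduces outputs byte for byte.  The `desk`
profile scales the bootstrap count to 100 and strides XPEHH cores (every
10th SNP) for quick runs.

## Problem sizes in tests and the acceptance script

Replicated calibration checks run the full study-scale herd (n = 332,
four chromosomes, ~23k sites): 20 replicates for heritability and trait
correlation, 50 for the variance-explained formula, 10 for the windowed
Tajima's D median, one scan each for the sweep-signature and null-calibration
checks (XPEHH at every 10th core).  Unit tests use a scaled herd (n = 60,
two chromosomes, ~1.2k sites).  These sizes are the package's chosen
trade-off between statistical resolution and runtime.

## Known limitations

* Drift at N = 500 over 60 generations exceeds a real conserved herd's;
  final sweep frequency varies (≈ 0.8–0.98 across seeds), so single-run
  window statistics vary more than replicate medians.
* GREML heritability on these herds carries a small upward bias (~0.02–0.03)
  from sweep-aligned family structure; the calibration tolerance absorbs it.
* The gene test's Satterthwaite tail is approximate in the far tail; the
  Monte-Carlo option exists for small p but is not the default.
* mmscore power is mildly attenuated when the causal SNP's region
  contributes to the GRM (no leave-one-chromosome-out correction, matching
  the original tooling).
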