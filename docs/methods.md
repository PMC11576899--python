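# Methods

## The covA statistic

`ancestra` quantifies the relative genetic similarity of a contemporary
individual *i* to each of several ancestral populations *p* (by default the
three main ancestral components of modern Europeans: Western
Hunter-Gatherers, WHG; Early European Farmers, EEF; Steppe Bronze Age,
SBA). Over a locus set *S*,

    covA(i, p) = (1/|S|) * Σ_{l∈S} (x_il − f̄_l)(f_pl − ḡ_l)

where `x_il` is the individual's allele dosage divided by two, `f̄_l` the
cohort mean of `x` at locus *l*, `f_pl` the effect-allele frequency of the
reference panel for ancestry *p*, and `ḡ_l` the unweighted mean of `f_pl`
across ancestries. Centering the panel term on the cross-ancestry mean makes
the statistic *relative*: Σ_p covA(i, p) = 0 for every individual, so with
three ancestries only two degrees of freedom exist and regression models may
include at most two covA terms as covariates. Division by |S| puts
genome-wide covA (*GW-covA*, all variants) and region-restricted covA
(*TAGR-covA*, variants inside trait-associated genomic regions) on a common
scale; since columns are standardized across individuals before regression,
the constant factor is immaterial. Missing modern dosages are skipped per
individual with renormalization by that individual's observed locus count
rather than imputed. Reference frequencies with fewer than `min_calls` (= 10)
non-missing diploid calls in any ancestry are masked at that locus for all
ancestries.

The exact algebraic form of the statistic is a design choice of this
package: the defining contracts are the sum-to-zero identity, invariance
under allele-label flips (both centered factors negate), and equality with a
literal per-locus loop (all property-tested).

TAGRs are built by centering a 20 kb window (configurable) on each 1-based
hit position, converting to 0-based half-open coordinates, clipping at zero
and merging overlapping or book-ended windows.

## Association models

For each trait *t* and ancestry *p* the model is

    t_i = β0 + β_covA(p)·covA(i, p) + β_c·c_i + ε_i

fit by OLS for continuous traits (the reported effect is the slope on the
standardized covA), by maximum-likelihood logistic regression for binary
traits and by proportional-odds (logit link) ordinal regression for ordered
categories (effect = odds ratio, Wald two-sided p in all cases). When covA
is TAGR-restricted, two genome-wide covA columns (default WHG and EEF — any
pair spans the two degrees of freedom) should be included among the
covariates to absorb genome-wide structure. Multiple testing across traits
and ancestries is controlled by Benjamini–Hochberg step-up FDR at q = 0.05.

Continuous traits are preprocessed in a fixed order: optional log transform,
optional residualization on an adjustment covariate (e.g. BMI), removal of
values more than 4 inter-quartile ranges outside the quartiles, then
standardization to mean 0 / SD 1.

Sibships are connected components of kinship pairs with coefficient in
[0.177, 0.354] flagged as full siblings; any component whose members are not
all pairwise full siblings is dropped entirely. The within-sibship model
decomposes covA into the sibship mean covA_sib and the individual deviation
covA′ = covA − covA_sib (the two summing back exactly) and reports the
coefficient on covA′, which is immune to confounders constant within a
sibship — the classic defense against environmental stratification that
tracks ancestry.

## The simulator

The generator emulates the study conditions: three ancestral populations
diverging under Gaussian stabilizing selection on an additive polygenic
trait, admixing into a present-day cohort with ~12% WHG-like contribution.

**Hybrid scheme.** Founder diversity for each unlinked interval comes from a
neutral msprime coalescent of a single ancestral population at
mutation–drift equilibrium (binary mutation model, so sites stay
biallelic); both daughter branches at the deepest split draw their founders
from that pool. From the deepest split a numpy forward Wright–Fisher phase
takes over: fitness-proportional parent sampling, independent assortment
across intervals, Poisson crossovers within intervals, and pedigree
recording for the final generations. Local ancestry is tracked per allele
copy at each interval's focal SNP and assigned at the admixture pulses.

**Demography (defaults, configurable).** One ancestral population of
Ne = 10,000; the WHG-like branch splits 800 generations ago; the remaining
lineage splits into EEF- and SBA-like branches 500 generations ago. The
present-day lineage starts as the WHG branch and receives an EEF pulse of
proportion 0.75 at 200 generations and an SBA pulse of 0.52 at 150
generations, giving an expected final composition WHG 0.25 × 0.48 = 0.12,
EEF 0.36, SBA 0.52 — the broad-brush post-glacial history of Britain
(large Neolithic farmer turnover followed by a majority steppe-related
turnover). Expected fractions follow in closed form by multiplying the
surviving proportions of successive pulses. Reference panels (100
individuals per ancestry) are frozen one generation before the first pulse
affecting each branch, mimicking pre-admixture ancient samples.

**Trait, fitness and effect sizes.** Each segregating interval carries one
focal SNP (the most central common variant, founder MAF ≥ 0.01); a
configurable number are causal with effects β_l ~ N(0, 1), rescaled once at
the deepest split so founder Var(GV) = h². Environmental noise is drawn
each generation with variance Var(GV)(1 − h²)/h², keeping realized
heritability at h² (initial trait variance is therefore 1, so trait optima
and the fitness SD ω are in initial-trait-SD units). Fitness is
w = exp(−(t − optimum)²/2ω²); `selection_mode` applies it to the branch
populations (`pre_admixture`, with per-ancestry optima and optimum 0 in the
unsplit EEF/SBA ancestor), to the present-day lineage only
(`post_admixture`), or nowhere (`none`, also triggered by ω = ∞).

**Rescaling.** `SimScenario.scaled(c)` divides Ne, event times and the
cohort size by *c*, multiplies mutation and recombination rates by *c*, and
divides ω² by *c*, preserving drift and selection per scaled generation
(standard population-genetic rescaling). Panel sizes are sample sizes, not
effective sizes, and are kept at 100. Two profiles are used throughout:
`reduced()` (100 × 5 kb intervals, c = 10: Ne 1,000, cohort 1,000) for the
acceptance protocols and `test_scale()` (c = 20) for unit-level runs. Power
quantities that depend on absolute sample and locus counts (e.g.
true-positive rates) are attenuated at reduced scale; the tests account for
this with binomial-error bands at the reduced replicate counts.

**GWAS-like ascertainment.** A causal SNP is "discovered" when its explained
trait-variance fraction 2f(1−f)β²/Var(t) reaches τ. The default
τ = 0.5·h²/n_causal (half the mean per-locus fraction) retains 393 of 1,000
loci on the neutral full-scale founder spectrum, inside the 351–565 range
the full protocol produces.

**What the generator does not emulate.** Chromosome-scale linkage and LD
between trait loci, non-additive architectures, assortative mating,
sample-selection and measurement artifacts of real biobanks, and aDNA
missingness/damage in the reference panels. Passing tests therefore
demonstrate the statistical behavior of the method under the stated model,
not robustness to these real-data features.

## Evaluation protocol

Per replicate: simulate → ascertain causal SNPs → build TAGRs spanning the
ascertained intervals → compute standardized covA of the cohort against the
reference panels → regress the raw simulated trait on each ancestry's covA
with no covariates. Reference populations are ranked by mean genetic value
(ties broken by the fixed label order WHG, EEF, SBA and flagged);
differentiation is ΔGV = (highest − second highest mean GV)/trait SD.
True-positive rate per ΔGV bin (default edges 0, 0.1, 0.25, 0.5, 1, ∞) is
the fraction of replicates where argmax_p |β_covA(p)| is the top-GV ancestry
— of the reference panels, or of the present-day local ancestries, whose GV
is 2·Σ_l β_l·f_pl over allele copies with that local ancestry (loci where an
ancestry has no copies are skipped and reported). Identifiability is
asymmetric across ancestries: because the components sum to zero, a shift in
the minor (12%) WHG-like component loads much of its |slope| onto the
complementary major components, so WHG-shifted scenarios are the hardest to
identify — increasingly so at small cohort and locus counts. Quantiles use linear
interpolation between order statistics (numpy default). Empty TPR bins are
reported as missing, never as zero.

## Numerical and degenerate-input choices

* Determinism: a scenario plus seed reproduces bit-identical output;
  per-replicate seeds derive from a master seed via `SeedSequence` (always
  below 2³¹).
* Fixation of all causal loci during the forward phase falls back to the
  founding-generation environmental variance instead of dividing by zero.
* Selfing is excluded by resampling; fitness weights that underflow to a
  zero sum fall back to uniform parent sampling.
* Collinear design matrices raise an error naming the offending columns
  (pivoted QR); non-convergent logistic/ordinal fits raise with the
  optimizer diagnostics.
* `preprocess_trait` rejects logs of non-positive values and zero-variance
  traits; `phenotype_from_gv` rejects h² outside (0, 1] and zero GV variance.
* Ancient samples are projected onto modern PCs by per-sample least squares
  over the observed loci (partial coverage renormalizes rather than shrinks
  projections); no shrinkage correction is applied. "Ellipse diameters of 3
  core-set SDs" is read as semi-axes of 1.5 SD — the plausible alternative
  (semi-axis 3 SD) would be a uniformly more permissive rule, and the
  monotonicity of inclusion in the ellipse scale is property-tested.

## Known limitations

* The covA closed form is this package's reconstruction of a verbally
  described statistic; alternative per-locus weightings (e.g. variance
  scaling by f(1−f)) satisfy the same contracts and could shift effect
  sizes by a constant factor (harmless after standardization).
* The demographic defaults are deliberately broad-brush; realized ancestry
  fractions drift around the closed-form expectation, increasingly so at
  reduced Ne.
* At reduced scale the equal-optimum slope threshold and the TPR bands are
  sensitive to cohort size and TAGR counts; they are checked against the
  full-protocol values with tolerances reflecting the reduced replicate
  counts, as described above.
* The within-sibship design protects against confounders shared within
  sibships; confounders that differ between siblings and correlate with
  covA′ remain undetectable by construction.
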