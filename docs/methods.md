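# Methods

`musema` implements the quantitative-genetic machinery of a mammalian
mutation-accumulation (MA) experiment: many inbred lines bred by
brother–sister mating so that selection is too weak to purge new
mutations, a cryopreserved control branch revived late in the experiment
to separate environmental from genetic change, and two estimators of the
mutational variance feeding mean-standardised evolvability metrics.  This
note records the models, the conventions the package commits to where
several readings are possible, and what the synthetic-data tests do and do
not establish.

## Pedigree model and burn-in

A pedigree is a topologically ordered list of individuals; founders have
no recorded parents, everyone else has both.  The experimental founder
pair is generation 0.  Because the founders derive from a strain kept by
sib mating for hundreds of generations, analyses assume their genetic
variation is at mutation–drift balance; this is encoded by prepending a
burn-in chain of full-sib pairs with no trait data (default 20
generations, indices −20…−1).  With 20 recorded burn-in pairs the earliest
pair are pedigree founders and are unrelated by convention, so the
full-sib recursion F_t = (1 + 2F_{t−1} + F_{t−2})/4 applies 19 times on
the way to the experimental founders, giving F ≈ 0.983 (one iteration
short of the familiar 0.986); the difference is immaterial for any
quantity the package computes.  Inbreeding coefficients come from the
tabular kinship method.

## Relationship matrices

The numerator matrix **A** uses the standard tabular recursion with the
recorded founders as base.  The origin-generation matrix **A_k** scales
variance contributed by mutations arising in generation-k individuals:
generation-k individuals are mutually unrelated, non-inbred carriers of
one unit of new variance; descendants follow

    A_k[i,j] = (A_k[s,j] + A_k[d,j])/2          (j born earlier)
    A_k[i,i] = (T_s + T_d)/2 + A_k[s,d]/2,      T_i = (T_s + T_d)/2

where T_i is the summed variance of the individual's two haplotype values
(T ≡ 1 in ordinary A; it decays toward the origin cohort's contribution in
A_k).  This individual-level recursion is exact under Mendelian gene
dropping and is verified against a Monte-Carlo oracle that seeds
unit-variance haplotype effects and transmits them by literal coin-flip
segregation.  The mutational matrix is **M** = Σ_k A_k over origin
generations from the earliest (burn-in included by default, matching the
mutation–drift-balance founder assumption; a switch restricts to k ≥ 0)
to the second-to-last generation t — final-generation mutations are
excluded because they cannot contribute observations.

Matrices are dense and meant for desk-scale pedigrees (≲ a few thousand
individuals); `Pedigree.ancestor_closure` prunes to phenotyped individuals
plus ancestors.  Monte-Carlo agreement is asserted entrywise within 3
standard errors; across the thousands of entries of a 60-individual
matrix a few ~3.2-SE excursions are ordinary extreme-value noise, so the
tests require ≥99.5% of entries within 3 SE and none beyond 5 SE.

## Mutation-drop estimator of h²_M

The between-line estimator uses only line means.  10⁶ mutations (test
scales use fewer) are dropped into the complete pedigree including
burn-in: each of the n individuals receives on average b = 10⁶/n
mutations of effect ±a with a = √(2/b), so the bookkeeping variance
V_M = b·a²/2 is exactly 1.  Note the convention: b·a²/2 is the additive
variance at the within-individual allele frequency of 1/2; the realized
variance of the seeded genotypic values is b·a² = 2 per individual.  The
synthetic-data generator's `v_m` is the realized per-individual variance,
so the drop estimator's truth on generated data is v_m/2 while the animal
model recovers v_m itself — the two estimators use different unit
conventions, both stated here and tested.

From one drop, line means of genotypic values give the expected
between-line genetic trajectory g; iid standard-normal draws averaged
over 100 replicates give the environmental trajectory e; and the observed
sex-corrected between-line variance trajectory z (from generation t₁, the
first with ≥2 lines, to the last generation t₂) is fitted as
z ≈ x·g + y·e by unconstrained least squares.  h²_M = x/y and may be
negative.  Sex correction subtracts per-sex grand means (a
per-generation-by-sex option exists).  Confidence intervals bootstrap the
MA lines (g and e fixed — they describe the design, not the phenotypes),
taking empirical 2.5/97.5 percentiles; bootstrap replicates whose
resampled lines leave fewer than two informative generations are skipped.

Two finite-design properties are worth knowing.  First, g is a single
stochastic realization sharing the line structure with z, so the fit has
an errors-in-variables attenuation at small line counts; the bootstrap
interval is wide enough that coverage of the truth remains near nominal
(measured 88% at 25 lines × 12 generations over 100 replicate
experiments; the tests assert the 85–99% band).  Second, the
environmental trajectory e assumes iid individual environments; shared
litter/maternal environments inflate between-line variance in a shape e
cannot fully absorb, leaking a small positive offset into the mutational
weight (≈ +0.002 in h²_M units at our test scale with litter and maternal
variances of 0.1).  The null-calibration test therefore runs under the
estimator's assumed iid model; on clustered data the estimator is mildly
anticonservative.

## Animal model

The mixed model for a trait y is

    y = Xβ + Z₁u_litter + Z₂u_maternal + Z_a a + Z_m m + e,

with fixed effects sex, generation (categorical by default; linear
optional) and natal litter size for morphometric traits (fitness traits,
which attach to mothers, use generation only), environmental random
effects for the rearing litter and the mother, a base-population additive
effect with covariance A·σ²_a and a mutational effect with covariance
M·σ²_m.  REML estimation works on the phenotypic covariance
V = Σ σ²ᵢBᵢ + σ²_e I with average-information steps, step-halving, and EM
fallback, so the restricted log-likelihood never decreases.  Convergence:
relative component change < 10⁻⁶, a three-iteration likelihood plateau,
or a 20-iteration plateau (< 10⁻⁶ relative improvement) on likelihood
ridges; components are floored at 10⁻¹⁰ of the phenotypic variance.

Two identifiability facts shape the tests.  First, with fully inbred
founders A is nearly constant over the experiment and is absorbed by the
intercept, so σ²_a is likelihood-flat: it can wander without changing the
fit while σ²_m remains identified.  The tests therefore check that the
mutational variance is insensitive to dropping A (the paper-level
observation for long-inbred strains) rather than pinning σ²_a.  Second,
when each mother rears exactly one litter the litter and maternal
groupings coincide and only their sum is identified; fits are run without
the aliased effect where a test needs a clean answer.

Evolvability metrics from the mutational variance: h²_M = V_M/total,
CV_M = √V_M/mean, I_M = V_M/mean² = CV_M², and a rescaled CV_M dividing
by 3 for weights (volumes) and 2 for lengths to deflate the positive
correlation among dimensions of multidimensional traits.

## Trait trends and the control contrast

Per-generation change is OLS of trait on generation number (plus sex and
litter size for morphometric traits); the slope is expressed as percent
of the experiment-wide mean with a ±2·SE interval on the same scale.  The
MA-vs-control comparison assigns records to three calendar windows by
birth date (inclusive endpoints: 2022-06-29…09-26, 09-27…12-29,
12-30…2023-03-01), fits window (categorical) + experiment (control
reference) + covariates, subtracts the MA effect from the control mean
and expresses it as percent of the control mean.  Any window-constant
environmental shift cancels exactly, which is the design's point.
`extrapolate_decline` is the linear arithmetic used for per-generation
rates and the human projection (total/generations × rate ratio ×
horizon).

## SNM filtering and rate

Candidates are single-nucleotide sites where exactly one sequenced line
sample is non-reference and both founders are homozygous reference.  The
nine criteria (quality ≥30; all depths in [10,60); heterozygote allele
balance in [0.25,0.75]; impurity reads in non-mutated MA samples ≤25;
not in phase; sex-chromosome calls homozygous; ≤2 alleles; ≤1
cross-chromosome mate read) are order-independent, and a verdict lists
every failed criterion.  The impurity threshold search raises the
allowance from zero until no further true positives are admitted.  The
callable genome applies criteria 1–3 to every site (invariant records
included), autosomes + X, Y excluded unconditionally.  Phase flags and
cross-chromosome mate counts are consumed as per-variant annotations
(`PH`, `XC`); reconstructing them from reads is out of scope.

The rate divides the mutation count by 2 × callable sites × generations ×
mice (generations = mean pedigree depth to the sequenced individuals, so
mice × generations is the per-mouse sum of transmission opportunities).
The gene-dropping correction plants one heterozygous mutation in a
uniformly chosen eligible individual (non-burn-in, born no later than the
sequencing generation), transmits it by random segregation, and counts it
detected only when exactly one sequenced sample carries it — the same
uniqueness rule the candidate filter applies, which also removes
expansion-phase mutations shared across lines.  The factor is
1/P(detected) ≥ 1, with the loss and sharing components reported
separately; an exact frontier dynamic programme over copy-number states
provides the enumeration oracle for small pedigrees (MC agreement <1% at
10⁶ iterations is asserted).

## Synthetic data

The generator mirrors the study design: founder pair, 3-generation
expansion to 55 lines, up to 3 matings per line per generation chosen
from one randomly picked litter with substitution from further litters
and a cross-family (within-line) fallback at a configurable rate (13%
observed in the study); litters are truncated-Poisson (mean 6.5, chosen
to put the comparison-window cohort near the study's ~2,000 mice);
matings fail with probability 0.10, calibrated so line survival at
generation 18 lands near the study's 51/55; survival to weaning is ~100%.
A pair's pups are treated as one rearing group even when produced in two
litters (only lines reduced to a single pair produce two).  Calendar
dates assign one generation ≈ 13 weeks, anchored so MA generations 19–21
overlap the control comparison windows; the control branch freezes at
generation 3, revives at MA generation 16, expands 2 generations, and
breeds 20 lines for 3 more generations.

Phenotypes decompose exactly into stored parts (fixed + litter +
maternal + additive + mutational + residual; reconstruction is
bit-exact).  Base-additive values gene-drop founder haplotype effects
(exact A covariance, inbreeding included).  Mutational values are
per-individual Gaussian bundles of variance v_m transmitted Mendelianly
as discrete heterozygous loci; burn-in individuals are seeded too by
default so founders carry mutation–drift-balance variation, matching the
estimators' assumption.  The configured MA-vs-control genetic deficit is
applied as a mean shift to MA records (fitness traits get a fractional
shift of the count scale, acceptable for contrast recovery but not a
mechanistic litter-size model).  The generator does not simulate reads,
linkage, selection, IAP retroelements, or epigenetic inheritance — so
passing tests establish the estimators' statistical behaviour under the
stated variance structure, not robustness to those real-data features.

## Problem sizes used in the checked studies

Chosen to keep full runs at desk scale: oracle agreement on random
pedigrees ≤60 individuals at 2×10⁵ replicates; the h²_M coverage study
at 25 lines × 12 generations, one drop of 2×10⁵ mutations, 100 replicate
experiments × 400 bootstrap resamples; REML studies at 6 lines × 6
generations (~130 records per fit); the correction-factor comparison at
10⁶ iterations on a 5-line toy pedigree.
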