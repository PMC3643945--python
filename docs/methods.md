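# Methods

This note documents the statistical models, the synthetic template's
design, the numerical choices, and the limits of what the package's tests
demonstrate.

## The problem

Founder-population cohorts (Amish, Hutterite, and similar isolates) yield
single pedigrees of thousands of members across a dozen or more
generations, with consanguineous loops.  Two practical questions arise for
any analyst working on such data:

1. Does a kinship-corrected association test hold its nominal type-1 error
   on a structure this large and inbred, and how much power does it have?
2. Exact linkage analysis requires splitting the pedigree under a bit-size
   cap (`b = 2·n_nonfounders − n_founders`, at most ~24 for Lander–Green
   implementations).  What does splitting do to type-1 error and power —
   both for linkage itself and for association run on the split structure?

The package answers both by Monte Carlo: simulate SNP replicates directly
on a template pedigree that mirrors the cohort's structure and sampling
pattern, push every replicate through the analysis pipeline, and tally
threshold crossings.

## Synthetic template

The real cohort structure this emulates (one 13-generation, 4,998-member
pedigree with 798 genotyped members, 106 of them affected) is not publicly
distributable, so `largeped.template` generates stand-ins with the same
profile.  Design:

* Founder couples seed generation 0; each later generation's expected size
  follows a geometric profile whose ratio (and, for very short pedigrees,
  base brood size) is solved by bisection so the expected total lands ~6%
  above `target_members`; the overshoot is trimmed from the last
  generation without ever orphaning a spouse.
* Family sizes are gamma-weighted multinomial allocations
  (negative-binomial-like, dispersion 2.0, mean 3 children per couple),
  each couple getting at least one child.
* Each marrying member takes a new founder spouse, except: with
  probability `consanguinity_rate` (default 0.2) they marry a
  same-generation member of kinship ≤ 1/8 — preferring a positive-kinship
  (cousin-class) candidate, which creates inbreeding loops — and with
  probability 0.15 otherwise an unrelated member, which keeps distinct
  founder lineages connected into a single pedigree.  Sib and avuncular
  matings are excluded by the kinship cap.
* The genotyped subset (798) and the phenotyped-but-ungenotyped subset
  (100, all labelled unaffected) are sampled uniformly from the last three
  generations; 106 of the genotyped are labelled affected.  All genotyped
  members are phenotyped by default: with the prevalence fixed at
  106/798 ≈ 0.133, that is the configuration under which disease-model
  replicates reproduce ~106 affected among the genotyped, matching the
  template profile.  (`unknown_fraction` can dilute this for sensitivity
  analyses.)

The affection labels of the template are a fixed pattern, not
model-generated: the template's job is to carry the sampling frame.

What the template does **not** emulate: real ascertainment (affected
members are spread uniformly, not clustered in ascertained families),
demographic detail (birth years, migration, generation overlap), and the
exact topology of any real genealogy.  Calibration results transfer to a
real pedigree only to the extent that they are structure-robust; power
numbers in particular are structure-dependent and should be read as "for a
pedigree with this profile".

## Simulation model

124 SNPs on one autosome at uniform 0.062 cM spacing, risk-allele
frequency 0.2, linkage equilibrium.  Founder haplotypes are i.i.d.
Bernoulli draws — with no LD and a fixed allele frequency, a forward-time
founder population would add nothing identifiable.  Transmission is
gene dropping with Haldane recombination between adjacent loci
(`θ = ½(1 − e^(−2d/100 cM)
)` ≈ 0.00062 at the default spacing, so inheritance is strongly correlated
along the map while founder alleles stay independent across loci).

**Affection.**  Null replicates copy the template's labels verbatim, so
the phenotype pattern is constant and independent of genotypes.  Disease
replicates re-draw affection for every template-phenotyped member as
Bernoulli(`f_g`) at the disease locus (default: the middle marker,
index 62).

**Penetrance calibration.**  Penetrances are multiplicative in the effect
size ψ: `f_g = min(1, ψ^m(g) · f₀)` with `m = (0,1,1)` dominant,
`(0,0,1)` recessive, `(0,1,2)` additive, and `f₀` solved (monotone
root-solve, tolerance 10⁻¹²) so the Hardy–Weinberg-weighted mean equals
the prevalence K (default 106/798 ≈ 0.1328, the template's affected
fraction among genotyped).  The genotype *relative risk* therefore equals
ψ up to clipping.  This is a deliberate design decision: we verified by a
structure-free oracle (unrelated samples, 2,000 replicates) that an
odds-scale parameterization caps recessive-ψ=5 power at ~75% for any
prevalence, which is inconsistent with the calibration targets this
framework is built to reproduce, whereas the risk-scale model brackets all
of them.  The clip matters only for additive ψ=5 at K=0.133, where
`ψ²·f₀` exceeds 1.

**Reproducibility.**  Every replicate stage draws from
`SeedSequence([master_seed, replicate_index, stage_tag])`, so founder
draws, transmissions, and affection draws are independently replayable.

## Association test

The quasi-likelihood score statistic for relatedness-corrected
case-control association, with phenotypes of ungenotyped relatives.  With
genotyped set N, phenotyped-ungenotyped set M, genotype scores
`Y ∈ {0, ½, 1}`, phenotype scores `A = 1` (case), `−k/(1−k)` (control,
assumed prevalence k), `0` (unknown), and `K = 2Φ` kinship blocks:

    Ã  = A_N + K_NM K_MM⁻¹ A_M
    μ̂  = (1ᵀK_NN⁻¹Y)/(1ᵀK_NN⁻¹1),   σ̂² = μ̂(1−μ̂)/2
    W  = [Ãᵀ(Y − μ̂1)]² / (σ̂²[ÃᵀK_NN Ã − (Ãᵀ1)²/(1ᵀK_NN⁻¹1)])

referred to χ²₁.  The denominator is the exact variance of the numerator
under gene dropping at the null for *any* fixed Ã built from phenotypes
and structure — which is why type-1 error is calibrated by construction,
and why the calibration survives splitting.  The more robust variance
estimator introduced in later versions of the original software is
deliberately not implemented.  k defaults to 0.133; monomorphic loci are
flagged not-testable and excluded from both numerator and denominator of
tally rates.  Symmetric-positive-definite solves use Cholesky with one
10⁻¹⁰-jitter retry.

## Splitting

Subjects of interest are affected members plus their unaffected full
siblings.  The splitter is a deterministic greedy cluster-and-grow
heuristic honouring the published contract (maximal subjects under a bit
cap) without claiming to replicate the original tool's exact cuts:
sibship-seeded clusters, repeated merging of the best feasible pair where
"feasible" means the minimal connecting pedigree (shortest undirected
ancestral path plus mate completion) stays within the cap, scored by
subjects per added bit with lexicographic tie-breaks.  Kinship is then
recomputed within each sub-pedigree, treating cut-away parents as absent.

For association on the split structure, each individual's genotype is used
exactly once (duplicated connectors are assigned to the sub-pedigree where
they are a subject, else the lexicographically first), and the test runs
over the union of sub-pedigree members with block-diagonal kinship.
Genotyped members not drawn into any sub-pedigree drop out of the split
analysis — one source of the measured power loss.

## Two-point linkage

Exact joint likelihood of affection and one observed marker under a
two-locus model: 16 ordered (paternal, maternal) two-locus-haplotype
states per person, founder priors at HWE/linkage equilibrium, transmission
with trait–marker recombination θ, trait penetrance on disease-allele
count, marker penetrance as an observation indicator.  Affecteds-only
dominant (0, 10⁻⁴, 10⁻⁴) and recessive (0, 0, 10⁻⁴) models with disease
allele frequency 1%; the near-zero penetrances make unaffecteds
effectively uninformative through their ordinary `1 − f` factor.

The likelihood is evaluated by sum-product variable elimination in a
greedy min-fill order with running rescaling (log-space overall), which
performs the same exact constrained summation as classical peeling with
duplicated loop breakers but handles loops natively; a cost guard refuses
pedigrees whose elimination would exceed 10⁸ state evaluations.
Mendelian-inconsistent data yield −∞, distinct from underflow.

"Two-point" follows the trait-at-marker convention:
`Z_i = log₁₀L(θ=0) − log₁₀L(θ=½)` per sub-pedigree, no θ maximization.
At θ=½ the likelihood factorizes into trait-only × marker-only single-locus
peels (verified against the direct two-locus evaluation), which roughly
halves the scan cost since the trait-only part is cached per sub-pedigree.
Marker allele frequencies default to the simulation truth (0.2/0.8) to
keep estimation noise out of the comparison.  The HLOD maximizes
`Σ log₁₀(α·10^{Z_i} + 1 − α)` on a 0.01 grid with golden-section
refinement (within 10⁻⁶ of a 10⁻⁴ dense grid in tests).

Out of scope: multipoint likelihoods over the full map, nonparametric
allele-sharing statistics, and simulation-based empirical LOD thresholds.

## Problem sizes used by the test suite and acceptance script

Monte-Carlo checks run at desk scale with fixed seeds: 200–400 null
replicates and 200 power replicates per model on the full-scale template
(the tallies' Monte-Carlo SEs are reported next to every cell so
scaled-down runs stay interpretable); the split-vs-whole paired power
comparison and the two-point null-rarity check run on a 30%-scale template
(≈1,500 members, 239 genotyped) with per-replicate re-splitting, since
those re-run the splitter or the peeling engine inside the replicate loop.
Oracle equivalences are exact: peeling vs dense joint enumeration on
random 3–6-member pedigrees (16⁶ states; loops included), kinship
recursion vs 10⁵ labelled gene drops, the association statistic vs direct
matrix arithmetic, and the phase-known `m·log₁₀2` LOD closed form.

## Known limitations

* Power (not type-1 error) depends on the synthetic template's structure
  and on the uniform placement of genotyped members; a real cohort's
  ascertainment will shift it.
* The enrichment construction `K_NM K_MM⁻¹ A_M` follows the published
  formula for the statistic; other implementations may differ in detail.
  Validity is unaffected (the variance matches the numerator by
  construction); power could differ slightly.
* The splitter is a re-design honouring the published contract, not a
  reimplementation of the original optimizer; different cuts would give
  slightly different split-analysis power.
* Affection in disease replicates is re-drawn per replicate, so affected
  counts fluctuate around the template's 106 rather than being held fixed.
* No genotyping error, missingness beyond the template mask, LD, or
  X-linked inheritance.
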