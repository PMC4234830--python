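# Methods

## The model

`selftrans` models a *C. elegans* population in which three sexes
segregate at a single autosomal locus. XX individuals carrying at least
one wild-type *fog-2* allele make self-sperm and are self-compatible
hermaphrodites; XX homozygotes for the recessive *fog-2(q71)* knockout
are functional females; XO individuals are males regardless of
genotype. Hermaphrodites cannot fertilise each other, so matings occur
only between males and XX individuals. The wild-type allele is the
"selfing allele": its fate during experimental evolution is the
package's central object.

### Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| α | outcross-fitness: compound of all fitness components expressed under outcrossing, relative to selfing | required | dimensionless, grid [0, 2] |
| β | probability that a non-cross-fertilised hermaphrodite selfs (brood level; no mixed broods) | 1 | probability |
| σ | male survivorship deficit relative to hermaphrodites | 0 | proportion |
| δ | inbreeding depression applied to selfed broods where the design calls for it | 0 | proportion |
| N | census size, constant across generations | 10⁴ in simulations | individuals |
| B | selfed brood weight, B = 2β(1−δ) | 2 | dimensionless |

The defaults are the study conditions: no survivorship difference
between the sexes across salt concentrations, no detectable inbreeding
depression, and fully selfed broods (male sperm precedence makes mixed
broods rare).

### One generation (individual-based kernel)

1. With m the realised male frequency, each female or hermaphrodite is
   collected into a mating pair with probability min(αm, 1): K =
   min(round(αm·n_XX), n_XX) dams are drawn uniformly without
   replacement, and K sires uniformly with replacement from the males.
2. Unmated hermaphrodites self (probability β); unmated females leave
   no brood.
3. N offspring are drawn by sampling pairs and pseudo-pairs uniformly
   with replacement; genotypes segregate Mendelianly; offspring of true
   pairs are male with probability ½ (down-weighted by 1−σ), selfed
   offspring are always XX; XX sex follows from genotype.

The quota is *per XX individual*, not per capita: for an androdioecious
population (all XX hermaphroditic) the recursion's male frequency
reduces exactly to the male maintenance function
m′ = αm/(2αm + B(1−αm)), which simplifies to m′ = αm/2 at B = 2. This
anchors three facts simultaneously: the maintenance threshold α > 2,
the one-generation male decline 0.45 → 0.31 implied by the high-salt
selfing rate 0.38, and the fixation of the selfing allele within ~35
generations at α ≈ 1.4. A per-capita quota (αmN with N the census)
caps at the XX count in the relevant regime, silently switches off
selfing, and can reproduce none of the three — the per-XX reading is
therefore the implemented meaning.

The deterministic module iterates the exact infinite-population limit
of the same kernel. The male maintenance function and the full
recursion agree for androdioecy and in the rare-male limit; in trioecy
they differ because unmated females leave no brood, and both are
exposed deliberately.

A note on the printed maintenance function: its β symbol plays the
role of the full selfed brood weight. The implementation takes a
single `brood_weight` B = 2β(1−δ); substituting a bare β = 1 would put
the maintenance threshold at α > 1, contradicting the threshold α > 2
that the same model states, so B is the implemented meaning.

### Random numbers

A single public trajectory (`run_trajectory`) draws from a substream
spawned from its seed. The replicate engine (`run_replicates`), which
backs the likelihood machinery, draws all replicates from one generator
with every sampling call vectorised across the batch; replicates are
reproducible as a batch, not in isolation. This is a deliberate trade:
batching makes a 51-point likelihood grid with 20 replicate simulations
per point affordable on one core. Mating quotas round half to even;
initial censuses are apportioned by largest-remainder rounding
(deterministic, exact).

## Inference of outcross-fitness α

Samples of genotyped individuals (wild-type allele counts out of 2n)
taken at a handful of generations delimit periods. For each candidate α
on a 51-point grid over [0, 2], every period is simulated independently
from its own observed starting frequencies (20 batched replicates at
the experiment's census); the replicate-mean final wild-type frequency
parameterises a binomial log-likelihood for the allele count observed
at the period's end, and the terms are summed over periods and
replicate populations. The grid argmax is the ML estimate; the CI is
the contiguous grid range with 2·ΔlnL below a configurable drop
(default 3.84, the 95% χ²₁ point — the likelihood-interval convention;
the drop is a parameter because conventions differ). Boundary maxima
and ties are flagged, ties breaking to the lowest α.

Starting male frequencies come from the observation when recorded;
otherwise the simulated mean male frequency at the previous period's
end under the same α is chained forward and the choice is recorded in
the result metadata. Observed boundary counts (0 or 2n wild-type
alleles) are clamped to 1/(2n+1) and 2n/(2n+1), the generalisation of
the 48-individual convention (1/97, 96/97); simulated means are clamped
at the 2N-allele resolution so log-likelihoods stay finite.

Using the replicate-*mean* frequency in the binomial (rather than the
replicate mixture) is the printed procedure and is kept as the default
on purpose; it understates between-replicate drift variance, which is
one reason reported CIs should be read as likelihood ranges rather than
calibrated frequentist intervals.

## Fitness estimators

* **Transition fitness s** — pooled OLS slope of y = ln(p/(1−p)) on
  generation (shared slope and intercept across replicate series),
  frequencies clamped as above. Near the detection boundaries the clamp
  is deliberately conservative: on trajectories that saturate (logits
  beyond ~±4) it shrinks the slope by ~0.02 at 96-allele sampling,
  while on windows spanning logits ±2.4 the estimator's bias is below
  0.01 (both measured by the test suite's recovery experiments).
* **Competitive fitness w** = ln(p_wt,t1/p_GFP,t1) −
  ln(p_wt,t0/p_GFP,t0) over one competition cycle against a GFP tester.
  GFP scoring is presence/absence and the transgene is dominant, so
  scored positives mix homozygotes and heterozygotes. The correction
  assumes random mating and selfing with no sex-ratio distortion: each
  competitor outcrosses a fraction 2m_i of its progeny (the selfing-rate
  identity), sires are apportioned by male supply (adult frequency ×
  male frequency), cross-competitor progeny are heterozygous, and the
  unknown adult frequencies are iterated to a fixed point starting from
  the final phenotype frequencies. These equations are a reconstruction
  — the original analysis script is not public — pinned by a
  brute-force enumeration oracle in the tests; allele mass is conserved
  exactly and the correction is the identity when neither competitor
  carries males. Records whose setup deviates from the expected 50:50
  mix by more than a configurable band (default ±0.15) are flagged;
  exclusion is the caller's decision, never silent.
* **w_t and Δw_t** — w minus the block mean of the ancestral reference
  (reference records centre to exactly 0 within each block; blocks
  without a reference are excluded with a warning), then minus the
  ancestor mean for the population's reproduction system.
* **Male fitness w_m** = logit of the wild-type-sired progeny share
  (setup fixed at 0.5, so logit(p₀) = 0), after discarding plates with
  fewer than six transferred females or fewer than twenty scored
  progeny. The fertility-observation filter (≥5 progeny; ≥10% male
  progeny in outcrossed treatments) is provided alongside; both filters
  return per-rule rejection tallies and are idempotent.

## SNP diversity

Genotypes are 0/1/2 reference-allele counts with missing values.
Cleaning follows the staged rule: drop loci >80% missing, then
individuals >60% missing, then loci >50% missing. Loci with minor
allele frequency strictly below 0.05 are removed before analysis.
1−Ho is one minus the mean heterozygote proportion across SNPs
(non-missing calls only). Pairwise LD uses Burrows' composite
disequilibrium on pairwise-complete individuals, with the composite
correlation normaliser including the within-locus disequilibria D_A,
D_B — the appropriate convention for unphased genotypes under selfing,
where Hardy-Weinberg cannot be assumed. Pair-level r² values are
retained so summaries other than the all-pairs mean can be formed;
populations with fewer than two post-filter loci get no r² (a real
outcome for highly selfed samples). The ANCOVA of fitness responses on
a diversity covariate uses sequential (Type I) sums of squares with the
covariate entered before the three-level reproduction-system factor
(error d.f. = n − 4), built from explicit nested OLS fits because
formula interfaces reorder categorical terms ahead of covariates.

## Synthetic data

The generators emulate the structure and sampling depth of the study's
five data tables, with the generating truth in a sidecar next to every
table: ~48 genotyped individuals and 300 sexed individuals per time
point for trajectories; 12 blocks of 4–6 competition replicates scored
at ~1 232 larvae with shared block shifts (so block centring is
exercised); ~17 females per mating plate; 58 SNPs in contiguous LD
blocks. Trajectory tables are produced by the simulator itself from the
trioecious starting conditions (wild-type allele at 2.6 × 10⁻², males
at 0.45).

SNP matrices use Wright's equilibrium inbreeding F = S/(2−S) for
selfing rate S. Autozygosity alone cancels out of Burrows' r (both the
covariance and its normaliser scale by 1+F), so the generator also
raises the within-block haplotype-copying probability from its
outcrossed baseline to 1 − (1 − base)(1 − F), standing in for the
suppression of effective recombination under selfing. This emulates the
direction and rough magnitude of the homozygosity/LD response, not a
recombination map: passing tests show the statistics respond to mating
system as intended, not that the generator reproduces any particular
genome's LD decay. Likewise the competition generator draws phenotype
counts from the same mating-class model the correction assumes —
recovery tests validate the estimator's internal consistency and
sampling behaviour, not the model's adequacy for real assay data.

## Problem sizes and numerical checks

The test suite's simulation experiments run at the sizes chosen for
them: parameter recovery uses N = 2 000 with 20 likelihood replicates
and 20 datasets per generating α (sampling at generations 0/10/20/30,
where the sweep is informative across α ∈ [0.8, 1.6]); the
stochastic/deterministic comparison uses 200 replicates at N = 10⁴ over
20 generations, with a >3 SE generation required to replicate in an
independent batch before counting as disagreement (60 correlated
comparisons make a single 3 SE excursion expected noise, while a real
kernel defect replicates); fixation checks use 100 replicates at
N = 10⁴ over 50 generations. Extinct replicates are excluded from
period means with a warning; a trajectory that loses all reproducers is
truncated and flagged rather than padded.

## Known limitations

* Generations are discrete and non-overlapping; no density dependence,
  spatial structure, sperm competition within broods, or mutation at
  the sex-determination loci. Males arise only from outcrossing
  (spontaneous X non-disjunction is not modelled).
* Salt (or any environment) enters only through α and the initial
  conditions, not as an explicit variable.
* The GFP marker in the competition cycle is a fully linked neutral
  locus; no recombination is modelled over the single generation.
* Near the maintenance boundary (α → 2) the selfing allele still fixes
  eventually but can take well over 50 generations, mirroring the
  persistence of males in the gradual-regime populations.
* The heterozygote-correction equations are a reconstruction pinned by
  an enumeration oracle; the original script may differ in detail.
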