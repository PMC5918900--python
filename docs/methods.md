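# Methods

## The scientific setting

Clonal plants such as *Glechoma hederacea* grow as networks of ramets
connected by stolons. When a mother ramet rooted in living soil produces
daughter ramets that root in sterile substrate, any microorganism found in
the daughters' root endosphere must have travelled through the plant itself.
The experimental design this package analyses has, per clonal lineage
("ecotype"), one mother ramet and four daughter ramets (two consecutive
positions, D1 and D2, on each of two stolons), sequenced for three amplicon
markers (bacterial 16S, archaeal 16S, fungal 18S), plus unplanted control
pots that capture airborne/watering contaminants. Ten ecotypes replicate the
design.

## Heritability index and null model

For ecotype *e*, the heritability index is

    I_obs(e) = #{ OTUs present in the mother's roots
                  and in >= k of its daughters' roots },   k = 2 by default

("present" means >= 1 read in the processed table). Whether I_obs exceeds
chance is judged against a randomisation null: each daughter community is
replaced by a uniform random sample, without replacement and of the same
richness, drawn from a species pool; the index of each randomised network is
scored against the *true* mother set. Two pool definitions are first-class,
because both appear plausible for this design: the ecotype's own mother
community (`ecotype`), and the union of all mother communities (`regional`,
the default). Sampling probabilities are equal for all pool members —
abundance is deliberately ignored, since the hypothesis concerns species
identity, not read counts.

With N = |pool|, r_j the richness of daughter j, and m = |mother ∩ pool|,
each mother OTU lands in daughter j independently with probability r_j/N, so

    E[I_null] = m * P( Σ_j Bernoulli(r_j/N) >= k )

computed exactly over the 2^4 inclusion patterns (`exact_null_expectation`).
This closed form is the oracle the Monte-Carlo sampler is tested against; the
sampler itself exploits exchangeability (the number of mother OTUs drawn is
hypergeometric, and given that number the hit set is a uniform subset), which
makes 9999 iterations over a 3000-OTU pool cheap.

Per ecotype the standardized effect size is

    SES = (I_obs − mean(I_null)) / sd(I_null)

and the group-level inference is a one-sample t test of the SES values
against zero, alternative "greater", df = (non-excluded ecotypes) − 1.
Ecotypes are excluded — reported, never silently — when they lack a mother
sample, have fewer daughters than k, or have a degenerate null
(sd(I_null) = 0, e.g. when every daughter's richness equals the pool size).
Normality of the SES values is checked with Shapiro–Wilk and reported.

Default n_iter = 9999; k ∈ {1,2,3,4} exposed (k=2 default — k >= 3 makes
most null draws zero and inflates the contrast). Seeded runs are
bit-reproducible; per-ecotype streams are spawned from one seed sequence.

## Preprocessing

Order: prevalence filter (OTUs in >= 3 samples), control-pot
decontamination, rarefaction to a common depth. Decontamination is binary
presence-based: any OTU with a single read in any control pot is removed from
every sample, then the controls are dropped. We decontaminate *before*
rarefying: presence in controls is assessed at full depth, and a control pot
with fewer reads than the normalisation depth would otherwise be discarded
before its OTUs could be removed (control pots can be nearly read-free, as
unplanted substrate often is). The rarefy-first order remains available
(`decontaminate_first=False`).

Rarefaction draws a uniform subsample of reads without replacement
(multivariate hypergeometric); samples below the target depth are dropped.
The depth itself, chosen by eye in typical amplicon workflows, is replaced by
a reproducible heuristic: the largest single-significant-digit depth
retaining >= 90% of the read-positive samples — always overridable.
Rarefaction curves use the closed-form hypergeometric expectation
E[S(d)] = Σ_i (1 − C(T−c_i, d)/C(T, d)), with a Monte-Carlo mode for
cross-checking.

## Richness mixed models

Richness is the count of OTUs with nonzero reads, at whole-community and
per-phylum scope. Two linear mixed models (statsmodels MixedLM, REML):

* mother vs daughter: `richness ~ role + (1 | ecotype)`;
* dilution, daughters only: `richness ~ position + stolon +
  (1 | ecotype/stolon)` — a variance component for stolon-within-ecotype
  carries the repeated measurement of each stolon.

F statistics for the 1-df effects are squared Wald t ratios with containment
denominator df: an effect is tested against the number of units at the level
where it varies, minus the units of the coarser level, minus the fixed
parameters at that level (role: n − n_eco − 1; position: n − n_units − 1;
stolon: n_units − n_eco − 1). With the full design (50 root samples) this
gives df patterns like F(1,39) for role and F(1,19)/F(1,9) for
position/stolon. Residual normality is Shapiro–Wilk-checked; on failure the
response is log(x+1)- then sqrt-transformed, and the transformation used is
always reported. Phyla with nonzero richness in both roles in fewer than 3
ecotypes are skipped with a report entry rather than fitted unstably.
Optimisers are tried in sequence (lbfgs, bfgs, powell, nm) because
near-boundary variance estimates can break a single method.

## PLS-DA

Composition contrasts (mothers vs daughters, the three-group position
contrast, D1 vs D2) use PLS-DA: NIPALS PLS2 of the autoscaled OTU matrix
(columns centred, unit variance; constant columns dropped and recorded)
against centred one-hot class labels, deflating both blocks per component.
Classification is by arg-max predicted dummy response. Components are chosen
by stratified cross-validated misclassification (7 folds by default, seeded,
ties to fewer components); significance comes from a label-permutation test
on the minimum CV error, p = (1 + #{perm <= obs}) / (n_perm + 1) with 999
permutations by default. The permutation-of-CV-error scheme is this
package's own choice of validation statistic; published PLS-DA p values from
other toolchains need not be numerically identical.

Numerical choices: convergence tolerance 1e-10 on the relative score change,
cap 2000 iterations. Under permuted labels the two leading cross-covariance
eigenvalues are occasionally near-tied and the power iteration plateaus; a
component that reaches the cap while stationary to 1e-4 is accepted (the
choice of basis inside a tied subspace does not affect classification), and
anything worse raises with diagnostics. Tiny training folds may exhaust the
X residual or lose columns to autoscaling; cross-validation then backs off
to the largest fittable component count instead of aborting. Ties in the
permutation statistic count against significance (conservative).

## Sequence overlap

The fraction of daughter reads whose sequence occurs exactly (case-folded,
no trimming, no reverse-complement matching — amplicons are
orientation-normalised upstream) among mother reads. Dereplicated FASTA with
`;size=N` annotations is supported; the statistic is invariant to
dereplication and monotone in the mother set.

## Synthetic data generator

The generator is first-class, tested code; it emulates the study conditions
so every stage is testable without the deposited data:

* 10 ecotypes, 1 mother + 4 daughter root samples each, 3 control pots,
  three markers (fungal pool 180 OTUs across 5 phyla with mother richness
  40; bacterial pool 3384 across 8 phyla with mother richness 800; archaea
  mothers-only).
* Pool-level log-normal OTU weights (sigma 1.2) drive both which OTUs
  colonise a mother and their read abundance — the occupancy–abundance
  coupling real amplicon tables show. Without it, a >= 3-sample prevalence
  filter strips implausibly many reads from the richest samples.
* Transmission: per ecotype one Bernoulli-filtered "cohort" of the mother
  community (phylum-specific probabilities; Basidiomycota pass more readily
  than Ascomycota/Glomeromycota), then per-daughter retention (0.85 fungi /
  0.8 bacteria) with multiplicative decay at position D2 and on the
  second-emitted stolon. A per-ecotype log-normal multiplier (sigma 0.6) on
  transmission reproduces the wide between-ecotype spread of observed
  heritability.
* `sharing` ∈ [0,1] interpolates between fully-shared cohorts and
  per-daughter independent draws from the mother set. This — not retention —
  is the "cohort sharing strength" knob: retention rescales the observed
  index and the null's mean and sd together, so SES is non-monotone in it,
  while SES rises monotonically in `sharing`.
* `cohort_mode="independent"` draws each daughter uniformly from the
  regional pool: exactly the null model's assembly process, used for type-I
  error calibration.
* Reads are multinomial at fixed depth over log-normal per-sample noise;
  contaminant OTUs occupy control pots (and, for bacteria, root samples at a
  low rate).

What the generator does **not** emulate: sequencing error and chimeras,
phylogenetic correlation between OTUs, abundance-dependent transmission,
compositional (closure) effects beyond the multinomial, and between-sample
depth variation. Passing tests therefore demonstrate correctness of the
statistics under the stated assembly model, not robustness to every artefact
of real amplicon data.

## Problem sizes used in tests and the acceptance script

The acceptance script runs the full study-scale defaults (9999 null
iterations, 999 permutations). Simulation-heavy checks use deliberately
scaled designs chosen for tight Monte-Carlo error at desk scale: the type-I
experiment uses 1000 replicates of a 10-ecotype design with pool 60 /
mother 40 / daughter richness ~10 at 299 null iterations; the power
experiment uses 200 replicates of the fungal-scale generator; oracle
equivalence uses pools of <= 6 OTUs where exhaustive enumeration is exact.

## Known limitations

* The two pool modes answer slightly different questions; with the regional
  pool, mother OTUs absent from an ecotype's own roots still enter the null.
  Neither mode is declared "the" correct one.
* Containment df is one convention among several (Satterthwaite and
  Kenward-Roger differ in unbalanced designs); printed F values from other
  software may differ without either being wrong.
* Per-ecotype SES values from a finite null (9999 draws) carry Monte-Carlo
  noise of order 1/sqrt(9999) that the group t test treats as real variance;
  this is negligible at the default setting.
* The one-file spreadsheet reader is deliberately permissive (taxonomy
  columns recognised by header token, metadata inferred from sample-name
  patterns) because deposited supplementary tables rarely document their
  schema.
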