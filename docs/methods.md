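# Methods

This note records the models implemented in `biphase`, the assumptions
behind them, the defaults and why they were chosen, and what the bundled
synthetic data can and cannot establish about behaviour on real cohorts.

## The problem

A gene is functionally knocked out in an individual only when both copies
are disrupted: by a homozygous damaging variant, or by two different
damaging variants on opposite haplotypes (compound heterozygosity, CH).
Two variants on the same haplotype (multi-hit *cis*) leave one intact
copy. Distinguishing CH from cis requires phase, and the variants that
matter are rare — precisely where statistical phasing is least reliable.
The pipeline therefore treats phasing confidence as a first-class
quantity: every heterozygous genotype carries a posterior probability
(PP) that its haplotype assignment is correct, and phase-dependent calls
are restricted to genotypes with PP at or above a threshold
(default 0.9).

## Synthetic cohorts

`cohort.simulate_haplotypes` generates diploid haplotypes per site
independently — there is no linkage disequilibrium, recombination map,
population structure or relatedness beyond the explicit trios. This is a
deliberate reduction: carrier classification and every statistic built on
it depend only on within-gene phase configurations, which the generator
plants explicitly. Consequences of the reduction: switch errors here are
independent across sites, whereas real statistical phasing produces
correlated switch tracts; allele-frequency spectra are matched only
marginally; and conditioning stages see no genuine LD (tests that need an
"LD proxy" construct the correlation directly). Passing tests therefore
demonstrate correctness of the algorithms under the stated sampling
models, not robustness to the haplotype structure of real populations.

Defaults encode the statistical structure the analysis assumes for a
confidence-filtered phased exome call set:

- `maf_spectrum = {singleton: 0.12, MAC 2-5: 0.28, MAC 6-10: 0.10,
  low-frequency: 0.50}` — 12% singletons among retained variants; the
  low-frequency component draws MAF uniformly up to the qualifying cap of
  5%.
- `mask_proportions = {pLoF: 0.03, damaging missense: 0.05, other
  missense: 0.57, synonymous: 0.35}` — damaging categories are a small
  minority of coding variation, in the proportions typical of annotated
  exomes.
- Trio children inherit one whole haplotype from each parent, so truth
  trios have zero Mendelian errors by construction; parents are flagged
  so association stages can exclude them.
- MAC/MAF are recomputed from the final matrix (children included), so
  the column-sum invariant holds exactly; columns left monomorphic by
  untransmitted founder singletons are dropped.

The bundled demo (`chpipe demo`) additionally enriches the damaging
fraction (pLoF 0.10, damaging missense 0.15) so that bi-allelic carriers
are plentiful at demonstration scale; that choice belongs to the demo,
not to the generator defaults.

### Phase-error injection

`inject_phase_errors` flips each heterozygous genotype independently with
a MAC-bin-specific probability and attaches a PP score drawn from a
bin-specific two-component model (correct genotypes uniform on
[0.95, 1.0], flipped ones uniform on [0.5, 0.95] by default — informative
but not perfectly separable). A per-genotype flip probability r yields a
pair-level switch-error rate of exactly r only for pairs whose partner
genotype is correctly phased; round-trip fixtures therefore alternate
rare hets with confidently phased common hets, which is also the regime
of real data (rare variants anchored between common scaffold variants).
When adjacent rare hets can both flip, the observed pair SER is
2r(1−r)-shaped and lower than r; the switch-error calculator reports
exactly what it sees.

### Liability phenotypes

The binary-trait simulator follows a liability-threshold model with
spike-and-slab gene effects. With B the column-standardized bi-allelic
carrier matrix over m retained genes:

    y_i = Σ_j B_ij θ_j + ε_i,   ε_i ~ N(0, 1 − h²)
    θ_j = 0                        with probability 1 − π_θ
    θ_j ~ N(b/(m π_θ), h²/(m π_θ)) with probability π_θ

Cases are samples with liability above the standard-normal quantile at
1 − prevalence (default 0.10). E[θ] = b/m and the variance of y is
1 + b²(1−π_θ)/(m π_θ); the "variance one" property is exact only up to
the mean-effect term, which is negligible for the moderate b (≤ 2) used
throughout the tests. Standardization of B makes variance explained per
gene frequency-independent, so rare-carrier genes get large per-carrier
effects. Constant carrier columns cannot be standardized and are dropped
with a warning.

### Onset times

Event ages are exponential with per-class proportional hazards
(`baseline_rate` default 0.02/year from age at entry, entry uniform on
[30, 40], administrative censoring uniform on [65, 80]). Because the
exponential is memoryless, drawing the residual time from entry samples
exactly from the left-truncated proportional-hazards model. This is the
simplest generator satisfying the assumptions of the Cox stage; it has
constant hazards and uninformative censoring, which real health-record
data do not.

## Phasing evaluation

Switch errors are counted between contiguous resolvable heterozygous
sites per sample: a pair is an error when its relative phase differs
between the estimated and truth haplotypes, which makes every quantity
invariant to globally flipping a sample's haplotypes. Pairs are assigned
to the MAC bin of their rarer variant (the rarer variant limits phasing
difficulty). Genotypes below the PP threshold are removed before
pairing; unresolvable sites are skipped, never counted as switches.
Confidence intervals are Wilson 95% bounds. Trio transmission resolves a
child-heterozygous site whenever at least one parent is homozygous
(hom × het and hom × hom crosses both force the transmitted alleles);
Mendelian inconsistencies and de-novo sites are flagged and excluded.
Gene-level aggregation — the fraction of (sample, gene) units with ≥2
resolvable hets in the gene body and no within-gene switch — is our
convention, exposed as `gene_level_ser`.

## Carrier calling

Qualifying variants pass a consequence mask (pLoF, damaging missense,
their union, other missense, or synonymous) and a MAF cap (default 5%).
PP filtering is genotype-level: a low-PP het is *phase unknown* — it can
never create a CH or cis call, but it still implies at least one
affected copy, so it supports `het` status and the additive encoding.
Class precedence within a gene is hom > CH > cis > het > WT; a sample
that is simultaneously hom and CH counts once, as bi-allelic (that is
what association consumes), with a flag preserved. The recessive
encoding is presence of a bi-allelic (CH or hom) state → 2, absence → 0;
the additive encoding counts affected copies 0/1/2. Multi-allelic sites
are assumed pre-split into bi-allelic records. Ultra-rare collapsing
(MAC ≤ 10) produces a carrier *indicator* (not a count) per sample, with
rarer-than-5%-but-not-ultra-rare variants returned individually for
conditioning.

## Association

The null logistic model is fitted on covariates only (statsmodels GLM);
the score for genotype g is T = gᵀ(y − μ̂) with variance equal to the
efficient information after projecting g off the covariate space under
the null weights. Samples are assumed unrelated — the synthetic cohorts
are — so no genetic-relatedness-matrix machinery is included; this is
the single deliberate methodological reduction relative to a biobank
mixed-model pipeline.

For |T/√V| ≤ 2 the two-sided normal approximation is used. Beyond that,
tails come from a saddlepoint approximation, and here the package makes
a considered choice. The normal approximation fails under extreme
case-control imbalance because it ignores the case-total margin; a
saddlepoint of the *unconditional* score fixes the skew but still
differs from margin-conditional (Fisher-exact) tails by several-fold for
rare carriers. Each tail is therefore approximated by a double
(Skovgaard) saddlepoint of the score *conditional on the case total*,
with Daniels' lattice correction in the denominator term, since the
conditional score for a collapsed 0/2 genotype lives on a lattice of
spacing 2. This matches Fisher-exact tails within a few percent in the
interior of the support. At the boundary of the conditional support
(e.g. every carrier a case) the saddlepoint equations diverge; for
two-valued genotypes the tail is then computed exactly as a conditional
carrier-count tail — Fisher's noncentral hypergeometric with the mean
carrier/non-carrier odds, which reduces to the central Fisher tail when
covariates are absent. Non-convergence elsewhere falls back to the
unconditional saddlepoint and finally to the normal approximation, with
a flag.

Scans enforce the carrier floors among samples with non-missing
phenotype (≥5 bi-allelic carriers for the recessive scan, ≥10 disrupted
haplotypes for the additive scan) and attach the Bonferroni threshold
α/(genes × traits) for the tested grid. Conditioning columns (polygenic
score, selected common variants, additive dosage, rare and collapsed
ultra-rare burden) are absorbed into the null design; columns that do
not increase the design rank are dropped with a warning, and every
result records the conditioning set actually used. The iterative
common-variant scan is greedy forward selection, stopping when the best
conditional p is not below 5×10⁻⁶ or 25 signals are held; ties break by
larger absolute score, then lower genomic position.

Utility formulas: Bonferroni α/(n_genes·n_traits); effective sample size
n_eff = 4/(1/n_cases + 1/n_controls); one-sided sign test
P(X ≥ k | n, ½). The polygenic-score MAF filter is
max(floor, f(min(n_cases, n_controls))) with floor 0.01; the
count-dependent term is configurable (default 2/min) because the
functional form of the published filter is ambiguous as printed, and the
package declines to resolve it silently.

## Phase permutation

The empirical null for "is this association driven by phase?" shuffles
the CH/cis label multiset across samples carrying multiple qualifying
variants (≥10 such samples required), re-derives the recessive encoding,
and recomputes the score strength t = T²/V against the shared
covariate-only null (the null fit does not involve the genotype). The
one-sided empirical p is (1/n) Σ I(t_i ≥ t_observed), implemented
verbatim — it can return 0 — with an optional add-one correction off by
default. The ≥ comparison uses a 10⁻⁹ relative tolerance so that a
permutation reproducing the observed labelling is counted as a tie
rather than lost to summation-order jitter. Homozygous, single-het and
wild-type rows are never touched, so label counts are conserved exactly.
When all eligible samples carry one label the distribution is degenerate
and the result is flagged (p = 1 by the formula). Without covariates,
permutations that select the same number of cases are exact ties of the
statistic, which biases the empirical p upward by construction;
uniformity checks therefore include a covariate, as the real scans do.

## Enrichment, expectations, power

Per-gene counts of samples carrying a variant class are modelled as
Poisson with log-linear terms for gene-set membership and log mutation
rate (a covariate by default; an offset mode is provided). The rate
ratio is exp of the membership coefficient with a profile-likelihood 95%
interval computed by bisection on the deviance; an all-zero stratum is
flagged with an unbounded interval.

Under Hardy-Weinberg and inter-site independence, with per-haplotype
carriage probability q_v per site:

    P(hom) = 1 − Π(1 − q_v²)
    P(CH)  = Π(1 − q_v²) − 2·Π(1 − q_v) + Π(1 − q_v)²

(hom takes precedence, matching the caller). The Monte-Carlo counterpart
draws per-haplotype Bernoulli(q) alleles — the only reading under which
homozygote frequency is q² — pairs haplotypes into diploids, and
averages over 10 replicates by default.

The power solver returns the minimal odds ratio at which the 1-df
carrier association test reaches a target power (default 80%) at a given
α. Power is evaluated with the two-proportion normal approximation using
distinct null and alternative variances, the form behind standard
genetic power calculators; a chi-square noncentrality evaluated at
expected counts was rejected because it uses the null variance under
the alternative and overstates power by ~10 percentage points in the
rare-carrier regime (the Monte-Carlo oracle decides). At OR = 1 the
power equals α exactly. Below ~20 expected carriers any continuous
approximation degrades against a discrete rejection rule; the solver
reports what the approximation gives and the Monte-Carlo check in the
acceptance suite quantifies the residual gap.

## Survival

Cox partial-likelihood fits (lifelines) compare carrier classes against
a configurable reference (heterozygotes by default), with left
truncation at entry age and the Efron tie approximation. Eligibility
follows the two floors: ≥5 two-hit carriers and ≥100 heterozygotes;
contrasts with zero events are flagged NaN rather than dropped silently.
Proportional hazards are not tested, consistent with the intended
screening use. Kaplan-Meier curves honour left truncation; a
reference-class swap inverts the corresponding hazard ratio exactly.

## Problem sizes and numerical choices

The test and acceptance suites run at desk scale, chosen so every
stochastic check has resolving power while the whole suite stays fast:
null calibration at 500 genes × 20,000 samples; permutation validity at
1,000 permutations × 20 seeds (the production default allows up to
100,000 permutations); Cox coverage over 200 null fits; power
verification over 5,000 Monte-Carlo replicates; switch-error round trips
over ≥2,000 comparison pairs. Calibration conditions use carrier
frequencies of 10⁻³–10⁻² (20–200 carriers per gene): at singleton-scale
counts the score statistic is so discrete that a continuous
Kolmogorov-Smirnov reference rejects even when the binomial type-I check
passes, so uniformity is asserted where the instrument is valid.
Newton solves for the conditional saddlepoint are damped with step
halving and accept roots at 10⁻¹⁰ relative residual; logistic null fits
cap at 100 IRLS iterations and clip fitted probabilities to
[10⁻¹⁰, 1−10⁻¹⁰]; rank decisions for collinearity use exact matrix rank
on the candidate design.

## Known limitations

- No linkage disequilibrium or switch-tract correlation in the
  generator; phasing-quality conclusions transfer to real data only at
  the level of counting logic, not error structure.
- The score test assumes unrelated samples; applying the pipeline to
  cohorts with cryptic relatedness requires an external mixed-model or
  GRM correction.
- The conditional saddlepoint conditions on the case total only; with
  strong covariates the exact conditional distribution given all
  covariate scores differs, and the mean-odds boundary tail is an
  approximation in that regime.
- Annotation is consumed, never predicted: mask categories, MAFs and
  mutation rates are inputs.
- X-chromosome/haploid logic is out of scope; genes are autosomal.
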