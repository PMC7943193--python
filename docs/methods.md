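# Methods

This note records the models, defaults, and numerical choices behind
nucleoscan, and what the synthetic tests do and do not establish about
behaviour on real data.

## Read processing

Paired 125-bp reads covering a 126-nt (42-codon) variant region are
processed in four stages.

**Flank trimming.** The forward mate must begin with the 5′ constant
region, the reverse mate with the reverse complement of the 3′ constant
region. A pair is discarded when either flank mismatches its reference at
more than `max_flank_mismatch_rate` (default 0.2) of positions.

**Merging.** The reverse mate is reverse-complemented and the ungapped
overlap maximising matches-minus-mismatches is selected, ties going to the
longest overlap. Overlaps shorter than `min_overlap` (default 20 nt) or
below 80% identity are rejected — without the identity floor, a pair whose
true overlap is too short would be merged at an arbitrary, mostly
mismatching offset instead of rejected. At overlap disagreements the base
with the higher Phred quality wins and keeps its quality; quality ties go
to the forward mate. Agreeing bases keep the higher of the two qualities.

**Length/quality filter.** The consensus must have exactly the expected
length (this excludes all indels by construction) and satisfy the Phred
rule: by default every base ≥ Q30 (`quality_rule="min"`); a mean-quality
reading is available (`"mean"`). `N` bases carry Q0 and therefore fail the
default rule.

**Aggregation and annotation.** Passing sequences are exactly
deduplicated per sample (deterministic lexicographic row order). An
optional abundance-greedy correction collapses sequences within a
Levenshtein radius into their most abundant neighbour; it is off by
default because downstream count thresholds already suppress rare
sequencing errors, and exact dedup is deterministic and auditable.
Variants are annotated against the wild-type coding sequence: substitution
count, translation, class (wildtype / synonymous / missense / nonsense),
and 1-based amino-acid substitutions. A nonsynonymous variant that also
carries a synonymous change in a different codon is classed `rejected`:
its amino-acid annotation would be shared with the clean variant while its
nucleotide history differs, confounding substitution-level aggregation.

**Analysis filters.** Scored variants need ≥ `min_input_reads` (default
50) in *every* input replicate and at most 2 amino-acid substitutions.

## Nucleation scores

With within-sample frequencies `F`, `ES_i = ln F_i(out) − ln F_i(in)` and
`NS_i = ES_i − ES_wt`. Natural logarithms throughout; because scores are
relative to wild type, the log base only rescales them. The sample totals
cancel in the difference, so with pseudocount 0 the scores are exactly
invariant to sequencing depth.

**Pseudocount.** Counts enter as `c + pseudocount` with default 0.5.
The exact Poisson expectation of `ln(C + x)` shows why: at a true mean of
2 counts, `ln(C+1)` is biased by +0.28 natural-log units while `ln(C+0.5)`
is biased by only +0.026; at mean ≥ 3 the 0.5 form is unbiased to three
decimals. With `ln(C+1)` the scores of strongly depleted variants (the
interesting ones in a nucleation screen) are visibly compressed toward
zero. Pseudocounts of 0 (analytic identities) and 1 remain available.

**Log debiasing.** For the default scoring path the residual low-count
bias of `ln(c + 0.5)` is removed explicitly: each variant's expected count
per sample is estimated by pooling counts across replicates, and the exact
Poisson bias of the plug-in log at that expectation is subtracted
(`poisson_log_moments`; the exact sum is evaluated below a mean of 50,
above which the bias is below 1e-3). Variants never observed in a sample
get no correction — nothing can be estimated there — and their scores are
lower bounds in magnitude.

**Error model.** The modelled score variance is

    σ²_ir = m_in[r]·(v_in,i,r + v_in,wt,r) + m_out[r]·(v_out,i,r + v_out,wt,r) + a[r]

where `v = 1/(λ̂ + pseudocount)` is the delta-method variance of the
log-count estimator evaluated at the pooled expected count λ̂. Evaluating
at pooled expectations rather than per-replicate observed counts matters
twice over: observed-count weights are correlated with the very noise they
weigh (a replicate that fluctuated low gets a larger modelled variance and
a smaller weight, pulling the weighted mean toward zero and attenuating
the score scale by several percent), and pooling three replicates nearly
halves the noise of the variance estimate itself. The wild-type terms are
included even though they are small: the WT reference is itself counted.

The modifiers are fitted by iteratively reweighted least squares on the
moment conditions of the normal model. Given current variances, the
leverage-corrected squared residual `(ns_ir − μ_i)² / (1 − w_ir/Σ_r w_ir)`
— `μ_i` the precision-weighted replicate mean — has expectation `σ²_ir`,
linear in `(m_in, m_out, a)`; a bounded weighted least-squares step
(weights `1/σ⁴`, the inverse variance of a squared normal residual)
updates each replicate's triple, and the loop runs to parameter
convergence (relative tolerance 1e-6, max 100 iterations; typical
convergence in ~20). The leverage correction undoes the degrees-of-freedom
loss from estimating `μ_i` on the same replicates; without it fitted
variances are biased low by about (R−1)/R. Bounds `m ≥ 1, a ≥ 0` keep
every fitted variance at or above the pure-Poisson floor. A direct
quasi-Newton maximisation of the profile likelihood was tried and
rejected: that surface rewards driving one replicate's variance toward
zero (its leverage → 1 makes its residuals vanish while −ln σ grows
without bound), and the optimiser reliably collapsed one replicate's
parameters onto the bounds. The IRLS stationary conditions are the
likelihood's moment equations and do not share the degeneracy.

Variants whose pooled expected count is below 10 in any sample are
excluded from the fit (not from scoring): their counts sit against the
zero floor, so their replicate scatter is censored and understates the
modelled variance, which otherwise inflates `m_out` by 10–50%. On toy
tables with fewer than 50 informative variants the exclusion is skipped.

**Merging, centering, classes.** Replicates merge by the error-weighted
mean, `σ_merged = (Σ 1/σ²)^(−1/2)` — monotone non-increasing in the number
of replicates. Scores are then centered on the error-weighted mean of
synonymous variants arising from a single nucleotide change, the natural
neutral set; centering is idempotent and leaves sigmas untouched. Effect
classes come from a two-sided z-test (`z = ns/σ`) with Benjamini–Hochberg
FDR over all scored variants (singles and doubles together): `increase` /
`decrease` when `q < FDR` (default 0.1) with the corresponding sign, else
`wt_like`. A one-sided variant of the test is switchable.

## Positional architecture

Single amino-acid missense scores form a 42 × 19 position-by-mutant
matrix; nucleotide variants encoding the same substitution are combined by
error-weighted mean, and nonsense variants never enter. Distances between
position rows are Euclidean over the columns observed in both rows,
rescaled by `sqrt(n_columns / n_shared)` so sparsity does not shrink
distances; with no missing cells this is plain Euclidean, and a pair with
no shared column is an error rather than a guess (no imputation — PAM's
medoids stay actual data rows). K-medoids uses the classical BUILD + SWAP
(steepest-descent) procedure with ties broken toward the lowest index, so
the partition is deterministic; total cost never increases across swaps.
K ∈ [1,10] is selected by average silhouette width on the same distance,
with K = 1 assigned width 0 so "no structure" is a well-posed competitor;
identical rows therefore select K = 1. Stability: each of `n_draws`
(default 100) resampling rounds perturbs every observed cell by
Normal(0, σ_cell) — draws independent per cell — and re-runs the
selection; reported are the distribution of optimal K and the frequency
with which each pair of positions co-clusters.

Per-position profiles count significant `increase` / `decrease` calls at
a stated FDR over the substitution-level matrix cells. A position is
called a **gatekeeper** when significant increases are at least as common
as decreases (`n_up ≥ n_down`) and most of its observed mutations are
significant (`(n_up + n_down)/n_observed ≥ 0.5`); both thresholds are
exposed because "most mutations significantly different" admits more than
one operationalisation. Region summaries (Nt / Ct ranges plus the
gatekeeper set, mutually exclusive) report class fractions separately for
singles and doubles, a double counting toward a region only when both
substitutions fall inside it.

## Sequence features

Property difference scores are `Δp = Σ (p(mut) − p(wt))` over a variant's
substitutions — zero for synonymous, additive for doubles, undefined for
stops. Properties come from an AAindex1-format reader; Kyte–Doolittle
hydropathy and Hopp–Woods hydrophilicity ship with the package, and any
other vector (e.g. a hydrophobicity principal component) can be supplied
as a file. Correlations with NS use the error-weighted Pearson coefficient
(weights `1/σ²`, invariant to rescaling); its p-value uses a t
approximation at the Kish effective sample size `(Σw)²/Σw²`, which is a
documented convention, not an exact null.

Charge analysis counts {R,K} as positive and {D,E} as negative over the
full mutant sequence; histidine is treated as polar-uncharged, which is
what makes wild-type Aβ42 come out at 3 positive / 6 negative, net −3,
nine charged residues. A variant is *eligible* for the charge grouping
only when every substitution keeps both sides within the
polar/charged/glycine classes, so charge effects are not confounded with
hydrophobicity changes. Groups are keyed exactly by
(net charge, number of charged residues) with per-group n, median, and
quartiles.

## Disease-variant discrimination

Positives are the dominant familial-Alzheimer substitutions from an
editable label table (the package ships the 12-variant set plus recessive
A2V, which is excluded from positives); negatives are all other scored
single amino-acid missense variants. The AUC is computed as the normalised
Mann–Whitney U with average ranks (ties count one half) — invariant under
any strictly monotone transform of the scores — and the curve sweeps the
score threshold. Categories over scored singles are mutually exclusive
with label precedence: `known_fAD`, else `candidate_fAD` (significant
increase), `protective_like` (significant decrease), or `benign`
(WT-like).

## Synthetic data

The generator emulates the study design stage by stage, all randomness
flowing from one numpy Generator.

- **Wild type.** A fixed, arbitrary 126-nt ORF — deliberately not the real
  Aβ coding sequence, so no test can silently depend on real codon usage.
- **Library.** `simulate_library` samples molecules whose substitution
  count follows either a categorical spectrum (default: 29.9% WT, 23.8%
  single-nt, 21.8% double-nt, remainder 3–4, an error-prone-PCR-like
  profile) or a truncated Poisson, with uniform positions and uniform
  alternative bases. `balanced_library` instead enumerates distinct
  variants with log-normal frequency spread (default sd 0.5) and a pinned
  WT fraction (default 0.2) — the controlled-coverage setting used for
  calibration studies, where a target median input count is set directly
  through depth.
- **True effects.** One draw per distinct (position, mutant aa), reused
  across variants sharing the substitution. Defaults mimic a modular
  aggregation landscape: N-terminal positions Normal(0, 1), C-terminal
  Normal(−3, 1), terminal "gatekeeper" positions Normal(+1, 0.5), stops at
  −4, doubles additive with Normal(0, τ=0.2) epistasis noise.
- **Selection and counts.** Input counts are negative-binomial around
  depth × frequency with variance `m_in × mean` (exactly Poisson at
  m = 1); output expected frequencies are input frequencies × exp(ES + ε),
  ε ~ Normal(0, √a) independent per variant and replicate, renormalised,
  then drawn with inflation `m_out`. The wild type's ε is off by default:
  WT anchors every score, so WT selection noise is a per-replicate common
  offset on all scores (absorbed by centering), not independent noise, and
  including it would make the injected `a` unrecoverable as defined.
- **FASTQ.** Each counted molecule is emitted as a read pair (constant
  flanks, configurable read length and substitution error rate, Phred
  values consistent with that rate, Q40 at rate 0). At error rate 0 the
  count → FASTQ → count loop reproduces the table byte for byte.

**Problem sizes.** The verification suite uses 2,000 variants at median
input count 500 for score-recovery checks, 5,000 for noise-model recovery,
and ~10⁵ reads for the FASTQ round trip — sizes at which each measured
quantity is stable while the whole suite stays fast.

**Calibration experiment design.** Recovering all nine modifiers within
tight bounds is an identifiability question, not just a sample-size one: a
Cramér–Rao analysis shows that under symmetric input/output depths the
input term's variance share is too small for `m_in` to be estimated
precisely (bound ≥ 30% relative at 5,000 variants). The recovery
experiment therefore separates depths (median input ~100, output ~1,000),
widens the frequency spread (log-sd 1.0), uses neutral-centred effects
(sd 1.5), and injects `m_in = 1.6, m_out = 1.8, a = 0.02` shared across
replicates, reporting each parameter class as its replicate mean. Under
this design the bound is ≤ 10% per class and observed errors are ≤ ~10%.

## What the synthetic tests do and do not show

The generator reproduces the features the estimator actually exploits:
relative-frequency selection dynamics, Poisson/NB count noise with
replicate-specific overdispersion, variant-level selection noise, a
modular effect landscape, and exact read structure. It does **not**
simulate PCR jackpots or bottleneck lineages, chimeric reads,
position-dependent sequencing error, codon-usage structure in the real
peptide, or correlated errors between variants sharing molecular history.
Passing tests therefore establish the statistical machinery —
unbiasedness, calibration, clustering and ranking behaviour — under the
stated noise model, not the wet-lab fidelity of any particular dataset.
Error calibration is asserted where the model claims it: on variants with
pooled expected counts ≥ 10 everywhere, standardized residuals have
variance within [0.85, 1.15]; for censored variants the reported σ is
deliberately conservative (coverage stays within [0.92, 0.97] globally).

## Degenerate inputs and tie-breaks

Empty flanks, missing WT rows, single replicates, empty synonymous sets,
all-zero samples, and disconnected position pairs raise informative
errors rather than guessing. Merge-quality ties prefer the forward mate;
PAM ties prefer the lowest index; silhouette ties prefer the smaller K;
BH runs over the full scored set. Scores of variants with zero observed
output counts are finite (pseudocount) but magnitude-censored, and their
variance terms fall back to the pseudocount floor.
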