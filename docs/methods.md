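# Methods

## The model

Treatment-selection ("predictive") biomarkers are genes whose association
with outcome differs *by treatment arm*, as opposed to prognostic markers
that shift outcome regardless of arm. For biochemical progression-free
survival (bPFS, months from surgery to PSA-defined recurrence) in a two-arm
neoadjuvant cohort — NCHT (docetaxel + androgen deprivation, t = 0) versus
NHT (hormonal therapy alone, t = 1) — the per-gene screening model is the
Cox proportional-hazards model

    h_i(t) = h0(t) · exp(β₁ tᵢ + β₂ gᵢ + β₃ tᵢ gᵢ),

with gᵢ the gene's log2(TPM+1) expression. β₃ is the interaction
(treatment-modification) effect; its Wald statistic z = β̂₃ / se(β̂₃) carries
the decision direction: since t = 1 codes NHT, a positive β₃ means higher
expression raises the hazard under NHT relative to NCHT, so high expression
favours NCHT; negative z favours NHT. exp(β₃) is the interaction hazard
ratio (iHR), the multiplicative hazard modification per expression unit
under NHT relative to NCHT. Genes with interaction p < 0.05 (raw, no
multiplicity correction by default; a Benjamini–Hochberg mode is available)
form the signature, weighted by their z-scores:

    DNTP score = Σ_g z_g · expr_g.

Expression enters unstandardised on the log2(TPM+1) scale. That choice is
dimensional: the published cutoff (−95.798) with nine weights near −3.6 and
one at +3.74 is only attainable when typical expression sits around 3, the
scale of log2(TPM+1) for moderately expressed genes; z-standardised
expression would put scores two orders of magnitude smaller.

A single cutoff c splits the cohort: score ≥ c is the high-score
(NCHT-preferable) group — the boundary belongs to the high side — and
score < c the low-score (NHT-preferable) group. The cutoff is chosen by
scanning the midpoints of consecutive sorted unique scores, keeping only
candidates where each side retains ≥ 20% of patients (``min_group_fraction``)
and both arms appear on both sides, and minimising the Wald p of the
interaction in a Cox fit on {group, treatment, group × treatment}. The
"best bPFS difference" objective is genuinely open; minimal interaction p
was chosen because the stratified claim being evaluated is precisely a
group-by-treatment interaction, and a secondary objective (maximise the
smaller within-group log-rank χ²) is available behind
``scan_cutoff(..., objective="logrank")``. The per-candidate diagnostics
table (interaction p, within-group log-rank p) is always returned so the
selection surface can be inspected rather than trusted.

## Cox fitting

The partial likelihood is maximised by Newton–Raphson from β = 0, with
Efron's approximation for tied event times (Breslow optional; the two agree
exactly when no event times are tied), step-halving whenever a step would
decrease the log-likelihood, at most 100 iterations, and convergence when
the score sup-norm falls below 1e-9 or the step change below 1e-10. At tied
times, censored subjects remain in the risk set of events at the same
instant (risk set = {time ≥ t}). Variances come from the inverse observed
information. There is no penalisation: monotone likelihoods (perfect
separation) are *flagged* as non-converged — screening must surface unstable
genes, not mask them — using a scale-invariant runaway check
(|β̂_j|·sd(x_j) > 20 or se_j·sd(x_j) > 50). Non-converged genes are reported
but excluded from selection. The fitter is validated three ways: against a
1e-3 grid search of the explicitly evaluated partial likelihood on ≤15-subject
instances, against lifelines on simulated cohorts (coefficients and standard
errors to ≤1e-5), and by invariance properties (covariate rescaling,
treatment recoding).

## Kaplan–Meier and log-rank

Product-limit estimation evaluated at distinct event times; the median is
the step-function convention, the first time with S(t) ≤ 0.5, without
interpolation, and is undefined (None) when the curve never reaches 0.5.
The two-group log-rank test accumulates hypergeometric means and variances
per event time (variance terms skipped when a single subject is at risk).
Significance threshold for all survival comparisons is 0.05.

## Exact tests and table conventions

Two-sided exact p-values use the minimum-likelihood rule (sum of
probabilities of all margin-fixed tables no more probable than the observed
one), the convention of R's `fisher.test`, which published clinical tables
are computed with. 2×2 tables delegate to `scipy.stats.fisher_exact`; r×c
tables are enumerated exactly by recursive margin-constrained row
composition — a 4×2 table over 64 patients enumerates in milliseconds — with
an explicit enumeration budget error rather than a silent Monte-Carlo
fallback. Zero rows/columns are dropped (they carry no information); a zero
margin in a 2×2 yields p = 1 with a warning. "Missing" categories are
displayed in cohort tables but excluded from tests. Rank-sum comparisons
use the exact distribution for small tie-free samples and the tie-corrected
normal approximation otherwise; binomial proportions get Wilson score
intervals. Percentages print with half-to-even rounding at 2 d.p.
(53.125% → 53.12%), matching how R-rounded clinical tables read.

## Pathway regulation consistency

For a pathway restricted to genes present in both differential-expression
tables, with significance meaning |logFC| > 1 in the requested direction and
adjusted p < 0.05 (a |logFC| > 2 preset mirrors the stricter variant used
for preference-group comparisons):

* `level1_consis` — genes significant in the same direction under both
  treatments;
* `level2_consis` — genes significant under exactly one treatment and
  direction-concordant (any |logFC|) under the other;
* `level1_coef` = J(sigA, sigB);
* `consis_coef` = J(sigA ∪ L2, sigB ∪ L2) with L2 the level-2 gene set,
  i.e. (level1 + level2)/|sigA ∪ sigB|.

The consis_coef construction is the one design point that was genuinely
under-determined. Augmenting *both* significant sets with the level-2 genes
(rather than each with its own direction-concordant genes) was chosen
because it is the only reading under which the coefficient (a) can never
fall below `level1_coef` — adding L2 ⊆ sigA ∪ sigB grows the intersection
without growing the union — and (b) equals 1 exactly when every one-sided
significant gene is at least concordant on the other side, the qualitative
behaviour the statistic is meant to capture. The operationalisation is
isolated in `pathway_consistency` so it can be swapped. Genes absent from
either DE table are dropped, not imputed; an empty pathway overlap yields a
flagged zero record.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
not any real patients. Defaults emulate the target study design:
64 patients split exactly 32/32 (Bernoulli assignment available), 200 genes
with expression Normal(3, 1) truncated at 0 on the log2(TPM+1) scale, an
exponential baseline hazard with rate ln 2/10 per month (median 10 months),
independent exponential censoring at 0.05/month plus a 60-month
administrative horizon — together giving an event fraction near the 58%
biochemical-recurrence rate of a 2014–2018 surgical cohort with a ~10-month
median bPFS. Event times are drawn by inverse transform from the
configured proportional-hazards model (exponential or Weibull baseline);
planted effects enter through β₁ (arm), per-gene β₂ (prognostic) and β₃
(predictive) maps. `generate_split_cohort` plants a true crossover: patients
at or above a score threshold get hazard multiplier `benefit_hr` under NHT
and 1 under NCHT, reversed below it, so cutoff recovery can be measured
against ground truth.

One seed drives five independent substreams (assignment, expression, event
times, censoring, nuisance covariates) via `numpy.random.SeedSequence.spawn`,
so changing the gene count does not perturb the clinical draws and identical
seeds give bit-identical cohorts.

What the generator does **not** emulate: gene–gene correlation, library-size
or batch structure, count-level noise (expression marginals are independent
truncated normals), informative censoring, or covariate–outcome association
(age, PSA, Gleason, stage are drawn from realistic marginals independently
of survival). Passing tests therefore demonstrate the statistical
correctness of the procedures under the assumed proportional-hazards data
model, not robustness to the correlation structure of real tumour
transcriptomes.

## Problem sizes and numerical choices

Simulation-backed tests use: type-I error of the interaction Wald test at
n = 100 over 2,000 replicates (band 0.05 ± 0.012); β₃ recovery at n = 500
over 200 replicates (mean bias < 0.05); cutoff recovery on n = 400
designed-crossover cohorts (≥ 90% grouping agreement); null calibration of
the log-rank test and KS checks of the inverse-transform sampler at
n = 4,000–5,000. These sizes give Monte-Carlo error comfortably inside each
band while keeping the default suite around two minutes.

Ties between Newton candidates in the cutoff scan resolve to the first
minimal interaction p in score order. The treatment coding is fixed at
0 = NCHT, 1 = NHT everywhere; string labels are translated at the file
boundary only. Signature serialisation is JSON and round-trips the printed
decimals exactly (weights are stored as numbers, never re-derived).

## Known limitations

* The screen fits genes marginally; correlated genes yield correlated
  z-scores, and the signature does not re-estimate weights jointly — by
  design, matching the published construction.
* The cutoff scan optimises a selection criterion over many correlated
  candidates; its minimal p is not a valid hypothesis test and is reported
  as a diagnostic, with the designed-crossover simulations providing the
  calibration evidence.
* `fisher_rxc` is exact but exponential in table size; it is intended for
  the small clinical tables it serves (≲ 5×3 with n ≲ 100).
* Interval-censored PSA recurrence times, time-varying effects, stratified
  baselines and robust variances are out of scope.
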