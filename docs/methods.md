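# Methods

## Scope and model

`dcepref` implements the quantitative pipeline of a discrete choice
experiment (DCE) on community-based care for MDR-TB patients. Three
attributes describe a care model: DOT provider (family member — reference,
community health worker, expert client), location of care (workplace —
reference, home) and additional support (SMS — reference, phone call,
travel voucher). Each choice task offers two designed profiles and an
opt-out ("neither") whose utility is normalized to zero; a respondent
answers eight tasks.

Utilities are linear in an alternative-specific constant (ASC) and five
dummy-coded level indicators, with i.i.d. Gumbel errors, giving multinomial
logit choice probabilities per task. The mixed logit (random-parameters
logit) lets the five attribute-level coefficients vary across respondents as
independent normals, `β_i = μ + σ ⊙ z_i`; the ASC is fixed, since the model
is identified by the propensity to choose any designed option over opting
out and the data carry little information about its dispersion. Correlated
coefficients and non-normal mixing are out of scope.

## Estimation

The panel simulated log-likelihood is

    SLL(μ, σ) = Σ_i ln [ (1/R) Σ_r Π_t P_it(chosen | μ + σ ⊙ z_ir) ],

computed with log-sum-exp stabilization both across alternatives and across
draws. Draws are Halton sequences: one prime base per random coefficient
(2, 3, 5, 7, 11 by default), the first 10 elements discarded (they are the
coarsest and most correlated across bases), each respondent taking a
contiguous block of R values per dimension, mapped through the standard
normal inverse CDF. The draws involve no pseudo-randomness, so a fit is a
deterministic function of the data and settings. R defaults to 1000, the
convention the study states; simulations in the test suite use smaller R
(64–200) chosen for statistical adequacy at their sample sizes.

Optimization is L-BFGS-B on the per-respondent *average* SLL with the
analytic score (the score is exact; a test verifies it against central
differences at 1e-5). Averaging keeps the gradient-norm convergence
tolerance (1e-5, sup-norm) meaningful across sample sizes. Starting values
are the conditional-logit estimates with all SDs at 0.1; the conditional
logit itself is fit by Newton–Raphson with analytic Hessian and step
halving, flagging separation when coefficients diverge (|β| > 10) or the
gradient tolerance is not met. Standard errors come from the inverse
numeric Hessian (central differences of the analytic gradient) of the SLL;
no sandwich correction is applied. SD estimates are reported in absolute
value — the likelihood is symmetric in each σ's sign — and tested against
zero with the normal approximation, as is conventional for heterogeneity
SDs. Columns with no variation across alternatives within any task carry no
information and are dropped with a warning rather than poisoning the
Hessian.

Known limitation: with few respondents or weakly identified SDs (e.g. the
phone-call SD, whose generating value is 0.19), |σ̂| piles up near zero and
its Wald test is conservative; mean coefficients are well behaved at the
study scale.

## Design construction and evaluation

The design matrix has one row per (task, alternative), task-major, opt-out
last and all-zero, ASC attached to designed rows. D-efficiency is defined at
a coefficient prior (zero by default, the utility-neutral case) from the
multinomial-logit information matrix `I(β) = Σ_t X_t'(diag(p_t) − p_t p_t')X_t`
with K = 5 (the ASC is excluded: it is a nuisance for design comparison and
including it would change K across opt-out conventions). The reported score
is `det(I/t)^(1/K)` normalized by the utility-neutral balanced orthogonal
ideal, whose per-task information is `diag(2/9)` per dummy column — the
maximum variance a 0/1 column can attain across three alternatives under
uniform probabilities — so the score lies in (0, 1] at zero priors, and a
design referenced against itself scores exactly 1. Published D-efficiency
figures computed by other software use unstated coding and normalization
conventions and are not comparable digit-for-digit; this package's
convention is fixed and testable against a direct-determinant oracle.

Design search is coordinate exchange: from a seeded random design, propose
one level change of one alternative and keep it only if D-efficiency
increases. This is a local search run with a few thousand iterations; it
reliably beats the best of 1000 random designs in the test suite but makes
no global-optimality claim. Profiles may repeat across tasks; identical
profiles within a task are rejected.

The Orme sample-size rule `N > 500·c/(t·a)` uses the largest level count c,
rounds up, inflates by the anticipated nonresponse rate and rounds up again
— both ceilings so the bound is never undershot (c=3, t=8, a=2 with 10%
nonresponse gives 104).

## Synthetic data generator

The generator emulates the study conditions: 103 respondents, the shipped
8-task design, and the published mixed-logit estimates as the generating
population (means 0.52, 1.13, 0.89, 1.25, 0.70, 1.35; SDs 0, 1.85, 1.77,
1.19, 0.19, 0.55). Covariates (gender, age group, HIV status, months on
treatment) are drawn from the published marginals — 43/103 female, 42/103
aged 20–34, 40/103 HIV-positive, 31/102 under six months with one missing
value — independently of each other and of preferences. The default
allocation reproduces the marginal counts exactly (largest-remainder
apportionment with a seeded shuffle), so stratum row counts match the
study's footnote arithmetic (1512/960 by HIV status; 744 + 1704 = 2448 by
treatment duration with one respondent's 24 rows excluded as missing); an
`independent` mode draws each respondent independently instead. A
preference-shift hook adds a constant to chosen coefficients in one stratum
to induce subgroup differences in simulations.

Choices are sampled from the logit probabilities with a random stream keyed
per (respondent, task content), making the generator invariant to task
order within the design. The generator does not model nonresponse,
attribute non-attendance, lexicographic responders or preference–covariate
correlation beyond the explicit shift hook, so passing recovery tests
demonstrate correctness of the estimator under the assumed data-generating
process, not robustness to real-world survey behaviour.

## Postestimation

Relative importance uses the range method on point estimates: an
attribute's range is max − min over its level coefficients with the
reference at 0, and importance is the range as a percent of the sum of
ranges (undefined, and signalled, when all ranges are zero). The shipped
two-decimal coefficient fixture reproduces the published 36.2 / 33.5 / 30.3
percent split; full-precision inputs give 36.1% for support — a rounding
artifact of the published table, which is why the two-decimal fixture is
the default input for reproduction.

Ranking enumerates all 18 attribute-level combinations (rather than the 16
printed rows, which contain label inconsistencies), scores each with
`V = constant + Σ indicator·coefficient`, sorts descending and assigns dense
ranks with lexicographic tie-break.

Subgroup analysis splits the sample on a binary covariate (rows with a
missing value excluded and counted), refits the mixed logit per stratum
with all parameters free, and compares the five attribute-level means with
independent-samples Wald tests, `z = (b₁−b₂)/√(se₁²+se₂²)`, two-sided
normal p-values. SDs and the ASC are not compared. Simulations in the test
suite check this test's calibration (type-I error at identical strata of
150 respondents each over 100 replicates) and power (a +1.0 home-preference
shift at 1000 respondents per stratum is detected in ≥ 8/10 replicates).

## Reproducibility

The pipeline (`dce run` / `run_pipeline`) derives all stage seeds from one
root seed via seed-sequence spawning and stamps every output with the seed
and a hash of the analysis-relevant configuration; repeated runs are
byte-identical except for log timestamps. Halton-based estimation is
deterministic by construction. Simulation sizes used in the test suite —
recovery at 1000 respondents × 200 draws × 10 replicates, CI coverage at
250 × 64 × 20, subgroup calibration at 150/stratum × 64 × 100 — are the
package's standing choices for balancing Monte-Carlo error against runtime.
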