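# Methods

## Response model and conjugate inference

Each subject's symptom score at a visit is modeled as a linear
combination of their L baseline latent factors, the four medication
dosages at that visit, and an intercept, plus Gaussian noise:
y = Xω + ε. The baseline block of the design matrix is constant within a
subject, so a subject's own visits identify at most five directions of
the P = L + 4 + 1 parameter space (the four dose columns plus the
combined baseline/intercept direction); with P = 19 the per-subject
problem is always underdetermined, which is why the prior and the
model-space pooling carry real inferential weight rather than being
decoration.

Inference uses the Normal–Inverse-Gamma conjugate family,
ω | σ² ~ N(τ, σ²Λ⁻¹), σ² ~ InvGamma(α, β), with the standard update

    Λ_n = Λ₀ + XᵀX,  τ_n = Λ_n⁻¹(Λ₀τ₀ + Xᵀy),
    α_n = α₀ + n/2,  β_n = β₀ + ½(yᵀy + τ₀ᵀΛ₀τ₀ − τ_nᵀΛ_nτ_n)

and the Student-t posterior predictive t_ν(xτ, (β/α)(1 + xΛ⁻¹xᵀ)),
ν = 2α. The β update is computed in the algebraically equivalent residual
form β₀ + ½[(y − Xτ_n)ᵀy + (τ₀ − τ_n)ᵀΛ₀τ₀], which does not cancel large
quadratics; a non-positive β from exact-fit rounding is clamped to a tiny
positive value with a warning. Singular precision solves fall back to a
jitter of 1e−8·trace/P. Batch and sequential updates agree to ~1e−12,
which the suite checks against a dense grid-integration oracle at small P
and a batch-vs-sequential identity at P = 19. The two symptom dimensions
(inattentiveness, hyperactivity) get fully independent models.

One ambiguity deserves note: the predictive-variance expression is
implemented as 1 + xΛ̂⁻¹xᵀ, i.e. with the covariance-scale matrix, which
is the form consistent with conjugate theory and with treating Λ̂⁻¹ as
the stored covariance-scale. Column order is fixed as
[factors | IR-MPH, XR-MPH, DEX, ATOM | intercept].

## Prior elicitation

Quantitative effect sizes from heterogeneous studies cannot be pooled on
a common scale, so the elicited prior encodes directions only: τ₀ entries
are −1 for symptom-lowering effects (all four medications) and ±1 for
baseline factors by their association sign. Diagonal variances start at
1; each quality-qualifying contradicting study adds 0.5, otherwise each
supporting study subtracts 0.1 with a floor of 0.5. When a column has
both kinds of evidence the contradiction rule wins — inflation is the
conservative response to genuine disagreement. Off-diagonal covariance
entries are zero unless a causal link between two parameters is declared;
declared links default to zero magnitude with an explicit override hook,
and a supplied magnitude set must leave the matrix positive
semidefinite. α₀ = β₀ = 1 by default (a vague unit-scale noise prior);
both are configurable, as their elicited values are inherently
study-specific. The shipped `default_evidence()` table is an
illustrative, configurable stand-in for a study-specific rapid-review
table, not a reproduction of one.

## Virtual patient profiles

Method 1 fits least-squares maps from baselines to posterior parameters
over the training pool (through the origin, matching the f(b) = bQ̂
form); the posterior covariance travels through its upper-triangular,
row-major half-vectorization, and the reconstructed matrix — which linear
mixing can leave indefinite — is repaired by symmetrizing and clipping
eigenvalues below 1e−8. α̂\* and β̂\* are pool means. Rank-deficient
baseline matrices are handled by SVD truncation and logged.

Method 2 retains the ⌈0.175·|pool|⌉ nearest subjects by Euclidean
baseline distance (ties at the retention boundary are all kept, floor of
one subject) and averages their posteriors with normalized
exp(−1.15·d) weights. The profile is a convex combination of valid
posteriors, so no repair is ever needed; the weighted average is applied
to the covariance-scale matrices Λ̂_s⁻¹ directly (averaging precisions
instead would give a genuinely different — and less literal — estimator).
The defaults λ = 1.15 and 17.5% are the validated settings for this
framework; both are exposed in `KernelConfig`. Distances use the actual
Euclidean metric (with the square root), so d = 0 iff baselines coincide
and the triangle inequality holds. Polynomial feature expansions for
Method 1 were deliberately left out: beyond-linear maps are known to
generalize worse in this setting, and the linear map keeps the
well-specified regime analyzable.

## Prediction regimes and cross-validation

AI predicts every visit from the virtual profile with no updating; BR
predicts visit 1 from the profile and every later visit from the
*elicited prior* refit on all visits seen so far (deliberately ignoring
the model space — it is the no-pool benchmark, and keeping its prior
strictly elicited is the point of the contrast); BU updates the virtual
profile one visit at a time. All three regimes are prequential — the
prediction at visit *a* never touches the outcome at visit *a* or later —
and the first-visit predictions of the three regimes are bitwise
identical by construction. Visits with missing outcomes are predicted
but skipped when updating, with a log message.

Cross-validation is patient-coherent: subjects (never visits) are
shuffled into k folds whose sizes differ by at most one. Pools and
profile maps are fitted on training folds only. Because the factor
scores are simulated directly, the per-fold refitting of the factor
extraction that a real questionnaire pipeline would need is replaced by
the identity — a deliberate simplification; the synthetic factors play
the role of already-extracted scores.

## Remission classification

Remission at a visit is score ≤ threshold, with −0.97
(inattentiveness) and −0.92 (hyperactivity) as the clinical defaults and
the boundary inclusive ("a mean item score of one or less"), applied
identically to truths and predictions so ties resolve consistently. A
nonnegative critical value c is subtracted from the point estimate before
thresholding; larger c classifies more visits as remission, raising
sensitivity at the cost of specificity. Two sweeps are provided: an
additive scalar c (negative grid values are permitted inside ROC sweeps
so the curve reaches both corners) and the default quantile sweep, in
which a common one-sided confidence level is converted per case into
c_i = t_q(ν_i)·scale_i — uncertain predictions get larger offsets, which
is what makes the classifier genuinely uncertainty-aware. Operating
points maximize balanced accuracy on training-fold in-sample predictions
only, ties breaking toward the smaller critical value, and are applied
unchanged to the validation fold. AUC is the trapezoid area over the
swept (FPR, TPR) points with (0,0) and (1,1) appended; on an
all-gaps additive grid this equals the Mann–Whitney pairwise concordance
exactly, which the suite asserts to 1e−9. Metrics with zero denominators
are reported as explicit `None`, never as silent NaNs.

The rms error is √[mean over subject-courses of the per-subject mean
squared error]: per-subject averaging first (so long courses do not
dominate), square root last, which puts the value on the symptom-score
scale.

## Synthetic cohort generator

The generator emulates a forced-titration clinic: per subject, L = 14
standard-normal baseline factors; an appointment count drawn uniformly
on 1–22 (the distribution across patients is not otherwise constrained,
and uniform is an acknowledged stand-in); a combined equivalent
daily dose following a stepwise ramp (0.5, 1.0, 1.5, 2.25, 3.0 dose
units, then plateau) scaled per subject by U(0.8, 1.2), with the active
medication switching to another type with probability 0.1 per visit; and
outcomes y = Xω_s + ε per dimension. Doses are expressed in tens of
milligrams of IR-MPH-equivalent daily dose so that unit-scale regression
coefficients are commensurate with the ±1 sign-encoded prior (a 30 mg
plateau is 3.0 units and a −0.5/unit effect moves the score by −1.5).

Subject response vectors are drawn around a population mean — factor
effects ±0.15, medication effects −0.5/unit, intercept 1.34 — with
spreads (0.05, 0.1, 0.3) and correlation 0.7 between the two symptom
dimensions' vectors, reflecting that the dimensions respond similarly
but not identically. Observation noise defaults to σ = 0.5 on the
standardized score scale. The intercept was calibrated once, via the
package's own `calibrate_prevalence` bisection, so that default cohorts
show ≈14% visit-level remission; `calibrate_prevalence` remains available
to retarget any configuration and errors out when a target is
unreachable within its search bounds.

What the generator does **not** emulate: questionnaire items and factor
extraction (factors are emitted directly), adherence and persistence
effects, adverse drug reactions, dropout correlated with response, and
EDD unit conversion from datasheets. Passing tests therefore demonstrate
the correctness and internal consistency of the inference machinery
under the stated generative assumptions — not clinical performance on
real cohorts, whose published error and AUC levels arise from data this
package cannot regenerate.

## Test-design notes

The profile-fidelity check runs in Method 1's well-specified regime: a
noiseless cohort whose response vectors are exactly linear in the
baseline with effects routed through the medication-response coefficient
and the intercept, and a prior that pins the structurally zero
coefficients. There — and only there — the fitted posteriors are
themselves linear in the baseline, so the linear profile map should be
near-exact; the suite requires validation rms < 0.05 and observes
≈0.003. Parameter-recovery and coverage checks use a dose-response-only
course (no baseline covariates) so that every coefficient is identified
by dose variation, 500 visits at σ = 0.3, and 1,000 held-out draws. The
strategy-ordering check averages 20 seeded 150-subject replicates
(5-fold CV, one symptom dimension) — heterogeneity across seeds is real,
so the BU ≤ AI claim is asserted about the mean, not per replicate.
Problem sizes throughout (cohorts of 40–200 subjects, 5–10 folds) were
chosen to keep the full suite fast while leaving every statistical
assertion comfortably powered.
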