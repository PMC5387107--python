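"""Fit one patient's dose-response model by conjugate Bayesian updating.

The elicited prior encodes only effect directions from the literature
(medications lower symptoms); each observed appointment sharpens the
posterior, and the Student-t posterior predictive quantifies how sure the
model is about the next visit.
"""

import numpy as np

import modelspace as ms

prior = ms.build_prior(ms.default_evidence(), ms.default_parameter_names())
print(f"elicited prior: P = {prior.dim}, medication prior means "
      f"{prior.tau[14:18].tolist()}, diagonal variances in "
      f"[{prior.lambda_inv.diagonal().min():.1f}, {prior.lambda_inv.diagonal().max():.1f}]")

cohort = ms.generate_cohort(ms.CohortConfig(n_subjects=1, appointment_range=(10, 10), seed=7))
s = cohort.subjects[0]
X = s.design()
y = s.outcomes[:, 0]  # inattentiveness

state = prior
print("\nvisit  dose  observed  predicted  95% interval")
for a in range(s.n_appointments):
    dist = ms.posterior_predictive(state, X[a])
    lo, hi = dist.interval(0.95)
    print(f"{a + 1:5d}  {s.dosages[a].sum():4.2f}  {y[a]:8.2f}  {dist.location:9.2f}"
          f"  [{lo:6.2f}, {hi:6.2f}]")
    state = ms.nig_update(state, ms.DesignBlock(X[a:a + 1], y[a:a + 1]))

err = np.abs(state.tau[14] - s.true_omega[14, 0])
print(f"\nIR-MPH coefficient: fitted {state.tau[14]:.3f} vs true {s.true_omega[14, 0]:.3f} "
      f"(|error| {err:.3f})")
print("Early predictions carry wide intervals from the sign-only prior; each")
print("update narrows them and pulls the dose-response coefficient toward truth.")
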