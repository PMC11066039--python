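"""Simulate a PD cohort and align it on the common disease timescale.

Generates a 200-patient two-subtype cohort, fits the latent-time joint
mixed-effects model, and prints how well the per-patient time shifts and mean
slopes are recovered.
"""

import numpy as np

import pdprog as pp

cohort = pp.make_fixture("well_separated")
print(f"cohort: {cohort.n_patients} patients, {len(cohort.measurements)} measurements, "
      f"{len(cohort.outcomes)} outcomes; clipping rate {cohort.metadata['clip_rate']:.2%}")

fit = pp.fit_ltjmm(cohort)
print(f"MAP fit converged in {fit.diagnostics['n_iter']} EM iterations")

gt = cohort.ground_truth.set_index("patient_id").loc[fit.params.patients]
corr = np.corrcoef(fit.params.delta, gt["true_delta"])[0, 1]
print(f"corr(estimated time shift, true shift) = {corr:.3f}  "
      "(how accurately patients are placed on the common timescale)")
print(f"estimated sigma_delta = {fit.params.sigma_delta:.2f} years (generating: 3.0)")
print("\nmean slope per outcome (normalized units/year):")
for k, name in enumerate(fit.params.outcomes):
    print(f"  {name:8s} gamma_hat = {fit.params.gamma[k]:.4f}")

res = pp.heldout_last_visit_r2(cohort)
print(f"\nheld-out last-visit R^2 = {res['r2']:.2f} "
      f"({res['n_held_out']} held-out measurements)")
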