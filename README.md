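# pdprog — data-driven Parkinson's disease progression subtyping

Parkinson's disease progresses at very different speeds in different
patients.  That heterogeneity confounds counseling and inflates the sample
sizes of neuroprotection trials — unless it can be decomposed into
*progression subtypes* and exploited.  `pdprog` is a Python library for
exactly that workflow, aimed at biostatisticians and clinical-research
methodologists working with longitudinal cohort data:

1. **Temporal alignment.**  A latent-time joint mixed-effects model (LTJMM)
   fits K clinical outcomes jointly as linear functions of time since
   diagnosis, with a per-patient latent time shift δᵢ shared across
   outcomes:

       y_ijk = xᵢ'β_k + γ_k (t_ijk + δᵢ) + α0_ik + α1_ik t_ijk + ε_ijk

   placing every patient on a *common disease timescale* (t + δᵢ).
2. **Progression scores.**  Model-predicted trajectories on that common
   timescale are standardized into per-patient, per-outcome progression
   scores (change from the common-time origin in SD-at-origin units).
3. **Subtype discovery.**  A recurrent variational autoencoder with a
   Gaussian-mixture latent (VaDER-style, pure numpy with verified manual
   gradients) clusters the score trajectories; the number of clusters is
   chosen by prediction strength against a random-clustering null, and
   assignments are stabilized by consensus over 20 trainings.  On every
   fixture this discovers a *slow-* and a *fast-progressing* subtype.
4. **Characterization.**  Per-subtype mixed-effects progression models,
   Hedges-corrected standardized mean differences pooled per symptom domain
   by a three-level random-effects meta-analysis, baseline logistic
   associations, Cox survival on the common timescale, covariate-adjusted
   cross-sectional comparisons, Benjamini-Hochberg multiplicity control.
5. **Prediction & trial enrichment.**  An L2-penalized logistic regression
   (nested repeated 5×20 cross-validation) predicts a patient's subtype from
   baseline (or baseline + one-year) scores; thresholding the predicted
   fast-subtype probability yields an enrichment curve, and the Edland
   closed-form sample-size formula — validated against a Monte-Carlo trial
   simulator — translates enrichment into smaller required trials.

Clinical PD cohorts are access-restricted, so the package includes a
synthetic-cohort generator (`pdprog.simulate`) reproducing the statistical
structure the analysis assumes: two latent subtypes with distinct slopes,
latent time shifts, correlated random effects, bounded ordinal-like scales,
irregular visits, missingness, and subtype-linked mortality.  All tests and
examples run on these cohorts; see `docs/methods.md` for what that does and
does not demonstrate about real data.

## Worked example

```python
import numpy as np
import pdprog as pp

cohort = pp.make_fixture("well_separated")     # 200 synthetic patients, 7 outcomes
fit = pp.fit_ltjmm(cohort)                     # EM on the marginal posterior
gt = cohort.ground_truth.set_index("patient_id").loc[fit.params.patients]
print(np.corrcoef(fit.params.delta, gt["true_delta"])[0, 1])
```

prints `0.851...` — the correlation between estimated and generating time
shifts, i.e. how accurately patients are placed on the common timescale.
Continuing (`examples/02_subtype_discovery.py`):

```text
prediction strength vs random-clustering null:
 k  statistic  null_mean  null_q95  p_value
 2      1.000      0.560     0.637     0.01
 ...
chosen number of subtypes: 2
consensus assignment: 57 fast / 143 slow
adjusted Rand index vs generating subtypes: 1.000  (1.0 = perfect recovery)
```

k = 2 is the smallest cluster number whose prediction strength beats random
clustering, and the 20-run consensus recovers the generating subtypes
exactly.  The trial-design example (`examples/04_enrichment_trial_design.py`)
then shows the payoff:

```text
baseline+1y nested-CV ROC-AUC: 0.63
at ~30% eligibility the enrolled cohort is 53% fast (prevalence 28%)
required total n without enrichment: 1294
required total n at the enriched fraction: 704 (46% reduction)
Monte-Carlo power at that n: 80.0% (target 80%)
```

Enrolling only patients with a high predicted fast-subtype probability
roughly doubles the fast fraction and nearly halves the required trial size
at unchanged power.

Each script in `examples/` is a short narrative of one capability:
simulation + model fit, subtype discovery, subtype characterization, and
enrichment trial design.

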