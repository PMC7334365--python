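# svdnet

Structural brain-network efficiency and longitudinal cognitive decline in
cerebral small vessel disease (SVD), as a fully synthetic, end-to-end
testable pipeline.

## The scientific problem

SVD — visible on MRI as white matter hyperintensities (WMH), lacunes and
microbleeds — is the leading vascular cause of cognitive impairment, yet the
conventional lesion markers explain cognition poorly. A better candidate
mechanism is disruption of the white matter *network*: reconstruct each
subject's structural connectome from diffusion tractography, summarize it
with graph theory, and ask which network measure best predicts cognitive
performance and its decline over years of follow-up.

`svdnet` implements that analysis chain for researchers in network
neuroscience and vascular cognitive impairment:

1. **Tractography** — deterministic FACT-style streamlining on tensor-field
   phantoms: seeds at centers of voxels with FA > 0.2, fixed-step
   propagation along the principal direction, termination on mask exit,
   FA < 0.2, or a turning angle > 60°.
2. **Connectome construction** — two of the 90 AAL-style regions (45 per
   hemisphere, cerebellum excluded) are connected when a streamline's
   endpoints lie in both; the edge weight is
   `mean-FA × streamline-count / region-volume`, giving an undirected
   weighted 90 × 90 matrix.
3. **Graph metrics** — 21 measures on the binarized and weighted networks
   (density, degree/strength, global and local efficiency, characteristic
   path length, clustering, transitivity, modularity, betweenness,
   assortativity, rich club), plus normalized efficiencies

   E_glob^norm = E_glob(W) / ⟨E_glob(W_null)⟩,  E_loc^norm = E_loc(W) / ⟨E_loc(W_null)⟩

   against degree-preserving (Maslov–Sneppen) null ensembles. Weighted
   shortest paths use edge lengths 1/w; E_glob = ⟨1/d_ij⟩ over node pairs
   with unreachable pairs contributing zero.
4. **Cognitive composites** — raw timed test scores become speed–accuracy
   trade-off (SAT) scores and baseline-normed z-scores, averaged into the
   cognitive index (CI), psychomotor speed (PMS), memory and
   attention–executive function (A&EF); decline = follow-up − baseline.
5. **Feature selection** — elastic net (mixing parameter α = 0.05, near
   ridge, so collinear measures share signal) over the 21 standardized
   measures with unpenalized clinical covariates; penalty chosen by seeded
   10-fold cross-validation; the measure with the largest |coefficient| is
   selected.
6. **Longitudinal modelling** — linear mixed-effects models of each
   composite:

   y_ij = β₀ + βᵀx_i + β_E E_i + β_t t_ij + β_Et E_i t_ij + b_0i + b_1i t_ij + ε_ij

   with correlated subject random intercept and slope (unstructured 2×2
   covariance), fit by maximum likelihood; the efficiency-by-time
   interaction β_Et is tested by a likelihood-ratio test against the
   null model without it, χ²(1) = 2(ℓ_full − ℓ_null).

Because clinical cohort data of this kind is not publicly deposited, the
package ships a first-class **synthetic-data module**: per-subject
small-world connectomes (Watts–Strogatz backbone, log-normal weights)
degraded by a latent lesion-severity variable that also drives the MRI
covariates, three-visit cognitive trajectories (0 / 5.3 / 8.7 years,
retention 436/434/308) generated by the mixed model above, and
severity-ranked (informative) attrition.

## Worked example

```python
from svdnet import SimulationConfig, simulate_cohort, fit_lme, likelihood_ratio_test

cfg = SimulationConfig(n_subjects=200, n_retained=(200, 199, 140), seed=3)
cohort = simulate_cohort(cfg)

null = fit_lme(cohort.long, "ci", "global_efficiency_w",
               baseline=cohort.subjects, with_interaction=False)
full = fit_lme(cohort.long, "ci", "global_efficiency_w",
               baseline=cohort.subjects, with_interaction=True)
print(full.fixed_effects.loc["predictor:time_years"])
print(likelihood_ratio_test(null, full))
```

prints (abridged)

```
estimate    0.036715
se          0.006012
ci_low      0.024931
ci_high     0.048499
p           1.016940e-09
Name: predictor:time_years, dtype: float64
LRTResult(chi_square=34.486, df=1, p_value=4.29e-09)
```

The interaction estimate 0.037 ± 0.006 recovers the generating coefficient
(0.04 z-units per year per SD of baseline global efficiency) within one
standard error: subjects with lower baseline network efficiency decline
faster, and the likelihood-ratio test strongly prefers the model with the
efficiency-by-time interaction.

The same analysis runs from the shell:

```bash
svdnet simulate --seed 3 --out cohort
svdnet run --seed 3 --out results/   # full pipeline incl. phantom tracking
```

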