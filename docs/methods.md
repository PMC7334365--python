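# Methods

This note documents the models, conventions and numerical choices behind
`svdnet`, in the order the pipeline runs them.

## Tractography

Tracking is a fixed-step approximation of classical FACT (fiber assignment
by continuous tracking). From each seed — the center of every masked voxel
with FA above the start threshold (default 0.2) — two branches propagate in
opposite directions. Each step advances `step_size` (default half the voxel
size, 1.25 mm at the default 2.5 mm isotropic grid) along the principal
direction of the *current* voxel, sign-aligned with the previous step
(principal directions are axial, so their sign carries no information; the
initial direction is canonicalized by making its largest component
positive, which also makes streamlines invariant to a global sign flip of
the direction field). A branch terminates when it leaves the brain mask,
enters a voxel with FA below the stop threshold (0.2), when the angle
between the principal directions of successive distinct voxels exceeds
`max_turn_angle` (60°; evaluated after sign alignment, so the effective
angle is always ≤ 90°), or after `max_steps`. Terminating points are not
appended, so every stored point lies inside the mask and the endpoints sit
in the last accepted voxel.

Choices that classical implementations leave open and we fix explicitly:
direction lookup is nearest-voxel rather than boundary-crossing (with
step ≤ half voxel no voxel is skipped along axis-aligned bundles);
tracking is bidirectional (a `bidirectional` flag disables it); there is
no minimum-length filter, but streamlines with fewer than two points are
discarded as degenerate. A streamline's `mean_fa` is the mean FA over the
ordered set of distinct voxels it visits.

## Connectome construction

Regions i and j are connected if a streamline's first and last points fall
in the voxels of parcels i and j (nearest-voxel containment, 0-based
indices, voxel centers at `(index + 0.5) · voxel_size`; no parcel
dilation). Streamlines with a background endpoint or both endpoints in the
same parcel are discarded — self-loops are excluded by the zero-diagonal
contract of the output matrix. The edge weight is

    w_ij = (mean over connecting streamlines of mean_fa) · N_ij / norm(V_i, V_j)

with volumes in cm³. The volume normalization is the **mean** of the two
endpoint-region volumes by default; the literature is ambiguous between
one region's volume, the sum and the mean, so `volume_norm` exposes
`mean | sum | geometric`. The mean keeps weights on the scale of
FA × count per unit volume, and any fixed choice only rescales weights
globally, which the normalized efficiencies are invariant to.

## Graph measures

The 21-measure vector spans the families commonly reported for structural
networks: nine binary measures (density, mean degree, global efficiency,
local efficiency, characteristic path length, clustering, transitivity,
modularity, mean betweenness), eight weighted counterparts (mean strength
replacing density/degree), degree assortativity, the mean rich-club
coefficient, and the two null-normalized efficiencies. Published reports
rarely enumerate their exact measure sets; this list is this package's
canonical definition and is fixed in `svdnet.metrics.METRIC_NAMES`.

Conventions:

* Weighted path length of an edge is `1/w` (the standard convention for
  FA-weighted connectomes); `-log(w/w_max)` is available via
  `distance="neglog"`.
* Global efficiency is the mean of `1/d_ij` over ordered pairs; unreachable
  pairs contribute 0, so disconnected nodes depress efficiency instead of
  breaking it. Characteristic path length returns an `inf` sentinel when
  any pair is unreachable; `compute_all` records the subject in a
  `disconnected` flag, and the elastic-net stage imputes the column's
  maximum finite value — this mirrors the standard argument for preferring
  efficiency over path length in populations where a few percent of
  subjects have disconnected nodes.
* Local efficiency of a node is the global efficiency of the subgraph
  induced by its neighbours (weights retained in the weighted variant);
  nodes with fewer than two neighbours contribute 0.
* Weighted clustering uses the geometric mean of triangle weights scaled by
  the maximum weight (Onnela); weighted transitivity divides the summed
  triangle intensities by the number of connected triples.
* Modularity returns the best Q over three deterministic candidate
  partitions — CNM greedy agglomeration, seeded Louvain, and a
  leading-eigenvector bisection — each refined by greedy single-node moves
  until no move improves Q. This costs little at 90 nodes and removes the
  known pathologies of any single heuristic.
* Betweenness is mean node betweenness with unordered-pair counting and
  fractional attribution over tied shortest paths.
* The rich-club coefficient φ(k) = 2E₍>k₎ / (N₍>k₎(N₍>k₎−1)) is averaged
  over k = 1..k_max, skipping levels with fewer than two qualifying nodes;
  it is reported raw (not null-normalized), since only the efficiencies
  carry a null normalization in the reported vector.

**Null models.** Degree-preserving nulls are Maslov–Sneppen double-edge
swaps: `swaps_per_edge × m` proposals (default 10 per edge), rejecting any
proposal creating self-loops or multi-edges, so graphs with no valid swap
(a triangle) are returned unchanged. Weighted nulls reassign the observed
weight multiset uniformly at random onto the rewired topology. The
normalized efficiencies divide the observed weighted global/local
efficiency by the ensemble mean of the same measure; the default ensemble
size in cohort evaluations is 20 nulls per subject, which puts the Monte
Carlo error of the ensemble mean well below the between-subject spread.

## Synthetic cohort generator

The generator emulates the statistical structure the downstream analysis
assumes, not raw imaging. Defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 436 | cohort size |
| `visit_times` | 0, 5.3, 8.7 y | assessment waves |
| `n_retained` | 436, 434, 308 | retention per wave |
| `n_nodes` | 90 | AAL-style parcels |
| `base_degree`, `rewire_prob` | 14, 0.12 | Watts–Strogatz backbone |
| `weight_law` | logN(−1, 0.6) | edge weights |
| `severity_law` | Beta(2, 5) | latent lesion severity s_i ∈ [0,1] |
| `lesion` | p_del = 0.4·s, attenuation 1 − 0.5·s | network damage |
| `random_effects` | SD 0.55 / 0.055, corr −0.3 | intercept/slope (z-units, z/y) |
| `resid_sd` | 0.30 | residual noise (z-units) |
| β_Et defaults | 0.04 (CI, PMS), 0.08 (memory), 0.08 (A&EF) | interaction, z/y per SD |

Each subject's connectome starts from a Watts–Strogatz ring lattice,
receives i.i.d. log-normal weights, then loses each edge independently
with probability `0.4·s_i` and has surviving weights attenuated by
`1 − 0.5·s_i`. The backbone parameters (degree 14, rewiring 0.12) were
calibrated once so that the cohort means of the null-normalized
efficiencies sit at the descriptive values the analysis should reproduce
(≈ 0.91 normalized global, ≈ 3.2 normalized local); they are configuration,
not constants.

Covariates are noisy monotone functions of severity — the link functions
(linear-Gaussian for continuous covariates, Poisson with log-linear rates
for lesion counts) are this module's choice, with marginals matched to a
realistic SVD cohort demography (age 65.2 ± 8.8 y, 45.6 % women, WMH
median ≈ 6.4 ml rising with severity, total brain volume 1097.8 ± 120.8 ml
falling with severity, ≈ 22 % with lacunes and ≈ 15 % with microbleeds).
The latent severity is stored per subject so recovery tests can correlate
it with the generated covariates.

Outcomes follow the random-intercept-and-slope model of the analysis
itself, with the predictor network measure standardized across the
baseline cohort (so β_Et is per SD of the measure; the generator and the
fitting stage share this convention). Attrition drops the
highest-severity subjects first, emulating the informative attrition of
ageing cohorts; `attrition="random"` switches to completely-at-random
dropout for sensitivity analyses.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: no diffusion signal, scanner noise,
registration error, or WMH spatial structure; covariate links are
convenient parametric choices; and, notably, the severity-ranked dropout
selects only on variables the models adjust for (covariates and baseline
efficiency), so it is *ignorable* for the ML fits — estimates stay
consistent and only lose precision. Real attrition can select on the
latent decline trajectory itself and then genuinely biases estimates; that
mechanism is outside this generator, and the test suite asserts the
ignorable behaviour that actually holds here.

## Cognitive composites

SAT (speed–accuracy trade-off) = correct/seconds; any monotone variant
only rescales a measure before z-scoring, so composites are robust to this
choice. All z-scores use *baseline* cohort norms at every visit, so
decline (follow-up − baseline) is in baseline-SD units. The Stroop
interference ratio (color-word SAT over the mean of reading and naming
SATs) is z-scored and negated before entering A&EF, keeping every
composite "higher = better". CI averages four components (the RAVLT
learning-trials and delayed-recall z-scores are first averaged into one
component); PMS three; memory six; A&EF three. A composite with fewer
than half its components available is missing.

The generator writes composites directly; `synthesize_raw_scores` inverts
the composite arithmetic to emit a raw battery that reproduces them to
1e-10 (timed tests get a fixed 60 s duration and a real-valued correct
count — the battery is synthetic, not a literal transcript).

## Elastic net with unpenalized covariates

Objective: `1/(2n)‖y − Xβ − Zγ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖²)` with X the
standardized 21-measure block, Z the intercept plus covariates, and
α = 0.05. γ is profiled out exactly — minimizing over γ gives the same
objective with X and y projected off span(Z) — so each λ needs one
coordinate-descent solve on the projected design; this is the exact joint
solution with unpenalized covariates, not a two-step approximation.
λ is chosen on a 60-point geometric path (down to 1e-3 of the smallest
all-zero λ) by 10-fold cross-validation, folds stratified by outcome
quartile and seeded (plain K-fold when strata are smaller than the fold
count); the CV-minimum rule is the default, the one-standard-error rule is
available. Lacune and microbleed counts enter the elastic net as presence
indicators and the mixed models as counts, matching how adjustment sets
are usually reported in each context. Coefficients are reported on the
standardized-predictor scale, and the selected measure maximizes the
absolute coefficient.

## Mixed models and the likelihood-ratio test

Both models — null (covariates + measure + time) and full (adding
measure × time) — are fit by maximum likelihood, not REML, because they
differ in fixed effects and the LRT is only valid on ML fits. Random
effects are a correlated subject intercept and slope (unstructured 2 × 2
covariance). Fits use statsmodels' MixedLM (L-BFGS, 400 iterations); a
non-converged fit is retried and finally falls back to independent
intercept and slope, flagged on the result. Wald 95 % intervals are
reported per fixed effect. The LRT is χ² = 2(ℓ_full − ℓ_null) on df = the
number of added fixed effects (1 here); a negative statistic beyond 1e-6
triggers a refit warning and is clamped to zero. The implementation is
cross-checked against lme4's `lmer` (ML) in the test suite.

## Problem sizes and determinism

Cohort evaluations use 20-null ensembles per subject and 50 replicate
cohorts for interaction-coefficient recovery; with 436 subjects these runs
complete in minutes on a single core thanks to JIT-compiled local
efficiency and rewiring kernels. All randomness flows from a single seed
through `numpy.random.SeedSequence` children: subject generation, outcome
generation, null ensembles and CV folds are separately and reproducibly
seeded, and identical seeds give byte-identical outputs end to end.

## Known limitations

* The fixed-step tracker is a deliberate simplification of
  boundary-crossing FACT; on oblique bundles it can visit voxels in a
  slightly different order than an exact implementation.
* The 21-measure list is a canonical choice, not a reconstruction of any
  particular study's (typically supplementary and unpublished) list.
* Mixed-model fits on cohorts with near-zero random-effect variances can
  sit on the boundary of the parameter space; the LRT p-values there are
  conservative, which the type-I calibration test quantifies.
* The generator's attrition is ignorable by construction (see above);
  conclusions about real informative attrition cannot be drawn from it.
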