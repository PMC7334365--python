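"""Synthetic SVD cohort generation.

Emulates a longitudinal small-vessel-disease cohort: per-subject small-world
structural connectomes degraded by a latent lesion-severity variable, MRI
covariates (WMH volume, lacunes, microbleeds, total brain volume, ...) that
are noisy monotone functions of that severity, and three-visit cognitive
composite trajectories generated by a random-intercept-and-slope mixed model
whose slope depends on standardized baseline network efficiency.

Attrition is severity-ranked by default (subjects with the worst latent
severity drop out first), emulating the informative attrition of ageing
cohorts; completely-at-random dropout is available for sensitivity analyses.
All randomness flows from a single seed through ``numpy.random.SeedSequence``
children, so subject generation and outcome generation are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .config import SimulationConfig
from .connectome import Connectome
from .metrics import global_efficiency, local_efficiency

__all__ = [
    "CohortData",
    "simulate_connectome",
    "simulate_subjects",
    "simulate_outcomes",
    "simulate_cohort",
]

COVARIATE_COLUMNS = ("age", "sex", "education", "depression", "wmh_ml",
                     "n_lacunes", "n_microbleeds", "tbv_ml")


@dataclass
class CohortData:
    """Everything one simulated cohort produces."""

    subjects: pd.DataFrame                    # one row per subject
    long: pd.DataFrame                        # one row per subject-visit
    connectomes: list[Connectome] | None = None
    config: SimulationConfig | None = None
    predictor_scaling: dict[str, tuple[float, float]] = field(
        default_factory=dict)                 # metric -> (mean, sd) at baseline


def simulate_connectome(config: SimulationConfig, severity: float,
                        rng: np.random.Generator) -> Connectome:
    """One lesioned small-world connectome.

    Starts from a Watts–Strogatz ring-lattice topology (``n_nodes``,
    ``base_degree``, ``rewire_prob``), assigns i.i.d. log-normal weights,
    then deletes each edge with probability ``deletion_scale * severity``
    and attenuates surviving weights by ``1 - attenuation_scale * severity``.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must be in [0, 1]")
    if config.base_degree < 2:
        raise ValueError("base_degree must be at least 2")
    n = config.n_nodes
    ws_seed = int(rng.integers(0, 2 ** 31 - 1))
    G = nx.watts_strogatz_graph(n, config.base_degree, config.rewire_prob,
                                seed=ws_seed)
    W = np.zeros((n, n))
    edges = np.array(G.edges(), dtype=int)
    wl = config.weight_law
    weights = rng.lognormal(mean=wl.mu, sigma=wl.sigma, size=len(edges))
    p_del = min(1.0, config.lesion.deletion_scale * severity)
    atten = max(0.0, 1.0 - config.lesion.attenuation_scale * severity)
    keep = rng.random(len(edges)) >= p_del
    for (i, j), w, k in zip(edges, weights, keep):
        if k:
            W[i, j] = W[j, i] = w * atten
    volumes = rng.lognormal(mean=np.log(8000.0), sigma=0.35, size=n)
    return Connectome(weights=W, node_volumes=volumes)


def _covariates_from_severity(severity: np.ndarray,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Noisy monotone covariate links calibrated to the cohort's demography.

    Continuous covariates are linear-Gaussian in standardized severity
    (age 65.2 +/- 8.8 y, TBV 1097.8 +/- 120.8 ml, log-normal WMH around a
    6.4 ml median); lesion counts are Poisson with log-linear severity rates
    tuned so roughly a fifth of subjects have lacunes and a sixth have
    microbleeds.
    """
    n = severity.size
    zs = (severity - severity.mean()) / max(severity.std(), 1e-12)
    age = 65.2 + 8.8 * (0.45 * zs + np.sqrt(1 - 0.45 ** 2) *
                        rng.standard_normal(n))
    sex = (rng.random(n) < 0.456).astype(int)        # 1 = woman
    education = np.clip(np.round(5.0 - 0.8 * zs + 1.1 *
                                 rng.standard_normal(n)), 1, 7).astype(int)
    depression = np.clip(11.0 + 4.0 * zs + 6.0 * rng.standard_normal(n),
                         0.0, None)
    wmh_ml = np.exp(np.log(6.4) + 0.9 * zs + 0.55 * rng.standard_normal(n))
    n_lacunes = rng.poisson(np.exp(-2.3 + 2.6 * severity))
    n_microbleeds = rng.poisson(np.exp(-2.7 + 2.6 * severity))
    tbv_ml = 1097.8 + 120.8 * (-0.35 * zs + np.sqrt(1 - 0.35 ** 2) *
                               rng.standard_normal(n))
    return pd.DataFrame({
        "age": age, "sex": sex, "education": education,
        "depression": depression, "wmh_ml": wmh_ml,
        "n_lacunes": n_lacunes, "n_microbleeds": n_microbleeds,
        "tbv_ml": tbv_ml,
    })


def simulate_subjects(config: SimulationConfig,
                      seed: int | np.random.SeedSequence | None = None,
                      metrics: tuple[str, ...] | None = None,
                      keep_connectomes: bool = False) -> CohortData:
    """Draw severities, connectomes, covariates and baseline network metrics.

    ``metrics`` restricts which network measures are computed per subject
    (default: the measures any configured outcome uses as predictor, plus
    weighted global efficiency). Outcome trajectories are added separately by
    :func:`simulate_outcomes`.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)

    if metrics is None:
        metrics = tuple(dict.fromkeys(
            ["global_efficiency_w"] +
            [spec.predictor for spec in config.outcomes.values()]))

    sev = rng.beta(config.severity_law.a, config.severity_law.b,
                   size=config.n_subjects)
    covs = _covariates_from_severity(sev, rng)

    conns: list[Connectome] = []
    metric_rows = {m: np.empty(config.n_subjects) for m in metrics}
    for i in range(config.n_subjects):
        conn = simulate_connectome(config, sev[i], rng)
        for m in metrics:
            metric_rows[m][i] = _compute_metric(conn, m)
        if keep_connectomes:
            conns.append(conn)

    subjects = pd.DataFrame({
        "subject_id": [f"sub-{i:04d}" for i in range(config.n_subjects)],
        "lesion_severity": sev,
    })
    subjects = pd.concat([subjects, covs], axis=1)
    for m in metrics:
        subjects[m] = metric_rows[m]

    scaling = {m: (float(subjects[m].mean()), float(subjects[m].std(ddof=0)))
               for m in metrics}
    return CohortData(subjects=subjects, long=pd.DataFrame(),
                      connectomes=conns if keep_connectomes else None,
                      config=config, predictor_scaling=scaling)


def _compute_metric(conn: Connectome, name: str) -> float:
    W = conn.weights
    if name == "global_efficiency_w":
        return global_efficiency(W, weighted=True)
    if name == "local_efficiency_w":
        return local_efficiency(W, weighted=True)
    if name == "global_efficiency_b":
        return global_efficiency((W > 0).astype(float), weighted=False)
    if name == "local_efficiency_b":
        return local_efficiency((W > 0).astype(float), weighted=False)
    raise ValueError(f"unsupported per-subject metric {name!r}")


def simulate_outcomes(cohort: CohortData,
                      seed: int | np.random.SeedSequence | None = None
                      ) -> pd.DataFrame:
    """Generate the long-format visit table with composite trajectories.

    For each composite the linear predictor is
    ``b0 + sum_c beta_c z(x_c) + beta_E E_i + beta_t t + beta_Et E_i t``
    with ``E_i`` the predictor network measure standardized across the
    baseline cohort, plus a bivariate-normal subject random intercept and
    slope and i.i.d. Gaussian residuals. Attrition then truncates each visit
    to its retained count, dropping the highest-severity subjects first
    (or uniformly at random when ``attrition='random'``).
    """
    config = cohort.config
    if config is None:
        raise ValueError("cohort carries no config")
    if seed is None:
        seed = np.random.SeedSequence(config.seed).spawn(1)[0]
    rng = np.random.default_rng(seed)
    subjects = cohort.subjects
    n = len(subjects)
    times = np.asarray(config.visit_times)
    n_visits = times.size

    # standardized covariate design (fixed across outcomes)
    xz = np.zeros((n, len(COVARIATE_COLUMNS)))
    betas = np.zeros(len(COVARIATE_COLUMNS))
    for k, c in enumerate(COVARIATE_COLUMNS):
        col = subjects[c].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        xz[:, k] = (col - col.mean()) / sd if sd > 0 else 0.0
        betas[k] = config.covariate_effects.get(c, 0.0)
    cov_term = xz @ betas

    rows: dict[str, np.ndarray] = {}
    for name, spec in config.outcomes.items():
        mu_m, sd_m = cohort.predictor_scaling[spec.predictor]
        E = (subjects[spec.predictor].to_numpy() - mu_m) / max(sd_m, 1e-12)
        re_cov = config.random_effects.cov()
        b = (rng.multivariate_normal([0.0, 0.0], re_cov, size=n)
             if re_cov.any() else np.zeros((n, 2)))
        eps = (config.resid_sd * rng.standard_normal((n, n_visits))
               if config.resid_sd > 0 else np.zeros((n, n_visits)))
        y = (config.intercept + cov_term + spec.beta_predictor * E)[:, None] \
            + (spec.beta_time + spec.beta_interaction * E + b[:, 1])[:, None] \
            * times[None, :] + b[:, 0][:, None] + eps
        rows[name] = y

    # attrition: nested retained sets
    order = (np.argsort(subjects["lesion_severity"].to_numpy(),
                        kind="stable")
             if config.attrition == "severity" else rng.permutation(n))
    records = []
    for v, (t, n_keep) in enumerate(zip(times, config.n_retained)):
        kept = np.sort(order[:n_keep])
        for i in kept:
            rec = {"subject_id": subjects["subject_id"].iat[i],
                   "visit": v + 1, "time_years": float(t)}
            for name in config.outcomes:
                rec[name] = float(rows[name][i, v])
            for c in COVARIATE_COLUMNS:
                rec[c] = subjects[c].iat[i]
            records.append(rec)
    long = pd.DataFrame.from_records(records)
    return long.sort_values(["subject_id", "visit"]).reset_index(drop=True)


def simulate_cohort(config: SimulationConfig,
                    keep_connectomes: bool = False) -> CohortData:
    """Full cohort: subjects, connectomes (optional) and visit table."""
    ss = np.random.SeedSequence(config.seed)
    subj_ss, outcome_ss = ss.spawn(2)
    cohort = simulate_subjects(config, seed=subj_ss,
                               keep_connectomes=keep_connectomes)
    cohort.long = simulate_outcomes(cohort, seed=outcome_ss)
    return cohort
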