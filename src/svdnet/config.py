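"""Simulation and pipeline configuration.

A single :class:`SimulationConfig` drives cohort generation: network topology
(Watts–Strogatz small-world backbone), log-normal edge weights, a latent
per-subject lesion-severity variable that both prunes the network and shapes
the MRI covariates, and a random-intercept/random-slope longitudinal outcome
model whose slope depends on baseline network efficiency.

Configs round-trip through YAML so every pipeline run can log the resolved
configuration alongside its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

__all__ = [
    "WeightLaw",
    "SeverityLaw",
    "LesionModel",
    "RandomEffects",
    "OutcomeSpec",
    "SimulationConfig",
    "load_config",
    "save_config",
]


@dataclass
class WeightLaw:
    """Log-normal law for edge weights: exp(Normal(mu, sigma))."""

    mu: float = -1.0
    sigma: float = 0.6


@dataclass
class SeverityLaw:
    """Beta law for the latent lesion severity s_i in [0, 1]."""

    a: float = 2.0
    b: float = 5.0


@dataclass
class LesionModel:
    """Severity-dependent network damage.

    Each edge is deleted independently with probability
    ``deletion_scale * s`` and surviving weights are multiplied by
    ``1 - attenuation_scale * s``.
    """

    deletion_scale: float = 0.4
    attenuation_scale: float = 0.5


@dataclass
class RandomEffects:
    """Bivariate-normal subject random intercept and slope (unstructured)."""

    sd_intercept: float = 0.55
    sd_slope: float = 0.055
    corr: float = -0.3

    def cov(self) -> np.ndarray:
        c = self.corr * self.sd_intercept * self.sd_slope
        return np.array([[self.sd_intercept ** 2, c],
                         [c, self.sd_slope ** 2]])


@dataclass
class OutcomeSpec:
    """Fixed-effect structure of one longitudinal cognitive composite.

    ``beta_interaction`` is in z-units per year per SD of the predictor
    network measure (the predictor is standardized across the baseline
    cohort before entering the linear predictor).
    """

    predictor: str = "global_efficiency_w"
    beta_predictor: float = 0.10
    beta_time: float = -0.05
    beta_interaction: float = 0.04


def _default_outcomes() -> dict[str, OutcomeSpec]:
    return {
        "ci": OutcomeSpec("global_efficiency_w", 0.10, -0.05, 0.04),
        "pms": OutcomeSpec("global_efficiency_w", 0.10, -0.06, 0.04),
        "memory": OutcomeSpec("global_efficiency_w", 0.10, -0.05, 0.08),
        "aef": OutcomeSpec("local_efficiency_b", 0.10, -0.05, 0.08),
    }


def _default_covariate_effects() -> dict[str, float]:
    # per-SD effects of the (standardized) covariates on the composite
    return {
        "age": -0.15,
        "sex": 0.05,
        "education": 0.15,
        "depression": -0.05,
        "wmh_ml": -0.10,
        "n_lacunes": -0.05,
        "n_microbleeds": -0.03,
        "tbv_ml": 0.10,
    }


@dataclass
class SimulationConfig:
    """Full specification of a synthetic longitudinal SVD cohort."""

    n_subjects: int = 436
    visit_times: tuple[float, ...] = (0.0, 5.3, 8.7)
    n_retained: tuple[int, ...] = (436, 434, 308)
    n_nodes: int = 90
    base_degree: int = 14
    rewire_prob: float = 0.12
    weight_law: WeightLaw = field(default_factory=WeightLaw)
    severity_law: SeverityLaw = field(default_factory=SeverityLaw)
    lesion: LesionModel = field(default_factory=LesionModel)
    covariate_effects: dict[str, float] = field(
        default_factory=_default_covariate_effects)
    outcomes: dict[str, OutcomeSpec] = field(default_factory=_default_outcomes)
    random_effects: RandomEffects = field(default_factory=RandomEffects)
    resid_sd: float = 0.30
    intercept: float = 0.0
    attrition: str = "severity"  # "severity" (informative) or "random" (MCAR)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if len(self.visit_times) != len(self.n_retained):
            raise ValueError("visit_times and n_retained must align")
        if any(t2 <= t1 for t1, t2 in
               zip(self.visit_times, self.visit_times[1:])):
            raise ValueError("visit_times must be strictly increasing")
        if any(n2 > n1 for n1, n2 in zip(self.n_retained, self.n_retained[1:])):
            raise ValueError("n_retained must be non-increasing")
        if max(self.n_retained) > self.n_subjects:
            raise ValueError("n_retained cannot exceed n_subjects")
        if not 0.0 <= self.rewire_prob <= 1.0:
            raise ValueError("rewire_prob must be in [0, 1]")
        if self.base_degree < 2:
            raise ValueError("base_degree must be at least 2")
        if self.attrition not in ("severity", "random"):
            raise ValueError("attrition must be 'severity' or 'random'")
        cov = self.random_effects.cov()
        if not np.allclose(cov, cov.T) or np.linalg.eigvalsh(cov).min() < -1e-12:
            raise ValueError("random-effects covariance must be symmetric PSD")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def conv(obj):
            if dataclasses.is_dataclass(obj):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        d = {f.name: conv(getattr(self, f.name))
             for f in dataclasses.fields(self)}
        d["outcomes"] = {k: dataclasses.asdict(v)
                         for k, v in self.outcomes.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "visit_times" in d:
            d["visit_times"] = tuple(d["visit_times"])
        if "n_retained" in d:
            d["n_retained"] = tuple(d["n_retained"])
        for key, sub in (("weight_law", WeightLaw),
                         ("severity_law", SeverityLaw),
                         ("lesion", LesionModel),
                         ("random_effects", RandomEffects)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "outcomes" in d:
            d["outcomes"] = {k: OutcomeSpec(**v) if isinstance(v, dict) else v
                             for k, v in d["outcomes"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(data.get("simulation", data))


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"simulation": config.to_dict()}, fh,
                       default_flow_style=False, sort_keys=False)
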