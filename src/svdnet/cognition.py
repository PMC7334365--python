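"""Composite cognitive scores from a timed neuropsychological battery.

Raw test scores become z-scores against baseline cohort norms and are
averaged into four composites:

* **CI** (cognitive index): one-letter memory-scanning SAT, Stroop reading
  SAT, symbol-digit substitution, and the mean of the RAVLT learning-trials
  and delayed-recall z-scores.
* **PMS** (psychomotor speed): one-letter memory-scanning SAT, Stroop
  reading SAT, symbol-digit substitution.
* **Memory**: RAVLT immediate and delayed recall, Rey Complex Figure
  immediate and delayed recall, and the 2- and 3-letter memory-scanning SATs.
* **A&EF** (attention & executive function): Stroop interference (color-word
  SAT divided by the mean of the reading and naming SATs, z-score negated so
  higher is better), verbal fluency, and the Verbal Series Attention Test SAT.

SAT (speed-accuracy trade-off) scores are correct responses per second.
Follow-up visits are standardized against *baseline* norms so that decline
(follow-up minus baseline) is expressed in baseline-SD units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Norms", "DEFAULT_NORMS", "sat_score", "zscore_vs_baseline",
           "composite_scores", "decline", "synthesize_raw_scores",
           "RAW_COLUMNS"]

#: Measures entering the composites, with the score actually z-scored
#: (an SAT for timed tests, the raw score otherwise).
MEASURES = (
    "ppmst1_sat", "ppmst2_sat", "ppmst3_sat",
    "stroop_read_sat", "stroop_name_sat", "stroop_interference",
    "sdst", "ravlt_trials", "ravlt_delayed",
    "rcft_immediate", "rcft_delayed", "fluency", "vsat_sat",
)

RAW_COLUMNS = (
    "ppmst_1letter_correct", "ppmst_1letter_seconds",
    "ppmst_2letter_correct", "ppmst_2letter_seconds",
    "ppmst_3letter_correct", "ppmst_3letter_seconds",
    "stroop_reading_correct", "stroop_reading_seconds",
    "stroop_naming_correct", "stroop_naming_seconds",
    "stroop_colorword_correct", "stroop_colorword_seconds",
    "sdst_score", "ravlt_trials_mean", "ravlt_delayed",
    "rcft_immediate", "rcft_delayed", "fluency_score",
    "vsat_correct", "vsat_seconds",
)


@dataclass
class Norms:
    """Baseline mean and SD per measure, used for all visits."""

    mean: dict[str, float]
    sd: dict[str, float]

    def z(self, name: str, value):
        sd = self.sd[name]
        if sd == 0:
            raise ValueError(f"zero baseline SD for {name!r}")
        return (value - self.mean[name]) / sd


DEFAULT_NORMS = Norms(
    mean={
        "ppmst1_sat": 0.90, "ppmst2_sat": 0.55, "ppmst3_sat": 0.40,
        "stroop_read_sat": 1.60, "stroop_name_sat": 1.20,
        "stroop_interference": 0.45,
        "sdst": 28.0, "ravlt_trials": 8.5, "ravlt_delayed": 7.0,
        "rcft_immediate": 16.0, "rcft_delayed": 15.0,
        "fluency": 23.0, "vsat_sat": 0.95,
    },
    sd={
        "ppmst1_sat": 0.06, "ppmst2_sat": 0.05, "ppmst3_sat": 0.04,
        "stroop_read_sat": 0.12, "stroop_name_sat": 0.10,
        "stroop_interference": 0.035,
        "sdst": 6.0, "ravlt_trials": 2.0, "ravlt_delayed": 2.5,
        "rcft_immediate": 5.0, "rcft_delayed": 5.0,
        "fluency": 6.0, "vsat_sat": 0.06,
    },
)


def sat_score(correct, seconds):
    """Speed-accuracy trade-off: correct responses per second."""
    seconds = np.asarray(seconds, dtype=float)
    if (seconds <= 0).any():
        raise ValueError("test duration must be positive")
    return np.asarray(correct, dtype=float) / seconds


def zscore_vs_baseline(values, baseline_mean: float, baseline_sd: float):
    """(x - baseline_mean) / baseline_sd; SD must be positive."""
    if baseline_sd == 0:
        raise ValueError("baseline SD must be nonzero")
    return (np.asarray(values, dtype=float) - baseline_mean) / baseline_sd


def _measures_from_raw(raw: pd.DataFrame) -> pd.DataFrame:
    m = pd.DataFrame(index=raw.index)
    m["ppmst1_sat"] = sat_score(raw["ppmst_1letter_correct"],
                                raw["ppmst_1letter_seconds"])
    m["ppmst2_sat"] = sat_score(raw["ppmst_2letter_correct"],
                                raw["ppmst_2letter_seconds"])
    m["ppmst3_sat"] = sat_score(raw["ppmst_3letter_correct"],
                                raw["ppmst_3letter_seconds"])
    m["stroop_read_sat"] = sat_score(raw["stroop_reading_correct"],
                                     raw["stroop_reading_seconds"])
    m["stroop_name_sat"] = sat_score(raw["stroop_naming_correct"],
                                     raw["stroop_naming_seconds"])
    cw_sat = sat_score(raw["stroop_colorword_correct"],
                       raw["stroop_colorword_seconds"])
    m["stroop_interference"] = cw_sat / (
        (m["stroop_read_sat"] + m["stroop_name_sat"]) / 2.0)
    m["sdst"] = raw["sdst_score"]
    m["ravlt_trials"] = raw["ravlt_trials_mean"]
    m["ravlt_delayed"] = raw["ravlt_delayed"]
    m["rcft_immediate"] = raw["rcft_immediate"]
    m["rcft_delayed"] = raw["rcft_delayed"]
    m["fluency"] = raw["fluency_score"]
    m["vsat_sat"] = sat_score(raw["vsat_correct"], raw["vsat_seconds"])
    return m


def _nanmean_if_half(cols: list[pd.Series]) -> pd.Series:
    """Mean of available components when at least half are present."""
    stacked = pd.concat(cols, axis=1)
    n_ok = stacked.notna().sum(axis=1)
    out = stacked.mean(axis=1, skipna=True)
    out[n_ok < (stacked.shape[1] + 1) // 2] = np.nan
    return out


def composite_scores(raw: pd.DataFrame,
                     norms: Norms = DEFAULT_NORMS) -> pd.DataFrame:
    """CI / PMS / memory / A&EF composites from raw test scores.

    The Stroop interference z-score is negated before entering A&EF so every
    composite reads "higher = better". A composite is missing when fewer
    than half of its components are available.
    """
    m = _measures_from_raw(raw)
    z = pd.DataFrame({name: norms.z(name, m[name]) for name in MEASURES},
                     index=raw.index)
    ravlt_combo = (z["ravlt_trials"] + z["ravlt_delayed"]) / 2.0
    out = pd.DataFrame(index=raw.index)
    out["ci"] = _nanmean_if_half(
        [z["ppmst1_sat"], z["stroop_read_sat"], z["sdst"], ravlt_combo])
    out["pms"] = _nanmean_if_half(
        [z["ppmst1_sat"], z["stroop_read_sat"], z["sdst"]])
    out["memory"] = _nanmean_if_half(
        [z["ravlt_trials"], z["ravlt_delayed"], z["rcft_immediate"],
         z["rcft_delayed"], z["ppmst2_sat"], z["ppmst3_sat"]])
    out["aef"] = _nanmean_if_half(
        [-z["stroop_interference"], z["fluency"], z["vsat_sat"]])
    if out.isna().all(axis=1).any():
        raise ValueError("a visit has all composite components missing")
    return out


def decline(baseline: pd.DataFrame, followup: pd.DataFrame) -> pd.DataFrame:
    """Follow-up minus baseline, componentwise (baseline-SD units)."""
    cols = ["ci", "pms", "memory", "aef"]
    return followup[cols].reset_index(drop=True) \
        - baseline[cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# inverse mapping: composites -> a consistent raw battery
# ---------------------------------------------------------------------------

def synthesize_raw_scores(composites: pd.DataFrame,
                          norms: Norms = DEFAULT_NORMS,
                          seconds: float = 60.0) -> pd.DataFrame:
    """Raw test scores that reproduce the given composites exactly.

    Used by the synthetic-cohort generator when a raw battery is requested:
    component z-scores are chosen so that recomputing the composites via
    :func:`composite_scores` returns the input (to numerical precision).
    Timed tests are emitted with a fixed duration and a real-valued correct
    count; counts are nonnegative for composite values in a realistic range
    but are not rounded to integers, so the battery is synthetic rather than
    a literal test transcript.
    """
    ci = composites["ci"].to_numpy(dtype=float)
    pms = composites["pms"].to_numpy(dtype=float)
    memory = composites["memory"].to_numpy(dtype=float)
    aef = composites["aef"].to_numpy(dtype=float)

    # shared CI/PMS components sit at the PMS value; the RAVLT combo absorbs
    # the CI residual; the remaining memory components absorb the rest.
    z = {name: None for name in MEASURES}
    z["ppmst1_sat"] = pms
    z["stroop_read_sat"] = pms
    z["sdst"] = pms
    z_rav = 4.0 * ci - 3.0 * pms
    z["ravlt_trials"] = z_rav
    z["ravlt_delayed"] = z_rav
    z_rest = (6.0 * memory - 2.0 * z_rav) / 4.0
    for name in ("rcft_immediate", "rcft_delayed", "ppmst2_sat",
                 "ppmst3_sat"):
        z[name] = z_rest
    z["stroop_name_sat"] = np.zeros_like(aef)
    z["stroop_interference"] = -aef
    z["fluency"] = aef
    z["vsat_sat"] = aef

    def raw_of(name):
        return norms.mean[name] + np.asarray(z[name]) * norms.sd[name]

    out = pd.DataFrame(index=composites.index)
    for prefix, name in (("ppmst_1letter", "ppmst1_sat"),
                         ("ppmst_2letter", "ppmst2_sat"),
                         ("ppmst_3letter", "ppmst3_sat"),
                         ("stroop_reading", "stroop_read_sat"),
                         ("stroop_naming", "stroop_name_sat"),
                         ("vsat", "vsat_sat")):
        sat = raw_of(name)
        col = prefix + "_correct" if prefix != "vsat" else "vsat_correct"
        sec = prefix + "_seconds" if prefix != "vsat" else "vsat_seconds"
        out[col] = sat * seconds
        out[sec] = seconds
    interference = raw_of("stroop_interference")
    read_sat = raw_of("stroop_read_sat")
    name_sat = raw_of("stroop_name_sat")
    cw_sat = interference * (read_sat + name_sat) / 2.0
    out["stroop_colorword_correct"] = cw_sat * seconds
    out["stroop_colorword_seconds"] = seconds
    out["sdst_score"] = raw_of("sdst")
    out["ravlt_trials_mean"] = raw_of("ravlt_trials")
    out["ravlt_delayed"] = raw_of("ravlt_delayed")
    out["rcft_immediate"] = raw_of("rcft_immediate")
    out["rcft_delayed"] = raw_of("rcft_delayed")
    out["fluency_score"] = raw_of("fluency")
    return out[list(RAW_COLUMNS)]
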