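"""End-to-end pipeline orchestration and canonical fixture generation.

Stages: phantom -> tractography -> connectome (a demonstration of the
imaging chain on a bundle phantom), then simulate -> per-subject metrics ->
raw cognitive battery -> elastic-net selection -> mixed-model fit on the
simulated cohort. Every stage logs its inputs, outputs and seeds into a run
manifest, and a completed stage is skipped on ``resume`` runs when its
outputs already exist.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig, save_config
from .connectome import Parcellation, build_connectome, write_adjacency_tsv
from .cognition import composite_scores, synthesize_raw_scores
from .metrics import METRIC_NAMES, compute_all
from .models import (DEFAULT_COVARIATES, ElasticNetSpec, elastic_net_select,
                     fit_lme, likelihood_ratio_test)
from .phantom import make_bundle_phantom, save_phantom
from .simulate import simulate_cohort
from .tracking import TrackingParams, track_all, write_streamlines

__all__ = ["RunManifest", "run_pipeline", "make_fixtures",
           "subject_metrics_table"]

log = logging.getLogger("svdnet.pipeline")


@dataclass
class RunManifest:
    config: dict
    seed: int
    software_version: str = __version__
    started: str = ""
    finished: str = ""
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, str],
               **info) -> None:
        entry = {"stage": stage, "outputs": outputs, **info}
        self.stages.append(entry)
        log.info("[%s] done: %s", stage, ", ".join(outputs.values()))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def subject_metrics_table(cohort, n_nulls: int = 100,
                          swaps_per_edge: int = 10,
                          seed: int = 0) -> pd.DataFrame:
    """Full 21-measure vector per subject, plus the disconnected-node flag.

    Null-model seeds are derived deterministically per subject from ``seed``.
    """
    if cohort.connectomes is None:
        raise ValueError("cohort was simulated without keep_connectomes")
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(cohort.connectomes))
    for conn, sid, cs in zip(cohort.connectomes,
                             cohort.subjects["subject_id"], child_seeds):
        vec = compute_all(conn.weights, n_nulls=n_nulls,
                          swaps_per_edge=swaps_per_edge,
                          seed=int(cs % (2 ** 31)))
        vec["subject_id"] = sid
        rows.append(vec)
    df = pd.DataFrame(rows)
    n_disc = int(df["disconnected"].sum())
    if n_disc:
        log.info("%d/%d subjects have one or more disconnected nodes",
                 n_disc, len(df))
    return df[["subject_id", *METRIC_NAMES, "disconnected"]]


def _stage_done(paths: dict[str, str], resume: bool) -> bool:
    return resume and all(os.path.exists(p) for p in paths.values())


def run_pipeline(config: SimulationConfig | str, out_dir: str,
                 seed: int | None = None, n_nulls: int = 20,
                 outcome: str = "ci", resume: bool = False) -> RunManifest:
    """Run every stage in order and write the manifest last.

    ``config`` may be a :class:`SimulationConfig` or a YAML path. ``seed``
    overrides the config seed. A stage failure aborts with the failing stage
    named; outputs of completed stages are retained.
    """
    if isinstance(config, (str, os.PathLike)):
        from .config import load_config
        config = load_config(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    save_config(config, os.path.join(out_dir, "resolved_config.yaml"))

    def path(*names):
        return {n: os.path.join(out_dir, n) for n in names}

    stage = "phantom"
    try:
        outs = path("phantom")
        phantom = make_bundle_phantom(shape=(20, 10, 10), voxel_size=2.5)
        if not _stage_done(outs, resume):
            save_phantom(phantom, outs["phantom"])
        manifest.record(stage, outs, shape=list(phantom.shape))

        stage = "track"
        outs = path("streamlines.txt")
        params = TrackingParams()
        sset = track_all(phantom, params)
        if not _stage_done(outs, resume):
            write_streamlines(sset, outs["streamlines.txt"])
        manifest.record(stage, outs, n_streamlines=len(sset))

        stage = "connectome"
        outs = path("phantom_connectome.tsv")
        parc = Parcellation(labels=phantom.labels,
                            voxel_size=phantom.voxel_size)
        conn = build_connectome(sset, parc)
        if not _stage_done(outs, resume):
            write_adjacency_tsv(conn, outs["phantom_connectome.tsv"])
        manifest.record(stage, outs,
                        n_edges=int((conn.weights > 0).sum() // 2))

        stage = "simulate"
        outs = path("subjects.csv", "cohort.csv")
        cohort = simulate_cohort(config, keep_connectomes=True)
        cohort.subjects.to_csv(outs["subjects.csv"], index=False)
        cohort.long.to_csv(outs["cohort.csv"], index=False)
        manifest.record(stage, outs, n_subjects=len(cohort.subjects),
                        n_rows=len(cohort.long), seed=config.seed)

        stage = "metrics"
        outs = path("metrics.csv")
        mdf = subject_metrics_table(cohort, n_nulls=n_nulls,
                                    seed=config.seed)
        mdf.to_csv(outs["metrics.csv"], index=False, float_format="%.10g")
        manifest.record(stage, outs, n_nulls=n_nulls,
                        n_disconnected=int(mdf["disconnected"].sum()))

        stage = "cognition"
        outs = path("raw_battery.csv", "composites.csv")
        base = cohort.long[cohort.long["visit"] == 1]
        raw = synthesize_raw_scores(base[["ci", "pms", "memory", "aef"]])
        raw.insert(0, "subject_id", base["subject_id"].to_numpy())
        raw.to_csv(outs["raw_battery.csv"], index=False)
        comp = composite_scores(raw)
        comp.insert(0, "subject_id", base["subject_id"].to_numpy())
        comp.to_csv(outs["composites.csv"], index=False)
        manifest.record(stage, outs, n_rows=len(raw))

        stage = "select"
        outs = path("selection.json")
        merged = base.merge(mdf, on="subject_id")
        feats = merged[list(METRIC_NAMES)]
        covs = merged[list(DEFAULT_COVARIATES)].copy()
        covs["n_lacunes"] = (covs["n_lacunes"] > 0).astype(int)
        covs["n_microbleeds"] = (covs["n_microbleeds"] > 0).astype(int)
        sel = elastic_net_select(feats, merged[outcome], covs,
                                 ElasticNetSpec(seed=config.seed))
        with open(outs["selection.json"], "w") as fh:
            json.dump({"selected_measure": sel.selected_measure,
                       "chosen_lambda": sel.chosen_lambda,
                       "normalized_coefficients":
                           sel.normalized_coefficients}, fh, indent=2)
        manifest.record(stage, outs, selected=sel.selected_measure)

        stage = "lme"
        outs = path("lme.json")
        predictor = sel.selected_measure
        null = fit_lme(cohort.long, outcome, predictor, baseline=mdf,
                       with_interaction=False)
        full = fit_lme(cohort.long, outcome, predictor, baseline=mdf,
                       with_interaction=True)
        lrt = likelihood_ratio_test(null, full)
        with open(outs["lme.json"], "w") as fh:
            json.dump({
                "outcome": outcome,
                "predictor": predictor,
                "fixed_effects": json.loads(
                    full.fixed_effects.to_json(orient="index")),
                "log_likelihood_null": null.log_likelihood,
                "log_likelihood_full": full.log_likelihood,
                "chi_square": lrt.chi_square, "df": lrt.df,
                "p_value": lrt.p_value,
            }, fh, indent=2)
        manifest.record(stage, outs, chi_square=lrt.chi_square,
                        p_value=lrt.p_value)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(os.path.join(out_dir, "manifest.json"))
    return manifest


def make_fixtures(out_dir: str, seed: int = 7) -> dict[str, str]:
    """Write the canonical test fixtures.

    Straight and 90-degree-bend phantoms, a set of 12-node random graphs
    with their package-computed metric values (for cross-checking against
    brute-force oracles), and a 30-subject mini-cohort.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    straight = make_bundle_phantom(shape=(20, 10, 10))
    paths.update({f"straight_{k}": v for k, v in
                  save_phantom(straight,
                               os.path.join(out_dir, "straight")).items()})
    bent = make_bundle_phantom(shape=(20, 20, 10), bend_angle=90.0)
    paths.update({f"bent_{k}": v for k, v in
                  save_phantom(bent, os.path.join(out_dir, "bent")).items()})

    rng = np.random.default_rng(seed)
    graphs = []
    for g in range(10):
        n = int(rng.integers(6, 13))
        p = float(rng.uniform(0.25, 0.7))
        A = (rng.random((n, n)) < p).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        W = A * rng.uniform(0.2, 2.0, size=(n, n))
        W = np.triu(W, 1)
        W = W + W.T
        vec = compute_all(W, n_nulls=5, seed=seed + g)
        graphs.append({"weights": W.tolist(),
                       "metrics": {k: v for k, v in vec.items()}})
    gpath = os.path.join(out_dir, "oracle_graphs.json")
    with open(gpath, "w") as fh:
        json.dump({"seed": seed, "graphs": graphs}, fh)
    paths["oracle_graphs"] = gpath

    cfg = SimulationConfig(n_subjects=30, n_retained=(30, 29, 21), seed=seed)
    cohort = simulate_cohort(cfg)
    cpath = os.path.join(out_dir, "mini_cohort.csv")
    cohort.long.to_csv(cpath, index=False)
    paths["mini_cohort"] = cpath
    spath = os.path.join(out_dir, "mini_subjects.csv")
    cohort.subjects.to_csv(spath, index=False)
    paths["mini_subjects"] = spath
    return paths
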