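"""Elastic-net selection and mixed-model estimation/testing behaviour."""

import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from svdnet.config import RandomEffects, SimulationConfig
from svdnet.models import (ElasticNetSpec, elastic_net_select, fit_lme,
                           likelihood_ratio_test)
from svdnet.simulate import simulate_cohort


def planted_features(seed=5, n=200, p=21, signal_col=3, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    z3 = (X[:, signal_col] - X[:, signal_col].mean()) / X[:, signal_col].std()
    y = z3 + noise * rng.standard_normal(n)
    names = [f"m{i}" for i in range(p)]
    return pd.DataFrame(X, columns=names), pd.Series(y), rng


class TestElasticNet:
    def test_planted_signal_recovery(self):
        X, y, _ = planted_features()
        res = elastic_net_select(X, y, spec=ElasticNetSpec(seed=1))
        assert res.selected_measure == "m3"
        assert res.normalized_coefficients["m3"] > 0.5

    def test_null_outcome_shrinks_coefficients(self):
        X, y, rng = planted_features()
        res = elastic_net_select(X, y, spec=ElasticNetSpec(seed=1))
        y0 = pd.Series(rng.standard_normal(len(y)))
        res0 = elastic_net_select(X, y0, spec=ElasticNetSpec(seed=1))
        max0 = max(abs(v) for v in res0.normalized_coefficients.values())
        assert abs(res.normalized_coefficients["m3"]) >= 5.0 * max0

    def test_duplicated_predictor_shares_signal(self):
        X, y, _ = planted_features()
        X2 = X.copy()
        X2["m3_dup"] = X["m3"]
        res = elastic_net_select(X2, y, spec=ElasticNetSpec(seed=1))
        c1 = res.normalized_coefficients["m3"]
        c2 = res.normalized_coefficients["m3_dup"]
        assert abs(c1) > 0.1 and abs(c2) > 0.1      # both retained
        assert c1 == pytest.approx(c2, rel=0.05)    # near-equal split

    def test_affine_rescaling_invariance(self):
        X, y, _ = planted_features()
        res1 = elastic_net_select(X, y, spec=ElasticNetSpec(seed=1))
        X2 = X.copy()
        X2["m7"] = X2["m7"] * 50.0 - 11.0
        res2 = elastic_net_select(X2, y, spec=ElasticNetSpec(seed=1))
        for k in res1.normalized_coefficients:
            assert res1.normalized_coefficients[k] == pytest.approx(
                res2.normalized_coefficients[k], abs=1e-6)

    def test_constant_column_dropped_with_warning(self):
        X, y, _ = planted_features()
        X["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = elastic_net_select(X, y, spec=ElasticNetSpec(seed=1))
        assert "flat" in res.dropped_columns
        assert "flat" not in res.normalized_coefficients

    def test_covariate_adjustment_removes_confounded_hit(self):
        # outcome driven purely by a covariate that also leaks into m0:
        # adjusted selection should not credit m0 with the full signal
        rng = np.random.default_rng(8)
        n = 300
        cov = rng.standard_normal(n)
        X = pd.DataFrame(rng.standard_normal((n, 21)),
                         columns=[f"m{i}" for i in range(21)])
        X["m0"] = 0.9 * cov + 0.4 * rng.standard_normal(n)
        y = pd.Series(2.0 * cov + 0.1 * rng.standard_normal(n))
        unadj = elastic_net_select(X, y, spec=ElasticNetSpec(seed=2))
        adj = elastic_net_select(X, y, pd.DataFrame({"cov": cov}),
                                 spec=ElasticNetSpec(seed=2))
        assert abs(adj.normalized_coefficients["m0"]) < \
            abs(unadj.normalized_coefficients["m0"]) / 3.0


def lme_cohort(seed, n=150, beta_int=0.04, resid=0.3,
               re=RandomEffects(0.5, 0.05, -0.3)):
    cfg = SimulationConfig(n_subjects=n, n_retained=(n, n, n), seed=seed,
                           resid_sd=resid, random_effects=re)
    cfg.outcomes["ci"].beta_interaction = beta_int
    return simulate_cohort(cfg)


class TestLME:
    def test_noise_free_exact_recovery(self):
        coh = lme_cohort(seed=4, n=60, resid=0.0,
                         re=RandomEffects(0.0, 0.0, 0.0))
        fit = fit_lme(coh.long, "ci", "global_efficiency_w",
                      baseline=coh.subjects)
        spec = coh.config.outcomes["ci"]
        assert fit.coef("predictor:time_years") == pytest.approx(
            spec.beta_interaction, abs=1e-6)
        assert fit.coef("time_years") == pytest.approx(spec.beta_time,
                                                       abs=1e-6)

    def test_ci_brackets_estimate(self):
        coh = lme_cohort(seed=7)
        fit = fit_lme(coh.long, "ci", "global_efficiency_w",
                      baseline=coh.subjects)
        fe = fit.fixed_effects
        assert (fe["ci_low"] <= fe["estimate"]).all()
        assert (fe["estimate"] <= fe["ci_high"]).all()
        assert fit.random_effects_cov.shape == (2, 2)
        evals = np.linalg.eigvalsh(fit.random_effects_cov)
        assert evals.min() >= -1e-8

    def test_lrt_internal_consistency(self):
        coh = lme_cohort(seed=9)
        null = fit_lme(coh.long, "ci", "global_efficiency_w",
                       baseline=coh.subjects, with_interaction=False)
        full = fit_lme(coh.long, "ci", "global_efficiency_w",
                       baseline=coh.subjects, with_interaction=True)
        lrt = likelihood_ratio_test(null, full)
        assert lrt.df == 1
        assert lrt.chi_square == pytest.approx(
            2.0 * (full.log_likelihood - null.log_likelihood), abs=1e-9)
        assert 0.0 <= lrt.p_value <= 1.0

    def test_identical_fits_give_zero_chi_square(self):
        coh = lme_cohort(seed=9)
        full = fit_lme(coh.long, "ci", "global_efficiency_w",
                       baseline=coh.subjects, with_interaction=True)
        lrt = likelihood_ratio_test(full, full)
        assert lrt.chi_square == 0.0
        assert lrt.p_value == 1.0

    def test_non_nested_rejected(self):
        coh = lme_cohort(seed=9)
        null = fit_lme(coh.long, "ci", "global_efficiency_w",
                       baseline=coh.subjects, with_interaction=False)
        full = fit_lme(coh.long, "ci", "global_efficiency_w",
                       baseline=coh.subjects, with_interaction=True,
                       covariates=("age",))
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(full, null)

    def test_severity_ranked_attrition_is_ignorable_given_covariates(self):
        """Severity-ranked dropout selects on variables the model adjusts
        for (covariates and baseline efficiency), so the ML interaction
        estimate stays near the truth while losing precision relative to
        complete follow-up of the same cohorts."""
        est_attr, est_full, se_diff = [], [], []
        for seed in (31, 32, 33, 34):
            cfg = SimulationConfig(n_subjects=200,
                                   n_retained=(200, 170, 120), seed=seed)
            cfg.outcomes["ci"].beta_interaction = 0.08
            full_cfg = SimulationConfig(n_subjects=200,
                                        n_retained=(200, 200, 200), seed=seed)
            full_cfg.outcomes["ci"].beta_interaction = 0.08
            coh_attr = simulate_cohort(cfg)
            coh_full = simulate_cohort(full_cfg)
            f_attr = fit_lme(coh_attr.long, "ci", "global_efficiency_w",
                             baseline=coh_attr.subjects)
            f_full = fit_lme(coh_full.long, "ci", "global_efficiency_w",
                             baseline=coh_full.subjects)
            est_attr.append(f_attr.coef("predictor:time_years"))
            est_full.append(f_full.coef("predictor:time_years"))
            ix = "predictor:time_years"
            se_diff.append(f_attr.fixed_effects.loc[ix, "se"]
                           - f_full.fixed_effects.loc[ix, "se"])
        assert abs(np.mean(est_attr) - 0.08) < 0.01
        assert np.mean(se_diff) > 0.0   # attrition costs precision


def test_lme_agrees_with_lme4():
    """Cross-check the ML fit against lme4 on the same data."""
    coh = lme_cohort(seed=12, n=80)
    data = coh.long.merge(
        coh.subjects[["subject_id", "global_efficiency_w"]], on="subject_id")
    mu = data.groupby("subject_id")["global_efficiency_w"].first().mean()
    sd = data.groupby("subject_id")["global_efficiency_w"].first().std(ddof=0)
    data["pred_z"] = (data["global_efficiency_w"] - mu) / sd
    csv = "/tmp/lme_xcheck.csv"
    data.to_csv(csv, index=False)
    rscript = textwrap.dedent("""
        suppressMessages(library(lme4))
        d <- read.csv("%s")
        m <- lmer(ci ~ age + sex + education + depression + wmh_ml +
                  n_lacunes + n_microbleeds + tbv_ml + pred_z + time_years +
                  pred_z:time_years + (1 + time_years | subject_id),
                  data = d, REML = FALSE,
                  control = lmerControl(calc.derivs = FALSE))
        fe <- fixef(m)
        cat(jsonlite::toJSON(list(ll = as.numeric(logLik(m)),
            b_int = as.numeric(fe[["pred_z:time_years"]]),
            b_time = as.numeric(fe[["time_years"]]))))
    """ % csv)
    out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    ref = {k: v[0] for k, v in json.loads(out.stdout).items()}
    fit = fit_lme(coh.long, "ci", "global_efficiency_w",
                  baseline=coh.subjects)
    assert fit.coef("predictor:time_years") == pytest.approx(ref["b_int"],
                                                             abs=1e-4)
    assert fit.coef("time_years") == pytest.approx(ref["b_time"], abs=1e-4)
    assert fit.log_likelihood == pytest.approx(ref["ll"], abs=1e-2)
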