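"""Elastic-net feature selection and linear mixed-effects modelling.

The elastic net (mixing parameter 0.05, i.e. nearly ridge, so collinear
network measures share signal rather than being arbitrarily dropped) ranks
the 21 network measures by the absolute value of their standardized
coefficient, with clinical covariates included unpenalized. The penalty
strength is chosen by seeded 10-fold cross-validation, folds stratified by
outcome quartile.

The mixed models are fit by maximum likelihood (not REML, since the null
and full model differ in fixed effects) with correlated subject random
intercept and slope; the interaction between baseline network measure and
time is assessed by a likelihood-ratio test on one degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = ["ElasticNetSpec", "ElasticNetResult", "elastic_net_select",
           "LMEResult", "fit_lme", "LRTResult", "likelihood_ratio_test",
           "DEFAULT_COVARIATES"]

DEFAULT_COVARIATES = ("age", "sex", "education", "depression", "wmh_ml",
                      "n_lacunes", "n_microbleeds", "tbv_ml")


# ---------------------------------------------------------------------------
# elastic net with unpenalized covariates
# ---------------------------------------------------------------------------

@dataclass
class ElasticNetSpec:
    alpha_mix: float = 0.05          # L1 share of the penalty (glmnet alpha)
    n_folds: int = 10
    lambda_rule: str = "lambda_min"  # or "lambda_1se"
    n_lambdas: int = 60
    lambda_min_ratio: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_mix <= 1.0:
            raise ValueError("alpha_mix must be in [0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.lambda_rule not in ("lambda_min", "lambda_1se"):
            raise ValueError("lambda_rule must be lambda_min or lambda_1se")


@dataclass
class ElasticNetResult:
    normalized_coefficients: dict[str, float]
    selected_measure: str
    chosen_lambda: float
    covariate_coefficients: dict[str, float] = field(default_factory=dict)
    cv_mse: dict[float, float] = field(default_factory=dict)
    dropped_columns: list[str] = field(default_factory=list)


def _profile_design(X: np.ndarray, Z: np.ndarray, y: np.ndarray):
    """Profile out the unpenalized block Z from the joint objective.

    Minimizing 1/(2n)||y - X b - Z g||^2 + pen(b) over g for fixed b gives
    g = Z^+ (y - X b), leaving the exact profile objective
    1/(2n)||M y - M X b||^2 + pen(b) with M the projector off span(Z).
    Solving the elastic net on (M X, M y) is therefore the exact joint
    solution with Z unpenalized, not a two-step approximation.
    """
    Zpinv = np.linalg.pinv(Z)
    P = Z @ Zpinv
    MX = X - P @ X
    My = y - P @ y
    return MX, My, Zpinv


def _solve_partial_penalty(X: np.ndarray, Z: np.ndarray, y: np.ndarray,
                           lam: float, l1_ratio: float
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Elastic net on X with unpenalized covariate block Z (see above)."""
    MX, My, Zpinv = _profile_design(X, Z, y)
    enet = ElasticNet(alpha=lam, l1_ratio=l1_ratio, fit_intercept=False,
                      max_iter=50000, tol=1e-8)
    enet.fit(MX, My)
    beta = enet.coef_.copy()
    gamma = Zpinv @ (y - X @ beta)
    return beta, gamma


def _lambda_path(X: np.ndarray, Z: np.ndarray, y: np.ndarray,
                 spec: ElasticNetSpec) -> np.ndarray:
    resid0 = y - Z @ (np.linalg.pinv(Z) @ y)
    n = len(y)
    # smallest lambda that zeroes all penalized coefficients (L1 part)
    lam_max = np.max(np.abs(X.T @ resid0)) / (n * max(spec.alpha_mix, 1e-3))
    return np.geomspace(lam_max, lam_max * spec.lambda_min_ratio,
                        spec.n_lambdas)


def elastic_net_select(features: pd.DataFrame, outcome: pd.Series,
                       covariates: pd.DataFrame | None = None,
                       spec: ElasticNetSpec | None = None
                       ) -> ElasticNetResult:
    """Select the network measure with the largest standardized coefficient.

    Network-measure columns are standardized to mean 0 / SD 1 (coefficients
    are reported on that scale); covariates and the intercept are unpenalized.
    Constant feature columns are dropped with a warning. Non-finite feature
    values (e.g. the infinite characteristic path length of disconnected
    networks) are imputed with the column's maximum finite value.
    """
    spec = spec or ElasticNetSpec()
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    if spec.n_folds > n:
        raise ValueError("more CV folds than observations")

    feats = features.copy()
    for col in feats.columns:
        colvals = feats[col].to_numpy(dtype=float)
        bad = ~np.isfinite(colvals)
        if bad.any():
            finite = colvals[~bad]
            colvals[bad] = finite.max() if finite.size else 0.0
            feats[col] = colvals
    dropped = [c for c in feats.columns
               if feats[c].std(ddof=0) == 0]
    if dropped:
        warnings.warn(f"dropping constant feature columns: {dropped}")
        feats = feats.drop(columns=dropped)
    names = list(feats.columns)
    X = feats.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)

    if covariates is not None and len(covariates.columns):
        Z = np.column_stack([np.ones(n),
                             covariates.to_numpy(dtype=float)])
        cov_names = ["intercept"] + list(covariates.columns)
    else:
        Z = np.ones((n, 1))
        cov_names = ["intercept"]

    lambdas = _lambda_path(X, Z, y, spec)
    quartiles = pd.qcut(y, q=4, labels=False, duplicates="drop")
    if pd.Series(quartiles).value_counts().min() >= spec.n_folds:
        splitter = StratifiedKFold(n_splits=spec.n_folds, shuffle=True,
                                   random_state=spec.seed)
        splits = splitter.split(X, quartiles)
    else:  # strata too small to stratify; fall back to plain K-fold
        splitter = KFold(n_splits=spec.n_folds, shuffle=True,
                         random_state=spec.seed)
        splits = splitter.split(X)
    fold_mse = np.zeros((spec.n_folds, len(lambdas)))
    for f, (tr, te) in enumerate(splits):
        MX, My, Zpinv = _profile_design(X[tr], Z[tr], y[tr])
        enet = ElasticNet(alpha=lambdas[0], l1_ratio=spec.alpha_mix,
                          fit_intercept=False, max_iter=50000, tol=1e-8,
                          warm_start=True)
        for li, lam in enumerate(lambdas):
            enet.alpha = lam
            enet.fit(MX, My)
            beta = enet.coef_
            gamma = Zpinv @ (y[tr] - X[tr] @ beta)
            pred = X[te] @ beta + Z[te] @ gamma
            fold_mse[f, li] = np.mean((y[te] - pred) ** 2)
    mean_mse = fold_mse.mean(axis=0)
    i_min = int(np.argmin(mean_mse))
    if spec.lambda_rule == "lambda_1se":
        se = fold_mse.std(axis=0, ddof=1) / np.sqrt(spec.n_folds)
        ok = np.flatnonzero(mean_mse <= mean_mse[i_min] + se[i_min])
        i_choose = int(ok[0])  # lambdas descend: first = most regularized
    else:
        i_choose = i_min
    lam = float(lambdas[i_choose])

    beta, gamma = _solve_partial_penalty(X, Z, y, lam, spec.alpha_mix)
    coefs = dict(zip(names, beta.tolist()))
    selected = max(coefs, key=lambda k: abs(coefs[k]))
    return ElasticNetResult(
        normalized_coefficients=coefs,
        selected_measure=selected,
        chosen_lambda=lam,
        covariate_coefficients=dict(zip(cov_names, gamma.tolist())),
        cv_mse={float(lv): float(mv) for lv, mv in zip(lambdas, mean_mse)},
        dropped_columns=dropped,
    )


# ---------------------------------------------------------------------------
# linear mixed-effects models
# ---------------------------------------------------------------------------

@dataclass
class LMEResult:
    fixed_effects: pd.DataFrame       # estimate, se, ci_low, ci_high, p
    random_effects_cov: np.ndarray    # 2x2 (intercept, slope)
    resid_sd: float
    log_likelihood: float
    n_obs: int
    n_subjects: int
    converged: bool
    terms: tuple[str, ...]
    diagonal_fallback: bool = False

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "estimate"])


def fit_lme(long: pd.DataFrame, outcome: str, predictor: str,
            baseline: pd.DataFrame | None = None,
            covariates: tuple[str, ...] = DEFAULT_COVARIATES,
            with_interaction: bool = True,
            standardize_predictor: bool = True,
            time_col: str = "time_years",
            group_col: str = "subject_id") -> LMEResult:
    """ML fit of outcome ~ covariates + predictor + time (+ predictor:time)
    with correlated subject random intercept and slope.

    The predictor is a baseline network measure, constant within subject; if
    it is not already a column of ``long`` it is merged from ``baseline``
    (a per-subject table, e.g. a metrics CSV). It is standardized across
    subjects by default, so the interaction coefficient is in z-units per
    year per SD of the measure. Wald 95% intervals are reported per fixed
    effect. If the unstructured random-effects fit fails to converge, the
    model is refit with independent intercept and slope and flagged.
    """
    if predictor not in long.columns:
        if baseline is None:
            raise ValueError(
                f"{predictor!r} not in the visit table and no baseline "
                "measure table was provided")
        long = long.merge(baseline[[group_col, predictor]], on=group_col,
                          how="left")
    data = long.dropna(subset=[outcome, predictor, time_col]).copy()
    if standardize_predictor:
        base = data.sort_values(time_col).groupby(group_col)[predictor].first()
        mu, sd = float(base.mean()), float(base.std(ddof=0))
        data["_pred"] = (data[predictor] - mu) / (sd if sd > 0 else 1.0)
    else:
        data["_pred"] = data[predictor]

    terms = list(covariates) + ["_pred", time_col]
    if with_interaction:
        terms.append(f"_pred:{time_col}")
    formula = f"{outcome} ~ " + " + ".join(terms)

    def _fit(re_formula, vc_formula=None):
        model = smf.mixedlm(formula, data, groups=data[group_col],
                            re_formula=re_formula, vc_formula=vc_formula)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=False, method="lbfgs", maxiter=400)

    diagonal = False
    fit = _fit(f"~{time_col}")
    if not fit.converged:
        retry = _fit(f"~{time_col}")  # statsmodels restarts differ slightly
        if retry.converged:
            fit = retry
        else:
            fit = _fit("1", vc_formula={"slope": f"0 + {time_col}"})
            diagonal = True

    k_fe = fit.k_fe
    fe_names = fit.model.exog_names
    params = np.asarray(fit.fe_params)
    se = np.asarray(fit.bse.iloc[:k_fe])
    zcrit = stats.norm.ppf(0.975)
    fe = pd.DataFrame({
        "estimate": params,
        "se": se,
        "ci_low": params - zcrit * se,
        "ci_high": params + zcrit * se,
        "p": 2 * stats.norm.sf(np.abs(params) / np.where(se > 0, se, np.inf)),
    }, index=fe_names)

    if diagonal:
        cov_re = np.diag([float(fit.cov_re.iloc[0, 0]),
                          float(fit.vcomp[0])])
    else:
        cov_re = np.asarray(fit.cov_re)

    rename = {"_pred": "predictor",
              f"_pred:{time_col}": f"predictor:{time_col}"}
    fe.index = [rename.get(ix, ix) for ix in fe.index]
    return LMEResult(
        fixed_effects=fe,
        random_effects_cov=cov_re,
        resid_sd=float(np.sqrt(fit.scale)),
        log_likelihood=float(fit.llf),
        n_obs=int(len(data)),
        n_subjects=int(data[group_col].nunique()),
        converged=bool(fit.converged),
        terms=tuple(fe.index),
        diagonal_fallback=diagonal,
    )


@dataclass
class LRTResult:
    chi_square: float
    df: int
    p_value: float


def likelihood_ratio_test(null_fit: LMEResult, full_fit: LMEResult,
                          tol: float = 1e-6) -> LRTResult:
    """chi2 = 2 (ll_full - ll_null) on df = difference in fixed effects."""
    if set(null_fit.terms) - set(full_fit.terms):
        raise ValueError("null model is not nested in the full model")
    extra = set(full_fit.terms) - set(null_fit.terms)
    df = len(extra)
    if df == 0:
        return LRTResult(chi_square=0.0, df=0, p_value=1.0)
    chi2 = 2.0 * (full_fit.log_likelihood - null_fit.log_likelihood)
    if chi2 < -tol:
        warnings.warn("negative LRT statistic beyond tolerance; "
                      "the full-model fit may not have converged")
    chi2 = max(chi2, 0.0)
    return LRTResult(chi_square=float(chi2), df=df,
                     p_value=float(stats.chi2.sf(chi2, df)))
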