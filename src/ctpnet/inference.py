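"""Permutation tests and screened multiple linear regression.

Condition differences in network metrics are tested with a within-subject
sign-flip permutation test (10,000 permutations by default) after age and
sex are regressed out; rejection uses the 95th percentile of the absolute
null distribution (two-tailed, 5% type I error). The regression stage
screens candidate nodal predictors by Pearson correlation (p < 0.01,
uncorrected, as specified), fits an OLS model with intercept via
statsmodels, and can re-apply a fitted predictor set to new data to test
whether the model transfers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


def _covariate_design(covariates: pd.DataFrame, n: int) -> np.ndarray:
    cols = [np.ones(n)]
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype == object or str(col.dtype) == "category":
            codes, _ = pd.factorize(col)
            col = codes.astype(float)
        col = np.asarray(col, dtype=float)
        if np.ptp(col) == 0:
            warnings.warn(f"covariate '{name}' is constant; dropped")
            continue
        cols.append(col)
    return np.column_stack(cols)


def residualize_covariates(y: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Least-squares residuals of y on [intercept | covariates].

    Categorical covariates (e.g. sex) are integer-coded; constant columns
    are dropped with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = _covariate_design(covariates, n)
    if n < X.shape[1] + 1:
        raise ValueError("too few subjects for the covariate design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class PermutationResult:
    """Sign-flip permutation test output.

    ``observed_diff`` is always the raw mean condition difference;
    ``observed_stat`` and ``null_distribution`` are on the scale of the
    statistic actually permuted (the mean difference itself, or the
    covariate-adjusted t statistic when covariates are removed).
    """

    observed_diff: float
    null_distribution: np.ndarray = field(repr=False)
    p_two_tailed: float
    n_perm: int
    alpha: float
    covariates_removed: list
    seed: int
    observed_stat: float = 0.0
    statistic: str = "mean_diff"
    zero_variance: bool = False

    @property
    def critical_value(self) -> float:
        """95th (1-alpha) percentile of the absolute null distribution."""
        return float(np.quantile(np.abs(self.null_distribution), 1 - self.alpha))

    @property
    def reject(self) -> bool:
        return self.p_two_tailed <= self.alpha


def paired_permutation_test(x_a, x_b, covariates: pd.DataFrame | None = None,
                            n_perm: int = 10000, seed: int = 0,
                            alpha: float = 0.05,
                            method: str = "signflip") -> PermutationResult:
    """Two-tailed permutation test of a paired condition difference.

    Without covariates this is the classic within-subject sign-flip test of
    the mean difference: the null is built by random sign flips of each
    subject's difference. With covariates, age/sex are removed with the
    Freedman-Lane scheme — reduced-model (covariates-only) residuals are
    sign-flipped, the covariate fit is added back, and the full model with
    intercept is refit, permuting a studentized intercept statistic; this
    keeps the empirical type I error at the nominal level, which simple
    residualization of the flipped differences does not. method="unpaired"
    instead permutes the pooled condition values across subjects.
    p = (1 + #{|null| >= |obs|}) / (1 + n_perm).
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.shape != x_b.shape or x_a.ndim != 1:
        raise ValueError("x_a and x_b must be equal-length vectors")
    n = len(x_a)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    removed = list(covariates.columns) if covariates is not None else []
    d = x_a - x_b
    observed = float(d.mean())
    rng = np.random.default_rng(seed)
    if np.ptp(d) == 0:
        return PermutationResult(observed_diff=observed,
                                 null_distribution=np.zeros(n_perm),
                                 p_two_tailed=1.0, n_perm=n_perm, alpha=alpha,
                                 covariates_removed=removed, seed=seed,
                                 zero_variance=True)
    if method == "signflip" and covariates is not None:
        X0 = _covariate_design(covariates, n)[:, 1:]  # covariates, no intercept
        X0 = X0 - X0.mean(axis=0, keepdims=True)
        F = np.hstack([np.ones((n, 1)), X0])
        G = np.linalg.inv(F.T @ F)
        P = G @ F.T
        M = np.eye(n) - F @ P
        dof = n - F.shape[1]
        g00 = G[0, 0]

        def t_rows(V: np.ndarray) -> np.ndarray:
            num = V @ P[0]
            rss = np.maximum(((V @ M.T) ** 2).sum(axis=-1), 1e-300)
            return num / np.sqrt(rss / dof * g00)

        observed_stat = float(t_rows(d[None, :])[0])
        if X0.shape[1]:
            b0, *_ = np.linalg.lstsq(X0, d, rcond=None)
            fit0 = X0 @ b0
        else:
            fit0 = np.zeros(n)
        e0 = d - fit0
        signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
        null = t_rows(fit0[None, :] + signs * e0[None, :])
        p = (1.0 + np.count_nonzero(np.abs(null) >= abs(observed_stat))) \
            / (1.0 + n_perm)
        return PermutationResult(observed_diff=observed, null_distribution=null,
                                 p_two_tailed=float(p), n_perm=n_perm,
                                 alpha=alpha, covariates_removed=removed,
                                 seed=seed, observed_stat=observed_stat,
                                 statistic="freedman_lane_t")
    if method == "signflip":
        signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
        null = signs @ d / n
    elif method == "unpaired":
        pooled = np.concatenate([x_a, x_b])
        if covariates is not None:
            pooled = residualize_covariates(
                pooled, pd.concat([covariates, covariates], ignore_index=True))
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(pooled)
            null[i] = perm[:n].mean() - perm[n:].mean()
    else:
        raise ValueError("method must be 'signflip' or 'unpaired'")
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(observed))) / (1.0 + n_perm)
    return PermutationResult(observed_diff=observed, null_distribution=null,
                             p_two_tailed=float(p), n_perm=n_perm, alpha=alpha,
                             covariates_removed=removed, seed=seed,
                             observed_stat=observed)


def screen_predictors(dependent, candidates: pd.DataFrame,
                      alpha: float = 0.01) -> tuple[list, pd.DataFrame]:
    """Retain candidates whose Pearson correlation with y has p < alpha.

    The screen is deliberately uncorrected for multiple comparisons. Returns
    the retained names and the full screening table (r, p per candidate).
    """
    y = np.asarray(dependent, dtype=float)
    if len(y) < 5:
        raise ValueError("need at least 5 subjects to screen")
    rows = []
    for name in candidates.columns:
        x = np.asarray(candidates[name], dtype=float)
        if np.ptp(x) == 0:
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((name, r, p))
    table = pd.DataFrame(rows, columns=["predictor", "r", "p"])
    retained = list(table.loc[table["p"] < alpha, "predictor"])
    return retained, table


@dataclass
class RegressionModel:
    """Screened OLS model of a task-network metric on rest-network nodal metrics."""

    dependent: str
    predictors: list
    coefficients: pd.Series
    r_squared: float
    adjusted_r_squared: float
    model_p: float
    per_predictor_variance_explained: dict
    per_predictor_semipartial_r2: dict
    n: int
    screen_alpha: float
    results: object = field(default=None, repr=False)  # statsmodels results

    def summary(self):
        return self.results.summary()


def fit_mlra(dependent, predictors: pd.DataFrame, dependent_name: str = "y",
             screen_alpha: float = 0.01) -> RegressionModel:
    """Ordinary least squares with intercept on the screened predictor set.

    Per-predictor "variance explained" is the squared zero-order Pearson
    correlation with the dependent; the squared semi-partial correlation is
    reported alongside.
    """
    y = np.asarray(dependent, dtype=float)
    n, p = len(y), predictors.shape[1]
    if p < 1:
        raise ValueError("no predictors supplied")
    if n <= p + 1:
        raise ValueError(f"n={n} subjects cannot support p={p} predictors "
                         "plus intercept")
    X = sm.add_constant(predictors.astype(float), has_constant="add")
    res = sm.OLS(y, X).fit()
    zero_order = {c: float(stats.pearsonr(predictors[c], y)[0] ** 2)
                  for c in predictors.columns}
    # squared semi-partial: drop in R^2 when the predictor is removed
    semi = {}
    for c in predictors.columns:
        others = [o for o in predictors.columns if o != c]
        if others:
            r2_red = sm.OLS(y, sm.add_constant(predictors[others].astype(float),
                                               has_constant="add")).fit().rsquared
        else:
            r2_red = 0.0
        semi[c] = float(res.rsquared - r2_red)
    return RegressionModel(
        dependent=dependent_name, predictors=list(predictors.columns),
        coefficients=res.params, r_squared=float(res.rsquared),
        adjusted_r_squared=float(res.rsquared_adj),
        model_p=float(res.f_pvalue), per_predictor_variance_explained=zero_order,
        per_predictor_semipartial_r2=semi, n=n, screen_alpha=screen_alpha,
        results=res)


@dataclass
class TransferReport:
    """Outcome of re-applying a fitted predictor set to new data."""

    dependent: str
    predictors: list
    adjusted_r_squared: float
    model_p: float
    transfers: bool
    n: int


def cross_apply_model(model: RegressionModel, new_dependent,
                      new_predictor_table: pd.DataFrame,
                      dependent_name: str = "y",
                      alpha: float = 0.05) -> TransferReport:
    """Refit the model's fixed predictor set on new data.

    The model "fails to transfer" when the refit's overall F-test p >= alpha.
    """
    missing = [c for c in model.predictors if c not in new_predictor_table.columns]
    if missing:
        raise ValueError(f"new table lacks predictor column(s): {missing}")
    refit = fit_mlra(new_dependent, new_predictor_table[model.predictors],
                     dependent_name=dependent_name,
                     screen_alpha=model.screen_alpha)
    return TransferReport(dependent=dependent_name, predictors=model.predictors,
                          adjusted_r_squared=refit.adjusted_r_squared,
                          model_p=refit.model_p,
                          transfers=bool(refit.model_p < alpha), n=refit.n)
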