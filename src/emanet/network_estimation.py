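"""Estimation of temporal, contemporaneous and between-subject networks.

The estimator is a node-wise multilevel VAR(1).  For each node j one
linear mixed model is fitted:

    y_j(t) ~ 1 + sum_k beta_jk * c_k(t-1) + sum_{k != j} b_jk * mean_k(i)
             + u_i + eps(t)

where c_k is the within-person-centered lagged value of node k, mean_k(i)
is person i's mean of node k (a level-2 predictor), and u_i a random
person intercept.  The fixed lag slopes beta_jk form row j of the temporal
network (diagonal = autoregression).  The level-2 slopes, standardised and
averaged over the two directions of each pair, form the between-subject
network.  The contemporaneous network consists of partial correlations of
the mixed-model residuals, obtained by node-wise regression of each
residual on all the others and a signed geometric-mean combination of the
two directional coefficients (which reproduces the Gaussian-graphical-model
partial-correlation identity exactly on a single sample).

Only fixed temporal effects are estimated — with a few dozen occasions per
person, person-specific slopes are not identifiable with any precision —
and missing rows are handled by per-model complete-case deletion (no
imputation).

p-values are two-sided Wald tests.  The default reference distribution is
the standard normal; ``pvalue_method="t"`` switches to a crude
within/between degrees-of-freedom split (level-1 slopes: residual df;
level-2 slopes: persons minus level-2 parameters), a conservative
alternative in small samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .lag_design import CENTERED_PREFIX, OUTCOME_PREFIX, LaggedDesign, PersonMeans

__all__ = [
    "TemporalNetwork",
    "ContemporaneousNetwork",
    "BetweenNetwork",
    "FitDiagnostics",
    "TemporalFit",
    "fit_temporal",
    "fit_between",
    "fit_contemporaneous",
    "pcor_from_precision",
]

MEAN_PREFIX = "mean_"


class EstimationError(RuntimeError):
    pass


@dataclass
class TemporalNetwork:
    """Directed lag-1 network.  weights[j, k] = effect of node k at t-1 on
    node j at t; the diagonal holds autoregressive effects."""

    weights: pd.DataFrame
    se: pd.DataFrame
    pvalues: pd.DataFrame
    n_obs: pd.Series
    converged: pd.Series
    fallback: pd.Series
    directed: bool = True

    @property
    def item_names(self) -> list[str]:
        return list(self.weights.index)


@dataclass
class ContemporaneousNetwork:
    """Undirected residual partial-correlation network.

    ``p1[j, k]`` is the p-value of k's coefficient in j's residual
    regression, ``p2[j, k]`` the converse; both matrices are stored in
    full, so for an unordered pair read (p1[j, k], p1[k, j]).
    """

    weights: pd.DataFrame
    p1: pd.DataFrame
    p2: pd.DataFrame
    sign_conflict: pd.DataFrame
    n_obs: int = 0
    directed: bool = False

    @property
    def item_names(self) -> list[str]:
        return list(self.weights.index)


@dataclass
class BetweenNetwork:
    """Undirected person-mean network; each edge is the mean of the two
    standardised level-2 regression slopes of the pair."""

    weights: pd.DataFrame
    p1: pd.DataFrame
    p2: pd.DataFrame
    sign_conflict: pd.DataFrame
    directed: bool = False

    @property
    def item_names(self) -> list[str]:
        return list(self.weights.index)


@dataclass
class FitDiagnostics:
    """Per node-model bookkeeping: sample sizes, variance components,
    convergence and fallback status."""

    table: pd.DataFrame

    def __getitem__(self, col):
        return self.table[col]


@dataclass
class TemporalFit:
    """Everything produced by the node-wise mixed models."""

    temporal: TemporalNetwork
    residuals: pd.DataFrame
    between_coef: pd.DataFrame
    between_se: pd.DataFrame
    between_p: pd.DataFrame
    person_mean_sd: pd.Series
    diagnostics: FitDiagnostics
    standardized: bool
    pvalue_method: str


def _wald_p(params, bse, df_map, method):
    """Two-sided Wald p-values; ``df_map`` maps parameter name -> df for
    the t reference (ignored for the normal reference)."""
    z = params / bse
    if method == "normal":
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=params.index)
    out = {}
    for name, zi in z.items():
        df = max(df_map.get(name, 1), 1)
        out[name] = 2 * stats.t.sf(abs(zi), df)
    return pd.Series(out)


def fit_temporal(
    design: LaggedDesign,
    means: PersonMeans | None = None,
    standardize: bool = True,
    pvalue_method: str = "normal",
) -> TemporalFit:
    """Fit the node-wise multilevel lag-1 models.

    With ``standardize`` (default) every item is z-scored on the pooled
    mean/SD of the outcome rows before fitting, so coefficients are on a
    correlation-like scale.  Returns the temporal network, a residual table
    aligned with the design rows (observed minus fixed part minus predicted
    person intercept), raw level-2 coefficient/SE/p matrices for the
    between-subject network, and per-model diagnostics.

    Falls back to pooled OLS (flagged) when the mixed model will not
    converge, and to plain OLS without person-mean terms when only a
    single person is present.
    """
    if pvalue_method not in ("normal", "t"):
        raise ValueError("pvalue_method must be 'normal' or 't'")
    if means is None:
        means = design.means
    if design.is_empty:
        raise EstimationError("empty lagged design: no usable (t-1 -> t) pairs")
    items = design.item_names
    m = len(items)
    tab = design.table
    persons = tab["person_id"]
    n_persons = persons.nunique()

    # scale factors from the pooled outcome rows
    if standardize:
        mu = {it: tab[OUTCOME_PREFIX + it].mean() for it in items}
        sd = {it: tab[OUTCOME_PREFIX + it].std(ddof=1) for it in items}
        for it in items:
            if not np.isfinite(sd[it]) or sd[it] == 0:
                raise EstimationError(f"item {it} has zero variance; cannot standardise")
    else:
        mu = {it: 0.0 for it in items}
        sd = {it: 1.0 for it in items}

    y = pd.DataFrame({it: (tab[OUTCOME_PREFIX + it] - mu[it]) / sd[it] for it in items})
    c = pd.DataFrame({it: tab[CENTERED_PREFIX + it] / sd[it] for it in items})
    pm = means.means.reindex(persons)
    pm = pd.DataFrame(
        {it: (pm[it].to_numpy() - mu[it]) / sd[it] for it in items}, index=tab.index
    )
    person_mean_sd = (
        pd.DataFrame({it: (means.means[it] - mu[it]) / sd[it] for it in items})
        .std(ddof=1)
    )

    idx = pd.Index(items, name="item")
    B = pd.DataFrame(np.nan, index=idx, columns=idx)
    SE = B.copy()
    P = B.copy()
    bcoef = B.copy()
    bse_m = B.copy()
    bp = B.copy()
    resid = pd.DataFrame(np.nan, index=tab.index, columns=items)
    diag_rows = []
    single_person = n_persons < 2

    for j, it_j in enumerate(items):
        lag_cols = {f"lag:{k}": c[k] for k in items}
        mean_cols = (
            {} if single_person else {f"mean:{k}": pm[k] for k in items if k != it_j}
        )
        X = pd.DataFrame({"const": 1.0, **lag_cols, **mean_cols})
        yj = y[it_j]
        mask = yj.notna() & X.notna().all(axis=1)
        Xj, yjv, grp = X[mask], yj[mask], persons[mask]
        n = int(mask.sum())
        if n < X.shape[1] + 1:
            diag_rows.append((it_j, n, grp.nunique(), np.nan, np.nan, False, "too_few_rows"))
            continue

        fallback = None
        result = None
        if not single_person:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                try:
                    model = MixedLM(yjv.to_numpy(), Xj, groups=grp.to_numpy())
                    result = model.fit(reml=True)
                    if not result.converged or not np.all(np.isfinite(result.bse_fe)):
                        result = model.fit(reml=True, method="lbfgs")
                    if not result.converged or not np.all(np.isfinite(result.bse_fe)):
                        result = None
                        fallback = "ols"
                except (np.linalg.LinAlgError, ValueError):
                    result = None
                    fallback = "ols"
        else:
            fallback = "single_person_ols"

        if result is not None:
            params, bse = result.fe_params, result.bse_fe
            re_var = float(np.asarray(result.cov_re)[0, 0])
            try:
                re = result.random_effects
                u = grp.map({g: float(np.asarray(v)[0]) for g, v in re.items()})
                u = u.to_numpy()
            except (ValueError, np.linalg.LinAlgError):
                # boundary fit: random-intercept variance estimated at 0,
                # so the predicted person intercepts are all 0
                u = np.zeros(len(Xj))
            fitted = Xj.to_numpy() @ params.to_numpy() + u
            res_var = float(result.scale)
            converged = bool(result.converged)
        else:
            ols = sm.OLS(yjv.to_numpy(), Xj).fit()
            params, bse = ols.params, ols.bse
            fitted = ols.fittedvalues
            re_var, res_var = 0.0, float(ols.scale)
            converged = True

        df_map = {}
        if pvalue_method == "t":
            n_l2 = len(mean_cols)
            df_l1 = n - X.shape[1] - (0 if result is None else grp.nunique())
            df_l2 = grp.nunique() - n_l2 - 1
            for name in params.index:
                df_map[name] = df_l2 if name.startswith("mean:") else df_l1
        pvals = _wald_p(params, bse, df_map, pvalue_method)

        for k in items:
            B.loc[it_j, k] = params[f"lag:{k}"]
            SE.loc[it_j, k] = bse[f"lag:{k}"]
            P.loc[it_j, k] = pvals[f"lag:{k}"]
            if f"mean:{k}" in params.index:
                bcoef.loc[it_j, k] = params[f"mean:{k}"]
                bse_m.loc[it_j, k] = bse[f"mean:{k}"]
                bp.loc[it_j, k] = pvals[f"mean:{k}"]
        resid.loc[mask, it_j] = yjv.to_numpy() - np.asarray(fitted)
        diag_rows.append((it_j, n, grp.nunique(), re_var, res_var, converged, fallback))

    diagnostics = FitDiagnostics(
        pd.DataFrame(
            diag_rows,
            columns=[
                "item", "n_obs", "n_persons", "random_intercept_var",
                "residual_var", "converged", "fallback",
            ],
        ).set_index("item")
    )
    temporal = TemporalNetwork(
        weights=B,
        se=SE,
        pvalues=P,
        n_obs=diagnostics["n_obs"],
        converged=diagnostics["converged"],
        fallback=diagnostics["fallback"].notna(),
    )
    resid = pd.concat([tab[["person_id", "day", "beep"]], resid], axis=1)
    return TemporalFit(
        temporal=temporal,
        residuals=resid,
        between_coef=bcoef,
        between_se=bse_m,
        between_p=bp,
        person_mean_sd=person_mean_sd,
        diagnostics=diagnostics,
        standardized=standardize,
        pvalue_method=pvalue_method,
    )


def fit_between(fit: TemporalFit) -> BetweenNetwork:
    """Combine the level-2 slopes into the between-subject network.

    Each raw slope b[j<-k] is standardised by the ratio of person-mean SDs
    (SD of mean_k over SD of mean_j), putting it on a correlation scale;
    the edge weight is the arithmetic mean of the two directions.  Pairs
    whose directional slopes disagree in sign get weight 0 and a flag
    (averaging across conflicting signs would fabricate a direction-free
    effect neither regression supports).
    """
    items = list(fit.between_coef.index)
    idx = pd.Index(items, name="item")
    w = pd.DataFrame(0.0, index=idx, columns=idx)
    p1 = pd.DataFrame(np.nan, index=idx, columns=idx)
    p2 = p1.copy()
    conflict = pd.DataFrame(False, index=idx, columns=idx)
    sd = fit.person_mean_sd
    for a_i, j in enumerate(items):
        for k in items[a_i + 1:]:
            bjk = fit.between_coef.loc[j, k] * sd[k] / sd[j]
            bkj = fit.between_coef.loc[k, j] * sd[j] / sd[k]
            if np.isnan(bjk) or np.isnan(bkj):
                w.loc[j, k] = w.loc[k, j] = np.nan
                continue
            if bjk * bkj < 0:
                conflict.loc[j, k] = conflict.loc[k, j] = True
                weight = 0.0
            else:
                weight = 0.5 * (bjk + bkj)
            w.loc[j, k] = w.loc[k, j] = weight
            p1.loc[j, k] = p1.loc[k, j] = fit.between_p.loc[j, k]
            p2.loc[j, k] = p2.loc[k, j] = fit.between_p.loc[k, j]
    return BetweenNetwork(weights=w, p1=p1, p2=p2, sign_conflict=conflict)


def fit_contemporaneous(
    residuals: pd.DataFrame, item_names: list[str] | None = None
) -> ContemporaneousNetwork:
    """Partial correlations of the temporal-model residuals.

    Node-wise OLS: each residual series is regressed on all the others
    over complete-case rows.  For a pair (j, k) with directional
    coefficients g_jk (k in j's model) and g_kj, the partial correlation is
    sign(g_jk) * sqrt(g_jk * g_kj) — an exact sample identity — unless the
    signs conflict, in which case the edge is 0 and flagged.  Directional
    OLS t-test p-values are retained for the display rule.
    """
    if item_names is None:
        item_names = [c for c in residuals.columns if c not in ("person_id", "day", "beep")]
    m = len(item_names)
    R = residuals[item_names].dropna()
    n = len(R)
    if n < m + 2:
        raise EstimationError(f"need at least {m + 2} complete residual rows, have {n}")
    X = R.to_numpy()
    # collinearity check with named culprits
    corr = np.corrcoef(X, rowvar=False)
    rank = np.linalg.matrix_rank(corr)
    if rank < m:
        off = np.abs(corr - np.eye(m))
        j, k = np.unravel_index(np.argmax(off), off.shape)
        raise EstimationError(
            f"residual matrix is rank deficient (rank {rank} < {m}); "
            f"most collinear pair: {item_names[j]} / {item_names[k]}"
        )

    gamma = np.full((m, m), np.nan)
    pmat = np.full((m, m), np.nan)
    for j in range(m):
        others = [k for k in range(m) if k != j]
        Xj = sm.add_constant(X[:, others])
        fitj = sm.OLS(X[:, j], Xj).fit()
        for pos, k in enumerate(others):
            gamma[j, k] = fitj.params[pos + 1]
            pmat[j, k] = fitj.pvalues[pos + 1]

    idx = pd.Index(item_names, name="item")
    w = pd.DataFrame(0.0, index=idx, columns=idx)
    p1 = pd.DataFrame(np.nan, index=idx, columns=idx)
    p2 = p1.copy()
    conflict = pd.DataFrame(False, index=idx, columns=idx)
    for j in range(m):
        for k in range(j + 1, m):
            gjk, gkj = gamma[j, k], gamma[k, j]
            if gjk * gkj < 0:
                conflict.iloc[j, k] = conflict.iloc[k, j] = True
                val = 0.0
            else:
                val = float(np.sign(gjk) * np.sqrt(gjk * gkj))
            w.iloc[j, k] = w.iloc[k, j] = val
            p1.iloc[j, k] = p1.iloc[k, j] = pmat[j, k]
            p2.iloc[j, k] = p2.iloc[k, j] = pmat[k, j]
    return ContemporaneousNetwork(weights=w, p1=p1, p2=p2, sign_conflict=conflict, n_obs=n)


def pcor_from_precision(cov: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Partial correlations from a covariance matrix via its inverse.

    pcor_jk = -P_jk / sqrt(P_jj * P_kk) where P = cov^{-1}; the diagonal
    is set to zero.  This is the Gaussian-graphical-model identity used as
    the independent cross-check for the regression-based estimator.
    """
    labels = None
    if isinstance(cov, pd.DataFrame):
        labels = cov.index
        cov = cov.to_numpy()
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive definite") from exc
    prec = np.linalg.inv(cov)
    d = np.sqrt(np.diag(prec))
    pcor = -prec / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    if labels is not None:
        return pd.DataFrame(pcor, index=labels, columns=labels)
    return pcor
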