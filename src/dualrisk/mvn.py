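"""Maximum likelihood for a partially observed multivariate normal.

This is the estimation core of the package: an EM algorithm for the
mean/covariance of a multivariate normal with arbitrary missingness
patterns (full-information maximum likelihood, FIML), a regression model
derived from the fitted joint moments, cluster-robust sandwich standard
errors built from per-cluster score contributions of the observed-data
likelihood, chi-square-based fit indices, and a paired change test.

The regression estimator is exposed statsmodels-style: a
:class:`FIMLRegression` model object whose :meth:`~FIMLRegression.fit`
returns a :class:`FIMLRegressionResults` carrying coefficients, robust
standard errors, Wald tests, R² and a ``summary()`` table.

Under the missing-at-random assumption the observed-data likelihood
yields unbiased estimates without discarding partially observed rows;
couples (or any grouping) are handled as nuisance clusters in the
sandwich covariance, not as model terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MvnFit",
    "em_mvn",
    "independence_loglik",
    "FIMLRegression",
    "FIMLRegressionResults",
    "fiml_regression",
    "delta_r2",
    "fit_indices",
    "FitIndices",
    "paired_change_test",
]

_LOG2PI = np.log(2.0 * np.pi)


class EstimationError(ValueError):
    """Estimation cannot proceed (degenerate input, collinearity, ...)."""


# ---------------------------------------------------------------------------
# EM for the partially observed MVN
# ---------------------------------------------------------------------------


@dataclass
class MvnFit:
    """ML estimate of a multivariate normal from partially observed data.

    Covariance uses the ML (n) denominator.  ``loglik_trace`` is the
    observed-data log-likelihood at the end of each EM iteration and is
    non-decreasing.
    """

    names: list[str]
    mean: np.ndarray
    cov: np.ndarray
    loglik: float
    n_obs: int
    n_patterns: int
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray
    ridge_applied: bool = False
    n_dropped_rows: int = 0

    @property
    def sds(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def corr(self) -> np.ndarray:
        s = self.sds
        return self.cov / np.outer(s, s)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_patterns": self.n_patterns,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "loglik_trace": self.loglik_trace.tolist(),
            "ridge_applied": self.ridge_applied,
        }


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(c) for c in data.columns]
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("data must be a 2-D table (observations x variables)")
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def _patterns(mask_obs: np.ndarray):
    """Group row indices by missingness pattern (mask_obs True = observed)."""
    uniq, inverse = np.unique(mask_obs, axis=0, return_inverse=True)
    return [(uniq[k].nonzero()[0], np.flatnonzero(inverse == k)) for k in range(len(uniq))]


def _observed_loglik(x: np.ndarray, patterns, mu: np.ndarray, sigma: np.ndarray) -> float:
    ll = 0.0
    for obs_idx, rows in patterns:
        soo = sigma[np.ix_(obs_idx, obs_idx)]
        diff = x[np.ix_(rows, obs_idx)] - mu[obs_idx]
        sign, logdet = np.linalg.slogdet(soo)
        if sign <= 0:
            return -np.inf
        sol = np.linalg.solve(soo, diff.T)
        quad = np.einsum("ij,ji->i", diff, sol)
        k = len(obs_idx)
        ll += -0.5 * (len(rows) * (k * _LOG2PI + logdet) + quad.sum())
    return float(ll)


def em_mvn(data, tol: float = 1e-8, max_iter: int = 500) -> MvnFit:
    """Fit mean and covariance of an MVN to data with missing entries.

    E-step: per missingness pattern, conditional means and covariances of
    the missing block given the observed block.  M-step: pooled moment
    update with the ML (n) denominator.  Iterates until the change in
    observed-data log-likelihood falls below ``tol``.

    Rows with every variable missing are dropped with a warning.  A
    variable observed fewer than twice is an error.  A singular
    covariance is ridge-regularized (1e-8 · trace/d on the diagonal) with
    a warning; non-convergence sets ``converged=False`` rather than
    raising.
    """
    x, names = _as_matrix(data)
    obs = np.isfinite(x)
    full_missing = ~obs.any(axis=1)
    n_dropped = int(full_missing.sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} fully missing rows", stacklevel=2)
        x, obs = x[~full_missing], obs[~full_missing]
    n, d = x.shape
    if n < 2:
        raise EstimationError("need at least 2 (partially) observed rows")
    per_var = obs.sum(axis=0)
    if (per_var < 2).any():
        bad = [names[j] for j in np.flatnonzero(per_var < 2)]
        raise EstimationError(f"variables observed fewer than twice: {bad}")

    patterns = _patterns(obs)

    # init: marginal means, diagonal ML variances (always PSD)
    xz = np.where(obs, x, 0.0)
    mu = xz.sum(axis=0) / per_var
    var = (np.where(obs, (x - mu) ** 2, 0.0)).sum(axis=0) / per_var
    var = np.maximum(var, 1e-12)
    sigma = np.diag(var)

    ridge_applied = False
    ll_trace = []
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        t1 = np.zeros(d)
        t2 = np.zeros((d, d))
        for obs_idx, rows in patterns:
            mis_idx = np.setdiff1d(np.arange(d), obs_idx, assume_unique=True)
            y = x[np.ix_(rows, obs_idx)]
            xhat = np.empty((len(rows), d))
            xhat[:, obs_idx] = y
            cadd = np.zeros((d, d))
            if len(mis_idx):
                soo = sigma[np.ix_(obs_idx, obs_idx)]
                smo = sigma[np.ix_(mis_idx, obs_idx)]
                sol = np.linalg.solve(soo, (y - mu[obs_idx]).T)  # k x n_p
                xhat[:, mis_idx] = mu[mis_idx] + (smo @ sol).T
                cond = sigma[np.ix_(mis_idx, mis_idx)] - smo @ np.linalg.solve(
                    soo, smo.T
                )
                cadd[np.ix_(mis_idx, mis_idx)] = len(rows) * cond
            t1 += xhat.sum(axis=0)
            t2 += xhat.T @ xhat + cadd
        mu = t1 / n
        sigma = t2 / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        eigmin = np.linalg.eigvalsh(sigma)[0]
        if eigmin < 1e-12 * np.trace(sigma) / d:
            ridge = 1e-8 * np.trace(sigma) / d
            sigma = sigma + ridge * np.eye(d)
            if not ridge_applied:
                warnings.warn(
                    f"singular covariance during EM; ridge {ridge:.3e} applied",
                    stacklevel=2,
                )
            ridge_applied = True
        ll = _observed_loglik(x, patterns, mu, sigma)
        ll_trace.append(ll)
        if np.isfinite(ll) and abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations", stacklevel=2)

    return MvnFit(
        names=names,
        mean=mu,
        cov=sigma,
        loglik=ll_trace[-1],
        n_obs=n,
        n_patterns=len(patterns),
        n_iter=it,
        converged=converged,
        loglik_trace=np.array(ll_trace),
        ridge_applied=ridge_applied,
        n_dropped_rows=n_dropped,
    )


def independence_loglik(data) -> tuple[float, int]:
    """ML log-likelihood of the independence (diagonal-covariance) model.

    Each variable gets its own ML mean and variance over its observed
    values; with a diagonal covariance the observed-data likelihood
    factorizes over cells.  Returns ``(loglik, n_constrained)`` where the
    second element is the number of covariances fixed to zero (the df of
    the baseline model for CFI).
    """
    x, names = _as_matrix(data)
    obs = np.isfinite(x)
    x = x[obs.any(axis=1)]
    obs = np.isfinite(x)
    d = x.shape[1]
    ll = 0.0
    for j in range(d):
        v = x[obs[:, j], j]
        if len(v) < 2:
            raise EstimationError(f"variable {names[j]} observed fewer than twice")
        m, s2 = v.mean(), v.var()  # ML (n) denominator
        ll += float(np.sum(stats.norm.logpdf(v, m, np.sqrt(s2))))
    return ll, d * (d - 1) // 2


# ---------------------------------------------------------------------------
# Scores of the observed-data likelihood (for the sandwich)
# ---------------------------------------------------------------------------


def _vech_pairs(d: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(d) for j in range(i, d)]


def _theta_pack(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    d = len(mu)
    pairs = _vech_pairs(d)
    return np.concatenate([mu, np.array([sigma[i, j] for i, j in pairs])])


def _theta_unpack(theta: np.ndarray, d: int):
    mu = theta[:d]
    sigma = np.zeros((d, d), dtype=theta.dtype)
    for k, (i, j) in enumerate(_vech_pairs(d)):
        sigma[i, j] = theta[d + k]
        sigma[j, i] = theta[d + k]
    return mu, sigma


def _row_scores(x: np.ndarray, patterns, theta: np.ndarray, d: int) -> np.ndarray:
    """Per-row score of the observed-data log-likelihood wrt (mu, vech Sigma).

    Analytic in theta, so it supports complex input (used for the
    complex-step observed information).
    """
    mu, sigma = _theta_unpack(theta, d)
    pairs = _vech_pairs(d)
    pos = {(i, j): k for k, (i, j) in enumerate(pairs)}
    p = d + len(pairs)
    scores = np.zeros((x.shape[0], p), dtype=theta.dtype)
    for obs_idx, rows in patterns:
        soo = sigma[np.ix_(obs_idx, obs_idx)]
        prec = np.linalg.inv(soo)
        diff = x[np.ix_(rows, obs_idx)] - mu[obs_idx]
        u = diff @ prec  # n_p x k ; rows are prec @ diff_i
        scores[np.ix_(rows, obs_idx)] = u
        # dl/dSigma_full (symmetric gradient) = 0.5 * (u_i u_i' - prec)
        g = 0.5 * (np.einsum("ni,nj->nij", u, u) - prec[None, :, :])
        for a, ia in enumerate(obs_idx):
            for b_, jb in enumerate(obs_idx):
                if ia > jb:
                    continue
                k = pos[(ia, jb)]
                mult = 1.0 if ia == jb else 2.0
                scores[rows, d + k] += mult * g[:, a, b_]
    return scores


def _observed_information(x, patterns, theta, d) -> np.ndarray:
    """-d(total score)/d(theta) via complex-step differentiation."""
    p = len(theta)
    a = np.zeros((p, p))
    h = 1e-20
    for k in range(p):
        th = theta.astype(complex)
        th[k] += 1j * h
        s = _row_scores(x, patterns, th, d).sum(axis=0)
        a[:, k] = -s.imag / h
    return 0.5 * (a + a.T)


# ---------------------------------------------------------------------------
# FIML regression
# ---------------------------------------------------------------------------


def _regression_from_theta(theta, d):
    """Map joint-MVN parameters to (b0, b) with the outcome first.

    Analytic (rational) in theta, so complex-step applies for the delta
    method.
    """
    mu, sigma = _theta_unpack(theta, d)
    sxx = sigma[1:, 1:]
    sxy = sigma[1:, 0]
    b = np.linalg.solve(sxx, sxy)
    b0 = mu[0] - b @ mu[1:]
    return np.concatenate([[b0], b])


class FIMLRegressionResults:
    """Results of a FIML regression with cluster-robust standard errors.

    Attributes
    ----------
    params : pandas.Series
        Raw coefficients, ``const`` first.
    bse, zvalues, pvalues : pandas.Series
        Cluster-robust (sandwich) standard errors and the Wald z tests
        (two-tailed, standard normal reference).
    params_standardized : pandas.Series
        Coefficients in SD units, ``beta_j = b_j * sd(x_j) / sd(y)`` with
        model-implied SDs from the joint FIML fit.
    rsquared : float
        Model-implied ``b' Sigma_xx b / sigma_yy``.
    mvn : MvnFit
        The underlying joint mean/covariance estimate.
    """

    def __init__(self, model, mvn: MvnFit, params, cov_params, n_clusters, correction):
        self.model = model
        self.mvn = mvn
        names = ["const"] + list(model.predictors)
        self.params = pd.Series(params, index=names)
        self.cov_params = pd.DataFrame(cov_params, index=names, columns=names)
        self.bse = pd.Series(np.sqrt(np.diag(cov_params)), index=names)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.params / self.bse
        self.zvalues = z
        self.pvalues = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=names)
        self.n_clusters = n_clusters
        self.cluster_correction = correction
        self.nobs = mvn.n_obs

        sxx = mvn.cov[1:, 1:]
        syy = mvn.cov[0, 0]
        b = params[1:]
        self.rsquared = float(b @ sxx @ b / syy)
        sd_x = np.sqrt(np.diag(sxx))
        sd_y = np.sqrt(syy)
        self.params_standardized = pd.Series(
            b * sd_x / sd_y, index=list(model.predictors)
        )
        self.bse_standardized = pd.Series(
            self.bse.iloc[1:].to_numpy() * sd_x / sd_y, index=list(model.predictors)
        )

    @property
    def llf(self) -> float:
        """Observed-data log-likelihood (the model is just-identified, so
        this equals the saturated joint-MVN log-likelihood)."""
        return self.mvn.loglik

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def fit_indices(self) -> "FitIndices":
        """Chi-square fit statistics against the saturated / baseline models.

        The regression is a reparametrization of the saturated joint
        normal, so its chi-square is 0 on 0 df (RMSEA reported as 0 with
        a note); the baseline is the independence model with free means
        and variances.
        """
        ll_base, df_base = independence_loglik(self.model._frame)
        return fit_indices(
            model_loglik=self.llf,
            saturated_loglik=self.mvn.loglik,
            baseline_loglik=ll_base,
            df_model=0,
            df_baseline=df_base,
            n=self.nobs,
        )

    def summary(self) -> str:
        lines = [
            "FIML regression (joint-normal ML, cluster-robust SEs)",
            f"  outcome: {self.model.outcome}   n_obs: {self.nobs}   "
            f"clusters: {self.n_clusters} ({self.cluster_correction})",
            f"  R^2: {self.rsquared:.4f}   loglik: {self.llf:.3f}   "
            f"EM iterations: {self.mvn.n_iter}"
            + ("" if self.mvn.converged else "   [NOT CONVERGED]"),
            "",
            f"  {'term':<16}{'b':>10}{'beta':>10}{'rob. SE':>10}{'z':>8}{'p':>9}",
        ]
        for name in self.params.index:
            beta = (
                f"{self.params_standardized[name]:>10.4f}"
                if name in self.params_standardized.index
                else " " * 10
            )
            lines.append(
                f"  {name:<16}{self.params[name]:>10.4f}{beta}"
                f"{self.bse[name]:>10.4f}{self.zvalues[name]:>8.2f}"
                f"{self.pvalues[name]:>9.4f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "outcome": self.model.outcome,
            "predictors": list(self.model.predictors),
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "zvalues": self.zvalues.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "params_standardized": self.params_standardized.to_dict(),
            "rsquared": self.rsquared,
            "nobs": int(self.nobs),
            "n_clusters": int(self.n_clusters),
            "loglik": float(self.llf),
            "converged": bool(self.mvn.converged),
        }


class FIMLRegression:
    """Linear regression under FIML with cluster-robust standard errors.

    The joint vector (outcome, predictors) is modelled as multivariate
    normal; the regression coefficients are derived from the fitted
    moments (``b = Sigma_xx^{-1} sigma_xy``), which is the ML regression
    under missing-at-random data and also uses rows with a missing
    outcome or missing predictors.  Standard errors come from a cluster
    sandwich over per-cluster score contributions of the observed-data
    likelihood, mapped to the coefficients by the delta method.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per observation; NaN marks missing.
    outcome, predictors : str, sequence of str
        Column names.
    cluster : str, optional
        Column holding cluster (couple) labels; omit for independent
        observations (each row its own cluster — the sandwich then
        reduces to the heteroskedasticity-robust form).
    """

    def __init__(self, data: pd.DataFrame, outcome: str, predictors, cluster: str | None = None):
        predictors = list(predictors)
        missing = [c for c in [outcome, *predictors] if c not in data.columns]
        if missing:
            raise EstimationError(f"columns absent from data: {missing}")
        if cluster is not None and cluster not in data.columns:
            raise EstimationError(f"cluster column {cluster!r} absent from data")
        self.outcome = outcome
        self.predictors = predictors
        self.cluster = cluster
        frame = data[[outcome, *predictors]].astype(float)
        keep = np.isfinite(frame.to_numpy()).any(axis=1)
        self._frame = frame.loc[keep].reset_index(drop=True)
        if cluster is not None:
            self._cluster_ids = data.loc[keep, cluster].to_numpy()
        else:
            self._cluster_ids = np.arange(keep.sum())
        self.n_dropped = int((~keep).sum())

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, cluster: str | None = None):
        """Build from a simple additive formula, e.g. ``"y ~ x1 + x2"``."""
        lhs, _, rhs = formula.partition("~")
        outcome = lhs.strip()
        predictors = [t.strip() for t in rhs.split("+") if t.strip() and t.strip() != "1"]
        if not outcome or not predictors:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(data, outcome, predictors, cluster=cluster)

    def fit(
        self,
        tol: float = 1e-8,
        max_iter: int = 500,
        small_sample: str = "CR1",
    ) -> FIMLRegressionResults:
        """Estimate the model.

        ``small_sample`` selects the cluster correction: ``"CR1"``
        multiplies the meat by G/(G-1) (default), ``"none"`` is plain
        CR0.
        """
        if small_sample not in ("CR1", "none"):
            raise ValueError("small_sample must be 'CR1' or 'none'")
        mvn = em_mvn(self._frame, tol=tol, max_iter=max_iter)
        d = len(mvn.names)
        p = len(self.predictors)

        codes, uniques = pd.factorize(self._cluster_ids)
        n_clusters = len(uniques)
        if n_clusters < p + 1:
            raise EstimationError(
                f"{n_clusters} clusters for {p} predictors: need at least predictors + 1"
            )

        corr_x = mvn.corr[1:, 1:]
        if p > 1:
            off = np.abs(corr_x - np.eye(p))
            i, j = np.unravel_index(off.argmax(), off.shape)
            if off[i, j] > 1.0 - 1e-6 or np.linalg.cond(corr_x) > 1e10:
                raise EstimationError(
                    f"collinear predictors: {self.predictors[i]!r} and "
                    f"{self.predictors[j]!r} (|r| = {np.abs(corr_x[i, j]):.6f})"
                )

        x = self._frame.to_numpy(dtype=float)
        # rows fully missing were not passed to em_mvn's internal drop; keep aligned
        obs = np.isfinite(x)
        keep = obs.any(axis=1)
        x, codes = x[keep], codes[keep]
        patterns = _patterns(np.isfinite(x))

        theta = _theta_pack(mvn.mean, mvn.cov)
        s = _row_scores(x, patterns, theta, d).real
        a = _observed_information(x, patterns, theta, d)

        g = np.zeros((n_clusters, len(theta)))
        np.add.at(g, codes, s)
        meat = g.T @ g
        if small_sample == "CR1" and n_clusters > 1:
            meat *= n_clusters / (n_clusters - 1)
        v_theta = np.linalg.solve(a, np.linalg.solve(a, meat).T)

        # delta method to (b0, b)
        jac = np.zeros((p + 1, len(theta)))
        h = 1e-20
        for k in range(len(theta)):
            th = theta.astype(complex)
            th[k] += 1j * h
            jac[:, k] = _regression_from_theta(th, d).imag / h
        params = _regression_from_theta(theta, d).real
        cov_params = jac @ v_theta @ jac.T
        cov_params = 0.5 * (cov_params + cov_params.T)

        return FIMLRegressionResults(self, mvn, params, cov_params, n_clusters, small_sample)


def fiml_regression(
    data: pd.DataFrame,
    outcome: str,
    predictors,
    cluster_ids=None,
    **fit_kwargs,
) -> FIMLRegressionResults:
    """Functional wrapper: fit a FIML regression in one call.

    ``cluster_ids`` may be a column name or an array aligned with
    ``data``'s rows.
    """
    if cluster_ids is None or isinstance(cluster_ids, str):
        return FIMLRegression(data, outcome, predictors, cluster=cluster_ids).fit(**fit_kwargs)
    work = data.copy()
    work["_cluster"] = np.asarray(cluster_ids)
    return FIMLRegression(work, outcome, predictors, cluster="_cluster").fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# Model comparison and fit statistics
# ---------------------------------------------------------------------------


def delta_r2(full, reduced) -> float:
    """Increment in explained variance between nested models.

    Accepts two :class:`FIMLRegressionResults` (the reduced predictor set
    must be a subset of the full set) or two plain R² floats.
    """
    if isinstance(full, FIMLRegressionResults) and isinstance(reduced, FIMLRegressionResults):
        if not set(reduced.model.predictors) <= set(full.model.predictors):
            raise EstimationError("models are not nested: reduced predictors not a subset")
        if full.model.outcome != reduced.model.outcome:
            raise EstimationError("models are not nested: different outcomes")
        return full.rsquared - reduced.rsquared
    return float(full) - float(reduced)


@dataclass
class FitIndices:
    chi2: float
    df: int
    pvalue: float
    rmsea: float
    cfi: float
    chi2_baseline: float
    df_baseline: int
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "pvalue": self.pvalue,
            "rmsea": self.rmsea,
            "cfi": self.cfi,
            "chi2_baseline": self.chi2_baseline,
            "df_baseline": self.df_baseline,
            "note": self.note,
        }


def fit_indices(
    model_loglik: float,
    saturated_loglik: float,
    baseline_loglik: float,
    df_model: int,
    df_baseline: int,
    n: int,
    eps: float = 1e-12,
) -> FitIndices:
    """Chi-square, RMSEA and CFI from model/saturated/baseline log-likelihoods.

    ``chi2 = 2 (ll_sat - ll_model)``;
    ``RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1)))`` (0 with a note when
    df = 0); ``CFI = 1 - max(chi2_m - df_m, 0) /
    max(chi2_b - df_b, chi2_m - df_m, eps)``.
    """
    tol = 1e-6 * max(1.0, abs(saturated_loglik))
    if model_loglik > saturated_loglik + tol:
        raise EstimationError("model log-likelihood exceeds the saturated log-likelihood")
    if baseline_loglik > model_loglik + tol:
        raise EstimationError("baseline log-likelihood exceeds the model log-likelihood")
    chi2_m = max(2.0 * (saturated_loglik - model_loglik), 0.0)
    chi2_b = max(2.0 * (saturated_loglik - baseline_loglik), 0.0)
    note = ""
    if df_model == 0:
        rmsea = 0.0
        pvalue = 1.0
        note = "model is just-identified (df = 0); RMSEA reported as 0"
    else:
        rmsea = float(np.sqrt(max(chi2_m - df_model, 0.0) / (df_model * (n - 1))))
        pvalue = float(stats.chi2.sf(chi2_m, df_model))
    cfi = 1.0 - max(chi2_m - df_model, 0.0) / max(
        chi2_b - df_baseline, chi2_m - df_model, eps
    )
    return FitIndices(
        chi2=float(chi2_m),
        df=int(df_model),
        pvalue=pvalue,
        rmsea=rmsea,
        cfi=float(cfi),
        chi2_baseline=float(chi2_b),
        df_baseline=int(df_baseline),
        note=note,
    )


def paired_change_test(w5, w6, pairing_ids=None):
    """One-sample t test on within-person differences (wave 6 - wave 5).

    When ``pairing_ids`` are given, the two vectors are aligned on them;
    otherwise they are taken as already aligned.  Only complete pairs
    enter.  Returns ``(t, df, p)`` with ``df = n_pairs - 1``.
    """
    w5 = np.asarray(w5, dtype=float)
    w6 = np.asarray(w6, dtype=float)
    if pairing_ids is not None:
        s5 = pd.Series(w5, index=pd.Index(pairing_ids[0] if isinstance(pairing_ids, tuple) else pairing_ids))
        s6 = pd.Series(w6, index=pd.Index(pairing_ids[1] if isinstance(pairing_ids, tuple) else pairing_ids))
        joined = pd.concat([s5, s6], axis=1, join="inner")
        w5, w6 = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    ok = np.isfinite(w5) & np.isfinite(w6)
    diff = (w6 - w5)[ok]
    if len(diff) < 2:
        raise EstimationError("paired change test needs at least 2 complete pairs")
    if diff.std(ddof=1) == 0.0:
        if np.all(diff == 0.0):
            # no change anywhere: t is 0 by convention (0/0 limit)
            return 0.0, int(len(diff) - 1), 1.0
        raise EstimationError("all differences identical and nonzero: zero-SD t is undefined")
    t, p = stats.ttest_1samp(diff, 0.0)
    return float(t), int(len(diff) - 1), float(p)
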