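"""Estimators for the exposure and participation equations.

Three fitters are provided:

* :func:`fit_ols` -- least squares on the observed (participant) log BLLs
  with the CR1 cluster-robust sandwich covariance, clustering on standard
  enumeration areas (SEAs), and t(G-1) P values;
* :func:`fit_probit` -- probit maximum likelihood for the participation
  equation, Fisher scoring with step-halving and an analytic gradient,
  clustered covariance;
* :func:`fit_heckman_two_step` -- the two-step selection correction: probit
  on the full sample, inverse Mills ratio lambda = psi/Psi evaluated at the
  fitted index of the selected records, then OLS of log BLL on the outcome
  regressors plus lambda.  The P value of lambda's coefficient is the test
  for selection on unobservables.

Estimation is unweighted throughout; the survey's sampling weights enter
only at the aggregation stage.

Also here: the Welch/pooled two-sample t test used for participant versus
non-participant balance diagnostics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import (
    CollinearityError,
    ConvergenceError,
    SeparationError,
    UndefinedStatisticError,
)
from .features import DesignMatrix

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100


@dataclass
class FitResult:
    """One fitted linear equation with cluster-robust inference."""

    params: pd.Series
    cov: pd.DataFrame
    bse: pd.Series
    pvalues: pd.Series
    r_squared: Optional[float]
    n_obs: int
    n_clusters: int
    resid: np.ndarray = field(repr=False, default=None)
    sigma2: Optional[float] = None  # SSR / (n - k)

    def tvalues(self) -> pd.Series:
        return self.params / self.bse


@dataclass
class ProbitFit:
    """Probit MLE: coefficients, clustered covariance and fitted index."""

    params: pd.Series
    cov: pd.DataFrame
    bse: pd.Series
    pvalues: pd.Series
    loglike: float
    index: np.ndarray = field(repr=False, default=None)
    probs: np.ndarray = field(repr=False, default=None)
    n_obs: int = 0
    n_clusters: int = 0
    loglike_path: list = field(default_factory=list, repr=False)


@dataclass
class HeckmanFit:
    """Two-step selection-corrected fit.

    ``selection_test`` is the P value of the inverse-Mills-ratio coefficient
    in the second stage; a small value indicates selection on unobservables.
    """

    first_stage: ProbitFit
    imr: pd.Series
    second_stage: FitResult
    selection_test: float


def _check_rank(X: np.ndarray, names) -> None:
    """Raise :class:`CollinearityError` naming suspect columns if X is rank deficient."""
    # Tiny diagonal entries of R flag (near-)rank deficiency; a pivoted QR
    # then attributes it to specific columns.
    _, r = np.linalg.qr(X, mode="reduced")
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.size else 0.0
    if scale == 0.0 or np.any(diag < 1e-10 * scale):
        # re-run with pivoting through scipy for column attribution
        from scipy.linalg import qr as sqr

        _, r2, piv = sqr(X, mode="economic", pivoting=True)
        d2 = np.abs(np.diag(r2))
        bad = [names[piv[i]] for i in range(len(d2)) if d2[i] < 1e-10 * max(d2.max(), 1e-300)]
        raise CollinearityError(bad or list(names))


def _cr1_cov(X: np.ndarray, u: np.ndarray, clusters: np.ndarray, bread_inv: np.ndarray) -> np.ndarray:
    """CR1 cluster sandwich: c * B (sum_g s_g s_g') B with s_g = X_g' u_g."""
    n, k = X.shape
    su = X * u[:, None]
    groups = pd.factorize(clusters)[0]
    G = groups.max() + 1
    S = np.zeros((G, k))
    np.add.at(S, groups, su)
    meat = S.T @ S
    c = (G / (G - 1.0)) * ((n - 1.0) / (n - k))
    return c * bread_inv @ meat @ bread_inv


def fit_ols(design: DesignMatrix) -> FitResult:
    """Least squares with CR1 cluster-robust standard errors.

    P values use a t distribution with G-1 degrees of freedom, G the number
    of clusters.  Requires more observations than columns and at least two
    clusters; a rank-deficient design raises :class:`CollinearityError`
    naming the collinear columns.
    """
    if design.y is None:
        raise ValueError("design has no outcome")
    X = design.values()
    y = design.y.to_numpy(dtype=float)
    names = design.columns
    n, k = X.shape
    clusters = np.asarray(design.clusters)
    G = len(pd.unique(clusters))
    if n <= k:
        raise ValueError(f"need n_obs > n_columns ({n} <= {k})")
    if G < 2:
        raise ValueError("need at least two clusters")
    _check_rank(X, names)

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    u = y - fitted
    ssr = float(u @ u)
    if "const" in names:
        sst = float(np.sum((y - y.mean()) ** 2))
    else:
        sst = float(y @ y)
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")

    xtx_inv = np.linalg.inv(X.T @ X)
    cov = _cr1_cov(X, u, clusters, xtx_inv)
    bse = np.sqrt(np.diag(cov))
    tstat = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=G - 1)
    idx = pd.Index(names)
    return FitResult(
        params=pd.Series(beta, index=idx),
        cov=pd.DataFrame(cov, index=idx, columns=idx),
        bse=pd.Series(bse, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        r_squared=r2,
        n_obs=n,
        n_clusters=G,
        resid=u,
        sigma2=ssr / (n - k),
    )


def inverse_mills(index) -> np.ndarray:
    """Inverse Mills ratio lambda(z) = psi(z) / Psi(z), the standard normal hazard.

    Computed through the scaled complementary error function, so it stays
    accurate far in the lower tail (where psi and Psi both underflow):
    lambda(z) = sqrt(2/pi) / erfcx(-z / sqrt(2)).
    """
    z = np.asarray(index, dtype=float)
    out = math.sqrt(2.0 / math.pi) / special.erfcx(-z / math.sqrt(2.0))
    return out if out.shape else float(out)


def fit_probit(
    design: DesignMatrix,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ProbitFit:
    """Probit MLE via Fisher scoring with step-halving.

    Convergence when the gradient max-norm falls below ``tol``.  The
    covariance is the CR1 clustered sandwich around the observed-information
    bread.  Raises :class:`SeparationError` when coefficients diverge (a
    symptom of perfect separation) and ValueError when the outcome is
    degenerate (all zero or all one).
    """
    if design.y is None:
        raise ValueError("design has no outcome")
    X = design.values()
    y = design.y.to_numpy(dtype=float)
    names = design.columns
    n, k = X.shape
    clusters = np.asarray(design.clusters)
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ValueError("binary outcome has a single class")
    _check_rank(X, names)

    beta = np.zeros(k)
    if "const" in names:
        beta[names.index("const")] = stats.norm.ppf(ybar)

    def loglike(b):
        z = X @ b
        return float(np.sum(y * stats.norm.logcdf(z) + (1 - y) * stats.norm.logcdf(-z)))

    ll = loglike(beta)
    ll_path = [ll]
    converged = False
    for _ in range(max_iter):
        z = X @ beta
        # score s_i = phi * (y - Phi) / (Phi * (1 - Phi)); lambda-form is stable
        lam_pos = inverse_mills(-z)  # phi/(1-Phi)
        lam_neg = inverse_mills(z)  # phi/Phi
        s = y * lam_neg - (1 - y) * lam_pos
        grad = X.T @ s
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = lam_neg * lam_pos  # phi^2 / (Phi (1-Phi)), expected information weight
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        # step-halving keeps the log-likelihood non-decreasing
        scale = 1.0
        for _half in range(50):
            cand = beta + scale * step
            ll_new = loglike(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = ll_new
        ll_path.append(ll)
        if np.max(np.abs(beta)) > 1e3 or ll > -1e-6:
            # a log-likelihood at (numerically) zero means every record is
            # classified perfectly: the MLE does not exist
            raise SeparationError(
                "coefficients diverging; the outcome may be perfectly separated"
            )
    if not converged:
        z = X @ beta
        grad = X.T @ (y * inverse_mills(z) - (1 - y) * inverse_mills(-z))
        if np.max(np.abs(grad)) >= tol:
            raise ConvergenceError(
                f"probit did not converge in {max_iter} iterations "
                f"(max |grad| = {np.max(np.abs(grad)):.3g})"
            )
    if ll > -1e-6:
        raise SeparationError("perfect classification: the probit MLE does not exist")

    z = X @ beta
    lam_pos = inverse_mills(-z)
    lam_neg = inverse_mills(z)
    s = y * lam_neg - (1 - y) * lam_pos
    w = lam_neg * lam_pos
    H = (X * w[:, None]).T @ X
    bread = np.linalg.inv(H)
    cov = _cr1_cov(X, s, clusters, bread)
    bse = np.sqrt(np.diag(cov))
    zstat = beta / bse
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    idx = pd.Index(names)
    return ProbitFit(
        params=pd.Series(beta, index=idx),
        cov=pd.DataFrame(cov, index=idx, columns=idx),
        bse=pd.Series(bse, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        loglike=ll,
        index=z,
        probs=stats.norm.cdf(z),
        n_obs=n,
        n_clusters=len(pd.unique(clusters)),
        loglike_path=ll_path,
    )


def fit_heckman_two_step(
    outcome_design: DesignMatrix,
    selection_design: DesignMatrix,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> HeckmanFit:
    """Two-step selection correction.

    Stage 1 fits the participation probit on all records of
    ``selection_design``; stage 2 regresses the observed log BLLs on the
    outcome regressors plus the inverse Mills ratio evaluated at the fitted
    selection index of the selected records, with cluster-robust standard
    errors that treat the ratio as an ordinary regressor.

    The outcome rows must be (a subset of) the selected rows of the
    selection design, matched by index.  If the selection design contains no
    regressor excluded from the outcome design, a warning is issued:
    identification then rests on the nonlinearity of the Mills ratio alone.
    """
    extra = set(selection_design.columns) - set(outcome_design.columns)
    if not extra:
        warnings.warn(
            "no exclusion restriction: selection design adds no regressor beyond "
            "the outcome design; identification relies on nonlinearity only",
            stacklevel=2,
        )
    first = fit_probit(selection_design, tol=tol, max_iter=max_iter)

    sel_index = pd.Series(first.index, index=selection_design.X.index)
    missing = outcome_design.X.index.difference(selection_design.X.index)
    if len(missing):
        raise ValueError("outcome rows missing from the selection design")
    selected_flag = selection_design.y.loc[outcome_design.X.index]
    if not (selected_flag == 1).all():
        raise ValueError("outcome design contains non-selected records")

    imr = pd.Series(
        inverse_mills(sel_index.loc[outcome_design.X.index].to_numpy()),
        index=outcome_design.X.index,
        name="imr",
    )
    X2 = outcome_design.X.copy()
    X2["imr"] = imr
    second_design = DesignMatrix(
        X=X2,
        y=outcome_design.y,
        clusters=outcome_design.clusters,
        cohort=outcome_design.cohort,
        equation="outcome",
        weights=outcome_design.weights,
    )
    second = fit_ols(second_design)
    return HeckmanFit(
        first_stage=first,
        imr=imr,
        second_stage=second,
        selection_test=float(second.pvalues["imr"]),
    )


def compare_groups(
    records: pd.DataFrame,
    variable: str,
    by: str = "participated",
    equal_var: bool = False,
):
    """Two-sample t test of identical means across the two ``by`` groups.

    Welch's unequal-variance form by default (``equal_var=True`` for the
    pooled version).  Returns (t statistic, P value).  Raises
    :class:`UndefinedStatisticError` when both groups have zero variance.
    """
    groups = records.groupby(records[by].astype(int))[variable]
    levels = sorted(groups.groups)
    if len(levels) != 2:
        raise UndefinedStatisticError(f"'{by}' must define exactly two nonempty groups")
    a = groups.get_group(levels[1]).dropna().to_numpy(dtype=float)
    b = groups.get_group(levels[0]).dropna().to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise UndefinedStatisticError("both groups must be nonempty")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise UndefinedStatisticError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def participation_balance(records: pd.DataFrame, variables) -> pd.DataFrame:
    """Participant vs non-participant means/SDs with t-test P values.

    The balance-table diagnostic: one row per variable with the group means,
    SDs and the Welch P value for identical means.
    """
    rows = []
    part = records["participated"].astype(int) == 1
    for var in variables:
        a = records.loc[part, var].dropna()
        b = records.loc[~part, var].dropna()
        t, p = compare_groups(records, var)
        rows.append(
            {
                "variable": var,
                "participant_mean": a.mean(),
                "participant_sd": a.std(ddof=1),
                "nonparticipant_mean": b.mean(),
                "nonparticipant_sd": b.std(ddof=1),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
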