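"""Core survival statistics.

This module houses the statistical machinery the screening pipeline is built
on:

* :func:`concordance_index` -- Harrell's C for right-censored data, with the
  exact pair bookkeeping (concordant / discordant / tied-risk comparable
  pairs) exposed on the returned :class:`PerformanceRecord`.
* :func:`logrank_test` / :func:`logrank_many` -- the two-group log-rank
  chi-square test.  ``logrank_many`` evaluates the test for many features at
  once (each feature defining its own two-group patient stratification),
  which is what makes 100-iteration split-half screening over hundreds of
  features per platform affordable.
* :func:`welch_t_test` / :func:`welch_many` -- two-sided unequal-variance
  t-tests (Welch-Satterthwaite degrees of freedom).
* :class:`CoxPH` -- a Cox proportional-hazards estimator in the scikit-learn
  idiom (``fit`` / ``predict`` / ``score``) backed by a vectorised
  Newton-Raphson maximiser of the partial likelihood with Efron handling of
  tied event times and step-halving.  The low-level :func:`cox_fit_raw` is
  exposed for callers (the exhaustive subset search) that need thousands of
  small fits without estimator overhead.

Survival outcomes are passed around as a structured numpy array with fields
``event`` (bool, death observed) and ``time`` (float, days) -- the same
convention scikit-survival uses; :func:`survival_array` builds one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

log = logging.getLogger(__name__)

SURVIVAL_DTYPE = np.dtype([("event", "?"), ("time", "<f8")])


def survival_array(time, event) -> np.ndarray:
    """Pack parallel time/event sequences into a structured survival array."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if time.size == 0:
        raise ValueError("survival sample must be nonempty")
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if np.any(~np.isfinite(time)) or np.any(time < 0):
        raise ValueError("survival times must be finite and nonnegative")
    out = np.empty(time.size, dtype=SURVIVAL_DTYPE)
    out["time"] = time
    out["event"] = event
    return out


def survival_from_clinical(clinical: pd.DataFrame) -> np.ndarray:
    """Survival array from a clinical table (``time_days`` / ``event``)."""
    return survival_array(clinical["time_days"].to_numpy(float),
                          clinical["event"].to_numpy(bool))


def as_survival(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.names is None or set(y.dtype.names) != {"event", "time"}:
        raise ValueError("y must be a structured array with 'event' and 'time' "
                         "fields; build one with survival_array(time, event)")
    return y


# ---------------------------------------------------------------------------
# Concordance index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerformanceRecord:
    """Pair bookkeeping behind a Harrell concordance index.

    Comparable pairs are ordered pairs (i, j) where patient i experienced the
    event and ``time_i < time_j`` (strictly); the pair is concordant when the
    predicted risk of i exceeds that of j, and tied risks count one half.
    """

    concordant: int
    discordant: int
    tied_risk: int

    @property
    def n_comparable(self) -> int:
        return self.concordant + self.discordant + self.tied_risk

    @property
    def cindex(self) -> float:
        return (self.concordant + 0.5 * self.tied_risk) / self.n_comparable


def concordance_index(risk, y) -> PerformanceRecord:
    """Harrell's concordance index of a risk score on censored outcomes.

    Higher risk is expected for shorter survival. Raises ``ValueError`` when
    no pair of patients is comparable (e.g. a single patient, or no events).
    """
    y = as_survival(y)
    risk = np.asarray(risk, dtype=float)
    if risk.shape != y.shape:
        raise ValueError("risk must be defined for every patient")
    if np.any(~np.isfinite(risk)):
        raise ValueError("risk scores must be finite for every patient")
    t, e = y["time"], y["event"]
    # i indexes the (event, earlier-time) member of each comparable pair
    comp = e[:, None] & (t[:, None] < t[None, :])
    dr = risk[:, None] - risk[None, :]
    conc = int(np.count_nonzero(comp & (dr > 0)))
    disc = int(np.count_nonzero(comp & (dr < 0)))
    tied = int(np.count_nonzero(comp & (dr == 0)))
    if conc + disc + tied == 0:
        raise ValueError("no comparable pairs: concordance undefined")
    return PerformanceRecord(conc, disc, tied)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    group_sizes: tuple = ()
    note: str = ""


def logrank_many(time, event, groups) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-group log-rank statistic for many stratifications at once.

    Parameters
    ----------
    time, event : arrays of length n
    groups : int array (n_features, n)
        Per feature: 1 = first group ("high"), 0 = second group ("low"),
        -1 = patient excluded for that feature.

    Returns ``(statistic, p_value, o_minus_e)`` arrays of length n_features,
    where ``o_minus_e`` is observed-minus-expected deaths in the first group
    (positive: the first group dies faster). Features whose pooled variance
    is zero (no events among included patients, or a degenerate grouping)
    get statistic 0 and p-value 1.
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    groups = np.asarray(groups)
    if groups.ndim == 1:
        groups = groups[None, :]
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    g = groups[:, order]
    # distinct times; per-feature tallies at each via grouped reductions
    _, starts = np.unique(t, return_index=True)
    inc = (g >= 0)
    hi = (g == 1)
    # at-risk counts: suffix sums evaluated at each distinct-time start
    n_risk = np.cumsum(inc[:, ::-1], axis=1)[:, ::-1][:, starts].astype(float)
    n1_risk = np.cumsum(hi[:, ::-1], axis=1)[:, ::-1][:, starts].astype(float)
    ev = e[None, :]
    d_all = np.add.reduceat((inc & ev).astype(float), starts, axis=1)
    d1 = np.add.reduceat((hi & ev).astype(float), starts, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_risk > 0, n1_risk / np.maximum(n_risk, 1), 0.0)
        oe = d1 - d_all * frac
        var = np.where(
            n_risk > 1,
            d_all * frac * (1.0 - frac) * (n_risk - d_all) / np.maximum(n_risk - 1.0, 1.0),
            0.0,
        )
    o_minus_e = oe.sum(axis=1)
    v = var.sum(axis=1)
    stat = np.zeros(groups.shape[0])
    p = np.ones(groups.shape[0])
    ok = v > 0
    stat[ok] = o_minus_e[ok] ** 2 / v[ok]
    p[ok] = sps.chi2.sf(stat[ok], df=1)
    return stat, p, o_minus_e


def logrank_test(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-group log-rank test between two survival samples.

    Both samples must be nonempty. If no event is observed in either group
    the curves cannot differ and the test degenerates to statistic 0 / p 1
    (a warning is emitted).
    """
    a = as_survival(a)
    b = as_survival(b)
    time = np.concatenate([a["time"], b["time"]])
    event = np.concatenate([a["event"], b["event"]])
    grp = np.concatenate([np.ones(a.size, np.int8), np.zeros(b.size, np.int8)])
    if not event.any():
        warnings.warn("log-rank test with zero events in both groups", stacklevel=2)
        return TestResult(0.0, 1.0, (a.size, b.size), note="no events")
    stat, p, _ = logrank_many(time, event, grp[None, :])
    return TestResult(float(stat[0]), float(p[0]), (a.size, b.size))


# ---------------------------------------------------------------------------
# Welch t-test
# ---------------------------------------------------------------------------

def welch_many(values, mask_a, mask_b) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature two-sided Welch t-test between two patient groups.

    ``values`` is (n_features, n) with NaN marking missing entries; the masks
    are boolean patient vectors. Features with fewer than two non-missing
    values in either group, or with zero pooled standard error, get NaN
    statistic and p-value (skipped, not fatal).
    """
    values = np.asarray(values, float)
    mask_a = np.asarray(mask_a, bool)
    mask_b = np.asarray(mask_b, bool)

    def _moments(mask):
        v = values[:, mask]
        ok = np.isfinite(v)
        n = ok.sum(axis=1).astype(float)
        s = np.where(ok, v, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = s / n
            ss = (np.where(ok, v, 0.0) ** 2).sum(axis=1)
            var = (ss - n * m**2) / (n - 1.0)
        return n, m, np.clip(var, 0.0, None)

    na, ma, va = _moments(mask_a)
    nb, mb, vb = _moments(mask_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        se2 = va / na + vb / nb
        tstat = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (va**2 / (na**2 * (na - 1.0)) + vb**2 / (nb**2 * (nb - 1.0)))
    bad = (na < 2) | (nb < 2) | ~np.isfinite(tstat)
    tstat = np.where(bad, np.nan, tstat)
    p = np.full(tstat.shape, np.nan)
    ok = ~bad
    p[ok] = 2.0 * sps.t.sf(np.abs(tstat[ok]), df[ok])
    return tstat, p


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Welch (unequal-variance) t-test between two value lists."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t_test requires >=2 non-missing values per group")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), (x.size, y.size))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties, Newton-Raphson with step-halving)
# ---------------------------------------------------------------------------

def _cox_setup(time: np.ndarray, event: np.ndarray) -> dict:
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(bool)
    death_pos = np.flatnonzero(e)
    d_times = t[death_pos]
    evt_times = np.unique(d_times)
    risk_start = np.searchsorted(t, evt_times, side="left")
    grp_start = np.searchsorted(d_times, evt_times, side="left")
    d_counts = np.diff(np.append(grp_start, death_pos.size))
    row_group = np.repeat(np.arange(evt_times.size), d_counts)
    if d_counts.size:
        row_frac = np.concatenate([np.arange(c) for c in d_counts]) / d_counts[row_group]
    else:
        row_frac = np.zeros(0)
    return dict(order=order, t=t, e=e, death_pos=death_pos, risk_start=risk_start,
                grp_start=grp_start, row_group=row_group, row_frac=row_frac)


def _suffix_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _cox_nll(beta, Xs, setup, derivs=True):
    """Negative Efron partial log-likelihood (and gradient / information)."""
    n, p = Xs.shape
    eta = Xs @ beta
    eta = eta - eta.max() if n else eta  # loglik is invariant to this shift
    w = np.exp(eta)
    dp = setup["death_pos"]
    rg = setup["row_group"]
    rf = setup["row_frac"]
    S_R = _suffix_cumsum(w)[setup["risk_start"]]
    S_D = np.add.reduceat(w[dp], setup["grp_start"]) if dp.size else np.zeros(0)
    denom = S_R[rg] - rf * S_D[rg]
    with np.errstate(divide="ignore"):
        nll = float(np.log(denom).sum() - eta[dp].sum())
    if not derivs:
        return nll
    Xw = Xs * w[:, None]
    MxR = _suffix_cumsum(Xw)[setup["risk_start"]]
    MxD = np.add.reduceat(Xw[dp], setup["grp_start"], axis=0)
    mbar = (MxR[rg] - rf[:, None] * MxD[rg]) / denom[:, None]
    grad = Xs[dp].sum(axis=0) - mbar.sum(axis=0)  # gradient of the loglik
    XXw = (Xs[:, :, None] * Xs[:, None, :]).reshape(n, p * p) * w[:, None]
    VxR = _suffix_cumsum(XXw)[setup["risk_start"]]
    VxD = np.add.reduceat(XXw[dp], setup["grp_start"], axis=0)
    a2 = ((VxR[rg] - rf[:, None] * VxD[rg]) / denom[:, None]).sum(axis=0).reshape(p, p)
    info = a2 - mbar.T @ mbar
    return nll, grad, info


def cox_null_loglik(time, event) -> float:
    """Partial log-likelihood of the empty (all-coefficients-zero) model."""
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    setup = _cox_setup(time, event)
    return -_cox_nll(np.zeros(0), np.zeros((time.size, 0)), setup, derivs=False)


# |beta| beyond this (per standardized covariate unit) signals a monotone
# likelihood / perfect risk separation rather than a plausible hazard ratio
_BETA_DIVERGED = 15.0


def cox_fit_raw(X, time, event, max_iter: int = 50, tol: float = 1e-9) -> dict:
    """Fit a Cox model on a dense complete-case design matrix.

    Returns a dict with ``beta``, ``loglik``, ``null_loglik``, ``converged``,
    ``n_iter`` and ``message``. Non-convergence (including monotone
    likelihood from perfect risk separation, and singular information from
    collinear covariates) is flagged, never raised.
    """
    X = np.ascontiguousarray(X, dtype=float)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    n, p = X.shape
    setup = _cox_setup(time, event)
    Xs = X[setup["order"]]
    beta = np.zeros(p)
    nll, grad, info = _cox_nll(beta, Xs, setup)
    null_loglik = -nll
    converged = False
    message = "ok"
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        scale = 1.0
        new_nll = None
        for _ in range(30):
            cand = beta + scale * step
            cand_nll = _cox_nll(cand, Xs, setup, derivs=False)
            if np.isfinite(cand_nll) and cand_nll <= nll:
                new_nll = cand_nll
                break
            scale *= 0.5
        if new_nll is None:
            # cannot improve: converged if the gradient is essentially zero
            converged = bool(np.linalg.norm(grad) < 1e-6 * max(1.0, abs(nll)))
            if not converged:
                message = "step-halving failed"
            break
        beta = beta + scale * step
        delta = nll - new_nll
        if np.max(np.abs(beta)) > _BETA_DIVERGED:
            message = "diverging coefficients (possible perfect separation)"
            nll = new_nll
            break
        nll, grad, info = _cox_nll(beta, Xs, setup)
        if (delta < tol * max(1.0, abs(nll))
                and np.max(np.abs(grad)) < 1e-6 * max(1.0, abs(nll))):
            converged = True
            break
    else:
        message = "maximum iterations reached"
    return dict(beta=beta, loglik=-nll, null_loglik=null_loglik,
                converged=converged, n_iter=it, message=message)


class CoxPH(BaseEstimator):
    """Cox proportional-hazards model with Efron tie handling.

    scikit-learn style estimator: ``fit(X, y)`` with X a patients-by-features
    DataFrame/array and y a structured survival array; ``predict`` returns
    the linear predictor (risk score, higher = shorter expected survival);
    ``score`` returns Harrell's C on complete-covariate rows.

    Rows with any missing covariate are dropped at fit time (complete-case
    analysis; missing values are never imputed). Fitted attributes:

    - ``coef_`` : pd.Series of log hazard ratios
    - ``log_likelihood_``, ``null_log_likelihood_``
    - ``aic_`` : -2 loglik + 2 k
    - ``n_used_`` : complete cases used
    - ``converged_``, ``fit_message_``
    """

    def __init__(self, max_iter: int = 50, tol: float = 1e-9):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        Xdf = pd.DataFrame(X)
        y = as_survival(y)
        if Xdf.shape[0] != y.size:
            raise ValueError("X and y have different numbers of patients")
        if Xdf.shape[1] < 1:
            raise ValueError("at least one covariate is required")
        V = Xdf.to_numpy(dtype=float)
        rows = ~np.isnan(V).any(axis=1)
        n_used = int(rows.sum())
        if n_used < Xdf.shape[1] + 2:
            raise ValueError(
                f"too few complete cases ({n_used}) for {Xdf.shape[1]} covariates")
        if not y["event"][rows].any():
            raise ValueError("no events among complete cases")
        raw = cox_fit_raw(V[rows], y["time"][rows], y["event"][rows],
                          max_iter=self.max_iter, tol=self.tol)
        self.feature_names_in_ = np.asarray(Xdf.columns, dtype=object)
        self.n_features_in_ = Xdf.shape[1]
        self.coef_ = pd.Series(raw["beta"], index=list(Xdf.columns), name="coef")
        self.log_likelihood_ = float(raw["loglik"])
        self.null_log_likelihood_ = float(raw["null_loglik"])
        self.aic_ = -2.0 * self.log_likelihood_ + 2.0 * Xdf.shape[1]
        self.n_used_ = n_used
        self.converged_ = bool(raw["converged"])
        self.fit_message_ = raw["message"]
        self.n_iter_ = raw["n_iter"]
        if not self.converged_:
            log.warning("Cox fit did not converge (%s): covariates %s",
                        self.fit_message_, list(Xdf.columns))
        return self

    def predict(self, X) -> np.ndarray:
        """Linear predictor; rows with missing covariates get NaN."""
        Xdf = pd.DataFrame(X)
        missing = [c for c in self.coef_.index if c not in Xdf.columns]
        if missing:
            raise ValueError(f"covariates absent from X: {missing}")
        V = Xdf[list(self.coef_.index)].to_numpy(dtype=float)
        return V @ self.coef_.to_numpy()

    def performance(self, X, y) -> PerformanceRecord:
        y = as_survival(y)
        risk = self.predict(X)
        rows = np.isfinite(risk)
        return concordance_index(risk[rows], y[rows])

    def score(self, X, y) -> float:
        return self.performance(X, y).cindex

    def coefficients_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"covariate": self.coef_.index,
                             "coefficient": self.coef_.to_numpy()})

    def to_tsv(self, path) -> None:
        self.coefficients_frame().to_csv(path, sep="\t", index=False)


def fit_cox(covariates: pd.DataFrame, y, **kwargs) -> CoxPH:
    """Functional wrapper: fit a :class:`CoxPH` on named covariate columns."""
    return CoxPH(**kwargs).fit(covariates, y)
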