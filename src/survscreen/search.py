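"""Exhaustive rank-k Cox model search and backward-AIC integration.

For each marker-selection approach the pipeline fits *every* size-r subset
of the candidate markers (r = model rank, 1..10 for the single approaches,
1..6 for the combined approach whose pool can reach 30 features) and keeps
the model with the highest training concordance index; AIC breaks ties,
then lexicographic covariate names. Subsets are streamed, never
materialised, and a configurable cap bounds the enumeration with a logged
downgrade.

Clinical integration follows backward elimination on AIC: starting from the
model containing all markers plus the clinical covariates (gender, age,
tumor grade, tumor stage as single integer-coded features), repeatedly drop
the covariate whose removal lowers AIC the most, stopping when no removal
improves it. The multi-omics model applies the same procedure to the union
of per-platform marker lists, disambiguated by platform-prefixed names.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .stats import (CoxPH, as_survival, concordance_index, cox_fit_raw,
                    cox_null_loglik, fit_cox)

log = logging.getLogger(__name__)

CLINICAL_COVARIATES = ("gender", "age", "grade", "stage")


@dataclass
class ModelSearchConfig:
    max_rank: int = 10
    max_rank_combined: int = 6
    clinical_covariates: tuple = CLINICAL_COVARIATES
    max_subsets: int | None = None  # cap on enumerated subsets per rank

    def __post_init__(self):
        if not 1 <= self.max_rank_combined <= self.max_rank:
            raise ValueError("need 1 <= max_rank_combined <= max_rank")

    def rank_limit(self, approach: str) -> int:
        return self.max_rank_combined if approach == "combined" else self.max_rank


def _subset_complete_rows(V: np.ndarray, cols: Sequence[int]) -> np.ndarray:
    return ~np.isnan(V[:, cols]).any(axis=1)


class BestSubsetCox(BaseEstimator):
    """Exhaustive best-subset Cox search at a fixed rank.

    ``fit(X, y)`` enumerates every ``rank``-sized subset of the columns of X
    (streamed via ``itertools.combinations``), fits a Cox model per subset
    on that subset's complete cases, and keeps the converged fit with the
    highest training concordance; ties break by lower AIC, then by
    lexicographic covariate names. ``max_subsets`` caps the enumeration
    (logged downgrade). Fitted attributes: ``model_`` (a refit
    :class:`~survscreen.stats.CoxPH`), ``features_``, ``train_c_``,
    ``n_evaluated_``, ``n_failed_``, ``capped_``.
    """

    def __init__(self, rank: int = 1, max_subsets: int | None = None,
                 max_iter: int = 50, tol: float = 1e-9):
        self.rank = rank
        self.max_subsets = max_subsets
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = as_survival(y)
        feats = list(X.columns)
        if len(feats) < self.rank:
            raise ValueError(f"need at least rank={self.rank} candidate features, "
                             f"got {len(feats)}")
        V = X.to_numpy(dtype=float)
        t, e = y["time"], y["event"]
        best = None  # (cindex, -aic, names, cols)
        n_eval = n_failed = 0
        capped = False
        for count, cols in enumerate(itertools.combinations(range(len(feats)),
                                                            self.rank)):
            if self.max_subsets is not None and count >= self.max_subsets:
                capped = True
                log.warning("subset search capped at %d of the possible "
                            "combinations (rank %d over %d candidates)",
                            self.max_subsets, self.rank, len(feats))
                break
            rows = _subset_complete_rows(V, cols)
            n = int(rows.sum())
            if n < self.rank + 2 or not e[rows].any():
                n_failed += 1
                continue
            raw = cox_fit_raw(V[np.ix_(rows, cols)], t[rows], e[rows],
                              max_iter=self.max_iter, tol=self.tol)
            if not raw["converged"]:
                n_failed += 1
                continue
            n_eval += 1
            risk = V[np.ix_(rows, cols)] @ raw["beta"]
            try:
                c = concordance_index(risk, y[rows]).cindex
            except ValueError:
                n_failed += 1
                continue
            aic = -2.0 * raw["loglik"] + 2.0 * self.rank
            names = tuple(str(feats[i]) for i in cols)
            key = (c, -aic, tuple(sorted(names)))
            if best is None or _better(key, best[0]):
                best = (key, cols)
        if best is None:
            raise RuntimeError(
                f"no rank-{self.rank} subset produced a converged Cox fit "
                f"({n_failed} failures over {len(feats)} candidates)")
        cols = best[1]
        self.features_ = [feats[i] for i in cols]
        self.model_ = CoxPH(max_iter=self.max_iter, tol=self.tol).fit(
            X[self.features_], y)
        self.train_c_ = float(best[0][0])
        self.n_evaluated_ = n_eval
        self.n_failed_ = n_failed
        self.capped_ = capped
        return self

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(pd.DataFrame(X)[self.features_])

    def score(self, X, y) -> float:
        return self.model_.score(pd.DataFrame(X)[self.features_], y)


def _better(a: tuple, b: tuple, tol: float = 1e-12) -> bool:
    """Lexicographic comparison with a float tolerance on C and AIC."""
    for x, y in zip(a[:2], b[:2]):
        if x > y + tol:
            return True
        if x < y - tol:
            return False
    return a[2] < b[2]


def best_model_per_rank(candidates: Sequence, X: pd.DataFrame, y, rank: int,
                        max_subsets: int | None = None) -> BestSubsetCox:
    """Best rank-``rank`` Cox model over a candidate marker pool."""
    pool = [c for c in candidates]
    return BestSubsetCox(rank=rank, max_subsets=max_subsets).fit(X[pool], y)


# ---------------------------------------------------------------------------
# Clinical model
# ---------------------------------------------------------------------------

def clinical_design(clinical: pd.DataFrame,
                    covariates: Sequence[str] = CLINICAL_COVARIATES) -> pd.DataFrame:
    """Clinical covariates as a numeric design matrix (gender binary, age
    continuous, grade/stage integer-coded ordinals)."""
    return clinical[list(covariates)].astype(float)


def clinical_model(clinical: pd.DataFrame, y=None,
                   covariates: Sequence[str] = CLINICAL_COVARIATES) -> CoxPH:
    """Cox model on clinical covariates only (complete-case fit)."""
    from .stats import survival_from_clinical
    X = clinical_design(clinical, covariates)
    if y is None:
        y = survival_from_clinical(clinical)
    frac = float(X.notna().all(axis=1).mean())
    if frac < 0.9:
        log.warning("clinical covariates complete for only %.0f%% of patients",
                    100 * frac)
    return fit_cox(X, y)


# ---------------------------------------------------------------------------
# Backward AIC elimination
# ---------------------------------------------------------------------------

class BackwardAICCox(BaseEstimator):
    """Backward covariate elimination on AIC for Cox models.

    Starts from the model containing every column of X, fitted on the
    complete cases of that full covariate set; those rows stay fixed for the
    whole elimination path so AIC values are comparable across steps. Each
    step removes the single covariate whose removal yields the lowest AIC,
    as long as that AIC is lower than the current model's; elimination may
    run down to the empty (null) model. If the initial fit fails, the model
    falls back to ``fallback_covariates`` (typically the clinical block)
    with a logged warning.

    Fitted attributes: ``features_``, ``aic_trace_`` (strictly decreasing),
    ``removed_``, ``model_`` (``None`` when everything was eliminated).
    """

    def __init__(self, fallback_covariates: Sequence[str] = (),
                 max_iter: int = 50, tol: float = 1e-9):
        self.fallback_covariates = tuple(fallback_covariates)
        self.max_iter = max_iter
        self.tol = tol

    def _raw_aic(self, V, t, e, cols):
        if not cols:
            return -2.0 * cox_null_loglik(t, e), None
        raw = cox_fit_raw(V[:, cols], t, e, max_iter=self.max_iter, tol=self.tol)
        if not raw["converged"]:
            return np.inf, raw
        return -2.0 * raw["loglik"] + 2.0 * len(cols), raw

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = as_survival(y)
        feats = list(X.columns)
        Vall = X.to_numpy(dtype=float)
        rows = ~np.isnan(Vall).any(axis=1)
        self.fallback_used_ = False
        ok = rows.sum() >= len(feats) + 2 and y["event"][rows].any()
        if ok:
            aic0, raw0 = self._raw_aic(Vall[rows], y["time"][rows],
                                       y["event"][rows], list(range(len(feats))))
            ok = np.isfinite(aic0)
        if not ok:
            fallback = [c for c in self.fallback_covariates if c in X.columns]
            log.warning("initial backward-AIC model failed to fit; falling back "
                        "to covariates %s", fallback)
            self.fallback_used_ = True
            feats = fallback
            if not feats:
                raise RuntimeError("initial model failed and no fallback "
                                   "covariates are available")
            Vall = X[feats].to_numpy(dtype=float)
            rows = ~np.isnan(Vall).any(axis=1)
            aic0, raw0 = self._raw_aic(Vall[rows], y["time"][rows],
                                       y["event"][rows], list(range(len(feats))))
            if not np.isfinite(aic0):
                raise RuntimeError("fallback clinical model failed to fit")
        V = Vall[rows]
        t, e = y["time"][rows], y["event"][rows]
        current = list(range(len(feats)))
        aic = aic0
        trace = [aic0]
        removed = []
        while current:
            best_aic = np.inf
            best_drop = None
            for i in current:
                cand = [c for c in current if c != i]
                cand_aic, _ = self._raw_aic(V, t, e, cand)
                if cand_aic < best_aic - 1e-12:
                    best_aic = cand_aic
                    best_drop = i
            if best_drop is None or best_aic >= aic - 1e-12:
                break
            current = [c for c in current if c != best_drop]
            removed.append(feats[best_drop])
            aic = best_aic
            trace.append(aic)
        self.features_ = [feats[i] for i in current]
        self.aic_trace_ = trace
        self.aic_ = aic
        self.removed_ = removed
        self.n_rows_ = int(rows.sum())
        if self.features_:
            self.model_ = CoxPH(max_iter=self.max_iter, tol=self.tol).fit(
                X.loc[rows, self.features_], y[rows])
        else:
            self.model_ = None
            log.warning("backward elimination removed every covariate; the "
                        "final model is the null model")
        return self

    def predict(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        if self.model_ is None:
            return np.zeros(X.shape[0])
        return self.model_.predict(X[self.features_])

    def score(self, X, y) -> float:
        y = as_survival(y)
        risk = self.predict(X)
        rows = np.isfinite(risk)
        return concordance_index(risk[rows], y[rows]).cindex


def backward_aic_integration(markers: pd.DataFrame, clinical: pd.DataFrame,
                             y=None,
                             covariates: Sequence[str] = CLINICAL_COVARIATES,
                             ) -> BackwardAICCox:
    """Integrate molecular markers with clinical covariates via backward AIC.

    ``markers`` is a patients-by-markers value matrix (may be empty); the
    clinical block is always part of the initial model and serves as the
    fallback when the full initial model cannot be fitted.
    """
    from .stats import survival_from_clinical
    clin_X = clinical_design(clinical, covariates)
    markers = pd.DataFrame(markers) if markers is not None else pd.DataFrame(index=clin_X.index)
    if len(markers.columns):
        markers = markers.loc[clin_X.index]
        X = pd.concat([markers, clin_X], axis=1)
    else:
        X = clin_X
    if y is None:
        y = survival_from_clinical(clinical)
    return BackwardAICCox(fallback_covariates=covariates).fit(X, y)


def multi_omics_design(per_platform: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Union of per-platform marker matrices with platform-prefixed names."""
    blocks = []
    for platform, block in per_platform.items():
        if block is None or block.shape[1] == 0:
            continue
        renamed = block.rename(columns={c: f"{platform}:{c}" for c in block.columns})
        blocks.append(renamed)
    if not blocks:
        return pd.DataFrame()
    out = pd.concat(blocks, axis=1)
    return out


def multi_omics_model(per_platform: Mapping[str, pd.DataFrame],
                      clinical: pd.DataFrame, y=None,
                      covariates: Sequence[str] = CLINICAL_COVARIATES,
                      ) -> BackwardAICCox:
    """Multi-omics integration: platform-prefixed marker union + clinical."""
    design = multi_omics_design(per_platform)
    if design.shape[1] == 0:
        log.info("multi-omics model with no markers reduces to the clinical model")
    return backward_aic_integration(design if design.shape[1] else None,
                                    clinical, y=y, covariates=covariates)
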