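"""Resampling-based prognostic marker selection.

Three stratification approaches screen each molecular feature of a training
cohort for association with overall survival, each repeated over 100 random
split-half iterations of the training cohort:

* **extreme score** -- within each half, patients with Z-score > 1 form a
  "high" group and Z-score < -1 a "low" group; a feature scores one
  iteration when the two-group log-rank test is significant (p < 0.05) in
  both halves and both groups hold at least 10 patients in each half;
* **mean score** -- same machinery with the threshold at Z = 0 (above vs
  below the training average; Z exactly 0 is assigned to the low group);
* **extreme survival** -- within each half, patients who died within the
  first year versus patients who lived longer than five years; a feature
  scores when the Welch t-test on its raw values separates the two groups
  in both halves.  Halves without 10 short- and 10 long-survivors skip the
  whole iteration (excluded from the frequency denominator).

Features are ranked by selection frequency and the top 10 returned as
:class:`MarkerCandidate` rows; the **combined** approach is the union of the
three top lists (up to 30 candidates).  Somatic mutations get a single
carrier-versus-non-carrier log-rank screen instead of resampling.

The selectors are scikit-learn style estimators: ``fit(X, y)`` with X a
patients-by-features DataFrame (Z-scores for the score approaches, raw
values for the survival approach) and y a structured survival array;
``transform`` keeps the selected columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .stats import as_survival, logrank_many, welch_many

log = logging.getLogger(__name__)

CANDIDATE_COLUMNS = ("feature_id", "frequency", "n_iterations_effective",
                     "direction", "mean_p", "approach")


@dataclass
class SelectionConfig:
    """Tunables of the resampling marker screen (defaults = study values)."""

    n_iterations: int = 100
    z_extreme: float = 1.0
    z_mean: float = 0.0
    min_group: int = 10
    alpha: float = 0.05
    short_survival_days: float = 365.0
    long_survival_days: float = 1825.0
    top_k: int = 10
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_group < 1:
            raise ValueError("min_group must be >= 1")
        if not self.short_survival_days < self.long_survival_days:
            raise ValueError("short survival horizon must precede the long one")


def stratify_by_z(values: np.ndarray, lower: float, upper: float,
                  low_inclusive: bool = True) -> np.ndarray:
    """Group labels from per-patient values: 1 strictly above ``upper``, 0
    below ``lower``, -1 excluded (between thresholds, or missing).

    ``low_inclusive`` controls the low boundary: the mean-score screen uses
    ``Z <= 0`` (a value exactly at the threshold goes to the low group,
    keeping the rule deterministic), while the extreme screen uses the
    strict ``Z < -1``.
    """
    values = np.asarray(values, float)
    out = np.full(values.shape, -1, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        out[values > upper] = 1
        out[(values <= lower) if low_inclusive else (values < lower)] = 0
    out[~np.isfinite(values)] = -1
    return out


def survival_strata(y, short_days: float, long_days: float) -> tuple[np.ndarray, np.ndarray]:
    """Short-survivor / long-survivor masks.

    Short survivors died (event observed) within ``short_days``; long
    survivors have observed or censored time beyond ``long_days`` (a patient
    alive past five years is a long survivor whether or not they later
    died). Patients censored before the short horizon belong to neither.
    """
    y = as_survival(y)
    short = y["event"] & (y["time"] <= short_days)
    long_ = y["time"] > long_days
    return short, long_


def _rank_candidates(features, freq, n_eff, mean_p, worse_votes, better_votes,
                     top_k, approach) -> pd.DataFrame:
    """Frequency-desc ranking with (mean passing p, feature id) tie-breaks."""
    sel = freq > 0
    if not sel.any():
        log.warning("%s: no feature was ever selected", approach)
        return pd.DataFrame(columns=list(CANDIDATE_COLUMNS))
    feats = np.asarray(features, dtype=object)[sel]
    freq = freq[sel]
    mp = mean_p[sel] / freq
    direction = np.where(worse_votes[sel] > better_votes[sel], "high_worse",
                         np.where(better_votes[sel] > worse_votes[sel],
                                  "high_better", "undetermined"))
    order = np.lexsort((feats.astype(str), mp, -freq))
    order = order[: top_k] if top_k is not None else order
    return pd.DataFrame({
        "feature_id": feats[order],
        "frequency": freq[order].astype(int),
        "n_iterations_effective": n_eff,
        "direction": direction[order],
        "mean_p": mp[order],
        "approach": approach,
    })


class _SplitHalfSelector(BaseEstimator):
    """Shared machinery of the split-half resampling screens.

    One random half-split is drawn per iteration and shared by every feature
    of the platform. Splits are drawn over the *sorted* patient ids, so the
    result is invariant to the row order of X (only the ids and the seed
    matter).
    """

    approach = ""

    def __init__(self, n_iterations=100, min_group=10, alpha=0.05, top_k=10,
                 rng_seed=0):
        self.n_iterations = n_iterations
        self.min_group = min_group
        self.alpha = alpha
        self.top_k = top_k
        self.rng_seed = rng_seed

    @classmethod
    def from_config(cls, cfg: SelectionConfig, rng_seed: int | None = None):
        kw = dict(n_iterations=cfg.n_iterations, min_group=cfg.min_group,
                  alpha=cfg.alpha, top_k=cfg.top_k,
                  rng_seed=cfg.rng_seed if rng_seed is None else rng_seed)
        extra = cls._config_kwargs(cfg)
        return cls(**kw, **extra)

    @staticmethod
    def _config_kwargs(cfg: SelectionConfig) -> dict:
        return {}

    # subclasses: given per-half value slice (F, n_half) and survival slice,
    # return (passed, p, worse_sign) arrays, or None to skip the iteration.
    def _screen_half(self, values, y):  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = as_survival(y)
        if X.shape[0] != y.size:
            raise ValueError("X and y have different numbers of patients")
        ids_sorted = np.array(sorted(map(str, X.index)), dtype=object)
        pos = pd.Index(X.index.astype(str)).get_indexer(ids_sorted)
        values = X.to_numpy(dtype=float).T  # (F, n)
        n = values.shape[1]
        F = values.shape[0]
        rng = np.random.default_rng(self.rng_seed)
        freq = np.zeros(F, dtype=int)
        p_sum = np.zeros(F)
        worse = np.zeros(F, dtype=int)
        better = np.zeros(F, dtype=int)
        n_eff = 0
        n_skipped = 0
        for _ in range(self.n_iterations):
            perm = rng.permutation(n)
            halves = (pos[perm[: n // 2]], pos[perm[n // 2:]])
            it_pass = np.ones(F, dtype=bool)
            it_p = np.zeros(F)
            it_sign = np.zeros(F)
            skipped = False
            for half in halves:
                res = self._screen_half(values[:, half], y[half])
                if res is None:
                    skipped = True
                    break
                passed, p, sign = res
                it_pass &= passed
                it_p += np.where(np.isfinite(p), p, 1.0)
                it_sign += np.where(passed, sign, 0.0)
            if skipped:
                n_skipped += 1
                continue
            n_eff += 1
            freq[it_pass] += 1
            p_sum[it_pass] += it_p[it_pass] / 2.0
            worse[it_pass & (it_sign > 0)] += 1
            better[it_pass & (it_sign < 0)] += 1
        if n_skipped:
            log.info("%s: %d/%d iterations skipped (ineligible half-splits)",
                     self.approach, n_skipped, self.n_iterations)
        self.n_effective_ = n_eff
        self.n_skipped_ = n_skipped
        self.frequencies_ = pd.Series(freq, index=X.columns, name="frequency")
        self.candidates_ = _rank_candidates(
            list(X.columns), freq, n_eff, p_sum, worse, better, self.top_k,
            self.approach)
        self.selected_features_ = list(self.candidates_["feature_id"])
        return self

    def get_support(self) -> list:
        return list(self.selected_features_)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.selected_features_]


class _ZThresholdSelector(_SplitHalfSelector):
    """Log-rank screen between groups defined by Z-score thresholds."""

    z_low = 0.0
    z_high = 0.0
    low_inclusive = True

    def _screen_half(self, values, y):
        g = stratify_by_z(values, self.z_low, self.z_high, self.low_inclusive)
        n_high = (g == 1).sum(axis=1)
        n_low = (g == 0).sum(axis=1)
        eligible = (n_high >= self.min_group) & (n_low >= self.min_group)
        if not eligible.any():
            # still a valid iteration: every feature simply fails it
            return np.zeros(values.shape[0], bool), np.ones(values.shape[0]), \
                np.zeros(values.shape[0])
        stat, p, oe = logrank_many(y["time"], y["event"], g)
        passed = eligible & (p < self.alpha)
        # oe > 0: more deaths than expected in the high group -> high is worse
        return passed, p, np.sign(oe)


class ExtremeScoreSelector(_ZThresholdSelector):
    """Extreme score stratification: Z > 1 ("extremely high") vs Z < -1."""

    approach = "extreme_score"
    low_inclusive = False

    def __init__(self, n_iterations=100, min_group=10, alpha=0.05, top_k=10,
                 rng_seed=0, z_extreme=1.0):
        super().__init__(n_iterations, min_group, alpha, top_k, rng_seed)
        self.z_extreme = z_extreme

    @staticmethod
    def _config_kwargs(cfg: SelectionConfig) -> dict:
        return {"z_extreme": cfg.z_extreme}

    @property
    def z_low(self):
        return -self.z_extreme

    @property
    def z_high(self):
        return self.z_extreme


class MeanScoreSelector(_ZThresholdSelector):
    """Mean score stratification: above vs below the training average."""

    approach = "mean_score"

    def __init__(self, n_iterations=100, min_group=10, alpha=0.05, top_k=10,
                 rng_seed=0, z_threshold=0.0):
        super().__init__(n_iterations, min_group, alpha, top_k, rng_seed)
        self.z_threshold = z_threshold

    @staticmethod
    def _config_kwargs(cfg: SelectionConfig) -> dict:
        return {"z_threshold": cfg.z_mean}

    @property
    def z_low(self):
        return self.z_threshold

    @property
    def z_high(self):
        return self.z_threshold


class ExtremeSurvivalSelector(_SplitHalfSelector):
    """Extreme survival stratification: first-year deaths vs 5-year survivors.

    Operates on raw (untransformed) molecular values; features score an
    iteration when the Welch t-test separates the two patient groups in both
    halves. Iterations whose halves lack 10 patients in either group are
    skipped for all features and removed from the frequency denominator.
    """

    approach = "extreme_survival"

    def __init__(self, n_iterations=100, min_group=10, alpha=0.05, top_k=10,
                 rng_seed=0, short_survival_days=365.0, long_survival_days=1825.0):
        super().__init__(n_iterations, min_group, alpha, top_k, rng_seed)
        self.short_survival_days = short_survival_days
        self.long_survival_days = long_survival_days

    @staticmethod
    def _config_kwargs(cfg: SelectionConfig) -> dict:
        return {"short_survival_days": cfg.short_survival_days,
                "long_survival_days": cfg.long_survival_days}

    def _screen_half(self, values, y):
        short, long_ = survival_strata(y, self.short_survival_days,
                                       self.long_survival_days)
        if short.sum() < self.min_group or long_.sum() < self.min_group:
            return None
        t, p = welch_many(values, short, long_)
        passed = np.isfinite(p) & (p < self.alpha)
        # higher values among short survivors -> high is worse
        return passed, p, np.sign(np.where(np.isfinite(t), t, 0.0))


def combined_candidates(lists: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Union of per-approach candidate lists (the combined approach).

    Each feature keeps its maximum frequency, the direction of the
    highest-frequency occurrence, and a merged provenance string.
    """
    frames = [f for f in lists if len(f)]
    if not frames:
        return pd.DataFrame(columns=list(CANDIDATE_COLUMNS))
    allc = pd.concat(frames, ignore_index=True)
    rows = []
    for fid, grp in allc.groupby("feature_id", sort=False):
        best = grp.sort_values(["frequency", "approach"],
                               ascending=[False, True]).iloc[0]
        rows.append({
            "feature_id": fid,
            "frequency": int(grp["frequency"].max()),
            "n_iterations_effective": int(grp["n_iterations_effective"].max()),
            "direction": best["direction"],
            "mean_p": float(grp["mean_p"].min()),
            "approach": "+".join(sorted(grp["approach"].unique())),
        })
    out = pd.DataFrame(rows)
    out = out.sort_values(["frequency", "mean_p", "feature_id"],
                          ascending=[False, True, True], kind="stable")
    return out.reset_index(drop=True)


class MutationSelector(BaseEstimator):
    """Carrier vs non-carrier log-rank screen for somatic mutation calls.

    No resampling: one log-rank test per gene (or per variant, depending on
    how the binary matrix is keyed) on the full training cohort; genes with
    p < alpha and at least ``min_group`` patients on both sides are
    returned, frequency fixed at 1.
    """

    approach = "mutation"

    def __init__(self, min_group=10, alpha=0.05, rng_seed=0):
        self.min_group = min_group
        self.alpha = alpha
        self.rng_seed = rng_seed  # unused; kept for interface symmetry

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = as_survival(y)
        values = X.to_numpy(dtype=float).T
        g = np.full(values.shape, -1, dtype=np.int8)
        with np.errstate(invalid="ignore"):
            g[values == 1] = 1
            g[values == 0] = 0
        n1 = (g == 1).sum(axis=1)
        n0 = (g == 0).sum(axis=1)
        eligible = (n1 >= self.min_group) & (n0 >= self.min_group)
        stat, p, oe = logrank_many(y["time"], y["event"], g)
        passed = eligible & (p < self.alpha)
        feats = np.asarray(X.columns, dtype=object)[passed]
        order = np.argsort(p[passed], kind="stable")
        self.candidates_ = pd.DataFrame({
            "feature_id": feats[order],
            "frequency": 1,
            "n_iterations_effective": 1,
            "direction": np.where(oe[passed][order] > 0, "high_worse",
                                  np.where(oe[passed][order] < 0, "high_better",
                                           "undetermined")),
            "mean_p": p[passed][order],
            "approach": self.approach,
        })
        self.frequencies_ = pd.Series(passed.astype(int), index=X.columns)
        self.selected_features_ = list(self.candidates_["feature_id"])
        return self

    def get_support(self) -> list:
        return list(self.selected_features_)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.selected_features_]


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def extreme_score_selection(z: pd.DataFrame, y, cfg: SelectionConfig,
                            rng_seed: int | None = None) -> pd.DataFrame:
    return ExtremeScoreSelector.from_config(cfg, rng_seed).fit(z, y).candidates_


def mean_score_selection(z: pd.DataFrame, y, cfg: SelectionConfig,
                         rng_seed: int | None = None) -> pd.DataFrame:
    return MeanScoreSelector.from_config(cfg, rng_seed).fit(z, y).candidates_


def extreme_survival_selection(raw: pd.DataFrame, y, cfg: SelectionConfig,
                               rng_seed: int | None = None) -> pd.DataFrame:
    return ExtremeSurvivalSelector.from_config(cfg, rng_seed).fit(raw, y).candidates_


def mutation_gene_selection(binary: pd.DataFrame, y,
                            cfg: SelectionConfig) -> pd.DataFrame:
    return MutationSelector(min_group=cfg.min_group,
                            alpha=cfg.alpha).fit(binary, y).candidates_
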