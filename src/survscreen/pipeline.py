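"""Three-fold ordered cross-validation over the marker screen and model
search, plus the association reports.

Patients are sorted by survival/follow-up time and dealt round-robin into
k = 3 equally sized sets, so the sets are balanced in survival time and
vital status; each round trains on two sets (Z-score fitting, marker
selection, model search) and evaluates the winning models on the held-out
third. Nothing fitted in a round ever sees the round's test patients: the
training stage receives a cohort restricted to the training ids.

Aggregation reports per (platform, approach, rank) the mean and standard
deviation of the train/test concordance over the three rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort, OmicsMatrix, filter_features, fit_zscore
from .search import (BackwardAICCox, BestSubsetCox, ModelSearchConfig,
                     backward_aic_integration, clinical_design, clinical_model,
                     multi_omics_model)
from .selection import (CANDIDATE_COLUMNS, ExtremeScoreSelector,
                        ExtremeSurvivalSelector, MeanScoreSelector,
                        MutationSelector, SelectionConfig, combined_candidates)
from .stats import CoxPH, as_survival, concordance_index, survival_from_clinical

log = logging.getLogger(__name__)

APPROACHES = ("extreme_score", "mean_score", "extreme_survival", "combined")

ROW_COLUMNS = ("round", "platform", "approach", "rank", "n_candidates",
               "train_c", "test_c")


@dataclass(frozen=True)
class CVPlan:
    """An ordered k-fold assignment of patient ids."""

    k: int
    sets: tuple

    def __post_init__(self):
        sizes = [len(s) for s in self.sets]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("CV set sizes must differ by at most one")
        flat = [p for s in self.sets for p in s]
        if len(flat) != len(set(flat)):
            raise ValueError("CV sets must be disjoint")

    def train_ids(self, test_index: int) -> list:
        return [p for i, s in enumerate(self.sets) if i != test_index for p in s]

    def test_ids(self, test_index: int) -> list:
        return list(self.sets[test_index])


def assign_cv_sets(clinical: pd.DataFrame, k: int = 3) -> CVPlan:
    """Sort patients by survival/follow-up time and deal them round-robin.

    Ties in time break by (event desc, patient id asc) so deceased and
    censored patients with equal times interleave deterministically. The
    assignment is fully deterministic given the clinical table.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(clinical) < k:
        raise ValueError("cohort smaller than the number of CV sets")
    ids = [pid for _, _, pid in sorted(
        (float(clinical.loc[pid, "time_days"]),
         not bool(clinical.loc[pid, "event"]), str(pid))
        for pid in clinical.index)]
    sets = tuple(tuple(ids[i::k]) for i in range(k))
    return CVPlan(k=k, sets=sets)


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Spawn n reproducible component seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


# ---------------------------------------------------------------------------
# One cross-validation round
# ---------------------------------------------------------------------------

@dataclass
class RoundFit:
    """Everything fitted on one round's training cohort."""

    round_index: int
    scalers: dict = field(default_factory=dict)
    candidates: dict = field(default_factory=dict)     # (platform, approach) -> DataFrame
    rank_models: dict = field(default_factory=dict)    # (platform, approach, rank) -> BestSubsetCox
    integrated: dict = field(default_factory=dict)     # platform -> BackwardAICCox
    mutation_model: CoxPH | None = None
    mutation_features: list = field(default_factory=list)
    clinical: CoxPH | None = None
    multi_omics: BackwardAICCox | None = None


def fit_training(train: Cohort, selection_cfg: SelectionConfig,
                 search_cfg: ModelSearchConfig, seed: int,
                 platforms=None, approaches=APPROACHES,
                 round_index: int = 0) -> RoundFit:
    """Run the full training stage of one round on a training-only cohort.

    The argument carries *only* training patients, which structurally
    prevents test-set leakage during selection and model fitting.
    """
    y = survival_from_clinical(train.clinical)
    out = RoundFit(round_index=round_index)
    platform_list = [p for p in train.omics if platforms is None or p in platforms]
    seeds = derive_seeds(seed, 3 * max(len(platform_list), 1))
    si = 0
    for platform in platform_list:
        m = train.omics[platform]
        if platform == "mutation":
            try:
                sel = MutationSelector(min_group=selection_cfg.min_group,
                                       alpha=selection_cfg.alpha).fit(m.X(), y)
                out.candidates[(platform, "mutation")] = sel.candidates_
                if sel.selected_features_:
                    out.mutation_features = sel.selected_features_
                    out.mutation_model = CoxPH().fit(
                        m.X()[sel.selected_features_], y)
            except Exception:
                log.exception("mutation platform failed; skipping")
            continue
        try:
            scaler = fit_zscore(m, train.patients)
            Z = scaler.transform(m.X())
            out.scalers[platform] = scaler
            lists = {}
            if "extreme_score" in approaches:
                lists["extreme_score"] = ExtremeScoreSelector.from_config(
                    selection_cfg, seeds[si]).fit(Z, y).candidates_
            if "mean_score" in approaches:
                lists["mean_score"] = MeanScoreSelector.from_config(
                    selection_cfg, seeds[si + 1]).fit(Z, y).candidates_
            if "extreme_survival" in approaches:
                lists["extreme_survival"] = ExtremeSurvivalSelector.from_config(
                    selection_cfg, seeds[si + 2]).fit(m.X(), y).candidates_
            if "combined" in approaches:
                lists["combined"] = combined_candidates(list(lists.values()))
            si += 3
            for approach, cand in lists.items():
                out.candidates[(platform, approach)] = cand
                pool = list(cand["feature_id"])
                for rank in range(1, search_cfg.rank_limit(approach) + 1):
                    if len(pool) < rank:
                        break
                    try:
                        model = BestSubsetCox(
                            rank=rank, max_subsets=search_cfg.max_subsets
                        ).fit(Z[pool], y)
                        out.rank_models[(platform, approach, rank)] = model
                    except (RuntimeError, ValueError) as exc:
                        log.warning("%s/%s rank %d search failed: %s",
                                    platform, approach, rank, exc)
            combined = out.candidates.get((platform, "combined"))
            if combined is not None and len(combined):
                markers = Z[list(combined["feature_id"])]
                out.integrated[platform] = backward_aic_integration(
                    markers, train.clinical, y,
                    covariates=search_cfg.clinical_covariates)
        except Exception:
            log.exception("platform %s failed; skipping", platform)
    try:
        out.clinical = clinical_model(train.clinical,
                                      covariates=search_cfg.clinical_covariates)
    except Exception:
        log.exception("clinical-only model failed")
    # multi-omics: union of each platform's combined marker list
    per_platform = {}
    for platform in platform_list:
        cand = out.candidates.get((platform, "combined"))
        if cand is None or not len(cand) or platform not in out.scalers:
            continue
        Z = out.scalers[platform].transform(train.omics[platform].X())
        per_platform[platform] = Z[list(cand["feature_id"])]
    if out.mutation_features and "mutation" in platform_list:
        per_platform["mutation"] = train.omics["mutation"].X()[out.mutation_features]
    try:
        out.multi_omics = multi_omics_model(
            per_platform, train.clinical, y,
            covariates=search_cfg.clinical_covariates)
    except Exception:
        log.exception("multi-omics model failed")
    return out


def _safe_score(model, X, y) -> float:
    try:
        return float(model.score(X, y))
    except ValueError as exc:
        log.warning("test-set scoring failed: %s", exc)
        return np.nan


def evaluate_round(fit: RoundFit, train: Cohort, test: Cohort,
                   search_cfg: ModelSearchConfig) -> pd.DataFrame:
    """Score every fitted model of a round on the held-out test cohort."""
    y_test = survival_from_clinical(test.clinical)
    y_train = survival_from_clinical(train.clinical)
    rows = []

    def add(platform, approach, rank, n_cand, train_c, test_c):
        rows.append(dict(round=fit.round_index, platform=platform,
                         approach=approach, rank=rank, n_candidates=n_cand,
                         train_c=train_c, test_c=test_c))

    for (platform, approach, rank), model in fit.rank_models.items():
        scaler = fit.scalers[platform]
        Zt = scaler.transform(test.omics[platform].X())
        n_cand = len(fit.candidates[(platform, approach)])
        add(platform, approach, rank, n_cand, model.train_c_,
            _safe_score(model, Zt, y_test))
    for platform, model in fit.integrated.items():
        scaler = fit.scalers[platform]
        Zt = scaler.transform(test.omics[platform].X())
        Xt = pd.concat([Zt, clinical_design(test.clinical,
                                            search_cfg.clinical_covariates)], axis=1)
        Ztr = scaler.transform(train.omics[platform].X())
        Xtr = pd.concat([Ztr, clinical_design(train.clinical,
                                              search_cfg.clinical_covariates)], axis=1)
        add(platform, "integrated", 0, len(model.features_),
            _safe_score(model, Xtr, y_train), _safe_score(model, Xt, y_test))
    if fit.mutation_model is not None:
        Xt = test.omics["mutation"].X()[fit.mutation_features]
        Xtr = train.omics["mutation"].X()[fit.mutation_features]
        add("mutation", "mutation", 0, len(fit.mutation_features),
            _safe_score(fit.mutation_model, Xtr, y_train),
            _safe_score(fit.mutation_model, Xt, y_test))
    if fit.clinical is not None:
        Xt = clinical_design(test.clinical, search_cfg.clinical_covariates)
        Xtr = clinical_design(train.clinical, search_cfg.clinical_covariates)
        add("clinical", "clinical", 0, 0,
            _safe_score(fit.clinical, Xtr, y_train),
            _safe_score(fit.clinical, Xt, y_test))
    if fit.multi_omics is not None and fit.multi_omics.features_:
        def multi_design(cohort):
            blocks = []
            for platform, scaler in fit.scalers.items():
                Z = scaler.transform(cohort.omics[platform].X())
                blocks.append(Z.rename(columns={c: f"{platform}:{c}"
                                                for c in Z.columns}))
            if fit.mutation_features:
                mm = cohort.omics["mutation"].X()[fit.mutation_features]
                blocks.append(mm.rename(columns={c: f"mutation:{c}"
                                                 for c in mm.columns}))
            blocks.append(clinical_design(cohort.clinical,
                                          search_cfg.clinical_covariates))
            return pd.concat(blocks, axis=1)

        add("multi_omics", "integrated", 0, len(fit.multi_omics.features_),
            _safe_score(fit.multi_omics, multi_design(train), y_train),
            _safe_score(fit.multi_omics, multi_design(test), y_test))
    return pd.DataFrame(rows, columns=list(ROW_COLUMNS))


def run_round(cohort: Cohort, plan: CVPlan, test_index: int,
              selection_cfg: SelectionConfig | None = None,
              search_cfg: ModelSearchConfig | None = None,
              seed: int = 0, platforms=None,
              approaches=APPROACHES) -> tuple[pd.DataFrame, RoundFit]:
    """Train on two CV sets, evaluate on the held-out one."""
    selection_cfg = selection_cfg or SelectionConfig()
    search_cfg = search_cfg or ModelSearchConfig()
    train = cohort.subset(plan.train_ids(test_index))
    test = cohort.subset(plan.test_ids(test_index))
    fit = fit_training(train, selection_cfg, search_cfg, seed,
                       platforms=platforms, approaches=approaches,
                       round_index=test_index)
    rows = evaluate_round(fit, train, test, search_cfg)
    return rows, fit


def aggregate(rows: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Cross-round mean and standard deviation per (platform, approach, rank).

    Cells observed in fewer than k rounds are flagged ``complete = False``
    rather than silently averaged.
    """
    grouped = rows.groupby(["platform", "approach", "rank"], sort=True)
    summary = grouped.agg(
        train_c_mean=("train_c", "mean"), train_c_sd=("train_c", "std"),
        test_c_mean=("test_c", "mean"), test_c_sd=("test_c", "std"),
        n_rounds=("round", "nunique"),
    ).reset_index()
    summary["complete"] = summary["n_rounds"] == k
    if (~summary["complete"]).any():
        log.warning("%d summary cells observed in fewer than %d rounds",
                    int((~summary["complete"]).sum()), k)
    return summary


@dataclass
class CVResult:
    plan: CVPlan
    rows: pd.DataFrame
    summary: pd.DataFrame
    markers: pd.DataFrame
    fits: list


def run_cv(cohort: Cohort, selection_cfg: SelectionConfig | None = None,
           search_cfg: ModelSearchConfig | None = None, k: int = 3,
           master_seed: int = 0, platforms=None,
           approaches=APPROACHES) -> CVResult:
    """The full pipeline: feature filtering, ordered k-fold CV, aggregation."""
    selection_cfg = selection_cfg or SelectionConfig()
    search_cfg = search_cfg or ModelSearchConfig()
    n = len(cohort.clinical)
    filtered = Cohort(
        clinical=cohort.clinical,
        omics={p: filter_features(m, n) for p, m in cohort.omics.items()},
        normals=cohort.normals, segments=cohort.segments,
        annotation=cohort.annotation, mutations=cohort.mutations,
        ground_truth=cohort.ground_truth)
    plan = assign_cv_sets(filtered.clinical, k=k)
    seeds = derive_seeds(master_seed, k)
    all_rows = []
    all_markers = []
    fits = []
    for r in range(k):
        log.info("cross-validation round %d/%d", r + 1, k)
        rows, fit = run_round(filtered, plan, r, selection_cfg, search_cfg,
                              seed=seeds[r], platforms=platforms,
                              approaches=approaches)
        all_rows.append(rows)
        fits.append(fit)
        for (platform, approach), cand in fit.candidates.items():
            if not len(cand):
                continue
            c = cand.copy()
            c["platform"] = platform
            c["round"] = r
            all_markers.append(c)
    rows = pd.concat(all_rows, ignore_index=True)
    markers = (pd.concat(all_markers, ignore_index=True) if all_markers
               else pd.DataFrame(columns=list(CANDIDATE_COLUMNS) + ["platform", "round"]))
    return CVResult(plan=plan, rows=rows, summary=aggregate(rows, k=k),
                    markers=markers, fits=fits)


# ---------------------------------------------------------------------------
# Auxiliary association reports
# ---------------------------------------------------------------------------

def stage_association_report(m: OmicsMatrix, clinical: pd.DataFrame,
                             features=None) -> pd.DataFrame:
    """Spearman association of marker values with integer tumor stage."""
    feats = list(features) if features is not None else m.feature_ids
    stage = clinical["stage"].astype(float)
    rows = []
    for f in feats:
        v = m.values.loc[f].reindex(clinical.index).astype(float)
        ok = v.notna() & stage.notna()
        sub_v, sub_s = v[ok], stage[ok]
        if sub_s.nunique() < 2 or sub_v.nunique() < 2:
            rows.append(dict(feature_id=f, rho=np.nan, p_value=np.nan,
                             n=int(ok.sum()), status="skipped"))
            continue
        rho, p = sps.spearmanr(sub_v, sub_s)
        rows.append(dict(feature_id=f, rho=float(rho), p_value=float(p),
                         n=int(ok.sum()), status="ok"))
    return pd.DataFrame(rows)


def meth_expr_report(meth: pd.DataFrame, expr: pd.DataFrame, pairs,
                     tissue: pd.Series) -> pd.DataFrame:
    """Methylation-expression interconnection per feature pair.

    ``meth``/``expr`` are features-by-samples frames that may mix tumor and
    normal samples; ``tissue`` labels every sample ('tumor' or 'normal').
    Each pair gets within-tissue methylation means, a Welch t-test of
    methylation tumor vs normal, and the cross-sample Pearson correlation
    between methylation and expression.
    """
    from .stats import welch_t_test
    rows = []
    for meth_f, expr_f in pairs:
        mv = meth.loc[meth_f]
        ev = expr.loc[expr_f]
        lab = tissue.reindex(mv.index)
        tum = mv[(lab == "tumor") & mv.notna()]
        nor = mv[(lab == "normal") & mv.notna()]
        status = "ok"
        if len(tum) < 3 or len(nor) < 3:
            status = "insufficient_samples"
        t_stat = p = np.nan
        if len(tum) >= 2 and len(nor) >= 2:
            res = welch_t_test(tum.to_numpy(), nor.to_numpy())
            t_stat, p = res.statistic, res.p_value
        common = mv.index.intersection(ev.index)
        both = mv[common].notna() & ev[common].notna()
        corr = np.nan
        if both.sum() >= 3:
            corr = float(np.corrcoef(mv[common][both], ev[common][both])[0, 1])
        rows.append(dict(
            meth_feature=meth_f, expr_feature=expr_f,
            meth_mean_tumor=float(tum.mean()) if len(tum) else np.nan,
            meth_mean_normal=float(nor.mean()) if len(nor) else np.nan,
            t_statistic=t_stat, p_value=p, correlation=corr,
            n_tumor=int(len(tum)), n_normal=int(len(nor)), status=status))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plots (optional, thin)
# ---------------------------------------------------------------------------

def plot_rank_curves(summary: pd.DataFrame, path=None):
    """Test concordance versus model rank, one panel per platform."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    data = summary[summary["approach"].isin(APPROACHES)]
    platforms = sorted(data["platform"].unique())
    if not platforms:
        return None
    fig, axes = plt.subplots(1, len(platforms), figsize=(4 * len(platforms), 3.5),
                             squeeze=False, sharey=True)
    clin = summary[summary["approach"] == "clinical"]
    for ax, platform in zip(axes[0], platforms):
        sub = data[data["platform"] == platform]
        for approach, grp in sub.groupby("approach"):
            grp = grp.sort_values("rank")
            ax.plot(grp["rank"], grp["test_c_mean"], marker="o", label=approach)
        if len(clin):
            ax.axhline(float(clin["test_c_mean"].iloc[0]), color="gray",
                       linestyle="--", linewidth=1, label="clinical only")
        ax.set_title(platform)
        ax.set_xlabel("model rank (number of markers)")
        ax.set_ylim(0.3, 1.0)
    axes[0][0].set_ylabel("test C-index (mean over rounds)")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_integration(summary: pd.DataFrame, path=None):
    """Omics-only vs omics+clinical vs clinical-only comparison bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    best_omics = (summary[summary["approach"].isin(APPROACHES)]
                  .groupby("platform")["test_c_mean"].max())
    integrated = (summary[summary["approach"] == "integrated"]
                  .set_index("platform")["test_c_mean"])
    clin = summary[summary["approach"] == "clinical"]["test_c_mean"]
    fig, ax = plt.subplots(figsize=(7, 3.5))
    platforms = sorted(best_omics.index)
    x = np.arange(len(platforms))
    ax.bar(x - 0.2, [best_omics.get(p, np.nan) for p in platforms], 0.4,
           label="omics only")
    ax.bar(x + 0.2, [integrated.get(p, np.nan) for p in platforms], 0.4,
           label="omics + clinical")
    if len(clin):
        ax.axhline(float(clin.iloc[0]), color="gray", linestyle="--",
                   label="clinical only")
    ax.set_xticks(x, platforms)
    ax.set_ylabel("test C-index")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
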