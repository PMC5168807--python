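"""Synthetic multi-omics survival cohorts with known ground truth.

The generator emulates the statistical structure of a TCGA-style clear-cell
renal carcinoma cohort at desk scale: right-censored overall survival,
clinical covariates (gender, age, grade, stage), Gaussian molecular values
per expression platform, beta-valued methylation obtained by a logistic
transform of a latent normal, per-patient copy-number segmentations whose
gene-level summary is recovered through interval mapping, sparse binary
somatic mutations, and whole-patient per-platform missingness mirroring the
availability table of such cohorts.

Survival follows a Weibull proportional-hazards mechanism: with linear
predictor lp (clinical terms plus planted molecular terms), event times are

    T = scale * (E / exp(lp)) ** (1 / shape),  E ~ Exp(1),

which satisfies proportional hazards by construction. Censoring is an
independent uniform horizon calibrated so the realised censoring fraction
matches the requested target.

Every planted marker is driven by a standard-normal latent score that
enters the log hazard linearly with its coefficient beta; the observed
feature is a monotone map of the latent score (identity for expression,
logistic for methylation, a scaled copy for CNV segment means, carrier
status for mutations), so selection on Z-scores sees the planted signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, OmicsMatrix, map_genes_to_segments, mutation_matrix

log = logging.getLogger(__name__)

# Per-platform tumor-sample availability of the motivating cohort
# (patients with a molecular profile, out of 533).
_AVAILABILITY = {"mirna": 493, "mrna": 518, "protein": 454,
                 "cnv": 511, "methylation": 477, "mutation": 533}

DEFAULT_FEATURE_COUNTS = {"mirna": 150, "mrna": 400, "protein": 123,
                          "cnv": 200, "methylation": 300, "mutation": 80}

DEFAULT_MISSING = {p: 1.0 - n / 533.0 for p, n in _AVAILABILITY.items()}

STAGE_PROBS = (267 / 536, 57 / 536, 126 / 536, 86 / 536)
GRADE_PROBS = (0.25, 0.40, 0.25, 0.10)

DEFAULT_CLINICAL_BETAS = {"gender": 0.1, "age_per_decade": 0.3,
                          "grade": 0.3, "stage": 0.5}


@dataclass(frozen=True)
class PlantedMarker:
    """One feature given a known hazard effect.

    ``beta`` is the log hazard ratio per standard deviation of the latent
    score; ``stage_coupling`` adds that many latent units per tumor stage
    step (stage-coupled methylation markers); ``pair_with`` names a feature
    on another platform whose latent score is the (sign-flipped) copy of
    this one, emulating methylation-expression anti-correlation.
    """

    platform: str
    index: int
    beta: float
    stage_coupling: float = 0.0
    pair_with: tuple | None = None  # (platform, index, sign)

    def feature_id(self) -> str:
        return feature_name(self.platform, self.index)


def feature_name(platform: str, index: int) -> str:
    prefix = {"mirna": "mir", "mrna": "gene", "protein": "prot",
              "cnv": "cnv_gene", "methylation": "cg", "mutation": "mut_gene"}
    return f"{prefix.get(platform, platform)}-{index:04d}"


@dataclass
class SimulationConfig:
    """Study conditions of a simulated cohort (defaults = cohort scale of
    the motivating study: 533 patients, 176/533 observed deaths, per-platform
    availability as in its data-availability table)."""

    n_patients: int = 533
    feature_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_COUNTS))
    planted: Sequence[PlantedMarker] = ()
    clinical_betas: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_BETAS))
    weibull_shape: float = 1.1
    weibull_scale: float = 2500.0  # days
    censoring_fraction: float = 357 / 533
    missing_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING))
    scattered_missing_fraction: float = 0.0
    mutation_rate_range: tuple = (0.01, 0.12)
    n_normals: Mapping[str, int] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.censoring_fraction < 1.0:
            raise ValueError(
                f"censoring fraction must lie strictly in (0, 1); achievable "
                f"range is open on both ends, got {self.censoring_fraction}")
        for m in self.planted:
            if m.index >= self.feature_counts.get(m.platform, 0):
                raise ValueError(f"planted marker index {m.index} out of range "
                                 f"for platform {m.platform}")
            if not np.isfinite(m.beta):
                raise ValueError("planted beta must be finite")


@dataclass
class GroundTruth:
    """What the generator knows: realised per-patient linear predictor,
    planted marker registry, latent scores and censoring outcome."""

    linear_predictor: pd.Series
    planted: pd.DataFrame
    latent: pd.DataFrame  # planted feature ids x patients
    censoring_fraction_realized: float
    n_events: int


def _censoring_horizon(t_event: np.ndarray, target: float) -> float:
    """Uniform-horizon scale c such that E[P(C < T)] = target, C ~ U(0, c)."""
    lo, hi = 1e-9, float(t_event.max()) * 1e6 + 1.0

    def frac(c):
        return float(np.minimum(t_event / c, 1.0).mean())

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _simulate_clinical(rng, n) -> pd.DataFrame:
    ids = [f"PT{i:04d}" for i in range(n)]
    return pd.DataFrame({
        "gender": rng.integers(0, 2, n),
        "age": np.clip(rng.normal(60.0, 12.0, n), 25.0, 90.0).round(1),
        "grade": rng.choice([1, 2, 3, 4], size=n, p=GRADE_PROBS),
        "stage": rng.choice([1, 2, 3, 4], size=n, p=STAGE_PROBS),
    }, index=pd.Index(ids, name="patient_id"))


def _random_segmentation(rng, chrom_lengths, patients, gene_frame,
                         planted_values: dict) -> pd.DataFrame:
    """Per-patient tiling segmentations; planted genes get their own segment
    carrying the patient's planted segment mean."""
    records = []
    planted_by_chrom: dict[str, list] = {}
    for (gid, chrom, gs, ge), vals in planted_values.items():
        planted_by_chrom.setdefault(chrom, []).append((gs, ge, vals))
    for pid_i, pid in enumerate(patients):
        for chrom, L in chrom_lengths.items():
            k = 1 + rng.poisson(3)
            cuts = np.sort(rng.uniform(0, L, k - 1)).astype(int) if k > 1 else np.array([], int)
            bounds = np.concatenate([[0], np.unique(cuts), [L]])
            starts, ends = bounds[:-1], bounds[1:]
            means = rng.normal(0.0, 0.25, starts.size)
            segs = list(zip(starts.tolist(), ends.tolist(), means.tolist()))
            for gs, ge, vals in planted_by_chrom.get(chrom, []):
                carved = []
                for s, e, m in segs:
                    if e <= gs or s >= ge:
                        carved.append((s, e, m))
                        continue
                    if s < gs:
                        carved.append((s, gs, m))
                    if e > ge:
                        carved.append((ge, e, m))
                carved.append((gs, ge, float(vals[pid_i])))
                segs = sorted(carved)
            for s, e, m in segs:
                if e > s:
                    records.append((pid, chrom, int(s), int(e),
                                    max(int((e - s) // 5000), 1), round(float(m), 6)))
    return pd.DataFrame(records, columns=["sample", "chromosome", "start", "end",
                                          "num_probes", "segment_mean"])


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Generate a full multi-platform cohort; the returned
    :class:`~survscreen.cohort.Cohort` carries a :class:`GroundTruth`."""
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_patients
    clinical = _simulate_clinical(rng, n)
    patients = list(clinical.index)

    planted = {(m.platform, m.index): m for m in cfg.planted}
    # latent standard-normal score per planted marker (stage coupling added)
    latents: dict[tuple, np.ndarray] = {}
    stage_c = clinical["stage"].to_numpy(float) - float(np.dot(STAGE_PROBS, [1, 2, 3, 4]))
    for key, m in planted.items():
        z = rng.normal(0.0, 1.0, n)
        if m.stage_coupling:
            z = z + m.stage_coupling * stage_c
        latents[key] = z
    # paired features reuse (sign-flipped) latent of their source marker
    for key, m in planted.items():
        if m.pair_with is not None:
            platform, idx, sign = m.pair_with
            latents[(platform, idx)] = sign * latents[key] + rng.normal(0, 0.5, n)

    # --- molecular platforms -------------------------------------------
    omics: dict[str, OmicsMatrix] = {}
    for platform in ("mirna", "mrna", "protein"):
        F = cfg.feature_counts.get(platform, 0)
        if not F:
            continue
        vals = rng.normal(0.0, 1.0, (F, n))
        for (pf, idx), z in latents.items():
            if pf == platform:
                vals[idx] = z
        features = [feature_name(platform, i) for i in range(F)]
        omics[platform] = OmicsMatrix(platform,
                                      pd.DataFrame(vals, index=features,
                                                   columns=patients), "continuous")

    F_me = cfg.feature_counts.get("methylation", 0)
    if F_me:
        mu = rng.normal(0.0, 0.8, F_me)
        lat = rng.normal(0.0, 1.0, (F_me, n))
        for (pf, idx), z in latents.items():
            if pf == "methylation":
                lat[idx] = z
                mu[idx] = 0.0
        beta_vals = 1.0 / (1.0 + np.exp(-(mu[:, None] + lat)))
        features = [feature_name("methylation", i) for i in range(F_me)]
        omics["methylation"] = OmicsMatrix(
            "methylation", pd.DataFrame(beta_vals, index=features,
                                        columns=patients), "beta")

    # --- copy number: genome, genes, per-patient segmentations ----------
    segments = annotation = None
    F_cnv = cfg.feature_counts.get("cnv", 0)
    if F_cnv:
        chrom_lengths = {"chr1": 40_000_000, "chr2": 30_000_000, "chr3": 30_000_000}
        chroms = list(chrom_lengths)
        genes = []
        for i in range(F_cnv):
            chrom = chroms[i % len(chroms)]
            slot = i // len(chroms)
            start = 50_000 + slot * 120_000
            genes.append((chrom, start, start + 20_000,
                          feature_name("cnv", i), 0, "+-"[i % 2]))
        annotation = pd.DataFrame(genes, columns=["chromosome", "start", "end",
                                                  "gene_id", "score", "strand"])
        planted_values = {}
        for (pf, idx), z in latents.items():
            if pf == "cnv":
                row = annotation.iloc[idx]
                planted_values[(row["gene_id"], row["chromosome"],
                                int(row["start"]), int(row["end"]))] = 0.3 * z
        segments = _random_segmentation(rng, chrom_lengths, patients,
                                        annotation, planted_values)
        cnv = map_genes_to_segments(segments, annotation)
        cnv = OmicsMatrix("cnv", cnv.values[patients], "segment_mean")
        omics["cnv"] = cnv

    # --- somatic mutations ----------------------------------------------
    maf = None
    F_mut = cfg.feature_counts.get("mutation", 0)
    mut_carrier = {}
    if F_mut:
        rates = rng.uniform(*cfg.mutation_rate_range, F_mut)
        for (pf, idx), _ in latents.items():
            if pf == "mutation":
                rates[idx] = max(rates[idx], 0.10)  # planted genes stay testable
        carriers = rng.random((F_mut, n)) < rates[:, None]
        rows = []
        for i in range(F_mut):
            gid = feature_name("mutation", i)
            mut_carrier[i] = carriers[i]
            for j in np.flatnonzero(carriers[i]):
                variant = f"{gid}_v{int(rng.integers(1, 3))}"
                rows.append((patients[j], gid, variant))
        maf = pd.DataFrame(rows, columns=["patient_id", "gene_id", "variant_id"])
        omics["mutation"] = mutation_matrix(maf, patients)

    # --- survival mechanism ---------------------------------------------
    cb = dict(DEFAULT_CLINICAL_BETAS)
    cb.update(cfg.clinical_betas)
    lp = (cb.get("gender", 0.0) * (clinical["gender"].to_numpy(float) - 0.5)
          + cb.get("age_per_decade", 0.0) * (clinical["age"].to_numpy(float) - 60.0) / 10.0
          + cb.get("grade", 0.0) * (clinical["grade"].to_numpy(float) - 2.0)
          + cb.get("stage", 0.0) * stage_c)
    for key, m in planted.items():
        if m.platform == "mutation":
            lp = lp + m.beta * mut_carrier[m.index].astype(float)
        else:
            lp = lp + m.beta * latents[key]
    expo = rng.exponential(1.0, n)
    t_event = cfg.weibull_scale * (expo / np.exp(lp)) ** (1.0 / cfg.weibull_shape)
    horizon = _censoring_horizon(t_event, cfg.censoring_fraction)
    t_cens = rng.uniform(0.0, horizon, n)
    event = t_event <= t_cens
    time = np.minimum(t_event, t_cens)
    clinical["time_days"] = np.round(time, 1)
    clinical["event"] = event

    # --- platform missingness (whole patients, availability-table style) -
    for platform, m in omics.items():
        frac = cfg.missing_fractions.get(platform, 0.0)
        k = int(round(frac * n))
        if k:
            masked = rng.choice(n, size=k, replace=False)
            cols = [patients[i] for i in masked]
            m.values[cols] = np.nan
            if platform == "cnv" and segments is not None:
                # unprofiled patients have no segmentation on disk either
                segments = segments[~segments["sample"].isin(cols)].reset_index(drop=True)
            if platform == "mutation" and maf is not None:
                maf = maf[~maf["patient_id"].isin(cols)].reset_index(drop=True)
        if cfg.scattered_missing_fraction:
            mask = rng.random(m.values.shape) < cfg.scattered_missing_fraction
            v = m.values.to_numpy(float)
            v[mask] = np.nan
            omics[platform] = OmicsMatrix(platform,
                                          pd.DataFrame(v, index=m.values.index,
                                                       columns=m.values.columns),
                                          m.value_kind)

    # --- normal-tissue companions (methylation / expression pairs) ------
    normals: dict[str, pd.DataFrame] = {}
    for platform, n_norm in (cfg.n_normals or {}).items():
        if platform not in omics or n_norm <= 0:
            continue
        ids = [f"NT{i:04d}" for i in range(n_norm)]
        F = omics[platform].n_features
        features = omics[platform].feature_ids
        if platform == "methylation":
            mu_n = rng.normal(0.0, 0.8, F)
            lat_n = rng.normal(0.0, 1.0, (F, n_norm))
            for (pf, idx), m in planted.items():
                if pf == "methylation" and m.pair_with is not None:
                    # tumors hypomethylated relative to normal tissue
                    lat_n[idx] += 1.5
                    mu_n[idx] = 0.0
            vals = 1.0 / (1.0 + np.exp(-(mu_n[:, None] + lat_n)))
        else:
            vals = rng.normal(0.0, 1.0, (F, n_norm))
            for key, m in planted.items():
                if m.pair_with is not None and m.pair_with[0] == platform:
                    # normals sit where the (hypermethylated) normal latent
                    # would map them: sign * (+1.5)
                    vals[m.pair_with[1]] += 1.5 * m.pair_with[2]
        normals[platform] = pd.DataFrame(vals, index=features, columns=ids)

    registry = pd.DataFrame(
        [{"platform": m.platform, "feature_id": m.feature_id(), "beta": m.beta,
          "stage_coupling": m.stage_coupling,
          "paired_feature": (feature_name(*m.pair_with[:2])
                             if m.pair_with else ""),
          "pair_sign": m.pair_with[2] if m.pair_with else 0}
         for m in cfg.planted],
        columns=["platform", "feature_id", "beta", "stage_coupling",
                 "paired_feature", "pair_sign"])
    latent_df = pd.DataFrame(
        {feature_name(*k): v for k, v in latents.items()}, index=patients).T
    truth = GroundTruth(
        linear_predictor=pd.Series(lp, index=patients, name="lp"),
        planted=registry,
        latent=latent_df,
        censoring_fraction_realized=float(1.0 - event.mean()),
        n_events=int(event.sum()),
    )
    return Cohort(clinical=clinical, omics=omics, normals=normals,
                  segments=segments, annotation=annotation, mutations=maf,
                  ground_truth=truth)


def kirc_like_cohort(seed: int = 0, planted: bool = True) -> Cohort:
    """Convenience preset at the motivating study's scale.

    533 patients, ~67% censoring, per-platform availability as published,
    a handful of planted markers per platform at mixed effect sizes, one
    stage-coupled methylation marker, one methylation-expression
    anti-correlated pair, and normal-tissue companion samples for the
    methylation and miRNA platforms.
    """
    markers = []
    if planted:
        markers = [
            PlantedMarker("mirna", 3, np.log(3.0),
                          pair_with=None),
            PlantedMarker("mirna", 7, np.log(2.0)),
            PlantedMarker("mrna", 11, np.log(3.0)),
            PlantedMarker("mrna", 42, np.log(2.0)),
            PlantedMarker("protein", 5, np.log(2.5)),
            PlantedMarker("methylation", 17, np.log(3.0), stage_coupling=0.4),
            PlantedMarker("methylation", 33, np.log(2.0),
                          pair_with=("mirna", 3, -1.0)),
            PlantedMarker("cnv", 9, np.log(2.0)),
            PlantedMarker("mutation", 4, np.log(4.0)),
        ]
    cfg = SimulationConfig(
        planted=markers,
        n_normals={"methylation": 358, "mirna": 71},
        rng_seed=seed,
    )
    return simulate_cohort(cfg)


def null_cohort(seed: int = 0, n_patients: int = 533,
                features_per_platform: int | None = None) -> Cohort:
    """A no-signal cohort: no planted markers, null clinical effects."""
    counts = dict(DEFAULT_FEATURE_COUNTS)
    if features_per_platform is not None:
        counts = {p: features_per_platform for p in counts}
        counts["protein"] = min(counts["protein"], features_per_platform)
    cfg = SimulationConfig(
        n_patients=n_patients,
        feature_counts=counts,
        planted=(),
        clinical_betas={k: 0.0 for k in DEFAULT_CLINICAL_BETAS},
        rng_seed=seed,
    )
    return simulate_cohort(cfg)
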