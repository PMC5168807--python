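"""Cohort data model, file I/O, feature filtering and CNV gene mapping.

The on-disk dialects are deliberately plain text:

* clinical table -- TSV with header
  ``patient_id  gender  age  grade  stage  time_days  event`` (event 0/1,
  gender 0/1, grade/stage ordinal 1-4, empty cell or ``NA`` = missing);
* feature matrices -- TSV, first column ``feature_id``, remaining columns
  patient ids, ``NA``/empty = missing;
* copy number -- SEG-like TSV (sample, chromosome, start, end, num_probes,
  segment_mean), 0-based half-open coordinates;
* gene annotation -- BED-like TSV (chrom, start, end, gene_id, score,
  strand);
* somatic mutations -- MAF-like TSV reduced to
  (patient_id, gene_id, variant_id) rows.

Quantitative molecular values are carried in :class:`OmicsMatrix`
(features x patients with an explicit NaN missing marker); patients-by-
features views for estimators come from :meth:`OmicsMatrix.X`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

log = logging.getLogger(__name__)

PLATFORMS = ("mirna", "mrna", "protein", "cnv", "methylation", "mutation")
VALUE_KINDS = ("continuous", "beta", "segment_mean", "binary")
CLINICAL_COLUMNS = ("gender", "age", "grade", "stage", "time_days", "event")

SEG_COLUMNS = ("sample", "chromosome", "start", "end", "num_probes", "segment_mean")
BED_COLUMNS = ("chromosome", "start", "end", "gene_id", "score", "strand")
MAF_COLUMNS = ("patient_id", "gene_id", "variant_id")


@dataclass
class OmicsMatrix:
    """Quantitative values of one molecular platform, features x patients."""

    platform: str
    values: pd.DataFrame  # index = feature ids, columns = patient ids
    value_kind: str = "continuous"

    def __post_init__(self):
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> "OmicsMatrix":
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        # rename_axis (not in-place mutation): the axes may share Index
        # objects with other tables
        self.values = self.values.rename_axis(index="feature_id", columns=None)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r} on platform {self.platform}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate patient id {dup!r} on platform {self.platform}")
        v = self.values.to_numpy(dtype=float)
        present = np.isfinite(v)
        if self.value_kind == "beta":
            bad = present & ((v < 0) | (v > 1))
            if bad.any():
                raise ValueError(f"{self.platform}: beta values outside [0, 1]")
        if self.value_kind == "binary":
            bad = present & (v != 0) & (v != 1)
            if bad.any():
                raise ValueError(f"{self.platform}: binary values outside {{0, 1}}")
        return self

    # -- views --------------------------------------------------------------
    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def patient_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def X(self, patient_ids: Iterable | None = None) -> pd.DataFrame:
        """Patients-by-features view (estimator orientation)."""
        out = self.values.T
        if patient_ids is not None:
            out = out.loc[list(patient_ids)]
        return out

    def restrict(self, patient_ids: Iterable) -> "OmicsMatrix":
        ids = [p for p in patient_ids if p in self.values.columns]
        return OmicsMatrix(self.platform, self.values[ids], self.value_kind)


@dataclass
class Cohort:
    """One study cohort: clinical table plus per-platform omics matrices."""

    clinical: pd.DataFrame
    omics: dict[str, OmicsMatrix] = field(default_factory=dict)
    normals: dict[str, pd.DataFrame] = field(default_factory=dict)  # features x normal samples
    segments: pd.DataFrame | None = None
    annotation: pd.DataFrame | None = None
    mutations: pd.DataFrame | None = None
    ground_truth: object | None = None

    @property
    def patients(self) -> list:
        return list(self.clinical.index)

    def subset(self, patient_ids: Iterable) -> "Cohort":
        ids = list(patient_ids)
        return Cohort(
            clinical=self.clinical.loc[ids],
            omics={k: m.restrict(ids) for k, m in self.omics.items()},
            normals=self.normals,
            segments=self.segments,
            annotation=self.annotation,
            mutations=self.mutations,
            ground_truth=self.ground_truth,
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_clinical(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str}, na_values=["NA", ""])
    missing = [c for c in ("patient_id",) + CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {missing}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"{path}: duplicate patient id {dup!r}")
    df = df.set_index("patient_id")
    for col in ("age", "time_days"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric value in column {col!r}: {exc}") from None
    for col in ("gender", "grade", "stage", "event"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
    neg = df.index[df["time_days"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative survival time for patient {neg[0]!r}")
    bad_event = df.index[~df["event"].isna() & ~df["event"].isin([0, 1])]
    if len(bad_event):
        raise ValueError(f"{path}: event must be 0/1 (patient {bad_event[0]!r})")
    for col, lo, hi in (("gender", 0, 1), ("grade", 1, 4), ("stage", 1, 4)):
        vals = df[col].dropna()
        if ((vals < lo) | (vals > hi)).any():
            bad = vals[(vals < lo) | (vals > hi)].index[0]
            raise ValueError(f"{path}: {col} out of range for patient {bad!r}")
    df["event"] = df["event"].astype(bool)
    df["time_days"] = df["time_days"].astype(float)
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    out = clinical.copy()
    out["event"] = out["event"].astype(int)
    out.index.name = "patient_id"
    out.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_matrix(path, platform: str, value_kind: str = "continuous") -> OmicsMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""], dtype={0: str})
    if df.columns[0] != "feature_id":
        raise ValueError(f"{path}: malformed header, first column must be 'feature_id'")
    df = df.set_index("feature_id")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(
                f"{path}: non-numeric value in patient column {col!r}: {exc}") from None
    return OmicsMatrix(platform, df.astype(float), value_kind)


def write_matrix(m: OmicsMatrix, path) -> None:
    out = m.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_segments(path) -> pd.DataFrame:
    """Read a SEG-like table; validates coordinates and per-patient overlap."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chromosome": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns and c != "num_probes"]
    if missing:
        raise ValueError(f"{path}: malformed SEG header, missing {missing}")
    if "num_probes" not in df.columns:
        df["num_probes"] = pd.NA
    validate_segments(df)
    return df[list(SEG_COLUMNS)]


def validate_segments(seg: pd.DataFrame) -> None:
    bad = seg[seg["start"] >= seg["end"]]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(f"segment with start >= end: {r['sample']} "
                         f"{r['chromosome']}:{r['start']}-{r['end']}")
    for (sample, chrom), grp in seg.groupby(["sample", "chromosome"], sort=False):
        g = grp.sort_values("start")
        overlap = g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]
        if overlap.any():
            i = int(np.flatnonzero(overlap)[0])
            a, b = g.iloc[i], g.iloc[i + 1]
            raise ValueError(
                f"overlapping segments for patient {sample!r} on {chrom}: "
                f"[{a['start']},{a['end']}) and [{b['start']},{b['end']})")


def write_segments(seg: pd.DataFrame, path) -> None:
    seg.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a BED-like gene annotation (0-based half-open)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS,
                     dtype={"chromosome": str, "gene_id": str, "strand": str})
    if (df["start"] >= df["end"]).any():
        r = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(f"{path}: gene with start >= end: {r['gene_id']}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    return df


def write_gene_annotation(genes: pd.DataFrame, path) -> None:
    genes[list(BED_COLUMNS)].to_csv(path, sep="\t", index=False, header=False)


def read_mutations(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: malformed mutation table, missing {missing}")
    return df[list(MAF_COLUMNS)]


def write_mutations(maf: pd.DataFrame, path) -> None:
    maf[list(MAF_COLUMNS)].to_csv(path, sep="\t", index=False)


def mutation_matrix(maf: pd.DataFrame, patients: Iterable, key: str = "gene_id",
                    profiled_patients: Iterable | None = None) -> OmicsMatrix:
    """Binary carrier matrix from MAF-like rows, keyed by gene or variant.

    Patients in ``patients`` but not in ``profiled_patients`` (when given)
    are marked missing rather than mutation-free.
    """
    patients = list(patients)
    keys = sorted(maf[key].unique())
    mat = pd.DataFrame(0.0, index=keys, columns=patients)
    hit = maf[maf["patient_id"].isin(patients)]
    for pid, gid in zip(hit["patient_id"], hit[key]):
        mat.loc[gid, pid] = 1.0
    if profiled_patients is not None:
        unprofiled = [p for p in patients if p not in set(profiled_patients)]
        mat[unprofiled] = np.nan
    return OmicsMatrix("mutation", mat, "binary")


def read_cohort(clinical_path, matrix_paths: Mapping[str, object] | None = None,
                seg_path=None, annotation_path=None, maf_path=None,
                value_kinds: Mapping[str, str] | None = None) -> Cohort:
    """Read a full cohort from the TSV dialects above.

    Patients present in a matrix but absent from the clinical table are
    dropped with a logged warning; CNV is delivered gene-level via
    :func:`map_genes_to_segments` when SEG + annotation files are given.
    """
    clinical = read_clinical(clinical_path)
    kinds = {"methylation": "beta", "mutation": "binary", "cnv": "segment_mean"}
    if value_kinds:
        kinds.update(value_kinds)
    omics: dict[str, OmicsMatrix] = {}
    for platform, path in (matrix_paths or {}).items():
        m = read_matrix(path, platform, kinds.get(platform, "continuous"))
        extra = [p for p in m.patient_ids if p not in clinical.index]
        if extra:
            log.warning("%s: dropping %d patients absent from the clinical table "
                        "(e.g. %r)", platform, len(extra), extra[0])
        m = m.restrict([p for p in m.patient_ids if p in clinical.index])
        omics[platform] = m
    segments = annotation = maf = None
    if seg_path is not None and annotation_path is not None:
        segments = read_segments(seg_path)
        extra = sorted(set(segments["sample"]) - set(clinical.index))
        if extra:
            log.warning("cnv: dropping %d patients absent from the clinical table "
                        "(e.g. %r)", len(extra), extra[0])
            segments = segments[segments["sample"].isin(clinical.index)]
        annotation = read_gene_annotation(annotation_path)
        cnv = map_genes_to_segments(segments, annotation)
        # patients without a segmentation are unprofiled, not segment-free
        full = cnv.values.reindex(columns=clinical.index)
        omics["cnv"] = OmicsMatrix("cnv", full, "segment_mean")
    if maf_path is not None:
        maf = read_mutations(maf_path)
        extra = sorted(set(maf["patient_id"]) - set(clinical.index))
        if extra:
            log.warning("mutation: dropping %d patients absent from the clinical "
                        "table (e.g. %r)", len(extra), extra[0])
            maf = maf[maf["patient_id"].isin(clinical.index)]
        omics["mutation"] = mutation_matrix(maf, clinical.index)
    return Cohort(clinical=clinical, omics=omics, segments=segments,
                  annotation=annotation, mutations=maf)


# ---------------------------------------------------------------------------
# Feature filtering and Z-scores
# ---------------------------------------------------------------------------

def filter_features(m: OmicsMatrix, cohort_size: int) -> OmicsMatrix:
    """Keep features quantified in strictly more than half of the patients."""
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    counts = m.values.notna().sum(axis=1).to_numpy()
    keep = counts * 2 > cohort_size
    return OmicsMatrix(m.platform, m.values.loc[keep], m.value_kind)


class ZScoreScaler(BaseEstimator, TransformerMixin):
    """Per-feature Z-score transform fitted on tumor samples of one cohort.

    ``fit`` estimates per-feature mean and sample standard deviation (n-1
    denominator) over the fitting patients, ignoring missing entries;
    features with fewer than two distinct non-missing values (zero variance)
    are flagged, logged and excluded from the transform output rather than
    raising. ``transform`` maps values to Z-scores and propagates missing
    entries unchanged.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] == 0:
            raise ValueError("cannot fit a Z-score transform on zero patients")
        mean = X.mean(axis=0, skipna=True)
        sd = X.std(axis=0, ddof=1, skipna=True)
        ok = sd.notna() & (sd > 0)
        self.dropped_features_ = list(X.columns[~ok])
        if self.dropped_features_:
            log.warning("Z-score fit: excluding %d zero-variance features (e.g. %r)",
                        len(self.dropped_features_), self.dropped_features_[0])
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.mean_ = mean[ok]
        self.sd_ = sd[ok]
        self.kept_features_ = list(self.mean_.index)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        unknown = [c for c in X.columns
                   if c not in set(self.kept_features_) | set(self.dropped_features_)]
        if unknown:
            raise ValueError(f"features not covered by the fitted transform: {unknown[:3]}")
        cols = [c for c in X.columns if c in set(self.kept_features_)]
        return (X[cols] - self.mean_[cols]) / self.sd_[cols]


def fit_zscore(m: OmicsMatrix, fit_ids: Iterable) -> ZScoreScaler:
    """Fit a Z-score transform on a patient subset (training tumor samples)."""
    ids = list(fit_ids)
    if not ids:
        raise ValueError("fit_ids must be nonempty")
    return ZScoreScaler().fit(m.X(ids))


def apply_zscore(t: ZScoreScaler, m: OmicsMatrix) -> OmicsMatrix:
    """Apply a fitted Z-score transform to a platform matrix."""
    z = t.transform(m.X())
    return OmicsMatrix(m.platform, z.T, "continuous")


# ---------------------------------------------------------------------------
# CNV gene-segment mapping
# ---------------------------------------------------------------------------

def map_genes_to_segments(segments: pd.DataFrame, genes: pd.DataFrame) -> OmicsMatrix:
    """Gene-level copy-number matrix from a patient segmentation.

    A gene's value for a patient is the overlap-length-weighted mean of the
    segment means of all segments overlapping the gene interval (0-based
    half-open; strand is ignored -- copy number is strand-agnostic). Genes
    with no overlapping segment for a patient are missing. Overlapping
    segments within one patient/chromosome are an input error.
    """
    validate_segments(segments)
    patients = list(dict.fromkeys(segments["sample"]))
    pat_row = {p: j for j, p in enumerate(patients)}
    gene_ids = list(genes["gene_id"])
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    out = np.full((len(gene_ids), len(patients)), np.nan)
    gene_by_chrom = {
        str(c): (g["gene_id"].to_numpy(), g["start"].to_numpy(float), g["end"].to_numpy(float))
        for c, g in genes.groupby("chromosome", sort=False)
    }
    for (pid, chrom), grp in segments.groupby(["sample", "chromosome"], sort=False):
        hit = gene_by_chrom.get(str(chrom))
        if hit is None:
            continue
        gids, gstart, gend = hit
        grp = grp.sort_values("start")
        s = grp["start"].to_numpy(float)
        e = grp["end"].to_numpy(float)
        mu = grp["segment_mean"].to_numpy(float)
        j = pat_row[pid]
        for gid, gs, ge in zip(gids, gstart, gend):
            lo = int(np.searchsorted(e, gs, side="right"))
            hi = int(np.searchsorted(s, ge, side="left"))
            if hi <= lo:
                continue
            ov = np.minimum(e[lo:hi], ge) - np.maximum(s[lo:hi], gs)
            w = ov.sum()
            if w > 0:
                out[gene_row[gid], j] = float(ov @ mu[lo:hi]) / w
    values = pd.DataFrame(out, index=gene_ids, columns=patients)
    return OmicsMatrix("cnv", values, "segment_mean")


# ---------------------------------------------------------------------------
# Cohort-level writers (the synthetic generator uses these as well)
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, directory) -> None:
    """Write a cohort to a directory in the declared TSV dialects."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_clinical(cohort.clinical, directory / "clinical.tsv")
    for platform, m in cohort.omics.items():
        if platform in ("cnv", "mutation"):
            continue  # written in their native dialects below
        write_matrix(m, directory / f"{platform}.tsv")
    if cohort.segments is not None:
        write_segments(cohort.segments, directory / "cnv.seg")
    elif "cnv" in cohort.omics:
        write_matrix(cohort.omics["cnv"], directory / "cnv.tsv")
    if cohort.annotation is not None:
        write_gene_annotation(cohort.annotation, directory / "genes.bed")
    if cohort.mutations is not None:
        write_mutations(cohort.mutations, directory / "mutations.maf.tsv")
    for platform, normals in cohort.normals.items():
        out = normals.copy()
        out.index.name = "feature_id"
        out.to_csv(directory / f"{platform}_normal.tsv", sep="\t", na_rep="NA")


def read_cohort_dir(directory) -> Cohort:
    """Read back a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    matrix_paths = {}
    for platform in PLATFORMS:
        p = directory / f"{platform}.tsv"
        if p.exists():
            matrix_paths[platform] = p
    seg = directory / "cnv.seg"
    bed = directory / "genes.bed"
    maf = directory / "mutations.maf.tsv"
    cohort = read_cohort(
        directory / "clinical.tsv", matrix_paths,
        seg_path=seg if seg.exists() and bed.exists() else None,
        annotation_path=bed if seg.exists() and bed.exists() else None,
        maf_path=maf if maf.exists() else None,
    )
    for p in directory.glob("*_normal.tsv"):
        platform = p.name[: -len("_normal.tsv")]
        df = pd.read_csv(p, sep="\t", na_values=["NA", ""]).set_index("feature_id")
        cohort.normals[platform] = df.astype(float)
    return cohort
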