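"""Cohort I/O, feature filtering, Z-scores and CNV gene mapping."""

import logging

import numpy as np
import pandas as pd
import pytest

from survscreen.cohort import (Cohort, OmicsMatrix, ZScoreScaler, apply_zscore,
                               filter_features, fit_zscore,
                               map_genes_to_segments, mutation_matrix,
                               read_clinical, read_cohort, read_cohort_dir,
                               read_matrix, write_cohort)
from survscreen.simulate import kirc_like_cohort


def _clinical_tsv(tmp_path, rows, name="clinical.tsv"):
    header = "patient_id\tgender\tage\tgrade\tstage\ttime_days\tevent"
    p = tmp_path / name
    p.write_text("\n".join([header] + rows) + "\n")
    return p


def _matrix_tsv(tmp_path, patients, rows, name="mrna.tsv"):
    p = tmp_path / name
    lines = ["feature_id\t" + "\t".join(patients)]
    lines += [fid + "\t" + "\t".join(vals) for fid, vals in rows]
    p.write_text("\n".join(lines) + "\n")
    return p


class TestReaders:
    def test_matrix_restricted_to_clinical_patients(self, tmp_path):
        clin = _clinical_tsv(tmp_path, [
            "P1\t0\t60\t2\t1\t100\t1",
            "P2\t1\t55\t3\t2\t200\t0",
            "P3\t0\t70\t1\t1\t300\t1",
        ])
        mat = _matrix_tsv(tmp_path, ["P1", "P2", "P3"],
                          [("g1", ["1", "2", "3"]), ("g2", ["4", "NA", "6"])])
        cohort = read_cohort(clin, {"mrna": mat})
        assert cohort.omics["mrna"].patient_ids == ["P1", "P2", "P3"]
        assert cohort.omics["mrna"].n_features == 2

    def test_unknown_patient_column_dropped_with_warning(self, tmp_path, caplog):
        clin = _clinical_tsv(tmp_path, ["P1\t0\t60\t2\t1\t100\t1",
                                        "P2\t1\t55\t3\t2\t200\t0"])
        mat = _matrix_tsv(tmp_path, ["P1", "P2", "PX"],
                          [("g1", ["1", "2", "3"])])
        with caplog.at_level(logging.WARNING):
            cohort = read_cohort(clin, {"mrna": mat})
        assert cohort.omics["mrna"].patient_ids == ["P1", "P2"]
        assert any("PX" in r.message for r in caplog.records)

    def test_negative_time_names_the_patient(self, tmp_path):
        clin = _clinical_tsv(tmp_path, ["P1\t0\t60\t2\t1\t100\t1",
                                        "P2\t1\t55\t3\t2\t-5\t0"])
        with pytest.raises(ValueError, match="P2"):
            read_clinical(clin)

    def test_duplicate_patient_id_rejected(self, tmp_path):
        clin = _clinical_tsv(tmp_path, ["P1\t0\t60\t2\t1\t100\t1",
                                        "P1\t1\t55\t3\t2\t200\t0"])
        with pytest.raises(ValueError, match="duplicate"):
            read_clinical(clin)

    def test_non_numeric_matrix_value_reports_file(self, tmp_path):
        mat = _matrix_tsv(tmp_path, ["P1", "P2"], [("g1", ["1", "oops"])])
        with pytest.raises(ValueError, match="non-numeric"):
            read_matrix(mat, "mrna")

    def test_beta_range_enforced(self):
        with pytest.raises(ValueError, match="beta"):
            OmicsMatrix("methylation",
                        pd.DataFrame({"P1": [0.5], "P2": [1.2]}, index=["cg1"]),
                        "beta")


class TestRoundTrip:
    def test_write_then_read_is_exact(self, tmp_path, planted_cohort):
        sub = planted_cohort.subset(planted_cohort.patients[:60])
        sub = Cohort(clinical=sub.clinical, omics=sub.omics,
                     normals=planted_cohort.normals,
                     segments=planted_cohort.segments[
                         planted_cohort.segments["sample"].isin(sub.patients)],
                     annotation=planted_cohort.annotation,
                     mutations=planted_cohort.mutations[
                         planted_cohort.mutations["patient_id"].isin(sub.patients)])
        write_cohort(sub, tmp_path)
        back = read_cohort_dir(tmp_path)
        pd.testing.assert_frame_equal(
            back.clinical, sub.clinical, check_dtype=False)
        for platform in ("mirna", "mrna", "protein", "methylation", "cnv"):
            pd.testing.assert_frame_equal(
                back.omics[platform].values, sub.omics[platform].values,
                check_dtype=False)
        # mutation matrix is reconstructed from the MAF rows
        muts = back.omics["mutation"].values
        orig = sub.omics["mutation"].values.loc[muts.index, muts.columns]
        pd.testing.assert_frame_equal(muts, orig, check_dtype=False)
        assert set(back.normals) == {"methylation", "mirna"}


class TestFilterFeatures:
    def test_more_than_half_boundary(self):
        # 533-patient cohort: 267 observed values retained, 266 dropped
        n = 533
        vals = np.full((2, n), np.nan)
        vals[0, :267] = 1.0
        vals[1, :266] = 1.0
        m = OmicsMatrix("mrna", pd.DataFrame(
            vals, index=["kept", "dropped"],
            columns=[f"P{i}" for i in range(n)]))
        out = filter_features(m, n)
        assert out.feature_ids == ["kept"]

    def test_fully_observed_unchanged_and_idempotent(self):
        rng = np.random.default_rng(0)
        m = OmicsMatrix("mrna", pd.DataFrame(
            rng.normal(size=(5, 8)), index=[f"g{i}" for i in range(5)],
            columns=[f"P{i}" for i in range(8)]))
        once = filter_features(m, 8)
        assert once.feature_ids == m.feature_ids
        twice = filter_features(once, 8)
        pd.testing.assert_frame_equal(twice.values, once.values)

    def test_all_missing_feature_dropped(self):
        m = OmicsMatrix("mrna", pd.DataFrame(
            [[np.nan, np.nan], [1.0, 2.0]], index=["gone", "kept"],
            columns=["P1", "P2"]))
        assert filter_features(m, 2).feature_ids == ["kept"]


class TestZScore:
    def test_hand_computed_transform(self):
        m = OmicsMatrix("mrna", pd.DataFrame(
            {"P1": [1.0], "P2": [2.0], "P3": [3.0]}, index=["g"]))
        t = fit_zscore(m, ["P1", "P2", "P3"])
        assert t.mean_["g"] == pytest.approx(2.0)
        assert t.sd_["g"] == pytest.approx(1.0)  # sample sd, n-1 denominator
        z = apply_zscore(t, m)
        np.testing.assert_allclose(z.values.loc["g"], [-1.0, 0.0, 1.0])

    def test_value_at_mean_plus_sd_is_extreme_high_boundary(self):
        m = OmicsMatrix("mrna", pd.DataFrame(
            {"P1": [1.0], "P2": [2.0], "P3": [3.0]}, index=["g"]))
        t = fit_zscore(m, ["P1", "P2", "P3"])
        z = t.transform(pd.DataFrame({"g": [3.0]}, index=["PX"]))
        assert z.loc["PX", "g"] == pytest.approx(1.0)

    def test_constant_feature_flagged_and_excluded(self, caplog):
        m = OmicsMatrix("mrna", pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"],
            columns=["P1", "P2", "P3"]))
        with caplog.at_level(logging.WARNING):
            t = fit_zscore(m, ["P1", "P2", "P3"])
        assert t.dropped_features_ == ["flat"]
        assert apply_zscore(t, m).feature_ids == ["ok"]

    def test_self_standardisation(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(3.0, 2.5, size=(6, 40))
        vals[rng.random((6, 40)) < 0.15] = np.nan
        m = OmicsMatrix("mrna", pd.DataFrame(
            vals, index=[f"g{i}" for i in range(6)],
            columns=[f"P{i}" for i in range(40)]))
        t = fit_zscore(m, m.patient_ids)
        z = apply_zscore(t, m)
        means = z.values.mean(axis=1, skipna=True)
        sds = z.values.std(axis=1, ddof=1)
        np.testing.assert_allclose(means, 0.0, atol=1e-9)
        np.testing.assert_allclose(sds, 1.0, atol=1e-9)

    def test_missing_stays_missing(self):
        m = OmicsMatrix("mrna", pd.DataFrame(
            {"P1": [1.0], "P2": [np.nan], "P3": [3.0], "P4": [5.0]},
            index=["g"]))
        z = apply_zscore(fit_zscore(m, m.patient_ids), m)
        assert np.isnan(z.values.loc["g", "P2"])

    def test_unknown_feature_errors(self):
        t = ZScoreScaler().fit(pd.DataFrame({"g": [1.0, 2.0, 4.0]}))
        with pytest.raises(ValueError, match="not covered"):
            t.transform(pd.DataFrame({"other": [1.0]}))


def _seg(sample, chrom, start, end, mean):
    return dict(sample=sample, chromosome=chrom, start=start, end=end,
                num_probes=1, segment_mean=mean)


def _genes(rows):
    return pd.DataFrame(rows, columns=["chromosome", "start", "end",
                                       "gene_id", "score", "strand"])


class TestGeneSegmentMapping:
    def test_gene_inside_single_segment(self):
        seg = pd.DataFrame([_seg("P1", "chr1", 0, 1000, 0.4)])
        genes = _genes([("chr1", 100, 200, "G1", 0, "+")])
        m = map_genes_to_segments(seg, genes)
        assert m.values.loc["G1", "P1"] == pytest.approx(0.4)

    def test_overlap_weighted_mean(self):
        # gene [100,300) over segments [0,200)@0.2 and [200,400)@0.6
        seg = pd.DataFrame([_seg("P1", "chr1", 0, 200, 0.2),
                            _seg("P1", "chr1", 200, 400, 0.6)])
        genes = _genes([("chr1", 100, 300, "G1", 0, "-")])
        m = map_genes_to_segments(seg, genes)
        assert m.values.loc["G1", "P1"] == pytest.approx(0.4)

    def test_gene_without_segments_is_missing(self):
        seg = pd.DataFrame([_seg("P1", "chr1", 0, 1000, 0.4)])
        genes = _genes([("chr2", 100, 200, "G1", 0, "+")])
        m = map_genes_to_segments(seg, genes)
        assert np.isnan(m.values.loc["G1", "P1"])

    def test_overlapping_segments_rejected_citing_pair(self):
        seg = pd.DataFrame([_seg("P1", "chr1", 0, 200, 0.2),
                            _seg("P1", "chr1", 150, 400, 0.6)])
        genes = _genes([("chr1", 100, 300, "G1", 0, "+")])
        with pytest.raises(ValueError, match=r"\[0,200\).*\[150,400\)"):
            map_genes_to_segments(seg, genes)

    def test_invariant_to_record_order_and_segment_split(self):
        rng = np.random.default_rng(2)
        bounds = np.sort(rng.integers(0, 10_000, 6))
        bounds = np.unique(np.concatenate([[0], bounds, [10_000]]))
        segs = [_seg("P1", "chr1", int(a), int(b), float(rng.normal()))
                for a, b in zip(bounds[:-1], bounds[1:])]
        genes = _genes([("chr1", 1200, 7800, "G1", 0, "+")])
        base = map_genes_to_segments(pd.DataFrame(segs), genes)
        shuffled = pd.DataFrame(segs).sample(frac=1.0, random_state=0)
        split = []
        for s in segs:
            mid = (s["start"] + s["end"]) // 2
            if mid > s["start"] and mid < s["end"]:
                split.append(_seg("P1", "chr1", s["start"], mid, s["segment_mean"]))
                split.append(_seg("P1", "chr1", mid, s["end"], s["segment_mean"]))
            else:
                split.append(s)
        for variant in (shuffled, pd.DataFrame(split)):
            out = map_genes_to_segments(variant, genes)
            assert out.values.loc["G1", "P1"] == pytest.approx(
                base.values.loc["G1", "P1"], rel=1e-12)


class TestMutationMatrix:
    def test_carrier_matrix_and_variant_mode(self):
        maf = pd.DataFrame({
            "patient_id": ["P1", "P1", "P2"],
            "gene_id": ["GA", "GB", "GA"],
            "variant_id": ["GA_v1", "GB_v1", "GA_v2"],
        })
        by_gene = mutation_matrix(maf, ["P1", "P2", "P3"])
        assert by_gene.values.loc["GA"].tolist() == [1.0, 1.0, 0.0]
        by_variant = mutation_matrix(maf, ["P1", "P2", "P3"], key="variant_id")
        assert by_variant.values.loc["GA_v2"].tolist() == [0.0, 1.0, 0.0]

    def test_unprofiled_patients_are_missing(self):
        maf = pd.DataFrame({"patient_id": ["P1"], "gene_id": ["GA"],
                            "variant_id": ["GA_v1"]})
        m = mutation_matrix(maf, ["P1", "P2"], profiled_patients=["P1"])
        assert np.isnan(m.values.loc["GA", "P2"])
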