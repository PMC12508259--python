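"""Signature scoring, clustering/PCA and overlap-count contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

import evsubtype as ev
from evsubtype import scoring
from evsubtype.io_formats import Scale, SignatureCollection, Subtype
from evsubtype.scoring import cut_clusters
from evsubtype.synthetic import simulate_ne_reference_cohort, truth_signatures

from _oracles import upgma_cophenetic, venn_regions
from conftest import SEED


def _matrix(values: dict, index, scale=Scale.GLOG) -> ev.ProteinMatrix:
    return ev.ProteinMatrix(pd.DataFrame(values, index=index), scale)


class TestZscoreSignatureScore:
    def test_dominant_sample_scores_one(self):
        m = _matrix(
            {"s1": [1.0, 2.0], "s2": [3.0, 4.0], "s3": [9.0, 8.0]},
            ["G1", "G2"],
        )
        table = scoring.zscore_signature_score(m, ["G1", "G2"], "sig")
        assert table.scores.loc["s3", "sig"] == 1.0
        assert table.scores.loc["s1", "sig"] == 0.0

    def test_matches_two_line_oracle(self):
        """2 genes x 3 samples: sum of z then min-max, computed longhand."""
        vals = pd.DataFrame(
            {"s1": [1.0, 10.0], "s2": [2.0, 30.0], "s3": [6.0, 20.0]},
            index=["G1", "G2"],
        )
        m = ev.ProteinMatrix(vals, Scale.GLOG)
        z = vals.sub(vals.mean(axis=1), axis=0).div(vals.std(axis=1, ddof=1), axis=0)
        raw = z.sum(axis=0)
        expected = (raw - raw.min()) / (raw.max() - raw.min())
        table = scoring.zscore_signature_score(m, ["G1", "G2"], "sig")
        pd.testing.assert_series_equal(
            table.scores["sig"], expected, check_names=False
        )

    @given(
        scale=st.floats(0.1, 50.0),
        shift=st.floats(-100.0, 100.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_per_gene_affine_rescaling(self, scale, shift):
        rng = np.random.default_rng(SEED)
        vals = pd.DataFrame(
            rng.normal(size=(4, 6)),
            index=[f"G{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(6)],
        )
        base = scoring.zscore_signature_score(
            ev.ProteinMatrix(vals, Scale.GLOG), list(vals.index), "sig"
        )
        transformed = vals.copy()
        transformed.iloc[0] = transformed.iloc[0] * scale + shift
        other = scoring.zscore_signature_score(
            ev.ProteinMatrix(transformed, Scale.GLOG), list(vals.index), "sig"
        )
        pd.testing.assert_frame_equal(base.scores, other.scores, atol=1e-9)

    def test_endpoints_attained_and_coverage(self):
        rng = np.random.default_rng(SEED)
        vals = pd.DataFrame(
            rng.normal(size=(5, 8)),
            index=[f"G{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(8)],
        )
        table = scoring.zscore_signature_score(
            ev.ProteinMatrix(vals, Scale.GLOG), ["G0", "G1", "MISSING"], "sig"
        )
        s = table.scores["sig"]
        assert s.min() == 0.0 and s.max() == 1.0
        assert table.coverage["sig"] == (2, 3)

    def test_degenerate_scores_flagged_at_half(self):
        m = _matrix({"s1": [1.0, 5.0], "s2": [1.0, 5.0], "s3": [1.0, 5.0]},
                    ["G1", "G2"])
        table = scoring.zscore_signature_score(m, ["G1", "G2"], "sig")
        assert (table.scores["sig"] == 0.5).all()
        assert table.degenerate == ["sig"]

    def test_no_genes_found_reports_missing(self):
        m = _matrix({"s1": [1.0, 2.0], "s2": [2.0, 1.0]}, ["G1", "G2"])
        table = scoring.zscore_signature_score(m, ["ABSENT1", "ABSENT2"], "sig")
        assert table.scores["sig"].isna().all()
        assert table.coverage["sig"] == (0, 2)

    def test_replicate_averaging_before_rescaling(self, study_cohort):
        design, glog = study_cohort["design"], study_cohort["glog"]
        sigs = truth_signatures(study_cohort["truth"])
        per_line = scoring.zscore_signature_score(
            glog, sigs["TRUE_AR_POS"], "AR", design, "mean-of-replicates"
        )
        assert set(per_line.scores.index) == set(design.table["cell_line"])
        assert per_line.scores["AR"].min() == 0.0
        assert per_line.scores["AR"].max() == 1.0

    def test_subtype_ranking_recovered(self, study_cohort):
        """AR+ samples take the top of the rescaled AR-signature scores."""
        design, glog = study_cohort["design"], study_cohort["glog"]
        sigs = truth_signatures(study_cohort["truth"])
        table = scoring.score_signatures(glog, sigs, design)
        for subtype in (Subtype.AR_POS, Subtype.AR_NEG_NE_POS,
                        Subtype.AR_NEG_NE_NEG):
            s = table.scores[f"TRUE_{subtype.value}"]
            own = s[design.samples_of(subtype)]
            rest = s.drop(design.samples_of(subtype))
            assert own.min() > rest.max()


class TestCorrelationNeScore:
    def test_self_and_negated_reference(self):
        """Reference set to a sample's z-profile: that sample scores exactly
        +1, and -1 against the negated reference."""
        rng = np.random.default_rng(SEED)
        vals = pd.DataFrame(
            rng.normal(size=(10, 5)),
            index=[f"G{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(5)],
        )
        z = vals.sub(vals.mean(axis=1), axis=0).div(vals.std(axis=1, ddof=1), axis=0)
        genes = list(vals.index)
        m = ev.ProteinMatrix(vals, Scale.GLOG)
        sig = SignatureCollection({"NE": genes}, reference_profile=z["s2"])
        out = scoring.correlation_ne_score(m, sig, "NE")
        assert out.scores.loc["s2", "NE"] == pytest.approx(1.0)
        sig_neg = SignatureCollection({"NE": genes}, reference_profile=-z["s2"])
        out_neg = scoring.correlation_ne_score(m, sig_neg, "NE")
        assert out_neg.scores.loc["s2", "NE"] == pytest.approx(-1.0)

    def test_separates_ne_high_from_background(self):
        matrix, sig, high = simulate_ne_reference_cohort(seed=SEED)
        out = scoring.correlation_ne_score(matrix, sig, "NE_SET")
        s = out.scores["NE_SET"]
        assert s[high].min() > 0.8
        assert abs(s.drop(high).mean()) < 0.2

    def test_insufficient_overlap_reports_missing(self):
        m = _matrix({"s1": [1.0, 2.0], "s2": [2.0, 1.0]}, ["G1", "G2"])
        sig = SignatureCollection(
            {"NE": ["G1", "G2", "G3"]},
            reference_profile=pd.Series({"G1": 1.0, "G2": 2.0}),
        )
        out = scoring.correlation_ne_score(m, sig, "NE")
        assert out.scores["NE"].isna().all()
        assert out.coverage["NE"] == (2, 3)


class TestSignatureCoverage:
    def test_full_and_disjoint(self):
        m = _matrix({"s1": [1.0, 2.0, 3.0]}, ["G1", "G2", "G3"])
        coll = SignatureCollection(
            {"all": ["G1", "G2", "G3"], "none": ["X1", "X2"], "half": ["G1", "X1"]}
        )
        cov = scoring.signature_coverage(m, coll)
        assert cov == {"all": (3, 3), "none": (0, 2), "half": (1, 2)}


class TestHierarchicalCluster:
    def test_duplicate_columns_merge_first_at_zero_height(self):
        rng = np.random.default_rng(SEED)
        col = rng.normal(size=20)
        vals = pd.DataFrame(
            {"a": col, "b": col, "c": rng.normal(size=20),
             "d": rng.normal(size=20)},
            index=[f"G{i}" for i in range(20)],
        )
        res = scoring.hierarchical_cluster(ev.ProteinMatrix(vals, Scale.GLOG))
        first = res.linkage_matrix[0]
        assert first[2] == pytest.approx(0.0, abs=1e-12)
        assert {res.items[int(first[0])], res.items[int(first[1])]} == {"a", "b"}

    def test_four_item_merge_heights_by_hand(self):
        """Toy distances engineered through column profiles: check the merge
        heights against the longhand UPGMA agglomeration of the same
        distance matrix."""
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(
            rng.normal(size=(30, 4)), columns=["a", "b", "c", "d"],
            index=[f"G{i}" for i in range(30)],
        )
        res = scoring.hierarchical_cluster(ev.ProteinMatrix(vals, Scale.GLOG))
        dist = 1 - np.corrcoef(vals.to_numpy(), rowvar=False)
        np.fill_diagonal(dist, 0.0)
        coph_oracle, heights_oracle = upgma_cophenetic(dist)
        np.testing.assert_allclose(
            sorted(res.linkage_matrix[:, 2]), heights_oracle, atol=1e-12
        )
        coph_pkg = squareform(cophenet(res.linkage_matrix))
        np.testing.assert_allclose(coph_pkg, coph_oracle, atol=1e-12)

    @pytest.mark.parametrize("n_items", [5, 8, 12])
    def test_matches_brute_force_upgma(self, n_items):
        rng = np.random.default_rng(SEED + n_items)
        vals = pd.DataFrame(
            rng.normal(size=(40, n_items)),
            columns=[f"s{i:02d}" for i in range(n_items)],
            index=[f"G{i}" for i in range(40)],
        )
        res = scoring.hierarchical_cluster(ev.ProteinMatrix(vals, Scale.GLOG))
        dist = 1 - np.corrcoef(vals.to_numpy(), rowvar=False)
        np.fill_diagonal(dist, 0.0)
        coph_oracle, _ = upgma_cophenetic(dist)
        coph_pkg = squareform(cophenet(res.linkage_matrix))
        np.testing.assert_allclose(coph_pkg, coph_oracle, atol=1e-10)

    def test_zero_variance_item_flagged_distance_one(self):
        vals = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 5.0], "flat": [7.0, 7.0, 7.0]},
            index=["G1", "G2", "G3"],
        )
        res = scoring.hierarchical_cluster(ev.ProteinMatrix(vals, Scale.GLOG))
        assert res.zero_variance_items == ["flat"]

    def test_subtype_purity_on_study_cohort(self, study_cohort):
        """Cutting the sample tree into 3 clusters recovers the subtypes."""
        design, glog = study_cohort["design"], study_cohort["glog"]
        res = scoring.hierarchical_cluster(glog)
        labels = cut_clusters(res, 3)
        for cluster in set(labels.values()):
            members = [s for s, c in labels.items() if c == cluster]
            subtypes = {design.subtype_of(s) for s in members}
            assert len(subtypes) == 1


class TestPca:
    def test_identical_samples_identical_coordinates(self):
        rng = np.random.default_rng(SEED)
        col = rng.normal(size=30)
        vals = pd.DataFrame(
            {"a": col, "b": col, "c": rng.normal(size=30)},
            index=[f"G{i}" for i in range(30)],
        )
        res = scoring.pca_project(ev.ProteinMatrix(vals, Scale.GLOG))
        np.testing.assert_allclose(
            res.pca_coordinates.loc["a"], res.pca_coordinates.loc["b"], atol=1e-9
        )

    def test_explained_variance_non_increasing(self, study_cohort):
        res = scoring.pca_project(study_cohort["glog"])
        ev_ratio = res.explained_variance
        assert (np.diff(ev_ratio) <= 1e-12).all()
        assert ev_ratio.sum() <= 1.0 + 1e-9

    def test_subtype_separation_positive_silhouette(self, study_cohort):
        from sklearn.metrics import silhouette_score

        design = study_cohort["design"]
        res = scoring.pca_project(study_cohort["glog"])
        labels = [design.subtype_of(s).value for s in res.pca_coordinates.index]
        assert silhouette_score(res.pca_coordinates.iloc[:, :2], labels) > 0


class TestOverlapCounts:
    def test_toy_regions_match_set_oracle(self, study_cohort):
        rng = np.random.default_rng(SEED)
        design = study_cohort["design"]
        proteins = [f"P{i}" for i in range(10)]
        det = pd.DataFrame(
            rng.random((10, len(design.sample_ids))) > 0.3,
            index=proteins, columns=design.sample_ids,
        )
        venn = scoring.overlap_counts(det, design)
        oracle_sets = {}
        for st_ in ("AR_POS", "AR_NEG_NE_POS", "AR_NEG_NE_NEG"):
            cols = design.samples_of(st_)
            oracle_sets[st_] = {
                p for p in proteins if all(det.loc[p, c] for c in cols)
            }
        oracle = venn_regions(oracle_sets)
        assert set(venn.regions) == set(oracle)
        for key in oracle:
            assert venn.regions[key] == oracle[key]
        # region sizes sum to the union
        union = set().union(*oracle_sets.values())
        assert sum(len(v) for v in venn.regions.values()) == len(union)

    def test_everywhere_detected_protein_in_core(self, study_cohort):
        design = study_cohort["design"]
        det = pd.DataFrame(
            True, index=["P1"], columns=design.sample_ids
        )
        venn = scoring.overlap_counts(det, design)
        assert "P1" in venn.core

    def test_one_missing_isolation_excludes_from_subtype_set(self, study_cohort):
        design = study_cohort["design"]
        det = pd.DataFrame(True, index=["P1"], columns=design.sample_ids)
        det.loc["P1", design.samples_of(Subtype.AR_POS)[0]] = False
        venn = scoring.overlap_counts(det, design)
        assert "P1" not in venn.subtype_sets["AR_POS"]
        assert "P1" in venn.subtype_sets["AR_NEG_NE_POS"]


class TestCohortOverlap:
    def test_identical_and_disjoint(self):
        a = _matrix({"s1": [1.0, 2.0]}, ["P1", "P2"])
        b = _matrix({"t1": [3.0, 4.0]}, ["P1", "P2"])
        shared, only_a, only_b = scoring.cohort_overlap(a, b)
        assert shared == {"P1", "P2"} and not only_a and not only_b
        c = _matrix({"t1": [3.0, 4.0]}, ["X1", "X2"])
        shared, only_a, only_b = scoring.cohort_overlap(a, c)
        assert not shared and only_a == {"P1", "P2"} and only_b == {"X1", "X2"}
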