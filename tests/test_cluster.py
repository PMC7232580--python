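import numpy as np
import pytest

from ecgcluster.cluster import (
    ClusterModel,
    CrossTab,
    FeatureMatrix,
    PipelineConfig,
    concentricity,
    crosstab,
    euclidean_distance,
    kmeans,
    ratio,
    report_to_json,
    run_pipeline,
)
from ecgcluster.cohort import CohortConfig
from ecgcluster.io import CONDITIONS, MedicalRecord

from conftest import brute_force_min_sse


class TestEuclideanDistance:
    def test_identity_and_pythagoras(self):
        assert euclidean_distance([1, 2], [1, 2]) == 0.0
        assert euclidean_distance([0, 0], [3, 4]) == 5.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=(2, 6))
            assert euclidean_distance(a, b) == euclidean_distance(b, a)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])


class TestKmeans:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        m = kmeans(X, 1, seed=0)
        assert np.allclose(m.centers[0], X.mean(axis=0))
        assert m.sse == pytest.approx(float(((X - X.mean(axis=0)) ** 2).sum()))

    def test_k_equals_n_zero_error(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 3))
        m = kmeans(X, 6, seed=0, n_init=10)
        assert m.sse == pytest.approx(0.0, abs=1e-12)

    def test_two_blobs_recover_exhaustive_optimum(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.2, (3, 2)), rng.normal(10, 0.2, (3, 2))])
        m = kmeans(X, 2, seed=0, n_init=5)
        assert m.labels[:3].std() == 0 and m.labels[3:].std() == 0
        assert m.labels[0] != m.labels[3]
        assert m.sse == pytest.approx(brute_force_min_sse(X, 2), rel=1e-9)

    def test_sse_non_increasing(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 5))
        for seed in range(5):
            m = kmeans(X, 4, seed=seed)
            diffs = np.diff(m.sse_history)
            assert np.all(diffs <= 1e-9)

    def test_centers_are_cluster_means(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 3))
        m = kmeans(X, 3, seed=1)
        for j in range(3):
            members = X[m.labels == j]
            assert np.allclose(m.centers[j], members.mean(axis=0), atol=1e-9)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans(np.zeros((3, 2)), 4)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        a = kmeans(X, 3, seed=9)
        b = kmeans(X, 3, seed=9)
        assert np.array_equal(a.labels, b.labels)
        assert a.sse == b.sse

    def test_matches_sklearn_from_same_initialization(self):
        sklearn = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 4))
        init = X[np.random.default_rng(11).choice(60, size=3, replace=False)]
        ours = kmeans(X, 3, seed=11)
        ref = sklearn.KMeans(n_clusters=3, init=init, n_init=1, max_iter=300).fit(X)
        assert ours.sse == pytest.approx(ref.inertia_, rel=1e-6)

    def test_standardized_clustering_invariant_to_column_rescaling(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 4))
        fm = FeatureMatrix(ids=[f"s{i}" for i in range(50)], X=X)
        scaled = FeatureMatrix(
            ids=fm.ids, X=X * np.array([1.0, 100.0, 0.01, 5.0]) + np.array([0, 3, -2, 1])
        )
        a = kmeans(fm.standardized(), 3, seed=2)
        b = kmeans(scaled.standardized(), 3, seed=2)
        assert np.array_equal(a.labels, b.labels)


def _records(flags_by_id):
    recs = []
    for sid, f in flags_by_id.items():
        kwargs = dict.fromkeys(CONDITIONS, False)
        kwargs.update(f)
        recs.append(MedicalRecord(subject_id=sid, **kwargs))
    return recs


def _model(labels, k):
    labels = np.asarray(labels)
    return ClusterModel(
        k=k, centers=np.zeros((k, 1)), labels=labels, sse=0.0, n_iter=1, seed=0,
        sse_history=[0.0],
    )


class TestCrossTabAndMetrics:
    def test_counts_and_conservation(self):
        ids = [f"s{i}" for i in range(6)]
        labels = [0, 0, 0, 1, 1, 1]
        recs = _records(
            {
                "s0": {"diabetes": True},
                "s1": {},
                "s2": {"smoker": True},
                "s3": {"diabetes": True},
                "s4": {"diabetes": True, "smoker": True},
                "s5": {},
            }
        )
        tab = crosstab(_model(labels, 2), ids, recs)
        assert tab.group_sizes.tolist() == [3, 3]
        assert tab.positives["diabetes"].tolist() == [1, 2]
        assert tab.positives["smoker"].tolist() == [1, 1]
        for c in CONDITIONS:
            assert tab.positives[c].sum() == tab.total_positives[c]

    def test_missing_record_names_subject(self):
        with pytest.raises(KeyError, match="s1"):
            crosstab(_model([0, 0], 1), ["s0", "s1"], _records({"s0": {}}))

    def test_unknown_flags_excluded_from_denominators(self):
        ids = ["a", "b", "c"]
        recs = [
            MedicalRecord("a", diabetes=True, obesity=False, hypertension=False, smoker=False),
            MedicalRecord("b", diabetes=None, obesity=False, hypertension=False, smoker=False),
            MedicalRecord("c", diabetes=False, obesity=False, hypertension=False, smoker=False),
        ]
        tab = crosstab(_model([0, 0, 0], 1), ids, recs)
        assert ratio(tab, "diabetes", 1) == pytest.approx(0.5)  # 1 of 2 known

    def test_all_unknown_gives_not_applicable(self):
        recs = [MedicalRecord("a"), MedicalRecord("b")]
        tab = crosstab(_model([0, 1], 2), ["a", "b"], recs)
        assert ratio(tab, "diabetes", 1) is None
        assert concentricity(tab, "diabetes") is None

    def test_ratio_from_printed_counts(self):
        # waveform-feature clustering at k=8: smokers 11/21, 7/9, 2/3
        tab = CrossTab.from_counts(
            group_sizes=[21, 69, 19, 9, 7, 149, 3, 13],
            positives={"smoker": [11, 0, 9, 7, 1, 35, 2, 8]},
        )
        assert ratio(tab, "smoker", 1) * 100 == pytest.approx(52.38, abs=0.005)
        assert ratio(tab, "smoker", 4) * 100 == pytest.approx(77.78, abs=0.005)
        assert ratio(tab, "smoker", 7) * 100 == pytest.approx(66.67, abs=0.005)
        assert ratio(tab, "smoker", 2) == 0.0

    def test_concentricity_from_printed_counts(self):
        # RBP-feature clustering at k=2: diabetes counts (8, 21)
        tab = CrossTab.from_counts(group_sizes=[140, 150], positives={"diabetes": [8, 21]})
        value, group = concentricity(tab, "diabetes")
        assert value * 100 == pytest.approx(72.41, abs=0.005)
        assert group == 2

    def test_concentricity_extremes(self):
        tab = CrossTab.from_counts([10, 10, 10], {"smoker": [6, 0, 0]})
        assert concentricity(tab, "smoker") == (1.0, 1)
        even = CrossTab.from_counts([10, 10], {"smoker": [3, 3]})
        value, _ = concentricity(even, "smoker")
        assert value == pytest.approx(0.5)


class TestPipeline:
    def _config(self, **kw):
        cohort = CohortConfig(
            n_subjects=12,
            seed=5,
            duration=8.0,
            prevalence=kw.pop("prevalence", None) or {c: 0.25 for c in CONDITIONS},
        )
        return PipelineConfig(
            cohort=cohort, feature_sets=("waveform",), ks=(2,), cluster_seed=5, **kw
        )

    def test_reports_are_byte_identical(self):
        r1 = run_pipeline(self._config())
        r2 = run_pipeline(self._config())
        assert report_to_json(r1) == report_to_json(r2)

    def test_zero_prevalence_metrics_not_applicable(self):
        report = run_pipeline(self._config(prevalence={c: 0.0 for c in CONDITIONS}))
        metrics = report["feature_sets"]["waveform"]["k"]["2"]["metrics"]
        for c in CONDITIONS:
            assert metrics["concentricity"][c] is None
            assert not any(metrics["significant"][c])

    def test_crosstab_table_rendered(self):
        report = run_pipeline(self._config())
        table = report["feature_sets"]["waveform"]["k"]["2"]["table"]
        assert "Group 1" in table and "Diabetes" in table
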