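import numpy as np
import pytest

from sodphrv.exceptions import InsufficientDataError, ParameterError
from sodphrv.knn_ensemble import (
    ClassificationReport,
    EnsembleConfig,
    SubjectFeatures,
    _classify_held_out,
    _regularized_inverse_covariance,
    classify_subject,
    compute_subject_features,
    nn_classify,
    precompute_features,
    run_experiment,
    sdrr_threshold_baseline,
    summary_table,
    table2_configs,
    training_arrays,
    vote_groups,
    vote_realizations,
    window_starts,
)
import pandas as pd

SMALL_CFG = dict(train_length=2000, window_length=1000, mc=3)


def small_config(**kw):
    return EnsembleConfig(**{**SMALL_CFG, **kw})


class TestEnsembleConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(distance="cosine"),
            dict(k=2),
            dict(k=0),
            dict(window_length=3000),
            dict(mc=0),
            dict(realization_threshold=0.0),
            dict(group_threshold=1.5),
            dict(feature_set=()),
            dict(feature_set=("ctm", "bogus")),
        ],
    )
    def test_invalid(self, kw):
        with pytest.raises(ParameterError):
            small_config(**kw)

    def test_subsets_all_nonempty(self):
        cfg = small_config(feature_set=("ctm", "d_mean", "sdrr"))
        subsets = cfg.feature_subsets()
        assert len(subsets) == 7  # 2^3 - 1
        assert ("ctm",) in subsets and ("ctm", "d_mean", "sdrr") in subsets

    def test_six_features_give_63_groups(self):
        cfg = small_config(
            feature_set=("ctm", "d_mean", "cctm1", "cctm2", "cctm3", "cctm4")
        )
        assert len(cfg.feature_subsets()) == 63


class TestWindowStarts:
    def test_paper_geometry(self):
        starts = window_starts(70000, 30000, 31)
        assert len(starts) == 31
        assert starts[0] == 0 and starts[-1] == 40000
        assert np.all(np.diff(starts) >= 0)
        assert set(np.diff(starts)) <= {1333, 1334}

    def test_mc_one(self):
        np.testing.assert_array_equal(window_starts(70000, 30000, 1), [0])

    def test_mc_two_endpoints(self):
        np.testing.assert_array_equal(window_starts(100, 40, 2), [0, 60])

    def test_infeasible(self):
        with pytest.raises(ParameterError):
            window_starts(100, 200, 3)


class TestVoting:
    def test_realization_boundary_30_of_31(self):
        flags = np.ones(31, dtype=int)
        flags[0] = 0  # 30/31 = 0.9677 > 0.95
        assert vote_realizations(flags, 31, 0.95) == 1

    def test_realization_boundary_29_of_31(self):
        flags = np.ones(31, dtype=int)
        flags[:2] = 0  # 29/31 = 0.9355
        assert vote_realizations(flags, 31, 0.95) == 0

    def test_all_wrong(self):
        assert vote_realizations(np.ones(31), 31, 0.95) == 1

    def test_single_group_degenerate(self):
        assert vote_groups([1], 0.95) is True
        assert vote_groups([0], 0.95) is False

    def test_group_strictness(self):
        # 62/63 = 0.984 > 0.95 ; 59/63 = 0.937
        assert vote_groups([1] * 62 + [0], 0.95) is True
        assert vote_groups([1] * 59 + [0] * 4, 0.95) is False

    def test_empty_groups_error(self):
        with pytest.raises(ParameterError):
            vote_groups([])


class TestNNClassify:
    def test_exact_match_wins(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert nn_classify([1.0, 1.0], X, ["N", "CHF"]) == "CHF"

    def test_1d_nearest(self):
        assert nn_classify([0.2], [[0.0], [1.0]], ["N", "CHF"]) == "N"

    def test_tie_broken_by_lowest_index(self):
        X = np.array([[0.5], [0.5]])
        assert nn_classify([0.5], X, ["CHF", "N"]) == "CHF"

    def test_identity_covariance_equals_euclidean(self, rng):
        for _ in range(100):
            X = rng.normal(size=(10, 3))
            y = ["N"] * 5 + ["CHF"] * 5
            t = rng.normal(size=3)
            assert nn_classify(t, X, y, "euclidean") == nn_classify(
                t, X, y, "mahalanobis", VI=np.eye(3)
            )

    def test_mahalanobis_rescales(self):
        # feature 2 has huge scale; Euclidean is dominated by it,
        # Mahalanobis is not
        X = np.array([[0.0, 0.0], [1.0, 900.0], [0.2, 1100.0]])
        y = ["N", "CHF", "CHF"]
        t = np.array([0.1, 1000.0])
        assert nn_classify(t, X, y, "euclidean") == "CHF"

    def test_empty_train(self):
        with pytest.raises(ParameterError):
            nn_classify([0.1], np.empty((0, 1)), [])

    def test_nonfinite_rejected(self):
        with pytest.raises(ParameterError):
            nn_classify([np.nan], [[0.0]], ["N"])

    def test_k3_majority(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0]])
        y = ["N", "CHF", "CHF", "N"]
        assert nn_classify([0.0], X, y, k=3) == "CHF"

    def test_singular_covariance_regularized(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0], [2.0, 4.0]])
        VI = _regularized_inverse_covariance(X)
        assert np.all(np.isfinite(VI))

    def test_covariance_needs_two_rows(self):
        with pytest.raises(InsufficientDataError):
            _regularized_inverse_covariance(np.array([[1.0, 2.0]]))


class TestLeaveOneOutHygiene:
    def test_held_out_absent_from_training(self, small_cohort):
        cfg = small_config()
        feats = precompute_features(small_cohort, cfg)
        held = small_cohort[0].subject_id
        X, y, ids = training_arrays(feats, held, [0, 6])
        assert held not in ids
        assert X.shape == (len(small_cohort) - 1, 2)
        assert len(y) == len(ids)

    def test_unknown_held_out(self, small_cohort):
        feats = precompute_features(small_cohort, small_config())
        with pytest.raises(ParameterError):
            training_arrays(feats, "nobody", [0])


def fake_features(rows):
    """Build a features dict from (id, group, train_vec, test_rows)."""
    out = {}
    for sid, group, train, tests in rows:
        out[sid] = SubjectFeatures(
            subject_id=sid,
            group=group,
            train=np.asarray(train, dtype=float),
            tests=np.asarray(tests, dtype=float),
        )
    return out


def vec(v):
    return np.full(7, float(v))


class TestClassifySubject:
    def test_all_correct_not_misclassified(self):
        cfg = small_config(feature_set=("ctm",), mc=2)
        feats = fake_features(
            [
                ("n0", "N", vec(0.1), [vec(0.1), vec(0.12)]),
                ("n1", "N", vec(0.11), [vec(0.1), vec(0.1)]),
                ("c0", "CHF", vec(0.9), [vec(0.9), vec(0.88)]),
                ("c1", "CHF", vec(0.91), [vec(0.9), vec(0.9)]),
            ]
        )
        mis, P = _classify_held_out(feats, "n0", cfg)
        assert mis is False and list(P) == [0]

    def test_all_wrong_misclassified(self):
        cfg = small_config(feature_set=("ctm",), mc=2)
        feats = fake_features(
            [
                ("n0", "N", vec(0.1), [vec(0.9), vec(0.9)]),  # looks like CHF
                ("n1", "N", vec(0.11), [vec(0.1), vec(0.1)]),
                ("c0", "CHF", vec(0.9), [vec(0.9), vec(0.88)]),
                ("c1", "CHF", vec(0.91), [vec(0.9), vec(0.9)]),
            ]
        )
        mis, P = _classify_held_out(feats, "n0", cfg)
        assert mis is True and list(P) == [1]

    def test_nan_test_feature_counts_as_wrong(self):
        cfg = small_config(feature_set=("d_mean",), mc=2)
        bad = np.full(7, 0.1)
        bad[1] = np.nan  # d_mean slot
        feats = fake_features(
            [
                ("n0", "N", vec(0.1), [bad, bad]),
                ("n1", "N", vec(0.11), [vec(0.1), vec(0.1)]),
                ("c0", "CHF", vec(0.9), [vec(0.9), vec(0.9)]),
            ]
        )
        mis, P = _classify_held_out(feats, "n0", cfg)
        assert mis is True and list(P) == [1]

    def test_public_entrypoint(self, small_cohort):
        cfg = small_config(feature_set=("ctm", "sdrr"))
        mis, P = classify_subject(small_cohort[0], small_cohort, cfg)
        assert isinstance(mis, bool)
        assert len(P) == 3

    def test_subject_must_be_in_cohort(self, small_cohort):
        with pytest.raises(ParameterError):
            classify_subject(small_cohort[0], small_cohort[1:], small_config())


@pytest.fixture(scope="module")
def reports(small_cohort):
    configs = [
        small_config(feature_set=("ctm", "d_mean"), distance=d)
        for d in ("euclidean", "mahalanobis")
    ]
    return run_experiment(small_cohort, configs)


class TestRunExperiment:
    def test_report_shape(self, reports, small_cohort):
        assert len(reports) == 2
        for rep in reports:
            assert set(rep.per_subject) == {s.subject_id for s in small_cohort}
            assert rep.n_misclassified == rep.n_misclassified_n + rep.n_misclassified_chf

    def test_separated_cohort_classified_cleanly(self, reports):
        for rep in reports:
            assert rep.n_misclassified == 0

    def test_determinism(self, small_cohort, reports):
        again = run_experiment(
            small_cohort,
            [small_config(feature_set=("ctm", "d_mean"), distance="euclidean")],
        )[0]
        assert again.to_json_dict() == reports[0].to_json_dict()

    def test_summary_table(self, reports):
        tbl = summary_table(reports)
        assert list(tbl["distance"]) == ["euclidean", "mahalanobis"]
        assert "feature_set" in tbl.columns

    def test_table2_configs_grid(self):
        configs = table2_configs(train_length=2000, window_length=1000, mc=3)
        assert len(configs) == 8  # 4 feature sets x 2 distances
        sizes = {len(c.feature_set) for c in configs}
        assert sizes == {1, 2, 6}


class TestSubjectFeatureGeometry:
    def test_short_series_uses_available_beats(self, small_cohort, caplog):
        cfg = EnsembleConfig(train_length=10000, window_length=5000, mc=3)
        with caplog.at_level("INFO", logger="sodphrv.knn_ensemble"):
            sf = compute_subject_features(small_cohort[0], cfg)
        assert sf.tests.shape == (3, 7)
        assert any("available" in r.message for r in caplog.records)

    def test_window_count(self, small_cohort):
        sf = compute_subject_features(small_cohort[0], small_config(mc=5))
        assert sf.tests.shape == (5, 7)
        assert sf.train.shape == (7,)


class TestSDRRThresholdBaseline:
    def test_perfect_separation(self):
        tbl = pd.DataFrame(
            {"group": ["N"] * 3 + ["CHF"] * 3, "sdrr": [0.09, 0.1, 0.11, 0.02, 0.03, 0.04]}
        )
        errors, threshold = sdrr_threshold_baseline(tbl)
        assert errors == 0
        assert 0.04 < threshold < 0.09

    def test_identical_values_degenerate(self):
        tbl = pd.DataFrame({"group": ["N"] * 4 + ["CHF"] * 2, "sdrr": [0.05] * 6})
        errors, _ = sdrr_threshold_baseline(tbl)
        assert errors == 2  # size of the smaller class

    def test_fixed_threshold(self):
        tbl = pd.DataFrame({"group": ["N", "CHF"], "sdrr": [0.1, 0.02]})
        errors, threshold = sdrr_threshold_baseline(tbl, threshold=0.05)
        assert errors == 0 and threshold == 0.05

    def test_missing_sdrr_rejected(self):
        tbl = pd.DataFrame({"group": ["N", "CHF"], "sdrr": [0.1, np.nan]})
        with pytest.raises(ParameterError):
            sdrr_threshold_baseline(tbl)


class TestReportSerialization:
    def test_json_roundtrip(self, small_cohort, tmp_path):
        rep = run_experiment(small_cohort, [small_config(feature_set=("sdrr",))])[0]
        path = tmp_path / "report.json"
        rep.write_json(path)
        import json

        data = json.loads(path.read_text())
        assert data["config"]["feature_set"] == ["sdrr"]
        assert set(data["per_subject"]) == {s.subject_id for s in small_cohort}
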