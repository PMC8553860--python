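"""The four scoring algorithms: arithmetic, invariances, ALG4 fit, cut-offs."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cariescan.calibration import CutoffEntry, CutoffSet
from cariescan.cohort import SignalVector, ToothRecord, signal_model
from cariescan.errors import (
    ConfigurationError,
    InsufficientSignalError,
    InsufficientTrainingError,
    ReferenceMissingError,
)
from cariescan.histology import DiagnosticLevel
from cariescan.scoring import (
    Alg4Model,
    alg1_raw,
    alg2_raw,
    alg3_raw,
    alg4_features,
    alg4_raw,
    apply_cutoffs,
    fit_alg4,
    fit_alg4_features,
    score_cohort,
    sound_reference,
)
from cariescan.stats import auc_delong

from conftest import quiet_config


def sv(r_fluo=0.1, g_fluo=0.8, r=0.7, g=0.7, b=0.6):
    return SignalVector(r_fluo, g_fluo, r, g, b)


positive_signal = st.builds(
    sv,
    r_fluo=st.floats(0.01, 1.0),
    g_fluo=st.floats(0.01, 1.0),
    r=st.floats(0.01, 1.0),
    g=st.floats(0.01, 1.0),
    b=st.floats(0.01, 1.0),
)


class TestRawScores:
    @pytest.mark.parametrize(("g_fluo", "raw"), [(1.0, 0.0), (0.25, 0.75), (0.2, 0.8)])
    def test_alg1_is_green_loss(self, g_fluo, raw):
        assert alg1_raw(sv(g_fluo=g_fluo)) == pytest.approx(raw)

    @pytest.mark.parametrize(
        ("site_g", "ref_g", "raw"),
        [(0.4, 0.8, 0.5), (0.8, 0.8, 0.0), (0.9, 0.8, -0.125)],
    )
    def test_alg2_is_relative_green_loss(self, site_g, ref_g, raw):
        assert alg2_raw(sv(g_fluo=site_g), sv(g_fluo=ref_g)) == pytest.approx(raw)

    def test_alg2_zero_reference_rejected(self):
        with pytest.raises(InsufficientSignalError):
            alg2_raw(sv(), sv(g_fluo=0.0))

    def test_alg3_is_red_green_log_ratio(self):
        ref = sv(r_fluo=0.1, g_fluo=0.8)
        assert alg3_raw(ref, ref) == pytest.approx(0.0)
        # red ratio 2, green ratio 0.5 -> log 4
        site = sv(r_fluo=0.2, g_fluo=0.4)
        assert alg3_raw(site, ref) == pytest.approx(math.log(4.0))

    def test_alg3_nonpositive_intensity_rejected(self):
        with pytest.raises(InsufficientSignalError):
            alg3_raw(sv(r_fluo=0.0), sv())

    @given(site=positive_signal, ref=positive_signal, scale=st.floats(0.1, 1.0))
    def test_brightness_invariance_of_ratio_scores(self, site, ref, scale):
        site2 = SignalVector.from_array(site.as_array() * scale)
        ref2 = SignalVector.from_array(ref.as_array() * scale)
        assert alg2_raw(site2, ref2) == pytest.approx(alg2_raw(site, ref), abs=1e-9)
        assert alg3_raw(site2, ref2) == pytest.approx(alg3_raw(site, ref), abs=1e-9)
        model = Alg4Model(intercept=0.3, coefficients=np.array([0.5, -1, 2, 0.1, -0.2]),
                          n_train=0)
        assert alg4_raw(site2, ref2, model) == pytest.approx(
            alg4_raw(site, ref, model), abs=1e-9
        )
        # ALG1 is deliberately an absolute signal
        if abs(1 - scale) > 1e-3 and site.g_fluo > 1e-3:
            assert alg1_raw(site2) != pytest.approx(alg1_raw(site), abs=1e-12)


class TestSoundReference:
    def test_returns_stored_per_condition_reference(self):
        tooth = ToothRecord("T1", 0.0, sv(g_fluo=0.8), sv(g_fluo=0.9))
        assert sound_reference(tooth, "in_vivo").g_fluo == 0.8
        assert sound_reference(tooth, "in_vitro").g_fluo == 0.9

    def test_missing_reference_raises(self):
        tooth = ToothRecord("T1", 0.0, None, sv())
        with pytest.raises(ReferenceMissingError):
            sound_reference(tooth, "in_vivo")


class TestAlg4:
    def test_null_model_predicts_half(self):
        model = Alg4Model(intercept=0.0, coefficients=np.zeros(5), n_train=0)
        assert alg4_raw(sv(), sv(g_fluo=0.3), model) == pytest.approx(0.5)

    def test_site_equal_to_reference_gives_logistic_intercept(self):
        model = Alg4Model(intercept=1.2, coefficients=np.array([3.0, -2, 1, 0.5, 4]),
                          n_train=0)
        assert alg4_raw(sv(), sv(), model) == pytest.approx(1 / (1 + math.exp(-1.2)))

    def test_monotone_in_positively_weighted_feature(self):
        model = Alg4Model(intercept=0.0, coefficients=np.array([0.0, 2.0, 0, 0, 0]),
                          n_train=0)  # weight on delta_Rfluo
        ref = sv()
        lo = alg4_raw(sv(r_fluo=0.05), ref, model)
        hi = alg4_raw(sv(r_fluo=0.4), ref, model)
        assert hi > lo

    def test_recovers_single_informative_feature(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(400, 5))
        y = rng.random(400) < 1 / (1 + np.exp(-3 * x[:, 0]))  # delta_Gfluo only
        model = fit_alg4_features(x, y)
        assert np.argmax(np.abs(model.coefficients)) == 0
        assert abs(model.coefficients[0]) > 3 * np.max(np.abs(model.coefficients[1:]))

    def test_null_labels_give_chance_level_holdout_auc(self):
        rng = np.random.default_rng(1)
        x_train, x_test = rng.normal(size=(800, 5)), rng.normal(size=(800, 5))
        y_train, y_test = rng.random(800) < 0.5, rng.random(800) < 0.5
        model = fit_alg4_features(x_train, y_train)
        scores = [model.predict_proba(row) for row in x_test]
        assert abs(auc_delong(scores, y_test).az - 0.5) <= 0.05

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(100, 5))
        y = x[:, 1] + 0.5 * rng.normal(size=100) > 0
        a, b = fit_alg4_features(x, y), fit_alg4_features(x, y)
        assert a.intercept == b.intercept
        assert np.array_equal(a.coefficients, b.coefficients)

    def test_too_few_sites_per_class_rejected(self):
        x = np.zeros((30, 5))
        y = np.r_[np.ones(5, bool), np.zeros(25, bool)]
        with pytest.raises(InsufficientTrainingError):
            fit_alg4_features(x, y)

    def test_features_are_log_ratios(self):
        site, ref = sv(r_fluo=0.2, g_fluo=0.4), sv(r_fluo=0.1, g_fluo=0.8)
        f = alg4_features(site, ref)
        assert f[0] == pytest.approx(math.log(0.5))   # delta_Gfluo
        assert f[1] == pytest.approx(math.log(2.0))   # delta_Rfluo

    def test_json_round_trip(self, tmp_path):
        model = Alg4Model(intercept=-0.7, coefficients=np.array([1, 2, 3, 4, 5.0]),
                          n_train=99)
        path = tmp_path / "m.json"
        model.to_json(path)
        back = Alg4Model.from_json(path)
        assert back.intercept == model.intercept
        assert np.array_equal(back.coefficients, model.coefficients)


def three_level_cutoffs(thresholds=(0.2, 0.5, 0.8)):
    levels = (DiagnosticLevel.E1, DiagnosticLevel.D1, DiagnosticLevel.D2)
    return CutoffSet(
        "ALG3",
        [CutoffEntry(lv, t, 1.0, 1.0, True) for lv, t in zip(levels, thresholds)],
    )


class TestApplyCutoffs:
    def test_counts_thresholds_met(self):
        cs = three_level_cutoffs()
        assert apply_cutoffs(0.1, cs) == 0
        assert apply_cutoffs(0.5, cs) == 2  # exactly at the D1 cut-off: >= convention
        assert apply_cutoffs(0.95, cs) == 3

    def test_two_point_scale_saturates(self):
        cs = CutoffSet(
            "ALG2",
            [
                CutoffEntry(DiagnosticLevel.E1, 0.2, 1, 1, True),
                CutoffEntry(DiagnosticLevel.D1, 0.6, 1, 1, True),
            ],
        )
        assert apply_cutoffs(5.0, cs) == 2

    def test_missing_raw_propagates(self):
        assert apply_cutoffs(None, three_level_cutoffs()) is None
        assert apply_cutoffs(float("nan"), three_level_cutoffs()) is None

    def test_wrong_arity_rejected(self):
        broken = CutoffSet("ALG3", [CutoffEntry(DiagnosticLevel.E1, 0.2, 1, 1, True)])
        with pytest.raises(ConfigurationError):
            apply_cutoffs(0.5, broken)

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_cutoffs(0.5, three_level_cutoffs((0.8, 0.5, 0.2)))

    @given(st.lists(st.floats(-1, 2), min_size=2, max_size=10))
    def test_monotone_step_function(self, raws):
        cs = three_level_cutoffs()
        ordinals = [apply_cutoffs(r, cs) for r in sorted(raws)]
        assert ordinals == sorted(ordinals)


class TestScoreCohort:
    def test_missing_signals_propagate_as_insufficient(self, study_cohort):
        import copy

        cohort = copy.deepcopy(study_cohort)
        cohort[0].sites[0].signals_in_vivo = None
        scores = score_cohort(cohort, algorithms=("ALG1", "ALG2"))
        site = cohort[0].sites[0].site_id
        sel = scores[(scores.site_id == site) & (scores.condition == "in_vivo")]
        assert sel.raw_score.isna().all()

    def test_raw_scores_track_severity_without_noise(self, quiet_cohort, quiet_scores):
        # orientation invariant: severity-sorted sites give sorted raw scores
        severities = {
            s.site_id: s.latent_severity for t in quiet_cohort for s in t.sites
        }
        for algorithm, group in quiet_scores.groupby("algorithm"):
            g = group[group.condition == "in_vitro"].copy()
            g["severity"] = g.site_id.map(severities)
            g = g.sort_values("severity")
            raws = g.raw_score.to_numpy()
            assert np.all(np.diff(raws) >= -1e-9), algorithm

    def test_alg4_requires_model(self, quiet_cohort):
        with pytest.raises(ConfigurationError):
            score_cohort(quiet_cohort, algorithms=("ALG4",), alg4_model=None)
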