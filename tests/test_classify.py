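"""AUC oracle, CV classifier behaviour, permutation p-values and BH FDR."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import soundmap as sm
from soundmap.classify import (
    ClassifierResult,
    fdr_adjust,
    participant_counts,
    permutation_pvalue,
    sensitivity_specificity,
)

from conftest import make_profile


def brute_force_auc(scores, labels):
    """Independent oracle: explicit pair counting with half-credit ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    total = wins = 0.0
    for sc in scores[labels]:
        for sn in scores[~labels]:
            total += 1
            if sc > sn:
                wins += 1
            elif sc == sn:
                wins += 0.5
    return wins / total


class TestAucMannWhitney:
    def test_perfect_separation(self):
        assert sm.auc_mann_whitney([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_chance(self):
        assert sm.auc_mann_whitney([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_enumerated_pairs(self):
        # cases {0.9, 0.2} vs controls {0.3, 0.6}: 2 of 4 pairs won
        assert sm.auc_mann_whitney([0.9, 0.2, 0.3, 0.6], [1, 1, 0, 0]) == 0.5

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=20),
        st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_pair_counting(self, scores, data):
        n = len(scores)
        n_case = data.draw(st.integers(1, n - 1))
        labels = np.zeros(n, bool)
        labels[:n_case] = True
        # quantise to provoke ties
        scores = np.round(np.asarray(scores), 1)
        assert sm.auc_mann_whitney(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_matches_scipy_u_statistic(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        u = stats.mannwhitneyu(scores[labels], scores[~labels]).statistic
        assert sm.auc_mann_whitney(scores, labels) == pytest.approx(
            u / (labels.sum() * (~labels).sum())
        )

    def test_monotone_transform_and_order_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        labels = np.arange(30) < 12
        base = sm.auc_mann_whitney(scores, labels)
        assert sm.auc_mann_whitney(np.exp(scores), labels) == pytest.approx(base)
        perm = rng.permutation(30)
        assert sm.auc_mann_whitney(scores[perm], labels[perm]) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            sm.auc_mann_whitney([1.0, 2.0], [1, 1])


class TestSensitivitySpecificity:
    def test_reported_convention_swaps_roles(self):
        scores = np.array([0.9, 0.9, 0.1, 0.4, 0.6])
        labels = np.array([1, 1, 1, 0, 0], bool)
        sens, spec = sensitivity_specificity(scores, labels)  # as-reported
        # cases correct: 2/3 -> called "specificity"; controls correct: 1/2
        assert spec == pytest.approx(2 / 3)
        assert sens == pytest.approx(1 / 2)
        sens_std, spec_std = sensitivity_specificity(scores, labels, convention="standard")
        assert sens_std == pytest.approx(2 / 3)
        assert spec_std == pytest.approx(1 / 2)


class TestFdrAdjust:
    def test_hand_executed_step_up_example(self):
        q, reject = fdr_adjust([0.01, 0.02, 0.04, 0.20], alpha=0.05)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.20])
        # largest k with p_(k) <= k*alpha/m is k = 2
        assert list(reject) == [True, True, False, False]

    def test_all_ones(self):
        q, reject = fdr_adjust([1.0, 1.0, 1.0])
        assert np.all(q == 1.0) and not reject.any()

    def test_single_p_unchanged(self):
        q, _ = fdr_adjust([0.03])
        assert q[0] == pytest.approx(0.03)

    def test_q_geq_p_and_monotone(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        q, _ = fdr_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejections_superset_of_bonferroni(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.random(30) ** 2
            _, reject = fdr_adjust(p, alpha=0.05)
            bonf = p <= 0.05 / len(p)
            assert np.all(reject[bonf])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestSoundClassifier:
    def test_null_cohort_near_chance(self, fast_cfg):
        data = sm.generate_cohort(make_profile(seed=31), 100, 100)
        res = sm.train_sound_classifier(data, "s0", folds=5, config=fast_cfg, seed=2)
        assert 0.4 <= res.auc <= 0.6

    def test_signal_cohort_detected_and_deterministic(
        self, signal_cohort_small, fast_cfg
    ):
        res1 = sm.train_sound_classifier(
            signal_cohort_small, "s0", folds=5, config=fast_cfg, seed=3
        )
        res2 = sm.train_sound_classifier(
            signal_cohort_small, "s0", folds=5, config=fast_cfg, seed=3
        )
        assert res1.auc == res2.auc
        np.testing.assert_array_equal(res1.oof_scores, res2.oof_scores)
        assert res1.auc > 0.7
        assert len(res1.oof_scores) == signal_cohort_small.n_participants
        assert res1.correct_flags.mean() > 0.5

    def test_too_few_participants_suggests_fewer_folds(self, fast_cfg):
        data = sm.generate_cohort(make_profile(seed=32), 6, 30)
        with pytest.raises(ValueError, match="folds"):
            sm.train_sound_classifier(data, "s0", folds=10, config=fast_cfg)

    def test_tuning_grid_respected(self, signal_cohort_small):
        cfg = sm.ForestConfig(n_trees=30, grid=(2, 8), inner_folds=2)
        res = sm.train_sound_classifier(
            signal_cohort_small, "s0", folds=5, config=cfg, seed=4
        )
        assert set(res.tuning) <= {2, 8}
        assert len(res.tuning) == 5


class TestPermutation:
    def test_minimum_attainable_p_on_strong_signal(self, tiny_cfg):
        spec = make_profile(effect_cells={(0, "rage"): 2.0}, seed=33)
        data = sm.generate_cohort(spec, 20, 20)
        p, obs, null = sm.permutation_p(
            data, "s0", n_perm=19, folds=3, config=tiny_cfg, seed=5
        )
        assert p == pytest.approx(1.0 / 20.0)
        assert obs > null.max()

    def test_n_perm_zero_rejected(self, tiny_cfg, null_cohort_small):
        with pytest.raises(ValueError, match="n_perm"):
            sm.permutation_p(null_cohort_small, "s0", n_perm=0, config=tiny_cfg)

    def test_generic_engine_super_uniform_null(self):
        # cheap statistic, many null datasets: p-values should not be
        # anti-conservative
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(100):
            x = rng.normal(size=30)
            labels = np.zeros(30, bool)
            labels[:15] = True

            def stat(y, x=x):
                return sm.auc_mann_whitney(x, y.astype(bool))

            p, _, _ = permutation_pvalue(stat, labels, n_perm=39, seed=int(rng.integers(2**31)))
            pvals.append(p)
        assert np.mean(np.array(pvals) < 0.05) <= 0.12


@pytest.fixture(scope="module")
def spread_cohort():
    # signal spread over four sounds, two descriptors each
    cells = {}
    for i, descs in enumerate(
        [
            ("rage", "annoyance"),
            ("body_tension", "distress"),
            ("anxiety", "discomfort"),
            ("disgust", "flinching"),
        ]
    ):
        for d in descs:
            cells[(i, d)] = 0.7
    return sm.generate_cohort(
        make_profile(n_sounds=4, effect_cells=cells, seed=34), 150, 150
    )


class TestAggregate:
    def test_aggregate_beats_single_sounds_when_signal_is_spread(self, spread_cohort):
        cfg = sm.ForestConfig(n_trees=150, grid=(8,), min_samples_leaf=5)
        per_sound = [
            sm.train_sound_classifier(spread_cohort, s, folds=5, config=cfg, seed=i).auc
            for i, s in enumerate(spread_cohort.sounds)
        ]
        agg, _ = sm.aggregate_classifier(spread_cohort, folds=5, config=cfg, seed=9)
        assert agg.auc >= max(per_sound)

    def test_scoring_invariant_to_column_order(self, spread_cohort, fast_cfg):
        _, model = sm.aggregate_classifier(spread_cohort, folds=5, config=fast_cfg, seed=9)
        base = model.score(spread_cohort)
        reordered = dataclasses.replace(
            spread_cohort,
            ratings=spread_cohort.ratings[:, ::-1, :].copy(),
            sounds=list(reversed(spread_cohort.sounds)),
        )
        np.testing.assert_array_equal(model.score(reordered), base)

    def test_missing_columns_named(self, spread_cohort, fast_cfg):
        _, model = sm.aggregate_classifier(spread_cohort, folds=5, config=fast_cfg, seed=9)
        truncated = dataclasses.replace(
            spread_cohort,
            ratings=spread_cohort.ratings[:, :2, :],
            sounds=spread_cohort.sounds[:2],
        )
        with pytest.raises(ValueError, match="s2"):
            model.score(truncated)

    def test_null_scores_centre_on_prevalence(self, fast_cfg):
        data = sm.generate_cohort(make_profile(n_sounds=2, seed=35), 60, 60)
        _, model = sm.aggregate_classifier(data, folds=5, config=fast_cfg, seed=10)
        fresh = sm.generate_cohort(make_profile(n_sounds=2, seed=99), 60, 60)
        assert abs(model.score(fresh).mean() - 0.5) < 0.1

    def test_round_trip_save_load(self, spread_cohort, fast_cfg, tmp_path):
        _, model = sm.aggregate_classifier(spread_cohort, folds=5, config=fast_cfg, seed=9)
        model.save(tmp_path / "model.joblib")
        back = sm.AggregateModel.load(tmp_path / "model.joblib")
        np.testing.assert_array_equal(back.score(spread_cohort), model.score(spread_cohort))


class TestParticipantCounts:
    def _fake_result(self, sound, flags, labels, ids):
        return ClassifierResult(
            sound=sound,
            auc=0.5,
            sensitivity=0.5,
            specificity=0.5,
            oof_scores=np.where(flags == labels, 0.9, 0.1),
            correct_flags=flags,
            participant_ids=ids,
            labels=labels,
        )

    def test_perfect_classifiers_give_full_counts(self):
        ids = [f"P{i}" for i in range(6)]
        labels = np.array([1, 1, 1, 0, 0, 0], bool)
        results = [
            self._fake_result(f"s{k}", np.ones(6, bool), labels, ids) for k in range(4)
        ]
        scores, _ = participant_counts(results)
        assert all(s.n_correct == 4 for s in scores)
        assert len(scores) == 3  # cases only

    def test_roster_mismatch_rejected(self):
        labels = np.array([1, 0], bool)
        a = self._fake_result("a", np.ones(2, bool), labels, ["P0", "P1"])
        b = self._fake_result("b", np.ones(2, bool), labels, ["P0", "P2"])
        with pytest.raises(ValueError, match="roster"):
            participant_counts([a, b])
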