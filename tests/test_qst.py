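"""QST threshold computation and composite-score behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpnsig.qst import (
    NormativeBounds,
    QSTRecord,
    ReferenceStats,
    composite_pain_sensitivity,
    flag_extreme_qst,
    mechanical_pain_threshold,
    score_trials_table,
    t50_from_ratings,
    thermal_pain_threshold,
)

REF = ReferenceStats(44.5, 1.5, 15.0, 7.0, 1.8, 0.35)


class TestThermalThreshold:
    @pytest.mark.parametrize(
        "trials, expected",
        [
            ([44.0, 44.6, 44.2, 44.8, 44.4, 44.5], 44.5),
            ([45.0] * 6, 45.0),
            ([10.0, 20.0], 20.0),
        ],
    )
    def test_discards_first_then_averages(self, trials, expected):
        assert thermal_pain_threshold(trials) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [[44.0], [], [44.0, np.nan, 44.2]])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            thermal_pain_threshold(bad)

    @given(st.lists(st.floats(30, 50), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_permutation_invariant_after_first(self, trials):
        base = thermal_pain_threshold(trials)
        shuffled = [trials[0]] + trials[:0:-1]
        assert thermal_pain_threshold(shuffled) == pytest.approx(base)


class TestMechanicalThreshold:
    def test_identical_forces_give_log10(self):
        assert mechanical_pain_threshold([64] * 10) == pytest.approx(np.log10(64))

    def test_staircase_runs(self):
        forces = [8, 16, 32, 64, 128, 8, 16, 32, 64, 128]
        # mean of log10 forces, symmetric around 32 mN
        assert mechanical_pain_threshold(forces) == pytest.approx(1.505, abs=5e-4)

    def test_nonpositive_force_rejected(self):
        with pytest.raises(ValueError):
            mechanical_pain_threshold([32, 0])


class TestT50:
    def test_quadratic_generating_curve(self):
        temps = np.linspace(42.5, 48.0, 15)
        ratings = (100 / 30.25) * (temps - 42.5) ** 2
        expected = 42.5 + np.sqrt(50 * 30.25 / 100)  # closed-form root
        assert t50_from_ratings(list(zip(temps, ratings))) == pytest.approx(
            expected, abs=1e-6
        )

    def test_linear_ratings_fall_back_to_linear_root(self):
        temps = np.linspace(42.0, 48.0, 10)
        ratings = 12.5 * (temps - 42.0)
        assert t50_from_ratings(list(zip(temps, ratings))) == pytest.approx(46.0, abs=1e-6)

    def test_rating_50_never_reached(self):
        temps = np.linspace(42.5, 48.0, 15)
        with pytest.raises(ValueError):
            t50_from_ratings([(t, 10.0) for t in temps])

    def test_constant_ratings_degenerate(self):
        with pytest.raises(ValueError):
            t50_from_ratings([(42.0, 50.0), (44.0, 50.0), (46.0, 50.0)])


class TestCompositeScore:
    def test_record_at_reference_means_scores_zero(self):
        rec = QSTRecord("s", hpt=44.5, cpt=15.0, mpt=1.8)
        assert composite_pain_sensitivity(rec, REF).score == pytest.approx(0.0)

    def test_one_sd_more_sensitive_in_each_modality(self):
        rec = QSTRecord("s", hpt=44.5 - 1.5, cpt=15.0 + 7.0, mpt=1.8 - 0.35)
        res = composite_pain_sensitivity(rec, REF)
        assert res.score == pytest.approx(1.0)
        assert res.n_modalities_used == 3

    def test_high_hpt_lowers_score(self):
        rec = QSTRecord("s", hpt=44.5 + 3.0, cpt=15.0, mpt=1.8)
        assert composite_pain_sensitivity(rec, REF).score == pytest.approx(-2 / 3)

    def test_modality_subset(self):
        rec = QSTRecord("s", hpt=44.5 - 1.5, cpt=15.0 + 7.0, mpt=1.8)
        res = composite_pain_sensitivity(rec, REF, modalities=("hpt", "cpt"))
        assert res.score == pytest.approx(1.0)
        assert res.n_modalities_used == 2

    def test_missing_modality_raises(self):
        rec = QSTRecord("s", hpt=44.5, cpt=15.0)
        with pytest.raises(ValueError, match="mpt"):
            composite_pain_sensitivity(rec, REF)

    def test_score_equals_mean_of_adjusted_z(self):
        rec = QSTRecord("s", hpt=46.1, cpt=9.3, mpt=2.2)
        res = composite_pain_sensitivity(rec, REF)
        assert res.score == pytest.approx(np.mean(list(res.z_values.values())), abs=1e-15)

    def test_affine_reunit_invariance(self):
        """z-scores are unit-free: rescaling a modality and its reference
        statistics together leaves the composite unchanged."""
        rec_c = QSTRecord("s", hpt=46.0, cpt=10.0, mpt=2.0)
        # express HPT in Fahrenheit together with its reference stats
        rec_f = QSTRecord("s", hpt=46.0 * 1.8 + 32, cpt=10.0, mpt=2.0)
        ref_f = ReferenceStats(44.5 * 1.8 + 32, 1.5 * 1.8, 15.0, 7.0, 1.8, 0.35)
        a = composite_pain_sensitivity(rec_c, REF).score
        b = composite_pain_sensitivity(rec_f, ref_f).score
        assert a == pytest.approx(b, abs=1e-12)

    def test_population_scored_against_own_reference(self, rng):
        """Scores built from a population's own reference have mean ~0 and
        the variance implied by the modality covariance (direct oracle)."""
        n = 400
        latent = rng.multivariate_normal(
            [0, 0, 0], [[1, 0.5, 0.3], [0.5, 1, 0.4], [0.3, 0.4, 1]], size=n
        )
        recs = [
            QSTRecord(f"s{i}", hpt=44.5 - 1.5 * u, cpt=15 + 7 * v, mpt=1.8 - 0.35 * w)
            for i, (u, v, w) in enumerate(latent)
        ]
        ref = ReferenceStats.from_population(recs)
        scores = np.array([composite_pain_sensitivity(r, ref).score for r in recs])
        assert abs(scores.mean()) < 1e-12
        # oracle: score = mean of 3 adjusted z-values computed directly
        z = np.column_stack(
            [
                -(np.array([r.hpt for r in recs]) - ref.hpt_mu) / ref.hpt_sd,
                (np.array([r.cpt for r in recs]) - ref.cpt_mu) / ref.cpt_sd,
                -(np.array([r.mpt for r in recs]) - ref.mpt_mu) / ref.mpt_sd,
            ]
        )
        expected_var = z.mean(axis=1).var()
        assert scores.var() == pytest.approx(expected_var, rel=1e-12)


class TestExtremeScreening:
    BOUNDS = NormativeBounds(
        bounds={"hpt": (40.0, 48.0), "cpt": (3.0, 28.0), "mpt": (1.0, 2.5)}
    )

    @pytest.mark.parametrize(
        "rec, decision, n_flags",
        [
            (QSTRecord("a", hpt=44.0, cpt=15.0, mpt=1.8), "keep", 0),
            (QSTRecord("b", hpt=49.0, cpt=15.0, mpt=1.8), "keep", 1),
            (QSTRecord("c", hpt=49.0, cpt=2.0, mpt=1.8), "exclude", 2),
            (QSTRecord("d", hpt=49.0, cpt=2.0, mpt=2.9), "exclude", 3),
        ],
    )
    def test_two_flag_rule(self, rec, decision, n_flags):
        got, flags = flag_extreme_qst(rec, self.BOUNDS)
        assert got == decision
        assert sum(flags.values()) == n_flags

    def test_unset_template_bounds_rejected(self):
        with pytest.raises(ValueError, match="unset"):
            NormativeBounds(bounds={"hpt": (None, None), "cpt": (3, 28), "mpt": (1, 2.5)})

    def test_missing_modality_bounds_rejected(self):
        rec = QSTRecord("a", hpt=44.0, cpt=15.0, mpt=1.8)
        with pytest.raises(ValueError):
            flag_extreme_qst(rec, NormativeBounds(bounds={"hpt": (40.0, 48.0)}))


def test_score_trials_table_roundtrip(small_cohort, default_reference):
    table = score_trials_table(small_cohort.qst_trials, default_reference)
    assert len(table) == len(small_cohort.subjects)
    assert {"hpt", "cpt", "mpt", "score"} <= set(table.columns)
    # thresholds recomputable by hand from the trial table
    trials = small_cohort.qst_trials
    sid = table.loc[0, "subject_id"]
    hpt_trials = trials.query("subject_id == @sid and modality == 'hpt'").sort_values(
        "trial_index"
    )["value"].to_numpy()
    assert table.loc[0, "hpt"] == pytest.approx(hpt_trials[1:].mean())
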