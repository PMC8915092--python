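import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wristhrv import (
    ArtifactRuleConfig,
    DegradationProfile,
    HeartRateSeries,
    compute_hrv_summary,
    correct_artifacts,
    detect_artifacts,
    hr_to_ibi,
    ibi_to_hr,
    make_cohort,
    select_correction_rule,
)
from wristhrv.ibi import ARTIFACT_RULES
from wristhrv.series import BeatFlag, IBISeries, SeriesValidationError

from conftest import make_series


def ibi(values, flags=None):
    values = np.asarray(values, dtype=float)
    if flags is None:
        flags = [BeatFlag.NORMAL] * values.size
    return IBISeries(intervals_ms=values, flags=flags)


class TestHrIbiConversion:
    def test_definitional_values(self):
        s = make_series([60.0, 120.0])
        out = hr_to_ibi(s)
        assert out.intervals_ms[0] == pytest.approx(1000.0)
        assert out.intervals_ms[1] == pytest.approx(500.0)

    def test_round_trip_to_machine_precision(self, hr_series):
        assert ibi_to_hr(hr_to_ibi(hr_series)) == pytest.approx(hr_series.values, rel=1e-15)

    def test_nonpositive_hr_rejected(self):
        s = make_series([-5.0, 60.0], hr_band=(-10.0, 300.0))
        with pytest.raises(SeriesValidationError, match="positive"):
            hr_to_ibi(s)


class TestDetectArtifacts:
    @pytest.mark.parametrize("rule", ARTIFACT_RULES)
    def test_constant_series_has_no_artifacts(self, rule):
        assert detect_artifacts(ibi([800.0] * 10), ArtifactRuleConfig(rule=rule)).size == 0

    def test_kamath_flags_increase_and_not_the_rebound(self):
        # 800 -> 1100 is +37.5% (> 32.5%): flagged; 800 vs accepted 800: clean
        flagged = detect_artifacts(ibi([800, 1100, 800]), ArtifactRuleConfig(rule="kamath"))
        assert list(flagged) == [1]

    def test_kamath_asymmetric_decrease_threshold(self):
        # 800 -> 620 is -22.5%, below the 24.5% decrease threshold: not flagged
        flagged = detect_artifacts(ibi([800, 620, 800]), ArtifactRuleConfig(rule="kamath"))
        assert flagged.size == 0

    def test_malik_within_20_percent_not_flagged(self):
        flagged = detect_artifacts(ibi([800, 900, 800]), ArtifactRuleConfig(rule="malik"))
        assert flagged.size == 0

    def test_malik_flags_beyond_20_percent(self):
        flagged = detect_artifacts(ibi([800, 1000, 800]), ArtifactRuleConfig(rule="malik"))
        assert list(flagged) == [1]

    def test_first_interval_never_flagged_and_karlsson_spares_last(self):
        series = ibi([800, 800, 1400, 800, 1400])
        for rule in ARTIFACT_RULES:
            flagged = detect_artifacts(series, ArtifactRuleConfig(rule=rule))
            assert 0 not in flagged
        assert 4 not in detect_artifacts(series, ArtifactRuleConfig(rule="karlsson"))

    def test_ectopic_burst_fully_flagged_against_accepted_history(self):
        # short-long ectopic pair: both deviate from the last *accepted* 800
        flagged = detect_artifacts(
            ibi([800, 800, 480, 1120, 800, 800]), ArtifactRuleConfig(rule="kamath")
        )
        assert list(flagged) == [2, 3]

    def test_acar_uses_mean_of_last_nine_accepted(self):
        vals = [800.0] * 9 + [1000.0]  # +25% vs mean 800 -> flagged at 20%
        flagged = detect_artifacts(ibi(vals), ArtifactRuleConfig(rule="acar"))
        assert list(flagged) == [9]

    def test_too_short_series_rejected(self):
        with pytest.raises(SeriesValidationError):
            detect_artifacts(ibi([800.0]), ArtifactRuleConfig(rule="malik"))


class TestCorrectArtifacts:
    def test_clean_series_is_identity(self):
        series = ibi([800.0] * 10)
        out = correct_artifacts(series, ArtifactRuleConfig(rule="kamath"))
        assert np.array_equal(out.intervals_ms, series.intervals_ms)

    def test_interior_artifact_replaced_plausibly(self):
        series = ibi([800, 1100, 800, 800, 800])
        out = correct_artifacts(series, ArtifactRuleConfig(rule="kamath"))
        assert 700 < out.intervals_ms[1] < 900
        assert out.flags[1] == BeatFlag.INTERPOLATED
        assert np.array_equal(out.intervals_ms[[0, 2, 3, 4]], [800, 800, 800, 800])

    def test_no_artifact_flags_remain_after_correction(self):
        series = ibi([800, 1100, 800, 480, 800, 800])
        out = correct_artifacts(series, ArtifactRuleConfig(rule="kamath"))
        assert out.artifact_indices.size == 0
        assert set(out.interpolated_indices) == set(
            detect_artifacts(series, ArtifactRuleConfig(rule="kamath"))
        )

    @pytest.mark.parametrize("rule", ["malik", "kamath"])
    def test_detect_correct_idempotent(self, rule):
        rng = np.random.default_rng(4)
        vals = 1000 + rng.normal(0, 30, 300)
        ect = rng.choice(np.arange(10, 290), 8, replace=False)
        vals[ect] *= 0.55
        out = correct_artifacts(ibi(vals), ArtifactRuleConfig(rule=rule))
        assert detect_artifacts(out, ArtifactRuleConfig(rule=rule)).size == 0

    def test_too_few_accepted_intervals_is_capability_error(self):
        series = ibi([800, 1400, 790, 1400, 810])
        strict = ArtifactRuleConfig(rule="malik", malik_threshold=0.001)
        with pytest.raises(SeriesValidationError, match="laxer"):
            correct_artifacts(series, strict)


class TestRuleSelection:
    def _cohort_ibis(self, rate=0.02, n=6, seed=3):
        bundle = make_cohort(n, DegradationProfile(ectopic_rate=rate), master_seed=seed)
        series = [hr_to_ibi(e["wrist"]) for e in bundle]
        refs = [e["ground_truth_hrv"] for e in bundle]
        return series, refs

    def test_perfect_match_scores_r2_of_one(self):
        bundle = make_cohort(5, DegradationProfile(), master_seed=1)
        series = [e["ground_truth_ibi"] for e in bundle]
        refs = [e["ground_truth_hrv"] for e in bundle]
        result = select_correction_rule(series, refs, rules=("kamath",))
        assert result["r2"]["kamath"] == pytest.approx(1.0)

    def test_correcting_rule_beats_inert_rule_on_ectopic_data(self):
        series, refs = self._cohort_ibis()
        # a Kamath variant with absurdly lax thresholds never flags anything
        inert = ArtifactRuleConfig(rule="kamath", kamath_increase=50.0, kamath_decrease=0.99)
        from wristhrv.ibi import compute_hrv_summary as chs, correct_artifacts as ca
        from wristhrv.stats import r_squared

        def score(config):
            vals = [chs(ca(s, config)).rmssd for s in series]
            ref = [r.rmssd for r in refs]
            return r_squared(np.array(vals), np.array(ref))

        assert score(ArtifactRuleConfig(rule="kamath")) > score(inert)

    def test_single_rule_is_returned(self):
        series, refs = self._cohort_ibis(n=3)
        assert select_correction_rule(series, refs, rules=("malik",))["best_rule"] == "malik"

    def test_fewer_than_three_subjects_warns(self):
        series, refs = self._cohort_ibis(n=2)
        with pytest.warns(UserWarning, match="unstable"):
            select_correction_rule(series, refs)


class TestHrvSummary:
    def test_constant_series_has_zero_variability(self):
        s = compute_hrv_summary(ibi([800.0, 800.0, 800.0]))
        assert s.sdnn == 0 and s.rmssd == 0 and s.pnn50 == 0

    def test_rmssd_of_symmetric_step(self):
        s = compute_hrv_summary(ibi([800.0, 850.0, 800.0]))
        assert s.rmssd == pytest.approx(50.0)

    def test_pnn50_uses_strict_inequality(self):
        assert compute_hrv_summary(ibi([800.0, 851.0, 800.0])).pnn50 == pytest.approx(100.0)
        assert compute_hrv_summary(ibi([800.0, 850.0, 800.0])).pnn50 == pytest.approx(0.0)

    def test_ten_minute_constant_recording_has_zero_sdann(self):
        n = int(10 * 60_000 / 1000)
        s = compute_hrv_summary(ibi([1000.0] * n), segment_minutes=5)
        assert s.sdann == pytest.approx(0.0)
        assert s.sdnn_index == pytest.approx(0.0)

    def test_short_recording_leaves_segment_metrics_undefined(self):
        s = compute_hrv_summary(ibi([800.0, 820.0, 790.0, 810.0]))
        assert np.isnan(s.sdann) and np.isnan(s.sdnn_index)

    def test_hr_stats_ordering(self):
        rng = np.random.default_rng(0)
        s = compute_hrv_summary(ibi(1000 + rng.normal(0, 50, 200)))
        assert s.min_hr <= s.mean_hr <= s.max_hr

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(min_value=400, max_value=1600), min_size=3, max_size=50),
        st.floats(min_value=0.5, max_value=3.0),
    )
    def test_scale_equivariance_of_ms_metrics(self, vals, c):
        base = compute_hrv_summary(ibi(vals))
        scaled = compute_hrv_summary(ibi([v * c for v in vals]))
        assert scaled.sdnn == pytest.approx(c * base.sdnn, rel=1e-9, abs=1e-9)
        assert scaled.rmssd == pytest.approx(c * base.rmssd, rel=1e-9, abs=1e-9)

    def test_pnn50_not_scale_invariant(self):
        vals = [800.0, 830.0, 800.0]  # 30 ms steps: below threshold
        assert compute_hrv_summary(ibi(vals)).pnn50 == 0.0
        # doubling pushes steps to 60 ms: above threshold
        assert compute_hrv_summary(ibi([v * 2 for v in vals])).pnn50 == 100.0

    def test_sdnn_permutation_invariant_but_rmssd_not(self):
        a = [700.0, 900.0, 750.0, 880.0, 720.0]
        b = [700.0, 750.0, 720.0, 880.0, 900.0]  # same multiset, reordered
        sa, sb = compute_hrv_summary(ibi(a)), compute_hrv_summary(ibi(b))
        assert sa.sdnn == pytest.approx(sb.sdnn)
        assert sa.rmssd != pytest.approx(sb.rmssd)

    def test_singleton_series_rejected(self):
        with pytest.raises(SeriesValidationError):
            compute_hrv_summary(ibi([800.0]))
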