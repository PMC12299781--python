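"""Mapping contracts: bands, pitch modes, frequencies, tone parameters."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from stsonify.mapping import (
    FIVE_STATE_HARMONIC_PRESET,
    MappingConfig,
    STCategory,
    categorize,
    order_leads,
    pitch_offset,
    semitone_to_frequency,
    tone_params,
)
from stsonify.synthetic_ecg import make_st_profile, STProfile

finite_st = st.floats(min_value=-1.0, max_value=1.0,
                      allow_nan=False, allow_infinity=False)


def _cfg(**kw) -> MappingConfig:
    return MappingConfig.from_dict({**MappingConfig().to_dict(), **kw})


class TestCategorize:
    @pytest.mark.parametrize("stv,expected", [
        (-0.25, STCategory.STRONG_SUPPRESSION),
        (-0.15, STCategory.MODERATE_SUPPRESSION),
        (-0.1, STCategory.ISOELECTRIC),   # isoelectric band is closed
        (0.0, STCategory.ISOELECTRIC),
        (0.1, STCategory.ISOELECTRIC),
        (0.15, STCategory.MODERATE_ELEVATION),
        (0.2, STCategory.MODERATE_ELEVATION),
        (0.25, STCategory.STRONG_ELEVATION),
    ])
    def test_band_boundaries(self, stv, expected):
        assert categorize(stv) == expected

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            categorize(float("nan"))

    @given(finite_st)
    @settings(max_examples=200, derandomize=True)
    def test_exactly_one_band_always(self, stv):
        assert categorize(stv) in STCategory


class TestPitchOffset:
    def test_continuous_endpoints_and_midpoint(self, study_config):
        cfg = _cfg(mode="continuous")
        assert pitch_offset(0.4, cfg) == pytest.approx(7.0)
        assert pitch_offset(-0.4, cfg) == pytest.approx(-7.0)
        assert pitch_offset(0.0, cfg) == pytest.approx(0.0)
        assert pitch_offset(0.2, cfg) == pytest.approx(3.5)  # 0.2/0.4 * 7

    def test_continuous_clamps_beyond_source_interval(self):
        cfg = _cfg(mode="continuous")
        assert pitch_offset(2.0, cfg) == pytest.approx(7.0)
        assert pitch_offset(-9.0, cfg) == pytest.approx(-7.0)

    @pytest.mark.parametrize("stv,expected", [
        (0.25, 7.0), (0.15, 4.0), (0.0, 0.0), (-0.15, -5.0), (-0.25, -8.0),
    ])
    def test_five_state_study_offsets(self, study_config, stv, expected):
        assert pitch_offset(stv, study_config) == expected

    def test_five_state_harmonic_preset(self):
        cfg = _cfg(five_state_offsets=FIVE_STATE_HARMONIC_PRESET)
        assert pitch_offset(-0.25, cfg) == -9.0
        assert pitch_offset(0.25, cfg) == 7.0

    @pytest.mark.parametrize("stv,expected", [
        (0.25, 8.0), (-0.25, -11.0), (0.0, 0.0),
    ])
    def test_dissonant_extremes(self, stv, expected):
        assert pitch_offset(stv, _cfg(mode="five_state_dissonant")) == expected

    @pytest.mark.parametrize("stv,expected", [
        (-0.15, -5.0), (-0.05, 0.0), (0.05, 0.0), (0.15, 7.0),
    ])
    def test_tristate(self, stv, expected):
        assert pitch_offset(stv, _cfg(mode="tristate")) == expected

    def test_diatonic_center_maps_to_zero_offset(self):
        cfg = _cfg(mode="diatonic")
        assert pitch_offset(0.0, cfg) == 0.0

    @given(finite_st)
    @settings(max_examples=300, derandomize=True)
    def test_chromatic_equals_rounded_continuous(self, stv):
        cont = pitch_offset(stv, _cfg(mode="continuous"))
        chrom = pitch_offset(stv, _cfg(mode="chromatic"))
        assert chrom == float(round(cont)) or abs(chrom - cont) <= 0.5
        assert abs(chrom - cont) <= 0.5

    @given(finite_st)
    @settings(max_examples=200, derandomize=True)
    def test_continuous_antisymmetry(self, stv):
        cfg = _cfg(mode="continuous")
        assert pitch_offset(-stv, cfg) == pytest.approx(
            -pitch_offset(stv, cfg), abs=1e-12)

    @pytest.mark.parametrize("mode", ["continuous", "chromatic", "diatonic",
                                      "five_state", "five_state_dissonant",
                                      "tristate"])
    @given(a=finite_st, b=finite_st)
    @settings(max_examples=100, derandomize=True)
    def test_monotonicity_every_mode(self, mode, a, b):
        cfg = _cfg(mode=mode)
        lo, hi = min(a, b), max(a, b)
        assert pitch_offset(lo, cfg) <= pitch_offset(hi, cfg)

    @given(finite_st)
    @settings(max_examples=200, derandomize=True)
    def test_clamping_bounds_continuous_and_chromatic(self, stv):
        assert abs(pitch_offset(stv, _cfg(mode="continuous"))) <= 7.0
        assert abs(pitch_offset(stv, _cfg(mode="chromatic"))) <= 7.0

    def test_isoelectric_category_implies_reference_frequency(
            self, study_config):
        for stv in (-0.1, -0.03, 0.0, 0.07, 0.1):
            assert categorize(stv) == STCategory.ISOELECTRIC
            k = pitch_offset(stv, study_config)
            assert k == 0.0
            assert semitone_to_frequency(k, study_config.f0) == 554.0


class TestSemitoneToFrequency:
    def test_reference_and_octave(self):
        assert semitone_to_frequency(0, 554) == 554.0
        assert semitone_to_frequency(12, 440) == pytest.approx(880.0)

    def test_fifth_above_reference(self):
        assert semitone_to_frequency(7, 554) == pytest.approx(830.07, abs=0.01)

    @given(st.floats(min_value=-24, max_value=24, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_octave_law(self, k):
        assert semitone_to_frequency(k + 12, 554) == pytest.approx(
            2 * semitone_to_frequency(k, 554))

    def test_rejects_nonpositive_f0(self):
        with pytest.raises(ValueError):
            semitone_to_frequency(0, 0.0)


class TestToneParams:
    @pytest.mark.parametrize("stv,dur,boost,n,curve", [
        (0.05, 0.050, 0.0, 2, -3.0),
        (0.15, 0.080, 5.0, 4, 3.0),
        (-0.15, 0.080, 5.0, 4, 3.0),
        (0.30, 0.100, 15.0, 4, 3.0),
        (-0.30, 0.100, 15.0, 4, 3.0),
    ])
    def test_banded_parameters(self, study_config, stv, dur, boost, n, curve):
        p = tone_params(stv, study_config)
        assert (p.duration_s, p.level_boost_db, p.n_harmonics,
                p.envelope_curve) == (dur, boost, n, curve)

    def test_final_level_combines_base_and_scaled_boost(self, study_config):
        assert tone_params(0.30, study_config).level_db == pytest.approx(-22.0)
        assert tone_params(0.15, study_config).level_db == pytest.approx(-24.0)
        assert tone_params(0.05, study_config).level_db == pytest.approx(-25.0)

    def test_rejects_non_finite(self, study_config):
        with pytest.raises(ValueError):
            tone_params(math.inf, study_config)


class TestOrderLeads:
    def test_cabrera_order_and_avr_negation(self):
        profile = make_st_profile("inferior-severe")
        seq = order_leads(profile, "cabrera")
        labels = [t.label for t in seq.limb_group]
        assert labels == ["aVL", "I", "-aVR", "II", "aVF", "III"]
        avr = seq.limb_group[2]
        assert avr.negated and avr.value == -profile["aVR"]
        assert [t.label for t in seq.precordial_group] == [
            "V1", "V2", "V3", "V4", "V5", "V6"]

    def test_cabrera_negation_flips_sign(self):
        values = make_st_profile("IE").to_dict()
        values["aVR"] = -0.2
        seq = order_leads(STProfile(values), "cabrera")
        assert seq.limb_group[2].value == pytest.approx(0.2)

    def test_counterclockwise_starts_with_unnegated_avr(self):
        profile = make_st_profile("anterior-moderate")
        seq = order_leads(profile, "counterclockwise")
        assert [t.label for t in seq.limb_group] == [
            "aVR", "III", "aVF", "II", "I", "aVL"]
        assert not seq.limb_group[0].negated
        assert seq.limb_group[0].value == profile["aVR"]

    def test_unknown_channel_mode_rejected(self):
        with pytest.raises(ValueError):
            order_leads(make_st_profile("IE"), "clockwise")


class TestMappingConfig:
    def test_defaults_are_the_study_configuration(self, study_config):
        assert study_config.mode == "five_state"
        assert study_config.five_state_offsets == (-8, -5, 0, 4, 7)
        assert study_config.f0 == 554.0
        assert study_config.dt_s == 0.120
        assert study_config.set_separation_beats == 8
        assert study_config.stride_beats == 2
        assert study_config.base_level_db == -25.0
        assert study_config.db_scale == 0.2

    def test_yaml_round_trip(self, tmp_path, study_config):
        path = tmp_path / "cfg.yaml"
        study_config.to_yaml(path)
        assert MappingConfig.from_yaml(path) == study_config

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            _cfg(mode="whale_song")
        with pytest.raises(ValueError):
            _cfg(theta1=0.3, theta2=0.2)
        with pytest.raises(ValueError):
            _cfg(five_state_offsets=(7, 4, 0, -5, -8))
        with pytest.raises(ValueError):
            _cfg(source_interval=(-0.4, 0.3))
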