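"""Calibration transforms, pattern encoding and motility indices."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dcmkit as dk
from dcmkit.errors import (
    ConfigError,
    DegenerateCalibrationError,
    InvalidGeometryError,
    MalformedWaveError,
)
from dcmkit.motility import (
    ContractionEvent,
    MotilityIndexConfig,
    MotilityPattern,
    motility_index,
    motility_index_dcm,
    summarize_wave,
)
from dcmkit.patterns import pattern_from_dict, pattern_to_dict


class TestCalibration:
    @pytest.mark.parametrize(
        "sd, expected",
        [(11.91, 4.80), (17.95, 6.87), (0.0, 0.72)],
    )
    def test_membrane_displacement_operating_points(self, sd, expected):
        assert round(dk.membrane_displacement(sd), 2) == pytest.approx(expected)

    @pytest.mark.parametrize("sd, expected", [(11.91, 25), (17.95, 60)])
    def test_occlusion_degree_operating_points(self, sd, expected):
        assert round(dk.occlusion_degree_from_syringe(sd)) == expected

    def test_occlusion_degree_root(self):
        with pytest.warns(UserWarning):  # below the in vivo calibration span
            assert dk.occlusion_degree_from_syringe(44.03 / 5.797) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "ss, expected", [(1.97, 1.55), (38.0, 12.98), (31.13, 10.80)]
    )
    def test_occlusion_velocity_operating_points(self, ss, expected):
        assert round(dk.occlusion_velocity(ss), 2) == pytest.approx(expected)

    def test_out_of_range_commands_warn_not_raise(self):
        with pytest.warns(UserWarning):
            dk.membrane_displacement(30.0)
        with pytest.warns(UserWarning):
            dk.occlusion_velocity(60.0)

    @pytest.mark.parametrize("ax, an, expected", [(3.0, 3.0, 0.0), (0.0, 2.0, 100.0), (1.0, 2.0, 50.0)])
    def test_occlusion_degree_from_areas(self, ax, an, expected):
        assert dk.occlusion_degree_from_areas(ax, an) == pytest.approx(expected)

    def test_relaxation_beyond_neutral_is_negative(self):
        assert dk.occlusion_degree_from_areas(2.2, 2.0) < 0

    def test_invalid_areas_rejected(self):
        with pytest.raises(InvalidGeometryError):
            dk.occlusion_degree_from_areas(1.0, 0.0)
        with pytest.raises(InvalidGeometryError):
            dk.occlusion_degree_from_areas(-0.1, 1.0)

    @settings(deadline=None, max_examples=50)
    @given(
        x=st.floats(min_value=0.0, max_value=28.0),
        which=st.sampled_from(["md", "od", "ov"]),
    )
    def test_inverse_forward_round_trip(self, x, which):
        forward = {
            "md": dk.membrane_displacement,
            "od": dk.occlusion_degree_from_syringe,
            "ov": dk.occlusion_velocity,
        }[which]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert dk.invert_calibration(forward(x), which) == pytest.approx(x, abs=1e-9)

    def test_inverse_of_stimulated_wave_speed(self):
        assert dk.invert_calibration(12.98, "ov") == pytest.approx(38.0, abs=0.02)

    def test_zero_slope_is_degenerate(self):
        with pytest.raises(DegenerateCalibrationError):
            dk.CalibrationMap(ov_slope=0.0)


def _event(seg, start, ov=10.0, md=5.0, od=50.0, **kw):
    return ContractionEvent(
        segment_index=seg, start_time=start, occlusion_degree=od,
        occlusion_velocity=ov, membrane_displacement=md, **kw,
    )


class TestMotilityIndices:
    def test_static_pattern_scores_zero(self, study_patterns):
        assert motility_index(study_patterns["static"]) == 0.0
        assert motility_index_dcm(study_patterns["static"]) == 0.0

    @pytest.mark.parametrize(
        "name, mi",
        [("baseline", 180.0), ("cppw_antegrade", 200.0),
         ("cppw_retrograde", 200.0), ("peg", 440.0), ("maltose", 380.0)],
    )
    def test_published_mi_values(self, study_patterns, name, mi):
        assert motility_index(study_patterns[name]) == pytest.approx(mi)

    @pytest.mark.parametrize("name, mi_dcm", [("peg", 0.085), ("maltose", 0.073)])
    def test_published_stimulated_mi_dcm(self, study_patterns, name, mi_dcm):
        assert round(motility_index_dcm(study_patterns[name]), 3) == pytest.approx(mi_dcm)

    def test_single_contraction_inside_one_interval(self):
        pattern = MotilityPattern(name="one", events=[_event(4, 5.0)])
        assert motility_index(pattern) == pytest.approx(20.0)

    def test_boundary_spanning_contraction_counts_twice(self):
        # contraction [19, 21.5] s overlaps sub-intervals 1 and 2
        pattern = MotilityPattern(name="span", events=[_event(4, 19.0, ov=2.0)])
        assert motility_index(pattern) == pytest.approx(40.0)

    def test_indices_additive_over_disjoint_event_sets(self, study_patterns):
        a = MotilityPattern(name="a", events=[_event(2, 5.0), _event(6, 30.0)])
        b = MotilityPattern(name="b", events=[_event(4, 70.0), _event(8, 110.0, ov=20.0)])
        both = a.with_events(a.events + b.events)
        assert motility_index(both) == pytest.approx(motility_index(a) + motility_index(b))
        assert motility_index_dcm(both) == pytest.approx(
            motility_index_dcm(a) + motility_index_dcm(b)
        )

    @pytest.mark.parametrize("factor", [2.0, 0.5, 3.0])
    def test_mi_dcm_homogeneous_in_velocity(self, factor):
        # events well inside sub-intervals so counting is scale-invariant
        events = [_event(2, 5.0), _event(5, 45.0), _event(9, 85.0)]
        base = MotilityPattern(name="base", events=events)
        scaled = base.with_events(
            dataclasses.replace(ev, occlusion_velocity=ev.occlusion_velocity * factor)
            for ev in events
        )
        assert motility_index_dcm(scaled) == pytest.approx(
            factor * motility_index_dcm(base)
        )

    def test_mi_dcm_ordering_across_study_patterns(self, study_patterns):
        order = ["static", "baseline", "cppw_antegrade", "maltose", "peg"]
        values = [motility_index_dcm(study_patterns[n]) for n in order]
        assert values == sorted(values)
        assert len(set(values)) == len(values)

    def test_mismatched_partition_rejected(self, study_patterns):
        cfg = MotilityIndexConfig(t_iv=25.0, k=6)
        with pytest.raises(ConfigError):
            motility_index(study_patterns["peg"], cfg)

    def test_bad_normalisation_rejected(self):
        with pytest.raises(ConfigError):
            MotilityIndexConfig(omega=0.0)


class TestWaves:
    @pytest.mark.parametrize(
        "pattern, wave_id, velocity, distance",
        [
            ("cppw_antegrade", "cppw", 3.72, 28.0),
            ("cppw_retrograde", "cppw", 3.62, 28.0),
            ("baseline", "ppw", 0.37, 8.4),
            ("peg", "a1", 4.25, 11.2),
            ("peg", "a2", 5.05, 8.4),
            ("peg", "a3", 5.26, 8.4),
            ("peg", "r1", 4.25, 11.2),
            ("peg", "r2", 5.14, 11.2),
            ("maltose", "a1", 4.76, 5.6),
            ("maltose", "a2", 5.31, 8.4),
            ("maltose", "a3", 5.54, 8.4),
            ("maltose", "r1", 6.09, 11.2),
            ("maltose", "r2", 5.54, 8.4),
        ],
    )
    def test_wave_summaries_match_published_velocities(
        self, study_patterns, pattern, wave_id, velocity, distance
    ):
        ws = summarize_wave(study_patterns[pattern], wave_id)
        assert ws.propagation_distance == pytest.approx(distance)
        assert ws.wave_velocity == pytest.approx(velocity, abs=0.005)
        assert ws.propagation_distance == pytest.approx(
            ws.n_segments_involved * study_patterns[pattern].segment_length
        )
        assert ws.wave_velocity == pytest.approx(ws.propagation_distance / ws.time_taken)

    def test_three_adjacent_segments_travel_8_4_cm(self, study_patterns):
        assert summarize_wave(study_patterns["baseline"], "ppw").propagation_distance == pytest.approx(8.4)

    def test_single_member_wave_rejected(self):
        pattern = MotilityPattern(name="w", events=[_event(3, 0.0, kind="wave_member", wave_id="w")])
        with pytest.raises(MalformedWaveError):
            summarize_wave(pattern, "w")

    def test_non_contiguous_wave_rejected(self):
        events = [
            _event(2, 0.0, kind="wave_member", wave_id="w", direction="antegrade"),
            _event(5, 1.0, kind="wave_member", wave_id="w", direction="antegrade"),
        ]
        with pytest.raises(MalformedWaveError):
            summarize_wave(MotilityPattern(name="w", events=events), "w")

    def test_too_fast_wave_rejected(self):
        with pytest.raises(MalformedWaveError):
            dk.make_wave("w", [1, 2], 0.0, 50.0, 1.0, 5.0, wave_velocity_cm_s=100.0)


class TestPatternValidation:
    def test_event_outside_cycle_rejected(self):
        with pytest.raises(ValueError):
            MotilityPattern(name="bad", events=[_event(1, 150.0)])

    def test_event_segment_outside_lumen_rejected(self):
        with pytest.raises(ValueError):
            MotilityPattern(name="bad", events=[_event(11, 0.0)])

    def test_occlusion_degree_bounds(self):
        with pytest.raises(ValueError):
            _event(1, 0.0, od=120.0)

    def test_cycles_over_protocol_duration(self, study_patterns):
        assert study_patterns["peg"].cycles_over(24.0) == 720

    def test_yaml_round_trip(self, tmp_path, study_patterns):
        src = study_patterns["maltose"]
        path = tmp_path / "maltose.yaml"
        dk.save_pattern(src, path)
        loaded = dk.load_pattern(path)
        assert loaded == src

    def test_dict_round_trip_all_patterns(self, study_patterns):
        for pattern in study_patterns.values():
            assert pattern_from_dict(pattern_to_dict(pattern)) == pattern

    def test_unknown_pattern_name(self):
        with pytest.raises(ConfigError):
            dk.load_pattern("no-such-pattern")
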