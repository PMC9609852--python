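"""Mass-balance reconstruction: per-equation oracles and pipeline properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dcmkit as dk
from dcmkit.errors import DataError
from dcmkit.reconstruction import (
    STUDY_SCHEDULE_H,
    LumenGeometry,
    SegmentalConcentrationSeries,
    cumulative_removed,
    interpolate_lumen_profile,
    lumen_mass,
    release_profile,
    sampled_mass,
    total_sampled_at_t,
)


def make_series(values_by_time, ports=(1, 3, 5, 7, 10), replicate=0):
    """Build a series from {time_h: {port: conc}} or {time_h: scalar}."""
    rows = []
    for t, v in values_by_time.items():
        for p in ports:
            conc = v if np.isscalar(v) else v[p]
            rows.append(
                {"time_h": t, "port": p, "concentration_mg_per_ml": conc, "replicate": replicate}
            )
    return SegmentalConcentrationSeries(pd.DataFrame(rows))


class TestGeometry:
    def test_default_volume_balance(self):
        g = LumenGeometry()
        assert g.total_volume == pytest.approx(100.0)
        assert 10 * 8.9 + 11.0 == pytest.approx(g.total_volume)

    def test_post_sampling_volumes_are_proportional(self):
        g = LumenGeometry()
        assert g.segment_volume_sampled == pytest.approx(0.95 * 8.9)
        assert g.flexure_volume_sampled == pytest.approx(10.45)
        total_after = g.n_segments * g.segment_volume_sampled + g.flexure_volume_sampled
        assert total_after == pytest.approx(95.0)

    def test_media_turnover_over_protocol(self):
        assert LumenGeometry().media_turnover(11) == pytest.approx(0.55)


class TestEquationOracles:
    @pytest.mark.parametrize("c, v, expected", [(0.0, 1.0, 0.0), (2.0, 1.0, 2.0), (3.07, 1.0, 3.07)])
    def test_sampled_mass(self, c, v, expected):
        assert sampled_mass(c, v) == pytest.approx(expected)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DataError):
            sampled_mass(-0.1)

    @pytest.mark.parametrize(
        "masses, expected",
        [
            ({1: 0, 3: 0, 5: 0, 7: 0, 10: 0}, 0.0),
            ({1: 2, 3: 2, 5: 2, 7: 2, 10: 2}, 10.0),
            ({1: 3.07, 3: 1.5, 5: 0.2, 7: 0.1, 10: 0.05}, 4.92),
        ],
    )
    def test_total_sampled(self, masses, expected):
        assert total_sampled_at_t(masses) == pytest.approx(expected)

    def test_missing_port_behaviour(self):
        masses = {1: 1.0, 3: 1.0, 5: 1.0, 7: 1.0}
        with pytest.raises(DataError):
            total_sampled_at_t(masses)
        with pytest.warns(UserWarning):
            assert total_sampled_at_t(masses, missing="skip") == pytest.approx(4.0)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(min_value=0, max_value=50), min_size=1, max_size=12))
    def test_cumulative_removed_is_prefix_sum(self, values):
        # brute-force prefix-sum oracle
        expected = [sum(values[: i + 1]) for i in range(len(values))]
        assert cumulative_removed(values) == pytest.approx(expected)


class TestInterpolation:
    def test_constant_field_is_exact_everywhere(self):
        seg, flex = interpolate_lumen_profile({p: 2.0 for p in (1, 3, 5, 7, 10)})
        assert seg == pytest.approx(np.full(10, 2.0))
        assert flex == pytest.approx(2.0)

    def test_midpoint_of_linear_profile(self):
        seg, _ = interpolate_lumen_profile({1: 3.0, 3: 1.0, 5: 0.0, 7: 0.0, 10: 0.0})
        assert seg[1] == pytest.approx(2.0)  # S2 midway between S1 and S3

    def test_linear_gradient_recovered_exactly(self):
        g = LumenGeometry()
        line = lambda x: 0.5 + 0.05 * x
        ports = {p: line(g.segment_centres[p - 1]) for p in g.sample_ports}
        seg, flex = interpolate_lumen_profile(ports, g)
        assert seg == pytest.approx(line(g.segment_centres))
        assert flex == pytest.approx(ports[10])

    def test_measured_ports_preserved_exactly(self):
        ports = {1: 3.1, 3: 0.4, 5: 1.7, 7: 0.9, 10: 0.2}
        seg, _ = interpolate_lumen_profile(ports)
        for p, v in ports.items():
            assert seg[p - 1] == pytest.approx(v)

    def test_single_port_cannot_interpolate(self):
        with pytest.raises(DataError):
            interpolate_lumen_profile({1: 2.0})


class TestLumenMass:
    def test_uniform_field_with_printed_volumes(self):
        # explicit printed post-sampling volumes: 10 * 8.5 * 2 + 10.45 * 2
        g = LumenGeometry(segment_volume_sampled=8.5, flexure_volume_sampled=10.45)
        assert lumen_mass(np.full(10, 2.0), 2.0, g) == pytest.approx(190.9)

    def test_zero_field(self):
        assert lumen_mass(np.zeros(10), 0.0) == pytest.approx(0.0)

    def test_wrong_length_rejected(self):
        with pytest.raises(DataError):
            lumen_mass(np.zeros(7), 0.0)


class TestReleaseProfile:
    def test_all_zero_concentrations_give_zero_release(self):
        series = make_series({t: 0.0 for t in STUDY_SCHEDULE_H})
        profile = release_profile(series)
        assert profile.released_fraction == pytest.approx(np.zeros(12))
        assert profile.monotonicity_violations == 0

    def test_uniform_concentration_closed_form(self):
        # constant 2 mg/mL at all ports: m_L = 2 * 95 = 190 mg at every time,
        # m_removed grows by 10 mg per timepoint -> M_i = 190 + 10 * (i + 1)
        series = make_series({t: 2.0 for t in STUDY_SCHEDULE_H})
        with pytest.warns(UserWarning, match="110%"):
            profile = release_profile(series)
        expected = 190.0 + 10.0 * np.arange(1, 13)
        assert profile.released_mass == pytest.approx(expected)
        assert profile.m_lumen == pytest.approx(np.full(12, 190.0))
        assert profile.m_removed == pytest.approx(10.0 * np.arange(1, 13))

    def test_linearity_in_concentration_scale(self, maltose_sim):
        series = maltose_sim.measured
        base = release_profile(series)
        scaled = release_profile(series.scaled(0.37))
        assert scaled.released_mass == pytest.approx(0.37 * base.released_mass)

    def test_replicates_aggregated_not_pooled(self):
        series = make_series({1.0: 1.0, 2.0: 2.0})
        frame2 = series.frame.copy()
        frame2["replicate"] = 1
        frame2["concentration_mg_per_ml"] *= 3.0
        both = SegmentalConcentrationSeries(pd.concat([series.frame, frame2]))
        with pytest.warns(UserWarning, match="110%"):  # 3x replicate overshoots
            profile = release_profile(both)
        p0 = release_profile(series)
        with pytest.warns(UserWarning, match="110%"):
            p1 = release_profile(both.for_replicate(1))
        assert profile.n[0] == 2
        assert profile.released_mass == pytest.approx(
            (p0.released_mass + p1.released_mass) / 2
        )
        assert profile.sd[0] > 0

    def test_sampling_correction_term_matters(self, maltose_sim):
        """Ignoring withdrawn mass underestimates cumulative release."""
        profile = release_profile(maltose_sim.measured)
        uncorrected = profile.released_mass - profile.m_removed
        truth = dk.ground_truth_release(maltose_sim).released_mass
        assert (uncorrected[-3:] < truth[-3:]).all()
        # correction removes most of the bias at the end of the run
        assert abs(profile.released_mass[-1] - truth[-1]) < abs(
            uncorrected[-1] - truth[-1]
        )
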