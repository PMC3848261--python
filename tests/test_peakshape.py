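"""Generalized logistic peak shapes, parameter solving, rendering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from isograd.errors import DomainError, InsufficientDataError
from isograd.gradient import PeakPrediction
from isograd.peakshape import (
    GLDParams,
    area_at_concentration,
    gld_density,
    render_chromatogram,
    solve_gld_params,
)


def _oracle_three_times(params):
    """Mode and half-height crossings located directly on the density."""
    mode = params.A + params.B * math.log(params.C)
    half = gld_density(params, mode) / 2.0

    def g(t):
        return gld_density(params, t) - half

    span = params.B
    while g(mode - span) > 0:
        span *= 2
    t_front = brentq(g, mode - span, mode, xtol=1e-13)
    span = params.B
    while g(mode + span) > 0:
        span *= 2
    t_tail = brentq(g, mode, mode + span, xtol=1e-13)
    return t_front, mode, t_tail


class TestDensity:
    def test_symmetric_case_value_at_mode(self):
        p = GLDParams(A=10.0, B=0.5, C=1.0)
        assert gld_density(p, 10.0) == pytest.approx(1.0 / (4 * 0.5))

    def test_symmetric_case_mirror(self):
        p = GLDParams(A=3.0, B=0.2, C=1.0)
        x = np.linspace(0.0, 2.0, 50)
        assert np.allclose(gld_density(p, 3.0 - x), gld_density(p, 3.0 + x), atol=1e-12)

    def test_far_tails_are_stable(self):
        p = GLDParams(A=0.0, B=0.01, C=2.0)
        vals = gld_density(p, np.array([-5.0, 5.0]))  # |A-t|/B = 500
        assert np.all(np.isfinite(vals)) and np.all(vals >= 0)

    @pytest.mark.parametrize(
        "params",
        [(0.0, 1.0, 1.0), (10.0, 0.2, 2.5), (5.0, 0.05, 0.1), (2.0, 2.0, 10.0)],
    )
    def test_normalized(self, params):
        p = GLDParams(*params)
        total, _ = quad(lambda t: gld_density(p, t), -np.inf, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        b=st.floats(0.05, 2.0),
        c=st.floats(0.1, 10.0),
    )
    def test_normalized_property(self, b, c):
        p = GLDParams(1.0, b, c)
        total, _ = quad(lambda t: gld_density(p, t), -np.inf, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(DomainError):
            GLDParams(0.0, -1.0, 1.0)
        with pytest.raises(DomainError):
            GLDParams(0.0, 1.0, 0.0)


class TestSolve:
    def test_symmetric_input_gives_plain_logistic(self):
        p = solve_gld_params(9.0, 10.0, 11.0)
        assert p.C == pytest.approx(1.0, abs=1e-6)
        assert p.A == pytest.approx(10.0, abs=1e-8)

    def test_roundtrip_against_density_oracle(self):
        truth = GLDParams(10.0, 0.2, 2.5)
        t_front, t_apex, t_tail = _oracle_three_times(truth)
        sol = solve_gld_params(t_front, t_apex, t_tail)
        assert sol.A == pytest.approx(truth.A, abs=1e-4)
        assert sol.B == pytest.approx(truth.B, abs=1e-4)
        assert sol.C == pytest.approx(truth.C, abs=1e-3)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(b=st.floats(0.05, 2.0), c=st.floats(0.2, 5.0))
    def test_roundtrip_property(self, b, c):
        truth = GLDParams(5.0, b, c)
        t_front, t_apex, t_tail = _oracle_three_times(truth)
        sol = solve_gld_params(t_front, t_apex, t_tail)
        assert sol.B == pytest.approx(truth.B, rel=1e-4)
        assert sol.C == pytest.approx(truth.C, rel=1e-3)

    def test_mode_and_half_heights_satisfied(self):
        sol = solve_gld_params(9.7, 10.0, 10.4)
        mode = sol.A + sol.B * math.log(sol.C)
        assert mode == pytest.approx(10.0, abs=1e-8)
        half = gld_density(sol, mode) / 2.0
        assert gld_density(sol, 9.7) == pytest.approx(half, rel=1e-8)
        assert gld_density(sol, 10.4) == pytest.approx(half, rel=1e-8)

    def test_scale_equivariance(self):
        base = solve_gld_params(9.7, 10.0, 10.4)
        s = 3.0
        wide = solve_gld_params(10.0 - s * 0.3, 10.0, 10.0 + s * 0.4)
        assert wide.B == pytest.approx(s * base.B, rel=1e-6)
        assert wide.C == pytest.approx(base.C, rel=1e-6)

    def test_unordered_times_rejected(self):
        with pytest.raises(DomainError):
            solve_gld_params(10.0, 10.0, 11.0)

    def test_oversaturated_tailing_rejected(self):
        """Tailing/fronting half-width ratios beyond the generalized
        logistic's representable range (~1.48) have no solution."""
        from isograd.errors import NoSolutionError

        with pytest.raises(NoSolutionError):
            solve_gld_params(9.7, 10.0, 10.8)  # ratio 2.67


class TestAreaLookup:
    def test_linear_midpoint(self):
        assert area_at_concentration([(2.0, 100.0), (98.0, 20.0)], 50.0) == 60.0

    def test_clamped_outside_range(self):
        table = [(2.0, 100.0), (98.0, 20.0)]
        assert area_at_concentration(table, 1.0) == 100.0
        assert area_at_concentration(table, 120.0) == 20.0

    def test_matches_piecewise_oracle(self):
        table = [(2.0, 100.0), (26.0, 85.0), (50.0, 70.0), (74.0, 55.0), (98.0, 40.0)]
        for c in (3.0, 20.0, 33.3, 61.0, 97.9):
            xs = [row[0] for row in table]
            ys = [row[1] for row in table]
            i = max(j for j in range(len(xs)) if xs[j] <= c)
            i = min(i, len(xs) - 2)
            frac = (c - xs[i]) / (xs[i + 1] - xs[i])
            oracle = ys[i] + frac * (ys[i + 1] - ys[i])
            assert area_at_concentration(table, c) == pytest.approx(oracle, abs=1e-12)

    def test_singleton_table_rejected(self):
        with pytest.raises(InsufficientDataError):
            area_at_concentration([(2.0, 100.0)], 5.0)


class TestRender:
    def test_trace_integral_equals_stretching_factors(self):
        p1 = PeakPrediction("a", 9.7, 10.0, 10.3, stretching_factor=2.0)
        p2 = PeakPrediction("b", 19.6, 20.0, 20.5, stretching_factor=3.0)
        trace = render_chromatogram([p1], grid_step=0.005, horizon=30.0)
        assert trace.integral() == pytest.approx(2.0, abs=1e-3)
        trace2 = render_chromatogram([p1, p2], grid_step=0.005, horizon=40.0)
        assert trace2.integral() == pytest.approx(5.0, abs=1e-3)

    def test_far_from_peaks_is_flat_zero(self):
        p = PeakPrediction("a", 9.9, 10.0, 10.1, stretching_factor=1.0)
        trace = render_chromatogram([p], grid_step=0.01, horizon=30.0)
        far = trace.intensities[trace.times > 20.0]
        assert np.all(far < 1e-12)

    def test_empty_peaks_rejected(self):
        with pytest.raises(DomainError):
            render_chromatogram([], 0.01, 30.0)
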