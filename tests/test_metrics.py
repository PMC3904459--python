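"""Curve metrics: flatness, range crossings, extension, comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sobpkit import (
    DepthDoseCurve,
    InputError,
    RBEParams,
    RangeUndefinedError,
    bio_range_extension,
    compare,
    compute_metrics,
    flatness,
    range_at,
    terminal_mean_rbe,
    three_way_scheme,
    two_way_scheme,
)


def brute_force_distal_crossing(curve, level):
    """Scan oracle: deepest grid point still at or above the level."""
    idx = np.nonzero(curve.values >= level)[0]
    return float(curve.depths[idx[-1]]) if idx.size else math.nan


class TestFlatness:
    def test_constant_curve_is_flat(self):
        curve = DepthDoseCurve(np.arange(20.0), np.full(20, 7.0))
        assert flatness(curve, (0.0, 19.0)) == 0.0

    def test_three_level_example(self):
        values = np.array([99.0, 100.0, 101.0] * 4)
        curve = DepthDoseCurve(np.arange(12.0), values)
        assert flatness(curve, (0.0, 11.0)) == pytest.approx(2.0)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(3)
        values = 90 + 20 * rng.random(30)
        curve = DepthDoseCurve(np.arange(30.0), values)
        base = flatness(curve, (0.0, 29.0))
        assert flatness(curve.scaled(scale), (0.0, 29.0)) == pytest.approx(
            base, rel=1e-9
        )
        assert base >= 0

    def test_sparse_region_rejected(self):
        curve = DepthDoseCurve(np.arange(20.0), np.full(20, 7.0))
        with pytest.raises(InputError):
            flatness(curve, (0.0, 5.0))


class TestRangeAt:
    def test_step_curve(self):
        depths = np.arange(0.0, 100.0, 0.5)
        values = np.where(depths <= 50.0, 100.0, 0.0)
        z = range_at(DepthDoseCurve(depths, values), 0.9, 100.0)
        assert abs(z - 50.0) <= 0.5

    def test_linear_ramp_interpolation(self):
        depths = np.arange(0.0, 70.0, 0.5)
        values = np.clip(100.0 * (60.0 - depths) / 10.0, 0.0, 100.0)
        curve = DepthDoseCurve(depths, values)
        assert range_at(curve, 0.5, 100.0) == pytest.approx(55.0, abs=1e-9)

    def test_monotone_in_fraction(self, physical_curve):
        z80 = range_at(physical_curve, 0.8, 100.0)
        z90 = range_at(physical_curve, 0.9, 100.0)
        assert z80 >= z90

    def test_no_crossing_raises(self):
        curve = DepthDoseCurve(np.arange(10.0), np.full(10, 1.0))
        with pytest.raises(RangeUndefinedError):
            range_at(curve, 0.9, 100.0)  # never reaches 90
        with pytest.raises(RangeUndefinedError):
            range_at(curve, 0.5, 1.0)  # never falls below 0.5

    @pytest.mark.parametrize("bad_fraction", [0.0, 1.0, -0.5, 2.0])
    def test_fraction_domain(self, bad_fraction):
        curve = DepthDoseCurve(np.arange(10.0), np.arange(10.0)[::-1] * 1.0)
        with pytest.raises(InputError):
            range_at(curve, bad_fraction, 10.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_scan(self, seed):
        """Interpolated crossing agrees with a grid-scan oracle to one step."""
        rng = np.random.default_rng(seed)
        step = 0.1
        depths = np.arange(0.0, 60.0, step)
        edge = rng.uniform(20.0, 50.0)
        width = rng.uniform(0.5, 5.0)
        values = 100.0 / (1.0 + np.exp((depths - edge) / width))
        curve = DepthDoseCurve(depths, values)
        fraction = rng.uniform(0.1, 0.9)
        z = range_at(curve, fraction, 100.0)
        z_oracle = brute_force_distal_crossing(curve, fraction * 100.0)
        assert abs(z - z_oracle) <= step


class TestBioRangeExtension:
    def test_zero_saturation_no_extension(self, default_beam, grid):
        params = RBEParams(saturation_fraction=0.0)
        assert bio_range_extension(default_beam, params, grid) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_default_extension_in_expected_band(self, default_beam, rbe_params,
                                                grid):
        ext = bio_range_extension(default_beam, rbe_params, grid)
        assert 0.0 < ext <= 2.0
        assert ext < 3.0

    def test_nondecreasing_in_saturation(self, default_beam, grid):
        exts = [
            bio_range_extension(
                default_beam, RBEParams(saturation_fraction=a), grid
            )
            for a in (0.0, 0.1, 0.2, 0.35)
        ]
        assert np.all(np.diff(exts) >= -1e-9)


class TestTerminalMeanRbe:
    def test_zero_saturation_gives_baseline(self, default_beam, grid):
        params = RBEParams(saturation_fraction=0.0)
        tmr = terminal_mean_rbe(default_beam, params, None, grid)
        assert tmr == pytest.approx(1.1, rel=1e-12)

    def test_unmodulated_within_model_bounds(self, default_beam, rbe_params,
                                             grid):
        tmr = terminal_mean_rbe(default_beam, rbe_params, None, grid)
        assert 1.1 < tmr < 1.485

    def test_modulation_reduces_terminal_rbe(self, default_beam, rbe_params,
                                             grid):
        unmod = terminal_mean_rbe(default_beam, rbe_params, None, grid)
        two = terminal_mean_rbe(
            default_beam, rbe_params, two_way_scheme(), grid
        )
        three = terminal_mean_rbe(
            default_beam, rbe_params, three_way_scheme(), grid
        )
        assert three <= two <= unmod
        assert two < unmod

    def test_bad_window_rejected(self, default_beam, rbe_params, grid):
        with pytest.raises(InputError):
            terminal_mean_rbe(default_beam, rbe_params, None, grid, window=0.0)


@pytest.fixture(scope="module")
def reports(default_beam, rbe_params, grid):
    unmod = compute_metrics(default_beam, rbe_params, None, grid)
    two = compute_metrics(default_beam, rbe_params, two_way_scheme(), grid)
    return unmod, two


class TestReportsAndCompare:
    def test_report_internal_consistency(self, reports):
        unmod, _ = reports
        assert unmod.range_extension == pytest.approx(
            unmod.r90_biological - unmod.r90_physical
        )
        depths = sorted(unmod.dose_beyond)
        tails = [unmod.dose_beyond[d] for d in depths]
        assert np.all(np.diff(tails) <= 1e-9)

    def test_rbe_weighting_worsens_plateau_flatness(self, reports):
        unmod, _ = reports
        assert unmod.flatness_biological > unmod.flatness_physical

    def test_compare_self_is_unchanged(self, reports):
        unmod, _ = reports
        for record in compare(unmod, unmod).values():
            assert record["flag"] == "unchanged"
            assert record["delta"] == 0.0

    def test_compare_antisymmetric(self, reports):
        unmod, two = reports
        fwd = compare(unmod, two)
        rev = compare(two, unmod)
        for key in fwd:
            assert fwd[key]["delta"] == pytest.approx(-rev[key]["delta"])

    def test_two_way_improves_terminal_rbe_and_hotspot(self, reports):
        comparison = compare(*reports)
        assert comparison["terminal_mean_rbe"]["flag"] == "improved"
        assert comparison["distal_hotspot_ratio"]["flag"] == "improved"
        assert comparison["flatness_biological"]["flag"] == "improved"
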