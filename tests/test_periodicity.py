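"""Periodicity tests: detrending against a re-coded sliding mean, sinusoid
fitting against noiseless recovery and a dense grid oracle, breakpoint
scanning, and structure assignment."""

import numpy as np
import pytest

from scanmap import (assign_structure, detrend, fill_missing, fit_segments,
                     fit_sinusoid, scan_breakpoints)
from scanmap.periodicity import ResidueSeries, SegmentFit


def series_from(values, first=31, mask=None):
    values = tuple(float(v) for v in values)
    n = len(values)
    return ResidueSeries(tuple(range(first, first + n)), values,
                         tuple(mask) if mask else (False,) * n)


def sliding_mean_subtract(values, window):
    """Independently coded truncated-window detrend (the oracle)."""
    h = window // 2
    out = []
    for i in range(len(values)):
        lo, hi = max(0, i - h), min(len(values), i + h + 1)
        out.append(values[i] - sum(values[lo:hi]) / (hi - lo))
    return out


class TestDetrend:
    def test_constant_series_corrects_to_zero(self):
        corrected = detrend(series_from([0.7] * 12), 5)
        assert all(v == 0.0 for v in corrected.values)

    def test_symmetric_window_centre(self):
        corrected = detrend(series_from([1, 2, 3, 4, 5]), 5)
        assert corrected.values[2] == pytest.approx(0.0)

    @pytest.mark.parametrize("window", [5, 7, 9, 11])
    def test_matches_independent_sliding_mean(self, window):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, 52).tolist()
        corrected = detrend(series_from(vals), window)
        np.testing.assert_allclose(corrected.values,
                                   sliding_mean_subtract(vals, window),
                                   atol=1e-12)

    def test_even_or_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            detrend(series_from([1.0] * 10), 4)
        with pytest.raises(ValueError, match="outside"):
            detrend(series_from([1.0] * 10), 11)


class TestFillMissing:
    def test_absent_positions_get_wt_value_and_flag(self):
        series = fill_missing([31, 32, 34], [0.5, 0.6, 0.7], (31, 35))
        assert series.values == (0.5, 0.6, 1.0, 0.7, 1.0)
        assert series.fill_mask == (False, False, True, False, True)

    def test_nothing_missing_is_identity(self):
        series = fill_missing([31, 32, 33], [0.1, 0.2, 0.3], (31, 33))
        assert series.values == (0.1, 0.2, 0.3)
        assert not any(series.fill_mask)

    def test_all_missing_warns_and_fills_flat(self):
        with pytest.warns(UserWarning, match="no measured positions"):
            series = fill_missing([], [], (31, 36))
        assert series.values == (1.0,) * 6


def sine(x, a, b, c):
    return a * np.sin(2 * np.pi * np.asarray(x, dtype=float) / b + c)


class TestFitSinusoid:
    def test_noiseless_recovery_is_exact(self):
        x = np.arange(45, 67)
        fit = fit_sinusoid(series_from(sine(x, 0.2, 3.6, 1.0), first=45))
        assert fit.a == pytest.approx(0.2, abs=1e-6)
        assert fit.b == pytest.approx(3.6, abs=1e-6)
        assert fit.c == pytest.approx(1.0, abs=1e-6)
        assert fit.r == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("draw", range(25))
    def test_noiseless_recovery_across_parameter_grid(self, draw):
        rng = np.random.default_rng(100 + draw)
        a = rng.uniform(0.05, 0.5)
        b = rng.uniform(2.0, 8.0)
        c = rng.uniform(0.0, 2 * np.pi)
        x = np.arange(31, 53)
        fit = fit_sinusoid(series_from(sine(x, a, b, c), first=31))
        assert fit.a == pytest.approx(a, abs=1e-6)
        assert fit.b == pytest.approx(b, abs=1e-6)
        # phase compared on the circle
        dc = (fit.c - c + np.pi) % (2 * np.pi) - np.pi
        assert abs(dc) < 1e-6

    def test_phase_wrap_equivalence(self):
        x = np.arange(45, 67)
        f1 = fit_sinusoid(series_from(sine(x, 0.3, 3.5, 0.7), first=45))
        f2 = fit_sinusoid(series_from(sine(x, 0.3, 3.5, 0.7 + 2 * np.pi), first=45))
        assert f1.sse == pytest.approx(f2.sse, abs=1e-12)
        assert f1.b == pytest.approx(f2.b, abs=1e-9)

    def test_amplitude_reported_nonnegative(self):
        x = np.arange(31, 43)
        fit = fit_sinusoid(series_from(-sine(x, 0.2, 4.0, 0.3), first=31))
        assert fit.a >= 0
        assert fit.sse < 1e-12

    def test_sse_beats_dense_grid_oracle(self):
        rng = np.random.default_rng(13)
        x = np.arange(45, 67)
        y = sine(x, 0.25, 3.6, 1.2) + rng.normal(0, 0.05, x.size)
        fit = fit_sinusoid(series_from(y, first=45))
        # dense (b, c) grid with amplitude solved in closed form per point
        best = np.inf
        cs = np.arange(0, 2 * np.pi, 2 * np.pi / 180)
        for b in np.arange(2.0, 8.0, 0.005):
            basis = np.sin(2 * np.pi * x[None, :] / b + cs[:, None])
            denom = np.sum(basis * basis, axis=1)
            a = (basis @ y) / denom
            sse = np.sum((y[None, :] - a[:, None] * basis) ** 2, axis=1)
            best = min(best, float(sse.min()))
        assert fit.sse <= best + 1e-6

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            fit_sinusoid(series_from([0.1, -0.1, 0.1, -0.1, 0.1]))


class TestFitSegments:
    def test_pure_sinusoid_single_fit_r_one(self):
        x = np.arange(31, 83)
        fits, whole = fit_segments(series_from(sine(x, 0.2, 3.6, 0.5)), ())
        assert len(fits) == 1
        assert whole.r == pytest.approx(1.0, abs=1e-9)

    def test_phase_jump_split_beats_global_fit(self):
        x1 = np.arange(31, 45)
        x2 = np.arange(45, 67)
        y = np.concatenate([sine(x1, 0.25, 3.6, 0.2),
                            sine(x2, 0.25, 3.6, 0.2 + np.pi)])
        series = series_from(y, first=31)
        fits, whole = fit_segments(series, (45,))
        assert sum(f.sse for f in fits) < whole.sse

    def test_segment_boundaries(self):
        x = np.arange(31, 83)
        fits, _ = fit_segments(series_from(sine(x, 0.2, 3.6, 0.5)), (45, 67))
        assert [f.segment for f in fits] == [(31, 44), (45, 66), (67, 82)]

    def test_too_short_segment_rejected(self):
        x = np.arange(31, 83)
        with pytest.raises(ValueError, match="shorter"):
            fit_segments(series_from(sine(x, 0.2, 3.6, 0.5)), (34,))


class TestScanBreakpoints:
    def test_recovers_phase_change_within_one_residue(self):
        rng = np.random.default_rng(21)
        x1 = np.arange(31, 50)
        x2 = np.arange(50, 70)
        y = np.concatenate([sine(x1, 0.3, 3.6, 0.1),
                            sine(x2, 0.3, 3.6, 0.1 + np.pi)])
        y = y + rng.normal(0, 0.02, y.size)
        bps, fits = scan_breakpoints(series_from(y, first=31), n_breaks=1)
        assert len(bps) == 1
        assert abs(bps[0] - 50) <= 1

    def test_pure_sinusoid_prefers_no_breakpoints(self):
        x = np.arange(31, 83)
        bps, fits = scan_breakpoints(series_from(sine(x, 0.3, 3.6, 0.4)),
                                     n_breaks=2)
        assert bps == ()
        assert len(fits) == 1


@pytest.mark.parametrize("b, label", [
    (3.49, "alpha-helix"),
    (3.28, "alpha-helix"),
    (3.6, "alpha-helix"),
    (2.0, "strand-like"),
    (5.5, "irregular/ambiguous"),
])
def test_structure_assignment_from_periodicity(b, label):
    fit = SegmentFit(segment=(31, 44), a=0.2, b=b, c=0.0, r=0.9, sse=0.1)
    assert assign_structure(fit)["label"] == label
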