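import numpy as np
import pytest

from clicklabel import (
    Chromatogram,
    build_kinetic_trace,
    detect_and_integrate,
    fit_rate_constant,
    fraction_conjugated,
    fraction_reacted,
    gen_chromatogram_series,
)
from clicklabel.chromatogram import Peak, PeakSet


def gaussian_trace(apex=8.8, sigma=0.15, height=1.0):
    rt = np.arange(0.0, 20.0, 0.01)
    return Chromatogram(rt=rt, signal=height * np.exp(-0.5 * ((rt - apex) / sigma) ** 2))


class TestDetectAndIntegrate:
    def test_single_gaussian_area(self):
        ps = detect_and_integrate(gaussian_trace(), expected_rts=[8.8])
        peak = ps.by_label("conjugate")
        assert peak.rt_apex == pytest.approx(8.8, abs=0.02)
        # analytic Gaussian area: h * sigma * sqrt(2 pi)
        assert peak.area == pytest.approx(0.15 * np.sqrt(2 * np.pi), rel=0.01)

    def test_flat_trace_zero_areas(self):
        rt = np.arange(0.0, 20.0, 0.01)
        ps = detect_and_integrate(Chromatogram(rt=rt, signal=np.zeros_like(rt)))
        assert all(p.area == 0.0 for p in ps.peaks)

    def test_synthetic_two_peak_recovery(self, fig2_clean):
        series = gen_chromatogram_series(fig2_clean, total_area=1.0)
        for chrom in series:
            f = fraction_reacted(chrom.timestamp, fig2_clean.rc)
            ps = detect_and_integrate(chrom)
            assert ps.by_label("conjugate").area == pytest.approx(f, abs=0.02)
            assert ps.by_label("free_dye").area == pytest.approx(1 - f, abs=0.02)

    def test_dye_conservation_over_series(self, fig2_clean):
        series = gen_chromatogram_series(fig2_clean, total_area=1.0)
        totals = []
        for chrom in series:
            ps = detect_and_integrate(chrom)
            totals.append(ps.by_label("conjugate").area + ps.by_label("free_dye").area)
        assert np.ptp(totals) / np.mean(totals) < 0.02

    def test_bad_window(self):
        with pytest.raises(ValueError):
            detect_and_integrate(gaussian_trace(), window=0.0)


class TestFractionConjugated:
    @pytest.mark.parametrize("areas, expect", [((1.0, 1.0), 0.5), ((3.0, 1.0), 0.75)])
    def test_arithmetic(self, areas, expect):
        ps = PeakSet(
            peaks=(
                Peak(8.8, 1.0, areas[0], "conjugate"),
                Peak(16.5, 1.0, areas[1], "free_dye"),
            )
        )
        assert fraction_conjugated(ps) == expect

    def test_all_zero_undefined(self):
        ps = PeakSet(
            peaks=(Peak(8.8, 0, 0.0, "conjugate"), Peak(16.5, 0, 0.0, "free_dye"))
        )
        with pytest.raises(ValueError):
            fraction_conjugated(ps)

    def test_late_timepoint_nearly_all_conjugated(self, fig2_clean):
        series = gen_chromatogram_series(fig2_clean)
        at_267min = next(c for c in series if c.timestamp == 267 * 60.0)
        f = fraction_conjugated(detect_and_integrate(at_267min))
        assert f == pytest.approx(0.976, abs=0.01)  # only trace free dye left


class TestBuildKineticTrace:
    def test_fractions_follow_rate_law(self, fig2_clean):
        series = gen_chromatogram_series(fig2_clean)
        trace = build_kinetic_trace(series)
        expected = [
            fraction_reacted(t, fig2_clean.rc) for t in fig2_clean.timepoints
        ]  # {0.091, 0.604, 0.976, 1.000}
        assert np.allclose(trace.fraction_reacted, expected, atol=0.01)
        assert trace.fraction_reacted[0] == pytest.approx(0.0906, abs=0.01)

    def test_nondecreasing_over_series(self, fig2_clean):
        trace = build_kinetic_trace(gen_chromatogram_series(fig2_clean))
        assert np.all(np.diff(trace.fraction_reacted) >= 0)

    def test_order_invariance(self, fig2_clean):
        series = gen_chromatogram_series(fig2_clean)
        fwd = build_kinetic_trace(series)
        rev = build_kinetic_trace(series[::-1])
        assert fwd == rev

    def test_single_chromatogram_rejected(self, fig2_clean):
        with pytest.raises(ValueError):
            build_kinetic_trace(gen_chromatogram_series(fig2_clean)[:1])

    def test_duplicate_timestamps_rejected(self, fig2_clean):
        series = gen_chromatogram_series(fig2_clean)
        with pytest.raises(ValueError, match="duplicate"):
            build_kinetic_trace([series[0], series[0]])

    def test_height_mode_normalized_to_plateau(self, fig2_clean):
        trace = build_kinetic_trace(
            gen_chromatogram_series(fig2_clean), mode="height"
        )
        assert trace.fraction_reacted[-1] == pytest.approx(1.0)
        assert np.all(np.diff(trace.fraction_reacted) >= 0)

    def test_end_to_end_rate_recovery(self, fig2_clean):
        """Chromatogram series -> trace -> fit recovers the generating K."""
        trace = build_kinetic_trace(gen_chromatogram_series(fig2_clean))
        fit = fit_rate_constant(trace, a0=fig2_clean.rc.a0, b0=fig2_clean.rc.b0)
        assert fit.k_hat == pytest.approx(4.31, rel=0.05)
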