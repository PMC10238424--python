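import numpy as np
import pytest

from clicklabel import (
    CorrelationCurve,
    FcsComponent,
    FcsFit,
    brightness,
    fit_curve,
    g_model,
    gen_fcs_curve,
    tau_d_scale,
)
from clicklabel.fcs import FREE_DYE_TAU_D, IdentifiabilityWarning

CONJ_TAU = 133e-6  # ~150 kDa conjugate


def single(n=5.0, tau=130e-6, s=5.0):
    return FcsFit(n=n, components=(FcsComponent(tau, 1.0),), s=s)


class TestGModel:
    def test_zero_lag_amplitude(self):
        fit = single(n=5.0)
        assert g_model(fit.components[0].tau_d / 1000, fit) == pytest.approx(
            1 / 5.0, rel=0.01
        )

    def test_half_amplitude_at_tau_d_in_2d_limit(self):
        fit = single(n=2.0, s=1e6)
        assert g_model(fit.components[0].tau_d, fit) == pytest.approx(
            1 / (2 * 2.0), rel=1e-3
        )

    def test_two_component_additivity(self):
        taus = np.logspace(-6, 0, 30)
        a = single(n=1.0, tau=25e-6)
        b = single(n=1.0, tau=25e-6 * 5.3)
        mix = FcsFit(
            n=1.0,
            components=(FcsComponent(25e-6, 0.5), FcsComponent(25e-6 * 5.3, 0.5)),
        )
        assert np.allclose(
            g_model(taus, mix), 0.5 * g_model(taus, a) + 0.5 * g_model(taus, b)
        )

    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            FcsFit(n=1.0, components=(FcsComponent(25e-6, 0.4),))


class TestFitCurve:
    def test_single_component_noiseless_roundtrip(self):
        curve = gen_fcs_curve([FcsComponent(130e-6, 1.0)], n=5.0)
        fit = fit_curve(curve, n_components=1)
        assert fit.n == pytest.approx(5.0, rel=1e-4)
        assert fit.components[0].tau_d == pytest.approx(130e-6, rel=1e-4)

    def test_free_dye_fraction_recovered(self):
        """Day-100-style stability check: 15% free dye, fixed fast tau."""
        curve = gen_fcs_curve(
            [FcsComponent(FREE_DYE_TAU_D, 0.15), FcsComponent(CONJ_TAU, 0.85)],
            n=5.0,
            noise_rel=0.01,
            seed=13,
        )
        fit = fit_curve(curve, n_components=2, fixed_tau_free=FREE_DYE_TAU_D)
        assert fit.components[0].fraction == pytest.approx(0.15, abs=0.03)

    def test_close_diffusion_times_warn(self):
        curve = gen_fcs_curve(
            [FcsComponent(100e-6, 0.5), FcsComponent(120e-6, 0.5)], n=5.0
        )
        with pytest.warns(IdentifiabilityWarning):
            fit_curve(curve, n_components=2, fixed_tau_free=100e-6)

    def test_insufficient_lag_span_rejected(self):
        lags = np.logspace(-5, -4, 25)
        curve = CorrelationCurve(lags=lags, g=np.ones_like(lags))
        with pytest.raises(ValueError, match="decades"):
            fit_curve(curve)


class TestBrightness:
    def test_cpm_arithmetic(self):
        curve = gen_fcs_curve(
            [FcsComponent(130e-6, 1.0)], n=5.0, mean_intensity=10_000.0
        )
        fit = fit_curve(curve)
        assert brightness(curve, fit) == pytest.approx(2_000.0, rel=1e-3)
        assert fit.cpm == pytest.approx(2_000.0, rel=1e-3)

    def test_missing_intensity_rejected(self):
        curve = gen_fcs_curve([FcsComponent(130e-6, 1.0)], n=5.0)
        with pytest.raises(ValueError, match="mean_intensity"):
            brightness(curve, fit_curve(curve))

    def test_conjugate_to_dye_brightness_ratio(self):
        """A conjugate generated 2x brighter per molecule reads out as 2.0."""
        cpm_dye = 1_000.0
        n = 5.0
        dye = gen_fcs_curve(
            [FcsComponent(FREE_DYE_TAU_D, 1.0)], n=n, mean_intensity=cpm_dye * n
        )
        conj = gen_fcs_curve(
            [FcsComponent(CONJ_TAU, 1.0)], n=n, mean_intensity=2.0 * cpm_dye * n
        )
        ratio = brightness(conj, fit_curve(conj)) / brightness(dye, fit_curve(dye))
        assert ratio == pytest.approx(2.0, rel=0.05)

    @pytest.mark.parametrize("adol, ratio", [(2, 2.0), (4, 2.5), (6, 2.8), (8, 3.0)])
    def test_self_quenching_ratio_recovery(self, adol, ratio):
        """Generated sublinear brightness-vs-aDoL ratios are recovered.

        Anchors: 2x at aDoL 2 and 3x at aDoL 8; interior points follow the
        generator's quenching table.
        """
        cpm_dye = 1_000.0
        conj = gen_fcs_curve(
            [FcsComponent(CONJ_TAU, 1.0)],
            n=5.0,
            mean_intensity=ratio * cpm_dye * 5.0,
            noise_rel=0.01,
            seed=adol,
        )
        got = brightness(conj, fit_curve(conj)) / cpm_dye
        assert got == pytest.approx(ratio, rel=0.05)


class TestTauDScale:
    def test_identity(self):
        assert tau_d_scale(1000.0, 1000.0, 25e-6) == 25e-6

    def test_antibody_vs_free_dye(self):
        # (150 kDa / 1 kDa)^(1/3) = 5.31 => 25 us -> 133 us
        assert tau_d_scale(150_000.0, 1000.0, 25e-6) == pytest.approx(
            133e-6, rel=0.005
        )

    def test_monotone_in_mw(self):
        taus = [tau_d_scale(mw, 1000.0, 25e-6) for mw in (1e3, 1e4, 1e5, 1e6)]
        assert taus == sorted(taus)
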