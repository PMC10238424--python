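import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from clicklabel import (
    KineticTrace,
    ReactionConditions,
    completion_check,
    fit_rate_constant,
    fraction_reacted,
    time_to_fraction,
)


def ode_fraction(t, a0, b0, k):
    """Independent oracle: integrate dx/dt = K(a0-x)(b0-x) numerically."""
    if t == 0:
        return 0.0
    sol = solve_ivp(
        lambda _, x: k * (a0 - x[0]) * (b0 - x[0]),
        (0.0, t),
        [0.0],
        rtol=1e-10,
        atol=1e-16,
    )
    return sol.y[0, -1] / b0


class TestFractionReacted:
    def test_zero_time(self, fig2_conditions):
        assert fraction_reacted(0.0, fig2_conditions) == 0.0

    def test_reference_milestone_55min(self, fig2_conditions):
        # > 50% of the dye attached by 55 min under the monitoring conditions
        assert fraction_reacted(3300.0, fig2_conditions) == pytest.approx(
            0.604, abs=5e-4
        )

    def test_minimum_concentration_24h(self):
        rc = ReactionConditions(a0=25e-6, b0=10e-6, k=4.31)
        assert fraction_reacted(86400.0, rc) == pytest.approx(0.9978, abs=5e-4)

    def test_equal_concentration_closed_form(self):
        rc = ReactionConditions(a0=10e-6, b0=10e-6, k=4.31)
        # Kt[A]0/(1+Kt[A]0) at 24 h
        assert fraction_reacted(86400.0, rc) == pytest.approx(0.788, abs=5e-4)

    def test_negative_time_rejected(self, fig2_conditions):
        with pytest.raises(ValueError):
            fraction_reacted(-1.0, fig2_conditions)

    @pytest.mark.parametrize("a0_uM", [25.0, 74.67])
    @pytest.mark.parametrize("b0_uM", [10.0, 26.67, 100.0])
    @pytest.mark.parametrize("k", [0.5, 4.31, 20.0])
    def test_agrees_with_ode_oracle(self, a0_uM, b0_uM, k):
        rc = ReactionConditions(a0=a0_uM * 1e-6, b0=b0_uM * 1e-6, k=k)
        for t in np.logspace(1, 5, 9):
            assert fraction_reacted(t, rc) == pytest.approx(
                ode_fraction(t, rc.a0, rc.b0, k), abs=1e-6
            )

    def test_monotone_in_time_and_rate(self):
        ts = np.logspace(0, 6, 60)
        for k in (0.5, 4.31, 20.0):
            rc = ReactionConditions(a0=74.67e-6, b0=26.67e-6, k=k)
            f = fraction_reacted(ts, rc)
            assert np.all(np.diff(f) >= 0)
        f_by_k = [
            fraction_reacted(3300.0, ReactionConditions(74.67e-6, 26.67e-6, k))
            for k in (0.5, 4.31, 20.0)
        ]
        assert f_by_k == sorted(f_by_k)

    @pytest.mark.parametrize("a0_uM, b0_uM", [(25.0, 10.0), (10.0, 25.0)])
    def test_long_time_asymptote(self, a0_uM, b0_uM):
        rc = ReactionConditions(a0=a0_uM * 1e-6, b0=b0_uM * 1e-6, k=4.31)
        assert fraction_reacted(1e9, rc) == pytest.approx(rc.max_fraction, abs=1e-6)

    def test_long_time_asymptote_equal_concentrations(self):
        # equal concentrations converge algebraically: f = 1 - 1/(1+Kta0)
        rc = ReactionConditions(a0=30e-6, b0=30e-6, k=4.31)
        assert fraction_reacted(1e9, rc) == pytest.approx(1.0, abs=1e-5)


class TestTimeToFraction:
    def test_completion_time_25_10(self):
        rc = ReactionConditions(a0=25e-6, b0=10e-6, k=4.31)
        t99 = time_to_fraction(0.99, rc)
        assert t99 == pytest.approx(63_434, rel=1e-3)  # ~17.6 h, under 24 h
        assert t99 < 86_400

    @settings(deadline=None, derandomize=True)
    @given(
        f=st.floats(1e-6, 0.99),
        a0=st.floats(5e-6, 200e-6),
        ratio=st.floats(0.3, 5.0),
        k=st.floats(0.1, 50.0),
    )
    def test_roundtrip_identity(self, f, a0, ratio, k):
        rc = ReactionConditions(a0=a0, b0=a0 * ratio, k=k)
        if f >= rc.max_fraction:
            return
        t = time_to_fraction(f, rc)
        assert fraction_reacted(t, rc) == pytest.approx(f, rel=1e-9, abs=1e-12)

    def test_small_fraction_limit(self, fig2_conditions):
        assert time_to_fraction(1e-9, fig2_conditions) < 1e-2

    def test_unattainable_fraction_with_dye_excess(self):
        rc = ReactionConditions(a0=10e-6, b0=25e-6, k=4.31)  # max 0.4
        with pytest.raises(ValueError, match="not attainable"):
            time_to_fraction(0.5, rc)


class TestFitRateConstant:
    def _trace(self, rc, n=12, noise=0.0, seed=0):
        tmax = time_to_fraction(0.99, rc)
        ts = np.linspace(tmax / (2 * n), tmax, n)
        f = fraction_reacted(ts, rc)
        if noise:
            rng = np.random.default_rng(seed)
            f = np.clip(f * (1 + noise * rng.standard_normal(n)), 0, 1)
        return KineticTrace(ts, f)

    def test_noiseless_recovery_exact(self, fig2_conditions):
        rc = fig2_conditions
        fit = fit_rate_constant(self._trace(rc), rc.a0, rc.b0)
        assert fit.k_hat == pytest.approx(4.31, rel=1e-6)
        assert fit.k_stderr >= 0
        assert fit.residual_rms < 1e-9

    def test_noisy_recovery_within_5pct(self, fig2_conditions):
        rc = fig2_conditions
        fit = fit_rate_constant(self._trace(rc, noise=0.02, seed=11), rc.a0, rc.b0)
        assert fit.k_hat == pytest.approx(4.31, rel=0.05)

    def test_degenerate_traces_rejected(self, fig2_conditions):
        rc = fig2_conditions
        with pytest.raises(ValueError, match="degenerate"):
            fit_rate_constant(
                KineticTrace([1.0, 2.0, 3.0], [0.0, 0.0, 0.0]), rc.a0, rc.b0
            )
        with pytest.raises(ValueError, match="at least 3"):
            fit_rate_constant(KineticTrace([1.0, 2.0], [0.1, 0.2]), rc.a0, rc.b0)


class TestCompletionCheck:
    def test_minimum_concentrations_complete_at_24h(self):
        rc = ReactionConditions(a0=25e-6, b0=10e-6, k=4.31)
        rep = completion_check(rc, 86400.0, threshold=0.99)
        assert rep.complete and rep.fraction == pytest.approx(0.9978, abs=5e-4)
        assert rep.warnings == ()

    def test_below_minimum_concentrations_warn(self):
        rc = ReactionConditions(a0=5e-6, b0=2e-6, k=4.31)
        rep = completion_check(rc, 86400.0, threshold=0.99)
        assert any("10 uM" in w for w in rep.warnings)
        assert any("25 uM" in w for w in rep.warnings)

    def test_dye_excess_warns(self):
        rc = ReactionConditions(a0=25e-6, b0=50e-6, k=4.31)
        rep = completion_check(rc, 86400.0)
        assert any("dye excess" in w for w in rep.warnings)
        assert not rep.complete

    def test_bad_threshold(self, fig2_conditions):
        with pytest.raises(ValueError):
            completion_check(fig2_conditions, 3600.0, threshold=1.5)
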