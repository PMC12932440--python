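"""Integration accuracy, fixed-point preservation, and trajectory regimes."""
import numpy as np
import pytest

import osteomeno as om
from osteomeno.model import STATE_VARS, EstrogenModel, rhs
from osteomeno.parameters import DAYS_PER_YEAR
from osteomeno.simulation import SimulationConfig, sensitivity_envelope, simulate


def _component(traj, name):
    return traj.component(name)


class TestIntegrationAccuracy:
    def test_constant_estrogen_preserves_equilibrium_60_years(self, p):
        e = EstrogenModel.constant(1.0)
        traj = simulate(p, None, e)
        y0 = om.premenopausal_steady_state(p).state.as_array()
        # six cell/signal species stay on the fixed point for 60 years
        for i, name in enumerate(STATE_VARS[:6]):
            np.testing.assert_allclose(
                traj.states[:, i], y0[i], rtol=1e-6,
                err_msg=f"{name} drifted off its equilibrium",
            )
        # density drifts linearly at the constant formation/resorption gap
        drift = rhs(0.0, y0, p, None, e)[STATE_VARS.index("Bd")]
        expected = 1.0 + drift * (traj.times - traj.times[0])
        np.testing.assert_allclose(_component(traj, "Bd"), expected, rtol=1e-5)

    def test_adaptive_solution_matches_fixed_step_rk4(self, p, s_short):
        """Independent fixed-step RK4 oracle over 5 years post-onset."""
        e = EstrogenModel.surgical(p.t_m, s_short.kappa_E, s_short.k_syn)
        horizon = p.t_m + 5 * DAYS_PER_YEAR
        traj = simulate(p, s_short, e, SimulationConfig(t_end=horizon))
        i_m = int(np.argmin(np.abs(traj.times - p.t_m)))
        y = traj.states[i_m].copy()

        h = 0.25
        n_steps = int(round((horizon - p.t_m) / h))

        def f(t, y):
            return rhs(t, y, p, s_short, e, post_branch_at_onset=True)

        t = p.t_m
        for _ in range(n_steps):
            k1 = f(t, y)
            k2 = f(t + h / 2, y + h / 2 * k1)
            k3 = f(t + h / 2, y + h / 2 * k2)
            k4 = f(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h

        y_adaptive = traj.states[-1]
        rel = np.abs(y - y_adaptive) / np.maximum(np.abs(y_adaptive), 1.0)
        assert rel.max() < 1e-5

    def test_halving_tolerances_changes_endpoint_below_1e6(self, p, s_long):
        e = EstrogenModel.surgical(p.t_m, s_long.kappa_E, s_long.k_syn)
        r1 = simulate(p, s_long, e).relative_bmd[-1]
        tight = SimulationConfig(abs_tol=5e-9, rel_tol=5e-9)
        r2 = simulate(p, s_long, e, tight).relative_bmd[-1]
        assert abs(r1 - r2) < 1e-6


class TestTrajectoryContainer:
    def test_normalization_at_onset_is_exact(self, traj_short):
        assert traj_short.relative_at(0.0) == pytest.approx(1.0, abs=1e-12)
        i_m = int(np.argmin(np.abs(traj_short.times - traj_short.t_m)))
        assert traj_short.relative_bmd[i_m] == 1.0

    def test_interpolation_reproduces_grid_and_stays_local(self, traj_short):
        yrs = traj_short.years_since_onset()
        np.testing.assert_allclose(
            traj_short.relative_at(yrs[::7]), traj_short.relative_bmd[::7],
            rtol=1e-12,
        )
        # interpolant between neighboring grid points stays in their range
        for k in (400, 500, 610):
            mid = 0.5 * (yrs[k] + yrs[k + 1])
            lo, hi = sorted(
                (traj_short.relative_bmd[k], traj_short.relative_bmd[k + 1])
            )
            assert lo - 1e-12 <= traj_short.relative_at(mid) <= hi + 1e-12

    def test_extrapolation_rejected(self, traj_short):
        with pytest.raises(om.DomainError):
            traj_short.relative_at(31.0)
        with pytest.raises(om.DomainError):
            traj_short.relative_at(-31.0)

    def test_times_increasing_and_cells_nonnegative(
        self, traj_nat, traj_short, traj_long
    ):
        for traj in (traj_nat, traj_short, traj_long):
            assert np.all(np.diff(traj.times) > 0)
            assert (traj.states[:, :6] >= 0).all()

    def test_invalid_config_rejected(self, p):
        with pytest.raises(om.DomainError):
            SimulationConfig(t_start=p.t_m + 1.0).resolve(p.t_m)
        with pytest.raises(om.DomainError):
            SimulationConfig(abs_tol=-1.0).resolve(p.t_m)
        with pytest.raises(om.DomainError):
            SimulationConfig(output_grid=np.array([3.0, 2.0, 1.0])).resolve(2.5)


class TestMenopauseRegimes:
    def test_sudden_estrogen_loss_accelerates_early_density_loss(
        self, traj_nat, traj_zero
    ):
        """Abrupt estrogen loss alone outpaces natural decline early on."""
        yrs = traj_nat.years_since_onset()
        for horizon in (1.0, 2.0, 5.0):
            i0 = int(np.argmin(np.abs(yrs)))
            ih = int(np.argmin(np.abs(yrs - horizon)))
            drop_nat = traj_nat.component("Bd")[i0] - traj_nat.component("Bd")[ih]
            drop_surg = traj_zero.component("Bd")[i0] - traj_zero.component("Bd")[ih]
            assert drop_surg > drop_nat

    def test_short_term_osteocytes_dip_and_recover(self, traj_short):
        yrs = traj_short.years_since_onset()
        S = traj_short.component("S")
        S0 = S[int(np.argmin(np.abs(yrs)))]
        post = S[yrs >= 0]
        assert post.min() / S0 < 0.96          # a clear dip...
        assert post[-1] / S0 > 0.97            # ...that recovers
        assert post[-1] > post.min()

    def test_long_term_osteocytes_decline_permanently_to_about_80pct(
        self, traj_long
    ):
        yrs = traj_long.years_since_onset()
        S = traj_long.component("S")
        S0 = S[int(np.argmin(np.abs(yrs)))]
        s25 = S[int(np.argmin(np.abs(yrs - 25)))] / S0
        assert 0.70 < s25 < 0.85
        # still declining at the end of the window: no recovery
        assert S[-1] <= S[int(np.argmin(np.abs(yrs - 20)))]

    def test_no_new_effects_overshoots_late_density_loss(
        self, traj_zero, traj_short, traj_long
    ):
        assert traj_zero.component("Bd")[-1] < traj_short.component("Bd")[-1]
        assert traj_zero.component("Bd")[-1] < traj_long.component("Bd")[-1]

    def test_long_term_density_loss_slows_late(self, traj_zero, traj_long):
        """The permanent osteocyte deficit damps sclerostin and slows loss."""
        yrs = traj_long.years_since_onset()
        late = yrs >= 25
        def rate(traj):
            return np.polyfit(yrs[late], traj.component("Bd")[late], 1)[0]
        assert rate(traj_long) > rate(traj_zero)


class TestSensitivityEnvelope:
    def test_zero_fraction_reproduces_nominal(self, p, s_short, e_surg):
        env = sensitivity_envelope(p, s_short, e_surg, fraction=0.0)
        np.testing.assert_array_equal(env.upper.states, env.nominal.states)
        np.testing.assert_array_equal(env.lower.states, env.nominal.states)

    def test_tau_zero_stays_zero(self, p, s_long, e_surg):
        env = sensitivity_envelope(p, s_long, e_surg, fraction=0.25)
        # both members keep the permanent effect; they differ via the folds
        assert not np.allclose(env.upper.states, env.lower.states)

    def test_envelope_width_small_early_large_late(self, p, s_short, e_surg):
        env = sensitivity_envelope(p, s_short, e_surg, fraction=0.25)
        yrs = env.nominal.years_since_onset()
        width = np.abs(env.upper.component("Bd") - env.lower.component("Bd"))
        early = width[(yrs > 0) & (yrs <= 2)].max()
        late = width[yrs >= 10].max()
        assert early < 0.2 * late
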