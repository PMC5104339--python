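"""ODE core: derivative identities, event handling, and structural limits."""

import numpy as np
import pytest

from icpkpd.model import (IntegrationError, Trajectory, initial_state, integrate,
                          interval_extrema, rhs, steady_state_profile)
from icpkpd.regimen import DoseEvent, Regimen


class TestRhsIdentities:
    def test_drug_free_equilibrium(self, tfv):
        """With no drug anywhere and dNTPs at baseline, nothing moves."""
        y = initial_state(tfv)
        dy = rhs(y, 0.0, tfv)
        assert np.allclose(dy, 0.0, atol=1e-12)

    def test_empty_dntp_production(self, tfv):
        """All-zero state: only the dNTP production terms fire, at R0*Kout."""
        dy = rhs(np.zeros(8), 0.0, tfv)
        assert np.allclose(dy[:6], 0.0)
        assert dy[6] == pytest.approx(tfv.dntp("dATP").R0 * 1.0)
        assert dy[7] == pytest.approx(tfv.dntp("dGTP").R0 * 1.0)

    def test_half_maximal_inhibition_at_ec50(self, tfv):
        """A4 = EC50 and A7 = R0 gives dA7/dt = -0.5*R0 (gamma absent)."""
        d = tfv.dntp("dATP")
        y = np.zeros(8)
        y[3] = d.EC50
        y[6] = d.R0
        dy = rhs(y, 0.0, tfv)
        assert dy[6] == pytest.approx(-0.5 * d.R0, rel=1e-12)

    def test_formation_halved_at_sc50(self, tfv):
        """Saturation level A5 = SC50 halves the formation flux into A4."""
        y = np.zeros(8)
        y[1] = 390.0  # 1 ng/mL at Vc_F = 390 L
        base = rhs(y, 0.0, tfv)[3]
        y[4] = tfv.ic.SC50
        halved = rhs(y, 0.0, tfv)[3]
        assert halved == pytest.approx(base / 2.0, rel=1e-12)

    def test_gamma_waning_clock(self, tfv):
        """dGTP inhibition is scaled by 1/(1+t^gamma): full at t=0, halved
        when t^gamma = 1 (t = 1 day)."""
        d = tfv.dntp("dGTP")
        y = np.zeros(8)
        y[3] = d.EC50
        y[7] = d.R0
        at0 = rhs(y, 0.0, tfv)[7]
        at1 = rhs(y, 1.0, tfv)[7]
        assert at0 == pytest.approx(-0.5 * d.R0, rel=1e-12)
        assert at1 == pytest.approx(-0.25 * d.R0, rel=1e-12)

    def test_rejects_bad_state(self, tfv):
        with pytest.raises(ValueError):
            rhs(np.zeros(5), 0.0, tfv)
        y = np.zeros(8)
        y[0] = np.inf
        with pytest.raises(ValueError):
            rhs(y, 0.0, tfv)


class TestIntegrate:
    def test_empty_regimen_is_inert(self, tfv):
        traj = integrate(Regimen([], "TFV"), tfv, np.linspace(0, 30, 61))
        assert np.all(traj.plasma_conc == 0.0)
        assert np.all(traj.ic_conc == 0.0)
        assert np.allclose(traj.dntp("dATP"), 155.0, rtol=1e-9)
        assert np.allclose(traj.dntp("dGTP"), 245.0, rtol=1e-9)

    def test_plasma_dose_superposition(self, tfv):
        """The plasma subsystem is linear: the response to two staggered doses
        equals the sum of the single-dose responses, to within 0.1%."""
        grid = np.linspace(0, 6, 241)
        a = integrate(Regimen.single("TFV", time=0.0), tfv, grid)
        b = integrate(Regimen.single("TFV", time=1.0), tfv, grid)
        both = integrate(Regimen.single("TFV", time=0.0).merged(
            Regimen.single("TFV", time=1.0)), tfv, grid)
        expect = a.plasma_conc + b.plasma_conc
        mask = expect > 1e-3 * expect.max()
        err = np.abs(both.plasma_conc[mask] - expect[mask]) / expect[mask]
        assert err.max() < 1e-3

    def test_plasma_scales_with_dose_ic_saturates(self, tfv):
        """Doubling every dose doubles A1-A3 exactly; the anabolite rises
        less than twofold because formation saturates."""
        grid = np.linspace(0, 10, 201)
        reg = Regimen.daily("TFV", 10)
        one = integrate(reg, tfv, grid)
        two = integrate(reg.scaled(2.0), tfv, grid)
        mask = one.states[1] > 1e-6 * one.states[1].max()
        for i in (0, 1, 2):
            m = one.states[i] > 1e-6 * max(one.states[i].max(), 1e-12)
            assert np.allclose(two.states[i][m], 2.0 * one.states[i][m], rtol=1e-3)
        assert two.ic_conc[-1] < 2.0 * one.ic_conc[-1]
        assert two.ic_conc[-1] > one.ic_conc[-1]

    def test_sample_at_dose_time_is_pre_dose(self, tfv):
        """A grid point exactly at a dose event takes the left-limit value."""
        grid = np.array([0.0, 0.5, 1.0])
        traj = integrate(Regimen.daily("TFV", 2), tfv, grid)
        assert traj.states[0, 0] == 0.0       # depot sampled before first dose
        # depot at t=1 is the nearly-empty pre-second-dose value (Ka=80/day)
        assert traj.states[0, 2] < 1.0

    def test_nonnegative_states(self, tfv, ftc):
        for chain in (tfv, ftc):
            traj = integrate(Regimen.daily(chain.analyte, 5), chain,
                             np.linspace(0, 40, 401))
            assert traj.states.min() >= 0.0

    def test_dntp_returns_to_baseline_after_washout(self, tfv, ftc):
        """Non-waning dNTPs recover to within 1% of R0 once drug is gone
        (washout >= 10/Kout days)."""
        for chain, stream in ((tfv, "dATP"), (ftc, "dCTP"), (ftc, "TTP")):
            grid = np.linspace(0.0, 45.0, 451)
            traj = integrate(Regimen.daily(chain.analyte, 30), chain, grid)
            r0 = chain.dntp(stream).R0
            assert traj.dntp(stream)[-1] == pytest.approx(r0, rel=0.01)

    def test_linear_limit_matches_convolution(self, tfv):
        """With SC50 -> inf and R = 0 the anabolite is the linear one-
        compartment response to plasma forcing; check against a numeric
        convolution of the simulated plasma curve within 0.5%."""
        lin = tfv.copy()
        lin.ic.SC50 = 1e12
        lin.ic.R = 1e-12
        grid = np.linspace(0, 8, 3201)
        traj = integrate(Regimen.single("TFV"), lin, grid)
        kf, kel = lin.ic.Kf, lin.ic.Kel
        c = traj.plasma_conc
        # A4(t) = Kf e^{-Kel t} * int_0^t C(s) e^{Kel s} ds  (integrating factor),
        # evaluated by trapezoid quadrature on the simulated plasma curve
        from scipy.integrate import cumulative_trapezoid
        integral = cumulative_trapezoid(c * np.exp(kel * grid), grid, initial=0.0)
        conv = kf * np.exp(-kel * grid) * integral
        mask = traj.ic_conc > 0.05 * traj.ic_conc.max()
        err = np.abs(conv[mask] - traj.ic_conc[mask]) / traj.ic_conc[mask]
        assert err.max() < 0.005

    def test_dose_before_grid_raises(self, tfv):
        with pytest.raises(ValueError, match="before the start"):
            integrate(Regimen.single("TFV", time=-1.0), tfv, np.linspace(0, 2, 11))

    def test_unsorted_grid_raises(self, tfv):
        with pytest.raises(ValueError, match="sorted"):
            integrate(Regimen.single("TFV"), tfv, np.array([0.0, 2.0, 1.0]))


class TestSteadyStateProfile:
    def test_single_dose_equals_integrate(self, tfv):
        prof = steady_state_profile(tfv, 1.0, 1, resolution=0.05)
        ref = integrate(Regimen.single("TFV"), tfv, prof.times)
        assert np.allclose(prof.states, ref.states, rtol=1e-9, atol=1e-9)

    def test_anabolite_accumulates(self, tfv):
        prof = steady_state_profile(tfv, 1.0, 50)
        first_max, _ = interval_extrema(prof, "TFVDP", 1.0, 0)
        last_max, _ = interval_extrema(prof, "TFVDP", 1.0, 49)
        assert last_max / first_max > 1.0

    def test_steady_state_interval_auc_equals_dose_over_cl(self, tfv):
        """For the linear plasma subsystem, the steady-state dosing-interval
        AUC equals dose/CL (within 1%, trapezoid error included)."""
        prof = steady_state_profile(tfv, 1.0, 50, resolution=1.0 / 200)
        mask = prof.times >= 49.0
        auc = np.trapezoid(prof.plasma_conc[mask], prof.times[mask])
        assert auc == pytest.approx(tfv.dose_ug / tfv.plasma.CL_F, rel=0.01)

    def test_coarse_resolution_warns(self, tfv):
        with pytest.warns(UserWarning, match="resolution"):
            steady_state_profile(tfv, 1.0, 2, resolution=0.5)

    def test_saturation_subadditivity_in_dose(self, tfv):
        """Steady-state anabolite exposure per unit dose is non-increasing in
        dose (formation saturates)."""
        per_dose = []
        for mult in (0.5, 1.0, 2.0, 4.0):
            prof = steady_state_profile(tfv, 1.0, 30, dose_ug=mult * tfv.dose_ug)
            mask = prof.times >= 29.0
            per_dose.append(np.mean(prof.ic_conc[mask]) / mult)
        assert all(a >= b * (1 - 1e-9) for a, b in zip(per_dose, per_dose[1:]))


class TestTrajectoryExport:
    def test_tidy_frame(self, tfv):
        traj = integrate(Regimen.single("TFV"), tfv, np.linspace(0, 2, 5))
        df = traj.to_frame()
        assert set(df.columns) == {"time_days", "stream", "value", "units"}
        assert set(df["stream"]) == {"TFV", "TFVDP", "dATP", "dGTP"}
        assert (df.loc[df.stream == "TFV", "units"] == "ng/mL").all()
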