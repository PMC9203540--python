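import dataclasses

import numpy as np
import pytest

import coxtcm as cx
from conftest import FIG_ETA


@pytest.fixture(scope="module")
def simeoni():
    return cx.GrowthParams("simeoni", lambda0=0.25, lambda1=0.4603, phi=20)


class TestGrowthRate:
    def test_zero_proliferating_mass(self, simeoni):
        assert cx.growth_rate(0.0, 0.5, simeoni) == 0.0

    def test_exponential_regime_below_threshold(self, simeoni):
        w = simeoni.w_th / 10
        assert cx.growth_rate(1.0, w, simeoni) == pytest.approx(0.25, rel=1e-3)

    def test_linear_regime_above_threshold(self, simeoni):
        w = 10 * simeoni.w_th
        assert cx.growth_rate(1.0, w, simeoni) == pytest.approx(0.4603 / w, rel=1e-2)

    def test_no_overflow_for_enormous_mass(self, simeoni):
        # (lambda0 w / lambda1)^20 overflows double for w ~ 1e20; log-domain must survive
        val = cx.growth_rate(1.0, 1e40, simeoni)
        assert np.isfinite(val) and val == pytest.approx(0.4603 / 1e40, rel=1e-6)

    def test_logistic_variant(self):
        g = cx.GrowthParams("logistic", lambda0=0.12, umax=0.0066)
        assert cx.growth_rate(0.002, 0.0033, g) == pytest.approx(0.12 * 0.5 * 0.002)

    def test_negative_state_rejected(self, simeoni):
        with pytest.raises(ValueError):
            cx.growth_rate(-0.1, 0.1, simeoni)


class TestMortalityRate:
    def test_values(self):
        m = cx.MortalityParams(eta=0.7816)
        assert cx.mortality_rate(0.0, 1.0, m) == 0.0
        assert cx.mortality_rate(1.0, 1.0, m) == pytest.approx(0.7816)
        assert cx.mortality_rate(2.0, 3.0, m) == pytest.approx(2 * cx.mortality_rate(2.0, 1.5, m))


class TestRHS:
    def test_undamaged_drug_free_state(self, simeoni):
        tcm = cx.TCMParams(n=4, k1=0.2859, p=1.0)
        mort = cx.MortalityParams(eta=0.7816)
        d = cx.erlang_tcm_rhs(np.array([0.5, 0, 0, 0, 0.0]), 0.0, simeoni, mort, tcm)
        assert np.all(d[1:] == 0)
        assert d[0] == pytest.approx(cx.growth_rate(0.5, 0.5, simeoni))

    def test_cascade_sum_identities_on_random_states(self, simeoni):
        rng = np.random.default_rng(7)
        mort = cx.MortalityParams(eta=0.7816)
        erl = cx.TCMParams(n=4, k1=0.2859, p=1.0)
        cox = cx.TCMParams(n=4, k1=0.2859, p=0.44268)
        for _ in range(200):
            v = rng.uniform(0, 2, 5)
            C = rng.uniform(0, 10)
            k_out = 0.7816 * C * v[0]
            de = cx.erlang_tcm_rhs(v, C, simeoni, mort, erl)
            assert de[1:].sum() == pytest.approx(k_out - erl.k1 * v[4], abs=1e-12)
            dc = cx.coxian_tcm_rhs(v, C, simeoni, mort, cox)
            expected = k_out - (1 - cox.p) * cox.k1 * v[1:4].sum() - cox.k1 * v[4]
            assert dc[1:].sum() == pytest.approx(expected, abs=1e-12)

    def test_coxian_p1_equals_erlang_rhs(self, simeoni):
        rng = np.random.default_rng(11)
        mort = cx.MortalityParams(eta=0.7816)
        tcm = cx.TCMParams(n=4, k1=0.2859, p=1.0)
        for _ in range(1000):
            v = rng.uniform(0, 5, 5)
            C = rng.uniform(0, 50)
            de = cx.erlang_tcm_rhs(v, C, simeoni, mort, tcm)
            dc = cx.coxian_tcm_rhs(v, C, simeoni, mort, tcm)
            np.testing.assert_allclose(de, dc, atol=1e-14)

    def test_dimension_mismatch_and_domain_errors(self, simeoni):
        mort = cx.MortalityParams(eta=0.7816)
        with pytest.raises(ValueError, match="compartments"):
            cx.erlang_tcm_rhs(np.zeros(4), 0.0, simeoni, mort, cx.TCMParams(4, 0.2859))
        with pytest.raises(ValueError, match="p must"):
            cx.coxian_tcm_rhs(np.zeros(5), 0.0, simeoni, mort, _bad_p())


def _bad_p():
    t = cx.TCMParams(4, 0.2859, 1.0)
    object.__setattr__(t, "p", 1.5)  # bypass constructor to exercise the RHS guard
    return t


class TestSimulate:
    def test_drug_free_exponential_phase(self, simeoni):
        mort = cx.MortalityParams(eta=0.7816)
        tcm = cx.TCMParams(n=4, k1=0.2859, p=1.0)
        grid = np.linspace(0, 5, 51)
        traj = cx.simulate_tcm("erlang", simeoni, mort, tcm, 0.0, 0.0121, grid)
        np.testing.assert_allclose(traj.w, 0.0121 * np.exp(0.25 * grid), rtol=5e-3)

    def test_logistic_saturates_monotonically(self):
        g = cx.GrowthParams("logistic", lambda0=0.25, umax=1.0)
        mort = cx.MortalityParams(eta=0.0)
        tcm = cx.TCMParams(n=3, k1=0.3, p=1.0)
        grid = np.linspace(0, 80, 161)
        traj = cx.simulate_tcm("erlang", g, mort, tcm, 0.0, 0.05, grid)
        assert np.all(np.diff(traj.w) >= -1e-12)
        assert traj.w[-1] == pytest.approx(1.0, rel=1e-4)

    def test_continuation_probability_separates_trajectories(self, mouse150):
        grid = np.linspace(0, 40, 401)
        erl = cx.simulate_tcm(
            "erlang", mouse150["growth"], mouse150["mortality"],
            dataclasses.replace(mouse150["tcm"], p=1.0),
            cx.BolusConcentration(mouse150["pk"], mouse150["schedule"]),
            mouse150["w0"], grid, atol=1e-12,
        )
        cox = cx.simulate_tcm(
            "coxian", mouse150["growth"], mouse150["mortality"], mouse150["tcm"],
            cx.BolusConcentration(mouse150["pk"], mouse150["schedule"]),
            mouse150["w0"], grid, atol=1e-12,
        )
        window = (grid >= 13) & (grid <= 30)
        assert np.abs(erl.w[window] - cox.w[window]).max() > 0.05

    def test_nonnegativity_through_the_stiff_kill_phase(self, mouse150):
        grid = np.linspace(0, 40, 401)
        traj = cx.simulate_tcm(
            "coxian", mouse150["growth"], mouse150["mortality"], mouse150["tcm"],
            cx.BolusConcentration(mouse150["pk"], mouse150["schedule"]),
            mouse150["w0"], grid, atol=1e-12,
        )
        assert traj.u.min() >= -1e-9
        assert traj.y.min() >= -1e-9

    def test_mass_budget_along_trajectory(self, simeoni):
        # d(u + sum y)/dt == k_in - (1-p) k1 sum_{i<n} y_i - k1 y_n, checked
        # from the RHS evaluated on simulated states
        mort = cx.MortalityParams(eta=FIG_ETA)
        tcm = cx.TCMParams(n=4, k1=0.2859, p=0.5)
        grid = np.linspace(0, 30, 301)
        traj = cx.simulate_tcm("coxian", simeoni, mort, tcm, 2016.15, 0.0121, grid)
        for idx in range(0, 301, 25):
            v = np.concatenate(([traj.u[idx]], traj.y[idx]))
            d = cx.coxian_tcm_rhs(v, traj.C[idx], simeoni, mort, tcm)
            k_in = cx.growth_rate(traj.u[idx], v.sum(), simeoni)
            expected = k_in - (1 - tcm.p) * tcm.k1 * traj.y[idx][:-1].sum() - tcm.k1 * traj.y[idx][-1]
            assert d.sum() == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_invalid_model_and_negative_w0(self, simeoni):
        mort = cx.MortalityParams(eta=0.0)
        tcm = cx.TCMParams(n=2, k1=0.3)
        with pytest.raises(ValueError):
            cx.simulate_tcm("weibull", simeoni, mort, tcm, 0.0, 0.01, np.linspace(0, 1, 5))
        with pytest.raises(ValueError):
            cx.simulate_tcm("erlang", simeoni, mort, tcm, 0.0, -0.01, np.linspace(0, 1, 5))


class TestConvolutionOracle:
    def _scenario(self, mouse150):
        return {
            "growth": mouse150["growth"],
            "mortality": cx.MortalityParams(eta=FIG_ETA),
            "conc": cx.BolusConcentration(mouse150["pk"], mouse150["schedule"]),
        }

    def test_no_kill_keeps_cascade_empty(self, simeoni):
        mort = cx.MortalityParams(eta=0.0)
        kern = cx.ErlangSpec(4, 0.2859)
        grid = np.linspace(0, 10, 2001)
        _, u, y = cx.convolution_oracle(simeoni, mort, kern, 0.0, 0.0121, grid)
        np.testing.assert_allclose(y, 0.0, atol=1e-14)
        # Heun co-integration is second order: O(h^2) drift over the horizon
        np.testing.assert_allclose(u, 0.0121 * np.exp(0.25 * grid), rtol=1e-4)

    def test_linear_chain_trick_equivalence(self, mouse150):
        sc = self._scenario(mouse150)
        kern = cx.ErlangSpec(4, 0.2859)
        tcm = cx.TCMParams(n=4, k1=0.2859, p=1.0)
        grid = np.linspace(0, 40, 4001)
        _, u, y = cx.convolution_oracle(sc["growth"], sc["mortality"], kern, sc["conc"], 0.0121, grid)
        traj = cx.simulate_tcm(
            "erlang", sc["growth"], sc["mortality"], tcm, sc["conc"], 0.0121, grid,
            rtol=1e-10, atol=1e-12,
        )
        ref = traj.total_damaged
        assert np.abs(y - ref).max() / np.abs(ref).max() < 1e-3

    def test_error_halves_under_grid_refinement(self, mouse150):
        sc = self._scenario(mouse150)
        kern = cx.ErlangSpec(4, 0.2859)
        tcm = cx.TCMParams(n=4, k1=0.2859, p=1.0)
        errs = []
        for n_pts in (2001, 4001):
            grid = np.linspace(0, 40, n_pts)
            _, _, y = cx.convolution_oracle(
                sc["growth"], sc["mortality"], kern, sc["conc"], 0.0121, grid
            )
            traj = cx.simulate_tcm(
                "erlang", sc["growth"], sc["mortality"], tcm, sc["conc"], 0.0121, grid,
                rtol=1e-10, atol=1e-12,
            )
            errs.append(np.abs(y - traj.total_damaged).max())
        assert errs[1] <= 0.5 * errs[0]

    def test_narrow_kernel_approaches_pure_delay(self):
        # Erlang(n, n/T) concentrates at lag T; the damaged-mass loss term
        # approaches the shifted kill k_out(t - T), i.e. the DDE limit
        growth = cx.GrowthParams("logistic", lambda0=0.25, umax=1.0)
        mort = cx.MortalityParams(eta=0.001)
        T = 4.0
        grid = np.linspace(0, 24, 1201)
        h = grid[1] - grid[0]
        lag = round(T / h)

        def dde_reference():
            # Heun with exact lagged kill instead of the convolution
            u = np.empty(grid.size)
            y = np.empty(grid.size)
            u[0], y[0] = 0.3, 0.0
            kout = lambda j, uj: mort.eta * 50.0 * uj
            hist = [kout(0, u[0])]
            for j in range(grid.size - 1):
                loss_j = hist[j - lag] if j >= lag else 0.0
                g_j = hist[j]
                du_j = cx.growth_rate(u[j], u[j] + y[j], growth) - g_j
                dy_j = g_j - loss_j
                up, yp = u[j] + h * du_j, y[j] + h * dy_j
                g_n = kout(j + 1, up)
                loss_n = hist[j + 1 - lag] if j + 1 > lag else 0.0
                du_n = cx.growth_rate(up, up + yp, growth) - g_n
                dy_n = g_n - loss_n
                u[j + 1] = u[j] + 0.5 * h * (du_j + du_n)
                y[j + 1] = y[j] + 0.5 * h * (dy_j + dy_n)
                hist.append(kout(j + 1, u[j + 1]))
            return y

        y_dde = dde_reference()
        gaps = []
        for n in (10, 40, 160):
            kern = cx.ErlangSpec(n, n / T)
            _, _, y = cx.convolution_oracle(growth, mort, kern, 50.0, 0.3, grid)
            gaps.append(np.abs(y - y_dde).max())
        assert gaps[2] < gaps[1] < gaps[0]

    def test_nonuniform_grid_rejected(self, simeoni):
        mort = cx.MortalityParams(eta=0.0)
        kern = cx.ErlangSpec(2, 1.0)
        with pytest.raises(ValueError, match="uniform"):
            cx.convolution_oracle(simeoni, mort, kern, 0.0, 0.01, np.array([0, 0.1, 0.3]))

    def test_off_grid_dose_event_rejected(self, mouse150):
        sc = self._scenario(mouse150)
        grid = np.linspace(0, 40, 301)  # step 0.1333..., day 13 not a node
        with pytest.raises(ValueError, match="grid node"):
            cx.convolution_oracle(
                sc["growth"], sc["mortality"], cx.ErlangSpec(4, 0.2859), sc["conc"],
                0.0121, grid,
            )
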