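"""Tests for recovery metrics: return time, mixing time, tau0, fronts,
and the IR/RR/MR decomposition."""

import math

import numpy as np
import pytest

from spatialrecovery import (
    Disturbance,
    Domain,
    GrowthModel,
    ModelParams,
    NOT_RECOVERED,
    StateField,
    decompose,
    front_metrics,
    integrate,
    local_timescale,
    mixing_time,
    return_time,
)

LN561 = math.log(0.99 * 0.85 / (0.01 * 0.15))  # logistic return-time closed form


class TestReturnTime:
    def test_undisturbed_equilibrium_is_zero(self, logistic, small_lattice):
        params = ModelParams(r=1.0, d=1.0, growth=logistic)
        traj = integrate(StateField.uniform(small_lattice, 1.0), params,
                         small_lattice, t_max=5.0)
        assert return_time(traj, 1.0) == 0.0

    @pytest.mark.parametrize("r,expected", [(1.0, LN561), (2.0, LN561 / 2)])
    def test_logistic_closed_form_inversion(self, logistic, small_lattice, r, expected):
        params = ModelParams(r=r, d=0.0, growth=logistic)
        traj = integrate(StateField.uniform(small_lattice, 0.15), params,
                         small_lattice, t_max=10.0, store_every=0.01)
        assert return_time(traj, 1.0) == pytest.approx(expected, abs=1e-4)

    def test_not_recovered_sentinel(self, power3, small_lattice):
        params = ModelParams(r=1.0, d=0.0, growth=power3)
        traj = integrate(StateField.uniform(small_lattice, 0.1), params,
                         small_lattice, t_max=1.0)
        assert return_time(traj, 1.0) == NOT_RECOVERED


class TestMixingTime:
    def test_uniform_state_zero(self, logistic, small_lattice):
        params = ModelParams(r=1.0, d=1.0, growth=logistic)
        traj = integrate(StateField.uniform(small_lattice, 0.5), params,
                         small_lattice, t_max=2.0)
        assert mixing_time(traj, 1.0, eps=0.01) == 0.0

    def test_single_harmonic_decay_rate(self, logistic):
        """Pure diffusion: slowest Fourier mode decays at d*(2 pi/L)^2."""
        L, n, d, eps = 50.0, 256, 2.0, 0.01
        dom = Domain.lattice(L, n)
        x = dom.positions()
        amp = 0.3
        state = StateField(1.0 + amp * np.sin(2 * np.pi * x / L))
        params = ModelParams(r=1.0, d=d, growth=logistic)
        traj = integrate(state, params, dom, t_max=300.0, store_every=0.25,
                         reaction_on=False)
        q = 2 * np.pi / L
        expected = math.log(2 * amp / (eps * 1.0)) / (d * q * q)
        assert mixing_time(traj, 1.0, eps=eps) == pytest.approx(expected, rel=0.01)

    def test_strong_dispersal_mixes_faster(self, power3):
        dom = Domain.lattice(100.0, 256)
        dist = Disturbance(sigma=0.5, rho=0.85)
        from spatialrecovery import apply_disturbance

        eq = StateField.uniform(dom, 1.0)
        disturbed = apply_disturbance(eq, dist, dom, power3)
        tm = {}
        for d in (0.0, 1e3):
            params = ModelParams(r=1.0, d=d, growth=power3)
            traj = integrate(disturbed, params, dom, t_max=800.0)
            tm[d] = mixing_time(traj, 1.0, eps=0.01)
        # d = 1e3 homogenizes at rate ~ d (2 pi / L)^2 ~ 4: within ~a time unit
        assert tm[1e3] < 2.0
        assert tm[0.0] > 30 * tm[1e3]


class TestLocalTimescale:
    def test_logistic_closed_form(self, logistic):
        assert local_timescale(logistic, rho=0.85).tau0 == pytest.approx(LN561, abs=1e-6)

    def test_r_free_nondimensionalization(self, logistic):
        # tau0 integrates the r-scaled dynamics, so r never enters
        t1 = local_timescale(logistic, rho=0.6).tau0
        assert t1 == pytest.approx(math.log(0.99 * 0.6 / (0.01 * 0.4)), abs=1e-6)

    def test_total_removal_with_nonlinearity_never_recovers(self, power3):
        with pytest.warns(UserWarning, match="extinction fixed point"):
            assert local_timescale(power3, rho=1.0).tau0 == math.inf

    def test_monotone_in_rho_and_gamma(self):
        """tau0 grows with disturbance intensity and with nonlinearity."""
        taus_rho = [local_timescale(GrowthModel(gamma=2.0), rho).tau0
                    for rho in (0.3, 0.6, 0.9)]
        assert taus_rho == sorted(taus_rho)
        taus_gamma = [local_timescale(GrowthModel(gamma=g), 0.8).tau0
                      for g in (0.0, 1.0, 3.0)]
        assert taus_gamma == sorted(taus_gamma)


class TestFrontMetrics:
    def test_nondimensional_invariance(self, power3):
        """(r, d) = (1, 1) and (4, 0.25) give identical u and lam."""
        fm1 = front_metrics(ModelParams(r=1.0, d=1.0, growth=power3), rho=0.9)
        fm2 = front_metrics(ModelParams(r=4.0, d=0.25, growth=power3), rho=0.9)
        assert fm1.u == pytest.approx(fm2.u, rel=0.01)
        assert fm1.lam == pytest.approx(fm2.lam, rel=0.01)

    def test_bistable_front_exists_below_half_allee(self, bistable):
        """The K state invades 0 for Allee threshold < 1/2; the cubic-front
        closed form gives u = (1 - 2a)/sqrt(2)."""
        fm = front_metrics(ModelParams(r=1.0, d=1.0, growth=bistable), rho=1.0)
        assert fm.u > 0
        assert fm.u == pytest.approx((1 - 2 * 0.3) / math.sqrt(2), rel=0.05)

    def test_requires_dispersal(self, power3):
        with pytest.raises(ValueError, match="d > 0"):
            front_metrics(ModelParams(r=1.0, d=0.0, growth=power3))


class TestDecompose:
    DIST = Disturbance(sigma=0.5, rho=0.85)

    def test_dispersal_free_is_pure_isolated(self, power3, small_lattice):
        params = ModelParams(r=1.0, d=0.0, growth=power3)
        dec = decompose(params, small_lattice, self.DIST)
        assert (dec.f_IR, dec.f_RR, dec.f_MR) == (1.0, 0.0, 0.0)
        assert dec.mixing_time == math.inf

    def test_fractions_sum_to_one(self, power3, small_lattice):
        params = ModelParams(r=1.0, d=5.0, growth=power3)
        dec = decompose(params, small_lattice, self.DIST)
        assert dec.f_IR + dec.f_RR + dec.f_MR == pytest.approx(1.0, abs=1e-9)
        for f in (dec.f_IR, dec.f_RR, dec.f_MR):
            assert 0.0 <= f <= 1.0

    def test_eps_mix_sensitivity_is_mild(self, power3, small_lattice):
        """The mixing threshold is a convention; the dominant regime must not
        depend on it across the plausible range."""
        params = ModelParams(r=0.01, d=8.0, growth=power3)
        doms = [decompose(params, small_lattice, self.DIST, eps_mix=e).dominant
                for e in (0.005, 0.01, 0.05)]
        assert set(doms) == {"MR"}
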