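"""Unit and property tests for the reaction-diffusion core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatialrecovery import (
    Domain,
    GrowthModel,
    ModelParams,
    StateField,
    dispersal_term,
    growth_term,
    integrate,
)


class TestGrowthTerm:
    @pytest.mark.parametrize(
        "gamma,N,expected",
        [
            (3.0, 1.0, 0.0),      # equilibrium root
            (3.0, 0.0, 0.0),      # extinction root
            (0.0, 0.5, 0.25),     # logistic: 1*0.5*(1-0.5)
            (3.0, 0.5, 0.03125),  # 0.5*0.5*0.125
        ],
    )
    def test_pointwise_values(self, gamma, N, expected):
        params = ModelParams(r=1.0, d=1.0, growth=GrowthModel(gamma=gamma))
        out = growth_term(np.array([N]), params)
        assert out[0] == pytest.approx(expected, abs=1e-14)

    def test_scales_with_r(self):
        g = GrowthModel(gamma=0.0)
        N = np.array([0.3])
        one = growth_term(N, ModelParams(r=1.0, d=0.0, growth=g))
        five = growth_term(N, ModelParams(r=5.0, d=0.0, growth=g))
        assert five[0] == pytest.approx(5 * one[0])

    def test_negative_density_rejected(self):
        params = ModelParams()
        with pytest.raises(ValueError, match="negative"):
            growth_term(np.array([-0.1]), params)

    def test_bistable_roots(self, bistable):
        assert bistable.F(np.array([1.0]))[0] == pytest.approx(0.0)
        assert bistable.F(np.array([0.3]))[0] == pytest.approx(0.0)

    def test_bistable_sign_structure(self, bistable):
        # decay below the Allee threshold, growth between threshold and K
        assert bistable.reaction(np.array([0.1]))[0] < 0
        assert bistable.reaction(np.array([0.6]))[0] > 0


class TestDispersalTerm:
    def test_uniform_state_in_kernel(self, small_lattice):
        params = ModelParams(d=2.0)
        state = StateField.uniform(small_lattice, 0.7)
        assert np.allclose(dispersal_term(state, params, small_lattice), 0.0)

    def test_path_network_laplacian(self, path3):
        params = ModelParams(d=1.0)
        state = StateField(np.array([0.0, 1.0, 0.0]))
        out = dispersal_term(state, params, path3)
        assert np.allclose(out, [1.0, -2.0, 1.0])

    @pytest.mark.parametrize("boundary", ["periodic", "no_flux"])
    def test_conservation_lattice(self, boundary):
        dom = Domain.lattice(10.0, 64, boundary=boundary)
        rng = np.random.default_rng(1)
        state = StateField(rng.uniform(0, 2, 64))
        out = dispersal_term(state, ModelParams(d=3.0), dom)
        assert abs(out.sum() * dom.dx) < 1e-10

    def test_conservation_network(self, path3):
        state = StateField(np.array([0.2, 1.5, 0.4]))
        out = dispersal_term(state, ModelParams(d=2.5), path3)
        assert abs(out.sum()) < 1e-12


class TestIntegrate:
    def test_equilibrium_fixed_point(self, power3, small_lattice):
        params = ModelParams(r=1.0, d=2.0, growth=power3)
        traj = integrate(StateField.uniform(small_lattice, 1.0), params,
                         small_lattice, t_max=5.0)
        assert np.abs(traj.states - 1.0).max() < 1e-12

    def test_logistic_closed_form(self, logistic, small_lattice):
        params = ModelParams(r=1.0, d=0.0, growth=logistic)
        n0 = 0.15
        traj = integrate(StateField.uniform(small_lattice, n0), params,
                         small_lattice, t_max=10.0, store_every=0.1)
        t = traj.times
        exact = n0 * np.exp(t) / (1 + n0 * (np.exp(t) - 1))
        assert np.abs(traj.states[:, 0] - exact).max() < 1e-6

    def test_pure_diffusion_conserves_biomass(self, logistic, small_lattice):
        rng = np.random.default_rng(3)
        state = StateField(rng.uniform(0.1, 1.4, small_lattice.n_cells))
        params = ModelParams(r=1.0, d=10.0, growth=logistic)
        traj = integrate(state, params, small_lattice, t_max=20.0,
                         reaction_on=False)
        b = traj.total_biomass
        assert abs(b[-1] - b[0]) / b[0] < 1e-10

    def test_rate_rescaling_collapse(self, power3):
        """(r, d) -> (c r, c d) rescales time exactly: same states at t/c."""
        dom = Domain.lattice(50.0, 128)
        rng = np.random.default_rng(5)
        state = StateField(rng.uniform(0.1, 1.0, 128))
        c = 4.0
        base = ModelParams(r=1.0, d=1.0, growth=power3)
        fast = ModelParams(r=c, d=c, growth=power3)
        t1 = integrate(state, base, dom, t_max=8.0, store_every=1.0)
        t2 = integrate(state, fast, dom, t_max=8.0 / c, store_every=1.0 / c)
        assert np.allclose(t1.states, t2.states, atol=1e-10)

    def test_resolution_convergence(self, power3):
        """Halving dx changes the trajectory by well under 1% in sup-norm."""
        params = ModelParams(r=1.0, d=1.0, growth=power3)
        out, pos = {}, {}
        for n in (128, 256):
            dom = Domain.lattice(40.0, n)
            x = dom.positions()
            state = StateField(np.where(abs(x - 20.0) < 10.0, 0.1, 1.0))
            traj = integrate(state, params, dom, t_max=10.0, store_every=5.0)
            out[n], pos[n] = traj.states[-1], x
        fine_on_coarse = np.interp(pos[128], pos[256], out[256])
        assert np.abs(fine_on_coarse - out[128]).max() < 0.01

    @pytest.mark.parametrize("n0,limit", [(0.2, 0.0), (0.4, 1.0)])
    def test_bistable_threshold_dynamics(self, bistable, small_lattice, n0, limit):
        """Uniform states decay below the Allee threshold and grow above it."""
        params = ModelParams(r=1.0, d=0.0, growth=bistable)
        traj = integrate(StateField.uniform(small_lattice, n0), params,
                         small_lattice, t_max=200.0)
        assert traj.states[-1, 0] == pytest.approx(limit, abs=1e-3)

    def test_network_integration_reaches_equilibrium(self, path3, logistic):
        params = ModelParams(r=1.0, d=0.5, growth=logistic)
        traj = integrate(StateField(np.array([0.1, 1.0, 0.5])), params,
                         path3, t_max=40.0)
        assert np.allclose(traj.states[-1], 1.0, atol=1e-6)


class TestDomain:
    def test_asymmetric_adjacency_rejected(self):
        A = np.array([[0, 1], [0, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            Domain.network(A)

    def test_self_loop_rejected(self):
        A = np.array([[1, 1], [1, 0]], dtype=float)
        with pytest.raises(ValueError, match="diagonal"):
            Domain.network(A)

    def test_disconnected_network_warns(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1.0
        with pytest.warns(UserWarning, match="connected"):
            Domain.network(A)

    @given(st.integers(min_value=8, max_value=64))
    @settings(max_examples=10, deadline=None)
    def test_lattice_spacing(self, n):
        dom = Domain.lattice(10.0, n)
        assert dom.dx == pytest.approx(10.0 / n)
        assert dom.system_measure == pytest.approx(10.0)


@given(
    gamma=st.floats(min_value=0.0, max_value=5.0),
    N=st.floats(min_value=0.0, max_value=1.0),
)
@settings(max_examples=50, deadline=None)
def test_growth_sign_property(gamma, N):
    """Power-logistic growth is nonnegative on [0, K] and zero at the roots."""
    g = GrowthModel(gamma=gamma)
    val = g.reaction(np.array([N]))[0]
    assert val >= -1e-15
    if N in (0.0, 1.0) and gamma > 0:
        assert val == pytest.approx(0.0, abs=1e-15)
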