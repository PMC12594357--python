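"""Carbon-pool transformation, graph diffusion and the 0D baseline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skelpore.biosim import (
    BioParams,
    BioState,
    diffusion_step_explicit,
    diffusion_step_implicit,
    dc_voxel2_per_day,
    ode0d,
    place_initial_biomass,
    simulate,
    theta,
    transform_step,
    uniform_dom,
)
from skelpore.poregraph import PoreGraph

from conftest import fixture_graph


def _two_node_graph():
    return PoreGraph(
        volumes=[1.0, 1.0],
        centroids=np.zeros((2, 3)),
        arcs=[[1, 2]],
        faces=[1],
        distances=[1.0],
    )


DAY = 86400.0


class TestTransformStep:
    def test_hand_computed_example(self):
        # rho=0.2/d, mu=0.5/d, beta=0.55, dt=0.1 d, no DOM
        state = BioState(b=np.array([[1.0], [0.0], [0.0], [0.0], [0.0]]), volumes=[1.0])
        params = BioParams(dt=0.1 * DAY)
        out = transform_step(state, params)
        assert out.b.ravel() == pytest.approx([0.93, 0.0275, 0.0225, 0.0, 0.02])
        assert out.b.sum() == pytest.approx(1.0)

    def test_all_zero_state(self):
        state = BioState.zeros([1.0, 2.0])
        out = transform_step(state, BioParams())
        assert (out.b == 0).all()

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        mb=st.floats(0, 10),
        dom=st.floats(0, 10),
        som=st.floats(0, 10),
        fom=st.floats(0, 10),
        dt=st.floats(1.0, 3600.0),
    )
    def test_conservation_property(self, mb, dom, som, fom, dt):
        state = BioState(b=np.array([[mb], [dom], [som], [fom], [0.0]]), volumes=[3.0])
        params = BioParams(dt=dt, v_fom=0.3)
        try:
            out = transform_step(state, params)
        except ValueError:
            return  # step rejected as too large for this state: a valid outcome
        assert out.b.sum() == pytest.approx(state.b.sum(), rel=1e-12, abs=1e-12)
        assert (out.b >= 0).all()

    def test_growth_moves_dom_to_biomass(self):
        state = BioState(b=np.array([[1.0], [5.0], [0.0], [0.0], [0.0]]), volumes=[1.0])
        params = BioParams(dt=0.01 * DAY, k_dom=1.0)
        out = transform_step(state, params)
        assert out.b[0, 0] > state.b[0, 0] - 0.007  # growth outweighs losses
        assert out.b[1, 0] < state.b[1, 0]

    def test_oversized_step_rejected(self):
        state = BioState(b=np.array([[1.0], [0.0], [0.0], [0.0], [0.0]]), volumes=[1.0])
        with pytest.raises(ValueError, match="dt must be below"):
            transform_step(state, BioParams(dt=2.0 * DAY))

    def test_negative_pool_names_node(self):
        # huge biomass draws more DOM than node 1 holds in one step
        b = np.array([[0.0, 50.0], [1.0, 0.01], [0.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        state = BioState(b=b, volumes=[1.0, 1.0])
        with pytest.raises(ValueError, match="node 1"):
            transform_step(state, BioParams(dt=0.05 * DAY, k_dom=1e-6))


class TestTheta:
    def test_arithmetic(self):
        params = BioParams(alpha=0.35, dc=1.0, dt=30 * DAY)
        assert theta((2.0, 4.0), params) == pytest.approx(5.25)

    def test_zero_contact_area(self):
        assert theta((0.0, 4.0), BioParams()) == 0.0

    def test_linear_in_dt(self):
        p1 = BioParams(dt=30.0)
        p2 = BioParams(dt=60.0)
        assert theta((3.0, 2.0), p2) == pytest.approx(2 * theta((3.0, 2.0), p1))

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            theta((1.0, 0.0), BioParams())

    def test_dc_unit_conversion(self):
        # DOM in water at 24 um voxels: ~1e5 voxel^2/day
        assert dc_voxel2_per_day(6.73e-6, 24.0) == pytest.approx(1.0095e5, rel=1e-3)


class TestDiffusionSteps:
    def test_implicit_two_node_closed_form(self):
        # v=(1,1), theta=1, c=(1,0) -> (2/3, 1/3)
        g = _two_node_graph()
        params = BioParams(alpha=1.0, dc=1.0, dt=DAY)
        state = BioState.zeros(g.volumes)
        state.b[1] = [1.0, 0.0]
        out = diffusion_step_implicit(state, g, params)
        assert out.b[1] == pytest.approx([2 / 3, 1 / 3])

    def test_explicit_two_node(self):
        # theta = 0.25 -> c' = (0.75, 0.25)
        g = _two_node_graph()
        params = BioParams(alpha=0.25, dc=1.0, dt=DAY)
        state = BioState.zeros(g.volumes)
        state.b[1] = [1.0, 0.0]
        out = diffusion_step_explicit(state, g, params)
        assert out.b[1] == pytest.approx([0.75, 0.25])

    def test_uniform_concentration_is_equilibrium(self):
        g = fixture_graph(40, seed=3)
        params = BioParams(dc=100.0, dt=30.0)
        state = BioState.zeros(g.volumes)
        state.b[1] = 0.7 * g.volumes  # c = 0.7 everywhere
        for step in (diffusion_step_implicit, diffusion_step_explicit):
            out = step(state, g, params)
            assert out.b[1] == pytest.approx(state.b[1], rel=1e-9)

    def test_explicit_stability_violation_names_bound(self):
        g = _two_node_graph()
        params = BioParams(alpha=1.0, dc=1.5, dt=DAY)  # theta/v = 1.5
        state = BioState.zeros(g.volumes)
        state.b[1] = [1.0, 0.0]
        with pytest.raises(ValueError, match="dt must be below"):
            diffusion_step_explicit(state, g, params)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 1000), scale=st.floats(0.1, 5.0))
    def test_conservation_and_maximum_principle(self, seed, scale):
        g = fixture_graph(30, seed=seed % 17)
        rng = np.random.default_rng(seed)
        params = BioParams(dc=scale * 50.0, dt=30.0)
        state = BioState.zeros(g.volumes)
        state.b[1] = rng.random(30) * g.volumes
        out = diffusion_step_implicit(state, g, params)
        assert out.b[1].sum() == pytest.approx(state.b[1].sum(), rel=1e-11)
        c0, c1 = state.concentrations, out.concentrations
        assert c1.min() >= c0.min() - 1e-12
        assert c1.max() <= c0.max() + 1e-12


class TestSimulate:
    def test_zero_diffusion_decouples_nodes(self):
        g = fixture_graph(10, seed=2)
        params = BioParams(dc=0.0, dt=600.0, k_dom=0.01)
        state = BioState.zeros(g.volumes)
        state.b[0] = np.linspace(0.1, 1.0, 10)
        state.b[1] = uniform_dom(g, 5.0)
        res = simulate(g, state, params, duration=6000.0)
        # oracle: iterate the transformation alone
        ref = state.copy()
        for _ in range(10):
            ref = transform_step(ref, params)
        assert res.totals[-1] == pytest.approx(ref.totals(), rel=1e-12)

    def test_single_node_graph_equals_0d(self):
        g = PoreGraph(
            volumes=[7.0],
            centroids=np.zeros((1, 3)),
            arcs=np.empty((0, 2)),
            faces=np.empty(0),
            distances=np.empty(0),
        )
        params = BioParams(dt=300.0, k_dom=0.01)
        state = BioState(b=np.array([[0.2], [1.0], [0.0], [0.0], [0.0]]), volumes=[7.0])
        res = simulate(g, state, params, duration=3000.0)
        ref = ode0d((0.2, 1.0, 0.0, 0.0), params, 3000.0, volume=7.0)
        assert res.totals == pytest.approx(ref.totals, rel=1e-12)

    def test_total_carbon_constant(self):
        g = fixture_graph(25, seed=4)
        params = BioParams(dc=200.0, dt=60.0, k_dom=0.001)
        state = BioState.zeros(g.volumes)
        state.b[0] = place_initial_biomass(g, 0.5, n_spots=5, mode="spots", seed=0)
        state.b[1] = uniform_dom(g, 3.0)
        res = simulate(g, state, params, duration=600 * 60.0)
        totals = res.totals.sum(axis=1)
        assert np.abs(totals - totals[0]).max() / totals[0] < 1e-10

    def test_truncation_warns(self):
        g = fixture_graph(5, seed=1)
        state = BioState.zeros(g.volumes)
        with pytest.warns(UserWarning, match="truncating"):
            simulate(g, state, BioParams(dt=30.0), duration=100.0)


class TestOde0d:
    def test_geometric_biomass_decay(self):
        # v_dom = mu = 0, no SOM/FOM: DOM constant, MB *= (1 - rho dt) each step
        params = BioParams(v_dom=0.0, mu=0.0, dt=0.1 * DAY)
        res = ode0d((1.0, 0.5, 0.0, 0.0), params, 2 * DAY, volume=1.0)
        k = len(res.times) - 1
        assert res.totals[-1, 0] == pytest.approx((1 - 0.2 * 0.1) ** k)
        assert res.totals[:, 1] == pytest.approx(np.full(k + 1, 0.5))

    def test_conservation_every_step(self):
        params = BioParams(dt=600.0, k_dom=0.01)
        res = ode0d((0.18, 2.0, 0.1, 0.0), params, DAY, volume=100.0)
        sums = res.totals.sum(axis=1)
        assert np.abs(sums - sums[0]).max() / sums[0] < 1e-12

    def test_long_run_respires_almost_everything(self):
        """With DOM-rich initial conditions all pools drain into CO2 over
        multi-decade horizons (MB, DOM, SOM each end below 1% of carbon)."""
        params = BioParams(dt=120.0, k_dom=1e-6)
        duration = 10950 * DAY  # ~30 years
        res = ode0d((0.18, 2.0, 0.0, 0.0), params, duration, volume=4e4, record_every=7200)
        total0 = res.totals[0].sum()
        end = res.totals[-1]
        assert end[4] / total0 > 0.98  # CO2 absorbs nearly all carbon
        for pool in (0, 1, 2):
            assert end[pool] / total0 < 0.01


class TestPlacement:
    def test_spots_equal_split_when_all_nodes(self):
        g = PoreGraph(
            volumes=np.ones(6),
            centroids=np.zeros((6, 3)),
            arcs=np.empty((0, 2)),
            faces=np.empty(0),
            distances=np.empty(0),
        )
        b1 = place_initial_biomass(g, 1.2, n_spots=6, mode="spots", seed=0)
        assert b1 == pytest.approx(np.full(6, 0.2))

    def test_seeded_determinism(self):
        g = fixture_graph(50, seed=6)
        a = place_initial_biomass(g, 1.0, n_spots=10, mode="spots", seed=42)
        b = place_initial_biomass(g, 1.0, n_spots=10, mode="spots", seed=42)
        assert np.array_equal(a, b)
        assert (a > 0).sum() == 10

    def test_uniform_dom_equal_concentration(self):
        g = fixture_graph(20, seed=8)
        b2 = uniform_dom(g, 5.0)
        c = b2 / g.volumes
        assert c == pytest.approx(np.full(20, c[0]))
        assert b2.sum() == pytest.approx(5.0)

    def test_too_many_spots_rejected(self):
        g = fixture_graph(10, seed=0)
        with pytest.raises(ValueError, match="distinct"):
            place_initial_biomass(g, 1.0, n_spots=11, mode="spots", seed=0)

    def test_random_mode_allows_collisions(self):
        g = fixture_graph(5, seed=0)
        b1 = place_initial_biomass(g, 1.0, n_spots=50, mode="random", seed=1)
        assert b1.sum() == pytest.approx(1.0)

    def test_weights_option(self):
        g = fixture_graph(10, seed=0)
        w = np.arange(1, 4, dtype=float)
        b1 = place_initial_biomass(g, 6.0, n_spots=3, mode="spots", seed=2, weights=w)
        assert sorted(b1[b1 > 0]) == pytest.approx([1.0, 2.0, 3.0])


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            BioParams(beta=1.5)
        with pytest.raises(ValueError):
            BioParams(alpha=0.0)
        with pytest.raises(ValueError):
            BioParams(dt=-1.0)
        with pytest.raises(ValueError):
            BioParams(rho=-0.1)
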