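import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trustdyn as td
from trustdyn.errors import (
    ConfigurationError,
    IntegrationError,
    ParameterError,
    StabilityError,
)
from trustdyn.network import (
    LAYER_EXC,
    LAYER_FB_INH,
    LAYER_FF_INH,
    compute_delays,
    delays_to_steps,
)


class TestGain:
    def test_limits_and_midpoint(self):
        assert td.gain(-1e6, 6.0) == pytest.approx(0.0, abs=1e-12)
        assert td.gain(1e6, 6.0) == pytest.approx(6.0, abs=1e-12)
        # C*Q*(1 - exp(-e)) at u = 0 reduces to C*Q*(1 - 1/e)
        assert td.gain(0.0, 6.0) == pytest.approx(6.0 * (1 - np.exp(-1)), rel=1e-12)

    @pytest.mark.parametrize("q,c", [(0.0, 1.0), (-2.0, 1.0), (6.0, 0.0), (6.0, -1.0)])
    def test_invalid_parameters(self, q, c):
        with pytest.raises(ParameterError):
            td.gain(0.0, q, c)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        u=st.floats(-10, 10),
        du=st.floats(1e-3, 5),
        q=st.floats(3, 20),
        c=st.floats(0.1, 5),
    )
    def test_strictly_monotone_in_responsive_range(self, u, du, q, c):
        lo, hi = td.gain(u, q, c), td.gain(u + du, q, c)
        assert lo < hi
        assert 0.0 <= lo and hi < c * q + 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        u=st.floats(-1e4, 1e4),
        du=st.floats(0, 1e4),
        q=st.floats(0.5, 20),
        c=st.floats(0.1, 5),
    )
    def test_nondecreasing_and_bounded_everywhere(self, u, du, q, c):
        lo, hi = td.gain(u, q, c), td.gain(u + du, q, c)
        assert lo <= hi
        assert 0.0 <= lo and hi <= c * q


class TestGeometry:
    def test_unit_accounting(self, default_geometry):
        geo = default_geometry
        assert geo.n_units == 450
        for s in geo.structures:
            assert len(geo.units(structure=s, layer=LAYER_EXC)) == 100
            assert len(geo.units(structure=s, layer=LAYER_FF_INH)) == 25
            assert len(geo.units(structure=s, layer=LAYER_FB_INH)) == 25

    def test_single_structure_count(self):
        assert td.build_geometry(structures=("OFC",)).n_units == 150

    def test_max_excitatory_distance(self, default_geometry):
        geo = default_geometry
        exc = geo.units(structure="OFC", layer=LAYER_EXC)
        d = geo.distances()[np.ix_(exc, exc)]
        # brute force over all pairs: opposite corners of the 10x10 grid
        assert d.max() == pytest.approx(np.sqrt(162.0), rel=1e-12)
        assert (np.diag(d) == 0).all()
        assert (d >= 0).all()

    def test_non_square_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            td.build_geometry(n_excitatory=90)
        with pytest.raises(ConfigurationError):
            td.build_geometry(n_inhibitory=24)


class TestDelays:
    def test_synaptic_and_axonal_delays(self, default_geometry):
        geo = default_geometry
        delays = compute_delays(geo, t_syn=0.8, v_ee=0.5)
        exc = geo.units(structure="OFC", layer=LAYER_EXC)
        inh = geo.units(structure="OFC", layer=LAYER_FB_INH)
        # inhibitory-involving connections: synaptic delay only
        assert delays[inh[0], exc[0]] == pytest.approx(0.8)
        # nearest-neighbour excitatory pair: 0.8 + 1 mm / 0.5 m/s = 2.8 ms
        d = geo.distances()[np.ix_(exc, exc)]
        i, j = np.argwhere(np.isclose(d, 1.0))[0]
        assert delays[exc[i], exc[j]] == pytest.approx(2.8)
        # most distant excitatory pair (brute force)
        i, j = np.unravel_index(np.nanargmax(d), d.shape)
        assert delays[exc[i], exc[j]] == pytest.approx(0.8 + np.sqrt(162.0) / 0.5)

    def test_rounding_to_steps(self):
        steps = delays_to_steps(np.array([[0.8, 2.8], [0.2, 26.26]]), dt=1.0)
        assert steps.tolist() == [[1, 3], [1, 26]]

    def test_invalid_parameters(self, default_geometry):
        with pytest.raises(ParameterError):
            compute_delays(default_geometry, t_syn=-1.0)
        with pytest.raises(ParameterError):
            compute_delays(default_geometry, v_ee=0.0)


class TestInitWeights:
    def test_bounds_and_no_self_connections(self, default_geometry):
        conn = td.init_weights(default_geometry, seed=3)
        assert conn.weights.min() >= 0.0
        assert conn.weights.max() <= 1.0
        assert (np.diag(conn.weights) == 0).all()

    def test_seeded_determinism(self, default_geometry):
        a = td.init_weights(default_geometry, seed=11)
        b = td.init_weights(default_geometry, seed=11)
        c = td.init_weights(default_geometry, seed=12)
        assert np.array_equal(a.weights, b.weights)
        assert not np.array_equal(a.weights, c.weights)

    def test_exponential_distance_decay(self, default_geometry):
        # Monte-Carlo oracle: mean weight at d = 5 mm over many seeds equals
        # e^{-4/5} x mean weight at d = 1 mm (the |N(0,1)| factor cancels)
        geo = default_geometry
        d = geo.distances()
        exc = geo.excitatory_mask
        ee = exc[:, None] & exc[None, :]
        near = ee & np.isclose(d, 1.0)
        far = ee & np.isclose(d, 5.0)
        near_sum = far_sum = 0.0
        for seed in range(30):
            w = td.init_weights(geo, seed=seed).weights
            near_sum += w[near].mean()
            far_sum += w[far].mean()
        assert far_sum / near_sum == pytest.approx(np.exp(-4.0 / 5.0), rel=0.05)

    def test_sign_follows_presynaptic_layer(self, default_geometry):
        conn = td.init_weights(default_geometry, seed=0)
        exc = default_geometry.excitatory_mask
        assert (conn.sign[exc] == 1.0).all()
        assert (conn.sign[~exc] == -1.0).all()


class TestEulerStep:
    def test_pure_decay(self):
        u1 = td.euler_step(1.0, 10.0, 0.0, 0.0, 0.0, 1.0)
        assert u1 == pytest.approx(0.9)
        u = 1.0
        for _ in range(10):
            u = td.euler_step(u, 10.0, 0.0, 0.0, 0.0, 1.0)
        # first-order Euler error relative to the analytic exponential
        assert u == pytest.approx(0.9**10)
        assert abs(u - np.exp(-1)) < 0.025

    def test_fixed_point(self):
        assert td.euler_step(0.0, 10.0, 0.0, 0.0, 0.0, 1.0) == 0.0

    def test_stability_guard(self):
        with pytest.raises(StabilityError):
            td.euler_step(1.0, 5.0, 0.0, 0.0, 0.0, 5.0)

    def test_convergence_order(self):
        # halving dt approximately halves the error against exp(-1)
        def error(dt):
            u, t = 1.0, 0.0
            while t < 10.0 - 1e-9:
                u = td.euler_step(u, 10.0, 0.0, 0.0, 0.0, dt)
                t += dt
            return abs(u - np.exp(-1))

        ratio = error(0.5) / error(1.0)
        assert 0.35 < ratio < 0.65


@pytest.fixture(scope="module")
def small_network(default_geometry):
    conn = td.init_weights(default_geometry, seed=0)
    return td.Network(default_geometry, conn)


class TestRunTrial:
    def test_null_dynamics(self, default_geometry):
        conn = td.init_weights(default_geometry, seed=0)
        conn.weights[:] = 0.0
        net = td.Network(default_geometry, conn)
        trace = net.run_trial([], td.IntegrationConfig(duration=50.0, transient=0.0))
        assert np.all(trace.u == 0.0)
        assert trace.n_steps == 50

    def test_trace_shape(self, small_network):
        cfg = td.IntegrationConfig(duration=300.0, transient=100.0)
        trace = small_network.run_trial([], cfg)
        assert trace.u.shape == (300, 450)
        assert trace.g.shape == (300, 450)

    def test_bit_reproducible_with_noise(self, small_network):
        cfg = td.IntegrationConfig(duration=100.0, transient=0.0)
        noise = td.NoiseSpec(sd=0.5, seed=42)
        a = small_network.run_trial([], cfg, noise=noise)
        b = small_network.run_trial([], cfg, noise=noise)
        assert np.array_equal(a.u, b.u)

    def test_divergence_reported_with_step(self, small_network):
        drives = [td.Drive(np.arange(10), np.nan)]
        with pytest.raises(IntegrationError) as err:
            small_network.run_trial(drives, td.IntegrationConfig(duration=20.0, transient=0.0))
        assert err.value.step == 0

    def test_trace_frame_columns(self, small_network):
        cfg = td.IntegrationConfig(duration=5.0, transient=0.0)
        frame = small_network.run_trial([], cfg).to_frame()
        assert list(frame.columns) == ["time_ms", "unit_id", "u", "g"]
        assert len(frame) == 5 * 450
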