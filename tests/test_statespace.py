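"""Tissue-circuit state-space model: passivity, inversion, discretization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbgnet import statespace as ss
from nbgnet.errors import SingularMatrixError, ValidationError

log_param = st.floats(min_value=-2.0, max_value=2.0)


def _random_circuit(rng):
    # log-uniform spread around the defaults
    base = ss.TissueCircuitParams()
    scale = lambda: 10 ** rng.uniform(-1.5, 1.5)
    return ss.TissueCircuitParams(
        r_cortex=base.r_cortex * scale(),
        r_dura=base.r_dura * scale(),
        c_dura=base.c_dura * scale(),
        r_compact1=base.r_compact1 * scale(),
        r_compact2=base.r_compact2 * scale(),
        r_trabecular=base.r_trabecular * scale(),
        c_spongy=base.c_spongy * scale(),
        c_interface=base.c_interface * scale(),
    )


class TestCircuitToStatespace:
    def test_three_states_and_labels(self):
        model = ss.circuit_to_statespace(ss.TissueCircuitParams())
        assert model.n_states == 3
        assert model.state_labels == ("C_dura", "C_spongy", "C_interface")

    def test_passivity_hurwitz_over_random_parameters(self):
        """An RC ladder is dissipative: A is Hurwitz for any positive values."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            model = ss.circuit_to_statespace(_random_circuit(rng))
            assert np.all(np.linalg.eigvals(model.a).real < 0)

    def test_dc_gain_is_resistive_divider(self):
        """With capacitors in steady state the gain is the resistive divider."""
        p = ss.TissueCircuitParams()
        expected = p.r_trabecular / (p.r_cortex + p.r_compact1 + p.r_dura + p.r_trabecular)
        model = ss.circuit_to_statespace(p)
        assert model.dc_gain()[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_large_dura_capacitance_shorts_the_dura(self):
        """C_dura -> inf pins the dura voltage: divider of the series resistances."""
        p = ss.TissueCircuitParams(c_dura=1e6)
        model = ss.circuit_to_statespace(p)
        # at any nonzero frequency the huge capacitor is a short
        h = model.frequency_response(2 * np.pi * 1.0)[0, 0]
        expected = p.r_trabecular / (p.r_cortex + p.r_compact1 + p.r_trabecular)
        assert abs(h) == pytest.approx(expected, rel=1e-3)

    def test_step_response_matches_rk4_oracle(self):
        """Unit-step output agrees with dense RK4 integration of the ODE."""
        model = ss.circuit_to_statespace(ss.TissueCircuitParams())
        dt = 1e-5
        t_len = 20000
        a, b, c = model.a, model.b[:, 0], model.c

        def f(x):
            return a @ x + b  # u = 1

        x = np.zeros(3)
        y_rk4 = np.empty(t_len)
        for t in range(t_len):
            y_rk4[t] = (c @ x)[0]
            k1 = f(x)
            k2 = f(x + 0.5 * dt * k1)
            k3 = f(x + 0.5 * dt * k2)
            k4 = f(x + dt * k3)
            x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        dss = ss.discretize(model, dt, scheme="zoh")
        y_zoh = ss.simulate_statespace(dss, np.ones((1, t_len)))
        assert np.max(np.abs(y_zoh[0] - y_rk4)) < 1e-8
        # approaches the DC gain from below, bounded
        assert y_zoh[0, -1] == pytest.approx(model.dc_gain()[0, 0], rel=1e-3)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValidationError):
            ss.TissueCircuitParams(r_cortex=-1.0)
        with pytest.raises(ValidationError):
            ss.TissueCircuitParams(c_spongy=0.0)


class TestInvert:
    def test_scalar_static_gain(self):
        model = ss.StateSpaceModel(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)), [[2.0]])
        inv = ss.invert_statespace(model)
        assert inv.d[0, 0] == pytest.approx(0.5)

    def test_double_inversion_round_trip(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n, m = 4, 2
            # well-conditioned D: orthogonal factors, singular values in [1, 2]
            q1, _ = np.linalg.qr(rng.normal(size=(m, m)))
            q2, _ = np.linalg.qr(rng.normal(size=(m, m)))
            d = q1 @ np.diag(rng.uniform(1.0, 2.0, size=m)) @ q2
            model = ss.StateSpaceModel(
                rng.normal(size=(n, n)),
                rng.normal(size=(n, m)),
                rng.normal(size=(m, n)),
                d,
            )
            twice = ss.invert_statespace(ss.invert_statespace(model))
            for attr in ("a", "b", "c", "d"):
                np.testing.assert_allclose(
                    getattr(twice, attr), getattr(model, attr), atol=1e-12
                )

    def test_forward_then_inverse_reconstructs_input(self):
        """Composing the discrete model with its algebraic inverse is the identity."""
        rng = np.random.default_rng(5)
        model = ss.StateSpaceModel(
            -np.eye(3) * 50 + rng.normal(size=(3, 3)),
            rng.normal(size=(3, 2)),
            rng.normal(size=(2, 3)),
            rng.normal(size=(2, 2)) + 2 * np.eye(2),
        )
        dss = ss.discretize(model, 1e-3, scheme="euler")
        inv = ss.invert_discrete(dss)
        t = np.arange(2000) * 1e-3
        u = np.vstack([np.sin(2 * np.pi * 3 * t), np.cos(2 * np.pi * 5 * t)])
        y = ss.simulate_statespace(dss, u)
        u_rec = ss.simulate_statespace(inv, y)
        rel = np.sqrt(np.mean((u - u_rec) ** 2)) / np.sqrt(np.mean(u**2))
        assert rel < 1e-6

    def test_zero_d_raises_named_singularity(self):
        model = ss.StateSpaceModel(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)), [[0.0]])
        with pytest.raises(SingularMatrixError, match="singular value"):
            ss.invert_statespace(model)

    def test_singular_d_without_regularization_raises(self):
        model = ss.StateSpaceModel(
            np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)), [[1.0, 0.0], [0.0, 0.0]]
        )
        with pytest.raises(SingularMatrixError, match="singular"):
            ss.invert_statespace(model, regularize=False)


class TestDiscretize:
    def test_zero_a_gives_identity_under_both_schemes(self):
        model = ss.StateSpaceModel(np.zeros((2, 2)), np.eye(2), np.eye(2), np.zeros((2, 2)))
        for scheme in ("euler", "zoh"):
            dss = ss.discretize(model, 0.1, scheme=scheme)
            np.testing.assert_allclose(dss.ad, np.eye(2), atol=1e-15)

    def test_scalar_zoh_closed_form(self):
        a = 3.7
        model = ss.StateSpaceModel([[-a]], [[1.0]], [[1.0]], [[0.0]])
        dss = ss.discretize(model, 0.01, scheme="zoh")
        assert dss.ad[0, 0] == pytest.approx(np.exp(-a * 0.01), rel=1e-12)

    def test_euler_first_order_convergence_to_zoh(self):
        """Halving dt roughly halves the euler-vs-zoh output error."""
        model = ss.circuit_to_statespace(ss.TissueCircuitParams())
        errs = []
        for dt in (2e-4, 1e-4):
            n = int(0.2 / dt)
            t = np.arange(n) * dt
            u = np.sin(2 * np.pi * 10 * t)[None, :]
            y_e = ss.simulate_statespace(ss.discretize(model, dt, "euler"), u)
            y_z = ss.simulate_statespace(ss.discretize(model, dt, "zoh"), u)
            errs.append(np.sqrt(np.mean((y_e - y_z) ** 2)))
        ratio = errs[0] / errs[1]
        assert 1.5 < ratio < 2.5

    def test_euler_instability_recorded_as_warning(self):
        model = ss.StateSpaceModel([[-3000.0]], [[1.0]], [[1.0]], [[0.0]])
        with pytest.warns(UserWarning, match="unstable"):
            dss = ss.discretize(model, 1e-3, scheme="euler")
        assert dss.warnings and not dss.stable


class TestSimulate:
    def test_zero_input_zero_state_gives_zero(self, small_transfer):
        y = ss.simulate_statespace(small_transfer, np.zeros((6, 50)))
        assert np.all(y == 0)

    def test_superposition(self, small_transfer, rng):
        u1 = rng.normal(size=(6, 200))
        u2 = rng.normal(size=(6, 200))
        lhs = ss.simulate_statespace(small_transfer, 2.0 * u1 - 3.0 * u2)
        rhs = 2.0 * ss.simulate_statespace(small_transfer, u1) - 3.0 * ss.simulate_statespace(
            small_transfer, u2
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_impulse_response_of_rc_matches_exponential(self):
        rc = 0.02
        model = ss.StateSpaceModel([[-1.0 / rc]], [[1.0 / rc]], [[1.0]], [[0.0]])
        dt = 1e-3
        dss = ss.discretize(model, dt, scheme="zoh")
        u = np.zeros((1, 100))
        u[0, 0] = 1.0
        y = ss.simulate_statespace(dss, u)
        t_idx = np.arange(1, 100)
        expected = (1 - np.exp(-dt / rc)) * np.exp(-(t_idx - 1) * dt / rc)
        np.testing.assert_allclose(y[0, 1:], expected, atol=1e-10)
        assert y[0, 0] == 0.0  # no feedthrough


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_assembled_transfer_block_structure(seed):
    """Multi-channel assembly: block-diagonal A, one tissue block per output."""
    rng = np.random.default_rng(seed)
    w = rng.normal(size=(2, 5))
    block = ss.circuit_to_statespace(ss.TissueCircuitParams())
    model = ss.assemble_transfer(block, w, feedthrough_gain=0.1)
    assert model.n_states == 6 and model.n_inputs == 5 and model.n_outputs == 2
    np.testing.assert_allclose(model.a[:3, 3:], 0.0)
    np.testing.assert_allclose(model.a[3:, :3], 0.0)
    np.testing.assert_allclose(model.d, 0.1 * w)  # tissue block has no feedthrough
    # each output block sees all inputs through its mixing row
    np.testing.assert_allclose(model.b[:3, :], block.b @ w[:1, :])
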