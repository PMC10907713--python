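"""Bond-graph network core: init, step/rollout contracts, gradients, connectivity."""

import numpy as np
import pytest

from nbgnet import network as net
from nbgnet import statespace as ss
from nbgnet import synthetic as syn
from nbgnet._training import TrainConfig
from nbgnet.errors import DivergenceError, ValidationError

ARCH = net.NBGNetArch(n_in=3, n_out=2, dt=1.0, mlp_hidden=7)


class TestInit:
    def test_seed_determinism(self):
        p1 = net.init_nbgnet(ARCH, seed=5)
        p2 = net.init_nbgnet(ARCH, seed=5)
        np.testing.assert_array_equal(p1.to_vector(), p2.to_vector())
        assert not np.array_equal(p1.to_vector(), net.init_nbgnet(ARCH, seed=6).to_vector())

    def test_glorot_support_bound(self):
        p = net.init_nbgnet(ARCH, seed=0)
        d, nh = ARCH.mlp_input_dim, ARCH.mlp_hidden
        lim1 = np.sqrt(6.0 / (d + nh))
        lim2 = np.sqrt(6.0 / (nh + 1))
        assert np.max(np.abs(p.w1f)) <= lim1 and np.max(np.abs(p.w1g)) <= lim1
        assert np.max(np.abs(p.w2f)) <= lim2 and np.max(np.abs(p.w2g)) <= lim2
        assert np.all(p.b1f == 0) and np.all(p.b2g == 0)

    def test_sample_mean_matches_uniform_moments(self):
        big = net.NBGNetArch(n_in=100, n_out=40, dt=1.0)
        p = net.init_nbgnet(big, seed=1)
        w = np.concatenate([p.w1f.ravel(), p.w1g.ravel()])
        assert w.size > 1e5
        lim = np.sqrt(6.0 / (big.mlp_input_dim + big.mlp_hidden))
        sd = lim / np.sqrt(3.0)
        assert abs(w.mean()) < 3 * sd / np.sqrt(w.size)


class TestStepAndRollout:
    def test_zero_everything_outputs_zero(self):
        p = net.init_nbgnet(ARCH, seed=0)
        for w in p.weights():
            w[...] = 0.0
        y, q_next = net.nbgnet_step(p, np.zeros(6), np.zeros(3))
        assert np.all(y == 0) and np.all(q_next == 0)

    def test_tanh_saturation_keeps_outputs_finite(self):
        p = net.init_nbgnet(ARCH, seed=0)
        y, q_next = net.nbgnet_step(p, np.zeros(6), np.full(3, 1e6))
        assert np.all(np.isfinite(y)) and np.all(np.isfinite(q_next))

    def test_causality_future_samples_do_not_matter(self, rng):
        p = net.init_nbgnet(ARCH, seed=2)
        u = rng.normal(size=(3, 100))
        u_cut = u.copy()
        u_cut[:, 60:] = 0.0
        y_full, _ = net.nbgnet_rollout(p, u)
        y_cut, _ = net.nbgnet_rollout(p, u_cut)
        np.testing.assert_array_equal(y_full[:, :60], y_cut[:, :60])

    def test_divergence_reports_step_index(self):
        p = net.init_nbgnet(net.NBGNetArch(n_in=1, n_out=1, dt=1.0, activation="identity"), seed=0)
        # unstable identity-activation dynamics: q <- 3q
        p.w1f[...] = 0.0
        p.w1f[0, :, 0, 0] = 2.0  # dq_k = 2 q_0 + u
        p.w1f[0, :, 0, 3] = 1.0  # input drive (z index ns..ns+m)
        p.w2f[...] = 0.0
        p.w2f[:, :, 0] = 1.0
        p.w1g[...] = 0.0
        p.w1g[0, 0, 0] = 1e300
        p.w2g[...] = 0.0
        p.w2g[0, 0] = 1e300
        with pytest.raises(DivergenceError, match="step"):
            net.nbgnet_rollout(p, np.ones((1, 2000)))

    def test_input_dimension_checked(self, rng):
        p = net.init_nbgnet(ARCH, seed=0)
        with pytest.raises(ValidationError):
            net.nbgnet_rollout(p, rng.normal(size=(4, 10)))


class TestLinearEmbedding:
    @pytest.mark.parametrize("dt", [1.0, 1e-3])
    def test_identity_activation_reproduces_euler_statespace(self, dt, rng):
        block = ss.circuit_to_statespace(ss.TissueCircuitParams())
        model = ss.assemble_transfer(block, rng.normal(size=(2, 3)), feedthrough_gain=0.2)
        dss = ss.discretize(model, 1e-3, scheme="euler")
        arch = net.NBGNetArch(n_in=3, n_out=2, dt=dt, activation="identity")
        # express the euler update in the network's own step units
        emb_source = ss.DiscreteStateSpace(dss.ad, dss.bd, dss.cd, dss.dd, dt=dt)
        p = net.embed_linear(arch, emb_source)
        u = rng.normal(size=(3, 400))
        y_net, _ = net.nbgnet_rollout(p, u)
        y_ss = ss.simulate_statespace(dss, u)
        assert np.sqrt(np.mean((y_net - y_ss) ** 2)) < 1e-10

    def test_single_step_matches_euler_step(self, rng):
        block = ss.circuit_to_statespace(ss.TissueCircuitParams())
        model = ss.assemble_transfer(block, rng.normal(size=(1, 2)), feedthrough_gain=0.1)
        dss = ss.discretize(model, 1e-3, scheme="euler")
        arch = net.NBGNetArch(n_in=2, n_out=1, dt=1.0, activation="identity")
        p = net.embed_linear(arch, ss.DiscreteStateSpace(dss.ad, dss.bd, dss.cd, dss.dd, dt=1.0))
        x = rng.normal(size=3)
        u = rng.normal(size=2)
        y, q_next = net.nbgnet_step(p, x, u)
        y_exp = dss.cd @ x + dss.dd @ u
        x_exp = dss.ad @ x + dss.bd @ u
        np.testing.assert_allclose(y, y_exp, atol=1e-12)
        np.testing.assert_allclose(q_next.ravel(), x_exp, atol=1e-12)

    def test_equilibrium_constant_input_constant_output(self):
        """Starting at the fixed point of a stable linear embedding, a constant
        input yields a constant output."""
        block = ss.circuit_to_statespace(ss.TissueCircuitParams())
        model = ss.assemble_transfer(block, np.array([[1.0]]), feedthrough_gain=0.1)
        dss = ss.discretize(model, 1e-3, scheme="euler")
        arch = net.NBGNetArch(n_in=1, n_out=1, dt=1.0, activation="identity")
        p = net.embed_linear(arch, ss.DiscreteStateSpace(dss.ad, dss.bd, dss.cd, dss.dd, dt=1.0))
        u0 = 0.7
        q_star = np.linalg.solve(np.eye(3) - dss.ad, dss.bd[:, 0] * u0)
        y, _ = net.nbgnet_rollout(p, np.full((1, 200), u0), q0=q_star)
        np.testing.assert_allclose(y, y[0, 0], atol=1e-9)


class TestGradient:
    @pytest.mark.parametrize("activation", ["tanh", "identity"])
    def test_bptt_matches_central_finite_differences(self, activation, rng):
        arch = net.NBGNetArch(n_in=2, n_out=2, dt=0.7, mlp_hidden=3, activation=activation)
        p = net.init_nbgnet(arch, seed=3)
        model = net._NBGModel(p)
        u = rng.normal(size=(2, 9))
        yt = rng.normal(size=(2, 9))
        _, grad = model.loss_and_grad(u, yt, rng)
        vec = p.to_vector()
        eps = 1e-6
        fd = np.empty_like(vec)
        for i in range(vec.size):
            v = vec.copy()
            v[i] += eps
            p.from_vector(v)
            lp = model.loss(u, yt)
            v[i] -= 2 * eps
            p.from_vector(v)
            lm = model.loss(u, yt)
            fd[i] = (lp - lm) / (2 * eps)
        p.from_vector(vec)
        assert np.linalg.norm(grad - fd) / np.linalg.norm(fd) < 1e-6


@pytest.fixture(scope="module")
def tiny_session():
    transfer = syn.default_transfer(n_fine=3, n_coarse=2, fs=500.0, seed=3)
    cfg = syn.SimConfig(
        n_fine=3, n_coarse=2, n_trials=12, fs=500.0, trial_length=1.0, seed=8
    )
    return syn.simulate_session(cfg, transfer)


class TestTraining:
    def test_history_determinism(self, tiny_session):
        cfg = TrainConfig(max_updates=60, seed=4)
        runs = []
        for _ in range(2):
            p = net.init_nbgnet(net.NBGNetArch(n_in=3, n_out=2, dt=1.0), seed=4)
            _, hist = net.train_nbgnet(p, tiny_session, "forward", cfg)
            runs.append([l for _, l in hist.train_loss])
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_returned_params_no_worse_than_init(self, tiny_session):
        cfg = TrainConfig(max_updates=100, seed=0)
        p = net.init_nbgnet(net.NBGNetArch(n_in=3, n_out=2, dt=1.0), seed=0)
        _, hist = net.train_nbgnet(p, tiny_session, "forward", cfg)
        assert hist.best_val <= hist.val_loss[0][1]

    def test_zero_target_drives_outputs_to_zero(self, tiny_session):
        sess = syn.RecordingSession(
            fine=tiny_session.fine,
            coarse=np.zeros_like(tiny_session.coarse),
            fs=tiny_session.fs,
            labels=tiny_session.labels,
            channel_meta=tiny_session.channel_meta,
        )
        arch = net.NBGNetArch(n_in=3, n_out=2, dt=1.0)
        p = net.init_nbgnet(arch, seed=1)
        init_rms = np.sqrt(np.mean(net.predict(p, sess.fine[0]) ** 2))
        trained, hist = net.train_nbgnet(p, sess, "forward", TrainConfig(max_updates=600, seed=1))
        pred = net.predict(trained, sess.fine[0])
        # constant-zero targets: outputs shrink toward zero, loss collapses
        assert np.sqrt(np.mean(pred**2)) < 0.25 * init_rms
        assert hist.best_val < 0.1 * hist.val_loss[0][1]

    def test_linear_session_identity_activation_recovers(self):
        """Noise-free linear transfer + identity activations: near-exact recovery."""
        transfer = syn.default_transfer(n_fine=3, n_coarse=2, fs=500.0, seed=3)
        cfg = syn.SimConfig(
            n_fine=3, n_coarse=2, n_trials=12, fs=500.0, trial_length=1.0,
            noise_sd=0.0, nonlinearity_gain=0.0, seed=9,
        )
        sess = syn.simulate_session(cfg, transfer)
        arch = net.NBGNetArch(n_in=3, n_out=2, dt=1.0, activation="identity")
        p = net.init_nbgnet(arch, seed=2)
        trained, hist = net.train_nbgnet(
            p, sess, "forward",
            TrainConfig(max_updates=30000, seed=2, lr=5e-3, window_samples=250, patience=10000),
        )
        k = int(hist.val_idx[0])
        pred = net.predict(trained, sess.fine[k])
        rel = np.sqrt(np.mean((pred - sess.coarse[k]) ** 2)) / np.sqrt(np.mean(sess.coarse[k] ** 2))
        assert rel < 1e-3

    def test_too_few_trials_rejected(self, tiny_session):
        short = syn.RecordingSession(
            fine=tiny_session.fine[:5],
            coarse=tiny_session.coarse[:5],
            fs=tiny_session.fs,
            labels=tiny_session.labels[:5],
            channel_meta=tiny_session.channel_meta,
        )
        p = net.init_nbgnet(net.NBGNetArch(n_in=3, n_out=2, dt=1.0), seed=0)
        with pytest.raises(ValidationError, match="10 trials"):
            net.train_nbgnet(p, short, "forward", TrainConfig(max_updates=10))


class TestEffectiveConnectivity:
    def test_zero_weights_give_zero_connectivity(self, rng):
        p = net.init_nbgnet(ARCH, seed=0)
        for w in p.weights():
            w[...] = 0.0
        ec = net.effective_connectivity(p, [rng.normal(size=(3, 50))])
        np.testing.assert_array_equal(ec.w, 0.0)

    def test_linear_embedding_sensitivity_is_feedthrough(self, rng):
        """For a linear network the instantaneous input->output Jacobian is D."""
        block = ss.circuit_to_statespace(ss.TissueCircuitParams())
        mix = rng.normal(size=(2, 3))
        model = ss.assemble_transfer(block, mix, feedthrough_gain=0.5)
        dss = ss.discretize(model, 1e-3, scheme="euler")
        arch = net.NBGNetArch(n_in=3, n_out=2, dt=1.0, activation="identity")
        p = net.embed_linear(arch, ss.DiscreteStateSpace(dss.ad, dss.bd, dss.cd, dss.dd, dt=1.0))
        ec = net.effective_connectivity(p, [rng.normal(size=(3, 80))])
        np.testing.assert_allclose(ec.w, dss.dd.T, atol=1e-10)
        # sign pattern matches the static gain when feedthrough dominates
        static = dss.dd + dss.cd @ np.linalg.solve(np.eye(6) - dss.ad, dss.bd)
        assert np.all(np.sign(ec.w) == np.sign(static.T))

    def test_analytic_matches_finite_differences(self, rng):
        """On a single-sample trial both routes average the same time point."""
        p = net.init_nbgnet(ARCH, seed=7)
        u = rng.normal(size=(3, 1))
        w_an = net.effective_connectivity(p, [u], method="analytic").w
        w_fd = net.effective_connectivity(p, [u], method="fd").w
        assert np.max(np.abs(w_an - w_fd)) / np.max(np.abs(w_an)) < 1e-4

    def test_fd_and_analytic_jacobians_agree_pointwise(self, rng):
        """At matched time points the two sensitivity routes agree to 1e-4."""
        p = net.init_nbgnet(ARCH, seed=9)
        u = rng.normal(size=(3, 40))
        w_an = net._instantaneous_jacobian(p, u[:, :1])
        w_fd = net._fd_jacobian(p, u[:, :1], stride=1)
        assert np.max(np.abs(w_an - w_fd)) / max(np.max(np.abs(w_an)), 1e-12) < 1e-4

    def test_grouping_by_target(self, rng):
        p = net.init_nbgnet(ARCH, seed=1)
        trials = [rng.normal(size=(3, 30)) for _ in range(6)]
        ec = net.effective_connectivity(p, trials, group_by=np.array([1, 1, 2, 2, 3, 3]))
        assert set(ec.per_group) == {1, 2, 3}
        np.testing.assert_allclose(
            np.mean([ec.per_group[g] for g in (1, 2, 3)], axis=0), ec.w, atol=1e-12
        )

    def test_state_jacobian_identity_at_zero_weights(self, rng):
        p = net.init_nbgnet(ARCH, seed=0)
        for w in p.weights():
            w[...] = 0.0
        j = net.state_jacobian(p, rng.normal(size=(3, 20)))
        for b in range(ARCH.n_out):
            np.testing.assert_allclose(j[b], np.eye(3), atol=1e-12)


class TestCheckpointRoundTrip:
    def test_bit_exact_model_io(self, tmp_path):
        from nbgnet import io as nio

        p = net.init_nbgnet(ARCH, seed=11)
        p.in_mean = np.arange(3.0)
        p.in_std = np.ones(3)
        p.out_mean = np.zeros(2)
        p.out_std = np.full(2, 2.0)
        path = tmp_path / "model.h5"
        nio.save_model(p, path)
        q = nio.load_model(path)
        assert q.arch == p.arch
        np.testing.assert_array_equal(q.to_vector(), p.to_vector())
        np.testing.assert_array_equal(q.in_mean, p.in_mean)
        np.testing.assert_array_equal(q.out_std, p.out_std)
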