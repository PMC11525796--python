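"""LSN layer, masked layers, Wasserstein losses, gradient penalty, autodiff."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scgrnsim import nn
from scgrnsim.nn import Tensor, autodiff as ad


class TestLsn:
    def test_proportional_example(self):
        out, scale = nn.LsnLayer(20_000)(Tensor([[1.0, 3.0]]))
        assert np.allclose(out.data, [[5000.0, 15000.0]])
        assert np.allclose(scale, [5000.0])

    def test_uniform_row(self):
        out, _ = nn.LsnLayer(20_000)(Tensor(np.full((1, 8), 3.0)))
        assert np.allclose(out.data, 20_000 / 8)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_sums_and_proportions(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.gamma(1.0, 1.0, size=(5, 7)) + 1e-3
        out, scale = nn.LsnLayer(20_000)(Tensor(x))
        assert np.allclose(out.data.sum(axis=1), 20_000, rtol=1e-9)
        assert np.allclose(out.data / out.data.sum(1, keepdims=True),
                           x / x.sum(1, keepdims=True))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            nn.LsnLayer(100)(Tensor([[1.0, -0.5]]))

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            nn.LsnLayer(100)(Tensor([[0.0, 0.0]]))


class TestWasserstein:
    def test_arithmetic_example(self):
        c, g = nn.wasserstein_losses(Tensor([1.0, 1.0]), Tensor([0.0, 0.0]))
        assert c.item() == -1.0 and g.item() == 0.0

    def test_identical_distributions_zero(self):
        s = Tensor([0.3, -0.2, 1.1])
        c, _ = nn.wasserstein_losses(s, Tensor(s.data.copy()))
        assert c.item() == pytest.approx(0.0)

    def test_better_fakes_lower_generator_loss(self):
        # sign convention via a linear critic: raising fake scores must
        # decrease the generator loss
        _, g_lo = nn.wasserstein_losses(Tensor([0.0]), Tensor([1.0, 2.0]))
        _, g_hi = nn.wasserstein_losses(Tensor([0.0]), Tensor([3.0, 4.0]))
        assert g_hi.item() < g_lo.item()

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            nn.wasserstein_losses(Tensor(np.empty(0)), Tensor([1.0]))


class TestGradientPenalty:
    def test_unit_gradient_critic_gives_zero(self):
        u = np.array([[0.6], [0.8]])  # ||u|| = 1
        critic = lambda t: ad.matmul(t, Tensor(u))
        rng = np.random.default_rng(0)
        gp = nn.gradient_penalty(
            critic, Tensor(rng.normal(size=(9, 2))),
            Tensor(rng.normal(size=(9, 2))), lam=10.0, rng=rng,
        )
        assert gp.item() == pytest.approx(0.0, abs=1e-12)

    def test_constant_critic_gives_lambda(self):
        critic = lambda t: ad.tsum(t, axis=1, keepdims=True) * 0.0
        rng = np.random.default_rng(1)
        gp = nn.gradient_penalty(
            critic, Tensor(rng.normal(size=(6, 3))),
            Tensor(rng.normal(size=(6, 3))), lam=10.0, rng=rng,
        )
        assert gp.item() == pytest.approx(10.0, rel=1e-5)

    def test_seeded_determinism_and_shape_check(self):
        rng_data = np.random.default_rng(2)
        real = Tensor(rng_data.normal(size=(4, 3)))
        fake = Tensor(rng_data.normal(size=(4, 3)))
        w = Tensor(rng_data.normal(size=(3, 1)), requires_grad=True)
        critic = lambda t: ad.matmul(ad.relu(t), w)
        a = nn.gradient_penalty(critic, real, fake, rng=np.random.default_rng(5))
        b = nn.gradient_penalty(critic, real, fake, rng=np.random.default_rng(5))
        assert a.item() == b.item()
        with pytest.raises(ValueError, match="shape"):
            nn.gradient_penalty(critic, real, Tensor(np.zeros((3, 3))))

    def test_penalty_gradient_matches_finite_differences(self):
        # the double-backprop path: d(penalty)/d(critic weight)
        rng = np.random.default_rng(3)
        w = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        v = Tensor(rng.normal(size=(4, 1)), requires_grad=True)
        critic = lambda t: ad.matmul(ad.relu(ad.matmul(t, w)), v)
        real = Tensor(rng.normal(size=(6, 3)))
        fake = Tensor(rng.normal(size=(6, 3)))
        gp_fn = lambda: nn.gradient_penalty(
            critic, real, fake, lam=10.0, rng=np.random.default_rng(42)
        )
        nn.backward(gp_fn(), [w, v])
        analytic = w.grad.data[1, 2]
        eps, orig = 1e-6, w.data[1, 2]
        w.data[1, 2] = orig + eps
        hi = gp_fn().item()
        w.data[1, 2] = orig - eps
        lo = gp_fn().item()
        w.data[1, 2] = orig
        assert analytic == pytest.approx((hi - lo) / (2 * eps), rel=1e-5)


class TestLabelerLoss:
    def test_identical_is_zero(self):
        x = Tensor(np.arange(6.0).reshape(2, 3))
        assert nn.labeler_loss(x, Tensor(x.data.copy())).item() == 0.0

    def test_arithmetic_example(self):
        est = Tensor([[1.0, 0.0], [0.0, 1.0]])
        tgt = Tensor([[0.0, 0.0], [0.0, 0.0]])
        assert nn.labeler_loss(est, tgt).item() == pytest.approx(1.0)

    def test_matches_elementwise_brute_force(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        expected = np.mean([np.sum((a[i] - b[i]) ** 2) for i in range(5)])
        assert nn.labeler_loss(Tensor(a), Tensor(b)).item() == pytest.approx(expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nn.labeler_loss(Tensor(np.zeros((2, 3))), Tensor(np.zeros((3, 2))))


class TestMaskedLinear:
    def test_masked_paths_have_zero_gradient_flow(self):
        # finite-difference: output j must not respond to masked input i
        rng = np.random.default_rng(5)
        mask = (rng.random((6, 4)) < 0.5).astype(float)
        mask[0, :] = 1.0  # keep every unit connected
        layer = nn.MaskedLinear(mask, rng)
        x = rng.normal(size=(1, 6))
        base = layer(Tensor(x)).data
        for i in range(6):
            xp = x.copy()
            xp[0, i] += 1.0
            delta = layer(Tensor(xp)).data - base
            for j in range(4):
                if mask[i, j] == 0:
                    assert delta[0, j] == 0.0

    def test_masked_weights_stay_exactly_zero_after_updates(self):
        rng = np.random.default_rng(6)
        mask = (rng.random((5, 5)) < 0.4).astype(float)
        mask[0, :] = 1.0
        layer = nn.MaskedLinear(mask, rng)
        opt = nn.AMSGrad(layer.parameters(), lr=0.05)
        for _ in range(20):
            x = Tensor(rng.normal(size=(8, 5)))
            loss = ((layer(x) - 1.0) ** 2).mean()
            nn.backward(loss, layer.parameters())
            opt.step()
            opt.zero_grad()
            assert np.all(layer.effective_weight[mask == 0] == 0.0)
            assert np.all(layer.weight.data[mask == 0] == 0.0)


class TestPolicies:
    def test_critic_has_no_batch_norm(self):
        from scgrnsim.controller import make_critic

        critic = make_critic(10, (16, 16, 16), np.random.default_rng(0))
        assert not any(isinstance(m, nn.BatchNorm1d) for m in critic.modules())

    def test_generator_hidden_layers_batch_normed(self):
        gen = nn.MLP(4, (8, 8, 8), 6, np.random.default_rng(0),
                     batch_norm=True, out_activation="relu")
        bns = [m for m in gen.modules() if isinstance(m, nn.BatchNorm1d)]
        assert len(bns) == 3

    def test_batchnorm_eval_mode_is_per_sample_deterministic(self):
        bn = nn.BatchNorm1d(3)
        rng = np.random.default_rng(7)
        bn(Tensor(rng.normal(size=(32, 3))))  # accumulate running stats
        bn.eval()
        x = rng.normal(size=(1, 3))
        a = bn(Tensor(x)).data
        b = bn(Tensor(np.vstack([x, rng.normal(size=(9, 3))]))).data[:1]
        assert np.array_equal(a, b)


class TestAutodiff:
    def test_mlp_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(8)
        mlp = nn.MLP(4, (8, 8), 3, rng, batch_norm=True, out_activation="relu")
        x = rng.normal(size=(5, 4))
        loss_fn = lambda: ((mlp(Tensor(x)) - 1.0) ** 2).mean()
        params = mlp.parameters()
        nn.backward(loss_fn(), params)
        p = params[0]
        eps, (i, j) = 1e-6, (1, 2)
        orig = p.data[i, j]
        p.data[i, j] = orig + eps
        hi = loss_fn().item()
        p.data[i, j] = orig - eps
        lo = loss_fn().item()
        p.data[i, j] = orig
        assert p.grad.data[i, j] == pytest.approx((hi - lo) / (2 * eps), rel=1e-4)

    def test_take_columns_and_concat_roundtrip_gradient(self):
        x = Tensor(np.arange(12.0).reshape(3, 4), requires_grad=True)
        perm = np.array([2, 0, 3, 1])
        y = ad.take_columns(x, perm)
        loss = (y * Tensor(np.ones((3, 4)))).sum()
        (g,) = ad.grad(loss, [x])
        assert np.array_equal(g.data, np.ones((3, 4)))
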