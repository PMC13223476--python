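"""Low-rank logit Gaussians: sampling statistics, MC marginal probabilities,
and the dual-scale uncertainty loss with its zero-covariance limit."""

import numpy as np
import pytest

from grmaseg import (
    GRMANet,
    LowRankGaussian,
    MCSettings,
    NetConfig,
    Volume3D,
    au_loss,
    build_multiscale_inputs,
    mc_class_probability,
    predict_distribution,
    sample_logits,
)
from grmaseg.autodiff import Tensor


def toy_gaussian(rng=None, n_vox=2, n_cls=3, rank=2, scale=1.0):
    rng = rng or np.random.default_rng(0)
    n = n_vox * n_cls
    mu = rng.normal(size=(n_vox, 1, 1, n_cls)).astype(np.float32)
    p = (scale * rng.normal(size=(n, rank))).astype(np.float32)
    dg = (0.5 + rng.random(n)).astype(np.float32)
    return LowRankGaussian(mu, p, dg)


def test_head_outputs_have_contract_shapes(small_phantom):
    vol, _ = small_phantom
    net = GRMANet(NetConfig(base_channels=4, au_rank=3, seed=5))
    _, au_feats = net.forward(build_multiscale_inputs(vol), return_au_features=True)
    g = predict_distribution(au_feats[1], net.au_heads[0])
    h, w, d = vol.shape
    assert tuple(g.mu.shape) == (h, w, d, 2)
    assert tuple(g.cov_factor.shape) == (h * w * d * 2, 3)
    assert tuple(g.cov_diag.shape) == (h * w * d * 2,)
    assert g.cov_diag.data.min() > 0


def test_zero_features_zero_weights_give_softplus_floor_diag(small_phantom):
    vol, _ = small_phantom
    net = GRMANet(NetConfig(base_channels=4, seed=5))
    head = net.au_heads[0]
    for p in head.parameters():
        p.data[:] = 0.0
    feats = Tensor(np.zeros((1, 4, 8, 8, 8), np.float32))
    g = predict_distribution(feats, head)
    assert np.abs(g.mu.data).max() == 0.0
    assert np.allclose(g.cov_diag.data, np.log(2.0) + 1e-6, atol=1e-6)


def test_degenerate_distribution_samples_equal_mu():
    g = toy_gaussian()
    g.cov_factor.data[:] = 0.0
    g.cov_diag.data[:] = 1e-12
    s = sample_logits(g, MCSettings(8, seed=0))
    assert np.abs(s.data - g.mu.data[None]).max() < 1e-4


def test_sampling_is_seed_reproducible():
    g = toy_gaussian()
    a = sample_logits(g, MCSettings(16, seed=42))
    b = sample_logits(g, MCSettings(16, seed=42))
    assert np.array_equal(a.data, b.data)
    c = sample_logits(g, MCSettings(16, seed=43))
    assert not np.array_equal(a.data, c.data)


def test_sample_mean_obeys_clt_bound():
    g = toy_gaussian()
    m = 10_000
    s = sample_logits(g, MCSettings(m, seed=1)).data.reshape(m, -1)
    marg_std = np.sqrt((g.cov_factor.data ** 2).sum(1) + g.cov_diag.data)
    err = np.abs(s.mean(0) - g.mu.data.ravel())
    assert np.all(err <= 4.0 * marg_std / np.sqrt(m))


def test_empirical_covariance_matches_lowrank_parameterization():
    g = toy_gaussian()
    m = 10_000
    s = sample_logits(g, MCSettings(m, seed=3)).data.reshape(m, -1)
    emp = np.cov(s.T)
    ref = g.dense_covariance()
    rel = np.linalg.norm(emp - ref) / np.linalg.norm(ref)
    assert rel < 0.10


def test_single_sample_symmetric_logits_give_half():
    s = Tensor(np.zeros((1, 1, 1, 1, 2), np.float32))
    p = mc_class_probability(s)
    assert np.allclose(p.data, 0.5)


def test_zero_covariance_probability_equals_softmax_mu():
    g = toy_gaussian()
    g.cov_factor.data[:] = 0.0
    g.cov_diag.data[:] = 1e-12
    p = mc_class_probability(sample_logits(g, MCSettings(40, seed=0)))
    mu = g.mu.data
    ref = np.exp(mu) / np.exp(mu).sum(-1, keepdims=True)
    assert np.abs(p.data - ref).max() < 1e-5


def test_large_isotropic_covariance_drives_probability_to_half():
    n = 2
    g = LowRankGaussian(
        np.zeros((1, 1, 1, n), np.float32),
        np.zeros((n, 1), np.float32),
        np.full(n, 100.0, np.float32),
    )
    p = mc_class_probability(sample_logits(g, MCSettings(10_000, seed=9)))
    assert np.abs(p.data - 0.5).max() < 0.02


def test_mc_probability_is_a_simplex_field(rng):
    s = Tensor(rng.normal(size=(7, 3, 2, 2, 4)).astype(np.float32))
    p = mc_class_probability(s).data
    assert p.min() >= 0
    assert np.abs(p.sum(-1) - 1.0).max() < 1e-5


# -- the loss -----------------------------------------------------------------

def _plain_ce(mu, labels):
    prob = np.exp(mu) / np.exp(mu).sum(-1, keepdims=True)
    pick = np.take_along_axis(prob, labels[..., None], axis=-1)[..., 0]
    return float(-np.log(pick).mean())


def test_perfect_prediction_gives_vanishing_loss():
    mu = np.zeros((2, 2, 2, 2), np.float32)
    labels = np.random.default_rng(0).integers(0, 2, (2, 2, 2))
    mu[..., 1] = 40.0 * labels - 20.0
    mu[..., 0] = -mu[..., 1]
    g = LowRankGaussian(mu, np.zeros((16, 1), np.float32), np.full(16, 1e-10, np.float32))
    loss = au_loss({1: g}, labels, MCSettings(4, 0))
    assert float(loss.data) < 1e-5


def test_uniform_probability_costs_ln2_per_scale():
    labels = np.zeros((2, 2, 2), np.int64)
    zeros = lambda: LowRankGaussian(  # noqa: E731
        np.zeros((2, 2, 2, 2), np.float32),
        np.zeros((16, 1), np.float32),
        np.full(16, 1e-10, np.float32),
    )
    labels4 = np.zeros((4, 4, 4), np.int64)
    g1 = LowRankGaussian(np.zeros((4, 4, 4, 2), np.float32),
                         np.zeros((128, 1), np.float32), np.full(128, 1e-10, np.float32))
    loss = au_loss({1: g1, 2: zeros()}, labels4, MCSettings(4, 0))
    assert abs(float(loss.data) - 2 * np.log(2)) < 1e-5


def test_two_voxel_loss_matches_manual_cross_entropy():
    mu = np.array([[[[1.0, -1.0]]], [[[0.5, 0.25]]]], np.float32)  # (2,1,1,2)
    labels = np.array([[[0]], [[1]]], np.int64)
    g = LowRankGaussian(mu, np.zeros((4, 1), np.float32), np.full(4, 1e-12, np.float32))
    loss = au_loss({1: g}, labels, MCSettings(8, 5))
    assert abs(float(loss.data) - _plain_ce(mu.astype(np.float64), labels)) < 1e-6


def test_zero_covariance_limit_recovers_plain_cross_entropy(rng):
    """As Sigma -> 0 the MC-marginalized loss equals CE(softmax(mu), y) at
    both scales."""
    h, w, d, c = 8, 8, 8, 2
    labels = rng.integers(0, 2, (h, w, d))
    mu1 = rng.normal(size=(h, w, d, c)).astype(np.float32)
    mu2 = rng.normal(size=(h // 2, w // 2, d // 2, c)).astype(np.float32)

    def degen(mu):
        n = mu.size
        return LowRankGaussian(mu, np.zeros((n, 2), np.float32), np.full(n, 1e-8, np.float32))

    loss = au_loss({1: degen(mu1), 2: degen(mu2)}, labels, MCSettings(16, 0))
    ref = _plain_ce(mu1.astype(np.float64), labels) + _plain_ce(
        mu2.astype(np.float64), labels[1::2, 1::2, 1::2]
    )
    assert abs(float(loss.data) - ref) < 1e-5


def test_loss_gradient_matches_finite_differences():
    """Reparameterized sampling keeps au_loss differentiable in mu, P, Dg."""
    rng = np.random.default_rng(2)
    mu = rng.normal(size=(2, 1, 1, 2)).astype(np.float32)
    p = (0.3 * rng.normal(size=(4, 2))).astype(np.float32)
    dg = (0.5 + rng.random(4)).astype(np.float32)
    labels = np.array([[[0]], [[1]]], np.int64)
    mc = MCSettings(64, seed=7)

    def loss_at(mu_a, p_a, dg_a):
        g = LowRankGaussian(Tensor(mu_a, True), Tensor(p_a, True), Tensor(dg_a, True))
        return au_loss({1: g}, labels, mc), g

    loss, g = loss_at(mu, p, dg)
    loss.backward()
    eps = 1e-2
    for tensor, arr, name in ((g.mu, mu, "mu"), (g.cov_factor, p, "P"), (g.cov_diag, dg, "Dg")):
        flat_grad = tensor.grad.ravel()
        idxs = [0, arr.size // 2, arr.size - 1]
        for i in idxs:
            up, dn = arr.copy().ravel(), arr.copy().ravel()
            up[i] += eps
            dn[i] -= eps
            args = {"mu": [mu, p, dg], "P": [mu, p, dg], "Dg": [mu, p, dg]}[name]
            pos = [a.copy() for a in args]
            neg = [a.copy() for a in args]
            j = {"mu": 0, "P": 1, "Dg": 2}[name]
            pos[j] = up.reshape(arr.shape)
            neg[j] = dn.reshape(arr.shape)
            fd = (float(loss_at(*pos)[0].data) - float(loss_at(*neg)[0].data)) / (2 * eps)
            an = float(flat_grad[i])
            assert abs(fd - an) / max(abs(fd), abs(an), 1e-2) < 1e-3, (name, i, fd, an)


def test_scale_mismatch_is_a_config_error():
    g = toy_gaussian()
    with pytest.raises(ValueError):
        au_loss({1: g}, np.zeros((4, 4, 4), np.int64), MCSettings(2, 0))
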