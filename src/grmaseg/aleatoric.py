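"""Aleatoric uncertainty as a low-rank multivariate normal over logits.

The per-scale logit field eta ~ N(mu, Sigma) with Sigma = P P^T + diag(Dg)
over the flattened voxel-class vector (length H*W*D*C, rank-r factor P).  The
dense covariance is never materialized: sampling uses the reparameterization

    eta = mu + P e1 + sqrt(Dg) * e2,   e1 ~ N(0, I_r), e2 ~ N(0, I),

so the supervised uncertainty loss L_AUM stays differentiable through mu, P
and Dg.  Class probabilities are the Monte-Carlo average of the per-sample
softmax; L_AUM is, by default, the cross-entropy of that averaged probability
against the (per-scale nearest-neighbour downsampled) ground truth, summed
over the configured scales.  The alternative reading (average of per-sample
log-probabilities) is selectable via ``mode="mean-log"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, log_softmax, softmax
from .backbone import AUHead
from .volume import downsample_labels

_DIAG_EPS = 1e-6   # floor added to softplus(raw) so Dg stays strictly positive
_LOG_EPS = 1e-8    # clamp inside the cross-entropy log


@dataclass
class MCSettings:
    """Monte-Carlo sample count and sampling seed."""

    m_samples: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.m_samples < 1:
            raise ValueError("m_samples must be >= 1")


@dataclass
class LowRankGaussian:
    """mu: (H, W, D, C); cov_factor: (H*W*D*C, r); cov_diag: (H*W*D*C,) > 0."""

    mu: Tensor
    cov_factor: Tensor
    cov_diag: Tensor

    def __post_init__(self):
        if not isinstance(self.mu, Tensor):
            self.mu = Tensor(self.mu)
        if not isinstance(self.cov_factor, Tensor):
            self.cov_factor = Tensor(self.cov_factor)
        if not isinstance(self.cov_diag, Tensor):
            self.cov_diag = Tensor(self.cov_diag)
        n = self.mu.size
        if self.cov_factor.shape[0] != n or self.cov_diag.shape != (n,):
            raise ValueError(
                f"covariance shapes {self.cov_factor.shape}/{self.cov_diag.shape} "
                f"inconsistent with mu of {n} entries"
            )

    @property
    def rank(self) -> int:
        return self.cov_factor.shape[1]

    @property
    def event_shape(self) -> tuple:
        return self.mu.shape

    def dense_covariance(self) -> np.ndarray:
        """P P^T + diag(Dg) as a dense array (small toys / tests only)."""
        p = self.cov_factor.data
        return p @ p.T + np.diag(self.cov_diag.data)


def predict_distribution(features: Tensor, head: AUHead) -> LowRankGaussian:
    """Run the three 1x1x1 heads on decoder features (1, C_f, H, W, D)."""
    c = head.num_classes
    r = head.rank
    mu = head.conv_mu(features).transpose((0, 2, 3, 4, 1))  # (1, H, W, D, C)
    spatial = mu.shape[1:4]
    mu = mu.reshape(*spatial, c)
    v = int(np.prod(spatial))
    fac = head.conv_factor(features).transpose((0, 2, 3, 4, 1))          # (1,H,W,D,r*C)
    fac = fac.reshape(v, r, c).transpose((0, 2, 1)).reshape(v * c, r)    # (V*C, r)
    raw = head.conv_diag(features).transpose((0, 2, 3, 4, 1)).reshape(v * c)
    diag = raw.softplus() + _DIAG_EPS
    return LowRankGaussian(mu, fac, diag)


def sample_logits(g: LowRankGaussian, mc: MCSettings) -> Tensor:
    """M reparameterized draws, returned as (M, *event_shape)."""
    n = g.mu.size
    r = g.rank
    rng = np.random.default_rng(mc.seed)
    dtype = g.mu.data.dtype
    e1 = Tensor(rng.standard_normal((r, mc.m_samples)).astype(dtype))
    e2 = Tensor(rng.standard_normal((n, mc.m_samples)).astype(dtype))
    flat_mu = g.mu.reshape(n, 1)
    eta = flat_mu + g.cov_factor @ e1 + g.cov_diag.sqrt().reshape(n, 1) * e2  # (N, M)
    m = mc.m_samples
    return eta.transpose((1, 0)).reshape(m, *g.event_shape)


def mc_class_probability(samples: Tensor | np.ndarray) -> Tensor:
    """(1/M) sum_t softmax(eta_t) over the trailing class axis; simplex field."""
    if not isinstance(samples, Tensor):
        samples = Tensor(samples)
    return softmax(samples, axis=-1).mean(axis=0)


def _one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    return np.eye(num_classes, dtype=np.float32)[labels]


def _scale_labels(labels: np.ndarray, scale: int) -> np.ndarray:
    return labels if scale == 1 else downsample_labels(labels, 2 ** (scale - 1))


def au_loss(
    gaussians: dict[int, LowRankGaussian],
    labels: np.ndarray,
    mc: MCSettings,
    num_classes: int = 2,
    mode: str = "mean-prob",
) -> Tensor:
    """L_AUM: per-scale voxel-averaged cross-entropy, summed over scales.

    gaussians maps scale index -> LowRankGaussian (scales {1, 2} by default
    upstream); labels is the full-resolution integer mask.
    """
    if mode not in ("mean-prob", "mean-log"):
        raise ValueError(f"unknown AU loss mode {mode!r}")
    if not gaussians:
        raise ValueError("au_loss needs at least one scale")
    total: Tensor | None = None
    for i, (scale, g) in enumerate(sorted(gaussians.items())):
        y = _scale_labels(labels, scale)
        if tuple(g.event_shape[:3]) != y.shape:
            raise ValueError(
                f"scale {scale}: gaussian spatial shape {g.event_shape[:3]} "
                f"does not match downsampled labels {y.shape}"
            )
        onehot = Tensor(_one_hot(y, num_classes))
        samples = sample_logits(g, MCSettings(mc.m_samples, mc.seed + i))
        if mode == "mean-prob":
            probs = mc_class_probability(samples)
            ce = -(probs.clamp(_LOG_EPS, 1.0).log() * onehot).sum(axis=-1).mean()
        else:
            logp = log_softmax(samples, axis=-1).mean(axis=0)
            ce = -(logp * onehot).sum(axis=-1).mean()
        total = ce if total is None else total + ce
    return total
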