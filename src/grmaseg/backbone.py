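"""GRMA-Net: a three-branch 3-D encoder-decoder with per-layer attention
aggregation, optional graph reasoning at a configurable encoder layer, and
four multi-scale decoder output heads.

The three branches see the input volume F and its x2 / x4 trilinear
downsamples Q and G.  The F branch max-pools after layers 1-3, Q after 2-3
and G after layer 3 only, so from layer 2 (Q) and layer 3 (G) onward the
branches march in lock-step with F's pyramid; earlier layers aggregate
different spatial resolutions by bringing Q_i / G_i to F_i's grid with
nearest upsampling.  Because the attention gates depend only on channel
means (GAP), this alignment is numerically exact.

Decoder scale p halves every axis p-1 times; scale 1 matches the input shape.
Heads emit logits; softmax is applied only at loss/metric boundaries.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import (
    Conv3d,
    GroupNorm,
    Linear,
    Module,
    ModuleList,
    Tensor,
    concat,
    default_groups,
    global_avg_pool,
    maxpool3d,
    upsample_nearest,
)
from .figr import FIGR
from .volume import Volume3D, resize_volume

_VALID_FIGR_LAYERS = (0, 2, 3, 4)
_VALID_NODE_FRACTIONS = (0.5, 0.25, 0.125)


@dataclass(frozen=True)
class NetConfig:
    base_channels: int = 16
    channel_multiplier: int = 2
    num_classes: int = 2
    in_channels: int = 1
    figr_layer: int = 4            # 0 disables graph reasoning
    figr_node_fraction: float = 0.25
    au_scales: tuple[int, ...] = (1, 2)
    au_rank: int = 10
    au_enabled: bool = True
    seed: int = 1337

    def __post_init__(self):
        if self.figr_layer not in _VALID_FIGR_LAYERS:
            raise ValueError(f"figr_layer must be one of {_VALID_FIGR_LAYERS}")
        if not any(abs(self.figr_node_fraction - f) < 1e-9 for f in _VALID_NODE_FRACTIONS):
            raise ValueError(f"figr_node_fraction must be one of {_VALID_NODE_FRACTIONS}")
        if any(s not in (1, 2, 3, 4) for s in self.au_scales):
            raise ValueError("au_scales must be within 1..4")

    @property
    def channels(self) -> tuple[int, int, int, int]:
        b, m = self.base_channels, self.channel_multiplier
        return (b, b * m, b * m ** 2, b * m ** 3)


@dataclass
class MultiScaleInput:
    """F at full resolution plus its deterministic x2 (Q) and x4 (G) downsamples."""

    f: np.ndarray
    q: np.ndarray
    g: np.ndarray


def build_multiscale_inputs(vol: Volume3D) -> MultiScaleInput:
    shape = vol.shape
    if any(s % 4 for s in shape):
        raise ValueError(f"input shape {shape} must be divisible by 4 per axis")
    q = resize_volume(vol, tuple(s // 2 for s in shape))
    g = resize_volume(vol, tuple(s // 4 for s in shape))
    return MultiScaleInput(vol.intensities, q.intensities, g.intensities)


class AttentionAggregate(Module):
    """Fig-5 style channel gates: A2 = sigmoid(FC(GAP(Q_i))),
    H = F*A2 + F;  A3 = sigmoid(FC(GAP(G_i))),  AMF = H*A3 + H."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.fc_q = Linear(channels, channels, rng)
        self.fc_g = Linear(channels, channels, rng)

    def forward(self, f_i: Tensor, q_i: Tensor, g_i: Tensor) -> Tensor:
        if f_i.shape != q_i.shape or f_i.shape != g_i.shape:
            raise ValueError(
                f"branch feature shapes differ: {f_i.shape}, {q_i.shape}, {g_i.shape}"
            )
        n, c = f_i.shape[0], f_i.shape[1]
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        a2 = self.fc_q(global_avg_pool(q_i)).sigmoid().reshape(n, c, 1, 1, 1)
        h = f_i * a2 + f_i
        a3 = self.fc_g(global_avg_pool(g_i)).sigmoid().reshape(n, c, 1, 1, 1)
        return h * a3 + h


class ConvBlock(Module):
    """Two {3x3x3 conv, group norm, ReLU} units."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv3d(cin, cout, 3, rng)
        self.norm1 = GroupNorm(default_groups(cout), cout)
        self.conv2 = Conv3d(cout, cout, 3, rng)
        self.norm2 = GroupNorm(default_groups(cout), cout)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(self.conv1(x)).relu()
        return self.norm2(self.conv2(x)).relu()


class AUHead(Module):
    """1x1x1 heads emitting the low-rank logit-Gaussian parameters."""

    def __init__(self, cin: int, num_classes: int, rank: int, rng: np.random.Generator):
        super().__init__()
        self.rank = rank
        self.num_classes = num_classes
        self.conv_mu = Conv3d(cin, num_classes, 1, rng)
        self.conv_factor = Conv3d(cin, rank * num_classes, 1, rng)
        self.conv_diag = Conv3d(cin, num_classes, 1, rng)


# pooling schedule: F pools after layers 1-3, Q after 2-3, G after 3 only
_POOL_AFTER = {"f": (1, 2, 3), "q": (2, 3), "g": (3,)}


class GRMANet(Module):
    def __init__(self, cfg: NetConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.channels
        for branch in ("f", "q", "g"):
            blocks = ModuleList()
            cin = cfg.in_channels
            for c in ch:
                blocks.append(ConvBlock(cin, c, rng))
                cin = c
            setattr(self, f"enc_{branch}", blocks)
        self.attention = ModuleList(AttentionAggregate(c, rng) for c in ch)
        if cfg.figr_layer:
            self.figr = FIGR(ch[cfg.figr_layer - 1], rng, cfg.figr_node_fraction)
        else:
            self.figr = None
        # decoder stages producing scales 3, 2, 1 (scale 4 is the deepest AMF)
        self.dec3 = ConvBlock(ch[3] + ch[2], ch[2], rng)
        self.dec2 = ConvBlock(ch[2] + ch[1], ch[1], rng)
        self.dec1 = ConvBlock(ch[1] + ch[0], ch[0], rng)
        self.heads = ModuleList(Conv3d(c, cfg.num_classes, 1, rng) for c in ch)
        if cfg.au_enabled:
            self.au_heads = ModuleList(
                AUHead(ch[s - 1], cfg.num_classes, cfg.au_rank, rng) for s in cfg.au_scales
            )
        else:
            self.au_heads = ModuleList()

    # -- forward --------------------------------------------------------------
    def forward(self, x: MultiScaleInput, return_au_features: bool = False):
        """Returns the four logit grids [scale1..scale4]; optionally also the
        decoder features at the configured AU scales."""
        for name, arr in (("F", x.f), ("Q", x.q), ("G", x.g)):
            if arr.ndim != 3:
                raise ValueError(f"{name} must be a 3-D grid, got ndim={arr.ndim}")
        for ax, n in enumerate(x.f.shape):
            if n < 8 or n % 8:
                raise ValueError(f"input axis {ax} has size {n}; need >=8, divisible by 8")
        cur = {
            "f": Tensor(x.f[None, None]),
            "q": Tensor(x.q[None, None]),
            "g": Tensor(x.g[None, None]),
        }
        amf: list[Tensor] = []
        for layer in range(1, 5):
            for b in ("f", "q", "g"):
                cur[b] = getattr(self, f"enc_{b}")[layer - 1](cur[b])
            f_i, q_i, g_i = cur["f"], cur["q"], cur["g"]
            if self.figr is not None and self.cfg.figr_layer == layer:
                f_i = self.figr(f_i)
                cur["f"] = f_i
            # early layers run at the branch's native (coarser) resolution;
            # bring them to F_i's grid by nearest upsampling (exact for the
            # GAP-driven gates, which depend only on channel means)
            if q_i.shape != f_i.shape:
                q_i = upsample_nearest(q_i, f_i.shape[2] // q_i.shape[2])
            if g_i.shape != f_i.shape:
                g_i = upsample_nearest(g_i, f_i.shape[2] // g_i.shape[2])
            amf.append(self.attention[layer - 1](f_i, q_i, g_i))
            if layer < 4:
                for b in ("f", "q", "g"):
                    if layer in _POOL_AFTER[b]:
                        cur[b] = maxpool3d(cur[b])
        d4 = amf[3]
        d3 = self.dec3(concat([upsample_nearest(d4), amf[2]], axis=1))
        d2 = self.dec2(concat([upsample_nearest(d3), amf[1]], axis=1))
        d1 = self.dec1(concat([upsample_nearest(d2), amf[0]], axis=1))
        decoder_feats = {1: d1, 2: d2, 3: d3, 4: d4}
        logits = [self.heads[p - 1](decoder_feats[p]) for p in (1, 2, 3, 4)]
        if return_au_features:
            au_feats = {s: decoder_feats[s] for s in self.cfg.au_scales}
            return logits, au_feats
        return logits


def count_parameters(net: Module) -> int:
    return net.num_parameters()


# -- checkpointing ------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(net: GRMANet, path: str | Path, extra: dict | None = None) -> Path:
    """Weights as .npz plus a JSON sidecar recording the NetConfig."""
    path = Path(path)
    np.savez(path, **net.state_dict())
    sidecar = {
        "version": CHECKPOINT_VERSION,
        "net_config": asdict(net.cfg),
        "extra": extra or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> tuple[GRMANet, dict]:
    path = Path(path)
    npz_path = path if path.exists() else path.with_suffix(".npz")
    if not npz_path.exists():
        raise FileNotFoundError(f"no checkpoint at {path}")
    sidecar_path = npz_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing checkpoint sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    cfg_dict = dict(sidecar["net_config"])
    cfg_dict["au_scales"] = tuple(cfg_dict["au_scales"])
    net = GRMANet(NetConfig(**cfg_dict))
    with np.load(npz_path) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net, sidecar.get("extra", {})
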