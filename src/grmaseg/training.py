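"""Semi-supervised mean-teacher training.

Student and teacher share the GRMA-Net architecture; the teacher is updated
only as an exponential moving average of the student.  Each step combines

* supervised multi-scale soft-Dice on labeled data (L_DICE),
* the dual-scale aleatoric-uncertainty cross-entropy (L_AUM), and
* KL-variance-guided multi-scale pseudo-label consistency on unlabeled data:
  L'_con = (1/4) sum_p mean[ exp(-KL_p) * CE(student_p, pseudo_p) + KL_p ],

with L_total = L_DICE + L_AUM + lambda(step) * L'_con and lambda ramping
sigmoid-style from ~0 to the configured consistency weight.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .aleatoric import MCSettings, au_loss, predict_distribution
from .autodiff import Adam, Tensor, log_softmax, softmax
from .backbone import (
    GRMANet,
    MultiScaleInput,
    NetConfig,
    build_multiscale_inputs,
    save_checkpoint,
)
from .phantom import DatasetSplit, augment
from .volume import LabelMask, Volume3D, downsample_labels
from . import metrics as segmetrics

_EPS = 1e-8
_NOISE_PLACEMENTS = ("none", "student", "teacher", "both")


@dataclass
class TrainConfig:
    learning_rate: float = 3e-4
    batch_size: int = 1
    epochs: int = 400
    ema_decay: float = 0.999
    consistency_weight: float = 0.1
    ramp_len: int = 1000              # steps until lambda reaches its plateau
    noise_placement: str = "student"
    noise_std: float = 0.1
    noise_clip: float = 0.2
    ema_warmup: bool = True           # decay_t = min(1 - 1/(t+1), ema_decay)
    seed: int = 1337
    augment: bool = True
    augment_noise_std: float = 0.05
    mc_train: int = 20
    mc_eval: int = 50
    au_mode: str = "mean-prob"
    # ablation switches
    au_enabled: bool = True
    ue_enabled: bool = True           # KL guidance of the consistency loss
    figr_enabled: bool = True
    consistency_enabled: bool = True
    eval_model: str = "student"

    def __post_init__(self):
        if not (0.0 < self.ema_decay < 1.0):
            raise ValueError("ema_decay must be in (0, 1)")
        if self.consistency_weight < 0:
            raise ValueError("consistency_weight must be >= 0")
        if self.noise_placement not in _NOISE_PLACEMENTS:
            raise ValueError(f"noise_placement must be one of {_NOISE_PLACEMENTS}")
        if self.eval_model not in ("student", "teacher"):
            raise ValueError("eval_model must be 'student' or 'teacher'")


class TeacherStudentPair:
    """Identical architectures; the teacher gets EMA updates, never gradients."""

    def __init__(self, net_cfg: NetConfig, ema_decay: float = 0.999):
        self.student = GRMANet(net_cfg)
        self.teacher = GRMANet(net_cfg)
        self.teacher.load_state_dict(self.student.state_dict())
        for p in self.teacher.parameters():
            p.requires_grad = False
        self.ema_decay = float(ema_decay)


def ema_update(pair: TeacherStudentPair, decay: Optional[float] = None) -> None:
    """theta' <- decay * theta' + (1 - decay) * theta, elementwise."""
    d = pair.ema_decay if decay is None else float(decay)
    s_params = dict(pair.student.named_parameters())
    t_params = dict(pair.teacher.named_parameters())
    if s_params.keys() != t_params.keys():
        raise ValueError("student/teacher parameter trees differ")
    for k, tp in t_params.items():
        tp.data *= d
        tp.data += (1.0 - d) * s_params[k].data


# -- loss components ----------------------------------------------------------

def _scale_labels(labels: np.ndarray, scale: int) -> np.ndarray:
    return labels if scale == 1 else downsample_labels(labels, 2 ** (scale - 1))


def dice_multiscale_loss(logits: Sequence[Tensor], mask: LabelMask) -> Tensor:
    """Soft-Dice loss per scale against downsampled masks, averaged over scales."""
    if mask.shape != tuple(logits[0].shape[2:]):
        raise ValueError(
            f"mask shape {mask.shape} does not match scale-1 logits {tuple(logits[0].shape[2:])}"
        )
    c = logits[0].shape[1]
    total: Tensor | None = None
    smooth = 1e-6
    for p, lg in enumerate(logits, start=1):
        y = _scale_labels(mask.labels, p)
        onehot = np.eye(c, dtype=np.float32)[y]                   # (H, W, D, C)
        onehot_t = Tensor(onehot.transpose(3, 0, 1, 2)[None])     # (1, C, H, W, D)
        probs = softmax(lg, axis=1)
        inter = (probs * onehot_t).sum(axis=(0, 2, 3, 4))
        denom = probs.sum(axis=(0, 2, 3, 4)) + Tensor(onehot_t.data.sum(axis=(0, 2, 3, 4)))
        dice_c = (inter * 2.0 + smooth) / (denom + smooth)
        loss_p = 1.0 - dice_c.mean()
        total = loss_p if total is None else total + loss_p
    return total * (1.0 / len(logits))


def make_pseudo_labels(teacher_logits: Sequence[Tensor]) -> list[np.ndarray]:
    """Per-scale argmax hard labels; exact ties resolve to the lowest class."""
    return [np.argmax(lg.data, axis=1)[0] for lg in teacher_logits]


def kl_variance(student_logits, teacher_logits):
    """Per-voxel D_KL(softmax(student) || softmax(teacher)) at one scale.

    NumPy inputs -> float64 array (analysis path); Tensor inputs -> float32
    Tensor in the student's gradient graph, teacher treated as constant.
    Negative round-off is clipped at zero.
    """
    if isinstance(student_logits, Tensor):
        s = softmax(student_logits, axis=1)
        ls = log_softmax(student_logits, axis=1)
        lt = Tensor(_log_softmax_np(teacher_logits.data if isinstance(teacher_logits, Tensor)
                                    else teacher_logits, axis=1).astype(np.float32))
        return (s * (ls - lt)).sum(axis=1).relu()
    s_arr = np.asarray(student_logits, dtype=np.float64)
    t_arr = np.asarray(teacher_logits, dtype=np.float64)
    if s_arr.shape != t_arr.shape:
        raise ValueError(f"logit shapes differ: {s_arr.shape} vs {t_arr.shape}")
    axis = 1 if s_arr.ndim >= 2 else 0
    ls = _log_softmax_np(s_arr, axis=axis)
    lt = _log_softmax_np(t_arr, axis=axis)
    kl = (np.exp(ls) * (ls - lt)).sum(axis=axis)
    return np.maximum(kl, 0.0)


def _log_softmax_np(x: np.ndarray, axis: int) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def consistency_loss(
    student_logits: Sequence[Tensor],
    pseudo_labels: Sequence[np.ndarray],
    kl_maps: Sequence[Tensor],
    exp_weight: bool = True,
    additive_kl: bool = True,
) -> Tensor:
    """(1/P) sum_p mean[ exp(-KL_p) * CE_p + KL_p ]; both guidance terms
    switch off together when the uncertainty estimation is disabled."""
    if not (len(student_logits) == len(pseudo_labels) == len(kl_maps)):
        raise ValueError("per-scale inputs have inconsistent lengths")
    c = student_logits[0].shape[1]
    total: Tensor | None = None
    for lg, pl, kl in zip(student_logits, pseudo_labels, kl_maps):
        onehot = np.eye(c, dtype=np.float32)[pl].transpose(3, 0, 1, 2)[None]
        ce = -(log_softmax(lg, axis=1) * Tensor(onehot)).sum(axis=1)   # (1, H, W, D)
        term = (-kl).exp() * ce if exp_weight else ce
        if additive_kl:
            term = term + kl
        val = term.mean()
        total = val if total is None else total + val
    return total * (1.0 / len(student_logits))


def consistency_ramp(step: int, ramp_len: int, weight: float) -> float:
    """lambda(step) = weight * exp(-5 (1 - step/ramp_len)^2), clamped at weight."""
    if ramp_len <= 0:
        return float(weight)
    t = min(float(step) / float(ramp_len), 1.0)
    return float(weight) * float(np.exp(-5.0 * (1.0 - t) ** 2))


def total_loss(l_dice: Tensor, l_aum: Tensor | float, l_con: Tensor | float,
               step: int, cfg: TrainConfig) -> tuple[Tensor, float]:
    lam = consistency_ramp(step, cfg.ramp_len, cfg.consistency_weight)
    out = l_dice
    if isinstance(l_aum, Tensor):
        out = out + l_aum
    if isinstance(l_con, Tensor) and lam > 0:
        out = out + lam * l_con
    return out, lam


# -- the step and loop --------------------------------------------------------

def _perturb(vol: Volume3D, rng: np.random.Generator, std: float, clip: float) -> Volume3D:
    noise = np.clip(rng.normal(0.0, std, vol.shape), -clip, clip).astype(np.float32)
    return Volume3D(vol.intensities + noise, vol.spacing)


def train_step(
    pair: TeacherStudentPair,
    labeled_batch: Sequence[tuple[Volume3D, LabelMask]],
    unlabeled_batch: Sequence[Volume3D],
    cfg: TrainConfig,
    optimizer: Adam,
    step: int,
    rng: np.random.Generator,
) -> dict:
    """One optimization step; returns the loss breakdown."""
    if not labeled_batch:
        raise ValueError("labeled batch must be non-empty")
    student = pair.student
    au_on = cfg.au_enabled and student.cfg.au_enabled

    l_dice: Tensor | None = None
    l_aum: Tensor | float = 0.0
    for vol, mask in labeled_batch:
        msi = build_multiscale_inputs(vol)
        if au_on:
            logits, au_feats = student.forward(msi, return_au_features=True)
            gaussians = {
                s: predict_distribution(au_feats[s], student.au_heads[i])
                for i, s in enumerate(student.cfg.au_scales)
            }
            mc = MCSettings(cfg.mc_train, seed=int(rng.integers(2 ** 31)))
            la = au_loss(gaussians, mask.labels, mc,
                         num_classes=student.cfg.num_classes, mode=cfg.au_mode)
            l_aum = la if isinstance(l_aum, float) else l_aum + la
        else:
            logits = student.forward(msi)
        ld = dice_multiscale_loss(logits, mask)
        l_dice = ld if l_dice is None else l_dice + ld
    inv = 1.0 / len(labeled_batch)
    l_dice = l_dice * inv
    if isinstance(l_aum, Tensor):
        l_aum = l_aum * inv

    lam = consistency_ramp(step, cfg.ramp_len, cfg.consistency_weight)
    l_con: Tensor | float = 0.0
    kl_means: list[float] = []
    if cfg.consistency_enabled and lam > 0 and len(unlabeled_batch) > 0:
        for vol_u in unlabeled_batch:
            s_in = vol_u
            t_in = vol_u
            if cfg.noise_placement in ("student", "both"):
                s_in = _perturb(vol_u, rng, cfg.noise_std, cfg.noise_clip)
            if cfg.noise_placement in ("teacher", "both"):
                t_in = _perturb(vol_u, rng, cfg.noise_std, cfg.noise_clip)
            s_logits = student.forward(build_multiscale_inputs(s_in))
            t_logits = pair.teacher.forward(build_multiscale_inputs(t_in))
            pseudo = make_pseudo_labels(t_logits)
            kls = [kl_variance(sl, tl) for sl, tl in zip(s_logits, t_logits)]
            kl_means = [float(k.data.mean()) for k in kls]
            lc = consistency_loss(
                s_logits, pseudo, kls,
                exp_weight=cfg.ue_enabled, additive_kl=cfg.ue_enabled,
            )
            l_con = lc if isinstance(l_con, float) else l_con + lc
        if isinstance(l_con, Tensor):
            l_con = l_con * (1.0 / len(unlabeled_batch))

    total = l_dice
    if isinstance(l_aum, Tensor):
        total = total + l_aum
    if isinstance(l_con, Tensor):
        total = total + lam * l_con

    optimizer.zero_grad()
    total.backward()
    optimizer.step()
    # standard mean-teacher decay warm-up: the teacher tracks the student
    # closely at the start, then settles into the configured long average
    decay = min(1.0 - 1.0 / (step + 1), pair.ema_decay) if cfg.ema_warmup else None
    ema_update(pair, decay)

    return {
        "step": step,
        "l_dice": float(l_dice.data),
        "l_aum": float(l_aum.data) if isinstance(l_aum, Tensor) else 0.0,
        "l_con": float(l_con.data) if isinstance(l_con, Tensor) else 0.0,
        "lambda": lam,
        "l_total": float(total.data),
        "kl_mean_per_scale": kl_means,
    }


def predict_mask(net: GRMANet, vol: Volume3D) -> LabelMask:
    """Scale-1 argmax segmentation of a volume."""
    logits = net.forward(build_multiscale_inputs(vol))
    labels = np.argmax(logits[0].data, axis=1)[0]
    return LabelMask(labels, net.cfg.num_classes, vol.spacing)


def mean_validation_dice(net: GRMANet, items: Sequence[tuple[Volume3D, LabelMask]]) -> float:
    scores = [
        segmetrics.dice(predict_mask(net, v).labels > 0, m.labels > 0) for v, m in items
    ]
    return float(np.mean(scores)) if scores else float("nan")


def train(
    split: DatasetSplit,
    cfg: TrainConfig,
    net_cfg: NetConfig,
    out_dir: str | Path | None = None,
    max_steps: Optional[int] = None,
    val_every: int = 1,
    pair: Optional[TeacherStudentPair] = None,
    start_epoch: int = 0,
) -> tuple[TeacherStudentPair, list[dict]]:
    """Epoch loop over train_step with per-epoch validation, JSONL logging and
    checkpointing.  `max_steps` truncates the run for short experiments."""
    if not split.labeled:
        raise ValueError("training requires at least one labeled case")
    if cfg.figr_enabled != (net_cfg.figr_layer != 0):
        net_cfg = NetConfig(**{**asdict(net_cfg),
                               "figr_layer": 4 if cfg.figr_enabled else 0})
    if cfg.au_enabled != net_cfg.au_enabled:
        net_cfg = NetConfig(**{**asdict(net_cfg), "au_enabled": cfg.au_enabled})
    if pair is None:
        pair = TeacherStudentPair(net_cfg, cfg.ema_decay)
    optimizer = Adam(pair.student.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)

    out_dir = Path(out_dir) if out_dir is not None else None
    log_path = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        log_path = out_dir / "train_log.jsonl"

    history: list[dict] = []
    step = start_epoch * max(1, len(split.labeled))
    n_lab = len(split.labeled)
    done = False
    for epoch in range(start_epoch, cfg.epochs):
        order = rng.permutation(n_lab)
        for idx in order:
            vol, mask = split.labeled[int(idx)]
            if cfg.augment:
                vol, mask = augment(vol, mask, seed=int(rng.integers(2 ** 31)),
                                    noise_std=cfg.augment_noise_std)
            unlab: list[Volume3D] = []
            if split.unlabeled:
                unlab = [split.unlabeled[int(rng.integers(len(split.unlabeled)))]]
            rec = train_step(pair, [(vol, mask)], unlab, cfg, optimizer, step, rng)
            rec["epoch"] = epoch
            history.append(rec)
            if log_path is not None:
                with log_path.open("a") as fh:
                    fh.write(json.dumps(rec) + "\n")
            step += 1
            if max_steps is not None and step >= max_steps:
                done = True
                break
        if split.validation and (epoch % val_every == 0 or done):
            net = pair.student if cfg.eval_model == "student" else pair.teacher
            vd = mean_validation_dice(net, split.validation)
            history.append({"epoch": epoch, "val_dice": vd})
            if log_path is not None:
                with log_path.open("a") as fh:
                    fh.write(json.dumps(history[-1]) + "\n")
        if out_dir is not None:
            save_checkpoint(pair.student, out_dir / "student.npz",
                            extra={"epoch": epoch, "step": step})
            save_checkpoint(pair.teacher, out_dir / "teacher.npz",
                            extra={"epoch": epoch, "step": step})
        if done:
            break
    return pair, history
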