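"""Mean-teacher machinery: losses, pseudo-labels, KL guidance, EMA, the
training step and loop."""

import json
from types import SimpleNamespace

import numpy as np
import pytest

from grmaseg import (
    DatasetSplit,
    LabelMask,
    NetConfig,
    PhantomConfig,
    TeacherStudentPair,
    TrainConfig,
    consistency_loss,
    consistency_ramp,
    dice_multiscale_loss,
    ema_update,
    kl_variance,
    make_phantom,
    make_pseudo_labels,
    make_split,
    predict_mask,
    total_loss,
    train,
    train_step,
)
from grmaseg.autodiff import Adam, Tensor
from grmaseg.autodiff.modules import Module, Parameter
from grmaseg.training import mean_validation_dice
from grmaseg.volume import downsample_labels


def _logit_pyramid(labels, flip=False, strength=30.0):
    """Four-scale logits saturated toward (or away from) integer labels."""
    out = []
    for p in range(1, 5):
        y = labels if p == 1 else downsample_labels(labels, 2 ** (p - 1))
        onehot = np.eye(2, dtype=np.float32)[y].transpose(3, 0, 1, 2)[None]
        if flip:
            onehot = onehot[:, ::-1]
        out.append(Tensor(strength * (2.0 * onehot - 1.0)))
    return out


@pytest.fixture(scope="module")
def small_labels():
    rng = np.random.default_rng(0)
    return rng.integers(0, 2, (8, 8, 8))


def test_dice_loss_vanishes_when_saturated_correct(small_labels):
    loss = dice_multiscale_loss(_logit_pyramid(small_labels), LabelMask(small_labels))
    assert float(loss.data) < 1e-4


def test_dice_loss_is_one_for_complement_prediction(small_labels):
    loss = dice_multiscale_loss(_logit_pyramid(small_labels, flip=True), LabelMask(small_labels))
    assert float(loss.data) == pytest.approx(1.0, abs=1e-4)


def test_dice_loss_matches_manual_soft_dice(rng):
    labels = rng.integers(0, 2, (8, 8, 8))
    logits = [Tensor(rng.normal(size=(1, 2, 8 // f, 8 // f, 8 // f)).astype(np.float32))
              for f in (1, 2, 4, 8)]
    got = float(dice_multiscale_loss(logits, LabelMask(labels)).data)

    total = 0.0
    for p, lg in enumerate(logits, start=1):
        y = labels if p == 1 else downsample_labels(labels, 2 ** (p - 1))
        z = lg.data.astype(np.float64)
        prob = np.exp(z) / np.exp(z).sum(1, keepdims=True)
        onehot = np.eye(2)[y].transpose(3, 0, 1, 2)[None]
        per_class = []
        for c in range(2):
            inter = (prob[:, c] * onehot[:, c]).sum()
            per_class.append((2 * inter + 1e-6) / (prob[:, c].sum() + onehot[:, c].sum() + 1e-6))
        total += 1.0 - np.mean(per_class)
    assert got == pytest.approx(total / 4, abs=1e-5)


def test_pseudo_labels_are_onehot_argmax_with_low_index_ties():
    logits = [Tensor(np.array([[[[[3.2]]], [[[-1.0]]]]], np.float32))]
    assert make_pseudo_labels(logits)[0].item() == 0
    tie = [Tensor(np.zeros((1, 2, 1, 1, 1), np.float32))]
    assert make_pseudo_labels(tie)[0].item() == 0
    rng = np.random.default_rng(1)
    rand = [Tensor(rng.normal(size=(1, 3, 4, 4, 2)).astype(np.float32))]
    pl = make_pseudo_labels(rand)[0]
    onehot = np.eye(3)[pl]
    assert np.all(onehot.max(-1) == 1.0)  # zero-entropy per voxel


def test_kl_variance_closed_form_and_identities():
    student = np.array([[np.log(3.0), 0.0]]).T.reshape(1, 2, 1, 1, 1)
    teacher = np.zeros((1, 2, 1, 1, 1))
    got = kl_variance(student, teacher)[0, 0, 0, 0]
    want = 0.75 * np.log(1.5) + 0.25 * np.log(0.5)
    assert abs(got - want) < 1e-9
    same = kl_variance(student, student)
    assert np.all(same == 0.0)


def test_kl_variance_nonnegative_on_many_random_pairs(rng):
    s = rng.normal(size=(100_000, 2)).T.reshape(1, 2, 100, 100, 10)
    t = rng.normal(size=(100_000, 2)).T.reshape(1, 2, 100, 100, 10)
    kl = kl_variance(s, t)
    assert kl.min() >= 0.0


def test_consistency_loss_zero_when_student_equals_saturated_teacher(small_labels):
    logits = _logit_pyramid(small_labels)
    pseudo = make_pseudo_labels(logits)
    kls = [kl_variance(l, Tensor(l.data)) for l in logits]
    loss = consistency_loss(logits, pseudo, kls)
    assert float(loss.data) < 1e-4


def test_consistency_reduces_to_ce_when_kl_zero(rng):
    logits = [Tensor(rng.normal(size=(1, 2, 4, 4, 2)).astype(np.float32)) for _ in range(4)]
    pseudo = [rng.integers(0, 2, (4, 4, 2)) for _ in range(4)]
    zero_kl = [Tensor(np.zeros((1, 4, 4, 2), np.float32)) for _ in range(4)]
    got = float(consistency_loss(logits, pseudo, zero_kl).data)
    ref = 0.0
    for lg, pl in zip(logits, pseudo):
        z = lg.data.astype(np.float64)
        logp = z - np.log(np.exp(z).sum(1, keepdims=True))
        pick = np.take_along_axis(logp, pl[None, None], axis=1)
        ref += float(-pick.mean())
    assert got == pytest.approx(ref / 4, abs=1e-5)


def test_consistency_single_voxel_manual_arithmetic():
    """exp(-KL) * CE + KL on one voxel with the closed-form KL above."""
    s = Tensor(np.array([np.log(3.0), 0.0], np.float32).reshape(1, 2, 1, 1, 1))
    t = Tensor(np.zeros((1, 2, 1, 1, 1), np.float32))
    kl = kl_variance(s, t)
    pseudo = [np.zeros((1, 1, 1), np.int64)]
    loss = float(consistency_loss([s], pseudo, [kl]).data)
    kl_val = 0.75 * np.log(1.5) + 0.25 * np.log(0.5)
    ce_val = -np.log(0.75)
    assert loss == pytest.approx(np.exp(-kl_val) * ce_val + kl_val, abs=1e-6)


def _toy_pair():
    class One(Module):
        def __init__(self, val):
            super().__init__()
            self.w = Parameter(np.array(val, np.float32))

    return SimpleNamespace(student=One([1.0, 2.0]), teacher=One([0.0, 0.0]), ema_decay=0.999)


def test_ema_single_step_exact_formula():
    pair = _toy_pair()
    ema_update(pair)
    assert np.allclose(pair.teacher.w.data, [0.001, 0.002])
    pair2 = _toy_pair()
    pair2.teacher.w.data[:] = pair2.student.w.data
    ema_update(pair2)
    assert np.array_equal(pair2.teacher.w.data, pair2.student.w.data)  # fixed point


def test_ema_geometric_halving_time():
    pair = _toy_pair()
    pair.teacher.w.data[:] = 0.0
    gap0 = np.abs(pair.teacher.w.data - pair.student.w.data).max()
    for _ in range(693):  # ln2 / ln(1/0.999) ~ 693 steps per halving
        ema_update(pair)
    gap = np.abs(pair.teacher.w.data - pair.student.w.data).max()
    assert 0.47 <= gap / gap0 <= 0.53


def test_ema_teacher_stays_in_convex_envelope(rng):
    pair = _toy_pair()
    lo = np.minimum(pair.teacher.w.data.copy(), np.inf)
    hi = -lo
    for _ in range(1000):
        pair.student.w.data = rng.normal(size=2).astype(np.float32)
        lo = np.minimum(lo, np.minimum(pair.student.w.data, pair.teacher.w.data))
        hi = np.maximum(hi, np.maximum(pair.student.w.data, pair.teacher.w.data))
        ema_update(pair)
        assert np.all(pair.teacher.w.data >= lo - 1e-6)
        assert np.all(pair.teacher.w.data <= hi + 1e-6)


def test_total_loss_arithmetic_and_ramp():
    cfg = TrainConfig(ramp_len=0)  # lambda pinned at its plateau 0.1
    out, lam = total_loss(Tensor(np.float32(0.5)), Tensor(np.float32(0.2)),
                          Tensor(np.float32(1.0)), step=10, cfg=cfg)
    assert lam == pytest.approx(0.1)
    assert float(out.data) == pytest.approx(0.8, abs=1e-6)
    ramped = TrainConfig(ramp_len=100)
    lams = [consistency_ramp(s, 100, 0.1) for s in range(0, 140, 10)]
    assert lams[0] < 1e-3
    assert all(b >= a for a, b in zip(lams, lams[1:]))
    assert lams[-1] == pytest.approx(0.1)
    out0, lam0 = total_loss(Tensor(np.float32(0.5)), Tensor(np.float32(0.2)), 0.0, 0, ramped)
    assert float(out0.data) == pytest.approx(0.7, abs=1e-5)


@pytest.fixture(scope="module")
def mini_split():
    cfg = PhantomConfig(shape=(16, 16, 8), n_lesions=1, radius_range=(2.0, 3.0), seed=0)
    return make_split(cfg, n_labeled=2, n_unlabeled=3, n_val=1, n_test=1, seed=21)


def _mini_net_cfg(**kw):
    return NetConfig(base_channels=4, au_rank=2, seed=3, **kw)


def test_train_step_is_seed_deterministic(mini_split):
    def run():
        pair = TeacherStudentPair(_mini_net_cfg())
        opt = Adam(pair.student.parameters(), lr=1e-3)
        rng = np.random.default_rng(1337)
        recs = []
        for s in range(3):
            recs.append(train_step(pair, mini_split.labeled[:1], mini_split.unlabeled[:1],
                                   TrainConfig(ramp_len=0), opt, s, rng))
        return recs

    a, b = run(), run()
    for ra, rb in zip(a, b):
        assert ra["l_total"] == rb["l_total"]
        assert ra["l_dice"] == rb["l_dice"]


def test_empty_labeled_batch_is_rejected(mini_split):
    pair = TeacherStudentPair(_mini_net_cfg())
    opt = Adam(pair.student.parameters())
    with pytest.raises(ValueError):
        train_step(pair, [], mini_split.unlabeled[:1], TrainConfig(), opt, 0,
                   np.random.default_rng(0))


def test_pure_supervised_step_when_unlabeled_empty(mini_split):
    pair = TeacherStudentPair(_mini_net_cfg())
    opt = Adam(pair.student.parameters(), lr=1e-3)
    rec = train_step(pair, mini_split.labeled[:1], [], TrainConfig(ramp_len=0), opt, 0,
                     np.random.default_rng(0))
    assert rec["l_con"] == 0.0
    assert rec["l_total"] == pytest.approx(rec["l_dice"] + rec["l_aum"], abs=1e-6)


@pytest.mark.parametrize("placement", ["none", "student"])
def test_teacher_input_stays_clean_unless_configured(mini_split, placement, monkeypatch):
    pair = TeacherStudentPair(_mini_net_cfg())
    opt = Adam(pair.student.parameters(), lr=1e-3)
    seen = []
    orig = pair.teacher.forward
    monkeypatch.setattr(pair.teacher, "forward",
                        lambda msi, **kw: (seen.append(msi.f.copy()), orig(msi, **kw))[1])
    cfg = TrainConfig(ramp_len=0, noise_placement=placement, mc_train=2)
    train_step(pair, mini_split.labeled[:1], mini_split.unlabeled[:1], cfg, opt, 0,
               np.random.default_rng(0))
    assert len(seen) == 1
    assert np.array_equal(seen[0], mini_split.unlabeled[0].intensities)


def test_short_training_decreases_supervised_dice_loss(mini_split):
    cfg = TrainConfig(learning_rate=1e-3, ramp_len=0, augment=False, mc_train=4, epochs=100)
    pair, history = train(mini_split, cfg, _mini_net_cfg(), max_steps=50)
    steps = [h for h in history if "l_dice" in h]
    first = np.mean([h["l_dice"] for h in steps[:5]])
    last = np.mean([h["l_dice"] for h in steps[-5:]])
    assert last < first


def test_train_writes_log_checkpoints_and_resumes(tmp_path, mini_split):
    cfg = TrainConfig(learning_rate=1e-3, epochs=2, augment=False, mc_train=2)
    pair, history = train(mini_split, cfg, _mini_net_cfg(), out_dir=tmp_path)
    assert (tmp_path / "student.npz").exists()
    assert (tmp_path / "teacher.npz").exists()
    lines = [json.loads(l) for l in (tmp_path / "train_log.jsonl").read_text().splitlines()]
    assert any("l_total" in l for l in lines)
    assert any("val_dice" in l for l in lines)
    # resume continues the epoch counter
    cfg3 = TrainConfig(learning_rate=1e-3, epochs=3, augment=False, mc_train=2)
    _, hist2 = train(mini_split, cfg3, _mini_net_cfg(), pair=pair, start_epoch=2)
    epochs = {h["epoch"] for h in hist2 if "l_total" in h}
    assert epochs == {2}


def test_validation_dice_is_computable(mini_split):
    pair = TeacherStudentPair(_mini_net_cfg())
    vd = mean_validation_dice(pair.student, mini_split.validation)
    assert 0.0 <= vd <= 1.0
    pm = predict_mask(pair.student, mini_split.validation[0][0])
    assert pm.shape == mini_split.validation[0][0].shape
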