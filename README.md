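# grmaseg

Semi-supervised 3-D lesion segmentation for chest-CT-like volumes, built for
the setting where pixel-accurate annotations are scarce: a small labeled
pool, a much larger unlabeled pool, and lesions that are small, low-contrast
and blurred at their boundaries. The intended users are medical-image-
analysis researchers who want a fully offline-testable implementation of the
method — every experiment in this repository runs on synthetic lung-like
phantoms generated by the package itself.

## The method

Three components around a mean-teacher loop (student network θ, teacher
θ′ updated only by exponential moving average, θ′ ← αθ′ + (1−α)θ):

* **GRMA-Net backbone** — a three-branch 3-D encoder–decoder. The volume
  `F` and its ×2/×4 downsamples `Q`, `G` are encoded separately and fused
  per layer by channel-attention gates
  (`AMF_i = (F_i⊙A2 + F_i)⊙A3 + (F_i⊙A2 + F_i)` with
  `A_k = σ(FC(GAP(·)))`); the decoder emits class logits at four scales.
* **FIGR** (feature-interaction graph reasoning) before the deepest
  attention module: channel features are projected to a small fully
  connected graph (`N_f = C/4` nodes, `S_f = C/2` states), mixed by the
  Laplacian-smoothed graph convolution `Ṽ = σ((I + A_fᵀ) V_f W_f)`, and
  re-projected with a residual join.
* **Dual-scale aleatoric uncertainty** — at decoder scales 1 and 2 the
  logits follow a low-rank multivariate normal
  `η ~ N(μ, PPᵀ + diag(D))`; Monte-Carlo marginalizing the softmax gives
  `L_AUM`, the cross-entropy of the averaged class probability.

On unlabeled data the teacher's per-scale argmax pseudo-labels `p̂_p` and
the voxelwise KL-variance `KL_p = D_KL(softmax(student_p) ‖ softmax(teacher_p))`
form the uncertainty-guided consistency loss

    L'_con = (1/4) Σ_p mean[ exp(−KL_p)·CE(softmax(student_p), p̂_p) + KL_p ],

and the total objective is `L_total = L_DICE + L_AUM + λ(t)·L'_con` with a
sigmoid-ramped consistency weight λ. Evaluation uses Dice, Jaccard,
normalized surface dice (NSD, tolerance τ), average distance of boundaries
(ADB) and HD95.

The network stack runs on a compact NumPy reverse-mode autodiff core
(`grmaseg.autodiff`) written for this package — no deep-learning framework
is required.

## Worked example

```python
import numpy as np
from grmaseg import (PhantomConfig, NetConfig, TrainConfig,
                     make_split, train, predict_mask)
from grmaseg.metrics import evaluate_case

cfg = PhantomConfig(shape=(32, 32, 8), n_lesions=2, radius_range=(2.0, 3.5), seed=0)
split = make_split(cfg, n_labeled=4, n_unlabeled=20, n_val=0, n_test=5, seed=1)
tc = TrainConfig(learning_rate=3e-3, consistency_weight=0.1, ramp_len=100,
                 augment=False, epochs=1000, seed=1)
pair, history = train(split, tc, NetConfig(base_channels=8, seed=1), max_steps=200)

vol, mask = split.test[0]
rep = evaluate_case(predict_mask(pair.student, vol).labels > 0, mask.labels > 0, tau=1.0)
print(f"dice={rep.dice:.3f} nsd={rep.nsd:.3f} adb={rep.adb:.2f}")
```

This trains the full semi-supervised stack for 200 steps on a 24-volume
phantom corpus (about two minutes on one CPU) and prints the held-out
overlap and boundary quality of the first test case:

```
dice=0.625 nsd=0.821 adb=0.70
```

— Dice 0.625 is the harmonic overlap of predicted and true lesion voxels
(a 200-step CPU run is far from converged); NSD 0.821 says 82% of boundary
surface lies within 1 voxel of the other surface; ADB is the mean boundary
distance in voxels. Exact numbers vary with the seed.

The same pipeline is scriptable from the shell:

```bash
grmaseg simulate --out data --seed 1337
grmaseg train    --out run  --data data --seed 1337 --max-steps 200
grmaseg predict  --checkpoint run/student.npz --inputs data/test_000_vol.nii.gz --out pred
grmaseg evaluate --pred pred --truth pred --tau 1.0 --csv metrics.csv
```

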