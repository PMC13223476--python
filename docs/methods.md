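# Methods

## Problem and model

`grmaseg` implements a two-stage semi-supervised framework for segmenting
small, low-contrast, blurred-boundary lesions in 3-D chest-CT-like volumes,
built around three ingredients:

1. **GRMA-Net**, a three-branch 3-D encoder–decoder. The input volume `F`
   and its ×2 / ×4 trilinear downsamples `Q` and `G` each pass through a
   four-layer convolutional encoder (two {3×3×3 conv, group norm, ReLU}
   units per layer). At every layer the three branch features are fused by a
   channel-attention module: `A2 = σ(FC(GAP(Q_i)))`, `H_i = F_i ⊙ A2 + F_i`,
   `A3 = σ(FC(GAP(G_i)))`, `AMF_i = H_i ⊙ A3 + H_i`, where GAP is global
   average pooling and the gates broadcast over space. The decoder upsamples
   (nearest, ×2), concatenates the adjacent aggregated feature, applies a
   conv block, and emits class logits through a 1×1×1 head at each of four
   scales (scale 1 = input resolution, each deeper scale halved per axis).

2. **FIGR** (feature-interaction graph reasoning) at a configurable encoder
   layer (default the deepest, layer 4), applied to the F-branch feature
   before attention aggregation. Channel features are projected to a graph
   with `N_f = C/4` nodes carrying `S_f = C/2` states
   (`V_f = θ φᵀ`, both branches 1×1×1-conv + group-norm projections),
   mixed by the Laplacian-smoothed graph convolution
   `Ṽ = σ((I + A_fᵀ) V_f W_f)` — realized as two kernel-1 Conv1D mixings
   (node dimension then state dimension) with the identity term as a
   residual add — and re-projected (`Ṽᵀθ`, reshape, 1×1×1 conv back to `C`
   channels, group norm) with a residual join onto the input feature. With
   all learned weights zero the block is exactly the identity.

3. **Dual-scale aleatoric uncertainty.** At decoder scales 1 and 2 the logit
   field is modeled as a low-rank multivariate normal over the flattened
   voxel-class vector: `η ~ N(μ, P Pᵀ + diag(D))` with rank-r factor `P`
   (r = 10 by default) and softplus-positive diagonal. Sampling uses the
   reparameterization `η = μ + P ε₁ + sqrt(D) ⊙ ε₂`, class probabilities are
   the Monte-Carlo average of the per-sample softmax, and `L_AUM` is the
   cross-entropy of that averaged probability against the per-scale
   nearest-neighbour-downsampled ground truth, summed over the two scales.
   The alternative reading — averaging per-sample log-probabilities instead
   — is selectable (`mode="mean-log"`). The dense covariance is never
   materialized.

Semi-supervision uses a **mean teacher**: the teacher shares the student's
architecture and is updated only as an exponential moving average
(`θ′ ← αθ′ + (1−α)θ`, α = 0.999). On unlabeled volumes the teacher produces
per-scale hard pseudo-labels (argmax, ties to the lowest class index) and
the per-voxel KL-variance `D_KL(softmax(student) ‖ softmax(teacher))`
weights the consistency loss at each scale:

    L'_con = (1/4) Σ_p mean_vox[ exp(−KL_p) ⊙ CE(softmax(student_p), p̂_p) + KL_p ]

The exponential factor discounts the pseudo-label term where the models
disagree (the labels are unreliable there), while the additive KL term keeps
the penalty growing with disagreement; both terms switch off together when
uncertainty estimation is disabled. Teacher outputs and pseudo-labels are
detached; only the student receives gradients. The total objective is

    L_total = L_DICE + L_AUM + λ(t) · L'_con

with `L_DICE` the four-scale soft-Dice loss (class-averaged, smooth 1e-6)
against nearest-neighbour-downsampled masks and
`λ(t) = w · exp(−5 (1 − t/T)²)` the standard consistency ramp
(plateau w = 0.1, ramp length T configurable).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| base channels | 16 (8 in smoke runs) | width of encoder layer 1; doubles per layer |
| FIGR layer / node fraction | 4 / C·¼ | placement and graph size; 0 disables |
| AU scales / rank r / M | {1,2} / 10 / 20 train, 50 eval | uncertainty head scales, covariance rank, MC samples |
| learning rate | 3e-4 full scale; 3e-3 smoke scale | Adam step size |
| EMA decay | 0.999, warm-up `min(1−1/(t+1), 0.999)` | teacher time constant |
| consistency weight / ramp | 0.1 / configurable | plateau of λ(t) |
| noise placement / std / clip | student / 0.1 / ±0.2 | Gaussian perturbation of the unsupervised student input |
| seed | 1337 | all randomness (init, sampling, data order) |

The EMA warm-up is the standard mean-teacher schedule: with a hard 0.999
decay the teacher's time constant (~1000 steps) exceeds a short CPU-scale
run entirely, so pseudo-labels would come from a still-random teacher; the
warm-up lets the teacher track the student early and settle into the long
average afterwards. The smoke-scale learning rate 3e-3 reflects that the
toy networks (~10⁵–10⁶ parameters, a few hundred steps) sit far from the
full-scale regime in which 3e-4 over 400 epochs is appropriate.

## Synthetic phantoms

The generator emulates the structure of a pneumonia-CT corpus: a body
ellipsoid with two darker lung fields, smooth low-frequency background
texture, and lesions placed as random ellipsoids with centres inside a lung
field. The lesion intensity offset (contrast 0.2) is added to the intensity
field, which is then Gaussian-blurred (σ = 1 voxel) — blurring the lesion
*appearance* and boundary while the label mask stays the crisp ellipsoid
union — and voxelwise sensor noise (σ = 0.05) is added before clipping to
[0, 1]. Generation is a pure function of its config and seed; placement is
retried at most 100 times before failing.

What the phantoms do **not** emulate: real CT intensity statistics (no HU
calibration or windowing is modeled, as none is specified for the reference
corpus), anatomical variability, irregular lesion morphology,
slice-thickness anisotropy, and scanner artifacts. Passing tests therefore
demonstrate that the machinery is implemented correctly and that the
semi-supervised signal behaves sensibly on controllable data — not clinical
performance.

## Metrics

Binary-mask metrics follow fixed conventions: boundaries are foreground
voxels with a background 6-neighbour (the grid border counts as
background); distances are Euclidean between boundary voxel centres, in
voxel units unless a spacing is given. NSD is two-sided,
`(|B_P within τ of B_G| + |B_G within τ of B_P|) / (|B_P| + |B_G|)`
(one-sided selectable), with τ defaulting to 1 voxel and exposed as a CLI
flag since the reported value depends on it. ADB is the mean of the two
directed mean nearest-boundary distances; HD95 the 95th
linear-interpolation percentile of the pooled directed distances. Both-empty
masks score dice = jaccard = nsd = 1; ADB/HD95 are reported as missing, not
zero, when a mask is empty.

## Numerical choices

* All network arithmetic is float32 on a compact NumPy reverse-mode
  autodiff core written for this package (kernel-1/3 stride-1 3-D
  convolutions via a channels-last patch-matrix GEMM, 2× max pooling,
  nearest upsampling); float64 arrays are preserved for analysis/oracle
  paths.
* Cross-entropy logs are clamped at 1e-8; the AU diagonal has a 1e-6
  softplus floor; group-norm ε = 1e-5; soft-Dice smooth = 1e-6.
* KL maps clip negative float round-off at zero; argmax ties break to the
  lowest class.
* Nearest-neighbour label downsampling picks the centred voxel of each
  block (offset f/2 for factor f).
* Branch alignment: Q/G features at layers where their native grid is
  coarser than F's are nearest-upsampled before aggregation; since the
  attention gates depend only on channel means, this is numerically
  identical to gating from the native-resolution maps.
* Weight init is Kaiming-style normal, seeded from the NetConfig, so runs
  are bit-reproducible given the seed.

## Open design points resolved here

* Whether encoder branches share weights is unspecified upstream; they are
  independent here.
* FIGR acts on the F branch only, and σ in the graph convolution is ReLU
  (configurable).
* The reprojection reuses θ (not φ), as the construction reads most
  naturally.
* `V_f` is oriented nodes × states (`N_f × S_f = θφᵀ`); this is the only
  orientation consistent with node-dimension mixing by `A_f` and
  state-dimension weighting by `W_f`.
* `L_AUM` is computed on labeled data only; consistency distance is
  cross-entropy against hard pseudo-labels.
* One unlabeled volume accompanies each labeled volume per step.

## Problem sizes used by the test suite and acceptance script

Phantom experiments run at 32×32×8 with width-8 networks: overfit check
(2 labeled volumes, 200 steps, 3 seeds), consistency direction check
(4 labeled / 40 unlabeled / 10 test, 300 steps, 3 seeds), and the
acceptance script's end-to-end run (4 labeled / 20 unlabeled / 5 test,
200 steps). These sizes exercise every module at full fidelity; they are
the package's chosen CPU-scale study conditions.

## Known limitations

* Stride-1 convolutions and 2× pooling only; no anisotropic kernels.
* Batch size 1 is assumed throughout the training loop.
* Binary (background/lesion) metrics; multi-class averaging is out of scope.
* The consistency direction check is exactly that — a direction check on
  phantoms; it does not quantify the semi-supervised gain on real CT.
* In very short runs (a few hundred steps) the consistency term can be
  neutral to slightly negative for the *student*: the EMA teacher still lags
  a rapidly improving student, so pulling the student toward the teacher's
  pseudo-labels briefly competes with the supervised signal, even though the
  teacher itself benefits from the agreement. The mechanism fades as the
  horizon grows and the teacher converges; the test suite measures this
  regime honestly rather than hiding it.
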