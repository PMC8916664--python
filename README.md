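# gaitproto

Explainable **open-set gait recognition** from multimodal shoe-insole sensors.

People can be identified by how they walk. With pressure- and IMU-equipped
insoles, each walking cycle yields a *unit step*: a `T x 28` matrix of 16
plantar-pressure channels, 6 accelerometer axes and 6 gyroscope axes sampled
at 100 Hz. `gaitproto` implements the full recognition-and-explanation
pipeline for such data, for researchers in gait biometrics and wearable
sensing who need an *open-set* recognizer — one that can also say "this
walker is nobody I know" — together with attribution maps that show *which
parts of a step* the model relies on.

## The method

**1. Prototyping encoder–decoder.** An encoder `f` with three per-modality
1-D convolutional sub-encoders (32/64/128 filters) and dense 256/128 layers
maps a unit step `s = [s_pre, s_acc, s_rot]` to a unit-norm embedding
`v ∈ R^128`. A mirrored decoder `g` reconstructs each modality. Training
minimizes

    L = L_triplet + λ · L_proto
    L_triplet = max(0, ‖v_a − v_p‖² − ‖v_a − v_n‖² + α)
    L_proto   = (1/|M|) Σ_{m∈M} ‖ĝ(f(s^m)) − ĉ_a^m‖²

where `c_a^m` is subject *a*'s **prototype** (the mean of their unit steps,
channel `m` by channel), hats denote per-channel L2 normalization, and the
triplet (anchor, positive, negative) pairs same-subject and
different-subject steps. Defaults: margin `α = 1.25`, weight `λ = 1.0`.

**2. Few-shot open-set recognition.** Subjects split 20/10/10 into
training / known / unknown groups. From `n = 10` reserved *shots* per known
subject, the pipeline computes a centroid `D_a = (1/n) Σ v_i,a` and fits a
one-class SVM per subject (RBF kernel `K(v,v') = exp(−γ‖v−v'‖²)`, dual with
box `1/(νn)` and `Σα = 1`). A query `v` goes to the nearest centroid `p` and
is accepted iff

    h_p(v) = Σ_i α_i K(v_i,p, v) − δ_p  ≥  τ

with `δ_p` anchored at a margin support vector. Defaults `γ = 2.2`,
`ν = 0.06`, `τ = −0.1`. Metrics: TPR on known-test steps (accepted *and*
correctly identified), TNR on unknown-test steps (rejected), and ACC, all
averaged over 10 repeated splits.

**3. Explanation.** Sensitivity analysis (`|∂f(s)_c/∂s|`) and LRP-ε
(relevance redistribution `R_i = Σ_j x_i w_ij / (Σ_i x_i w_ij + ε·sign) R_j`)
produce per-component maps `A_c(s)`, averaged over the 128 components and
over all training steps into a **common attribution map**. The map is
validated by *region perturbation*: rank all `T x 28` positions by relevance
magnitude, occlude quintiles O1 (most relevant) … O5, and measure how much
recognition degrades versus a size-matched random-occlusion baseline.

Since real insole datasets of this kind are private, the package ships a
first-class synthetic generator: per-subject smooth channel templates
(pressure exactly zero in the swing window), noisy time-warped step draws,
and the study-scale default of 40 subjects x 158 steps.

## Worked example

```python
import numpy as np
from gaitproto import ExperimentConfig, generate_dataset, run_experiment, run_perturbation
from gaitproto.synthetic import GenerationConfig
from gaitproto.recognizer import SplitSpec
from gaitproto.encoder import EncoderConfig

cfg = ExperimentConfig(
    generation=GenerationConfig(n_subjects=12, steps_per_subject=30, T=100),
    encoder=EncoderConfig(epochs=3, anchors_per_epoch=256, batch_size=32),
    split=SplitSpec(n_train=6, n_known=3, n_unknown=3, n_shots=10, repetitions=3),
    seed=42,
)
dataset = generate_dataset(cfg.generation)          # 12 subjects x 30 steps
result = run_experiment(dataset, cfg, keep_pipelines=1)
print(result.to_frame().to_string(index=False))

frame = run_perturbation(result.pipelines[0], cfg, np.random.default_rng(42))
print(frame[["occlusion", "TPR", "TNR", "ACC"]].to_string(index=False))
```

Output (~1 minute on one CPU core):

```
  TP  FN   TN  FP  TPR  TNR  ACC repetition
60.0 0.0 90.0 0.0  1.0  1.0  1.0          0
60.0 0.0 90.0 0.0  1.0  1.0  1.0          1
60.0 0.0 90.0 0.0  1.0  1.0  1.0          2
60.0 0.0 90.0 0.0  1.0  1.0  1.0       mean

occlusion      TPR  TNR      ACC
       O1 0.583333  1.0 0.833333
       O2 1.000000  1.0 1.000000
       O3 1.000000  1.0 1.000000
       O4 1.000000  1.0 1.000000
       O5 1.000000  1.0 1.000000
   random 0.950000  1.0 0.980000
```

Twelve well-separated synthetic subjects are recognized perfectly (TPR =
TNR = 1 on every split — each row counts the 60 known-test and 90
unknown-test steps of one repetition). The perturbation table is the
interesting part: occluding the top-relevance quintile **O1** of the
LRP common map knocks TPR down to 0.58, far below the random-occlusion
baseline (0.95), while occluding the least-relevant quintile O5 changes
nothing — the attribution map has found the step regions the recognizer
actually uses. At the full default scale (`ExperimentConfig()`: 40 x 158
steps, 10 repetitions, ~3 min) the same run prints mean TPR 0.986 / TNR
1.000 / ACC 0.993, and the ordering gains headroom: occluding O1 drives TPR
to 0.001 (random baseline: 0.592) while O5 leaves it at 0.974.

A command-line interface wraps the same stages:

```bash
gaitproto simulate --seed 1 --out data/
gaitproto train    --dataset data/ --out run/
gaitproto evaluate --dataset data/ --checkpoint run/checkpoint.npz --out metrics/
gaitproto explain  --dataset data/ --checkpoint run/checkpoint.npz --method lrp --out maps/
gaitproto perturb  --dataset data/ --checkpoint run/checkpoint.npz --out perturb/
```

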