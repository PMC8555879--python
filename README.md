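# seizadapt

Multi-class seizure-type classification from multi-lead EEG with a hybrid
deep network and **adversarial domain adaptation**: a model trained on one
labeled cohort is adapted to a new, unlabeled cohort (new patients, new
hardware) using only that cohort's raw EEG.

The package is aimed at researchers working on automated EEG analysis who
need (a) the full three-phase training protocol as a library, (b) a synthetic
EEG corpus generator so every stage is testable without credentialed clinical
data, and (c) reproducible command-line experiments.

## The model

A recording is stored as a lead × time matrix. Ending at a reference time
*t*, eight contiguous 2-s windows are cropped (a 16-s lookback). The
network has five parameter partitions:

* **g₁ — short-term feature extractor**: a 1-D squeeze-and-excitation
  residual CNN (five SE-Res blocks in series; channels 20/40/80/160/160,
  kernels 16/8/5/3/3 at full width). Each block rescales its channels by
  sigmoid excitation weights computed from a global-max-pooled channel
  descriptor, letting the network weight leads/channels differentially —
  focal seizures involve a subset of leads, generalized seizures all of
  them. A global max pool emits one 160-dim feature vector per window.
* **f₁** — a two-layer softmax head used only while g₁ is trained on single
  windows.
* **g₂ — long-term feature extractor**: three stacked merged-gate recurrent
  layers. The cell merges the forget and input gates of an LSTM into one
  update gate *u*:

      uᵗ = σ(F_u([hᵗ⁻¹, xᵗ]))
      rᵗ = σ(F_r([hᵗ⁻¹, xᵗ]))
      h̃ᵗ = tanh(F_o([hᵗ⁻¹ ⊙ rᵗ, xᵗ]))
      hᵗ = (1 − uᵗ) ⊙ hᵗ⁻¹ + uᵗ ⊙ h̃ᵗ

  Temporal max pooling after each layer collapses the 8 steps 8 → 4 → 2 → 1.
* **f₂ — seizure classifier** and **f_d — domain discriminator**: MLPs with
  two hidden layers on the deep feature hᵀ; f₂ ends in a softmax over the
  classes (Normal / FNSZ / GNSZ / CPSZ by default), f_d in a sigmoid
  estimating P(target cohort).

Training proceeds in three phases (Adam, batch 128, learning rate 0.001):

1. **Phase 1** — supervised cross-entropy training of (g₁, f₁) on labeled
   2-s ictal windows.
2. **Phase 2** — g₁ frozen; supervised training of (g₂, f₂) on labeled
   8-window sequences.
3. **Phase 3** — alternating adversarial adaptation with an unlabeled target
   corpus: train f_d to convergence on source-vs-target deep features
   (binary cross-entropy, everything else frozen), then freeze f_d and
   fine-tune (g₂, f₂) to minimize `class CE on source − domain BCE on mixed
   batches`, aligning the two cohorts in deep feature space while holding
   source accuracy.

The whole network, its gradients and the optimizer are implemented in numpy;
analytic gradients are verified against central finite differences in the
test suite.

## Worked example

Synthetic corpora stand in for clinical data: pink-plus-white-noise
background, one Hann-enveloped oscillatory burst per seizure record whose
frequency encodes the class and whose lead involvement encodes focal vs
generalized, and a parameterized source→target cohort shift (per-lead gain,
burst-frequency offset, extra sensor noise).

```python
import seizadapt as sa
from seizadapt.experiments import scaled_model_config, scaled_train_config
from seizadapt.io import CropPolicy
from seizadapt.model import SeizureHDN

spec = sa.default_spec(n_leads=8, sampling_rate=64.0)
shift = sa.default_target_shift()          # gain 1.5, +0.5 Hz, 1.5 uV noise
policy = CropPolicy(normalization="off")   # the gain shift must reach the network

source = sa.generate_corpus(spec, 50, seed=11, domain_index=0, policy=policy)
target = sa.generate_corpus(spec, 50, shift=shift, seed=12, domain_index=1, policy=policy)
src_eval = sa.generate_corpus(spec, 25, seed=13, domain_index=0, policy=policy)
tgt_eval = sa.generate_corpus(spec, 25, shift=shift, seed=14, domain_index=1, policy=policy)

model = SeizureHDN.from_sequences(source, target,
                                  config=scaled_model_config(),
                                  train_config=scaled_train_config(seed=0))
fit = model.fit()
print(fit.summary())

eX, ey, _ = sa.stack_sequences(src_eval)
tX, ty, _ = sa.stack_sequences(tgt_eval)
adapted = fit.adapt(eval_source=(eX, ey), eval_target=(tX, ty))
print(adapted.summary())
```

Output (abridged; the run takes about a minute on one CPU):

```
Hybrid deep network — supervised fit
============================================
classes:            normal, cpsz, fnsz, gnsz
sequences (source): 200
leads / window:     8 x 128 samples
phase 1 epochs:     50  (final loss 0.0003)
phase 2 epochs:     400  (final loss 0.0001)
training accuracy:  1.000

Adversarial domain adaptation
============================================
 round  disc_loss  disc_accuracy  disc_accuracy_post  source_accuracy  target_accuracy
     0        NaN          0.500                 NaN            1.000            0.390
     1      0.001          1.000               0.830            1.000            0.440
     2      0.039          0.995               0.760            1.000            0.450
     3      0.034          0.995               0.810            1.000            0.500
     4      0.037          0.980               0.840            1.000            0.510

partitions changed: g1=False, f1=False, g2=True, f2=True, fd=True
source accuracy: 1.000 -> 1.000
target accuracy: 0.390 -> 0.510
discriminator accuracy (trained -> after fine-tune): 1.000 -> 0.840
```

Reading it: the supervised model is perfect on its own cohort but drops to
0.39 on the shifted cohort; the domain discriminator separates the cohorts
perfectly (1.000), confirming a detectable shift. Four adversarial rounds
lift target accuracy to 0.51 while source accuracy stays at 1.000 and the
frozen discriminator is pushed toward chance — the method's intended effect,
at desk scale.

## Command line

```bash
seizadapt simulate --config config.yaml      # synthetic EDF corpus + annotations
seizadapt train    --config config.yaml      # phases 1-2, checkpoint + metrics
seizadapt adapt    --config config.yaml --checkpoint out/checkpoint.npz
seizadapt evaluate --config config.yaml --checkpoint out/checkpoint.npz
```

`seizadapt.cli.example_config()` returns a complete runnable YAML. Real
EDF recordings are supported via `edf_dir` + an annotation CSV
(`record_id, onset_s, offset_s, label`); non-EEG channels are filtered by
name.

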