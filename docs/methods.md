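# Methods

This note documents the model, the synthetic data it is exercised on, the
numerical choices, and the limits of what the package's tests demonstrate.

## Model and training protocol

The classifier maps an 8-window (16 s) multi-lead EEG sequence to one of M
seizure classes. Its five parameter partitions — SE-Res CNN front-end g1,
window-level head f1, merged-gate recurrent stack g2, sequence classifier
f2, domain discriminator fd — and the three-phase protocol (supervised
front-end, supervised recurrent stack with frozen front-end, alternating
adversarial adaptation) are described in the README and in the module
docstrings of `seizadapt.network` and `seizadapt.training`. Throughout,
freezing acts on whole partitions and is verified by hashing.

Design points that were genuinely open and how they were resolved:

* **Merged-gate update.** The state update is the convex combination
  `h = (1-u) ⊙ h_prev + u ⊙ h̃`, the only form consistent with a gate that
  "keeps 1-u of the past": with u = 0 the state is frozen, with u = 1 it is
  replaced. Unit tests pin both limits and a hand-computed step.
* **Gate sub-networks.** Each gate is driven by its own fully connected
  network of `gate_depth` affine layers (default 4; ReLU between layers,
  linear output before the gate non-linearity). Depth 1 recovers the
  classical single-affine gate and is the setting used by the
  hand-arithmetic oracles.
* **Pooling.** Temporal max pooling with factor 2 after each recurrent
  layer (8 → 4 → 2 → 1 steps); the single final state is the deep feature.
  Inside SE-Res blocks and at the CNN-to-vector bridge, global max pooling
  is used, matching the block's own channel-descriptor pooling.
* **Convolutions** are stride-1 with 'same' zero padding (even kernels pad
  one extra sample on the right), so length is preserved until pooling and
  kernel-length preconditions stay trivially satisfiable.
* **No batch normalization** anywhere; per-sample outputs are independent of
  batch composition by construction.
* **Initialization**: fan-in-scaled uniform, one seeded generator per
  network; all experiment randomness (init, shuffling, folds, corpus
  generation) derives from explicit integer seeds.
* **Feature standardization between g1 and g2.** After phase 1 a frozen
  per-dimension standardizer (mean/sd of g1 features over the source
  training set) is fitted and applied identically to both domains. Without
  it, raw global-max-pooled feature magnitudes saturate the recurrent gates
  and phase-2 optimization is erratic; because the same affine map is
  applied to both cohorts, domain differences remain visible to the
  discriminator. The standardizer is stored in checkpoints.
* **Adversarial term.** Implemented as gradient-sign reversal of the domain
  BCE with respect to g2/f2 (f2 receives no adversarial gradient in
  practice since fd does not depend on it). Each fine-tune round stops as
  soon as the mixed-batch BCE reaches ln 2: at that point the frozen
  discriminator is at chance, and pushing further swaps the domains in
  feature space instead of aligning them. Without this stop the per-round
  target accuracy oscillates wildly.
* **Discriminator convergence**: mean relative loss change below `disc_tol`
  (1e-3) over 5 consecutive epochs, capped at `disc_max_epochs`.
* **Losses** are the standard negated (nonnegative) cross-entropy and
  binary cross-entropy with predictions clipped at 1e-12.
* **Weight decay** is available for phases 2–3 but defaults to 0: on the
  reference corpus sizes it prevented the recurrent stack from fitting at
  all, and the feature standardizer proved to be the effective stabilizer.

## Synthetic data generator

The generator (`seizadapt.synth`) emulates the statistical skeleton an
annotated seizure corpus presents to this method, not EEG physiology:

* **Background**: pink (1/f) noise plus white Gaussian noise, each at
  `background_noise_sd` (default 1 µV-equivalent unit), per lead.
* **Seizure**: one Hann-enveloped sinusoidal burst per record. Burst
  frequency encodes the class; `involved_lead_fraction` encodes focal
  (subset of leads) vs generalized (all leads) semantics. The default
  4-class task mirrors a Normal/FNSZ/GNSZ/CPSZ setup: no burst; 9 Hz on a
  quarter of the leads; 3 Hz on all leads; 6 Hz on half the leads
  (amplitude 5, duration 10 s, in a 32-s record at 256 Hz with 20 leads).
* **Domain shift**: per-lead gain, a burst-frequency offset, and extra
  white noise. The default target shift is gain 1.5, +0.5 Hz, 1.5 µV extra
  noise. Two constraints pin it: the generator's detectability contract (a
  two-layer net on pooled band-power features must separate 200+200
  source/target sequences at ≥ 80%; measured ≈ 0.98) and well-posedness of
  unsupervised alignment — the frequency offset must stay well below the
  3 Hz class spacing, otherwise each target class sits between two source
  classes and alignment has no class-consistent solution.
* **Determinism**: record r of class c in a corpus with master seed m is
  generated from `SeedSequence([m, c, r])`, so corpora are reproducible
  record by record; identical (spec, shift, seed) gives bit-identical
  output.

What the generator does **not** model: artifacts (eye blinks, muscle, line
noise), non-stationary background, spike-wave morphology, inter-seizure
variability within a patient, or realistic electrode geometry. Passing
tests therefore demonstrate that the implementation realizes the method and
that the method behaves as claimed under its own assumptions — not clinical
performance on real EEG.

## Windowing and normalization

Sequences are 8 contiguous, non-overlapping 2-s windows ending at a
reference time (event midpoint and event onset for seizures; a 16-s stride
outside a ±60 s peri-ictal margin for interictal samples). Time is seconds
from record start, intervals half-open, sample indices 0-based. References
earlier than the 16-s lookback are skipped (real recordings) or moved
forward to the earliest croppable time (synthetic corpus generation, where
the record is known to be burst-free outside the event).

Per-window z-scoring of each lead is the `CropPolicy` default and
stabilizes training on heterogeneous recordings — but it also erases any
gain component of a cohort shift before the network can see it. The
reference adaptation experiment therefore crops with `normalization="off"`:
amplitude differences between cohorts are exactly the kind of variation the
adaptation phase exists to absorb, so normalizing them away would bypass
the method under study. The switch (`off` / `per-window` / `per-record`) is
part of the cropping policy and recorded with every experiment config.

## Reference (scaled-down) experiment

`seizadapt.experiments.run_scaled_experiment` fixes the package's reference
conditions, chosen once to keep a full three-seed run within minutes on one
CPU while preserving every structural element of the method:

* corpora: 4 classes × 50 sequences per domain (200/domain) for training,
  25 per class per domain held out for evaluation; 8 leads; 2-s windows at
  64 Hz (128 samples);
* network: channels 8/16/16/32/32 with the full kernel schedule 16/8/5/3/3,
  excitation hidden 8, hidden dim 32, gate depth 2, heads of width 32;
* schedule: phase 1 50 epochs on the last 2 (ictal) windows of each
  sequence; phase 2 400 epochs; discriminator ≤ 300 epochs per round;
  4 adversarial rounds of ≤ 60 fine-tune steps at learning rate 3e-4 with
  the ln 2 stop.

Phase-1 windows are taken from the sequence tail because midpoint-referenced
sequences are ictal only in their last ~3 windows; labeling pre-ictal
background with the seizure class would corrupt the window-level objective.

Measured quantities (held-out, target labels used for evaluation only):
source and target accuracy before and after adaptation, and the
discriminator's held-out domain accuracy after training vs after the
fine-tune half-step. `scripts/acceptance.py` reports the medians over three
seeds.

## Known limitations

* The adversarial alignment is not monotone per seed: individual runs can
  regress on the target while the median over seeds improves. This is
  inherent to adversarial objectives at these sample sizes.
* The numpy engine is float64 and single-threaded matmul-bound; it is sized
  for desk-scale experiments and gradient verification, not for full-width
  training on clinical corpora.
* EDF support covers the standard 16-bit container (one writer-side data
  record per second); EDF+ annotations embedded in the file are not parsed —
  events come from the CSV table.
* Per-patient vs per-corpus adaptation is a deployment choice; the API
  takes whatever target set it is given and takes no position.
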