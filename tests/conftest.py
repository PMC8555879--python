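"""Shared fixtures: tiny synthetic specs and reduced network configs.

Everything is generated programmatically; no fixture files on disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from seizadapt.io import CropPolicy, stack_sequences
from seizadapt.network import HDNConfig, HDNetwork
from seizadapt.synth import ClassDef, SyntheticSpec, default_classes, generate_corpus
from seizadapt.training import TrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    """4 leads at 32 Hz: the cheapest spec that exercises the full pipeline."""
    return SyntheticSpec(n_leads=4, sampling_rate=32.0, record_duration=24.0,
                         class_defs=default_classes(burst_amplitude=5.0,
                                                    burst_duration=6.0))


@pytest.fixture(scope="session")
def tiny_config() -> HDNConfig:
    return HDNConfig(n_leads=4, n_classes=4, senet_channels=(4, 6),
                     senet_kernels=(3, 3), excitation_hidden=3, f1_hidden=8,
                     hidden_dim=6, gate_depth=2, classifier_hidden=8,
                     discriminator_hidden=8)


@pytest.fixture
def tiny_net(tiny_config) -> HDNetwork:
    return HDNetwork(tiny_config, seed=7)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_spec):
    """12 labeled sequences (3 per class), stacked."""
    seqs = generate_corpus(tiny_spec, 3, seed=99, domain_index=0)
    return stack_sequences(seqs)


@pytest.fixture
def fast_train_config() -> TrainConfig:
    return TrainConfig(epochs_phase1=2, epochs_phase2=3, disc_max_epochs=3,
                       adversarial_rounds=1, finetune_steps=2, batch_size=16,
                       seed=0)
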