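"""The hybrid deep network (HDN) for multi-class seizure classification.

Architecture
------------
* ``g1`` — a 1-D squeeze-and-excitation residual CNN (SENet): five SE-Res
  blocks in series (channels 20/40/80/160/160, kernels 16/8/5/3/3 at the
  default width), each block rescaling its channels by sigmoid excitation
  weights computed from a global-max-pooled channel descriptor.  A final
  global max pool emits one short-term feature vector per 2-s window.
* ``f1`` — a two-layer fully connected softmax head used only while the
  front-end is trained on single windows.
* ``g2`` — three stacked merged-gate recurrent layers.  The cell merges the
  forget and input gates of an LSTM into a single update gate ``u``::

      u  = sigmoid(F_u([h_prev, x]))
      r  = sigmoid(F_r([h_prev, x]))
      h~ = tanh(F_o([h_prev * r, x]))
      h  = (1 - u) * h_prev + u * h~

  Each gate is controlled by its own small fully connected network
  (``gate_depth`` affine layers; depth 1 reduces to the classical single
  affine gate).  After each recurrent layer a temporal max pool halves the
  sequence, so 8 input steps collapse 8 -> 4 -> 2 -> 1.
* ``f2`` — seizure classifier: an MLP with two hidden layers and a softmax
  output over the seizure classes.
* ``fd`` — domain discriminator: an MLP with two hidden layers and a single
  sigmoid output estimating P(target domain | deep feature).

Parameters are partitioned exactly along these five sub-networks; the
training phases freeze and update whole partitions, never single arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nnet import (
    MLP,
    Conv1d,
    Dense,
    GlobalMaxPool1d,
    Module,
    TemporalMaxPool,
    params_hash,
    sigmoid,
    softmax,
)

CHECKPOINT_FORMAT_VERSION = 1
PARTITIONS = ("g1", "f1", "g2", "f2", "fd")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SEResBlockConfig:
    in_channels: int
    out_channels: int
    kernel_length: int
    excitation_hidden: int = 20

    def __post_init__(self) -> None:
        for name in ("in_channels", "out_channels", "kernel_length", "excitation_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class SENetConfig:
    n_leads: int
    blocks: tuple[SEResBlockConfig, ...]

    def __post_init__(self) -> None:
        if self.n_leads < 1:
            raise ValueError("n_leads must be >= 1")
        if not self.blocks:
            raise ValueError("SENet needs at least one block")
        if self.blocks[0].in_channels != self.n_leads:
            raise ValueError("first block must take n_leads input channels")
        for prev, nxt in zip(self.blocks, self.blocks[1:]):
            if nxt.in_channels != prev.out_channels:
                raise ValueError("block channel chain broken: "
                                 f"{prev.out_channels} -> {nxt.in_channels}")

    @property
    def feature_dim(self) -> int:
        return self.blocks[-1].out_channels

    @classmethod
    def default(cls, n_leads: int = 20,
                channels: tuple[int, ...] = (20, 40, 80, 160, 160),
                kernels: tuple[int, ...] = (16, 8, 5, 3, 3),
                excitation_hidden: int = 20) -> "SENetConfig":
        if len(channels) != len(kernels):
            raise ValueError("channels and kernels must have equal length")
        blocks = []
        cin = n_leads
        for cout, k in zip(channels, kernels):
            blocks.append(SEResBlockConfig(cin, cout, k, excitation_hidden))
            cin = cout
        return cls(n_leads=n_leads, blocks=tuple(blocks))


@dataclass(frozen=True)
class HDNConfig:
    """Full network configuration; defaults follow the reference architecture."""

    n_leads: int = 20
    n_classes: int = 4
    senet_channels: tuple[int, ...] = (20, 40, 80, 160, 160)
    senet_kernels: tuple[int, ...] = (16, 8, 5, 3, 3)
    excitation_hidden: int = 20
    f1_hidden: int = 64
    hidden_dim: int = 128
    gate_depth: int = 4
    n_steps: int = 8
    pool_factor: int = 2
    n_recurrent_layers: int = 3
    classifier_hidden: int = 64
    discriminator_hidden: int = 64

    def senet_config(self) -> SENetConfig:
        return SENetConfig.default(self.n_leads, self.senet_channels,
                                   self.senet_kernels, self.excitation_hidden)

    @property
    def feature_dim(self) -> int:
        return self.senet_channels[-1]

    def to_dict(self) -> dict:
        return {
            "n_leads": self.n_leads, "n_classes": self.n_classes,
            "senet_channels": list(self.senet_channels),
            "senet_kernels": list(self.senet_kernels),
            "excitation_hidden": self.excitation_hidden,
            "f1_hidden": self.f1_hidden, "hidden_dim": self.hidden_dim,
            "gate_depth": self.gate_depth, "n_steps": self.n_steps,
            "pool_factor": self.pool_factor,
            "n_recurrent_layers": self.n_recurrent_layers,
            "classifier_hidden": self.classifier_hidden,
            "discriminator_hidden": self.discriminator_hidden,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HDNConfig":
        d = dict(d)
        for key in ("senet_channels", "senet_kernels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# SE-Res front-end
# ---------------------------------------------------------------------------

class SEResBlock(Module):
    """Residual conv block with channel excitation.

    out = z * excite(gmp(z)) + skip(x), with z = relu(conv2(relu(conv1(x))))
    and a 1x1 convolution on the skip path whenever channel counts differ.
    ``excitation_override`` (None, scalar, or [C_out] vector) replaces the
    excitation weights — a diagnostic hook for isolating the residual path.
    """

    def __init__(self, config: SEResBlockConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.config = config
        self.conv1 = self.add_child("conv1", Conv1d(config.in_channels, config.out_channels,
                                                    config.kernel_length, rng))
        self.conv2 = self.add_child("conv2", Conv1d(config.out_channels, config.out_channels,
                                                    config.kernel_length, rng))
        self.fc1 = self.add_child("fc1", Dense(config.out_channels, config.excitation_hidden, rng))
        self.fc2 = self.add_child("fc2", Dense(config.excitation_hidden, config.out_channels, rng))
        self.skip = None
        if config.in_channels != config.out_channels:
            self.skip = self.add_child("skip", Conv1d(config.in_channels, config.out_channels, 1, rng))
        self.gmp = GlobalMaxPool1d()
        self.excitation_override: float | np.ndarray | None = None

    def forward(self, x: np.ndarray):
        if x.shape[2] < self.config.kernel_length:
            raise ValueError(f"input length {x.shape[2]} shorter than kernel "
                             f"{self.config.kernel_length}")
        a1, c1 = self.conv1.forward(x)
        r1 = np.maximum(a1, 0.0)
        a2, c2 = self.conv2.forward(r1)
        z = np.maximum(a2, 0.0)
        p, cp = self.gmp.forward(z)
        e_pre, ce1 = self.fc1.forward(p)
        e_hidden = np.maximum(e_pre, 0.0)
        s_pre, ce2 = self.fc2.forward(e_hidden)
        s = sigmoid(s_pre)
        if self.excitation_override is not None:
            s = np.broadcast_to(np.asarray(self.excitation_override, dtype=float),
                                s.shape).copy()
        if self.skip is not None:
            skip_out, cskip = self.skip.forward(x)
        else:
            skip_out, cskip = x, None
        if skip_out.shape != z.shape:
            raise ValueError(f"main/skip shape mismatch: {z.shape} vs {skip_out.shape}")
        out = z * s[:, :, None] + skip_out
        cache = (c1, a1, c2, a2, z, cp, ce1, e_pre, ce2, s, cskip)
        return out, cache

    def backward(self, dy: np.ndarray, cache):
        c1, a1, c2, a2, z, cp, ce1, e_pre, ce2, s, cskip = cache
        if self.skip is not None:
            dx = self.skip.backward(dy, cskip)
        else:
            dx = dy.copy()
        dz = dy * s[:, :, None]
        if self.excitation_override is None:
            ds = (dy * z).sum(axis=2)
            ds_pre = ds * s * (1.0 - s)
            de_hidden = self.fc2.backward(ds_pre, ce2)
            de_pre = de_hidden * (e_pre > 0)
            dp = self.fc1.backward(de_pre, ce1)
            dz = dz + self.gmp.backward(dp, cp)
        da2 = dz * (a2 > 0)
        dr1 = self.conv2.backward(da2, c2)
        da1 = dr1 * (a1 > 0)
        dx = dx + self.conv1.backward(da1, c1)
        return dx


class SENet(Module):
    """Short-term feature extractor g1: SE-Res blocks + global max pool."""

    def __init__(self, config: SENetConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.config = config
        self.blocks = [self.add_child(f"block{i}", SEResBlock(bc, rng))
                       for i, bc in enumerate(config.blocks)]
        self.gmp = GlobalMaxPool1d()

    def forward(self, x: np.ndarray):
        if x.ndim != 3 or x.shape[1] != self.config.n_leads:
            raise ValueError(f"SENet expected [B, {self.config.n_leads}, L] input, "
                             f"got shape {x.shape}")
        caches = []
        for block in self.blocks:
            x, c = block.forward(x)
            caches.append(c)
        feat, cg = self.gmp.forward(x)
        caches.append(cg)
        return feat, caches

    def backward(self, dfeat: np.ndarray, caches):
        dx = self.gmp.backward(dfeat, caches[-1])
        for block, c in zip(reversed(self.blocks), reversed(caches[:-1])):
            dx = block.backward(dx, c)
        return dx


# ---------------------------------------------------------------------------
# merged-gate recurrent stack
# ---------------------------------------------------------------------------

class RecurrentCell(Module):
    """Merged-gate recurrent cell; each gate driven by its own MLP."""

    def __init__(self, input_dim: int, hidden_dim: int, gate_depth: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if gate_depth < 1:
            raise ValueError("gate_depth must be >= 1")
        self.input_dim, self.hidden_dim = input_dim, hidden_dim
        dims = [hidden_dim + input_dim] + [hidden_dim] * gate_depth
        self.F_u = self.add_child("F_u", MLP(dims, rng))
        self.F_r = self.add_child("F_r", MLP(dims, rng))
        self.F_o = self.add_child("F_o", MLP(dims, rng))

    def step(self, h_prev: np.ndarray, x_t: np.ndarray):
        if h_prev.shape[-1] != self.hidden_dim or x_t.shape[-1] != self.input_dim:
            raise ValueError(f"cell expected state dim {self.hidden_dim} / input dim "
                             f"{self.input_dim}, got {h_prev.shape[-1]} / {x_t.shape[-1]}")
        hx = np.concatenate([h_prev, x_t], axis=-1)
        au, cu = self.F_u.forward(hx)
        u = sigmoid(au)
        ar, cr = self.F_r.forward(hx)
        r = sigmoid(ar)
        gated = np.concatenate([h_prev * r, x_t], axis=-1)
        ao, co = self.F_o.forward(gated)
        h_tilde = np.tanh(ao)
        h = (1.0 - u) * h_prev + u * h_tilde
        cache = (h_prev, u, r, h_tilde, cu, cr, co)
        return h, cache

    def step_backward(self, dh: np.ndarray, cache):
        h_prev, u, r, h_tilde, cu, cr, co = cache
        H = self.hidden_dim
        du = dh * (h_tilde - h_prev)
        dh_tilde = dh * u
        dh_prev = dh * (1.0 - u)
        dao = dh_tilde * (1.0 - h_tilde * h_tilde)
        dgated = self.F_o.backward(dao, co)
        d_hr, dx = dgated[..., :H], dgated[..., H:].copy()
        dh_prev = dh_prev + d_hr * r
        dr = d_hr * h_prev
        dhx = self.F_r.backward(dr * r * (1.0 - r), cr)
        dhx = dhx + self.F_u.backward(du * u * (1.0 - u), cu)
        dh_prev = dh_prev + dhx[..., :H]
        dx = dx + dhx[..., H:]
        return dh_prev, dx


class RecurrentLayer(Module):
    """Unrolls one cell over T steps from a zero initial state."""

    def __init__(self, cell: RecurrentCell) -> None:
        super().__init__()
        self.cell = self.add_child("cell", cell)

    def forward(self, x: np.ndarray):
        B, T, _ = x.shape
        h = np.zeros((B, self.cell.hidden_dim))
        states, caches = [], []
        for t in range(T):
            h, c = self.cell.step(h, x[:, t, :])
            states.append(h)
            caches.append(c)
        return np.stack(states, axis=1), caches

    def backward(self, dH: np.ndarray, caches):
        B, T, _ = dH.shape
        dx = np.zeros((B, T, self.cell.input_dim))
        dh = np.zeros((B, self.cell.hidden_dim))
        for t in reversed(range(T)):
            dh_total = dh + dH[:, t, :]
            dh, dx_t = self.cell.step_backward(dh_total, caches[t])
            dx[:, t, :] = dx_t
        return dx


class RecurrentStack(Module):
    """g2: recurrent layers, each followed by temporal max pooling.

    With 3 layers and pool factor 2, 8 steps collapse 8 -> 4 -> 2 -> 1; the
    single pooled state is the long-term deep feature.
    """

    def __init__(self, input_dim: int, hidden_dim: int, gate_depth: int,
                 n_layers: int, pool_factor: int, n_steps: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if n_steps != pool_factor ** n_layers:
            raise ValueError(f"n_steps={n_steps} must equal pool_factor**n_layers="
                             f"{pool_factor ** n_layers}")
        self.n_steps = n_steps
        self.hidden_dim = hidden_dim
        self.layers: list[RecurrentLayer] = []
        self.pools: list[TemporalMaxPool] = []
        d = input_dim
        for i in range(n_layers):
            layer = RecurrentLayer(RecurrentCell(d, hidden_dim, gate_depth, rng))
            self.layers.append(self.add_child(f"layer{i}", layer))
            self.pools.append(TemporalMaxPool(pool_factor))
            d = hidden_dim

    def forward(self, x: np.ndarray):
        if x.ndim != 3 or x.shape[1] != self.n_steps:
            raise ValueError(f"recurrent stack expected [B, {self.n_steps}, D] "
                             f"sequences, got shape {x.shape}")
        caches = []
        for layer, pool in zip(self.layers, self.pools):
            x, cl = layer.forward(x)
            x, cp = pool.forward(x)
            caches.append((cl, cp))
        return x[:, 0, :], caches

    def backward(self, dfeat: np.ndarray, caches):
        dx = dfeat[:, None, :]
        for layer, pool, (cl, cp) in zip(reversed(self.layers), reversed(self.pools),
                                         reversed(caches)):
            dx = pool.backward(dx, cp)
            dx = layer.backward(dx, cl)
        return dx


# ---------------------------------------------------------------------------
# full network with partitioned parameters
# ---------------------------------------------------------------------------

class HDNetwork:
    """The five-partition hybrid network: g1, f1, g2, f2, fd."""

    def __init__(self, config: HDNConfig, seed: int) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        F = config.feature_dim
        # frozen standardization of g1 features, fitted on source-train data
        # after phase 1; applied identically to both domains so cohort shifts
        # stay visible while the recurrent stack sees O(1) inputs
        self.feature_mu = np.zeros(F)
        self.feature_sd = np.ones(F)
        self.g1 = SENet(config.senet_config(), rng)
        self.f1 = MLP([F, config.f1_hidden, config.n_classes], rng)
        self.g2 = RecurrentStack(F, config.hidden_dim, config.gate_depth,
                                 config.n_recurrent_layers, config.pool_factor,
                                 config.n_steps, rng)
        w = config.classifier_hidden
        self.f2 = MLP([config.hidden_dim, w, w, config.n_classes], rng)
        wd = config.discriminator_hidden
        self.fd = MLP([config.hidden_dim, wd, wd, 1], rng)

    @property
    def partitions(self) -> dict[str, Module]:
        return {"g1": self.g1, "f1": self.f1, "g2": self.g2, "f2": self.f2, "fd": self.fd}

    def partition_hashes(self) -> dict[str, str]:
        return {name: params_hash(mod) for name, mod in self.partitions.items()}

    # -- forward paths -----------------------------------------------------

    def window_features(self, windows: np.ndarray) -> np.ndarray:
        """g1 on a batch of 2-s windows [B, n_leads, L] -> [B, F],
        standardized by the fitted feature statistics."""
        feat, _ = self.g1.forward(windows)
        return (feat - self.feature_mu) / self.feature_sd

    def fit_feature_norm(self, sequences: np.ndarray, batch: int = 64) -> None:
        """Fit the frozen per-dimension feature standardizer on (source
        training) sequences ``[N, T, n_leads, L]``."""
        self.feature_mu = np.zeros(self.config.feature_dim)
        self.feature_sd = np.ones(self.config.feature_dim)
        feats = self.sequence_features(sequences, batch=batch)
        flat = feats.reshape(-1, feats.shape[-1])
        self.feature_mu = flat.mean(axis=0)
        self.feature_sd = np.maximum(flat.std(axis=0), 1e-8)

    def sequence_features(self, sequences: np.ndarray, batch: int = 64) -> np.ndarray:
        """g1 applied window-wise: [N, T, n_leads, L] -> [N, T, F]."""
        N, T = sequences.shape[:2]
        flat = sequences.reshape(N * T, *sequences.shape[2:])
        outs = [self.window_features(flat[i:i + batch]) for i in range(0, len(flat), batch)]
        return np.concatenate(outs, axis=0).reshape(N, T, -1)

    def deep_features(self, feature_seqs: np.ndarray) -> np.ndarray:
        """g2 on precomputed short-term features [N, T, F] -> [N, H]."""
        h, _ = self.g2.forward(feature_seqs)
        return h

    def classify_windows(self, windows: np.ndarray) -> np.ndarray:
        # f1 is the phase-1 head: it reads raw g1 features, fitted before the
        # feature standardizer exists
        feat, _ = self.g1.forward(windows)
        logits, _ = self.f1.forward(feat)
        return softmax(logits)

    def classify_sequences(self, sequences: np.ndarray) -> np.ndarray:
        """[N, T, n_leads, L] -> class probabilities [N, M]."""
        h = self.deep_features(self.sequence_features(sequences))
        logits, _ = self.f2.forward(h)
        return softmax(logits)

    def discriminate_features(self, feature_seqs: np.ndarray) -> np.ndarray:
        """P(target | deep feature) from precomputed short-term features."""
        logits, _ = self.fd.forward(self.deep_features(feature_seqs))
        return sigmoid(logits)[:, 0]

    def discriminate_sequences(self, sequences: np.ndarray) -> np.ndarray:
        return self.discriminate_features(self.sequence_features(sequences))

    # -- checkpointing -----------------------------------------------------

    def save_checkpoint(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {}
        for pname, mod in self.partitions.items():
            for key, arr in mod.named_params():
                arrays[f"{pname}/{key}"] = arr
        arrays["norm/mu"] = self.feature_mu
        arrays["norm/sd"] = self.feature_sd
        meta = json.dumps({"format_version": CHECKPOINT_FORMAT_VERSION,
                           "config": self.config.to_dict()})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    def load_checkpoint(self, path: str | Path) -> None:
        config, arrays = read_checkpoint(path)
        if config.to_dict() != self.config.to_dict():
            raise ValueError("checkpoint config does not match network config")
        for pname, mod in self.partitions.items():
            prefix = f"{pname}/"
            state = {k[len(prefix):]: v for k, v in arrays.items() if k.startswith(prefix)}
            mod.load_state_dict(state)
        self.feature_mu = np.asarray(arrays["norm/mu"], dtype=float)
        self.feature_sd = np.asarray(arrays["norm/sd"], dtype=float)


def read_checkpoint(path: str | Path) -> tuple[HDNConfig, dict[str, np.ndarray]]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format: {meta.get('format_version')}")
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    return HDNConfig.from_dict(meta["config"]), arrays


def load_network(path: str | Path) -> HDNetwork:
    config, _ = read_checkpoint(path)
    net = HDNetwork(config, seed=0)
    net.load_checkpoint(path)
    return net


# ---------------------------------------------------------------------------
# functional views of the individual forward operations
# ---------------------------------------------------------------------------

def se_res_block_forward(x: np.ndarray, block: SEResBlock) -> np.ndarray:
    y, _ = block.forward(x)
    return y


def senet_forward(window: np.ndarray, senet: SENet) -> np.ndarray:
    single = window.ndim == 2
    if single:
        window = window[None]
    feat, _ = senet.forward(window)
    return feat[0] if single else feat


def recurrent_cell_step(h_prev: np.ndarray, x_t: np.ndarray, cell: RecurrentCell) -> np.ndarray:
    single = h_prev.ndim == 1
    if single:
        h_prev, x_t = h_prev[None], x_t[None]
    h, _ = cell.step(h_prev, x_t)
    return h[0] if single else h


def recurrent_stack_forward(sequence: np.ndarray, stack: RecurrentStack) -> np.ndarray:
    single = sequence.ndim == 2
    if single:
        sequence = sequence[None]
    h, _ = stack.forward(sequence)
    return h[0] if single else h


def classifier_forward(feature: np.ndarray, head: MLP) -> np.ndarray:
    single = feature.ndim == 1
    if single:
        feature = feature[None]
    logits, _ = head.forward(feature)
    probs = softmax(logits)
    return probs[0] if single else probs


def discriminator_forward(feature: np.ndarray, head: MLP) -> np.ndarray:
    single = feature.ndim == 1
    if single:
        feature = feature[None]
    logits, _ = head.forward(feature)
    p = sigmoid(logits)[:, 0]
    return p[0] if single else p
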