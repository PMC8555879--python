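"""Three-phase training of the hybrid network, plus adaptation and metrics.

Phase 1 trains the SE-Res front-end ``g1`` with its window-level softmax head
``f1`` on labeled 2-s windows (cross-entropy).  Phase 2 freezes ``g1`` and
trains the recurrent stack ``g2`` and seizure classifier ``f2`` on labeled
8-window sequences.  Phase 3 is alternating adversarial domain adaptation:
with everything else frozen, the domain discriminator ``fd`` is trained to
convergence on source-vs-target deep features (binary cross-entropy); then,
with ``fd`` and ``g1`` frozen, ``g2``/``f2`` are fine-tuned to minimize

    class CE on labeled source  -  domain BCE on mixed batches,

i.e. the feature map is pushed to confuse the discriminator (gradient-sign
reversal on the BCE term) while source-label accuracy is maintained.

Because ``g1`` never changes after phase 1, phases 2-3 run on short-term
features precomputed once per dataset; that is an exact reformulation, not an
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .network import HDNetwork
from .nnet import Adam, params_hash, sigmoid, softmax

EPS = 1e-12


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"labels out of range for {n_classes} classes")
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def cross_entropy(y: np.ndarray, y_hat: np.ndarray, eps: float = EPS) -> float:
    """Mean categorical cross-entropy -(1/N) sum_i sum_c y_ic log y^_ic."""
    y, y_hat = np.asarray(y, dtype=float), np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: targets {y.shape} vs predictions {y_hat.shape}")
    return float(-(y * np.log(np.clip(y_hat, eps, None))).sum() / y.shape[0])


def domain_bce(d: np.ndarray, d_hat: np.ndarray, eps: float = EPS) -> float:
    """Mean binary cross-entropy over domain indices d in {0,1}."""
    d, d_hat = np.asarray(d, dtype=float).ravel(), np.asarray(d_hat, dtype=float).ravel()
    if d.shape != d_hat.shape:
        raise ValueError(f"shape mismatch: domains {d.shape} vs predictions {d_hat.shape}")
    d_hat = np.clip(d_hat, eps, 1.0 - eps)
    return float(-(d * np.log(d_hat) + (1.0 - d) * np.log(1.0 - d_hat)).mean())


# ---------------------------------------------------------------------------
# batches and configuration
# ---------------------------------------------------------------------------

@dataclass
class LabeledBatch:
    """Mini-batch of inputs with one-hot class labels."""

    x: np.ndarray
    y: np.ndarray  # [N_b, M] one-hot

    def __post_init__(self) -> None:
        if self.x.shape[0] != self.y.shape[0] or self.x.shape[0] < 1:
            raise ValueError("batch size mismatch or empty batch")
        if not np.allclose(self.y.sum(axis=1), 1.0):
            raise ValueError("labels must be one-hot (rows summing to 1)")


@dataclass
class DomainBatch:
    """Mini-batch with domain indices; both domains must be present."""

    x: np.ndarray
    d: np.ndarray  # [N_b] in {0, 1}

    def __post_init__(self) -> None:
        d = np.asarray(self.d)
        if not set(np.unique(d)) <= {0, 1}:
            raise ValueError("domain indices must be 0 (source) or 1 (target)")
        if len(set(np.unique(d))) < 2:
            raise ValueError("a domain batch must contain both domains")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the reference protocol
    (Adam, batch size 128, learning rate 0.001)."""

    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs_phase1: int = 100
    epochs_phase2: int = 700
    disc_max_epochs: int = 100
    disc_tol: float = 1e-3       # relative loss change defining convergence
    disc_window: int = 5         # consecutive epochs averaged for the test
    adversarial_rounds: int = 5
    weight_decay: float = 0.0    # L2 penalty applied in phases 2-3 (g2/f2)
    finetune_steps: int = 50     # g2/f2 updates per adversarial round
    finetune_lr: float | None = None  # None -> learning_rate
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.disc_tol) <= 0:
            raise ValueError("learning_rate, batch_size and disc_tol must be positive")
        for name in ("epochs_phase1", "epochs_phase2", "disc_max_epochs",
                     "adversarial_rounds", "finetune_steps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class AdaptationReport:
    """Per-round adaptation record.

    Row 0 is the pre-adaptation baseline; subsequent rows follow each
    discriminator-train / fine-tune alternation.  ``disc_accuracy`` is the
    held-out domain accuracy right after discriminator training;
    ``disc_accuracy_post`` is the same discriminator re-evaluated after the
    fine-tune half-step (the adversarial objective should push it down).
    """

    rows: list[dict] = field(default_factory=list)
    changed: dict[str, bool] = field(default_factory=dict)

    def add(self, **kwargs) -> None:
        self.rows.append(kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _minibatches(rng: np.random.Generator, n: int, batch_size: int):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


# ---------------------------------------------------------------------------
# supervised phases
# ---------------------------------------------------------------------------

def train_phase1(net: HDNetwork, windows: np.ndarray, labels: np.ndarray,
                 config: TrainConfig) -> list[float]:
    """Supervised training of g1 + f1 on labeled 2-s windows.

    Only ``theta_g1`` and ``theta_f1`` are updated.  Returns the per-epoch
    mean cross-entropy history.
    """
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("phase 1 needs labels from at least 2 classes")
    M = net.config.n_classes
    Y = one_hot(labels, M)
    rng = np.random.default_rng(config.seed)
    opt = Adam([net.g1, net.f1], lr=config.learning_rate)
    history: list[float] = []
    for _ in range(config.epochs_phase1):
        losses = []
        for idx in _minibatches(rng, len(windows), config.batch_size):
            xb, yb = windows[idx], Y[idx]
            feat, cg1 = net.g1.forward(xb)
            logits, cf1 = net.f1.forward(feat)
            p = softmax(logits)
            losses.append(cross_entropy(yb, p))
            opt.zero_grad()
            dlogits = (p - yb) / len(idx)
            dfeat = net.f1.backward(dlogits, cf1)
            net.g1.backward(dfeat, cg1)
            opt.step()
        history.append(float(np.mean(losses)))
    return history


def train_phase2(net: HDNetwork, sequences: np.ndarray, labels: np.ndarray,
                 config: TrainConfig,
                 features: np.ndarray | None = None) -> dict[str, list[float]]:
    """Supervised training of g2 + f2 on labeled window sequences.

    ``g1`` is frozen; pass ``features`` ([N, 8, F], from
    ``net.sequence_features``) to skip recomputing the frozen front-end.
    Returns per-epoch loss and training-accuracy histories.
    """
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("phase 2 needs labels from at least 2 classes")
    if features is None:
        features = net.sequence_features(sequences)
    Y = one_hot(labels, net.config.n_classes)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam([net.g2, net.f2], lr=config.learning_rate,
               weight_decay=config.weight_decay)
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    for _ in range(config.epochs_phase2):
        losses, correct = [], 0
        for idx in _minibatches(rng, len(features), config.batch_size):
            xb, yb = features[idx], Y[idx]
            h, cg2 = net.g2.forward(xb)
            logits, cf2 = net.f2.forward(h)
            p = softmax(logits)
            losses.append(cross_entropy(yb, p))
            correct += int((p.argmax(1) == yb.argmax(1)).sum())
            opt.zero_grad()
            dlogits = (p - yb) / len(idx)
            dh = net.f2.backward(dlogits, cf2)
            net.g2.backward(dh, cg2)
            opt.step()
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / len(features))
    return history


# ---------------------------------------------------------------------------
# adversarial phase
# ---------------------------------------------------------------------------

def train_discriminator(net: HDNetwork, source_features: np.ndarray,
                        target_features: np.ndarray, config: TrainConfig,
                        rng: np.random.Generator | None = None) -> list[float]:
    """Train fd to separate source from target deep features; all other
    partitions are frozen.  Stops when the mean relative loss change over
    ``disc_window`` consecutive epochs falls below ``disc_tol``, or at
    ``disc_max_epochs``.
    """
    if len(source_features) == 0 or len(target_features) == 0:
        raise ValueError("discriminator training needs both domains present")
    rng = rng or np.random.default_rng(config.seed + 2)
    opt = Adam([net.fd], lr=config.learning_rate)
    half = max(1, config.batch_size // 2)
    # g2 is frozen here, so its deep features are fixed for the whole loop
    hs = net.deep_features(source_features)
    ht = net.deep_features(target_features)
    history: list[float] = []
    for _ in range(config.disc_max_epochs):
        losses = []
        n_batches = max(1, min(len(hs), len(ht)) // half)
        for _b in range(n_batches):
            si = rng.choice(len(hs), size=min(half, len(hs)), replace=False)
            ti = rng.choice(len(ht), size=min(half, len(ht)), replace=False)
            batch = DomainBatch(
                x=np.concatenate([hs[si], ht[ti]]),
                d=np.concatenate([np.zeros(len(si), int), np.ones(len(ti), int)]))
            logits, cfd = net.fd.forward(batch.x)
            p = sigmoid(logits)[:, 0]
            losses.append(domain_bce(batch.d, p))
            opt.zero_grad()
            dlogit = ((p - batch.d) / len(batch.d))[:, None]
            net.fd.backward(dlogit, cfd)
            opt.step()
        history.append(float(np.mean(losses)))
        if len(history) > config.disc_window:
            recent = np.array(history[-(config.disc_window + 1):])
            rel = np.abs(np.diff(recent)) / np.maximum(np.abs(recent[:-1]), EPS)
            if rel.mean() < config.disc_tol:
                break
    return history


def adversarial_finetune(net: HDNetwork, source_features: np.ndarray,
                         source_labels: np.ndarray, target_features: np.ndarray,
                         config: TrainConfig, steps: int | None = None,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Fine-tune g2 + f2 against the frozen discriminator.

    Minimizes [class CE on labeled source] - [domain BCE on mixed batches]
    over theta_g2/theta_f2; the sign-reversed BCE gradient pushes deep
    features toward discriminator confusion.  ``fd`` and ``g1`` stay frozen.
    Returns the per-step record of both loss terms.

    The adversarial term is maximized only up to ln 2, the value at which the
    frozen discriminator is at chance: once a step's mixed-batch BCE reaches
    ln 2 the round stops, since pushing further swaps the domains in feature
    space instead of aligning them.
    """
    if len(target_features) == 0:
        raise ValueError("adversarial fine-tuning needs unlabeled target data")
    steps = config.finetune_steps if steps is None else steps
    rng = rng or np.random.default_rng(config.seed + 3)
    Y = one_hot(np.asarray(source_labels, dtype=int), net.config.n_classes)
    opt = Adam([net.g2, net.f2], lr=config.finetune_lr or config.learning_rate,
               weight_decay=config.weight_decay)
    half = max(1, config.batch_size // 2)
    rows = []
    for step in range(steps):
        si = rng.choice(len(source_features), size=min(half, len(source_features)),
                        replace=False)
        ti = rng.choice(len(target_features), size=min(half, len(target_features)),
                        replace=False)
        opt.zero_grad()
        # classification term on labeled source
        hs, cg2s = net.g2.forward(source_features[si])
        logits, cf2 = net.f2.forward(hs)
        p = softmax(logits)
        class_loss = cross_entropy(Y[si], p)
        dlogits = (p - Y[si]) / len(si)
        dh = net.f2.backward(dlogits, cf2)
        net.g2.backward(dh, cg2s)
        # adversarial term on a mixed batch, gradient sign reversed into g2
        xb = np.concatenate([source_features[si], target_features[ti]])
        d = np.concatenate([np.zeros(len(si)), np.ones(len(ti))])
        hm, cg2m = net.g2.forward(xb)
        dlogit_fd, cfd = net.fd.forward(hm)
        pd_hat = sigmoid(dlogit_fd)[:, 0]
        adv_loss = domain_bce(d, pd_hat)
        if adv_loss >= np.log(2.0):
            rows.append({"step": step, "class_loss": class_loss,
                         "adv_loss": adv_loss, "stopped": True})
            break
        ddisc = ((pd_hat - d) / len(d))[:, None]
        net.fd.zero_grad()           # fd is frozen; discard its gradients
        dhm = net.fd.backward(ddisc, cfd)
        net.fd.zero_grad()
        net.g2.backward(-dhm, cg2m)  # sign reversal: maximize the BCE
        opt.step()
        rows.append({"step": step, "class_loss": class_loss, "adv_loss": adv_loss})
    return pd.DataFrame(rows)


def run_adaptation(net: HDNetwork, source_sequences: np.ndarray,
                   source_labels: np.ndarray, target_sequences: np.ndarray,
                   config: TrainConfig,
                   eval_source: tuple[np.ndarray, np.ndarray] | None = None,
                   eval_target: tuple[np.ndarray, np.ndarray] | None = None,
                   ) -> AdaptationReport:
    """Alternate discriminator training and adversarial fine-tuning.

    ``eval_source``/``eval_target`` are optional held-out labeled sets
    (sequences, labels) used only for reporting accuracies; target labels
    never drive a gradient.  The held-out features also provide the
    discriminator's held-out domain accuracy.
    """
    if len(target_sequences) == 0:
        raise ValueError("adaptation needs unlabeled target data")
    before = net.partition_hashes()
    feats_s = net.sequence_features(source_sequences)
    feats_t = net.sequence_features(target_sequences)
    feats_s_eval = net.sequence_features(eval_source[0]) if eval_source else None
    feats_t_eval = net.sequence_features(eval_target[0]) if eval_target else None
    rng = np.random.default_rng(config.seed + 4)
    report = AdaptationReport()

    def domain_accuracy() -> float | None:
        fs = feats_s_eval if feats_s_eval is not None else feats_s
        ft = feats_t_eval if feats_t_eval is not None else feats_t
        ps = net.discriminate_features(fs)
        pt = net.discriminate_features(ft)
        return float(((ps < 0.5).sum() + (pt >= 0.5).sum()) / (len(ps) + len(pt)))

    def accuracies() -> tuple[float | None, float | None]:
        src = tgt = None
        if eval_source is not None:
            src = accuracy_from_features(net, feats_s_eval, eval_source[1])
        if eval_target is not None:
            tgt = accuracy_from_features(net, feats_t_eval, eval_target[1])
        return src, tgt

    src0, tgt0 = accuracies()
    report.add(round=0, disc_loss=np.nan, disc_accuracy=domain_accuracy(),
               disc_accuracy_post=np.nan, source_accuracy=src0, target_accuracy=tgt0)
    for rnd in range(1, config.adversarial_rounds + 1):
        disc_history = train_discriminator(net, feats_s, feats_t, config, rng=rng)
        disc_acc = domain_accuracy()
        adversarial_finetune(net, feats_s, source_labels, feats_t, config, rng=rng)
        src, tgt = accuracies()
        report.add(round=rnd,
                   disc_loss=disc_history[-1] if disc_history else np.nan,
                   disc_accuracy=disc_acc, disc_accuracy_post=domain_accuracy(),
                   source_accuracy=src, target_accuracy=tgt)
    after = net.partition_hashes()
    report.changed = {k: before[k] != after[k] for k in before}
    return report


# ---------------------------------------------------------------------------
# evaluation and cross-validation
# ---------------------------------------------------------------------------

def accuracy_from_features(net: HDNetwork, features: np.ndarray,
                           labels: np.ndarray) -> float:
    h = net.deep_features(features)
    logits, _ = net.f2.forward(h)
    return float((logits.argmax(1) == np.asarray(labels)).mean())


def confusion_table(y_true: np.ndarray, y_pred: np.ndarray,
                    label_names: list[str] | None = None) -> pd.DataFrame:
    labels = list(range(len(label_names))) if label_names else None
    cm = _sk_confusion(y_true, y_pred, labels=labels)
    names = label_names or [str(i) for i in np.unique(np.r_[y_true, y_pred])]
    return pd.DataFrame(cm, index=pd.Index(names, name="true"),
                        columns=pd.Index(names, name="predicted"))


def evaluate(net: HDNetwork, sequences: np.ndarray, labels: np.ndarray,
             label_names: list[str] | None = None,
             features: np.ndarray | None = None) -> tuple[float, pd.DataFrame]:
    """Accuracy + per-class confusion table of the sequence classifier."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) == 0:
        raise ValueError("cannot evaluate on an empty set")
    if features is None:
        features = net.sequence_features(sequences)
    h = net.deep_features(features)
    logits, _ = net.f2.forward(h)
    y_pred = logits.argmax(1)
    cm = confusion_table(labels, y_pred,
                         label_names or [str(i) for i in range(net.config.n_classes)])
    accuracy = float(np.trace(cm.values) / len(labels))
    return accuracy, cm


def kfold_split(labels: np.ndarray, k: int = 6,
                seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Label-stratified k-fold partition; folds are disjoint, exhaustive and
    differ in size by at most one."""
    labels = np.asarray(labels)
    if k > len(labels):
        raise ValueError(f"k={k} exceeds dataset size {len(labels)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(labels)), labels)]
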