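"""Model/Results front door for the seizure classifier.

``SeizureHDN`` is built from data (a source corpus, optionally a target
corpus); ``fit()`` runs the two supervised phases and returns an
``HDNResults`` carrying the fitted network, loss histories, accuracies and a
``summary()`` table; ``HDNResults.adapt()`` runs the adversarial domain
adaptation and returns an ``AdaptationResults``.  Simulation helpers and
learning-curve plots hang off these two objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import WindowSequence, stack_sequences
from .network import HDNConfig, HDNetwork
from .training import (
    AdaptationReport,
    TrainConfig,
    evaluate,
    kfold_split,
    run_adaptation,
    train_phase1,
    train_phase2,
)


def tail_windows(X: np.ndarray, y: np.ndarray,
                 per_sequence: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Labeled single windows for phase 1: the last ``per_sequence`` windows
    of each sequence.

    Sequences are referenced at the event midpoint, so the tail windows lie
    inside the ictal interval and carry the sequence's class honestly; early
    windows are pre-ictal background and would dilute the window-level labels.
    """
    N, T = X.shape[:2]
    k = min(per_sequence, T)
    W = X[:, T - k:].reshape(N * k, *X.shape[2:])
    return W, np.repeat(y, k)


class SeizureHDN:
    """Hybrid deep network seizure classifier, statsmodels-style.

    Parameters
    ----------
    source_X, source_y : labeled source-domain sequences ``[N, 8, C, S]``
        and integer class labels.
    target_X : optional unlabeled target-domain sequences for adaptation.
    label_names : class-index -> name mapping (index order of ``source_y``).
    config, train_config : network and optimization settings.
    """

    def __init__(self, source_X: np.ndarray, source_y: np.ndarray,
                 target_X: np.ndarray | None = None,
                 label_names: list[str] | None = None,
                 config: HDNConfig | None = None,
                 train_config: TrainConfig | None = None) -> None:
        self.source_X = np.asarray(source_X, dtype=float)
        self.source_y = np.asarray(source_y, dtype=int)
        if self.source_X.ndim != 4:
            raise ValueError("source_X must be [N, n_windows, n_leads, samples]")
        if len(self.source_X) != len(self.source_y):
            raise ValueError("source_X and source_y lengths differ")
        self.target_X = None if target_X is None else np.asarray(target_X, dtype=float)
        n_classes = int(self.source_y.max()) + 1
        self.label_names = label_names or [str(i) for i in range(n_classes)]
        n_leads = self.source_X.shape[2]
        self.config = config or HDNConfig(n_leads=n_leads, n_classes=n_classes)
        if self.config.n_leads != n_leads:
            raise ValueError(f"config expects {self.config.n_leads} leads, "
                             f"data has {n_leads}")
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_sequences(cls, source: list[WindowSequence],
                       target: list[WindowSequence] | None = None,
                       **kwargs) -> "SeizureHDN":
        """Build the model from lists of labeled :class:`WindowSequence`."""
        X, y, names = stack_sequences(source)
        tX = None
        if target:
            tX = np.stack([s.windows for s in target])
        return cls(X, y, target_X=tX, label_names=names, **kwargs)

    def fit(self, seed: int | None = None) -> "HDNResults":
        """Run supervised phases 1 and 2 and evaluate on the training set."""
        tc = self.train_config
        if seed is not None:
            tc = TrainConfig(**{**tc.to_dict(), "seed": seed})
        net = HDNetwork(self.config, seed=tc.seed)
        W, wy = tail_windows(self.source_X, self.source_y)
        phase1_history = train_phase1(net, W, wy, tc)
        net.fit_feature_norm(self.source_X)
        features = net.sequence_features(self.source_X)
        phase2_history = train_phase2(net, self.source_X, self.source_y, tc,
                                      features=features)
        accuracy, cm = evaluate(net, self.source_X, self.source_y,
                                self.label_names, features=features)
        return HDNResults(model=self, network=net, train_config=tc,
                          phase1_loss=phase1_history, phase2_history=phase2_history,
                          train_accuracy=accuracy, train_confusion=cm)

    def cross_validate(self, k: int = 6, seed: int | None = None) -> pd.DataFrame:
        """Label-stratified k-fold: fit on k-1 folds, score on the held-out
        fold; returns one row per fold."""
        tc_seed = self.train_config.seed if seed is None else seed
        rows = []
        for fold, (tr, va) in enumerate(kfold_split(self.source_y, k=k, seed=tc_seed)):
            sub = SeizureHDN(self.source_X[tr], self.source_y[tr],
                             label_names=self.label_names, config=self.config,
                             train_config=self.train_config)
            res = sub.fit(seed=tc_seed + fold)
            acc, _ = evaluate(res.network, self.source_X[va], self.source_y[va],
                              self.label_names)
            rows.append({"fold": fold, "n_train": len(tr), "n_val": len(va),
                         "train_accuracy": res.train_accuracy, "val_accuracy": acc})
        return pd.DataFrame(rows)


@dataclass
class HDNResults:
    """Result of the two supervised training phases."""

    model: SeizureHDN
    network: HDNetwork
    train_config: TrainConfig
    phase1_loss: list[float]
    phase2_history: dict[str, list[float]]
    train_accuracy: float
    train_confusion: pd.DataFrame

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class-index predictions for sequences ``[N, 8, C, S]``."""
        return self.network.classify_sequences(np.asarray(X, dtype=float)).argmax(1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.network.classify_sequences(np.asarray(X, dtype=float))

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        acc, _ = evaluate(self.network, np.asarray(X, dtype=float),
                          np.asarray(y, dtype=int), self.model.label_names)
        return acc

    def adapt(self, target_X: np.ndarray | None = None,
              eval_source: tuple[np.ndarray, np.ndarray] | None = None,
              eval_target: tuple[np.ndarray, np.ndarray] | None = None,
              ) -> "AdaptationResults":
        """Adversarial domain adaptation toward (unlabeled) target sequences."""
        tX = target_X if target_X is not None else self.model.target_X
        if tX is None:
            raise ValueError("no target data: pass target_X or build the model "
                             "with a target corpus")
        report = run_adaptation(self.network, self.model.source_X,
                                self.model.source_y, np.asarray(tX, dtype=float),
                                self.train_config, eval_source=eval_source,
                                eval_target=eval_target)
        return AdaptationResults(results=self, report=report)

    def save(self, path: str | Path) -> None:
        self.network.save_checkpoint(path)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Hybrid deep network — supervised fit",
            "=" * 44,
            f"classes:            {', '.join(self.model.label_names)}",
            f"sequences (source): {len(self.model.source_X)}",
            f"leads / window:     {cfg.n_leads} x {self.model.source_X.shape[3]} samples",
            f"feature dim / hidden: {cfg.feature_dim} / {cfg.hidden_dim}",
            f"phase 1 epochs:     {len(self.phase1_loss)}"
            + (f"  (final loss {self.phase1_loss[-1]:.4f})" if self.phase1_loss else ""),
            f"phase 2 epochs:     {len(self.phase2_history['loss'])}"
            + (f"  (final loss {self.phase2_history['loss'][-1]:.4f})"
               if self.phase2_history["loss"] else ""),
            f"training accuracy:  {self.train_accuracy:.3f}",
            "",
            "confusion (training set):",
            self.train_confusion.to_string(),
        ]
        return "\n".join(lines)

    def plot_learning_curves(self, path: str | Path | None = None):
        """Loss (phases 1-2) and phase-2 accuracy curves."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2))
        ax1.plot(self.phase1_loss, label="phase 1 (g1+f1)")
        ax1.plot(self.phase2_history["loss"], label="phase 2 (g2+f2)")
        ax1.set_xlabel("epoch"); ax1.set_ylabel("cross-entropy"); ax1.legend()
        ax2.plot(self.phase2_history["accuracy"])
        ax2.set_xlabel("epoch"); ax2.set_ylabel("phase-2 training accuracy")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
        return fig


@dataclass
class AdaptationResults:
    """Result of the adversarial adaptation phase."""

    results: HDNResults
    report: AdaptationReport

    @property
    def table(self) -> pd.DataFrame:
        return self.report.to_dataframe()

    def _metric(self, column: str, row: int) -> float | None:
        val = self.table[column].iloc[row]
        return None if pd.isna(val) else float(val)

    def summary(self) -> str:
        t = self.table
        lines = ["Adversarial domain adaptation", "=" * 44,
                 t.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
                 "",
                 "partitions changed: "
                 + ", ".join(f"{k}={v}" for k, v in self.report.changed.items())]
        for col, row0, name in (("source_accuracy", 0, "source accuracy"),
                                ("target_accuracy", 0, "target accuracy"),
                                ("disc_accuracy", min(1, len(t) - 1),
                                 "discriminator accuracy (trained -> after fine-tune)")):
            pre, post = self._metric(col, row0), self._metric(
                "disc_accuracy_post" if col == "disc_accuracy" else col, -1)
            if pre is not None and post is not None:
                lines.append(f"{name}: {pre:.3f} -> {post:.3f}")
        return "\n".join(lines)
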