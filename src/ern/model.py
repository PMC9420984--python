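"""Model / Results surface for fitting the network to a topographic dataset.

``EmotionRecognizer`` wraps a :class:`~ern.topology.TopoDataset` plus an
architecture config; ``fit`` runs mini-batch gradient training (Adam by
default, learning rate 0.001, dropout 0.6) and returns an
``EmotionRecognizerResults`` carrying the trained network, the loss trace
and evaluation helpers, statsmodels-style::

    model = EmotionRecognizer(dataset, ERNConfig())
    res = model.fit(TrainConfig(max_epochs=10, seed=0), train_idx, val_idx)
    print(res.summary())

Training is deterministic in (seed, thread count): weight initialisation,
batch shuffling and dropout masks all derive from the TrainConfig seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .metrics import MetricsReport, compute_metrics
from .network import ERN, ERNConfig
from .topology import TopoDataset

__all__ = ["TrainConfig", "EmotionRecognizer", "EmotionRecognizerResults"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.  Defaults follow the published protocol:
    Adam at learning rate 0.001; dropout probability is part of the
    architecture config (0.6) unless overridden here."""

    learning_rate: float = 0.001
    optimizer: str = "adam"
    max_epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    dropout_p: float | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer not in ("adam", "adadelta"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if not 0 <= self.max_epochs <= 500:
            raise ValueError("max_epochs must lie in [0, 500]")


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class _AdaDelta:
    def __init__(self, params, lr=1.0, rho=0.95, eps=1e-6):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.eg = [np.zeros_like(p) for p in params]
        self.ex = [np.zeros_like(p) for p in params]

    def step(self, params, grads):
        for p, g, eg, ex in zip(params, grads, self.eg, self.ex):
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            dx = -np.sqrt((ex + self.eps) / (eg + self.eps)) * g
            ex *= self.rho
            ex += (1 - self.rho) * dx * dx
            p += self.lr * dx


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int, loss: float):
        super().__init__(f"non-finite loss {loss} at epoch {epoch}")
        self.epoch = epoch


class EmotionRecognizer:
    """Four-class emotion classifier over 9x9xT topographic segments."""

    def __init__(self, dataset: TopoDataset, config: ERNConfig | None = None):
        if len(dataset) == 0:
            raise ValueError("dataset is empty")
        self.dataset = dataset
        self.config = config or ERNConfig()
        labels = dataset.labels
        if labels.size and (labels.min() < 0 or labels.max() >= self.config.n_classes):
            raise ValueError("labels outside the configured class range")

    @classmethod
    def from_trialset(cls, trialset, config: ERNConfig | None = None,
                      **assemble_kwargs) -> "EmotionRecognizer":
        """Convenience constructor running topographic assembly first."""
        from .topology import assemble_dataset

        return cls(assemble_dataset(trialset, **assemble_kwargs), config)

    def fit(self, train_cfg: TrainConfig | None = None,
            train_idx: Sequence[int] | None = None,
            eval_idx: Sequence[int] | None = None) -> "EmotionRecognizerResults":
        """Train the network on ``train_idx`` (default: all segments).

        ``eval_idx`` only selects the default evaluation split of the
        returned results; it is never touched during training.
        """
        cfg = train_cfg or TrainConfig()
        arch = self.config
        if cfg.dropout_p is not None:
            from dataclasses import replace

            arch = replace(arch, dropout_p=cfg.dropout_p)
        ds = self.dataset
        idx = np.arange(len(ds)) if train_idx is None else np.asarray(train_idx)
        X = ds.grids[idx]
        y = ds.labels[idx]
        rng = np.random.default_rng(cfg.seed)
        net = ERN(arch, input_shape=ds.grids.shape[1:],
                  seed=int(rng.integers(2**31)))
        optim = (_Adam(net.params, cfg.learning_rate) if cfg.optimizer == "adam"
                 else _AdaDelta(net.params))
        loss_trace: list[float] = []
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(X))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(X), cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                loss, grads = net.loss_and_grads(X[batch], y[batch], rng=rng)
                if not np.isfinite(loss):
                    raise DivergenceError(epoch, loss)
                optim.step(net.params, grads)
                epoch_loss += loss
                n_batches += 1
            loss_trace.append(epoch_loss / max(n_batches, 1))
        return EmotionRecognizerResults(self, net, cfg, np.asarray(loss_trace),
                                        train_idx=np.asarray(idx),
                                        eval_idx=None if eval_idx is None
                                        else np.asarray(eval_idx))


@dataclass
class EmotionRecognizerResults:
    """Trained-model results: the fitted network, the per-epoch mean loss
    trace, and evaluation over any index subset of the parent dataset."""

    model: EmotionRecognizer
    network: ERN
    train_cfg: TrainConfig
    loss_trace: np.ndarray
    train_idx: np.ndarray
    eval_idx: np.ndarray | None = None
    _metrics_cache: dict = field(default_factory=dict, repr=False)

    def predict_proba(self, grids: np.ndarray, batch_size: int = 32) -> np.ndarray:
        grids = np.asarray(grids)
        out = [self.network.predict_proba(grids[s:s + batch_size])
               for s in range(0, len(grids), batch_size)]
        return np.concatenate(out) if out else np.zeros((0, self.model.config.n_classes))

    def predict(self, grids: np.ndarray) -> np.ndarray:
        return self.predict_proba(grids).argmax(axis=1)

    def evaluate(self, idx: Sequence[int] | None = None) -> MetricsReport:
        """Metrics over the given segment indices (default: eval_idx, else
        the training split)."""
        if idx is None:
            idx = self.eval_idx if self.eval_idx is not None else self.train_idx
        idx = np.asarray(idx)
        key = idx.tobytes()
        if key not in self._metrics_cache:
            ds = self.model.dataset
            scores = self.predict_proba(ds.grids[idx])
            self._metrics_cache[key] = compute_metrics(
                ds.labels[idx], scores.argmax(axis=1), scores,
                self.model.config.n_classes,
            )
        return self._metrics_cache[key]

    def summary(self) -> str:
        """Plain-text summary table of the fit and its evaluation."""
        rep = self.evaluate()
        cfg, arch = self.train_cfg, self.model.config
        lines = [
            "Emotion Recognition Network Results",
            "=" * 55,
            f"variant:            {arch.variant}",
            f"branch kernels:     {arch.branch_a_kernel} / {arch.effective_branch_b_kernel}",
            f"feature maps:       {arch.branch_maps} per branch, {arch.head_maps} head",
            f"dropout:            {arch.dropout_p}",
            f"parameters:         {self.network.parameter_count():,}",
            f"optimizer:          {cfg.optimizer} (lr={cfg.learning_rate})",
            f"epochs:             {len(self.loss_trace)}"
            + (f", final loss {self.loss_trace[-1]:.4f}" if len(self.loss_trace) else ""),
            f"train segments:     {len(self.train_idx)}",
            "-" * 55,
            f"accuracy:           {rep.accuracy:.4f}",
            f"macro F1:           {rep.macro_f1:.4f}",
            f"macro AUC:          {rep.macro_auc:.4f}",
            "class   precision   recall       F1      AUC",
        ]
        for m in range(arch.n_classes):
            lines.append(
                f"  {m}      {rep.precision[m]:7.4f}  {rep.recall[m]:7.4f}"
                f"  {rep.f1[m]:7.4f}  {rep.auc[m]:7.4f}"
            )
        return "\n".join(lines)
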