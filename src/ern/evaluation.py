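"""Cross-validation, lockbox protocol, Fisher channel ranking and the
experiment drivers (electrode subsets, scaled-down recovery / ablation runs).

The Fisher score of electrode v over classes m = 0..M is

    F(v) = sum_m n_m (mu_{m,v} - mu_v)^2  /  sum_m n_m sigma^2_{m,v}

with n_m the class sample count, mu_{m,v} / sigma^2_{m,v} the class mean and
(population) variance of the electrode's feature, and mu_v the grand mean.
The per-electrode feature defaults to the segment's mean power at that
electrode's grid cell; raw-sample pooling is available via ``feature=``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import sklearn.model_selection

from .metrics import MetricsReport, compute_metrics
from .model import EmotionRecognizer, EmotionRecognizerResults, TrainConfig
from .network import ERNConfig
from .topology import ElectrodeLayout, TopoDataset, default_layout

__all__ = [
    "kfold_split",
    "cv_mean",
    "cross_validate",
    "CrossValidationResults",
    "FisherRanking",
    "fisher_scores",
    "mask_to_top_k",
    "subset_run",
    "LockboxSplit",
    "LockboxProtocol",
    "lockbox_protocol",
]


def kfold_split(n: int, k: int = 10, seed: int = 0):
    """Shuffled k-fold index splits: test sets partition 0..n-1, sizes differ
    by at most one; deterministic in the seed."""
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    kf = sklearn.model_selection.KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in kf.split(np.arange(n))]


def cv_mean(fold_accuracies: Sequence[float]) -> float:
    """Mean of per-fold accuracies — the headline cross-validation figure."""
    accs = np.asarray(fold_accuracies, dtype=float)
    if accs.size == 0:
        raise ValueError("no folds")
    return float(accs.mean())


@dataclass
class CrossValidationResults:
    """Per-fold accuracies and metric reports from k-fold cross-validation."""

    fold_accuracies: list[float]
    fold_metrics: list[MetricsReport]

    @property
    def mean_accuracy(self) -> float:
        return cv_mean(self.fold_accuracies)

    def summary(self) -> str:
        lines = [f"{k}-fold cross-validation".format(k=len(self.fold_accuracies))]
        for i, a in enumerate(self.fold_accuracies, start=1):
            lines.append(f"  fold {i:2d}: {100 * a:6.2f}%")
        lines.append(f"  mean:    {100 * self.mean_accuracy:6.2f}%")
        return "\n".join(lines)


def cross_validate(
    dataset: TopoDataset,
    config: ERNConfig | None = None,
    train_cfg: TrainConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> CrossValidationResults:
    """Train and evaluate on each of ``n_folds`` shuffled folds; the mean of
    the fold accuracies is the reported figure."""
    train_cfg = train_cfg or TrainConfig()
    accs, reports = [], []
    for fold, (tr, te) in enumerate(kfold_split(len(dataset), n_folds, seed)):
        res = EmotionRecognizer(dataset, config).fit(
            replace(train_cfg, seed=train_cfg.seed + fold), tr, te
        )
        rep = res.evaluate(te)
        accs.append(rep.accuracy)
        reports.append(rep)
    return CrossValidationResults(accs, reports)


# ---------------------------------------------------------------------------
# Fisher channel ranking

@dataclass
class FisherRanking:
    """Per-electrode Fisher scores and the induced descending ordering."""

    scores: dict[str, float]
    order: list[str] = field(init=False)

    def __post_init__(self) -> None:
        # NaN scores (degenerate electrodes) sort after every real score
        self.order = sorted(
            self.scores,
            key=lambda n: (np.isnan(self.scores[n]), -self.scores[n]),
        )

    def top(self, k: int) -> list[str]:
        if not 1 <= k <= len(self.order):
            raise ValueError(f"top_k must lie in 1..{len(self.order)}")
        return self.order[:k]


def _electrode_features(
    dataset: TopoDataset, layout: ElectrodeLayout, names: Sequence[str],
    feature: str, fs: float,
) -> np.ndarray:
    """Per-segment electrode features, shape (n_obs, n_electrodes, n_feats)."""
    cells = np.array([layout[n] for n in names])
    series = dataset.grids[:, cells[:, 0], cells[:, 1], :]  # (n, C, L)
    if feature == "band_power":
        from .preprocess import BANDS

        L = series.shape[-1]
        freqs = np.fft.rfftfreq(L, d=1.0 / fs)
        spec = np.abs(np.fft.rfft(series, axis=-1)) ** 2
        feats = [
            spec[..., (freqs >= b.low_hz) & (freqs < b.high_hz)].sum(axis=-1)
            for b in (BANDS["theta"], BANDS["alpha"], BANDS["beta"],
                      BANDS["gamma"])
        ]
        return np.stack(feats, axis=-1)
    if feature == "mean_power":
        return np.mean(np.square(series, dtype=float), axis=-1)[..., None]
    if feature == "raw":
        # pool every sample as one observation of the electrode
        n, C, L = series.shape
        return series.transpose(0, 2, 1).reshape(n * L, C)[..., None]
    raise ValueError(f"unknown feature {feature!r}")


def fisher_scores(
    dataset: TopoDataset,
    layout: ElectrodeLayout | None = None,
    names: Sequence[str] | None = None,
    feature: str = "band_power",
    fs: float = 128.0,
    ddof: int = 0,
) -> FisherRanking:
    """Fisher score of every electrode: between-class over within-class
    scatter of the electrode's per-segment feature.

    The default feature is the segment's power in each rhythm band
    (theta/alpha/beta/gamma); the electrode's score is the best band's, so a
    channel discriminating in any band ranks high even when broadband power
    is uninformative.  ``mean_power`` (broadband) and ``raw`` (sample
    pooling) are available alternatives.  Population (1/n) class variances
    by default; ``ddof=1`` switches to sample variances.  Electrodes whose
    within-class scatter is zero in every class get score NaN (reported,
    ranked after every finite score).
    """
    layout = layout or default_layout()
    if names is None:
        names = sorted(layout.positions, key=lambda n: layout[n])
    labels = dataset.labels
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes for a Fisher score")
    feats = _electrode_features(dataset, layout, names, feature, fs)
    if feature == "raw":
        labels = np.repeat(labels, dataset.segment_length)
    grand = feats.mean(axis=0)
    num = np.zeros(feats.shape[1:])
    den = np.zeros(feats.shape[1:])
    for m in classes:
        fm = feats[labels == m]
        n_m = len(fm)
        num += n_m * (fm.mean(axis=0) - grand) ** 2
        den += n_m * fm.var(axis=0, ddof=ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_feat = np.where(den > 0, num / den, np.nan)
    best = np.full(len(names), np.nan)
    finite = ~np.all(np.isnan(per_feat), axis=-1)
    best[finite] = np.nanmax(per_feat[finite], axis=-1)
    return FisherRanking({n: float(best[i]) for i, n in enumerate(names)})


def mask_to_top_k(
    dataset: TopoDataset, ranking: FisherRanking, top_k: int,
    layout: ElectrodeLayout | None = None,
) -> TopoDataset:
    """Copy of the dataset with every electrode outside the top_k zeroed."""
    layout = layout or default_layout()
    keep = set(ranking.top(top_k))
    grids = np.zeros_like(dataset.grids)
    for name in keep:
        r, c = layout[name]
        grids[:, r, c, :] = dataset.grids[:, r, c, :]
    return TopoDataset(grids, dataset.labels.copy(), list(dataset.provenance))


def subset_run(
    dataset: TopoDataset,
    ranking: FisherRanking,
    top_k: int,
    config: ERNConfig | None = None,
    train_cfg: TrainConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> float:
    """Mean CV accuracy using only the top_k Fisher-ranked electrodes
    (all other grid cells zeroed)."""
    masked = mask_to_top_k(dataset, ranking, top_k)
    return cross_validate(masked, config, train_cfg, n_folds, seed).mean_accuracy


# ---------------------------------------------------------------------------
# lockbox protocol

@dataclass(frozen=True)
class LockboxSplit:
    """Held-out fraction evaluated exactly once after all tuning."""

    optimization_fraction: float = 0.9
    lockbox_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.optimization_fraction + self.lockbox_fraction - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if not 0 < self.lockbox_fraction < 1:
            raise ValueError("lockbox fraction must lie in (0, 1)")

    def indices(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(n)
        n_lock = int(round(n * self.lockbox_fraction))
        return np.sort(perm[n_lock:]), np.sort(perm[:n_lock])


class LockboxProtocol:
    """Guards the lockbox: tuning sees only the optimization set, and the
    lockbox may be evaluated exactly once (the result is cached immutably)."""

    def __init__(self, dataset: TopoDataset, split: LockboxSplit | None = None):
        self.dataset = dataset
        self.split = split or LockboxSplit()
        self.opt_idx, self.lock_idx = self.split.indices(len(dataset))
        self._lockbox_report: MetricsReport | None = None

    @property
    def optimization_set(self) -> TopoDataset:
        return TopoDataset(
            self.dataset.grids[self.opt_idx], self.dataset.labels[self.opt_idx]
        )

    def evaluate_lockbox(self, results: EmotionRecognizerResults) -> MetricsReport:
        """One-shot evaluation on the lockbox; a second call is refused."""
        if self._lockbox_report is not None:
            raise RuntimeError(
                "lockbox already evaluated; the one-time estimate is immutable"
            )
        scores = results.predict_proba(self.dataset.grids[self.lock_idx])
        self._lockbox_report = compute_metrics(
            self.dataset.labels[self.lock_idx], scores.argmax(axis=1), scores,
            results.model.config.n_classes,
        )
        return self._lockbox_report


def lockbox_protocol(
    dataset: TopoDataset,
    split: LockboxSplit | None = None,
    config: ERNConfig | None = None,
    train_cfg: TrainConfig | None = None,
    n_folds: int = 10,
) -> tuple[float, float]:
    """Run the full protocol: k-fold CV on the optimization set, then a final
    model trained on all optimization data evaluated once on the lockbox.

    Returns (optimization accuracy, lockbox accuracy).
    """
    proto = LockboxProtocol(dataset, split)
    opt_ds = proto.optimization_set
    cv = cross_validate(opt_ds, config, train_cfg, n_folds,
                        seed=proto.split.seed)
    final = EmotionRecognizer(dataset, config).fit(
        train_cfg or TrainConfig(), train_idx=proto.opt_idx
    )
    lock = proto.evaluate_lockbox(final)
    return cv.mean_accuracy, lock.accuracy
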