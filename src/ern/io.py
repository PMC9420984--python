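"""Trial-structured EEG containers and four-class label handling.

A recording is a stack of trials, each ``n_channels x n_samples`` at a fixed
sampling rate, with one label per trial.  Labels come in two flavours:
continuous valence/arousal self-ratings on the 1-9 scale (DEAP-style), which
are discretised into the four quadrant classes LVLA/LVHA/HVLA/HVHA, and
categorical four-class labels (SEED-IV-style: happy/sad/neutral/fear), which
pass through unchanged.

Two on-disk dialects are supported: a native HDF5 layout (one group per
subject with ``data``/``labels`` datasets and ``fs``/``channel_names``
attributes) and MAT containers, both legacy (v5) and v7.3/HDF5-backed, which
mirrors how the public affective-EEG benchmarks are distributed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import scipy.io

__all__ = [
    "DEAP_32_CHANNELS",
    "LabelRecord",
    "RawTrialSet",
    "discretize_labels",
    "passthrough_labels",
    "read_trialset",
    "write_trialset",
]

#: Canonical 32-channel montage (10-20 names) in the order the DEAP
#: distribution stores them.  Readers reorder by name to match.
DEAP_32_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: Class indices for the valence/arousal quadrants.
CLASS_NAMES: tuple[str, ...] = ("LVLA", "LVHA", "HVLA", "HVHA")


@dataclass(frozen=True)
class LabelRecord:
    """One trial's label: either a (valence, arousal) pair or a categorical class.

    Exactly one of the two forms must be present.  Continuous ratings live on
    the 1-9 scale (1 negative, 5 neutral, 9 positive).
    """

    valence: float | None = None
    arousal: float | None = None
    categorical: int | None = None

    def __post_init__(self) -> None:
        has_va = self.valence is not None or self.arousal is not None
        has_cat = self.categorical is not None
        if has_va and (self.valence is None or self.arousal is None):
            raise ValueError("valence and arousal must be given together")
        if has_va == has_cat:
            raise ValueError(
                "exactly one of (valence, arousal) or categorical must be present"
            )
        if has_va:
            for name, v in (("valence", self.valence), ("arousal", self.arousal)):
                if not 1.0 <= float(v) <= 9.0:
                    raise ValueError(f"{name}={v} outside the 1-9 rating scale")
        else:
            if self.categorical not in (0, 1, 2, 3):
                raise ValueError(
                    f"categorical label {self.categorical} not in {{0,1,2,3}}"
                )

    @property
    def is_continuous(self) -> bool:
        return self.valence is not None


@dataclass
class RawTrialSet:
    """A subject's recording: ``data[trial, channel, sample]`` plus metadata."""

    subject_id: str
    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    labels: list[LabelRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be trials x channels x samples, got shape {self.data.shape}"
            )
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[1]} channel rows but "
                f"{len(self.channel_names)} channel_names were declared"
            )
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.labels and len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} trials"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def reorder_channels(self, names: Sequence[str]) -> "RawTrialSet":
        """Return a copy with channels rearranged to the given name order."""
        idx = [list(self.channel_names).index(n) for n in names]
        return RawTrialSet(
            subject_id=self.subject_id,
            data=self.data[:, idx, :].copy(),
            fs=self.fs,
            channel_names=list(names),
            labels=list(self.labels),
        )


def discretize_labels(record: LabelRecord, threshold: float = 5.0) -> int:
    """Map a (valence, arousal) rating pair to one of the four quadrant classes.

    Ratings at or below the threshold count as "low", strictly above as
    "high": LVLA -> 0, LVHA -> 1, HVLA -> 2, HVHA -> 3.  The default
    threshold 5 is the scale's neutral midpoint.
    """
    if not record.is_continuous:
        raise ValueError(
            "record carries a categorical label; use passthrough_labels instead"
        )
    high_v = record.valence > threshold
    high_a = record.arousal > threshold
    return (2 if high_v else 0) + (1 if high_a else 0)


def passthrough_labels(record: LabelRecord) -> int:
    """Return a categorical four-class label unchanged."""
    if record.is_continuous:
        raise ValueError(
            "record carries continuous ratings; use discretize_labels instead"
        )
    return int(record.categorical)


def class_of(record: LabelRecord, threshold: float = 5.0) -> int:
    """Class index of a label record of either flavour."""
    if record.is_continuous:
        return discretize_labels(record, threshold)
    return passthrough_labels(record)


# ---------------------------------------------------------------------------
# serialisation
#
# Labels are packed as an (n_trials, 3) float matrix [valence, arousal,
# categorical] with NaN marking the absent form, so one numeric dataset
# covers both label flavours in every dialect.

def _labels_to_matrix(labels: Sequence[LabelRecord]) -> np.ndarray:
    out = np.full((len(labels), 3), np.nan)
    for i, rec in enumerate(labels):
        if rec.is_continuous:
            out[i, 0] = rec.valence
            out[i, 1] = rec.arousal
        else:
            out[i, 2] = rec.categorical
    return out


def _labels_from_matrix(mat: np.ndarray) -> list[LabelRecord]:
    recs = []
    for row in np.atleast_2d(mat):
        if math.isnan(row[2]):
            recs.append(LabelRecord(valence=float(row[0]), arousal=float(row[1])))
        else:
            recs.append(LabelRecord(categorical=int(row[2])))
    return recs


def write_trialset(trialset: RawTrialSet, path: str | Path, dialect: str = "hdf5") -> Path:
    """Write a trial set losslessly; the result round-trips through read_trialset."""
    path = Path(path)
    if trialset.n_trials == 0:
        raise ValueError("refusing to write an empty trial set")
    if dialect == "hdf5":
        with h5py.File(path, "w", track_order=False) as f:
            g = f.create_group(trialset.subject_id)
            # track_times off so identical content gives identical bytes
            g.create_dataset("data", data=trialset.data, track_times=False)
            g.create_dataset("labels", data=_labels_to_matrix(trialset.labels),
                             track_times=False)
            g.attrs["fs"] = float(trialset.fs)
            g.attrs["channel_names"] = [str(n) for n in trialset.channel_names]
    elif dialect == "mat":
        scipy.io.savemat(
            str(path),
            {
                "subject_id": trialset.subject_id,
                "data": trialset.data,
                "labels": _labels_to_matrix(trialset.labels),
                "fs": float(trialset.fs),
                "channel_names": np.array(list(trialset.channel_names), dtype=object),
            },
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_trialset(path: str | Path, dialect: str = "hdf5") -> RawTrialSet:
    """Read a trial set written by :func:`write_trialset`.

    The MAT reader handles both legacy (v5) files via scipy and v7.3
    (HDF5-backed) files via h5py.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "hdf5":
        with h5py.File(path, "r") as f:
            if len(f.keys()) != 1:
                raise ValueError("expected exactly one subject group")
            sid = next(iter(f.keys()))
            g = f[sid]
            for key in ("data", "labels"):
                if key not in g:
                    raise ValueError(f"container missing dataset {key!r}")
            data = np.asarray(g["data"])
            labels = _labels_from_matrix(np.asarray(g["labels"]))
            fs = float(g.attrs["fs"])
            names = [
                n.decode() if isinstance(n, bytes) else str(n)
                for n in g.attrs["channel_names"]
            ]
        return RawTrialSet(sid, data, fs, names, labels)
    if dialect == "mat":
        try:
            raw = scipy.io.loadmat(str(path), squeeze_me=False)
            data = np.asarray(raw["data"])
            labels = _labels_from_matrix(np.asarray(raw["labels"]))
            fs = float(np.asarray(raw["fs"]).ravel()[0])
            names = [str(n[0]) if np.ndim(n) else str(n) for n in raw["channel_names"].ravel()]
            sid = str(np.asarray(raw["subject_id"]).ravel()[0])
        except NotImplementedError:  # MAT v7.3 is an HDF5 file
            with h5py.File(path, "r") as f:
                data = np.asarray(f["data"])
                labels = _labels_from_matrix(np.asarray(f["labels"]))
                fs = float(np.asarray(f["fs"]).ravel()[0])
                names = [
                    n.decode() if isinstance(n, bytes) else str(n)
                    for n in np.asarray(f["channel_names"]).ravel()
                ]
                sid = str(np.asarray(f["subject_id"]).ravel()[0])
        return RawTrialSet(sid, data, fs, names, labels)
    raise ValueError(f"unknown dialect {dialect!r}")
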