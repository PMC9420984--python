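"""Topographic 9x9 grid mapping of the 32-channel 10-20 montage.

Each channel's time series is placed at its scalp-relative cell of a sparse
9x9 matrix (row 0 = front of head, column 0 = left ear side, column 4 =
midline); the 49 cells without an electrode stay exactly zero.  Stacking the
grid over time yields the 9 x 9 x L input blocks of the classifier.

The coordinates are shipped as an editable plain-text table (``name,row,col``)
so an alternative digitisation of the montage can be dropped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

from .io import DEAP_32_CHANNELS, RawTrialSet, class_of
from .preprocess import WindowSpec, correct_baseline, window_segments

__all__ = [
    "GRID_SIZE",
    "ElectrodeLayout",
    "TopoDataset",
    "default_layout",
    "map_to_grid",
    "grid_to_channels",
    "normalize_grid",
    "assemble_dataset",
]

GRID_SIZE = 9

# name,row,col table: 9 scalp rows front-to-back, columns left-to-right,
# midline sites (Fz/Cz/Pz/Oz) on column 4.
_DEFAULT_LAYOUT_TABLE = """\
Fp1,0,3
Fp2,0,5
AF3,1,3
AF4,1,5
F7,2,0
F3,2,2
Fz,2,4
F4,2,6
F8,2,8
FC5,3,1
FC1,3,3
FC2,3,5
FC6,3,7
T7,4,0
C3,4,2
Cz,4,4
C4,4,6
T8,4,8
CP5,5,1
CP1,5,3
CP2,5,5
CP6,5,7
P7,6,0
P3,6,2
Pz,6,4
P4,6,6
P8,6,8
PO3,7,3
PO4,7,5
O1,8,3
Oz,8,4
O2,8,5
"""


@dataclass(frozen=True)
class ElectrodeLayout:
    """Injective mapping channel name -> (row, col) on the 9x9 grid."""

    positions: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        cells = list(self.positions.values())
        if len(set(cells)) != len(cells):
            raise ValueError("two channels share a grid cell")
        for name, (r, c) in self.positions.items():
            if not (0 <= r < GRID_SIZE and 0 <= c < GRID_SIZE):
                raise ValueError(f"{name} at ({r},{c}) outside the 9x9 grid")

    def __contains__(self, name: str) -> bool:
        return name in self.positions

    def __getitem__(self, name: str) -> tuple[int, int]:
        return self.positions[name]

    @classmethod
    def from_table(cls, text: str) -> "ElectrodeLayout":
        positions = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, r, c = line.split(",")
            positions[name] = (int(r), int(c))
        return cls(positions)

    @classmethod
    def from_file(cls, path: str | Path) -> "ElectrodeLayout":
        return cls.from_table(Path(path).read_text())


def default_layout() -> ElectrodeLayout:
    """The documented 32-channel layout (all canonical channels present)."""
    layout = ElectrodeLayout.from_table(_DEFAULT_LAYOUT_TABLE)
    missing = set(DEAP_32_CHANNELS) - set(layout.positions)
    assert not missing, f"layout table missing {missing}"
    return layout


def map_to_grid(
    segment: np.ndarray, layout: ElectrodeLayout, names: Sequence[str]
) -> np.ndarray:
    """Place a C x L channel matrix onto the 9 x 9 x L grid; empty cells are 0."""
    segment = np.asarray(segment)
    C, L = segment.shape
    if C != len(names):
        raise ValueError(f"{C} rows for {len(names)} channel names")
    grid = np.zeros((GRID_SIZE, GRID_SIZE, L), dtype=segment.dtype)
    for i, name in enumerate(names):
        if name not in layout:
            raise KeyError(f"channel {name!r} has no layout position")
        r, c = layout[name]
        grid[r, c] = segment[i]
    return grid


def grid_to_channels(
    grid: np.ndarray, layout: ElectrodeLayout, names: Sequence[str]
) -> np.ndarray:
    """Inverse lookup: recover the C x L channel matrix from a grid."""
    return np.stack([grid[layout[n][0], layout[n][1]] for n in names])


def normalize_grid(
    grid: np.ndarray,
    mode: str = "zscore",
    occupied: Iterable[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Normalise each occupied cell's time series within the segment.

    zscore: mean 0, variance 1 per cell (zero-variance cells are left at 0);
    minmax: rescale occupied values to [0, 1] per cell (constant cells -> 0);
    none: identity.  Empty cells remain exactly 0 in every mode.
    """
    if mode == "none":
        return grid.copy()
    grid = np.asarray(grid, dtype=float)
    if occupied is None:
        occupied = [tuple(rc) for rc in np.argwhere(np.any(grid != 0, axis=-1))]
    out = np.zeros_like(grid)
    for r, c in occupied:
        x = grid[r, c]
        if mode == "zscore":
            sd = x.std()
            out[r, c] = (x - x.mean()) / sd if sd > 0 else 0.0
        elif mode == "minmax":
            lo, hi = x.min(), x.max()
            out[r, c] = (x - lo) / (hi - lo) if hi > lo else 0.0
        else:
            raise ValueError(f"unknown normalisation mode {mode!r}")
    return out


@dataclass
class TopoDataset:
    """Stack of 9 x 9 x L grid segments with one class label each.

    ``provenance[i]`` records (subject_id, trial index, window index) for
    segment i.
    """

    grids: np.ndarray
    labels: np.ndarray
    provenance: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grids = np.asarray(self.grids)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.grids) != len(self.labels):
            raise ValueError("grids and labels disagree in length")

    def __len__(self) -> int:
        return len(self.grids)

    @property
    def segment_length(self) -> int:
        return self.grids.shape[-1]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("grids", data=self.grids)
            f.create_dataset("labels", data=self.labels)
            if self.provenance:
                prov = np.array(
                    [f"{s}:{t}:{w}" for s, t, w in self.provenance], dtype="S64"
                )
                f.create_dataset("provenance", data=prov)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TopoDataset":
        with h5py.File(path, "r") as f:
            grids = np.asarray(f["grids"])
            labels = np.asarray(f["labels"])
            prov = []
            if "provenance" in f:
                for raw in np.asarray(f["provenance"]):
                    s, t, w = raw.decode().split(":")
                    prov.append((s, int(t), int(w)))
        return cls(grids, labels, prov)


def assemble_dataset(
    trialset: RawTrialSet,
    layout: ElectrodeLayout | None = None,
    window: WindowSpec | None = None,
    baseline_s: float = 0.0,
    normalize: str = "zscore",
    threshold: float = 5.0,
    dtype=np.float32,
) -> TopoDataset:
    """Run trials through baseline correction, windowing and grid mapping.

    Every window inherits its trial's class label.  ``baseline_s`` seconds at
    the start of each trial are consumed as the baseline reference (0 for
    recordings without a pre-stimulus period).
    """
    layout = layout or default_layout()
    window = window or WindowSpec(1.0, 0.0)
    occupied = [layout[n] for n in trialset.channel_names]
    if len(trialset.labels) != trialset.n_trials:
        raise ValueError("labels and trials disagree in count")

    grids, labels, prov = [], [], []
    for t in range(trialset.n_trials):
        trial = trialset.data[t]
        if baseline_s > 0:
            trial = correct_baseline(trial, trialset.fs, baseline_s)
        windows = window_segments(trial, trialset.fs, window)
        cls = class_of(trialset.labels[t], threshold)
        for k, seg in enumerate(windows):
            grid = map_to_grid(seg, layout, trialset.channel_names)
            grid = normalize_grid(grid, normalize, occupied=occupied)
            grids.append(grid.astype(dtype))
            labels.append(cls)
            prov.append((trialset.subject_id, t, k))
    if not grids:
        L = int(round(window.length_s * trialset.fs))
        return TopoDataset(
            np.zeros((0, GRID_SIZE, GRID_SIZE, L), dtype=dtype), np.zeros(0, int), []
        )
    return TopoDataset(np.stack(grids), np.asarray(labels), prov)
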