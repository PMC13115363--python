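"""Shared I/O: electrode layouts, run configuration, label binarisation.

The electrode layout file is plain text, one electrode per line
(``name row col``), ``#`` starting a comment.  Grid indices are 0-based,
row-major, top-left origin.  A 32-channel cap on the standard 8x9 scalp grid
ships with the package (:func:`default_layout_path`).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("msdafuse")

__all__ = [
    "ElectrodeLayout", "RunConfig", "RecordingSet",
    "load_layout", "write_layout", "default_layout_path", "binarize_rating",
    "load_run_config",
]


class LayoutError(ValueError):
    """Malformed or inconsistent electrode layout."""


@dataclasses.dataclass(frozen=True)
class ElectrodeLayout:
    """Channel -> (row, col) placement on a rectangular scalp grid."""

    entries: tuple[tuple[str, int, int], ...]
    grid_rows: int = 8
    grid_cols: int = 9

    def __post_init__(self):
        seen_pos: set[tuple[int, int]] = set()
        seen_name: set[str] = set()
        for name, row, col in self.entries:
            if not (0 <= row < self.grid_rows and 0 <= col < self.grid_cols):
                raise LayoutError(
                    f"electrode {name!r} at ({row},{col}) outside "
                    f"{self.grid_rows}x{self.grid_cols} grid")
            if (row, col) in seen_pos:
                raise LayoutError(f"duplicate grid position ({row},{col})")
            if name in seen_name:
                raise LayoutError(f"duplicate electrode name {name!r}")
            seen_pos.add((row, col))
            seen_name.add(name)

    @property
    def n_channels(self) -> int:
        return len(self.entries)

    @property
    def channel_names(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    def positions(self) -> np.ndarray:
        """(n_channels, 2) array of (row, col) indices in entry order."""
        return np.array([(r, c) for _, r, c in self.entries], dtype=np.intp)

    def occupancy(self) -> np.ndarray:
        """Boolean grid, True where an electrode sits."""
        occ = np.zeros((self.grid_rows, self.grid_cols), dtype=bool)
        for _, r, c in self.entries:
            occ[r, c] = True
        return occ


def default_layout_path() -> Path:
    """Path of the bundled 32-channel 8x9 layout."""
    return Path(importlib.resources.files("msdafuse") / "data" / "deap_32.layout")


def load_layout(path: str | Path, grid_rows: int = 8, grid_cols: int = 9) -> ElectrodeLayout:
    """Parse a layout file; rejects malformed lines and out-of-grid indices."""
    entries: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise LayoutError(
                    f"{path}:{lineno}: expected 'name row col', got {raw.rstrip()!r}")
            name, row_s, col_s = parts
            try:
                row, col = int(row_s), int(col_s)
            except ValueError as exc:
                raise LayoutError(f"{path}:{lineno}: non-integer index") from exc
            entries.append((name, row, col))
    return ElectrodeLayout(tuple(entries), grid_rows, grid_cols)


def write_layout(layout: ElectrodeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# name row col\n")
        for name, row, col in layout.entries:
            fh.write(f"{name} {row} {col}\n")


@dataclasses.dataclass
class RunConfig:
    """Training hyper-parameters shared by the branch and fusion trainers.

    Defaults follow the experimental protocol this package implements:
    Adam at 5e-4 for the two modality branches, 1e-4 for the fusion head,
    batch sizes 128 (face) / 32 (EEG and fusion), 20 fusion epochs, and
    modality dropout with probability 0.1 during fusion training.
    """

    learning_rate_branch: float = 5e-4
    learning_rate_fusion: float = 1e-4
    batch_face: int = 128
    batch_eeg: int = 32
    batch_fusion: int = 32
    branch_epochs: int = 30
    fusion_epochs: int = 20
    modality_dropout_p: float = 0.1
    rating_threshold: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate_branch <= 0 or self.learning_rate_fusion <= 0:
            raise ValueError("learning rates must be positive")
        if not 0.0 <= self.modality_dropout_p <= 1.0:
            raise ValueError("modality_dropout_p must lie in [0,1]")

    def log_settings(self) -> None:
        """Echo every configuration value into the run log."""
        for field in dataclasses.fields(self):
            logger.info("config %s = %r", field.name, getattr(self, field.name))


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML mapping (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def binarize_rating(rating: float, threshold: float = 5.0) -> int:
    """Map a 1-9 affect rating to a binary label: 1 if above threshold.

    Ratings at or below the threshold become 0 (low), strictly above
    become 1 (high).
    """
    if not 1.0 <= rating <= 9.0:
        raise ValueError(f"rating {rating} outside the 1-9 scale")
    return int(rating > threshold)


@dataclasses.dataclass
class RecordingSet:
    """One subject's aligned trials: EEG, face-frame sequences, labels."""

    subject_id: str
    trials: list  # of eeg_features.EEGTrial
    face_frames: list  # per trial: array (n_frames, H, W)
    labels: np.ndarray  # per-trial binary labels

    def __post_init__(self):
        if len(self.trials) != len(self.face_frames):
            raise ValueError("trials and face-frame sequences differ in count")
        if len(self.labels) != len(self.trials):
            raise ValueError("labels must be present for every trial")
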