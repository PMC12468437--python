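"""Audio and manifest I/O, windowing, splits and balanced resampling.

The evaluation protocol this package implements draws, on every
iteration, a balanced subset of n recordings per class from a pool of
six-second segments, runs stratified k-fold cross-validation on it, and
repeats.  This module provides the corpus bookkeeping for that: CSV
manifests, WAV round-trips, fixed-length windowing, a stratified
8:1:1-style split and the balanced resampler.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synth import MANIFEST_COLUMNS, PCGRecording

__all__ = [
    "DatasetManifest",
    "SplitAssignment",
    "AudioSegment",
    "read_wav",
    "write_wav",
    "segment_recording",
    "stratified_split",
    "balanced_resample",
    "balanced_indices",
]

VALID_LABELS = ("normal", "abnormal")


class UnsupportedFormatError(ValueError):
    """Raised for audio files that are not mono 16-bit PCM."""


@dataclass
class DatasetManifest:
    """A table of recordings: path, label, condition plus metadata."""

    table: pd.DataFrame
    path: Path | None = None
    validate_unique: bool = True

    def __post_init__(self) -> None:
        bad = set(self.table["label"]) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"labels must be one of {VALID_LABELS}, found {sorted(bad)}")
        if self.validate_unique and self.table["path"].duplicated().any():
            raise ValueError("manifest paths must be unique")

    @classmethod
    def from_rows(cls, rows: list[dict], path: str | Path | None = None) -> "DatasetManifest":
        cols = MANIFEST_COLUMNS if rows == [] else list(rows[0])
        return cls(pd.DataFrame(rows, columns=cols), Path(path) if path else None)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetManifest":
        return cls(pd.read_csv(Path(path)), Path(path))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.table["label"].value_counts().to_dict()
        return {label: int(counts.get(label, 0)) for label in VALID_LABELS}

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SplitAssignment:
    """Record -> {train, validation, test} partition map."""

    table: pd.DataFrame  # manifest columns + "partition"
    ratios: tuple[float, float, float]
    seed: int

    def partition(self, name: str) -> pd.DataFrame:
        return self.table[self.table["partition"] == name].reset_index(drop=True)

    def counts(self) -> dict[str, int]:
        return self.table["partition"].value_counts().to_dict()

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


@dataclass
class AudioSegment:
    """One fixed-length window cut from a recording."""

    samples: np.ndarray
    sample_rate: int
    source_path: str
    window_index: int
    label: str

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


def write_wav(recording: PCGRecording, path: str | Path) -> Path:
    """Write a recording as mono 16-bit PCM WAV (RIFF)."""
    path = Path(path)
    clipped = np.clip(recording.samples, -1.0, 1.0)
    wavfile.write(path, recording.sample_rate, np.round(clipped * 32767.0).astype(np.int16))
    return path


def read_wav(path: str | Path, label: str = "normal", condition: str = "normal") -> PCGRecording:
    """Read a mono 16-bit PCM WAV into a :class:`PCGRecording`.

    Raises :class:`UnsupportedFormatError` for multi-channel or
    non-16-bit-integer audio.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sample_rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise UnsupportedFormatError(f"{path}: expected mono audio, got {data.ndim} channels")
    if data.dtype != np.int16:
        raise UnsupportedFormatError(f"{path}: expected 16-bit PCM, got dtype {data.dtype}")
    return PCGRecording(
        samples=data.astype(np.float64) / 32767.0,
        sample_rate=int(sample_rate),
        label=label,
        condition=condition,
    )


def segment_recording(
    recording: PCGRecording, window_s: float = 6.0, overlap_s: float = 0.0
) -> list[AudioSegment]:
    """Cut a recording into consecutive full windows.

    Stride is ``window_s - overlap_s``; an incomplete tail is discarded
    so every segment has exactly the window length.  A recording shorter
    than one window yields an empty list.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not (0 <= overlap_s < window_s):
        raise ValueError("overlap_s must satisfy 0 <= overlap_s < window_s")
    win = round(window_s * recording.sample_rate)
    stride = round((window_s - overlap_s) * recording.sample_rate)
    segments = []
    start, idx = 0, 0
    while start + win <= len(recording.samples):
        segments.append(
            AudioSegment(
                samples=recording.samples[start : start + win].copy(),
                sample_rate=recording.sample_rate,
                source_path="",
                window_index=idx,
                label=recording.label,
            )
        )
        start += stride
        idx += 1
    return segments


def _largest_remainder_counts(n: int, ratios: tuple[float, ...]) -> list[int]:
    exact = [n * r for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    # Ties broken by partition order (train first), as remainders sort stably.
    order = sorted(range(len(ratios)), key=lambda i: exact[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def stratified_split(
    manifest: DatasetManifest,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Class-stratified train/validation/test split.

    Per-class partition sizes come from largest-remainder rounding of
    the requested ratios, so class proportions in each partition deviate
    from the global proportion by at most one record.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    parts = ["train", "validation", "test"]
    table = manifest.table.copy()
    table["partition"] = ""
    for label in sorted(table["label"].unique()):
        idx = table.index[table["label"] == label].to_numpy()
        rng.shuffle(idx)
        counts = _largest_remainder_counts(len(idx), ratios)
        pos = 0
        for part, c in zip(parts, counts):
            table.loc[idx[pos : pos + c], "partition"] = part
            pos += c
    return SplitAssignment(table=table, ratios=ratios, seed=seed)


def balanced_indices(
    labels: np.ndarray,
    n_per_class: int = 218,
    iterations: int = 50,
    seed: int = 0,
    replace: bool = False,
) -> Iterator[np.ndarray]:
    """Yield index arrays of balanced subsets, one per iteration.

    Each iteration draws ``n_per_class`` members of each class without
    replacement (within the iteration).  Iterations are independent
    draws from the full pool.
    """
    labels = np.asarray(labels)
    per_class = {lab: np.flatnonzero(labels == lab) for lab in VALID_LABELS}
    if not replace:
        for lab, idx in per_class.items():
            if len(idx) < n_per_class:
                raise ValueError(
                    f"class {lab!r} has {len(idx)} members, fewer than "
                    f"n_per_class={n_per_class}; enable replacement or shrink the draw"
                )
    rng = np.random.default_rng(seed)
    for _ in range(iterations):
        chosen = [
            rng.choice(per_class[lab], size=n_per_class, replace=replace)
            for lab in VALID_LABELS
        ]
        yield np.sort(np.concatenate(chosen))


def balanced_resample(
    pool: DatasetManifest,
    n_per_class: int = 218,
    iterations: int = 50,
    seed: int = 0,
    replace: bool = False,
) -> Iterator[DatasetManifest]:
    """Yield balanced sub-manifests (n_per_class of each class) per iteration."""
    labels = pool.table["label"].to_numpy()
    for idx in balanced_indices(labels, n_per_class, iterations, seed, replace):
        sub = pool.table.iloc[idx].reset_index(drop=True)
        yield DatasetManifest(sub, validate_unique=not replace)
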