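"""Reading raw triaxial recordings, sliding-window segmentation, subject splits.

Recordings follow the common wearable-logger CSV convention of one row
per sample, ``time,x,y,z``, with the activity label and subject ID kept
outside the file (directory layout or a manifest).  Segmentation and the
subject-wise split are deliberately simple: windows are contiguous
slices of a single recording and inherit its label, and every window of
a subject lands in exactly one of train/validation/test, so no subject
leaks across partitions.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .spectral import Window

__all__ = [
    "Recording",
    "DatasetSplit",
    "read_accel_csv",
    "write_accel_csv",
    "read_manifest",
    "sliding_windows",
    "split_by_subject",
]


@dataclass
class Recording:
    """A continuous triaxial acceleration stream from one subject."""

    samples: np.ndarray  # shape (T, 3)
    fs: float
    label: str
    subject: str
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(
                f"expected a (T, 3) matrix, got shape {self.samples.shape}"
            )
        if len(self.samples) < 1:
            raise ValueError("recording is empty")
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def read_accel_csv(
    path: str | Path, fs: float, label: str, subject: str
) -> Recording:
    """Parse a ``time,x,y,z`` CSV into a :class:`Recording`.

    Rows must be numeric with at least four columns and non-decreasing
    timestamps; a malformed row is reported with its 1-based line number.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and any(
                not _is_number(cell) for cell in row[:4]
            ):
                continue  # header line
            if len(row) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected time,x,y,z (4 columns), "
                    f"got {len(row)}"
                )
            try:
                rows.append([float(cell) for cell in row[:4]])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value in row {row!r}"
                ) from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    data = np.asarray(rows)
    t = data[:, 0]
    if np.any(np.diff(t) < 0):
        bad = int(np.argmax(np.diff(t) < 0)) + 2
        raise ValueError(f"{path}:{bad}: timestamps decrease")
    return Recording(
        samples=data[:, 1:4], fs=fs, label=label, subject=subject,
        source=str(path),
    )


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_accel_csv(rec: Recording, path: str | Path) -> None:
    """Write a recording in the ``time,x,y,z`` convention (no header)."""
    t = np.arange(rec.n_samples) / rec.fs
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for ti, (x, y, z) in zip(t, rec.samples):
            writer.writerow(
                [f"{ti:.6f}", repr(float(x)), repr(float(y)), repr(float(z))]
            )


def read_manifest(path: str | Path, fs: float) -> list[Recording]:
    """Load recordings listed in a manifest CSV: ``path,label,subject``.

    Relative paths resolve against the manifest's directory.
    """
    path = Path(path)
    recordings = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "path", "label", "subject"
        } <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: manifest needs columns path,label,subject"
            )
        for row in reader:
            rec_path = Path(row["path"])
            if not rec_path.is_absolute():
                rec_path = path.parent / rec_path
            recordings.append(
                read_accel_csv(rec_path, fs, row["label"], row["subject"])
            )
    return recordings


def sliding_windows(
    rec: Recording, window_size: int, stride: int | None = None
) -> list[Window]:
    """Cut a recording into fixed-length windows.

    Window ``i`` covers samples ``[i*stride, i*stride + w)`` (0-based,
    half-open); the trailing remainder is dropped, giving exactly
    ``floor((T - w) / stride) + 1`` windows.  The stride defaults to the
    window size (non-overlapping).  A recording shorter than one window
    yields an empty list with a warning.
    """
    if stride is None:
        stride = window_size
    if window_size < 1 or stride < 1:
        raise ValueError("window size and stride must be >= 1")
    T = rec.n_samples
    if window_size > T:
        warnings.warn(
            f"recording of {T} samples shorter than window ({window_size}); "
            "no windows produced",
            stacklevel=2,
        )
        return []
    n = (T - window_size) // stride + 1
    return [
        Window(
            values=rec.samples[i * stride : i * stride + window_size].T,
            label=rec.label,
            subject=rec.subject,
        )
        for i in range(n)
    ]


@dataclass
class DatasetSplit:
    """Subject-disjoint train/validation/test windows plus segmentation metadata."""

    train: list[Window]
    valid: list[Window]
    test: list[Window]
    class_set: list[str]
    fs: float
    window_size: int
    stride: int
    subjects: dict[str, list[str]] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        parts = [set(s) for s in self.subjects.values()] or [
            {w.subject for w in ws}
            for ws in (self.train, self.valid, self.test)
        ]
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                if parts[i] & parts[j]:
                    raise ValueError(
                        f"subject overlap between partitions: {parts[i] & parts[j]}"
                    )
        known = set(self.class_set)
        for w in (*self.train, *self.valid, *self.test):
            if w.label not in known:
                raise ValueError(f"window label {w.label!r} not in class set")

    def to_json(self, path: str | Path) -> None:
        """Persist the split description (not the data) for reproducibility."""
        with open(path, "w") as fh:
            json.dump(
                {
                    "class_set": self.class_set,
                    "fs": self.fs,
                    "window_size": self.window_size,
                    "stride": self.stride,
                    "seed": self.seed,
                    "subjects": self.subjects,
                    "n_windows": {
                        "train": len(self.train),
                        "valid": len(self.valid),
                        "test": len(self.test),
                    },
                },
                fh,
                indent=2,
            )


def split_by_subject(
    recordings: Sequence[Recording],
    n_train: int,
    n_valid: int,
    n_test: int,
    seed: int,
    window_size: int,
    stride: int | None = None,
) -> DatasetSplit:
    """Assign whole subjects to train/valid/test, then segment.

    Subjects are shuffled under ``seed`` and dealt out disjointly; every
    window of a subject follows that subject's partition, so the split
    is leakage-free by construction.
    """
    if stride is None:
        stride = window_size
    subjects = sorted({r.subject for r in recordings})
    need = n_train + n_valid + n_test
    if len(subjects) < need:
        raise ValueError(
            f"need {need} distinct subjects, found {len(subjects)}"
        )
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    assignment = {
        "train": order[:n_train],
        "valid": order[n_train : n_train + n_valid],
        "test": order[n_train + n_valid : need],
    }
    member = {s: part for part, subs in assignment.items() for s in subs}

    fs_values = {r.fs for r in recordings}
    if len(fs_values) != 1:
        raise ValueError(f"mixed sampling frequencies: {sorted(fs_values)}")
    (fs,) = fs_values

    parts: dict[str, list[Window]] = {"train": [], "valid": [], "test": []}
    for rec in recordings:
        part = member.get(rec.subject)
        if part is None:
            continue  # subject not drawn into any partition
        parts[part].extend(sliding_windows(rec, window_size, stride))

    class_set = sorted({r.label for r in recordings})
    return DatasetSplit(
        train=parts["train"],
        valid=parts["valid"],
        test=parts["test"],
        class_set=class_set,
        fs=fs,
        window_size=window_size,
        stride=stride,
        subjects=assignment,
        seed=seed,
    )


def stack_windows(
    windows: Iterable[Window], class_set: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into ``(X, y)`` arrays for the classifier.

    ``X`` has shape (N, 3, w); ``y`` holds integer indices into
    ``class_set``.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("no windows to stack")
    index = {c: i for i, c in enumerate(class_set)}
    X = np.stack([w.values for w in windows])
    y = np.array([index[w.label] for w in windows], dtype=int)
    return X, y
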