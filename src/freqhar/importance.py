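"""Phase 1: find each activity's important frequency by an FFT-bin masking sweep.

A classifier trained on unfiltered data is evaluated on validation
windows in which one frequency bin at a time has been zeroed (DC is
never masked; the sweep runs over (0, Nyquist]).  For each class the
per-class accuracy (recall) as a function of the masked bin forms an
:class:`ImportanceCurve`; the bin whose removal hurts that class most
is its *important frequency*.  A class whose curve never drops below
the unmasked baseline — beyond a small tolerance — resolves to 0 Hz:
its information lives in the DC component (e.g. standing still).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .spectral import SpectrumGrid, Window, apply_gains, make_mask_profile

__all__ = [
    "ImportanceCurve",
    "FrequencyBank",
    "mask_sweep",
    "select_important_frequency",
    "build_frequency_bank",
]


@dataclass(frozen=True)
class ImportanceCurve:
    """Per-class recall as a function of the masked frequency bin."""

    label: str
    baseline_acc: float
    acc_by_bin: np.ndarray  # entry i = recall with bin (i + 1) masked
    grid: SpectrumGrid
    defined: bool = True

    def __post_init__(self) -> None:
        acc = np.asarray(self.acc_by_bin, dtype=float)
        if self.defined:
            if acc.shape != (self.grid.n_bins - 1,):
                raise ValueError(
                    f"expected {self.grid.n_bins - 1} sweep points, got {acc.shape}"
                )
            if np.any(acc < 0) or np.any(acc > 1):
                raise ValueError("accuracies must lie in [0, 1]")
            if not 0 <= self.baseline_acc <= 1:
                raise ValueError("baseline accuracy must lie in [0, 1]")
        object.__setattr__(self, "acc_by_bin", acc)

    @property
    def bins(self) -> np.ndarray:
        return np.arange(1, self.grid.n_bins)

    def to_rows(self) -> list[tuple]:
        rows = [(self.label, 0, 0.0, self.baseline_acc)]
        for k, a in zip(self.bins, self.acc_by_bin):
            rows.append((self.label, int(k), float(self.grid.bin_to_hz(k)), float(a)))
        return rows


def export_curves_csv(curves: Sequence[ImportanceCurve], path: str | Path) -> None:
    """Write all curves as (class, bin, hz, accuracy); bin 0 row = baseline."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class", "bin", "hz", "accuracy"])
        for curve in curves:
            if curve.defined:
                writer.writerows(curve.to_rows())


@dataclass(frozen=True)
class FrequencyBank:
    """Mapping class -> important frequency (bin index and Hz)."""

    entries: dict[str, tuple[int, float]]
    grid: SpectrumGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, (k, hz) in self.entries.items():
            if not 0 <= hz <= self.grid.fs / 2:
                raise ValueError(f"{label}: {hz} Hz outside [0, Nyquist]")
            if not 0 <= k <= self.grid.n_bins - 1:
                raise ValueError(f"{label}: bin {k} outside the grid")

    @property
    def classes(self) -> list[str]:
        return list(self.entries)

    def bin_of(self, label: str) -> int:
        return self.entries[label][0]

    def hz_of(self, label: str) -> float:
        return self.entries[label][1]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["class", "bin", "hz"])
            for label, (k, hz) in self.entries.items():
                writer.writerow([label, k, f"{hz:.6g}"])

    @classmethod
    def from_csv(cls, path: str | Path, grid: SpectrumGrid) -> "FrequencyBank":
        entries = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries[row["class"]] = (int(row["bin"]), float(row["hz"]))
        return cls(entries=entries, grid=grid, provenance={"source": str(path)})


PredictFn = Callable[[np.ndarray], np.ndarray]


def _predictor(model) -> PredictFn:
    """Accept a trained classifier or any callable X -> argmax labels."""
    if hasattr(model, "predict_proba"):
        return lambda X: model.predict_proba(X).argmax(axis=1)
    if callable(model):
        return model
    raise TypeError("model must expose predict_proba or be callable")


def mask_sweep(
    model,
    valid_windows: Sequence[Window],
    grid: SpectrumGrid,
    class_set: Sequence[str],
    band_width: int = 1,
) -> list[ImportanceCurve]:
    """Mask one bin at a time over the validation set; record per-class recall.

    The model must have been trained on *unfiltered* data from subjects
    disjoint from ``valid_windows``.  ``band_width`` > 1 widens each
    occlusion to that many consecutive bins (the sweep still steps one
    bin at a time and never touches DC).  A class with no validation
    windows yields an undefined curve.
    """
    if band_width < 1:
        raise ValueError("band width must be >= 1")
    if not valid_windows:
        raise ValueError("no validation windows")
    X = np.stack([w.values for w in valid_windows])
    if X.shape[-1] != grid.n_samples:
        raise ValueError(
            f"window length {X.shape[-1]} != grid length {grid.n_samples}"
        )
    index = {c: i for i, c in enumerate(class_set)}
    y = np.array([index[w.label] for w in valid_windows])
    predict = _predictor(model)

    def per_class_recall(labels: np.ndarray) -> np.ndarray:
        recall = np.full(len(class_set), np.nan)
        for c in range(len(class_set)):
            members = y == c
            if members.any():
                recall[c] = float((labels[members] == c).mean())
        return recall

    baseline = per_class_recall(predict(X))

    spectrum = np.fft.rfft(X, axis=-1)
    n_bins = grid.n_bins
    sweep = np.empty((n_bins - 1, len(class_set)))
    for k in range(1, n_bins):
        hi = min(k + band_width - 1, n_bins - 1)
        # equivalent to apply_gains with make_mask_profile(grid, (k, hi))
        masked = spectrum.copy()
        masked[..., k : hi + 1] = 0.0
        Xk = np.fft.irfft(masked, n=grid.n_samples, axis=-1)
        sweep[k - 1] = per_class_recall(predict(Xk))

    curves = []
    for c, label in enumerate(class_set):
        defined = bool(np.isfinite(baseline[c]))
        curves.append(
            ImportanceCurve(
                label=label,
                baseline_acc=float(baseline[c]) if defined else float("nan"),
                acc_by_bin=sweep[:, c] if defined else np.empty(0),
                grid=grid,
                defined=defined,
            )
        )
    return curves


def select_important_frequency(
    curve: ImportanceCurve, tolerance: float = 0.005
) -> tuple[int, float]:
    """The masked bin that hurts this class most; 0 Hz if none does.

    Returns ``(bin, Hz)``: the argmin of the sweep curve, ties broken
    toward the lowest bin.  If no mask lowers recall below
    ``baseline - tolerance`` the class is DC-dominated and the result is
    ``(0, 0.0)``.  Only decreases matter; bins where masking *improves*
    recall never influence the choice.
    """
    if not curve.defined:
        raise ValueError(f"curve for class {curve.label!r} is undefined")
    acc = curve.acc_by_bin
    if float(acc.min()) >= curve.baseline_acc - tolerance:
        return 0, 0.0
    k = int(np.argmin(acc)) + 1  # sweep starts at bin 1; argmin takes first tie
    return k, float(curve.grid.bin_to_hz(k))


def build_frequency_bank(
    curves: Sequence[ImportanceCurve],
    grid: SpectrumGrid,
    tolerance: float = 0.005,
    provenance: dict | None = None,
) -> FrequencyBank:
    """Apply the selection rule to every class's curve."""
    entries = {}
    for curve in curves:
        if curve.label in entries:
            raise ValueError(f"duplicate curve for class {curve.label!r}")
        entries[curve.label] = select_important_frequency(curve, tolerance)
    prov = {"tolerance": tolerance}
    if provenance:
        prov.update(provenance)
    return FrequencyBank(entries=entries, grid=grid, provenance=prov)
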