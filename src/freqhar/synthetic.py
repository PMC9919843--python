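"""Synthetic triaxial accelerometer benchmark with planted spectral structure.

Each activity class is a sum of sinusoids: a dominant oscillation placed
exactly on an FFT bin of the target analysis grid, optional harmonics,
a per-axis DC offset (gravity/posture analogue) and i.i.d. Gaussian
noise.  One *static* class (DC plus noise only) is always part of the
default benchmark, mirroring standing still, whose only informative
component is the 0 Hz bin.  Subjects perturb the class template with
small frequency/amplitude jitter and random phases, so subject-wise
splits are genuinely harder than random splits.

The generator's defaults define the study conditions of every
end-to-end experiment in this package: 4 classes with dominant bins
{0, 3, 6, 10} on a (w=128, fs=64 Hz) grid, 10 subjects split 6/2/2,
16 s per recording, noise s.d. 0.3 against unit oscillation amplitude.
Oscillatory classes share the same DC offset and amplitude, so the
classifier can only separate them by frequency content — the regime the
frequency-masking analysis is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataio import DatasetSplit, Recording, split_by_subject, write_accel_csv
from .importance import FrequencyBank
from .spectral import SpectrumGrid

__all__ = [
    "ClassSpec",
    "SubjectSpec",
    "generate_recording",
    "generate_benchmark",
    "default_class_specs",
    "write_benchmark_csvs",
]


@dataclass(frozen=True)
class ClassSpec:
    """Spectral recipe of one activity class."""

    label: str
    dominant_hz: float
    harmonics: tuple[tuple[float, float], ...] = ()  # (multiple, rel. amplitude)
    dc_offset: tuple[float, float, float] = (0.0, 0.0, 1.0)
    amplitude: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.3
    static: bool = False

    def __post_init__(self) -> None:
        if self.static and (self.dominant_hz != 0 or self.harmonics):
            raise ValueError("a static class has no oscillatory terms")
        if any(a < 0 for a in self.amplitude) or self.noise_sd < 0:
            raise ValueError("amplitudes and noise s.d. must be >= 0")


@dataclass(frozen=True)
class SubjectSpec:
    """Per-subject perturbation of the class templates."""

    subject: str
    freq_jitter: float = 0.0  # multiplicative, e.g. 0.02 for +/-2 %
    amp_jitter: float = 0.0
    seed: int = 0


def generate_recording(
    class_spec: ClassSpec,
    subject_spec: SubjectSpec,
    duration_s: float,
    fs: float,
    seed: int,
) -> Recording:
    """Synthesize one labelled recording for one subject.

    Per axis: ``dc + sum_h amp * rel_amp * sin(2 pi h f_subj t + phi) +
    N(0, noise_sd)``, where ``f_subj`` is the class's dominant frequency
    scaled by the subject's jitter factor and ``phi`` is a per-axis,
    per-harmonic random phase.  Fully reproducible under ``seed`` (the
    subject's own seed fixes the jitter; ``seed`` fixes phase and noise).
    """
    T = int(round(duration_s * fs))
    if T < 1 or fs <= 0:
        raise ValueError(f"invalid duration {duration_s} s at fs {fs}")
    sub_rng = np.random.default_rng(subject_spec.seed)
    f_factor = 1.0 + subject_spec.freq_jitter * sub_rng.uniform(-1, 1)
    a_factor = 1.0 + subject_spec.amp_jitter * sub_rng.uniform(-1, 1)
    f0 = class_spec.dominant_hz * f_factor
    if f0 >= fs / 2:
        raise ValueError(
            f"jittered frequency {f0:.3f} Hz at or above Nyquist {fs / 2}"
        )

    rng = np.random.default_rng(seed)
    t = np.arange(T) / fs
    samples = np.empty((T, 3))
    terms = [] if class_spec.static else [(1.0, 1.0), *class_spec.harmonics]
    for axis in range(3):
        sig = np.full(T, class_spec.dc_offset[axis])
        amp = class_spec.amplitude[axis] * a_factor
        for multiple, rel in terms:
            phase = rng.uniform(0, 2 * np.pi)
            sig = sig + amp * rel * np.sin(2 * np.pi * multiple * f0 * t + phase)
        if class_spec.noise_sd > 0:
            sig = sig + rng.normal(0.0, class_spec.noise_sd, size=T)
        samples[:, axis] = sig
    return Recording(
        samples=samples, fs=fs, label=class_spec.label,
        subject=subject_spec.subject, source="synthetic",
    )


def default_class_specs(
    grid: SpectrumGrid,
    planted_bins: Sequence[int] = (0, 3, 6, 10),
    noise_sd: float = 0.3,
) -> list[ClassSpec]:
    """Class recipes with dominant frequencies on exact grid bins.

    Bin 0 denotes the static class; it gets a distinctive DC offset.
    Oscillatory classes share DC offset and amplitude so that frequency
    is the only separating feature.
    """
    if len(set(planted_bins)) != len(planted_bins):
        raise ValueError("planted bins must be distinct")
    specs = []
    for i, k in enumerate(planted_bins):
        if not 0 <= k <= grid.n_bins - 1:
            raise ValueError(f"planted bin {k} outside the grid")
        if k == 0:
            specs.append(
                ClassSpec(
                    label="static",
                    dominant_hz=0.0,
                    dc_offset=(0.8, -0.2, 0.4),
                    amplitude=(0.0, 0.0, 0.0),
                    noise_sd=noise_sd,
                    static=True,
                )
            )
        else:
            specs.append(
                ClassSpec(
                    label=f"osc_bin{k:02d}",
                    dominant_hz=float(grid.bin_to_hz(k)),
                    harmonics=((2.0, 0.2),),
                    dc_offset=(0.0, 0.0, 1.0),
                    amplitude=(1.0, 1.0, 1.0),
                    noise_sd=noise_sd,
                )
            )
    return specs


def generate_benchmark(
    seed: int,
    planted_bins: Sequence[int] = (0, 3, 6, 10),
    n_subjects: int = 10,
    per_split_subjects: tuple[int, int, int] = (6, 2, 2),
    duration_s: float = 16.0,
    fs: float = 64.0,
    window_size: int = 128,
    stride: int | None = None,
    noise_sd: float = 0.3,
    freq_jitter: float = 0.02,
    amp_jitter: float = 0.10,
) -> tuple[DatasetSplit, FrequencyBank]:
    """Full labelled benchmark plus the ground-truth frequency bank.

    One recording per (subject, class); subjects are split disjointly
    into train/valid/test.  The returned bank maps each class label to
    its planted bin — the recovery target for the masking analysis.
    """
    if sum(per_split_subjects) > n_subjects:
        raise ValueError("per-split subject counts exceed n_subjects")
    grid = SpectrumGrid(window_size, fs)
    specs = default_class_specs(grid, planted_bins, noise_sd=noise_sd)
    # jitter must not move a planted frequency by more than half a bin
    max_hz = max((s.dominant_hz for s in specs), default=0.0)
    if freq_jitter * max_hz > grid.bin_hz / 2:
        raise ValueError(
            f"frequency jitter {freq_jitter} moves the highest planted tone "
            f"by more than half a bin ({grid.bin_hz / 2:.3g} Hz)"
        )

    master = np.random.default_rng(seed)
    subjects = [
        SubjectSpec(
            subject=f"S{i:03d}",
            freq_jitter=freq_jitter,
            amp_jitter=amp_jitter,
            seed=int(master.integers(2**31)),
        )
        for i in range(n_subjects)
    ]
    recordings = [
        generate_recording(
            spec, sub, duration_s, fs, seed=int(master.integers(2**31))
        )
        for sub in subjects
        for spec in specs
    ]
    split = split_by_subject(
        recordings,
        *per_split_subjects,
        seed=int(master.integers(2**31)),
        window_size=window_size,
        stride=stride,
    )
    bank = FrequencyBank(
        entries={
            spec.label: (k, float(grid.bin_to_hz(k)))
            for spec, k in zip(specs, planted_bins)
        },
        grid=grid,
        provenance={"source": "planted", "seed": seed},
    )
    return split, bank


def write_benchmark_csvs(
    out_dir: str | Path,
    seed: int,
    **benchmark_kwargs,
) -> Path:
    """Write the benchmark as per-recording CSVs plus a manifest.

    Exercises the real-data code path end to end; returns the manifest
    path.  Regenerates the recordings (not the split) so every file on
    disk corresponds to one subject/class recording.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fs = benchmark_kwargs.get("fs", 64.0)
    window_size = benchmark_kwargs.get("window_size", 128)
    grid = SpectrumGrid(window_size, fs)
    specs = default_class_specs(
        grid,
        benchmark_kwargs.get("planted_bins", (0, 3, 6, 10)),
        noise_sd=benchmark_kwargs.get("noise_sd", 0.3),
    )
    master = np.random.default_rng(seed)
    n_subjects = benchmark_kwargs.get("n_subjects", 10)
    subjects = [
        SubjectSpec(
            subject=f"S{i:03d}",
            freq_jitter=benchmark_kwargs.get("freq_jitter", 0.02),
            amp_jitter=benchmark_kwargs.get("amp_jitter", 0.10),
            seed=int(master.integers(2**31)),
        )
        for i in range(n_subjects)
    ]
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w") as fh:
        fh.write("path,label,subject\n")
        for sub in subjects:
            for spec in specs:
                rec = generate_recording(
                    spec, sub,
                    benchmark_kwargs.get("duration_s", 16.0), fs,
                    seed=int(master.integers(2**31)),
                )
                name = f"{sub.subject}_{spec.label}.csv"
                write_accel_csv(rec, out_dir / name)
                fh.write(f"{name},{spec.label},{sub.subject}\n")
    return manifest
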