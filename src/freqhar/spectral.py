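"""FFT-domain gain profiles for triaxial accelerometer windows.

A :class:`GainProfile` is a real per-bin multiplier over the one-sided
spectrum of a window.  Applying it means: forward real FFT per axis,
scale each complex coefficient by its gain (phase preserved), inverse
FFT back to the time domain.  Two families of profiles exist:

* **masks** — gain 0 on a single bin (or band), 1 elsewhere; used to
  occlude one frequency at a time when searching for the frequency a
  classifier relies on for each activity;
* **emphasis windows** — gain 1 at a centre bin and a floor of 0.5
  elsewhere, shaped as a peak, Gaussian, triangular or random window;
  used to enhance the important frequency of one activity class.

The DC bin (0 Hz, the signal mean) is never masked and never
attenuated: it carries posture/orientation information, and for static
activities it is the only informative component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DCProtectionError",
    "SpectrumGrid",
    "GainProfile",
    "Window",
    "make_mask_profile",
    "make_peak_profile",
    "make_gaussian_profile",
    "make_triangular_profile",
    "make_random_profile",
    "make_unit_profile",
    "make_emphasis_profile",
    "apply_profile",
    "apply_gains",
]


class DCProtectionError(ValueError):
    """Raised when an operation would mask the DC (0 Hz) bin."""


@dataclass(frozen=True)
class SpectrumGrid:
    """One-sided FFT bin layout of a length-``n_samples`` window at ``fs`` Hz.

    Bin ``k`` maps to frequency ``k * fs / n_samples``; the highest bin
    sits at or below the Nyquist frequency ``fs / 2``.
    """

    n_samples: int
    fs: float

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError(f"window length must be >= 2, got {self.n_samples}")
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")

    @property
    def n_bins(self) -> int:
        return self.n_samples // 2 + 1

    @property
    def bin_hz(self) -> float:
        return self.fs / self.n_samples

    def bin_to_hz(self, k: int | np.ndarray) -> float | np.ndarray:
        return k * self.bin_hz

    def hz_to_bin(self, hz: float) -> int:
        """Nearest bin for a frequency (must not exceed Nyquist)."""
        if not 0 <= hz <= self.fs / 2:
            raise ValueError(f"{hz} Hz outside [0, {self.fs / 2}] Hz")
        return int(round(hz / self.bin_hz))


@dataclass(frozen=True)
class GainProfile:
    """Per-bin real multiplier in [0, 1] over a one-sided spectrum."""

    grid: SpectrumGrid
    gains: np.ndarray
    kind: str
    center_bin: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        gains = np.asarray(self.gains, dtype=float)
        if gains.shape != (self.grid.n_bins,):
            raise ValueError(
                f"gains shape {gains.shape} != ({self.grid.n_bins},)"
            )
        if np.any(gains < 0) or np.any(gains > 1):
            raise ValueError("all gains must lie in [0, 1]")
        object.__setattr__(self, "gains", gains)

    @property
    def center_hz(self) -> float | None:
        if self.center_bin is None:
            return None
        return self.grid.bin_to_hz(self.center_bin)

    def to_text(self, path: str | Path) -> None:
        """Write a two-column (bin_hz, gain) text table for inspection."""
        hz = self.grid.bin_to_hz(np.arange(self.grid.n_bins))
        with open(path, "w") as fh:
            fh.write("bin_hz\tgain\n")
            for f, g in zip(hz, self.gains):
                fh.write(f"{f:.6g}\t{g:.10g}\n")


@dataclass(frozen=True)
class Window:
    """One segmented sample: a 3 x w acceleration matrix plus provenance."""

    values: np.ndarray  # shape (3, w), axis-major
    label: str
    subject: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != 3:
            raise ValueError(f"expected a (3, w) matrix, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("window contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def length(self) -> int:
        return self.values.shape[1]


def _check_center(grid: SpectrumGrid, center_bin: int) -> None:
    if not 0 <= center_bin <= grid.n_bins - 1:
        raise ValueError(
            f"center bin {center_bin} outside [0, {grid.n_bins - 1}]"
        )


def _check_floor(floor: float) -> None:
    if not 0 < floor <= 1:
        raise ValueError(f"floor must be in (0, 1], got {floor}")


def make_mask_profile(
    grid: SpectrumGrid, band: int | tuple[int, int] | Sequence[int]
) -> GainProfile:
    """Zero one bin (or an inclusive bin range); every other gain is 1.

    Bin 0 is the DC component and may never be masked.
    """
    if isinstance(band, (int, np.integer)):
        lo = hi = int(band)
    else:
        lo, hi = int(band[0]), int(band[1])
    if lo > hi:
        raise ValueError(f"empty band ({lo}, {hi})")
    if lo <= 0:
        if lo == 0 or hi >= 0:
            raise DCProtectionError(
                "bin 0 is the DC component and must not be masked"
            )
        raise ValueError(f"band ({lo}, {hi}) out of range")
    if hi > grid.n_bins - 1:
        raise ValueError(
            f"band ({lo}, {hi}) exceeds highest bin {grid.n_bins - 1}"
        )
    gains = np.ones(grid.n_bins)
    gains[lo : hi + 1] = 0.0
    return GainProfile(grid, gains, kind="mask", center_bin=lo,
                       meta={"band": (lo, hi)})


def make_unit_profile(grid: SpectrumGrid) -> GainProfile:
    """All-ones profile; applying it is the identity."""
    return GainProfile(grid, np.ones(grid.n_bins), kind="unit")


def make_peak_profile(
    grid: SpectrumGrid, center_bin: int, floor: float = 0.5
) -> GainProfile:
    """Keep the centre bin unchanged, halve every other amplitude.

    Gain 1 at ``center_bin`` and at DC; ``floor`` (default 1/2) elsewhere.
    """
    _check_center(grid, center_bin)
    _check_floor(floor)
    gains = np.full(grid.n_bins, floor)
    gains[center_bin] = 1.0
    gains[0] = 1.0
    return GainProfile(grid, gains, kind="peak", center_bin=center_bin)


def make_gaussian_profile(
    grid: SpectrumGrid,
    center_bin: int,
    sigma_bins: float = 10.0,
    floor: float = 0.5,
) -> GainProfile:
    """Gaussian emphasis: 1 at the centre, decaying towards ``floor``.

    ``gains[k] = floor + (1 - floor) * exp(-(k - center)^2 / (2 sigma^2))``
    with sigma measured in bins (default 10).
    """
    _check_center(grid, center_bin)
    _check_floor(floor)
    if sigma_bins <= 0:
        raise ValueError(f"sigma must be positive, got {sigma_bins}")
    k = np.arange(grid.n_bins, dtype=float)
    gains = floor + (1.0 - floor) * np.exp(
        -((k - center_bin) ** 2) / (2.0 * sigma_bins**2)
    )
    gains[0] = 1.0
    return GainProfile(
        grid, gains, kind="gaussian", center_bin=center_bin,
        meta={"sigma_bins": sigma_bins, "floor": floor},
    )


def make_triangular_profile(
    grid: SpectrumGrid,
    center_bin: int,
    half_width_bins: int | None = None,
    floor: float = 0.5,
) -> GainProfile:
    """Triangular emphasis: vertex 1 at the centre, linear ramp, clamped at ``floor``.

    ``half_width_bins`` defaults to the distance from the centre to the
    farther edge of the spectrum, so the ramp spans the whole band.
    """
    _check_center(grid, center_bin)
    _check_floor(floor)
    if half_width_bins is None:
        half_width_bins = max(center_bin, grid.n_bins - 1 - center_bin)
        half_width_bins = max(half_width_bins, 1)
    if half_width_bins < 1:
        raise ValueError(f"half width must be >= 1, got {half_width_bins}")
    k = np.arange(grid.n_bins, dtype=float)
    gains = np.maximum(
        floor, 1.0 - (1.0 - floor) * np.abs(k - center_bin) / half_width_bins
    )
    gains[0] = 1.0
    return GainProfile(
        grid, gains, kind="triangular", center_bin=center_bin,
        meta={"half_width_bins": half_width_bins, "floor": floor},
    )


def make_random_profile(
    grid: SpectrumGrid,
    cutoff_hz: float = 7.8,
    rng_seed: int | None = None,
    outside_gain: float = 1.0,
) -> GainProfile:
    """Random emphasis: i.i.d. uniform gains on [0.5, 1] over (0, cutoff] Hz.

    Bins above the cutoff take ``outside_gain`` (1 by default; pass 0.5
    for floor-consistency with the shaped windows).  DC keeps gain 1.
    This control window carries no class information, so comparing it
    with the shaped windows isolates the value of emphasizing the right
    frequency.
    """
    if not 0 < cutoff_hz <= grid.fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz outside (0, {grid.fs / 2}] Hz"
        )
    if not 0 < outside_gain <= 1:
        raise ValueError(f"outside gain must be in (0, 1], got {outside_gain}")
    rng = np.random.default_rng(rng_seed)
    k = np.arange(grid.n_bins)
    in_band = (k >= 1) & (grid.bin_to_hz(k) <= cutoff_hz)
    gains = np.full(grid.n_bins, outside_gain)
    gains[in_band] = rng.uniform(0.5, 1.0, size=int(in_band.sum()))
    gains[0] = 1.0
    return GainProfile(
        grid, gains, kind="random", center_bin=None,
        meta={"cutoff_hz": cutoff_hz, "rng_seed": rng_seed},
    )


_EMPHASIS_MAKERS = {
    "peak": make_peak_profile,
    "gaussian": make_gaussian_profile,
    "triangular": make_triangular_profile,
}


def make_emphasis_profile(
    grid: SpectrumGrid,
    kind: str,
    center_bin: int,
    rng_seed: int | None = None,
    **kwargs,
) -> GainProfile:
    """Dispatch on filter kind (peak / gaussian / triangular / random).

    The random window ignores ``center_bin`` — it is the no-information
    control.
    """
    if kind == "random":
        return make_random_profile(grid, rng_seed=rng_seed, **kwargs)
    try:
        maker = _EMPHASIS_MAKERS[kind]
    except KeyError:
        raise ValueError(
            f"unknown filter kind {kind!r}; expected one of "
            f"{sorted(_EMPHASIS_MAKERS) + ['random']}"
        ) from None
    return maker(grid, center_bin, **kwargs)


def apply_gains(values: np.ndarray, gains: np.ndarray) -> np.ndarray:
    """Scale the one-sided spectrum of real signals along the last axis.

    ``values`` may be (w,), (3, w) or (N, 3, w); the gain is applied to
    each complex rFFT coefficient, so amplitude scales and phase is
    preserved, and the inverse transform is exactly real.
    """
    values = np.asarray(values, dtype=float)
    w = values.shape[-1]
    if gains.shape != (w // 2 + 1,):
        raise ValueError(
            f"gains length {gains.shape[0]} does not match window length {w}"
        )
    spectrum = np.fft.rfft(values, axis=-1)
    spectrum *= gains
    return np.fft.irfft(spectrum, n=w, axis=-1)


def apply_profile(window: Window, profile: GainProfile) -> Window:
    """Filter one window per axis; label and subject are preserved."""
    if window.length != profile.grid.n_samples:
        raise ValueError(
            f"window length {window.length} != profile grid length "
            f"{profile.grid.n_samples}"
        )
    filtered = apply_gains(window.values, profile.gains)
    return Window(values=filtered, label=window.label, subject=window.subject)
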