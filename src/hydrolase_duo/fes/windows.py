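"""Umbrella-sampling window container and plain-text window I/O.

A window is one biased simulation: a harmonic restraint
½kx(x−x₀)² + ½ky(y−y₀)² added to the underlying potential, plus the
time series of the two collective variables sampled under that bias.

On disk a set of windows is a directory with one ``windows.meta`` file
(one row per window: index, center, force constants, temperature) and
one whitespace-delimited ``window_<i>.dat`` per window with columns
``step  x  y`` — the layout commonly produced by umbrella-sampling
drivers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["UmbrellaWindow", "write_windows", "read_windows"]


@dataclass(frozen=True)
class UmbrellaWindow:
    """One biased sampling window over two collective variables (Å)."""

    center: tuple[float, float]
    force_constants: tuple[float, float]  # kcal/mol/Å²; ½k convention
    temperature: float  # K
    samples: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 2:
            raise ValueError(f"samples must have shape (n, 2), got {samples.shape}")
        if len(samples) < 1:
            raise ValueError("window must contain at least one sample")
        if any(k < 0 for k in self.force_constants):
            raise ValueError(f"force constants must be >= 0, got {self.force_constants}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def bias_energy(self, x, y):
        """Restraint energy ½kx(x−x₀)² + ½ky(y−y₀)², kcal/mol."""
        kx, ky = self.force_constants
        x0, y0 = self.center
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return 0.5 * kx * (x - x0) ** 2 + 0.5 * ky * (y - y0) ** 2


def write_windows(windows: list[UmbrellaWindow], directory: str | Path) -> None:
    """Write windows to ``directory`` (created if absent)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame(
        {
            "window": range(len(windows)),
            "x0": [w.center[0] for w in windows],
            "y0": [w.center[1] for w in windows],
            "kx": [w.force_constants[0] for w in windows],
            "ky": [w.force_constants[1] for w in windows],
            "temperature_K": [w.temperature for w in windows],
        }
    )
    meta.to_csv(directory / "windows.meta", sep="\t", index=False)
    for i, w in enumerate(windows):
        arr = np.column_stack([np.arange(w.n_samples), w.samples])
        np.savetxt(
            directory / f"window_{i}.dat",
            arr,
            fmt=["%d", "%.8f", "%.8f"],
            header="step x y",
        )


def read_windows(directory: str | Path) -> list[UmbrellaWindow]:
    """Read a window set written by :func:`write_windows`."""
    directory = Path(directory)
    meta_path = directory / "windows.meta"
    if not meta_path.exists():
        raise FileNotFoundError(f"no windows.meta in {directory}")
    meta = pd.read_csv(meta_path, sep="\t")
    windows = []
    for row in meta.itertuples():
        data = np.loadtxt(directory / f"window_{int(row.window)}.dat")
        data = np.atleast_2d(data)
        windows.append(
            UmbrellaWindow(
                center=(row.x0, row.y0),
                force_constants=(row.kx, row.ky),
                temperature=row.temperature_K,
                samples=data[:, 1:3],
            )
        )
    return windows
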