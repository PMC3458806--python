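"""Normalization of raw FRAP traces to pre-bleach levels.

A raw trace in detector units is background-subtracted and divided by
the mean background-subtracted signal of the last ``prebleach_window``
scans before the bleach, so 1.0 is the unperturbed fluorescence level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RawCurve",
    "NormalizedCurve",
    "DegenerateCurveError",
    "normalize_curve",
    "average_curves",
    "read_raw_csv",
    "write_curve_csv",
    "read_curve_csv",
]


class DegenerateCurveError(ValueError):
    """The trace has no usable dynamic range above background."""


@dataclass(frozen=True)
class RawCurve:
    """Raw fluorescence trace in arbitrary detector units.

    ``background`` is a single scalar offset per curve; ``n_prebleach``
    is the declared index of the bleach scan (never inferred from the
    data).
    """

    time: np.ndarray
    intensity: np.ndarray
    background: float
    n_prebleach: int

    def __post_init__(self) -> None:
        if self.background < 0:
            raise ValueError("background must be non-negative")
        if self.intensity.shape != self.time.shape:
            raise ValueError("time and intensity must have the same length")
        if self.intensity.size < self.n_prebleach + 1:
            raise ValueError("trace must extend beyond the bleach scan")


@dataclass(frozen=True)
class NormalizedCurve:
    """Dimensionless FRAP curve; pre-bleach window mean is 1 by construction."""

    time: np.ndarray
    intensity: np.ndarray
    n_prebleach: int
    prebleach_window: int = 50


def normalize_curve(raw: RawCurve, prebleach_window: int = 50) -> NormalizedCurve:
    """Background-subtract and scale to the pre-bleach plateau.

    The normalizer is the mean of the ``prebleach_window`` scans
    immediately preceding the bleach (background-subtracted). The time
    axis is preserved.

    Raises
    ------
    DegenerateCurveError
        If the pre-bleach mean does not exceed the background.
    ValueError
        If the window exceeds the pre-bleach span.
    """
    if prebleach_window < 1 or prebleach_window > raw.n_prebleach:
        raise ValueError(
            f"prebleach_window must be in [1, {raw.n_prebleach}], got {prebleach_window}"
        )
    pre = raw.intensity[raw.n_prebleach - prebleach_window : raw.n_prebleach]
    scale = float(pre.mean()) - raw.background
    if scale <= 0:
        raise DegenerateCurveError(
            "pre-bleach mean does not exceed background; nothing to normalize"
        )
    intensity = (raw.intensity - raw.background) / scale
    return NormalizedCurve(
        time=raw.time.copy(),
        intensity=intensity,
        n_prebleach=raw.n_prebleach,
        prebleach_window=prebleach_window,
    )


def average_curves(curves: list[NormalizedCurve]) -> NormalizedCurve:
    """Average per-cell normalized curves sharing one time axis.

    Normalization must precede averaging because expression levels (and
    hence raw intensities) differ from cell to cell.
    """
    if not curves:
        raise ValueError("no curves to average")
    first = curves[0]
    for c in curves[1:]:
        if c.time.shape != first.time.shape or not np.allclose(
            c.time, first.time, rtol=0, atol=1e-9
        ):
            raise ValueError("curves have mismatched time axes")
        if c.n_prebleach != first.n_prebleach:
            raise ValueError("curves have mismatched bleach indices")
    mean = np.mean([c.intensity for c in curves], axis=0)
    return NormalizedCurve(
        time=first.time.copy(),
        intensity=mean,
        n_prebleach=first.n_prebleach,
        prebleach_window=first.prebleach_window,
    )


def read_raw_csv(path: str | Path, background: float | None = None,
                 n_prebleach: int = 100) -> RawCurve:
    """Read a raw trace CSV with columns ``time_s``, ``intensity``.

    An optional ``background`` column is averaged into the scalar
    background; an explicit ``background`` argument overrides it.
    """
    df = pd.read_csv(path)
    if background is None:
        background = float(df["background"].mean()) if "background" in df else 0.0
    return RawCurve(
        time=df["time_s"].to_numpy(float),
        intensity=df["intensity"].to_numpy(float),
        background=background,
        n_prebleach=n_prebleach,
    )


def write_curve_csv(path: str | Path, time: np.ndarray, intensity: np.ndarray,
                    column: str = "intensity_norm") -> None:
    pd.DataFrame({"time_s": time, column: intensity}).to_csv(path, index=False)


def read_curve_csv(path: str | Path, column: str = "intensity_norm",
                   n_prebleach: int = 100) -> NormalizedCurve:
    df = pd.read_csv(path)
    return NormalizedCurve(
        time=df["time_s"].to_numpy(float),
        intensity=df[column].to_numpy(float),
        n_prebleach=n_prebleach,
    )
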