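"""Core data containers for dynamic angiography.

The canonical intensity convention throughout the package is *contrast
concentration*: larger pixel values mean more iodinated contrast. X-ray
fluoroscopy natively renders contrast dark; the DICOM reader can invert
(see :func:`pulsewave.io.read_angiogram` with ``polarity="fluoro"``).

Coordinates are 0-based ``(row, col)`` with the origin at the top-left;
frame indices are 0-based and frames are assumed uniformly spaced at
``1 / frame_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["AngiogramSequence", "CardiacTrace", "Roi", "IntracranialMask"]

#: Upper edge (Hz) of the physiologic cardiac band; a cardiac trace must be
#: sampled faster than twice this to represent the band without aliasing.
CARDIAC_BAND_CEILING_HZ = 3.0


@dataclass
class AngiogramSequence:
    """A time-ordered stack of 2-D grayscale frames at a known frame rate.

    Parameters
    ----------
    frames
        Nonnegative intensities indexed ``(frame, row, col)``.
    frame_rate
        Acquisition rate in Hz. Cerebral runs are typically 6-7 Hz, which is
        faster than twice the human cardiac rate of 1-2 Hz.
    t0
        Timestamp of frame 0 in seconds.
    meta
        Free-form provenance mapping (source file, polarity applied, ...).
    """

    frames: np.ndarray
    frame_rate: float
    t0: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (frame, row, col), got ndim={self.frames.ndim}")
        if self.frames.shape[0] < 2:
            raise ValueError("an angiogram needs at least 2 frames")
        if self.frames.shape[1] < 1 or self.frames.shape[2] < 1:
            raise ValueError("frames must contain at least one pixel")
        if not (self.frame_rate > 0):
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite intensities")
        if self.frames.min() < 0:
            raise ValueError(
                "negative intensity: the canonical representation is contrast "
                "concentration (>= 0); use polarity='fluoro' to invert x-ray data"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (uniform grid)."""
        return self.t0 + np.arange(self.n_frames) / self.frame_rate

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.frame_rate


@dataclass
class CardiacTrace:
    """A sampled 1-D cardiac signal (pulse-oximeter plethysmogram)."""

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.samples.size < 2:
            raise ValueError("cardiac trace needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("cardiac trace contains non-finite samples")
        if not (self.sample_rate > 2.0 * CARDIAC_BAND_CEILING_HZ):
            raise ValueError(
                f"cardiac trace sample_rate {self.sample_rate} Hz must exceed "
                f"{2.0 * CARDIAC_BAND_CEILING_HZ} Hz (twice the cardiac band ceiling)"
            )

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.sample_rate

    def covers(self, t_start: float, t_end: float) -> bool:
        """Whether the trace's time span contains ``[t_start, t_end]``."""
        eps = 1e-9
        return self.t0 - eps <= t_start and t_end <= self.t0 + self.duration + eps


_ROI_LABELS = {"artery", "vein", "other"}


@dataclass
class Roi:
    """A small hand-placed region of interest in a named vessel.

    ``pixels`` is an ``(n, 2)`` integer array of ``(row, col)`` coordinates.
    """

    pixels: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.size == 0:
            raise ValueError("ROI must be nonempty")
        px = np.atleast_2d(px)
        if px.ndim != 2 or px.shape[1] != 2:
            raise ValueError("ROI pixels must be an (n, 2) array of (row, col)")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.allclose(px, np.round(px)):
                raise ValueError("ROI coordinates must be integers")
            px = np.round(px).astype(np.intp)
        # canonical order, duplicates dropped
        px = np.unique(px.astype(np.intp), axis=0)
        if px.min() < 0:
            raise ValueError("ROI coordinates must be nonnegative")
        self.pixels = px
        if self.label not in _ROI_LABELS:
            raise ValueError(f"ROI label must be one of {sorted(_ROI_LABELS)}, got {self.label!r}")

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]

    def check_bounds(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.pixels[:, 0].max() >= h or self.pixels[:, 1].max() >= w:
            raise ValueError(f"ROI coordinates exceed frame shape {shape}")

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize the ROI into a boolean image of the given shape."""
        self.check_bounds(shape)
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m

    def disjoint_from(self, other: "Roi") -> bool:
        a = {tuple(p) for p in self.pixels}
        b = {tuple(p) for p in other.pixels}
        return not (a & b)


@dataclass
class IntracranialMask:
    """Hand-drawn outer mask restricting analysis to intracranial pixels."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("intracranial mask must be 2-D")
        if not self.mask.any():
            raise ValueError("intracranial mask is empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def contains_roi(self, roi: Roi) -> bool:
        roi.check_bounds(self.shape)
        return bool(self.mask[roi.pixels[:, 0], roi.pixels[:, 1]].all())
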