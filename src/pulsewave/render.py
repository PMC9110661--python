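"""Brightness-hue rendering of complex frames and ROI scattergrams.

A complex pixel is rendered with magnitude as brightness and phase as hue,
phase 0 at the positive horizontal direction (red) rotating counterclockwise
around the HSV hue wheel. Rendering is a pure view layer: it never alters
the numeric artifacts it draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .coherence import _check_frame
from .containers import Roi
from .wavelet import WaveletAngiogram

__all__ = ["RenderSpec", "complex_to_rgb", "scattergram"]


@dataclass
class RenderSpec:
    """Display mapping for complex frames."""

    magnitude_percentile_clip: float = 99.0  # brightness clip percentile
    gamma: float = 1.0  # display exponent on normalized magnitude

    def __post_init__(self) -> None:
        if not (50.0 < self.magnitude_percentile_clip <= 100.0):
            raise ValueError("magnitude_percentile_clip must be in (50, 100]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def complex_to_rgb(frame: np.ndarray, spec: RenderSpec | None = None) -> np.ndarray:
    """Map a complex 2-D array to an 8-bit RGB image.

    Hue encodes arg(z) (0 rad = red, counterclockwise); brightness encodes
    |z| clipped at the configured percentile then gamma-mapped. Zero
    magnitude renders black regardless of phase.
    """
    spec = spec or RenderSpec()
    z = np.asarray(frame, dtype=np.complex128)
    if z.ndim != 2:
        raise ValueError("frame must be 2-D")
    if not np.all(np.isfinite(z.view(np.float64))):
        raise ValueError("frame contains NaN or infinite values")
    mag = np.abs(z)
    hue = (np.angle(z) % (2.0 * np.pi)) / (2.0 * np.pi)
    vmax = np.percentile(mag, spec.magnitude_percentile_clip)
    val = np.zeros_like(mag) if vmax == 0 else np.clip(mag / vmax, 0.0, 1.0) ** spec.gamma
    hsv = np.stack([hue, np.ones_like(hue), val], axis=-1)
    rgb = hsv_to_rgb(hsv)
    return np.round(rgb * 255.0).astype(np.uint8)


def scattergram(
    wav: WaveletAngiogram,
    rois: list[Roi] | tuple[Roi, ...],
    frame: int,
    *,
    make_figure: bool = False,
):
    """Per-ROI complex samples at one frame, optionally with a polar plot.

    Returns ``(samples, fig)`` where ``samples`` maps each ROI label to its
    complex coefficient array — the numeric surface downstream statistics
    use — and ``fig`` is a matplotlib polar scatter (or None).
    """
    _check_frame(wav, frame)
    samples: dict[str, np.ndarray] = {}
    for roi in rois:
        if roi.n_pixels == 0:
            raise ValueError("empty ROI")
        roi.check_bounds(wav.frame_shape)
        samples[roi.label] = wav.coeffs[frame, roi.pixels[:, 0], roi.pixels[:, 1]]
    fig = None
    if make_figure:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
        for label, z in samples.items():
            ax.scatter(np.angle(z), np.abs(z), s=12, alpha=0.7, label=label)
        ax.legend(loc="upper right")
        ax.set_title(f"wavelet scattergram, frame {frame}")
    return samples, fig
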