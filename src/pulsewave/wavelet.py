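"""Gabor (analytic Morlet) continuous-wavelet machinery.

The pulse-wave angiogram is produced in three steps:

1. :func:`gabor_cwt` transforms a 1-D signal against a grid of scales with the
   analytic Gabor mother wavelet

   .. math::

      \\psi_a(u) = \\pi^{-1/4} a^{-1/2}
                   \\exp(i\\,\\omega_0 u / a)\\, \\exp(-u^2 / (2 a^2)),

   so the coefficient at scale :math:`a` and time :math:`t` is the
   correlation of the zero-mean signal with :math:`\\psi_a^*` centred at
   :math:`t` (equivalently, convolution with the Hermitian kernel). The
   equivalent analysis frequency of a scale is
   :math:`f = \\omega_0 / (2\\pi a)`.
2. :func:`cardiac_reference` applies the transform to the external cardiac
   trace at high frequency resolution (larger :math:`\\omega_0`), selects the
   dominant cardiac scale within the physiologic band and keeps the
   unit-magnitude coefficient phasor as the cardiac reference.
3. :func:`crosscorrelate` transforms every pixel's time signal at the selected
   cardiac frequency and multiplies by the conjugate reference phasor; with a
   single retained scale this demodulated product *is* the time-domain complex
   envelope, so the result holds each pixel's cardiac-band magnitude and its
   phase relative to the cardiac reference.

Frames within the cone of influence (closer than :math:`a\\sqrt{2}` seconds to
either end of the record) are flagged invalid and zeroed; reflect padding is
used for the convolution itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import fft as sp_fft

__all__ = [
    "GaborParams",
    "CardiacReference",
    "WaveletAngiogram",
    "gabor_cwt",
    "cardiac_reference",
    "crosscorrelate",
]

COI_FACTOR = np.sqrt(2.0)
#: kernel support half-width in units of the scale (Gaussian sigma = a)
KERNEL_SUPPORT_SIGMAS = 4.0


@dataclass
class GaborParams:
    """Tunable parameters of the Gabor analysis.

    omega0
        Dimensionless centre frequency of the mother wavelet used on image
        pixel signals. Must be >= 5 for the analytic approximation to be
        admissible (negligible negative-frequency leakage).
    omega0_trace
        Centre frequency used on the external cardiac trace; at least twice
        ``omega0`` so the trace is filtered at comparatively high frequency
        resolution.
    band
        Physiologic cardiac frequency interval in Hz searched for the
        dominant scale. The human cardiac rate is ~1-2 Hz.
    n_scales
        Number of logarithmically spaced scales spanning ``band``.
    scales
        Optional explicit scale grid (seconds, strictly increasing) that
        overrides the derived grid.
    mag_floor
        Fraction of the median coefficient magnitude below which reference
        frames are marked invalid.
    band_width
        Half-width (in scale-grid steps) of an optional magnitude-weighted
        scale-neighbourhood average in :func:`crosscorrelate`; 0 keeps the
        single selected scale.
    """

    omega0: float = 6.0
    omega0_trace: float = 12.0
    band: tuple[float, float] = (0.5, 3.0)
    n_scales: int = 32
    scales: np.ndarray | None = None
    mag_floor: float = 0.1
    band_width: int = 0

    def __post_init__(self) -> None:
        if self.omega0 < 5:
            raise ValueError(f"omega0 must be >= 5 for admissibility, got {self.omega0}")
        if self.omega0_trace < 2 * self.omega0:
            raise ValueError("omega0_trace must be >= 2 * omega0 (high frequency resolution)")
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError(f"band must satisfy 0 < lo < hi, got {self.band}")
        if self.n_scales < 2:
            raise ValueError("need at least 2 scales")
        if self.scales is not None:
            s = np.asarray(self.scales, dtype=np.float64)
            if s.ndim != 1 or s.size < 1 or np.any(np.diff(s) <= 0) or s[0] <= 0:
                raise ValueError("scales must be a strictly increasing positive 1-D array")
            self.scales = s

    def scale_grid(self, omega0: float, rate: float | None = None) -> np.ndarray:
        """Strictly increasing scale grid (seconds) covering ``band``.

        When ``rate`` is given the grid is restricted to frequencies strictly
        below the Nyquist frequency of that sampling rate.
        """
        if self.scales is not None:
            return self.scales
        lo, hi = self.band
        if rate is not None:
            hi = min(hi, 0.5 * rate * (1.0 - 1e-9))
            if hi <= lo:
                raise ValueError(
                    f"no cardiac scale inside the band: band floor {lo} Hz is not below "
                    f"the Nyquist frequency {rate / 2.0} Hz of a {rate} Hz acquisition"
                )
        freqs = np.geomspace(lo, hi, self.n_scales)
        return omega0 / (2.0 * np.pi * freqs[::-1])


@dataclass
class CardiacReference:
    """Unit-magnitude cardiac phasor extracted from the external trace."""

    phasor: np.ndarray  # complex, |phasor| in {0, 1}
    scale_star: float  # selected trace-domain scale, seconds
    freq_star: float  # implied cardiac frequency, Hz
    valid: np.ndarray  # per-frame validity
    omega0_trace: float = 12.0

    def __post_init__(self) -> None:
        self.phasor = np.asarray(self.phasor, dtype=np.complex128)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.phasor.shape != self.valid.shape:
            raise ValueError("phasor and valid must have the same length")


@dataclass
class WaveletAngiogram:
    """Complex cardiac-frequency field: one phasor per pixel per frame.

    Magnitude is cardiac-band magnitude; phase is measured *relative to* the
    cardiac reference. Invalid frames (reference dropout or cone of
    influence) hold exact zeros.
    """

    coeffs: np.ndarray  # complex (frame, row, col)
    scale_star: float  # image-domain scale, seconds
    freq_star: float
    frame_rate: float
    valid: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.complex128)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.coeffs.ndim != 3:
            raise ValueError("coeffs must be (frame, row, col)")
        if self.valid.shape != (self.coeffs.shape[0],):
            raise ValueError("valid must be a per-frame vector")
        if not np.all(np.isfinite(self.coeffs.view(np.float64))):
            raise ValueError("coeffs contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coeffs.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.coeffs.shape[1:]


# ---------------------------------------------------------------------------

def _gabor_kernel(a: float, rate: float, omega0: float) -> tuple[np.ndarray, int]:
    """Sampled Hermitian Gabor kernel at scale ``a`` and its half-length."""
    dt = 1.0 / rate
    half = int(np.ceil(KERNEL_SUPPORT_SIGMAS * a * rate))
    u = np.arange(-half, half + 1) * dt
    x = u / a
    psi = (np.pi ** -0.25) * (a ** -0.5) * np.exp(1j * omega0 * x - 0.5 * x * x) * dt
    return psi, half


def _convolve_same(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """FFT convolution along axis 0, 'same' output length (odd kernels)."""
    n = x.shape[0] + kernel.shape[0] - 1
    nfast = sp_fft.next_fast_len(n)
    K = sp_fft.fft(kernel, nfast)
    X = sp_fft.fft(x, nfast, axis=0)
    full = sp_fft.ifft(X * (K.reshape((-1,) + (1,) * (x.ndim - 1))), axis=0)
    half = (kernel.shape[0] - 1) // 2
    return full[half : half + x.shape[0]]


def coi_valid(n_frames: int, rate: float, scale: float) -> np.ndarray:
    """Frames farther than ``scale * sqrt(2)`` seconds from either record edge."""
    idx = np.arange(n_frames)
    edge_dist = np.minimum(idx, n_frames - 1 - idx) / rate
    return edge_dist >= COI_FACTOR * scale


def gabor_cwt(
    signal: np.ndarray,
    rate: float,
    params: GaborParams | None = None,
    *,
    omega0: float | None = None,
    scales: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous Gabor wavelet transform of a 1-D signal.

    Returns ``(W, valid)`` where ``W`` is the complex coefficient array of
    shape ``(n_scales, T)`` and ``valid`` the boolean cone-of-influence mask
    (True = outside the cone). The temporal mean of the signal is removed
    before transformation and the convolution uses reflect padding.
    """
    params = params or GaborParams()
    s = np.asarray(signal, dtype=np.float64).ravel()
    if np.any(np.isnan(s)):
        raise ValueError("signal contains NaN")
    T = s.size
    if T < 8:
        raise ValueError(f"signal too short for wavelet analysis: {T} < 8 samples")
    if not (rate > 0):
        raise ValueError("rate must be positive")
    w0 = params.omega0 if omega0 is None else omega0
    grid = params.scale_grid(w0) if scales is None else np.asarray(scales, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("empty scale grid")

    s = s - s.mean()
    W = np.empty((grid.size, T), dtype=np.complex128)
    valid = np.empty((grid.size, T), dtype=bool)
    for i, a in enumerate(grid):
        psi, half = _gabor_kernel(a, rate, w0)
        if half >= T:
            raise ValueError(
                f"signal of {T} samples is shorter than the wavelet support at scale {a:.3g} s"
            )
        padded = np.pad(s, half, mode="reflect")
        W[i] = _convolve_same(padded, psi)[half : half + T]
        valid[i] = coi_valid(T, rate, a)
    return W, valid


def cardiac_reference(
    trace_at_frames: np.ndarray,
    frame_rate: float,
    params: GaborParams | None = None,
) -> CardiacReference:
    """Extract the cardiac reference phasor from the frame-aligned trace.

    The dominant cardiac scale maximizes the time-mean squared coefficient
    magnitude (over frames outside the cone of influence) across the scale
    grid within the physiologic band; the reference is the unit-normalized
    coefficient row at that scale. Frames inside the cone, or whose magnitude
    falls below ``mag_floor`` times the median, are marked invalid and carry a
    zero phasor.
    """
    params = params or GaborParams()
    grid = params.scale_grid(params.omega0_trace, rate=frame_rate)
    W, coi = gabor_cwt(trace_at_frames, frame_rate, params, omega0=params.omega0_trace, scales=grid)

    power = np.full(grid.size, -np.inf)
    for i in range(grid.size):
        if coi[i].any():
            power[i] = np.mean(np.abs(W[i, coi[i]]) ** 2)
    if not np.isfinite(power).any():
        raise ValueError("no scale has any frame outside the cone of influence")
    i_star = int(np.argmax(power))
    a_star = float(grid[i_star])
    f_star = params.omega0_trace / (2.0 * np.pi * a_star)
    if not (params.band[0] - 1e-9 <= f_star <= params.band[1] + 1e-9):
        raise ValueError(f"selected cardiac frequency {f_star:.3f} Hz falls outside the band")

    row = W[i_star]
    mag = np.abs(row)
    med = np.median(mag[coi[i_star]])
    valid = coi[i_star] & (mag >= params.mag_floor * med) & (mag > 0)
    if not valid.any():
        raise ValueError("cardiac trace yields no valid frames (all below magnitude floor)")
    phasor = np.zeros_like(row)
    phasor[valid] = row[valid] / mag[valid]
    return CardiacReference(
        phasor=phasor, scale_star=a_star, freq_star=f_star, valid=valid,
        omega0_trace=params.omega0_trace,
    )


def crosscorrelate(
    angio,
    ref: CardiacReference,
    params: GaborParams | None = None,
) -> WaveletAngiogram:
    """Cross-correlate every pixel time signal against the cardiac reference.

    Each pixel is Gabor-transformed at the image-domain cardiac scale
    ``omega0 / (2 pi freq_star)`` (optionally a magnitude-weighted average
    over ``band_width`` neighbouring grid scales) and multiplied by the
    conjugate reference phasor. Frames invalid in the reference or inside the
    image-scale cone of influence are zeroed and excluded via ``valid``.
    """
    params = params or GaborParams()
    frames = angio.frames
    T, H, Wd = frames.shape
    if ref.phasor.shape[0] != T:
        raise ValueError(
            f"cardiac reference length {ref.phasor.shape[0]} does not match frame count {T}"
        )
    rate = angio.frame_rate
    a_img = params.omega0 / (2.0 * np.pi * ref.freq_star)

    if params.band_width > 0:
        step = (params.band[1] / params.band[0]) ** (1.0 / (params.n_scales - 1))
        scales = [a_img * step**j for j in range(-params.band_width, params.band_width + 1)]
    else:
        scales = [a_img]

    X = frames.reshape(T, -1).astype(np.float64)
    X = X - X.mean(axis=0)

    acc = np.zeros((T, X.shape[1]), dtype=np.complex128)
    wsum = 0.0
    valid_img = np.ones(T, dtype=bool)
    for a in scales:
        psi, half = _gabor_kernel(a, rate, params.omega0)
        if half >= T:
            raise ValueError("angiogram too short for the cardiac-scale wavelet support")
        Xp = np.pad(X, ((half, half), (0, 0)), mode="reflect")
        Wa = _convolve_same(Xp, psi)[half : half + T]
        weight = 1.0 if len(scales) == 1 else float(np.mean(np.abs(Wa)))
        acc += weight * Wa
        wsum += weight
        valid_img &= coi_valid(T, rate, a)
    acc /= wsum

    valid = ref.valid & valid_img
    coeffs = acc * np.conj(ref.phasor)[:, None]
    coeffs[~valid] = 0
    return WaveletAngiogram(
        coeffs=coeffs.reshape(T, H, Wd),
        scale_star=a_img,
        freq_star=ref.freq_star,
        frame_rate=rate,
        valid=valid,
        meta={"omega0": params.omega0, "n_scales_averaged": len(scales)},
    )
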