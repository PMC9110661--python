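"""Coherence classification and arterial/parenchymal/venous mask construction.

Two complex pixel values are *relatively coherent* when their phases lie
within +/- pi/2 of each other, i.e. when the real part of one times the
conjugate of the other is positive; otherwise they are *reciprocally
coherent* (nominally ~180 deg apart). A single seed ROI's mean phasor at one
analysis frame therefore splits the image into a coherent and a reciprocal
half; Otsu binarization of the signed coherent projection keeps the pixels
whose cardiac activity is both strong and on-phase, yielding a spatial
coherence mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import IntracranialMask, Roi
from .wavelet import WaveletAngiogram

__all__ = [
    "CoherenceMap",
    "CoherenceMasks",
    "roi_mean",
    "is_coherent",
    "select_analysis_frame",
    "otsu_threshold",
    "build_masks",
    "mask_stability",
]


@dataclass
class CoherenceMap:
    """Signed projection Re(z * conj(ref_unit)) of every pixel at one frame."""

    signed_projection: np.ndarray  # (H, W) real
    ref_phase: float  # radians
    frame_index: int


@dataclass
class CoherenceMasks:
    """Arterial/venous/parenchymal segmentation from two seed ROIs.

    The three masks are pairwise disjoint subsets of the intracranial mask;
    the parenchymal mask is the intracranial remainder. Seed ROI pixels are
    excluded from all three masks so the segmentation never certifies the
    pixels it was conditioned on.
    """

    arterial: np.ndarray
    venous: np.ndarray
    parenchymal: np.ndarray
    intracranial: np.ndarray
    seed_arterial: Roi
    seed_venous: Roi
    frame_index: int
    thresholds: dict | None = None
    ref_phases: dict | None = None

    def __post_init__(self) -> None:
        for name in ("arterial", "venous", "parenchymal", "intracranial"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if np.logical_and(self.arterial, self.venous).any():
            raise ValueError("arterial and venous masks overlap")
        for name in ("arterial", "venous", "parenchymal"):
            m = getattr(self, name)
            if np.logical_and(m, ~self.intracranial).any():
                raise ValueError(f"{name} mask leaves the intracranial mask")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"arterial": self.arterial, "parenchymal": self.parenchymal, "venous": self.venous}


def _check_frame(wav: WaveletAngiogram, frame: int) -> None:
    if not (0 <= frame < wav.n_frames):
        raise ValueError(f"frame {frame} out of range [0, {wav.n_frames})")
    if not wav.valid[frame]:
        raise ValueError(
            f"frame {frame} is flagged invalid (cone of influence or reference dropout)"
        )


def roi_mean(wav: WaveletAngiogram, roi: Roi, frame: int) -> complex:
    """Arithmetic mean of the complex coefficients over the ROI at one frame."""
    _check_frame(wav, frame)
    roi.check_bounds(wav.frame_shape)
    vals = wav.coeffs[frame, roi.pixels[:, 0], roi.pixels[:, 1]]
    return complex(vals.mean())


def is_coherent(z: complex, ref: complex) -> bool:
    """True when ``z`` is relatively coherent to ``ref`` (within +/- pi/2).

    Computed as Re(z * conj(ref)) > 0; a projection of exactly zero —
    including z = 0 — is classified reciprocal by convention (strict
    inequality), which makes the boundary deterministic.
    """
    if ref == 0:
        raise ValueError("reference phasor must be nonzero")
    return (z * np.conj(ref)).real > 0


def select_analysis_frame(
    raw,
    wav: WaveletAngiogram,
    arterial_roi: Roi,
    venous_roi: Roi,
) -> int:
    """Pick the analysis frame between the arterial and venous bolus peaks.

    The window is the open interval between the raw time-signal peak of the
    arterial ROI and that of the venous ROI; within it the valid frame
    maximizing the real component of the arterial ROI mean of the wavelet
    angiogram is returned (earliest on ties).
    """
    curves = {}
    for name, roi in (("arterial", arterial_roi), ("venous", venous_roi)):
        roi.check_bounds(raw.frames.shape[1:])
        curves[name] = raw.frames[:, roi.pixels[:, 0], roi.pixels[:, 1]].mean(axis=1)
    p_art = int(np.argmax(curves["arterial"]))
    p_ven = int(np.argmax(curves["venous"]))
    if p_ven <= p_art:
        raise ValueError(
            "ROIs not artery/vein-ordered: arterial raw peak at frame "
            f"{p_art} does not precede venous raw peak at frame {p_ven}"
        )
    window = np.arange(p_art + 1, p_ven)
    window = window[wav.valid[window]]
    if window.size == 0:
        raise ValueError(
            f"no valid frame strictly between the arterial ({p_art}) and venous "
            f"({p_ven}) peaks"
        )
    re_art = np.array([roi_mean(wav, arterial_roi, int(f)).real for f in window])
    return int(window[int(np.argmax(re_art))])  # argmax -> earliest on ties


def otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Otsu's threshold: the histogram bin edge maximizing between-class variance.

    Values strictly below the returned threshold form the lower class. Ties
    are broken toward the lower threshold. Raises if all values are identical
    (no second class exists).
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2:
        raise ValueError("need at least two values")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if v.max() == v.min():
        raise ValueError("all values identical; Otsu threshold undefined")
    hist, edges = np.histogram(v, bins=int(bins))
    w = hist.astype(np.float64) / v.size
    centers = 0.5 * (edges[:-1] + edges[1:])
    cum_w = np.cumsum(w)
    cum_mu = np.cumsum(w * centers)
    mu_total = cum_mu[-1]

    # candidate thresholds are the interior edges edges[1..bins-1]
    w0 = cum_w[:-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_total * w0 - cum_mu[:-1]) ** 2 / (w0 * w1)
    between[(w0 <= 0) | (w1 <= 0)] = -np.inf
    # lowest edge within a relative 1e-12 of the maximum: makes the
    # tie-toward-lower rule deterministic under floating-point plateaus
    top = between.max()
    best = int(np.argmax(between >= top - 1e-12 * abs(top)))
    return float(edges[best + 1])


def _roi_union_mask(shape: tuple[int, int], *rois: Roi) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    for roi in rois:
        m |= roi.to_mask(shape)
    return m


def build_masks(
    wav: WaveletAngiogram,
    arterial_roi: Roi,
    venous_roi: Roi,
    intracranial: IntracranialMask,
    frame: int,
    *,
    bins: int = 256,
    min_component: int = 1,
) -> CoherenceMasks:
    """Build arterial, venous, and parenchymal coherence masks at one frame.

    For each seed ROI the signed projection of every pixel onto the ROI's
    unit mean phasor is computed; Otsu's method over the coherent
    (positive-projection) intracranial pixels gives the binarization
    threshold, and suprathreshold coherent pixels inside the intracranial
    mask — excluding both seed ROIs — form the vessel mask. A pixel
    qualifying for both vessel masks (possible because the two references
    are not exactly antipodal) is assigned to the larger signed projection.
    ``min_component`` > 1 removes 8-connected components smaller than that
    many pixels, suppressing isolated coherent pixels without coherent
    neighbours.
    """
    _check_frame(wav, frame)
    shape = wav.frame_shape
    if intracranial.shape != shape:
        raise ValueError("intracranial mask shape does not match the angiogram")
    if not arterial_roi.disjoint_from(venous_roi):
        raise ValueError("arterial and venous seed ROIs overlap")
    for roi in (arterial_roi, venous_roi):
        if not intracranial.contains_roi(roi):
            raise ValueError(f"seed ROI {roi.label!r} is not inside the intracranial mask")

    z = wav.coeffs[frame]
    seeds = _roi_union_mask(shape, arterial_roi, venous_roi)
    proj: dict[str, np.ndarray] = {}
    supra: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    ref_phases: dict[str, float] = {}
    for name, roi in (("arterial", arterial_roi), ("venous", venous_roi)):
        ref = roi_mean(wav, roi, frame)
        if ref == 0:
            raise ValueError(f"{name} ROI mean is exactly zero at frame {frame}")
        ref_unit = ref / abs(ref)
        ref_phases[name] = float(np.angle(ref_unit))
        p = (z * np.conj(ref_unit)).real
        coherent = (p > 0) & intracranial.mask
        if coherent.sum() < 2:
            raise ValueError(
                f"almost no pixels coherent to the {name} ROI at frame {frame}; "
                "check the ROI placement or pick another valid frame"
            )
        thresholds[name] = otsu_threshold(p[coherent], bins=bins)
        proj[name] = p
        supra[name] = coherent & (p >= thresholds[name]) & ~seeds

    both = supra["arterial"] & supra["venous"]
    art = supra["arterial"] & ~(both & (proj["venous"] > proj["arterial"]))
    ven = supra["venous"] & ~(both & (proj["arterial"] >= proj["venous"]))

    if min_component > 1:
        structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
        for m in (art, ven):
            labels, n = ndimage.label(m, structure=structure)
            if n:
                sizes = np.bincount(labels.ravel())
                small = np.flatnonzero(sizes < min_component)
                m &= ~np.isin(labels, small[small > 0])

    for name, m in (("arterial", art), ("venous", ven)):
        if not m.any():
            raise ValueError(
                f"resulting {name} mask is empty: the seed ROI may be misplaced, the "
                f"frame ({frame}) poorly chosen, or the cardiac signal too weak"
            )
    par = intracranial.mask & ~art & ~ven & ~seeds
    return CoherenceMasks(
        arterial=art,
        venous=ven,
        parenchymal=par,
        intracranial=intracranial.mask,
        seed_arterial=arterial_roi,
        seed_venous=venous_roi,
        frame_index=int(frame),
        thresholds=thresholds,
        ref_phases=ref_phases,
    )


def mask_stability(
    wav: WaveletAngiogram,
    arterial_roi: Roi,
    venous_roi: Roi,
    intracranial: IntracranialMask,
    frames,
    reference_frame: int,
    **kwargs,
) -> dict[int, dict[str, float]]:
    """Jaccard overlap of masks recomputed at other frames vs a reference frame.

    The canonical segmentation is single-frame; this utility quantifies how
    little the masks depend on which valid frame is chosen.
    """
    from .stats import jaccard

    ref = build_masks(wav, arterial_roi, venous_roi, intracranial, reference_frame, **kwargs)
    out: dict[int, dict[str, float]] = {}
    for f in frames:
        f = int(f)
        if f == reference_frame or not wav.valid[f]:
            continue
        try:
            m = build_masks(wav, arterial_roi, venous_roi, intracranial, f, **kwargs)
        except ValueError:
            continue
        out[f] = {
            "arterial": jaccard(ref.arterial, m.arterial),
            "venous": jaccard(ref.venous, m.venous),
        }
    return out
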