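"""File readers/writers and trace/frame time alignment.

Supported formats
-----------------
* **Portable array container** (``.npz``): a single-file archive holding the
  frame cube, ``frame_rate``, ``t0`` and a JSON metadata string. This is the
  interchange format between pipeline stages and needs no DICOM machinery.
* **DICOM multiframe** (read-only) via :mod:`pydicom`; frame rate is taken
  from FrameTime / CineRate or a caller override.
* **CSV cardiac trace**: either two columns ``time_s,value`` or a single
  ``value`` column with a ``# sample_rate: <Hz>`` header comment.
* **PNG binary masks** (0/255) and **JSON ROI files**
  (``{"label": ..., "pixels": [[r, c], ...]}``).
"""

from __future__ import annotations

import json
import os
from typing import Any

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .containers import AngiogramSequence, CardiacTrace, IntracranialMask, Roi

__all__ = [
    "read_angiogram",
    "write_angiogram",
    "read_wavelet",
    "write_wavelet",
    "read_cardiac_trace",
    "write_cardiac_trace",
    "resample_trace_to_frames",
    "read_roi",
    "write_roi",
    "read_mask_png",
    "write_mask_png",
]

#: Tolerated per-frame DICOM frame-time jitter, as a fraction of the period.
MAX_FRAME_JITTER = 0.10


# ---------------------------------------------------------------------------
# portable container

def write_angiogram(angio: AngiogramSequence, path: str | os.PathLike) -> None:
    """Write an :class:`AngiogramSequence` to the portable ``.npz`` container."""
    np.savez(
        path,
        frames=angio.frames,
        frame_rate=np.float64(angio.frame_rate),
        t0=np.float64(angio.t0),
        meta=np.bytes_(json.dumps(angio.meta).encode()),
    )


def _read_container(path: str | os.PathLike) -> AngiogramSequence:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode()) if "meta" in z else {}
        return AngiogramSequence(
            frames=z["frames"],
            frame_rate=float(z["frame_rate"]),
            t0=float(z["t0"]) if "t0" in z else 0.0,
            meta=meta,
        )


def write_wavelet(wav, path: str | os.PathLike) -> None:
    """Write a wavelet angiogram: complex cube as two real cubes + metadata."""
    np.savez(
        path,
        real=wav.coeffs.real,
        imag=wav.coeffs.imag,
        scale_star=np.float64(wav.scale_star),
        freq_star=np.float64(wav.freq_star),
        frame_rate=np.float64(wav.frame_rate),
        valid=wav.valid,
        meta=np.bytes_(json.dumps(wav.meta).encode()),
    )


def read_wavelet(path: str | os.PathLike):
    from .wavelet import WaveletAngiogram

    if not os.path.exists(path):
        raise FileNotFoundError(f"wavelet container not found: {path}")
    with np.load(path) as z:
        return WaveletAngiogram(
            coeffs=z["real"] + 1j * z["imag"],
            scale_star=float(z["scale_star"]),
            freq_star=float(z["freq_star"]),
            frame_rate=float(z["frame_rate"]),
            valid=z["valid"],
            meta=json.loads(bytes(z["meta"]).decode()) if "meta" in z else {},
        )


# ---------------------------------------------------------------------------
# DICOM

def _dicom_frame_rate(ds) -> float | None:
    # FrameTime is in ms per frame; CineRate / RecommendedDisplayFrameRate in fps
    ft = getattr(ds, "FrameTime", None)
    if ft:
        return 1000.0 / float(ft)
    ftv = getattr(ds, "FrameTimeVector", None)
    if ftv is not None and len(ftv) > 1:
        deltas = np.asarray([float(x) for x in ftv[1:]])
        period = float(np.mean(deltas))
        if period <= 0:
            return None
        if np.max(np.abs(deltas - period)) > MAX_FRAME_JITTER * period:
            raise ValueError(
                "non-uniform DICOM frame times: jitter exceeds "
                f"{MAX_FRAME_JITTER:.0%} of the frame period; uniform sampling is required"
            )
        return 1000.0 / period
    for tag in ("CineRate", "RecommendedDisplayFrameRate"):
        v = getattr(ds, tag, None)
        if v:
            return float(v)
    return None


def read_angiogram(
    path: str | os.PathLike,
    format: str | None = None,
    *,
    frame_rate: float | None = None,
    polarity: str = "concentration",
) -> AngiogramSequence:
    """Read a dynamic angiogram from DICOM or the portable container.

    Parameters
    ----------
    path
        Input file. Format is inferred from the extension unless ``format``
        (``"dicom"`` or ``"container"``) is given.
    frame_rate
        Override when the file metadata lacks a frame rate.
    polarity
        ``"concentration"`` keeps values as-is (larger = more contrast);
        ``"fluoro"`` inverts x-ray brightness as ``max - value`` so that
        contrast becomes positive concentration.
    """
    if polarity not in ("concentration", "fluoro"):
        raise ValueError(f"polarity must be 'concentration' or 'fluoro', got {polarity!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(f"angiogram file not found: {path}")
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        format = "dicom" if ext in (".dcm", ".dicom") else "container"

    if format in ("container", "array-container", "npz"):
        angio = _read_container(path)
        frames = angio.frames
        rate = frame_rate if frame_rate is not None else angio.frame_rate
        t0, meta = angio.t0, angio.meta
    elif format == "dicom":
        import pydicom

        ds = pydicom.dcmread(path)
        frames = np.asarray(ds.pixel_array, dtype=np.float64)
        if frames.ndim == 2:
            raise ValueError("DICOM file holds a single frame; a multiframe series is required")
        if frames.ndim != 3:
            raise ValueError(f"unsupported DICOM pixel array ndim={frames.ndim}")
        rate = frame_rate if frame_rate is not None else _dicom_frame_rate(ds)
        if rate is None:
            raise ValueError(
                "DICOM metadata lacks a frame rate (FrameTime / FrameTimeVector / "
                "CineRate); pass frame_rate= explicitly"
            )
        t0, meta = 0.0, {"source": str(path), "sop_class": str(getattr(ds, "SOPClassUID", ""))}
    else:
        raise ValueError(f"unknown angiogram format {format!r}")

    if polarity == "fluoro":
        frames = frames.max() - frames
    meta = dict(meta)
    meta.setdefault("polarity", polarity)
    return AngiogramSequence(frames=frames, frame_rate=float(rate), t0=t0, meta=meta)


# ---------------------------------------------------------------------------
# cardiac trace CSV

def write_cardiac_trace(trace: CardiacTrace, path: str | os.PathLike) -> None:
    """Write a trace as two-column CSV with round-trip-exact float formatting."""
    times = trace.times
    with open(path, "w", newline="") as fh:
        fh.write(f"# sample_rate: {float(trace.sample_rate)!r}\n")
        fh.write(f"# t0: {float(trace.t0)!r}\n")
        fh.write("time_s,value\n")
        for t, v in zip(times, trace.samples):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def read_cardiac_trace(path: str | os.PathLike) -> CardiacTrace:
    """Read a cardiac trace CSV.

    Accepts ``time_s,value`` columns (sample rate inferred from the uniform,
    strictly increasing time column) or a lone ``value`` column accompanied by
    a ``# sample_rate: <Hz>`` header comment.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"cardiac trace file not found: {path}")
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line.lstrip("#").partition(":")
            try:
                header[key.strip()] = float(val)
            except ValueError:
                pass
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        try:
            df = pd.read_csv(fh, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            raise ValueError(f"cardiac trace file {path} holds no samples") from None
    if df.empty:
        raise ValueError(f"cardiac trace file {path} holds no samples")

    t0 = header.get("t0", 0.0)
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=np.float64)
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0))
            raise ValueError(
                f"trace time column must be strictly increasing; violation after row {bad}"
            )
        period = float(np.mean(dt))
        if np.max(np.abs(dt - period)) > 1e-6 * max(period, 1.0):
            raise ValueError("trace time column is not uniformly sampled")
        rate = header.get("sample_rate", 1.0 / period)
        t0 = header.get("t0", float(t[0]))
        values = df["value"].to_numpy(dtype=np.float64)
    elif "value" in df.columns:
        if "sample_rate" not in header:
            raise ValueError(
                "single-column trace CSV requires a '# sample_rate: <Hz>' header line"
            )
        rate = header["sample_rate"]
        values = df["value"].to_numpy(dtype=np.float64)
    else:
        raise ValueError("trace CSV must have columns (time_s, value) or (value)")
    return CardiacTrace(samples=values, sample_rate=float(rate), t0=float(t0))


def resample_trace_to_frames(trace: CardiacTrace, angio: AngiogramSequence) -> np.ndarray:
    """Linearly interpolate the cardiac trace at the angiogram frame times.

    The trace must cover the full angiographic time span; linear interpolation
    is exact for affine signals and adequate given the >= 10x oversampling of
    clinical plethysmograms relative to angiographic frame rates.
    """
    ft = angio.times
    if not trace.covers(ft[0], ft[-1]):
        raise ValueError(
            "cardiac trace does not cover the angiogram: trace spans "
            f"[{trace.t0:.3f}, {trace.t0 + trace.duration:.3f}] s but frames span "
            f"[{ft[0]:.3f}, {ft[-1]:.3f}] s"
        )
    return np.interp(ft, trace.times, trace.samples)


# ---------------------------------------------------------------------------
# ROI JSON and mask PNG

def write_roi(roi: Roi, path: str | os.PathLike) -> None:
    payload: dict[str, Any] = {"label": roi.label, "pixels": roi.pixels.tolist()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_roi(path: str | os.PathLike) -> Roi:
    if not os.path.exists(path):
        raise FileNotFoundError(f"ROI file not found: {path}")
    with open(path) as fh:
        payload = json.load(fh)
    return Roi(pixels=np.asarray(payload["pixels"], dtype=np.intp), label=payload["label"])


def write_mask_png(mask: np.ndarray | IntracranialMask, path: str | os.PathLike) -> None:
    m = mask.mask if isinstance(mask, IntracranialMask) else np.asarray(mask, dtype=bool)
    iio.imwrite(path, (m.astype(np.uint8) * 255))


def read_mask_png(path: str | os.PathLike) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(f"mask file not found: {path}")
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img > 127
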