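"""Synthetic angiogram generator with known ground truth.

The phantom emulates a contrast bolus traversing a cerebral vascular tree:
every vessel or parenchymal pixel carries a gamma-shaped time-intensity
envelope (shape ``k``, scale ``theta`` seconds, delay ``d`` seconds,
amplitude ``A``; the gamma density is normalized to unit peak before scaling
so ``A`` is directly the bolus peak regardless of shape) and an
envelope-gated multiplicative cardiac modulation

.. math::

   s(t) = \\mathrm{env}(t)\\,\\bigl(1 + (a_c/A)\\cos(\\Phi(t) + \\varphi)\\bigr)
          + \\mathcal{N}(0, \\sigma) + B,

where :math:`\\Phi(t)` is the shared cardiac phase integral (also emitted as
the synthetic pulse-oximeter trace :math:`\\cos\\Phi`), :math:`\\varphi` the
pixel's assigned cardiac phase, and :math:`B` a small pedestal that keeps
intensities nonnegative under the additive noise. Venous phases are centred
pi away from arterial ones — the arteriovenous reciprocity the analysis is
meant to recover — unless ``control_mix`` is set, in which case arterial and
venous cardiac parameters are drawn exchangeably and no arteriovenous
difference exists by construction.

Compartment defaults follow the physiology of a cerebral injection: the
bolus is several seconds wide — wider than the few-second arterial-to-venous
transit — so arterial, parenchymal, and venous envelopes overlap strongly
while their mean arrival times stay ordered (8.5, 11.5, 15.7 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import stats as sp_stats
from skimage.draw import disk as sk_disk

from .containers import AngiogramSequence, CardiacTrace, IntracranialMask, Roi
from .stats import circ_mean, circ_rmse, jaccard, resultant_length, wrap_angle
from .wavelet import WaveletAngiogram

__all__ = [
    "BolusParams",
    "CompartmentSpec",
    "PhantomLayout",
    "SimulationConfig",
    "SimulatedDataset",
    "GroundTruth",
    "RecoveryReport",
    "make_phantom_layout",
    "seed_rois",
    "sample_bolus_params",
    "render_synthetic_angiogram",
    "validate_recovery",
]

ROLES = ("arterial", "venous", "parenchymal")


@dataclass
class BolusParams:
    """Per-pixel bolus and cardiac modulation parameters (ground truth)."""

    k: float  # gamma shape, dimensionless
    theta: float  # gamma scale, seconds
    delay: float  # bolus onset delay, seconds
    amp: float  # bolus peak amplitude A, intensity units
    cardiac_amp: float  # cardiac modulation amplitude a_c at bolus peak
    phase: float  # assigned cardiac phase, radians in (-pi, pi]

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.theta > 0 and self.amp > 0):
            raise ValueError("gamma shape, scale and amplitude must be positive")
        if self.cardiac_amp < 0:
            raise ValueError("cardiac amplitude must be nonnegative")


@dataclass
class CompartmentSpec:
    """Normal/wrapped-normal parameter distributions for one compartment."""

    k: tuple[float, float]
    theta: tuple[float, float]
    delay: tuple[float, float]
    amp: tuple[float, float]
    cardiac_amp: tuple[float, float]
    phase: tuple[float, float]  # (center radians, wrapped-normal sd)

    def __post_init__(self) -> None:
        for name in ("k", "theta", "delay", "amp", "cardiac_amp", "phase"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} spread must be nonnegative, got sd={sd}")


def _default_compartments() -> dict[str, CompartmentSpec]:
    # Arterial: early, right-skewed, strongly pulsatile. Venous: broad, late
    # mean arrival, phase pi away. Parenchymal: intermediate timing, faint
    # bolus and near-absent pulsation (capillary blush).
    return {
        "arterial": CompartmentSpec(
            k=(2.0, 0.15), theta=(2.5, 0.25), delay=(3.5, 0.4),
            amp=(1.0, 0.10), cardiac_amp=(0.60, 0.06), phase=(0.0, 0.3),
        ),
        "venous": CompartmentSpec(
            k=(1.6, 0.10), theta=(7.0, 0.7), delay=(4.5, 0.5),
            amp=(0.85, 0.10), cardiac_amp=(0.50, 0.05), phase=(np.pi, 0.3),
        ),
        "parenchymal": CompartmentSpec(
            k=(2.0, 0.20), theta=(3.5, 0.35), delay=(4.5, 0.6),
            amp=(0.30, 0.05), cardiac_amp=(0.06, 0.02), phase=(np.pi / 2, 1.0),
        ),
    }


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic validation.

    Defaults mirror a 6 Hz cerebral acquisition of 256 frames with a 1.2 Hz
    cardiac rate and bolus signal-to-noise ``A / noise_sigma = 3``.
    """

    frame_rate: float = 6.0
    duration: float = 256 / 6.0  # seconds -> 256 frames
    cardiac_rate: float = 1.2
    beat_jitter: float = 0.0  # fractional sd of per-beat period
    noise_sigma: float = 1.0 / 3.0
    baseline: float = 2.0  # pedestal keeping intensities nonnegative
    trace_rate: float = 60.0
    seed: int = 0
    control_mix: bool = False
    compartments: dict[str, CompartmentSpec] = field(default_factory=_default_compartments)

    def __post_init__(self) -> None:
        if self.frame_rate <= 2.0 * self.cardiac_rate:
            raise ValueError(
                f"frame_rate {self.frame_rate} Hz must exceed twice the cardiac rate "
                f"{self.cardiac_rate} Hz (sampling theorem)"
            )
        if self.noise_sigma < 0 or self.beat_jitter < 0:
            raise ValueError("noise_sigma and beat_jitter must be nonnegative")
        missing = set(ROLES) - set(self.compartments)
        if missing:
            raise ValueError(f"missing compartment specs: {sorted(missing)}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class PhantomLayout:
    """Procedural vessel geometry: disjoint arterial and venous trees inside
    an elliptical intracranial mask, parenchyma as the remainder."""

    height: int
    width: int
    arterial_mask: np.ndarray
    venous_mask: np.ndarray
    parenchymal_mask: np.ndarray
    intracranial_mask: np.ndarray
    arterial_anchor: tuple[int, int]
    venous_anchor: tuple[int, int]
    seed: int

    def role_of(self) -> np.ndarray:
        """Integer role map: 0 background, 1 arterial, 2 venous, 3 parenchymal."""
        role = np.zeros((self.height, self.width), dtype=np.uint8)
        role[self.parenchymal_mask] = 3
        role[self.arterial_mask] = 1
        role[self.venous_mask] = 2
        return role


def _draw_tube(mask: np.ndarray, path: np.ndarray, radius: float) -> None:
    for r, c in path:
        rr, cc = sk_disk((r, c), radius, shape=mask.shape)
        mask[rr, cc] = True


def _vessel_tree(
    rng: np.random.Generator,
    shape: tuple[int, int],
    col_range: tuple[float, float],
    height: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk trunk with two side branches; returns (mask, trunk path)."""
    h, w = shape
    lo, hi = int(col_range[0] * w), int(col_range[1] * w)
    row = int(0.85 * h)
    col = int(rng.integers(lo + (hi - lo) // 3, hi - (hi - lo) // 3 + 1))
    trunk = []
    while row > int(0.15 * h):
        trunk.append((row, col))
        row -= 1
        col = int(np.clip(col + rng.integers(-1, 2), lo, hi - 1))
    trunk = np.asarray(trunk)
    mask = np.zeros(shape, dtype=bool)
    _draw_tube(mask, trunk, radius=2.6)
    n = len(trunk)
    for frac, drift in ((0.3, -1), (0.5, 1), (0.7, -1)):
        r, c = trunk[int(frac * n)]
        branch = []
        for _ in range(int(0.25 * h)):
            r -= 1
            c = int(np.clip(c + drift * int(rng.integers(0, 2)) + int(rng.integers(-1, 2)), lo, hi - 1))
            if r <= int(0.10 * h):
                break
            branch.append((r, c))
        if branch:
            _draw_tube(mask, np.asarray(branch), radius=1.6)
    return mask, trunk


def make_phantom_layout(height: int = 128, width: int = 128, seed: int = 0) -> PhantomLayout:
    """Deterministic procedural phantom: arterial tree left, venous tree right.

    The two trees occupy disjoint column bands, so arterial and venous masks
    can never overlap; both are clipped to the elliptical intracranial mask.
    """
    if height < 64 or width < 64:
        raise ValueError(f"phantom must be at least 64x64, got {height}x{width}")
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ry, rx = 0.46 * height, 0.46 * width
    intracranial = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0

    art, art_trunk = _vessel_tree(rng, (height, width), (0.12, 0.45), height)
    ven, ven_trunk = _vessel_tree(rng, (height, width), (0.55, 0.88), height)
    art &= intracranial
    ven &= intracranial
    min_px = 50
    if art.sum() < min_px or ven.sum() < min_px:
        raise ValueError("frame too small to place both vessel trees inside the ellipse")

    def _anchor(trunk: np.ndarray, mask: np.ndarray) -> tuple[int, int]:
        for frac in (0.5, 0.4, 0.6, 0.3, 0.7):
            r, c = trunk[int(frac * len(trunk))]
            if mask[r, c]:
                return int(r), int(c)
        ridx, cidx = np.nonzero(mask)
        return int(ridx[len(ridx) // 2]), int(cidx[len(cidx) // 2])

    par = intracranial & ~art & ~ven
    return PhantomLayout(
        height=height, width=width,
        arterial_mask=art, venous_mask=ven, parenchymal_mask=par,
        intracranial_mask=intracranial,
        arterial_anchor=_anchor(art_trunk, art),
        venous_anchor=_anchor(ven_trunk, ven),
        seed=seed,
    )


def seed_rois(layout: PhantomLayout, radius: int = 2) -> tuple[Roi, Roi]:
    """Small seed ROIs on the arterial and venous trunks (the phantom's
    stand-in for the clinician's hand-placed vessel ROIs)."""
    out = []
    for anchor, mask, label in (
        (layout.arterial_anchor, layout.arterial_mask, "artery"),
        (layout.venous_anchor, layout.venous_mask, "vein"),
    ):
        rr, cc = sk_disk(anchor, radius + 0.5, shape=mask.shape)
        keep = mask[rr, cc]
        out.append(Roi(pixels=np.column_stack([rr[keep], cc[keep]]), label=label))
    return out[0], out[1]


def _truncated_normal(rng, mean, sd, lower, size):
    draws = rng.normal(mean, sd, size)
    return np.clip(draws, lower, None)


def sample_bolus_params(
    role: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw bolus/cardiac parameters for pixels of one compartment.

    With ``size=None`` a single :class:`BolusParams` is returned; otherwise a
    dict of arrays of length ``size``. When ``config.control_mix`` is set the
    *cardiac* parameters (amplitude and phase) of arterial and venous pixels
    are drawn from a 50/50 mixture of the two compartments' distributions, so
    the two vessel populations are exchangeable in cardiac behaviour while
    bolus travel retains its compartment identity.
    """
    if role not in ROLES:
        raise ValueError(f"role must be one of {ROLES}, got {role!r}")
    spec = config.compartments[role]
    n = 1 if size is None else int(size)
    draws = {
        "k": _truncated_normal(rng, *spec.k, 1.1, n),
        "theta": _truncated_normal(rng, *spec.theta, 0.2, n),
        "delay": _truncated_normal(rng, *spec.delay, 0.0, n),
        "amp": _truncated_normal(rng, *spec.amp, 0.02, n),
    }

    if config.control_mix and role in ("arterial", "venous"):
        other = config.compartments["venous" if role == "arterial" else "arterial"]
        pick_other = rng.random(n) < 0.5
        card_specs = [(spec, ~pick_other), (other, pick_other)]
    else:
        card_specs = [(spec, np.ones(n, dtype=bool))]
    cardiac_amp = np.empty(n)
    phase = np.empty(n)
    for sp, sel in card_specs:
        m = int(sel.sum())
        if m == 0:
            continue
        cardiac_amp[sel] = _truncated_normal(rng, *sp.cardiac_amp, 0.0, m)
        phase[sel] = wrap_angle(sp.phase[0] + rng.normal(0.0, sp.phase[1], m))
    draws["cardiac_amp"] = cardiac_amp
    draws["phase"] = np.atleast_1d(phase)

    if size is None:
        return BolusParams(**{key: float(v[0]) for key, v in draws.items()})
    return draws


def _cardiac_phase_fn(config: SimulationConfig, rng: np.random.Generator) -> Callable:
    """Phase integral Phi(t) shared by the trace and all pixel modulations."""
    f = config.cardiac_rate
    if config.beat_jitter == 0:
        return lambda t: 2.0 * np.pi * f * np.asarray(t, dtype=np.float64)
    period = 1.0 / f
    n_beats = int(np.ceil(config.duration * f)) + 4
    periods = np.clip(rng.normal(period, config.beat_jitter * period, n_beats), 0.3 * period, None)
    beat_times = np.concatenate([[0.0], np.cumsum(periods)])
    beat_phase = 2.0 * np.pi * np.arange(beat_times.size)
    return lambda t: np.interp(np.asarray(t, dtype=np.float64), beat_times, beat_phase)


def _unit_peak_envelope(t: np.ndarray, k, theta, delay, amp) -> np.ndarray:
    """Gamma-variate envelopes, (T, n), each normalized to peak ``amp``."""
    x = t[:, None] - delay[None, :]
    env = sp_stats.gamma.pdf(x, k[None, :], scale=theta[None, :])
    peak = sp_stats.gamma.pdf((k - 1.0) * theta, k, scale=theta)  # k > 1 guaranteed
    return env * (amp / peak)[None, :]


@dataclass
class GroundTruth:
    """Assigned per-pixel parameters and the generating layout/config."""

    layout: PhantomLayout
    config: SimulationConfig
    param_maps: dict[str, np.ndarray]  # each (H, W), NaN outside tissue

    @property
    def phase_map(self) -> np.ndarray:
        return self.param_maps["phase"]


@dataclass
class SimulatedDataset:
    angio: AngiogramSequence
    trace: CardiacTrace
    truth: GroundTruth


def render_synthetic_angiogram(
    layout: PhantomLayout,
    config: SimulationConfig | None = None,
) -> SimulatedDataset:
    """Render the sequential frames of a simulated angiogram plus its trace.

    Deterministic given ``config.seed``. Background pixels hold baseline +
    noise only; tissue pixels add their gamma envelope with envelope-gated
    cardiac modulation. The emitted pulse trace is the cosine of the same
    cardiac phase integral that drives every pixel.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    T = config.n_frames
    t = np.arange(T) / config.frame_rate
    phi = _cardiac_phase_fn(config, rng)
    phi_frames = phi(t)

    H, W = layout.height, layout.width
    frames = rng.normal(0.0, config.noise_sigma, (T, H, W)) + config.baseline

    names = ("k", "theta", "delay", "amp", "cardiac_amp", "phase")
    param_maps = {name: np.full((H, W), np.nan) for name in names}
    role_masks = {
        "arterial": layout.arterial_mask,
        "venous": layout.venous_mask,
        "parenchymal": layout.parenchymal_mask,
    }
    for role, mask in role_masks.items():
        ridx, cidx = np.nonzero(mask)
        n = ridx.size
        if n == 0:
            continue
        draws = sample_bolus_params(role, config, rng, size=n)
        env = _unit_peak_envelope(t, draws["k"], draws["theta"], draws["delay"], draws["amp"])
        mod = 1.0 + (draws["cardiac_amp"] / draws["amp"])[None, :] * np.cos(
            phi_frames[:, None] + draws["phase"][None, :]
        )
        frames[:, ridx, cidx] += env * mod
        for name in names:
            param_maps[name][ridx, cidx] = draws[name]

    np.clip(frames, 0.0, None, out=frames)
    angio = AngiogramSequence(
        frames=frames,
        frame_rate=config.frame_rate,
        meta={"simulated": True, "seed": config.seed, "control_mix": config.control_mix},
    )

    margin = 1.0
    tt = np.arange(0.0, t[-1] + margin, 1.0 / config.trace_rate)
    trace = CardiacTrace(samples=np.cos(phi(tt)), sample_rate=config.trace_rate, t0=0.0)
    truth = GroundTruth(layout=layout, config=config, param_maps=param_maps)
    return SimulatedDataset(angio=angio, trace=trace, truth=truth)


# ---------------------------------------------------------------------------
# recovery metrics

@dataclass
class RecoveryReport:
    """Assigned-vs-recovered comparison on a simulated angiogram."""

    phase_circ_corr: float
    phase_circ_rmse: float
    magnitude_pearson_r: float
    phase_separation: float  # |circular mean arterial - venous| of recovered phases
    separation_resultant: float  # concentration of pooled arteriovenous phase contrasts
    separation_significant: bool
    jaccard_arterial: float | None = None
    jaccard_venous: float | None = None
    jaccard_chance_arterial: float | None = None
    jaccard_chance_venous: float | None = None
    jaccard_cross_arterial: float | None = None  # arterial mask vs venous truth
    jaccard_cross_venous: float | None = None  # venous mask vs arterial truth
    #: mean own-compartment minus cross-compartment Jaccard; ~0 when the masks
    #: carry no arterial-vs-venous identity (the control expectation)
    mask_discrimination: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _recovered_phase_map(wav: WaveletAngiogram) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-weighted per-pixel phase over valid frames, plus a mask of
    pixels with any signal."""
    acc = wav.coeffs.sum(axis=0)  # invalid frames are exact zeros
    has_signal = np.abs(acc) > 0
    phase = np.full(acc.shape, np.nan)
    phase[has_signal] = np.angle(acc[has_signal])
    return phase, has_signal


def _chance_jaccard(mask: np.ndarray, truth: np.ndarray, universe: np.ndarray) -> float:
    """Expected Jaccard if the mask were placed at random inside ``universe``."""
    n = float(universe.sum())
    m, tsize = float(mask.sum()), float(truth.sum())
    inter = m * tsize / n
    return inter / (m + tsize - inter)


def validate_recovery(truth: GroundTruth, wav: WaveletAngiogram, masks=None) -> RecoveryReport:
    """Compare recovered cardiac-frequency parameters with the assigned ones.

    Phase agreement is summarized by the Fisher-Lee circular correlation and
    circular RMSE over vessel pixels; magnitude agreement by the Pearson
    correlation between the time-mean coefficient magnitude and the assigned
    cardiac amplitude. The arteriovenous separation statistics quantify
    whether the two vessel populations are reciprocal: each arterial pixel
    phase is contrasted against the venous circular mean and vice versa, and
    the mean resultant length of the pooled contrasts measures how
    concentrated that separation is (low values = no organized arteriovenous
    difference, the expected control outcome).
    """
    layout = truth.layout
    vessels = layout.arterial_mask | layout.venous_mask
    if not vessels.any():
        raise ValueError("phantom has no vessel pixels")
    if wav.frame_shape != (layout.height, layout.width):
        raise ValueError("wavelet angiogram shape does not match the phantom")

    rec_phase, has_signal = _recovered_phase_map(wav)
    use = vessels & has_signal
    if use.sum() < 2:
        raise ValueError("no vessel pixels carry recovered signal")
    assigned = truth.phase_map[use]
    recovered = rec_phase[use]
    corr = _safe_circ_corr(assigned, recovered)
    rmse = circ_rmse(assigned, recovered)

    mean_mag = np.abs(wav.coeffs).mean(axis=0)
    mag_r = float(np.corrcoef(truth.param_maps["cardiac_amp"][use], mean_mag[use])[0, 1])

    art_use = layout.arterial_mask & has_signal
    ven_use = layout.venous_mask & has_signal
    mu_a = circ_mean(rec_phase[art_use])
    mu_v = circ_mean(rec_phase[ven_use])
    separation = abs(wrap_angle(mu_a - mu_v))
    contrasts = np.concatenate([
        wrap_angle(rec_phase[art_use] - mu_v),
        wrap_angle(mu_a - rec_phase[ven_use]),
    ])
    sep_resultant = resultant_length(contrasts)

    report = RecoveryReport(
        phase_circ_corr=corr,
        phase_circ_rmse=rmse,
        magnitude_pearson_r=mag_r,
        phase_separation=separation,
        separation_resultant=sep_resultant,
        separation_significant=sep_resultant >= 0.5,
    )
    if masks is not None:
        md = masks.as_dict() if hasattr(masks, "as_dict") else masks
        universe = layout.intracranial_mask
        report.jaccard_arterial = jaccard(md["arterial"], layout.arterial_mask)
        report.jaccard_venous = jaccard(md["venous"], layout.venous_mask)
        report.jaccard_chance_arterial = _chance_jaccard(
            md["arterial"], layout.arterial_mask, universe
        )
        report.jaccard_chance_venous = _chance_jaccard(md["venous"], layout.venous_mask, universe)
        report.jaccard_cross_arterial = jaccard(md["arterial"], layout.venous_mask)
        report.jaccard_cross_venous = jaccard(md["venous"], layout.arterial_mask)
        report.mask_discrimination = 0.5 * (
            (report.jaccard_arterial - report.jaccard_cross_arterial)
            + (report.jaccard_venous - report.jaccard_cross_venous)
        )
    return report


def _safe_circ_corr(a: np.ndarray, b: np.ndarray) -> float:
    from .stats import circ_corr

    try:
        return circ_corr(a, b)
    except ValueError:
        return float("nan")  # a degenerate (zero-spread) sample


def control_config(base: SimulationConfig | None = None, seed: int | None = None) -> SimulationConfig:
    """The mixed-parameter negative control of the same study conditions."""
    cfg = base or SimulationConfig()
    return replace(cfg, control_mix=True, seed=cfg.seed if seed is None else seed)
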