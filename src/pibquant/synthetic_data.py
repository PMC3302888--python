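"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the data the multi-modal study design produces:

* dynamic PET time-activity curves under simplified reference tissue model
  (SRTM) kinetics, on the acquisition frame schedules (52 and 162 frames),
* small dynamic phantom volumes with region label maps,
* 96-well saturation-binding plates (twelve concentrations 0.2-48 nM,
  octuplicate total and blocked wells),
* fluorescence micrographs with disk-shaped plaques placed to a target
  burden and lognormal radii,
* dual-isotope (3H + 11C) binned autoradiograph exposures,
* a four-group multimodal cohort drawn from correlated per-group
  distributions.

Everything is reproducible from an integer seed; noiseless outputs are
deterministic.  Frame values are frame averages (PET frames integrate
counts), TAC noise is Gaussian with variance proportional to
concentration/duration, autoradiograph counts are Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    SECONDS_PER_MINUTE,
    DynamicVolume,
    FrameSchedule,
    TimeActivityCurve,
)

__all__ = [
    "PlasmaInputParams",
    "SRTMParams",
    "NoiseSpec",
    "ContinuousCurve",
    "make_frame_schedule",
    "simulate_reference_tac",
    "simulate_target_tac",
    "simulate_tac_pair",
    "PhantomRegion",
    "PhantomLayout",
    "simulate_dynamic_volume",
    "SiteTruth",
    "AssayDesign",
    "simulate_binding_assay",
    "PlaqueChannelSpec",
    "simulate_plaque_image",
    "simulate_dual_label_autoradiograph",
    "GroupParams",
    "CohortSpec",
    "default_cohort_spec",
    "simulate_cohort",
]

#: named acquisition frame schedules, (count, duration_s) blocks
NAMED_SCHEDULES: dict[str, tuple[tuple[int, float], ...]] = {
    # 60 min, 52 frames
    "52f": ((24, 10.0), (12, 30.0), (10, 120.0), (6, 300.0)),
    # 60 min, 162 frames with 1-s initial resolution
    "162f": ((120, 1.0), (24, 10.0), (8, 30.0), (10, 300.0)),
}


def make_frame_schedule(code) -> FrameSchedule:
    """Build a frame schedule from a named code ("52f", "162f") or explicit
    ``(count, duration_s)`` blocks."""
    if isinstance(code, str):
        try:
            blocks = NAMED_SCHEDULES[code]
        except KeyError:
            raise ValueError(
                f"unknown schedule code {code!r}; known: {sorted(NAMED_SCHEDULES)}"
            ) from None
        return FrameSchedule.from_blocks(blocks)
    return FrameSchedule.from_blocks(code)


# ---------------------------------------------------------------------------
# SRTM forward simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlasmaInputParams:
    """Arterial input: gamma-variate bolus plus a slowly clearing tail.

    Cp(t) = amplitude * [ u^shape * exp(shape*(1-u))
                          + tail_fraction * (1 - exp(-3*u)) ] * exp(-clearance*t)

    with u = t / peak_time_min.  The bolus term peaks near ``peak_time_min``
    and washes out at ~shape/peak_time; the recirculation tail rises on the
    same time scale and clears mono-exponentially at ``clearance_per_min``,
    which therefore sets the terminal plasma rate — keeping it slower than
    the tissue efflux constants puts the late scan in transient
    equilibrium.  ``shape=0, tail_fraction=0`` degenerates to the pure
    mono-exponential ``amplitude * exp(-clearance*t)``, which admits a
    closed-form tissue curve (used by the test oracles).  The curve is
    nonnegative and integrable; the reference-tissue estimators never see
    it.
    """

    amplitude: float = 100.0  # kBq/cc
    peak_time_min: float = 0.5
    shape: float = 2.0
    clearance_per_min: float = 0.01
    tail_fraction: float = 0.2

    def __call__(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        u = np.clip(t / self.peak_time_min, 0.0, None)
        terms = np.zeros_like(u)
        if self.shape > 0:
            with np.errstate(invalid="ignore"):
                bolus = u**self.shape * np.exp(self.shape * (1.0 - u))
            terms = terms + np.where(t <= 0, 0.0, bolus)
        else:
            terms = terms + 1.0
        if self.tail_fraction > 0:
            terms = terms + self.tail_fraction * (1.0 - np.exp(-3.0 * u))
        return self.amplitude * terms * np.exp(-self.clearance_per_min * t)


@dataclass(frozen=True)
class SRTMParams:
    """Simplified reference tissue model kinetics.

    r1 is the target/reference delivery ratio K1/K1', k2 the target efflux
    constant (1/min), bp_nd the non-displaceable binding potential,
    ref_k1 (ml/ccm/min) and ref_k2prime (1/min) the reference one-tissue
    constants.  The apparent target efflux is k2a = k2/(1+BP_ND).
    """

    r1: float = 1.0
    k2: float = 0.15
    bp_nd: float = 0.5
    ref_k1: float = 0.3
    ref_k2prime: float = 0.15

    def __post_init__(self) -> None:
        if self.k2 <= 0 or self.ref_k2prime <= 0:
            raise ValueError("k2 and ref_k2prime must be positive")
        if self.bp_nd <= -1:
            raise ValueError("bp_nd must exceed -1")

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.bp_nd)

    @classmethod
    def consistent(
        cls,
        bp_nd: float,
        r1: float = 1.0,
        ref_k1: float = 0.3,
        ref_k2prime: float = 0.15,
    ) -> "SRTMParams":
        """Kinetics with a common non-displaceable distribution volume
        (K1/k2 = K1'/k2', i.e. k2 = r1*k2'), the regime in which the
        reference-tissue estimators are exact."""
        return cls(
            r1=r1,
            k2=r1 * ref_k2prime,
            bp_nd=bp_nd,
            ref_k1=ref_k1,
            ref_k2prime=ref_k2prime,
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian frame noise with sd = scale * sqrt(value / duration_min)."""

    scale: float = 0.0

    def frame_sd(self, value: np.ndarray, duration_min: np.ndarray) -> np.ndarray:
        return self.scale * np.sqrt(np.clip(value, 0.0, None) / duration_min)


class ContinuousCurve(NamedTuple):
    """A curve sampled on a fine regular grid (minutes)."""

    t_min: np.ndarray
    value: np.ndarray

    @property
    def dt_min(self) -> float:
        return float(self.t_min[1] - self.t_min[0])


def _conv_exp(f: np.ndarray, dt: float, k: float) -> np.ndarray:
    """(f x exp(-k t))(t) on a regular grid, exact for piecewise-linear f.

    Uses the recursive update y_{n+1} = E*y_n + analytic step integral with
    linear interpolation of f over each step; far more accurate than
    rectangle-rule convolution at the same grid spacing.
    """
    n = f.size
    y = np.zeros(n)
    if k * dt < 1e-12:
        # negligible decay over a step: plain trapezoid accumulation
        return np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * dt)])
    E = np.exp(-k * dt)
    # with f linear over [0, dt]:
    # int_0^dt f(s) e^{-k(dt-s)} ds = f_n*(1-E)/k + (f_{n+1}-f_n)*(dt/k - (1-E)/k^2)/dt
    a = (1.0 - E) / k
    b = (dt / k - (1.0 - E) / k**2) / dt
    # linear recursion y_{n+1} = E*y_n + c_n solved with an IIR filter
    from scipy.signal import lfilter

    c = f[:-1] * a + (f[1:] - f[:-1]) * b
    y[1:] = lfilter([1.0], [1.0, -E], c)
    return y


def _frame_average(curve: ContinuousCurve, schedule: FrameSchedule) -> np.ndarray:
    """Average the continuous curve over each frame (PET frames integrate)."""
    t = curve.t_min * SECONDS_PER_MINUTE
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (curve.value[1:] + curve.value[:-1]) * np.diff(t))])
    start = np.interp(schedule.frame_start, t, cum)
    end = np.interp(schedule.frame_end, t, cum)
    return (end - start) / schedule.frame_duration


def _fine_grid(schedule: FrameSchedule, grid_dt_s: float) -> np.ndarray:
    n = int(np.ceil(schedule.total_duration / grid_dt_s)) + 1
    return np.linspace(0.0, schedule.total_duration, n) / SECONDS_PER_MINUTE


def reference_curve(
    plasma: PlasmaInputParams, params: SRTMParams, t_min: np.ndarray
) -> ContinuousCurve:
    """Continuous reference-region curve C_R = K1' * (Cp x exp(-k2' t))."""
    cp = plasma(t_min)
    dt = float(t_min[1] - t_min[0])
    cr = params.ref_k1 * _conv_exp(cp, dt, params.ref_k2prime)
    return ContinuousCurve(t_min, cr)


def target_curve(ref: ContinuousCurve, params: SRTMParams) -> ContinuousCurve:
    """Continuous target curve under SRTM:
    C_T = R1*C_R + (k2 - R1*k2a) * (C_R x exp(-k2a t))."""
    conv = _conv_exp(ref.value, ref.dt_min, params.k2a)
    ct = params.r1 * ref.value + (params.k2 - params.r1 * params.k2a) * conv
    return ContinuousCurve(ref.t_min, ct)


def simulate_reference_tac(
    plasma: PlasmaInputParams,
    params: SRTMParams,
    schedule: FrameSchedule,
    grid_dt_s: float = 0.25,
) -> TimeActivityCurve:
    """Frame-averaged reference-region TAC from the one-tissue forward model."""
    t_min = _fine_grid(schedule, grid_dt_s)
    ref = reference_curve(plasma, params, t_min)
    if not np.any(ref.value > 0):
        raise ValueError("degenerate plasma curve: reference TAC is identically zero")
    return TimeActivityCurve(schedule, _frame_average(ref, schedule), region_label="cerebellum")


def simulate_target_tac(
    ref,
    params: SRTMParams,
    schedule: FrameSchedule,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    region_label: str = "neocortex",
) -> TimeActivityCurve:
    """Frame-averaged target TAC under SRTM kinetics.

    ``ref`` is a :class:`ContinuousCurve` on a fine grid (<= 1 s spacing
    recommended); a frame-level TAC is accepted and linearly upsampled, at
    reduced accuracy.
    """
    if isinstance(ref, TimeActivityCurve):
        t_min = _fine_grid(ref.schedule, 0.25)
        mid = np.concatenate([[0.0], ref.schedule.midpoint / SECONDS_PER_MINUTE])
        val = np.concatenate([[0.0], ref.value])
        ref = ContinuousCurve(t_min, np.interp(t_min, mid, val))
    ct = target_curve(ref, params)
    values = _frame_average(ct, schedule)
    if noise is not None and noise.scale > 0:
        rng = np.random.default_rng(seed)
        sd = noise.frame_sd(values, schedule.frame_duration / SECONDS_PER_MINUTE)
        values = values + rng.normal(0.0, 1.0, values.shape) * sd
    return TimeActivityCurve(schedule, values, region_label=region_label)


def simulate_tac_pair(
    plasma: PlasmaInputParams,
    params: SRTMParams,
    schedule: FrameSchedule,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    grid_dt_s: float = 0.25,
) -> tuple[TimeActivityCurve, TimeActivityCurve]:
    """Convenience: (reference TAC, target TAC) from one forward simulation."""
    t_min = _fine_grid(schedule, grid_dt_s)
    ref = reference_curve(plasma, params, t_min)
    ref_tac = TimeActivityCurve(schedule, _frame_average(ref, schedule), region_label="cerebellum")
    if noise is not None and noise.scale > 0:
        rng = np.random.default_rng(seed)
        sd = noise.frame_sd(ref_tac.value, schedule.frame_duration / SECONDS_PER_MINUTE)
        ref_tac = TimeActivityCurve(
            schedule, ref_tac.value + rng.normal(0.0, 1.0, sd.shape) * sd, "cerebellum"
        )
        tgt = simulate_target_tac(ref, params, schedule, noise, seed=None if seed is None else seed + 1)
    else:
        tgt = simulate_target_tac(ref, params, schedule)
    return ref_tac, tgt


# ---------------------------------------------------------------------------
# dynamic phantom volumes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomRegion:
    """A spherical region in voxel coordinates."""

    label: int
    center: tuple[float, float, float]
    radius: float


@dataclass(frozen=True)
class PhantomLayout:
    shape: tuple[int, int, int] = (32, 32, 32)
    regions: tuple[PhantomRegion, ...] = (
        PhantomRegion(1, (9.5, 16.0, 16.0), 5.5),  # target
        PhantomRegion(2, (22.5, 16.0, 16.0), 5.5),  # reference
    )

    def label_map(self) -> np.ndarray:
        grid = np.indices(self.shape, dtype=float)
        labels = np.zeros(self.shape, dtype=np.int16)
        for region in self.regions:
            d2 = sum((grid[i] - region.center[i]) ** 2 for i in range(3))
            inside = d2 <= region.radius**2
            if np.any(labels[inside] != 0):
                raise ValueError(f"region {region.label} overlaps another region")
            labels[inside] = region.label
        return labels


def simulate_dynamic_volume(
    layout: PhantomLayout,
    region_params: dict[int, SRTMParams],
    schedule: FrameSchedule,
    plasma: PlasmaInputParams | None = None,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    grid_dt_s: float = 0.25,
) -> tuple[DynamicVolume, np.ndarray]:
    """Dynamic phantom volume: each voxel draws its region's SRTM TAC plus
    independent frame noise.  Returns ``(volume, label_map)``."""
    plasma = plasma or PlasmaInputParams()
    labels = layout.label_map()
    present = {int(l) for l in np.unique(labels) if l != 0}
    missing = present - set(region_params)
    if missing:
        raise ValueError(f"no kinetics given for region labels {sorted(missing)}")

    t_min = _fine_grid(schedule, grid_dt_s)
    # all regions share the reference one-tissue constants of the first param set
    any_params = next(iter(region_params.values()))
    ref = reference_curve(plasma, any_params, t_min)

    data = np.zeros((*layout.shape, schedule.n_frames))
    for label in sorted(present):
        tac = simulate_target_tac(ref, region_params[label], schedule)
        data[labels == label] = tac.value
    if noise is not None and noise.scale > 0:
        rng = np.random.default_rng(seed)
        dur_min = schedule.frame_duration / SECONDS_PER_MINUTE
        sd = noise.frame_sd(data, dur_min[None, None, None, :])
        data = data + rng.normal(0.0, 1.0, data.shape) * sd
    return DynamicVolume(data, voxel_size_mm, schedule), labels


# ---------------------------------------------------------------------------
# saturation binding plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteTruth:
    """Ground-truth binding sites: Kd (nM) and Bmax (fmol/mg) per site,
    nonspecific slope NS (fmol/mg per nM) and additive background."""

    kd: tuple[float, ...] = (5.2,)
    bmax: tuple[float, ...] = (200.0,)
    ns: float = 2.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if len(self.kd) != len(self.bmax) or not 1 <= len(self.kd) <= 2:
            raise ValueError("need 1 or 2 (kd, bmax) site pairs")
        if any(k <= 0 for k in self.kd) or any(b < 0 for b in self.bmax):
            raise ValueError("kd must be positive, bmax nonnegative")
        if self.ns < 0:
            raise ValueError("nonspecific slope must be nonnegative")

    def specific(self, conc_nm: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc_nm, dtype=float)
        out = np.zeros_like(conc)
        for kd, bmax in zip(self.kd, self.bmax):
            out = out + bmax * conc / (kd + conc)
        return out

    def total(self, conc_nm: np.ndarray) -> np.ndarray:
        return self.specific(conc_nm) + self.ns * np.asarray(conc_nm) + self.background

    def nonspecific(self, conc_nm: np.ndarray) -> np.ndarray:
        return self.ns * np.asarray(conc_nm, dtype=float) + self.background


@dataclass(frozen=True)
class AssayDesign:
    """Plate design: twelve log-spaced concentrations 0.2-48 nM, octuplicate
    total and blocked (3 uM cold ligand) wells."""

    concentration_nm: tuple[float, ...] = tuple(
        float(c) for c in np.geomspace(0.2, 48.0, 12)
    )
    replicates: int = 8

    def __post_init__(self) -> None:
        if len(self.concentration_nm) == 0:
            raise ValueError("empty concentration grid")
        if any(c <= 0 for c in self.concentration_nm):
            raise ValueError("concentrations must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def simulate_binding_assay(
    truth: SiteTruth,
    design: AssayDesign = AssayDesign(),
    noise_cv: float = 0.05,
    seed: int | None = None,
):
    """Simulate a saturation-binding plate.

    Well values carry multiplicative Gaussian noise of coefficient of
    variation ``noise_cv`` around the true isotherm; blocked wells see only
    the nonspecific component.  Returns a
    :class:`pibquant.binding_assay.BindingAssayData`.
    """
    from .binding_assay import BindingAssayData

    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    conc = np.asarray(design.concentration_nm, dtype=float)
    rng = np.random.default_rng(seed)
    shape = (conc.size, design.replicates)
    total_mean = truth.total(conc)[:, None]
    ns_mean = truth.nonspecific(conc)[:, None]
    if noise_cv > 0:
        total = total_mean * (1.0 + noise_cv * rng.normal(size=shape))
        nonspecific = ns_mean * (1.0 + noise_cv * rng.normal(size=shape))
    else:
        total = np.broadcast_to(total_mean, shape).copy()
        nonspecific = np.broadcast_to(ns_mean, shape).copy()
    return BindingAssayData(
        concentration_nm=conc,
        total=total,
        nonspecific=nonspecific,
        free_calibration=conc.copy(),
    )


# ---------------------------------------------------------------------------
# plaque micrographs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlaqueChannelSpec:
    """Per-channel rendering: plaque amplitude and Gaussian background, in
    16-bit counts.  ``colocalization`` is the fraction of plaques visible in
    both antibody channels (Ab40 and Ab42); the remainder splits evenly."""

    amplitude: float = 3000.0
    background_mean: float = 200.0
    background_sd: float = 8.0
    colocalization: float = 0.8


def _render_disks(shape, centers, radii_px) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.indices(shape)
    for (cy, cx), r in zip(centers, radii_px):
        y0, y1 = max(0, int(cy - r - 1)), min(shape[0], int(cy + r + 2))
        x0, x1 = max(0, int(cx - r - 1)), min(shape[1], int(cx + r + 2))
        sub = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2 <= r**2
        mask[y0:y1, x0:x1] |= sub
    return mask


def simulate_plaque_image(
    roi_mask: np.ndarray,
    burden_pct: float,
    radius_median_um: float = 18.0,
    radius_sigma_log: float = 0.45,
    pixel_size_um: float = 5.0,
    channels: PlaqueChannelSpec = PlaqueChannelSpec(),
    seed: int | None = None,
    tolerance_pct_points: float = 0.1,
    max_attempts: int = 200_000,
):
    """Render a multi-channel micrograph with disk plaques at a target burden.

    Disks (lognormal radii, centres uniform in the ROI) are added until the
    rendered union-mask area fraction inside the ROI is within
    ``tolerance_pct_points`` of ``burden_pct``; a candidate that would
    overshoot the band is rejected and redrawn.  Overlap is allowed; the
    ground truth is the rendered union mask, matching the definition of
    burden as an area fraction.

    Returns ``(images, truth)`` where ``images`` maps channel name
    ('thioS', 'ab40', 'ab42') to a uint16 image and ``truth`` is a
    :class:`pibquant.histology.PlaqueSet` measured on the union mask.
    """
    from .histology import PlaqueSet, labeled_plaque_set

    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not 0 <= burden_pct <= 40:
        raise ValueError("burden_pct must be within [0, 40]")
    roi_px = int(roi_mask.sum())
    if roi_px == 0:
        raise ValueError("ROI mask is empty")
    rng = np.random.default_rng(seed)
    shape = roi_mask.shape

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    union = np.zeros(shape, dtype=bool)
    target_px = burden_pct / 100.0 * roi_px
    band_px = tolerance_pct_points / 100.0 * roi_px
    roi_coords = np.argwhere(roi_mask)
    attempts = 0
    while burden_pct > 0:
        filled = int((union & roi_mask).sum())
        # aim for the centre of the tolerance band so small targets are not
        # systematically undershot by the first disk that enters the band
        if filled >= target_px - 0.1 * band_px:
            break
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "target burden unreachable for the given radius distribution and ROI"
            )
        cy, cx = roi_coords[rng.integers(roi_coords.shape[0])] + rng.random(2) - 0.5
        r_um = radius_median_um * np.exp(radius_sigma_log * rng.standard_normal())
        r_px = max(r_um / pixel_size_um, 1.0)
        cand = _render_disks(shape, [(cy, cx)], [r_px])
        new_px = int((cand & roi_mask & ~union).sum())
        # reject candidates that would overshoot; the working band is a
        # quarter of the stated tolerance so the final fraction lands well
        # inside +/- tolerance_pct_points even for small targets
        if filled + new_px > target_px + 0.25 * band_px:
            continue
        union |= cand
        centers.append((float(cy), float(cx)))
        radii.append(float(r_um))

    union &= roi_mask

    # channel membership: thioS sees every plaque; antibody channels split
    n = len(centers)
    both = rng.random(n) < channels.colocalization
    only40 = (~both) & (rng.random(n) < 0.5)
    only42 = ~both & ~only40
    masks = {
        "thioS": union,
        "ab40": _render_disks(
            shape,
            [c for c, m in zip(centers, both | only40) if m],
            [r / pixel_size_um for r, m in zip(radii, both | only40) if m],
        )
        & roi_mask,
        "ab42": _render_disks(
            shape,
            [c for c, m in zip(centers, both | only42) if m],
            [r / pixel_size_um for r, m in zip(radii, both | only42) if m],
        )
        & roi_mask,
    }
    images = {}
    for name, mask in masks.items():
        img = channels.background_mean + channels.background_sd * rng.standard_normal(shape)
        img[mask] += channels.amplitude
        images[name] = np.clip(img, 0, 65535).astype(np.uint16)

    truth = labeled_plaque_set(union, roi_mask, pixel_size_um, channel="thioS")
    truth_channels = {
        name: labeled_plaque_set(mask, roi_mask, pixel_size_um, channel=name)
        for name, mask in masks.items()
    }
    return images, truth, truth_channels


# ---------------------------------------------------------------------------
# dual-isotope autoradiograph exposures
# ---------------------------------------------------------------------------


def simulate_dual_label_autoradiograph(
    pattern_a: np.ndarray,
    pattern_b: np.ndarray,
    isotopes,
    exposure_bins: Sequence[tuple[float, float]],
    counts_scale: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Binned dual-label exposure stack.

    ``pattern_a``/``pattern_b`` are per-pixel count *rates* for the two
    isotopes at the start of exposure; counts in bin b are Poisson with mean
    ``counts_scale * (A * int_b e^{-lam_a t} dt + B * int_b e^{-lam_b t} dt)``
    (a stable isotope has lam = 0 and the integral reduces to the bin
    width).  Returns an array of shape ``(n_bins, *pattern.shape)``.
    """
    from .autoradiography import decay_integrals

    a = np.asarray(pattern_a, dtype=float)
    b = np.asarray(pattern_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("patterns must share a shape")
    bins = [(float(lo), float(hi)) for lo, hi in exposure_bins]
    if any(hi <= lo for lo, hi in bins):
        raise ValueError("exposure bins must have positive length")
    w_a = decay_integrals(bins, isotopes[0])
    w_b = decay_integrals(bins, isotopes[1])
    rng = np.random.default_rng(seed)
    stack = np.empty((len(bins), *a.shape))
    for i in range(len(bins)):
        lam = counts_scale * (a * w_a[i] + b * w_b[i])
        stack[i] = rng.poisson(np.clip(lam, 0.0, None))
    return stack


# ---------------------------------------------------------------------------
# multimodal cohort
# ---------------------------------------------------------------------------

MODALITIES = (
    "pet_bpnd",
    "autoradio_ratio",
    "thioS_burden_pct",
    "ab40_insoluble_pg_mg",
    "ab42_insoluble_pg_mg",
    "biodist_telencephalon_ratio",
)

SEVERITY_ORDER = ("ctl-old", "tgtg-young", "tg-old", "tgtg-old")


@dataclass(frozen=True)
class GroupParams:
    """Per-group sample size and modality means/SDs.  A modality mapped to
    None is unavailable for the group (missing at the design level)."""

    n: int
    means: dict[str, float | None]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if any(sd < 0 for sd in self.sds.values()):
            raise ValueError("SDs must be nonnegative")


@dataclass(frozen=True)
class CohortSpec:
    """Study cohort: groups, per-modality distributions and a common
    cross-modality correlation applied within each group."""

    groups: dict[str, GroupParams]
    correlation: float = 0.7
    seed: int = 0

    def correlation_matrix(self, k: int) -> np.ndarray:
        R = np.full((k, k), self.correlation)
        np.fill_diagonal(R, 1.0)
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-10:
            raise ValueError("correlation matrix not positive semidefinite")
        return R


def default_cohort_spec(
    seed: int = 0, n_override: dict[str, int] | None = None, correlation: float = 0.7
) -> CohortSpec:
    """Cohort at the study's group-level summaries.

    Autoradiograph neocortex-to-cerebellum ratios, Thioflavin S neocortical
    burdens and telencephalon-to-cerebellum biodistribution ratios use the
    printed group means and SDs; the hemizygous-old group has no
    biodistribution arm.  Insoluble Ab40/42 levels centre on the assayed
    per-group tissue values with a 15% CV, and PET BP_ND group parameters
    are plausible defaults consistent with the printed severity ordering
    (see docs/methods.md).
    """
    n_override = n_override or {}

    def g(n, pet, auto, burden, ab40, ab42, biodist):
        means = {
            "pet_bpnd": pet[0],
            "autoradio_ratio": auto[0],
            "thioS_burden_pct": burden[0],
            "ab40_insoluble_pg_mg": ab40[0],
            "ab42_insoluble_pg_mg": ab42[0],
            "biodist_telencephalon_ratio": None if biodist is None else biodist[0],
        }
        sds = {
            "pet_bpnd": pet[1],
            "autoradio_ratio": auto[1],
            "thioS_burden_pct": burden[1],
            "ab40_insoluble_pg_mg": ab40[1],
            "ab42_insoluble_pg_mg": ab42[1],
            "biodist_telencephalon_ratio": 0.0 if biodist is None else biodist[1],
        }
        return GroupParams(n=n, means=means, sds=sds)

    groups = {
        "tg-old": g(
            n_override.get("tg-old", 5),
            (0.55, 0.10),
            (1.90, 0.26),
            (7.72, 1.03),
            (169915.9, 0.15 * 169915.9),
            (145010.5, 0.15 * 145010.5),
            None,
        ),
        "tgtg-young": g(
            n_override.get("tgtg-young", 5),
            (0.30, 0.06),
            (1.25, 0.07),
            (4.68, 0.70),
            (172152.3, 0.15 * 172152.3),
            (178821.1, 0.15 * 178821.1),
            (1.87, 0.58),
        ),
        "tgtg-old": g(
            n_override.get("tgtg-old", 5),
            (1.10, 0.15),
            (2.54, 0.27),
            (11.78, 1.63),
            (657818.2, 0.15 * 657818.2),
            (572182.5, 0.15 * 572182.5),
            (4.23, 0.46),
        ),
        "ctl-old": g(
            n_override.get("ctl-old", 5),
            (-0.05, 0.03),
            (0.93, 0.02),
            (0.61, 0.17),
            (30.0, 10.0),
            (30.0, 10.0),
            (0.67, 0.12),
        ),
    }
    return CohortSpec(groups=groups, correlation=correlation, seed=seed)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Per-animal multimodal records from a correlated Gaussian model.

    Within each group the modality vector is drawn from a multivariate
    normal with the group means/SDs and the spec's common correlation;
    unavailable modalities come out as NaN.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, params in spec.groups.items():
        cols = [m for m in MODALITIES if m in params.means]
        R = spec.correlation_matrix(len(cols))
        L = np.linalg.cholesky(R + 1e-12 * np.eye(len(cols)))
        z = rng.standard_normal((params.n, len(cols))) @ L.T
        for i in range(params.n):
            row: dict[str, object] = {
                "animal_id": f"{group}-{i + 1:02d}",
                "group": group,
            }
            for j, m in enumerate(cols):
                mean = params.means[m]
                if mean is None:
                    row[m] = np.nan
                else:
                    row[m] = mean + params.sds[m] * z[i, j]
            rows.append(row)
    return pd.DataFrame(rows)
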