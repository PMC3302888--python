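"""Reference-tissue kinetic quantification of dynamic PET data.

Implements the quantification chain used for [11C]PiB mouse imaging with the
cerebellum as reference region:

* static target-to-reference uptake ratios on a late time window,
* tissue-ratio (AUC ratio) binding estimates,
* the multilinear reference tissue model (MRTM) and its two-parameter
  variant MRTM2 with a fixed reference efflux constant k2',
* voxelwise parametric BP_ND maps.

The multilinear operational equations are exact linearisations of
one-tissue-compartment kinetics.  For MRTM the regression is

    C_T(t) = g1 * int_0^t C_R + g2 * int_0^t C_T + g3 * C_R(t)

with BP_ND = -(g1/g2 + 1) and k2' = g1/g3.  MRTM2 fixes k2' and reduces to

    C_T(t) = g1 * (int_0^t C_R + C_R(t)/k2') + g2 * int_0^t C_T

with the same BP_ND expression.  Ordinary least squares is applied over
frames whose midpoint lies at or after the linear-phase onset t*.

Conventions: frame schedules are stored in seconds, kinetic rate constants
in 1/min, activity concentrations in kBq/cc.  Negative BP_ND values are
preserved (control animals legitimately sit below the reference region).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "DynamicVolume",
    "KineticFitResult",
    "tac_from_voi",
    "cumulative_integral",
    "static_ratio",
    "ito_ratio_bp",
    "fit_mrtm",
    "estimate_k2prime",
    "fit_mrtm2",
    "parametric_bp_map",
    "read_tac_csv",
    "write_tac_csv",
]

SECONDS_PER_MINUTE = 60.0

#: default start of the linear phase for multilinear fits, minutes
DEFAULT_T_STAR_MIN = 5.0

#: default late static window (start, stop), minutes
DEFAULT_STATIC_WINDOW_MIN = (20.0, 30.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous PET frame timing.

    Parameters
    ----------
    frame_start : array of float
        Frame start times in seconds, strictly increasing, first frame at 0.
    frame_duration : array of float
        Frame durations in seconds, all positive.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValueError("frame_start and frame_duration must be 1-D and equal length")
        if start.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        gaps = start[1:] - (start[:-1] + dur[:-1])
        if np.any(np.abs(gaps) > 1e-6):
            raise ValueError("frames must be contiguous (gap-free)")

    @classmethod
    def from_blocks(cls, blocks: Sequence[tuple[int, float]]) -> "FrameSchedule":
        """Build a schedule from ``(count, duration_s)`` blocks starting at t=0."""
        durations: list[float] = []
        for count, duration in blocks:
            if count < 1:
                raise ValueError(f"block count must be >= 1, got {count}")
            if duration <= 0:
                raise ValueError(f"frame duration must be positive, got {duration}")
            durations.extend([float(duration)] * int(count))
        dur = np.asarray(durations)
        start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        return cls(start, dur)

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def midpoint(self) -> np.ndarray:
        """Frame midpoints, seconds."""
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def total_duration(self) -> float:
        return float(self.frame_end[-1])


@dataclass
class TimeActivityCurve:
    """Decay-corrected activity concentration per frame for one region."""

    schedule: FrameSchedule
    value: np.ndarray
    region_label: str = ""

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        if self.value.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"value length {self.value.size} does not match "
                f"{self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(self.value)):
            raise ValueError("TAC values must be finite")


@dataclass
class DynamicVolume:
    """4-D dynamic PET volume (x, y, z, frame) with voxel size in mm."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic volume must be 4-D (x, y, z, frame)")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError("fourth axis must match the frame schedule")


@dataclass
class KineticFitResult:
    """Multilinear reference-tissue fit result.

    ``gamma3`` is ``None`` for MRTM2 (two-parameter model).  ``ok`` is False
    for rank-deficient / non-finite fits; such results carry NaNs rather
    than raising, so voxelwise use can record failures per voxel.
    """

    model: str
    gamma1: float
    gamma2: float
    gamma3: float | None
    bp_nd: float
    k2prime: float
    residual_rss: float
    n_frames_used: int
    t_star_min: float
    ok: bool = True
    message: str = ""

    @property
    def dvr(self) -> float:
        """Distribution volume ratio, identically BP_ND + 1."""
        return self.bp_nd + 1.0

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "gamma1": self.gamma1,
            "gamma2": self.gamma2,
            "gamma3": self.gamma3,
            "bp_nd": self.bp_nd,
            "dvr": self.dvr,
            "k2prime_per_min": self.k2prime,
            "residual_rss": self.residual_rss,
            "n_frames_used": self.n_frames_used,
            "t_star_min": self.t_star_min,
            "ok": self.ok,
            "message": self.message,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _failed_fit(model: str, t_star_min: float, n_used: int, message: str) -> KineticFitResult:
    return KineticFitResult(
        model=model,
        gamma1=np.nan,
        gamma2=np.nan,
        gamma3=np.nan if model == "mrtm" else None,
        bp_nd=np.nan,
        k2prime=np.nan,
        residual_rss=np.nan,
        n_frames_used=n_used,
        t_star_min=t_star_min,
        ok=False,
        message=message,
    )


# ---------------------------------------------------------------------------
# TAC extraction and integrals
# ---------------------------------------------------------------------------


def tac_from_voi(vol: DynamicVolume, mask: np.ndarray, label: int) -> TimeActivityCurve:
    """Per-frame unweighted mean over all voxels carrying ``label``."""
    mask = np.asarray(mask)
    if mask.shape != vol.data.shape[:3]:
        raise ValueError("label map shape does not match volume")
    sel = mask == label
    if not np.any(sel):
        raise ValueError(f"label {label} not present in mask")
    values = vol.data[sel].mean(axis=0)
    return TimeActivityCurve(vol.schedule, values, region_label=str(label))


def _midpoint_integrals(tac: TimeActivityCurve) -> np.ndarray:
    """Cumulative trapezoid integral of the TAC evaluated at frame midpoints.

    The piecewise representation anchors the curve at (0, 0) and linearly
    interpolates between frame midpoints; units are value * seconds.
    """
    t = np.concatenate([[0.0], tac.schedule.midpoint])
    y = np.concatenate([[0.0], tac.value])
    increments = 0.5 * (y[1:] + y[:-1]) * np.diff(t)
    return np.cumsum(increments)


def cumulative_integral(tac: TimeActivityCurve, t: float) -> float:
    """Integral of the TAC from 0 to ``t`` s.

    Frame values are frame averages, so the natural piecewise
    representation is the step function that reproduces each frame's
    integral exactly; a constant TAC c over [0, T] integrates to c*T.
    """
    if t < 0 or t > tac.schedule.total_duration:
        raise ValueError(f"t={t} s outside the schedule [0, {tac.schedule.total_duration}]")
    start = tac.schedule.frame_start
    end = tac.schedule.frame_end
    overlap = np.clip(np.minimum(end, t) - start, 0.0, None)
    return float(np.sum(tac.value * overlap))


def _window_mean(tac: TimeActivityCurve, window_min: tuple[float, float]) -> float:
    """Duration-weighted mean over frames fully or partially inside the window."""
    lo, hi = (window_min[0] * SECONDS_PER_MINUTE, window_min[1] * SECONDS_PER_MINUTE)
    if hi <= lo:
        raise ValueError("window must have positive length")
    if lo < -1e-9 or hi > tac.schedule.total_duration + 1e-9:
        raise ValueError("window extends beyond the schedule")
    start = np.maximum(tac.schedule.frame_start, lo)
    end = np.minimum(tac.schedule.frame_end, hi)
    overlap = np.clip(end - start, 0.0, None)
    if overlap.sum() <= 0:
        raise ValueError("no frames overlap the window")
    return float(np.sum(tac.value * overlap) / overlap.sum())


def static_ratio(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    window_min: tuple[float, float] = DEFAULT_STATIC_WINDOW_MIN,
) -> float:
    """Late static uptake ratio: windowed mean of target over reference.

    Mirrors the static 10-min frame (20-30 min p.i.) ratio; for
    reference-region kinetics without specific binding the ratio sits below
    one in control-like data.
    """
    ref_mean = _window_mean(reference, window_min)
    if ref_mean <= 0:
        raise ValueError("reference mean in window must be positive")
    return _window_mean(target, window_min) / ref_mean


def ito_ratio_bp(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    window_min: tuple[float, float] = DEFAULT_STATIC_WINDOW_MIN,
) -> float:
    """Tissue-ratio binding estimate: AUC_target / AUC_reference - 1.

    AUCs are taken over ``window_min``.  At transient equilibrium the AUC
    ratio approaches the distribution volume ratio, so the estimate
    approaches BP_ND from below as the window moves late.
    """
    lo, hi = (window_min[0] * SECONDS_PER_MINUTE, window_min[1] * SECONDS_PER_MINUTE)
    if hi <= lo:
        raise ValueError("degenerate window")
    auc_t = cumulative_integral(target, hi) - cumulative_integral(target, lo)
    auc_r = cumulative_integral(reference, hi) - cumulative_integral(reference, lo)
    if auc_r <= 0:
        raise ValueError("reference AUC must be positive")
    return auc_t / auc_r - 1.0


# ---------------------------------------------------------------------------
# multilinear reference tissue models
# ---------------------------------------------------------------------------


def _design_frames(schedule: FrameSchedule, t_star_min: float) -> np.ndarray:
    return schedule.midpoint >= t_star_min * SECONDS_PER_MINUTE


def fit_mrtm(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    t_star_min: float = DEFAULT_T_STAR_MIN,
) -> KineticFitResult:
    """Three-parameter multilinear reference tissue model (MRTM).

    Returns BP_ND = -(g1/g2 + 1) and the reference efflux constant
    k2' = g1/g3 (1/min).  Rank deficiency is flagged on the result rather
    than raised, so the fit is safe in voxelwise loops.
    """
    if target.schedule.n_frames != reference.schedule.n_frames:
        raise ValueError("target and reference must share a schedule")
    if not np.any(reference.value != 0):
        raise ValueError("reference TAC is identically zero")
    sel = _design_frames(target.schedule, t_star_min)
    n_used = int(sel.sum())
    if n_used < 4:
        raise ValueError(f"need >= 4 frames at/after t*={t_star_min} min, have {n_used}")

    # integrals in value*min so that the gammas carry 1/min units directly
    int_r = _midpoint_integrals(reference) / SECONDS_PER_MINUTE
    int_t = _midpoint_integrals(target) / SECONDS_PER_MINUTE
    X = np.column_stack([int_r[sel], int_t[sel], reference.value[sel]])
    y = target.value[sel]
    coef, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3 or not np.all(np.isfinite(coef)):
        # exact proportionality target = c * reference makes the integral
        # columns collinear; BP_ND = c - 1 is still identified (DVR = c),
        # but k2' is not
        denom = float(reference.value[sel] @ reference.value[sel])
        c = float(target.value[sel] @ reference.value[sel]) / denom
        resid_prop = target.value[sel] - c * reference.value[sel]
        if np.linalg.norm(resid_prop) <= 1e-8 * np.linalg.norm(target.value[sel]):
            return KineticFitResult(
                model="mrtm",
                gamma1=np.nan,
                gamma2=np.nan,
                gamma3=np.nan,
                bp_nd=c - 1.0,
                k2prime=np.nan,
                residual_rss=float(resid_prop @ resid_prop),
                n_frames_used=n_used,
                t_star_min=t_star_min,
                ok=True,
                message="target proportional to reference; k2' unidentifiable",
            )
        return _failed_fit("mrtm", t_star_min, n_used, "rank-deficient design matrix")
    g1, g2, g3 = coef
    if g2 == 0 or g3 == 0:
        return _failed_fit("mrtm", t_star_min, n_used, "degenerate coefficients")
    resid = y - X @ coef
    return KineticFitResult(
        model="mrtm",
        gamma1=float(g1),
        gamma2=float(g2),
        gamma3=float(g3),
        bp_nd=float(-(g1 / g2 + 1.0)),
        k2prime=float(g1 / g3),
        residual_rss=float(resid @ resid),
        n_frames_used=n_used,
        t_star_min=t_star_min,
    )


def estimate_k2prime(
    reference: TimeActivityCurve,
    targets: Sequence[TimeActivityCurve],
    t_star_min: float = DEFAULT_T_STAR_MIN,
    pooling: str = "median",
) -> float:
    """Pool the reference efflux constant k2' from several regional MRTM fits.

    The study design uses four cortical regions; the pooled value then
    fixes MRTM2.  Pooling is the median by default (robust to one bad
    regional fit); ``pooling="mean"`` is available.
    """
    if len(targets) < 2:
        raise ValueError("need at least 2 regional target TACs")
    estimates = []
    for tac in targets:
        fit = fit_mrtm(tac, reference, t_star_min=t_star_min)
        if fit.ok and np.isfinite(fit.k2prime) and fit.k2prime > 0:
            estimates.append(fit.k2prime)
        else:
            warnings.warn(
                f"MRTM fit failed for region '{tac.region_label}'; excluded from k2' pooling",
                stacklevel=2,
            )
    if not estimates:
        raise ValueError("all regional MRTM fits failed")
    if pooling == "median":
        return float(np.median(estimates))
    if pooling == "mean":
        return float(np.mean(estimates))
    raise ValueError(f"unknown pooling rule {pooling!r}")


def fit_mrtm2(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    k2prime: float,
    t_star_min: float = DEFAULT_T_STAR_MIN,
) -> KineticFitResult:
    """Two-parameter multilinear reference tissue model (MRTM2).

    ``k2prime`` (1/min) is the reference efflux constant fixed from a prior
    MRTM estimate; the combined regressor is int C_R + C_R/k2'.
    """
    if k2prime <= 0:
        raise ValueError("k2prime must be positive")
    if target.schedule.n_frames != reference.schedule.n_frames:
        raise ValueError("target and reference must share a schedule")
    sel = _design_frames(target.schedule, t_star_min)
    n_used = int(sel.sum())
    if n_used < 3:
        raise ValueError(f"need >= 3 frames at/after t*={t_star_min} min, have {n_used}")

    int_r = _midpoint_integrals(reference) / SECONDS_PER_MINUTE
    int_t = _midpoint_integrals(target) / SECONDS_PER_MINUTE
    X = np.column_stack([int_r[sel] + reference.value[sel] / k2prime, int_t[sel]])
    y = target.value[sel]
    coef, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2 or not np.all(np.isfinite(coef)):
        return _failed_fit("mrtm2", t_star_min, n_used, "rank-deficient design matrix")
    g1, g2 = coef
    if g2 == 0:
        return _failed_fit("mrtm2", t_star_min, n_used, "degenerate coefficients")
    resid = y - X @ coef
    return KineticFitResult(
        model="mrtm2",
        gamma1=float(g1),
        gamma2=float(g2),
        gamma3=None,
        bp_nd=float(-(g1 / g2 + 1.0)),
        k2prime=float(k2prime),
        residual_rss=float(resid @ resid),
        n_frames_used=n_used,
        t_star_min=t_star_min,
    )


def parametric_bp_map(
    vol: DynamicVolume,
    reference: TimeActivityCurve,
    k2prime: float,
    brain_mask: np.ndarray | None = None,
    t_star_min: float = DEFAULT_T_STAR_MIN,
) -> tuple[np.ndarray, int]:
    """Voxelwise MRTM2 BP_ND map.

    Fits every voxel inside ``brain_mask`` (whole volume if None) with the
    two-parameter model; failed voxels (rank deficiency, non-finite data)
    are set to NaN and counted.  Returns ``(bp_map, n_failed)``.

    The per-voxel 2x2 normal equations are solved vectorised; this is
    algebraically the same least-squares problem as :func:`fit_mrtm2`.
    """
    if k2prime <= 0:
        raise ValueError("k2prime must be positive")
    shape = vol.data.shape[:3]
    if brain_mask is None:
        brain_mask = np.ones(shape, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != shape:
        raise ValueError("brain mask shape does not match volume")

    sel = _design_frames(vol.schedule, t_star_min)
    int_r = _midpoint_integrals(reference) / SECONDS_PER_MINUTE
    x1 = int_r[sel] + reference.value[sel] / k2prime  # shared regressor

    Y = vol.data[brain_mask][:, :]  # (nvox, nframes)
    # per-voxel cumulative trapezoid over midpoints with zero anchor
    t = np.concatenate([[0.0], vol.schedule.midpoint]) / SECONDS_PER_MINUTE
    dt = np.diff(t)
    Yp = np.concatenate([np.zeros((Y.shape[0], 1)), Y], axis=1)
    int_y = np.cumsum(0.5 * (Yp[:, 1:] + Yp[:, :-1]) * dt, axis=1)

    x2 = int_y[:, sel]  # (nvox, n_used)
    y = Y[:, sel]

    a11 = float(x1 @ x1)
    a12 = x2 @ x1
    a22 = np.einsum("ij,ij->i", x2, x2)
    b1 = y @ x1
    b2 = np.einsum("ij,ij->i", x2, y)
    det = a11 * a22 - a12**2
    scale = np.maximum(a11 * a22, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        g1 = (a22 * b1 - a12 * b2) / det
        g2 = (a11 * b2 - a12 * b1) / det
        bp = -(g1 / g2 + 1.0)
    bad = (~np.isfinite(bp)) | (np.abs(det) <= 1e-12 * scale) | (g2 == 0)
    bp[bad] = np.nan

    bp_map = np.full(shape, np.nan)
    bp_map[brain_mask] = bp
    return bp_map, int(bad.sum())


# ---------------------------------------------------------------------------
# CSV / NIfTI interchange
# ---------------------------------------------------------------------------


def write_tac_csv(tac: TimeActivityCurve, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "frame_start_s": tac.schedule.frame_start,
            "frame_duration_s": tac.schedule.frame_duration,
            "value_kBq_cc": tac.value,
            "region": tac.region_label,
        }
    )
    df.to_csv(path, index=False)


def read_tac_csv(path: str | Path) -> TimeActivityCurve:
    df = pd.read_csv(path)
    schedule = FrameSchedule(
        df["frame_start_s"].to_numpy(float), df["frame_duration_s"].to_numpy(float)
    )
    region = str(df["region"].iloc[0]) if "region" in df else ""
    return TimeActivityCurve(schedule, df["value_kBq_cc"].to_numpy(float), region_label=region)


def write_bp_map_nifti(bp_map: np.ndarray, voxel_size_mm, path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag([*voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(bp_map.astype(np.float32), affine), str(path))
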