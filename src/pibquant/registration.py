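"""Rigid co-registration by normalized mutual information.

Rigid transforms are parameterised by a translation (mm) and intrinsic
z-y-x Euler angles (degrees) about a rotation centre (volume centre by
default).  Similarity is the normalized mutual information

    NMI(A, B) = (H(A) + H(B)) / H(A, B)

computed from the joint intensity histogram over the overlap domain; the
score is 1 for independent images and 2 for identical discrete images.
Optimisation is derivative-free (Nelder-Mead) on a two-level
coarse-to-fine pyramid.  The study's manual-correction step is replaced by
reviewable binary-contour overlay QC images (red = reference contour,
green = test contour) on all three orthogonal mid-planes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "normalized_mutual_information",
    "rigid_register",
    "apply_rigid",
    "overlay_qc",
]


def _euler_zyx_matrix(rotation_deg) -> np.ndarray:
    """Rotation matrix for intrinsic z-y-x Euler angles in degrees."""
    az, ay, ax = np.deg2rad(np.asarray(rotation_deg, dtype=float))
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return Rz @ Ry @ Rx


def _euler_from_matrix(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_euler_zyx_matrix` (degrees), gimbal-safe for |ay|<90."""
    ay = np.arcsin(-np.clip(R[2, 0], -1.0, 1.0))
    az = np.arctan2(R[1, 0], R[0, 0])
    ax = np.arctan2(R[2, 1], R[2, 2])
    return np.rad2deg(np.array([az, ay, ax]))


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ (x - center) + center + translation, world coordinates in mm.

    ``rotation_deg`` holds intrinsic z-y-x Euler angles.  With the default
    ``center=None`` the rotation centre is the volume centre at application
    time.
    """

    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] | None = None

    @property
    def matrix(self) -> np.ndarray:
        return _euler_zyx_matrix(self.rotation_deg)

    def inverse(self) -> "RigidTransform":
        R = self.matrix
        Rinv = R.T
        t = np.asarray(self.translation_mm)
        return RigidTransform(
            translation_mm=tuple(-(Rinv @ t)),
            rotation_deg=tuple(_euler_from_matrix(Rinv)),
            center_mm=self.center_mm,
        )

    def params(self) -> np.ndarray:
        return np.concatenate([self.translation_mm, self.rotation_deg])

    @classmethod
    def from_params(cls, p, center=None) -> "RigidTransform":
        p = np.asarray(p, dtype=float)
        return cls(tuple(p[:3]), tuple(p[3:6]), center)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "translation_mm": list(self.translation_mm),
                    "rotation_deg": list(self.rotation_deg),
                    "center_mm": None if self.center_mm is None else list(self.center_mm),
                    "euler_order": "intrinsic z-y-x",
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        d = json.loads(Path(path).read_text())
        c = d.get("center_mm")
        return cls(tuple(d["translation_mm"]), tuple(d["rotation_deg"]), None if c is None else tuple(c))


def apply_rigid(
    vol: np.ndarray,
    tf: RigidTransform,
    voxel_size_mm=(1.0, 1.0, 1.0),
    interpolation: str = "trilinear",
) -> np.ndarray:
    """Resample ``vol`` under the rigid transform (out-of-field -> 0).

    World coordinates are mm with the origin at the volume centre unless the
    transform carries an explicit centre.  ``interpolation`` is
    ``"trilinear"`` (default) or ``"nearest"``.
    """
    vol = np.asarray(vol, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected a 3-D volume")
    order = {"trilinear": 1, "nearest": 0}[interpolation]
    vs = np.asarray(voxel_size_mm, dtype=float)
    m = (np.asarray(vol.shape, dtype=float) - 1.0) / 2.0 * vs  # world centre offset
    c = np.asarray(tf.center_mm, dtype=float) if tf.center_mm is not None else np.zeros(3)
    t = np.asarray(tf.translation_mm, dtype=float)
    Rinv = tf.matrix.T
    # i_in = Vinv(Rinv(world_out - c - t) + c) with world = i*vs - m
    A = Rinv * vs[None, :] / vs[:, None]
    offset = (Rinv @ (-m - c - t) + c + m) / vs
    return ndimage.affine_transform(vol, A, offset=offset, order=order, mode="constant", cval=0.0)


def normalized_mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """NMI = (H(A)+H(B))/H(A,B) from the joint histogram over voxels where
    both images are finite.  Raises on a constant image (zero entropy)."""
    if bins < 8:
        raise ValueError("need at least 8 histogram bins")
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size == 0:
        raise ValueError("no overlapping finite voxels")
    if a.min() == a.max() or b.min() == b.max():
        raise ValueError("constant image has zero entropy; NMI undefined")
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def entropy(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    h_joint = entropy(p.ravel())
    if h_joint == 0:
        raise ValueError("degenerate joint histogram")
    return (entropy(pa) + entropy(pb)) / h_joint


@dataclass
class RegistrationResult:
    transform: RigidTransform
    nmi: float
    converged: bool
    message: str = ""
    n_evaluations: int = 0


def _downsample(vol: np.ndarray, factor: int = 2) -> np.ndarray:
    sm = ndimage.gaussian_filter(vol, sigma=factor / 2.0)
    return sm[::factor, ::factor, ::factor]


def rigid_register(
    moving: np.ndarray,
    fixed: np.ndarray,
    init: RigidTransform | None = None,
    voxel_size_mm=(1.0, 1.0, 1.0),
    bins: int = 32,
    pyramid_levels: int = 2,
    maxiter: int = 400,
) -> RegistrationResult:
    """Find the rigid transform maximising NMI(apply_rigid(moving), fixed).

    Nelder-Mead search on a coarse-to-fine pyramid (Gaussian smoothing +
    2x decimation per level), deterministic for a fixed init.  A run that
    exhausts the iteration budget is flagged ``converged=False`` with the
    best transform so far — never a silent wrong answer.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must share a grid")
    init = init or RigidTransform()
    vs = np.asarray(voxel_size_mm, dtype=float)

    levels = []
    mov, fix, scale = moving, fixed, 1
    for level in range(pyramid_levels):
        levels.append((mov, fix, vs * scale))
        if level < pyramid_levels - 1:
            mov, fix, scale = _downsample(mov), _downsample(fix), scale * 2
    levels = levels[::-1]  # coarse first

    p = init.params()
    total_evals = 0
    converged = True
    message = ""
    for mov, fix, level_vs in levels:

        def neg_nmi(params):
            tf = RigidTransform.from_params(params)
            resampled = apply_rigid(mov, tf, voxel_size_mm=level_vs)
            try:
                return -normalized_mutual_information(resampled, fix, bins=bins)
            except ValueError:
                return 0.0  # degenerate overlap: worst score

        res = minimize(
            neg_nmi,
            p,
            method="Nelder-Mead",
            options={
                "maxiter": maxiter,
                "xatol": 0.01,
                "fatol": 1e-7,
                "initial_simplex": _initial_simplex(p, step_t=float(level_vs.max()), step_r=2.0),
            },
        )
        p = res.x
        total_evals += res.nfev
        if not res.success:
            converged = False
            message = res.message

    best = RigidTransform.from_params(p)
    final = apply_rigid(moving, best, voxel_size_mm=vs)
    try:
        score = normalized_mutual_information(final, fixed, bins=bins)
    except ValueError:
        score = np.nan
        converged = False
        message = message or "degenerate overlap at optimum"
    return RegistrationResult(best, score, converged, message, total_evals)


def _initial_simplex(p0: np.ndarray, step_t: float, step_r: float) -> np.ndarray:
    steps = np.array([step_t] * 3 + [step_r] * 3)
    simplex = np.tile(p0, (7, 1))
    for i in range(6):
        simplex[i + 1, i] += steps[i]
    return simplex


def _binary_contour(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def overlay_qc(a: np.ndarray, b: np.ndarray, thresholds) -> list[dict]:
    """Binary-contour overlay QC for co-registered volumes.

    For each threshold, the volumes are binarised at that level and the
    contours of the three orthogonal mid-planes rendered into RGB images
    with red = ``a`` and green = ``b``; coinciding contours appear yellow.
    Returns a list of ``{"threshold", "plane", "image"}`` records
    (3 planes per threshold).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("volumes must share a grid")
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold list must be nonempty")
    out = []
    mids = [s // 2 for s in a.shape]
    planes = {
        "axial": (np.s_[:, :, mids[2]]),
        "coronal": (np.s_[:, mids[1], :]),
        "sagittal": (np.s_[mids[0], :, :]),
    }
    for thr in thresholds:
        mask_a = a > thr
        mask_b = b > thr
        for plane, sl in planes.items():
            ca = _binary_contour(mask_a[sl])
            cb = _binary_contour(mask_b[sl])
            rgb = np.zeros((*ca.shape, 3), dtype=np.uint8)
            rgb[..., 0][ca] = 255
            rgb[..., 1][cb] = 255
            out.append({"threshold": float(thr), "plane": plane, "image": rgb})
    return out


def write_qc_pngs(overlays: list[dict], out_dir: str | Path) -> list[Path]:
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, rec in enumerate(overlays):
        path = out_dir / f"qc_{i:02d}_{rec['plane']}_thr{rec['threshold']:g}.png"
        iio.imwrite(path, rec["image"])
        paths.append(path)
    return paths
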