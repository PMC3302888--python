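"""Autoradiograph densitometry and dual-isotope decay unmixing.

Densitometry is background-subtracted integrated density per unit ROI
area, and target-to-reference (neocortex-to-cerebellum) ratios thereof.

Dual-label exposures mix a practically stable isotope (3H, half-life
12.3 y) with a rapidly decaying one (11C, half-life 20.364 min).  Binning
the exposure in time makes the two components separable: expected counts
in bin b at pixel p are

    counts_b(p) = a(p) * dt_b + c(p) * int_b exp(-lambda t) dt

with a the 3H rate and c the 11C initial rate.  Unmixing solves this
two-column linear model per pixel under nonnegativity (physical rates),
which for two variables reduces to an exact active-set solution of the
normal equations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "IsotopeSpec",
    "H3",
    "C11",
    "decay_integrals",
    "background_subtract",
    "integrated_density",
    "region_ratio",
    "unmix_dual_label",
    "write_tiff_stack",
    "read_tiff_stack",
]


@dataclass(frozen=True)
class IsotopeSpec:
    """Radioisotope with half-life in minutes (lambda = ln2 / half-life)."""

    name: str
    half_life_min: float

    def __post_init__(self) -> None:
        if self.half_life_min <= 0:
            raise ValueError("half-life must be positive")

    @property
    def lam_per_min(self) -> float:
        return np.log(2.0) / self.half_life_min


#: tritium; decay over a <= 2 h exposure is < 1e-8 and treated as constant
H3 = IsotopeSpec("H-3", 12.32 * 365.25 * 24 * 60)

#: carbon-11
C11 = IsotopeSpec("C-11", 20.364)


def decay_integrals(bins: Sequence[tuple[float, float]], isotope: IsotopeSpec) -> np.ndarray:
    """int_b exp(-lambda t) dt for each (start, stop) bin in minutes."""
    lam = isotope.lam_per_min
    out = np.empty(len(bins))
    for i, (lo, hi) in enumerate(bins):
        if hi <= lo:
            raise ValueError("exposure bins must have positive length")
        if lam * (hi - lo) < 1e-12:
            out[i] = hi - lo
        else:
            out[i] = (np.exp(-lam * lo) - np.exp(-lam * hi)) / lam
    return out


def background_subtract(image: np.ndarray, background) -> np.ndarray:
    """Subtract a background level (scalar, or the mean over a boolean
    region mask) and clip at zero."""
    image = np.asarray(image, dtype=float)
    if isinstance(background, np.ndarray) and background.dtype == bool:
        if not background.any():
            raise ValueError("background region is empty")
        level = float(image[background].mean())
    else:
        level = float(background)
    if not np.isfinite(level):
        raise ValueError("background estimate must be finite")
    return np.clip(image - level, 0.0, None)


def integrated_density(image: np.ndarray, roi: np.ndarray) -> float:
    """Integrated density per unit area: ROI pixel sum / ROI pixel count."""
    image = np.asarray(image, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if image.shape != roi.shape:
        raise ValueError("image and ROI must share a shape")
    n = int(roi.sum())
    if n == 0:
        raise ValueError("ROI is empty")
    return float(image[roi].sum()) / n


def region_ratio(image: np.ndarray, target_roi: np.ndarray, reference_roi: np.ndarray) -> float:
    """Target-to-reference ratio of per-area integrated densities."""
    ref = integrated_density(image, reference_roi)
    if ref <= 0:
        raise ValueError("reference density must be positive")
    return integrated_density(image, target_roi) / ref


def unmix_dual_label(
    stack: np.ndarray,
    bins: Sequence[tuple[float, float]],
    isotopes: tuple[IsotopeSpec, IsotopeSpec] = (H3, C11),
    nonnegative: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Separate a binned dual-label stack into per-isotope rate images.

    ``stack`` has shape (n_bins, H, W); ``bins`` are (start, stop) minutes
    from exposure begin.  Returns ``(rate_a, rate_b)`` — for the default
    isotope pair, the 3H rate and the 11C initial rate.  The per-pixel
    2-variable least-squares problem is solved in closed form; with
    ``nonnegative`` the exact two-variable active-set solution is used.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_bins, H, W)")
    if stack.shape[0] != len(bins) or len(bins) < 2:
        raise ValueError("need >= 2 bins matching the stack depth")
    d1 = decay_integrals(bins, isotopes[0])
    d2 = decay_integrals(bins, isotopes[1])

    a11 = float(d1 @ d1)
    a12 = float(d1 @ d2)
    a22 = float(d2 @ d2)
    det = a11 * a22 - a12 * a12
    if abs(det) <= 1e-12 * a11 * a22:
        raise ValueError("singular unmixing design: exposure bins are too similar")

    Y = stack.reshape(stack.shape[0], -1)
    b1 = d1 @ Y
    b2 = d2 @ Y
    a = (a22 * b1 - a12 * b2) / det
    c = (a11 * b2 - a12 * b1) / det

    if nonnegative:
        # exact 2-variable NNLS: clamp a negative coordinate to zero and
        # re-solve the remaining single-variable problem
        neg_a = a < 0
        a_clamped = np.where(neg_a, 0.0, a)
        c_clamped = np.where(neg_a, np.maximum(b2 / a22, 0.0), c)
        neg_c = c_clamped < 0
        c_final = np.where(neg_c, 0.0, c_clamped)
        a_final = np.where(neg_c & ~neg_a, np.maximum(b1 / a11, 0.0), a_clamped)
        a, c = a_final, c_final

    shape = stack.shape[1:]
    return a.reshape(shape), c.reshape(shape)


def write_tiff_stack(stack: np.ndarray, bins, path: str | Path) -> None:
    """16-bit TIFF (one page per exposure bin) with a JSON sidecar of bin
    times in minutes."""
    import json

    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.clip(stack, 0, 65535).astype(np.uint16))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"bins_min": [[float(a), float(b)] for a, b in bins]}))


def read_tiff_stack(path: str | Path):
    import json

    import tifffile

    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    bins = [tuple(b) for b in json.loads(path.with_suffix(".json").read_text())["bins_min"]]
    return stack, bins
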