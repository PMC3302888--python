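"""Saturation-binding analysis: global one- and two-site regression,
specific-binding / Scatchard / semilog representations and in vitro
binding potential.

The global model fits total and blocked (nonspecific) wells jointly,
sharing the nonspecific slope NS (and optionally an additive background):

    total(L)       = sum_i Bmax_i * L / (Kd_i + L) + NS * L + bg
    nonspecific(L) = NS * L + bg

by unweighted least squares over every replicate well.  Bmax in fmol per
mg wet tissue converts to nM under the density assumption that one gram
of brain occupies one millilitre, so the in vitro binding potential is
simply BP = sum_i Bmax_i / Kd_i with both in matching units.

Free-ligand depletion is neglected (free ~ added); the free-tracer
calibration column is carried for bookkeeping only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BindingAssayData",
    "SiteFit",
    "fit_one_site_global",
    "fit_two_site_global",
    "specific_binding",
    "binding_potential",
    "scatchard_transform",
    "semilog_curve",
    "select_model",
    "read_assay_csv",
    "write_assay_csv",
]


@dataclass
class BindingAssayData:
    """Replicate well table for one tissue sample.

    ``total`` and ``nonspecific`` are (n_concentrations, n_replicates)
    matrices in bound fmol/mg; concentrations in nM, strictly increasing.
    """

    concentration_nm: np.ndarray
    total: np.ndarray
    nonspecific: np.ndarray
    free_calibration: np.ndarray | None = None
    background: float = 0.0

    def __post_init__(self) -> None:
        self.concentration_nm = np.asarray(self.concentration_nm, dtype=float)
        self.total = np.atleast_2d(np.asarray(self.total, dtype=float))
        self.nonspecific = np.atleast_2d(np.asarray(self.nonspecific, dtype=float))
        m = self.concentration_nm.size
        if np.any(self.concentration_nm <= 0) or np.any(np.diff(self.concentration_nm) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        if self.total.shape[0] != m or self.nonspecific.shape[0] != m:
            raise ValueError("well matrices must have one row per concentration")

    @property
    def n_concentrations(self) -> int:
        return int(self.concentration_nm.size)


@dataclass
class SiteFit:
    """Result of a global saturation fit.

    Sites are ordered by ascending Kd for two-site fits.  ``bp`` is the in
    vitro binding potential sum(Bmax_i/Kd_i) under the 1 fmol/mg = 1 nM
    conversion.  ``flags`` carries qualitative findings ("no specific
    component", identifiability warnings, boundary pins).
    """

    n_sites: int
    kd_nm: np.ndarray
    bmax_fmol_mg: np.ndarray
    ns: float
    background: float
    se_kd: np.ndarray
    se_bmax: np.ndarray
    se_ns: float
    residual_rss: float
    n_points: int
    n_parameters: int
    flags: tuple[str, ...] = ()

    @property
    def bp(self) -> float:
        return float(np.sum(self.bmax_fmol_mg / self.kd_nm))

    def model_total(self, conc_nm) -> np.ndarray:
        conc = np.asarray(conc_nm, dtype=float)
        out = self.ns * conc + self.background
        for kd, bmax in zip(self.kd_nm, self.bmax_fmol_mg):
            out = out + bmax * conc / (kd + conc)
        return out

    def model_specific(self, conc_nm) -> np.ndarray:
        conc = np.asarray(conc_nm, dtype=float)
        out = np.zeros_like(conc)
        for kd, bmax in zip(self.kd_nm, self.bmax_fmol_mg):
            out = out + bmax * conc / (kd + conc)
        return out

    def model_nonspecific(self, conc_nm) -> np.ndarray:
        return self.ns * np.asarray(conc_nm, dtype=float) + self.background

    def confidence_band(self, conc_nm, level: float = 0.95):
        """Pointwise confidence band of the fitted total curve (delta
        method on the parameter covariance)."""
        if self._cov is None:
            raise ValueError("fit covariance unavailable")
        conc = np.asarray(conc_nm, dtype=float)
        grads = _total_gradient(conc, self.kd_nm, self.bmax_fmol_mg, self._share_bg)
        var = np.einsum("ij,jk,ik->i", grads, self._cov, grads)
        dof = max(self.n_points - self.n_parameters, 1)
        tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
        mid = self.model_total(conc)
        half = tcrit * np.sqrt(np.clip(var, 0.0, None))
        return mid - half, mid + half

    _cov: np.ndarray | None = None
    _share_bg: bool = False

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "kd_nm": self.kd_nm.tolist(),
            "bmax_fmol_mg": self.bmax_fmol_mg.tolist(),
            "ns_fmol_mg_per_nm": self.ns,
            "background": self.background,
            "se_kd": self.se_kd.tolist(),
            "se_bmax": self.se_bmax.tolist(),
            "se_ns": self.se_ns,
            "bp": self.bp,
            "rss": self.residual_rss,
            "n_points": self.n_points,
            "flags": list(self.flags),
        }


def binding_potential(bmax_fmol_mg: float, kd_nm: float) -> float:
    """In vitro binding potential Bmax/Kd.

    Bmax in fmol per mg wet tissue is taken as numerically equal to its
    concentration in nM (1 fmol/mg = 1 pmol/g = 1 pmol/ml = 1 nM under a
    brain density of 1 g/ml), so the quotient is dimensionless.
    """
    if kd_nm <= 0:
        raise ValueError("Kd must be positive")
    return bmax_fmol_mg / kd_nm


# ---------------------------------------------------------------------------
# global fits
# ---------------------------------------------------------------------------


def _stack_wells(data: BindingAssayData):
    conc = data.concentration_nm
    lt = np.repeat(conc, data.total.shape[1])
    yt = data.total.ravel()
    ln = np.repeat(conc, data.nonspecific.shape[1])
    yn = data.nonspecific.ravel()
    return lt, yt, ln, yn


def _total_gradient(conc, kd, bmax, share_bg):
    cols = []
    for k, b in zip(kd, bmax):
        cols.append(b * conc * -1.0 / (k + conc) ** 2 * k)  # d/d log kd  (chain rule)
        cols.append(conc / (k + conc))  # d/d bmax
    cols.append(conc)  # d/d ns
    if share_bg:
        cols.append(np.ones_like(conc))
    return np.column_stack(cols)


def _global_fit(
    data: BindingAssayData,
    n_sites: int,
    kd0: np.ndarray,
    bmax0: np.ndarray,
    share_background: bool,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares core.  Parameters: [log kd_i, bmax_i]*n + [ns, (bg)].
    Returns (theta, covariance, rss)."""
    lt, yt, ln, yn = _stack_wells(data)
    ns0 = max(np.polyfit(ln, yn, 1)[0], 1e-6)

    def unpack(theta):
        kd = np.exp(theta[0 : 2 * n_sites : 2])
        bmax = theta[1 : 2 * n_sites : 2]
        ns = theta[2 * n_sites]
        bg = theta[2 * n_sites + 1] if share_background else 0.0
        return kd, bmax, ns, bg

    def residuals(theta):
        kd, bmax, ns, bg = unpack(theta)
        rt = yt - (np.sum(bmax[:, None] * lt[None, :] / (kd[:, None] + lt[None, :]), axis=0) + ns * lt + bg)
        rn = yn - (ns * ln + bg)
        return np.concatenate([rt, rn])

    theta0 = np.empty(2 * n_sites + 1 + int(share_background))
    theta0[0 : 2 * n_sites : 2] = np.log(kd0)
    theta0[1 : 2 * n_sites : 2] = bmax0
    theta0[2 * n_sites] = ns0
    if share_background:
        theta0[-1] = 0.0

    lower = np.full(theta0.shape, -np.inf)
    upper = np.full(theta0.shape, np.inf)
    lower[1 : 2 * n_sites : 2] = 0.0  # bmax >= 0
    lower[2 * n_sites] = 0.0  # ns >= 0
    res = optimize.least_squares(
        residuals, np.clip(theta0, lower + 1e-12, None), bounds=(lower, upper),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
    )
    if not res.success and res.status <= 0:
        raise RuntimeError(f"global fit did not converge: {res.message}")
    rss = float(2 * res.cost)
    # heteroscedasticity-robust (sandwich) covariance: well noise is
    # multiplicative, so the homoscedastic (JTJ)^-1 * s^2 form would
    # understate the uncertainty of parameters driven by high-signal wells
    J = res.jac
    r = res.fun
    try:
        bread = np.linalg.inv(J.T @ J)
        meat = J.T @ (J * r[:, None] ** 2)
        n_res, k = J.shape
        cov = bread @ meat @ bread * n_res / max(n_res - k, 1)
    except np.linalg.LinAlgError:
        cov = np.full((theta0.size, theta0.size), np.nan)
    return res.x, cov, rss


def _build_fit(
    data: BindingAssayData, theta, cov, rss, n_sites, share_background, flags=()
) -> SiteFit:
    kd = np.exp(theta[0 : 2 * n_sites : 2])
    bmax = theta[1 : 2 * n_sites : 2]
    ns = float(theta[2 * n_sites])
    bg = float(theta[2 * n_sites + 1]) if share_background else 0.0
    order = np.argsort(kd)
    kd, bmax = kd[order], bmax[order]
    # delta method: se(kd) = kd * se(log kd)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    se_logkd = se[0 : 2 * n_sites : 2][order]
    se_bmax = se[1 : 2 * n_sites : 2][order]
    se_kd = kd * se_logkd
    lt, yt, ln, yn = _stack_wells(data)
    n_points = yt.size + yn.size
    flags = list(flags)
    if bmax.sum() <= 1.96 * np.nansum(se_bmax) or bmax.sum() < 1e-4:
        flags.append("no specific component")
    fit = SiteFit(
        n_sites=n_sites,
        kd_nm=kd,
        bmax_fmol_mg=bmax,
        ns=ns,
        background=bg,
        se_kd=se_kd,
        se_bmax=se_bmax,
        se_ns=float(se[2 * n_sites]),
        residual_rss=rss,
        n_points=n_points,
        n_parameters=theta.size,
        flags=tuple(flags),
    )
    fit._cov = cov
    fit._share_bg = share_background
    return fit


def fit_one_site_global(data: BindingAssayData, share_background: bool = False) -> SiteFit:
    """Global one-site fit of total and nonspecific wells with shared NS.

    Starting values come from the data (terminal slope for NS, half-maximal
    specific binding for Kd).  Parameter standard errors derive from the
    Gauss-Newton covariance at the optimum; a saturable component whose
    Bmax confidence interval spans zero is flagged "no specific component"
    (BP is then effectively zero).
    """
    if data.n_concentrations < 4:
        raise ValueError("need at least 4 distinct concentrations")
    conc = data.concentration_nm
    spec0 = np.clip(data.total.mean(axis=1) - data.nonspecific.mean(axis=1), 0.0, None)
    bmax0 = max(float(spec0.max()), 1e-3)
    half = bmax0 / 2.0
    kd0 = float(np.interp(half, spec0, conc)) if spec0.max() > 0 else float(np.median(conc))
    kd0 = min(max(kd0, conc.min() / 10), conc.max() * 10)
    theta, cov, rss = _global_fit(data, 1, np.array([kd0]), np.array([bmax0]), share_background)
    return _build_fit(data, theta, cov, rss, 1, share_background)


def fit_two_site_global(data: BindingAssayData, share_background: bool = False) -> SiteFit:
    """Global two-site fit; sites ordered by ascending Kd.

    Starting values are taken from a small log-spaced grid of Kd pairs
    (lowest-RSS restart wins, ties to the smaller Kd1).  Poorly separated
    sites (Kd ratio < 5) and boundary-pinned components are flagged, since
    the two-site model is then not identifiable from the isotherm alone.
    """
    if data.n_concentrations < 6:
        raise ValueError("need at least 6 distinct concentrations")
    conc = data.concentration_nm
    spec0 = np.clip(data.total.mean(axis=1) - data.nonspecific.mean(axis=1), 0.0, None)
    btot = max(float(spec0.max()), 1e-3)
    kd_grid = np.geomspace(conc.min() / 2, conc.max() * 4, 5)
    best = None
    for i, k1 in enumerate(kd_grid):
        for k2 in kd_grid[i + 1 :]:
            try:
                theta, cov, rss = _global_fit(
                    data, 2, np.array([k1, k2]), np.array([btot / 2, btot / 2]), share_background
                )
            except RuntimeError:
                continue
            key = (round(rss, 9), np.exp(theta[0]))
            if best is None or key < best[0]:
                best = (key, theta, cov, rss)
    if best is None:
        raise RuntimeError("two-site global fit failed from every start")
    _, theta, cov, rss = best
    flags = []
    kd = np.sort(np.exp(theta[0:4:2]))
    bmax = theta[1:4:2]
    if kd[1] / kd[0] < 5:
        flags.append("sites poorly separated (Kd ratio < 5)")
    if np.any(bmax <= 1e-6 * max(btot, 1.0)):
        flags.append("boundary-pinned site (Bmax ~ 0); model collapses to one site")
    return _build_fit(data, theta, cov, rss, 2, share_background, flags)


def select_model(data: BindingAssayData, alpha: float = 0.05):
    """One- vs two-site selection by the extra-sum-of-squares F-test.

    Returns ``(chosen_fit, F, p)``; the two-site model is retained only if
    it improves the fit significantly at ``alpha``.
    """
    one = fit_one_site_global(data)
    two = fit_two_site_global(data)
    df1 = one.n_points - one.n_parameters
    df2 = two.n_points - two.n_parameters
    if two.residual_rss >= one.residual_rss or df2 <= 0:
        return one, 0.0, 1.0
    F = ((one.residual_rss - two.residual_rss) / (df1 - df2)) / (two.residual_rss / df2)
    p = float(stats.f.sf(F, df1 - df2, df2))
    return (two if p < alpha else one), float(F), p


# ---------------------------------------------------------------------------
# representations
# ---------------------------------------------------------------------------


def specific_binding(data: BindingAssayData, fit: SiteFit, n_grid: int = 200):
    """Specific-binding points and dense model curve.

    Points are replicate-mean total minus the fitted nonspecific line;
    the curve is the fitted saturable component on a log-spaced grid.
    Returns ``(conc, specific_points, grid, model_curve)``.
    """
    conc = data.concentration_nm
    points = data.total.mean(axis=1) - fit.model_nonspecific(conc)
    grid = np.geomspace(conc.min(), conc.max(), n_grid)
    return conc, points, grid, fit.model_specific(grid)


def scatchard_transform(specific: np.ndarray, free_nm: np.ndarray):
    """Scatchard pairs (bound, bound/free); nonpositive bound values are
    excluded and counted.  For exact one-site data the pairs fall on a line
    of slope -1/Kd with x-intercept Bmax.

    Returns ``(bound, bound_over_free, n_excluded)``.
    """
    specific = np.asarray(specific, dtype=float)
    free_nm = np.asarray(free_nm, dtype=float)
    if np.any(free_nm <= 0):
        raise ValueError("free concentrations must be positive")
    keep = specific > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} nonpositive bound value(s) from Scatchard plot",
                      stacklevel=2)
    return specific[keep], specific[keep] / free_nm[keep], n_excluded


def semilog_curve(fit: SiteFit, conc_range_nm=None, n_grid: int = 801):
    """Semilogarithmic specific-binding curve and its inflection count.

    Evaluates the fitted saturable component on a dense log10 grid and
    counts sign changes of the second derivative with respect to log L —
    the qualitative one- vs two-site diagnostic (a single site shows
    exactly one inflection, two well-separated sites show three).

    Returns ``(log10_l, specific, n_inflections)``.
    """
    if conc_range_nm is None:
        lo = float(min(fit.kd_nm.min() / 100.0, 0.01))
        hi = float(max(fit.kd_nm.max() * 100.0, 100.0))
    else:
        lo, hi = conc_range_nm
    logl = np.linspace(np.log10(lo), np.log10(hi), n_grid)
    y = fit.model_specific(10.0**logl)
    if float(y.max() - y.min()) < 1e-4:  # flat within any assay resolution
        return logl, y, 0
    d2 = np.diff(y, 2)
    tol = 1e-9 * max(float(np.abs(d2).max()), 1e-300)
    sign = np.sign(np.where(np.abs(d2) < tol, 0.0, d2))
    sign = sign[sign != 0]
    n_inflections = int(np.sum(sign[1:] != sign[:-1])) if sign.size else 0
    return logl, y, n_inflections


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------


def write_assay_csv(data: BindingAssayData, path: str | Path) -> None:
    rows = []
    for kind, mat in (("total", data.total), ("nonspecific", data.nonspecific)):
        for i, c in enumerate(data.concentration_nm):
            for r in range(mat.shape[1]):
                rows.append((c, kind, r + 1, mat[i, r]))
    if data.free_calibration is not None:
        for i, c in enumerate(data.concentration_nm):
            rows.append((c, "free", 1, data.free_calibration[i]))
    pd.DataFrame(rows, columns=["concentration_nM", "well_type", "replicate", "value"]).to_csv(
        path, index=False
    )


def read_assay_csv(path: str | Path) -> BindingAssayData:
    df = pd.read_csv(path)

    def matrix(kind):
        sub = df[df.well_type == kind]
        return sub.pivot_table(index="concentration_nM", columns="replicate", values="value").to_numpy()

    conc = np.sort(df.loc[df.well_type == "total", "concentration_nM"].unique())
    free = None
    if (df.well_type == "free").any():
        free = (
            df[df.well_type == "free"].sort_values("concentration_nM")["value"].to_numpy(float)
        )
    return BindingAssayData(conc, matrix("total"), matrix("nonspecific"), free_calibration=free)
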