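"""Cross-modality validation statistics and the end-to-end pipeline.

Per-animal multimodal records (PET BP_ND, autoradiograph ratio, Thioflavin
burden, insoluble Ab levels, biodistribution ratios) are summarised per
group, compared between severity-adjacent groups with Welch t-tests
(two-sided, unequal variances, no multiplicity correction by default),
correlated pairwise (Pearson, pairwise-complete), and checked for full
group separation of per-group value ranges.

``run_pipeline`` drives the all-synthetic workflow: cohort simulation,
kinetics and binding-assay demonstrations, group statistics, a scatter
matrix figure and a provenance log, all reproducible from one seed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "WelchResult",
    "summarize_groups",
    "welch_ttest",
    "welch_from_summary",
    "pearson_matrix",
    "group_separation",
    "SeparationResult",
    "adjacent_group_tests",
    "run_pipeline",
    "SEVERITY_ORDER",
]

#: severity staging used for adjacent-group testing
SEVERITY_ORDER = ("ctl-old", "tgtg-young", "tg-old", "tgtg-old")


@dataclass
class GroupSummary:
    group: str
    modality: str
    n: int
    mean: float
    sd: float
    min: float
    max: float
    n_missing: int = 0


def summarize_groups(
    tab: pd.DataFrame, modality: str, group_col: str = "group"
) -> list[GroupSummary]:
    """Per-group n, mean, SD (n-1 denominator), min and max; missing values
    are excluded and counted.  A single-animal group reports sd = 0 (flagged
    by n < 2)."""
    if modality not in tab.columns:
        raise ValueError(f"modality column {modality!r} not present")
    out = []
    for group, sub in tab.groupby(group_col, sort=False):
        x = sub[modality].to_numpy(float)
        missing = int(np.isnan(x).sum())
        x = x[~np.isnan(x)]
        if x.size == 0:
            raise ValueError(f"group {group!r} has no data for {modality!r}")
        out.append(
            GroupSummary(
                group=str(group),
                modality=modality,
                n=int(x.size),
                mean=float(x.mean()),
                sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
                min=float(x.min()),
                max=float(x.max()),
                n_missing=missing,
            )
        )
    return out


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def welch_ttest(a, b) -> WelchResult:
    """Two-sided Welch t-test (unequal variances, Welch-Satterthwaite df).

    If both samples have zero variance and equal means the difference is
    identically zero and p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0)
        return WelchResult(np.inf if a.mean() > b.mean() else -np.inf, float(a.size + b.size - 2), 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def welch_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> WelchResult:
    """Welch test from summary statistics (textbook Welch-Satterthwaite)."""
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def adjacent_group_tests(
    tab: pd.DataFrame,
    modality: str,
    order: Sequence[str] = SEVERITY_ORDER,
    holm: bool = False,
) -> pd.DataFrame:
    """Welch tests between severity-adjacent groups (the study's test
    sequence); optional Holm correction, off by default to mirror the
    uncorrected 5% level."""
    rows = []
    for g1, g2 in zip(order[:-1], order[1:]):
        a = tab.loc[tab.group == g1, modality]
        b = tab.loc[tab.group == g2, modality]
        res = welch_ttest(a, b)
        rows.append({"group_a": g1, "group_b": g2, "t": res.t, "df": res.df, "p": res.p})
    df = pd.DataFrame(rows)
    if holm:
        order_idx = np.argsort(df.p.to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order_idx):
            running = max(running, (m - rank) * df.p.iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_holm"] = adj
    return df


def pearson_matrix(tab: pd.DataFrame, modalities: Sequence[str]):
    """Pairwise-complete Pearson correlation matrix with per-cell n.

    Returns ``(r, n)`` DataFrames; the diagonal is 1 and the matrix is
    symmetric.  A constant column yields NaN (undefined r) with a warning.
    """
    import warnings

    sub = tab[list(modalities)].astype(float)
    k = len(modalities)
    r = np.eye(k)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        xi = sub.iloc[:, i].to_numpy()
        n[i, i] = int(np.isfinite(xi).sum())
        for j in range(i + 1, k):
            xj = sub.iloc[:, j].to_numpy()
            ok = np.isfinite(xi) & np.isfinite(xj)
            n[i, j] = n[j, i] = int(ok.sum())
            if ok.sum() < 3:
                raise ValueError(
                    f"need >= 3 complete pairs for {modalities[i]} vs {modalities[j]}"
                )
            a, b = xi[ok], xj[ok]
            if a.std() == 0 or b.std() == 0:
                warnings.warn(
                    f"constant column in pair ({modalities[i]}, {modalities[j]}); r undefined",
                    stacklevel=2,
                )
                r[i, j] = r[j, i] = np.nan
            else:
                r[i, j] = r[j, i] = float(np.corrcoef(a, b)[0, 1])
    idx = list(modalities)
    return pd.DataFrame(r, index=idx, columns=idx), pd.DataFrame(n, index=idx, columns=idx)


@dataclass
class SeparationResult:
    separated: bool
    margins: dict[tuple[str, str], float]
    overlapping_pairs: list[tuple[str, str]]


def group_separation(
    tab: pd.DataFrame, modality: str, ordered_groups: Sequence[str] = SEVERITY_ORDER
) -> SeparationResult:
    """Check whether per-group [min, max] ranges are pairwise disjoint in
    the stated severity order (full group separation).

    The margin for an adjacent pair is ``next.min - prev.max``; a negative
    margin names an overlapping pair.
    """
    present = [g for g in ordered_groups if (tab.group == g).any()]
    if len(present) < 2:
        raise ValueError("need at least 2 groups present")
    ranges = {}
    for g in present:
        x = tab.loc[tab.group == g, modality].to_numpy(float)
        x = x[~np.isnan(x)]
        ranges[g] = (float(x.min()), float(x.max()))
    margins = {}
    overlapping = []
    for g1, g2 in zip(present[:-1], present[1:]):
        margin = ranges[g2][0] - ranges[g1][1]
        margins[(g1, g2)] = margin
        if margin <= 0:
            overlapping.append((g1, g2))
    return SeparationResult(not overlapping, margins, overlapping)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

DEFAULT_PIPELINE_CONFIG: dict = {
    "stages": ["cohort", "kinetics", "assay"],
    "cohort": {"correlation": 0.7},
    "kinetics": {"schedule": "52f", "bp_nd": 0.5, "t_star_min": 5.0},
    "assay": {"kd_nm": 5.2, "bmax_fmol_mg": 200.0, "ns": 2.0, "noise_cv": 0.05},
}


def run_pipeline(config: dict | str | Path | None, out_dir: str | Path, seed: int = 0) -> dict:
    """Run the all-synthetic pipeline and write a report bundle.

    Stages (selectable via ``config["stages"]``): ``cohort`` (simulation,
    group summaries, adjacent Welch tests, Pearson scatter matrix, group
    separation), ``kinetics`` (TAC simulation and the four binding
    estimators), ``assay`` (plate simulation and the global one-site fit).
    Outputs are CSV/JSON plus a PNG scatter matrix and a provenance log;
    identical config and seed give bit-identical tables.  A stage failure
    is recorded in the report rather than aborting the run.
    """
    import pibquant

    if config is None:
        config = DEFAULT_PIPELINE_CONFIG
    elif isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", DEFAULT_PIPELINE_CONFIG["stages"])
    report: dict = {"stages": {}, "failures": {}}

    if "cohort" in stages:
        try:
            report["stages"]["cohort"] = _stage_cohort(config.get("cohort", {}), out, seed)
        except Exception as err:  # noqa: BLE001 - reported, not raised
            report["failures"]["cohort"] = repr(err)
    if "kinetics" in stages:
        try:
            report["stages"]["kinetics"] = _stage_kinetics(config.get("kinetics", {}), out, seed)
        except Exception as err:  # noqa: BLE001
            report["failures"]["kinetics"] = repr(err)
    if "assay" in stages:
        try:
            report["stages"]["assay"] = _stage_assay(config.get("assay", {}), out, seed)
        except Exception as err:  # noqa: BLE001
            report["failures"]["assay"] = repr(err)

    report["provenance"] = {
        "seed": seed,
        "config": config,
        "pibquant_version": pibquant.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _stage_cohort(cfg: dict, out: Path, seed: int) -> dict:
    from .synthetic_data import MODALITIES, default_cohort_spec, simulate_cohort

    spec = default_cohort_spec(seed=seed, correlation=cfg.get("correlation", 0.7))
    tab = simulate_cohort(spec)
    tab.to_csv(out / "cohort.csv", index=False)

    summaries = []
    for modality in MODALITIES:
        # drop groups with no data for this modality (designed missingness)
        present = tab[tab[modality].notna()]
        for s in summarize_groups(present, modality):
            summaries.append(vars(s))
    pd.DataFrame(summaries).to_csv(out / "group_summaries.csv", index=False)

    tests = adjacent_group_tests(tab, "autoradio_ratio")
    tests.to_csv(out / "adjacent_welch_tests.csv", index=False)

    modalities = [m for m in MODALITIES if tab[m].notna().sum() >= 3]
    r, n = pearson_matrix(tab, modalities)
    r.to_csv(out / "pearson_r.csv")
    n.to_csv(out / "pearson_n.csv")
    _scatter_matrix_png(tab, modalities, out / "scatter_matrix.png")

    sep = group_separation(tab, "autoradio_ratio")
    return {
        "n_animals": int(len(tab)),
        "separation_autoradio": sep.separated,
        "adjacent_p": tests.p.tolist(),
    }


def _stage_kinetics(cfg: dict, out: Path, seed: int) -> dict:
    from .kinetics import (
        estimate_k2prime,
        fit_mrtm,
        fit_mrtm2,
        ito_ratio_bp,
        static_ratio,
        write_tac_csv,
    )
    from .synthetic_data import (
        NoiseSpec,
        PlasmaInputParams,
        SRTMParams,
        make_frame_schedule,
        simulate_tac_pair,
    )

    schedule = make_frame_schedule(cfg.get("schedule", "52f"))
    params = SRTMParams.consistent(bp_nd=cfg.get("bp_nd", 0.5))
    noise = NoiseSpec(scale=cfg.get("noise_scale", 0.0))
    ref, tgt = simulate_tac_pair(PlasmaInputParams(), params, schedule, noise=noise, seed=seed)
    write_tac_csv(ref, out / "tac_reference.csv")
    write_tac_csv(tgt, out / "tac_target.csv")
    t_star = cfg.get("t_star_min", 5.0)
    mrtm = fit_mrtm(tgt, ref, t_star_min=t_star)
    k2p = estimate_k2prime(ref, [tgt] * 4, t_star_min=t_star)
    mrtm2 = fit_mrtm2(tgt, ref, k2p, t_star_min=t_star)
    results = {
        "true_bp_nd": params.bp_nd,
        "static_ratio_20_30": static_ratio(tgt, ref),
        "ito_ratio_bp": ito_ratio_bp(tgt, ref),
        "mrtm": mrtm.to_dict(),
        "mrtm2": mrtm2.to_dict(),
        "k2prime_pooled": k2p,
    }
    (out / "kinetics_fits.json").write_text(json.dumps(results, indent=2))
    return {"mrtm_bp": mrtm.bp_nd, "mrtm2_bp": mrtm2.bp_nd}


def _stage_assay(cfg: dict, out: Path, seed: int) -> dict:
    from .binding_assay import fit_one_site_global, write_assay_csv
    from .synthetic_data import SiteTruth, simulate_binding_assay

    truth = SiteTruth(
        kd=(cfg.get("kd_nm", 5.2),), bmax=(cfg.get("bmax_fmol_mg", 200.0),), ns=cfg.get("ns", 2.0)
    )
    data = simulate_binding_assay(truth, noise_cv=cfg.get("noise_cv", 0.05), seed=seed)
    write_assay_csv(data, out / "assay.csv")
    fit = fit_one_site_global(data)
    (out / "assay_fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
    return {"kd_nm": float(fit.kd_nm[0]), "bmax": float(fit.bmax_fmol_mg[0]), "bp": fit.bp}


def _scatter_matrix_png(tab: pd.DataFrame, modalities, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(modalities)
    fig, axes = plt.subplots(k, k, figsize=(2.2 * k, 2.2 * k), squeeze=False)
    colors = {"tg-old": "tab:orange", "tgtg-young": "gold", "tgtg-old": "tab:red", "ctl-old": "tab:blue"}
    for i, mi in enumerate(modalities):
        for j, mj in enumerate(modalities):
            ax = axes[i][j]
            if i == j:
                for g, sub in tab.groupby("group"):
                    ax.hist(sub[mi].dropna(), alpha=0.6, color=colors.get(g, "gray"))
            else:
                for g, sub in tab.groupby("group"):
                    ax.scatter(sub[mj], sub[mi], s=10, color=colors.get(g, "gray"), label=g)
            if i == k - 1:
                ax.set_xlabel(mj, fontsize=6)
            if j == 0:
                ax.set_ylabel(mi, fontsize=6)
            ax.tick_params(labelsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
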