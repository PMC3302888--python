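"""Tissue-count biodistribution: %ID/g and region-to-cerebellum ratios.

Tissue and standard counts are decay-corrected to injection time with the
11C decay constant; the percent injected dose per gram is

    %ID/g = 100 * (tissue counts / full-dose-equivalent standard counts) / mass

where the standard represents a known fraction of the injected dose.
Region ratios relative to the cerebellum cancel the dose, the standard
fraction and (for simultaneous counting) the decay correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .autoradiography import C11

__all__ = [
    "BiodistRecord",
    "percent_id_per_gram",
    "region_to_cerebellum_ratios",
    "biodistribution_table",
    "BRAIN_REGIONS",
]

#: dissection vocabulary of the four brain parts
BRAIN_REGIONS = (
    "olfactory system",
    "telencephalon",
    "cerebellum",
    "diencephalon and midbrain",
)


@dataclass
class BiodistRecord:
    """Gamma-counter record for one tissue of one animal."""

    tissue: str
    mass_g: float
    counts: float
    count_time_min_pi: float
    standard_counts: float
    standard_fraction: float
    standard_time_min_pi: float = 0.0

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("tissue mass must be positive")
        if self.counts < 0:
            raise ValueError("counts must be nonnegative")
        if self.standard_counts <= 0:
            raise ValueError("standard counts must be positive")
        if not 0 < self.standard_fraction <= 1:
            raise ValueError("standard fraction must be in (0, 1]")


def percent_id_per_gram(rec: BiodistRecord) -> float:
    """Percent injected dose per gram tissue, decay-corrected to injection."""
    lam = C11.lam_per_min
    tissue_at_t0 = rec.counts * np.exp(lam * rec.count_time_min_pi)
    standard_at_t0 = rec.standard_counts * np.exp(lam * rec.standard_time_min_pi)
    full_dose_counts = standard_at_t0 / rec.standard_fraction
    return 100.0 * (tissue_at_t0 / full_dose_counts) / rec.mass_g


def region_to_cerebellum_ratios(records: Iterable[BiodistRecord]) -> dict[str, float]:
    """Per-region %ID/g divided by cerebellar %ID/g (cerebellum required)."""
    records = list(records)
    values = {rec.tissue: percent_id_per_gram(rec) for rec in records}
    known = {r.tissue for r in records}
    unknown = known - set(BRAIN_REGIONS)
    if unknown:
        import warnings

        warnings.warn(f"free-text tissue name(s): {sorted(unknown)}", stacklevel=2)
    if "cerebellum" not in values:
        raise ValueError("cerebellum record is required for ratio calculation")
    cereb = values["cerebellum"]
    if cereb <= 0:
        raise ValueError("cerebellar %ID/g must be positive")
    return {tissue: v / cereb for tissue, v in values.items() if tissue != "cerebellum"}


def biodistribution_table(df: pd.DataFrame, standard_fraction: float) -> pd.DataFrame:
    """Vectorised convenience over a CSV-style table.

    Input columns: animal, tissue, mass_g, counts, count_min_pi,
    standard_counts (optionally standard_min_pi).  Returns one row per
    (animal, tissue) with pct_id_g and ratio_to_cerebellum.
    """
    out = []
    for animal, sub in df.groupby("animal", sort=False):
        recs = [
            BiodistRecord(
                tissue=row.tissue,
                mass_g=row.mass_g,
                counts=row.counts,
                count_time_min_pi=row.count_min_pi,
                standard_counts=row.standard_counts,
                standard_fraction=standard_fraction,
                standard_time_min_pi=getattr(row, "standard_min_pi", 0.0),
            )
            for row in sub.itertuples()
        ]
        pct = {r.tissue: percent_id_per_gram(r) for r in recs}
        ratios = region_to_cerebellum_ratios(recs)
        for tissue, v in pct.items():
            out.append(
                {
                    "animal": animal,
                    "tissue": tissue,
                    "pct_id_g": v,
                    "ratio_to_cerebellum": ratios.get(tissue, 1.0 if tissue == "cerebellum" else np.nan),
                }
            )
    return pd.DataFrame(out)
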