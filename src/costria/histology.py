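"""Striatal interneuron density quantification and group comparisons.

Counts come as a per-animal, per-slice region table (four rostrocaudal
slices spanning roughly +1.80 to -0.12 mm from bregma; regions DLSt, DMSt,
VSt; markers ChAT or PV). Densities are cells per square millimeter;
group summaries are reported as mean +/- SEM over animals and compared
with unpaired two-sided t tests, matching the source tables' layout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

HISTOLOGY_REGIONS = ("DLSt", "DMSt", "VSt")
MARKERS = ("ChAT", "PV")
REQUIRED_COLUMNS = ("animal_id", "group", "slice", "region", "marker", "area_mm2", "count")


def _check_table(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if (table["count"] < 0).any():
        raise ValueError("counts must be nonnegative")
    bad = set(table["slice"]) - {1, 2, 3, 4}
    if bad:
        raise ValueError(f"slice indices outside 1..4: {sorted(bad)}")


def density_per_region(table: pd.DataFrame) -> pd.DataFrame:
    """Exact density (cells/mm^2) per animal x slice x region x marker."""
    _check_table(table)
    if (table["area_mm2"] <= 0).any():
        raise ValueError("area must be positive")
    out = table.copy()
    out["density"] = out["count"] / out["area_mm2"]
    return out


def percent_decrease(mean_reference: float, mean_treated: float) -> float:
    """100 x (reference - treated) / reference.

    The definition is reference-anchored (not antisymmetric under swapping
    roles) and monotone decreasing in the treated mean.
    """
    if mean_reference <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (mean_reference - mean_treated) / mean_reference


def animal_region_density(densities: pd.DataFrame) -> pd.DataFrame:
    """Per-animal region density: total count / total area over slices."""
    g = densities.groupby(["marker", "region", "group", "animal_id"])
    out = g.agg(count=("count", "sum"), area_mm2=("area_mm2", "sum")).reset_index()
    out["density"] = out["count"] / out["area_mm2"]
    return out


def _summarize(values: np.ndarray) -> tuple[float, float, int]:
    n = len(values)
    sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return float(values.mean()), sem, n


def regional_comparison(
    densities: pd.DataFrame,
    group_a: str = "control",
    group_b: str = "VPA",
    welch: bool = False,
    by_slice: bool = False,
) -> pd.DataFrame:
    """Two-sided unpaired t tests per marker x region (or x slice).

    The sampling unit is the animal. Equal-variance t by default (``welch``
    switches to Welch's correction); groups with a single animal are
    skipped with a flag. Returns a summary frame mirroring the source
    tables: mean +/- SEM per group plus t, df, p.
    """
    keys = ["marker", "region"] + (["slice"] if by_slice else [])
    base = densities if by_slice else animal_region_density(densities)
    rows = []
    for key, sub in base.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        a = sub.loc[sub["group"] == group_a, "density"].to_numpy(float)
        b = sub.loc[sub["group"] == group_b, "density"].to_numpy(float)
        row = dict(zip(keys, key))
        if len(a):
            row["mean_a"], row["sem_a"], row["n_a"] = _summarize(a)
        if len(b):
            row["mean_b"], row["sem_b"], row["n_b"] = _summarize(b)
        if len(a) < 2 or len(b) < 2:
            row["flag"] = "comparison skipped: group with < 2 animals"
        elif a.var() == 0 and b.var() == 0 and a.mean() == b.mean():
            # degenerate but well-defined: identical constant groups
            row.update(t=0.0, p=1.0, df=float(len(a) + len(b) - 2),
                       percent_decrease=0.0, flag="")
        else:
            t, p = sps.ttest_ind(a, b, equal_var=not welch)
            row.update(
                t=float(t), p=float(p),
                df=float(len(a) + len(b) - 2) if not welch else np.nan,
                percent_decrease=percent_decrease(a.mean(), b.mean()),
                flag="",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def total_cells_per_brain(table: pd.DataFrame) -> pd.DataFrame:
    """Total immunopositive cells per animal (summed over slices/regions)."""
    _check_table(table)
    g = table.groupby(["marker", "group", "animal_id"])["count"].sum()
    return g.reset_index(name="total_cells")


def rostrocaudal_gradient(densities: pd.DataFrame) -> pd.DataFrame:
    """Density slope along the rostrocaudal axis per marker x region x group.

    OLS slope of density against slice index (1 = rostral, 4 = caudal)
    over all animal-slice points; direction is the slope's sign.
    """
    if "density" not in densities.columns:
        densities = density_per_region(densities)
    rows = []
    for (marker, region, group), sub in densities.groupby(["marker", "region", "group"]):
        x = sub["slice"].to_numpy(float)
        y = sub["density"].to_numpy(float)
        if np.unique(x).size < 2:
            raise ValueError(
                f"{marker}/{region}/{group}: need >= 2 slices for a gradient"
            )
        slope = float(((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum())
        direction = "increasing" if slope > 0 else "decreasing" if slope < 0 else "flat"
        rows.append(
            {"marker": marker, "region": region, "group": group,
             "slope": slope, "direction": direction}
        )
    return pd.DataFrame(rows)


__all__ = [
    "HISTOLOGY_REGIONS", "MARKERS", "REQUIRED_COLUMNS",
    "density_per_region", "percent_decrease", "animal_region_density",
    "regional_comparison", "total_cells_per_brain", "rostrocaudal_gradient",
]
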