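"""Published error-matrix worked examples bundled with the package.

The national assessment of the Ghana 2018 cropland maps published its
stratified area-proportion error matrices (per-pixel and segmented maps,
four zones plus the whole country).  Those printed matrices ship here as
CSV so the accuracy and adjusted-area arithmetic can be recomputed from
the cells and checked against the printed summary metrics.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .assessment import AreaErrorMatrix, accuracy_metrics, estimate_area

__all__ = [
    "load_error_matrices",
    "load_reported_metrics",
    "table2_report",
]

CLASSES = ("noncrop", "crop")


def _data_path(name: str):
    return resources.files("fieldmapper").joinpath("data", name)


def load_error_matrices(path=None) -> dict[tuple[str, str], AreaErrorMatrix]:
    """Bundled (or user-supplied) printed matrices keyed by (map, zone)."""
    src = path if path is not None else _data_path("reference_error_matrices.csv")
    df = pd.read_csv(src)
    out: dict[tuple[str, str], AreaErrorMatrix] = {}
    for (m, z), grp in df.groupby(["map", "zone"], sort=False):
        grp = grp.set_index("map_class").loc[list(CLASSES)]
        percent = grp[["ref_noncrop_pct", "ref_crop_pct"]].to_numpy()
        area = grp["area_total_km2"].iloc[0]
        out[(m, z)] = AreaErrorMatrix.from_percentages(
            CLASSES,
            percent,
            grp["n"].to_numpy(),
            None if pd.isna(area) else float(area),
        )
    return out


def load_reported_metrics() -> pd.DataFrame:
    df = pd.read_csv(_data_path("reference_reported_metrics.csv"))
    df["cls"] = df["cls"].fillna("")
    return df


def table2_report(path=None) -> pd.DataFrame:
    """Recompute every printed summary metric from the matrix cells.

    Returns rows (map, zone, metric, cls, stated_pct, recomputed_pct,
    difference).  Percentages are on the printed scale (0-100).
    """
    matrices = load_error_matrices(path)
    reported = load_reported_metrics()
    rows = []
    for _, r in reported.iterrows():
        key = (r["map"], r["zone"])
        if key not in matrices:
            continue
        m = matrices[key]
        rep = accuracy_metrics(m)
        if r["metric"] == "overall":
            value = rep.overall
        elif r["metric"] == "users":
            value = rep.users[r["cls"]]
        elif r["metric"] == "producers":
            value = rep.producers[r["cls"]]
        elif r["metric"] == "adjusted_proportion":
            value = estimate_area(m).proportions[r["cls"]]
        else:
            continue
        rows.append(
            {
                "map": r["map"],
                "zone": r["zone"],
                "metric": r["metric"],
                "cls": r["cls"],
                "stated_pct": r["value_pct"],
                "recomputed_pct": round(100 * value, 4),
                "difference": round(100 * value - r["value_pct"], 4),
            }
        )
    return pd.DataFrame(rows)


def recompute(map_name: str, zone: str, metric: str, cls: str = "") -> float:
    """One recomputed metric (percent scale) from the bundled matrices."""
    m = load_error_matrices()[(map_name, zone)]
    if metric == "overall":
        return 100 * accuracy_metrics(m).overall
    if metric == "users":
        return 100 * accuracy_metrics(m).users[cls]
    if metric == "producers":
        return 100 * accuracy_metrics(m).producers[cls]
    if metric == "adjusted_proportion":
        return 100 * estimate_area(m).proportions[cls]
    raise ValueError(f"unknown metric {metric!r}")
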