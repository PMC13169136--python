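"""Semi-quantitation by percent peak area.

Compounds are quantified relative to their own metabolite class: each
compound's integrated area under the curve (AUC, arbitrary units) is
expressed as a percentage of the summed areas of its class, and each class
as a percentage of the grand total (area-weighted).  No calibration curves
are involved; the numbers compare compounds within one run, not across
instruments.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["class_percentages", "read_area_table", "write_percentages"]

REQUIRED_COLUMNS = ("compound_id", "class", "area")


def read_area_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: area table lacks column(s) {missing}")
    return df


def class_percentages(areas: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent peak area per compound (within class) and per class (of total).

    ``areas`` needs columns ``compound_id``, ``class`` and ``area`` (>= 0).
    Returns ``(per_compound, per_class)``; within each class the compound
    percentages sum to 100, as do the class shares.  A class whose areas sum
    to zero has undefined percentages, reported as NaN.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in areas.columns]
    if missing:
        raise ValueError(f"area table lacks column(s) {missing}")
    if (areas["area"] < 0).any():
        raise ValueError("areas must be non-negative")

    df = areas.copy()
    class_totals = df.groupby("class")["area"].transform("sum")
    df["pct_of_class"] = (df["area"] / class_totals) * 100.0

    per_class = (
        df.groupby("class", as_index=False)["area"].sum().rename(
            columns={"area": "class_area"}
        )
    )
    grand = per_class["class_area"].sum()
    per_class["pct_of_total"] = (
        per_class["class_area"] / grand * 100.0 if grand > 0 else float("nan")
    )
    return df[["compound_id", "class", "area", "pct_of_class"]], per_class


def write_percentages(
    path: str | Path, per_compound: pd.DataFrame, per_class: pd.DataFrame
) -> None:
    """Write both percentage tables into one TSV (class rows marked)."""
    comp = per_compound.copy()
    cls = per_class.rename(
        columns={"class_area": "area", "pct_of_total": "pct_of_class"}
    )
    cls.insert(0, "compound_id", "TOTAL:" + cls["class"])
    pd.concat([comp, cls], ignore_index=True).to_csv(path, sep="\t", index=False)
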