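"""Readers and writers for the long-format CSV interchange tables.

Germination counts travel as one row per dish x inspection day
(``accession, treatment_mM, replicate, day, new_germinated, n_sown,
abnormal_final``); seedling morphometry as one row per seedling
(``accession, treatment_mM, box, seedling, shoot_mm, main_root_mm,
lateral_root_mm``).  Both round-trip exactly through the corresponding
writer.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    DishCounts,
    GerminationPanel,
    InspectionSchedule,
    SeedlingBox,
    SeedlingPanel,
)

__all__ = [
    "read_germination_table",
    "write_germination_table",
    "read_seedling_table",
    "write_seedling_table",
]

log = logging.getLogger(__name__)

GERM_COLUMNS = [
    "accession",
    "treatment_mM",
    "replicate",
    "day",
    "new_germinated",
    "n_sown",
    "abnormal_final",
]

SEEDLING_COLUMNS = [
    "accession",
    "treatment_mM",
    "box",
    "seedling",
    "shoot_mm",
    "main_root_mm",
    "lateral_root_mm",
]


class TableFormatError(ValueError):
    """The CSV is missing required columns or is structurally malformed."""


class TableValidationError(ValueError):
    """The CSV parsed but violates a count/length invariant."""


def read_germination_table(
    path: str | Path,
    schedule: InspectionSchedule,
    cumulative: bool = False,
) -> GerminationPanel:
    """Read a long-format germination-count CSV into a panel.

    ``abnormal_final`` needs to be populated only on final-day rows.  With
    ``cumulative=True`` the ``new_germinated`` column is interpreted as
    cumulative germinated counts and differenced; decreases are rejected.
    """
    df = pd.read_csv(path)
    if df.empty and df.columns.size == 0:
        log.warning("germination table %s is empty", path)
        return GerminationPanel([], schedule)
    missing = [c for c in GERM_COLUMNS if c not in df.columns and c != "abnormal_final"]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    if "abnormal_final" not in df.columns:
        df["abnormal_final"] = np.nan

    bad_days = sorted(set(df["day"].astype(float)) - set(schedule.times))
    if bad_days:
        raise TableValidationError(
            f"{path}: day(s) {bad_days} are not in the schedule {list(schedule.times)}"
        )

    dishes: list[DishCounts] = []
    for (acc, trt, rep), grp in df.groupby(
        ["accession", "treatment_mM", "replicate"], sort=False
    ):
        key = (str(acc), float(trt), str(rep))
        days = grp["day"].astype(float)
        if days.duplicated().any():
            dup = sorted(days[days.duplicated()].unique())
            raise TableValidationError(
                f"dish {key}: duplicated day row(s) {dup}"
            )
        n_sown = grp["n_sown"].astype(int)
        if n_sown.nunique() > 1:
            raise TableValidationError(f"dish {key}: inconsistent n_sown")
        counts = grp.sort_values("day")
        values = counts["new_germinated"].astype(int).to_numpy()
        day_order = counts["day"].astype(float).to_numpy()
        if cumulative:
            diffs = np.diff(np.concatenate([[0], values]))
            if np.any(diffs < 0):
                raise TableValidationError(
                    f"dish {key}: cumulative counts decrease over time"
                )
            values = diffs
        new_germ = dict(zip(day_order, (int(v) for v in values)))
        total = int(sum(new_germ.values()))
        if total > int(n_sown.iloc[0]):
            raise TableValidationError(
                f"dish {key}: germinated total {total} exceeds "
                f"sown {int(n_sown.iloc[0])}"
            )
        final_rows = counts[counts["day"].astype(float) == schedule.final_time]
        abnormal = 0
        if not final_rows.empty:
            val = final_rows["abnormal_final"].iloc[-1]
            abnormal = 0 if pd.isna(val) else int(val)
        dishes.append(
            DishCounts(
                accession=str(acc),
                treatment_mM=float(trt),
                replicate=str(rep),
                n_sown=int(n_sown.iloc[0]),
                new_germ=new_germ,
                n_abnormal=abnormal,
            )
        )
    if not dishes:
        log.warning("germination table %s contains no dishes", path)
    return GerminationPanel(dishes, schedule)


def write_germination_table(panel: GerminationPanel, path: str | Path) -> None:
    """Write a panel back to the long CSV format (exact round trip)."""
    rows = []
    for dish in panel.dishes:
        for day in sorted(dish.new_germ):
            rows.append(
                {
                    "accession": dish.accession,
                    "treatment_mM": dish.treatment_mM,
                    "replicate": dish.replicate,
                    "day": day,
                    "new_germinated": dish.new_germ[day],
                    "n_sown": dish.n_sown,
                    "abnormal_final": dish.n_abnormal
                    if day == panel.schedule.final_time
                    else np.nan,
                }
            )
    pd.DataFrame(rows, columns=GERM_COLUMNS).to_csv(path, index=False)


def read_seedling_table(
    path: str | Path,
    germinability: dict[tuple[str, float], float] | None = None,
) -> SeedlingPanel:
    """Read a per-seedling morphometry CSV into a box panel.

    ``germinability`` optionally maps (accession, treatment_mM) to the
    germination percentage from the germination screen, attached to each box
    for the vigor index.
    """
    df = pd.read_csv(path)
    missing = [c for c in SEEDLING_COLUMNS if c not in df.columns and c != "seedling"]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    lengths_cols = ["shoot_mm", "main_root_mm", "lateral_root_mm"]
    if (df[lengths_cols].to_numpy(dtype=float) < 0).any():
        bad = df[(df[lengths_cols] < 0).any(axis=1)].iloc[0]
        raise TableValidationError(
            f"negative length for accession {bad['accession']} box {bad['box']}"
        )
    boxes: list[SeedlingBox] = []
    for (acc, trt, box), grp in df.groupby(
        ["accession", "treatment_mM", "box"], sort=False
    ):
        germ = None
        if germinability is not None:
            germ = germinability.get((str(acc), float(trt)))
        boxes.append(
            SeedlingBox(
                accession=str(acc),
                treatment_mM=float(trt),
                box=str(box),
                lengths=grp[lengths_cols].to_numpy(dtype=float),
                germinability_pct=germ,
            )
        )
    if not boxes:
        log.warning("seedling table %s contains no boxes", path)
    return SeedlingPanel(boxes)


def write_seedling_table(panel: SeedlingPanel, path: str | Path) -> None:
    rows = []
    for b in panel.boxes:
        for i, (shoot, main, lat) in enumerate(b.lengths, start=1):
            rows.append(
                {
                    "accession": b.accession,
                    "treatment_mM": b.treatment_mM,
                    "box": b.box,
                    "seedling": i,
                    "shoot_mm": shoot,
                    "main_root_mm": main,
                    "lateral_root_mm": lat,
                }
            )
    pd.DataFrame(rows, columns=SEEDLING_COLUMNS).to_csv(path, index=False)
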