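"""Core data model for germination-count and seedling-morphometry panels.

A germination trial records, for each petri dish, the number of *newly*
germinated seeds at each inspection day after sowing (DAS) plus the number of
morphologically abnormal seedlings at the final count.  A seedling trial
records per-seedling shoot, main-root and lateral-root lengths per germination
box.  Both are collected into panel containers spanning
accession x treatment x replicate, sharing one inspection schedule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "InspectionSchedule",
    "DishCounts",
    "SeedlingBox",
    "GerminationPanel",
    "SeedlingPanel",
    "Diagnostic",
    "validate_panel",
]


@dataclass(frozen=True)
class InspectionSchedule:
    """Ordered inspection days (DAS) at which germination was counted.

    The trials scored germination at 1, 2, 3 and 6 DAS; any strictly
    increasing positive sequence is accepted.
    """

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        if len(times) == 0:
            raise ValueError("schedule needs at least one inspection day")
        if any(t <= 0 for t in times):
            raise ValueError("inspection days must be positive (DAS)")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("inspection days must be strictly increasing")
        object.__setattr__(self, "times", times)

    @property
    def final_time(self) -> float:
        return self.times[-1]

    @property
    def intervals(self) -> tuple[tuple[float, float], ...]:
        """Censoring intervals (D_{t-1}, D_t] induced by the schedule, D_0 = 0."""
        lefts = (0.0,) + self.times[:-1]
        return tuple(zip(lefts, self.times))

    @classmethod
    def from_string(cls, text: str) -> "InspectionSchedule":
        """Parse a comma-separated day list such as ``"1,2,3,6"``."""
        return cls(tuple(float(x) for x in text.split(",") if x.strip()))

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self) -> Iterator[float]:
        return iter(self.times)


@dataclass
class DishCounts:
    """One petri dish: sown seeds, new germinations per day, abnormal count.

    ``new_germ`` maps inspection day -> seeds newly germinated since the
    previous inspection (N_t, not cumulative).  ``n_abnormal`` is the number of
    abnormal seedlings among all germinated at the final count.
    """

    accession: str
    treatment_mM: float
    replicate: str
    n_sown: int
    new_germ: dict[float, int]
    n_abnormal: int = 0

    def __post_init__(self) -> None:
        self.new_germ = {float(d): int(n) for d, n in self.new_germ.items()}

    @property
    def g_final(self) -> int:
        """Total germinated seeds at the final count (G6 in a 6-DAS trial)."""
        return int(sum(self.new_germ.values()))

    @property
    def n_normal(self) -> int:
        """Normal seedlings at the final count: germinated minus abnormal."""
        return self.g_final - self.n_abnormal

    @property
    def key(self) -> tuple[str, float, str]:
        return (self.accession, self.treatment_mM, self.replicate)

    def counts_in_order(self, schedule: InspectionSchedule) -> np.ndarray:
        """New-germination counts aligned to the schedule; raises if incomplete."""
        missing = [d for d in schedule.times if d not in self.new_germ]
        if missing:
            raise ValueError(
                f"dish {self.key}: no count for inspection day(s) {missing}"
            )
        return np.array([self.new_germ[d] for d in schedule.times], dtype=int)

    def problems(self, schedule: InspectionSchedule | None = None) -> list[str]:
        """Invariant violations for this dish, as human-readable strings."""
        out: list[str] = []
        if self.n_sown <= 0:
            out.append("n_sown must be positive")
        if self.treatment_mM < 0:
            out.append("treatment (mM NaCl) must be non-negative")
        if any(n < 0 for n in self.new_germ.values()):
            out.append("negative germination count")
        if self.g_final > self.n_sown:
            out.append(
                f"germinated total {self.g_final} exceeds sown {self.n_sown}"
            )
        if self.n_abnormal < 0 or self.n_abnormal > self.g_final:
            out.append(
                f"abnormal count {self.n_abnormal} outside [0, {self.g_final}]"
            )
        if schedule is not None:
            extra = sorted(set(self.new_germ) - set(schedule.times))
            if extra:
                out.append(f"days outside the schedule: {extra}")
            missing = [d for d in schedule.times if d not in self.new_germ]
            if missing:
                out.append(f"incomplete schedule: missing day(s) {missing}")
        return out


@dataclass
class SeedlingBox:
    """One germination box of measured seedlings.

    ``lengths`` is an (n, 3) array of per-seedling (shoot, main-root,
    lateral-root) lengths in mm; a box may hold fewer seedlings than sown.
    ``germinability_pct`` is the accession x treatment germination percentage
    carried over from the germination screen, used by the vigor index.
    """

    accession: str
    treatment_mM: float
    box: str
    lengths: np.ndarray
    germinability_pct: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.lengths, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("lengths must be an (n, 3) array of mm values")
        self.lengths = arr

    @property
    def n_seedlings(self) -> int:
        return self.lengths.shape[0]

    @property
    def key(self) -> tuple[str, float, str]:
        return (self.accession, self.treatment_mM, self.box)

    def trait_means(self) -> np.ndarray:
        """Mean (shoot, main root, lateral root) length over measured seedlings."""
        if self.n_seedlings == 0:
            raise ValueError(f"box {self.key}: no seedlings measured")
        return self.lengths.mean(axis=0)

    def problems(self) -> list[str]:
        out: list[str] = []
        if self.treatment_mM < 0:
            out.append("treatment (mM NaCl) must be non-negative")
        if np.any(self.lengths < 0):
            out.append("negative seedling length")
        if self.germinability_pct is not None and not (
            0 <= self.germinability_pct <= 100
        ):
            out.append(f"germinability {self.germinability_pct} outside [0, 100]")
        return out


@dataclass
class GerminationPanel:
    """Collection of dishes spanning accessions x treatments x replicates."""

    dishes: list[DishCounts]
    schedule: InspectionSchedule

    def __len__(self) -> int:
        return len(self.dishes)

    def __iter__(self) -> Iterator[DishCounts]:
        return iter(self.dishes)

    @property
    def accessions(self) -> list[str]:
        seen = dict.fromkeys(d.accession for d in self.dishes)
        return list(seen)

    @property
    def treatments(self) -> list[float]:
        return sorted({d.treatment_mM for d in self.dishes})

    def subset(
        self,
        accession: str | None = None,
        treatment_mM: float | None = None,
    ) -> "GerminationPanel":
        keep = [
            d
            for d in self.dishes
            if (accession is None or d.accession == accession)
            and (treatment_mM is None or d.treatment_mM == treatment_mM)
        ]
        return GerminationPanel(keep, self.schedule)


@dataclass
class SeedlingPanel:
    """Collection of seedling boxes spanning accessions x treatments."""

    boxes: list[SeedlingBox]

    def __len__(self) -> int:
        return len(self.boxes)

    def __iter__(self) -> Iterator[SeedlingBox]:
        return iter(self.boxes)

    @property
    def accessions(self) -> list[str]:
        seen = dict.fromkeys(b.accession for b in self.boxes)
        return list(seen)


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding, attached to the offending dish/box key."""

    key: tuple
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.key}: {self.message}"


def validate_panel(panel: GerminationPanel | SeedlingPanel) -> list[Diagnostic]:
    """Check every type invariant; returns one diagnostic per violation.

    Diagnostics, not exceptions: a well-formed panel yields an empty list and
    no valid input raises.
    """
    out: list[Diagnostic] = []
    if isinstance(panel, GerminationPanel):
        seen: set[tuple] = set()
        for dish in panel.dishes:
            for msg in dish.problems(panel.schedule):
                out.append(Diagnostic(dish.key, msg))
            if dish.key in seen:
                out.append(Diagnostic(dish.key, "duplicate dish"))
            seen.add(dish.key)
    else:
        seen = set()
        for box in panel.boxes:
            for msg in box.problems():
                out.append(Diagnostic(box.key, msg))
            if box.key in seen:
                out.append(Diagnostic(box.key, "duplicate box"))
            seen.add(box.key)
    return out
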