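"""Shared fixtures: worked dishes, small panels, random-instance generators."""

from __future__ import annotations

import numpy as np
import pytest

from germscreen.data import DishCounts, GerminationPanel, InspectionSchedule
from germscreen.timetoevent import SeedIntervals


@pytest.fixture
def schedule() -> InspectionSchedule:
    return InspectionSchedule((1, 2, 3, 6))


@pytest.fixture
def worked_dish() -> DishCounts:
    """The reference dish: 10/20/5/0 new germinations of 50 sown, 3 abnormal."""
    return DishCounts("CCE-X", 0.0, "r1", 50, {1: 10, 2: 20, 3: 5, 6: 0}, 3)


@pytest.fixture
def worked_dish_3day() -> tuple[DishCounts, InspectionSchedule]:
    """Index worked example: 20/20/10 at days 1/2/3, 50 sown, 45 normal."""
    sched = InspectionSchedule((1, 2, 3))
    return DishCounts("W", 0.0, "r1", 50, {1: 20, 2: 20, 3: 10}, 5), sched


def random_interval_instance(
    rng: np.random.Generator,
    max_obs: int = 12,
    max_turnbull: int = 4,
) -> SeedIntervals | None:
    """A random small interval-censored instance with few Turnbull intervals.

    Endpoints are drawn from a day grid plus infinity; instances whose
    innermost-interval count exceeds ``max_turnbull`` are rejected (return
    None) so callers can resample.
    """
    from germscreen.timetoevent import turnbull_intervals

    days = np.array([0.0, 1.0, 2.0, 3.0, 6.0])
    n = int(rng.integers(2, max_obs + 1))
    lefts = []
    rights = []
    for _ in range(n):
        i = int(rng.integers(0, len(days)))
        if i == len(days) - 1 or rng.random() < 0.2:
            lefts.append(days[i] if i < len(days) else days[-1])
            rights.append(np.inf)
        else:
            j = int(rng.integers(i + 1, len(days) + 1))
            if j >= len(days):
                rights.append(np.inf)
            else:
                rights.append(days[j])
            lefts.append(days[i])
    data = SeedIntervals(
        np.array(lefts), np.array(rights), ["g"] * n, ["d"] * n
    )
    if turnbull_intervals(data).shape[0] > max_turnbull:
        return None
    return data


def brute_force_loglik(data: SeedIntervals, step: float = 0.01) -> float:
    """Grid-search maximum of the interval-censored log-likelihood.

    Enumerates every probability vector on the Turnbull intervals whose
    masses are multiples of ``step`` and returns the best attained
    log-likelihood — an oracle independent of the EM path.
    """
    from itertools import product

    from germscreen.timetoevent import turnbull_intervals

    ivals = turnbull_intervals(data)
    J = ivals.shape[0]
    A = (
        (ivals[None, :, 0] >= data.left[:, None])
        & (ivals[None, :, 1] <= data.right[:, None])
    ).astype(float)
    m = int(round(1.0 / step))
    if J == 1:
        return 0.0  # all mass on the single interval; log-lik sum of log(1)
    grids = _compositions(m, J) * step  # (P, J)
    with np.errstate(divide="ignore"):
        ll = np.log(grids @ A.T).sum(axis=1)
    return float(np.max(ll))


_COMP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _compositions(total: int, parts: int) -> np.ndarray:
    """All non-negative integer vectors of length ``parts`` summing to total.

    Stars-and-bars enumeration, cached (J <= 4 at step 0.01 is ~177k rows).
    """
    from itertools import combinations

    key = (total, parts)
    if key not in _COMP_CACHE:
        bars = np.array(
            list(combinations(range(total + parts - 1), parts - 1)), dtype=int
        )
        padded = np.hstack(
            [
                np.full((bars.shape[0], 1), -1),
                bars,
                np.full((bars.shape[0], 1), total + parts - 1),
            ]
        )
        _COMP_CACHE[key] = np.diff(padded, axis=1) - 1
    return _COMP_CACHE[key]
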