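"""Nonparametric time-to-event analysis of interval-censored germination.

Each seed's germination time is known only up to the interval between two
consecutive inspections, (L, R]; seeds that never germinate within the trial
are right-censored on (final_day, inf).  The cumulative germination curve is
estimated by the Turnbull nonparametric maximum-likelihood estimator (NPMLE),
fitted with the self-consistency EM iteration.  On top of the fit this module
provides quantile extraction (T50) with a bootstrap standard error,
generalized Wilcoxon scores against the pooled fit, and a permutation test
for equality of group curves.

Notation: F(t) is the cumulative probability of having germinated by t on the
sown-seed scale (so F(final) is the germinable fraction and 1 - F(final) the
right-censored mass); S = 1 - F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .data import DishCounts, GerminationPanel, InspectionSchedule

__all__ = [
    "SeedIntervals",
    "NPMLEFit",
    "QuantileEstimate",
    "GroupComparison",
    "counts_to_intervals",
    "panel_to_intervals",
    "turnbull_intervals",
    "fit_npmle",
    "cdf_at",
    "quantile_time",
    "t50_germinated",
    "bootstrap_quantile_se",
    "wilcoxon_scores",
    "permutation_test",
]


def _object_array(values) -> np.ndarray:
    """1-D object array of labels; keeps tuples as scalar elements."""
    values = list(values)
    arr = np.empty(len(values), dtype=object)
    arr[:] = values
    return arr


def label_mask(labels: np.ndarray, value: object) -> np.ndarray:
    """Elementwise equality mask that treats tuple labels as scalars."""
    return np.fromiter((x == value for x in labels), dtype=bool, count=len(labels))


@dataclass
class SeedIntervals:
    """A multiset of censoring intervals (L, R] with group and dish labels.

    ``right`` may be ``np.inf`` for seeds that never germinated within the
    observation window.
    """

    left: np.ndarray
    right: np.ndarray
    group: np.ndarray
    dish: np.ndarray

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.group = _object_array(self.group)
        self.dish = _object_array(self.dish)
        n = self.left.size
        if not (self.right.size == self.group.size == self.dish.size == n):
            raise ValueError("left/right/group/dish must have equal length")
        if np.any(self.left < 0):
            raise ValueError("interval left endpoints must be >= 0")
        if np.any(self.right <= self.left):
            raise ValueError("intervals must satisfy R > L")

    @property
    def n(self) -> int:
        return int(self.left.size)

    @property
    def groups(self) -> list:
        seen = dict.fromkeys(self.group.tolist())
        return list(seen)

    def subset(self, mask: np.ndarray) -> "SeedIntervals":
        return SeedIntervals(
            self.left[mask], self.right[mask], self.group[mask], self.dish[mask]
        )

    @classmethod
    def concat(cls, parts: Sequence["SeedIntervals"]) -> "SeedIntervals":
        return cls(
            np.concatenate([p.left for p in parts]),
            np.concatenate([p.right for p in parts]),
            np.concatenate([p.group for p in parts]),
            np.concatenate([p.dish for p in parts]),
        )


def counts_to_intervals(
    dish: DishCounts,
    schedule: InspectionSchedule,
    group: object | None = None,
) -> SeedIntervals:
    """Expand dish counts into per-seed censoring intervals.

    The N_t seeds first seen germinated at inspection D_t get (D_{t-1}, D_t]
    with D_0 = 0 (germination cannot precede sowing); the n_sown - G seeds
    never seen germinated get (final_day, inf).
    """
    counts = dish.counts_in_order(schedule)
    lefts: list[float] = []
    rights: list[float] = []
    for (lo, hi), n in zip(schedule.intervals, counts):
        lefts.extend([lo] * int(n))
        rights.extend([hi] * int(n))
    n_cens = dish.n_sown - int(counts.sum())
    if n_cens < 0:
        raise ValueError(f"dish {dish.key}: germinated total exceeds sown")
    lefts.extend([schedule.final_time] * n_cens)
    rights.extend([np.inf] * n_cens)
    label = group if group is not None else (dish.accession, dish.treatment_mM)
    m = len(lefts)
    return SeedIntervals(
        np.array(lefts),
        np.array(rights),
        [label] * m,
        ["|".join(map(str, dish.key))] * m,
    )


def panel_to_intervals(
    panel: GerminationPanel,
    group_by: str = "accession_treatment",
) -> SeedIntervals:
    """Expand a whole panel; ``group_by`` one of ``accession_treatment``,
    ``accession``, ``treatment``."""
    parts = []
    for dish in panel.dishes:
        if group_by == "accession":
            label: object = dish.accession
        elif group_by == "treatment":
            label = dish.treatment_mM
        else:
            label = (dish.accession, dish.treatment_mM)
        parts.append(counts_to_intervals(dish, panel.schedule, group=label))
    if not parts:
        raise ValueError("panel has no dishes")
    return SeedIntervals.concat(parts)


# ---------------------------------------------------------------------------
# Turnbull NPMLE
# ---------------------------------------------------------------------------


def turnbull_intervals(data: SeedIntervals) -> np.ndarray:
    """Maximal-intersection (innermost) intervals supporting all NPMLE mass.

    A candidate (q, p] qualifies when q is some observation's left endpoint,
    p is the smallest endpoint strictly greater than q, and p is some
    observation's right endpoint — i.e. no other endpoint falls strictly
    inside (q, p).
    """
    lefts = np.unique(data.left)
    rights = np.unique(data.right)
    all_pts = np.unique(np.concatenate([lefts, rights]))
    right_set = set(rights.tolist())
    out = []
    for q in lefts:
        above = all_pts[all_pts > q]
        if above.size == 0:
            continue
        p = above[0]
        if p in right_set:
            out.append((q, p))
    if not out:
        raise ValueError("no Turnbull interval found (malformed data)")
    return np.array(out, dtype=float)


@dataclass
class NPMLEFit:
    """Turnbull NPMLE: support intervals, masses and the induced step CDF."""

    intervals: np.ndarray  # (J, 2) columns (q_j, p_j], ordered
    masses: np.ndarray  # w_j >= 0, sum 1 (right-censored mass included)
    loglik: float
    n_iter: int
    converged: bool
    n: int

    @property
    def cum_masses(self) -> np.ndarray:
        return np.cumsum(self.masses)

    @property
    def finite_max(self) -> float:
        """Largest F value attained at a finite time (germinable fraction)."""
        finite = np.isfinite(self.intervals[:, 1])
        if not finite.any():
            return 0.0
        return float(self.cum_masses[np.where(finite)[0][-1]])

    def survival(self, t: float | np.ndarray) -> np.ndarray:
        return 1.0 - _cdf_values(self, np.asarray(t, dtype=float))


class CdfPoint(NamedTuple):
    prob: float
    indeterminate: bool


def _cdf_values(fit: NPMLEFit, t: np.ndarray) -> np.ndarray:
    """Vectorized F(t) using linear interpolation inside Turnbull intervals.

    Outside the support the NPMLE is flat and fully determined; inside a
    Turnbull interval any non-decreasing path is an NPMLE, and the linear
    path is the declared representation policy.  Mass on an unbounded final
    interval accrues only at +inf.
    """
    q = fit.intervals[:, 0]
    p = fit.intervals[:, 1]
    cum = fit.cum_masses
    prev = np.concatenate([[0.0], cum[:-1]])
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    for i, ti in enumerate(t):
        if np.isinf(ti):
            out[i] = 1.0
            continue
        # completed intervals
        done = p <= ti
        val = cum[done][-1] if done.any() else 0.0
        # inside an interval?
        inside = (q < ti) & (ti < p)
        j = np.where(inside)[0]
        if j.size:
            jj = j[0]
            if np.isfinite(p[jj]):
                frac = (ti - q[jj]) / (p[jj] - q[jj])
                val = max(val, prev[jj] + fit.masses[jj] * frac)
            else:
                val = max(val, prev[jj])
        out[i] = val
    return out


def cdf_at(fit: NPMLEFit, t: float) -> CdfPoint:
    """F(t) with a flag marking representational indeterminacy.

    Exact at Turnbull right endpoints and on plateaus between intervals;
    inside a Turnbull interval the value follows the linear-interpolation
    policy and ``indeterminate`` is True (the region the study's curves shade
    as censoring uncertainty).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    val = float(_cdf_values(fit, np.array([t]))[0])
    q = fit.intervals[:, 0]
    p = fit.intervals[:, 1]
    inside = bool(np.any((q < t) & (t < p) & (fit.masses > 0)))
    return CdfPoint(val, inside)


def fit_npmle(
    data: SeedIntervals,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    gap_tol: float = 1e-6,
) -> NPMLEFit:
    """Fit the Turnbull NPMLE by self-consistency EM from uniform masses.

    The log-likelihood sum_i log sum_{j: (q_j,p_j] subset (L_i,R_i]} w_j is
    concave over the simplex on the Turnbull intervals, and the EM update
    w_j <- w_j/n * sum_i alpha_ij / sum_k alpha_ik w_k never decreases it.
    Convergence is declared when max_j |Delta w_j| < tol, or when the
    certified optimality gap falls below ``gap_tol``: by concavity the
    attained log-likelihood is within n * (max_j d_j - 1) of the optimum,
    where d_j = (1/n) sum_i alpha_ij / P_i is the EM multiplier (masses
    shrinking to a boundary zero approach it only sublinearly, while the
    objective stabilizes long before).  Failure to converge within
    ``max_iter`` is flagged, never silent.
    """
    if data.n == 0:
        raise ValueError("need at least one interval")
    ivals = turnbull_intervals(data)
    J = ivals.shape[0]
    # alpha_ij = 1 if Turnbull interval j lies inside observation i's interval
    alpha = (ivals[None, :, 0] >= data.left[:, None]) & (
        ivals[None, :, 1] <= data.right[:, None]
    )
    if not alpha.any(axis=1).all():
        raise ValueError("an observation contains no Turnbull interval")
    A = alpha.astype(float)
    n = data.n
    w = np.full(J, 1.0 / J)
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = A @ w  # P(observation i) under current masses
        loglik = float(np.log(denom).sum())
        d = (A.T @ (1.0 / denom)) / n  # EM multipliers; optimality gap bound
        w_new = w * d
        delta = float(np.max(np.abs(w_new - w)))
        gap_bound = n * (float(d.max()) - 1.0)
        w = w_new
        if delta < tol or gap_bound < gap_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"NPMLE EM did not converge within {max_iter} iterations",
            RuntimeWarning,
        )
    denom = A @ w
    loglik = float(np.log(denom).sum())
    return NPMLEFit(
        intervals=ivals,
        masses=w,
        loglik=loglik,
        n_iter=it,
        converged=converged,
        n=n,
    )


# ---------------------------------------------------------------------------
# Quantiles
# ---------------------------------------------------------------------------


@dataclass
class QuantileEstimate:
    """A CDF quantile (e.g. T50) with optional bootstrap standard error."""

    p: float
    time: float  # NaN when undefined
    se: float = float("nan")
    n_boot: int = 0
    n_undefined: int = 0

    @property
    def defined(self) -> bool:
        return np.isfinite(self.time)


def quantile_time(fit: NPMLEFit, p: float) -> QuantileEstimate:
    """Smallest t with F(t) >= p, interpolating linearly across the crossing
    Turnbull interval; undefined (NaN, not an exception) when the attainable
    F at finite times stays below p."""
    if not 0 < p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    eps = 1e-12
    if fit.finite_max < p - eps:
        return QuantileEstimate(p=p, time=float("nan"))
    q = fit.intervals[:, 0]
    pe = fit.intervals[:, 1]
    cum = fit.cum_masses
    prev = 0.0
    for j in range(len(cum)):
        if cum[j] >= p - eps:
            if p <= prev + eps:
                # already reached at the previous right endpoint
                return QuantileEstimate(p=p, time=float(pe[j - 1]))
            w = cum[j] - prev
            frac = (p - prev) / w if w > 0 else 1.0
            t = q[j] + frac * (pe[j] - q[j])
            return QuantileEstimate(p=p, time=float(t))
        prev = cum[j]
    return QuantileEstimate(p=p, time=float("nan"))  # pragma: no cover


def t50_germinated(fit: NPMLEFit) -> QuantileEstimate:
    """Time to reach 50% of the *germinated* seeds (the reported T50).

    The target is half the germinable fraction, 0.5 * F(final), so the value
    is invariant to the non-germinating share and estimates the latent median
    germination time of viable seeds.
    """
    target = 0.5 * fit.finite_max
    if target <= 0:
        return QuantileEstimate(p=0.5, time=float("nan"))
    est = quantile_time(fit, target)
    return QuantileEstimate(p=0.5, time=est.time)


def bootstrap_quantile_se(
    data: SeedIntervals,
    p: float = 0.5,
    n_boot: int = 500,
    seed: int | np.random.Generator | None = None,
    relative: bool = False,
) -> QuantileEstimate:
    """Bootstrap SE of a quantile, resampling seeds within dishes.

    Each replicate resamples seeds with replacement inside every dish
    (preserving the experimental design), refits the NPMLE and re-extracts
    the quantile.  With ``relative=True`` the target is 0.5 * F(final) per
    replicate (the reported T50 definition).  Replicates with an undefined
    quantile are dropped and counted; if more than half are undefined the SE
    is reported undefined.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fit = fit_npmle(data)
    point = t50_germinated(fit) if relative else quantile_time(fit, p)
    dish_idx = {d: np.where(data.dish == d)[0] for d in dict.fromkeys(data.dish.tolist())}
    times = []
    n_undef = 0
    for _ in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx, size=idx.size, replace=True) for idx in dish_idx.values()]
        )
        bfit = fit_npmle(data.subset(take))
        est = t50_germinated(bfit) if relative else quantile_time(bfit, p)
        if est.defined:
            times.append(est.time)
        else:
            n_undef += 1
    if n_undef > n_boot / 2 or len(times) < 2:
        se = float("nan")
    else:
        se = float(np.std(times, ddof=1))
    return QuantileEstimate(
        p=point.p,
        time=point.time,
        se=se,
        n_boot=n_boot - n_undef,
        n_undefined=n_undef,
    )


# ---------------------------------------------------------------------------
# Generalized Wilcoxon scores and the permutation test
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Per-group generalized Wilcoxon score sums and permutation inference."""

    group_scores: dict
    group_sizes: dict
    statistic: float = float("nan")
    p_value: float = float("nan")
    n_permutations: int = 0
    pooled_fit: NPMLEFit | None = None
    seed_scores: np.ndarray | None = None


def _seed_scores(data: SeedIntervals, fit: NPMLEFit) -> np.ndarray:
    """u_i = S(L_i) + S(R_i) - 1 against the pooled fit, with S(inf) = 0."""
    s_left = 1.0 - _cdf_values(fit, data.left)
    s_right = 1.0 - _cdf_values(fit, data.right)  # F(inf) = 1 so S(inf) = 0
    return s_left + s_right - 1.0


def wilcoxon_scores(data: SeedIntervals) -> GroupComparison:
    """Generalized Wilcoxon score sums per group against the pooled NPMLE.

    A positive group sum means the group germinated earlier than the pooled
    sample, a negative one later; across all groups the per-seed scores sum
    to approximately zero.
    """
    groups = data.groups
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    masks = {g: label_mask(data.group, g) for g in groups}
    sizes = {g: int(m.sum()) for g, m in masks.items()}
    if any(s == 0 for s in sizes.values()):
        raise ValueError("every group needs at least one seed")
    fit = fit_npmle(data)
    u = _seed_scores(data, fit)
    scores = {g: float(u[m].sum()) for g, m in masks.items()}
    return GroupComparison(
        group_scores=scores,
        group_sizes=sizes,
        pooled_fit=fit,
        seed_scores=u,
    )


def permutation_test(
    data: SeedIntervals,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    unit: str = "dish",
) -> GroupComparison:
    """Permutation test of curve equality across groups.

    The statistic is sum_g (group score)^2 / n_g computed from the
    generalized Wilcoxon scores against the pooled fit (which is invariant
    under relabeling, so only label shuffles need recomputing).  Labels are
    permuted at the chosen unit — ``dish`` (default; respects the
    experimental unit) or ``seed``.  The p-value uses the add-one estimator
    p = (1 + #{permuted >= observed}) / (1 + n_perm).
    """
    if unit not in ("dish", "seed"):
        raise ValueError("unit must be 'dish' or 'seed'")
    if n_perm < 99:
        warnings.warn("fewer than 99 permutations gives a coarse p-value", UserWarning)
    comp = wilcoxon_scores(data)  # raises for < 2 groups
    u = comp.seed_scores
    assert u is not None
    groups = list(comp.group_scores)
    code_of = {g: i for i, g in enumerate(groups)}
    g_codes = np.array([code_of[g] for g in data.group], dtype=int)
    k = len(groups)

    if unit == "dish":
        units = list(dict.fromkeys(data.dish.tolist()))
        unit_idx = {d: np.where(data.dish == d)[0] for d in units}
        unit_scores = np.array([u[idx].sum() for idx in unit_idx.values()])
        unit_sizes = np.array([idx.size for idx in unit_idx.values()])
        unit_codes = np.array(
            [g_codes[idx[0]] for idx in unit_idx.values()], dtype=int
        )
        for d, idx in unit_idx.items():
            if np.unique(g_codes[idx]).size > 1:
                raise ValueError(f"dish {d} spans multiple groups; use unit='seed'")
        per_group_units = np.bincount(unit_codes, minlength=k)
        if np.any(per_group_units < 2):
            raise ValueError("need >= 2 permutation units per group")
    else:
        unit_scores = u
        unit_sizes = np.ones_like(u)
        unit_codes = g_codes
        if np.any(np.bincount(unit_codes, minlength=k) < 2):
            raise ValueError("need >= 2 permutation units per group")

    def statistic(codes: np.ndarray) -> float:
        sums = np.bincount(codes, weights=unit_scores, minlength=k)
        ns = np.bincount(codes, weights=unit_sizes, minlength=k)
        return float(np.sum(sums**2 / ns))

    obs = statistic(unit_codes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_codes = unit_codes[rng.permutation(unit_codes.size)]
        if statistic(perm_codes) >= obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    comp.statistic = obs
    comp.p_value = p
    comp.n_permutations = n_perm
    return comp
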