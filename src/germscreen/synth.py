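"""Synthetic germination trials and seedling morphometry.

The generator emulates the statistical structure the analysis assumes:
each seed is viable with probability pi (pi0 under control, pi0 * rho under
salt); viable seeds draw a latent germination time from a log-normal whose
median is multiplied by a delay factor delta under salt, with a dish-level
random effect on the log-median; observed data are the latent times binned
by the inspection schedule, with seeds unfinished at the final inspection
right-censored.  Abnormal seedlings are Bernoulli among germinated.
Seedling lengths are Gamma with archetype-specific control means and salt
multipliers.

Stress increases synchrony in this system (observed STI_GSI > 1), so the
log-scale sd shrinks under salt (``sigma_salt_mult``); a pure delay model
would otherwise make salt germination look *less* synchronous after binning.
Because the control distribution is itself concentrated in the first
inspection interval, synthetic STI_GSI lands near parity rather than above
it — a known limitation documented in the methods note.

Three accession archetypes mirror the screening panel's phenotype clusters:
C1 slow-but-complete (delayed germination, high final germination, vigorous
seedlings), C2 salt-susceptible at germination (strong viability loss), and
C3 fast-but-frail (quick, synchronous germination, poor seedling growth).
Archetype parameters are referenced at the 200 mM screening concentration
and interpolate linearly in concentration for gradient designs.

Ground-truth archetype labels are always emitted beside the data: the
testable surface is parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (
    DishCounts,
    GerminationPanel,
    InspectionSchedule,
    SeedlingBox,
    SeedlingPanel,
)

__all__ = [
    "ArchetypeParams",
    "SimulationConfig",
    "simulate_dish",
    "simulate_panel",
    "simulate_seedlings",
    "simulate_gradient",
    "default_screening_config",
    "expected_germinability_pct",
]

REFERENCE_MM = 200.0  # concentration at which archetype parameters are defined


@dataclass(frozen=True)
class ArchetypeParams:
    """Generative parameters for one accession archetype.

    mu0: log-median germination time under control (log-DAS).
    sigma: log-scale sd of latent germination times under control.
    delta: multiplier on the median time at the reference salt level (>= 1).
    pi0: control viability fraction; rho: salt viability multiplier (<= 1).
    alpha0 / alpha_salt: abnormality probability among germinated seedlings.
    length_means: control (shoot, main root, lateral root) means, mm.
    length_sti: salt multipliers per trait at the reference level.
    tau: dish-level random-effect sd on the log-median.
    sigma_salt_mult: shrink factor on sigma at the reference salt level
        (stress synchronizes germination).
    accession_sd: accession-level sd on the log-median within the archetype.
    """

    name: str
    mu0: float
    sigma: float
    delta: float
    pi0: float
    rho: float
    alpha0: float
    alpha_salt: float
    length_means: tuple[float, float, float]
    length_sti: tuple[float, float, float]
    tau: float = 0.05
    sigma_salt_mult: float = 0.6
    accession_sd: float = 0.04

    def __post_init__(self) -> None:
        if not (0 <= self.pi0 <= 1 and 0 <= self.rho <= 1):
            raise ValueError("viability parameters must lie in [0, 1]")
        if self.delta < 1:
            raise ValueError("delta must be >= 1 (salt delays germination)")
        if not (0 <= self.alpha0 <= 1 and 0 <= self.alpha_salt <= 1):
            raise ValueError("abnormality probabilities must lie in [0, 1]")
        if any(m <= 0 for m in self.length_means) or any(
            s <= 0 for s in self.length_sti
        ):
            raise ValueError("length parameters must be positive")

    # --- dose interpolation (linear in concentration, anchored at 200 mM) ---

    def frac(self, treatment_mM: float) -> float:
        return treatment_mM / REFERENCE_MM

    def delta_at(self, treatment_mM: float) -> float:
        return 1.0 + (self.delta - 1.0) * self.frac(treatment_mM)

    def pi_at(self, treatment_mM: float) -> float:
        return float(np.clip(self.pi0 * (1.0 - (1.0 - self.rho) * self.frac(treatment_mM)), 0.0, 1.0))

    def sigma_at(self, treatment_mM: float) -> float:
        mult = 1.0 + (self.sigma_salt_mult - 1.0) * self.frac(treatment_mM)
        return self.sigma * max(mult, 0.25)

    def alpha_at(self, treatment_mM: float) -> float:
        return float(
            np.clip(
                self.alpha0 + (self.alpha_salt - self.alpha0) * self.frac(treatment_mM),
                0.0,
                1.0,
            )
        )


def _default_archetypes() -> dict[str, tuple[ArchetypeParams, int]]:
    """The three screening archetypes with panel accession counts 32/9/14."""
    c1 = ArchetypeParams(
        name="C1",
        mu0=math.log(0.85),
        sigma=0.60,
        delta=1.75,
        pi0=0.97,
        rho=0.90,
        alpha0=0.06,
        alpha_salt=0.13,
        length_means=(30.0, 45.0, 20.0),
        length_sti=(0.53, 0.29, 0.17),
    )
    c2 = ArchetypeParams(
        name="C2",
        mu0=math.log(0.80),
        sigma=0.60,
        delta=2.0,
        pi0=0.95,
        rho=0.60,
        alpha0=0.08,
        alpha_salt=0.17,
        length_means=(30.0, 45.0, 20.0),
        length_sti=(0.47, 0.23, 0.07),
    )
    c3 = ArchetypeParams(
        name="C3",
        mu0=math.log(0.65),
        sigma=0.60,
        delta=1.35,
        pi0=0.98,
        rho=0.90,
        alpha0=0.05,
        alpha_salt=0.14,
        length_means=(30.0, 45.0, 20.0),
        length_sti=(0.24, 0.15, 0.04),
    )
    return {"C1": (c1, 32), "C2": (c2, 9), "C3": (c3, 14)}


@dataclass
class SimulationConfig:
    """Design and generative parameters for one simulated trial."""

    archetypes: dict[str, tuple[ArchetypeParams, int]] = field(
        default_factory=_default_archetypes
    )
    schedule: InspectionSchedule = field(
        default_factory=lambda: InspectionSchedule((1, 2, 3, 6))
    )
    n_dishes: int = 3
    n_seeds_per_dish: int = 50
    n_boxes: int = 5
    n_seedlings_per_box: int = 11
    treatments: tuple[float, ...] = (0.0, 200.0)
    length_cv: float = 0.25  # coefficient of variation of seedling lengths
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_dishes, self.n_seeds_per_dish, self.n_boxes, self.n_seedlings_per_box) <= 0:
            raise ValueError("design sizes must be positive")
        if 0.0 not in self.treatments:
            raise ValueError("treatments must include the 0 mM control")

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "schedule": list(self.schedule.times),
            "n_dishes": self.n_dishes,
            "n_seeds_per_dish": self.n_seeds_per_dish,
            "n_boxes": self.n_boxes,
            "n_seedlings_per_box": self.n_seedlings_per_box,
            "treatments": list(self.treatments),
            "length_cv": self.length_cv,
            "rng_seed": self.rng_seed,
            "archetypes": {
                name: {"n_accessions": n, **asdict(p)}
                for name, (p, n) in self.archetypes.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        doc = yaml.safe_load(Path(path).read_text())
        archetypes = {}
        for name, spec in doc["archetypes"].items():
            n = spec.pop("n_accessions")
            spec["length_means"] = tuple(spec["length_means"])
            spec["length_sti"] = tuple(spec["length_sti"])
            archetypes[name] = (ArchetypeParams(**spec), n)
        return cls(
            archetypes=archetypes,
            schedule=InspectionSchedule(tuple(doc["schedule"])),
            n_dishes=doc["n_dishes"],
            n_seeds_per_dish=doc["n_seeds_per_dish"],
            n_boxes=doc["n_boxes"],
            n_seedlings_per_box=doc["n_seedlings_per_box"],
            treatments=tuple(doc["treatments"]),
            length_cv=doc.get("length_cv", 0.25),
            rng_seed=doc["rng_seed"],
        )


def default_screening_config(rng_seed: int = 0) -> SimulationConfig:
    """The 57-accession x {0, 200 mM} x 3-dish x 50-seed screening design."""
    return SimulationConfig(rng_seed=rng_seed)


def simulate_dish(
    params: ArchetypeParams,
    treatment_mM: float,
    schedule: InspectionSchedule,
    n_seeds: int,
    rng: np.random.Generator,
    accession: str = "SYN",
    replicate: str = "r1",
    mu_accession: float | None = None,
) -> DishCounts:
    """Simulate one dish of interval-censored germination counts."""
    mu = mu_accession if mu_accession is not None else params.mu0
    mu_dish = rng.normal(mu, params.tau) if params.tau > 0 else mu
    delta = params.delta_at(treatment_mM)
    sigma = params.sigma_at(treatment_mM)
    pi = params.pi_at(treatment_mM)
    viable = rng.random(n_seeds) < pi
    n_viable = int(viable.sum())
    if sigma > 0:
        times = rng.lognormal(mu_dish + math.log(delta), sigma, size=n_viable)
    else:
        times = np.full(n_viable, math.exp(mu_dish) * delta)
    counts: dict[float, int] = {}
    prev = 0.0
    for day in schedule.times:
        counts[day] = int(np.sum((times > prev) & (times <= day)))
        prev = day
    g = sum(counts.values())
    alpha = params.alpha_at(treatment_mM)
    n_abn = int(rng.binomial(g, alpha)) if g > 0 else 0
    return DishCounts(
        accession=accession,
        treatment_mM=treatment_mM,
        replicate=replicate,
        n_sown=n_seeds,
        new_germ=counts,
        n_abnormal=n_abn,
    )


def simulate_panel(
    config: SimulationConfig,
) -> tuple[GerminationPanel, pd.DataFrame]:
    """Simulate the full screening panel plus its ground-truth table.

    Accessions are assigned to archetypes in the configured counts; each
    accession carries a small log-median offset so accessions within an
    archetype are similar but not identical.  Fully reproducible from
    ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    dishes: list[DishCounts] = []
    truth_rows = []
    acc_no = 0
    for name, (params, n_acc) in config.archetypes.items():
        for _ in range(n_acc):
            acc_no += 1
            acc = f"A{acc_no:02d}"
            mu_acc = (
                rng.normal(params.mu0, params.accession_sd)
                if params.accession_sd > 0
                else params.mu0
            )
            truth_rows.append(
                {
                    "accession": acc,
                    "archetype": name,
                    "mu_accession": mu_acc,
                    "delta": params.delta,
                    "rho": params.rho,
                    "pi0": params.pi0,
                }
            )
            for trt in config.treatments:
                for r in range(1, config.n_dishes + 1):
                    dishes.append(
                        simulate_dish(
                            params,
                            trt,
                            config.schedule,
                            config.n_seeds_per_dish,
                            rng,
                            accession=acc,
                            replicate=f"r{r}",
                            mu_accession=mu_acc,
                        )
                    )
    panel = GerminationPanel(dishes, config.schedule)
    truth = pd.DataFrame(truth_rows)
    return panel, truth


def simulate_gradient(
    schedule: InspectionSchedule | None = None,
    treatments: tuple[float, ...] = (0.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0),
    n_dishes: int = 3,
    n_seeds: int = 50,
    rng_seed: int = 0,
) -> tuple[GerminationPanel, pd.DataFrame]:
    """Two-variety x 7-concentration gradient trial (the level-finding design).

    The two varieties take the slow-but-complete (C1) and fast-but-frail (C3)
    archetypes, matching the commercial varieties' later cluster assignments.
    """
    schedule = schedule or InspectionSchedule((1, 2, 3, 6))
    arch = _default_archetypes()
    varieties = {"VAR-C1": arch["C1"][0], "VAR-C3": arch["C3"][0]}
    rng = np.random.default_rng(rng_seed)
    dishes = []
    truth_rows = []
    for vname, params in varieties.items():
        truth_rows.append({"accession": vname, "archetype": params.name,
                           "delta": params.delta, "rho": params.rho})
        for trt in treatments:
            for r in range(1, n_dishes + 1):
                dishes.append(
                    simulate_dish(
                        params, trt, schedule, n_seeds, rng,
                        accession=vname, replicate=f"r{r}",
                    )
                )
    return GerminationPanel(dishes, schedule), pd.DataFrame(truth_rows)


def expected_germinability_pct(
    params: ArchetypeParams,
    treatment_mM: float,
    schedule: InspectionSchedule,
) -> float:
    """Model-expected germination percentage by the final inspection."""
    from scipy.stats import norm

    mu = params.mu0 + math.log(params.delta_at(treatment_mM))
    sigma = params.sigma_at(treatment_mM)
    done = norm.cdf((math.log(schedule.final_time) - mu) / sigma) if sigma > 0 else float(
        math.exp(mu) <= schedule.final_time
    )
    return 100.0 * params.pi_at(treatment_mM) * float(done)


def simulate_seedlings(
    config: SimulationConfig,
    accessions: pd.DataFrame | None = None,
    germinability: dict[tuple[str, float], float] | None = None,
) -> tuple[SeedlingPanel, pd.DataFrame]:
    """Simulate the seedling-morphometry trial with ground truth.

    ``accessions`` is a truth-table-like frame with columns
    ``accession, archetype`` selecting the genotypes to grow (default: the
    13-genotype design, 7 C1 / 3 C2 / 4 C3).  Per-seedling lengths are Gamma
    (cv 0.25) with archetype control means and salt multipliers equal to the
    archetype trait STIs.  ``germinability`` overrides the attached
    germination percentage; by default the model-expected value is used.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    arch = {name: p for name, (p, _) in config.archetypes.items()}
    if accessions is None:
        rows = []
        design = {"C1": 7, "C2": 3, "C3": 4}
        i = 0
        for name, n in design.items():
            for _ in range(n):
                i += 1
                rows.append({"accession": f"G{i:02d}", "archetype": name})
        accessions = pd.DataFrame(rows)
    boxes: list[SeedlingBox] = []
    truth_rows = []
    cv = config.length_cv
    shape = 1.0 / cv**2 if cv > 0 else float("inf")
    for _, row in accessions.iterrows():
        params = arch[row["archetype"]]
        truth_rows.append(
            {
                "accession": row["accession"],
                "archetype": row["archetype"],
                "length_sti_shoot": params.length_sti[0],
                "length_sti_main": params.length_sti[1],
                "length_sti_lateral": params.length_sti[2],
            }
        )
        for trt in config.treatments:
            frac = params.frac(trt)
            mult = np.array(
                [1.0 + (s - 1.0) * frac for s in params.length_sti]
            )
            means = np.asarray(params.length_means) * mult
            if germinability is not None:
                germ = germinability.get((row["accession"], trt))
            else:
                germ = expected_germinability_pct(params, trt, config.schedule)
            for b in range(1, config.n_boxes + 1):
                if cv > 0:
                    lengths = rng.gamma(
                        shape,
                        means / shape,
                        size=(config.n_seedlings_per_box, 3),
                    )
                else:
                    lengths = np.tile(means, (config.n_seedlings_per_box, 1))
                boxes.append(
                    SeedlingBox(
                        accession=row["accession"],
                        treatment_mM=trt,
                        box=f"b{b}",
                        lengths=lengths,
                        germinability_pct=germ,
                    )
                )
    return SeedlingPanel(boxes), pd.DataFrame(truth_rows)
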