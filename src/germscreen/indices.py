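"""Germination indices, stress tolerance indices and the seedling vigor index.

Per dish, with N_t newly germinated seeds at inspection day D_t, G the total
germinated at the final count, Ntot the sown seeds and Nnorm the normal
seedlings at the final count:

    TG (%)        = G / Ntot * 100           total germination
    VC (DAS^-1)   = G / sum(N_t * D_t)       velocity coefficient
    GI (seed/DAS) = sum(N_t / D_t)           germination index (early weight)
    MGT (DAS)     = sum(N_t * D_t) / Ntot    mean germination time
    GSI           = sum(N_t (N_t - 1)) / (G (G - 1))   synchrony index
    NR (%)        = Nnorm / G * 100          normality rate

MGT divides by the sown count exactly as the trial protocol prints it; the
conventional germinated-seed denominator is available via
``mgt_denominator="germinated"``.  Note the identity MGT * VC = G / Ntot
(with the default denominator), used as an internal consistency check.

A stress tolerance index (STI) is the ratio of an index under salt to its
value under control, STI_x = X_200 / X_0; the seedling vigor index is
SVI = germinability(%) * (mean shoot + main-root + lateral-root length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

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
    "IndexSet",
    "VigorResult",
    "INDEX_NAMES",
    "compute_indices",
    "indices_table",
    "stress_tolerance_index",
    "panel_sti_matrix",
    "seedling_vigor_index",
    "seedling_sti_table",
]

log = logging.getLogger(__name__)

INDEX_NAMES = ("TG", "NR", "GI", "VC", "GSI", "MGT")


@dataclass(frozen=True)
class IndexSet:
    """The six germination indices for one dish (NaN marks undefined)."""

    tg: float
    vc: float
    gi: float
    mgt: float
    gsi: float
    nr: float

    @property
    def abnormality_pct(self) -> float:
        return 100.0 - self.nr

    def as_dict(self) -> dict[str, float]:
        return {
            "TG": self.tg,
            "NR": self.nr,
            "GI": self.gi,
            "VC": self.vc,
            "GSI": self.gsi,
            "MGT": self.mgt,
        }


def compute_indices(
    dish: DishCounts,
    schedule: InspectionSchedule,
    mgt_denominator: str = "ntot",
) -> IndexSet:
    """All six indices for one dish, straight from the printed formulas.

    Degenerate dishes propagate NaN rather than raising: GSI is undefined for
    G <= 1 (the formula divides by G(G-1)), NR for G = 0; TG, VC, GI and MGT
    are 0 for an empty dish.
    """
    if mgt_denominator not in ("ntot", "germinated"):
        raise ValueError("mgt_denominator must be 'ntot' or 'germinated'")
    nt = dish.counts_in_order(schedule).astype(float)
    dt = np.asarray(schedule.times, dtype=float)
    g = float(nt.sum())
    ntot = float(dish.n_sown)
    ntd = float(np.sum(nt * dt))

    tg = g / ntot * 100.0
    vc = g / ntd if ntd > 0 else 0.0
    gi = float(np.sum(nt / dt))
    mgt_den = ntot if mgt_denominator == "ntot" else g
    mgt = ntd / mgt_den if mgt_den > 0 else 0.0
    gsi = float(np.sum(nt * (nt - 1)) / (g * (g - 1))) if g > 1 else float("nan")
    nr = dish.n_normal / g * 100.0 if g > 0 else float("nan")
    return IndexSet(tg=tg, vc=vc, gi=gi, mgt=mgt, gsi=gsi, nr=nr)


def indices_table(
    panel: GerminationPanel,
    mgt_denominator: str = "ntot",
) -> pd.DataFrame:
    """One row of indices per dish, tidy for aggregation and export."""
    rows = []
    for dish in panel.dishes:
        idx = compute_indices(dish, panel.schedule, mgt_denominator)
        rows.append(
            {
                "accession": dish.accession,
                "treatment_mM": dish.treatment_mM,
                "replicate": dish.replicate,
                **idx.as_dict(),
            }
        )
    return pd.DataFrame(rows)


def stress_tolerance_index(x0: float, x200: float) -> float:
    """STI_x = X_200 / X_0; NaN when the control value is zero or undefined."""
    if x0 is None or not np.isfinite(x0) or x0 == 0:
        return float("nan")
    if x200 is None or not np.isfinite(x200):
        return float("nan")
    return float(x200 / x0)


def panel_sti_matrix(
    panel: GerminationPanel,
    control_mM: float = 0.0,
    stress_mM: float = 200.0,
    aggregation: str = "ratio_of_means",
    mgt_denominator: str = "ntot",
) -> pd.DataFrame:
    """Accession x index matrix of stress tolerance indices.

    Indices are computed per dish, averaged over replicates within
    accession x treatment (NaN-aware), then ratioed stress/control
    (``ratio_of_means``, the default — stabler near zero denominators);
    ``mean_of_ratios`` pairs replicate means instead.  Accessions missing
    either treatment are excluded with a logged diagnostic.
    """
    if aggregation not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError("aggregation must be 'ratio_of_means' or 'mean_of_ratios'")
    per_dish = indices_table(panel, mgt_denominator)
    rows = {}
    for acc, grp in per_dish.groupby("accession", sort=False):
        ctrl = grp[grp["treatment_mM"] == control_mM]
        salt = grp[grp["treatment_mM"] == stress_mM]
        if ctrl.empty or salt.empty:
            log.warning(
                "accession %s lacks treatment %s; excluded from STI matrix",
                acc,
                control_mM if ctrl.empty else stress_mM,
            )
            continue
        if aggregation == "ratio_of_means":
            x0 = ctrl[list(INDEX_NAMES)].mean()
            x200 = salt[list(INDEX_NAMES)].mean()
            rows[acc] = {
                name: stress_tolerance_index(x0[name], x200[name])
                for name in INDEX_NAMES
            }
        else:
            ratios = []
            for (_, c), (_, s) in zip(
                ctrl.sort_values("replicate").iterrows(),
                salt.sort_values("replicate").iterrows(),
            ):
                ratios.append(
                    {
                        name: stress_tolerance_index(c[name], s[name])
                        for name in INDEX_NAMES
                    }
                )
            rows[acc] = pd.DataFrame(ratios).mean().to_dict()
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(INDEX_NAMES))
    out.index.name = "accession"
    return out


@dataclass(frozen=True)
class VigorResult:
    """Seedling vigor index for one box with its component trait means."""

    box_key: tuple
    svi: float
    shoot_mean: float
    main_root_mean: float
    lateral_root_mean: float


def seedling_vigor_index(box: SeedlingBox) -> VigorResult:
    """SVI = germinability(%) x (mean shoot + main-root + lateral-root), %*mm.

    The germinability percentage is kept on its printed 0-100 scale; the
    scale cancels in STI_SVI so no normalization is applied.
    """
    if box.germinability_pct is None:
        raise ValueError(f"box {box.key}: germinability_pct is required for SVI")
    means = box.trait_means()  # raises on empty box
    svi = float(box.germinability_pct * means.sum())
    return VigorResult(
        box_key=box.key,
        svi=svi,
        shoot_mean=float(means[0]),
        main_root_mean=float(means[1]),
        lateral_root_mean=float(means[2]),
    )


TRAIT_NAMES = ("shoot", "main_root", "lateral_root", "SVI")


def seedling_sti_table(
    panel: SeedlingPanel,
    control_mM: float = 0.0,
    stress_mM: float = 200.0,
) -> pd.DataFrame:
    """Per-accession STIs for trait means and SVI (salt over control).

    Box-level trait means and SVI are averaged over replicate boxes within
    accession x treatment, then ratioed — mirroring the germination-side STI
    aggregation.
    """
    rows = []
    for b in panel.boxes:
        vr = seedling_vigor_index(b)
        rows.append(
            {
                "accession": b.accession,
                "treatment_mM": b.treatment_mM,
                "box": b.box,
                "shoot": vr.shoot_mean,
                "main_root": vr.main_root_mean,
                "lateral_root": vr.lateral_root_mean,
                "SVI": vr.svi,
            }
        )
    df = pd.DataFrame(rows)
    out = {}
    for acc, grp in df.groupby("accession", sort=False):
        ctrl = grp[grp["treatment_mM"] == control_mM]
        salt = grp[grp["treatment_mM"] == stress_mM]
        if ctrl.empty or salt.empty:
            log.warning("accession %s lacks a treatment; excluded from seedling STIs", acc)
            continue
        x0 = ctrl[list(TRAIT_NAMES)].mean()
        x200 = salt[list(TRAIT_NAMES)].mean()
        out[acc] = {
            t: stress_tolerance_index(x0[t], x200[t]) for t in TRAIT_NAMES
        }
    res = pd.DataFrame.from_dict(out, orient="index", columns=list(TRAIT_NAMES))
    res.index.name = "accession"
    return res
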