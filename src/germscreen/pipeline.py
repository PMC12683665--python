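"""End-to-end orchestration of the three screening experiments.

Experiment 1: salinity-gradient time-to-event analysis of two varieties —
per-group Wilcoxon scores, T50 with bootstrap SE, an overall permutation
test, and ANOVA contrasts of total germination and abnormality percentages.

Experiment 2: STI screening of the accession panel — per-dish indices, the
accession x index STI matrix, PCA, hierarchical k-means clusters,
within-cluster PCAs, and Kruskal-Wallis + Dunn-Bonferroni contrasts of each
STI across clusters.

Experiment 3: seedling morphometry — per-accession trait and vigor-index
STIs, compared across the germination clusters.

Each stage is runnable from files produced by earlier stages or by hand; a
run manifest captures the command, seed, configuration and input hashes so
deterministic stages reproduce byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import GerminationPanel, SeedlingPanel, validate_panel
from .indices import indices_table, panel_sti_matrix, seedling_sti_table, INDEX_NAMES, TRAIT_NAMES
from .screening import anova_pairwise, dunn_bonferroni, hkmeans, pca_sti
from .timetoevent import (
    bootstrap_quantile_se,
    panel_to_intervals,
    permutation_test,
    wilcoxon_scores,
)

__all__ = [
    "RunManifest",
    "run_experiment1",
    "run_experiment2",
    "run_experiment3",
]

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Provenance for one pipeline run (command, config, inputs, seed)."""

    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S")
    )

    @staticmethod
    def hash_file(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir) / "manifest.json"
        out.write_text(json.dumps(self.__dict__, indent=2, default=str))
        return out


def _check_panel(panel) -> None:
    diags = validate_panel(panel)
    if diags:
        raise ValueError(
            "panel failed validation: " + "; ".join(str(d) for d in diags[:5])
        )


def run_experiment1(
    panel: GerminationPanel,
    n_perm: int = 1000,
    n_boot: int = 200,
    seed: int | None = None,
) -> dict[str, pd.DataFrame | float]:
    """Gradient time-to-event analysis (the level-finding experiment).

    Returns a per-(variety, treatment) table of generalized Wilcoxon scores
    (against the all-group pooled fit), T50 on the germinated-fraction scale
    with bootstrap SE, the overall permutation p-value, and per-variety
    ANOVA-Sidak letters for total germination and abnormality percentages.
    """
    _check_panel(panel)
    if len(panel.treatments) < 2:
        raise ValueError("need >= 2 treatment groups")
    rng = np.random.default_rng(seed)
    data = panel_to_intervals(panel, group_by="accession_treatment")
    comp = wilcoxon_scores(data)
    rows = []
    for variety in panel.accessions:
        for trt in panel.treatments:
            group = (variety, trt)
            if group not in comp.group_scores:
                continue
            sub = data.subset(
                np.array([g == group for g in data.group], dtype=bool)
            )
            est = bootstrap_quantile_se(
                sub, n_boot=n_boot, seed=rng, relative=True
            )
            rows.append(
                {
                    "accession": variety,
                    "treatment_mM": trt,
                    "n_seeds": comp.group_sizes[group],
                    "wilcoxon_score": comp.group_scores[group],
                    "t50": est.time,
                    "se50": est.se,
                }
            )
    tte = pd.DataFrame(rows)
    perm = permutation_test(data, n_perm=n_perm, seed=rng, unit="dish")

    # static endpoints: TG% and abnormality% per dish, ANOVA within variety
    idx = indices_table(panel)
    idx["abnormality_pct"] = 100.0 - idx["NR"]
    contrasts = []
    for variety in panel.accessions:
        sub = idx[idx["accession"] == variety]
        for endpoint in ("TG", "abnormality_pct"):
            groups = {
                trt: g[endpoint].dropna().to_numpy()
                for trt, g in sub.groupby("treatment_mM")
            }
            groups = {t: v for t, v in groups.items() if v.size >= 2}
            if len(groups) < 2:
                continue
            res = anova_pairwise(groups, adjust="sidak")
            for trt, vals in groups.items():
                contrasts.append(
                    {
                        "accession": variety,
                        "endpoint": endpoint,
                        "treatment_mM": trt,
                        "mean": float(np.mean(vals)),
                        "se": float(np.std(vals, ddof=1) / np.sqrt(vals.size)),
                        "letters": res.letters.get(trt, ""),
                        "F": res.statistic,
                        "p": res.p_value,
                    }
                )
    return {
        "tte": tte,
        "permutation_p": perm.p_value,
        "permutation_statistic": perm.statistic,
        "endpoints": pd.DataFrame(contrasts),
    }


def run_experiment2(
    panel: GerminationPanel,
    k: int = 3,
    seed: int | None = None,
    control_mM: float = 0.0,
    stress_mM: float = 200.0,
) -> dict:
    """STI screening: indices, STI matrix, PCA, clusters, cluster contrasts."""
    _check_panel(panel)
    treatments = set(panel.treatments)
    if not {control_mM, stress_mM} <= treatments:
        raise ValueError(
            f"panel must contain both {control_mM} and {stress_mM} mM treatments"
        )
    idx = indices_table(panel)
    sti = panel_sti_matrix(panel, control_mM=control_mM, stress_mM=stress_mM)
    degenerate = bool(np.allclose(sti.to_numpy(dtype=float), 1.0, atol=1e-9, equal_nan=True))
    if degenerate:
        log.warning("all STIs are 1 (stress identical to control); clustering is degenerate")
        return {
            "indices": idx,
            "sti": sti,
            "pca": None,
            "clusters": None,
            "cluster_table": pd.DataFrame(),
            "within_pca": {},
            "tests": {},
            "degenerate": True,
        }
    pca = pca_sti(sti)
    clusters = hkmeans(sti, k=k, seed=seed)
    within_pca = {}
    for c in sorted(clusters.labels.unique()):
        members = clusters.labels[clusters.labels == c].index
        if len(members) >= 3:
            within_pca[int(c)] = pca_sti(sti.loc[members])
    tests = {}
    for name in INDEX_NAMES:
        groups = {
            int(c): sti.loc[clusters.labels[clusters.labels == c].index, name]
            .dropna()
            .to_numpy()
            for c in sorted(clusters.labels.unique())
        }
        groups = {c: v for c, v in groups.items() if v.size >= 1}
        if len(groups) >= 2 and sum(v.size for v in groups.values()) >= 2:
            tests[name] = dunn_bonferroni(groups)
    cluster_table = pd.DataFrame(
        {
            "cluster": clusters.labels,
            "PC1": pca.scores["PC1"],
            "PC2": pca.scores["PC2"] if "PC2" in pca.scores else np.nan,
        }
    )
    return {
        "indices": idx,
        "sti": sti,
        "pca": pca,
        "clusters": clusters,
        "cluster_table": cluster_table,
        "within_pca": within_pca,
        "tests": tests,
        "degenerate": degenerate,
    }


def run_experiment3(
    panel: SeedlingPanel,
    clusters: pd.Series,
    control_mM: float = 0.0,
    stress_mM: float = 200.0,
) -> dict:
    """Seedling STI report by germination cluster.

    ``clusters`` maps accession -> cluster id (from experiment 2 or a file).
    Returns per-accession trait/SVI STIs and Kruskal-Wallis + Dunn-Bonferroni
    contrasts across clusters for each trait.
    """
    _check_panel(panel)
    sti = seedling_sti_table(panel, control_mM=control_mM, stress_mM=stress_mM)
    missing = [a for a in sti.index if a not in clusters.index]
    if missing:
        raise ValueError(f"no cluster label for accession(s): {missing}")
    sti = sti.assign(cluster=[int(clusters[a]) for a in sti.index])
    tests = {}
    for trait in TRAIT_NAMES:
        groups = {
            int(c): g[trait].dropna().to_numpy()
            for c, g in sti.groupby("cluster")
        }
        groups = {c: v for c, v in groups.items() if v.size >= 1}
        if len(groups) >= 2:
            tests[trait] = dunn_bonferroni(groups)
    summary = (
        sti.groupby("cluster")[list(TRAIT_NAMES)].agg(["mean", "sem"])
    )
    return {"sti": sti, "tests": tests, "summary": summary}
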