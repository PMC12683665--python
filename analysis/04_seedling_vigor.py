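"""Seedling experiment: do germination clusters predict seedling salt response?

Computes per-genotype STIs for shoot, main-root and lateral-root length and
the seedling vigor index (SVI), then contrasts them across the germination
clusters from the screening step (Kruskal-Wallis + Dunn-Bonferroni).
Prints the trait-impact ordering and the per-cluster STI_SVI means.
"""

import argparse
from pathlib import Path

import pandas as pd

from germscreen.io import read_seedling_table
from germscreen.pipeline import RunManifest, run_experiment3

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--boxes", type=Path,
                    default=ROOT / "results" / "sim" / "boxes.csv")
    ap.add_argument("--germinability", type=Path,
                    default=ROOT / "results" / "sim" / "germinability.csv")
    ap.add_argument("--box-truth", type=Path,
                    default=ROOT / "results" / "sim" / "box_truth.csv")
    ap.add_argument("--clusters", type=Path,
                    default=ROOT / "results" / "screening" / "clusters.csv",
                    help="accession->cluster table from the screening step")
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results" / "seedlings")
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    gdf = pd.read_csv(args.germinability)
    germ = {
        (str(r["accession"]), float(r["treatment_mM"])): float(r["germinability_pct"])
        for _, r in gdf.iterrows()
    }
    panel = read_seedling_table(args.boxes, germinability=germ)
    # The seedling genotypes are the cluster representatives; map them to the
    # screening clusters through the generating archetype of each genotype
    # and the modal cluster of that archetype in the screening partition.
    screen = pd.read_csv(args.clusters, index_col=0)["cluster"]
    box_truth = pd.read_csv(args.box_truth).set_index("accession")
    panel_truth = pd.read_csv(
        args.boxes.parent / "panel_truth.csv"
    ).set_index("accession")
    joined = pd.DataFrame({"cluster": screen}).join(panel_truth["archetype"])
    modal = joined.groupby("archetype")["cluster"].agg(lambda s: s.mode()[0])
    clusters = box_truth["archetype"].map(modal)

    res = run_experiment3(panel, clusters)
    res["sti"].to_csv(out / "seedling_sti.csv")
    res["summary"].to_csv(out / "summary_by_cluster.csv")
    rows = []
    for trait, t in res["tests"].items():
        for g, letter in t.letters.items():
            rows.append({"trait": trait, "cluster": g, "letters": letter,
                         "H": t.statistic, "p": t.p_value})
    pd.DataFrame(rows).to_csv(out / "seedling_contrasts.csv", index=False)
    RunManifest(
        command="analysis/04_seedling_vigor.py", seed=None,
        input_hashes={"boxes": RunManifest.hash_file(args.boxes)},
    ).write(out)

    sti = res["sti"]
    overall = sti[["shoot", "main_root", "lateral_root"]].mean()
    print("mean trait STIs (least to most impacted): "
          + ", ".join(f"{k}={v:.2f}" for k, v in
                      overall.sort_values(ascending=False).items()))
    for c, grp in sti.groupby("cluster"):
        print(f"cluster {c}: n={len(grp)}, STI_SVI={grp.SVI.mean():.2f}")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
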