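"""Generate the three synthetic trials that the downstream analyses consume.

Writes, under results/sim/:
  gradient_counts.csv   two varieties x 7 NaCl levels x 3 dishes x 50 seeds
  panel_counts.csv      55 accessions x {0, 200 mM} x 3 dishes x 50 seeds
  panel_truth.csv       ground-truth archetype per accession
  boxes.csv             14 genotypes x 2 treatments x 5 boxes x 11 seedlings
  box_truth.csv         ground-truth archetype per genotype
  config.yaml           the generative configuration snapshot
"""

import argparse
from pathlib import Path

import pandas as pd

from germscreen.io import write_germination_table, write_seedling_table
from germscreen.pipeline import RunManifest
from germscreen.synth import (
    default_screening_config,
    simulate_gradient,
    simulate_panel,
    simulate_seedlings,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results" / "sim")
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    gradient, gradient_truth = simulate_gradient(rng_seed=args.seed)
    write_germination_table(gradient, out / "gradient_counts.csv")
    gradient_truth.to_csv(out / "gradient_truth.csv", index=False)

    cfg = default_screening_config(rng_seed=args.seed)
    panel, truth = simulate_panel(cfg)
    write_germination_table(panel, out / "panel_counts.csv")
    truth.to_csv(out / "panel_truth.csv", index=False)

    boxes, box_truth = simulate_seedlings(cfg)
    write_seedling_table(boxes, out / "boxes.csv")
    box_truth.to_csv(out / "box_truth.csv", index=False)
    germ = (
        pd.DataFrame(
            {
                "accession": [b.accession for b in boxes],
                "treatment_mM": [b.treatment_mM for b in boxes],
                "germinability_pct": [b.germinability_pct for b in boxes],
            }
        )
        .drop_duplicates()
        .reset_index(drop=True)
    )
    germ.to_csv(out / "germinability.csv", index=False)
    cfg.to_yaml(out / "config.yaml")
    RunManifest(command="analysis/01_simulate_trials.py", seed=args.seed).write(out)

    print(f"gradient trial: {len(gradient)} dishes")
    print(f"screening panel: {len(panel)} dishes, {truth.shape[0]} accessions "
          f"({truth.archetype.value_counts().to_dict()})")
    print(f"seedling trial: {len(boxes)} boxes, {box_truth.shape[0]} genotypes")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
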