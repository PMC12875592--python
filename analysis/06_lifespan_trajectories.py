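#!/usr/bin/env python
"""Developmental-stage trajectories of pathway expression.

Cleans the simulated developmental dataset (stage-coverage, duplicate
genes, RPKM detection floor), log2-transforms, equalizes donors by
upper-quartile normalization, and computes per-stage medians plus LOESS
curves against log10 age for each pathway. The planted pentose-phosphate
decline should emerge as a monotone falling trajectory.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

import energymaps as em

IN = Path("results/simulated_inputs")
OUT = Path("results/lifespan")


def main() -> None:
    dataset = em.io.read_lifespan(IN)
    stage_table = em.lifespan.load_stage_table()
    sets = em.genesets.load_final_genesets()

    n_genes_raw = dataset.expression.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dataset = em.lifespan.cleanup(dataset, stage_table)
    print(f"cleanup: {n_genes_raw} -> {dataset.expression.shape[1]} genes, "
          f"{len(dataset.samples)} samples kept")
    dataset = em.lifespan.LifespanDataset(
        samples=dataset.samples,
        expression=em.lifespan.log2_transform(dataset.expression),
    )
    dataset = em.lifespan.upper_quartile_normalize(dataset)

    traj_rows, curves = [], {}
    for name, gs in sets.items():
        traj = em.lifespan.stage_trajectory(dataset, gs, stage_table)
        traj.insert(0, "pathway", name)
        traj_rows.append(traj)
        trend = spearmanr(np.arange(len(traj)), traj["median"]).statistic
        print(f"{name}: stage medians "
              f"{np.round(traj['median'].to_numpy(), 2).tolist()} "
              f"(rank trend {trend:+.2f})")
        genes = [g for g in sorted(gs.genes)
                 if g in dataset.expression.columns]
        sample_means = dataset.expression[genes].mean(axis=1)
        curve = em.lifespan.loess_trajectory(
            dataset.samples["age_pcd"].to_numpy(), sample_means.to_numpy()
        )
        curves["log10_age"] = curve["log10_age"].to_numpy()
        curves[f"{name}_fitted"] = curve["fitted"].to_numpy()

    em.io.write_tsv(pd.concat(traj_rows, ignore_index=True),
                    OUT / "stage_trajectories.tsv", index=False)
    grid = curves.pop("log10_age")
    em.io.write_tsv(
        pd.DataFrame(curves, index=pd.Index(grid, name="log10_age")),
        OUT / "loess_curves.tsv",
    )
    print(f"wrote trajectories to {OUT}")


if __name__ == "__main__":
    main()
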