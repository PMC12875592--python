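#!/usr/bin/env python
"""Summarize regional expression into per-pathway brain maps.

Builds the mean, z-scored and first-principal-component map for each
energy pathway and the per-class means over the cytoarchitectonic
annotation, and reports how tightly the PC1 and mean summaries agree.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

import energymaps as em

IN_EXPR = Path("results/expression")
IN_SIM = Path("results/simulated_inputs")
OUT = Path("results/maps")


def main() -> None:
    values = em.io.read_tsv(IN_EXPR / "region_by_gene_expression.tsv")
    ds = em.io.read_tsv(IN_EXPR / "differential_stability.tsv")["ds"]
    expr = em.ahba.RegionExpressionMatrix(values=values, ds=ds, n_donors=6)
    parc = em.io.read_parcellation(IN_SIM / "parcellation.tsv")
    sets = em.genesets.load_final_genesets()

    table, group_rows, pc1_rows = {}, [], []
    for name, gs in sets.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean_map = em.maps.pathway_mean_map(expr, gs)
            zmap = em.maps.zscore_map(mean_map)
            pc1 = em.maps.pathway_pc1_map(expr, gs)
        table[f"{name}_mean"] = mean_map.values
        table[f"{name}_z"] = zmap.values
        table[f"{name}_pc1"] = pc1.values
        agree = np.corrcoef(mean_map.values, pc1.values)[0, 1]
        pc1_rows.append({"pathway": name,
                         "variance_explained": pc1.variance_explained,
                         "corr_with_mean_map": agree})
        gm = em.maps.group_mean(zmap, parc.annotations["cyto_class"])
        gm.insert(0, "pathway", name)
        group_rows.append(gm)
        print(f"{name}: {mean_map.meta['n_genes']} genes, PC1 explains "
              f"{pc1.variance_explained:.1%}, corr(mean, PC1) = {agree:.2f}")

    em.io.write_tsv(pd.DataFrame(table, index=values.index),
                    OUT / "pathway_maps.tsv")
    em.io.write_tsv(pd.DataFrame(pc1_rows), OUT / "pc1_summary.tsv",
                    index=False)
    em.io.write_tsv(pd.concat(group_rows, ignore_index=True),
                    OUT / "class_means.tsv", index=False)
    print(f"wrote maps to {OUT}")


if __name__ == "__main__":
    main()
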