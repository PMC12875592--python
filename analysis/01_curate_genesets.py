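#!/usr/bin/env python
"""Curate the five energy-pathway gene sets by two-source consensus.

Loads the packaged annotation exports (a GO-style and a Reactome-style
table), intersects them per pathway, applies the hexokinase exclusion,
and writes the finalized sets with their pairwise overlap matrix. The
expected structure: minimal overlap, with the three succinate
dehydrogenase genes shared between the TCA and OXPHOS sets and PFKFB2
shared between glycolysis and lactate.
"""

from importlib import resources
from pathlib import Path

import energymaps.genesets as gs
from energymaps.io import write_tsv

OUT = Path("results/genesets")


def main() -> None:
    data = resources.files("energymaps.data")
    with resources.as_file(
        data.joinpath("annotations_source_a.synthetic.tsv")
    ) as pa, resources.as_file(
        data.joinpath("annotations_source_b.synthetic.tsv")
    ) as pb, resources.as_file(data.joinpath("exclusions.yaml")) as pe:
        rec_a = gs.load_annotation_table(pa, "source_A")
        rec_b = gs.load_annotation_table(pb, "source_B")
        exclusions = gs.load_exclusions(pe)

    names = list(gs.load_final_genesets())
    ids_a = list(dict.fromkeys(r.pathway_id for r in rec_a))
    ids_b = list(dict.fromkeys(r.pathway_id for r in rec_b))
    final = {}
    for name, ida, idb in zip(names, ids_a, ids_b):
        consensus = gs.consensus_gene_set(
            name,
            [r for r in rec_a if r.pathway_id == ida],
            [r for r in rec_b if r.pathway_id == idb],
        )
        final[name] = gs.apply_exclusions(consensus, exclusions.get(name, []))
        removed = [g for g, r in final[name].exclusions_applied
                   if "no-op" not in r]
        print(f"{name}: {len(consensus)} consensus genes"
              + (f", excluded {removed}" if removed else ""))

    OUT.mkdir(parents=True, exist_ok=True)
    gs.write_genesets_tsv(final, OUT / "final_genesets.tsv")
    overlaps = gs.overlap_matrix(final)
    write_tsv(overlaps, OUT / "overlap_matrix.tsv")
    print("\npairwise shared-gene counts (diagonal = set size):")
    print(overlaps.to_string())
    shared = gs.pathway_overlap(final["tca"], final["oxphos"])
    print(f"\nTCA/OXPHOS shared genes: {sorted(shared)}")
    print(f"glycolysis/lactate shared genes: "
          f"{sorted(gs.pathway_overlap(final['glycolysis'], final['lactate']))}")


if __name__ == "__main__":
    main()
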