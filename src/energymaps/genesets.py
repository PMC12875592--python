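"""Curation of energy-metabolism pathway gene sets.

Pathway gene sets (glycolysis, pentose phosphate pathway, TCA cycle,
oxidative phosphorylation, lactate metabolism and transport) are built by
consensus between two annotation sources — an export of GO biological
process annotations and an export of Reactome pathway annotations. A gene
enters a pathway set only when both sources annotate it to that pathway.
Documented manual exclusions (the hexokinase rule: hexokinase gates entry
into both glycolysis and the pentose phosphate pathway, so it belongs to
neither map) are applied afterwards from a config file.

Gene symbols are normalized by uppercasing and stripping whitespace; no
alias resolution is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "AnnotationRecord",
    "PathwayGeneSet",
    "GenesetFormatError",
    "load_annotation_table",
    "consensus_gene_set",
    "apply_exclusions",
    "pathway_overlap",
    "load_exclusions",
    "load_final_genesets",
    "overlap_matrix",
]

REQUIRED_COLUMNS = ("pathway_id", "pathway_name", "gene")


class GenesetFormatError(ValueError):
    """Raised when an annotation or gene-set table violates its format."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One (gene, pathway, source) annotation assertion."""

    gene: str
    pathway_id: str
    source: str
    pathway_name: str = ""


@dataclass
class PathwayGeneSet:
    """A named, finalized set of gene symbols with per-gene provenance.

    ``provenance`` maps each retained gene to the pair of source pathway
    identifiers (source A, source B) that supported its inclusion; a
    ``None`` entry marks a manually curated gene without dual support.
    ``exclusions_applied`` records (gene, reason) pairs, including no-ops
    for exclusion rules that did not match any gene.
    """

    name: str
    genes: frozenset[str]
    provenance: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)
    exclusions_applied: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def _normalize_symbol(gene: object) -> str:
    return str(gene).strip().upper()


def load_annotation_table(path: str | Path, source: str) -> list[AnnotationRecord]:
    """Parse a delimited annotation export into :class:`AnnotationRecord` rows.

    The table must carry columns ``pathway_id``, ``pathway_name`` and
    ``gene`` (header matching is case-insensitive); the delimiter is
    sniffed (tab or comma). Blank lines are skipped; gene symbols are
    uppercased and stripped.
    """
    import csv

    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         skip_blank_lines=True)
    except (pd.errors.EmptyDataError, csv.Error):
        raise GenesetFormatError(
            f"annotation table {path} is empty or undelimited"
        ) from None
    if df.empty:
        raise GenesetFormatError(f"annotation table {path} has no data rows")

    lower = {c.lower().strip(): c for c in df.columns}
    missing = [c for c in REQUIRED_COLUMNS if c not in lower]
    if missing:
        raise GenesetFormatError(
            f"annotation table {path} is missing required column(s): "
            + ", ".join(missing)
        )
    df = df.rename(columns={lower[c]: c for c in REQUIRED_COLUMNS})

    records = []
    for row in df.itertuples(index=False):
        gene = _normalize_symbol(row.gene)
        if not gene or gene == "NAN":
            raise GenesetFormatError(f"empty gene symbol in {path}")
        records.append(
            AnnotationRecord(
                gene=gene,
                pathway_id=str(row.pathway_id).strip(),
                source=source,
                pathway_name=str(row.pathway_name).strip(),
            )
        )
    return records


def consensus_gene_set(
    name: str,
    records_a: Iterable[AnnotationRecord],
    records_b: Iterable[AnnotationRecord],
) -> PathwayGeneSet:
    """Intersect two sources' annotations for one pathway.

    Only genes annotated in both sources are retained. A disjoint pair of
    sources is valid and yields an empty set (with a warning), not an
    error.
    """
    a_by_gene = {r.gene: r for r in records_a}
    b_by_gene = {r.gene: r for r in records_b}
    shared = set(a_by_gene) & set(b_by_gene)
    if not shared:
        warnings.warn(
            f"consensus for pathway '{name}' is empty: the two sources share "
            "no genes",
            stacklevel=2,
        )
    provenance = {
        g: (a_by_gene[g].pathway_id, b_by_gene[g].pathway_id) for g in sorted(shared)
    }
    return PathwayGeneSet(name=name, genes=frozenset(shared), provenance=provenance)


def apply_exclusions(
    gs: PathwayGeneSet, exclusions: Sequence[tuple[str, str]]
) -> PathwayGeneSet:
    """Remove listed genes from a set, logging both hits and no-ops."""
    applied = list(gs.exclusions_applied)
    genes = set(gs.genes)
    provenance = dict(gs.provenance)
    for gene, reason in exclusions:
        gene = _normalize_symbol(gene)
        if gene in genes:
            genes.discard(gene)
            provenance.pop(gene, None)
            applied.append((gene, reason))
        else:
            applied.append((gene, f"no-op (absent): {reason}"))
    return PathwayGeneSet(
        name=gs.name,
        genes=frozenset(genes),
        provenance=provenance,
        exclusions_applied=applied,
    )


def pathway_overlap(gs_a: PathwayGeneSet, gs_b: PathwayGeneSet) -> frozenset[str]:
    """Genes shared between two finalized pathway sets (symmetric)."""
    return frozenset(gs_a.genes & gs_b.genes)


def overlap_matrix(genesets: Mapping[str, PathwayGeneSet]) -> pd.DataFrame:
    """Pairwise shared-gene counts between pathways (diagonal = set size)."""
    names = list(genesets)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            mat.loc[a, b] = len(pathway_overlap(genesets[a], genesets[b]))
    return mat


def load_exclusions(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Load a YAML exclusion config mapping pathway -> [(gene, reason)].

    Each entry lists a gene, the pathways it must be removed from, and a
    human-readable reason.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out: dict[str, list[tuple[str, str]]] = {}
    for rule in cfg.get("exclusions", []):
        gene = _normalize_symbol(rule["gene"])
        reason = str(rule.get("reason", "excluded by config"))
        for pw in rule.get("pathways", []):
            out.setdefault(str(pw), []).append((gene, reason))
    return out


def _packaged(name: str):
    return resources.files("energymaps.data").joinpath(name)


def load_final_genesets(path: str | Path | None = None) -> dict[str, PathwayGeneSet]:
    """Load finalized pathway gene sets from a gene-set TSV.

    The TSV has one row per gene with columns ``pathway``, ``gene``,
    ``source_A_id`` and ``source_B_id``. When ``path`` is omitted the
    packaged reference fixture is used: a synthetic reconstruction of the
    five consensus energy-pathway sets that reproduces the documented
    overlap structure (three succinate dehydrogenase genes shared by the
    TCA and OXPHOS sets, PFKFB2 shared by glycolysis and lactate, and a
    hexokinase-free glycolysis/PPP).
    """
    if path is None:
        with resources.as_file(_packaged("consensus_genesets.synthetic.tsv")) as p:
            return load_final_genesets(p)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pathway", "gene", "source_A_id", "source_B_id"}
    missing = required - set(df.columns)
    if missing:
        raise GenesetFormatError(
            f"gene-set table {path} is missing column(s): {sorted(missing)}"
        )
    out: dict[str, PathwayGeneSet] = {}
    for pw, grp in df.groupby("pathway", sort=False):
        genes = [_normalize_symbol(g) for g in grp["gene"]]
        if len(genes) != len(set(genes)):
            raise GenesetFormatError(f"duplicate genes in pathway '{pw}' of {path}")
        provenance = {
            _normalize_symbol(r.gene): (r.source_A_id, r.source_B_id)
            for r in grp.itertuples(index=False)
        }
        out[str(pw)] = PathwayGeneSet(
            name=str(pw), genes=frozenset(genes), provenance=provenance
        )
    return out


def write_genesets_tsv(
    genesets: Mapping[str, PathwayGeneSet], path: str | Path
) -> None:
    """Write finalized gene sets in the one-row-per-gene TSV dialect."""
    rows = []
    for name, gs in genesets.items():
        for gene in sorted(gs.genes):
            a, b = gs.provenance.get(gene, (None, None))
            rows.append({"pathway": name, "gene": gene,
                         "source_A_id": a or "", "source_B_id": b or ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
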