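"""Synthetic inputs for the whole pipeline.

Generates, from a seed and a :class:`SyntheticSpec`, every input the
other modules consume: a mirror-symmetric spherical parcellation with
contiguous class annotations, spatially autocorrelated gene expression
patterns (Gaussian fields with an exponential geodesic kernel), donor
sample tables emulating a multi-donor microarray atlas (left-dominant
sampling, unsampled parcels, decoy probes, background flags), and a
developmental RPKM dataset with planted stage trajectories.

The generators are pure functions of (spec, seed): identical seeds
reproduce identical outputs. What is emulated — and what is not — is
discussed in the package methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .ahba import DonorSampleTable, Parcellation
from .genesets import PathwayGeneSet
from .lifespan import LifespanDataset, StageTable
from .maps import BrainMap

__all__ = [
    "SyntheticSpec",
    "make_parcellation",
    "gp_map",
    "make_donor_tables",
    "make_lifespan_dataset",
]

#: Each hemisphere is its own near-spherical surface: radius and midline
#: offset (mm) of the two hemisphere spheres.
HEMISPHERE_RADIUS_MM = 30.0
HEMISPHERE_OFFSET_MM = 35.0

#: Diagonal jitter added to spatial covariance matrices before Cholesky.
COVARIANCE_JITTER = 1e-8


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic cohort.

    Defaults describe a small six-donor atlas: 100 parcels per
    hemisphere, 60 genes in five planted pathway-sized sets, spatial
    correlation length 0.3 rad, within-donor noise SD 0.5, 15% of parcels
    unsampled per donor, right hemisphere sampled in two donors only.
    """

    n_parcels_per_hemisphere: int = 100
    n_donors: int = 6
    n_genes: int = 60
    correlation_length: float = 0.3
    noise_sd: float = 0.5
    class_effects: dict[tuple[str, object], float] = field(default_factory=dict)
    stage_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    class_annotation: str = "cyto_class"
    n_classes: int = 7
    unsampled_fraction: float = 0.15
    n_right_hemisphere_donors: int = 2
    decoy_fraction: float = 0.3
    background_fraction: float = 0.1
    sample_jitter_mm: float = 0.5
    n_regions: int = 6
    n_samples_per_region_stage: int = 10
    lifespan_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parcels_per_hemisphere < 10:
            raise ValueError("need at least 10 parcels per hemisphere")
        if self.n_donors < 1:
            raise ValueError("need at least one donor")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")


def _sphere_lattice(n: int, rng: np.random.Generator,
                    jitter: float = 0.01) -> np.ndarray:
    """Near-uniform unit vectors on the full sphere (Fibonacci lattice
    with small seeded angular jitter)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n  # uniform in (-1, 1)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    r = np.sqrt(1.0 - z**2)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    pts = pts + jitter * rng.standard_normal(pts.shape)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def make_parcellation(spec: SyntheticSpec) -> Parcellation:
    """Mirror-symmetric two-sphere parcellation with contiguous classes.

    Each hemisphere is modelled as its own near-spherical surface (as
    cortical hemispheres are in surface space): left-hemisphere centroids
    come from a jittered Fibonacci lattice on a 30 mm sphere centered at
    x = -35 mm, and right-hemisphere centroids are their x-mirror images.
    Class annotations are k spatial clusters (k-means on left centroids,
    labels mirrored), emulating contiguous cytoarchitectonic classes.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_parcels_per_hemisphere
    left_unit = _sphere_lattice(n, rng)
    left = left_unit * HEMISPHERE_RADIUS_MM
    left[:, 0] -= HEMISPHERE_OFFSET_MM
    right = left * np.array([-1.0, 1.0, 1.0])
    centroids = np.vstack([left, right])
    ids = np.array(
        [f"L{i:03d}" for i in range(n)] + [f"R{i:03d}" for i in range(n)]
    )
    hemisphere = np.array(["L"] * n + ["R"] * n)
    km = KMeans(n_clusters=spec.n_classes, n_init=4,
                random_state=int(rng.integers(2**31 - 1)))
    left_labels = km.fit_predict(left)
    labels = np.concatenate([left_labels, left_labels])
    annotations = {
        spec.class_annotation: np.array([f"class_{c}" for c in labels]),
    }
    return Parcellation(ids=ids, hemisphere=hemisphere, centroids=centroids,
                        annotations=annotations)


def _geodesic_covariance(parc: Parcellation, correlation_length: float
                         ) -> np.ndarray:
    """Block-per-hemisphere exponential kernel on geodesic distance.

    Centroids are projected onto each hemisphere's unit sphere (about the
    hemisphere centroid mean); within a hemisphere the covariance is
    exp(-d/lambda) with d the great-circle distance, and the two
    hemispheres are independent blocks.
    """
    hemis = np.asarray(parc.hemisphere)
    cov = np.zeros((len(parc), len(parc)))
    for h in np.unique(hemis):
        idx = np.flatnonzero(hemis == h)
        pts = parc.centroids[idx]
        centered = pts - pts.mean(axis=0)
        unit = centered / np.linalg.norm(centered, axis=1, keepdims=True)
        cosang = np.clip(unit @ unit.T, -1.0, 1.0)
        d = np.arccos(cosang)
        cov[np.ix_(idx, idx)] = np.exp(-d / correlation_length)
    cov[np.diag_indices_from(cov)] += COVARIANCE_JITTER
    return cov


def gp_map(
    parc: Parcellation,
    correlation_length: float,
    rng: np.random.Generator | int,
) -> BrainMap:
    """Sample a zero-mean Gaussian field over parcel centroids.

    The covariance between parcels is exp(-d/lambda) with d the
    great-circle (geodesic) distance between their unit-sphere positions;
    the jittered covariance is factorized by Cholesky decomposition.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    cov = _geodesic_covariance(parc, correlation_length)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("spatial covariance is not positive-definite "
                         "after jitter") from err
    values = L @ rng.standard_normal(len(parc))
    return BrainMap(parcels=pd.Index(parc.ids), values=values,
                    name="gp", kind="mean",
                    meta={"correlation_length": correlation_length})


def _ground_truth_patterns(
    spec: SyntheticSpec,
    parc: Parcellation,
    genesets: Mapping[str, PathwayGeneSet],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Planted parcel-by-gene patterns: shared Gaussian fields plus class
    effects for designated gene sets, in SD units of the field.

    Patterns are mirror-symmetric across hemispheres (the right-hemisphere
    value of a gene equals its mirrored left-hemisphere value), matching
    the hemispheric-symmetry assumption behind bilateral sample mirroring.
    """
    left = np.flatnonzero(np.asarray(parc.hemisphere) == "L")
    right = np.flatnonzero(np.asarray(parc.hemisphere) == "R")
    if len(left) != len(right):
        raise ValueError("ground truth requires a mirror-symmetric parcellation")
    left_parc = Parcellation(
        ids=parc.ids[left], hemisphere=parc.hemisphere[left],
        centroids=parc.centroids[left],
    )
    cov = _geodesic_covariance(left_parc, spec.correlation_length)
    L = np.linalg.cholesky(cov)
    genes: list[str] = []
    for gs in genesets.values():
        for g in sorted(gs.genes):
            if g not in genes:  # genes shared between pathways appear once
                genes.append(g)
    extra = spec.n_genes - len(genes)
    genes.extend(f"BKG{i:03d}" for i in range(max(0, extra)))
    half = L @ rng.standard_normal((len(left), len(genes)))
    patterns = np.empty((len(parc), len(genes)))
    patterns[left] = half
    patterns[right] = half  # mirrored parcels share the left pattern
    truth = pd.DataFrame(patterns, index=pd.Index(parc.ids), columns=genes)
    labels = parc.annotations.get(spec.class_annotation)
    for (set_name, cls), effect in spec.class_effects.items():
        if labels is None:
            raise ValueError("parcellation lacks the class annotation "
                             f"'{spec.class_annotation}'")
        if set_name not in genesets:
            raise ValueError(f"class effect refers to unknown set '{set_name}'")
        mask = labels == cls
        for g in genesets[set_name].genes:
            if g in truth.columns:
                truth.loc[mask, g] += effect
    return truth


def make_donor_tables(
    spec: SyntheticSpec,
    parc: Parcellation,
    genesets: Mapping[str, PathwayGeneSet],
) -> tuple[list[DonorSampleTable], pd.DataFrame]:
    """Generate donor sample tables and the planted ground truth.

    Per donor, samples sit at jittered parcel centroids; a configurable
    fraction of parcels is left unsampled and only the first
    ``n_right_hemisphere_donors`` donors include right-hemisphere
    samples. Each gene has a faithful probe; a fraction of genes carries
    an additional decoy probe whose regional profile is shuffled per
    donor (so it cannot be consistent across donors). Intensities are
    2**(6 + pattern + noise); above-background flags are cleared for a
    random ``background_fraction`` of probe-sample pairs.

    Returns ``(tables, truth)`` where ``truth`` is the parcel-by-gene
    matrix of planted patterns (class effects included, noise excluded).
    """
    rng = np.random.default_rng(spec.seed + 1)
    truth = _ground_truth_patterns(spec, parc, genesets, rng)
    genes = list(truth.columns)
    n_decoy = int(round(spec.decoy_fraction * len(genes)))
    decoy_genes = set(rng.choice(genes, size=n_decoy, replace=False).tolist())

    probe_rows = []
    for g in genes:
        probe_rows.append({"probe_id": f"p_{g}_1", "gene": g})
        if g in decoy_genes:
            probe_rows.append({"probe_id": f"p_{g}_2", "gene": g})
    probes = pd.DataFrame(probe_rows).set_index("probe_id")

    id_to_pos = {pid: i for i, pid in enumerate(parc.ids)}
    left_ids = parc.ids[parc.hemisphere == "L"]
    tables = []
    for d in range(spec.n_donors):
        donor_id = f"donor{d + 1:02d}"
        pool = parc.ids if d < spec.n_right_hemisphere_donors else left_ids
        n_sampled = max(1, int(round((1 - spec.unsampled_fraction) * len(pool))))
        sampled = rng.choice(pool, size=n_sampled, replace=False)
        sampled = np.sort(sampled)
        coords = np.array([parc.centroids[id_to_pos[p]] for p in sampled])
        coords = coords + spec.sample_jitter_mm * rng.standard_normal(coords.shape)
        # jitter must not push a sample across the midline
        signs = np.where(
            np.array([p.startswith("R") for p in sampled]), 1.0, -1.0
        )
        coords[:, 0] = signs * np.abs(coords[:, 0])
        sample_ids = [f"{donor_id}_s{i:03d}" for i in range(len(sampled))]
        samples = pd.DataFrame(
            {"x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
             "structure": sampled},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        base = truth.loc[sampled].to_numpy()  # samples x genes
        log_expr = {}
        for j, g in enumerate(genes):
            signal = base[:, j] + spec.noise_sd * rng.standard_normal(len(sampled))
            log_expr[f"p_{g}_1"] = signal
            if g in decoy_genes:
                shuffled = truth[g].to_numpy()[
                    rng.permutation(len(parc))
                ][: len(sampled)]
                log_expr[f"p_{g}_2"] = (
                    shuffled + spec.noise_sd * rng.standard_normal(len(sampled))
                )
        expression = pd.DataFrame(
            {pid: 2.0 ** (6.0 + v) for pid, v in log_expr.items()}
        ).T
        expression.columns = samples.index
        expression = expression.reindex(probes.index)
        pa = pd.DataFrame(
            rng.random(expression.shape) >= spec.background_fraction,
            index=expression.index, columns=expression.columns,
        )
        tables.append(
            DonorSampleTable(
                donor_id=donor_id, samples=samples, probes=probes,
                expression=expression, pa_calls=pa,
            )
        )
    return tables, truth


def make_lifespan_dataset(
    spec: SyntheticSpec,
    genesets: Mapping[str, PathwayGeneSet],
    stage_table: StageTable,
) -> LifespanDataset:
    """Generate a developmental RPKM dataset with planted trajectories.

    For every (region, stage) cell, ``n_samples_per_region_stage``
    samples are drawn; each (stage, replicate) pair is one donor sampled
    in all regions, with an age log-uniform within the stage interval.
    log2(RPKM + 1) for a gene is a gene-specific baseline (uniform on
    [2, 6]) plus the planted stage effect of its gene set plus Gaussian
    noise. The dataset plants one always-low gene (``ALWAYSLOW``, RPKM
    around 0.2) to exercise the retention filter and duplicates the first
    pathway gene's symbol to exercise deduplication.
    """
    rng = np.random.default_rng(spec.seed + 2)
    regions = [f"region_{i}" for i in range(spec.n_regions)]
    stages = stage_table.stages
    genes: list[str] = []
    gene_set_of: dict[str, str] = {}
    for name, gs in genesets.items():
        for g in sorted(gs.genes):
            if g not in gene_set_of:
                genes.append(g)
                gene_set_of[g] = name
    # stage-stable background genes: the upper-quartile scaling must be
    # anchored by genes outside the planted pathways, as in genome-wide data
    for i in range(max(0, spec.n_genes - len(genes))):
        g = f"BKG{i:03d}"
        genes.append(g)
        gene_set_of[g] = "__background__"
    # robustly expressed genes (RPKM ~ 7-63): trajectories are defined for
    # genes that pass the detection filter, so planted genes must sit above
    # the RPKM >= 1 floor throughout their planted excursions
    baseline = {g: rng.uniform(3.0, 6.0) for g in genes}

    rows = []
    ages = {}
    t = stage_table.table
    for _, stage_row in t.iterrows():
        stage = stage_row["stage"]
        lo, hi = stage_row["min_pcd"], stage_row["max_pcd"]
        for rep in range(spec.n_samples_per_region_stage):
            donor = f"ls_{stage}_{rep:02d}"
            age = float(np.exp(rng.uniform(np.log(lo), np.log(hi - 1e-9))))
            ages[donor] = age
            for region in regions:
                rows.append(
                    {"sample_id": f"{donor}_{region}", "donor_id": donor,
                     "region": region, "age_pcd": age, "stage": stage}
                )
    samples = pd.DataFrame(rows).set_index("sample_id")

    log2_vals = np.empty((len(samples), len(genes)))
    stage_of_sample = samples["stage"].to_numpy()
    for j, g in enumerate(genes):
        mu = baseline[g]
        effects = np.array(
            [
                spec.stage_effects.get((gene_set_of[g], s), 0.0)
                for s in stage_of_sample
            ]
        )
        log2_vals[:, j] = (
            mu + effects + spec.lifespan_noise_sd
            * rng.standard_normal(len(samples))
        )
    rpkm = np.clip(2.0**log2_vals - 1.0, 0.0, None)
    expression = pd.DataFrame(rpkm, index=samples.index, columns=genes)

    # planted always-low gene: fails RPKM >= 1 nearly everywhere
    expression["ALWAYSLOW"] = np.clip(
        2.0 ** (0.2 + 0.1 * rng.standard_normal(len(samples))) - 1.0, 0.0, None
    )
    # duplicated gene symbol (second copy is noise; cleanup keeps the first)
    first = genes[0]
    dup = pd.DataFrame(
        {first: np.clip(
            2.0 ** rng.uniform(1.0, 3.0, len(samples)) - 1.0, 0.0, None
        )},
        index=samples.index,
    )
    expression = pd.concat([expression, dup], axis=1)
    return LifespanDataset(samples=samples, expression=expression)
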