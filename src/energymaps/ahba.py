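"""Donor microarray processing into a parcel-by-gene expression matrix.

The pipeline mirrors the standard workflow for regional transcriptomic
atlases built from a small number of post-mortem donors:

1. probes below background intensity in >=50% of samples (pooled across
   donors) are discarded;
2. when several probes index one gene, the probe with the highest
   differential stability (mean pairwise Spearman correlation of regional
   profiles across donors) is kept;
3. tissue samples are mirrored across the midline to increase spatial
   coverage, then assigned to the nearest parcel within a distance
   tolerance (2 mm by default);
4. expression is normalized per sample across genes with a robust sigmoid
   (median/IQR logistic) rescaled to [0, 1], then identically per gene
   across samples;
5. normalized samples are averaged within parcels per donor; parcels
   without samples are filled by inverse-distance-weighted interpolation
   from the donor's nearest samples;
6. donor matrices are averaged and genes with differential stability
   <= 0.1 are dropped.

Parcels are represented by their centroid coordinates; the assignment and
interpolation rules operate on centroids (a deliberate, documented
simplification relative to voxel-level atlases — no imaging files are
involved anywhere in this package).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

__all__ = [
    "ProbeRecord",
    "DonorSampleTable",
    "Parcellation",
    "RegionExpressionMatrix",
    "filter_probes",
    "differential_stability",
    "select_probe_per_gene",
    "mirror_samples",
    "assign_samples",
    "fill_missing_parcels",
    "robust_sigmoid",
    "select_probes_for_donors",
    "assemble",
]

#: IQR -> sigma conversion for a normal distribution, used as the robust
#: scale inside the sigmoid.
IQR_TO_SIGMA = 1.35

#: Distance floor (mm) for inverse-distance interpolation weights.
MIN_INTERP_DISTANCE_MM = 0.1


@dataclass
class ProbeRecord:
    """One probe's intensities and above-background flags over samples."""

    probe_id: str
    gene: str
    intensities: np.ndarray
    above_background: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.above_background = np.asarray(self.above_background, dtype=bool)
        if self.intensities.shape != self.above_background.shape:
            raise ValueError(
                f"probe {self.probe_id}: intensities and above_background "
                "must have equal length"
            )


@dataclass
class DonorSampleTable:
    """One donor's tissue samples and probe-level expression.

    ``samples`` is indexed by sample id with columns ``x``, ``y``, ``z``
    (mm, x > 0 = right hemisphere) and ``structure``; ``probes`` is indexed
    by probe id with a ``gene`` column; ``expression`` and ``pa_calls``
    are probe-by-sample matrices (intensities / above-background flags).
    """

    donor_id: str
    samples: pd.DataFrame
    probes: pd.DataFrame
    expression: pd.DataFrame
    pa_calls: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.samples) < 1:
            raise ValueError(f"donor {self.donor_id}: needs at least one sample")
        coords = self.samples[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"donor {self.donor_id}: non-finite sample coordinates")
        if not self.expression.columns.equals(self.samples.index):
            raise ValueError(f"donor {self.donor_id}: expression columns != samples")
        if self.expression.shape != self.pa_calls.shape:
            raise ValueError(f"donor {self.donor_id}: expression/pa_calls mismatch")

    def probe_records(self) -> list[ProbeRecord]:
        """View the probe matrices as a list of :class:`ProbeRecord`."""
        expr = self.expression.to_numpy(float)
        pa = self.pa_calls.to_numpy(bool)
        genes = self.probes["gene"]
        return [
            ProbeRecord(pid, genes.loc[pid], expr[i], pa[i])
            for i, pid in enumerate(self.expression.index)
        ]


@dataclass
class Parcellation:
    """Parcel ids with hemisphere labels, centroids and class annotations."""

    ids: np.ndarray
    hemisphere: np.ndarray  # 'L' / 'R' per parcel
    centroids: np.ndarray  # P x 3, mm
    annotations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.hemisphere = np.asarray(self.hemisphere)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("parcel ids must be unique")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("parcel centroids must be finite")
        for name, vec in self.annotations.items():
            vec = np.asarray(vec)
            if len(vec) != len(self.ids):
                raise ValueError(f"annotation '{name}' length != number of parcels")
            self.annotations[name] = vec

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class RegionExpressionMatrix:
    """Donor-averaged parcel-by-gene matrix with per-gene stability scores."""

    values: pd.DataFrame  # parcels x genes
    ds: pd.Series  # per-gene differential stability
    n_donors: int

    @property
    def parcels(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns


def filter_probes(
    probes: Sequence[ProbeRecord], max_below_fraction: float = 0.5
) -> list[ProbeRecord]:
    """Drop probes below background in >= ``max_below_fraction`` of samples.

    Records sharing a probe id (e.g., the same probe observed in several
    donors) are pooled before computing the below-background fraction, and
    the probe is retained or discarded as a unit. The boundary is
    inclusive: a probe below background in exactly half the samples is
    discarded at the default threshold.
    """
    if not 0 < max_below_fraction <= 1:
        raise ValueError("max_below_fraction must be in (0, 1]")
    pooled_below: dict[str, int] = {}
    pooled_total: dict[str, int] = {}
    for rec in probes:
        n = rec.above_background.size
        if n == 0:
            raise ValueError(f"probe {rec.probe_id} has zero samples")
        pooled_below[rec.probe_id] = pooled_below.get(rec.probe_id, 0) + int(
            (~rec.above_background).sum()
        )
        pooled_total[rec.probe_id] = pooled_total.get(rec.probe_id, 0) + n
    keep = {
        pid
        for pid in pooled_total
        if pooled_below[pid] / pooled_total[pid] < max_below_fraction
    }
    return [rec for rec in probes if rec.probe_id in keep]


def _spearman_pair(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = rankdata(x), rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def differential_stability(profiles: Mapping[str, pd.Series]) -> float:
    """Mean pairwise Spearman correlation of regional profiles across donors.

    Each value of ``profiles`` is one donor's parcel profile for a single
    gene (or probe); profiles are compared pairwise over the parcels
    sampled in both donors. Pairs where either profile has zero rank
    variance are excluded with a warning; if no pair is defined the score
    is NaN.
    """
    donors = list(profiles)
    if len(donors) < 2:
        raise ValueError("differential stability needs at least two donors")
    rhos = []
    undefined = 0
    for a, b in combinations(donors, 2):
        pa, pb = profiles[a], profiles[b]
        common = pa.index.intersection(pb.index)
        va = pa.loc[common].to_numpy(float)
        vb = pb.loc[common].to_numpy(float)
        ok = np.isfinite(va) & np.isfinite(vb)
        if ok.sum() < 2:
            undefined += 1
            continue
        rho = _spearman_pair(va[ok], vb[ok])
        if np.isnan(rho):
            undefined += 1
        else:
            rhos.append(rho)
    if undefined:
        warnings.warn(
            f"{undefined} donor pair(s) had undefined correlation (zero rank "
            "variance or insufficient overlap) and were excluded",
            stacklevel=2,
        )
    if not rhos:
        return float("nan")
    return float(np.mean(rhos))


def select_probe_per_gene(
    probes: Iterable[ProbeRecord],
    donor_profiles: Mapping[str, Mapping[str, pd.Series]],
) -> dict[str, str]:
    """Pick, per gene, the probe with the most donor-consistent profile.

    ``donor_profiles`` maps probe id -> donor id -> parcel profile. Ties
    on differential stability break to the lexicographically smaller probe
    id. Genes whose probes all lack a defined score are omitted.
    """
    by_gene: dict[str, list[str]] = {}
    for rec in probes:
        by_gene.setdefault(rec.gene, []).append(rec.probe_id)
    selection: dict[str, str] = {}
    for gene, pids in by_gene.items():
        pids = sorted(set(pids))
        if len(pids) == 1:
            selection[gene] = pids[0]
            continue
        best_pid, best_ds = None, -np.inf
        for pid in pids:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ds = differential_stability(donor_profiles[pid])
            if np.isnan(ds):
                continue
            if ds > best_ds:  # strict: earlier (lexicographic) pid wins ties
                best_pid, best_ds = pid, ds
        if best_pid is None:
            # no probe has a defined score; fall back to the first probe so
            # single-donor runs (where DS is undefined) still select one
            best_pid = pids[0]
        selection[gene] = best_pid
    return selection


def mirror_samples(table: DonorSampleTable) -> DonorSampleTable:
    """Duplicate every sample across the midline (x -> -x).

    Expression values and background flags are copied; mirrored samples
    get ids suffixed ``__m``. Sample count exactly doubles (midline
    samples produce a coincident duplicate, which is kept).
    """
    mirrored = table.samples.copy()
    mirrored["x"] = -mirrored["x"]
    mirrored.index = [f"{s}__m" for s in table.samples.index]
    samples = pd.concat([table.samples, mirrored])
    expr_m = table.expression.copy()
    expr_m.columns = mirrored.index
    pa_m = table.pa_calls.copy()
    pa_m.columns = mirrored.index
    return DonorSampleTable(
        donor_id=table.donor_id,
        samples=samples,
        probes=table.probes,
        expression=pd.concat([table.expression, expr_m], axis=1),
        pa_calls=pd.concat([table.pa_calls, pa_m], axis=1),
    )


def assign_samples(
    table: DonorSampleTable, parc: Parcellation, tol_mm: float = 2.0
) -> pd.Series:
    """Map each sample to its nearest parcel within ``tol_mm`` (else NaN).

    Assignment is hemisphere-respecting: a sample with x < 0 can only be
    assigned to left-hemisphere parcels, x > 0 only to right-hemisphere
    parcels (midline samples may match either). Among equidistant parcels
    within tolerance the one earliest in parcellation order wins.
    """
    if tol_mm <= 0:
        raise ValueError("tol_mm must be positive")
    if len(parc) == 0:
        raise ValueError("empty parcellation")
    coords = table.samples[["x", "y", "z"]].to_numpy(float)
    dists = cdist(coords, parc.centroids)
    # forbid cross-hemisphere matches
    sample_x = coords[:, 0]
    left_parcels = parc.hemisphere == "L"
    right_parcels = parc.hemisphere == "R"
    dists[np.ix_(sample_x < 0, right_parcels)] = np.inf
    dists[np.ix_(sample_x > 0, left_parcels)] = np.inf
    # np.argmin returns the first (lowest-index) minimizer: documented tie-break
    nearest = np.argmin(dists, axis=1)
    mind = dists[np.arange(len(coords)), nearest]
    assigned = np.where(mind <= tol_mm, parc.ids[nearest], None)
    return pd.Series(assigned, index=table.samples.index, name="parcel")


def fill_missing_parcels(
    matrix: pd.DataFrame,
    sample_values: pd.DataFrame,
    sample_coords: pd.DataFrame,
    parc: Parcellation,
    k: int = 10,
) -> pd.DataFrame:
    """Complete empty parcel rows by inverse-distance-weighted interpolation.

    Each all-NaN parcel row receives the weighted mean of the ``k``
    nearest samples to the parcel centroid, with weights 1/d normalized to
    sum one and distances floored at 0.1 mm. ``sample_values`` is a
    sample-by-gene matrix aligned with ``sample_coords`` rows. (This is a
    parcel-level counterpart of a voxel-wise nearest-sample rule.)
    """
    if len(sample_values) == 0:
        raise ValueError("donor has zero samples; cannot interpolate")
    out = matrix.copy()
    missing = out.index[out.isna().all(axis=1)]
    if len(missing) == 0:
        return out
    coords = sample_coords[["x", "y", "z"]].to_numpy(float)
    values = sample_values.to_numpy(float)
    id_to_pos = {pid: i for i, pid in enumerate(parc.ids)}
    for pid in missing:
        centroid = parc.centroids[id_to_pos[pid]][None, :]
        d = cdist(centroid, coords)[0]
        order = np.argsort(d, kind="stable")[: min(k, len(d))]
        w = 1.0 / np.maximum(d[order], MIN_INTERP_DISTANCE_MM)
        w /= w.sum()
        out.loc[pid] = w @ values[order]
    return out


def robust_sigmoid(values: np.ndarray, rescale: bool = True) -> np.ndarray:
    """Outlier-robust logistic normalization, optionally unit-rescaled.

    y_i = 1 / (1 + exp(-(x_i - median) / (IQR / 1.35))); with ``rescale``
    the result is min-max scaled to [0, 1]. The transform is strictly
    order-preserving whenever IQR > 0. A zero-IQR input yields the
    constant 0.5 (flagged with a warning; the rescale is skipped).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("robust_sigmoid needs at least two values")
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        warnings.warn("zero IQR: robust_sigmoid returns a constant 0.5 map",
                      stacklevel=2)
        return np.full_like(x, 0.5)
    with np.errstate(over="ignore"):  # exp overflow saturates to y = 0
        y = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / IQR_TO_SIGMA)))
    if rescale:
        lo, hi = y.min(), y.max()
        y = (y - lo) / (hi - lo)
    return y


def _normalize_sample_matrix(gene_by_sample: pd.DataFrame) -> pd.DataFrame:
    """Two-pass robust-sigmoid normalization of a gene-by-sample matrix.

    Pass 1 normalizes across genes within each sample; pass 2 across
    samples within each gene. Each pass is followed by a unit-interval
    rescale (per vector).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pass1 = gene_by_sample.apply(
            lambda col: pd.Series(robust_sigmoid(col.to_numpy()), index=col.index),
            axis=0,
        )
        pass2 = pass1.apply(
            lambda row: pd.Series(robust_sigmoid(row.to_numpy()), index=row.index),
            axis=1,
        )
    return pass2


def select_probes_for_donors(
    donors: Sequence[DonorSampleTable],
    parc: Parcellation,
    tol_mm: float = 2.0,
    max_below_fraction: float = 0.5,
    mirror: bool = True,
):
    """Background-filter probes, assign samples and pick one probe per gene.

    Returns ``(selection, donor_profiles, prepared)``: the gene -> probe
    mapping, the per-probe donor regional profiles used to score it, and
    the (mirrored table, assignment) pairs for downstream assembly.
    """
    if len(donors) == 0:
        raise ValueError("needs at least one donor")

    # 1. probe intensity filter, pooled over all donors' samples
    all_records = [rec for t in donors for rec in t.probe_records()]
    retained = filter_probes(all_records, max_below_fraction)
    retained_ids = sorted({r.probe_id for r in retained})
    if not retained_ids:
        raise ValueError("no probes survive the background-intensity filter")

    # 2. mirror and assign each donor's samples
    prepared = []
    for table in donors:
        t = mirror_samples(table) if mirror else table
        assignment = assign_samples(t, parc, tol_mm)
        keep = assignment.notna()
        prepared.append((t, assignment[keep]))

    # 3. per-probe regional profiles (raw parcel means) -> probe selection
    donor_profiles: dict[str, dict[str, pd.Series]] = {
        pid: {} for pid in retained_ids
    }
    for t, assignment in prepared:
        expr = t.expression.loc[retained_ids, assignment.index]
        prof = expr.T.groupby(assignment).mean()  # parcel x probe
        for pid in retained_ids:
            donor_profiles[pid][t.donor_id] = prof[pid]
    probe_meta = {r.probe_id: r.gene for r in retained}
    records_unique = [
        ProbeRecord(pid, probe_meta[pid], np.zeros(1), np.zeros(1, dtype=bool))
        for pid in retained_ids
    ]
    selection = select_probe_per_gene(records_unique, donor_profiles)
    return selection, donor_profiles, prepared


def assemble(
    donors: Sequence[DonorSampleTable],
    parc: Parcellation,
    ds_threshold: float = 0.1,
    tol_mm: float = 2.0,
    max_below_fraction: float = 0.5,
    k_interp: int = 10,
    mirror: bool = True,
) -> RegionExpressionMatrix:
    """Run the full donor-to-region pipeline; see the module docstring.

    Genes are retained when their differential stability is strictly
    greater than ``ds_threshold``; with a single donor stability is
    undefined and the filter is skipped.
    """
    selection, donor_profiles, prepared = select_probes_for_donors(
        donors, parc, tol_mm=tol_mm, max_below_fraction=max_below_fraction,
        mirror=mirror,
    )
    genes = sorted(selection)
    probe_of = {g: selection[g] for g in genes}

    # 4. per-donor normalization, parcel averaging, interpolation
    parcel_index = pd.Index(parc.ids, name="parcel")
    donor_matrices = []
    for t, assignment in prepared:
        gene_by_sample = t.expression.loc[[probe_of[g] for g in genes],
                                          assignment.index]
        gene_by_sample.index = pd.Index(genes, name="gene")
        normalized = _normalize_sample_matrix(gene_by_sample)
        sample_by_gene = normalized.T  # samples x genes
        parcel_means = sample_by_gene.groupby(assignment).mean()
        donor_matrix = parcel_means.reindex(parcel_index)
        donor_matrix = fill_missing_parcels(
            donor_matrix,
            sample_by_gene,
            t.samples.loc[assignment.index],
            parc,
            k=k_interp,
        )
        donor_matrices.append(donor_matrix)

    # 5. donor averaging and the differential-stability gene filter
    stacked = pd.concat(donor_matrices, keys=range(len(donor_matrices)))
    mean_matrix = stacked.groupby(level=1, sort=False).mean().reindex(parcel_index)
    if mean_matrix.isna().all(axis=1).any():
        bad = mean_matrix.index[mean_matrix.isna().all(axis=1)].tolist()
        raise ValueError(f"parcels with no expression in any donor: {bad}")

    if len(donors) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = pd.Series(
                {g: differential_stability(donor_profiles[probe_of[g]])
                 for g in genes}
            )
        keep_genes = ds.index[ds > ds_threshold]
        mean_matrix = mean_matrix[keep_genes]
        ds = ds[keep_genes]
    else:
        ds = pd.Series(np.nan, index=pd.Index(genes))

    return RegionExpressionMatrix(
        values=mean_matrix, ds=ds, n_donors=len(donors)
    )
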