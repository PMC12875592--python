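"""Per-pathway parcel maps: mean expression, first principal component,
z-scoring and aggregation over parcel groupings."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .ahba import RegionExpressionMatrix
from .genesets import PathwayGeneSet

__all__ = [
    "BrainMap",
    "pathway_mean_map",
    "zscore_map",
    "pathway_pc1_map",
    "group_mean",
]


@dataclass
class BrainMap:
    """One scalar per parcel, with provenance metadata.

    ``kind`` is one of ``mean``, ``pc1`` or ``zscored``;
    ``variance_explained`` is set for PC1 maps only.
    """

    parcels: pd.Index
    values: np.ndarray
    name: str = ""
    kind: str = "mean"
    variance_explained: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.parcels):
            raise ValueError("map length does not match parcel count")

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.parcels, name=self.name)


def _pathway_submatrix(
    expr: RegionExpressionMatrix, gs: PathwayGeneSet
) -> pd.DataFrame:
    present = [g for g in sorted(gs.genes) if g in expr.genes]
    absent = sorted(gs.genes - set(present))
    if not present:
        raise ValueError(
            f"no genes of pathway '{gs.name}' are present in the expression "
            f"matrix (absent: {absent})"
        )
    if absent:
        warnings.warn(
            f"pathway '{gs.name}': {len(absent)} gene(s) absent from the "
            f"expression matrix: {absent}",
            stacklevel=3,
        )
    return expr.values[present]


def pathway_mean_map(
    expr: RegionExpressionMatrix, gs: PathwayGeneSet
) -> BrainMap:
    """Per-parcel unweighted mean over the pathway's available genes."""
    sub = _pathway_submatrix(expr, gs)
    return BrainMap(
        parcels=sub.index,
        values=sub.to_numpy().mean(axis=1),
        name=gs.name,
        kind="mean",
        meta={"n_genes": sub.shape[1]},
    )


def zscore_map(m: BrainMap) -> BrainMap:
    """Standardize a map to mean 0, population SD 1."""
    sd = float(np.std(m.values))
    if sd == 0:
        raise ValueError("cannot z-score a constant map")
    return BrainMap(
        parcels=m.parcels,
        values=(m.values - m.values.mean()) / sd,
        name=m.name,
        kind="zscored",
        meta=dict(m.meta),
    )


def pathway_pc1_map(
    expr: RegionExpressionMatrix, gs: PathwayGeneSet
) -> BrainMap:
    """First principal component of the parcel-by-pathway-gene submatrix.

    Gene columns are centered and scaled (correlation PCA); the component
    is sign-oriented to correlate non-negatively with the pathway mean
    map. ``variance_explained`` is the PC1 share of total variance.
    """
    sub = _pathway_submatrix(expr, gs)
    if sub.shape[1] < 2:
        raise ValueError("PC1 needs at least two pathway genes present")
    if sub.shape[0] <= 2:
        raise ValueError("PC1 needs more than two parcels")
    X = sub.to_numpy()
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        constant = sub.columns[sd == 0].tolist()
        raise ValueError(f"constant gene column(s) cannot be standardized: {constant}")
    Z = (X - X.mean(axis=0)) / sd
    if np.linalg.matrix_rank(Z) < 1 or len(np.unique(Z, axis=0)) < 2:
        raise ValueError("degenerate input: fewer than two distinct parcel rows")
    # SVD of the standardized matrix: scores = U * S, var share = S^2 / sum S^2
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, 0] * S[0]
    varexp = float(S[0] ** 2 / np.sum(S**2))
    mean_map = X.mean(axis=1)
    orient = np.corrcoef(scores, mean_map)[0, 1]
    if orient < 0:
        scores = -scores
    return BrainMap(
        parcels=sub.index,
        values=scores,
        name=gs.name,
        kind="pc1",
        variance_explained=varexp,
        meta={"n_genes": sub.shape[1]},
    )


def group_mean(m: BrainMap, labels, ignore: str | None = None) -> pd.DataFrame:
    """Per-class unweighted means of a map over a categorical annotation.

    Returns a table with columns ``class``, ``n_parcels`` and ``mean``.
    Parcels labelled ``ignore`` are excluded; empty classes are omitted
    with a warning.
    """
    labels = np.asarray(labels)
    if len(labels) != len(m.parcels):
        raise ValueError("labels length does not match map length")
    rows = []
    classes = pd.unique(labels)
    for cls in classes:
        if ignore is not None and cls == ignore:
            continue
        mask = labels == cls
        if mask.sum() == 0:
            warnings.warn(f"class '{cls}' has zero parcels; omitted", stacklevel=2)
            continue
        rows.append(
            {"class": cls, "n_parcels": int(mask.sum()),
             "mean": float(m.values[mask].mean())}
        )
    return pd.DataFrame(rows)
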