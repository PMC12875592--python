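"""Developmental (lifespan) transcriptome trajectories.

Operates on RPKM-scale expression sampled across donors, cortical regions
and post-conception ages. The procedure: basic cleanup (regions must have
at least one sample in every developmental stage; duplicate gene symbols
collapse to their first occurrence; genes must reach RPKM >= 1 in at
least 80% of samples of every retained region-by-stage cell), log2(x+1)
transform, upper-quartile cross-donor normalization, per-pathway sample
means, per-stage medians, and LOESS smoothing against log10 age.

A microarray variant of the retention filter (log2 signal >= 6) is
available through ``cleanup(..., variant="log2signal")``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genesets import PathwayGeneSet

__all__ = [
    "StageTable",
    "LifespanDataset",
    "load_stage_table",
    "cleanup",
    "log2_transform",
    "upper_quartile_normalize",
    "stage_trajectory",
    "loess_trajectory",
]


@dataclass
class StageTable:
    """Ordered developmental stages as [min_pcd, max_pcd) age intervals."""

    table: pd.DataFrame  # columns: stage, min_pcd, max_pcd, index

    def __post_init__(self) -> None:
        t = self.table.sort_values("index").reset_index(drop=True)
        if (t["min_pcd"] >= t["max_pcd"]).any():
            raise ValueError("stage intervals must have min_pcd < max_pcd")
        if not np.allclose(t["max_pcd"].to_numpy()[:-1],
                           t["min_pcd"].to_numpy()[1:]):
            raise ValueError("stage intervals must be contiguous and ordered")
        self.table = t

    @property
    def stages(self) -> list[str]:
        return self.table["stage"].tolist()

    def stage_of(self, age_pcd: float) -> str:
        t = self.table
        hit = t[(t["min_pcd"] <= age_pcd) & (age_pcd < t["max_pcd"])]
        if hit.empty:
            raise ValueError(f"age {age_pcd} pcd outside the covered range")
        return str(hit.iloc[0]["stage"])

    def assign(self, ages_pcd: Sequence[float]) -> pd.Series:
        return pd.Series([self.stage_of(a) for a in ages_pcd])


def load_stage_table(path: str | Path | None = None) -> StageTable:
    """Load a stage table TSV; defaults to the packaged eight-stage table
    (early fetal through adulthood, boundaries in post-conception days
    following conventional developmental-stage definitions)."""
    if path is None:
        with resources.as_file(
            resources.files("energymaps.data").joinpath("stage_table.tsv")
        ) as p:
            return load_stage_table(p)
    return StageTable(pd.read_csv(path, sep="\t"))


@dataclass
class LifespanDataset:
    """Developmental samples and their RPKM-scale expression.

    ``samples`` is indexed by sample id with columns ``donor_id``,
    ``region``, ``age_pcd`` and ``stage``; ``expression`` is a
    sample-by-gene matrix (duplicate gene columns are permitted before
    cleanup).
    """

    samples: pd.DataFrame
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.samples.index.equals(self.expression.index):
            raise ValueError("samples and expression must share an index")
        if (self.samples["age_pcd"] <= 0).any():
            raise ValueError("ages must be positive (post-conception days)")
        vals = self.expression.to_numpy(float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("expression values must be finite and >= 0")

    @property
    def genes(self) -> pd.Index:
        return self.expression.columns


def cleanup(
    dataset: LifespanDataset,
    stage_table: StageTable,
    min_rpkm: float = 1.0,
    min_fraction: float = 0.8,
    variant: str = "rpkm",
    log2_signal_threshold: float = 6.0,
) -> LifespanDataset:
    """Apply the three cleanup filters; idempotent.

    1. Keep regions with >= 1 sample in every stage of ``stage_table``.
    2. Collapse duplicate gene symbols to their first occurrence.
    3. Keep genes whose value passes the retention threshold in at least
       ``min_fraction`` of samples within *every* retained region-by-stage
       cell (RPKM >= ``min_rpkm``, or log2(signal) >= ``log2_signal_threshold``
       for the microarray variant). The 80% boundary is inclusive.
    """
    if variant not in ("rpkm", "log2signal"):
        raise ValueError("variant must be 'rpkm' or 'log2signal'")
    samples = dataset.samples
    stages = stage_table.stages

    counts = samples.groupby(["region", "stage"]).size().unstack(fill_value=0)
    counts = counts.reindex(columns=stages, fill_value=0)
    good_regions = counts.index[(counts > 0).all(axis=1)]
    if len(good_regions) == 0:
        raise ValueError("no region has samples in every developmental stage")
    keep_samples = samples["region"].isin(good_regions)
    samples = samples[keep_samples]
    expression = dataset.expression.loc[samples.index]

    # duplicate gene symbols -> first occurrence
    dup = expression.columns.duplicated(keep="first")
    expression = expression.loc[:, ~dup]

    threshold = min_rpkm if variant == "rpkm" else float(2.0**log2_signal_threshold)
    passing = expression.to_numpy(float) >= threshold
    passing = pd.DataFrame(passing, index=expression.index,
                           columns=expression.columns)
    cell_frac = passing.groupby(
        [samples["region"], samples["stage"]]
    ).mean()
    keep_genes = (cell_frac >= min_fraction).all(axis=0)
    expression = expression.loc[:, keep_genes[keep_genes].index]
    if expression.shape[1] == 0:
        warnings.warn("no gene passes the retention filter", stacklevel=2)
    return LifespanDataset(samples=samples.copy(), expression=expression.copy())


def log2_transform(values: np.ndarray | pd.DataFrame):
    """Elementwise log2(x + 1); input must be nonnegative."""
    arr = values.to_numpy(float) if isinstance(values, pd.DataFrame) else np.asarray(
        values, float
    )
    if (arr < 0).any():
        raise ValueError("log2_transform requires nonnegative values")
    out = np.log2(arr + 1.0)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def upper_quartile_normalize(dataset: LifespanDataset) -> LifespanDataset:
    """Equalize donors' 75th-percentile expression.

    Each donor's values are divided by that donor's 75th percentile
    (linear-interpolation quantile over all of the donor's entries) and
    multiplied by the mean 75th percentile across donors, so that after
    normalization every donor's q75 equals the pre-normalization mean q75.
    """
    donors = dataset.samples["donor_id"]
    q75 = {}
    for donor, idx in donors.groupby(donors).groups.items():
        vals = dataset.expression.loc[idx].to_numpy(float)
        q = float(np.percentile(vals, 75))
        if q <= 0:
            raise ValueError(f"donor {donor}: 75th percentile is not positive")
        q75[donor] = q
    mean_q75 = float(np.mean(list(q75.values())))
    expr = dataset.expression.copy().astype(float)
    for donor, idx in donors.groupby(donors).groups.items():
        expr.loc[idx] = expr.loc[idx] * (mean_q75 / q75[donor])
    return LifespanDataset(samples=dataset.samples.copy(), expression=expr)


def stage_trajectory(
    dataset: LifespanDataset,
    gs: PathwayGeneSet,
    stage_table: StageTable,
) -> pd.DataFrame:
    """Per-stage medians of the per-sample pathway mean expression.

    Returns a table with columns ``stage``, ``n`` and ``median``, ordered
    by stage; stages without samples are omitted with a warning.
    """
    present = [g for g in sorted(gs.genes) if g in dataset.expression.columns]
    if not present:
        raise ValueError(f"no genes of pathway '{gs.name}' in the dataset")
    sample_means = dataset.expression[present].mean(axis=1)
    rows = []
    for stage in stage_table.stages:
        mask = dataset.samples["stage"] == stage
        if mask.sum() == 0:
            warnings.warn(f"stage '{stage}' has no samples; omitted", stacklevel=2)
            continue
        rows.append(
            {"stage": stage, "n": int(mask.sum()),
             "median": float(sample_means[mask].median())}
        )
    return pd.DataFrame(rows)


def loess_trajectory(
    ages_pcd: Sequence[float],
    values: Sequence[float],
    span: float = 0.75,
    n_grid: int = 100,
) -> pd.DataFrame:
    """LOESS smoothing of values against log10(age), on an even grid.

    Degree-1 (locally linear) fits with tricube weights; the bandwidth at
    each grid point is the distance to the ceil(span * n)-th nearest
    design point. Returns columns ``log10_age`` and ``fitted``. Exact for
    inputs linear in log10(age).
    """
    ages = np.asarray(ages_pcd, dtype=float)
    y = np.asarray(values, dtype=float)
    if ages.size != y.size:
        raise ValueError("ages and values must have equal length")
    if ages.size < 10:
        raise ValueError("loess_trajectory needs at least 10 points")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if (ages <= 0).any():
        raise ValueError("ages must be positive")
    x = np.log10(ages)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct ages")
    grid = np.linspace(x.min(), x.max(), n_grid)
    q = max(2, int(np.ceil(span * x.size)))
    q = min(q, x.size)
    fitted = np.empty(n_grid)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.sort(d)[q - 1]
        if h == 0:
            fitted[i] = y[d == 0].mean()
            continue
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        sw = w.sum()
        # weighted least squares on [1, x - x0]; intercept = fit at x0
        xc = x - x0
        swx = (w * xc).sum()
        swxx = (w * xc * xc).sum()
        swy = (w * y).sum()
        swxy = (w * xc * y).sum()
        denom = sw * swxx - swx**2
        if denom <= np.finfo(float).eps * sw * swxx:
            fitted[i] = swy / sw  # local design is degenerate; fall back to mean
        else:
            beta = (sw * swxy - swx * swy) / denom
            alpha = (swy - beta * swx) / sw
            fitted[i] = alpha
    return pd.DataFrame({"log10_age": grid, "fitted": fitted})
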