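"""Plain-text readers and writers with metadata sidecars.

Every numeric artifact is a tab-delimited table with a single header
line; each writer can attach a JSON sidecar (``<file>.meta.json``)
recording the seed and configuration hash of the producing run. Floats
are written with a fixed format so identical runs produce byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ahba import DonorSampleTable, Parcellation
from .lifespan import LifespanDataset
from .spatial import SpinEnsemble

__all__ = [
    "write_tsv",
    "read_tsv",
    "sha256_of",
    "write_donor_table",
    "read_donor_table",
    "write_parcellation",
    "read_parcellation",
    "write_ensemble",
    "read_ensemble",
    "write_lifespan",
    "read_lifespan",
]

FLOAT_FORMAT = "%.10g"


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    metadata: dict | None = None,
    index: bool = True,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index,
              lineterminator="\n")
    if metadata is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(metadata, sort_keys=True, indent=1) + "\n")
    return path


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    try:
        return pd.read_csv(path, sep="\t", index_col=index_col)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as err:
        raise ValueError(f"malformed table {path}: {err}") from err


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_donor_table(table: DonorSampleTable, outdir: str | Path) -> Path:
    """Write one donor as the samples/probes/expression/pa_calls TSV trio."""
    outdir = Path(outdir) / table.donor_id
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(table.samples, outdir / "samples.tsv")
    write_tsv(table.probes, outdir / "probes.tsv")
    write_tsv(table.expression, outdir / "expression.tsv")
    write_tsv(table.pa_calls.astype(int), outdir / "pa_calls.tsv")
    return outdir


def read_donor_table(donor_dir: str | Path) -> DonorSampleTable:
    donor_dir = Path(donor_dir)
    samples = read_tsv(donor_dir / "samples.tsv")
    probes = read_tsv(donor_dir / "probes.tsv")
    expression = read_tsv(donor_dir / "expression.tsv")
    pa = read_tsv(donor_dir / "pa_calls.tsv").astype(bool)
    for col in ("x", "y", "z", "structure"):
        if col not in samples.columns:
            raise ValueError(f"{donor_dir}/samples.tsv lacks column '{col}'")
    return DonorSampleTable(
        donor_id=donor_dir.name, samples=samples, probes=probes,
        expression=expression, pa_calls=pa,
    )


def write_parcellation(parc: Parcellation, path: str | Path) -> Path:
    df = pd.DataFrame(
        {"parcel_id": parc.ids, "hemisphere": parc.hemisphere,
         "x": parc.centroids[:, 0], "y": parc.centroids[:, 1],
         "z": parc.centroids[:, 2]}
    )
    for name, vec in parc.annotations.items():
        df[name] = vec
    return write_tsv(df, path, index=False)


def read_parcellation(path: str | Path) -> Parcellation:
    df = read_tsv(path, index_col=None)
    required = {"parcel_id", "hemisphere", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parcellation {path} lacks column(s) {sorted(missing)}")
    annotations = {
        c: df[c].to_numpy() for c in df.columns if c not in required
    }
    return Parcellation(
        ids=df["parcel_id"].to_numpy(),
        hemisphere=df["hemisphere"].to_numpy(),
        centroids=df[["x", "y", "z"]].to_numpy(float),
        annotations=annotations,
    )


def write_ensemble(ens: SpinEnsemble, path: str | Path) -> Path:
    """Write permutation rows as an integer TSV plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, ens.perms, fmt="%d", delimiter="\t")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {"seed": ens.seed, "n_rot": ens.n_rot,
             "n_parcels": ens.n_parcels,
             "centroid_source": ens.centroid_source},
            sort_keys=True, indent=1,
        )
        + "\n"
    )
    return path


def read_ensemble(path: str | Path) -> SpinEnsemble:
    path = Path(path)
    perms = np.loadtxt(path, dtype=np.int64, delimiter="\t", ndmin=2)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return SpinEnsemble(
        perms=perms, seed=int(meta.get("seed", -1)),
        centroid_source=str(meta.get("centroid_source", "")),
    )


def write_lifespan(ds: LifespanDataset, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(ds.samples, outdir / "lifespan_samples.tsv")
    # gene x sample orientation, mirroring consortium-style exports
    write_tsv(ds.expression.T, outdir / "lifespan_expression.tsv")
    return outdir


def read_lifespan(outdir: str | Path) -> LifespanDataset:
    outdir = Path(outdir)
    samples = read_tsv(outdir / "lifespan_samples.tsv")
    expression = read_tsv(outdir / "lifespan_expression.tsv").T
    expression = expression.loc[samples.index]
    return LifespanDataset(samples=samples, expression=expression)
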