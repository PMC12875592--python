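"""Run configuration and the end-to-end pipeline.

``run_pipeline`` chains gene-set loading, donor-matrix assembly, pathway
map construction, spin-null inference and the lifespan trajectory
analysis into one reproducible run: every artifact is a TSV with a
metadata sidecar, and a manifest records a checksum for each output.
Identical configuration and seed reproduce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ahba, genesets as gsmod, io, lifespan as lsmod, maps as mapsmod
from . import spatial, synthetic

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    When ``donor_dirs`` is empty the inputs are simulated from
    ``synthetic`` (a :class:`~energymaps.synthetic.SyntheticSpec` field
    mapping); otherwise donor tables and the parcellation are read from
    the given paths.
    """

    output_dir: str = "results/run"
    seed: int = 0
    n_rot: int = 10_000
    ds_threshold: float = 0.1
    tolerance_mm: float = 2.0
    filter_variant: str = "rpkm"
    geneset_path: str | None = None
    parcellation_path: str | None = None
    donor_dirs: list[str] = field(default_factory=list)
    lifespan_dir: str | None = None
    stage_table_path: str | None = None
    enrichment_fdr: bool = True
    synthetic: dict = field(default_factory=dict)


def validate_config(cfg: RunConfig | dict | str | Path) -> RunConfig:
    """Fill defaults, check ranges and referenced paths; idempotent."""
    if isinstance(cfg, (str, Path)):
        with open(cfg) as fh:
            cfg = yaml.safe_load(fh) or {}
    if isinstance(cfg, dict):
        unknown = set(cfg) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = RunConfig(**cfg)
    if cfg.n_rot < 1:
        raise ValueError("n_rot must be >= 1")
    if not 0 <= cfg.ds_threshold <= 1:
        raise ValueError("ds_threshold must be in [0, 1]")
    if cfg.tolerance_mm <= 0:
        raise ValueError("tolerance_mm must be positive")
    if cfg.filter_variant not in ("rpkm", "log2signal"):
        raise ValueError("filter_variant must be 'rpkm' or 'log2signal'")
    for attr in ("geneset_path", "parcellation_path", "stage_table_path",
                 "lifespan_dir"):
        p = getattr(cfg, attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{attr}: no such path: {p}")
    for d in cfg.donor_dirs:
        if not Path(d).exists():
            raise FileNotFoundError(f"donor_dirs: no such path: {d}")
    if cfg.donor_dirs and cfg.parcellation_path is None:
        raise ValueError("donor_dirs given but parcellation_path missing")
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    cfg = validate_config(cfg)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": cfg.seed, "config_hash": _config_hash(cfg)}
    artifacts: list[Path] = []

    def save(df: pd.DataFrame, name: str, index: bool = True) -> None:
        artifacts.append(io.write_tsv(df, out / name, metadata=meta,
                                      index=index))

    stage = "genesets"
    try:
        sets = gsmod.load_final_genesets(cfg.geneset_path)
        save(gsmod.overlap_matrix(sets), "geneset_overlaps.tsv")

        stage = "inputs"
        spec = synthetic.SyntheticSpec(seed=cfg.seed, **cfg.synthetic)
        if cfg.donor_dirs:
            donors = [io.read_donor_table(d) for d in cfg.donor_dirs]
            parc = io.read_parcellation(cfg.parcellation_path)
        else:
            parc = synthetic.make_parcellation(spec)
            donors, truth = synthetic.make_donor_tables(spec, parc, sets)
            inputs = out / "inputs"
            io.write_parcellation(parc, inputs / "parcellation.tsv")
            for t in donors:
                io.write_donor_table(t, inputs / "donors")
            io.write_tsv(truth, inputs / "ground_truth_patterns.tsv")

        stage = "assemble"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            expr = ahba.assemble(
                donors, parc, ds_threshold=cfg.ds_threshold,
                tol_mm=cfg.tolerance_mm,
            )
        save(expr.values, "region_by_gene_expression.tsv")
        save(expr.ds.rename("ds").to_frame(), "differential_stability.tsv")

        stage = "maps"
        mean_maps, z_maps, map_table = {}, {}, {}
        pc1_rows = []
        for name, gs in sets.items():
            try:
                m = mapsmod.pathway_mean_map(expr, gs)
            except ValueError:
                continue
            mean_maps[name] = m
            z_maps[name] = mapsmod.zscore_map(m)
            map_table[f"{name}_mean"] = m.values
            map_table[f"{name}_z"] = z_maps[name].values
            try:
                pc1 = mapsmod.pathway_pc1_map(expr, gs)
                map_table[f"{name}_pc1"] = pc1.values
                pc1_rows.append({"pathway": name,
                                 "variance_explained": pc1.variance_explained})
            except ValueError:
                pass
        maps_df = pd.DataFrame(map_table, index=expr.parcels)
        save(maps_df, "pathway_maps.tsv")
        save(pd.DataFrame(pc1_rows), "pc1_variance_explained.tsv", index=False)

        stage = "spin-nulls"
        ens = spatial.spin_permutations(parc, n_rot=cfg.n_rot, seed=cfg.seed)
        artifacts.append(io.write_ensemble(ens, out / "spin_ensemble.tsv"))

        stage = "correlate"
        names = list(mean_maps)
        rho = pd.DataFrame(np.nan, index=names, columns=names)
        pspin = pd.DataFrame(np.nan, index=names, columns=names)
        for i, a in enumerate(names):
            for b in names[i:]:
                if a == b:
                    rho.loc[a, b] = 1.0
                    continue
                res = spatial.spin_correlation_test(mean_maps[a],
                                                    mean_maps[b], ens)
                rho.loc[a, b] = rho.loc[b, a] = res.rho
                pspin.loc[a, b] = pspin.loc[b, a] = res.p_spin
        save(rho, "map_correlations_rho.tsv")
        save(pspin, "map_correlations_pspin.tsv")

        stage = "enrich"
        enr_rows = []
        for ann_name, labels in parc.annotations.items():
            for pw, zmap in z_maps.items():
                for res in spatial.class_enrichment_test(zmap, labels, ens):
                    enr_rows.append(
                        {"annotation": ann_name, "pathway": pw,
                         "class": res.label,
                         "observed_mean": res.observed_mean,
                         "p_spin": res.p_spin, "direction": res.direction}
                    )
        enr = pd.DataFrame(enr_rows)
        if len(enr) and cfg.enrichment_fdr:
            enr["p_spin_fdr"] = spatial.bh_fdr(enr["p_spin"].to_numpy())
        save(enr, "class_enrichment.tsv", index=False)

        stage = "lifespan"
        stages = lsmod.load_stage_table(cfg.stage_table_path)
        if cfg.lifespan_dir:
            ls = io.read_lifespan(cfg.lifespan_dir)
        else:
            ls = synthetic.make_lifespan_dataset(spec, sets, stages)
            io.write_lifespan(ls, out / "inputs")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ls = lsmod.cleanup(ls, stages, variant=cfg.filter_variant)
            ls = lsmod.LifespanDataset(
                samples=ls.samples,
                expression=lsmod.log2_transform(ls.expression),
            )
            ls = lsmod.upper_quartile_normalize(ls)
        traj_rows, curves = [], {}
        for name, gs in sets.items():
            try:
                traj = lsmod.stage_trajectory(ls, gs, stages)
            except ValueError:
                continue
            traj.insert(0, "pathway", name)
            traj_rows.append(traj)
            present = [g for g in sorted(gs.genes) if g in ls.expression.columns]
            sample_means = ls.expression[present].mean(axis=1)
            curve = lsmod.loess_trajectory(
                ls.samples["age_pcd"].to_numpy(), sample_means.to_numpy()
            )
            curves[f"{name}_fitted"] = curve["fitted"].to_numpy()
            curves["log10_age"] = curve["log10_age"].to_numpy()
        if traj_rows:
            save(pd.concat(traj_rows, ignore_index=True),
                 "stage_trajectories.tsv", index=False)
        if curves:
            grid = curves.pop("log10_age")
            save(pd.DataFrame(curves, index=pd.Index(grid, name="log10_age")),
                 "loess_curves.tsv")
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_hash": _config_hash(cfg),
        "artifacts": {
            str(p.relative_to(out)): io.sha256_of(p) for p in sorted(artifacts)
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    )
    return manifest
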