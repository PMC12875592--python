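"""Developmental trajectories: cleanup, normalization, medians, LOESS."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import energymaps.lifespan as ls
import energymaps.synthetic as syn
from energymaps.genesets import PathwayGeneSet


def make_dataset(cells, genes_values, ages=None):
    """cells: list of (region, stage, n_samples); genes_values: dict
    gene -> callable(region, stage, rep) -> rpkm."""
    rows, data = [], {g: [] for g in genes_values}
    stage_mid = {
        s: 0.5 * (lo + hi)
        for s, lo, hi in zip(
            ls.load_stage_table().stages,
            ls.load_stage_table().table["min_pcd"],
            ls.load_stage_table().table["max_pcd"],
        )
    }
    for region, stage, n in cells:
        for rep in range(n):
            sid = f"{region}_{stage}_{rep}"
            rows.append(
                {"sample_id": sid, "donor_id": f"d_{stage}_{rep}",
                 "region": region, "age_pcd": stage_mid[stage],
                 "stage": stage}
            )
            for g, fn in genes_values.items():
                data[g].append(fn(region, stage, rep))
    samples = pd.DataFrame(rows).set_index("sample_id")
    expression = pd.DataFrame(data, index=samples.index)
    return ls.LifespanDataset(samples=samples, expression=expression)


@pytest.fixture(scope="module")
def stages():
    return ls.load_stage_table()


class TestStageTable:
    def test_eight_ordered_contiguous_stages(self, stages):
        assert len(stages.stages) == 8
        assert stages.stages[0] == "early_fetal"
        assert stages.stages[-1] == "adulthood"

    def test_stage_lookup_boundaries(self, stages):
        t = stages.table
        first = t.iloc[0]
        assert stages.stage_of(first["min_pcd"]) == first["stage"]
        # interval upper bounds are exclusive
        assert stages.stage_of(first["max_pcd"]) == t.iloc[1]["stage"]
        with pytest.raises(ValueError, match="outside"):
            stages.stage_of(1.0)


class TestCleanup:
    def test_region_missing_a_stage_is_dropped(self, stages):
        cells = [("A", s, 2) for s in stages.stages]
        cells += [("B", s, 2) for s in stages.stages[1:]]  # no early_fetal
        ds = make_dataset(cells, {"G1": lambda *a: 5.0})
        out = ls.cleanup(ds, stages)
        assert set(out.samples["region"]) == {"A"}

    def test_retention_boundary_is_inclusive_at_80_percent(self, stages):
        cells = [("A", s, 5) for s in stages.stages]
        # exactly 4/5 samples >= 1 RPKM in every cell
        ds = make_dataset(
            cells, {"G1": lambda r, s, rep: 0.5 if rep == 0 else 2.0,
                    "G2": lambda r, s, rep: 0.5 if rep <= 1 else 2.0}
        )
        out = ls.cleanup(ds, stages)
        assert list(out.genes) == ["G1"]  # 3/5 fails, 4/5 passes

    def test_duplicate_gene_collapses_to_first_and_planted_low_gene_drops(
        self, stages, final_genesets
    ):
        spec = syn.SyntheticSpec(seed=0, n_regions=3,
                                 n_samples_per_region_stage=4)
        ds = syn.make_lifespan_dataset(
            spec, {"ppp": final_genesets["ppp"]}, stages
        )
        assert ds.expression.columns.duplicated().sum() == 1
        out = ls.cleanup(ds, stages)
        assert "ALWAYSLOW" not in out.genes
        assert out.expression.columns.duplicated().sum() == 0

    def test_idempotent(self, stages, final_genesets):
        spec = syn.SyntheticSpec(seed=1, n_regions=2,
                                 n_samples_per_region_stage=3)
        ds = syn.make_lifespan_dataset(
            spec, {"ppp": final_genesets["ppp"]}, stages
        )
        once = ls.cleanup(ds, stages)
        twice = ls.cleanup(once, stages)
        pd.testing.assert_frame_equal(once.expression, twice.expression)


class TestTransforms:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (1.0, 1.0), (7.0, 3.0)])
    def test_log2_offset_one(self, x, expected):
        assert ls.log2_transform(np.array([x]))[0] == expected

    def test_log2_rejects_negatives(self):
        with pytest.raises(ValueError, match="nonnegative"):
            ls.log2_transform(np.array([-0.1]))

    def test_upper_quartile_scales_by_known_factors(self, stages):
        cells = [("A", s, 2) for s in stages.stages]
        # donor d_<stage>_0 constant 2, d_<stage>_1 constant 4 -> q75 2 and 4
        ds = make_dataset(
            cells, {"G1": lambda r, s, rep: 2.0 * (rep + 1),
                    "G2": lambda r, s, rep: 2.0 * (rep + 1)}
        )
        out = ls.upper_quartile_normalize(ds)
        np.testing.assert_allclose(out.expression.to_numpy(), 3.0)

    def test_single_donor_is_unchanged(self):
        samples = pd.DataFrame(
            {"donor_id": "d", "region": "A", "age_pcd": 100.0,
             "stage": "early_fetal"},
            index=pd.Index(["s1", "s2"], name="sample_id"),
        )
        expr = pd.DataFrame({"G1": [1.0, 5.0]}, index=samples.index)
        ds = ls.LifespanDataset(samples=samples, expression=expr)
        out = ls.upper_quartile_normalize(ds)
        pd.testing.assert_frame_equal(out.expression, expr)

    def test_postcondition_all_donor_q75_equal(self, stages):
        rng = np.random.default_rng(0)
        cells = [(f"R{r}", s, 5) for r in range(2) for s in stages.stages]
        ds = make_dataset(
            cells,
            {f"G{g}": (lambda r, s, rep, g=g: float(rng.lognormal(1, 0.8)))
             for g in range(6)},
        )
        out = ls.upper_quartile_normalize(ds)
        donors = out.samples.groupby("donor_id").groups
        q = [np.percentile(out.expression.loc[idx].to_numpy(), 75)
             for idx in donors.values()]
        np.testing.assert_allclose(q, q[0], atol=1e-9)

    def test_rank_order_within_donor_is_preserved(self, stages):
        rng = np.random.default_rng(1)
        cells = [("A", s, 3) for s in stages.stages]
        ds = make_dataset(
            cells, {f"G{g}": (lambda r, s, rep, g=g: float(rng.uniform(0.1, 9)))
                    for g in range(4)},
        )
        out = ls.upper_quartile_normalize(ds)
        for _, idx in out.samples.groupby("donor_id").groups.items():
            before = ds.expression.loc[idx].to_numpy().ravel()
            after = out.expression.loc[idx].to_numpy().ravel()
            np.testing.assert_array_equal(np.argsort(before),
                                          np.argsort(after))


class TestStageTrajectory:
    def test_one_sample_per_stage_equals_pathway_means(self, stages):
        cells = [("A", s, 1) for s in stages.stages]
        values = {s: float(i) for i, s in enumerate(stages.stages)}
        ds = make_dataset(cells, {"G1": lambda r, s, rep: values[s],
                                  "G2": lambda r, s, rep: values[s] + 2.0})
        gs = PathwayGeneSet("demo", frozenset(["G1", "G2"]))
        traj = ls.stage_trajectory(ds, gs, stages)
        np.testing.assert_allclose(
            traj["median"], [values[s] + 1.0 for s in stages.stages]
        )

    def test_median_is_robust_to_an_outlier(self, stages):
        cells = [("A", "early_fetal", 3)]
        vals = [1.0, 2.0, 100.0]
        ds = make_dataset(cells, {"G1": lambda r, s, rep: vals[rep]})
        gs = PathwayGeneSet("demo", frozenset(["G1"]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # seven empty stages
            traj = ls.stage_trajectory(ds, gs, stages)
        assert traj["median"].iloc[0] == 2.0

    def test_sample_order_invariance(self, stages, final_genesets):
        spec = syn.SyntheticSpec(seed=2, n_regions=2,
                                 n_samples_per_region_stage=3)
        ds = syn.make_lifespan_dataset(
            spec, {"ppp": final_genesets["ppp"]}, stages
        )
        perm = np.random.default_rng(0).permutation(len(ds.samples))
        shuffled = ls.LifespanDataset(
            samples=ds.samples.iloc[perm],
            expression=ds.expression.iloc[perm],
        )
        a = ls.stage_trajectory(ds, final_genesets["ppp"], stages)
        b = ls.stage_trajectory(shuffled, final_genesets["ppp"], stages)
        pd.testing.assert_frame_equal(a, b)


class TestLoess:
    def test_linear_input_is_reproduced_exactly(self):
        ages = np.geomspace(60, 10_000, 40)
        y = 2.0 - 0.7 * np.log10(ages)
        out = ls.loess_trajectory(ages, y, span=0.5)
        np.testing.assert_allclose(
            out["fitted"], 2.0 - 0.7 * out["log10_age"], atol=1e-6
        )

    def test_constant_input_gives_constant_curve(self):
        ages = np.geomspace(60, 10_000, 25)
        out = ls.loess_trajectory(ages, np.full(25, 4.2))
        np.testing.assert_allclose(out["fitted"], 4.2, atol=1e-9)

    def test_matches_direct_tricube_local_fit_at_probe_points(self):
        rng = np.random.default_rng(3)
        ages = np.geomspace(60, 10_000, 60)
        x = np.log10(ages)
        y = 1.0 + 0.5 * (x - 3) ** 2 + 0.2 * rng.standard_normal(60)
        out = ls.loess_trajectory(ages, y, span=0.75, n_grid=5)
        q = int(np.ceil(0.75 * 60))
        for x0, got in zip(out["log10_age"], out["fitted"]):
            d = np.abs(x - x0)
            h = np.sort(d)[q - 1]
            w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
            X = np.column_stack([np.ones_like(x), x - x0])
            beta, *_ = np.linalg.lstsq(
                X * np.sqrt(w)[:, None], y * np.sqrt(w), rcond=None
            )
            assert got == pytest.approx(beta[0], abs=1e-8)

    def test_input_contracts(self):
        with pytest.raises(ValueError, match="at least 10"):
            ls.loess_trajectory([100.0] * 5, [1.0] * 5)
        with pytest.raises(ValueError, match="distinct"):
            ls.loess_trajectory([100.0] * 12, list(range(12)))

    def test_planted_decline_is_recovered(self, stages, final_genesets):
        decline = {("ppp", s): -0.2 * i for i, s in enumerate(stages.stages)}
        hits = 0
        for seed in range(5):
            spec = syn.SyntheticSpec(seed=seed, stage_effects=decline)
            ds = syn.make_lifespan_dataset(
                spec, {"ppp": final_genesets["ppp"]}, stages
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ds = ls.cleanup(ds, stages)
            ds = ls.LifespanDataset(
                samples=ds.samples,
                expression=ls.log2_transform(ds.expression),
            )
            ds = ls.upper_quartile_normalize(ds)
            traj = ls.stage_trajectory(ds, final_genesets["ppp"], stages)
            rho = spearmanr(np.arange(len(traj)), traj["median"]).statistic
            hits += rho <= -0.9
        assert hits >= 4
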