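"""Donor processing: probe filtering, stability, assignment, normalization."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

import energymaps.ahba as ah


def probe(pid, below, total, gene="G1"):
    flags = np.array([False] * below + [True] * (total - below))
    return ah.ProbeRecord(pid, gene, np.ones(total), flags)


def tiny_parcellation(centroids, hemis=None):
    centroids = np.asarray(centroids, float)
    n = len(centroids)
    hemis = hemis if hemis is not None else np.where(
        centroids[:, 0] > 0, "R", "L"
    )
    return ah.Parcellation(
        ids=np.array([f"p{i}" for i in range(n)]),
        hemisphere=np.asarray(hemis),
        centroids=centroids,
    )


def tiny_donor(donor_id, coords, values, genes=None):
    """values: probes x samples array; one probe per gene by default."""
    values = np.atleast_2d(np.asarray(values, float))
    n_probes, n_samples = values.shape
    genes = genes or [f"G{i}" for i in range(n_probes)]
    sample_ids = [f"{donor_id}_s{i}" for i in range(n_samples)]
    samples = pd.DataFrame(
        np.asarray(coords, float), columns=["x", "y", "z"],
        index=pd.Index(sample_ids, name="sample_id"),
    )
    samples["structure"] = "ctx"
    probes = pd.DataFrame(
        {"gene": genes}, index=pd.Index([f"pr{i}" for i in range(n_probes)],
                                        name="probe_id")
    )
    expression = pd.DataFrame(values, index=probes.index, columns=samples.index)
    pa = pd.DataFrame(True, index=probes.index, columns=samples.index)
    return ah.DonorSampleTable(donor_id, samples, probes, expression, pa)


class TestFilterProbes:
    @pytest.mark.parametrize(
        "below,total,kept",
        [(6, 10, False), (4, 10, True), (5, 10, False)],  # >=50% boundary
    )
    def test_background_fraction_boundary(self, below, total, kept):
        out = ah.filter_probes([probe("p1", below, total)])
        assert (len(out) == 1) is kept

    def test_pooling_across_donors(self):
        # 2/4 below in donor 1, 0/4 below in donor 2 -> pooled 2/8 < 0.5
        recs = [probe("p1", 2, 4), probe("p1", 0, 4)]
        assert len(ah.filter_probes(recs)) == 2
        # pooled 5/8 >= 0.5 -> both records dropped
        recs = [probe("p2", 4, 4), probe("p2", 1, 4)]
        assert ah.filter_probes(recs) == []

    def test_zero_sample_probe_is_an_error(self):
        with pytest.raises(ValueError, match="zero samples"):
            ah.filter_probes([probe("p1", 0, 0)])


class TestDifferentialStability:
    def test_identical_profiles_score_one(self):
        prof = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        assert ah.differential_stability({"d1": prof, "d2": prof.copy()}) == 1.0

    def test_reversed_rank_order_scores_minus_one(self):
        prof = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        rev = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        assert ah.differential_stability({"d1": prof, "d2": rev}) == -1.0

    def test_matches_bruteforce_pairwise_spearman_mean(self):
        rng = np.random.default_rng(5)
        idx = [f"p{i}" for i in range(20)]
        profiles = {
            f"d{k}": pd.Series(rng.normal(size=20), index=idx) for k in range(4)
        }
        ds = ah.differential_stability(profiles)
        donors = list(profiles)
        brute = np.mean(
            [
                spearmanr(profiles[a], profiles[b]).statistic
                for i, a in enumerate(donors)
                for b in donors[i + 1:]
            ]
        )
        assert ds == pytest.approx(brute, abs=1e-12)

    def test_zero_variance_pair_is_excluded_with_warning(self):
        idx = list("abcd")
        flat = pd.Series([1.0, 1.0, 1.0, 1.0], index=idx)
        var = pd.Series([1.0, 2.0, 3.0, 4.0], index=idx)
        with pytest.warns(UserWarning, match="undefined"):
            ds = ah.differential_stability({"d1": flat, "d2": var, "d3": var})
        assert ds == 1.0  # only the (d2, d3) pair is defined


class TestProbeSelection:
    def _profiles(self, spearman_by_probe):
        idx = [f"p{i}" for i in range(6)]
        base = pd.Series(np.arange(6.0), index=idx)
        out = {}
        for pid, faithful in spearman_by_probe.items():
            other = base if faithful else base.iloc[::-1].set_axis(idx)
            out[pid] = {"d1": base, "d2": other}
        return out

    def test_highest_stability_probe_wins(self):
        probes = [probe("prB", 0, 4, "G1"), probe("prA", 0, 4, "G1")]
        profiles = self._profiles({"prA": False, "prB": True})
        assert ah.select_probe_per_gene(probes, profiles) == {"G1": "prB"}

    def test_tie_breaks_to_lexicographically_smaller_probe(self):
        probes = [probe("prB", 0, 4, "G1"), probe("prA", 0, 4, "G1")]
        profiles = self._profiles({"prA": True, "prB": True})
        assert ah.select_probe_per_gene(probes, profiles) == {"G1": "prA"}

    def test_single_probe_gene_is_passed_through(self):
        assert ah.select_probe_per_gene(
            [probe("prX", 0, 4, "G9")], {}
        ) == {"G9": "prX"}


class TestMirrorAssign:
    def test_mirror_negates_x_and_doubles_count(self):
        t = tiny_donor("d1", [[-30.0, 20.0, 10.0]], [[5.0]])
        m = ah.mirror_samples(t)
        assert len(m.samples) == 2
        assert m.samples["x"].tolist() == [-30.0, 30.0]
        assert (m.expression.to_numpy() == 5.0).all()

    def test_midline_sample_keeps_coincident_duplicate(self):
        t = tiny_donor("d1", [[0.0, 1.0, 2.0]], [[5.0]])
        assert len(ah.mirror_samples(t).samples) == 2

    def test_assignment_at_centroid_within_tolerance_and_beyond(self):
        parc = tiny_parcellation([[-10, 0, 0], [-20, 0, 0]])
        t = tiny_donor("d1", [[-10, 0, 0], [-20, 0, 3.0], [-15, 0, 0]],
                       [[1.0, 2.0, 3.0]])
        a = ah.assign_samples(t, parc, tol_mm=2.0)
        assert a.iloc[0] == "p0"
        assert a.iloc[1] is None  # 3 mm away from everything
        assert a.iloc[2] is None

    def test_equidistant_tie_goes_to_earlier_parcel(self):
        parc = tiny_parcellation([[-10, 0, 0], [-12, 0, 0]])
        t = tiny_donor("d1", [[-11, 0, 0]], [[1.0]])
        assert ah.assign_samples(t, parc, tol_mm=2.0).iloc[0] == "p0"

    def test_assignment_respects_hemisphere(self):
        # the left parcel is nearer, but the sample lies in the right
        # hemisphere and must go to the right parcel
        parc = tiny_parcellation([[-0.5, 0, 0], [1.0, 0, 0]])
        t = tiny_donor("d1", [[0.1, 0, 0]], [[1.0]])
        assert ah.assign_samples(t, parc, tol_mm=5.0).iloc[0] == "p1"

    def test_empty_parcellation_is_an_error(self):
        parc = tiny_parcellation(np.empty((0, 3)))
        t = tiny_donor("d1", [[0, 0, 0]], [[1.0]])
        with pytest.raises(ValueError, match="empty"):
            ah.assign_samples(t, parc, tol_mm=2.0)


class TestFillMissingParcels:
    def _setup(self, coords, values):
        parc = tiny_parcellation([[-10.0, 0, 0], [-30.0, 0, 0]])
        matrix = pd.DataFrame(
            [[1.0], [np.nan]], index=pd.Index(parc.ids), columns=["G1"]
        )
        sample_values = pd.DataFrame(
            {"G1": values},
            index=pd.Index([f"s{i}" for i in range(len(values))]),
        )
        sample_coords = pd.DataFrame(
            np.asarray(coords, float), columns=["x", "y", "z"],
            index=sample_values.index,
        )
        return parc, matrix, sample_values, sample_coords

    def test_single_neighbor_copies_its_value(self):
        parc, matrix, sv, sc = self._setup([[-10, 0, 0]], [7.0])
        out = ah.fill_missing_parcels(matrix, sv, sc, parc)
        assert out.loc["p1", "G1"] == 7.0

    def test_equidistant_samples_average(self):
        parc, matrix, sv, sc = self._setup(
            [[-30, 0, 5.0], [-30, 0, -5.0]], [2.0, 4.0]
        )
        out = ah.fill_missing_parcels(matrix, sv, sc, parc)
        assert out.loc["p1", "G1"] == pytest.approx(3.0)

    def test_matches_inverse_distance_formula(self):
        # three samples at distances 1, 2, 4 from the empty parcel centroid
        parc, matrix, sv, sc = self._setup(
            [[-31, 0, 0], [-32, 0, 0], [-34, 0, 0]], [1.0, 1.0, 9.0]
        )
        out = ah.fill_missing_parcels(matrix, sv, sc, parc)
        w = np.array([1.0, 1 / 2, 1 / 4])
        expected = float(w @ np.array([1.0, 1.0, 9.0]) / w.sum())
        assert out.loc["p1", "G1"] == pytest.approx(expected, abs=1e-12)

    def test_no_samples_is_an_error(self):
        parc, matrix, sv, sc = self._setup([[-10, 0, 0]], [1.0])
        with pytest.raises(ValueError, match="zero samples"):
            ah.fill_missing_parcels(matrix, sv.iloc[:0], sc.iloc[:0], parc)


class TestRobustSigmoid:
    def test_median_maps_to_half_before_rescale(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = ah.robust_sigmoid(x, rescale=False)
        assert y[2] == pytest.approx(0.5)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        med = np.median(x)
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        direct = 1 / (1 + np.exp(-(x - med) / (iqr / 1.35)))
        direct = (direct - direct.min()) / (direct.max() - direct.min())
        np.testing.assert_allclose(ah.robust_sigmoid(x), direct, atol=1e-12)

    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=30, unique=True),
        st.floats(0.1, 10.0),
        st.floats(-5.0, 5.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_affine_invariance_and_range(self, xs, a, b):
        from hypothesis import assume

        x = np.asarray(xs)
        # the invariant holds where the affine image keeps a resolvable IQR
        xt = a * x + b
        assume(np.percentile(x, 75) > np.percentile(x, 25))
        assume(np.percentile(xt, 75) > np.percentile(xt, 25))
        y = ah.robust_sigmoid(x)
        np.testing.assert_allclose(ah.robust_sigmoid(a * x + b), y, atol=1e-8)
        assert y.min() == 0.0 and y.max() == 1.0
        # order preserving (non-strict where float precision collapses ties)
        assert (np.diff(y[np.argsort(x)]) >= 0).all()

    def test_zero_iqr_flags_constant_output(self):
        with pytest.warns(UserWarning, match="zero IQR"):
            y = ah.robust_sigmoid(np.ones(5))
        assert (y == 0.5).all()


class TestAssemble:
    def test_two_identical_donors_equal_one_and_ds_is_one(
        self, small_parcellation
    ):
        rng = np.random.default_rng(0)
        parc = small_parcellation
        coords = parc.centroids[parc.hemisphere == "L"]
        values = rng.lognormal(size=(5, len(coords)))
        d1 = tiny_donor("d1", coords, values)
        d2 = tiny_donor("d2", coords, values)
        one = ah.assemble([d1], parc)
        two = ah.assemble([d1, d2], parc)
        assert (two.ds == 1.0).all()
        pd.testing.assert_frame_equal(one.values, two.values)

    def test_raising_ds_threshold_never_adds_genes(self, small_cohort,
                                                   small_parcellation):
        donors, _, _ = small_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            low = ah.assemble(donors, small_parcellation, ds_threshold=0.1)
            high = ah.assemble(donors, small_parcellation, ds_threshold=0.5)
        assert set(high.genes) <= set(low.genes)

    def test_left_only_donor_yields_mirror_symmetric_matrix(
        self, small_parcellation
    ):
        rng = np.random.default_rng(3)
        parc = small_parcellation
        left = parc.hemisphere == "L"
        coords = parc.centroids[left]
        values = rng.lognormal(size=(4, left.sum()))
        out = ah.assemble([tiny_donor("d1", coords, values)], parc)
        left_block = out.values.loc[[p for p in parc.ids if p.startswith("L")]]
        right_block = out.values.loc[[p for p in parc.ids if p.startswith("R")]]
        np.testing.assert_allclose(
            left_block.to_numpy(), right_block.to_numpy(), atol=1e-9
        )

    def test_output_is_complete_and_ordered(self, small_expression,
                                            small_parcellation):
        assert not small_expression.values.isna().any().any()
        assert list(small_expression.parcels) == list(small_parcellation.ids)
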