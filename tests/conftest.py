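"""Shared fixtures: packaged gene sets and small synthetic cohorts.

Expensive objects (the calibration parcellation and its spin ensemble)
are session-scoped so the inference tests share one null family, the way
a real analysis fixes its nulls once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import energymaps as em


@pytest.fixture(scope="session")
def final_genesets():
    return em.genesets.load_final_genesets()


@pytest.fixture(scope="session")
def stage_table():
    return em.lifespan.load_stage_table()


@pytest.fixture(scope="session")
def small_spec():
    """A compact six-donor cohort used across module tests."""
    return em.synthetic.SyntheticSpec(
        seed=1234, n_parcels_per_hemisphere=30, n_donors=4, n_genes=24,
    )


@pytest.fixture(scope="session")
def small_parcellation(small_spec):
    return em.synthetic.make_parcellation(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_spec, small_parcellation, final_genesets):
    sets = {k: final_genesets[k] for k in ("ppp", "lactate")}
    donors, truth = em.synthetic.make_donor_tables(
        small_spec, small_parcellation, sets
    )
    return donors, truth, sets


@pytest.fixture(scope="session")
def small_expression(small_cohort, small_parcellation):
    donors, _, _ = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return em.ahba.assemble(donors, small_parcellation)


@pytest.fixture(scope="session")
def calibration_setting():
    """400-parcel parcellation, lambda=0.3 field factor and a 1000-row
    spin ensemble: the study conditions of the inference analyses."""
    spec = em.synthetic.SyntheticSpec(
        seed=11, n_parcels_per_hemisphere=200, correlation_length=0.3
    )
    parc = em.synthetic.make_parcellation(spec)
    ens = em.spatial.spin_permutations(parc, n_rot=1000, seed=42)
    cov = em.synthetic._geodesic_covariance(parc, 0.3)
    chol = np.linalg.cholesky(cov)
    return parc, ens, chol
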