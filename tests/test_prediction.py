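"""Tests for the stage-2 prediction models (GBLUP, BayesCpi, RKHS, multi-trait)."""

import numpy as np
import pandas as pd
import pytest

from clovergs.prediction import (
    PredictionModelSpec,
    fit_bayes_c_pi,
    fit_gblup,
    fit_multitrait,
    fit_rkhs,
    gaussian_kernel,
    mean_imputed_centred,
)
from clovergs.relatedness import RelationshipMatrix, grm_vanraden
from tests.conftest import make_genotypes


@pytest.fixture(scope="module")
def marker_panel():
    rng = np.random.default_rng(8)
    n, m = 120, 600
    p = rng.uniform(0.1, 0.5, m)
    dosage = rng.binomial(2, p, (n, m)).astype(np.int8)
    geno = make_genotypes(dosage)
    beta = np.zeros(m)
    qtl = rng.choice(m, 40, replace=False)
    beta[qtl] = rng.normal(0, 1, 40)
    g = mean_imputed_centred(geno) @ beta
    g = (g - g.mean()) / g.std()
    y = pd.Series(g + rng.normal(0, 0.7, n), index=geno.sample_ids, name="t")
    return geno, y, g


def test_gblup_with_identity_matrix_is_ridge_to_the_mean(marker_panel):
    geno, y, _ = marker_panel
    G = RelationshipMatrix(np.eye(len(y)), list(y.index), "vanraden", np.array([]))
    res = fit_gblup(y, G)
    lam = res.extras["lambda"]
    expected = lam / (lam + 1.0) * (y.to_numpy() - res.mu)
    np.testing.assert_allclose(res.gebv.to_numpy(), expected, atol=1e-8)


def test_gblup_equals_ridge_marker_regression(marker_panel):
    """RR-BLUP/GBLUP equivalence on complete data: marker ridge regression
    with the matched penalty reproduces the GEBVs."""
    geno, y, _ = marker_panel
    G = grm_vanraden(geno)
    res = fit_gblup(y, G)
    X = mean_imputed_centred(geno)
    denom = 2 * np.sum(G.allele_freqs * (1 - G.allele_freqs))
    lam = res.extras["lambda"]
    alpha = np.linalg.solve(X @ X.T / denom * lam + np.eye(len(y)), y.to_numpy() - res.mu)
    gebv_rr = X @ (X.T @ alpha) * lam / denom
    np.testing.assert_allclose(res.gebv.to_numpy(), gebv_rr, atol=1e-6)


def test_gblup_eigen_and_direct_solvers_agree(marker_panel):
    geno, y, _ = marker_panel
    G = grm_vanraden(geno)
    y_miss = y.copy()
    y_miss.iloc[:20] = np.nan  # unphenotyped candidates get predictions too
    r1 = fit_gblup(y_miss, G, solver="eigen")
    r2 = fit_gblup(y_miss, G, solver="direct")
    np.testing.assert_allclose(r1.gebv.to_numpy(), r2.gebv.to_numpy(), atol=1e-8)


def test_gblup_five_individual_worked_fixture():
    """Dense MME inversion on a hand-sized fixture matches the eigen path."""
    G = RelationshipMatrix(
        np.array(
            [
                [1.02, 0.51, 0.00, 0.12, 0.25],
                [0.51, 0.98, 0.03, 0.08, 0.21],
                [0.00, 0.03, 1.05, 0.49, 0.02],
                [0.12, 0.08, 0.49, 0.97, 0.05],
                [0.25, 0.21, 0.02, 0.05, 1.01],
            ]
        ),
        [f"i{k}" for k in range(5)],
        "vanraden",
        np.array([]),
    )
    y = pd.Series([1.2, 0.9, -0.7, -0.4, 0.1], index=G.sample_ids)
    r1 = fit_gblup(y, G, solver="eigen")
    r2 = fit_gblup(y, G, solver="direct")
    np.testing.assert_allclose(r1.gebv.to_numpy(), r2.gebv.to_numpy(), atol=1e-8)


def test_gebvs_invariant_to_response_shift(marker_panel):
    geno, y, _ = marker_panel
    G = grm_vanraden(geno)
    r1 = fit_gblup(y, G)
    r2 = fit_gblup(y + 100.0, G)
    np.testing.assert_allclose(r1.gebv.to_numpy(), r2.gebv.to_numpy(), atol=1e-6)
    spec = PredictionModelSpec(model="bayes_c_pi", iterations=400, burn_in=100, seed=4)
    b1 = fit_bayes_c_pi(y, geno, spec)
    b2 = fit_bayes_c_pi(y + 100.0, geno, spec)
    np.testing.assert_allclose(b1.gebv.to_numpy(), b2.gebv.to_numpy(), atol=1e-8)


def test_zero_phenotypic_variance_raises(marker_panel):
    geno, y, _ = marker_panel
    G = grm_vanraden(geno)
    with pytest.raises(ValueError, match="variance"):
        fit_gblup(pd.Series(1.0, index=y.index), G)


# ----------------------------------------------------------------- BayesCpi


def test_bayescpi_null_data_includes_few_markers(marker_panel):
    geno, y, _ = marker_panel
    rng = np.random.default_rng(9)
    y_null = pd.Series(rng.normal(0, 1, len(y)), index=y.index)
    res = fit_bayes_c_pi(
        y_null, geno, PredictionModelSpec(model="bayes_c_pi", iterations=800, burn_in=300, seed=1)
    )
    assert res.gebv.var() < 0.3 * y_null.var()


def test_bayescpi_recovers_oligogenic_qtl():
    """5 QTL / 1000 markers at h2 = 0.8: the top-10 inclusion markers
    contain most true QTL (median over seeds >= 3)."""
    hits = []
    for seed in (1, 2, 3):
        rng = np.random.default_rng(seed)
        n, m = 300, 1000
        p = rng.uniform(0.1, 0.5, m)
        dosage = rng.binomial(2, p, (n, m)).astype(np.int8)
        geno = make_genotypes(dosage)
        X = mean_imputed_centred(geno)
        qtl = rng.choice(m, 5, replace=False)
        g = X[:, qtl] @ rng.normal(0, 1, 5)
        g = g / g.std() * np.sqrt(0.8)
        y = pd.Series(g + rng.normal(0, np.sqrt(0.2), n), index=geno.sample_ids)
        res = fit_bayes_c_pi(
            y, geno, PredictionModelSpec(model="bayes_c_pi", seed=seed)
        )
        top10 = set(res.extras["inclusion_prob"].nlargest(10).index)
        true_ids = set(geno.marker_info["id"].iloc[qtl])
        hits.append(len(top10 & true_ids))
    assert np.median(hits) >= 3


def test_bayescpi_chains_are_stable_and_deterministic(marker_panel):
    geno, y, _ = marker_panel
    spec1 = PredictionModelSpec(model="bayes_c_pi", seed=11)
    spec2 = PredictionModelSpec(model="bayes_c_pi", seed=12)
    r1 = fit_bayes_c_pi(y, geno, spec1)
    r2 = fit_bayes_c_pi(y, geno, spec2)
    assert np.corrcoef(r1.gebv, r2.gebv)[0, 1] > 0.98
    r1b = fit_bayes_c_pi(y, geno, spec1)
    np.testing.assert_array_equal(r1.gebv.to_numpy(), r1b.gebv.to_numpy())


# -------------------------------------------------------------------- RKHS


def test_rkhs_clones_receive_identical_gebvs():
    rng = np.random.default_rng(13)
    dosage = rng.binomial(2, 0.4, (40, 300)).astype(np.int8)
    dosage[39] = dosage[0]
    geno = make_genotypes(dosage)
    y = pd.Series(rng.normal(0, 1, 40), index=geno.sample_ids)
    y.iloc[39] = y.iloc[0]
    res = fit_rkhs(y, geno, PredictionModelSpec(model="rkhs"))
    assert res.gebv.iloc[39] == pytest.approx(res.gebv.iloc[0], abs=1e-8)


def test_rkhs_bandwidth_zero_collapses_to_intercept(marker_panel):
    geno, y, _ = marker_panel
    res = fit_rkhs(y, geno, PredictionModelSpec(model="rkhs", rkhs_bandwidth=1e-9))
    assert res.gebv.std() < 1e-3 * y.std()


def test_rkhs_close_to_gblup_on_additive_trait(marker_panel):
    """Purely additive architecture: the Gaussian kernel and the linear GRM
    rank individuals nearly identically."""
    geno, y, _ = marker_panel
    rg = fit_gblup(y, grm_vanraden(geno))
    rk = fit_rkhs(y, geno, PredictionModelSpec(model="rkhs"))
    assert np.corrcoef(rg.gebv, rk.gebv)[0, 1] > 0.97


def test_degenerate_kernel_raises():
    dosage = np.tile(np.array([0, 1, 2, 1], dtype=np.int8)[:, None], (1, 50))
    clones = np.tile(dosage[0], (4, 1)).astype(np.int8)
    with pytest.raises(ValueError, match="degenerate"):
        gaussian_kernel(make_genotypes(clones))


# -------------------------------------------------------------- multi-trait


@pytest.fixture(scope="module")
def bivariate_panel():
    def build(rg, seed, n=150, m=500, h2=0.6):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.1, 0.5, m)
        dosage = rng.binomial(2, p, (n, m)).astype(np.int8)
        geno = make_genotypes(dosage)
        X = mean_imputed_centred(geno)
        L = np.linalg.cholesky(np.array([[1.0, rg], [rg, 1.0]]) + 1e-10 * np.eye(2))
        eff = rng.normal(0, 1, (60, 2)) @ L.T
        qtl = rng.choice(m, 60, replace=False)
        B = X[:, qtl] @ eff
        # recolour so the realized genetic correlation is exactly rg
        Lc = np.linalg.cholesky(np.cov(B, rowvar=False) + 1e-10 * np.eye(2))
        B = B @ np.linalg.inv(Lc).T @ L.T
        B = B / B.std(axis=0)
        E = rng.normal(0, 1, (n, 2))
        # orthogonalize the residual draws against the genetic values and
        # decorrelate them, so the simulated truth carries the nominal
        # parameters exactly (R diagonal, corr(E) = 0, cov(B, E) = 0)
        E = E - E.mean(axis=0)
        E -= B @ np.linalg.lstsq(B, E, rcond=None)[0]
        E = E @ np.linalg.inv(np.linalg.cholesky(np.cov(E, rowvar=False))).T
        E *= np.sqrt((1 - h2) / h2)
        Y = pd.DataFrame(B + E, index=geno.sample_ids, columns=["t1", "t2"])
        return geno, Y, B

    return build


def test_multitrait_recovers_genetic_correlation(bivariate_panel):
    geno, Y, _ = bivariate_panel(rg=0.8, seed=21)
    G = grm_vanraden(geno)
    res = fit_multitrait(
        Y, G, PredictionModelSpec(model="multitrait", iterations=1200, burn_in=400, seed=1)
    )
    assert res.extras["genetic_correlation"] == pytest.approx(0.8, abs=0.1)
    assert np.all(np.linalg.eigvalsh(res.K) > 0)
    assert np.all(np.diag(res.R) > 0)


def test_multitrait_null_correlation_recovery(bivariate_panel):
    geno, Y, _ = bivariate_panel(rg=0.0, seed=22)
    G = grm_vanraden(geno)
    res = fit_multitrait(
        Y, G, PredictionModelSpec(model="multitrait", iterations=1200, burn_in=400, seed=2)
    )
    assert -0.15 < res.extras["genetic_correlation"] < 0.15


def test_multitrait_degenerates_to_single_trait_gblup(bivariate_panel):
    """Masking every secondary-trait record reduces the primary-trait GEBVs
    to single-trait GBLUP up to MCMC error."""
    geno, Y, _ = bivariate_panel(rg=0.6, seed=23)
    G = grm_vanraden(geno)
    mask = pd.DataFrame(True, index=Y.index, columns=Y.columns)
    mask["t2"] = False
    res = fit_multitrait(
        Y, G,
        PredictionModelSpec(model="multitrait", iterations=1500, burn_in=500, seed=3),
        observed_mask=mask,
    )
    st = fit_gblup(Y["t1"], G)
    assert np.corrcoef(res.gebv["t1"], st.gebv)[0, 1] > 0.97


def test_multitrait_requires_primary_observations(bivariate_panel):
    geno, Y, _ = bivariate_panel(rg=0.5, seed=24)
    G = grm_vanraden(geno)
    Y2 = Y.copy()
    Y2["t1"] = np.nan
    with pytest.raises(ValueError, match="primary"):
        fit_multitrait(Y2, G, PredictionModelSpec(model="multitrait", iterations=20, burn_in=10))


def test_spec_validation():
    with pytest.raises(ValueError, match="burn_in"):
        PredictionModelSpec(iterations=100, burn_in=100)
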