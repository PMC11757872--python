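"""Tests for the stage-1 REML mixed model and heritability formulas."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from clovergs.stage1_phenotype import (
    VarianceComponents,
    family_mean_sigma_pf,
    fit_stage1,
    heritability_family_mean,
)
from clovergs.synthetic_data import (
    SimConfig,
    simulate_population,
    simulate_trial_phenotypes,
)


def _sim_pheno(vc, n_families=80, seed=1, **kwargs):
    cfg = SimConfig(
        n_families=n_families,
        seedlings_per_family=20,
        n_markers=200,
        n_qtl=50,
        var_components=[dict(vc)],
        seed=seed,
        **kwargs,
    )
    pop = simulate_population(cfg)
    return pop, simulate_trial_phenotypes(pop, cfg, seed=seed + 1)


def test_reml_parameter_recovery_over_seeds():
    """REML estimates of (s2_f, s2_fl, s2_fy, s2_e) centre on the simulated
    truth within two empirical standard errors."""
    truth = dict(sigma2_f=1.0, sigma2_fl=0.5, sigma2_fy=0.5, sigma2_e=2.0)
    ests = []
    for seed in range(6):
        _, pheno = _sim_pheno(truth, n_families=80, seed=100 + seed)
        vc, _ = fit_stage1(pheno, "trait1")
        ests.append([vc.sigma2_f, vc.sigma2_fl, vc.sigma2_fy, vc.sigma2_e])
    ests = np.asarray(ests)
    mean = ests.mean(axis=0)
    se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
    for i, key in enumerate(truth):
        assert abs(mean[i] - truth[key]) < 2 * se[i] + 0.05 * truth[key], key


def test_noise_free_blups_equal_centred_family_means():
    vc = dict(sigma2_f=1.0, sigma2_fl=0.0, sigma2_fy=0.0, sigma2_e=0.0)
    pop, pheno = _sim_pheno(vc, n_families=40, seed=9)
    _, fb = fit_stage1(pheno, "trait1")
    fam = pheno[pheno["entry_type"] == "family"]
    means = fam.groupby("entry_id")["value"].mean()
    centred = (means - means.mean()).reindex(fb.blups.index)
    np.testing.assert_allclose(fb.blups.to_numpy(), centred.to_numpy(), atol=1e-5)
    # and they recover the family-mean true breeding values
    truth = pd.Series(pop.family_mean_tbv[:, 0], index=pop.family_ids)
    r = np.corrcoef(fb.blups.reindex(truth.index), truth)[0, 1]
    assert r > 0.9999


def test_balanced_one_way_blups_match_closed_form():
    """Single location/year: BLUP_i = shrinkage * (ybar_i - ybar) with
    shrinkage s2_f / (s2_f + s2_e / r)."""
    vc = dict(sigma2_f=1.0, sigma2_fl=0.0, sigma2_fy=0.0, sigma2_e=2.0)
    _, pheno = _sim_pheno(
        vc, n_families=60, seed=11, n_locations=1, n_years=1, n_checks_per_rep=0
    )
    est, fb = fit_stage1(pheno, "trait1")
    fam = pheno[pheno["entry_type"] == "family"]
    means = fam.groupby("entry_id")["value"].mean()
    r = fam.groupby("entry_id").size().iloc[0]
    shrink = est.sigma2_f / (est.sigma2_f + est.sigma2_e / r)
    expected = shrink * (means - means.mean())
    np.testing.assert_allclose(
        fb.blups.to_numpy(), expected.reindex(fb.blups.index).to_numpy(), atol=1e-6
    )
    # shrinkage: BLUPs never exceed the centred means in magnitude
    centred = (means - means.mean()).reindex(fb.blups.index)
    assert (np.abs(fb.blups.to_numpy()) <= np.abs(centred.to_numpy()) + 1e-9).all()


def test_reml_invariant_to_location_shift():
    vc = dict(sigma2_f=0.8, sigma2_fl=0.3, sigma2_fy=0.3, sigma2_e=1.5)
    _, pheno = _sim_pheno(vc, n_families=40, seed=13)
    vc1, fb1 = fit_stage1(pheno, "trait1")
    shifted = pheno.copy()
    shifted["value"] = shifted["value"] + 57.0
    vc2, fb2 = fit_stage1(shifted, "trait1")
    assert vc2.sigma2_f == pytest.approx(vc1.sigma2_f, rel=1e-4, abs=1e-6)
    assert vc2.sigma2_e == pytest.approx(vc1.sigma2_e, rel=1e-4)
    np.testing.assert_allclose(fb2.blups, fb1.blups, atol=1e-5)
    assert fb2.grand_mean == pytest.approx(fb1.grand_mean + 57.0, abs=1e-5)


def test_blups_sum_to_zero(small_pheno):
    _, fb = fit_stage1(small_pheno, "trait1")
    assert abs(fb.blups.sum()) < 1e-6 * fb.blups.abs().max() * len(fb.blups)


def test_single_location_drops_interaction(small_pop):
    cfg = small_pop.config
    pheno = simulate_trial_phenotypes(small_pop, cfg, seed=31)
    one_loc = pheno[pheno["location"] == "loc1"]
    vc, _ = fit_stage1(one_loc, "trait1")
    assert vc.sigma2_fl == 0.0
    assert vc.n_locations == 1


def test_lme4_oracle_agreement(tmp_path):
    """Independent REML oracle: lme4 on the same data returns the same
    variance components and family BLUPs."""
    vc = dict(sigma2_f=1.0, sigma2_fl=0.4, sigma2_fy=0.4, sigma2_e=1.5)
    _, pheno = _sim_pheno(vc, n_families=40, seed=17, n_checks_per_rep=0)
    est, fb = fit_stage1(pheno, "trait1")
    csv = tmp_path / "pheno.csv"
    pheno.to_csv(csv, index=False)
    rscript = textwrap.dedent("""
        suppressMessages(library(lme4))
        d <- read.csv(commandArgs(TRUE)[1])
        d$rl <- interaction(d$location, d$rep)
        m <- lmer(value ~ location + year + rl +
                  (1|entry_id) + (1|entry_id:location) + (1|entry_id:year),
                  data = d, REML = TRUE,
                  control = lmerControl(check.conv.singular = "ignore"))
        v <- as.data.frame(VarCorr(m))
        rownames(v) <- v$grp
        cat(v["entry_id", "vcov"], v["entry_id:location", "vcov"],
            v["entry_id:year", "vcov"], sigma(m)^2, "\\n")
        b <- ranef(m)$entry_id
        write.csv(data.frame(id = rownames(b), blup = b[,1]),
                  commandArgs(TRUE)[2], row.names = FALSE)
    """)
    rfile = tmp_path / "oracle.R"
    rfile.write_text(rscript)
    out_csv = tmp_path / "blups_r.csv"
    res = subprocess.run(
        ["Rscript", str(rfile), str(csv), str(out_csv)],
        capture_output=True, text=True, timeout=300,
    )
    assert res.returncode == 0, res.stderr
    r_comps = [float(x) for x in res.stdout.split()]
    ours = [est.sigma2_f, est.sigma2_fl, est.sigma2_fy, est.sigma2_e]
    for a, b in zip(ours, r_comps):
        assert a == pytest.approx(b, rel=0.02, abs=0.02)
    r_blups = pd.read_csv(out_csv).set_index("id")["blup"]
    joined = pd.concat([fb.blups, r_blups], axis=1, join="inner")
    assert np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1] > 0.999


def test_heritability_formula_values():
    vc = VarianceComponents(1.0, 0.0, 0.0, 0.0, 1, 1, 1)
    assert heritability_family_mean(vc) == pytest.approx(1.0)
    vc = VarianceComponents(1.0, 0.0, 0.0, 3.0, 1, 1, 1)
    assert heritability_family_mean(vc) == pytest.approx(0.25)
    assert vc.sigma2_A == 4.0 * vc.sigma2_f


def test_heritability_decreases_with_residual_variance():
    h2 = [
        heritability_family_mean(VarianceComponents(1.0, 0.5, 0.5, s2e, 2, 3, 3))
        for s2e in (0.5, 1.0, 2.0, 4.0)
    ]
    assert all(a > b for a, b in zip(h2, h2[1:]))


def test_heritability_recovery_from_simulation():
    """End-to-end: simulated data with a known family-mean h2 yields a
    stage-1 REML estimate within 0.1."""
    truth = dict(sigma2_f=1.0, sigma2_fl=0.5, sigma2_fy=0.5, sigma2_e=2.0)
    target_h2 = heritability_family_mean(VarianceComponents(**truth, n_locations=2, n_years=3, n_reps=3))
    ests = []
    for seed in range(4):
        _, pheno = _sim_pheno(truth, n_families=80, seed=300 + seed)
        vc, _ = fit_stage1(pheno, "trait1")
        ests.append(heritability_family_mean(vc))
    assert np.mean(ests) == pytest.approx(target_h2, abs=0.1)


def test_sigma_pf_years_of_data():
    vc = VarianceComponents(1.0, 0.5, 0.6, 2.0, 2, 3, 3)
    s3 = family_mean_sigma_pf(vc, years_of_data=3)
    s2 = family_mean_sigma_pf(vc, years_of_data=2)
    assert s3 < s2  # more years shrink the family-mean variance


def test_zero_total_variance_raises():
    vc = VarianceComponents(0.0, 0.0, 0.0, 0.0, 2, 3, 3)
    with pytest.raises(ValueError):
        heritability_family_mean(vc)


def test_insufficient_families_raise(small_pheno):
    tiny = small_pheno[small_pheno["entry_id"].isin(["F001"])]
    with pytest.raises(ValueError):
        fit_stage1(tiny, "trait1")
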