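"""grammar_gwas: QC filters, IBS/MDS, spectral REML, residual scan and
genomic control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snpwave import GenotypeMatrix, KinshipMatrix, build_grm
from snpwave.gwas import (
    CHI2_MEDIAN_1DF,
    design_matrix,
    fit_polygenic,
    genomic_control,
    grammar_scan,
    mds_coordinates,
    pairwise_ibs,
    qc_filter,
)
from snpwave.simulate import (
    simulate_half_sib_genotypes,
    simulate_phenotypes_and_pedigree,
)


def gm_from(calls):
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix([f"s{i}" for i in range(calls.shape[0])],
                          [f"p{j}" for j in range(calls.shape[1])], calls)


def _study(n=300, m=800, h2=0.0, qtl=(), seed=0, n_sires=15):
    rng = np.random.default_rng(seed + 1_000_003)
    p = rng.uniform(0.1, 0.9, size=m)
    gm, ped = simulate_half_sib_genotypes(p, "b", n_sires=n_sires,
                                          n_offspring=n - n_sires, seed=seed)
    study = simulate_phenotypes_and_pedigree(gm, qtl=list(qtl), h2=h2,
                                             seed=seed, pedigree=ped)
    return gm, study


# ---------------------------------------------------------------------------
# IBS + qc_filter

def test_pairwise_ibs_values():
    d = np.array([[0.0, 2.0], [0.0, 2.0], [2.0, 0.0], [1.0, 1.0]])
    ibs = pairwise_ibs(d)
    assert ibs[0, 1] == 1.0
    assert ibs[0, 2] == 0.0
    assert ibs[0, 3] == 0.5


def test_qc_filter_low_maf_removed():
    rng = np.random.default_rng(0)
    calls = rng.binomial(2, 0.4, size=(100, 200)).astype(np.int8)
    calls[:, 2] = 0
    calls[0, 2] = 1  # maf 0.005
    gm = gm_from(calls)
    filtered, ledger = qc_filter(gm)
    assert ("snp", "p2", "maf") in ledger
    assert "p2" not in filtered.probeset_ids


def test_qc_filter_low_call_rate_sample_removed():
    rng = np.random.default_rng(1)
    calls = rng.binomial(2, 0.4, size=(30, 40)).astype(np.int8)
    calls[4, :38] = -1  # call rate 0.05
    gm = gm_from(calls)
    # duplicate detection disabled: on 2 surviving calls IBS is degenerate
    filtered, ledger = qc_filter(gm, dup_ibs=1.01)
    assert ("sample", "s4", "sample_cr") in ledger
    assert "s4" not in filtered.sample_ids


def test_qc_filter_duplicate_pair_one_removed():
    rng = np.random.default_rng(2)
    calls = rng.binomial(2, 0.5, size=(10, 200)).astype(np.int8)
    calls[7] = calls[3]
    gm = gm_from(calls)
    filtered, ledger = qc_filter(gm)
    dup = [l for l in ledger if l[2] == "duplicate"]
    assert dup == [("sample", "s7", "duplicate")]
    assert "s3" in filtered.sample_ids and "s7" not in filtered.sample_ids


def test_qc_filter_empty_result_errors():
    gm = gm_from(np.zeros((5, 3)))
    with pytest.raises(ValueError):
        qc_filter(gm)  # all SNPs monomorphic -> all fail maf


# ---------------------------------------------------------------------------
# MDS

def test_mds_duplicate_clusters_collapse():
    rng = np.random.default_rng(3)
    a, b, c3 = (rng.binomial(2, 0.5, size=100).astype(np.int8)
                for _ in range(3))
    gm = gm_from(np.vstack([a, a, b, b, c3, c3]))
    coords, _ = mds_coordinates(gm, k=2)
    c = coords.to_numpy()
    assert np.linalg.norm(c[0] - c[1]) < 1e-8
    assert np.linalg.norm(c[2] - c[3]) < 1e-8
    assert np.linalg.norm(c[4] - c[5]) < 1e-8
    assert np.linalg.norm(c[0] - c[2]) > 1e-3


def test_mds_equidistant_triple():
    # three samples each homozygous-alt on their own disjoint SNP block:
    # all pairwise 1-IBS distances equal, reproduced by the coordinates
    m = 30
    calls = np.zeros((3, 3 * m), dtype=np.int8)
    for i in range(3):
        calls[i, i * m:(i + 1) * m] = 2
    gm = gm_from(calls)
    dist = 1.0 - pairwise_ibs(gm.dosage())
    coords, _ = mds_coordinates(gm, k=2)
    c = coords.to_numpy()
    for i in range(3):
        for j in range(i + 1, 3):
            assert np.linalg.norm(c[i] - c[j]) == pytest.approx(
                dist[i, j], rel=1e-8)


def test_mds_simplex_distances_reproduced():
    # four samples each with their own disjoint alt block form a regular
    # tetrahedron (all pairwise distances equal): classical MDS at k = 3
    # reproduces the distances exactly
    m = 30
    calls = np.zeros((4, 4 * m), dtype=np.int8)
    for i in range(4):
        calls[i, i * m:(i + 1) * m] = 2
    gm = gm_from(calls)
    dist = 1.0 - pairwise_ibs(gm.dosage())
    coords, _ = mds_coordinates(gm, k=3)
    c = coords.to_numpy()
    for i in range(4):
        for j in range(i + 1, 4):
            assert np.linalg.norm(c[i] - c[j]) == pytest.approx(
                dist[i, j], rel=1e-8)


def test_mds_needs_enough_samples():
    gm = gm_from(np.array([[0, 2], [2, 0]]))
    with pytest.raises(ValueError):
        mds_coordinates(gm, k=2)


# ---------------------------------------------------------------------------
# design matrix + REML

def test_design_matrix_layout():
    gm, study = _study(n=120, seed=4)
    x = design_matrix(study.phenotypes)
    assert "intercept" in x.columns and "age_months" in x.columns
    assert np.linalg.matrix_rank(x.to_numpy()) == x.shape[1]


def test_design_matrix_rank_deficient_rejected():
    ph = pd.DataFrame({"lact_record": [1.0, 2.0, 3.0],
                       "farm": [1, 1, 1],
                       "age_months": [1.0, 1.0, 1.0]})
    # constant age column duplicates the intercept
    with pytest.raises(ValueError):
        design_matrix(ph)


def test_null_heritability_estimated_near_zero():
    # data simulated with sigma_a = 0: h2_hat below 0.05 at n = 500
    gm, study = _study(n=500, m=1500, h2=0.0, seed=5, n_sires=25)
    fit = fit_polygenic(study.phenotypes, build_grm(gm))
    assert fit.h2 < 0.05
    assert fit.sigma_a >= 0 and fit.sigma_e >= 0


def test_heritability_recovered_at_045():
    est = []
    for seed in (6, 7, 8):
        gm, study = _study(n=400, m=1500, h2=0.45, seed=seed, n_sires=20)
        est.append(fit_polygenic(study.phenotypes, build_grm(gm)).h2)
    assert abs(np.mean(est) - 0.45) < 0.1


def test_farm_effects_recovered_within_two_se():
    # identity kinship, h2 = 0: GLS reduces to OLS whose SEs we can compute
    gm, study = _study(n=500, m=200, h2=0.0, seed=9)
    kin = KinshipMatrix(gm.sample_ids, np.eye(gm.n_samples), "genomic")
    fit = fit_polygenic(study.phenotypes, kin)
    x = design_matrix(study.phenotypes).to_numpy()
    se = np.sqrt(np.diag(np.linalg.inv(x.T @ x))
                 * (fit.sigma_a + fit.sigma_e))
    names = list(design_matrix(study.phenotypes).columns)
    farm_effects = study.truth["fixed_effects"]["farm"]
    for lev in (2, 3, 4):
        col = names.index(f"farm[{lev}]")
        true = farm_effects[lev - 1] - farm_effects[0]
        assert abs(fit.beta[f"farm[{lev}]"] - true) < 2 * se[col]


def test_identity_kinship_residuals_match_ols():
    # spec invariant: K = I makes GRAMMAR equal single-step regression
    gm, study = _study(n=250, m=400, h2=0.0, seed=10)
    kin = KinshipMatrix(gm.sample_ids, np.eye(gm.n_samples), "genomic")
    fit = fit_polygenic(study.phenotypes, kin)
    x = design_matrix(study.phenotypes).to_numpy()
    y = study.phenotypes["lact_record"].to_numpy()
    ols_beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    ols_resid = y - x @ ols_beta
    chi2_grammar = grammar_scan(fit.residuals, gm)["chi2"].to_numpy()
    chi2_ols = grammar_scan(ols_resid, gm)["chi2"].to_numpy()
    np.testing.assert_allclose(chi2_grammar, chi2_ols, rtol=1e-6, atol=1e-9)


def test_reml_fit_well_formed():
    gm, study = _study(n=200, m=800, h2=0.3, seed=11)
    fit = fit_polygenic(study.phenotypes, build_grm(gm))
    assert np.isfinite(fit.reml_loglik)
    assert 0.0 <= fit.h2 <= 1.0
    assert fit.h2 == pytest.approx(
        fit.sigma_a / (fit.sigma_a + fit.sigma_e), abs=1e-8)
    assert len(fit.residuals) == len(fit.blup) == gm.n_samples


def test_non_psd_kinship_rejected():
    gm, study = _study(n=50, m=100, h2=0.0, seed=12)
    bad = -np.eye(gm.n_samples)
    kin = KinshipMatrix(gm.sample_ids, bad, "genomic")
    with pytest.raises(ValueError):
        fit_polygenic(study.phenotypes, kin)


# ---------------------------------------------------------------------------
# scan + genomic control

def test_monomorphic_snp_reported_missing():
    calls = np.array([[0, 0], [1, 0], [2, 0]], dtype=np.int8)
    gm = gm_from(calls)
    scan = grammar_scan(np.array([0.1, -0.2, 0.1]), gm)
    assert np.isnan(scan.loc[1, "chi2"])
    assert np.isfinite(scan.loc[0, "chi2"])


def test_null_scan_type_one_calibrated():
    gm, study = _study(n=400, m=2000, h2=0.0, seed=13)
    kin = KinshipMatrix(gm.sample_ids, np.eye(gm.n_samples), "genomic")
    fit = fit_polygenic(study.phenotypes, kin)
    scan = grammar_scan(fit.residuals, gm)
    frac = (scan["p_raw"] < 0.05).mean()
    assert abs(frac - 0.05) < 4 * np.sqrt(0.05 * 0.95 / 2000)


def test_planted_qtl_has_smallest_p():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed + 5_000)
        p = rng.uniform(0.2, 0.8, size=600)
        gm, ped = simulate_half_sib_genotypes(p, "b", n_sires=600,
                                              n_offspring=0, seed=seed)
        # 600 unrelated individuals; QTL sized to ~5% of phenotypic variance
        qtl_id = gm.probeset_ids[123]
        freq = gm.calls[:, 123].mean() / 2
        beta = np.sqrt(0.05 * 450**2 / (2 * freq * (1 - freq)))
        study = simulate_phenotypes_and_pedigree(
            gm, qtl=[(qtl_id, float(beta))], h2=0.05, seed=seed)
        kin = KinshipMatrix(gm.sample_ids, np.eye(600), "genomic")
        fit = fit_polygenic(study.phenotypes, kin)
        scan = grammar_scan(fit.residuals, gm)
        if scan.loc[scan["chi2"].idxmax(), "snp"] == qtl_id:
            hits += 1
    assert hits >= 18


def test_genomic_control_null_lambda_near_one():
    rng = np.random.default_rng(14)
    chi2 = rng.chisquare(1, size=10_000)
    scan = pd.DataFrame({"snp": [f"s{i}" for i in range(10_000)],
                         "chi2": chi2,
                         "p_raw": stats.chi2.sf(chi2, 1)})
    res = genomic_control(scan)
    assert abs(res.lambda_raw - 1.0) < 0.05


def test_genomic_control_scale_equivariance():
    rng = np.random.default_rng(15)
    chi2 = rng.chisquare(1, size=5000) * 1.5  # inflated so lambda_raw > 1
    scan = pd.DataFrame({"snp": [f"s{i}" for i in range(5000)],
                         "chi2": chi2, "p_raw": stats.chi2.sf(chi2, 1)})
    res1 = genomic_control(scan)
    scan2 = scan.assign(chi2=scan["chi2"] * 2)
    res2 = genomic_control(scan2)
    assert res2.lam == pytest.approx(2 * res1.lam)
    np.testing.assert_allclose(res2.table["p_gc"], res1.table["p_gc"])


def test_genomic_control_significant_set():
    chi2 = np.full(100, 0.45)
    chi2[:3] = 40.0  # p ~ 2.5e-10, far below 1e-4 after correction
    scan = pd.DataFrame({"snp": [f"s{i}" for i in range(100)],
                         "chi2": chi2, "p_raw": stats.chi2.sf(chi2, 1)})
    res = genomic_control(scan, alpha=1e-4)
    assert sorted(res.significant) == ["s0", "s1", "s2"]
    np.testing.assert_allclose(res.table["chi2_gc"],
                               res.table["chi2"] / res.lam)


def test_lambda_floored_at_one():
    rng = np.random.default_rng(16)
    chi2 = rng.chisquare(1, size=5000) * 0.5  # deflated
    scan = pd.DataFrame({"snp": [f"s{i}" for i in range(5000)],
                         "chi2": chi2, "p_raw": stats.chi2.sf(chi2, 1)})
    res = genomic_control(scan)
    assert res.lam == 1.0 and res.lambda_raw < 1.0
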