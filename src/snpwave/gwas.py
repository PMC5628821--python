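"""Two-step GRAMMAR association pipeline with genomic control.

Step one fits an additive polygenic mixed model

    y = X beta + g + e,   g ~ N(0, sigma_a^2 K),   e ~ N(0, sigma_e^2 I)

by REML, where the fixed effects are herd/management classes (farm, calving
year and season, parity) plus an age covariate, and K is a genomic (or
pedigree) relationship matrix. REML uses a single spectral decomposition of
K and a one-dimensional profile likelihood in the heritability ratio, so the
fit is exact and deterministic at this scale. Step two regresses the
environmental residuals y - X beta_hat - g_hat (the GRAMMAR convention: the
predicted polygenic values are removed) on each SNP's allele dosage, giving
a 1-df chi-square per SNP. Genomic control divides the statistics by
lambda = median(chi^2) / 0.4549 (floored at 1) before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from snpwave.genotypes import GenotypeMatrix, NOCALL
from snpwave.kinship import KinshipMatrix

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...

FIXED_EFFECT_CLASSES = ("farm", "calv_year", "calv_season", "calvings")
AGE_COLUMN = "age_months"
TRAIT_COLUMN = "lact_record"


@dataclass
class PolygenicFit:
    sigma_a: float
    sigma_e: float
    h2: float
    beta: pd.Series
    residuals: np.ndarray      # y - X beta - predicted polygenic values
    blup: np.ndarray
    reml_loglik: float


@dataclass
class GwasResult:
    table: pd.DataFrame        # snp, effect, chi2, p_raw, chi2_gc, p_gc
    lam: float
    alpha: float
    significant: list[str] = field(default_factory=list)
    lambda_raw: float | None = None  # before the floor at 1


# ---------------------------------------------------------------------------
# genotype/sample QC

def pairwise_ibs(dosage: np.ndarray) -> np.ndarray:
    """Mean identity-by-state over pairwise-complete SNPs;
    IBS(a, b) = 1 - |d_a - d_b| / 2 per SNP."""
    n = dosage.shape[0]
    ibs = np.ones((n, n))
    ok = ~np.isnan(dosage)
    for i in range(n):
        diff = np.abs(dosage[i] - dosage)        # (n, m) with NaN where missing
        both = ok[i] & ok
        sim = 1.0 - diff / 2.0
        with np.errstate(invalid="ignore"):
            ibs[i] = np.where(both, sim, np.nan).sum(axis=1, where=both) \
                / both.sum(axis=1)
    return (ibs + ibs.T) / 2.0


def qc_filter(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    snp_cr_min: float = 0.10,
    sample_cr_min: float = 0.10,
    dup_ibs: float = 0.99,
) -> tuple[GenotypeMatrix, list[tuple[str, str, str]]]:
    """Remove duplicated samples (pairwise IBS >= ``dup_ibs``; the first of
    each pair is kept), then samples and SNPs below the call-rate and MAF
    thresholds. Returns the filtered matrix and a removal ledger of
    (kind, id, reason)."""
    ledger: list[tuple[str, str, str]] = []
    calls = genotypes.calls
    called = calls != NOCALL

    sample_cr = called.mean(axis=1)
    dosage = genotypes.dosage()
    ibs = pairwise_ibs(dosage)
    drop_samples: set[int] = set()
    n = genotypes.n_samples
    for i in range(n):
        if i in drop_samples:
            continue
        for j in range(i + 1, n):
            if j not in drop_samples and ibs[i, j] >= dup_ibs:
                drop_samples.add(j)
                ledger.append(("sample", genotypes.sample_ids[j], "duplicate"))
    for i in range(n):
        if i not in drop_samples and sample_cr[i] < sample_cr_min:
            drop_samples.add(i)
            ledger.append(("sample", genotypes.sample_ids[i], "sample_cr"))

    keep_rows = [i for i in range(n) if i not in drop_samples]
    sub = calls[keep_rows]
    called = sub != NOCALL
    snp_cr = called.mean(axis=0)
    with np.errstate(invalid="ignore"):
        d = np.where(called, sub, np.nan).astype(float)
        freq = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep_cols = []
    for k, pid in enumerate(genotypes.probeset_ids):
        if snp_cr[k] < snp_cr_min:
            ledger.append(("snp", pid, "snp_cr"))
        elif not maf[k] >= maf_min:  # NaN (all missing) also fails
            ledger.append(("snp", pid, "maf"))
        else:
            keep_cols.append(k)
    if not keep_rows or not keep_cols:
        raise ValueError("QC removed every sample or every SNP")
    filtered = GenotypeMatrix(
        [genotypes.sample_ids[i] for i in keep_rows],
        [genotypes.probeset_ids[k] for k in keep_cols],
        calls[np.ix_(keep_rows, keep_cols)],
        genotypes.probeset_to_snp,
        genotypes.sample_breed,
    )
    return filtered, ledger


# ---------------------------------------------------------------------------
# population structure

def mds_coordinates(genotypes: GenotypeMatrix, k: int = 2
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical multidimensional scaling of 1 - IBS distances.

    Double-centres the squared distance matrix and eigendecomposes it;
    returns the top-k coordinates and the eigenvalues used.
    """
    if genotypes.n_samples < k + 1:
        raise ValueError("need at least k+1 samples")
    dist = 1.0 - pairwise_ibs(genotypes.dosage())
    np.fill_diagonal(dist, 0.0)
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if (vals > 1e-10).sum() < k:
        raise ValueError(f"only {(vals > 1e-10).sum()} positive eigenvalues; "
                         f"cannot return {k} dimensions")
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    df = pd.DataFrame(coords, index=genotypes.sample_ids,
                      columns=[f"C{i + 1}" for i in range(k)])
    return df, vals[:k]


# ---------------------------------------------------------------------------
# polygenic REML and the residual scan

def design_matrix(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Dummy-coded fixed-effect design: intercept, class effects for farm,
    calving year, calving season and parity, plus the age covariate."""
    cols = {"intercept": np.ones(len(phenotypes))}
    for name in FIXED_EFFECT_CLASSES:
        if name not in phenotypes.columns:
            continue
        levels = sorted(phenotypes[name].unique())
        for lev in levels[1:]:  # first level absorbed by the intercept
            cols[f"{name}[{lev}]"] = (phenotypes[name] == lev).astype(float)
    if AGE_COLUMN in phenotypes.columns:
        cols[AGE_COLUMN] = phenotypes[AGE_COLUMN].astype(float).to_numpy()
    x = pd.DataFrame(cols, index=phenotypes.index)
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValueError("rank-deficient fixed-effect design")
    return x


def fit_polygenic(
    phenotypes: pd.DataFrame,
    kinship: KinshipMatrix,
    trait: str = TRAIT_COLUMN,
) -> PolygenicFit:
    """Spectral REML for the single-kinship animal model.

    With K = U S U', rotating by U' makes the covariance diagonal,
    w_i = h2 s_i + (1 - h2), and the REML criterion is a smooth function of
    h2 alone; it is maximized by bounded scalar optimization, after which
    the variance scale, GLS fixed effects, polygenic BLUPs and environmental
    residuals follow in closed form.
    """
    ids = list(phenotypes.index)
    if ids != list(kinship.sample_ids):
        try:
            order = [kinship.sample_ids.index(i) for i in ids]
        except ValueError as err:
            raise ValueError("phenotype ids missing from kinship") from err
        kmat = kinship.matrix[np.ix_(order, order)]
    else:
        kmat = kinship.matrix
    s, u = np.linalg.eigh((kmat + kmat.T) / 2.0)
    if s.min() < -1e-6:
        raise ValueError("kinship matrix is not positive semi-definite")
    s = np.clip(s, 0.0, None)

    x = design_matrix(phenotypes)
    y = phenotypes[trait].to_numpy(dtype=float)
    xs, names = u.T @ x.to_numpy(), list(x.columns)
    ys = u.T @ y
    n, p = len(y), xs.shape[1]

    def reml_neg_loglik(h2: float) -> float:
        w = h2 * s + (1.0 - h2)
        xtw = xs.T / w
        xtwx = xtw @ xs
        beta = np.linalg.solve(xtwx, xtw @ ys)
        r = ys - xs @ beta
        rss = float(r @ (r / w))
        sign, logdet_xwx = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return np.inf
        ll = -0.5 * ((n - p) * np.log(rss / (n - p)) + np.sum(np.log(w))
                     + logdet_xwx)
        return -ll

    res = optimize.minimize_scalar(reml_neg_loglik, bounds=(1e-6, 1 - 1e-6),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    h2 = float(res.x)
    w = h2 * s + (1.0 - h2)
    xtw = xs.T / w
    beta = np.linalg.solve(xtw @ xs, xtw @ ys)
    r = ys - xs @ beta
    sigma2 = float(r @ (r / w)) / (n - p)
    sigma_a, sigma_e = h2 * sigma2, (1.0 - h2) * sigma2
    # BLUP of polygenic values: g_hat = h2 S W^{-1} (rotated residual), back-rotated
    g_hat = u @ (h2 * s / w * r)
    residuals = y - x.to_numpy() @ beta - g_hat
    return PolygenicFit(
        sigma_a=sigma_a,
        sigma_e=sigma_e,
        h2=h2,
        beta=pd.Series(beta, index=names),
        residuals=residuals,
        blup=g_hat,
        reml_loglik=-float(res.fun),
    )


def grammar_scan(residuals: np.ndarray, genotypes: GenotypeMatrix
                 ) -> pd.DataFrame:
    """Per-SNP simple regression of the step-one residuals on allele dosage
    (missing calls mean-imputed); chi-square is the squared Wald statistic.
    Monomorphic SNPs get NaN."""
    r = np.asarray(residuals, dtype=float)
    if len(r) != genotypes.n_samples:
        raise ValueError("residuals not aligned with genotype samples")
    x = genotypes.dosage(impute_mean=True)
    n = len(r)
    xc = x - x.mean(axis=0)
    rc = r - r.mean()
    sxx = (xc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (xc.T @ rc) / sxx
        rss = (rc**2).sum() - beta**2 * sxx
        se2 = rss / (n - 2) / sxx
        chi2 = beta**2 / se2
    mono = sxx <= 0
    beta[mono] = np.nan
    chi2[mono] = np.nan
    p = stats.chi2.sf(chi2, df=1)
    return pd.DataFrame({"snp": genotypes.probeset_ids, "n": n,
                         "effect": beta, "chi2": chi2, "p_raw": p})


def genomic_control(scan: pd.DataFrame, alpha: float = 1e-4) -> GwasResult:
    """Genomic-control correction: lambda = median(chi2)/0.4549 floored at 1;
    corrected p-values from chi2/lambda; significance at ``alpha``."""
    chi2 = scan["chi2"].to_numpy(dtype=float)
    valid = np.isfinite(chi2)
    if not valid.any():
        raise ValueError("no valid association statistics")
    lam_raw = float(np.median(chi2[valid]) / CHI2_MEDIAN_1DF)
    lam = max(lam_raw, 1.0)
    table = scan.copy()
    table["chi2_gc"] = table["chi2"] / lam
    table["p_gc"] = stats.chi2.sf(table["chi2_gc"], df=1)
    sig = table.loc[table["p_gc"] <= alpha, "snp"].tolist()
    return GwasResult(table=table, lam=lam, alpha=alpha, significant=sig,
                      lambda_raw=lam_raw)
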