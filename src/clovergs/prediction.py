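"""Stage 2: genomic prediction models producing GEBVs.

Single-trait models: GBLUP and KGD-GBLUP (one code path, differing only in
the relationship matrix supplied), BayesCpi (spike-and-slab Gibbs sampler)
and RKHS (Gaussian kernel fitted with the GBLUP machinery).  The multi-trait
model is a Gibbs sampler for the Kronecker mixed model with genetic
covariance K (x) G (K unstructured, inverse-Wishart prior) and diagonal
residual covariance; masked phenotype cells are excluded from the
likelihood, which is what enables the MTCV1/MTCV2 cross-validation schemes.

The stage-2 response is the stage-1 family BLUP attached to the genotyped
maternal parent; phenotyped individuals are those with a non-missing entry
in the response, everyone else in the relationship matrix is predicted
through genomic covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as opt
from scipy.stats import invwishart

from clovergs._gibbs import bayes_c_pi_gibbs
from clovergs.genotype_qc import GenotypeData
from clovergs.relatedness import RelationshipMatrix

log = logging.getLogger(__name__)


@dataclass
class PredictionModelSpec:
    """Model choice and hyperparameters for stage-2 prediction."""

    model: str = "gblup"
    grm_flavour: str = "vanraden"
    iterations: int = 3000
    burn_in: int = 1500
    thin: int = 1
    rkhs_bandwidth: float = 1.0
    prior_df: float = 5.0
    prior_r2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class GEBVResult:
    """Genomic estimated breeding values plus model parameter estimates."""

    gebv: pd.Series | pd.DataFrame
    mu: float | np.ndarray
    sigma2_g: float | None = None
    sigma2_e: float | None = None
    posterior_sd: pd.Series | None = None
    K: np.ndarray | None = None
    R: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def _as_series(blups) -> pd.Series:
    if isinstance(blups, pd.Series):
        return blups
    if hasattr(blups, "blups"):  # FamilyBLUPs
        return blups.blups
    raise TypeError("expected a pandas Series or FamilyBLUPs")


def _align_response(y: pd.Series, sample_ids: list[str]) -> np.ndarray:
    """Response vector over sample_ids with NaN for unphenotyped entries."""
    return y.reindex(sample_ids).to_numpy(float)


def mean_imputed_centred(g: GenotypeData) -> np.ndarray:
    """Dosage matrix with marker-mean imputation, centred per marker."""
    d = g.dosage_float()
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    idx = np.where(np.isnan(d))
    d[idx] = np.take(col_mean, idx[1])
    return d - col_mean


def gaussian_kernel(g: GenotypeData, bandwidth: float = 1.0) -> RelationshipMatrix:
    """Gaussian kernel K_ij = exp(-h d2_ij / median(d2)) on imputed dosages."""
    X = mean_imputed_centred(g)
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    d2 = np.clip(d2, 0.0, None)
    off = d2[np.triu_indices_from(d2, k=1)]
    med = np.median(off)
    if med <= 0:
        raise ValueError("degenerate kernel: all pairwise distances are zero")
    K = np.exp(-bandwidth * d2 / med)
    return RelationshipMatrix(
        values=K,
        sample_ids=list(g.sample_ids),
        flavour="rkhs",
        allele_freqs=np.array([]),
    )


# ------------------------------------------------------------------- GBLUP


def _reml_1d(s: np.ndarray, Uty: np.ndarray, Utx: np.ndarray):
    """Profiled REML over the variance ratio for y = mu + g, g~N(0, l*s2e*G).

    Works in the eigenbasis of the training-block relationship matrix
    (eigenvalues ``s``).  Returns (lambda, sigma2_e, mu).
    """
    n = len(s)

    def neg2ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = lam * s + 1.0
        xwx = np.sum(Utx**2 / w)
        mu = np.sum(Utx * Uty / w) / xwx
        r = Uty - Utx * mu
        sigma2_e = np.sum(r**2 / w) / (n - 1)
        if sigma2_e <= 0:
            return np.inf
        return np.sum(np.log(w)) + np.log(xwx) + (n - 1) * np.log(sigma2_e)

    res = opt.minimize_scalar(neg2ll, bounds=(-10.0, 12.0), method="bounded")
    lam = float(np.exp(res.x))
    w = lam * s + 1.0
    xwx = np.sum(Utx**2 / w)
    mu = float(np.sum(Utx * Uty / w) / xwx)
    r = Uty - Utx * mu
    sigma2_e = float(np.sum(r**2 / w) / (n - 1))
    return lam, sigma2_e, mu


def fit_gblup(
    blups,
    G: RelationshipMatrix,
    spec: PredictionModelSpec | None = None,
    solver: str = "eigen",
) -> GEBVResult:
    """GBLUP: y = mu + Zg + e with g ~ N(0, sigma2_g G).

    Variance components come from profiled REML on a single eigendecomposition
    of the training block of G.  All individuals in G receive GEBVs;
    unphenotyped ones are predicted through their genomic covariance with the
    training set.  ``solver='direct'`` recomputes the solution by dense
    mixed-model-equation inversion (cross-check path).
    """
    y = _align_response(_as_series(blups), G.sample_ids)
    train = np.isfinite(y)
    n_train = int(train.sum())
    if n_train < 3:
        raise ValueError("need at least 3 phenotyped individuals")
    y_t = y[train]
    if np.var(y_t) <= 0:
        raise ValueError("zero phenotypic variance in training set")

    Gv = np.asarray(G.values, float)
    if np.isnan(Gv).any():
        raise ValueError("relationship matrix contains missing entries")
    Gtt = Gv[np.ix_(train, train)]
    s_eig, U = np.linalg.eigh((Gtt + Gtt.T) / 2)
    if s_eig.min() < -1e-6:
        # moment estimators (depth-adjusted kinship) can be slightly
        # indefinite from sampling noise; bend small negative eigenvalues
        if s_eig.min() < -0.05 * s_eig.max():
            raise ValueError(
                "relationship matrix is not PSD beyond bending tolerance"
            )
        log.warning(
            "bending relationship matrix: clipping eigenvalues >= %.3g at 0",
            s_eig.min(),
        )
    s_eig = np.clip(s_eig, 0.0, None)
    Uty = U.T @ y_t
    Utx = U.T @ np.ones(n_train)
    lam, sigma2_e, mu = _reml_1d(s_eig, Uty, Utx)

    r = Uty - Utx * mu
    w = lam * s_eig + 1.0
    if solver == "eigen":
        alpha = U @ (r / w)  # = (lam*Gtt + I)^-1 (y - mu)
    elif solver == "direct":
        V = lam * Gtt + np.eye(n_train)
        alpha = np.linalg.solve(V, y_t - mu)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    gebv = lam * (Gv[:, train] @ alpha)

    return GEBVResult(
        gebv=pd.Series(gebv, index=pd.Index(G.sample_ids), name="gebv"),
        mu=mu,
        sigma2_g=lam * sigma2_e,
        sigma2_e=sigma2_e,
        extras={"lambda": lam, "flavour": G.flavour, "n_train": n_train},
    )


def fit_rkhs(
    blups,
    genotypes: GenotypeData,
    spec: PredictionModelSpec | None = None,
) -> GEBVResult:
    """RKHS regression: Gaussian kernel in place of the GRM."""
    spec = spec or PredictionModelSpec(model="rkhs")
    K = gaussian_kernel(genotypes, spec.rkhs_bandwidth)
    res = fit_gblup(blups, K, spec)
    res.extras["bandwidth"] = spec.rkhs_bandwidth
    return res


def fit_bayes_c_pi(
    blups,
    genotypes: GenotypeData,
    spec: PredictionModelSpec | None = None,
) -> GEBVResult:
    """BayesCpi whole-genome regression on mean-imputed dosages.

    Priors follow the convention of Bayesian whole-genome-regression
    software: scaled-inverse chi-square on slab and residual variances
    (df ``prior_df``, scales from the phenotypic variance with an R2
    heuristic), uniform prior on the inclusion probability.
    """
    spec = spec or PredictionModelSpec(model="bayes_c_pi")
    y_all = _align_response(_as_series(blups), genotypes.sample_ids)
    train = np.isfinite(y_all)
    if train.sum() < 10:
        raise ValueError("need at least 10 phenotyped individuals")
    X = mean_imputed_centred(genotypes)
    y_t = y_all[train]
    vy = float(np.var(y_t, ddof=1))

    sum_var_x = float(np.mean(X[train] ** 2, axis=0).sum())
    if sum_var_x <= 0:
        raise ValueError("no marker variance in training set")
    scale_b = spec.prior_r2 * vy / (0.5 * sum_var_x)
    scale_e = (1.0 - spec.prior_r2) * vy

    Xt = np.ascontiguousarray(X[train].T)
    (
        beta_mean, incl_prob, mu, pi_mean, s2b, s2e, g_mean, g_sd, n_in_mean,
    ) = bayes_c_pi_gibbs(
        Xt,
        y_t.astype(float),
        spec.iterations,
        spec.burn_in,
        spec.thin,
        spec.prior_df,
        scale_b,
        scale_e,
        int(spec.seed) % (2**31 - 1),
    )
    gebv = X @ beta_mean
    post_sd = np.full(len(y_all), np.nan)
    post_sd[train] = g_sd
    ids = pd.Index(genotypes.sample_ids)
    return GEBVResult(
        gebv=pd.Series(gebv, index=ids, name="gebv"),
        mu=float(mu),
        sigma2_g=float(s2b),
        sigma2_e=float(s2e),
        posterior_sd=pd.Series(post_sd, index=ids),
        extras={
            "inclusion_prob": pd.Series(incl_prob, index=genotypes.marker_info["id"]),
            "pi_in_mean": float(pi_mean),
            "n_included_mean": float(n_in_mean),
        },
    )


# -------------------------------------------------------------- multi-trait


def fit_multitrait(
    blups: pd.DataFrame,
    G: RelationshipMatrix,
    spec: PredictionModelSpec | None = None,
    observed_mask: pd.DataFrame | None = None,
    primary_trait: str | None = None,
) -> GEBVResult:
    """Multi-trait Kronecker mixed model by Gibbs sampling.

    ``blups`` is individuals x traits; ``observed_mask`` (same shape, bool)
    marks which cells enter the likelihood — NaN cells are always excluded.
    Genetic effects b ~ N(0, K (x) G) with K unstructured (inverse-Wishart
    prior); residuals have diagonal trait covariance R.  Returns posterior
    mean GEBVs for every individual and trait plus posterior K and R.
    """
    spec = spec or PredictionModelSpec(model="multitrait")
    traits = list(blups.columns)
    T = len(traits)
    if T < 2:
        raise ValueError("multi-trait model needs >= 2 traits")
    ids = list(G.sample_ids)
    n = len(ids)
    Y = blups.reindex(ids).to_numpy(float)
    obs = np.isfinite(Y)
    if observed_mask is not None:
        obs &= observed_mask.reindex(index=ids, columns=traits).fillna(False).to_numpy(bool)
    primary = primary_trait or traits[0]
    if obs[:, traits.index(primary)].sum() == 0:
        raise ValueError("no observed phenotypes for the primary trait")
    Yz = np.where(obs, np.nan_to_num(Y), 0.0)

    rng = np.random.default_rng(spec.seed)
    Gv = np.asarray(G.values, float) + 1e-6 * np.eye(n)
    Ginv = np.linalg.inv((Gv + Gv.T) / 2)

    vy = np.array(
        [np.nanvar(Y[obs[:, t], t], ddof=1) if obs[:, t].sum() > 1 else 1.0
         for t in range(T)]
    )
    vy = np.where(vy > 0, vy, 1.0)
    mu = np.array(
        [np.nanmean(Y[obs[:, t], t]) if obs[:, t].any() else 0.0 for t in range(T)]
    )
    K = np.diag(0.5 * vy)
    Rdiag = 0.5 * vy
    B = np.zeros((n, T))

    nu0 = T + 2
    S0 = np.diag(0.5 * vy)
    nuR = 5.0
    Se = 0.5 * vy

    n_saved = 0
    B_sum = np.zeros((n, T))
    K_sum = np.zeros((T, T))
    R_sum = np.zeros(T)
    mu_sum = np.zeros(T)

    diag_idx = np.arange(T * n)
    for it in range(spec.iterations):
        # --- genetic effects b | rest
        Kinv = np.linalg.inv(K)
        P = np.kron(Kinv, Ginv)
        P[diag_idx, diag_idx] += (obs.T / Rdiag[:, None]).reshape(-1)
        rhs = ((obs * (Yz - mu)) / Rdiag).T.reshape(-1)
        L = np.linalg.cholesky(P)
        m_vec = sla.cho_solve((L, True), rhs, check_finite=False)
        z = rng.standard_normal(T * n)
        b = m_vec + sla.solve_triangular(L.T, z, lower=False, check_finite=False)
        B = b.reshape(T, n).T

        # --- intercepts and residual variances
        for t in range(T):
            o = obs[:, t]
            n_o = int(o.sum())
            if n_o == 0:  # fully masked trait: prior draw only
                Rdiag[t] = nuR * Se[t] / rng.chisquare(nuR)
                continue
            resid = Y[o, t] - B[o, t]
            mu[t] = resid.mean() + rng.standard_normal() * np.sqrt(Rdiag[t] / n_o)
            sse = float(np.sum((Y[o, t] - mu[t] - B[o, t]) ** 2))
            Rdiag[t] = (sse + nuR * Se[t]) / rng.chisquare(nuR + n_o)

        # --- genetic covariance K | b
        S = B.T @ Ginv @ B
        K = invwishart.rvs(df=nu0 + n, scale=S0 + S, random_state=rng)
        K = np.atleast_2d(K)
        ev = np.linalg.eigvalsh(K)
        if ev.min() < 1e-10:
            log.warning("multitrait: K update lost positive-definiteness, jittering")
            K += (1e-8 - min(ev.min(), 0.0)) * np.eye(T)

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            n_saved += 1
            B_sum += B
            K_sum += K
            R_sum += Rdiag
            mu_sum += mu

    gebv = pd.DataFrame(B_sum / n_saved, index=pd.Index(ids), columns=traits)
    K_mean = K_sum / n_saved
    R_mean = np.diag(R_sum / n_saved)
    return GEBVResult(
        gebv=gebv,
        mu=mu_sum / n_saved,
        K=K_mean,
        R=R_mean,
        extras={
            "primary_trait": primary,
            "genetic_correlation": K_mean[0, 1] / np.sqrt(K_mean[0, 0] * K_mean[1, 1])
            if T >= 2
            else None,
        },
    )
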