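"""Stage 1: univariate REML mixed model on plot-level trial data.

Fits ``y = mu + location + year + rep(location) + f + fl + fy + eps`` with
independent normal random effects for family (f), family-by-location (fl)
and family-by-year (fy), yielding variance components, empirical family
BLUPs and the half-sib family-mean heritability.  Check-cultivar plots enter
through fixed cultivar effects and inform the location/year/rep terms but
contribute no family effect.

The REML criterion is maximised directly: variance ratios are profiled
against the residual variance and the restricted log-likelihood is evaluated
through the mixed-model equations (one sparse cross-product pass, then a
dense Cholesky per evaluation), which keeps crossed random effects exact
without large-n dense algebra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as opt
import scipy.sparse as sp

log = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    """REML variance components and the trial design counts they refer to."""

    sigma2_f: float
    sigma2_fl: float
    sigma2_fy: float
    sigma2_e: float
    n_locations: int
    n_years: int
    n_reps: int

    @property
    def sigma2_A(self) -> float:
        """Additive variance: 4x the among-HS-family variance."""
        return 4.0 * self.sigma2_f

    def __post_init__(self) -> None:
        for name in ("sigma2_f", "sigma2_fl", "sigma2_fy", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FamilyBLUPs:
    """Empirical BLUPs of family effects plus the trial grand mean."""

    blups: pd.Series  # indexed by family id, one trait
    grand_mean: float
    trait: str


def family_mean_sigma_pf(
    vc: VarianceComponents, years_of_data: int | None = None
) -> float:
    """Among-family phenotypic SD on the family-mean basis.

    ``sigma_PF = sqrt(s2_f + s2_fl/l + s2_fy/y + s2_e/(l*y*r))`` for an
    evaluation design with l locations, y years and r replicates — the
    standard HS family-mean variance for the trial design.  ``years_of_data``
    overrides the number of years (e.g. gain from 2 vs 3 years of records).
    """
    y = years_of_data if years_of_data is not None else vc.n_years
    l, r = vc.n_locations, vc.n_reps
    var = vc.sigma2_f + vc.sigma2_fl / l + vc.sigma2_fy / y + vc.sigma2_e / (l * y * r)
    if var <= 0:
        raise ValueError("zero family-mean phenotypic variance")
    return float(np.sqrt(var))


def heritability_family_mean(
    vc: VarianceComponents, years_of_data: int | None = None
) -> float:
    """Half-sib family-mean heritability for the evaluation design."""
    sigma_pf = family_mean_sigma_pf(vc, years_of_data)
    return float(vc.sigma2_f / sigma_pf**2)


def _indicator(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    rows = np.flatnonzero(codes >= 0)
    return sp.csr_matrix(
        (np.ones(len(rows)), (rows, codes[rows])), shape=(len(codes), n_levels)
    )


def fit_stage1(
    pheno: pd.DataFrame,
    trait: str,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[VarianceComponents, FamilyBLUPs]:
    """Fit the stage-1 model for one trait and return (components, BLUPs).

    ``pheno`` is the tidy long table (entry_id, entry_type, location, year,
    rep, trait, value).  Interaction components confounded by the design
    (single location or single year) are dropped with a warning.  Negative
    boundary estimates are clamped at zero.
    """
    df = pheno[(pheno["trait"] == trait) & pheno["value"].notna()].copy()
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    # repeated checks share (entry, loc, year, rep); distinguish by plot when given
    key = ["entry_id", "location", "year", "rep", "trait"]
    if {"row", "col"}.issubset(df.columns):
        key += ["row", "col"]
    if df.duplicated(key).any():
        raise ValueError("duplicate phenotype records for the same plot")

    fam_df = df[df["entry_type"] == "family"]
    fam_counts = fam_df["entry_id"].value_counts()
    if (fam_counts >= 2).sum() < 2:
        raise ValueError("need >= 2 families with >= 2 observations each")

    y = df["value"].to_numpy(float)
    n = len(y)
    n_loc = df["location"].nunique()
    n_yr = df["year"].nunique()
    n_rep = df["rep"].nunique()

    # ---- fixed effects: intercept, location, year, rep(location), checks
    X_cols = [np.ones(n)]
    for col, levels in (("location", None), ("year", None)):
        codes, uniq = pd.factorize(df[col], sort=True)
        for lv in range(1, len(uniq)):
            X_cols.append((codes == lv).astype(float))
    rl_codes, rl_uniq = pd.factorize(
        df["location"].astype(str) + ":" + df["rep"].astype(str), sort=True
    )
    # drop one rep per location to avoid confounding with location dummies
    keep = [
        i for i, lv in enumerate(rl_uniq) if not lv.endswith(":" + sorted(set(df["rep"]))[0])
    ]
    for lv in keep:
        X_cols.append((rl_codes == lv).astype(float))
    is_check = (df["entry_type"] == "check").to_numpy()
    if is_check.any():
        ccodes, cuniq = pd.factorize(df.loc[is_check, "entry_id"], sort=True)
        for lv in range(len(cuniq)):
            col = np.zeros(n)
            col[np.flatnonzero(is_check)[ccodes == lv]] = 1.0
            X_cols.append(col)
    X = np.column_stack(X_cols)
    p = X.shape[1]

    # ---- random effects
    is_fam = ~is_check
    fam_codes = np.full(n, -1)
    fam_codes[is_fam], fam_levels = pd.factorize(df.loc[is_fam, "entry_id"], sort=True)
    q_f = len(fam_levels)
    blocks = [("f", _indicator(fam_codes, q_f))]
    if n_loc > 1:
        fl_codes = np.where(
            is_fam, fam_codes * n_loc + pd.factorize(df["location"], sort=True)[0], -1
        )
        blocks.append(("fl", _indicator(fl_codes, q_f * n_loc)))
    else:
        log.warning("single location: family-by-location component dropped")
    if n_yr > 1:
        fy_codes = np.where(
            is_fam, fam_codes * n_yr + pd.factorize(df["year"], sort=True)[0], -1
        )
        blocks.append(("fy", _indicator(fy_codes, q_f * n_yr)))
    else:
        log.warning("single year: family-by-year component dropped")

    Z = sp.hstack([b for _, b in blocks], format="csr")
    q_sizes = [b.shape[1] for _, b in blocks]
    q = sum(q_sizes)

    # one-time cross products
    XtX = X.T @ X
    XtZ = (Z.T @ X).T
    ZtZ = (Z.T @ Z).toarray()
    Xty = X.T @ y
    Zty = Z.T @ y
    yty = float(y @ y)
    Wty = np.concatenate([Xty, Zty])
    block_slices = np.split(np.arange(q), np.cumsum(q_sizes)[:-1])

    M0 = np.zeros((p + q, p + q))
    M0[:p, :p] = XtX
    M0[:p, p:] = XtZ
    M0[p:, :p] = XtZ.T
    M0[p:, p:] = ZtZ

    def reml_parts(log_gamma: np.ndarray):
        gam = np.exp(np.clip(log_gamma, -15.0, 15.0))
        M = M0.copy()
        for g_val, sl in zip(gam, block_slices):
            ii = p + sl
            M[ii, ii] += 1.0 / g_val
        try:
            cf = sla.cho_factor(M, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        sol = sla.cho_solve(cf, Wty, check_finite=False)
        ypy = yty - float(sol @ Wty)
        if ypy <= 0:
            return None
        logdet_M = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        logdet_gamma = float(sum(len(sl) * lg for lg, sl in zip(np.log(gam), block_slices)))
        sigma2_e = ypy / (n - p)
        neg2ll = (n - p) * np.log(sigma2_e) + logdet_M + logdet_gamma
        return neg2ll, sigma2_e, sol, gam

    def objective(log_gamma: np.ndarray) -> float:
        parts = reml_parts(log_gamma)
        return np.inf if parts is None else parts[0]

    x0 = np.full(len(blocks), np.log(0.2))
    res = opt.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": tol, "maxiter": max_iter, "maxfev": max_iter},
    )
    parts = reml_parts(res.x)
    if parts is None or not np.isfinite(res.fun):
        raise RuntimeError(f"REML did not converge: {res.message}")
    if not res.success:
        log.warning("REML optimiser stopped early: %s", res.message)
    _, sigma2_e, sol, gam = parts

    comps = dict.fromkeys(("f", "fl", "fy"), 0.0)
    for (name, _), g_val in zip(blocks, gam):
        val = g_val * sigma2_e
        comps[name] = 0.0 if val < 1e-10 else float(val)

    vc = VarianceComponents(
        sigma2_f=comps["f"],
        sigma2_fl=comps["fl"],
        sigma2_fy=comps["fy"],
        sigma2_e=float(sigma2_e),
        n_locations=n_loc,
        n_years=n_yr,
        n_reps=n_rep,
    )

    beta = sol[:p]
    u_f = sol[p : p + q_f]
    fam_rows = is_fam
    grand_mean = float((X[fam_rows] @ beta).mean())
    blups = FamilyBLUPs(
        blups=pd.Series(u_f, index=pd.Index(fam_levels, name="family_id"), name=trait),
        grand_mean=grand_mean,
        trait=trait,
    )
    return vc, blups


def fit_all_traits(
    pheno: pd.DataFrame, traits: list[str] | None = None
) -> tuple[dict[str, VarianceComponents], pd.DataFrame]:
    """Fit every trait; returns components per trait and a BLUP table."""
    traits = traits or sorted(pheno["trait"].unique())
    vcs, blup_cols = {}, {}
    for t in traits:
        vc, fb = fit_stage1(pheno, t)
        vcs[t] = vc
        blup_cols[t] = fb.blups
    return vcs, pd.DataFrame(blup_cols)
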