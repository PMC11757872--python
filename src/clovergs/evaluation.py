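"""Monte-Carlo cross-validation, MTCV schemes and design sweeps.

Predictive ability is the Pearson correlation between GEBVs and observed
(stage-1 BLUP) phenotypes in the held-out test set; bias is the slope of
the regression of observed on predicted values (1 = unbiased).  Relationship
matrices are computed once over all individuals — standard GBLUP semantics,
where relationships with candidates lacking phenotypes are known.

Iterations in which the predictions are constant leave the correlation
undefined; those iterations are recorded as missing and excluded from the
summaries (never coerced to zero), with a count kept in the result.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clovergs.genotype_qc import GenotypeData
from clovergs.prediction import (
    GEBVResult,
    PredictionModelSpec,
    fit_bayes_c_pi,
    fit_gblup,
    fit_multitrait,
    fit_rkhs,
    gaussian_kernel,
)
from clovergs.relatedness import RelationshipMatrix, grm_kgd, grm_vanraden

log = logging.getLogger(__name__)


@dataclass
class CVConfig:
    """Monte-Carlo cross-validation settings (default 80/20, 100 repeats)."""

    n_iterations: int = 100
    train_fraction: float = 0.8
    scheme: str = "single_trait"  # single_trait | mtcv1 | mtcv2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.scheme not in ("single_trait", "mtcv1", "mtcv2"):
            raise ValueError(f"unknown CV scheme {self.scheme!r}")


@dataclass
class PredictionData:
    """Everything stage 2 needs: responses, genotypes and relationship matrices."""

    blups: pd.DataFrame  # individuals x traits
    genotypes: GenotypeData | None = None
    grms: dict[str, RelationshipMatrix] = field(default_factory=dict)
    primary_trait: str | None = None
    secondary_traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.primary_trait is None:
            self.primary_trait = self.blups.columns[0]

    def grm_for(self, spec: PredictionModelSpec) -> RelationshipMatrix:
        flavour = "kgd" if spec.model == "kgd_gblup" else spec.grm_flavour
        if spec.model == "kgd_gblup":
            flavour = "kgd"
        if flavour not in self.grms:
            if self.genotypes is None:
                raise ValueError(f"no {flavour} GRM and no genotypes to build one")
            builder = grm_kgd if flavour == "kgd" else grm_vanraden
            self.grms[flavour] = builder(self.genotypes)
        return self.grms[flavour]

    @property
    def ids(self) -> list[str]:
        if self.grms:
            return list(next(iter(self.grms.values())).sample_ids)
        return list(self.genotypes.sample_ids)


@dataclass
class PredictionResult:
    """Per-iteration predictive abilities and biases, with summaries."""

    iterations: pd.DataFrame  # columns: iteration, predictive_ability, bias
    label: str = ""

    @property
    def predictive_ability(self) -> np.ndarray:
        return self.iterations["predictive_ability"].to_numpy()

    @property
    def mean_r(self) -> float:
        return float(np.nanmean(self.predictive_ability))

    @property
    def sd_r(self) -> float:
        return float(np.nanstd(self.predictive_ability, ddof=1))

    @property
    def se_r(self) -> float:
        n = np.isfinite(self.predictive_ability).sum()
        return self.sd_r / np.sqrt(n)

    @property
    def mean_bias(self) -> float:
        return float(np.nanmean(self.iterations["bias"].to_numpy()))

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.predictive_ability).sum())

    def notch(self) -> tuple[float, float]:
        """Median notch interval (median +/- 1.58*IQR/sqrt(n))."""
        r = self.predictive_ability
        r = r[np.isfinite(r)]
        q1, med, q3 = np.percentile(r, [25, 50, 75])
        half = 1.58 * (q3 - q1) / np.sqrt(len(r))
        return med - half, med + half


def _r_and_bias(observed: np.ndarray, predicted: np.ndarray):
    ok = np.isfinite(observed) & np.isfinite(predicted)
    obs, pred = observed[ok], predicted[ok]
    if len(obs) < 3 or np.std(pred) == 0 or np.std(obs) == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(obs, pred)[0, 1])
    bias = float(np.cov(obs, pred)[0, 1] / np.var(pred, ddof=1))
    return r, bias


def mtcv_masks(
    scheme: str,
    test_ids,
    ids,
    traits,
    primary_trait,
) -> pd.DataFrame:
    """Observed-phenotype mask for a multi-trait CV split.

    MTCV1 masks every trait of the test individuals (no phenotype at all);
    MTCV2 masks only their primary-trait phenotypes, keeping the secondary
    trait observed.  Training individuals are observed for all traits.
    """
    if scheme not in ("mtcv1", "mtcv2"):
        raise ValueError(f"unknown multi-trait CV scheme {scheme!r}")
    mask = pd.DataFrame(True, index=pd.Index(ids), columns=list(traits))
    test_ids = list(test_ids)
    if scheme == "mtcv1":
        mask.loc[test_ids, :] = False
    else:
        mask.loc[test_ids, primary_trait] = False
    return mask


def _fit_for_split(
    data: PredictionData,
    spec: PredictionModelSpec,
    y_masked: pd.Series,
    test_ids: list[str],
    cv_scheme: str,
    iter_seed: int,
    kernel: RelationshipMatrix | None = None,
) -> GEBVResult:
    spec_i = PredictionModelSpec(**{**spec.__dict__, "seed": iter_seed})
    if cv_scheme in ("mtcv1", "mtcv2"):
        traits = [data.primary_trait] + list(data.secondary_traits)
        mask = mtcv_masks(cv_scheme, test_ids, data.ids, traits, data.primary_trait)
        return fit_multitrait(
            data.blups[traits],
            data.grm_for(spec_i),
            spec_i,
            observed_mask=mask,
            primary_trait=data.primary_trait,
        )
    if spec.model in ("gblup", "kgd_gblup"):
        return fit_gblup(y_masked, data.grm_for(spec_i), spec_i)
    if spec.model == "rkhs":
        if kernel is None:
            kernel = gaussian_kernel(data.genotypes, spec.rkhs_bandwidth)
        return fit_gblup(y_masked, kernel, spec_i)
    if spec.model == "bayes_c_pi":
        return fit_bayes_c_pi(y_masked, data.genotypes, spec_i)
    raise ValueError(f"unknown model {spec.model!r}")


def monte_carlo_cv(
    data: PredictionData,
    model_spec: PredictionModelSpec,
    cv: CVConfig,
    label: str | None = None,
) -> PredictionResult:
    """Repeat random train/test splits, fit on training only, score on test."""
    y = data.blups[data.primary_trait]
    phenotyped = [i for i in data.ids if i in y.index and np.isfinite(y[i])]
    if len(phenotyped) < 10:
        raise ValueError("need >= 10 phenotyped and genotyped entries")
    n_test = max(1, round((1 - cv.train_fraction) * len(phenotyped)))
    rng = np.random.default_rng(cv.seed)
    kernel = None
    if model_spec.model == "rkhs" and cv.scheme == "single_trait":
        kernel = gaussian_kernel(data.genotypes, model_spec.rkhs_bandwidth)

    rows = []
    for it in range(cv.n_iterations):
        test_ids = list(rng.choice(phenotyped, size=n_test, replace=False))
        y_masked = y.copy()
        y_masked.loc[test_ids] = np.nan
        iter_seed = int(rng.integers(0, 2**31 - 1))
        res = _fit_for_split(
            data, model_spec, y_masked, test_ids, cv.scheme, iter_seed, kernel
        )
        gebv = res.gebv[data.primary_trait] if isinstance(res.gebv, pd.DataFrame) else res.gebv
        r, bias = _r_and_bias(
            y.loc[test_ids].to_numpy(float), gebv.loc[test_ids].to_numpy(float)
        )
        if np.isnan(r):
            log.warning("iteration %d: constant predictions, r undefined", it)
        rows.append((it, r, bias))
    return PredictionResult(
        iterations=pd.DataFrame(
            rows, columns=["iteration", "predictive_ability", "bias"]
        ),
        label=label or f"{model_spec.model}/{cv.scheme}",
    )


def sweep_training_size(
    data: PredictionData,
    model_spec: PredictionModelSpec,
    sizes=(20, 40, 60, 80, 100, 120, 140, 160, 180, 200),
    cv: CVConfig | None = None,
) -> dict[int, PredictionResult]:
    """Predictive ability as a function of training-population size.

    Per iteration the 20% test set is drawn first from all families, then the
    training pool is subsampled to the requested size — test difficulty is
    constant across sizes.  A size covering the whole pool reproduces the
    plain Monte-Carlo CV under the same seed.
    """
    cv = cv or CVConfig()
    y = data.blups[data.primary_trait]
    phenotyped = [i for i in data.ids if i in y.index and np.isfinite(y[i])]
    n_test = max(1, round((1 - cv.train_fraction) * len(phenotyped)))
    out: dict[int, PredictionResult] = {}
    for size in sizes:
        if size < 10:
            warnings.warn(f"training size {size} < 10: unstable correlations")
        rng = np.random.default_rng(cv.seed)
        rows = []
        for it in range(cv.n_iterations):
            test_ids = list(rng.choice(phenotyped, size=n_test, replace=False))
            pool = [i for i in phenotyped if i not in set(test_ids)]
            iter_seed = int(rng.integers(0, 2**31 - 1))
            if size < len(pool):
                train_ids = list(rng.choice(pool, size=size, replace=False))
            else:
                train_ids = pool
            y_masked = y.copy()
            y_masked.loc[~y_masked.index.isin(train_ids)] = np.nan
            res = _fit_for_split(
                data, model_spec, y_masked, test_ids, "single_trait", iter_seed
            )
            r, bias = _r_and_bias(
                y.loc[test_ids].to_numpy(float),
                res.gebv.loc[test_ids].to_numpy(float),
            )
            rows.append((it, r, bias))
        out[size] = PredictionResult(
            iterations=pd.DataFrame(
                rows, columns=["iteration", "predictive_ability", "bias"]
            ),
            label=f"{model_spec.model}/n_train={size}",
        )
    return out


def sweep_marker_count(
    data: PredictionData,
    model_spec: PredictionModelSpec,
    counts=(55, 110, 550, 1100, 5500, 11000, 55000),
    cv: CVConfig | None = None,
) -> dict[int, PredictionResult]:
    """Predictive ability as a function of marker number.

    Markers are subsampled uniformly per iteration and the relationship
    matrix rebuilt from the subset.  Using every marker reproduces the plain
    run under the same seed.
    """
    cv = cv or CVConfig()
    if data.genotypes is None:
        raise ValueError("marker sweep requires genotype data")
    m_total = data.genotypes.n_markers
    if max(counts) > m_total:
        raise ValueError("marker count exceeds available markers")
    y = data.blups[data.primary_trait]
    phenotyped = [i for i in data.ids if i in y.index and np.isfinite(y[i])]
    n_test = max(1, round((1 - cv.train_fraction) * len(phenotyped)))
    builder = grm_kgd if model_spec.model == "kgd_gblup" else grm_vanraden

    out: dict[int, PredictionResult] = {}
    for count in counts:
        rng = np.random.default_rng(cv.seed)
        rows = []
        for it in range(cv.n_iterations):
            test_ids = list(rng.choice(phenotyped, size=n_test, replace=False))
            iter_seed = int(rng.integers(0, 2**31 - 1))
            if count < m_total:
                marker_idx = rng.choice(m_total, size=count, replace=False)
                G = builder(data.genotypes.subset(markers=np.sort(marker_idx)))
            else:
                G = data.grm_for(model_spec)
            y_masked = y.copy()
            y_masked.loc[test_ids] = np.nan
            spec_i = PredictionModelSpec(**{**model_spec.__dict__, "seed": iter_seed})
            res = fit_gblup(y_masked, G, spec_i)
            r, bias = _r_and_bias(
                y.loc[test_ids].to_numpy(float),
                res.gebv.loc[test_ids].to_numpy(float),
            )
            rows.append((it, r, bias))
        out[count] = PredictionResult(
            iterations=pd.DataFrame(
                rows, columns=["iteration", "predictive_ability", "bias"]
            ),
            label=f"{model_spec.model}/m={count}",
        )
    return out


def accuracy_from_predictive_ability(r: float, h2: float) -> float:
    """Prediction accuracy r / sqrt(h2), clipped to [-1, 1] with a warning."""
    if h2 <= 0:
        raise ValueError("h2 must be > 0")
    if h2 > 1:
        raise ValueError("h2 must be <= 1")
    acc = r / np.sqrt(h2)
    if abs(acc) > 1:
        warnings.warn("accuracy clipped to [-1, 1]")
        acc = float(np.clip(acc, -1.0, 1.0))
    return float(acc)
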