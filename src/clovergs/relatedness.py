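"""Genomic relationship matrices and population-structure diagnostics.

Two GRM flavours are provided:

* ``grm_vanraden`` — the classical marker GRM ``G = XX' / (2 Σ p_i(1-p_i))``
  with markers coded −1/0/1, centred by ``P = 2(p_i − 0.5)`` and missing
  calls mean-imputed.
* ``grm_kgd`` — a depth-adjusted estimator for low-coverage GBS data that
  needs no imputation.  Off-diagonals use only markers observed in both
  individuals (numerator and denominator restricted to the shared set).
  Diagonals use the fractional dosage ``d = 2·alt_reads/depth`` and remove
  the read-sampling inflation of the naive self-relatedness: under binomial
  read sampling at depth k, ``E[(d − 2p)²] = (g − 2p)² + g(2−g)/k``, and
  ``d(2−d)·k/(k−1)`` is unbiased for ``g(2−g)`` when k ≥ 2, so subtracting
  ``d(2−d)/(k−1)`` per marker (with the Hardy–Weinberg fallback ``2pq`` at
  k = 1) makes the diagonal unbiased for the true self-relatedness.

The MDS diagnostic performs classical scaling (principal coordinates) on the
inner-product distances ``d²_ij = G_ii + G_jj − 2 G_ij``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from clovergs.genotype_qc import GenotypeData

log = logging.getLogger(__name__)


@dataclass
class RelationshipMatrix:
    """Square symmetric kinship matrix with construction metadata."""

    values: np.ndarray
    sample_ids: list[str]
    flavour: str
    allele_freqs: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if len(self.sample_ids) != v.shape[0]:
            raise ValueError("sample_ids length must match matrix order")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def with_ridge(self, ridge: float = 1e-6) -> np.ndarray:
        """Values with a small diagonal ridge for downstream solvers."""
        log.debug("adding ridge %g to %s GRM diagonal", ridge, self.flavour)
        return self.values + ridge * np.eye(self.n)

    def subset(self, idx) -> "RelationshipMatrix":
        idx = np.asarray(idx)
        return RelationshipMatrix(
            values=self.values[np.ix_(idx, idx)].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            flavour=self.flavour,
            allele_freqs=self.allele_freqs,
        )


def _allele_freqs(g: GenotypeData) -> np.ndarray:
    d = g.dosage_float()
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2 * np.sum(~np.isnan(d), axis=0))
    return p


def grm_vanraden(
    g: GenotypeData, allele_freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """VanRaden GRM with marker-mean imputation of missing calls."""
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    p = _allele_freqs(g) if allele_freqs is None else np.asarray(allele_freqs)
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    denom = 2 * np.sum(p[poly] * (1 - p[poly]))
    if denom <= 0:
        raise ValueError("no polymorphic markers: zero GRM denominator")

    M = g.dosage_float() - 1.0  # coded -1/0/1
    col_mean = np.nanmean(np.where(np.isfinite(M), M, np.nan), axis=0)
    inds = np.where(np.isnan(M))
    M[inds] = np.take(col_mean, inds[1])
    X = (M - 2 * (p - 0.5))[:, poly]
    G = X @ X.T / denom
    return RelationshipMatrix(
        values=G, sample_ids=list(g.sample_ids), flavour="vanraden", allele_freqs=p
    )


def grm_kgd(
    g: GenotypeData, allele_freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """Depth-adjusted GRM for low-coverage GBS data (no imputation).

    Requires the allele-depth matrices.  Pairs with no shared non-missing
    marker get a NaN entry (flagged in the log).  Allele frequencies default
    to estimates from the naive calls over all individuals.
    """
    if not g.has_depth:
        raise ValueError(
            "depth matrix unavailable; use grm_vanraden for call-only data"
        )
    depth = g.depth.astype(float)
    obs = depth > 0
    p = _allele_freqs(g) if allele_freqs is None else np.asarray(allele_freqs)
    p = np.where(np.isfinite(p), p, 0.0)
    pq = p * (1 - p)

    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(obs, 2.0 * g.alt_reads / depth, 0.0)
    Y = np.where(obs, d - 2 * p, 0.0)
    W = obs.astype(float)

    num = Y @ Y.T
    den = 2.0 * (W * pq) @ W.T
    with np.errstate(divide="ignore", invalid="ignore"):
        G = num / den
    n_empty = int(np.sum(den == 0))
    if n_empty:
        log.warning("grm_kgd: %d pairs share no informative marker", n_empty)
        G[den == 0] = np.nan

    # diagonal: remove read-sampling inflation
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(depth >= 2, d * (2 - d) / (depth - 1), 0.0)
    corr = np.where(depth == 1, 2 * pq[None, :], corr)
    diag_num = np.sum(np.where(obs, Y**2 - corr, 0.0), axis=1)
    diag_den = 2.0 * np.sum(np.where(obs, pq[None, :], 0.0), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.fill_diagonal(G, diag_num / diag_den)
    return RelationshipMatrix(
        values=G, sample_ids=list(g.sample_ids), flavour="kgd", allele_freqs=p
    )


def mds_from_grm(G: RelationshipMatrix, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical MDS (principal coordinates) of a GRM.

    Uses the inner-product distances ``d²_ij = G_ii + G_jj − 2 G_ij``, which
    is equivalent to double-centring G.  Returns (coordinates n×k,
    eigenvalues descending).
    """
    n = G.n
    if k > n - 1:
        raise ValueError("k must be at most n - 1")
    V = np.asarray(G.values, dtype=float)
    if not np.allclose(V, V.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ V @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0, None))
    return coords, vals
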