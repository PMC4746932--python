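"""Kinship estimation and per-gene pseudo-heritability.

The model for one gene's (standardized) expression vector y over n donors is

    y = beta0 * 1 + u + eps,   u ~ N(0, h * K),   eps ~ N(0, (1 - h) * I),

where K is the realized relationship matrix (RRM) estimated from genome-wide
SNP dosages and h in [0, 1) is the *pseudo-heritability*: the fraction of
expression variance explained by genome-wide donor similarity.  Expression
is normalized to unit total variance, and the covariance is parameterized as
sigma^2 (h K + (1-h) I) with the overall scale sigma^2 profiled out
analytically, so h — the variance fraction — is the single parameter
searched.  It is estimated by restricted maximum likelihood (REML by
default, plain ML by flag) evaluated in the eigenbasis of K, so that a
single eigendecomposition is shared by every gene in a tissue.

Two kinship centerings are available:

``standard``
    VanRaden RRM, K(r,s) = (1/L) * sum_l (g_lr - 2 p_l)(g_ls - 2 p_l)
    / (2 p_l (1 - p_l)); diagonal ~ 1 + F.  The default.
``as_printed``
    Centering by p_l and scaling by p_l (1 - p_l), for fidelity runs against
    analyses that used that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import ExpressionMatrix, GenotypeMatrix, ValidationError

H_MAX = 1.0 - 1e-6
GRID_STEP = 0.01
EIGEN_JITTER = 1e-8


@dataclass
class KinshipMatrix:
    """Symmetric donor × donor genomic similarity with cached eigenpairs.

    Eigenvalues are stored in descending order; a diagonal jitter of 1e-8 is
    applied before decomposition whenever the smallest eigenvalue is negative,
    and residual negative eigenvalues below -1e-8 are rejected.
    """

    values: np.ndarray
    donors: list[str]
    eigenvectors: np.ndarray = field(init=False, repr=False)
    eigenvalues: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        if K.shape[0] != K.shape[1] or K.shape[0] != len(self.donors):
            raise ValidationError("kinship matrix shape does not match donor list")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValidationError("kinship matrix is not symmetric")
        K = (K + K.T) / 2.0
        w, U = np.linalg.eigh(K)
        if w.min() < -1e-10:  # genuinely indefinite beyond float round-off
            K = K + EIGEN_JITTER * np.eye(K.shape[0])
            w, U = np.linalg.eigh(K)
        if w.min() < -EIGEN_JITTER:
            raise ValidationError(
                f"kinship not positive semi-definite after jitter (min eig {w.min():.3g})"
            )
        order = np.argsort(w)[::-1]
        self.values = K
        self.eigenvalues = np.clip(w[order], 0.0, None)
        self.eigenvectors = U[:, order]

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.donors, columns=self.donors)

    def subset(self, donors: Sequence[str]) -> "KinshipMatrix":
        """Restrict to (and reorder by) a donor subset; eigenpairs recomputed."""
        idx = {d: i for i, d in enumerate(self.donors)}
        missing = [d for d in donors if d not in idx]
        if missing:
            raise ValidationError(f"donors absent from kinship: {missing[:5]}")
        sel = [idx[d] for d in donors]
        return KinshipMatrix(self.values[np.ix_(sel, sel)], list(donors))


def compute_kinship(gt: GenotypeMatrix, centering: str = "standard") -> KinshipMatrix:
    """Realized relationship matrix from 0/1/2 dosages.

    Requires at least 10 polymorphic SNPs (the kinship estimate is unstable
    below that).
    """
    if centering not in ("standard", "as_printed"):
        raise ValueError(f"unknown centering {centering!r}")
    G = gt.values
    p = gt.allele_freq.to_numpy(dtype=float)
    L = G.shape[1]
    if L < 10:
        raise ValidationError(f"need >= 10 polymorphic SNPs for kinship, got {L}")
    if centering == "standard":
        Z = (G - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    else:
        Z = (G - p) / np.sqrt(p * (1.0 - p))
    K = (Z @ Z.T) / L
    return KinshipMatrix(K, gt.donors)


@dataclass
class HeritabilityEstimate:
    gene: str
    tissue: str
    h: float
    intercept: float
    loglik: float
    converged: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.h < 1.0):
            raise ValidationError(f"pseudo-heritability out of [0,1): {self.h}")


def _spectral_loglik_terms(h: np.ndarray, lam: np.ndarray, x2: np.ndarray):
    """Return (sum log d, a = x' D^-1 x, weights 1/d) on the eigen grid.

    h: (H,) grid; lam: (n,) eigenvalues; x2: (n,) squared rotated intercept.
    """
    d = np.outer(h, lam) + (1.0 - h)[:, None]  # (H, n)
    inv = 1.0 / d
    logdet = np.log(d).sum(axis=1)
    a = inv @ x2
    return logdet, a, inv


def _loglik_profile(
    Yt: np.ndarray, xt: np.ndarray, lam: np.ndarray, h_grid: np.ndarray, reml: bool
) -> np.ndarray:
    """Restricted (or full) log-likelihood for every gene at every grid h.

    The covariance is sigma^2 * (h K + (1-h) I) with the overall scale
    sigma^2 profiled out analytically (the FaST-LMM parameterization: h is
    the variance *fraction*, the total variance is free).  Yt: (G, n)
    rotated expression; xt: (n,) rotated intercept column.  Returns (H, G)
    log-likelihoods up to an additive constant.
    """
    n = Yt.shape[1]
    x2 = xt**2
    logdet, a, inv = _spectral_loglik_terms(h_grid, lam, x2)
    b = inv @ (xt[:, None] * Yt.T)  # (H, G): x' D^-1 y
    c = inv @ (Yt.T**2)            # (H, G): y' D^-1 y
    quad = np.clip(c - b**2 / a[:, None], 1e-300, None)
    if reml:
        dof = n - 1
        ll = -0.5 * (logdet[:, None] + np.log(a)[:, None] + dof * np.log(quad / dof))
    else:
        ll = -0.5 * (logdet[:, None] + n * np.log(quad / n))
    return ll


def _loglik_single(y_t, xt, lam, h, reml):
    return _loglik_profile(y_t[None, :], xt, lam, np.atleast_1d(float(h)), reml)[0, 0]


def estimate_heritability_many(
    Y: np.ndarray,
    K: KinshipMatrix,
    genes: Sequence[str] | None = None,
    tissue: str = "",
    reml: bool = True,
    standardize: bool = True,
) -> list[HeritabilityEstimate]:
    """Pseudo-heritability for many genes sharing one kinship eigenbasis.

    ``Y`` is genes × donors, aligned to ``K.donors``.  Each gene is scaled to
    unit sample variance (the model's normalization) unless ``standardize``
    is False.  The optimizer is a dense grid over [0, 1-1e-6] at step 0.01
    followed by bounded scalar refinement around the best grid point, with a
    flat-likelihood tie-break at h = 0.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if Y.shape[1] != K.n_donors:
        raise ValidationError(
            f"expression ({Y.shape[1]} donors) misaligned with kinship ({K.n_donors})"
        )
    if not np.isfinite(Y).all():
        bad = np.argwhere(~np.isfinite(Y))[0]
        raise ValidationError(f"non-finite expression value at gene row {bad[0]}")
    if genes is None:
        genes = [f"g{i}" for i in range(Y.shape[0])]
    if standardize:
        sd = Y.std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ValidationError("constant expression vector; cannot standardize")
        Y = Y / sd[:, None]

    U, lam = K.eigenvectors, K.eigenvalues
    Yt = Y @ U                     # rotated data, (G, n)
    xt = U.T @ np.ones(K.n_donors)

    h_grid = np.append(np.arange(0.0, 1.0, GRID_STEP), H_MAX)
    ll_grid = _loglik_profile(Yt, xt, lam, h_grid, reml)  # (H, G)
    best_idx = np.argmax(ll_grid, axis=0)

    out: list[HeritabilityEstimate] = []
    for g, gene in enumerate(genes):
        i = int(best_idx[g])
        h_best = float(h_grid[i])
        ll_best = float(ll_grid[i, g])
        lo = h_grid[max(i - 1, 0)]
        hi = h_grid[min(i + 1, len(h_grid) - 1)]
        converged = True
        if hi > lo:
            res = minimize_scalar(
                lambda h: -_loglik_single(Yt[g], xt, lam, h, reml),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-8},
            )
            converged = bool(res.success)
            if res.success and -res.fun > ll_best:
                h_best, ll_best = float(np.clip(res.x, 0.0, H_MAX)), float(-res.fun)
        # flat-likelihood tie-break: prefer the no-transformation solution
        ll_at_zero = float(ll_grid[0, g])
        if ll_best - ll_at_zero < 1e-9:
            h_best, ll_best = 0.0, ll_at_zero
        d = h_best * lam + (1.0 - h_best)
        a = float(np.sum(xt**2 / d))
        beta0 = float(np.sum(xt * Yt[g] / d) / a) if a > 0 else 0.0
        out.append(
            HeritabilityEstimate(
                gene=str(gene), tissue=tissue, h=h_best,
                intercept=beta0, loglik=ll_best, converged=converged,
            )
        )
    return out


def estimate_heritability(
    y: np.ndarray | pd.Series, K: KinshipMatrix, gene: str = "", tissue: str = "",
    reml: bool = True,
) -> HeritabilityEstimate:
    """Single-gene wrapper around :func:`estimate_heritability_many`."""
    y = np.asarray(y, dtype=float)
    return estimate_heritability_many(y[None, :], K, [gene], tissue, reml=reml)[0]


def estimate_heritability_matrix(
    expr: ExpressionMatrix, K: KinshipMatrix, reml: bool = True
) -> list[HeritabilityEstimate]:
    """Per-gene estimates for a whole tissue; kinship restricted to the
    tissue's donors (eigendecomposition recomputed for the subset)."""
    Ksub = K.subset(expr.donors) if expr.donors != K.donors else K
    return estimate_heritability_many(
        expr.values, Ksub, expr.genes, tissue=expr.tissue, reml=reml
    )
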