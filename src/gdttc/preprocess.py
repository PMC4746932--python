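"""Gene filtering and covariate/hidden-factor residualization.

Applied before any correlation work: lowly/invariantly expressed genes can
produce artificially high correlations, so a gene is removed when its
standard deviation is smaller than 20% of its max-minus-min range (and when
its variance is exactly zero, which the literal rule does not catch but
which breaks rank correlation).  Known covariates and hidden confounders
(e.g. externally computed PEER factors, or the PCA stand-in below) are
regressed out gene-by-gene and the residuals re-standardized to unit
variance, matching the mixed model's unit-total-variance normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError


@dataclass
class FilterReport:
    tissue: str
    kept: list[str]
    removed_low_variance: list[str]
    removed_zero_variance: list[str]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def filter_low_variance(
    expr: ExpressionMatrix, fraction: float = 0.2
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop genes with sd < fraction * (max - min), and zero-variance genes.

    Requires at least 3 donors.  Raises when nothing survives.
    """
    if expr.n_donors < 3:
        raise ValidationError(f"need >= 3 donors to filter, got {expr.n_donors}")
    values = expr.values
    sd = np.nanstd(values, axis=1, ddof=1)
    rng = np.nanmax(values, axis=1) - np.nanmin(values, axis=1)
    zero = sd == 0
    low = (~zero) & (sd < fraction * rng)
    keep = ~(zero | low)
    genes = np.array(expr.genes)
    report = FilterReport(
        tissue=expr.tissue,
        kept=list(genes[keep]),
        removed_low_variance=list(genes[low]),
        removed_zero_variance=list(genes[zero]),
    )
    if not keep.any():
        raise ValidationError(
            f"no genes survive the variance filter in tissue {expr.tissue!r} "
            f"({int(zero.sum())} zero-variance, {int(low.sum())} low-variance)"
        )
    return replace(expr, data=expr.data.loc[keep].copy()), report


def residualize(expr: ExpressionMatrix, factors: pd.DataFrame) -> ExpressionMatrix:
    """Least-squares residuals on intercept + factors, unit-variance rescaled.

    ``factors`` is donors × k, indexed by donor id; rows are aligned to the
    expression donors.  A rank-deficient design is rejected with the
    offending columns named.
    """
    missing = [d for d in expr.donors if d not in factors.index]
    if missing:
        raise ValidationError(f"factor table missing donors: {missing[:5]}")
    F = factors.loc[expr.donors].to_numpy(dtype=float)
    n, k = F.shape
    if k >= n:
        raise ValidationError(f"{k} factors for {n} donors; need k < n")
    X = np.column_stack([np.ones(n), F])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name collinear columns via pivoted QR: pivots beyond the rank
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        cols = ["(intercept)"] + [str(c) for c in factors.columns]
        bad = [cols[i] for i in piv[rank:]]
        raise ValidationError(f"rank-deficient factor table; collinear columns: {bad}")
    Y = expr.values  # genes x donors
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    sd = resid.std(axis=0, ddof=1)
    if (sd == 0).any():
        zero_genes = list(np.array(expr.genes)[sd == 0])
        raise ValidationError(
            f"residuals identically zero for genes {zero_genes[:5]}; "
            "these genes are fully explained by the factors"
        )
    resid = resid / sd
    data = pd.DataFrame(resid.T, index=expr.genes, columns=expr.donors)
    return replace(expr, data=data)


def estimate_hidden_factors(expr: ExpressionMatrix, k: int) -> pd.DataFrame:
    """First k principal axes of donor-space covariance of standardized
    expression — a generic stand-in for externally computed hidden-factor
    models.  Returns a donors × k table with orthonormal columns.
    """
    if k <= 0:
        raise ValidationError(f"number of hidden factors must be positive, got {k}")
    if k >= min(expr.n_genes, expr.n_donors):
        raise ValidationError(
            f"k={k} must be < min(genes, donors) = {min(expr.n_genes, expr.n_donors)}"
        )
    Y = expr.values
    sd = Y.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValidationError("constant gene present; filter before factor estimation")
    Z = (Y - Y.mean(axis=1, keepdims=True)) / sd[:, None]
    # right singular vectors = principal donor-space axes
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    return pd.DataFrame(
        vt[:k].T, index=expr.donors, columns=[f"PC{i + 1}" for i in range(k)]
    )
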