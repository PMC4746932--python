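"""Cross-tissue Spearman correlation, edge calling and permutation FDR.

An inter-tissue edge joins gene i in tissue A to gene j in tissue B (never
two genes of one tissue) when the pair is significant **both** before and
after genetic decorrelation:

    p_decorrelated < 1e-3   AND   p_original < 10^(-3.5)

(strict inequalities; the second, tighter threshold on the original data
guards against artifacts introduced by the whitening transform itself).
Significance of a Spearman coefficient r at sample size n uses the classical
t approximation t = r * sqrt((n-2) / (1-r^2)) referred to Student's t with
n - 2 degrees of freedom, two-sided.

The false discovery rate of an edge set is estimated by donor-label
permutation: tissue B's donors are shuffled relative to both the genotypes
and tissue A, heritabilities and transforms are re-estimated on the permuted
data, edges are re-called, and the FDR is the mean over permutations of
(permuted edge count / observed edge count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ValidationError
from .decorrelate import apply_transform
from .genetics import KinshipMatrix, estimate_heritability_matrix

P_DECOR_MAX = 1e-3
P_ORIG_MAX = 10.0 ** (-3.5)
MIN_SHARED_DONORS = 10


class UndefinedCorrelationError(ValueError):
    """A correlation is undefined (constant vector, n < 4)."""


def spearman_p(x, y) -> tuple[float, float, float]:
    """Spearman r with its t statistic and two-sided p-value.

    r is the Pearson correlation of average ranks; |r| = 1 maps to p = 0 by
    convention.  Requires >= 4 aligned non-missing pairs and non-constant
    vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise UndefinedCorrelationError(f"need >= 4 non-missing pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-12:  # snap float noise on perfectly monotone pairs
        r = float(np.sign(r))
    df = n - 2
    if abs(r) >= 1.0:
        return r, float(np.sign(r) * np.inf), 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(t), float(min(p, 1.0))


@dataclass(frozen=True)
class CorrelationRecord:
    gene_a: str
    tissue_a: str
    gene_b: str
    tissue_b: str
    n: int
    r_orig: float
    t_orig: float
    p_orig: float
    r_decor: float
    t_decor: float
    p_decor: float
    is_edge: bool


@dataclass
class EdgeSet:
    """Called edges for one tissue pair plus the testing totals.

    ``genes_a`` / ``genes_b`` are the tested gene universes (needed for the
    gene-to-module binomial null); they may be None on a round-trip from disk,
    in which case ``n_genes_a`` / ``n_genes_b`` carry the counts.
    """

    tissue_a: str
    tissue_b: str
    records: list[CorrelationRecord]
    n_pairs_tested: int = 0
    n_genes_a: int = 0
    n_genes_b: int = 0
    genes_a: tuple[str, ...] | None = field(default=None, repr=False)
    genes_b: tuple[str, ...] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.tissue_a == self.tissue_b:
            raise ValidationError("edge set must be bipartite across two tissues")
        if self.genes_a is not None:
            self.n_genes_a = len(self.genes_a)
        if self.genes_b is not None:
            self.n_genes_b = len(self.genes_b)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_edges(self) -> int:
        return len(self.records)

    def pair_set(self) -> set[tuple[str, str, str, str]]:
        """Unordered pair identity, for symmetry checks."""
        return {
            frozenset_key(r.gene_a, r.tissue_a, r.gene_b, r.tissue_b)
            for r in self.records
        }

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "gene_A", "tissue_A", "gene_B", "tissue_B",
            "r_orig", "p_orig", "r_decor", "p_decor", "n", "t_orig", "t_decor",
        ]
        rows = [
            (r.gene_a, r.tissue_a, r.gene_b, r.tissue_b,
             r.r_orig, r.p_orig, r.r_decor, r.p_decor, r.n, r.t_orig, r.t_decor)
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=cols)


def frozenset_key(gene_a, tissue_a, gene_b, tissue_b):
    return frozenset(((gene_a, tissue_a), (gene_b, tissue_b)))


def _rank_standardize(expr: ExpressionMatrix, donors: list[str]):
    """Rank each gene across the shared donors and scale to unit norm.

    Genes with a missing value or constant ranks over the shared donors are
    dropped (returned separately).
    """
    sub = expr.data.loc[:, donors].to_numpy(dtype=float)
    ok = np.isfinite(sub).all(axis=1)
    ranks = np.apply_along_axis(stats.rankdata, 1, sub[ok])
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(ranks, axis=1)
    nonconst = norm > 0
    Z = ranks[nonconst] / norm[nonconst][:, None]
    genes = np.array(expr.genes)[ok][nonconst]
    return Z, list(genes)


def _p_from_r(R: np.ndarray, n: int):
    df = n - 2
    R = np.clip(R, -1.0, 1.0)
    R = np.where(np.abs(R) >= 1.0 - 1e-12, np.sign(R), R)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = R * np.sqrt(df / (1.0 - R * R))
    P = np.where(np.abs(R) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(T), df))
    return T, P


def _shared_donors(a: ExpressionMatrix, b: ExpressionMatrix) -> list[str]:
    shared = [d for d in a.donors if d in set(b.donors)]
    if len(shared) < MIN_SHARED_DONORS:
        raise ValidationError(
            f"tissue pair shares only {len(shared)} donors "
            f"(< {MIN_SHARED_DONORS} required)"
        )
    return shared


def call_edges(
    orig_a: ExpressionMatrix,
    orig_b: ExpressionMatrix,
    decor_a: ExpressionMatrix,
    decor_b: ExpressionMatrix,
    p_decor_max: float = P_DECOR_MAX,
    p_orig_max: float = P_ORIG_MAX,
) -> EdgeSet:
    """Score every cross-tissue gene pair on the shared donors and apply the
    dual-threshold rule.

    Only genes present (and non-missing, non-constant) in both the original
    and decorrelated matrices of a tissue are tested; ``n`` for both p-values
    is the shared-donor count of the pair.
    """
    if orig_a.tissue == orig_b.tissue:
        raise ValidationError("edge calling requires two distinct tissues")
    shared = _shared_donors(orig_a, orig_b)
    shared_dec = [d for d in decor_a.donors if d in set(decor_b.donors)]
    if set(shared_dec) != set(shared):
        # decorrelated matrices must cover the same donors (symmetric form)
        shared_dec = shared
    n = len(shared)

    Zoa, genes_oa = _rank_standardize(orig_a, shared)
    Zob, genes_ob = _rank_standardize(orig_b, shared)
    Zda, genes_da = _rank_standardize(decor_a, shared_dec)
    Zdb, genes_db = _rank_standardize(decor_b, shared_dec)

    pos_oa = {g: i for i, g in enumerate(genes_oa)}
    pos_da = {g: i for i, g in enumerate(genes_da)}
    pos_ob = {g: i for i, g in enumerate(genes_ob)}
    pos_db = {g: i for i, g in enumerate(genes_db)}
    ga = [g for g in genes_oa if g in pos_da]
    gb = [g for g in genes_ob if g in pos_db]
    ia_o = [pos_oa[g] for g in ga]
    ia_d = [pos_da[g] for g in ga]
    ib_o = [pos_ob[g] for g in gb]
    ib_d = [pos_db[g] for g in gb]

    Ro = Zoa[ia_o] @ Zob[ib_o].T
    Rd = Zda[ia_d] @ Zdb[ib_d].T
    To, Po = _p_from_r(Ro, n)
    Td, Pd = _p_from_r(Rd, len(shared_dec))

    mask = (Pd < p_decor_max) & (Po < p_orig_max)
    records = []
    for i, j in zip(*np.nonzero(mask)):
        records.append(
            CorrelationRecord(
                gene_a=ga[i], tissue_a=orig_a.tissue,
                gene_b=gb[j], tissue_b=orig_b.tissue,
                n=n,
                r_orig=float(Ro[i, j]), t_orig=float(To[i, j]), p_orig=float(Po[i, j]),
                r_decor=float(Rd[i, j]), t_decor=float(Td[i, j]), p_decor=float(Pd[i, j]),
                is_edge=True,
            )
        )
    return EdgeSet(
        tissue_a=orig_a.tissue, tissue_b=orig_b.tissue, records=records,
        n_pairs_tested=len(ga) * len(gb),
        genes_a=tuple(ga), genes_b=tuple(gb),
    )


def significant_pairs(
    a: ExpressionMatrix, b: ExpressionMatrix, p_max: float
) -> EdgeSet:
    """Single-threshold significant pairs for one matrix pair (used by the
    decorrelation diagnostics to build before/after edge sets)."""
    if a.tissue == b.tissue:
        raise ValidationError("requires two distinct tissues")
    shared = _shared_donors(a, b)
    n = len(shared)
    Za, ga = _rank_standardize(a, shared)
    Zb, gb = _rank_standardize(b, shared)
    R = Za @ Zb.T
    T, P = _p_from_r(R, n)
    mask = P < p_max
    records = [
        CorrelationRecord(
            gene_a=ga[i], tissue_a=a.tissue, gene_b=gb[j], tissue_b=b.tissue,
            n=n, r_orig=float(R[i, j]), t_orig=float(T[i, j]), p_orig=float(P[i, j]),
            r_decor=float("nan"), t_decor=float("nan"), p_decor=float("nan"),
            is_edge=True,
        )
        for i, j in zip(*np.nonzero(mask))
    ]
    return EdgeSet(
        tissue_a=a.tissue, tissue_b=b.tissue, records=records,
        n_pairs_tested=len(ga) * len(gb), genes_a=tuple(ga), genes_b=tuple(gb),
    )


@dataclass
class PermutationFdr:
    observed_edges: int
    permuted_counts: list[int]
    fdr: float  # NaN when observed_edges == 0 (undefined)

    def to_dict(self) -> dict:
        return {
            "observed_edges": self.observed_edges,
            "permuted_counts": list(self.permuted_counts),
            "fdr": self.fdr,
        }


def permutation_fdr(
    orig_a: ExpressionMatrix,
    orig_b: ExpressionMatrix,
    kinship: KinshipMatrix,
    estimates_a=None,
    estimates_b=None,
    n_perm: int = 5,
    seed: int = 0,
    p_decor_max: float = P_DECOR_MAX,
    p_orig_max: float = P_ORIG_MAX,
    form: str = "symmetric_sqrt",
) -> PermutationFdr:
    """Donor-label-permutation FDR for one tissue pair.

    Tissue B's donor labels are permuted relative to both the genotypes and
    tissue A; heritability and the transform D are re-estimated on the
    permuted data before edges are re-called.  FDR is the mean over
    permutations of (permuted edge count / observed edge count); when no edge
    is observed the FDR is undefined and reported as NaN.
    """
    if n_perm <= 0:
        raise ValueError(f"n_perm must be positive, got {n_perm}")
    if estimates_a is None:
        estimates_a = estimate_heritability_matrix(orig_a, kinship)
    if estimates_b is None:
        estimates_b = estimate_heritability_matrix(orig_b, kinship)
    decor_a = apply_transform(orig_a, estimates_a, kinship, form=form)
    decor_b = apply_transform(orig_b, estimates_b, kinship, form=form)
    observed = call_edges(
        orig_a, orig_b, decor_a, decor_b, p_decor_max, p_orig_max
    ).n_edges
    if observed == 0:
        return PermutationFdr(observed_edges=0, permuted_counts=[], fdr=float("nan"))

    rng = np.random.default_rng(seed)
    counts = []
    donors_b = orig_b.donors
    for _ in range(n_perm):
        perm = rng.permutation(len(donors_b))
        # relabel tissue B's columns with a shuffled donor ordering
        perm_data = pd.DataFrame(
            orig_b.data.to_numpy(), index=orig_b.genes,
            columns=[donors_b[i] for i in perm],
        )
        perm_b = ExpressionMatrix(perm_data, tissue=orig_b.tissue)
        est_perm = estimate_heritability_matrix(perm_b, kinship)
        decor_perm = apply_transform(perm_b, est_perm, kinship, form=form)
        es = call_edges(orig_a, perm_b, decor_a, decor_perm, p_decor_max, p_orig_max)
        counts.append(es.n_edges)
    fdr = float(np.mean([c / observed for c in counts]))
    return PermutationFdr(observed_edges=observed, permuted_counts=counts, fdr=fdr)
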