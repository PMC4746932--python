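"""Core in-memory containers shared across the pipeline.

The two workhorses are :class:`ExpressionMatrix` (one tissue's genes × donors
table, tagged as original or genetically decorrelated) and
:class:`GenotypeMatrix` (donors × SNPs dosages with per-SNP alternate-allele
frequencies, the source for kinship estimation).  Both are thin, validated
wrappers around :class:`pandas.DataFrame` so that every downstream stage can
rely on unique, aligned identifier indexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input violates a structural contract (duplicate ids, bad coding...)."""


class FormatError(ValueError):
    """On-disk artifact is malformed (non-numeric cell, short line...)."""


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise ValidationError(f"duplicate {what} identifier(s): {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes × donors expression values for a single tissue.

    Parameters
    ----------
    data
        DataFrame indexed by gene identifiers with donor identifiers as
        columns.  Values are covariate-adjusted expression levels; missing
        values are carried as NaN and handled downstream (a gene with a
        missing value is dropped for the affected tissue pair).
    tissue
        Tissue label.
    decorrelated
        True once the kinship-based whitening transform has been applied.
    """

    data: pd.DataFrame
    tissue: str = ""
    decorrelated: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "donor")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def donors(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_donors(self) -> int:
        return self.data.shape[1]

    def subset_donors(self, donors: Sequence[str]) -> "ExpressionMatrix":
        missing = [d for d in donors if d not in self.data.columns]
        if missing:
            raise ValidationError(f"donors absent from tissue {self.tissue!r}: {missing[:5]}")
        return replace(self, data=self.data.loc[:, list(donors)].copy())

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ValidationError(f"genes absent from tissue {self.tissue!r}: {missing[:5]}")
        return replace(self, data=self.data.loc[list(genes)].copy())


@dataclass
class GenotypeMatrix:
    """Donors × SNPs dosage matrix coded 0/1/2 (missing entries imputed).

    ``allele_freq`` holds the per-SNP alternate-allele frequency ``p_l``
    computed from non-missing entries *before* imputation.  Monomorphic SNPs
    (``p_l`` of 0 or 1) have already been dropped; their count is kept in
    ``n_monomorphic_dropped``.  ``raw`` optionally retains the pre-imputation
    integer dosages (used by the simulator's VCF writer).
    """

    data: pd.DataFrame
    allele_freq: pd.Series
    n_monomorphic_dropped: int = 0
    raw: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "donor")
        _check_unique(self.data.columns, "SNP")
        if list(self.allele_freq.index) != list(self.data.columns):
            raise ValidationError("allele frequencies misaligned with SNP columns")

    @property
    def donors(self) -> list[str]:
        return list(self.data.index)

    @property
    def snps(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_snps(self) -> int:
        return self.data.shape[1]


def build_genotype_matrix(
    dosages: pd.DataFrame, raw: pd.DataFrame | None = None
) -> GenotypeMatrix:
    """Finalize a donors × SNPs dosage table into a :class:`GenotypeMatrix`.

    Computes per-SNP alternate-allele frequencies over non-missing donors,
    drops monomorphic SNPs (p_l in {0, 1}, including all-missing columns) and
    mean-imputes remaining missing entries.  Raises if no SNP survives.
    """
    values = dosages.to_numpy(dtype=float)
    bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"genotype entry not in {{0,1,2,missing}} at donor "
            f"{dosages.index[r]!r}, SNP {dosages.columns[c]!r}"
        )
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isnan(values), np.nan, values), axis=0)
    freq = mean / 2.0
    keep = np.isfinite(freq) & (freq > 0.0) & (freq < 1.0)
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValidationError("no polymorphic SNPs remain after filtering")
    values = values[:, keep]
    mean = mean[keep]
    # mean imputation of missing genotypes
    idx = np.where(np.isnan(values))
    values[idx] = mean[idx[1]]
    cols = dosages.columns[keep]
    data = pd.DataFrame(values, index=dosages.index, columns=cols)
    if raw is not None:
        raw = raw.loc[:, cols]
    return GenotypeMatrix(
        data=data,
        allele_freq=pd.Series(mean / 2.0, index=cols, name="p"),
        n_monomorphic_dropped=n_dropped,
        raw=raw,
    )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT contents); members de-duplicated on load."""

    sets: dict[str, GeneSet]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        sets = {}
        for name, genes in mapping.items():
            uniq = tuple(dict.fromkeys(str(g) for g in genes if g))
            if not uniq:
                raise ValidationError(f"gene set {name!r} is empty")
            sets[name] = GeneSet(name=name, description="", genes=uniq)
        return cls(sets=sets)
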