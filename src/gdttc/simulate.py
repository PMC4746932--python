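"""Seeded synthetic multi-tissue cohorts with known ground truth.

The generator emulates the data model the pipeline assumes: donors carry SNP
genotypes that induce a kinship structure (families share a parental
haplotype pool, so within-family kinship is elevated); each gene's
expression is a heritable component u ~ N(0, h K) plus independent noise
N(0, (1-h) I), with total variance one; tissues share only a subset of
donors; and non-genetic cross-tissue signal is planted by adding a shared
latent factor to one source gene in the first tissue and to a module of
genes in the second tissue, scaled so the expected pairwise correlation is
``signal_strength``.  The planted mechanism is deliberately additive and
non-genetic — it is exactly the kind of inter-tissue signal the
decorrelation step must *retain*.

Every random draw flows from the single config seed, so equal configs give
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GenotypeMatrix,
    ValidationError,
    build_genotype_matrix,
)
from .genetics import compute_kinship


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a small multi-tissue expression cohort: 150 donors
    genotyped at 1000 independent SNPs, two tissues of 120 genes with
    per-gene heritabilities uniform on [0, 0.8), one planted module of 30
    genes at pairwise correlation 0.5, and 80% donor overlap per tissue.
    ``n_families=None`` means every donor is unrelated (its own family).
    """

    n_donors: int = 150
    n_snps: int = 1000
    n_tissues: int = 2
    genes_per_tissue: int = 120
    heritability_range: tuple[float, float] = (0.0, 0.8)
    n_planted_modules: int = 1
    module_size: int = 30
    signal_strength: float = 0.5
    donor_overlap_fraction: float = 0.8
    seed: int = 0
    n_families: Optional[int] = None
    share_genetic_across_tissues: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.heritability_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValidationError(f"heritability_range must lie in [0,1): {lo, hi}")
        if self.module_size > self.genes_per_tissue:
            raise ValidationError("module_size exceeds genes_per_tissue")
        if not (0.0 < self.donor_overlap_fraction <= 1.0):
            raise ValidationError("donor_overlap_fraction must be in (0, 1]")
        if not (0.0 <= self.signal_strength < 1.0):
            raise ValidationError("signal_strength must be in [0, 1)")
        if self.n_planted_modules > 0 and self.signal_strength > 0 and self.n_tissues < 2:
            raise ValidationError("planted modules require at least two tissues")
        if self.n_planted_modules * self.module_size > self.genes_per_tissue:
            raise ValidationError("planted modules exceed the target tissue's genes")


@dataclass(frozen=True)
class PlantedModule:
    source_gene: str
    source_tissue: str
    target_tissue: str
    target_genes: tuple[str, ...]


@dataclass
class CohortTruth:
    heritability: dict[str, dict[str, float]]  # tissue -> gene -> true h
    planted: list[PlantedModule]
    drivers: dict[str, set] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "heritability": self.heritability,
            "planted": [
                {
                    "source_gene": p.source_gene,
                    "source_tissue": p.source_tissue,
                    "target_tissue": p.target_tissue,
                    "target_genes": list(p.target_genes),
                }
                for p in self.planted
            ],
            "drivers": {g: sorted(d) for g, d in self.drivers.items()},
        }


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    expression: dict[str, ExpressionMatrix]
    truth: CohortTruth
    config: SimulationConfig

    def __post_init__(self) -> None:
        for planted in self.truth.planted:
            src = self.expression[planted.source_tissue]
            tgt = self.expression[planted.target_tissue]
            if planted.source_gene not in src.data.index:
                raise ValidationError("truth source gene missing from expression")
            missing = [g for g in planted.target_genes if g not in tgt.data.index]
            if missing:
                raise ValidationError(f"truth target genes missing: {missing[:5]}")


def simulate_genotypes(
    n_donors: int,
    n_snps: int,
    n_families: Optional[int] = None,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> GenotypeMatrix:
    """Family-structured SNP dosages.

    SNP alternate-allele frequencies are uniform on [0.05, 0.5].  Donors are
    grouped round-robin into families; each family has two latent parents
    (two haplotypes each, Bernoulli(p) per SNP) and every donor inherits one
    allele per SNP from each parent, so realized kinship is elevated within
    families.  ``n_families=None`` (or == n_donors) yields unrelated donors.
    """
    if n_snps < 10:
        raise ValidationError(f"need >= 10 SNPs for a stable kinship, got {n_snps}")
    if n_families is None:
        n_families = n_donors
    if not (1 <= n_families <= n_donors):
        raise ValidationError("n_families must be between 1 and n_donors")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.5, size=n_snps)
    fam = np.arange(n_donors) % n_families
    # parental haplotypes: (family, parent in {0,1}, haplotype in {0,1}, snp)
    parents = (rng.random((n_families, 2, 2, n_snps)) < p).astype(np.int8)
    pick = rng.integers(0, 2, size=(n_donors, 2, n_snps))
    donor_idx = np.arange(n_donors)
    maternal = parents[fam, 0, :, :][donor_idx[:, None], pick[:, 0, :], np.arange(n_snps)]
    paternal = parents[fam, 1, :, :][donor_idx[:, None], pick[:, 1, :], np.arange(n_snps)]
    G = (maternal + paternal).astype(np.int8)
    donors = [f"D{i:04d}" for i in range(n_donors)]
    snps = [f"S{i:05d}" for i in range(n_snps)]
    raw = pd.DataFrame(G, index=donors, columns=snps)
    return build_genotype_matrix(raw.astype(float), raw=raw)


def simulate_expression(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedCohort:
    """Heritable expression plus planted non-genetic cross-tissue modules."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    K = compute_kinship(genotypes)
    n = K.n_donors
    try:
        L = np.linalg.cholesky(K.values + 1e-8 * np.eye(n))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by jitter
        raise ValidationError("kinship not positive semi-definite after jitter") from exc

    tissues = [f"T{t + 1}" for t in range(config.n_tissues)]
    genes = [f"G{i:04d}" for i in range(config.genes_per_tissue)]
    lo, hi = config.heritability_range

    shared_h = shared_u = None
    if config.share_genetic_across_tissues:
        shared_h = rng.uniform(lo, hi, size=config.genes_per_tissue) if hi > lo else np.full(config.genes_per_tissue, lo)
        shared_u = L @ rng.standard_normal((n, config.genes_per_tissue))

    herit: dict[str, dict[str, float]] = {}
    expr_full: dict[str, np.ndarray] = {}
    for t in tissues:
        if config.share_genetic_across_tissues:
            h = shared_h
            u = shared_u
        else:
            h = rng.uniform(lo, hi, size=config.genes_per_tissue) if hi > lo else np.full(config.genes_per_tissue, lo)
            u = L @ rng.standard_normal((n, config.genes_per_tissue))
        eps = rng.standard_normal((n, config.genes_per_tissue))
        Y = (np.sqrt(h) * u + np.sqrt(1.0 - h) * eps).T  # genes x donors
        herit[t] = {g: float(hv) for g, hv in zip(genes, h)}
        expr_full[t] = Y

    planted: list[PlantedModule] = []
    drivers: dict[str, set] = {}
    if config.share_genetic_across_tissues:
        drivers = {g: {g} for g in genes}
    if config.n_planted_modules > 0 and config.signal_strength > 0 and config.n_tissues >= 2:
        src_tissue, tgt_tissue = tissues[0], tissues[1]
        alpha = np.sqrt(config.signal_strength / (1.0 - config.signal_strength))
        scale = np.sqrt(1.0 + alpha**2)
        order = rng.permutation(config.genes_per_tissue)
        used = 0
        for _ in range(config.n_planted_modules):
            src_idx = int(order[used]); used += 1
            tgt_idx = [int(i) for i in order[used:used + config.module_size]]
            used += config.module_size
            f = rng.standard_normal(n)
            expr_full[src_tissue][src_idx] = (
                expr_full[src_tissue][src_idx] + alpha * f
            ) / scale
            for i in tgt_idx:
                expr_full[tgt_tissue][i] = (expr_full[tgt_tissue][i] + alpha * f) / scale
            planted.append(
                PlantedModule(
                    source_gene=genes[src_idx],
                    source_tissue=src_tissue,
                    target_tissue=tgt_tissue,
                    target_genes=tuple(genes[i] for i in tgt_idx),
                )
            )

    donors = np.array(genotypes.donors)
    n_keep = max(2, int(round(config.donor_overlap_fraction * n)))
    expression: dict[str, ExpressionMatrix] = {}
    for t in tissues:
        keep = np.sort(rng.choice(n, size=n_keep, replace=False))
        data = pd.DataFrame(expr_full[t][:, keep], index=genes, columns=donors[keep])
        expression[t] = ExpressionMatrix(data, tissue=t)

    truth = CohortTruth(heritability=herit, planted=planted, drivers=drivers)
    return SimulatedCohort(
        genotypes=genotypes, expression=expression, truth=truth, config=config
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Genotypes + expression from a single seed."""
    rng = np.random.default_rng(config.seed)
    gt = simulate_genotypes(
        config.n_donors, config.n_snps, config.n_families, rng=rng
    )
    return simulate_expression(gt, config, rng=rng)
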