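"""Configuration-driven end-to-end orchestration.

Stages per run: variance filter -> residualization -> kinship -> per-gene
pseudo-heritability -> whitening -> dual-threshold edge calling (every
unordered tissue pair) -> permutation FDR -> gene-to-module detection (both
directions of every pair) -> optional gene-set enrichment.  All outputs are
plain TSV/JSON; re-running with an identical config and seed reproduces them
byte for byte.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field as dc_field
from itertools import combinations
from pathlib import Path

import yaml

from . import io_formats
from .asymmetry import detect_gene_to_module
from .containers import ValidationError
from .decorrelate import apply_transform
from .enrich import hypergeom_enrich, ontology_levels
from .genetics import compute_kinship, estimate_heritability_matrix
from .network import P_DECOR_MAX, P_ORIG_MAX, call_edges, permutation_fdr

logger = logging.getLogger("gdttc")


def n_unordered_pairs(n_tissues: int) -> int:
    """T tissues give T(T-1)/2 unordered tissue pairs."""
    if n_tissues < 0:
        raise ValueError("tissue count cannot be negative")
    return n_tissues * (n_tissues - 1) // 2


@dataclass
class RunConfig:
    """Validated run description (YAML on disk)."""

    tissues: list[dict]                      # each: {label, expression, factors?}
    genotypes: str
    output_dir: str
    p_decor_max: float = P_DECOR_MAX
    p_orig_max: float = P_ORIG_MAX
    filter_fraction: float = 0.2
    k_hidden: int = 0
    n_perm: int = 5
    min_size: int = 10
    ratio: float = 0.1
    alpha: float = 0.05
    seed: int = 0
    form: str = "symmetric_sqrt"
    centering: str = "standard"
    gmt: str | None = None
    obo: str | None = None
    go_level: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        errors = []
        if len(self.tissues) < 2:
            errors.append("need at least two tissues")
        labels = [t.get("label") for t in self.tissues]
        if len(set(labels)) != len(labels):
            errors.append("tissue labels must be unique")
        paths = [self.genotypes] + [t.get("expression") for t in self.tissues]
        paths += [t["factors"] for t in self.tissues if t.get("factors")]
        if self.gmt:
            paths.append(self.gmt)
        if self.obo:
            paths.append(self.obo)
        for p in paths:
            if not p or not Path(p).exists():
                errors.append(f"missing input path: {p}")
        for name in ("p_decor_max", "p_orig_max", "filter_fraction", "ratio", "alpha"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        if errors:
            raise ValidationError("; ".join(errors))


@dataclass
class RunReport:
    n_tissues: int
    n_unordered_pairs: int
    seed: int
    stages: dict = dc_field(default_factory=dict)
    tissues: dict = dc_field(default_factory=dict)
    pairs: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_tissues": self.n_tissues,
            "n_unordered_pairs": self.n_unordered_pairs,
            "seed": self.seed,
            "stages": self.stages,
            "tissues": self.tissues,
            "pairs": self.pairs,
        }


class StageFailure(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage for every tissue pair; see module docstring."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = [t["label"] for t in config.tissues]
    report = RunReport(
        n_tissues=len(labels),
        n_unordered_pairs=n_unordered_pairs(len(labels)),
        seed=config.seed,
    )

    def stage(name):
        logger.info("stage %s", name)
        report.stages[name] = {"started": True}
        return time.time()

    def done(name, t0, **info):
        report.stages[name].update(elapsed_s=round(time.time() - t0, 3), **info)

    try:
        t0 = stage("genotypes")
        gt = io_formats.read_genotypes(config.genotypes)
        kin = compute_kinship(gt, centering=config.centering)
        done("genotypes", t0, n_donors=len(gt.donors), n_snps=gt.n_snps,
             n_monomorphic_dropped=gt.n_monomorphic_dropped)
    except Exception as exc:
        raise StageFailure("genotypes", exc) from exc

    orig, decor = {}, {}
    for tcfg in config.tissues:
        label = tcfg["label"]
        try:
            t0 = stage(f"preprocess:{label}")
            expr = io_formats.read_expression(tcfg["expression"], tissue=label)
            n_in = expr.n_genes
            from .preprocess import estimate_hidden_factors, filter_low_variance, residualize

            expr, freport = filter_low_variance(expr, fraction=config.filter_fraction)
            if tcfg.get("factors"):
                factors = io_formats.read_covariates(tcfg["factors"])
                expr = residualize(expr, factors)
            elif config.k_hidden > 0:
                factors = estimate_hidden_factors(expr, config.k_hidden)
                expr = residualize(expr, factors)
            done(f"preprocess:{label}", t0, genes_in=n_in, genes_kept=expr.n_genes,
                 donors=expr.n_donors,
                 removed_low_variance=len(freport.removed_low_variance),
                 removed_zero_variance=len(freport.removed_zero_variance))

            t0 = stage(f"decorrelate:{label}")
            estimates = estimate_heritability_matrix(expr, kin)
            io_formats.write_heritability(estimates, outdir / f"heritability.{label}.tsv")
            decor[label] = apply_transform(expr, estimates, kin, form=config.form)
            orig[label] = expr
            report.tissues[label] = {
                "genes": expr.n_genes,
                "donors": expr.n_donors,
                "mean_h": sum(e.h for e in estimates) / len(estimates),
            }
            done(f"decorrelate:{label}", t0)
        except StageFailure:
            raise
        except Exception as exc:
            io_formats.write_json(report.to_dict(), outdir / "summary.json")
            raise StageFailure(f"preprocess/decorrelate:{label}", exc) from exc

    gene_sets = levels = None
    if config.gmt:
        gene_sets = io_formats.read_gmt(config.gmt)
        if config.obo:
            levels = ontology_levels(io_formats.read_obo(config.obo))

    for idx, (a, b) in enumerate(combinations(labels, 2)):
        pair_key = f"{a}--{b}"
        try:
            t0 = stage(f"edges:{pair_key}")
            edges = call_edges(
                orig[a], orig[b], decor[a], decor[b],
                p_decor_max=config.p_decor_max, p_orig_max=config.p_orig_max,
            )
            io_formats.write_edges(edges, outdir / f"edges.{pair_key}.tsv")
            pair_info = {
                "n_edges": edges.n_edges,
                "n_pairs_tested": edges.n_pairs_tested,
            }
            done(f"edges:{pair_key}", t0)

            if config.n_perm > 0:
                t0 = stage(f"fdr:{pair_key}")
                fdr_seed = config.seed + 1009 * (idx + 1)
                fdr = permutation_fdr(
                    orig[a], orig[b], kin,
                    n_perm=config.n_perm, seed=fdr_seed,
                    p_decor_max=config.p_decor_max, p_orig_max=config.p_orig_max,
                    form=config.form,
                )
                pair_info["fdr"] = fdr.to_dict()
                pair_info["fdr_seed"] = fdr_seed
                done(f"fdr:{pair_key}", t0)

            t0 = stage(f"modules:{pair_key}")
            modules = {}
            for src, tgt in ((a, b), (b, a)):
                mods = detect_gene_to_module(
                    edges, src, tgt, min_size=config.min_size, ratio=config.ratio
                )
                modules[f"{src}->{tgt}"] = mods
                io_formats.write_modules_json(mods, outdir / f"modules.{src}--{tgt}.json")
                pair_info[f"n_modules_{src}->{tgt}"] = len(mods)
            done(f"modules:{pair_key}", t0)

            if gene_sets is not None:
                t0 = stage(f"enrich:{pair_key}")
                enr_payload = {}
                for direction, mods in modules.items():
                    tgt = direction.split("->")[1]
                    universe = orig[tgt].genes
                    enr_payload[direction] = [
                        {
                            "source": m.source_gene,
                            "results": [
                                r.to_dict()
                                for r in hypergeom_enrich(
                                    m.members, gene_sets, universe,
                                    level_filter=config.go_level, levels=levels,
                                    alpha=config.alpha,
                                )
                            ],
                        }
                        for m in mods
                    ]
                io_formats.write_json(enr_payload, outdir / f"enrichment.{pair_key}.json")
                done(f"enrich:{pair_key}", t0)

            report.pairs[pair_key] = pair_info
        except StageFailure:
            raise
        except Exception as exc:
            io_formats.write_json(report.to_dict(), outdir / "summary.json")
            raise StageFailure(pair_key, exc) from exc

    io_formats.write_json(report.to_dict(), outdir / "summary.json")
    return report
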