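"""Readers and writers for every on-disk artifact the pipeline touches.

Formats: tab-delimited UTF-8 tables ('.' decimal) for expression, genotype
dosages, covariates, kinship and edges; VCF 4.x for genotypes; GMT for gene
sets; OBO 1.2 for ontologies; JSON for module and enrichment reports.  All
parsers validate and reject rather than silently coerce: duplicate
identifiers, non-numeric cells and malformed lines raise with the offending
location named.  Writers serialize floats with enough digits that
read-after-write reproduces values to better than 1e-6.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .containers import (
    ExpressionMatrix,
    FormatError,
    GeneSet,
    GeneSetCollection,
    GenotypeMatrix,
    ValidationError,
    build_genotype_matrix,
)
from .genetics import KinshipMatrix
from .network import CorrelationRecord, EdgeSet

logger = logging.getLogger("gdttc")

_NA_MARKERS = {"", "NA", "NaN", "nan", "na"}
_FLOAT_FMT = "%.10g"


def _read_table_lines(path) -> list[list[str]]:
    with open(path, "r", encoding="utf-8") as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.strip() != ""]


def _parse_numeric_table(path, what: str) -> pd.DataFrame:
    """TSV with a string id column and numeric body; NA markers allowed."""
    rows = _read_table_lines(path)
    if len(rows) < 2:
        raise FormatError(f"{what} table {path} has no data rows")
    header = rows[0]
    col_ids = header[1:]
    if not col_ids:
        raise FormatError(f"{what} table {path} has no value columns")
    if len(set(col_ids)) != len(col_ids):
        dups = sorted({c for c in col_ids if col_ids.count(c) > 1})
        raise ValidationError(f"duplicate column identifier(s) in {path}: {dups[:5]}")
    row_ids = []
    body = np.empty((len(rows) - 1, len(col_ids)))
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(
                f"{what} table {path} line {r}: expected {len(header)} fields, got {len(row)}"
            )
        row_ids.append(row[0])
        for c, cell in enumerate(row[1:]):
            if cell in _NA_MARKERS:
                body[r - 2, c] = np.nan
                continue
            try:
                body[r - 2, c] = float(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric value {cell!r} at row {row[0]!r}, "
                    f"column {col_ids[c]!r} of {path}"
                ) from None
    if len(set(row_ids)) != len(row_ids):
        dups = sorted({g for g in row_ids if row_ids.count(g) > 1})
        raise ValidationError(f"duplicate row identifier(s) in {path}: {dups[:5]}")
    return pd.DataFrame(body, index=row_ids, columns=col_ids)


def read_expression(path, tissue: str = "") -> ExpressionMatrix:
    """Genes × donors expression TSV; first column gene ids, header donor ids.

    Missing values ('NA', empty) are carried as NaN and flagged downstream.
    """
    df = _parse_numeric_table(path, "expression")
    return ExpressionMatrix(df, tissue=tissue or Path(str(path)).stem)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="gene", na_rep="NA")


def read_covariates(path) -> pd.DataFrame:
    """Donors × factors numeric TSV (first column donor ids)."""
    return _parse_numeric_table(path, "covariate")


def write_covariates(factors: pd.DataFrame, path) -> None:
    factors.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="donor")


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, format: str = "auto") -> GenotypeMatrix:
    """Donor genotypes from VCF (biallelic SNPs) or a donors × SNPs 0/1/2 TSV.

    Per-SNP alternate-allele frequencies are computed from non-missing
    entries, missing genotypes are imputed to the SNP mean and monomorphic
    SNPs dropped (count logged).  Raises when no SNP remains.
    """
    path = str(path)
    if format == "auto":
        format = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if format == "vcf":
        gt = _read_genotypes_vcf(path)
    elif format == "tsv":
        df = _parse_numeric_table(path, "genotype")
        gt = build_genotype_matrix(df, raw=df)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if gt.n_monomorphic_dropped:
        logger.info(
            "dropped %d monomorphic SNP(s) from %s", gt.n_monomorphic_dropped, path
        )
    return gt


def _read_genotypes_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    donors = list(vcf.samples)
    ids, cols = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        g = var.gt_types.astype(float)
        dosage = np.select([g == 0, g == 1, g == 3], [0.0, 1.0, 2.0], default=np.nan)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        cols.append(dosage)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic/non-SNP record(s) in {path}")
    if not cols:
        raise ValidationError(f"no biallelic SNP records found in {path}")
    df = pd.DataFrame(np.column_stack(cols), index=donors, columns=ids)
    return build_genotype_matrix(df, raw=df)


def write_genotypes_tsv(gt: GenotypeMatrix, path, raw: bool = True) -> None:
    """Write dosages (pre-imputation integers when available and ``raw``)."""
    df = gt.raw if (raw and gt.raw is not None) else gt.data
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="donor", na_rep="NA")


def write_genotypes_vcf(gt: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with GT fields, one synthetic chromosome."""
    raw = gt.raw if gt.raw is not None else gt.data.round()
    codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gt.donors)
            + "\n"
        )
        for j, snp in enumerate(raw.columns):
            col = raw.iloc[:, j]
            gts = [
                "./." if pd.isna(v) else codes[int(v)]
                for v in col
            ]
            fh.write(
                f"1\t{j + 1}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# kinship


def write_kinship(K: KinshipMatrix, path) -> None:
    K.to_frame().to_csv(path, sep="\t", float_format="%.12g", index_label="donor")


def read_kinship(path) -> KinshipMatrix:
    df = _parse_numeric_table(path, "kinship")
    if list(df.index) != list(df.columns):
        raise ValidationError(f"kinship table {path} rows and columns disagree")
    return KinshipMatrix(df.to_numpy(), list(df.index))


def write_heritability(estimates, path) -> None:
    rows = [(e.gene, e.h, e.loglik, e.converged) for e in estimates]
    pd.DataFrame(rows, columns=["gene", "h", "loglik", "converged"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_heritability(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns or "h" not in df.columns:
        raise FormatError(f"heritability table {path} needs 'gene' and 'h' columns")
    return dict(zip(df["gene"].astype(str), df["h"].astype(float)))


# ---------------------------------------------------------------------------
# gene sets and ontologies


def read_gmt(path) -> GeneSetCollection:
    """Standard GMT: name <tab> description <tab> member genes...

    Empty sets and duplicate set names are rejected; trailing empty fields
    and duplicate members are dropped.
    """
    sets: dict[str, GeneSet] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT {path} line {lineno}: expected >= 3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g != ""))
            if not genes:
                raise ValidationError(f"GMT {path} line {lineno}: set {name!r} is empty")
            if name in sets:
                raise ValidationError(f"GMT {path} line {lineno}: duplicate set {name!r}")
            sets[name] = GeneSet(name=name, description=desc, genes=genes)
    return GeneSetCollection(sets=sets)


def read_obo(path) -> nx.DiGraph:
    """Ontology as a DAG of is_a edges (child -> parent).

    Obsolete terms are excluded; relationships other than is_a (e.g.
    part_of) are ignored, since the level definition presumes the single
    is_a hierarchy.  A cyclic ontology is a fatal validation error.
    """
    multi = obonet.read_obo(path, ignore_obsolete=True)
    graph = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        graph.add_node(node, **{k: data[k] for k in ("name", "namespace") if k in data})
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValidationError(f"ontology contains an is_a cycle: {cycle[:3]}...")
    return graph


# ---------------------------------------------------------------------------
# edges and modules

_EDGE_COLUMNS = [
    "gene_A", "tissue_A", "gene_B", "tissue_B",
    "r_orig", "p_orig", "r_decor", "p_decor", "n", "t_orig", "t_decor",
]


def write_edges(edges: EdgeSet, path) -> None:
    """Edge TSV with a metadata comment line; read-back equals input."""
    meta = (
        f"# gdttc-edges\ttissue_a={edges.tissue_a}\ttissue_b={edges.tissue_b}"
        f"\tn_pairs_tested={edges.n_pairs_tested}"
        f"\tn_genes_a={edges.n_genes_a}\tn_genes_b={edges.n_genes_b}\n"
    )
    df = edges.to_frame()[_EDGE_COLUMNS]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(meta)
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA")


def read_edges(path) -> EdgeSet:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# gdttc-edges"):
            raise FormatError(f"{path} is not a gdttc edge file")
        meta = dict(
            item.split("=", 1) for item in first.strip().split("\t")[1:]
        )
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    records = [
        CorrelationRecord(
            gene_a=str(row.gene_A), tissue_a=str(row.tissue_A),
            gene_b=str(row.gene_B), tissue_b=str(row.tissue_B),
            n=int(row.n),
            r_orig=float(row.r_orig), t_orig=float(row.t_orig), p_orig=float(row.p_orig),
            r_decor=float(row.r_decor), t_decor=float(row.t_decor),
            p_decor=float(row.p_decor),
            is_edge=True,
        )
        for row in df.itertuples()
    ]
    return EdgeSet(
        tissue_a=meta["tissue_a"], tissue_b=meta["tissue_b"], records=records,
        n_pairs_tested=int(meta.get("n_pairs_tested", 0)),
        n_genes_a=int(meta.get("n_genes_a", 0)),
        n_genes_b=int(meta.get("n_genes_b", 0)),
    )


def write_modules_json(modules: Iterable, path) -> None:
    payload = [m.to_dict() for m in modules]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
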