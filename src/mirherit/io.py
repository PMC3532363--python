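"""Readers and writers for the on-disk formats.

Everything is plain text: tab-separated tables with '#'-prefixed comment
headers (seed and provenance recorded there), GMT for target sets (set
name, class tag in the description field, then gene ids), VCF 4.2 for
genotypes (GT only, ./. for missing, region gene as an INFO tag). Missing
values in tables are written as "NA". Writers emit deterministic byte
streams so that a write → read → write cycle is bit-identical.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    CONVENTIONAL,
    MIRTRON,
    ExpressionMatrix,
    GenotypeMatrix,
    TargetSet,
    TargetSetCollection,
    TrioTable,
)
from .exceptions import ParameterError

NA = "NA"


def _write_table(df: pd.DataFrame, path, comments: Sequence[str] = (), index_label=None) -> None:
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", na_rep=NA, index_label=index_label, lineterminator="\n")


def _read_table(path, index_col=0) -> pd.DataFrame:
    # round_trip parsing so write -> read -> write is bit-identical
    return pd.read_csv(
        path, sep="\t", comment="#", index_col=index_col, na_values=[NA],
        float_precision="round_trip",
    )


# -- expression ---------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, path, comments: Sequence[str] = ()) -> None:
    _write_table(expr.values, path, comments, index_label="gene_id")


def read_expression(path, sample_meta: pd.DataFrame) -> ExpressionMatrix:
    return ExpressionMatrix(_read_table(path), sample_meta)


def write_matrix(df: pd.DataFrame, path, comments: Sequence[str] = (), index_label="id") -> None:
    _write_table(df, path, comments, index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return _read_table(path)


# -- sample metadata and trios ------------------------------------------------

def write_sample_meta(meta: pd.DataFrame, path, comments: Sequence[str] = ()) -> None:
    _write_table(meta[["population", "role"]], path, comments, index_label="sample_id")


def read_sample_meta(path) -> pd.DataFrame:
    return _read_table(path)


def write_trios(trios: TrioTable, path, comments: Sequence[str] = ()) -> None:
    _write_table(trios.table.set_index("trio_id"), path, comments, index_label="trio_id")


def read_trios(path) -> TrioTable:
    return TrioTable(_read_table(path).reset_index())


# -- GMT ----------------------------------------------------------------------

def write_gmt(targets: TargetSetCollection, path, comments: Sequence[str] = ()) -> None:
    with open(path, "w", newline="\n") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        for ts in targets:
            genes = "\t".join(sorted(ts.genes))
            fh.write(f"{ts.mirna_id}\t{ts.mirna_class}|{ts.provenance}\t{genes}\n")


def read_gmt(path) -> TargetSetCollection:
    sets = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParameterError(f"GMT line {line_no}: fewer than 3 fields")
            name, desc = fields[0], fields[1]
            klass, _, provenance = desc.partition("|")
            if klass not in (CONVENTIONAL, MIRTRON):
                klass, provenance = CONVENTIONAL, desc
            sets.append(
                TargetSet(name, frozenset(fields[2:]), klass, provenance or "unknown")
            )
    return TargetSetCollection(sets)


# -- VCF ----------------------------------------------------------------------

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(geno: GenotypeMatrix, path, comments: Sequence[str] = ()) -> None:
    meta = geno.meta
    samples = list(geno.sample_ids)
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in comments:
            fh.write(f"##comment={c}\n")
        for chrom in pd.unique(meta.loc[geno.snp_ids, "chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Mapped region gene">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for snp in geno.snp_ids:
            row = meta.loc[snp]
            gene = row.get("region_gene")
            info = f"GENE={gene}" if pd.notna(gene) and gene is not None else "."
            gts = "\t".join(
                "./." if np.isnan(v) else _GT[v] for v in geno.codes.loc[snp].to_numpy()
            )
            ref = row.get("ref", "A")
            alt = row.get("alt", "G")
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, rows, meta_rows = [], [], []
    for variant in vcf:
        codes = np.empty(len(samples))
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            codes[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        snp_ids.append(variant.ID)
        rows.append(codes)
        meta_rows.append(
            {
                "chrom": variant.CHROM,
                "pos": variant.POS,
                "ref": variant.REF,
                "alt": variant.ALT[0] if variant.ALT else ".",
                "region_gene": variant.INFO.get("GENE"),
            }
        )
    vcf.close()
    codes = pd.DataFrame(np.vstack(rows), index=snp_ids, columns=samples)
    meta = pd.DataFrame(meta_rows, index=pd.Index(snp_ids, name="snp_id"))
    return GenotypeMatrix(codes, meta)


# -- RE-score output ----------------------------------------------------------

def write_rescores(re_matrix, out_dir, comments: Sequence[str] = ()) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_table(re_matrix.re, out_dir / "re_scores.tsv", comments, index_label="mirna_id")
    _write_table(
        re_matrix.mean_re.to_frame(), out_dir / "mean_re.tsv", comments, index_label="sample_id"
    )
    _write_table(
        re_matrix.n_targets_used.rename("n_targets_used").to_frame(),
        out_dir / "n_targets_used.tsv",
        comments,
        index_label="mirna_id",
    )
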