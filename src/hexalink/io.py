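"""Readers and writers for the on-disk formats used by the pipeline.

FASTA is handled through Biopython, VCF reading through pysam.  VCF/BED/TSV
writing is plain deterministic text so that identical inputs give
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VCF_HEADER = "##fileformat=VCFv4.2"


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seqs[name]), id=name, description="")
               for name in seqs]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_variants_vcf(variants: pd.DataFrame, chrom_lengths: dict[str, int],
                       path) -> None:
    """Write inter-reference variant sites.  REF is the A allele, ALT the B
    allele; both are echoed in INFO for self-description."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER + "\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Allele of reference A">\n')
        fh.write('##INFO=<ID=AB,Number=1,Type=String,Description="Allele of reference B">\n')
        for chrom in sorted(chrom_lengths):
            fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, a, b in variants[["chrom", "pos", "allele_A", "allele_B"]].itertuples(index=False):
            fh.write(f"{chrom}\t{pos + 1}\t.\t{a}\t{b}\t.\t.\tAA={a};AB={b}\n")


def read_variants_vcf(path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            rows.append((rec.chrom, rec.pos - 1, rec.ref, rec.alts[0]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "allele_A", "allele_B"])


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    """BED (0-based half-open).  ``extra_cols`` become columns 4+."""
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + (extra_cols or [])
    return pd.read_csv(path, sep="\t", header=None, names=names)


def write_manifest(params: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
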