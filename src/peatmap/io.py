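"""Readers and writers for the plain-text formats used across the pipeline.

VCF here is deliberately minimal: haploid GT fields (0, 1 or .), one sample
column per gametophyte, biallelic records only — the shape emitted by the
upstream variant callers after filtering.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .linkage_map import HaploidGenotypes

MISSING = -1


def write_haploid_vcf(path, g: HaploidGenotypes, ref: str = "A", alt: str = "T") -> None:
    """Write a haploid genotype matrix as a minimal biallelic VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in g.markers["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        code = {0: "0", 1: "1", MISSING: "."}
        for (_, row), calls in zip(g.markers.iterrows(), g.calls):
            gts = "\t".join(code[int(c)] for c in calls)
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_haploid_vcf(path) -> HaploidGenotypes:
    """Read a haploid biallelic VCF into a genotype matrix."""
    markers, rows, samples = [], [], None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            markers.append(
                {"chrom": fields[0], "pos": int(fields[1]), "id": fields[2]}
            )
            gt = [f.split(":")[0] for f in fields[9:]]
            rows.append([0 if x == "0" else 1 if x == "1" else MISSING for x in gt])
    if samples is None:
        raise ValueError("missing VCF header line")
    return HaploidGenotypes(
        markers=pd.DataFrame(markers),
        samples=samples,
        calls=np.asarray(rows, dtype=np.int8),
    )


def write_fasta(path, genome: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in genome.items()),
        path,
        "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_bed(path, intervals) -> None:
    """Write (chrom, start, end[, ...]) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_map_tsv(path, lmap) -> None:
    lmap.to_frame().to_csv(path, sep="\t", index=False)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
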