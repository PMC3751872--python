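"""Readers and writers for the pipeline's on-disk formats.

Coordinate dialects follow each format's convention: GFF3 and VCF are
1-based inclusive, bedGraph is 0-based half-open. Internally all interval
arithmetic is 0-based half-open. Expression matrices travel as TSV (genes x
samples) with a sample-metadata TSV mapping sample id -> (state, replicate).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import ExpressionSet
from .mutations import MutationCall, PooledLocus

__all__ = [
    "write_expression", "load_expression",
    "write_annotation", "load_annotation",
    "write_genome", "load_genome",
    "write_bedgraph", "load_bedgraph",
    "write_links", "load_links",
    "write_vcf", "load_vcf",
    "write_pool_counts", "load_pool_counts",
]


# -- expression -------------------------------------------------------------

def write_expression(eset: ExpressionSet, matrix_path, meta_path) -> None:
    eset.to_frame().to_csv(matrix_path, sep="\t", index_label="gene")
    meta = pd.DataFrame(
        {
            "sample": [f"{s}.r{r}" for s, r in eset.samples],
            "state": [s for s, _ in eset.samples],
            "replicate": [r for _, r in eset.samples],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def load_expression(matrix_path, meta_path) -> ExpressionSet:
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if mat.index.duplicated().any():
        dupes = sorted(set(mat.index[mat.index.duplicated()]))
        raise ValueError(f"duplicate gene ids in {matrix_path}: {dupes[:5]}")
    meta = pd.read_csv(meta_path, sep="\t").set_index("sample")
    samples = []
    for col in mat.columns:
        if col not in meta.index:
            raise ValueError(f"sample {col!r} missing from metadata {meta_path}")
        samples.append((str(meta.loc[col, "state"]), int(meta.loc[col, "replicate"])))
    return ExpressionSet(list(mat.index), samples, mat.to_numpy(dtype=float))


# -- annotation (GFF3) ------------------------------------------------------

def write_annotation(
    annotation: list[tuple[str, int, int, str]], path, seqid: str = "chr"
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene, start, end, strand in annotation:
            attrs = f"ID={gene};locus_tag={gene}"
            fh.write(
                f"{seqid}\tthermoevo\tCDS\t{start}\t{end}\t.\t{strand}\t0\t{attrs}\n"
            )


def load_annotation(path) -> list[tuple[str, int, int, str]]:
    """CDS/gene records as (locus_tag, start, end, strand), 1-based inclusive."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            seqid, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype not in ("CDS", "gene"):
                continue
            tags = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            name = tags.get("locus_tag") or tags.get("ID")
            if name is None:
                raise ValueError(f"{path}:{lineno}: feature without ID/locus_tag")
            records.append((name, int(start), int(end), strand))
    return records


# -- genome (FASTA) ---------------------------------------------------------

def write_genome(sequence: str, path, seqid: str = "chr") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=seqid, description="")], path, "fasta")


def load_genome(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# -- coverage (bedGraph) ----------------------------------------------------

def write_bedgraph(track: np.ndarray, path, seqid: str = "chr") -> None:
    """Run-length encode a per-base track as 0-based half-open bedGraph."""
    track = np.asarray(track, dtype=float)
    with open(path, "w") as fh:
        if track.size == 0:
            return
        change = np.nonzero(np.diff(track))[0] + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [track.size]])
        for s, e in zip(starts, ends):
            v = track[s]
            fh.write(f"{seqid}\t{s}\t{e}\t{v:g}\n")


def load_bedgraph(path, length: int | None = None) -> np.ndarray:
    frame = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "value"])
    if length is None:
        length = int(frame["end"].max()) if len(frame) else 0
    track = np.zeros(length)
    for _, row in frame.iterrows():
        track[int(row["start"]) : int(row["end"])] = row["value"]
    return track


# -- paired links -----------------------------------------------------------

def write_links(links: pd.DataFrame, path) -> None:
    links.to_csv(path, sep="\t", index=False)


def load_links(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- variants (VCF) ---------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=thermoevo
##INFO=<ID=SUPPORT,Number=.,Type=String,Description="Callers supporting the call">
##INFO=<ID=REGION,Number=1,Type=String,Description="coding or non-coding">
##INFO=<ID=GENE,Number=1,Type=String,Description="Locus tag of the affected gene">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Predicted coding effect">
##INFO=<ID=POOLFREQ,Number=1,Type=Float,Description="Pooled alternate-allele frequency">
##INFO=<ID=BENEFICIAL,Number=0,Type=Flag,Description="Candidate beneficial mutation">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: list[MutationCall], path, beneficial: set | None = None) -> None:
    beneficial = beneficial or set()
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in sorted(calls, key=lambda c: c.key):
            info = []
            if c.caller_support:
                info.append("SUPPORT=" + ",".join(sorted(c.caller_support)))
            if c.region:
                info.append(f"REGION={c.region}")
            if c.gene:
                info.append(f"GENE={c.gene}")
            if c.effect:
                info.append(f"EFFECT={c.effect}")
            if c.pooled_freq is not None:
                info.append(f"POOLFREQ={c.pooled_freq:.4f}")
            if c.key in beneficial:
                info.append("BENEFICIAL")
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t"
                + (";".join(info) or ".")
                + "\n"
            )


def load_vcf(path) -> list[MutationCall]:
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected >=8 VCF columns")
            chrom, pos, _, ref, alt, _, _, info = fields[:8]
            tags: dict[str, str | None] = {}
            for kv in info.split(";"):
                if kv in (".", ""):
                    continue
                k, _, v = kv.partition("=")
                tags[k] = v or None
            calls.append(
                MutationCall(
                    chrom,
                    int(pos),
                    ref,
                    alt,
                    caller_support=frozenset(
                        (tags.get("SUPPORT") or "").split(",")
                    ) if tags.get("SUPPORT") else frozenset(),
                    region=tags.get("REGION"),
                    gene=tags.get("GENE"),
                    effect=tags.get("EFFECT"),
                    pooled_freq=float(tags["POOLFREQ"]) if tags.get("POOLFREQ") else None,
                )
            )
    return calls


# -- pooled counts ----------------------------------------------------------

def write_pool_counts(loci: list[PooledLocus], path, ref: str = "N", alt: str = "N") -> None:
    frame = pd.DataFrame(
        {
            "chrom": [l.chrom for l in loci],
            "pos": [l.pos for l in loci],
            "ref": ref,
            "alt": alt,
            "ref_reads": [l.ref_reads for l in loci],
            "alt_reads": [l.alt_reads for l in loci],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def load_pool_counts(path) -> list[PooledLocus]:
    frame = pd.read_csv(path, sep="\t")
    return [
        PooledLocus(str(r["chrom"]), int(r["pos"]), int(r["ref_reads"]), int(r["alt_reads"]))
        for _, r in frame.iterrows()
    ]


# -- misc -------------------------------------------------------------------

def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
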