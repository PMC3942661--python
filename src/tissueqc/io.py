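"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTQ is Phred+33 with ``/1``/``/2`` mate suffixes; SAM is a minimal
dialect (single gapless M block, paired/proper/strand/mate-strand/
first/second flags only); GTF carries ``exon`` features with a
``gene_id`` attribute.
"""
from __future__ import annotations

import os
from typing import Iterable, Iterator

import numpy as np
import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import AlignmentRecord, GeneModel, ReadPair

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80


# --------------------------------------------------------------------- FASTQ
def _encode_quals(quals: np.ndarray) -> str:
    return "".join(chr(int(q) + 33) for q in quals)


def _decode_quals(qstring: str) -> np.ndarray:
    return np.frombuffer(qstring.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33


def write_fastq_pair(pairs: Iterable[ReadPair], path1: str, path2: str) -> int:
    n = 0
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.bases1}\n+\n{_encode_quals(p.quals1)}\n")
            f2.write(f"@{p.id}/2\n{p.bases2}\n+\n{_encode_quals(p.quals2)}\n")
            n += 1
    return n


def read_fastq_pair(path1: str, path2: str) -> Iterator[ReadPair]:
    with open(path1) as f1, open(path2) as f2:
        for (id1, seq1, q1), (id2, seq2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            base1, base2 = id1.split()[0], id2.split()[0]
            if base1.endswith("/1"):
                base1 = base1[:-2]
            if base2.endswith("/2"):
                base2 = base2[:-2]
            if base1 != base2:
                raise ValueError(f"mate id mismatch: {id1!r} vs {id2!r}")
            yield ReadPair(base1, seq1, _decode_quals(q1), seq2, _decode_quals(q2))


# ----------------------------------------------------------------------- SAM
def sam_flag(mate: int, strand: str, mate_strand: str) -> int:
    flag = FLAG_PAIRED | FLAG_PROPER
    flag |= FLAG_FIRST if mate == 1 else FLAG_SECOND
    if strand == "-":
        flag |= FLAG_REVERSE
    if mate_strand == "-":
        flag |= FLAG_MATE_REVERSE
    return flag


def write_sam(
    records: Iterable[tuple[AlignmentRecord, str, str]],
    references: dict[str, int],
    path: str,
) -> None:
    """Write alignment records as SAM text.

    ``records`` yields (record, seq, qual_string); seq/qual may be "*".
    """
    recs = list(records)
    by_id: dict[tuple[str, int], AlignmentRecord] = {
        (r.read_id, r.mate): r for r, _, _ in recs
    }
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rec, seq, qual in recs:
            other = by_id.get((rec.read_id, 3 - rec.mate))
            mate_strand = other.strand if other else "+"
            flag = sam_flag(rec.mate, rec.strand, mate_strand)
            rnext, pnext = "*", 0
            tlen = 0
            if other is not None:
                rnext = "=" if other.reference == rec.reference else other.reference
                pnext = other.start + 1
                if other.reference == rec.reference:
                    left = min(rec.start, other.start)
                    right = max(rec.end, other.end)
                    tlen = right - left if rec.start <= other.start else left - right
            fh.write(
                f"{rec.read_id}\t{flag}\t{rec.reference}\t{rec.start + 1}\t"
                f"{rec.mapq}\t{rec.length}M\t{rnext}\t{pnext}\t{tlen}\t{seq}\t{qual}\n"
            )


def read_sam(path: str) -> list[AlignmentRecord]:
    records = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            quals = seg.query_qualities
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    mate=2 if seg.is_read2 else 1,
                    reference=seg.reference_name,
                    start=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    length=seg.reference_length or 0,
                    mapq=seg.mapping_quality,
                    mate_reference=(
                        seg.next_reference_name or "" if seg.is_paired else ""
                    ),
                    mate_start=max(seg.next_reference_start, 0),
                    qual_sum=int(sum(quals)) if quals is not None else 0,
                )
            )
    return records


# ----------------------------------------------------------------------- GTF
def write_gtf(genes: Iterable[GeneModel], path: str, source: str = "tissueqc") -> None:
    with open(path, "w") as fh:
        for g in genes:
            for s, e in g.exons:
                attrs = f'gene_id "{g.gene_id}";'
                fh.write(
                    f"{g.reference}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str) -> list[GeneModel]:
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            gene_id = None
            for token in f[8].split(";"):
                token = token.strip()
                if token.startswith("gene_id"):
                    gene_id = token.split(None, 1)[1].strip('" ')
            if gene_id is None:
                raise ValueError(f"exon feature without gene_id: {line!r}")
            rec = exons.setdefault(
                gene_id, {"reference": f[0], "strand": f[6], "exons": []}
            )
            rec["exons"].append((int(f[3]) - 1, int(f[4])))
    return [
        GeneModel(gid, rec["reference"], rec["strand"], rec["exons"])
        for gid, rec in exons.items()
    ]


# --------------------------------------------------------------------- FASTA
def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
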