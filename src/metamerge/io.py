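"""Readers and writers for the on-disk formats the pipeline touches.

FASTA is parsed by hand so format errors can name the offending line;
FASTQ goes through Biopython's fast iterator; SAM through pysam; GFF3 is a
small tabular subset (gene/CDS rows).  On disk SAM and GFF3 are 1-based as
their standards require; everything in memory is 0-based half-open.
"""

from __future__ import annotations

import contextlib
import logging
import sys
import time
from collections.abc import Iterable, Iterator
from pathlib import Path

import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .types import (
    AlignmentRecord,
    AnnotationRecord,
    FormatError,
    GeneFeature,
    PairingError,
    ReadPair,
    ReferenceError_,
    SeqRecord,
)

logger = logging.getLogger("metamerge")


def setup_logging(level: int = logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level)


@contextlib.contextmanager
def stage_timer(stage: str) -> Iterator[None]:
    t0 = time.perf_counter()
    logger.info("stage %s: start", stage)
    yield
    logger.info("stage %s: done in %.2f s", stage, time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file; records keep file order, sequences are uppercased."""
    records: list[SeqRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(
                f"{path}: empty sequence for header at line {header_line}"
            )
        rid, _, desc = header.partition(" ")
        records.append(SeqRecord(id=rid, sequence=seq, description=desc))
        header, chunks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                if len(line) == 1:
                    raise FormatError(f"{path}: empty FASTA header at line {line_no}")
                header, header_line = line[1:], line_no
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: sequence before any header at line {line_no}"
                    )
                chunks.append(line)
        flush(line_no=-1)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ

def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read single-end FASTQ as (id-with-description, seq, qual) tuples."""
    out = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            if len(seq) != len(qual):
                raise FormatError(f"{path}: seq/qual length mismatch for {title!r}")
            out.append((title, seq.upper(), qual))
    return out


def _strip_mate_suffix(title: str) -> str:
    rid = title.split()[0]
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid


def pair_mates(
    r1: Iterable[tuple[str, str, str]], r2: Iterable[tuple[str, str, str]]
) -> list[ReadPair]:
    """Pair mate streams positionally; ids come from mate 1."""
    r1, r2 = list(r1), list(r2)
    if len(r1) != len(r2):
        raise PairingError(
            f"mate files differ in length: {len(r1)} vs {len(r2)} records"
        )
    pairs = []
    for (t1, s1, q1), (_t2, s2, q2) in zip(r1, r2):
        pairs.append(ReadPair(id=_strip_mate_suffix(t1), seq1=s1, seq2=s2, qual1=q1, qual2=q2))
    return pairs


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    return pair_mates(read_fastq(r1_path), read_fastq(r2_path))


def write_fastq_pairs(
    pairs: Iterable[ReadPair], r1_path: str | Path, r2_path: str | Path
) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


# ---------------------------------------------------------------------------
# SAM (via pysam; text SAM subset, no BAM)

_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_MATE1 = 0x40
_FLAG_MATE2 = 0x80


def write_sam(
    records: Iterable[AlignmentRecord],
    reference: dict[str, int],
    path: str | Path,
) -> None:
    """Write alignments as text SAM; ``reference`` maps target id -> length."""
    names = list(reference)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": n, "LN": reference[n]} for n in names],
        }
    )
    index = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.query_id
            flag = _FLAG_PAIRED
            flag |= _FLAG_MATE1 if rec.is_mate1 else _FLAG_MATE2
            if rec.properly_paired:
                flag |= _FLAG_PROPER
            if not rec.mapped:
                flag |= _FLAG_UNMAPPED
                seg.flag = flag
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 0
            else:
                if rec.target_id not in index:
                    raise ReferenceError_(f"unknown target id {rec.target_id!r}")
                if rec.strand == "-":
                    flag |= _FLAG_REVERSE
                seg.flag = flag
                seg.reference_id = index[rec.target_id]
                seg.reference_start = rec.target_start  # pysam handles +1 on disk
                seg.cigarstring = rec.cigar
                seg.mapping_quality = rec.mapq
                seg.template_length = rec.fragment_len
            if rec.seq:
                seg.query_sequence = rec.seq
                seg.query_qualities = pysam.qualitystring_to_array(rec.qual)
            out.write(seg)


def read_sam(
    path: str | Path, reference: dict[str, int] | None = None
) -> list[AlignmentRecord]:
    """Read text SAM; positions are converted to 0-based half-open."""
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        if reference is not None:
            for sq in fh.header.get("SQ", []):
                if sq["SN"] not in reference:
                    raise ReferenceError_(f"unknown target id {sq['SN']!r} in header")
        for seg in fh:
            unmapped = seg.is_unmapped
            qual = (
                pysam.array_to_qualitystring(seg.query_qualities)
                if seg.query_qualities is not None
                else ""
            )
            out.append(
                AlignmentRecord(
                    query_id=seg.query_name,
                    target_id=None if unmapped else seg.reference_name,
                    target_start=0 if unmapped else seg.reference_start,
                    strand="-" if (not unmapped and seg.is_reverse) else "+",
                    cigar="" if unmapped else (seg.cigarstring or ""),
                    mapq=seg.mapping_quality,
                    is_mate1=bool(seg.flag & _FLAG_MATE1),
                    properly_paired=seg.is_proper_pair,
                    fragment_len=seg.template_length,
                    seq=seg.query_sequence or "",
                    qual=qual,
                )
            )
    return out


# ---------------------------------------------------------------------------
# GFF3 (gene/CDS subset)

def read_gff3(path: str | Path) -> list[GeneFeature]:
    """Read gene/CDS rows; disk 1-based inclusive -> 0-based half-open."""
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{line_no}: expected 9 columns")
            seqid, _src, ftype, start_s, end_s, _score, strand, frame_s, attrs = cols
            if ftype not in ("gene", "CDS"):
                continue
            start, end = int(start_s), int(end_s)
            if end < start:
                raise FormatError(f"{path}:{line_no}: end < start")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("ID")
            if gid is None:
                gid = f"{seqid}:{start - 1}-{end}"
                logger.warning("%s:%d: missing ID attribute; using %s", path, line_no, gid)
            frame = int(frame_s) if frame_s in "012" else 0
            feats.append(
                GeneFeature(
                    gene_id=gid,
                    scaffold_id=seqid,
                    start=start - 1,
                    end=end,
                    strand=strand,
                    frame=frame,
                )
            )
    return feats


def write_gff3(features: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.scaffold_id,
                        "metamerge",
                        "CDS",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        str(f.frame),
                        f"ID={f.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotation and matrix tables

def read_annotation_tsv(path: str | Path) -> dict[str, AnnotationRecord]:
    """Read the gene annotation table (tab-separated, semicolon reactions)."""
    out: dict[str, AnnotationRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene_id", "ko", "cog", "reactions"]
        if header != expected:
            raise FormatError(f"{path}: header must be {expected}, got {header}")
        for line_no, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}:{line_no}: expected 4 columns")
            gid, ko, cog, reactions = cols
            if gid in out:
                raise FormatError(f"{path}:{line_no}: duplicate gene_id {gid!r}")
            out[gid] = AnnotationRecord(
                gene_id=gid,
                ko=ko or None,
                cog=cog or None,
                reactions=frozenset(r for r in reactions.split(";") if r),
            )
    return out


def write_annotation_tsv(
    annotations: Iterable[AnnotationRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tko\tcog\treactions\n")
        for a in annotations:
            fh.write(
                f"{a.gene_id}\t{a.ko or ''}\t{a.cog or ''}\t"
                + ";".join(sorted(a.reactions))
                + "\n"
            )


def write_matrix_tsv(matrix, path: str | Path) -> None:
    """Write a pandas DataFrame (genes x samples) as TSV."""
    matrix.to_csv(path, sep="\t")
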