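"""Exact-match read placement under the perfect-unique filter.

Downstream analyses only ever consume alignments with zero mismatches at a
single genomic location, so the mapper's semantics are exact substring
matching on both strands: seed on the read's first k-mer, verify the full
read, and count every 0-mismatch location as a hit.  ``n_hits`` is carried
on every record so the uniqueness filter is a pure predicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .config import GenomeSet, revcomp

logger = logging.getLogger("metaribo")


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    contig_id: str
    pos: int  # 1-based leftmost aligned base on the forward strand
    strand: str  # '+' or '-'
    length: int
    n_mismatch: int = 0
    n_hits: int = 1

    def five_prime(self) -> int:
        """1-based position of the read's 5' end on its own strand."""
        return self.pos if self.strand == "+" else self.pos + self.length - 1


class SeedIndex:
    """k-mer -> forward-strand location lookup over a genome set."""

    def __init__(self, genomes: GenomeSet, k: int = 21) -> None:
        if k < 8:
            raise ValueError(f"seed length k={k} is too unspecific; need k >= 8")
        if len(genomes) == 0:
            raise ValueError("empty genome set")
        self.k = k
        self.genomes = genomes
        self._index: dict[str, list[tuple[str, int]]] = {}
        for contig in genomes:
            seq = contig.sequence
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((contig.id, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """Forward-strand (contig_id, 0-based position) hits of a k-mer."""
        return self._index.get(kmer, [])


def build_index(genomes: GenomeSet, k: int = 21) -> SeedIndex:
    return SeedIndex(genomes, k)


def _exact_hits(index: SeedIndex, read: str) -> list[tuple[str, int, str]]:
    """All (contig, 0-based leftmost, strand) 0-mismatch locations of a read."""
    hits: list[tuple[str, int, str]] = []
    k = index.k
    for oriented, strand in ((read, "+"), (revcomp(read), "-")):
        seed = oriented[:k]
        for contig_id, i in index.lookup(seed):
            seq = index.genomes[contig_id].sequence
            if seq[i : i + len(oriented)] == oriented:
                hits.append((contig_id, i, strand))
    hits.sort()
    return hits


def map_reads(
    index: SeedIndex, reads: Iterable[tuple[str, str]]
) -> list[AlignmentRecord]:
    """Report every perfect hit of every read, annotated with its hit count.

    ``reads`` yields (read_id, sequence).  Reads shorter than the seed are
    dropped with a logged tally; reads with no perfect hit produce nothing.
    """
    records: list[AlignmentRecord] = []
    n_short = 0
    for read_id, seq in reads:
        seq = seq.upper()
        if len(seq) < index.k:
            n_short += 1
            continue
        hits = _exact_hits(index, seq)
        for contig_id, i, strand in hits:
            records.append(
                AlignmentRecord(
                    read_id=read_id,
                    contig_id=contig_id,
                    pos=i + 1,
                    strand=strand,
                    length=len(seq),
                    n_mismatch=0,
                    n_hits=len(hits),
                )
            )
    if n_short:
        logger.info("dropped %d reads shorter than k=%d", n_short, index.k)
    return records


def filter_unique_perfect(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep only zero-mismatch alignments at a unique genomic location."""
    return [r for r in records if r.n_mismatch == 0 and r.n_hits == 1]


# ---------------------------------------------------------------------------
# FASTQ / SAM I/O
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def write_sam(
    records: Iterable[AlignmentRecord], genomes: GenomeSet, path: str | Path
) -> None:
    """Emit minimal valid SAM: @SQ headers, strand FLAG, MAPQ 255, NM tag."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c.id, "LN": len(c)} for c in genomes],
    }
    tid = {c.id: i for i, c in enumerate(genomes)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment()
            a.query_name = r.read_id
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = tid[r.contig_id]
            a.reference_start = r.pos - 1
            a.mapping_quality = 255
            a.cigarstring = f"{r.length}M"
            a.set_tag("NM", r.n_mismatch)
            a.set_tag("NH", r.n_hits)
            out.write(a)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Load SAM alignments; NM is mandatory, n_hits counts equal-best records.

    For each read, the number of its records at the minimal NM defines
    ``n_hits`` (an NH tag, when present, overrides this bookkeeping, which
    covers mappers that only report one record per multi-mapping read).
    """
    raw: list[tuple[AlignmentRecord, int | None]] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for lineno, a in enumerate(fh, start=1):
            if a.is_unmapped:
                continue
            if not a.has_tag("NM"):
                raise ValueError(
                    f"{path}: alignment record {lineno} ({a.query_name}) lacks NM tag"
                )
            rec = AlignmentRecord(
                read_id=a.query_name,
                contig_id=a.reference_name,
                pos=a.reference_start + 1,
                strand="-" if a.is_reverse else "+",
                length=a.infer_query_length() or len(a.query_sequence or ""),
                n_mismatch=a.get_tag("NM"),
                n_hits=1,
            )
            nh = a.get_tag("NH") if a.has_tag("NH") else None
            raw.append((rec, nh))
    best: dict[str, int] = {}
    counts: dict[str, int] = {}
    for rec, _ in raw:
        b = best.get(rec.read_id)
        if b is None or rec.n_mismatch < b:
            best[rec.read_id] = rec.n_mismatch
    for rec, _ in raw:
        if rec.n_mismatch == best[rec.read_id]:
            counts[rec.read_id] = counts.get(rec.read_id, 0) + 1
    out = []
    for rec, nh in raw:
        n_hits = nh if nh is not None else counts[rec.read_id]
        out.append(replace(rec, n_hits=n_hits))
    return out
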