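"""Six-frame ORF prediction and smORF selection.

ORFs are called with a transparent scan: in each of the six reading frames,
every in-frame stop codon closes the ORF that begins at the outermost
upstream in-frame start codon with no intervening stop (the maximal-ORF
convention).  Coordinates are 1-based inclusive on the forward strand with
``start < end`` regardless of strand; ``nt_length`` includes the stop codon
while the protein string excludes it, so ``nt_length == 3 * (len(protein) + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .config import (
    DEFAULT_START_CODONS,
    STOP_CODONS,
    Contig,
    GenomeSet,
    revcomp,
)


@dataclass(frozen=True)
class OrfRecord:
    orf_id: str
    contig_id: str
    start: int  # 1-based inclusive, start < end
    end: int
    strand: str  # '+' or '-'
    protein: str  # initiator Met included, stop excluded

    @property
    def nt_length(self) -> int:
        return self.end - self.start + 1

    @property
    def aa_length(self) -> int:
        return len(self.protein)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"{self.orf_id}: start must precede end")
        if self.nt_length % 3 != 0:
            raise ValueError(f"{self.orf_id}: nt_length not a codon multiple")
        if self.nt_length != 3 * (len(self.protein) + 1):
            raise ValueError(f"{self.orf_id}: protein/nt length mismatch")


def translate_orf(nt_sequence: str) -> str:
    """Translate a stop-terminated coding sequence (bacterial table 11).

    The initiator codon is rendered as M even when it is GTG or TTG.
    Internal stop codons and non-codon-multiple lengths are hard errors.
    """
    nt_sequence = nt_sequence.upper()
    if len(nt_sequence) % 3 != 0:
        raise ValueError(f"length {len(nt_sequence)} is not a multiple of 3")
    if len(nt_sequence) < 6:
        raise ValueError("coding sequence must hold at least start and stop codons")
    if nt_sequence[-3:] not in STOP_CODONS:
        raise ValueError(f"sequence does not end with a stop codon: {nt_sequence[-3:]}")
    body = nt_sequence[:-3]
    protein = str(Seq(body).translate(table=11))
    if "*" in protein:
        raise ValueError(f"internal stop codon at codon {protein.index('*') + 1}")
    return "M" + protein[1:]


def _scan_forward(seq: str, start_codons: frozenset, min_orf_nt: int):
    """Yield (start0, end0_inclusive_of_stop) ORF spans on the given string."""
    n = len(seq)
    for frame in range(3):
        outermost: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if outermost is not None:
                    if (i + 3) - outermost >= min_orf_nt:
                        yield outermost, i + 2
                    outermost = None
            elif outermost is None and codon in start_codons:
                outermost = i


def find_orfs(
    contig: Contig,
    min_orf_nt: int = 15,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
) -> list[OrfRecord]:
    """Scan all six frames of a contig for stop-terminated ORFs.

    Returns records sorted by (start, end, strand); ids encode the locus.
    """
    starts = frozenset(s.upper() for s in start_codons)
    if not starts or not starts <= {"ATG", "GTG", "TTG"}:
        raise ValueError("start_codons must be a nonempty subset of {ATG, GTG, TTG}")
    seq = contig.sequence
    n = len(seq)
    found: list[OrfRecord] = []
    for a0, b0 in _scan_forward(seq, starts, min_orf_nt):
        found.append(
            OrfRecord(
                orf_id=f"{contig.id}:{a0 + 1}-{b0 + 1}:+",
                contig_id=contig.id,
                start=a0 + 1,
                end=b0 + 1,
                strand="+",
                protein=translate_orf(seq[a0 : b0 + 1]),
            )
        )
    rc = revcomp(seq)
    for a0, b0 in _scan_forward(rc, starts, min_orf_nt):
        # rc index i corresponds to forward index n - 1 - i
        start = n - b0  # 1-based forward coordinates
        end = n - a0
        found.append(
            OrfRecord(
                orf_id=f"{contig.id}:{start}-{end}:-",
                contig_id=contig.id,
                start=start,
                end=end,
                strand="-",
                protein=translate_orf(rc[a0 : b0 + 1]),
            )
        )
    found.sort(key=lambda o: (o.contig_id, o.start, o.end, o.strand))
    return found


def find_orfs_genome(
    genomes: GenomeSet,
    min_orf_nt: int = 15,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
) -> list[OrfRecord]:
    out: list[OrfRecord] = []
    for contig in genomes:
        out.extend(find_orfs(contig, min_orf_nt, start_codons))
    return out


def select_smorfs(
    orfs: Iterable[OrfRecord], smorf_aa_range: tuple[int, int] = (5, 50)
) -> list[OrfRecord]:
    """Keep ORFs whose protein length falls in the smORF window (inclusive)."""
    lo, hi = smorf_aa_range
    return [o for o in orfs if lo <= len(o.protein) <= hi]


def orf_nt_sequence(orf: OrfRecord, genomes: GenomeSet) -> str:
    """Coding-strand nucleotide sequence of an ORF, stop codon included."""
    seq = genomes[orf.contig_id].sequence[orf.start - 1 : orf.end]
    return seq if orf.strand == "+" else revcomp(seq)


# ---------------------------------------------------------------------------
# GFF3 output / input
# ---------------------------------------------------------------------------

def write_gff3(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for o in orfs:
        attrs = f"ID={o.orf_id};protein_length={len(o.protein)}"
        lines.append(
            "\t".join(
                [
                    o.contig_id,
                    "metaribo",
                    "CDS",
                    str(o.start),
                    str(o.end),
                    ".",
                    o.strand,
                    "0",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path, genomes: GenomeSet) -> list[OrfRecord]:
    orfs: list[OrfRecord] = []
    for raw in Path(path).read_text().splitlines():
        if not raw or raw.startswith("#"):
            continue
        f = raw.split("\t")
        if len(f) != 9:
            raise ValueError(f"malformed GFF3 line: {raw!r}")
        contig_id, _, _, start, end, _, strand, _, attrs = f
        attr_map = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        start_i, end_i = int(start), int(end)
        seq = genomes[contig_id].sequence[start_i - 1 : end_i]
        if strand == "-":
            seq = revcomp(seq)
        orfs.append(
            OrfRecord(
                orf_id=attr_map.get("ID", f"{contig_id}:{start}-{end}:{strand}"),
                contig_id=contig_id,
                start=start_i,
                end=end_i,
                strand=strand,
                protein=translate_orf(seq),
            )
        )
    return orfs
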