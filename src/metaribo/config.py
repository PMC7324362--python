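"""Shared types, pipeline thresholds, and FASTA / flat-config I/O.

Every tunable threshold used downstream lives in :class:`PipelineConfig`,
so that a single object documents the analysis conventions: the 15 bp ORF
cutoff, the 5-50 aa smORF window, the MetaRibo-Seq RPKM > 10 translation
call, the ten-read metagene filter, the clustering identity/coverage
parameters, the homolog e-value and length-window filter, and the
|log2FC| > 1 & FDR < 0.05 differential call rule.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("metaribo")

VALID_BASES = frozenset("ACGT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")


@dataclass
class PipelineConfig:
    """All stated analysis thresholds, with their conventional defaults.

    Fractions are in (0, 1]; lengths in nucleotides unless suffixed _aa.
    """

    min_orf_nt: int = 15
    smorf_aa_range: tuple[int, int] = (5, 50)
    translation_rpkm_threshold: float = 10.0
    min_reads_metagene: int = 10
    family_identity_smorf: float = 0.50
    family_identity_diff: float = 0.70
    cluster_length_diff_cutoff: float = 0.95
    cluster_long_coverage: float = 0.95
    homolog_evalue_max: float = 0.05
    homolog_length_window: tuple[float, float] = (0.90, 1.10)
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    neighborhood_max_genes: int = 10
    domain_coverage_min: float = 0.80
    localization_member_fraction: float = 0.80
    other_abundance_threshold: float = 0.03
    metagene_flank_nt: int = 50
    rng_seed: int = 0
    pool_replicates: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lo, hi = self.smorf_aa_range
        if not (2 <= lo <= hi):
            raise ValueError(
                f"smorf_aa_range must satisfy 2 <= lo <= hi, got ({lo}, {hi})"
            )
        for name in (
            "family_identity_smorf",
            "family_identity_diff",
            "cluster_length_diff_cutoff",
            "cluster_long_coverage",
            "domain_coverage_min",
            "localization_member_fraction",
            "other_abundance_threshold",
        ):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in (
            "min_orf_nt",
            "translation_rpkm_threshold",
            "min_reads_metagene",
            "homolog_evalue_max",
            "lfc_threshold",
            "fdr_threshold",
            "neighborhood_max_genes",
            "metagene_flank_nt",
        ):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        wlo, whi = self.homolog_length_window
        if not (0.0 < wlo <= whi):
            raise ValueError(
                f"homolog_length_window must satisfy 0 < lo <= hi, got ({wlo}, {whi})"
            )


_PAIR_FIELDS = {"smorf_aa_range": int, "homolog_length_window": float}
_BOOL_FIELDS = {"pool_replicates"}
_INT_FIELDS = {
    "min_orf_nt",
    "min_reads_metagene",
    "neighborhood_max_genes",
    "metagene_flank_nt",
    "rng_seed",
}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file; unset keys take defaults.

    Pairs are comma-separated (``smorf_aa_range = 5,50``).  Unknown keys are
    a hard error so typos never silently fall back to a default.
    """
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in _PAIR_FIELDS:
            cast = _PAIR_FIELDS[key]
            parts = [cast(p) for p in val.split(",")]
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: {key} needs two values")
            values[key] = tuple(parts)
        elif key in _BOOL_FIELDS:
            if val.lower() not in ("true", "false"):
                raise ValueError(f"{path}:{lineno}: {key} must be true/false")
            values[key] = val.lower() == "true"
        elif key in _INT_FIELDS:
            values[key] = int(val)
        else:
            values[key] = float(val)
    return PipelineConfig(**values)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    lines = []
    for f in dataclasses.fields(PipelineConfig):
        v = getattr(config, f.name)
        if isinstance(v, tuple):
            v = ",".join(str(x) for x in v)
        elif isinstance(v, bool):
            v = "true" if v else "false"
        lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sequence containers
# ---------------------------------------------------------------------------

@dataclass
class Contig:
    """A community reference sequence with an optional taxon label."""

    id: str
    sequence: str
    taxon: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        for i, base in enumerate(self.sequence):
            if base not in VALID_BASES:
                raise ValueError(
                    f"contig {self.id!r}: invalid symbol {base!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


class GenomeSet:
    """An ordered collection of contigs with unique ids."""

    def __init__(self, contigs: Iterable[Contig] = ()) -> None:
        self._contigs: dict[str, Contig] = {}
        for c in contigs:
            self.add(c)

    def add(self, contig: Contig) -> None:
        if contig.id in self._contigs:
            raise ValueError(f"duplicate contig id {contig.id!r}")
        self._contigs[contig.id] = contig

    def __iter__(self) -> Iterator[Contig]:
        return iter(self._contigs.values())

    def __len__(self) -> int:
        return len(self._contigs)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._contigs

    def __getitem__(self, contig_id: str) -> Contig:
        return self._contigs[contig_id]

    def ids(self) -> list[str]:
        return list(self._contigs)

    def total_length(self) -> int:
        return sum(len(c) for c in self)


def read_fasta(path: str | Path) -> GenomeSet:
    """Read contigs, normalizing case and rejecting non-ACGT symbols."""
    genomes = GenomeSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        genomes.add(Contig(id=rec.id, sequence=str(rec.seq)))
    if len(genomes) == 0:
        raise ValueError(f"{path}: no FASTA records")
    return genomes


def write_fasta(genomes: GenomeSet | Iterable[Contig], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="") for c in genomes
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_protein_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in entries]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate protein id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
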