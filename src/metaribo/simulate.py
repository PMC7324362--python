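"""Synthetic mixed-community ground truth: genomes, abundances, reads.

The generator plants unambiguous protein-coding genes (including 5-50 aa
smORFs and, optionally, homologous families diverged from a common
ancestor) on multi-taxon genomes, assigns lognormal transcription levels
and per-gene translational efficiencies with planted regulated subsets,
and emits error-free reads:

* metagenomic reads — uniform over both strands of every genome;
* RNA fragments — uniform over transcribed gene spans on the coding
  strand, at a rate proportional to transcription level;
* ribosome footprints — 5' ends drawn per gene at a rate proportional to
  transcription x translational efficiency, mixing frame-weighted body
  density with multiplicative start- and stop-window peaks, plus an
  optional genome-wide background.

Reads are exact substrings (or reverse complements) of their source
contig, so the perfect-unique mapping filter loses nothing except genuine
repeats; a truth SAM records every read's source position.  Each planted
gene is preceded by an in-frame stop codon so the maximal-ORF caller
recovers exactly the planted coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import Contig, GenomeSet, revcomp
from .diffreg import DesignSpec
from .mapping import AlignmentRecord, write_fastq, write_sam
from .orfs import OrfRecord, translate_orf, write_gff3

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_CODON_TABLE = {
    "F": ["TTT", "TTC"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"], "M": ["ATG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "A": ["GCT", "GCC", "GCA", "GCG"],
    "Y": ["TAT", "TAC"], "H": ["CAT", "CAC"], "Q": ["CAA", "CAG"],
    "N": ["AAT", "AAC"], "K": ["AAA", "AAG"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "C": ["TGT", "TGC"], "W": ["TGG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"], "G": ["GGT", "GGC", "GGA", "GGG"],
}
_STOPS = ["TAA", "TAG", "TGA"]


@dataclass
class SignalModel:
    """Positional model for ribosome-footprint 5' ends within genes."""

    start_peak_weight: float = 10.0
    stop_peak_weight: float = 5.0
    start_window_nt: int = 12
    stop_window_nt: int = 12
    frame_weights: tuple[float, float, float] = (0.6, 0.2, 0.2)
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.frame_weights) - 1.0) > 1e-12:
            raise ValueError("frame_weights must sum to 1")
        if min(self.frame_weights) < 0 or self.start_peak_weight < 0 or \
                self.stop_peak_weight < 0 or self.background_rate < 0:
            raise ValueError("signal model weights must be nonnegative")


@dataclass
class FamilySpec:
    """Planted homologous smORF families diverged from a shared ancestor.

    ``aa_divergence`` is the expected pairwise amino-acid divergence
    between two family members; each member is mutated away from the
    ancestor at the per-site rate that yields this pairwise divergence
    (two members diverged independently at rate r differ at a site with
    probability 2r(1-r) + r^2 (18/19) under uniform substitution).
    """

    n_families: int = 0
    members_per_family: int = 0
    aa_divergence: float = 0.10
    protein_len_aa: int = 30
    nt_variants: Optional[int] = None  # members share DNA among this many variants

    @property
    def member_mutation_rate(self) -> float:
        # solve (1-r)^2 + r^2/19 = 1 - d for r in [0, 1)
        d = self.aa_divergence
        return (19.0 / 20.0) * (1.0 - math.sqrt(max(0.0, 1.0 - 20.0 * d / 19.0)))


@dataclass
class GeneTruth:
    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str
    nt_seq: str  # coding orientation, stop codon included
    is_smorf: bool
    taxon: str
    family_id: Optional[str] = None
    is_decoy: bool = False
    transcription_level: float = 1.0
    translational_efficiency: float = 1.0
    regulated_class: str = "none"  # none | transcriptional | translational | both
    planted_lfc_rna: float = 0.0
    planted_lfc_ribo: float = 0.0

    def to_orf(self) -> OrfRecord:
        return OrfRecord(
            orf_id=self.gene_id,
            contig_id=self.contig_id,
            start=self.start,
            end=self.end,
            strand=self.strand,
            protein=self.protein,
        )


@dataclass
class SimulationTruth:
    genes: list[GeneTruth] = field(default_factory=list)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def orfs(self) -> list[OrfRecord]:
        return [g.to_orf() for g in self.genes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(g) for g in self.genes])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_gff3(self, path: str | Path) -> None:
        write_gff3(self.orfs(), path)


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [_CODON_TABLE[aa][rng.integers(0, len(_CODON_TABLE[aa]))] for aa in protein]
    codons[0] = "ATG"  # planted genes use the unambiguous initiator
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def _random_protein(rng: np.random.Generator, aa_len: int) -> str:
    body = "".join(np.array(list(AA20))[rng.integers(0, 20, size=aa_len - 1)])
    return "M" + body


def _mutate_protein(rng: np.random.Generator, protein: str, divergence: float) -> str:
    out = list(protein)
    for i in range(1, len(out)):  # initiator Met is conserved
        if rng.random() < divergence:
            choices = AA20.replace(out[i], "")
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def simulate_community(
    n_taxa: int = 3,
    genome_length_nt: int = 30_000,
    n_genes: int = 60,
    smorf_fraction: float = 0.3,
    decoy_fraction: float = 0.0,
    family_spec: Optional[FamilySpec] = None,
    seed: int = 0,
    protein_len_range_aa: tuple[int, int] = (60, 200),
    smorf_len_range_aa: tuple[int, int] = (5, 50),
    min_gap_nt: int = 20,
    max_gap_nt: int = 100,
) -> tuple[GenomeSet, SimulationTruth]:
    """Generate multi-taxon genomes with planted, recoverable genes.

    Genes are packed non-overlapping with random intergenic spacers and an
    in-frame stop codon immediately upstream of each start, so the ORF
    caller's outermost-start rule recovers exactly the planted gene.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n_smorf = round(n_genes * smorf_fraction)
    n_decoy = round(n_genes * decoy_fraction)
    if n_decoy > n_genes:
        raise ValueError("decoy_fraction yields more decoys than genes")

    # plan the gene payloads (protein + nt) before placement
    payloads: list[dict] = []
    for i in range(n_genes):
        is_smorf = i < n_smorf
        lo, hi = smorf_len_range_aa if is_smorf else protein_len_range_aa
        aa_len = int(rng.integers(lo, hi + 1))
        protein = _random_protein(rng, aa_len)
        payloads.append(
            {"protein": protein, "nt": _back_translate(rng, protein),
             "is_smorf": is_smorf, "family_id": None}
        )
    if family_spec is not None and family_spec.n_families > 0:
        for fi in range(family_spec.n_families):
            ancestor = _random_protein(rng, family_spec.protein_len_aa)
            fam_id = f"PF{fi + 1:04d}"
            rate = family_spec.member_mutation_rate
            variants: list[tuple[str, str]] = []
            if family_spec.nt_variants:
                for _ in range(family_spec.nt_variants):
                    p = _mutate_protein(rng, ancestor, rate)
                    variants.append((p, _back_translate(rng, p)))
            for mi in range(family_spec.members_per_family):
                if family_spec.nt_variants:
                    protein, nt = variants[mi % family_spec.nt_variants]
                else:
                    protein = _mutate_protein(rng, ancestor, rate)
                    nt = _back_translate(rng, protein)
                payloads.append(
                    {"protein": protein, "nt": nt,
                     "is_smorf": len(protein) <= 50, "family_id": fam_id}
                )

    # round-robin assignment of genes to taxa, then sequential packing
    per_taxon: list[list[dict]] = [[] for _ in range(n_taxa)]
    for i, payload in enumerate(payloads):
        per_taxon[i % n_taxa].append(payload)

    contigs: list[Contig] = []
    genes: list[GeneTruth] = []
    gi = 0
    for ti in range(n_taxa):
        taxon = f"Taxon_{ti + 1}"
        contig_id = f"t{ti + 1}"
        required = sum(len(p["nt"]) + 3 + min_gap_nt for p in per_taxon[ti])
        if required > genome_length_nt:
            raise ValueError(
                f"cannot pack {len(per_taxon[ti])} genes ({required} nt needed) into "
                f"a {genome_length_nt} nt genome; increase genome_length_nt"
            )
        parts: list[str] = []
        cursor = 0
        for pi, payload in enumerate(per_taxon[ti]):
            gi += 1
            remaining = per_taxon[ti][pi:]
            # keep room for every later cassette plus its minimal spacer
            gap_cap = (
                genome_length_nt
                - cursor
                - sum(len(q["nt"]) + 3 for q in remaining)
                - (len(remaining) - 1) * min_gap_nt
            )
            gap = int(rng.integers(min_gap_nt, max_gap_nt + 1))
            gap = max(min_gap_nt, min(gap, gap_cap))
            strand = "+" if rng.random() < 0.5 else "-"
            cassette = "TAA" + payload["nt"]  # upstream in-frame stop
            placed = cassette if strand == "+" else revcomp(cassette)
            parts.append(_random_dna(rng, gap))
            cursor += gap
            if strand == "+":
                start = cursor + 3 + 1
                end = cursor + len(cassette)
            else:
                start = cursor + 1
                end = cursor + len(payload["nt"])
            parts.append(placed)
            cursor += len(cassette)
            genes.append(
                GeneTruth(
                    gene_id=f"g{gi:05d}",
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand=strand,
                    protein=payload["protein"],
                    nt_seq=payload["nt"],
                    is_smorf=payload["is_smorf"],
                    taxon=taxon,
                    family_id=payload["family_id"],
                )
            )
        if cursor < genome_length_nt:
            parts.append(_random_dna(rng, genome_length_nt - cursor))
        contigs.append(Contig(id=contig_id, sequence="".join(parts), taxon=taxon))

    # mark decoys (planted but never translated), spread over plain genes
    plain = [g for g in genes if g.family_id is None]
    decoy_idx = rng.choice(len(plain), size=min(n_decoy, len(plain)), replace=False)
    for i in sorted(int(x) for x in decoy_idx):
        plain[i].is_decoy = True
        plain[i].translational_efficiency = 0.0

    return GenomeSet(contigs), SimulationTruth(genes)


# ---------------------------------------------------------------------------
# Abundances and regulation
# ---------------------------------------------------------------------------

def simulate_abundances(
    truth: SimulationTruth,
    lognormal_mu: float = 0.0,
    lognormal_sigma: float = 1.0,
    n_regulated: tuple[int, int, int] = (0, 0, 0),
    lfc_magnitude: float = 2.0,
    te_sigma: float = 0.5,
    seed: int = 0,
) -> SimulationTruth:
    """Fill transcription levels, translational efficiencies, and regulation.

    ``n_regulated`` counts genes per class (transcriptional, translational,
    both).  Translational regulation changes footprint output only
    (planted RNA log2FC is 0); the "both" class changes transcription and
    adds an independent translational shift on top.
    """
    rng = np.random.default_rng(seed)
    genes = truth.genes
    n_t, n_tr, n_b = n_regulated
    translated = [g for g in genes if not g.is_decoy]
    if n_t + n_tr + n_b > len(translated):
        raise ValueError("more regulated genes requested than translated genes exist")
    for g in genes:
        g.transcription_level = float(
            math.exp(lognormal_mu + lognormal_sigma * rng.standard_normal())
        )
        if not g.is_decoy:
            g.translational_efficiency = float(
                math.exp(te_sigma * rng.standard_normal())
            )
        g.regulated_class = "none"
        g.planted_lfc_rna = 0.0
        g.planted_lfc_ribo = 0.0
    chosen = rng.choice(len(translated), size=n_t + n_tr + n_b, replace=False)
    classes = ["transcriptional"] * n_t + ["translational"] * n_tr + ["both"] * n_b
    for idx, cls in zip(chosen, classes):
        g = translated[int(idx)]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        g.regulated_class = cls
        if cls == "transcriptional":
            g.planted_lfc_rna = sign * lfc_magnitude
            g.planted_lfc_ribo = sign * lfc_magnitude  # translation follows mRNA
        elif cls == "translational":
            g.planted_lfc_rna = 0.0
            g.planted_lfc_ribo = sign * lfc_magnitude
        else:
            sign2 = 1.0 if rng.random() < 0.5 else -1.0
            g.planted_lfc_rna = sign * lfc_magnitude
            g.planted_lfc_ribo = sign * lfc_magnitude + sign2 * lfc_magnitude
    return truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _position_weights(
    genomes: GenomeSet,
    truth: SimulationTruth,
    signal_model: SignalModel,
    assay: str,
    read_length_nt: int,
    condition: int,
) -> dict[tuple[str, str], np.ndarray]:
    weights = {
        (c.id, s): np.zeros(len(c), dtype=float) for c in genomes for s in "+-"
    }
    if assay == "metagenomic":
        for c in genomes:
            weights[(c.id, "+")][:] = 1.0
            weights[(c.id, "-")][:] = 1.0
    else:
        for g in truth:
            rate = g.transcription_level
            if assay == "ribo":
                rate *= g.translational_efficiency
                if condition == 2:
                    rate *= 2.0 ** g.planted_lfc_ribo
            elif condition == 2:
                rate *= 2.0 ** g.planted_lfc_rna
            if rate <= 0:
                continue
            glen = g.end - g.start + 1
            offsets = np.arange(glen)
            if assay == "rna":
                pos_w = np.full(glen, rate)
            else:
                pos_w = rate * np.asarray(signal_model.frame_weights)[offsets % 3] * 3.0
                pos_w[: signal_model.start_window_nt] *= signal_model.start_peak_weight
                if signal_model.stop_window_nt > 0:
                    pos_w[-signal_model.stop_window_nt:] *= signal_model.stop_peak_weight
            arr = weights[(g.contig_id, g.strand)]
            if g.strand == "+":
                arr[g.start - 1 : g.end] += pos_w
            else:
                arr[g.start - 1 : g.end] += pos_w[::-1]
        if assay == "ribo" and signal_model.background_rate > 0:
            for c in genomes:
                weights[(c.id, "+")] += signal_model.background_rate
                weights[(c.id, "-")] += signal_model.background_rate
    # a read must fit inside its contig
    for c in genomes:
        if read_length_nt > len(c):
            raise ValueError(f"read length exceeds contig {c.id} length")
        weights[(c.id, "+")][len(c) - read_length_nt + 1 :] = 0.0
        weights[(c.id, "-")][: read_length_nt - 1] = 0.0
    return weights


def simulate_reads(
    genomes: GenomeSet,
    truth: SimulationTruth,
    signal_model: SignalModel,
    assay: str,
    read_length_nt: int = 30,
    n_reads: int = 10_000,
    seed: int = 0,
    condition: int = 1,
    fastq_path: Optional[str | Path] = None,
    sam_path: Optional[str | Path] = None,
    read_prefix: Optional[str] = None,
) -> tuple[list[tuple[str, str]], list[AlignmentRecord]]:
    """Draw error-free reads from the positional model; return (reads, truth).

    Footprint/fragment 5' ends are sampled multinomially from the
    per-position weights, so exactly ``n_reads`` records are produced and
    each read occurs verbatim at its truth position.
    """
    if assay not in ("metagenomic", "rna", "ribo"):
        raise ValueError(f"unknown assay {assay!r}")
    if n_reads < 0:
        raise ValueError("n_reads must be nonnegative")
    rng = np.random.default_rng(seed)
    weights = _position_weights(
        genomes, truth, signal_model, assay, read_length_nt, condition
    )
    keys = sorted(weights)
    flat = np.concatenate([weights[k] for k in keys])
    total = flat.sum()
    if n_reads > 0 and total <= 0:
        raise ValueError("no positions with positive sampling weight")
    reads: list[tuple[str, str]] = []
    records: list[AlignmentRecord] = []
    prefix = read_prefix or f"{assay}_c{condition}"
    if n_reads > 0:
        draws = rng.multinomial(n_reads, flat / total)
        bounds = np.cumsum([0] + [len(weights[k]) for k in keys])
        idx = 0
        nz = np.nonzero(draws)[0]
        for flat_pos in nz:
            which = np.searchsorted(bounds, flat_pos, side="right") - 1
            contig_id, strand = keys[which]
            pos0 = int(flat_pos - bounds[which])
            seq = genomes[contig_id].sequence
            if strand == "+":
                left0 = pos0
                read_seq = seq[left0 : left0 + read_length_nt]
            else:
                left0 = pos0 - read_length_nt + 1
                read_seq = revcomp(seq[left0 : left0 + read_length_nt])
            for _ in range(int(draws[flat_pos])):
                read_id = f"{prefix}_r{idx:08d}"
                idx += 1
                reads.append((read_id, read_seq))
                records.append(
                    AlignmentRecord(
                        read_id=read_id,
                        contig_id=contig_id,
                        pos=left0 + 1,
                        strand=strand,
                        length=read_length_nt,
                        n_mismatch=0,
                        n_hits=1,
                    )
                )
    if fastq_path is not None:
        write_fastq(reads, fastq_path)
    if sam_path is not None:
        write_sam(records, genomes, sam_path)
    return reads, records


# ---------------------------------------------------------------------------
# Count-level simulation for the differential module
# ---------------------------------------------------------------------------

def simulate_counts(
    truth: SimulationTruth,
    n_replicates: int = 3,
    mean_depth: float = 50.0,
    rep_sigma: float = 0.15,
    lib_sigma: float = 0.10,
    assays: Sequence[str] = ("rna", "ribo"),
    seed: int = 0,
) -> tuple[pd.DataFrame, DesignSpec]:
    """Replicate count matrices for differential testing.

    Per gene and library the count is Poisson with a lognormal
    replicate-level rate (biological noise, ``rep_sigma``) and a lognormal
    library-depth factor (``lib_sigma``); planted log2 shifts apply in
    condition 2.  Rates are scaled so the condition-1 mean count is
    ``mean_depth``.
    """
    rng = np.random.default_rng(seed)
    genes = truth.genes
    gene_ids = [g.gene_id for g in genes]
    columns, samplegroup, assay_type, replicate = [], [], [], []
    data = {}
    for assay in assays:
        if assay == "rna":
            base = np.array([g.transcription_level for g in genes])
            lfc = np.array([g.planted_lfc_rna for g in genes])
        elif assay == "ribo":
            base = np.array(
                [g.transcription_level * g.translational_efficiency for g in genes]
            )
            lfc = np.array([g.planted_lfc_ribo for g in genes])
        else:
            raise ValueError(f"unknown assay {assay!r}")
        positive = base[base > 0]
        scale = mean_depth / positive.mean() if positive.size else 1.0
        for cond in (1, 2):
            rate = base * scale * (2.0 ** lfc if cond == 2 else 1.0)
            for rep in range(1, n_replicates + 1):
                lib = math.exp(lib_sigma * rng.standard_normal())
                noise = np.exp(rep_sigma * rng.standard_normal(len(genes)))
                col = rng.poisson(rate * lib * noise)
                name = f"cond{cond}_{assay}_rep{rep}"
                columns.append(name)
                data[name] = col
                samplegroup.append(f"cond{cond}")
                assay_type.append(assay)
                replicate.append(f"rep{rep}")
    counts = pd.DataFrame(data, index=gene_ids)
    design = DesignSpec(samplegroup=samplegroup, assay_type=assay_type, replicate=replicate)
    return counts, design
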