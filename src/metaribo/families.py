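"""Protein-family machinery for small proteins.

Pairwise scoring is Smith-Waterman local alignment under BLOSUM62 with
affine gaps (open 11, extend 1); bit scores and e-values follow the
Karlin-Altschul statistics with the standard gapped BLOSUM62 parameters.
Identity is identical residues over local-alignment columns (internal gaps
count as columns; end gaps are outside a local alignment by construction).

Clustering follows the greedy incremental scheme of identity-threshold
clustering tools: sequences sorted by length (longest first), each either
joining the best qualifying existing cluster — identity with the
representative at or above the threshold, length ratio and
representative-coverage constraints satisfied — or founding a new one.
Cluster qualification scores candidates with an end-to-end global
alignment (see :func:`global_identity`); the local model above is for
database-search hits, where clipping to the best-scoring region is the
intended behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

# Gapped Karlin-Altschul parameters for BLOSUM62, gap open 11 / extend 1.
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass
class PairwiseHit:
    query_id: str
    subject_id: str
    identity: float
    aligned_query_fraction: float
    alignment_length: int
    score: float
    bit_score: float
    e_value: float


@dataclass
class ProteinFamily:
    family_id: str
    representative_id: str
    member_ids: list[str]
    member_proteins: dict[str, str]
    member_nt_sequences: Optional[dict[str, str]] = None
    synthesized: bool = False
    rnacode_support: Optional[bool] = None
    localization: str = "none"

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError(f"{self.family_id}: representative is not a member")
        rep_len = len(self.member_proteins[self.representative_id])
        for m in self.member_ids:
            if len(self.member_proteins[m]) > rep_len:
                raise ValueError(f"{self.family_id}: member {m} longer than representative")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _aligner()


def pairwise_align(
    a_protein: str,
    b_protein: str,
    a_id: str = "query",
    b_id: str = "subject",
    n_subjects: int = 1,
) -> PairwiseHit:
    """Best local alignment of two proteins with identity, coverage, e-value.

    The e-value search space is len(a) * len(b) * n_subjects, so a hit's
    significance reflects the size of the database it was searched against.
    """
    if not a_protein or not b_protein:
        raise ValueError("empty protein sequence")
    alignments = _ALIGNER.align(a_protein, b_protein)
    try:
        best = alignments[0]
    except IndexError:  # no positive-scoring local alignment exists
        return PairwiseHit(
            query_id=a_id, subject_id=b_id, identity=0.0,
            aligned_query_fraction=0.0, alignment_length=0, score=0.0,
            bit_score=0.0, e_value=math.inf,
        )
    score = float(best.score)
    cols = 0
    matches = 0
    q_aligned = 0
    qa, sa = best.aligned  # blocks of (start, end) pairs, no end gaps
    for (qs, qe), (ss, se) in zip(qa, sa):
        q_aligned += qe - qs
        for i in range(qe - qs):
            cols += 1
            if a_protein[qs + i] == b_protein[ss + i]:
                matches += 1
    # internal gap columns: unaligned residues inside the aligned spans
    if len(qa):
        q_span = qa[-1][1] - qa[0][0]
        s_span = sa[-1][1] - sa[0][0]
        cols += (q_span - q_aligned) + (s_span - sum(e - s for s, e in sa))
    align_len = cols
    identity = matches / cols if cols else 0.0
    bit = (KA_LAMBDA * score - math.log(KA_K)) / math.log(2.0)
    space = len(a_protein) * len(b_protein) * max(1, n_subjects)
    e_value = space * 2.0 ** (-bit)
    return PairwiseHit(
        query_id=a_id,
        subject_id=b_id,
        identity=identity,
        aligned_query_fraction=q_aligned / len(a_protein),
        alignment_length=align_len,
        score=score,
        bit_score=bit,
        e_value=e_value,
    )


_GLOBAL_ALIGNER = Align.PairwiseAligner()
_GLOBAL_ALIGNER.mode = "global"
_GLOBAL_ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
_GLOBAL_ALIGNER.open_gap_score = -11.0
_GLOBAL_ALIGNER.extend_gap_score = -1.0


def global_identity(a_protein: str, b_protein: str) -> tuple[float, float]:
    """(identity, coverage-of-longer) from an end-to-end global alignment.

    End gaps are penalized, so terminal mismatches stay aligned instead of
    being clipped — the identity denominator is the full alignment column
    count, mirroring how banded-global clustering tools score candidate
    pairs.  Coverage of the longer sequence is the span between its first
    and last aligned residue pair over its length.
    """
    best = _GLOBAL_ALIGNER.align(a_protein, b_protein)[0]
    qa, sa = best.aligned
    matches = 0
    aligned_pairs = 0
    for (qs, qe), (ss, se) in zip(qa, sa):
        for i in range(qe - qs):
            aligned_pairs += 1
            if a_protein[qs + i] == b_protein[ss + i]:
                matches += 1
    if not aligned_pairs:
        return 0.0, 0.0
    columns = best.length
    longer, blocks = (
        (a_protein, qa) if len(a_protein) >= len(b_protein) else (b_protein, sa)
    )
    span = blocks[-1][1] - blocks[0][0]
    return matches / columns, span / len(longer)


def greedy_cluster(
    proteins: Mapping[str, str],
    identity_c: float = 0.50,
    length_diff_cutoff: float = 0.0,
    long_coverage: float = 0.0,
) -> list[ProteinFamily]:
    """Greedy incremental identity clustering with representative matching.

    Candidates are processed longest-first (ties broken by id); each joins
    the qualifying cluster with the highest identity (best-match semantics)
    or founds a new cluster.  Qualification against a representative R for
    candidate Q requires identity >= identity_c, len(Q)/len(R) >=
    length_diff_cutoff, and the alignment covering >= long_coverage of R.
    """
    if not proteins:
        raise ValueError("no proteins to cluster")
    order = sorted(proteins, key=lambda pid: (-len(proteins[pid]), pid))
    clusters: list[dict] = []
    for pid in order:
        seq = proteins[pid]
        best_i, best_identity = None, -1.0
        for i, cl in enumerate(clusters):
            rep_seq = proteins[cl["rep"]]
            if len(seq) / len(rep_seq) < length_diff_cutoff:
                continue
            identity, rep_covered = global_identity(seq, rep_seq)
            if identity >= identity_c and rep_covered >= long_coverage:
                if identity > best_identity:
                    best_i, best_identity = i, identity
        if best_i is None:
            clusters.append({"rep": pid, "members": [pid]})
        else:
            clusters[best_i]["members"].append(pid)
    families = []
    for i, cl in enumerate(clusters, start=1):
        families.append(
            ProteinFamily(
                family_id=f"F{i:05d}",
                representative_id=cl["rep"],
                member_ids=cl["members"],
                member_proteins={m: proteins[m] for m in cl["members"]},
            )
        )
    return families


def assign_family_homologs(
    smorf_proteins: Mapping[str, str],
    family_representatives: Mapping[str, str],
    evalue_max: float = 0.05,
    length_window: tuple[float, float] = (0.90, 1.10),
) -> list[tuple[str, str, PairwiseHit]]:
    """Best significant reference-family hit per smORF.

    A hit qualifies when e-value <= evalue_max and the alignment length is
    within the stated window of the smORF protein length (90-110% by
    default); among qualifying hits the smallest e-value wins.
    """
    n_subjects = len(family_representatives)
    links: list[tuple[str, str, PairwiseHit]] = []
    for sid, sseq in smorf_proteins.items():
        best: Optional[PairwiseHit] = None
        best_fam: Optional[str] = None
        for fam_id, rep_seq in family_representatives.items():
            hit = pairwise_align(sseq, rep_seq, sid, fam_id, n_subjects=n_subjects)
            if hit.e_value > evalue_max:
                continue
            lo, hi = length_window
            if not (lo * len(sseq) <= hit.alignment_length <= hi * len(sseq)):
                continue
            if best is None or hit.e_value < best.e_value:
                best, best_fam = hit, fam_id
        if best is not None:
            links.append((sid, best_fam, best))
    return links


def family_synthesis_evidence(
    families: Sequence[ProteinFamily],
    homolog_links: Sequence[tuple[str, str]],
    translated_calls: Mapping[str, bool],
) -> list[ProteinFamily]:
    """Flag a family as synthesized when any linked smORF shows translation.

    ``homolog_links`` pairs (smorf_id, family_id); every linked smORF id
    must have a translation call.
    """
    by_id = {f.family_id: f for f in families}
    for smorf_id, family_id in homolog_links:
        if smorf_id not in translated_calls:
            raise ValueError(f"no translation call for linked smORF {smorf_id!r}")
        if family_id not in by_id:
            raise ValueError(f"unknown family id {family_id!r} in homolog links")
        if translated_calls[smorf_id]:
            by_id[family_id].synthesized = True
    return list(families)


def collapse_unique_dna(family: ProteinFamily) -> list[tuple[str, int]]:
    """Deduplicate member nucleotide sequences; (sequence, count), most common first."""
    if family.member_nt_sequences is None:
        raise ValueError(f"{family.family_id}: no nucleotide sequences recorded")
    counts: dict[str, int] = {}
    for m in family.member_ids:
        nt = family.member_nt_sequences.get(m)
        if nt is None:
            raise ValueError(f"{family.family_id}: member {m} lacks a nucleotide sequence")
        counts[nt] = counts.get(nt, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def domain_enrichment(
    n_population: int,
    k_population_with_domain: int,
    n_sample: int,
    k_sample_with_domain: int,
) -> float:
    """Upper-tail hypergeometric P(X >= k) for domain-bearing proteins."""
    if not (
        0 <= k_population_with_domain <= n_population
        and 0 <= k_sample_with_domain <= n_sample <= n_population
        and k_sample_with_domain <= k_population_with_domain
    ):
        raise ValueError("inconsistent hypergeometric counts")
    return float(
        stats.hypergeom.sf(
            k_sample_with_domain - 1, n_population, k_population_with_domain, n_sample
        )
    )
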