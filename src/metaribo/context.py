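"""Taxonomy propagation, genomic neighborhoods, and localization calls.

Reads are classified by the gene containing their 5' end: the read takes
the gene's taxon label, which puts metagenomic, transcriptomic and
ribosome-profiling libraries on the same footing regardless of how the
genes themselves were classified.  Neighborhoods are measured in gene
ranks along a contig (not nucleotides), and family localization follows a
membership-majority rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .families import ProteinFamily
from .mapping import AlignmentRecord
from .orfs import OrfRecord
from .quantify import ASSAYS, STRANDED_ASSAYS, FeatureIndex

logger = logging.getLogger("metaribo")


@dataclass
class TaxonAbundance:
    """Per-taxon fractions of classified reads, plus the unclassified share."""

    fractions: dict[str, float]
    n_classified: int
    n_unclassified: int

    @property
    def unclassified_fraction(self) -> float:
        total = self.n_classified + self.n_unclassified
        return self.n_unclassified / total if total else 0.0


def propagate_taxonomy(
    gene_taxa: Mapping[str, str],
    alignments: Iterable[AlignmentRecord],
    orfs: Sequence[OrfRecord],
    assay: str = "ribo",
) -> tuple[dict[str, str], TaxonAbundance]:
    """Classify each read by the taxon of the gene containing its 5' end.

    Reads landing in no gene are unclassified; reads in a gene whose id is
    missing from ``gene_taxa`` are counted unclassified with a logged
    tally.  When the 5' end falls in two same-strand overlapping genes with
    different taxa, the gene whose start codon is closer wins and the
    ambiguity is tallied.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}")
    index = FeatureIndex(orfs)
    read_taxa: dict[str, str] = {}
    taxon_counts: dict[str, int] = {}
    n_unclassified = 0
    n_missing = 0
    n_ambiguous = 0
    for a in alignments:
        strand = a.strand if assay in STRANDED_ASSAYS else None
        hits = index.hits(a.contig_id, a.five_prime(), strand)
        if not hits:
            n_unclassified += 1
            continue
        if len(hits) > 1:
            taxa_seen = {gene_taxa.get(o.orf_id) for o in hits}
            if len(taxa_seen) > 1:
                n_ambiguous += 1

            def start_distance(o: OrfRecord) -> int:
                anchor = o.start if o.strand == "+" else o.end
                return abs(a.five_prime() - anchor)

            hits = sorted(hits, key=lambda o: (start_distance(o), o.orf_id))
        gene = hits[0]
        taxon = gene_taxa.get(gene.orf_id)
        if taxon is None:
            n_missing += 1
            n_unclassified += 1
            continue
        read_taxa[a.read_id] = taxon
        taxon_counts[taxon] = taxon_counts.get(taxon, 0) + 1
    if n_missing:
        logger.info("%d reads hit genes with no taxon label", n_missing)
    if n_ambiguous:
        logger.info("%d reads fell in overlapping genes with differing taxa", n_ambiguous)
    n_classified = sum(taxon_counts.values())
    fractions = (
        {t: c / n_classified for t, c in sorted(taxon_counts.items())}
        if n_classified
        else {}
    )
    return read_taxa, TaxonAbundance(fractions, n_classified, n_unclassified)


def group_other(
    fractions: Mapping[str, float], threshold: float = 0.03
) -> dict[str, float]:
    """Merge taxa strictly below the abundance threshold into "Other"."""
    kept: dict[str, float] = {}
    other = 0.0
    for taxon, frac in sorted(fractions.items()):
        if frac < threshold:
            other += frac
        else:
            kept[taxon] = frac
    if other > 0:
        kept["Other"] = other
    return kept


# ---------------------------------------------------------------------------
# Genomic neighborhoods
# ---------------------------------------------------------------------------

@dataclass
class NeighborDomainReport:
    smorf_id: str
    neighbor_ids: list[str]
    domain_rows: pd.DataFrame  # columns: orf_id, domain_id, e_value, pssm_coverage


def neighborhood_scan(
    orfs_on_contig: Sequence[OrfRecord],
    smorf_id: str,
    domain_table: pd.DataFrame,
    max_genes: int = 10,
    evalue_max: float = 0.05,
    coverage_min: float = 0.80,
) -> NeighborDomainReport:
    """Domains of genes within ``max_genes`` ranks of a smORF on its contig.

    ``domain_table`` stands in for an external PSSM search: one row per
    (orf_id, domain_id, e_value, pssm_coverage).  Rows must pass
    e <= evalue_max and coverage >= coverage_min.  Rank distance ignores
    strand; position order is by start coordinate.
    """
    ordered = sorted(orfs_on_contig, key=lambda o: (o.start, o.end, o.orf_id))
    ids = [o.orf_id for o in ordered]
    if smorf_id not in ids:
        raise ValueError(f"smORF {smorf_id!r} not among the contig's genes")
    rank = ids.index(smorf_id)
    neighbor_ids = [
        ids[i]
        for i in range(max(0, rank - max_genes), min(len(ids), rank + max_genes + 1))
        if i != rank
    ]
    rows = domain_table[
        domain_table["orf_id"].isin(neighbor_ids)
        & (domain_table["e_value"] <= evalue_max)
        & (domain_table["pssm_coverage"] >= coverage_min)
    ].reset_index(drop=True)
    return NeighborDomainReport(smorf_id=smorf_id, neighbor_ids=neighbor_ids, domain_rows=rows)


def domain_cooccurrence(
    reports: Iterable[NeighborDomainReport],
) -> pd.DataFrame:
    """Count, per domain, how many smORF neighborhoods contain it."""
    tallies: dict[str, int] = {}
    n_smorfs = 0
    for rep in reports:
        n_smorfs += 1
        for dom in set(rep.domain_rows["domain_id"]):
            tallies[dom] = tallies.get(dom, 0) + 1
    out = pd.DataFrame(
        {"domain_id": list(tallies), "n_smorf_neighborhoods": list(tallies.values())}
    ).sort_values(
        ["n_smorf_neighborhoods", "domain_id"], ascending=[False, True]
    ).reset_index(drop=True)
    out.attrs["n_smorfs"] = n_smorfs
    return out


def localization_call(
    family: ProteinFamily,
    per_protein_flags: Mapping[str, tuple[bool, bool]],
    member_fraction: float = 0.80,
) -> str:
    """Family localization from per-member (secreted, transmembrane) flags.

    Returns "secreted", "transmembrane", "secreted+transmembrane" when both
    qualify, or "none".  The rule is inclusive: a fraction of flagged
    members >= ``member_fraction`` qualifies.
    """
    n = len(family.member_ids)
    n_sec = n_tm = 0
    for m in family.member_ids:
        if m not in per_protein_flags:
            raise ValueError(f"{family.family_id}: member {m} has no localization flags")
        sec, tm = per_protein_flags[m]
        n_sec += bool(sec)
        n_tm += bool(tm)
    labels = []
    if n_sec / n >= member_fraction:
        labels.append("secreted")
    if n_tm / n >= member_fraction:
        labels.append("transmembrane")
    return "+".join(labels) if labels else "none"
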