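"""Taxonomy propagation, Other-grouping, neighborhoods, localization."""

import numpy as np
import pandas as pd
import pytest

from metaribo import (
    AlignmentRecord,
    OrfRecord,
    ProteinFamily,
    SignalModel,
    build_index,
    filter_unique_perfect,
    group_other,
    localization_call,
    map_reads,
    neighborhood_scan,
    propagate_taxonomy,
    simulate_reads,
)
from metaribo.context import domain_cooccurrence


def _orf(oid, start, end, strand="+", contig="g"):
    aa = (end - start + 1) // 3 - 1
    return OrfRecord(oid, contig, start, end, strand, "M" * aa)


def test_all_reads_in_one_taxon():
    orf = _orf("o1", 10, 60)
    reads = [AlignmentRecord(f"r{i}", "g", 20 + i, "+", 10) for i in range(5)]
    read_taxa, ab = propagate_taxonomy({"o1": "X"}, reads, [orf], "ribo")
    assert set(read_taxa.values()) == {"X"}
    assert ab.fractions == {"X": 1.0}
    assert ab.unclassified_fraction == 0.0


def test_reads_outside_genes_unclassified():
    orf = _orf("o1", 10, 30)
    reads = [AlignmentRecord("r", "g", 100, "+", 10)]
    read_taxa, ab = propagate_taxonomy({"o1": "X"}, reads, [orf], "ribo")
    assert read_taxa == {}
    assert ab.fractions == {}
    assert ab.unclassified_fraction == 1.0


def test_missing_gene_label_counts_unclassified():
    orf = _orf("o1", 10, 60)
    reads = [AlignmentRecord("r", "g", 20, "+", 10)]
    _, ab = propagate_taxonomy({}, reads, [orf], "ribo")
    assert ab.n_unclassified == 1


def test_conservation_classified_plus_unclassified():
    orfs = [_orf("o1", 10, 60), _orf("o2", 100, 150)]
    rng = np.random.default_rng(0)
    reads = [
        AlignmentRecord(f"r{i}", "g", int(rng.integers(1, 200)), "+", 5)
        for i in range(300)
    ]
    _, ab = propagate_taxonomy({"o1": "X", "o2": "Y"}, reads, orfs, "ribo")
    assert ab.n_classified + ab.n_unclassified == len(reads)


def test_simulator_taxon_fractions_match_truth(small_community):
    genomes, truth = small_community
    reads, truth_records = simulate_reads(
        genomes, truth, SignalModel(), "ribo", 30, 5000, seed=5
    )
    aln = filter_unique_perfect(map_reads(build_index(genomes, 21), reads))
    gene_taxa = {g.gene_id: g.taxon for g in truth}
    read_taxa, ab = propagate_taxonomy(gene_taxa, aln, truth.orfs(), "ribo")
    # truth fractions from the known source positions of the same alignments
    truth_by_id = {r.read_id: r for r in truth_records}
    contig_taxon = {c.id: c.taxon for c in genomes}
    truth_counts: dict[str, int] = {}
    for rid in read_taxa:
        taxon = contig_taxon[truth_by_id[rid].contig_id]
        truth_counts[taxon] = truth_counts.get(taxon, 0) + 1
    n = sum(truth_counts.values())
    for taxon, frac in ab.fractions.items():
        assert frac == pytest.approx(truth_counts[taxon] / n)


def test_group_other_strict_threshold():
    grouped = group_other({"A": 0.5, "B": 0.48, "C": 0.02}, 0.03)
    assert grouped == {"A": 0.5, "B": 0.48, "Other": pytest.approx(0.02)}
    assert group_other({"A": 0.6, "B": 0.4}, 0.03) == {"A": 0.6, "B": 0.4}
    assert group_other({"A": 0.029}, 0.03) == {"Other": pytest.approx(0.029)}


def test_group_other_preserves_total():
    rng = np.random.default_rng(1)
    raw = rng.dirichlet(np.ones(20))
    fractions = {f"t{i}": float(v) for i, v in enumerate(raw)}
    grouped = group_other(fractions, 0.03)
    assert sum(grouped.values()) == pytest.approx(sum(fractions.values()), abs=1e-9)


def _contig_genes(n):
    return [_orf(f"o{i}", 1 + 100 * i, 60 + 100 * i) for i in range(n)]


def test_neighborhood_rank_window():
    genes = _contig_genes(25)
    table = pd.DataFrame(
        {
            "orf_id": [f"o{i}" for i in range(25)],
            "domain_id": ["D"] * 25,
            "e_value": [0.01] * 25,
            "pssm_coverage": [0.9] * 25,
        }
    )
    report = neighborhood_scan(genes, "o12", table, max_genes=10)
    assert "o2" in report.neighbor_ids and "o22" in report.neighbor_ids
    assert "o1" not in report.neighbor_ids and "o23" not in report.neighbor_ids
    assert "o12" not in report.neighbor_ids


def test_neighborhood_domain_filters():
    genes = _contig_genes(3)
    table = pd.DataFrame(
        {
            "orf_id": ["o0", "o2", "o2"],
            "domain_id": ["weak_cov", "weak_e", "good"],
            "e_value": [0.01, 0.06, 0.05],
            "pssm_coverage": [0.79, 0.9, 0.80],
        }
    )
    report = neighborhood_scan(genes, "o1", table)
    assert list(report.domain_rows["domain_id"]) == ["good"]


def test_neighborhood_unknown_smorf_and_lonely_contig():
    genes = _contig_genes(1)
    table = pd.DataFrame(columns=["orf_id", "domain_id", "e_value", "pssm_coverage"])
    report = neighborhood_scan(genes, "o0", table)
    assert report.neighbor_ids == []
    with pytest.raises(ValueError, match="ghost"):
        neighborhood_scan(genes, "ghost", table)


def test_domain_cooccurrence_counts_neighborhoods():
    genes = _contig_genes(5)
    table = pd.DataFrame(
        {
            "orf_id": ["o0", "o4"],
            "domain_id": ["TCS", "TCS"],
            "e_value": [0.01, 0.01],
            "pssm_coverage": [0.9, 0.9],
        }
    )
    reports = [neighborhood_scan(genes, s, table, max_genes=10) for s in ("o1", "o2")]
    summary = domain_cooccurrence(reports)
    assert summary.loc[0, "domain_id"] == "TCS"
    assert summary.loc[0, "n_smorf_neighborhoods"] == 2


def _family(members):
    return ProteinFamily(
        "F1", members[0], list(members), {m: "MKKLL" for m in members}
    )


@pytest.mark.parametrize(
    "flags,expected",
    [
        ({"m1": (True, False), "m2": (True, False), "m3": (True, False),
          "m4": (True, False), "m5": (False, False)}, "secreted"),  # 4/5 = 0.8
        ({"m1": (True, False), "m2": (True, False), "m3": (True, False),
          "m4": (False, False), "m5": (False, False)}, "none"),  # 3/5
        ({"m1": (False, True), "m2": (False, True), "m3": (False, True),
          "m4": (False, True), "m5": (False, True)}, "transmembrane"),
        ({"m1": (True, True), "m2": (True, True), "m3": (True, True),
          "m4": (True, True), "m5": (True, True)}, "secreted+transmembrane"),
    ],
)
def test_localization_membership_rule(flags, expected):
    fam = _family(sorted(flags))
    assert localization_call(fam, flags) == expected


def test_localization_missing_flag_is_error():
    fam = _family(["m1", "m2"])
    with pytest.raises(ValueError, match="m2"):
        localization_call(fam, {"m1": (True, False)})
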