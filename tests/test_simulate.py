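"""Simulator contracts: determinism, error-free reads, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaribo import (
    FamilySpec,
    SignalModel,
    build_index,
    filter_unique_perfect,
    map_reads,
    count_features,
    rpkm,
    revcomp,
    simulate_abundances,
    simulate_community,
    simulate_counts,
    simulate_reads,
)


def test_empty_community():
    genomes, truth = simulate_community(n_taxa=2, genome_length_nt=2000, n_genes=0, seed=1)
    assert len(truth) == 0
    assert len(genomes) == 2


def test_infeasible_packing_raises():
    with pytest.raises(ValueError, match="genome_length"):
        simulate_community(n_taxa=1, genome_length_nt=500, n_genes=20, seed=1)


def test_genome_determinism_for_fixed_seed():
    a = simulate_community(seed=3, n_genes=20, genome_length_nt=12_000)
    b = simulate_community(seed=3, n_genes=20, genome_length_nt=12_000)
    assert [c.sequence for c in a[0]] == [c.sequence for c in b[0]]
    assert a[1].to_frame().equals(b[1].to_frame())


def test_seed_isolation_reads_vs_genomes(small_community):
    genomes, truth = small_community
    sm = SignalModel()
    r1, _ = simulate_reads(genomes, truth, sm, "ribo", 30, 500, seed=10)
    r2, _ = simulate_reads(genomes, truth, sm, "ribo", 30, 500, seed=11)
    assert r1 != r2  # read stream moves with its own seed
    again = simulate_community(
        n_taxa=3, genome_length_nt=20_000, n_genes=40, smorf_fraction=0.3, seed=101
    )
    assert [c.sequence for c in again[0]] == [c.sequence for c in genomes]


def test_planted_gene_structure(small_community):
    _, truth = small_community
    for g in truth:
        assert g.nt_seq.startswith("ATG")
        assert g.nt_seq[-3:] in ("TAA", "TAG", "TGA")
        assert len(g.nt_seq) == 3 * (len(g.protein) + 1)
        if g.is_smorf:
            assert 5 <= len(g.protein) <= 50


def test_degenerate_lognormal_abundances(small_community):
    _, truth = small_community
    simulate_abundances(truth, lognormal_mu=1.0, lognormal_sigma=0.0, seed=1)
    levels = [g.transcription_level for g in truth]
    assert levels == pytest.approx([np.exp(1.0)] * len(levels))


def test_null_construction_and_planted_classes(small_community):
    _, truth = small_community
    simulate_abundances(truth, n_regulated=(0, 0, 0), seed=2)
    assert all(g.regulated_class == "none" for g in truth)
    assert all(g.planted_lfc_rna == 0 and g.planted_lfc_ribo == 0 for g in truth)
    simulate_abundances(truth, n_regulated=(3, 4, 2), lfc_magnitude=2.0, seed=3)
    classes = pd.Series([g.regulated_class for g in truth]).value_counts()
    assert classes.get("transcriptional", 0) == 3
    assert classes.get("translational", 0) == 4
    assert classes.get("both", 0) == 2
    for g in truth:
        if g.regulated_class == "translational":
            assert g.planted_lfc_rna == 0.0
            assert abs(g.planted_lfc_ribo) == 2.0


def test_too_many_regulated_raises(small_community):
    _, truth = small_community
    with pytest.raises(ValueError, match="regulated"):
        simulate_abundances(truth, n_regulated=(100, 0, 0), seed=1)


def test_reads_are_exact_substrings(small_community):
    genomes, truth = small_community
    reads, records = simulate_reads(
        genomes, truth, SignalModel(), "ribo", 30, 2000, seed=6
    )
    assert len(reads) == len(records) == 2000
    for (rid, seq), r in zip(reads, records):
        assert rid == r.read_id
        window = genomes[r.contig_id].sequence[r.pos - 1 : r.pos - 1 + r.length]
        assert seq == (window if r.strand == "+" else revcomp(window))


def test_zero_reads_and_negative_reads(small_community):
    genomes, truth = small_community
    reads, records = simulate_reads(genomes, truth, SignalModel(), "rna", 30, 0, seed=1)
    assert reads == [] and records == []
    with pytest.raises(ValueError, match="nonnegative"):
        simulate_reads(genomes, truth, SignalModel(), "rna", 30, -1, seed=1)


def test_zero_background_confines_ribo_reads(small_community):
    genomes, truth = small_community
    sm = SignalModel(background_rate=0.0)
    _, records = simulate_reads(genomes, truth, sm, "ribo", 30, 1000, seed=7)
    spans = {
        (g.contig_id, g.strand): [] for g in truth
    }
    for g in truth:
        spans[(g.contig_id, g.strand)].append((g.start, g.end))
    for r in records:
        five = r.five_prime()
        assert any(
            s <= five <= e for s, e in spans.get((r.contig_id, r.strand), [])
        ), "footprint outside every gene despite zero background"


def test_truth_frame_fractions_match_signal_model(small_community):
    genomes, truth = small_community
    sm = SignalModel(frame_weights=(0.6, 0.2, 0.2))
    _, records = simulate_reads(genomes, truth, sm, "ribo", 30, 50_000, seed=8)
    by_gene = {
        (g.contig_id, g.strand): g for g in truth
    }
    frames = np.zeros(3)
    for r in records:
        five = r.five_prime()
        for g in truth:
            if g.contig_id == r.contig_id and g.strand == r.strand and g.start <= five <= g.end:
                off = five - g.start if g.strand == "+" else g.end - five
                frames[off % 3] += 1
                break
    fracs = frames / frames.sum()
    assert np.allclose(fracs, (0.6, 0.2, 0.2), atol=0.01)


def test_fastq_determinism_bytewise(tmp_path, small_community):
    genomes, truth = small_community
    sm = SignalModel()
    p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
    simulate_reads(genomes, truth, sm, "ribo", 30, 300, seed=9, fastq_path=p1)
    simulate_reads(genomes, truth, sm, "ribo", 30, 300, seed=9, fastq_path=p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_rna_rpkm_recovers_transcription_levels(small_community):
    """Parameter recovery: RNA RPKM correlates with planted transcription."""
    genomes, truth = small_community
    reads, _ = simulate_reads(genomes, truth, SignalModel(), "rna", 30, 50_000, seed=12)
    aln = filter_unique_perfect(map_reads(build_index(genomes, 21), reads))
    orfs = truth.orfs()
    counts, lib = count_features(aln, orfs, "rna")
    lengths = pd.Series({o.orf_id: o.nt_length for o in orfs})
    values = rpkm(counts, lengths, lib)
    planted = pd.Series({g.gene_id: g.transcription_level for g in truth})
    r, _ = stats.pearsonr(np.log10(values + 1e-3), np.log10(planted))
    assert r > 0.9


def test_simulated_counts_shape_and_null_mean(small_community):
    _, truth = small_community
    simulate_abundances(truth, n_regulated=(0, 0, 0), seed=4)
    counts, design = simulate_counts(truth, n_replicates=3, mean_depth=50, seed=5)
    assert counts.shape == (len(truth), 12)
    design.validate_for("interaction")
    # global null: condition means agree within sampling error
    c1 = counts.loc[:, [c for c in counts if "cond1" in c]].to_numpy().mean()
    c2 = counts.loc[:, [c for c in counts if "cond2" in c]].to_numpy().mean()
    assert abs(c1 - c2) / c1 < 0.1
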