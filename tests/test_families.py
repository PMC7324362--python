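"""Alignment oracle, greedy clustering vs exhaustive rules, homolog filter,
family evidence, DNA collapse, hypergeometric enrichment."""

import math

import numpy as np
import pytest
from scipy import stats

from metaribo import (
    FamilySpec,
    ProteinFamily,
    assign_family_homologs,
    collapse_unique_dna,
    domain_enrichment,
    family_synthesis_evidence,
    greedy_cluster,
    pairwise_align,
    simulate_community,
)
from metaribo.families import KA_K, KA_LAMBDA, global_identity

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# -- pairwise alignment -----------------------------------------------------

def sw_affine_oracle(a, b, matrix, open_pen=11.0, ext_pen=1.0):
    """Textbook three-state affine Smith-Waterman, best local score."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]))
            X[i][j] = max(M[i - 1][j] - open_pen, X[i - 1][j] - ext_pen)
            Y[i][j] = max(M[i][j - 1] - open_pen, Y[i][j - 1] - ext_pen)
            best = max(best, M[i][j])
    return best


def test_identical_sequences_full_identity():
    hit = pairwise_align("MKKLLVVAG", "MKKLLVVAG")
    assert hit.identity == 1.0
    assert hit.aligned_query_fraction == 1.0


@pytest.mark.parametrize("seed", range(10))
def test_local_score_matches_dp_oracle(seed):
    from Bio.Align import substitution_matrices

    matrix = substitution_matrices.load("BLOSUM62")
    rng = np.random.default_rng(seed)
    a = "".join(np.array(list(AA20))[rng.integers(0, 20, size=int(rng.integers(4, 13)))])
    b = "".join(np.array(list(AA20))[rng.integers(0, 20, size=int(rng.integers(4, 13)))])
    hit = pairwise_align(a, b)
    assert hit.score == pytest.approx(sw_affine_oracle(a, b, matrix))


def test_evalue_calibration_on_unrelated_peptides():
    """Random 30-aa peptides vs a 1e5-subject search space are insignificant."""
    rng = np.random.default_rng(12)
    insignificant = 0
    trials = 60
    for _ in range(trials):
        a = "".join(np.array(list(AA20))[rng.integers(0, 20, size=30)])
        b = "".join(np.array(list(AA20))[rng.integers(0, 20, size=30)])
        hit = pairwise_align(a, b, n_subjects=100_000)
        insignificant += hit.e_value > 0.05
    assert insignificant >= 0.95 * trials


def test_evalue_scales_with_search_space():
    a = "MKKLLVVAGFTAEEA"
    small = pairwise_align(a, a, n_subjects=1)
    large = pairwise_align(a, a, n_subjects=1000)
    assert large.e_value == pytest.approx(1000 * small.e_value)
    assert small.bit_score == pytest.approx(
        (KA_LAMBDA * small.score - math.log(KA_K)) / math.log(2)
    )


# -- greedy clustering ------------------------------------------------------

def greedy_oracle(proteins, c, s_cutoff, al_cov):
    """Independent loop re-applying the clustering rules literally."""
    order = sorted(proteins, key=lambda p: (-len(proteins[p]), p))
    clusters = []
    for pid in order:
        candidates = []
        for ci, (rep, members) in enumerate(clusters):
            if len(proteins[pid]) / len(proteins[rep]) < s_cutoff:
                continue
            ident, cov = global_identity(proteins[pid], proteins[rep])
            if ident >= c and cov >= al_cov:
                candidates.append((ident, -ci))
        if candidates:
            _, neg = max(candidates)
            clusters[-neg][1].append(pid)
        else:
            clusters.append((pid, [pid]))
    return sorted(frozenset(m) for _, m in clusters)


def test_two_identical_proteins_one_cluster():
    fams = greedy_cluster({"a": "MKKLLVVAG", "b": "MKKLLVVAG"})
    assert len(fams) == 1
    assert sorted(fams[0].member_ids) == ["a", "b"]


def test_forty_percent_identity_splits_at_half():
    a = "M" + "".join(AA20[i % 20] for i in range(29))
    b = "M" + "".join(AA20[(i * 7 + 3) % 20] for i in range(29))
    ident, _ = global_identity(a, b)
    assert ident < 0.5
    assert len(greedy_cluster({"a": a, "b": b}, identity_c=0.5)) == 2


@pytest.mark.parametrize("seed", range(3))
def test_partition_matches_rule_oracle(seed):
    rng = np.random.default_rng(seed)
    proteins = {}
    # three ancestor groups with mutated members, <=25 sequences total
    for gi in range(3):
        anc = "M" + "".join(np.array(list(AA20))[rng.integers(0, 20, size=24)])
        for mi in range(7):
            seq = list(anc)
            for i in range(1, len(seq)):
                if rng.random() < 0.08:
                    seq[i] = AA20[rng.integers(0, 20)]
            proteins[f"g{gi}m{mi}"] = "".join(seq)
    fams = greedy_cluster(proteins, 0.5, 0.95, 0.95)
    got = sorted(frozenset(f.member_ids) for f in fams)
    assert got == greedy_oracle(proteins, 0.5, 0.95, 0.95)


def test_representative_is_longest_member():
    proteins = {"long": "MKKLLVVAGAAKKLL", "short": "MKKLLVVAGAAKKL"}
    (fam,) = greedy_cluster(proteins, 0.5, 0.5, 0.5)
    assert fam.representative_id == "long"


def test_planted_family_pairwise_identities(family_community):
    """10% pairwise divergence -> all member pairs >= 80% identity."""
    _, truth = family_community
    by_family: dict[str, list[str]] = {}
    for g in truth:
        by_family.setdefault(g.family_id, []).append(g.protein)
    for members in by_family.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ident, _ = global_identity(members[i], members[j])
                assert ident >= 0.80


def test_members_meet_identity_vs_representative(family_community):
    _, truth = family_community
    proteins = {g.gene_id: g.protein for g in truth}
    for fam in greedy_cluster(proteins, 0.5, 0.95, 0.95):
        rep = fam.member_proteins[fam.representative_id]
        for m in fam.member_ids:
            ident, _ = global_identity(fam.member_proteins[m], rep)
            assert ident >= 0.5


# -- homolog assignment -----------------------------------------------------

def test_homolog_filter_boundaries():
    rng = np.random.default_rng(3)
    rep = "M" + "".join(np.array(list(AA20))[rng.integers(0, 20, size=39)])
    links = assign_family_homologs({"q": rep}, {"fam1": rep})
    assert len(links) == 1
    sid, fam, hit = links[0]
    assert (sid, fam) == ("q", "fam1")
    assert hit.identity == 1.0
    # an 89%-length hit is rejected by the length window
    short_rep = rep[: int(0.6 * len(rep))]
    assert assign_family_homologs({"q": rep}, {"fam1": short_rep}) == []
    # an insignificant e-value is rejected no matter the identity
    assert (
        assign_family_homologs({"q": rep}, {"fam1": rep}, evalue_max=1e-300) == []
    )


def test_homolog_picks_best_evalue():
    rng = np.random.default_rng(5)
    q = "M" + "".join(np.array(list(AA20))[rng.integers(0, 20, size=29)])
    near = q[:-3] + "AAA"
    reps = {"exact": q, "near": near}
    links = assign_family_homologs({"q": q}, reps)
    assert links[0][1] == "exact"


# -- evidence, DNA collapse, enrichment -------------------------------------

def _family(members, nt=None):
    proteins = {m: "MKKLLVVAG" for m in members}
    return ProteinFamily(
        "F1", sorted(members)[0], list(members), proteins, member_nt_sequences=nt
    )


def test_synthesis_evidence_rules():
    fam = _family(["p1"])
    family_synthesis_evidence([fam], [("s1", "F1")], {"s1": True})
    assert fam.synthesized
    fam2 = _family(["p1"])
    family_synthesis_evidence([fam2], [("s1", "F1")], {"s1": False})
    assert not fam2.synthesized
    fam3 = _family(["p1"])
    family_synthesis_evidence([fam3], [], {})
    assert not fam3.synthesized
    with pytest.raises(ValueError, match="no translation call"):
        family_synthesis_evidence([_family(["p1"])], [("ghost", "F1")], {})


def test_synthesis_evidence_monotone():
    fam = _family(["p1"])
    family_synthesis_evidence([fam], [("s1", "F1")], {"s1": True})
    family_synthesis_evidence([fam], [("s2", "F1")], {"s2": False})
    assert fam.synthesized  # adding evidence never unsets the flag


def test_collapse_unique_dna():
    fam = _family(
        ["m1", "m2", "m3"], nt={"m1": "ATGTAA", "m2": "ATGTAA", "m3": "ATGTGA"}
    )
    assert collapse_unique_dna(fam) == [("ATGTAA", 2), ("ATGTGA", 1)]
    with pytest.raises(ValueError, match="lacks"):
        collapse_unique_dna(_family(["m1"], nt={}))


def test_collapse_recovers_planted_variants():
    _, truth = simulate_community(
        n_taxa=1,
        genome_length_nt=8000,
        n_genes=0,
        family_spec=FamilySpec(
            n_families=1, members_per_family=10, aa_divergence=0.1,
            protein_len_aa=25, nt_variants=3,
        ),
        seed=9,
    )
    members = [g for g in truth if g.family_id == "PF0001"]
    fam = ProteinFamily(
        "PF0001",
        max((g.gene_id for g in members), key=lambda gid: (len(next(x.protein for x in members if x.gene_id == gid)), gid)),
        [g.gene_id for g in members],
        {g.gene_id: g.protein for g in members},
        member_nt_sequences={g.gene_id: g.nt_seq for g in members},
    )
    uniq = collapse_unique_dna(fam)
    assert len(uniq) == 3
    assert sorted(c for _, c in uniq) == [3, 3, 4]


def test_hypergeometric_closed_form():
    assert domain_enrichment(10, 5, 5, 5) == pytest.approx(1 / 252)
    assert domain_enrichment(10, 5, 5, 0) == 1.0


@pytest.mark.parametrize("seed", range(5))
def test_hypergeometric_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    n_pop = int(rng.integers(5, 21))
    k_pop = int(rng.integers(0, n_pop + 1))
    n_sam = int(rng.integers(1, n_pop + 1))
    k_obs = int(rng.integers(0, min(k_pop, n_sam) + 1))
    total = math.comb(n_pop, n_sam)
    tail = sum(
        math.comb(k_pop, k) * math.comb(n_pop - k_pop, n_sam - k)
        for k in range(k_obs, min(k_pop, n_sam) + 1)
        if n_sam - k <= n_pop - k_pop
    )
    assert domain_enrichment(n_pop, k_pop, n_sam, k_obs) == pytest.approx(tail / total)


def test_inconsistent_counts_rejected():
    with pytest.raises(ValueError):
        domain_enrichment(10, 11, 5, 2)
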