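"""Seed-and-extend alignment: spaced seeds, searches, gates, attribution."""

import numpy as np
import pytest

from metapepiter.align import (
    GateParams,
    NT_SCORING,
    PROTEIN_SCORING,
    SeedIndex,
    SpacedSeed,
    abundance_assign,
    build_seed_index,
    nucleotide_search,
    passes_aa_gate,
    passes_nt_gate,
    protein_search,
    smith_waterman,
    translated_search,
    AlignmentHit,
)
from metapepiter.seqdb import SequenceRecord, reverse_complement

from conftest import random_dna, random_protein


def _dna(i, seq):
    return SequenceRecord(f"s{i}", seq, alphabet="dna")


def _aa(i, seq):
    return SequenceRecord(f"p{i}", seq, alphabet="protein")


def _mutate(rng, seq, n_subs):
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        out[pos] = "ACGT".replace(out[pos], "")[int(rng.integers(3))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Smith-Waterman oracle

def test_sw_exact_match():
    h = smith_waterman("ACGT", "ACGT", NT_SCORING)
    assert h.score == 4 and h.identity == 1.0 and h.aligned_len == 4


def test_sw_no_similarity():
    h = smith_waterman("AAAA", "TTTT", NT_SCORING)
    assert h.score == 0


def test_sw_score_symmetric(rng):
    for _ in range(10):
        a, b = random_dna(rng, 60), random_dna(rng, 60)
        assert smith_waterman(a, b, NT_SCORING).score == smith_waterman(b, a, NT_SCORING).score


def test_sw_identity_counts_round_to_integers(rng):
    a = random_dna(rng, 120)
    b = _mutate(rng, a, 15)
    h = smith_waterman(a, b, NT_SCORING)
    n_ident = h.identity * h.aligned_len
    assert abs(n_ident - round(n_ident)) < 1e-9


# ---------------------------------------------------------------------------
# Spaced seeds and the index

def test_default_seed_shape():
    s = SpacedSeed()
    assert s.weight == 12 and s.span == 21
    assert s.pattern[0] == "1" and s.pattern[-1] == "1"


def test_seed_pattern_validation():
    with pytest.raises(ValueError):
        SpacedSeed("0110")
    with pytest.raises(ValueError):
        SpacedSeed("1a1")


def test_index_posting_counts(rng):
    seed = SpacedSeed()
    subjects = [_dna(i, random_dna(rng, n)) for i, n in enumerate([21, 50, 10, 300])]
    idx = build_seed_index(subjects, seed)
    assert idx.n_postings == sum(max(0, len(s.seq) - seed.span + 1) for s in subjects)


def test_index_own_window_lookup(rng):
    from metapepiter.align import _seed_keys, encode_dna

    seed = SpacedSeed()
    subj = _dna(0, random_dna(rng, 100))
    idx = build_seed_index([subj], seed)
    keys = _seed_keys(encode_dna(subj.seq), seed)
    qoff, sidx, soff = idx.lookup(keys[10:11])
    assert 10 in soff


# ---------------------------------------------------------------------------
# Nucleotide search

def test_nucleotide_search_exact_copy(rng):
    subjects = [_dna(i, random_dna(rng, 600)) for i in range(10)]
    q = SequenceRecord("q", subjects[4].seq[100:300] )
    hits = nucleotide_search(q, SeedIndex(subjects))
    best = max(hits, key=lambda h: h.score)
    assert best.subject_id == "s4" and best.identity == 1.0 and best.aligned_len >= 200
    assert best.s_start == 100 and best.s_end == 300


def test_nucleotide_search_reverse_complement_strand(rng):
    subjects = [_dna(i, random_dna(rng, 600)) for i in range(5)]
    q = SequenceRecord("q", reverse_complement(subjects[2].seq[50:450]))
    hits = nucleotide_search(q, SeedIndex(subjects))
    best = max(hits, key=lambda h: h.score)
    assert best.subject_id == "s2" and best.strand == "-" and best.identity == 1.0


def test_nucleotide_search_strand_flip_symmetry(rng):
    subjects = [_dna(i, random_dna(rng, 500)) for i in range(5)]
    q = SequenceRecord("q", _mutate(rng, subjects[1].seq[100:400], 20))
    qrc = SequenceRecord("q", reverse_complement(q.seq))
    idx = SeedIndex(subjects)
    fwd = {(h.subject_id, h.s_start, h.s_end, h.strand, h.score) for h in nucleotide_search(q, idx)}
    rev = {(h.subject_id, h.s_start, h.s_end, h.strand, h.score) for h in nucleotide_search(qrc, idx)}
    flip = {"+": "-", "-": "+"}
    assert {(s, a, b, flip[st], sc) for s, a, b, st, sc in fwd} == rev


def test_nucleotide_search_agrees_with_sw_oracle(rng):
    """Seeded search must reproduce the optimal local alignment whenever an
    exact spaced-seed match lies on the optimal (substitution-only) diagonal."""
    seed = SpacedSeed()
    found, eligible = 0, 0
    for _ in range(30):
        s = random_dna(rng, 400)
        start = int(rng.integers(0, 150))
        region = s[start : start + 200]
        q = random_dna(rng, 40) + _mutate(rng, region, int(rng.integers(0, 60))) + random_dna(rng, 40)
        subj = _dna(0, s)
        oracle = smith_waterman(q, s, NT_SCORING)
        if oracle.evalue > GateParams().max_evalue:
            continue
        d = oracle.s_start - oracle.q_start
        ones = seed.ones
        has_seed = any(
            all(q[qo + p] == s[qo + d + p] for p in ones)
            for qo in range(oracle.q_start, oracle.q_end - seed.span + 1)
        )
        if not has_seed:
            continue
        eligible += 1
        hits = nucleotide_search(SequenceRecord("q", q), SeedIndex([subj], seed))
        if any(
            h.score == oracle.score
            and (h.q_start, h.q_end, h.s_start, h.s_end) == (oracle.q_start, oracle.q_end, oracle.s_start, oracle.s_end)
            for h in hits
        ):
            found += 1
    assert eligible >= 10
    assert found == eligible


# ---------------------------------------------------------------------------
# Gates

@pytest.mark.parametrize(
    "identity,length,expected",
    [(1.0, 200, True), (0.60, 140, False), (0.49, 500, False), (0.50, 150, True)],
)
def test_nt_gate(identity, length, expected):
    hit = AlignmentHit("q", "s", 0, length, 0, length, identity=identity, aligned_len=length)
    assert passes_nt_gate(hit, GateParams()) is expected


@pytest.mark.parametrize(
    "identity,length,expected",
    [(0.80, 50, True), (0.79, 50, False), (0.80, 49, False), (0.95, 60, True)],
)
def test_aa_gate(identity, length, expected):
    hit = AlignmentHit("q", "s", 0, length, 0, length, identity=identity, aligned_len=length)
    assert passes_aa_gate(hit, GateParams()) is expected


def test_gates_monotone(rng):
    gates = GateParams()
    for _ in range(50):
        ident = float(rng.uniform(0.4, 1.0))
        ln = int(rng.integers(50, 400))
        h = AlignmentHit("q", "s", 0, ln, 0, ln, identity=ident, aligned_len=ln)
        if passes_nt_gate(h, gates):
            better = AlignmentHit(
                "q", "s", 0, ln + 10, 0, ln + 10,
                identity=min(1.0, ident + 0.05), aligned_len=ln + 10,
            )
            assert passes_nt_gate(better, gates)


def test_evalue_decreasing_in_score():
    evs = [NT_SCORING.evalue(s, 500, 10000) for s in range(10, 100, 10)]
    assert all(a > b for a, b in zip(evs, evs[1:]))


# ---------------------------------------------------------------------------
# Translated and protein search

def test_translated_search_finds_embedded_gene_frame(rng):
    from metapepiter.simdata import SimParams, generate_community

    comm = generate_community(SimParams(n_genomes=1, genes_per_genome=8, rng_seed=11))
    proteins = comm.protein_records()
    correct = 0
    for t in range(20):
        gene = comm.genes[int(rng.integers(len(comm.genes)))]
        offset = int(rng.integers(0, 3))
        strand = "+" if rng.random() < 0.5 else "-"
        insert = gene.cds if strand == "+" else reverse_complement(gene.cds)
        trace = SequenceRecord(
            f"t{t}", random_dna(rng, 30 + offset) + insert + random_dna(rng, 30)
        )
        hits = translated_search(trace, proteins)
        if not hits:
            continue
        best = min(hits, key=lambda h: (h.evalue, -h.score))
        if best.subject_id == gene.gene_id and best.strand == strand:
            correct += 1
    assert correct == 20


def test_translated_search_identity_one_for_verbatim_region(rng):
    prot = _aa(0, random_protein(rng, 120))
    # reverse-translate a 60-aa region with one codon per residue
    from metapepiter.simdata import _codons_for

    dna = "".join(_codons_for(a)[0] for a in prot.seq[20:80])
    trace = SequenceRecord("t", "G" + dna + random_dna(rng, 20))  # frame +2
    hits = translated_search(trace, [prot])
    best = max(hits, key=lambda h: h.score)
    # the verbatim 60-aa block must be matched exactly; local extension may
    # add a few positive-scoring (non-identical) columns at the edges
    assert best.frame == 2 and best.n_identical >= 60
    assert best.s_start <= 20 and best.s_end >= 80


def test_protein_search_identical_ranks_first(rng):
    subjects = [_aa(i, random_protein(rng, 80)) for i in range(12)]
    q = SequenceRecord("q", subjects[5].seq, alphabet="protein")
    hits = protein_search(q, subjects)
    assert hits and hits[0].subject_id == "p5" and hits[0].identity == 1.0


def test_protein_search_empty_subjects():
    q = _aa(0, "MKTAYIAKQRQISFVK")
    assert protein_search(q, []) == []


def test_protein_search_ranking_matches_exhaustive_sw(rng):
    base = random_protein(rng, 100)
    subjects = []
    for i in range(10):
        s = list(base)
        for pos in rng.choice(100, size=5 + 3 * i, replace=False):
            s[pos] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(20))]
        subjects.append(_aa(i, "".join(s)))
    q = SequenceRecord("q", base, alphabet="protein")
    hits = protein_search(q, subjects)
    exhaustive = sorted(
        (smith_waterman(q.seq, s.seq, PROTEIN_SCORING, "q", s.id) for s in subjects),
        key=lambda h: (-h.score, h.subject_id),
    )
    assert [h.subject_id for h in hits] == [h.subject_id for h in exhaustive]


# ---------------------------------------------------------------------------
# Abundance / lineage attribution

def test_abundance_assign_modes(rng):
    genomes = [
        SequenceRecord(f"g{i}", random_dna(rng, 3000), alphabet="dna", organism=f"OTU{i}")
        for i in range(3)
    ]
    idx = SeedIndex(genomes)
    verbatim = SequenceRecord("t1", genomes[1].seq[500:900])
    for mode in ("ani95", "mining"):
        org, hit = abundance_assign(verbatim, idx, mode=mode)
        assert org == "OTU1" and hit.identity == 1.0

    drifted = SequenceRecord("t2", _mutate(rng, genomes[1].seq[500:900], 30))  # ~92.5% id
    org95, hit95 = abundance_assign(drifted, idx, mode="ani95")
    orgmine, _ = abundance_assign(drifted, idx, mode="mining")
    assert org95 is None and 0.90 < hit95.identity < 0.95
    assert orgmine == "OTU1"

    far = SequenceRecord("t3", _mutate(rng, genomes[1].seq[500:900], 70))  # ~82% id
    assert abundance_assign(far, idx, mode="ani95")[0] is None
    assert abundance_assign(far, idx, mode="mining")[0] is None
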