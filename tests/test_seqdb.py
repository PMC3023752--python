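"""Sequence-database construction: FASTA I/O, redundancy, decoys,
translation, ORF filtering and tryptic digestion."""

import re
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metapepiter.seqdb import (
    DigestParams,
    FastaParseError,
    OrfFilterParams,
    SequenceRecord,
    build_search_db,
    digest,
    make_decoy,
    minimize_redundancy,
    passes_orf_filter,
    read_fasta,
    reverse_complement,
    six_frame_translate,
    split_at_stops,
    three_frame_translate,
    write_fasta,
)

from conftest import random_dna, random_protein


# ---------------------------------------------------------------------------
# FASTA I/O

def test_read_fasta_basic(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">a\nATGC\n")
    (rec,) = read_fasta(p, "dna")
    assert rec.id == "a" and rec.seq == "ATGC"


def test_read_fasta_wrapped_lines(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">a some description\nAT\nGC\n")
    (rec,) = read_fasta(p, "dna")
    assert rec.seq == "ATGC"


def test_read_fasta_alphabet_violation(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">a\nATB\n")
    with pytest.raises(ValueError, match="'a'"):
        read_fasta(p, "dna")


def test_read_fasta_malformed_names_line(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text("ATGC\n>a\nATGC\n")
    with pytest.raises(FastaParseError, match="line 1"):
        read_fasta(p, "dna")


def test_fasta_roundtrip_preserves_attributes(tmp_path):
    recs = [
        SequenceRecord(
            id="p1",
            seq="MKTAYIAK",
            alphabet="protein",
            organism="OTU01",
            subspecies_group="g1",
            source_frame=-2,
            source_trace_id="t9",
        ),
        SequenceRecord(id="p2", seq="MK" * 50, alphabet="protein", is_decoy=True),
    ]
    path = tmp_path / "db.fasta"
    write_fasta(recs, path)
    back = read_fasta(path, "protein")
    assert [(r.id, r.seq, r.organism, r.subspecies_group, r.is_decoy, r.source_frame, r.source_trace_id) for r in back] == [
        (r.id, r.seq, r.organism, r.subspecies_group, r.is_decoy, r.source_frame, r.source_trace_id) for r in recs
    ]


# ---------------------------------------------------------------------------
# Redundancy minimization

def _prot(i, seq, group):
    return SequenceRecord(id=f"p{i}", seq=seq, alphabet="protein", subspecies_group=group)


def test_minimize_redundancy_within_group_collapses():
    out = minimize_redundancy([_prot(1, "MKTA", "reuteri"), _prot(2, "MKTA", "reuteri")])
    assert len(out) == 1
    assert set(out[0].member_ids) == {"p1", "p2"}


def test_minimize_redundancy_across_groups_kept():
    out = minimize_redundancy([_prot(1, "MKTA", "reuteri"), _prot(2, "MKTA", "gasseri")])
    assert len(out) == 2


def test_minimize_redundancy_distinct_and_idempotent(rng):
    recs = [_prot(i, random_protein(rng, 20), "g") for i in range(30)]
    once = minimize_redundancy(recs)
    assert len(once) == 30
    assert minimize_redundancy(once) == once
    # union of member ids is preserved
    assert {m for r in once for m in r.member_ids} == {r.id for r in recs}


# ---------------------------------------------------------------------------
# Decoys

def test_make_decoy_reverses_and_tags():
    (d,) = make_decoy([_prot(1, "MKTA", "g")])
    assert d.seq == "ATKM" and d.is_decoy and d.id == "REV_p1"


def test_make_decoy_palindrome_still_flagged():
    (d,) = make_decoy([_prot(1, "ACA", "g")])
    assert d.seq == "ACA" and d.is_decoy


def test_make_decoy_refuses_double_reversal(rng):
    db = [_prot(i, random_protein(rng, 15), "g") for i in range(5)]
    decoys = make_decoy(db)
    with pytest.raises(ValueError):
        make_decoy(decoys)
    # reversing a decoy's sequence recovers the original
    assert [d.seq[::-1] for d in decoys] == [r.seq for r in db]


def test_decoy_composition_matches_targets(rng):
    db = [_prot(i, random_protein(rng, 40), "g") for i in range(20)]
    decoys = make_decoy(db)
    assert sorted(map(len, decoys)) == sorted(map(len, db))
    assert Counter("".join(d.seq for d in decoys)) == Counter("".join(r.seq for r in db))


# ---------------------------------------------------------------------------
# Translation

def test_six_frame_examples():
    frames = six_frame_translate(SequenceRecord("x", "ATGAAA"))
    assert frames[1] == "MK"
    assert frames[-1] == "FH"  # revcomp TTTCAT -> F,H


def test_reverse_strand_frames_equal_forward_frames_of_revcomp(rng):
    seq = random_dna(rng, 100)
    f = six_frame_translate(SequenceRecord("x", seq))
    g = six_frame_translate(SequenceRecord("y", reverse_complement(seq)))
    assert {f[-1], f[-2], f[-3]} == {g[1], g[2], g[3]}


def test_three_frame_partition(rng):
    rec = SequenceRecord("x", random_dna(rng, 80))
    plus = three_frame_translate(rec, "+")
    minus = three_frame_translate(rec, "-")
    assert {**plus, **minus} == six_frame_translate(rec)
    assert three_frame_translate(SequenceRecord("y", "TTTCAT"), "-")[-1] == "MK"


@pytest.mark.parametrize("length", [3, 10, 47, 100])
def test_forward_frame_residue_counts(rng, length):
    rec = SequenceRecord("x", random_dna(rng, length))
    frames = six_frame_translate(rec)
    total = sum(len(frames[f]) for f in (1, 2, 3))
    assert total == length // 3 + (length - 1) // 3 + (length - 2) // 3


def test_ambiguous_codon_translates_to_x():
    frames = six_frame_translate(SequenceRecord("x", "ATNGGG"))
    assert frames[1] == "XG"


def test_too_short_record_warns_and_returns_nothing():
    with pytest.warns(UserWarning):
        assert six_frame_translate(SequenceRecord("x", "AT")) == {}


@pytest.mark.parametrize(
    "translation,expected",
    [("MK*AAAA", ["MK", "AAAA"]), ("***", []), ("MKNOSTOPS", ["MKNOSTOPS"])],
)
def test_split_at_stops(translation, expected):
    assert split_at_stops(translation) == expected


# ---------------------------------------------------------------------------
# ORF filter

def _oracle_orf(frag, min_len=25, min_internal=5):
    """Direct enumeration of the fully-tryptic-stretch condition."""
    if len(frag) < min_len:
        return False
    n = len(frag)
    for i in range(n):
        if frag[i] not in "KR" or (i + 1 < n and frag[i + 1] == "P"):
            continue
        for j in range(i + 1 + min_internal, n):
            if frag[j] not in "KR" or (j + 1 < n and frag[j + 1] == "P"):
                continue
            interior = frag[i + 1 : j]
            ok = all(
                c not in "KR" or (i + 1 + p + 1 < n and frag[i + 1 + p + 1] == "P")
                for p, c in enumerate(interior)
            )
            if ok:
                return True
    return False


@pytest.mark.parametrize(
    "frag,expected",
    [
        ("A" * 24, False),                      # below the 25-residue minimum
        ("A" * 30, False),                      # no tryptic boundary at all
        ("A" * 10 + "K" + "A" * 5 + "K" + "A" * 13, True),
        ("A" * 10 + "KP" + "A" * 5 + "K" + "A" * 13, False),  # left boundary blocked by P
    ],
)
def test_orf_filter_examples(frag, expected):
    assert passes_orf_filter(frag) is expected


def test_orf_filter_agrees_with_enumeration_oracle(rng):
    # K/R/P-enriched alphabet stresses the boundary conditions
    alphabet = "KKRRPPACDEFGHILMNQSTVWY"
    for _ in range(2000):
        frag = random_protein(rng, int(rng.integers(20, 45)), alphabet)
        assert passes_orf_filter(frag) == _oracle_orf(frag), frag


def test_orf_filter_terminal_boundary_switch():
    # tryptic stretch at the very start: fails strict mode, passes permissive
    frag = "AAAAAK" + "A" * 30
    assert not passes_orf_filter(frag)
    assert passes_orf_filter(frag, OrfFilterParams(accept_terminal_boundaries=True))


# ---------------------------------------------------------------------------
# Naive translation database

def test_build_search_db_matches_bruteforce(rng):
    records = [SequenceRecord(f"t{i}", random_dna(rng, 300)) for i in range(20)]
    db = build_search_db(records)
    expected = 0
    for rec in records:
        for frame, tr in six_frame_translate(rec).items():
            expected += sum(passes_orf_filter(f) for f in split_at_stops(tr))
    assert len(db) == expected
    assert all(r.source_trace_id is not None and r.source_frame is not None for r in db)


def test_build_search_db_recovers_embedded_gene(rng):
    from metapepiter.simdata import SimParams, generate_community

    comm = generate_community(SimParams(n_genomes=1, genes_per_genome=1, rng_seed=3))
    gene = comm.genes[0]
    trace = SequenceRecord("t0", random_dna(rng, 50) + gene.cds + random_dna(rng, 50))
    db = build_search_db([trace])
    assert any(gene.protein[1:] in r.seq for r in db)  # beyond the start Met


# ---------------------------------------------------------------------------
# Digestion

def test_digest_examples():
    loose = DigestParams(missed_cleavages=0, min_peptide_len=1, max_peptide_len=100)
    assert [p for p, _s, _e in digest("MKRAPK", loose)] == ["MK", "R", "APK"]
    assert [p for p, _s, _e in digest("PEPTIDE", loose)] == ["PEPTIDE"]
    one = DigestParams(missed_cleavages=1, min_peptide_len=1, max_peptide_len=100)
    assert {p for p, _s, _e in digest("AKCK", one)} == {"AK", "CK", "AKCK"}


@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_digest_zero_missed_reconstructs_protein(protein):
    loose = DigestParams(missed_cleavages=0, min_peptide_len=1, max_peptide_len=1000)
    peps = digest(protein, loose)
    assert "".join(p for p, _s, _e in peps) == protein
    assert all(protein[s:e] == p for p, s, e in peps)
    for p, _s, _e in peps:
        for i in range(len(p) - 1):
            assert not (p[i] in "KR" and p[i + 1] != "P")
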