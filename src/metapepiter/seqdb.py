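"""Sequence database construction.

FASTA I/O with attribute-carrying deflines, subspecies-level redundancy
minimization, reversed-sequence decoy generation, six-/three-frame naive
translation with stop-splitting, tryptic ORF filtering and in-silico tryptic
digestion.  These are the building blocks for both the curated reference
("synthetic metaproteome") search space and the trace-derived second-round
search space.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

__all__ = [
    "SequenceRecord",
    "OrfFilterParams",
    "DigestParams",
    "read_fasta",
    "write_fasta",
    "minimize_redundancy",
    "make_decoy",
    "reverse_complement",
    "translate_frame",
    "six_frame_translate",
    "three_frame_translate",
    "split_at_stops",
    "tryptic_pattern",
    "passes_orf_filter",
    "build_search_db",
    "digest",
]

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZUO*")

STOP = "*"
DECOY_TAG = "REV_"

# Bacterial/archaeal code (translation table 11).  Naive translation: no
# start-codon logic, stops emitted as '*', any codon containing an ambiguity
# character maps to 'X'.
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODON_MAP: dict[str, str] = dict(_TABLE11.forward_table)
for _c in _TABLE11.stop_codons:
    _CODON_MAP[_c] = STOP

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


@dataclass
class SequenceRecord:
    """A named nucleotide or protein sequence with provenance.

    ``source_frame`` is in {-3..-1, +1..+3} for translated records;
    ``source_trace_id`` links a translation back to the trace it came from.
    ``member_ids`` lists every original id collapsed into this record by
    redundancy minimization (always contains ``id`` itself).
    """

    id: str
    seq: str
    alphabet: str = "dna"  # "dna" | "protein"
    organism: str = ""
    subspecies_group: str = ""
    is_decoy: bool = False
    source_frame: int | None = None
    source_trace_id: str | None = None
    member_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        bad = set(self.seq) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid {self.alphabet} symbol(s) "
                f"{''.join(sorted(bad))!r}"
            )
        if not self.member_ids:
            self.member_ids = (self.id,)

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# FASTA I/O.  Deflines are ">id key=value key=value ..."; recognised keys are
# organism=, group=, decoy=1, frame=, trace=, members= (comma-joined).

def _defline(rec: SequenceRecord) -> str:
    parts = [rec.id]
    if rec.organism:
        parts.append(f"organism={rec.organism}")
    if rec.subspecies_group:
        parts.append(f"group={rec.subspecies_group}")
    if rec.is_decoy:
        parts.append("decoy=1")
    if rec.source_frame is not None:
        parts.append(f"frame={rec.source_frame:+d}")
    if rec.source_trace_id is not None:
        parts.append(f"trace={rec.source_trace_id}")
    if rec.member_ids != (rec.id,):
        parts.append("members=" + ",".join(rec.member_ids))
    return " ".join(parts)


def _record_from_defline(defline: str, seq: str, alphabet: str) -> SequenceRecord:
    fields = defline.split()
    rid, attrs = fields[0], {}
    for tok in fields[1:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            attrs[k] = v
    members = tuple(attrs["members"].split(",")) if "members" in attrs else ()
    frame = int(attrs["frame"]) if "frame" in attrs else None
    return SequenceRecord(
        id=rid,
        seq=seq,
        alphabet=alphabet,
        organism=attrs.get("organism", ""),
        subspecies_group=attrs.get("group", ""),
        is_decoy=attrs.get("decoy") == "1",
        source_frame=frame,
        source_trace_id=attrs.get("trace"),
        member_ids=members,
    )


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, order preserved.

    Raises :class:`FastaParseError` (naming the offending line) for
    structural problems and ``ValueError`` (naming the record) for alphabet
    violations.
    """
    records: list[SequenceRecord] = []
    defline: str | None = None
    chunks: list[str] = []
    def_lineno = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if defline is not None:
                    if not chunks:
                        raise FastaParseError(
                            f"{path}: line {def_lineno}: entry with no sequence"
                        )
                    records.append(
                        _record_from_defline(defline, "".join(chunks), alphabet)
                    )
                defline, chunks, def_lineno = line[1:].strip(), [], lineno
            elif defline is None:
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first '>' header"
                )
            else:
                chunks.append(line)
    if defline is not None:
        if not chunks:
            raise FastaParseError(f"{path}: line {def_lineno}: entry with no sequence")
        records.append(_record_from_defline(defline, "".join(chunks), alphabet))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{_defline(rec)}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Redundancy minimization and decoys.

def minimize_redundancy(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Collapse exact duplicate protein sequences within a subspecies group.

    A sequence shared by two strains of the same subspecies enters the
    database once (carrying both ids); the same sequence appearing in a
    different group is kept separately.  Idempotent; order of first
    occurrence preserved.
    """
    out: list[SequenceRecord] = []
    index: dict[tuple[str, str], int] = {}
    for rec in records:
        key = (rec.subspecies_group, rec.seq.upper())
        if key in index:
            keeper = out[index[key]]
            merged = keeper.member_ids + tuple(
                m for m in rec.member_ids if m not in keeper.member_ids
            )
            out[index[key]] = replace(keeper, member_ids=merged)
        else:
            index[key] = len(out)
            out.append(rec)
    return out


def make_decoy(records: Sequence[SequenceRecord], tag: str = DECOY_TAG) -> list[SequenceRecord]:
    """Reverse each protein sequence; prefix ids with ``tag``; flag as decoy."""
    decoys = []
    for rec in records:
        if rec.is_decoy:
            raise ValueError(f"record {rec.id!r} is already a decoy; refusing to re-reverse")
        decoys.append(
            replace(
                rec,
                id=tag + rec.id,
                seq=rec.seq[::-1],
                is_decoy=True,
                member_ids=tuple(tag + m for m in rec.member_ids),
            )
        )
    return decoys


# ---------------------------------------------------------------------------
# Naive translation.

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_frame(dna: str, offset: int) -> str:
    """Translate one reading frame (0-based ``offset`` on the given strand)."""
    out = []
    for i in range(offset, len(dna) - 2, 3):
        out.append(_CODON_MAP.get(dna[i : i + 3], "X"))
    return "".join(out)


def six_frame_translate(rec: SequenceRecord) -> dict[int, str]:
    """All six naive frame translations, keyed by frame in {±1, ±2, ±3}.

    Frames +1/+2/+3 read the forward strand at offsets 0/1/2; −1/−2/−3 read
    the reverse complement likewise.  Stops appear as ``*``.
    """
    if len(rec.seq) < 3:
        warnings.warn(f"record {rec.id!r} shorter than one codon; no translation")
        return {}
    fwd, rev = rec.seq, reverse_complement(rec.seq)
    frames = {}
    for off in range(3):
        frames[off + 1] = translate_frame(fwd, off)
        frames[-(off + 1)] = translate_frame(rev, off)
    return frames


def three_frame_translate(rec: SequenceRecord, strand: str) -> dict[int, str]:
    """Three frame translations of one strand ('+' or '-')."""
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    full = six_frame_translate(rec)
    sign = 1 if strand == "+" else -1
    return {f: t for f, t in full.items() if f * sign > 0}


def split_at_stops(translation: str) -> list[str]:
    """Maximal stop-free fragments of a naive translation, in order."""
    return [frag for frag in translation.split(STOP) if frag]


# ---------------------------------------------------------------------------
# Tryptic ORF filter.

@dataclass
class OrfFilterParams:
    """Minimal requirements a naive translation fragment must meet.

    A fragment survives when it is at least ``min_length_aa`` residues long
    and contains a fully tryptic peptide with more than
    ``min_tryptic_internal_len`` interior residues: a K/R boundary (not
    followed by P) on each side, interior residues either non-K/R or a K/R
    immediately before P.  ``accept_terminal_boundaries`` additionally lets
    the fragment ends stand in for cleavage sites (off by default: protein
    N-termini are not preceded by a cleavage site, and we filter strictly).
    """

    min_length_aa: int = 25
    min_tryptic_internal_len: int = 5
    accept_terminal_boundaries: bool = False

    def __post_init__(self) -> None:
        if self.min_length_aa < 1 or self.min_tryptic_internal_len < 1:
            raise ValueError("ORF filter lengths must be >= 1")


def tryptic_pattern(min_internal: int = 5, terminal_ok: bool = False) -> re.Pattern[str]:
    interior = rf"(?:[^KR]|[KR](?=P)){{{min_internal},}}"
    if terminal_ok:
        return re.compile(rf"(?:^|[KR](?!P)){interior}(?:[KR](?!P)|$)")
    return re.compile(rf"[KR](?!P){interior}[KR](?!P)")


def passes_orf_filter(fragment: str, params: OrfFilterParams | None = None) -> bool:
    """Does a stop-free fragment qualify for the naive-translation database?"""
    params = params or OrfFilterParams()
    if len(fragment) < params.min_length_aa:
        return False
    pat = tryptic_pattern(params.min_tryptic_internal_len, params.accept_terminal_boundaries)
    return pat.search(fragment) is not None


def build_search_db(
    dna_records: Iterable[SequenceRecord],
    orf_params: OrfFilterParams | None = None,
    frames: str = "six",
    strands: Mapping[str, str] | None = None,
) -> list[SequenceRecord]:
    """Naively translate DNA records into a filtered protein search database.

    ``frames="six"`` translates both strands; ``frames="three"`` translates
    only the strand given per record id in ``strands`` (as inferred from a
    translated homology search).  Each surviving stop-free fragment becomes a
    protein record retaining its source trace id and frame.
    """
    orf_params = orf_params or OrfFilterParams()
    out: list[SequenceRecord] = []
    for rec in dna_records:
        if frames == "six":
            translations = six_frame_translate(rec)
        elif frames == "three":
            if strands is None or rec.id not in strands:
                raise ValueError(f"three-frame mode needs a strand for record {rec.id!r}")
            translations = three_frame_translate(rec, strands[rec.id])
        else:
            raise ValueError(f"frames must be 'six' or 'three', got {frames!r}")
        for frame in sorted(translations, key=lambda f: (f < 0, abs(f))):
            for i, frag in enumerate(split_at_stops(translations[frame])):
                if passes_orf_filter(frag, orf_params):
                    out.append(
                        SequenceRecord(
                            id=f"{rec.id}|f{frame:+d}.{i}",
                            seq=frag,
                            alphabet="protein",
                            organism=rec.organism,
                            subspecies_group=rec.subspecies_group,
                            source_frame=frame,
                            source_trace_id=rec.id,
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# In-silico tryptic digestion.

@dataclass
class DigestParams:
    """Trypsin digestion: cleave after K/R except before P."""

    missed_cleavages: int = 1
    min_peptide_len: int = 6
    max_peptide_len: int = 40
    proline_rule: bool = True

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.min_peptide_len > self.max_peptide_len:
            raise ValueError("min_peptide_len must be <= max_peptide_len")


def digest(protein: str, params: DigestParams | None = None) -> list[tuple[str, int, int]]:
    """Tryptic peptides of ``protein`` as (peptide, start, end), 0-based half-open.

    Fully tryptic only; up to ``missed_cleavages`` internal sites; length
    bounds applied after cleavage.
    """
    params = params or DigestParams()
    n = len(protein)
    cuts = [0]
    for i in range(n - 1):
        if protein[i] in "KR" and not (params.proline_rule and protein[i + 1] == "P"):
            cuts.append(i + 1)
    cuts.append(n)
    out = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + params.missed_cleavages, len(cuts))):
            s, e = cuts[a], cuts[b]
            if params.min_peptide_len <= e - s <= params.max_peptide_len:
                out.append((protein[s:e], s, e))
    return out
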