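"""Seed-and-extend local alignment.

A spaced-seed nucleotide search (discontiguous-megablast stand-in), a
frame-aware translated search (blastx stand-in) and a protein-protein search
(blastp stand-in), all extending seeded candidate pairs with an affine-gap
Smith-Waterman kernel.  The full Smith-Waterman routine is exposed directly
as well, serving as the exhaustive oracle the heuristic searches are tested
against.

E-values follow the Karlin-Altschul form E = K*m*n*exp(-lambda*S) with the
canonical parameter values for the default scoring schemes (nucleotide
reward +1 / penalty -2: lambda=1.33, K=0.621; BLOSUM62 with gap 11/1:
lambda=0.267, K=0.041).  Bit-exact BLAST statistics are a non-goal; the
downstream gates act on identity and aligned length, which are robust to the
exact E-value scale.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .seqdb import SequenceRecord, reverse_complement, six_frame_translate, split_at_stops

__all__ = [
    "SpacedSeed",
    "AlignmentHit",
    "GateParams",
    "Scoring",
    "NT_SCORING",
    "PROTEIN_SCORING",
    "smith_waterman",
    "SeedIndex",
    "build_seed_index",
    "nucleotide_search",
    "ProteinIndex",
    "translated_search",
    "protein_search",
    "passes_nt_gate",
    "passes_aa_gate",
    "abundance_assign",
]

# ---------------------------------------------------------------------------
# Sequence encoding

_NT_ORDER = "ACGTN"
_NT_CODE = np.full(128, 4, dtype=np.int8)
for _i, _c in enumerate(_NT_ORDER):
    _NT_CODE[ord(_c)] = _i

_AA_ORDER = "ARNDCQEGHILKMFPSTWYVBZX"
_AA_CODE = np.full(128, _AA_ORDER.index("X"), dtype=np.int8)
for _i, _c in enumerate(_AA_ORDER):
    _AA_CODE[ord(_c)] = _i


def encode_dna(seq: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def encode_protein(seq: str) -> np.ndarray:
    return _AA_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _nt_submat(match: int, mismatch: int) -> np.ndarray:
    m = np.full((5, 5), mismatch, dtype=np.int16)
    np.fill_diagonal(m, match)
    m[4, :] = mismatch  # N never counts as a match
    m[:, 4] = mismatch
    return m


def _blosum62() -> np.ndarray:
    b = substitution_matrices.load("BLOSUM62")
    n = len(_AA_ORDER)
    m = np.zeros((n, n), dtype=np.int16)
    for i, a in enumerate(_AA_ORDER):
        for j, c in enumerate(_AA_ORDER):
            m[i, j] = int(b[a][c])
    return m


@dataclass(frozen=True)
class Scoring:
    """Substitution matrix + affine gap costs + Karlin-Altschul parameters.

    A gap of length L costs ``gap_open + L * gap_extend``.
    """

    submat: np.ndarray
    gap_open: int
    gap_extend: int
    lambda_: float
    k: float
    encode: str  # "dna" | "protein"

    def encode_seq(self, seq: str) -> np.ndarray:
        return encode_dna(seq) if self.encode == "dna" else encode_protein(seq)

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.k * m * max(n, 1) * math.exp(-self.lambda_ * score)


NT_SCORING = Scoring(_nt_submat(1, -2), 5, 2, 1.33, 0.621, "dna")
PROTEIN_SCORING = Scoring(_blosum62(), 11, 1, 0.267, 0.041, "protein")


# ---------------------------------------------------------------------------
# Hits and gates

@dataclass
class AlignmentHit:
    """One local alignment; coordinates 0-based half-open on each sequence."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str = "+"
    frame: int | None = None
    identity: float = 0.0
    aligned_len: int = 0
    score: float = 0.0
    evalue: float = math.inf

    @property
    def n_identical(self) -> int:
        return round(self.identity * self.aligned_len)


@dataclass
class GateParams:
    """Every retention threshold of the enrichment and attribution steps."""

    nt_min_identity: float = 0.50
    nt_min_len: int = 150
    aa_min_identity: float = 0.80
    aa_min_len: int = 50
    max_evalue: float = 0.01
    abundance_min_ani: float = 0.95
    mining_min_identity: float = 0.90
    mining_min_len: int = 300


def passes_nt_gate(hit: AlignmentHit, gates: GateParams) -> bool:
    """Nucleotide retention gate: >=50% identity over >=150 nt (or better)."""
    return hit.identity >= gates.nt_min_identity and hit.aligned_len >= gates.nt_min_len


def passes_aa_gate(hit: AlignmentHit, gates: GateParams) -> bool:
    """Translated retention gate: >=80% identity over >=50 aa (or better)."""
    return hit.identity >= gates.aa_min_identity and hit.aligned_len >= gates.aa_min_len


def passes_ani_gate(identity: float, gates: GateParams) -> bool:
    """Abundance attribution gate: best-hit identity at or above 95% ANI."""
    return identity >= gates.abundance_min_ani


def passes_mining_gate(identity: float, aligned_len: int, gates: GateParams) -> bool:
    """Meta-mining attribution gate: strictly >90% identity over >300 nt."""
    return identity > gates.mining_min_identity and aligned_len > gates.mining_min_len


# ---------------------------------------------------------------------------
# Smith-Waterman kernel (affine gaps, full traceback statistics)

@njit(cache=False)
def _sw_kernel(a, b, submat, gap_open, gap_extend):
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.zeros((n + 1, m + 1), dtype=np.int32)  # gap in a (left move)
    F = np.zeros((n + 1, m + 1), dtype=np.int32)  # gap in b (up move)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 left, 3 up
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = max(H[i, j - 1] - gap_open - gap_extend, E[i, j - 1] - gap_extend)
            f = max(H[i - 1, j] - gap_open - gap_extend, F[i - 1, j] - gap_extend)
            d = H[i - 1, j - 1] + submat[ai, b[j - 1]]
            h = d
            p = 1
            if e > h:
                h, p = e, 2
            if f > h:
                h, p = f, 3
            if h <= 0:
                h, p = 0, 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            ptr[i, j] = p
            if h > best:
                best, bi, bj = h, i, j
    # traceback from (bi, bj); state 0 = in H, 2 = in E (gap), 3 = in F (gap)
    i, j = bi, bj
    state = 0
    n_cols = 0
    n_ident = 0
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] <= 0 or ptr[i, j] == 0:
                break
            p = ptr[i, j]
            if p == 1:
                n_cols += 1
                if a[i - 1] == b[j - 1]:
                    n_ident += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            n_cols += 1
            if E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = 0
            j -= 1
        else:
            n_cols += 1
            if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = 0
            i -= 1
    return best, i, bi, j, bj, n_ident, n_cols


def smith_waterman(
    a: str,
    b: str,
    scoring: Scoring = NT_SCORING,
    query_id: str = "a",
    subject_id: str = "b",
) -> AlignmentHit:
    """Optimal affine-gap local alignment of ``a`` (query) vs ``b`` (subject).

    Exhaustive O(len(a)*len(b)) dynamic program; used directly for short
    protein comparisons and as the test oracle for the seeded searches.
    """
    ea, eb = scoring.encode_seq(a), scoring.encode_seq(b)
    score, qs, qe, ss, se, n_ident, n_cols = _sw_kernel(
        ea, eb, scoring.submat, scoring.gap_open, scoring.gap_extend
    )
    if score <= 0 or n_cols == 0:
        return AlignmentHit(query_id, subject_id, 0, 0, 0, 0, score=0.0)
    return AlignmentHit(
        query_id,
        subject_id,
        q_start=qs,
        q_end=qe,
        s_start=ss,
        s_end=se,
        identity=n_ident / n_cols,
        aligned_len=n_cols,
        score=float(score),
        evalue=scoring.evalue(score, len(a), len(b)),
    )


# ---------------------------------------------------------------------------
# Spaced seeds

@dataclass(frozen=True)
class SpacedSeed:
    """A spaced seed: '1' positions must match, '0' positions are free."""

    pattern: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            object.__setattr__(self, "pattern", default_coding_pattern())
        if set(self.pattern) - {"0", "1"} or not (
            self.pattern.startswith("1") and self.pattern.endswith("1")
        ):
            raise ValueError(f"bad seed pattern {self.pattern!r}")

    @property
    def span(self) -> int:
        return len(self.pattern)

    @property
    def weight(self) -> int:
        return self.pattern.count("1")

    @property
    def ones(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.pattern) if c == "1"], dtype=np.int64)


def default_coding_pattern(weight: int = 12, span: int = 21) -> str:
    """A coding-biased spaced seed of the given weight and span.

    Don't-care positions are placed on codon wobble positions (every third
    base) first, then on second codon positions from the centre outwards
    until the weight is reached.  The exact NCBI template is not public
    knowledge; only weight/span and the coding bias are preserved.
    """
    cells = [1] * span
    wobble = [p for p in range(1, span - 1) if p % 3 == 2]
    second = sorted((p for p in range(1, span - 1) if p % 3 == 1), key=lambda p: abs(p - span // 2))
    zeros = (wobble + [p for p in second if p not in wobble])[: span - weight]
    if len(zeros) < span - weight:
        raise ValueError(f"cannot build weight-{weight} span-{span} coding seed")
    for p in zeros:
        cells[p] = 0
    return "".join(map(str, cells))


def _seed_keys(codes: np.ndarray, seed: SpacedSeed) -> np.ndarray:
    """Spaced-seed key at every window offset; -1 where the window hits an N."""
    L = codes.shape[0]
    nwin = L - seed.span + 1
    if nwin <= 0:
        return np.empty(0, dtype=np.int64)
    keys = np.zeros(nwin, dtype=np.int64)
    valid = np.ones(nwin, dtype=bool)
    mult = 1
    for p in seed.ones:
        window = codes[p : p + nwin].astype(np.int64)
        valid &= window < 4
        keys += window * mult
        mult *= 4
    keys[~valid] = -1
    return keys


class SeedIndex:
    """Sorted spaced-seed key index over a set of nucleotide subjects."""

    def __init__(self, subjects: Sequence[SequenceRecord], seed: SpacedSeed | None = None):
        self.seed = seed or SpacedSeed()
        self.subjects = list(subjects)
        self.total_len = sum(len(s) for s in self.subjects)
        keys_parts, sidx_parts, off_parts = [], [], []
        for i, rec in enumerate(self.subjects):
            k = _seed_keys(encode_dna(rec.seq), self.seed)
            if k.size == 0:
                continue
            ok = k >= 0
            keys_parts.append(k[ok])
            off_parts.append(np.nonzero(ok)[0].astype(np.int64))
            sidx_parts.append(np.full(int(ok.sum()), i, dtype=np.int64))
        if keys_parts:
            keys = np.concatenate(keys_parts)
            order = np.argsort(keys, kind="stable")
            self.keys = keys[order]
            self.sidx = np.concatenate(sidx_parts)[order]
            self.soff = np.concatenate(off_parts)[order]
        else:
            self.keys = np.empty(0, dtype=np.int64)
            self.sidx = np.empty(0, dtype=np.int64)
            self.soff = np.empty(0, dtype=np.int64)

    @property
    def n_postings(self) -> int:
        return int(self.keys.size)

    def lookup(self, query_keys: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(query_offset, subject_idx, subject_offset) for every seed match."""
        ok = query_keys >= 0
        qoff_all = np.nonzero(ok)[0]
        qk = query_keys[ok]
        lo = np.searchsorted(self.keys, qk, side="left")
        hi = np.searchsorted(self.keys, qk, side="right")
        counts = hi - lo
        if counts.sum() == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z, z
        qoff = np.repeat(qoff_all, counts)
        idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
        return qoff, self.sidx[idx], self.soff[idx]


def build_seed_index(subjects: Sequence[SequenceRecord], seed: SpacedSeed | None = None) -> SeedIndex:
    return SeedIndex(subjects, seed)


@njit(cache=False)
def _sw_banded_kernel(a, b, submat, gap_open, gap_extend, dlo, dhi):
    """Local DP restricted to diagonals d = j - i in [dlo, dhi].

    Cost is len(a) * band width regardless of subject length, which makes
    extension around a seeded diagonal cluster cheap even against long
    subjects.  Cells outside the band behave as score 0 (alignment paths may
    not leave the band)."""
    n, m = a.shape[0], b.shape[0]
    w = dhi - dlo + 1
    NEG = -10**9
    H = np.full((n + 1, w), 0, dtype=np.int32)
    E = np.full((n + 1, w), NEG, dtype=np.int32)
    F = np.full((n + 1, w), NEG, dtype=np.int32)
    ptr = np.zeros((n + 1, w), dtype=np.uint8)
    best, bi, bc = 0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for c in range(w):
            j = i + dlo + c
            if j < 1 or j > m:
                H[i, c] = 0
                E[i, c] = NEG
                F[i, c] = NEG
                ptr[i, c] = 0
                continue
            # left neighbour (i, j-1) -> column c-1; up (i-1, j) -> c+1;
            # diag (i-1, j-1) -> same column of row i-1
            h_left = H[i, c - 1] if c >= 1 else NEG
            e_left = E[i, c - 1] if c >= 1 else NEG
            h_up = H[i - 1, c + 1] if c + 1 < w else NEG
            f_up = F[i - 1, c + 1] if c + 1 < w else NEG
            e = max(h_left - gap_open - gap_extend, e_left - gap_extend)
            f = max(h_up - gap_open - gap_extend, f_up - gap_extend)
            d = H[i - 1, c] + submat[ai, b[j - 1]]
            h = d
            p = 1
            if e > h:
                h, p = e, 2
            if f > h:
                h, p = f, 3
            if h <= 0:
                h, p = 0, 0
            H[i, c] = h
            E[i, c] = e
            F[i, c] = f
            ptr[i, c] = p
            if h > best:
                best, bi, bc = h, i, c
    # traceback (state 0 = H, 2 = E, 3 = F)
    i, c = bi, bc
    state = 0
    n_cols = 0
    n_ident = 0
    while i > 0 and 0 <= c < w:
        j = i + dlo + c
        if j <= 0:
            break
        if state == 0:
            if H[i, c] <= 0 or ptr[i, c] == 0:
                break
            p = ptr[i, c]
            if p == 1:
                n_cols += 1
                if a[i - 1] == b[j - 1]:
                    n_ident += 1
                i -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            n_cols += 1
            if c >= 1 and E[i, c] == H[i, c - 1] - gap_open - gap_extend:
                state = 0
            c -= 1
        else:
            n_cols += 1
            if c + 1 < w and F[i, c] == H[i - 1, c + 1] - gap_open - gap_extend:
                state = 0
            i -= 1
            c += 1
    qs, ss = i, i + dlo + c
    qe, se = bi, bi + dlo + bc
    return best, qs, qe, ss, se, n_ident, n_cols


# ---------------------------------------------------------------------------
# Nucleotide search (discontiguous-megablast stand-in)

_DIAG_GAP = 100   # seed diagonals closer than this merge into one candidate
_BAND_PAD = 24    # extra diagonals either side of the seeded cluster


def _cluster_diagonals(diags: np.ndarray, gap: int = _DIAG_GAP) -> list[tuple[int, int]]:
    d = np.unique(diags)
    clusters = []
    start = prev = int(d[0])
    for x in d[1:]:
        if int(x) - prev > gap:
            clusters.append((start, prev))
            start = int(x)
        prev = int(x)
    clusters.append((start, prev))
    return clusters


def _extend_candidates(
    q_codes: np.ndarray,
    qlen: int,
    query_id: str,
    strand: str,
    index: SeedIndex,
    scoring: Scoring,
    max_evalue: float,
) -> list[AlignmentHit]:
    keys = _seed_keys(q_codes, index.seed)
    qoff, sidx, soff = index.lookup(keys)
    hits: list[AlignmentHit] = []
    for si in np.unique(sidx):
        mask = sidx == si
        subj = index.subjects[int(si)]
        s_codes = scoring.encode_seq(subj.seq)
        diags = soff[mask] - qoff[mask]
        for dlo, dhi in _cluster_diagonals(diags):
            score, qs, qe, ss, se, n_ident, n_cols = _sw_banded_kernel(
                q_codes,
                s_codes,
                scoring.submat,
                scoring.gap_open,
                scoring.gap_extend,
                dlo - _BAND_PAD,
                dhi + _BAND_PAD,
            )
            if score <= 0 or n_cols == 0:
                continue
            ev = scoring.evalue(score, qlen, index.total_len)
            if ev > max_evalue:
                continue
            if strand == "-":
                qs, qe = qlen - qe, qlen - qs
            hits.append(
                AlignmentHit(
                    query_id,
                    subj.id,
                    q_start=qs,
                    q_end=qe,
                    s_start=ss,
                    s_end=se,
                    strand=strand,
                    identity=n_ident / n_cols,
                    aligned_len=n_cols,
                    score=float(score),
                    evalue=ev,
                )
            )
    return hits


def _dedup_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop hits whose subject interval is contained in a higher-scoring hit."""
    hits = sorted(hits, key=lambda h: (-h.score, h.subject_id, h.s_start))
    kept: list[AlignmentHit] = []
    for h in hits:
        contained = any(
            k.subject_id == h.subject_id
            and k.strand == h.strand
            and k.s_start <= h.s_start
            and h.s_end <= k.s_end
            for k in kept
        )
        if not contained:
            kept.append(h)
    return kept


def nucleotide_search(
    query: SequenceRecord,
    index: SeedIndex,
    gates: GateParams | None = None,
    scoring: Scoring = NT_SCORING,
) -> list[AlignmentHit]:
    """Spaced-seed search of one DNA query against an indexed subject pool.

    Both strands are searched (the query is reverse-complemented for the
    minus strand); seeded candidate regions are extended with the local
    aligner and hits with E-value above the reporting threshold dropped.
    """
    gates = gates or GateParams()
    qlen = len(query.seq)
    hits = _extend_candidates(
        encode_dna(query.seq), qlen, query.id, "+", index, scoring, gates.max_evalue
    )
    hits += _extend_candidates(
        encode_dna(reverse_complement(query.seq)),
        qlen,
        query.id,
        "-",
        index,
        scoring,
        gates.max_evalue,
    )
    return _dedup_hits(hits)


# ---------------------------------------------------------------------------
# Protein k-mer index, translated search, protein search

class ProteinIndex:
    """Exact k-mer prefilter over protein subjects for seeded SW extension."""

    def __init__(self, subjects: Sequence[SequenceRecord], k: int = 4, min_shared: int = 3):
        self.subjects = list(subjects)
        self.k = k
        self.min_shared = min_shared
        self.total_len = sum(len(s) for s in self.subjects)
        self._table: dict[str, list[int]] = {}
        for i, rec in enumerate(self.subjects):
            seen = set()
            seq = rec.seq
            for j in range(len(seq) - k + 1):
                kmer = seq[j : j + k]
                if "X" in kmer or "*" in kmer or kmer in seen:
                    continue
                seen.add(kmer)
                self._table.setdefault(kmer, []).append(i)

    def candidates(self, query: str) -> list[int]:
        counts: Counter[int] = Counter()
        seen = set()
        for j in range(len(query) - self.k + 1):
            kmer = query[j : j + self.k]
            if kmer in seen:
                continue
            seen.add(kmer)
            for i in self._table.get(kmer, ()):
                counts[i] += 1
        return sorted(i for i, c in counts.items() if c >= self.min_shared)


def protein_search(
    query: SequenceRecord,
    subjects: Sequence[SequenceRecord] | ProteinIndex,
    max_evalue: float = 10.0,
    scoring: Scoring = PROTEIN_SCORING,
) -> list[AlignmentHit]:
    """Local protein search (blastp stand-in), ranked by E-value.

    Ties broken by score (descending) then subject id; seeded by shared
    exact k-mers, extended by Smith-Waterman.
    """
    index = subjects if isinstance(subjects, ProteinIndex) else ProteinIndex(subjects)
    hits = []
    for i in index.candidates(query.seq):
        subj = index.subjects[i]
        h = smith_waterman(query.seq, subj.seq, scoring, query.id, subj.id)
        if h.score <= 0:
            continue
        h.evalue = scoring.evalue(h.score, len(query.seq), index.total_len)
        if h.evalue <= max_evalue:
            hits.append(h)
    hits.sort(key=lambda h: (h.evalue, -h.score, h.subject_id))
    return hits


def translated_search(
    trace: SequenceRecord,
    proteins: Sequence[SequenceRecord] | ProteinIndex,
    gates: GateParams | None = None,
    scoring: Scoring = PROTEIN_SCORING,
    min_fragment_len: int = 10,
) -> list[AlignmentHit]:
    """Six-frame translated search of a DNA trace against proteins (blastx
    stand-in).

    Every stop-free fragment of every frame is aligned to the seeded
    candidate proteins; hits record the frame and strand of the fragment
    they came from.  Query coordinates are in fragment amino-acid space.
    """
    gates = gates or GateParams()
    index = proteins if isinstance(proteins, ProteinIndex) else ProteinIndex(proteins)
    hits: list[AlignmentHit] = []
    for frame, translation in six_frame_translate(trace).items():
        for frag in split_at_stops(translation):
            if len(frag) < min_fragment_len:
                continue
            for i in index.candidates(frag):
                subj = index.subjects[i]
                h = smith_waterman(frag, subj.seq, scoring, trace.id, subj.id)
                if h.score <= 0:
                    continue
                h.evalue = scoring.evalue(h.score, len(frag), index.total_len)
                if h.evalue > gates.max_evalue:
                    continue
                h.frame = frame
                h.strand = "+" if frame > 0 else "-"
                hits.append(h)
    # keep the best hit per (subject, frame) region
    best: dict[tuple[str, int], AlignmentHit] = {}
    for h in hits:
        key = (h.subject_id, h.frame)
        if key not in best or h.score > best[key].score:
            best[key] = h
    out = list(best.values())
    out.sort(key=lambda h: (h.evalue, -h.score, h.subject_id, h.frame))
    return out


# ---------------------------------------------------------------------------
# Abundance / lineage attribution

def abundance_assign(
    trace: SequenceRecord,
    ref_index: SeedIndex,
    gates: GateParams | None = None,
    mode: str = "ani95",
) -> tuple[str | None, AlignmentHit | None]:
    """Attribute a trace to the lineage of its best reference-genome hit.

    ``mode="ani95"``: assigned iff best-hit identity >= 95% ANI.
    ``mode="mining"``: assigned iff identity > 90% over > 300 nt (the
    meta-mining gate).  Returns (organism-or-None, best hit-or-None).
    """
    gates = gates or GateParams()
    hits = nucleotide_search(trace, ref_index, gates)
    if not hits:
        return None, None
    best = max(hits, key=lambda h: (h.score, -h.evalue))
    org = next(s.organism for s in ref_index.subjects if s.id == best.subject_id)
    if mode == "ani95":
        ok = passes_ani_gate(best.identity, gates)
    elif mode == "mining":
        ok = passes_mining_gate(best.identity, best.aligned_len, gates)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return (org if ok else None), best


def hits_to_tsv(hits: Iterable[AlignmentHit]) -> str:
    """BLAST outfmt-6-like TSV (printed coordinates 1-based inclusive)."""
    lines = []
    for h in hits:
        mism = h.aligned_len - h.n_identical
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    h.query_id,
                    h.subject_id,
                    f"{100 * h.identity:.2f}",
                    h.aligned_len,
                    mism,
                    0,
                    h.q_start + 1,
                    h.q_end,
                    h.s_start + 1,
                    h.s_end,
                    f"{h.evalue:.3g}",
                    f"{h.score:.1f}",
                )
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
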