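"""Validation harness: independent oracles and benchmark measurements.

Everything here recomputes a quantity from scratch against a reference that
is independent of the code path it checks: brute-force enumeration for the
ORF filter, the exhaustive Smith-Waterman program for the seeded searches, a
forward-summed Poisson series for the E-value tail, and ground-truth labels
for the end-to-end benchmark.  Both the test suite and the reproduction
script are thin wrappers over these functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import align, seqdb
from .align import GateParams, NT_SCORING, PROTEIN_SCORING, SeedIndex, SpacedSeed
from .psm import poisson_tail
from .seqdb import SequenceRecord
from .simdata import SimParams, SimResult, generate_community, simulate_benchmark
from .workflow import IterativeResult, WorkflowConfig, run_iterative, search_pass

__all__ = [
    "BenchmarkMetrics",
    "run_standard_benchmark",
    "matched_vs_unmatched",
    "orf_filter_oracle_agreement",
    "aligner_oracle_agreement",
    "poisson_tail_max_rel_error",
    "frameshift_orf_recovery_rate",
]


# ---------------------------------------------------------------------------
# End-to-end benchmark

def _norm(p: str) -> str:
    return p.replace("I", "L")


@dataclass
class BenchmarkMetrics:
    sim: SimResult
    result: IterativeResult
    n_pass1: int
    n_pass2: int
    n_union: int
    n_both: int
    gain_ratio: float
    refound_fraction: float
    realized_fdr_pass1: float
    realized_fdr_pass2: float
    n_variant_recovered: int
    n_variant_total: int


def run_standard_benchmark(seed: int, params: SimParams | None = None) -> BenchmarkMetrics:
    """Simulate the standard community and run the full iterative workflow.

    Realized FDR is the fraction of accepted identifications whose peptide
    differs (I/L-insensitively) from the spectrum's true peptide.
    """
    params = params or SimParams(rng_seed=seed)
    sim = simulate_benchmark(params)
    result = run_iterative(
        sim.spectra,
        sim.community.protein_records(),
        sim.community.cds_records(),
        sim.traces,
    )

    def realized_fdr(hits):
        if not hits:
            return 0.0
        wrong = sum(
            1 for h in hits if _norm(h.peptide) != _norm(sim.truth.spectra[h.spectrum_id][0])
        )
        return wrong / len(hits)

    m = result.merged
    n_var_total = sum(1 for v in sim.truth.spectra.values() if v[3])
    n_var_found = sum(1 for sid in m.merged if sim.truth.spectra[sid][3])
    return BenchmarkMetrics(
        sim=sim,
        result=result,
        n_pass1=m.n_set1,
        n_pass2=m.n_set2,
        n_union=m.n_union,
        n_both=m.n_both,
        gain_ratio=m.n_union / max(1, m.n_set1),
        refound_fraction=m.n_both / max(1, m.n_set1),
        realized_fdr_pass1=realized_fdr(result.pass1.accepted),
        realized_fdr_pass2=realized_fdr(result.pass2.accepted),
        n_variant_recovered=n_var_found,
        n_variant_total=n_var_total,
    )


def matched_vs_unmatched(
    seed: int,
    n_genomes: int = 4,
    genes_per_genome: int = 60,
    n_traces: int = 1200,
    n_spectra: int = 500,
) -> dict:
    """Matched- vs unmatched-metagenome effect.

    Spectra from community A are searched against naive six-frame
    translations of A's own trace pool (matched) and of an unrelated
    community B's pool (unmatched) under identical settings and FDR.
    """
    cfg = WorkflowConfig()

    def community(s):
        return simulate_benchmark(
            SimParams(
                n_genomes=n_genomes,
                genes_per_genome=genes_per_genome,
                n_traces=n_traces,
                n_spectra=n_spectra,
                rng_seed=s,
            )
        )

    a, b = community(seed), community(seed + 1)
    db_matched = seqdb.build_search_db(a.traces, cfg.orf)
    db_unmatched = seqdb.build_search_db(b.traces, cfg.orf)
    n_matched = len(search_pass(a.spectra, db_matched, cfg, cfg.first_pass_evalue).accepted)
    n_unmatched = len(search_pass(a.spectra, db_unmatched, cfg, cfg.first_pass_evalue).accepted)
    return {
        "n_matched": n_matched,
        "n_unmatched": n_unmatched,
        "ratio": n_matched / max(1, n_unmatched),
        "n_spectra": n_spectra,
    }


# ---------------------------------------------------------------------------
# ORF filter oracle

def orf_filter_bruteforce(frag: str, min_len: int = 25, min_internal: int = 5) -> bool:
    """Direct enumeration of the fully-tryptic-stretch condition, independent
    of the regular expression used by the filter."""
    if len(frag) < min_len:
        return False
    n = len(frag)
    for i in range(n):
        if frag[i] not in "KR" or (i + 1 < n and frag[i + 1] == "P"):
            continue
        for j in range(i + 1 + min_internal, n):
            if frag[j] not in "KR" or (j + 1 < n and frag[j + 1] == "P"):
                continue
            if all(
                frag[p] not in "KR" or (p + 1 < n and frag[p + 1] == "P")
                for p in range(i + 1, j)
            ):
                return True
    return False


def orf_filter_oracle_agreement(n_fragments: int = 10_000, seed: int = 0) -> float:
    """Fraction of random fragments on which the filter and the brute-force
    enumeration agree (expected: 1.0)."""
    rng = np.random.default_rng(seed)
    alphabet = "KKRRPPACDEFGHILMNQSTVWY"
    agree = 0
    for _ in range(n_fragments):
        length = int(rng.integers(15, 45))
        frag = "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))
        agree += seqdb.passes_orf_filter(frag) == orf_filter_bruteforce(frag)
    return agree / n_fragments


# ---------------------------------------------------------------------------
# Aligner oracle

def _random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def _random_protein(rng, n):
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[i] for i in rng.integers(20, size=n))


def _mutate_str(rng, seq, alphabet, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            others = alphabet.replace(out[i], "")
            out[i] = others[int(rng.integers(len(others)))]
    return "".join(out)


def aligner_oracle_agreement(n_pairs: int = 200, seed: int = 0) -> dict:
    """Seeded searches vs the exhaustive Smith-Waterman oracle.

    Substitution-only homologies are planted into random pairs (nucleotide
    pairs <= 500 nt, protein pairs <= 200 aa).  A pair is *eligible* when the
    oracle alignment clears the reporting threshold and contains an exact
    seed match on its diagonal; the search must then reproduce the oracle's
    score and coordinates exactly.
    """
    rng = np.random.default_rng(seed)
    gates = GateParams()
    seed_pat = SpacedSeed()
    ones = seed_pat.ones
    nt_eligible = nt_found = 0
    for _ in range(n_pairs):
        s = _random_dna(rng, int(rng.integers(300, 501)))
        rlen = int(rng.integers(100, min(250, len(s) - 50)))
        start = int(rng.integers(0, len(s) - rlen))
        region = _mutate_str(rng, s[start : start + rlen], "ACGT", float(rng.uniform(0, 0.25)))
        q = _random_dna(rng, 30) + region + _random_dna(rng, 30)
        oracle = align.smith_waterman(q, s, NT_SCORING)
        if oracle.score <= 0 or oracle.evalue > gates.max_evalue:
            continue
        d = oracle.s_start - oracle.q_start
        has_seed = any(
            qo + d >= 0
            and qo + d + seed_pat.span <= len(s)
            and all(q[qo + p] == s[qo + d + p] for p in ones)
            for qo in range(oracle.q_start, oracle.q_end - seed_pat.span + 1)
        )
        if not has_seed:
            continue
        nt_eligible += 1
        hits = align.nucleotide_search(
            SequenceRecord("q", q), SeedIndex([SequenceRecord("s", s)], seed_pat), gates
        )
        if any(
            h.score == oracle.score
            and (h.q_start, h.q_end, h.s_start, h.s_end)
            == (oracle.q_start, oracle.q_end, oracle.s_start, oracle.s_end)
            for h in hits
        ):
            nt_found += 1

    aa_eligible = aa_found = 0
    for _ in range(n_pairs):
        s = _random_protein(rng, int(rng.integers(120, 201)))
        rlen = int(rng.integers(60, 110))
        start = int(rng.integers(0, len(s) - rlen))
        region = _mutate_str(
            rng, s[start : start + rlen], "ACDEFGHIKLMNPQRSTVWY", float(rng.uniform(0, 0.3))
        )
        q = _random_protein(rng, 15) + region + _random_protein(rng, 15)
        subj = SequenceRecord("s", s, alphabet="protein")
        oracle = align.smith_waterman(q, s, PROTEIN_SCORING)
        total_len = len(s)
        oracle_ev = PROTEIN_SCORING.evalue(oracle.score, len(q), total_len)
        if oracle.score <= 0 or oracle_ev > gates.max_evalue:
            continue
        aa_eligible += 1
        hits = align.protein_search(
            SequenceRecord("q", q, alphabet="protein"), [subj], max_evalue=gates.max_evalue
        )
        if any(
            h.score == oracle.score
            and (h.q_start, h.q_end, h.s_start, h.s_end)
            == (oracle.q_start, oracle.q_end, oracle.s_start, oracle.s_end)
            for h in hits
        ):
            aa_found += 1
    return {
        "nt_eligible": nt_eligible,
        "nt_found": nt_found,
        "aa_eligible": aa_eligible,
        "aa_found": aa_found,
        "agreement": (nt_found + aa_found) / max(1, nt_eligible + aa_eligible),
    }


# ---------------------------------------------------------------------------
# Poisson tail

def poisson_tail_max_rel_error(k_max: int = 20, mus: tuple[float, ...] = (0.1, 1.0, 5.0)) -> float:
    """Maximum relative error of the E-value tail vs a forward-summed series."""
    worst = 0.0
    for mu in mus:
        for k in range(0, k_max + 1):
            terms = []
            term = math.exp(-mu) * mu**k / math.factorial(k)
            i = k
            while term > 0 and i < k + 400:
                terms.append(term)
                i += 1
                term *= mu / i
            expected = math.fsum(terms)
            got = poisson_tail(k, mu)
            if expected > 0:
                worst = max(worst, abs(got - expected) / expected)
    return worst


# ---------------------------------------------------------------------------
# Frameshift tolerance

def frameshift_orf_recovery_rate(n_constructions: int = 100, seed: int = 0) -> float:
    """Fraction of single-base-insertion traces whose three-frame translation
    still yields a passing ORF containing a tryptic peptide downstream of the
    insertion."""
    rng = np.random.default_rng(seed)
    comm = generate_community(
        SimParams(n_genomes=2, genes_per_genome=max(20, n_constructions // 4), rng_seed=seed)
    )
    ok = 0
    for t in range(n_constructions):
        gene = comm.genes[int(rng.integers(len(comm.genes)))]
        pos = int(rng.integers(len(gene.cds) // 4, len(gene.cds) // 2))
        base = "ACGT"[int(rng.integers(4))]
        shifted = gene.cds[:pos] + base + gene.cds[pos:]
        trace = SequenceRecord(f"fs{t}", shifted, alphabet="dna")
        db = seqdb.build_search_db([trace], frames="three", strands={trace.id: "+"})
        # a tryptic peptide safely downstream of the insertion point
        downstream_aa = pos // 3 + 2
        peptides = [
            p
            for p, s, _e in seqdb.digest(gene.protein)
            if s >= downstream_aa and len(p) >= 7
        ]
        if not peptides:
            continue
        probe = peptides[len(peptides) // 2]
        if any(probe in rec.seq for rec in db):
            ok += 1
    return ok / n_constructions
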