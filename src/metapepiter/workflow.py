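"""Iterative metaproteome mining workflow.

First peptide-spectrum-matching pass against a curated reference proteome;
homology-guided selection of raw metagenomic traces using the genes behind
the first-pass hits (spaced-seed DNA gate, then translated-protein gate);
strand-aware three-frame translation of the selected traces into an enriched
per-sample search space; a second PSM pass; merging of the two passes;
COG-based functional profiling and lineage attribution by spectral counts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from . import align, fdr as fdrmod, psm, seqdb
from .align import AlignmentHit, GateParams, ProteinIndex, SeedIndex, SpacedSeed
from .psm import PsmHit, SearchParams, TandemSpectrum
from .seqdb import DigestParams, OrfFilterParams, SequenceRecord

logger = logging.getLogger("metapepiter")

__all__ = [
    "WorkflowConfig",
    "PassResult",
    "SelectionResult",
    "MergeResult",
    "IterativeResult",
    "CogAssignment",
    "search_pass",
    "first_pass",
    "select_traces",
    "build_iterative_db",
    "second_pass",
    "merge_passes",
    "assign_cogs",
    "taxon_mine",
    "run_compare",
    "run_iterative",
]


@dataclass
class WorkflowConfig:
    """Every tunable of the pipeline in one validated structure."""

    orf: OrfFilterParams = field(default_factory=OrfFilterParams)
    digest: DigestParams = field(default_factory=DigestParams)
    search: SearchParams = field(default_factory=SearchParams)
    gates: GateParams = field(default_factory=GateParams)
    seed: SpacedSeed = field(default_factory=SpacedSeed)
    fdr_nominal: float = 0.01
    first_pass_evalue: float = 0.01
    cog_max_evalue: float = 1e-10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.first_pass_evalue > self.search.hitlist_max_evalue:
            raise ValueError("first_pass_evalue must be <= hitlist_max_evalue")

    @classmethod
    def from_yaml(cls, path: str) -> "WorkflowConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for name, sub in (
            ("orf", OrfFilterParams),
            ("digest", DigestParams),
            ("search", SearchParams),
            ("gates", GateParams),
        ):
            if name in raw:
                kwargs[name] = sub(**raw.pop(name))
        if "seed_pattern" in raw:
            kwargs["seed"] = SpacedSeed(raw.pop("seed_pattern"))
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class PassResult:
    """One PSM pass: full hit list, FDR decision and accepted identifications."""

    hits: list[PsmHit]
    accepted: list[PsmHit]
    fdr: fdrmod.FdrResult

    @property
    def accepted_spectra(self) -> set[str]:
        return {h.spectrum_id for h in self.accepted}


def search_pass(
    spectra: Sequence[TandemSpectrum],
    target_records: Sequence[SequenceRecord],
    config: WorkflowConfig,
    max_accept_evalue: float | None = None,
) -> PassResult:
    """Search spectra against targets + their reversed decoys and apply FDR.

    Duplicate target sequences are collapsed first; decoys are generated from
    this database itself (FDR is always per search-database).  Accepted hits
    are non-decoy rank-1 hits passing the FDR threshold and, if given, the
    ``max_accept_evalue`` cap.
    """
    targets = seqdb.minimize_redundancy(list(target_records))
    decoys = seqdb.make_decoy(targets)
    index = psm.PeptideIndex(targets + decoys, config.digest, config.search)
    logger.info("search_pass: %d targets, %d index entries", len(targets), len(index))
    hits = psm.search(spectra, index, config.search)
    if not hits:
        return PassResult([], [], fdrmod.FdrResult(-1.0, 0, 0, config.fdr_nominal, False))
    accepted, result = fdrmod.apply_fdr(hits, config.fdr_nominal)
    if max_accept_evalue is not None:
        accepted = [h for h in accepted if h.evalue < max_accept_evalue]
    logger.info(
        "search_pass: %d/%d spectra accepted (threshold %.3g, fallback=%s)",
        len(accepted),
        len(spectra),
        result.threshold_evalue,
        result.fallback_used,
    )
    return PassResult(hits, accepted, result)


def first_pass(
    spectra: Sequence[TandemSpectrum],
    proteome: Sequence[SequenceRecord],
    config: WorkflowConfig,
) -> PassResult:
    """PSM pass against the curated reference ("synthetic") metaproteome."""
    return search_pass(spectra, proteome, config, max_accept_evalue=config.first_pass_evalue)


@dataclass
class SelectionResult:
    """Trace selection audit: which traces survived which gate, and why."""

    selected: dict[str, str]                 # trace_id -> inferred strand
    nt_retained: dict[str, set[str]]         # trace_id -> selecting gene ids
    aa_hits: dict[str, AlignmentHit]         # trace_id -> best translated hit
    n_hit_proteins: int = 0
    n_genes_queried: int = 0


def select_traces(
    pass1: PassResult,
    cds_by_protein: Mapping[str, SequenceRecord],
    traces: Sequence[SequenceRecord],
    config: WorkflowConfig,
    proteins_by_id: Mapping[str, SequenceRecord] | None = None,
    trace_index: SeedIndex | None = None,
) -> SelectionResult:
    """Homology-guided enrichment of the trace pool.

    Step one: spaced-seed nucleotide search of every first-pass hit gene
    against the traces, retaining traces at >=50% identity over >=150 nt.
    Step two: translated search of the retained traces against the hit
    proteins, retaining traces at >=80% identity over >=50 aa; the strand of
    the best translated hit is recorded for three-frame translation.
    """
    gates = config.gates
    hit_protein_ids: set[str] = set()
    for h in pass1.accepted:
        hit_protein_ids.update(h.source_ids)
    genes: dict[str, SequenceRecord] = {}
    hit_proteins: list[SequenceRecord] = []
    for pid in sorted(hit_protein_ids):
        if pid.startswith(seqdb.DECOY_TAG):
            continue  # a shared-peptide decoy source has no gene by design
        cds = cds_by_protein.get(pid)
        if cds is None:
            logger.warning("hit protein %s has no recorded gene; skipped", pid)
            continue
        genes[pid] = cds
        if proteins_by_id is not None and pid in proteins_by_id:
            hit_proteins.append(proteins_by_id[pid])
        else:
            hit_proteins.append(
                SequenceRecord(
                    id=pid,
                    seq=seqdb.translate_frame(cds.seq, 0).rstrip("*").replace("*", "X"),
                    alphabet="protein",
                )
            )
    index = trace_index or SeedIndex(traces, config.seed)
    trace_by_id = {t.id: t for t in traces}
    nt_retained: dict[str, set[str]] = {}
    queried: set[str] = set()
    for pid, cds in genes.items():
        if cds.id in queried:  # several proteins may share one gene record
            continue
        queried.add(cds.id)
        for hit in align.nucleotide_search(cds, index, gates):
            if align.passes_nt_gate(hit, gates):
                nt_retained.setdefault(hit.subject_id, set()).add(cds.id)
    logger.info(
        "select_traces: %d hit proteins, %d genes queried, %d traces past nt gate",
        len(hit_protein_ids),
        len(queried),
        len(nt_retained),
    )
    pindex = ProteinIndex(hit_proteins)
    selected: dict[str, str] = {}
    aa_hits: dict[str, AlignmentHit] = {}
    # fragments clearly shorter than the aa gate can never yield a
    # qualifying alignment, so skip them up front (small slack for gaps)
    min_frag = max(10, int(0.9 * gates.aa_min_len))
    for tid in sorted(nt_retained):
        best: AlignmentHit | None = None
        for hit in align.translated_search(
            trace_by_id[tid], pindex, gates, min_fragment_len=min_frag
        ):
            if align.passes_aa_gate(hit, gates) and (best is None or hit.score > best.score):
                best = hit
        if best is not None:
            selected[tid] = best.strand
            aa_hits[tid] = best
    logger.info("select_traces: %d traces past aa gate", len(selected))
    return SelectionResult(
        selected, nt_retained, aa_hits, len(hit_protein_ids), len(queried)
    )


def build_iterative_db(
    selection: SelectionResult,
    traces: Sequence[SequenceRecord],
    config: WorkflowConfig,
) -> list[SequenceRecord]:
    """Per-sample enriched search space from the selected traces.

    Each selected trace is three-frame translated on its inferred strand,
    split at stops and ORF-filtered; surviving fragments keep their trace id
    and frame as provenance.
    """
    chosen = [t for t in traces if t.id in selection.selected]
    strands = {t.id: selection.selected[t.id] for t in chosen}
    db = seqdb.build_search_db(chosen, config.orf, frames="three", strands=strands)
    logger.info("build_iterative_db: %d traces -> %d ORF records", len(chosen), len(db))
    return db


def second_pass(
    spectra: Sequence[TandemSpectrum],
    iterative_db: Sequence[SequenceRecord],
    config: WorkflowConfig,
) -> PassResult:
    """PSM pass against the trace-derived database (its own decoys and FDR)."""
    if not iterative_db:
        return PassResult([], [], fdrmod.FdrResult(-1.0, 0, 0, config.fdr_nominal, False))
    return search_pass(spectra, iterative_db, config, max_accept_evalue=config.first_pass_evalue)


@dataclass
class MergeResult:
    """Union of two identification sets with per-spectrum conflict resolution."""

    merged: dict[str, PsmHit]       # spectrum_id -> winning hit
    n_set1: int
    n_set2: int
    n_both: int                     # spectra identified by both passes
    n_union: int
    origin: dict[str, str]          # spectrum_id -> "set1" | "set2" | "both"


def merge_passes(set1: Sequence[PsmHit], set2: Sequence[PsmHit]) -> MergeResult:
    """Combine two accepted-hit sets over spectra.

    Per spectrum the lower-E-value identification wins; ties go to set 2
    (the larger, enriched database).  Identifications are compared with I/L
    treated as equal.
    """
    by1 = {h.spectrum_id: h for h in set1}
    by2 = {h.spectrum_id: h for h in set2}
    merged: dict[str, PsmHit] = {}
    origin: dict[str, str] = {}
    for sid in sorted(set(by1) | set(by2)):
        h1, h2 = by1.get(sid), by2.get(sid)
        if h1 is not None and h2 is not None:
            origin[sid] = "both"
            merged[sid] = h1 if h1.evalue < h2.evalue else h2
        elif h1 is not None:
            origin[sid] = "set1"
            merged[sid] = h1
        else:
            origin[sid] = "set2"
            merged[sid] = h2
    n_both = sum(1 for v in origin.values() if v == "both")
    return MergeResult(merged, len(by1), len(by2), n_both, len(merged), origin)


# ---------------------------------------------------------------------------
# Functional and taxonomic attribution

@dataclass
class CogAssignment:
    spectrum_id: str
    cog_id: str
    cog_category: str
    source_id: str


def parse_cog_member_id(record_id: str) -> tuple[str, str]:
    """COG reference ids follow '<cog>_<category letter>|<member id>'."""
    head = record_id.split("|", 1)[0]
    cog_id, cat = head.rsplit("_", 1)
    return cog_id, cat


def assign_cogs(
    hits: Mapping[str, PsmHit] | Sequence[PsmHit],
    cog_records: Sequence[SequenceRecord],
    source_seqs: Mapping[str, SequenceRecord],
    config: WorkflowConfig,
) -> tuple[list[CogAssignment], Counter]:
    """Best-hit COG assignment for every identified spectrum.

    Each hit's source sequence (the reference protein, or the translated ORF
    fragment for trace-derived hits) is searched against the COG reference;
    the best hit assigns its COG when its E-value beats the configured cap
    (default 1e-10).  Every spectrum inherits its source's COG; counts are
    aggregated per single-letter functional category.
    """
    hit_list = list(hits.values()) if isinstance(hits, Mapping) else list(hits)
    cindex = ProteinIndex(cog_records)
    cache: dict[str, tuple[str, str] | None] = {}
    assignments: list[CogAssignment] = []
    counts: Counter = Counter()
    for h in sorted(hit_list, key=lambda x: x.spectrum_id):
        sid = sorted(h.source_ids)[0]
        if sid not in cache:
            src = source_seqs.get(sid)
            if src is None:
                cache[sid] = None
            else:
                found = align.protein_search(src, cindex, max_evalue=config.cog_max_evalue)
                if found and found[0].evalue < config.cog_max_evalue:
                    cache[sid] = parse_cog_member_id(found[0].subject_id)
                else:
                    cache[sid] = None
        res = cache[sid]
        if res is not None:
            cog_id, cat = res
            assignments.append(CogAssignment(h.spectrum_id, cog_id, cat, sid))
            counts[cat] += 1
    return assignments, counts


def taxon_mine(
    trace_ids: Sequence[str],
    traces: Sequence[SequenceRecord],
    ref_index: SeedIndex,
    gates: GateParams,
    mode: str = "mining",
) -> Counter:
    """Lineage attribution of selected traces by best reference-genome hit.

    Returns spectral-count-style bins per lineage plus an explicit
    "unassigned" bin; bins always sum to the number of traces given.
    """
    by_id = {t.id: t for t in traces}
    counts: Counter = Counter()
    for tid in trace_ids:
        lineage, _hit = align.abundance_assign(by_id[tid], ref_index, gates, mode=mode)
        counts[lineage if lineage is not None else "unassigned"] += 1
    return counts


# ---------------------------------------------------------------------------
# Comparison runs and end-to-end orchestration

def run_compare(
    spectra: Sequence[TandemSpectrum],
    dbs: Mapping[str, Sequence[SequenceRecord]],
    config: WorkflowConfig,
) -> dict:
    """Run several search strategies under identical settings and FDR.

    Returns per-strategy accepted counts and pairwise spectrum overlaps."""
    results = {name: search_pass(spectra, db, config, config.first_pass_evalue) for name, db in dbs.items()}
    report: dict = {
        "n_spectra": len(spectra),
        "accepted": {name: len(r.accepted) for name, r in results.items()},
        "overlap": {},
    }
    names = sorted(results)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            report["overlap"][f"{a}&{b}"] = len(
                results[a].accepted_spectra & results[b].accepted_spectra
            )
    report["_results"] = results
    return report


@dataclass
class IterativeResult:
    pass1: PassResult
    selection: SelectionResult
    iterative_db: list[SequenceRecord]
    pass2: PassResult
    merged: MergeResult


def run_iterative(
    spectra: Sequence[TandemSpectrum],
    proteome: Sequence[SequenceRecord],
    cds_records: Sequence[SequenceRecord],
    traces: Sequence[SequenceRecord],
    config: WorkflowConfig | None = None,
    trace_index: SeedIndex | None = None,
) -> IterativeResult:
    """The full iterative method: PSM pass 1 -> trace enrichment -> translated
    per-sample database -> PSM pass 2 -> merged identifications.

    ``cds_records`` must pair with ``proteome`` by shared record id (gene to
    protein provenance).
    """
    config = config or WorkflowConfig()
    p1 = first_pass(spectra, proteome, config)
    cds_by_protein = {c.id: c for c in cds_records}
    proteins_by_id = {p.id: p for p in proteome}
    selection = select_traces(
        p1, cds_by_protein, traces, config, proteins_by_id, trace_index
    )
    db2 = build_iterative_db(selection, traces, config)
    p2 = second_pass(spectra, db2, config)
    merged = merge_passes(p1.accepted, p2.accepted)
    logger.info(
        "run_iterative: pass1=%d pass2=%d union=%d both=%d",
        merged.n_set1,
        merged.n_set2,
        merged.n_union,
        merged.n_both,
    )
    return IterativeResult(p1, selection, db2, p2, merged)
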