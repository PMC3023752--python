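"""Synthetic benchmark generator.

Builds a mock gut community with known ground truth: annotated reference
genomes and proteomes (the curated "synthetic metagenome/metaproteome"),
sample strains that differ from the references by single-amino-acid
polymorphisms (SAPs), a pool of unassembled Sanger-like trace reads drawn
from the strains with substitution and indel errors, a COG-like protein
family reference, and simulated tryptic MS/MS spectra with peak dropout,
m/z jitter and noise peaks.

The defaults define the standard benchmark conditions: 10 genomes x 200
genes, 2% per-residue SAP rate, 5,000 traces of 800+/-150 nt with 0.5%
substitutions and 0.1% indels, 3,000 spectra of which 30% come from variant
peptides absent from the references.  Everything is deterministic under
``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .psm import PROTON, TandemSpectrum, peptide_mass, theoretical_ions
from .seqdb import (
    DigestParams,
    SequenceRecord,
    digest,
    reverse_complement,
    translate_frame,
)

__all__ = [
    "SimParams",
    "Gene",
    "Community",
    "GroundTruth",
    "SimResult",
    "generate_community",
    "generate_variant_strains",
    "generate_trace_pool",
    "simulate_spectra",
    "simulate_benchmark",
]

_SENSE_CODONS = None
_STOP_CODONS = ("TAA", "TAG", "TGA")
_COG_CATEGORIES = "CEFGHIJKLMNOPTUV"


def _sense_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from .seqdb import _CODON_MAP

        _SENSE_CODONS = sorted(c for c, aa in _CODON_MAP.items() if aa != "*")
    return _SENSE_CODONS


def _codons_for(aa: str) -> list[str]:
    from .seqdb import _CODON_MAP

    return sorted(c for c, a in _CODON_MAP.items() if a == aa)


@dataclass
class SimParams:
    """Benchmark generator settings (rates per unit; lengths in nt/Da)."""

    n_genomes: int = 10
    genes_per_genome: int = 200
    gene_len_range: tuple[int, int] = (300, 900)
    intergenic_range: tuple[int, int] = (20, 100)
    dirichlet_alpha: float = 3.0
    community_abundances: tuple[float, ...] | None = None
    n_traces: int = 5000
    trace_len_mean: float = 800.0
    trace_len_sd: float = 150.0
    sub_rate: float = 0.005
    indel_rate: float = 0.001
    variant_strain_sap_rate: float = 0.02
    n_spectra: int = 3000
    peak_dropout: float = 0.2
    n_noise_peaks: int = 10
    mz_jitter_sd: float = 0.05
    precursor_jitter_sd: float = 0.005
    frac_variant_peptides: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for r in (
            self.sub_rate,
            self.indel_rate,
            self.variant_strain_sap_rate,
            self.peak_dropout,
            self.frac_variant_peptides,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.community_abundances is not None:
            ab = np.asarray(self.community_abundances, dtype=float)
            if ab.size != self.n_genomes or not np.isclose(ab.sum(), 1.0):
                raise ValueError("community_abundances must have n_genomes entries summing to 1")


@dataclass
class Gene:
    gene_id: str
    genome_id: str
    start: int  # on the genome forward strand, 0-based half-open
    end: int
    cds: str
    protein: str


@dataclass
class Community:
    genomes: list[SequenceRecord]          # DNA; organism carries the lineage
    genes: list[Gene]
    abundances: np.ndarray                 # per genome, sums to 1
    cog_of_gene: dict[str, str]            # gene_id -> COG id
    cog_category: dict[str, str]           # COG id -> single-letter class

    def cds_records(self) -> list[SequenceRecord]:
        return [
            SequenceRecord(
                id=g.gene_id,
                seq=g.cds,
                alphabet="dna",
                organism=self._org(g.genome_id),
                subspecies_group=g.genome_id,
            )
            for g in self.genes
        ]

    def protein_records(self) -> list[SequenceRecord]:
        return [
            SequenceRecord(
                id=g.gene_id,
                seq=g.protein,
                alphabet="protein",
                organism=self._org(g.genome_id),
                subspecies_group=g.genome_id,
            )
            for g in self.genes
        ]

    def cog_records(self) -> list[SequenceRecord]:
        """COG-like family reference: one family per reference protein,
        member ids encoded as '<cog>_<category>|<gene>'."""
        return [
            SequenceRecord(
                id=f"{self.cog_of_gene[g.gene_id]}_{self.cog_category[self.cog_of_gene[g.gene_id]]}|{g.gene_id}",
                seq=g.protein,
                alphabet="protein",
            )
            for g in self.genes
        ]

    def _org(self, genome_id: str) -> str:
        return next(r.organism for r in self.genomes if r.id == genome_id)


@dataclass
class GroundTruth:
    """Everything needed to score pipeline output as true/false."""

    saps: list[tuple[str, int, str, str]] = field(default_factory=list)
    # trace_id -> (genome_id, start, end, strand)
    traces: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    # spectrum_id -> (peptide, gene_id, genome_id, is_variant)
    spectra: dict[str, tuple[str, str, str, bool]] = field(default_factory=dict)

    def spectra_tsv(self) -> str:
        lines = ["spectrum_id\tpeptide\tgene_id\tgenome_id\tvariant"]
        for sid, (pep, gid, gen, var) in sorted(self.spectra.items()):
            lines.append(f"{sid}\t{pep}\t{gid}\t{gen}\t{int(var)}")
        return "\n".join(lines) + "\n"


@dataclass
class SimResult:
    params: SimParams
    community: Community
    strain_genes: list[Gene]
    strain_genomes: list[SequenceRecord]
    traces: list[SequenceRecord]
    spectra: list[TandemSpectrum]
    truth: GroundTruth


# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, length_nt: int) -> str:
    n_codons = max(length_nt // 3, 3)
    sense = _sense_codons()
    body = rng.choice(len(sense), size=n_codons - 2)
    stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
    return "ATG" + "".join(sense[i] for i in body) + stop


def generate_community(params: SimParams, rng: np.random.Generator | None = None) -> Community:
    """Reference genomes, annotated genes/proteins and a COG-like reference."""
    rng = rng or np.random.default_rng(params.rng_seed)
    genomes: list[SequenceRecord] = []
    genes: list[Gene] = []
    cog_of_gene: dict[str, str] = {}
    cog_category: dict[str, str] = {}
    bases = "ACGT"
    cog_serial = 0
    for gi in range(params.n_genomes):
        gid = f"genome{gi:02d}"
        org = f"OTU{gi:02d}"
        parts: list[str] = []
        pos = 0
        for gj in range(params.genes_per_genome):
            spacer_len = int(rng.integers(params.intergenic_range[0], params.intergenic_range[1] + 1))
            spacer = "".join(bases[i] for i in rng.integers(4, size=spacer_len))
            parts.append(spacer)
            pos += spacer_len
            L = int(rng.integers(params.gene_len_range[0], params.gene_len_range[1] + 1))
            cds = _random_cds(rng, L)
            gene_id = f"{gid}_g{gj:03d}"
            protein = translate_frame(cds, 0).rstrip("*")
            genes.append(Gene(gene_id, gid, pos, pos + len(cds), cds, protein))
            parts.append(cds)
            pos += len(cds)
            cog = f"COG{cog_serial:04d}"
            cog_serial += 1
            cog_of_gene[gene_id] = cog
            cog_category[cog] = _COG_CATEGORIES[int(rng.integers(len(_COG_CATEGORIES)))]
        genomes.append(
            SequenceRecord(id=gid, seq="".join(parts), alphabet="dna", organism=org)
        )
    if params.community_abundances is not None:
        ab = np.asarray(params.community_abundances, dtype=float)
    else:
        ab = rng.dirichlet([params.dirichlet_alpha] * params.n_genomes)
    return Community(genomes, genes, ab, cog_of_gene, cog_category)


def generate_variant_strains(
    community: Community,
    sap_rate: float,
    rng: np.random.Generator,
    truth: GroundTruth | None = None,
) -> tuple[list[Gene], list[SequenceRecord]]:
    """Strain copies of every genome with Poisson-placed nonsynonymous SAPs.

    DNA and protein are kept consistent: each SAP replaces a whole codon with
    a codon of the new residue.  Returns (strain genes, strain genomes).
    """
    truth = truth if truth is not None else GroundTruth()
    aa_pool = "ACDEFGHIKLMNPQRSTVWY"
    strain_genes: list[Gene] = []
    new_seqs = {g.id: list(g.seq) for g in community.genomes}
    for gene in community.genes:
        protein = list(gene.protein)
        cds = list(gene.cds)
        n_res = len(protein)
        n_saps = rng.poisson(sap_rate * n_res)
        sites = rng.choice(n_res, size=min(n_saps, n_res), replace=False) if n_saps else []
        for site in sorted(int(s) for s in np.atleast_1d(sites)):
            old = protein[site]
            choices = [a for a in aa_pool if a != old]
            new = choices[int(rng.integers(len(choices)))]
            codons = _codons_for(new)
            codon = codons[int(rng.integers(len(codons)))]
            protein[site] = new
            cds[3 * site : 3 * site + 3] = list(codon)
            truth.saps.append((gene.gene_id, site, old, new))
        strain_cds = "".join(cds)
        strain_genes.append(
            Gene(gene.gene_id, gene.genome_id, gene.start, gene.end, strain_cds, "".join(protein))
        )
        seq = new_seqs[gene.genome_id]
        seq[gene.start : gene.end] = list(strain_cds)
    strain_genomes = [
        SequenceRecord(
            id=g.id, seq="".join(new_seqs[g.id]), alphabet="dna", organism=g.organism
        )
        for g in community.genomes
    ]
    return strain_genes, strain_genomes


def _mutate_read(seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator) -> str:
    bases = "ACGT"
    out: list[str] = []
    for c in seq:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:
            out.append(bases[int(rng.integers(4))])  # insertion before c
        if rng.random() < sub_rate:
            others = bases.replace(c, "") if c in bases else bases
            c = others[int(rng.integers(len(others)))]
        out.append(c)
    return "".join(out)


def generate_trace_pool(
    strain_genomes: Sequence[SequenceRecord],
    params: SimParams,
    abundances: np.ndarray,
    rng: np.random.Generator,
    truth: GroundTruth | None = None,
) -> list[SequenceRecord]:
    """Sanger-like reads from the strain genomes, abundance-weighted, with
    random strand and substitution/indel errors."""
    truth = truth if truth is not None else GroundTruth()
    traces: list[SequenceRecord] = []
    genome_idx = rng.choice(len(strain_genomes), size=params.n_traces, p=abundances)
    for i in range(params.n_traces):
        genome = strain_genomes[int(genome_idx[i])]
        L = int(np.clip(rng.normal(params.trace_len_mean, params.trace_len_sd), 150, len(genome.seq)))
        start = int(rng.integers(0, len(genome.seq) - L + 1))
        frag = genome.seq[start : start + L]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = reverse_complement(frag)
        read = _mutate_read(frag, params.sub_rate, params.indel_rate, rng)
        tid = f"trace{i:05d}"
        truth.traces[tid] = (genome.id, start, start + L, strand)
        traces.append(SequenceRecord(id=tid, seq=read, alphabet="dna", organism=genome.organism))
    return traces


def simulate_spectra(
    strain_genes: Sequence[Gene],
    community: Community,
    params: SimParams,
    rng: np.random.Generator,
    digest_params: DigestParams | None = None,
    truth: GroundTruth | None = None,
) -> list[TandemSpectrum]:
    """Simulated tryptic MS/MS spectra from the strain proteomes.

    A ``frac_variant_peptides`` share of spectra is drawn from peptides that
    carry at least one SAP and are therefore absent from the reference
    proteome digest; the rest from peptides shared with the references.
    Spectra get peak dropout, Gaussian m/z jitter and uniform noise peaks.
    """
    truth = truth if truth is not None else GroundTruth()
    digest_params = digest_params or DigestParams()
    ab_of_genome = {g.id: a for g, a in zip(community.genomes, community.abundances)}
    ref_peptides: set[str] = set()
    for gene in community.genes:
        for pep, _s, _e in digest(gene.protein, digest_params):
            ref_peptides.add(pep.replace("I", "L"))
    variant_pool: list[tuple[str, str, str]] = []  # (peptide, gene_id, genome_id)
    ref_pool: list[tuple[str, str, str]] = []
    for gene in strain_genes:
        for pep, _s, _e in digest(gene.protein, digest_params):
            if "X" in pep or "B" in pep or "Z" in pep:
                continue
            item = (pep, gene.gene_id, gene.genome_id)
            if pep.replace("I", "L") in ref_peptides:
                ref_pool.append(item)
            else:
                variant_pool.append(item)

    def _weights(pool: list[tuple[str, str, str]]) -> np.ndarray:
        w = np.array([ab_of_genome[g] for _p, _g2, g in pool], dtype=float)
        return w / w.sum()

    w_var = _weights(variant_pool) if variant_pool else None
    w_ref = _weights(ref_pool) if ref_pool else None
    spectra: list[TandemSpectrum] = []
    for i in range(params.n_spectra):
        use_variant = w_var is not None and rng.random() < params.frac_variant_peptides
        pool, w = (variant_pool, w_var) if use_variant else (ref_pool, w_ref)
        pep, gene_id, genome_id = pool[int(rng.choice(len(pool), p=w))]
        charge = 2 if rng.random() < 0.7 else 3
        mass = peptide_mass(pep)
        mz = (mass + charge * PROTON) / charge + rng.normal(0, params.precursor_jitter_sd)
        ions = theoretical_ions(pep, (), charge)
        keep = rng.random(ions.size) >= params.peak_dropout
        if keep.sum() < 3:  # a spectrum needs some signal to exist at all
            keep[rng.choice(ions.size, size=3, replace=False)] = True
        obs = ions[keep] + rng.normal(0, params.mz_jitter_sd, size=int(keep.sum()))
        noise = rng.uniform(100.0, max(1500.0, float(ions.max()) + 50.0), size=params.n_noise_peaks)
        mz_all = np.concatenate([obs, noise])
        inten = np.concatenate(
            [rng.uniform(50.0, 100.0, obs.size), rng.uniform(1.0, 30.0, noise.size)]
        )
        sid = f"spec{i:05d}"
        truth.spectra[sid] = (pep, gene_id, genome_id, bool(use_variant))
        spectra.append(
            TandemSpectrum(sid, mz, charge, np.column_stack([mz_all, inten]))
        )
    return spectra


def simulate_benchmark(params: SimParams | None = None) -> SimResult:
    """Generate the full benchmark: community, strains, traces, spectra."""
    params = params or SimParams()
    rng = np.random.default_rng(params.rng_seed)
    truth = GroundTruth()
    community = generate_community(params, rng)
    strain_genes, strain_genomes = generate_variant_strains(
        community, params.variant_strain_sap_rate, rng, truth
    )
    traces = generate_trace_pool(strain_genomes, params, community.abundances, rng, truth)
    spectra = simulate_spectra(strain_genes, community, params, rng, truth=truth)
    return SimResult(params, community, strain_genes, strain_genomes, traces, spectra, truth)
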