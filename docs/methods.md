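# Methods

## Problem setting

Shotgun metaproteomics assigns tandem-MS spectra to peptides by matching
observed fragment ions against theoretical spectra of candidate peptides
from a sequence database. For a complex, partly uncharacterised community
such as the human gut microbiota no database lists exactly the peptides in
the sample: curated reference proteomes miss strain-level variation (a
single amino-acid polymorphism, SAP, makes a peptide invisible to exact
matching), while naive six-frame translations of large metagenomic
repositories drown the search in pseudo-gene noise and make decoy-based FDR
estimation impractically expensive.

`metapepiter` implements an iterative middle path:

1. **Pass 1** — search the spectra against a curated, non-redundant
   reference metaproteome with reversed decoys and a 1% peptide FDR.
2. **Enrichment** — use the coding sequences behind the accepted hits to
   fish homologous raw trace reads out of an unassembled metagenomic pool:
   first a spaced-seed nucleotide search (traces retained at >= 50%
   identity over >= 150 nt), then a translated protein-level search
   (retained at >= 80% identity over >= 50 aa), which also fixes each
   trace's coding strand.
3. **Translation** — three-frame translate each selected trace on its
   inferred strand (three frames tolerate the frame shifts that single-base
   indels in raw reads cause), split at stops, and keep fragments of >= 25
   residues containing a fully tryptic stretch.
4. **Pass 2** — search the spectra against this small, enriched, per-sample
   database with its own decoys and its own 1% FDR; merge the two passes
   per spectrum (lower E-value wins, ties to the enriched database).

Downstream, identified spectra are profiled functionally (best protein hit
in a COG-like family reference at E < 1e-10 assigns its category; counts
aggregate per single-letter class) and taxonomically (each selected trace
attributed to the lineage of its best reference-genome hit, either at
>= 95% ANI or at the meta-mining gate of > 90% identity over > 300 nt).

## PSM engine

The engine is a deliberately small OMSSA-style scorer. Peptides come from
an in-silico tryptic digest (cleave after K/R except before P; default 1
missed cleavage, length 6–40 aa — common search practice, consistent with
the >5-residue fully-tryptic filter). Cysteine carries a fixed
carbamidomethyl (+57.02146 Da); variable states are oxidised methionine
(+15.99491 Da) and carboxymethyl cysteine (+58.00548 Da, replacing the
fixed state), at most two variable mods per peptide. Theoretical spectra
are singly charged b/y ladders, plus doubly charged ions for precursors of
charge >= 3. A candidate is any indexed (modified) peptide whose neutral
mass lies within 0.03 Da of the observed neutral mass; its score is the
number of theoretical ions with an observed peak within 0.4 Da. The
significance model treats random matches as Poisson with mean
`mu = n_ions * min(1, n_peaks * 2 * tol / mz_range)`; the per-candidate
tail probability times the number of candidates in the precursor window is
the reported E-value (hit-list cap 0.1, reporting/acceptance cap 0.01).
I and L are isobaric and are treated as equal whenever identifications are
merged or compared. Ties are broken on the I/L-normalised peptide string,
so results do not depend on database record order.

## FDR control

Rank-1 hits only. The threshold scan walks the sorted target E-values and
keeps the largest threshold t with `#decoys(<=t) / #targets(<=t) <= 1%`
(the conventional reversed-database estimator). When the scan accepts
nothing or no decoy hits exist to estimate from, the fallback uses the
E-value of the best decoy — the best false positive — as an exclusive
threshold, capped at 0.01. FDR is always computed per search database;
pass 2 uses decoys reversed from the enriched database itself.

## Alignment

All searches are seed-and-extend with a shared affine-gap Smith–Waterman
core (match +1 / mismatch −2, gap open 5 / extend 2 for DNA; BLOSUM62 with
gap open 11 / extend 1 for protein; a gap of length L costs open + L·extend).
The nucleotide search uses a weight-12, span-21 spaced seed whose don't-care
positions fall on codon wobble positions first — the coding-bias template is
configurable, since only the weight/span pair is fixed by design. Seed
postings are held in one sorted key array per pool; seed hits are clustered
by diagonal (clusters closer than 100 diagonals merge) and each cluster is
extended with a banded Smith–Waterman restricted to the cluster's diagonals
± 24, which makes extension cost proportional to query length × band width
rather than to subject length. Protein and translated searches prefilter
candidate pairs by shared exact 4-mers (≥ 3 distinct shared words) before
running the full local DP. E-values follow the Karlin–Altschul form
`E = K·m·n·exp(−λS)` with the canonical published constants for the two
scoring schemes (λ=1.33, K=0.621 nucleotide; λ=0.267, K=0.041 protein);
reproducing BLAST statistics bit-exactly is a non-goal — every downstream
decision rides on identity and aligned length, which are insensitive to
the E-value scale.

Identity is identical columns divided by all alignment columns including
gap columns. The retention gates are inclusive (>= 50%/150 nt,
>= 80%/50 aa, >= 95% ANI) except the meta-mining gate, which is strict
(> 90% over > 300 nt) as printed.

## Synthetic benchmark

The generator builds what the method needs to be testable end to end with
known ground truth:

* **Community** — 10 genomes × 200 genes by default; random CDSs of
  300–900 nt (start/stop flanked, no internal stops; compact but
  realistic coding lengths), 20–100 nt intergenic spacers, Dirichlet(3)
  community abundances. A COG-like reference assigns one family and a
  random single-letter category per reference protein.
* **Strains** — each genome gets a sample strain with Poisson-placed
  nonsynonymous SAPs at 2% per residue, DNA and protein kept consistent.
  Strain variation is the lever behind the method's headline effect.
* **Traces** — 5,000 Sanger-like reads, 800 ± 150 nt, sampled from strain
  genomes proportional to abundance, random strand, 0.5% substitutions and
  0.1% indels per base (so a typical read carries roughly one frameshift).
* **Spectra** — 3,000 tryptic spectra sampled from strain proteomes, 30%
  from peptides carrying a SAP (hence absent from the references), with
  20% peak dropout, 0.05 Da fragment m/z jitter, 0.005 Da precursor jitter
  and 10 uniform noise peaks; charge 2 or 3.

Everything is deterministic under the generator seed. What the simulation
does **not** model: intensity structure and chromatography, PTMs beyond the
configured set, quality scores, real codon usage, sequence homology between
community members, and real SAP substitution biases. Passing tests
therefore demonstrate the mechanics and calibration of the workflow under
controlled conditions, not instrument-level realism.

## Validation and measured behaviour

`metapepiter.validation` recomputes every headline quantity against an
independent reference: brute-force enumeration for the ORF filter, the
exhaustive Smith–Waterman program for the seeded searches (score and
coordinate agreement whenever the optimal alignment clears the reporting
threshold and contains an exact seed), a forward-summed Poisson series for
the E-value tail, ground-truth labels for realized FDR, and conservation
identities for the spectral-count reports. `scripts/acceptance.py` wraps
these into a single JSON report.

One measured limitation deserves emphasis. With the printed modification
set, a reference peptide plus one variable mod can be exactly isobaric with
a variant peptide (carboxymethyl-vs-carbamidomethyl differs by +0.98402 Da,
the D/N and E/Q residue gap; oxidation differs by +15.99491 Da, the S/A
gap). Spectra of such variant peptides can be confidently — and wrongly —
assigned to the mod-shifted reference peptide in pass 1, matching every
fragment ion outside the SAP position. Reversed decoys cannot model this
homology-driven error path, so the realized false-identification fraction
in pass 1 can exceed the nominal 1% (we observe roughly 1.2–2.2% across
seeds at nominal 1%; pass 2, whose database contains the true variants,
calibrates better and the merge step corrects most of these spectra). This
is a genuine property of target-decoy FDR under strain variation — and one
more argument for enriching the search space rather than trusting a
reference database.

## Problem sizes and runtime choices

The standard benchmark (above) runs the full two-pass workflow in a few
minutes on one core. The matched-vs-unmatched comparison uses a more
compact pair of communities (4 genomes × 60 genes, 1,200 traces, 500
spectra) because naive six-frame translation inflates the search space
roughly tenfold; lineage attribution reports on a 300-trace subsample of
the selected traces. These sizes are the package's validation defaults; all
of them scale up through `SimParams`.

## Design choices where the design was open

* The printed ORF-filter regular expression requires a *preceding* K/R
  boundary, so a protein's N-terminal peptide can never satisfy it. We
  follow it literally; `OrfFilterParams.accept_terminal_boundaries`
  (default off) also accepts fragment ends as boundaries.
* The 25-residue minimum is applied per stop-free fragment (filtering whole
  six-frame translations would leave almost nothing usable).
* Decoy deflines are tagged `REV_`.
* Database deduplication keys on the exact residue string within a
  subspecies group; I/L are *not* merged at the database level, only at
  identification reporting.
* Step-2 enrichment queries the full CDS of each hit protein, not just the
  matched peptide's codons.
* The COG source sequence for a trace-derived hit is the translated ORF
  fragment, not the whole trace.
* Precursor tolerance is interpreted in Da. Missed cleavages (1) and
  peptide length bounds (6–40) are declared assumptions.
* Pass-2 FDR is computed on pass-2 hits alone; the merged table reports
  per-pass provenance so both views are available.
* When one spectrum is identified by both passes with different peptides,
  the lower E-value wins and an exact tie goes to the enriched database.
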