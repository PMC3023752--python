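"""Peptide-spectrum matching.

A lightweight OMSSA-style search engine: tryptic peptide index with fixed and
variable modifications, theoretical b/y fragment ladders, counting of matched
product ions within a tolerance window, and a Poisson-tail E-value per
candidate.  Defaults mirror a standard carbamidomethyl workflow: fixed
carbamidomethyl-C (+57.02146 Da), variable oxidation-M (+15.99491 Da) and
carboxymethyl-C (+58.00548 Da, replacing the fixed state on a given
cysteine), product tolerance 0.4 Da, precursor tolerance 0.03 Da, hit-list
E-value cap 0.1.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf
from pyteomics.mass import std_aa_mass
from scipy.stats import poisson

from .seqdb import DigestParams, SequenceRecord, digest

__all__ = [
    "PROTON",
    "WATER",
    "TandemSpectrum",
    "SearchParams",
    "PsmHit",
    "read_mgf",
    "write_mgf",
    "peptide_mass",
    "residue_masses",
    "theoretical_ions",
    "match_count",
    "poisson_evalue",
    "PeptideIndex",
    "search",
]

PROTON = 1.007276
WATER = 18.010565

CARBAMIDOMETHYL = 57.02146
OXIDATION = 15.99491
CARBOXYMETHYL = 58.00548

_AA_MASS = dict(std_aa_mass)


@dataclass
class TandemSpectrum:
    """One MS/MS spectrum: precursor and a sorted fragment peak list."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    peaks: np.ndarray  # shape (n, 2): m/z, intensity; sorted by m/z

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if self.peaks.shape[0] < 1:
            raise ValueError(f"spectrum {self.spectrum_id!r}: no peaks")
        if np.any(self.peaks[:, 0] <= 0):
            raise ValueError(f"spectrum {self.spectrum_id!r}: non-positive m/z")
        order = np.argsort(self.peaks[:, 0], kind="stable")
        self.peaks = self.peaks[order]
        if self.precursor_charge < 1:
            raise ValueError(f"spectrum {self.spectrum_id!r}: charge must be >= 1")

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def neutral_mass(self) -> float:
        return self.precursor_mz * self.precursor_charge - self.precursor_charge * PROTON


@dataclass
class SearchParams:
    """Search-engine settings; tolerances in Da."""

    product_tol: float = 0.4
    precursor_tol: float = 0.03
    hitlist_max_evalue: float = 0.1
    report_max_evalue: float = 0.01
    max_variable_mods_per_peptide: int = 2
    fixed_cys_delta: float = CARBAMIDOMETHYL
    variable_mods: tuple[tuple[str, str, float], ...] = (
        ("Oxidation", "M", OXIDATION),
        ("Carboxymethyl", "C", CARBOXYMETHYL - CARBAMIDOMETHYL),
    )

    def __post_init__(self) -> None:
        if self.product_tol <= 0 or self.precursor_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.hitlist_max_evalue < self.report_max_evalue:
            raise ValueError("hitlist_max_evalue must be >= report_max_evalue")


@dataclass
class PsmHit:
    """One peptide-spectrum match."""

    spectrum_id: str
    peptide: str
    mods: tuple[tuple[int, str], ...]  # (0-based position, mod name)
    source_ids: frozenset[str]
    matched_ions: int
    total_theoretical_ions: int
    evalue: float
    is_decoy: bool
    rank: int = 0

    @property
    def peptide_key(self) -> tuple[str, tuple[tuple[int, str], ...]]:
        """I/L-insensitive identification key (isobaric residues merged)."""
        return self.peptide.replace("I", "L"), self.mods


# ---------------------------------------------------------------------------
# MGF I/O (pyteomics-backed)

def read_mgf(path: str | Path) -> list[TandemSpectrum]:
    """Read an MGF file; blocks without CHARGE default to 2+ with a warning."""
    spectra = []
    with _mgf.read(str(path), use_index=False) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"spectrum_{i}"))
            charge_list = params.get("charge")
            if charge_list:
                charge = int(charge_list[0])
            else:
                warnings.warn(f"spectrum {title!r} has no CHARGE; assuming 2+")
                charge = 2
            peaks = np.column_stack([entry["m/z array"], entry["intensity array"]])
            spectra.append(
                TandemSpectrum(
                    spectrum_id=title,
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    peaks=peaks,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[TandemSpectrum], path: str | Path) -> None:
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.peaks[:, 1],
            "params": {
                "title": s.spectrum_id,
                "pepmass": s.precursor_mz,
                "charge": f"{s.precursor_charge}+",
            },
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# Masses and fragment ladders

def residue_masses(
    peptide: str,
    mods: Sequence[tuple[int, str]] = (),
    params: SearchParams | None = None,
) -> np.ndarray:
    """Per-residue monoisotopic masses with fixed + variable mods applied."""
    params = params or SearchParams()
    try:
        masses = np.array([_AA_MASS[a] for a in peptide], dtype=float)
    except KeyError as exc:
        raise ValueError(f"peptide {peptide!r}: unknown residue {exc}") from exc
    for i, a in enumerate(peptide):
        if a == "C":
            masses[i] += params.fixed_cys_delta
    deltas = {name: (res, d) for name, res, d in params.variable_mods}
    for pos, name in mods:
        res, d = deltas[name]
        if peptide[pos] != res:
            raise ValueError(f"mod {name} at {pos} does not sit on {res}")
        masses[pos] += d
    return masses


def peptide_mass(
    peptide: str,
    mods: Sequence[tuple[int, str]] = (),
    params: SearchParams | None = None,
) -> float:
    """Neutral monoisotopic peptide mass (residues + water + mod deltas)."""
    return float(residue_masses(peptide, mods, params).sum() + WATER)


def theoretical_ions(
    peptide: str,
    mods: Sequence[tuple[int, str]] = (),
    precursor_charge: int = 2,
    params: SearchParams | None = None,
) -> np.ndarray:
    """Sorted b/y fragment m/z ladder.

    Singly charged b- and y-ions for all proper prefixes/suffixes; doubly
    charged ions are added when the precursor charge is 3 or more.
    """
    masses = residue_masses(peptide, mods, params)
    prefix = np.cumsum(masses)[:-1]  # b fragments (neutral residue sums)
    suffix = np.cumsum(masses[::-1])[:-1] + WATER  # y fragments
    neutral = np.concatenate([prefix, suffix])
    mz = neutral + PROTON
    if precursor_charge >= 3:
        mz = np.concatenate([mz, (neutral + 2 * PROTON) / 2.0])
    return np.sort(mz)


def match_count(spectrum: TandemSpectrum, ions: np.ndarray, product_tol: float) -> int:
    """Number of theoretical ions with >=1 experimental peak within the
    tolerance; each theoretical ion counts at most once."""
    peaks = spectrum.mz
    lo = np.searchsorted(peaks, ions - product_tol, side="left")
    hi = np.searchsorted(peaks, ions + product_tol, side="right")
    return int(np.count_nonzero(hi > lo))


def poisson_tail(k: int, mu: float) -> float:
    """P(X >= k) for X ~ Poisson(mu)."""
    return float(poisson.sf(k - 1, mu))


def poisson_evalue(
    k: int,
    n_theoretical: int,
    spectrum: TandemSpectrum,
    params: SearchParams,
    n_candidates: int,
) -> float:
    """E-value of observing >= k random ion matches.

    The per-ion chance of a random match is the fraction of the spectrum's
    m/z range covered by tolerance windows around its peaks, so the null
    match count is Poisson with mean
    mu = n_theoretical * min(1, n_peaks * 2 * tol / range); the candidate
    multiplicity converts the tail probability into an expectation.
    """
    span = float(spectrum.mz[-1] - spectrum.mz[0])
    if span <= 0:
        frac = 1.0
    else:
        frac = min(1.0, spectrum.mz.size * 2.0 * params.product_tol / span)
    mu = n_theoretical * frac
    return poisson_tail(k, mu) * n_candidates


# ---------------------------------------------------------------------------
# Peptide index and search

@dataclass
class _Entry:
    mass: float
    peptide: str
    mods: tuple[tuple[int, str], ...]
    source_ids: frozenset[str]
    is_decoy: bool


class PeptideIndex:
    """Neutral-mass-sorted index of (modified) tryptic peptides.

    Built by digesting a target+decoy database and enumerating variable-mod
    isoforms.  Entries with the same I/L-normalized peptide and mod set are
    merged, pooling their source ids; an entry is a decoy entry only when
    every source is a decoy.
    """

    def __init__(
        self,
        records: Sequence[SequenceRecord],
        digest_params: DigestParams | None = None,
        search_params: SearchParams | None = None,
    ):
        digest_params = digest_params or DigestParams()
        self.search_params = search_params or SearchParams()
        sp = self.search_params
        delta_of = {name: d for name, _res, d in sp.variable_mods}
        # per-residue masses with the fixed mod folded in, for fast cumsums
        base_mass = dict(_AA_MASS)
        base_mass["C"] += sp.fixed_cys_delta
        merged: dict[tuple[str, tuple[tuple[int, str], ...]], _Entry] = {}
        for rec in records:
            cums = np.concatenate(
                ([0.0], np.cumsum([base_mass.get(a, math.nan) for a in rec.seq]))
            )
            for pep, s, e in digest(rec.seq, digest_params):
                base = float(cums[e] - cums[s]) + WATER
                if math.isnan(base):
                    continue  # X/B/Z-containing peptides are not searchable
                for mods in self._mod_isoforms(pep, sp):
                    key = (pep.replace("I", "L"), mods)
                    prev = merged.get(key)
                    if prev is None:
                        merged[key] = _Entry(
                            mass=base + sum(delta_of[n] for _p, n in mods),
                            peptide=pep,
                            mods=mods,
                            source_ids=frozenset([rec.id]),
                            is_decoy=rec.is_decoy,
                        )
                    else:
                        merged[key] = _Entry(
                            mass=prev.mass,
                            peptide=min(prev.peptide, pep),
                            mods=mods,
                            source_ids=prev.source_ids | {rec.id},
                            is_decoy=prev.is_decoy and rec.is_decoy,
                        )
        self.entries = sorted(merged.values(), key=lambda e: (e.mass, e.peptide, e.mods))
        self.masses = np.array([e.mass for e in self.entries], dtype=float)

    @staticmethod
    def _mod_isoforms(
        peptide: str, params: SearchParams
    ) -> list[tuple[tuple[int, str], ...]]:
        sites: list[tuple[int, str]] = []
        for name, res, _d in params.variable_mods:
            sites.extend((i, name) for i, a in enumerate(peptide) if a == res)
        isoforms: list[tuple[tuple[int, str], ...]] = []
        for r in range(min(params.max_variable_mods_per_peptide, len(sites)) + 1):
            for combo in itertools.combinations(sites, r):
                isoforms.append(tuple(sorted(combo)))
        return isoforms

    def __len__(self) -> int:
        return len(self.entries)

    def candidates(self, neutral_mass: float, tol: float) -> range:
        lo = int(np.searchsorted(self.masses, neutral_mass - tol, side="left"))
        hi = int(np.searchsorted(self.masses, neutral_mass + tol, side="right"))
        return range(lo, hi)


def search(
    spectra: Sequence[TandemSpectrum],
    index: PeptideIndex,
    params: SearchParams | None = None,
) -> list[PsmHit]:
    """Match every spectrum against the peptide index.

    Candidates are index entries within the precursor tolerance of the
    observed neutral mass; each is scored by matched b/y ions and assigned a
    Poisson-tail E-value.  Hits within the hit-list cap are returned with
    per-spectrum ranks (rank 1 = best; ties broken by I/L-normalized peptide
    string so results do not depend on database record order).
    """
    params = params or index.search_params
    if len(index) == 0:
        warnings.warn("empty peptide index; no hits")
        return []
    hits: list[PsmHit] = []
    for spec in spectra:
        cand = index.candidates(spec.neutral_mass, params.precursor_tol)
        n_candidates = len(cand)
        if n_candidates == 0:
            continue
        spec_hits: list[PsmHit] = []
        for ci in cand:
            entry = index.entries[ci]
            ions = theoretical_ions(entry.peptide, entry.mods, spec.precursor_charge, params)
            k = match_count(spec, ions, params.product_tol)
            ev = poisson_evalue(k, ions.size, spec, params, n_candidates)
            if ev > params.hitlist_max_evalue:
                continue
            spec_hits.append(
                PsmHit(
                    spectrum_id=spec.spectrum_id,
                    peptide=entry.peptide,
                    mods=entry.mods,
                    source_ids=entry.source_ids,
                    matched_ions=k,
                    total_theoretical_ions=int(ions.size),
                    evalue=ev,
                    is_decoy=entry.is_decoy,
                )
            )
        spec_hits.sort(key=lambda h: (h.evalue, h.peptide_key))
        for r, h in enumerate(spec_hits, start=1):
            h.rank = r
        hits.extend(spec_hits)
    return hits


def hits_to_tsv(hits: Iterable[PsmHit]) -> str:
    """PSM table: spectrum, peptide, mods, E-value, ions, sources, decoy, rank."""
    lines = [
        "spectrum_id\tpeptide\tmods\tevalue\tmatched\ttotal\tsource_ids\tdecoy\trank"
    ]
    for h in hits:
        mods = ";".join(f"{p}:{n}" for p, n in h.mods) or "-"
        lines.append(
            f"{h.spectrum_id}\t{h.peptide}\t{mods}\t{h.evalue:.6g}\t"
            f"{h.matched_ions}\t{h.total_theoretical_ions}\t"
            f"{','.join(sorted(h.source_ids))}\t{int(h.is_decoy)}\t{h.rank}"
        )
    return "\n".join(lines) + "\n"
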