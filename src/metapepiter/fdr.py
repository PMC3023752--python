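"""Target-decoy FDR estimation and thresholding.

Reversed-database decoy counting with the conventional decoys/targets
estimator, plus a fallback for sparse hit sets: when the regular scan cannot
establish a threshold, the E-value of the best decoy ("best false positive")
is used, capped at 0.01.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

from .psm import PsmHit

__all__ = ["FdrResult", "estimate_threshold", "fallback_threshold", "apply_fdr"]

FALLBACK_CAP_EVALUE = 0.01


@dataclass
class FdrResult:
    threshold_evalue: float
    n_target_accepted: int
    n_decoy_accepted: int
    fdr_nominal: float
    fallback_used: bool


def _rank1(hits: Sequence[PsmHit]) -> tuple[list[PsmHit], list[PsmHit]]:
    best = [h for h in hits if h.rank == 1]
    targets = sorted((h for h in best if not h.is_decoy), key=lambda h: h.evalue)
    decoys = sorted((h for h in best if h.is_decoy), key=lambda h: h.evalue)
    return targets, decoys


def estimate_threshold(hits: Sequence[PsmHit], fdr_nominal: float = 0.01) -> FdrResult:
    """Largest E-value threshold with estimated FDR <= ``fdr_nominal``.

    Candidate thresholds are the distinct E-values of rank-1 target hits,
    scanned ascending; at each, FDR is estimated as
    (#decoys <= t) / (#targets <= t).  Raises on an empty hit list.
    """
    if not hits:
        raise ValueError("empty hit list")
    targets, decoys = _rank1(hits)
    best_t = None
    best_counts = (0, 0)
    d_evs = [h.evalue for h in decoys]
    n_t = 0
    for i, h in enumerate(targets):
        # advance to the last target sharing this E-value
        if i + 1 < len(targets) and targets[i + 1].evalue == h.evalue:
            continue
        n_t = i + 1
        n_d = bisect.bisect_right(d_evs, h.evalue)
        if n_d / n_t <= fdr_nominal:
            best_t = h.evalue
            best_counts = (n_t, n_d)
    if best_t is None:
        return FdrResult(-1.0, 0, 0, fdr_nominal, False)
    return FdrResult(best_t, best_counts[0], best_counts[1], fdr_nominal, False)


def fallback_threshold(
    hits: Sequence[PsmHit],
    cap_evalue: float = FALLBACK_CAP_EVALUE,
    fdr_nominal: float = 0.01,
) -> FdrResult:
    """Sparse-hit fallback: threshold at the best decoy E-value (exclusive),
    never above ``cap_evalue``."""
    targets, decoys = _rank1(hits)
    threshold = min(decoys[0].evalue, cap_evalue) if decoys else cap_evalue
    exclusive = bool(decoys) and decoys[0].evalue <= cap_evalue
    if exclusive:
        n_t = sum(1 for h in targets if h.evalue < threshold)
        n_d = 0
    else:
        n_t = sum(1 for h in targets if h.evalue <= threshold)
        n_d = sum(1 for h in decoys if h.evalue <= threshold)
    return FdrResult(threshold, n_t, n_d, fdr_nominal, True)


def apply_fdr(
    hits: Sequence[PsmHit],
    fdr_nominal: float = 0.01,
    min_decoys: int = 1,
    cap_evalue: float = FALLBACK_CAP_EVALUE,
) -> tuple[list[PsmHit], FdrResult]:
    """Accepted rank-1 target hits at the nominal FDR.

    Uses the threshold scan; falls back to the best-false-positive rule when
    the scan accepts no targets or there are fewer than ``min_decoys`` decoy
    hits to estimate from.
    """
    if not hits:
        raise ValueError("empty hit list")
    targets, decoys = _rank1(hits)
    result = estimate_threshold(hits, fdr_nominal)
    if result.n_target_accepted == 0 or len(decoys) < min_decoys:
        result = fallback_threshold(hits, cap_evalue, fdr_nominal)
        if decoys and decoys[0].evalue <= cap_evalue:
            accepted = [h for h in targets if h.evalue < result.threshold_evalue]
        else:
            accepted = [h for h in targets if h.evalue <= result.threshold_evalue]
    else:
        accepted = [h for h in targets if h.evalue <= result.threshold_evalue]
    return accepted, result
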