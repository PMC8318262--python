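"""Two-factor peak-set comparison.

Tests whether one factor's peaks (the *query*, e.g. the lower-occupancy
factor) are a subset of another's (the *subject*) using the asymmetric
overlap-fraction rule: a query peak matches if at least ``min_fraction`` of
its own length is covered by some subject peak. Query peaks that fail the
rule are explained by a three-way classification: an overlapping subject
signal that stayed below the calling threshold, a nearby-but-shifted/wider
subject peak, or no nearby subject peak at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import ConfigError
from .peaks import Peak, PeakCallParams, call_peaks
from .tracks import CoverageTrack

UNMATCHED_REASONS = ("no_nearby_peak", "shifted_or_wider", "below_threshold")


@dataclass(frozen=True)
class OverlapParams:
    """min_fraction is a fraction of the QUERY peak's length; search_window is
    the summit-to-summit distance defining "same region"; relaxed_threshold is
    the probe threshold for the below-threshold explanation."""

    min_fraction: float = 0.5
    search_window: int = 1000
    relaxed_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.min_fraction <= 1):
            raise ConfigError("min_fraction must be in (0, 1]")
        if self.search_window < 0:
            raise ConfigError("search_window must be >= 0")


@dataclass(frozen=True)
class MatchedPeak:
    query: Peak
    best_subject: Peak
    fraction: float


def overlap_fraction(q: Peak, s: Peak) -> float:
    """|q ∩ s| / |q|; zero for different chromosomes."""
    if q.chrom != s.chrom:
        return 0.0
    inter = min(q.end, s.end) - max(q.start, s.start)
    return max(inter, 0) / q.width


def find_subset_peaks(
    query: Sequence[Peak],
    subject: Sequence[Peak],
    params: OverlapParams = OverlapParams(),
) -> tuple[list[MatchedPeak], list[Peak], int, float]:
    """Partition query peaks into matched/unmatched against subject peaks.

    A query peak is matched iff some subject peak covers at least
    ``min_fraction`` of it; the best-covering subject (ties: leftmost) is
    recorded. Returns (matched, unmatched, matched count, matched proportion).
    Uses a per-chromosome sorted sweep rather than all-pairs comparison.
    """
    subj_sorted: dict[str, list[Peak]] = {}
    for s in sorted(subject):
        subj_sorted.setdefault(s.chrom, []).append(s)

    matched: list[MatchedPeak] = []
    unmatched: list[Peak] = []
    for q in sorted(query):
        best: Optional[Peak] = None
        best_frac = 0.0
        for s in subj_sorted.get(q.chrom, []):
            if s.start >= q.end:
                break
            if s.end <= q.start:
                continue
            frac = overlap_fraction(q, s)
            if frac > best_frac:
                best, best_frac = s, frac
        if best is not None and best_frac >= params.min_fraction:
            matched.append(MatchedPeak(query=q, best_subject=best,
                                       fraction=best_frac))
        else:
            unmatched.append(q)
    n = len(query)
    count = len(matched)
    return matched, unmatched, count, (count / n if n else 0.0)


def classify_unmatched(
    q: Peak,
    subject_peaks: Sequence[Peak],
    subject_diff: Optional[CoverageTrack],
    params: OverlapParams = OverlapParams(),
    primary: PeakCallParams = PeakCallParams(),
) -> str:
    """Explain why an unmatched query peak has no qualifying subject peak.

    1. ``below_threshold``: re-calling the subject difference track at the
       relaxed threshold yields a peak covering >= min_fraction of q — there
       was subject signal, just under the primary threshold.
    2. ``shifted_or_wider``: a primary subject peak has its summit within
       ``search_window`` of q's summit (sub-fraction overlaps included).
    3. ``no_nearby_peak``: neither holds.

    With no ``subject_diff`` available only the two geometric reasons can be
    assigned; reason 1 is then reported as ``shifted_or_wider`` or
    ``no_nearby_peak`` with a ``*`` suffix flagging the missing probe.
    """
    if subject_diff is not None:
        relaxed = PeakCallParams(
            threshold=params.relaxed_threshold,
            min_width=primary.min_width,
            merge_gap=primary.merge_gap,
        )
        for s in call_peaks(subject_diff, relaxed):
            if overlap_fraction(q, s) >= params.min_fraction:
                return "below_threshold"
    nearby = any(
        s.chrom == q.chrom and abs(s.summit - q.summit) <= params.search_window
        for s in subject_peaks
    )
    reason = "shifted_or_wider" if nearby else "no_nearby_peak"
    return reason if subject_diff is not None else reason + "*"


def bound_gene_union(
    annots_query,
    annots_subject,
    matched: Sequence[MatchedPeak],
) -> list[str]:
    """Sorted unique genes annotated to matched query peaks or their best
    subject peaks — the "genes bound by both factors" set."""
    by_peak_q = {a.peak.name: a for a in annots_query}
    by_peak_s = {a.peak.name: a for a in annots_subject}
    genes: set[str] = set()
    for m in matched:
        for a in (by_peak_q.get(m.query.name), by_peak_s.get(m.best_subject.name)):
            if a is not None:
                genes.update(a.gene_ids)
    return sorted(genes)


def write_overlap_report(
    matched: Sequence[MatchedPeak],
    unmatched_reasons: Sequence[tuple[Peak, str]],
    path: str | Path,
) -> None:
    rows = [
        {"query": m.query.name, "status": "matched",
         "subject": m.best_subject.name, "fraction": round(m.fraction, 4),
         "reason": ""}
        for m in matched
    ] + [
        {"query": q.name, "status": "unmatched", "subject": "",
         "fraction": 0.0, "reason": reason}
        for q, reason in unmatched_reasons
    ]
    pd.DataFrame(
        rows, columns=["query", "status", "subject", "fraction", "reason"]
    ).to_csv(path, sep="\t", index=False)
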