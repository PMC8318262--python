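"""Threshold-based peak calling on a difference coverage track.

A peak is a maximal run of bases whose difference-track depth is at or above
a threshold (2.5 normalized-depth units by default, the value used throughout
this analysis style), after optional merging of runs separated by small gaps
and removal of runs shorter than a minimum width. The summit is the leftmost
position of maximal depth within the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .tracks import CoverageTrack


@dataclass(frozen=True)
class PeakCallParams:
    """Thresholding parameters.

    threshold:
        Minimum difference-track depth (inclusive) for a base to be enriched.
    min_width:
        Minimum peak width in bp after gap merging; shorter runs are noise.
    merge_gap:
        Runs separated by at most this many sub-threshold bases are merged.
    """

    threshold: float = 2.5
    min_width: int = 50
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigError("threshold must be > 0")
        if self.min_width < 1:
            raise ConfigError("min_width must be >= 1")
        if self.merge_gap < 0:
            raise ConfigError("merge_gap must be >= 0")


@dataclass(frozen=True, order=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int = field(compare=False, default=0)
    height: float = field(compare=False, default=0.0)
    name: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ConfigError(f"empty peak interval {self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start


def _runs_at_or_above(v: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    above = v >= threshold
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def call_peaks(
    diff: CoverageTrack,
    params: PeakCallParams = PeakCallParams(),
    name_prefix: str = "peak",
) -> list[Peak]:
    """Call peaks on a (clamped) difference track.

    Runs with depth >= threshold are found per chromosome, runs separated by
    <= merge_gap bases are merged, runs shorter than min_width are dropped,
    and the summit is the leftmost argmax of depth within each surviving run.
    Peaks are returned sorted by (chrom, start) and named
    ``<name_prefix>_<k>`` in that order.
    """
    out: list[Peak] = []
    for chrom in sorted(diff.data):
        v = diff.data[chrom]
        runs = _runs_at_or_above(v, params.threshold)
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] <= params.merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s < params.min_width:
                continue
            summit = s + int(np.argmax(v[s:e]))
            out.append(
                Peak(chrom=chrom, start=int(s), end=int(e), summit=summit,
                     height=float(v[summit]))
            )
    return [
        Peak(chrom=p.chrom, start=p.start, end=p.end, summit=p.summit,
             height=p.height, name=f"{name_prefix}_{k}")
        for k, p in enumerate(sorted(out), start=1)
    ]


def peak_set_summary(peaks: Sequence[Peak]) -> dict:
    """Count plus width/height quartiles of a peak set."""
    if not peaks:
        return {"count": 0}
    widths = np.array([p.width for p in peaks], dtype=float)
    heights = np.array([p.height for p in peaks], dtype=float)
    q = [0.25, 0.5, 0.75]
    return {
        "count": len(peaks),
        "width_quantiles": dict(zip(("q25", "q50", "q75"), np.quantile(widths, q))),
        "height_quantiles": dict(zip(("q25", "q50", "q75"), np.quantile(heights, q))),
        "total_bp": int(widths.sum()),
    }


def write_peaks_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as BED6+2: name, score=round(10*height), strand '.', then
    summit offset from peak start and summit height."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t"
                f"{round(10 * p.height)}\t.\t{p.summit - p.start}\t{float(p.height)!r}\n"
            )


def read_peaks_bed(path: str | Path) -> list[Peak]:
    peaks: list[Peak] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
            summit = start + int(f[6]) if len(f) > 6 else (start + end) // 2
            height = float(f[7]) if len(f) > 7 else 0.0
            peaks.append(Peak(chrom=chrom, start=start, end=end, summit=summit,
                              height=height, name=name))
    return peaks
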