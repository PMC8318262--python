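"""Per-base coverage tracks: build from fragment intervals, combine, normalize, subtract.

The central object is :class:`CoverageTrack`, a dense per-chromosome vector of
per-base fragment depth. ChIP enrichment is measured on a *difference track*:
the normalized coverage of the tagged sample minus that of the untagged
control, clamped at zero. All interval arithmetic is 0-based half-open (BED
convention); bedGraph serialization collapses runs of equal depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, InputError, NormalizationError

logger = logging.getLogger(__name__)

DEFAULT_NORMALIZATION_TARGET = 10_000_000


@dataclass
class CoverageTrack:
    """Dense per-base depth vectors keyed by chromosome.

    Attributes
    ----------
    data:
        Mapping chromosome name -> float64 vector of length equal to the
        chromosome; ``data[c][i]`` is the depth at base ``i``.
    total_fragments:
        Number of fragments that built the track (summed across replicates
        after :func:`combine_replicates`).
    scale_applied:
        Multiplicative factor applied by :func:`normalize_track` (1.0 for a
        raw track).
    """

    data: dict[str, np.ndarray]
    total_fragments: int
    scale_applied: float = 1.0

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    def same_chromosomes(self, other: "CoverageTrack") -> bool:
        return self.chrom_sizes == other.chrom_sizes


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``<chrom>\\t<length>`` file."""
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, length = line.split("\t")[:2]
        sizes[name] = int(length)
    return sizes


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read the first three columns of a BED file (chrom, start, end)."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], comment="#",
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                           "start": pd.Series(dtype=np.int64),
                           "end": pd.Series(dtype=np.int64)})
    return df


def build_coverage(
    fragments: str | Path | pd.DataFrame,
    chrom_sizes: Mapping[str, int],
) -> CoverageTrack:
    """Count, for every base, the number of fragments covering it.

    ``fragments`` is a BED3 path or an equivalent DataFrame with columns
    chrom/start/end (0-based half-open). Raises :class:`InputError` for
    intervals on unknown chromosomes or beyond chromosome ends, naming the
    offending record.
    """
    if not isinstance(fragments, pd.DataFrame):
        fragments = read_bed_intervals(fragments)
    data = {c: np.zeros(int(n), dtype=np.float64) for c, n in chrom_sizes.items()}
    total = 0
    for chrom, sub in fragments.groupby("chrom", sort=False):
        if chrom not in data:
            first = sub.iloc[0]
            raise InputError(
                f"unknown chromosome in record {chrom}:{first.start}-{first.end}"
            )
        size = len(data[chrom])
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        bad = (starts < 0) | (ends > size) | (starts >= ends)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise InputError(
                f"interval out of bounds or empty: {chrom}:{starts[i]}-{ends[i]}"
                f" (chromosome length {size})"
            )
        # classic difference-array coverage: +1 at starts, -1 at ends, cumsum
        delta = np.zeros(size + 1, dtype=np.float64)
        np.add.at(delta, starts, 1.0)
        np.add.at(delta, ends, -1.0)
        data[chrom] += np.cumsum(delta[:-1])
        total += len(sub)
    return CoverageTrack(data=data, total_fragments=total, scale_applied=1.0)


def combine_replicates(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Element-wise sum of replicate tracks; fragment totals add, scale resets."""
    if not tracks:
        raise InputError("no tracks to combine")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_chromosomes(t):
            raise InputError("tracks cover different chromosome sets or lengths")
    data = {c: sum(t.data[c] for t in tracks) for c in first.data}
    data = {c: np.asarray(v, dtype=np.float64) for c, v in data.items()}
    return CoverageTrack(
        data=data,
        total_fragments=sum(t.total_fragments for t in tracks),
        scale_applied=1.0,
    )


def normalize_track(
    track: CoverageTrack, target_fragments: int = DEFAULT_NORMALIZATION_TARGET
) -> CoverageTrack:
    """Scale depths so the track corresponds to ``target_fragments`` fragments."""
    if track.total_fragments <= 0:
        raise NormalizationError("cannot normalize a track with zero fragments")
    scale = target_fragments / track.total_fragments
    logger.info(
        "normalizing track: %d fragments -> target %d (scale %.6g)",
        track.total_fragments, target_fragments, scale,
    )
    return CoverageTrack(
        data={c: v * scale for c, v in track.data.items()},
        total_fragments=track.total_fragments,
        scale_applied=scale,
    )


def subtract_tracks(tagged: CoverageTrack, control: CoverageTrack) -> CoverageTrack:
    """Difference track ``max(0, tagged - control)``.

    Both tracks must be normalized to the same effective fragment count
    (``total_fragments * scale_applied``); negative differences are clamped to
    zero because only positive enrichment over the control is thresholded.
    """
    if not tagged.same_chromosomes(control):
        raise ContractError("tagged and control tracks cover different chromosomes")
    eff_t = tagged.total_fragments * tagged.scale_applied
    eff_c = control.total_fragments * control.scale_applied
    if not np.isclose(eff_t, eff_c, rtol=1e-6):
        raise ContractError(
            f"tracks normalized to different targets ({eff_t:.1f} vs {eff_c:.1f})"
        )
    data = {
        c: np.maximum(tagged.data[c] - control.data[c], 0.0) for c in tagged.data
    }
    return CoverageTrack(data=data, total_fragments=tagged.total_fragments,
                         scale_applied=tagged.scale_applied)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a 4-column bedGraph, run-length collapsed, zero runs omitted.

    Depths are written with shortest round-trip float formatting so a
    write/read cycle reproduces the vectors exactly.
    """
    with open(path, "w") as fh:
        for chrom in track.data:
            v = track.data[chrom]
            if len(v) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(v)]))
            for s, e in zip(starts, ends):
                depth = float(v[s])
                if depth == 0.0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{depth!r}\n")


def read_bedgraph(path: str | Path, chrom_sizes: Mapping[str, int]) -> CoverageTrack:
    """Read a bedGraph back into a dense track (total_fragments unknown -> 0)."""
    data = {c: np.zeros(int(n), dtype=np.float64) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, s, e, depth = line.split("\t")[:4]
            if chrom not in data:
                raise InputError(f"line {lineno}: unknown chromosome {chrom!r}")
            data[chrom][int(s):int(e)] = float(depth)
    return CoverageTrack(data=data, total_fragments=0, scale_applied=1.0)
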