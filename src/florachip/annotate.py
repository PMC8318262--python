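"""Peak-to-gene annotation by closest transcription start site.

Each peak is linked to the gene whose TSS is nearest its summit and classified
into one of six positional categories relative to that gene (upstream,
overlap_start, inside, overlap_end, downstream, encompassing), all strand
aware. A peak lying inside one gene whose nearest TSS belongs to an adjacent
gene is reported with both genes, nearest first — the dual-gene convention of
closest-TSS annotators.

Coordinates are 0-based half-open internally; GFF3 input (1-based inclusive)
is converted at the reader. For a gene body ``[s, e)`` the TSS base is ``s``
on the plus strand and ``e - 1`` on the minus strand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .peaks import Peak

logger = logging.getLogger(__name__)

CATEGORIES = (
    "upstream",
    "overlap_start",
    "inside",
    "overlap_end",
    "downstream",
    "encompassing",
)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int   # body start, 0-based
    end: int     # body end, half-open

    @property
    def tss(self) -> int:
        """TSS base: 5' end of the body in gene orientation."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """TES base: 3' end of the body in gene orientation."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class PeakAnnotation:
    peak: Peak
    gene_ids: tuple[str, ...]  # 1 or 2, primary (nearest TSS) first
    category: str
    signed_tss_distance: int   # negative = upstream of TSS in gene orientation


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene features from a GFF3 file (attribute key ``ID``)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise InputError(f"line {lineno}: expected 9 GFF3 columns")
            if f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID")
            if gid is None:
                raise InputError(f"line {lineno}: gene record lacks ID attribute")
            genes.append(
                GeneModel(gene_id=gid, chrom=f[0], strand=f[6],
                          start=int(f[3]) - 1, end=int(f[4]))
            )
    return genes


def write_gff3_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tflorachip\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def classify_position(peak: Peak, gene: GeneModel) -> str:
    """Six-way positional category of a peak relative to one gene.

    Decision order: encompassing (peak contains the whole body), overlap of
    the TSS base, overlap of the TES base, inside the body, wholly 5' of the
    TSS (upstream, strand aware), else downstream.
    """
    covers = lambda pos: peak.start <= pos < peak.end
    if peak.start <= gene.start and peak.end >= gene.end:
        return "encompassing"
    if covers(gene.tss):
        return "overlap_start"
    if covers(gene.tes):
        return "overlap_end"
    if peak.start >= gene.start and peak.end <= gene.end:
        return "inside"
    if gene.strand == "+":
        if peak.end <= gene.tss:
            return "upstream"
    else:
        if peak.start > gene.tss:
            return "upstream"
    return "downstream"


def signed_tss_distance(peak: Peak, gene: GeneModel) -> int:
    """Summit-to-TSS distance in gene orientation (negative = upstream)."""
    if gene.strand == "+":
        return peak.summit - gene.tss
    return gene.tss - peak.summit


def assign_closest_tss(
    peaks: Sequence[Peak], genes: Sequence[GeneModel]
) -> list[PeakAnnotation]:
    """Annotate each peak with the gene(s) of nearest TSS.

    Primary gene minimizes |summit - TSS| on the same chromosome (ties broken
    by lexicographically smaller gene id). If the peak overlaps the body of a
    different gene, that gene is reported second. Peaks on chromosomes with no
    genes are skipped with a warning.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index: dict[str, dict] = {}
    for chrom, gs in by_chrom.items():
        tss = np.array([g.tss for g in gs])
        order = np.argsort(tss, kind="stable")
        starts = np.array([g.start for g in gs])
        body_order = np.argsort(starts, kind="stable")
        index[chrom] = {
            "genes": gs,
            "tss_sorted": tss[order],
            "tss_order": order,
            "start_sorted": starts[body_order],
            "end_sorted": np.array([gs[i].end for i in body_order]),
            "body_order": body_order,
        }

    out: list[PeakAnnotation] = []
    for peak in peaks:
        idx = index.get(peak.chrom)
        if idx is None:
            warnings.warn(
                f"peak {peak.name or peak.start} on chromosome {peak.chrom!r} "
                "has no genes; left unannotated"
            )
            continue
        gs = idx["genes"]
        ts, order = idx["tss_sorted"], idx["tss_order"]
        j = int(np.searchsorted(ts, peak.summit))
        # candidate sorted positions flanking the insertion point
        cand = [k for k in (j - 1, j) if 0 <= k < len(ts)]
        best_d = min(abs(int(ts[k]) - peak.summit) for k in cand)
        # collect every gene achieving the minimal distance (tss values can tie)
        winners = [
            gs[int(order[k])]
            for k in range(len(ts))
            if abs(int(ts[k]) - peak.summit) == best_d
        ] if len(ts) <= 8 else _winners_binary(ts, order, gs, peak.summit, best_d)
        primary = min(winners, key=lambda g: g.gene_id)

        # dual-gene rule: a body-overlapping gene other than the primary
        overlapping = [
            g for g in gs
            if g.gene_id != primary.gene_id
            and g.start < peak.end and peak.start < g.end
        ]
        gene_ids: tuple[str, ...]
        if overlapping:
            second = min(
                overlapping,
                key=lambda g: (abs(g.tss - peak.summit), g.gene_id),
            )
            gene_ids = (primary.gene_id, second.gene_id)
        else:
            gene_ids = (primary.gene_id,)
        out.append(
            PeakAnnotation(
                peak=peak,
                gene_ids=gene_ids,
                category=classify_position(peak, primary),
                signed_tss_distance=signed_tss_distance(peak, primary),
            )
        )
    return out


def _winners_binary(ts, order, gs, summit, best_d):
    lo = int(np.searchsorted(ts, summit - best_d, side="left"))
    hi = int(np.searchsorted(ts, summit + best_d, side="right"))
    return [
        gs[int(order[k])] for k in range(lo, hi)
        if abs(int(ts[k]) - summit) == best_d
    ]


def summarize_positions(annots: Sequence[PeakAnnotation]) -> dict:
    """Fraction of peaks per category and mean |distance| of upstream peaks."""
    if not annots:
        return {"count": 0, "fractions": {}, "mean_upstream_distance": float("nan")}
    n = len(annots)
    fractions = {
        c: sum(1 for a in annots if a.category == c) / n for c in CATEGORIES
    }
    up = [abs(a.signed_tss_distance) for a in annots if a.category == "upstream"]
    return {
        "count": n,
        "fractions": fractions,
        "mean_upstream_distance": float(np.mean(up)) if up else float("nan"),
    }


def write_annotations(annots: Sequence[PeakAnnotation], path: str | Path) -> None:
    rows = [
        {
            "peak": a.peak.name,
            "chrom": a.peak.chrom,
            "summit": a.peak.summit,
            "gene_ids": ",".join(a.gene_ids),
            "category": a.category,
            "signed_tss_distance": a.signed_tss_distance,
        }
        for a in annots
    ]
    pd.DataFrame(
        rows,
        columns=["peak", "chrom", "summit", "gene_ids", "category",
                 "signed_tss_distance"],
    ).to_csv(path, sep="\t", index=False)
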