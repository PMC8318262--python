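"""End-to-end orchestration: simulate -> coverage -> peaks -> annotate ->
set comparison -> motifs -> targets, from one flat config, with a manifest.

Each stage writes its outputs under the run directory and records record
counts in the manifest; a rerun with the same config and seed is
byte-identical on all text outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    PeakAnnotation,
    assign_closest_tss,
    summarize_positions,
    write_annotations,
)
from .errors import ConfigError, StageError
from .motifs import (
    OffsetSummary,
    extract_peak_sequences,
    offsets_between,
    scan,
    write_hits,
)
from .peaks import Peak, PeakCallParams, call_peaks, peak_set_summary, write_peaks_bed
from .setops import (
    MatchedPeak,
    OverlapParams,
    bound_gene_union,
    classify_unmatched,
    find_subset_peaks,
    write_overlap_report,
)
from .synthio import SimConfig, SimBundle, generate_bundle, write_bundle
from .targets import (
    ExpressionRecord,
    direct_target_report,
    fisher_enrichment,
    intersect_gene_sets,
    read_term_table,
)
from .tracks import (
    CoverageTrack,
    build_coverage,
    combine_replicates,
    normalize_track,
    subtract_tracks,
    write_bedgraph,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "coverage", "peaks_A", "peaks_B",
    "annotate", "setops", "motifs", "targets",
)


@dataclass(frozen=True)
class AnalysisParams:
    """Analysis-side knobs of the flat run config."""

    threshold: float = 2.5
    min_width: int = 50
    merge_gap: int = 0
    min_fraction: float = 0.5
    search_window: int = 1000
    relaxed_threshold: float = 1.0
    motif_p_threshold: float = 1e-4
    query_offset: int = 2
    # None -> scale each tagged/control pair to the smaller of their two
    # totals; down-scaling the deeper track avoids inflating Poisson noise
    # in the sparser one (the usual treatment-vs-control scaling rule)
    normalization_target: Optional[int] = None

    def peak_params(self) -> PeakCallParams:
        return PeakCallParams(
            threshold=self.threshold, min_width=self.min_width,
            merge_gap=self.merge_gap,
        )

    def overlap_params(self) -> OverlapParams:
        return OverlapParams(
            min_fraction=self.min_fraction, search_window=self.search_window,
            relaxed_threshold=self.relaxed_threshold,
        )


def load_run_config(path: str | Path) -> tuple[SimConfig, AnalysisParams]:
    """Parse the flat YAML config into simulation and analysis halves."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("run config must be a flat mapping")
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    ana_fields = {f.name for f in dataclasses.fields(AnalysisParams)}
    unknown = set(raw) - sim_fields - ana_fields
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = SimConfig(**{k: v for k, v in raw.items() if k in sim_fields})
    cfg.validate()
    params = AnalysisParams(**{k: v for k, v in raw.items() if k in ana_fields})
    return cfg, params


@dataclass
class PipelineResult:
    bundle: SimBundle
    diff: dict[str, CoverageTrack]
    peaks: dict[str, list[Peak]]
    annots: dict[str, list[PeakAnnotation]]
    matched: list[MatchedPeak]
    unmatched_reasons: list[tuple[Peak, str]]
    matched_proportion: float
    bound_genes: list[str]
    hits: dict[str, list]
    offsets: OffsetSummary
    enrichment: list
    venn: dict
    report: pd.DataFrame
    manifest: dict


def _difference_track(
    tagged_frames, control_frames, chrom_sizes, target: Optional[int]
) -> CoverageTrack:
    tagged = combine_replicates(
        [build_coverage(df, chrom_sizes) for df in tagged_frames]
    )
    control = combine_replicates(
        [build_coverage(df, chrom_sizes) for df in control_frames]
    )
    if control.total_fragments == 0:
        # nothing to subtract; the tagged track is already the difference
        return tagged
    t = target or min(tagged.total_fragments, control.total_fragments)
    return subtract_tracks(
        normalize_track(tagged, t), normalize_track(control, t)
    )


def run_pipeline(
    config: str | Path | tuple[SimConfig, AnalysisParams],
    outdir: str | Path,
) -> PipelineResult:
    """Execute all stages; returns in-memory results plus the manifest."""
    if isinstance(config, (str, Path)):
        cfg, params = load_run_config(config)
    else:
        cfg, params = config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {**dataclasses.asdict(cfg), **dataclasses.asdict(params)},
        "stages": {},
    }

    def record(stage: str, outputs: dict[str, Path], counts: dict[str, int]):
        # paths are stored relative to the run directory so that identical
        # configs yield byte-identical manifests wherever the run lives
        manifest["stages"][stage] = {
            "outputs": {
                k: str(Path(v).relative_to(outdir)) for k, v in outputs.items()
            },
            "counts": counts,
        }

    t0 = time.time()
    stage = "simulate"
    try:
        bundle = generate_bundle(cfg)
        paths = write_bundle(bundle, outdir / "sim")
        record(stage, paths, {
            "genes": len(bundle.genes),
            "sites_A": len(bundle.sites),
            "sites_B": sum(1 for s in bundle.sites if s.is_b),
            "fragments": sum(
                len(df) for reps in bundle.fragments.values() for df in reps
            ),
        })
        logger.info("stage %s done in %.2fs", stage, time.time() - t0)

        stage = "coverage"
        chrom_sizes = bundle.chrom_sizes
        diff = {}
        for factor, sample in (("A", "tagged_A"), ("B", "tagged_B")):
            diff[factor] = _difference_track(
                bundle.fragments[sample], bundle.fragments["untagged"],
                chrom_sizes, params.normalization_target,
            )
            write_bedgraph(diff[factor], outdir / f"diff_{factor}.bedgraph")
        record(stage, {f"diff_{f}": outdir / f"diff_{f}.bedgraph" for f in diff},
               {f"nonzero_bases_{f}": int(sum((v > 0).sum() for v in diff[f].data.values()))
                for f in diff})

        peaks: dict[str, list[Peak]] = {}
        for factor in ("A", "B"):
            stage = f"peaks_{factor}"
            peaks[factor] = call_peaks(
                diff[factor], params.peak_params(), name_prefix=f"{factor}_peak"
            )
            p = outdir / f"peaks_{factor}.bed"
            write_peaks_bed(peaks[factor], p)
            record(stage, {"peaks": p}, {"peaks": len(peaks[factor])})

        stage = "annotate"
        annots = {}
        outputs, counts = {}, {}
        for factor in ("A", "B"):
            annots[factor] = assign_closest_tss(peaks[factor], bundle.genes)
            p = outdir / f"annot_{factor}.tsv"
            write_annotations(annots[factor], p)
            outputs[f"annot_{factor}"] = p
            counts[f"annot_{factor}"] = len(annots[factor])
        record(stage, outputs, counts)

        stage = "setops"
        matched, unmatched, n_matched, prop = find_subset_peaks(
            peaks["B"], peaks["A"], params.overlap_params()
        )
        unmatched_reasons = [
            (
                q,
                classify_unmatched(
                    q, peaks["A"], diff["A"], params.overlap_params(),
                    params.peak_params(),
                ),
            )
            for q in unmatched
        ]
        p = outdir / "overlap_report.tsv"
        write_overlap_report(matched, unmatched_reasons, p)
        bound = bound_gene_union(annots["B"], annots["A"], matched)
        bound_path = outdir / "bound_genes.txt"
        bound_path.write_text("".join(g + "\n" for g in bound))
        record(stage, {"overlap_report": p, "bound_genes": bound_path},
               {"matched": n_matched, "unmatched": len(unmatched),
                "bound_genes": len(bound)})

        stage = "motifs"
        shared = [m.query for m in matched]
        seqs = extract_peak_sequences(
            outdir / "sim" / "genome.fa", shared
        )
        motif_a, motif_b = bundle.motifs
        hits = {
            "A": scan(seqs, motif_a, params.motif_p_threshold),
            "B": scan(seqs, motif_b, params.motif_p_threshold),
        }
        offsets = offsets_between(
            hits["A"], hits["B"], seqs.keys(), query_offset=params.query_offset
        )
        outputs = {}
        for f in hits:
            outputs[f"hits_{f}"] = outdir / f"hits_{f}.tsv"
            write_hits(hits[f], outputs[f"hits_{f}"])
        offsets_path = outdir / "offsets.json"
        offsets_path.write_text(json.dumps({
            "histogram": {str(k): v for k, v in offsets.histogram.items()},
            "modal_offset": offsets.modal_offset,
            "n_a_hits": offsets.n_a_hits,
            "n_a_at_modal": offsets.n_a_at_modal,
            "query_offset": offsets.query_offset,
            "n_a_at_query": offsets.n_a_at_query,
        }, indent=2) + "\n")
        outputs["offsets"] = offsets_path
        record(stage, outputs, {
            "hits_A": len(hits["A"]), "hits_B": len(hits["B"]),
            "offset_pairs": sum(offsets.histogram.values()),
        })

        stage = "targets"
        universe = [g.gene_id for g in bundle.genes]
        terms = read_term_table(outdir / "sim" / "terms.tsv")
        enrichment = fisher_enrichment(bound, terms, universe)
        enrich_path = outdir / "enrichment.tsv"
        pd.DataFrame([dataclasses.asdict(r) for r in enrichment]).to_csv(
            enrich_path, sep="\t", index=False
        )
        de_records = {
            label: [
                ExpressionRecord(gene_id=r.gene_id, log2fc=r.log2fc, dataset=label)
                for r in df.itertuples()
            ]
            for label, df in bundle.de_tables.items()
        }
        venn = intersect_gene_sets(bound, de_records)
        venn_path = outdir / "venn.json"
        venn_path.write_text(json.dumps(venn, indent=2, sort_keys=True) + "\n")
        report = direct_target_report(
            annots["B"] + annots["A"], bound, de_records,
            loss_dataset="loss_mutant",
        )
        report_path = outdir / "direct_targets.tsv"
        report.to_csv(report_path, sep="\t", index=False)
        record(stage, {"enrichment": enrich_path, "venn": venn_path,
                       "direct_targets": report_path},
               {"enriched_terms": len(enrichment),
                "candidates": len(report),
                "top_tier": int(report["top_tier"].sum()) if len(report) else 0})
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline finished in %.2fs", time.time() - t0)
    return PipelineResult(
        bundle=bundle, diff=diff, peaks=peaks, annots=annots,
        matched=matched, unmatched_reasons=unmatched_reasons,
        matched_proportion=prop, bound_genes=bound, hits=hits,
        offsets=offsets, enrichment=enrichment, venn=venn, report=report,
        manifest=manifest,
    )
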