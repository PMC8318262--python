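"""Synthetic ChIP fixture generator with planted, recoverable structure.

Emulates the data layout of a two-factor, two-replicate ChIP experiment with
an untagged control: a toy genome, non-overlapping gene models, planted
binding sites for a primary factor A with a lower-occupancy subset also bound
by factor B, already-aligned fragment intervals (BED) per sample/replicate,
differential-expression tables with controlled overlap with the bound genes,
a toy term->gene annotation table, and the two factor consensus motifs as a
MEME file. Embedded motif instances satisfy both consensi simultaneously so
that the A motif scans back exactly 2 bp downstream of the B motif — the
nested-motif geometry of the AIL/PLT factor pair this emulates.

Everything is driven by one :class:`SimConfig`; the same config (seed
included) reproduces the bundle byte for byte.

What the generator does NOT model: sequencing errors, PCR duplicates,
mappability, chromatin accessibility, or realistic genome composition.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .annotate import GeneModel, write_gff3_genes
from .errors import ConfigError, PlacementError
from .motifs import (
    IUPAC,
    MOTIF_A_CONSENSUS,
    MOTIF_B_CONSENSUS,
    PWMotif,
    pwm_from_consensus,
    reverse_complement,
    write_meme,
)

BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment.

    Counts are per the two-replicate tagged/control design; ``amp_A`` is the
    mean fragment yield per planted A site per replicate, ``amp_ratio_B``
    scales it for the lower-occupancy factor B, ``background_rate`` is in
    fragments per kb per replicate.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 500_000
    n_genes: int = 150
    n_sites_A: int = 50
    subset_frac_B: float = 0.2
    amp_A: int = 30
    amp_ratio_B: float = 0.5
    frag_len: int = 200
    background_rate: float = 0.5
    n_replicates: int = 2
    de_overlap_frac: float = 0.8
    de_up_frac: float = 0.5
    # fraction of genes present in both DE tables given opposite signs;
    # default mirrors the 15-of-29 opposite-regulation split this emulates
    de_opposite_frac: float = 15 / 29
    n_de_background: int = 40
    # site placement: this fraction of sites goes within tss_window bp
    # upstream of a random TSS, the rest uniform genome-wide
    tss_bias_frac: float = 0.7
    tss_window: int = 2500
    min_site_spacing: int = 1000
    n_terms: int = 10

    def validate(self) -> None:
        counts = {
            "n_chrom": self.n_chrom, "chrom_len": self.chrom_len,
            "n_genes": self.n_genes, "n_sites_A": self.n_sites_A,
            "amp_A": self.amp_A, "frag_len": self.frag_len,
            "n_replicates": self.n_replicates,
        }
        for name, value in counts.items():
            if int(value) < 1:
                raise ConfigError(f"{name} must be >= 1 (got {value})")
        fracs = {
            "subset_frac_B": self.subset_frac_B,
            "de_overlap_frac": self.de_overlap_frac,
            "de_up_frac": self.de_up_frac,
            "de_opposite_frac": self.de_opposite_frac,
            "tss_bias_frac": self.tss_bias_frac,
        }
        for name, value in fracs.items():
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1] (got {value})")
        if not (0.0 < self.amp_ratio_B <= 1.0):
            raise ConfigError("amp_ratio_B must be in (0, 1]")
        if self.background_rate < 0:
            raise ConfigError("background_rate must be >= 0")
        if self.chrom_len <= 10 * self.frag_len:
            raise ConfigError("chrom_len must exceed 10 x frag_len")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


@dataclass(frozen=True)
class PlantedSite:
    chrom: str
    center: int
    factor: str            # 'B_and_A' or 'A_only'
    motif_embedded: bool
    strand: str = "+"      # orientation of the embedded motif instance

    @property
    def is_b(self) -> bool:
        return self.factor == "B_and_A"


@dataclass
class SimBundle:
    """In-memory handle on a generated fixture set."""

    cfg: SimConfig
    genome: dict[str, bytearray]
    genes: list[GeneModel]
    sites: list[PlantedSite]
    fragments: dict[str, list[pd.DataFrame]]     # sample -> per-replicate BED frames
    de_tables: dict[str, pd.DataFrame]           # dataset label -> (gene_id, log2fc)
    terms: pd.DataFrame                          # term_id, term_name, gene_id
    motifs: tuple[PWMotif, PWMotif]              # (factor A, factor B)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def b_bound_genes(self) -> list[str]:
        return nearest_genes_to_sites(
            [s for s in self.sites if s.is_b], self.genes
        )

    def a_bound_genes(self) -> list[str]:
        return nearest_genes_to_sites(self.sites, self.genes)


# -- generation steps -------------------------------------------------------


def generate_genome(cfg: SimConfig, rng: np.random.Generator) -> dict[str, bytearray]:
    cfg.validate()
    genome: dict[str, bytearray] = {}
    for i in range(cfg.n_chrom):
        codes = rng.integers(0, 4, size=cfg.chrom_len)
        seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes]
        genome[f"chr{i + 1}"] = bytearray(seq.tobytes())
    return genome


def generate_gene_models(
    cfg: SimConfig, genome: dict[str, bytearray], rng: np.random.Generator
) -> list[GeneModel]:
    """Place non-overlapping genes of length 500-3000 bp, random strand."""
    chroms = sorted(genome)
    total = sum(len(genome[c]) for c in chroms)
    if cfg.n_genes * 500 > total:
        raise PlacementError(
            f"cannot place {cfg.n_genes} genes of >= 500 bp in {total} bp"
        )
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneModel] = []
    width = len(str(cfg.n_genes))
    tries = 0
    max_tries = 200 * cfg.n_genes
    while len(genes) < cfg.n_genes:
        if tries > max_tries:
            raise PlacementError(
                f"placed only {len(genes)}/{cfg.n_genes} genes after "
                f"{max_tries} attempts"
            )
        tries += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(500, 3001))
        limit = len(genome[chrom]) - length
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        iv = (start, start + length)
        j = bisect_left(occupied[chrom], iv)
        prev_ok = j == 0 or occupied[chrom][j - 1][1] <= start
        next_ok = j == len(occupied[chrom]) or occupied[chrom][j][0] >= iv[1]
        if not (prev_ok and next_ok):
            continue
        insort(occupied[chrom], iv)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"gene_{len(genes) + 1:0{width}d}", chrom=chrom,
                strand=strand, start=start, end=start + length,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def _resolve_nested_instance(rng: np.random.Generator) -> str:
    """Concrete sequence matching the B consensus at offset 0 and the A
    consensus at offset 2; length = 2 + width(A)."""
    length = 2 + len(MOTIF_A_CONSENSUS)
    letters = []
    for pos in range(length):
        allowed = set(IUPAC[MOTIF_B_CONSENSUS[pos]]) if pos < len(MOTIF_B_CONSENSUS) else set(BASES)
        if pos >= 2:
            allowed &= set(IUPAC[MOTIF_A_CONSENSUS[pos - 2]])
        choices = sorted(allowed)
        letters.append(choices[int(rng.integers(len(choices)))])
    return "".join(letters)


def plant_sites_and_motifs(
    cfg: SimConfig,
    genome: dict[str, bytearray],
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
) -> tuple[list[PlantedSite], tuple[PWMotif, PWMotif]]:
    """Plant A sites (a random subset also B), embedding nested motif
    instances into the genome at each site.

    ``tss_bias_frac`` of sites land uniformly within ``tss_window`` bp
    upstream (strand-aware) of a random TSS; the rest are uniform. Site
    centers keep ``min_site_spacing`` bp apart and clear of chromosome ends.
    Embedding mutates ``genome`` in place so FASTA and site records agree.
    """
    chroms = sorted(genome)
    margin = 2 * cfg.frag_len + 50
    centers: dict[str, list[int]] = {c: [] for c in chroms}
    placed: list[tuple[str, int]] = []
    tries, max_tries = 0, 500 * cfg.n_sites_A
    while len(placed) < cfg.n_sites_A:
        if tries > max_tries:
            raise PlacementError(
                f"placed only {len(placed)}/{cfg.n_sites_A} sites after "
                f"{max_tries} attempts; relax min_site_spacing or enlarge genome"
            )
        tries += 1
        if rng.random() < cfg.tss_bias_frac and genes:
            g = genes[int(rng.integers(len(genes)))]
            offset = int(rng.integers(1, cfg.tss_window + 1))
            center = g.tss - offset if g.strand == "+" else g.tss + offset
            chrom = g.chrom
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            center = int(rng.integers(margin, len(genome[chrom]) - margin))
        if not (margin <= center < len(genome[chrom]) - margin):
            continue
        j = bisect_left(centers[chrom], center)
        near = [
            centers[chrom][k]
            for k in (j - 1, j)
            if 0 <= k < len(centers[chrom])
        ]
        if any(abs(center - c) < cfg.min_site_spacing for c in near):
            continue
        insort(centers[chrom], center)
        placed.append((chrom, center))

    placed.sort()
    n_b = round(cfg.n_sites_A * cfg.subset_frac_B)
    b_idx = set(rng.choice(len(placed), size=n_b, replace=False).tolist())

    sites: list[PlantedSite] = []
    for i, (chrom, center) in enumerate(placed):
        strand = "+" if rng.random() < 0.5 else "-"
        instance = _resolve_nested_instance(rng)
        if strand == "-":
            written = reverse_complement(instance)
        else:
            written = instance
        start = center - len(written) // 2
        genome[chrom][start:start + len(written)] = written.encode("ascii")
        sites.append(
            PlantedSite(
                chrom=chrom, center=center,
                factor="B_and_A" if i in b_idx else "A_only",
                motif_embedded=True, strand=strand,
            )
        )
    motif_a = pwm_from_consensus(MOTIF_A_CONSENSUS, motif_id="factorA_MEME2")
    motif_b = pwm_from_consensus(MOTIF_B_CONSENSUS, motif_id="factorB_MEME2")
    return sites, (motif_a, motif_b)


def simulate_fragments(
    cfg: SimConfig,
    chrom_sizes: dict[str, int],
    sites: Sequence[PlantedSite],
    rng: np.random.Generator,
) -> dict[str, list[pd.DataFrame]]:
    """Fragment BED frames for tagged_A, tagged_B, untagged x replicates.

    Background fragments start uniformly at Poisson(background_rate/kb)
    density; tagged samples add Poisson(amp) fragments per cognate site whose
    centers scatter normally (sd = frag_len/2) around the site center.
    """
    chroms = sorted(chrom_sizes)
    samples = {
        "tagged_A": [s for s in sites],
        "tagged_B": [s for s in sites if s.is_b],
        "untagged": [],
    }
    amps = {
        "tagged_A": float(cfg.amp_A),
        "tagged_B": cfg.amp_A * cfg.amp_ratio_B,
        "untagged": 0.0,
    }
    out: dict[str, list[pd.DataFrame]] = {}
    for sample in ("tagged_A", "tagged_B", "untagged"):
        reps = []
        for _ in range(cfg.n_replicates):
            rows_chrom, rows_start = [], []
            for chrom in chroms:
                size = chrom_sizes[chrom]
                n_bg = int(rng.poisson(size / 1000 * cfg.background_rate))
                if n_bg:
                    starts = rng.integers(0, size - cfg.frag_len, size=n_bg)
                    rows_chrom.extend([chrom] * n_bg)
                    rows_start.extend(starts.tolist())
            for s in samples[sample]:
                n = int(rng.poisson(amps[sample]))
                if not n:
                    continue
                centers = rng.normal(s.center, cfg.frag_len / 2, size=n)
                starts = np.rint(centers - cfg.frag_len / 2).astype(int)
                starts = np.clip(starts, 0, chrom_sizes[s.chrom] - cfg.frag_len)
                rows_chrom.extend([s.chrom] * n)
                rows_start.extend(starts.tolist())
            df = pd.DataFrame({
                "chrom": pd.Series(rows_chrom, dtype=str),
                "start": pd.Series(rows_start, dtype=np.int64),
            })
            df["end"] = df["start"] + cfg.frag_len
            df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
            reps.append(df)
        out[sample] = reps
    return out


def nearest_genes_to_sites(
    sites: Sequence[PlantedSite], genes: Sequence[GeneModel]
) -> list[str]:
    """Sorted unique ids of the nearest-TSS gene for each site center."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    found: set[str] = set()
    for s in sites:
        gs = by_chrom.get(s.chrom, [])
        if not gs:
            continue
        best = min(gs, key=lambda g: (abs(g.tss - s.center), g.gene_id))
        found.add(best.gene_id)
    return sorted(found)


def generate_de_tables(
    cfg: SimConfig,
    genes: Sequence[GeneModel],
    sites: Sequence[PlantedSite],
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Two DE tables (loss_mutant, induction) with controlled structure.

    Genes nearest a B site enter each table with probability
    ``de_overlap_frac``; among genes landing in both, a ``de_opposite_frac``
    share receives opposite signs. ``n_de_background`` unbound genes pad each
    table, signed positive with probability ``de_up_frac``.
    """
    bound = nearest_genes_to_sites([s for s in sites if s.is_b], genes)
    unbound = sorted(set(g.gene_id for g in genes) - set(bound))

    entries: dict[str, dict[str, float]] = {"loss_mutant": {}, "induction": {}}

    def magnitude() -> float:
        return round(float(rng.uniform(0.2, 2.5)), 3)

    def sign() -> int:
        return 1 if rng.random() < cfg.de_up_frac else -1

    for gene in bound:
        in_loss = rng.random() < cfg.de_overlap_frac
        in_ind = rng.random() < cfg.de_overlap_frac
        if in_loss and in_ind:
            s = sign()
            if rng.random() < cfg.de_opposite_frac:
                signs = (s, -s)
            else:
                signs = (s, s)
            entries["loss_mutant"][gene] = signs[0] * magnitude()
            entries["induction"][gene] = signs[1] * magnitude()
        elif in_loss:
            entries["loss_mutant"][gene] = sign() * magnitude()
        elif in_ind:
            entries["induction"][gene] = sign() * magnitude()

    for label in ("loss_mutant", "induction"):
        pool = [g for g in unbound if g not in entries[label]]
        n_bg = min(cfg.n_de_background, len(pool))
        chosen = rng.choice(len(pool), size=n_bg, replace=False)
        for idx in sorted(chosen.tolist()):
            entries[label][pool[idx]] = sign() * magnitude()

    return {
        label: pd.DataFrame(
            {"gene_id": sorted(vals), "log2fc": [vals[g] for g in sorted(vals)]}
        )
        for label, vals in entries.items()
    }


def generate_term_table(
    cfg: SimConfig,
    genes: Sequence[GeneModel],
    sites: Sequence[PlantedSite],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Flat term->gene table; term_01 is loaded with B-bound genes so the
    enrichment stage has real signal, the rest are random subsets."""
    all_ids = sorted(g.gene_id for g in genes)
    bound = nearest_genes_to_sites([s for s in sites if s.is_b], genes)
    rows = []
    for t in range(1, cfg.n_terms + 1):
        tid = f"TERM:{t:04d}"
        if t == 1:
            members = set(bound)
            extra = rng.choice(len(all_ids), size=min(5, len(all_ids)), replace=False)
            members |= {all_ids[i] for i in extra.tolist()}
            name = "planted_bound_process"
        else:
            k = int(rng.integers(10, 31))
            pick = rng.choice(len(all_ids), size=min(k, len(all_ids)), replace=False)
            members = {all_ids[i] for i in pick.tolist()}
            name = f"random_process_{t}"
        for g in sorted(members):
            rows.append({"term_id": tid, "term_name": name, "gene_id": g})
    return pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"])


# -- bundle assembly and serialization --------------------------------------


def generate_bundle(cfg: SimConfig) -> SimBundle:
    """Run all generation steps in fixed order from one seeded RNG."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genome = generate_genome(cfg, rng)
    genes = generate_gene_models(cfg, genome, rng)
    sites, motif_pair = plant_sites_and_motifs(cfg, genome, genes, rng)
    fragments = simulate_fragments(
        cfg, {c: len(s) for c, s in genome.items()}, sites, rng
    )
    de_tables = generate_de_tables(cfg, genes, sites, rng)
    terms = generate_term_table(cfg, genes, sites, rng)
    return SimBundle(
        cfg=cfg, genome=genome, genes=genes, sites=sites,
        fragments=fragments, de_tables=de_tables, terms=terms,
        motifs=motif_pair,
    )


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Serialize a bundle; returns a name -> path map of everything written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    records = [
        SeqRecord(Seq(bytes(seq).decode("ascii")), id=chrom, description="")
        for chrom, seq in sorted(bundle.genome.items())
    ]
    SeqIO.write(records, str(paths["genome"]), "fasta")

    paths["chrom_sizes"] = outdir / "chrom.sizes"
    paths["chrom_sizes"].write_text(
        "".join(f"{c}\t{n}\n" for c, n in sorted(bundle.chrom_sizes.items()))
    )

    paths["genes"] = outdir / "genes.gff3"
    write_gff3_genes(bundle.genes, paths["genes"])

    for label, pred in (("sites_A", lambda s: True), ("sites_B", lambda s: s.is_b)):
        p = outdir / f"{label}.bed"
        with open(p, "w") as fh:
            for s in bundle.sites:
                if pred(s):
                    fh.write(
                        f"{s.chrom}\t{s.center - 25}\t{s.center + 25}\t"
                        f"{s.factor}\t0\t{s.strand}\n"
                    )
        paths[label] = p

    frag_dir = outdir / "fragments"
    frag_dir.mkdir(exist_ok=True)
    for sample, reps in bundle.fragments.items():
        for k, df in enumerate(reps, 1):
            p = frag_dir / f"{sample}_rep{k}.bed"
            df.to_csv(p, sep="\t", header=False, index=False)
            paths[f"fragments/{sample}_rep{k}"] = p

    for label, df in bundle.de_tables.items():
        p = outdir / f"de_{label}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"de_{label}"] = p

    paths["terms"] = outdir / "terms.tsv"
    bundle.terms.to_csv(paths["terms"], sep="\t", index=False)

    paths["motifs"] = outdir / "motifs.meme"
    write_meme(list(bundle.motifs), paths["motifs"])

    paths["config"] = outdir / "sim_config.yaml"
    bundle.cfg.to_yaml(paths["config"])
    return paths
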