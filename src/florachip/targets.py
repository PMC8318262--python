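"""Term enrichment on bound-gene sets and ChIP x expression integration.

Enrichment uses the one-sided (over-representation) hypergeometric test —
the upper tail of Fisher's exact test on the 2x2 table of term membership
vs. selection — with Bonferroni correction over the tested terms. P-values
are computed with exact integer arithmetic so they agree with tail-sum
enumeration to machine precision.

Integration intersects the genes bound by both factors with differential-
expression tables from two perturbations (factor loss-of-function and factor
induction) and classifies each shared gene's regulation direction; genes
bound and oppositely regulated in the two perturbations are the strongest
direct-target candidates (a gene activated by the factor should fall when
the factor is lost and rise when it is induced).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import InputError


@dataclass(frozen=True)
class TermAnnotation:
    term_id: str
    term_name: str
    genes: frozenset[str]


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    k: int        # selected genes carrying the term
    n_sel: int    # selected-set size (within universe)
    K: int        # term size in universe
    N: int        # universe size
    p_value: float
    p_bonferroni: float


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    log2fc: float
    dataset: str  # e.g. 'loss_mutant', 'induction_4h', 'induction_8h'


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact.

    Computed as a rational number (integer binomials) and rounded once to
    float, so results match exhaustive tail enumeration bit-for-bit.
    """
    if k <= 0:
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, hi + 1))
    return float(Fraction(num, comb(N, n)))


def read_term_table(path: str | Path) -> list[TermAnnotation]:
    """Read a flat term->gene TSV (term_id, term_name, gene_id; 1 row/pair)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"term_id", "term_name", "gene_id"}
    if not required <= set(df.columns):
        raise InputError(f"term table must have columns {sorted(required)}")
    out = []
    for (tid, tname), sub in df.groupby(["term_id", "term_name"], sort=True):
        out.append(TermAnnotation(tid, tname, frozenset(sub["gene_id"])))
    return out


def fisher_enrichment(
    selected: Iterable[str],
    terms: Sequence[TermAnnotation],
    universe: Iterable[str],
) -> list[EnrichmentRow]:
    """Over-representation test of each term in the selected gene set.

    Terms with no annotated gene in the universe are excluded from testing
    and from the Bonferroni factor m. Rows are sorted by raw p (ties by
    term_id).
    """
    universe = set(universe)
    selected = set(selected)
    stray = sorted(selected - universe)
    if stray:
        raise InputError(f"selected genes outside universe: {stray}")
    N, n_sel = len(universe), len(selected)
    tested = [
        (t, t.genes & universe) for t in terms if t.genes & universe
    ]
    m = len(tested)
    rows = []
    for t, genes_in_universe in tested:
        K = len(genes_in_universe)
        k = len(genes_in_universe & selected)
        p = hypergeom_upper_tail(k, N, K, n_sel)
        rows.append(
            EnrichmentRow(
                term_id=t.term_id, term_name=t.term_name, k=k, n_sel=n_sel,
                K=K, N=N, p_value=p, p_bonferroni=min(1.0, m * p),
            )
        )
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def read_de_table(path: str | Path, dataset: str) -> list[ExpressionRecord]:
    """Read a DE TSV with columns gene_id, log2fc; duplicates deduplicated
    (first kept) with a warning."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "log2fc": float})
    if not {"gene_id", "log2fc"} <= set(df.columns):
        raise InputError("DE table must have columns gene_id, log2fc")
    if df["gene_id"].duplicated().any():
        dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
        warnings.warn(f"duplicate gene ids in {path}: {dupes}; keeping first")
        df = df.drop_duplicates("gene_id", keep="first")
    return [
        ExpressionRecord(gene_id=r.gene_id, log2fc=r.log2fc, dataset=dataset)
        for r in df.itertuples()
    ]


def intersect_gene_sets(
    bound: Iterable[str],
    de_tables: Mapping[str, Sequence[ExpressionRecord]],
) -> dict:
    """Venn intersections of the bound-gene set with each DE list and both.

    Returns sizes and sorted member lists keyed
    ``bound_and_<label>`` plus ``bound_and_all``.
    """
    bound = set(bound)
    result: dict = {"n_bound": len(bound)}
    members_all = bound.copy()
    for label, records in de_tables.items():
        de_genes = {r.gene_id for r in records}
        inter = sorted(bound & de_genes)
        result[f"n_{label}"] = len(de_genes)
        result[f"bound_and_{label}"] = inter
        result[f"n_bound_and_{label}"] = len(inter)
        members_all &= de_genes
    result["bound_and_all"] = sorted(members_all)
    result["n_bound_and_all"] = len(members_all)
    return result


LOSS_DATASET = "loss_mutant"


def classify_direction(
    gene: str, records: Sequence[ExpressionRecord], loss_dataset: str = LOSS_DATASET
) -> str:
    """Regulation-direction label for one gene across perturbation datasets.

    'opposite' when the loss-of-function sign differs from the induction
    sign, 'concordant' when both present with equal signs, 'ambiguous' when
    induction timepoints disagree with each other, else 'single_dataset'.
    Zero log2fc carries no direction and is dropped with a warning.
    """
    mine = [r for r in records if r.gene_id == gene]
    if not mine:
        raise InputError(f"no expression records for gene {gene}")
    usable = []
    for r in mine:
        if r.log2fc == 0:
            warnings.warn(f"{gene}: log2fc == 0 in {r.dataset}; no direction")
        else:
            usable.append(r)
    loss_signs = {r.log2fc > 0 for r in usable if r.dataset == loss_dataset}
    ind_signs = {r.log2fc > 0 for r in usable if r.dataset != loss_dataset}
    if not loss_signs or not ind_signs:
        return "single_dataset"
    if len(ind_signs) > 1:
        return "ambiguous"
    return "opposite" if loss_signs != ind_signs else "concordant"


def direct_target_report(
    annots,
    bound_genes: Iterable[str],
    de_tables: Mapping[str, Sequence[ExpressionRecord]],
    loss_dataset: str = LOSS_DATASET,
) -> pd.DataFrame:
    """One row per bound gene appearing in at least one DE table.

    Columns: gene, peaks, category, signed_tss_distance, the log2fc per
    dataset, datasets present, direction label, and top_tier — True for
    genes bound plus oppositely regulated in both perturbation types.
    """
    gene_peaks: dict[str, list] = {}
    for a in annots:
        for g in a.gene_ids:
            gene_peaks.setdefault(g, []).append(a)
    all_records: dict[str, list[ExpressionRecord]] = {}
    for records in de_tables.values():
        for r in records:
            all_records.setdefault(r.gene_id, []).append(r)

    rows = []
    for gene in sorted(set(bound_genes)):
        records = all_records.get(gene, [])
        if not records:
            continue
        direction = classify_direction(gene, records, loss_dataset=loss_dataset)
        ann = gene_peaks.get(gene, [])
        row = {
            "gene": gene,
            "peaks": ",".join(a.peak.name for a in ann),
            "category": ",".join(a.category for a in ann),
            "signed_tss_distance": ",".join(
                str(a.signed_tss_distance) for a in ann
            ),
            "datasets": ",".join(sorted({r.dataset for r in records})),
            "direction": direction,
            "top_tier": direction == "opposite",
        }
        for r in records:
            row[f"log2fc_{r.dataset}"] = r.log2fc
        rows.append(row)
    base_cols = ["gene", "peaks", "category", "signed_tss_distance",
                 "datasets", "direction", "top_tier"]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=base_cols)
    extra = sorted(c for c in df.columns if c not in base_cols)
    return df[base_cols + extra]
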