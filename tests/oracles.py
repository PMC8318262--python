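"""Independent brute-force reference implementations used only by tests.

Every function here re-derives a pipeline quantity by the most literal
possible method (per-base scans, all-pairs comparisons, exhaustive window
enumeration) so that the optimized package code can be checked against an
implementation that shares no code path with it.
"""

from __future__ import annotations

from math import comb

import numpy as np

BASES = "ACGT"


def coverage_oracle(intervals, length):
    """Per-base membership count: O(n_intervals * length)."""
    depth = [0.0] * length
    for start, end in intervals:
        for i in range(start, end):
            depth[i] += 1.0
    return np.array(depth)


def call_peaks_oracle(v, threshold, min_width, merge_gap):
    """Literal per-base run scan -> list of (start, end, summit, height)."""
    runs = []
    i, n = 0, len(v)
    while i < n:
        if v[i] >= threshold:
            j = i
            while j < n and v[j] >= threshold:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if e - s < min_width:
            continue
        summit = s
        for k in range(s, e):
            if v[k] > v[summit]:
                summit = k
        out.append((s, e, summit, float(v[summit])))
    return out


def nearest_tss_oracle(summit, genes):
    """All-pairs nearest TSS; returns the winning gene (lexicographic tie)."""
    best = None
    for g in genes:
        d = abs(g.tss - summit)
        if best is None or d < best[0] or (d == best[0] and g.gene_id < best[1]):
            best = (d, g.gene_id, g)
    return best[2]


def classify_oracle(p_start, p_end, g_start, g_end, strand):
    """Independent six-way positional classification from raw coordinates."""
    tss = g_start if strand == "+" else g_end - 1
    tes = g_end - 1 if strand == "+" else g_start
    if p_start <= g_start and p_end >= g_end:
        return "encompassing"
    if p_start <= tss < p_end:
        return "overlap_start"
    if p_start <= tes < p_end:
        return "overlap_end"
    if g_start <= p_start and p_end <= g_end:
        return "inside"
    if strand == "+" and p_end <= tss:
        return "upstream"
    if strand == "-" and p_start > tss:
        return "upstream"
    return "downstream"


def subset_oracle(query, subject, min_fraction):
    """All-pairs overlap-fraction partition -> (matched names, unmatched names)."""
    matched, unmatched = [], []
    subject = sorted(subject, key=lambda s: (s.chrom, s.start, s.end))
    for q in query:
        best_frac, best = 0.0, None
        for s in subject:
            if s.chrom != q.chrom:
                continue
            inter = min(q.end, s.end) - max(q.start, s.start)
            frac = max(inter, 0) / (q.end - q.start)
            if frac > best_frac:
                best_frac, best = frac, s
        if best is not None and best_frac >= min_fraction:
            matched.append((q.name, best.name))
        else:
            unmatched.append(q.name)
    return matched, unmatched


def scan_oracle(seq, motif, p_threshold):
    """Window-by-window scan on both strands using the quantized matrix.

    Returns a set of (start, strand, int_score) for hits at p <= threshold,
    where the p-value of an integer score is taken from exhaustive-or-DP-free
    re-derivation via the motif's tail only through public exact_pvalue.
    """
    from florachip.motifs import SCALE, exact_pvalue, reverse_complement

    ints = motif.int_logodds()
    w = motif.width
    hits = set()
    for strand in "+-":
        for start in range(len(seq) - w + 1):
            window = seq[start:start + w].upper()
            if "N" in window:
                continue
            probe = window if strand == "+" else reverse_complement(window)
            try:
                total = sum(
                    int(ints[i][BASES.index(probe[i])]) for i in range(w)
                )
            except ValueError:
                continue
            if exact_pvalue(motif, total / SCALE) <= p_threshold:
                hits.add((start, strand, total))
    return hits


def pvalue_enumeration_oracle(motif, score):
    """P(window >= score) by enumerating all 4**w background windows."""
    from florachip.motifs import SCALE

    ints = motif.int_logodds()
    w = motif.width
    bg = motif.background
    cutoff = int(round(score * SCALE))
    total_p = 0.0
    stack = [(0, 0, 1.0)]
    while stack:
        pos, acc, prob = stack.pop()
        if pos == w:
            if acc >= cutoff:
                total_p += prob
            continue
        for b in range(4):
            stack.append((pos + 1, acc + int(ints[pos][b]), prob * bg[b]))
    return total_p


def offsets_oracle(hits_a, hits_b):
    """All-pairs same-peak same-strand offset histogram."""
    hist: dict[int, int] = {}
    for a in hits_a:
        for b in hits_b:
            if a.seqname != b.seqname or a.strand != b.strand:
                continue
            d = a.start - b.start
            off = d if a.strand == "+" else -d
            hist[off] = hist.get(off, 0) + 1
    return hist


def hypergeom_tail_float_oracle(k, N, K, n):
    """Upper tail as a float sum of per-term probabilities."""
    if k <= 0:
        return 1.0
    denom = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) / denom
               for i in range(k, min(K, n) + 1))
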