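# Methods

This note records the models, conventions, and numerical choices behind
florachip, and what the synthetic experiments do and do not demonstrate.

## Coverage and the difference track

Coverage is the per-base count of fragments overlapping each position,
computed per chromosome with a difference array (+1 at starts, −1 at ends,
cumulative sum); intervals are 0-based half-open throughout, and GFF3 input
(1-based inclusive) is converted at the reader. Replicates are summed before
normalization.

Normalization scales a track's depths by `target / total_fragments`. The
standalone `normalize_track` default target is 10⁷ fragments, a conventional
library size. Inside the pipeline the tagged/control pair is instead scaled
to the **smaller** of the two totals. Scaling the deeper track down rather
than the sparser track up is the usual treatment-vs-control rule (it is what
MACS does by default): up-scaling a sparse track multiplies its Poisson
fluctuations, and on the synthetic data lets chance stacks of three
background fragments clear the calling threshold. Down-scaling keeps the
difference track in (sub-)raw-coverage units where the default threshold of
2.5 separates planted signal (depth ≳ 15 after scaling) from background
(mean depth ≈ 0.2) cleanly.

The difference track is clamped at zero: only positive enrichment over the
control is biologically meaningful here, and clamping makes peak boundaries
well defined.

## Peak calling

A peak is a maximal run of bases with difference depth ≥ τ (inclusive;
default τ = 2.5), after merging runs separated by ≤ `merge_gap` bases
(default 0) and discarding runs shorter than `min_width` (default 50 bp,
which suppresses few-fragment noise runs while being far below the ≈500 bp
width of a genuine peak at the default amplification). The summit is the
leftmost argmax of depth within the peak; leftmost tie-breaking keeps calls
deterministic. Note that the peak *count* is not monotone in τ — raising the
threshold can split one run into two — but the total enriched bp is, and the
higher-threshold peak set always occupies a subset of the lower-threshold
bases; the tests assert exactly that.

## Peak-to-gene annotation

The distance anchor is the peak summit, the best single-point estimate of
the binding position. The primary gene minimizes |summit − TSS| on the same
chromosome (ties go to the lexicographically smaller gene id). If the peak
overlaps the body of a different gene than the primary, both are reported,
primary first — the dual-gene convention for peaks lying inside one gene
whose neighbor's TSS is closer. For a gene body `[s, e)` the TSS base is `s`
(+ strand) or `e − 1` (− strand).

Positional categories are assigned in a fixed decision order: encompassing
(peak ⊇ body), overlap_start (peak covers the TSS base), overlap_end (covers
the TES base), inside (peak ⊆ body), upstream (wholly 5′ of the TSS, strand
aware), else downstream. The order matters only for peaks that satisfy
several geometric predicates and makes the six categories a partition.
"Mean upstream distance" averages |summit − TSS| over upstream-category
peaks only; peaks overlapping the TSS contribute to overlap_start instead.

## Peak-set comparison

`overlap_fraction(q, s) = |q ∩ s| / |q|` is deliberately asymmetric: the
query (lower-occupancy factor) peak is the denominator, matching the
"query peaks overlap at least 50% with a subject peak" phrasing and BEDtools
`-f` semantics. Matching uses a per-chromosome sorted sweep; the tests check
it against an all-pairs oracle.

Unmatched query peaks are explained in priority order: (1) *below_threshold*
if re-calling the subject difference track at a relaxed threshold (default
1.0) yields a peak covering ≥ the match fraction of the query — i.e. the
subject factor does bind there, just under the primary threshold; (2)
*shifted_or_wider* if a primary subject peak's summit lies within
`search_window` (default 1 kb, an operationalization of "the same region");
(3) *no_nearby_peak*. The order makes the three reasons mutually exclusive
and exhaustive. Without a subject difference track only the geometric
reasons are available and the reason is flagged with `*`.

## Motif model and exact p-values

IUPAC consensi become PWMs by giving the allowed letters a total probability
`strength` (default 0.95) split equally, the remainder shared by the other
letters; `N` is uniform. The two packaged consensi are the published MEME
motifs of the two factors; the A motif equals the B motif minus its leading
`GG`, so genuine co-occurrences sit at offset +2.

Scores are log-odds in bits against the background (uniform by default),
quantized to 1/1000 bit per matrix cell; window scores are sums of the
quantized cells, so scores and the null distribution live on one integer
lattice. The exact p-value `P(score′ ≥ score)` under the background is
computed by convolving the per-position score distributions (dynamic
programming), yielding a tail table; it is non-increasing in the score,
equals 1 at the minimum score, and matches exhaustive 4^w enumeration for
small widths. The default hit threshold is p ≤ 1e-4 (the FIMO default).
Minus-strand windows are scored with the reverse-complemented matrix and
share the forward tail table; with a non-uniform background this is an
approximation (exact for the uniform default).

Offsets between two motifs' hits are computed within shared peaks for
same-strand pairs as `start_a − start_b`, negated on the minus strand so the
sign is in motif orientation. Two pairing rules are reported, since both are
defensible: the all-pairs histogram (and its modal offset), and the count of
A hits having a B hit at exactly the modal (or a queried) offset. "Same
location" means the exact modal offset — no tolerance window.

## Enrichment and DE integration

Term enrichment is the one-sided over-representation test: the
hypergeometric upper tail `P(X ≥ k)` for k annotated genes among n selected,
term size K, universe N — the upper tail of Fisher's exact test. It is
computed with exact integer binomials and rounded once to float, so it
matches tail enumeration to machine precision. Bonferroni multiplies by the
number m of terms with at least one annotated gene in the universe (empty
terms are not tests), capped at 1. The universe defaults to all genes in the
GFF3.

Direction classification compares the sign of a gene's log2 fold change in
the loss-of-function dataset with its sign upon factor induction: opposite
signs mark candidate direct targets (a factor-activated gene falls when the
factor is lost and rises when it is induced); equal signs are concordant;
disagreeing induction timepoints give `ambiguous`; a gene present in only
one perturbation type is `single_dataset`. Zero fold changes carry no
direction and are dropped with a warning.

## The synthetic generator

The generator emulates the *design* of a two-replicate tagged/untagged ChIP
experiment, not its chemistry. Defaults (all in `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| n_chrom × chrom_len | 2 × 500 kb | toy genome |
| n_genes | 150 | non-overlapping genes, 0.5–3 kb, random strand |
| n_sites_A | 50 | planted factor-A sites |
| subset_frac_B | 0.2 | share of A sites also bound by B (B ⊂ A) |
| amp_A | 30 | mean fragments per site per replicate |
| amp_ratio_B | 0.5 | B occupancy relative to A (lower-occupancy factor) |
| frag_len | 200 bp | fragment length, a typical sonication size |
| background_rate | 0.5 /kb/replicate | uniform background fragments |
| n_replicates | 2 | per sample |
| de_overlap_frac | 0.8 | P(B-bound gene enters each DE table) |
| de_opposite_frac | 15/29 | opposite-sign share of doubly-DE bound genes |
| tss_bias_frac / tss_window | 0.7 / 2.5 kb | sites placed upstream of a TSS |

Site placement: 70% of sites land uniformly within 2.5 kb upstream
(strand-aware) of a random TSS and 30% uniformly, with ≥ 1 kb spacing so
peaks stay unimodal and distinct. Fragment centers scatter normally around
the site center with sd = frag_len/2, giving single-mode peaks; counts per
site and background counts are Poisson. At every site a concrete sequence
satisfying both consensi simultaneously (B at offset 0, A at offset +2) is
written into the genome on a random strand, so FASTA, site BED, and motif
fixtures stay consistent. A toy term table is emitted with one term loaded
with the B-bound genes so the enrichment stage has planted signal.

Everything derives from one `numpy` generator seeded by `SimConfig.seed` in
a fixed order, so an identical config reproduces the bundle byte for byte.

Not modeled: sequencing errors, PCR duplicates, mappability, GC or
accessibility bias, non-uniform background, diploidy, isoforms. Passing
tests therefore demonstrate the *computational* correctness and the
recoverability of planted structure under idealized noise — not performance
on real libraries, where background is structured and normalization choices
matter more.

## Problem sizes and determinism

The seed-averaged checks use ten pipeline runs on the 1 Mb toy genome
(~6000 fragments each), which keeps the whole suite and the acceptance
script in the tens of seconds while leaving ≥ 100 planted B peaks pooled for
the proportion estimates. Property-based tests are derandomized via fixed
seeds. All tie-breaks (summit, nearest-TSS gene, best subject peak, modal
offset) are leftmost/lexicographic/smallest-value so outputs are
reproducible across platforms.
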