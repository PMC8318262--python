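"""PWM motif scanning with exact p-value calibration, and motif-offset analysis.

Consensus strings in the degenerate IUPAC alphabet are converted to position
weight matrices; sequences are scanned on both strands with log-odds scores
(bits, relative to a background model), and each score is converted to an
exact p-value — the probability that a random background window scores at
least as high — computed by dynamic programming over the per-position score
distribution. Scores are quantized to 1/1000 bit per matrix cell so that
window scores and the p-value distribution live on the same integer lattice.

The offset analysis measures the signed start-coordinate spacing between
co-occurring hits of two motifs inside shared peaks, in motif orientation:
two factors recognizing the same genomic element through nested motifs show
a single modal offset (here +2 when the shorter motif equals the longer one
minus its first two positions).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .errors import ConfigError, InputError
from .peaks import Peak

SCALE = 1000  # score lattice: 1/1000 bit
BASES = "ACGT"
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# Published MEME consensus motifs for the two AIL/PLT-family factors studied
# here; the factor-A motif equals the factor-B motif minus its first two
# positions (the leading GG), hence co-occurring hits sit at offset +2.
MOTIF_A_CONSENSUS = "CACRRDWHYCRAKGMNNNN"
MOTIF_B_CONSENSUS = "GGCACRHWTYYCRAKGMNN"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWMotif:
    """Position weight matrix with background model.

    matrix:
        (width, 4) per-position probabilities over A,C,G,T; rows sum to 1.
    background:
        Length-4 background probabilities (uniform by default).
    pseudocount:
        Fraction of background mixed into each row before taking log-odds,
        guarding against zero probabilities in matrices read from files.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or len(self.matrix) < 1:
            raise ConfigError("matrix must be (width, 4) with width >= 1")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("matrix rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ConfigError("background must sum to 1")
        self._tables: dict = {}

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    def int_logodds(self) -> np.ndarray:
        """(width, 4) integer log-odds in 1/1000-bit units."""
        p = (self.matrix + self.pseudocount * self.background) / (
            1.0 + self.pseudocount
        )
        lo = np.log2(p / self.background)
        return np.rint(lo * SCALE).astype(np.int64)

    def max_score(self) -> float:
        return float(self.int_logodds().max(axis=1).sum()) / SCALE

    def min_score(self) -> float:
        return float(self.int_logodds().min(axis=1).sum()) / SCALE

    # -- exact p-value machinery -------------------------------------------

    def _tail(self) -> tuple[int, np.ndarray]:
        """(min_total, tail) with tail[k] = P(total >= min_total + k)."""
        if "tail" in self._tables:
            return self._tables["tail"]
        ints = self.int_logodds()
        mins = ints.min(axis=1)
        dist = np.array([1.0])
        for i in range(self.width):
            offs = ints[i] - mins[i]
            pos = np.zeros(int(offs.max()) + 1)
            np.add.at(pos, offs, self.background)
            dist = np.convolve(dist, pos)
        tail = np.cumsum(dist[::-1])[::-1]
        result = (int(mins.sum()), tail)
        self._tables["tail"] = result
        return result


def exact_pvalue(motif: PWMotif, score: float) -> float:
    """P(window score >= ``score``) for a random background window.

    Exact on the 1/1000-bit lattice that scores are reported on. Scores at or
    below the minimum achievable give 1; scores above the maximum clamp to
    the probability of the maximum (p stays in (0, 1]).
    """
    min_total, tail = motif._tail()
    k = int(round(score * SCALE)) - min_total
    if k <= 0:
        return 1.0
    if k >= len(tail):
        k = len(tail) - 1
    return float(tail[k])


def pwm_from_consensus(
    consensus: str, strength: float = 0.95, motif_id: str = "",
    background: Optional[np.ndarray] = None,
) -> PWMotif:
    """Turn an IUPAC consensus into a PWM.

    At each position the letters allowed by the code share probability
    ``strength`` equally; the remaining letters share ``1 - strength``.
    ``N`` is uniform regardless of strength.
    """
    if not (0 < strength <= 1):
        raise ConfigError("strength must be in (0, 1]")
    rows = []
    for pos, ch in enumerate(consensus.upper()):
        allowed = IUPAC.get(ch)
        if allowed is None:
            raise InputError(f"illegal IUPAC character {ch!r} at position {pos}")
        row = np.empty(4)
        if len(allowed) == 4:
            row[:] = 0.25
        else:
            row[:] = (1.0 - strength) / (4 - len(allowed))
            for b in allowed:
                row[BASES.index(b)] = strength / len(allowed)
        rows.append(row)
    kwargs = {} if background is None else {"background": background}
    return PWMotif(motif_id=motif_id or consensus, matrix=np.array(rows), **kwargs)


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    seqname: str       # chromosome or peak id
    start: int         # 0-based leftmost coordinate of the occupied window
    strand: str        # '+' or '-'
    score: float       # log-odds, bits
    p_value: float


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(BASES):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_int_scores(enc: np.ndarray, ints: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores of all windows plus a validity mask (no N)."""
    w = len(ints)
    n = len(enc) - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    ext = np.concatenate([ints, np.zeros((w, 1), dtype=np.int64)], axis=1)
    totals = np.zeros(n, dtype=np.int64)
    has_n = np.zeros(n, dtype=bool)
    for j in range(w):
        col = enc[j:j + n]
        totals += ext[j][col]
        has_n |= col == 4
    return totals, ~has_n


def scan(
    seqs: Mapping[str, str],
    motif: PWMotif,
    p_threshold: float = 1e-4,
) -> list[MotifHit]:
    """FIMO-style scan of sequences on both strands.

    Windows containing N are skipped; a hit is reported when the exact
    p-value of its score is at or below ``p_threshold``. Hits are sorted by
    (sequence, start, strand).
    """
    ints = motif.int_logodds()
    rc_ints = ints[::-1, ::-1]
    min_total, tail = motif._tail()
    hits: list[MotifHit] = []
    for name in seqs:
        enc = _encode(seqs[name])
        for strand, mat in (("+", ints), ("-", rc_ints)):
            totals, valid = _window_int_scores(enc, mat)
            if len(totals) == 0:
                continue
            k = np.clip(totals - min_total, 0, len(tail) - 1)
            pv = tail[k]
            pv = np.where(totals - min_total <= 0, 1.0, pv)
            keep = valid & (pv <= p_threshold)
            for i in np.flatnonzero(keep):
                hits.append(
                    MotifHit(
                        motif_id=motif.motif_id, seqname=name, start=int(i),
                        strand=strand, score=float(totals[i]) / SCALE,
                        p_value=float(pv[i]),
                    )
                )
    hits.sort(key=lambda h: (h.seqname, h.start, h.strand))
    return hits


# -- offset analysis --------------------------------------------------------


@dataclass
class OffsetSummary:
    """Co-occurrence spacing of two motifs inside shared peaks.

    histogram:
        All same-strand, same-peak hit pairs binned by signed offset
        ``start_a - start_b`` in motif orientation (negated on '-' strand).
    modal_offset:
        Most frequent offset (ties -> smallest offset value).
    n_a_hits:
        Total a-motif hits inside shared peaks.
    n_a_at_modal / n_a_at_query:
        Number of a-hits having at least one same-strand b-hit at exactly the
        modal / queried offset (nearest-pair-per-a-hit rule).
    """

    histogram: dict[int, int]
    modal_offset: Optional[int]
    n_a_hits: int
    n_a_at_modal: int
    query_offset: Optional[int] = None
    n_a_at_query: int = 0


def _oriented_offset(a: MotifHit, b: MotifHit) -> int:
    d = a.start - b.start
    return d if a.strand == "+" else -d


def offsets_between(
    hits_a: Sequence[MotifHit],
    hits_b: Sequence[MotifHit],
    shared_peaks: Iterable[str],
    query_offset: Optional[int] = None,
) -> OffsetSummary:
    """Offset histogram and modal-offset co-occurrence counts."""
    shared = set(shared_peaks)
    a_by_peak: dict[str, list[MotifHit]] = {}
    b_by_peak: dict[str, list[MotifHit]] = {}
    for h in hits_a:
        if h.seqname in shared:
            a_by_peak.setdefault(h.seqname, []).append(h)
    for h in hits_b:
        if h.seqname in shared:
            b_by_peak.setdefault(h.seqname, []).append(h)

    hist: Counter = Counter()
    for peak, alist in a_by_peak.items():
        for a in alist:
            for b in b_by_peak.get(peak, []):
                if b.strand == a.strand:
                    hist[_oriented_offset(a, b)] += 1

    modal = (
        min(hist, key=lambda o: (-hist[o], o)) if hist else None
    )

    def n_a_at(offset: Optional[int]) -> int:
        if offset is None:
            return 0
        count = 0
        for peak, alist in a_by_peak.items():
            blist = b_by_peak.get(peak, [])
            for a in alist:
                if any(
                    b.strand == a.strand and _oriented_offset(a, b) == offset
                    for b in blist
                ):
                    count += 1
        return count

    return OffsetSummary(
        histogram=dict(sorted(hist.items())),
        modal_offset=modal,
        n_a_hits=sum(len(v) for v in a_by_peak.values()),
        n_a_at_modal=n_a_at(modal),
        query_offset=query_offset,
        n_a_at_query=n_a_at(query_offset),
    )


# -- sequence and file plumbing ---------------------------------------------


def extract_peak_sequences(
    genome_fasta: str | Path, peaks: Sequence[Peak]
) -> dict[str, str]:
    """Peak-name -> uppercase sequence, sliced from an indexed FASTA."""
    fa = Fasta(str(genome_fasta))
    out: dict[str, str] = {}
    for p in peaks:
        if p.chrom not in fa:
            raise InputError(f"peak {p.name}: chromosome {p.chrom!r} not in FASTA")
        out[p.name] = str(fa[p.chrom][p.start:p.end]).upper()
    return out


def write_meme(motifs: Sequence[PWMotif], path: str | Path) -> None:
    """Minimal MEME motif format writer."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[i]:.5f}" for i, b in enumerate(BASES)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list[PWMotif]:
    """Minimal MEME motif format reader (letter-probability matrices)."""
    text = Path(path).read_text()
    bg = np.full(4, 0.25)
    m_bg = re.search(
        r"Background letter frequencies[^\n]*\n([^\n]+)", text
    )
    if m_bg:
        fields = m_bg.group(1).split()
        freqs = {fields[i]: float(fields[i + 1]) for i in range(0, len(fields), 2)}
        if set(BASES) <= set(freqs):
            bg = np.array([freqs[b] for b in BASES])
    motifs: list[PWMotif] = []
    blocks = re.split(r"^MOTIF\s+", text, flags=re.M)[1:]
    for block in blocks:
        lines = block.splitlines()
        motif_id = lines[0].split()[0]
        header = next(
            (i for i, ln in enumerate(lines)
             if ln.startswith("letter-probability matrix")), None
        )
        if header is None:
            raise InputError(f"motif {motif_id}: no letter-probability matrix")
        w_match = re.search(r"w=\s*(\d+)", lines[header])
        width = int(w_match.group(1)) if w_match else None
        rows = []
        for ln in lines[header + 1:]:
            parts = ln.split()
            if len(parts) != 4:
                break
            rows.append([float(x) for x in parts])
            if width is not None and len(rows) == width:
                break
        mat = np.array(rows)
        mat = mat / mat.sum(axis=1, keepdims=True)  # tolerate rounded rows
        motifs.append(
            PWMotif(motif_id=motif_id, matrix=mat, background=bg,
                    pseudocount=0.01)
        )
    return motifs


def write_hits(hits: Sequence[MotifHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"motif": h.motif_id, "seqname": h.seqname, "start": h.start,
             "strand": h.strand, "score": round(h.score, 4),
             "p_value": h.p_value}
            for h in hits
        ],
        columns=["motif", "seqname", "start", "strand", "score", "p_value"],
    ).to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path) -> list[MotifHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        MotifHit(motif_id=str(r.motif), seqname=str(r.seqname), start=int(r.start),
                 strand=str(r.strand), score=float(r.score),
                 p_value=float(r.p_value))
        for r in df.itertuples()
    ]
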