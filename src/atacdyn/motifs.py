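"""PWM scanning of peak sequences and differential motif enrichment.

PWMs are read from JASPAR-style count matrices, normalised per position with
a pseudocount, and scored as log2-odds against a background base composition
(uniform by default). A sequence "has" a motif if any window on either strand
reaches the score threshold; differential enrichment between two peak sets is
the two-sided Fisher exact test on the per-peak presence/absence 2x2 table,
with Benjamini-Hochberg adjustment across motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import GenomeLayout, GenomicInterval

__all__ = [
    "PWM",
    "MotifHit",
    "MotifEnrichmentResult",
    "read_jaspar",
    "bundled_motifs",
    "read_fasta",
    "write_fasta",
    "extract_sequences",
    "scan_pwm",
    "motif_enrichment",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_PSEUDOCOUNT = 0.01


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with background model, scored in bits."""

    motif_id: str
    matrix: np.ndarray  # length x 4 probabilities (A, C, G, T)
    background: np.ndarray  # 4 probabilities
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4 or mat.shape[0] < 4:
            raise ValueError("PWM matrix must be (length >= 4) x 4")
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1 after normalisation")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: Sequence[float] | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        probs = counts / counts.sum(axis=1, keepdims=True)
        probs = probs + pseudocount
        probs = probs / probs.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(motif_id, probs, bg, pseudocount)

    @property
    def log_odds(self) -> np.ndarray:
        """Per-position log2(p_base / bg_base)."""
        return np.log2(self.matrix / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id, self.matrix[::-1, ::-1].copy(), self.background, self.pseudocount
        )


def read_jaspar(
    path, background: Sequence[float] | None = None, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> list[PWM]:
    """Read JASPAR count-matrix text into normalised PWMs."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.column_stack([m.counts[b] for b in _BASES])
        name = m.name or m.matrix_id
        out.append(PWM.from_counts(str(name), counts, background, pseudocount))
    return out


def bundled_motifs(**kwargs) -> list[PWM]:
    """The package's bundled synthetic example motif set (JASPAR format)."""
    path = Path(__file__).parent / "data" / "synthetic_motifs.jaspar"
    return read_jaspar(path, **kwargs)


# ---------------------------------------------------------------------------
# Sequence handling
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an uppercase chrom -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def extract_sequences(
    sequences: Mapping[str, str] | str | Path,
    intervals: Iterable[GenomicInterval],
    genome: GenomeLayout | None = None,
) -> list[str]:
    """Uppercase half-open slices of the genome for a list of intervals.

    ``sequences`` may be a FASTA path or an in-memory mapping. If a genome
    layout is given, sequence lengths are checked against it first.
    """
    if not isinstance(sequences, Mapping):
        sequences = read_fasta(sequences)
    if genome is not None:
        for chrom, length in genome.lengths.items():
            if chrom not in sequences:
                raise ValueError(f"FASTA is missing chromosome {chrom!r}")
            if len(sequences[chrom]) != length:
                raise ValueError(
                    f"FASTA length for {chrom!r} is {len(sequences[chrom])}, "
                    f"genome layout says {length}"
                )
    out = []
    for iv in intervals:
        seq = sequences.get(iv.chrom)
        if seq is None:
            raise ValueError(f"no sequence for chromosome {iv.chrom!r}")
        if iv.end > len(seq):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} beyond sequence end {len(seq)}"
            )
        out.append(seq[iv.start : iv.end].upper())
    return out


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifHit:
    position: int  # 0-based window start on the forward strand
    strand: str  # '+' or '-'
    score: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(arr.shape, 4, dtype=np.int8)  # 4 = N / anything else
    for base, i in _BASE_INDEX.items():
        code[arr == ord(base)] = i
    return code


def _window_scores(code: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score of every window; windows containing non-ACGT bases are -inf."""
    L = log_odds.shape[0]
    n = len(code) - L + 1
    if n <= 0:
        return np.empty(0)
    padded = np.hstack([log_odds, np.full((L, 1), -np.inf)])  # col 4 poisons N
    windows = np.lib.stride_tricks.sliding_window_view(code, L)
    scores = padded[np.arange(L), windows].sum(axis=1)
    return scores


def scan_pwm(sequence: str, pwm: PWM, score_threshold: float) -> list[MotifHit]:
    """All motif hits on both strands at or above a log2-odds threshold.

    Positions are 0-based window starts in forward-strand coordinates on both
    strands. Sequences shorter than the motif give no hits; windows containing
    non-ACGT bases are skipped.
    """
    code = _encode(sequence)
    hits = []
    fwd = _window_scores(code, pwm.log_odds)
    for pos in np.flatnonzero(fwd >= score_threshold):
        hits.append(MotifHit(int(pos), "+", float(fwd[pos])))
    rev = _window_scores(code, pwm.reverse_complement().log_odds)
    for pos in np.flatnonzero(rev >= score_threshold):
        hits.append(MotifHit(int(pos), "-", float(rev[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _has_motif(sequences: Sequence[str], pwm: PWM, threshold: float) -> np.ndarray:
    out = np.zeros(len(sequences), dtype=bool)
    lo_f = pwm.log_odds
    lo_r = pwm.reverse_complement().log_odds
    for i, seq in enumerate(sequences):
        code = _encode(seq)
        f = _window_scores(code, lo_f)
        if len(f) and f.max() >= threshold:
            out[i] = True
            continue
        r = _window_scores(code, lo_r)
        if len(r) and r.max() >= threshold:
            out[i] = True
    return out


# ---------------------------------------------------------------------------
# Differential enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifEnrichmentResult:
    motif_id: str
    hits_a: int
    n_a: int
    hits_b: int
    n_b: int
    odds_ratio: float
    p_value: float
    adjusted_p: float
    direction: str  # 'A', 'B' or 'none'


def default_threshold(pwm: PWM, fraction_of_max: float = 0.8) -> float:
    """A per-motif threshold as a fraction of the best attainable score."""
    return fraction_of_max * pwm.max_score


def motif_enrichment(
    sequences_a: Sequence[str],
    sequences_b: Sequence[str],
    pwms: Sequence[PWM],
    threshold: float | None = None,
) -> list[MotifEnrichmentResult]:
    """Per-motif differential presence between two peak-sequence sets.

    ``threshold`` is an absolute log2-odds cutoff shared by all motifs; when
    None each motif uses :func:`default_threshold`. Odds ratios are
    Haldane-corrected (add 0.5 to every cell) whenever a cell is zero.
    """
    if not sequences_a or not sequences_b:
        raise ValueError("both sequence sets must be nonempty")
    if not pwms:
        raise ValueError("empty PWM list")
    raw = []
    for pwm in pwms:
        thr = default_threshold(pwm) if threshold is None else threshold
        ha = int(_has_motif(sequences_a, pwm, thr).sum())
        hb = int(_has_motif(sequences_b, pwm, thr).sum())
        table = np.array(
            [[ha, len(sequences_a) - ha], [hb, len(sequences_b) - hb]], dtype=float
        )
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        if (table == 0).any():
            table = table + 0.5
        odds = float((table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0]))
        raw.append((pwm.motif_id, ha, len(sequences_a), hb, len(sequences_b), odds, p))
    adj = multipletests([r[6] for r in raw], method="fdr_bh")[1]
    out = []
    for (motif_id, ha, na, hb, nb, odds, p), q in zip(raw, adj):
        direction = "none" if np.isclose(odds, 1.0) else ("A" if odds > 1 else "B")
        out.append(
            MotifEnrichmentResult(motif_id, ha, na, hb, nb, odds, p, float(q), direction)
        )
    return out
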