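"""Degenerate DR4 thyroid-response-element scanning and consensus motifs.

The canonical thyroid response element (TRE) bound by the TR/RXR
heterodimer is a direct repeat of the AGGTCA half-site spaced by four
unconstrained bases (DR4): ``AGGTCANNNNAGGTCA``.  :func:`scan_promoter`
finds every window of a promoter matching the pattern within a mismatch
budget, counting mismatches only at the 12 half-site positions (the N
spacer matches anything).  :func:`build_motif` turns the matched 16-mers
into a position frequency matrix with per-position information content
(bits) and a mixed-case consensus string in the style logo tools print
(invariant positions uppercase, majority positions lowercase, the rest
``n``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DR4_PATTERN",
    "ScanConfig",
    "TREHit",
    "MotifModel",
    "reverse_complement",
    "scan_promoter",
    "scan_set",
    "build_motif",
]

DR4_PATTERN = "AGGTCANNNNAGGTCA"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_SEQ_ALPHABET = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScanConfig:
    """Scan settings: pattern, mismatch budget, window and strand mode.

    ``max_mismatch`` applies to the pattern's non-N positions only.
    ``window_bp`` is the promoter window honoured by :func:`scan_set`
    (sequences shorter than the window are scanned in full).  ``strands``
    is ``"both"`` or ``"forward_only"``.
    """

    pattern: str = DR4_PATTERN
    max_mismatch: int = 4
    window_bp: int = 5000
    strands: str = "both"

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if not set(pat) <= _SEQ_ALPHABET:
            raise ValueError("pattern may only contain A, C, G, T, N")
        object.__setattr__(self, "pattern", pat)
        n_informative = sum(b != "N" for b in pat)
        if not 0 <= self.max_mismatch <= n_informative:
            raise ValueError(
                f"max_mismatch must lie in [0, {n_informative}] for this pattern"
            )
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.strands not in ("both", "forward_only"):
            raise ValueError("strands must be 'both' or 'forward_only'")


@dataclass(frozen=True)
class TREHit:
    """One pattern match: 0-based forward-coordinate start, strand,
    the window as read 5'->3' on the matching strand, and its half-site
    mismatch count."""

    gene_id: str
    start: int
    strand: str
    matched_seq: str
    mismatches: int


def _mismatch_profile(seq: str, pattern: str) -> np.ndarray:
    """Mismatch count of every window of ``seq`` against ``pattern``.

    Non-N pattern positions require an exact base match; an N in the
    *sequence* therefore counts as a mismatch there.
    """
    k = len(pattern)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n_win = len(seq) - k + 1
    mm = np.zeros(n_win, dtype=np.int32)
    for off, pb in enumerate(pattern):
        if pb == "N":
            continue
        mm += arr[off : off + n_win] != ord(pb)
    return mm


def scan_promoter(seq: str, config: ScanConfig, gene_id: str = "") -> list[TREHit]:
    """All pattern hits in one sequence within the mismatch budget.

    Reverse-strand hits report the reverse-complement window with ``start``
    still the forward coordinate of the window's leftmost base.  Results are
    sorted by start, ``+`` before ``-`` at equal start.  A sequence shorter
    than the pattern yields no hits.
    """
    seq = seq.upper()
    bad = set(seq) - _SEQ_ALPHABET
    if bad:
        raise ValueError(f"illegal sequence characters: {sorted(bad)}")
    k = len(config.pattern)
    if len(seq) < k:
        return []
    hits: list[TREHit] = []
    mm_fwd = _mismatch_profile(seq, config.pattern)
    for start in np.flatnonzero(mm_fwd <= config.max_mismatch):
        start = int(start)
        hits.append(
            TREHit(gene_id, start, "+", seq[start : start + k], int(mm_fwd[start]))
        )
    if config.strands == "both":
        rc = reverse_complement(seq)
        mm_rev = _mismatch_profile(rc, config.pattern)
        n = len(seq)
        for j in np.flatnonzero(mm_rev <= config.max_mismatch):
            j = int(j)
            hits.append(TREHit(gene_id, n - k - j, "-", rc[j : j + k], int(mm_rev[j])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_set(
    promoters: Mapping[str, str],
    config: ScanConfig,
    mode: str = "all_hits",
) -> pd.DataFrame:
    """Scan a promoter set; return a BED6-like table.

    Columns: gene_id, start, end (half-open), matched_seq, mismatches,
    strand.  Only the last ``window_bp`` bases of each promoter (the window
    adjacent to the transcription start site) are scanned; shorter
    promoters are scanned in full.  ``mode="best_per_gene"`` keeps one hit
    per gene: fewest mismatches, ties broken by smallest start then
    ``+`` strand.
    """
    if mode not in ("all_hits", "best_per_gene"):
        raise ValueError("mode must be 'all_hits' or 'best_per_gene'")
    rows = []
    k = len(config.pattern)
    for gene, seq in promoters.items():
        window = seq[-config.window_bp :] if len(seq) > config.window_bp else seq
        offset = len(seq) - len(window)
        gene_hits = scan_promoter(window, config, gene_id=gene)
        if mode == "best_per_gene" and gene_hits:
            gene_hits = [
                min(
                    gene_hits,
                    key=lambda h: (h.mismatches, h.start, 0 if h.strand == "+" else 1),
                )
            ]
        for h in gene_hits:
            rows.append(
                {
                    "gene_id": gene,
                    "start": h.start + offset,
                    "end": h.start + offset + k,
                    "matched_seq": h.matched_seq,
                    "mismatches": h.mismatches,
                    "strand": h.strand,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "start", "end", "matched_seq", "mismatches", "strand"]
    )


@dataclass
class MotifModel:
    """Position frequency matrix with information content and consensus.

    ``counts`` and ``frequencies`` are position × base (A, C, G, T)
    DataFrames; ``ic`` holds the per-position information content in bits,
    ``2 + sum_b f_b log2 f_b`` (0 for a uniform column, 2 for an invariant
    one); ``consensus`` is the mixed-case consensus string.
    """

    counts: pd.DataFrame
    frequencies: pd.DataFrame
    ic: np.ndarray
    consensus: str

    @property
    def n_sequences(self) -> int:
        return int(self.counts.iloc[0].sum())

    def save(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "position"
        out.to_csv(path, sep="\t")


def build_motif(
    hit_sequences: Sequence[str],
    upper_threshold: float = 0.75,
    lower_threshold: float = 0.5,
) -> MotifModel:
    """Position frequency matrix and consensus from aligned 16-mers.

    The consensus letter at a position is the most frequent base in
    uppercase if its frequency reaches ``upper_threshold``, lowercase if it
    reaches ``lower_threshold``, else ``n``.  Frequency ties go to the
    first base in A < C < G < T order.
    """
    if len(hit_sequences) == 0:
        raise ValueError("build_motif requires at least one sequence")
    width = 16
    bases = "ACGT"
    counts = np.zeros((width, 4), dtype=np.int64)
    for seq in hit_sequences:
        seq = seq.upper()
        if len(seq) != width:
            raise ValueError(f"motif sequences must be {width} bp, got {len(seq)!r}")
        if not set(seq) <= set(bases):
            raise ValueError(f"motif sequences must be ACGT only: {seq}")
        for i, b in enumerate(seq):
            counts[i, bases.index(b)] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    letters = []
    for i in range(width):
        j = int(np.argmax(freqs[i]))  # argmax takes the first maximum: A<C<G<T
        f = freqs[i, j]
        if f >= upper_threshold:
            letters.append(bases[j])
        elif f >= lower_threshold:
            letters.append(bases[j].lower())
        else:
            letters.append("n")
    idx = pd.RangeIndex(width, name="position")
    return MotifModel(
        counts=pd.DataFrame(counts, index=idx, columns=list(bases)),
        frequencies=pd.DataFrame(freqs, index=idx, columns=list(bases)),
        ic=ic,
        consensus="".join(letters),
    )
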