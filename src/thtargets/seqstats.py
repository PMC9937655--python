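"""Count-matrix container, sequence I/O and descriptive statistics.

The central object is :class:`CountMatrix`: an integer gene × sample table
of read counts together with a condition label for every sample and a
transcript length (bp) for every gene.  On top of it this module provides
FPKM normalization, assembly-style length statistics (mean, N50, N90,
length-interval histogram) and plain-text (TSV / FASTA) round trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "CountMatrix",
    "LengthStats",
    "length_stats",
    "fpkm",
    "read_fasta",
    "write_fasta",
]

DEFAULT_BIN_EDGES = (0, 1000, 2000, 3000)


@dataclass
class CountMatrix:
    """Gene × sample read counts with sample conditions and gene lengths.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, genes as rows, samples as columns.
    conditions
        Series mapping each sample id to its condition label
        (e.g. ``control``, ``TH``, ``CHX``, ``TH_CHX``).
    gene_lengths
        Series mapping each gene id to its transcript length in bp.
    """

    counts: pd.DataFrame
    conditions: pd.Series
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        self.conditions = self.conditions.loc[list(self.counts.columns)]
        missing = set(self.counts.index) - set(self.gene_lengths.index)
        if missing:
            raise ValueError(f"genes without length: {sorted(missing)[:5]} ...")
        self.gene_lengths = self.gene_lengths.loc[list(self.counts.index)].astype(np.int64)
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition, in column order."""
        sel = self.conditions[self.conditions == condition]
        return [s for s in self.counts.columns if s in set(sel.index)]

    # ---------------------------------------------------------------- I/O
    def save(self, outdir: str | Path) -> None:
        """Write counts.tsv, conditions.tsv and gene_lengths.tsv to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.rename_axis("gene_id").to_csv(outdir / "counts.tsv", sep="\t")
        self.conditions.rename("condition").rename_axis("sample_id").to_csv(
            outdir / "conditions.tsv", sep="\t"
        )
        self.gene_lengths.rename("length").rename_axis("gene_id").to_csv(
            outdir / "gene_lengths.tsv", sep="\t"
        )

    @classmethod
    def load(
        cls,
        counts_tsv: str | Path,
        conditions_tsv: str | Path,
        lengths_tsv: str | Path,
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        cond = pd.read_csv(conditions_tsv, sep="\t", index_col=0).iloc[:, 0]
        lengths = pd.read_csv(lengths_tsv, sep="\t", index_col=0).iloc[:, 0]
        return cls(counts, cond, lengths)


@dataclass
class LengthStats:
    """Summary statistics of a set of sequence lengths (bp)."""

    n_sequences: int
    total_bp: int
    min_length: int
    max_length: int
    mean_length: float
    n50: int
    n90: int
    bin_counts: dict[str, int] = field(default_factory=dict)


def _nx(sorted_desc: np.ndarray, cumsum: np.ndarray, frac: float) -> int:
    """First length (descending order) at which cumulative bp reaches frac of total."""
    target = frac * cumsum[-1]
    idx = int(np.searchsorted(cumsum, target))
    return int(sorted_desc[idx])


def length_stats(
    lengths: Sequence[int] | np.ndarray,
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> LengthStats:
    """Mean/N50/N90 and binned counts for transcript lengths.

    N50 is the length L such that sequences of length >= L together cover at
    least half of the total bases (descending cumulative rule; the standard
    assembly-stats convention); N90 is the analogue at 90%.  Bins are
    half-open ``[lo, hi)`` with a final open-ended ``>= last edge`` bin.
    """
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("length_stats requires a non-empty list of lengths")
    if (arr <= 0).any():
        raise ValueError("sequence lengths must be positive")
    desc = np.sort(arr)[::-1]
    csum = np.cumsum(desc)
    edges = list(bin_edges) + [np.inf]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"[{int(lo)},{int(hi)})" if np.isfinite(hi) else f">={int(lo)}")
    hist, _ = np.histogram(arr, bins=np.array(edges, dtype=float))
    return LengthStats(
        n_sequences=int(arr.size),
        total_bp=int(csum[-1]),
        min_length=int(desc[-1]),
        max_length=int(desc[0]),
        mean_length=float(arr.mean()),
        n50=_nx(desc, csum, 0.5),
        n90=_nx(desc, csum, 0.9),
        bin_counts=dict(zip(labels, (int(h) for h in hist))),
    )


def fpkm(matrix: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    ``FPKM[g, s] = counts[g, s] * 1e9 / (library_size[s] * length[g])`` with
    the library size taken as the column sum of the count matrix.
    """
    libsize = matrix.counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    scale = 1e9 / libsize.astype(float)
    return matrix.counts.mul(scale, axis=1).div(matrix.gene_lengths.astype(float), axis=0)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-line) FASTA into an ordered ``{id: uppercase sequence}`` map.

    Duplicate record ids are an error: downstream per-gene bookkeeping
    assumes one promoter per gene.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record id: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
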