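"""Synthetic four-condition expression experiment with planted TH targets.

Emulates the factorial design used to separate direct from late
thyroid-hormone (TH) response genes: four groups (control, TH, CHX,
TH_CHX) with replicate tadpole pools each, where CHX (cycloheximide)
blocks translation so that only genes needing no new protein synthesis
still respond to TH.  Gene classes and their planted expression rules:

====================  ==========================================
class                 condition mean relative to control
====================  ==========================================
``direct_up``         x 2^L in TH and TH_CHX
``direct_down``       x 2^-L in TH and TH_CHX
``late``              x 2^L in TH only (CHX-sensitive)
``chx_response``      x 2^L in CHX and TH_CHX
``null``              constant
====================  ==========================================

with L = ``effect_lfc``.  Counts are negative-binomial with
``var = mu + dispersion * mu^2`` (the parameterization of the
DESeq-family tools).  Promoters are uniform-random sequences; each
direct-target promoter additionally carries exactly one planted DR4
element (AGGTCA-N4-AGGTCA with a controlled number of half-site
mismatches) on a recorded strand at a recorded 0-based position.

Counts and promoters are drawn from separate RNG streams spawned from the
master seed, so the promoter set does not change when only the count
draw is varied (and vice versa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .seqstats import CountMatrix, write_fasta
from .tremotif import DR4_PATTERN, reverse_complement

__all__ = ["SimConfig", "GroundTruth", "generate_counts", "generate_promoters", "simulate"]

CONDITIONS = ("control", "TH", "CHX", "TH_CHX")
CLASSES = ("direct_up", "direct_down", "late", "chx_response", "null")
CONTRASTS = ("th_vs_ctrl", "thchx_vs_chx", "chx_vs_ctrl", "thchx_vs_ctrl")

BASES = np.array(list("ACGT"))

DEFAULT_FRACTIONS: dict[str, float] = {
    "direct_up": 0.02,
    "direct_down": 0.01,
    "late": 0.05,
    "chx_response": 0.10,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated experiment.

    Defaults mirror the study design this generator emulates: 4 replicates
    per condition, a 5,000-bp promoter window, and a strong (8-fold,
    ``effect_lfc=3``) planted response typical of the top TH targets.
    ``mean_log_range`` is the log10 range of baseline means (10–1000 counts
    by default); ``dispersion`` is the NB overdispersion alpha shared by all
    genes.
    """

    n_genes: int = 1000
    n_reps_per_condition: int = 4
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    effect_lfc: float = 3.0
    dispersion: float = 0.1
    mean_log_range: tuple[float, float] = (1.0, 3.0)
    gene_length_range: tuple[int, int] = (500, 5000)
    promoter_length: int = 5000
    planted_mismatches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_reps_per_condition <= 0:
            raise ValueError("n_genes and n_reps_per_condition must be positive")
        unknown = set(self.class_fractions) - set(CLASSES[:-1])
        if unknown:
            raise ValueError(f"unknown gene classes in fractions: {sorted(unknown)}")
        fracs = {k: float(v) for k, v in self.class_fractions.items()}
        if any(v < 0 for v in fracs.values()):
            raise ValueError("class fractions must be non-negative")
        if sum(fracs.values()) > 1:
            raise ValueError("class fractions must sum to at most 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.mean_log_range[0] > self.mean_log_range[1]:
            raise ValueError("mean_log_range must be (low, high) with low <= high")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("gene_length_range must be (low, high) with low <= high")
        if self.gene_length_range[0] <= 0:
            raise ValueError("gene lengths must be positive")
        if self.promoter_length < 16:
            raise ValueError("promoter_length must be at least 16 bp")
        if not 0 <= self.planted_mismatches <= 4:
            raise ValueError("planted_mismatches must lie in [0, 4]")

    def class_counts(self) -> dict[str, int]:
        """Exact gene count per class (fractions rounded, remainder null)."""
        counts = {
            k: int(round(self.n_genes * self.class_fractions.get(k, 0.0)))
            for k in CLASSES[:-1]
        }
        n_special = sum(counts.values())
        if n_special > self.n_genes:
            raise ValueError("class fractions allocate more genes than n_genes")
        counts["null"] = self.n_genes - n_special
        return counts


@dataclass
class GroundTruth:
    """Per-gene truth table of a simulated experiment.

    ``table`` columns: ``class_label``; one ``true_lfc_<contrast>`` column
    per pairwise contrast; ``tre_pos`` (0-based forward-coordinate start of
    the planted DR4 element, -1 if none), ``tre_strand`` (``+``/``-``/empty)
    and ``tre_seq`` (the planted 16-mer as read 5'->3' on its strand).
    """

    table: pd.DataFrame

    def genes_of(self, label: str) -> list[str]:
        return list(self.table.index[self.table["class_label"] == label])

    @property
    def direct_genes(self) -> list[str]:
        return list(
            self.table.index[self.table["class_label"].isin(["direct_up", "direct_down"])]
        )

    def save(self, path: str | Path) -> None:
        self.table.rename_axis("gene_id").to_csv(path, sep="\t")


def _true_lfc(label: str, effect: float) -> dict[str, float]:
    lfc = dict.fromkeys(CONTRASTS, 0.0)
    if label == "direct_up":
        lfc["th_vs_ctrl"] = effect
        lfc["thchx_vs_chx"] = effect
        lfc["thchx_vs_ctrl"] = effect
    elif label == "direct_down":
        lfc["th_vs_ctrl"] = -effect
        lfc["thchx_vs_chx"] = -effect
        lfc["thchx_vs_ctrl"] = -effect
    elif label == "late":
        lfc["th_vs_ctrl"] = effect
    elif label == "chx_response":
        lfc["chx_vs_ctrl"] = effect
        lfc["thchx_vs_ctrl"] = effect
    return lfc


def generate_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw the count matrix and its ground truth for one experiment.

    Deterministic in ``config.seed``; the same seed always yields the same
    matrix and truth regardless of whether promoters are generated too.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    n = config.n_genes
    genes = [f"gene{i:05d}" for i in range(n)]
    counts_per_class = config.class_counts()

    labels = np.array(
        sum(([lab] * k for lab, k in counts_per_class.items()), []), dtype=object
    )
    labels = labels[rng.permutation(n)]

    base_mu = 10 ** rng.uniform(*config.mean_log_range, size=n)
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n
    )

    truth_rows = []
    mu = np.empty((n, 4))  # gene x condition means
    for i, lab in enumerate(labels):
        lfc = _true_lfc(lab, config.effect_lfc)
        mu[i, 0] = base_mu[i]
        mu[i, 1] = base_mu[i] * 2 ** lfc["th_vs_ctrl"]
        mu[i, 2] = base_mu[i] * 2 ** lfc["chx_vs_ctrl"]
        mu[i, 3] = base_mu[i] * 2 ** lfc["thchx_vs_ctrl"]
        truth_rows.append(
            {"class_label": lab, **{f"true_lfc_{c}": lfc[c] for c in CONTRASTS}}
        )

    r = 1.0 / config.dispersion  # NB size; var = mu + alpha mu^2
    nrep = config.n_reps_per_condition
    cols, data = [], []
    for j, cond in enumerate(CONDITIONS):
        p = r / (r + mu[:, j])
        draw = rng.negative_binomial(r, p[:, None], size=(n, nrep))
        data.append(draw)
        cols.extend(f"{cond}_{k + 1}" for k in range(nrep))
    counts = pd.DataFrame(np.hstack(data), index=genes, columns=cols)

    conditions = pd.Series(
        {f"{cond}_{k + 1}": cond for cond in CONDITIONS for k in range(nrep)}
    ).loc[cols]
    matrix = CountMatrix(counts, conditions, pd.Series(lengths, index=genes))

    truth = pd.DataFrame(truth_rows, index=genes)
    truth["tre_pos"] = -1
    truth["tre_strand"] = ""
    truth["tre_seq"] = ""
    return matrix, GroundTruth(truth)


def _plant_element(rng: np.random.Generator, n_mismatch: int) -> str:
    """One DR4 16-mer: random spacer, exactly n_mismatch half-site mutations."""
    elem = list(DR4_PATTERN)
    halfsite_pos = [i for i, b in enumerate(elem) if b != "N"]
    for i in range(len(elem)):
        if elem[i] == "N":
            elem[i] = str(rng.choice(BASES))
    for i in rng.choice(halfsite_pos, size=n_mismatch, replace=False):
        alternatives = [b for b in "ACGT" if b != elem[i]]
        elem[i] = str(rng.choice(alternatives))
    return "".join(elem)


def generate_promoters(truth: GroundTruth, config: SimConfig) -> dict[str, str]:
    """Uniform-random promoters; direct-target genes get one planted element.

    Returns ``{gene_id: sequence}`` of length ``config.promoter_length`` and
    records each planted element's position, strand and sequence in
    ``truth.table`` (position is the forward-strand coordinate of the
    leftmost base; the stored sequence reads 5'->3' on the recorded strand).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    L = config.promoter_length
    promoters: dict[str, str] = {}
    for gene in truth.table.index:
        seq = rng.choice(BASES, size=L)
        if truth.table.at[gene, "class_label"] in ("direct_up", "direct_down"):
            elem = _plant_element(rng, config.planted_mismatches)
            pos = int(rng.integers(0, L - 16 + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = elem if strand == "+" else reverse_complement(elem)
            seq[pos : pos + 16] = list(inserted)
            truth.table.at[gene, "tre_pos"] = pos
            truth.table.at[gene, "tre_strand"] = strand
            truth.table.at[gene, "tre_seq"] = elem
        promoters[gene] = "".join(seq)
    return promoters


def simulate(config: SimConfig) -> tuple[CountMatrix, GroundTruth, dict[str, str]]:
    """Counts, ground truth and promoters in one call."""
    matrix, truth = generate_counts(config)
    promoters = generate_promoters(truth, config)
    return matrix, truth, promoters


def save_simulation(
    matrix: CountMatrix,
    truth: GroundTruth,
    promoters: Mapping[str, str],
    outdir: str | Path,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.save(outdir)
    truth.save(outdir / "ground_truth.tsv")
    write_fasta(promoters, outdir / "promoters.fasta")
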