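"""Classification of TH direct targets from pairwise DET sets.

The experimental logic: a gene still responding to thyroid hormone when
cycloheximide blocks translation needs no intermediate protein and is a
*direct* TR target.  Concretely, a gene is ``direct_up`` (``direct_down``)
when it is up (down) in BOTH the TH-vs-control and the TH+CHX-vs-CHX
DET sets; direction concordance is required, and discordant overlaps are
flagged rather than silently called.  Genes responding to TH alone are
``late`` targets (their response requires new protein synthesis); genes
in the CHX-vs-control set but not the TH set are ``chx_response``;
everything else is ``null``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .detest import DETSet

__all__ = ["TargetClassification", "OverlapCounts", "classify_targets", "overlap_counts"]

LABELS = ("direct_up", "direct_down", "late", "chx_response", "null")


@dataclass
class TargetClassification:
    """Per-gene label plus the membership flags supporting it.

    ``table`` columns: label; in_th_vs_ctrl / dir_th_vs_ctrl;
    in_thchx_vs_chx / dir_thchx_vs_chx; discordant (True when the gene is
    in both focal sets with opposite directions).
    """

    table: pd.DataFrame

    def genes_of(self, label: str) -> list[str]:
        return list(self.table.index[self.table["label"] == label])

    @property
    def counts(self) -> dict[str, int]:
        vc = self.table["label"].value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in LABELS}

    def save(self, path) -> None:
        self.table.rename_axis("gene_id").to_csv(path, sep="\t")


@dataclass(frozen=True)
class OverlapCounts:
    """Venn-style tallies of two directional DET sets.

    ``shared`` counts genes present in both sets with the same direction;
    genes present in both with opposite directions are tallied in
    ``discordant`` and contribute to both "only" counts.
    """

    a_only: int
    shared: int
    b_only: int
    discordant: int


def classify_targets(
    th_vs_ctrl: DETSet,
    thchx_vs_chx: DETSet,
    chx_vs_ctrl: DETSet | None = None,
) -> TargetClassification:
    """Label every gene of the universe from the focal DET sets.

    Priority: direct (concordant member of both focal sets) > late
    (TH-vs-control only) > chx_response (CHX-vs-control but not
    TH-vs-control) > null.  Discordant focal overlaps are flagged and are
    not direct.  All sets must share one gene universe.
    """
    universe = th_vs_ctrl.universe
    others = [thchx_vs_chx] + ([chx_vs_ctrl] if chx_vs_ctrl is not None else [])
    for other in others:
        if other.universe != universe:
            raise ValueError(
                f"DET sets come from different gene universes "
                f"({len(universe)} vs {len(other.universe)} genes)"
            )
    rows = []
    chx_dirs = chx_vs_ctrl.directions if chx_vs_ctrl is not None else {}
    for gene in sorted(universe):
        d_th = th_vs_ctrl.directions.get(gene)
        d_focal = thchx_vs_chx.directions.get(gene)
        discordant = d_th is not None and d_focal is not None and d_th != d_focal
        if d_th is not None and d_focal is not None and d_th == d_focal:
            label = "direct_up" if d_th > 0 else "direct_down"
        elif d_th is not None and d_focal is None:
            label = "late"
        elif gene in chx_dirs and d_th is None:
            label = "chx_response"
        else:
            label = "null"
        rows.append(
            {
                "gene_id": gene,
                "label": label,
                "in_th_vs_ctrl": d_th is not None,
                "dir_th_vs_ctrl": d_th or 0,
                "in_thchx_vs_chx": d_focal is not None,
                "dir_thchx_vs_chx": d_focal or 0,
                "discordant": discordant,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    return TargetClassification(table)


def overlap_counts(a: DETSet, b: DETSet) -> OverlapCounts:
    """Venn tallies with direction-aware sharing (see :class:`OverlapCounts`)."""
    if a.universe != b.universe:
        raise ValueError("DET sets come from different gene universes")
    shared = discordant = 0
    for gene in set(a.directions) & set(b.directions):
        if a.directions[gene] == b.directions[gene]:
            shared += 1
        else:
            discordant += 1
    a_only = len(a.directions) - shared
    b_only = len(b.directions) - shared
    return OverlapCounts(a_only=a_only, shared=shared, b_only=b_only, discordant=discordant)
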