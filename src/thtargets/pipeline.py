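"""End-to-end orchestration: counts -> contrasts -> direct targets -> TREs.

One call (:func:`run_pipeline`) drives the full analysis from a config
mapping: simulate or ingest a four-condition count experiment, normalize
to FPKM, fit the four pairwise contrasts, apply the DET filter, classify
direct / late / CHX-response targets, scan direct-target promoters for
DR4 elements, build the consensus motif, and (optionally) run term
over-representation on the TH DET set.  Every intermediate is persisted
as TSV so any stage can be re-entered from files — in particular,
pre-computed contrast tables can be supplied instead of counts, which is
how the published 45-transcript worked example enters mid-pipeline.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import enrich as enrich_mod
from .detest import ContrastResult, call_dets, fit_contrast
from .seqstats import CountMatrix, fpkm, read_fasta
from .synth import SimConfig, save_simulation, simulate
from .targetcall import classify_targets, overlap_counts
from .tremotif import ScanConfig, build_motif, scan_set

__all__ = ["run_pipeline"]

log = logging.getLogger("thtargets.pipeline")

CONTRAST_PAIRS = {
    "th_vs_ctrl": ("control", "TH"),
    "thchx_vs_chx": ("CHX", "TH_CHX"),
    "chx_vs_ctrl": ("control", "CHX"),
    "thchx_vs_ctrl": ("control", "TH_CHX"),
}
FOCAL = ("th_vs_ctrl", "thchx_vs_chx", "chx_vs_ctrl")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("inputs")
def _obtain_inputs(
    config: Mapping[str, Any], outdir: Path, seed: int
) -> tuple[CountMatrix | None, dict[str, str] | None, Any]:
    """Counts + promoters from the synth block or from input paths; may be
    absent entirely when pre-computed contrasts are supplied."""
    truth = None
    if "synth" in config:
        sim_kwargs = dict(config["synth"] or {})
        sim_kwargs.setdefault("seed", seed)
        if "class_fractions" in sim_kwargs:
            sim_kwargs["class_fractions"] = dict(sim_kwargs["class_fractions"])
        for key in ("mean_log_range", "gene_length_range"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sim = SimConfig(**sim_kwargs)
        matrix, truth, promoters = simulate(sim)
        save_simulation(matrix, truth, promoters, outdir / "simulated")
        log.info("simulated %d genes x %d samples (seed %d)",
                 len(matrix.genes), len(matrix.samples), sim.seed)
        return matrix, promoters, truth
    if "inputs" in config:
        paths = config["inputs"]
        matrix = CountMatrix.load(
            paths["counts"], paths["conditions"], paths["lengths"]
        )
        promoters = read_fasta(paths["promoters"]) if "promoters" in paths else None
        return matrix, promoters, None
    if "contrasts" in config:
        return None, None, None
    raise ValueError("config must contain a 'synth', 'inputs' or 'contrasts' block")


@_stage("contrasts")
def _contrast_tables(
    config: Mapping[str, Any], matrix: CountMatrix | None, outdir: Path
) -> dict[str, ContrastResult]:
    contrasts: dict[str, ContrastResult] = {}
    if "contrasts" in config:
        for name, path in config["contrasts"].items():
            if name not in CONTRAST_PAIRS:
                raise ValueError(f"unknown contrast name: {name!r}")
            contrasts[name] = ContrastResult.load(path, *CONTRAST_PAIRS[name])
        return contrasts
    assert matrix is not None
    for name, (cond_a, cond_b) in CONTRAST_PAIRS.items():
        result = fit_contrast(matrix, cond_a, cond_b)
        result.save(outdir / f"contrast_{name}.tsv")
        contrasts[name] = result
        log.info("contrast %s: %d genes", name, len(result.table))
    return contrasts


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Run the analysis described by ``config``; returns the JSON summary.

    Config keys (all blocks optional unless noted):

    - ``seed``: master seed (default 0); the simulation draws from it.
    - ``synth`` | ``inputs`` | ``contrasts``: exactly one input mode —
      simulator overrides, paths to counts/conditions/lengths(/promoters),
      or paths to pre-computed contrast TSVs.
    - ``thresholds``: ``lfc_min`` (default 1.0) and ``padj_max`` (0.05).
    - ``scan``: DR4 scan settings (pattern, max_mismatch, window_bp, strands).
    - ``annotation``: term->gene TSV for over-representation of the TH DETs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    thresholds = {"lfc_min": 1.0, "padj_max": 0.05, **(config.get("thresholds") or {})}

    matrix, promoters, truth = _obtain_inputs(config, outdir, seed)

    if matrix is not None:
        fpkm(matrix).rename_axis("gene_id").to_csv(outdir / "fpkm.tsv", sep="\t")

    contrasts = _contrast_tables(config, matrix, outdir)
    if "th_vs_ctrl" not in contrasts or "thchx_vs_chx" not in contrasts:
        raise RuntimeError(
            "pipeline stage 'contrasts' failed: both focal contrasts "
            "(th_vs_ctrl, thchx_vs_chx) are required"
        )

    det_sets = {
        name: call_dets(contrasts[name], **thresholds)
        for name in FOCAL
        if name in contrasts
    }
    for name, det in det_sets.items():
        pd.Series(det.directions, name="direction").rename_axis("gene_id").to_csv(
            outdir / f"dets_{name}.tsv", sep="\t"
        )

    classification = classify_targets(
        det_sets["th_vs_ctrl"],
        det_sets["thchx_vs_chx"],
        det_sets.get("chx_vs_ctrl"),
    )
    classification.save(outdir / "classification.tsv")
    _direct_report(classification, contrasts, outdir)

    venn = {}
    for direction, tag in ((1, "up"), (-1, "down")):
        a = det_sets["th_vs_ctrl"].genes(direction)
        b = det_sets["thchx_vs_chx"].genes(direction)
        venn[tag] = {
            "th_vs_ctrl_only": len(a - b),
            "shared": len(a & b),
            "thchx_vs_chx_only": len(b - a),
        }
    ov = overlap_counts(det_sets["th_vs_ctrl"], det_sets["thchx_vs_chx"])

    summary: dict[str, Any] = {
        "seed": seed,
        "thresholds": thresholds,
        "n_genes": len(det_sets["th_vs_ctrl"].universe),
        "det_counts": {name: len(det) for name, det in sorted(det_sets.items())},
        "class_counts": classification.counts,
        "venn": venn,
        "discordant": ov.discordant,
    }

    direct_genes = classification.genes_of("direct_up") + classification.genes_of(
        "direct_down"
    )
    if promoters is not None and direct_genes:
        scan_cfg = ScanConfig(**(config.get("scan") or {}))
        direct_promoters = {g: promoters[g] for g in direct_genes if g in promoters}
        hits = scan_set(direct_promoters, scan_cfg, mode="best_per_gene")
        hits.to_csv(outdir / "tre_hits.bed", sep="\t", index=False)
        clean = [s for s in hits["matched_seq"] if "N" not in s]
        if clean:
            motif = build_motif(clean)
            motif.save(outdir / "motif_counts.tsv")
            summary["tre"] = {
                "n_genes_scanned": len(direct_promoters),
                "n_hit_genes": int(len(hits)),
                "n_motif_sequences": len(clean),
                "consensus": motif.consensus,
            }
        else:
            log.info("no N-free TRE hits; consensus stage skipped")
            summary["tre"] = {
                "n_genes_scanned": len(direct_promoters),
                "n_hit_genes": int(len(hits)),
                "n_motif_sequences": 0,
                "consensus": None,
            }
    else:
        log.info("no direct targets or no promoters; TRE stage skipped")
        summary["tre"] = None

    if "annotation" in config:
        ann = enrich_mod.read_annotation_tsv(config["annotation"])
        focal = contrasts["th_vs_ctrl"].table
        universe = set(focal.index[focal["padj"].notna()])
        de = det_sets["th_vs_ctrl"].genes() & universe
        table = enrich_mod.ora(de, ann, universe)
        table.to_csv(outdir / "enrichment_th_vs_ctrl.tsv", sep="\t", index=False)
        summary["enrichment"] = {
            "n_terms_tested": int(len(table)),
            "n_significant": int(table["significant"].sum()),
        }

    if truth is not None:
        summary["truth_class_counts"] = {
            lab: int((truth.table["class_label"] == lab).sum())
            for lab in sorted(truth.table["class_label"].unique())
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _direct_report(classification, contrasts, outdir: Path) -> None:
    """Report table of the direct targets: log2FC and q in both focal contrasts."""
    direct = classification.table[
        classification.table["label"].isin(["direct_up", "direct_down"])
    ]
    rows = []
    for gene in direct.index:
        rows.append(
            {
                "gene_id": gene,
                "label": direct.at[gene, "label"],
                "lfc_th_vs_ctrl": contrasts["th_vs_ctrl"].table.at[gene, "log2fc"],
                "q_th_vs_ctrl": contrasts["th_vs_ctrl"].table.at[gene, "padj"],
                "lfc_thchx_vs_chx": contrasts["thchx_vs_chx"].table.at[gene, "log2fc"],
                "q_thchx_vs_chx": contrasts["thchx_vs_chx"].table.at[gene, "padj"],
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "label",
            "lfc_th_vs_ctrl",
            "q_th_vs_ctrl",
            "lfc_thchx_vs_chx",
            "q_thchx_vs_chx",
        ],
    ).to_csv(outdir / "direct_targets_report.tsv", sep="\t", index=False)
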