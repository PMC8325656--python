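"""End-to-end orchestration: simulate/load -> ratios -> annotation -> consensus ->
normalization -> presence -> Venn -> enrichment, with every intermediate written
to disk and a manifest tying the run together.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .annotate import annotate_ev, consensus_ev_counts, ev_detection_sets, marker_qc
from .config import (
    AnalysisThresholds,
    EnrichmentConfig,
    PresenceRules,
    PROTEOME_HISTOLOGY,
    TRANSCRIPT_HISTOLOGY,
)
from .differential import differential_group, venn_proteins
from .enrichment import gsea, rank_genes
from .nanostring import normalize, qc_samples
from .presence import call_presence, detect_replicates, detected_anywhere, venn_mrna
from .ratios import compute_reference_ratios, merge_plexes
from .simulate import SyntheticConfig, generate_nanostring, generate_proteomics


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    Either ``synthetic`` is set (the generator provides both omics tables)
    or the four input paths are. Histology maps default to the study layout.
    """

    out_dir: Path
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    quant_values: Path | None = None
    quant_design: Path | None = None
    counts: Path | None = None
    probe_classes: Path | None = None
    count_samples: Path | None = None
    gene_sets: Path | None = None
    histology_proteome: dict = field(default_factory=lambda: dict(PROTEOME_HISTOLOGY))
    histology_transcript: dict = field(default_factory=lambda: dict(TRANSCRIPT_HISTOLOGY))
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    presence_rules: PresenceRules = field(default_factory=PresenceRules)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    manual_qc_exclusions: dict = field(default_factory=dict)

    def validate_against(self, cell_lines_proteome, cell_lines_transcript) -> None:
        for line in cell_lines_proteome:
            if line not in self.histology_proteome:
                raise PipelineError(f"stage=config: cell line {line!r} missing from proteome histology map")
        for line in cell_lines_transcript:
            if line not in self.histology_transcript:
                raise PipelineError(f"stage=config: cell line {line!r} missing from transcript histology map")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # annotate with the failing stage
                raise PipelineError(f"stage={name}: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order, writing all intermediates under ``out_dir``.

    Returns a dict of in-memory results keyed by stage name; identical
    (config, seed) pairs produce byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    row_counts: dict[str, int] = {}

    if config.synthetic is not None:
        syn = SyntheticConfig(
            **{**config.synthetic.__dict__, "seed": config.seed}
        )
        quant, prot_truth = _stage("simulate_proteomics")(generate_proteomics)(syn)
        counts, rna_truth = _stage("simulate_nanostring")(generate_nanostring)(syn)
        histology_prot = {l: h for l, h in syn.cell_lines}
        histology_rna = dict(histology_prot)
        io.write_quant_table(quant, out / "quant.tsv", out / "quant_design.tsv")
        io.write_count_matrix(
            counts, out / "counts.tsv", out / "probe_classes.tsv", out / "count_samples.tsv"
        )
        outputs["quant"] = out / "quant.tsv"
        outputs["counts"] = out / "counts.tsv"
    else:
        quant = _stage("read_quant")(io.read_quant_table)(config.quant_values, config.quant_design)
        counts = _stage("read_counts")(io.read_count_matrix)(
            config.counts, config.probe_classes, config.count_samples
        )
        prot_truth = rna_truth = None
        histology_prot = config.histology_proteome
        histology_rna = config.histology_transcript
        config.validate_against(
            set(quant.design.loc[~quant.design["is_reference"], "cell_line"]),
            set(counts.samples["cell_line"]),
        )

    # --- proteome branch
    ratios = _stage("ratios")(compute_reference_ratios)(quant)
    merged = _stage("merge")(merge_plexes)(ratios)
    io.write_ratio_matrix(merged, out / "ratios.tsv")
    outputs["ratios"] = out / "ratios.tsv"
    row_counts["ratios"] = len(merged.proteins)

    annot = _stage("annotate")(annotate_ev)(merged, config.thresholds)
    annot.table.to_csv(out / "ev_annotation.tsv", sep="\t", index=False)
    outputs["ev_annotation"] = out / "ev_annotation.tsv"
    row_counts["ev_annotation"] = len(annot.table)

    markers = _stage("marker_qc")(marker_qc)(merged, thresholds=config.thresholds)
    markers.to_csv(out / "marker_qc.tsv", sep="\t", index=False)

    counts_k, _sets_k = _stage("consensus")(consensus_ev_counts)(annot)

    groups = {h: [l for l, hh in histology_prot.items() if hh == h] for h in ("benign", "ccRCC", "pRCC")}
    diffs = {}
    for a, b in (("pRCC", "benign"), ("ccRCC", "benign"), ("pRCC", "ccRCC")):
        if groups[a] and groups[b]:
            res = _stage("differential")(differential_group)(
                merged, groups[a], groups[b], "EV", config.thresholds
            )
            res.table.to_csv(out / f"differential_{a}_vs_{b}.tsv", sep="\t")
            diffs[(a, b)] = res

    detection = _stage("detection")(ev_detection_sets)(merged)
    venn_prot = _stage("venn_proteins")(venn_proteins)(detection, histology_prot)
    venn_prot.to_frame().to_csv(out / "venn_proteins.tsv", sep="\t", index=False)
    (out / "venn_proteins.json").write_text(
        json.dumps(venn_prot.region_sizes(), indent=2, sort_keys=True) + "\n"
    )
    outputs["venn_proteins"] = out / "venn_proteins.tsv"

    # --- transcript branch
    qc = _stage("qc")(qc_samples)(counts, manual_exclusions=config.manual_qc_exclusions)
    io.write_qc_report(qc, out / "qc.tsv")
    norm = _stage("normalize")(normalize)(counts, qc)
    io.write_normalized(norm, out / "normalized.tsv", out / "norm_factors.tsv")
    outputs["normalized"] = out / "normalized.tsv"
    row_counts["normalized"] = len(norm.values)

    detection_rna = _stage("detect")(detect_replicates)(norm, qc)
    pres = _stage("presence")(call_presence)(
        detection_rna, counts.samples, histology_rna, config.presence_rules
    )
    pres.by_line.rename_axis("gene").to_csv(out / "presence_by_line.tsv", sep="\t")
    pres.by_type.rename_axis("gene").to_csv(out / "presence_by_type.tsv", sep="\t")
    any_set, all_set = detected_anywhere(detection_rna, pres)

    venn_rna = _stage("venn_mrna")(venn_mrna)(pres)
    venn_rna.to_frame().to_csv(out / "venn_mrna.tsv", sep="\t", index=False)
    (out / "venn_mrna.json").write_text(
        json.dumps(venn_rna.region_sizes(), indent=2, sort_keys=True) + "\n"
    )
    outputs["venn_mrna"] = out / "venn_mrna.tsv"

    # --- enrichment branch (needs >=1 sample per side)
    gsea_result = None
    samples_by_type = {
        h: [
            s
            for s in norm.values.columns
            if histology_rna.get(counts.samples.loc[s, "cell_line"]) == h
        ]
        for h in ("benign", "ccRCC")
    }
    if config.gene_sets and all(samples_by_type.values()):
        ranked = _stage("rank")(rank_genes)(
            norm, samples_by_type["ccRCC"], samples_by_type["benign"]
        )
        io.write_rnk(ranked, out / "ccRCC_vs_benign.rnk")
        sets = _stage("gene_sets")(io.read_gmt)(config.gene_sets)
        enr_cfg = EnrichmentConfig(
            **{**config.enrichment.__dict__, "seed": config.seed}
        )
        gsea_result = _stage("gsea")(gsea)(ranked, sets, enr_cfg)
        gsea_result.to_csv(out / "gsea.tsv", sep="\t")
        outputs["gsea"] = out / "gsea.tsv"

    manifest = io.write_manifest(
        out / "manifest.json",
        config={"seed": config.seed, "thresholds": config.thresholds.__dict__},
        outputs={k: str(v) for k, v in outputs.items()},
        row_counts=row_counts,
        version=__version__,
    )
    return {
        "ratios": merged,
        "annotation": annot,
        "marker_qc": markers,
        "consensus_counts": counts_k,
        "differential": diffs,
        "detection": detection,
        "venn_proteins": venn_prot,
        "qc": qc,
        "normalized": norm,
        "presence": pres,
        "detected_any": any_set,
        "present_all_lines": all_set,
        "venn_mrna": venn_rna,
        "gsea": gsea_result,
        "proteome_truth": prot_truth,
        "transcript_truth": rna_truth,
        "manifest": manifest,
    }
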