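"""End-to-end orchestration.

``run_pipeline`` wires the stages together: read phased panel -> region
mask -> cross-class LD exclusion -> single-variant deficit scan -> geneLOF
collapsing and gene-based scan -> FDR calibration against intergenic
variants -> gene-set over-representation -> carrier-couple miscarriage
analysis. Every output file carries the configuration hash and seed, and
the stage log records the variant/gene counts entering and leaving each
stage (the study-design funnel).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import enrichment, fdr, genelof, io, scan
from .couples import carrier_couple_analysis, identify_carrier_couples

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and outputs of one pipeline run.

    Thresholds default to the scan's standard constants: strong-deficit
    ratio 0.1, minimum tested expected count 0.5, geneLOF MAF bound 2%,
    cross-class r^2 0.8, alpha 0.05 and the fixed expected-count bin edges.
    """

    vcf_paths: dict[str, str] = field(default_factory=dict)  # population -> path
    annotation_path: str = ""
    mask_bed_path: str | None = None
    gene_sets_path: str | None = None
    couples_path: str | None = None
    exclusion_list_path: str | None = None
    output_dir: str = "homdeficit_out"
    seed: int = 0
    strong_ratio: float = scan.STRONG_RATIO
    min_lambda: float = scan.MIN_LAMBDA
    genelof_maf_max: float = genelof.GENELOF_MAF_MAX
    r2_threshold: float = 0.8
    alpha: float = 0.05
    match_ratio: int = 100

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**io.read_yaml(path))

    def config_hash(self) -> str:
        payload = repr(sorted(self.to_dict().items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns the result bundle.

    Any stage failure aborts with the stage name and cause. Results are
    returned in-memory and, when ``output_dir`` is set, written as TSV/JSON
    with a metadata echo of the configuration.
    """
    bundle: dict = {"config": config.to_dict(),
                    "config_hash": config.config_hash(),
                    "stage_counts": {}}
    counts = bundle["stage_counts"]
    stage = "setup"
    try:
        stage = "read_panel"
        panel = io.read_panel(config.vcf_paths)
        annotations = io.read_tsv(config.annotation_path)
        counts["variants_read"] = panel.n_variants
        logger.info("read %d variants across %d populations",
                    panel.n_variants, len(panel.populations))

        stage = "mask_filter"
        if config.mask_bed_path:
            mask = io.read_bed(config.mask_bed_path)
            keep = []
            for row in annotations.itertuples(index=False):
                sub = mask[mask["chrom"] == row.chrom]
                pos0 = io.vcf_pos_to_bed_start(row.pos)
                keep.append(bool(((sub["start"] <= pos0)
                                  & (pos0 < sub["end"])).any()))
            annotations = annotations[pd.Series(keep, index=annotations.index)]
        counts["variants_in_mask"] = len(annotations)

        stage = "ld_exclusion"
        retained = scan.crossclass_ld_exclude(panel, annotations,
                                              r2_threshold=config.r2_threshold)
        kept_ids = {v for ids in retained.values() for v in ids}
        annotations = annotations[annotations["variant_id"].isin(kept_ids)]
        counts["variants_after_ld_exclusion"] = len(annotations)

        stage = "single_variant_scan"
        results = scan.scan_panel(panel, annotations,
                                  min_lambda=config.min_lambda,
                                  strong_ratio=config.strong_ratio)
        results = results[results["unit_id"].isin(set(annotations["variant_id"]))]
        for cls, grp in results.groupby("impact_class"):
            counts[f"tested_{cls}"] = int(grp["tested"].sum())
            counts[f"strong_deficit_{cls}"] = int(grp["strong_deficit"].sum())
        bundle["variant_results"] = results

        stage = "genelof"
        exclude = set()
        if config.exclusion_list_path:
            exclude = set(pd.read_csv(config.exclusion_list_path,
                                      header=None)[0].astype(str))
        qualifying = genelof.select_qualifying_plofs(
            annotations, panel, maf_max=config.genelof_maf_max,
            exclude_ids=exclude)
        matrices = genelof.collapse_to_genelof(panel, qualifying)
        catalogue = genelof.build_knockout_catalogue(matrices)
        gene_results = genelof.genelof_deficit_scan(
            matrices, min_lambda=config.min_lambda,
            strong_ratio=config.strong_ratio)
        counts["genes_collapsed"] = len(gene_results)
        counts["genes_tested"] = int(gene_results["tested"].sum()) \
            if len(gene_results) else 0
        bundle["gene_results"] = gene_results
        bundle["knockout_catalogue"] = catalogue
        bundle["genelof_matrices"] = matrices

        stage = "fdr_calibration"
        fdr_tables = {}
        for pav_class in ("plof", "moderate"):
            if (results["impact_class"] == pav_class).any():
                fdr_tables[pav_class] = fdr.calibrate_fdr(results,
                                                          pav_class=pav_class)
        bundle["fdr_tables"] = fdr_tables

        stage = "enrichment"
        if config.gene_sets_path and len(gene_results):
            gene_sets = io.read_gene_sets(config.gene_sets_path)
            bundle["enrichment"] = enrichment.overrepresentation_by_bin(
                gene_results, gene_sets)

        stage = "couples"
        if config.couples_path and len(gene_results):
            couples = io.read_couples(config.couples_path)
            genes = sorted(gene_results["unit_id"])
            couples = identify_carrier_couples(matrices, couples, genes)
            deficit_genes = sorted(
                gene_results.loc[gene_results["strong_deficit"], "unit_id"])
            if deficit_genes:
                bundle["couples"] = carrier_couple_analysis(
                    couples, deficit_genes, ratio=config.match_ratio,
                    alpha=config.alpha)

        stage = "write_outputs"
        if config.output_dir:
            _write_bundle(bundle, config)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.to_dict(), "config_hash": bundle["config_hash"],
            "seed": config.seed, "stage_counts": bundle["stage_counts"]}
    io.write_yaml(meta, out / "run_metadata.yaml")
    io.write_tsv(bundle["variant_results"], out / "variant_deficit.tsv")
    if len(bundle.get("gene_results", [])):
        io.write_tsv(bundle["gene_results"], out / "gene_deficit.tsv")
    if "knockout_catalogue" in bundle:
        io.write_json(bundle["knockout_catalogue"].to_dict(),
                      out / "knockout_catalogue.json")
    for pav_class, table in bundle.get("fdr_tables", {}).items():
        io.write_tsv(table, out / f"fdr_{pav_class}.tsv")
    if "enrichment" in bundle:
        io.write_tsv(bundle["enrichment"], out / "enrichment.tsv")
    if "couples" in bundle and len(bundle["couples"]):
        io.write_tsv(bundle["couples"], out / "couples.tsv")
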