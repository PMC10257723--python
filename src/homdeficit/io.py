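"""File formats: phased VCF, annotation/couples/gene-set TSV, BED, YAML.

Coordinate conventions are centralized here: VCF positions are 1-based
inclusive, BED intervals 0-based half-open. Phased VCF is the genotype
exchange format — an unphased separator is a hard error because the scan
and the gene collapsing are defined on haplotypes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml
from scipy import sparse

from .couples import CoupleRecord
from .panel import CohortPanel, PopulationPanel
from .simulate import SimulationConfig, resolve_genes


def vcf_pos_to_bed_start(pos: int) -> int:
    """1-based inclusive VCF position -> 0-based BED start."""
    return pos - 1


def bed_start_to_vcf_pos(start: int) -> int:
    """0-based BED start -> 1-based inclusive VCF position."""
    return start + 1


# ---------------------------------------------------------------------------
# synthetic-cohort coordinate layout

GENE_SPAN = 20_000
GENE_STRIDE = 200_000
GENE_OFFSET = 100_000  # BED start of the first gene


def layout_variants(config: SimulationConfig) -> pd.DataFrame:
    """Assign deterministic coordinates and alleles to a simulated cohort.

    Genes are laid out as disjoint intervals on chr1 (BED start
    ``GENE_OFFSET + k * GENE_STRIDE``, length ``GENE_SPAN`` for the k-th
    gene); genic variants are placed at successive positions inside their
    gene. Intergenic variants live on the gene-free chr2, so they belong to
    every intergenic distance set. Returns the annotation table
    (variant_id, chrom, pos, ref, alt, impact_class, gene, plof_confidence,
    survival_fraction, freq_<population>).
    """
    variants = resolve_genes(config)
    genes = sorted({v.gene for v in variants if v.gene is not None})
    gene_start = {g: GENE_OFFSET + k * GENE_STRIDE for k, g in enumerate(genes)}
    offsets: dict[str, int] = {}
    rows = []
    next_intergenic = 1
    for v in variants:
        if v.gene is None:
            chrom, pos = "chr2", next_intergenic
            next_intergenic += 1_000
        else:
            k = offsets.get(v.gene, 0)
            offsets[v.gene] = k + 1
            if k >= GENE_SPAN:
                raise ValueError(f"gene {v.gene!r} holds too many variants")
            chrom, pos = "chr1", bed_start_to_vcf_pos(gene_start[v.gene] + k)
        row = {
            "variant_id": v.variant_id, "chrom": chrom, "pos": pos,
            "ref": "A", "alt": "C", "impact_class": v.impact_class,
            "gene": v.gene, "plof_confidence": v.plof_confidence,
            "survival_fraction": v.survival_fraction,
        }
        for pop in config.populations:
            row[f"freq_{pop.name}"] = v.per_population_freq.get(pop.name, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def gene_intervals(config: SimulationConfig) -> pd.DataFrame:
    """BED-convention intervals (chrom, start, end, name) of the simulated genes."""
    variants = resolve_genes(config)
    genes = sorted({v.gene for v in variants if v.gene is not None})
    return pd.DataFrame({
        "chrom": "chr1",
        "start": [GENE_OFFSET + k * GENE_STRIDE for k in range(len(genes))],
        "end": [GENE_OFFSET + k * GENE_STRIDE + GENE_SPAN
                for k in range(len(genes))],
        "name": genes,
    })


# ---------------------------------------------------------------------------
# VCF


def write_population_vcf(panel: CohortPanel, population: str,
                         annotations: pd.DataFrame, path: str | Path) -> None:
    """Write one population's phased genotypes as an uncompressed VCF."""
    pop = panel.population(population)
    ann = annotations.set_index("variant_id")
    order = ann.loc[list(panel.variant_ids)].reset_index()
    order["col"] = [panel.variant_index(v) for v in order["variant_id"]]
    order = order.sort_values(["chrom", "pos", "variant_id"], kind="stable")

    n = pop.n_individuals
    contigs = sorted(order["chrom"].unique())
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=homdeficit\n##population={population}\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, pop.individual_ids)) + "\n")
        for row in order.itertuples(index=False):
            j = row.col
            a, b = pop.column_indices(j)
            av = np.zeros(n, dtype=np.uint8)
            bv = np.zeros(n, dtype=np.uint8)
            av[a] = 1
            bv[b] = 1
            gts = np.char.add(np.char.add(av.astype("U1"), "|"), bv.astype("U1"))
            if pop.missing is not None:
                mi = pop.missing.indices[pop.missing.indptr[j]:
                                         pop.missing.indptr[j + 1]]
                gts[mi] = ".|."
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t"
                     f"{row.alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_panel(vcf_paths: dict[str, str | Path]) -> CohortPanel:
    """Read phased VCFs (one per population) into a cohort panel.

    Genotypes must be diploid and phased ("|" separator); an unphased call
    is a hard error naming the record. Multiallelic records are split into
    one biallelic unit per alternate allele. Missing calls are recorded and
    excluded from counts. The panel's variant set is the union across
    populations; a variant absent from a population is coded all-reference
    there (frequency 0).
    """
    variant_order: list[str] = []
    seen: set[str] = set()
    per_pop: dict[str, dict] = {}

    for pop_name, path in vcf_paths.items():
        vf = pysam.VariantFile(str(path))
        samples = list(vf.header.samples)
        n = len(samples)
        cols: dict[str, tuple[list[int], list[int], list[int]]] = {}
        for rec in vf:
            alts = rec.alts or ()
            for alt_idx, alt in enumerate(alts, start=1):
                if rec.id and rec.id != "." and len(alts) == 1:
                    vid = rec.id
                else:
                    vid = f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
                a_idx: list[int] = []
                b_idx: list[int] = []
                m_idx: list[int] = []
                for i, sample in enumerate(samples):
                    call = rec.samples[sample]
                    gt = call["GT"]
                    if gt is None or len(gt) != 2:
                        raise ValueError(
                            f"{path}: record {rec.chrom}:{rec.pos} sample "
                            f"{sample}: non-diploid genotype {gt!r}")
                    if gt[0] is None or gt[1] is None:
                        m_idx.append(i)
                        continue
                    if not call.phased:
                        raise ValueError(
                            f"{path}: record {rec.chrom}:{rec.pos} sample "
                            f"{sample}: unphased genotype (\"/\" separator)")
                    if gt[0] == alt_idx:
                        a_idx.append(i)
                    if gt[1] == alt_idx:
                        b_idx.append(i)
                if vid in cols:
                    raise ValueError(f"{path}: duplicate variant unit {vid!r}")
                cols[vid] = (a_idx, b_idx, m_idx)
                if vid not in seen:
                    seen.add(vid)
                    variant_order.append(vid)
        per_pop[pop_name] = {"samples": samples, "n": n, "cols": cols}

    m = len(variant_order)
    col_of = {v: j for j, v in enumerate(variant_order)}
    populations = []
    for pop_name, data in per_pop.items():
        n = data["n"]
        ra, ca, rb, cb, rm, cm = [], [], [], [], [], []
        for vid, (a_idx, b_idx, m_idx) in data["cols"].items():
            j = col_of[vid]
            ra.extend(a_idx); ca.extend([j] * len(a_idx))
            rb.extend(b_idx); cb.extend([j] * len(b_idx))
            rm.extend(m_idx); cm.extend([j] * len(m_idx))

        def build(rows, colidx):
            return sparse.csc_matrix(
                (np.ones(len(rows), dtype=np.uint8), (rows, colidx)),
                shape=(n, m), dtype=np.uint8)

        populations.append(PopulationPanel(
            name=pop_name, hap_a=build(ra, ca), hap_b=build(rb, cb),
            individual_ids=np.array(data["samples"], dtype=object),
            missing=build(rm, cm) if rm else None))
    return CohortPanel(variant_ids=np.array(variant_order, dtype=object),
                       populations=populations)


# ---------------------------------------------------------------------------
# TSV / BED / YAML


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED intervals as (chrom, start, end[, name]); 0-based half-open."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    frame.columns = ["chrom", "start", "end", "name"][: frame.shape[1]]
    return frame


def write_bed(frame: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name") if c in frame.columns]
    frame[cols].to_csv(path, sep="\t", index=False, header=False)


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Gene-set membership TSV with columns (gene, set_label)."""
    frame = pd.read_csv(path, sep="\t")
    return {label: set(grp["gene"]) for label, grp in frame.groupby("set_label")}


def write_gene_sets(sets: dict[str, set[str]], path: str | Path) -> None:
    rows = [(g, label) for label, genes in sets.items() for g in sorted(genes)]
    pd.DataFrame(rows, columns=["gene", "set_label"]).to_csv(
        path, sep="\t", index=False)


def write_couples(records: list[CoupleRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        status = ";".join(f"{g}:{s}" for g, s in sorted(r.carrier_status.items()))
        rows.append({
            "couple_id": r.couple_id, "mother": r.mother, "father": r.father,
            "carrier_status": status, "n_pregnancies": r.n_pregnancies,
            "n_miscarriages": r.n_miscarriages, "birth_year": r.birth_year,
            "n_children_dead_before_2": r.n_children_dead_before_2,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_couples(path: str | Path) -> list[CoupleRecord]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    records = []
    for row in frame.itertuples(index=False):
        status = {}
        if row.carrier_status:
            for item in str(row.carrier_status).split(";"):
                gene, s = item.split(":")
                status[gene] = s
        records.append(CoupleRecord(
            couple_id=str(row.couple_id), mother=str(row.mother),
            father=str(row.father), carrier_status=status,
            n_pregnancies=int(row.n_pregnancies),
            n_miscarriages=int(row.n_miscarriages),
            birth_year=int(row.birth_year),
            n_children_dead_before_2=int(row.n_children_dead_before_2)))
    return records


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
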