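"""Miscarriage excess among carrier couples.

A couple in which both partners are heterozygous carriers of a pLOF in the
same gene has a one-in-four chance per pregnancy of conceiving a homozygote.
If homozygotes for that gene are lost in utero, such couples should show an
excess of miscarriages relative to matched non-carrier couples, while
couples with a single carrier should not — the signature of a recessive
lethal. Cases are compared with 1:100 nearest-neighbour matched controls
(matched on maternal birth year and number of pregnancies, with
replacement) using the Fisher exact test, both on ever-miscarriage status
and per pregnancy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import FisherResult, fisher_exact_2x2

logger = logging.getLogger(__name__)

MATCH_RATIO = 100


@dataclass
class CoupleRecord:
    """One couple's genotype-relevant status and reproductive history."""

    couple_id: str
    mother: str
    father: str
    carrier_status: dict = field(default_factory=dict)  # gene -> both/one/neither
    n_pregnancies: int = 0
    n_miscarriages: int = 0
    birth_year: int = 1960
    n_children_dead_before_2: int = 0

    def __post_init__(self) -> None:
        if self.n_miscarriages > self.n_pregnancies:
            raise ValueError(
                f"couple {self.couple_id!r}: miscarriages exceed pregnancies")

    @property
    def ever_miscarriage(self) -> bool:
        return self.n_miscarriages >= 1

    @property
    def n_live_births(self) -> int:
        return self.n_pregnancies - self.n_miscarriages


def identify_carrier_couples(genelof: dict[str, pd.DataFrame],
                             couples: list[CoupleRecord],
                             genes: list[str]) -> list[CoupleRecord]:
    """Fill per-gene carrier status from geneLOF genotypes.

    Status is "both" only when each parent is heterozygous (exactly one
    haplotype affected); a homozygous parent does not make a heterozygous
    carrier couple and is logged. Couples with a partner missing from the
    genotype matrices are dropped with a log entry.
    """
    lookup: dict[str, pd.Series] = {}
    for frame in genelof.values():
        for ind in frame.index:
            lookup[ind] = frame.loc[ind]

    out = []
    for cpl in couples:
        gm = lookup.get(cpl.mother)
        gf = lookup.get(cpl.father)
        if gm is None or gf is None:
            logger.info("couple %s dropped: partner not genotyped", cpl.couple_id)
            continue
        status = {}
        for gene in genes:
            am = int(gm.get(gene, 0))
            af = int(gf.get(gene, 0))
            if am == 1 and af == 1:
                status[gene] = "both"
            elif am >= 1 or af >= 1:
                status[gene] = "one"
                if am == 2 or af == 2:
                    logger.info("couple %s: homozygous parent for %s, "
                                "not a heterozygous carrier couple",
                                cpl.couple_id, gene)
            else:
                status[gene] = "neither"
        cpl.carrier_status = status
        out.append(cpl)
    return out


def split_by_status(couples: list[CoupleRecord],
                    gene: str | None = None) -> dict[str, list[CoupleRecord]]:
    """Partition couples into both/one/neither carrier groups.

    With ``gene=None`` a couple counts as "both" ("one") if it is a double
    (single) carrier for any gene in its status map, and "neither" only if
    it carries nothing anywhere.
    """
    groups: dict[str, list[CoupleRecord]] = {"both": [], "one": [], "neither": []}
    for cpl in couples:
        statuses = ([cpl.carrier_status.get(gene, "neither")] if gene
                    else list(cpl.carrier_status.values()) or ["neither"])
        if "both" in statuses:
            groups["both"].append(cpl)
        elif "one" in statuses:
            groups["one"].append(cpl)
        else:
            groups["neither"].append(cpl)
    return groups


def match_control_couples(cases: list[CoupleRecord],
                          pool: list[CoupleRecord],
                          ratio: int = MATCH_RATIO,
                          seed: int = 0) -> list[CoupleRecord]:
    """1:``ratio`` nearest-neighbour control matching with replacement.

    For each case couple the ``ratio`` nearest pool couples by Euclidean
    distance on (birth year, number of pregnancies), both standardized by
    the pool standard deviation, are selected; a pool couple may serve
    several cases (matching with replacement). Ties break on couple id, so
    the matched multiset is deterministic.
    """
    if not pool:
        raise ValueError("empty control pool")
    if len(pool) < ratio:
        warnings.warn(
            f"control pool ({len(pool)}) smaller than matching ratio ({ratio}); "
            "using every pool couple per case", stacklevel=2)
    k = min(ratio, len(pool))

    def covariates(records: list[CoupleRecord]) -> np.ndarray:
        return np.array([[r.birth_year, r.n_pregnancies] for r in records],
                        dtype=float)

    xp = covariates(pool)
    sd = xp.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    xp_s = xp / sd
    pool_ids = np.array([r.couple_id for r in pool], dtype=object)
    id_order = np.argsort(pool_ids, kind="stable")

    controls: list[CoupleRecord] = []
    for case in cases:
        xc = np.array([case.birth_year, case.n_pregnancies], dtype=float) / sd
        d = np.sqrt(((xp_s - xc) ** 2).sum(axis=1))
        # stable selection: sort by (distance, couple_id)
        order = np.lexsort((pool_ids, d))
        controls.extend(pool[i] for i in order[:k])
    return controls


def miscarriage_ever_test(cases: list[CoupleRecord],
                          controls: list[CoupleRecord],
                          level: float = 0.95) -> FisherResult:
    """Fisher exact test on ever-miscarriage status, cases vs matched controls."""
    if not cases or not controls:
        raise ValueError("both arms must be non-empty")
    a = sum(c.ever_miscarriage for c in cases)
    b = len(cases) - a
    c = sum(c.ever_miscarriage for c in controls)
    d = len(controls) - c
    return fisher_exact_2x2([[a, b], [c, d]], level=level)


def miscarriage_per_pregnancy_test(cases: list[CoupleRecord],
                                   controls: list[CoupleRecord],
                                   level: float = 0.95) -> FisherResult:
    """Fisher exact test on pooled pregnancy outcomes (miscarriage vs not)."""
    a = sum(c.n_miscarriages for c in cases)
    b = sum(c.n_live_births for c in cases)
    c = sum(x.n_miscarriages for x in controls)
    d = sum(x.n_live_births for x in controls)
    if a + b == 0 or c + d == 0:
        raise ValueError("an arm has zero pregnancies")
    return fisher_exact_2x2([[a, b], [c, d]], level=level)


def carrier_couple_analysis(couples: list[CoupleRecord],
                            genes: list[str],
                            ratio: int = MATCH_RATIO,
                            alpha: float = 0.05,
                            min_total_pregnancies: int = 2) -> pd.DataFrame:
    """Per-gene and overall miscarriage-excess table.

    For each gene, double-carrier couples are compared against non-carrier
    (neither for every gene) couples matched 1:ratio; genes whose carrier
    couples have fewer than ``min_total_pregnancies`` pregnancies in total
    are skipped. The per-gene significance threshold is Bonferroni-corrected
    for the number of genes tested, and an "all genes" row pools every
    double-carrier couple.
    """
    overall = split_by_status(couples, gene=None)
    pool = overall["neither"]
    rows = []

    def run(name: str, cases: list[CoupleRecord]) -> dict | None:
        if not cases:
            return None
        controls = match_control_couples(cases, pool, ratio=ratio)
        fr = miscarriage_ever_test(cases, controls)
        return {
            "gene": name,
            "n_couples": len(cases),
            "n_children": sum(c.n_live_births for c in cases),
            "n_children_dead_before_2": sum(c.n_children_dead_before_2
                                            for c in cases),
            "miscarriage_ever": sum(c.ever_miscarriage for c in cases),
            "odds_ratio": fr.odds_ratio,
            "ci_low": fr.ci[0], "ci_high": fr.ci[1],
            "p": fr.p_two_sided,
        }

    tested_genes = []
    for gene in genes:
        cases = split_by_status(couples, gene=gene)["both"]
        if sum(c.n_pregnancies for c in cases) < min_total_pregnancies:
            continue
        row = run(gene, cases)
        if row is not None:
            tested_genes.append(gene)
            rows.append(row)
    all_row = run("all", overall["both"])
    if all_row is not None:
        rows.append(all_row)
    out = pd.DataFrame(rows)
    if len(out):
        n_tested = max(len(tested_genes), 1)
        out["significant"] = out["p"] < alpha / n_tested
        out.attrs["bonferroni_threshold"] = alpha / n_tested
    return out
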