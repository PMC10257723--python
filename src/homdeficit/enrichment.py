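"""Gene-set over-representation among deficit genes.

Association between a strong deficit of homozygosity and gene-set
membership is measured on 2x2 tables with the two-sided Fisher exact test.
The reported effect size is the conditional maximum-likelihood odds ratio
(the odds ratio maximizing the noncentral hypergeometric likelihood given
the table margins) with its exact tail-inversion confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

#: expected-count strata used for the gene-set analysis
ENRICHMENT_BINS = ((1.0, 5.0), (5.0, math.inf))


@dataclass(frozen=True)
class FisherResult:
    """Two-sided Fisher exact test on a 2x2 table.

    ``odds_ratio`` is the conditional MLE; it is NaN when a margin is
    degenerate (then p is 1 and no association is estimable), 0 or inf when
    the observed count sits on the boundary of the hypergeometric support.
    """

    odds_ratio: float
    ci: tuple[float, float]
    p_two_sided: float
    table: tuple[tuple[int, int], tuple[int, int]]


def fisher_exact_2x2(table, level: float = 0.95) -> FisherResult:
    """Exact conditional analysis of a 2x2 contingency table.

    The two-sided p-value sums the probabilities of all tables (given the
    margins, at odds ratio 1) no more probable than the observed one; the
    odds ratio solves the conditional score equation
    E_psi[a | margins] = a.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if degenerate:
        return FisherResult(odds_ratio=math.nan, ci=(math.nan, math.nan),
                            p_two_sided=1.0, table=((a, b), (c, d)))
    p = float(stats.fisher_exact(t, alternative="two-sided").pvalue)
    res = _odds_ratio(t, kind="conditional")
    ci = res.confidence_interval(confidence_level=level)
    return FisherResult(odds_ratio=float(res.statistic),
                        ci=(float(ci.low), float(ci.high)),
                        p_two_sided=p, table=((a, b), (c, d)))


def overrepresentation_by_bin(gene_results: pd.DataFrame,
                              gene_sets: dict[str, set[str]],
                              bins=ENRICHMENT_BINS,
                              level: float = 0.95) -> pd.DataFrame:
    """Fisher exact over-representation per (gene set, expected-count bin).

    ``gene_results`` is a gene-level deficit-scan frame (unit_id, lambda,
    tested, strong_deficit). For each bin and set the 2x2 is

        rows:    strong deficit yes / no   (among tested genes in the bin)
        columns: in set yes / no

    Empty strata are flagged (NaN odds ratio, n_genes 0) rather than tested.
    """
    tested = gene_results[gene_results["tested"]]
    rows = []
    for set_name, members in gene_sets.items():
        for lo, hi in bins:
            sub = tested[(tested["lambda"] >= lo) & (tested["lambda"] < hi)]
            hi_s = "inf" if math.isinf(hi) else f"{hi:g}"
            row = {"gene_set": set_name, "bin": f"[{lo:g},{hi_s})",
                   "n_genes": len(sub)}
            if len(sub) == 0:
                row.update({"a": 0, "b": 0, "c": 0, "d": 0,
                            "odds_ratio": np.nan, "ci_low": np.nan,
                            "ci_high": np.nan, "p": np.nan})
                rows.append(row)
                continue
            deficit = sub["strong_deficit"].to_numpy(dtype=bool)
            in_set = sub["unit_id"].isin(members).to_numpy()
            a = int((deficit & in_set).sum())
            b = int((deficit & ~in_set).sum())
            c = int((~deficit & in_set).sum())
            d = int((~deficit & ~in_set).sum())
            fr = fisher_exact_2x2([[a, c], [b, d]], level=level)
            row.update({"a": a, "b": b, "c": c, "d": d,
                        "odds_ratio": fr.odds_ratio,
                        "ci_low": fr.ci[0], "ci_high": fr.ci[1],
                        "p": fr.p_two_sided})
            rows.append(row)
    return pd.DataFrame(rows)
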