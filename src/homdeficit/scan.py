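"""Deficit-of-homozygosity scan.

For a rare biallelic variant, the allele frequency p_i in population i is
estimated from carrier haplotypes, and under Hardy-Weinberg equilibrium the
expected number of homozygotes across populations is

    lambda = sum_i n_i * p_i**2 .

A variant shows a *strong deficit of homozygosity* when the observed
homozygote count O is 10% or less of lambda; O approximately follows a
Poisson(lambda) distribution, which yields a one-sided deviation p-value
and, with Bonferroni correction, a significance threshold per variant class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats

from .panel import CohortPanel

#: impact classes ordered by predicted functional severity
CLASS_RANK = {"intergenic": 0, "low": 1, "moderate": 2, "plof": 3}

#: default thresholds of the scan
MIN_LAMBDA = 0.5
STRONG_RATIO = 0.1
INTERGENIC_DISTANCES = (5_000, 50_000, 100_000, 250_000, 500_000)


@dataclass(frozen=True)
class PopulationFrequency:
    population: str
    p_hat: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_hat <= 1.0:
            raise ValueError("allele frequency estimate outside [0, 1]")
        if self.n < 0:
            raise ValueError("population size must be non-negative")


def estimate_population_frequency(panel: CohortPanel,
                                  variant_id: str) -> list[PopulationFrequency]:
    """Per-population alternate-allele frequency p_i = alt haplotypes / 2 n_i."""
    j = panel.variant_index(variant_id)
    out = []
    for pop in panel.populations:
        n = int(pop.genotyped_counts()[j])
        alt = int(pop.alt_haplotype_counts()[j])
        p = alt / (2 * n) if n else 0.0
        out.append(PopulationFrequency(population=pop.name, p_hat=p, n=n))
    return out


def expected_homozygotes(freqs: list[PopulationFrequency]) -> tuple[float, dict]:
    """Expected homozygote count lambda = sum_i n_i p_i**2, with per-population terms."""
    terms = {f.population: f.n * f.p_hat ** 2 for f in freqs}
    return float(sum(terms.values())), terms


def observed_homozygotes(panel: CohortPanel, variant_id: str) -> tuple[int, dict]:
    """Observed homozygous-alternate count, combined and per population."""
    j = panel.variant_index(variant_id)
    per_pop = {pop.name: int(pop.hom_alt_counts()[j]) for pop in panel.populations}
    return sum(per_pop.values()), per_pop


def classify_strong_deficit(observed: float, lam: float,
                            min_lambda: float = MIN_LAMBDA,
                            ratio: float = STRONG_RATIO) -> tuple[bool, bool]:
    """Return (tested, strong_deficit).

    A variant is tested when lambda exceeds ``min_lambda``; it has a strong
    deficit when tested and O <= ratio * lambda (inclusive: "10% or less").
    """
    if observed < 0 or lam < 0:
        raise ValueError("counts must be non-negative")
    tested = lam > min_lambda
    strong = bool(tested and observed <= ratio * lam)
    return tested, strong


def poisson_deficit_pvalue(observed: int, lam: float) -> float:
    """One-sided lower-tail P(X <= O) for X ~ Poisson(lambda)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return float(stats.poisson.cdf(observed, lam))


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def maf_for_expected_count(expected: float, total_n: float) -> float:
    """Allele frequency at which a single population of ``total_n`` individuals
    expects ``expected`` homozygotes: the inversion of lambda = n p**2."""
    if expected <= 0 or total_n <= 0:
        raise ValueError("expected count and population size must be positive")
    return math.sqrt(expected / total_n)


def scan_panel(panel: CohortPanel,
               annotations: pd.DataFrame | None = None,
               min_lambda: float = MIN_LAMBDA,
               strong_ratio: float = STRONG_RATIO,
               frequency_override: pd.DataFrame | None = None) -> pd.DataFrame:
    """Run the deficit scan over every variant of the panel.

    Returns one row per variant: combined and per-population expected (E)
    and observed (O) homozygote counts, O/E ratio, tested and strong-deficit
    flags and the Poisson one-sided p-value. Variants whose pooled alternate
    frequency exceeds 0.5 are excluded from testing with a warning (the scan
    targets rare alternate alleles).

    ``annotations`` (optional) is joined on ``variant_id`` to carry impact
    class and gene labels into the result.

    ``frequency_override`` (optional) supplies dosage-based allele-frequency
    estimates — columns (variant_id, population, p_hat), e.g. expected
    carrier haplotypes from imputation divided by 2n — which replace the
    hard-call estimate for the listed (variant, population) pairs; observed
    homozygotes are always counted from the hard calls.
    """
    override: dict[tuple[str, str], float] = {}
    if frequency_override is not None:
        for row in frequency_override.itertuples(index=False):
            if not 0.0 <= row.p_hat <= 1.0:
                raise ValueError("override frequency outside [0, 1]")
            override[(row.variant_id, row.population)] = float(row.p_hat)

    m = panel.n_variants
    lam = np.zeros(m)
    obs = np.zeros(m, dtype=np.int64)
    alt_total = np.zeros(m, dtype=np.int64)
    n_total = np.zeros(m, dtype=np.int64)
    per_pop: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pop in panel.populations:
        n = pop.genotyped_counts().astype(float)
        alt = pop.alt_haplotype_counts()
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, alt / (2 * n), 0.0)
        if override:
            for j, vid in enumerate(panel.variant_ids):
                key = (vid, pop.name)
                if key in override:
                    p[j] = override[key]
        lam_pop = n * p ** 2
        obs_pop = pop.hom_alt_counts()
        lam += lam_pop
        obs += obs_pop
        alt_total += alt
        n_total += n.astype(np.int64)
        per_pop[pop.name] = (lam_pop, obs_pop)

    pooled_freq = np.where(n_total > 0, alt_total / (2 * n_total), 0.0)
    high_freq = pooled_freq > 0.5
    if high_freq.any():
        warnings.warn(
            f"{int(high_freq.sum())} variant(s) with pooled alternate frequency "
            "above 0.5 excluded from deficit testing", stacklevel=2)

    tested = (lam > min_lambda) & ~high_freq
    strong = tested & (obs <= strong_ratio * lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lam > 0, obs / lam, np.nan)
    pval = np.full(m, np.nan)
    pval[tested] = stats.poisson.cdf(obs[tested], lam[tested])

    out = pd.DataFrame({
        "unit_id": panel.variant_ids,
        "lambda": lam,
        "observed": obs,
        "ratio": ratio,
        "tested": tested,
        "strong_deficit": strong,
        "p_poisson": pval,
        "pooled_freq": pooled_freq,
    })
    for name, (lam_pop, obs_pop) in per_pop.items():
        out[f"lambda_{name}"] = lam_pop
        out[f"observed_{name}"] = obs_pop
    if annotations is not None:
        ann = annotations.set_index("variant_id")
        cols = [c for c in ("impact_class", "gene", "plof_confidence", "chrom", "pos")
                if c in ann.columns]
        out = out.join(ann[cols], on="unit_id")
    return out


# ---------------------------------------------------------------------------
# linkage-disequilibrium hygiene


def _pooled_column(panel: CohortPanel, j: int) -> tuple[np.ndarray, int]:
    """Pooled 0/1 haplotype vector (implicitly) for variant j: returns the
    concatenated carrier-index array offsets and total haplotype count."""
    parts = []
    offset = 0
    for pop in panel.populations:
        a, b = pop.column_indices(j)
        parts.append(a + offset)
        offset += pop.n_individuals
        parts.append(b + offset)
        offset += pop.n_individuals
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.intp), offset


def haplotype_r2(panel: CohortPanel, variant_a: str, variant_b: str) -> float:
    """Squared haplotype correlation r^2 on pooled haplotypes.

    r^2 = (p_AB - p_A p_B)^2 / (p_A q_A p_B q_B); 0 by convention when
    either variant is monomorphic.
    """
    ja = panel.variant_index(variant_a)
    jb = panel.variant_index(variant_b)
    ca, total = _pooled_column(panel, ja)
    cb, _ = _pooled_column(panel, jb)
    p_a = ca.size / total
    p_b = cb.size / total
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return 0.0
    p_ab = np.intersect1d(ca, cb, assume_unique=True).size / total
    num = (p_ab - p_a * p_b) ** 2
    den = p_a * (1 - p_a) * p_b * (1 - p_b)
    return float(num / den)


def crossclass_ld_exclude(panel: CohortPanel,
                          annotations: pd.DataFrame,
                          r2_threshold: float = 0.8) -> dict[str, list[str]]:
    """Class-hygiene exclusion of cross-class linked variants.

    A variant is removed from its impact class when its pooled-haplotype r^2
    with any variant of a strictly higher class (hierarchy plof > moderate >
    low > intergenic) exceeds the threshold; plof variants are never removed.
    Returns the retained variant ids per class.
    """
    ann = annotations.set_index("variant_id")["impact_class"]
    X = panel.pooled_haplotypes().astype(np.float64)
    total = X.shape[0]
    counts = np.asarray(X.sum(axis=0)).ravel()
    p = counts / total

    ids_by_class: dict[str, list[str]] = {c: [] for c in CLASS_RANK}
    col_by_class: dict[str, list[int]] = {c: [] for c in CLASS_RANK}
    for j, vid in enumerate(panel.variant_ids):
        cls = ann.get(vid)
        if cls in CLASS_RANK:
            ids_by_class[cls].append(vid)
            col_by_class[cls].append(j)

    retained: dict[str, list[str]] = {"plof": list(ids_by_class["plof"])}
    for cls in ("moderate", "low", "intergenic"):
        higher_cols = [c for hc, cols in col_by_class.items()
                       if CLASS_RANK[hc] > CLASS_RANK[cls] for c in cols]
        own_cols = col_by_class[cls]
        if not own_cols:
            retained[cls] = []
            continue
        if not higher_cols:
            retained[cls] = list(ids_by_class[cls])
            continue
        A = X[:, own_cols]
        B = X[:, higher_cols]
        co = (A.T @ B).toarray() / total  # p_AB
        pa = p[own_cols][:, None]
        pb = p[higher_cols][None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (co - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb))
        r2 = np.nan_to_num(r2, nan=0.0)
        keep = (r2 <= r2_threshold).all(axis=1)
        retained[cls] = [vid for vid, k in zip(ids_by_class[cls], keep) if k]
    return retained


# ---------------------------------------------------------------------------
# intergenic distance sets


def classify_intergenic_by_distance(variants: pd.DataFrame,
                                    gene_intervals: pd.DataFrame,
                                    distances: tuple[int, ...] = INTERGENIC_DISTANCES
                                    ) -> pd.DataFrame:
    """Assign intergenic variants to minimum-distance sets.

    ``variants`` needs columns (variant_id, chrom, pos) with 1-based VCF
    positions; ``gene_intervals`` columns (chrom, start, end) in 0-based
    half-open BED convention. A variant belongs to the distance-d set iff
    its position is more than d bases from every genic interval. Returns a
    frame indexed by variant_id with the distance to the nearest gene and
    one boolean column ``gt_<d>`` per requested distance.
    """
    if (gene_intervals["end"] <= gene_intervals["start"]).any():
        raise ValueError("malformed gene interval: end must exceed start")
    by_chrom = {}
    for chrom, grp in gene_intervals.groupby("chrom"):
        ivs = grp.sort_values("start")[["start", "end"]].to_numpy(dtype=np.int64)
        # merge overlaps so searchsorted distances are well defined
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged, dtype=np.int64)
        by_chrom[chrom] = (arr[:, 0], arr[:, 1])

    pos0 = variants["pos"].to_numpy(dtype=np.int64) - 1  # 0-based position
    chroms = variants["chrom"].to_numpy()
    dist = np.full(len(variants), np.inf)
    for chrom, (starts, ends) in by_chrom.items():
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        x = pos0[sel]
        k = np.searchsorted(starts, x, side="right")
        km1 = np.maximum(k - 1, 0)
        inside = (k > 0) & (x < ends[km1])
        left = np.where(k > 0, x - (ends[km1] - 1), np.inf)
        kk = np.minimum(k, len(starts) - 1)
        right = np.where(k < len(starts), starts[kk] - x, np.inf)
        dist[sel] = np.where(inside, 0.0, np.minimum(left, right))

    out = pd.DataFrame({"variant_id": variants["variant_id"].to_numpy(),
                        "distance": dist}).set_index("variant_id")
    for d in distances:
        out[f"gt_{d}"] = out["distance"] > d
    return out


# ---------------------------------------------------------------------------
# power analysis


def power_two_proportions(p1: float, p2: float, n_per_group: float,
                          alpha: float = 0.05) -> float:
    """Classical two-sample proportions power with pooled-variance null.

    power = Phi( (|p1 - p2| sqrt(n) - z_{1-a/2} sqrt(2 pbar qbar))
                 / sqrt(p1 q1 + p2 q2) )
    """
    for p in (p1, p2):
        if not 0.0 < p < 1.0:
            raise ValueError("proportions must lie strictly in (0, 1)")
    if n_per_group <= 0:
        raise ValueError("n_per_group must be positive")
    pbar = (p1 + p2) / 2.0
    qbar = 1.0 - pbar
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    num = abs(p1 - p2) * math.sqrt(n_per_group) - z * math.sqrt(2 * pbar * qbar)
    den = math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))
    return float(stats.norm.cdf(num / den))


def solve_n_two_proportions(p1: float, p2: float, alpha: float = 0.05,
                            power: float = 0.8) -> float:
    """Per-group sample size at which the two-proportion test reaches ``power``."""
    if not 0.0 < power < 1.0:
        raise ValueError("power must lie in (0, 1)")
    if p1 == p2:
        raise ValueError("p1 and p2 must differ")

    def gap(n: float) -> float:
        return power_two_proportions(p1, p2, n, alpha) - power

    lo, hi = 2.0, 4.0
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e15:
            raise RuntimeError("sample size search failed to bracket")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-9, rtol=1e-12))


# ---------------------------------------------------------------------------
# inbreeding (validation plumbing)


def estimate_inbreeding(panel: CohortPanel) -> pd.DataFrame:
    """Method-of-moments per-individual inbreeding coefficient.

    f_i = 1 - (observed het count) / (expected het count sum_v 2 p_v q_v),
    computed against the individual's own population frequencies. Intended
    to validate simulated cohorts; needs a reasonable number (>= ~100) of
    polymorphic variants to be stable.
    """
    frames = []
    for pop in panel.populations:
        n = pop.n_individuals
        alt = pop.alt_haplotype_counts()
        p = alt / (2.0 * n)
        poly = (p > 0) & (p < 1)
        if not poly.any():
            raise ValueError(f"population {pop.name!r} has no polymorphic variants")
        cols = np.flatnonzero(poly)
        A = pop.hap_a[:, cols]
        B = pop.hap_b[:, cols]
        a_rows = np.asarray(A.sum(axis=1)).ravel()
        b_rows = np.asarray(B.sum(axis=1)).ravel()
        hom_rows = np.asarray(A.multiply(B).sum(axis=1)).ravel()
        het = a_rows + b_rows - 2 * hom_rows
        expected = float(np.sum(2.0 * p[cols] * (1.0 - p[cols])))
        f_hat = 1.0 - het / expected
        frames.append(pd.DataFrame({
            "population": pop.name,
            "individual": pop.individual_ids,
            "f_hat": f_hat,
        }))
    return pd.concat(frames, ignore_index=True)
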