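"""Empirical FDR calibration against intergenic variants.

Intergenic variants have the lowest predicted functional impact, so the
fraction of them showing a strong deficit of homozygosity estimates how
often a deficit arises by chance (or through genotyping/imputation
artifacts, which do not preferentially hit protein-altering variants).
Within bins of expected homozygote count,

    FDR = f_intergenic / f_pav,        PPV = 1 - FDR,

where f_pav is the strong-deficit fraction among a protein-altering class.
Confidence intervals for the FDR treat the two deficit counts as
independent Poisson rates; see :func:`rate_ratio_ci`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: half-open expected-count bins of the calibration
BIN_EDGES = (0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 13.0, 250.0, math.inf)

RATE_RATIO_METHOD = "conditional-binomial exact (Clopper-Pearson)"


def bin_labels() -> list[str]:
    out = []
    for lo, hi in zip(BIN_EDGES[:-1], BIN_EDGES[1:]):
        hi_s = "inf" if math.isinf(hi) else f"{hi:g}"
        out.append(f"[{lo:g},{hi_s})")
    return out


def bin_by_expected_count(lam) -> np.ndarray:
    """Bin index of each tested expected count (half-open bins).

    Raises on lambda <= 0.5: such variants are below the testing threshold
    and are never calibrated.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if (lam <= 0.5).any():
        raise ValueError("expected count must exceed 0.5 to be binned")
    idx = np.searchsorted(np.asarray(BIN_EDGES), lam, side="right") - 1
    return idx


def deficit_fraction(strong: np.ndarray) -> tuple[int, int, float]:
    """(n_deficit, n_tested, fraction) for a set of tested variants.

    Raises on an empty set: an empty class-bin is unavailable, not zero.
    """
    strong = np.asarray(strong, dtype=bool)
    n_tested = strong.size
    if n_tested == 0:
        raise ValueError("no tested variants in this class/bin")
    n_def = int(strong.sum())
    return n_def, n_tested, n_def / n_tested


def compute_fdr(f_intergenic: float, f_pav: float) -> tuple[float, float]:
    """FDR = f_intergenic / f_pav and PPV = 1 - FDR (FDR reported uncapped)."""
    if f_pav <= 0:
        raise ValueError("f_pav must be positive: FDR unavailable")
    fdr = f_intergenic / f_pav
    return fdr, 1.0 - fdr


def rate_ratio_ci(x1: int, n1: float, x2: int, n2: float,
                  level: float = 0.95) -> tuple[float, float]:
    """Exact CI for the ratio of two independent Poisson rates (x1/n1)/(x2/n2).

    Conditions on the total x1 + x2 — given the total, x1 is binomial with
    success probability theta = (r1 n1)/(r1 n1 + r2 n2) — maps an exact
    Clopper-Pearson interval for theta through theta/(1-theta) * n2/n1.
    """
    if x1 < 0 or x2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("exposures must be positive")
    if x1 + x2 == 0:
        raise ValueError("both counts zero: ratio unavailable")
    total = x1 + x2
    alpha = 1.0 - level
    lo_t = 0.0 if x1 == 0 else float(stats.beta.ppf(alpha / 2, x1, total - x1 + 1))
    hi_t = 1.0 if x1 == total else float(stats.beta.ppf(1 - alpha / 2, x1 + 1,
                                                        total - x1))
    scale = n2 / n1
    lo = 0.0 if lo_t == 0.0 else lo_t / (1.0 - lo_t) * scale
    hi = math.inf if hi_t == 1.0 else hi_t / (1.0 - hi_t) * scale
    return lo, hi


@dataclass(frozen=True)
class FDRBin:
    """Calibration summary for one expected-count bin and one variant class."""

    lo: float
    hi: float
    n_deficit_pav: int
    n_tested_pav: int
    n_deficit_intergenic: int
    n_tested_intergenic: int
    f_pav: float
    f_intergenic: float
    fdr: float | None
    ppv: float | None
    ci: tuple[float, float] | None

    @property
    def fdr_capped(self) -> float | None:
        return None if self.fdr is None else min(self.fdr, 1.0)


def calibrate_fdr(results: pd.DataFrame,
                  pav_class: str = "plof",
                  intergenic_class: str = "intergenic",
                  level: float = 0.95) -> pd.DataFrame:
    """Per-bin FDR calibration of one protein-altering class.

    ``results`` is a deficit-scan frame with columns lambda, tested,
    strong_deficit and impact_class. Returns one row per expected-count bin
    with class counts, deficit fractions, FDR (uncapped and capped for
    display), PPV and the rate-ratio CI; bins where either class is empty or
    f_pav is zero carry NaN (unavailable), never an implicit zero.
    """
    tested = results[results["tested"]].copy()
    tested["bin"] = bin_by_expected_count(tested["lambda"].to_numpy())
    rows = []
    for b, (lo, hi) in enumerate(zip(BIN_EDGES[:-1], BIN_EDGES[1:])):
        sub = tested[tested["bin"] == b]
        pav = sub[sub["impact_class"] == pav_class]
        inter = sub[sub["impact_class"] == intergenic_class]
        row = {
            "bin": bin_labels()[b], "lo": lo, "hi": hi,
            "n_deficit_pav": int(pav["strong_deficit"].sum()),
            "n_tested_pav": len(pav),
            "n_deficit_intergenic": int(inter["strong_deficit"].sum()),
            "n_tested_intergenic": len(inter),
            "f_pav": np.nan, "f_intergenic": np.nan,
            "fdr": np.nan, "fdr_capped": np.nan, "ppv": np.nan,
            "ci_low": np.nan, "ci_high": np.nan,
        }
        if len(pav):
            row["f_pav"] = row["n_deficit_pav"] / row["n_tested_pav"]
        if len(inter):
            row["f_intergenic"] = row["n_deficit_intergenic"] / row["n_tested_intergenic"]
        if len(pav) and len(inter) and row["f_pav"] > 0:
            fdr, ppv = compute_fdr(row["f_intergenic"], row["f_pav"])
            row["fdr"], row["ppv"] = fdr, ppv
            row["fdr_capped"] = min(fdr, 1.0)
            if row["n_deficit_intergenic"] + row["n_deficit_pav"] > 0:
                lo_ci, hi_ci = rate_ratio_ci(
                    row["n_deficit_intergenic"], row["n_tested_intergenic"],
                    row["n_deficit_pav"], row["n_tested_pav"], level=level)
                row["ci_low"], row["ci_high"] = lo_ci, hi_ci
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["ci_method"] = RATE_RATIO_METHOD
    out.attrs["pav_class"] = pav_class
    return out


def pooled_fdr(results: pd.DataFrame,
               pav_class: str = "plof",
               intergenic_class: str = "intergenic",
               min_lambda: float | None = None,
               max_lambda: float | None = None) -> float:
    """Single FDR estimate pooled over a lambda range (diagnostics/validation)."""
    tested = results[results["tested"]]
    if min_lambda is not None:
        tested = tested[tested["lambda"] >= min_lambda]
    if max_lambda is not None:
        tested = tested[tested["lambda"] < max_lambda]
    pav = tested[tested["impact_class"] == pav_class]
    inter = tested[tested["impact_class"] == intergenic_class]
    _, _, f_pav = deficit_fraction(pav["strong_deficit"].to_numpy())
    _, _, f_int = deficit_fraction(inter["strong_deficit"].to_numpy())
    fdr, _ = compute_fdr(f_int, f_pav)
    return fdr
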