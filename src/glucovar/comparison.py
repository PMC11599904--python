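"""Standardized allele-frequency contrasts between a reference cohort and panels.

To compare cohorts of very different sizes on an equal footing, each
population's allele frequency at a variant is converted to integer "yes"
(alternate) and "no" (reference) allele counts out of a fixed total — by
default 118, the diploid allele count of a 59-individual reference cohort:

    yes = round_half_up(AF × 118),   no = 118 − yes.

Each (variant, comparator) pair then gets a two-sided Fisher exact test on
the standardized 2×2 table, a Hochberg step-up adjustment across the
comparisons, and a direction sign: sign(AF_reference − AF_comparator).
Variants significant in at least three comparisons and carrying a High or
Moderate predicted impact make the primary report; everything else goes to
a supplementary list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AlleleFrequencyEntry",
    "ComparisonMatrix",
    "allele_frequency",
    "allele_frequency_table",
    "standardize_counts",
    "fisher_exact_two_sided",
    "hochberg_adjust",
    "compare_reference_to_panels",
    "select_reportable",
]

logger = logging.getLogger(__name__)

#: Relative tolerance for hypergeometric probability ties in the two-sided
#: Fisher test (tables whose probability exceeds the observed one by less
#: than this factor still count as "as extreme").
TIE_RTOL = 1e-7


@dataclass
class AlleleFrequencyEntry:
    """Allele counts and frequency for one variant in one population."""

    variant: str
    population: str
    alt_count: int
    called_alleles: int

    def __post_init__(self) -> None:
        if self.called_alleles <= 0:
            raise ValueError(
                f"no called alleles for {self.variant} in {self.population}"
            )
        if not 0 <= self.alt_count <= self.called_alleles:
            raise ValueError("alt_count must lie in [0, called_alleles]")

    @property
    def af(self) -> float:
        return self.alt_count / self.called_alleles


def allele_frequency(dosages, population: str, variant: str = "variant") -> AlleleFrequencyEntry:
    """Allele counting over diploid dosages with missing entries (NaN).

    alt_count is the sum of called dosages; called_alleles is twice the
    number of called samples.  All-missing input raises.
    """
    d = np.asarray(dosages, dtype=float)
    called = ~np.isnan(d)
    if not called.any():
        raise ValueError(f"no called alleles for {variant} in {population}")
    return AlleleFrequencyEntry(
        variant=variant,
        population=population,
        alt_count=int(d[called].sum()),
        called_alleles=2 * int(called.sum()),
    )


def allele_frequency_table(gm) -> pd.DataFrame:
    """Per-(variant, population) allele counts for a whole genotype matrix.

    Rows where a population has no called genotype at a variant are
    omitted (downstream consumers treat absence as "unassessable").
    """
    rows = []
    for pop, idx in gm.population_index().items():
        block = gm.dosage[idx]
        called = ~np.isnan(block)
        alt = np.nansum(block, axis=0)
        n_called = called.sum(axis=0)
        for j, vid in enumerate(gm.variant_ids):
            if n_called[j] == 0:
                continue
            rows.append(
                {
                    "variant": vid,
                    "population": pop,
                    "alt_count": int(alt[j]),
                    "called_alleles": 2 * int(n_called[j]),
                    "af": alt[j] / (2 * n_called[j]),
                }
            )
    return pd.DataFrame(rows)


def standardize_counts(af: float, total_alleles: int = 118) -> tuple[int, int]:
    """Convert a frequency to integer yes/no allele counts out of a fixed total.

    yes = round-half-up(af × total); no = total − yes, so the pair always
    conserves the standardization total.
    """
    if not 0 <= af <= 1:
        raise ValueError(f"allele frequency must lie in [0, 1], got {af}")
    if total_alleles < 2:
        raise ValueError("total_alleles must be >= 2")
    yes = int(math.floor(af * total_alleles + 0.5))
    return yes, total_alleles - yes


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2×2 table of nonnegative integers.

    Probability-mass rule: with all margins fixed, sum the hypergeometric
    probabilities of every table whose probability is at most that of the
    observed table (within relative tolerance ``TIE_RTOL`` for float ties).
    """
    (a, b), (c, d) = (
        (int(table[0][0]), int(table[0][1])),
        (int(table[1][0]), int(table[1][1])),
    )
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be nonnegative")
    N = a + b + c + d
    K = a + b  # row-1 margin
    n = a + c  # column-1 margin
    if N == 0 or K in (0, N) or n in (0, N):
        return 1.0  # degenerate margin: only one table possible
    lo = max(0, n - (N - K))
    hi = min(n, K)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + TIE_RTOL)].sum())
    return min(p, 1.0)


def hochberg_adjust(pvals) -> np.ndarray:
    """Hochberg step-up adjusted p-values, in the original input order.

    With ascending order statistics p(1) ≤ … ≤ p(m), the adjusted value at
    rank i is min over j ≥ i of (m−j+1)·p(j), capped at 1.  Delegates to
    statsmodels' Simes–Hochberg implementation.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="simes-hochberg")[1]


@dataclass
class ComparisonMatrix:
    """Long-form comparison results plus the reference label.

    ``data`` has one row per (variant, comparator): allele frequencies and
    standardized counts on both sides, raw and Hochberg-adjusted p, and the
    direction sign ("+" reference higher, "−" lower, "0" equal).
    ``impact`` maps variant → impact tier when annotations were supplied.
    """

    data: pd.DataFrame
    reference: str
    impact: dict[str, str] | None = None
    hochberg_scope: str = "per_variant"

    def to_wide(self) -> pd.DataFrame:
        """One row per variant, p/adjusted-p/sign columns per comparator."""
        wide = self.data.pivot(
            index="variant", columns="comparator", values=["p_raw", "p_adj", "sign"]
        )
        wide.columns = [f"{stat}_{comp}" for stat, comp in wide.columns]
        wide = wide.reset_index()
        if self.impact:
            wide.insert(1, "impact", wide["variant"].map(self.impact))
        return wide


def compare_reference_to_panels(
    af_table: pd.DataFrame,
    reference: str,
    comparators: list[str],
    total_alleles: int = 118,
    hochberg_scope: str = "per_variant",
    impact: dict[str, str] | None = None,
) -> ComparisonMatrix:
    """Fisher-compare the reference cohort to each panel, variant by variant.

    Both sides of every 2×2 table are standardized to ``total_alleles``
    through the same rounding rule.  ``hochberg_scope`` picks the family
    for the step-up adjustment: ``per_variant`` (default; a variant's
    comparisons form one family) or ``global`` (all tests at once).
    Variants missing the reference or any comparator entry are skipped with
    a warning.
    """
    if hochberg_scope not in ("per_variant", "global"):
        raise ValueError("hochberg_scope must be 'per_variant' or 'global'")
    rows = []
    for vid, grp in af_table.groupby("variant", sort=False):
        pops = grp.set_index("population")
        needed = [reference, *comparators]
        if any(p not in pops.index for p in needed):
            logger.warning("variant %s lacks some population entries; skipped", vid)
            continue
        af_ref = pops.loc[reference, "alt_count"] / pops.loc[reference, "called_alleles"]
        yes_ref, no_ref = standardize_counts(af_ref, total_alleles)
        for comp in comparators:
            af_cmp = pops.loc[comp, "alt_count"] / pops.loc[comp, "called_alleles"]
            yes_cmp, no_cmp = standardize_counts(af_cmp, total_alleles)
            p = fisher_exact_two_sided([[yes_ref, no_ref], [yes_cmp, no_cmp]])
            sign = "0" if af_ref == af_cmp else ("+" if af_ref > af_cmp else "-")
            rows.append(
                {
                    "variant": vid,
                    "comparator": comp,
                    "af_ref": af_ref,
                    "af_cmp": af_cmp,
                    "yes_ref": yes_ref,
                    "no_ref": no_ref,
                    "yes_cmp": yes_cmp,
                    "no_cmp": no_cmp,
                    "p_raw": p,
                    "sign": sign,
                }
            )
    data = pd.DataFrame(rows)
    if not data.empty:
        if hochberg_scope == "per_variant":
            data["p_adj"] = data.groupby("variant", sort=False)["p_raw"].transform(
                lambda s: hochberg_adjust(s.values)
            )
        else:
            data["p_adj"] = hochberg_adjust(data["p_raw"].values)
    else:
        data = pd.DataFrame(
            columns=[
                "variant", "comparator", "af_ref", "af_cmp", "yes_ref", "no_ref",
                "yes_cmp", "no_cmp", "p_raw", "sign", "p_adj",
            ]
        )
    return ComparisonMatrix(
        data=data, reference=reference, impact=impact, hochberg_scope=hochberg_scope
    )


def select_reportable(
    matrix: ComparisonMatrix,
    alpha: float = 0.05,
    min_populations: int = 3,
    tiers: tuple[str, ...] = ("High", "Moderate"),
    use_adjusted: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split variants into the primary report and the supplementary list.

    A variant is reportable iff it is significant (p < alpha, raw by
    default) in at least ``min_populations`` of its comparisons AND its
    impact tier is in ``tiers``.  Returns ``(reported, supplementary)``
    frames, each with the per-variant significant-comparison count.
    """
    if matrix.data.empty:
        empty = pd.DataFrame(columns=["variant", "impact", "n_significant"])
        return empty, empty.copy()
    col = "p_adj" if use_adjusted else "p_raw"
    counts = (
        (matrix.data[col] < alpha)
        .groupby(matrix.data["variant"], sort=False)
        .sum()
        .rename("n_significant")
    )
    out = counts.reset_index()
    impact = matrix.impact or {}
    out["impact"] = out["variant"].map(impact)
    reportable = (out["n_significant"] >= min_populations) & out["impact"].isin(tiers)
    return (
        out[reportable].reset_index(drop=True),
        out[~reportable].reset_index(drop=True),
    )
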