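"""Variant inclusion filters and group-exclusive variant detection.

Two stages.  First, panel-level inclusion: a genotype counts as *called*
when its read depth reaches a minimum (default 10 reads); a sample is a
*carrier* when called with at least one alternate allele; a variant is
retained when it has enough carriers in the study cohort (default 10) or —
the override — when it is novel, i.e. absent from previously reported
populations.  Second, exclusivity: a variant is private to a study group
when it carries alternate alleles there but shows zero alternate alleles in
every reference panel that actually has called alleles at that site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import classify_impact
from .io import GenotypeMatrix

__all__ = [
    "SelectionCriteria",
    "ExclusiveVariantReport",
    "apply_inclusion_filters",
    "find_exclusive_variants",
]


@dataclass
class SelectionCriteria:
    """Inclusion thresholds for the panel-level variant filter."""

    min_coverage: int = 10
    min_carriers: int = 10
    cohort_size: int = 64
    novel_overrides: bool = True

    def __post_init__(self) -> None:
        if self.min_coverage < 0:
            raise ValueError("min_coverage must be >= 0")
        if self.min_carriers < 1:
            raise ValueError("min_carriers must be >= 1")


def apply_inclusion_filters(
    genotypes: GenotypeMatrix,
    coverage: np.ndarray | None = None,
    criteria: SelectionCriteria | None = None,
    novelty: np.ndarray | None = None,
) -> list[str]:
    """Return the variant ids passing the carrier-count / novelty filter.

    Parameters
    ----------
    coverage
        Optional samples × variants read-depth matrix.  When absent, a
        genotype is treated as called iff it is non-missing (the VCF
        ``./.`` convention stands in for below-threshold depth).
    novelty
        Optional per-variant booleans; novel variants are retained
        regardless of carrier count when ``criteria.novel_overrides``.

    The retained list preserves input variant order.  Lowering
    ``min_carriers`` can only grow the retained set (monotone filter).
    """
    if criteria is None:
        criteria = SelectionCriteria()
    called = ~genotypes.missing_mask
    if coverage is not None:
        coverage = np.asarray(coverage)
        if coverage.shape != genotypes.dosage.shape:
            raise ValueError(
                f"coverage shape {coverage.shape} does not match genotypes "
                f"{genotypes.dosage.shape}"
            )
        called &= coverage >= criteria.min_coverage
    if novelty is None:
        novelty = np.zeros(genotypes.n_variants, dtype=bool)
    else:
        novelty = np.asarray(novelty, dtype=bool)
        if novelty.shape != (genotypes.n_variants,):
            raise ValueError("one novelty flag required per variant")

    carrier = called & (np.nan_to_num(genotypes.dosage, nan=0.0) >= 1)
    carriers_per_variant = carrier.sum(axis=0)
    keep = carriers_per_variant >= criteria.min_carriers
    if criteria.novel_overrides:
        keep |= novelty
    return [vid for vid, k in zip(genotypes.variant_ids, keep) if k]


@dataclass
class ExclusiveVariantReport:
    """Variants private to each target group.

    ``per_group`` maps group label → frame of its exclusive variants with
    the group allele frequency and (when a consequence is available) the
    impact tier.  ``union_count`` deduplicates across groups by
    (chrom, pos, ref, alt) — or by variant id when coordinates are absent.
    ``unassessable`` lists variants where some reference panel had zero
    called alleles, so exclusivity could not be established.
    """

    per_group: dict[str, pd.DataFrame]
    union_count: int
    union_keys: list = field(default_factory=list)
    unassessable: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for group, tab in self.per_group.items():
            part = tab.copy()
            part.insert(0, "group", group)
            parts.append(part)
        if not parts:
            return pd.DataFrame(columns=["group", "variant", "af"])
        return pd.concat(parts, ignore_index=True)


def find_exclusive_variants(
    af_table: pd.DataFrame,
    target_groups: list[str],
    reference_panels: list[str],
) -> ExclusiveVariantReport:
    """Scan a per-population allele table for group-private variants.

    ``af_table`` has one row per (variant, population) with columns
    ``variant``, ``population``, ``alt_count``, ``called_alleles`` and
    optionally ``chrom``/``pos``/``ref``/``alt``, ``gene``,
    ``consequence``.  A variant is exclusive to target group *g* iff its
    alternate count is positive in *g* and zero — with called alleles — in
    every reference panel.  Variants lacking a row for some reference
    panel, or where a panel has zero called alleles, are flagged
    unassessable and never reported.
    """
    required = {"variant", "population", "alt_count", "called_alleles"}
    missing = required - set(af_table.columns)
    if missing:
        raise ValueError(f"af_table missing columns {sorted(missing)}")

    have_coords = {"chrom", "pos", "ref", "alt"} <= set(af_table.columns)
    by_variant = dict(tuple(af_table.groupby("variant", sort=False)))

    per_group: dict[str, list[dict]] = {g: [] for g in target_groups}
    unassessable: list[str] = []
    union_keys: list = []
    seen = set()

    for vid, rows in by_variant.items():
        pop_rows = rows.set_index("population")
        ok = True
        for panel in reference_panels:
            if panel not in pop_rows.index or pop_rows.loc[panel, "called_alleles"] <= 0:
                ok = False
                break
        if not ok:
            unassessable.append(vid)
            continue
        if any(pop_rows.loc[panel, "alt_count"] > 0 for panel in reference_panels):
            continue  # observed in a reference panel: not exclusive anywhere
        for group in target_groups:
            if group not in pop_rows.index:
                continue
            grow = pop_rows.loc[group]
            if grow["alt_count"] > 0 and grow["called_alleles"] > 0:
                entry = {
                    "variant": vid,
                    "af": grow["alt_count"] / grow["called_alleles"],
                }
                if "gene" in pop_rows.columns:
                    entry["gene"] = grow["gene"]
                if "consequence" in pop_rows.columns and pd.notna(grow["consequence"]):
                    entry["consequence"] = grow["consequence"]
                    entry["impact"] = classify_impact(grow["consequence"])
                per_group[group].append(entry)
                key = (
                    (grow["chrom"], grow["pos"], grow["ref"], grow["alt"])
                    if have_coords
                    else vid
                )
                if key not in seen:
                    seen.add(key)
                    union_keys.append(key)

    frames = {
        g: pd.DataFrame(items)
        if items
        else pd.DataFrame(columns=["variant", "af"])
        for g, items in per_group.items()
    }
    return ExclusiveVariantReport(
        per_group=frames,
        union_count=len(union_keys),
        union_keys=union_keys,
        unassessable=unassessable,
    )
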