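"""Variant consequence classification and annotation summaries.

Predicted consequence labels (SnpEff-style) are mapped onto the four
standard impact tiers — High, Moderate, Low, Modifier — and whole panels of
annotated variants are tabulated by mutation type, genomic region,
consequence and impact, with percentages rounded half-up to one decimal.

The consequence set is closed: eleven categories covering coding changes
(synonymous, non-synonymous, stop gain), splice-region combinations,
untranslated regions, intronic/intragenic variants and two rarer classes
(protein structural interaction locus, "next protein").  The tier mapping
is exhaustive over this set and raises on anything else rather than
defaulting silently.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CONSEQUENCE_CATEGORIES",
    "CONSEQUENCE_IMPACT",
    "IMPACT_TIERS",
    "VariantRecord",
    "AnnotationSummary",
    "normalize_consequence",
    "classify_impact",
    "summarize_annotations",
    "impact_counts_from_consequence_counts",
]

IMPACT_TIERS = ("High", "Moderate", "Low", "Modifier")

#: The closed set of recognised consequence categories (canonical spelling).
CONSEQUENCE_CATEGORIES = (
    "intragenic",
    "intronic",
    "next protein",
    "non synonymous coding",
    "non synonymous coding + splice site region",
    "protein structural interaction locus",
    "splice site region + intron",
    "synonymous coding",
    "stop gained",
    "3'UTR",
    "5'UTR",
)

# Spelling variants seen in the wild ("intron" vs "intronic", "stop codon"
# vs "stop gained", primed UTR labels) fold onto the canonical names.
_ALIASES = {
    "intron": "intronic",
    "stop codon": "stop gained",
    "3'utr prime": "3'UTR",
    "5'utr prime": "5'UTR",
    "3' utr": "3'UTR",
    "5' utr": "5'UTR",
}

#: Consequence → impact tier.  Exhaustive over CONSEQUENCE_CATEGORIES.
CONSEQUENCE_IMPACT = {
    "stop gained": "High",
    "protein structural interaction locus": "High",
    "non synonymous coding": "Moderate",
    "non synonymous coding + splice site region": "Moderate",
    "synonymous coding": "Low",
    "splice site region + intron": "Low",
    "next protein": "Low",
    "intronic": "Modifier",
    "intragenic": "Modifier",
    "3'UTR": "Modifier",
    "5'UTR": "Modifier",
}

# Consequence → broad genomic region used by the summary's region dimension.
_REGION_OF_CONSEQUENCE = {
    "non synonymous coding": "exon/CDS",
    "non synonymous coding + splice site region": "exon/CDS",
    "synonymous coding": "exon/CDS",
    "intronic": "intronic",
    "intragenic": "intragenic",
    "3'UTR": "3'UTR",
    "5'UTR": "5'UTR",
    "stop gained": "other",
    "protein structural interaction locus": "other",
    "splice site region + intron": "other",
    "next protein": "other",
}


def normalize_consequence(label: str) -> str:
    """Fold a consequence label onto its canonical spelling.

    Raises
    ------
    ValueError
        If the label is not one of the recognised categories.
    """
    key = " ".join(str(label).strip().lower().split())
    key = _ALIASES.get(key, key)
    for cat in CONSEQUENCE_CATEGORIES:
        if key == cat.lower():
            return cat
    raise ValueError(f"unknown consequence category: {label!r}")


def classify_impact(consequence: str) -> str:
    """Return the impact tier (High/Moderate/Low/Modifier) for a consequence.

    The mapping is total on the closed category set; unknown categories
    raise instead of being assigned a default tier.
    """
    return CONSEQUENCE_IMPACT[normalize_consequence(consequence)]


@dataclass
class VariantRecord:
    """One biallelic variant with its annotation.

    ``mutation_type`` and ``region`` are derived from the alleles and the
    consequence when not given explicitly: a variant is an SNV iff both
    alleles are single bases, and the region follows the consequence
    (coding consequences sit in exon/CDS, splice/stop/structural classes in
    "other").
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    rsid: str | None = None
    mutation_type: str = field(default="")
    region: str = field(default="")

    def __post_init__(self) -> None:
        self.consequence = normalize_consequence(self.consequence)
        derived = "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"
        if not self.mutation_type:
            self.mutation_type = derived
        elif self.mutation_type != derived:
            raise ValueError(
                f"mutation_type {self.mutation_type!r} inconsistent with alleles "
                f"{self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )
        if not self.region:
            self.region = _REGION_OF_CONSEQUENCE[self.consequence]

    @property
    def impact(self) -> str:
        return classify_impact(self.consequence)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Deduplication key (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 0.25 → 0.3 at 1 digit, unlike banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _percent(count: int, total: int) -> float:
    # quantize the exact ratio, not a float approximation of it
    q = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass
class AnnotationSummary:
    """Per-dimension category counts with percentages of the panel total."""

    total: int
    tables: dict[str, pd.DataFrame]
    percent_defined: bool = True

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one long table: dimension, category, count, percent."""
        parts = []
        for dim, tab in self.tables.items():
            part = tab.copy()
            part.insert(0, "dimension", dim)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


def summarize_annotations(records: Iterable[VariantRecord]) -> AnnotationSummary:
    """Tabulate a variant panel by mutation type, region, consequence, impact.

    Percentages are 100·count/total rounded half-up to one decimal.  An
    empty panel yields zero counts with ``percent_defined=False`` rather
    than a division error.
    """
    records = list(records)
    total = len(records)
    dims = {
        "mutation_type": [r.mutation_type for r in records],
        "region": [r.region for r in records],
        "consequence": [r.consequence for r in records],
        "impact": [r.impact for r in records],
    }
    tables = {}
    for dim, labels in dims.items():
        counts = Counter(labels)
        rows = [
            {
                "category": cat,
                "count": n,
                "percent": _percent(n, total) if total else float("nan"),
            }
            for cat, n in sorted(counts.items())
        ]
        tables[dim] = pd.DataFrame(rows, columns=["category", "count", "percent"])
    return AnnotationSummary(total=total, tables=tables, percent_defined=total > 0)


def impact_counts_from_consequence_counts(
    consequence_counts: Mapping[str, int]
) -> dict[str, int]:
    """Aggregate per-consequence counts into the four impact tiers."""
    out = {tier: 0 for tier in IMPACT_TIERS}
    for consequence, n in consequence_counts.items():
        out[classify_impact(consequence)] += int(n)
    return out
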