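"""Packaged reference tables from the comparative exome study this pipeline models.

Four hand-transcribed summary tables ship as TSV resources:

* ``table1`` — annotation counts for the 253-variant panel, by mutation
  type, region, consequence and impact tier;
* ``table2`` — variants private to the two indigenous study cohorts
  (group, coordinates, gene, consequence, impact, in-group frequency);
* ``table3`` — the frequency-comparison matrix: per variant, an impact
  label plus a p-value and a direction sign for each of the six
  reference-vs-panel contrasts;
* ``table4`` — pairwise PERMANOVA statistics (R², pseudo-F, p) for the
  eleven population pairs.

These are test oracles and worked-example inputs, not outputs of this
package.  ``load_study_table`` is the single entry point.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "POPULATION_SIZES",
    "TABLE3_COMPARATORS",
    "REFERENCE_POPULATION",
    "FixtureSet",
    "load_study_table",
    "load_fixture_set",
    "table2_as_af_table",
    "table3_as_comparison_frame",
]

#: Cohort sizes: the two indigenous study groups and the five continental
#: reference panels (1000 Genomes phase 3).
POPULATION_SIZES = {
    "IND-LLA": 5,
    "IND-NLLA": 59,
    "AFR": 661,
    "AMR": 347,
    "EAS": 504,
    "EUR": 503,
    "SAS": 489,
}

#: The comparison matrix contrasts the reference cohort against these six.
REFERENCE_POPULATION = "IND-NLLA"
TABLE3_COMPARATORS = ("IND-LLA", "AFR", "AMR", "EAS", "EUR", "SAS")

_NAMES = ("table1", "table2", "table3", "table4")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("glucovar.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_study_table(name: str):
    """Load one packaged reference table.

    Parameters
    ----------
    name
        One of ``table1``, ``table2``, ``table3``, ``table4``.

    Returns
    -------
    ``table1`` → dict of dimension → {category: count};
    the others → a pandas DataFrame in transcription order.
    """
    if name not in _NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {_NAMES}")
    df = _read(name)
    if name == "table1":
        out: dict[str, dict[str, int]] = {}
        for dim, part in df.groupby("dimension", sort=False):
            out[dim] = dict(zip(part["category"], part["count"].astype(int)))
        return out
    return df


@dataclass
class FixtureSet:
    """All four reference tables, loaded together."""

    table1_counts: dict
    table2_variants: pd.DataFrame
    table3_matrix: pd.DataFrame
    table4_rows: pd.DataFrame


def load_fixture_set() -> FixtureSet:
    return FixtureSet(
        table1_counts=load_study_table("table1"),
        table2_variants=load_study_table("table2"),
        table3_matrix=load_study_table("table3"),
        table4_rows=load_study_table("table4"),
    )


def table2_as_af_table(reference_panels=("AFR", "AMR", "EAS", "EUR", "SAS")) -> pd.DataFrame:
    """Recast the group-private variant table as a per-population allele table.

    Each listed variant gets a nonzero alternate count in its own group
    (back-computed from the printed in-group frequency and the group's
    allele total, at least 1) and an explicit zero count with called
    alleles in every reference panel — the configuration the exclusivity
    scan expects as input.
    """
    t2 = load_study_table("table2")
    group_alleles = {"INDG-LLA": 10, "INDG-NLLA": 118}
    rows = []
    for _, rec in t2.iterrows():
        vid = f"{rec['chrom']}:{rec['pos']}:{rec['ref']}:{rec['alt']}"
        called = group_alleles[rec["group"]]
        alt = max(1, int(np.floor(rec["frequency"] * called + 0.5)))
        rows.append(
            {
                "variant": vid,
                "population": rec["group"],
                "alt_count": alt,
                "called_alleles": called,
                "chrom": rec["chrom"],
                "pos": rec["pos"],
                "ref": rec["ref"],
                "alt": rec["alt"],
                "gene": rec["gene"],
                "consequence": rec["region_detail"],
            }
        )
        # absent from its sibling study group unless listed there too
        for panel in reference_panels:
            rows.append(
                {
                    "variant": vid,
                    "population": panel,
                    "alt_count": 0,
                    "called_alleles": 2 * POPULATION_SIZES[panel],
                    "chrom": rec["chrom"],
                    "pos": rec["pos"],
                    "ref": rec["ref"],
                    "alt": rec["alt"],
                    "gene": rec["gene"],
                    "consequence": rec["region_detail"],
                }
            )
    return pd.DataFrame(rows).drop_duplicates(subset=["variant", "population"])


def table3_as_comparison_frame() -> pd.DataFrame:
    """Reshape the comparison matrix to long form.

    Returns a frame with one row per (variant, comparator): columns
    ``variant``, ``gene``, ``impact``, ``comparator``, ``p_raw``, ``sign``.
    """
    t3 = load_study_table("table3")
    rows = []
    for _, rec in t3.iterrows():
        for comp in TABLE3_COMPARATORS:
            rows.append(
                {
                    "variant": rec["variant"],
                    "gene": rec["gene"],
                    "impact": rec["impact"],
                    "comparator": comp,
                    "p_raw": float(rec[f"p_{comp}"]),
                    "sign": rec[f"sign_{comp}"],
                }
            )
    return pd.DataFrame(rows)
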