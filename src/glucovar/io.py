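"""Genotype containers and file input/output.

The central in-memory container is :class:`GenotypeMatrix`: a samples ×
variants matrix of alternate-allele dosages (0/1/2) with missing genotypes
stored as NaN, per-sample population labels, and optional per-variant
coordinates (chrom, pos, ref, alt).

VCF reading and writing go through :mod:`pysam`; tabular side files
(population map, consequence annotations, result tables) are plain TSV
handled with pandas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "GenotypeMatrix",
    "read_vcf",
    "write_vcf",
    "read_population_map",
    "write_population_map",
    "read_annotations",
    "write_annotations",
    "read_novelty_flags",
    "write_table",
]

#: Canonical float format for every TSV this package writes.  A fixed format
#: keeps outputs byte-identical across runs with the same seed.
FLOAT_FORMAT = "%.10g"


@dataclass
class GenotypeMatrix:
    """Samples × variants alternate-allele dosage matrix.

    Parameters
    ----------
    dosage
        Float array of shape ``(n_samples, n_variants)`` holding 0, 1, 2 or
        NaN (missing genotype).
    sample_ids, variant_ids
        Row and column labels.
    populations
        Population label per sample, aligned with ``sample_ids``.
    variants
        Optional per-variant metadata frame indexed by ``variant_ids`` with
        at least columns ``chrom``, ``pos``, ``ref``, ``alt``.
    """

    dosage: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]
    populations: np.ndarray
    variants: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D samples × variants array")
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.variant_ids)} variants"
            )
        if len(self.populations) != len(self.sample_ids):
            raise ValueError("one population label required per sample")
        called = self.dosage[~np.isnan(self.dosage)]
        if called.size and not np.isin(called, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where a genotype is missing."""
        return np.isnan(self.dosage)

    def population_index(self) -> dict[str, np.ndarray]:
        """Map population label → integer sample indices, in first-seen order."""
        out: dict[str, np.ndarray] = {}
        for label in dict.fromkeys(self.populations):
            out[label] = np.flatnonzero(self.populations == label)
        return out

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosage=self.dosage[index],
            sample_ids=[self.sample_ids[i] for i in index],
            variant_ids=list(self.variant_ids),
            populations=self.populations[index],
            variants=self.variants,
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_FROM_DOSAGE = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a biallelic genotype matrix as an uncompressed VCF.

    Missing genotypes are written as ``./.``.  Variant coordinates come from
    ``gm.variants``; when absent, placeholder coordinates (contig "1",
    positions 1..n) are used.
    """
    variants = gm.variants
    if variants is None:
        variants = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, gm.n_variants + 1),
                "ref": "A",
                "alt": "C",
            },
            index=gm.variant_ids,
        )
    header = pysam.VariantHeader()
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")],
    )
    for contig in dict.fromkeys(variants["chrom"].astype(str)):
        header.contigs.add(contig)
    for sample in gm.sample_ids:
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, vid in enumerate(gm.variant_ids):
            row = variants.iloc[j]
            rec = vf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            rec.id = str(vid)
            for i, sample in enumerate(gm.sample_ids):
                value = gm.dosage[i, j]
                if math.isnan(value):
                    rec.samples[sample]["GT"] = (None, None)
                else:
                    rec.samples[sample]["GT"] = _GT_FROM_DOSAGE[int(value)]
            vf.write(rec)


def read_vcf(path: str | Path, population_map: pd.Series | None = None) -> GenotypeMatrix:
    """Read a biallelic diploid VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    population_map
        Optional sample → population mapping (e.g. from
        :func:`read_population_map`).  Samples absent from the map are
        labelled ``"unknown"``; with no map every sample is ``"unknown"``.
    """
    rows = []
    meta = []
    variant_ids: list[str] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"only biallelic records supported, got {rec.chrom}:{rec.pos}"
                )
            dos = np.full(len(samples), np.nan)
            for i, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                dos[i] = float(sum(1 for a in gt if a != 0))
            vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
            variant_ids.append(vid)
            rows.append(dos)
            meta.append((rec.chrom, rec.pos, rec.ref, rec.alts[0]))
    dosage = np.array(rows).T if rows else np.empty((len(samples), 0))
    variants = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"], index=variant_ids)
    if population_map is not None:
        populations = np.array(
            [population_map.get(s, "unknown") for s in samples], dtype=object
        )
    else:
        populations = np.array(["unknown"] * len(samples), dtype=object)
    return GenotypeMatrix(
        dosage=dosage,
        sample_ids=samples,
        variant_ids=variant_ids,
        populations=populations,
        variants=variants,
    )


# ---------------------------------------------------------------------------
# tabular side files
# ---------------------------------------------------------------------------

def read_population_map(path: str | Path) -> pd.Series:
    """Read a two-column sample → population TSV into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("population map needs two columns: sample, population")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def write_population_map(gm: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame({"sample": gm.sample_ids, "population": gm.populations}).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path: str | Path) -> pd.Series:
    """Read variant consequence annotations (variant_id, [gene,] consequence)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "consequence" not in df.columns:
        raise ValueError("annotation TSV needs a 'consequence' column")
    key = df.columns[0]
    return pd.Series(df["consequence"].values, index=df[key].values)


def write_annotations(
    variant_ids: list[str], consequences: list[str], path: str | Path,
    genes: list[str] | None = None,
) -> None:
    data = {"variant_id": variant_ids}
    if genes is not None:
        data["gene"] = genes
    data["consequence"] = consequences
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_novelty_flags(path: str | Path) -> pd.Series:
    """Read per-variant novelty flags (variant_id, novel as true/false)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    flags = df.iloc[:, 1].str.strip().str.lower().isin(["true", "1", "yes"])
    return pd.Series(flags.values, index=df.iloc[:, 0].values)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV with the package-wide float format."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
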