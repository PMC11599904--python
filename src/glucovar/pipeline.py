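"""End-to-end orchestration: simulate/ingest → annotate → select → compare → diverge.

A :class:`PipelineConfig` (loadable from YAML) drives the full analysis and
produces five tabular outputs in the chosen directory:

* ``annotation_summary.tsv`` — panel tabulation by type/region/consequence/impact
* ``exclusive_variants.tsv`` — variants private to the study groups
* ``comparison_matrix.tsv`` + ``comparison_supplementary.tsv`` — standardized
  Fisher contrasts with Hochberg adjustment, signs and the reporting split
* ``mds_coordinates.tsv`` — classical-MDS embedding of population profiles
* ``pairwise_permanova.tsv`` — per-pair R², pseudo-F, raw/adjusted p

Every run is reproducible from its seed; a ``RunReport`` records per-stage
parameters, counts and output paths.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .annotation import IMPACT_TIERS, VariantRecord, summarize_annotations
from .comparison import (
    allele_frequency_table,
    compare_reference_to_panels,
    select_reportable,
)
from .divergence import (
    classical_mds,
    distance_matrix,
    dosage_distance_matrix,
    pairwise_permanova,
    permanova_results_frame,
    population_profile_matrix,
)
from .selection import SelectionCriteria, find_exclusive_variants
from .simulate import SimulationConfig, simulate_panel

__all__ = [
    "ComparisonSettings",
    "DivergenceSettings",
    "PipelineConfig",
    "RunReport",
    "load_config",
    "validate_config",
    "run_analysis",
]

logger = logging.getLogger(__name__)


@dataclass
class ComparisonSettings:
    reference: str = "IND-NLLA"
    comparators: tuple[str, ...] = ("IND-LLA", "AFR", "AMR", "EAS", "EUR", "SAS")
    alpha: float = 0.05
    min_populations: int = 3
    tiers: tuple[str, ...] = ("High", "Moderate")
    total_alleles: int = 118
    hochberg_scope: str = "per_variant"
    use_adjusted: bool = False


@dataclass
class DivergenceSettings:
    metric: str = "euclidean"
    k: int = 2
    n_permutations: int = 999


@dataclass
class PipelineConfig:
    """Declarative configuration for one full run."""

    mode: str = "simulate"
    vcf_path: str | None = None
    annotation_path: str | None = None
    population_map_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    comparison: ComparisonSettings = field(default_factory=ComparisonSettings)
    divergence: DivergenceSettings = field(default_factory=DivergenceSettings)
    target_groups: tuple[str, ...] = ("IND-LLA", "IND-NLLA")
    reference_panels: tuple[str, ...] = ("AFR", "AMR", "EAS", "EUR", "SAS")
    output_dir: str = "glucovar_out"
    seed: int = 0


@dataclass
class Issue:
    code: str
    message: str


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (missing keys → defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    nested = {
        "simulation": SimulationConfig,
        "selection": SelectionCriteria,
        "comparison": ComparisonSettings,
        "divergence": DivergenceSettings,
    }
    for key, value in raw.items():
        if key in nested and isinstance(value, dict):
            base = dataclasses.asdict(getattr(cfg, key))
            known = {f.name for f in dataclasses.fields(nested[key])}
            unknown = set(value) - known
            if unknown:
                raise ValueError(f"unknown {key} keys: {sorted(unknown)}")
            base.update(value)
            # tuples survive YAML as lists; normalise
            base = {
                k: tuple(v) if isinstance(v, list) else v for k, v in base.items()
            }
            setattr(cfg, key, nested[key](**base))
        elif hasattr(cfg, key):
            if isinstance(value, list):
                value = tuple(value)
            setattr(cfg, key, value)
        else:
            raise ValueError(f"unknown config key: {key}")
    return cfg


def validate_config(config: PipelineConfig) -> list[Issue]:
    """Check config invariants; returns issues (empty = valid), never raises."""
    issues: list[Issue] = []
    if config.mode not in ("simulate", "vcf"):
        issues.append(Issue("bad_mode", f"mode must be simulate|vcf, got {config.mode!r}"))
    if config.mode == "vcf":
        for label, path in (
            ("vcf_path", config.vcf_path),
            ("population_map_path", config.population_map_path),
            ("annotation_path", config.annotation_path),
        ):
            if path is None:
                issues.append(Issue("missing_input", f"{label} required in vcf mode"))
            elif not Path(path).exists():
                issues.append(Issue("missing_input", f"{label} does not exist: {path}"))
    if not 0 < config.comparison.alpha < 1:
        issues.append(Issue("alpha_out_of_range", f"alpha={config.comparison.alpha}"))
    if config.comparison.min_populations < 1:
        issues.append(Issue("bad_min_populations", "min_populations must be >= 1"))
    if not set(config.comparison.tiers) <= set(IMPACT_TIERS):
        issues.append(Issue("bad_tiers", f"tiers must be among {IMPACT_TIERS}"))
    if config.comparison.total_alleles < 2:
        issues.append(Issue("bad_total_alleles", "total_alleles must be >= 2"))
    if config.divergence.metric not in ("euclidean", "manhattan", "bray-curtis"):
        issues.append(Issue("bad_metric", f"metric={config.divergence.metric!r}"))
    if config.divergence.n_permutations < 1:
        issues.append(Issue("bad_permutations", "n_permutations must be >= 1"))
    if config.divergence.k < 1:
        issues.append(Issue("bad_k", "k must be >= 1"))
    if config.mode == "simulate":
        try:
            config.simulation.validate()
        except ValueError as exc:
            issues.append(Issue("bad_simulation", str(exc)))
    return issues


@dataclass
class StageRecord:
    stage: str
    params: dict
    counts: dict
    outputs: list[str]
    started: float
    finished: float


@dataclass
class RunReport:
    seed: int
    stages: list[StageRecord] = field(default_factory=list)

    @property
    def output_files(self) -> list[str]:
        return [p for s in self.stages for p in s.outputs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.stage,
                    "params": repr(s.params),
                    "counts": repr(s.counts),
                    "outputs": ";".join(s.outputs),
                    "seconds": round(s.finished - s.started, 3),
                }
                for s in self.stages
            ]
        )


def _record(report: RunReport, stage: str, params: dict, counts: dict, outputs: list[Path], t0: float) -> None:
    report.stages.append(
        StageRecord(
            stage=stage,
            params=params,
            counts=counts,
            outputs=[str(p) for p in outputs],
            started=t0,
            finished=time.time(),
        )
    )
    logger.info("stage %s done: %s", stage, counts)


def run_analysis(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline; fails fast with the offending stage named."""
    issues = validate_config(config)
    if issues:
        raise ValueError(
            "invalid config: " + "; ".join(f"{i.code}: {i.message}" for i in issues)
        )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    logger.info("run seed = %d", config.seed)

    stage = "ingest"
    try:
        t0 = time.time()
        if config.mode == "simulate":
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            gm, annotations = simulate_panel(sim)
            params = dataclasses.asdict(sim)
        else:
            popmap = gio.read_population_map(config.population_map_path)
            gm = gio.read_vcf(config.vcf_path, population_map=popmap)
            ann = gio.read_annotations(config.annotation_path)
            annotations = pd.DataFrame(
                {
                    "variant_id": gm.variant_ids,
                    "gene": "NA",
                    "consequence": [ann.get(v, "intronic") for v in gm.variant_ids],
                }
            )
            params = {"vcf": config.vcf_path}
        _record(
            report, stage, params,
            {"samples": gm.n_samples, "variants": gm.n_variants}, [], t0,
        )

        stage = "annotate"
        t0 = time.time()
        variants_meta = gm.variants if gm.variants is not None else pd.DataFrame(
            {"chrom": "1", "pos": 1, "ref": "A", "alt": "C"}, index=gm.variant_ids
        )
        records = [
            VariantRecord(
                chrom=str(variants_meta.loc[v, "chrom"]),
                pos=int(variants_meta.loc[v, "pos"]),
                ref=str(variants_meta.loc[v, "ref"]),
                alt=str(variants_meta.loc[v, "alt"]),
                gene=str(g),
                consequence=str(c),
            )
            for v, g, c in zip(
                annotations["variant_id"], annotations["gene"], annotations["consequence"]
            )
        ]
        summary = summarize_annotations(records)
        p_summary = out / "annotation_summary.tsv"
        gio.write_table(summary.to_frame(), p_summary)
        _record(report, stage, {}, {"total": summary.total}, [p_summary], t0)

        stage = "allele_frequencies"
        t0 = time.time()
        af_table = allele_frequency_table(gm)
        consequence_of = dict(zip(annotations["variant_id"], annotations["consequence"]))
        impact_of = {v: r.impact for v, r in zip(annotations["variant_id"], records)}
        _record(report, stage, {}, {"rows": len(af_table)}, [], t0)

        stage = "exclusive"
        t0 = time.time()
        af_ext = af_table.assign(
            consequence=af_table["variant"].map(consequence_of)
        )
        excl = find_exclusive_variants(
            af_ext, list(config.target_groups), list(config.reference_panels)
        )
        p_excl = out / "exclusive_variants.tsv"
        gio.write_table(excl.to_frame(), p_excl)
        _record(
            report, stage,
            {"targets": config.target_groups, "panels": config.reference_panels},
            {"union": excl.union_count, "unassessable": len(excl.unassessable)},
            [p_excl], t0,
        )

        stage = "compare"
        t0 = time.time()
        cs = config.comparison
        matrix = compare_reference_to_panels(
            af_table,
            reference=cs.reference,
            comparators=list(cs.comparators),
            total_alleles=cs.total_alleles,
            hochberg_scope=cs.hochberg_scope,
            impact=impact_of,
        )
        reported, supplementary = select_reportable(
            matrix,
            alpha=cs.alpha,
            min_populations=cs.min_populations,
            tiers=cs.tiers,
            use_adjusted=cs.use_adjusted,
        )
        p_cmp = out / "comparison_matrix.tsv"
        p_sup = out / "comparison_supplementary.tsv"
        gio.write_table(matrix.to_wide(), p_cmp)
        gio.write_table(supplementary, p_sup)
        p_rep = out / "comparison_reportable.tsv"
        gio.write_table(reported, p_rep)
        _record(
            report, stage, dataclasses.asdict(cs),
            {"variants": matrix.data["variant"].nunique() if not matrix.data.empty else 0,
             "reportable": len(reported)},
            [p_cmp, p_sup, p_rep], t0,
        )

        stage = "mds"
        t0 = time.time()
        pops = list(dict.fromkeys(gm.populations))
        profiles = population_profile_matrix(af_table, pops, list(gm.variant_ids))
        D_pop = distance_matrix(profiles, metric=config.divergence.metric)
        emb = classical_mds(D_pop, k=config.divergence.k)
        coords = emb.coordinates.copy()
        coords.insert(0, "population", coords.index)
        p_mds = out / "mds_coordinates.tsv"
        gio.write_table(coords, p_mds)
        _record(
            report, stage,
            {"metric": config.divergence.metric, "k": config.divergence.k},
            {"populations": len(pops), "goodness": round(emb.goodness, 6)},
            [p_mds], t0,
        )

        stage = "permanova"
        t0 = time.time()
        metric = config.divergence.metric
        if metric == "bray-curtis":
            metric = "euclidean"  # dosage distances support euclidean/manhattan
        D_ind = dosage_distance_matrix(gm, metric=metric)
        # study-style pair list: each target cohort against every other group
        pairs, seen_pairs = [], set()
        present = list(dict.fromkeys(gm.populations))
        for target in config.target_groups:
            if target not in present:
                continue
            for other in present:
                key = frozenset((target, other))
                if other == target or key in seen_pairs:
                    continue
                seen_pairs.add(key)
                pairs.append((target, other))
        results = pairwise_permanova(
            D_ind,
            gm.populations,
            pairs=pairs or None,
            n_permutations=config.divergence.n_permutations,
            seed=config.seed,
        )
        p_perm = out / "pairwise_permanova.tsv"
        gio.write_table(permanova_results_frame(results), p_perm)
        _record(
            report, stage,
            {"metric": metric, "n_permutations": config.divergence.n_permutations},
            {"pairs": len(results)}, [p_perm], t0,
        )

        stage = "report"
        t0 = time.time()
        p_report = out / "run_report.tsv"
        gio.write_table(report.to_frame(), p_report)
        _record(report, stage, {}, {"stages": len(report.stages)}, [p_report], t0)
    except Exception as exc:
        for path in report.output_files:
            p = Path(path)
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report
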