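"""Pipeline orchestration: configuration, stage ordering, report generation.

``run_classify`` executes the analysis stages in a fixed order —
site/genotype quality filter, missing-rate filter, repeat masking,
locus classification, parent-pattern partitioning, segregation tests,
source-exclusion screens — and writes tabular outputs plus a summary JSON.
Every removed locus is attributed to exactly one stage, so input loci =
kept loci + the sum of per-stage removals.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import (
    ParentPattern,
    classification_summary,
    classify_matrix,
    filter_missing_rate,
    parent_patterns,
    per_individual_stats,
    segregation_test,
)
from .errors import ConfigurationError
from .model import GenotypeMatrix, SiteQualityThresholds, read_matrix_tsv
from .screens import (
    export_blast_queries,
    extract_flanks,
    gc_depth_screen,
    load_repeats,
    mask_repeats,
    organelle_screen,
)
from .simulate import SimParams, simulate
from .vcfio import quality_filter, read_vcf

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_classify", "run_simulate", "load_config"]


@dataclass
class PipelineConfig:
    """Inputs, parent ids, thresholds and output location for one run."""

    out_dir: str
    vcf: str | None = None
    matrix_tsv: str | None = None
    reference: str | None = None
    repeats: str | None = None
    organelles: str | None = None
    gc_depth: str | None = None
    female_id: str = "female_parent"
    male_id: str = "male_parent"
    apply_quality_filter: bool = True
    thresholds: SiteQualityThresholds = field(default_factory=SiteQualityThresholds)
    max_missing_rate: float = 0.15
    identical_requires_complete: bool = True
    alpha: float = 0.05
    flank_length: int = 400
    screen_min_identity: float = 0.9
    screen_min_length: int = 100
    screen_seed_k: int = 21
    gc_low: float = 0.40
    gc_high: float = 0.60
    seed: int = 0

    def validate(self) -> None:
        if (self.vcf is None) == (self.matrix_tsv is None):
            raise ConfigurationError("exactly one of vcf or matrix_tsv must be given")
        for name in ("vcf", "matrix_tsv", "reference", "repeats", "organelles", "gc_depth"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"{name} input not found: {path}")
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ConfigurationError("max_missing_rate must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")


def load_config(path, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file plus overrides."""
    with Path(path).open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    thresholds = raw.pop("thresholds", None)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    config = PipelineConfig(**raw)
    if thresholds is not None:
        config.thresholds = SiteQualityThresholds(**thresholds)
    return config


@dataclass
class RunReport:
    """Stage accounting and result summary for one classification run."""

    n_input_loci: int
    n_removed_quality: int
    n_removed_missing_rate: int
    n_removed_repeats: int
    n_kept: int
    classification: dict
    individual_summary: dict
    segregation: dict
    screens: dict
    config: dict
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _load_matrix(config: PipelineConfig, outdir: Path) -> tuple:
    """Stage 1: quality filter (VCF input only) and matrix loading."""
    n_removed_quality = 0
    if config.vcf is not None:
        vcf_path = Path(config.vcf)
        if config.apply_quality_filter:
            filtered = outdir / "quality_filtered.vcf"
            qstats = quality_filter(vcf_path, filtered, config.thresholds)
            n_removed_quality = qstats.n_sites_removed
            logger.info(
                "quality filter: %d sites in, %d removed, %d genotypes masked",
                qstats.n_sites_in, qstats.n_sites_removed, qstats.n_genotypes_masked,
            )
            vcf_path = filtered
        matrix, rstats = read_vcf(vcf_path, config.female_id, config.male_id)
        logger.info("loaded %d SNP loci (%d records skipped)", matrix.n_loci, rstats.n_skipped)
    else:
        matrix = read_matrix_tsv(config.matrix_tsv)
        logger.info("loaded %d loci from matrix TSV", matrix.n_loci)
    return matrix, n_removed_quality


def _run_screens(config: PipelineConfig, matrix: GenotypeMatrix, table: pd.DataFrame, patterns, outdir: Path) -> dict:
    """Stage 7: flank extraction, BLAST-query export, organelle and GC-depth screens."""
    screens: dict = {}
    if config.reference is not None and matrix.n_loci:
        import pyfaidx

        reference = pyfaidx.Fasta(config.reference)
        both_het = [
            matrix.loci[i]
            for i, p in enumerate(patterns)
            if p is ParentPattern.BOTH_HET_IDENTICAL
        ]
        if both_het:
            windows = extract_flanks(reference, both_het, config.flank_length)
            export_blast_queries(windows, outdir / "blast_queries.fasta")
            screens["n_blast_queries"] = len(windows)
            screens["n_flank_ref_mismatch"] = sum(w.ref_mismatch for w in windows)
        one_het = [
            matrix.loci[i] for i, p in enumerate(patterns) if p is ParentPattern.ONE_PARENT_HET
        ]
        if one_het and config.organelles is not None:
            organelles = {
                rec.name: str(rec[:]) for rec in pyfaidx.Fasta(config.organelles)
            }
            windows = extract_flanks(reference, one_het, config.flank_length)
            hits, clean = organelle_screen(
                windows,
                organelles,
                min_identity=config.screen_min_identity,
                min_length=config.screen_min_length,
                seed_k=config.screen_seed_k,
            )
            pd.DataFrame(
                [dataclasses.asdict(h) for h in hits],
                columns=[
                    "window_id", "target_id", "identity", "length",
                    "strand", "window_start", "target_start",
                ],
            ).to_csv(outdir / "organelle_hits.tsv", sep="\t", index=False)
            screens["n_organelle_screened"] = len(windows)
            screens["n_organelle_hits"] = len(hits)
            screens["n_organelle_clean"] = len(clean)
    if config.gc_depth is not None:
        points = pd.read_csv(config.gc_depth, sep="\t")
        flagged, frac = gc_depth_screen(points, config.gc_low, config.gc_high)
        flagged.to_csv(outdir / "gc_depth_flagged.tsv", sep="\t", index=False)
        screens["n_gc_depth_points"] = len(points)
        screens["n_gc_depth_flagged"] = len(flagged)
        screens["frac_gc_depth_flagged"] = frac
    return screens


def run_classify(config: PipelineConfig) -> RunReport:
    """Run the full classification workflow and write all outputs."""
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix, n_removed_quality = _load_matrix(config, outdir)
    n_input = matrix.n_loci + n_removed_quality

    matrix, n_removed_miss = filter_missing_rate(matrix, config.max_missing_rate)
    logger.info("missing-rate filter: removed %d, kept %d", n_removed_miss, matrix.n_loci)

    n_removed_repeats = 0
    if config.repeats is not None:
        repeats = load_repeats(config.repeats)
        matrix, n_removed_repeats = mask_repeats(matrix, repeats)
        logger.info("repeat mask: removed %d, kept %d", n_removed_repeats, matrix.n_loci)

    if matrix.n_loci == 0:
        logger.warning("no loci left after filtering; writing empty report")
        report = RunReport(
            n_input, n_removed_quality, n_removed_miss, n_removed_repeats, 0,
            {}, {}, {}, {}, _config_echo(config),
        )
        (outdir / "summary.json").write_text(report.to_json() + "\n", encoding="utf-8")
        return report

    table = classify_matrix(
        matrix, identical_requires_complete=config.identical_requires_complete
    )
    patterns = parent_patterns(matrix)
    table["parent_pattern"] = [p.value for p in patterns]
    table["class"] = table["het_any"].map(
        {True: "HETEROZYGOUS_ANY", False: "UNIFORM_HOMOZYGOUS"}
    )
    table[
        ["scaffold", "position", "class", "identical_het_all", "parent_pattern"]
    ].to_csv(outdir / "classification.tsv", sep="\t", index=False)

    stats, ind_summary = per_individual_stats(matrix)
    pd.DataFrame([dataclasses.asdict(s) for s in stats]).to_csv(
        outdir / "individual_stats.tsv", sep="\t", index=False
    )

    seg_rows = []
    for i, p in enumerate(patterns):
        if p is ParentPattern.PARENTS_HOM_DIFFERENT:
            seg_rows.append(dataclasses.asdict(segregation_test(i, matrix, config.alpha)))
    seg_df = pd.DataFrame(
        seg_rows,
        columns=[
            "locus_id", "n_allele_female", "n_allele_male", "n_het_offspring",
            "n_missing_offspring", "chi2", "p_value", "consistent_1_1", "untestable",
        ],
    )
    seg_df.to_csv(outdir / "segregation.tsv", sep="\t", index=False)
    testable = seg_df[~seg_df["untestable"].astype(bool)] if len(seg_rows) else seg_df
    seg_summary = {
        "n_tested": int(len(testable)),
        "n_untestable": int(len(seg_df) - len(testable)),
        "n_consistent_1_1": int(testable["consistent_1_1"].sum()) if len(testable) else 0,
        "alpha": config.alpha,
    }

    screens = _run_screens(config, matrix, table, patterns, outdir)

    summary = classification_summary(
        matrix, identical_requires_complete=config.identical_requires_complete
    )
    report = RunReport(
        n_input_loci=n_input,
        n_removed_quality=n_removed_quality,
        n_removed_missing_rate=n_removed_miss,
        n_removed_repeats=n_removed_repeats,
        n_kept=matrix.n_loci,
        classification=summary,
        individual_summary=ind_summary,
        segregation=seg_summary,
        screens=screens,
        config=_config_echo(config),
    )
    (outdir / "summary.json").write_text(report.to_json() + "\n", encoding="utf-8")
    return report


def _config_echo(config: PipelineConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["thresholds"] = dataclasses.asdict(config.thresholds)
    return echo


def run_simulate(params: SimParams, out_dir) -> dict:
    """Draw a bundle from the generative model and write it to ``out_dir``."""
    logger.info("simulating with seed %d", params.seed)
    bundle = simulate(params)
    paths = bundle.write(out_dir)
    logger.info(
        "wrote bundle: %d loci x %d individuals under %s",
        bundle.matrix.n_loci, bundle.matrix.n_individuals, out_dir,
    )
    return paths
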