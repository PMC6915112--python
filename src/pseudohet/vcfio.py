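"""VCF input/output and hard quality filtering.

The pipeline starts from a multi-sample VCF produced by a short-variant
caller run on the two parents and their haploid offspring.  Only biallelic
SNP records are loaded; multiallelic, indel and symbolic records are
skipped and counted.  Because callers differ in how they encode ploidy for
haploid samples, both diploid-style ("0/0", "0/1", "./.") and haploid-style
("0", "1", ".") GT fields are accepted; phased separators are treated the
same as unphased ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .errors import ConfigurationError, ParseError
from .model import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    DNA_BASES,
    GenotypeMatrix,
    Locus,
    SiteQualityThresholds,
)

logger = logging.getLogger(__name__)

__all__ = ["ReadStats", "QualityFilterStats", "read_vcf", "write_vcf", "quality_filter"]


@dataclass
class ReadStats:
    """Record-level tallies from :func:`read_vcf`."""

    n_loaded: int = 0
    n_skipped_multiallelic: int = 0
    n_skipped_indel: int = 0
    n_skipped_symbolic: int = 0

    @property
    def n_skipped(self) -> int:
        return self.n_skipped_multiallelic + self.n_skipped_indel + self.n_skipped_symbolic


def _is_snp_allele(a: str | None) -> bool:
    return a is not None and len(a) == 1 and a.upper() in DNA_BASES


def _gt_to_code(gt: tuple) -> int:
    """Map a GT tuple (diploid- or haploid-style) to a call code."""
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return MISSING
    if len(set(alleles)) > 1:
        return HET
    return HOM_REF if alleles[0] == 0 else HOM_ALT


def read_vcf(path, female_id: str, male_id: str) -> tuple:
    """Load a multi-sample VCF into a :class:`GenotypeMatrix`.

    Parents are placed first in individual order (female, then male).
    Returns ``(matrix, ReadStats)``.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        for pid in (female_id, male_id):
            if pid not in samples:
                raise ConfigurationError(f"sample {pid!r} not in VCF header ({samples})")
        offspring = [s for s in samples if s not in (female_id, male_id)]
        individuals = [female_id, male_id] + offspring

        stats = ReadStats()
        loci: list = []
        rows: list = []
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                stats.n_skipped_multiallelic += 1
                continue
            alt = alts[0]
            if alt.startswith("<") or alt == "*":
                stats.n_skipped_symbolic += 1
                continue
            if not (_is_snp_allele(rec.ref) and _is_snp_allele(alt)):
                stats.n_skipped_indel += 1
                continue
            loci.append(Locus(rec.chrom, rec.pos, rec.ref.upper(), alt.upper()))
            row = np.empty(len(individuals), dtype=np.int8)
            for j, sid in enumerate(individuals):
                gt = rec.samples[sid].get("GT") or (None,)
                row[j] = _gt_to_code(gt)
            rows.append(row)
            stats.n_loaded += 1

    codes = (
        np.vstack(rows) if rows else np.empty((0, len(individuals)), dtype=np.int8)
    )
    matrix = GenotypeMatrix(loci, individuals, codes)
    if stats.n_skipped:
        logger.info(
            "read_vcf: loaded %d SNP records, skipped %d (multiallelic=%d, indel=%d, symbolic=%d)",
            stats.n_loaded,
            stats.n_skipped,
            stats.n_skipped_multiallelic,
            stats.n_skipped_indel,
            stats.n_skipped_symbolic,
        )
    return matrix, stats


_CODE_TO_GT = {
    HOM_REF: (0, 0),
    HOM_ALT: (1, 1),
    HET: (0, 1),
    MISSING: (None, None),
}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write the matrix as a VCF 4.2 file (diploid-style GT encoding)."""
    path = Path(path)
    header = pysam.VariantHeader()
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")],
    )
    contigs: dict = {}
    for locus in matrix.loci:
        contigs[locus.scaffold] = max(contigs.get(locus.scaffold, 0), locus.position)
    for name, max_pos in contigs.items():
        header.contigs.add(name, length=max_pos + 1)
    for sid in matrix.individuals:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, locus in enumerate(matrix.loci):
            rec = out.new_record(
                contig=locus.scaffold,
                start=locus.position - 1,
                alleles=(locus.ref, locus.alt),
            )
            for j, sid in enumerate(matrix.individuals):
                rec.samples[sid]["GT"] = _CODE_TO_GT[int(matrix.codes[i, j])]
            out.write(rec)


@dataclass
class QualityFilterStats:
    """Site removal and genotype masking tallies from :func:`quality_filter`."""

    n_sites_in: int = 0
    n_sites_kept: int = 0
    n_removed_qd: int = 0
    n_removed_fs: int = 0
    n_removed_mq: int = 0
    n_removed_sor: int = 0
    n_removed_qual: int = 0
    n_genotypes_masked: int = 0
    n_missing_annotations: int = 0

    @property
    def n_sites_removed(self) -> int:
        return self.n_sites_in - self.n_sites_kept


def _info_float(rec, key: str, declared: set, stats: QualityFilterStats):
    val = rec.info.get(key) if key in declared else None
    if val is None:
        stats.n_missing_annotations += 1
        return None
    if isinstance(val, tuple):
        val = val[0]
    return float(val)


def quality_filter(
    in_path,
    out_path,
    thresholds: SiteQualityThresholds | None = None,
) -> QualityFilterStats:
    """Apply hard site filters and per-genotype depth masking to a VCF.

    A site is removed when any of QD < qd_min, FS > fs_max, MQ < mq_min,
    SOR > sor_max, or QUAL < site_qual_min holds; an individual genotype at
    a kept site is set to missing when its DP is below genotype_depth_min.
    Absent INFO/QUAL/DP annotations pass with a warning tally, so minimal
    VCFs (e.g. simulated ones) are untouched.  The operation is idempotent.
    """
    thresholds = thresholds or SiteQualityThresholds()
    in_path, out_path = Path(in_path), Path(out_path)
    stats = QualityFilterStats()
    with pysam.VariantFile(str(in_path)) as vf:
        declared = set(vf.header.info)
        has_dp = "DP" in set(vf.header.formats)
        with pysam.VariantFile(str(out_path), "w", header=vf.header) as out:
            for rec in vf:
                stats.n_sites_in += 1
                qd = _info_float(rec, "QD", declared, stats)
                fs = _info_float(rec, "FS", declared, stats)
                mq = _info_float(rec, "MQ", declared, stats)
                sor = _info_float(rec, "SOR", declared, stats)
                if qd is not None and qd < thresholds.qd_min:
                    stats.n_removed_qd += 1
                    continue
                if fs is not None and fs > thresholds.fs_max:
                    stats.n_removed_fs += 1
                    continue
                if mq is not None and mq < thresholds.mq_min:
                    stats.n_removed_mq += 1
                    continue
                if sor is not None and sor > thresholds.sor_max:
                    stats.n_removed_sor += 1
                    continue
                if rec.qual is not None and rec.qual < thresholds.site_qual_min:
                    stats.n_removed_qual += 1
                    continue
                if has_dp and "DP" in rec.format:
                    for sid in rec.samples:
                        sample = rec.samples[sid]
                        dp = sample.get("DP")
                        gt = sample.get("GT") or (None,)
                        if dp is not None and dp < thresholds.genotype_depth_min:
                            if any(a is not None for a in gt):
                                sample["GT"] = tuple(None for _ in gt)
                                stats.n_genotypes_masked += 1
                stats.n_sites_kept += 1
                out.write(rec)
    if stats.n_missing_annotations:
        logger.warning(
            "quality_filter: %d absent INFO annotations passed without evaluation",
            stats.n_missing_annotations,
        )
    return stats
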