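"""Source-exclusion screens for pseudo-heterozygous SNP candidates.

Heterozygous calls in haploids can in principle come from repetitive
sequence, organellar (plastid/mitochondrial) reads, or exogenous DNA in
the assembly, rather than from collapsed nuclear duplications.  The
screens here rule those sources out:

* repeat-interval masking of SNPs (BED / GFF3 annotations),
* extraction of fixed-width flanking windows around each SNP from the
  reference for downstream alignment or BLAST export,
* an ungapped seed-and-extend alignment of flank windows against organelle
  genomes (exact k-mer seeds, both strands),
* a GC-vs-depth window screen flagging windows whose composition or
  coverage departs from the genome-wide bulk.

Interval arithmetic is 0-based half-open internally (BED convention);
SNP positions arrive 1-based (VCF convention) and are converted at the
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

from .errors import ParseError, UsageError
from .model import GenotypeMatrix, Locus

logger = logging.getLogger(__name__)

__all__ = [
    "Interval",
    "RepeatAnnotation",
    "FlankWindow",
    "ScreenHit",
    "load_repeats",
    "mask_repeats",
    "extract_flanks",
    "organelle_screen",
    "export_blast_queries",
    "gc_depth_screen",
]


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a scaffold."""

    scaffold: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")


class RepeatAnnotation:
    """Repeat intervals grouped by scaffold with O(log n) point queries."""

    def __init__(self, intervals=()):
        self._trees: dict = {}
        self.n_intervals = 0
        for iv in intervals:
            self.add(iv)

    def add(self, interval: Interval) -> None:
        self._trees.setdefault(interval.scaffold, IntervalTree()).addi(
            interval.start, interval.end
        )
        self.n_intervals += 1

    def contains(self, scaffold: str, pos0: int) -> bool:
        """True when the 0-based position falls inside any repeat interval."""
        tree = self._trees.get(scaffold)
        return bool(tree is not None and tree.overlaps_point(pos0))

    def scaffolds(self) -> list:
        return sorted(self._trees)


def load_repeats(path, fmt: str | None = None) -> RepeatAnnotation:
    """Read a repeat annotation from BED or GFF3.

    BED start/end are taken verbatim (already 0-based half-open); GFF3
    coordinates (1-based inclusive) are converted.  Strand is ignored.
    ``fmt`` is inferred from the file suffix when not given.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix == ".bed":
            fmt = "bed"
        elif suffix in (".gff", ".gff3"):
            fmt = "gff3"
        else:
            raise ParseError(f"{path}: cannot infer repeat format from suffix {suffix!r}")
    if fmt not in ("bed", "gff3"):
        raise ValueError(f"unknown repeat format {fmt!r}")
    annotation = RepeatAnnotation()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    scaffold, start, end = fields[0], int(fields[1]), int(fields[2])
                else:
                    scaffold, start, end = fields[0], int(fields[3]) - 1, int(fields[4])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed {fmt} line") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: empty interval [{start}, {end})")
            annotation.add(Interval(scaffold, start, end))
    return annotation


def mask_repeats(matrix: GenotypeMatrix, repeats: RepeatAnnotation) -> tuple:
    """Discard loci whose SNP base overlaps a repeat interval.

    Only the single SNP base is tested (flanks are not considered).
    Returns ``(kept_matrix, n_removed)``; order is preserved.
    """
    keep = [
        i
        for i, locus in enumerate(matrix.loci)
        if not repeats.contains(locus.scaffold, locus.position - 1)
    ]
    return matrix.subset_loci(keep), matrix.n_loci - len(keep)


@dataclass(frozen=True)
class FlankWindow:
    """A reference window centered on a SNP.

    ``start``/``end`` are 1-based inclusive on the scaffold (reporting
    convention); ``snp_offset`` is the 0-based index of the SNP within
    ``sequence``.  ``ref_mismatch`` flags windows where the reference base
    at the SNP does not equal the locus ref allele.
    """

    locus: Locus
    start: int
    end: int
    sequence: str
    snp_offset: int
    ref_mismatch: bool = False

    @property
    def id(self) -> str:
        return self.locus.id


def _scaffold_length(reference, name: str) -> int:
    return len(reference[name])


def extract_flanks(reference, loci, total_length: int = 400) -> list:
    """Extract windows of ``total_length`` centered on each SNP.

    For an even total length the SNP sits right of center: ``total//2``
    bases left, ``total - total//2 - 1`` right (200/199 for 400).  Windows
    are truncated at scaffold ends with ``snp_offset`` adjusted.
    ``reference`` is any mapping from scaffold name to an indexable
    sequence (a ``pyfaidx.Fasta`` or a plain dict of strings).
    """
    if total_length < 1:
        raise ValueError("total_length must be >= 1")
    left = total_length // 2
    right = total_length - left - 1
    windows = []
    for locus in loci:
        try:
            scaffold = reference[locus.scaffold]
        except KeyError as exc:
            raise UsageError(f"scaffold {locus.scaffold!r} absent from reference") from exc
        length = len(scaffold)
        pos0 = locus.position - 1
        if pos0 >= length:
            raise UsageError(f"{locus.id}: position beyond scaffold end ({length} bp)")
        start0 = max(0, pos0 - left)
        end0 = min(length, pos0 + right + 1)
        seq = str(scaffold[start0:end0]).upper()
        snp_offset = pos0 - start0
        mismatch = seq[snp_offset] != locus.ref
        if mismatch:
            logger.warning("%s: reference base %s != ref allele %s", locus.id, seq[snp_offset], locus.ref)
        windows.append(FlankWindow(locus, start0 + 1, end0, seq, snp_offset, mismatch))
    return windows


@dataclass(frozen=True)
class ScreenHit:
    """An ungapped alignment of a flank window to an organelle sequence."""

    window_id: str
    target_id: str
    identity: float
    length: int
    strand: str
    window_start: int
    target_start: int


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _kmer_index(seq: str, k: int) -> dict:
    index: dict = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _extend(query: str, target: str, q: int, t: int, k: int, min_identity: float) -> tuple:
    """Greedy ungapped extension of an exact seed in both directions.

    Each direction extends while the running identity of the whole
    alignment stays at or above ``min_identity``.  Returns
    (q_start, t_start, length, identity).
    """
    matches = k
    length = k
    # extend left
    qi, ti = q - 1, t - 1
    q_start, t_start = q, t
    while qi >= 0 and ti >= 0:
        m = matches + (query[qi] == target[ti])
        if m / (length + 1) < min_identity:
            break
        matches, length = m, length + 1
        q_start, t_start = qi, ti
        qi, ti = qi - 1, ti - 1
    # extend right
    qi, ti = q + k, t + k
    while qi < len(query) and ti < len(target):
        m = matches + (query[qi] == target[ti])
        if m / (length + 1) < min_identity:
            break
        matches, length = m, length + 1
        qi, ti = qi + 1, ti + 1
    return q_start, t_start, length, matches / length


def organelle_screen(
    windows,
    organelles: dict,
    min_identity: float = 0.9,
    min_length: int = 100,
    seed_k: int = 21,
) -> tuple:
    """Align flank windows to organelle sequences by seed-and-extend.

    Exact ``seed_k``-mer matches between a window (either strand) and an
    organelle sequence are extended without gaps while the running identity
    stays >= ``min_identity``; extensions of length >= ``min_length`` are
    reported.  Returns ``(hits, clean_window_ids)``; one best hit per
    (window, target, strand) is kept.
    """
    if not organelles:
        raise UsageError("organelle_screen requires at least one organelle sequence")
    if not 0.0 < min_identity <= 1.0:
        raise ValueError("min_identity must be in (0, 1]")
    indexes = {
        name: _kmer_index(str(seq).upper(), seed_k) for name, seq in organelles.items()
    }
    hits = []
    clean = []
    for window in windows:
        best: dict = {}
        for strand, query in (("+", window.sequence), ("-", _revcomp(window.sequence))):
            for target_id, index in indexes.items():
                target = str(organelles[target_id]).upper()
                covered_until = -1
                for qpos in range(len(query) - seed_k + 1):
                    if qpos <= covered_until:
                        continue  # seed lies inside an already-reported extension
                    kmer = query[qpos : qpos + seed_k]
                    for tpos in index.get(kmer, ()):
                        q_start, t_start, length, identity = _extend(
                            query, target, qpos, tpos, seed_k, min_identity
                        )
                        if length >= min_length and identity >= min_identity:
                            key = (target_id, strand)
                            prev = best.get(key)
                            if prev is None or (length, identity) > (prev.length, prev.identity):
                                best[key] = ScreenHit(
                                    window.id, target_id, identity, length, strand,
                                    q_start, t_start,
                                )
                            covered_until = max(covered_until, q_start + length - seed_k)
        if best:
            hits.extend(sorted(best.values(), key=lambda h: (h.target_id, h.strand)))
        else:
            clean.append(window.id)
    return hits, clean


def export_blast_queries(windows, path) -> None:
    """Write flank windows as a wrapped FASTA of BLAST query sequences.

    Record ids are ``scaffold_position``; duplicates get ``_2``, ``_3`` ...
    suffixes so ids stay unique.
    """
    windows = list(windows)
    if not windows:
        raise UsageError("no windows to export")
    seen: dict = {}
    records = []
    for window in windows:
        base = window.id
        seen[base] = seen.get(base, 0) + 1
        rid = base if seen[base] == 1 else f"{base}_{seen[base]}"
        records.append(SeqRecord(Seq(window.sequence), id=rid, description=""))
    SeqIO.write(records, str(path), "fasta")


def gc_depth_screen(
    points: pd.DataFrame,
    gc_low: float = 0.40,
    gc_high: float = 0.60,
    depth_band: tuple = (1.0, 99.0),
) -> tuple:
    """Flag windows whose GC or depth departs from the genome-wide bulk.

    ``points`` needs columns ``window_id``, ``gc`` (fraction) and ``depth``.
    A point is contamination-suspect when its GC lies outside
    [gc_low, gc_high] or its depth lies outside the empirical
    ``depth_band`` percentile interval.  Returns
    ``(flagged_points, fraction_flagged)``.
    """
    required = {"window_id", "gc", "depth"}
    missing_cols = required - set(points.columns)
    if missing_cols:
        raise UsageError(f"GC-depth table missing columns {sorted(missing_cols)}")
    if len(points) == 0:
        raise UsageError("GC-depth screen requires at least one point")
    gc = points["gc"].to_numpy(dtype=float)
    depth = points["depth"].to_numpy(dtype=float)
    if ((gc < 0) | (gc > 1)).any():
        raise ValueError("gc values must be fractions in [0, 1]")
    if (depth < 0).any():
        raise ValueError("depth values must be >= 0")
    lo, hi = np.percentile(depth, depth_band)
    suspect = (gc < gc_low) | (gc > gc_high) | (depth < lo) | (depth > hi)
    flagged = points.loc[suspect].copy()
    return flagged, float(suspect.mean())
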