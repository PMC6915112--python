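"""Generative model of a haploid cross with collapsed segmental duplications.

The simulator emulates the situation where a fragmented assembly collapses
segmental duplications onto single scaffolds, so reads from both paralogous
copies pile up at one position and a haploid individual is called
heterozygous there (pseudo-heterozygosity).  Each simulated locus is one of
four types:

FIXED_COLLAPSED_DUP
    Both collapsed copies are fixed for different alleles in every
    haplotype: every individual is heterozygous (before missingness).
SEG_COLLAPSED_DUP
    A collapsed duplication whose second copy segregates: each parent's
    copy-2 allele is the alternative with probability ``q``
    (``seg_dup_allele_freq``); each offspring inherits one parent's
    two-copy haplotype uniformly.  The call is heterozygous iff the
    inherited haplotype's copies differ.
SINGLE_COPY_SEG
    An honest single-copy marker: one parent homozygous reference, the
    other homozygous alternative (order randomised); offspring inherit
    either allele with probability 1/2, segregating 1:1.
MONOMORPHIC
    All individuals homozygous reference.

Calls are independently set missing with probability ``missing_rate``.
The bundle also carries a random reference genome (SNP ref alleles match
it), optional planted repeat intervals, random organelle sequences, and a
per-locus truth table, so every downstream stage can be tested against
known ground truth.  Default parameters reproduce the statistical
structure of a published 9,989-locus x 62-gametophyte matrix; the
derivation of the defaults is in docs/methods.md.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .errors import UsageError
from .classify import ParentPattern, classify_matrix, parent_patterns
from .model import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, Locus, write_matrix_tsv
from .screens import Interval
from .vcfio import write_vcf

__all__ = [
    "LOCUS_TYPES",
    "SimParams",
    "SimBundle",
    "simulate",
    "truth_compare",
    "estimate_duplication_fraction",
    "DuplicationFractionEstimate",
]

LOCUS_TYPES = ("FIXED_COLLAPSED_DUP", "SEG_COLLAPSED_DUP", "SINGLE_COPY_SEG", "MONOMORPHIC")

# one independent generator per model component, so e.g. changing how depths
# are drawn never perturbs haplotypes for the same seed
_STREAMS = {
    "reference": 0,
    "positions": 1,
    "types": 2,
    "haplotypes": 3,
    "missing": 4,
    "repeats": 5,
    "organelle": 6,
    "depth": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SimParams:
    """Parameters of the haploid-cross generative model.

    Defaults emulate a 62-gametophyte whole-genome resequencing study:
    60 offspring, 9,989 post-repeat-masking loci, locus-type mixture
    weights (0.77, 0.06, 0.01, 0.16) over
    (fixed collapsed duplication, segregating collapsed duplication,
    single-copy segregating, monomorphic), per-call missing rate 0.058 and
    segregating-duplication copy-2 alternative-allele frequency 0.8.
    ``repeat_overlap_fraction`` defaults to 0 because the emulated matrix
    is the post-masking marker set; raise it to exercise repeat masking.
    """

    n_offspring: int = 60
    n_loci: int = 9989
    weights: tuple = (0.77, 0.06, 0.01, 0.16)
    seg_dup_allele_freq: float = 0.8
    missing_rate: float = 0.058
    repeat_overlap_fraction: float = 0.0
    n_scaffolds: int = 40
    scaffold_length: int = 50_000
    organelle_length: int = 150_000
    allele_balance: float = 0.5
    mean_depth: float = 16.0
    emit_depths: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_offspring < 1 or self.n_loci < 1:
            raise ValueError("n_offspring and n_loci must be >= 1")
        if len(self.weights) != 4 or any(w < 0 for w in self.weights):
            raise ValueError("weights must be four non-negative numbers")
        if not math.isclose(sum(self.weights), 1.0, abs_tol=1e-9):
            raise ValueError(f"weights must sum to 1, got {sum(self.weights)}")
        for name in ("seg_dup_allele_freq", "missing_rate", "repeat_overlap_fraction", "allele_balance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        usable = self.n_scaffolds * max(0, self.scaffold_length - 400)
        if self.n_loci > usable:
            raise ValueError(
                f"{self.n_loci} loci do not fit in {self.n_scaffolds} scaffolds of "
                f"{self.scaffold_length} bp with 200-bp end margins"
            )


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


@dataclass
class SimBundle:
    """Everything one simulation run produces, in memory.

    ``truth`` has one row per locus (matrix order) with columns
    locus_id, scaffold, position, type, female_hap, male_hap, in_repeat.
    ``depths`` (optional) maps (locus_index, individual_index) to
    (copy1_reads, copy2_reads) for emitted allele depths.
    """

    params: SimParams
    reference: dict
    matrix: GenotypeMatrix
    repeats: list
    organelles: dict
    truth: pd.DataFrame
    depths: dict | None = None

    def write(self, outdir) -> dict:
        """Write the bundle to disk; returns the mapping of artifact paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": outdir / "reference.fasta",
            "organelles": outdir / "organelles.fasta",
            "matrix_tsv": outdir / "matrix.tsv",
            "vcf": outdir / "matrix.vcf",
            "repeats": outdir / "repeats.bed",
            "truth": outdir / "truth.tsv",
            "params": outdir / "params.json",
        }
        _write_fasta(self.reference, paths["reference"])
        _write_fasta(self.organelles, paths["organelles"])
        write_matrix_tsv(self.matrix, paths["matrix_tsv"])
        write_vcf(self.matrix, paths["vcf"])
        with paths["repeats"].open("w", encoding="utf-8") as fh:
            for iv in self.repeats:
                fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with paths["params"].open("w", encoding="utf-8") as fh:
            json.dump(asdict(self.params), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _write_fasta(sequences: dict, path, width: int = 60) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate(params: SimParams) -> SimBundle:
    """Draw one complete dataset from the generative model (deterministic per seed)."""
    n_ind = params.n_offspring + 2
    n = params.n_loci

    # reference scaffolds
    ref_rng = _rng(params.seed, "reference")
    reference = {
        f"scaffold{i + 1}": _random_dna(ref_rng, params.scaffold_length)
        for i in range(params.n_scaffolds)
    }
    names = list(reference)

    # SNP positions: uniform without replacement over per-scaffold slots
    # at least 200 bp from scaffold ends, so default flank windows never truncate
    pos_rng = _rng(params.seed, "positions")
    per_scaffold = params.scaffold_length - 400
    slots = pos_rng.choice(params.n_scaffolds * per_scaffold, size=n, replace=False)
    slots.sort()
    scaffold_idx = slots // per_scaffold
    pos0 = slots % per_scaffold + 200  # 0-based
    loci = []
    for si, p0 in zip(scaffold_idx, pos0):
        scaffold = names[si]
        ref_base = reference[scaffold][p0]
        alt_base = _BASES[
            (np.flatnonzero(_BASES != ref_base.encode())[pos_rng.integers(0, 3)])
        ].decode("ascii")
        loci.append(Locus(scaffold, int(p0) + 1, ref_base, alt_base))

    # locus types and haplotypes
    types = _rng(params.seed, "types").choice(4, size=n, p=params.weights)
    hap_rng = _rng(params.seed, "haplotypes")
    codes = np.empty((n, n_ind), dtype=np.int8)
    female_hap = np.empty(n, dtype=object)
    male_hap = np.empty(n, dtype=object)
    q = params.seg_dup_allele_freq

    fixed = types == 0
    codes[fixed] = HET
    female_hap[fixed] = "ref+alt"
    male_hap[fixed] = "ref+alt"

    seg = np.flatnonzero(types == 1)
    if seg.size:
        f_het = hap_rng.random(seg.size) < q
        m_het = hap_rng.random(seg.size) < q
        inherit_f = hap_rng.integers(0, 2, size=(seg.size, params.n_offspring)) == 0
        codes[seg, 0] = np.where(f_het, HET, HOM_REF)
        codes[seg, 1] = np.where(m_het, HET, HOM_REF)
        off = np.where(
            inherit_f, np.where(f_het, HET, HOM_REF)[:, None], np.where(m_het, HET, HOM_REF)[:, None]
        )
        codes[np.ix_(seg, range(2, n_ind))] = off
        female_hap[seg] = np.where(f_het, "ref+alt", "ref+ref")
        male_hap[seg] = np.where(m_het, "ref+alt", "ref+ref")

    single = np.flatnonzero(types == 2)
    if single.size:
        female_is_ref = hap_rng.random(single.size) < 0.5
        inherit_f = hap_rng.integers(0, 2, size=(single.size, params.n_offspring)) == 0
        f_code = np.where(female_is_ref, HOM_REF, HOM_ALT)
        m_code = np.where(female_is_ref, HOM_ALT, HOM_REF)
        codes[single, 0] = f_code
        codes[single, 1] = m_code
        codes[np.ix_(single, range(2, n_ind))] = np.where(
            inherit_f, f_code[:, None], m_code[:, None]
        )
        female_hap[single] = np.where(female_is_ref, "ref", "alt")
        male_hap[single] = np.where(female_is_ref, "alt", "ref")

    mono = types == 3
    codes[mono] = HOM_REF
    female_hap[mono] = "ref"
    male_hap[mono] = "ref"

    # optional allele depths, drawn before missingness so a masked call
    # still has a generative depth record when requested
    depths = None
    if params.emit_depths:
        depth_rng = _rng(params.seed, "depth")
        total = depth_rng.poisson(params.mean_depth, size=(n, n_ind))
        copy1 = depth_rng.binomial(total, params.allele_balance)
        depths = {
            (i, j): (int(copy1[i, j]), int(total[i, j] - copy1[i, j]))
            for i in range(n)
            for j in range(n_ind)
            if codes[i, j] == HET
        }

    if params.missing_rate > 0:
        miss = _rng(params.seed, "missing").random((n, n_ind)) < params.missing_rate
        codes[miss] = MISSING

    # planted repeat intervals around a fraction of loci
    rep_rng = _rng(params.seed, "repeats")
    n_planted = int(round(params.repeat_overlap_fraction * n))
    in_repeat = np.zeros(n, dtype=bool)
    repeats = []
    if n_planted:
        planted = rep_rng.choice(n, size=n_planted, replace=False)
        in_repeat[planted] = True
        for i in sorted(planted):
            locus = loci[i]
            p0 = locus.position - 1
            repeats.append(
                Interval(locus.scaffold, max(0, p0 - 25), min(params.scaffold_length, p0 + 25))
            )

    organelle_rng = _rng(params.seed, "organelle")
    organelles = {
        "plastid": _random_dna(organelle_rng, params.organelle_length),
        "mitochondrion": _random_dna(organelle_rng, params.organelle_length),
    }

    individuals = ["female_parent", "male_parent"] + [
        f"F1_{k + 1:02d}" for k in range(params.n_offspring)
    ]
    matrix = GenotypeMatrix(loci, individuals, codes)
    truth = pd.DataFrame(
        {
            "locus_id": [l.id for l in loci],
            "scaffold": [l.scaffold for l in loci],
            "position": [l.position for l in loci],
            "type": [LOCUS_TYPES[t] for t in types],
            "female_hap": female_hap,
            "male_hap": male_hap,
            "in_repeat": in_repeat,
        }
    )
    return SimBundle(params, reference, matrix, repeats, organelles, truth, depths)


def truth_compare(
    bundle: SimBundle, classification: pd.DataFrame | None = None,
    *, identical_requires_complete: bool = True,
) -> pd.DataFrame:
    """Cross-tabulate true locus types against assigned classes and patterns.

    Returns a DataFrame indexed by true type with columns
    (n, het_any, identical_het_all, <each parent pattern>).  With no
    missingness the mapping is exact for three types:
    FIXED_COLLAPSED_DUP -> identical_het_all, SINGLE_COPY_SEG ->
    PARENTS_HOM_DIFFERENT, MONOMORPHIC -> uniform homozygous +
    PARENTS_HOM_SAME.
    """
    if classification is None:
        classification = classify_matrix(
            bundle.matrix, identical_requires_complete=identical_requires_complete
        )
    if len(classification) != len(bundle.truth):
        raise UsageError(
            f"classification covers {len(classification)} loci, truth has {len(bundle.truth)}"
        )
    if len(bundle.truth) == 0:
        return pd.DataFrame()
    patterns = parent_patterns(bundle.matrix)
    df = pd.DataFrame(
        {
            "type": bundle.truth["type"].to_numpy(),
            "het_any": classification["het_any"].to_numpy(),
            "identical_het_all": classification["identical_het_all"].to_numpy(),
            "pattern": [p.value for p in patterns],
        }
    )
    rows = {}
    for t, group in df.groupby("type"):
        row = {
            "n": len(group),
            "het_any": int(group["het_any"].sum()),
            "identical_het_all": int(group["identical_het_all"].sum()),
        }
        for p in ParentPattern:
            row[p.value] = int((group["pattern"] == p.value).sum())
        rows[t] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("type")


@dataclass(frozen=True)
class DuplicationFractionEstimate:
    """Fraction of loci with >= 1 heterozygous call, with exact binomial CI."""

    estimate: float
    ci_low: float
    ci_high: float
    n_loci: int
    n_het_any: int


def estimate_duplication_fraction(
    matrix: GenotypeMatrix, confidence: float = 0.95
) -> DuplicationFractionEstimate:
    """Estimate the collapsed-duplication locus fraction.

    Every locus with at least one heterozygous call in a haploid population
    is a collapsed-duplication candidate; the fraction of such loci is
    reported with a Clopper-Pearson binomial confidence interval.
    """
    if matrix.n_loci == 0:
        raise UsageError("cannot estimate from an empty matrix")
    k = int((matrix.codes == HET).any(axis=1).sum())
    n = matrix.n_loci
    a = 1.0 - confidence
    low = 0.0 if k == 0 else float(beta_dist.ppf(a / 2, k, n - k + 1))
    high = 1.0 if k == n else float(beta_dist.ppf(1 - a / 2, k + 1, n - k))
    return DuplicationFractionEstimate(k / n, low, high, n, k)
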