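"""Core data types for haploid-sample genotype matrices.

A mapping population of haploid individuals (two parents plus their
offspring) genotyped at biallelic SNPs is held as a :class:`GenotypeMatrix`:
an ordered list of loci, an ordered list of individual ids (parents first),
and a loci x individuals grid of calls.  Because every locus is biallelic,
each cell is fully described by one of four states relative to the locus —
homozygous reference, homozygous alternative, heterozygous, or missing —
which the matrix stores as a compact ``int8`` code grid.  The user-facing
per-cell view is a :class:`Call` carrying explicit alleles.

Display follows the conventional single-letter notation: a homozygous call
is shown as its base, a heterozygous call as the IUPAC ambiguity letter for
its allele pair (W=A/T, R=A/G, K=G/T, Y=C/T, M=A/C, S=C/G), and a missing
call as an en dash.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InconsistentMatrixError, ParseError

__all__ = [
    "DNA_BASES",
    "IUPAC_PAIR_TO_CODE",
    "IUPAC_CODE_TO_PAIR",
    "MISSING_SYMBOL",
    "CallCategory",
    "Call",
    "Locus",
    "GenotypeMatrix",
    "SiteQualityThresholds",
    "HOM_REF",
    "HOM_ALT",
    "HET",
    "MISSING",
    "encode_symbol",
    "decode_symbol",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

DNA_BASES = ("A", "C", "G", "T")

#: Bijection between the six unordered distinct base pairs and IUPAC letters.
IUPAC_PAIR_TO_CODE: dict[frozenset, str] = {
    frozenset("AT"): "W",
    frozenset("AG"): "R",
    frozenset("GT"): "K",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("CG"): "S",
}
IUPAC_CODE_TO_PAIR: dict[str, frozenset] = {
    code: pair for pair, code in IUPAC_PAIR_TO_CODE.items()
}

#: Missing genotype display symbol (en dash, as in the published table);
#: an ASCII hyphen is accepted on input.
MISSING_SYMBOL = "–"
_ACCEPTED_MISSING = {MISSING_SYMBOL, "-", ".", "—"}

# Per-locus call codes used in the matrix grid.
HOM_REF: int = 0
HOM_ALT: int = 1
HET: int = 2
MISSING: int = 3


class CallCategory(enum.Enum):
    HOM = "HOM"
    HET = "HET"
    MISSING = "MISSING"


@dataclass(frozen=True)
class Call:
    """One individual's genotype at one locus.

    ``alleles`` is an unordered set: two distinct bases for HET, a single
    base for HOM (both copies equal), empty for MISSING.
    """

    category: CallCategory
    alleles: frozenset = frozenset()

    def __post_init__(self) -> None:
        bad = [a for a in self.alleles if a not in DNA_BASES]
        if bad:
            raise ValueError(f"non-DNA allele(s) {bad!r}")
        n = len(self.alleles)
        if self.category is CallCategory.HET and n != 2:
            raise ValueError("HET call requires two distinct alleles")
        if self.category is CallCategory.HOM and n != 1:
            raise ValueError("HOM call requires exactly one allele")
        if self.category is CallCategory.MISSING and n != 0:
            raise ValueError("MISSING call carries no alleles")

    @classmethod
    def hom(cls, base: str) -> "Call":
        return cls(CallCategory.HOM, frozenset({base}))

    @classmethod
    def het(cls, a: str, b: str) -> "Call":
        if a == b:
            raise ValueError("HET alleles must differ")
        return cls(CallCategory.HET, frozenset({a, b}))

    @classmethod
    def missing(cls) -> "Call":
        return cls(CallCategory.MISSING)

    @property
    def is_het(self) -> bool:
        return self.category is CallCategory.HET

    @property
    def is_hom(self) -> bool:
        return self.category is CallCategory.HOM

    @property
    def is_missing(self) -> bool:
        return self.category is CallCategory.MISSING


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP site; ``position`` is 1-based (VCF convention)."""

    scaffold: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref not in DNA_BASES or self.alt not in DNA_BASES:
            raise ValueError(f"ref/alt must be single DNA bases, got {self.ref!r}/{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def id(self) -> str:
        return f"{self.scaffold}_{self.position}"


@dataclass(frozen=True)
class SiteQualityThresholds:
    """Site- and genotype-level hard filters applied to called variants.

    Defaults mirror the standard hard-filter recipe for short variants
    (QD < 2.0 || FS > 60.0 || MQ < 40.0 || SOR > 10.0) plus a minimum site
    quality of 20 and a minimum per-genotype depth of 4.
    """

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    sor_max: float = 10.0
    site_qual_min: float = 20.0
    genotype_depth_min: int = 4

    def __post_init__(self) -> None:
        for name in ("qd_min", "fs_max", "mq_min", "sor_max", "site_qual_min", "genotype_depth_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _code_to_call(code: int, locus: Locus) -> Call:
    if code == HOM_REF:
        return Call.hom(locus.ref)
    if code == HOM_ALT:
        return Call.hom(locus.alt)
    if code == HET:
        return Call.het(locus.ref, locus.alt)
    if code == MISSING:
        return Call.missing()
    raise ValueError(f"unknown call code {code}")


def _call_to_code(call: Call, locus: Locus) -> int:
    if call.is_missing:
        return MISSING
    if not call.alleles <= {locus.ref, locus.alt}:
        raise InconsistentMatrixError(
            f"call alleles {sorted(call.alleles)} outside ref/alt "
            f"{{{locus.ref},{locus.alt}}} at {locus.id}"
        )
    if call.is_het:
        return HET
    (base,) = call.alleles
    return HOM_REF if base == locus.ref else HOM_ALT


@dataclass
class GenotypeMatrix:
    """Loci x individuals genotype grid with the two parents first.

    ``codes`` is an ``int8`` array of shape ``(n_loci, n_individuals)``
    holding per-locus call codes (:data:`HOM_REF`, :data:`HOM_ALT`,
    :data:`HET`, :data:`MISSING`).  Individuals 0 and 1 are the female and
    male parent respectively; the rest are offspring.
    """

    loci: list
    individuals: list
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.loci), len(self.individuals)):
            raise ValueError(
                f"code grid {self.codes.shape} does not match "
                f"{len(self.loci)} loci x {len(self.individuals)} individuals"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual ids must be unique")
        if len(self.individuals) < 2:
            raise ValueError("matrix requires at least the two parents")
        if self.codes.size and not np.isin(self.codes, (HOM_REF, HOM_ALT, HET, MISSING)).all():
            raise ValueError("invalid call codes in grid")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_calls(
        cls,
        loci: Sequence[Locus],
        individuals: Sequence[str],
        calls: Sequence[Sequence[Call]],
    ) -> "GenotypeMatrix":
        """Build from an explicit grid of :class:`Call` objects."""
        codes = np.empty((len(loci), len(individuals)), dtype=np.int8)
        for i, locus in enumerate(loci):
            row = calls[i]
            if len(row) != len(individuals):
                raise ValueError(f"row {i} has {len(row)} calls, expected {len(individuals)}")
            for j, call in enumerate(row):
                codes[i, j] = _call_to_code(call, locus)
        return cls(list(loci), list(individuals), codes)

    # -- access -----------------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def female_id(self) -> str:
        return self.individuals[0]

    @property
    def male_id(self) -> str:
        return self.individuals[1]

    @property
    def offspring_ids(self) -> list:
        return self.individuals[2:]

    def call(self, locus_index: int, individual_index: int) -> Call:
        return _code_to_call(int(self.codes[locus_index, individual_index]), self.loci[locus_index])

    def locus_calls(self, locus_index: int) -> list:
        locus = self.loci[locus_index]
        return [_code_to_call(int(c), locus) for c in self.codes[locus_index]]

    def subset_loci(self, keep: Iterable[int]) -> "GenotypeMatrix":
        idx = list(keep)
        return GenotypeMatrix(
            [self.loci[i] for i in idx], list(self.individuals), self.codes[idx]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.individuals == other.individuals
            and np.array_equal(self.codes, other.codes)
        )


# -- symbol codec ---------------------------------------------------------


def encode_symbol(call: Call) -> str:
    """Render a call as its display symbol: base, IUPAC letter, or en dash."""
    if call.is_missing:
        return MISSING_SYMBOL
    if call.is_hom:
        (base,) = call.alleles
        return base
    try:
        return IUPAC_PAIR_TO_CODE[call.alleles]
    except KeyError as exc:  # unreachable for distinct DNA bases
        raise AssertionError(f"no IUPAC code for pair {sorted(call.alleles)}") from exc


def decode_symbol(symbol: str, ref: str, alt: str) -> Call:
    """Inverse of :func:`encode_symbol`, validated against the locus alleles.

    Raises :class:`ParseError` for an unknown symbol and
    :class:`InconsistentMatrixError` when the decoded alleles are not a
    subset of ``{ref, alt}``.
    """
    site = {ref, alt}
    if symbol in _ACCEPTED_MISSING:
        return Call.missing()
    if symbol in DNA_BASES:
        if symbol not in site:
            raise InconsistentMatrixError(
                f"homozygous {symbol} inconsistent with ref/alt {sorted(site)}"
            )
        return Call.hom(symbol)
    if symbol in IUPAC_CODE_TO_PAIR:
        pair = IUPAC_CODE_TO_PAIR[symbol]
        if pair != frozenset(site):
            raise InconsistentMatrixError(
                f"heterozygous {symbol}={'/'.join(sorted(pair))} inconsistent "
                f"with ref/alt {sorted(site)}"
            )
        return Call.het(ref, alt)
    raise ParseError(f"unknown genotype symbol {symbol!r}")


# -- TSV matrix I/O -------------------------------------------------------

_TSV_FIXED_COLUMNS = ["Chr", "Position", "Ref", "Alt"]


def write_matrix_tsv(matrix: GenotypeMatrix, path) -> None:
    """Write the matrix in the tabular dialect ``Chr Position Ref Alt <ids...>``."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_FIXED_COLUMNS + list(matrix.individuals)) + "\n")
        for i, locus in enumerate(matrix.loci):
            symbols = [encode_symbol(_code_to_call(int(c), locus)) for c in matrix.codes[i]]
            fh.write(
                "\t".join([locus.scaffold, str(locus.position), locus.ref, locus.alt] + symbols)
                + "\n"
            )


def read_matrix_tsv(path) -> GenotypeMatrix:
    """Read a matrix written by :func:`write_matrix_tsv` (lossless round trip)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if cols[: len(_TSV_FIXED_COLUMNS)] != _TSV_FIXED_COLUMNS:
            raise ParseError(f"{path}: unexpected header {header!r}")
        individuals = cols[len(_TSV_FIXED_COLUMNS):]
        if len(individuals) < 2:
            raise ParseError(f"{path}: need at least two individual columns")
        loci: list = []
        rows: list = []
        seen: set = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise ParseError(f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}")
            scaffold, pos_s, ref, alt = fields[:4]
            try:
                locus = Locus(scaffold, int(pos_s), ref, alt)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            key = (locus.scaffold, locus.position)
            if key in seen:
                raise ParseError(f"{path}:{lineno}: duplicated locus {locus.id}")
            seen.add(key)
            try:
                row = [decode_symbol(s, locus.ref, locus.alt) for s in fields[4:]]
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            loci.append(locus)
            rows.append(row)
        return GenotypeMatrix.from_calls(loci, individuals, rows)
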