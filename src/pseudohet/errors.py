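"""Exception hierarchy shared across the package."""


class PseudohetError(Exception):
    """Base class for all package errors."""


class ParseError(PseudohetError):
    """Malformed input file (VCF, TSV, BED, GFF3, FASTA)."""


class InconsistentMatrixError(PseudohetError):
    """A call's alleles are not a subset of its locus ref/alt."""


class ConfigurationError(PseudohetError):
    """Bad pipeline configuration: missing files, unknown sample ids."""


class ClassificationError(PseudohetError):
    """A locus cannot be classified (e.g. every call missing)."""


class UsageError(PseudohetError):
    """An operation was invoked outside its precondition."""
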