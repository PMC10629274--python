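"""Exception hierarchy shared across the package."""


class HlaQuantError(Exception):
    """Base class for all package errors."""


class AlleleParseError(HlaQuantError, ValueError):
    """An HLA allele string does not follow GENE*dd:dd[:dd][P] nomenclature."""


class UnsupportedGeneError(HlaQuantError, ValueError):
    """The allele names a locus outside HLA-A/-B/-C."""


class MissingSequenceError(HlaQuantError, KeyError):
    """A genotype allele has no sequence record in the allele database."""


class NoCallError(HlaQuantError, ValueError):
    """Genotyping cannot proceed (e.g. no read is compatible with any allele)."""


class UndefinedRatioError(HlaQuantError, ZeroDivisionError):
    """A reporter-intensity ratio is undefined (zero reference, zero floor)."""
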