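"""HLA class I allele nomenclature: parsing, rendering, field reduction.

HLA alleles are written ``GENE*field1:field2[:field3][P]`` where *field1* is
the allele group (serological family), *field2* the protein-level variant and
*field3* a synonymous coding-sequence variant.  A trailing ``P`` marks a
P-group: the set of alleles sharing an identical peptide-binding-domain
protein sequence.  Two-field ("WMDA") names are the protein-level resolution
used throughout cohort analyses; only the class I heavy-chain loci HLA-A,
HLA-B and HLA-C are supported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .errors import AlleleParseError, UnsupportedGeneError

CLASS_I_GENES = ("A", "B", "C")

_ALLELE_RE = re.compile(
    r"^(?:HLA-)?(?P<gene>[A-Z][A-Z0-9]*)\*"
    r"(?P<f1>\d+):(?P<f2>\d+)(?::(?P<f3>\d+))?(?P<p>P)?$"
)


@dataclass(frozen=True, order=True)
class AlleleName:
    """A parsed HLA class I allele identifier.

    Ordering is lexicographic on (gene, field1, field2, field3), which gives
    the canonical tie-break order used by the genotyper.
    """

    gene: str
    field1: int
    field2: int
    field3: Optional[int] = None
    p_group: bool = False

    def __post_init__(self) -> None:
        if self.gene not in CLASS_I_GENES:
            raise UnsupportedGeneError(
                f"unsupported HLA locus {self.gene!r}; only class I genes "
                f"{'/'.join(CLASS_I_GENES)} are handled"
            )
        if self.field1 <= 0 or self.field2 <= 0:
            raise AlleleParseError("allele numeric fields must be positive")
        if self.field3 is not None and self.field3 <= 0:
            raise AlleleParseError("field3 must be positive when present")

    def render(self) -> str:
        """Canonical string form, zero-padded to two digits per field."""
        s = f"{self.gene}*{self.field1:02d}:{self.field2:02d}"
        if self.field3 is not None:
            s += f":{self.field3:02d}"
        if self.p_group:
            s += "P"
        return s

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @property
    def is_two_field(self) -> bool:
        return self.field3 is None

    def drop_field3(self) -> "AlleleName":
        if self.field3 is None:
            return self
        return AlleleName(self.gene, self.field1, self.field2, None, self.p_group)


def parse_allele(text: str) -> AlleleName:
    """Parse an allele string such as ``A*24:02P`` or ``HLA-C*07:02:01``.

    Raises
    ------
    AlleleParseError
        If the string does not follow the nomenclature pattern.
    UnsupportedGeneError
        If the locus is not HLA-A/-B/-C (e.g. ``DRB1*01:01``).
    """
    m = _ALLELE_RE.match(text.strip())
    if m is None:
        raise AlleleParseError(f"malformed HLA allele string: {text!r}")
    gene = m.group("gene")
    if gene not in CLASS_I_GENES:
        raise UnsupportedGeneError(
            f"unsupported HLA locus {gene!r} in {text!r}; only class I genes "
            f"{'/'.join(CLASS_I_GENES)} are handled"
        )
    f3 = m.group("f3")
    return AlleleName(
        gene=gene,
        field1=int(m.group("f1")),
        field2=int(m.group("f2")),
        field3=int(f3) if f3 is not None else None,
        p_group=m.group("p") is not None,
    )


def to_two_field(name: AlleleName, db=None) -> AlleleName:
    """Reduce an allele name to two-field (protein-level, WMDA) resolution.

    Drops the coding-sequence synonym field.  When *db* (an
    :class:`~hlaquant.references.AlleleDatabase`) carries a P-group table the
    reduced name's ``P`` flag is set from it; otherwise the input flag is
    preserved rather than guessed.  Idempotent.
    """
    reduced = name.drop_field3()
    if db is not None:
        flag = db.p_group_flag(reduced)
        if flag is not None:
            reduced = AlleleName(
                reduced.gene, reduced.field1, reduced.field2, None, flag
            )
    return reduced


def allele_group(name: AlleleName) -> str:
    """The allele-group label, e.g. ``B*15:01P`` -> ``"B*15"``.

    Allele groups collect alleles with similar protein sequences; they depend
    only on the gene and the first numeric field.
    """
    return f"{name.gene}*{name.field1:02d}"


def same_two_field(a: AlleleName, b: AlleleName) -> bool:
    """Protein-level identity, ignoring field3 and the P flag."""
    return (a.gene, a.field1, a.field2) == (b.gene, b.field1, b.field2)
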