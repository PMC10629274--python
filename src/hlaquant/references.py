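"""Allele sequence databases, genotypes and personalized references.

The allele database holds full-length coding and protein sequences for class I
alleles (IMGT/HLA-style).  From it we build the two personalized references
the analyses need:

* a transcript reference where the generic HLA-I entries of a common
  transcriptome are replaced by the sample's own allele coding sequences, and
* a proteome-wide search database (standard proteome + all HLA alleles +
  contaminants) with per-record provenance used for peptide specificity calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import HlaQuantError, MissingSequenceError
from .nomenclature import AlleleName, parse_allele, same_two_field, to_two_field


@dataclass(frozen=True)
class AlleleRecord:
    """One allele's full-length coding and protein sequence."""

    name: AlleleName
    protein: str
    cds: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.protein:
            raise HlaQuantError(f"allele {self.name.render()} has empty protein")
        if self.cds is not None:
            if len(self.cds) % 3 != 0:
                raise HlaQuantError(
                    f"allele {self.name.render()}: cds length {len(self.cds)} "
                    "is not a multiple of 3"
                )
            translated = str(Seq(self.cds).translate()).rstrip("*")
            if translated != self.protein:
                raise HlaQuantError(
                    f"allele {self.name.render()}: translated cds does not "
                    "match the protein sequence"
                )


class AlleleDatabase:
    """Collection of :class:`AlleleRecord` keyed by canonical allele name.

    Supports lookup at full resolution and by two-field reduction, plus an
    optional explicit P-group table mapping protein-level names to their
    P-group membership flag (the flag is never inferred).
    """

    def __init__(
        self,
        records: Iterable[AlleleRecord] = (),
        p_group_table: Optional[Dict[Tuple[str, int, int], bool]] = None,
    ) -> None:
        self._records: Dict[str, AlleleRecord] = {}
        self._p_groups = dict(p_group_table or {})
        for rec in records:
            self.add(rec)

    def add(self, rec: AlleleRecord) -> None:
        key = rec.name.render()
        if key in self._records:
            raise HlaQuantError(f"duplicate allele record {key}")
        self._records[key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def get(self, name: AlleleName) -> Optional[AlleleRecord]:
        return self._records.get(name.render())

    def lookup_two_field(self, name: AlleleName) -> List[AlleleRecord]:
        """All records whose two-field reduction matches *name*."""
        return [r for r in self._records.values() if same_two_field(r.name, name)]

    def resolve(self, name: AlleleName) -> AlleleRecord:
        """A record for *name*, trying exact then two-field lookup."""
        rec = self.get(name)
        if rec is not None:
            return rec
        hits = self.lookup_two_field(name)
        if not hits:
            raise MissingSequenceError(
                f"allele {name.render()} has no sequence in the database"
            )
        return sorted(hits, key=lambda r: r.name)[0]

    def p_group_flag(self, name: AlleleName) -> Optional[bool]:
        return self._p_groups.get((name.gene, name.field1, name.field2))

    # ---- FASTA round trip -------------------------------------------------

    def to_fasta(self, path) -> None:
        records = []
        for rec in sorted(self._records.values(), key=lambda r: r.name):
            records.append(
                SeqRecord(Seq(rec.protein), id=rec.name.render(), description="protein")
            )
            if rec.cds is not None:
                records.append(
                    SeqRecord(Seq(rec.cds), id=rec.name.render(), description="cds")
                )
        _write_fasta(records, path)

    @classmethod
    def from_fasta(cls, path) -> "AlleleDatabase":
        """Load a database written by :meth:`to_fasta` (paired protein/cds
        entries sharing one canonical allele name)."""
        proteins: Dict[str, str] = {}
        cdss: Dict[str, str] = {}
        for sr in SeqIO.parse(str(path), "fasta"):
            kind = sr.description.split()[-1] if sr.description else "protein"
            if kind == "cds":
                cdss[sr.id] = str(sr.seq)
            else:
                proteins[sr.id] = str(sr.seq)
        db = cls()
        for name_str, protein in proteins.items():
            db.add(
                AlleleRecord(
                    name=parse_allele(name_str),
                    protein=protein,
                    cds=cdss.get(name_str),
                )
            )
        return db


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of two-field allele names at one locus of one sample."""

    sample_id: str
    gene: str
    alleles: Tuple[AlleleName, AlleleName]

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a.gene != self.gene or b.gene != self.gene:
            raise HlaQuantError(
                f"genotype gene {self.gene} does not match alleles "
                f"{a.render()}, {b.render()}"
            )
        # store in canonical order so equality is order-insensitive
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def homozygous(self) -> bool:
        return self.alleles[0] == self.alleles[1]

    @property
    def distinct_alleles(self) -> Tuple[AlleleName, ...]:
        if self.homozygous:
            return (self.alleles[0],)
        return self.alleles

    def allele_set(self) -> frozenset:
        return frozenset(a.render() for a in self.alleles)


# ---- genotype table I/O ----------------------------------------------------

GENOTYPE_COLUMNS = ["sample_id", "gene", "allele1", "allele2"]


def genotypes_to_frame(genotypes: Iterable[Genotype]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": g.sample_id,
            "gene": g.gene,
            "allele1": g.alleles[0].render(),
            "allele2": g.alleles[1].render(),
        }
        for g in genotypes
    ]
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


def frame_to_genotypes(frame: pd.DataFrame) -> List[Genotype]:
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            Genotype(
                sample_id=str(row.sample_id),
                gene=str(row.gene),
                alleles=(parse_allele(row.allele1), parse_allele(row.allele2)),
            )
        )
    return out


def read_genotypes(path) -> List[Genotype]:
    return frame_to_genotypes(pd.read_csv(path, sep="\t", dtype=str))


def write_genotypes(genotypes: Iterable[Genotype], path) -> None:
    genotypes_to_frame(genotypes).to_csv(path, sep="\t", index=False)


# ---- personalized transcript reference -------------------------------------


def build_personalized_transcript_reference(
    common_ref: Sequence[SeqRecord],
    genotypes: Sequence[Genotype],
    db: AlleleDatabase,
    hla_entry_filter: Callable[[str], bool],
) -> List[SeqRecord]:
    """Replace generic HLA-I transcript entries with the sample's alleles.

    Keeps every common-reference entry whose identifier fails
    *hla_entry_filter*, then appends one coding sequence per distinct allele
    across the sample's genotypes (a homozygous genotype contributes a single
    entry), sorted by canonical allele name.
    """
    kept = [sr for sr in common_ref if not hla_entry_filter(sr.id)]
    if genotypes and len(kept) == len(common_ref):
        warnings.warn(
            "hla_entry_filter removed no entries while genotypes were "
            "supplied; the filter may be misconfigured",
            stacklevel=2,
        )
    seen = {}
    for g in genotypes:
        for allele in g.distinct_alleles:
            seen[allele.render()] = allele
    missing = []
    added = []
    for key in sorted(seen):
        allele = seen[key]
        try:
            rec = db.resolve(allele)
        except MissingSequenceError:
            missing.append(key)
            continue
        if rec.cds is None:
            missing.append(key)
            continue
        added.append(SeqRecord(Seq(rec.cds), id=key, description="hla_allele"))
    if missing:
        raise MissingSequenceError(
            "alleles missing coding sequences in the database: "
            + ", ".join(missing)
        )
    return kept + added


# ---- proteome search database ----------------------------------------------

PROVENANCE_STANDARD = "standard"
PROVENANCE_HLA = "hla"
PROVENANCE_CONTAMINANT = "contaminant"


@dataclass(frozen=True)
class SearchRecord:
    """One protein entry of the search database with its provenance class."""

    record_id: str
    sequence: str
    provenance: str  # standard | hla | contaminant
    gene: Optional[str] = None  # gene symbol; "HLA-A" etc. for hla records
    allele: Optional[AlleleName] = None  # two-field name for hla records


@dataclass
class SearchDatabase:
    """Provenance-tagged concatenation of proteome, HLA alleles, contaminants."""

    records: List[SearchRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def hla_records(self) -> List[SearchRecord]:
        return [r for r in self.records if r.provenance == PROVENANCE_HLA]

    def to_fasta(self, path) -> None:
        out = []
        for r in self.records:
            desc = f"provenance={r.provenance}"
            if r.gene:
                desc += f" gene={r.gene}"
            out.append(SeqRecord(Seq(r.sequence), id=r.record_id, description=desc))
        _write_fasta(out, path)


def build_search_database(
    common_proteome: Sequence[SeqRecord],
    db: AlleleDatabase,
    contaminants: Sequence[SeqRecord] = (),
) -> SearchDatabase:
    """Concatenate proteome + HLA allele proteins + contaminants.

    Duplicate sequences are allowed across sources (specificity classification
    resolves them later); HLA records are indexed by two-field allele name.
    The gene symbol of a standard record is taken from a ``gene=...`` token in
    its description when present, else the record id.
    """
    if len(db) == 0:
        raise HlaQuantError("allele database is empty; HLA quantification impossible")
    records: List[SearchRecord] = []
    for sr in common_proteome:
        records.append(
            SearchRecord(
                record_id=sr.id,
                sequence=str(sr.seq),
                provenance=PROVENANCE_STANDARD,
                gene=_gene_from_description(sr),
            )
        )
    for rec in sorted(db, key=lambda r: r.name):
        two = to_two_field(rec.name, db)
        records.append(
            SearchRecord(
                record_id=rec.name.render(),
                sequence=rec.protein,
                provenance=PROVENANCE_HLA,
                gene=f"HLA-{rec.name.gene}",
                allele=two,
            )
        )
    for sr in contaminants:
        records.append(
            SearchRecord(
                record_id=sr.id,
                sequence=str(sr.seq),
                provenance=PROVENANCE_CONTAMINANT,
                gene=_gene_from_description(sr),
            )
        )
    return SearchDatabase(records)


def _gene_from_description(sr: SeqRecord) -> str:
    for token in (sr.description or "").split():
        if token.startswith("gene="):
            return token[5:]
    return sr.id


def _write_fasta(records: Sequence[SeqRecord], path) -> None:
    # 60-column wrapped output, deterministic record order
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> List[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))
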