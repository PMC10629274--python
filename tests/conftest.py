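"""Shared fixtures: a hand-built miniature allele family whose tryptic
peptides have known specificity classes, plus helper constructors."""

from __future__ import annotations

import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from hlaquant.nomenclature import parse_allele
from hlaquant.references import (
    AlleleDatabase,
    AlleleRecord,
    Genotype,
    build_search_database,
)
from hlaquant.simulate import _reverse_translate

# Building blocks: each segment is one tryptic peptide (no internal K/R,
# C-terminal K/R not followed by P).
PEP_SHARED_ALL = "AGELYNK"        # occurs in every gene -> multi-HLA-gene
PEP_A_SHARED = "NMATYHER"         # both HLA-A alleles only -> gene-specific, allele-shared
PEP_A1 = "TVDLGTLR"               # unique to A*24:02P -> allele-specific
PEP_A2 = "TVELGTLR"               # unique to A*25:01P
PEP_A3 = "TVQLGTLR"               # unique to A*03:01P
PEP_B1 = "WQDNITLR"
PEP_B2 = "WQENITLR"
PEP_C1 = "FPMYNQSK"
PEP_C2 = "FPMYNQTK"
PEP_CONTAM = "LSSDLQVTK"          # in every allele AND the keratin contaminant

ALLELE_PROTEINS = {
    "A*24:02P": PEP_SHARED_ALL + PEP_A_SHARED + PEP_A1 + PEP_CONTAM,
    "A*25:01P": PEP_SHARED_ALL + PEP_A_SHARED + PEP_A2 + PEP_CONTAM,
    "A*03:01P": PEP_SHARED_ALL + PEP_A_SHARED + PEP_A3 + PEP_CONTAM,
    "B*13:02P": PEP_SHARED_ALL + PEP_B1 + PEP_CONTAM,
    "B*15:01P": PEP_SHARED_ALL + PEP_B2 + PEP_CONTAM,
    "C*07:02P": PEP_SHARED_ALL + PEP_C1 + PEP_CONTAM,
    "C*04:01P": PEP_SHARED_ALL + PEP_C2 + PEP_CONTAM,
}


@pytest.fixture(scope="session")
def allele_db() -> AlleleDatabase:
    db = AlleleDatabase(
        p_group_table={("C", 7, 2): True, ("A", 24, 2): True}
    )
    for name, protein in ALLELE_PROTEINS.items():
        db.add(
            AlleleRecord(
                name=parse_allele(name),
                protein=protein,
                cds=_reverse_translate(protein),
            )
        )
    return db


@pytest.fixture(scope="session")
def search_db(allele_db):
    standard = [
        SeqRecord(Seq("MSTNVALDQREGFLHSITK"), id="PROT1", description="gene=PROT1"),
        SeqRecord(Seq("MDEQWVNTHKAGILPSTYR"), id="PROT2", description="gene=PROT2"),
    ]
    contaminants = [
        SeqRecord(Seq(PEP_CONTAM + "GAVVDSQK"), id="KRT1", description="gene=KRT1"),
    ]
    return build_search_database(standard, allele_db, contaminants)


def make_genotype(sample_id: str, allele1: str, allele2: str) -> Genotype:
    a1, a2 = parse_allele(allele1), parse_allele(allele2)
    return Genotype(sample_id=sample_id, gene=a1.gene, alleles=(a1, a2))


@pytest.fixture
def het_a_genotype() -> Genotype:
    return make_genotype("S1", "A*24:02P", "A*25:01P")
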