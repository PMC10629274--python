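"""Bundled published cohort tables.

Ships the RNA-level HLA-I genotype discrepancy calls reported for paired
CPTAC tumor/adjacent-normal samples in four studies (LUAD, LSCC, HNSCC,
CCRCC), together with the number of RNAseq tumor/normal pairs per study.
These are small printed tables used as worked-example inputs for the paired
genotype comparison.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Tuple

import pandas as pd

from .genotyping import LohCall, detect_loh
from .nomenclature import parse_allele
from .references import Genotype

#: Number of patients with both tumor and adjacent-normal RNAseq data,
#: per study, for the four studies with reported genotype discrepancies.
PAIRED_RNASEQ_COUNTS: Dict[str, int] = {
    "LUAD": 102,
    "LSCC": 95,
    "HNSCC": 61,
    "CCRCC": 75,
}


def load_loh_genotype_table() -> pd.DataFrame:
    """The published tumor/normal genotype discrepancy rows (one row per
    patient-gene) with columns study, gene, patient_id, tumor_allele1/2,
    normal_allele1/2."""
    with resources.files("hlaquant.data").joinpath(
        "cptac_loh_genotypes.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def loh_calls_from_table(table: pd.DataFrame = None) -> List[Tuple[str, LohCall]]:
    """Run the paired tumor/normal comparison on each row of the discrepancy
    table; returns (study, LohCall) pairs."""
    if table is None:
        table = load_loh_genotype_table()
    out: List[Tuple[str, LohCall]] = []
    for row in table.itertuples(index=False):
        tumor = Genotype(
            sample_id=row.patient_id,
            gene=row.gene,
            alleles=(parse_allele(row.tumor_allele1), parse_allele(row.tumor_allele2)),
        )
        normal = Genotype(
            sample_id=row.patient_id,
            gene=row.gene,
            alleles=(parse_allele(row.normal_allele1), parse_allele(row.normal_allele2)),
        )
        out.append((row.study, detect_loh(tumor, normal, patient_id=row.patient_id)))
    return out


def loh_summary() -> pd.DataFrame:
    """Per-study LOH patient counts and rates over the paired cohorts.

    Columns: study, n_loh_patients, n_discrepant_patients,
    n_reverse_patients, paired_n, loh_rate.
    """
    calls = loh_calls_from_table()
    rows = []
    for study in ("LUAD", "LSCC", "HNSCC", "CCRCC"):
        study_calls = [c for s, c in calls if s == study]
        loh_patients = {c.patient_id for c in study_calls if c.status.value == "loh"}
        reverse_patients = {
            c.patient_id for c in study_calls if c.status.value == "reverse_discrepancy"
        }
        discrepant = {
            c.patient_id for c in study_calls if c.status.value != "concordant"
        }
        paired = PAIRED_RNASEQ_COUNTS[study]
        rows.append(
            {
                "study": study,
                "n_loh_patients": len(loh_patients),
                "n_discrepant_patients": len(discrepant),
                "n_reverse_patients": len(reverse_patients),
                "paired_n": paired,
                "loh_rate": len(loh_patients) / paired,
            }
        )
    return pd.DataFrame(rows)
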