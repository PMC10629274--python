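"""RNA-level HLA-I genotyping, LOH and allele-imbalance calling.

Genotyping is a simplified read-compatibility procedure standing in for
pseudoalignment: a read is compatible with an allele iff every k-mer of the
read occurs in the allele's coding sequence.  A greedy iterative pair
selection picks the two alleles explaining the most reads, and homozygosity
is called when the minor-to-major ratio of *non-shared* read counts falls
below a threshold (default 15%).

Paired tumor/normal genotypes are then compared: loss of heterozygosity (LOH)
is a tumor collapsing to one of the two alleles present in the matched normal
tissue.  Allele imbalance is a softer signal on heterozygous pairs: one
allele's RNA falls below half of the other in the tumor, beyond what the
normal tissue shows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import HlaQuantError, NoCallError
from .nomenclature import AlleleName, to_two_field
from .references import AlleleRecord, Genotype

DEFAULT_KMER = 31
DEFAULT_HOMOZYGOSITY_THRESHOLD = 0.15


@dataclass
class CompatibilityMatrix:
    """Boolean read x allele compatibility with id bookkeeping."""

    read_ids: List[str]
    alleles: List[AlleleName]
    compat: np.ndarray  # bool, shape (n_reads, n_alleles)
    n_short_reads: int = 0  # reads shorter than k, incompatible everywhere

    def __post_init__(self) -> None:
        self.compat = np.asarray(self.compat, dtype=bool)
        if self.compat.shape != (len(self.read_ids), len(self.alleles)):
            raise HlaQuantError("compatibility matrix shape does not match ids")

    def column(self, allele: AlleleName) -> np.ndarray:
        return self.compat[:, self.alleles.index(allele)]


def _kmers(seq: str, k: int):
    return (seq[i : i + k] for i in range(len(seq) - k + 1))


def build_compatibility(
    reads: Sequence[Tuple[str, str]],
    candidate_alleles: Sequence[AlleleRecord],
    k: int = DEFAULT_KMER,
) -> CompatibilityMatrix:
    """Compatibility of each read with each candidate allele.

    *reads* is a sequence of ``(read_id, sequence)``.  Reads shorter than *k*
    are incompatible with every allele and counted in ``n_short_reads``.
    """
    allele_kmer_sets = []
    names = []
    for rec in candidate_alleles:
        if rec.cds is None:
            raise HlaQuantError(f"allele {rec.name.render()} has no cds")
        allele_kmer_sets.append(set(_kmers(rec.cds, k)))
        names.append(rec.name)
    n_short = 0
    matrix = np.zeros((len(reads), len(names)), dtype=bool)
    for i, (_rid, seq) in enumerate(reads):
        if len(seq) < k:
            n_short += 1
            continue
        read_kmers = list(_kmers(seq, k))
        for j, kset in enumerate(allele_kmer_sets):
            matrix[i, j] = all(km in kset for km in read_kmers)
    return CompatibilityMatrix(
        read_ids=[rid for rid, _ in reads],
        alleles=names,
        compat=matrix,
        n_short_reads=n_short,
    )


def nonshared_counts(
    compat: CompatibilityMatrix, a: AlleleName, b: AlleleName
) -> Tuple[int, int, int]:
    """(shared, only_a, only_b) read counts for an allele pair."""
    ca, cb = compat.column(a), compat.column(b)
    shared = int(np.sum(ca & cb))
    only_a = int(np.sum(ca & ~cb))
    only_b = int(np.sum(cb & ~ca))
    return shared, only_a, only_b


def _best_allele(
    compat: CompatibilityMatrix, explained: np.ndarray
) -> Tuple[AlleleName, int]:
    """Allele adding the most unexplained reads; ties by canonical order."""
    gains = [
        (int(np.sum(compat.compat[:, j] & ~explained)), compat.alleles[j])
        for j in range(len(compat.alleles))
    ]
    best_gain = max(g for g, _ in gains)
    best_name = min(name for g, name in gains if g == best_gain)
    return best_name, best_gain


def call_genotype(
    compat: CompatibilityMatrix,
    sample_id: str = "sample",
    homozygosity_threshold: float = DEFAULT_HOMOZYGOSITY_THRESHOLD,
    db=None,
) -> Genotype:
    """Greedy iterative genotype selection with a homozygosity threshold.

    The first allele is the one explaining the most reads; the second adds
    the most reads on top of it; the pair is re-ranked until stable.  The
    genotype collapses to homozygous when the minor-to-major ratio of
    non-shared counts is strictly below *homozygosity_threshold*.  Reported
    at two-field resolution.
    """
    if not compat.compat.any():
        raise NoCallError("no read is compatible with any candidate allele")
    none_explained = np.zeros(len(compat.read_ids), dtype=bool)
    first, _ = _best_allele(compat, none_explained)
    second, _ = _best_allele(compat, compat.column(first))
    pair = (first, second)
    for _ in range(20):  # re-rank until the unordered pair is stable
        a, _ = _best_allele(compat, compat.column(pair[1]))
        b, _ = _best_allele(compat, compat.column(a))
        new_pair = (a, b)
        if frozenset(p.render() for p in new_pair) == frozenset(
            p.render() for p in pair
        ):
            pair = new_pair
            break
        pair = new_pair

    shared, only_a, only_b = nonshared_counts(compat, pair[0], pair[1])
    # major = allele with the larger non-shared count; ties by canonical name
    if only_a > only_b or (only_a == only_b and pair[0] <= pair[1]):
        major, minor = pair[0], pair[1]
        nmaj, nmin = only_a, only_b
    else:
        major, minor = pair[1], pair[0]
        nmaj, nmin = only_b, only_a

    gene = major.gene
    major2 = to_two_field(major, db)
    minor2 = to_two_field(minor, db)
    if nmaj == 0:
        warnings.warn(
            "all reads shared between the selected allele pair; homozygous "
            "call rests on degenerate evidence",
            stacklevel=2,
        )
        return Genotype(sample_id, gene, (major2, major2))
    if nmin / nmaj < homozygosity_threshold:
        return Genotype(sample_id, gene, (major2, major2))
    return Genotype(sample_id, gene, (major2, minor2))


class LohStatus(str, Enum):
    CONCORDANT = "concordant"
    LOH = "loh"
    REVERSE_DISCREPANCY = "reverse_discrepancy"
    OTHER_DISCREPANCY = "other_discrepancy"


@dataclass(frozen=True)
class LohCall:
    patient_id: str
    gene: str
    status: LohStatus
    lost_allele: Optional[AlleleName] = None


def detect_loh(tumor: Genotype, normal: Genotype, patient_id: Optional[str] = None) -> LohCall:
    """Classify a paired tumor/normal genotype comparison at one locus.

    ``loh``: normal heterozygous, tumor homozygous for one of the normal
    alleles (the other one is reported as lost).  ``reverse_discrepancy``:
    the opposite direction (tumor heterozygous, normal homozygous).  Any
    other mismatch is ``other_discrepancy``.
    """
    if tumor.gene != normal.gene:
        raise HlaQuantError(
            f"gene mismatch between tumor ({tumor.gene}) and normal "
            f"({normal.gene}) genotypes"
        )
    pid = patient_id or tumor.sample_id
    gene = tumor.gene
    if tumor.allele_set() == normal.allele_set() and tumor.homozygous == normal.homozygous:
        return LohCall(pid, gene, LohStatus.CONCORDANT)
    if (
        not normal.homozygous
        and tumor.homozygous
        and tumor.alleles[0].render() in normal.allele_set()
    ):
        retained = tumor.alleles[0]
        lost = next(a for a in normal.alleles if a != retained)
        return LohCall(pid, gene, LohStatus.LOH, lost_allele=lost)
    if normal.homozygous and not tumor.homozygous:
        return LohCall(pid, gene, LohStatus.REVERSE_DISCREPANCY)
    return LohCall(pid, gene, LohStatus.OTHER_DISCREPANCY)


@dataclass(frozen=True)
class ImbalanceCall:
    patient_id: str
    gene: str
    imbalanced: bool
    tumor_ratio: float  # minor/major, linear scale, in (0, 1]
    normal_ratio: float


def detect_imbalance(
    tumor_allele_expr: Tuple[float, float],
    normal_allele_expr: Tuple[float, float],
    patient_id: str = "",
    gene: str = "A",
    minor_fraction: float = 0.5,
    fold_margin: float = 1.5,
) -> ImbalanceCall:
    """Allele expression imbalance on a heterozygous tumor/normal pair.

    Imbalanced iff the tumor minor/major ratio is strictly below
    *minor_fraction* AND the tumor major/minor fold is at least *fold_margin*
    times the normal major/minor fold.  Inputs are linear-scale expression
    pairs in matching allele order; all values must be strictly positive
    (add pseudocounts upstream before linearizing).
    """
    t = tuple(float(x) for x in tumor_allele_expr)
    n = tuple(float(x) for x in normal_allele_expr)
    if min(t) <= 0 or min(n) <= 0:
        raise HlaQuantError(
            "allele expression must be strictly positive; apply a pseudocount "
            "before linearizing"
        )
    t_ratio = min(t) / max(t)
    n_ratio = min(n) / max(n)
    imbalanced = (t_ratio < minor_fraction) and (
        (1.0 / t_ratio) >= fold_margin * (1.0 / n_ratio)
    )
    return ImbalanceCall(patient_id, gene, imbalanced, t_ratio, n_ratio)


def loh_calls_to_frame(calls: Sequence[LohCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "gene": c.gene,
                "status": c.status.value,
                "lost_allele": c.lost_allele.render() if c.lost_allele else "",
            }
            for c in calls
        ],
        columns=["patient_id", "gene", "status", "lost_allele"],
    )
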