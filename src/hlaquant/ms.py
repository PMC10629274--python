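"""TMT proteomics: digestion, PSM filtering, peptide specificity and
allele-aware protein quantification.

The pipeline starts from peptide-spectrum-match (PSM) tables (spectral search
itself is upstream).  PSMs are filtered on the search expectation value,
reporter-ion intensities are aggregated per peptide across scans, charges and
chromatographic fractions, and every peptide is expressed as a log2 ratio of
its channel intensity over the plex's pooled reference channel, median
centered per sample.

Because HLA-I genes are highly homologous, quantification must be
genotype-aware: a peptide is only used for a sample's HLA gene if its
sequence occurs verbatim in one of the sample's own allele protein
sequences, and per-allele quantification uses only peptides discriminating
the two alleles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from pyteomics import parser as pyt_parser
from scipy import stats

from .errors import HlaQuantError, MissingSequenceError, UndefinedRatioError
from .nomenclature import AlleleName, to_two_field
from .references import (
    AlleleDatabase,
    Genotype,
    PROVENANCE_HLA,
    SearchDatabase,
)

TRYPSIN_RULE = r"[KR](?!P)"  # cleave after K/R except before proline
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
DEFAULT_EXPECTATION_THRESHOLD = 1e-3

PSM_KEY_COLUMNS = ["peptide", "plex_id", "fraction", "charge", "scan", "expectation"]


# ---------------------------------------------------------------------------
# digestion


def digest(
    protein: str,
    missed_cleavages: int = 0,
    min_len: int = 7,
    max_len: int = 40,
) -> FrozenSet[str]:
    """In-silico tryptic digest of a protein sequence.

    Cleaves after K or R except when the next residue is P, allows up to
    *missed_cleavages* internal missed sites and keeps products within
    ``[min_len, max_len]``.
    """
    for pos, residue in enumerate(protein):
        if residue not in AMINO_ACIDS:
            raise HlaQuantError(
                f"invalid residue {residue!r} at position {pos} of protein"
            )
    peptides = pyt_parser.cleave(
        protein, TRYPSIN_RULE, missed_cleavages=missed_cleavages, min_length=1
    )
    return frozenset(p for p in peptides if min_len <= len(p) <= max_len)


# ---------------------------------------------------------------------------
# PSM tables

def reporter_columns(psms: pd.DataFrame) -> List[str]:
    """The reporter-channel columns of a PSM table (all non-key columns)."""
    return [c for c in psms.columns if c not in PSM_KEY_COLUMNS]


def strip_modifications(peptide: str) -> str:
    """Collapse a modified peptide string to its bare sequence.

    Removes bracketed/parenthesised mass tags and lowercase markers, e.g.
    ``"AC[+57.0215]DEK"`` -> ``"ACDEK"``.
    """
    return re.sub(r"[\[\(][^\]\)]*[\]\)]|[^A-Z]", "", peptide)


def filter_psms(
    psms: pd.DataFrame,
    expectation_threshold: float = DEFAULT_EXPECTATION_THRESHOLD,
) -> pd.DataFrame:
    """High-confidence PSMs: expectation strictly below the threshold and at
    least one positive reporter intensity.  Order-preserving."""
    channels = reporter_columns(psms)
    conf = psms["expectation"] < expectation_threshold
    has_reporter = (psms[channels].fillna(0) > 0).any(axis=1)
    return psms.loc[conf & has_reporter].copy()


def read_psms(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_psms(psms: pd.DataFrame, path) -> None:
    psms.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# plex design


@dataclass
class PlexDesign:
    """Mapping of TMT channels to samples, one pooled-reference channel per plex.

    Backed by a table with columns plex_id, channel, sample_id, is_reference.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"plex_id", "channel", "sample_id", "is_reference"}
        if not required.issubset(self.table.columns):
            raise HlaQuantError(f"plex design must have columns {sorted(required)}")
        self.table = self.table.copy()
        self.table["is_reference"] = self.table["is_reference"].astype(bool)
        for plex_id, grp in self.table.groupby("plex_id"):
            if grp["is_reference"].sum() != 1:
                raise HlaQuantError(
                    f"plex {plex_id} must have exactly one reference channel"
                )
            if grp["channel"].duplicated().any():
                raise HlaQuantError(f"duplicate channel labels in plex {plex_id}")

    @property
    def plex_ids(self) -> List:
        return sorted(self.table["plex_id"].unique().tolist())

    def reference_channel(self, plex_id) -> str:
        grp = self.table[self.table["plex_id"] == plex_id]
        if grp.empty:
            raise HlaQuantError(f"unknown plex id {plex_id!r}")
        return str(grp.loc[grp["is_reference"], "channel"].iloc[0])

    def sample_channels(self, plex_id) -> Dict[str, str]:
        """sample_id -> channel for the non-reference members of a plex."""
        grp = self.table[(self.table["plex_id"] == plex_id) & ~self.table["is_reference"]]
        return dict(zip(grp["sample_id"].astype(str), grp["channel"].astype(str)))

    @classmethod
    def read(cls, path) -> "PlexDesign":
        return cls(pd.read_csv(path, sep="\t"))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peptide specificity


class SpecificityClass(str, Enum):
    DISCARD_NONHLA_OVERLAP = "discard_nonhla_overlap"
    DISCARD_MULTI_HLA_GENE = "discard_multi_hla_gene"
    HLA_GENE_SPECIFIC = "hla_gene_specific"


class AlleleResolution(str, Enum):
    ALLELE_SPECIFIC = "allele_specific"
    ALLELE_SHARED = "allele_shared"
    UNMATCHED = "unmatched"


@dataclass(frozen=True)
class PeptideSpecificity:
    """Sample-independent classification of one peptide against the search DB."""

    peptide: str
    hit_genes: FrozenSet[str]
    hit_hla_alleles: FrozenSet[AlleleName]
    spec_class: SpecificityClass

    @property
    def hla_gene(self) -> Optional[str]:
        if self.spec_class is SpecificityClass.HLA_GENE_SPECIFIC:
            return next(iter(self.hit_genes))
        return None


@dataclass(frozen=True)
class GenotypeMatch:
    """Per-sample specificity of an HLA-gene-specific peptide."""

    peptide: str
    sample_id: str
    genotype_matched: bool
    resolution: AlleleResolution
    allele: Optional[AlleleName] = None  # set for allele-specific peptides


def _canon(seq: str, collapse_il: bool) -> str:
    return seq.replace("I", "L") if collapse_il else seq


def classify_specificity(
    peptide: str, search_db: SearchDatabase, collapse_il: bool = False
) -> PeptideSpecificity:
    """Classify a peptide by exact substring matching against the search DB.

    ``hla_gene_specific`` requires that every hit is an HLA record and all
    hits fall on a single HLA gene.  Peptides touching any non-HLA record
    (standard proteome or contaminant) are discarded as non-HLA overlap;
    peptides spanning several HLA genes are discarded as multi-gene.
    I and L are treated as distinct residues unless *collapse_il*.
    """
    pep = _canon(peptide, collapse_il)
    hit_genes: Set[str] = set()
    hit_alleles: Set[AlleleName] = set()
    non_hla_hit = False
    for rec in search_db.records:
        if pep in _canon(rec.sequence, collapse_il):
            if rec.provenance == PROVENANCE_HLA:
                hit_genes.add(rec.gene)
                if rec.allele is not None:
                    hit_alleles.add(rec.allele.drop_field3())
            else:
                non_hla_hit = True
                hit_genes.add(rec.gene)
    hla_genes = {g for g in hit_genes if g.startswith("HLA-")}
    if non_hla_hit or not hla_genes:
        cls = SpecificityClass.DISCARD_NONHLA_OVERLAP
    elif len(hla_genes) > 1:
        cls = SpecificityClass.DISCARD_MULTI_HLA_GENE
    else:
        cls = SpecificityClass.HLA_GENE_SPECIFIC
    return PeptideSpecificity(
        peptide=peptide,
        hit_genes=frozenset(hit_genes),
        hit_hla_alleles=frozenset(hit_alleles),
        spec_class=cls,
    )


def match_to_genotype(
    spec: PeptideSpecificity,
    genotype: Genotype,
    db: AlleleDatabase,
    collapse_il: bool = False,
) -> GenotypeMatch:
    """Match an HLA-gene-specific peptide against one sample's genotype.

    The peptide is genotype-matched when its sequence occurs verbatim in the
    protein sequence of at least one of the sample's two alleles;
    allele-specific when it occurs in exactly one of a heterozygous pair.
    """
    if spec.spec_class is not SpecificityClass.HLA_GENE_SPECIFIC:
        raise HlaQuantError(
            "match_to_genotype requires an HLA-gene-specific peptide"
        )
    pep = _canon(spec.peptide, collapse_il)
    matched_alleles = []
    for allele in genotype.distinct_alleles:
        rec = db.resolve(allele)
        if pep in _canon(rec.protein, collapse_il):
            matched_alleles.append(allele)
    if not matched_alleles:
        return GenotypeMatch(
            spec.peptide, genotype.sample_id, False, AlleleResolution.UNMATCHED
        )
    if genotype.homozygous or len(matched_alleles) == 2:
        return GenotypeMatch(
            spec.peptide, genotype.sample_id, True, AlleleResolution.ALLELE_SHARED
        )
    return GenotypeMatch(
        spec.peptide,
        genotype.sample_id,
        True,
        AlleleResolution.ALLELE_SPECIFIC,
        allele=matched_alleles[0],
    )


# ---------------------------------------------------------------------------
# reporter aggregation and ratios


def aggregate_peptides(psms: pd.DataFrame, design: Optional[PlexDesign] = None) -> pd.DataFrame:
    """Sum reporter intensities per (peptide, plex) over scans, charges and
    fractions.  Missing channel values contribute zero.  Returns a frame
    indexed by (peptide, plex_id) with one column per channel."""
    if design is not None:
        known = set(design.plex_ids)
        unknown = set(psms["plex_id"].unique()) - known
        if unknown:
            raise HlaQuantError(f"unknown plex id(s) in PSM table: {sorted(unknown)}")
    channels = reporter_columns(psms)
    work = psms.copy()
    work["peptide"] = work["peptide"].map(strip_modifications)
    agg = work.groupby(["peptide", "plex_id"], sort=True)[channels].sum(min_count=1)
    return agg.fillna(0.0)


def peptide_log_ratio(
    agg: pd.DataFrame,
    design: PlexDesign,
    floor: float = 0.0,
    center: bool = True,
) -> pd.DataFrame:
    """Per-peptide log2 ratio of each sample channel to the plex's pooled
    reference, median-centered per sample across peptides.

    Returns a long frame with columns peptide, sample_id, plex_id,
    log2_ratio.  Centering offsets are stored in ``result.attrs["centering"]``.
    """
    rows = []
    for (peptide, plex_id), intens in agg.iterrows():
        ref_channel = design.reference_channel(plex_id)
        ref = float(intens.get(ref_channel, 0.0))
        if ref + floor <= 0:
            raise UndefinedRatioError(
                f"zero reference intensity for peptide {peptide!r} in plex "
                f"{plex_id!r} with floor {floor}"
            )
        for sample_id, channel in design.sample_channels(plex_id).items():
            value = float(intens.get(channel, 0.0))
            if value + floor <= 0:
                continue  # peptide not observed in this channel
            rows.append(
                {
                    "peptide": peptide,
                    "sample_id": sample_id,
                    "plex_id": plex_id,
                    "log2_ratio": np.log2((value + floor) / (ref + floor)),
                }
            )
    ratios = pd.DataFrame(rows, columns=["peptide", "sample_id", "plex_id", "log2_ratio"])
    offsets = {}
    if center and not ratios.empty:
        med = ratios.groupby("sample_id")["log2_ratio"].transform("median")
        offsets = (
            ratios.groupby("sample_id")["log2_ratio"].median().to_dict()
        )
        ratios["log2_ratio"] = ratios["log2_ratio"] - med
    ratios.attrs["centering"] = offsets
    return ratios


# ---------------------------------------------------------------------------
# protein abundance


def protein_abundance(
    agg: pd.DataFrame,
    design: PlexDesign,
    specificity: Dict[str, PeptideSpecificity],
    mode: str,
    genotypes: Optional[Dict[str, Dict[str, Genotype]]] = None,
    db: Optional[AlleleDatabase] = None,
    floor: float = 0.0,
    collapse_il: bool = False,
) -> pd.DataFrame:
    """Sample-level protein abundance as log2 ratio of summed intensities.

    mode ``whole_proteome_gene``: peptides hitting exactly one gene are
    summed per gene.  mode ``hla_gene``: only genotype-matched,
    HLA-gene-specific peptides of the sample contribute.  mode
    ``hla_allele``: only allele-specific peptides, one feature per allele.
    *genotypes* maps sample_id -> gene (A/B/C) -> Genotype and is required for
    the HLA modes.  Features with no contributing peptide are absent rather
    than zero.

    Returns columns sample_id, feature, log2_ratio, n_peptides.
    """
    if mode not in {"whole_proteome_gene", "hla_gene", "hla_allele"}:
        raise HlaQuantError(f"unknown protein abundance mode {mode!r}")
    if mode != "whole_proteome_gene" and (genotypes is None or db is None):
        raise HlaQuantError(f"mode {mode!r} requires genotypes and an allele database")

    # accumulate per (sample, feature): [sample_sum, ref_sum, peptide set]
    acc: Dict[tuple, list] = {}

    for (peptide, plex_id), intens in agg.iterrows():
        spec = specificity.get(peptide)
        if spec is None:
            continue
        ref_channel = design.reference_channel(plex_id)
        ref = float(intens.get(ref_channel, 0.0))
        for sample_id, channel in design.sample_channels(plex_id).items():
            value = float(intens.get(channel, 0.0))
            features = _peptide_features(
                spec, sample_id, mode, genotypes, db, collapse_il
            )
            for feature in features:
                key = (sample_id, feature)
                entry = acc.setdefault(key, [0.0, 0.0, set()])
                entry[0] += value
                entry[1] += ref
                entry[2].add(peptide)

    rows = []
    for (sample_id, feature), (s_sum, r_sum, peptides) in sorted(acc.items()):
        if s_sum + floor <= 0 or r_sum + floor <= 0:
            continue
        rows.append(
            {
                "sample_id": sample_id,
                "feature": feature,
                "log2_ratio": np.log2((s_sum + floor) / (r_sum + floor)),
                "n_peptides": len(peptides),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "feature", "log2_ratio", "n_peptides"])


def _peptide_features(
    spec: PeptideSpecificity,
    sample_id: str,
    mode: str,
    genotypes,
    db,
    collapse_il: bool,
) -> List[str]:
    if mode == "whole_proteome_gene":
        if len(spec.hit_genes) == 1:
            return [next(iter(spec.hit_genes))]
        return []
    if spec.spec_class is not SpecificityClass.HLA_GENE_SPECIFIC:
        return []
    gene_symbol = spec.hla_gene  # e.g. "HLA-A"
    locus = gene_symbol.split("-")[1]
    sample_genotypes = genotypes.get(sample_id, {})
    genotype = sample_genotypes.get(locus)
    if genotype is None:
        return []
    match = match_to_genotype(spec, genotype, db, collapse_il=collapse_il)
    if mode == "hla_gene":
        return [gene_symbol] if match.genotype_matched else []
    # hla_allele
    if match.resolution is AlleleResolution.ALLELE_SPECIFIC:
        return [match.allele.render()]
    return []


def center_per_feature(abundance: pd.DataFrame) -> pd.DataFrame:
    """Median-center log2 ratios per feature across samples (whole-proteome
    convention)."""
    out = abundance.copy()
    med = out.groupby("feature")["log2_ratio"].transform("median")
    out["log2_ratio"] = out["log2_ratio"] - med
    return out


# ---------------------------------------------------------------------------
# matched vs unmatched peptide comparison


@dataclass(frozen=True)
class MatchedUnmatchedResult:
    """Paired comparison of genotype-matched vs unmatched peptide medians."""

    gene: str
    n_samples: int
    mean_difference: float  # matched minus unmatched, log2
    se: float
    t: float
    p: float
    computable: bool = True
    sample_medians: Optional[pd.DataFrame] = None


def matched_vs_unmatched_stats(
    peptide_ratios: pd.DataFrame,
    matches: Iterable[GenotypeMatch],
    gene: str = "HLA-A",
) -> MatchedUnmatchedResult:
    """Paired t-test of per-sample median matched vs unmatched peptide ratios.

    *peptide_ratios* is the long frame from :func:`peptide_log_ratio`
    restricted to HLA-gene-specific peptides of *gene*; *matches* supplies
    the per-(sample, peptide) genotype-match flags.  Samples lacking either a
    matched or an unmatched peptide are dropped; with fewer than two usable
    samples the result is flagged not computable.
    """
    flag = {(m.sample_id, m.peptide): m.genotype_matched for m in matches}
    work = peptide_ratios.copy()
    work["matched"] = [
        flag.get((s, p)) for s, p in zip(work["sample_id"], work["peptide"])
    ]
    work = work.dropna(subset=["matched"])
    med = (
        work.groupby(["sample_id", "matched"])["log2_ratio"]
        .median()
        .unstack("matched")
    )
    med = med.dropna()
    if med.shape[0] < 2 or True not in med.columns or False not in med.columns:
        return MatchedUnmatchedResult(gene, int(med.shape[0]), np.nan, np.nan,
                                      np.nan, np.nan, computable=False)
    diffs = (med[True] - med[False]).to_numpy(dtype=float)
    n = len(diffs)
    mean_diff = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    se = sd / np.sqrt(n)
    if sd == 0.0:
        # degenerate: identical medians in every sample carry no evidence
        t_stat, p = (0.0, 1.0) if mean_diff == 0 else (np.inf, 0.0)
    else:
        t_stat, p = stats.ttest_rel(med[True], med[False])
        t_stat, p = float(t_stat), float(p)
    return MatchedUnmatchedResult(
        gene=gene,
        n_samples=n,
        mean_difference=mean_diff,
        se=se,
        t=t_stat,
        p=p,
        sample_medians=med,
    )
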