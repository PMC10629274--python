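"""Cohort-level statistics on HLA-I genotypes and expression.

Covers homozygosity rates, paired tumor/normal differential expression from
peptide-level quantities (with BH multiple-testing control and allele-level
fold-change flags), allele-group frequency enrichment against
ancestry-weighted population frequencies, and a small variance-partition
helper quantifying how much of protein variation a covariate explains beyond
RNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import HlaQuantError
from .nomenclature import AlleleName, allele_group
from .references import Genotype

DEFAULT_ALPHA = 0.05
MIN_ALLELE_PEPTIDES = 3


# ---------------------------------------------------------------------------
# homozygosity


def homozygosity_rates(
    genotypes: Iterable[Genotype],
    tissue_of: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Fraction of homozygous genotypes per gene (and tissue when a
    sample -> tissue mapping is given)."""
    rows = []
    for g in genotypes:
        rows.append(
            {
                "gene": g.gene,
                "tissue": tissue_of.get(g.sample_id, "all") if tissue_of else "all",
                "homozygous": g.homozygous,
            }
        )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return pd.DataFrame(columns=["tissue", "gene", "n", "n_homozygous", "rate"])
    out = (
        frame.groupby(["tissue", "gene"])["homozygous"]
        .agg(n="size", n_homozygous="sum")
        .reset_index()
    )
    out["rate"] = out["n_homozygous"] / out["n"]
    return out


# ---------------------------------------------------------------------------
# paired tumor/normal differential expression


class Direction(str, Enum):
    OVER = "over"
    UNDER = "under"
    NS = "ns"


@dataclass
class PairedComparison:
    patient_id: str
    gene: str
    log2fc_protein: float
    p: float
    p_adj: Optional[float] = None
    direction: Direction = Direction.NS
    n_tumor_peptides: int = 0
    n_normal_peptides: int = 0
    computable: bool = True
    log2fc_rna: Optional[float] = None


def paired_differential(
    tumor_peptide_ratios: Mapping[str, Sequence[float]],
    normal_peptide_ratios: Mapping[str, Sequence[float]],
    gene: str = "HLA-A",
    alpha: float = DEFAULT_ALPHA,
    pooled: bool = False,
) -> List[PairedComparison]:
    """Per-patient tumor vs normal t-test on eligible peptide log2 ratios.

    Inputs map patient id to that patient's genotype-matched peptide log2
    ratios in tumor and normal tissue.  Welch's unequal-variance t-test by
    default (``pooled=True`` for the classical pooled-variance test); BH
    adjustment is applied across patients; direction is assigned at the
    adjusted *alpha*.
    """
    comparisons: List[PairedComparison] = []
    for patient in sorted(set(tumor_peptide_ratios) | set(normal_peptide_ratios)):
        t_vals = np.asarray(tumor_peptide_ratios.get(patient, ()), dtype=float)
        n_vals = np.asarray(normal_peptide_ratios.get(patient, ()), dtype=float)
        if len(t_vals) < 2 or len(n_vals) < 2:
            comparisons.append(
                PairedComparison(patient, gene, np.nan, np.nan,
                                 n_tumor_peptides=len(t_vals),
                                 n_normal_peptides=len(n_vals),
                                 computable=False)
            )
            continue
        log2fc = float(np.mean(t_vals) - np.mean(n_vals))
        if np.std(t_vals, ddof=1) == 0 and np.std(n_vals, ddof=1) == 0:
            p = 1.0 if log2fc == 0 else 0.0
        else:
            _, p = sps.ttest_ind(t_vals, n_vals, equal_var=pooled)
            p = float(p)
        comparisons.append(
            PairedComparison(patient, gene, log2fc, p,
                             n_tumor_peptides=len(t_vals),
                             n_normal_peptides=len(n_vals))
        )
    usable = [c for c in comparisons if c.computable]
    if usable:
        adj = benjamini_hochberg([c.p for c in usable])
        for c, pa in zip(usable, adj):
            c.p_adj = float(pa)
            if c.p_adj < alpha:
                c.direction = Direction.OVER if c.log2fc_protein > 0 else Direction.UNDER
            else:
                c.direction = Direction.NS
    return comparisons


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, never below the raw p)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def comparisons_to_frame(comparisons: Sequence[PairedComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "gene": c.gene,
                "log2fc_protein": c.log2fc_protein,
                "p": c.p,
                "p_adj": c.p_adj,
                "direction": c.direction.value,
                "n_tumor_peptides": c.n_tumor_peptides,
                "n_normal_peptides": c.n_normal_peptides,
                "computable": c.computable,
            }
            for c in comparisons
        ]
    )


# ---------------------------------------------------------------------------
# allele-level fold changes


@dataclass(frozen=True)
class AlleleFoldChange:
    patient_id: str
    allele: AlleleName
    log2fc_protein: float
    n_peptides_tumor: int
    n_peptides_normal: int
    flag20: bool
    flag30: bool
    log2fc_rna: Optional[float] = None


def allele_fold_changes(
    tumor_allele_quant: pd.DataFrame,
    normal_allele_quant: pd.DataFrame,
    significant_patients: Iterable[str],
    tumor_sample_of: Mapping[str, str],
    normal_sample_of: Mapping[str, str],
    rna_allele_log2fc: Optional[Mapping[tuple, float]] = None,
    min_peptides: int = MIN_ALLELE_PEPTIDES,
) -> List[AlleleFoldChange]:
    """Per-allele tumor/normal fold changes from allele-specific peptides.

    *tumor_allele_quant* / *normal_allele_quant* are ``protein_abundance``
    outputs in ``hla_allele`` mode (features are allele names).  Only
    patients flagged significant by the paired differential test are
    considered, and an allele needs at least *min_peptides* unique
    allele-specific peptides in both tissues to be reported.  ``flag20``
    marks a linear fold change deviating from 1 by more than 20%;
    ``flag30`` marks over 30% overexpression.
    """
    t_idx = tumor_allele_quant.set_index(["sample_id", "feature"])
    n_idx = normal_allele_quant.set_index(["sample_id", "feature"])
    out: List[AlleleFoldChange] = []
    for patient in sorted(set(significant_patients)):
        t_sample = tumor_sample_of.get(patient)
        n_sample = normal_sample_of.get(patient)
        if t_sample is None or n_sample is None:
            continue
        t_rows = t_idx.loc[[t_sample]] if t_sample in t_idx.index.get_level_values(0) else None
        if t_rows is None:
            continue
        for (_, feature), t_row in t_rows.iterrows():
            key = (n_sample, feature)
            if key not in n_idx.index:
                continue
            n_row = n_idx.loc[key]
            if (
                t_row["n_peptides"] < min_peptides
                or n_row["n_peptides"] < min_peptides
            ):
                continue
            log2fc = float(t_row["log2_ratio"] - n_row["log2_ratio"])
            fc = 2.0 ** log2fc
            from .nomenclature import parse_allele

            out.append(
                AlleleFoldChange(
                    patient_id=patient,
                    allele=parse_allele(feature),
                    log2fc_protein=log2fc,
                    n_peptides_tumor=int(t_row["n_peptides"]),
                    n_peptides_normal=int(n_row["n_peptides"]),
                    flag20=abs(fc - 1.0) > 0.2,
                    flag30=fc > 1.3,
                    log2fc_rna=(rna_allele_log2fc or {}).get((patient, feature)),
                )
            )
    return out


# ---------------------------------------------------------------------------
# allele-group frequency enrichment


@dataclass(frozen=True)
class FrequencyEnrichment:
    group: str
    observed_count: int
    total_alleles: int
    observed_af: float
    expected_af: float
    excess: float
    p: float
    p_adj: float
    enriched: bool


def allele_frequency_enrichment(
    genotypes: Iterable[Genotype],
    expected_afs: Mapping[str, Mapping[str, float]],
    ancestry_weights: Mapping[str, float],
    alpha: float = DEFAULT_ALPHA,
    min_excess: float = 0.5,
) -> List[FrequencyEnrichment]:
    """Allele-group frequency enrichment against population expectations.

    *expected_afs* maps ancestry -> {allele-group label -> frequency};
    *ancestry_weights* gives the cohort's ancestry composition (summing to
    one).  Each patient contributes two alleles per gene; the observed count
    of each group is tested against the ancestry-weighted expected frequency
    with a two-sided exact binomial test, BH-adjusted across groups within
    each gene.  A group is enriched when the adjusted p-value is below
    *alpha* and the observed frequency exceeds the expectation by more than
    *min_excess* (e.g. 0.5 = 50% higher than expected).
    """
    genotypes = list(genotypes)
    weight_sum = sum(ancestry_weights.values())
    if not np.isclose(weight_sum, 1.0):
        raise HlaQuantError("ancestry weights must sum to 1")
    by_gene: Dict[str, List[str]] = {}
    for g in genotypes:
        by_gene.setdefault(g.gene, []).extend(
            allele_group(a) for a in g.alleles
        )
    results: List[FrequencyEnrichment] = []
    for gene in sorted(by_gene):
        groups = pd.Series(by_gene[gene]).value_counts()
        total = int(groups.sum())
        rows = []
        for group, count in sorted(groups.items()):
            expected = 0.0
            known = False
            for ancestry, weight in ancestry_weights.items():
                af = expected_afs.get(ancestry, {}).get(group)
                if af is not None:
                    expected += weight * af
                    known = True
            if not known or expected <= 0:
                import warnings

                warnings.warn(
                    f"allele group {group} absent from the expected "
                    "frequency table; excluded from enrichment",
                    stacklevel=2,
                )
                continue
            p = sps.binomtest(int(count), total, expected, alternative="two-sided").pvalue
            rows.append((group, int(count), expected, float(p)))
        if not rows:
            continue
        adj = benjamini_hochberg([r[3] for r in rows])
        for (group, count, expected, p), p_adj in zip(rows, adj):
            observed = count / total
            excess = observed / expected - 1.0
            results.append(
                FrequencyEnrichment(
                    group=group,
                    observed_count=count,
                    total_alleles=total,
                    observed_af=observed,
                    expected_af=expected,
                    excess=excess,
                    p=p,
                    p_adj=float(p_adj),
                    enriched=bool(p_adj < alpha and excess > min_excess),
                )
            )
    return results


def enrichment_to_frame(results: Sequence[FrequencyEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "observed_count": r.observed_count,
                "total_alleles": r.total_alleles,
                "observed_af": r.observed_af,
                "expected_af": r.expected_af,
                "excess": r.excess,
                "p": r.p,
                "p_adj": r.p_adj,
                "enriched": r.enriched,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# variance partition (protein ~ rna [+ score])


@dataclass(frozen=True)
class VariancePartition:
    r2_base: float
    r2_full: float
    coef_score: float
    coef_score_se: float
    residual_score_correlation: float
    n: int
    collinear: bool = False


def variance_partition(
    protein: Sequence[float],
    rna: Sequence[float],
    score: Sequence[float],
) -> VariancePartition:
    """R-squared gain of adding a covariate to the protein ~ RNA model.

    Fits ordinary least squares ``protein ~ rna`` and
    ``protein ~ rna + score`` and reports both R², the covariate's
    coefficient (with SE) and the correlation of the base-model residuals
    with the covariate.
    """
    protein = np.asarray(protein, dtype=float)
    rna = np.asarray(rna, dtype=float)
    score = np.asarray(score, dtype=float)
    mask = np.isfinite(protein) & np.isfinite(rna) & np.isfinite(score)
    protein, rna, score = protein[mask], rna[mask], score[mask]
    n = len(protein)
    if n < 3:
        raise HlaQuantError("variance partition needs at least 3 complete samples")
    if np.std(rna) == 0 or np.std(score) == 0:
        raise HlaQuantError("predictors must not be constant")
    x_base = sm.add_constant(rna)
    x_full = sm.add_constant(np.column_stack([rna, score]))
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        base = sm.OLS(protein, x_base).fit()
        return VariancePartition(
            r2_base=float(base.rsquared),
            r2_full=np.nan,
            coef_score=np.nan,
            coef_score_se=np.nan,
            residual_score_correlation=np.nan,
            n=n,
            collinear=True,
        )
    base = sm.OLS(protein, x_base).fit()
    full = sm.OLS(protein, x_full).fit()
    resid_corr = float(np.corrcoef(base.resid, score)[0, 1])
    return VariancePartition(
        r2_base=float(base.rsquared),
        r2_full=float(full.rsquared),
        coef_score=float(full.params[2]),
        coef_score_se=float(full.bse[2]),
        residual_score_correlation=resid_corr,
        n=n,
    )


# ---------------------------------------------------------------------------
# correlation


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    p: float
    n: int
    defined: bool = True


def correlation(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a defined-ness flag for constant
    input; Spearman uses average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise HlaQuantError("correlation needs at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(method, np.nan, np.nan, len(x), defined=False)
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise HlaQuantError(f"unknown correlation method {method!r}")
    return CorrelationResult(method, float(r), float(p), len(x))
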