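"""Allele-level RNA quantification and normalization.

HLA-I genes are quantified per allele against the sample's personalized
reference: reads compatible with exactly one of the two genotype alleles
count fully to it, reads compatible with both are split evenly (the EM fixed
point under uniform priors for a two-allele reference).  Counts are
normalized per sample to a log2 scale with a pseudocount — a deliberately
simple, documented variance-taming transform — and the gene total of a
heterozygous sample is the log-sum of its two alleles.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .errors import HlaQuantError
from .genotyping import CompatibilityMatrix, nonshared_counts
from .nomenclature import AlleleName
from .references import Genotype

METHOD_MEDIAN_RATIO = "median_ratio"
METHOD_COLUMN_SUM = "column_sum"


def quantify_alleles(
    compat: CompatibilityMatrix, genotype: Genotype
) -> Dict[str, float]:
    """Per-allele read counts under the even-split rule.

    Returns a mapping from canonical allele name to (possibly fractional)
    count.  Homozygous genotypes receive all compatible reads on the single
    allele.
    """
    if genotype.homozygous:
        a = genotype.alleles[0]
        return {a.render(): float(np.sum(compat.column(a)))}
    a, b = genotype.alleles
    shared, only_a, only_b = nonshared_counts(compat, a, b)
    return {
        a.render(): only_a + shared / 2.0,
        b.render(): only_b + shared / 2.0,
    }


def normalize(
    counts: pd.DataFrame,
    pseudocount: float = 1.0,
    method: str = "auto",
) -> pd.DataFrame:
    """Library-size normalization to a log2 scale.

    Size factors are median-of-ratios (DESeq-style) when every feature is
    positive in every sample, else column-sum scaling (column sum over the
    mean of column sums).  The normalized value is
    ``log2(count / size_factor + pseudocount)``.  The method and pseudocount
    are recorded in ``result.attrs``.
    """
    counts = counts.astype(float)
    if (counts < 0).any().any():
        raise HlaQuantError("count table contains negative values")
    col_sums = counts.sum(axis=0)
    zero_cols = col_sums[col_sums == 0]
    if len(zero_cols):
        raise HlaQuantError(
            f"all-zero sample(s): {', '.join(map(str, zero_cols.index))}"
        )
    if method == "auto":
        method = (
            METHOD_MEDIAN_RATIO
            if (counts > 0).all().all() and counts.shape[0] >= 1
            else METHOD_COLUMN_SUM
        )
    if method == METHOD_MEDIAN_RATIO:
        log_geomean = np.log(counts).mean(axis=1)
        size_factors = np.exp(
            np.log(counts).sub(log_geomean, axis=0).median(axis=0)
        )
    elif method == METHOD_COLUMN_SUM:
        size_factors = col_sums / col_sums.mean()
    else:
        raise HlaQuantError(f"unknown normalization method {method!r}")
    normed = np.log2(counts.div(size_factors, axis=1) + pseudocount)
    normed.attrs["method"] = method
    normed.attrs["pseudocount"] = pseudocount
    normed.attrs["size_factors"] = size_factors.to_dict()
    return normed


def gene_total_from_alleles(
    allele_expr: Tuple[float, float] | float, homozygous: bool = False
) -> float:
    """Gene-level log2 expression from allele-level log2 values.

    Heterozygous: ``log2(2**a1 + 2**a2)``; homozygous: the single allele's
    value unchanged.
    """
    if homozygous:
        if isinstance(allele_expr, (tuple, list)):
            return float(allele_expr[0])
        return float(allele_expr)
    a1, a2 = allele_expr
    return float(np.log2(2.0 ** a1 + 2.0 ** a2))


def write_expression(frame: pd.DataFrame, path) -> None:
    """TSV with a one-line metadata header (#method=, #pseudocount=)."""
    with open(path, "w") as fh:
        method = frame.attrs.get("method", "none")
        pseudocount = frame.attrs.get("pseudocount", "")
        fh.write(f"#method={method}\t#pseudocount={pseudocount}\n")
        frame.to_csv(fh, sep="\t")


def read_expression(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().strip()
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    attrs = {}
    for token in header.lstrip("#").split("\t"):
        key, _, value = token.lstrip("#").partition("=")
        attrs[key] = value
    frame.attrs.update(attrs)
    return frame
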