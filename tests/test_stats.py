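"""Cohort statistics: homozygosity, differential tests, enrichment,
variance partition, correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hlaquant.errors import HlaQuantError
from hlaquant.stats import (
    Direction,
    allele_fold_changes,
    allele_frequency_enrichment,
    benjamini_hochberg,
    correlation,
    homozygosity_rates,
    paired_differential,
    variance_partition,
)

from conftest import make_genotype


# ---------------------------------------------------------------------------
# homozygosity


def test_homozygosity_counting():
    genos = [
        make_genotype(f"s{i}", "A*24:02P", "A*24:02P") for i in range(3)
    ] + [
        make_genotype(f"s{i+3}", "A*24:02P", "A*25:01P") for i in range(7)
    ]
    rates = homozygosity_rates(genos)
    assert rates.loc[0, "rate"] == pytest.approx(0.30)
    all_het = homozygosity_rates(
        [make_genotype("x", "B*13:02P", "B*15:01P")]
    )
    assert all_het.loc[0, "rate"] == 0.0


def test_homozygosity_stratified_by_tissue():
    genos = [
        make_genotype("t1", "A*24:02P", "A*24:02P"),
        make_genotype("n1", "A*24:02P", "A*25:01P"),
    ]
    rates = homozygosity_rates(genos, {"t1": "T", "n1": "N"})
    by = rates.set_index("tissue")["rate"]
    assert by["T"] == 1.0 and by["N"] == 0.0


# ---------------------------------------------------------------------------
# BH adjustment: independent step-up oracle


def bh_oracle(pvals):
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        value = min(prev, pvals[idx] * m / rank)
        adj[idx] = value
        prev = value
    return adj


def test_bh_worked_example():
    adj = benjamini_hochberg([0.01, 0.02, 0.04])
    assert np.allclose(adj, [0.03, 0.03, 0.04])


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=30))
def test_bh_matches_oracle_and_is_monotone(pvals):
    adj = benjamini_hochberg(pvals)
    assert np.allclose(adj, bh_oracle(np.asarray(pvals)))
    assert (adj >= np.asarray(pvals) - 1e-12).all()
    order = np.argsort(pvals)
    assert (np.diff(adj[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# paired differential


def welch_t_oracle(x, y):
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t_stat = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return t_stat, 2 * tdist.sf(abs(t_stat), df)


def test_paired_differential_strong_effect():
    comps = paired_differential(
        {"P1": [2.0, 2.1, 1.9]}, {"P1": [0.0, 0.1, -0.1]}
    )
    c = comps[0]
    assert c.log2fc_protein == pytest.approx(2.0)
    _, p_ref = welch_t_oracle([2.0, 2.1, 1.9], [0.0, 0.1, -0.1])
    assert c.p == pytest.approx(p_ref)
    assert c.direction is Direction.OVER


def test_paired_differential_null_and_insufficient():
    comps = paired_differential(
        {"P1": [1.0, 1.0, 1.0], "P2": [0.5]},
        {"P1": [1.0, 1.0, 1.0], "P2": [0.5, 0.4]},
    )
    by = {c.patient_id: c for c in comps}
    assert by["P1"].log2fc_protein == 0.0
    assert by["P1"].direction is Direction.NS
    assert not by["P2"].computable
    assert by["P1"].p_adj >= by["P1"].p


# ---------------------------------------------------------------------------
# allele fold-change flags


def _allele_quant(sample, feature, log2_ratio, n_peptides):
    return {"sample_id": sample, "feature": feature,
            "log2_ratio": log2_ratio, "n_peptides": n_peptides}


def test_allele_fold_change_flags_and_min_peptides():
    tumor = pd.DataFrame([
        _allele_quant("P1-T", "A*24:02P", np.log2(1.35), 4),
        _allele_quant("P1-T", "A*25:01P", np.log2(1.10), 5),
        _allele_quant("P2-T", "A*24:02P", np.log2(2.0), 5),
    ])
    normal = pd.DataFrame([
        _allele_quant("P1-N", "A*24:02P", 0.0, 3),
        _allele_quant("P1-N", "A*25:01P", 0.0, 3),
        _allele_quant("P2-N", "A*24:02P", 0.0, 2),  # below the 3-peptide rule
    ])
    out = allele_fold_changes(
        tumor, normal, ["P1", "P2"],
        {"P1": "P1-T", "P2": "P2-T"}, {"P1": "P1-N", "P2": "P2-N"},
    )
    by = {(r.patient_id, r.allele.render()): r for r in out}
    r135 = by[("P1", "A*24:02P")]
    assert r135.flag20 and r135.flag30
    r110 = by[("P1", "A*25:01P")]
    assert not r110.flag20
    assert ("P2", "A*24:02P") not in by  # insufficient normal peptides


# ---------------------------------------------------------------------------
# allele-group frequency enrichment


def exact_binom_oracle(k, n, p):
    """Two-sided exact binomial p-value by enumeration (min-likelihood)."""
    pk = math.comb(n, k) * p**k * (1 - p) ** (n - k)
    total = 0.0
    for i in range(n + 1):
        pi = math.comb(n, i) * p**i * (1 - p) ** (n - i)
        if pi <= pk * (1 + 1e-9):
            total += pi
    return min(total, 1.0)


def _cohort(counts):
    """counts: mapping group-number -> patient count, gene B, homozygous for
    simplicity so allele counts are 2x patients."""
    genos = []
    i = 0
    for group, n in counts.items():
        for _ in range(n):
            genos.append(
                make_genotype(f"s{i}", f"B*{group:02d}:01", f"B*{group:02d}:01")
            )
            i += 1
    return genos


def test_enrichment_excess_formula():
    # observed 18.9% vs expected 10.74% -> about 76% more than expected
    genos = _cohort({15: 17, 7: 73})  # 34 of 180 alleles ~ 18.9%
    expected = {"pop": {"B*15": 0.1074, "B*07": 0.8}}
    out = allele_frequency_enrichment(genos, expected, {"pop": 1.0})
    b15 = next(r for r in out if r.group == "B*15")
    assert b15.observed_af == pytest.approx(0.1889, abs=1e-3)
    assert b15.excess == pytest.approx(0.759, abs=0.01)
    assert b15.p == pytest.approx(
        exact_binom_oracle(b15.observed_count, b15.total_alleles, 0.1074)
    )
    assert b15.enriched


def test_enrichment_null_group_not_flagged():
    genos = _cohort({15: 10, 7: 90})
    expected = {"pop": {"B*15": 0.10, "B*07": 0.90}}
    out = allele_frequency_enrichment(genos, expected, {"pop": 1.0})
    b15 = next(r for r in out if r.group == "B*15")
    assert b15.excess == pytest.approx(0.0)
    assert not b15.enriched


def test_enrichment_ancestry_weighting_and_missing_group():
    genos = _cohort({15: 50, 99: 50})
    expected = {"eur": {"B*15": 0.2}, "afr": {"B*15": 0.4}}
    with pytest.warns(UserWarning, match="B\\*99"):
        out = allele_frequency_enrichment(
            genos, expected, {"eur": 0.75, "afr": 0.25}
        )
    b15 = next(r for r in out if r.group == "B*15")
    assert b15.expected_af == pytest.approx(0.25)
    assert all(r.group != "B*99" for r in out)


def test_enrichment_power_on_simulated_cohort():
    """A group drawn at 75% above its population frequency is flagged in a
    cohort contributing a few hundred alleles; a matched group is not."""
    from hlaquant import simulate

    params = simulate.SimParams(n_patients=150, loh_rate=0.0, imbalance_rate=0.0)
    db, truth = simulate.make_allele_db(23, params)
    names = sorted(r.name.render() for r in db if r.name.gene == "A")
    # groups: A*01 covers names[0:2], A*02 covers names[2:4]
    drawn = {"A": dict(zip(names, [0.20, 0.15, 0.35, 0.30]))}
    simulate.make_cohort(db, truth, 23, allele_frequencies=drawn)
    genos = [truth.normal_genotypes[pid]["A"] for pid in truth.normal_genotypes]
    expected = {"pop": {"A*01": 0.20, "A*02": 0.65}}  # A*01 drawn 75% above
    out = allele_frequency_enrichment(genos, expected, {"pop": 1.0})
    by = {r.group: r for r in out}
    assert by["A*01"].enriched
    assert not by["A*02"].enriched


# ---------------------------------------------------------------------------
# variance partition


def test_variance_partition_exact_identity():
    rng = np.random.default_rng(2)
    rna = rng.normal(0, 1, 100)
    score = rng.normal(0, 1, 100)
    protein = rna - score
    res = variance_partition(protein, rna, score)
    assert res.r2_full == pytest.approx(1.0)
    assert res.coef_score == pytest.approx(-1.0)
    assert res.residual_score_correlation < 0


def test_variance_partition_null_covariate():
    rng = np.random.default_rng(3)
    rna = rng.normal(0, 1, 2000)
    protein = rna + rng.normal(0, 0.5, 2000)
    score = rng.normal(0, 1, 2000)
    res = variance_partition(protein, rna, score)
    assert res.r2_full - res.r2_base < 0.01
    assert abs(res.coef_score) < 3 * res.coef_score_se + 0.05


def test_variance_partition_collinear_flag():
    rng = np.random.default_rng(4)
    rna = rng.normal(0, 1, 50)
    res = variance_partition(rna + rng.normal(0, 0.1, 50), rna, 2 * rna)
    assert res.collinear
    assert math.isnan(res.coef_score)


def test_variance_partition_recovers_injected_effect():
    """coef_score lands within 2 SE of the injected coefficient in >=95% of
    replicates (a GBM-style protein = rna + beta*score + noise cohort)."""
    rng = np.random.default_rng(5)
    beta = -0.5
    hits = 0
    n_rep = 100
    for _ in range(n_rep):
        rna = rng.normal(0, 1, 80)
        score = rng.normal(0, 1, 80)
        protein = 0.8 * rna + beta * score + rng.normal(0, 0.6, 80)
        res = variance_partition(protein, rna, score)
        hits += abs(res.coef_score - beta) <= 2 * res.coef_score_se
    assert hits >= 0.95 * n_rep - 2


# ---------------------------------------------------------------------------
# correlation


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def test_correlation_methods():
    x = np.array([0.2, 1.0, 1.7, 2.4, 3.9, 5.0])
    assert correlation(x, 2 * x + 1).r == pytest.approx(1.0)
    expy = np.exp(x)
    assert correlation(x, expy, "spearman").r == pytest.approx(1.0)
    assert correlation(x, expy, "pearson").r < 1.0
    y = np.array([1.2, 0.4, 2.2, 1.8, 3.1, 2.5])
    assert correlation(x, y).r == pytest.approx(pearson_oracle(x, y), abs=1e-12)


def test_correlation_constant_input_flagged():
    res = correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert not res.defined
    with pytest.raises(HlaQuantError):
        correlation([1.0, 2.0], [1.0, 2.0])
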