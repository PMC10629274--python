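"""Digestion, PSM filtering, specificity and TMT quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hlaquant.errors import HlaQuantError, UndefinedRatioError
from hlaquant.ms import (
    AlleleResolution,
    PlexDesign,
    SpecificityClass,
    aggregate_peptides,
    classify_specificity,
    digest,
    filter_psms,
    match_to_genotype,
    matched_vs_unmatched_stats,
    peptide_log_ratio,
    protein_abundance,
    strip_modifications,
    GenotypeMatch,
)

import conftest
from conftest import make_genotype


# ---------------------------------------------------------------------------
# digestion: independent brute-force oracle


def brute_force_digest(seq, missed_cleavages, min_len, max_len):
    """Enumerate fragments between all cleavage points directly."""
    cuts = [0]
    for i, ch in enumerate(seq):
        if ch in "KR" and not (i + 1 < len(seq) and seq[i + 1] == "P"):
            if i + 1 not in cuts:
                cuts.append(i + 1)
    if cuts[-1] != len(seq):
        cuts.append(len(seq))
    segments = [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]
    out = set()
    for i in range(len(segments)):
        for j in range(i, min(i + missed_cleavages + 1, len(segments))):
            frag = seq[segments[i][0] : segments[j][1]]
            if min_len <= len(frag) <= max_len:
                out.add(frag)
    return out


@pytest.mark.parametrize(
    "seq, mc, expected",
    [
        ("AKRPGK", 0, {"AK", "RPGK"}),
        ("MKAKR", 1, {"MK", "AK", "R", "MKAK", "AKR"}),
        ("NQSEQVV", 0, {"NQSEQVV"}),  # no cleavage site: whole sequence
    ],
)
def test_digest_examples(seq, mc, expected):
    assert digest(seq, mc, min_len=1, max_len=40) == expected


def test_digest_rejects_invalid_residue():
    with pytest.raises(HlaQuantError, match="position 2"):
        digest("AKXduh", 0)


@settings(derandomize=True, max_examples=150)
@given(
    seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60),
    mc=st.integers(0, 2),
    min_len=st.integers(1, 7),
)
def test_digest_matches_brute_force(seq, mc, min_len):
    assert digest(seq, mc, min_len, 40) == brute_force_digest(seq, mc, min_len, 40)


# ---------------------------------------------------------------------------
# PSM filtering


def _psm_frame(rows):
    cols = ["peptide", "plex_id", "fraction", "charge", "scan", "expectation",
            "126", "127N"]
    return pd.DataFrame(rows, columns=cols)


def test_filter_psms_threshold_and_reporters():
    psms = _psm_frame([
        ["PEPTIDEK", "p1", 1, 2, 1, 0.0005, 100.0, 50.0],   # kept
        ["PEPTIDEK", "p1", 1, 2, 2, 0.001, 100.0, 50.0],    # boundary: dropped
        ["PEPTIDEK", "p1", 1, 2, 3, 0.0005, 0.0, 0.0],      # no reporter: dropped
        ["OTHERPEK", "p1", 2, 3, 4, 0.01, 100.0, 50.0],     # low confidence
    ])
    kept = filter_psms(psms)
    assert list(kept["scan"]) == [1]


def test_strip_modifications():
    assert strip_modifications("AC[+57.0215]DEK") == "ACDEK"
    assert strip_modifications("n(42.01)PEPTIDEK") == "PEPTIDEK"


# ---------------------------------------------------------------------------
# specificity classification


def test_specificity_classes(search_db):
    spec = classify_specificity(conftest.PEP_A_SHARED, search_db)
    assert spec.spec_class is SpecificityClass.HLA_GENE_SPECIFIC
    assert spec.hit_genes == {"HLA-A"}
    assert len(spec.hit_hla_alleles) == 3

    multi = classify_specificity(conftest.PEP_SHARED_ALL, search_db)
    assert multi.spec_class is SpecificityClass.DISCARD_MULTI_HLA_GENE

    contam = classify_specificity(conftest.PEP_CONTAM, search_db)
    assert contam.spec_class is SpecificityClass.DISCARD_NONHLA_OVERLAP

    nonhla = classify_specificity("EGFLHSITK", search_db)
    assert nonhla.spec_class is SpecificityClass.DISCARD_NONHLA_OVERLAP
    assert nonhla.hit_genes == {"PROT1"}


def test_specificity_monotone_under_database_growth(allele_db, search_db):
    """Adding records can only move peptides toward discard, never rescue."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from hlaquant.references import build_search_database

    peptides = [conftest.PEP_A1, conftest.PEP_A_SHARED, conftest.PEP_CONTAM]
    before = {p: classify_specificity(p, search_db).spec_class for p in peptides}
    bigger = build_search_database(
        [SeqRecord(Seq("MSTNVALDQREGFLHSITK"), id="PROT1", description="gene=PROT1"),
         SeqRecord(Seq(conftest.PEP_A1 + "AAAAAAA"), id="PROTX", description="gene=PROTX")],
        allele_db,
        [SeqRecord(Seq(conftest.PEP_CONTAM + "GAVVDSQK"), id="KRT1", description="gene=KRT1")],
    )
    after = {p: classify_specificity(p, bigger).spec_class for p in peptides}
    for p in peptides:
        if before[p] is not SpecificityClass.HLA_GENE_SPECIFIC:
            assert after[p] is not SpecificityClass.HLA_GENE_SPECIFIC
    # the peptide newly covered by a standard protein is discarded now
    assert after[conftest.PEP_A1] is SpecificityClass.DISCARD_NONHLA_OVERLAP


def test_match_to_genotype_resolutions(search_db, allele_db, het_a_genotype):
    spec_a1 = classify_specificity(conftest.PEP_A1, search_db)
    m = match_to_genotype(spec_a1, het_a_genotype, allele_db)
    assert m.genotype_matched
    assert m.resolution is AlleleResolution.ALLELE_SPECIFIC
    assert m.allele.render() == "A*24:02P"

    spec_shared = classify_specificity(conftest.PEP_A_SHARED, search_db)
    m2 = match_to_genotype(spec_shared, het_a_genotype, allele_db)
    assert m2.resolution is AlleleResolution.ALLELE_SHARED

    spec_a3 = classify_specificity(conftest.PEP_A3, search_db)
    hom = make_genotype("S", "A*24:02P", "A*24:02P")
    m3 = match_to_genotype(spec_a3, hom, allele_db)
    assert not m3.genotype_matched
    assert m3.resolution is AlleleResolution.UNMATCHED


# ---------------------------------------------------------------------------
# aggregation and ratios


def _design():
    return PlexDesign(pd.DataFrame({
        "plex_id": ["p1"] * 3,
        "channel": ["126", "127N", "131"],
        "sample_id": ["s1", "s2", "pooled_reference"],
        "is_reference": [False, False, True],
    }))


def test_plex_design_validation():
    with pytest.raises(HlaQuantError, match="reference"):
        PlexDesign(pd.DataFrame({
            "plex_id": ["p1", "p1"],
            "channel": ["126", "127N"],
            "sample_id": ["s1", "s2"],
            "is_reference": [False, False],
        }))


def test_aggregate_sums_across_charges_and_fractions():
    psms = pd.DataFrame({
        "peptide": ["PEPTIDEK", "PEPTIDEK", "OTHERPEK"],
        "plex_id": ["p1", "p1", "p1"],
        "fraction": [1, 2, 1],
        "charge": [2, 3, 2],
        "scan": [1, 2, 3],
        "expectation": [1e-4] * 3,
        "126": [100.0, 50.0, 7.0],
        "127N": [10.0, 5.0, 3.0],
        "131": [40.0, 40.0, 10.0],
    })
    agg = aggregate_peptides(psms, _design())
    assert agg.loc[("PEPTIDEK", "p1"), "126"] == 150.0
    assert agg.loc[("PEPTIDEK", "p1"), "127N"] == 15.0
    assert agg.loc[("OTHERPEK", "p1"), "126"] == 7.0
    with pytest.raises(HlaQuantError, match="plex"):
        aggregate_peptides(psms.assign(plex_id="mystery"), _design())


def test_peptide_log_ratio_and_centering():
    agg = pd.DataFrame(
        {"126": [800.0, 200.0], "127N": [200.0, 200.0], "131": [200.0, 200.0]},
        index=pd.MultiIndex.from_tuples(
            [("AAAAAAK", "p1"), ("CCCCCCK", "p1")], names=["peptide", "plex_id"]
        ),
    )
    raw = peptide_log_ratio(agg, _design(), center=False)
    s1 = raw[raw.sample_id == "s1"].set_index("peptide")["log2_ratio"]
    assert s1["AAAAAAK"] == pytest.approx(2.0)
    assert s1["CCCCCCK"] == pytest.approx(0.0)
    centered = peptide_log_ratio(agg, _design(), center=True)
    med = centered.groupby("sample_id")["log2_ratio"].median()
    assert np.allclose(med.to_numpy(), 0.0)


def test_zero_reference_with_zero_floor_is_an_error():
    agg = pd.DataFrame(
        {"126": [800.0], "127N": [200.0], "131": [0.0]},
        index=pd.MultiIndex.from_tuples(
            [("AAAAAAK", "p1")], names=["peptide", "plex_id"]
        ),
    )
    with pytest.raises(UndefinedRatioError):
        peptide_log_ratio(agg, _design(), floor=0.0)


# ---------------------------------------------------------------------------
# protein abundance


def _hla_agg():
    # two A-gene peptides: one matched to A*24:02P only, one shared
    return pd.DataFrame(
        {"126": [300.0, 120.0], "127N": [50.0, 60.0], "131": [100.0, 40.0]},
        index=pd.MultiIndex.from_tuples(
            [(conftest.PEP_A1, "p1"), (conftest.PEP_A_SHARED, "p1")],
            names=["peptide", "plex_id"],
        ),
    )


def test_protein_abundance_hla_gene_mode(search_db, allele_db):
    spec = {
        p: classify_specificity(p, search_db)
        for p in [conftest.PEP_A1, conftest.PEP_A_SHARED]
    }
    genotypes = {
        "s1": {"A": make_genotype("s1", "A*24:02P", "A*25:01P")},
        "s2": {"A": make_genotype("s2", "A*03:01P", "A*03:01P")},
    }
    quant = protein_abundance(
        _hla_agg(), _design(), spec, "hla_gene", genotypes=genotypes, db=allele_db
    )
    q = quant.set_index(["sample_id", "feature"])
    # s1: both peptides matched -> log2((300+120)/(100+40)) = log2(3)
    assert q.loc[("s1", "HLA-A"), "log2_ratio"] == pytest.approx(np.log2(3.0))
    assert q.loc[("s1", "HLA-A"), "n_peptides"] == 2
    # s2 (homozygous A*03:01P): only the pan-A shared peptide matches
    assert q.loc[("s2", "HLA-A"), "n_peptides"] == 1
    assert q.loc[("s2", "HLA-A"), "log2_ratio"] == pytest.approx(np.log2(60.0 / 40.0))


def test_protein_abundance_allele_mode_excludes_shared(search_db, allele_db):
    spec = {
        p: classify_specificity(p, search_db)
        for p in [conftest.PEP_A1, conftest.PEP_A_SHARED]
    }
    genotypes = {"s1": {"A": make_genotype("s1", "A*24:02P", "A*25:01P")},
                 "s2": {"A": make_genotype("s2", "A*24:02P", "A*24:02P")}}
    quant = protein_abundance(
        _hla_agg(), _design(), spec, "hla_allele", genotypes=genotypes, db=allele_db
    )
    q = quant.set_index(["sample_id", "feature"])
    # only the discriminating peptide counts, only for the matching allele
    assert q.loc[("s1", "A*24:02P"), "log2_ratio"] == pytest.approx(np.log2(3.0))
    assert q.loc[("s1", "A*24:02P"), "n_peptides"] == 1
    assert ("s1", "A*25:01P") not in q.index
    # homozygous samples have no allele-specific peptides at all
    assert not q.index.get_level_values(0).str.contains("s2").any()


def test_protein_abundance_whole_proteome_mode(search_db):
    agg = pd.DataFrame(
        {"126": [300.0], "127N": [60.0], "131": [100.0]},
        index=pd.MultiIndex.from_tuples(
            [("EGFLHSITK", "p1")], names=["peptide", "plex_id"]
        ),
    )
    spec = {"EGFLHSITK": classify_specificity("EGFLHSITK", search_db)}
    quant = protein_abundance(agg, _design(), spec, "whole_proteome_gene")
    q = quant.set_index(["sample_id", "feature"])
    assert q.loc[("s1", "PROT1"), "log2_ratio"] == pytest.approx(np.log2(3.0))


# ---------------------------------------------------------------------------
# matched vs unmatched


def _ratio_frame(sample_values):
    rows = []
    for sample, peptide_vals in sample_values.items():
        for pep, val in peptide_vals.items():
            rows.append({"peptide": pep, "sample_id": sample, "plex_id": "p1",
                         "log2_ratio": val})
    return pd.DataFrame(rows)


def paired_t_oracle(diffs):
    """Classical paired t from first principles."""
    from scipy.stats import t as tdist

    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    mean = diffs.mean()
    se = diffs.std(ddof=1) / np.sqrt(n)
    t_stat = mean / se
    p = 2 * tdist.sf(abs(t_stat), df=n - 1)
    return t_stat, p


def test_matched_vs_unmatched_constant_offset():
    samples = {}
    rng = np.random.default_rng(1)
    offset = 1.5
    for i in range(8):
        base = rng.normal(0, 0.1)
        samples[f"s{i}"] = {
            "MATCHAAK": base + offset, "MATCHBBK": base + offset + 0.05,
            "UNMATAAK": base, "UNMATBBK": base - 0.05,
        }
    matches = [
        GenotypeMatch(p, s, p.startswith("MATCH"),
                      AlleleResolution.ALLELE_SHARED)
        for s in samples for p in samples[s]
    ]
    res = matched_vs_unmatched_stats(_ratio_frame(samples), matches)
    assert res.computable
    assert res.mean_difference == pytest.approx(offset, abs=0.06)
    med = res.sample_medians
    t_ref, p_ref = paired_t_oracle((med[True] - med[False]).to_numpy())
    assert res.t == pytest.approx(t_ref)
    assert res.p == pytest.approx(p_ref)
    assert res.p < 1e-6


def test_matched_vs_unmatched_degenerate_and_insufficient():
    samples = {f"s{i}": {"MATCHAAK": 1.0, "UNMATAAK": 1.0} for i in range(4)}
    matches = [
        GenotypeMatch(p, s, p.startswith("MATCH"), AlleleResolution.ALLELE_SHARED)
        for s in samples for p in samples[s]
    ]
    res = matched_vs_unmatched_stats(_ratio_frame(samples), matches)
    assert res.mean_difference == 0.0 and res.p == 1.0

    single = {"s0": {"MATCHAAK": 1.0, "UNMATAAK": 0.0}}
    matches1 = [GenotypeMatch(p, "s0", p.startswith("MATCH"),
                              AlleleResolution.ALLELE_SHARED) for p in single["s0"]]
    res1 = matched_vs_unmatched_stats(_ratio_frame(single), matches1)
    assert not res1.computable
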