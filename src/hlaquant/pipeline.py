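"""End-to-end pipeline orchestration on synthetic cohorts.

Runs the stages in order — cohort simulation, RNA-level genotyping from
reads, LOH/imbalance calling, RNA normalization, MS quantification and
cohort statistics — writing plain-text TSV/JSON outputs plus a manifest
carrying the configuration and its hash.  Re-running an identical
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import genotyping, ms, rna, simulate, stats
from .errors import HlaQuantError
from .references import (
    Genotype,
    build_search_database,
    genotypes_to_frame,
)


@dataclass
class RunConfig:
    """All knobs of one pipeline run; serialized verbatim into the manifest."""

    seed: int = 0
    study: str = "synthetic"
    homozygosity_threshold: float = 0.15
    expectation_threshold: float = 1e-3
    minor_fraction: float = 0.5
    fold_margin: float = 1.5
    alpha: float = 0.05
    flag20: float = 0.2
    flag30: float = 0.3
    min_allele_peptides: int = 3
    kmer: int = 31
    pseudocount: float = 1.0
    sim: simulate.SimParams = field(default_factory=simulate.SimParams)

    def __post_init__(self) -> None:
        for name in ("homozygosity_threshold", "minor_fraction", "alpha",
                     "flag20", "flag30"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise HlaQuantError(f"{name} must lie in (0, 1); got {value}")
        for name in ("fold_margin", "kmer", "min_allele_peptides"):
            if getattr(self, name) <= 0:
                raise HlaQuantError(f"{name} must be positive")
        if self.expectation_threshold < 0:
            raise HlaQuantError("expectation_threshold must be non-negative")

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = simulate.SimParams(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


def run_pipeline(config: RunConfig, outdir) -> Dict[str, object]:
    """Execute all stages on a synthetic cohort and write the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: Dict[str, object] = {}
    stage = "simulate"
    try:
        sim = simulate.simulate_cohort(config.seed, config.sim)
        db, truth = sim["db"], sim["truth"]
        db.to_fasta(outdir / "alleles.fasta")
        truth.to_json(outdir / "truth.json")
        sim["counts"].to_csv(outdir / "counts.tsv", sep="\t")
        ms.write_psms(sim["psms"], outdir / "psms.tsv")
        sim["design"].write(outdir / "plex_design.tsv")

        stage = "genotyping"
        called_t, called_n = {}, {}
        loh_calls = []
        for pid in sorted(truth.normal_genotypes):
            called_t[pid], called_n[pid] = {}, {}
            for gene in sorted(truth.normal_genotypes[pid]):
                candidates = sorted(
                    (r for r in db if r.name.gene == gene), key=lambda r: r.name
                )
                for tissue, store in (("T", called_t), ("N", called_n)):
                    reads = simulate.make_reads(
                        truth, db, config.seed, f"{pid}-{tissue}", gene
                    )
                    compat = genotyping.build_compatibility(
                        reads, candidates, k=config.kmer
                    )
                    store[pid][gene] = genotyping.call_genotype(
                        compat,
                        sample_id=f"{pid}-{tissue}",
                        homozygosity_threshold=config.homozygosity_threshold,
                        db=db,
                    )
                loh_calls.append(
                    genotyping.detect_loh(
                        called_t[pid][gene], called_n[pid][gene], patient_id=pid
                    )
                )
        genotypes_to_frame(
            [g for pid in called_t for g in called_t[pid].values()]
            + [g for pid in called_n for g in called_n[pid].values()]
        ).to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
        genotyping.loh_calls_to_frame(loh_calls).to_csv(
            outdir / "loh_calls.tsv", sep="\t", index=False
        )
        results["loh_calls"] = loh_calls
        results["called_tumor"] = called_t
        results["called_normal"] = called_n

        stage = "rna_quant"
        counts = sim["counts"]
        expr = rna.normalize(counts, pseudocount=config.pseudocount)
        rna.write_expression(expr, outdir / "expression.tsv")
        imbalance_calls = []
        for pid in sorted(called_t):
            for gene in sorted(called_t[pid]):
                gt, gn = called_t[pid][gene], called_n[pid][gene]
                if gt.homozygous or gn.homozygous:
                    continue
                pair_t = _allele_counts(counts, f"{pid}-T", gt, config.pseudocount)
                pair_n = _allele_counts(counts, f"{pid}-N", gn, config.pseudocount)
                imbalance_calls.append(
                    genotyping.detect_imbalance(
                        pair_t, pair_n, patient_id=pid, gene=gene,
                        minor_fraction=config.minor_fraction,
                        fold_margin=config.fold_margin,
                    )
                )
        pd.DataFrame(
            [
                {
                    "patient_id": c.patient_id,
                    "gene": c.gene,
                    "imbalanced": c.imbalanced,
                    "tumor_ratio": round(c.tumor_ratio, 6),
                    "normal_ratio": round(c.normal_ratio, 6),
                }
                for c in imbalance_calls
            ],
            columns=["patient_id", "gene", "imbalanced", "tumor_ratio", "normal_ratio"],
        ).to_csv(outdir / "imbalance_calls.tsv", sep="\t", index=False)
        results["imbalance_calls"] = imbalance_calls

        stage = "ms_quant"
        search_db = build_search_database(
            sim["background_proteins"], db, contaminants=()
        )
        filtered = ms.filter_psms(sim["psms"], config.expectation_threshold)
        agg = ms.aggregate_peptides(filtered, sim["design"])
        ratios = ms.peptide_log_ratio(agg, sim["design"])
        specificity = {
            pep: ms.classify_specificity(pep, search_db)
            for pep in sorted({p for p, _ in agg.index})
        }
        genotype_map = _genotype_map(called_t, called_n)
        gene_quant = ms.protein_abundance(
            agg, sim["design"], specificity, "hla_gene",
            genotypes=genotype_map, db=db,
        )
        allele_quant = ms.protein_abundance(
            agg, sim["design"], specificity, "hla_allele",
            genotypes=genotype_map, db=db,
        )
        gene_quant.to_csv(outdir / "protein_gene.tsv", sep="\t", index=False)
        allele_quant.to_csv(outdir / "protein_allele.tsv", sep="\t", index=False)
        results["gene_quant"] = gene_quant
        results["allele_quant"] = allele_quant
        results["peptide_ratios"] = ratios
        results["specificity"] = specificity

        stage = "cohort_stats"
        all_genotypes = [
            g
            for store in (called_t, called_n)
            for pid in store
            for g in store[pid].values()
        ]
        tissue_of = {g.sample_id: g.sample_id.rsplit("-", 1)[1] for g in all_genotypes}
        homozygosity = stats.homozygosity_rates(all_genotypes, tissue_of)
        homozygosity.to_csv(outdir / "homozygosity.tsv", sep="\t", index=False)
        comparisons = []
        for gene_letter in sorted({g.gene for g in all_genotypes}):
            tumor_sets, normal_sets = matched_peptide_ratio_sets(
                ratios, specificity, genotype_map, db, f"HLA-{gene_letter}"
            )
            comparisons.extend(
                stats.paired_differential(
                    tumor_sets, normal_sets, gene=f"HLA-{gene_letter}",
                    alpha=config.alpha,
                )
            )
        diff = stats.comparisons_to_frame(comparisons)
        diff = diff.round(8)
        diff.to_csv(outdir / "differential.tsv", sep="\t", index=False)
        results["differential"] = comparisons
        results["homozygosity"] = homozygosity

        manifest = {
            "config": config.to_dict(),
            "config_hash": config.digest(),
            "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except Exception as exc:  # annotate the failing stage
        raise HlaQuantError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


def _allele_counts(counts: pd.DataFrame, sample: str, genotype: Genotype,
                   pseudocount: float):
    a, b = genotype.alleles
    col = counts[sample]
    return (
        float(col.get(a.render(), 0.0)) + pseudocount,
        float(col.get(b.render(), 0.0)) + pseudocount,
    )


def _genotype_map(called_t, called_n):
    out = {}
    for pid in called_t:
        out[f"{pid}-T"] = called_t[pid]
        out[f"{pid}-N"] = called_n[pid]
    return out


def matched_peptide_ratio_sets(
    ratios: pd.DataFrame,
    specificity: Dict[str, ms.PeptideSpecificity],
    genotype_map: Dict[str, Dict[str, Genotype]],
    db,
    gene_symbol: str,
):
    """Genotype-matched, gene-specific peptide log2 ratios per patient,
    split into tumor and normal dictionaries keyed by patient id."""
    locus = gene_symbol.split("-")[1]
    tumor_sets: Dict[str, list] = {}
    normal_sets: Dict[str, list] = {}
    matched_cache: Dict[tuple, bool] = {}
    for row in ratios.itertuples(index=False):
        spec = specificity.get(row.peptide)
        if spec is None or spec.spec_class is not ms.SpecificityClass.HLA_GENE_SPECIFIC:
            continue
        if spec.hla_gene != gene_symbol:
            continue
        genos = genotype_map.get(row.sample_id)
        if genos is None or locus not in genos:
            continue
        cache_key = (row.peptide, genos[locus].allele_set())
        matched = matched_cache.get(cache_key)
        if matched is None:
            matched = ms.match_to_genotype(spec, genos[locus], db).genotype_matched
            matched_cache[cache_key] = matched
        if not matched:
            continue
        pid, tissue = row.sample_id.rsplit("-", 1)
        target = tumor_sets if tissue == "T" else normal_sets
        target.setdefault(pid, []).append(float(row.log2_ratio))
    return tumor_sets, normal_sets
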