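"""Synthetic cohort generation with recorded ground truth.

Every pipeline stage is exercised on fully synthetic data: a homologous
three-gene allele family (shared and allele-unique tryptic peptides, like
real class I loci), cohort genotypes drawn from allele frequencies with
injected LOH and allele-imbalance events, negative-binomial RNA counts with
injected tumor overexpression, and DDA-sampled TMT PSM tables with a pooled
reference channel.  All randomness flows from one seed; regeneration from
(seed, parameters) is bit-identical.

The generator emulates the *statistical* structure of a TMT proteogenomic
cohort — detection is plex-level (isobaric identification), the pooled
reference is the mean of plex members, reporter noise is log-normal — not
spectra: there are no m/z values or fragment ions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import HlaQuantError
from .ms import PlexDesign, digest
from .nomenclature import AlleleName
from .references import AlleleDatabase, AlleleRecord, Genotype

# residue sampling weights: K/R combined ~8.5% gives a mean tryptic peptide
# length near 12; P kept rare to limit cleavage suppression
_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_WEIGHTS = np.array(
    [0.08, 0.02, 0.05, 0.06, 0.04, 0.07, 0.02, 0.05, 0.05, 0.09,
     0.02, 0.04, 0.02, 0.04, 0.035, 0.07, 0.06, 0.07, 0.015, 0.03]
)
_WEIGHTS = _WEIGHTS / _WEIGHTS.sum()

# deterministic reverse translation (one fixed codon per residue, no stops)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

TMT10_CHANNELS = ["126", "127N", "127C", "128N", "128C",
                  "129N", "129C", "130N", "130C", "131"]
TMT11_CHANNELS = TMT10_CHANNELS + ["131C"]

EVENT_NONE = "none"
EVENT_LOH = "loh"
EVENT_IMBALANCE = "imbalance"


@dataclass
class SimParams:
    """Generator parameters; defaults define the standard study conditions."""

    # allele family
    n_genes: int = 3
    alleles_per_gene: int = 4
    protein_length: int = 365
    substitution_rate: float = 0.02
    cross_gene_divergence: float = 0.05
    # the non-HLA proteome anchoring per-sample median centering; kept large
    # relative to the HLA peptide pool, as in a real whole-proteome run
    n_background_proteins: int = 40
    background_protein_length: int = 200

    # cohort
    n_patients: int = 60
    loh_rate: float = 0.08
    imbalance_rate: float = 0.08
    imbalance_factor: float = 0.3

    # RNA
    depth: int = 300  # expected reads per gene per sample
    dispersion: float = 0.05  # NB dispersion; 0 -> deterministic rounding
    read_length: int = 50
    error_rate: float = 0.0
    de_fraction: float = 0.5  # fraction of patients with tumor overexpression
    de_log2fc: float = 1.0

    # TMT proteomics
    plex_size: int = 10
    detect_prob: float = 0.7
    intensity_cv: float = 0.15
    background_fraction: float = 0.25  # co-isolation noise floor vs reference
    decoy_fraction: float = 0.0
    intensity_scale: float = 1.0e6
    missed_cleavages: int = 0
    min_peptide_len: int = 7
    max_peptide_len: int = 40


@dataclass
class GroundTruth:
    """Everything injected by the generator, recoverable for testing."""

    seed: int
    params: SimParams
    gene_letters: List[str] = field(default_factory=list)
    # genotypes[pid][gene] for each tissue
    normal_genotypes: Dict[str, Dict[str, Genotype]] = field(default_factory=dict)
    tumor_genotypes: Dict[str, Dict[str, Genotype]] = field(default_factory=dict)
    events: Dict[Tuple[str, str], str] = field(default_factory=dict)
    lost_alleles: Dict[Tuple[str, str], str] = field(default_factory=dict)
    imbalance_factors: Dict[Tuple[str, str], float] = field(default_factory=dict)
    gene_log2fc: Dict[Tuple[str, str], float] = field(default_factory=dict)
    # per-allele unique/shared tryptic peptide inventory
    unique_peptides: Dict[str, List[str]] = field(default_factory=dict)
    gene_shared_peptides: Dict[str, List[str]] = field(default_factory=dict)
    # per sample (pid-T / pid-N), per gene: linear protein abundance
    protein_abundance: Dict[str, Dict[str, float]] = field(default_factory=dict)
    expected_allele_counts: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "params": dataclasses.asdict(self.params),
            "events": {f"{p}:{g}": e for (p, g), e in sorted(self.events.items())},
            "lost_alleles": {
                f"{p}:{g}": a for (p, g), a in sorted(self.lost_alleles.items())
            },
            "imbalance_factors": {
                f"{p}:{g}": f for (p, g), f in sorted(self.imbalance_factors.items())
            },
            "gene_log2fc": {
                f"{p}:{g}": v for (p, g), v in sorted(self.gene_log2fc.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(_RESIDUES), size=length, p=_WEIGHTS)
    return "".join(_RESIDUES[i] for i in idx)


def _mutate(rng: np.random.Generator, protein: str, rate: float) -> str:
    chars = list(protein)
    n_sub = rng.binomial(len(chars), rate)
    positions = rng.choice(len(chars), size=n_sub, replace=False)
    for pos in positions:
        current = chars[pos]
        alternatives = [r for r in _RESIDUES if r != current]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _reverse_translate(protein: str) -> str:
    return "".join(_CODON[r] for r in protein)


def make_allele_db(
    seed: int, params: Optional[SimParams] = None, max_retries: int = 25
) -> Tuple[AlleleDatabase, GroundTruth]:
    """A homologous allele family with shared and allele-unique peptides.

    One base chain per gene (derived from a common ancestor so some peptides
    cross gene boundaries), alleles derived by point substitutions.  Unless
    the substitution rate is zero, the generator retries until every allele
    has at least one allele-unique tryptic peptide and at least one peptide
    shared within its gene.
    """
    params = params or SimParams()
    genes = [chr(ord("A") + i) for i in range(params.n_genes)]
    for attempt in range(max_retries):
        rng = np.random.default_rng((seed, attempt))
        ancestor = _random_protein(rng, params.protein_length)
        records: List[AlleleRecord] = []
        for gene in genes:
            base = _mutate(rng, ancestor, params.cross_gene_divergence)
            for i in range(params.alleles_per_gene):
                name = AlleleName(
                    gene=gene, field1=(i // 2) + 1, field2=(i % 2) + 1, p_group=True
                )
                protein = _mutate(rng, base, params.substitution_rate)
                records.append(
                    AlleleRecord(name=name, protein=protein,
                                 cds=_reverse_translate(protein))
                )
        truth = GroundTruth(seed=seed, params=params, gene_letters=genes)
        if _inventory(records, params, truth) or params.substitution_rate == 0:
            db = AlleleDatabase(records)
            return db, truth
    raise HlaQuantError(
        "could not satisfy the unique/shared peptide constraint; raise the "
        "substitution rate or the number of retries"
    )


def _inventory(records, params: SimParams, truth: GroundTruth) -> bool:
    """Record per-allele unique/shared peptides; True iff constraints hold."""
    peptides = {
        r.name.render(): digest(
            r.protein, params.missed_cleavages,
            params.min_peptide_len, params.max_peptide_len,
        )
        for r in records
    }
    ok = True
    for r in records:
        key = r.name.render()
        others = set().union(
            *(peps for k, peps in peptides.items() if k != key)
        ) if len(peptides) > 1 else set()
        same_gene_others = set().union(
            *(peps for k, peps in peptides.items()
              if k != key and k.startswith(r.name.gene)),
            set(),
        )
        unique = sorted(peptides[key] - others)
        shared = sorted(peptides[key] & same_gene_others)
        truth.unique_peptides[key] = unique
        truth.gene_shared_peptides[key] = shared
        if not unique or not shared:
            ok = False
    return ok


def make_background_proteins(seed: int, params: SimParams):
    """Non-HLA 'standard proteome' records used in search databases."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng((seed, 977))
    out = []
    for i in range(params.n_background_proteins):
        protein = _random_protein(rng, params.background_protein_length)
        out.append(
            SeqRecord(Seq(protein), id=f"BG{i + 1:03d}", description=f"gene=BG{i + 1:03d}")
        )
    return out


def make_cohort(
    db: AlleleDatabase,
    truth: GroundTruth,
    seed: int,
    allele_frequencies: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> GroundTruth:
    """Draw paired normal/tumor genotypes with injected LOH and imbalance.

    Normal genotypes are drawn allele-wise i.i.d. from per-gene allele
    frequencies (uniform over the database's alleles by default).  The tumor
    genotype equals the normal one, except that a heterozygous gene collapses
    to one uniformly chosen allele with probability ``loh_rate``, or —
    mutually exclusively — records an RNA imbalance factor with probability
    ``imbalance_rate``.
    """
    params = truth.params
    rng = np.random.default_rng((seed, 1))
    by_gene: Dict[str, List[AlleleName]] = {}
    for rec in db:
        by_gene.setdefault(rec.name.gene, []).append(rec.name)
    for gene in by_gene:
        by_gene[gene] = sorted(by_gene[gene])
    freqs = {}
    for gene, names in by_gene.items():
        if allele_frequencies and gene in allele_frequencies:
            given = allele_frequencies[gene]
            probs = np.array([given[n.render()] for n in names], dtype=float)
            if not np.isclose(probs.sum(), 1.0):
                raise HlaQuantError(f"allele frequencies for gene {gene} must sum to 1")
        else:
            probs = np.full(len(names), 1.0 / len(names))
        freqs[gene] = probs

    for i in range(params.n_patients):
        pid = f"P{i + 1:03d}"
        truth.normal_genotypes[pid] = {}
        truth.tumor_genotypes[pid] = {}
        for gene in sorted(by_gene):
            names = by_gene[gene]
            picks = rng.choice(len(names), size=2, p=freqs[gene])
            normal = Genotype(f"{pid}-N", gene, (names[picks[0]], names[picks[1]]))
            event = EVENT_NONE
            tumor_alleles = normal.alleles
            if not normal.homozygous:
                u = rng.random()
                if u < params.loh_rate:
                    event = EVENT_LOH
                    keep = normal.alleles[int(rng.integers(2))]
                    lost = next(a for a in normal.alleles if a != keep)
                    tumor_alleles = (keep, keep)
                    truth.lost_alleles[(pid, gene)] = lost.render()
                elif u < params.loh_rate + params.imbalance_rate:
                    event = EVENT_IMBALANCE
                    truth.imbalance_factors[(pid, gene)] = params.imbalance_factor
            tumor = Genotype(f"{pid}-T", gene, tumor_alleles)
            truth.normal_genotypes[pid][gene] = normal
            truth.tumor_genotypes[pid][gene] = tumor
            truth.events[(pid, gene)] = event
            # gene-level tumor differential expression
            if rng.random() < params.de_fraction:
                truth.gene_log2fc[(pid, gene)] = params.de_log2fc
            else:
                truth.gene_log2fc[(pid, gene)] = 0.0
    return truth


def _allele_shares(genotype: Genotype, imbalance: Optional[float]) -> Dict[str, float]:
    """Linear expression share per distinct allele (sums to 1)."""
    if genotype.homozygous:
        return {genotype.alleles[0].render(): 1.0}
    a, b = genotype.alleles  # canonical order
    if imbalance is None:
        return {a.render(): 0.5, b.render(): 0.5}
    # the second (canonically later) allele is the suppressed minor allele
    total = 1.0 + imbalance
    return {a.render(): 1.0 / total, b.render(): imbalance / total}


def expected_allele_counts(truth: GroundTruth) -> Dict[str, Dict[str, float]]:
    """Expected RNA read counts per sample per allele, after fold changes and
    imbalance factors."""
    params = truth.params
    out: Dict[str, Dict[str, float]] = {}
    for pid in truth.normal_genotypes:
        for tissue, genos in (("N", truth.normal_genotypes[pid]),
                              ("T", truth.tumor_genotypes[pid])):
            sample = f"{pid}-{tissue}"
            out[sample] = {}
            for gene, genotype in genos.items():
                scale = 1.0
                imbalance = None
                if tissue == "T":
                    scale = 2.0 ** truth.gene_log2fc[(pid, gene)]
                    if truth.events[(pid, gene)] == EVENT_IMBALANCE:
                        imbalance = truth.imbalance_factors[(pid, gene)]
                for allele, share in _allele_shares(genotype, imbalance).items():
                    out[sample][allele] = params.depth * scale * share
    truth.expected_allele_counts = out
    return out


def make_rna_counts(truth: GroundTruth, seed: int) -> pd.DataFrame:
    """Negative-binomial allele-level RNA counts (features x samples).

    With dispersion 0 the counts are the rounded expectations.
    """
    params = truth.params
    rng = np.random.default_rng((seed, 2))
    expected = expected_allele_counts(truth)
    samples = sorted(expected)
    features = sorted({a for counts in expected.values() for a in counts})
    matrix = np.zeros((len(features), len(samples)))
    for j, sample in enumerate(samples):
        for i, feat in enumerate(features):
            mu = expected[sample].get(feat, 0.0)
            if mu <= 0:
                continue
            if params.dispersion <= 0:
                matrix[i, j] = round(mu)
            else:
                n = 1.0 / params.dispersion
                p = n / (n + mu)
                matrix[i, j] = rng.negative_binomial(n, p)
    return pd.DataFrame(matrix, index=features, columns=samples)


def make_reads(
    truth: GroundTruth,
    db: AlleleDatabase,
    seed: int,
    sample: str,
    gene: str,
) -> List[Tuple[str, str]]:
    """Simulated RNA reads for one sample at one locus.

    Read counts per allele follow the expected counts (rounded); reads are
    substrings of the allele cds at uniform positions with uniform
    substitution errors at ``error_rate``.
    """
    params = truth.params
    rng = np.random.default_rng((seed, 3, _stable_hash(sample), _stable_hash(gene)))
    if not truth.expected_allele_counts:
        expected_allele_counts(truth)
    expected = truth.expected_allele_counts[sample]
    reads: List[Tuple[str, str]] = []
    nucleotides = "ACGT"
    for allele_str in sorted(expected):
        allele_gene = allele_str.split("*")[0]
        if allele_gene != gene:
            continue
        from .nomenclature import parse_allele

        rec = db.resolve(parse_allele(allele_str))
        cds = rec.cds
        n_reads = int(round(expected[allele_str]))
        max_start = len(cds) - params.read_length
        for r in range(n_reads):
            start = int(rng.integers(0, max_start + 1))
            read = list(cds[start : start + params.read_length])
            if params.error_rate > 0:
                for pos in range(len(read)):
                    if rng.random() < params.error_rate:
                        read[pos] = nucleotides[int(rng.integers(4))]
            reads.append((f"{sample}|{allele_str}|{r}", "".join(read)))
    return reads


def _stable_hash(text: str) -> int:
    value = 0
    for ch in text:
        value = (value * 131 + ord(ch)) % 2_147_483_647
    return value


# ---------------------------------------------------------------------------
# TMT PSM simulation


def protein_truth(truth: GroundTruth) -> Dict[str, Dict[str, float]]:
    """True linear protein abundance per sample per gene (tumor fold changes
    mirror the RNA level)."""
    out: Dict[str, Dict[str, float]] = {}
    for pid in truth.normal_genotypes:
        for tissue in ("N", "T"):
            sample = f"{pid}-{tissue}"
            out[sample] = {}
            for gene in truth.normal_genotypes[pid]:
                fc = 2.0 ** truth.gene_log2fc[(pid, gene)] if tissue == "T" else 1.0
                out[sample][gene] = fc
    truth.protein_abundance = out
    return out


def make_plex_design(truth: GroundTruth) -> PlexDesign:
    """Assign tumor/normal samples to TMT plexes, one pooled reference
    channel (the last channel) per plex.  A patient's tumor and normal
    samples are always co-multiplexed, so whole pairs fill each plex
    (an odd member channel may stay unused)."""
    params = truth.params
    channels = TMT10_CHANNELS if params.plex_size == 10 else TMT11_CHANNELS
    if params.plex_size not in (10, 11):
        raise HlaQuantError("plex_size must be 10 or 11")
    patients_per_plex = (params.plex_size - 1) // 2
    pids = sorted(truth.normal_genotypes)
    rows = []
    for start in range(0, len(pids), patients_per_plex):
        plex_id = f"plex{start // patients_per_plex + 1:02d}"
        members = [
            f"{pid}-{tissue}"
            for pid in pids[start : start + patients_per_plex]
            for tissue in ("T", "N")
        ]
        for channel, sample in zip(channels, members):
            rows.append({"plex_id": plex_id, "channel": channel,
                         "sample_id": sample, "is_reference": False})
        rows.append({"plex_id": plex_id, "channel": channels[-1],
                     "sample_id": "pooled_reference", "is_reference": True})
    return PlexDesign(pd.DataFrame(rows))


def _peptide_abundance(
    peptide: str,
    sample: str,
    gene_of_sample_abundance: Dict[str, float],
    genotype: Dict[str, Genotype],
    allele_proteins: Dict[str, str],
    truth: GroundTruth,
    pid: str,
) -> float:
    """Linear abundance of one peptide in one sample: the summed abundance of
    the sample's alleles whose protein contains the peptide."""
    total = 0.0
    for gene, geno in genotype.items():
        imbalance = None
        if sample.endswith("-T") and truth.events[(pid, gene)] == EVENT_IMBALANCE:
            imbalance = truth.imbalance_factors[(pid, gene)]
        shares = _allele_shares(geno, imbalance)
        for allele_str, share in shares.items():
            if peptide in allele_proteins[allele_str]:
                total += gene_of_sample_abundance[gene] * share
    return total


def make_psm_tables(
    truth: GroundTruth,
    db: AlleleDatabase,
    seed: int,
    background_proteins=None,
) -> Tuple[pd.DataFrame, PlexDesign]:
    """DDA-sampled TMT PSM tables with a pooled reference channel.

    Detection is per (peptide, plex) with probability ``detect_prob``
    (identification is plex-level in isobaric multiplexing).  Detected
    peptides receive log-normal reporter intensities proportional to each
    member sample's true abundance; samples not carrying the peptide get a
    co-isolation noise floor of ``background_fraction`` times the reference.
    The pooled reference channel is the arithmetic mean of member-sample
    abundances.  True PSMs draw expectation values below 1e-3; an optional
    ``decoy_fraction`` adds rows above the threshold.
    """
    params = truth.params
    rng = np.random.default_rng((seed, 4))
    design = make_plex_design(truth)
    protein_truth(truth)
    allele_proteins = {rec.name.render(): rec.protein for rec in db}
    peptide_sources: Dict[str, List[str]] = {}
    for allele_str, protein in sorted(allele_proteins.items()):
        for pep in sorted(
            digest(protein, params.missed_cleavages,
                   params.min_peptide_len, params.max_peptide_len)
        ):
            peptide_sources.setdefault(pep, []).append(allele_str)
    background = {}
    if background_proteins:
        for sr in background_proteins:
            for pep in sorted(
                digest(str(sr.seq), params.missed_cleavages,
                       params.min_peptide_len, params.max_peptide_len)
            ):
                background.setdefault(pep, []).append(sr.id)

    sigma = float(np.sqrt(np.log1p(params.intensity_cv ** 2)))
    channels = TMT10_CHANNELS if params.plex_size == 10 else TMT11_CHANNELS
    rows = []
    scan = 0
    for plex_id in design.plex_ids:
        sample_channels = design.sample_channels(plex_id)
        ref_channel = design.reference_channel(plex_id)
        # candidate peptides: those of alleles carried by any member, plus
        # the background proteome (present in every sample)
        member_alleles = set()
        member_pids = {}
        for sample in sample_channels:
            pid = sample.rsplit("-", 1)[0]
            member_pids[sample] = pid
            genos = (
                truth.tumor_genotypes[pid]
                if sample.endswith("-T")
                else truth.normal_genotypes[pid]
            )
            for geno in genos.values():
                member_alleles.update(a.render() for a in geno.distinct_alleles)
        candidates = sorted(
            {p for p, sources in peptide_sources.items()
             if member_alleles.intersection(sources)}
        ) + sorted(background)
        for peptide in candidates:
            if rng.random() >= params.detect_prob:
                continue
            abundances = {}
            for sample in sorted(sample_channels):
                pid = member_pids[sample]
                genos = (
                    truth.tumor_genotypes[pid]
                    if sample.endswith("-T")
                    else truth.normal_genotypes[pid]
                )
                if peptide in background:
                    abundances[sample] = 1.0
                else:
                    abundances[sample] = _peptide_abundance(
                        peptide, sample, truth.protein_abundance[sample],
                        genos, allele_proteins, truth, pid,
                    )
            ref_abundance = float(np.mean(list(abundances.values())))
            if ref_abundance <= 0:
                continue
            intensities = {}
            for sample, channel in sorted(sample_channels.items()):
                level = abundances[sample]
                if level <= 0:
                    level = params.background_fraction * ref_abundance
                noise = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                intensities[channel] = level * params.intensity_scale * noise
            ref_noise = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
            intensities[ref_channel] = (
                ref_abundance * params.intensity_scale * ref_noise
            )
            n_psms = int(rng.integers(1, 4))
            weights = rng.dirichlet(np.ones(n_psms)) if n_psms > 1 else np.array([1.0])
            for w in weights:
                scan += 1
                row = {
                    "peptide": peptide,
                    "plex_id": plex_id,
                    "fraction": int(rng.integers(1, 13)),
                    "charge": int(rng.integers(2, 4)),
                    "scan": scan,
                    "expectation": 10.0 ** rng.uniform(-6.0, -3.5),
                }
                for channel in channels:
                    row[channel] = float(w) * intensities.get(channel, 0.0)
                rows.append(row)
            if params.decoy_fraction > 0 and rng.random() < params.decoy_fraction:
                scan += 1
                row = {
                    "peptide": peptide[::-1],
                    "plex_id": plex_id,
                    "fraction": int(rng.integers(1, 13)),
                    "charge": int(rng.integers(2, 4)),
                    "scan": scan,
                    "expectation": 10.0 ** rng.uniform(-2.5, -1.0),
                }
                for channel in channels:
                    row[channel] = intensities.get(channel, 0.0)
                rows.append(row)
    psms = pd.DataFrame(
        rows,
        columns=["peptide", "plex_id", "fraction", "charge", "scan",
                 "expectation"] + channels,
    )
    return psms, design


def expected_log2_ratio_frame(
    truth: GroundTruth,
    db: AlleleDatabase,
    design: PlexDesign,
    peptide_plexes,
    background_proteins=None,
) -> pd.DataFrame:
    """Noise-free expected peptide log2 ratios for given (peptide, plex) keys.

    The oracle counterpart of the sampled PSM tables: for each detected
    (peptide, plex) pair it computes the exact channel and pooled-reference
    abundances the generator draws noise around, and returns uncentered
    ``log2(level / reference)`` per member sample.  Used to separate
    detection sampling from intensity noise when testing estimators.
    """
    params = truth.params
    if not truth.protein_abundance:
        protein_truth(truth)
    allele_proteins = {rec.name.render(): rec.protein for rec in db}
    background_ids = {
        pep
        for sr in (background_proteins or ())
        for pep in digest(str(sr.seq), params.missed_cleavages,
                          params.min_peptide_len, params.max_peptide_len)
    }
    rows = []
    for peptide, plex_id in peptide_plexes:
        sample_channels = design.sample_channels(plex_id)
        abundances = {}
        for sample in sorted(sample_channels):
            pid = sample.rsplit("-", 1)[0]
            genos = (
                truth.tumor_genotypes[pid]
                if sample.endswith("-T")
                else truth.normal_genotypes[pid]
            )
            if peptide in background_ids:
                abundances[sample] = 1.0
            else:
                abundances[sample] = _peptide_abundance(
                    peptide, sample, truth.protein_abundance[sample],
                    genos, allele_proteins, truth, pid,
                )
        ref = float(np.mean(list(abundances.values())))
        if ref <= 0:
            continue
        for sample, level in abundances.items():
            if level <= 0:
                level = params.background_fraction * ref
            rows.append(
                {
                    "peptide": peptide,
                    "sample_id": sample,
                    "plex_id": plex_id,
                    "log2_ratio": float(np.log2(level / ref)),
                }
            )
    return pd.DataFrame(rows, columns=["peptide", "sample_id", "plex_id", "log2_ratio"])


def simulate_cohort(
    seed: int, params: Optional[SimParams] = None
) -> Dict[str, object]:
    """End-to-end synthetic cohort: allele DB, genotypes, RNA counts, PSM
    tables and the ground truth, all derived from one seed."""
    params = params or SimParams()
    db, truth = make_allele_db(seed, params)
    make_cohort(db, truth, seed)
    counts = make_rna_counts(truth, seed)
    background = make_background_proteins(seed, params)
    psms, design = make_psm_tables(truth, db, seed, background_proteins=background)
    return {
        "db": db,
        "truth": truth,
        "counts": counts,
        "psms": psms,
        "design": design,
        "background_proteins": background,
    }
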