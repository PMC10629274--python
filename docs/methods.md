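# Methods

This note documents the models, rules and numerical choices behind
`hlaquant`, what the synthetic data generator does and does not emulate,
and the known limitations.

## Nomenclature and references

Alleles are handled at the protein ("two-field"/WMDA) level, e.g.
`A*24:02P`; a trailing `P` marks a P-group (alleles with an identical
peptide-binding-domain protein sequence).  Parsing accepts an optional
`HLA-` prefix and a third (coding-sequence synonym) field; canonical
rendering zero-pads fields to two digits.  Reducing to two fields never
*infers* P-group membership: the flag is taken from an explicit P-group
table when the allele database carries one, otherwise the input flag is
preserved.  Only HLA-A/-B/-C are supported; class II loci are rejected.

Personalized transcript references are built by *identifier*, not sequence
similarity: entries of the common transcriptome matching a configurable
HLA-identifier predicate are removed and the sample's distinct allele
coding sequences appended (a homozygous genotype contributes one entry, so
pseudoalignment counts are not split arbitrarily between duplicates).
Output order is deterministic — original order, then alleles by canonical
name.  Allele records validate that the coding sequence translates exactly
to the stored protein.

## Genotyping

The genotyper is a deliberately simple, deterministic stand-in for
pseudoalignment-based typing: a read is compatible with an allele iff every
k-mer of the read (default k = 31) occurs in the allele's coding sequence.
Genotype selection is greedy and iterative: the first allele explains the
most reads, the second adds the most reads on top of it, and the pair is
re-ranked until stable; ties break by canonical allele-name order.
Homozygosity is called when the minor/major ratio of *non-shared* read
counts is strictly below the threshold (default 0.15; strictness at the
boundary is a documented choice and the threshold is a parameter).  A pair
with zero non-shared reads on both sides is reported homozygous for the
major allele with a degenerate-evidence warning.

Paired tumor/normal comparison: `loh` means the normal tissue is
heterozygous and the tumor is homozygous for one of the two normal alleles
(the other is reported lost); the opposite direction is
`reverse_discrepancy`; any other mismatch is `other_discrepancy`.  Note a
subtlety of the swap symmetry: an `loh` call always becomes
`reverse_discrepancy` when tissues are swapped, but a `reverse_discrepancy`
only becomes `loh` when the homozygous allele is contained in the
heterozygous pair.  Published descriptions of this classification
sometimes state the direction inconsistently; this package follows the
convention above (tumor homozygous + normal heterozygous = LOH), which
matches the worked-example table it ships.

Allele imbalance (heterozygous in both tissues) is called when the tumor
minor/major expression ratio is strictly below `minor_fraction` (default
0.5) *and* the tumor major/minor fold is at least `fold_margin` (default
1.5) times the normal fold.  Comparisons use `<` and `≥` exactly as the
thresholds are phrased; expression must be made strictly positive upstream
(pseudocount before linearizing).

## RNA quantification

Reads compatible with exactly one genotype allele count fully to it; reads
compatible with both are split 50/50 — with a two-allele reference this is
the EM fixed point under uniform priors, and the rule is isolated in one
function (`quantify_alleles`) so an EM-weighted split could be slotted in.
Normalization is `log2(count / size_factor + 1)` with median-of-ratios
(DESeq-style) size factors when all features are positive everywhere, else
column-sum scaling; the method is recorded in the output metadata.  This
is a deliberately simple variance-taming transform: the downstream
statistics only need a stable log scale, and the metadata hook allows a
heavier variance-stabilizing transform to replace it.  Gene totals of
heterozygous samples are the log-sum of the two alleles,
`log2(2^a1 + 2^a2)`; homozygous samples pass the single allele through.

## MS quantification

The pipeline starts from PSM tables — spectral search is upstream and out
of scope; a documented TSV contract (peptide, plex_id, fraction, charge,
scan, expectation, one column per reporter channel) defines the interface.
Tryptic digestion cleaves after K/R except before proline (the stated rule
exactly, without the additional ExPASy exceptions), with configurable
missed cleavages (default 0) and length bounds (default 7–40).

PSM filtering keeps records with expectation strictly below 0.001 and at
least one positive reporter.  Modified peptide strings are collapsed to
bare sequences before grouping; reporter intensities are summed per
(peptide, plex) across scans, charges and fractions.  Peptide ratios are
`log2((sample + floor)/(reference + floor))` against the plex's pooled
reference channel, then median-centered per sample across all quantified
peptides; the intensity floor defaults to 0 and a zero reference with zero
floor is an error (the synthetic generator never emits zero reference
intensities).  Whole-proteome tables are instead median-centered per
protein across samples; the two centerings are separate named operations.
No TMT isotope-impurity correction is applied.

Peptide specificity is exact substring matching against the
provenance-tagged search database, with isoleucine and leucine distinct by
default (an I=L mode exists for sensitivity analysis).  Any hit on a
non-HLA record discards the peptide; hits on several HLA genes discard it;
the survivors are HLA-gene-specific.  Against a sample's genotype a
peptide is *matched* when it occurs in at least one of the two allele
proteins, *allele-specific* when in exactly one of a heterozygous pair.
Protein abundance sums intensities first and then takes the ratio (rather
than averaging peptide ratios): gene mode uses genotype-matched
gene-specific peptides, allele mode only allele-specific ones; features
with no contributing peptide are absent, not zero.

The matched-vs-unmatched comparison takes each sample's median log2 ratio
over matched and over unmatched gene-specific peptides and applies a
paired t-test across samples; a zero-variance difference vector is treated
as no evidence (p = 1 when the mean difference is 0).

## Cohort statistics

Per-patient tumor/normal differential expression is a Welch
(unequal-variance) t-test on the eligible peptide log2 ratios of the two
tissues — the peptide sets differ between tissues, so an unpaired test is
the appropriate default; a pooled-variance option exists.
Benjamini–Hochberg adjustment is applied across patients within gene ×
study, and direction is assigned at adjusted p < 0.05.  Allele-level fold
changes are computed from allele-specific peptides only, reported only for
patients significant in the gene-level test with at least 3 unique
allele-specific peptides in both tissues; flags mark linear fold changes
deviating more than 20% from 1 and overexpression above 30%.

Allele-group frequency enrichment compares observed group counts (two
alleles per patient per gene) with ancestry-weighted expected population
frequencies using a two-sided exact binomial test — no specific test is
canonical for this comparison, and the binomial on allele counts is the
minimal model — with BH adjustment across groups within a gene; a group is
enriched when adjusted p < 0.05 and the observed frequency exceeds the
expectation by more than 50%.  Expected frequencies are a required input,
never bundled: population registry tables differ and the ancestry
adjustment should be explicit.  The variance partition fits OLS
`protein ~ rna` and `protein ~ rna + score` and reports both R², the
covariate coefficient with its SE, and the correlation of base-model
residuals with the covariate; collinear predictors yield a flagged result.

## Synthetic cohorts

The generator's defaults define the standard study conditions:

| parameter | default | rationale |
|---|---|---|
| genes × alleles | 3 × 4 | three class I loci, a handful of common alleles |
| chain length | 365 aa | class I heavy-chain scale |
| substitution rate | 0.02 | ~7 substitutions/allele: shared and unique tryptic peptides coexist |
| cross-gene divergence | 0.05 | keeps some peptides multi-gene, exercising discard rules |
| background proteins | 40 × 200 aa | a non-HLA proteome that anchors per-sample median centering, as in a real whole-proteome run |
| cohort | 60 patients | desk-scale cohort; tests state smaller sizes where speed matters |
| LOH / imbalance rates | 0.08 / 0.08 | event prevalence in the single-digit-percent range seen in paired cohorts |
| imbalance factor | 0.3 | below the 0.5 calling threshold |
| RNA depth / dispersion | 300 reads/gene, NB dispersion 0.05 | bulk RNA-seq-like counts; dispersion 0 gives deterministic rounding |
| tumor effect | log2FC 1.0 in 50% of patient-genes | two-fold overexpression, the magnitude the cohort analyses target |
| TMT plex | 10 channels, last = pooled reference | tumor/normal pairs co-multiplexed; whole pairs per plex |
| detection probability | 0.7 per (peptide, plex) | DDA misses peptides at the plex level — identification is shared across isobaric channels |
| intensity CV | 0.15 | log-normal reporter noise in the 10–20% range typical of TMT |
| background fraction | 0.25 | co-isolation noise floor for peptides a sample does not carry, giving a ~2 log2 matched/unmatched separation — the order observed in real cohorts |

The pooled reference channel is the arithmetic mean of the plex members'
true abundances.  True PSMs draw expectation values below the 0.001
threshold; an optional decoy fraction draws above it.  Everything is
derived from one seed; regeneration is byte-identical.

What the generator does **not** emulate: spectra (no m/z, fragment ions,
retention time), peptide-dependent ionization efficiency, ratio
compression from co-isolation beyond the constant background floor,
alignment artifacts, intron-containing alleles, and genotyping error in
the allele frequencies.  Passing recovery tests therefore demonstrates
the correctness and statistical calibration of the pipeline's rules, not
robustness to every artifact of real acquisitions.

## Numerical and design choices

- Strict `<` at the homozygosity (0.15) and expectation (0.001)
  thresholds; `<` / `≥` for the imbalance rule; all thresholds are
  configurable parameters carried in `RunConfig` and serialized into every
  run manifest.
- Ties in allele selection break by canonical name order; all outputs are
  deterministically ordered, making runs reproducible byte for byte.
- Degenerate statistics are flagged rather than raised where a cohort scan
  must continue (too few peptides → not-computable comparison; constant
  input → undefined correlation), and raised where the input is unusable
  (no compatible reads, all-zero sample, zero reference at zero floor).
- Problem sizes in the test suite (12–60 patients, 10–100 replicates) are
  chosen so the full suite completes in a few minutes while leaving the
  statistical checks well-powered.

## Limitations

- The k-mer compatibility genotyper ignores sequencing error in reads
  (an errored k-mer simply makes a read incompatible) and does not model
  transcript abundance; it is not a replacement for EM-based typing tools
  on real data.
- The 50/50 shared-read split is exact only for balanced two-allele
  references; strong imbalance shifts shared reads incorrectly (unique
  reads still dominate the ratio estimate).
- Enrichment requires externally supplied population allele frequencies
  and ancestry weights; no registry data ships with the package.
- Gene- and allele-level protein estimates inherit the coverage problem of
  real cohorts: homozygous samples have no allele-specific peptides by
  definition, and genes with few discriminating peptides quantify poorly.
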