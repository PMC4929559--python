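# rhizolink

Linking natural variation in root-exudate metabolite profiles to nonsense
mutations in enzyme genes, across a panel of *Arabidopsis thaliana*
accessions.

## The problem

Untargeted LC/MS profiling of root exudates from genetically diverse
accessions (such as the 19 MAGIC founders) yields a matrix of *features* —
signals with a mass-to-charge ratio (m/z), retention time (RT) and
intensity. Some compounds are completely undetectable in particular
accessions. When the biosynthetic enzyme for a compound carries a premature
stop codon in exactly those accessions, the qualitative metabolic phenotype
can be traced to a single gene without any crossing or QTL mapping: the
feature's **absence pattern** (the set of accessions lacking it in every
replicate) equals the gene's **stop pattern** (the set of accessions whose
predicted protein is prematurely terminated).

`rhizolink` implements this matching workflow end to end, for people who
want to run it on their own feature matrices and variant tables, or to
study its statistical behaviour on simulated data:

1. **Preprocessing** — half-minimum imputation of missing values, per-feature
   log/z transformation, Kolmogorov–Smirnov normality QC, surrogate-variable
   batch correction, and blank filtering: a Welch heteroscedastic one-way
   ANOVA across all accessions plus the culture-medium blank
   (Benjamini–Hochberg FDR over features), with two-sample Welch tests
   against the blank as post-hoc confirmation. The Welch statistic, with
   `w_i = n_i/s_i²`, `W = Σw_i`, `x̄_w = Σw_i x̄_i / W` and
   `Λ = Σ[(1 − w_i/W)²/(n_i − 1)]/(k² − 1)`, is
   `F* = [Σw_i(x̄_i − x̄_w)²/(k − 1)] / [1 + 2(k − 2)Λ]` on
   `(k − 1, 1/(3Λ))` degrees of freedom.
2. **Clustering** — UPGMA on the Pearson correlation distance `d = 1 − r`
   between accession profiles, with multiscale-bootstrap cluster support:
   features are resampled at scales r ∈ {0.5, …, 1.4}, the per-scale
   bootstrap probabilities BP(r) are fitted to
   `Φ⁻¹(1 − BP(r)) = v√r + c/√r` by weighted least squares, and the
   approximately unbiased support is `AU = 1 − Φ(v − c)`. Dendrograms are
   cut at a correlation threshold (default 0.95).
3. **Genomics** — variant tables (VCF or a simple per-accession TSV) are
   restricted to annotated CDS; pairwise accession distances count allele
   mismatches per locus; each accession's variants are applied to the CDS,
   translated, and premature termination is called (nonsense SNP,
   frameshift, or large deletion) for every gene on an enzyme list.
4. **Annotation** — co-eluting features (RT single-linkage) are screened for
   M+1 isotopologue spacing (1.00336/|z| Da), intensity ratio and
   per-sample correlation; heads of isotope series are flagged
   monoisotopic ("[M]").
5. **Linkage** — absence patterns from the pre-imputation detection matrix
   are filtered (pattern length ≥ 1, monoisotopic flag, median observed
   intensity ≥ 10,000) and matched *exactly* against enzyme stop patterns;
   the report lists candidate (feature, gene) links with a per-length tally.

A first-class synthetic-data generator (`rhizolink.simulate`) produces
paired genomes, variant tables and feature matrices with *planted*
gene → metabolite links (censoring below a detection limit, blank
background features, batch effects, isotope companions, decoy absence
patterns, nonsense SNPs and one frameshift deletion), so the whole pipeline
is testable by parameter recovery, without downloads.

## Worked example

```python
from rhizolink import SyntheticConfig, run_all

result = run_all(SyntheticConfig(seed=1), nboot=100, seed=1)
print(result.funnel)
for c in result.report.candidates:
    print(c.feature_id, sorted(c.pattern), "->", c.genes, c.mechanisms)
print(result.recovery)
```

prints

```
{'n_features_total': 604, 'n_blank_differential': 560, 'n_absent_ge1': 86,
 'n_absent_len1': 27, 'n_absent_len2': 35, 'n_absent_len3': 24,
 'n_monoisotopic_absent': 14, 'n_intensity_passing': 14,
 'n_matched_features': 5, 'n_matched_len1': 1, 'n_matched_len2': 4}
F0444 ['Sf-2'] -> ['GENE0001'] ['nonsense_snp']
F0357 ['Rsch-4', 'Zu-0'] -> ['GENE0117'] ['nonsense_snp']
F0451 ['Mt-0', 'No-0'] -> ['GENE0108'] ['nonsense_snp']
F0329 ['Bur-0', 'Ws-0'] -> ['GENE0105'] ['nonsense_snp']
F0187 ['No-0', 'Tsu-0'] -> ['GENE0149'] ['frameshift']
{'n_truth_links': 5, 'n_reported_pairs': 5, 'recall': 1.0, 'precision': 1.0,
 'n_multi_gene_candidates': 0}
```

Reading: of 604 simulated features, 560 differ from the blank, 86 are absent
in at least one accession, 14 survive the monoisotopic and intensity
filters, and 5 match an enzyme stop pattern exactly — precisely the 5
planted causal links (one absent only in Sf-2, four with two-accession
patterns), with no false positives.

The same workflow is available from the shell:

```bash
rhizolink simulate --seed 1 --out data/
rhizolink preprocess --features data/features.tsv --samples data/samples.tsv --out pre/
rhizolink stops --variants data/variants.vcf --gff3 data/genes.gff3 \
    --fasta data/reference.fasta --enzymes data/enzyme_genes.txt --out stops/
rhizolink link --features data/features.tsv --samples data/samples.tsv \
    --stops stops/stop_patterns.tsv --retained pre/retained_features.tsv --out report/
# or everything at once:
rhizolink run-all --seed 1 --out out/
```

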