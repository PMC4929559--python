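# Methods

This note documents the models and procedures implemented in `rhizolink`,
the parameters that matter, the design choices that were genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Study design assumed

A panel of `n` accessions (default: the 19 Arabidopsis MAGIC founders) is
profiled in `r` replicate experiments (default 3); the replicate index
doubles as the batch, mirroring independent hydroponic growth experiments.
Culture-medium blanks accompany each batch. Features from negative- and
positive-mode electrospray ionisation are processed separately (one ion
mode per matrix, enforced by the container). The pipeline starts *after*
peak picking and alignment: raw-spectra processing, retention-time
alignment and gap filling are upstream and out of scope.

## Preprocessing

**Detection vs. intensity.** Absence calling is detection-based, not
numeric: a missing cell means the peak picker found nothing. The raw
("detection") matrix is therefore carried through the pipeline untouched,
and all imputation and transformation happen on a copy.

**Imputation.** Missing values are replaced by half the *per-feature*
minimum observed intensity (a global-minimum variant would couple features
of very different abundance; the per-feature rule keeps imputed values
below each feature's own detection range). Features with no observed value
cannot be imputed and raise an error.

**Transformation.** Natural log, then per-feature z-scaling to mean 0 /
sd 1 across samples. The log base is a cosmetic choice — z-scores are
identical for any base — and is fixed to `e` for reproducibility. Features
that are exactly constant after the log step carry no information and are
dropped with a logged warning. A one-sample Kolmogorov–Smirnov test against
N(0, 1) is reported per feature as QC only; it never drops features.

**Batch correction.** A deliberately simple two-step surrogate-variable
estimator: (1) residualise every feature on accession means (blanks form
their own group); (2) take the top `k` right-singular vectors of the
residual matrix as surrogate variables, with `k` chosen by a permutation
test on the singular values (each residual row permuted independently,
100 permutations, α = 0.05; components accepted while the observed singular
value stays above the permutation distribution) or fixed via `n_sv`. Each
feature is then regressed on accession indicators plus surrogates and the
surrogate contribution subtracted. This is not the iteratively reweighted
estimator of the original surrogate-variable literature; for the purpose
here — removing additive non-biological structure before clustering and
blank filtering — the simplified estimator is sufficient and fully
testable: on simulated batch shifts of 2 log units it removes ≥ 90 % of the
batch-mean separation while preserving accession effects (r > 0.95), which
the unit suite asserts.

**Blank filtering.** On the corrected, transformed matrix, each feature is
tested with a Welch heteroscedastic one-way ANOVA across all accession
groups plus the blank group; p-values are Benjamini–Hochberg adjusted over
features, and features with adjusted p < 0.05 *and* an unadjusted
two-sample Welch test p < 0.05 against the blank in at least one accession
are retained. The omnibus test is BH-corrected; the post-hoc two-sample
tests are deliberately uncorrected (they only confirm direction/location of
an already-significant omnibus result). Groups of n = 2 are allowed so that
one lost replicate does not abort a run; a group with zero variance makes
the feature untestable and it is dropped with a logged count. Order of
operations is fixed as impute → log/z → SVA → blank filter; SVA-before-
filtering is the default because the blank contrast itself benefits from
batch correction, and because imputed blank cells are constant per feature
until the surrogate regression separates them.

Note on calibration: the Welch approximation is *liberal* when many tiny
groups are compared (with 20 groups of n = 3 the null rejection rate at
α = 0.05 is ≈ 0.28–0.29, a property shared by R's `oneway.test` and
pingouin, both of which this implementation matches to machine precision).
The BH step operates on these p-values as given. Practically this makes the
blank filter *less* strict, which only enlarges the feature set entering
the absence screen; absence calls themselves are unaffected because they
use detection, not p-values.

## Clustering with bootstrap support

Accession profiles (per-accession replicate means of the corrected,
retained features) are compared by Pearson correlation distance
`d = 1 − r` and clustered by average linkage (UPGMA, SciPy's deterministic
implementation). Cluster confidence uses multiscale bootstrap resampling of
the features: at each scale `r ∈ {0.5, 0.6, …, 1.4}` (the conventional
grid), `B` bootstrap draws of `⌈n·r⌉` features are taken with replacement,
the samples re-clustered, and each original cluster's bootstrap probability
BP(r) recorded. The signed-distance/curvature model

    Φ⁻¹(1 − BP(r)) = v·√r + c/√r

is fitted by weighted least squares with binomial variance weights
`w_r = B·φ(ψ_r)² / (BP_r(1 − BP_r))`, giving `AU = 1 − Φ(v − c)`; when the
curvature `c` vanishes, AU reduces to BP(1), which the tests assert on
model-generated curves. Scales where the raw BP is exactly 0 or 1 carry no
information about the decay of support and are excluded from the fit; when
fewer than two informative scales remain, the AU estimate degenerates to
the clipped bound `1 − 1/(B+1)` (unanimous support) or `1/(B+1)` (never
seen), and the result is flagged `degenerate`. Bootstrap draws whose
resampled feature set leaves a sample constant are skipped (no tree exists
for them). Dendrograms are cut at a correlation threshold `t` (height
`1 − t`, default `t = 0.95`); cluster counts at this cut depend on the
upstream surrogate-variable estimate and are reported, not asserted.

The genetic distance matrix — allele mismatch counts per variant locus,
accessions absent from a record carrying the reference allele; a Hamming
distance, hence a metric — feeds the identical UPGMA code path.

## Variant consequences

Variants are restricted to annotated CDS (1-based inclusive GFF3
intervals; ref alleles validated against the reference genome; multi-allelic
records split to biallelic first). Per accession and gene, edits are
applied to the gene's genomic span right-to-left so reference coordinates
stay valid, CDS segment boundaries are shifted for upstream length changes
(a variant spanning an intron boundary edits the genomic sequence before
splicing), the segments are spliced, minus-strand genes are
reverse-complemented, and the result is translated from position 1 with
the standard genetic code. A call is *premature* when the first in-frame
stop lands strictly before the reference protein's stop, or when more than
10 % of the CDS has been deleted (large structural deletions count as
loss of function even without an early stop in the remaining frame). The
mechanism is classified from the causal edits: frameshift (net indel not a
multiple of 3) > large deletion > nonsense SNP. This direct
translate-and-compare replaces alignment-based evaluation of predicted
proteins; for SNP/indel-derived truncation the decision is equivalent and
deterministic, with no aligner dependency. Only one transcript model per
gene is supported; a gene counts as non-functional if that model's CDS is
prematurely terminated.

## Isotope annotation

Features are grouped by retention-time proximity (single linkage, tolerance
0.05 min) and, within a group, feature B is the `isotope_k` companion of A
when the m/z spacing matches `k · 1.00336/|z|` Da for charge `z ≤ 2` within
20 ppm, the mean intensity ratio lies in [0.02, 0.8], and the per-sample
intensity correlation over commonly detected samples is ≥ 0.8. Heads of
detected series are flagged monoisotopic. The default candidate filter
policy is **strict**: only flagged heads pass, matching the restrictive
behaviour of annotation-based "[M]" filters (lone features without a
detected companion are excluded); a **permissive** policy additionally
passes unassigned singletons. Full adduct dictionaries, pseudospectra and
fragment-ion annotation are out of scope — downstream only the binary
monoisotopic flag is consumed.

## Pattern matching

A feature is absent in an accession iff *all* replicates are missing (an
optional numeric LOD can reinterpret small observed values as missing; the
missing-value default reflects that "below the limit of detection" is the
peak picker's decision, and the absence threshold is acknowledged as the
workflow's soft spot). Blank samples never enter absence calls. Candidate
features need pattern length ≥ 1, the monoisotopic flag, and a median
*observed* intensity ≥ 10,000 counts (median over detected values only —
absent accessions must not drag down genuinely strong features). Matching
is exact set equality of absence and stop patterns over the identical
accession universe; all genes matching a feature are listed (multi-gene
rows flag pattern collisions), and unmatched features are reported
separately. Fuzzy (subset/Jaccard) matching is deliberately not offered.
Pattern lengths 1–3 are tallied prominently in the report summary;
matching itself runs at all lengths.

## The synthetic-data generator

The generator emulates: log-normal feature intensities (base level
N(μ = 11, σ = 0.8) on the log scale, ≈ e¹¹ ≈ 60,000 counts median);
per-accession biological effects (σ = 0.3) and replicate noise (σ = 0.2);
additive per-batch shifts (σ = 0.5 log units) shared by all features of a
batch; censoring of values below a detection limit (500 counts) to missing;
blank/background features (10 % of parents) present in blanks and samples
alike; M+1 isotopologue companions (ratio 0.15–0.5, jitter σ = 0.03 on the
log scale) for all planted features plus 20 % of other parents
(`isotope_fraction = 0` disables companions entirely); decoy absence
patterns (15 % of exudate features, sizes 1–3, never colliding with planted
patterns unless collisions are explicitly requested); and a 200-gene
reference genome with introns, both strands, background synonymous/missense
SNPs (Poisson rate 2 per gene) that never create stops, planted nonsense
SNPs, and one planted 1–2 bp frameshift deletion. Planted base intensities
are redrawn to exceed 25,000 counts so the planted compounds are strong
signals, as validated gene–metabolite cases typically are. Every planted
edit is verified at generation time by applying and re-translating it, and
the resulting stop codon index is recorded in the truth file.

What the generator does **not** emulate: chromatographic peak shape and
drift, adducts and in-source fragments, isotope fine structure, correlated
biosynthetic pathways (feature–feature correlation beyond isotope pairs),
population-genetic realism of the variant spectrum, and partial
(replicate-inconsistent) absences. Passing parameter-recovery tests on this
generator therefore demonstrates the correctness of the pipeline's logic
under its own absence model — not robustness to borderline peak-picking
decisions on real data, which the absence-definition threshold issue makes
the dominant failure mode in practice (false positives from intensity
distributions that straddle the detection limit must be excluded by
inspection).

## Numerical choices

- Determinism: every stochastic step takes a seed; generator sub-streams
  are derived as `(seed, stage)` pairs, so gene models, variants and the
  feature matrix are individually reproducible. Same config ⇒
  byte-identical output files.
- Degenerate inputs: constant features are dropped at transform; constant
  sample columns make correlation distance undefined and raise; features
  with a zero-variance test group are untestable in the blank filter and
  are dropped with a logged count; empty enzyme lists raise.
- Tie-breaking: UPGMA delegates to SciPy's deterministic nearest-neighbor
  chain; report rows sort by (pattern length, m/z, feature id); BP at
  scale 1 is read from the grid point nearest r = 1.
- Default problem sizes (19 × 3 samples, ~500 parent features, 200 genes,
  5 planted links, B = 100 bootstrap replicates in the driver, B = 1000 in
  the standalone clustering command) keep a full desk run in the tens of
  seconds while matching the scale of the motivating study design.

## Known limitations

- Exact pattern equality is brittle to a single miscalled absence; this is
  inherent to the qualitative matching idea, and the decoy machinery exists
  precisely to quantify the resulting precision on synthetic data.
- The blank filter inherits the Welch approximation's liberal small-sample
  calibration (see above).
- Missense variants, promoter/regulatory variation, splice-site effects,
  start-loss, and redundancy between paralogous enzymes are out of scope.
- Cross-ion-mode cluster matching is manual/visual in the motivating
  workflow and is not implemented.
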