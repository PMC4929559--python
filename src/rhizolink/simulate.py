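"""Paired synthetic genomes and LC/MS feature matrices with planted links.

The generator emulates the study design this pipeline targets: a panel of
Arabidopsis accessions (default: the 19 MAGIC founders) grown in replicated
hydroponic batches, root-exudate LC/MS features with censoring below a limit
of detection, culture-medium blank background signals, additive batch
effects on the log scale, M+1 isotopologue companion features, and coding
variants in a reference genome — including planted nonsense SNPs (and one
small frameshift deletion) in "enzyme" genes whose carrier accessions lack
the linked metabolite feature in every replicate.  Each planted
gene -> feature causal link is recorded as ground truth so downstream
parameter recovery is directly testable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    ACCESSIONS_19,
    BLANK,
    FeatureMatrix,
    GeneModel,
    PlantedLink,
    VariantRecord,
)
from .annotate import ISOTOPE_MASS_DIFF
from .genomics import apply_variants, call_premature_stop

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_gene_models",
    "select_enzyme_genes",
    "generate_variants",
    "generate_feature_matrix",
    "generate_dataset",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGT", "TGCA")
SENSE_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Dimensions and noise levels of a synthetic study.

    Defaults mirror the targeted study design: 19 accessions x 3 replicate
    hydroponic experiments (the replicate index doubles as the batch), a few
    hundred ESI(-) features and a few hundred genes, with 5 planted
    gene -> metabolite links.
    """

    n_accessions: int = 19
    n_replicates: int = 3
    n_blanks: int = 3
    n_genes: int = 200
    n_enzyme_genes: int = 60
    n_features: int = 500
    n_planted_links: int = 5
    cds_length_codons: tuple[int, int] = (60, 200)
    #: intensity below which the peak picker reports nothing (value censored)
    lod: float = 500.0
    #: log-intensity distribution of feature base levels
    mu_log: float = 11.0
    sigma_log: float = 0.8
    #: per-accession biological effect and replicate noise, log scale
    accession_sd: float = 0.3
    replicate_sd: float = 0.2
    #: additive per-batch shift on the log scale
    batch_effect_sd: float = 0.5
    #: fraction of non-planted parent features given an M+1 companion
    isotope_fraction: float = 0.2
    #: isotopologue / parent mean intensity ratio range
    isotope_ratio: tuple[float, float] = (0.15, 0.5)
    #: Poisson rate of synonymous/missense background SNPs per gene
    background_variant_rate: float = 2.0
    #: fraction of features that are blank/medium background signals
    background_feature_fraction: float = 0.10
    #: fraction of exudate features given a decoy absence pattern
    decoy_absence_fraction: float = 0.15
    #: plant a second enzyme gene with the same stop pattern as link 0,
    #: forcing a multi-gene match in the final report
    planted_pattern_collision: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_accessions": self.n_accessions,
            "n_replicates": self.n_replicates,
            "n_blanks": self.n_blanks,
            "n_genes": self.n_genes,
            "n_enzyme_genes": self.n_enzyme_genes,
            "n_features": self.n_features,
            "n_planted_links": self.n_planted_links,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_planted_links > min(self.n_enzyme_genes, self.n_features):
            raise ValueError(
                "n_planted_links must not exceed min(n_enzyme_genes, n_features)"
            )
        if self.n_enzyme_genes > self.n_genes:
            raise ValueError("n_enzyme_genes must not exceed n_genes")
        if self.lod <= 0:
            raise ValueError("lod must be positive")
        lo, hi = self.cds_length_codons
        if lo < 10 or hi < lo:
            raise ValueError("cds_length_codons must be a range with minimum >= 10")

    @property
    def accession_names(self) -> tuple[str, ...]:
        if self.n_accessions <= len(ACCESSIONS_19):
            return ACCESSIONS_19[: self.n_accessions]
        extra = tuple(
            f"Acc-{i:02d}" for i in range(len(ACCESSIONS_19), self.n_accessions)
        )
        return ACCESSIONS_19 + extra


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces, plus the ground truth."""

    config: SyntheticConfig
    genome: dict[str, str]
    gene_models: list[GeneModel]
    enzyme_gene_ids: list[str]
    variants: list[VariantRecord]
    truth: list[PlantedLink]
    feature_matrix: FeatureMatrix

    def __post_init__(self) -> None:
        enzyme = set(self.enzyme_gene_ids)
        fids = set(self.feature_matrix.feature_ids)
        for link in self.truth:
            if link.gene_id not in enzyme:
                raise ValueError(f"truth gene {link.gene_id} not in enzyme list")
            if link.feature_id not in fids:
                raise ValueError(f"truth feature {link.feature_id} not in matrix")


# ---------------------------------------------------------------------------
# gene models and reference genome
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def generate_gene_models(
    config: SyntheticConfig,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Lay out ``n_genes`` protein-coding genes on one synthetic chromosome.

    Each CDS starts with ATG, ends on a stop codon and contains no internal
    in-frame stop; about half the genes carry one intron and strands are
    drawn at random.  Returns the gene models and the reference genome
    (``{chrom: sequence}``), mutually consistent.
    """
    rng = np.random.default_rng([config.seed, 0])
    chrom = "chr1"
    parts: list[str] = []
    cursor = 1  # next free 1-based position
    genes: list[GeneModel] = []
    lo, hi = config.cds_length_codons
    for i in range(config.n_genes):
        gap = int(rng.integers(100, 301))
        parts.append(_random_bases(rng, gap))
        cursor += gap
        n_codons = int(rng.integers(lo, hi + 1))
        body = "".join(rng.choice(SENSE_CODONS, size=n_codons - 2))
        cds = "ATG" + body + str(rng.choice(STOP_CODONS))
        strand = str(rng.choice(["+", "-"]))
        gene_id = f"GENE{i + 1:04d}"
        if rng.random() < 0.5 and n_codons >= 20:
            cut = 3 * int(rng.integers(5, n_codons - 5))
            intron = "GT" + _random_bases(rng, int(rng.integers(56, 117))) + "AG"
            p1, p2 = cds[:cut], cds[cut:]
            if strand == "+":
                gseq = p1 + intron + p2
                segs = [
                    (cursor, cursor + len(p1) - 1),
                    (cursor + len(p1) + len(intron), cursor + len(gseq) - 1),
                ]
            else:
                gseq = (p1 + intron + p2).translate(COMPLEMENT)[::-1]
                segs = [
                    (cursor, cursor + len(p2) - 1),
                    (cursor + len(p2) + len(intron), cursor + len(gseq) - 1),
                ]
        else:
            gseq = cds if strand == "+" else cds.translate(COMPLEMENT)[::-1]
            segs = [(cursor, cursor + len(cds) - 1)]
        parts.append(gseq)
        cursor += len(gseq)
        protein = _translate(cds)
        genes.append(GeneModel(gene_id, chrom, strand, segs, cds, protein[:-1]))
    parts.append(_random_bases(rng, 200))
    return genes, {chrom: "".join(parts)}


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds).translate())


def select_enzyme_genes(config: SyntheticConfig, gene_models: list[GeneModel]) -> list[str]:
    """Deterministic random subset of genes flagged as the enzyme list."""
    rng = np.random.default_rng([config.seed, 3])
    ids = [g.gene_id for g in gene_models]
    chosen = rng.choice(len(ids), size=config.n_enzyme_genes, replace=False)
    return sorted(ids[i] for i in chosen)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def _cds_pos_to_genomic(gene: GeneModel, cpos: int) -> int:
    """Map a 0-based position in the spliced CDS to a 1-based genomic position."""
    lengths = [e - s + 1 for s, e in gene.cds_segments]
    if gene.strand == "+":
        offset = cpos
        for (s, _), ln in zip(gene.cds_segments, lengths):
            if offset < ln:
                return s + offset
            offset -= ln
    else:
        offset = cpos
        for (_, e), ln in zip(reversed(gene.cds_segments), list(reversed(lengths))):
            if offset < ln:
                return e - offset
            offset -= ln
    raise IndexError(f"{gene.gene_id}: CDS position {cpos} out of range")


def _nonsense_candidates(cds: str, codon_index: int) -> list[tuple[int, str]]:
    """Single-base edits of codon ``codon_index`` (0-based) yielding a stop.

    Returns (cds position, new base) pairs in transcript orientation.
    """
    codon = cds[3 * codon_index : 3 * codon_index + 3]
    out = []
    for j in range(3):
        for b in BASES:
            if b == codon[j]:
                continue
            mutated = codon[:j] + b + codon[j + 1 :]
            if mutated in STOP_CODONS:
                out.append((3 * codon_index + j, b))
    return out


def _snp_record(
    gene: GeneModel, genome: dict[str, str], cpos: int, new_base: str, accession: str
) -> VariantRecord:
    gpos = _cds_pos_to_genomic(gene, cpos)
    ref = genome[gene.chrom][gpos - 1]
    alt = new_base if gene.strand == "+" else new_base.translate(COMPLEMENT)
    return VariantRecord(accession, gene.chrom, gpos, ref, alt)


def _frameshift_deletion_records(
    gene: GeneModel, genome: dict[str, str], cpos: int, n_del: int, accession: str
) -> VariantRecord | None:
    """Anchored deletion of ``n_del`` coding bases starting at CDS pos ``cpos``.

    Returns None when the run crosses a segment boundary (caller retries).
    """
    gpositions = sorted(_cds_pos_to_genomic(gene, cpos + i) for i in range(n_del))
    if gpositions[-1] - gpositions[0] != n_del - 1:
        return None
    g_lo = gpositions[0]
    anchor = g_lo - 1
    if anchor < 1:
        return None
    chromseq = genome[gene.chrom]
    ref = chromseq[anchor - 1 : anchor - 1 + n_del + 1]
    return VariantRecord(accession, gene.chrom, anchor, ref, ref[0])


def generate_variants(
    config: SyntheticConfig,
    gene_models: list[GeneModel],
    genome: dict[str, str],
) -> tuple[list[VariantRecord], list[PlantedLink]]:
    """Plant loss-of-function links in enzyme genes, plus background SNPs.

    For each planted link every affected accession carries an edit truncating
    the predicted protein (a nonsense SNP for most links; one link always
    uses a small frameshift deletion).  Background variants are synonymous or
    missense SNPs in non-planted genes and never create premature stops.
    Every planted edit is verified by applying it and re-translating; the
    resulting first stop codon index is recorded in the truth.
    """
    rng = np.random.default_rng([config.seed, 1])
    accessions = list(config.accession_names)
    models = {g.gene_id: g for g in gene_models}
    enzyme_ids = select_enzyme_genes(config, gene_models)
    usable = [
        g for g in enzyme_ids
        if len(models[g].protein) >= max(30, config.cds_length_codons[0] - 1)
    ]
    if len(usable) < config.n_planted_links + int(config.planted_pattern_collision):
        raise ValueError("not enough sufficiently long enzyme genes to plant links")
    order = rng.permutation(len(usable))
    planted_gene_ids = [usable[i] for i in order[: config.n_planted_links]]
    collision_gene = (
        usable[order[config.n_planted_links]]
        if config.planted_pattern_collision
        else None
    )

    used_patterns: set[frozenset[str]] = set()
    links: list[PlantedLink] = []
    variants: list[VariantRecord] = []

    def draw_pattern() -> frozenset[str]:
        for _ in range(1000):
            size = int(rng.integers(1, 4))
            chosen = frozenset(
                accessions[i]
                for i in rng.choice(len(accessions), size=size, replace=False)
            )
            if chosen not in used_patterns and len(chosen) < len(accessions):
                return chosen
        raise RuntimeError("could not draw a fresh absence pattern")

    def plant_truncation(gene_id: str, affected: frozenset[str], mechanism: str):
        gene = models[gene_id]
        n_codons = len(gene.cds_seq) // 3
        recs: list[VariantRecord] | None = None
        stop_index = None
        for _ in range(200):
            k = int(rng.integers(5, n_codons - 8))
            if mechanism == "nonsense_snp":
                cands = _nonsense_candidates(gene.cds_seq, k)
                if not cands:
                    continue
                cpos, base = cands[int(rng.integers(0, len(cands)))]
                trial = [_snp_record(gene, genome, cpos, base, acc) for acc in sorted(affected)]
            else:  # frameshift: delete 1 or 2 coding bases
                n_del = int(rng.integers(1, 3))
                one = _frameshift_deletion_records(
                    gene, genome, 3 * k, n_del, sorted(affected)[0]
                )
                if one is None:
                    continue
                trial = [
                    VariantRecord(acc, one.chrom, one.pos, one.ref, one.alt)
                    for acc in sorted(affected)
                ]
            status = call_premature_stop(
                apply_variants(gene, [trial[0]], genome),
                gene.protein,
                gene_id=gene_id,
                accession=trial[0].accession,
                variants=[trial[0]],
                reference_cds_len=len(gene.cds_seq),
            )
            if status.premature:
                recs, stop_index = trial, status.first_stop_codon_index
                break
        if recs is None:
            raise RuntimeError(f"could not plant a truncating edit in {gene_id}")
        variants.extend(recs)
        return stop_index

    frameshift_link = int(rng.integers(0, config.n_planted_links))
    for li, gene_id in enumerate(planted_gene_ids):
        affected = draw_pattern()
        used_patterns.add(affected)
        mech = "frameshift" if li == frameshift_link else "nonsense_snp"
        stop_index = plant_truncation(gene_id, affected, mech)
        links.append(
            PlantedLink(
                gene_id=gene_id,
                feature_id="",  # filled when the feature matrix is generated
                affected_accessions=affected,
                mechanism=mech,
                stop_codon_index=stop_index,
            )
        )
    if collision_gene is not None:
        plant_truncation(collision_gene, links[0].affected_accessions, "nonsense_snp")

    # background: synonymous/missense SNPs, never creating stops
    planted = set(planted_gene_ids) | ({collision_gene} if collision_gene else set())
    for gene in gene_models:
        if gene.gene_id in planted:
            continue
        n_bg = int(rng.poisson(config.background_variant_rate))
        taken: set[int] = set()
        for _ in range(n_bg):
            n_codons = len(gene.cds_seq) // 3
            for _ in range(50):
                cpos = int(rng.integers(3, 3 * (n_codons - 1)))
                ci = cpos // 3
                codon = gene.cds_seq[3 * ci : 3 * ci + 3]
                j = cpos % 3
                base = str(rng.choice([b for b in BASES if b != codon[j]]))
                if codon[:j] + base + codon[j + 1 :] in STOP_CODONS:
                    continue
                gpos = _cds_pos_to_genomic(gene, cpos)
                if gpos in taken:
                    continue
                taken.add(gpos)
                size = int(rng.integers(1, 5))
                carriers = rng.choice(len(accessions), size=size, replace=False)
                for ai in sorted(carriers):
                    variants.append(
                        _snp_record(gene, genome, cpos, base, accessions[ai])
                    )
                break
    variants.sort(key=lambda r: (r.chrom, r.pos, r.accession, r.alt))
    return variants, links


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

def generate_feature_matrix(
    config: SyntheticConfig, truth: list[PlantedLink]
) -> tuple[FeatureMatrix, list[PlantedLink]]:
    """Simulate the LC/MS feature matrix and bind truth links to features.

    Returns the matrix and the truth list with ``feature_id`` filled in.
    Planted features are forced missing in all replicates of their affected
    accessions and are guaranteed strong signals elsewhere (well above the
    detection limit and the downstream median-intensity filter); every
    planted feature receives an M+1 isotopologue companion so it survives a
    strict monoisotopic filter.
    """
    rng = np.random.default_rng([config.seed, 2])
    accessions = list(config.accession_names)

    sample_rows = []
    for acc in accessions:
        for rep in range(1, config.n_replicates + 1):
            sample_rows.append((f"{acc}_r{rep}", acc, rep, rep, False))
    for b in range(1, config.n_blanks + 1):
        batch = (b - 1) % config.n_replicates + 1
        sample_rows.append((f"BLANK_b{b}", BLANK, b, batch, True))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "accession", "replicate", "batch", "is_blank"]
    ).set_index("sample_id")

    n_bg = int(round(config.background_feature_fraction * config.n_features))
    n_exu = config.n_features - n_bg
    feature_ids = [f"F{i + 1:04d}" for i in range(config.n_features)]
    is_background = np.zeros(config.n_features, dtype=bool)
    bg_idx = rng.choice(config.n_features, size=n_bg, replace=False)
    is_background[bg_idx] = True
    exu_idx = np.flatnonzero(~is_background)

    planted_feat_pos = rng.choice(len(exu_idx), size=len(truth), replace=False)
    planted_idx = exu_idx[planted_feat_pos]
    bound_truth = [
        dataclasses.replace(link, feature_id=feature_ids[fi])
        for link, fi in zip(truth, planted_idx)
    ]
    planted_patterns = {l.affected_accessions for l in bound_truth}

    # decoy absence patterns on non-planted exudate features
    decoy_pool = [i for i in exu_idx if i not in set(planted_idx)]
    n_decoy = int(round(config.decoy_absence_fraction * len(decoy_pool)))
    decoy_idx = rng.choice(len(decoy_pool), size=n_decoy, replace=False)
    absent_in: dict[int, frozenset[str]] = {}
    for link, fi in zip(bound_truth, planted_idx):
        absent_in[fi] = link.affected_accessions
    for di in decoy_idx:
        fi = decoy_pool[di]
        for _ in range(100):
            size = int(rng.integers(1, 4))
            chosen = frozenset(
                accessions[i] for i in rng.choice(len(accessions), size=size, replace=False)
            )
            if chosen not in planted_patterns:
                absent_in[fi] = chosen
                break

    mz = np.round(rng.uniform(100, 1000, size=config.n_features), 4)
    rt = np.round(rng.uniform(0.5, 11.5, size=config.n_features), 3)
    mu = rng.normal(config.mu_log, config.sigma_log, size=config.n_features)
    # planted compounds are strong signals: base level comfortably above both
    # the detection limit and the downstream median-intensity filter
    strong = np.log(25000.0)
    for fi in planted_idx:
        while mu[fi] < strong:
            mu[fi] = rng.normal(config.mu_log, config.sigma_log)

    batch_shift = rng.normal(0.0, config.batch_effect_sd, size=config.n_replicates)
    acc_eff = rng.normal(0.0, config.accession_sd, size=(config.n_features, len(accessions)))
    acc_pos = {a: i for i, a in enumerate(accessions)}

    values = np.full((config.n_features, len(samples)), np.nan)
    for si, (sid, row) in enumerate(samples.iterrows()):
        shift = batch_shift[int(row["batch"]) - 1]
        noise = rng.normal(0.0, config.replicate_sd, size=config.n_features)
        if row["is_blank"]:
            logv = mu + shift + noise
            logv[~is_background] = -np.inf  # exudate features absent from medium
        else:
            ai = acc_pos[row["accession"]]
            logv = mu + acc_eff[:, ai] + shift + noise
            for fi, pattern in absent_in.items():
                if row["accession"] in pattern:
                    logv[fi] = -np.inf
        values[:, si] = np.exp(logv)
    values[values < config.lod] = np.nan

    # M+1 isotopologue companions: all planted features, plus a random
    # fraction of the remaining parents; isotope_fraction = 0 switches
    # companions off entirely (no feature pair with isotopologue spacing)
    if config.isotope_fraction > 0:
        companion_of = list(planted_idx)
        others = [i for i in range(config.n_features) if i not in set(planted_idx)]
        n_iso = int(round(config.isotope_fraction * len(others)))
        for oi in rng.choice(len(others), size=n_iso, replace=False):
            companion_of.append(others[oi])
        companion_of = sorted(companion_of)
    else:
        companion_of = []
    comp_rows = []
    comp_meta = []
    lo_r, hi_r = config.isotope_ratio
    for fi in companion_of:
        ratio = rng.uniform(lo_r, hi_r)
        jitter = np.exp(rng.normal(0.0, 0.03, size=values.shape[1]))
        comp = values[fi] * ratio * jitter
        comp[comp < config.lod] = np.nan
        comp_rows.append(comp)
        comp_meta.append(
            (f"{feature_ids[fi]}i", round(mz[fi] + ISOTOPE_MASS_DIFF, 4), rt[fi])
        )

    all_ids = feature_ids + [m[0] for m in comp_meta]
    all_values = np.vstack([values] + [r[None, :] for r in comp_rows]) if comp_rows else values
    features = pd.DataFrame(
        {
            "mz": np.concatenate([mz, [m[1] for m in comp_meta]]),
            "rt": np.concatenate([rt, [m[2] for m in comp_meta]]),
            "mode": "ESI(-)",
        },
        index=pd.Index(all_ids, name="feature_id"),
    )
    intensities = pd.DataFrame(all_values, index=features.index, columns=samples.index)
    return FeatureMatrix(intensities, features, samples), bound_truth


def generate_dataset(config: SyntheticConfig | None = None, **kwargs) -> SyntheticDataset:
    """Generate a complete, internally consistent synthetic study."""
    if config is None:
        config = SyntheticConfig(**kwargs)
    elif kwargs:
        config = dataclasses.replace(config, **kwargs)
    genes, genome = generate_gene_models(config)
    enzyme_ids = select_enzyme_genes(config, genes)
    variants, truth = generate_variants(config, genes, genome)
    matrix, truth = generate_feature_matrix(config, truth)
    return SyntheticDataset(
        config=config,
        genome=genome,
        gene_models=genes,
        enzyme_gene_ids=enzyme_ids,
        variants=variants,
        truth=truth,
        feature_matrix=matrix,
    )
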