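"""Variant handling: CDS restriction, mismatch distances, premature-stop calls.

Variant tables (one record per accession x locus, differences from the
reference) are restricted to annotated coding sequence, summed into a
pairwise mismatch distance matrix between accessions, and applied to each
gene's CDS to predict the accession protein.  A gene is called prematurely
terminated in an accession when the variant-applied CDS translates to a stop
before the reference protein's end (nonsense SNP, frameshift indel) or when
a deletion removes a substantial part of the CDS.

Coordinates: GFF3 and variant positions are 1-based inclusive; internal
sequence slices are 0-based half-open.  Accessions missing from a record are
assumed homozygous reference (variant tables list differences only).
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
from Bio.Seq import Seq

from .cluster import DistanceMatrix
from .datatypes import GeneModel, ProteinStatus, StopPattern, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "restrict_to_cds",
    "mismatch_distance",
    "apply_variants",
    "call_premature_stop",
    "enzyme_stop_patterns",
    "split_multiallelic",
]

#: Fraction of CDS length that a deletion must remove to count as a
#: loss-of-function structural deletion on its own.
LARGE_DELETION_FRACTION = 0.10


def split_multiallelic(records: list[VariantRecord]) -> list[VariantRecord]:
    """Split comma-separated ALT alleles into biallelic records (no-op otherwise)."""
    out = []
    for rec in records:
        if "," in rec.alt:
            for alt in rec.alt.split(","):
                out.append(VariantRecord(rec.accession, rec.chrom, rec.pos, rec.ref, alt))
        else:
            out.append(rec)
    return out


def restrict_to_cds(
    variants: list[VariantRecord],
    gene_models: list[GeneModel],
    genome: dict[str, str] | None = None,
) -> dict[str, list[VariantRecord]]:
    """Keep variants whose reference span intersects a CDS interval.

    Returns a mapping gene_id -> variants (a variant overlapping two genes is
    listed under both).  If ``genome`` is given, every retained record's ref
    allele is checked against the reference sequence; a disagreement raises.
    """
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in gene_models:
        by_chrom[g.chrom].append(g)
    out: dict[str, list[VariantRecord]] = defaultdict(list)
    for rec in variants:
        if genome is not None:
            ref_seq = genome[rec.chrom][rec.pos - 1 : rec.pos - 1 + len(rec.ref)]
            if ref_seq.upper() != rec.ref.upper():
                raise ValueError(
                    f"ref allele mismatch at {rec.chrom}:{rec.pos}: "
                    f"record says {rec.ref!r}, reference has {ref_seq!r}"
                )
        for g in by_chrom.get(rec.chrom, ()):
            if g.overlaps(rec.pos, rec.end):
                out[g.gene_id].append(rec)
    return dict(out)


def mismatch_distance(
    variants: list[VariantRecord], accessions: list[str]
) -> DistanceMatrix:
    """Pairwise mismatch count between accessions over all variant loci.

    For each locus (chrom, pos, ref) every accession carries either its
    recorded alternative allele or, absent a record, the reference allele;
    each pairwise allele disagreement adds 1 to the distance.  This is a
    Hamming distance over allele vectors, hence a metric.
    """
    acc_index = {a: i for i, a in enumerate(accessions)}
    loci: dict[tuple, dict[int, str]] = defaultdict(dict)
    for rec in variants:
        if rec.accession not in acc_index:
            continue
        loci[(rec.chrom, rec.pos, rec.ref)][acc_index[rec.accession]] = rec.alt
    n = len(accessions)
    D = np.zeros((n, n), dtype=float)
    for alleles in loci.values():
        codes = np.zeros(n, dtype=object)
        for i, alt in alleles.items():
            codes[i] = alt
        D += (codes[:, None] != codes[None, :]).astype(float)
    return DistanceMatrix(list(accessions), D)


# ---------------------------------------------------------------------------
# applying variants to a gene
# ---------------------------------------------------------------------------

def apply_variants(
    gene: GeneModel,
    variants: list[VariantRecord],
    genome: dict[str, str],
) -> str:
    """Return the accession CDS after applying one accession's variants.

    Edits are applied to the gene's genomic span right-to-left (so earlier
    positions stay valid), CDS segment boundaries are shifted for length
    changes upstream of them, then the segments are spliced and
    reverse-complemented for minus-strand genes.  Overlapping variants raise.
    A variant spanning an intron (or segment) boundary is applied to the
    genomic sequence before splicing, deleting the coding bases it covers.
    """
    span_start, span_end = gene.span
    seq = list(genome[gene.chrom][span_start - 1 : span_end])
    # segment coordinates local to the span, 0-based half-open
    segs = [[s - span_start, e - span_start + 1] for s, e in gene.cds_segments]

    ordered = sorted(variants, key=lambda r: r.pos, reverse=True)
    for later, earlier in zip(ordered, ordered[1:]):
        if earlier.end >= later.pos:
            raise ValueError(
                f"{gene.gene_id}: overlapping variants at "
                f"{earlier.chrom}:{earlier.pos} and {later.chrom}:{later.pos}"
            )
    for rec in ordered:
        p = rec.pos - span_start
        if p < 0 or p + len(rec.ref) > len(seq):
            # clip to the span: only the in-span part of a long deletion matters
            left = max(p, 0)
            right = min(p + len(rec.ref), len(seq))
            if left >= right:
                continue
            seq[left:right] = []
            p, ref_len, alt_len = left, right - left, 0
        else:
            current = "".join(seq[p : p + len(rec.ref)])
            if current.upper() != rec.ref.upper():
                raise ValueError(
                    f"{gene.gene_id}: ref mismatch at {rec.chrom}:{rec.pos}"
                )
            seq[p : p + len(rec.ref)] = list(rec.alt)
            ref_len, alt_len = len(rec.ref), len(rec.alt)
        delta = alt_len - ref_len
        if delta:
            for seg in segs:
                for j in (0, 1):
                    q = seg[j]
                    if q <= p:
                        continue
                    if q >= p + ref_len:
                        seg[j] = q + delta
                    else:  # boundary inside the edited region
                        seg[j] = p + min(alt_len, q - p)
    spliced = "".join("".join(seq[max(s, 0) : max(e, 0)]) for s, e in segs)
    if gene.strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
    return spliced


def _classify_mechanism(
    variants: list[VariantRecord], acc_cds: str, ref_cds_len: int
) -> str:
    net = sum(v.length_change for v in variants)
    deleted = ref_cds_len - len(acc_cds)
    if any(v.length_change % 3 != 0 for v in variants):
        if deleted > LARGE_DELETION_FRACTION * ref_cds_len:
            return "deletion"
        return "frameshift"
    if deleted > LARGE_DELETION_FRACTION * ref_cds_len:
        return "deletion"
    if any(v.is_snp for v in variants):
        return "nonsense_snp"
    return "none" if net == 0 else "frameshift"


def call_premature_stop(
    accession_cds: str,
    reference_protein: str,
    *,
    gene_id: str = "",
    accession: str = "",
    variants: list[VariantRecord] | None = None,
    reference_cds_len: int | None = None,
) -> ProteinStatus:
    """Call premature termination by direct translation of the accession CDS.

    The CDS is translated from position 1 with the standard genetic code;
    the call is premature when the first in-frame stop falls strictly before
    the reference protein's stop position, or when more than 10% of the CDS
    has been deleted (large structural deletion).  The mechanism is
    classified from the causal edits when ``variants`` are supplied.
    """
    if not accession_cds:
        raise ValueError("accession CDS is empty")
    ref_cds_len = reference_cds_len if reference_cds_len is not None else (
        3 * (len(reference_protein) + 1)
    )
    if len(accession_cds) < 3:
        return ProteinStatus(gene_id, accession, True, None, "deletion")
    usable = len(accession_cds) - len(accession_cds) % 3
    protein = str(Seq(accession_cds[:usable]).translate())
    stop = protein.find("*")
    first_stop = stop + 1 if stop >= 0 else None  # 1-based codon index
    premature = stop >= 0 and stop < len(reference_protein)
    large_del = (ref_cds_len - len(accession_cds)) > LARGE_DELETION_FRACTION * ref_cds_len
    # a runaway translation (no stop at all in a frameshifted tail shorter
    # than the reference) is not premature by the stop criterion alone
    if not premature and not large_del:
        return ProteinStatus(gene_id, accession, False, first_stop, "none")
    mech = (
        _classify_mechanism(variants, accession_cds, ref_cds_len)
        if variants
        else ("deletion" if large_del and not premature else "nonsense_snp")
    )
    if mech == "none":
        mech = "nonsense_snp" if premature else "deletion"
    return ProteinStatus(gene_id, accession, True, first_stop, mech)


def enzyme_stop_patterns(
    gene_models: list[GeneModel],
    variants: list[VariantRecord],
    enzyme_gene_ids: list[str],
    accessions: list[str],
    genome: dict[str, str],
    *,
    return_statuses: bool = False,
):
    """Per-enzyme-gene boolean stop patterns over the accession panel.

    Only genes with at least one prematurely terminated accession yield a
    pattern (all-reference genes carry no signal for matching).  Enzyme ids
    without a gene model are logged and skipped.
    """
    if not enzyme_gene_ids:
        raise ValueError("empty enzyme gene list")
    models = {g.gene_id: g for g in gene_models}
    missing = [g for g in enzyme_gene_ids if g not in models]
    if missing:
        logger.warning("enzyme list: %d id(s) without a gene model skipped", len(missing))
    enzymes = [models[g] for g in enzyme_gene_ids if g in models]
    per_gene = restrict_to_cds(variants, enzymes, genome)
    patterns: list[StopPattern] = []
    statuses: list[ProteinStatus] = []
    acc_tuple = tuple(accessions)
    for gene in enzymes:
        recs = per_gene.get(gene.gene_id, [])
        by_acc: dict[str, list[VariantRecord]] = defaultdict(list)
        for r in recs:
            by_acc[r.accession].append(r)
        flags = np.zeros(len(acc_tuple), dtype=bool)
        for i, acc in enumerate(acc_tuple):
            if acc not in by_acc:
                continue
            acc_cds = apply_variants(gene, by_acc[acc], genome)
            status = call_premature_stop(
                acc_cds,
                gene.protein,
                gene_id=gene.gene_id,
                accession=acc,
                variants=by_acc[acc],
                reference_cds_len=len(gene.cds_seq),
            )
            statuses.append(status)
            flags[i] = status.premature
        if flags.any():
            patterns.append(StopPattern(gene.gene_id, acc_tuple, flags))
    if return_statuses:
        return patterns, statuses
    return patterns
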