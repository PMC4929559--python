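"""Unit tests for CDS restriction, mismatch distances and stop calling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizolink import (
    VariantRecord,
    apply_variants,
    call_premature_stop,
    enzyme_stop_patterns,
    mismatch_distance,
    restrict_to_cds,
)
from rhizolink.datatypes import GeneModel
from rhizolink.genomics import split_multiallelic


# a + strand gene with one intron: CDS = ATG CAA GGT TGT ... TAA
_CDS = "ATG" + "CAAGGTTGTCCAGAA" * 4 + "TAA"  # 66 nt, 22 codons
_INTRON = "GT" + "ACGTAC" * 5 + "AG"


def _plus_gene(offset=10):
    cut = 30
    p1, p2 = _CDS[:cut], _CDS[cut:]
    genome_seq = "A" * (offset - 1) + p1 + _INTRON + p2 + "T" * 20
    segs = [
        (offset, offset + len(p1) - 1),
        (offset + len(p1) + len(_INTRON), offset + len(p1) + len(_INTRON) + len(p2) - 1),
    ]
    from Bio.Seq import Seq

    gene = GeneModel("G1", "chr1", "+", segs, _CDS, str(Seq(_CDS).translate())[:-1])
    return gene, {"chr1": genome_seq}


_CODON = {}
for b1 in "TCAG":
    for b2 in "TCAG":
        for b3 in "TCAG":
            _CODON[b1 + b2 + b3] = None
_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for i, codon in enumerate(_CODON):
    _CODON[codon] = _TABLE[i]


def _translate_oracle(cds):
    """Frame-1 translation from an explicit codon table (independent of Biopython)."""
    return "".join(
        _CODON.get(cds[i : i + 3], "X") for i in range(0, len(cds) - len(cds) % 3, 3)
    )


class TestRestrictToCds:
    def test_inside_retained_outside_dropped(self):
        gene, genome = _plus_gene()
        inside = VariantRecord("a1", "chr1", 12, genome["chr1"][11], "T"
                               if genome["chr1"][11] != "T" else "C")
        intron = VariantRecord("a1", "chr1", 42, genome["chr1"][41], "T"
                               if genome["chr1"][41] != "T" else "C")
        intergenic = VariantRecord("a1", "chr1", 2, "A", "G")
        out = restrict_to_cds([inside, intron, intergenic], [gene], genome)
        assert out == {"G1": [inside]}

    def test_ref_mismatch_raises(self):
        gene, genome = _plus_gene()
        bad = VariantRecord("a1", "chr1", 12, "N", "T")
        with pytest.raises(ValueError, match="ref allele mismatch"):
            restrict_to_cds([bad], [gene], genome)

    def test_synthetic_counts_match_interval_oracle(self, small_dataset):
        ds = small_dataset
        out = restrict_to_cds(ds.variants, ds.gene_models, ds.genome)
        kept = sum(len(v) for v in out.values())
        oracle = 0
        for rec in ds.variants:
            for g in ds.gene_models:
                if g.chrom == rec.chrom and any(
                    s <= rec.end and rec.pos <= e for s, e in g.cds_segments
                ):
                    oracle += 1
        assert kept == oracle


class TestMismatchDistance:
    def _oracle(self, variants, accessions):
        loci = {}
        for v in variants:
            loci.setdefault((v.chrom, v.pos, v.ref), {})[v.accession] = v.alt
        n = len(accessions)
        D = np.zeros((n, n))
        for alleles in loci.values():
            for i, j in itertools.combinations(range(n), 2):
                ai = alleles.get(accessions[i], "ref")
                aj = alleles.get(accessions[j], "ref")
                if ai != aj:
                    D[i, j] += 1
                    D[j, i] += 1
        return D

    def test_identical_variant_sets_distance_zero(self):
        recs = [VariantRecord(a, "chr1", 5, "A", "T") for a in ("x", "y")]
        d = mismatch_distance(recs, ["x", "y"])
        assert d.d[0, 1] == 0

    def test_private_snps_add_up(self):
        recs = [VariantRecord("x", "chr1", p, "A", "T") for p in (1, 2, 3)]
        recs += [VariantRecord("y", "chr1", p, "A", "T") for p in (10, 20)]
        d = mismatch_distance(recs, ["x", "y"])
        assert d.d[0, 1] == 5

    def test_matches_bruteforce_oracle_and_triangle(self):
        rng = np.random.default_rng(2)
        accs = [f"a{i}" for i in range(5)]
        recs = []
        for _ in range(60):
            acc = accs[rng.integers(5)]
            pos = int(rng.integers(1, 30))
            alt = "ACGT"[rng.integers(4)]
            ref = "ACGT"[(("ACGT".index(alt)) + 1) % 4]
            recs.append(VariantRecord(acc, "chr1", pos, ref, alt))
        # collapse duplicates per (acc, locus): keep first record
        seen = set()
        uniq = []
        for r in recs:
            key = (r.accession, r.chrom, r.pos)
            if key not in seen:
                seen.add(key)
                uniq.append(r)
        d = mismatch_distance(uniq, accs).d
        assert np.array_equal(d, self._oracle(uniq, accs))
        for i, j, k in itertools.permutations(range(5), 3):
            assert d[i, j] <= d[i, k] + d[k, j]

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_record_order(self, seed):
        rng = np.random.default_rng(seed)
        accs = ["a", "b", "c"]
        recs = []
        used = set()
        for _ in range(10):
            acc = accs[rng.integers(3)]
            pos = int(rng.integers(1, 10))
            if (acc, pos) in used:
                continue
            used.add((acc, pos))
            recs.append(VariantRecord(acc, "chr1", pos, "A", "ACGT"[rng.integers(1, 4)]))
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert np.array_equal(
            mismatch_distance(recs, accs).d, mismatch_distance(shuffled, accs).d
        )


class TestApplyVariants:
    def test_no_variants_returns_reference_cds(self):
        gene, genome = _plus_gene()
        assert apply_variants(gene, [], genome) == _CDS

    def test_reference_cds_for_every_generated_gene(self, small_dataset):
        for gene in small_dataset.gene_models:
            assert apply_variants(gene, [], small_dataset.genome) == gene.cds_seq
            status = call_premature_stop(gene.cds_seq, gene.protein,
                                         reference_cds_len=len(gene.cds_seq))
            assert not status.premature

    def test_nonsense_snp_lands_in_codon(self):
        gene, genome = _plus_gene()
        # codon 2 is CAA at CDS pos 3..5 -> genomic offset+3..offset+5
        pos = 10 + 3
        rec = VariantRecord("a1", "chr1", pos, "C", "T")  # CAA -> TAA
        out = apply_variants(gene, [rec], genome)
        assert out[3:6] == "TAA"
        status = call_premature_stop(out, gene.protein, variants=[rec],
                                     reference_cds_len=len(gene.cds_seq))
        assert status.premature and status.first_stop_codon_index == 2
        assert status.mechanism == "nonsense_snp"

    def test_overlapping_variants_raise(self):
        gene, genome = _plus_gene()
        a = VariantRecord("a1", "chr1", 12, genome["chr1"][11:14], "A")
        b = VariantRecord("a1", "chr1", 13, genome["chr1"][12], "G"
                          if genome["chr1"][12] != "G" else "C")
        with pytest.raises(ValueError, match="overlap"):
            apply_variants(gene, [a, b], genome)

    def test_frameshift_matches_independent_translation_oracle(self):
        gene, genome = _plus_gene()
        # 1-bp anchored deletion inside codon 5 (CDS pos 12..14)
        pos = 10 + 12
        rec = VariantRecord("a1", "chr1", pos - 1,
                            genome["chr1"][pos - 2 : pos], genome["chr1"][pos - 2])
        out = apply_variants(gene, [rec], genome)
        assert len(out) == len(_CDS) - 1
        oracle = _translate_oracle(out)
        status = call_premature_stop(out, gene.protein, variants=[rec],
                                     reference_cds_len=len(gene.cds_seq))
        first = oracle.find("*")
        assert status.premature == (0 <= first < len(gene.protein))
        if status.premature:
            assert status.first_stop_codon_index == first + 1
            assert status.mechanism == "frameshift"

    def test_short_cds_is_deletion_mechanism(self):
        status = call_premature_stop("AT", "MSTOP")
        assert status.premature and status.mechanism == "deletion"


class TestEnzymeStopPatterns:
    def test_planted_stops_recovered_background_silent(self, small_dataset):
        ds = small_dataset
        accs = list(ds.config.accession_names)
        patterns, statuses = enzyme_stop_patterns(
            ds.gene_models, split_multiallelic(ds.variants), ds.enzyme_gene_ids,
            accs, ds.genome, return_statuses=True,
        )
        by_gene = {p.gene_id: p for p in patterns}
        planted = {l.gene_id: l for l in ds.truth}
        for gene_id, link in planted.items():
            assert by_gene[gene_id].affected == link.affected_accessions
        # background variants never create stops: no non-planted gene patterns
        assert set(by_gene) == set(planted)
        # recorded stop codon index is reproduced
        status_of = {(s.gene_id, s.accession): s for s in statuses}
        for link in ds.truth:
            for acc in link.affected_accessions:
                s = status_of[(link.gene_id, acc)]
                assert s.premature and s.first_stop_codon_index == link.stop_codon_index

    def test_accession_order_does_not_change_patterns(self, small_dataset):
        ds = small_dataset
        accs = list(ds.config.accession_names)
        rev = list(reversed(accs))
        a = enzyme_stop_patterns(ds.gene_models, ds.variants, ds.enzyme_gene_ids,
                                 accs, ds.genome)
        b = enzyme_stop_patterns(ds.gene_models, ds.variants, ds.enzyme_gene_ids,
                                 rev, ds.genome)
        assert {p.gene_id: p.affected for p in a} == {p.gene_id: p.affected for p in b}

    def test_empty_enzyme_list_raises(self, small_dataset):
        with pytest.raises(ValueError):
            enzyme_stop_patterns(small_dataset.gene_models, small_dataset.variants,
                                 [], ["Col-0"], small_dataset.genome)
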