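"""Readers and writers for the pipeline's on-disk formats.

Formats: feature matrix + sample metadata TSV, reference FASTA, GFF3
(1-based inclusive CDS features carrying a gene ID), multi-sample VCF v4.2
(haploid calls encoded as homozygous diploid genotypes) or a simple tabular
variant dialect (``accession  chrom  pos  ref  alt``), enzyme gene lists,
truth JSON, distance matrices and Newick trees.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cluster import DistanceMatrix
from .datatypes import FeatureMatrix, GeneModel, PlantedLink, VariantRecord

__all__ = [
    "write_feature_matrix", "read_feature_matrix",
    "write_fasta", "read_fasta",
    "write_gff3", "read_gff3",
    "write_vcf", "read_vcf",
    "write_variants_tsv", "read_variants_tsv",
    "write_enzyme_list", "read_enzyme_list",
    "write_truth", "read_truth",
    "write_distance_matrix", "read_distance_matrix",
    "write_dataset",
]


# -- feature matrix ---------------------------------------------------------

def write_feature_matrix(matrix: FeatureMatrix, features_path, samples_path) -> None:
    """Write ``features.tsv`` (id, mz, rt, mode, one column per sample) and
    ``samples.tsv`` (sample, accession, replicate, batch, is_blank)."""
    tab = matrix.features.copy()
    tab.insert(0, "feature_id", tab.index)
    for col in matrix.intensities.columns:
        tab[col] = matrix.intensities[col]
    tab.to_csv(features_path, sep="\t", index=False, na_rep="NA")
    s = matrix.samples.copy()
    s.insert(0, "sample_id", s.index)
    s["is_blank"] = s["is_blank"].astype(int)
    s.to_csv(samples_path, sep="\t", index=False)


def read_feature_matrix(features_path, samples_path) -> FeatureMatrix:
    tab = pd.read_csv(features_path, sep="\t", na_values=["NA"])
    samples = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
    samples["is_blank"] = samples["is_blank"].astype(bool)
    tab = tab.set_index("feature_id")
    features = tab[["mz", "rt", "mode"]]
    intensities = tab[list(samples.index)].astype(float)
    intensities.columns = samples.index  # keep the sample_id index name
    return FeatureMatrix(intensities, features, samples)


# -- FASTA ------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- GFF3 -------------------------------------------------------------------

def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = g.span
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds_segments, 1):
                fh.write(
                    f"{g.chrom}\tsynthetic\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


def read_gff3(path, genome: dict[str, str]) -> list[GeneModel]:
    """Rebuild gene models from GFF3 + the reference genome.

    The spliced CDS and reference protein are re-derived from the sequence,
    so a round trip reproduces the in-memory objects exactly.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for gene in db.features_of_type("gene"):
        segs = sorted(
            (cds.start, cds.end)
            for cds in db.children(gene, featuretype="CDS")
        )
        spliced = "".join(genome[gene.seqid][s - 1 : e] for s, e in segs)
        if gene.strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
        protein = str(Seq(spliced).translate())
        genes.append(
            GeneModel(gene.id, gene.seqid, gene.strand, segs, spliced, protein[:-1])
        )
    genes.sort(key=lambda g: (g.chrom, g.span[0]))
    return genes


# -- variants ---------------------------------------------------------------

def write_vcf(
    variants: list[VariantRecord],
    accessions: list[str],
    genome: dict[str, str],
    path,
) -> None:
    """Multi-sample VCF v4.2; haploid calls written as homozygous GTs."""
    by_locus: dict[tuple[str, int, str, str], set[str]] = {}
    for rec in variants:
        by_locus.setdefault((rec.chrom, rec.pos, rec.ref, rec.alt), set()).add(rec.accession)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in genome.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(accessions) + "\n")
        for (chrom, pos, ref, alt), carriers in sorted(by_locus.items()):
            gts = ["1/1" if a in carriers else "0/0" for a in accessions]
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def read_vcf(path) -> list[VariantRecord]:
    """Parse a multi-sample VCF into per-accession variant records."""
    import pysam

    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            for alt_i, alt in enumerate(rec.alts or (), start=1):
                for acc in samples:
                    gt = rec.samples[acc].get("GT")
                    if gt and any(a == alt_i for a in gt if a is not None):
                        out.append(
                            VariantRecord(acc, rec.chrom, rec.pos, rec.ref, alt)
                        )
    out.sort(key=lambda r: (r.chrom, r.pos, r.accession, r.alt))
    return out


def write_variants_tsv(variants: list[VariantRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tchrom\tpos\tref\talt\n")
        for r in variants:
            fh.write(f"{r.accession}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\n")


def read_variants_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"pos": int})
    out = [
        VariantRecord(r.accession, r.chrom, int(r.pos), r.ref, r.alt)
        for r in df.itertuples(index=False)
    ]
    out.sort(key=lambda r: (r.chrom, r.pos, r.accession, r.alt))
    return out


# -- misc -------------------------------------------------------------------

def write_enzyme_list(gene_ids: list[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gene_ids))


def read_enzyme_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_truth(truth: list[PlantedLink], path) -> None:
    data = [
        {
            "gene_id": l.gene_id,
            "feature_id": l.feature_id,
            "affected_accessions": sorted(l.affected_accessions),
            "mechanism": l.mechanism,
            "stop_codon_index": l.stop_codon_index,
        }
        for l in truth
    ]
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def read_truth(path) -> list[PlantedLink]:
    data = json.loads(Path(path).read_text())
    return [
        PlantedLink(
            gene_id=d["gene_id"],
            feature_id=d["feature_id"],
            affected_accessions=frozenset(d["affected_accessions"]),
            mechanism=d["mechanism"],
            stop_codon_index=d["stop_codon_index"],
        )
        for d in data
    ]


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    pd.DataFrame(dist.d, index=dist.labels, columns=dist.labels).to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float))


def write_dataset(dataset, outdir) -> dict[str, Path]:
    """Write a full synthetic dataset (the simulator's external interface)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "reference.fasta",
        "gff3": out / "genes.gff3",
        "vcf": out / "variants.vcf",
        "variants_tsv": out / "variants.tsv",
        "features": out / "features.tsv",
        "samples": out / "samples.tsv",
        "enzymes": out / "enzyme_genes.txt",
        "truth": out / "truth.json",
    }
    write_fasta(dataset.genome, paths["fasta"])
    write_gff3(dataset.gene_models, paths["gff3"])
    write_vcf(dataset.variants, list(dataset.config.accession_names),
              dataset.genome, paths["vcf"])
    write_variants_tsv(dataset.variants, paths["variants_tsv"])
    write_feature_matrix(dataset.feature_matrix, paths["features"], paths["samples"])
    write_enzyme_list(dataset.enzyme_gene_ids, paths["enzymes"])
    write_truth(dataset.truth, paths["truth"])
    return paths
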