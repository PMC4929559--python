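"""Core in-memory containers shared across the pipeline.

The pipeline revolves around a handful of objects: an LC/MS feature matrix
(features x samples, with per-feature m/z, retention time and ion mode, and
per-sample accession / replicate / batch metadata), gene models with spliced
coding sequences, variant records, and the boolean accession patterns that
the matching step compares (metabolite *absence* patterns vs. premature-stop
*stop* patterns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ACCESSIONS_19",
    "BLANK",
    "FeatureMatrix",
    "VariantRecord",
    "GeneModel",
    "ProteinStatus",
    "StopPattern",
    "AbsencePattern",
    "TestResult",
    "PlantedLink",
]

#: The 19 founder accessions of the Arabidopsis MAGIC population, used as
#: default accession labels throughout (synthetic data included).
ACCESSIONS_19 = (
    "Bur-0", "Can-0", "Col-0", "Ct-1", "Edi-0", "Hi-0", "Kn-0", "Ler-0",
    "Mt-0", "No-0", "Oy-0", "Po-0", "Rsch-4", "Sf-2", "Tsu-0", "Wil-2",
    "Ws-0", "Wu-0", "Zu-0",
)

#: Accession label reserved for culture-medium blank samples.
BLANK = "BLANK"


@dataclass
class FeatureMatrix:
    """LC/MS feature intensity matrix plus feature and sample metadata.

    Parameters
    ----------
    intensities
        DataFrame of nonnegative intensities, rows = feature ids,
        columns = sample ids.  NaN marks a value below the limit of
        detection (the peak picker reported nothing).
    features
        DataFrame indexed by feature id with columns ``mz`` (Th),
        ``rt`` (min) and ``mode`` (``"ESI(-)"`` or ``"ESI(+)"``).
    samples
        DataFrame indexed by sample id with columns ``accession``,
        ``replicate``, ``batch`` and ``is_blank``.  Blank samples carry
        accession :data:`BLANK`.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame
    #: True once intensities are on a transformed (log/z) scale, where
    #: negative values are legitimate.
    transformed: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.intensities.index.equals(self.features.index):
            raise ValueError("feature metadata does not cover intensity rows")
        if list(self.intensities.columns) != list(self.samples.index):
            raise ValueError("sample metadata does not cover intensity columns")
        modes = set(self.features["mode"].unique())
        if len(modes) > 1:
            raise ValueError(
                f"a FeatureMatrix holds a single ion mode, got {sorted(modes)}; "
                "process ESI(-) and ESI(+) separately"
            )
        if (self.features["mz"] <= 0).any():
            raise ValueError("m/z values must be positive")
        if (self.features["rt"] < 0).any():
            raise ValueError("retention times must be nonnegative")
        if not self.transformed:
            with np.errstate(invalid="ignore"):
                if np.nansum(self.intensities.to_numpy() < 0):
                    raise ValueError("intensities must be nonnegative")

    # -- convenience views ---------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def accessions(self) -> list[str]:
        """Non-blank accessions in first-appearance order."""
        acc = self.samples.loc[~self.samples["is_blank"], "accession"]
        return list(dict.fromkeys(acc))

    def blank_sample_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["is_blank"]])

    def samples_of(self, accession: str) -> list[str]:
        return list(self.samples.index[self.samples["accession"] == accession])

    def subset_features(self, feature_ids) -> "FeatureMatrix":
        ids = list(feature_ids)
        return FeatureMatrix(
            self.intensities.loc[ids].copy(),
            self.features.loc[ids].copy(),
            self.samples.copy(),
            transformed=self.transformed,
        )

    def drop_blanks(self) -> "FeatureMatrix":
        keep = self.samples.index[~self.samples["is_blank"]]
        return FeatureMatrix(
            self.intensities[keep].copy(),
            self.features.copy(),
            self.samples.loc[keep].copy(),
            transformed=self.transformed,
        )

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.intensities.copy(), self.features.copy(), self.samples.copy(),
            transformed=self.transformed,
        )


@dataclass(frozen=True)
class VariantRecord:
    """One sequence difference of an accession relative to the reference.

    ``pos`` is 1-based on the reference; ``ref``/``alt`` are the reference
    and alternative allele strings (SNP, insertion or deletion).
    """

    accession: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def end(self) -> int:
        """Last reference base touched (1-based inclusive)."""
        return self.pos + len(self.ref) - 1

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass
class GeneModel:
    """A protein-coding gene: ordered CDS segments plus derived sequences.

    ``cds_segments`` are 1-based inclusive genomic intervals in ascending
    genomic order; ``cds_seq`` is the spliced, strand-corrected coding
    sequence (starts ATG, ends on a stop codon) and ``protein`` its
    translation without the terminal stop.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: list[tuple[int, int]]
    cds_seq: str
    protein: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.cds_seq) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        segs = self.cds_segments
        if any(s > e for s, e in segs):
            raise ValueError(f"{self.gene_id}: malformed CDS interval")
        if sorted(segs) != segs:
            raise ValueError(f"{self.gene_id}: CDS segments not in genomic order")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (1-based inclusive, first to last CDS base)."""
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds_segments)

    def overlaps(self, start: int, end: int) -> bool:
        return any(s <= end and start <= e for s, e in self.cds_segments)


@dataclass(frozen=True)
class ProteinStatus:
    """Premature-termination call for one (gene, accession) pair."""

    gene_id: str
    accession: str
    premature: bool
    first_stop_codon_index: int | None  # 1-based codon index, None if no stop
    mechanism: str  # nonsense_snp | frameshift | deletion | none


@dataclass
class StopPattern:
    """Boolean accession vector: True where the predicted protein is truncated."""

    gene_id: str
    accessions: tuple[str, ...]
    pattern: np.ndarray

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=bool)
        if self.pattern.shape != (len(self.accessions),):
            raise ValueError("pattern length must equal number of accessions")

    @property
    def affected(self) -> frozenset[str]:
        return frozenset(str(a) for a in np.asarray(self.accessions)[self.pattern])

    @property
    def length(self) -> int:
        return int(self.pattern.sum())


@dataclass
class AbsencePattern:
    """Boolean accession vector: True where a feature is absent in all replicates."""

    feature_id: str
    accessions: tuple[str, ...]
    absent: np.ndarray

    def __post_init__(self) -> None:
        self.absent = np.asarray(self.absent, dtype=bool)
        if self.absent.shape != (len(self.accessions),):
            raise ValueError("pattern length must equal number of accessions")

    @property
    def absent_in(self) -> frozenset[str]:
        return frozenset(str(a) for a in np.asarray(self.accessions)[self.absent])

    @property
    def length(self) -> int:
        """Pattern length = number of accessions lacking the feature."""
        return int(self.absent.sum())


@dataclass(frozen=True)
class TestResult:
    """Result of a Welch test on one feature/compound."""

    feature_id: str
    statistic: float
    df1: float
    df2: float
    p: float
    p_adj: float = float("nan")


@dataclass(frozen=True)
class PlantedLink:
    """Ground-truth record of one simulated gene -> metabolite causal link."""

    gene_id: str
    feature_id: str
    affected_accessions: frozenset[str] = field(default_factory=frozenset)
    mechanism: str = "nonsense_snp"
    stop_codon_index: int | None = None
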