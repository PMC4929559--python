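"""Matching metabolite absence patterns to premature-stop patterns.

A feature is *absent* in an accession when it is below the limit of
detection in every replicate of that accession; the set of absent accessions
is the feature's absence pattern and its cardinality the pattern length.
Candidate features (pattern length >= 1, monoisotopic annotation, median
observed intensity above a threshold) are matched to enzyme genes whose
premature-stop pattern over the same accession panel is *identical*; each
match is a candidate gene -> metabolite link, reported with full filter
provenance and a per-pattern-length tally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import AnnotationResult
from .datatypes import AbsencePattern, FeatureMatrix, StopPattern

__all__ = [
    "MatchCandidate",
    "MatchReport",
    "absence_patterns",
    "filter_candidates",
    "match_patterns",
    "write_report",
    "read_report",
]


@dataclass
class MatchCandidate:
    """One feature whose absence pattern equals >= 1 gene's stop pattern."""

    feature_id: str
    mz: float
    rt: float
    pattern: frozenset[str]
    genes: list[str]
    mechanisms: list[str]
    median_intensity: float
    monoisotopic_flag: bool = True

    @property
    def length(self) -> int:
        return len(self.pattern)


@dataclass
class MatchReport:
    candidates: list[MatchCandidate]
    unmatched: list[AbsencePattern]
    #: funnel provenance: counts after each successive filter
    funnel: dict[str, int] = field(default_factory=dict)

    def tally_by_length(self) -> dict[int, int]:
        """Matched-feature counts per pattern length (the "9/7/1" tally)."""
        out: dict[int, int] = {}
        for c in self.candidates:
            out[c.length] = out.get(c.length, 0) + 1
        return dict(sorted(out.items()))


def absence_patterns(
    detection_matrix: FeatureMatrix, lod: float | None = None
) -> list[AbsencePattern]:
    """Per-feature absence patterns from the pre-imputation detection matrix.

    A feature is absent in an accession iff every replicate value is missing
    (or below ``lod`` when a numeric limit is given).  Blank samples are
    excluded; patterns run over the non-blank accessions in panel order.
    """
    matrix = detection_matrix.drop_blanks()
    accs = tuple(matrix.accessions)
    X = matrix.intensities
    missing = X.isna() if lod is None else (X.isna() | (X < lod))
    cols_of = {a: matrix.samples_of(a) for a in accs}
    for a, cols in cols_of.items():
        if not cols:
            raise ValueError(f"accession {a} has zero replicates")
    out = []
    for fid in X.index:
        row = missing.loc[fid]
        absent = np.array([row[cols_of[a]].all() for a in accs], dtype=bool)
        out.append(AbsencePattern(fid, accs, absent))
    return out


def filter_candidates(
    patterns: list[AbsencePattern],
    annotations: list[AnnotationResult],
    detection_matrix: FeatureMatrix,
    *,
    min_median: float = 10_000.0,
    min_len: int = 1,
    max_len: int | None = None,
    policy: str = "strict",
) -> list[AbsencePattern]:
    """Apply the candidate filters to absence patterns.

    Keeps features with pattern length in ``[min_len, max_len]``, a
    monoisotopic annotation under ``policy`` (see
    :func:`rhizolink.annotate.monoisotopic_filter`), and a median *observed*
    (non-missing, non-blank) intensity of at least ``min_median``.
    """
    from .annotate import monoisotopic_filter

    mono = monoisotopic_filter(annotations, policy)
    nonblank = detection_matrix.drop_blanks().intensities
    out = []
    for pat in patterns:
        if pat.length < min_len:
            continue
        if max_len is not None and pat.length > max_len:
            continue
        if pat.feature_id not in mono:
            continue
        obs = nonblank.loc[pat.feature_id].dropna()
        if len(obs) == 0 or float(obs.median()) < min_median:
            continue
        out.append(pat)
    return out


def match_patterns(
    feature_patterns: list[AbsencePattern],
    stop_patterns: list[StopPattern],
    detection_matrix: FeatureMatrix | None = None,
) -> MatchReport:
    """Exact matching of absence patterns against stop patterns.

    A feature matches a gene iff their boolean accession vectors are
    identical (set equality of affected accessions); all matching genes are
    listed per feature.  Features matching no gene are reported separately.
    Both inputs must run over the same accession universe.
    """
    universes = {p.accessions for p in feature_patterns} | {
        s.accessions for s in stop_patterns
    }
    if len(universes) > 1:
        raise ValueError(
            "absence and stop patterns disagree on the accession universe: "
            + "; ".join(str(sorted(u)) for u in universes)
        )
    by_pattern: dict[frozenset[str], list[StopPattern]] = {}
    for sp in stop_patterns:
        if sp.length == 0:
            continue
        by_pattern.setdefault(sp.affected, []).append(sp)
    candidates: list[MatchCandidate] = []
    unmatched: list[AbsencePattern] = []
    for fp in feature_patterns:
        hits = by_pattern.get(fp.absent_in, [])
        if not hits:
            unmatched.append(fp)
            continue
        mz = rt = np.nan
        median = np.nan
        if detection_matrix is not None:
            mz = float(detection_matrix.features.at[fp.feature_id, "mz"])
            rt = float(detection_matrix.features.at[fp.feature_id, "rt"])
            obs = (
                detection_matrix.drop_blanks()
                .intensities.loc[fp.feature_id]
                .dropna()
            )
            median = float(obs.median()) if len(obs) else np.nan
        candidates.append(
            MatchCandidate(
                feature_id=fp.feature_id,
                mz=mz,
                rt=rt,
                pattern=fp.absent_in,
                genes=sorted(h.gene_id for h in hits),
                mechanisms=[],
                median_intensity=median,
            )
        )
    candidates.sort(key=lambda c: (c.length, c.mz if np.isfinite(c.mz) else 0.0,
                                   c.feature_id))
    return MatchReport(candidates, unmatched)


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

def write_report(report: MatchReport, outdir) -> dict[str, Path]:
    """Write the candidate report: TSV + JSON plus the unmatched table.

    Row order is deterministic (pattern length, then m/z, then feature id).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "candidates": out / "candidates.tsv",
        "unmatched": out / "unmatched.tsv",
        "summary": out / "report.json",
    }
    rows = [
        {
            "feature_id": c.feature_id,
            "mz": c.mz,
            "rt": c.rt,
            "pattern": ",".join(sorted(c.pattern)),
            "pattern_length": c.length,
            "genes": ",".join(c.genes),
            "mechanisms": ",".join(c.mechanisms),
            "median_intensity": c.median_intensity,
            "monoisotopic": int(c.monoisotopic_flag),
        }
        for c in report.candidates
    ]
    pd.DataFrame(
        rows,
        columns=["feature_id", "mz", "rt", "pattern", "pattern_length", "genes",
                 "mechanisms", "median_intensity", "monoisotopic"],
    ).to_csv(paths["candidates"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "feature_id": p.feature_id,
                "pattern": ",".join(sorted(p.absent_in)),
                "pattern_length": p.length,
            }
            for p in report.unmatched
        ],
        columns=["feature_id", "pattern", "pattern_length"],
    ).to_csv(paths["unmatched"], sep="\t", index=False)
    summary = {
        "n_candidates": len(report.candidates),
        "n_unmatched": len(report.unmatched),
        "matched_by_length": {str(k): v for k, v in report.tally_by_length().items()},
        "funnel": report.funnel,
    }
    paths["summary"].write_text(json.dumps(summary, indent=2) + "\n")
    return paths


def read_report(outdir, accessions: tuple[str, ...] | None = None) -> MatchReport:
    """Re-read a written report (round-trips the candidate rows)."""
    out = Path(outdir)
    cand = pd.read_csv(out / "candidates.tsv", sep="\t",
                       keep_default_na=False, na_values=[""])
    candidates = []
    for r in cand.itertuples(index=False):
        pattern = frozenset(str(r.pattern).split(",")) if r.pattern else frozenset()
        genes = str(r.genes).split(",") if r.genes else []
        mechanisms = str(r.mechanisms).split(",") if r.mechanisms else []
        candidates.append(
            MatchCandidate(
                feature_id=r.feature_id,
                mz=float(r.mz),
                rt=float(r.rt),
                pattern=pattern,
                genes=genes,
                mechanisms=mechanisms,
                median_intensity=float(r.median_intensity),
                monoisotopic_flag=bool(int(r.monoisotopic)),
            )
        )
    unmatched = []
    if accessions is not None:
        acc = tuple(accessions)
        um = pd.read_csv(out / "unmatched.tsv", sep="\t",
                         keep_default_na=False, na_values=[""])
        for r in um.itertuples(index=False):
            absent_in = set(str(r.pattern).split(",")) if r.pattern else set()
            unmatched.append(
                AbsencePattern(
                    r.feature_id, acc, np.array([a in absent_in for a in acc])
                )
            )
    summary = json.loads((out / "report.json").read_text())
    return MatchReport(candidates, unmatched, funnel=summary.get("funnel", {}))
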