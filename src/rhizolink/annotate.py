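"""Isotope annotation of co-eluting LC/MS features.

A simplified stand-in for full adduct/isotope annotation: features are
grouped by retention-time proximity (single linkage), and within each
co-elution group a feature is called the ``isotope_k`` companion of another
when their m/z spacing matches k times the C13-C12 mass difference
(1.00336 Da, divided by the charge), their mean intensity ratio lies in a
plausible isotopologue range, and their per-sample intensities correlate.
Heads of detected isotope series are flagged monoisotopic ("[M]"); the
downstream candidate filter consumes only that flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix

__all__ = [
    "AnnotationResult",
    "group_coeluting",
    "detect_isotopes",
    "annotate_isotopes",
    "monoisotopic_filter",
    "ISOTOPE_MASS_DIFF",
]

#: Mass difference between consecutive isotopologue peaks (13C - 12C), Da.
ISOTOPE_MASS_DIFF = 1.00336


@dataclass(frozen=True)
class AnnotationResult:
    feature_id: str
    group_id: int
    isotope_role: str  # "monoisotopic" | "isotope_k" (k >= 1) | "unassigned"
    monoisotopic_flag: bool
    partner_id: str | None = None  # the lighter feature this one is an isotope of


def group_coeluting(features: pd.DataFrame, rt_tol: float = 0.05) -> pd.Series:
    """Single-linkage grouping of features by retention time.

    Two features join the same group when their RT differ by at most
    ``rt_tol`` minutes; chains extend transitively.  Returns a Series
    feature_id -> group id (0-based, ordered by ascending group RT).
    """
    order = features["rt"].sort_values(kind="mergesort").index
    rts = features.loc[order, "rt"].to_numpy(dtype=float)
    gid = 0
    groups = np.zeros(len(order), dtype=int)
    for i in range(1, len(order)):
        if rts[i] - rts[i - 1] > rt_tol:
            gid += 1
        groups[i] = gid
    return pd.Series(groups, index=order, name="group_id").loc[features.index]


def detect_isotopes(
    group: pd.DataFrame,
    intensities: pd.DataFrame,
    *,
    ppm_tol: float = 20.0,
    max_charge: int = 2,
    min_ratio: float = 0.02,
    max_ratio: float = 0.8,
    min_corr: float = 0.8,
) -> dict[str, tuple[str, int, str | None]]:
    """Isotope roles within one co-elution group.

    Returns feature_id -> (role, k, partner): feature B is ``isotope_1`` of A
    when m/z(B) - m/z(A) matches 1.00336/|z| within the ppm tolerance for
    some charge z <= ``max_charge``, the mean intensity ratio B/A lies in
    ``[min_ratio, max_ratio]`` and the per-sample intensity correlation over
    commonly detected samples is at least ``min_corr``.  Chains extend to
    ``isotope_k``; chain heads become ``monoisotopic``; the rest stay
    ``unassigned``.
    """
    ids = sorted(group.index, key=lambda f: (group.at[f, "mz"], f))
    mz = {f: float(group.at[f, "mz"]) for f in ids}
    means = {
        f: float(np.nanmean(intensities.loc[f].to_numpy(dtype=float)))
        if intensities.loc[f].notna().any()
        else 0.0
        for f in ids
    }
    parent: dict[str, str] = {}
    for b in ids:
        best = None
        for a in ids:
            if a == b or mz[a] >= mz[b]:
                continue
            diff = mz[b] - mz[a]
            for z in range(1, max_charge + 1):
                expected = ISOTOPE_MASS_DIFF / z
                tol = ppm_tol * 1e-6 * mz[b] + 1e-9
                if abs(diff - expected) > tol:
                    continue
                if means[a] <= 0:
                    continue
                ratio = means[b] / means[a]
                if not (min_ratio <= ratio <= max_ratio):
                    continue
                xa = intensities.loc[a].to_numpy(dtype=float)
                xb = intensities.loc[b].to_numpy(dtype=float)
                both = ~np.isnan(xa) & ~np.isnan(xb)
                if both.sum() < 3:
                    continue
                if np.std(xa[both]) == 0 or np.std(xb[both]) == 0:
                    continue
                r = float(np.corrcoef(xa[both], xb[both])[0, 1])
                if r < min_corr:
                    continue
                cand = (abs(diff - expected), a)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            parent[b] = best[1]
    roles: dict[str, tuple[str, int, str | None]] = {}
    heads = set()
    for f in ids:
        if f in parent:
            k, anc = 0, f
            seen = set()
            while anc in parent and anc not in seen:
                seen.add(anc)
                anc = parent[anc]
                k += 1
            roles[f] = (f"isotope_{k}", k, parent[f])
            heads.add(anc)
    for f in ids:
        if f in heads and f not in parent:
            roles[f] = ("monoisotopic", 0, None)
        elif f not in roles:
            roles[f] = ("unassigned", 0, None)
    return roles


def annotate_isotopes(
    matrix: FeatureMatrix,
    *,
    rt_tol: float = 0.05,
    ppm_tol: float = 20.0,
    max_charge: int = 2,
    min_ratio: float = 0.02,
    max_ratio: float = 0.8,
    min_corr: float = 0.8,
) -> list[AnnotationResult]:
    """Group co-eluting features and assign isotope roles across the matrix."""
    groups = group_coeluting(matrix.features, rt_tol)
    out: list[AnnotationResult] = []
    for gid in sorted(groups.unique()):
        members = groups.index[groups == gid]
        roles = detect_isotopes(
            matrix.features.loc[members],
            matrix.intensities.loc[members],
            ppm_tol=ppm_tol,
            max_charge=max_charge,
            min_ratio=min_ratio,
            max_ratio=max_ratio,
            min_corr=min_corr,
        )
        for fid in members:
            role, _, partner = roles[fid]
            out.append(
                AnnotationResult(
                    feature_id=fid,
                    group_id=int(gid),
                    isotope_role=role,
                    monoisotopic_flag=role == "monoisotopic",
                    partner_id=partner,
                )
            )
    index = {matrix.feature_ids[i]: i for i in range(len(matrix.feature_ids))}
    out.sort(key=lambda r: index[r.feature_id])
    return out


def monoisotopic_filter(
    results: list[AnnotationResult], policy: str = "strict"
) -> set[str]:
    """Feature ids passing the monoisotopic ("[M]") filter.

    ``strict`` keeps only heads of detected isotope series (the restrictive
    behaviour of the original annotation-based filter); ``permissive`` also
    keeps unassigned singletons.
    """
    if policy == "strict":
        return {r.feature_id for r in results if r.isotope_role == "monoisotopic"}
    if policy == "permissive":
        return {
            r.feature_id
            for r in results
            if r.isotope_role in ("monoisotopic", "unassigned")
        }
    raise ValueError(f"unknown policy {policy!r}")
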