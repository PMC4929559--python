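"""Feature-matrix preprocessing and the study's statistical tests.

Turns a raw (peak-picked, aligned) feature matrix into

* a blank-filtered, batch-corrected intensity matrix for clustering, and
* the untouched pre-imputation detection matrix used later for absence calls,

via half-minimum imputation, log / z transformation, a Kolmogorov-Smirnov
normality QC, surrogate-variable batch correction, and Welch tests (omnibus
heteroscedastic one-way ANOVA plus two-sample post-hoc tests against the
culture-medium blank) with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import BLANK, FeatureMatrix, TestResult

logger = logging.getLogger(__name__)

__all__ = [
    "ZeroVarianceError",
    "impute_half_min",
    "log_z_transform",
    "ks_normality",
    "welch_anova",
    "welch_two_sample",
    "bh_adjust",
    "blank_filter",
    "sva_correct",
    "differential_metabolites",
]


class ZeroVarianceError(ValueError):
    """A group entering a variance-based test is constant or too small."""


# ---------------------------------------------------------------------------
# imputation and transformation
# ---------------------------------------------------------------------------

def impute_half_min(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace missing values by half the per-feature minimum observed intensity.

    The input matrix is left untouched (it remains the detection matrix used
    for absence calls); a new matrix without missing values is returned.

    Raises
    ------
    ValueError
        If a feature has no observed value at all (nothing to halve).
    """
    X = matrix.intensities
    n_obs = X.notna().sum(axis=1)
    if (n_obs == 0).any():
        bad = list(X.index[n_obs == 0])
        raise ValueError(f"cannot impute features with zero observed values: {bad}")
    fill = 0.5 * X.min(axis=1)
    out = X.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    return FeatureMatrix(out, matrix.features.copy(), matrix.samples.copy())


def log_z_transform(
    matrix: FeatureMatrix, *, on_zero_variance: str = "drop"
) -> FeatureMatrix:
    """Natural log, then per-feature z-scaling to mean 0 / sd 1 across samples.

    Parameters
    ----------
    on_zero_variance
        ``"drop"`` (default) removes features that are constant after the log
        step with a logged warning; ``"error"`` raises instead.
    """
    X = matrix.intensities
    if (X.to_numpy() <= 0).any() or X.isna().any().any():
        raise ValueError("log_z_transform requires strictly positive, complete intensities")
    L = np.log(X)
    sd = L.std(axis=1, ddof=1)
    flat = (L.max(axis=1) - L.min(axis=1)) == 0  # exact constancy check
    if flat.any():
        if on_zero_variance == "error":
            raise ZeroVarianceError(
                f"zero-variance features: {list(L.index[flat])}"
            )
        logger.warning("dropping %d zero-variance feature(s) after log transform", flat.sum())
        L = L.loc[~flat]
        sd = sd.loc[~flat]
    Z = L.sub(L.mean(axis=1), axis=0).div(sd, axis=0)
    return FeatureMatrix(Z, matrix.features.loc[Z.index].copy(),
                         matrix.samples.copy(), transformed=True)


def ks_normality(matrix: FeatureMatrix) -> pd.Series:
    """One-sample Kolmogorov-Smirnov test of each feature against N(0, 1).

    QC only: the p-values are reported, never used to drop features.
    Constant (degenerate) features get NaN.
    """
    out = {}
    for fid, row in matrix.intensities.iterrows():
        x = row.to_numpy(dtype=float)
        if np.nanstd(x) == 0 or np.isnan(x).any():
            out[fid] = np.nan
        else:
            out[fid] = stats.kstest(x, "norm").pvalue
    return pd.Series(out, name="ks_p")


# ---------------------------------------------------------------------------
# Welch tests and FDR
# ---------------------------------------------------------------------------

def welch_anova(groups: list[np.ndarray], feature_id: str = "") -> TestResult:
    """Welch's heteroscedastic one-way ANOVA.

    With ``w_i = n_i / s_i^2``, ``W = sum w_i``, weighted grand mean
    ``xbar_w = sum w_i xbar_i / W`` and
    ``lam = sum[(1 - w_i/W)^2 / (n_i - 1)] / (k^2 - 1)``::

        F* = [sum w_i (xbar_i - xbar_w)^2 / (k - 1)] / [1 + 2 (k - 2) lam]
        df1 = k - 1,  df2 = 1 / (3 lam)

    and p is the upper tail of the F(df1, df2) distribution.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("welch_anova needs at least two groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ZeroVarianceError(f"group {i} has n < 2")
        if np.var(g, ddof=1) == 0:
            raise ZeroVarianceError(f"group {i} has zero variance")
    n = np.array([g.size for g in arrays], dtype=float)
    m = np.array([g.mean() for g in arrays])
    v = np.array([g.var(ddof=1) for g in arrays])
    w = n / v
    W = w.sum()
    mw = (w * m).sum() / W
    lam = ((1.0 - w / W) ** 2 / (n - 1.0)).sum() / (k**2 - 1.0)
    F = ((w * (m - mw) ** 2).sum() / (k - 1.0)) / (1.0 + 2.0 * (k - 2.0) * lam)
    df1 = k - 1.0
    df2 = 1.0 / (3.0 * lam)
    p = float(stats.f.sf(F, df1, df2))
    return TestResult(feature_id, float(F), df1, df2, p)


def welch_two_sample(a, b, feature_id: str = "") -> TestResult:
    """Two-sided two-sample Welch t-test (Welch–Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ZeroVarianceError("welch_two_sample needs n >= 2 in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(feature_id, float(res.statistic), 1.0, float(res.df), float(res.pvalue))


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# surrogate-variable batch correction
# ---------------------------------------------------------------------------

@dataclass
class SvaResult:
    corrected: FeatureMatrix
    n_sv: int
    surrogate_variables: np.ndarray  # (n_sv, n_samples)
    singular_value_p: np.ndarray


def sva_correct(
    matrix: FeatureMatrix,
    n_sv: int | str = "auto",
    *,
    n_permutations: int = 100,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> SvaResult:
    """Remove non-biological variation by a two-step surrogate-variable estimate.

    Each feature is residualised on accession means (blanks form their own
    group); the top right-singular vectors of the residual matrix are taken
    as surrogate variables.  With ``n_sv="auto"`` the number of surrogates is
    chosen by a permutation test on the residual singular values (each row of
    the residual matrix permuted independently, ``n_permutations`` draws,
    components kept while their permutation p-value stays below ``alpha``).
    Each feature is then regressed on accession indicators plus the
    surrogates, and the surrogate contribution is subtracted.
    """
    X = matrix.intensities.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("sva_correct requires a complete (imputed) matrix")
    groups = matrix.samples["accession"].to_numpy()
    levels = list(dict.fromkeys(groups))
    if len([g for g in levels if g != BLANK]) < 2:
        raise ValueError("sva_correct needs at least two accessions")
    n_feat, n_samp = X.shape
    D = np.stack([(groups == g).astype(float) for g in levels], axis=1)  # design
    hat = D @ np.linalg.pinv(D)
    R = X - X @ hat.T  # residuals after removing accession means

    sv_obs = np.linalg.svd(R, compute_uv=False)
    max_k = n_samp - len(levels)
    if n_sv == "auto":
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(sv_obs))
        for _ in range(n_permutations):
            P = np.array([rng.permutation(row) for row in R])
            P = P - P.mean(axis=1, keepdims=True)
            sv_perm = np.linalg.svd(P, compute_uv=False)
            exceed += sv_perm >= sv_obs
        pvals = (1.0 + exceed) / (1.0 + n_permutations)
        k = 0
        while k < min(len(pvals), max_k) and pvals[k] < alpha:
            k += 1
    else:
        k = int(n_sv)
        pvals = np.full(len(sv_obs), np.nan)
        if k >= max_k and k > 0:
            raise ValueError(
                f"n_sv={k} >= residual degrees of freedom ({max_k})"
            )
    if k == 0:
        sv = np.empty((0, n_samp))
        corrected = X.copy()
    else:
        _, _, Vt = np.linalg.svd(R, full_matrices=False)
        sv = Vt[:k]  # (k, n_samples)
        full = np.concatenate([D, sv.T], axis=1)
        coef, *_ = np.linalg.lstsq(full, X.T, rcond=None)
        gamma = coef[len(levels):]  # (k, n_features)
        corrected = X - (sv.T @ gamma).T
    out = FeatureMatrix(
        pd.DataFrame(corrected, index=matrix.intensities.index,
                     columns=matrix.intensities.columns),
        matrix.features.copy(),
        matrix.samples.copy(),
        transformed=matrix.transformed,
    )
    return SvaResult(out, k, sv, pvals)


# ---------------------------------------------------------------------------
# blank filtering and differential testing
# ---------------------------------------------------------------------------

@dataclass
class BlankFilterResult:
    retained: list[str]
    table: pd.DataFrame  # feature_id, F, p, p_adj, min_posthoc_p, retained
    n_degenerate: int


def blank_filter(matrix: FeatureMatrix, alpha: float = 0.05) -> BlankFilterResult:
    """Separate exudate features from experimental artifacts via the blank.

    A feature is retained when (i) the BH-adjusted Welch one-way ANOVA over
    all accession groups plus the blank group is significant at ``alpha`` and
    (ii) an unadjusted two-sample Welch test against the blank is significant
    in at least one accession (post-hoc).  Operates on batch-corrected,
    transformed intensities.  Features for which the omnibus test is
    degenerate (a constant group) cannot be tested and are dropped with a
    logged count.
    """
    blanks = matrix.blank_sample_ids()
    if not blanks:
        raise ValueError("blank_filter requires blank samples in the matrix")
    acc_samples = {a: matrix.samples_of(a) for a in matrix.accessions}
    X = matrix.intensities
    rows = []
    n_degenerate = 0
    for fid in X.index:
        vals = X.loc[fid]
        blank_vals = vals[blanks].to_numpy(dtype=float)
        groups = [vals[s].to_numpy(dtype=float) for s in acc_samples.values()]
        try:
            omni = welch_anova(groups + [blank_vals], fid)
            posthoc = min(
                welch_two_sample(g, blank_vals).p for g in groups
            )
        except ZeroVarianceError:
            n_degenerate += 1
            continue
        rows.append((fid, omni.statistic, omni.p, posthoc))
    if n_degenerate:
        logger.warning("blank_filter: %d feature(s) with a degenerate group dropped",
                       n_degenerate)
    table = pd.DataFrame(rows, columns=["feature_id", "F", "p", "min_posthoc_p"])
    table["p_adj"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    table["retained"] = (table["p_adj"] < alpha) & (table["min_posthoc_p"] < alpha)
    retained = list(table.loc[table["retained"], "feature_id"])
    return BlankFilterResult(retained, table, n_degenerate)


def differential_metabolites(
    areas: pd.DataFrame, accessions: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Welch one-way ANOVA across accessions per compound, BH over compounds.

    ``areas`` holds log-transformed, z-scaled peak areas (compounds x samples);
    ``accessions`` maps each sample column to its accession.  Returns a table
    with ``F``, ``p``, ``p_adj`` and a ``significant`` flag at ``p_adj < alpha``.
    """
    accessions = accessions.loc[areas.columns]
    levels = list(dict.fromkeys(accessions))
    rows = []
    for cid in areas.index:
        groups = [
            areas.loc[cid, accessions.index[accessions == a]].to_numpy(dtype=float)
            for a in levels
        ]
        res = welch_anova(groups, cid)
        rows.append((cid, res.statistic, res.df1, res.df2, res.p))
    table = pd.DataFrame(rows, columns=["compound_id", "F", "df1", "df2", "p"])
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return table
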