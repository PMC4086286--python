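"""Hypervariable (HV) gene detection against a technical-noise reference.

A gene is hypervariable when its variability across the time course exceeds
the technical variability of the platform, as estimated from a reference
group of expressed but low-variability genes. The default test statistic
per gene is the one-way ANOVA contrast of time-course variability against
pooled technical noise:

    F = MS_between / s²_ref,
    MS_between = Σ_g m_g (x̄_g - x̄)² / (G - 1)

where the groups g are the (treatment, time) replicate groups and s²_ref is
the pooled within-replicate-group residual variance of the reference group.
p is the upper tail of F with (G - 1, pooled df) degrees of freedom, and
genes are flagged at the Bonferroni-style cutoff p < 1/N, N being the
number of genes expressed above background. ``statistic="total"`` instead
uses the gene's total variance about its grand mean (df = n - 1), the
variant appropriate when no replicate structure exists beyond the groups
themselves.

A gene counts as expressed when its pre-floor z-score reaches the
expression threshold in at least ``expressed_min_arrays`` arrays (default
2: expression must replicate). With a single-array rule, the ~0.1% of
pure-background probes that fluctuate past three SDs in any one of the
arrays enter N as floored spike patterns whose log-scale variance dwarfs
the technical noise of genuinely expressed genes; requiring two arrays
suppresses these while leaving real expressed genes untouched.

The reference group starts from all expressed genes and is iteratively
trimmed: genes whose replicate residual variance is significantly above the
pooled variance (upper-tail F-test at ``alpha_ref``) are removed and the
pool is re-estimated until a fixed point. Because trimming truncates the
upper tail of the variance distribution, the raw trimmed pool would
underestimate the technical variance by ~10% and inflate every F statistic;
the pool is therefore corrected for the truncation analytically
(``bias_correction``): each member's df is weighted by
kappa = P(chi²_{df+2} < c) / P(chi²_{df} < c), the expected fraction of a
chi² mean retained below the trim threshold c.

Flagged genes are then screened by a leave-one-out replicate-error filter:
if removing the single sample with the largest positive (or, separately,
largest negative) residual significantly collapses the residual variance,
the gene's variability is attributed to a one-replicate artifact and it is
dropped. Because the excluded sample is *selected* as the most extreme
residual, the ratio v_full / v_excluded is not F-distributed under the null
(the naive F reference would drop clean genes at several times the nominal
rate); the filter therefore calibrates against the Monte-Carlo null
distribution of the same selected-extreme statistic under the identical
replicate design (fixed internal seed, cached per design), at familywise
level ``alpha_loo``.
"""

from __future__ import annotations

import functools
import warnings
from typing import Hashable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import HVResult, NormalizedMatrix, ReferenceGroup
from .errors import InsufficientData, InsufficientReplication, ReferenceCollapse

__all__ = [
    "residual_variance",
    "build_reference_group",
    "hv_test",
    "hv_threshold",
    "loo_filter",
    "detect_hv",
    "HVDetector",
]

_LOO_NULL_DRAWS = 20000
_LOO_NULL_SEED = 20140702  # fixed: the calibration table is part of the method


def _group_index(group_labels: Sequence[Hashable]) -> tuple[np.ndarray, int]:
    labels = list(group_labels)
    uniq = list(dict.fromkeys(labels))
    codes = np.array([uniq.index(g) for g in labels])
    return codes, len(uniq)


def _residual_stats(values: np.ndarray, codes: np.ndarray, n_groups: int):
    """Residual SSR and df under the group-mean model, vectorized over rows.

    values: (n_genes, n_samples); returns (ssr (n_genes,), df, residuals)."""
    n = values.shape[-1]
    v2 = np.atleast_2d(values)
    means = np.empty_like(v2)
    for g in range(n_groups):
        sel = codes == g
        means[:, sel] = v2[:, sel].mean(axis=1, keepdims=True)
    resid = v2 - means
    ssr = (resid**2).sum(axis=1)
    df = n - n_groups
    return ssr, df, resid


def residual_variance(
    gene_values: Sequence[float], group_labels: Sequence[Hashable]
) -> tuple[float, int]:
    """Residual variance of one gene under the replicate-group-mean model.

    residual = value - mean of its (treatment, time) group;
    variance = sum of squared residuals / df, df = n_samples - n_groups.
    """
    x = np.asarray(gene_values, dtype=float)
    codes, n_groups = _group_index(group_labels)
    if x.size != codes.size:
        raise ValueError("gene_values and group_labels lengths differ")
    df = x.size - n_groups
    if df < 1:
        raise InsufficientReplication(
            f"residual df = {df} (< 1): every group needs replication"
        )
    ssr, df, _ = _residual_stats(x, codes, n_groups)
    return float(ssr[0] / df), int(df)


def _trim_kappa(df: np.ndarray, pooled_df: float, alpha: float) -> np.ndarray:
    """Expected retained fraction of a chi²_df mean truncated at the
    alpha-level trim threshold (in sigma units, assuming an unbiased pool)."""
    fcrit = stats.f.ppf(1.0 - alpha, df, pooled_df)
    c = df * fcrit
    return stats.chi2.cdf(c, df + 2) / stats.chi2.cdf(c, df)


def build_reference_group(
    values: pd.DataFrame,
    group_labels: Sequence[Hashable],
    alpha_ref: float = 0.05,
    min_genes: int = 50,
    max_iter: int = 100,
    bias_correction: bool = True,
) -> ReferenceGroup:
    """Build the low-variability reference group over expressed genes.

    ``values``: log expression of the *expressed* genes (genes × arrays).
    Starts with all genes; the pooled variance is the df-weighted pool of
    residual sums-of-squares; genes with upper-tail F-test p < ``alpha_ref``
    against the pool are removed; repeat to a fixed point (or ``max_iter``).
    Deterministic given its input.
    """
    if values.shape[0] < min_genes:
        raise InsufficientData(
            f"reference group needs >= {min_genes} expressed genes, "
            f"got {values.shape[0]}"
        )
    codes, n_groups = _group_index(group_labels)
    df_resid = values.shape[1] - n_groups
    if df_resid < 1:
        raise InsufficientReplication("no residual df: every group is size 1")
    ssr, _, _ = _residual_stats(values.to_numpy(), codes, n_groups)
    n = len(ssr)
    dfs = np.full(n, df_resid, dtype=float)
    member = np.ones(n, dtype=bool)
    iterations = 0
    for it in range(max_iter):
        iterations = it + 1
        pooled_df = dfs[member].sum()
        if bias_correction and it > 0:
            kappa = _trim_kappa(dfs, pooled_df, alpha_ref)
            pooled = ssr[member].sum() / (dfs[member] * kappa[member]).sum()
        else:
            pooled = ssr[member].sum() / pooled_df
        if pooled <= 0:
            raise ReferenceCollapse("pooled reference variance is zero")
        F = (ssr / dfs) / pooled
        p = stats.f.sf(F, dfs, pooled_df)
        new_member = member & ~(p < alpha_ref)
        if not new_member.any():
            raise ReferenceCollapse("every gene trimmed from the reference")
        if new_member.sum() == member.sum():
            break
        member = new_member
    pooled_df = dfs[member].sum()
    if bias_correction:
        kappa = _trim_kappa(dfs, pooled_df, alpha_ref)
        pooled = ssr[member].sum() / (dfs[member] * kappa[member]).sum()
    else:
        pooled = ssr[member].sum() / pooled_df
    return ReferenceGroup(
        member_probe_ids=[str(p_) for p_ in values.index[member]],
        pooled_variance=float(pooled),
        pooled_df=int(pooled_df),
        iterations_to_converge=iterations,
    )


def hv_test(
    variance: float, df_gene: int, reference: ReferenceGroup
) -> tuple[float, float]:
    """F statistic and upper-tail p of one gene against the reference pool."""
    F = variance / reference.pooled_variance
    p = float(stats.f.sf(F, df_gene, reference.pooled_df))
    return float(F), p


def hv_threshold(p_values: Sequence[float], n_expressed: int) -> np.ndarray:
    """Bonferroni-style flagging at the strict cutoff p < 1/N."""
    if n_expressed < 1:
        raise InsufficientData("N_expressed must be >= 1")
    return np.asarray(p_values, dtype=float) < 1.0 / n_expressed


@functools.lru_cache(maxsize=32)
def _loo_null_table(group_sizes: tuple[int, ...]) -> np.ndarray:
    """Sorted Monte-Carlo null of max(F_-max, F_-min) for a replicate design.

    Simulates ``_LOO_NULL_DRAWS`` standard-normal datasets with the given
    group sizes and returns the sorted selected-extreme variance-ratio
    statistic. Depends only on the design, so it is cached; the seed is a
    fixed constant — the table is part of the method, not of a user run.
    """
    rng = np.random.default_rng(_LOO_NULL_SEED)
    n = int(sum(group_sizes))
    codes = np.concatenate(
        [np.full(m, g) for g, m in enumerate(group_sizes)]
    )
    x = rng.standard_normal((_LOO_NULL_DRAWS, n))
    stat = _loo_statistics(x, codes, len(group_sizes))[0]
    return np.sort(stat)


def _loo_statistics(values: np.ndarray, codes: np.ndarray, n_groups: int):
    """max(F_-max, F_-min) per row, plus the per-side ratios and the excluded
    column indices. Exclusion of sample j from a group of size m reduces the
    group SSR by m/(m-1) * r_j² (the group mean is refitted)."""
    v2 = np.atleast_2d(values)
    n = v2.shape[1]
    sizes = np.array([(codes == g).sum() for g in range(n_groups)])
    ssr, df_full, resid = _residual_stats(v2, codes, n_groups)
    v_full = ssr / df_full

    def side(idx):
        m = sizes[codes[idx]]
        rows = np.arange(v2.shape[0])
        r = resid[rows, idx]
        factor = np.where(m > 1, m / np.maximum(m - 1.0, 1.0), 0.0)
        ssr_red = ssr - factor * r**2
        # df after removal: one sample fewer; a group shrinking to zero
        # members would restore a df, but removing from a size-1 group
        # contributes nothing (its residual is 0), df_red = df_full then.
        df_red = np.where(m > 1, df_full - 1, df_full)
        with np.errstate(divide="ignore", invalid="ignore"):
            v_red = ssr_red / df_red
            F = np.where(v_red > 0, v_full / v_red, np.inf)
        F = np.where(df_red >= 1, F, np.nan)
        return F, df_red

    i_max = np.argmax(resid, axis=1)
    i_min = np.argmin(resid, axis=1)
    F_plus, df_plus = side(i_max)
    F_minus, df_minus = side(i_min)
    both = np.vstack([F_plus, F_minus])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stat = np.nanmax(both, axis=0)
    which = np.nanargmax(np.where(np.isnan(both), -np.inf, both), axis=0)
    excluded = np.where(which == 0, i_max, i_min)
    return stat, F_plus, F_minus, excluded


def loo_filter(
    gene_values: Sequence[float],
    group_labels: Sequence[Hashable],
    alpha_loo: float = 0.05,
) -> tuple[bool, Optional[int]]:
    """Leave-one-out replicate-error screen for a single gene.

    Excludes the sample with the largest positive residual and, separately,
    the one with the largest negative residual; a significant collapse of
    the residual variance on either exclusion (selection-calibrated
    Monte-Carlo null, familywise level ``alpha_loo``) marks the gene as a
    likely single-replicate artifact.

    Returns (keep, suspect_sample_position); the suspect is the excluded
    sample position (column index) when the gene is dropped, else None.
    """
    x = np.asarray(gene_values, dtype=float)[None, :]
    codes, n_groups = _group_index(group_labels)
    df_full = x.shape[1] - n_groups
    if df_full < 1:
        raise InsufficientReplication("residual df < 1")
    if df_full - 1 < 1:
        warnings.warn("insufficient df after exclusion; gene kept unfiltered")
        return True, None
    stat, _, _, excluded = _loo_statistics(x, codes, n_groups)
    if np.isnan(stat[0]):
        return True, None
    null = _loo_null_table(tuple(int((codes == g).sum()) for g in range(n_groups)))
    exceed = len(null) - np.searchsorted(null, stat[0], side="left")
    p = (1.0 + exceed) / (len(null) + 1.0)
    if p < alpha_loo:
        return False, int(excluded[0])
    return True, None


class HVDetector(BaseEstimator):
    """Full HV-gene detector (scikit-learn-style estimator).

    ``fit(X, y)`` takes a :class:`NormalizedMatrix` (or a log-value
    DataFrame plus an explicit mask) and the per-array replicate-group
    labels ``y`` (anything hashable, typically (treatment, time) tuples).

    Fitted attributes
    -----------------
    result_ : HVResult           per-gene table and metadata
    reference_ : ReferenceGroup  pooled technical variance
    n_expressed_ : int           N, the 1/N cutoff denominator
    p_cutoff_ : float            1/N
    hv_probes_ : list[str]       flagged gene identifiers
    """

    def __init__(
        self,
        alpha_ref: float = 0.05,
        alpha_loo: float = 0.05,
        expressed_min_arrays: int = 2,
        min_reference_genes: int = 50,
        bias_correction: bool = True,
        statistic: str = "between",
    ):
        self.alpha_ref = alpha_ref
        self.alpha_loo = alpha_loo
        self.expressed_min_arrays = expressed_min_arrays
        self.min_reference_genes = min_reference_genes
        self.bias_correction = bias_correction
        self.statistic = statistic

    def fit(self, X: NormalizedMatrix, y: Sequence[Hashable]) -> "HVDetector":
        if not isinstance(X, NormalizedMatrix):
            raise TypeError("X must be a NormalizedMatrix")
        groups = list(y)
        if len(groups) != X.log_values.shape[1]:
            raise ValueError("one group label per array required")
        expressed_idx = X.expressed_genes(self.expressed_min_arrays)
        n_expressed = len(expressed_idx)
        if n_expressed == 0:
            raise InsufficientData("no genes expressed above background")
        values = X.log_values.loc[expressed_idx]
        codes, n_groups = _group_index(groups)
        n_arrays = values.shape[1]
        if n_arrays - n_groups < 1:
            raise InsufficientReplication("design has no replicate df")

        reference = build_reference_group(
            values,
            groups,
            alpha_ref=self.alpha_ref,
            min_genes=self.min_reference_genes,
            bias_correction=self.bias_correction,
        )

        if self.statistic not in ("between", "total"):
            raise ValueError("statistic must be 'between' or 'total'")
        arr = values.to_numpy()
        grand = arr.mean(axis=1, keepdims=True)
        sst = ((arr - grand) ** 2).sum(axis=1)
        if self.statistic == "between":
            if n_groups < 2:
                raise InsufficientReplication(
                    "statistic='between' needs at least 2 replicate groups"
                )
            ssr_w, _, _ = _residual_stats(arr, codes, n_groups)
            df_gene = n_groups - 1
            variance = (sst - ssr_w) / df_gene
        else:
            df_gene = n_arrays - 1
            variance = sst / df_gene
        F = variance / reference.pooled_variance
        p = stats.f.sf(F, df_gene, reference.pooled_df)
        cutoff = 1.0 / n_expressed
        flags = p < cutoff

        loo_dropped = np.zeros(n_expressed, dtype=bool)
        suspect = np.array([None] * n_expressed, dtype=object)
        flagged_rows = np.flatnonzero(flags)
        if flagged_rows.size and df_gene - 1 >= 1 and n_arrays - n_groups >= 2:
            stat, _, _, excluded = _loo_statistics(arr[flagged_rows], codes, n_groups)
            null = _loo_null_table(
                tuple(int((codes == g).sum()) for g in range(n_groups))
            )
            exceed = len(null) - np.searchsorted(null, stat, side="left")
            p_loo = (1.0 + exceed) / (len(null) + 1.0)
            drop = p_loo < self.alpha_loo
            loo_dropped[flagged_rows] = drop
            cols = list(values.columns)
            for r, d, e in zip(flagged_rows, drop, excluded):
                if d:
                    suspect[r] = str(cols[int(e)])

        hv_flag = flags & ~loo_dropped
        table = pd.DataFrame(
            {
                "variance": variance,
                "df": df_gene,
                "F": F,
                "p": p,
                "cutoff": cutoff,
                "hv_flag": hv_flag,
                "loo_dropped": loo_dropped,
                "suspect_sample": suspect,
            },
            index=values.index,
        )
        self.reference_ = reference
        self.n_expressed_ = n_expressed
        self.p_cutoff_ = cutoff
        self.result_ = HVResult(
            table=table,
            n_expressed=n_expressed,
            p_cutoff=cutoff,
            reference=reference,
        )
        self.hv_probes_ = self.result_.hv_probes
        return self


def detect_hv(
    normalized: NormalizedMatrix,
    group_labels: Sequence[Hashable],
    **params,
) -> HVResult:
    """Run the full HV detection pipeline; see :class:`HVDetector`."""
    return HVDetector(**params).fit(normalized, group_labels).result_
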