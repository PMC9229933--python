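"""Per-bin differential-abundance statistics for the 2×2 cohort.

For every retained bin we report the HSC/LSC ratio of group means on the
raw intensity scale, and test the treatment effect with an ordinary
least-squares linear model on log2(value + pseudocount). Two modes:

``per_week`` (default)
    one fit per bin per week, intercept + treatment; the treatment
    t-statistic with n−2 residual df is algebraically identical to the
    classical pooled-variance two-sample t-test on the transformed
    values. Only per-week fits can produce separate week-14 and week-22
    significance columns.

``pooled_additive``
    one fit per bin across both weeks with treatment + age main effects
    (the study's stated model wording); the treatment contrast is
    reported once with n−3 df.

P-values are two-sided from the t distribution and adjusted within each
week across the retained (post-filter) bins by the Benjamini–Hochberg
step-up, implemented here in closed form. Significance tiers follow the
study's reporting: q < 0.05, 0.05 ≤ q < 0.1, else "ns".

The OLS fits are computed from the normal equations directly (the design
has ≤ 3 columns), vectorised across bins.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import (
    TIER_LOOSE,
    TIER_NS,
    TIER_STRICT,
    BinMatrix,
    BinTestResult,
    ConfigurationError,
    SampleMetadata,
    ValidationError,
    metadata_frame,
)

log = logging.getLogger(__name__)

MODES = ("per_week", "pooled_additive")
TRANSFORMS = ("log2", "identity")


def assign_tier(q: float) -> str:
    """Map an FDR q-value to the study's reporting tier.

    q < 0.05 → "lt_0.05"; 0.05 ≤ q < 0.1 → "lt_0.1"; q ≥ 0.1 → "ns"
    (strict inequalities at both boundaries).
    """
    if not (0.0 <= q <= 1.0) or np.isnan(q):
        raise ValidationError(f"q-value {q!r} outside [0, 1]")
    if q < 0.05:
        return TIER_STRICT
    if q < 0.1:
        return TIER_LOOSE
    return TIER_NS


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, mapped back to input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1. Guarantees
    q >= p elementwise and monotonicity of q along the p-ordering.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be a 1-D vector")
    if p.size == 0:
        return np.array([])
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def group_ratio(
    matrix: BinMatrix, meta: Sequence[SampleMetadata], week: int
) -> dict[str, float]:
    """HSC/LSC ratio of per-group arithmetic mean bin values at one week.

    Computed on the raw intensity scale. If the LSC group mean is <= 0
    the ratio is undefined and reported as NaN (flagged in the log, not
    silently dropped).
    """
    mdf = metadata_frame(meta)
    ids = [s for s in matrix.sample_ids if s in mdf.index]
    sub = mdf.loc[ids]
    hsc = [s for s in ids if sub.at[s, "treatment"] == "HSC" and sub.at[s, "week"] == week]
    lsc = [s for s in ids if sub.at[s, "treatment"] == "LSC" and sub.at[s, "week"] == week]
    if not hsc or not lsc:
        raise ValidationError(f"week {week}: need >=1 sample per treatment")
    mean_h = matrix.data.loc[hsc].mean(axis=0)
    mean_l = matrix.data.loc[lsc].mean(axis=0)
    out: dict[str, float] = {}
    n_undefined = 0
    for lab in matrix.bin_labels:
        ml = float(mean_l[lab])
        if ml <= 0:
            out[lab] = float("nan")
            n_undefined += 1
        else:
            out[lab] = float(mean_h[lab]) / ml
    if n_undefined:
        log.warning(
            "week %s: ratio undefined (LSC mean <= 0) at %d bins", week, n_undefined
        )
    return out


def auto_pseudocount(matrix: BinMatrix) -> float:
    """Half the smallest positive value in the matrix (variance-stabilising
    offset for the log2 test scale)."""
    v = matrix.values
    pos = v[v > 0]
    if pos.size == 0:
        raise ValidationError("matrix has no positive values; cannot set pseudocount")
    return float(pos.min()) / 2.0


def _ols_treatment_tests(
    y: np.ndarray, X: np.ndarray, coef_idx: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray]:
    """Closed-form OLS of each column of y on X; t-test for one coefficient.

    Returns (beta, t, p, df, degenerate) with beta/t/p per bin. Zero
    residual variance yields p = 1 when the effect is also 0, otherwise
    the bin is flagged degenerate (t = ±inf, p = 0).
    """
    n, k = X.shape
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < k:
        raise ValidationError("singular design matrix (missing cells?)")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)  # k × bins
    resid = y - X @ beta
    df = n - k
    if df <= 0:
        raise ValidationError("no residual degrees of freedom")
    rss = np.einsum("ij,ij->j", resid, resid)
    # guard against negative rounding noise
    rss = np.maximum(rss, 0.0)
    scale = np.maximum(np.einsum("ij,ij->j", y, y), 1.0)
    zero_var = rss <= 1e-24 * scale
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[coef_idx, coef_idx], 0.0))
    b = beta[coef_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    degenerate = np.zeros(y.shape[1], dtype=bool)
    if np.any(zero_var):
        null_effect = np.abs(b) <= 1e-12 * np.sqrt(scale)
        exact_null = zero_var & null_effect
        exact_alt = zero_var & ~null_effect
        b[exact_null] = 0.0
        t[exact_null] = 0.0
        p[exact_null] = 1.0
        t[exact_alt] = np.sign(b[exact_alt]) * np.inf
        p[exact_alt] = 0.0
        degenerate[exact_alt] = True
    return b, t, p, float(df), degenerate


def fit_bin_model(
    matrix: BinMatrix,
    meta: Sequence[SampleMetadata],
    mode: str = "per_week",
    transform: str = "log2",
    pseudocount: Optional[float] = None,
) -> list[BinTestResult]:
    """Fit the per-bin treatment model and BH-adjust within each week.

    ``transform="log2"`` tests log2(max(value, 0) + pseudocount) with
    pseudocount defaulting to half the smallest positive matrix value;
    ``"identity"`` tests raw values (useful for oracle checks). Ratios
    are always reported on the raw scale regardless of the test scale.
    """
    if mode not in MODES:
        raise ConfigurationError(f"unknown model mode {mode!r}; choose from {MODES}")
    if transform not in TRANSFORMS:
        raise ConfigurationError(f"unknown transform {transform!r}")
    if matrix.n_bins == 0:
        raise ValidationError("no bins left after filtering; cannot fit models")
    mdf = metadata_frame(meta)
    missing = [s for s in matrix.sample_ids if s not in mdf.index]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")
    mdf = mdf.loc[matrix.sample_ids]

    values = matrix.values
    if transform == "log2":
        pc = auto_pseudocount(matrix) if pseudocount is None else float(pseudocount)
        if pc <= 0:
            raise ConfigurationError("pseudocount must be positive")
        y_all = np.log2(np.maximum(values, 0.0) + pc)
    else:
        y_all = values.astype(float)

    treat = (mdf["treatment"] == "HSC").to_numpy(dtype=float)
    labels = matrix.bin_labels
    results: list[BinTestResult] = []

    if mode == "per_week":
        for week in (14, 22):
            sel = (mdf["week"] == week).to_numpy()
            if sel.sum() == 0:
                continue
            tr = treat[sel]
            if min((tr == 1).sum(), (tr == 0).sum()) < 2:
                raise ValidationError(f"week {week}: need >=2 samples per cell")
            X = np.column_stack([np.ones(sel.sum()), tr])
            b, t, p, df, dg = _ols_treatment_tests(y_all[sel], X, coef_idx=1)
            ratios = group_ratio(matrix, meta, week)
            q = bh_adjust(p)
            for j, lab in enumerate(labels):
                results.append(
                    BinTestResult(
                        bin_label=lab,
                        week=str(week),
                        ratio_hsc_lsc=ratios[lab],
                        log2_effect=float(b[j]),
                        t_stat=float(t[j]),
                        df=df,
                        p_raw=float(p[j]),
                        q_fdr=float(q[j]),
                        tier=assign_tier(float(q[j])),
                        degenerate=bool(dg[j]),
                    )
                )
    else:  # pooled_additive
        age = (mdf["week"] == 22).to_numpy(dtype=float)
        for week in (14, 22):
            tr_w = treat[(mdf["week"] == week).to_numpy()]
            if min((tr_w == 1).sum(), (tr_w == 0).sum()) < 2:
                raise ValidationError(f"week {week}: need >=2 samples per cell")
        X = np.column_stack([np.ones(len(treat)), treat, age])
        b, t, p, df, dg = _ols_treatment_tests(y_all, X, coef_idx=1)
        q = bh_adjust(p)
        # pooled ratio: HSC mean over LSC mean across both weeks
        hsc_mean = values[treat == 1].mean(axis=0)
        lsc_mean = values[treat == 0].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            pooled_ratio = np.where(lsc_mean > 0, hsc_mean / lsc_mean, np.nan)
        for j, lab in enumerate(labels):
            results.append(
                BinTestResult(
                    bin_label=lab,
                    week="pooled",
                    ratio_hsc_lsc=float(pooled_ratio[j]),
                    log2_effect=float(b[j]),
                    t_stat=float(t[j]),
                    df=df,
                    p_raw=float(p[j]),
                    q_fdr=float(q[j]),
                    tier=assign_tier(float(q[j])),
                    degenerate=bool(dg[j]),
                )
            )
    return results


def tier_counts(results: Sequence[BinTestResult]) -> pd.DataFrame:
    """Per-week counts of bins in each significance tier."""
    rows = []
    df = pd.DataFrame(
        [(r.week, r.tier) for r in results], columns=["week", "tier"]
    )
    for week, grp in df.groupby("week"):
        rows.append(
            {
                "week": week,
                "n_bins": len(grp),
                "n_lt_0.05": int((grp["tier"] == TIER_STRICT).sum()),
                "n_lt_0.1": int((grp["tier"] == TIER_LOOSE).sum()),
                "n_ns": int((grp["tier"] == TIER_NS).sum()),
            }
        )
    return pd.DataFrame(rows)
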