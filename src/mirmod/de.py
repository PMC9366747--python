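"""Count normalisation and moderated differential expression.

Implements the standard small RNA-seq count workflow: CPM expression
filtering, TMM (trimmed mean of M-values) scaling factors, log2-CPM,
a per-feature two-group linear contrast with empirical-Bayes variance
moderation (prior df and scale fitted by moment-matching the log-variance
distribution through digamma/trigamma inversion), Benjamini-Hochberg
adjustment, enriched-set selection by (adjusted p, |log2FC|) thresholds,
and the 2^-ddCt relative-quantification calculator for qPCR Ct tables.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

D0_CAP = 1e6  # prior df at/above this is treated as infinite


def cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on raw (or supplied effective) library sizes."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    if (lib_sizes <= 0).any():
        bad = list(lib_sizes.index[lib_sizes <= 0])
        raise ValueError(f"zero/negative library size in samples: {bad}")
    return counts.div(lib_sizes, axis=1) * 1e6


def cpm_filter(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 3
) -> pd.DataFrame:
    """Keep features with CPM >= ``min_cpm`` in >= ``min_samples`` samples.

    CPM is computed on raw library sizes (column sums), before TMM.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    keep = (cpm(counts) >= min_cpm).sum(axis=1) >= min_samples
    return counts.loc[keep]


def tmm_factors(
    counts: pd.DataFrame,
    trim_M: float = 0.3,
    trim_A: float = 0.05,
    ref_column: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    Per non-reference sample: M (log2 ratio of depth-scaled counts vs the
    reference sample) and A (average log2 abundance) are computed over
    features positive in both samples; features in the upper/lower
    ``trim_M`` tail of M and ``trim_A`` tail of A are removed; the factor is
    2 to the precision-weighted mean of the surviving M values (binomial
    delta-method weights).  The reference sample is the one whose 75th
    count-fraction percentile is closest to the mean across samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    frac = counts.div(lib, axis=1)
    q75 = frac.quantile(0.75, axis=0)
    if ref_column is None:
        ref_column = (q75 - q75.mean()).abs().idxmin()

    y_r = counts[ref_column].to_numpy(float)
    n_r = lib[ref_column]
    factors = {}
    for col in counts.columns:
        if col == ref_column:
            factors[col] = 1.0
            continue
        y_k = counts[col].to_numpy(float)
        n_k = lib[col]
        pos = (y_k > 0) & (y_r > 0)
        if not pos.any():
            warnings.warn(f"no shared positive features for {col}; factor 1")
            factors[col] = 1.0
            continue
        yk, yr = y_k[pos], y_r[pos]
        M = np.log2((yk / n_k) / (yr / n_r))
        A = 0.5 * np.log2((yk / n_k) * (yr / n_r))
        w = (n_k - yk) / (n_k * yk) + (n_r - yr) / (n_r * yr)
        n = M.size
        lo_M, hi_M = np.floor(n * trim_M) + 1, n + 1 - (np.floor(n * trim_M) + 1)
        lo_A, hi_A = np.floor(n * trim_A) + 1, n + 1 - (np.floor(n * trim_A) + 1)
        rank_M = stats.rankdata(M)
        rank_A = stats.rankdata(A)
        keep = (rank_M >= lo_M) & (rank_M <= hi_M) & \
               (rank_A >= lo_A) & (rank_A <= hi_A)
        if not keep.any() or w[keep].sum() == 0:
            warnings.warn(f"degenerate trim for {col}; factor 1")
            factors[col] = 1.0
            continue
        f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
        if not np.isfinite(f):
            f = 0.0
        factors[col] = float(2.0 ** f)
    fac = pd.Series(factors).reindex(counts.columns)
    fac /= np.exp(np.log(fac).mean())  # geometric mean 1
    return fac


def log_cpm(
    counts: pd.DataFrame,
    tmm: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 CPM with a +``prior_count`` offset, on TMM-effective library sizes."""
    lib = counts.sum(axis=0).astype(float)
    if tmm is not None:
        lib = lib * tmm
    return np.log2((counts + prior_count).div(lib + 1.0, axis=1) * 1e6)


# ---------------------------------------------------------------------------
# empirical Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_f_dist(variances: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match ``(d0, s0^2)`` of a scaled inverse-chi-square variance prior.

    Under the hierarchical model s_g^2 ~ s0^2 * F(df, d0), the log sample
    variances have mean ``ln s0^2 + psi(df/2) - ln(df/2) - psi(d0/2) +
    ln(d0/2)`` and variance ``psi'(df/2) + psi'(d0/2)``; both moments are
    inverted here.  Returns ``d0 = inf`` (capped) when the observed spread is
    no larger than the sampling spread.
    """
    v = np.asarray(variances, float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 2:
        raise ValueError("need >= 2 positive variances to fit the prior")
    e = np.log(v)
    mean_e = e.mean()
    var_e = e.var(ddof=1)
    excess = var_e - special.polygamma(1, df / 2.0)
    # E[ln s^2] = ln s0^2 + (psi(df/2) - ln(df/2)) - (psi(d0/2) - ln(d0/2))
    bias_df = special.polygamma(0, df / 2.0) - np.log(df / 2.0)
    if excess <= 0:
        d0 = np.inf
        ln_s0 = mean_e - bias_df
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        if d0 >= D0_CAP:
            d0 = np.inf
        bias_d0 = (special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)
                   if np.isfinite(d0) else 0.0)
        ln_s0 = mean_e - bias_df + bias_d0
    return (float(d0), float(np.exp(ln_s0)))


def moderated_t_test(
    log_expr: pd.DataFrame,
    groups: Sequence[str],
    contrast: tuple[str, str] | None = None,
    d0_override: float | None = None,
    block: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-feature two-group contrast with empirical-Bayes shrunk variances.

    ``groups`` labels the columns of ``log_expr``; ``contrast=(A, B)`` tests
    B - A (defaults to the two labels in sorted order).  ``block`` adds a
    categorical covariate (e.g. donor) to the linear model.  ``d0_override=0``
    reduces to the ordinary two-sample t-test; a very large value gives the
    fully pooled limit.  Returns a DataFrame with ``log2fc``, ``ave_expr``,
    ``t``, ``p``, ``padj`` and ``direction``.
    """
    groups = list(groups)
    if len(groups) != log_expr.shape[1]:
        raise ValueError("groups length must match number of samples")
    levels = sorted(set(groups))
    if contrast is None:
        if len(levels) != 2:
            raise ValueError("need exactly two group levels or an explicit contrast")
        contrast = (levels[0], levels[1])
    a, b = contrast
    use = [g in (a, b) for g in groups]
    X_labels = [g for g, u in zip(groups, use) if u]
    Y = log_expr.loc[:, use].to_numpy(float)
    n = Y.shape[1]
    if X_labels.count(a) < 2 or X_labels.count(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if log_expr.shape[0] < 10 and d0_override is None:
        raise ValueError("need >= 10 features for prior estimation")

    # design: intercept + group indicator (+ block dummies)
    cols = [np.ones(n), np.array([1.0 if g == b else 0.0 for g in X_labels])]
    if block is not None:
        blk = [v for v, u in zip(list(block), use) if u]
        for lev in sorted(set(blk))[1:]:
            cols.append(np.array([1.0 if v == lev else 0.0 for v in blk]))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    df_resid = n - rank
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    XtX_inv = np.linalg.pinv(X.T @ X)
    H = XtX_inv @ X.T
    beta = Y @ H.T  # features x params
    resid = Y - beta @ X.T
    s2 = (resid ** 2).sum(axis=1) / df_resid
    lfc = beta[:, 1]
    unscaled_se = np.sqrt(XtX_inv[1, 1])

    if d0_override is not None:
        d0 = float(d0_override)
        s02 = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
    else:
        d0, s02 = fit_f_dist(s2, df_resid)

    if d0 == 0:
        s2_post = s2.copy()
    elif not np.isfinite(d0) or d0 >= D0_CAP:
        d0 = np.inf
        s2_post = np.full_like(s2, s02)
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
    df_total = df_resid + (0 if not np.isfinite(d0) else d0)
    df_t = np.inf if not np.isfinite(d0) else df_total

    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / (np.sqrt(s2_post) * unscaled_se)
    t = np.where(np.isfinite(t), t, 0.0)
    if np.isinf(df_t):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_t)

    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "ave_expr": Y.mean(axis=1),
            "t": t,
            "p": p,
            "padj": bh_adjust(p),
        },
        index=log_expr.index,
    )
    out["direction"] = np.where(out["log2fc"] > 0, f"up_in_{b}", f"up_in_{a}")
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s02 if d0_override is None else None
    out.attrs["df_resid"] = df_resid
    out.attrs["contrast"] = contrast
    out.attrs["s2_post"] = s2_post
    return out


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs propagate and are
    excluded from the number of tests."""
    p = np.asarray(list(p_values) if not isinstance(p_values, np.ndarray)
                   else p_values, float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def select_enriched(
    de: pd.DataFrame, alpha: float = 0.05, lfc: float = 2.0
) -> tuple[set[str], set[str]]:
    """(enriched_in_B, enriched_in_A) by adjusted p < alpha and |log2FC| > lfc."""
    sig = de["padj"] < alpha
    up_b = set(de.index[sig & (de["log2fc"] > lfc)])
    up_a = set(de.index[sig & (de["log2fc"] < -lfc)])
    return up_b, up_a


def differential_expression(
    counts: pd.DataFrame,
    groups: Sequence[str],
    contrast: tuple[str, str],
    min_cpm: float = 1.0,
    min_samples: int = 3,
    block: Sequence[str] | None = None,
) -> pd.DataFrame:
    """CPM filter -> TMM -> log2-CPM -> moderated t -> BH, in one call."""
    filtered = cpm_filter(counts, min_cpm=min_cpm, min_samples=min_samples)
    tmm = tmm_factors(filtered)
    lc = log_cpm(filtered, tmm)
    return moderated_t_test(lc, groups, contrast=contrast, block=block)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def ddct(
    ct: pd.DataFrame,
    target: str,
    reference_genes: Sequence[str],
    group_labels: Sequence[str],
    treated: str,
    control: str,
) -> dict:
    """2^-ddCt relative quantification.

    ``ct`` is samples x genes (Ct cycles).  Per sample, dCt = Ct(target) -
    mean Ct over the reference genes; ddCt = mean dCt(treated) - mean
    dCt(control); RQ = 2^-ddCt.  Per-sample RQs (2^-(dCt - mean dCt
    control)) are returned for plotting/statistics.
    """
    missing = [g for g in reference_genes if g not in ct.columns]
    if missing:
        raise ValueError(f"reference genes absent from Ct table: {missing}")
    if target not in ct.columns:
        raise ValueError(f"target {target!r} absent from Ct table")
    if (ct[list(reference_genes) + [target]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    labels = pd.Series(list(group_labels), index=ct.index)
    for grp in (treated, control):
        idx = labels.index[labels == grp]
        if len(idx) == 0 or ct.loc[idx, target].isna().any():
            bad = list(ct.loc[idx, target].index[ct.loc[idx, target].isna()]) \
                if len(idx) else []
            raise ValueError(
                f"group {grp!r} missing target measurements (samples {bad})"
            )
    dct = ct[target] - ct[list(reference_genes)].mean(axis=1)
    ddct_val = dct[labels == treated].mean() - dct[labels == control].mean()
    rq = 2.0 ** (-ddct_val)
    per_sample = 2.0 ** (-(dct - dct[labels == control].mean()))
    return {
        "ddct": float(ddct_val),
        "rq": float(rq),
        "per_sample_rq": per_sample,
        "dct": dct,
    }
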