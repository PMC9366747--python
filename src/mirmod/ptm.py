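"""Summary statistics over modification profiles.

Per-miRNA modified-read fractions (with a minimum-read exclusion), top-N
miRNA set construction (by expression or by enrichment), positional
mono-addition fractions, and the nonparametric group comparisons used to
contrast compartments: exact Wilcoxon signed-rank for paired donors,
Mann-Whitney for unpaired designs, Kruskal-Wallis across >= 2 groups.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mirmod.profiler import IsomiRCall, ModificationProfile, Unaligned


def fraction_modified(
    calls_by_sample: Mapping[str, Iterable[IsomiRCall | Unaligned]],
    min_reads: int = 10,
    mirna_set: Iterable[str] | None = None,
    end: str | None = None,
) -> pd.DataFrame:
    """Per (miRNA, sample) fraction of assigned reads carrying >= 1 event.

    Rows with fewer than ``min_reads`` assigned reads are flagged excluded
    and carry no fraction.  ``end`` ('5p'/'3p') restricts which events make a
    read count as modified (default: any end).  ``mirna_set`` restricts the
    table to those miRNAs.
    """
    scope = set(mirna_set) if mirna_set is not None else None
    rows = []
    for sample_id, calls in calls_by_sample.items():
        n: dict[str, int] = {}
        n_mod: dict[str, int] = {}
        for call in calls:
            if not isinstance(call, IsomiRCall):
                continue
            if scope is not None and call.mirna_id not in scope:
                continue
            n[call.mirna_id] = n.get(call.mirna_id, 0) + 1
            events = call.events if end is None else [
                e for e in call.events if e.end == end
            ]
            if events:
                n_mod[call.mirna_id] = n_mod.get(call.mirna_id, 0) + 1
        for mid in sorted(n):
            excluded = n[mid] < min_reads
            rows.append({
                "sample_id": sample_id,
                "mirna_id": mid,
                "n_reads": n[mid],
                "n_modified": n_mod.get(mid, 0),
                "fraction": np.nan if excluded else n_mod.get(mid, 0) / n[mid],
                "excluded": excluded,
            })
    return pd.DataFrame(
        rows, columns=["sample_id", "mirna_id", "n_reads", "n_modified",
                       "fraction", "excluded"],
    )


def fraction_modified_from_profiles(
    profiles: Mapping[str, ModificationProfile],
    min_reads: int = 10,
    mirna_set: Iterable[str] | None = None,
    end: str | None = None,
) -> pd.DataFrame:
    """Modified-read fraction table computed from profile aggregates.

    Streaming counterpart of :func:`fraction_modified` for runs where the
    per-read calls were not retained; yields identical tables.
    """
    scope = set(mirna_set) if mirna_set is not None else None
    key = "any" if end is None else end
    rows = []
    for sample_id, prof in profiles.items():
        for mid in sorted(prof.assigned_per_mirna):
            if scope is not None and mid not in scope:
                continue
            n = prof.assigned_per_mirna[mid]
            n_mod = prof.modified_per_mirna.get(mid, {}).get(key, 0)
            excluded = n < min_reads
            rows.append({
                "sample_id": sample_id, "mirna_id": mid, "n_reads": n,
                "n_modified": n_mod,
                "fraction": np.nan if excluded else n_mod / n,
                "excluded": excluded,
            })
    return pd.DataFrame(
        rows, columns=["sample_id", "mirna_id", "n_reads", "n_modified",
                       "fraction", "excluded"],
    )


def top_sets(
    data: pd.DataFrame,
    mode: str,
    group: Sequence[str] | None = None,
    n: int = 30,
    alpha: float = 0.05,
) -> list[str]:
    """Ordered top-``n`` miRNA set.

    mode='expressed': ``data`` is a counts matrix; rank by mean CPM over the
    columns named in ``group`` (all columns if None).  mode='enriched':
    ``data`` is a DE result table; rank by log2FC (toward group B) among
    features with adjusted p < ``alpha``.  Ties break by feature ID.
    """
    if mode == "expressed":
        cols = list(group) if group is not None else list(data.columns)
        sub = data[cols]
        score = (sub.div(sub.sum(axis=0), axis=1) * 1e6).mean(axis=1)
    elif mode == "enriched":
        sig = data[data["padj"] < alpha]
        if len(sig) < n:
            warnings.warn(
                f"only {len(sig)} significant features for top-{n} enriched set"
            )
        score = sig["log2fc"]
    else:
        raise ValueError("mode must be 'expressed' or 'enriched'")
    if mode == "expressed" and n > len(score):
        raise ValueError(f"n={n} exceeds number of features {len(score)}")
    order = sorted(score.index, key=lambda m: (-score[m], m))
    return order[:n]


def positional_mono_fractions(
    profiles: Mapping[str, ModificationProfile] | ModificationProfile,
    positions: Sequence[int] = (-1, 0, 1),
    end: str = "3p",
    mirna_set: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Fraction of in-scope reads with a mono-addition of each nucleotide.

    Numerator: reads whose call contains a mono-addition run start of that
    nucleotide at that position (a mono run has exactly one event, which is
    its run start).  Denominator: assigned reads in scope (all assigned
    reads, or those assigned to ``mirna_set``).
    """
    if isinstance(profiles, ModificationProfile):
        profiles = {profiles.sample_id: profiles}
    scope = set(mirna_set) if mirna_set is not None else None
    rows = []
    for sample_id, prof in profiles.items():
        if scope is None:
            denom = prof.total_assigned
        else:
            denom = sum(prof.assigned_per_mirna.get(m, 0) for m in scope)
        if denom == 0:
            raise ValueError(f"empty scope for sample {sample_id}")
        for pos in positions:
            for nt in "ACGU":
                num = sum(
                    cnt for (mid, e, p, n_, kind, run), cnt in prof.counts.items()
                    if e == end and p == pos and n_ == nt
                    and kind == "addition" and run == "mono"
                    and (scope is None or mid in scope)
                )
                rows.append({
                    "sample_id": sample_id, "end": end, "position": pos,
                    "nucleotide": nt, "n_reads": num, "n_total": denom,
                    "fraction": num / denom,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------

def _signed_rank_exact_p(ranks2: np.ndarray, w_plus2: float) -> float:
    """Two-sided exact p for the signed-rank sum by subset-sum DP.

    ``ranks2`` are the (tie-averaged) ranks doubled so they are integers;
    ``w_plus2`` is the doubled observed positive-rank sum.  All 2^n sign
    assignments are equally likely under H0.
    """
    total = int(ranks2.sum())
    # dp[s] = number of sign assignments with positive-rank sum s (doubled)
    dp = np.zeros(total + 1, dtype=float)
    dp[0] = 1.0
    for r in ranks2.astype(int):
        dp[r:] = dp[r:] + dp[:total + 1 - r]
    n_total = dp.sum()  # == 2^n
    w = int(round(w_plus2))
    p_low = dp[: w + 1].sum() / n_total
    p_high = dp[w:].sum() / n_total
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    exact_limit: int = 25,
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test (two-sided).

    Zero differences are dropped and tied absolute differences receive
    averaged ranks.  The null distribution is enumerated exactly (via
    dynamic programming over sign assignments) for n <= ``exact_limit``
    non-zero pairs, otherwise the normal approximation with tie correction
    is used.  Returns (W = positive-rank sum, p).
    """
    x = np.asarray(x, float)
    if y is not None:
        y = np.asarray(y, float)
        if x.shape != y.shape:
            raise ValueError("paired vectors must have equal length")
        d = x - y
    else:
        d = x
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= exact_limit:
        p = _signed_rank_exact_p(np.round(ranks * 2), w_plus * 2)
    else:
        mu = n * (n + 1) / 4.0
        # tie correction on the variance
        _, tie_counts = np.unique(ranks, return_counts=True)
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - \
            (tie_counts ** 3 - tie_counts).sum() / 48.0
        z = (w_plus - mu) / np.sqrt(sigma2)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return w_plus, min(1.0, p)


def _kw_h(values: np.ndarray, sizes: Sequence[int]) -> float:
    """Tie-corrected Kruskal-Wallis H for concatenated group values."""
    ranks = stats.rankdata(values)
    n = values.size
    h = 0.0
    start = 0
    for sz in sizes:
        r = ranks[start:start + sz]
        h += r.sum() ** 2 / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    tie = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    return h / tie if tie > 0 else 0.0


def kruskal_wallis(
    *groups: Sequence[float], method: str = "chi2"
) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction.

    method='chi2' (default) uses the chi-square approximation on k-1 df
    (scipy); method='exact' enumerates every distinct assignment of the
    pooled observations to the group sizes and reports P(H >= observed) —
    feasible for small total N only.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 groups")
    arrs = [np.asarray(g, float) for g in groups]
    if method == "chi2":
        h, p = stats.kruskal(*arrs)
        return float(h), float(p)
    if method != "exact":
        raise ValueError("method must be 'chi2' or 'exact'")
    pooled = np.concatenate(arrs)
    sizes = [a.size for a in arrs]
    n = pooled.size
    if n > 12:
        raise ValueError("exact Kruskal-Wallis limited to total N <= 12")
    h_obs = _kw_h(pooled, sizes)

    # H depends only on the per-group rank sums, so enumerate partitions of
    # the pooled ranks into the observed group sizes
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    if tie <= 0:  # all observations identical
        return 0.0, 1.0
    const = 12.0 / (n * (n + 1))

    count = 0
    total = 0

    def recurse(remaining: tuple[int, ...], g: int, acc: float) -> None:
        nonlocal count, total
        if g == len(sizes) - 1:
            s = ranks[list(remaining)].sum()
            h = (const * (acc + s * s / sizes[g]) - 3 * (n + 1)) / tie
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
            return
        for combo in itertools.combinations(remaining, sizes[g]):
            s = ranks[list(combo)].sum()
            rest = tuple(i for i in remaining if i not in set(combo))
            recurse(rest, g + 1, acc + s * s / sizes[g])

    recurse(tuple(range(n)), 0, 0.0)
    return float(h_obs), count / total


def compare_groups(
    values: Mapping[str, Sequence[float]],
    test: str = "wilcoxon_signed_rank",
    method: str = "chi2",
) -> dict:
    """Compare per-donor values between groups.

    ``values`` maps group name -> per-donor vector (aligned by donor for the
    paired test).  ``test`` is one of 'wilcoxon_signed_rank' (2 paired
    groups), 'mann_whitney' (2 unpaired groups), 'kruskal_wallis' (>= 2
    groups; ``method`` selects chi2 or exact enumeration).
    """
    names = list(values)
    arrs = [np.asarray(values[g], float) for g in names]
    if test == "wilcoxon_signed_rank":
        if len(arrs) != 2:
            raise ValueError("signed-rank test needs exactly 2 groups")
        stat, p = wilcoxon_signed_rank(arrs[0], arrs[1])
    elif test == "mann_whitney":
        if len(arrs) != 2:
            raise ValueError("Mann-Whitney needs exactly 2 groups")
        res = stats.mannwhitneyu(arrs[0], arrs[1], alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "kruskal_wallis":
        stat, p = kruskal_wallis(*arrs, method=method)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"test": test, "groups": names, "statistic": stat, "p": p}
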