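"""Independent brute-force oracles used by the tests and the acceptance
script.  Deliberately naive: exhaustive enumeration and literal formula
transcription, sharing no code with the package implementation."""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# adapter trimming: enumerate every (start, overlap) pair
# ---------------------------------------------------------------------------

def oracle_adapter_start(read: str, adapter: str, max_error_rate: float,
                         min_overlap: int):
    """Best qualifying adapter-prefix occurrence by literal enumeration."""
    best = None
    best_start = None
    for start in range(len(read)):
        overlap = min(len(adapter), len(read) - start)
        if overlap < min_overlap:
            continue
        mism = sum(
            1 for i in range(overlap) if read[start + i] != adapter[i]
        )
        if mism > math.floor(max_error_rate * overlap):
            continue
        matches = overlap - mism
        if best is None or matches > best or \
                (matches == best and start < best_start):
            best, best_start = matches, start
    return best_start


# ---------------------------------------------------------------------------
# isomiR decomposition: enumerate every (reference, shift, core) candidate
# ---------------------------------------------------------------------------

def oracle_classify(read: str, refs: dict[str, str], max_offset5: int = 4,
                    max_internal_mismatch: int = 1, min_core: int = 14,
                    max_tail: int = 8):
    """Optimal decomposition by exhaustive enumeration.

    Returns ``(mirna_id, offset5, core_first, core_last, ambiguous)`` or
    ``None`` when no valid decomposition exists.  Applies the published
    objective: maximal core, minimal non-templated bases, minimal |offset5|,
    lexicographic miRNA ID.
    """
    best_full = None
    best3 = None
    tied_ids = set()
    n = len(read)
    for mid in sorted(refs):
        canon = refs[mid]
        L = len(canon)
        for shift in range(-max_offset5, max_offset5 + 1):
            for r1 in range(n):
                for r2 in range(r1, n):
                    if r1 + shift < 0 or r2 + shift > L - 1:
                        continue
                    if read[r1] != canon[r1 + shift]:
                        continue
                    if read[r2] != canon[r2 + shift]:
                        continue
                    # maximal extension: adjacent in-template bases mismatch
                    if r1 > 0 and r1 - 1 + shift >= 0 \
                            and read[r1 - 1] == canon[r1 - 1 + shift]:
                        continue
                    if r2 < n - 1 and r2 + 1 + shift <= L - 1 \
                            and read[r2 + 1] == canon[r2 + 1 + shift]:
                        continue
                    mism = [r for r in range(r1, r2 + 1)
                            if read[r] != canon[r + shift]]
                    if len(mism) > max_internal_mismatch:
                        continue
                    ok = True
                    for r in mism:
                        downstream = sum(
                            1 for q in range(r + 1, r2 + 1)
                            if read[q] == canon[q + shift]
                        )
                        if downstream < 2:
                            ok = False
                            break
                    if not ok:
                        continue
                    core_len = r2 - r1 + 1
                    if core_len < min_core:
                        continue
                    tail5, tail3 = r1, n - 1 - r2
                    if tail5 > max_tail or tail3 > max_tail:
                        continue
                    key3 = (-core_len, tail5 + tail3 + len(mism), abs(shift))
                    full = key3 + (mid, shift, r1)
                    if best3 is None or key3 < best3:
                        best3 = key3
                        tied_ids = {mid}
                    elif key3 == best3:
                        tied_ids.add(mid)
                    if best_full is None or full < best_full:
                        best_full = full
                        best = (mid, shift, r1, r2)
    if best_full is None:
        return None
    mid, shift, r1, r2 = best
    return (mid, -shift, r1 + shift, r2 + shift, len(tied_ids) > 1)


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------

def oracle_bh(p: list[float]) -> list[float]:
    """Literal step-up with sort + cumulative minimum."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0).tolist()


def oracle_signed_rank_p(diffs: list[float]) -> float:
    """Two-sided exact p by enumerating all 2^n sign patterns."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    if n == 0:
        return 1.0
    absd = [abs(x) for x in d]
    # average ranks over ties
    ranks = []
    for a in absd:
        less = sum(1 for b in absd if b < a)
        eq = sum(1 for b in absd if b == a)
        ranks.append(less + (eq + 1) / 2.0)
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    lo = hi = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-12:
            lo += 1
        if w >= w_obs - 1e-12:
            hi += 1
    total = 2 ** n
    return min(1.0, 2.0 * min(lo / total, hi / total))


def oracle_kw(groups: list[list[float]]):
    """Tie-corrected H and exact permutation p by full enumeration."""
    pooled = [x for g in groups for x in g]
    sizes = [len(g) for g in groups]
    n = len(pooled)

    def ranks_of(vals):
        out = []
        for a in vals:
            less = sum(1 for b in vals if b < a)
            eq = sum(1 for b in vals if b == a)
            out.append(less + (eq + 1) / 2.0)
        return out

    def h_stat(vals):
        ranks = ranks_of(vals)
        h = 0.0
        start = 0
        for sz in sizes:
            h += sum(ranks[start:start + sz]) ** 2 / sz
            start += sz
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        ties = {}
        for v in vals:
            ties[v] = ties.get(v, 0) + 1
        corr = 1.0 - sum(t ** 3 - t for t in ties.values()) / (n ** 3 - n)
        return h / corr if corr > 0 else 0.0

    h_obs = h_stat(pooled)
    count = total = 0
    for perm in itertools.permutations(pooled):
        total += 1
        if h_stat(list(perm)) >= h_obs - 1e-12:
            count += 1
    return h_obs, count / total


def oracle_hypergeom_tail(k: int, big_n: int, big_k: int, n_draw: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by direct summation."""
    total = 0.0
    for x in range(k, min(big_k, n_draw) + 1):
        total += (math.comb(big_k, x) * math.comb(big_n - big_k, n_draw - x)
                  / math.comb(big_n, n_draw))
    return min(1.0, total)


def oracle_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def oracle_tmm_factor(counts_k, counts_r, lib_k, lib_r,
                      trim_m=0.3, trim_a=0.05):
    """Step-by-step trimmed weighted mean of M-values for one sample pair."""
    M, A, W = [], [], []
    for yk, yr in zip(counts_k, counts_r):
        if yk > 0 and yr > 0:
            M.append(math.log2((yk / lib_k) / (yr / lib_r)))
            A.append(0.5 * math.log2((yk / lib_k) * (yr / lib_r)))
            W.append((lib_k - yk) / (lib_k * yk) + (lib_r - yr) / (lib_r * yr))
    n = len(M)

    def avg_rank(vals, x):
        less = sum(1 for v in vals if v < x)
        eq = sum(1 for v in vals if v == x)
        return less + (eq + 1) / 2.0

    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    num = den = 0.0
    for m, a, w in zip(M, A, W):
        rm, ra = avg_rank(M, m), avg_rank(A, a)
        if lo_m <= rm <= hi_m and lo_a <= ra <= hi_a:
            num += m / w
            den += 1.0 / w
    return 2.0 ** (num / den)


def oracle_ddct(ct_target_treated, ct_refs_treated,
                ct_target_control, ct_refs_control):
    """Literal 2^-ddCt on per-sample Ct lists (refs: list of lists)."""
    dct_t = [t - sum(r) / len(r) for t, r in
             zip(ct_target_treated, ct_refs_treated)]
    dct_c = [t - sum(r) / len(r) for t, r in
             zip(ct_target_control, ct_refs_control)]
    ddct = sum(dct_t) / len(dct_t) - sum(dct_c) / len(dct_c)
    return 2.0 ** (-ddct)
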