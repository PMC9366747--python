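"""Short-motif (4-8 nt) enrichment in miRNA sequence sets.

Foreground (e.g. EV-enriched miRNAs) and background (the full canonical
collection) are first made non-redundant by greedy centroid clustering at a
sequence-identity threshold; exact k-mers are then tested for
over-representation under a ZOOPS presence/absence model (a sequence counts
once no matter how often it contains the motif) with a one-sided Fisher
exact test, Bonferroni-style adjusted into an E-value over the number of
candidates examined.  Searches run on the forward strand only, matching how
sorting motifs are read by RNA-binding proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import edlib
from scipy import stats


def _norm(seq: str) -> str:
    return seq.upper().replace("T", "U")


def sequence_identity(a: str, b: str) -> float:
    """1 - Levenshtein(a, b) / max(|a|, |b|)."""
    if not a and not b:
        return 1.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def reduce_redundancy(
    sequences: Sequence[tuple[str, str]] | Sequence[str],
    identity_threshold: float = 0.8,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Greedy centroid clustering at an identity threshold.

    Sequences are processed in order of decreasing length, ties broken
    lexicographically; each joins the first centroid it matches at identity
    >= ``identity_threshold``, otherwise it founds a new cluster.  Returns
    the centroid list (id, sequence) and a member-id -> centroid-id map.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("identity_threshold must be in (0, 1]")
    items: list[tuple[str, str]] = []
    for i, entry in enumerate(sequences):
        if isinstance(entry, str):
            items.append((f"seq{i + 1}", _norm(entry)))
        else:
            items.append((entry[0], _norm(entry[1])))
    if not items:
        raise ValueError("empty sequence set")
    ordered = sorted(items, key=lambda kv: (-len(kv[1]), kv[1], kv[0]))
    centroids: list[tuple[str, str]] = []
    cluster_map: dict[str, str] = {}
    for sid, seq in ordered:
        for cid, cseq in centroids:
            if sequence_identity(seq, cseq) >= identity_threshold:
                cluster_map[sid] = cid
                break
        else:
            centroids.append((sid, seq))
            cluster_map[sid] = sid
    return centroids, cluster_map


@dataclass(frozen=True)
class MotifResult:
    motif: str
    k: int
    fg_with: int
    fg_total: int
    bg_with: int
    bg_total: int
    p: float
    e_adj: float

    def __post_init__(self) -> None:
        if not (self.fg_with <= self.fg_total and self.bg_with <= self.bg_total):
            raise ValueError("presence counts exceed set sizes")


def _presence_p(fg_with: int, fg_total: int, bg_with: int, bg_total: int) -> float:
    """One-sided Fisher exact p for foreground enrichment (hypergeometric tail)."""
    return float(stats.hypergeom.sf(
        fg_with - 1, fg_total + bg_total, fg_with + bg_with, fg_total
    ))


def zoops_enrichment(
    foreground: Sequence[tuple[str, str]] | Sequence[str],
    background: Sequence[tuple[str, str]] | Sequence[str],
    k_min: int = 4,
    k_max: int = 8,
    e_threshold: float = 0.2,
    min_fg_sequences: int = 2,
    return_all: bool = False,
    exclude_foreground: bool = False,
) -> list[MotifResult]:
    """Exact-k-mer ZOOPS enrichment of foreground vs background.

    Candidates are every k-mer (k_min <= k <= k_max) present in at least
    ``min_fg_sequences`` foreground sequences; for each, presence counts
    (one per sequence) enter a one-sided Fisher exact test, and
    ``e_adj = p x total number of candidates`` (reported unclipped).
    Results with ``e_adj < e_threshold`` are returned sorted by
    (e_adj, motif); ``return_all`` disables the threshold.
    """
    def seqs_of(entries):
        out = []
        for i, entry in enumerate(entries):
            out.append(_norm(entry) if isinstance(entry, str) else _norm(entry[1]))
        return out

    fg = seqs_of(foreground)
    bg = seqs_of(background)
    if exclude_foreground:
        fg_set = set(fg)
        bg = [s for s in bg if s not in fg_set]
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    shortest = min(len(s) for s in fg)
    if k_max > shortest:
        warnings.warn(
            f"k up to {k_max} requested but shortest foreground sequence is "
            f"{shortest} nt; longer k values are skipped for short sequences"
        )

    def kmer_presence(seqs: list[str], k: int) -> dict[str, int]:
        pres: dict[str, int] = {}
        for s in seqs:
            for km in {s[i:i + k] for i in range(len(s) - k + 1)}:
                pres[km] = pres.get(km, 0) + 1
        return pres

    candidates: list[tuple[str, int, int]] = []  # motif, k, fg_with
    fg_presence_by_k: dict[int, dict[str, int]] = {}
    for k in range(k_min, k_max + 1):
        pres = kmer_presence(fg, k)
        fg_presence_by_k[k] = pres
        for motif, cnt in pres.items():
            if cnt >= min_fg_sequences:
                candidates.append((motif, k, cnt))
    n_candidates = len(candidates)

    results = []
    bg_presence_by_k = {
        k: kmer_presence(bg, k) for k in {k for _, k, _ in candidates}
    }
    for motif, k, fg_with in candidates:
        bg_with = bg_presence_by_k[k].get(motif, 0)
        p = _presence_p(fg_with, len(fg), bg_with, len(bg))
        e_adj = p * n_candidates
        results.append(MotifResult(
            motif=motif, k=k, fg_with=fg_with, fg_total=len(fg),
            bg_with=bg_with, bg_total=len(bg), p=p, e_adj=e_adj,
        ))
    results.sort(key=lambda r: (r.e_adj, r.motif))
    if return_all:
        return results
    return [r for r in results if r.e_adj < e_threshold]
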