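"""Read-to-miRNA assignment and positional modification calling.

Each preprocessed read is aligned ungapped against a collection of canonical
mature miRNAs and decomposed into a templated core plus non-templated 5'/3'
tails and substitutions.  Events are reported in an end-anchored coordinate
frame: position 0 is the canonical terminal nucleotide of that end, negative
positions run into the miRNA body, positive positions extend beyond the
canonical terminus.  Only events at positions -4..+4 are reported.

Decomposition rule
------------------
For a read, every candidate (reference, alignment shift) is evaluated; a
decomposition chooses a contiguous core of the read aligned inside the
canonical sequence such that

* the first and last core bases match the template,
* a core base adjacent to a read base that also matches the template is
  never a core boundary (maximal extension: bases matching the template are
  consumed as templated),
* core mismatches are substitutions, each requiring at least two templated
  matches 3'-ward of it within the core, at most ``max_internal_mismatch``
  in total.

Read bases outside the core are non-templated additions (mono if the run
has length 1, poly otherwise).  Among all valid decompositions the call
(1) maximises core length, (2) minimises total non-templated bases
(tails + substitutions), (3) prefers the smaller absolute 5' offset, and
(4) falls back to the lexicographically smaller miRNA ID, flagged
ambiguous.  Reads whose best core is shorter than ``min_core`` or whose
tail exceeds ``max_tail`` are unaligned.

This deterministic parsimony rule replaces probabilistic (EM-based)
multi-mapping resolution: it is exactly reproducible and checkable
against a brute-force oracle.  A non-templated base that coincidentally
matches the template is, by parsimony, counted as templated, which slightly
under-counts true non-templated additions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from mirmod.preprocess import _open_maybe_gzip, parse_fastq
from mirmod.simulate import RNA_ALPHABET, MiRNAReference, check_unique_ids

ENDS = ("5p", "3p")
KINDS = ("addition", "substitution")
RUNS = ("mono", "poly", "-")  # '-' for substitutions
REPORT_WINDOW = 4  # events reported at positions -4..+4


@dataclass(frozen=True)
class IsomiRParams:
    """Tunable thresholds of the classifier."""

    max_offset5: int = 4
    max_internal_mismatch: int = 1
    min_core: int = 14
    max_tail: int = 8

    def max_safe_seed_length(self) -> int:
        """Longest seed guaranteed (pigeonhole) to hit every valid core."""
        m = self.max_internal_mismatch
        return -(-(self.min_core - m) // (m + 1))


@dataclass(frozen=True)
class Event:
    """One modification event in end-anchored coordinates."""

    end: str  # '5p' | '3p'
    position: int  # -4..+4
    kind: str  # 'addition' | 'substitution'
    nucleotide: str
    run: str = "-"  # 'mono' | 'poly' for additions
    run_start: bool = False


@dataclass
class IsomiRCall:
    read_id: str
    mirna_id: str
    offset5: int  # positive: read extends outward past the canonical 5' end
    core: tuple[int, int]  # first/last matched canonical positions (0-based)
    events: list[Event]
    ambiguous: bool = False

    @property
    def modified(self) -> bool:
        return bool(self.events)


@dataclass
class Unaligned:
    read_id: str
    reason: str  # 'no_candidate' | 'core_too_short' | 'tail_too_long' | 'alphabet' | ...


@dataclass
class SeedIndex:
    """Exact k-mer lookup from reference subsequences to (mirna_id, offset)."""

    seed_length: int
    seeds: dict[str, list[tuple[str, int]]]
    short_refs: list[str] = field(default_factory=list)


def build_index(
    references: Sequence[MiRNAReference], seed_length: int = 7
) -> SeedIndex:
    """Index every ``seed_length``-mer of every reference.

    References shorter than the seed length are indexed by their full
    sequence (with a warning) and additionally tracked so candidate
    generation can still reach them.
    """
    if not references:
        raise ValueError("empty reference collection")
    check_unique_ids(references)
    seeds: dict[str, list[tuple[str, int]]] = {}
    short: list[str] = []
    for ref in references:
        seq = ref.sequence
        if len(seq) < seed_length:
            warnings.warn(
                f"{ref.mirna_id} shorter than seed length {seed_length}; "
                "indexed by full sequence"
            )
            seeds.setdefault(seq, []).append((ref.mirna_id, 0))
            short.append(ref.mirna_id)
            continue
        for off in range(len(seq) - seed_length + 1):
            seeds.setdefault(seq[off:off + seed_length], []).append(
                (ref.mirna_id, off)
            )
    return SeedIndex(seed_length, seeds, short)


# ---------------------------------------------------------------------------
# decomposition of one read against one (reference, shift)
# ---------------------------------------------------------------------------

def _candidate_cores(read: str, canon: str, shift: int, params: IsomiRParams):
    """Yield valid cores ``(r1, r2, n_mismatch)`` in read coordinates.

    ``shift`` is the canonical index aligned with read position 0.  Cores are
    maximal unions of match-runs joined across substitution gaps.
    """
    n, L = len(read), len(canon)
    r_lo = max(0, -shift)
    r_hi = min(n, L - shift)  # exclusive
    if r_hi - r_lo <= 0:
        return
    # maximal runs of template matches within the aligned window
    runs: list[tuple[int, int]] = []
    r = r_lo
    while r < r_hi:
        if read[r] == canon[r + shift]:
            start = r
            while r < r_hi and read[r] == canon[r + shift]:
                r += 1
            runs.append((start, r - 1))
        else:
            r += 1
    max_mm = params.max_internal_mismatch
    for i in range(len(runs)):
        for j in range(i, len(runs)):
            core_runs = runs[i:j + 1]
            n_mm = sum(
                core_runs[k + 1][0] - core_runs[k][1] - 1
                for k in range(len(core_runs) - 1)
            )
            if n_mm > max_mm:
                break
            if j > i:
                # every substitution needs >= 2 templated matches 3'-ward of
                # it within the core; check each gap against the runs after it
                valid = True
                downstream = 0
                for k in range(len(core_runs) - 1, 0, -1):
                    downstream += core_runs[k][1] - core_runs[k][0] + 1
                    if downstream < 2:
                        valid = False
                        break
                if not valid:
                    continue
            yield core_runs[0][0], core_runs[-1][1], n_mm


_OBJ_INF = (10 ** 9,)


def _evaluate_candidate(read: str, canon: str, shift: int, params: IsomiRParams):
    """Best decomposition of ``read`` vs ``canon`` at ``shift``, or None.

    Returns ``(key, detail)`` where ``key`` orders decompositions by the
    global objective (smaller is better) and ``detail`` carries what is
    needed to emit events.
    """
    best = None
    for r1, r2, n_mm in _candidate_cores(read, canon, shift, params):
        core_len = r2 - r1 + 1
        if core_len < params.min_core:
            continue
        tail5, tail3 = r1, len(read) - 1 - r2
        if tail5 > params.max_tail or tail3 > params.max_tail:
            continue
        non_templated = tail5 + tail3 + n_mm
        key = (-core_len, non_templated, abs(shift), shift, r1)
        if best is None or key < best[0]:
            best = (key, (r1, r2, n_mm))
    return best


def _emit_events(read: str, canon: str, shift: int, r1: int, r2: int) -> list[Event]:
    L = len(canon)
    events: list[Event] = []
    # 5' tail: innermost base (r1-1) is the run start; positions -c in the
    # 5' frame where c is the canonical-frame index of the base
    tail5_len = r1
    for r in range(r1 - 1, -1, -1):
        pos = -(r + shift)
        if -REPORT_WINDOW <= pos <= REPORT_WINDOW:
            events.append(Event(
                end="5p", position=pos, kind="addition", nucleotide=read[r],
                run="mono" if tail5_len == 1 else "poly",
                run_start=(r == r1 - 1),
            ))
    # substitutions inside the core
    for r in range(r1, r2 + 1):
        c = r + shift
        if read[r] == canon[c]:
            continue
        dist3, dist5 = L - 1 - c, c
        if dist3 <= REPORT_WINDOW:
            events.append(Event("3p", c - (L - 1), "substitution", read[r]))
        elif dist5 <= REPORT_WINDOW:
            events.append(Event("5p", -c, "substitution", read[r]))
        # interior mismatches outside both windows are tolerated, unreported
    # 3' tail: innermost base (r2+1) is the run start
    tail3_len = len(read) - 1 - r2
    for r in range(r2 + 1, len(read)):
        pos = (r + shift) - (L - 1)
        if -REPORT_WINDOW <= pos <= REPORT_WINDOW:
            events.append(Event(
                end="3p", position=pos, kind="addition", nucleotide=read[r],
                run="mono" if tail3_len == 1 else "poly",
                run_start=(r == r2 + 1),
            ))
    return events


def _candidate_pairs(
    read: str, index: SeedIndex, refs_by_id: Mapping[str, str],
    params: IsomiRParams,
) -> set[tuple[str, int]]:
    n = len(read)
    k = index.seed_length
    cands: set[tuple[str, int]] = set()
    for r in range(0, n - k + 1):
        for mid, off in index.seeds.get(read[r:r + k], ()):
            shift = off - r
            if abs(shift) <= params.max_offset5:
                cands.add((mid, shift))
    for mid in index.short_refs:
        for shift in range(-params.max_offset5, params.max_offset5 + 1):
            cands.add((mid, shift))
    return cands


def classify_read(
    read: str,
    references: Sequence[MiRNAReference] | Mapping[str, str],
    index: SeedIndex,
    params: IsomiRParams = IsomiRParams(),
    read_id: str = "read",
) -> IsomiRCall | Unaligned:
    """Assign one read to a canonical miRNA and call its modifications."""
    if isinstance(references, Mapping):
        refs_by_id = references
    else:
        refs_by_id = {ref.mirna_id: ref.sequence for ref in references}
    read = read.upper().replace("T", "U")
    if len(read) < 16:
        return Unaligned(read_id, "too_short")
    if set(read) - set(RNA_ALPHABET):
        return Unaligned(read_id, "alphabet")
    if index.seed_length > params.max_safe_seed_length():
        warnings.warn(
            f"seed length {index.seed_length} exceeds the completeness bound "
            f"{params.max_safe_seed_length()} for min_core={params.min_core}, "
            f"max_internal_mismatch={params.max_internal_mismatch}; "
            "some valid assignments may be missed"
        )

    best_key = None
    best = None  # (mirna_id, shift, r1, r2)
    tied_mids: set[str] = set()
    for mid, shift in sorted(_candidate_pairs(read, index, refs_by_id, params)):
        res = _evaluate_candidate(read, refs_by_id[mid], shift, params)
        if res is None:
            continue
        (neg_core, non_templated, abs_shift, _shift, _r1), (r1, r2, n_mm) = res
        key = (neg_core, non_templated, abs_shift, mid, shift, r1)
        if best_key is None or key[:3] < best_key[:3]:
            tied_mids = {mid}
        elif key[:3] == best_key[:3]:
            tied_mids.add(mid)
        if best_key is None or key < best_key:
            best_key, best = key, (mid, shift, r1, r2)
    ambiguous = len(tied_mids) > 1
    if best is None:
        # distinguish the two dominant failure modes for reporting
        if _candidate_pairs(read, index, refs_by_id, params):
            return Unaligned(read_id, "no_valid_core")
        return Unaligned(read_id, "no_candidate")

    mid, shift, r1, r2 = best
    canon = refs_by_id[mid]
    events = _emit_events(read, canon, shift, r1, r2)
    return IsomiRCall(
        read_id=read_id,
        mirna_id=mid,
        offset5=-shift,
        core=(r1 + shift, r2 + shift),
        events=events,
        ambiguous=ambiguous,
    )


# ---------------------------------------------------------------------------
# per-sample profiling
# ---------------------------------------------------------------------------

ProfileKey = tuple[str, str, int, str, str, str]  # mirna, end, pos, nt, kind, run


@dataclass
class ModificationProfile:
    """Per-sample event counts by (miRNA, end, position, nucleotide, kind, run)."""

    sample_id: str
    counts: dict[ProfileKey, int] = field(default_factory=dict)
    total_assigned: int = 0
    n_unaligned: int = 0
    assigned_per_mirna: dict[str, int] = field(default_factory=dict)
    # per-miRNA counts of reads with >= 1 event, overall and per end
    modified_per_mirna: dict[str, dict[str, int]] = field(default_factory=dict)

    def add_call(self, call: IsomiRCall) -> None:
        self.total_assigned += 1
        self.assigned_per_mirna[call.mirna_id] = (
            self.assigned_per_mirna.get(call.mirna_id, 0) + 1
        )
        if call.events:
            rec = self.modified_per_mirna.setdefault(
                call.mirna_id, {"any": 0, "5p": 0, "3p": 0}
            )
            rec["any"] += 1
            for end in set(ev.end for ev in call.events):
                rec[end] += 1
        for ev in call.events:
            key = (call.mirna_id, ev.end, ev.position, ev.nucleotide,
                   ev.kind, ev.run)
            self.counts[key] = self.counts.get(key, 0) + 1

    def cpm(self, key: ProfileKey) -> float:
        if self.total_assigned == 0:
            return 0.0
        return self.counts.get(key, 0) * 1e6 / self.total_assigned

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": self.sample_id, "mirna_id": k[0], "end": k[1],
                "position": k[2], "nucleotide": k[3], "kind": k[4],
                "run": k[5], "count": v, "cpm": self.cpm(k),
            }
            for k, v in sorted(self.counts.items())
        ]
        cols = ["sample_id", "mirna_id", "end", "position", "nucleotide",
                "kind", "run", "count", "cpm"]
        return pd.DataFrame(rows, columns=cols)

    def mirna_stats_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mirna_id": mid,
                "assigned": n,
                "modified_any": self.modified_per_mirna.get(mid, {}).get("any", 0),
                "modified_5p": self.modified_per_mirna.get(mid, {}).get("5p", 0),
                "modified_3p": self.modified_per_mirna.get(mid, {}).get("3p", 0),
            }
            for mid, n in sorted(self.assigned_per_mirna.items())
        ]
        return pd.DataFrame(rows, columns=["mirna_id", "assigned",
                                           "modified_any", "modified_5p",
                                           "modified_3p"])

    def to_tsv(self, path: str | Path,
               mirna_stats_path: str | Path | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(f"#sample_id={self.sample_id}\n")
            fh.write(f"#total_assigned={self.total_assigned}\n")
            fh.write(f"#n_unaligned={self.n_unaligned}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)
        if mirna_stats_path is not None:
            self.mirna_stats_frame().to_csv(mirna_stats_path, sep="\t",
                                            index=False)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 mirna_stats: str | Path | None = None) -> "ModificationProfile":
        meta: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                k, _, v = line[1:].rstrip("\n").partition("=")
                meta[k] = v
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t")
        prof = cls(
            sample_id=meta.get("sample_id", ""),
            total_assigned=int(meta.get("total_assigned", 0)),
            n_unaligned=int(meta.get("n_unaligned", 0)),
        )
        for row in df.itertuples(index=False):
            key = (row.mirna_id, row.end, int(row.position), row.nucleotide,
                   row.kind, row.run)
            prof.counts[key] = int(row.count)
        if mirna_stats is not None:
            stats_df = pd.read_csv(mirna_stats, sep="\t")
            for row in stats_df.itertuples(index=False):
                prof.assigned_per_mirna[row.mirna_id] = int(row.assigned)
                prof.modified_per_mirna[row.mirna_id] = {
                    "any": int(row.modified_any),
                    "5p": int(row.modified_5p),
                    "3p": int(row.modified_3p),
                }
        return prof

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModificationProfile):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.counts == other.counts
            and self.total_assigned == other.total_assigned
            and self.n_unaligned == other.n_unaligned
            and self.assigned_per_mirna == other.assigned_per_mirna
            and {k: v for k, v in self.modified_per_mirna.items()
                 if v.get("any")}
            == {k: v for k, v in other.modified_per_mirna.items()
                if v.get("any")}
        )


def _iter_reads(reads) -> Iterator[tuple[str, str]]:
    if isinstance(reads, (str, Path)):
        with _open_maybe_gzip(reads) as fh:
            for read_id, seq, _qual in parse_fastq(fh):
                yield read_id, seq
    else:
        yield from reads


def profile_sample(
    reads,
    references: Sequence[MiRNAReference],
    index: SeedIndex | None = None,
    params: IsomiRParams = IsomiRParams(),
    sample_id: str = "sample",
    calls_out: list | None = None,
) -> tuple[ModificationProfile, pd.Series]:
    """Classify every read of a sample; returns (profile, per-miRNA counts).

    ``reads`` is an iterable of ``(read_id, sequence)`` or a FASTQ path.
    Classification is cached by read sequence, so duplicated reads (the
    common case in small RNA-seq) cost one decomposition.  ``calls_out``,
    if given, collects the per-read :class:`IsomiRCall`/:class:`Unaligned`
    records.
    """
    if index is None:
        index = build_index(references)
    refs_by_id = {r.mirna_id: r.sequence for r in references}
    profile = ModificationProfile(sample_id=sample_id)
    cache: dict[str, IsomiRCall | Unaligned] = {}
    for read_id, seq in _iter_reads(reads):
        res = cache.get(seq)
        if res is None:
            res = classify_read(seq, refs_by_id, index, params, read_id=read_id)
            cache[seq] = res
        if isinstance(res, IsomiRCall):
            call = IsomiRCall(read_id, res.mirna_id, res.offset5, res.core,
                              res.events, res.ambiguous)
            profile.add_call(call)
            if calls_out is not None:
                calls_out.append(call)
        else:
            profile.n_unaligned += 1
            if calls_out is not None:
                calls_out.append(Unaligned(read_id, res.reason))
    counts = pd.Series(
        {m: profile.assigned_per_mirna.get(m, 0) for m in refs_by_id},
        name=sample_id, dtype=int,
    )
    return profile, counts


def calls_to_frame(calls: Iterable[IsomiRCall | Unaligned]) -> pd.DataFrame:
    """Long-format per-read call table (one row per read)."""
    rows = []
    for c in calls:
        if isinstance(c, IsomiRCall):
            rows.append({
                "read_id": c.read_id, "mirna_id": c.mirna_id,
                "offset5": c.offset5, "core_first": c.core[0],
                "core_last": c.core[1], "n_events": len(c.events),
                "modified": int(c.modified), "ambiguous": int(c.ambiguous),
                "status": "assigned",
            })
        else:
            rows.append({
                "read_id": c.read_id, "mirna_id": "", "offset5": 0,
                "core_first": -1, "core_last": -1, "n_events": 0,
                "modified": 0, "ambiguous": 0, "status": c.reason,
            })
    return pd.DataFrame(rows)
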