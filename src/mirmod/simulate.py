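"""Ground-truth small RNA-seq simulator.

Generates a toy canonical miRNA collection (optionally with a planted
EV-sorting motif) and per-sample FASTQ libraries whose reads carry known
5'/3' trimming, non-templated tails, sequencing errors and adapter
read-through, together with full truth tables.  Every downstream stage of
the pipeline is testable against these tables.

The default generative settings emulate the study design the package was
built around: five donors, three compartments (resting NK cells, activated
NK cells, NK-derived EVs), log-normal miRNA abundance with EV-enrichment
effects planted on a subset of miRNAs, compartment-specific 3' addition
rates (cytosine most frequent, mono-additions dominating poly-additions),
5' rates one tenth of the 3' rates, and a sorting motif planted in the
EV-enriched miRNAs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

RNA_ALPHABET = "ACGU"
COMPARTMENTS = ("resting", "activated", "EV")

#: default Illumina small-RNA 3' adapter (NEB small RNA kit prefix)
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"


def _validate_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class MiRNAReference:
    """A canonical mature miRNA: the coordinate frame for modification calls."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.mirna_id}: empty sequence")
        bad = set(self.sequence) - set(RNA_ALPHABET)
        if bad:
            raise ValueError(
                f"{self.mirna_id}: non-RNA characters {sorted(bad)} in sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def check_unique_ids(references: Sequence[MiRNAReference]) -> None:
    ids = [r.mirna_id for r in references]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate miRNA IDs: {dup}")


def write_fasta(references: Iterable[MiRNAReference], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ref in references:
            fh.write(f">{ref.mirna_id}\n{ref.sequence}\n")


def read_fasta(path: str | Path) -> list[MiRNAReference]:
    """Load a mature-miRNA FASTA; T is read as U (sequences stored as RNA)."""
    from Bio import SeqIO

    refs = [
        MiRNAReference(rec.id, str(rec.seq).upper().replace("T", "U"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    check_unique_ids(refs)
    return refs


@dataclass
class PtmRates:
    """Per-end modification rates for one compartment.

    p_trim
        probability a read is trimmed at this end; the number of removed
        bases is geometric (support >= 1, success prob ``trim_geometric_p``).
    p_add
        probability a non-templated tail is appended at this end.
    p_mono_given_add
        probability the tail has length 1; otherwise length is
        2 + extra, extra geometric-1 with success prob
        ``poly_extra_geometric_p``.
    addition_nucleotide_probs
        mapping A/C/G/U -> probability, i.i.d. per tail base.  A tail whose
        first base would re-create the canonical base it replaces is
        redrawn, so tails are non-templated by construction.
    """

    p_trim: float
    trim_geometric_p: float
    p_add: float
    p_mono_given_add: float
    addition_nucleotide_probs: dict[str, float]
    poly_extra_geometric_p: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_trim", "trim_geometric_p", "p_add",
                     "p_mono_given_add", "poly_extra_geometric_p"):
            _validate_prob(name, getattr(self, name))
        probs = self.addition_nucleotide_probs
        if set(probs) != set(RNA_ALPHABET):
            raise ValueError(
                f"addition_nucleotide_probs keys must be {set(RNA_ALPHABET)}"
            )
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"addition_nucleotide_probs sums to {total}, not 1")
        for nt, p in probs.items():
            _validate_prob(f"addition_nucleotide_probs[{nt}]", p)

    def scaled(self, factor: float) -> "PtmRates":
        """Rates with trim/add probabilities multiplied by ``factor``."""
        return dataclasses.replace(
            self, p_trim=self.p_trim * factor, p_add=self.p_add * factor
        )


@dataclass
class SimTruth:
    """Full generative parameter record of a synthetic experiment."""

    seed: int
    n_mirnas: int
    baseline_log_expression: dict[str, float]
    group_log2fc: dict[str, dict[str, float]]  # mirna -> compartment -> log2FC
    ptm_rates: dict[str, dict[str, PtmRates]]  # compartment -> end(3p/5p) -> rates
    seq_error_rate: float
    adapter: str
    planted_motif: str
    motif_carrier_ids: set[str] = field(default_factory=set)
    design: list[tuple[str, str, str]] = field(default_factory=list)
    donor_log_offsets: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate_prob("seq_error_rate", self.seq_error_rate)
        sample_ids = [s for s, _, _ in self.design]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample IDs in design must be unique")

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        obj = dataclasses.asdict(self)
        obj["motif_carrier_ids"] = sorted(self.motif_carrier_ids)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            obj = json.load(fh)
        obj["motif_carrier_ids"] = set(obj["motif_carrier_ids"])
        obj["design"] = [tuple(row) for row in obj["design"]]
        obj["ptm_rates"] = {
            comp: {end: PtmRates(**rates) for end, rates in ends.items()}
            for comp, ends in obj["ptm_rates"].items()
        }
        return cls(**obj)


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def generate_reference(
    n_mirnas: int,
    length_range: tuple[int, int] = (20, 23),
    motif_spec: Mapping[str, object] | None = None,
    seed: int = 0,
) -> tuple[list[MiRNAReference], dict]:
    """Generate a toy canonical miRNA collection.

    ``motif_spec`` is ``{"motif": str, "n_carriers": int}``; exactly
    ``n_carriers`` sequences contain the motif as a contiguous substring and
    all others are guaranteed motif-free.  Returns the collection and a
    truth fragment (seed, motif, carrier IDs).
    """
    lo, hi = length_range
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    if lo < 8:
        raise ValueError("minimum reference length must be >= 8")
    if lo > hi:
        raise ValueError("length_range must satisfy min <= max")

    motif = ""
    n_carriers = 0
    if motif_spec:
        motif = str(motif_spec["motif"]).upper().replace("T", "U")
        n_carriers = int(motif_spec["n_carriers"])
        if set(motif) - set(RNA_ALPHABET):
            raise ValueError(f"motif {motif!r} is not an RNA string")
        if len(motif) >= lo:
            raise ValueError(
                f"motif length {len(motif)} must be < minimum reference length {lo}"
            )
        if n_carriers > n_mirnas:
            raise ValueError("n_carriers cannot exceed n_mirnas")

    rng = np.random.default_rng(seed)
    nucs = np.array(list(RNA_ALPHABET))
    width = len(str(n_mirnas))
    refs: list[MiRNAReference] = []
    seen: set[str] = set()
    for i in range(n_mirnas):
        carrier = i < n_carriers
        for _attempt in range(10_000):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(nucs, size=length))
            if carrier:
                pos = int(rng.integers(0, length - len(motif) + 1))
                seq = seq[:pos] + motif + seq[pos + len(motif):]
            if motif and not carrier and motif in seq:
                continue
            if seq not in seen:
                seen.add(seq)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not construct a unique sequence")
        refs.append(MiRNAReference(f"syn-mir-{i + 1:0{width}d}", seq))

    carriers = {r.mirna_id for r in refs[:n_carriers]} if motif else set()
    fragment = {
        "seed": seed,
        "n_mirnas": n_mirnas,
        "planted_motif": motif,
        "motif_carrier_ids": carriers,
    }
    return refs, fragment


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

def default_design(n_donors: int = 5) -> list[tuple[str, str, str]]:
    """5 donors x 3 compartments; sample IDs ``<compartment>_D<k>``."""
    return [
        (f"{comp}_D{d}", comp, f"D{d}")
        for comp in COMPARTMENTS
        for d in range(1, n_donors + 1)
    ]


def default_ptm_rates() -> dict[str, dict[str, PtmRates]]:
    """Compartment-specific 3' rates; 5' rates are the 3' rates / 10.

    Cytosine is the most frequent addition, adenine second; EVs tail more
    than their secreting cells, and activation lowers the addition rate —
    the qualitative ordering the pipeline is meant to recover.
    """
    probs = {
        "resting": {"A": 0.30, "C": 0.45, "G": 0.10, "U": 0.15},
        "activated": {"A": 0.25, "C": 0.45, "G": 0.10, "U": 0.20},
        "EV": {"A": 0.30, "C": 0.50, "G": 0.05, "U": 0.15},
    }
    p_add = {"resting": 0.10, "activated": 0.08, "EV": 0.16}
    out: dict[str, dict[str, PtmRates]] = {}
    for comp in COMPARTMENTS:
        three_p = PtmRates(
            p_trim=0.15,
            trim_geometric_p=0.5,
            p_add=p_add[comp],
            p_mono_given_add=0.9,
            addition_nucleotide_probs=probs[comp],
        )
        out[comp] = {"3p": three_p, "5p": three_p.scaled(0.1)}
    return out


def default_truth(
    references: Sequence[MiRNAReference],
    seed: int,
    fragment: Mapping[str, object] | None = None,
    n_donors: int = 5,
    ev_enriched_fraction: float = 0.2,
    ev_log2fc: float = 3.0,
    activation_fraction: float = 0.1,
    activation_log2fc: float = 2.0,
    baseline_sd: float = 1.5,
    donor_sd: float = 0.2,
    seq_error_rate: float = 0.001,
    adapter: str = DEFAULT_ADAPTER,
) -> SimTruth:
    """Assemble a SimTruth with the default study conditions.

    ``activated`` is the reference compartment (log2FC 0 everywhere).  If a
    motif was planted (``fragment``), the EV-enriched set is the carrier set,
    so the sorting motif travels with EV enrichment.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11CE]))
    ids = [r.mirna_id for r in references]
    n = len(ids)
    baseline = {
        mid: float(v) for mid, v in zip(ids, rng.normal(0.0, baseline_sd, n))
    }

    fragment = fragment or {}
    carriers = set(fragment.get("motif_carrier_ids", set()))
    if carriers:
        ev_ids = sorted(carriers)
    else:
        n_ev = max(1, round(ev_enriched_fraction * n))
        ev_ids = sorted(rng.choice(ids, size=n_ev, replace=False).tolist())
    n_act = max(1, round(activation_fraction * n))
    act_ids = rng.choice(ids, size=n_act, replace=False).tolist()

    group_log2fc: dict[str, dict[str, float]] = {
        mid: {comp: 0.0 for comp in COMPARTMENTS} for mid in ids
    }
    for mid in ev_ids:
        group_log2fc[mid]["EV"] = ev_log2fc
    for mid in act_ids:
        group_log2fc[mid]["resting"] = float(
            rng.choice([-activation_log2fc, activation_log2fc])
        )

    design = default_design(n_donors)
    donors = sorted({d for _, _, d in design})
    donor_log_offsets = {
        d: {mid: float(v) for mid, v in zip(ids, rng.normal(0.0, donor_sd, n))}
        for d in donors
    }

    return SimTruth(
        seed=seed,
        n_mirnas=n,
        baseline_log_expression=baseline,
        group_log2fc=group_log2fc,
        ptm_rates=default_ptm_rates(),
        seq_error_rate=seq_error_rate,
        adapter=adapter.upper(),
        planted_motif=str(fragment.get("planted_motif", "")),
        motif_carrier_ids=carriers,
        design=design,
        donor_log_offsets=donor_log_offsets,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

_LN2 = float(np.log(2.0))


def _draw_tail(rng: np.random.Generator, rates: PtmRates,
               forbidden_first: str | None) -> str:
    nucs = list(RNA_ALPHABET)
    p = [rates.addition_nucleotide_probs[nt] for nt in nucs]
    while True:
        if rng.random() < rates.p_mono_given_add:
            length = 1
        else:
            length = 2 + int(rng.geometric(rates.poly_extra_geometric_p)) - 1
        tail = "".join(rng.choice(nucs, size=length, p=p))
        if forbidden_first is None or tail[0] != forbidden_first:
            return tail


def _mutate_read(seq: str, rng: np.random.Generator, error_rate: float) -> tuple[str, int]:
    if error_rate <= 0:
        return seq, 0
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    if hits.size == 0:
        return seq, 0
    chars = list(seq)
    for i in hits:
        others = [nt for nt in RNA_ALPHABET if nt != chars[i]]
        chars[i] = others[int(rng.integers(3))]
    return "".join(chars), int(hits.size)


@dataclass
class SimOutput:
    """Paths written by :func:`simulate_experiment`."""

    fastq_paths: dict[str, Path]
    reference_fasta: Path
    truth_reads: Path
    truth_counts: Path
    truth_json: Path


def simulate_read(
    canonical: str,
    rates3: PtmRates,
    rates5: PtmRates,
    seq_error_rate: float,
    rng: np.random.Generator,
) -> dict:
    """Apply the per-read generative model to one canonical sequence.

    Returns the insert sequence plus the true event record (trim lengths,
    tails, number of substitution errors).  Trims are clipped so at least 10
    canonical bases survive.
    """
    n = len(canonical)
    trim5 = trim3 = 0
    if rng.random() < rates5.p_trim:
        trim5 = int(rng.geometric(rates5.trim_geometric_p))
    if rng.random() < rates3.p_trim:
        trim3 = int(rng.geometric(rates3.trim_geometric_p))
    # keep a classifiable core
    while n - trim5 - trim3 < 10:
        if trim3 >= trim5 and trim3 > 0:
            trim3 -= 1
        elif trim5 > 0:
            trim5 -= 1
        else:  # pragma: no cover
            break
    core = canonical[trim5: n - trim3] if trim3 else canonical[trim5:]

    tail5 = tail3 = ""
    if rng.random() < rates5.p_add:
        forbidden = canonical[trim5 - 1] if trim5 > 0 else None
        tail5 = _draw_tail(rng, rates5, forbidden)
    if rng.random() < rates3.p_add:
        forbidden = canonical[n - trim3] if trim3 > 0 else None
        tail3 = _draw_tail(rng, rates3, forbidden)

    insert = tail5 + core + tail3
    insert, n_errors = _mutate_read(insert, rng, seq_error_rate)
    return {
        "insert": insert,
        "trim5": trim5,
        "trim3": trim3,
        "tail5": tail5,
        "tail3": tail3,
        "n_errors": n_errors,
    }


def simulate_experiment(
    references: Sequence[MiRNAReference],
    truth: SimTruth,
    reads_per_sample: int,
    outdir: str | Path,
    fixed_length: int | None = None,
) -> SimOutput:
    """Write one FASTQ per design sample plus ground-truth tables.

    Reads are emitted as DNA (U -> T) with constant 'I' qualities and the
    3' adapter appended.  ``fixed_length`` pads (cycling the adapter) or
    truncates every record to that length; the default emits variable-length
    records (insert + adapter).  Fully deterministic given ``truth.seed``.
    """
    if reads_per_sample < 1:
        raise ValueError("reads_per_sample must be >= 1")
    if not references:
        raise ValueError("empty reference collection")
    if not truth.design:
        raise ValueError("empty design")
    check_unique_ids(references)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref_by_id = {r.mirna_id: r.sequence for r in references}
    ids = [r.mirna_id for r in references]

    root_ss = np.random.SeedSequence([truth.seed, 0x5EED])
    children = root_ss.spawn(len(truth.design))

    fastq_paths: dict[str, Path] = {}
    reads_rows: list[str] = []
    counts_rows: list[str] = []

    for (sample_id, compartment, donor), ss in zip(truth.design, children):
        rng = np.random.default_rng(ss)
        offsets = truth.donor_log_offsets.get(donor, {})
        logw = np.array([
            truth.baseline_log_expression[m]
            + _LN2 * truth.group_log2fc[m].get(compartment, 0.0)
            + offsets.get(m, 0.0)
            for m in ids
        ])
        p = np.exp(logw - logw.max())
        p /= p.sum()
        sources = rng.choice(len(ids), size=reads_per_sample, p=p)

        rates3 = truth.ptm_rates[compartment]["3p"]
        rates5 = truth.ptm_rates[compartment]["5p"]
        path = outdir / f"{sample_id}.fastq"
        fastq_paths[sample_id] = path
        src_counts = np.zeros(len(ids), dtype=int)
        with open(path, "w") as fh:
            for i, src in enumerate(sources):
                mid = ids[src]
                src_counts[src] += 1
                rec = simulate_read(
                    ref_by_id[mid], rates3, rates5, truth.seq_error_rate, rng
                )
                seq = rec["insert"] + truth.adapter
                if fixed_length is not None:
                    while len(seq) < fixed_length:
                        seq += truth.adapter
                    seq = seq[:fixed_length]
                dna = seq.replace("U", "T")
                read_id = f"{sample_id}.{i}"
                fh.write(f"@{read_id}\n{dna}\n+\n{'I' * len(dna)}\n")
                modified = int(bool(rec["tail5"] or rec["tail3"]
                                    or rec["n_errors"]))
                reads_rows.append(
                    "\t".join(map(str, (
                        sample_id, read_id, mid, rec["trim5"], rec["trim3"],
                        rec["tail5"], rec["tail3"], rec["n_errors"],
                        len(rec["insert"]), modified,
                    )))
                )
        for j, mid in enumerate(ids):
            counts_rows.append(
                f"{sample_id}\t{mid}\t{p[j]:.10g}\t{src_counts[j]}"
            )

    ref_fa = outdir / "reference.fasta"
    write_fasta(references, ref_fa)
    truth_reads = outdir / "truth_reads.tsv"
    with open(truth_reads, "w") as fh:
        fh.write("sample_id\tread_id\tmirna_id\ttrim5\ttrim3\ttail5\ttail3\t"
                 "n_errors\tinsert_length\tmodified\n")
        fh.write("\n".join(reads_rows) + "\n")
    truth_counts = outdir / "truth_counts.tsv"
    with open(truth_counts, "w") as fh:
        fh.write("sample_id\tmirna_id\texpected_proportion\ttrue_count\n")
        fh.write("\n".join(counts_rows) + "\n")
    truth_json = outdir / "sim_truth.json"
    truth.to_json(truth_json)

    return SimOutput(fastq_paths, ref_fa, truth_reads, truth_counts, truth_json)


# ---------------------------------------------------------------------------
# count-matrix level simulation (for DE calibration/power studies)
# ---------------------------------------------------------------------------

def simulate_counts(
    n_features: int,
    n_per_group: tuple[int, int],
    seed: int,
    lib_size: int = 1_000_000,
    baseline_sd: float = 1.5,
    bio_sd: float = 0.3,
    planted_log2fc: float = 0.0,
    planted_fraction: float = 0.0,
):
    """Two-group count matrix with log-normal abundance and Poisson sampling.

    Returns ``(counts DataFrame, labels list, planted feature index)``.
    ``planted_log2fc`` is applied to the first ``planted_fraction`` of the
    features in group B; zero fraction gives a null experiment.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_a, n_b = n_per_group
    base = rng.normal(0.0, baseline_sd, n_features)
    n_planted = round(planted_fraction * n_features)
    lfc = np.zeros(n_features)
    lfc[:n_planted] = planted_log2fc

    cols = {}
    labels = []
    for j in range(n_a + n_b):
        grp = "A" if j < n_a else "B"
        labels.append(grp)
        eta = base + rng.normal(0.0, bio_sd, n_features)
        if grp == "B":
            eta = eta + _LN2 * lfc
        p = np.exp(eta - eta.max())
        p /= p.sum()
        cols[f"{grp}{j + 1}"] = rng.poisson(lib_size * p)
    features = [f"feat{i + 1}" for i in range(n_features)]
    counts = pd.DataFrame(cols, index=features)
    planted = features[:n_planted]
    return counts, labels, planted
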