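"""End-to-end pipeline: simulate/load -> preprocess -> profile -> DE ->
PtM statistics -> motif enrichment -> report.

A single YAML config drives every stage; all randomness flows through one
seed.  Each run directory receives the stage outputs, a human-readable
summary (``report.json``) and a machine-readable ``manifest.json`` with
parameter values and SHA-256 hashes of every written file, so identical
config + seed yields identical manifests.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from mirmod import __version__, de, motifs, ptm, preprocess
from mirmod.profiler import IsomiRParams, build_index, profile_sample
from mirmod.simulate import (
    MiRNAReference,
    default_truth,
    generate_reference,
    read_fasta,
    simulate_experiment,
)

log = logging.getLogger("mirmod")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "reference": None,  # FASTA path for real data runs
    "fastq": None,      # {sample_id: path} for real data runs
    "design": None,     # TSV path (sample_id, compartment, donor)
    "simulate": {
        "n_mirnas": 50,
        "length_range": [20, 23],
        "motif": None,  # {"motif": str, "n_carriers": int}
        "reads_per_sample": 5000,
        "n_donors": 5,
        "ev_enriched_fraction": 0.2,
        "ev_log2fc": 3.0,
    },
    "preprocess": {
        "adapter": None,  # defaults to the simulated adapter
        "min_length": 20,
        "max_error_rate": 0.1,
        "min_overlap": 3,
    },
    "profile": {
        "seed_length": 7,
        "max_offset5": 4,
        "max_internal_mismatch": 1,
        "min_core": 14,
        "max_tail": 8,
        "write_calls": False,
    },
    "de": {
        "min_cpm": 1.0,
        "min_samples": 3,
        "alpha": 0.05,
        "lfc": 2.0,
        "contrasts": [["activated", "EV"], ["resting", "activated"]],
        "block_donor": False,
    },
    "ptm": {
        "min_reads": 10,
        "top_n": 30,
        "positions": [-1, 0, 1],
        "end": "3p",
    },
    "motifs": {
        "identity_threshold": 0.8,
        "k_min": 4,
        "k_max": 8,
        "e_threshold": 0.2,
        "exclude_foreground": False,
    },
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict:
    """Merge a YAML config over the defaults; unknown keys are rejected."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    if overrides:
        user = _merge(user, dict(overrides))
    return _merge_validated(cfg, user, trail="")


def _merge(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _merge_validated(defaults: dict, user: dict, trail: str) -> dict:
    out = copy.deepcopy(defaults)
    for k, v in user.items():
        if k not in defaults:
            raise ConfigError(f"unknown config key: {trail}{k}")
        if isinstance(defaults[k], dict) and defaults[k] and isinstance(v, dict) \
                and k not in ("motif", "fastq"):
            out[k] = _merge_validated(defaults[k], v, trail=f"{trail}{k}.")
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Accumulates stage outputs and writes the manifest/report."""

    def __init__(self, outdir: Path, config: dict):
        self.outdir = outdir
        self.config = config
        self.stages: list[str] = []
        self.files: dict[str, str] = {}
        self.report: dict[str, Any] = {}

    def register(self, stage: str, *paths: Path) -> None:
        if stage not in self.stages:
            self.stages.append(stage)
        for p in paths:
            self.files[str(p.relative_to(self.outdir))] = _sha256(p)

    def finalise(self) -> Path:
        report_path = self.outdir / "report.json"
        with open(report_path, "w") as fh:
            json.dump(self.report, fh, indent=1, sort_keys=True, default=str)
        self.register("report", report_path)
        manifest = {
            "package_version": __version__,
            "config": self.config,
            "stages": self.stages,
            "files": dict(sorted(self.files.items())),
        }
        manifest_path = self.outdir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest_path


def _stage(name: str):
    log.info("stage %s started", name)
    return time.time()


def run_pipeline(config: dict, outdir: str | Path, seed: int | None = None) -> Path:
    """Run every stage; returns the run directory.

    Raises with the stage name on any failure.  ``seed`` overrides the
    config seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = _merge(config, {"seed": int(seed)})
    run = PipelineRun(outdir, config)
    stage = "configure"
    try:
        # ------------------------------------------------------------ inputs
        stage = "simulate"
        _stage(stage)
        sim_cfg = config["simulate"]
        if config["fastq"] is not None:
            refs = read_fasta(config["reference"])
            design_df = pd.read_csv(config["design"], sep="\t")
            design = [tuple(r) for r in design_df[
                ["sample_id", "compartment", "donor"]].itertuples(index=False)]
            fastq_paths = {s: Path(p) for s, p in config["fastq"].items()}
            adapter = config["preprocess"]["adapter"]
            if adapter is None:
                raise ConfigError("preprocess.adapter is required for real data")
            run.stages.append(stage)
        else:
            motif_spec = sim_cfg["motif"]
            refs, fragment = generate_reference(
                n_mirnas=sim_cfg["n_mirnas"],
                length_range=tuple(sim_cfg["length_range"]),
                motif_spec=motif_spec,
                seed=config["seed"],
            )
            truth = default_truth(
                refs, seed=config["seed"], fragment=fragment,
                n_donors=sim_cfg["n_donors"],
                ev_enriched_fraction=sim_cfg["ev_enriched_fraction"],
                ev_log2fc=sim_cfg["ev_log2fc"],
            )
            simdir = outdir / "simulated"
            out = simulate_experiment(
                refs, truth, sim_cfg["reads_per_sample"], simdir
            )
            fastq_paths = out.fastq_paths
            design = truth.design
            adapter = config["preprocess"]["adapter"] or truth.adapter
            run.register(stage, out.reference_fasta, out.truth_reads,
                         out.truth_counts, out.truth_json,
                         *out.fastq_paths.values())

        design_by_sample = {s: (comp, donor) for s, comp, donor in design}

        # -------------------------------------------------------- preprocess
        stage = "preprocess"
        _stage(stage)
        pp = config["preprocess"]
        trimdir = outdir / "trimmed"
        trimdir.mkdir(exist_ok=True)
        trim_reports = {}
        for sample_id, path in fastq_paths.items():
            out_fq = trimdir / f"{sample_id}.trimmed.fastq"
            rep = preprocess.preprocess_fastq(
                path, out_fq, adapter=adapter, min_length=pp["min_length"],
                max_error_rate=pp["max_error_rate"],
                min_overlap=pp["min_overlap"],
            )
            rep_path = trimdir / f"{sample_id}.trim_report.tsv"
            rep.to_tsv(rep_path)
            trim_reports[sample_id] = rep
            run.register(stage, out_fq, rep_path)
        run.report["trimming"] = {
            s: {"n_input": r.n_input, "n_retained": r.n_retained,
                "retained_fraction": round(r.retained_fraction, 6)}
            for s, r in trim_reports.items()
        }

        # ----------------------------------------------------------- profile
        stage = "profile"
        _stage(stage)
        pf = config["profile"]
        params = IsomiRParams(
            max_offset5=pf["max_offset5"],
            max_internal_mismatch=pf["max_internal_mismatch"],
            min_core=pf["min_core"],
            max_tail=pf["max_tail"],
        )
        index = build_index(refs, seed_length=pf["seed_length"])
        profdir = outdir / "profiles"
        profdir.mkdir(exist_ok=True)
        profiles = {}
        count_cols = {}
        for sample_id in fastq_paths:
            calls_out = [] if pf["write_calls"] else None
            prof, counts = profile_sample(
                trimdir / f"{sample_id}.trimmed.fastq", refs, index, params,
                sample_id=sample_id, calls_out=calls_out,
            )
            profiles[sample_id] = prof
            count_cols[sample_id] = counts
            ppath = profdir / f"{sample_id}.profile.tsv"
            spath = profdir / f"{sample_id}.mirna_stats.tsv"
            prof.to_tsv(ppath, mirna_stats_path=spath)
            run.register(stage, ppath, spath)
            if calls_out is not None:
                from mirmod.profiler import calls_to_frame
                cpath = profdir / f"{sample_id}.calls.tsv"
                calls_to_frame(calls_out).to_csv(cpath, sep="\t", index=False)
                run.register(stage, cpath)
        counts_df = pd.DataFrame(count_cols)
        counts_path = outdir / "counts.tsv"
        counts_df.to_csv(counts_path, sep="\t")
        run.register(stage, counts_path)
        total_reads = {s: trim_reports[s].n_retained for s in fastq_paths}
        run.report["alignment"] = {
            s: {
                "assigned": profiles[s].total_assigned,
                "unaligned": profiles[s].n_unaligned,
                "assigned_fraction": round(
                    profiles[s].total_assigned / max(1, total_reads[s]), 6
                ),
            }
            for s in fastq_paths
        }

        # ---------------------------------------------------------------- de
        stage = "de"
        _stage(stage)
        dcfg = config["de"]
        labels = [design_by_sample[s][0] for s in counts_df.columns]
        donors = [design_by_sample[s][1] for s in counts_df.columns]
        de_results = {}
        de_summary = {}
        for contrast in dcfg["contrasts"]:
            a, b = contrast
            res = de.differential_expression(
                counts_df, labels, contrast=(a, b),
                min_cpm=dcfg["min_cpm"], min_samples=dcfg["min_samples"],
                block=donors if dcfg["block_donor"] else None,
            )
            name = f"{a}_vs_{b}"
            de_results[name] = res
            de_path = outdir / f"de_{name}.tsv"
            res.to_csv(de_path, sep="\t")
            run.register(stage, de_path)
            up_b, up_a = de.select_enriched(res, alpha=dcfg["alpha"],
                                            lfc=dcfg["lfc"])
            de_summary[name] = {
                "n_tested": int(len(res)),
                f"enriched_in_{b}": sorted(up_b),
                f"enriched_in_{a}": sorted(up_a),
            }
        run.report["de"] = de_summary

        # --------------------------------------------------------------- ptm
        stage = "ptm"
        _stage(stage)
        pcfg = config["ptm"]
        act_samples = [s for s in counts_df.columns
                       if design_by_sample[s][0] == "activated"]
        top_expressed = ptm.top_sets(
            counts_df, "expressed", group=act_samples,
            n=min(pcfg["top_n"], counts_df.shape[0]),
        )
        ev_contrast = next(
            (f"{a}_vs_{b}" for a, b in dcfg["contrasts"] if b == "EV"), None
        )
        top_enriched = []
        if ev_contrast in de_results:
            top_enriched = ptm.top_sets(
                de_results[ev_contrast], "enriched", n=pcfg["top_n"],
                alpha=dcfg["alpha"],
            )
        frac_tables = {}
        for set_name, mset in (("top_expressed", top_expressed),
                               ("top_ev_enriched", top_enriched)):
            if not mset:
                continue
            tab = ptm.fraction_modified_from_profiles(
                profiles, min_reads=pcfg["min_reads"], mirna_set=mset,
            )
            tpath = outdir / f"fraction_modified_{set_name}.tsv"
            tab.to_csv(tpath, sep="\t", index=False)
            run.register(stage, tpath)
            frac_tables[set_name] = tab
        mono = ptm.positional_mono_fractions(
            profiles, positions=tuple(pcfg["positions"]), end=pcfg["end"],
        )
        mono_path = outdir / "positional_mono_fractions.tsv"
        mono.to_csv(mono_path, sep="\t", index=False)
        run.register(stage, mono_path)

        # donor-level summaries + tests
        ptm_report: dict[str, Any] = {
            "top_expressed_activated": top_expressed,
            "top_ev_enriched": top_enriched,
        }
        for set_name, tab in frac_tables.items():
            med = {}
            donor_means: dict[str, dict[str, float]] = {}
            ok = tab[~tab["excluded"]]
            for sample_id, sub in ok.groupby("sample_id"):
                comp, donor = design_by_sample[sample_id]
                med.setdefault(comp, []).extend(sub["fraction"].tolist())
                donor_means.setdefault(comp, {})[donor] = float(
                    sub["fraction"].mean()
                )
            ptm_report[f"median_fraction_{set_name}"] = {
                comp: (float(np.median(v)) if v else None)
                for comp, v in med.items()
            }
            comps = sorted(donor_means)
            if len(comps) >= 2:
                shared = sorted(
                    set.intersection(*(set(donor_means[c]) for c in comps))
                )
                if len(shared) >= 2:
                    groups = {
                        c: [donor_means[c][d] for d in shared] for c in comps
                    }
                    kw = ptm.compare_groups(groups, test="kruskal_wallis")
                    ptm_report[f"kruskal_wallis_{set_name}"] = {
                        "H": kw["statistic"], "p": kw["p"],
                    }
        run.report["ptm"] = ptm_report

        # ------------------------------------------------------------ motifs
        stage = "motifs"
        _stage(stage)
        mcfg = config["motifs"]
        ev_enriched_ids = []
        if ev_contrast in de_summary:
            ev_enriched_ids = de_summary[ev_contrast].get("enriched_in_EV", [])
        motif_rows = []
        if len(ev_enriched_ids) >= 2:
            seq_by_id = {r.mirna_id: r.sequence for r in refs}
            fg = [(m, seq_by_id[m]) for m in ev_enriched_ids]
            bg = [(r.mirna_id, r.sequence) for r in refs]
            fg_nr, _ = motifs.reduce_redundancy(
                fg, identity_threshold=mcfg["identity_threshold"]
            )
            bg_nr, _ = motifs.reduce_redundancy(
                bg, identity_threshold=mcfg["identity_threshold"]
            )
            hits = motifs.zoops_enrichment(
                fg_nr, bg_nr, k_min=mcfg["k_min"], k_max=mcfg["k_max"],
                e_threshold=mcfg["e_threshold"],
                exclude_foreground=mcfg["exclude_foreground"],
            )
            motif_rows = [dataclasses.asdict(h) for h in hits]
        motif_path = outdir / "motifs.tsv"
        pd.DataFrame(
            motif_rows, columns=["motif", "k", "fg_with", "fg_total",
                                 "bg_with", "bg_total", "p", "e_adj"],
        ).to_csv(motif_path, sep="\t", index=False)
        run.register(stage, motif_path)
        run.report["motifs"] = motif_rows

        return run.finalise().parent
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
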