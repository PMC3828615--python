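"""End-to-end orchestration: simulate -> quantify -> call -> evaluate ->
concordance, with a YAML-configurable, fully deterministic run.

All stochastic steps live in the synthetic generator; given the same config
(including seed) two runs produce byte-identical output files.  Outputs are
TSV/JSON only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .concordance import assessed_fraction, concordance_summary, direction_tally, report_to_json, write_report
from .diffexp import (
    Tier,
    calls_to_frame,
    load_array_signals,
    load_ssh_pairs,
    ma_differential,
    per_sample_ratios,
    ssh_differential,
    vote_classify,
)
from .evaluation import evaluate_markers, evaluations_to_tsv
from .marker_db import load_marker_catalogue, save_marker_catalogue
from .smallrna import (
    Condition,
    load_read_library,
    quantify_libraries,
    read_reference_fasta,
    write_fastq,
)
from .synthetic import (
    generate_truth,
    random_reference,
    render_reads,
    simulate_array_signals,
    simulate_count_libraries,
    simulate_ssh_pairs,
    truth_catalogue,
)
from .diffexp import save_array_signals, save_ssh_pairs


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class ReadInput:
    path: str
    sample: str
    condition: str


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Parameter defaults are the published thresholds: 16 nt minimum read
    length, 2 mismatches, cut-off tiers 2x/3x/4x, p < 0.01 and 1.5-fold for
    the microarray, a total of 10 normalized reads for SSH.
    """

    reference: str = ""
    catalogue: str = ""
    reads: list[ReadInput] = field(default_factory=list)
    pooled_normal: str = "normal_pool"
    ssh_pairs: str | None = None
    array_signals: str | None = None
    array_conditions: str | None = None
    adapter: str = "TCGTATGCCGTCTTCTGCTTG"
    min_len: int = 16
    max_mismatch: int = 2
    min_overlap: int = 6
    tiers: list[str] = field(default_factory=lambda: ["SOFT", "MEDIUM", "STRICT"])
    concordance_tier: str = "SOFT"
    p_threshold: float = 0.01
    min_fold: float = 1.5
    min_total: float = 10.0
    ssh_total_mode: str = "sum"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        reads = [ReadInput(**r) for r in data.pop("reads", [])]
        cfg = cls(**data)
        cfg.reads = reads
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapper

    return deco


@_stage("quantify")
def _quantify(config: RunConfig):
    reference = read_reference_fasta(config.reference)
    libraries = []
    for entry in config.reads:
        p = Path(entry.path)
        if not p.exists():
            raise FileNotFoundError(f"read library not found: {p}")
        libraries.append(load_read_library(p, entry.sample, Condition(entry.condition)))
    counts, results = quantify_libraries(
        libraries,
        reference,
        adapter=config.adapter,
        min_len=config.min_len,
        max_mismatch=config.max_mismatch,
        min_overlap=config.min_overlap,
    )
    return counts, results


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and write the report bundle into ``outdir``.

    Returns the summary dictionary that is also written to
    ``concordance_summary.json`` (augmented with tallies and the assessed
    fraction).  Raises PipelineError with a stage-named message on failure.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        catalogue = load_marker_catalogue(config.catalogue)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[catalogue] {exc}") from exc

    counts, quant_results = _quantify(config)
    counts.to_tsv(outdir / "counts_raw.tsv", outdir / "counts_rpm.tsv")

    tumor_ids = [r.sample for r in config.reads if Condition(r.condition) == Condition.TUMOR]
    tiers = [Tier[t] for t in config.tiers]

    try:
        profiles = per_sample_ratios(counts, tumor_ids, config.pooled_normal)
        ds_calls_by_tier = {
            tier: {
                m: c
                for m, c in (
                    (m, vote_classify(p, tier)) for m, p in profiles.items()
                )
                if c is not None
            }
            for tier in tiers
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[ds-call] {exc}") from exc

    ssh_calls = {}
    if config.ssh_pairs:
        try:
            for pair in load_ssh_pairs(config.ssh_pairs):
                call = ssh_differential(
                    pair,
                    min_total=config.min_total,
                    min_fold=config.min_fold,
                    total_mode=config.ssh_total_mode,
                )
                if call is not None:
                    ssh_calls[pair.mirna_id] = call
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"[ssh-call] {exc}") from exc

    ma_calls = {}
    if config.array_signals:
        try:
            table = load_array_signals(config.array_signals, config.array_conditions)
            ma_calls = ma_differential(
                table, p_threshold=config.p_threshold, min_fold=config.min_fold
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"[ma-call] {exc}") from exc

    frames = []
    for tier in tiers:
        frames.append(calls_to_frame(ds_calls_by_tier[tier]))
    if ssh_calls:
        frames.append(calls_to_frame(ssh_calls))
    if ma_calls:
        frames.append(calls_to_frame(ma_calls))
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "calls.tsv", sep="\t", index=False
    )

    try:
        evaluations = []
        for tier in tiers:
            evaluations.extend(evaluate_markers(catalogue, profiles, tier))
        evaluations_to_tsv(evaluations, outdir / "evaluations.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[evaluate] {exc}") from exc

    try:
        conc_tier = Tier[config.concordance_tier]
        calls_by_method = {"DS": ds_calls_by_tier[conc_tier]}
        if ssh_calls:
            calls_by_method["SSH"] = ssh_calls
        if ma_calls:
            calls_by_method["MA"] = ma_calls
        report = concordance_summary(calls_by_method, catalogue)
        write_report(
            report, outdir / "concordance_per_marker.tsv", outdir / "concordance_summary.json"
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[concordance] {exc}") from exc

    ds_primary = ds_calls_by_tier[conc_tier]
    n_up, n_down, n_mixed, n_neutral = direction_tally(list(ds_primary.values()))
    n_assessed, pct_assessed = assessed_fraction(catalogue, set(ds_primary))
    summary = report_to_json(report)
    summary["ds_direction_tally"] = {
        "up": n_up, "down": n_down, "mixed": n_mixed, "neutral": n_neutral
    }
    summary["catalogue_assessed"] = {
        "n": n_assessed, "percent": round(pct_assessed, 1)
    }
    summary["quantification"] = {
        sid: {k: round(v, 3) for k, v in sorted(res.stats.items())}
        for sid, res in sorted(quant_results.items())
    }
    (outdir / "concordance_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    manifest = {
        "tool": "mirmarker",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary


def simulate_inputs(
    outdir: str | Path,
    seed: int = 0,
    n_mirna: int = 100,
    read_depth: float = 5000,
    count_depth: float = 1e5,
    n_tumor: int = 9,
    n_normal_members: int = 6,
    dispersion: float = 0.05,
    error_rate: float = 0.005,
    n_ma_tumor: int = 8,
    n_ma_normal: int = 4,
    log2_sd: float = 0.5,
    ssh_capture_bias: float = 0.4,
) -> RunConfig:
    """Write a complete simulated input bundle ("paperlike" preset, scaled to
    desk size) and the RunConfig that consumes it.

    ``read_depth`` controls the rendered FASTQ libraries (kept small so the
    mismatch-tolerant mapper stays fast); ``count_depth`` is used for the
    SSH abundance scale.  Returns the RunConfig (also written as run.yaml).
    """
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    truth = generate_truth(n_mirna=n_mirna, seed=seed)
    reference = random_reference(truth.mirnas, seed=seed + 1)
    counts = simulate_count_libraries(
        truth,
        n_tumor=n_tumor,
        n_normal_members=n_normal_members,
        depth=read_depth,
        dispersion=dispersion,
        seed=seed + 2,
    )
    adapter = "TCGTATGCCGTCTTCTGCTTG"
    libraries = render_reads(
        counts, reference, adapter=adapter, error_rate=error_rate, seed=seed + 3
    )
    read_inputs = []
    for lib in libraries:
        path = outdir / "reads" / f"{lib.sample_id}.fastq"
        write_fastq(lib, path)
        read_inputs.append(
            ReadInput(path=str(path), sample=lib.sample_id, condition=lib.condition.value)
        )

    with open(outdir / "reference.fasta", "w", encoding="utf-8") as fh:
        for mid, seq in reference.items():
            fh.write(f">{mid}\n{seq}\n")

    catalogue = truth_catalogue(truth)
    save_marker_catalogue(catalogue, outdir / "catalogue.tsv")
    truth.to_tsv(outdir / "truth.tsv")

    array = simulate_array_signals(
        truth, n_tumor=n_ma_tumor, n_normal=n_ma_normal, log2_sd=log2_sd, seed=seed + 4
    )
    save_array_signals(
        array, outdir / "array_signals.tsv", outdir / "array_conditions.tsv"
    )
    ssh = simulate_ssh_pairs(
        truth, depth=count_depth / 10, capture_bias=ssh_capture_bias, seed=seed + 5
    )
    save_ssh_pairs(ssh, outdir / "ssh_pairs.tsv")

    config = RunConfig(
        reference=str(outdir / "reference.fasta"),
        catalogue=str(outdir / "catalogue.tsv"),
        reads=read_inputs,
        pooled_normal="normal_pool",
        ssh_pairs=str(outdir / "ssh_pairs.tsv"),
        array_signals=str(outdir / "array_signals.tsv"),
        array_conditions=str(outdir / "array_conditions.tsv"),
        adapter=adapter,
        seed=seed,
    )
    config.to_yaml(outdir / "run.yaml")
    return config
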