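"""End-to-end orchestration: simulate/load -> condition -> profile -> test.

``run_all`` is the single entry point behind the command line and the
analysis scripts.  All randomness flows from one root seed, split
deterministically per stage (and per feature for the observed-window
subsampler), so a run is byte-identical given (inputs, seed).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats, preprocess, profiles, simulate, stats
from .errors import EmptyMatrixError, FeatureSpeedError, InsufficientDataError
from .types import Dataset

logger = logging.getLogger(__name__)


def _stage_seed(root_seed: int, *labels) -> int:
    """Deterministic 31-bit seed for a named pipeline stage."""
    import zlib

    entropy = [root_seed] + [zlib.crc32(str(lab).encode()) for lab in labels]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    sim: simulate.SimConfig | None = None
    input_dir: str | Path | None = None
    #: per-track conditioning: {"occupancy": {"outliers": 1.5}, "structure": {"zscore": True}}
    track_directives: dict = field(default_factory=lambda: {
        "occupancy": {"outliers": 1.5},
        "structure": {"zscore": True},
    })
    discrepancy_max: float = 0.05
    stat_window: profiles.WindowSpec = profiles.STATISTIC_WINDOW
    vis_window: profiles.WindowSpec = profiles.VISUALIZATION_WINDOW
    codon_window: profiles.WindowSpec = profiles.CODON_WINDOW
    n_background: int = 1000
    max_windows: int = 1000
    min_windows: int = 10
    alpha: float = 0.05
    equal_var: bool = False
    smooth_nt: int = 6
    smooth_codon: int = 2
    seed: int = 0
    out_dir: str | Path | None = None

    def validate(self) -> None:
        if (self.sim is None) == (self.input_dir is None):
            raise ValueError("exactly one of sim / input_dir must be set")
        for name in self.track_directives:
            if not isinstance(name, str):
                raise ValueError("track names must be strings")

    def resolved(self) -> dict:
        cfg = {
            "track_directives": self.track_directives,
            "discrepancy_max": self.discrepancy_max,
            "stat_window": [self.stat_window.upstream, self.stat_window.downstream],
            "vis_window": [self.vis_window.upstream, self.vis_window.downstream],
            "n_background": self.n_background,
            "max_windows": self.max_windows,
            "min_windows": self.min_windows,
            "alpha": self.alpha,
            "equal_var": self.equal_var,
            "smooth_nt": self.smooth_nt,
            "seed": self.seed,
        }
        if self.input_dir is not None:
            cfg["input_dir"] = str(self.input_dir)
        return cfg


@dataclass
class RunResult:
    dataset: Dataset
    report: pd.DataFrame
    results: list[stats.CorrelationTestResult]
    profiles: dict[tuple[str, str], profiles.AverageProfile]
    log: dict


def prepare_dataset(config: RunConfig) -> tuple[Dataset, dict]:
    """Obtain and condition the dataset; returns (dataset, log counts)."""
    if config.sim is not None:
        dataset = simulate.generate_dataset(config.sim)
    else:
        dataset = io_formats.read_dataset(config.input_dir)
    log: dict = {"load": dict(dataset.load_log)}

    trimmed = {}
    for tid, record in dataset.transcripts.items():
        trimmed[tid] = (preprocess.trim_utrs(record)
                        if record.utr5_len or record.utr3_len else record)
    dataset.transcripts = trimmed

    log["discrepancy_dropped"] = preprocess.filter_discrepant(
        dataset, config.discrepancy_max)

    for track_name in sorted(config.track_directives):
        directive = config.track_directives[track_name]
        if "outliers" in directive:
            policy = preprocess.OutlierPolicy(k=float(directive["outliers"]))
            count = preprocess.remove_outliers(dataset, track_name, policy)
            log[f"outliers_removed_{track_name}"] = count
        if directive.get("zscore"):
            base_stats = preprocess.zscore_by_base(dataset, track_name)
            log[f"base_stats_{track_name}"] = {
                b: {"mu": base_stats.mu[b], "sigma": base_stats.sigma[b],
                    "n": base_stats.n[b]}
                for b in "ACGT"
            }

    if dataset.trna is not None:
        for record in dataset.transcripts.values():
            preprocess.build_codon_track(record, dataset.trna)
    return dataset, log


def run_all(config: RunConfig) -> RunResult:
    """Full pipeline; per-feature failures are logged, not fatal.

    Emits (when ``out_dir`` is set): ``report.tsv``,
    ``profiles/<feature>_<track>.tsv``, ``run_log.json`` and a resolved
    config echo (YAML).
    """
    config.validate()
    dataset, log = prepare_dataset(config)
    log["skipped"] = {}

    background: dict[str, stats.CorrelationDistribution] = {}
    for track_name in sorted(config.track_directives):
        try:
            background[track_name] = stats.background_distribution(
                dataset, track_name, config.stat_window.length,
                n_vectors=config.n_background,
                seed=_stage_seed(config.seed, "background", track_name),
            )
        except FeatureSpeedError as exc:
            log["skipped"][f"background:{track_name}"] = str(exc)

    results: list[stats.CorrelationTestResult] = []
    avg_profiles: dict[tuple[str, str], profiles.AverageProfile] = {}
    for feature_name in dataset.feature_names():
        n_instances = len(dataset.instances_of(feature_name))
        for track_name in sorted(config.track_directives):
            key = f"{feature_name}:{track_name}"
            try:
                vis_matrix = profiles.build_profile_matrix(
                    dataset, feature_name, track_name, config.vis_window)
                prof = profiles.average_profile(vis_matrix)
                prof.smoothed = profiles.smooth(prof.mean, config.smooth_nt)
                avg_profiles[(feature_name, track_name)] = prof

                if track_name not in background:
                    log["skipped"][key] = "no background distribution"
                    continue
                stat_matrix = profiles.build_profile_matrix(
                    dataset, feature_name, track_name, config.stat_window)
                n_complete = stat_matrix.complete_rows().shape[0]
                if n_complete < config.min_windows:
                    log["skipped"][key] = (
                        f"only {n_complete} complete windows "
                        f"(minimum {config.min_windows})"
                    )
                    continue
                obs = stats.observed_distribution(
                    stat_matrix, max_windows=config.max_windows,
                    seed=_stage_seed(config.seed, "observed", feature_name, track_name),
                )
                results.append(stats.association_test(
                    obs, background[track_name],
                    feature_name=feature_name, track_name=track_name,
                    n_instances=n_instances, equal_var=config.equal_var,
                ))
            except (EmptyMatrixError, InsufficientDataError, FeatureSpeedError) as exc:
                log["skipped"][key] = str(exc)
                logger.warning("feature %s / track %s skipped: %s",
                               feature_name, track_name, exc)

        # descriptive codon-level tRNA profile (no test: tRNA availability is
        # constrained by amino-acid identity, so the background is ill-posed)
        if dataset.trna is not None:
            try:
                codon_matrix = profiles.build_profile_matrix(
                    dataset, feature_name, "trna", config.codon_window)
                prof = profiles.average_profile(codon_matrix)
                prof.smoothed = profiles.smooth(prof.mean, config.smooth_codon)
                avg_profiles[(feature_name, "trna")] = prof
            except (EmptyMatrixError, FeatureSpeedError) as exc:
                log["skipped"][f"{feature_name}:trna"] = str(exc)

    report = io_formats.report_frame(results)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_report(results, out / "report.tsv")
        profile_dir = out / "profiles"
        profile_dir.mkdir(exist_ok=True)
        for (feature_name, track_name), prof in sorted(avg_profiles.items()):
            safe = feature_name.replace(" ", "_").replace("/", "-")
            prof.to_frame().to_csv(profile_dir / f"{safe}_{track_name}.tsv",
                                   sep="\t", index=False, float_format="%.12g")
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=1, sort_keys=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.resolved(), fh, sort_keys=True)

    return RunResult(dataset=dataset, report=report, results=results,
                     profiles=avg_profiles, log=log)


def gene_report(dataset: Dataset, transcript_id: str,
                tracks: list[str] | None = None,
                smooth_w: int = 6,
                subrange: tuple[int, int] | None = None
                ) -> tuple[pd.DataFrame, list[dict]]:
    """Per-gene profile: smoothed track values with feature spans overlaid.

    Feature spans are converted to nucleotide coordinates
    ``3*(start_res-1) .. 3*end_res`` (half-open).  A sub-range beyond the
    CDS is clipped with a warning.  Returns (table, feature spans).
    """
    record = dataset.transcripts.get(transcript_id)
    if record is None:
        raise KeyError(f"unknown transcript {transcript_id!r}")
    tracks = tracks if tracks is not None else sorted(record.tracks)
    n = len(record.cds)
    lo, hi = (0, n) if subrange is None else subrange
    if lo < 0 or hi > n:
        logger.warning("sub-range %s clipped to CDS bounds [0, %d)", (lo, hi), n)
        lo, hi = max(lo, 0), min(hi, n)

    columns: dict[str, np.ndarray] = {"position": np.arange(lo, hi)}
    for name in tracks:
        values = record.tracks[name]
        columns[name] = values[lo:hi]
        columns[f"{name}_smoothed"] = profiles.smooth(values, smooth_w)[lo:hi]
    table = pd.DataFrame(columns)

    spans = []
    for inst in dataset.features:
        if inst.protein_id != transcript_id:
            continue
        nt_start, nt_end = 3 * (inst.start_res - 1), 3 * inst.end_res
        if nt_end > lo and nt_start < hi:
            spans.append({"feature_name": inst.feature_name,
                          "start_res": inst.start_res, "end_res": inst.end_res,
                          "nt_start": nt_start, "nt_end": nt_end})
    spans.sort(key=lambda s: (s["nt_start"], s["feature_name"]))
    return table, spans
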