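"""End-to-end orchestration: cohort -> P3 table -> networks -> correlations.

The in-memory functions (:func:`analyze_task`, :func:`analyze_rest`,
:func:`analyze_cohort`, :func:`correlate_cohort`) are the pipeline proper;
the ``stage_*`` functions wrap them as file-to-file steps so that the CLI's
individual subcommands composed manually produce byte-identical artifacts
to ``run-all``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import SpectralParams, adjacency_from_recording, mfc
from .erp import (P3_CHANNELS, average_erp, bandpass, baseline_correct,
                  epoch, extract_p3, reject_artifacts, rereference_average)
from .graph import metric_set
from .io import (Adjacency, Recording, read_adjacency, read_events,
                 read_recording, write_adjacency, write_events,
                 write_recording)
from .simulate import CohortSpec, simulate_cohort, truth_table
from .stats import edgewise_correlations, metric_correlations

logger = logging.getLogger(__name__)

__all__ = [
    "ErpConfig",
    "StatsConfig",
    "analyze_task",
    "analyze_rest",
    "analyze_cohort",
    "correlate_cohort",
    "stage_simulate",
    "stage_erp",
    "stage_network",
    "stage_correlate",
    "run_all",
]


@dataclass
class ErpConfig:
    """Task-branch settings; ``band_hz=None`` skips the band-pass filter."""

    band_hz: tuple[float, float] | None = (0.5, 6.0)
    window_ms: tuple[float, float] = (-200.0, 800.0)
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    reject_threshold_uv: float = 75.0
    channels: tuple[str, ...] = P3_CHANNELS
    search_ms: tuple[float, float] = (300.0, 500.0)
    half_width_ms: float = 50.0

    @classmethod
    def from_dict(cls, d: dict) -> "ErpConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown erp field(s): {sorted(unknown)}")
        out = cls(**d)
        if out.band_hz is not None:
            out.band_hz = tuple(out.band_hz)
        out.window_ms = tuple(out.window_ms)
        out.baseline_ms = tuple(out.baseline_ms)
        out.channels = tuple(out.channels)
        out.search_ms = tuple(out.search_ms)
        return out


@dataclass
class StatsConfig:
    alpha: float = 0.01
    correction: str = "none"

    @classmethod
    def from_dict(cls, d: dict) -> "StatsConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown stats field(s): {sorted(unknown)}")
        out = cls(**d)
        if not 0 < out.alpha <= 1:
            raise ValueError(f"invalid stats.alpha: {out.alpha}")
        if out.correction not in ("none", "bh"):
            raise ValueError(f"invalid stats.correction: {out.correction}")
        return out


# ---------------------------------------------------------------------------
# in-memory pipeline
# ---------------------------------------------------------------------------


def analyze_task(rec: Recording, events: pd.DataFrame,
                 cfg: ErpConfig | None = None):
    """Task recording -> P3 measure.

    Returns ``(P3Measure, info)`` with ``info`` holding kept/total trial
    counts and the averaged target ERP.
    """
    cfg = cfg or ErpConfig()
    rec = rereference_average(rec)
    if cfg.band_hz is not None:
        rec = bandpass(rec, *cfg.band_hz)
    eps = epoch(rec, events, cfg.window_ms)
    eps = baseline_correct(eps, cfg.baseline_ms)
    eps = reject_artifacts(eps, cfg.reject_threshold_uv)
    erp = average_erp(eps, "target")
    measure = extract_p3(erp, eps.labels, eps.fs, cfg.window_ms,
                         cfg.channels, cfg.search_ms, cfg.half_width_ms)
    info = {
        "n_trials": int(eps.n_trials),
        "n_kept": int(eps.kept.sum()),
        "n_kept_target": int((eps.kept & (eps.condition == "target")).sum()),
        "rejected_trials": eps.meta.get("rejected_trials", []),
        "erp": erp,
    }
    return measure, info


def analyze_rest(rec: Recording, params: SpectralParams | None = None):
    """Resting recording -> (Adjacency, MetricSet, MFC)."""
    params = params or SpectralParams()
    adj = adjacency_from_recording(rec, params)
    metrics = metric_set(adj)
    return adj, metrics, mfc(adj)


def analyze_cohort(subjects, erp_cfg: ErpConfig | None = None,
                   spectral: SpectralParams | None = None):
    """Run both branches for every subject bundle.

    Returns ``(p3_table, metrics_table, adjacencies)`` where the tables are
    DataFrames keyed by ``subject_id`` and ``adjacencies`` maps subject_id
    -> Adjacency.
    """
    p3_rows, metric_rows, adjacencies = [], [], {}
    for sub in subjects:
        sid = sub["subject_id"]
        measure, info = analyze_task(sub["task"], sub["events"], erp_cfg)
        row = {"subject_id": sid, "amplitude": measure.amplitude,
               "latency": measure.latency,
               "n_kept_trials": info["n_kept"],
               "n_kept_target": info["n_kept_target"]}
        for ch, (a, l) in measure.per_channel.items():
            row[f"amp_{ch}"] = a
            row[f"lat_{ch}"] = l
        p3_rows.append(row)

        adj, metrics, w_mean = analyze_rest(sub["rest"], spectral)
        adjacencies[sid] = adj
        metric_rows.append({"subject_id": sid, "MFC": w_mean,
                            **metrics.as_dict(),
                            "n_segments_used": adj.n_segments_used})
        logger.info("subject %s: amp=%.3f uV lat=%.1f ms MFC=%.3f",
                    sid, measure.amplitude, measure.latency, w_mean)
    return pd.DataFrame(p3_rows), pd.DataFrame(metric_rows), adjacencies


def correlate_cohort(metrics: pd.DataFrame, p3: pd.DataFrame,
                     adjacencies, stats_cfg: StatsConfig | None = None):
    """Index- and edge-level correlation tables."""
    stats_cfg = stats_cfg or StatsConfig()
    corr = metric_correlations(metrics, p3)
    edges = edgewise_correlations(adjacencies, p3, alpha=stats_cfg.alpha,
                                  correction=stats_cfg.correction)
    return corr, edges


# ---------------------------------------------------------------------------
# on-disk stages (composed by the CLI)
# ---------------------------------------------------------------------------


def _cohort_dir(out_dir: Path) -> Path:
    return Path(out_dir) / "cohort"


def stage_simulate(spec: CohortSpec, out_dir) -> Path:
    """Write a simulated cohort (recordings, events, truth manifest)."""
    cohort_dir = _cohort_dir(out_dir)
    cohort_dir.mkdir(parents=True, exist_ok=True)
    subjects, truths = simulate_cohort(spec)
    for sub in subjects:
        sid = sub["subject_id"]
        write_recording(sub["rest"], cohort_dir / f"{sid}_rest.tsv")
        write_recording(sub["task"], cohort_dir / f"{sid}_task.tsv")
        write_events(sub["events"], cohort_dir / f"{sid}_events.tsv")
    tt = truth_table(truths)
    tt.to_csv(cohort_dir / "truth.tsv", sep="\t", index=False,
              float_format="%.12g")
    logger.info("wrote %d-subject cohort to %s", len(subjects), cohort_dir)
    return cohort_dir


def _iter_cohort(cohort_dir: Path):
    cohort_dir = Path(cohort_dir)
    ids = sorted(p.name[:-len("_rest.tsv")]
                 for p in cohort_dir.glob("*_rest.tsv"))
    if not ids:
        raise FileNotFoundError(f"no cohort recordings under {cohort_dir}")
    for sid in ids:
        yield {
            "subject_id": sid,
            "rest": read_recording(cohort_dir / f"{sid}_rest.tsv"),
            "task": read_recording(cohort_dir / f"{sid}_task.tsv"),
            "events": read_events(cohort_dir / f"{sid}_events.tsv"),
        }


def stage_erp(out_dir, erp_cfg: ErpConfig | None = None) -> Path:
    """Cohort dir -> per-subject P3 table (``p3.tsv``)."""
    out_dir = Path(out_dir)
    rows = []
    for sub in _iter_cohort(_cohort_dir(out_dir)):
        measure, info = analyze_task(sub["task"], sub["events"], erp_cfg)
        row = {"subject_id": sub["subject_id"],
               "amplitude": measure.amplitude, "latency": measure.latency,
               "n_kept_trials": info["n_kept"],
               "n_kept_target": info["n_kept_target"]}
        for ch, (a, l) in measure.per_channel.items():
            row[f"amp_{ch}"] = a
            row[f"lat_{ch}"] = l
        rows.append(row)
    path = out_dir / "p3.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.12g")
    return path


def stage_network(out_dir, spectral: SpectralParams | None = None) -> Path:
    """Cohort dir -> adjacency TSVs + network metrics table."""
    out_dir = Path(out_dir)
    adj_dir = out_dir / "adjacency"
    adj_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in _iter_cohort(_cohort_dir(out_dir)):
        adj, metrics, w_mean = analyze_rest(sub["rest"], spectral)
        write_adjacency(adj, adj_dir / f"{sub['subject_id']}.tsv")
        rows.append({"subject_id": sub["subject_id"], "MFC": w_mean,
                     **metrics.as_dict(),
                     "n_segments_used": adj.n_segments_used})
    path = out_dir / "metrics.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.12g")
    return path


def stage_correlate(out_dir, stats_cfg: StatsConfig | None = None
                    ) -> tuple[Path, Path]:
    """P3 + metrics + adjacency artifacts -> correlation tables."""
    out_dir = Path(out_dir)
    p3 = pd.read_csv(out_dir / "p3.tsv", sep="\t")
    metrics = pd.read_csv(out_dir / "metrics.tsv", sep="\t")
    adjacencies = {p.stem: read_adjacency(p)
                   for p in sorted((out_dir / "adjacency").glob("*.tsv"))}
    corr, edges = correlate_cohort(metrics, p3, adjacencies, stats_cfg)
    corr_path = out_dir / "correlations.tsv"
    edge_path = out_dir / "edges.tsv"
    corr.to_csv(corr_path, sep="\t", index=False, float_format="%.12g")
    edges.to_csv(edge_path, sep="\t", index=False, float_format="%.12g")
    return corr_path, edge_path


def run_all(spec: CohortSpec, out_dir,
            erp_cfg: ErpConfig | None = None,
            spectral: SpectralParams | None = None,
            stats_cfg: StatsConfig | None = None,
            config_echo: dict | None = None) -> Path:
    """Simulate + analyze + correlate; write ``report.json`` last."""
    out_dir = Path(out_dir)
    stage_simulate(spec, out_dir)
    stage_erp(out_dir, erp_cfg)
    stage_network(out_dir, spectral)
    stage_correlate(out_dir, stats_cfg)

    p3 = pd.read_csv(out_dir / "p3.tsv", sep="\t")
    metrics = pd.read_csv(out_dir / "metrics.tsv", sep="\t")
    corr = pd.read_csv(out_dir / "correlations.tsv", sep="\t")
    edges = pd.read_csv(out_dir / "edges.tsv", sep="\t")
    sig = edges[edges["sig_amp"] | edges["sig_lat"]]
    report = {
        "software": {"name": "p3net", "version": __version__},
        "seed": spec.seed,
        "config": config_echo or {
            "cohort": asdict(spec),
            "erp": asdict(erp_cfg or ErpConfig()),
            "connectivity": asdict(spectral or SpectralParams()),
            "stats": asdict(stats_cfg or StatsConfig()),
        },
        "subjects": json.loads(
            p3.merge(metrics, on="subject_id").to_json(orient="records")),
        "correlations": json.loads(corr.to_json(orient="records")),
        "significant_edges": json.loads(
            sig[["node_i", "node_j", "r_amp", "p_amp", "r_lat", "p_lat",
                 "sig_amp", "sig_lat"]].to_json(orient="records")),
    }
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True,
                                      default=str))
    logger.info("run report written to %s", report_path)
    return report_path
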