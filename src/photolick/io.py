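"""Session container format and the end-to-end pipeline.

A session lives in a directory holding a samples table (1 ms or
acquisition-rate clock: detector voltage or demodulated F465/F405, plus the
piezo trace), a long-format events table, and a JSON metadata sidecar
carrying the task configuration, generator parameters, seed and a
provenance chain that each processing step appends to.  Samples default to
Parquet (columnar, lossless for float64); CSV is accepted for both tables.

:func:`run_pipeline` chains simulate -> demodulate -> preprocess -> parse ->
quantify -> learning with fixed seeds and writes summary CSVs plus a run
report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import align as al
from . import behavior as beh
from . import learning as ld
from . import preprocess as pp
from . import synthetic as syn
from .demodulation import ChannelTraces, RawRecording, demodulate_recording
from .task import TaskConfig

__all__ = [
    "SCHEMA_VERSION",
    "SessionBundle",
    "SchemaError",
    "PipelineError",
    "read_session",
    "write_session",
    "bundle_from_simulation",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

_SAMPLE_COLUMNS = ({"detector_v"}, {"f465", "f405"})


class SchemaError(ValueError):
    """Session on disk does not match the expected schema."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is carried in the message."""


@dataclass
class SessionBundle:
    """In-memory session: samples + events tables and metadata sidecar."""

    samples: pd.DataFrame
    events: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "time_s" not in self.samples.columns:
            raise SchemaError("samples table needs a time_s column")
        if not any(cols <= set(self.samples.columns) for cols in _SAMPLE_COLUMNS):
            raise SchemaError("samples table needs detector_v or f465+f405 columns")
        t = self.samples["time_s"].to_numpy()
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise SchemaError("samples time_s must be strictly increasing")
        for col in ("time_s", "event_type", "value"):
            if col not in self.events.columns:
                raise SchemaError(f"events table needs a {col} column")
        self.meta.setdefault("schema_version", SCHEMA_VERSION)

    def append_provenance(self, stage: str, params: dict) -> None:
        self.meta.setdefault("provenance", []).append({"stage": stage, **params})


def write_session(
    bundle: SessionBundle, path: str | Path, samples_format: str = "parquet"
) -> Path:
    """Write a session directory: samples, events.csv, meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if samples_format == "parquet":
        bundle.samples.to_parquet(path / "samples.parquet", index=False)
    elif samples_format == "csv":
        bundle.samples.to_csv(path / "samples.csv", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown samples_format {samples_format!r}")
    bundle.events.to_csv(path / "events.csv", index=False, float_format="%.17g")
    with open(path / "meta.json", "w") as fh:
        json.dump(bundle.meta, fh, indent=2, sort_keys=True)
    return path


def read_session(path: str | Path) -> SessionBundle:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SchemaError(f"no meta.json in {path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    found = meta.get("schema_version")
    if found != SCHEMA_VERSION:
        raise SchemaError(
            f"schema version mismatch: expected {SCHEMA_VERSION}, found {found}"
        )
    if (path / "samples.parquet").exists():
        samples = pd.read_parquet(path / "samples.parquet")
    elif (path / "samples.csv").exists():
        samples = pd.read_csv(path / "samples.csv", float_precision="round_trip")
    else:
        raise SchemaError(f"no samples table in {path}")
    events_path = path / "events.csv"
    if not events_path.exists():
        raise SchemaError(f"no events table in {path}")
    events = pd.read_csv(events_path, float_precision="round_trip")
    return SessionBundle(samples=samples, events=events, meta=meta)


def bundle_from_simulation(sim: syn.SimulatedSession) -> SessionBundle:
    """Package a simulated session (raw detector + piezo + events + truth)."""
    raw = sim.raw
    t_raw = raw.times
    piezo_t = sim.events.piezo
    piezo_raw = np.interp(
        t_raw, np.arange(piezo_t.size) / sim.events.fs, piezo_t
    )
    samples = pd.DataFrame(
        {"time_s": t_raw, "detector_v": raw.samples, "piezo_v": piezo_raw}
    )
    events = sim.events.to_frame()
    truth = sim.truth
    meta = {
        "schema_version": SCHEMA_VERSION,
        "seed": sim.seed,
        "fs_acquisition": raw.fs,
        "carrier_freqs": list(raw.carrier_freqs),
        "modulation_depth": raw.modulation_depth,
        "session_t_end": sim.events.session_t_end,
        "task_config": sim.config.to_dict(),
        "ground_truth": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(truth).items()
        },
        "provenance": [{"stage": "simulate", "seed": sim.seed}],
    }
    return SessionBundle(samples=samples, events=events, meta=meta)


def _trial_averaged_traces(
    z_or_dff: np.ndarray,
    trials: beh.TrialTable,
    fs: float,
    pre: float = 1.0,
    post: float = 3.0,
) -> tuple[list[np.ndarray], list[str]]:
    """One trial-averaged trace per trial type (lick-aligned when licked,
    onset-aligned otherwise); the inputs to the normalization factor."""
    traces, provenance = [], []
    for ttype, sub in trials.df.groupby("type"):
        anchor = sub["first_report_lick_time"].where(
            sub["first_report_lick_time"].notna(), sub["onset_time"]
        ).to_numpy(dtype=float)
        try:
            ep = al.extract_epochs(z_or_dff, anchor, pre=pre, post=post, fs=fs)
        except ValueError:
            continue
        traces.append(ep.mean_trace())
        provenance.append(str(ttype))
    return traces, provenance


def run_pipeline(config: dict | None = None, seed: int = 0, outdir: str | Path = "out") -> dict:
    """Simulate one session and push it through every analysis stage.

    ``config`` keys (all optional): ``task_kind``, ``n_trials``, nested
    overrides ``task`` / ``behavior`` / ``photometry``, ``lowpass_hz``,
    ``windows`` (names from the registry), ``samples_format``.  Outputs
    under ``outdir``: the session bundle, ``trials.csv``,
    ``window_quants.csv``, ``blocks.csv`` (when evaluable) and
    ``report.json``.  Returns the report dict.
    """
    config = dict(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    task_kind = config.get("task_kind", "whisker_detection")
    n_trials = int(config.get("n_trials", 60))
    window_names = config.get("windows", list(al.WINDOWS))
    lowpass_hz = float(config.get("lowpass_hz", 25.0))

    def stage(name):
        class _Stage:
            def __enter__(self):
                logger.info("pipeline stage: %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return _Stage()

    report: dict = {"seed": seed, "task_kind": task_kind, "n_trials": n_trials}

    with stage("simulate"):
        cfg = TaskConfig.for_task(task_kind, **config.get("task", {}))
        params = syn.BehaviorParams(**config.get("behavior", {}))
        truth = syn.PhotometryGroundTruth(**config.get("photometry", {}))
        sim = syn.simulate_session(cfg, params, truth, n_trials, seed=seed)
        bundle = bundle_from_simulation(sim)
        write_session(
            bundle, outdir / "session", config.get("samples_format", "parquet")
        )

    with stage("demodulate"):
        channels = demodulate_recording(sim.raw, lowpass_cutoff=lowpass_hz)
        bundle.append_provenance("demodulate", {"lowpass_hz": lowpass_hz})

    with stage("preprocess"):
        dff = pp.preprocess_traces(channels)
        bundle.append_provenance(
            "preprocess", {"a": dff.fit_coeffs[0], "b": dff.fit_coeffs[1]}
        )

    with stage("parse"):
        trials = beh.parse_trials(sim.events, cfg)
        trials.df.to_csv(outdir / "trials.csv", index=False, float_format="%.17g")
        report["n_completed_trials"] = len(trials)
        report["trial_type_counts"] = trials.df["type"].value_counts().to_dict()
        if trials.n_stim and trials.n_nostim:
            perf = beh.performance_metrics(trials)
            report["performance"] = {
                "hit_rate": perf.hit_rate,
                "fa_rate": perf.fa_rate,
                "dprime": perf.dprime,
            }

    with stage("normalize"):
        traces, provenance = _trial_averaged_traces(dff.values, trials, dff.fs)
        factor = pp.compute_norm_factor(traces, provenance)
        z = pp.apply_zscore(dff, factor)
        bundle.append_provenance(
            "normalize", {"sigma": factor.sigma, "provenance": provenance}
        )
        report["norm_sigma"] = factor.sigma

    with stage("quantify"):
        quant_rows = []
        per_window: dict[str, pd.DataFrame] = {}
        for name in window_names:
            spec = al.WINDOWS[name]
            if spec.align == "whisker_stim":
                sub = trials.df[trials.df["stim"]]
                anchors = sub["onset_time"].to_numpy(dtype=float)
            else:
                sub = trials.df[trials.df["first_report_lick_time"].notna()]
                anchors = sub["first_report_lick_time"].to_numpy(dtype=float)
            if anchors.size == 0:
                continue
            pre = max(1.5, -min(spec.response[0], spec.baseline[0]) + 0.5)
            post = max(spec.response[1], spec.baseline[1]) + 0.5
            ep = al.extract_epochs(
                z, anchors, pre=pre, post=post, fs=dff.fs, t0=dff.t0,
                align_event=spec.align, trial_ids=sub["trial"].to_numpy(),
            )
            vals = al.window_quant(ep, spec)
            kept = sub.set_index("trial").loc[ep.trial_ids]
            for trial_id, ttype, v in zip(ep.trial_ids, kept["type"], vals):
                quant_rows.append(
                    {"trial": int(trial_id), "window": name, "type": ttype, "value": v}
                )
            per_window[name] = pd.DataFrame(
                {"trial": ep.trial_ids, "type": kept["type"].to_numpy(), "value": vals}
            )
        quants = pd.DataFrame(quant_rows)
        quants.to_csv(outdir / "window_quants.csv", index=False, float_format="%.17g")

    with stage("devaluation"):
        if "reward_peak" in per_window:
            rewarded = per_window["reward_peak"]
            rewarded = rewarded[rewarded["type"].isin(beh.REWARDED_TYPES)]
            if len(rewarded):
                fl = al.first_last_k(rewarded["value"].to_numpy(), k=15)
                report["devaluation"] = {
                    "first_mean": fl.first_mean,
                    "last_mean": fl.last_mean,
                    "k_used": fl.k_used,
                    "truncated": fl.truncated,
                }

    with stage("learning"):
        if "sensory_early" in per_window and trials.n_stim >= ld.BLOCK_DEFAULT:
            early = per_window["sensory_early"].set_index("trial")
            stim_trials = trials.df[trials.df["stim"]]
            ids = [t for t in stim_trials["trial"] if t in early.index]
            values = early.loc[ids, "value"].to_numpy(dtype=float)
            hits = (
                stim_trials.set_index("trial").loc[ids, "type"]
                .isin(beh.HIT_TYPES)
                .to_numpy(dtype=float)
            )
            n_use = min(len(values) // ld.BLOCK_DEFAULT * ld.BLOCK_DEFAULT,
                        ld.N_TRIALS_DEFAULT)
            if n_use >= 2 * ld.BLOCK_DEFAULT:  # need >= 2 blocks for a slope
                bs = ld.block_series(values, hits, n_trials=ld.N_TRIALS_DEFAULT
                                     if len(values) >= ld.N_TRIALS_DEFAULT else n_use)
                pd.DataFrame(
                    {
                        "block": bs.block_index,
                        "trial_center": bs.trial_center,
                        "dlight": bs.dlight,
                        "hit_rate": bs.hit_rate,
                    }
                ).to_csv(outdir / "blocks.csv", index=False, float_format="%.17g")
                learn: dict = {
                    "n_blocks": bs.n_blocks,
                    "dlight_slope": ld.learning_slope(bs, "dlight"),
                    "hit_slope": ld.learning_slope(bs, "hit_rate"),
                    "flagged_short": bs.flagged_short,
                }
                flag = ld.select_learners(hits)
                learn["learner"] = {
                    "evaluable": flag.evaluable,
                    "is_learner": flag.is_learner,
                    "r": None if np.isnan(flag.r) else flag.r,
                    "p": None if np.isnan(flag.p) else flag.p,
                }
                try:
                    r, p = ld.pearson_with_p(bs.trial_center, bs.dlight)
                    learn["dlight_block_r"] = r
                    learn["dlight_block_p"] = p
                except ValueError:
                    pass
                report["learning"] = learn

    with stage("write_report"):
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
        with open(outdir / "meta.json", "w") as fh:
            json.dump(bundle.meta, fh, indent=2, sort_keys=True)
    return report
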