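"""Configuration, tabular file I/O, seeding and the ``procode`` CLI.

Spike trains travel as two-column tab-separated text (``channel``,
``time_ms``, sorted by time); trace bundles as delimited tables with a
``time_ms`` first column (round-trip exact to 1e-12).  Config files may
be JSON, YAML or TOML; absent fields fall back to the model defaults
(dt = 0.1 ms, standard neuron constants).  Every run writes a manifest
(config snapshot, seed, version, output checksums) next to its outputs,
and all randomness flows from the single seed through a SeedSequence,
so reruns are byte-identical.
"""

from __future__ import annotations

import argparse
import dataclasses
import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from procode import __version__
from procode.core_model import NeuronParams, SpikeTrainSet, TraceBundle
from procode.experiments import ExperimentConfig, run_experiment
from procode.plasticity import PlasticityParams
from procode.theory import (
    MarkovEnvironment,
    TDParams,
    markov_fixed_point,
    periodic_fixed_point,
    td_lambda_learn,
    value_function,
)

__all__ = [
    "FormatError",
    "load_config",
    "save_config",
    "config_to_dict",
    "dict_to_config",
    "write_spiketrains",
    "read_spiketrains",
    "write_traces",
    "read_traces",
    "write_manifest",
    "PRESETS",
    "cli_main",
    "main",
]


class FormatError(ValueError):
    """A data or config file violates the expected format."""


# ---------------------------------------------------------------------------
# configuration


_CONFIG_KEYS = {f.name for f in dataclasses.fields(ExperimentConfig)}


def config_to_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["neuron"] = dataclasses.asdict(config.neuron)
    d["plasticity"] = dataclasses.asdict(config.plasticity)
    return d


def dict_to_config(data: dict) -> ExperimentConfig:
    data = dict(data)
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    try:
        neuron = NeuronParams(**data.pop("neuron", {}))
        plasticity = PlasticityParams(**data.pop("plasticity", {}))
        return ExperimentConfig(neuron=neuron, plasticity=plasticity, **data)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"invalid configuration: {exc}") from exc


def load_config(path) -> ExperimentConfig:
    """Read a config file (JSON/YAML/TOML by suffix), validate it and
    fill defaults for absent fields."""
    path = Path(path)
    text = path.read_text()
    suffix = path.suffix.lower()
    if suffix == ".json":
        data = json.loads(text)
    elif suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    elif suffix == ".toml":
        import tomllib

        data = tomllib.loads(text)
    else:
        raise FormatError(f"unsupported config suffix {suffix!r}")
    if data is None:
        data = {}
    return dict_to_config(data)


def save_config(config: ExperimentConfig, path) -> None:
    path = Path(path)
    path.write_text(json.dumps(config_to_dict(config), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# spike trains and traces


def write_spiketrains(spikes: SpikeTrainSet, path) -> None:
    """Two-column tab-separated text, one row per spike, sorted by time."""
    rows = []
    for ch, times in enumerate(spikes.spike_times):
        for t in times:
            rows.append((ch, t))
    rows.sort(key=lambda r: (r[1], r[0]))
    with open(path, "w") as fh:
        fh.write(f"# duration_ms={float(spikes.duration)!r} "
                 f"periodic={int(spikes.periodic)} "
                 f"n_channels={spikes.n_channels}\n")
        fh.write("channel\ttime_ms\n")
        for ch, t in rows:
            fh.write(f"{ch}\t{float(t)!r}\n")


def read_spiketrains(path) -> SpikeTrainSet:
    """Inverse of :func:`write_spiketrains`; validates the invariants and
    reports malformed lines with their line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise FormatError(f"{path}: missing header comment on line 1")
    meta = dict(item.split("=") for item in lines[0][1:].split())
    duration = float(meta["duration_ms"])
    periodic = bool(int(meta["periodic"]))
    n_channels = int(meta["n_channels"])
    if len(lines) < 2 or lines[1].strip() != "channel\ttime_ms":
        raise FormatError(f"{path}: expected 'channel\\ttime_ms' header on line 2")
    per_channel = [[] for _ in range(n_channels)]
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            ch = int(parts[0])
            t = float(parts[1])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: malformed line {lineno}: {line!r}") from exc
        if not 0 <= ch < n_channels:
            raise FormatError(f"{path}: line {lineno}: channel {ch} out of range")
        if not 0 <= t < duration:
            raise FormatError(f"{path}: line {lineno}: time {t} out of [0, duration)")
        per_channel[ch].append(t)
    try:
        return SpikeTrainSet(
            [np.array(ts) for ts in per_channel], duration=duration, periodic=periodic
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_traces(traces: TraceBundle, path) -> None:
    """Delimited trace table, full float precision (round-trip exact)."""
    traces.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_traces(path) -> TraceBundle:
    frame = pd.read_csv(path, sep="\t")
    missing = set(("time_ms",) + TraceBundle._FIELDS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing trace columns {sorted(missing)}")
    return TraceBundle.from_frame(frame)


def write_manifest(out_dir, config: ExperimentConfig | dict, seed: int) -> Path:
    """Checksummed inventory of a run's outputs."""
    out_dir = Path(out_dir)
    files = {}
    for p in sorted(out_dir.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        files[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    snapshot = config_to_dict(config) if isinstance(config, ExperimentConfig) else config
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": snapshot,
        "files": files,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# presets and CLI


def _preset_ramp_orthogonal():
    return {
        "plasticity": {"alpha": 0.985, "eta": 50.0, "tau": 9.0},
        "period": 2000.0,
        "n_training_periods": 500,
        "input": {"kind": "orthogonal", "n_synapses": 500},
        "schedule": {"kind": "pulse", "start": 1800.0, "stop": 2000.0, "g_E": 15.0},
    }


def _preset_ramp_frozen():
    return {
        "plasticity": {"alpha": 0.985, "eta": 50.0, "tau": 9.0},
        "period": 2000.0,
        "n_training_periods": 150,
        "input": {"kind": "frozen_poisson", "n_synapses": 1000, "rate": 0.002},
        "schedule": {"kind": "pulse", "start": 1800.0, "stop": 2000.0, "g_E": 15.0},
    }


def _preset_ramp_poisson():
    return {
        "plasticity": {"alpha": 0.985, "eta": 0.5, "tau": 9.0},
        "period": 2000.0,
        "n_training_periods": 400,
        "input": {"kind": "inhomogeneous_poisson", "n_synapses": 500, "rate": 0.02},
        "schedule": {"kind": "pulse", "start": 1800.0, "stop": 2000.0, "g_E": 15.0},
    }


def _preset_time_series():
    return {
        "plasticity": {"alpha": 0.9, "eta": 0.5, "tau": 2.0},
        "period": 2000.0,
        "n_training_periods": 100,
        "input": {"kind": "frozen_poisson", "n_synapses": 2000, "rate": 0.02},
        "schedule": {"kind": "multiharmonic", "g0": 6.0},
    }


def _preset_paired_associate():
    return {
        "plasticity": {"alpha": 0.985, "eta": 0.5, "tau": 9.0},
        "n_training_periods": 60,
        "input": {"kind": "stm", "n_stm": 2000},
        "schedule": {
            "kind": "paired", "sample_ms": 500.0, "delay_ms": 1000.0,
            "target_ms": 200.0, "iti_min": 3000.0, "iti_max": 10000.0,
            "g_E_A1": [5.0, 0.0, 5.0], "g_E_A2": [0.0, 5.0, 2.5],
        },
        "probe": {"n_trials": 5},
    }


def _preset_sequence_replay():
    return {
        "plasticity": {"alpha": 0.93, "eta": 5.0, "tau": 9.0},
        "n_training_periods": 300,
        "input": {"kind": "recurrent"},
        "schedule": {
            "kind": "sequential", "n_groups": 4, "group_size": 50,
            "pulse_ms": 100.0, "g_E": 20.0, "recall_ms": 20.0,
            "recall_window": 800.0,
        },
    }


PRESETS = {
    "ramp_orthogonal": _preset_ramp_orthogonal,
    "ramp_frozen": _preset_ramp_frozen,
    "ramp_poisson": _preset_ramp_poisson,
    "time_series": _preset_time_series,
    "paired_associate": _preset_paired_associate,
    "sequence_replay": _preset_sequence_replay,
}


def _scale_preset(data: dict, scale: float) -> dict:
    """Shrink population sizes and repetition counts proportionally."""
    if scale == 1.0:
        return data
    data = json.loads(json.dumps(data))  # deep copy
    data["n_training_periods"] = max(1, int(round(data["n_training_periods"] * scale)))
    inp = data.get("input", {})
    for key in ("n_synapses", "n_stm"):
        if key in inp:
            inp[key] = max(1, int(round(inp[key] * scale)))
    sched = data.get("schedule", {})
    if "group_size" in sched:
        sched["group_size"] = max(1, int(round(sched["group_size"] * scale)))
    return data


EXAMPLE_CHAIN = {
    "T": [[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]],
    "B": [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
    "r_I": [0.05, 0.0, 0.0],
    "lam": 1.0,
    "gamma": 0.3,
    "alpha": 0.5,
}


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _cmd_run(args) -> int:
    if args.config:
        config = load_config(args.config)
        data = config_to_dict(config)
    else:
        data = PRESETS[args.preset]()
    data = _scale_preset(data, args.scale)
    data["seed"] = args.seed
    config = dict_to_config(data)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    result = run_experiment(config)
    (out / "metrics.json").write_text(
        json.dumps(result.metrics, indent=2, sort_keys=True, default=_json_default)
        + "\n"
    )
    np.savetxt(out / "weights.tsv", np.atleast_2d(result.weights), delimiter="\t",
               fmt="%.17g")
    if result.traces is not None:
        write_traces(result.traces, out / "traces.tsv")
    if result.theory_rate is not None:
        np.savetxt(out / "theory_rate.tsv", result.theory_rate, fmt="%.17g")
    write_manifest(out, config, args.seed)
    return 0


def _cmd_theory(args) -> int:
    if args.config:
        data = json.loads(Path(args.config).read_text())
    else:
        data = dict(EXAMPLE_CHAIN)
    alpha = data.pop("alpha", 0.5)
    if args.which == "periodic":
        g = np.asarray(data["phi_Ustar"], dtype=float)
        out = periodic_fixed_point(
            g, data.get("lam", 1.0), alpha, data.get("tau", 9.0),
            data.get("period", g.size * 0.1), data.get("dt", 0.1),
        )
        payload = {"phi_Vstar": out}
    else:
        td_spec = data.pop("td", {})
        env = MarkovEnvironment(**data)
        if args.which == "markov":
            payload = {"r_V": markov_fixed_point(env, alpha)}
        else:  # td
            td = TDParams(**td_spec) if td_spec else TDParams(gamma_TD=env.gamma)
            traj, deltas = td_lambda_learn(env, alpha, td, seed=args.seed,
                                           n_steps=args.n_steps)
            payload = {
                "value_function": value_function(env, alpha, td),
                "final_weights": traj[-1],
                "mean_delta": float(np.mean(deltas)),
            }
    text = json.dumps(payload, indent=2, sort_keys=True, default=_json_default)
    print(text)
    if args.out:
        out = Path(args.out)
        out.mkdir(parents=True, exist_ok=True)
        (out / "theory.json").write_text(text + "\n")
        write_manifest(out, data, args.seed)
    return 0


def _build_parser() -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(
        prog="procode",
        description="Prospective-coding simulations and fixed-point theory",
    )
    sub = parser.add_subparsers(dest="command", required=True)

    p_run = sub.add_parser("run", help="run an experiment preset or config file")
    p_run.add_argument("preset", choices=sorted(PRESETS), nargs="?",
                       default="ramp_orthogonal")
    p_run.add_argument("--config", default=None, help="config file overriding the preset")
    p_run.add_argument("--seed", type=int, default=0)
    p_run.add_argument("--out", default="procode_out")
    p_run.add_argument("--scale", type=float, default=1.0,
                       help="shrink populations and repetitions by this factor")
    p_run.set_defaults(func=_cmd_run)

    p_th = sub.add_parser("theory", help="evaluate the analytic fixed points")
    p_th.add_argument("which", choices=("periodic", "markov", "td"))
    p_th.add_argument("--config", default=None, help="JSON file with the environment")
    p_th.add_argument("--seed", type=int, default=0)
    p_th.add_argument("--n-steps", type=int, default=20000)
    p_th.add_argument("--out", default=None)
    p_th.set_defaults(func=_cmd_theory)
    return parser


def cli_main(argv=None) -> int:
    """Entry point; returns the process exit status."""
    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:
        return int(exc.code or 0)
    try:
        return args.func(args)
    except (FormatError, ValueError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 2
    except RuntimeError as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 3


def main() -> None:  # console-script shim
    sys.exit(cli_main())
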