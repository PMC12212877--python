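"""Session-bundle serialization.

A bundle is a directory of plain-text files: ``config.json`` (session
config, eye parameters, ground-truth neuron parameters, schema version),
``trials.csv``, ``eye.csv``, ``spikes.csv``, and ``neurons.csv``.  All
CSVs are RFC-4180 with a header row, UTF-8, '.' decimal separator.  The
round trip is lossless: floats are written in shortest round-trip
representation, so ``read_bundle(write_bundle(b))`` equals ``b``
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import EyeTrace
from .synth import (
    EyeParams,
    GroundTruthNeuron,
    NeuronRecord,
    SessionBundle,
    SessionConfig,
    Trial,
)

__all__ = ["write_bundle", "read_bundle", "BundleIOError", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

_TRIAL_COLUMNS = [f.name for f in dataclasses.fields(Trial)]
_NEURON_COLUMNS = ["neuron_id", "extrafoveal_onset_elevated",
                   "control_window_rate", "included"]


class BundleIOError(OSError):
    """Raised when a bundle file is missing, truncated, or schema-invalid."""


def write_bundle(bundle: SessionBundle, path: str | Path) -> Path:
    """Write a session bundle to a directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    config = {
        "schema_version": SCHEMA_VERSION,
        "session": dataclasses.asdict(bundle.config),
        "eye_params": dataclasses.asdict(bundle.eye_params),
        "ground_truth": [dataclasses.asdict(gt) for gt in bundle.ground_truth],
    }
    (path / "config.json").write_text(json.dumps(config, indent=2), encoding="utf-8")

    trials = pd.DataFrame(
        [{c: getattr(tr, c) for c in _TRIAL_COLUMNS} for tr in bundle.trials],
        columns=_TRIAL_COLUMNS,
    )
    trials.to_csv(path / "trials.csv", index=False, float_format="%.17g")

    eye_rows = []
    for tid in sorted(bundle.eye_traces):
        tr = bundle.eye_traces[tid]
        eye_rows.append(pd.DataFrame({
            "trial_id": np.full(len(tr.t), tid, dtype=int),
            "t_ms": tr.t, "x_deg": tr.x, "y_deg": tr.y,
        }))
    eye = (pd.concat(eye_rows, ignore_index=True) if eye_rows
           else pd.DataFrame(columns=["trial_id", "t_ms", "x_deg", "y_deg"]))
    eye.to_csv(path / "eye.csv", index=False, float_format="%.17g")

    spike_rows = []
    for rec in bundle.neurons:
        for tid in sorted(rec.spikes):
            s = rec.spikes[tid]
            spike_rows.append(pd.DataFrame({
                "neuron_id": np.full(len(s), rec.neuron_id, dtype=int),
                "trial_id": np.full(len(s), tid, dtype=int),
                "spike_t_ms": s,
            }))
    spikes = (pd.concat(spike_rows, ignore_index=True) if spike_rows
              else pd.DataFrame(columns=["neuron_id", "trial_id", "spike_t_ms"]))
    spikes.to_csv(path / "spikes.csv", index=False, float_format="%.17g")

    neurons = pd.DataFrame(
        [{
            "neuron_id": rec.neuron_id,
            "extrafoveal_onset_elevated": rec.extrafoveal_onset_elevated,
            "control_window_rate": rec.control_window_rate,
            "included": rec.included,
        } for rec in bundle.neurons],
        columns=_NEURON_COLUMNS,
    )
    neurons.to_csv(path / "neurons.csv", index=False, float_format="%.17g")
    return path


def _read_csv(path: Path, name: str, columns: list[str]) -> pd.DataFrame:
    f = path / name
    if not f.exists():
        raise BundleIOError(f"bundle file missing: {name}")
    try:
        df = pd.read_csv(f, float_precision="round_trip")
    except Exception as exc:  # malformed / truncated file
        raise BundleIOError(f"cannot parse bundle file {name}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise BundleIOError(f"bundle file {name} lacks columns {missing}")
    return df


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def _opt_bool(value) -> bool | None:
    return None if pd.isna(value) else bool(value)


def read_bundle(path: str | Path) -> SessionBundle:
    """Read a bundle directory written by :func:`write_bundle`."""
    path = Path(path)
    cfg_file = path / "config.json"
    if not cfg_file.exists():
        raise BundleIOError("bundle file missing: config.json")
    try:
        raw = json.loads(cfg_file.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise BundleIOError(f"cannot parse bundle file config.json: {exc}") from exc
    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise BundleIOError(
            f"config.json: unknown schema_version {version!r} "
            f"(expected {SCHEMA_VERSION})")
    try:
        session = raw["session"]
        for key in ("fixation_to_stim_delay", "stim_to_go_delay", "condition_mix"):
            session[key] = tuple(session[key])
        config = SessionConfig(**session)
        eye_params = EyeParams(**raw["eye_params"])
        ground_truth = [GroundTruthNeuron(**g) for g in raw["ground_truth"]]
    except (KeyError, TypeError, ValueError) as exc:
        raise BundleIOError(f"config.json: invalid field: {exc}") from exc

    tdf = _read_csv(path, "trials.csv", _TRIAL_COLUMNS)
    trials = []
    for row in tdf.itertuples(index=False):
        d = row._asdict()
        trials.append(Trial(
            trial_id=int(d["trial_id"]), condition=str(d["condition"]),
            mode=str(d["mode"]), pre_sf=str(d["pre_sf"]), post_sf=str(d["post_sf"]),
            pre_shape=str(d["pre_shape"]), post_shape=str(d["post_shape"]),
            target_x=float(d["target_x"]), target_y=float(d["target_y"]),
            fix_on_ms=float(d["fix_on_ms"]), stim_on_ms=float(d["stim_on_ms"]),
            go_ms=_opt(d["go_ms"]), update_ms=_opt(d["update_ms"]),
            trial_end_ms=float(d["trial_end_ms"]),
            gt_saccade_on_ms=_opt(d["gt_saccade_on_ms"]),
            gt_saccade_end_ms=_opt(d["gt_saccade_end_ms"]),
            gt_landing_x=_opt(d["gt_landing_x"]), gt_landing_y=_opt(d["gt_landing_y"]),
            gt_catchup_on_ms=_opt(d["gt_catchup_on_ms"]),
        ))

    edf = _read_csv(path, "eye.csv", ["trial_id", "t_ms", "x_deg", "y_deg"])
    traces: dict[int, EyeTrace] = {}
    if len(edf):
        for tid, grp in edf.groupby("trial_id", sort=True):
            traces[int(tid)] = EyeTrace(
                t=grp["t_ms"].to_numpy(float),
                x=grp["x_deg"].to_numpy(float),
                y=grp["y_deg"].to_numpy(float),
                sampling_rate=config.sampling_rate,
            )

    sdf = _read_csv(path, "spikes.csv", ["neuron_id", "trial_id", "spike_t_ms"])
    ndf = _read_csv(path, "neurons.csv", _NEURON_COLUMNS)
    by_neuron: dict[int, dict[int, np.ndarray]] = {}
    if len(sdf):
        for (nid, tid), grp in sdf.groupby(["neuron_id", "trial_id"], sort=True):
            by_neuron.setdefault(int(nid), {})[int(tid)] = \
                grp["spike_t_ms"].to_numpy(float)
    trial_ids = [tr.trial_id for tr in trials]
    neurons = []
    for row in ndf.itertuples(index=False):
        d = row._asdict()
        nid = int(d["neuron_id"])
        spikes = by_neuron.get(nid, {})
        # trials with no spikes still get an (empty) entry
        full = {tid: spikes.get(tid, np.empty(0)) for tid in trial_ids}
        neurons.append(NeuronRecord(
            neuron_id=nid, spikes=full,
            extrafoveal_onset_elevated=_opt_bool(d["extrafoveal_onset_elevated"]),
            control_window_rate=_opt(d["control_window_rate"]),
            included=_opt_bool(d["included"]),
        ))

    return SessionBundle(
        config=config, eye_params=eye_params, trials=trials,
        eye_traces=traces, neurons=neurons, ground_truth=ground_truth,
    )
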