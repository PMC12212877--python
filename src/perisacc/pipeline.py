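"""End-to-end orchestration: generate -> detect -> screen -> quantify -> stats.

Runs the full analysis on a session bundle (synthetic or read from disk)
and writes machine-readable outputs: ``saccades.csv``, ``screening.csv``,
``responses.csv``, ``modulation.csv``, ``roc_timecourse.csv``,
``summary.json``, and a human-readable ``report.txt``.  Every output is
registered in ``manifest.json`` together with a hash of the run
configuration; stages refuse upstream files whose stamp does not match
the current configuration.  Re-running with an identical configuration
reproduces all outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import responses as resp
from . import stats as st
from .io import read_bundle, write_bundle
from .synth import (
    EyeParams,
    SessionBundle,
    SessionConfig,
    child_rng,
    sample_population,
)

__all__ = ["RunConfig", "run_pipeline", "make_report", "STANDARD_CONTRASTS"]

logger = logging.getLogger("perisacc")

CHANGE_CONDITIONS = ("sf_change", "shape_change", "combined_change")

#: The standard contrast table: all change conditions for both foveated
#: spatial frequencies with real saccades, plus the spatial-frequency
#: contrasts under simulated saccades.
STANDARD_CONTRASTS = tuple(
    [("real_saccade", sf, cond) for sf in ("low", "high") for cond in CHANGE_CONDITIONS]
    + [("simulated_saccade", sf, "sf_change") for sf in ("low", "high")]
)

_ALL_STAGES = ("generate", "detect", "screen", "quantify", "stats", "report")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; defaults are the package defaults."""

    output_dir: str
    bundle_dir: str | None = None  # read this bundle instead of generating
    seed: int = 0
    stages: tuple[str, ...] = _ALL_STAGES
    # generation
    n_trials: int = 800
    n_neurons: int = 40
    mode: str = "real_saccade"
    include_eye_traces: bool = True
    write_generated_bundle: bool = True
    gain_sf_change: float = 1.5
    gain_shape_change_low_sf: float = 1.15
    gain_shape_change_high_sf: float = 1.4
    # saccade detection
    speed_threshold: float = 20.0
    min_duration: float = 8.0
    min_intersaccadic_interval: float = 20.0
    smoothing_halfwidth: float = 5.0
    # response quantification
    kernel_sd: float = 10.0
    grid_step: float = 1.0
    peak_of_mean: bool = False
    alignment: str = "update"
    span: tuple[float, float] = resp.DEFAULT_SPAN
    # statistics
    n_perm: int = 10_000
    roc_bin_width: float = 50.0
    roc_step: float = 10.0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _manifest_path(outdir: Path) -> Path:
    return outdir / "manifest.json"


def _load_manifest(outdir: Path) -> dict:
    p = _manifest_path(outdir)
    return json.loads(p.read_text()) if p.exists() else {}


def _stamp(outdir: Path, filename: str, config_hash: str) -> None:
    manifest = _load_manifest(outdir)
    digest = hashlib.sha256((outdir / filename).read_bytes()).hexdigest()[:16]
    manifest[filename] = {"config_hash": config_hash, "sha256": digest}
    _manifest_path(outdir).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _check_stamp(outdir: Path, filename: str, config_hash: str) -> None:
    manifest = _load_manifest(outdir)
    entry = manifest.get(filename)
    if entry is None:
        raise RuntimeError(f"{filename}: not registered in manifest.json "
                           "(stale or missing upstream output)")
    if entry["config_hash"] != config_hash:
        raise RuntimeError(
            f"{filename}: written under config {entry['config_hash']}, "
            f"current config is {config_hash}; refusing stale output")


# ---------------------------------------------------------------------------
# stages


def _stage_generate(config: RunConfig, outdir: Path) -> SessionBundle:
    if config.bundle_dir is not None:
        logger.info("reading bundle from %s", config.bundle_dir)
        return read_bundle(config.bundle_dir)
    from .synth import default_neuron, generate_session

    session = SessionConfig(
        n_trials=config.n_trials, n_neurons=config.n_neurons,
        mode=config.mode, seed=config.seed,
    )
    base = default_neuron(
        gain_sf_change=config.gain_sf_change,
        gain_shape_change_low_sf=config.gain_shape_change_low_sf,
        gain_shape_change_high_sf=config.gain_shape_change_high_sf,
    )
    neurons = sample_population(config.n_neurons, config.seed, base=base)
    bundle = generate_session(session, EyeParams(), neurons,
                              include_eye_traces=config.include_eye_traces)
    logger.info("generated %d trials x %d neurons (%s)",
                config.n_trials, config.n_neurons, config.mode)
    if config.write_generated_bundle:
        write_bundle(bundle, outdir / "bundle")
    return bundle


def _stage_detect(config: RunConfig, outdir: Path, bundle: SessionBundle) -> pd.DataFrame:
    """Detect saccades, apply landing acceptance, validate update timing."""
    params = kin.DetectionParams(
        speed_threshold=config.speed_threshold,
        min_duration=config.min_duration,
        min_intersaccadic_interval=config.min_intersaccadic_interval,
        smoothing_halfwidth=config.smoothing_halfwidth,
    )
    rows = []
    for tr in bundle.trials:
        row = {
            "trial_id": tr.trial_id, "onset_ms": None, "end_ms": None,
            "amplitude_deg": None, "peak_speed_deg_s": None,
            "landing_x_deg": None, "landing_y_deg": None,
            "intra_saccadic": None, "speed_at_update_end": None,
            "catchup_latency_ms": None, "accepted": False, "exclusion": "",
        }
        if tr.mode == "simulated_saccade":
            row["accepted"] = True
            row["exclusion"] = ""
            rows.append(row)
            continue
        trace = bundle.eye_traces.get(tr.trial_id)
        if trace is None:
            # bundle without traces: trust the generator's bookkeeping
            row.update({"accepted": True})
            rows.append(row)
            continue
        events = [e for e in kin.detect_saccades(trace, params)
                  if e.amplitude >= kin.MICROSACCADE_AMPLITUDE_DEG]
        if not events:
            row["exclusion"] = "no_saccade"
            logger.info("trial %d excluded: no saccade detected", tr.trial_id)
            rows.append(row)
            continue
        primary = events[0]
        timing = kin.validate_update_timing(
            primary, tr.update_ms, trace, config.smoothing_halfwidth)
        latency = kin.first_catchup_latency(trace, primary, params)
        ok_landing = kin.accept_landing(primary, (tr.target_x, tr.target_y))
        accepted = ok_landing and timing["intra_saccadic"]
        if not ok_landing:
            row["exclusion"] = "landing"
            logger.info("trial %d excluded: landing > 2 deg from target", tr.trial_id)
        elif not timing["intra_saccadic"]:
            row["exclusion"] = "update_timing"
            logger.info("trial %d excluded: update not intra-saccadic", tr.trial_id)
        row.update({
            "onset_ms": primary.onset, "end_ms": primary.end,
            "amplitude_deg": primary.amplitude,
            "peak_speed_deg_s": primary.peak_speed,
            "landing_x_deg": primary.landing[0], "landing_y_deg": primary.landing[1],
            "intra_saccadic": timing["intra_saccadic"],
            "speed_at_update_end": timing["speed_at_update_end"],
            "catchup_latency_ms": latency, "accepted": accepted,
        })
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "saccades.csv", index=False)
    _stamp(outdir, "saccades.csv", config.config_hash())
    return df


def _stage_screen(config: RunConfig, outdir: Path, bundle: SessionBundle,
                  accepted: dict[int, bool]) -> pd.DataFrame:
    trials = [tr for tr in bundle.trials if accepted.get(tr.trial_id, True)]
    rows = []
    for rec in bundle.neurons:
        res = resp.screen_neuron(rec.spikes, trials, neuron_id=rec.neuron_id)
        rec.extrafoveal_onset_elevated = res.extrafoveal_onset_elevated
        rec.control_window_rate = res.control_window_rate
        rec.included = res.included
        if not res.included:
            reason = ("onset_elevation" if res.extrafoveal_onset_elevated
                      else "low_control_rate")
            logger.info("neuron %d excluded: %s", rec.neuron_id, reason)
        rows.append({
            "neuron_id": res.neuron_id,
            "extrafoveal_onset_elevated": res.extrafoveal_onset_elevated,
            "control_window_rate": res.control_window_rate,
            "included": res.included,
        })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "screening.csv", index=False)
    _stamp(outdir, "screening.csv", config.config_hash())
    return df


def _rasters_for(config: RunConfig, bundle: SessionBundle, rec, post_sf: str,
                 accepted: dict[int, bool]):
    trials = [tr for tr in bundle.trials
              if tr.post_sf == post_sf and accepted.get(tr.trial_id, True)]
    if not trials:
        return {}
    return resp.align_spikes(rec.spikes, trials, event=config.alignment,
                             span=config.span, neuron_id=rec.neuron_id)


def _stage_quantify(config: RunConfig, outdir: Path, bundle: SessionBundle,
                    accepted: dict[int, bool]) -> pd.DataFrame:
    rows = []
    for rec in bundle.neurons:
        if rec.included is False:
            continue
        for post_sf in ("low", "high"):
            window = resp.measurement_window(post_sf)
            rasters = _rasters_for(config, bundle, rec, post_sf, accepted)
            for cond, raster in rasters.items():
                m = resp.peak_response(raster, window, config.kernel_sd,
                                       config.grid_step, config.peak_of_mean)
                for tid, pk in zip(raster.trial_ids, m.per_trial_peaks):
                    rows.append({
                        "neuron_id": rec.neuron_id, "condition": cond,
                        "post_sf": post_sf, "trial_id": tid,
                        "peak_rate_spk_s": pk,
                        "window_lo_ms": window[0], "window_hi_ms": window[1],
                    })
    df = pd.DataFrame(rows, columns=["neuron_id", "condition", "post_sf",
                                     "trial_id", "peak_rate_spk_s",
                                     "window_lo_ms", "window_hi_ms"])
    df.to_csv(outdir / "responses.csv", index=False)
    _stamp(outdir, "responses.csv", config.config_hash())
    return df


def _stage_stats(config: RunConfig, outdir: Path, bundle: SessionBundle,
                 responses: pd.DataFrame, accepted: dict[int, bool]) -> dict:
    mode = bundle.config.mode
    perm_rng = child_rng(config.seed, 10)
    mod_rows = []
    summary: dict = {"mode": mode, "contrasts": {}}
    mi_by_contrast: dict[tuple[str, str], dict[int, float]] = {}

    for post_sf in ("low", "high"):
        sub = responses[responses["post_sf"] == post_sf]
        for cond in CHANGE_CONDITIONS:
            key = f"{cond}|{post_sf}"
            mis, results = [], []
            for nid, grp in sub.groupby("neuron_id"):
                ctrl = grp.loc[grp["condition"] == "control", "peak_rate_spk_s"].to_numpy()
                chg = grp.loc[grp["condition"] == cond, "peak_rate_spk_s"].to_numpy()
                if len(ctrl) < 2 or len(chg) < 2:
                    continue
                r_c, r_g = float(ctrl.mean()), float(chg.mean())
                mi = st.modulation_index(r_g, r_c)
                p = st.permutation_test(chg, ctrl, n_perm=config.n_perm, seed=perm_rng)
                res = st.ModulationResult(
                    neuron_id=int(nid), condition_pair=(cond, "control"),
                    r_change=r_g, r_control=r_c, mi=mi, perm_p=p,
                    individually_significant=p < st.SIGNIFICANCE_ALPHA)
                results.append(res)
                mis.append(mi)
                mi_by_contrast.setdefault((cond, post_sf), {})[int(nid)] = mi
                mod_rows.append({
                    "contrast": key, "neuron_id": int(nid),
                    "condition": cond, "post_sf": post_sf,
                    "r_change": r_g, "r_control": r_c, "mi": mi,
                    "perm_p": p,
                    "individually_significant": res.individually_significant,
                })
            if not results:
                continue
            mis = np.asarray(mis)
            prop = st.proportion_elevated(results)
            summary["contrasts"][key] = {
                "n_neurons": len(mis),
                "mi_mean": float(mis.mean()),
                "mi_median": float(np.median(mis)),
                "signed_rank_p": st.signed_rank(mis) if len(mis) >= 2 else None,
                "n_individually_significant": int(sum(
                    r.individually_significant for r in results)),
                "fraction_elevated": prop["fraction"],
                "effect_detected": bool(
                    len(mis) >= 2 and np.median(mis) > 0
                    and st.signed_rank(mis) < st.SIGNIFICANCE_ALPHA),
            }

    # additivity of combined changes (per foveated SF, when all three exist)
    for post_sf in ("low", "high"):
        triples = [
            (mi_by_contrast.get(("sf_change", post_sf), {}),
             mi_by_contrast.get(("shape_change", post_sf), {}),
             mi_by_contrast.get(("combined_change", post_sf), {}))
        ]
        a, b, c = triples[0]
        shared = sorted(set(a) & set(b) & set(c))
        if len(shared) >= 3:
            add = st.additivity_analysis(
                [a[n] for n in shared], [b[n] for n in shared],
                [c[n] for n in shared])
            summary[f"additivity_{post_sf}"] = {
                "r": add["r"], "p": add["p"], "n": len(shared)}

    mod_df = pd.DataFrame(mod_rows)
    mod_df.to_csv(outdir / "modulation.csv", index=False)
    _stamp(outdir, "modulation.csv", config.config_hash())

    # population ROC timecourse: per-neuron AUC(t), averaged across neurons
    # with a 95% normal-approximation band (mean +/- 1.96 SEM)
    roc_rows = []
    for post_sf in ("low", "high"):
        cond = "sf_change"
        aucs = []
        t_grid = None
        for rec in bundle.neurons:
            if rec.included is False:
                continue
            rasters = _rasters_for(config, bundle, rec, post_sf, accepted)
            if "control" not in rasters or cond not in rasters:
                continue
            if (rasters["control"].n_trials < 5 or rasters[cond].n_trials < 5):
                continue
            tc = st.roc_timecourse(
                rasters["control"], rasters[cond],
                bin_width=config.roc_bin_width, step=config.roc_step,
                n_boot=0, span=config.span)
            aucs.append(tc.auc)
            t_grid = tc.t
        if not aucs:
            continue
        arr = np.asarray(aucs)
        mean = arr.mean(axis=0)
        sem = (arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
               if arr.shape[0] > 1 else np.zeros_like(mean))
        for tval, a_, s_ in zip(t_grid, mean, sem):
            roc_rows.append({
                "contrast": f"{cond}|{post_sf}", "t_ms": tval, "auc": a_,
                "ci_lo": a_ - 1.96 * s_, "ci_hi": a_ + 1.96 * s_,
                "n_neurons": arr.shape[0],
            })
    roc_df = pd.DataFrame(roc_rows, columns=["contrast", "t_ms", "auc",
                                             "ci_lo", "ci_hi", "n_neurons"])
    roc_df.to_csv(outdir / "roc_timecourse.csv", index=False)
    _stamp(outdir, "roc_timecourse.csv", config.config_hash())

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    _stamp(outdir, "summary.json", config.config_hash())
    return summary


def make_report(outdir: str | Path, config: RunConfig | None = None) -> str:
    """Render the contrast tables from a finished run's outputs.

    One row per standard contrast (six real-saccade condition pairs and
    the two simulated-saccade spatial-frequency pairs) with n, mean and
    median modulation index, the population signed-rank p, and the count
    of individually significant neurons; contrasts without data are
    marked absent.  With zero included neurons the per-neuron exclusion
    reasons are listed instead.
    """
    outdir = Path(outdir)
    summary_file = outdir / "summary.json"
    if not summary_file.exists():
        raise FileNotFoundError(f"missing upstream file: {summary_file}")
    if config is not None:
        _check_stamp(outdir, "summary.json", config.config_hash())
    summary = json.loads(summary_file.read_text())
    mode = summary.get("mode", "real_saccade")

    lines = ["contrast tables (modulation index per condition pair)", ""]
    header = (f"{'mode':<18} {'foveated_sf':<12} {'change':<16} {'n':>4} "
              f"{'mi_mean':>9} {'mi_median':>10} {'p':>10} {'n_sig':>6}")
    lines += [header, "-" * len(header)]
    for c_mode, sf, cond in STANDARD_CONTRASTS:
        key = f"{cond}|{sf}"
        entry = summary["contrasts"].get(key) if c_mode == mode else None
        if entry is None:
            lines.append(f"{c_mode:<18} {sf:<12} {cond:<16} {'absent':>4}")
            continue
        lines.append(
            f"{c_mode:<18} {sf:<12} {cond:<16} {entry['n_neurons']:>4} "
            f"{entry['mi_mean']:>9.4f} {entry['mi_median']:>10.4f} "
            f"{entry['signed_rank_p']:>10.3g} "
            f"{entry['n_individually_significant']:>6}")
    for sf in ("low", "high"):
        add = summary.get(f"additivity_{sf}")
        if add:
            lines.append("")
            lines.append(
                f"additivity ({sf}-SF landing): r = {add['r']:.4f}, "
                f"p = {add['p']:.3g}, n = {add['n']}")

    screening_file = outdir / "screening.csv"
    if screening_file.exists():
        sdf = pd.read_csv(screening_file)
        if len(sdf) and not sdf["included"].any():
            lines += ["", "no neurons included after screening:"]
            for row in sdf.itertuples(index=False):
                reason = ("onset_elevation" if row.extrafoveal_onset_elevated
                          else f"control rate {row.control_window_rate:.2f} spk/s < 5")
                lines.append(f"  neuron {row.neuron_id}: {reason}")
    text = "\n".join(lines) + "\n"
    report_file = outdir / "report.txt"
    report_file.write_text(text)
    if config is not None:
        _stamp(outdir, "report.txt", config.config_hash())
    return text


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages end to end; returns the run report dict."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        report: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                        "stages": {}}
        bundle = _stage_generate(config, outdir)
        report["stages"]["generate"] = {
            "n_trials": len(bundle.trials), "n_neurons": len(bundle.neurons),
            "mode": bundle.config.mode}

        accepted: dict[int, bool] = {tr.trial_id: True for tr in bundle.trials}
        if "detect" in config.stages:
            sacc = _stage_detect(config, outdir, bundle)
            accepted = dict(zip(sacc["trial_id"], sacc["accepted"].astype(bool)))
            report["stages"]["detect"] = {
                "n_rows": len(sacc), "n_accepted": int(sacc["accepted"].sum())}

        if "screen" in config.stages:
            scr = _stage_screen(config, outdir, bundle, accepted)
            report["stages"]["screen"] = {
                "n_rows": len(scr), "n_included": int(scr["included"].sum())}

        responses = pd.DataFrame()
        if "quantify" in config.stages:
            responses = _stage_quantify(config, outdir, bundle, accepted)
            report["stages"]["quantify"] = {"n_rows": len(responses)}

        if "stats" in config.stages:
            summary = _stage_stats(config, outdir, bundle, responses, accepted)
            report["stages"]["stats"] = {
                "n_contrasts": len(summary["contrasts"])}
            report["headline"] = summary["contrasts"]

        if "report" in config.stages and (outdir / "summary.json").exists():
            make_report(outdir, config)
            report["stages"]["report"] = {"file": "report.txt"}

        (outdir / "run_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str))
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
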