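"""End-to-end analysis drivers tying the stages together.

Each experiment mode runs raw traces (read from disk or freshly simulated)
through QC, HMM idealization and the kinetic summaries, and writes a
result bundle: per-trace tables, a machine-readable ``summary.json``
carrying a provenance record (config hash, seed, package version), and an
audit log with one structured record per rejected trace.  Analysis never
touches the truth sidecar — ground truth exists only for tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dwell import (
    classify_injection_trace,
    dwell_histogram,
    estimate_rates,
    excursion_statistics,
    extract_dwells,
    median_dwell,
    state_occupancy,
)
from .ensemble import fit_single_exponential, relative_binding
from .hmm import fit_hmm, idealize_traces
from .io import read_timecourse, read_traces, write_timecourse, write_traces, write_truth
from .population import build_histogram, fit_two_gaussians, report_state_fractions
from .scenarios import BindingScenario, load_scenario
from .simulate import (
    simulate_binding_scenario,
    simulate_equilibrium_experiment,
    simulate_injection_experiment,
)
from .traces import SelectionPolicy, compute_fret, detect_photobleach, estimate_bleach_rate, select_traces

logger = logging.getLogger("pausekin")

__all__ = ["RunConfig", "run_pipeline", "analyze_injection", "analyze_equilibrium"]


@dataclasses.dataclass
class RunConfig:
    """One analysis run: experiment mode, inputs, parameters, outputs."""

    mode: str  # injection | equilibrium | population | binding | frameshift
    traces_path: str | None = None
    timecourse_path: str | None = None
    control_timecourse_path: str | None = None
    scenario: str | None = None  # packaged name or TOML path, used when simulating
    output_dir: str = "results"
    seed: int = 0
    injection_time: float = 10.0
    stability_threshold: float = 4.0
    dwell_bin_width: float = 2.0
    fret_bin_width: float = 0.01
    smoothing_window: int = 5
    hmm_tol: float = 1e-6
    hmm_max_iter: int = 500
    min_pre_bleach_frames: int = 20
    minus1_signal: float | None = None
    normalization_signal: float | None = None
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        payload.pop("log_level")
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "pausekin_version": __version__,
        "config": dataclasses.asdict(config),
    }


def _qc(raw_traces, config: RunConfig):
    # ensemble intensity reference: robust against traces dark from frame 0
    ref = float(
        np.median(
            [np.median(tr.acceptor[:20] + tr.donor[:20]) for tr in raw_traces]
        )
    )
    reports = [detect_photobleach(tr, reference_total=ref) for tr in raw_traces]
    frets = [compute_fret(tr, reference_total=ref) for tr in raw_traces]
    policy = SelectionPolicy(min_pre_bleach_frames=config.min_pre_bleach_frames)
    accepted, audit = select_traces(frets, reports, policy)
    for rec in audit:
        if not rec["accepted"]:
            logger.info("rejected trace %(trace_id)s: %(reason)s", rec)
    if not accepted:
        logger.warning("no traces passed selection")
    return reports, accepted, audit


def analyze_injection(raw_traces, config: RunConfig) -> dict:
    """QC -> pooled HMM -> Viterbi -> tau_bd / tau_trl / excursions."""
    reports, accepted, audit = _qc(raw_traces, config)
    model = fit_hmm(accepted, tol=config.hmm_tol, max_iter=config.hmm_max_iter)
    ideals = idealize_traces(model, accepted)
    outcomes = [
        classify_injection_trace(i, config.injection_time, config.stability_threshold)
        for i in ideals
    ]
    usable = [o for o in outcomes if not o.anomalous]
    bd = [o.tau_bd_s for o in usable]
    bd_cens = [o.tau_bd_s is None for o in usable]
    bd_vals = [o.tau_bd_s if o.tau_bd_s is not None else o.tau_bd_censor_at_s for o in usable]
    trl_pairs = [
        (o.tau_trl_s if o.tau_trl_s is not None else o.tau_trl_censor_at_s, o.tau_trl_s is None)
        for o in usable
        if o.tau_bd_s is not None
    ]
    summary: dict = {
        "n_traces": len(raw_traces),
        "n_accepted": len(accepted),
        "n_anomalous": sum(o.anomalous for o in outcomes),
        "hmm_means": model.means_.tolist(),
        "hmm_sds": model.sds_.tolist(),
    }
    obs_bd = [v for v in bd if v is not None]
    if len(obs_bd) >= 10:
        summary["tau_bd"] = median_dwell(bd_vals, censored=bd_cens, seed=config.seed)
        trl_vals = [v for v, _ in trl_pairs]
        trl_cens = [c for _, c in trl_pairs]
        if sum(not c for c in trl_cens) >= 10:
            summary["tau_trl"] = median_dwell(trl_vals, censored=trl_cens, seed=config.seed)
        summary["excursions"] = excursion_statistics(usable)
        summary["tau_bd_histogram"] = _hist_as_dict(obs_bd, config.dwell_bin_width)
        obs_trl = [v for v, c in trl_pairs if not c]
        if obs_trl:
            summary["tau_trl_histogram"] = _hist_as_dict(obs_trl, config.dwell_bin_width)
    summary["bleach"] = _bleach_summary(reports)
    return {
        "summary": summary,
        "outcomes": usable,
        "all_outcomes": outcomes,
        "model": model,
        "idealizations": ideals,
        "audit": audit,
    }


def _hist_as_dict(values, bin_width) -> dict:
    h = dwell_histogram(values, bin_width)
    return {
        "edges": h["edges"].tolist(),
        "counts": h["counts"].tolist(),
        "bin_width": h["bin_width"],
        "n": h["n"],
    }


def _bleach_summary(reports) -> dict:
    out = {}
    for channel in ("acceptor", "donor"):
        try:
            est = estimate_bleach_rate(reports, channel=channel)
            out[channel] = {k: est[k] for k in ("rate_per_s", "ci", "n_events", "total_time_s")}
        except ValueError:
            out[channel] = None
    return out


def analyze_equilibrium(raw_traces, config: RunConfig) -> dict:
    """QC -> pooled HMM -> dwell MLE rates, occupancy and bleach rate."""
    reports, accepted, audit = _qc(raw_traces, config)
    model = fit_hmm(accepted, tol=config.hmm_tol, max_iter=config.hmm_max_iter)
    ideals = idealize_traces(model, accepted)
    dwells = extract_dwells(ideals)
    dwell_rates = estimate_rates(dwells)
    dt = accepted[0].frame_interval if accepted else 0.1
    # Headline rates come from the Baum-Welch soft-count transition
    # probabilities (k = -ln(p_stay)/dt): unlike Viterbi dwell counting they
    # are not subject to the missed-event merge bias when dwells approach
    # the frame interval.  The censored dwell MLE is reported alongside.
    hmm_rates = {
        "NR->R": float(-np.log(max(model.transmat_[1, 1], 1e-12)) / dt),
        "R->NR": float(-np.log(max(model.transmat_[0, 0], 1e-12)) / dt),
    }
    summary = {
        "n_traces": len(raw_traces),
        "n_accepted": len(accepted),
        "hmm_means": model.means_.tolist(),
        "hmm_sds": model.sds_.tolist(),
        "rates": hmm_rates,
        "rate_estimator": "hmm_soft_counts",
        "dwell_mle_rates": {
            k: {"rate_per_s": r.rate_per_s, "ci": r.ci, "n_events": r.n_events}
            for k, r in dwell_rates.items()
        },
        "occupancy": state_occupancy(ideals),
        "bleach": _bleach_summary(reports),
    }
    return {
        "summary": summary,
        "model": model,
        "idealizations": ideals,
        "dwells": dwells,
        "audit": audit,
    }


def analyze_population(raw_traces, config: RunConfig) -> dict:
    """QC -> FRET histogram -> two-Gaussian NR/R fractions."""
    _, accepted, audit = _qc(raw_traces, config)
    hist = build_histogram(
        accepted, bin_width=config.fret_bin_width, smoothing_window=config.smoothing_window
    )
    pooled = np.concatenate([ft.analyzed_values for ft in accepted])
    fit = fit_two_gaussians(pooled)
    summary = {
        "n_traces": len(accepted),
        "n_frames": hist.n_frames,
        "fractions": report_state_fractions(fit),
        "mixture": {
            "means": fit.means.tolist(),
            "sds": fit.sds.tolist(),
            "weights": fit.weights.tolist(),
        },
    }
    return {"summary": summary, "histogram": hist, "fit": fit, "audit": audit}


def _simulate_for(config: RunConfig):
    scenario = load_scenario(config.scenario)
    if isinstance(scenario, BindingScenario):
        return scenario.replace(seed=config.seed)
    scenario = scenario.replace(seed=config.seed)
    return scenario


def run_pipeline(config: RunConfig) -> dict:
    """Run one configured analysis and write its result bundle."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"provenance": _provenance(config)}

    if config.mode in ("injection", "equilibrium", "population"):
        if config.traces_path:
            raw = read_traces(config.traces_path)
        elif config.scenario:
            scenario = _simulate_for(config)
            sim = (
                simulate_injection_experiment
                if scenario.mode == "injection"
                else simulate_equilibrium_experiment
            )
            raw = sim(scenario)
            write_traces(raw, out_dir / "traces.tsv")
            write_truth(raw, out_dir / "traces_truth.tsv")
        else:
            raise ValueError(f"{config.mode} mode needs traces_path or scenario")
        analyzer = {
            "injection": analyze_injection,
            "equilibrium": analyze_equilibrium,
            "population": analyze_population,
        }[config.mode]
        try:
            result = analyzer(raw, config)
        except Exception as err:
            raise RuntimeError(f"stage {config.mode!r} failed: {err}") from err
        bundle.update(result)
        if config.mode == "injection":
            _write_outcomes(result["all_outcomes"], out_dir / "injection_outcomes.tsv")
        pd.DataFrame(result["audit"]).to_csv(out_dir / "audit.tsv", sep="\t", index=False)

    elif config.mode == "binding":
        if config.timecourse_path:
            tc = read_timecourse(config.timecourse_path)
        elif config.scenario:
            tc = simulate_binding_scenario(_simulate_for(config))
            write_timecourse(tc, out_dir / "timecourse.tsv")
        else:
            raise ValueError("binding mode needs timecourse_path or scenario")
        fit = fit_single_exponential(tc)
        summary = {
            "k_app_per_min": fit.k_app,
            "amplitude": fit.amplitude,
            "k_stderr": fit.k_stderr,
        }
        if config.control_timecourse_path:
            ctrl = read_timecourse(config.control_timecourse_path)
            rel = relative_binding(tc.bound[-1], ctrl.bound[-1])
            summary["relative_binding"] = dataclasses.asdict(rel)
        bundle["summary"] = summary
        bundle["fit"] = fit

    elif config.mode == "frameshift":
        from .ensemble import frameshift_efficiency

        if config.minus1_signal is None or config.normalization_signal is None:
            raise ValueError("frameshift mode needs minus1_signal and normalization_signal")
        bundle["summary"] = frameshift_efficiency(
            config.minus1_signal, config.normalization_signal
        )
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    summary_doc = {"provenance": bundle["provenance"], "summary": bundle["summary"]}
    (out_dir / "summary.json").write_text(json.dumps(summary_doc, indent=2, default=_json_default))
    return bundle


def _write_outcomes(outcomes, path) -> None:
    rows = [
        {
            "trace_id": o.trace_id,
            "tau_bd_s": o.tau_bd_s,
            "tau_trl_s": o.tau_trl_s,
            "n_excursions": o.n_excursions,
            "censor_reasons": ";".join(o.censor_reasons),
            "anomalous": o.anomalous,
        }
        for o in outcomes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
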