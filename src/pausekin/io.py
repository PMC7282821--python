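"""Tabular I/O for traces, truth sidecars and binding time courses.

Traces travel as TSV with columns ``trace_id, frame, time_s, donor,
acceptor``; ground truth (when simulated) lives in a separate sidecar TSV
so analysis can be run blind to it.  Floats are written with 17 significant
digits and parsed with round-trip precision, so write->read is numerically
lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import BindingTimeCourse, RawTrace

__all__ = [
    "read_traces",
    "write_traces",
    "read_truth",
    "write_truth",
    "read_timecourse",
    "write_timecourse",
]

TRACE_COLUMNS = ["trace_id", "frame", "time_s", "donor", "acceptor"]
TRUTH_COLUMNS = [
    "trace_id",
    "tau_bd_true_s",
    "tau_trl_true_s",
    "n_excursions_true",
    "bleach_time_s",
    "tau_bd_censored",
    "tau_trl_censored",
]


class TraceParseError(ValueError):
    pass


def write_traces(traces: list[RawTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": tr.trace_id,
                    "frame": np.arange(len(tr)),
                    "time_s": tr.time,
                    "donor": tr.donor,
                    "acceptor": tr.acceptor,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_traces(path: str | Path) -> list[RawTrace]:
    """Read a trace TSV; malformed rows are reported with line numbers."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing columns {missing}")
    bad_lines = []
    for col in ("frame", "time_s", "donor", "acceptor"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        # +2: header line plus 1-based numbering
        bad_lines.extend((int(i) + 2, col) for i in df.index[coerced.isna()])
        df[col] = coerced
    if bad_lines:
        raise TraceParseError(f"{path}: non-numeric values at lines {sorted(set(bad_lines))[:5]}")
    dup = df.duplicated(subset=["trace_id", "frame"])
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup][:5]]
        raise TraceParseError(f"{path}: duplicate (trace_id, frame) rows at lines {lines}")
    traces = []
    for tid, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("frame")
        t = grp["time_s"].to_numpy()
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise TraceParseError(f"{path}: non-monotone time in trace {tid!r}")
        traces.append(
            RawTrace(str(tid), t, grp["donor"].to_numpy(), grp["acceptor"].to_numpy())
        )
    return traces


def write_truth(traces: list[RawTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        truth = tr.truth or {}
        bleach = [
            t
            for t in (truth.get("acceptor_bleach_time_s"), truth.get("donor_bleach_time_s"))
            if t is not None
        ]
        rows.append(
            {
                "trace_id": tr.trace_id,
                "tau_bd_true_s": truth.get("tau_bd_true_s"),
                "tau_trl_true_s": truth.get("tau_trl_true_s"),
                "n_excursions_true": truth.get("n_excursions_true"),
                "bleach_time_s": min(bleach) if bleach else None,
                "tau_bd_censored": truth.get("tau_bd_censored"),
                "tau_trl_censored": truth.get("tau_trl_censored"),
            }
        )
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "trace_id" not in df.columns:
        raise TraceParseError(f"{path}: missing trace_id column")
    return df.set_index("trace_id")


def write_timecourse(tc: BindingTimeCourse, path: str | Path) -> None:
    rows = []
    for j, rep in enumerate(tc.replicate_ids):
        for i, t in enumerate(tc.time_min):
            rows.append({"time_min": t, "replicate": rep, "bound": tc.bound[i, j]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_timecourse(path: str | Path) -> BindingTimeCourse:
    df = pd.read_csv(path, sep="\t")
    for col in ("time_min", "replicate", "bound"):
        if col not in df.columns:
            raise TraceParseError(f"{path}: missing column {col}")
    wide = df.pivot_table(index="time_min", columns="replicate", values="bound", sort=True)
    return BindingTimeCourse(
        wide.index.to_numpy(), wide.to_numpy(), [str(c) for c in wide.columns]
    )
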