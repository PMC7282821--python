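"""Kinetic observables from idealized traces.

Injection experiments yield two per-trace dwell times:

* ``tau_bd`` — from reagent injection to the first NR->R transition, the
  proxy for A-site tRNA binding;
* ``tau_trl`` — from that first NR->R transition to the transition into a
  *stable* NR state (observed for more than the 4-s stability threshold),
  the proxy for EF-G-catalyzed translocation.

NR visits during the rotated phase that last no longer than the threshold
are counted as excursions (unproductive pre-translocation fluctuations).
A trailing NR segment cut short by bleaching or by the end of acquisition
before it proves stable leaves ``tau_trl`` right-censored rather than
guessed.  Equilibrium experiments yield dwell sets per state; rates come
from the censored exponential MLE (events / total observed time), not from
HMM transition probabilities, so censoring is handled explicitly.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import binomtest

from ._stats import censored_exponential_mle
from .hmm import Idealization

__all__ = [
    "InjectionOutcome",
    "DwellSet",
    "RateEstimate",
    "classify_injection_trace",
    "extract_dwells",
    "dwell_histogram",
    "median_dwell",
    "estimate_rates",
    "state_occupancy",
    "excursion_statistics",
]


@dataclasses.dataclass
class InjectionOutcome:
    """Binding / translocation dwells of one injection trace."""

    trace_id: str
    tau_bd_s: float | None  # None = censored
    tau_trl_s: float | None
    n_excursions: int
    censor_reasons: list[str] = dataclasses.field(default_factory=list)
    anomalous: bool = False
    # censoring times (observation spans without the event), for KM estimates
    tau_bd_censor_at_s: float | None = None
    tau_trl_censor_at_s: float | None = None

    def __post_init__(self) -> None:
        for v in (self.tau_bd_s, self.tau_trl_s):
            if v is not None and v < 0:
                raise ValueError("dwell times must be >= 0")
        if self.n_excursions < 0:
            raise ValueError("n_excursions must be >= 0")


@dataclasses.dataclass
class DwellSet:
    """Flat list of state dwells: (state, duration s, censored, trace id)."""

    dwells: list[tuple[str, float, bool, str]]

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d, _, _ in self.dwells):
            raise ValueError("durations must be > 0")

    def durations(self, state: str, include_censored: bool = True) -> np.ndarray:
        return np.array(
            [d for s, d, c, _ in self.dwells if s == state and (include_censored or not c)]
        )

    def states(self) -> list[str]:
        return sorted({s for s, *_ in self.dwells})

    @property
    def total_time_s(self) -> float:
        return float(sum(d for _, d, _, _ in self.dwells))


@dataclasses.dataclass
class RateEstimate:
    transition: str
    rate_per_s: float
    ci: tuple[float, float]
    n_events: int
    total_time_s: float


def classify_injection_trace(
    ideal: Idealization,
    injection_time: float = 10.0,
    stability_threshold: float = 4.0,
) -> InjectionOutcome:
    """Assign tau_bd, tau_trl and the excursion count to one trace.

    The complex must be NR at injection (traces already rotated are flagged
    anomalous and excluded).  Stability is strict: an NR visit of exactly
    the threshold duration still counts as an excursion.
    """
    segs = ideal.segments
    end_time = ideal.start_time_s + ideal.analyzed_time_s
    if not segs or end_time <= injection_time:
        return InjectionOutcome(
            ideal.trace_id, None, None, 0, ["ends-before-injection"], anomalous=True
        )
    state_at_injection = None
    for state, start, dur in segs:
        if start <= injection_time < start + dur:
            state_at_injection = state
            break
    if state_at_injection != "NR":
        return InjectionOutcome(
            ideal.trace_id, None, None, 0, ["already-rotated-at-injection"], anomalous=True
        )

    r_start = None
    for state, start, dur in segs:
        if state == "R" and start >= injection_time:
            r_start = start
            break
    if r_start is None:
        return InjectionOutcome(
            ideal.trace_id,
            None,
            None,
            0,
            ["no-binding-observed"],
            tau_bd_censor_at_s=end_time - injection_time,
        )
    tau_bd = r_start - injection_time

    n_exc = 0
    tau_trl = None
    reasons: list[str] = []
    later = [s for s in segs if s[1] >= r_start]
    for i, (state, start, dur) in enumerate(later):
        if state != "NR":
            continue
        is_last = i == len(later) - 1
        if dur > stability_threshold:
            tau_trl = start - r_start
            break
        if is_last:
            reasons.append("stability-unconfirmed")  # truncated before proving stable
        else:
            n_exc += 1
    if tau_trl is None and not reasons:
        reasons.append("no-translocation-observed")  # trace ends in R
    return InjectionOutcome(
        ideal.trace_id,
        tau_bd,
        tau_trl,
        n_exc,
        reasons,
        tau_trl_censor_at_s=None if tau_trl is not None else end_time - r_start,
    )


def extract_dwells(idealizations: list[Idealization]) -> DwellSet:
    """Pool state dwells from equilibrium-mode idealizations.

    The first segment of each trace is kept as a complete dwell — for a
    stationary chain with exponential dwells, the residual time from the
    start of observation to the next transition is exponential at the same
    rate — while the trailing segment is right-censored by bleaching or by
    the end of acquisition.
    """
    dwells: list[tuple[str, float, bool, str]] = []
    for ideal in idealizations:
        segs = ideal.segments
        for i, (state, _, dur) in enumerate(segs):
            censored = i == len(segs) - 1
            dwells.append((state, dur, censored, ideal.trace_id))
    return DwellSet(dwells)


def dwell_histogram(values, bin_width: float = 2.0) -> dict:
    """Left-closed, right-open dwell histogram with bins starting at 0."""
    v = np.asarray([x for x in values if x is not None], dtype=float)
    if len(v) == 0:
        raise ValueError("no uncensored dwell values")
    n_bins = int(np.floor(v.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(v, bins=edges)
    assert counts.sum() == len(v)
    return {"edges": edges, "counts": counts, "bin_width": bin_width, "n": len(v)}


def median_dwell(
    values,
    censored=None,
    n_boot: int = 1000,
    confidence: float = 0.95,
    seed: int = 0,
) -> dict:
    """Median dwell time: naive (uncensored values only) and Kaplan-Meier.

    The naive median is the study's estimator; under right censoring it
    underestimates the true median, so the KM median is reported alongside
    whenever censoring is present.  The CI is a percentile bootstrap of the
    naive median.
    """
    v = np.asarray(values, dtype=float)
    cens = np.zeros(len(v), dtype=bool) if censored is None else np.asarray(censored, dtype=bool)
    obs = v[~cens]
    if len(obs) == 0:
        raise ValueError("no uncensored dwell values")
    naive = float(np.median(obs))
    out = {"median_s": naive, "n_uncensored": int(len(obs)), "n_censored": int(cens.sum())}
    if len(obs) >= 10:
        rng = np.random.default_rng(seed)
        boots = np.median(rng.choice(obs, size=(n_boot, len(obs)), replace=True), axis=1)
        a = (1.0 - confidence) / 2.0
        out["ci"] = (float(np.quantile(boots, a)), float(np.quantile(boots, 1 - a)))
    if cens.any():
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(v, event_observed=~cens)
        km_median = float(km.median_survival_time_)
        out["km_median_s"] = km_median if np.isfinite(km_median) else None
        if cens.mean() > 0.5 and not np.isfinite(km_median):
            out["km_undefined"] = True
    return out


def estimate_rates(dwells: DwellSet, confidence: float = 0.95) -> dict[str, RateEstimate]:
    """Censored exponential MLE of each state's exit rate.

    Keys are transition labels: the exit from NR is ``"NR->R"`` and vice
    versa (two-state model).
    """
    other = {"NR": "R", "R": "NR"}
    out: dict[str, RateEstimate] = {}
    for state in dwells.states():
        durs = dwells.durations(state, include_censored=True)
        n_events = len(dwells.durations(state, include_censored=False))
        res = censored_exponential_mle(n_events, float(durs.sum()), confidence)
        label = f"{state}->{other.get(state, '?')}"
        out[label] = RateEstimate(
            label, res["rate_per_s"], res["ci"], res["n_events"], res["total_time_s"]
        )
    return out


def state_occupancy(idealizations: list[Idealization]) -> dict[str, float]:
    """Fraction of analyzed (pre-bleach) time spent in each state."""
    if not idealizations:
        raise ValueError("need at least one idealization")
    time_in: dict[str, float] = {}
    for ideal in idealizations:
        for state, _, dur in ideal.segments:
            time_in[state] = time_in.get(state, 0.0) + dur
    total = sum(time_in.values())
    return {s: t / total for s, t in time_in.items()}


def excursion_statistics(outcomes: list[InjectionOutcome], confidence: float = 0.95) -> dict:
    """Fraction of traces with >= 1 pre-translocation excursion.

    Computed over traces whose tau_trl is observed (translocation
    confirmed), with a Clopper-Pearson binomial CI and the excursion-count
    distribution.
    """
    eligible = [o for o in outcomes if o.tau_trl_s is not None]
    if not eligible:
        raise ValueError("no traces with observed tau_trl")
    k = sum(1 for o in eligible if o.n_excursions >= 1)
    n = len(eligible)
    ci = binomtest(k, n).proportion_ci(confidence_level=confidence)
    counts: dict[int, int] = {}
    for o in eligible:
        counts[o.n_excursions] = counts.get(o.n_excursions, 0) + 1
    return {
        "fraction": k / n,
        "ci": (float(ci.low), float(ci.high)),
        "n": n,
        "count_distribution": dict(sorted(counts.items())),
    }
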