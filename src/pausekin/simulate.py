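"""Synthetic smFRET traces and ensemble binding time courses.

The generator emulates the three experiment types of the study:

* **equilibrium** — a ribosome fluctuating between the rotated (R, 0.4
  FRET) and non-rotated (NR, 0.6 FRET) conformations as a two-state
  continuous-time Markov chain, simulated exactly (Gillespie);
* **injection** — the complex sits in NR while reagents are delivered at
  ``injection_time``; an exponential wait (truth ``tau_bd``) precedes the
  NR->R transition reporting A-site tRNA binding; the rotated phase ends
  with the transition into a stable NR state reporting translocation
  (truth ``tau_trl``), optionally interrupted by 1-2 short NR excursions;
* **binding** — an ensemble bound-fraction time course following
  ``A_inf * (1 - exp(-k_app * t))``.

Hidden paths are generated in continuous time and binned to camera frames
by majority occupancy within each frame.  Photobleaching is single-step:
acceptor bleach drops I_A to baseline and dequenches the donor to the full
summed intensity; donor bleach drops both channels.  Post-bleach baselines
are Gaussian noise around zero, so naive FRET there is numerically
unstable — deliberately, to exercise the QC truncation downstream.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .scenarios import BindingScenario, SimScenario

__all__ = [
    "StatePath",
    "RawTrace",
    "BindingTimeCourse",
    "simulate_ctmc_path",
    "emit_intensities",
    "simulate_injection_experiment",
    "simulate_equilibrium_experiment",
    "simulate_binding_timecourse",
]


@dataclasses.dataclass
class StatePath:
    """Latent state trajectory: contiguous (state, start_s, duration_s) segments."""

    segments: list[tuple[str, float, float]]
    absorbing: bool = False

    def __post_init__(self) -> None:
        t = 0.0
        for state, start, dur in self.segments:
            if not math.isclose(start, t, abs_tol=1e-9):
                raise ValueError("segments must be contiguous")
            if dur <= 0:
                raise ValueError("segment durations must be > 0")
            t = start + dur

    @property
    def total_time(self) -> float:
        s, t0, d = self.segments[-1]
        return t0 + d

    def state_at(self, t: float) -> str:
        for state, start, dur in self.segments:
            if start <= t < start + dur:
                return state
        return self.segments[-1][0]

    def frame_labels(self, frame_interval: float, n_frames: int) -> np.ndarray:
        """Bin the continuous path to frames by majority occupancy.

        Each frame gets the label of the state occupying most of its
        [t, t + dt) window, mirroring camera integration; frames beyond the
        path keep the final state.
        """
        states = sorted({s for s, _, _ in self.segments})
        occ = np.zeros((len(states), n_frames))
        index = {s: i for i, s in enumerate(states)}
        for state, start, dur in self.segments:
            lo, hi = start, start + dur
            f0 = int(lo / frame_interval)
            f1 = min(int(math.ceil(hi / frame_interval)), n_frames)
            for f in range(f0, f1):
                a = max(lo, f * frame_interval)
                b = min(hi, (f + 1) * frame_interval)
                if b > a:
                    occ[index[state], f] += b - a
        # frames beyond the path keep the last state
        last = self.segments[-1][0]
        uncovered = occ.sum(axis=0) <= 0
        occ[index[last], uncovered] = 1.0
        winners = np.argmax(occ, axis=0)
        return np.array([states[w] for w in winners])


@dataclasses.dataclass
class RawTrace:
    """Two-channel intensity time series for one molecule, with optional truth."""

    trace_id: str
    time: np.ndarray  # s, uniform grid
    donor: np.ndarray  # I_D, a.u.
    acceptor: np.ndarray  # I_A, a.u.
    truth: dict | None = None  # StatePath, bleach times, true tau values

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.donor) == len(self.acceptor)):
            raise ValueError("series lengths must match")
        dt = np.diff(self.time)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-6):
            raise ValueError("time must be strictly increasing and uniform")

    @property
    def frame_interval(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 0.1

    def __len__(self) -> int:
        return len(self.time)


@dataclasses.dataclass
class BindingTimeCourse:
    """Ensemble bound fraction vs time (minutes), one column per replicate."""

    time_min: np.ndarray
    bound: np.ndarray  # shape (n_times, n_replicates)
    replicate_ids: list[str]
    truth_k_app: float | None = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.bound = np.atleast_2d(np.asarray(self.bound, dtype=float))
        if self.bound.shape[0] != len(self.time_min):
            self.bound = self.bound.T
        if len(self.time_min) < 2 or np.any(np.diff(self.time_min) <= 0):
            raise ValueError("need >= 2 strictly increasing time points")
        if np.any(self.time_min < 0):
            raise ValueError("times must be non-negative")


# ---------------------------------------------------------------------------
# continuous-time paths


def _gillespie_equilibrium(
    scenario: SimScenario, rng: np.random.Generator, initial: str | None = None
) -> StatePath:
    names = list(scenario.state_names)
    k = {s: 0.0 for s in names}
    k["NR"] = scenario.rate("NR->R")
    k["R"] = scenario.rate("R->NR")
    if any(v == 0.0 for v in k.values()):
        if all(v == 0.0 for v in k.values()):
            state = initial or "NR"
            return StatePath([(state, 0.0, scenario.duration)], absorbing=True)
        raise ValueError(
            "equilibrium mode needs positive exit rates in both states "
            "(zero exit rate in a non-absorbing state)"
        )
    if initial is None:
        # stationary start
        p_r = k["NR"] / (k["NR"] + k["R"])
        state = "R" if rng.random() < p_r else "NR"
    else:
        state = initial
    t = 0.0
    segments: list[tuple[str, float, float]] = []
    while t < scenario.duration:
        dwell = rng.exponential(1.0 / k[state])
        dwell = min(dwell, scenario.duration - t)
        segments.append((state, t, dwell))
        t += dwell
        state = "R" if state == "NR" else "NR"
    return StatePath(segments)


def _truncated_exponential(
    rng: np.random.Generator, mean: float, lo: float, hi: float
) -> float:
    """Sample Exp(mean) conditioned on [lo, hi] by inverse CDF."""
    k = 1.0 / mean
    a, b = math.exp(-k * lo), math.exp(-k * hi)
    u = rng.random()
    return -math.log(a - u * (a - b)) / k


def _injection_path(
    scenario: SimScenario, rng: np.random.Generator
) -> tuple[StatePath, dict]:
    """Latent injection-experiment path plus ground truth.

    NR until injection + binding wait; then a rotated phase of total span
    tau_trl (exponential at the translocation rate) optionally carrying 1-2
    NR excursions shorter than the stability threshold; then NR to the end
    of the acquisition (the stable post-translocation state).
    """
    dt = scenario.frame_interval
    if scenario.fixed_binding_wait is not None:
        wait = scenario.fixed_binding_wait
    else:
        wait = rng.exponential(1.0 / scenario.binding_rate)
    if scenario.fixed_r_span is not None:
        span = scenario.fixed_r_span
    else:
        span = rng.exponential(1.0 / scenario.translocation_rate)

    t_bind = scenario.injection_time + wait
    truth = {
        "tau_bd_true_s": wait,
        "tau_trl_true_s": span,
        "n_excursions_true": 0,
    }
    segments: list[tuple[str, float, float]] = []
    if t_bind >= scenario.duration:
        # binding never observed within the acquisition
        return StatePath([("NR", 0.0, scenario.duration)]), truth
    segments.append(("NR", 0.0, t_bind))

    # Excursions are modeled as Poisson arrivals during the rotated phase
    # (capped at 2, matching the observed "one or two" per trace), so longer
    # R phases are more likely to contain one.  The arrival rate is
    # calibrated so the marginal per-trace probability of >= 1 excursion
    # equals excursion_probability: for span ~ Exp(k_trl),
    # P(>=1) = 1 - k/(k + lambda) = p  =>  lambda = k_trl * p / (1 - p).
    # Dwells are exponential, truncated above half a second below the
    # stability threshold (so camera-frame jitter cannot promote a truth
    # excursion into an apparent translocation) and below a preferred
    # minimum of several frames, shrunk adaptively in short rotated phases.
    p = scenario.excursion_probability
    exc_hi = scenario.stable_state_dwell - 0.5
    dwells: list[float] = []
    if p > 0:
        lam = scenario.translocation_rate * p / (1.0 - p) if p < 1 else np.inf
        n_exc = min(int(rng.poisson(lam * span)) if np.isfinite(lam) else 2, 2)
        for _ in range(n_exc):
            remaining = span - sum(dwells) - (len(dwells) + 2) * dt
            hi = min(exc_hi, remaining)
            lo = min(scenario.excursion_dwell_min, 0.4 * hi)
            if hi <= max(lo, 2 * dt):
                continue  # rotated phase too short for a resolvable visit
            dwells.append(_truncated_exponential(rng, scenario.excursion_dwell_mean, lo, hi))
    truth["n_excursions_true"] = len(dwells)

    # place excursions at uniform interior positions of the pure-R time,
    # keeping every intervening R piece at least a few frames long so two
    # excursions cannot merge into one long NR visit
    r_total = span - sum(dwells)
    if dwells:
        n_ins = len(dwells)
        gap = min(0.5, max(3 * dt, 0.1 * r_total))
        free = r_total - (n_ins + 1) * gap
        if free < 0:
            gap = r_total / (n_ins + 2)
            free = r_total - (n_ins + 1) * gap
        u = np.sort(rng.uniform(0.0, free, size=n_ins))
        cuts = u + gap * np.arange(1, n_ins + 1)
    else:
        cuts = []
    t = t_bind
    prev = 0.0
    for cut, d in zip(cuts, dwells):
        r_piece = cut - prev
        segments.append(("R", t, r_piece))
        t += r_piece
        segments.append(("NR", t, d))
        t += d
        prev = cut
    segments.append(("R", t, r_total - prev))
    t += r_total - prev
    end = t_bind + span
    if end < scenario.duration:
        segments.append(("NR", end, scenario.duration - end))
    else:
        # rotated phase truncated by acquisition end
        segments = [(s, a, min(b, scenario.duration - a)) for s, a, b in segments if a < scenario.duration]
    return StatePath(segments), truth


def simulate_ctmc_path(
    scenario: SimScenario, mode: str | None = None, seed: int | None = None
) -> StatePath:
    """Exact continuous-time path of the two-state conformational chain.

    In equilibrium mode dwell times are exponential with the state's exit
    rate and the initial state is drawn from the stationary distribution.
    In injection mode the complex is NR until ``injection_time`` plus an
    exponential binding wait, and the path ends in the stable NR state.
    """
    mode = mode or scenario.mode
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    if mode == "equilibrium":
        return _gillespie_equilibrium(scenario, rng)
    if mode == "injection":
        path, _ = _injection_path(scenario, rng)
        return path
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# emission model


def _emit(path: StatePath, scenario: SimScenario, rng: np.random.Generator) -> RawTrace:
    n = scenario.n_frames
    dt = scenario.frame_interval
    time = np.arange(n) * dt
    labels = path.frame_labels(dt, n)
    means = np.array([scenario.fret_mean(s) for s in labels])
    e_app = means + rng.normal(0.0, scenario.fret_sd, size=n) if scenario.fret_sd > 0 else means
    total = scenario.total_intensity
    i_a = total * e_app
    i_d = total * (1.0 - e_app)

    t_acc = rng.exponential(1.0 / scenario.acceptor_bleach_rate) if scenario.acceptor_bleach_rate > 0 else np.inf
    t_don = rng.exponential(1.0 / scenario.donor_bleach_rate) if scenario.donor_bleach_rate > 0 else np.inf
    if t_acc < t_don:
        after = time >= t_acc
        i_a[after] = 0.0
        i_d[after] = total  # donor dequenching
    after_don = time >= t_don
    i_a[after_don] = 0.0
    i_d[after_don] = 0.0
    if scenario.intensity_noise_sd > 0:
        i_a = i_a + rng.normal(0.0, scenario.intensity_noise_sd, size=n)
        i_d = i_d + rng.normal(0.0, scenario.intensity_noise_sd, size=n)

    truth = {
        "path": path,
        "acceptor_bleach_time_s": None if not np.isfinite(t_acc) or t_acc > time[-1] + dt else float(t_acc),
        "donor_bleach_time_s": None if not np.isfinite(t_don) or t_don > time[-1] + dt else float(t_don),
    }
    return RawTrace("trace", time, i_d, i_a, truth=truth)


def emit_intensities(
    path: StatePath, scenario: SimScenario, seed: int | None = None
) -> RawTrace:
    """Render a latent path into donor/acceptor photon counts.

    Per frame, the apparent FRET is the state mean plus N(0, fret_sd);
    I_A = total * E, I_D = total * (1 - E), each with additive Gaussian
    channel noise.  Bleach times are exponential at the scenario rates;
    after acceptor bleach I_A drops to baseline and the donor dequenches
    to the full total intensity; after donor bleach both channels drop.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    return _emit(path, scenario, rng)


# ---------------------------------------------------------------------------
# experiment-level drivers


def _spawn_seeds(master: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(master).spawn(n)


def _run_experiment(scenario: SimScenario, mode: str) -> list[RawTrace]:
    traces = []
    for i, ss in enumerate(_spawn_seeds(scenario.seed, scenario.n_traces)):
        rng = np.random.default_rng(ss)
        if mode == "injection":
            path, truth = _injection_path(scenario, rng)
        else:
            path = _gillespie_equilibrium(scenario, rng)
            truth = {}
        trace = _emit(path, scenario, rng)  # same substream: path, noise, bleach
        trace.trace_id = f"{scenario.name}_{i:04d}"
        trace.truth.update(truth)
        if mode == "injection":
            _apply_censoring_truth(trace, scenario)
        traces.append(trace)
    return traces


def _apply_censoring_truth(trace: RawTrace, scenario: SimScenario) -> None:
    """Mark truth tau values censored by photobleaching or acquisition end."""
    truth = trace.truth
    bleach = [
        t
        for t in (truth.get("acceptor_bleach_time_s"), truth.get("donor_bleach_time_s"))
        if t is not None
    ]
    t_end = min(bleach) if bleach else scenario.duration
    t_bind = scenario.injection_time + truth["tau_bd_true_s"]
    truth["tau_bd_censored"] = bool(t_bind >= t_end)
    t_transloc = t_bind + truth["tau_trl_true_s"]
    # the stable NR must be observable for > stable_state_dwell to be confirmed
    truth["tau_trl_censored"] = bool(
        truth["tau_bd_censored"] or t_transloc + scenario.stable_state_dwell >= t_end
    )


def simulate_injection_experiment(scenario: SimScenario) -> list[RawTrace]:
    """Simulate an injection experiment: one RawTrace with truth per molecule."""
    if scenario.mode != "injection":
        scenario = scenario.replace(mode="injection")
    return _run_experiment(scenario, "injection")


def simulate_equilibrium_experiment(scenario: SimScenario) -> list[RawTrace]:
    """Simulate an equilibrium fluctuation experiment."""
    if scenario.mode != "equilibrium":
        scenario = scenario.replace(mode="equilibrium")
    return _run_experiment(scenario, "equilibrium")


def simulate_binding_timecourse(
    k_app: float,
    t_points,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 1.0,
) -> BindingTimeCourse:
    """Pseudo-first-order binding: bound(t) = A_inf (1 - exp(-k_app t)) + noise."""
    if k_app <= 0:
        raise ValueError("k_app must be > 0")
    t = np.asarray(t_points, dtype=float)
    rng = np.random.default_rng(seed)
    clean = amplitude * (1.0 - np.exp(-k_app * t))
    bound = np.tile(clean[:, None], (1, n_replicates))
    if noise_sd > 0:
        bound = bound + rng.normal(0.0, noise_sd, size=bound.shape)
    return BindingTimeCourse(
        t, bound, [f"rep{i+1}" for i in range(n_replicates)], truth_k_app=k_app
    )


def simulate_binding_scenario(scenario: BindingScenario) -> BindingTimeCourse:
    return simulate_binding_timecourse(
        scenario.k_app,
        scenario.t_points,
        scenario.n_replicates,
        scenario.noise_sd,
        scenario.seed,
        scenario.amplitude,
    )
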