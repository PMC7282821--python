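"""Simulation scenarios for the smFRET and ensemble-binding experiments.

A :class:`SimScenario` bundles every parameter the trace generator needs:
the two conformational states of the ribosome (non-rotated NR at ~0.6 FRET,
rotated R at ~0.4 FRET for the S6-cy5/L9-cy3 dye pair), their
interconversion rates, the camera frame interval, the reagent-injection
design, photobleaching rates and the per-trace excursion model.

Packaged scenarios (loadable by name with :func:`load_scenario`) encode the
study conditions:

``dnax_slip``
    Injection experiment on the slippery dnaX mRNA carrying the
    frameshift-stimulating stem-loop (FSS): slow A-site tRNA binding
    (median wait 18.2 s), slow translocation (median R-phase span 10.7 s),
    64% of traces showing 1-2 short pre-translocation NR excursions.
``dnax_slip_dfss``
    Same construct without the FSS: fast binding (3.8 s), fast
    translocation (1.5 s), 6% excursion traces.
``equilibrium_pretrans``
    Pre-translocation ribosomes fluctuating at 0.6 s^-1 (NR->R) and
    0.2 s^-1 (R->NR) with no injection.
``hiv_ns_binding``
    Ensemble filter-binding time course with apparent pseudo-first-order
    rate 0.1 min^-1.

Donor/acceptor intensity magnitudes and camera noise are not constrained by
the study; the defaults (total 1000 a.u., additive channel noise sd 50 a.u.)
are arbitrary round numbers and only set the scale of the synthetic data.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from importlib import resources
from pathlib import Path

__all__ = ["SimScenario", "BindingScenario", "load_scenario", "packaged_scenarios"]

LN2 = math.log(2.0)


@dataclasses.dataclass
class SimScenario:
    """Parameters of one simulated smFRET experiment.

    Rates are in s^-1, times in seconds, FRET values dimensionless.
    ``rate_matrix`` maps ``"NR->R"`` / ``"R->NR"`` to rates; in injection
    mode ``NR->R`` is the post-injection tRNA-binding rate and ``R->NR``
    the translocation rate, in equilibrium mode both are the fluctuation
    rates.
    """

    name: str = "custom"
    mode: str = "equilibrium"  # "equilibrium" | "injection"
    state_names: tuple[str, str] = ("R", "NR")
    fret_means: tuple[float, float] = (0.4, 0.6)
    fret_sd: float = 0.08
    rate_matrix: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"NR->R": 0.6, "R->NR": 0.2}
    )
    total_intensity: float = 1000.0
    intensity_noise_sd: float = 50.0
    frame_interval: float = 0.1
    duration: float = 200.0
    injection_time: float = 10.0
    binding_wait_median: float | None = None
    translocation_median: float | None = None
    excursion_probability: float = 0.0
    excursion_dwell_mean: float = 1.5
    excursion_dwell_min: float = 1.0
    donor_bleach_rate: float = 0.0
    acceptor_bleach_rate: float = 0.0
    stable_state_dwell: float = 4.0
    n_traces: int = 100
    seed: int = 0
    # test hooks: degenerate (delta) wait distributions
    fixed_binding_wait: float | None = None
    fixed_r_span: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("equilibrium", "injection"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.fret_means) != 2 or len(self.state_names) != 2:
            raise ValueError("exactly two states are modeled")
        lo, hi = self.fret_means
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("fret_means must be strictly ordered within [0, 1]")
        if self.fret_sd < 0 or self.intensity_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if any(v < 0 for v in self.rate_matrix.values()):
            raise ValueError("rates must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.mode == "injection" and self.duration <= self.injection_time:
            raise ValueError("duration must exceed injection_time")
        if self.n_traces < 1:
            raise ValueError("n_traces must be >= 1")
        if min(self.donor_bleach_rate, self.acceptor_bleach_rate) < 0:
            raise ValueError("bleach rates must be >= 0")
        if not 0.0 <= self.excursion_probability <= 1.0:
            raise ValueError("excursion_probability must be a probability")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))

    def rate(self, transition: str) -> float:
        return float(self.rate_matrix.get(transition, 0.0))

    @property
    def binding_rate(self) -> float:
        """Post-injection NR->R rate; derived from the median wait if given."""
        if self.binding_wait_median is not None:
            return LN2 / self.binding_wait_median
        return self.rate("NR->R")

    @property
    def translocation_rate(self) -> float:
        """R->NR rate ending the pre-translocation phase."""
        if self.translocation_median is not None:
            return LN2 / self.translocation_median
        return self.rate("R->NR")

    def fret_mean(self, state: str) -> float:
        return self.fret_means[self.state_names.index(state)]

    def replace(self, **changes) -> "SimScenario":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["state_names"] = list(self.state_names)
        d["fret_means"] = list(self.fret_means)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        d = dict(d)
        if "state_names" in d:
            d["state_names"] = tuple(d["state_names"])
        if "fret_means" in d:
            d["fret_means"] = tuple(d["fret_means"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
        return cls(**d)


@dataclasses.dataclass
class BindingScenario:
    """Ensemble filter-binding time-course conditions.

    ``k_app`` is the apparent pseudo-first-order rate in min^-1; time points
    are in minutes; ``noise_sd`` is the additive Gaussian noise on the bound
    fraction (already normalized so the no-stem-loop control plateaus at 1).
    """

    name: str = "custom"
    mode: str = "binding"
    k_app: float = 0.1
    amplitude: float = 1.0
    t_points: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    n_replicates: int = 3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_app <= 0:
            raise ValueError("k_app must be > 0")
        t = list(self.t_points)
        if len(t) < 2 or any(x < 0 for x in t) or sorted(t) != t:
            raise ValueError("t_points must be >= 2 non-negative increasing times")

    def replace(self, **changes) -> "BindingScenario":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_dict(cls, d: dict) -> "BindingScenario":
        d = dict(d)
        if "t_points" in d:
            d["t_points"] = tuple(d["t_points"])
        return cls(**d)


def packaged_scenarios() -> list[str]:
    """Names of the scenario files shipped with the package."""
    pkg = resources.files("pausekin") / "data"
    return sorted(p.name[: -len(".toml")] for p in pkg.iterdir() if p.name.endswith(".toml"))


def load_scenario(name_or_path: str | Path) -> "SimScenario | BindingScenario":
    """Load a scenario from a packaged name or a TOML file path."""
    path = Path(name_or_path)
    if path.suffix == ".toml" and path.exists():
        data = tomllib.loads(path.read_text())
    else:
        pkg = resources.files("pausekin") / "data" / f"{name_or_path}.toml"
        try:
            data = tomllib.loads(pkg.read_text())
        except FileNotFoundError:
            raise FileNotFoundError(
                f"no scenario file {name_or_path!r}; packaged: {packaged_scenarios()}"
            ) from None
    if data.get("mode") == "binding":
        return BindingScenario.from_dict(data)
    return SimScenario.from_dict(data)
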