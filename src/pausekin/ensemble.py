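"""Ensemble filter-binding kinetics and comparison statistics.

Bound-fraction time courses follow pseudo-first-order kinetics,
``bound(t) = A_inf (1 - exp(-k_app t))``, fit by nonlinear least squares
on the replicate-pooled data (per-replicate fits are available as a
diagnostic).  Binding extents are reported relative to the no-stem-loop
(dFSS) control with a two-sample t-test (Welch by default; the classical
pooled-variance Student test is a switch).  Frameshifting efficiency is
the A-site occupancy signal over the P-site normalization signal,
reported as a percentage.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, stats

from .simulate import BindingTimeCourse

__all__ = [
    "ExpFitResult",
    "RelativeBinding",
    "ExponentialBindingFit",
    "fit_single_exponential",
    "relative_binding",
    "frameshift_efficiency",
    "compare_rates",
]


@dataclasses.dataclass
class ExpFitResult:
    """Single-exponential fit: rate (min^-1), amplitude, uncertainty."""

    k_app: float
    amplitude: float
    k_stderr: float
    amplitude_stderr: float
    residuals: np.ndarray
    converged: bool
    boundary: bool = False  # rate pinned at zero

    def __post_init__(self) -> None:
        if self.converged and not np.isfinite(self.k_stderr):
            # a flat likelihood still yields a result, but callers should know
            self.boundary = True


@dataclasses.dataclass
class RelativeBinding:
    condition: str
    ratio: float
    ratio_sd: float
    n: int
    t_statistic: float
    p_value: float
    test: str = "welch"

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("relative binding must be >= 0")


class ExponentialBindingFit:
    """sklearn-style estimator for ``A_inf (1 - exp(-k t))`` time courses.

    Parameters: ``fix_amplitude`` pins A_inf (None = free); ``offset``
    adds a baseline term (off by default — the saturation model has none).
    After ``fit(t, y)``: ``k_app_``, ``amplitude_``, ``result_``.
    """

    def __init__(self, fix_amplitude: float | None = None, offset: bool = False):
        self.fix_amplitude = fix_amplitude
        self.offset = offset

    def get_params(self, deep: bool = True) -> dict:
        return {"fix_amplitude": self.fix_amplitude, "offset": self.offset}

    def set_params(self, **params) -> "ExponentialBindingFit":
        for key, val in params.items():
            setattr(self, key, val)
        return self

    def _model(self, t, *params):
        if self.fix_amplitude is not None:
            k = params[0]
            amp = self.fix_amplitude
            rest = params[1:]
        else:
            k, amp = params[0], params[1]
            rest = params[2:]
        y = amp * (1.0 - np.exp(-k * t))
        if self.offset:
            y = y + rest[0]
        return y

    def fit(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        min_pts = 2 if self.fix_amplitude is not None else 3
        if len(t) < min_pts:
            raise ValueError(f"need >= {min_pts} time points")
        if len(t) != len(y):
            raise ValueError("t and y must align")
        amp0 = max(float(np.max(y)), 1e-6)
        # crude initial rate: time to half the apparent plateau
        half = t[int(np.argmax(y >= 0.5 * amp0))] if np.any(y >= 0.5 * amp0) else t[-1]
        k0 = np.log(2.0) / max(half, t[0] if t[0] > 0 else np.min(t[t > 0], initial=1.0))
        p0 = [k0] if self.fix_amplitude is not None else [k0, amp0]
        if self.offset:
            p0.append(0.0)
        lo = np.zeros(len(p0))
        hi = np.full(len(p0), np.inf)
        if self.offset:
            lo[-1] = -np.inf
        try:
            popt, pcov = optimize.curve_fit(
                self._model, t, y, p0=p0, bounds=(lo, hi), maxfev=20000
            )
        except RuntimeError as err:
            raise RuntimeError(f"exponential fit did not converge: {err}") from err
        stderr = np.sqrt(np.diag(pcov))
        k = float(popt[0])
        amp = float(self.fix_amplitude if self.fix_amplitude is not None else popt[1])
        amp_se = 0.0 if self.fix_amplitude is not None else float(stderr[1])
        self.result_ = ExpFitResult(
            k_app=k,
            amplitude=amp,
            k_stderr=float(stderr[0]),
            amplitude_stderr=amp_se,
            residuals=y - self._model(t, *popt),
            converged=True,
            boundary=bool(k <= 1e-12),
        )
        self.k_app_ = k
        self.amplitude_ = amp
        return self

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude_ * (1.0 - np.exp(-self.k_app_ * t))


def fit_single_exponential(
    tc: BindingTimeCourse | tuple,
    fix_amplitude: float | None = None,
    pooled: bool = True,
) -> ExpFitResult:
    """Fit the pseudo-first-order model to a binding time course.

    Replicates are pooled into one least-squares problem by default;
    ``pooled=False`` returns the per-replicate fits as a list instead.
    """
    if isinstance(tc, BindingTimeCourse):
        t, y = tc.time_min, tc.bound
    else:
        t, y = np.asarray(tc[0], float), np.atleast_2d(np.asarray(tc[1], float)).T
    if not pooled:
        return [
            ExponentialBindingFit(fix_amplitude=fix_amplitude).fit(t, y[:, j]).result_
            for j in range(y.shape[1])
        ]
    tt = np.repeat(t, y.shape[1])
    yy = y.ravel()
    return ExponentialBindingFit(fix_amplitude=fix_amplitude).fit(tt, yy).result_


def relative_binding(
    sample_counts,
    control_counts,
    condition: str = "FSS",
    test: str = "welch",
) -> RelativeBinding:
    """Binding relative to the dFSS control: ratio of replicate means.

    The ratio's sd is propagated from the replicate sds; the attached
    two-sample t-test compares the raw replicate values (Welch by default,
    ``test="student"`` for the classical pooled-variance form).
    """
    a = np.asarray(sample_counts, dtype=float).ravel()
    b = np.asarray(control_counts, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if np.mean(b) == 0:
        raise ValueError("control mean is zero")
    ratio = float(np.mean(a) / np.mean(b))
    # first-order error propagation for a quotient of independent means
    rel_var = (np.var(a, ddof=1) / len(a)) / np.mean(a) ** 2 if np.mean(a) != 0 else 0.0
    rel_var += (np.var(b, ddof=1) / len(b)) / np.mean(b) ** 2
    ratio_sd = abs(ratio) * float(np.sqrt(rel_var))
    res = stats.ttest_ind(a, b, equal_var=(test == "student"))
    return RelativeBinding(
        condition, ratio, ratio_sd, len(a), float(res.statistic), float(res.pvalue), test
    )


def frameshift_efficiency(minus1_frame_signal: float, normalization_signal: float) -> dict:
    """-1 frameshifting efficiency: A-site signal over P-site normalization.

    Returned as a percentage; a ratio above 1 is flagged (occupancy cannot
    exceed the normalizer).
    """
    if normalization_signal <= 0:
        raise ValueError("normalization signal must be > 0")
    ratio = minus1_frame_signal / normalization_signal
    return {"efficiency_percent": 100.0 * ratio, "flagged": bool(ratio > 1.0)}


def compare_rates(fit_a: ExpFitResult, fit_b: ExpFitResult, confidence: float = 0.95) -> dict:
    """Fold change k_b / k_a with a delta-method (log-scale) CI."""
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    if fit_a.boundary or fit_a.k_app <= 0:
        raise ValueError("reference rate at boundary: fold change undefined")
    fold = fit_b.k_app / fit_a.k_app
    rel_var = (fit_a.k_stderr / fit_a.k_app) ** 2 + (fit_b.k_stderr / fit_b.k_app) ** 2
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    half = z * np.sqrt(rel_var)
    return {
        "fold_change": float(fold),
        "ci": (float(fold * np.exp(-half)), float(fold * np.exp(half))),
    }
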