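"""FRET-distribution histograms and their two-Gaussian decomposition.

Equilibrium FRET histograms pooled over many traces are decomposed into
two Gaussian components anchored near the 0.4 (rotated, R) and 0.6
(non-rotated, NR) states; the component *areas* (mixture weights) are the
reported state fractions.  Means are free parameters initialized at
0.4/0.6 so the recovered peak positions double as a QC check.

The sample path is plain EM on frame-level values
(:class:`TwoGaussianMixture`); a histogram can also be fit directly by
least squares on the binned density, which is what one does when only a
published histogram is available.  Histograms use moving-average (box)
smoothing with edge renormalization so the smoothed density keeps unit
mass.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .traces import FretTrace

__all__ = [
    "FretHistogram",
    "GaussianMixtureFit",
    "TwoGaussianMixture",
    "build_histogram",
    "fit_two_gaussians",
    "report_state_fractions",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclasses.dataclass
class FretHistogram:
    """FRET density histogram (raw and box-smoothed) over pre-bleach frames."""

    edges: np.ndarray
    density: np.ndarray  # raw, integrates to 1
    smoothed: np.ndarray  # box-filtered, integrates to 1
    n_traces: int
    n_frames: int
    smoothing_window: int
    weighting: str = "per_frame"

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclasses.dataclass
class GaussianMixtureFit:
    """Two-component decomposition with NR/R occupancy fractions."""

    means: np.ndarray  # ascending: [R, NR]
    sds: np.ndarray
    weights: np.ndarray  # sum to 1
    loglik: float | None
    converged: bool
    n_iter: int
    flags: list[str] = dataclasses.field(default_factory=list)

    @property
    def r_fraction(self) -> float:
        return float(self.weights[0])  # smaller mean ~0.4 -> rotated

    @property
    def nr_fraction(self) -> float:
        return float(self.weights[1])


def _box_smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Moving average with edge renormalization; preserves total mass."""
    if window <= 1:
        return y.copy()
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    norm = np.convolve(np.ones_like(y), kernel, mode="same")
    sm = num / norm
    total = y.sum()
    if sm.sum() > 0 and total > 0:
        sm *= total / sm.sum()
    return sm


def build_histogram(
    fret_traces,
    bin_width: float = 0.01,
    smoothing_window: int = 5,
    weighting: str = "per_frame",
    range_pad: float = 0.2,
) -> FretHistogram:
    """Pooled FRET histogram over the analyzed (pre-bleach) frames.

    ``per_frame`` weights every frame equally; ``per_trace`` gives each
    trace equal total weight regardless of its length (the study does not
    state which convention its histograms used, so both are offered).
    """
    arrays = []
    for tr in fret_traces:
        vals = tr.analyzed_values if isinstance(tr, FretTrace) else np.asarray(tr, float)
        vals = vals[np.isfinite(vals)]
        if len(vals):
            arrays.append(vals)
    if not arrays:
        raise ValueError("no analyzable frames")
    lo = min(0.0 - range_pad, min(a.min() for a in arrays))
    hi = max(1.0 + range_pad, max(a.max() for a in arrays))
    edges = np.arange(np.floor(lo / bin_width) * bin_width, hi + bin_width, bin_width)
    if weighting == "per_frame":
        pooled = np.concatenate(arrays)
        counts, _ = np.histogram(pooled, bins=edges)
        density = counts / (counts.sum() * bin_width)
    elif weighting == "per_trace":
        density = np.zeros(len(edges) - 1)
        for a in arrays:
            c, _ = np.histogram(a, bins=edges)
            density += c / max(c.sum(), 1)
        density /= len(arrays) * bin_width
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    smoothed = _box_smooth(density, smoothing_window)
    return FretHistogram(
        edges,
        density,
        smoothed,
        n_traces=len(arrays),
        n_frames=int(sum(len(a) for a in arrays)),
        smoothing_window=smoothing_window,
        weighting=weighting,
    )


class TwoGaussianMixture(BaseEstimator):
    """1-D two-component Gaussian mixture fit by EM.

    Component order is canonical (means ascending), so ``weights_[0]`` is
    the R fraction and ``weights_[1]`` the NR fraction.  The EM objective
    is monotone; emission sds are floored to avoid variance collapse
    (collapse is flagged rather than silently accepted).
    """

    def __init__(
        self,
        init_means=(0.4, 0.6),
        init_sds=(0.08, 0.08),
        tol: float = 1e-8,
        max_iter: int = 2000,
        sd_floor: float = 1e-3,
        fix_sds: bool = False,
    ):
        self.init_means = init_means
        self.init_sds = init_sds
        self.tol = tol
        self.max_iter = max_iter
        self.sd_floor = sd_floor
        self.fix_sds = fix_sds

    def fit(self, samples):
        x = np.asarray(samples, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if len(x) < 4:
            raise ValueError("need at least a handful of samples")
        mu = np.array(self.init_means, dtype=float)
        sd = np.array(self.init_sds, dtype=float)
        w = np.array([0.5, 0.5])
        self.flags_: list[str] = []
        prev = -np.inf
        self.converged_ = False
        history = []
        for it in range(self.max_iter):
            dens = w * np.exp(-0.5 * ((x[:, None] - mu) / sd) ** 2) / (sd * _SQRT2PI)
            tot = dens.sum(axis=1)
            tot = np.maximum(tot, 1e-300)
            loglik = float(np.log(tot).sum())
            history.append(loglik)
            if loglik - prev <= self.tol * abs(loglik) and it > 0:
                self.converged_ = True
                break
            prev = loglik
            resp = dens / tot[:, None]
            nk = resp.sum(axis=0)
            w = nk / len(x)
            mu = (resp * x[:, None]).sum(axis=0) / nk
            if not self.fix_sds:
                var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
                sd = np.sqrt(var)
                if np.any(sd < self.sd_floor):
                    self.flags_.append("variance-floor")
                    sd = np.maximum(sd, self.sd_floor)
        order = np.argsort(mu)
        self.means_, self.sds_, self.weights_ = mu[order], sd[order], w[order]
        self.loglik_ = history[-1]
        self.loglik_history_ = np.array(history)
        self.n_iter_ = len(history)
        if abs(self.means_[1] - self.means_[0]) < max(self.sds_):
            self.flags_.append("overlap")
        return self

    def predict_proba(self, samples) -> np.ndarray:
        x = np.asarray(samples, dtype=float).ravel()
        dens = (
            self.weights_
            * np.exp(-0.5 * ((x[:, None] - self.means_) / self.sds_) ** 2)
            / (self.sds_ * _SQRT2PI)
        )
        return dens / dens.sum(axis=1, keepdims=True)

    def to_fit(self) -> GaussianMixtureFit:
        return GaussianMixtureFit(
            self.means_,
            self.sds_,
            self.weights_,
            self.loglik_,
            self.converged_,
            self.n_iter_,
            list(self.flags_),
        )


def _two_gauss_density(x, w1, mu1, sd1, mu2, sd2):
    g1 = np.exp(-0.5 * ((x - mu1) / sd1) ** 2) / (sd1 * _SQRT2PI)
    g2 = np.exp(-0.5 * ((x - mu2) / sd2) ** 2) / (sd2 * _SQRT2PI)
    return w1 * g1 + (1.0 - w1) * g2


def fit_two_gaussians(
    data,
    init_means=(0.4, 0.6),
    init_sds=(0.08, 0.08),
    use_smoothed: bool = False,
) -> GaussianMixtureFit:
    """Two-Gaussian decomposition of FRET samples or of a histogram.

    Frame-level samples go through EM; a :class:`FretHistogram` is fit by
    least squares on its binned density.  Either way the fractions are
    component areas, not peak amplitudes.
    """
    if isinstance(data, FretHistogram):
        y = data.smoothed if use_smoothed else data.density
        x = data.centers
        p0 = [0.5, init_means[0], init_sds[0], init_means[1], init_sds[1]]
        popt, _ = curve_fit(
            _two_gauss_density,
            x,
            y,
            p0=p0,
            bounds=([0, -0.5, 1e-3, -0.5, 1e-3], [1, 1.5, 0.5, 1.5, 0.5]),
            maxfev=20000,
        )
        w1, mu1, sd1, mu2, sd2 = popt
        mus = np.array([mu1, mu2])
        sds = np.array([sd1, sd2])
        ws = np.array([w1, 1.0 - w1])
        order = np.argsort(mus)
        fit = GaussianMixtureFit(mus[order], sds[order], ws[order], None, True, 0)
        if abs(fit.means[1] - fit.means[0]) < max(fit.sds):
            fit.flags.append("overlap")
        return fit
    samples = np.asarray(data, dtype=float).ravel()
    if len(samples) < 100:
        raise ValueError("need >= 100 frames for a stable decomposition")
    return TwoGaussianMixture(init_means=init_means, init_sds=init_sds).fit(samples).to_fit()


def report_state_fractions(fit: GaussianMixtureFit) -> dict:
    """NR/R occupancy fractions (component areas) with QC warnings."""
    if not fit.converged:
        raise ValueError("mixture fit did not converge")
    out = {
        "nr_fraction": fit.nr_fraction,
        "r_fraction": fit.r_fraction,
        "nr_mean": float(fit.means[1]),
        "r_mean": float(fit.means[0]),
        "warnings": list(fit.flags),
    }
    return out
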