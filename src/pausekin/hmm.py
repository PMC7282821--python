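"""Two-state Gaussian-emission HMM idealization of FRET trajectories.

:class:`GaussianHmm` plays the role HaMMy-style software plays in smFRET
work: it fits a hidden Markov model with Gaussian emissions to pooled FRET
traces of one experimental condition (shared state definitions and
kinetics) and assigns each trace its most probable state path (Viterbi).
For the S6-cy5/L9-cy3 pair, state 0 is the rotated conformation (R, mean
FRET ~0.4) and state 1 the non-rotated one (NR, ~0.6); the label order is
made canonical by sorting the emission means, so label-swap symmetry never
leaks into downstream dwell analysis.

Implementation notes: scaled forward-backward run batched across traces
(sequences padded and masked), Baum-Welch with a monotone log-likelihood,
an emission-sd floor against variance collapse, and deterministic
percentile-based initialization so refits are reproducible without seeds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator

from .traces import FretTrace

__all__ = [
    "GaussianHmm",
    "Idealization",
    "fit_hmm",
    "forward_loglik",
    "viterbi_idealize",
    "idealize_traces",
]

_LOG2PI = np.log(2.0 * np.pi)
_TINY = 1e-300


@dataclasses.dataclass
class Idealization:
    """Idealized state path of one trace: per-frame labels plus segments."""

    trace_id: str
    frame_interval: float
    state_names: tuple[str, ...]
    labels: np.ndarray  # per analyzed frame, int state index
    posteriors: np.ndarray  # (n_frames, n_states)
    start_time_s: float = 0.0

    @property
    def analyzed_time_s(self) -> float:
        return len(self.labels) * self.frame_interval

    @property
    def segments(self) -> list[tuple[str, float, float]]:
        """Run-length segments (state name, start s, duration s)."""
        out = []
        if len(self.labels) == 0:
            return out
        change = np.flatnonzero(np.diff(self.labels)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(self.labels)]])
        for a, b in zip(starts, ends):
            out.append(
                (
                    self.state_names[self.labels[a]],
                    self.start_time_s + a * self.frame_interval,
                    (b - a) * self.frame_interval,
                )
            )
        return out


def _as_sequences(traces) -> list[np.ndarray]:
    seqs = []
    for tr in traces:
        if isinstance(tr, FretTrace):
            seqs.append(np.asarray(tr.analyzed_values, dtype=float))
        else:
            seqs.append(np.asarray(tr, dtype=float).ravel())
    return [s for s in seqs if len(s) > 0]


class GaussianHmm(BaseEstimator):
    """Gaussian-emission HMM fitted by Baum-Welch on pooled traces.

    Parameters
    ----------
    n_states : int
        Number of hidden states (2 for the R/NR model).
    tol : float
        Relative log-likelihood improvement declaring convergence.
    max_iter : int
        Baum-Welch iteration cap.
    sd_floor : float
        Lower bound on emission standard deviations (FRET units).
    init_means : tuple or None
        Initial emission means; default = 25th/…/75th percentiles of the
        pooled data (deterministic).

    Attributes (after fit)
    ----------------------
    means_, sds_ : (n_states,) emission parameters, means ascending.
    transmat_ : (n_states, n_states) per-frame transition probabilities.
    startprob_ : initial state distribution.
    loglik_ : final pooled log-likelihood; loglik_history_ per iteration.
    converged_, n_iter_ : convergence metadata.
    state_names_ : ("R", "NR") for two states, else ("S0", ...).
    """

    def __init__(
        self,
        n_states: int = 2,
        tol: float = 1e-6,
        max_iter: int = 500,
        sd_floor: float = 1e-3,
        init_means=None,
    ):
        self.n_states = n_states
        self.tol = tol
        self.max_iter = max_iter
        self.sd_floor = sd_floor
        self.init_means = init_means

    # -- internals -----------------------------------------------------------

    def _logpdf(self, x: np.ndarray) -> np.ndarray:
        """Gaussian log-density, broadcasting states on the last axis."""
        mu = self.means_
        sd = self.sds_
        z = (x[..., None] - mu) / sd
        return -0.5 * (z * z) - np.log(sd) - 0.5 * _LOG2PI

    def _pad(self, seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        t_max = max(len(s) for s in seqs)
        x = np.zeros((len(seqs), t_max))
        mask = np.zeros((len(seqs), t_max), dtype=bool)
        for i, s in enumerate(seqs):
            x[i, : len(s)] = s
            mask[i, : len(s)] = True
        return x, mask

    def _forward_backward(self, x: np.ndarray, mask: np.ndarray):
        """Masked, scaled forward-backward over padded sequences.

        Padded frames get emission probability 1, so their scaling factors
        are exactly 1 and contribute nothing to the log-likelihood.
        """
        n, t_max = x.shape
        k = len(self.means_)
        b = np.exp(self._logpdf(x))
        b[~mask] = 1.0
        np.maximum(b, _TINY, out=b)
        a_mat = self.transmat_
        alpha = np.empty((n, t_max, k))
        c = np.empty((n, t_max))
        f = self.startprob_ * b[:, 0]
        c[:, 0] = f.sum(axis=1)
        alpha[:, 0] = f / c[:, 0, None]
        for t in range(1, t_max):
            f = (alpha[:, t - 1] @ a_mat) * b[:, t]
            c[:, t] = f.sum(axis=1)
            alpha[:, t] = f / c[:, t, None]
        beta = np.empty((n, t_max, k))
        beta[:, -1] = 1.0
        for t in range(t_max - 2, -1, -1):
            beta[:, t] = (b[:, t + 1] * beta[:, t + 1]) @ a_mat.T / c[:, t + 1, None]
        gamma = alpha * beta
        gamma /= gamma.sum(axis=2, keepdims=True)
        loglik = float(np.log(c[mask]).sum())
        return alpha, beta, gamma, b, c, loglik

    # -- estimator API ---------------------------------------------------------

    def fit(self, traces, lengths=None):
        """Fit by Baum-Welch on a collection of FretTraces or 1-D arrays."""
        seqs = _as_sequences(traces)
        if not seqs:
            raise ValueError("need at least one non-empty trace")
        pooled = np.concatenate(seqs)
        if np.ptp(pooled) == 0:
            raise ValueError("degenerate emissions: all frames identical")
        k = self.n_states
        if self.init_means is not None:
            self.means_ = np.sort(np.asarray(self.init_means, dtype=float))
        else:
            qs = np.linspace(25, 75, k)
            self.means_ = np.percentile(pooled, qs)
            if np.ptp(self.means_) == 0:  # heavy-tailed corner: spread by std
                self.means_ = self.means_ + np.linspace(-1, 1, k) * pooled.std()
        self.sds_ = np.full(k, max(pooled.std() / 2.0, self.sd_floor))
        self.transmat_ = np.full((k, k), 1.0 / k)
        self.startprob_ = np.full(k, 1.0 / k)

        x, mask = self._pad(seqs)
        tmask = mask[:, 1:]  # valid transition steps t -> t+1
        history: list[float] = []
        self.converged_ = False
        for it in range(self.max_iter):
            alpha, beta, gamma, b, c, loglik = self._forward_backward(x, mask)
            history.append(loglik)
            if len(history) > 1:
                prev = history[-2]
                if abs(loglik - prev) <= self.tol * abs(prev):
                    self.converged_ = True
                    break
            # M step
            gma = gamma * mask[..., None]
            self.startprob_ = gamma[:, 0, :].mean(axis=0)
            bb = b[:, 1:] * beta[:, 1:] / c[:, 1:, None]
            al = alpha[:, :-1] * tmask[..., None]
            num = np.einsum("nti,ntj->ij", al, bb) * self.transmat_
            self.transmat_ = num / num.sum(axis=1, keepdims=True)
            w = gma.sum(axis=(0, 1))
            self.means_ = np.einsum("ntk,nt->k", gma, x) / w
            var = np.einsum("ntk,ntk->k", gma, (x[..., None] - self.means_) ** 2) / w
            self.sds_ = np.maximum(np.sqrt(var), self.sd_floor)
        self.n_iter_ = len(history)
        self.loglik_history_ = np.array(history)
        self.loglik_ = history[-1]
        self._canonicalize()
        self.state_names_ = ("R", "NR") if k == 2 else tuple(f"S{i}" for i in range(k))
        return self

    def _canonicalize(self) -> None:
        order = np.argsort(self.means_)
        self.means_ = self.means_[order]
        self.sds_ = self.sds_[order]
        self.startprob_ = self.startprob_[order]
        self.transmat_ = self.transmat_[np.ix_(order, order)]

    def _check_fitted(self) -> None:
        if not hasattr(self, "means_"):
            raise RuntimeError("model is not fitted")
        if np.any(self.sds_ <= 0):
            raise ValueError("degenerate emission sd")

    def score(self, trace) -> float:
        """Forward log-likelihood of one trace under the fitted model."""
        self._check_fitted()
        (seq,) = _as_sequences([trace])
        x = seq[None, :]
        mask = np.ones_like(x, dtype=bool)
        *_, loglik = self._forward_backward(x, mask)
        return loglik

    def predict_proba(self, trace) -> np.ndarray:
        """Per-frame posterior state probabilities (rows sum to 1)."""
        self._check_fitted()
        (seq,) = _as_sequences([trace])
        x = seq[None, :]
        mask = np.ones_like(x, dtype=bool)
        _, _, gamma, *_ = self._forward_backward(x, mask)
        return gamma[0]

    def predict(self, trace) -> np.ndarray:
        """Viterbi maximum a posteriori state path (int labels)."""
        self._check_fitted()
        (seq,) = _as_sequences([trace])
        logb = self._logpdf(seq)
        log_a = np.log(np.maximum(self.transmat_, _TINY))
        log_pi = np.log(np.maximum(self.startprob_, _TINY))
        t_len, k = logb.shape
        delta = log_pi + logb[0]
        back = np.zeros((t_len, k), dtype=np.int64)
        for t in range(1, t_len):
            cand = delta[:, None] + log_a
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(k)] + logb[t]
        path = np.empty(t_len, dtype=np.int64)
        path[-1] = int(np.argmax(delta))
        for t in range(t_len - 1, 0, -1):
            path[t - 1] = back[t, path[t]]
        return path


def _batch_viterbi(model: GaussianHmm, seqs: list[np.ndarray]) -> list[np.ndarray]:
    """Viterbi over many padded sequences in one time loop."""
    x, mask = model._pad(seqs)
    n, t_max = x.shape
    k = len(model.means_)
    logb = model._logpdf(x)
    logb[~mask] = 0.0
    log_a = np.log(np.maximum(model.transmat_, _TINY))
    log_pi = np.log(np.maximum(model.startprob_, _TINY))
    delta = log_pi + logb[:, 0]
    back = np.zeros((n, t_max, k), dtype=np.int8)
    identity = np.tile(np.arange(k, dtype=np.int8), (n, 1))
    for t in range(1, t_max):
        cand = delta[:, :, None] + log_a[None]
        arg = np.argmax(cand, axis=1).astype(np.int8)
        new = np.take_along_axis(cand, arg[:, None, :].astype(np.int64), axis=1)[:, 0, :]
        m = mask[:, t]
        back[:, t] = np.where(m[:, None], arg, identity)
        delta = np.where(m[:, None], new + logb[:, t], delta)
    paths = []
    for i, s in enumerate(seqs):
        t_len = len(s)
        path = np.empty(t_len, dtype=np.int64)
        path[-1] = int(np.argmax(delta[i]))
        for t in range(t_len - 1, 0, -1):
            path[t - 1] = back[i, t, path[t]]
        paths.append(path)
    return paths


def idealize_traces(model: GaussianHmm, traces) -> list[Idealization]:
    """Idealize a whole condition at once (batched Viterbi + posteriors)."""
    model._check_fitted()
    seqs = _as_sequences(traces)
    paths = _batch_viterbi(model, seqs)
    x, mask = model._pad(seqs)
    _, _, gamma, *_ = model._forward_backward(x, mask)
    out = []
    kept = [tr for tr in traces if not (isinstance(tr, FretTrace) and len(tr.analyzed_values) == 0)]
    for tr, seq, path, g in zip(kept, seqs, paths, gamma):
        if isinstance(tr, FretTrace):
            tid, dt = tr.trace_id, tr.frame_interval
        else:
            tid, dt = "trace", 0.1
        out.append(Idealization(tid, dt, model.state_names_, path, g[: len(seq)]))
    return out


# ---------------------------------------------------------------------------
# functional surface


def fit_hmm(
    traces,
    n_states: int = 2,
    init_means=None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
) -> GaussianHmm:
    """Fit the pooled Gaussian HMM for one condition (seed unused: init is
    deterministic)."""
    return GaussianHmm(
        n_states=n_states, tol=tol, max_iter=max_iter, init_means=init_means
    ).fit(traces)


def forward_loglik(model: GaussianHmm, trace) -> float:
    return model.score(trace)


def viterbi_idealize(model: GaussianHmm, trace) -> Idealization:
    """Idealize one trace: Viterbi path, posteriors, run-length segments."""
    labels = model.predict(trace)
    post = model.predict_proba(trace)
    if isinstance(trace, FretTrace):
        tid = trace.trace_id
        dt = trace.frame_interval
    else:
        tid, dt = "trace", 0.1
    return Idealization(tid, dt, model.state_names_, labels, post)
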