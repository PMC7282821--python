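"""Shared small-sample statistics helpers."""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

__all__ = ["censored_exponential_mle"]


def censored_exponential_mle(
    n_events: int, total_time: float, confidence: float = 0.95
) -> dict:
    """MLE of an exponential rate from right-censored data.

    k_hat = events / total observed time (censored spans included); the
    confidence interval inverts the profile log-likelihood
    l(k) = E log k - k T.  With zero events only an upper bound exists.
    """
    if total_time <= 0:
        raise ValueError("total observed time must be > 0")
    q = chi2.ppf(confidence, df=1)
    if n_events == 0:
        return {
            "rate_per_s": 0.0,
            "ci": (0.0, float(q / (2.0 * total_time))),
            "n_events": 0,
            "total_time_s": float(total_time),
            "censored_only": True,
        }
    k_hat = n_events / total_time

    def dev(k: float) -> float:
        ll = n_events * np.log(k) - k * total_time
        ll_hat = n_events * np.log(k_hat) - n_events
        return 2.0 * (ll_hat - ll) - q

    lo = brentq(dev, k_hat * 1e-9, k_hat)
    hi = brentq(dev, k_hat, k_hat * 1e6)
    return {
        "rate_per_s": float(k_hat),
        "ci": (float(lo), float(hi)),
        "n_events": int(n_events),
        "total_time_s": float(total_time),
        "censored_only": False,
    }
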