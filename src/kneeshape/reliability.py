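"""Test-retest reliability of the shape vector: Bland-Altman statistics.

The smallest detectable difference (SDD) is the 95% limit of agreement of
test-retest score differences, i.e. 1.96 times the sample standard deviation
of the paired differences.  A longitudinal change smaller than the SDD cannot
be distinguished from measurement noise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["smallest_detectable_difference", "bland_altman", "bland_altman_plot"]


def _paired(test, retest):
    t = np.asarray(test, dtype=float).ravel()
    r = np.asarray(retest, dtype=float).ravel()
    if t.shape != r.shape:
        raise ValueError("test and retest lists must be paired (equal length)")
    if t.size < 2:
        raise ValueError("need at least 2 test-retest pairs")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
        raise ValueError("non-finite scores")
    return t, r


def smallest_detectable_difference(test, retest) -> float:
    """SDD = 1.96 x sample SD (ddof=1) of test-retest differences."""
    t, r = _paired(test, retest)
    return float(1.96 * np.std(t - r, ddof=1))


def bland_altman(test, retest) -> dict:
    """Bland-Altman summary: bias, 95% limits of agreement, SDD."""
    t, r = _paired(test, retest)
    d = t - r
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "sdd": 1.96 * sd,
        "n": int(t.size),
    }


def bland_altman_plot(test, retest, ax=None):
    """Plot paired differences against pair means with bias and 95% limits."""
    import matplotlib.pyplot as plt

    t, r = _paired(test, retest)
    stats = bland_altman(t, r)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((t + r) / 2.0, t - r, s=12, alpha=0.7)
    ax.axhline(stats["bias"], color="k", lw=1)
    for y in (stats["loa_low"], stats["loa_high"]):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("pair mean (normalized units)")
    ax.set_ylabel("test - retest difference")
    return ax
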