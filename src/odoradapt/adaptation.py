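"""Mechanism-discrimination regressions and ensemble spike-count timecourses.

The discriminating statistic is the ordinary-least-squares slope of each
unit's response change (last-trial minus first-trial in-window count)
against its first-trial count: a negative slope is the vesicle-depletion
signature (strong responders adapt most), a positive slope the
lateral-inhibition-facilitation signature (weak responders are
progressively suppressed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import TrialTensor
from .errors import AlignmentError, DegenerateInputError, UsageError

#: Verdicts attached to a mechanism-discrimination fit.
DEPLETION_LIKE = "depletion_like"
INHIBITION_LIKE = "inhibition_like"
FLAT = "flat"


@dataclass
class RegressionFit:
    """OLS fit summary.

    ``r_squared`` is defined as 0 (with ``degenerate=True``) when the
    response variable has zero variance, keeping pipelines total on
    degenerate inputs.
    """

    slope: float
    intercept: float
    r_squared: float
    n: int
    verdict: str | None = None
    degenerate: bool = False


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AlignmentError(f"x and y must be equal-length 1-D, got {x.shape} vs {y.shape}")
    if len(x) < 2:
        raise UsageError("need at least 2 observations for a regression")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all regressor values identical (degenerate design)")
    if np.ptp(y) == 0:
        return RegressionFit(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                             n=len(x), degenerate=True)
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(x),
    )


def response_change(tensor: TrialTensor, first: int, last: int) -> pd.DataFrame:
    """Per-unit in-window count change between two trials.

    ``first``/``last`` are 0-based trial-axis positions.  Returns a frame
    with columns ``unit_id, r_first, r_last, delta`` (delta = last - first;
    negative means response reduction).
    """
    if first == last:
        raise UsageError("first and last trials must differ")
    for t in (first, last):
        if not (0 <= t < tensor.n_trials):
            raise UsageError(f"trial position {t} outside 0..{tensor.n_trials - 1}")
    r_first = tensor.counts[:, :, first].sum(axis=1).astype(float)
    r_last = tensor.counts[:, :, last].sum(axis=1).astype(float)
    return pd.DataFrame(
        {
            "unit_id": tensor.unit_labels,
            "r_first": r_first,
            "r_last": r_last,
            "delta": r_last - r_first,
        }
    )


def depletion_vs_inhibition_fit(records: pd.DataFrame) -> RegressionFit:
    """OLS of per-unit delta on first-trial response; the slope sign carries
    the mechanism verdict (negative: depletion-like, positive:
    inhibition-like)."""
    fit = _ols(records["r_first"].to_numpy(), records["delta"].to_numpy())
    if fit.slope < 0:
        fit.verdict = DEPLETION_LIKE
    elif fit.slope > 0:
        fit.verdict = INHIBITION_LIKE
    else:
        fit.verdict = FLAT
    return fit


def cross_intensity_change_fit(records_high: pd.DataFrame, records_low: pd.DataFrame) -> RegressionFit:
    """OLS of per-unit high-intensity delta on low-intensity delta.

    Requires identical unit sets; a near-zero R-squared says adaptation at
    one intensity does not model adaptation at the other.
    """
    high = records_high.set_index("unit_id")
    low = records_low.set_index("unit_id")
    if set(high.index) != set(low.index):
        raise AlignmentError("high/low record unit sets differ")
    low = low.loc[high.index]
    return _ols(low["delta"].to_numpy(), high["delta"].to_numpy())


def ensemble_count_timecourse(tensor: TrialTensor) -> np.ndarray:
    """Total in-window spikes summed over units, per trial, in trial order."""
    return tensor.counts.sum(axis=(0, 1)).astype(float)


def fit_adaptation_decay(
    counts_per_trial: np.ndarray,
    baseline_counts: float = 0.0,
) -> dict[str, float]:
    """Recover (plateau, tau) of an exponential trial-wise decay.

    Fits ``y_k = base + s * (p + (1 - p) * exp(-(k-1)/tau))`` to an
    ensemble count timecourse with ``base`` fixed at ``baseline_counts``
    (the known un-adapted baseline mass, 0 if none).  Returns the fitted
    ``plateau``, ``tau_trials``, and the evoked trial-1 scale ``s``.
    """
    y = np.asarray(counts_per_trial, dtype=float) - baseline_counts
    k = np.arange(1, len(y) + 1, dtype=float)
    if len(y) < 4:
        raise UsageError("need at least 4 trials to fit the decay")
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant timecourse")

    def model(k, s, p, tau):
        return s * (p + (1 - p) * np.exp(-(k - 1) / tau))

    s0 = max(y[0], 1.0)
    p0 = float(np.clip(y[-3:].mean() / s0, 0.05, 0.95))
    popt, _ = optimize.curve_fit(
        model, k, y, p0=[s0, p0, 5.0],
        bounds=([0.0, 0.0, 0.1], [np.inf, 1.0, 100.0]), maxfev=10000,
    )
    return {"scale": float(popt[0]), "plateau": float(popt[1]), "tau_trials": float(popt[2])}
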