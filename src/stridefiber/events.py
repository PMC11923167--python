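"""Event-aligned activity and the three locomotion timing metrics.

Activity (z-scored dF/F) is extracted around locomotion onsets or offsets
into a trials x lags matrix, from which three metrics are computed:

* **peak time** — lag of the maximum of the trial-mean trace within
  +/-1 s of the anchor (ties resolve to the earliest lag);
* **pre-offset slope** — ordinary-least-squares slope of the trial-mean
  trace over the 0.5 s preceding offset, in z-units/s;
* **rise time** — onset latency from a 20-ms sliding window (2-ms steps,
  starting at -0.5 s) whose per-trial means are compared with each trial's
  own baseline (mean over [-1, -0.5) s) by a right-tailed paired t-test;
  the first run of 5 consecutive windows with p < 0.05 marks the rise, and
  the center of the run's first window is reported.  The search continues
  past the anchor (to +0.5 s by default) because activity can rise after
  movement onset.

All lag windows are half-open [a, b) except the peak window, which spans
the closed interval [-1, +1] the metric is defined on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .params import AnalysisParams

logger = logging.getLogger(__name__)


class EmptyMatrixError(ValueError):
    """No event had a full window inside the session."""


@dataclass
class AlignedMatrix:
    """Trials x lags activity matrix around one anchor type."""

    lags: np.ndarray  # s, uniform grid
    data: np.ndarray  # (n_trials, n_lags), z-units
    anchor: str = "onset"  # onset | offset
    trial_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != self.lags.size:
            raise ValueError("data and lag grid length mismatch")
        if self.data.shape[0] < 1:
            raise EmptyMatrixError("aligned matrix needs at least one trial")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("aligned matrix must not contain missing values")
        step = np.diff(self.lags)
        if self.lags.size > 1 and np.max(np.abs(step - step[0])) > 1e-9:
            raise ValueError("lag grid must be uniform")
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.data.shape[0])

    @property
    def rate(self) -> float:
        return 1.0 / (self.lags[1] - self.lags[0])

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def mean_trace(self) -> np.ndarray:
        return self.data.mean(axis=0)


def align_to_events(
    t: np.ndarray,
    z: np.ndarray,
    event_times: np.ndarray,
    window: tuple[float, float] = (-2.0, 2.0),
    anchor: str = "onset",
) -> AlignedMatrix:
    """Extract z around each event on the session grid (no interpolation).

    Events whose full window does not fit inside the session are dropped
    with a logged count.  The lag grid includes both window endpoints.
    """
    t = np.asarray(t, dtype=float)
    z = np.asarray(z, dtype=float)
    if t.shape != z.shape:
        raise ValueError("t and z must have equal length")
    rate = (t.size - 1) / (t[-1] - t[0])
    wlo = int(round(window[0] * rate))
    whi = int(round(window[1] * rate))
    lags = np.arange(wlo, whi + 1) / rate
    rows, kept_ids = [], []
    dropped = 0
    for i, ev in enumerate(np.atleast_1d(event_times)):
        ie = int(round((float(ev) - t[0]) * rate))
        if ie + wlo < 0 or ie + whi >= t.size:
            dropped += 1
            continue
        rows.append(z[ie + wlo : ie + whi + 1])
        kept_ids.append(i)
    if dropped:
        logger.info("align_to_events: dropped %d events with partial windows", dropped)
    if not rows:
        raise EmptyMatrixError("no event had a full window inside the session")
    return AlignedMatrix(
        lags=lags, data=np.vstack(rows), anchor=anchor, trial_ids=np.array(kept_ids)
    )


@dataclass
class OnsetMetrics:
    peak_time: float  # s
    rise_time: Optional[float]  # s, None if no rise detected


@dataclass
class OffsetMetrics:
    peak_time: float  # s
    slope: float  # z-units/s over [-0.5, 0)


def peak_time(
    aligned: AlignedMatrix, params: Optional[AnalysisParams] = None
) -> float:
    """Lag of maximum trial-mean activity within 1 s of the anchor."""
    p = params or AnalysisParams()
    lo, hi = p.peak_window
    mask = (aligned.lags >= lo - 1e-9) & (aligned.lags <= hi + 1e-9)
    if not mask.any() or aligned.lags[mask][0] > lo + 1e-9:
        raise ValueError(f"lag grid must cover [{lo:g}, {hi:g}] s")
    m = aligned.mean_trace()[mask]
    return float(aligned.lags[mask][int(np.argmax(m))])


def offset_slope(
    aligned: AlignedMatrix, params: Optional[AnalysisParams] = None
) -> float:
    """OLS slope (z-units/s) of the trial mean over the 0.5 s before offset."""
    p = params or AnalysisParams()
    lo, hi = p.slope_window
    mask = (aligned.lags >= lo - 1e-9) & (aligned.lags < hi - 1e-9)
    if mask.sum() < 2:
        raise ValueError("need at least 2 samples in the slope window")
    res = stats.linregress(aligned.lags[mask], aligned.mean_trace()[mask])
    return float(res.slope)


def rise_time(
    aligned: AlignedMatrix, params: Optional[AnalysisParams] = None
) -> Optional[float]:
    """Sliding-window onset latency, or None when no rise is detected.

    Implements the across-trial paired sliding-window test described in
    the module docstring.  Steps with zero across-trial variance of the
    window-minus-baseline differences are treated as non-significant.
    """
    p = params or AnalysisParams()
    if aligned.n_trials < 2:
        raise ValueError("rise-time detection needs >= 2 trials")
    lags, X = aligned.lags, aligned.data
    rate = aligned.rate
    blo, bhi = p.rise_baseline_window
    base_mask = (lags >= blo - 1e-9) & (lags < bhi - 1e-9)
    if not base_mask.any() or lags[0] > blo + 1e-9:
        raise ValueError("lag grid must cover the baseline window")
    nw = max(2, int(round(p.rise_window_len * rate)))
    ns = max(1, int(round(p.rise_step * rate)))
    s0 = int(np.searchsorted(lags, bhi - 1e-9))  # first window starts at -0.5 s
    starts = np.arange(s0, lags.size - nw + 1, ns)
    centers = lags[starts] + nw / (2.0 * rate)
    keep = centers <= p.rise_search_end + 1e-9
    starts, centers = starts[keep], centers[keep]
    if starts.size == 0:
        raise ValueError("lag grid too short for any sliding window")

    base = X[:, base_mask].mean(axis=1)
    cs = np.concatenate([np.zeros((X.shape[0], 1)), np.cumsum(X, axis=1)], axis=1)
    win_means = (cs[:, starts + nw] - cs[:, starts]) / nw
    d = win_means - base[:, None]
    n = X.shape[0]
    sd = d.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning(
            "rise_time: %d steps with zero variance treated as non-significant",
            int(zero_var.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = d.mean(axis=0) / (sd / np.sqrt(n))
    pvals = stats.t.sf(tstat, n - 1)
    sig = (pvals < p.rise_alpha) & ~zero_var
    run = 0
    for k, s in enumerate(sig):
        run = run + 1 if s else 0
        if run == p.rise_consecutive:
            return float(centers[k - p.rise_consecutive + 1])
    return None


def onset_metrics(
    aligned: AlignedMatrix, params: Optional[AnalysisParams] = None
) -> OnsetMetrics:
    return OnsetMetrics(peak_time(aligned, params), rise_time(aligned, params))


def offset_metrics(
    aligned: AlignedMatrix, params: Optional[AnalysisParams] = None
) -> OffsetMetrics:
    return OffsetMetrics(peak_time(aligned, params), offset_slope(aligned, params))
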