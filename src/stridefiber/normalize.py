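"""dF/F normalization: sliding-percentile baseline, isosbestic referencing.

Two dialects are implemented:

* **behavior mode** (self-paced locomotion recordings): each channel is
  pre-normalized to dF/F0 against a 10th-percentile baseline in a 5-s
  sliding window; the reference dF/F0 is low-pass filtered (2nd-order
  Butterworth, 3 Hz corner, applied zero-phase) and regressed onto the
  signal dF/F0 with RANSAC; the transformed reference is subtracted to give
  the final dF/F.
* **stim mode** (optogenetic stimulation recordings, where the evoked
  offset is large): a RANSAC regression of the raw demodulated signal on
  the raw reference yields the referenced signal F; dF/F = (signal - F)/F.
  No percentile baseline and no pre-filter.

dF/F is a fraction internally; QC thresholds quoted in percent are applied
after scaling by 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import LinearRegression, RANSACRegressor

from .params import AnalysisParams
from .session import PhotometrySession

logger = logging.getLogger(__name__)


@dataclass
class QCResult:
    """Session inclusion decision.

    A session is kept only when the maximum dF/F (in percent) exceeds
    ``qc_max_dff`` (there is real signal) and the Pearson correlation
    between dF/F and the transformed reference stays below ``qc_max_corr``
    (motion artifacts did not dominate).
    """

    max_dff: float  # percent
    signal_ref_corr: float  # Pearson r
    included: bool
    reason: str = ""


@dataclass
class NormalizedTrace:
    """dF/F and z-scored trace with method metadata."""

    t: np.ndarray  # s
    dff: np.ndarray  # fraction
    zscore: np.ndarray
    f0: np.ndarray  # baseline trace (behavior) or referenced F (stim)
    method: str  # behavior_mode | stim_mode
    sample_rate: float
    reference: Optional[np.ndarray] = None  # transformed reference dF/F
    qc: Optional[QCResult] = None
    params_used: dict = field(default_factory=dict)


def sliding_percentile_baseline(
    trace: np.ndarray,
    rate: float,
    window: float = 5.0,
    percentile: float = 10.0,
    align: str = "centered",
) -> np.ndarray:
    """Per-sample percentile of ``trace`` in a sliding window.

    The window is centered on each sample and truncated at the edges
    (``align='trailing'`` uses the preceding window instead).  Percentiles
    interpolate linearly between order statistics, matching
    ``numpy.percentile``.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    trace = np.asarray(trace, dtype=float)
    w = int(round(window * rate))
    if trace.size <= w:
        raise ValueError(
            f"trace ({trace.size} samples) must be longer than the "
            f"{window:g}-s window ({w} samples)"
        )
    s = pd.Series(trace)
    if align == "centered":
        h = w // 2
        roll = s.rolling(2 * h + 1, center=True, min_periods=1)
    elif align == "trailing":
        roll = s.rolling(w, min_periods=1)
    else:
        raise ValueError(f"unknown align {align!r}")
    return roll.quantile(percentile / 100.0, interpolation="linear").to_numpy()


def prenormalize_dff(trace: np.ndarray, f0: np.ndarray) -> np.ndarray:
    """(trace - F0) / F0, elementwise.  F0 must be strictly positive."""
    trace = np.asarray(trace, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        raise ValueError(f"F0 is non-positive at sample {bad[0]}")
    return (trace - f0) / f0


def _ransac_line(
    x: np.ndarray, y: np.ndarray, max_trials: int, random_state: int
) -> tuple[float, float, bool]:
    """Robust line y ~ a*x + b.

    Residual threshold is one median absolute deviation of a preliminary
    ordinary-least-squares fit's residuals; on consensus failure the OLS
    fit itself is returned (``fallback`` True).  Each RANSAC hypothesis is
    fit on a random quarter of the samples rather than a minimal pair:
    minimal 2-point hypotheses leave percent-level slope noise that shows
    up as uncancelled artifact after referencing, while subset-OLS
    hypotheses keep the consensus robust to transient-rich stretches with
    far tighter slopes.
    """
    X = x.reshape(-1, 1)
    ols = LinearRegression().fit(X, y)
    res = y - ols.predict(X)
    mad = float(np.median(np.abs(res - np.median(res))))
    if mad <= 0:
        # already a perfect (or constant-residual) fit
        return float(ols.coef_[0]), float(ols.intercept_), False
    # subset-OLS hypotheses first (tight slopes); when the threshold is so
    # tight that no subset line gathers inliers, minimal pairs can still
    # thread exact-fit regions, so retry before surrendering to OLS
    for min_samples in (0.25, 2):
        try:
            ransac = RANSACRegressor(
                estimator=LinearRegression(),
                residual_threshold=mad,
                min_samples=min_samples,
                max_trials=max_trials,
                random_state=random_state,
            ).fit(X, y)
            est = ransac.estimator_
            return float(est.coef_[0]), float(est.intercept_), False
        except ValueError as exc:
            last_exc = exc
    logger.warning("RANSAC found no consensus (%s); falling back to OLS", last_exc)
    return float(ols.coef_[0]), float(ols.intercept_), True


def lowpass_reference(ref: np.ndarray, rate: float, params: AnalysisParams) -> np.ndarray:
    """Zero-phase Butterworth low-pass of the reference dF/F0.

    Forward-backward filtering doubles the effective order but leaves the
    reference in phase with the signal, which the regression requires.
    """
    sos = sps.butter(params.butter_order, params.butter_corner, fs=rate, output="sos")
    return sps.sosfiltfilt(sos, ref)


def reference_correct_behavior(
    signal_dff: np.ndarray,
    ref_dff: np.ndarray,
    rate: float,
    params: Optional[AnalysisParams] = None,
    random_state: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the RANSAC-transformed, low-passed reference from the signal.

    Returns ``(final dF/F, transformed reference)``.
    """
    p = params or AnalysisParams()
    signal_dff = np.asarray(signal_dff, dtype=float)
    ref_dff = np.asarray(ref_dff, dtype=float)
    if signal_dff.shape != ref_dff.shape:
        raise ValueError("signal and reference must have equal length")
    ref_filt = lowpass_reference(ref_dff, rate, p)
    a, b, _ = _ransac_line(ref_filt, signal_dff, p.ransac_max_trials, random_state)
    transformed = a * ref_filt + b
    return signal_dff - transformed, transformed


def zscore_session(dff: np.ndarray) -> np.ndarray:
    """Z-score against the mean and SD of the entire recording session."""
    dff = np.asarray(dff, dtype=float)
    sd = dff.std()
    if sd == 0:
        raise ValueError("cannot z-score a zero-variance trace")
    return (dff - dff.mean()) / sd


def qc_session(
    dff: np.ndarray,
    ref_series: np.ndarray,
    params: Optional[AnalysisParams] = None,
) -> QCResult:
    """Apply the inclusion rule: max dF/F% above threshold AND low
    correlation with the (transformed) reference."""
    p = params or AnalysisParams()
    dff = np.asarray(dff, dtype=float)
    ref_series = np.asarray(ref_series, dtype=float)
    max_dff = float(dff.max() * 100.0)
    if dff.std() == 0 or ref_series.std() == 0:
        return QCResult(max_dff, np.nan, False, "zero-variance input")
    r = float(stats.pearsonr(dff, ref_series).statistic)
    included = (max_dff > p.qc_max_dff) and (r < p.qc_max_corr)
    reason = ""
    if max_dff <= p.qc_max_dff:
        reason = "low signal"
    elif r >= p.qc_max_corr:
        reason = "motion-contaminated"
    return QCResult(max_dff, r, included, reason)


class BehaviorNormalizer(BaseEstimator):
    """Behavior-mode dF/F pipeline as a fit/transform estimator.

    ``fit`` estimates the per-channel percentile baselines and the robust
    reference regression on a session; ``transform`` applies them and
    returns a :class:`NormalizedTrace` (``fit_transform`` is the usual
    one-session path).  Fitted attributes: ``coef_``, ``intercept_``,
    ``fallback_ols_``.
    """

    def __init__(self, params: Optional[AnalysisParams] = None, random_state: int = 0):
        self.params = params
        self.random_state = random_state

    def fit(self, session: PhotometrySession, y=None) -> "BehaviorNormalizer":
        p = self.params or AnalysisParams()
        rate = session.sample_rate
        f0_sig = sliding_percentile_baseline(
            session.signal, rate, p.f0_window, p.f0_percentile, p.f0_window_align
        )
        f0_ref = sliding_percentile_baseline(
            session.reference, rate, p.f0_window, p.f0_percentile, p.f0_window_align
        )
        sig_dff = prenormalize_dff(session.signal, f0_sig)
        ref_dff = prenormalize_dff(session.reference, f0_ref)
        ref_filt = lowpass_reference(ref_dff, rate, p)
        a, b, fb = _ransac_line(ref_filt, sig_dff, p.ransac_max_trials, self.random_state)
        self.coef_, self.intercept_, self.fallback_ols_ = a, b, fb
        return self

    def transform(self, session: PhotometrySession) -> NormalizedTrace:
        p = self.params or AnalysisParams()
        rate = session.sample_rate
        f0_sig = sliding_percentile_baseline(
            session.signal, rate, p.f0_window, p.f0_percentile, p.f0_window_align
        )
        f0_ref = sliding_percentile_baseline(
            session.reference, rate, p.f0_window, p.f0_percentile, p.f0_window_align
        )
        sig_dff = prenormalize_dff(session.signal, f0_sig)
        ref_dff = prenormalize_dff(session.reference, f0_ref)
        ref_filt = lowpass_reference(ref_dff, rate, p)
        transformed_ref = self.coef_ * ref_filt + self.intercept_
        dff = sig_dff - transformed_ref
        qc = qc_session(dff, transformed_ref, p)
        return NormalizedTrace(
            t=session.t,
            dff=dff,
            zscore=zscore_session(dff),
            f0=f0_sig,
            method="behavior_mode",
            sample_rate=session.sample_rate,
            reference=transformed_ref,
            qc=qc,
            params_used={
                "f0_window": p.f0_window,
                "f0_percentile": p.f0_percentile,
                "butter_order": p.butter_order,
                "butter_corner": p.butter_corner,
                "ransac_coef": self.coef_,
                "ransac_intercept": self.intercept_,
                "ransac_fallback_ols": self.fallback_ols_,
            },
        )

    def fit_transform(self, session: PhotometrySession, y=None) -> NormalizedTrace:
        return self.fit(session).transform(session)


class StimNormalizer(BaseEstimator):
    """Stim-mode dF/F: F from a raw-channel RANSAC regression.

    Designed for stimulation recordings where the evoked change rides on a
    large offset; the regression absorbs gain/offset differences, motion
    artifacts and photobleaching shared with the reference channel.
    """

    def __init__(self, params: Optional[AnalysisParams] = None, random_state: int = 0):
        self.params = params
        self.random_state = random_state

    def fit(self, session: PhotometrySession, y=None) -> "StimNormalizer":
        p = self.params or AnalysisParams()
        a, b, fb = _ransac_line(
            np.asarray(session.reference, float),
            np.asarray(session.signal, float),
            p.ransac_max_trials,
            self.random_state,
        )
        self.coef_, self.intercept_, self.fallback_ols_ = a, b, fb
        return self

    def transform(self, session: PhotometrySession) -> NormalizedTrace:
        f = self.coef_ * session.reference + self.intercept_
        bad = np.flatnonzero(f <= 0)
        if bad.size:
            raise ValueError(
                f"referenced signal F is non-positive at sample {bad[0]}"
            )
        dff = (session.signal - f) / f
        return NormalizedTrace(
            t=session.t,
            dff=dff,
            zscore=zscore_session(dff),
            f0=f,
            method="stim_mode",
            sample_rate=session.sample_rate,
            params_used={
                "ransac_coef": self.coef_,
                "ransac_intercept": self.intercept_,
                "ransac_fallback_ols": self.fallback_ols_,
            },
        )

    def fit_transform(self, session: PhotometrySession, y=None) -> NormalizedTrace:
        return self.fit(session).transform(session)


def normalize_behavior(
    session: PhotometrySession,
    params: Optional[AnalysisParams] = None,
    random_state: int = 0,
) -> NormalizedTrace:
    return BehaviorNormalizer(params, random_state).fit_transform(session)


def reference_correct_stim(
    session: PhotometrySession,
    params: Optional[AnalysisParams] = None,
    random_state: int = 0,
) -> NormalizedTrace:
    return StimNormalizer(params, random_state).fit_transform(session)
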