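"""Stimulation-locked photometry responses and epoch velocity summaries.

Per stimulation trial the dF/F trace is baseline-subtracted (mean of the
5 s preceding onset) and three offset-anchored quantities are computed:

* **initial elevation** — mean dF/F over [0.5, 1.0) s after onset;
* **maximum reduction** — minimum dF/F over the final 1 s of stimulation
  (negative when the signal is suppressed);
* **post-stimulation change** — mean dF/F over [4, 9) s after offset,
  capturing the rebound phase.

For the 3-min epoch open-field design, per-epoch mean velocity is
expressed as a ratio to each animal's own pre-stimulation baseline, and
ambulation/immobility bout summaries are restricted to each epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .bouts import BoutTable, WindowError, _window_indices
from .normalize import NormalizedTrace
from .params import AnalysisParams
from .session import BehaviorTrack, StimProtocol

logger = logging.getLogger(__name__)


@dataclass
class StimTrialWindow:
    """One baseline-subtracted trial, lags relative to stimulation onset."""

    trial_index: int
    lags: np.ndarray  # s
    dff: np.ndarray  # baseline-subtracted dF/F (fraction)
    stim_duration: float  # s

    @property
    def rate(self) -> float:
        return 1.0 / (self.lags[1] - self.lags[0])

    def _window_mean(self, a: float, b: float) -> float:
        ia, ib = _window_indices(self.lags, self.rate, a, b)
        return float(self.dff[ia:ib].mean())


def extract_stim_trials(
    norm: NormalizedTrace,
    protocol: StimProtocol,
    params: Optional[AnalysisParams] = None,
) -> list[StimTrialWindow]:
    """Cut baseline-subtracted trial windows out of a normalized session.

    Each trial needs ``stim_baseline_window`` s of history and
    ``stim_post_window[1]`` s after offset; trials without the margins are
    dropped with a logged reason.  Lags span [-5, duration + 9] s.
    """
    p = params or AnalysisParams()
    t, dff = norm.t, np.asarray(norm.dff, dtype=float)
    rate = norm.sample_rate
    pre = p.stim_baseline_window
    post = p.stim_post_window[1]
    trials = []
    for i, (onset, dur) in enumerate(
        zip(protocol.trial_onsets, protocol.trial_durations)
    ):
        i_on = int(round((onset - t[0]) * rate))
        ia = i_on - int(round(pre * rate))
        ib = i_on + int(round((dur + post) * rate))
        if ia < 0 or ib >= t.size:
            logger.warning(
                "trial %d at %.2f s dropped: needs %g s pre / %g s post margins",
                i, onset, pre, dur + post,
            )
            continue
        lags = np.arange(ia - i_on, ib - i_on + 1) / rate
        seg = dff[ia : ib + 1]
        base_mask = (lags >= -pre - 1e-9) & (lags < -1e-9)
        baseline = seg[base_mask].mean()
        trials.append(
            StimTrialWindow(
                trial_index=i,
                lags=lags,
                dff=seg - baseline,
                stim_duration=float(dur),
            )
        )
    return trials


def initial_elevation(
    trial: StimTrialWindow, params: Optional[AnalysisParams] = None
) -> float:
    """Mean dF/F over [0.5, 1.0) s after stimulation onset."""
    p = params or AnalysisParams()
    return trial._window_mean(*p.stim_elevation_window)


def max_reduction(
    trial: StimTrialWindow, params: Optional[AnalysisParams] = None
) -> float:
    """Lowest dF/F in the final 1 s of stimulation (suppression is < 0)."""
    p = params or AnalysisParams()
    a = trial.stim_duration - p.stim_reduction_window
    ia, ib = _window_indices(trial.lags, trial.rate, a, trial.stim_duration)
    return float(trial.dff[ia:ib].min())


def post_stim_change(
    trial: StimTrialWindow, params: Optional[AnalysisParams] = None
) -> float:
    """Mean dF/F over [4, 9) s after stimulation offset (rebound phase)."""
    p = params or AnalysisParams()
    a = trial.stim_duration + p.stim_post_window[0]
    b = trial.stim_duration + p.stim_post_window[1]
    return trial._window_mean(a, b)


def summarize_stim_trials(
    trials: list[StimTrialWindow],
    params: Optional[AnalysisParams] = None,
    on_mean_trace: bool = False,
) -> pd.DataFrame:
    """Per-trial metrics plus means grouped by stimulation duration.

    With ``on_mean_trace`` True, ``max_reduction`` is computed on the
    trial-mean trace of each duration group instead of per trial (the
    per-trial minimum of a noisy trace is biased downward; both modes are
    available).
    Returns a tidy frame with a ``level`` column: per-trial rows plus one
    ``session`` row per duration group.
    """
    p = params or AnalysisParams()
    if not trials:
        raise ValueError("no stimulation trials to summarize")
    rows = [
        {
            "level": "trial",
            "trial_index": tr.trial_index,
            "stim_duration": tr.stim_duration,
            "initial_elevation": initial_elevation(tr, p),
            "max_reduction": max_reduction(tr, p),
            "post_stim_change": post_stim_change(tr, p),
        }
        for tr in trials
    ]
    df = pd.DataFrame(rows)
    for dur, grp in df.groupby("stim_duration"):
        row = {
            "level": "session",
            "trial_index": -1,
            "stim_duration": dur,
            "initial_elevation": grp["initial_elevation"].mean(),
            "max_reduction": grp["max_reduction"].mean(),
            "post_stim_change": grp["post_stim_change"].mean(),
        }
        if on_mean_trace:
            members = [tr for tr in trials if tr.stim_duration == dur]
            mean_tr = StimTrialWindow(
                trial_index=-1,
                lags=members[0].lags,
                dff=np.mean([tr.dff for tr in members], axis=0),
                stim_duration=dur,
            )
            row["max_reduction"] = max_reduction(mean_tr, p)
        rows.append(row)
    return pd.DataFrame(rows)


def _clip_bout_stats(
    bouts: BoutTable, a: float, b: float
) -> tuple[int, float, float]:
    """(count, mean clipped duration, clipped time) of bouts with onset in
    [a, b); straddling bouts are clipped at the epoch end."""
    if len(bouts) == 0:
        return 0, np.nan, 0.0
    df = bouts.df
    sel = df[(df["onset"] >= a) & (df["onset"] < b)]
    if len(sel) == 0:
        return 0, np.nan, 0.0
    clipped = np.minimum(sel["offset"].to_numpy(), b) - sel["onset"].to_numpy()
    return len(sel), float(clipped.mean()), float(clipped.sum())


def epoch_velocity_summary(
    track: BehaviorTrack,
    protocol: StimProtocol,
    params: Optional[AnalysisParams] = None,
    ambulation: Optional[BoutTable] = None,
    immobility: Optional[BoutTable] = None,
    epoch_length: float = 180.0,
) -> pd.DataFrame:
    """Per-epoch velocity and bout summary for the 3-min epoch design.

    Epochs: ``prior`` (3 min before the 1st stimulation), each ``on``
    epoch, and the 3-min ``off`` period after each stimulation.  The
    velocity ratio divides each epoch mean by the prior mean (prior ratio
    is 1 by construction).
    """
    p = params or AnalysisParams()
    if protocol.n_trials < 2:
        raise ValueError("epoch summary needs >= 2 stimulation epochs")
    v, t = track.velocity, track.t
    rate = track.sample_rate
    t_end = t[0] + t.size / rate

    epochs: list[tuple[str, float, float]] = []
    first_on = protocol.trial_onsets[0]
    if first_on - epoch_length < t[0] - 1e-9:
        raise WindowError("no full baseline epoch before the first stimulation")
    epochs.append(("prior", first_on - epoch_length, first_on))
    for k, (on, dur) in enumerate(
        zip(protocol.trial_onsets, protocol.trial_durations), start=1
    ):
        off = on + dur
        epochs.append((f"on_{k}", on, off))
        off_end = off + epoch_length
        if k < protocol.n_trials:
            off_end = min(off_end, protocol.trial_onsets[k])
        off_end = min(off_end, t_end)
        epochs.append((f"off_{k}", off, off_end))

    rows = []
    prior_mean = None
    for name, a, b in epochs:
        ia, ib = _window_indices(t, rate, a, min(b, t_end))
        mean_v = float(v[ia:ib].mean())
        if name == "prior":
            prior_mean = mean_v
            if prior_mean == 0:
                raise ValueError("prior epoch mean velocity is zero; ratio undefined")
        minutes = (b - a) / 60.0
        row = {
            "epoch": name,
            "start": a,
            "end": b,
            "mean_velocity": mean_v,
            "velocity_ratio": mean_v / prior_mean,
        }
        if ambulation is not None:
            cnt, mdur, ctime = _clip_bout_stats(ambulation, a, b)
            row.update(
                ambulation_pct=100.0 * ctime / (b - a),
                ambulation_freq_per_min=cnt / minutes,
                ambulation_mean_dur=mdur,
            )
        if immobility is not None:
            cnt, mdur, _ = _clip_bout_stats(immobility, a, b)
            row.update(
                immobility_freq_per_min=cnt / minutes,
                immobility_mean_dur=mdur,
            )
        rows.append(row)
    return pd.DataFrame(rows)
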