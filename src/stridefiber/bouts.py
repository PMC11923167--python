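"""Locomotion bout segmentation and trial state classification.

Three assay-specific rule sets:

* **treadmill** — movement vs rest at 0.25 cm/s; rests shorter than 0.8 s
  are absorbed into the surrounding movement; movement periods shorter than
  0.5 s or slower than 0.5 cm/s on average are discarded.  Bout onset is the
  threshold crossing that ends a valid rest period, offset the crossing
  followed by one.
* **open-field ambulation** — supra-threshold (>2 cm/s) runs separated by
  <=0.5 s are merged, merged runs lasting <=0.5 s are dropped.
* **open-field immobility** — same machinery on sub-threshold (<2% pixel
  change) runs of the motion index.

Comparisons follow the printed operators strictly: for ambulation and
immobility a sample exactly at threshold belongs to neither class and breaks
a run.  For the treadmill the classes must partition time into movement and
rest bins, so movement is ``v > threshold`` and rest is its complement.
Bout boundaries are reported at the first sample of the new state.

Detectors are scikit-learn style estimators (``fit`` populates ``bouts_``);
the ``detect_*`` functions are thin wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .params import AnalysisParams
from .session import BehaviorTrack, TimingError

logger = logging.getLogger(__name__)

BOUT_COLUMNS = ["onset", "offset", "duration", "mean_velocity", "kind"]


class WindowError(ValueError):
    """A requested analysis window falls outside the recording."""


@dataclass
class BoutTable:
    """Segmented behavioral intervals with per-bout statistics.

    ``df`` has columns onset, offset, duration (s), mean_velocity (cm/s,
    NaN when no velocity applies) and kind (movement | ambulation |
    immobility).  ``span`` is the observed recording extent in seconds,
    needed for rate/percent summaries.
    """

    df: pd.DataFrame
    span: float = np.nan

    def __post_init__(self) -> None:
        if list(self.df.columns) != BOUT_COLUMNS:
            self.df = self.df.reindex(columns=BOUT_COLUMNS)
        if len(self.df):
            if not (self.df["onset"] < self.df["offset"]).all():
                raise ValueError("bout onset must precede offset")
            d = self.df["offset"] - self.df["onset"]
            if not np.allclose(d, self.df["duration"], atol=1e-9):
                raise ValueError("duration must equal offset - onset")
            for _, grp in self.df.groupby("kind"):
                o = grp.sort_values("onset")
                if (o["onset"].values[1:] < o["offset"].values[:-1]).any():
                    raise ValueError("bouts of one kind must not overlap")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_rows(cls, rows: list[dict], span: float = np.nan) -> "BoutTable":
        return cls(pd.DataFrame(rows, columns=BOUT_COLUMNS), span=span)

    @classmethod
    def empty(cls, span: float = np.nan) -> "BoutTable":
        return cls(pd.DataFrame(columns=BOUT_COLUMNS), span=span)

    # -- per-session summaries (the quantities plotted per mouse) ----------
    @property
    def total_time(self) -> float:
        return float(self.df["duration"].sum())

    @property
    def percent_time(self) -> float:
        return 100.0 * self.total_time / self.span

    @property
    def freq_per_min(self) -> float:
        return 60.0 * len(self) / self.span

    @property
    def mean_duration(self) -> float:
        return float(self.df["duration"].mean()) if len(self) else np.nan

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_bouts": len(self),
                    "percent_time": self.percent_time,
                    "freq_per_min": self.freq_per_min,
                    "mean_duration": self.mean_duration,
                    "mean_velocity": float(self.df["mean_velocity"].mean())
                    if len(self)
                    else np.nan,
                }
            ]
        )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a boolean array."""
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    stops = list(edges[mask[edges]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _merge_runs(
    runs: list[tuple[int, int]], max_gap_samples: float
) -> list[tuple[int, int]]:
    """Merge runs whose separating gap is <= max_gap_samples."""
    if not runs:
        return []
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] <= max_gap_samples:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [tuple(r) for r in merged]


def _check_track(track: BehaviorTrack) -> tuple[np.ndarray, float, float]:
    v = track.velocity
    rate = track.sample_rate
    dt = 1.0 / rate
    if not np.isfinite(rate) or rate <= 0:
        raise TimingError("behavior track has no valid sample rate")
    return v, rate, dt


class TreadmillBoutDetector(BaseEstimator):
    """Movement-bout segmentation for the head-fixed treadmill assay.

    Parameters mirror :class:`~stridefiber.params.AnalysisParams`:
    ``move_threshold`` (0.25 cm/s), ``min_rest_dur`` (0.8 s),
    ``min_move_dur`` (0.5 s), ``min_move_mean_vel`` (0.5 cm/s).

    ``rest_first`` controls rule order: when True (default), rests shorter
    than ``min_rest_dur`` are absorbed into the surrounding movement before
    the movement duration/velocity filters run; when False the movement
    filters run first.

    Attributes (after ``fit``): ``bouts_`` (:class:`BoutTable`).
    """

    def __init__(self, params: Optional[AnalysisParams] = None, rest_first: bool = True):
        self.params = params
        self.rest_first = rest_first

    def fit(self, track: BehaviorTrack, y=None) -> "TreadmillBoutDetector":
        p = self.params or AnalysisParams()
        v, rate, dt = _check_track(track)
        n = v.size
        moving = v > p.move_threshold
        # rest is valid only if strictly longer than min_rest_dur; shorter
        # interior rests are absorbed into the surrounding movement
        rest_samples = p.min_rest_dur * rate + 1e-6

        def move_ok(a: int, b: int) -> bool:
            return (b - a) >= p.min_move_dur * rate - 1e-6 and v[
                a:b
            ].mean() >= p.min_move_mean_vel

        move_runs = _runs(moving)
        if self.rest_first:
            candidates = _merge_runs(move_runs, rest_samples)
            surviving = [r for r in candidates if move_ok(*r)]
        else:
            surviving = _merge_runs(
                [r for r in move_runs if move_ok(*r)], rest_samples
            )
            candidates = surviving
        rows = []
        for a, b in surviving:
            # onset is the crossing ending a valid rest period, offset the
            # crossing followed by one; rest periods are the gaps between
            # candidate movement runs (session edges truncate the rest and
            # are judged by the actual gap duration)
            prev_end = max((bb for _, bb in candidates if bb <= a), default=0)
            next_start = min((aa for aa, _ in candidates if aa >= b), default=n)
            if (a - prev_end) < rest_samples or (next_start - b) < rest_samples:
                continue
            rows.append(
                {
                    "onset": track.t[a],
                    "offset": track.t[0] + b * dt,
                    "duration": (b - a) * dt,
                    "mean_velocity": float(v[a:b].mean()),
                    "kind": "movement",
                }
            )
        self.bouts_ = BoutTable.from_rows(rows, span=n * dt)
        return self

    def fit_detect(self, track: BehaviorTrack) -> BoutTable:
        return self.fit(track).bouts_


class _RunBoutDetector(BaseEstimator):
    """Shared merge-then-filter machinery for open-field bout scoring."""

    kind = ""

    def __init__(self, params: Optional[AnalysisParams] = None):
        self.params = params

    def _classify(self, track: BehaviorTrack, p: AnalysisParams) -> np.ndarray:
        raise NotImplementedError

    def fit(self, track: BehaviorTrack, y=None):
        p = self.params or AnalysisParams()
        v, rate, dt = _check_track(track)
        n = track.t.size
        mask = self._classify(track, p)
        runs = _runs(mask)
        # "separated by > min_sep" -> runs with gap <= min_sep merge first
        runs = _merge_runs(runs, p.ambulation_min_sep * rate + 1e-6)
        # "lasting for > min_dur" -> strictly longer survives
        runs = [(a, b) for a, b in runs if (b - a) > p.ambulation_min_dur * rate + 1e-6]
        rows = []
        for a, b in runs:
            rows.append(
                {
                    "onset": track.t[a],
                    "offset": track.t[0] + b * dt,
                    "duration": (b - a) * dt,
                    "mean_velocity": float(v[a:b].mean()),
                    "kind": self.kind,
                }
            )
        self.bouts_ = BoutTable.from_rows(rows, span=n * dt)
        return self

    def fit_detect(self, track: BehaviorTrack) -> BoutTable:
        return self.fit(track).bouts_


class AmbulationBoutDetector(_RunBoutDetector):
    """Open-field ambulation: velocity strictly above 2 cm/s, >0.5 s,
    separated by >0.5 s (closer runs merge)."""

    kind = "ambulation"

    def _classify(self, track: BehaviorTrack, p: AnalysisParams) -> np.ndarray:
        return track.velocity > p.ambulation_threshold


class ImmobilityBoutDetector(_RunBoutDetector):
    """Open-field immobility: motion index strictly below 2% pixel change,
    >0.5 s, separated by >0.5 s."""

    kind = "immobility"

    def _classify(self, track: BehaviorTrack, p: AnalysisParams) -> np.ndarray:
        if track.motion_index is None:
            raise ValueError("immobility scoring requires a motion_index")
        return track.motion_index < p.immobility_threshold


def detect_treadmill_bouts(
    track: BehaviorTrack, params: Optional[AnalysisParams] = None, rest_first: bool = True
) -> BoutTable:
    return TreadmillBoutDetector(params, rest_first=rest_first).fit_detect(track)


def detect_ambulation_bouts(
    track: BehaviorTrack, params: Optional[AnalysisParams] = None
) -> BoutTable:
    return AmbulationBoutDetector(params).fit_detect(track)


def detect_immobility_bouts(
    track: BehaviorTrack, params: Optional[AnalysisParams] = None
) -> BoutTable:
    return ImmobilityBoutDetector(params).fit_detect(track)


@dataclass
class StateLabel:
    """Behavioral state in the 0.5 s preceding a stimulation anchor."""

    trial_index: int
    anchor: str  # stim_onset | stim_offset
    label: str  # ambulatory | quiescent | unclassified


def _window_indices(
    t: np.ndarray, rate: float, a: float, b: float
) -> tuple[int, int]:
    """Sample indices of the half-open window [a, b) on a uniform grid."""
    t0 = t[0]
    ia = int(np.ceil((a - t0) * rate - 1e-6))
    ib = int(np.ceil((b - t0) * rate - 1e-6))
    if ia < 0 or ib > t.size or ib <= ia:
        raise WindowError(f"window [{a:g}, {b:g}) s outside recording")
    return ia, ib


def classify_trial_state(
    track: BehaviorTrack,
    anchor_time: float,
    anchor: str = "stim_onset",
    params: Optional[AnalysisParams] = None,
    trial_index: int = 0,
) -> StateLabel:
    """Label the 0.5 s before ``anchor_time`` as ambulatory / quiescent.

    Ambulatory: every sample strictly above 2 cm/s.  Quiescent (small
    movements allowed): every sample strictly below 1.5 cm/s.  Anything
    else is unclassified.  The threshold gap guarantees the labels are
    mutually exclusive.
    """
    p = params or AnalysisParams()
    v, rate, _ = _check_track(track)
    ia, ib = _window_indices(track.t, rate, anchor_time - p.state_window, anchor_time)
    w = v[ia:ib]
    if np.all(w > p.ambulatory_threshold):
        label = "ambulatory"
    elif np.all(w < p.quiescent_threshold):
        label = "quiescent"
    else:
        label = "unclassified"
    return StateLabel(trial_index=trial_index, anchor=anchor, label=label)


def classify_trials(
    track: BehaviorTrack,
    anchor_times: np.ndarray,
    anchor: str = "stim_onset",
    params: Optional[AnalysisParams] = None,
) -> list[StateLabel]:
    """Classify many trials; out-of-range windows are skipped with a log."""
    out = []
    for i, at in enumerate(np.atleast_1d(anchor_times)):
        try:
            out.append(classify_trial_state(track, float(at), anchor, params, i))
        except WindowError as exc:
            logger.warning("trial %d skipped: %s", i, exc)
    return out


def stim_velocity_change(
    track: BehaviorTrack,
    anchor_time: float,
    params: Optional[AnalysisParams] = None,
) -> tuple[float, float]:
    """Mean velocity in the 1 s before vs the 1 s from ``anchor_time``."""
    p = params or AnalysisParams()
    v, rate, _ = _check_track(track)
    w = p.stim_velocity_window
    ia, im = _window_indices(track.t, rate, anchor_time - w, anchor_time)
    im2, ib = _window_indices(track.t, rate, anchor_time, anchor_time + w)
    return float(v[ia:im].mean()), float(v[im2:ib].mean())
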