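"""Session containers: photometry, behavior, stimulation schedule.

All times are seconds on a session-relative clock (t[0] = 0 after alignment)
and all event windows downstream are half-open ``[a, b)``.  Containers
validate their invariants on construction so later stages can assume a
strictly uniform timebase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: tolerance on timebase uniformity, seconds
_DT_TOL = 1e-9


class SchemaError(ValueError):
    """A file or container does not match the declared schema."""


class TimingError(ValueError):
    """A timebase is missing, non-uniform, or non-overlapping."""


def _check_uniform(t: np.ndarray, what: str) -> float:
    """Return the (constant) sample step of ``t`` or raise ``TimingError``."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise TimingError(f"{what}: timebase needs >= 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise TimingError(f"{what}: time must be strictly increasing")
    step = (t[-1] - t[0]) / (t.size - 1)
    if np.max(np.abs(dt - step)) > _DT_TOL:
        raise TimingError(f"{what}: non-uniform timebase (tolerance {_DT_TOL} s)")
    return step


@dataclass
class PhotometrySession:
    """Demodulated fluorescence: one signal channel plus the UV reference.

    ``signal`` is the activity-dependent channel (465 nm GCaMP or 560 nm
    red dopamine sensor), ``reference`` the 405 nm isosbestic channel that
    shares motion and bleaching artifacts but carries no sensor signal.
    """

    t: np.ndarray  # s, uniform grid
    signal: np.ndarray  # a.u.
    reference: np.ndarray  # a.u.
    sample_rate: float = 1000.0  # Hz
    signal_wavelength: int = 465  # nm, 465 or 560
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        step = _check_uniform(self.t, "photometry")
        if abs(step - 1.0 / self.sample_rate) > _DT_TOL:
            raise TimingError(
                f"photometry: step {step:g} s inconsistent with "
                f"sample_rate {self.sample_rate:g} Hz"
            )
        if self.signal.shape != self.t.shape or self.reference.shape != self.t.shape:
            raise SchemaError("photometry: signal/reference length mismatch with t")
        if self.signal_wavelength not in (465, 560):
            raise SchemaError("signal_wavelength must be 465 or 560")
        for ts, _label in self.events:
            if not (self.t[0] <= ts <= self.t[-1]):
                raise TimingError(f"event at {ts:g} s outside recording span")


@dataclass
class BehaviorTrack:
    """Velocity trace (treadmill or open field), optionally a motion index.

    The treadmill encoder outputs volts; the default calibration of
    10 cm/s at 2.5 V gives 4 cm s^-1 V^-1.  ``motion_index`` is a
    normalized per-frame pixel-change proxy in [0, 1] from open-field video.
    """

    t: np.ndarray  # s, uniform grid
    velocity: np.ndarray  # cm/s
    motion_index: Optional[np.ndarray] = None
    calibration: float = 4.0  # cm/s per volt

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        _check_uniform(self.t, "behavior")
        if self.velocity.shape != self.t.shape:
            raise SchemaError("behavior: velocity length mismatch with t")
        if not np.all(np.isfinite(self.velocity)):
            raise SchemaError("behavior: velocity contains non-finite values")
        if self.motion_index is not None:
            self.motion_index = np.asarray(self.motion_index, dtype=float)
            if self.motion_index.shape != self.t.shape:
                raise SchemaError("behavior: motion_index length mismatch with t")
            if np.any((self.motion_index < 0) | (self.motion_index > 1)):
                raise SchemaError("behavior: motion_index must lie in [0, 1]")

    @property
    def sample_rate(self) -> float:
        return (self.t.size - 1) / (self.t[-1] - self.t[0])


@dataclass
class StimProtocol:
    """Optogenetic stimulation schedule.

    ``pulse_frequency`` 0 means constant light.  ``schedule_kind`` tags the
    design: two 3-min epochs with 3-min off periods, repeated 10-s trials,
    or trials of varied duration (2/5/15 s).
    """

    trial_onsets: np.ndarray  # s
    trial_durations: np.ndarray  # s
    pulse_frequency: float = 20.0  # Hz
    pulse_width: float = 5.0  # ms
    power: float = 3.0  # mW
    schedule_kind: str = "trial_varied"  # epoch_3min | trial_10s | trial_varied

    def __post_init__(self) -> None:
        self.trial_onsets = np.atleast_1d(np.asarray(self.trial_onsets, dtype=float))
        self.trial_durations = np.atleast_1d(
            np.asarray(self.trial_durations, dtype=float)
        )
        if self.trial_durations.size == 1 and self.trial_onsets.size > 1:
            self.trial_durations = np.full(
                self.trial_onsets.size, self.trial_durations[0]
            )
        if self.trial_onsets.shape != self.trial_durations.shape:
            raise SchemaError("stim: onsets and durations length mismatch")
        if np.any(np.diff(self.trial_onsets) <= 0):
            raise SchemaError("stim: trial onsets must be sorted and distinct")
        offsets = self.trial_onsets + self.trial_durations
        if np.any(offsets[:-1] > self.trial_onsets[1:]):
            raise SchemaError("stim: trials overlap")
        if self.schedule_kind not in ("epoch_3min", "trial_10s", "trial_varied"):
            raise SchemaError(f"unknown schedule_kind {self.schedule_kind!r}")

    @property
    def trial_offsets(self) -> np.ndarray:
        return self.trial_onsets + self.trial_durations

    @property
    def n_trials(self) -> int:
        return int(self.trial_onsets.size)


@dataclass
class SessionBundle:
    """One recording session: photometry, behavior and/or stimulation."""

    photometry: Optional[PhotometrySession] = None
    behavior: Optional[BehaviorTrack] = None
    stim: Optional[StimProtocol] = None
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.photometry is None and self.behavior is None and self.stim is None:
            raise SchemaError("bundle must contain at least one component")


def align_common_timebase(bundle: SessionBundle, rate: float) -> SessionBundle:
    """Resample all time-series components onto one uniform grid.

    Components are linearly interpolated onto a grid at ``rate`` Hz covering
    their overlapping time span, then shifted so t[0] = 0.  Event and trial
    timestamps are shifted by the same offset.  Idempotent: a bundle already
    on the target grid comes back numerically identical.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    spans = []
    if bundle.photometry is not None:
        spans.append((bundle.photometry.t[0], bundle.photometry.t[-1]))
    if bundle.behavior is not None:
        spans.append((bundle.behavior.t[0], bundle.behavior.t[-1]))
    if not spans:
        return bundle
    lo = max(s[0] for s in spans)
    hi = min(s[1] for s in spans)
    if hi <= lo:
        raise TimingError("alignment: components have empty time overlap")
    n = int(np.floor((hi - lo) * rate + _DT_TOL)) + 1
    grid = lo + np.arange(n) / rate

    photometry = bundle.photometry
    if photometry is not None:
        photometry = PhotometrySession(
            t=grid - lo,
            signal=np.interp(grid, photometry.t, photometry.signal),
            reference=np.interp(grid, photometry.t, photometry.reference),
            sample_rate=rate,
            signal_wavelength=photometry.signal_wavelength,
            events=[
                (ts - lo, label)
                for ts, label in photometry.events
                if lo <= ts <= grid[-1]
            ],
        )
    behavior = bundle.behavior
    if behavior is not None:
        mi = behavior.motion_index
        behavior = BehaviorTrack(
            t=grid - lo,
            velocity=np.interp(grid, behavior.t, behavior.velocity),
            motion_index=None if mi is None else np.interp(grid, behavior.t, mi),
            calibration=behavior.calibration,
        )
    stim = bundle.stim
    if stim is not None and lo != 0:
        stim = StimProtocol(
            trial_onsets=stim.trial_onsets - lo,
            trial_durations=stim.trial_durations,
            pulse_frequency=stim.pulse_frequency,
            pulse_width=stim.pulse_width,
            power=stim.power,
            schedule_kind=stim.schedule_kind,
        )
    return SessionBundle(
        photometry=photometry,
        behavior=behavior,
        stim=stim,
        subject_id=bundle.subject_id,
        meta=dict(bundle.meta),
    )
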