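"""Synthetic sessions with known ground truth.

The generator emulates the statistical structure the analyses assume —
exponential photobleaching, a motion artifact shared across channels with
per-channel gains, event-locked sensor transients with a configurable
lead/lag relative to locomotion onset, bout-structured treadmill velocity,
and stimulation-locked dopamine responses (brief elevation, ramped
suppression, exponential rebound).  It makes no claim of biophysical
realism: no spiking, sensor saturation or hemodynamics.

Every draw comes from a seeded generator, so a fixed seed gives
bit-identical output.  The isosbestic contract holds by construction: the
reference channel carries bleaching, artifact and noise but no transient
component, so any "signal" recovered from it downstream is an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, model_validator
from scipy import signal as sps

from .bouts import BoutTable
from .params import AnalysisParams
from .session import BehaviorTrack, PhotometrySession, SessionBundle, StimProtocol


class TransientKernel(BaseModel):
    """Double-exponential sensor impulse response (GCaMP8s stand-in)."""

    rise_tau: float = 0.05  # s
    decay_tau: float = 0.5  # s
    amplitude: float = 0.05  # a.u., peak height

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self):
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("kernel taus must be > 0")
        if self.rise_tau >= self.decay_tau:
            raise ValueError("rise_tau must be below decay_tau")
        return self

    def evaluate(self, rate: float) -> np.ndarray:
        t = np.arange(0.0, 8.0 * self.decay_tau, 1.0 / rate)
        k = np.exp(-t / self.decay_tau) - np.exp(-t / self.rise_tau)
        return self.amplitude * k / k.max()


class StimResponseShape(BaseModel):
    """Amplitudes of the stimulation-locked dopamine response, dF/F units."""

    elevation_amp: float = 0.0  # boxcar over [0.3, 1.2) s post onset
    suppression_amp: float = 0.02  # ramp depth reached at offset
    rebound_amp: float = 0.01  # exponential rebound height at offset
    rebound_tau: float = 5.0  # s

    model_config = {"frozen": True}


class SynthConfig(BaseModel):
    """All knobs of the synthetic-session generator.

    Defaults describe a head-fixed treadmill recording: 30 min at 1 kHz,
    a couple of walking bouts per minute a few cm/s fast, sensor
    transients leading locomotion onset by 150 ms, and a falling activity
    trend into locomotion offset (an early-activation subtype; see
    ``KREMEN1_LIKE``/``CALB1_LIKE`` presets).
    """

    duration: float = 1800.0  # s
    rate: float = 1000.0  # Hz

    # photometry
    baseline_F: float = 1.0  # a.u., bleaching plateau
    bleach_amp: float = 0.15  # a.u., decaying component
    bleach_tau: float = 1200.0  # s, photobleaching e-fold
    transient_kernel: TransientKernel = TransientKernel()
    event_lag: float = -0.15  # s, activity vs locomotion onset (neg = leads)
    offset_slope_sign: int = -1  # trend of activity into locomotion offset
    offset_ramp_rate: float = 0.04  # a.u./s over the 0.5 s before offset
    motion_amp: float = 0.0  # a.u., SD of the shared artifact
    motion_gain_signal: float = 1.0
    motion_gain_ref: float = 0.8
    artifact_corner: float = 1.0  # Hz, low-pass corner of the artifact
    noise_sd: float = 0.003  # a.u., white per-channel noise
    ref_baseline_frac: float = 0.7  # reference baseline vs signal baseline
    ref_bleach_tau_frac: float = 0.8  # reference bleaches a bit faster

    # locomotion
    bout_rate: float = 2.0  # bouts/min
    bout_dur_mean: float = 3.0  # s
    bout_vel_mean: float = 3.0  # cm/s
    rest_jitter: float = 0.1  # cm/s, capped below half the move threshold
    ramp_time: float = 0.3  # s, smooth on/off velocity ramps
    edge_margin: float = 2.5  # s, rest at session edges

    # stimulation
    stim_response: StimResponseShape = StimResponseShape()
    stim_noise_dff: float = 0.002  # dF/F-scale noise in stim sessions
    stim_on_vel_factor: float = 0.6  # open-field velocity scale during ON
    stim_off_vel_factor: float = 1.3  # rebound scale in the OFF epochs

    seed: int = 0

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self):
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be > 0")
        if self.bleach_tau <= 0:
            raise ValueError("bleach_tau must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.rest_jitter < 0.125:
            raise ValueError(
                "rest_jitter must stay below half the 0.25 cm/s move threshold"
            )
        if self.offset_slope_sign not in (-1, 1):
            raise ValueError("offset_slope_sign must be +1 or -1")
        return self

    def bleach_curve(self, t: np.ndarray, tau_frac: float = 1.0, scale: float = 1.0):
        return scale * (
            self.baseline_F + self.bleach_amp * np.exp(-t / (self.bleach_tau * tau_frac))
        )


#: generator presets mirroring the two striatonigral subtypes
KREMEN1_LIKE = dict(
    event_lag=0.08,
    offset_slope_sign=1,
    stim_response=StimResponseShape(
        elevation_amp=0.0, suppression_amp=0.02, rebound_amp=0.01, rebound_tau=5.0
    ),
)
CALB1_LIKE = dict(
    event_lag=-0.15,
    offset_slope_sign=-1,
    stim_response=StimResponseShape(
        elevation_amp=0.008, suppression_amp=0.005, rebound_amp=0.0, rebound_tau=5.0
    ),
)


@dataclass
class GroundTruth:
    """Generator-side truth for parameter-recovery tests."""

    true_bouts: Optional[BoutTable] = None
    true_event_lag: float = np.nan
    true_offset_slope: float = np.nan  # a.u./s, sign matches the generated trend
    true_stim_amplitudes: Optional[tuple[float, float, float]] = None
    artifact_trace: Optional[np.ndarray] = None
    transient_trace: Optional[np.ndarray] = None  # transient-only component
    response_trace: Optional[np.ndarray] = None  # noiseless stim response, dF/F
    noisy_response_trace: Optional[np.ndarray] = None  # response + drawn noise
    epoch_factors: Optional[dict] = None


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _lowpass_noise(
    rng: np.random.Generator, n: int, sd: float, corner: float, rate: float
) -> np.ndarray:
    """Zero-mean low-pass filtered Gaussian noise with the requested SD.

    The white-noise draw happens regardless of ``sd`` so that sessions
    generated from one seed stay comparable when an amplitude is zeroed.
    """
    w = rng.standard_normal(n)
    if sd == 0:
        return np.zeros(n)
    sos = sps.butter(2, corner, fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, w)
    x -= x.mean()
    s = x.std()
    return x * (sd / s) if s > 0 else x


def simulate_locomotion(
    config: SynthConfig, params: Optional[AnalysisParams] = None
) -> tuple[BehaviorTrack, BoutTable]:
    """Zero-inflated treadmill velocity with ground-truth segmentation.

    Rest is near-zero jitter strictly below the movement threshold; bouts
    are smooth trapezoids placed by a Poisson-like renewal process.  The
    returned :class:`BoutTable` gives the exact threshold crossings of the
    generated trace, so a correct detector recovers it sample-for-sample.
    """
    p = params or AnalysisParams()
    rng = _rng(config, 1)
    n = int(round(config.duration * config.rate))
    dt = 1.0 / config.rate
    t = np.arange(n) * dt

    expected = config.bout_rate * config.duration / 60.0
    if expected < 1:
        warnings.warn(
            f"expected bout count {expected:.2f} < 1; bout table may be empty",
            stacklevel=2,
        )

    # renewal process: next onset = previous onset + max(Exp, occupied time)
    bout_list = []  # (onset s, duration s, peak velocity cm/s)
    min_gap = max(2.0 * p.min_rest_dur, 1.6) + 2 * config.ramp_time
    if config.bout_rate > 0:
        scale = 60.0 / config.bout_rate
        onset = config.edge_margin + rng.exponential(scale)
        while True:
            dur = max(1.0, rng.gamma(4.0, config.bout_dur_mean / 4.0))
            vel = max(1.2, rng.normal(config.bout_vel_mean, 0.6))
            if onset + dur + config.ramp_time + config.edge_margin > config.duration:
                break
            bout_list.append((onset, dur, vel))
            onset = onset + max(rng.exponential(scale), dur + min_gap)

    v = np.zeros(n)
    ramp = config.ramp_time
    for onset, dur, vel in bout_list:
        a = int(round((onset - ramp) * config.rate))
        b = int(round((onset + dur + ramp) * config.rate))
        seg_t = t[a:b]
        up = _smoothstep((seg_t - (onset - ramp)) / ramp)
        down = _smoothstep(((onset + dur + ramp) - seg_t) / ramp)
        v[a:b] += vel * np.minimum(up, down)
    jitter = np.abs(
        _lowpass_noise(rng, n, config.rest_jitter / 2.5, 2.0, config.rate)
    )
    np.clip(jitter, 0.0, 0.999 * config.rest_jitter, out=jitter)
    v = v + jitter

    # ground truth: exact threshold crossings of the final trace per bout
    rows = []
    for onset, dur, vel in bout_list:
        a = max(0, int(round((onset - ramp) * config.rate)) - 2)
        b = min(n, int(round((onset + dur + ramp) * config.rate)) + 2)
        above = np.flatnonzero(v[a:b] > p.move_threshold)
        if above.size == 0:
            continue
        i0, i1 = a + above[0], a + above[-1] + 1  # [i0, i1) supra-threshold
        rows.append(
            {
                "onset": t[i0],
                "offset": t[0] + i1 * dt,
                "duration": (i1 - i0) * dt,
                "mean_velocity": float(v[i0:i1].mean()),
                "kind": "movement",
            }
        )
    track = BehaviorTrack(t=t, velocity=v)
    return track, BoutTable.from_rows(rows, span=n * dt)


def simulate_photometry(
    config: SynthConfig,
    behavior: BehaviorTrack,
    true_bouts: BoutTable,
) -> tuple[PhotometrySession, GroundTruth]:
    """Two-channel photometry locked to the given locomotion.

    ``signal`` = bleaching + onset-locked transients (at bout onset +
    ``event_lag``) + an offset-locked ramp whose pre-offset slope has
    ``offset_slope_sign`` + shared artifact + white noise.  ``reference``
    carries its own bleaching, the same artifact with a different gain,
    and noise — never transients.
    """
    rng = _rng(config, 2)
    t = behavior.t
    n = t.size
    rate = config.rate
    if abs(behavior.sample_rate - rate) * config.duration > 0.5:
        raise ValueError("behavior track and config disagree on sample rate")

    artifact = _lowpass_noise(rng, n, config.motion_amp, config.artifact_corner, rate)

    transients = np.zeros(n)
    onsets = true_bouts.df["onset"].to_numpy() if len(true_bouts) else np.array([])
    offsets = true_bouts.df["offset"].to_numpy() if len(true_bouts) else np.array([])
    train = np.zeros(n)
    for ev in onsets + config.event_lag:
        i = int(round((ev - t[0]) * rate))
        if 0 <= i < n:
            train[i] = 1.0
    if train.any():
        kernel = config.transient_kernel.evaluate(rate)
        transients = sps.fftconvolve(train, kernel)[:n]
    # offset-locked trend: linear approach over the 0.5 s before offset,
    # returning to zero over 1 s afterwards
    peak = config.offset_ramp_rate * 0.5
    for off in offsets:
        i0 = int(round((off - 0.5 - t[0]) * rate))
        i1 = int(round((off - t[0]) * rate))
        i2 = int(round((off + 1.0 - t[0]) * rate))
        i0c, i2c = max(i0, 0), min(i2, n)
        seg = np.arange(i0c, i2c)
        tri = np.where(
            seg < i1,
            (seg - i0) / max(i1 - i0, 1),
            1.0 - (seg - i1) / max(i2 - i1, 1),
        )
        transients[i0c:i2c] += config.offset_slope_sign * peak * np.clip(tri, 0, 1)

    signal = (
        config.bleach_curve(t)
        + transients
        + config.motion_gain_signal * artifact
        + config.noise_sd * rng.standard_normal(n)
    )
    reference = (
        config.bleach_curve(
            t, tau_frac=config.ref_bleach_tau_frac, scale=config.ref_baseline_frac
        )
        + config.motion_gain_ref * artifact
        + config.noise_sd * rng.standard_normal(n)
    )
    events = [(float(ts), "locomotion_onset") for ts in onsets]
    events += [(float(ts), "locomotion_offset") for ts in offsets]
    session = PhotometrySession(
        t=t,
        signal=signal,
        reference=reference,
        sample_rate=rate,
        signal_wavelength=465,
        events=sorted(events),
    )
    truth = GroundTruth(
        true_bouts=true_bouts,
        true_event_lag=config.event_lag,
        true_offset_slope=config.offset_slope_sign * config.offset_ramp_rate,
        artifact_trace=artifact,
        transient_trace=transients,
    )
    return session, truth


def simulate_session(
    config: SynthConfig, params: Optional[AnalysisParams] = None
) -> tuple[SessionBundle, GroundTruth]:
    """Behavior + photometry bundle for one treadmill session."""
    behavior, true_bouts = simulate_locomotion(config, params)
    photometry, truth = simulate_photometry(config, behavior, true_bouts)
    return (
        SessionBundle(photometry=photometry, behavior=behavior, subject_id="synthetic"),
        truth,
    )


def stim_response_trace(
    config: SynthConfig, protocol: StimProtocol, t: np.ndarray
) -> np.ndarray:
    """Noiseless stimulation response in dF/F units on the grid ``t``.

    Per trial: an elevation boxcar over [0.3, 1.2) s after onset, a linear
    suppression ramp reaching ``-suppression_amp`` at the final stimulated
    sample, and an exponential rebound from offset.
    """
    shape = config.stim_response
    rate = config.rate
    dt = 1.0 / rate
    r = np.zeros(t.size)
    for on, dur in zip(protocol.trial_onsets, protocol.trial_durations):
        off = on + dur
        if shape.elevation_amp != 0.0:
            m = (t >= on + 0.3 - 1e-9) & (t < on + 1.2 - 1e-9)
            r[m] += shape.elevation_amp
        if shape.suppression_amp != 0.0:
            m = (t >= on - 1e-9) & (t < off - 1e-9)
            # full depth at the last stimulated sample
            r[m] += -shape.suppression_amp * (t[m] - on) / max(dur - dt, dt)
        if shape.rebound_amp != 0.0:
            m = t >= off - 1e-9
            r[m] += shape.rebound_amp * np.exp(-(t[m] - off) / shape.rebound_tau)
    return r


def simulate_aligned_trials(
    n_trials: int = 40,
    lag_range: tuple[float, float] = (-1.0, 0.5),
    rate: float = 1000.0,
    step_lag: Optional[float] = None,
    step_amp: float = 1.0,
    trend_slope: float = 0.0,
    noise_sd: float = 0.3,
    noise_corner: float = 1.0,
    seed: int = 0,
):
    """Event-aligned trial matrix with a known step latency and/or trend.

    Each trial is band-limited Gaussian noise (zero-phase low-pass at
    ``noise_corner`` Hz, SD ``noise_sd`` z-units — photometry z-scores are
    band-limited, which is what makes the consecutive-window rise rule an
    effective multiplicity control) plus, optionally, a step of
    ``step_amp`` at ``step_lag`` and a linear trend of ``trend_slope``
    z-units/s through lag 0.  Returns an
    :class:`~stridefiber.events.AlignedMatrix`.
    """
    from .events import AlignedMatrix

    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    nlo = int(round(lag_range[0] * rate))
    nhi = int(round(lag_range[1] * rate))
    lags = np.arange(nlo, nhi + 1) / rate
    n = lags.size
    if noise_sd > 0:
        w = rng.standard_normal((n_trials, n))
        sos = sps.butter(2, noise_corner, fs=rate, output="sos")
        X = sps.sosfiltfilt(sos, w, axis=1)
        X *= noise_sd / X.std()
    else:
        X = np.zeros((n_trials, n))
    if step_lag is not None:
        X[:, lags >= step_lag - 1e-9] += step_amp
    if trend_slope != 0.0:
        X += trend_slope * lags
    return AlignedMatrix(lags=lags, data=X, anchor="onset")


def expected_stim_metrics(
    config: SynthConfig, stim_duration: float
) -> tuple[float, float, float]:
    """Closed-form expected (initial_elevation, max_reduction,
    post_stim_change) of the noiseless generated response.

    The elevation window [0.5, 1.0) also sees the suppression ramp; the
    rebound mean is the exact finite geometric sum of the sampled
    exponential over [4, 9) s post offset.
    """
    shape = config.stim_response
    dt = 1.0 / config.rate
    d = stim_duration
    ramp_mean = -shape.suppression_amp * (0.75 - dt / 2.0) / max(d - dt, dt)
    elevation = shape.elevation_amp + ramp_mean
    reduction = -shape.suppression_amp if shape.suppression_amp > 0 else 0.0
    n_post = int(round(5.0 * config.rate))
    q = np.exp(-dt / shape.rebound_tau)
    geom = np.exp(-4.0 / shape.rebound_tau) * (1 - q**n_post) / (n_post * (1 - q))
    post = shape.rebound_amp * geom
    return float(elevation), float(reduction), float(post)


def simulate_stim_session(
    config: SynthConfig, protocol: StimProtocol
) -> tuple[SessionBundle, GroundTruth]:
    """Stimulation session: raw two-channel photometry, schedule, truth.

    The raw signal is ``F_bleach * (1 + response + noise)`` so the stim-mode
    normalization must undo bleaching and channel gain to recover the
    response.  For the 3-min epoch design an open-field velocity trace is
    generated as well, scaled by ``stim_on_vel_factor`` during stimulation
    and ``stim_off_vel_factor`` in the off epochs.
    """
    margin = 10.0
    if protocol.trial_onsets[0] < margin or np.any(
        protocol.trial_offsets + margin > config.duration
    ):
        raise ValueError("trials need >= 10 s margins inside the session")
    rng = _rng(config, 3)
    n = int(round(config.duration * config.rate))
    t = np.arange(n) / config.rate

    response = stim_response_trace(config, protocol, t)
    noisy = response + config.stim_noise_dff * rng.standard_normal(n)
    f = config.bleach_curve(t)
    signal = f * (1.0 + noisy)
    reference = config.bleach_curve(
        t, tau_frac=config.ref_bleach_tau_frac, scale=config.ref_baseline_frac
    ) + config.noise_sd * rng.standard_normal(n)

    photometry = PhotometrySession(
        t=t,
        signal=signal,
        reference=reference,
        sample_rate=config.rate,
        signal_wavelength=560,
        events=[(float(on), "stim_onset") for on in protocol.trial_onsets],
    )
    behavior = None
    factors = None
    if protocol.schedule_kind == "epoch_3min":
        track, _ = simulate_locomotion(config)
        base = track.velocity
        scale = np.ones(n)
        epoch_masks = {"prior": (t >= protocol.trial_onsets[0] - 180.0)
                       & (t < protocol.trial_onsets[0])}
        epoch_scale = {"prior": 1.0}
        t_end = t[0] + n / config.rate
        for k, (on, dur) in enumerate(
            zip(protocol.trial_onsets, protocol.trial_durations), start=1
        ):
            off = on + dur
            off_end = off + 180.0
            if k < protocol.n_trials:
                off_end = min(off_end, protocol.trial_onsets[k])
            off_end = min(off_end, t_end)
            m_on = (t >= on) & (t < off)
            m_off = (t >= off) & (t < off_end)
            scale[m_on] = config.stim_on_vel_factor
            scale[m_off] = config.stim_off_vel_factor
            epoch_masks[f"on_{k}"] = m_on
            epoch_masks[f"off_{k}"] = m_off
            epoch_scale[f"on_{k}"] = config.stim_on_vel_factor
            epoch_scale[f"off_{k}"] = config.stim_off_vel_factor
        behavior = BehaviorTrack(t=t, velocity=base * scale)
        prior_mean = base[epoch_masks["prior"]].mean()
        factors = {
            "on": config.stim_on_vel_factor,
            "off": config.stim_off_vel_factor,
            "expected_velocity_ratio": {
                name: epoch_scale[name] * base[m].mean() / prior_mean
                for name, m in epoch_masks.items()
            },
        }
    shape = config.stim_response
    truth = GroundTruth(
        true_stim_amplitudes=(
            shape.elevation_amp,
            -shape.suppression_amp,
            shape.rebound_amp,
        ),
        response_trace=response,
        noisy_response_trace=noisy,
        epoch_factors=factors,
    )
    bundle = SessionBundle(
        photometry=photometry, behavior=behavior, stim=protocol, subject_id="synthetic"
    )
    return bundle, truth
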