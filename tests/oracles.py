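"""Independent brute-force reference implementations for the tests.

Everything here is written as explicit per-sample scans, deliberately
naive, and shares no code with the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def brute_sliding_percentile(
    x: np.ndarray, rate: float, window: float = 5.0, pct: float = 10.0
) -> np.ndarray:
    """Per-sample percentile over a centered, edge-truncated window."""
    n = len(x)
    w = int(round(window * rate))
    h = w // 2
    out = np.empty(n)
    for i in range(n):
        out[i] = np.percentile(x[max(0, i - h) : min(n, i + h + 1)], pct)
    return out


def _segments(flags: list[bool]) -> list[list]:
    """[state, start, stop) segments of a boolean sequence."""
    segs = []
    i, n = 0, len(flags)
    while i < n:
        j = i
        while j < n and flags[j] == flags[i]:
            j += 1
        segs.append([flags[i], i, j])
        i = j
    return segs


def scan_treadmill_bouts(
    v: np.ndarray,
    rate: float,
    thr: float = 0.25,
    min_move: float = 0.5,
    min_vel: float = 0.5,
    min_rest: float = 0.8,
) -> list[tuple[int, int]]:
    """Exhaustive-scan treadmill segmentation; [start, stop) sample pairs."""
    rest_s = min_rest * rate + 1e-6
    segs = _segments([float(vi) > thr for vi in v])
    # absorb interior rests not strictly longer than min_rest
    changed = True
    while changed:
        changed = False
        for k in range(1, len(segs) - 1):
            m, a, b = segs[k]
            if not m and (b - a) < rest_s and segs[k - 1][0] and segs[k + 1][0]:
                segs = (
                    segs[: k - 1]
                    + [[True, segs[k - 1][1], segs[k + 1][2]]]
                    + segs[k + 2 :]
                )
                changed = True
                break
    bouts = []
    for k, (m, a, b) in enumerate(segs):
        if not m:
            continue
        if (b - a) < min_move * rate - 1e-6:
            continue
        if np.mean(v[a:b]) < min_vel:
            continue
        pre_ok = k > 0 and (segs[k - 1][2] - segs[k - 1][1]) >= rest_s
        post_ok = k < len(segs) - 1 and (segs[k + 1][2] - segs[k + 1][1]) >= rest_s
        if pre_ok and post_ok:
            bouts.append((a, b))
    return bouts


def scan_run_bouts(
    mask: np.ndarray, rate: float, min_dur: float = 0.5, min_sep: float = 0.5
) -> list[tuple[int, int]]:
    """Exhaustive-scan merge-then-filter run detection (open-field rules)."""
    runs = [[a, b] for flag, a, b in _segments([bool(m) for m in mask]) if flag]
    merged: list[list[int]] = []
    for r in runs:
        if merged and (r[0] - merged[-1][1]) <= min_sep * rate + 1e-6:
            merged[-1][1] = r[1]
        else:
            merged.append(list(r))
    return [(a, b) for a, b in merged if (b - a) > min_dur * rate + 1e-6]


def brute_aligned_mean(
    z: np.ndarray, t: np.ndarray, events: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    """Average of per-event segments extracted by direct slicing."""
    rate = (len(t) - 1) / (t[-1] - t[0])
    lo = int(round(window[0] * rate))
    hi = int(round(window[1] * rate))
    segs = []
    for e in np.atleast_1d(events):
        i = int(round((e - t[0]) * rate))
        if i + lo >= 0 and i + hi < len(t):
            segs.append(z[i + lo : i + hi + 1])
    return np.mean(segs, axis=0)


def random_velocity_trace(
    rng: np.random.Generator, duration: float = 60.0, rate: float = 100.0
) -> np.ndarray:
    """Random non-negative velocity with rests, pulses and smooth wander."""
    n = int(duration * rate)
    v = np.zeros(n)
    t_cursor = 0
    while t_cursor < n:
        seg = int(rng.integers(int(0.1 * rate), int(4.0 * rate)))
        level = rng.choice([0.0, 0.0, rng.uniform(0.05, 6.0)])
        v[t_cursor : t_cursor + seg] = level
        t_cursor += seg
    v += rng.normal(0, 0.05, n)
    return np.abs(v)


def random_motion_index(
    rng: np.random.Generator, duration: float = 60.0, rate: float = 100.0
) -> np.ndarray:
    """Random motion index in [0, 1] with sub-2% quiet stretches."""
    n = int(duration * rate)
    m = np.zeros(n)
    t_cursor = 0
    while t_cursor < n:
        seg = int(rng.integers(int(0.1 * rate), int(3.0 * rate)))
        level = rng.choice([rng.uniform(0.0, 0.015), rng.uniform(0.03, 1.0)])
        m[t_cursor : t_cursor + seg] = level
        t_cursor += seg
    return np.clip(m + rng.normal(0, 0.002, n), 0.0, 1.0)
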