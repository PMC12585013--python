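"""Behavioral-state segmentation: per-frame masks from behavior traces.

Behavioral conditioning of the LN analyses works on per-frame boolean masks
aligned to the stimulus clock: locomotion (running above 2 cm/s vs.
stationary), pupil-size tertiles (constricted / neutral / dilated at the
33rd and 66th percentiles), pupil-derivative states (constricting / stable /
dilating at +/-0.01 normalized units per second), and eye stability (gaze
within one interquartile-range band around the median in both coordinates
for at least 2 s).  Behavior samples (30-60 Hz) are aligned to stimulus
frames by nearest sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import BehaviorTrace

RUN_THRESHOLD_CM_S = 2.0
PUPIL_DERIV_THRESHOLD = 0.01  # normalized pupil units per second
EYE_MIN_STABLE_S = 2.0
DERIV_SMOOTH_S = 0.5


def nearest_sample_indices(sample_times: np.ndarray, query_times: np.ndarray
                           ) -> np.ndarray:
    """Index of the nearest behavior sample for each query time."""
    sample_times = np.asarray(sample_times)
    query_times = np.asarray(query_times)
    idx = np.searchsorted(sample_times, query_times)
    idx = np.clip(idx, 1, sample_times.size - 1)
    left = sample_times[idx - 1]
    right = sample_times[idx]
    idx -= (query_times - left) < (right - query_times)
    return idx


def locomotion_mask(
    behavior: BehaviorTrace,
    frame_times: np.ndarray,
    threshold_cm_s: float = RUN_THRESHOLD_CM_S,
) -> dict:
    """Running/stationary masks and locomotion summaries.

    Running means speed strictly above the threshold at the nearest behavior
    sample.  Returns the fraction of frames spent running and the median
    speed over running samples (NaN when the animal never runs).
    """
    if behavior.time.size == 0:
        raise ValueError("empty behavior trace")
    running_samples = behavior.speed > threshold_cm_s
    idx = nearest_sample_indices(behavior.time, frame_times)
    running = running_samples[idx]
    med = (
        float(np.median(behavior.speed[running_samples]))
        if np.any(running_samples)
        else float("nan")
    )
    return {
        "running": running,
        "stationary": ~running,
        "fraction_running": float(running.mean()) if running.size else 0.0,
        "median_running_speed": med,
    }


def pupil_size_states(behavior: BehaviorTrace, frame_times: np.ndarray) -> dict:
    """Constricted / neutral / dilated masks by pupil-size tertiles.

    The 33rd and 66th percentiles are computed over the finite pupil samples
    of this recording phase.  Frames with a missing (NaN) nearest sample are
    excluded from all three masks; otherwise the masks partition the frames.
    A constant pupil is degenerate: everything is neutral and the result is
    flagged.
    """
    pupil = behavior.pupil_size
    finite = np.isfinite(pupil)
    vals = pupil[finite]
    if vals.size == 0:
        raise ValueError("pupil trace entirely missing")
    idx = nearest_sample_indices(behavior.time, frame_times)
    v = pupil[idx]
    ok = np.isfinite(v)
    if np.unique(vals).size < 3:
        return {
            "constricted": np.zeros(v.size, bool),
            "neutral": ok.copy(),
            "dilated": np.zeros(v.size, bool),
            "degenerate": True,
            "p33": float("nan"),
            "p66": float("nan"),
        }
    p33, p66 = np.percentile(vals, [33, 66])
    constricted = ok & (v < p33)
    dilated = ok & (v > p66)
    neutral = ok & ~constricted & ~dilated
    return {
        "constricted": constricted,
        "neutral": neutral,
        "dilated": dilated,
        "degenerate": False,
        "p33": float(p33),
        "p66": float(p66),
    }


def pupil_derivative_states(
    behavior: BehaviorTrace,
    frame_times: np.ndarray,
    threshold_per_s: float = PUPIL_DERIV_THRESHOLD,
    smooth_s: float = DERIV_SMOOTH_S,
) -> dict:
    """Constricting / stable / dilating masks from the pupil time derivative.

    The derivative (centered finite differences on the behavior clock) is
    smoothed with a ``smooth_s`` boxcar before thresholding at
    +/-``threshold_per_s``; the pupil is assumed already normalized (median
    ~1), so "point per second" is a normalized unit per second.
    """
    t, pupil = behavior.time, behavior.pupil_size
    fs = 1.0 / float(np.median(np.diff(t)))
    win = int(round(smooth_s * fs))
    if t.size < max(win, 3):
        raise ValueError("trace shorter than the smoothing window")
    deriv = np.gradient(pupil, t)
    if win > 1:
        kernel = np.ones(win) / win
        # reflect-pad so the smoothed trace keeps full length without edge bias
        padded = np.concatenate([deriv[win - 1:: -1][:win], deriv,
                                 deriv[-1: -win - 1: -1]])
        deriv = np.convolve(padded, kernel, mode="same")[win: win + t.size]
    idx = nearest_sample_indices(t, frame_times)
    d = deriv[idx]
    ok = np.isfinite(d)
    dilating = ok & (d > threshold_per_s)
    constricting = ok & (d < -threshold_per_s)
    stable = ok & ~dilating & ~constricting
    return {"constricting": constricting, "stable": stable, "dilating": dilating}


def eye_stability_mask(
    behavior: BehaviorTrace,
    frame_times: np.ndarray,
    min_duration_s: float = EYE_MIN_STABLE_S,
    band: str = "centered_iqr",
) -> np.ndarray:
    """Frames during which gaze stayed centered for at least ``min_duration_s``.

    A behavior sample is "centered" when both eye coordinates lie within a
    band of total width one interquartile range around the median
    (``|x - median| <= IQR/2``; pass ``band="quartiles"`` for the alternative
    [Q1, Q3] reading).  Only centered runs lasting at least
    ``min_duration_s`` are kept; an all-excluded trace yields an empty mask.
    """
    centered = np.ones(behavior.time.size, dtype=bool)
    for coord in (behavior.eye_x, behavior.eye_y):
        q1, med, q3 = np.percentile(coord[np.isfinite(coord)], [25, 50, 75])
        iqr = q3 - q1
        if band == "centered_iqr":
            centered &= np.abs(coord - med) <= iqr / 2
        elif band == "quartiles":
            centered &= (coord >= q1) & (coord <= q3)
        else:
            raise ValueError(f"unknown band {band!r}")
    # keep only runs of centered samples spanning >= min_duration_s
    kept = np.zeros_like(centered)
    t = behavior.time
    i = 0
    n = centered.size
    while i < n:
        if centered[i]:
            j = i
            while j + 1 < n and centered[j + 1]:
                j += 1
            if t[j] - t[i] >= min_duration_s:
                kept[i: j + 1] = True
            i = j + 1
        else:
            i += 1
    idx = nearest_sample_indices(t, frame_times)
    return kept[idx]


@dataclass
class StateMasks:
    """All per-frame behavioral-state masks for one stimulus."""

    running: np.ndarray
    stationary: np.ndarray
    constricted: np.ndarray
    neutral: np.ndarray
    dilated: np.ndarray
    constricting: np.ndarray
    stable: np.ndarray
    dilating: np.ndarray
    eye_stable: np.ndarray
    fraction_running: float
    median_running_speed: float

    @classmethod
    def from_behavior(
        cls, behavior: BehaviorTrace, frame_times: np.ndarray
    ) -> "StateMasks":
        loco = locomotion_mask(behavior, frame_times)
        size = pupil_size_states(behavior, frame_times)
        deriv = pupil_derivative_states(behavior, frame_times)
        eye = eye_stability_mask(behavior, frame_times)
        return cls(
            running=loco["running"],
            stationary=loco["stationary"],
            constricted=size["constricted"],
            neutral=size["neutral"],
            dilated=size["dilated"],
            constricting=deriv["constricting"],
            stable=deriv["stable"],
            dilating=deriv["dilating"],
            eye_stable=eye,
            fraction_running=loco["fraction_running"],
            median_running_speed=loco["median_running_speed"],
        )
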