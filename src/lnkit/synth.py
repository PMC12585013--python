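"""Synthetic stimuli, ground-truth LN-Poisson neurons and behavior traces.

Every downstream estimator in this package is exercised on data from this
module, so the generators reproduce the statistical structure the analyses
assume: binary full-field white noise at 60 FPS, luminance-balanced
checkerboard noise (half the pixels white in every frame), OFF-ON-OFF flash
protocols (2 s epochs, 1 s gray inter-trial), 8-direction grating responses,
spike trains from a linear-nonlinear-Poisson (LN-Poisson) cascade with a
half-wave-rectified nonlinearity, and pupil/locomotion/eye-position traces
with controllable state structure.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import BehaviorTrace, Session, SpikeTrain, StimulusTrace

FPS = 60.0
DT = 1.0 / FPS

FLASH_LABELS = ("OFF", "ON", "OFF2", "GRAY")
GRATING_ANGLES = np.arange(8) * 45.0  # degrees


@dataclass
class SpatialRF:
    """2-D Gaussian receptive field on the checkerboard pixel grid."""

    center_y: float
    center_x: float
    sigma_long: float
    sigma_short: float
    orientation: float = 0.0  # rad, long-axis angle

    def map(self, ny: int = 18, nx: int = 32) -> np.ndarray:
        """Evaluate the RF as an L2-normalized ny-by-nx weight map."""
        y, x = np.mgrid[0:ny, 0:nx]
        dy = y - self.center_y
        dx = x - self.center_x
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        u = c * dx + s * dy  # along long axis
        v = -s * dx + c * dy
        m = np.exp(-(u**2 / (2 * self.sigma_long**2) + v**2 / (2 * self.sigma_short**2)))
        return m / np.linalg.norm(m)


@dataclass
class GroundTruthNeuron:
    """Parameters of a simulated LN-Poisson neuron.

    The firing rate in frame ``t`` is::

        rate(t) = state_gain(t) * max(0, nl_slope * (proj(t) - nl_threshold))
                  + baseline_rate

    where ``proj`` is the stimulus convolved with ``true_filter`` (and
    spatially weighted by ``spatial_rf`` for checkerboard stimuli).
    ``state_gain`` multiplies the rectified drive, not the baseline, during
    frames where the designated behavioral state (running, by default) is
    active; it is 1 otherwise.
    """

    true_filter: np.ndarray  # per-lag weights, unit L2 norm
    nl_slope: float = 30.0  # Hz per unit projection
    nl_threshold: float = 0.0  # unit projection
    baseline_rate: float = 2.0  # Hz
    state_gain: float = 1.0
    spatial_rf: SpatialRF | None = None
    tuning: np.ndarray | None = None  # mean rate (Hz) per grating direction

    def __post_init__(self) -> None:
        self.true_filter = np.asarray(self.true_filter, dtype=np.float64)
        norm = np.linalg.norm(self.true_filter)
        if norm > 0:
            self.true_filter = self.true_filter / norm
        if self.nl_slope < 0:
            raise ValueError("nl_slope must be >= 0")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")


def biphasic_filter(
    n_lags: int = 30,
    peak_lag_s: float = 0.05,
    trough_delay_s: float = 0.06,
    width_s: float = 0.02,
    trough_frac: float = 0.6,
    polarity: int = 1,
    dt: float = DT,
) -> np.ndarray:
    """A biphasic (difference-of-Gaussians in time) temporal filter, unit L2.

    Lag 0 is the spike frame; the main lobe peaks ``peak_lag_s`` before the
    spike, mimicking the STA shape of a transient visual neuron.
    """
    t = np.arange(n_lags) * dt
    f = np.exp(-((t - peak_lag_s) ** 2) / (2 * width_s**2)) - trough_frac * np.exp(
        -((t - peak_lag_s - trough_delay_s) ** 2) / (2 * (1.4 * width_s) ** 2)
    )
    f = polarity * f
    return f / np.linalg.norm(f)


# ---------------------------------------------------------------------------
# Stimuli


def gen_fullfield_noise(
    duration_s: float,
    fps: float = FPS,
    dist: str = "binary",
    seed: int = 0,
    t0: float = 0.0,
) -> StimulusTrace:
    """Full-field white noise: iid +/-1 (binary) or standard normal frames."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if fps <= 0:
        raise ValueError("fps must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    frame_times = t0 + np.arange(n) / fps
    if dist == "binary":
        values = rng.choice(np.array([-1.0, 1.0]), size=n)
    elif dist == "gaussian":
        values = rng.standard_normal(n)
    else:
        raise ValueError(f"unknown dist {dist!r}")
    return StimulusTrace(kind="fullfield", frame_times=frame_times, values=values)


def gen_checkerboard(
    duration_s: float,
    fps: float = FPS,
    ny: int = 18,
    nx: int = 32,
    seed: int = 0,
    t0: float = 0.0,
) -> StimulusTrace:
    """Luminance-balanced checkerboard noise.

    Each frame is an independent random arrangement with exactly half of the
    ny*nx pixels white (+1), keeping the overall frame luminance constant.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    npix = ny * nx
    if npix % 2:
        raise ValueError("ny*nx must be even for luminance balance")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    frame_times = t0 + np.arange(n) / fps
    # each frame is an independent shuffle of a half-white template
    values = np.tile(np.repeat(np.array([1.0, -1.0]), npix // 2), (n, 1))
    rng.permuted(values, axis=1, out=values)
    return StimulusTrace(
        kind="checkerboard",
        frame_times=frame_times,
        values=values.reshape(n, ny, nx),
    )


def gen_flash_protocol(
    n_trials: int,
    epoch_s: float = 2.0,
    iti_s: float = 1.0,
    fps: float = FPS,
    t0: float = 0.0,
) -> StimulusTrace:
    """Full-field contrast-inverting protocol: OFF, ON, OFF (2 s each), 1 s gray.

    Returned as a frame-clocked trace whose per-frame value is the epoch
    label; one trial spans ``3 * epoch_s + iti_s`` seconds (7 s at defaults).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    labels, durs = FLASH_LABELS, (epoch_s, epoch_s, epoch_s, iti_s)
    per_epoch = [int(round(d * fps)) for d in durs]
    trial = np.concatenate([[lab] * n for lab, n in zip(labels, per_epoch)])
    values = np.tile(trial, n_trials)
    frame_times = t0 + np.arange(values.size) / fps
    return StimulusTrace(kind="flash", frame_times=frame_times, values=values)


def flash_epoch_starts(stim: StimulusTrace) -> dict:
    """Start times of each epoch per trial, keyed by label."""
    values = np.asarray(stim.values)
    starts: dict = {lab: [] for lab in FLASH_LABELS}
    prev = None
    for t, lab in zip(stim.frame_times, values):
        if lab != prev:
            starts[str(lab)].append(float(t))
            prev = lab
    return {k: np.asarray(v) for k, v in starts.items()}


def gen_grating_blocks(
    n_trials: int, block_s: float = 2.0, t0: float = 0.0
) -> StimulusTrace:
    """Direction labels for a moving-grating protocol (8 directions per trial)."""
    angles = np.tile(GRATING_ANGLES, n_trials)
    frame_times = t0 + np.arange(angles.size) * block_s
    return StimulusTrace(kind="grating", frame_times=frame_times, values=angles)


# ---------------------------------------------------------------------------
# Spike generation


def _poisson_spike_times(
    rate_per_bin: np.ndarray, bin_starts: np.ndarray, bin_width: float, rng
) -> np.ndarray:
    """Draw Poisson counts per bin and place spikes uniformly within bins."""
    counts = rng.poisson(rate_per_bin)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    starts = np.repeat(bin_starts, counts)
    times = starts + rng.uniform(0, bin_width, size=total)
    return np.sort(times)


def gen_ln_spikes(
    stim: StimulusTrace,
    neuron: GroundTruthNeuron,
    behavior: BehaviorTrace | None = None,
    seed: int = 0,
    unit_id: str = "ln",
    run_threshold_cm_s: float = 2.0,
) -> SpikeTrain:
    """Simulate spikes of an LN-Poisson neuron driven by a noise stimulus.

    Spikes are generated per frame as Poisson(rate * dt), matching the
    frame-clocked analyses.  If ``behavior`` is given, ``neuron.state_gain``
    multiplies the rectified stimulus drive during running frames
    (speed > ``run_threshold_cm_s``, nearest behavior sample).
    """
    if stim.kind not in ("fullfield", "checkerboard"):
        raise ValueError("gen_ln_spikes needs a fullfield or checkerboard stimulus")
    w = neuron.true_filter
    n = stim.n_frames
    if w.size > n:
        raise ValueError("filter longer than stimulus")
    if stim.kind == "checkerboard":
        if neuron.spatial_rf is None:
            raise ValueError("checkerboard stimulus requires a spatial_rf")
        vals = np.asarray(stim.values, dtype=np.float64)
        rf = neuron.spatial_rf.map(vals.shape[1], vals.shape[2])
        drive = vals.reshape(n, -1) @ rf.ravel()
    else:
        drive = np.asarray(stim.values, dtype=np.float64)
    # proj[f] = sum_k w[k] * drive[f - k]; frames with partial history keep
    # the zero-padded value (they contribute ~nothing to long recordings)
    proj = np.convolve(drive, w)[:n]
    gain = np.ones(n)
    if behavior is not None and neuron.state_gain != 1.0:
        idx = np.clip(
            np.searchsorted(behavior.time, stim.frame_times), 0, behavior.time.size - 1
        )
        gain[behavior.speed[idx] > run_threshold_cm_s] = neuron.state_gain
    rate = gain * np.maximum(0.0, neuron.nl_slope * (proj - neuron.nl_threshold))
    rate += neuron.baseline_rate
    dt = stim.dt
    rng = np.random.default_rng(seed)
    times = _poisson_spike_times(rate * dt, stim.frame_times, dt, rng)
    return SpikeTrain(
        unit_id=unit_id,
        spike_times=times,
        t_start=float(stim.frame_times[0]),
        t_end=float(stim.frame_times[-1] + dt),
    )


def gen_poisson_spikes(
    rate_hz: np.ndarray | float,
    duration_s: float,
    dt: float = 0.001,
    t0: float = 0.0,
    seed: int = 0,
    unit_id: str = "poisson",
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes from a rate profile sampled every ``dt``."""
    n = int(round(duration_s / dt))
    rate = np.broadcast_to(np.asarray(rate_hz, dtype=np.float64), (n,)) \
        if np.ndim(rate_hz) == 0 else np.asarray(rate_hz, dtype=np.float64)[:n]
    rng = np.random.default_rng(seed)
    starts = t0 + np.arange(n) * dt
    times = _poisson_spike_times(rate * dt, starts, dt, rng)
    return SpikeTrain(unit_id=unit_id, spike_times=times, t_start=t0,
                      t_end=t0 + n * dt)


def gen_flash_spikes(
    flash: StimulusTrace,
    on_off_pref: float = 1.0,
    peak_rate_hz: float = 60.0,
    baseline_hz: float = 3.0,
    latency_s: float = 0.05,
    tau_s: float = 0.04,
    seed: int = 0,
    unit_id: str = "flash",
) -> SpikeTrain:
    """Transient flash responses: an alpha-shaped rate burst after each
    preferred transition (ON onset for ON-preferring cells, ON offset for
    OFF-preferring), on top of baseline firing."""
    starts = flash_epoch_starts(flash)
    events = starts["ON"] if on_off_pref >= 0 else starts["OFF2"]
    dt = 0.001
    t_end = float(flash.frame_times[-1] + flash.dt)
    t0 = float(flash.frame_times[0])
    n = int(round((t_end - t0) / dt))
    t = t0 + np.arange(n) * dt
    rate = np.full(n, baseline_hz)
    for ev in events:
        rel = t - ev - latency_s
        m = rel > 0
        rate[m] += peak_rate_hz * (rel[m] / tau_s) * np.exp(1 - rel[m] / tau_s)
    rng = np.random.default_rng(seed)
    times = _poisson_spike_times(rate * dt, t, dt, rng)
    return SpikeTrain(unit_id=unit_id, spike_times=times, t_start=t0, t_end=t_end)


# ---------------------------------------------------------------------------
# Behavior


@dataclass
class BehaviorParams:
    """Knobs of the behavior generator.

    Pupil size follows a slow mean-reverting (Ornstein-Uhlenbeck) walk so
    that tertile and derivative segmentations are non-degenerate; locomotion
    comes in bouts with exponential dwell times so the 2 cm/s threshold sees
    both states; eye position is jittered fixations with occasional saccades.
    """

    fs_hz: float = 30.0
    pupil_mean: float = 1.0  # median-normalized units
    pupil_sd: float = 0.15
    pupil_tau_s: float = 20.0
    run_fraction: float = 0.2
    run_bout_mean_s: float = 10.0
    run_speed_cm_s: float = 8.0
    saccade_rate_hz: float = 0.2
    fixation_sd_deg: float = 3.0
    eye_jitter_deg: float = 0.1


def gen_behavior(
    duration_s: float, seed: int = 0, params: BehaviorParams | None = None,
    t0: float = 0.0,
) -> BehaviorTrace:
    """Generate a pupil/locomotion/eye-position trace with state structure."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    p = params or BehaviorParams()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * p.fs_hz))
    dt = 1.0 / p.fs_hz
    time = t0 + np.arange(n) * dt

    # pupil: OU process, stationary sd = pupil_sd, autocorr time = pupil_tau_s
    a = np.exp(-dt / p.pupil_tau_s)
    noise_sd = p.pupil_sd * np.sqrt(1 - a**2)
    pupil = np.empty(n)
    x = p.pupil_mean + p.pupil_sd * rng.standard_normal()
    for i in range(n):
        x = p.pupil_mean + a * (x - p.pupil_mean) + noise_sd * rng.standard_normal()
        pupil[i] = x

    # locomotion: alternating stationary/running bouts with exponential
    # dwell times, rescaled so the session's running duty matches the
    # configured fraction exactly (the realized duty of a finite draw of
    # exponential bouts would otherwise scatter by several points)
    speed = np.zeros(n)
    if p.run_fraction > 0:
        mean_run = p.run_bout_mean_s
        mean_stat = mean_run * (1 - p.run_fraction) / p.run_fraction
        run_durs, stat_durs = [], []
        total = 0.0
        while total < duration_s:
            stat_durs.append(rng.exponential(mean_stat))
            run_durs.append(rng.exponential(mean_run))
            total += stat_durs[-1] + run_durs[-1]
        run_durs = np.asarray(run_durs) * (
            p.run_fraction * duration_s / np.sum(run_durs)
        )
        stat_durs = np.asarray(stat_durs) * (
            (1 - p.run_fraction) * duration_s / np.sum(stat_durs)
        )
        t = 0.0
        for stat_d, run_d in zip(stat_durs, run_durs):
            t += stat_d
            i0, i1 = int(round(t * p.fs_hz)), min(int(round((t + run_d) * p.fs_hz)), n)
            if i1 > i0:
                prof = p.run_speed_cm_s + 2.0 * rng.standard_normal(i1 - i0)
                speed[i0:i1] = np.maximum(prof, 2.5)
            t += run_d
    # eye: fixations + saccades
    eye_x, eye_y = np.empty(n), np.empty(n)
    fx, fy = rng.normal(0, p.fixation_sd_deg, 2)
    p_sacc = p.saccade_rate_hz * dt
    for i in range(n):
        if rng.random() < p_sacc:
            fx, fy = rng.normal(0, p.fixation_sd_deg, 2)
        eye_x[i] = fx + p.eye_jitter_deg * rng.standard_normal()
        eye_y[i] = fy + p.eye_jitter_deg * rng.standard_normal()
    return BehaviorTrace(time=time, pupil_size=pupil, speed=speed,
                         eye_x=eye_x, eye_y=eye_y)


# ---------------------------------------------------------------------------
# Grating responses


def gen_grating_responses(
    neuron: GroundTruthNeuron, n_trials: int, seed: int = 0, trial_s: float = 2.0
) -> np.ndarray:
    """Mean firing rate per direction (8 angles) from Poisson trial counts."""
    if neuron.tuning is None:
        raise ValueError("neuron has no direction tuning curve")
    tuning = np.asarray(neuron.tuning, dtype=np.float64)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(tuning * trial_s, size=(n_trials, tuning.size))
    return counts.mean(axis=0) / trial_s


def cosine_tuning(preferred_deg: float, base_hz: float = 10.0, mod: float = 1.0
                  ) -> np.ndarray:
    """Tuning curve base*(1 + mod*cos(theta - preferred)) over the 8 angles."""
    th = np.deg2rad(GRATING_ANGLES)
    return base_hz * (1 + mod * np.cos(th - np.deg2rad(preferred_deg)))


# ---------------------------------------------------------------------------
# Whole sessions


def make_session(
    seed: int = 1,
    n_units: int = 3,
    noise_duration_s: float = 300.0,
    n_flash_trials: int = 10,
    n_grating_trials: int = 5,
    treatment: str = "saline",
    phase: str = "pre",
    gain_scale: float = 1.0,
) -> Session:
    """A complete synthetic session: 4 stimuli, behavior, LN-Poisson units.

    The stimuli are laid out sequentially (full-field noise, checkerboard,
    flash protocol, gratings); each unit responds to the noise stimuli
    through its LN cascade, to the flashes with a transient burst, and fires
    at baseline otherwise.  ``gain_scale`` multiplies every unit's
    nonlinearity slope, emulating a treatment that scales response gain.
    """
    rng = np.random.default_rng(seed)
    ff = gen_fullfield_noise(noise_duration_s, seed=seed + 101, t0=0.0)
    t1 = noise_duration_s
    cb = gen_checkerboard(noise_duration_s, seed=seed + 102, t0=t1)
    t2 = t1 + noise_duration_s
    fl = gen_flash_protocol(n_flash_trials, t0=t2)
    t3 = t2 + n_flash_trials * 7.0
    gr = gen_grating_blocks(n_grating_trials, t0=t3)
    t_end = t3 + n_grating_trials * 8 * 2.0
    behavior = gen_behavior(t_end, seed=seed + 103)

    units = []
    for i in range(n_units):
        polarity = 1 if i % 2 == 0 else -1
        filt = biphasic_filter(
            peak_lag_s=rng.uniform(0.04, 0.09), polarity=polarity
        )
        neuron = GroundTruthNeuron(
            true_filter=filt,
            nl_slope=gain_scale * rng.uniform(15, 35),
            nl_threshold=rng.uniform(0.1, 0.4),
            baseline_rate=rng.uniform(1, 4),
            spatial_rf=SpatialRF(
                center_y=rng.uniform(5, 13),
                center_x=rng.uniform(8, 24),
                sigma_long=rng.uniform(1.5, 2.5),
                sigma_short=rng.uniform(1.0, 1.5),
                orientation=rng.uniform(0, np.pi),
            ),
            tuning=cosine_tuning(rng.choice(GRATING_ANGLES), mod=rng.uniform(0, 0.8)),
        )
        uid = f"unit{i:02d}"
        s_ff = gen_ln_spikes(ff, neuron, behavior, seed=seed + 7 * i, unit_id=uid)
        s_cb = gen_ln_spikes(cb, neuron, behavior, seed=seed + 7 * i + 1, unit_id=uid)
        s_fl = gen_flash_spikes(
            fl, on_off_pref=polarity, seed=seed + 7 * i + 2, unit_id=uid
        )
        s_gr = gen_poisson_spikes(
            neuron.baseline_rate, t_end - t3, t0=t3, seed=seed + 7 * i + 3,
            unit_id=uid,
        )
        times = np.sort(
            np.concatenate(
                [s.spike_times for s in (s_ff, s_cb, s_fl, s_gr)]
            )
        )
        units.append(SpikeTrain(unit_id=uid, spike_times=times,
                                t_start=0.0, t_end=t_end))
    session = Session(
        units=units,
        stimuli=[ff, cb, fl, gr],
        behavior=behavior,
        animal_id=f"synthetic{seed}",
        treatment=treatment,
        phase=phase,
    )
    session.validate()
    return session
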