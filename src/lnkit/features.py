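"""Scalar response descriptors.

Latency and frequency of temporal filters, ON-OFF polarity, flash (contrast
step) responses, trial-reliability SNR for unit selection, receptive-field
size from 2-D Gaussian fits, direction/orientation selectivity indices, and
a coarse functional typing of temporal filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit

from .revcorr import SpatialFilter, TemporalFilter
from .session import SpikeTrain, StimulusTrace
from .synth import flash_epoch_starts

SNR_THRESHOLD = 0.15
DS_THRESHOLD = 0.15
FLASH_SEARCH_WINDOW_S = 0.25


# ---------------------------------------------------------------------------
# Temporal-filter descriptors


def _dog(t, a1, mu1, s1, a2, mu2, s2):
    return a1 * np.exp(-((t - mu1) ** 2) / (2 * s1**2)) - a2 * np.exp(
        -((t - mu2) ** 2) / (2 * s2**2)
    )


def fit_dog_latency(
    filt: TemporalFilter, return_fit: bool = False
) -> float | tuple[float, dict]:
    """Peak latency (s) of a temporal filter via a difference-of-Gaussians fit.

    The DoG is fitted by bounded nonlinear least squares, initialized from
    the raw argmax/argmin (three jittered restarts on failure); the latency
    is the time of the global-magnitude extremum of the fitted curve within
    the filter window.  If no fit converges the raw-extremum latency is
    returned and flagged in the fit info.
    """
    t = filt.lag_times
    v = filt.values
    T = t[-1] if t.size > 1 else filt.dt
    i_max, i_min = int(np.argmax(v)), int(np.argmin(v))
    raw_latency = float(t[i_max] if abs(v[i_max]) >= abs(v[i_min]) else t[i_min])
    width0 = max(2 * filt.dt, T / 15)
    p0 = [max(v[i_max], 1e-9), t[i_max], width0,
          max(-v[i_min], 1e-9), t[i_min], width0]
    lims = ([0, 0, filt.dt / 2, 0, 0, filt.dt / 2],
            [10 * np.max(np.abs(v)) + 1e-9, T, T, 10 * np.max(np.abs(v)) + 1e-9,
             T, T])
    rng = np.random.default_rng(0)
    popt = None
    for attempt in range(3):
        start = list(p0)
        if attempt:
            start[1] = float(np.clip(p0[1] + rng.normal(0, 2 * filt.dt), 0, T))
            start[4] = float(np.clip(p0[4] + rng.normal(0, 2 * filt.dt), 0, T))
        try:
            popt, _ = curve_fit(_dog, t, v, p0=start, bounds=lims, maxfev=5000)
            break
        except (RuntimeError, ValueError):
            continue
    if popt is None:
        info = {"converged": False, "latency_s": raw_latency}
        return (raw_latency, info) if return_fit else raw_latency
    grid = np.linspace(0, T, max(20 * t.size, 200))
    curve = _dog(grid, *popt)
    latency = float(grid[int(np.argmax(np.abs(curve)))])
    info = {"converged": True, "params": popt, "latency_s": latency}
    return (latency, info) if return_fit else latency


def spectral_peak_frequency(
    filt: TemporalFilter,
    band_hz: tuple[float, float] = (0.5, 30.0),
    min_fft: int = 1024,
) -> float:
    """Spectral peak frequency (Hz) of the mean-subtracted temporal filter.

    The filter is zero-padded to at least ``min_fft`` samples (keeping the
    60 Hz frame-clock sampling), and the magnitude-spectrum peak is searched
    in the 0.5-30 Hz band.  A flat filter returns NaN.
    """
    v = filt.values - filt.values.mean()
    if np.all(v == 0):
        return float("nan")
    n_fft = min_fft
    while n_fft < v.size:
        n_fft *= 2
    spec = np.abs(np.fft.rfft(v, n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=filt.dt)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    return float(freqs[in_band][int(np.argmax(spec[in_band]))])


def polarity_index(filt: TemporalFilter) -> float:
    """ON-OFF polarity of a temporal filter: (peak - valley) / (peak + valley),
    with peak and valley the magnitudes of the positive and negative extremes."""
    v = filt.values
    peak = max(float(v.max()), 0.0)
    valley = max(float(-v.min()), 0.0)
    if peak + valley == 0:
        return float("nan")
    return (peak - valley) / (peak + valley)


# ---------------------------------------------------------------------------
# Trial-based descriptors


def snr(trial_matrix: np.ndarray) -> float:
    """Response reliability: var_t[trial-mean] / mean_t[across-trial var].

    Computed on trials-by-time firing rates; units with SNR above 0.15 are
    considered visually driven.  Zero across-trial variance everywhere (a
    perfectly repeating response) returns +inf.
    """
    m = np.asarray(trial_matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a trials x time matrix with >= 2 trials")
    num = float(np.var(m.mean(axis=0)))
    den = float(np.mean(np.var(m, axis=0)))
    if den <= 1e-12 * max(num, 1.0):  # identical trials up to rounding
        return float("inf")
    return num / den


def trial_rate_matrix(
    spikes: SpikeTrain, trial_starts: np.ndarray, duration_s: float,
    dt: float = 1.0 / 60.0,
) -> np.ndarray:
    """Trials x time firing-rate matrix (Hz) aligned to trial starts."""
    n_bins = int(round(duration_s / dt))
    out = np.empty((len(trial_starts), n_bins))
    for i, t0 in enumerate(trial_starts):
        edges = t0 + np.arange(n_bins + 1) * dt
        idx = np.searchsorted(edges, spikes.spike_times, side="right") - 1
        counts = np.bincount(idx[(idx >= 0) & (idx < n_bins)], minlength=n_bins)
        out[i] = counts / dt
    return out


@dataclass
class FlashResponse:
    """PSTH-derived response to the contrast-inverting flash protocol."""

    psth_time_s: np.ndarray  # relative to the preferred transition
    psth_hz: np.ndarray  # trial-averaged, Gaussian-smoothed
    on_off_index: float
    peak_latency_ms: float
    peak_rate_hz: float
    aligned_to: str  # "onset" or "offset"


def flash_analysis(
    spikes: SpikeTrain,
    flash: StimulusTrace,
    smoothing_sd_ms: float = 2.0,
) -> FlashResponse:
    """Flash-response analysis: polarity, PSTH, and first-peak latency/rate.

    The ON-OFF index (r_ON - r_OFF) / (r_ON + r_OFF) uses the mean rates in
    the ON and the second OFF epochs.  The PSTH (1 ms bins, trial-averaged,
    smoothed with a Gaussian kernel truncated at 6 SD total support) is
    aligned to stimulus onset for ON-preferring cells (index >= 0) and to
    offset otherwise; the peak is the global maximum within (0, 250] ms.
    """
    starts = flash_epoch_starts(flash)
    on_starts, off2_starts = starts["ON"], starts["OFF2"]
    if len(on_starts) < 2:
        raise ValueError("need >= 2 flash trials")
    epoch_s = float(np.median(off2_starts[: len(on_starts)] - on_starts))

    def mean_rate(t0s: np.ndarray) -> float:
        total = 0
        for t0 in t0s:
            total += np.count_nonzero(
                (spikes.spike_times >= t0) & (spikes.spike_times < t0 + epoch_s)
            )
        return total / (len(t0s) * epoch_s)

    r_on, r_off = mean_rate(on_starts), mean_rate(off2_starts)
    ooi = float("nan") if r_on + r_off == 0 else (r_on - r_off) / (r_on + r_off)
    aligned_to = "onset" if not ooi < 0 else "offset"
    events = on_starts if aligned_to == "onset" else off2_starts

    dt = 0.001
    t_lo, t_hi = -0.05, FLASH_SEARCH_WINDOW_S
    n_bins = int(round((t_hi - t_lo) / dt))
    psth = np.zeros(n_bins)
    for ev in events:
        edges = ev + t_lo + np.arange(n_bins + 1) * dt
        idx = np.searchsorted(edges, spikes.spike_times, side="right") - 1
        psth += np.bincount(idx[(idx >= 0) & (idx < n_bins)], minlength=n_bins)
    psth = psth / (len(events) * dt)
    sd_bins = smoothing_sd_ms / 1000.0 / dt
    smoothed = gaussian_filter1d(psth, sd_bins, truncate=3.0)  # +/-3 SD = 6 SD
    t_axis = t_lo + (np.arange(n_bins) + 0.5) * dt
    search = t_axis > 0
    if np.all(psth[search] == 0):
        peak_latency_ms = float("nan")
        peak_rate = float("nan")
    else:
        k = int(np.argmax(smoothed[search]))
        peak_latency_ms = float(t_axis[search][k] * 1000.0)
        peak_rate = float(smoothed[search][k])
    return FlashResponse(
        psth_time_s=t_axis,
        psth_hz=smoothed,
        on_off_index=ooi,
        peak_latency_ms=peak_latency_ms,
        peak_rate_hz=peak_rate,
        aligned_to=aligned_to,
    )


# ---------------------------------------------------------------------------
# Spatial receptive field


def _gauss2d(coords, amp, cy, cx, s_long, s_short, theta, offset):
    y, x = coords
    dy, dx = y - cy, x - cx
    c, s = np.cos(theta), np.sin(theta)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return offset + amp * np.exp(
        -(u**2 / (2 * s_long**2) + v**2 / (2 * s_short**2))
    )


def fit_rf(spatial: SpatialFilter) -> float:
    """Fit a 2-D Gaussian envelope to a spatial STA map; RF size in pixels.

    RF size is twice the mean SD of the long and short axes, i.e.
    sigma_long + sigma_short.  The fit (amplitude, center, SDs, orientation,
    offset) is stored on ``spatial.fit``; non-convergence returns NaN and
    leaves the fit flagged as such.
    """
    m = spatial.map
    ny, nx = m.shape
    y, x = np.mgrid[0:ny, 0:nx]
    iy, ix = np.unravel_index(np.argmax(np.abs(m)), m.shape)
    amp0 = float(m[iy, ix])
    p0 = [amp0, float(iy), float(ix), 2.0, 1.5, 0.0, 0.0]
    span = max(ny, nx)
    amp_lim = 10 * abs(amp0) + 1e-12
    bounds = (
        [-amp_lim, -2.0, -2.0, 0.05, 0.05, -np.pi, -amp_lim],
        [amp_lim, ny + 2.0, nx + 2.0, span, span, np.pi, amp_lim],
    )
    try:
        popt, _ = curve_fit(
            _gauss2d, (y.ravel(), x.ravel()), m.ravel(), p0=p0, bounds=bounds,
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        spatial.fit = {"converged": False}
        return float("nan")
    amp, cy, cx, s_a, s_b, theta, offset = popt
    s_long, s_short = (s_a, s_b) if s_a >= s_b else (s_b, s_a)
    if s_a < s_b:
        theta += np.pi / 2
    spatial.fit = {
        "converged": True,
        "amplitude": float(amp),
        "center_y": float(cy),
        "center_x": float(cx),
        "sigma_long": float(s_long),
        "sigma_short": float(s_short),
        "orientation": float((theta + np.pi / 2) % np.pi - np.pi / 2),
        "offset": float(offset),
    }
    return float(s_long + s_short)


# ---------------------------------------------------------------------------
# Direction / orientation selectivity


def ds_os_index(rates: np.ndarray, alpha: int = 1,
                angles_deg: np.ndarray | None = None) -> float:
    """Normalized circular vector length of direction-tuned responses.

    ``|sum_k r_k exp(-i alpha w_k)| / sum_k r_k`` with alpha = 1 for
    direction and 2 for orientation selectivity.  All-zero rates are
    undefined (NaN).
    """
    rates = np.asarray(rates, dtype=np.float64)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    if angles_deg is None:
        angles_deg = np.arange(rates.size) * (360.0 / rates.size)
    total = rates.sum()
    if total == 0:
        return float("nan")
    w = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))
    vec = np.sum(rates * np.exp(-1j * alpha * w))
    return float(np.abs(vec) / total)


# ---------------------------------------------------------------------------
# Functional typing of temporal filters


def classify_types(
    filters: list[TemporalFilter], k: int = 6, seed: int = 0
) -> pd.DataFrame:
    """Cluster temporal filters into k functional types (t-SNE + k-means++).

    Filters are L2-normalized, embedded in 2-D with t-SNE, and clustered with
    k-means++.  Clusters are then named heuristically by the polarity of the
    cluster-mean filter (ON/OFF) and its peak-latency tercile within each
    polarity (fast/-/slow), yielding labels like "fast ON" ... "slow OFF".
    Deterministic under the seed.  A degenerate input set (fewer distinct
    filters than clusters) is flagged in ``result.attrs["degenerate"]``.
    """
    from sklearn.cluster import KMeans
    from sklearn.manifold import TSNE

    if len(filters) < k:
        raise ValueError(f"need at least {k} filters")
    X = np.stack([f.normalized() for f in filters])
    if np.unique(X, axis=0).shape[0] < k:
        out = pd.DataFrame(
            {"cluster": np.zeros(len(filters), dtype=int),
             "type_name": ["degenerate"] * len(filters)}
        )
        out.attrs["degenerate"] = True
        return out
    perplexity = float(min(30, max(2, (len(filters) - 1) // 3)))
    emb = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(X)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(emb)
    labels = km.labels_
    dt = filters[0].dt

    # name clusters: polarity sign of the mean filter, latency tercile within
    info = []
    for c in range(k):
        mean_f = X[labels == c].mean(axis=0)
        i_ext = int(np.argmax(np.abs(mean_f)))
        info.append({"cluster": c, "polarity": 1 if mean_f[i_ext] >= 0 else -1,
                     "latency": i_ext * dt})
    names = {}
    for pol, tag in ((1, "ON"), (-1, "OFF")):
        group = sorted(
            [d for d in info if d["polarity"] == pol], key=lambda d: d["latency"]
        )
        n = len(group)
        for rank, d in enumerate(group):
            if n <= 1:
                speed = ""
            elif rank < n / 3:
                speed = "fast "
            elif rank >= 2 * n / 3:
                speed = "slow "
            else:
                speed = ""
            names[d["cluster"]] = f"{speed}{tag}"
    out = pd.DataFrame(
        {"cluster": labels, "type_name": [names[c] for c in labels]}
    )
    out.attrs["degenerate"] = False
    return out
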