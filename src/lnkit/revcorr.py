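"""LN-cascade estimation by reverse correlation.

The linear stage is estimated by the spike-triggered average (STA) of a
white-noise stimulus over a 500 ms window at the 1/60 s frame clock; the
static nonlinearity is the histogram-ratio estimator

    P(response | stimulus) = N(stimulus | response) / N(stimulus) / dt

where both histograms are over the stimulus projected onto the L2-normalized
STA (bin size 0.1).  Per-bin STA significance is assessed against the null
that each STA bin is N(0, 1/C), C the number of triggering spikes; a unit's
filter is accepted when some bin within 200 ms of the spike reaches
p < 1e-10.

Conventions (the estimators are conditioned on behavioral state):
lag 0 is the frame containing the spike, lags count backwards in time; a
spike is retained only if its own frame and the full n_lags-frame history
before it fall inside the state mask, so state-conditioned STAs never mix
states across the filter window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .session import SpikeTrain, StimulusTrace, bin_spikes

N_LAGS_DEFAULT = 30  # 500 ms at 60 FPS
CRITERION_P = 1e-10
CRITERION_WINDOW_S = 0.2


@dataclass
class TemporalFilter:
    """An estimated (or constructed) temporal filter over lag bins.

    ``values[k]`` is the filter at lag ``k`` frames before the spike;
    ``spike_count`` is the number of spikes that entered the STA and sets
    the per-bin null variance 1/C.
    """

    values: np.ndarray
    dt: float = 1.0 / 60.0
    spike_count: int = 0
    p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def n_lags(self) -> int:
        return int(self.values.size)

    @property
    def lag_times(self) -> np.ndarray:
        """Time before spike of each lag bin, s."""
        return np.arange(self.n_lags) * self.dt

    def normalized(self) -> np.ndarray:
        norm = np.linalg.norm(self.values)
        if norm == 0:
            raise ValueError("zero-norm filter")
        return self.values / norm


@dataclass
class Nonlinearity:
    """Binned mapping from filter-projected stimulus to firing rate."""

    bin_edges: np.ndarray  # len = n_bins + 1, multiples of the bin width
    rate_hz: np.ndarray
    occupancy: np.ndarray  # frames per bin
    spike_counts: np.ndarray  # spikes per bin
    dt: float = 1.0 / 60.0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def occupied(self) -> np.ndarray:
        return self.occupancy > 0


@dataclass
class SpatialFilter:
    """Spatial STA map at the temporal peak lag, with optional Gaussian fit."""

    map: np.ndarray  # ny x nx
    peak_lag: int
    dt: float
    spike_count: int
    p_values: np.ndarray | None = None  # per pixel
    fit: dict | None = None  # filled by features.fit_rf

    @property
    def rf_size(self) -> float | None:
        if self.fit is None:
            return None
        return self.fit["sigma_long"] + self.fit["sigma_short"]


# ---------------------------------------------------------------------------
# Core array-level estimators (shared by session-level and simulator paths)


def valid_spike_frames(n_frames: int, n_lags: int, mask: np.ndarray | None
                       ) -> np.ndarray:
    """Boolean per frame: the frame and its full n_lags history are usable."""
    valid = np.zeros(n_frames, dtype=bool)
    valid[n_lags - 1:] = True
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != n_frames:
            raise ValueError("state mask length must equal the frame count")
        # frame f needs mask[f-n_lags+1 .. f] all true
        ok = (
            np.convolve(mask.astype(np.int64), np.ones(n_lags, dtype=np.int64))[
                : n_frames
            ]
            == n_lags
        )
        valid &= ok
    return valid


def sta_from_counts(
    counts: np.ndarray,
    stim_values: np.ndarray,
    n_lags: int,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """STA over lags 0..n_lags-1 from per-frame spike counts.

    ``STA[k]`` is the count-weighted mean of ``stim[f - k]`` over retained
    spike frames ``f``.  Returns (sta, retained spike count).
    """
    counts = np.asarray(counts)
    stim_values = np.asarray(stim_values, dtype=np.float64)
    n = stim_values.shape[0]
    if counts.size != n:
        raise ValueError("counts and stimulus length differ")
    valid = valid_spike_frames(n, n_lags, mask)
    c = np.where(valid, counts, 0).astype(np.float64)
    C = int(c.sum())
    if C == 0:
        raise ValueError("no spikes under mask")
    flat = stim_values.reshape(n, -1)
    c_v = c[n_lags - 1:]
    out = np.empty((n_lags,) + stim_values.shape[1:])
    for k in range(n_lags):
        # sum over f >= n_lags-1 of c[f] * stim[f-k]
        out[k] = (c_v @ flat[n_lags - 1 - k: n - k]).reshape(
            stim_values.shape[1:]
        ) / C
    if stim_values.ndim == 1:
        out = out.reshape(n_lags)
    return out, C


def projection_series(stim_values: np.ndarray, filter_values: np.ndarray
                      ) -> np.ndarray:
    """Per-frame projection of the preceding stimulus onto a filter.

    ``proj[f] = sum_k w[k] * stim[f-k]`` with zero padding before frame 0;
    only frames with a full history should be used downstream.
    """
    stim_values = np.asarray(stim_values, dtype=np.float64)
    w = np.asarray(filter_values, dtype=np.float64)
    return np.convolve(stim_values, w)[: stim_values.size]


# ---------------------------------------------------------------------------
# Session-level operations


def compute_sta(
    spikes: SpikeTrain,
    stim: StimulusTrace,
    state_mask: np.ndarray | None = None,
    n_lags: int = N_LAGS_DEFAULT,
) -> TemporalFilter:
    """Spike-triggered average of a full-field +/-1 noise stimulus.

    Spikes are binned on the stimulus frame clock; a spike is retained only
    if its frame and all ``n_lags`` preceding frames lie inside
    ``state_mask``.  Raises if no spikes survive.
    """
    if stim.kind != "fullfield":
        raise ValueError("compute_sta expects a fullfield stimulus")
    counts = bin_spikes(spikes, stim.frame_times)
    sta, C = sta_from_counts(counts, stim.values, n_lags, state_mask)
    tf = TemporalFilter(values=sta, dt=stim.dt, spike_count=C)
    tf.p_values = sta_pvalues(tf)
    return tf


def sta_pvalues(filt: TemporalFilter) -> np.ndarray:
    """Two-sided p per lag bin under the null STA_k ~ N(0, 1/C)."""
    if filt.spike_count <= 0:
        raise ValueError("spike_count must be positive")
    z = np.abs(filt.values) * np.sqrt(filt.spike_count)
    return 2.0 * sstats.norm.sf(z)


def passes_sta_criterion(
    filt: TemporalFilter,
    p_threshold: float = CRITERION_P,
    window_s: float = CRITERION_WINDOW_S,
) -> bool:
    """True iff some lag bin within ``window_s`` of the spike has p below
    threshold (unit-selection criterion for visually driven cells)."""
    p = filt.p_values if filt.p_values is not None else sta_pvalues(filt)
    in_window = filt.lag_times <= window_s
    return bool(np.any(p[in_window] < p_threshold))


def _binned_nonlinearity(
    proj: np.ndarray,
    counts: np.ndarray,
    valid: np.ndarray,
    dt: float,
    bin_width: float,
) -> Nonlinearity:
    proj_v = proj[valid]
    counts_v = counts[valid].astype(np.float64)
    lo = np.floor(proj_v.min() / bin_width) * bin_width
    hi = np.ceil(proj_v.max() / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + np.arange(n_bins + 1) * bin_width
    idx = np.clip(((proj_v - lo) / bin_width).astype(np.int64), 0, n_bins - 1)
    occ = np.bincount(idx, minlength=n_bins).astype(np.float64)
    spk = np.bincount(idx, weights=counts_v, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ > 0, spk / np.maximum(occ, 1) / dt, 0.0)
    return Nonlinearity(bin_edges=edges, rate_hz=rate, occupancy=occ,
                        spike_counts=spk, dt=dt)


def compute_nonlinearity(
    spikes: SpikeTrain,
    stim: StimulusTrace,
    filt: TemporalFilter,
    state_mask: np.ndarray | None = None,
    bin_width: float = 0.1,
) -> Nonlinearity:
    """Histogram-ratio static nonlinearity along the L2-normalized filter.

    rate(bin) = (spikes in frames with projection in bin) / (frames in bin) / dt.
    Frames without a full filter history, or excluded by the state mask, are
    dropped from both histograms, so the conservation identity
    sum(rate * occupancy * dt) = retained spike count holds exactly.
    """
    if stim.kind != "fullfield":
        raise ValueError("compute_nonlinearity expects a fullfield stimulus")
    w = filt.normalized()
    counts = bin_spikes(spikes, stim.frame_times)
    proj = projection_series(stim.values, w)
    valid = valid_spike_frames(stim.n_frames, filt.n_lags, state_mask)
    return _binned_nonlinearity(proj, counts, valid, stim.dt, bin_width)


def nonlinearity_from_counts(
    counts: np.ndarray,
    stim_values: np.ndarray,
    filter_values: np.ndarray,
    dt: float,
    mask: np.ndarray | None = None,
    bin_width: float = 0.1,
) -> Nonlinearity:
    """Array-level nonlinearity estimator (used by the simulator sweep)."""
    w = np.asarray(filter_values, dtype=np.float64)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("zero-norm filter")
    proj = projection_series(stim_values, w / norm)
    valid = valid_spike_frames(len(stim_values), w.size, mask)
    return _binned_nonlinearity(proj, np.asarray(counts), valid, dt, bin_width)


def gain_ratio(
    nl_after: Nonlinearity,
    nl_before: Nonlinearity,
    min_occupancy: int = 100,
) -> float:
    """Percent change of response gain between two nonlinearities.

    The ratio of the two curves is reduced to a single occupancy-weighted
    least-squares scale c minimizing sum w * (after - c * before)^2 over bins
    occupied at least ``min_occupancy`` times in both; returns 100*(c - 1).
    Returns NaN when fewer than 3 bins qualify.
    """
    edges_a, edges_b = nl_after.bin_edges, nl_before.bin_edges
    # align the shared binning (both grids are multiples of the bin width)
    width = edges_a[1] - edges_a[0]
    lo = min(edges_a[0], edges_b[0])
    ia = int(round((edges_a[0] - lo) / width))
    ib = int(round((edges_b[0] - lo) / width))
    n = max(ia + nl_after.rate_hz.size, ib + nl_before.rate_hz.size)

    def expand(nl, off):
        r = np.zeros(n)
        o = np.zeros(n)
        r[off: off + nl.rate_hz.size] = nl.rate_hz
        o[off: off + nl.rate_hz.size] = nl.occupancy
        return r, o

    ra, oa = expand(nl_after, ia)
    rb, ob = expand(nl_before, ib)
    use = (oa >= min_occupancy) & (ob >= min_occupancy)
    if use.sum() < 3:
        return float("nan")
    w = np.minimum(oa[use], ob[use])
    denom = np.sum(w * rb[use] ** 2)
    if denom == 0:
        return float("nan")
    c = np.sum(w * rb[use] * ra[use]) / denom
    return 100.0 * (c - 1.0)


def per_bin_gain_ratios(
    nl_after: Nonlinearity, nl_before: Nonlinearity, min_occupancy: int = 100
) -> np.ndarray:
    """Per-bin after/before rate ratios on the shared, well-occupied bins
    (median of these is an alternative gain-change summary)."""
    if nl_after.rate_hz.size != nl_before.rate_hz.size or not np.allclose(
        nl_after.bin_edges, nl_before.bin_edges
    ):
        raise ValueError("curves must share binning")
    use = (
        (nl_after.occupancy >= min_occupancy)
        & (nl_before.occupancy >= min_occupancy)
        & (nl_before.rate_hz > 0)
    )
    return nl_after.rate_hz[use] / nl_before.rate_hz[use]


def compute_spatial_sta(
    spikes: SpikeTrain,
    stim: StimulusTrace,
    stable_mask: np.ndarray | None = None,
    n_lags: int = N_LAGS_DEFAULT,
) -> SpatialFilter:
    """Per-pixel STA of checkerboard noise; the spatial map is taken at the
    lag of the global-magnitude peak across pixels.

    ``stable_mask`` is normally the eye-stability mask so that receptive
    fields are estimated only while gaze is steady.
    """
    if stim.kind != "checkerboard":
        raise ValueError("compute_spatial_sta expects a checkerboard stimulus")
    counts = bin_spikes(spikes, stim.frame_times)
    sta, C = sta_from_counts(counts, stim.values, n_lags, stable_mask)
    mags = np.abs(sta).reshape(n_lags, -1).max(axis=1)
    peak_lag = int(np.argmax(mags))
    smap = sta[peak_lag]
    z = np.abs(smap) * np.sqrt(C)
    return SpatialFilter(
        map=smap,
        peak_lag=peak_lag,
        dt=stim.dt,
        spike_count=C,
        p_values=2.0 * sstats.norm.sf(z),
    )


def mean_evoked_rate(
    spikes: SpikeTrain, stim: StimulusTrace, state_mask: np.ndarray | None = None
) -> float:
    """Mean firing rate (Hz) during stimulation, optionally state-masked."""
    counts = bin_spikes(spikes, stim.frame_times)
    if state_mask is not None:
        counts = counts[np.asarray(state_mask, dtype=bool)]
        n = counts.size
    else:
        n = stim.n_frames
    if n == 0:
        return float("nan")
    return float(counts.sum() / (n * stim.dt))
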