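"""Session data model and on-disk format.

A recording session bundles spike trains of sorted single units, the visual
stimuli that were presented (frame-clocked at a nominal 60 FPS), and the
simultaneously monitored behavior of the animal (pupil size, running speed,
eye position).  All times are in seconds, float64.  The frame clock is
authoritative: analyses are conditioned on the recorded ``frame_times``, not
on an assumed fixed frame rate, so dropped frames are handled naturally.

On disk a session is a single HDF5 file::

    /units/<unit_id>/spike_times     float64, s
    /stimuli/<n>/{kind, frame_times, values}
    /behavior/{time, pupil, speed, eye_x, eye_y}
    /meta/{animal_id, treatment, phase, schema_version}

plus a plain-CSV export (spikes.csv, behavior.csv) for interoperability.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np

SCHEMA_VERSION = 1

STIMULUS_KINDS = ("fullfield", "checkerboard", "flash", "grating")
TREATMENTS = ("saline", "chlorphenamine", "ciproxifan", "psem_tmn", "psem_nontmn")
PHASES = ("pre", "post")


class SessionFormatError(Exception):
    """A session file does not match the expected layout."""


class SessionValidationError(Exception):
    """A session object violates a data-model invariant."""


@dataclass
class SpikeTrain:
    """Spike times of one unit within a recording span.

    ``spike_times`` are sorted, in seconds, and must lie within
    ``[t_start, t_end]``.
    """

    unit_id: str
    spike_times: np.ndarray
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def mean_rate(self) -> float:
        span = self.t_end - self.t_start
        return self.n_spikes / span if span > 0 else np.nan

    def validate(self) -> None:
        if self.t_end < self.t_start:
            raise SessionValidationError(
                f"unit {self.unit_id!r}: t_end < t_start"
            )
        st = self.spike_times
        if st.ndim != 1:
            raise SessionValidationError(f"unit {self.unit_id!r}: spike_times not 1-D")
        if st.size:
            if np.any(np.diff(st) < 0):
                raise SessionValidationError(
                    f"unit {self.unit_id!r}: spike_times not sorted"
                )
            if st[0] < self.t_start or st[-1] > self.t_end:
                raise SessionValidationError(
                    f"unit {self.unit_id!r}: spikes outside [t_start, t_end]"
                )


@dataclass
class StimulusTrace:
    """One frame-clocked stimulus.

    ``values`` depends on ``kind``: per-frame scalar in {-1, +1} (fullfield),
    per-frame ny-by-nx array in {-1, +1} (checkerboard), per-frame epoch
    label (flash), or per-block direction angle in degrees (grating).
    """

    kind: str
    frame_times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        self.values = np.asarray(self.values)

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    @property
    def dt(self) -> float:
        """Median frame interval, s."""
        return float(np.median(np.diff(self.frame_times)))

    def validate(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise SessionValidationError(f"unknown stimulus kind {self.kind!r}")
        if np.any(np.diff(self.frame_times) <= 0):
            raise SessionValidationError(
                f"{self.kind} stimulus: frame_times not strictly increasing"
            )
        if len(self.values) != self.n_frames:
            raise SessionValidationError(
                f"{self.kind} stimulus: {len(self.values)} values for "
                f"{self.n_frames} frames"
            )
        if self.kind in ("fullfield", "checkerboard"):
            vals = np.asarray(self.values, dtype=np.float64)
            if not np.all(np.isin(vals, (-1.0, 1.0))):
                raise SessionValidationError(
                    f"{self.kind} stimulus: values must be exactly +/-1"
                )
            if self.kind == "checkerboard":
                if vals.ndim != 3:
                    raise SessionValidationError(
                        "checkerboard stimulus: values must be frames x ny x nx"
                    )
                # constant-luminance constraint: half the pixels white per frame
                sums = vals.reshape(vals.shape[0], -1).sum(axis=1)
                if np.any(sums != 0):
                    raise SessionValidationError(
                        "checkerboard stimulus: frames are not luminance-balanced"
                    )


@dataclass
class BehaviorTrace:
    """Pupil size, running speed and eye position sampled on a common clock."""

    time: np.ndarray
    pupil_size: np.ndarray
    speed: np.ndarray
    eye_x: np.ndarray
    eye_y: np.ndarray

    def __post_init__(self) -> None:
        for name in ("time", "pupil_size", "speed", "eye_x", "eye_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))

    def validate(self) -> None:
        n = self.time.size
        if np.any(np.diff(self.time) <= 0):
            raise SessionValidationError("behavior: time not strictly increasing")
        for name in ("pupil_size", "speed", "eye_x", "eye_y"):
            if getattr(self, name).size != n:
                raise SessionValidationError(f"behavior: {name} length mismatch")
        if np.any(self.speed < 0):
            raise SessionValidationError("behavior: negative speed")


@dataclass
class Session:
    """One recording session: units, stimuli, behavior, metadata."""

    units: list = field(default_factory=list)
    stimuli: list = field(default_factory=list)
    behavior: BehaviorTrace | None = None
    animal_id: str = "synthetic"
    treatment: str = "saline"
    phase: str = "pre"

    def validate(self) -> None:
        for u in self.units:
            u.validate()
        for s in self.stimuli:
            s.validate()
        if self.behavior is not None:
            self.behavior.validate()
        if self.treatment not in TREATMENTS:
            raise SessionValidationError(f"unknown treatment {self.treatment!r}")
        if self.phase not in PHASES:
            raise SessionValidationError(f"unknown phase {self.phase!r}")
        if self.units:
            t0 = min(u.t_start for u in self.units)
            t1 = max(u.t_end for u in self.units)
            for s in self.stimuli:
                if s.n_frames and (s.frame_times[0] < t0 or s.frame_times[-1] > t1):
                    raise SessionValidationError(
                        f"{s.kind} stimulus outside the recorded span"
                    )
            if self.behavior is not None and self.behavior.time.size:
                if self.behavior.time[0] < t0 or self.behavior.time[-1] > t1:
                    raise SessionValidationError("behavior outside the recorded span")

    def unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def stimulus(self, kind: str) -> StimulusTrace:
        for s in self.stimuli:
            if s.kind == kind:
                return s
        raise KeyError(kind)


def bin_spikes(train: SpikeTrain, frame_times: np.ndarray) -> np.ndarray:
    """Count spikes per stimulus frame at the frame clock (nominally 1/60 s bins).

    Bin ``i`` is the half-open interval ``[frame_i, frame_{i+1})``; the last
    bin closes at the last frame time plus the median frame interval.  A spike
    exactly on a frame boundary is counted in the later bin.
    """
    frame_times = np.asarray(frame_times, dtype=np.float64)
    if frame_times.size == 0:
        raise ValueError("empty frame_times")
    if np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame_times must be strictly increasing")
    if frame_times.size == 1:
        dt = 1.0 / 60.0
    else:
        dt = float(np.median(np.diff(frame_times)))
    edges = np.concatenate([frame_times, [frame_times[-1] + dt]])
    # np.histogram uses half-open bins except the last; shrink the final edge
    # by epsilon-free logic: count with searchsorted for exact half-open bins.
    idx = np.searchsorted(edges, train.spike_times, side="right") - 1
    counts = np.bincount(
        idx[(idx >= 0) & (idx < frame_times.size)], minlength=frame_times.size
    )
    return counts.astype(np.int64)


# ---------------------------------------------------------------------------
# HDF5 I/O


def save_session(session: Session, path: str | os.PathLike) -> None:
    """Write a session to a single HDF5 file (see module docstring for layout)."""
    session.validate()
    with h5py.File(path, "w") as f:
        units = f.create_group("units")
        for u in session.units:
            g = units.create_group(u.unit_id)
            g.create_dataset("spike_times", data=u.spike_times)
            g.attrs["t_start"] = u.t_start
            g.attrs["t_end"] = u.t_end
        stimuli = f.create_group("stimuli")
        for n, s in enumerate(session.stimuli):
            g = stimuli.create_group(str(n))
            g.attrs["kind"] = s.kind
            g.create_dataset("frame_times", data=s.frame_times)
            if s.kind == "flash":
                g.create_dataset(
                    "values", data=np.asarray(s.values, dtype="S8")
                )
            elif s.kind == "checkerboard":
                g.create_dataset(
                    "values", data=np.asarray(s.values, dtype=np.int8)
                )
            else:
                g.create_dataset("values", data=np.asarray(s.values, np.float64))
        if session.behavior is not None:
            b = f.create_group("behavior")
            b.create_dataset("time", data=session.behavior.time)
            b.create_dataset("pupil", data=session.behavior.pupil_size)
            b.create_dataset("speed", data=session.behavior.speed)
            b.create_dataset("eye_x", data=session.behavior.eye_x)
            b.create_dataset("eye_y", data=session.behavior.eye_y)
        meta = f.create_group("meta")
        meta.attrs["animal_id"] = session.animal_id
        meta.attrs["treatment"] = session.treatment
        meta.attrs["phase"] = session.phase
        meta.attrs["schema_version"] = SCHEMA_VERSION


def load_session(path: str | os.PathLike) -> Session:
    """Read and validate a session written by :func:`save_session`."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for required in ("units", "stimuli", "meta"):
            if required not in f:
                raise SessionFormatError(f"missing group /{required}")
        units = []
        for unit_id in sorted(f["units"]):
            g = f["units"][unit_id]
            if "spike_times" not in g:
                raise SessionFormatError(
                    f"missing dataset /units/{unit_id}/spike_times"
                )
            units.append(
                SpikeTrain(
                    unit_id=unit_id,
                    spike_times=g["spike_times"][()],
                    t_start=float(g.attrs["t_start"]),
                    t_end=float(g.attrs["t_end"]),
                )
            )
        stimuli = []
        for n in sorted(f["stimuli"], key=int):
            g = f["stimuli"][n]
            kind = g.attrs["kind"]
            values = g["values"][()]
            if kind == "flash":
                values = np.array([v.decode() for v in values])
            elif kind == "checkerboard":
                values = values.astype(np.float64)
            stimuli.append(
                StimulusTrace(kind=kind, frame_times=g["frame_times"][()],
                              values=values)
            )
        behavior = None
        if "behavior" in f:
            b = f["behavior"]
            behavior = BehaviorTrace(
                time=b["time"][()],
                pupil_size=b["pupil"][()],
                speed=b["speed"][()],
                eye_x=b["eye_x"][()],
                eye_y=b["eye_y"][()],
            )
        meta = f["meta"].attrs
        session = Session(
            units=units,
            stimuli=stimuli,
            behavior=behavior,
            animal_id=str(meta["animal_id"]),
            treatment=str(meta["treatment"]),
            phase=str(meta["phase"]),
        )
    session.validate()
    return session


def export_csv(session: Session, out_dir: str | os.PathLike) -> None:
    """Export spikes.csv (unit_id, time_s) and behavior.csv."""
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    rows = [
        {"unit_id": u.unit_id, "time_s": t}
        for u in session.units
        for t in u.spike_times
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
        os.path.join(out_dir, "spikes.csv"), index=False
    )
    if session.behavior is not None:
        b = session.behavior
        pd.DataFrame(
            {
                "time_s": b.time,
                "pupil": b.pupil_size,
                "speed": b.speed,
                "eye_x": b.eye_x,
                "eye_y": b.eye_y,
            }
        ).to_csv(os.path.join(out_dir, "behavior.csv"), index=False)
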