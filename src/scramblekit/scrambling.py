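"""Leaflet assignment and scrambled-lipid bookkeeping.

A lipid's leaflet is decided by the z-position of its phosphate bead
relative to the membrane center.  A lipid is *scrambled* at time t if
its leaflet then differs from its leaflet at the first analyzed
snapshot.  A flip-flop *event* is a leaflet change between consecutive
analyzed snapshots; a lipid that crosses and returns contributes two
events and no final scrambled count.

The analysis operates on snapshots at a fixed stride (default 10 ns);
midplane excursions shorter than the stride are invisible by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MembraneFrame, Structure
from .errors import ParameterError, ValidationError
from .geometry import membrane_midplane

UP_TO_DOWN = "up->down"
DOWN_TO_UP = "down->up"


def _step_labels(z: np.ndarray, midplane: float,
                 previous: np.ndarray | None,
                 buffer: float = 0.0) -> np.ndarray:
    """Boolean upper-leaflet labels for one snapshot.

    ``buffer`` (nm) is an optional hysteresis half-width: inside
    ``midplane +- buffer`` a lipid keeps its previous label.  Exact ties
    (z == midplane, buffer 0) inherit the previous label, or "upper" at
    the first snapshot.
    """
    z = np.asarray(z, dtype=float)
    upper = z > midplane + buffer
    lower = z < midplane - buffer
    if previous is None:
        # first snapshot: ties/buffer zone default to upper
        return ~lower
    out = previous.copy()
    out[upper] = True
    out[lower] = False
    return out


def assign_leaflets(frame: MembraneFrame, structure: Structure,
                    midplane: float | None = None,
                    previous: np.ndarray | None = None,
                    buffer: float = 0.0) -> np.ndarray:
    """Leaflet labels (True = upper) for every lipid, in residue-id order.

    ``midplane`` defaults to the wrapped mean phosphate z of this frame;
    pass an explicit value to pin the center (e.g. 0 for synthetic CV
    trajectories).
    """
    if midplane is None:
        midplane = membrane_midplane(frame, structure)
    z = frame.coords[structure.headgroup_ids, 2]
    return _step_labels(z, midplane, previous, buffer)


@dataclass
class ScramblingSeries:
    """Results of a scrambled-lipid analysis (the Fig-2A-style object).

    ``scrambled_count[t]`` is the number of lipids currently in the
    leaflet opposite to their initial one; ``cumulative_distinct[t]``
    counts lipids that have been scrambled at any time up to t.
    ``events`` holds ``(lipid_id, time_ps, direction)`` tuples ordered by
    time.
    """

    times: np.ndarray
    lipid_ids: np.ndarray
    labels: np.ndarray  # (n_times, n_lipids) bool, True = upper
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.shape != (len(self.times), len(self.lipid_ids)):
            raise ValidationError("labels shape mismatch")

    @property
    def scrambled_count(self) -> np.ndarray:
        return np.sum(self.labels != self.labels[0], axis=1)

    @property
    def cumulative_distinct(self) -> np.ndarray:
        ever = np.cumsum(self.labels != self.labels[0], axis=0) > 0
        return np.sum(ever, axis=1)

    @property
    def cumulative_events(self) -> np.ndarray:
        ev_times = np.array([t for _, t, _ in self.events], dtype=float)
        return np.array([np.sum(ev_times <= t) for t in self.times])

    @property
    def n_events(self) -> int:
        return len(self.events)

    def events_by_direction(self) -> dict[str, int]:
        out = {UP_TO_DOWN: 0, DOWN_TO_UP: 0}
        for _, _, d in self.events:
            out[d] += 1
        return out

    def running_average(self, window: float = 200_000.0) -> np.ndarray:
        return running_average(self, window)

    def rate(self, duration_us: float | None = None) -> dict[str, float]:
        return scrambling_rate(self, duration_us)

    def to_frame(self, window: float = 200_000.0) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ps": self.times,
            "scrambled_count": self.scrambled_count,
            "running_avg": self.running_average(window),
            "cumulative_events": self.cumulative_events,
            "cumulative_distinct": self.cumulative_distinct,
        })

    def summary(self) -> str:
        span_us = (self.times[-1] - self.times[0]) / 1e6 if len(self.times) > 1 else 0.0
        rates = self.rate() if span_us > 0 else {"total": float("nan")}
        lines = [
            "Scrambled-lipid analysis",
            "=" * 40,
            f"lipids analyzed            {len(self.lipid_ids):>10d}",
            f"snapshots                  {len(self.times):>10d}",
            f"span (us)                  {span_us:>10.4f}",
            f"flip-flop events           {self.n_events:>10d}",
            f"final scrambled count      {int(self.scrambled_count[-1]):>10d}",
        ]
        if span_us > 0:
            lines.append(f"rate (events/us)           {rates['total']:>10.3f}")
        return "\n".join(lines)


class ScramblingAnalysis:
    """Model object: configure a scrambled-lipid analysis, then ``fit``.

    Parameters
    ----------
    frames : sequence of MembraneFrame
        Time-ordered snapshots.
    structure : Structure
        Topology with lipid headgroups identified.
    stride_ps : float
        Analysis stride; only frames whose time offset from the first
        frame is a multiple of the stride are analyzed (default 10 ns).
    midplane : float or None
        Fixed membrane center; None (default) recomputes it per frame.
    buffer : float
        Optional hysteresis half-width around the midplane, nm.
    """

    def __init__(self, frames, structure: Structure,
                 stride_ps: float = 10_000.0,
                 midplane: float | None = None, buffer: float = 0.0):
        self.frames = list(frames)
        self.structure = structure
        self.stride_ps = float(stride_ps)
        self.midplane = midplane
        self.buffer = float(buffer)
        if self.stride_ps <= 0:
            raise ParameterError("stride must be positive")
        times = np.array([f.time for f in self.frames])
        if np.any(np.diff(times) <= 0):
            raise ValidationError("frame times must be strictly increasing")

    def fit(self) -> ScramblingSeries:
        times = np.array([f.time for f in self.frames])
        offsets = times - times[0]
        tol = 1e-6 * max(self.stride_ps, 1.0)
        keep = np.abs(offsets - self.stride_ps * np.round(
            offsets / self.stride_ps)) < tol
        analyzed = [f for f, k in zip(self.frames, keep) if k]
        lipid_ids = self.structure.lipid_residue_ids
        labels = np.empty((len(analyzed), len(lipid_ids)), dtype=bool)
        prev = None
        events = []
        for i, frame in enumerate(analyzed):
            prev = assign_leaflets(frame, self.structure,
                                   midplane=self.midplane, previous=prev,
                                   buffer=self.buffer)
            labels[i] = prev
            if i > 0:
                changed = np.nonzero(labels[i] != labels[i - 1])[0]
                for j in changed:
                    direction = UP_TO_DOWN if labels[i - 1][j] else DOWN_TO_UP
                    events.append((int(lipid_ids[j]), float(frame.time),
                                   direction))
        return ScramblingSeries(np.array([f.time for f in analyzed]),
                                lipid_ids, labels, events)


def scrambling_series(frames, structure: Structure,
                      stride_ps: float = 10_000.0,
                      midplane: float | None = None,
                      buffer: float = 0.0) -> ScramblingSeries:
    """Functional wrapper around :class:`ScramblingAnalysis`."""
    return ScramblingAnalysis(frames, structure, stride_ps=stride_ps,
                              midplane=midplane, buffer=buffer).fit()


def series_from_cv(times, s, lipid_ids=None) -> ScramblingSeries:
    """Scrambling series straight from per-lipid CV trajectories.

    ``s`` has shape (n_times, n_lipids); the membrane center is 0 by
    construction of the CV, so the leaflet rule reduces to the sign of
    s with the usual tie convention.
    """
    s = np.atleast_2d(np.asarray(s, dtype=float))
    times = np.asarray(times, dtype=float)
    if s.shape[0] != len(times):
        raise ValidationError("times/series length mismatch")
    if lipid_ids is None:
        lipid_ids = np.arange(s.shape[1])
    labels = np.empty(s.shape, dtype=bool)
    prev = None
    events = []
    for i in range(s.shape[0]):
        prev = _step_labels(s[i], 0.0, prev)
        labels[i] = prev
        if i > 0:
            for j in np.nonzero(labels[i] != labels[i - 1])[0]:
                direction = UP_TO_DOWN if labels[i - 1][j] else DOWN_TO_UP
                events.append((int(lipid_ids[j]), float(times[i]), direction))
    return ScramblingSeries(times, np.asarray(lipid_ids), labels, events)


def running_average(series, window: float = 200_000.0) -> np.ndarray:
    """Trailing mean of the scrambled count over the preceding ``window`` ps.

    The window is inclusive of the current sample; early samples average
    whatever is available (shorter effective window).
    """
    if isinstance(series, ScramblingSeries):
        times, counts = series.times, series.scrambled_count
    else:
        times, counts = series
        times = np.asarray(times, dtype=float)
        counts = np.asarray(counts, dtype=float)
    if len(times) > 1:
        stride = np.min(np.diff(times))
        if window < stride:
            raise ParameterError(
                f"running-average window {window} ps is shorter than the "
                f"sampling stride {stride} ps")
    out = np.empty(len(times), dtype=float)
    for i, t in enumerate(times):
        mask = (times > t - window) & (times <= t)
        out[i] = float(np.mean(counts[mask]))
    return out


def scrambling_rate(series: ScramblingSeries,
                    duration_us: float | None = None) -> dict[str, float]:
    """Flip-flop events per microsecond, total and per direction.

    ``duration_us`` defaults to the analyzed time span.
    """
    if duration_us is None:
        if len(series.times) < 2:
            raise ParameterError("cannot infer duration from a single snapshot")
        duration_us = (series.times[-1] - series.times[0]) / 1e6
    if duration_us <= 0:
        raise ParameterError("duration must be positive")
    by_dir = series.events_by_direction()
    return {
        "total": series.n_events / duration_us,
        UP_TO_DOWN: by_dir[UP_TO_DOWN] / duration_us,
        DOWN_TO_UP: by_dir[DOWN_TO_UP] / duration_us,
    }
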