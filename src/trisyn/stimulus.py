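"""Presynaptic stimulation: Poisson event trains and binary pulse signals.

A presynaptic release event opens a rectangular pulse of width ``tau``
(default 1 ms) in the drive signal I_pre(t). Events closer together than
``tau`` merge into one longer pulse — the drive is the indicator function of
the union of the intervals [t_i, t_i + tau). Event times are drawn in
continuous time (exponential gaps) and only snapped to the integration grid
when the pulse signal is built, so the stochastic process itself is exact.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidDiscretizationError, InvalidParameterError

__all__ = ["EventTrain", "PulseSignal", "generate_poisson_train", "pulses_from_events"]


@dataclass(frozen=True)
class EventTrain:
    """Ordered presynaptic event times on [0, duration)."""

    times: np.ndarray  # ms, strictly increasing
    duration: float  # ms
    rate: float  # kHz (events/ms)
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] >= self.duration):
            raise InvalidParameterError(
                "event times must be strictly increasing within [0, duration)"
            )

    def __len__(self) -> int:
        return int(self.times.size)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"event_index": np.arange(len(self)), "time_ms": self.times}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, rate: float = np.nan,
                 duration: float | None = None) -> "EventTrain":
        df = pd.read_csv(path)
        t = df["time_ms"].to_numpy(dtype=float)
        dur = duration if duration is not None else (t[-1] + 1.0 if t.size else 1.0)
        return cls(times=t, duration=float(dur), rate=float(rate))


@dataclass(frozen=True)
class PulseSignal:
    """Binary drive I_pre sampled on a fixed grid of step ``dt``."""

    samples: np.ndarray  # uint8 in {0, 1}
    dt: float  # ms
    tau: float  # ms

    def __post_init__(self) -> None:
        s = np.ascontiguousarray(np.asarray(self.samples), dtype=np.uint8)
        object.__setattr__(self, "samples", s)

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt

    @property
    def on_time(self) -> float:
        """Total time (ms) the drive is on."""
        return float(self.samples.sum()) * self.dt

    @property
    def onsets(self) -> np.ndarray:
        """Grid indices where a (possibly merged) pulse begins."""
        s = self.samples
        rising = np.flatnonzero((s[1:] == 1) & (s[:-1] == 0)) + 1
        if s.size and s[0] == 1:
            rising = np.concatenate(([0], rising))
        return rising


def generate_poisson_train(rate: float, duration: float, seed: int | None = None) -> EventTrain:
    """Draw a homogeneous Poisson event train.

    Parameters
    ----------
    rate : float
        Mean event rate in kHz (events per ms). ``rate=0`` yields an empty train.
    duration : float
        Simulated interval length in ms; events lie in [0, duration).
    seed : int, optional
        Seed for the underlying generator; fixed seed gives identical times.
    """
    if rate < 0:
        raise InvalidParameterError(f"rate must be >= 0, got {rate}")
    if duration <= 0:
        raise InvalidParameterError(f"duration must be > 0, got {duration}")
    if rate == 0:
        return EventTrain(np.empty(0), duration, rate, seed)
    rng = np.random.default_rng(seed)
    # Draw exponential gaps in blocks until the horizon is passed.
    expected = rate * duration
    times: list[np.ndarray] = []
    t_last = 0.0
    while t_last < duration:
        block = rng.exponential(1.0 / rate, size=max(int(expected * 0.2) + 16, 64))
        cum = t_last + np.cumsum(block)
        times.append(cum)
        t_last = cum[-1]
    all_times = np.concatenate(times)
    return EventTrain(all_times[all_times < duration], duration, rate, seed)


def pulses_from_events(train: EventTrain, tau: float = 1.0, dt: float = 0.01) -> PulseSignal:
    """Convert an event train to the binary pulse signal I_pre(t).

    Each event at t_i turns the signal on over [t_i, t_i + tau); overlapping
    intervals merge into a single longer pulse. The signal is sampled on the
    grid ``t_j = j*dt`` by marking every sample whose time falls inside the
    union of the intervals.
    """
    if tau <= 0:
        raise InvalidParameterError(f"tau must be > 0, got {tau}")
    if dt <= 0 or dt >= tau:
        raise InvalidDiscretizationError(f"require 0 < dt < tau, got dt={dt}, tau={tau}")
    n = int(round(train.duration / dt))
    samples = np.zeros(n, dtype=np.uint8)
    if len(train):
        start = np.clip(np.ceil(train.times / dt - 1e-9).astype(np.int64), 0, n)
        stop = np.clip(np.ceil((train.times + tau) / dt - 1e-9).astype(np.int64), 0, n)
        # Difference-array trick: O(n + events) union of intervals.
        diff = np.zeros(n + 1, dtype=np.int64)
        np.add.at(diff, start, 1)
        np.add.at(diff, stop, -1)
        samples[:] = (np.cumsum(diff[:-1]) > 0).astype(np.uint8)
    return PulseSignal(samples, dt=dt, tau=tau)
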