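"""Small deterministic synthetic fixtures for tests and demos.

All fixtures are generated programmatically; none model real recordings.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .stimulus import generate_poisson_train

__all__ = ["make_fixtures", "synthetic_hh_trace", "synthetic_logistic_curve"]

KINDS = ("poisson_train", "hh_trace", "logistic_curve")


def synthetic_hh_trace(n_spikes: int = 3, duration: float = 100.0, dt: float = 0.1,
                       rest: float = -65.0, peak: float = 35.0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic voltage trace with evenly spaced stereotyped spike bumps.

    Not an HH solution — a constructed waveform with unambiguous threshold
    crossings for exercising spike detection.
    """
    t = np.arange(0.0, duration, dt)
    V = np.full_like(t, rest)
    centers = (np.arange(1, n_spikes + 1)) * duration / (n_spikes + 1)
    for c in centers:
        V += (peak - rest) * np.exp(-((t - c) ** 2) / (2 * 0.25**2))
    return t, V


def synthetic_logistic_curve(L: float = 0.1, x0: float = 0.2, s: float = 0.05,
                             floor: float = 0.0, n: int = 20,
                             x_max: float = 0.6) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless logistic IO curve for fit self-consistency checks."""
    x = np.linspace(0.0, x_max, n)
    return x, floor + L / (1.0 + np.exp(-(x - x0) / s))


def make_fixtures(kind: str, outdir: str | Path, seed: int = 0,
                  **params) -> Path:
    """Write one named fixture file and return its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "poisson_train":
        rate = params.pop("rate", 0.1)
        duration = params.pop("duration", 1000.0)
        train = generate_poisson_train(rate, duration, seed=seed)
        path = outdir / "poisson_train.csv"
        train.to_csv(path)
    elif kind == "hh_trace":
        t, V = synthetic_hh_trace(**params)
        path = outdir / "hh_trace.csv"
        pd.DataFrame({"time_ms": t, "V_mV": V}).to_csv(path, index=False)
    elif kind == "logistic_curve":
        x, y = synthetic_logistic_curve(**params)
        path = outdir / "logistic_curve.csv"
        pd.DataFrame({"f_in_khz": x, "f_out_khz": y}).to_csv(path, index=False)
    else:
        raise InvalidParameterError(f"unknown fixture kind {kind!r}; valid: {KINDS}")
    return path
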