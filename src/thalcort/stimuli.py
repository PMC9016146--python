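"""Exogenous drive signals: normalized Gaussian noise and flicker pulse trains.

The three drive nodes are voltage signals on the 1 ms reporting grid: Ret and
Asy fluctuate around -65 mV and Sy around -75 mV, all with 2 mV SD.  Noise is
re-normalized after sampling so the realized sample mean and SD match the
targets exactly.  SSVEP flicker is a periodic pulse train (1 ms on-time,
5-10 mV amplitude, 1-30 Hz) superimposed on the Ret noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseConfig",
    "PulseConfig",
    "white_noise",
    "pulse_train",
    "superimpose",
    "drive_signals",
    "NOISE_MEANS",
    "NOISE_SD",
]

#: target noise means per exogenous node (mV)
NOISE_MEANS = {"Ret": -65.0, "Asy": -65.0, "Sy": -75.0}
NOISE_SD = 2.0


@dataclass(frozen=True)
class NoiseConfig:
    mean: float  # mV
    sd: float  # mV
    seed: "int | tuple"  # anything np.random.default_rng accepts
    n: int  # samples
    dt: float = 1e-3  # s
    distribution: str = "gaussian"  # "uniform" available for sensitivity runs

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n <= 0:
            raise ValueError("n must be > 0")


@dataclass(frozen=True)
class PulseConfig:
    frequency: float  # Hz
    amplitude: float  # mV
    duration: float  # s
    on_time: float = 1e-3  # s (one sample on the 1 ms grid)
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.amplitude < 0 or self.duration <= 0:
            raise ValueError("invalid pulse configuration")
        if self.frequency * self.on_time >= 1.0:
            raise ValueError("pulses overlap: frequency * on_time must be < 1")


def white_noise(cfg: NoiseConfig) -> np.ndarray:
    """Seeded noise series with *exactly* the target sample mean and SD.

    Gaussian by default; the raw draw is shifted/scaled so the realized first
    two sample moments (population SD, ddof=0) equal ``cfg.mean``/``cfg.sd``
    to machine precision.  Same seed -> identical series.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.distribution == "gaussian":
        x = rng.standard_normal(cfg.n)
    elif cfg.distribution == "uniform":
        x = rng.uniform(-1.0, 1.0, cfg.n)
    else:
        raise ValueError(f"unknown distribution {cfg.distribution!r}")
    if cfg.sd == 0 or cfg.n == 1:
        return np.full(cfg.n, cfg.mean)
    s = x.std()
    if s == 0:  # pragma: no cover - measure-zero draw
        return np.full(cfg.n, cfg.mean)
    return cfg.mean + (x - x.mean()) * (cfg.sd / s)


def pulse_train(cfg: PulseConfig) -> np.ndarray:
    """Periodic voltage-offset pulses: amplitude for one 1 ms sample per period.

    First pulse at t = 0; the k-th pulse lands on the grid sample nearest
    k / frequency.  Frequencies outside the tested 1-30 Hz range warn but run.
    """
    if not 1.0 <= cfg.frequency <= 30.0:
        warnings.warn(
            f"pulse frequency {cfg.frequency} Hz outside the tested 1-30 Hz range",
            stacklevel=2,
        )
    n = int(round(cfg.duration / cfg.dt))
    out = np.zeros(n)
    k = 0
    while True:
        idx = int(round(k / cfg.frequency / cfg.dt))
        if idx >= n:
            break
        out[idx] = cfg.amplitude
        k += 1
    return out


def superimpose(noise: np.ndarray, pulses: np.ndarray) -> np.ndarray:
    """Elementwise sum of a noise series and a pulse-offset series."""
    if noise.shape != pulses.shape:
        raise ValueError(
            f"length mismatch: noise {noise.shape} vs pulses {pulses.shape}"
        )
    return noise + pulses


def drive_signals(
    n: int,
    seed: int,
    sd: float = NOISE_SD,
    pulse: PulseConfig | None = None,
    distribution: str = "gaussian",
) -> np.ndarray:
    """(3, n) drive matrix for [Ret, Asy, Sy] on the 1 ms grid.

    The three streams are independent: node k uses seed sequence
    ``[seed, k]``.  A pulse train, if given, is superimposed on Ret only.
    """
    out = np.empty((3, n))
    for k, name in enumerate(("Ret", "Asy", "Sy")):
        # independent stream per node, reproducible from (seed, k)
        cfg = NoiseConfig(mean=NOISE_MEANS[name], sd=sd, seed=(seed, k), n=n,
                          distribution=distribution)
        out[k] = white_noise(cfg)
    if pulse is not None:
        out[0] = superimpose(out[0], pulse_train(pulse))
    return out
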