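"""Monte Carlo generation of raw photon arrival events.

Each excitation pulse, every pixel independently detects at most one photon:
a Bernoulli trial with the pixel's photon rate ``p0`` decides whether a
signal photon is seen, and its arrival time is drawn from the
single-exponential decay with that pixel's lifetime, truncated and
renormalized to the measurement window [0, T).  Background / dark counts are
uniform in time.  Everything downstream (dead time, TDC allocation,
quantization) is applied by :mod:`spadflim.readout`; this module produces
the loss-free arrival stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .config import SensorConfig

__all__ = [
    "DecayMap",
    "PhotonEvent",
    "EventStream",
    "generate_photon_arrivals",
    "add_background_events",
    "simulate_exposure",
]

# Pulses are simulated in fixed-size chunks, each with its own RNG substream
# spawned from the root seed, so a stream is reproducible and its prefix does
# not depend on the total number of pulses requested.
_CHUNK = 65536


@dataclass(frozen=True)
class DecayMap:
    """Per-pixel ground truth: lifetime grid (ns) and photon-rate grid."""

    tau: np.ndarray
    p0: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        p0 = np.asarray(self.p0, dtype=float)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "p0", p0)
        if tau.ndim != 2 or tau.shape != p0.shape:
            raise ValueError("tau and p0 must be 2-D grids of equal shape")
        if not np.all(tau > 0):
            raise ValueError("lifetimes must be positive everywhere")
        if np.any((p0 < 0) | (p0 > 1)):
            raise ValueError("photon rates must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tau.shape

    @classmethod
    def uniform(cls, config: SensorConfig, tau: float, p0: float | None = None) -> "DecayMap":
        """Uniform lifetime and intensity across the array."""
        if p0 is None:
            p0 = config.photon_rate_P0
        shape = (config.n_rows, config.n_cols)
        return cls(np.full(shape, float(tau)), np.full(shape, float(p0)))

    @classmethod
    def from_csv(cls, path: str | Path, config: SensorConfig, p0: float | None = None) -> "DecayMap":
        """Read a lifetime grid (ns) from a headerless CSV of floats."""
        tau = np.loadtxt(path, delimiter=",", ndmin=2)
        if tau.shape != (config.n_rows, config.n_cols):
            raise ValueError(
                f"lifetime grid shape {tau.shape} does not match the sensor "
                f"({config.n_rows}, {config.n_cols})"
            )
        if p0 is None:
            p0 = config.photon_rate_P0
        return cls(tau, np.full(tau.shape, float(p0)))

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.tau, delimiter=",", fmt="%.6g")


@dataclass(frozen=True)
class PhotonEvent:
    """A single photon arrival before readout filtering."""

    pulse_index: int
    row: int
    col: int
    t: float  # ns, in [0, T)
    is_background: bool = False


class EventStream:
    """Column-oriented container of photon arrivals for one exposure.

    Events are stored as parallel numpy arrays sorted by
    (pulse_index, arrival time); this is the in-memory form every other
    module consumes.  ``PhotonEvent`` objects are materialised only on
    iteration (small streams / tests).
    """

    def __init__(
        self,
        pulse_index: np.ndarray,
        row: np.ndarray,
        col: np.ndarray,
        t: np.ndarray,
        is_background: np.ndarray,
        *,
        config: SensorConfig,
        decay: DecayMap,
        n_pulses: int,
    ) -> None:
        self.pulse_index = np.asarray(pulse_index, dtype=np.int64)
        self.row = np.asarray(row, dtype=np.int32)
        self.col = np.asarray(col, dtype=np.int32)
        self.t = np.asarray(t, dtype=np.float64)
        self.is_background = np.asarray(is_background, dtype=bool)
        self.config = config
        self.decay = decay
        self.n_pulses = int(n_pulses)
        n = len(self.t)
        if not all(len(a) == n for a in (self.pulse_index, self.row, self.col, self.is_background)):
            raise ValueError("event columns must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    def __iter__(self) -> Iterator[PhotonEvent]:
        for i in range(len(self)):
            yield PhotonEvent(
                int(self.pulse_index[i]),
                int(self.row[i]),
                int(self.col[i]),
                float(self.t[i]),
                bool(self.is_background[i]),
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pulse_index": self.pulse_index,
                "row": self.row,
                "col": self.col,
                "t_ns": self.t,
                "is_background": self.is_background,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, lineterminator="\n")

    def _sort(self) -> None:
        order = np.lexsort((self.col, self.row, self.t, self.pulse_index))
        for name in ("pulse_index", "row", "col", "t", "is_background"):
            setattr(self, name, getattr(self, name)[order])


def _truncated_exp_times(u: np.ndarray, tau: np.ndarray, T: float) -> np.ndarray:
    # inverse CDF of (1/tau) e^{-t/tau} renormalized to [0, T)
    return -tau * np.log1p(-u * (-np.expm1(-T / tau)))


def generate_photon_arrivals(
    config: SensorConfig,
    decay: DecayMap,
    n_pulses: int,
    seed: int | None = None,
) -> EventStream:
    """Simulate signal-photon arrivals for ``n_pulses`` excitation periods.

    Per pulse and pixel, a detection happens with probability
    ``decay.p0[i, j]`` and its time follows the truncated renormalized
    exponential with lifetime ``decay.tau[i, j]`` on [0, T).  At most one
    event per pixel per pulse (the SPAD re-arms only at the global reset).
    Deterministic for a given seed.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    if decay.shape != (config.n_rows, config.n_cols):
        raise ValueError("decay map shape does not match the sensor")
    if seed is None:
        seed = config.seed

    T = config.laser_period_T
    p0_flat = decay.p0.ravel()
    tau_flat = decay.tau.ravel()
    n_pix = config.n_pixels

    root = np.random.SeedSequence(int(seed))
    n_chunks = (n_pulses + _CHUNK - 1) // _CHUNK
    children = root.spawn(n_chunks)

    cols: dict[str, list[np.ndarray]] = {k: [] for k in ("pulse", "pix", "t")}
    for ci in range(n_chunks):
        start = ci * _CHUNK
        size = min(_CHUNK, n_pulses - start)
        rng = np.random.default_rng(children[ci])
        fired = rng.random((size, n_pix)) < p0_flat
        pulse_loc, pix = np.nonzero(fired)
        u = rng.random(len(pix))
        t = _truncated_exp_times(u, tau_flat[pix], T)
        cols["pulse"].append(pulse_loc + start)
        cols["pix"].append(pix)
        cols["t"].append(t)

    pulse = np.concatenate(cols["pulse"])
    pix = np.concatenate(cols["pix"])
    t = np.concatenate(cols["t"])
    row, col = np.divmod(pix, config.n_cols)
    stream = EventStream(
        pulse, row, col, t,
        np.zeros(len(t), dtype=bool),
        config=config, decay=decay, n_pulses=n_pulses,
    )
    stream._sort()
    return stream


def add_background_events(
    stream: EventStream,
    config: SensorConfig,
    seed: int | None = None,
) -> EventStream:
    """Superimpose uniform background / dark-count events on a stream.

    Each pixel independently sees a background event with probability
    ``config.bg_rate`` per pulse, uniform on [0, T).  A pixel fires at most
    once per pulse, so where both a signal and a background event occur the
    earlier one survives.  ``bg_rate = 0`` returns the stream unchanged.
    """
    if config.bg_rate == 0:
        return stream
    if seed is None:
        seed = config.seed + 1

    T = config.laser_period_T
    n_pix = config.n_pixels
    root = np.random.SeedSequence(int(seed))
    n_chunks = (stream.n_pulses + _CHUNK - 1) // _CHUNK
    children = root.spawn(n_chunks)

    pulses, pixes, ts = [], [], []
    for ci in range(n_chunks):
        start = ci * _CHUNK
        size = min(_CHUNK, stream.n_pulses - start)
        rng = np.random.default_rng(children[ci])
        fired = rng.random((size, n_pix)) < config.bg_rate
        pulse_loc, pix = np.nonzero(fired)
        ts.append(rng.random(len(pix)) * T)
        pulses.append(pulse_loc + start)
        pixes.append(pix)

    bg_pulse = np.concatenate(pulses)
    bg_pix = np.concatenate(pixes)
    bg_t = np.concatenate(ts)
    bg_row, bg_col = np.divmod(bg_pix, config.n_cols)

    pulse = np.concatenate([stream.pulse_index, bg_pulse])
    row = np.concatenate([stream.row, bg_row])
    col = np.concatenate([stream.col, bg_col])
    t = np.concatenate([stream.t, bg_t])
    is_bg = np.concatenate(
        [stream.is_background, np.ones(len(bg_t), dtype=bool)]
    )

    # earlier-wins dedup per (pulse, pixel)
    pix_all = row.astype(np.int64) * config.n_cols + col
    key = pulse * n_pix + pix_all
    order = np.lexsort((t, key))
    key_sorted = key[order]
    keep = np.ones(len(key_sorted), dtype=bool)
    keep[1:] = key_sorted[1:] != key_sorted[:-1]
    sel = order[keep]
    out = EventStream(
        pulse[sel], row[sel], col[sel], t[sel], is_bg[sel],
        config=config, decay=stream.decay, n_pulses=stream.n_pulses,
    )
    out._sort()
    return out


def simulate_exposure(
    config: SensorConfig,
    decay: DecayMap,
    n_pulses: int,
    seed: int | None = None,
) -> EventStream:
    """Signal generation plus background, the usual entry point."""
    stream = generate_photon_arrivals(config, decay, n_pulses, seed)
    if config.bg_rate > 0:
        base = config.seed if seed is None else seed
        stream = add_background_events(stream, config, seed=base + 1)
    return stream
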