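"""Sensor and experiment configuration.

The default constants describe a 16x16 single-photon avalanche diode (SPAD)
array for time-correlated single photon counting (TCSPC) fluorescence
lifetime imaging: the array is tiled into 8x8 sub-arrays, each sharing four
time-to-digital converters (TDCs) behind an OR-tree whose pulse width sets
the readout dead time.  The laser runs at 10 MHz (100 ns measurement
window), the TDC least significant bit is 97.6 ps with a 10-bit code space
of which only codes 0..949 are emitted (0-95 ns quantized range).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SensorConfig", "load_config", "dump_config"]

_DEAD_TIME_MODES = ("paralyzable", "nonparalyzable")


@dataclass(frozen=True)
class SensorConfig:
    """All sensor / laser constants of one simulated experiment.

    Times are stored in the unit stated by the field name (ns or ps);
    ``laser_period_T`` and ``laser_rate_mhz`` are redundant and must agree.

    Parameters
    ----------
    n_rows, n_cols : int
        Array resolution (16 x 16 by default).
    subarray_size : int
        Side of the independent sub-arrays sharing one readout chain (8).
    n_tdc_per_subarray : int
        TDCs available per sub-array per excitation period (4).
    laser_period_T : float
        Excitation period / measurement window in ns (100).
    laser_rate_mhz : float
        Laser repetition rate in MHz (10).
    tdc_lsb_h : float
        TDC least-significant-bit (bin width) in ps (97.6).
    tdc_bins_M : int
        Code space of the TDC (1024 for a 10-bit converter).
    tdc_code_max : int
        Largest emitted code + 1; codes >= this are discarded (950).
    dead_time_tp : float
        OR-tree pulse width, i.e. readout dead time, in ps (360).
    encoder_hold_time : float
        Position-encoder hold time in ps; 0 disables the invalid-frame
        mechanism.
    photon_rate_P0 : float
        Probability that a pixel detects a signal photon per pulse (0.01).
    bg_rate : float
        Probability of a uniform background / dark-count event per pixel per
        pulse (0 by default).
    dead_time_mode : str
        'paralyzable' (merged pulses extend the OR-tree output) or
        'nonparalyzable'.
    seed : int
        Default random seed for simulations that do not receive one.
    """

    n_rows: int = 16
    n_cols: int = 16
    subarray_size: int = 8
    n_tdc_per_subarray: int = 4
    laser_period_T: float = 100.0
    laser_rate_mhz: float = 10.0
    tdc_lsb_h: float = 97.6
    tdc_bins_M: int = 1024
    tdc_code_max: int = 950
    dead_time_tp: float = 360.0
    encoder_hold_time: float = 0.0
    photon_rate_P0: float = 0.01
    bg_rate: float = 0.0
    dead_time_mode: str = "paralyzable"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0 or self.subarray_size <= 0:
            raise ValueError("array dimensions must be positive")
        if self.n_rows % self.subarray_size or self.n_cols % self.subarray_size:
            raise ValueError(
                "n_rows and n_cols must be divisible by subarray_size "
                f"({self.n_rows}x{self.n_cols} vs {self.subarray_size})"
            )
        if self.n_tdc_per_subarray < 1:
            raise ValueError("n_tdc_per_subarray must be >= 1")
        for name in ("laser_period_T", "laser_rate_mhz", "tdc_lsb_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("dead_time_tp", "encoder_hold_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.laser_period_T * self.laser_rate_mhz - 1e3) > 1e-6 * 1e3:
            raise ValueError(
                "laser_period_T [ns] must equal 1000 / laser_rate_mhz [MHz]"
            )
        for name in ("photon_rate_P0", "bg_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.tdc_code_max <= self.tdc_bins_M:
            raise ValueError("tdc_code_max must be in (0, tdc_bins_M]")
        if self.tdc_code_max * self.tdc_lsb_h * 1e-3 > self.laser_period_T:
            raise ValueError("quantized range exceeds the laser period")
        if self.dead_time_mode not in _DEAD_TIME_MODES:
            raise ValueError(f"dead_time_mode must be one of {_DEAD_TIME_MODES}")

    # -- derived quantities ------------------------------------------------

    @property
    def h_ns(self) -> float:
        """TDC bin width in ns."""
        return self.tdc_lsb_h * 1e-3

    @property
    def tp_ns(self) -> float:
        """Dead time in ns."""
        return self.dead_time_tp * 1e-3

    @property
    def hold_ns(self) -> float:
        return self.encoder_hold_time * 1e-3

    @property
    def quantized_range_ns(self) -> float:
        """Time span covered by emitted codes 0..tdc_code_max-1."""
        return self.tdc_code_max * self.h_ns

    @property
    def n_subarrays(self) -> int:
        return (self.n_rows // self.subarray_size) * (self.n_cols // self.subarray_size)

    @property
    def pixels_per_subarray(self) -> int:
        return self.subarray_size * self.subarray_size

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    def subarray_of(self, row, col):
        """Sub-array index of pixel(s), row-major over sub-array tiles."""
        import numpy as np

        tiles_per_row = self.n_cols // self.subarray_size
        return (np.asarray(row) // self.subarray_size) * tiles_per_row + (
            np.asarray(col) // self.subarray_size
        )

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SensorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {', '.join(unknown)}")
        return cls(**d)

    def replace(self, **kw: Any) -> "SensorConfig":
        return dataclasses.replace(self, **kw)


def load_config(path: str | Path) -> SensorConfig:
    """Read a SensorConfig from a JSON or YAML file.

    An empty file yields the default configuration; unknown keys are
    rejected with a message listing them.
    """
    text = Path(path).read_text()
    if not text.strip():
        return SensorConfig()
    if str(path).endswith((".yaml", ".yml")):
        data = yaml.safe_load(text)
    else:
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = yaml.safe_load(text)
    if data is None:
        return SensorConfig()
    if not isinstance(data, dict):
        raise ValueError("configuration file must contain a mapping")
    return SensorConfig.from_dict(data)


def dump_config(config: SensorConfig, path: str | Path) -> None:
    """Write a SensorConfig as JSON (load_config round-trips it)."""
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")
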