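"""Event-driven readout emulation.

Per excitation pulse and per 8x8 sub-array the chip applies, in order:

1. OR-tree pulse merging (dead time ``t_p``): two photon pulses closer than
   ``t_p`` merge at the OR-tree output and only the first is processed.  In
   *paralyzable* mode every arrival (processed or merged) extends the
   blocking window; in *nonparalyzable* mode only processed events do.
2. TDC allocation: at most ``n_tdc_per_subarray`` events are time-stamped
   per pulse, in arrival order; the rest are lost (1/16 data-rate reduction
   for 4 TDCs over 64 pixels).
3. Time quantization: ``code = floor(t / h)``; codes at or above
   ``tdc_code_max`` fall outside the quantized range and are discarded.
4. Position encoding and frame validation: the numbers of row, column and
   time entries must match and no encoder may emit the invalid code, which
   happens when two events are closer than the encoder hold time — then the
   whole sub-array frame for that pulse is abandoned.

Every generated event ends up exactly once either recorded or in one of the
four loss categories of :class:`LossReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SensorConfig
from .events import EventStream, PhotonEvent

__all__ = [
    "DetectedEvent",
    "FrameRecord",
    "LossReport",
    "ReadoutResult",
    "apply_dead_time",
    "allocate_tdcs",
    "quantize_time",
    "encode_positions_and_validate",
    "readout_exposure",
]

INVALID_CODE = 0b1000  # encoder output "1000": position could not be latched


@dataclass(frozen=True)
class DetectedEvent:
    """A photon that survived the readout chain, with its TDC code."""

    pulse_index: int
    row: int
    col: int
    t: float
    code: int


@dataclass(frozen=True)
class FrameRecord:
    """One sub-array's output for one excitation period."""

    pulse_index: int
    subarray: int
    time_codes: tuple[int, ...]
    row_codes: tuple[int, ...]
    col_codes: tuple[int, ...]
    valid: bool


@dataclass
class LossReport:
    """Where generated events went missing, by mechanism."""

    dead_time_merged: int = 0
    tdc_exhausted: int = 0
    code_overflow: int = 0
    invalid_frame: int = 0
    generated: int = 0
    recorded: int = 0

    @property
    def total_lost(self) -> int:
        return (
            self.dead_time_merged
            + self.tdc_exhausted
            + self.code_overflow
            + self.invalid_frame
        )

    def to_dict(self) -> dict[str, int]:
        return {
            "generated": self.generated,
            "recorded": self.recorded,
            "dead_time_merged": self.dead_time_merged,
            "tdc_exhausted": self.tdc_exhausted,
            "code_overflow": self.code_overflow,
            "invalid_frame": self.invalid_frame,
        }


# ---------------------------------------------------------------------------
# single-group operations (one sub-array, one pulse) — the reference surface
# ---------------------------------------------------------------------------


def _check_sorted(ts: np.ndarray) -> None:
    if np.any(np.diff(ts) < 0):
        raise ValueError("events must be sorted by arrival time")


def apply_dead_time(
    events: list[PhotonEvent], tp: float, mode: str = "paralyzable"
) -> list[PhotonEvent]:
    """Filter one pulse's sub-array events through the OR-tree dead time.

    ``tp`` is in ns.  An event is discarded iff it arrives strictly less
    than ``tp`` after the reference event: the immediately preceding arrival
    (paralyzable) or the last accepted event (nonparalyzable).  The first
    event is always accepted; an interval of exactly ``tp`` survives.
    Ties in time are broken by (row, col) order (the input must already be
    sorted that way).
    """
    ts = np.array([e.t for e in events])
    _check_sorted(ts)
    if not events:
        return []
    accepted = [events[0]]
    ref_t = events[0].t
    for ev in events[1:]:
        ok = ev.t - ref_t >= tp
        if ok:
            accepted.append(ev)
        if mode == "paralyzable":
            ref_t = ev.t
        elif ok:  # nonparalyzable: only accepted events re-arm the window
            ref_t = ev.t
    return accepted


def allocate_tdcs(events: list[PhotonEvent], n_tdc: int) -> list[PhotonEvent]:
    """Keep the first ``n_tdc`` events in arrival order; drop the rest."""
    _check_sorted(np.array([e.t for e in events]))
    return events[:n_tdc]


def quantize_time(t: float, config: SensorConfig) -> int | None:
    """TDC code of an arrival time, or None when outside the code range.

    Bins are half-open [code*h, (code+1)*h); codes >= ``tdc_code_max`` are
    discarded (the converter output is limited, not saturated).
    """
    if t < 0:
        raise ValueError("arrival time must be non-negative")
    code = int(np.floor(t / config.h_ns))
    return code if code < config.tdc_code_max else None


def encode_positions_and_validate(
    events: list[DetectedEvent], config: SensorConfig
) -> FrameRecord:
    """Emit row/column addresses for one sub-array's kept events.

    With a positive encoder hold time, two events closer than it make the
    earlier event's position unlatchable: its code becomes the invalid code
    and the whole frame is marked invalid (all its data is abandoned
    downstream).
    """
    n = config.subarray_size
    rows = [e.row % n for e in events]
    cols = [e.col % n for e in events]
    for e in events:
        if not (0 <= e.row % n < n and 0 <= e.col % n < n):
            raise ValueError("event position outside the sub-array")
    valid = True
    if config.hold_ns > 0 and len(events) > 1:
        ts = np.array([e.t for e in events])
        clashes = np.diff(ts) < config.hold_ns
        if np.any(clashes):
            valid = False
            for i in np.nonzero(clashes)[0]:
                rows[i] = INVALID_CODE
                cols[i] = INVALID_CODE
    pulse = events[0].pulse_index if events else -1
    sub = int(config.subarray_of(events[0].row, events[0].col)) if events else -1
    return FrameRecord(
        pulse_index=pulse,
        subarray=sub,
        time_codes=tuple(e.code for e in events),
        row_codes=tuple(rows),
        col_codes=tuple(cols),
        valid=valid,
    )


# ---------------------------------------------------------------------------
# vectorized full-exposure pipeline
# ---------------------------------------------------------------------------


class ReadoutResult:
    """Flat arrays of recorded events plus the loss accounting.

    ``valid`` marks events that belong to valid frames (all of them unless
    the encoder hold time is enabled).  ``to_frames`` materialises
    :class:`FrameRecord` objects and is meant for small exposures.
    """

    def __init__(
        self,
        pulse_index: np.ndarray,
        row: np.ndarray,
        col: np.ndarray,
        subarray: np.ndarray,
        code: np.ndarray,
        valid: np.ndarray,
        is_background: np.ndarray,
        losses: LossReport,
        config: SensorConfig,
        n_pulses: int,
    ) -> None:
        self.pulse_index = pulse_index
        self.row = row
        self.col = col
        self.subarray = subarray
        self.code = code
        self.valid = valid
        self.is_background = is_background
        self.losses = losses
        self.config = config
        self.n_pulses = n_pulses

    def __len__(self) -> int:
        return len(self.code)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pulse_index": self.pulse_index,
                "subarray_id": self.subarray,
                "time_code": self.code,
                "row_code": self.row % self.config.subarray_size,
                "col_code": self.col % self.config.subarray_size,
                "valid": self.valid,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, lineterminator="\n")

    def to_frames(self) -> list[FrameRecord]:
        frames: list[FrameRecord] = []
        if len(self) == 0:
            return frames
        key = self.pulse_index * self.config.n_subarrays + self.subarray
        bounds = np.nonzero(np.diff(key))[0] + 1
        n = self.config.subarray_size
        for lo, hi in zip(
            np.concatenate(([0], bounds)), np.concatenate((bounds, [len(self)]))
        ):
            sl = slice(lo, hi)
            frames.append(
                FrameRecord(
                    pulse_index=int(self.pulse_index[lo]),
                    subarray=int(self.subarray[lo]),
                    time_codes=tuple(int(c) for c in self.code[sl]),
                    row_codes=tuple(int(r) % n for r in self.row[sl]),
                    col_codes=tuple(int(c) % n for c in self.col[sl]),
                    valid=bool(self.valid[lo]),
                )
            )
        return frames


def _dead_time_keep_nonparalyzable(
    t: np.ndarray, group_start: np.ndarray, tp: float
) -> np.ndarray:
    keep = np.ones(len(t), dtype=bool)
    ref = -np.inf
    for i in range(len(t)):
        if group_start[i]:
            ref = t[i]
            continue
        if t[i] - ref < tp:
            keep[i] = False
        else:
            ref = t[i]
    return keep


def readout_exposure(stream: EventStream, config: SensorConfig) -> ReadoutResult:
    """Run the whole readout chain over an exposure's event stream.

    Applies per sub-array per pulse: dead-time merging, TDC allocation,
    time quantization, position encoding / frame validation; returns the
    recorded events and a :class:`LossReport` such that
    ``generated == recorded + total_lost``.
    """
    losses = LossReport(generated=len(stream))
    if len(stream) == 0:
        return ReadoutResult(
            *(np.empty(0, dtype=np.int64) for _ in range(5)),
            np.empty(0, dtype=bool),
            np.empty(0, dtype=bool),
            losses,
            config,
            stream.n_pulses,
        )

    sub = np.asarray(config.subarray_of(stream.row, stream.col), dtype=np.int64)
    # sort by (pulse, subarray, t, row, col); ties broken lexicographically
    order = np.lexsort((stream.col, stream.row, stream.t, sub, stream.pulse_index))
    pulse = stream.pulse_index[order]
    row = stream.row[order].astype(np.int64)
    col = stream.col[order].astype(np.int64)
    t = stream.t[order]
    is_bg = stream.is_background[order]
    sub = sub[order]

    key = pulse * config.n_subarrays + sub
    group_start = np.empty(len(key), dtype=bool)
    group_start[0] = True
    group_start[1:] = key[1:] != key[:-1]

    # 1. OR-tree dead time
    tp = config.tp_ns
    if tp == 0:
        keep = np.ones(len(t), dtype=bool)
    elif config.dead_time_mode == "paralyzable":
        keep = np.empty(len(t), dtype=bool)
        keep[0] = True
        keep[1:] = (t[1:] - t[:-1] >= tp) | group_start[1:]
    else:
        keep = _dead_time_keep_nonparalyzable(t, group_start, tp)
    losses.dead_time_merged = int((~keep).sum())

    pulse, row, col, t, is_bg, sub, key = (
        a[keep] for a in (pulse, row, col, t, is_bg, sub, key)
    )

    # 2. TDC allocation: rank within group < n_tdc
    if len(t):
        group_start = np.empty(len(key), dtype=bool)
        group_start[0] = True
        group_start[1:] = key[1:] != key[:-1]
        idx = np.arange(len(key))
        start_idx = np.maximum.accumulate(np.where(group_start, idx, 0))
        rank = idx - start_idx
        keep = rank < config.n_tdc_per_subarray
        losses.tdc_exhausted = int((~keep).sum())
        pulse, row, col, t, is_bg, sub, key = (
            a[keep] for a in (pulse, row, col, t, is_bg, sub, key)
        )

    # 3. time quantization
    code = np.floor(t / config.h_ns).astype(np.int64)
    keep = code < config.tdc_code_max
    losses.code_overflow = int((~keep).sum())
    pulse, row, col, t, is_bg, sub, key, code = (
        a[keep] for a in (pulse, row, col, t, is_bg, sub, key, code)
    )

    # 4. encoder hold time -> frame validity
    valid = np.ones(len(t), dtype=bool)
    if config.hold_ns > 0 and len(t) > 1:
        same_group = key[1:] == key[:-1]
        clash = same_group & (t[1:] - t[:-1] < config.hold_ns)
        # a clash invalidates the whole (pulse, subarray) frame
        bad_keys = np.unique(key[:-1][clash])
        if len(bad_keys):
            valid = ~np.isin(key, bad_keys)
        losses.invalid_frame = int((~valid).sum())

    losses.recorded = int(valid.sum())
    return ReadoutResult(
        pulse, row, col, sub, code, valid, is_bg, losses, config, stream.n_pulses
    )
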