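"""Closed-form pile-up model of the shared-readout sub-array.

When all pixels of an N x N sub-array observe the same decay
(mini-silicon-photomultiplier mode), an arrival at time ``t`` is recorded
only if no other arrival fell in the preceding dead-time window.  With mu
expected photons per sub-array per pulse, the per-pixel expected detection
density is

    c_aver(mu; t) = 1/(N^2 tau) * exp(-t/tau) * B(t)

    B(t) = exp(-mu (1 - e^{-t/tau}))                      t <  t_p
    B(t) = exp(-mu e^{-t/tau} (e^{t_p/tau} - 1))          t >= t_p

i.e. the undisturbed exponential modulated by the probability that the
blocking window [max(t - t_p, 0), t) is empty of other arrivals.  In array
mode each pixel has its own lifetime and rate, and the density of the
target pixel is its own detection density times the product of every other
pixel's miss probability over the same window.  The two branch factors are
continuous at t = t_p and both reduce to 1 when mu -> 0 or t_p -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TheoryParams",
    "expected_density_msp",
    "pixel_detection_density",
    "pixel_miss_probability",
    "modulated_detection_density",
    "counts_error_curve",
]


@dataclass(frozen=True)
class TheoryParams:
    """Parameters of the analytic pile-up model.

    ``mu`` is the expected number of photons the whole sub-array detects per
    pulse (N^2 * p0 in the uniform case); ``tau`` and ``tp`` are in ns.
    ``tau_grid`` / ``p0_grid`` hold per-pixel values for the array-mode
    formulas and default to the uniform case.
    """

    mu: float
    tau: float
    tp: float
    N: int = 8
    tau_grid: np.ndarray | None = None
    p0_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mu < 0 or self.tp < 0 or self.N < 1:
            raise ValueError("mu and tp must be >= 0 and N >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


def expected_density_msp(params: TheoryParams, t) -> np.ndarray:
    """Per-pixel expected detection density in MSP mode (counts per ns).

    Vectorised over ``t``; raises on negative times.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    tau, mu, tp, N = params.tau, params.mu, params.tp, params.N
    decay = np.exp(-t / tau) / (N * N * tau)
    early = -mu * (1.0 - np.exp(-t / tau))
    late = -mu * np.exp(-t / tau) * np.expm1(tp / tau)
    block = np.where(t < tp, early, late)
    return decay * np.exp(block)


def pixel_detection_density(p0: float, tau: float, t) -> np.ndarray:
    """Unmodulated per-pixel detection density (p0/tau) e^{-t/tau}."""
    t = np.asarray(t, dtype=float)
    return (p0 / tau) * np.exp(-t / tau)


def pixel_miss_probability(p0: float, tau: float, tp: float, t) -> np.ndarray:
    """Probability that a pixel does NOT fire in the blocking window.

    The blocking window for an event at time ``t`` is
    [max(t - tp, 0), t); the pixel's chance of firing inside it is the
    integral of its detection density over the window, so the miss
    probability is ``1 - p0 (e^{-max(t-tp,0)/tau} - e^{-t/tau})``.  Always
    in [1 - p0, 1].
    """
    t = np.asarray(t, dtype=float)
    lo = np.maximum(t - tp, 0.0)
    return 1.0 - p0 * (np.exp(-lo / tau) - np.exp(-t / tau))


def modulated_detection_density(
    p0_grid: np.ndarray,
    tau_grid: np.ndarray,
    tp: float,
    target: tuple[int, int],
    t,
) -> np.ndarray:
    """Array-mode detection density of one pixel under neighbour blocking.

    The target pixel's unmodulated density times the product over all other
    pixels of their miss probability in the dead-time window.  For a 1x1
    grid this is exactly the unmodulated density.
    """
    p0_grid = np.asarray(p0_grid, dtype=float)
    tau_grid = np.asarray(tau_grid, dtype=float)
    if p0_grid.shape != tau_grid.shape:
        raise ValueError("p0 and tau grids must have the same shape")
    ti, tj = target
    if not (0 <= ti < p0_grid.shape[0] and 0 <= tj < p0_grid.shape[1]):
        raise ValueError("target pixel outside the grid")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = pixel_detection_density(p0_grid[ti, tj], tau_grid[ti, tj], t)
    log_miss = np.zeros_like(t)
    for i in range(p0_grid.shape[0]):
        for j in range(p0_grid.shape[1]):
            if (i, j) == (ti, tj):
                continue
            log_miss += np.log(
                pixel_miss_probability(p0_grid[i, j], tau_grid[i, j], tp, t)
            )
    return out * np.exp(log_miss)


def counts_error_curve(
    params: TheoryParams,
    n_points: int = 512,
    t_max: float | None = None,
    target: tuple[int, int] = (0, 0),
    signed: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative counts error (modulated - ideal)/ideal on a time grid.

    In MSP mode (no grids supplied) this is the branch factor B(t) - 1 of
    the expected-density model; in array mode it compares the target
    pixel's modulated density with its own unmodulated exponential.  The
    time axis is returned normalized to ``t_max`` (default 10 lifetimes).
    Pile-up suppresses early counts most, so the magnitude is largest near
    the excitation and decays later on.
    """
    if t_max is None:
        t_max = 10.0 * params.tau
    t = np.linspace(0.0, t_max, n_points, endpoint=False)
    if params.tau_grid is None:
        ideal = np.exp(-t / params.tau) / (params.N**2 * params.tau)
        mod = expected_density_msp(params, t)
    else:
        p0g = params.p0_grid
        if p0g is None:
            p0g = np.full_like(params.tau_grid, params.mu / params.tau_grid.size)
        ti, tj = target
        ideal = pixel_detection_density(p0g[ti, tj], params.tau_grid[ti, tj], t)
        mod = modulated_detection_density(p0g, params.tau_grid, params.tp, target, t)
    err = (mod - ideal) / ideal
    if not signed:
        err = np.abs(err)
    return t / t_max, err
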