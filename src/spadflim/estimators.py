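"""Lifetime estimation from TDC-code histograms.

Three estimators of the single-exponential lifetime from a binned,
window-truncated decay histogram (bin width ``h``, ``M`` bins):

* MLE — the maximum-likelihood estimate solves

      1 + {e^{h/tau} - 1}^{-1} - M (e^{M h/tau} - 1)^{-1} = sum_j j N_j / N_c

  whose left side is exactly the mean bin index of the discretized
  truncated exponential; it is strictly increasing in tau, so the root is
  unique and found by bracketed root finding.

* CMM — the centre-of-mass estimate, the first moment of the histogram
  times the bin width.  With 0-based TDC codes the bin-centre estimate is
  ``(mean(code) + 1/2) h``; it ignores window truncation and therefore
  underestimates long lifetimes unless the optional truncation correction
  (inverting the truncated-exponential mean) is applied.

* LSM — minimizes Pearson's chi-square between the histogram and the
  expected binned-exponential counts.  A literal transcendental-equation
  variant (the squared-count-weighted moment identity, with the interval
  symbol read as the bin width) is available as ``mode='equation'``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .config import SensorConfig
from .readout import FrameRecord, ReadoutResult

__all__ = [
    "DecayHistogram",
    "LifetimeEstimate",
    "histogram_from_frames",
    "binned_exponential_probabilities",
    "estimate_cmm",
    "estimate_mle",
    "estimate_lsm",
    "subtract_uniform_background",
    "estimate",
]


@dataclass(frozen=True)
class DecayHistogram:
    """Binned arrival-time counts.

    ``counts[c]`` is the number of events with TDC code ``c`` (0-based);
    the 1-based bin index is ``j = c + 1``.  ``h`` is the bin width in ns.
    """

    counts: np.ndarray
    h: float
    T: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        # float counts are allowed so that expected-count (noise-free)
        # histograms can be fed to the estimators directly
        object.__setattr__(self, "counts", np.asarray(counts, dtype=float))
        if self.h <= 0 or self.T <= 0:
            raise ValueError("h and T must be positive")

    @property
    def M(self) -> int:
        return len(self.counts)

    @property
    def n_counts(self) -> float:
        return float(self.counts.sum())

    def mean_bin_index(self) -> float:
        """Mean 1-based bin index, sum_j j N_j / N_c."""
        if self.n_counts == 0:
            raise ValueError("empty histogram")
        j = np.arange(1, self.M + 1)
        return float(j @ self.counts / self.n_counts)

    @classmethod
    def from_csv(cls, path: str | Path, h: float, T: float) -> "DecayHistogram":
        data = np.loadtxt(path, delimiter=",", ndmin=2, skiprows=1)
        idx = data[:, 0].astype(int)  # 1-based bin index
        counts = np.zeros(int(idx.max()), dtype=float)
        counts[idx - 1] = data[:, 1]
        return cls(counts, h, T)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_index,count\n")
            for j, n in enumerate(self.counts, start=1):
                fh.write(f"{j},{n:g}\n")


@dataclass(frozen=True)
class LifetimeEstimate:
    tau_hat: float  # ns; nan when not converged
    method: str
    converged: bool
    n_used: int


def histogram_from_frames(
    frames: ReadoutResult | list[FrameRecord],
    config: SensorConfig,
    pixel: tuple[int, int] | None = None,
) -> DecayHistogram:
    """Accumulate the TCSPC histogram of one pixel (or the whole array).

    Only valid frames contribute; invalid frames are excluded entirely.
    ``pixel`` is an absolute (row, col); None pools all pixels.
    """
    M = config.tdc_code_max
    if pixel is not None:
        r, c = pixel
        if not (0 <= r < config.n_rows and 0 <= c < config.n_cols):
            raise ValueError("pixel outside the array")
    if isinstance(frames, ReadoutResult):
        sel = frames.valid
        if pixel is not None:
            sel = sel & (frames.row == pixel[0]) & (frames.col == pixel[1])
        codes = frames.code[sel]
    else:
        n = config.subarray_size
        tiles = config.n_cols // n
        codes_list: list[int] = []
        for fr in frames:
            if not fr.valid:
                continue
            sub_r, sub_c = divmod(fr.subarray, tiles)
            for code, rr, cc in zip(fr.time_codes, fr.row_codes, fr.col_codes):
                row = sub_r * n + rr
                col = sub_c * n + cc
                if pixel is None or (row, col) == tuple(pixel):
                    codes_list.append(code)
        codes = np.asarray(codes_list, dtype=np.int64)
    counts = np.bincount(codes, minlength=M) if len(codes) else np.zeros(M, np.int64)
    return DecayHistogram(counts, h=config.h_ns, T=config.laser_period_T)


def binned_exponential_probabilities(tau: float, h: float, M: int) -> np.ndarray:
    """Bin probabilities of the exponential truncated to M bins of width h.

    p_j = r^{j-1} (1 - r) / (1 - r^M) with r = e^{-h/tau}, j = 1..M.
    """
    j = np.arange(M)
    log_r = -h / tau
    logs = j * log_r
    p = np.exp(logs) * (-np.expm1(log_r))
    denom = -np.expm1(M * log_r)
    return p / denom


def _truncated_mean_bin_index(tau: float, h: float, M: int) -> float:
    """Mean 1-based bin index of the discretized truncated exponential.

    Equals 1 + 1/(e^{h/tau} - 1) - M/(e^{M h/tau} - 1); evaluated stably.
    """
    x = h / tau
    first = 1.0 + 1.0 / np.expm1(x) if x < 700 else 1.0
    mx = M * x
    second = M / np.expm1(mx) if mx < 700 else 0.0
    return first - second


def estimate_cmm(
    hist: DecayHistogram,
    index_origin: int = 0,
    truncation_correction: bool = False,
) -> LifetimeEstimate:
    """Centre-of-mass lifetime estimate.

    ``index_origin=0`` (default) applies the +1/2 bin-centre shift to the
    0-based TDC code, giving the histogram centroid; ``index_origin=1``
    applies it to the 1-based bin index instead (one full bin width more).
    With ``truncation_correction`` the centroid is mapped back through the
    mean of the window-truncated exponential, extending the usable range to
    lifetimes approaching a quarter of the window.
    """
    if index_origin not in (0, 1):
        raise ValueError("index_origin must be 0 or 1")
    n_c = hist.n_counts
    if n_c == 0:
        raise ValueError("cannot estimate a lifetime from an empty histogram")
    centroid = (hist.mean_bin_index() - 1 + index_origin + 0.5) * hist.h
    if not truncation_correction:
        return LifetimeEstimate(centroid, "CMM", True, n_c)
    Tw = hist.M * hist.h  # quantized window actually carrying counts

    def mean_of_truncated(tau: float) -> float:
        z = Tw / tau
        if z > 700:
            return tau
        return tau - Tw * np.exp(-z) / (-np.expm1(-z))

    lo, hi = hist.h / 100.0, 1e4 * Tw
    if not (mean_of_truncated(lo) < centroid < Tw / 2.0):
        return LifetimeEstimate(float("nan"), "CMM", False, n_c)
    tau = brentq(lambda s: mean_of_truncated(s) - centroid, lo, hi, rtol=1e-12)
    return LifetimeEstimate(float(tau), "CMM", True, n_c)


def estimate_mle(
    hist: DecayHistogram,
    bracket: tuple[float, float] | None = None,
    rtol: float = 1e-9,
) -> LifetimeEstimate:
    """Maximum-likelihood lifetime from the mean bin index.

    Solves the moment condition of the binned truncated exponential by
    Brent root finding on [h/100, 100 T] (configurable).  Monotonicity of
    the left side is asserted numerically; a moment outside the attainable
    range is reported as non-convergence, never silently clamped.
    """
    n_c = hist.n_counts
    if n_c == 0:
        raise ValueError("cannot estimate a lifetime from an empty histogram")
    m = hist.mean_bin_index()
    h, M = hist.h, hist.M
    if bracket is None:
        bracket = (h / 100.0, 100.0 * hist.T)
    lo, hi = bracket

    grid = np.geomspace(lo, hi, 24)
    vals = np.array([_truncated_mean_bin_index(g, h, M) for g in grid])
    # mathematically strictly increasing; allow float round-off on the
    # asymptotic plateau near (M+1)/2
    if np.any(np.diff(vals) < -1e-9 * (M + 1)):
        raise RuntimeError("mean-bin-index curve is not monotone on the bracket")

    f = lambda tau: _truncated_mean_bin_index(tau, h, M) - m
    if not (vals[0] < m < vals[-1]):
        return LifetimeEstimate(float("nan"), "MLE", False, n_c)
    tau = brentq(f, lo, hi, rtol=rtol)
    return LifetimeEstimate(float(tau), "MLE", True, n_c)


def _chisq(counts: np.ndarray, n_c: int, tau: float, h: float, M: int) -> float:
    p = binned_exponential_probabilities(tau, h, M)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        stat = float(np.sum(counts * counts / np.maximum(p, 1e-300)) / n_c) - n_c
    return stat if np.isfinite(stat) else float("inf")


def estimate_lsm(
    hist: DecayHistogram,
    mode: str = "chisq",
    rtol: float = 1e-9,
    n_grid: int = 200,
) -> LifetimeEstimate:
    """Least-squares (chi-square) lifetime fit.

    ``mode='chisq'`` (default) minimizes sum (N_j - e_j)^2 / e_j over tau
    with e_j the expected binned-exponential counts, via a coarse
    logarithmic scan refined by bounded scalar minimization.
    ``mode='equation'`` solves the printed weighted-moment identity (counts
    squared as weights, interval symbol read as the bin width) by bracketed
    root finding.
    """
    n_c = hist.n_counts
    if n_c == 0:
        raise ValueError("cannot estimate a lifetime from an empty histogram")
    counts = hist.counts.astype(float)
    h, M = hist.h, hist.M
    if np.count_nonzero(counts) == 1:
        return LifetimeEstimate(float("nan"), "LSM", False, n_c)

    if mode == "chisq":
        taus = np.geomspace(h / 10.0, 10.0 * hist.T, n_grid)
        stats = np.array([_chisq(counts, n_c, s, h, M) for s in taus])
        k = int(np.argmin(stats))
        lo = taus[max(k - 1, 0)]
        hi = taus[min(k + 1, n_grid - 1)]
        res = minimize_scalar(
            lambda s: _chisq(counts, n_c, s, h, M),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": rtol * taus[k]},
        )
        if not res.success or not np.isfinite(res.x):
            return LifetimeEstimate(float("nan"), "LSM", False, n_c)
        return LifetimeEstimate(float(res.x), "LSM", True, n_c)

    if mode != "equation":
        raise ValueError("mode must be 'chisq' or 'equation'")

    j = np.arange(1, M + 1, dtype=float)
    nz = counts > 0
    log_w0 = 2.0 * np.log(counts[nz])
    j_nz = j[nz]

    def resid(tau: float) -> float:
        lhs = _truncated_mean_bin_index(tau, h, M)
        logs = log_w0 + j_nz * (h / tau)
        logs -= logs.max()
        w = np.exp(logs)
        rhs = float((j_nz * w).sum() / w.sum())
        return lhs - rhs

    taus = np.geomspace(h / 10.0, 10.0 * hist.T, n_grid)
    vals = np.array([resid(s) for s in taus])
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    if len(sign_change) == 0:
        return LifetimeEstimate(float("nan"), "LSM", False, n_c)
    k = int(sign_change[0])
    tau = brentq(resid, taus[k], taus[k + 1], rtol=rtol)
    return LifetimeEstimate(float(tau), "LSM", True, n_c)


def subtract_uniform_background(hist: DecayHistogram, bg_level: float) -> DecayHistogram:
    """Subtract a flat per-bin background floor, clamping at zero.

    A simple uniform-background model: dark counts and ambient light are
    flat in arrival time, so a constant per-bin level is removed before
    estimation.
    """
    if bg_level < 0:
        raise ValueError("bg_level must be >= 0")
    counts = np.maximum(hist.counts - bg_level, 0.0)
    return DecayHistogram(counts, hist.h, hist.T)


_METHODS = {"mle": estimate_mle, "cmm": estimate_cmm, "lsm": estimate_lsm}


def estimate(hist: DecayHistogram, method: str, **kwargs) -> LifetimeEstimate:
    """Dispatch to one of the estimators by name ('mle', 'cmm', 'lsm')."""
    try:
        fn = _METHODS[method.lower()]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    return fn(hist, **kwargs)
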