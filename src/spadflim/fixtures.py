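"""Built-in toy phantoms and file-fixture generation.

Two phantom lifetime maps mirror the canonical test scenes: a fluorophore
rectangle on a darker background.  The exact scene geometry of the original
test pictures is unpublished, so a centred rectangle is used.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import SensorConfig, dump_config
from .estimators import histogram_from_frames
from .events import DecayMap, simulate_exposure
from .readout import readout_exposure

__all__ = ["phantom", "generate_fixtures", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("uniform", "phantom1", "phantom2", "histogram")


def phantom(
    config: SensorConfig,
    fluor_tau: float,
    bg_tau: float,
    p0: float | None = None,
) -> DecayMap:
    """Centred-rectangle phantom: fluorophore lifetime on a background.

    The rectangle covers the central half of the array in each dimension.
    """
    if p0 is None:
        p0 = config.photon_rate_P0
    tau = np.full((config.n_rows, config.n_cols), float(bg_tau))
    r0, r1 = config.n_rows // 4, 3 * config.n_rows // 4
    c0, c1 = config.n_cols // 4, 3 * config.n_cols // 4
    tau[r0:r1, c0:c1] = fluor_tau
    return DecayMap(tau, np.full(tau.shape, float(p0)))


def phantom1(config: SensorConfig) -> DecayMap:
    """14 ns fluorophore rectangle on a 4 ns background."""
    return phantom(config, fluor_tau=14.0, bg_tau=4.0)


def phantom2(config: SensorConfig) -> DecayMap:
    """10.5 ns fluorophore rectangle on a 4 ns background."""
    return phantom(config, fluor_tau=10.5, bg_tau=4.0)


def generate_fixtures(kind: str, out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write deterministic fixture files of the requested kind.

    kinds: 'uniform' (10.5 ns flat map), 'phantom1', 'phantom2' (rectangle
    scenes), 'histogram' (a short fixed-seed simulation's pooled histogram).
    Returns the paths written; re-running with the same seed reproduces
    them byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = SensorConfig(seed=seed)
    written: list[Path] = []

    if kind == "uniform":
        decay = DecayMap.uniform(config, 10.5)
        path = out / "uniform_10p5ns.csv"
        decay.to_csv(path)
        written.append(path)
    elif kind == "phantom1":
        path = out / "phantom1_14ns_on_4ns.csv"
        phantom1(config).to_csv(path)
        written.append(path)
    elif kind == "phantom2":
        path = out / "phantom2_10p5ns_on_4ns.csv"
        phantom2(config).to_csv(path)
        written.append(path)
    elif kind == "histogram":
        decay = DecayMap.uniform(config, 10.5)
        stream = simulate_exposure(config, decay, n_pulses=20000, seed=seed)
        result = readout_exposure(stream, config)
        hist = histogram_from_frames(result, config)
        path = out / "histogram_10p5ns.csv"
        hist.to_csv(path)
        written.append(path)
        cfg_path = out / "sensor_config.json"
        dump_config(config, cfg_path)
        written.append(cfg_path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")

    readme = out / "README.txt"
    with open(readme, "a") as fh:
        fh.write(f"{kind}: generated by spadflim.fixtures.generate_fixtures(seed={seed})\n")
    written.append(readme)
    return written
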