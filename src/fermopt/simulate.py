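"""Synthetic screens and CCD responses with known ground truth.

The generators emulate the two data shapes the pipeline consumes:

* :func:`simulate_screen` -- a single-factor screen where each alternative
  has a latent "true utility"; the four indices are monotone transforms of
  that utility into plausible instrument ranges (OD600 0-1.2, protein
  0-7 g/L, surface tension 55 down to 30 mN/m, clear zone 0-7.5 cm) plus
  independent Gaussian noise truncated at zero.
* :func:`simulate_ccd` -- responses from a known 10-coefficient quadratic
  surface evaluated at the coded CCD points plus N(0, sigma^2) noise.

Each generator derives one independent random substream per index/output
from a single seed, so enlarging the output does not perturb what was
already drawn, and equal seeds give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .rsm import CCDDesign, generate_ccd, quadratic_design_matrix
from .screen import DEFAULT_CRITERIA, SCREEN_COLUMNS, ScreenTable

__all__ = [
    "INDEX_RANGES",
    "ScreenSimConfig",
    "CCDSimConfig",
    "simulate_screen",
    "simulate_ccd",
]

#: (low, high) instrument ranges per index; surface tension is generated
#: decreasing in utility (a better producer lowers the tension).
INDEX_RANGES: dict[str, tuple[float, float]] = {
    "biomass": (0.0, 1.2),
    "protein_g_per_L": (0.0, 7.0),
    "surface_tension_mN_per_m": (30.0, 55.0),
    "clear_zone_cm": (0.0, 7.5),
}


@dataclass
class ScreenSimConfig:
    """Configuration of one synthetic single-factor screen.

    ``utilities`` are the latent qualities of the alternatives on an
    arbitrary positive scale; ``noise_sd`` is expressed as a fraction of
    each index's range; ``dropouts`` lists alternatives whose clear zone is
    forced to zero (emulating non-producers).
    """

    utilities: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0)
    noise_sd: float = 0.05
    seed: int = 0
    name: str = "synthetic-screen"
    labels: Sequence[str] | None = None
    dropouts: Sequence[int] = ()
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(INDEX_RANGES))

    def __post_init__(self):
        u = np.asarray(self.utilities, float)
        if u.size < 2 or np.any(u <= 0):
            raise ValueError("need >= 2 strictly positive utilities")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, (lo, hi) in self.ranges.items():
            if hi <= lo:
                raise ValueError(f"empty range for {name}")


def simulate_screen(config: ScreenSimConfig) -> ScreenTable:
    """Draw one screen table from the configured ground truth."""
    u = np.asarray(config.utilities, float)
    un = u / u.max()
    n = u.size
    labels = list(config.labels) if config.labels is not None else [
        f"alt{i+1}" for i in range(n)]
    streams = np.random.SeedSequence(config.seed).spawn(len(config.ranges))
    cols: dict[str, np.ndarray] = {"label": np.asarray(labels, object)}
    for (name, (lo, hi)), ss in zip(config.ranges.items(), streams):
        rng = np.random.default_rng(ss)
        span = hi - lo
        if name == "surface_tension_mN_per_m":
            base = hi - span * un
        else:
            base = lo + span * un
        vals = base + rng.normal(0.0, config.noise_sd * span, n)
        if name == "surface_tension_mN_per_m":
            # physical bound (0, 100]
            vals = np.clip(vals, 1e-6, 100.0)
        else:
            vals = np.clip(vals, 0.0, None)
        if name == "clear_zone_cm" and len(config.dropouts):
            vals[np.asarray(config.dropouts, int)] = 0.0
        cols[name] = np.round(vals, 4)
    df = pd.DataFrame(cols)[SCREEN_COLUMNS]
    return ScreenTable(df, name=config.name, criteria=DEFAULT_CRITERIA)


@dataclass
class CCDSimConfig:
    """Configuration of one synthetic CCD response set.

    ``beta`` is the generating coefficient vector in coded units, ordered
    as intercept, linear, two-way interactions, pure quadratics (10 terms
    for 3 factors).
    """

    beta: Sequence[float]
    noise_sd: float = 0.0
    n_center: int = 6
    alpha: float | None = None
    seed: int = 0

    def __post_init__(self):
        b = np.asarray(self.beta, float)
        # p = 1 + 2k + k(k-1)/2  =>  k from p
        for k in range(2, 12):
            if b.size == 1 + 2 * k + k * (k - 1) // 2:
                self.k = k
                break
        else:
            raise ValueError(f"{b.size} coefficients match no factor count")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_ccd(config: CCDSimConfig) -> tuple[CCDDesign, np.ndarray]:
    """Design plus noisy responses from the configured quadratic surface."""
    design = generate_ccd(config.k, alpha=config.alpha,
                          n_center=config.n_center)
    M = quadratic_design_matrix(design.coded)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    y = M @ np.asarray(config.beta, float)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, design.n_runs)
    return design, y
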