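"""Synthetic experimental designs for batch fermentation runs.

Real campaigns of this kind measure the alcohol content (°P) of a fermented
beverage under a modest number of statistically pre-designed conditions of
fermentation time, temperature and starter-culture dosage.  This module
emulates such a campaign: process factors are drawn by Latin-hypercube
stratified sampling over the design box and the response follows a quadratic
response surface with additive Gaussian measurement noise, clipped at zero
(a refractometer cannot read a negative extract).

The default surface is calibrated so that the design spans roughly 0.9-11.8
°P with the maximum near (72 h, 45.11 °C, 3.0 v/v) and the minimum at zero
dosage — the qualitative geometry of a small low-alcohol fruit-wine
optimisation study — and so that temperature (directly and through the
dose x temperature interaction) carries the dominant share of the response
variance, with dosage second and time a distant third, mirroring the
feature-importance structure such systems exhibit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from fermgan.table import REAL_LABEL, ConfigError, FeatureTable


@dataclass(frozen=True)
class SurfaceCoeffs:
    """Coefficients of the noise-free response surface.

    alcohol = max(clip_floor,
                  b0 + b_dose * d + b_time * (t / 72) + b_temp * u
                     + b_interact * d * u),   u = (T - 35) / 10

    Time is normalised by a 72 h reference fermentation and temperature is
    centred at 35 °C per decade so every coefficient is in °P per unit of a
    dimensionless factor.
    """

    b0: float = 0.9
    b_dose: float = 1.0
    b_time: float = 1.0
    b_temp: float = 2.6
    b_interact: float = 1.2
    noise_sd: float = 0.3
    clip_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.clip_floor < 0:
            raise ConfigError("clip_floor must be >= 0")


@dataclass(frozen=True)
class DesignRanges:
    """The design box and run count of the emulated campaign."""

    time: tuple[float, float] = (24.0, 72.0)
    temperature: tuple[float, float] = (25.9, 45.11)
    dose: tuple[float, float] = (0.0, 3.18)
    n_runs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("time", "temperature", "dose"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ConfigError(f"{name} range must be non-degenerate")
        if self.n_runs < 4:
            raise ConfigError("n_runs must be >= 4")


def response_surface(
    time: float | np.ndarray,
    temperature: float | np.ndarray,
    dose: float | np.ndarray,
    coeffs: SurfaceCoeffs = SurfaceCoeffs(),
    with_noise: bool = False,
    seed: int | np.random.Generator | None = None,
) -> float | np.ndarray:
    """Evaluate the alcohol response surface (°P) at given conditions."""
    t = np.asarray(time, dtype=float)
    T = np.asarray(temperature, dtype=float)
    d = np.asarray(dose, dtype=float)
    u = (T - 35.0) / 10.0
    z = (
        coeffs.b0
        + coeffs.b_dose * d
        + coeffs.b_time * (t / 72.0)
        + coeffs.b_temp * u
        + coeffs.b_interact * d * u
    )
    if with_noise and coeffs.noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        z = z + rng.normal(0.0, coeffs.noise_sd, size=np.shape(z))
    z = np.maximum(z, coeffs.clip_floor)
    return float(z) if z.ndim == 0 else z


def generate_design(
    ranges: DesignRanges = DesignRanges(),
    coeffs: SurfaceCoeffs = SurfaceCoeffs(),
) -> FeatureTable:
    """Generate a seeded Latin-hypercube design with noisy responses.

    Returns an ``n_runs``-row real-labelled FeatureTable; identical seeds
    produce identical tables.
    """
    rng = np.random.default_rng(ranges.seed)
    sampler = qmc.LatinHypercube(d=3, seed=rng)
    unit = sampler.random(ranges.n_runs)
    lows = np.array([ranges.time[0], ranges.temperature[0], ranges.dose[0]])
    highs = np.array([ranges.time[1], ranges.temperature[1], ranges.dose[1]])
    X = qmc.scale(unit, lows, highs)
    alcohol = response_surface(
        X[:, 0], X[:, 1], X[:, 2], coeffs, with_noise=True, seed=rng
    )
    values = np.column_stack([X, alcohol])
    return FeatureTable(values, np.full(ranges.n_runs, REAL_LABEL))
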