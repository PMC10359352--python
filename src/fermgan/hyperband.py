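"""Hyperband hyperparameter search over the surrogate's configuration space.

Hyperband runs several successive-halving brackets that trade the number of
sampled configurations against the training resource (epochs) each receives:
bracket s starts n = ceil((s_max+1)/(s+1) * eta^s) configurations at
resource R * eta^(-s) and repeatedly keeps the best 1/eta by validation
loss while multiplying their resource by eta.  With R = 81 and eta = 3 this
yields five brackets, the most exploratory of which screens 81 random
configurations at a single epoch each.

Configurations are retrained from scratch at each rung (no weight
checkpointing), so a trial's outcome depends only on its (spec, seed,
epochs) triple and the whole search is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fermgan.surrogate import AlcoholSurrogate, DataSplit, DnnSpec
from fermgan.table import ConfigError

__all__ = ["SearchSpace", "HyperbandConfig", "hyperband_search", "bracket_schedule"]

_ACTIVATION_CHOICES = ("softmax", "relu", "tanh", "sigmoid", "linear")


@dataclass(frozen=True)
class SearchSpace:
    """The tunable ranges: layer units, activations, learning rate, dropouts."""

    units_1: tuple[int, int] = (10, 30)  # inclusive, step 1
    units_2: tuple[int, int] = (2, 10)
    activations: tuple[str, ...] = _ACTIVATION_CHOICES
    learning_rates: tuple[float, ...] = (0.01, 0.0001, 1e-6)
    dropout_1: tuple[float, ...] = (0.5, 0.6, 0.7)  # [0.5, 0.7] step 0.1
    dropout_2: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5)  # [0.2, 0.5] step 0.1

    def __post_init__(self) -> None:
        if not (self.activations and self.learning_rates and self.dropout_1 and self.dropout_2):
            raise ConfigError("empty search space")
        for lo, hi in (self.units_1, self.units_2):
            if hi < lo or lo < 1:
                raise ConfigError("invalid units range")

    def sample(self, rng: np.random.Generator) -> DnnSpec:
        return DnnSpec(
            units_1=int(rng.integers(self.units_1[0], self.units_1[1] + 1)),
            units_2=int(rng.integers(self.units_2[0], self.units_2[1] + 1)),
            activation_1=str(rng.choice(self.activations)),
            activation_2=str(rng.choice(self.activations)),
            activation_out=str(rng.choice(self.activations)),
            learning_rate=float(rng.choice(self.learning_rates)),
            dropout_1=float(rng.choice(self.dropout_1)),
            dropout_2=float(rng.choice(self.dropout_2)),
        )


@dataclass(frozen=True)
class HyperbandConfig:
    """Maximum per-trial resource R (epochs), reduction factor eta, seed."""

    max_resource: int = 81
    eta: int = 3
    seed: int = 0
    batch_size: int = 10

    def __post_init__(self) -> None:
        if not self.max_resource >= self.eta >= 2:
            raise ConfigError("need max_resource >= eta >= 2")


def bracket_schedule(R: int, eta: int) -> list[list[tuple[int, int]]]:
    """The (n_configs, epochs) rungs of every bracket, most exploratory first."""
    s_max = int(math.floor(math.log(R) / math.log(eta)))
    brackets = []
    for s in range(s_max, -1, -1):
        n = math.ceil((s_max + 1) / (s + 1) * eta**s)
        r = R * eta ** (-s)
        rungs = []
        for i in range(s + 1):
            n_i = int(math.floor(n * eta ** (-i)))
            r_i = int(math.ceil(r * eta**i))
            rungs.append((n_i, min(r_i, R)))
        brackets.append(rungs)
    return brackets


def hyperband_search(
    space: SearchSpace,
    data: DataSplit,
    config: HyperbandConfig = HyperbandConfig(),
) -> tuple[DnnSpec, pd.DataFrame]:
    """Run hyperband and return the best spec plus the full trial log.

    The selection criterion is the final validation pure MSE; the winner is
    the configuration with the lowest criterion seen in any trial at any
    resource level.
    """
    rng = np.random.default_rng(config.seed)
    trial_rows: list[dict] = []
    best_spec, best_score = None, np.inf
    for b, rungs in enumerate(bracket_schedule(config.max_resource, config.eta)):
        n0, _ = rungs[0]
        candidates = [space.sample(rng) for _ in range(n0)]
        seeds = [int(s) for s in rng.integers(0, 2**31, size=n0)]
        for rung, (n_i, r_i) in enumerate(rungs):
            scored: list[tuple[float, DnnSpec, int]] = []
            for spec, trial_seed in zip(candidates[:n_i], seeds[:n_i]):
                try:
                    model = AlcoholSurrogate(data, spec)
                    res = model.fit(epochs=r_i, batch_size=config.batch_size, seed=trial_seed)
                    score = res.final_val_mse
                except (FloatingPointError, RuntimeError):
                    score = np.inf
                scored.append((score, spec, trial_seed))
                trial_rows.append(
                    {
                        "bracket": b,
                        "rung": rung,
                        "epochs": r_i,
                        "val_mse": score,
                        "seed": trial_seed,
                        **{f"hp_{k}": v for k, v in spec.__dict__.items()},
                    }
                )
                if score < best_score:
                    best_spec, best_score = spec, score
            # keep the top 1/eta for the next rung
            scored.sort(key=lambda t: t[0])
            keep = scored[: max(1, int(math.floor(n_i / config.eta)))]
            candidates = [s for _, s, _ in keep]
            seeds = [sd for _, _, sd in keep]
    assert best_spec is not None
    return best_spec, pd.DataFrame(trial_rows)
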