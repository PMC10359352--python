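"""Adversarial synthesis of tabular fermentation records.

A generator maps an 8-dimensional standard-normal latent vector to a scaled
4-vector (time, temperature, dose, alcohol) through a small dense network
with a tanh output; a discriminator scores 4-vectors with a 4-unit sigmoid
output head.  Both are trained adversarially on the min-max-scaled real
table: each iteration performs one discriminator update on a half-batch of
real rows (labelled 1), one on a half-batch of generated rows (labelled 0),
and one generator update through the frozen discriminator on a full batch of
latent vectors labelled as real.

The architecture and the unusually conservative optimiser (Adam with
learning rate 1e-5, betas 0.8, epsilon 1e-2 and gradient-norm clipping at
1e-4, with heavy L1/L2 regularisation and dropout) follow the reference
protocol this package reproduces; both are fully configurable.

Usage::

    gan = TabularGAN(real_table, GanConfig(seed=7))
    res = gan.fit()
    synthetic = res.synthesize()          # 10x the real sample by default
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from fermgan.nn import (
    Adam,
    BatchNorm,
    Dense,
    Dropout,
    Network,
    OptimizerSpec,
    binary_cross_entropy,
    mean_squared_error,
)
from fermgan.table import (
    SYNTHETIC_LABEL,
    ConfigError,
    FeatureTable,
    ScalerParams,
    fit_scaler,
    apply_scaler,
    invert_scaler,
)

# ---------------------------------------------------------------------------
# Declarative specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a declarative network description."""

    kind: str  # dense | batch_norm | dropout
    units: int | None = None
    activation: str = "linear"
    kernel_init: str = "glorot_uniform"
    l1_kernel: float = 0.0
    l1_bias: float = 0.0
    l2_activity: float = 0.0
    rate: float = 0.0


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered layer specs consuming ``input_dim`` inputs."""

    input_dim: int
    layers: tuple[LayerSpec, ...]
    name: str = "net"

    @property
    def output_dim(self) -> int:
        for layer in reversed(self.layers):
            if layer.kind == "dense":
                return int(layer.units)
        return self.input_dim


def build_network(spec: NetworkSpec, seed: int | None = 0) -> Network:
    layers = []
    dim = spec.input_dim
    for ls in spec.layers:
        if ls.kind == "dense":
            layers.append(
                Dense(
                    dim,
                    int(ls.units),
                    activation=ls.activation,
                    kernel_init=ls.kernel_init,
                    l1_kernel=ls.l1_kernel,
                    l1_bias=ls.l1_bias,
                    l2_activity=ls.l2_activity,
                )
            )
            dim = int(ls.units)
        elif ls.kind == "batch_norm":
            layers.append(BatchNorm(dim))
        elif ls.kind == "dropout":
            layers.append(Dropout(ls.rate))
        else:
            raise ConfigError(f"unknown layer kind {ls.kind!r}")
    return Network(layers, seed=seed, name=spec.name)


_REGULARIZED = dict(l1_kernel=0.1, l1_bias=0.1, l2_activity=0.1)

#: Default Adam settings of the adversarial protocol.
GAN_OPTIMIZER = OptimizerSpec(
    learning_rate=1e-5, beta_1=0.8, beta_2=0.8, epsilon=1e-2, clipnorm=1e-4
)


def discriminator_spec() -> NetworkSpec:
    return NetworkSpec(
        input_dim=4,
        name="discriminator",
        layers=(
            LayerSpec("dense", 22, "relu", "he_uniform", **_REGULARIZED),
            LayerSpec("batch_norm"),
            LayerSpec("dropout", rate=0.7),
            LayerSpec("dense", 35, "sigmoid", l1_kernel=0.1),
            LayerSpec("batch_norm"),
            LayerSpec("dropout", rate=0.5),
            LayerSpec("dense", 4, "sigmoid"),
        ),
    )


def generator_spec(latent_dim: int = 8) -> NetworkSpec:
    if latent_dim < 1:
        raise ConfigError("latent_dim must be >= 1")
    return NetworkSpec(
        input_dim=latent_dim,
        name="generator",
        layers=(
            LayerSpec("dense", 22, "relu", "he_uniform", **_REGULARIZED),
            LayerSpec("batch_norm"),
            LayerSpec("dropout", rate=0.7),
            LayerSpec("dense", 35, "sigmoid", l1_kernel=0.1),
            LayerSpec("batch_norm"),
            LayerSpec("dropout", rate=0.5),
            LayerSpec("dense", 4, "tanh"),
        ),
    )


def build_discriminator(seed: int | None = 0) -> Network:
    """The 4 -> 22 -> 35 -> 4 sigmoid-head discriminator (1,173 parameters)."""
    return build_network(discriminator_spec(), seed=seed)


def build_generator(latent_dim: int = 8, seed: int | None = 0) -> Network:
    """The latent -> 22 -> 35 -> 4 tanh-output generator."""
    return build_network(generator_spec(latent_dim), seed=seed)


def sample_latent(
    n: int, latent_dim: int = 8, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw n i.i.d. standard-normal latent vectors."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.standard_normal((n, latent_dim))


# ---------------------------------------------------------------------------
# Training configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GanConfig:
    """Adversarial training protocol.

    ``n_iterations`` counts generator updates; each iteration also performs
    two half-batch discriminator updates (real and generated rows fed in
    separate passes).  An evaluation record is appended every ``eval_every``
    iterations.
    """

    latent_dim: int = 8
    n_iterations: int = 10_000
    batch_size: int = 10
    eval_every: int = 20
    seed: int = 0
    real_label: float = 1.0
    fake_label: float = 0.0
    optimizer: OptimizerSpec = GAN_OPTIMIZER

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ConfigError("latent_dim must be >= 1")
        if self.batch_size % 2 != 0:
            raise ConfigError("batch_size must be even (half-batch protocol)")
        if self.eval_every < 1:
            raise ConfigError("eval_every must be >= 1")


class TrainingDivergedError(RuntimeError):
    """A non-finite loss was encountered during adversarial training."""


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class TabularGAN:
    """Adversarial model of a 4-feature fermentation table.

    Parameters
    ----------
    real : FeatureTable
        The experimental table in original units.  A min-max scaler to
        (-1, 1) is fitted on it (the generator's tanh output lives on that
        scale); pass ``scaler`` to reuse pre-fitted parameters.
    config : GanConfig
        Training protocol; ``config.seed`` drives initialisation, batch
        selection, latent sampling and dropout, making ``fit`` fully
        deterministic.
    """

    def __init__(
        self,
        real: FeatureTable,
        config: GanConfig = GanConfig(),
        scaler: ScalerParams | None = None,
    ) -> None:
        if len(real) < config.batch_size // 2:
            raise ConfigError("need at least batch_size/2 real rows")
        self.config = config
        self.scaler = scaler if scaler is not None else fit_scaler(real, (-1.0, 1.0))
        self.real = real
        self.real_scaled = apply_scaler(real, self.scaler).values

    def fit(self) -> "GANResults":
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        s_disc, s_gen, s_loop, s_eval = ss.spawn(4)
        disc = build_discriminator(seed=s_disc)
        gen = build_generator(cfg.latent_dim, seed=s_gen)
        adam_d = Adam(cfg.optimizer)
        adam_g = Adam(cfg.optimizer)
        rng = np.random.default_rng(s_loop)
        eval_rng = np.random.default_rng(s_eval)

        X = self.real_scaled
        n = X.shape[0]
        half = cfg.batch_size // 2
        out_dim = 4
        y_real_half = np.full((half, out_dim), cfg.real_label)
        y_fake_half = np.full((half, out_dim), cfg.fake_label)
        y_real_full = np.full((cfg.batch_size, out_dim), cfg.real_label)

        records: list[dict] = []
        d_loss_real = d_loss_fake = g_loss = np.nan
        for it in range(1, cfg.n_iterations + 1):
            # discriminator on real half-batch
            idx = rng.choice(n, size=half, replace=n < half)
            out = disc.forward(X[idx], training=True)
            loss, grad = binary_cross_entropy(y_real_half, out)
            d_loss_real = loss + disc.reg_loss()
            disc.backward(grad)
            adam_d.step(disc.params, disc.grads)

            # discriminator on generated half-batch
            z = rng.standard_normal((half, cfg.latent_dim))
            fake = gen.forward(z, training=False)
            out = disc.forward(fake, training=True)
            loss, grad = binary_cross_entropy(y_fake_half, out)
            d_loss_fake = loss + disc.reg_loss()
            disc.backward(grad)
            adam_d.step(disc.params, disc.grads)

            # generator through frozen discriminator (inference mode)
            z = rng.standard_normal((cfg.batch_size, cfg.latent_dim))
            gen_out = gen.forward(z, training=True)
            out = disc.forward(gen_out, training=False)
            loss, grad = binary_cross_entropy(y_real_full, out)
            g_loss = loss + gen.reg_loss()
            grad_x = disc.backward(grad)  # discriminator grads discarded
            gen.backward(grad_x)
            adam_g.step(gen.params, gen.grads)

            if not np.isfinite([d_loss_real, d_loss_fake, g_loss]).all():
                raise TrainingDivergedError(f"non-finite loss at iteration {it}")

            if it % cfg.eval_every == 0:
                records.append(
                    self._evaluate(it, disc, gen, eval_rng, d_loss_real, d_loss_fake, g_loss)
                )

        history = pd.DataFrame.from_records(records)
        return GANResults(gen, disc, history, self.scaler, cfg, n_real=n)

    def _evaluate(self, it, disc, gen, eval_rng, d_loss_real, d_loss_fake, g_loss) -> dict:
        cfg = self.config
        X = self.real_scaled
        out_real = disc.predict(X)
        mse_real, _ = mean_squared_error(np.full_like(out_real, cfg.real_label), out_real)
        z = eval_rng.standard_normal((X.shape[0], cfg.latent_dim))
        out_fake = disc.predict(gen.predict(z))
        acc_real = float(np.mean(out_real.mean(axis=1) > 0.5))
        acc_fake = float(np.mean(out_fake.mean(axis=1) <= 0.5))
        return {
            "iteration": it,
            "d_loss_real": d_loss_real,
            "d_loss_fake": d_loss_fake,
            "g_loss": g_loss,
            "d_mse": mse_real,
            "acc_real": acc_real,
            "acc_fake": acc_fake,
        }


class GANResults:
    """Trained generator/discriminator pair with its training history."""

    def __init__(
        self,
        generator: Network,
        discriminator: Network,
        history: pd.DataFrame,
        scaler: ScalerParams,
        config: GanConfig,
        n_real: int,
    ) -> None:
        self.generator = generator
        self.discriminator = discriminator
        self.history = history
        self.scaler = scaler
        self.config = config
        self.n_real = n_real

    def synthesize(self, n: int | None = None, seed: int | None = 0) -> FeatureTable:
        """Generate n synthetic rows in original units (default 10x real n)."""
        if n is None:
            n = 10 * self.n_real
        z = sample_latent(n, self.config.latent_dim, seed)
        scaled = self.generator.predict(z)
        table = FeatureTable(scaled, np.full(n, SYNTHETIC_LABEL))
        return invert_scaler(table, self.scaler)

    def summary(self) -> str:
        h = self.history
        lines = [
            "Tabular GAN results",
            "===================",
            f"iterations          : {self.config.n_iterations}",
            f"batch size          : {self.config.batch_size}",
            f"latent dimension    : {self.config.latent_dim}",
            f"real rows           : {self.n_real}",
            f"generator params    : {self.generator.n_params}",
            f"discriminator params: {self.discriminator.n_params}",
        ]
        if len(h):
            last = h.iloc[-1]
            lines += [
                f"final d loss (real) : {last['d_loss_real']:.4f}",
                f"final d loss (fake) : {last['d_loss_fake']:.4f}",
                f"final g loss        : {last['g_loss']:.4f}",
                f"final d accuracy    : real {last['acc_real']:.2f} / fake {last['acc_fake']:.2f}",
            ]
        return "\n".join(lines)
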