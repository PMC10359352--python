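"""End-to-end driver: design -> GAN -> synthesis -> fidelity -> tuning ->
comparison -> attribution, with deterministic per-stage seeding and a
manifest of every artifact written.

Every stage derives its seed from the global seed and its stage name, so a
stage can be rerun in isolation and still reproduce the full-pipeline
artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from fermgan import __version__
from fermgan.attribution import importance_summary, permutation_importance, shapley_values
from fermgan.design import DesignRanges, SurfaceCoeffs, generate_design
from fermgan.fidelity import fidelity_report
from fermgan.gan import GanConfig, TabularGAN
from fermgan.hyperband import HyperbandConfig, SearchSpace, hyperband_search
from fermgan.surrogate import AlcoholSurrogate, DnnSpec, compare_real_vs_synthetic
from fermgan.table import ConfigError, FeatureTable, SplitSpec, load_table

logger = logging.getLogger("fermgan")

STAGES = ("fixture", "train_gan", "synth", "validate", "tune", "compare", "explain")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest, 16) % (2**31)


@dataclass
class RunConfig:
    """Everything the pipeline needs; serialisable to/from YAML."""

    out_dir: str = "fermgan_run"
    seed: int = 0
    data_path: str | None = None  # CSV of real runs; None -> generate the design
    n_runs: int = 20
    noise_sd: float = 0.3
    gan_iterations: int = 10_000
    gan_batch_size: int = 10
    gan_eval_every: int = 20
    synth_n: int | None = None  # None -> 10x real rows
    alpha: float = 0.05
    hyperband_resource: int = 81
    hyperband_eta: int = 3
    dnn_epochs: int = 2000
    compare_repeats: int = 10
    split_fractions: tuple[float, float, float] = (0.58, 0.38, 0.04)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        SplitSpec(tuple(self.split_fractions))  # validates fractions
        if self.n_runs < 4:
            raise ConfigError("n_runs must be >= 4")

    def to_yaml(self, path: str | Path | None = None) -> str:
        import yaml

        payload = dataclasses.asdict(self)
        payload["split_fractions"] = list(self.split_fractions)
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "split_fractions" in payload:
            payload["split_fractions"] = tuple(payload["split_fractions"])
        return cls(**payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def register(stage: str, seed: int, *paths: Path) -> None:
        manifest["stages"][stage] = {
            "seed": seed,
            "artifacts": {p.name: _sha256(p) for p in paths},
        }
        logger.info("[%s] wrote %s", stage, ", ".join(p.name for p in paths))

    try:
        # 1. real data: load or emulate the experimental design
        seed = stage_seed(config.seed, "fixture")
        if config.data_path is not None:
            real = load_table(config.data_path)
            logger.info("[fixture] loaded %d real rows from %s", len(real), config.data_path)
        else:
            real = generate_design(
                DesignRanges(n_runs=config.n_runs, seed=seed),
                SurfaceCoeffs(noise_sd=config.noise_sd),
            )
            logger.info("[fixture] generated %d-run design", len(real))
        real_path = out / "real.csv"
        real.to_csv(real_path)
        register("fixture", seed, real_path)

        # 2. adversarial training
        seed = stage_seed(config.seed, "train_gan")
        gan = TabularGAN(
            real,
            GanConfig(
                n_iterations=config.gan_iterations,
                batch_size=config.gan_batch_size,
                eval_every=config.gan_eval_every,
                seed=seed,
            ),
        )
        gan_res = gan.fit()
        hist_path = out / "gan_history.csv"
        gan_res.history.to_csv(hist_path, index=False)
        gen_path = out / "generator.json"
        gan_res.generator.save(gen_path)
        disc_path = out / "discriminator.json"
        gan_res.discriminator.save(disc_path)
        scaler_path = out / "scaler.json"
        gan_res.scaler.to_json(scaler_path)
        register("train_gan", seed, hist_path, gen_path, disc_path, scaler_path)

        # 3. synthesis
        seed = stage_seed(config.seed, "synth")
        synthetic = gan_res.synthesize(config.synth_n, seed=seed)
        synth_path = out / "synthetic.csv"
        synthetic.to_csv(synth_path)
        logger.info("[synth] %d synthetic rows", len(synthetic))
        register("synth", seed, synth_path)

        # 4. fidelity battery
        seed = stage_seed(config.seed, "validate")
        report = fidelity_report(real, synthetic, alpha=config.alpha)
        report_path = out / "fidelity.json"
        report.to_json(report_path)
        logger.info("[validate]\n%s", report.summary())
        register("validate", seed, report_path)

        # 5. hyperband tuning on the synthetic corpus
        seed = stage_seed(config.seed, "tune")
        split = SplitSpec(tuple(config.split_fractions), seed=seed)
        model = AlcoholSurrogate(synthetic, split=split)
        best, trials = hyperband_search(
            SearchSpace(),
            model.split,
            HyperbandConfig(config.hyperband_resource, config.hyperband_eta, seed=seed),
        )
        best_path = out / "best_spec.json"
        best.to_json(best_path)
        trials_path = out / "hyperband_trials.csv"
        trials.to_csv(trials_path, index=False)
        logger.info("[tune] best spec %s", best)
        register("tune", seed, best_path, trials_path)

        # 6. real-vs-synthetic training comparison (default tuned spec)
        seed = stage_seed(config.seed, "compare")
        comparison = compare_real_vs_synthetic(
            real,
            synthetic,
            DnnSpec(),
            repeats=config.compare_repeats,
            epochs=config.dnn_epochs,
            seed=seed,
        )
        cmp_path = out / "comparison.json"
        cmp_path.write_text(json.dumps(comparison.to_dict(), indent=2))
        logger.info("[compare]\n%s", comparison.summary())
        register("compare", seed, cmp_path)

        # 7. attribution of a surrogate trained on the synthetic corpus
        seed = stage_seed(config.seed, "explain")
        surrogate = AlcoholSurrogate(
            synthetic, DnnSpec(), SplitSpec(tuple(config.split_fractions), seed=seed)
        )
        fit = surrogate.fit(epochs=config.dnn_epochs, seed=seed)
        imp = permutation_importance(
            fit,
            surrogate.split.validation.predictors,
            surrogate.split.validation.target,
            seed=seed,
        )
        shap = shapley_values(fit, surrogate.split.validation, surrogate.split.train)
        summary = importance_summary(imp, shap)
        imp_path = out / "importance.json"
        imp_path.write_text(json.dumps(summary, indent=2))
        shap_path = out / "shapley.csv"
        shap.to_frame().to_csv(shap_path, index=False)
        logger.info("[explain]\n%s", imp.summary())
        register("explain", seed, imp_path, shap_path)
    except Exception:
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        logger.exception("pipeline failed; partial manifest retained at %s", manifest_path)
        raise

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
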