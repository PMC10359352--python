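"""Statistical fidelity battery for real-vs-synthetic tables.

The question the battery answers: does the synthetic table come from the
same distribution as the experimental one?  It combines

* univariate normality screening (Lilliefors-corrected Kolmogorov-Smirnov
  and Shapiro-Wilk per feature),
* robust two-sample mean tests (Welch's t and the Brown-Forsythe F* test of
  equal means, both valid under unequal variances and sample sizes),
* the rank-based Kruskal-Wallis H test of distributional equality,
* principal component analysis with Hotelling T² 95% outlier screening and
  a single remove-and-refit pass,
* OPLS-DA (one class-predictive latent variable plus orthogonal components)
  to look for latent class separation the unsupervised projection may miss,
* second-order (full quadratic) response-surface fits of alcohol over
  time x temperature at a fixed dosage slice, for overlay plots.

A synthetic table of good fidelity shows non-significant two-sample tests,
no class separation in the projections, and closely matching fitted
surfaces.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from fermgan.table import (
    DegenerateFeatureError,
    FeatureTable,
    SchemaError,
    FEATURE_COLUMNS,
)

__all__ = [
    "TestResult",
    "PcaResult",
    "OplsResult",
    "SurfaceFit",
    "FidelityReport",
    "normality_tests",
    "welch_test",
    "brown_forsythe_means",
    "kruskal_wallis",
    "pca",
    "remove_t2_outliers",
    "opls_da",
    "surface_fit",
    "fidelity_report",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestResult:
    """One univariate test outcome."""

    test: str
    feature: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_sizes"] = list(self.group_sizes)
        return d


@dataclass
class PcaResult:
    """PCA scores/loadings with per-sample Hotelling T² statistics."""

    explained_variance_ratio: np.ndarray  # all components
    scores: np.ndarray  # (n, A) retained components
    loadings: np.ndarray  # (p, A)
    t2: np.ndarray  # per-sample Hotelling T² over retained components
    t2_limit: float  # 95% critical value
    n_components: int
    mean_: np.ndarray = field(repr=False, default=None)
    scale_: np.ndarray = field(repr=False, default=None)

    @property
    def cumulative_variance_ratio(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)

    def to_dict(self) -> dict:
        return {
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "cumulative_variance_ratio": self.cumulative_variance_ratio.tolist(),
            "t2_limit": self.t2_limit,
            "n_components": self.n_components,
            "n_outliers": int((self.t2 > self.t2_limit).sum()),
        }


@dataclass
class OplsResult:
    """OPLS-DA decomposition: one predictive + n orthogonal components."""

    t_pred: np.ndarray  # predictive scores
    p_pred: np.ndarray  # predictive loadings
    w_pred: np.ndarray  # predictive weights
    t_orth: np.ndarray  # (n, n_orth) orthogonal scores
    p_orth: np.ndarray  # (p, n_orth) orthogonal loadings
    r2x_components: np.ndarray  # predictive first, then orthogonal
    r2y: float

    @property
    def r2x_cum(self) -> float:
        return float(self.r2x_components.sum())

    def to_dict(self) -> dict:
        return {
            "r2x_components": self.r2x_components.tolist(),
            "r2x_cum": self.r2x_cum,
            "r2y": self.r2y,
        }


@dataclass(frozen=True)
class SurfaceFit:
    """Least-squares full quadratic z = b0 + bx x + by y + bxx x² + byy y² + bxy xy."""

    coefficients: tuple[float, float, float, float, float, float]
    rss: float
    dose_slice: float
    x_feature: str = "temperature"
    y_feature: str = "time"
    z_feature: str = "alcohol"

    def predict(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        b0, bx, by, bxx, byy, bxy = self.coefficients
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return b0 + bx * x + by * y + bxx * x * x + byy * y * y + bxy * x * y

    def to_dict(self) -> dict:
        return dataclasses.asdict(self) | {"coefficients": list(self.coefficients)}


# ---------------------------------------------------------------------------
# Univariate tests
# ---------------------------------------------------------------------------


def _check_sample(x: np.ndarray, name: str = "sample") -> np.ndarray:
    x = np.asarray(x, float).ravel()
    if x.size < 2:
        raise ValueError(f"{name} needs at least 2 observations")
    return x


def normality_tests(table: FeatureTable) -> list[TestResult]:
    """Lilliefors-corrected KS and Shapiro-Wilk normality tests per feature.

    The KS variant compares against a normal with mean and sd estimated from
    the sample and uses the Lilliefors null distribution for the p-value.
    """
    from statsmodels.stats.diagnostic import lilliefors

    if len(table) < 3:
        raise ValueError("need at least 3 rows for normality testing")
    results: list[TestResult] = []
    for name in table.column_names:
        x = table.column(name)
        if np.ptp(x) == 0:
            raise DegenerateFeatureError(f"constant feature: {name}")
        d, p_ks = lilliefors(x, dist="norm")
        results.append(TestResult("kolmogorov_smirnov", name, float(d), float(p_ks), (x.size,)))
        w, p_sw = stats.shapiro(x)
        results.append(TestResult("shapiro_wilk", name, float(w), float(p_sw), (x.size,)))
    return results


def welch_test(a: np.ndarray, b: np.ndarray, feature: str = "") -> TestResult:
    """Welch's two-sample t test (unequal variances), two-sided."""
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TestResult("welch", feature, 0.0, 1.0, (a.size, b.size))
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult("welch", feature, float(res.statistic), float(res.pvalue), (a.size, b.size))


def brown_forsythe_means(a: np.ndarray, b: np.ndarray, feature: str = "") -> TestResult:
    """Brown-Forsythe F* test of equal means under unequal variances.

    F* = sum n_i (xbar_i - xbar)^2 / sum (1 - n_i/N) s_i^2 with a
    Satterthwaite-type denominator df; for two equal-variance, equal-size
    groups it reduces to the classical one-way ANOVA F.
    """
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    groups = [a, b]
    ns = np.array([g.size for g in groups], float)
    means = np.array([g.mean() for g in groups])
    variances = np.array([g.var(ddof=1) for g in groups])
    N = ns.sum()
    grand = float((ns * means).sum() / N)
    numerator = float((ns * (means - grand) ** 2).sum())
    weights = (1.0 - ns / N) * variances
    denominator = float(weights.sum())
    if denominator == 0:
        if numerator == 0:
            return TestResult("brown_forsythe", feature, 0.0, 1.0, (a.size, b.size))
        raise ValueError("zero variance in both groups with unequal means")
    f_star = numerator / denominator
    c = weights / denominator
    df_den = 1.0 / float((c**2 / (ns - 1.0)).sum())
    p = float(stats.f.sf(f_star, len(groups) - 1, df_den))
    return TestResult("brown_forsythe", feature, float(f_star), p, (a.size, b.size))


def kruskal_wallis(a: np.ndarray, b: np.ndarray, feature: str = "") -> TestResult:
    """Kruskal-Wallis H test (tie-corrected) that both samples share one distribution."""
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # every observation tied: no evidence of any difference
        return TestResult("kruskal_wallis", feature, 0.0, 1.0, (a.size, b.size))
    h, p = stats.kruskal(a, b)
    return TestResult("kruskal_wallis", feature, float(h), float(p), (a.size, b.size))


# ---------------------------------------------------------------------------
# PCA with Hotelling T²
# ---------------------------------------------------------------------------


def hotelling_t2_limit(n: int, n_components: int, alpha: float = 0.05) -> float:
    """95% (by default) critical value of the Hotelling T² of PCA scores."""
    A, N = n_components, n
    f_crit = stats.f.ppf(1.0 - alpha, A, N - A)
    return float(A * (N - 1) * (N + 1) / (N * (N - A)) * f_crit)


def pca(
    table: FeatureTable | np.ndarray,
    n_components: int = 2,
    scaling: str = "unit-variance",
    alpha: float = 0.05,
) -> PcaResult:
    """PCA of the pooled table with per-sample Hotelling T² statistics.

    ``scaling`` is "unit-variance" (autoscaling, the chemometrics default)
    or "center-only".  Explained-variance fractions are reported for all
    components; scores/loadings and T² for the retained ``n_components``.
    """
    X = table.values if isinstance(table, FeatureTable) else np.asarray(table, float)
    n, p = X.shape
    if n <= n_components:
        raise ValueError("need more rows than components")
    if scaling not in ("unit-variance", "center-only"):
        raise ValueError("scaling must be 'unit-variance' or 'center-only'")
    sd = X.std(axis=0, ddof=1)
    if scaling == "unit-variance" and (sd == 0).any():
        j = int(np.flatnonzero(sd == 0)[0])
        raise DegenerateFeatureError(f"constant feature at column {j}")
    mean = X.mean(axis=0)
    scale = sd if scaling == "unit-variance" else np.ones(p)
    Z = (X - mean) / scale
    # SVD of the centred/scaled matrix == eigendecomposition of its covariance
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = S**2 / (n - 1)
    ratio = eigvals / eigvals.sum()
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components].T
    lam = eigvals[:n_components]
    t2 = np.sum(scores**2 / lam, axis=1)
    limit = hotelling_t2_limit(n, n_components, alpha)
    return PcaResult(ratio, scores, loadings, t2, limit, n_components, mean, scale)


def remove_t2_outliers(
    result: PcaResult, table: FeatureTable, scaling: str = "unit-variance"
) -> tuple[FeatureTable, PcaResult, np.ndarray]:
    """Drop rows beyond the T² 95% limit (one pass) and refit the PCA.

    Returns the filtered table, the refitted PcaResult and the removed row
    indices (into the original table).
    """
    flagged = np.flatnonzero(result.t2 > result.t2_limit)
    if flagged.size == len(table):
        raise ValueError("all rows flagged as outliers; refusing to empty the table")
    keep = np.setdiff1d(np.arange(len(table)), flagged)
    filtered = table.take(keep)
    refit = pca(filtered, result.n_components, scaling)
    return filtered, refit, flagged


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


def opls_da(
    X: np.ndarray,
    y: np.ndarray,
    n_orthogonal: int = 1,
    scale: bool = True,
) -> OplsResult:
    """Orthogonal projections to latent structures discriminant analysis.

    A single predictive component models class membership (y in {0,1},
    encoded ±1 and centred); ``n_orthogonal`` components capture feature
    variation orthogonal to it.  X is centred (and unit-variance scaled by
    default) internally.  R²X per component is ||t p'||²_F / ||X0||²_F.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y row counts differ")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y contains a single class; OPLS-DA needs two")
    if X.shape[0] <= 2 + n_orthogonal:
        raise ValueError("too few rows for the requested number of components")
    yv = np.where(y == classes.max(), 1.0, -1.0)
    yv = yv - yv.mean()
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scale and (sd == 0).any():
        raise DegenerateFeatureError("constant feature in X")
    Z0 = (X - mean) / (sd if scale else 1.0)
    ssx0 = float((Z0**2).sum())

    w = Z0.T @ yv
    w = w / np.linalg.norm(w)
    Z = Z0.copy()
    t_orth_list, p_orth_list, r2x_orth = [], [], []
    for _ in range(n_orthogonal):
        t = Z @ w
        p = Z.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no orthogonal variation left
        w_o = w_o / norm
        t_o = Z @ w_o
        p_o = Z.T @ t_o / (t_o @ t_o)
        Z = Z - np.outer(t_o, p_o)
        t_orth_list.append(t_o)
        p_orth_list.append(p_o)
        r2x_orth.append(float(np.outer(t_o, p_o).ravel() @ np.outer(t_o, p_o).ravel()) / ssx0)

    t_pred = Z @ w
    p_pred = Z.T @ t_pred / (t_pred @ t_pred)
    r2x_pred = float((np.outer(t_pred, p_pred) ** 2).sum()) / ssx0
    ssy = float(yv @ yv)
    q = (yv @ t_pred) / (t_pred @ t_pred)
    r2y = float((q * t_pred @ (q * t_pred)) / ssy) if ssy > 0 else 0.0
    t_orth = np.column_stack(t_orth_list) if t_orth_list else np.empty((X.shape[0], 0))
    p_orth = np.column_stack(p_orth_list) if p_orth_list else np.empty((X.shape[1], 0))
    r2x = np.array([r2x_pred] + r2x_orth)
    return OplsResult(t_pred, p_pred, w, t_orth, p_orth, r2x, r2y)


# ---------------------------------------------------------------------------
# Quadratic surface fits
# ---------------------------------------------------------------------------


def surface_fit(
    table: FeatureTable,
    x_feature: str = "temperature",
    y_feature: str = "time",
    z_feature: str = "alcohol",
    dose_slice: float | None = None,
) -> SurfaceFit:
    """Least-squares full quadratic fit of z over (x, y).

    ``dose_slice`` only annotates the dosage at which the overlay slice is
    drawn; all rows enter the fit (the tables are small).
    """
    if len(table) < 6:
        raise ValueError("need at least 6 rows for a 6-coefficient quadratic")
    x = table.column(x_feature)
    y = table.column(y_feature)
    z = table.column(z_feature)
    design = np.column_stack([np.ones_like(x), x, y, x * x, y * y, x * y])
    rank = np.linalg.matrix_rank(design)
    if rank < 6:
        raise np.linalg.LinAlgError(
            f"rank-deficient quadratic design (rank {rank} < 6): collinear "
            f"{x_feature}/{y_feature} values"
        )
    beta, _, _, _ = np.linalg.lstsq(design, z, rcond=None)
    rss = float(((design @ beta - z) ** 2).sum())
    if dose_slice is None:
        dose_slice = float(table.column("dose").mean())
    return SurfaceFit(tuple(float(b) for b in beta), rss, float(dose_slice), x_feature, y_feature, z_feature)


def surface_grid(fit: SurfaceFit, x_range, y_range, n: int = 25) -> "pd.DataFrame":
    """Evaluate a fitted surface on a regular grid (for overlay plots)."""
    import pandas as pd

    xs = np.linspace(*x_range, n)
    ys = np.linspace(*y_range, n)
    gx, gy = np.meshgrid(xs, ys)
    gz = fit.predict(gx, gy)
    return pd.DataFrame(
        {fit.x_feature: gx.ravel(), fit.y_feature: gy.ravel(), fit.z_feature: gz.ravel()}
    )


# ---------------------------------------------------------------------------
# The full battery
# ---------------------------------------------------------------------------


@dataclass
class FidelityReport:
    """Everything the battery computed, JSON-serialisable."""

    normality: list[TestResult]
    two_sample: list[TestResult]
    pca_initial: PcaResult
    pca_refit: PcaResult
    removed_outliers: list[int]
    opls: OplsResult
    surface_real: SurfaceFit
    surface_synthetic: SurfaceFit
    alpha: float
    passes: dict[str, bool]

    @property
    def all_two_sample_pass(self) -> bool:
        return all(self.passes.values())

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "normality": [t.to_dict() for t in self.normality],
            "two_sample": [t.to_dict() for t in self.two_sample],
            "pca_initial": self.pca_initial.to_dict(),
            "pca_refit": self.pca_refit.to_dict(),
            "removed_outliers": [int(i) for i in self.removed_outliers],
            "opls": self.opls.to_dict(),
            "surface_real": self.surface_real.to_dict(),
            "surface_synthetic": self.surface_synthetic.to_dict(),
            "passes": self.passes,
            "all_two_sample_pass": self.all_two_sample_pass,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        lines = ["Fidelity report", "==============="]
        for t in self.two_sample:
            verdict = "pass" if t.p_value > self.alpha else "FAIL"
            lines.append(
                f"{t.test:>16s} {t.feature:<12s} stat={t.statistic:8.4f} p={t.p_value:.4f} [{verdict}]"
            )
        cum2 = float(self.pca_refit.cumulative_variance_ratio[1])
        lines.append(f"PCA PC1+PC2 variance (refit): {100 * cum2:.1f}%")
        lines.append(f"outliers removed: {len(self.removed_outliers)}")
        lines.append(f"OPLS-DA R2X(cum): {self.opls.r2x_cum:.3f}")
        lines.append(f"overall two-sample verdict: {'pass' if self.all_two_sample_pass else 'FAIL'}")
        return "\n".join(lines)


def _minmax_pooled(real: np.ndarray, synthetic: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pooled = np.vstack([real, synthetic])
    lo = pooled.min(axis=0)
    span = np.ptp(pooled, axis=0)
    span[span == 0] = 1.0
    return (real - lo) / span, (synthetic - lo) / span


def fidelity_report(
    real: FeatureTable, synthetic: FeatureTable, alpha: float = 0.05
) -> FidelityReport:
    """Run the complete validation battery on a real/synthetic table pair.

    Two-sample mean tests run on pooled min-max-normalised features (the
    rank test is scale-invariant anyway); the PCA/OPLS-DA run on the pooled
    autoscaled table with one Hotelling T² outlier-removal pass; quadratic
    alcohol surfaces are fitted per dataset at the real table's mean dosage.
    A per-test flag records p > alpha (no distributional difference found).
    """
    if real.column_names != synthetic.column_names:
        raise SchemaError("real and synthetic tables have different schemas")
    normality = normality_tests(real.concat(synthetic))
    r_norm, s_norm = _minmax_pooled(real.values, synthetic.values)
    two_sample: list[TestResult] = []
    passes: dict[str, bool] = {}
    for j, name in enumerate(real.column_names):
        for fn in (welch_test, brown_forsythe_means, kruskal_wallis):
            t = fn(r_norm[:, j], s_norm[:, j], feature=name)
            two_sample.append(t)
            passes[f"{t.test}:{name}"] = bool(t.p_value > alpha)

    pooled = real.concat(synthetic)
    # class membership for OPLS-DA comes from which argument a row belongs
    # to, not from the stored labels (both tables may carry the same label)
    membership = np.concatenate([np.ones(len(real), int), np.zeros(len(synthetic), int)])
    pca_initial = pca(pooled, n_components=2)
    filtered, pca_refit, removed = remove_t2_outliers(pca_initial, pooled)
    kept = np.setdiff1d(np.arange(len(pooled)), np.asarray(removed, int))
    opls = opls_da(filtered.values, membership[kept], n_orthogonal=1)

    dose_slice = float(real.column("dose").mean())
    surf_real = surface_fit(real, dose_slice=dose_slice)
    surf_synth = surface_fit(synthetic, dose_slice=dose_slice)

    return FidelityReport(
        normality=normality,
        two_sample=two_sample,
        pca_initial=pca_initial,
        pca_refit=pca_refit,
        removed_outliers=[int(i) for i in removed],
        opls=opls,
        surface_real=surf_real,
        surface_synthetic=surf_synth,
        alpha=alpha,
        passes=passes,
    )
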