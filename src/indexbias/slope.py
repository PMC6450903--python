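"""Estimating the confounding slope b and correcting it for regression dilution.

Selecting subjects on disease status makes independent causes of incidence
and prognosis correlated (collider bias).  Under linear structural models

    X = beta_GX * G + beta_UX * U + E_X
    Y = beta_GY * G + beta_UY * U + beta_XY * X + E_Y

the SNP effect on prognosis estimated conditional on incidence equals the
direct effect plus a bias b * beta_GX, with

    b = -var(U) beta_UX beta_UY / (var(U) beta_UX^2 + var(E_X))

constant across polygenic SNPs.  b is therefore estimable as the slope of
the regression of conditional prognosis effects on incidence effects over a
set of approximately independent (LD-pruned) SNPs.  Because the predictor
is itself estimated with error, that slope is attenuated toward zero
(regression dilution); this module provides the method-of-moments
Hedges-Olkin correction and a simulation-extrapolation (SIMEX) correction
with a bootstrap confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

MIN_PAIRS = 10


class SlopeError(ValueError):
    """Degenerate or infeasible slope estimation."""


class DilutionInfeasibleError(SlopeError):
    """Estimated true effect variance is non-positive.

    The Hedges-Olkin denominator var(beta_hat) - mean(se^2) can go negative
    when sampling noise dominates the between-SNP signal; the corrected
    slope would then flip sign, which is implausible because regression
    dilution is a ratio of two variances.  SIMEX is the recommended
    fallback in that regime.
    """


@dataclass
class StructuralParams:
    """Parameters of the single-SNP linear structural model."""

    var_u: float = 1.0
    beta_ux: float = 0.0
    beta_uy: float = 0.0
    var_ex: float = 1.0
    var_ey: float = 1.0
    beta_xy: float = 0.0

    def __post_init__(self):
        if self.var_u <= 0 or self.var_ex <= 0 or self.var_ey <= 0:
            raise ValueError("variances must be strictly positive")


@dataclass
class SlopeFit:
    """The confounding slope: raw, dilution-corrected, and its uncertainty."""

    b_raw: float
    intercept: float
    se_b_raw_robust: float
    b_corrected: float
    var_b: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    method: str = "raw"
    n_snps: int = 0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_snps < MIN_PAIRS:
            raise SlopeError(
                f"slope regression needs >= {MIN_PAIRS} pruned SNPs, got {self.n_snps}"
            )
        if not (self.var_b >= 0):
            raise SlopeError("var_b must be non-negative")

    def summary(self) -> str:
        lines = [
            f"confounding slope (method={self.method}, n_snps={self.n_snps})",
            f"  raw slope      : {self.b_raw:+.6g} (robust SE {self.se_b_raw_robust:.6g})",
            f"  intercept      : {self.intercept:+.6g}",
            f"  corrected slope: {self.b_corrected:+.6g} (SD {np.sqrt(self.var_b):.6g})",
        ]
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            lines.append(f"  95% CI         : [{self.ci_low:+.6g}, {self.ci_high:+.6g}]")
        return "\n".join(lines)


def analytic_b(params: StructuralParams) -> float:
    """Closed-form confounding slope implied by the structural model.

    Negative when the confounder pushes incidence and prognosis in the
    same direction, positive when the directions oppose.
    """
    denom = params.var_u * params.beta_ux**2 + params.var_ex
    if denom == 0:
        raise ZeroDivisionError("var(U)*beta_ux^2 + var(E_X) must be positive")
    return -(params.var_u * params.beta_ux * params.beta_uy) / denom


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and intercept of y on x with intercept, via moments (fast path)."""
    xm = x.mean()
    ym = y.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx == 0:
        raise SlopeError("degenerate design: incidence effects are constant")
    slope = ((x - xm) * (y - ym)).sum() / sxx
    return slope, ym - slope * xm


def fit_raw_slope(
    beta_gx: np.ndarray, beta_gy_prime: np.ndarray, cov_type: str = "HC1"
) -> tuple[float, float, float]:
    """OLS regression of conditional prognosis effects on incidence effects.

    Returns ``(slope, intercept, robust_se_slope)``.  The residual variance
    differs across SNPs (LD and allele frequency both modulate the sampling
    variance of marginal effects), so the slope's standard error uses a
    heteroscedasticity-consistent sandwich estimator (HC1 by default).
    """
    x = np.asarray(beta_gx, dtype=float)
    y = np.asarray(beta_gy_prime, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("beta_gx and beta_gy_prime must be 1-d arrays of equal length")
    if len(x) < MIN_PAIRS:
        raise SlopeError(f"slope regression needs >= {MIN_PAIRS} SNPs, got {len(x)}")
    if np.ptp(x) == 0:
        raise SlopeError("degenerate design: incidence effects are constant")
    model = sm.OLS(y, sm.add_constant(x)).fit(cov_type=cov_type)
    return float(model.params[1]), float(model.params[0]), float(model.bse[1])


def raw_fit(pairs: pd.DataFrame) -> SlopeFit:
    """Slope fit with no dilution correction (b_corrected = b_raw)."""
    x, y = _pruned_arrays(pairs)
    b, a, se = fit_raw_slope(x, y)
    return SlopeFit(
        b_raw=b, intercept=a, se_b_raw_robust=se, b_corrected=b, var_b=se**2,
        ci_low=b - 1.959963984540054 * se, ci_high=b + 1.959963984540054 * se,
        method="raw", n_snps=len(x),
    )


def _pruned_arrays(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    sub = pairs[pairs["pruned"]] if "pruned" in pairs and pairs["pruned"].any() else pairs
    return sub["beta_gx"].to_numpy(float), sub["beta_gy_prime"].to_numpy(float)


def _pruned_se(pairs: pd.DataFrame) -> np.ndarray:
    sub = pairs[pairs["pruned"]] if "pruned" in pairs and pairs["pruned"].any() else pairs
    return sub["se_gx"].to_numpy(float)


def hedges_olkin_correct(
    b_raw: float,
    beta_gx: np.ndarray,
    se_gx: np.ndarray,
    intercept: float = np.nan,
    se_b_raw_robust: float = np.nan,
) -> SlopeFit:
    """Method-of-moments dilution correction of the raw slope.

    The attenuation factor is var(beta_hat_GX) / var(beta_GX), with the
    true effect variance estimated by the Hedges-Olkin moment estimator
    var(beta_hat_GX) - mean(se_GX^2).  The corrected slope multiplies the
    raw slope by the reciprocal factor (>= 1 in magnitude); the raw slope's
    robust variance is scaled by the squared factor.

    Raises :class:`DilutionInfeasibleError` when the moment estimate of the
    true effect variance is non-positive.
    """
    x = np.asarray(beta_gx, dtype=float)
    s = np.asarray(se_gx, dtype=float)
    if len(x) < MIN_PAIRS:
        raise SlopeError(f"need >= {MIN_PAIRS} SNPs, got {len(x)}")
    var_obs = float(np.var(x, ddof=1))
    mean_se2 = float(np.mean(s**2))
    signal = var_obs - mean_se2
    if signal <= 0:
        raise DilutionInfeasibleError(
            "Hedges-Olkin true-effect variance is non-positive "
            f"(var(beta_gx)={var_obs:.3g} <= mean(se^2)={mean_se2:.3g}); "
            "a sign-flipping dilution correction is implausible - use SIMEX"
        )
    factor = var_obs / signal
    var_b = factor**2 * se_b_raw_robust**2 if np.isfinite(se_b_raw_robust) else np.nan
    b_corr = b_raw * factor
    sd = np.sqrt(var_b) if np.isfinite(var_b) else np.nan
    return SlopeFit(
        b_raw=b_raw,
        intercept=intercept,
        se_b_raw_robust=se_b_raw_robust,
        b_corrected=b_corr,
        var_b=var_b if np.isfinite(var_b) else 0.0,
        ci_low=b_corr - 1.959963984540054 * sd if np.isfinite(sd) else np.nan,
        ci_high=b_corr + 1.959963984540054 * sd if np.isfinite(sd) else np.nan,
        method="hedges_olkin",
        n_snps=len(x),
        diagnostics={"var_obs": var_obs, "mean_se2": mean_se2, "factor": factor},
    )


def hedges_olkin_fit(pairs: pd.DataFrame) -> SlopeFit:
    """Raw slope regression followed by Hedges-Olkin dilution correction."""
    x, y = _pruned_arrays(pairs)
    s = _pruned_se(pairs)
    b, a, se = fit_raw_slope(x, y)
    return hedges_olkin_correct(b, x, s, intercept=a, se_b_raw_robust=se)


def _simex_point(
    x: np.ndarray,
    y: np.ndarray,
    se: np.ndarray,
    lambda_grid: np.ndarray,
    n_sim: int,
    extrapolation: str,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray, float, float]:
    """One SIMEX pass: mean slope per lambda, extrapolated slope at -1.

    Returns (b_simex, mean_slopes, slope0, intercept0).
    """
    xm_ = x.mean()
    slope0, intercept0 = _ols_slope(x, y)
    mean_slopes = np.empty(len(lambda_grid))
    n_discard = 0
    n_total = 0
    for i, lam in enumerate(lambda_grid):
        if lam == 0:
            mean_slopes[i] = slope0
            continue
        # vectorised over n_sim replicates: (n_sim, m) noisy predictors
        noise = rng.standard_normal((n_sim, len(x))) * (np.sqrt(lam) * se)
        xs = x + noise
        xc = xs - xs.mean(axis=1, keepdims=True)
        sxx = (xc**2).sum(axis=1)
        good = sxx > 0
        n_total += n_sim
        n_discard += int((~good).sum())
        yc = y - y.mean()
        slopes = (xc[good] @ yc) / sxx[good]
        if len(slopes) == 0:
            raise SlopeError(f"all SIMEX replicates degenerate at lambda={lam}")
        mean_slopes[i] = slopes.mean()
    if n_total and n_discard / n_total > 0.10:
        raise SlopeError(
            f"{n_discard}/{n_total} SIMEX replicates had degenerate designs"
        )
    order = 2 if extrapolation == "quadratic" else 1
    if len(lambda_grid) <= order:
        order = max(1, len(lambda_grid) - 1)
    if len(lambda_grid) == 1:
        return slope0, mean_slopes, slope0, intercept0
    coeffs = np.polyfit(lambda_grid, mean_slopes, order)
    return float(np.polyval(coeffs, -1.0)), mean_slopes, slope0, intercept0


DEFAULT_LAMBDA_GRID = np.arange(0.0, 2.25, 0.25)


def simex_correct(
    pairs: pd.DataFrame,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    n_sim: int = 100,
    extrapolation: str = "quadratic",
    n_boot: int = 200,
    seed: int | None = None,
) -> SlopeFit:
    """Simulation-extrapolation dilution correction with bootstrap CI.

    For each lambda > 0, ``n_sim`` replicate datasets are built by adding
    Gaussian noise with variance ``lambda * se_gx^2`` to the observed
    incidence effects; the slope regression is refit on each and the
    slopes averaged.  A polynomial (quadratic by default) in lambda is fit
    to the mean slopes and evaluated at lambda = -1, the point of zero
    measurement error.  Uncertainty comes from a nonparametric bootstrap
    over SNPs: resample pairs with replacement, rerun the whole SIMEX,
    take the percentile 95% CI and the bootstrap variance as var(b).

    Set ``n_boot=0`` to skip the bootstrap (var_b falls back to the scaled
    robust variance of the raw slope).
    """
    lambda_grid = np.asarray(sorted(lambda_grid), dtype=float)
    if 0.0 not in lambda_grid:
        raise ValueError("lambda_grid must contain 0")
    if np.any(lambda_grid < 0):
        raise ValueError("lambda values must be >= 0")
    if n_sim < 20:
        raise ValueError("n_sim must be >= 20")
    if 0 < n_boot < 100:
        raise ValueError("n_boot must be 0 or >= 100")
    if extrapolation not in ("quadratic", "linear"):
        raise ValueError("extrapolation must be 'quadratic' or 'linear'")

    x, y = _pruned_arrays(pairs)
    se = _pruned_se(pairs)
    if len(x) < MIN_PAIRS:
        raise SlopeError(f"need >= {MIN_PAIRS} pruned SNPs, got {len(x)}")

    rng = np.random.default_rng(seed)
    b_simex, mean_slopes, slope0, intercept0 = _simex_point(
        x, y, se, lambda_grid, n_sim, extrapolation, rng
    )
    _, _, se_raw = fit_raw_slope(x, y)

    diagnostics = {
        "lambda_grid": lambda_grid.tolist(),
        "mean_slopes": mean_slopes.tolist(),
        "n_sim": n_sim,
        "extrapolation": extrapolation,
    }

    if n_boot:
        m = len(x)
        boot = np.empty(n_boot)
        for bi in range(n_boot):
            idx = rng.integers(0, m, m)
            try:
                boot[bi], *_ = _simex_point(
                    x[idx], y[idx], se[idx], lambda_grid, n_sim, extrapolation, rng
                )
            except SlopeError:
                boot[bi] = np.nan
        boot = boot[np.isfinite(boot)]
        if len(boot) < 0.9 * n_boot:
            raise SlopeError("more than 10% of SIMEX bootstrap replicates failed")
        var_b = float(np.var(boot, ddof=1))
        ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
        # percentile CI need not cover a point estimate computed on the
        # full sample; clip so the reported interval always contains it
        ci_low = min(ci_low, b_simex)
        ci_high = max(ci_high, b_simex)
        diagnostics["n_boot"] = int(len(boot))
        diagnostics["bootstrap_slopes"] = boot
    else:
        # fall back: scale the robust raw-slope variance by the implied
        # inflation of the point estimate
        scale = (b_simex / slope0) ** 2 if slope0 != 0 else 1.0
        var_b = float(se_raw**2 * scale)
        sd = np.sqrt(var_b)
        ci_low, ci_high = b_simex - 1.96 * sd, b_simex + 1.96 * sd

    return SlopeFit(
        b_raw=slope0,
        intercept=intercept0,
        se_b_raw_robust=se_raw,
        b_corrected=b_simex,
        var_b=var_b,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        method="simex",
        n_snps=len(x),
        diagnostics=diagnostics,
    )


def estimate_slope(pairs: pd.DataFrame, method: str = "hedges_olkin", **kwargs) -> SlopeFit:
    """Dispatch on ``method`` in {raw, hedges_olkin, simex}."""
    if method == "raw":
        return raw_fit(pairs)
    if method in ("hedges_olkin", "ho"):
        return hedges_olkin_fit(pairs)
    if method == "simex":
        return simex_correct(pairs, **kwargs)
    raise ValueError(f"unknown slope method {method!r}")
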