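"""Per-variant bias correction, standard errors, p-values and diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .slope import SlopeFit

_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, df=1)  # 0.4549...


def adjust_effects(pairs: pd.DataFrame, slope: SlopeFit) -> pd.DataFrame:
    """Apply the bias correction to every variant in ``pairs``.

    The corrected prognosis effect removes the collider-induced component
    proportional to the incidence effect,

        beta_adj = beta_gy_prime - b * beta_gx

    with variance propagating both the measurement error in the two scans
    and the uncertainty of the slope itself:

        se_adj^2 = se_gy^2 + b^2 se_gx^2 + beta_gx^2 var(b) + se_gx^2 var(b)

    The Wald statistic z = beta_adj / se_adj is referred to the standard
    normal for two-sided p-values.  The slope is estimated on the pruned
    subset but applied to all variants.
    """
    if not (slope.var_b >= 0):
        raise ValueError("slope.var_b must be non-negative")
    b = slope.b_corrected
    vb = slope.var_b
    out = pairs.copy()
    bx = out["beta_gx"].to_numpy(float)
    sx = out["se_gx"].to_numpy(float)
    out["beta_gy_adj"] = out["beta_gy_prime"] - b * bx
    out["se_adj"] = np.sqrt(
        out["se_gy"].to_numpy(float) ** 2 + b**2 * sx**2 + bx**2 * vb + sx**2 * vb
    )
    out["z"] = out["beta_gy_adj"] / out["se_adj"]
    out["p"] = 2.0 * stats.norm.sf(np.abs(out["z"]))
    # two-sided tail can round to exactly 0 only below ~1e-308; keep p in (0, 1]
    out["p"] = np.clip(out["p"], np.finfo(float).tiny, 1.0)
    out["method"] = slope.method
    return out


def bootstrap_snp_inference(
    pair,
    slope: SlopeFit | None = None,
    slope_draws: np.ndarray | None = None,
    n_draws: int = 10_000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> dict:
    """Empirical distribution of the adjusted effect for one focal variant.

    The product b * beta_gx of two (approximately) normal estimates is not
    normal, and when the slope's CI is strongly asymmetric — as with a
    SIMEX fit dominated by noisy incidence effects — a Wald p-value is
    unreliable.  This draws ``beta_gy_prime ~ N(est, se_gy^2)``,
    ``beta_gx ~ N(est, se_gx^2)`` and b either from a supplied empirical
    distribution (e.g. SIMEX bootstrap slopes) or from N(b, var_b), forms
    the adjusted effect per draw, and reports the percentile CI and an
    empirical two-sided p-value floored at 1/n_draws (an order bound, not
    an exact level).

    ``pair`` is any mapping with fields ``beta_gy_prime, se_gy, beta_gx,
    se_gx`` (a pairs-table row works).
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    rng = np.random.default_rng(seed)
    if slope_draws is not None:
        slope_draws = np.asarray(slope_draws, dtype=float)
        if slope_draws.size == 0:
            raise ValueError("empty slope distribution")
        b = rng.choice(slope_draws, size=n_draws, replace=True)
    elif slope is not None:
        b = rng.normal(slope.b_corrected, np.sqrt(slope.var_b), size=n_draws)
    else:
        raise ValueError("provide either slope or slope_draws")

    by = rng.normal(pair["beta_gy_prime"], pair["se_gy"], size=n_draws)
    bx = rng.normal(pair["beta_gx"], pair["se_gx"], size=n_draws)
    draws = by - b * bx

    share_le = np.mean(draws <= 0.0)
    share_ge = np.mean(draws >= 0.0)
    p_emp = max(2.0 * min(share_le, share_ge), 1.0 / n_draws)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)])
    return {
        "estimate": float(np.median(draws)),
        "mean": float(draws.mean()),
        "p_empirical": float(min(p_emp, 1.0)),
        "p_is_bound": bool(p_emp <= 1.0 / n_draws),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_draws": n_draws,
        "draws": draws,
    }


def genomic_inflation(p_values) -> tuple[float, int]:
    """Genomic-control inflation factor lambda_GC.

    Median of the implied 1-df chi-square statistics divided by the null
    median 0.4549.  Returns ``(lambda_gc, n_used)``.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_MEDIAN_1DF), int(p.size)
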