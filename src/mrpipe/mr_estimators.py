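"""Univariable two-sample MR estimators and sensitivity statistics.

All estimators consume a :class:`~mrpipe.sumstats_io.HarmonisedSet` and
return an :class:`MREstimate` whose confidence interval is log-symmetric:
``or_`` equals the geometric mean of ``(or_low, or_high)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    NoInstrumentError,
)
from .sumstats_io import HarmonisedSet

#: 97.5% normal quantile; weights are treated as known, so the normal (not t)
#: reference is used throughout.
Z95 = 1.959964

METHODS = ("wald_ratio", "ivw_fixed", "ivw_mre", "egger")


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate for one exposure-outcome pair."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    or_: float
    or_low: float
    or_high: float
    pval: float
    n_snp: int
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None


@dataclass(frozen=True)
class SensitivityReport:
    """Heterogeneity, pleiotropy and directionality diagnostics."""

    cochran_q: float | None
    q_df: int | None
    q_pval: float | None
    egger_intercept: float | None
    egger_intercept_p: float | None
    steiger_direction_ok: bool
    steiger_p: float
    presso_global_p: float | None = None


def _two_sided_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _finish(method: str, beta: float, se: float, n_snp: int, **extra) -> MREstimate:
    ci_low = beta - Z95 * se
    ci_high = beta + Z95 * se
    pval = _two_sided_p(beta / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        or_=math.exp(beta),
        or_low=math.exp(ci_low),
        or_high=math.exp(ci_high),
        pval=pval,
        n_snp=n_snp,
        **extra,
    )


def estimate_from_or_ci(or_low: float, or_high: float, method: str = "ivw_fixed") -> MREstimate:
    """Reconstruct an estimate from the bounds of a log-symmetric 95% OR CI.

    The point estimate is the geometric mean of the bounds; the SE follows
    from the CI width on the log scale.
    """
    if not (0 < or_low <= or_high):
        raise ValueError("CI bounds must be positive with or_low <= or_high")
    lo, hi = math.log(or_low), math.log(or_high)
    return _finish(method, (lo + hi) / 2.0, (hi - lo) / (2.0 * Z95), n_snp=1)


def variance_explained(beta, se, n):
    """Per-SNP trait variance explained, ``t^2 / (t^2 + n - 2)``."""
    t2 = (np.asarray(beta, float) / np.asarray(se, float)) ** 2
    return t2 / (t2 + np.asarray(n, float) - 2.0)


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    second_order: bool = False,
) -> MREstimate:
    """Single-SNP causal estimate ``beta_out / beta_exp``.

    First-order delta SE ``se_out / |beta_exp|`` by default; the second-order
    variant adds the exposure-uncertainty term
    ``beta_out^2 * se_exp^2 / beta_exp^4``.
    """
    if beta_exp == 0:
        raise DegenerateInstrumentError("wald ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    if second_order:
        se = math.sqrt(se_out**2 / beta_exp**2 + beta_out**2 * se_exp**2 / beta_exp**4)
    else:
        se = se_out / abs(beta_exp)
    return _finish("wald_ratio", beta, se, n_snp=1)


def _ivw_core(bx, by, sy):
    w = 1.0 / sy**2
    s2 = float(np.sum(bx**2 * w))
    beta = float(np.sum(bx * by * w)) / s2
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, s2**-0.5, q


def ivw(hset: HarmonisedSet, mode: str = "auto") -> MREstimate:
    """Inverse-variance-weighted estimate: regression through the origin of
    outcome betas on exposure betas, weights ``se_out**-2``.

    ``mode='fixed'`` uses the analytic SE; ``'mre'`` multiplies it by
    ``max(1, sqrt(Q/(n-1)))`` (multiplicative random effects); ``'auto'``
    (default) applies the inflation only when ``Q/(n-1) > 1``.  A single SNP
    delegates to :func:`wald_ratio`.
    """
    if mode not in ("fixed", "mre", "auto"):
        raise ValueError(f"unknown ivw mode {mode!r}")
    n = hset.n_snp
    if n == 0:
        raise NoInstrumentError("no SNPs for IVW")
    if n == 1:
        return wald_ratio(
            float(hset.beta_exp[0]), float(hset.se_exp[0]),
            float(hset.beta_out[0]), float(hset.se_out[0]),
        )
    beta, se_fixed, q = _ivw_core(hset.beta_exp, hset.beta_out, hset.se_out)
    dispersion = q / (n - 1)
    inflate = mode == "mre" or (mode == "auto" and dispersion > 1.0)
    if inflate:
        se = se_fixed * max(1.0, math.sqrt(dispersion))
        method = "ivw_mre"
    else:
        se = se_fixed
        method = "ivw_fixed"
    return _finish(method, beta, se, n_snp=n)


def egger(hset: HarmonisedSet) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure betas with an
    intercept (the directional-pleiotropy test).

    Exposure betas are sign-oriented to be non-negative before fitting.
    SEs carry a multiplicative overdispersion factor
    ``max(1, sqrt(Q_egger/(n-2)))``.
    """
    n = hset.n_snp
    if n < 3:
        raise InsufficientInstrumentsError(f"egger needs >= 3 SNPs, got {n}")
    sign = np.where(hset.beta_exp < 0, -1.0, 1.0)
    bx = hset.beta_exp * sign
    by = hset.beta_out * sign
    w = 1.0 / hset.se_out**2
    X = np.column_stack([np.ones(n), bx])
    A = X.T @ (X * w[:, None])
    coef = np.linalg.solve(A, X.T @ (w * by))
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / (n - 2))
    cov = np.linalg.inv(A) * phi
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))
    return _finish(
        "egger",
        float(slope),
        float(se_slope),
        n_snp=n,
        egger_intercept=float(intercept),
        egger_intercept_p=_two_sided_p(intercept / se_int) if se_int > 0 else 1.0,
    )


def cochran_q(hset: HarmonisedSet, beta_hat: float) -> tuple[float, int, float]:
    """Heterogeneity of per-SNP Wald ratios around ``beta_hat``.

    Ratio-scale weights ``(se_out / beta_exp)**-2``; note this equals the
    regression-scale residual sum ``sum(w * (beta_out - beta_hat*beta_exp)^2)``.
    Returns ``(Q, df, p)`` with ``df = n_snp - 1``.
    """
    if hset.n_snp < 2:
        raise InsufficientInstrumentsError("cochran_q needs >= 2 SNPs")
    w = (hset.beta_exp / hset.se_out) ** 2
    ratios = hset.beta_out / hset.beta_exp
    q = float(np.sum(w * (ratios - beta_hat) ** 2))
    df = hset.n_snp - 1
    return q, df, float(stats.chi2.sf(q, df))


def steiger_test(hset: HarmonisedSet) -> tuple[bool, float]:
    """Whole-set directionality test.

    ``direction_ok`` requires the summed exposure variance explained to
    strictly exceed the outcome's.  The p-value compares the
    Fisher-transformed aggregate correlations ``sqrt(sum r2)`` for the two
    traits using their mean sample sizes.
    """
    r2_exp = float(np.sum(variance_explained(hset.beta_exp, hset.se_exp, hset.n_exp)))
    r2_out = float(np.sum(variance_explained(hset.beta_out, hset.se_out, hset.n_out)))
    direction_ok = r2_exp > r2_out
    r_exp = math.sqrt(min(r2_exp, 1.0 - 1e-12))
    r_out = math.sqrt(min(r2_out, 1.0 - 1e-12))
    n_e = float(np.mean(hset.n_exp))
    n_o = float(np.mean(hset.n_out))
    denom = math.sqrt(1.0 / max(n_e - 3.0, 1.0) + 1.0 / max(n_o - 3.0, 1.0))
    z = (math.atanh(r_exp) - math.atanh(r_out)) / denom
    return direction_ok, _two_sided_p(z)


def sensitivity_report(
    hset: HarmonisedSet,
    estimate: MREstimate,
    presso_global_p: float | None = None,
) -> SensitivityReport:
    """Assemble the standard sensitivity suite for one harmonised set.

    Q and the Egger intercept are reported only when enough SNPs are
    available (2 and 3 respectively).
    """
    q = q_df = q_p = None
    if hset.n_snp >= 2:
        q, q_df, q_p = cochran_q(hset, estimate.beta)
    e_int = e_int_p = None
    if hset.n_snp >= 3:
        e = egger(hset)
        e_int, e_int_p = e.egger_intercept, e.egger_intercept_p
    ok, sp = steiger_test(hset)
    return SensitivityReport(
        cochran_q=q,
        q_df=q_df,
        q_pval=q_p,
        egger_intercept=e_int,
        egger_intercept_p=e_int_p,
        steiger_direction_ok=ok,
        steiger_p=sp,
        presso_global_p=presso_global_p,
    )
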