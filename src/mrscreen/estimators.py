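"""Causal-effect estimators and diagnostics on harmonized variant pairs.

Implements the two-sample MR toolbox for summary data:

* Wald ratio — single-instrument estimate beta_out/beta_exp with the
  first-order delta-method standard error se_out/|beta_exp|.
* IVW — inverse-variance-weighted estimate, equivalently weighted least
  squares of beta_out on beta_exp through the origin with weights
  1/se_out²; fixed-effects, or multiplicative random-effects with the
  standard error inflated by sqrt(max(1, Q/(K-1))).
* Cochran's Q heterogeneity statistic.
* MR-Egger — the same regression with a free intercept; the intercept
  estimates average directional pleiotropy. Unstable for sparse
  instrument sets, hence gated at K >= 3 and annotated.
* cML-MA — constrained maximum likelihood with model averaging: for each
  candidate count k of invalid instruments, profile out k free direct
  effects (the instruments with the largest standardized residuals) and
  re-estimate the causal effect on the rest, iterating to convergence;
  average the per-k estimates with BIC weights.
* Steiger-type directionality test — compares the variance in exposure
  vs outcome explained by the instruments to flag reverse causation.

All estimators are invariant to simultaneous sign flips of
(beta_exp, beta_out) on any instrument, i.e. to allele recoding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, DomainError
from .harmonize import HarmonizedPair
from .sumstats import EffectWithCI, normal_pvalue, or_from_beta

__all__ = [
    "MREstimate",
    "CMLResult",
    "DirectionalityResult",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "egger",
    "cml_ma",
    "directionality_test",
]


@dataclass
class MREstimate:
    """A causal-effect estimate with its uncertainty and diagnostics."""

    method: str                  # wald | ivw_fixed | ivw_random | egger_slope | cml_ma
    beta: float
    se: float
    pval: float
    nsnp: int
    or_ci: EffectWithCI | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.or_ci is None and self.se >= 0 and math.isfinite(self.beta):
            self.or_ci = or_from_beta(self.beta, self.se)


def _arrays(pairs: Sequence[HarmonizedPair]):
    bx = np.array([p.beta_exp for p in pairs], dtype=float)
    sx = np.array([p.se_exp for p in pairs], dtype=float)
    by = np.array([p.beta_out for p in pairs], dtype=float)
    sy = np.array([p.se_out for p in pairs], dtype=float)
    return bx, sx, by, sy


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp.

    Standard error by the first-order delta method, se_out/|beta_exp|;
    undefined for a null exposure effect.
    """
    if pair.beta_exp == 0:
        raise DomainError(f"{pair.variant_id}: Wald ratio undefined for beta_exp = 0")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    return MREstimate(method="wald", beta=beta, se=se, pval=normal_pvalue(beta, se), nsnp=1)


def _ivw_fixed(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float]:
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se = 1.0 / math.sqrt(denom)
    return beta, se


def cochran_q(
    pairs: Sequence[HarmonizedPair], theta: float
) -> tuple[float, int, float] | None:
    """Cochran's Q heterogeneity statistic about a causal estimate theta.

    Q = sum_j (beta_out,j - theta * beta_exp,j)² / se_out,j², on K-1
    degrees of freedom. Returns None for K < 2 (not applicable with
    sparse instruments).
    """
    if len(pairs) < 2:
        return None
    bx, _, by, sy = _arrays(pairs)
    q = float(np.sum((by - theta * bx) ** 2 / sy**2))
    df = len(pairs) - 1
    return q, df, float(stats.chi2.sf(q, df))


def ivw(
    pairs: Sequence[HarmonizedPair],
    effects_model: str = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance-weighted causal estimate over >= 2 instruments.

    ``effects_model`` is ``"fixed"`` or ``"multiplicative_random"``; the
    random-effects variant inflates the fixed standard error by
    sqrt(max(1, Q/(K-1))), never deflating it. A single pair delegates
    to the Wald ratio with a notice.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ConfigurationError(f"unknown effects model {effects_model!r}")
    if len(pairs) == 0:
        raise DomainError("ivw requires at least one instrument")
    if len(pairs) == 1:
        est = wald_ratio(pairs[0])
        est.notes = "single instrument: IVW delegated to Wald ratio"
        return est
    bx, _, by, sy = _arrays(pairs)
    beta, se = _ivw_fixed(bx, by, sy)
    q, df, q_p = cochran_q(pairs, beta)
    if effects_model == "multiplicative_random":
        se *= math.sqrt(max(1.0, q / df))
        method = "ivw_random"
    else:
        method = "ivw_fixed"
    return MREstimate(
        method=method, beta=beta, se=se, pval=normal_pvalue(beta, se),
        nsnp=len(pairs), q_stat=q, q_df=df, q_pval=q_p,
    )


def egger(pairs: Sequence[HarmonizedPair]) -> MREstimate:
    """MR-Egger regression: weighted fit of beta_out on beta_exp with intercept.

    Exposure effects are first oriented non-negative (flipping both betas
    of an instrument, which no estimator here is sensitive to); weights
    are 1/se_out². The intercept estimates average directional
    pleiotropy. Gated at K >= 3; annotated as unstable for sparse
    instrument sets.
    """
    if len(pairs) < 3:
        raise DomainError("MR-Egger requires at least 3 instruments")
    import statsmodels.api as sm

    bx, _, by, sy = _arrays(pairs)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    icept, slope = fit.params
    icept_se, slope_se = fit.bse
    q = cochran_q(pairs, slope)
    return MREstimate(
        method="egger_slope", beta=float(slope), se=float(slope_se),
        pval=normal_pvalue(float(slope), float(slope_se)), nsnp=len(pairs),
        q_stat=q[0] if q else None, q_df=q[1] if q else None, q_pval=q[2] if q else None,
        egger_intercept=float(icept), egger_intercept_se=float(icept_se),
        egger_intercept_p=normal_pvalue(float(icept), float(icept_se)),
        notes="unstable for sparse IVs",
    )


@dataclass
class CMLResult:
    """Per-k constrained-ML solutions and their BIC model average."""

    k_values: list[int]
    theta_k: list[float]
    se_k: list[float]
    negloglik_k: list[float]
    bic_k: list[float]
    invalid_sets: list[list[str]]
    converged: list[bool]
    weights: np.ndarray
    theta_ma: float
    se_ma: float


def _cml_one_start(
    bx: np.ndarray, by: np.ndarray, w: np.ndarray, k: int,
    theta0: float, max_iter: int, tol: float,
) -> tuple[float, float, np.ndarray, bool]:
    theta = theta0
    invalid = np.zeros(len(bx), dtype=bool)
    converged = False
    for _ in range(max_iter):
        resid2 = w * (by - theta * bx) ** 2
        new_invalid = np.zeros_like(invalid)
        if k > 0:
            new_invalid[np.argsort(-resid2, kind="stable")[:k]] = True
        valid = ~new_invalid
        denom = float(np.sum(w[valid] * bx[valid] ** 2))
        new_theta = float(np.sum(w[valid] * bx[valid] * by[valid])) / denom
        if abs(new_theta - theta) < tol and np.array_equal(new_invalid, invalid):
            theta, invalid = new_theta, new_invalid
            converged = True
            break
        theta, invalid = new_theta, new_invalid
    valid = ~invalid
    negloglik = 0.5 * float(np.sum(w[valid] * (by[valid] - theta * bx[valid]) ** 2))
    return theta, negloglik, invalid, converged


def _cml_fixed_k(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray, k: int,
    starts: Sequence[float], max_iter: int, tol: float,
) -> tuple[float, float, float, np.ndarray, bool]:
    """Profile constrained-ML solution with exactly k invalid instruments.

    Alternates (i) ranking instruments by standardized residual and
    declaring the top k invalid (their direct effects are free, so they
    drop from the likelihood) with (ii) re-estimating theta by IVW over
    the valid set. The coordinate updates can stall in a local optimum,
    so several starting values are tried (the IVW estimate plus spread
    quantiles of the per-variant ratios) and the converged solution with
    the smallest negative log-likelihood wins.
    """
    w = 1.0 / sy**2
    best: tuple[float, float, np.ndarray, bool] | None = None
    for theta0 in starts:
        theta, nll, invalid, ok = _cml_one_start(bx, by, w, k, theta0, max_iter, tol)
        if best is None or (ok and not best[3]) or (ok == best[3] and nll < best[1]):
            best = (theta, nll, invalid, ok)
    theta, negloglik, invalid, converged = best
    valid = ~invalid
    se = 1.0 / math.sqrt(float(np.sum(w[valid] * bx[valid] ** 2)))
    return theta, se, negloglik, invalid, converged


def cml_ma(
    pairs: Sequence[HarmonizedPair],
    n_bic: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    max_k: int | None = None,
) -> tuple[CMLResult, MREstimate]:
    """Constrained maximum likelihood with BIC model averaging.

    Fits the invalid-instrument model for every candidate count
    k = 0 .. K-2 (or ``max_k``), then averages the per-k causal
    estimates with weights proportional to exp(-BIC_k / 2), where
    BIC_k = 2 * negloglik_k + k * ln(n_bic). The averaged variance adds
    the between-model spread to the within-model variances.

    ``n_bic`` defaults to the smallest sample size recorded on the pairs
    (exposure or outcome); it must be supplied when the pairs carry none.
    Non-converged k values are flagged and excluded from the average.
    """
    K = len(pairs)
    if K < 3:
        raise DomainError("cML-MA requires at least 3 instruments")
    if n_bic is None:
        ns = [n for p in pairs for n in (p.n_exp, p.n_out) if n is not None]
        if not ns:
            raise ConfigurationError("n_bic not given and pairs carry no sample sizes")
        n_bic = min(ns)
    bx, _, by, sy = _arrays(pairs)
    ids = [p.variant_id for p in pairs]
    theta0, _ = _ivw_fixed(bx, by, sy)
    with np.errstate(divide="ignore"):
        ratios = by / np.where(bx == 0, np.nan, bx)
    starts = [theta0] + [
        float(q) for q in np.nanquantile(ratios, [0.0, 0.25, 0.5, 0.75, 1.0])
        if math.isfinite(q)
    ]

    k_values = list(range(0, (max_k if max_k is not None else K - 2) + 1))
    theta_k, se_k, nll_k, bic_k, inv_sets, conv = [], [], [], [], [], []
    for k in k_values:
        th, se, nll, invalid, ok = _cml_fixed_k(bx, by, sy, k, starts, max_iter, tol)
        theta_k.append(th)
        se_k.append(se)
        nll_k.append(nll)
        bic_k.append(2.0 * nll + k * math.log(n_bic))
        inv_sets.append([ids[j] for j in np.flatnonzero(invalid)])
        conv.append(ok)
    if not any(conv):
        raise DomainError("cML-MA failed to converge for every candidate k")
    if not all(conv):
        warnings.warn(
            f"cML-MA: {conv.count(False)} of {len(conv)} candidate k values "
            "did not converge and are excluded from the model average",
            stacklevel=2,
        )

    bic = np.array(bic_k)
    bic_ref = min(b for b, c in zip(bic_k, conv) if c)  # shift for stable softmax
    w = np.where(conv, np.exp(-(bic - bic_ref) / 2.0), 0.0)
    w = w / w.sum()
    theta_ma = float(np.sum(w * np.array(theta_k)))
    se_ma = float(
        math.sqrt(np.sum(w * (np.array(se_k) ** 2 + (np.array(theta_k) - theta_ma) ** 2)))
    )
    result = CMLResult(
        k_values=k_values, theta_k=theta_k, se_k=se_k, negloglik_k=nll_k,
        bic_k=bic_k, invalid_sets=inv_sets, converged=conv,
        weights=w, theta_ma=theta_ma, se_ma=se_ma,
    )
    estimate = MREstimate(
        method="cml_ma", beta=theta_ma, se=se_ma,
        pval=normal_pvalue(theta_ma, se_ma), nsnp=K,
    )
    return result, estimate


@dataclass
class DirectionalityResult:
    """Steiger-type comparison of instrument variance explained."""

    r2_exposure: float
    r2_outcome: float
    direction_ok: bool
    steiger_p: float


def directionality_test(
    pairs: Sequence[HarmonizedPair],
    n_exposure: float | None = None,
    n_outcome: float | None = None,
) -> DirectionalityResult:
    """Test that the instruments explain more of the exposure than the outcome.

    Per instrument, variance explained is r²_j = 2 p (1-p) beta_j² on the
    standardized scale (for a binary outcome this is the observed-scale
    approximation). The summed r² values are compared with a Fisher-z
    test on the implied correlations; ``direction_ok`` is True when the
    exposure sum strictly exceeds the outcome sum, i.e. the causal arrow
    points exposure -> outcome. Instruments missing a frequency are
    excluded from the sums with a warning.
    """
    usable = [p for p in pairs if p.eaf_exp is not None and p.eaf_out is not None]
    if len(usable) < len(pairs):
        warnings.warn(
            f"{len(pairs) - len(usable)} instrument(s) without frequencies "
            "excluded from directionality sums",
            stacklevel=2,
        )
    if not usable:
        raise DomainError("directionality test needs at least one instrument with eaf")
    r2e = sum(2 * p.eaf_exp * (1 - p.eaf_exp) * p.beta_exp**2 for p in usable)
    r2o = sum(2 * p.eaf_out * (1 - p.eaf_out) * p.beta_out**2 for p in usable)
    r2e, r2o = min(r2e, 1.0), min(r2o, 1.0)

    if n_exposure is None:
        ns = [p.n_exp for p in usable if p.n_exp is not None]
        n_exposure = float(np.median(ns)) if ns else None
    if n_outcome is None:
        ns = [p.n_out for p in usable if p.n_out is not None]
        n_outcome = float(np.median(ns)) if ns else None

    if r2e == r2o:
        p_val = 1.0
    elif n_exposure is None or n_outcome is None or min(n_exposure, n_outcome) <= 3:
        p_val = float("nan")
    else:
        z_e = np.arctanh(min(math.sqrt(r2e), 1 - 1e-12))
        z_o = np.arctanh(min(math.sqrt(r2o), 1 - 1e-12))
        z = (z_e - z_o) / math.sqrt(1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3))
        p_val = float(max(2.0 * stats.norm.sf(abs(z)), 1e-300))
    return DirectionalityResult(
        r2_exposure=float(r2e), r2_outcome=float(r2o),
        direction_ok=bool(r2e > r2o), steiger_p=p_val,
    )
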