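"""Model/Results front door for two-sample MR, statsmodels-style.

:class:`MRModel` is built from harmonized exposure/outcome pairs (or
directly from two summary-statistics sets, which it harmonizes);
``fit()`` returns an :class:`MRResults` carrying the estimate, its
uncertainty, heterogeneity diagnostics and a ``summary()`` table.

>>> model = MRModel.from_studies(exposure_records, outcome_records)
>>> res = model.fit(method="ivw_random")
>>> print(res.summary())
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import estimators as est
from .estimators import CMLResult, DirectionalityResult, MREstimate
from .exceptions import ConfigurationError, DomainError
from .harmonize import Action, HarmonizedPair, HarmonizeReport, harmonize
from .sumstats import VariantAssociation

__all__ = ["MRModel", "MRResults"]

_METHODS = ("auto", "wald", "ivw_fixed", "ivw_random", "egger", "cml_ma")


class MRResults:
    """Fitted causal-effect results; wraps an :class:`MREstimate`.

    Attributes of the underlying estimate (``beta``, ``se``, ``pval``,
    ``or_ci``, ``nsnp``, ``q_stat`` ...) are reachable directly on the
    results object. ``cml`` holds the per-k :class:`CMLResult` when the
    method was cML-MA.
    """

    def __init__(self, model: "MRModel", estimate: MREstimate,
                 cml: CMLResult | None = None):
        self.model = model
        self.estimate = estimate
        self.cml = cml

    def __getattr__(self, name):
        return getattr(self.estimate, name)

    @property
    def conf_int(self) -> tuple[float, float]:
        """95% confidence interval on the beta scale."""
        from .sumstats import Z_975

        return (self.beta - Z_975 * self.se, self.beta + Z_975 * self.se)

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Two-sample MR results",
            "=" * 54,
            f"method:        {e.method}",
            f"instruments:   {e.nsnp}",
            f"beta:          {e.beta: .6f}  (se {e.se:.6f})",
            f"95% CI (beta): [{self.conf_int[0]: .6f}, {self.conf_int[1]: .6f}]",
            f"OR [95% CI]:   {e.or_ci.or_value:.4f} "
            f"[{e.or_ci.ci_lower:.4f}, {e.or_ci.ci_upper:.4f}]",
            f"p-value:       {e.pval:.4g}",
        ]
        if e.q_stat is not None:
            lines.append(f"Cochran Q:     {e.q_stat:.4f} on {e.q_df} df (p {e.q_pval:.4g})")
        if e.egger_intercept is not None:
            lines.append(
                f"Egger intercept: {e.egger_intercept: .6f} "
                f"(se {e.egger_intercept_se:.6f}, p {e.egger_intercept_p:.4g})"
            )
        if self.cml is not None:
            top = int(np.argmax(self.cml.weights))
            lines.append(
                f"cML-MA:        weight-dominant k = {self.cml.k_values[top]} "
                f"(w {self.cml.weights[top]:.3f})"
            )
        if e.notes:
            lines.append(f"note:          {e.notes}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """One-row DataFrame in the screen-table layout."""
        e = self.estimate
        return pd.DataFrame(
            [
                {
                    "method": e.method,
                    "beta": e.beta,
                    "se": e.se,
                    "pval": e.pval,
                    "or": e.or_ci.or_value,
                    "or_lo": e.or_ci.ci_lower,
                    "or_hi": e.or_ci.ci_upper,
                    "nsnp": e.nsnp,
                    "q_stat": e.q_stat,
                    "q_pval": e.q_pval,
                    "egger_intercept": e.egger_intercept,
                    "egger_intercept_p": e.egger_intercept_p,
                }
            ]
        )

    def plot(self, ax=None):
        """Scatter of instrument effects with the fitted causal slope."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        bx = np.array([p.beta_exp for p in self.model.pairs])
        by = np.array([p.beta_out for p in self.model.pairs])
        sy = np.array([p.se_out for p in self.model.pairs])
        ax.errorbar(bx, by, yerr=1.959964 * sy, fmt="o", ms=4, lw=0.8, capsize=2,
                    color="#34618d", alpha=0.8)
        xs = np.linspace(min(0, bx.min()), max(0, bx.max()), 50)
        icept = self.estimate.egger_intercept or 0.0
        ax.plot(xs, icept + self.estimate.beta * xs, color="#c0392b",
                label=f"{self.estimate.method}: {self.estimate.beta:.3f}")
        ax.axhline(0, color="grey", lw=0.5)
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_xlabel("instrument effect on exposure")
        ax.set_ylabel("instrument effect on outcome")
        ax.legend(frameon=False)
        return ax


class MRModel:
    """Two-sample MR model over harmonized instrument pairs.

    Parameters
    ----------
    pairs
        Harmonized exposure/outcome effect pairs, e.g. from
        :func:`mrscreen.harmonize.harmonize` or the class constructors.
    n_exposure, n_outcome
        Study sample sizes; default to the values carried on the pairs.
        Used for the cML-MA BIC penalty and the directionality test.
    """

    def __init__(
        self,
        pairs: Sequence[HarmonizedPair],
        n_exposure: float | None = None,
        n_outcome: float | None = None,
    ):
        self.pairs = list(pairs)
        if not self.pairs:
            raise DomainError("MRModel needs at least one harmonized pair")
        self.n_exposure = n_exposure
        self.n_outcome = n_outcome
        self.harmonize_report: HarmonizeReport | None = None

    @classmethod
    def from_studies(
        cls,
        exposure: Sequence[VariantAssociation],
        outcome: Sequence[VariantAssociation],
        drop_all_palindromic: bool = False,
    ) -> "MRModel":
        """Harmonize two summary-statistics sets and build the model."""
        pairs, report = harmonize(exposure, outcome, drop_all_palindromic)
        model = cls(pairs)
        model.harmonize_report = report
        return model

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "MRModel":
        """Build from a DataFrame with columns beta_exp, se_exp, beta_out, se_out
        (plus optional variant_id, eaf_exp, eaf_out, n_exp, n_out)."""
        required = {"beta_exp", "se_exp", "beta_out", "se_out"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigurationError(f"missing column(s): {sorted(missing)}")
        pairs = [
            HarmonizedPair(
                variant_id=str(row.get("variant_id", f"v{i:04d}")),
                effect_allele=str(row.get("effect_allele", "A")),
                other_allele=str(row.get("other_allele", "G")),
                beta_exp=float(row["beta_exp"]),
                se_exp=float(row["se_exp"]),
                beta_out=float(row["beta_out"]),
                se_out=float(row["se_out"]),
                eaf_exp=float(row.get("eaf_exp", np.nan)),
                eaf_out=float(row.get("eaf_out", np.nan)),
                action=Action.AS_IS,
                n_exp=row.get("n_exp"),
                n_out=row.get("n_out"),
            )
            for i, (_, row) in enumerate(df.iterrows())
        ]
        return cls(pairs, **kwargs)

    @property
    def nsnp(self) -> int:
        return len(self.pairs)

    def fit(self, method: str = "auto", **kwargs) -> MRResults:
        """Estimate the causal effect.

        ``method`` is one of ``auto`` (Wald ratio for a single
        instrument, random-effects IVW otherwise — the screening
        default), ``wald``, ``ivw_fixed``, ``ivw_random``, ``egger`` or
        ``cml_ma``. Extra keyword arguments are passed to the estimator
        (e.g. ``n_bic``, ``max_iter``, ``tol`` for cML-MA).
        """
        if method not in _METHODS:
            raise ConfigurationError(f"unknown method {method!r}; choose from {_METHODS}")
        if method == "auto":
            method = "wald" if self.nsnp == 1 else "ivw_random"
        if method == "wald":
            if self.nsnp != 1:
                raise DomainError("Wald ratio requires exactly one instrument")
            return MRResults(self, est.wald_ratio(self.pairs[0]))
        if method in ("ivw_fixed", "ivw_random"):
            effects = "fixed" if method == "ivw_fixed" else "multiplicative_random"
            return MRResults(self, est.ivw(self.pairs, effects_model=effects))
        if method == "egger":
            return MRResults(self, est.egger(self.pairs))
        kwargs.setdefault("n_bic", self._default_n_bic())
        cml, estimate = est.cml_ma(self.pairs, **kwargs)
        return MRResults(self, estimate, cml=cml)

    def _default_n_bic(self) -> float | None:
        ns = [n for n in (self.n_exposure, self.n_outcome) if n is not None]
        if ns:
            return min(ns)
        ns = [n for p in self.pairs for n in (p.n_exp, p.n_out) if n is not None]
        return min(ns) if ns else None

    def fit_all(self, n_bic: float | None = None) -> list[MRResults]:
        """Every estimator applicable at this instrument count.

        K = 1: Wald only. K = 2: fixed and random IVW. K >= 3: IVW pair
        plus MR-Egger and cML-MA — the screening battery.
        """
        if self.nsnp == 1:
            return [self.fit("wald")]
        out = [self.fit("ivw_fixed"), self.fit("ivw_random")]
        if self.nsnp >= 3:
            out.append(self.fit("egger"))
            out.append(self.fit("cml_ma", **({"n_bic": n_bic} if n_bic else {})))
        return out

    def directionality(self) -> DirectionalityResult:
        """Steiger-type reverse-causality check on the model's instruments."""
        return est.directionality_test(self.pairs, self.n_exposure, self.n_outcome)

    def cochran_q(self, theta: float | None = None):
        """Cochran's Q about ``theta`` (default: the fixed-effects IVW estimate)."""
        if theta is None:
            theta = self.fit("ivw_fixed").beta if self.nsnp > 1 else self.fit("wald").beta
        return est.cochran_q(self.pairs, theta)
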