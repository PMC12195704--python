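"""Two-step mediation MR with parametric bootstrap.

The causal chain exposure -> mediator -> outcome is decomposed with the
product-of-coefficients method on three independently estimated MR legs:

* beta_total — exposure -> outcome (gene instruments),
* beta_em    — exposure -> mediator (gene instruments),
* beta_mo    — mediator -> outcome (mediator instruments).

The indirect effect is beta_em * beta_mo and the proportion mediated is
100 * indirect / total (percent). Because only summary statistics exist,
the bootstrap is parametric: each replicate draws the two leg estimates
from their normal sampling distributions and the CI is the 2.5/97.5
percentile of the products. A pathway is reported as direction-consistent
only when the sign of the indirect effect agrees with the sign of the
total effect and both legs are individually significant (p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .estimators import DirectionalityResult, MREstimate
from .exceptions import ConfigurationError, DomainError
from .harmonize import HarmonizedPair
from .model import MRModel, MRResults

__all__ = ["MediationResult", "MediationModel", "two_step_mediation"]

_LEG_METHODS = ("ivw", "cml_ma")


@dataclass
class MediationResult:
    """One mediation pathway's decomposition, filters and bootstrap CI."""

    exposure: str
    mediator: str
    method: str                       # ivw | cml_ma
    beta_total: float
    se_total: float
    pval_total: float
    beta_em: float
    se_em: float
    pval_em: float
    beta_mo: float
    se_mo: float
    pval_mo: float
    beta_indirect: float
    proportion: float | None          # percent; None when beta_total == 0
    boot_ci_low: float
    boot_ci_high: float
    n_boot: int
    direction_consistent: bool
    reverse_causal_flag: bool

    def summary(self) -> str:
        prop = "undefined" if self.proportion is None else f"{self.proportion:.3f}%"
        return "\n".join(
            [
                f"Two-step mediation MR ({self.method})",
                "=" * 54,
                f"pathway:        {self.exposure} -> {self.mediator} -> outcome",
                f"total effect:   {self.beta_total: .6f} (se {self.se_total:.6f}, "
                f"p {self.pval_total:.4g})",
                f"step 1 (E->M):  {self.beta_em: .6f} (se {self.se_em:.6f}, "
                f"p {self.pval_em:.4g})",
                f"step 2 (M->O):  {self.beta_mo: .6f} (se {self.se_mo:.6f}, "
                f"p {self.pval_mo:.4g})",
                f"indirect:       {self.beta_indirect: .6f} "
                f"[boot 95% CI {self.boot_ci_low: .6f}, {self.boot_ci_high: .6f}; "
                f"{self.n_boot} draws]",
                f"proportion mediated: {prop}",
                f"direction consistent: {self.direction_consistent}   "
                f"reverse-causality flag: {self.reverse_causal_flag}",
                "=" * 54,
            ]
        )


def _fit_leg(pairs: Sequence[HarmonizedPair], method: str) -> MRResults:
    model = MRModel(pairs)
    if method == "ivw":
        return model.fit("auto")          # Wald for K=1, random-effects IVW otherwise
    if model.nsnp >= 3:
        return model.fit("cml_ma")
    # cML-MA is undefined below 3 instruments; the sparse-leg fallback is
    # the same auto rule the screen uses.
    return model.fit("auto")


class MediationModel:
    """Two-step mediation MR model over three harmonized leg datasets.

    Parameters
    ----------
    total_pairs, em_pairs, mo_pairs
        Harmonized pairs for the exposure->outcome, exposure->mediator
        and mediator->outcome legs. The two exposure legs are expected to
        share instruments; the mediator leg uses its own.
    exposure, mediator
        Labels carried into the result table.
    """

    def __init__(
        self,
        total_pairs: Sequence[HarmonizedPair],
        em_pairs: Sequence[HarmonizedPair],
        mo_pairs: Sequence[HarmonizedPair],
        exposure: str = "exposure",
        mediator: str = "mediator",
    ):
        for name, pairs in (("total", total_pairs), ("em", em_pairs), ("mo", mo_pairs)):
            if not pairs:
                raise DomainError(f"mediation leg {name!r} has no instruments")
        self.total_pairs = list(total_pairs)
        self.em_pairs = list(em_pairs)
        self.mo_pairs = list(mo_pairs)
        self.exposure = exposure
        self.mediator = mediator

    def fit(
        self,
        method: str = "ivw",
        n_boot: int = 1000,
        seed: int | None = None,
        alpha: float = 0.05,
    ) -> MediationResult:
        """Estimate the three legs, the indirect effect and its bootstrap CI.

        ``method`` selects the per-leg estimator (``ivw`` or ``cml_ma``;
        legs too sparse for cML-MA fall back to the Wald/IVW auto rule).
        The bootstrap perturbs the two legs entering the product; the
        total effect stays at its point estimate, since the CI is on the
        indirect effect itself.
        """
        if method not in _LEG_METHODS:
            raise ConfigurationError(f"unknown mediation method {method!r}")
        if n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")
        total = _fit_leg(self.total_pairs, method)
        em = _fit_leg(self.em_pairs, method)
        mo = _fit_leg(self.mo_pairs, method)

        beta_indirect = em.beta * mo.beta
        proportion = (
            None if total.beta == 0 else 100.0 * beta_indirect / total.beta
        )

        rng = np.random.default_rng(seed)
        em_star = rng.normal(em.beta, em.se, size=n_boot)
        mo_star = rng.normal(mo.beta, mo.se, size=n_boot)
        products = em_star * mo_star
        lo, hi = np.percentile(products, [100 * alpha / 2, 100 * (1 - alpha / 2)])

        direction_consistent = (
            np.sign(beta_indirect) == np.sign(total.beta)
            and em.pval < 0.05
            and mo.pval < 0.05
        )

        reverse = False
        for pairs in (self.em_pairs, self.mo_pairs):
            try:
                d = MRModel(pairs).directionality()
            except Exception:
                continue
            if not d.direction_ok:
                reverse = True

        return MediationResult(
            exposure=self.exposure,
            mediator=self.mediator,
            method=method,
            beta_total=total.beta, se_total=total.se, pval_total=total.pval,
            beta_em=em.beta, se_em=em.se, pval_em=em.pval,
            beta_mo=mo.beta, se_mo=mo.se, pval_mo=mo.pval,
            beta_indirect=beta_indirect,
            proportion=proportion,
            boot_ci_low=float(lo), boot_ci_high=float(hi),
            n_boot=n_boot,
            direction_consistent=bool(direction_consistent),
            reverse_causal_flag=reverse,
        )


def two_step_mediation(
    total_pairs: Sequence[HarmonizedPair],
    em_pairs: Sequence[HarmonizedPair],
    mo_pairs: Sequence[HarmonizedPair],
    method: str = "ivw",
    n_boot: int = 1000,
    seed: int | None = None,
    exposure: str = "exposure",
    mediator: str = "mediator",
) -> MediationResult:
    """Functional front end for :class:`MediationModel` (build + fit)."""
    return MediationModel(
        total_pairs, em_pairs, mo_pairs, exposure=exposure, mediator=mediator
    ).fit(method=method, n_boot=n_boot, seed=seed)
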