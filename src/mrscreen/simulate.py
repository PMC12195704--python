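"""Synthetic GWAS/eQTL/pQTL summary statistics with known causal structure.

Summary statistics are simulated directly on the (beta, se) scale — no
individual-level genotypes — because that is exactly the structure every
two-sample MR estimator consumes, and it keeps a full screen in seconds.

The generative model, per variant j:

* minor-allele frequency  maf_j ~ Uniform(maf_range)
* true instrument effect  b_j ~ Normal(beta_gx_mean, beta_gx_sd²)
  (defaults emulate a strong cis-QTL signal, so instruments pass the
  conventional F > 10 strength bound at consortium sample sizes)
* exposure sampling error  se_exp,j = 1 / sqrt(2 maf_j (1 - maf_j) n_exposure)
  and   beta_exp,j ~ Normal(b_j, se_exp,j²)
* direct (pleiotropic) effect  alpha_j = 0 for valid instruments,
  alpha_j ~ Normal(pleiotropy_mean, pleiotropy_sd²) for the invalid
  fraction — directional by default, the case that biases IVW
* outcome  beta_out,j ~ Normal(theta · b_j + alpha_j, se_out,j²) with
  se_out,j defined analogously under n_outcome.

A configurable fraction of variants is palindromic (A/T or C/G) and a
fraction has effect/other alleles swapped between the two studies (beta
negated, frequency mirrored), so the harmonization stage has real work
to do. Every draw is recorded in a truth object: which variants are
invalid, palindromic, coding-flipped, or frequency-ambiguous, together
with all true parameters.

p-values are computed from beta/se by the two-sided normal formula, so
the data-model consistency validator holds exactly on simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError
from .sumstats import LDMatrix, VariantAssociation, normal_pvalue

__all__ = [
    "SimulationConfig",
    "MediationConfig",
    "PairTruth",
    "MediationTruth",
    "simulate_pair",
    "simulate_mediation",
    "simulate_ld",
    "AMBIGUOUS_MAF_BAND",
]

#: Open MAF band within which a palindromic variant cannot be oriented
#: by frequency and must be dropped at harmonization.
AMBIGUOUS_MAF_BAND = (0.42, 0.58)

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_PLAIN_PAIRS = [
    ("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
    ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G"),
]


@dataclass
class SimulationConfig:
    """Parameters of one simulated exposure/outcome summary-statistics pair.

    Defaults are scaled to the consortium setting the package targets: an
    eQTL exposure study of ~32k samples, a disease GWAS of ~25k samples,
    and cis instruments strong enough to clear genome-wide significance.
    """

    n_variants: int = 30
    theta: float = 0.2                  # true causal effect, exposure -> outcome
    prop_invalid: float = 0.0           # fraction of instruments with direct effects
    pleiotropy_mean: float = 0.05       # directional by default; 0 => balanced
    pleiotropy_sd: float = 0.02
    n_exposure: float = 31_684
    n_outcome: float = 24_589
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_palindromic: float = 0.0
    frac_flipped_coding: float = 0.0
    ld_block: tuple[int, float] | None = None   # (block size, within-block r²)
    beta_gx_mean: float = 0.15          # true instrument-effect distribution
    beta_gx_sd: float = 0.05
    freq_noise_sd: float = 0.005        # between-study allele-frequency noise
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_spacing: int = 2_000
    id_prefix: str = "snp"
    seed: int = 0

    def validate(self) -> None:
        for name in ("prop_invalid", "frac_palindromic", "frac_flipped_coding"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.prop_invalid >= 1.0:
            raise ConfigurationError("prop_invalid must be < 1")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ConfigurationError("sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        if self.ld_block is not None and not (
            self.ld_block[0] >= 1 and 0.0 <= self.ld_block[1] <= 1.0
        ):
            raise ConfigurationError(f"invalid ld_block {self.ld_block}")


@dataclass
class PairTruth:
    """Ground truth behind one simulated exposure/outcome pair."""

    theta: float
    b: np.ndarray                       # true instrument effects on the exposure
    alpha: np.ndarray                   # true direct (pleiotropic) effects
    variant_ids: list[str]
    invalid_ids: list[str]
    palindromic_ids: list[str]
    flipped_ids: list[str]              # coding swapped in the outcome study
    ambiguous_ids: list[str]            # palindromes un-orientable by frequency
    config: SimulationConfig


@dataclass
class MediationConfig:
    """A gene -> protein -> disease mediation chain with known effects.

    ``beta_em`` is the gene-expression -> mediator-protein effect,
    ``beta_mo`` the protein -> outcome effect, ``beta_direct`` the
    exposure -> outcome path not through the mediator. The gene and
    protein instrument sets are disjoint, as cis-eQTL and cis-pQTL
    instruments for different loci are.
    """

    beta_em: float = 0.5
    beta_mo: float = 0.04
    beta_direct: float = 0.18
    gene_cfg: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(n_variants=20, id_prefix="gsnp", chrom="17")
    )
    protein_cfg: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(
            n_variants=20, id_prefix="psnp", chrom="9", n_exposure=34_557
        )
    )
    n_outcome_gwas: float = 24_589
    seed: int = 0

    @property
    def true_total(self) -> float:
        return self.beta_direct + self.beta_em * self.beta_mo

    @property
    def true_indirect(self) -> float:
        return self.beta_em * self.beta_mo

    @property
    def true_proportion(self) -> float:
        """True proportion mediated, in percent (NaN when the total effect is 0)."""
        if self.true_total == 0:
            return float("nan")
        return 100.0 * self.true_indirect / self.true_total


@dataclass
class MediationTruth:
    total: float
    indirect: float
    proportion: float                   # percent
    config: MediationConfig
    gene_truth: PairTruth
    protein_truth: PairTruth


def _analytic_se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _choose_flags(rng: np.random.Generator, k: int, frac: float) -> np.ndarray:
    """Exactly round(frac*k) True flags at random positions."""
    count = int(round(frac * k))
    flags = np.zeros(k, dtype=bool)
    if count:
        flags[rng.choice(k, size=count, replace=False)] = True
    return flags


def _records(
    cfg: SimulationConfig,
    ids: list[str],
    alleles: list[tuple[str, str]],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: float,
    flipped: np.ndarray,
) -> list[VariantAssociation]:
    out = []
    for j, vid in enumerate(ids):
        ea, oa = alleles[j]
        b, f = beta[j], eaf[j]
        if flipped[j]:
            ea, oa = oa, ea
            b = -b
            f = 1.0 - f
        out.append(
            VariantAssociation(
                variant_id=vid,
                chrom=cfg.chrom,
                pos=cfg.pos_start + j * cfg.pos_spacing,
                effect_allele=ea,
                other_allele=oa,
                eaf=float(f),
                beta=float(b),
                se=float(se[j]),
                pval=normal_pvalue(float(b), float(se[j])),
                n=n,
            )
        )
    return out


def simulate_pair(
    cfg: SimulationConfig,
) -> tuple[list[VariantAssociation], list[VariantAssociation], PairTruth]:
    """Simulate one exposure study and one outcome study over shared variants.

    Returns the two summary-statistics sets (in variant-index order, ids
    ``<prefix>0000`` ...) and the :class:`PairTruth` record. Fully
    deterministic under ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_variants
    ids = [f"{cfg.id_prefix}{j:04d}" for j in range(k)]

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=k)
    b = rng.normal(cfg.beta_gx_mean, cfg.beta_gx_sd, size=k)

    invalid = _choose_flags(rng, k, cfg.prop_invalid)
    alpha = np.where(invalid, rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=k), 0.0)

    palindromic = _choose_flags(rng, k, cfg.frac_palindromic)
    flipped = _choose_flags(rng, k, cfg.frac_flipped_coding)

    pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), size=k)
    plain_choice = rng.integers(0, len(_PLAIN_PAIRS), size=k)
    alleles = [
        _PALINDROMIC_PAIRS[pal_choice[j]] if palindromic[j] else _PLAIN_PAIRS[plain_choice[j]]
        for j in range(k)
    ]

    se_exp = _analytic_se(maf, cfg.n_exposure)
    se_out = _analytic_se(maf, cfg.n_outcome)
    beta_exp = rng.normal(b, se_exp)
    beta_out = rng.normal(cfg.theta * b + alpha, se_out)

    eaf_exp = maf
    eaf_out = np.clip(maf + rng.normal(0.0, cfg.freq_noise_sd, size=k), 1e-3, 1 - 1e-3)

    exposure = _records(cfg, ids, alleles, eaf_exp, beta_exp, se_exp,
                        cfg.n_exposure, np.zeros(k, dtype=bool))
    outcome = _records(cfg, ids, alleles, eaf_out, beta_out, se_out,
                       cfg.n_outcome, flipped)

    lo, hi = AMBIGUOUS_MAF_BAND
    maf_exp_side = np.minimum(eaf_exp, 1 - eaf_exp)
    maf_out_side = np.minimum(eaf_out, 1 - eaf_out)
    ambiguous = palindromic & (
        ((maf_exp_side > lo) & (maf_exp_side < hi))
        | ((maf_out_side > lo) & (maf_out_side < hi))
    )

    truth = PairTruth(
        theta=cfg.theta,
        b=b,
        alpha=alpha,
        variant_ids=ids,
        invalid_ids=[ids[j] for j in range(k) if invalid[j]],
        palindromic_ids=[ids[j] for j in range(k) if palindromic[j]],
        flipped_ids=[ids[j] for j in range(k) if flipped[j]],
        ambiguous_ids=[ids[j] for j in range(k) if ambiguous[j]],
        config=cfg,
    )
    return exposure, outcome, truth


def simulate_ld(cfg: SimulationConfig) -> LDMatrix | None:
    """Equicorrelated block-diagonal r² matrix matching ``cfg.ld_block``.

    Deliberately minimal LD: a single within-block r² and zero between
    blocks — enough to exercise clumping, not a population-genetic model.
    Returns None when the config declares no LD structure.
    """
    if cfg.ld_block is None:
        return None
    block, r2 = cfg.ld_block
    k = cfg.n_variants
    ids = [f"{cfg.id_prefix}{j:04d}" for j in range(k)]
    mat = np.zeros((k, k))
    for start in range(0, k, block):
        stop = min(start + block, k)
        mat[start:stop, start:stop] = r2
    np.fill_diagonal(mat, 1.0)
    return LDMatrix(variant_ids=ids, r2=mat)


def simulate_mediation(
    cfg: MediationConfig,
) -> tuple[
    tuple[list[VariantAssociation], list[VariantAssociation]],
    tuple[list[VariantAssociation], list[VariantAssociation]],
    tuple[list[VariantAssociation], list[VariantAssociation]],
    MediationTruth,
]:
    """Simulate the three summary-statistics pairs of a two-step mediation MR.

    Returns, in order: (exposure -> mediator), (mediator -> outcome),
    (exposure -> outcome total), plus the truth record. The exposure legs
    share the gene instrument set; the mediator leg uses the disjoint
    protein instrument set. The recorded true total effect is
    ``beta_direct + beta_em * beta_mo``.
    """
    rng = np.random.default_rng(cfg.seed)
    gseed, pseed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))

    # Gene instruments: effects b_j on expression; downstream true effects
    # on the mediator (b*beta_em) and the outcome (b*(direct + em*mo)).
    gcfg = cfg.gene_cfg
    gcfg.validate()
    grng = np.random.default_rng(gseed)
    kg = gcfg.n_variants
    gids = [f"{gcfg.id_prefix}{j:04d}" for j in range(kg)]
    gmaf = grng.uniform(gcfg.maf_range[0], gcfg.maf_range[1], size=kg)
    gb = grng.normal(gcfg.beta_gx_mean, gcfg.beta_gx_sd, size=kg)
    g_plain = grng.integers(0, len(_PLAIN_PAIRS), size=kg)
    galleles = [_PLAIN_PAIRS[c] for c in g_plain]
    no_flip = np.zeros(kg, dtype=bool)

    se_g_exp = _analytic_se(gmaf, gcfg.n_exposure)
    se_g_med = _analytic_se(gmaf, cfg.protein_cfg.n_exposure)
    se_g_out = _analytic_se(gmaf, cfg.n_outcome_gwas)
    beta_g_exp = grng.normal(gb, se_g_exp)
    beta_g_med = grng.normal(gb * cfg.beta_em, se_g_med)
    beta_g_out = grng.normal(gb * cfg.true_total, se_g_out)

    exp_on_gene = _records(gcfg, gids, galleles, gmaf, beta_g_exp, se_g_exp,
                           gcfg.n_exposure, no_flip)
    exp_on_med = _records(gcfg, gids, galleles, gmaf, beta_g_med, se_g_med,
                          cfg.protein_cfg.n_exposure, no_flip)
    exp_on_out = _records(gcfg, gids, galleles, gmaf, beta_g_out, se_g_out,
                          cfg.n_outcome_gwas, no_flip)

    gene_truth = PairTruth(
        theta=cfg.beta_em, b=gb, alpha=np.zeros(kg), variant_ids=gids,
        invalid_ids=[], palindromic_ids=[], flipped_ids=[], ambiguous_ids=[],
        config=gcfg,
    )

    # Protein instruments: effects c_j on the mediator; true outcome
    # effects c*beta_mo.
    pcfg = cfg.protein_cfg
    pcfg.validate()
    prng = np.random.default_rng(pseed)
    kp = pcfg.n_variants
    pids = [f"{pcfg.id_prefix}{j:04d}" for j in range(kp)]
    pmaf = prng.uniform(pcfg.maf_range[0], pcfg.maf_range[1], size=kp)
    pc = prng.normal(pcfg.beta_gx_mean, pcfg.beta_gx_sd, size=kp)
    p_plain = prng.integers(0, len(_PLAIN_PAIRS), size=kp)
    palleles = [_PLAIN_PAIRS[c] for c in p_plain]
    no_flip_p = np.zeros(kp, dtype=bool)

    se_p_med = _analytic_se(pmaf, pcfg.n_exposure)
    se_p_out = _analytic_se(pmaf, cfg.n_outcome_gwas)
    beta_p_med = prng.normal(pc, se_p_med)
    beta_p_out = prng.normal(pc * cfg.beta_mo, se_p_out)

    med_on_med = _records(pcfg, pids, palleles, pmaf, beta_p_med, se_p_med,
                          pcfg.n_exposure, no_flip_p)
    med_on_out = _records(pcfg, pids, palleles, pmaf, beta_p_out, se_p_out,
                          cfg.n_outcome_gwas, no_flip_p)

    protein_truth = PairTruth(
        theta=cfg.beta_mo, b=pc, alpha=np.zeros(kp), variant_ids=pids,
        invalid_ids=[], palindromic_ids=[], flipped_ids=[], ambiguous_ids=[],
        config=pcfg,
    )

    truth = MediationTruth(
        total=cfg.true_total,
        indirect=cfg.true_indirect,
        proportion=cfg.true_proportion,
        config=cfg,
        gene_truth=gene_truth,
        protein_truth=protein_truth,
    )
    return (
        (exp_on_gene, exp_on_med),
        (med_on_med, med_on_out),
        (exp_on_gene, exp_on_out),
        truth,
    )
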