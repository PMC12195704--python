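"""Instrumental-variable selection for cis-MR screens.

Four criteria, applied in order: minor-allele frequency, association
significance, cis-window plus LD clumping, and instrument strength.
All thresholds are strict inequalities (MAF > 0.01, p < 5e-8,
r² < 0.001, F > 10), so boundary values are excluded.

Clumping is greedy by ascending p-value — repeatedly take the most
significant unassigned variant as an index and discard everything
correlated with it (r² at or above the threshold) within the kb window.
Ties are broken by (chrom, pos, variant_id) so the result is
deterministic. Variants absent from the LD matrix are treated as
independent, with a warning in the audit trail: conservative for
survivorship, loud in the log.

Instrument strength uses the single-variant approximation
F = (beta/se)², i.e. the squared z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .exceptions import DataError
from .sumstats import GeneLocus, LDMatrix, VariantAssociation

__all__ = [
    "SelectionCriteria",
    "AuditEntry",
    "filter_maf",
    "filter_significance",
    "cis_filter",
    "clump",
    "f_statistic",
    "select_instruments",
]


@dataclass
class SelectionCriteria:
    """Thresholds for the four IV-selection criteria.

    ``cis_kb`` is the half-window around the gene body in kilobases; the
    screen runs it at 1000 (primary) and 100 (replication).
    """

    maf_min: float = 0.01
    p_max: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    cis_kb: float = 1000
    f_min: float = 10.0

    def __post_init__(self) -> None:
        for name in ("maf_min", "p_max", "clump_r2", "clump_kb", "cis_kb", "f_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AuditEntry:
    variant_id: str
    stage: str          # maf | significance | cis | clump | strength | selected
    reason: str


def filter_maf(
    variants: Sequence[VariantAssociation], maf_min: float = 0.01
) -> list[VariantAssociation]:
    """Keep variants with min(eaf, 1-eaf) strictly above ``maf_min``."""
    return [v for v in variants if v.maf > maf_min]


def filter_significance(
    variants: Sequence[VariantAssociation], p_max: float = 5e-8
) -> list[VariantAssociation]:
    """Keep variants with association p strictly below ``p_max``."""
    return [v for v in variants if v.pval < p_max]


def cis_filter(
    variants: Sequence[VariantAssociation], locus: GeneLocus, cis_kb: float = 1000
) -> list[VariantAssociation]:
    """Keep variants within ``cis_kb`` kilobases of the gene body (inclusive).

    Distance is measured from the nearer gene edge (start/end), not the
    TSS; the window is [start - cis_kb*1000, end + cis_kb*1000] on the
    gene's chromosome.
    """
    lo = locus.start - cis_kb * 1000
    hi = locus.end + cis_kb * 1000
    return [v for v in variants if v.chrom == locus.chrom and lo <= v.pos <= hi]


def f_statistic(v: VariantAssociation) -> float:
    """Single-variant instrument strength, F = (beta/se)²."""
    return (v.beta / v.se) ** 2


def clump(
    variants: Sequence[VariantAssociation],
    ld: LDMatrix | None,
    clump_r2: float = 0.001,
    clump_kb: float = 10_000,
) -> list[VariantAssociation]:
    """Greedy LD clumping: retain approximately independent index variants.

    Sort by ascending p (ties by chrom, pos, variant_id); repeatedly take
    the top unassigned variant as an index and remove unassigned variants
    with r² >= ``clump_r2`` against it lying within ``clump_kb`` kb.
    Index variants are returned in original input order. With ``ld`` None
    every variant is treated as independent and all survive.
    """
    if ld is None:
        return list(variants)
    missing = [v.variant_id for v in variants if v.variant_id not in ld]
    if missing:
        warnings.warn(
            f"{len(missing)} variant(s) absent from LD matrix treated as independent: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}",
            stacklevel=2,
        )
    order = sorted(
        range(len(variants)),
        key=lambda i: (variants[i].pval, variants[i].chrom, variants[i].pos,
                       variants[i].variant_id),
    )
    assigned: set[int] = set()
    index_set: set[int] = set()
    for i in order:
        if i in assigned:
            continue
        assigned.add(i)
        index_set.add(i)
        vi = variants[i]
        if vi.variant_id not in ld:
            continue
        for j in range(len(variants)):
            if j in assigned:
                continue
            vj = variants[j]
            if vj.variant_id not in ld:
                continue
            same_chrom = vi.chrom == vj.chrom
            within = same_chrom and abs(vi.pos - vj.pos) <= clump_kb * 1000
            if within and ld.lookup(vi.variant_id, vj.variant_id) >= clump_r2:
                assigned.add(j)
    return [v for i, v in enumerate(variants) if i in index_set]


def select_instruments(
    variants: Sequence[VariantAssociation],
    locus: GeneLocus,
    ld: LDMatrix | None,
    criteria: SelectionCriteria | None = None,
) -> tuple[list[VariantAssociation], list[AuditEntry]]:
    """Apply the four IV criteria in sequence; return survivors + audit trail.

    Stages run as MAF -> significance -> cis-window -> clumping ->
    strength. Every input variant appears exactly once in the audit
    trail, either with its exclusion stage and reason or as selected.
    Zero survivors is a valid outcome (the caller decides how to treat a
    gene with no instruments), not an error.
    """
    crit = criteria or SelectionCriteria()
    audit: list[AuditEntry] = []
    current = list(variants)

    def exclude(stage: str, dropped: Sequence[VariantAssociation], reason_fmt) -> None:
        for v in dropped:
            audit.append(AuditEntry(v.variant_id, stage, reason_fmt(v)))

    kept = filter_maf(current, crit.maf_min)
    exclude("maf", [v for v in current if v not in kept],
            lambda v: f"MAF {v.maf:.4g} <= {crit.maf_min}")
    current = kept

    kept = filter_significance(current, crit.p_max)
    exclude("significance", [v for v in current if v not in kept],
            lambda v: f"p {v.pval:.3g} >= {crit.p_max}")
    current = kept

    kept = cis_filter(current, locus, crit.cis_kb)
    exclude("cis", [v for v in current if v not in kept],
            lambda v: f"outside {crit.cis_kb:g} kb cis-window of {locus.symbol}")
    current = kept

    kept = clump(current, ld, crit.clump_r2, crit.clump_kb)
    kept_ids = {v.variant_id for v in kept}
    exclude("clump", [v for v in current if v.variant_id not in kept_ids],
            lambda v: f"in LD (r² >= {crit.clump_r2}) with a more significant index variant")
    current = kept

    kept = [v for v in current if f_statistic(v) > crit.f_min]
    exclude("strength", [v for v in current if f_statistic(v) <= crit.f_min],
            lambda v: f"F {f_statistic(v):.3g} <= {crit.f_min}")
    current = kept

    for v in current:
        audit.append(AuditEntry(v.variant_id, "selected", "passed all criteria"))
    return current, audit
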