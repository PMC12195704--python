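"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR needs the exposure and outcome effects of each variant
expressed on the same effect allele. Four situations arise:

* same allele pair, same orientation — nothing to do;
* effect/other swapped between the studies — negate the outcome beta and
  mirror its frequency;
* the outcome study reports the opposite strand — map alleles through
  the A<->T / C<->G complement, then apply the two cases above;
* palindromic variants (A/T or C/G), where strand cannot be resolved
  from alleles at all — orientation is inferred from allele frequencies,
  and variants whose minor-allele frequency in either study falls inside
  the open band (0.42, 0.58) are dropped as unresolvable.

Every pair records the action taken; the magnitude of the outcome beta
is never changed, only its sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .exceptions import DataError
from .sumstats import VariantAssociation

__all__ = [
    "Action",
    "HarmonizedPair",
    "HarmonizeReport",
    "complement_pair",
    "harmonize",
]

#: MAF band (open at both ends) within which a palindromic variant is
#: ambiguous and must be dropped.
AMBIGUOUS_BAND = (0.42, 0.58)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class Action(str, Enum):
    AS_IS = "as_is"
    CODING_FLIPPED = "coding_flipped"
    STRAND_FLIPPED = "strand_flipped"
    STRAND_AND_CODING_FLIPPED = "strand_and_coding_flipped"


@dataclass
class HarmonizedPair:
    """Exposure and outcome effects of one variant on a shared effect allele."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    eaf_out: float
    action: Action
    # carried through for directionality testing; optional otherwise
    n_exp: float | None = None
    n_out: float | None = None
    pval_exp: float | None = None
    pval_out: float | None = None


@dataclass
class HarmonizeReport:
    """Disposition counts over the union of variant ids in the two studies."""

    n_input: int = 0
    n_harmonized: int = 0
    n_palindromic_dropped: int = 0
    n_incompatible_dropped: int = 0
    n_single_study: int = 0
    dispositions: dict[str, str] = field(default_factory=dict)

    def check(self) -> None:
        total = (self.n_harmonized + self.n_palindromic_dropped
                 + self.n_incompatible_dropped + self.n_single_study)
        assert total == self.n_input, "report counts do not sum to n_input"


def complement_pair(effect_allele: str, other_allele: str) -> tuple[str, str]:
    """Map an allele pair to the opposite strand (A<->T, C<->G, positionally)."""
    return _COMPLEMENT[effect_allele.upper()], _COMPLEMENT[other_allele.upper()]


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def _in_band(eaf: float) -> bool:
    lo, hi = AMBIGUOUS_BAND
    return lo < min(eaf, 1.0 - eaf) < hi


def _index_unique(variants: Sequence[VariantAssociation], label: str):
    idx: dict[str, VariantAssociation] = {}
    for v in variants:
        if v.variant_id in idx:
            raise DataError(f"duplicate variant_id {v.variant_id!r} in {label} study")
        idx[v.variant_id] = v
    return idx


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    drop_all_palindromic: bool = False,
) -> tuple[list[HarmonizedPair], HarmonizeReport]:
    """Align outcome effects to the exposure's effect allele, variant by variant.

    Pairs are produced for variants present in both studies, in exposure
    order. Palindromic variants are oriented by matching minor alleles
    across the studies unless either study's MAF lies in the ambiguous
    band (0.42, 0.58), in which case they are dropped;
    ``drop_all_palindromic=True`` drops every palindrome regardless.
    Duplicated variant ids within a study raise :class:`DataError`.
    """
    exp_idx = _index_unique(exposure, "exposure")
    out_idx = _index_unique(outcome, "outcome")

    report = HarmonizeReport()
    all_ids = set(exp_idx) | set(out_idx)
    report.n_input = len(all_ids)

    pairs: list[HarmonizedPair] = []
    for vid in all_ids - (set(exp_idx) & set(out_idx)):
        report.n_single_study += 1
        report.dispositions[vid] = "single_study"

    for v_exp in exposure:
        vid = v_exp.variant_id
        v_out = out_idx.get(vid)
        if v_out is None:
            continue
        result = _harmonize_one(v_exp, v_out, drop_all_palindromic)
        if isinstance(result, str):
            if result.startswith("palindromic"):
                report.n_palindromic_dropped += 1
            else:
                report.n_incompatible_dropped += 1
            report.dispositions[vid] = result
        else:
            report.n_harmonized += 1
            report.dispositions[vid] = result.action.value
            pairs.append(result)
    report.check()
    return pairs, report


def _pair(v_exp, v_out, beta_out, eaf_out, action) -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=v_exp.variant_id,
        effect_allele=v_exp.effect_allele,
        other_allele=v_exp.other_allele,
        beta_exp=v_exp.beta,
        se_exp=v_exp.se,
        beta_out=beta_out,
        se_out=v_out.se,
        eaf_exp=v_exp.eaf,
        eaf_out=eaf_out,
        action=action,
        n_exp=v_exp.n,
        n_out=v_out.n,
        pval_exp=v_exp.pval,
        pval_out=v_out.pval,
    )


def _harmonize_one(
    v_exp: VariantAssociation, v_out: VariantAssociation, drop_all_palindromic: bool
) -> HarmonizedPair | str:
    ea_e, oa_e = v_exp.effect_allele, v_exp.other_allele
    ea_o, oa_o = v_out.effect_allele, v_out.other_allele

    if _is_palindromic(ea_e, oa_e) or _is_palindromic(ea_o, oa_o):
        if {ea_e, oa_e} != {ea_o, oa_o}:
            return "incompatible: palindromic vs non-palindromic allele sets"
        if drop_all_palindromic:
            return "palindromic: dropped by policy"
        if _in_band(v_exp.eaf) or _in_band(v_out.eaf):
            return "palindromic: ambiguous frequency"
        # Orient by frequency: does the outcome effect-allele frequency
        # look like eaf_exp (aligned) or 1 - eaf_exp (flipped)? For a
        # palindrome the allele labels cannot distinguish a coding swap
        # from a strand flip, so frequency decides; labels then only
        # refine the recorded action.
        aligned_by_freq = abs(v_out.eaf - v_exp.eaf) <= abs(v_out.eaf - (1.0 - v_exp.eaf))
        labels_match = ea_o == ea_e
        if aligned_by_freq:
            action = Action.AS_IS if labels_match else Action.STRAND_FLIPPED
            return _pair(v_exp, v_out, v_out.beta, v_out.eaf, action)
        action = Action.CODING_FLIPPED if not labels_match else Action.STRAND_AND_CODING_FLIPPED
        return _pair(v_exp, v_out, -v_out.beta, 1.0 - v_out.eaf, action)

    if (ea_o, oa_o) == (ea_e, oa_e):
        return _pair(v_exp, v_out, v_out.beta, v_out.eaf, Action.AS_IS)
    if (ea_o, oa_o) == (oa_e, ea_e):
        return _pair(v_exp, v_out, -v_out.beta, 1.0 - v_out.eaf, Action.CODING_FLIPPED)

    comp = complement_pair(ea_o, oa_o)
    if comp == (ea_e, oa_e):
        return _pair(v_exp, v_out, v_out.beta, v_out.eaf, Action.STRAND_FLIPPED)
    if comp == (oa_e, ea_e):
        return _pair(v_exp, v_out, -v_out.beta, 1.0 - v_out.eaf,
                     Action.STRAND_AND_CODING_FLIPPED)
    return "incompatible: allele sets cannot be reconciled"
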