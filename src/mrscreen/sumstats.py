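"""Core data model and I/O for GWAS/eQTL/pQTL summary statistics.

The in-memory unit is :class:`VariantAssociation`: one biallelic SNP's
additive association with one trait in one study (effect/other allele,
effect-allele frequency, beta, standard error, p-value, sample size).
Betas are stored exactly as supplied — log-odds for binary traits, SD
units for quantitative traits; the scale is study metadata, not part of
the record.

File formats are deliberately plain: tab-separated tables with a header.
Canonical summary-statistics columns are ``SNP CHR POS EA OA EAF BETA SE
P N``; arbitrary headers are supported through a column map. Genomic
coordinates are 1-based and inclusive throughout the package.

Odds-ratio utilities (``beta_from_or`` / ``or_from_beta`` /
``pvalue_from_or_ci``) convert between the reporting convention of
published association tables (OR with a 95% CI) and the (beta, se) scale
every estimator works on. The 97.5% normal quantile is fixed at
1.959964 so the two directions are exact inverses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DataError, DomainError

__all__ = [
    "VariantAssociation",
    "GeneLocus",
    "LDMatrix",
    "EffectWithCI",
    "RowReject",
    "Z_975",
    "VALID_BASES",
    "beta_from_or",
    "or_from_beta",
    "pvalue_from_or_ci",
    "normal_pvalue",
    "check_consistency",
    "read_sumstats",
    "write_sumstats",
    "read_gene_loci",
    "write_gene_loci",
    "read_ld_matrix",
    "write_ld_matrix",
    "variants_to_frame",
]

#: 97.5% standard-normal quantile used for all 95% confidence intervals.
#: Fixed at six decimals (not 1.96) so OR <-> beta round-trips are exact.
Z_975 = 1.959964

VALID_BASES = frozenset("ACGT")

#: Canonical summary-statistics header, field name -> column name.
CANONICAL_COLUMNS = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

# p-values are clipped into (0, 1]; 2*sf underflows near |z| ~ 38.
_P_FLOOR = 1e-300


def normal_pvalue(beta: float, se: float) -> float:
    """Two-sided p-value of beta/se under the standard normal.

    Returns 1.0 for a zero effect and 0.0 (with no warning here) for a
    degenerate se of 0 with a nonzero beta; callers that need a warning
    wrap this.
    """
    if beta == 0:
        return 1.0
    if se == 0:
        return 0.0
    return float(max(2.0 * stats.norm.sf(abs(beta) / se), _P_FLOOR))


@dataclass
class VariantAssociation:
    """One variant's summary association in one study."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    def __post_init__(self) -> None:
        self.effect_allele = self.effect_allele.upper()
        self.other_allele = self.other_allele.upper()
        self.chrom = str(self.chrom)
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise DataError(
                f"{self.variant_id}: alleles must be single bases in ACGT, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise DataError(f"{self.variant_id}: effect and other allele are identical")
        if not 0.0 <= self.eaf <= 1.0:
            raise DataError(f"{self.variant_id}: eaf {self.eaf} outside [0, 1]")
        if not self.se > 0:
            raise DataError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not 0.0 < self.pval <= 1.0:
            raise DataError(f"{self.variant_id}: pval {self.pval} outside (0, 1]")
        if not self.n > 0:
            raise DataError(f"{self.variant_id}: n must be > 0, got {self.n}")

    @property
    def maf(self) -> float:
        """Minor-allele frequency, min(eaf, 1 - eaf)."""
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is ambiguous."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


def check_consistency(v: VariantAssociation, rel_tol: float = 0.2) -> bool:
    """Flag whether the supplied p-value agrees with beta/se.

    Consortium files routinely round p-values, so disagreement is a
    validator flag, never a hard error. Returns True when the recomputed
    two-sided normal p is within ``rel_tol`` relative of the stored one.
    """
    p_calc = normal_pvalue(v.beta, v.se)
    if v.pval <= _P_FLOOR * 10 and p_calc <= _P_FLOOR * 10:
        return True
    return abs(p_calc - v.pval) <= rel_tol * v.pval


@dataclass
class GeneLocus:
    """A gene's genomic footprint (1-based, inclusive on both ends)."""

    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        self.chrom = str(self.chrom)
        if self.start > self.end:
            raise DataError(f"{self.symbol}: start {self.start} > end {self.end}")


@dataclass
class LDMatrix:
    """Pairwise squared-correlation (r²) matrix over named variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise DataError(f"LD matrix shape {self.r2.shape} does not match {k} ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise DataError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise DataError("LD matrix diagonal must be exactly 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise DataError("LD r² values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != k:
            raise DataError("duplicate variant ids in LD matrix")

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])


@dataclass
class EffectWithCI:
    """An odds ratio with its 95% confidence interval, as papers print it."""

    or_value: float
    ci_lower: float
    ci_upper: float
    pval: float | None = None

    def __post_init__(self) -> None:
        if min(self.or_value, self.ci_lower, self.ci_upper) <= 0:
            raise DomainError("odds ratio and CI bounds must be positive")
        if not self.ci_lower <= self.or_value <= self.ci_upper:
            raise DomainError(
                f"CI ({self.ci_lower}, {self.ci_upper}) does not bracket OR {self.or_value}"
            )


def beta_from_or(e: EffectWithCI) -> tuple[float, float]:
    """Log-odds effect and its standard error from an OR with 95% CI.

    beta = ln(OR); se = (ln(upper) - ln(lower)) / (2 * z_0.975).
    """
    beta = math.log(e.or_value)
    se = (math.log(e.ci_upper) - math.log(e.ci_lower)) / (2.0 * Z_975)
    return beta, se


def or_from_beta(beta: float, se: float) -> EffectWithCI:
    """Odds ratio with 95% CI from a log-odds beta and se; inverse of beta_from_or."""
    if se < 0:
        raise DomainError(f"se must be >= 0, got {se}")
    half = Z_975 * se
    return EffectWithCI(
        or_value=math.exp(beta),
        ci_lower=math.exp(beta - half),
        ci_upper=math.exp(beta + half),
        pval=normal_pvalue(beta, se) if se > 0 else None,
    )


def pvalue_from_or_ci(e: EffectWithCI) -> float:
    """Two-sided normal p-value recomputed from a printed OR and 95% CI.

    Lets a reader audit a published association table: the p implied by
    the interval should agree with the printed p up to CI rounding.
    A degenerate CI (zero width) with a non-unit OR yields p = 0 with a
    warning, since the interval claims infinite precision.
    """
    beta, se = beta_from_or(e)
    if se == 0 and beta != 0:
        import warnings

        warnings.warn("degenerate CI (zero width) with nonzero effect; p = 0", stacklevel=2)
        return 0.0
    return normal_pvalue(beta, se)


class RowReject(NamedTuple):
    """A data row dropped at parse time, with its 1-based file line number."""

    line: int
    variant_id: str
    reason: str


def _resolve_columns(header: Sequence[str], column_map: dict[str, str] | None) -> dict[str, str]:
    colmap = dict(CANONICAL_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(CANONICAL_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown field(s) in column map: {sorted(unknown)}")
        colmap.update(column_map)
    missing = [col for col in colmap.values() if col not in header]
    if missing:
        raise ConfigurationError(f"missing mandatory column(s): {missing}")
    return colmap


def read_sumstats(
    path: str | Path, column_map: dict[str, str] | None = None
) -> tuple[list[VariantAssociation], list[RowReject]]:
    """Read a tab-separated summary-statistics table.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Optional mapping from field names (``variant_id``, ``chrom``,
        ``pos``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``,
        ``se``, ``pval``, ``n``) to the column names used in the file.
        Unmapped fields fall back to the canonical header.

    Returns
    -------
    (records, rejects)
        Valid records in file order, plus one :class:`RowReject` per row
        that failed type coercion or the record invariants (indels and
        multi-allelic rows are rejected here: the pipeline is biallelic
        SNPs only). Line numbers are 1-based counting the header line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = _resolve_columns(df.columns, column_map)

    records: list[VariantAssociation] = []
    rejects: list[RowReject] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        raw = {f: row[df.columns.get_loc(c)] for f, c in colmap.items()}
        vid = raw["variant_id"]
        try:
            rec = VariantAssociation(
                variant_id=vid,
                chrom=raw["chrom"],
                pos=int(raw["pos"]),
                effect_allele=raw["effect_allele"],
                other_allele=raw["other_allele"],
                eaf=float(raw["eaf"]),
                beta=float(raw["beta"]),
                se=float(raw["se"]),
                pval=float(raw["pval"]),
                n=float(raw["n"]),
            )
        except (ValueError, DataError) as exc:
            rejects.append(RowReject(line=line, variant_id=vid, reason=str(exc)))
            continue
        records.append(rec)
    return records, rejects


def variants_to_frame(variants: Sequence[VariantAssociation]) -> pd.DataFrame:
    """Summary-statistics records as a DataFrame with canonical columns."""
    return pd.DataFrame(
        {
            col: [getattr(v, f) for v in variants]
            for f, col in CANONICAL_COLUMNS.items()
        }
    )


def write_sumstats(variants: Sequence[VariantAssociation], path: str | Path) -> None:
    """Write records as a canonical-column TSV (floats at 12 significant digits)."""
    variants_to_frame(variants).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_gene_loci(path: str | Path) -> list[GeneLocus]:
    """Read a 4-column gene-locus TSV (SYMBOL, CHR, START, END)."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = [c for c in ("SYMBOL", "CHR", "START", "END") if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing mandatory column(s): {missing}")
    return [
        GeneLocus(symbol=r.SYMBOL, chrom=str(r.CHR), start=int(r.START), end=int(r.END))
        for r in df.itertuples(index=False)
    ]


def write_gene_loci(loci: Sequence[GeneLocus], path: str | Path) -> None:
    pd.DataFrame(
        {
            "SYMBOL": [g.symbol for g in loci],
            "CHR": [g.chrom for g in loci],
            "START": [g.start for g in loci],
            "END": [g.end for g in loci],
        }
    ).to_csv(path, sep="\t", index=False)


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square r² TSV with variant ids as header row and first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise DataError("LD matrix row ids do not match column ids")
    return LDMatrix(variant_ids=ids, r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )
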