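"""Gene-set screening, PheWAS Bonferroni scanning, and the pipeline driver.

``screen_gene_set`` runs the full per-gene cis-MR battery at two cis
windows (primary 1 MB, replication 100 KB): instrument selection,
harmonization against the outcome GWAS, estimation (Wald ratio for a
single instrument, fixed+random IVW for several, cML-MA from three up)
and the directionality test. A gene replicates when its 100 KB estimate
is significant with the same sign as its 1 MB estimate.

``phewas_scan`` is the multiplicity scan: a Bonferroni threshold
alpha / n_phenotypes across a phenome-wide table of p-values.

``run_pipeline`` wires the stages together from a YAML/dict config —
including a fully self-contained mode where all summary statistics come
from the synthetic generator — and writes deterministic TSV/JSON
outputs plus a run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import DirectionalityResult, MREstimate
from .exceptions import ConfigurationError
from .harmonize import harmonize
from .instruments import SelectionCriteria, select_instruments
from .mediation import MediationResult, two_step_mediation
from .model import MRModel
from .simulate import MediationConfig, SimulationConfig, simulate_ld, simulate_mediation, simulate_pair
from .sumstats import (
    GeneLocus,
    LDMatrix,
    VariantAssociation,
    read_gene_loci,
    read_ld_matrix,
    read_sumstats,
    write_sumstats,
)

__all__ = ["ScreenRow", "PhewasRow", "screen_gene_set", "phewas_scan", "run_pipeline"]


@dataclass
class ScreenRow:
    """One gene x cis-window x method line of the screen table."""

    gene: str
    cis_kb: float
    method: str                     # estimator tag, or "none" for empty/error rows
    estimate: MREstimate | None
    directionality: DirectionalityResult | None
    replicated_100kb: bool = False
    notes: str = ""


@dataclass
class PhewasRow:
    phenotype: str
    category: str
    pval: float
    significant: bool


def _estimates_for(model: MRModel) -> list[tuple[str, MREstimate]]:
    if model.nsnp == 1:
        return [("wald", model.fit("wald").estimate)]
    out = [
        ("ivw_fixed", model.fit("ivw_fixed").estimate),
        ("ivw_random", model.fit("ivw_random").estimate),
    ]
    if model.nsnp >= 3:
        out.append(("cml_ma", model.fit("cml_ma").estimate))
    return out


def _primary(rows: Sequence[ScreenRow]) -> MREstimate | None:
    """The headline estimate of a window: Wald if single-IV, else random IVW."""
    for tag in ("ivw_random", "wald"):
        for r in rows:
            if r.method == tag and r.estimate is not None:
                return r.estimate
    return None


def screen_gene_set(
    genes: Sequence[str],
    exposure_by_gene: Mapping[str, Sequence[VariantAssociation]],
    outcome: Sequence[VariantAssociation],
    loci: Mapping[str, GeneLocus],
    ld: LDMatrix | None = None,
    criteria: SelectionCriteria | None = None,
    cis_windows_kb: Sequence[float] = (1000, 100),
) -> list[ScreenRow]:
    """Screen a gene set for causal association with the outcome.

    For each gene and cis window: select instruments from the gene's
    exposure summary statistics, harmonize against the outcome, fit the
    applicable estimators and run the directionality test. Genes with a
    missing locus yield an error row; genes with zero surviving
    instruments yield a "no instruments" row — the screen never aborts
    on a single gene.
    """
    base = criteria or SelectionCriteria()
    all_rows: list[ScreenRow] = []
    for gene in genes:
        per_window: dict[float, list[ScreenRow]] = {}
        for cis_kb in cis_windows_kb:
            rows: list[ScreenRow] = []
            locus = loci.get(gene)
            if locus is None:
                rows.append(ScreenRow(gene, cis_kb, "none", None, None,
                                      notes="error: no locus for gene"))
                per_window[cis_kb] = rows
                continue
            exposure = exposure_by_gene.get(gene, [])
            crit = dataclasses.replace(base, cis_kb=cis_kb)
            instruments, _ = select_instruments(exposure, locus, ld, crit)
            if not instruments:
                rows.append(ScreenRow(gene, cis_kb, "none", None, None,
                                      notes="no instruments"))
                per_window[cis_kb] = rows
                continue
            pairs, _ = harmonize(instruments, outcome)
            if not pairs:
                rows.append(ScreenRow(gene, cis_kb, "none", None, None,
                                      notes="no instruments after harmonization"))
                per_window[cis_kb] = rows
                continue
            model = MRModel(pairs)
            direction = model.directionality()
            for tag, estimate in _estimates_for(model):
                rows.append(ScreenRow(gene, cis_kb, tag, estimate, direction))
            per_window[cis_kb] = rows

        # replication: 100 KB estimate significant with the 1 MB sign
        if 1000 in per_window and 100 in per_window:
            e_wide = _primary(per_window[1000])
            e_narrow = _primary(per_window[100])
            replicated = (
                e_wide is not None
                and e_narrow is not None
                and e_narrow.pval < 0.05
                and np.sign(e_narrow.beta) == np.sign(e_wide.beta)
            )
            for rows in per_window.values():
                for r in rows:
                    r.replicated_100kb = bool(replicated)
        for cis_kb in cis_windows_kb:
            all_rows.extend(per_window[cis_kb])
    return all_rows


def screen_to_frame(rows: Sequence[ScreenRow]) -> pd.DataFrame:
    records = []
    for r in rows:
        e = r.estimate
        records.append(
            {
                "gene": r.gene,
                "cis_kb": r.cis_kb,
                "method": r.method,
                "nsnp": e.nsnp if e else 0,
                "beta": e.beta if e else np.nan,
                "se": e.se if e else np.nan,
                "pval": e.pval if e else np.nan,
                "or": e.or_ci.or_value if e else np.nan,
                "or_lo": e.or_ci.ci_lower if e else np.nan,
                "or_hi": e.or_ci.ci_upper if e else np.nan,
                "direction_ok": r.directionality.direction_ok if r.directionality else None,
                "steiger_p": r.directionality.steiger_p if r.directionality else np.nan,
                "replicated_100kb": r.replicated_100kb,
                "notes": r.notes,
            }
        )
    return pd.DataFrame(records)


def phewas_scan(
    rows: Sequence[tuple[str, str, float]], alpha: float = 0.05
) -> tuple[list[PhewasRow], dict]:
    """Bonferroni scan across a phenome-wide association table.

    ``rows`` are (phenotype, category, pval) triples. The significance
    threshold is alpha / n_phenotypes; output rows are sorted by
    ascending p. The summary counts significant hits per category.
    """
    if not rows:
        warnings.warn("phewas_scan called with no rows", stacklevel=2)
        return [], {"n_phenotypes": 0, "threshold": None, "n_significant": 0,
                    "per_category": {}}
    threshold = alpha / len(rows)
    out = sorted(
        (
            PhewasRow(phenotype=p, category=c, pval=float(v),
                      significant=bool(float(v) < threshold))
            for p, c, v in rows
        ),
        key=lambda r: (r.pval, r.phenotype),
    )
    per_cat: dict[str, int] = {}
    for r in out:
        if r.significant:
            per_cat[r.category] = per_cat.get(r.category, 0) + 1
    summary = {
        "n_phenotypes": len(out),
        "threshold": threshold,
        "n_significant": sum(r.significant for r in out),
        "per_category": per_cat,
        "min_p": out[0].pval,
        "top_phenotype": out[0].phenotype,
    }
    return out, summary


_PHEWAS_CATEGORIES = [
    "circulatory", "dermatological", "digestive", "endocrine", "genitourinary",
    "hematopoietic", "mental", "musculoskeletal", "neoplasms", "nervous",
    "respiratory", "sense organs",
]


def _simulate_phewas_rows(n: int, seed: int) -> list[tuple[str, str, float]]:
    """Null phenome: uniform p-values across the 12 category labels."""
    rng = np.random.default_rng(seed)
    pvals = rng.uniform(0.0, 1.0, size=n)
    return [
        (f"phenotype_{i:05d}", _PHEWAS_CATEGORIES[i % len(_PHEWAS_CATEGORIES)], float(p))
        for i, p in enumerate(pvals)
    ]


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


_STAGE_ALIASES = {"select": "screen", "harmonize": "screen", "estimate": "screen",
                  "screen": "screen", "mediate": "mediate", "phewas": "phewas"}


def run_pipeline(config, outdir: str | Path | None = None) -> dict:
    """Run the configured stages end to end; deterministic under the seed.

    ``config`` is a dict or YAML path. Top-level keys:

    * ``seed`` — master seed; every stage derives its own stream from it.
    * ``stages`` — subset of {screen, mediate, phewas} (selection,
      harmonization and estimation are all part of ``screen``).
    * ``simulate`` — self-contained mode: ``genes`` maps each gene symbol
      to :class:`~mrscreen.simulate.SimulationConfig` overrides, and the
      generator supplies exposure/outcome summary statistics plus loci.
    * ``inputs`` — file mode: paths for ``outcome``, ``loci``, optional
      ``ld``, and per-gene ``exposure`` TSVs.
    * ``criteria`` — :class:`SelectionCriteria` overrides.
    * ``mediation`` — :class:`MediationConfig` field overrides.
    * ``phewas`` — ``n_phenotypes`` (and optional ``alpha``).

    Writes ``screen.tsv``, ``mediation.tsv``, ``phewas.tsv`` and
    ``manifest.json`` into ``outdir`` and returns the output bundle as a
    dict of DataFrames/objects. Outputs are byte-identical across
    repeated runs with the same config and seed.
    """
    cfg = _load_config(config)
    outdir = Path(outdir or cfg.get("outdir", "mrscreen_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = {(_STAGE_ALIASES.get(s) or s) for s in cfg.get("stages", ["screen"])}
    unknown = stages - {"screen", "mediate", "phewas"}
    if unknown:
        raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")

    bundle: dict = {}
    manifest: dict = {
        "package": "mrscreen",
        "seed": seed,
        "stages": sorted(stages),
        "criteria": dataclasses.asdict(
            SelectionCriteria(**cfg.get("criteria", {}))
        ),
        "completed": [],
    }

    if "screen" in stages:
        crit = SelectionCriteria(**cfg.get("criteria", {}))
        if "simulate" in cfg:
            exposure_by_gene, outcome, loci, ld = _simulated_screen_inputs(cfg, seed)
        elif "inputs" in cfg:
            exposure_by_gene, outcome, loci, ld = _file_screen_inputs(cfg["inputs"])
        else:
            raise ConfigurationError("screen stage needs a 'simulate' or 'inputs' block")
        rows = screen_gene_set(
            sorted(exposure_by_gene), exposure_by_gene, outcome, loci, ld, crit
        )
        frame = screen_to_frame(rows)
        frame.to_csv(outdir / "screen.tsv", sep="\t", index=False, float_format="%.10g")
        bundle["screen"] = frame
        manifest["completed"].append("screen")
        manifest["n_screen_rows"] = len(frame)

    if "mediate" in stages:
        med_over = dict(cfg.get("mediation", {}))
        gene_over = med_over.pop("gene_cfg", {})
        prot_over = med_over.pop("protein_cfg", {})
        mcfg = MediationConfig(**med_over)
        mcfg.gene_cfg = dataclasses.replace(mcfg.gene_cfg, **gene_over)
        mcfg.protein_cfg = dataclasses.replace(mcfg.protein_cfg, **prot_over)
        mcfg.seed = seed + 1
        (em_e, em_o), (mo_e, mo_o), (tot_e, tot_o), truth = simulate_mediation(mcfg)
        em_pairs, _ = harmonize(em_e, em_o)
        mo_pairs, _ = harmonize(mo_e, mo_o)
        tot_pairs, _ = harmonize(tot_e, tot_o)
        results = [
            two_step_mediation(tot_pairs, em_pairs, mo_pairs, method=m,
                               n_boot=int(cfg.get("n_boot", 1000)), seed=seed + 2,
                               exposure="gene", mediator="protein")
            for m in ("ivw", "cml_ma")
        ]
        frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
        frame.to_csv(outdir / "mediation.tsv", sep="\t", index=False,
                     float_format="%.10g")
        bundle["mediation"] = results
        manifest["completed"].append("mediate")
        manifest["true_mediation_proportion_pct"] = truth.proportion

    if "phewas" in stages:
        pcfg = cfg.get("phewas", {})
        n = int(pcfg.get("n_phenotypes", 11_958))
        alpha = float(pcfg.get("alpha", 0.05))
        rows = _simulate_phewas_rows(n, seed + 3)
        scan, summary = phewas_scan(rows, alpha)
        frame = pd.DataFrame([dataclasses.asdict(r) for r in scan])
        frame.to_csv(outdir / "phewas.tsv", sep="\t", index=False,
                     float_format="%.10g")
        bundle["phewas"] = frame
        bundle["phewas_summary"] = summary
        manifest["completed"].append("phewas")
        manifest["phewas"] = {k: summary[k] for k in
                              ("n_phenotypes", "threshold", "n_significant")}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    bundle["manifest"] = manifest
    return bundle


def _simulated_screen_inputs(cfg: dict, seed: int):
    """Generator-backed inputs for the screen stage (self-contained mode)."""
    sim = cfg["simulate"]
    genes = sim.get("genes", {"GENE1": {}})
    exposure_by_gene: dict[str, list[VariantAssociation]] = {}
    outcome: list[VariantAssociation] = []
    loci: dict[str, GeneLocus] = {}
    ld = None
    for i, (gene, overrides) in enumerate(sorted(genes.items())):
        scfg = SimulationConfig(**{"chrom": str(i + 1), "id_prefix": f"g{i}snp",
                                   **overrides, "seed": seed * 1000 + i})
        exp, out, _ = simulate_pair(scfg)
        exposure_by_gene[gene] = exp
        outcome.extend(out)
        span = (scfg.n_variants - 1) * scfg.pos_spacing
        loci[gene] = GeneLocus(symbol=gene, chrom=scfg.chrom,
                               start=scfg.pos_start, end=scfg.pos_start + span)
        if scfg.ld_block is not None:
            block_ld = simulate_ld(scfg)
            ld = block_ld if ld is None else _merge_ld(ld, block_ld)
    return exposure_by_gene, outcome, loci, ld


def _merge_ld(a: LDMatrix, b: LDMatrix) -> LDMatrix:
    ka, kb = len(a.variant_ids), len(b.variant_ids)
    mat = np.zeros((ka + kb, ka + kb))
    mat[:ka, :ka] = a.r2
    mat[ka:, ka:] = b.r2
    return LDMatrix(variant_ids=a.variant_ids + b.variant_ids, r2=mat)


def _file_screen_inputs(inputs: dict):
    outcome, rejects = read_sumstats(inputs["outcome"],
                                     inputs.get("outcome_columns"))
    if rejects:
        warnings.warn(f"outcome file: {len(rejects)} row(s) rejected", stacklevel=2)
    loci = {g.symbol: g for g in read_gene_loci(inputs["loci"])}
    ld = read_ld_matrix(inputs["ld"]) if inputs.get("ld") else None
    exposure_by_gene = {}
    for gene, path in inputs["exposure"].items():
        records, rej = read_sumstats(path, inputs.get("exposure_columns"))
        if rej:
            warnings.warn(f"{gene} exposure: {len(rej)} row(s) rejected", stacklevel=2)
        exposure_by_gene[gene] = records
    return exposure_by_gene, outcome, loci, ld
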