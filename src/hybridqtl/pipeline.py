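"""End-to-end orchestration: simulate -> ls-means -> QC -> origins -> scan ->
multilocus fit -> R2 / cross-validation -> cross-model comparison."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .analysis import cross_validate, match_qtl, r2_summary
from .datatypes import GeneticMap, HybridPedigree, LineGenotypes
from .design import MODELS, base_fixed_matrix, build_population_design
from .lsmeans import fit_lsmeans
from .origins import expected_dosage_imputation, hybrid_founder_probs, origin_posteriors
from .qc import filter_lines, filter_markers, polymorphic_in_both_groups
from .scan import (
    build_model_designs,
    effective_marker_count,
    forward_backward_select,
    genomewide_threshold,
    single_marker_scan,
)

log = logging.getLogger("hybridqtl")


@dataclass
class RunConfig:
    geno: str | None = None
    map: str | None = None
    pedigree: str | None = None
    phenotypes: str | None = None
    founders: str | None = None  # founder genotype TSV (line_id/group/population + markers)
    models: tuple[str, ...] = MODELS
    alpha_genomewide: float = 0.05
    alpha_individual: float = 0.05
    meff_cutoff: float = 0.995
    genotyping_error_rate: float = 1e-3
    cv_train_fraction: float = 0.8
    cv_samplings: int = 100
    exclude_environments: tuple = ()  # per-trait list, dropped before ls-means
    vc_mode: str = "reestimate"
    run_selection: bool = True  # forward/backward multilocus fit after the scan
    run_cv: bool = True
    seed: int = 0

    def validate(self) -> None:
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model tag {m!r}; choose from {MODELS}")
        for name in ("alpha_genomewide", "alpha_individual", "meff_cutoff", "cv_train_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def _founder_genotypes_from_lines(founder_lines: LineGenotypes):
    """Interpret a founder genotype table (rows D1..D4,F1..F4) as FounderGenotypes."""
    from .datatypes import FounderGenotypes

    order = np.argsort(
        [0 if g == "D" else 1 for g in founder_lines.info["group"]], kind="stable"
    )
    d = founder_lines.dosage[order]
    if np.any(d == 0.5):
        raise ValueError("founder lines must be fully homozygous")
    return FounderGenotypes(
        d,
        list(founder_lines.info["line_id"].to_numpy()[order]),
        founder_lines.info["group"].to_numpy()[order],
        founder_lines.markers,
    )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run QC, origin inference, all requested scans and summaries.

    Writes TSV/JSON artifacts under ``out_dir`` and returns the summary
    dictionary (also written as summary.json).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    gmap = hio.read_map(config.map)
    lines = hio.read_genotypes(config.geno)
    lines, gmap = hio.reconcile_markers(lines, gmap)
    pedigree = hio.read_pedigree(config.pedigree)
    plots = hio.read_phenotypes(config.phenotypes)
    founders = _founder_genotypes_from_lines(
        hio.read_genotypes(config.founders)
    ) if config.founders else None

    summary: dict = {"seed": config.seed, "stages": {}}

    # phenotype adjustment
    ls = fit_lsmeans(plots, exclude_environments=tuple(config.exclude_environments))
    ls.table.to_csv(out / "lsmeans.tsv", sep="\t", index=False)
    summary["stages"]["lsmeans"] = {"n_hybrids": int(len(ls.table)), "sigma2_E": ls.sigma2_E}

    # genotype QC
    marker_report = filter_markers(lines)
    marker_report.table.to_csv(out / "marker_qc.tsv", sep="\t", index=False)
    line_report = filter_lines(lines, founders)
    line_report.to_csv(out / "line_qc.tsv", sep="\t", index=False)
    keep_lines = line_report["pass"].to_numpy()
    keep_markers = marker_report.passed
    lines_qc = lines.subset_lines(keep_lines).subset_markers(keep_markers)
    gmap_qc = GeneticMap(gmap.table[keep_markers].reset_index(drop=True))
    ped_tab = pedigree.table
    ok = ped_tab["dent_parent"].isin(lines_qc.info["line_id"]) & ped_tab["flint_parent"].isin(
        lines_qc.info["line_id"]
    )
    pedigree = HybridPedigree(ped_tab[ok].reset_index(drop=True))
    summary["stages"]["qc"] = {
        "markers_kept": int(keep_markers.sum()),
        "lines_kept": int(keep_lines.sum()),
        "hybrids_kept": int(ok.sum()),
    }

    # founder-origin probabilities and imputation
    if founders is None:
        raise ValueError("pipeline requires founder genotypes for origin inference")
    founders_qc_alleles = founders.alleles[:, keep_markers]
    from .datatypes import FounderGenotypes

    founders_qc = FounderGenotypes(
        founders_qc_alleles, founders.founder_ids, founders.group, lines_qc.markers
    )
    probs = origin_posteriors(lines_qc, founders_qc, gmap_qc, config.genotyping_error_rate)
    imputed = expected_dosage_imputation(lines_qc, probs, founders_qc)
    hprobs = hybrid_founder_probs(pedigree, probs)

    # align response
    y = ls.aligned_to(pedigree.table["hybrid_id"])
    pop = build_population_design(pedigree)
    X_base, base_names = base_fixed_matrix(pop)
    both_poly = polymorphic_in_both_groups(lines_qc)
    summary["stages"]["scan_sets"] = {
        "founder_alleles": int(gmap_qc.n_markers),
        "snp_within_group": int(both_poly.sum()),
        "hybrid_genotype": int(both_poly.sum()),
    }
    log.info(
        "scan sets: %d mapped markers (founder model), %d polymorphic in both groups",
        gmap_qc.n_markers,
        int(both_poly.sum()),
    )

    qtl_lists = {}
    for model in config.models:
        mask = None if model == "founder_alleles" else both_poly
        ds = build_model_designs(
            model,
            pedigree,
            gmap_qc,
            hybrid_probs=hprobs,
            line_dosage=imputed,
            line_ids=lines_qc.line_index(),
            line_groups=lines_qc.info["group"].to_numpy(),
            scan_mask=mask,
        )
        m_eff = effective_marker_count(
            ds.predictor_summary[:, ds.scan_mask], gmap_qc.chrom[ds.scan_mask], config.meff_cutoff
        )
        threshold = genomewide_threshold(m_eff, config.alpha_genomewide)
        scan = single_marker_scan(
            y, X_base, pop.Z_D, pop.Z_F, ds, threshold, vc_mode=config.vc_mode
        )
        scan.table.to_csv(out / f"scan_{model}.tsv", sep="\t", index=False)
        if not config.run_selection:
            summary["stages"][model] = {
                "m_eff": m_eff,
                "threshold": threshold,
                "n_above_threshold": int((scan.table["neglog10p"] > threshold).sum()),
            }
            continue
        fit = forward_backward_select(y, X_base, pop.Z_D, pop.Z_F, ds, threshold)
        fit.qtl_table.to_csv(out / f"qtl_{model}.tsv", sep="\t", index=False)
        r2 = r2_summary(y, fit, X_base, ds)
        model_summary = {
            "m_eff": m_eff,
            "threshold": threshold,
            "n_qtl": len(fit.selected),
            "R2_pop": r2.R2_pop,
            "R2_pop_plus_QTL": r2.R2_pop_plus_QTL,
            "R2_QTL": r2.R2_QTL,
            "R2_star_QTL": r2.R2_star_QTL,
            "variance_components": {
                "sigma2_D": fit.fit.vc.sigma2_D,
                "sigma2_F": fit.fit.vc.sigma2_F,
                "sigma2_e": fit.fit.vc.sigma2_e,
            },
        }
        if config.run_cv and len(fit.selected):
            strata = (
                pedigree.table["dent_pop"].astype(str) + "x" + pedigree.table["flint_pop"].astype(str)
            ).to_numpy()
            cv = cross_validate(
                y,
                X_base,
                ds,
                fit,
                strata,
                n_samplings=config.cv_samplings,
                train_fraction=config.cv_train_fraction,
                alpha_individual=config.alpha_individual,
                seed=config.seed,
            )
            cv.table.to_csv(out / f"cv_{model}.tsv", sep="\t", index=False)
            model_summary["cv"] = {
                r.variant: {"mean_r2": r.mean_r2, "sd_r2": r.sd_r2}
                for r in cv.table.itertuples()
            }
        summary["stages"][model] = model_summary
        qtl_lists[model] = fit.qtl_table[["chrom", "pos_cM", "marker"]].copy()

    if len(qtl_lists) > 1:
        matching = match_qtl(qtl_lists)
        matching["summary"].to_csv(out / "qtl_matching.tsv", sep="\t", index=False)
        summary["stages"]["matching"] = matching["summary"].to_dict(orient="records")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=float))
    return summary
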