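"""Genome scan, multiple-testing threshold and multilocus model selection.

The single-marker scan fits population structure plus one QTL block per
mapped position and records the conditional Wald test of the block and of
its GCA/SCA (or additive/dominance) components. The genome-wide 5% threshold
is Bonferroni on the effective number of markers, estimated per chromosome
from the eigenvalues of the marker correlation matrix (smallest k whose top
eigenvalues reach 99.5% of the trace). The final multilocus model is chosen
by forward inclusion of the most significant marker with backward pruning of
markers whose conditional test drops below the threshold, iterated to a
fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GeneticMap, HybridFounderProbs, HybridPedigree
from .design import (
    QTLDesign,
    build_founder_design,
    build_hybrid_design,
    build_snp_design,
    minor_allele_is_one,
    parent_dosage_matrix,
)
from .mixedmodel import MixedFit, added_block_test, reml_fit

FOUNDER_INDEX_WEIGHTS = np.array([0.0, 1.0, 2.0, 3.0])


@dataclass
class ModelDesignSet:
    """Per-marker QTL designs for one detection model over one map."""

    model: str
    designs: list[QTLDesign | None]
    scan_mask: np.ndarray
    gmap: GeneticMap
    predictor_summary: np.ndarray  # (units x markers) scalar codings for M_eff

    @property
    def component_names(self) -> list[str]:
        if self.model == "hybrid_genotype":
            return ["additive", "dominance"]
        return ["GCA_D", "GCA_F", "SCA"]


def build_model_designs(
    model: str,
    pedigree: HybridPedigree,
    gmap: GeneticMap,
    hybrid_probs: HybridFounderProbs | None = None,
    line_dosage: np.ndarray | None = None,
    line_ids: pd.Index | None = None,
    line_groups: np.ndarray | None = None,
    scan_mask: np.ndarray | None = None,
) -> ModelDesignSet:
    """Construct the QTL design at every scanned marker for one model.

    The Founder alleles model scans all mapped markers using the hybrid
    founder-transmission probabilities; the SNP models require parental-line
    dosages (imputed where missing) and scan only markers polymorphic in both
    groups (``scan_mask``).
    """
    m = gmap.n_markers
    designs: list[QTLDesign | None] = [None] * m
    if model == "founder_alleles":
        if hybrid_probs is None:
            raise ValueError("founder model needs hybrid founder probabilities")
        mask = np.ones(m, dtype=bool) if scan_mask is None else scan_mask.copy()
        for j in np.flatnonzero(mask):
            try:
                designs[j] = build_founder_design(hybrid_probs.dent[:, j, :], hybrid_probs.flint[:, j, :])
            except ValueError:
                mask[j] = False
        exp_idx_D = hybrid_probs.dent @ FOUNDER_INDEX_WEIGHTS
        exp_idx_F = hybrid_probs.flint @ FOUNDER_INDEX_WEIGHTS
        summary = np.vstack([exp_idx_D, exp_idx_F])
        return ModelDesignSet(model, designs, mask, gmap, summary)

    if model not in ("snp_within_group", "hybrid_genotype"):
        raise ValueError(f"unknown model {model!r}")
    if line_dosage is None or line_ids is None or line_groups is None:
        raise ValueError(f"{model} needs parental line dosages")
    xD = parent_dosage_matrix(pedigree, line_dosage, line_ids, "dent_parent")
    xF = parent_dosage_matrix(pedigree, line_dosage, line_ids, "flint_parent")
    mask = np.ones(m, dtype=bool) if scan_mask is None else scan_mask.copy()
    minor_D = minor_allele_is_one(line_dosage[line_groups == "D"])
    minor_F = minor_allele_is_one(line_dosage[line_groups == "F"])
    minor_pooled = minor_allele_is_one(line_dosage)
    for j in np.flatnonzero(mask):
        if np.isnan(xD[:, j]).any() or np.isnan(xF[:, j]).any():
            mask[j] = False
            continue
        try:
            if model == "snp_within_group":
                designs[j] = build_snp_design(xD[:, j], xF[:, j], bool(minor_D[j]), bool(minor_F[j]))
            else:
                designs[j] = build_hybrid_design(xD[:, j], xF[:, j], bool(minor_pooled[j]))
        except ValueError:
            mask[j] = False
    summary = np.vstack([xD, xF])
    return ModelDesignSet(model, designs, mask, gmap, summary)


# ---------------------------------------------------------------------------
# multiple testing


def effective_marker_count(
    marker_matrix: np.ndarray,
    chrom: np.ndarray,
    cutoff: float = 0.995,
) -> float:
    """Effective number of independent markers, summed over chromosomes.

    ``marker_matrix``: (units x markers) scalar marker codings, map order.
    Per chromosome, M_eff is the smallest k such that the top-k eigenvalues
    of the marker correlation matrix account for ``cutoff`` of its trace;
    chromosomes with a single (or no variable) marker contribute their
    marker count.
    """
    total = 0.0
    for c in pd.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        sub = marker_matrix[:, cols]
        sd = sub.std(axis=0)
        variable = sd > 0
        n_const = int((~variable).sum())
        sub = sub[:, variable]
        if sub.shape[1] < 2:
            total += sub.shape[1] + n_const
            continue
        R = np.corrcoef(sub, rowvar=False)
        vals = np.sort(np.linalg.eigvalsh(R))[::-1]
        csum = np.cumsum(vals)
        k = int(np.searchsorted(csum, cutoff * R.shape[0]) + 1)
        total += min(k, R.shape[0]) + n_const
    return float(total)


def genomewide_threshold(m_eff: float, alpha: float = 0.05) -> float:
    """-log10 p threshold for a genome-wide level alpha with m_eff tests."""
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    return float(-np.log10(alpha / m_eff))


# ---------------------------------------------------------------------------
# scanning


@dataclass
class ScanResult:
    table: pd.DataFrame  # marker, chrom, pos_cM, df, W, neglog10p + per component
    threshold: float | None
    model: str

    def top_marker(self) -> pd.Series:
        return self.table.loc[self.table["neglog10p"].idxmax()]


def _residualize(fit: MixedFit, conditioning: np.ndarray, block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Whiten and residualize a block against the conditioning columns."""
    Cw = fit.whiten(conditioning)
    Q, _ = np.linalg.qr(Cw)
    Bw = fit.whiten(block)
    return Bw - Q @ (Q.T @ Bw), Q


def _scan_once(
    fit: MixedFit,
    y: np.ndarray,
    conditioning: np.ndarray,
    design_set: ModelDesignSet,
    skip: set[int] = frozenset(),
) -> pd.DataFrame:
    """Test every scanned marker's block added last to the conditioning model."""
    Cw = fit.whiten(conditioning)
    Q, _ = np.linalg.qr(Cw)
    yw = fit.whiten(y)
    y_res = yw - Q @ (Q.T @ yw)
    # residual variance is re-profiled per marker under the full model
    resid_dof = len(y) - conditioning.shape[1]
    rows = []
    comps = design_set.component_names
    gmap = design_set.gmap
    for j in np.flatnonzero(design_set.scan_mask):
        if j in skip:
            continue
        d = design_set.designs[j]
        Bw = fit.whiten(d.reduced)
        B_res = Bw - Q @ (Q.T @ Bw)
        glob, comp, _ = added_block_test(
            y_res, B_res, fit.vc.sigma2_e, d.components, residual_dof=resid_dof
        )
        row = {
            "marker_index": j,
            "marker": gmap.markers[j],
            "chrom": gmap.chrom[j],
            "pos_cM": gmap.pos_cM[j],
            "df": glob.df,
            "W": glob.W,
            "neglog10p": glob.neglog10p,
        }
        for name in comps:
            r = comp.get(name)
            row[f"W_{name}"] = r.W if r else np.nan
            row[f"df_{name}"] = r.df if r else 0
            row[f"neglog10p_{name}"] = r.neglog10p if r else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def scan_given_fit(
    fit: MixedFit,
    y: np.ndarray,
    X_base: np.ndarray,
    design_set: ModelDesignSet,
    threshold: float | None = None,
) -> ScanResult:
    """Profiled scan reusing an existing base-model fit.

    Useful when several QTL models share the same population-structure base
    model: the REML fit is done once and each model's markers are tested
    against it.
    """
    return ScanResult(_scan_once(fit, y, X_base, design_set), threshold, design_set.model)


def single_marker_scan(
    y: np.ndarray,
    X_base: np.ndarray,
    Z_D: np.ndarray | None,
    Z_F: np.ndarray | None,
    design_set: ModelDesignSet,
    threshold: float | None = None,
    vc_mode: str = "reestimate",
    fix_zero_vc: bool = False,
) -> ScanResult:
    """Genome scan of one QTL model over its scan set.

    ``vc_mode``: "reestimate" refits the variance components at every marker
    (the default); "profile" estimates them once under the base model and
    keeps them fixed across markers, which is much faster and nearly
    identical when single-QTL effects are modest.
    """
    if vc_mode not in ("reestimate", "profile"):
        raise ValueError(f"unknown vc_mode {vc_mode!r}")
    base_fit = reml_fit(y, X_base, Z_D, Z_F, fix_zero=fix_zero_vc)
    if vc_mode == "profile" or fix_zero_vc:
        table = _scan_once(base_fit, y, X_base, design_set)
    else:
        rows = []
        comps = design_set.component_names
        gmap = design_set.gmap
        for j in np.flatnonzero(design_set.scan_mask):
            d = design_set.designs[j]
            Xj = np.hstack([X_base, d.reduced])
            fit_j = reml_fit(y, Xj, Z_D, Z_F)
            y_res_b, Q = _residualize(fit_j, X_base, d.reduced)
            yw = fit_j.whiten(y)
            y_res = yw - Q @ (Q.T @ yw)
            glob, comp, _ = added_block_test(y_res, y_res_b, fit_j.vc.sigma2_e, d.components)
            row = {
                "marker_index": j,
                "marker": gmap.markers[j],
                "chrom": gmap.chrom[j],
                "pos_cM": gmap.pos_cM[j],
                "df": glob.df,
                "W": glob.W,
                "neglog10p": glob.neglog10p,
            }
            for name in comps:
                r = comp.get(name)
                row[f"W_{name}"] = r.W if r else np.nan
                row[f"df_{name}"] = r.df if r else 0
                row[f"neglog10p_{name}"] = r.neglog10p if r else np.nan
            rows.append(row)
        table = pd.DataFrame(rows)
    return ScanResult(table, threshold, design_set.model)


# ---------------------------------------------------------------------------
# multilocus selection


@dataclass
class QTLModelFit:
    """Final multilocus model for one detection model."""

    model: str
    selected: list[int]  # marker indices, in order of inclusion
    qtl_table: pd.DataFrame  # conditional global + component tests per QTL
    fit: MixedFit
    threshold: float
    converged: bool
    base_columns: int

    @property
    def positions(self) -> pd.DataFrame:
        return self.qtl_table[["marker", "chrom", "pos_cM"]]


def _conditional_tests(
    fit: MixedFit,
    y: np.ndarray,
    X_base: np.ndarray,
    design_set: ModelDesignSet,
    selected: list[int],
) -> pd.DataFrame:
    """Added-last tests of each selected QTL given base + all other QTL."""
    base_cols = ["marker_index", "marker", "chrom", "pos_cM", "df", "W", "neglog10p"]
    comp_cols = [
        f"{stat}_{name}"
        for name in design_set.component_names
        for stat in ("W", "df", "neglog10p")
    ]
    if not selected:
        return pd.DataFrame(columns=base_cols + comp_cols)
    rows = []
    gmap = design_set.gmap
    for j in selected:
        others = [design_set.designs[k].reduced for k in selected if k != j]
        conditioning = np.hstack([X_base] + others) if others else X_base
        yw = fit.whiten(y)
        Cw = fit.whiten(conditioning)
        Q, _ = np.linalg.qr(Cw)
        y_res = yw - Q @ (Q.T @ yw)
        d = design_set.designs[j]
        Bw = fit.whiten(d.reduced)
        B_res = Bw - Q @ (Q.T @ Bw)
        glob, comp, beta = added_block_test(
            y_res, B_res, fit.vc.sigma2_e, d.components,
            residual_dof=len(y) - conditioning.shape[1],
        )
        row = {
            "marker_index": j,
            "marker": gmap.markers[j],
            "chrom": gmap.chrom[j],
            "pos_cM": gmap.pos_cM[j],
            "df": glob.df,
            "W": glob.W,
            "neglog10p": glob.neglog10p,
        }
        for name, r in comp.items():
            row[f"W_{name}"] = r.W
            row[f"df_{name}"] = r.df
            row[f"neglog10p_{name}"] = r.neglog10p
        rows.append(row)
    return pd.DataFrame(rows)


def forward_backward_select(
    y: np.ndarray,
    X_base: np.ndarray,
    Z_D: np.ndarray | None,
    Z_F: np.ndarray | None,
    design_set: ModelDesignSet,
    threshold: float,
    vc_mode: str = "profile",
    fix_zero_vc: bool = False,
    max_iterations: int = 50,
) -> QTLModelFit:
    """Forward/backward multilocus marker selection at the genome-wide threshold.

    Forward: add the most significant remaining marker above the threshold,
    conditioning on the current selection (ties broken by smaller p, then
    lower map position). Backward: drop any selected marker whose conditional
    global test falls below the threshold, weakest first. Iterate to a fixed
    point; the iteration cap returns the current model flagged unconverged.
    """
    selected: list[int] = []
    converged = False
    seen_states: set[tuple[int, ...]] = set()
    base_fit = reml_fit(y, X_base, Z_D, Z_F, fix_zero=fix_zero_vc)
    theta = None
    if vc_mode == "profile" and not fix_zero_vc:
        vc = base_fit.vc
        theta = (vc.sigma2_D / vc.sigma2_e, vc.sigma2_F / vc.sigma2_e)

    def _fit(X: np.ndarray):
        return reml_fit(y, X, Z_D, Z_F, fix_zero=fix_zero_vc, fixed_theta=theta)

    for _ in range(max_iterations):
        cols = [design_set.designs[j].reduced for j in selected]
        X_cond = np.hstack([X_base] + cols) if cols else X_base
        fit = _fit(X_cond)
        scan = _scan_once(fit, y, X_cond, design_set, skip=set(selected))
        changed = False
        if len(scan):
            above = scan[scan["neglog10p"] > threshold]
            if len(above):
                best = above.sort_values(
                    ["neglog10p", "chrom", "pos_cM"], ascending=[False, True, True]
                ).iloc[0]
                selected.append(int(best["marker_index"]))
                changed = True
        # backward pruning under the refitted model
        while len(selected) > 1:
            cols = [design_set.designs[j].reduced for j in selected]
            fit_b = _fit(np.hstack([X_base] + cols))
            cond = _conditional_tests(fit_b, y, X_base, design_set, selected)
            weakest = cond.sort_values(["neglog10p", "pos_cM"]).iloc[0]
            if weakest["neglog10p"] > threshold:
                break
            selected.remove(int(weakest["marker_index"]))
            changed = True
        state = tuple(sorted(selected))
        if not changed:
            converged = True
            break
        if state in seen_states:
            break
        seen_states.add(state)
    cols = [design_set.designs[j].reduced for j in selected]
    X_final = np.hstack([X_base] + cols) if cols else X_base
    # the final multilocus model re-estimates the variance components in full
    final_fit = reml_fit(y, X_final, Z_D, Z_F, fix_zero=fix_zero_vc)
    qtl_table = _conditional_tests(final_fit, y, X_base, design_set, selected)
    return QTLModelFit(
        model=design_set.model,
        selected=selected,
        qtl_table=qtl_table,
        fit=final_fit,
        threshold=threshold,
        converged=converged,
        base_columns=X_base.shape[1],
    )


def component_tests(model_fit: QTLModelFit, alpha_individual: float = 0.05) -> pd.DataFrame:
    """Per-QTL component significance flags from the final multilocus model.

    Flags each GCA/SCA (or additive/dominance) component at the individual
    5% level and at the genome-wide threshold.
    """
    t = model_fit.qtl_table.copy()
    comp_cols = [c.removeprefix("neglog10p_") for c in t.columns if c.startswith("neglog10p_")]
    cut_ind = -np.log10(alpha_individual)
    for name in comp_cols:
        t[f"{name}_sig_individual"] = t[f"neglog10p_{name}"] > cut_ind
        t[f"{name}_sig_genomewide"] = t[f"neglog10p_{name}"] > model_fit.threshold
    return t
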