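"""Variance-explained summaries, cross-validation and cross-model QTL matching.

R-squared values use fixed-effect predictions under the REML-estimated
variance structure: R2_pop from the population-only model, R2_pop+QTL from
the final multilocus model, R2_QTL by difference, and the within-population
share R2*_QTL = R2_QTL / (1 - R2_pop). Predictive ability is assessed by
stratified 80/20 cross-validation within each hybrid population: the
whole-data QTL are re-tested on the training set, population and QTL fixed
effects re-estimated, and the squared correlation between predicted and
observed test-set values recorded over samplings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from ._util import substream
from .mixedmodel import added_block_test
from .scan import ModelDesignSet, QTLModelFit


def _gls_beta(y: np.ndarray, X: np.ndarray, chol_V0: np.ndarray | None) -> np.ndarray:
    if chol_V0 is None:
        Xs, ys = X, y
    else:
        Xs = linalg.solve_triangular(chol_V0, X, lower=True)
        ys = linalg.solve_triangular(chol_V0, y, lower=True)
    beta, _, _, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    return beta


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("total sum of squares is zero")
    return 100.0 * (1.0 - float(np.sum((y - pred) ** 2)) / tss)


@dataclass
class R2Summary:
    R2_pop: float
    R2_pop_plus_QTL: float
    R2_QTL: float
    R2_star_QTL: float
    R2_pop_plus_QTL_no_sca: float
    R2_QTL_no_sca: float
    per_qtl: pd.DataFrame  # marker, R2_individual


def _model_columns(
    X_base: np.ndarray,
    design_set: ModelDesignSet,
    selected: list[int],
    drop_marker: int | None = None,
    gca_only: bool = False,
    sca_markers: set[int] | None = None,
) -> np.ndarray:
    """Base + QTL columns, optionally dropping one QTL or all/some SCA terms."""
    cols = [X_base]
    sca_like = {"SCA", "dominance"}
    for j in selected:
        if j == drop_marker:
            continue
        d = design_set.designs[j]
        if gca_only and not (sca_markers and j in sca_markers):
            keep = np.concatenate(
                [idx for name, idx in d.components.items() if name not in sca_like]
            )
            cols.append(d.reduced[:, np.sort(keep)])
        else:
            cols.append(d.reduced)
    return np.hstack(cols)


def r2_summary(
    y: np.ndarray,
    final_fit: QTLModelFit,
    X_base: np.ndarray,
    design_set: ModelDesignSet,
) -> R2Summary:
    """Percent phenotypic variance explained by population terms and QTL.

    Individual QTL R2 is the drop in R2_pop+QTL when that QTL's columns are
    removed and the fixed effects refitted under the same variance structure.
    """
    chol = final_fit.fit.chol_V0
    selected = final_fit.selected

    def fit_r2(X: np.ndarray) -> float:
        return _r2(y, X @ _gls_beta(y, X, chol))

    r2_pop = fit_r2(X_base)
    X_full = _model_columns(X_base, design_set, selected)
    r2_full = fit_r2(X_full)
    r2_qtl = r2_full - r2_pop
    r2_star = r2_qtl / (1.0 - r2_pop / 100.0) if r2_pop < 100.0 else float("nan")
    X_nosca = _model_columns(X_base, design_set, selected, gca_only=True)
    r2_full_nosca = fit_r2(X_nosca)
    rows = []
    for j in selected:
        X_dropped = _model_columns(X_base, design_set, selected, drop_marker=j)
        rows.append(
            {
                "marker_index": j,
                "marker": design_set.gmap.markers[j],
                "R2_individual": r2_full - fit_r2(X_dropped),
            }
        )
    return R2Summary(
        R2_pop=r2_pop,
        R2_pop_plus_QTL=r2_full,
        R2_QTL=r2_qtl,
        R2_star_QTL=r2_star,
        R2_pop_plus_QTL_no_sca=r2_full_nosca,
        R2_QTL_no_sca=r2_full_nosca - r2_pop,
        per_qtl=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    table: pd.DataFrame  # variant -> mean_r2, sd_r2
    n_samplings: int
    per_sampling: pd.DataFrame


def _stratified_split(
    strata: np.ndarray,
    train_fraction: float,
    min_stratum: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean training mask; 80% rounded up within each stratum.

    Strata smaller than ``min_stratum`` are merged into the largest stratum
    with a warning.
    """
    labels = pd.Series(strata).astype(str)
    counts = labels.value_counts()
    small = counts[counts < min_stratum].index
    if len(small):
        warnings.warn(
            f"{len(small)} hybrid population(s) with < {min_stratum} hybrids merged "
            "into the largest stratum for CV splitting"
        )
        labels[labels.isin(small)] = counts.idxmax()
    train = np.zeros(len(labels), dtype=bool)
    for _, idx in labels.groupby(labels).groups.items():
        idx = np.asarray(idx, dtype=int)
        n_train = int(np.ceil(train_fraction * len(idx)))
        chosen = rng.choice(idx, size=min(n_train, len(idx)), replace=False)
        train[chosen] = True
    return train


def _retain_significant(
    y: np.ndarray,
    X_base: np.ndarray,
    design_set: ModelDesignSet,
    selected: list[int],
    rows: np.ndarray,
    alpha: float,
) -> list[int]:
    """Backward-test QTL on a row subset, keeping those significant at alpha."""
    keep = list(selected)
    while keep:
        worst, worst_p = None, -1.0
        for j in keep:
            others = [design_set.designs[k].reduced[rows] for k in keep if k != j]
            C = np.hstack([X_base[rows]] + others) if others else X_base[rows]
            Q, _ = np.linalg.qr(C)
            yv = y[rows]
            y_res = yv - Q @ (Q.T @ yv)
            B = design_set.designs[j].reduced[rows]
            B_res = B - Q @ (Q.T @ B)
            n, p = C.shape[0], C.shape[1] + B_res.shape[1]
            beta_full, _, _, _ = np.linalg.lstsq(np.hstack([C, B]), yv, rcond=None)
            rss = float(np.sum((yv - np.hstack([C, B]) @ beta_full) ** 2))
            sigma2 = rss / max(n - p, 1)
            glob, _, _ = added_block_test(y_res, B_res, sigma2)
            if glob.p > worst_p:
                worst, worst_p = j, glob.p
        if worst_p <= alpha:
            break
        keep.remove(worst)
    return keep


def cross_validate(
    y: np.ndarray,
    X_base: np.ndarray,
    design_set: ModelDesignSet,
    final_fit: QTLModelFit,
    strata: np.ndarray,
    n_samplings: int = 100,
    train_fraction: float = 0.8,
    alpha_individual: float = 0.05,
    min_stratum: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified 80/20 cross-validation of predictive ability.

    Per sampling, the whole-data QTL are re-tested on the training set
    (retained at the individual 5% level), fixed effects re-estimated on
    training, and test hybrids predicted from fixed effects only. Variants:
    population-only baseline, population + GCA/additive QTL terms, and
    additionally the SCA/dominance terms of QTL for which they were
    significant at the individual 5% level on the whole data.
    """
    chol = final_fit.fit.chol_V0
    sca_like = [c for c in ("SCA", "dominance") if f"neglog10p_{c}" in final_fit.qtl_table.columns]
    sca_sig: set[int] = set()
    for c in sca_like:
        mask = final_fit.qtl_table[f"neglog10p_{c}"] > -np.log10(alpha_individual)
        sca_sig |= set(final_fit.qtl_table.loc[mask, "marker_index"].astype(int))

    records = []
    for s in range(n_samplings):
        rng = substream(seed, f"cv:{s}")
        train = _stratified_split(strata, train_fraction, min_stratum, rng)
        test = ~train
        tr = np.flatnonzero(train)
        retained = _retain_significant(
            y, X_base, design_set, final_fit.selected, tr, alpha_individual
        )
        chol_tr = None
        if chol is not None:
            V0 = chol @ chol.T
            chol_tr = linalg.cholesky(V0[np.ix_(tr, tr)], lower=True)
        rec = {"sampling": s, "n_retained": len(retained)}
        variants = {
            "population_only": ([], False, None),
            "gca": (retained, True, None),
            "gca_plus_sca": (retained, True, sca_sig),
        }
        for name, (sel, gca_only, sca_markers) in variants.items():
            X_full = _model_columns(X_base, design_set, sel, gca_only=gca_only, sca_markers=sca_markers)
            beta = _gls_beta(y[tr], X_full[tr], chol_tr)
            pred = X_full[test] @ beta
            obs = y[test]
            if np.std(pred) == 0 or np.std(obs) == 0:
                r2 = 0.0
            else:
                r2 = float(np.corrcoef(pred, obs)[0, 1] ** 2)
            rec[name] = r2
        records.append(rec)
    per_sampling = pd.DataFrame(records)
    table = pd.DataFrame(
        {
            "variant": ["population_only", "gca", "gca_plus_sca"],
            "mean_r2": [per_sampling[v].mean() for v in ("population_only", "gca", "gca_plus_sca")],
            "sd_r2": [per_sampling[v].std(ddof=1) for v in ("population_only", "gca", "gca_plus_sca")],
        }
    )
    return CVResult(table, n_samplings, per_sampling)


# ---------------------------------------------------------------------------
# cross-model QTL matching


def match_qtl(
    qtl_lists_by_model: dict[str, pd.DataFrame],
    window_cM: float = 10.0,
) -> dict[str, pd.DataFrame]:
    """Greedy nearest-distance pairwise matching of QTL across models.

    Each input table needs columns chrom and pos_cM. Within a chromosome,
    candidate pairs are matched in ascending distance order while both ends
    are free; a pair matches when distance < window (lower bound inclusive,
    upper exclusive). QTL on different chromosomes never match and matching
    is pairwise only (no chain-linking).
    """
    models = sorted(qtl_lists_by_model)
    pair_rows = []
    matched_any: dict[str, set[int]] = {m: set() for m in models}
    match_rows = []
    for ai in range(len(models)):
        for bi in range(ai + 1, len(models)):
            ma, mb = models[ai], models[bi]
            ta, tb = qtl_lists_by_model[ma], qtl_lists_by_model[mb]
            n_matched = 0
            for c in sorted(set(ta["chrom"]) & set(tb["chrom"])):
                ia = ta.index[ta["chrom"] == c].to_numpy()
                ib = tb.index[tb["chrom"] == c].to_numpy()
                cand = [
                    (abs(ta.loc[i, "pos_cM"] - tb.loc[j, "pos_cM"]), i, j)
                    for i in ia
                    for j in ib
                ]
                used_a: set[int] = set()
                used_b: set[int] = set()
                for dist, i, j in sorted(cand):
                    if dist >= window_cM or i in used_a or j in used_b:
                        continue
                    used_a.add(i)
                    used_b.add(j)
                    n_matched += 1
                    matched_any[ma].add(i)
                    matched_any[mb].add(j)
                    match_rows.append(
                        {
                            "model_a": ma,
                            "model_b": mb,
                            "chrom": c,
                            "pos_a": ta.loc[i, "pos_cM"],
                            "pos_b": tb.loc[j, "pos_cM"],
                            "distance_cM": dist,
                        }
                    )
            pair_rows.append({"model_a": ma, "model_b": mb, "n_matched": n_matched})
    summary = pd.DataFrame(
        {
            "model": models,
            "n_qtl": [len(qtl_lists_by_model[m]) for m in models],
            "n_specific": [
                len(qtl_lists_by_model[m]) - len(matched_any[m]) for m in models
            ],
        }
    )
    return {
        "pairs": pd.DataFrame(pair_rows),
        "matches": pd.DataFrame(match_rows),
        "summary": summary,
    }
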