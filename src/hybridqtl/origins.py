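"""Founder-origin probabilities for biparental inbred lines.

Each parental line descends from the two founders of its population. A
two-state hidden Markov chain along each chromosome tracks which founder the
line's resident allele descends from; the forward-backward algorithm yields
the exact posterior at every mapped position. Transitions between adjacent
loci use the Haldane recombination fraction of the cM distance — the
single-meiosis r for doubled-haploid lines and the inflated effective
fraction r* = 2r/(1+2r) for lines derived by repeated selfing. Emissions
compare the observed call with the founder alleles under a symmetric
per-call error rate; heterozygous calls at informative markers (residual
heterozygosity of selfed lines) are origin-ambiguous, and missing
observations emit 1.

Per-hybrid founder-transmission probabilities are then assembled by placing
each parent's two-founder posterior in the 4-founder slot of its population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import POP_PAIRS, haldane_r, ssd_effective_r
from .datatypes import (
    FounderGenotypes,
    FounderOriginProbs,
    GeneticMap,
    HybridFounderProbs,
    HybridPedigree,
    LineGenotypes,
)


def informative_status(a0: np.ndarray, a1: np.ndarray) -> pd.DataFrame:
    """Per-marker status for a founder pair: informative iff alleles differ.

    A missing founder call makes the marker uninformative with a
    MISSING_FOUNDER flag.
    """
    missing = np.isnan(a0) | np.isnan(a1)
    informative = ~missing & (a0 != a1)
    return pd.DataFrame(
        {
            "informative": informative,
            "flag": np.where(missing, "MISSING_FOUNDER", ""),
        }
    )


def _emissions(obs: np.ndarray, a0: np.ndarray, a1: np.ndarray, error_rate: float) -> np.ndarray:
    """Emission probabilities, shape (n_lines, n_markers, 2).

    P(obs | origin s) with the line expected homozygous for founder s's
    allele; a wrong call (the other homozygote or a heterozygote) has
    probability error_rate/2 each. Missing observations and markers with a
    missing founder call emit 1.
    """
    e = float(error_rate)
    n, m = obs.shape
    out = np.ones((n, m, 2))
    for s, a in enumerate((a0, a1)):
        known = ~np.isnan(a) & ~np.isnan(obs)
        match = obs == a[None, :]
        out[:, :, s] = np.where(known, np.where(match, 1.0 - e, e / 2.0), 1.0)
    return out


def _transition_probs(pos_cM: np.ndarray, line_type: str) -> np.ndarray:
    r = haldane_r(np.diff(pos_cM))
    if line_type == "SSD":
        r = ssd_effective_r(r)
    elif line_type != "DH":
        raise ValueError(f"unknown line_type {line_type!r}")
    return r


def forward_backward(emissions: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Exact 2-state posterior, vectorized over lines.

    ``emissions``: (n_lines, n_markers, 2); ``rho``: (n_markers-1,) switch
    probabilities. Returns P(state = 0) per line x marker.
    """
    n, m, _ = emissions.shape
    alpha = np.empty((n, m, 2))
    scale = np.empty((n, m))
    a = 0.5 * emissions[:, 0, :]
    scale[:, 0] = a.sum(axis=1)
    if np.any(scale[:, 0] <= 0.0):
        raise ValueError("zero-state likelihood; use a genotyping error rate > 0")
    alpha[:, 0, :] = a / scale[:, 0, None]
    for j in range(1, m):
        prev = alpha[:, j - 1, :]
        pred = np.empty_like(prev)
        pred[:, 0] = prev[:, 0] * (1 - rho[j - 1]) + prev[:, 1] * rho[j - 1]
        pred[:, 1] = prev[:, 1] * (1 - rho[j - 1]) + prev[:, 0] * rho[j - 1]
        a = pred * emissions[:, j, :]
        scale[:, j] = a.sum(axis=1)
        if np.any(scale[:, j] <= 0.0):
            raise ValueError("zero-state likelihood; use a genotyping error rate > 0")
        alpha[:, j, :] = a / scale[:, j, None]
    beta = np.ones((n, 2))
    post = np.empty((n, m))
    post[:, m - 1] = alpha[:, m - 1, 0]
    for j in range(m - 2, -1, -1):
        nxt = beta * emissions[:, j + 1, :]
        b = np.empty_like(nxt)
        b[:, 0] = nxt[:, 0] * (1 - rho[j]) + nxt[:, 1] * rho[j]
        b[:, 1] = nxt[:, 1] * (1 - rho[j]) + nxt[:, 0] * rho[j]
        beta = b / scale[:, j + 1, None]
        unnorm = alpha[:, j, :] * beta
        post[:, j] = unnorm[:, 0] / unnorm.sum(axis=1)
    return post


def founder_origin_hmm(
    obs: np.ndarray,
    founder_alleles: tuple[np.ndarray, np.ndarray],
    pos_cM: np.ndarray,
    line_type: str,
    genotyping_error_rate: float = 1e-3,
) -> np.ndarray:
    """Posterior P(descent from founder 1) for one chromosome.

    ``obs`` may be (n_markers,) for a single line or (n_lines, n_markers).
    """
    single = obs.ndim == 1
    obs2 = obs[None, :] if single else obs
    a0, a1 = founder_alleles
    em = _emissions(obs2.astype(float), np.asarray(a0, float), np.asarray(a1, float), genotyping_error_rate)
    rho = _transition_probs(np.asarray(pos_cM, float), line_type)
    post = forward_backward(em, rho)
    return post[0] if single else post


def origin_posteriors(
    lines: LineGenotypes,
    founders: FounderGenotypes,
    gmap: GeneticMap,
    genotyping_error_rate: float = 1e-3,
) -> FounderOriginProbs:
    """Posterior origin probabilities for every line, all chromosomes.

    Dent lines are treated as DH, Flint lines as SSD.
    """
    p = np.full((lines.n_lines, gmap.n_markers), np.nan)
    slices = gmap.chromosome_slices()
    for (group, pop), idx in lines.info.groupby(["group", "population"]).groups.items():
        rows = np.asarray(idx, dtype=int)
        a0, a1 = founders.pair_alleles(str(group), int(pop))
        line_type = "DH" if group == "D" else "SSD"
        for sl in slices.values():
            p[np.ix_(rows, np.arange(sl.start, sl.stop))] = founder_origin_hmm(
                lines.dosage[rows, sl],
                (a0[sl], a1[sl]),
                gmap.pos_cM[sl],
                line_type,
                genotyping_error_rate,
            )
    return FounderOriginProbs(p, lines.info.copy(), gmap.markers)


def hybrid_founder_probs(
    pedigree: HybridPedigree,
    line_probs: FounderOriginProbs,
) -> HybridFounderProbs:
    """Founder-transmission probabilities of each hybrid, per group.

    An inbred (or near-inbred) parent transmits its resident allele, so the
    hybrid's probability of carrying founder f's allele equals the parent
    line's own origin posterior; at residual-heterozygous loci the posterior
    already averages the two phases. Founders outside the parent's
    population get probability 0.
    """
    ped = pedigree.table
    n_h = len(ped)
    m = len(line_probs.markers)
    row_of = pd.Series(np.arange(len(line_probs.info)), index=line_probs.info["line_id"])
    out = {}
    for group, parent_col, pop_col in (
        ("D", "dent_parent", "dent_pop"),
        ("F", "flint_parent", "flint_pop"),
    ):
        missing = ~ped[parent_col].isin(row_of.index)
        if missing.any():
            raise ValueError(f"parents missing from probability table: {sorted(ped.loc[missing, parent_col])[:5]}")
        rows = row_of.loc[ped[parent_col]].to_numpy()
        p1 = line_probs.p_first[rows]
        probs = np.zeros((n_h, m, 4))
        pair = np.asarray(POP_PAIRS)[ped[pop_col].to_numpy()]
        hh = np.arange(n_h)
        probs[hh[:, None], np.arange(m)[None, :], pair[:, 0:1]] = p1
        probs[hh[:, None], np.arange(m)[None, :], pair[:, 1:2]] = 1.0 - p1
        out[group] = probs
    return HybridFounderProbs(out["D"], out["F"], pd.Index(ped["hybrid_id"]), line_probs.markers)


def expected_dosage_imputation(
    lines: LineGenotypes,
    probs: FounderOriginProbs,
    founders: FounderGenotypes,
    hard_call: bool = False,
) -> np.ndarray:
    """Impute missing calls as the posterior-expected founder allele.

    dosage = sum_f P(origin = f) * allele_f. Where both founders are missing
    the call stays missing. With ``hard_call`` the expectation is rounded to
    {0, 1} (DH material is never imputed heterozygous).
    """
    imputed = lines.dosage.copy()
    for (group, pop), idx in lines.info.groupby(["group", "population"]).groups.items():
        rows = np.asarray(idx, dtype=int)
        a0, a1 = founders.pair_alleles(str(group), int(pop))
        p1 = probs.p_first[rows]
        exp = p1 * np.nan_to_num(a0)[None, :] + (1 - p1) * np.nan_to_num(a1)[None, :]
        both_missing = np.isnan(a0) & np.isnan(a1)
        exp[:, both_missing] = np.nan
        # one founder missing: fall back to the known founder's allele
        only0 = np.isnan(a1) & ~np.isnan(a0)
        only1 = np.isnan(a0) & ~np.isnan(a1)
        exp[:, only0] = a0[only0][None, :]
        exp[:, only1] = a1[only1][None, :]
        if hard_call:
            exp = np.round(exp)
        hole = np.isnan(lines.dosage[rows])
        block = imputed[rows]
        block[hole] = exp[hole]
        imputed[rows] = block
    return imputed
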