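"""Marker- and line-level quality control for parental-line genotypes.

Filters follow fixed thresholds typical of array genotyping of biparental
inbred material:

* markers: <20% missing within each group, <=5% heterozygous calls among Dent
  lines and among all lines pooled, <=10% among Flint lines (selfed lines
  retain residual heterozygosity), pooled MAF >= 5%;
* lines: drop Dent lines with >10% and Flint lines with >25% heterozygous
  calls, plus an off-type screen against the line's population founders;
* a per-population chi-square test of 1:1 founder-allele segregation,
  Bonferroni-corrected by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FounderGenotypes, LineGenotypes

REASONS = ("MISSING", "HET_DENT", "HET_TOTAL", "HET_FLINT", "MAF", "SEGDIST", "MONO_ONE_GROUP")


@dataclass
class QCThresholds:
    max_missing_per_group: float = 0.20  # strict: fail at >= this
    max_het_dent: float = 0.05  # inclusive: fail above
    max_het_total: float = 0.05
    max_het_flint: float = 0.10
    min_maf: float = 0.05  # inclusive: keep at >= this
    segdist_alpha: float = 0.05  # Bonferroni-corrected per population
    max_line_het_dent: float = 0.10
    max_line_het_flint: float = 0.25
    max_offtype_fraction: float = 0.20


@dataclass
class MarkerQCReport:
    table: pd.DataFrame  # per-marker stats, pass flag, semicolon-joined reasons

    @property
    def passed(self) -> np.ndarray:
        return self.table["pass"].to_numpy(dtype=bool)


def _het_rate(d: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.nanmean(d == 0.5, axis=0)


def _maf(d: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(d, axis=0)
    return np.minimum(freq, 1.0 - freq)


def filter_markers(lines: LineGenotypes, thresholds: QCThresholds | None = None) -> MarkerQCReport:
    """Apply the marker-level missingness/heterozygosity/MAF filters.

    A marker passes iff missing < 20% within each group AND het <= 5% among
    Dent lines AND het <= 5% overall AND het <= 10% among Flint lines AND
    pooled MAF >= 5%.
    """
    th = thresholds or QCThresholds()
    if lines.info["group"].isna().any():
        raise ValueError("group labels missing for some lines")
    d_mask = lines.group_mask("D")
    f_mask = lines.group_mask("F")
    dent = lines.dosage[d_mask]
    flint = lines.dosage[f_mask]
    miss_d = np.isnan(dent).mean(axis=0) if dent.size else np.zeros(len(lines.markers))
    miss_f = np.isnan(flint).mean(axis=0) if flint.size else np.zeros(len(lines.markers))
    het_d = np.nan_to_num(_het_rate(dent))
    het_f = np.nan_to_num(_het_rate(flint))
    het_all = np.nan_to_num(_het_rate(lines.dosage))
    maf = np.nan_to_num(_maf(lines.dosage))

    reasons = [[] for _ in lines.markers]
    for arr, cond, code in (
        (miss_d, lambda v: v >= th.max_missing_per_group, "MISSING"),
        (miss_f, lambda v: v >= th.max_missing_per_group, "MISSING"),
        (het_d, lambda v: v > th.max_het_dent, "HET_DENT"),
        (het_all, lambda v: v > th.max_het_total, "HET_TOTAL"),
        (het_f, lambda v: v > th.max_het_flint, "HET_FLINT"),
        (maf, lambda v: v < th.min_maf, "MAF"),
    ):
        for i in np.flatnonzero(cond(arr)):
            if code not in reasons[i]:
                reasons[i].append(code)
    table = pd.DataFrame(
        {
            "marker": lines.markers,
            "missing_dent": miss_d,
            "missing_flint": miss_f,
            "het_dent": het_d,
            "het_flint": het_f,
            "het_total": het_all,
            "maf": maf,
            "pass": [not r for r in reasons],
            "reasons": [";".join(r) for r in reasons],
        }
    )
    return MarkerQCReport(table)


def segregation_distortion_test(
    population_genotypes: np.ndarray,
    founder_alleles: tuple[np.ndarray, np.ndarray],
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Chi-square 1:1 test of founder-allele segregation, per marker.

    ``population_genotypes``: dosages of the lines of one biparental
    population; ``founder_alleles``: allele vectors of its two founders.
    Uninformative markers (founders identical or a founder call missing) are
    skipped and flagged. Markers with p below the (optionally Bonferroni
    corrected) threshold are marked ``drop``.
    """
    a0, a1 = founder_alleles
    informative = (a0 != a1) & ~np.isnan(a0) & ~np.isnan(a1)
    d = population_genotypes
    with np.errstate(invalid="ignore"):
        n_obs = np.sum(~np.isnan(d), axis=0).astype(float)
        mean_dosage = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    # count of allele-1 lines (dosage contributes fractionally at het calls)
    n1 = np.nan_to_num(mean_dosage) * n_obs
    n0 = n_obs - n1
    # orient to founder-allele counts: founder 1 of the pair carries a0
    n_f1 = np.where(a0 == 1, n1, n0)
    n_f2 = n_obs - n_f1
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (n_f1 - n_f2) ** 2 / n_obs
    chi2 = np.where(informative & (n_obs > 0), chi2, np.nan)
    p = np.where(np.isnan(chi2), np.nan, stats.chi2.sf(np.nan_to_num(chi2), df=1))
    n_tested = int(np.sum(~np.isnan(chi2)))
    cutoff = alpha / max(n_tested, 1) if bonferroni else alpha
    drop = np.where(np.isnan(p), False, p < cutoff)
    return pd.DataFrame(
        {
            "chi2": chi2,
            "p": p,
            "informative": informative,
            "tested": ~np.isnan(chi2),
            "drop": drop,
        }
    )


def filter_lines(
    lines: LineGenotypes,
    founders: FounderGenotypes | None = None,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Line-level screen: heterozygosity caps and founder-consistency.

    Dent lines with >10% heterozygous calls and Flint lines with >25% are
    dropped. With founder genotypes supplied, a line is additionally dropped
    as off-type when more than ``max_offtype_fraction`` of its comparable
    calls are inconsistent with both of its population's founders (an allele
    neither founder carries, or a heterozygous call where the founders are
    identical).
    """
    th = thresholds or QCThresholds()
    d = lines.dosage
    with np.errstate(invalid="ignore"):
        het = np.nanmean(d == 0.5, axis=1)
    het = np.nan_to_num(het)
    cap = np.where(lines.info["group"] == "D", th.max_line_het_dent, th.max_line_het_flint)
    fail_het = het > cap

    offtype_frac = np.zeros(lines.n_lines)
    fail_off = np.zeros(lines.n_lines, dtype=bool)
    if founders is not None:
        for (group, pop), idx in lines.info.groupby(["group", "population"]).groups.items():
            rows = np.asarray(idx, dtype=int)
            a0, a1 = founders.pair_alleles(group, int(pop))
            ok_f = ~np.isnan(a0) & ~np.isnan(a1)
            sub = d[rows][:, ok_f]
            a0s, a1s = a0[ok_f], a1[ok_f]
            observed = ~np.isnan(sub)
            hom0_bad = (sub == 0.0) & (a0s != 0) & (a1s != 0)
            hom1_bad = (sub == 1.0) & (a0s != 1) & (a1s != 1)
            het_bad = (sub == 0.5) & (a0s == a1s)
            bad = hom0_bad | hom1_bad | het_bad
            n_cmp = observed.sum(axis=1)
            frac = np.divide(bad.sum(axis=1), n_cmp, out=np.zeros(len(rows)), where=n_cmp > 0)
            offtype_frac[rows] = frac
            fail_off[rows] = frac > th.max_offtype_fraction
    return pd.DataFrame(
        {
            "line_id": lines.info["line_id"],
            "group": lines.info["group"],
            "het_rate": het,
            "offtype_fraction": offtype_frac,
            "fail_het": fail_het,
            "fail_offtype": fail_off,
            "pass": ~(fail_het | fail_off),
        }
    )


def group_maf(lines: LineGenotypes) -> pd.DataFrame:
    """Within-group minor allele frequency per marker, on parental lines."""
    out = {}
    for g in ("D", "F"):
        sub = lines.dosage[lines.group_mask(g)]
        out[f"maf_{g}"] = _maf(sub)
    return pd.DataFrame(out, index=lines.markers)


def polymorphic_in_both_groups(lines: LineGenotypes, min_maf: float = 0.05) -> np.ndarray:
    """Scan-set flag: MAF strictly above ``min_maf`` within each group.

    Defines the marker set for the SNP within-group and Hybrid genotype
    models; the Founder alleles model scans all mapped markers.
    """
    maf = group_maf(lines)
    return (
        np.nan_to_num(maf["maf_D"].to_numpy()) > min_maf
    ) & (np.nan_to_num(maf["maf_F"].to_numpy()) > min_maf)
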