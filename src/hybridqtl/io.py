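"""TSV readers and writers for genotypes, maps, pedigrees and phenotypes.

All files are tab-separated with headers. Genotypes are line x marker dosage
matrices with values 0 / 0.5 / 1 / NA; maps carry chrom, marker, pos_cM;
pedigrees carry the hybrid and its two parents with population labels;
phenotypes are plot records (hybrid, environment, value).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GeneticMap, HybridPedigree, LineGenotypes

log = logging.getLogger("hybridqtl")

_VALID_DOSAGE = {0.0, 0.5, 1.0}


def read_map(path: str | Path) -> GeneticMap:
    t = pd.read_csv(path, sep="\t", dtype={"marker": str})
    missing = {"chrom", "marker", "pos_cM"} - set(t.columns)
    if missing:
        raise ValueError(f"map file {path}: missing columns {sorted(missing)}")
    sorted_t = t.sort_values(["chrom", "pos_cM"], kind="stable").reset_index(drop=True)
    if not sorted_t[["chrom", "marker"]].equals(t[["chrom", "marker"]].reset_index(drop=True)):
        log.warning("map %s had unsorted positions; rows re-sorted by (chrom, pos_cM)", path)
    return GeneticMap(sorted_t)


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path) -> LineGenotypes:
    """Genotype TSV: line_id, group, population, then one column per marker."""
    t = pd.read_csv(path, sep="\t", dtype={"line_id": str, "group": str})
    meta_cols = ["line_id", "group", "population"]
    missing = set(meta_cols) - set(t.columns)
    if missing:
        raise ValueError(f"genotype file {path}: missing columns {sorted(missing)}")
    markers = [c for c in t.columns if c not in meta_cols]
    dosage = t[markers].to_numpy(dtype=float)
    bad = ~np.isnan(dosage) & ~np.isin(dosage, [0.0, 0.5, 1.0])
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"genotype file {path}: invalid value {dosage[i, j]!r} for line "
            f"{t['line_id'].iloc[i]!r} at marker {markers[j]!r} (data row {i + 1})"
        )
    return LineGenotypes(dosage, t[meta_cols].copy(), pd.Index(markers))


def write_genotypes(lines: LineGenotypes, path: str | Path) -> None:
    t = lines.info[["line_id", "group", "population"]].copy()
    geno = pd.DataFrame(lines.dosage, columns=lines.markers)
    pd.concat([t, geno], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pedigree(path: str | Path) -> HybridPedigree:
    t = pd.read_csv(path, sep="\t", dtype={"hybrid_id": str, "dent_parent": str, "flint_parent": str})
    return HybridPedigree(t)


def write_pedigree(ped: HybridPedigree, path: str | Path) -> None:
    ped.table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype={"hybrid": str, "environment": str})
    missing = {"hybrid", "environment", "value"} - set(t.columns)
    if missing:
        raise ValueError(f"phenotype file {path}: missing columns {sorted(missing)}")
    return t


def write_phenotypes(plots: pd.DataFrame, path: str | Path) -> None:
    plots.to_csv(path, sep="\t", index=False)


def reconcile_markers(lines: LineGenotypes, gmap: GeneticMap) -> tuple[LineGenotypes, GeneticMap]:
    """Intersect genotype and map marker sets (map order wins)."""
    shared = gmap.markers[gmap.markers.isin(lines.markers)]
    frac = len(shared) / max(len(gmap.markers), 1)
    if frac < 0.5:
        raise ValueError(
            f"only {frac:.0%} of mapped markers present in the genotype file; "
            "check that the files belong together"
        )
    if len(shared) < len(gmap.markers) or len(shared) < len(lines.markers):
        log.warning(
            "marker reconciliation: %d mapped, %d genotyped, %d shared",
            len(gmap.markers),
            len(lines.markers),
            len(shared),
        )
    gmap2 = GeneticMap(gmap.table[gmap.table["marker"].isin(shared)].reset_index(drop=True))
    order = lines.markers.get_indexer(gmap2.markers)
    lines2 = LineGenotypes(lines.dosage[:, order], lines.info.copy(), gmap2.markers)
    return lines2, gmap2
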