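"""Core in-memory containers shared across the pipeline.

All tabular containers wrap pandas objects; genotype matrices are dense numpy
arrays (lines x markers) holding allele dosages 0 / 0.5 / 1 with NaN for
missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import GROUPS, POP_PAIRS


@dataclass
class GeneticMap:
    """Ordered marker positions in cM, one or more chromosomes.

    ``table`` has columns ``chrom`` (int), ``marker`` (str, unique genome-wide)
    and ``pos_cM`` (float, non-decreasing within a chromosome).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "marker", "pos_cM"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if self.table["marker"].duplicated().any():
            dup = self.table.loc[self.table["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicated marker id in map: {dup!r}")
        for chrom, grp in self.table.groupby("chrom"):
            pos = grp["pos_cM"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not sorted on chromosome {chrom}")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def markers(self) -> pd.Index:
        return pd.Index(self.table["marker"])

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos_cM(self) -> np.ndarray:
        return self.table["pos_cM"].to_numpy(dtype=float)

    def chromosome_slices(self) -> dict[int, slice]:
        """Contiguous row slice of each chromosome (markers are map-ordered)."""
        out: dict[int, slice] = {}
        chroms = self.chrom
        for c in pd.unique(chroms):
            idx = np.flatnonzero(chroms == c)
            out[int(c)] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def adjacent_distances(self) -> np.ndarray:
        """Distance in cM to the previous marker; NaN at each chromosome start."""
        d = np.diff(self.pos_cM, prepend=np.nan)
        starts = np.r_[True, self.chrom[1:] != self.chrom[:-1]]
        d[starts] = np.nan
        return d


@dataclass
class FounderGenotypes:
    """Biallelic calls for the founder inbred lines (fully homozygous).

    ``alleles`` is (n_founders x n_markers) with entries 0/1 (NaN = missing
    founder call); rows are ordered D founders then F founders.
    """

    alleles: np.ndarray
    founder_ids: list[str]
    group: np.ndarray  # "D"/"F" per row
    markers: pd.Index

    def group_rows(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.group == group)

    def pair_alleles(self, group: str, population: int) -> tuple[np.ndarray, np.ndarray]:
        """Allele vectors of the two founders of ``population`` (0..5) in ``group``."""
        i, j = POP_PAIRS[population]
        rows = self.group_rows(group)
        return self.alleles[rows[i]], self.alleles[rows[j]]


@dataclass
class LineGenotypes:
    """Genotypes of parental inbred lines with group/population labels.

    ``dosage``: (n_lines x n_markers), values in {0, 0.5, 1} or NaN.
    ``info``: per line ``line_id``, ``group`` ("D"/"F"), ``population`` (0..5).
    """

    dosage: np.ndarray
    info: pd.DataFrame
    markers: pd.Index

    def __post_init__(self) -> None:
        required = {"line_id", "group", "population"}
        if not required.issubset(self.info.columns):
            raise ValueError(f"line info needs columns {sorted(required)}")
        if self.dosage.shape != (len(self.info), len(self.markers)):
            raise ValueError("dosage shape inconsistent with info/markers")
        self.info = self.info.reset_index(drop=True)

    @property
    def n_lines(self) -> int:
        return len(self.info)

    def line_index(self) -> pd.Index:
        return pd.Index(self.info["line_id"])

    def group_mask(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return (self.info["group"] == group).to_numpy()

    def subset_lines(self, mask: np.ndarray) -> "LineGenotypes":
        return LineGenotypes(self.dosage[mask], self.info.loc[mask].copy(), self.markers)

    def subset_markers(self, mask: np.ndarray) -> "LineGenotypes":
        return LineGenotypes(self.dosage[:, mask], self.info.copy(), self.markers[mask])


@dataclass
class HybridPedigree:
    """Dent x Flint crosses: one row per hybrid.

    Columns: ``hybrid_id``, ``dent_parent``, ``flint_parent``, ``dent_pop``,
    ``flint_pop`` (populations 0..5).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"hybrid_id", "dent_parent", "flint_parent", "dent_pop", "flint_pop"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"pedigree needs columns {sorted(required)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_hybrids(self) -> int:
        return len(self.table)

    def validate_against(self, lines: LineGenotypes) -> None:
        ids = set(lines.line_index())
        for col, grp in (("dent_parent", "D"), ("flint_parent", "F")):
            missing = set(self.table[col]) - ids
            if missing:
                raise ValueError(f"{col} not in line genotypes: {sorted(missing)[:5]}")
        for col in ("dent_pop", "flint_pop"):
            bad = ~self.table[col].isin(range(6))
            if bad.any():
                raise ValueError(f"{col} outside 0..5 at rows {list(self.table.index[bad])[:5]}")


@dataclass
class FounderOriginProbs:
    """Posterior P(descent from founder 1 of the line's pair) per line x marker."""

    p_first: np.ndarray  # (n_lines x n_markers)
    info: pd.DataFrame  # line_id, group, population
    markers: pd.Index


@dataclass
class HybridFounderProbs:
    """Per hybrid x marker, probabilities of the transmitted allele's founder.

    ``dent`` and ``flint`` are (n_hybrids x n_markers x 4); each 4-vector sums
    to 1 and has support only on the parent population's two founders.
    """

    dent: np.ndarray
    flint: np.ndarray
    hybrid_ids: pd.Index
    markers: pd.Index


@dataclass
class LsMeans:
    """Adjusted hybrid means across environments."""

    table: pd.DataFrame  # hybrid, lsmean, n_env
    sigma2_E: float

    def aligned_to(self, hybrid_ids) -> np.ndarray:
        s = self.table.set_index("hybrid")["lsmean"]
        return s.loc[list(hybrid_ids)].to_numpy(dtype=float)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated design (see the simulator module)."""

    line_hap_origins: dict[str, np.ndarray]  # group -> (n_lines, 2, n_markers) int8
    line_info: dict[str, pd.DataFrame]
    transmitted: dict[str, np.ndarray]  # group -> (n_hybrids, n_markers) founder-in-pair 0/1
    qtl: pd.DataFrame  # chrom, pos_cM, marker, marker_index + effect payloads
    qtl_effects: list[dict]
    genetic_values: np.ndarray  # per hybrid, excludes e_h
    components: dict[str, np.ndarray]
    realized_variance: dict[str, float] = field(default_factory=dict)
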