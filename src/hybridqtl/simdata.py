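"""Synthetic factorial designs between two multiparental line populations.

Emulates the structure of a Dent x Flint hybrid QTL-mapping design: four
founder inbred lines per heterotic group, all six biparental populations per
group, doubled-haploid (DH) progeny in the Dent group and selfed (SSD) progeny
in the Flint group, an incomplete factorial in which most lines parent a
single hybrid, and multi-environment phenotypes generated from population
means, per-QTL GCA/SCA effects, random parental effects and residuals.

Meiosis uses the Haldane map function (no interference). SSD lines are
produced by explicit generation-by-generation selfing, so residual
heterozygosity arises at its natural rate (~2^-g per locus after g
generations) rather than being injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import POP_PAIRS, check_prob, haldane_r, substream
from .datatypes import (
    FounderGenotypes,
    GeneticMap,
    HybridPedigree,
    LineGenotypes,
    SimulationTruth,
)

# ---------------------------------------------------------------------------
# configuration


@dataclass
class MapSpec:
    n_chromosomes: int = 10
    chrom_length_cM: float = 160.0
    n_markers_per_chrom: int = 100
    spacing: str = "regular"  # or "uniform"

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.chrom_length_cM <= 0:
            raise ValueError("chrom_length_cM must be > 0")
        if self.n_markers_per_chrom < 2:
            raise ValueError("n_markers_per_chrom must be >= 2")
        if self.spacing not in ("regular", "uniform"):
            raise ValueError(f"unknown spacing {self.spacing!r}")


@dataclass
class FounderDivergence:
    """Per-marker allele structure of the founder panel.

    ``p_polymorphic``: probability a marker segregates within a group.
    ``p_shared_minor``: probability the two groups carry the same allele where
    a group is monomorphic (controls cross-group allele sharing).
    """

    p_polymorphic: float = 0.6
    p_shared_minor: float = 0.5

    def validate(self) -> None:
        check_prob(self.p_polymorphic, "p_polymorphic")
        check_prob(self.p_shared_minor, "p_shared_minor")


@dataclass
class QTLSpec:
    """One simulated QTL: GCA effect per founder and SCA per founder pair."""

    chrom: int
    pos_cM: float
    gca_dent: np.ndarray  # (4,)
    gca_flint: np.ndarray  # (4,)
    sca: np.ndarray  # (4, 4), [dent founder, flint founder]

    def __post_init__(self) -> None:
        self.gca_dent = np.asarray(self.gca_dent, dtype=float)
        self.gca_flint = np.asarray(self.gca_flint, dtype=float)
        self.sca = np.asarray(self.sca, dtype=float)
        if self.gca_dent.shape != (4,) or self.gca_flint.shape != (4,):
            raise ValueError("GCA effect vectors must have length 4")
        if self.sca.shape != (4, 4):
            raise ValueError("SCA effect matrix must be 4x4")


@dataclass
class VarianceSpec:
    sigma2_D: float = 0.0  # random Dent parental (GCA not at QTL)
    sigma2_F: float = 0.0  # random Flint parental
    sigma2_e: float = 1.0  # hybrid-level residual
    sigma2_env_plot: float = 0.0  # plot-level noise within environment

    def validate(self) -> None:
        for name in ("sigma2_D", "sigma2_F", "sigma2_e", "sigma2_env_plot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PopulationMeans:
    mu: float = 0.0
    dent: np.ndarray = field(default_factory=lambda: np.zeros(6))
    flint: np.ndarray = field(default_factory=lambda: np.zeros(6))
    interaction: np.ndarray = field(default_factory=lambda: np.zeros((6, 6)))

    def __post_init__(self) -> None:
        self.dent = np.asarray(self.dent, dtype=float)
        self.flint = np.asarray(self.flint, dtype=float)
        self.interaction = np.asarray(self.interaction, dtype=float)
        if self.dent.shape != (6,) or self.flint.shape != (6,):
            raise ValueError("population mean vectors must have length 6")
        if self.interaction.shape != (6, 6):
            raise ValueError("interaction means must be 6x6")


@dataclass
class SimConfig:
    """Full description of one synthetic design.

    Defaults mirror the study structure: 4 founders per group, the 6 founder
    pairs as populations in each group, DH Dent lines, Flint lines selfed for
    5 generations, 8 environments, and most lines contributing one hybrid
    (a minority two, a rare few three or four).
    """

    n_founders_per_group: int = 4
    populations: tuple = POP_PAIRS
    n_lines_per_population: int = 50
    line_type_group1: str = "DH"
    line_type_group2: str = "SSD"
    n_selfing_generations: int = 5
    residual_het_rate: float | None = None  # informational; het emerges from selfing
    map_spec: MapSpec = field(default_factory=MapSpec)
    founder_divergence: FounderDivergence = field(default_factory=FounderDivergence)
    qtl_spec: list[QTLSpec] = field(default_factory=list)
    variance: VarianceSpec = field(default_factory=VarianceSpec)
    population_means: PopulationMeans = field(default_factory=PopulationMeans)
    n_environments: int = 8
    hybrids_per_line_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.80, 2: 0.198, 3: 0.001, 4: 0.001}
    )
    missing_rate: float = 0.0
    genotyping_error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_founders_per_group != 4:
            raise ValueError("design is defined for 4 founders per group")
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("every founder pair may appear at most once per group")
        if self.n_lines_per_population < 1:
            raise ValueError("n_lines_per_population must be >= 1")
        if self.line_type_group1 != "DH" or self.line_type_group2 != "SSD":
            raise ValueError("group 1 must be DH, group 2 SSD")
        if self.n_selfing_generations < 1:
            raise ValueError("n_selfing_generations must be >= 1")
        self.map_spec.validate()
        self.founder_divergence.validate()
        self.variance.validate()
        if self.n_environments < 1:
            raise ValueError("n_environments must be >= 1")
        dist = self.hybrids_per_line_distribution
        if not dist or not set(dist) <= {1, 2, 3, 4}:
            raise ValueError("hybrids_per_line_distribution supports counts 1..4")
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ValueError("hybrids_per_line_distribution must sum to 1")
        check_prob(self.missing_rate, "missing_rate")
        check_prob(self.genotyping_error_rate, "genotyping_error_rate")


# ---------------------------------------------------------------------------
# map and founders


def simulate_map(map_spec: MapSpec, seed: int) -> GeneticMap:
    """Marker map with regular or uniform spacing, deterministic given seed."""
    map_spec.validate()
    rng = substream(seed, "map")
    rows = []
    for c in range(1, map_spec.n_chromosomes + 1):
        m = map_spec.n_markers_per_chrom
        if map_spec.spacing == "regular":
            pos = np.linspace(0.0, map_spec.chrom_length_cM, m)
        else:
            pos = np.sort(rng.uniform(0.0, map_spec.chrom_length_cM, size=m))
        for k, p in enumerate(pos, start=1):
            rows.append((c, f"c{c}_m{k}", float(p)))
    return GeneticMap(pd.DataFrame(rows, columns=["chrom", "marker", "pos_cM"]))


def simulate_founders(gmap: GeneticMap, config: SimConfig, seed: int) -> FounderGenotypes:
    """Homozygous founder genotypes, 4 per group, drawn independently per marker."""
    config.validate()
    rng = substream(seed, "founders")
    m = gmap.n_markers
    div = config.founder_divergence
    base = rng.integers(0, 2, size=m)  # shared reference allele
    alleles = np.empty((8, m), dtype=float)
    for g, rows in (("D", slice(0, 4)), ("F", slice(4, 8))):
        poly = rng.random(m) < div.p_polymorphic
        mono_allele = np.where(rng.random(m) < div.p_shared_minor, base, 1 - base)
        a = rng.integers(0, 2, size=(4, m)).astype(float)
        # condition polymorphic markers on actually segregating: flip one founder
        allsame = a.min(axis=0) == a.max(axis=0)
        fix = poly & allsame
        flip_row = rng.integers(0, 4, size=m)
        a[flip_row[fix], np.flatnonzero(fix)] = 1 - a[flip_row[fix], np.flatnonzero(fix)]
        a[:, ~poly] = mono_allele[~poly]
        alleles[rows] = a
    ids = [f"{g}0{k}" for g in "DF" for k in range(1, 5)]
    group = np.array(["D"] * 4 + ["F"] * 4)
    return FounderGenotypes(alleles, ids, group, gmap.markers)


# ---------------------------------------------------------------------------
# meiosis and line development


def _gametes(hapA: np.ndarray, hapB: np.ndarray, rec: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per row of (hapA, hapB).

    ``rec``: per-marker probability of switching parental haplotype relative
    to the previous marker; entry 0 and chromosome starts must be 0.5 (free
    recombination across chromosomes, random start phase).
    """
    n, m = hapA.shape
    switch = rng.random((n, m)) < rec[None, :]
    phase = np.cumsum(switch, axis=1) % 2
    return np.where(phase == 0, hapA, hapB)


def _recombination_profile(gmap: GeneticMap) -> np.ndarray:
    d = gmap.adjacent_distances()
    rec = haldane_r(np.nan_to_num(d, nan=0.0))
    rec[np.isnan(d)] = 0.5
    return rec


def simulate_biparental_lines(
    founders: FounderGenotypes,
    group: str,
    population: int,
    n_lines: int,
    line_type: str,
    gmap: GeneticMap,
    seed: int,
    n_selfing_generations: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Develop ``n_lines`` inbred lines from the cross of one founder pair.

    Returns ``(dosage, hap_origins)`` with dosage (n_lines x n_markers) in
    {0, 0.5, 1} and hap_origins (n_lines x 2 x n_markers) holding the
    within-pair founder index (0/1) of each haplotype.

    DH lines are a single recombinant F1 gamete doubled; SSD lines are selfed
    generation by generation from the F1, each generation drawing two
    independent gametes from the current plant.
    """
    rng = substream(seed, f"meiosis:{group}{population}:{line_type}")
    m = gmap.n_markers
    rec = _recombination_profile(gmap)
    f1_hapA = np.zeros((n_lines, m), dtype=np.int8)
    f1_hapB = np.ones((n_lines, m), dtype=np.int8)
    if line_type == "DH":
        g = _gametes(f1_hapA, f1_hapB, rec, rng).astype(np.int8)
        h1, h2 = g, g
    elif line_type == "SSD":
        h1, h2 = f1_hapA, f1_hapB
        for _ in range(n_selfing_generations):
            new1 = _gametes(h1, h2, rec, rng).astype(np.int8)
            new2 = _gametes(h1, h2, rec, rng).astype(np.int8)
            h1, h2 = new1, new2
    else:
        raise ValueError(f"unknown line_type {line_type!r}")
    a0, a1 = founders.pair_alleles(group, population)
    allele1 = np.where(h1 == 0, a0[None, :], a1[None, :])
    allele2 = np.where(h2 == 0, a0[None, :], a1[None, :])
    dosage = (allele1 + allele2) / 2.0
    origins = np.stack([h1, h2], axis=1)
    return dosage, origins


def _develop_group(
    founders: FounderGenotypes,
    group: str,
    config: SimConfig,
    gmap: GeneticMap,
    seed: int,
) -> tuple[LineGenotypes, np.ndarray]:
    line_type = "DH" if group == "D" else "SSD"
    dosages, origins, infos = [], [], []
    for pop in range(len(config.populations)):
        d, o = simulate_biparental_lines(
            founders,
            group,
            pop,
            config.n_lines_per_population,
            line_type,
            gmap,
            seed,
            config.n_selfing_generations,
        )
        dosages.append(d)
        origins.append(o)
        infos.append(
            pd.DataFrame(
                {
                    "line_id": [f"{group}{pop + 1}_L{k + 1:04d}" for k in range(len(d))],
                    "group": group,
                    "population": pop,
                }
            )
        )
    geno = LineGenotypes(np.vstack(dosages), pd.concat(infos, ignore_index=True), founders.markers)
    return geno, np.concatenate(origins, axis=0)


# ---------------------------------------------------------------------------
# mating design


def simulate_factorial(
    lines_D: pd.DataFrame,
    lines_F: pd.DataFrame,
    hybrids_per_line_distribution: dict[int, float],
    seed: int,
) -> HybridPedigree:
    """Incomplete factorial between the two groups of lines.

    Each line's number of hybrids is drawn from the configured distribution;
    parent pairs are unique; every (Dent population, Flint population)
    combination receives at least one hybrid whenever lines of both
    populations exist.
    """
    if len(lines_D) == 0 or len(lines_F) == 0:
        raise ValueError("both groups must contain lines")
    rng = substream(seed, "mating")
    counts = sorted(hybrids_per_line_distribution)
    probs = np.array([hybrids_per_line_distribution[c] for c in counts])
    cD = rng.choice(counts, size=len(lines_D), p=probs)
    cF = rng.choice(counts, size=len(lines_F), p=probs)
    if cD.sum() > len(lines_D) * len(lines_F) or cF.sum() > len(lines_D) * len(lines_F):
        raise ValueError("requested more hybrids than available parent pairs")
    slots_D = np.repeat(np.arange(len(lines_D)), cD)
    slots_F = np.repeat(np.arange(len(lines_F)), cF)
    rng.shuffle(slots_D)
    rng.shuffle(slots_F)
    n_h = min(len(slots_D), len(slots_F))
    d = slots_D[:n_h].copy()
    f = slots_F[:n_h].copy()

    def _dups() -> np.ndarray:
        pairs = d.astype(np.int64) * len(lines_F) + f
        _, first = np.unique(pairs, return_index=True)
        mask = np.ones(n_h, dtype=bool)
        mask[first] = False
        return np.flatnonzero(mask)

    for _ in range(200):
        dup = _dups()
        if len(dup) == 0:
            break
        swap_with = rng.integers(0, n_h, size=len(dup))
        f[dup], f[swap_with] = f[swap_with], f[dup].copy()
    else:
        keep = np.ones(n_h, dtype=bool)
        keep[_dups()] = False
        d, f = d[keep], f[keep]
        n_h = len(d)

    dpop = lines_D["population"].to_numpy()[d]
    fpop = lines_F["population"].to_numpy()[f]
    # guarantee coverage of all feasible population combinations
    present_D = set(lines_D["population"])
    present_F = set(lines_F["population"])
    for p in sorted(present_D):
        for q in sorted(present_F):
            if np.any((dpop == p) & (fpop == q)):
                continue
            combo = dpop.astype(np.int64) * 6 + fpop
            counts_by_combo = pd.Series(combo).value_counts()
            rich = counts_by_combo[counts_by_combo >= 2].index
            cand_i = np.flatnonzero((dpop == p) & pd.Series(combo).isin(rich).to_numpy())
            cand_j = np.flatnonzero((fpop == q) & pd.Series(combo).isin(rich).to_numpy())
            if len(cand_i) == 0 or len(cand_j) == 0:
                continue
            i = int(rng.choice(cand_i))
            j = int(rng.choice(cand_j))
            if i != j:
                f[i], f[j] = f[j], f[i]
                fpop[i], fpop[j] = fpop[j], fpop[i]
    table = pd.DataFrame(
        {
            "hybrid_id": [f"H{k + 1:05d}" for k in range(n_h)],
            "dent_parent": lines_D["line_id"].to_numpy()[d],
            "flint_parent": lines_F["line_id"].to_numpy()[f],
            "dent_pop": lines_D["population"].to_numpy()[d],
            "flint_pop": lines_F["population"].to_numpy()[f],
        }
    )
    # drop any duplicate pairs a coverage swap could have created
    table = table.drop_duplicates(["dent_parent", "flint_parent"]).reset_index(drop=True)
    return HybridPedigree(table)


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class SimulatedDesign:
    """Everything one synthetic study produces."""

    config: SimConfig
    gmap: GeneticMap
    founders: FounderGenotypes
    lines: LineGenotypes
    pedigree: HybridPedigree
    plots: pd.DataFrame  # hybrid, environment, value
    truth: SimulationTruth


def _qtl_marker_indices(gmap: GeneticMap, qtl_spec: list[QTLSpec]) -> list[int]:
    """Snap each QTL to the nearest mapped marker on its chromosome."""
    idx = []
    for q in qtl_spec:
        on = np.flatnonzero(gmap.chrom == q.chrom)
        if len(on) == 0:
            raise ValueError(f"QTL chromosome {q.chrom} not on the map")
        idx.append(int(on[np.argmin(np.abs(gmap.pos_cM[on] - q.pos_cM))]))
    return idx


def simulate_phenotypes(
    pedigree: HybridPedigree,
    truth_origins: dict[str, np.ndarray],
    line_info: dict[str, pd.DataFrame],
    gmap: GeneticMap,
    config: SimConfig,
    seed: int,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Plot-level phenotypes and the full ground truth of the generating model.

    A hybrid's genetic value is its population mean plus, per QTL, the Dent
    GCA, Flint GCA and SCA effects of the founder alleles it received, plus
    the random parental effects. The hybrid-level residual, fixed environment
    effects and plot noise are added on top.
    """
    rng = substream(seed, "phenotype")
    ped = pedigree.table
    n_h = len(ped)
    rec = _recombination_profile(gmap)
    pm = config.population_means
    var = config.variance

    transmitted: dict[str, np.ndarray] = {}
    parent_row: dict[str, np.ndarray] = {}
    for group, col in (("D", "dent_parent"), ("F", "flint_parent")):
        info = line_info[group]
        row_of = pd.Series(np.arange(len(info)), index=info["line_id"])
        rows = row_of.loc[ped[col]].to_numpy()
        parent_row[group] = rows
        h1 = truth_origins[group][rows, 0, :]
        h2 = truth_origins[group][rows, 1, :]
        transmitted[group] = _gametes(h1, h2, rec, rng).astype(np.int8)

    qtl_idx = _qtl_marker_indices(gmap, config.qtl_spec)
    pair_arr = np.asarray(config.populations)  # (6, 2) founder indices
    qtl_part = np.zeros(n_h)
    dpop = ped["dent_pop"].to_numpy()
    fpop = ped["flint_pop"].to_numpy()
    for q, m in zip(config.qtl_spec, qtl_idx):
        fD = pair_arr[dpop, transmitted["D"][:, m]]
        fF = pair_arr[fpop, transmitted["F"][:, m]]
        qtl_part += q.gca_dent[fD] + q.gca_flint[fF] + q.sca[fD, fF]

    uD_all = rng.normal(0.0, np.sqrt(var.sigma2_D), size=len(line_info["D"]))
    uF_all = rng.normal(0.0, np.sqrt(var.sigma2_F), size=len(line_info["F"]))
    uD = uD_all[parent_row["D"]]
    uF = uF_all[parent_row["F"]]
    pop_part = pm.mu + pm.dent[dpop] + pm.flint[fpop] + pm.interaction[dpop, fpop]
    genetic = pop_part + qtl_part + uD + uF
    e_h = rng.normal(0.0, np.sqrt(var.sigma2_e), size=n_h)
    # environment effects share the plot-level scale: one knob for field noise
    env_effects = rng.normal(0.0, np.sqrt(var.sigma2_env_plot), size=config.n_environments)

    frames = []
    for l in range(config.n_environments):
        noise = rng.normal(0.0, np.sqrt(var.sigma2_env_plot), size=n_h)
        frames.append(
            pd.DataFrame(
                {
                    "hybrid": ped["hybrid_id"],
                    "environment": f"env{l + 1}",
                    "value": genetic + e_h + env_effects[l] + noise,
                }
            )
        )
    plots = pd.concat(frames, ignore_index=True)

    qtl_table = pd.DataFrame(
        {
            "chrom": [q.chrom for q in config.qtl_spec],
            "pos_cM": [gmap.pos_cM[m] for m in qtl_idx],
            "marker": [gmap.markers[m] for m in qtl_idx],
            "marker_index": qtl_idx,
        }
    )
    truth = SimulationTruth(
        line_hap_origins=truth_origins,
        line_info=line_info,
        transmitted=transmitted,
        qtl=qtl_table,
        qtl_effects=[
            {"gca_dent": q.gca_dent, "gca_flint": q.gca_flint, "sca": q.sca}
            for q in config.qtl_spec
        ],
        genetic_values=genetic,
        components={
            "population": pop_part,
            "qtl": qtl_part,
            "u_D": uD,
            "u_F": uF,
            "e_h": e_h,
            "env_effects": env_effects,
        },
        realized_variance={
            "sigma2_D": float(np.var(uD_all, ddof=1)) if len(uD_all) > 1 else 0.0,
            "sigma2_F": float(np.var(uF_all, ddof=1)) if len(uF_all) > 1 else 0.0,
            "sigma2_e": float(np.var(e_h, ddof=1)) if n_h > 1 else 0.0,
            "var_qtl": float(np.var(qtl_part, ddof=1)) if n_h > 1 else 0.0,
            "var_population": float(np.var(pop_part, ddof=1)) if n_h > 1 else 0.0,
        },
    )
    return plots, truth


# ---------------------------------------------------------------------------
# end-to-end


def _apply_genotyping_noise(geno: LineGenotypes, config: SimConfig, rng: np.random.Generator) -> None:
    if config.genotyping_error_rate > 0:
        err = rng.random(geno.dosage.shape) < config.genotyping_error_rate
        states = np.array([0.0, 0.5, 1.0])
        shift = rng.integers(1, 3, size=geno.dosage.shape)
        cur = np.searchsorted(states, np.nan_to_num(geno.dosage, nan=0.0))
        geno.dosage[err] = states[(cur[err] + shift[err]) % 3]
    if config.missing_rate > 0:
        miss = rng.random(geno.dosage.shape) < config.missing_rate
        geno.dosage[miss] = np.nan


def simulate_design(config: SimConfig) -> SimulatedDesign:
    """Run the whole generator: map, founders, lines, factorial, phenotypes."""
    config.validate()
    gmap = simulate_map(config.map_spec, config.seed)
    founders = simulate_founders(gmap, config, config.seed)
    lines_by_group: dict[str, LineGenotypes] = {}
    origins: dict[str, np.ndarray] = {}
    for group in ("D", "F"):
        geno, orig = _develop_group(founders, group, config, gmap, config.seed)
        lines_by_group[group] = geno
        origins[group] = orig
    pedigree = simulate_factorial(
        lines_by_group["D"].info,
        lines_by_group["F"].info,
        config.hybrids_per_line_distribution,
        config.seed,
    )
    plots, truth = simulate_phenotypes(
        pedigree,
        origins,
        {g: lines_by_group[g].info for g in ("D", "F")},
        gmap,
        config,
        config.seed,
    )
    lines = LineGenotypes(
        np.vstack([lines_by_group["D"].dosage, lines_by_group["F"].dosage]),
        pd.concat([lines_by_group["D"].info, lines_by_group["F"].info], ignore_index=True),
        gmap.markers,
    )
    _apply_genotyping_noise(lines, config, substream(config.seed, "genotyping"))
    pedigree.validate_against(lines)
    return SimulatedDesign(config, gmap, founders, lines, pedigree, plots, truth)
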