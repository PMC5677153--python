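"""Fixed-effect design matrices: population structure and the three QTL codings.

Population structure enters every model through Dent-population, Flint-
population and interaction indicators (A, B, C), plus parent incidence
matrices Z_D, Z_F for the random parental effects.

Per marker, the QTL block is coded under one of three models:

* ``founder_alleles`` — 4 Dent and 4 Flint founder-transmission probability
  columns (GCA) plus their 16 elementwise products (SCA); identifiability is
  obtained by dropping a reference founder per group and every SCA column
  involving a reference founder, leaving 3 + 3 + 9 = 15 estimable effects;
* ``snp_within_group`` — per-group minor-allele dosage of the transmitting
  parent (0 / 0.5 / 1) and the Hadamard product of the two (1 + 1 + 1 d.f.);
* ``hybrid_genotype`` — additive coding Xa in {-1, -0.5, 0, 0.5, 1} and
  dominance coding Xd in {0, 0.5, 1} of the hybrid's own genotype with the
  minor allele defined on the pooled parents (1 + 1 d.f.).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import HybridPedigree

MODELS = ("founder_alleles", "snp_within_group", "hybrid_genotype")


@dataclass
class PopulationDesign:
    A: np.ndarray  # hybrids x 6 Dent-population indicators
    B: np.ndarray  # hybrids x 6 Flint-population indicators
    C: np.ndarray  # hybrids x 36 combination indicators, col = 6*dent + flint
    Z_D: np.ndarray  # hybrids x N_D parent incidence
    Z_F: np.ndarray
    dent_parents: pd.Index
    flint_parents: pd.Index


def build_population_design(pedigree: HybridPedigree) -> PopulationDesign:
    ped = pedigree.table
    n = len(ped)
    for col in ("dent_pop", "flint_pop"):
        if not ped[col].isin(range(6)).all():
            bad = ped.loc[~ped[col].isin(range(6)), col].iloc[0]
            raise ValueError(f"unknown population label {bad!r} in {col}")
    A = np.zeros((n, 6))
    B = np.zeros((n, 6))
    A[np.arange(n), ped["dent_pop"]] = 1.0
    B[np.arange(n), ped["flint_pop"]] = 1.0
    C = np.zeros((n, 36))
    C[np.arange(n), 6 * ped["dent_pop"].to_numpy() + ped["flint_pop"].to_numpy()] = 1.0
    dent_parents = pd.Index(pd.unique(ped["dent_parent"]))
    flint_parents = pd.Index(pd.unique(ped["flint_parent"]))
    Z_D = np.zeros((n, len(dent_parents)))
    Z_F = np.zeros((n, len(flint_parents)))
    Z_D[np.arange(n), dent_parents.get_indexer(ped["dent_parent"])] = 1.0
    Z_F[np.arange(n), flint_parents.get_indexer(ped["flint_parent"])] = 1.0
    return PopulationDesign(A, B, C, Z_D, Z_F, dent_parents, flint_parents)


def base_fixed_matrix(pop: PopulationDesign) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded population terms, all-zero columns dropped.

    On a design where all 36 combinations occur, [1 | A | B | C] has rank 36
    and this matrix has exactly 36 columns.
    """
    cols = [np.ones(pop.A.shape[0])]
    names = ["intercept"]
    for j in range(1, 6):
        cols.append(pop.A[:, j])
        names.append(f"dentpop{j + 1}")
    for j in range(1, 6):
        cols.append(pop.B[:, j])
        names.append(f"flintpop{j + 1}")
    for i in range(1, 6):
        for j in range(1, 6):
            cols.append(pop.C[:, 6 * i + j])
            names.append(f"inter{i + 1}x{j + 1}")
    X = np.column_stack(cols)
    keep = np.abs(X).sum(axis=0) > 0
    return X[:, keep], [nm for nm, k in zip(names, keep) if k]


@dataclass
class QTLDesign:
    """QTL columns at one marker: full coding and its estimable reduction."""

    model: str
    full: np.ndarray
    reduced: np.ndarray
    names: list[str]
    components: dict[str, np.ndarray]  # component -> column indices into reduced

    @property
    def nominal_df(self) -> int:
        return self.reduced.shape[1]


#: Helmert contrasts over 4 founders: columns orthogonal to the row-sum
#: constraint, giving sum-to-zero effect parametrizations
_HELMERT4 = np.array(
    [
        [1.0, 1.0, 1.0],
        [-1.0, 1.0, 1.0],
        [0.0, -2.0, 1.0],
        [0.0, 0.0, -3.0],
    ]
)


def build_founder_design(dent_probs: np.ndarray, flint_probs: np.ndarray, tol: float = 1e-6) -> QTLDesign:
    """Founder alleles coding at one marker.

    ``dent_probs``/``flint_probs``: (n x 4) transmission probabilities. The
    16 SCA columns of ``full`` are the elementwise products
    X_DF[:, 4*i + j] = X_D[:, i] * X_F[:, j]. The estimable reduction maps
    each group's 4 probability columns through sum-to-zero (Helmert)
    contrasts (3 GCA columns per group) and the 16 products through the
    contrast tensor product (9 SCA columns): the span given an intercept is
    identical to dropping a reference founder, but the GCA and SCA component
    tests become the standard factorial main-effect and interaction tests
    instead of reference-cell contrasts.
    """
    for name, p in (("dent", dent_probs), ("flint", flint_probs)):
        if np.any(np.abs(p.sum(axis=1) - 1.0) > tol):
            raise ValueError(f"{name} founder probabilities do not sum to 1")
    n = dent_probs.shape[0]
    X_DF3 = dent_probs[:, :, None] * flint_probs[:, None, :]
    X_DF = X_DF3.reshape(n, 16)
    full = np.hstack([dent_probs, flint_probs, X_DF])
    H = _HELMERT4
    gca_D = dent_probs @ H
    gca_F = flint_probs @ H
    sca = np.einsum("nij,ia,jb->nab", X_DF3, H, H).reshape(n, 9)
    reduced = np.hstack([gca_D, gca_F, sca])
    names = (
        [f"gcaD_c{k + 1}" for k in range(3)]
        + [f"gcaF_c{k + 1}" for k in range(3)]
        + [f"sca_c{a + 1}{b + 1}" for a in range(3) for b in range(3)]
    )
    components = {
        "GCA_D": np.arange(0, 3),
        "GCA_F": np.arange(3, 6),
        "SCA": np.arange(6, 15),
    }
    return QTLDesign("founder_alleles", full, reduced, names, components)


def _orient_minor(dosage: np.ndarray, minor_is_one: bool) -> np.ndarray:
    return dosage if minor_is_one else 1.0 - dosage


def build_snp_design(
    dent_parent_dosage: np.ndarray,
    flint_parent_dosage: np.ndarray,
    minor_is_one_dent: bool,
    minor_is_one_flint: bool,
) -> QTLDesign:
    """SNP within-group coding at one marker.

    Transmitting-parent genotype coded 0 for major-allele homozygotes, 1 for
    minor-allele homozygotes, 0.5 for heterozygotes, with the minor allele
    defined within each group; the SCA column is the Hadamard product.
    Imputed fractional dosages pass through in [0, 1].
    """
    for name, d in (("dent", dent_parent_dosage), ("flint", flint_parent_dosage)):
        if np.nanmin(d) == np.nanmax(d):
            raise ValueError(
                f"marker monomorphic among {name} parents; restrict the scan to "
                "markers polymorphic in both groups"
            )
    x_D = _orient_minor(dent_parent_dosage.astype(float), minor_is_one_dent)
    x_F = _orient_minor(flint_parent_dosage.astype(float), minor_is_one_flint)
    x_DF = x_D * x_F
    full = np.column_stack([x_D, x_F, x_DF])
    components = {"GCA_D": np.array([0]), "GCA_F": np.array([1]), "SCA": np.array([2])}
    return QTLDesign("snp_within_group", full, full.copy(), ["snpD", "snpF", "snpDF"], components)


def build_hybrid_design(
    dent_parent_dosage: np.ndarray,
    flint_parent_dosage: np.ndarray,
    minor_is_one_pooled: bool,
) -> QTLDesign:
    """Hybrid genotype coding at one marker (pooled minor allele).

    Xa is -1 / 0 / 1 for major-homozygous, heterozygous and minor-homozygous
    hybrids, with +-0.5 when a homozygous Dent parent meets a heterozygous
    Flint parent; Xd is 0 for homozygous hybrids, 1 for heterozygous ones and
    0.5 for the Dent-homozygous x Flint-heterozygous case. Dent parents are
    doubled haploids, so a heterozygous Dent call is a contract violation.
    """
    if np.any(dent_parent_dosage == 0.5):
        raise ValueError("heterozygous Dent parent: DH contract violated upstream")
    s_D = _orient_minor(dent_parent_dosage.astype(float), minor_is_one_pooled)
    s_F = _orient_minor(flint_parent_dosage.astype(float), minor_is_one_pooled)
    x_a = s_D + s_F - 1.0
    x_d = s_D + s_F - 2.0 * s_D * s_F
    full = np.column_stack([x_a, x_d])
    components = {"additive": np.array([0]), "dominance": np.array([1])}
    return QTLDesign("hybrid_genotype", full, full.copy(), ["Xa", "Xd"], components)


def minor_allele_is_one(dosage: np.ndarray) -> np.ndarray:
    """Per-marker flag: allele 1 is the minor allele (frequency tie -> allele 0).

    Computed on retained parental lines and frozen; ties at exactly 0.5 are
    broken towards the lexicographically first allele, 0.
    """
    with np.errstate(invalid="ignore"):
        freq1 = np.nanmean(dosage, axis=0)
    return np.nan_to_num(freq1, nan=1.0) < 0.5


def parent_dosage_matrix(
    pedigree: HybridPedigree,
    line_dosage: np.ndarray,
    line_ids: pd.Index,
    parent_col: str,
) -> np.ndarray:
    """(n_hybrids x n_markers) dosage of each hybrid's parent in one group."""
    rows = line_ids.get_indexer(pedigree.table[parent_col])
    if np.any(rows < 0):
        missing = pedigree.table[parent_col][rows < 0].iloc[0]
        raise ValueError(f"parent {missing!r} absent from line genotypes")
    return line_dosage[rows]
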