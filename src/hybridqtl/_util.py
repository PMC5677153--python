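"""Shared primitives: map distances, recombination, seeded substreams."""

from __future__ import annotations

import zlib

import numpy as np

#: the six unordered pairs of four founders, in lexicographic order; population
#: k of a group descends from founders POP_PAIRS[k]
POP_PAIRS: tuple[tuple[int, int], ...] = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

GROUPS = ("D", "F")


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def ssd_effective_r(r: np.ndarray | float) -> np.ndarray | float:
    """Effective recombination after many generations of selfing: r* = 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random stream derived from a master seed.

    Each pipeline stage (map, founders, meiosis, mating, phenotype, ...) draws
    from its own stream so stages are reproducible in isolation.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


def check_prob(x: float, name: str) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {x!r}")
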