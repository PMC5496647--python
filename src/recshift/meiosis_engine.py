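"""Meiosis: hotspot-restricted crossover sampling and gamete formation.

Crossovers can only occur inside recombination hotspot regions.  Each of the
H hotspots on a chromosome independently receives at most one crossover per
meiosis, with probability 1/H (Bernoulli, no interference), so the expected
number of crossovers per chromosome per meiosis is exactly 1 — i.e. every
chromosome is 1 Morgan and a 10-chromosome genome is 10 Morgan.  With 25
hotspots the per-hotspot probability is 0.04, with 50 it is 0.02, with 100
it is 0.01.  Within a hotspot the crossover position is uniform.

Gametes start on a uniformly chosen parental haplotype and switch at every
crossover; a site lying exactly at a crossover position belongs to the
segment on the right (half-open convention).  There is no obligate chiasma:
a chromosome transmits without crossover with probability (1-1/H)^H ~ 1/e.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import BoundsError, ConfigurationError
from .genome_architecture import RegionMap

__all__ = ["CrossoverSet", "sample_crossovers", "sample_crossover_counts", "make_gamete"]


@dataclass(eq=False)
class CrossoverSet:
    """Sorted crossover positions (bp) per chromosome for one meiosis."""

    positions: list[np.ndarray]
    chromosome_length_bp: int

    @property
    def total(self) -> int:
        return int(sum(len(p) for p in self.positions))


def _check_hotspots(region_map: RegionMap) -> int:
    h = region_map.n_hotspots_per_chromosome
    if h == 0:
        raise ConfigurationError("region map has a chromosome with zero hotspots")
    return h


def sample_crossovers(region_map: RegionMap, rng: np.random.Generator) -> CrossoverSet:
    """Sample one meiosis: Bernoulli(1/H) per hotspot, uniform within region."""
    h = _check_hotspots(region_map)
    length = region_map.region_length_bp
    out = []
    for c in range(region_map.n_chromosomes):
        starts = region_map.hotspot_starts(c)
        occurred = rng.random(h) < 1.0 / h
        pos = starts[occurred] + rng.random(int(occurred.sum())) * length
        out.append(pos)  # starts ascending => positions ascending
    return CrossoverSet(positions=out, chromosome_length_bp=region_map.chromosome_length_bp)


def sample_crossover_counts(
    region_map: RegionMap, n_meioses: int, rng: np.random.Generator
) -> np.ndarray:
    """Crossover counts for many meioses, shape ``(n_meioses, n_chromosomes)``.

    Vectorised counterpart of :func:`sample_crossovers` (identical Bernoulli
    model; positions are not materialised).  Used for map-length estimation.
    """
    h = _check_hotspots(region_map)
    counts = np.empty((n_meioses, region_map.n_chromosomes), dtype=np.int64)
    for c in range(region_map.n_chromosomes):
        counts[:, c] = (rng.random((n_meioses, h)) < 1.0 / h).sum(axis=1)
    return counts


def make_gamete(
    haplotype_pair: list[np.ndarray],
    site_positions: list[np.ndarray],
    crossovers: CrossoverSet,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Form one gamete from a parental haplotype pair.

    Parameters
    ----------
    haplotype_pair
        Per chromosome, array of shape ``(2, n_sites)`` with the two
        parental haplotypes.
    site_positions
        Per chromosome, sorted bp positions of the sites.
    crossovers
        Crossover positions from :func:`sample_crossovers`.
    rng
        Source of the per-chromosome starting-haplotype coin flips.
    """
    gamete = []
    for c, (pair, pos) in enumerate(zip(haplotype_pair, site_positions)):
        xpos = crossovers.positions[c]
        if len(xpos) and (xpos[0] < 0 or xpos[-1] >= crossovers.chromosome_length_bp):
            raise BoundsError(f"chromosome {c + 1}: crossover outside chromosome")
        start = int(rng.integers(2))
        # a site at exactly a crossover position lies right of the breakpoint
        n_breaks_left = np.searchsorted(xpos, pos, side="right")
        active = (start + n_breaks_left) % 2
        gamete.append(np.where(active == 0, pair[0], pair[1]))
    return gamete


def _gamete_batch(
    parent_haplotypes: np.ndarray,
    parent_rows: np.ndarray,
    site_positions: np.ndarray,
    starts: np.ndarray,
    region_length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gametes for many meioses on one chromosome.

    ``parent_haplotypes``: (n_parents, 2, n_sites); ``parent_rows``: (m,)
    row index of the parent for each meiosis.  RNG draw order per call:
    occurrence matrix, within-region offsets, starting haplotypes.  Returns
    an ``(m, n_sites)`` allele matrix.
    """
    m = len(parent_rows)
    h = len(starts)
    occurred = rng.random((m, h)) < 1.0 / h
    offsets = rng.random((m, h)) * region_length
    start_hap = rng.integers(0, 2, size=m)
    out = np.empty((m, parent_haplotypes.shape[2]), dtype=parent_haplotypes.dtype)
    for i in range(m):
        xpos = starts[occurred[i]] + offsets[i, occurred[i]]
        active = (start_hap[i] + np.searchsorted(xpos, site_positions, side="right")) % 2
        pair = parent_haplotypes[parent_rows[i]]
        out[i] = np.where(active == 0, pair[0], pair[1])
    return out
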