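"""Region maps: recombination hotspots and QTN clusters along each chromosome.

Each chromosome is partitioned into ``n_regions`` equal-length windows.
Exactly 10% of the windows are "active": they are recombination hotspots
and/or QTN clusters, evenly spaced with a period of 10 windows.  The three
trait-architecture scenarios differ only in where QTN clusters sit relative
to hotspots:

* scenario 1 — QTN anywhere on the chromosome (no clusters);
* scenario 2 — QTN clustered immediately *adjacent* to hotspots, so a single
  right-shift of the hotspots lands them exactly on the QTN clusters;
* scenario 3 — QTN clustered *inside* hotspots, so a shift moves
  recombination away from the QTN.

Hotspot shifting (``shift_hotspots``) moves every hotspot one window to the
right and models an intervention such as re-targeting PRDM9 binding sites.
Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import BoundsError, LayoutError, StateError

__all__ = ["RegionMap", "build_region_map", "shift_hotspots", "region_of"]

#: fraction of regions per chromosome that are active (hotspot / QTN cluster)
ACTIVE_FRACTION = 0.10
#: spacing (in regions) between consecutive active regions
ACTIVE_PERIOD = 10


@dataclass(frozen=True, eq=False)
class RegionMap:
    """Per-chromosome layout of recombination hotspots and QTN clusters.

    The same deterministic lattice is used on every chromosome.  Flags are
    boolean arrays of shape ``(n_chromosomes, n_regions)``.
    """

    n_regions: int
    region_length_bp: int
    n_chromosomes: int
    chromosome_length_bp: int
    scenario: int
    shifted: bool
    hotspot_flags: np.ndarray = field(repr=False)
    qtn_cluster_flags: np.ndarray = field(repr=False)

    @property
    def n_hotspots_per_chromosome(self) -> int:
        return int(self.hotspot_flags[0].sum())

    @property
    def recombination_probability(self) -> float:
        """Per-hotspot Bernoulli crossover probability (1 / #hotspots)."""
        return 1.0 / self.n_hotspots_per_chromosome

    def hotspot_indices(self, chromosome: int) -> np.ndarray:
        return np.flatnonzero(self.hotspot_flags[chromosome])

    def qtn_cluster_indices(self, chromosome: int) -> np.ndarray:
        return np.flatnonzero(self.qtn_cluster_flags[chromosome])

    def hotspot_starts(self, chromosome: int) -> np.ndarray:
        """Start coordinate (bp) of every hotspot region, ascending."""
        return self.hotspot_indices(chromosome) * self.region_length_bp

    def positions_in_clusters(self, positions: np.ndarray, chromosome: int) -> np.ndarray:
        """Boolean mask: which of ``positions`` fall in a QTN-cluster region."""
        regions = np.asarray(positions) // self.region_length_bp
        return self.qtn_cluster_flags[chromosome][regions.astype(np.intp)]

    def positions_in_hotspots(self, positions: np.ndarray, chromosome: int) -> np.ndarray:
        regions = np.asarray(positions) // self.region_length_bp
        return self.hotspot_flags[chromosome][regions.astype(np.intp)]

    def to_bed(self, path) -> None:
        """Write active regions as BED (0-based, half-open) intervals.

        Names are ``hotspot``, ``qtn_cluster`` or ``hotspot+qtn_cluster``.
        """
        L = self.region_length_bp
        with open(path, "w") as fh:
            for c in range(self.n_chromosomes):
                active = self.hotspot_flags[c] | self.qtn_cluster_flags[c]
                for r in np.flatnonzero(active):
                    names = []
                    if self.hotspot_flags[c, r]:
                        names.append("hotspot")
                    if self.qtn_cluster_flags[c, r]:
                        names.append("qtn_cluster")
                    fh.write(f"chr{c + 1}\t{r * L}\t{(r + 1) * L}\t{'+'.join(names)}\n")


def build_region_map(
    n_regions: int,
    scenario: int,
    chromosome_length_bp: int,
    n_chromosomes: int,
) -> RegionMap:
    """Construct the deterministic region layout for one scenario.

    Hotspots sit at region indices ``0, 10, 20, ...`` (10% of regions).
    Scenario 2 places QTN clusters one region to the right of each hotspot;
    scenario 3 co-locates them with the hotspots; scenario 1 has none.

    Raises
    ------
    LayoutError
        If ``n_regions`` is not divisible by 10, the regions do not tile the
        chromosome exactly, or regions would be shorter than 2 bp.
    """
    if scenario not in (1, 2, 3):
        raise LayoutError(f"scenario must be 1, 2 or 3, got {scenario}")
    if n_regions <= 0 or n_regions % ACTIVE_PERIOD != 0:
        raise LayoutError(
            f"n_regions must be a positive multiple of {ACTIVE_PERIOD}, got {n_regions}"
        )
    if chromosome_length_bp % n_regions != 0:
        raise LayoutError(
            f"chromosome length {chromosome_length_bp} bp is not an exact "
            f"multiple of n_regions={n_regions}; regions must tile the chromosome"
        )
    region_length = chromosome_length_bp // n_regions
    if region_length < 2:
        raise LayoutError(f"region length {region_length} bp < 2 bp")
    if n_chromosomes < 1:
        raise LayoutError("need at least one chromosome")

    hotspots = np.zeros(n_regions, dtype=bool)
    hotspots[::ACTIVE_PERIOD] = True
    clusters = np.zeros(n_regions, dtype=bool)
    if scenario == 2:
        clusters[1::ACTIVE_PERIOD] = True
    elif scenario == 3:
        clusters[::ACTIVE_PERIOD] = True

    return RegionMap(
        n_regions=n_regions,
        region_length_bp=region_length,
        n_chromosomes=n_chromosomes,
        chromosome_length_bp=chromosome_length_bp,
        scenario=scenario,
        shifted=False,
        hotspot_flags=np.broadcast_to(hotspots, (n_chromosomes, n_regions)).copy(),
        qtn_cluster_flags=np.broadcast_to(clusters, (n_chromosomes, n_regions)).copy(),
    )


def shift_hotspots(region_map: RegionMap) -> RegionMap:
    """Move every hotspot one region to the right; QTN clusters stay put.

    A hotspot in the last region of a chromosome wraps back to the start of
    its 10-region period (cannot occur with the standard lattice, which ends
    9 regions before the chromosome end).  The number of hotspots is
    conserved and the move is injective.

    Raises
    ------
    StateError
        If the map has already been shifted.
    """
    if region_map.shifted:
        raise StateError("hotspots have already been shifted once")
    n = region_map.n_regions
    new_flags = np.zeros_like(region_map.hotspot_flags)
    for c in range(region_map.n_chromosomes):
        old = np.flatnonzero(region_map.hotspot_flags[c])
        new = np.where(old + 1 >= n, old - (ACTIVE_PERIOD - 1), old + 1)
        if len(np.unique(new)) != len(new):  # pragma: no cover - lattice forbids it
            raise StateError("hotspot shift produced a collision")
        new_flags[c, new] = True
    return RegionMap(
        n_regions=region_map.n_regions,
        region_length_bp=region_map.region_length_bp,
        n_chromosomes=region_map.n_chromosomes,
        chromosome_length_bp=region_map.chromosome_length_bp,
        scenario=region_map.scenario,
        shifted=True,
        hotspot_flags=new_flags,
        qtn_cluster_flags=region_map.qtn_cluster_flags.copy(),
    )


def region_of(position: float, region_map: RegionMap) -> int:
    """Region index containing a bp position (0-based, half-open regions)."""
    if not 0 <= position < region_map.chromosome_length_bp:
        raise BoundsError(
            f"position {position} outside [0, {region_map.chromosome_length_bp})"
        )
    return int(position // region_map.region_length_bp)
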