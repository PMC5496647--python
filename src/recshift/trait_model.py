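"""Quantitative trait architecture: QTN sampling and true breeding values.

A single fully additive trait is controlled by ``n_qtn_total`` quantitative
trait nucleotides (QTN) sampled from the segregating founder sites, an equal
number per chromosome.  Allele-substitution effects are i.i.d.
Normal(0, 1/sqrt(n_qtn_total)), so that the trait variance is on a unit-ish
scale regardless of QTN count (10,000 QTN -> effect sd 0.01).  The true
breeding value (TBV) of an individual is the dosage-weighted sum of effects
over all QTN; there is no dominance and no epistasis, and dosages are not
centred (only differences and variances of TBV are ever reported).

Scenario eligibility: in scenario 1 QTN are drawn uniformly from all
segregating sites; in scenarios 2 and 3 only from sites inside QTN-cluster
regions of the :class:`~recshift.genome_architecture.RegionMap`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DimensionError, SamplingError
from .founder_synthesis import HaplotypePanel
from .genome_architecture import RegionMap

__all__ = [
    "TraitArchitecture",
    "sample_qtn",
    "sample_effects",
    "effect_sd",
    "compute_tbv",
    "compute_population_tbv",
]


def effect_sd(n_qtn_total: int) -> float:
    """Standard deviation of allele-substitution effects, 1/sqrt(n_QTN)."""
    if n_qtn_total < 1:
        raise SamplingError("need at least one QTN")
    return 1.0 / np.sqrt(n_qtn_total)


def sample_effects(n_qtn_total: int, rng: np.random.Generator) -> np.ndarray:
    """Draw i.i.d. Normal(0, 1/sqrt(n_qtn_total)) substitution effects."""
    return rng.normal(0.0, effect_sd(n_qtn_total), size=n_qtn_total)


@dataclass(eq=False)
class TraitArchitecture:
    """QTN site indices (into the founder panel) and their additive effects.

    ``qtn_indices[c]`` are sorted unique indices into
    ``panel.positions[c]``; ``effects[c]`` is the matching effect vector.
    """

    qtn_indices: list[np.ndarray]
    effects: list[np.ndarray]
    scenario: int

    @property
    def n_chromosomes(self) -> int:
        return len(self.qtn_indices)

    @property
    def n_qtn_total(self) -> int:
        return int(sum(len(ix) for ix in self.qtn_indices))

    @property
    def all_effects(self) -> np.ndarray:
        return np.concatenate(self.effects)

    def to_tsv(self, panel: HaplotypePanel, path) -> None:
        """Write the architecture as TSV: chrom, pos, allele, alpha."""
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tallele\talpha\n")
            for c in range(self.n_chromosomes):
                pos = panel.positions[c][self.qtn_indices[c]]
                for p, a in zip(pos, self.effects[c]):
                    fh.write(f"chr{c + 1}\t{p}\t1\t{a!r}\n")


def sample_qtn(
    panel: HaplotypePanel,
    region_map: RegionMap,
    n_per_chromosome: int,
    seed,
) -> TraitArchitecture:
    """Sample QTN uniformly without replacement from eligible sites.

    Eligible sites are all segregating sites (scenario 1) or the sites lying
    inside QTN-cluster regions (scenarios 2/3).  Effects are drawn after all
    positions, i.i.d. Normal(0, 1/sqrt(n_per_chromosome * n_chromosomes)).

    ``seed`` may be an int or a ``numpy.random.Generator``.

    Raises
    ------
    SamplingError
        If any chromosome has fewer eligible sites than ``n_per_chromosome``
        (the message names the chromosome).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_total = n_per_chromosome * panel.n_chromosomes
    indices: list[np.ndarray] = []
    for c in range(panel.n_chromosomes):
        if region_map.scenario == 1:
            eligible = np.arange(len(panel.positions[c]))
        else:
            mask = region_map.positions_in_clusters(panel.positions[c], c)
            eligible = np.flatnonzero(mask)
        if len(eligible) < n_per_chromosome:
            raise SamplingError(
                f"chromosome {c + 1}: only {len(eligible)} eligible sites for "
                f"{n_per_chromosome} QTN (scenario {region_map.scenario})"
            )
        chosen = rng.choice(eligible, size=n_per_chromosome, replace=False)
        indices.append(np.sort(chosen))
    alpha = sample_effects(n_total, rng)
    effects = [alpha[c * n_per_chromosome : (c + 1) * n_per_chromosome] for c in range(panel.n_chromosomes)]
    return TraitArchitecture(qtn_indices=indices, effects=effects, scenario=region_map.scenario)


def compute_tbv(dosages: np.ndarray, arch: TraitArchitecture) -> float:
    """TBV of one individual: sum_i dosage_i * alpha_i over all QTN.

    ``dosages`` is the genome-wide QTN dosage vector (counts of the '1'
    allele, each 0, 1 or 2) concatenated in chromosome order.
    """
    dosages = np.asarray(dosages)
    if dosages.shape != (arch.n_qtn_total,):
        raise DimensionError(
            f"dosage vector length {dosages.shape} != number of QTN {arch.n_qtn_total}"
        )
    if not np.isin(dosages, (0, 1, 2)).all():
        raise DimensionError("dosages must be 0, 1 or 2")
    return float(dosages @ arch.all_effects)


def compute_population_tbv(haplotypes: list[np.ndarray], arch: TraitArchitecture) -> np.ndarray:
    """Vectorised TBV for a whole generation.

    ``haplotypes[c]`` has shape ``(n_individuals, 2, n_sites_c)``.
    """
    n = haplotypes[0].shape[0]
    tbv = np.zeros(n)
    for c in range(arch.n_chromosomes):
        dos = haplotypes[c][:, :, arch.qtn_indices[c]].sum(axis=1)
        tbv += dos @ arch.effects[c]
    return tbv


def qtn_allele_frequencies(haplotypes: list[np.ndarray], arch: TraitArchitecture) -> np.ndarray:
    """Frequency of the '1' allele at every QTN, from the 2n haplotypes of
    the current generation, concatenated in chromosome order."""
    freqs = []
    for c in range(arch.n_chromosomes):
        sub = haplotypes[c][:, :, arch.qtn_indices[c]]
        freqs.append(sub.mean(axis=(0, 1)))
    return np.concatenate(freqs)
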