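"""The breeding program: founding, truncation selection, random mating.

Each generation holds ``n_individuals`` animals in an exactly equal sex
ratio (sexes assigned alternately M, F, M, F, ...).  The top ``n_sires``
males by true breeding value are truncation-selected as sires of the next
generation; every female is a candidate dam.  For each offspring a sire and
a dam are drawn uniformly with replacement and each parent contributes one
gamete through the hotspot-restricted meiosis model.

A run spans ``n_historical_generations`` labelled ``-(H-1) .. 0`` (founders
drawn from the base haplotype panel at the first of these) followed by
``n_future_generations`` labelled ``1 .. n``.  At generation 0 — the start
of future breeding — the recombination hotspots are optionally shifted one
region to the right.  Runs are fully deterministic given the seed, and two
arms (shift vs no shift) started from the same seed share a bit-identical
historical phase, giving common-random-number pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .exceptions import ConfigurationError
from .founder_synthesis import HaplotypePanel
from .genome_architecture import RegionMap, shift_hotspots
from .meiosis_engine import _gamete_batch
from .trait_model import TraitArchitecture, compute_population_tbv, qtn_allele_frequencies

__all__ = [
    "BreedingConfig",
    "Population",
    "found_population",
    "select_sires",
    "advance_generation",
    "run_breeding",
]

MALE, FEMALE = 0, 1


@dataclass(frozen=True)
class BreedingConfig:
    """Pedigree and selection design.

    Defaults are the full-scale study conditions: 1000 individuals per
    generation, 25 sires, 21 historical generations (-20..0) and 80 future
    generations (1..80).
    """

    n_individuals: int = 1000
    n_sires: int = 25
    n_historical_generations: int = 21
    n_future_generations: int = 80
    shift_at_generation_zero: bool = False
    seed: int = 1
    base_generation: int = 0
    #: "random": dams drawn uniformly with replacement per offspring;
    #: "two_per_dam": every dam has exactly two offspring (lower drift).
    dam_scheme: str = "random"

    def __post_init__(self) -> None:
        if self.n_individuals < 2 or self.n_individuals % 2 != 0:
            raise ConfigurationError("n_individuals must be even and >= 2")
        if not 1 <= self.n_sires <= self.n_individuals // 2:
            raise ConfigurationError("need 1 <= n_sires <= number of males")
        if self.n_historical_generations < 1 or self.n_future_generations < 0:
            raise ConfigurationError("generation counts must be >= 1 historical, >= 0 future")
        if self.dam_scheme not in ("random", "two_per_dam"):
            raise ConfigurationError(f"unknown dam scheme {self.dam_scheme!r}")

    @classmethod
    def desk(cls, seed: int = 1, **overrides) -> "BreedingConfig":
        """Desk-scale profile: 200 individuals, 10 sires, 10 + 20 generations."""
        params = dict(
            n_individuals=200,
            n_sires=10,
            n_historical_generations=10,
            n_future_generations=20,
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)


@dataclass(eq=False)
class Population:
    """One generation: per-chromosome haplotypes plus pedigree bookkeeping.

    ``haplotypes[c]`` has shape ``(n_individuals, 2, n_sites_c)``;
    ``site_positions`` is shared with the founder panel.
    """

    haplotypes: list[np.ndarray]
    site_positions: list[np.ndarray]
    chromosome_length_bp: int
    sex: np.ndarray
    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    tbv: np.ndarray
    generation: int

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def males(self) -> np.ndarray:
        return self.ids[self.sex == MALE]

    @property
    def females(self) -> np.ndarray:
        return self.ids[self.sex == FEMALE]

    def pedigree_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "sire": self.sire, "dam": self.dam})


def _alternating_sexes(n: int) -> np.ndarray:
    sex = np.empty(n, dtype=np.int8)
    sex[0::2] = MALE
    sex[1::2] = FEMALE
    return sex


def found_population(
    panel: HaplotypePanel,
    config: BreedingConfig,
    rng: np.random.Generator,
    arch: TraitArchitecture | None = None,
    generation: int | None = None,
) -> Population:
    """Found the first generation from the base haplotype panel.

    Every individual receives, per chromosome, two haplotypes drawn
    uniformly with replacement from the panel.  Sexes alternate M, F, ...
    for a deterministic exact 50/50 split.
    """
    if panel.n_haplotypes < 2:
        raise ConfigurationError("panel must contain at least two haplotypes")
    n = config.n_individuals
    haplotypes = []
    for c in range(panel.n_chromosomes):
        idx = rng.integers(0, panel.n_haplotypes, size=(n, 2))
        haplotypes.append(panel.alleles[c][idx])
    tbv = compute_population_tbv(haplotypes, arch) if arch is not None else np.full(n, np.nan)
    if generation is None:
        generation = -(config.n_historical_generations - 1)
    return Population(
        haplotypes=haplotypes,
        site_positions=panel.positions,
        chromosome_length_bp=panel.chromosome_length_bp,
        sex=_alternating_sexes(n),
        ids=np.arange(n, dtype=np.int64),
        sire=np.full(n, -1, dtype=np.int64),
        dam=np.full(n, -1, dtype=np.int64),
        tbv=tbv,
        generation=generation,
    )


def select_sires(pop: Population, n_sires: int) -> np.ndarray:
    """Truncation selection: ids of the ``n_sires`` males with highest TBV.

    Ties are broken deterministically in favour of the lower id.
    """
    male_rows = np.flatnonzero(pop.sex == MALE)
    if len(male_rows) < n_sires:
        raise ConfigurationError(f"only {len(male_rows)} males for {n_sires} sires")
    # lexsort: last key is primary -> sort by descending TBV, then ascending id
    order = np.lexsort((pop.ids[male_rows], -pop.tbv[male_rows]))
    return pop.ids[male_rows[order[:n_sires]]]


def advance_generation(
    pop: Population,
    sire_ids: np.ndarray,
    region_map: RegionMap,
    arch: TraitArchitecture,
    config: BreedingConfig,
    rng: np.random.Generator,
    id_offset: int = 0,
) -> Population:
    """Produce the next generation by random mating of sires x all dams.

    RNG draw order (fixed, so paired arms stay aligned): sire assignment,
    dam assignment, then per chromosome the sire-gamete batch followed by
    the dam-gamete batch (each batch draws crossover occurrences, positions
    and starting haplotypes; see ``meiosis_engine._gamete_batch``).
    """
    if len(sire_ids) == 0:
        raise ConfigurationError("empty sire list")
    n = config.n_individuals
    id_to_row = {int(i): r for r, i in enumerate(pop.ids)}
    sire_rows = np.array([id_to_row[int(s)] for s in sire_ids])
    female_rows = np.flatnonzero(pop.sex == FEMALE)

    sire_pick = sire_rows[rng.integers(0, len(sire_rows), size=n)]
    if config.dam_scheme == "two_per_dam":
        reps = int(np.ceil(n / len(female_rows) / 2)) * 2
        dam_pool = np.repeat(female_rows, reps)[:n]
        dam_pick = rng.permutation(dam_pool)
    else:
        dam_pick = female_rows[rng.integers(0, len(female_rows), size=n)]

    haplotypes = []
    for c in range(len(pop.haplotypes)):
        starts = region_map.hotspot_starts(c)
        paternal = _gamete_batch(
            pop.haplotypes[c], sire_pick, pop.site_positions[c], starts,
            region_map.region_length_bp, rng,
        )
        maternal = _gamete_batch(
            pop.haplotypes[c], dam_pick, pop.site_positions[c], starts,
            region_map.region_length_bp, rng,
        )
        haplotypes.append(np.stack([paternal, maternal], axis=1))

    return Population(
        haplotypes=haplotypes,
        site_positions=pop.site_positions,
        chromosome_length_bp=pop.chromosome_length_bp,
        sex=_alternating_sexes(n),
        ids=id_offset + np.arange(n, dtype=np.int64),
        sire=pop.ids[sire_pick],
        dam=pop.ids[dam_pick],
        tbv=compute_population_tbv(haplotypes, arch),
        generation=pop.generation + 1,
    )


def run_breeding(
    panel: HaplotypePanel,
    region_map: RegionMap,
    arch: TraitArchitecture,
    config: BreedingConfig,
    keep_populations: bool = False,
):
    """Run the full historical + future breeding program.

    Returns a tidy DataFrame with one row per generation (columns
    ``generation, mean_tbv, gain_std_units, genetic_variance,
    genic_variance, mean_heterozygosity``), or ``(frame, populations)``
    if ``keep_populations``.  Gain is standardised to the base generation
    (default 0) for every generation, historical ones included.
    """
    if region_map.shifted:
        raise ConfigurationError("run must start from an unshifted region map")
    rng = np.random.default_rng(config.seed)
    effects = arch.all_effects
    summaries: list[metrics.GenerationSummary] = []
    populations: list[Population] = []

    pop = found_population(panel, config, rng, arch)
    first_gen = pop.generation

    def record(p: Population) -> None:
        freqs = qtn_allele_frequencies(p.haplotypes, arch)
        summaries.append(metrics.summarize_generation(p.generation, p.tbv, freqs, effects))
        if keep_populations:
            populations.append(p)

    record(pop)
    current_map = region_map
    total_generations = config.n_historical_generations + config.n_future_generations
    for step in range(1, total_generations):
        if pop.generation == 0 and config.shift_at_generation_zero:
            current_map = shift_hotspots(current_map)
        sires = select_sires(pop, config.n_sires)
        pop = advance_generation(
            pop, sires, current_map, arch, config, rng,
            id_offset=step * config.n_individuals,
        )
        record(pop)
    # handle shift request even when there are no future generations
    if pop.generation == 0 and config.shift_at_generation_zero:
        current_map = shift_hotspots(current_map)

    frame = metrics.summaries_to_frame(summaries)
    base = frame[frame.generation == config.base_generation]
    if base.empty:
        raise ConfigurationError(
            f"base generation {config.base_generation} not in run "
            f"({first_gen}..{pop.generation})"
        )
    base_mean = float(base.mean_tbv.iloc[0])
    base_sd = float(np.sqrt(base.genetic_variance.iloc[0]))
    if base_sd <= 0:
        raise ConfigurationError("degenerate base generation: zero TBV variance")
    frame["gain_std_units"] = (frame.mean_tbv - base_mean) / base_sd
    if keep_populations:
        return frame, populations
    return frame
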