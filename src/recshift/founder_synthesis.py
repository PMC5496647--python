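"""Founder haplotype panels from a neutral coalescent.

The breeding simulation starts from a panel of base haplotypes whose
statistical structure emulates neutral whole-genome sequence from a
population with a declining-effective-size history (Holstein-like by
default: Ne 500 today, 1256 a thousand years ago, 4350 ten thousand years
ago, 43,500 a hundred thousand years ago, linear in between).

Chromosomes are simulated independently with **no intra-founder
recombination**: downstream results depend on the site-frequency spectrum of
standing variation, not on founder linkage structure, and dropping
recombination removes the heaviest computation.  Each chromosome is a
single-population coalescent (msprime) with binary mutations on a discrete
genome, so every site is bi-allelic with 0/1 alleles at integer bp
positions; non-segregating sites are dropped at creation.

The panel round-trips losslessly through a plain-text snapshot
(`HaplotypePanel.save` / `HaplotypePanel.load`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import yaml

from .exceptions import ConfigurationError, DegeneratePanelError

__all__ = [
    "FounderConfig",
    "HaplotypePanel",
    "synthesize_founders",
    "nucleotide_diversity",
    "watterson_theta",
]

#: Holstein-like Ne history: (time, effective size), time in years before
#: present, converted to generations via ``generation_interval``.
HOLSTEIN_DEMOGRAPHY = ((0.0, 500.0), (1_000.0, 1_256.0), (10_000.0, 4_350.0), (100_000.0, 43_500.0))

#: sub-epochs used to discretise each linear Ne ramp for the coalescent
_EPOCH_STEPS = 8


@dataclass(frozen=True)
class FounderConfig:
    """Configuration of the founder coalescent.

    Defaults are the full-scale study conditions: 1000 haplotypes for each of
    10 chromosomes of 1e8 bp, per-site mutation rate 2.5e-8, Holstein-like
    demography.  ``scale_factor`` shrinks chromosome lengths, effective sizes
    and demographic times jointly for desk-scale runs.
    """

    n_haplotypes: int = 1000
    n_chromosomes: int = 10
    chromosome_length_bp: int = 100_000_000
    mutation_rate: float = 2.5e-8
    demography: tuple[tuple[float, float], ...] = HOLSTEIN_DEMOGRAPHY
    generation_interval: float = 1.0
    scale_factor: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2 or self.n_haplotypes % 2 != 0:
            raise ConfigurationError("n_haplotypes must be even and >= 2")
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")
        if self.chromosome_length_bp <= 0:
            raise ConfigurationError("chromosome_length_bp must be positive")
        if self.mutation_rate <= 0:
            raise ConfigurationError("mutation_rate must be positive")
        if self.scale_factor <= 0:
            raise ConfigurationError("scale_factor must be positive")
        if self.generation_interval <= 0:
            raise ConfigurationError("generation_interval must be positive")
        demo = tuple((float(t), float(n)) for t, n in self.demography)
        if not demo:
            raise ConfigurationError("demography must have at least one epoch")
        times = [t for t, _ in demo]
        if any(n <= 0 for _, n in demo):
            raise ConfigurationError("effective sizes must be strictly positive")
        if times[0] != 0:
            raise ConfigurationError("first demography time point must be 0 (present)")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigurationError("demography times must be strictly increasing")
        object.__setattr__(self, "demography", demo)

    # -- scaled quantities -------------------------------------------------

    @property
    def effective_chromosome_length(self) -> int:
        """Chromosome length in bp after applying ``scale_factor``."""
        return max(1, int(round(self.chromosome_length_bp * self.scale_factor)))

    def scaled_demography(self) -> list[tuple[float, float]]:
        """(time in generations, Ne) after generation-interval and scaling."""
        return [
            (t / self.generation_interval * self.scale_factor, n * self.scale_factor)
            for t, n in self.demography
        ]

    def expected_sites_per_chromosome(self) -> float:
        """Watterson expectation E[S] = 4*Ne0*mu*L*a_{n-1} at the recent Ne.

        A lower bound when Ne grows back in time; used only to reject
        configurations that would yield a degenerate (< 10 sites) panel.
        """
        a_n = np.sum(1.0 / np.arange(1, self.n_haplotypes))
        ne0 = self.scaled_demography()[0][1]
        return 4.0 * ne0 * self.mutation_rate * self.effective_chromosome_length * a_n

    # -- construction helpers ---------------------------------------------

    @classmethod
    def desk(cls, seed: int = 1, **overrides) -> "FounderConfig":
        """Desk-scale profile: 200 haplotypes, 2 chromosomes x 1e6 bp,
        constant Ne = 100, mutation rate 1e-6 (E[S] ~ 2350 sites/chromosome)."""
        params = dict(
            n_haplotypes=200,
            n_chromosomes=2,
            chromosome_length_bp=1_000_000,
            mutation_rate=1e-6,
            demography=((0.0, 100.0),),
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "FounderConfig":
        """Load a config from a flat YAML mapping; keyword args override."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "demography" in data:
            data["demography"] = tuple(tuple(pair) for pair in data["demography"])
        data.update(overrides)
        return cls(**data)


@dataclass(eq=False)
class HaplotypePanel:
    """Founder haplotypes: per chromosome, sorted bp positions and a binary
    allele matrix of shape ``(n_haplotypes, n_sites)``."""

    positions: list[np.ndarray]
    alleles: list[np.ndarray]
    chromosome_length_bp: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_chromosomes(self) -> int:
        return len(self.positions)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles[0].shape[0]

    @property
    def n_sites(self) -> list[int]:
        return [len(p) for p in self.positions]

    @property
    def total_sites(self) -> int:
        return int(sum(self.n_sites))

    def allele_frequencies(self, chromosome: int) -> np.ndarray:
        """Frequency of the '1' allele at every site of one chromosome."""
        return self.alleles[chromosome].mean(axis=0)

    def validate(self) -> None:
        """Assert the panel invariants (binary, segregating, sorted, in-range)."""
        n = self.n_haplotypes
        for c in range(self.n_chromosomes):
            pos, mat = self.positions[c], self.alleles[c]
            if mat.shape != (n, len(pos)):
                raise ConfigurationError(f"chromosome {c}: shape mismatch")
            if len(pos) and (np.any(np.diff(pos) <= 0) or pos[0] < 0 or pos[-1] >= self.chromosome_length_bp):
                raise ConfigurationError(f"chromosome {c}: positions not sorted in-range")
            if not np.isin(mat, (0, 1)).all():
                raise ConfigurationError(f"chromosome {c}: non-binary alleles")
            counts = mat.sum(axis=0)
            if np.any((counts == 0) | (counts == n)):
                raise ConfigurationError(f"chromosome {c}: monomorphic sites present")

    # -- lossless text snapshot -------------------------------------------

    def save(self, directory) -> None:
        """Write the panel as plain text: one positions file and one 0/1
        allele-matrix file (one haplotype per line) per chromosome."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "n_chromosomes": self.n_chromosomes,
            "n_haplotypes": self.n_haplotypes,
            "chromosome_length_bp": int(self.chromosome_length_bp),
            "metadata": self.metadata,
        }
        (directory / "panel.json").write_text(json.dumps(meta, indent=1))
        for c in range(self.n_chromosomes):
            np.savetxt(directory / f"chr{c + 1}.positions.txt", self.positions[c], fmt="%d")
            with open(directory / f"chr{c + 1}.alleles.txt", "w") as fh:
                for row in self.alleles[c]:
                    fh.write("".join("1" if a else "0" for a in row) + "\n")

    @classmethod
    def load(cls, directory) -> "HaplotypePanel":
        directory = Path(directory)
        meta = json.loads((directory / "panel.json").read_text())
        positions, alleles = [], []
        for c in range(meta["n_chromosomes"]):
            pos = np.loadtxt(directory / f"chr{c + 1}.positions.txt", dtype=np.int64, ndmin=1)
            with open(directory / f"chr{c + 1}.alleles.txt") as fh:
                rows = [np.frombuffer(line.strip().encode(), dtype=np.uint8) - ord("0") for line in fh]
            positions.append(pos)
            alleles.append(np.vstack(rows).astype(np.uint8))
        return cls(
            positions=positions,
            alleles=alleles,
            chromosome_length_bp=meta["chromosome_length_bp"],
            metadata=meta.get("metadata", {}),
        )


def _build_demography(config: FounderConfig) -> msprime.Demography:
    """Piecewise-linear Ne(t) discretised into constant sub-epochs.

    Each interval between stated time points is split into ``_EPOCH_STEPS``
    sub-epochs whose size is the linear interpolation at the sub-interval
    midpoint; beyond the oldest time point Ne is held constant.
    """
    points = config.scaled_demography()
    demography = msprime.Demography()
    demography.add_population(name="pop", initial_size=points[0][1])
    for (t0, n0), (t1, n1) in zip(points, points[1:]):
        edges = np.linspace(t0, t1, _EPOCH_STEPS + 1)
        for lo, hi in zip(edges[:-1], edges[1:]):
            mid = 0.5 * (lo + hi)
            size = n0 + (n1 - n0) * (mid - t0) / (t1 - t0)
            demography.add_population_parameters_change(time=lo, initial_size=size)
    if len(points) > 1:
        demography.add_population_parameters_change(time=points[-1][0], initial_size=points[-1][1])
    demography.sort_events()
    return demography


def synthesize_founders(config: FounderConfig) -> HaplotypePanel:
    """Simulate the founder panel: independent non-recombining chromosomes
    under a neutral coalescent with the configured Ne history, binary
    mutations at rate ``mutation_rate`` per bp, monomorphic sites dropped.

    Deterministic given ``config.seed``.

    Raises
    ------
    DegeneratePanelError
        If desk scaling (``scale_factor`` < 1) would leave fewer than 10
        expected segregating sites per chromosome.  Explicit tiny
        configurations (e.g. many short validation chromosomes) are allowed.
    """
    if config.scale_factor < 1 and config.expected_sites_per_chromosome() < 10:
        raise DegeneratePanelError(
            "configuration expects fewer than 10 segregating sites per "
            "chromosome; increase length, mutation rate or scale_factor"
        )
    demography = _build_demography(config)
    ss = np.random.SeedSequence(config.seed)
    positions: list[np.ndarray] = []
    alleles: list[np.ndarray] = []
    length = config.effective_chromosome_length
    for child in ss.spawn(config.n_chromosomes):
        anc_seed, mut_seed = (int(s % (2**31 - 2)) + 1 for s in child.generate_state(2))
        # n/2 diploid samples = n haploid genomes on the diploid coalescent
        # timescale (E[pairwise diversity] = 4*Ne*mu per bp)
        ts = msprime.sim_ancestry(
            samples=config.n_haplotypes // 2,
            ploidy=2,
            demography=demography,
            sequence_length=length,
            recombination_rate=0.0,
            random_seed=anc_seed,
        )
        ts = msprime.sim_mutations(
            ts,
            rate=config.mutation_rate,
            model=msprime.BinaryMutationModel(),
            random_seed=mut_seed,
            discrete_genome=True,
        )
        geno = ts.genotype_matrix().T.astype(np.uint8)  # (n_hap, n_sites)
        pos = ts.tables.sites.position.astype(np.int64)
        counts = geno.sum(axis=0)
        keep = (counts > 0) & (counts < config.n_haplotypes)
        positions.append(pos[keep])
        alleles.append(np.ascontiguousarray(geno[:, keep]))
    panel = HaplotypePanel(
        positions=positions,
        alleles=alleles,
        chromosome_length_bp=length,
        metadata={"seed": config.seed, "mutation_rate": config.mutation_rate},
    )
    panel.validate()
    return panel


def nucleotide_diversity(panel: HaplotypePanel) -> float:
    """Mean pairwise diversity per bp, pi = sum_s 2 p q n/(n-1) / total length.

    Under neutrality with constant Ne, E[pi] = theta = 4*Ne*mu.
    """
    n = panel.n_haplotypes
    total = 0.0
    for c in range(panel.n_chromosomes):
        p = panel.allele_frequencies(c)
        total += float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1))
    return total / (panel.n_chromosomes * panel.chromosome_length_bp)


def watterson_theta(panel: HaplotypePanel) -> float:
    """Watterson's estimator of theta = 4*Ne*mu per bp from the site count."""
    a_n = float(np.sum(1.0 / np.arange(1, panel.n_haplotypes)))
    return panel.total_sites / a_n / (panel.n_chromosomes * panel.chromosome_length_bp)
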