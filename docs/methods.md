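# Methods

This note documents the model implemented by `recshift`, the defaults and
why they were chosen, the numerical conventions, and what the desk-scale
tests do and do not demonstrate.

## Founder haplotypes

Founders are drawn from a neutral single-population coalescent (msprime),
one independent, **non-recombining** tree per chromosome, with binary
mutations on a discrete genome so every site is bi-allelic with 0/1 alleles
at integer bp positions. Sites that are monomorphic in the sample are
dropped at creation; the panel invariant is that every site segregates.

Dropping intra-founder recombination is deliberate: the downstream response
variables (gain, σ²_A, σ²_α) depend on the frequency spectrum of standing
variation and on the recombination process *during breeding*, not on the
fine-scale LD structure of the base panel, and a recombining coalescent is
by far the heaviest computation in the pipeline. The cost is that founder
chromosomes carry whole-chromosome LD from a single genealogy; the ~10
historical generations of hotspot-restricted recombination then rework this
into the desert/hotspot LD structure the study turns on. Simulated
haplotypes are handed to the breeding phase as standing variation only — no
new mutations arise after founding.

Effective-size history is piecewise-linear in time (full-scale default:
Ne 500 at present, 1256 at 1,000, 4,350 at 10,000 and 43,500 at 100,000
time units ago). msprime supports only piecewise-constant epochs, so each
linear ramp is discretised into 8 constant sub-epochs evaluated at
sub-interval midpoints; the approximation error is far below the sampling
noise of any quantity we report. Times are given in years in the source
estimates but no generation interval is stated with them; the
`generation_interval` parameter (default 1, i.e. times read as generations)
makes the conversion explicit and configurable.

`scale_factor` shrinks chromosome length, Ne and demographic times jointly,
which preserves the per-chromosome expected site count scaling while
shrinking compute. A desk scaling that would leave fewer than 10 expected
segregating sites per chromosome is rejected as degenerate. Deliberately
tiny explicit configurations are allowed; the validation suite uses panels
of many 1-kb chromosomes precisely so that site genealogies are nearly
independent when testing the site-frequency spectrum.

Desk founder profile: 200 haplotypes, 2 chromosomes × 10⁶ bp, constant
Ne = 100, mutation rate 10⁻⁶. The rate is set so that E[S] ≈ 4Ne·μ·L·a_{n−1}
≈ 2,300–3,500 sites per chromosome; scenarios 2/3 restrict QTN sampling to
the 10% of the genome inside QTN clusters (~250+ eligible sites per
chromosome), which must comfortably exceed the 100 QTN sampled per
chromosome without replacement.

## Genome architecture and hotspot shifting

Each chromosome is tiled by `n_regions` equal windows (the window count
must divide the chromosome length; coordinates are 0-based half-open
throughout). Exactly 10% of windows are active, evenly spaced with period
10, starting at window 0 — any constant lattice offset is statistically
equivalent under the model. Scenario 2 places QTN clusters at hotspot
index + 1: "adjacent" is directionally ambiguous, and putting the cluster
one window to the right means a single right-shift lands hotspots exactly
on the clusters. Shifting moves every hotspot one window right (the
lattice guarantees the target window is inactive, so the move is injective
and conserves the hotspot count); QTN clusters never move. A map can be
shifted once; shifting twice is a state error.

## Meiosis

The crossover process is Bernoulli-per-hotspot: each of the H hotspots on a
chromosome independently receives at most one crossover per meiosis with
probability 1/H, positioned uniformly within the hotspot window. This is
the literal reading of a constant per-region recombination probability
(0.04/0.02/0.01 for 25/50/100 hotspots) and gives an expected map length of
exactly 1 Morgan per chromosome. There is no interference (independence
across hotspots) and no obligate chiasma — a chromosome transmits intact
with probability (1−1/H)^H ≈ e⁻¹. Gametes start on a uniformly chosen
parental haplotype and switch at each crossover; a site exactly at a
crossover position belongs to the right-hand segment.

## Breeding program

Generations are discrete and non-overlapping: `n_individuals` per
generation with sexes assigned alternately M, F, … so the 50/50 split is
exact. Founders draw each chromosome's two haplotypes uniformly **with
replacement** from the base panel. The `n_sires` top males by TBV are
truncation-selected (ties broken toward lower id, so selection is
deterministic); every offspring draws its sire uniformly from the selected
sires and its dam uniformly from all females, both with replacement. The
alternative `two_per_dam` scheme (every dam leaves exactly two offspring)
is provided because litter allocation changes the drift variance; the
default is the simplest reading of random mating. Under the default design
the variance-effective size is ≈ N without selection, and the neutral test
checks genic variance decays like (1 − 1/2N)ᵗ.

A run is driven by a single seeded NumPy generator with a fixed draw order
(sire picks, dam picks, then per chromosome the paternal and maternal
gamete batches). Two runs with the same seed that differ only in the
`shift_at_generation_zero` flag are therefore bit-identical through
generation 0 and diverge only through the shifted map — common-random-number
pairing of the shift arms, which the ordering analyses rely on.

## Response variables

Gain is reported in units of the base-generation TBV standard deviation;
the base defaults to generation 0, the start of future breeding, which is
what all curves are standardised to (a `base_generation` switch exists
because the start of the *selection* era, generation −20 … or generation 1,
is an equally defensible anchor). Genetic variance is the sample variance
of TBV, a′a/(n−1); genic variance is 2Σpq α² with allele frequencies counted
over the 2n haplotypes of the current generation. Fixed QTN stay in the
architecture and contribute zero. TBV is an uncentred dosage-weighted sum;
all reported quantities are differences or variances and hence invariant to
the missing centring constant.

## Experiment orchestration

The factorial crosses scenarios × region counts × shift arms × replicates.
Within a replicate all cells share one founder panel; within a cell both
shift arms share the breeding seed. Replicate and cell seeds are derived
from the master seed via `numpy.random.SeedSequence`, so the entire
factorial is deterministic and per-cell CSVs make interrupted runs
resumable. Aggregation reports replicate mean, sd and count per
(scenario, regions, shift, generation); with one replicate the sd is NaN by
construction.

## Desk-scale profile and what the tests show

The default experiment profile is: 200 individuals, 10 sires, 2 chromosomes
× 10⁶ bp, 100 QTN per chromosome, 100 regions (10 hotspots) per chromosome,
10 historical + 20 future generations, 10 replicates. These sizes make the
full ordering analysis run in minutes on one CPU while preserving the
qualitative structure of the full-scale design: strong male-side truncation
selection, 1 Morgan chromosomes, 10% active regions, clustered-vs-random
QTN.

At this scale the suite reproduces the directional findings: shifting
hotspots onto QTN clusters (scenario 2) increases final cumulative gain
(one-sided paired test over 10 replicates), shifting them off the clusters
(scenario 3) decreases it, shift arms retain more genic variance in
scenarios 1–2, and the benefit of shifting shrinks as hotspots become more
numerous. The hotspot-count contrast is run at 10 vs 40 hotspots per
chromosome: with chromosomes 100× shorter than full scale, proportionally
scaled hotspot counts keep the ratio of desert length to founder LD-block
length comparable, which is the quantity the effect rides on; a literal
25-vs-100 contrast on a 10⁶ bp chromosome leaves deserts too short for the
scenario-1 effect to rise above replicate noise.

What desk-scale passing does **not** show: magnitudes. With 2 chromosomes,
200 QTN of large effect (sd 1/√200) and 30 generations, selection exhausts
genic variance far faster than at full scale, founder LD is single-genealogy
rather than recombination-structured, and absolute gains in sd units are
not comparable to the full-scale curves. Only orderings and rates relative
to their own baselines are meaningful at this scale.

## Numerical choices and degenerate inputs

* Region maps require exact tiling (length divisible by region count) and
  regions ≥ 2 bp; region membership is floor division.
* Truncation selection breaks TBV ties by lower id; selection is fully
  deterministic given TBVs.
* A base generation with zero TBV variance makes gain undefined and raises
  an error rather than returning infinities.
* The expected-site guard uses the Watterson expectation at the most recent
  Ne, a lower bound under historical growth — conservative in the direction
  that matters for the guard.
* Effects are sampled after all QTN positions, so two scenarios sharing a
  seed differ in positions but are sampled from identical effect streams
  only when their eligible-site draws consume equal randomness; scenario
  comparisons in the experiment runner therefore use per-cell derived seeds
  rather than relying on stream alignment across scenarios.

## Known limitations

* Single fully additive trait; no dominance, epistasis, pleiotropy or
  mutation after founding.
* Selection on true breeding values only — no phenotypes, no estimated
  breeding values, no genomic selection machinery.
* Hotspots are all-or-nothing: uniform intensity inside, zero
  recombination outside; no sex-specific maps, interference or gene
  conversion.
* The founder panel emulates the frequency spectrum, not the LD structure,
  of a sequenced livestock population; full-scale founder generation
  (~3 × 10⁶ sites) is configured but is cluster-scale work, and the suite
  validates its site-count scaling rather than running it.
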