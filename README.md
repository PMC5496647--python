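# recshift

A stochastic, forward-in-time breeding-program simulator for asking one
question: **if you could move a genome's recombination hotspots, what would
it do to genetic gain?**

In most mammals, crossovers cluster in narrow hotspots whose positions are
set by PRDM9 binding. After many generations of selection with a fixed
recombination landscape, favourable and unfavourable alleles of causal
variants (QTN) accumulate in repulsion inside "recombination deserts",
where standing allelic variation is locked away from selection. Re-targeting
hotspots — e.g. by editing PRDM9 zinc-finger motifs — could release that
variation as new allele combinations. `recshift` quantifies this with a
desk-scale, fully seedable simulation of a closed livestock nucleus under
truncation selection on true breeding values (TBV).

## Model in brief

* **Founders** — a neutral-coalescent haplotype panel (msprime backend, no
  intra-founder recombination), bi-allelic segregating sites, per-site
  mutation rate 2.5 × 10⁻⁸ and a Holstein-like Ne history at full scale.
* **Genome architecture** — each chromosome is split into 250/500/1000
  equal regions; exactly 10% are *active* (recombination hotspot and/or QTN
  cluster), evenly spaced. Three scenarios: (1) QTN random, (2) QTN
  clustered adjacent to hotspots, (3) QTN clustered inside hotspots.
* **Meiosis** — each of the H hotspots on a chromosome independently
  receives at most one crossover with probability 1/H (no interference),
  so every chromosome is 1 Morgan and the 10-chromosome genome 10 Morgan.
  Crossovers never occur outside hotspots.
* **Trait** — fully additive, n QTN with effects αᵢ ~ N(0, 1/√n)
  (sd 0.01 for 10,000 QTN); TBV = Σ dosageᵢ·αᵢ.
* **Breeding** — 1000 individuals/generation in an exact 500/500 sex ratio;
  the top 25 males by TBV are sires, all females are dams, mating at random;
  21 historical generations (−20…0) then 80 future generations (1…80).
  At generation 0 the hotspots are optionally **shifted** one region over.
* **Responses per generation** — standardized gain
  (T̄BV_curr − T̄BV_base)/σ_TBV,base; genetic variance σ²_A = a′a/(n−1);
  genic variance σ²_α = 2Σpᵢqᵢαᵢ²; mean QTN heterozygosity.

Everything runs at a desk-scale profile by default (200 individuals,
2 chromosomes × 10⁶ bp, 100 QTN/chromosome, 10 + 20 generations); the
full-scale configuration is available but cluster-sized.

## Worked example

```python
import recshift as rs

panel = rs.synthesize_founders(rs.FounderConfig.desk(seed=1))
rmap  = rs.build_region_map(100, 2, panel.chromosome_length_bp, panel.n_chromosomes)
arch  = rs.sample_qtn(panel, rmap, 100, seed=2)

for shift in (False, True):
    cfg = rs.BreedingConfig.desk(seed=3, shift_at_generation_zero=shift)
    frame = rs.run_breeding(panel, rmap, arch, cfg)
    last, g0 = frame.iloc[-1], frame[frame.generation == 0].iloc[0]
    print(f"shift={shift}: gen-20 gain={last.gain_std_units:.2f} sd units, "
          f"genic variance {g0.genic_variance:.4f} -> {last.genic_variance:.4f}")
```

prints

```
shift=False: gen-20 gain=5.99 sd units, genic variance 0.1738 -> 0.0057
shift=True: gen-20 gain=8.15 sd units, genic variance 0.1738 -> 0.0264
```

This is scenario 2 (QTN clustered just outside hotspots). Keeping hotspots
fixed, the clusters never recombine internally and genic variance is nearly
exhausted after 20 generations (0.1738 → 0.0057). Shifting the hotspots
onto the QTN clusters at generation 0 releases the repulsion-phase
variation: more genic variance survives (0.0264) and cumulative gain rises
from ~6.0 to ~8.2 base-generation standard deviations. Running scenario 3
instead reverses the sign of the effect.

The same experiment, factorially over scenarios × region counts × shift
arms × replicates, via the CLI:

```bash
recshift run --out results/desk --profile desk --replicates 10 --seed 1
recshift aggregate results/desk/results.csv --out results/desk/agg.csv
recshift plot results/desk/agg.csv --out results/desk/figures
```

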