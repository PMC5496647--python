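"""Pedigree structure, truncation selection and multi-generation dynamics."""

import numpy as np
import pytest
from scipy import stats

import recshift as rs
from recshift.exceptions import ConfigurationError
from conftest import make_population


def _founders(panel, arch, n=200, seed=0, **kw):
    cfg = rs.BreedingConfig.desk(seed=seed, n_individuals=n, **kw)
    return rs.found_population(panel, cfg, np.random.default_rng(seed), arch), cfg


def test_equal_sex_ratio(desk_panel, desk_arch):
    pop, _ = _founders(desk_panel, desk_arch, n=200)
    assert len(pop.males) == len(pop.females) == 100
    # deterministic alternation M, F, M, F ...
    assert pop.sex[0] == 0 and pop.sex[1] == 1


def test_monomorphic_panel_gives_zero_variance(desk_arch, desk_panel):
    """A panel of one duplicated haplotype yields fully homozygous founders
    and zero genetic variance."""
    hap = [np.zeros((2, n), dtype=np.uint8) for n in desk_panel.n_sites]
    panel = rs.HaplotypePanel(
        positions=desk_panel.positions, alleles=hap,
        chromosome_length_bp=desk_panel.chromosome_length_bp,
    )
    pop, _ = _founders(panel, desk_arch, n=50)
    assert rs.genetic_variance(pop.tbv) == 0.0


def test_founder_frequencies_match_panel(desk_panel, desk_arch):
    """Sampling haplotypes with replacement preserves panel allele
    frequencies (4.5-sigma binomial band across all sites)."""
    pop, _ = _founders(desk_panel, desk_arch, n=500, seed=3)
    for c in range(desk_panel.n_chromosomes):
        p = desk_panel.allele_frequencies(c)
        obs = pop.haplotypes[c].mean(axis=(0, 1))
        se = np.sqrt(p * (1 - p) / (2 * 500))
        assert (np.abs(obs - p) < 4.5 * se + 1e-12).all()


def test_select_sires_argmax_and_limits():
    pop = make_population(tbvs=[1.0, 3.0, 2.0, 0.0], sexes=[0, 0, 0, 1])
    assert list(rs.select_sires(pop, 1)) == [1]
    assert sorted(rs.select_sires(pop, 3)) == [0, 1, 2]  # all males
    with pytest.raises(ConfigurationError):
        rs.select_sires(pop, 4)


def test_select_sires_matches_sort_oracle():
    rng = np.random.default_rng(8)
    tbvs = rng.normal(size=1000)
    sexes = np.tile([0, 1], 500)
    pop = make_population(tbvs=tbvs, sexes=sexes)
    chosen = rs.select_sires(pop, 25)
    males = [(tbvs[i], i) for i in range(1000) if sexes[i] == 0]
    oracle = [i for _, i in sorted(males, key=lambda t: (-t[0], t[1]))[:25]]
    assert list(chosen) == oracle


def test_select_sires_tie_break_lower_id():
    pop = make_population(tbvs=[2.0, 2.0, 2.0, 0.0], sexes=[0, 0, 0, 1])
    assert list(rs.select_sires(pop, 2)) == [0, 1]


def test_single_sire_forced_paternity(desk_panel, desk_arch, desk_map):
    pop, cfg = _founders(desk_panel, desk_arch, n=40, seed=1)
    sires = rs.select_sires(pop, 1)
    nxt = rs.advance_generation(pop, sires, desk_map, desk_arch, cfg, np.random.default_rng(2))
    assert (nxt.sire == sires[0]).all()
    assert np.isin(nxt.dam, pop.females).all()
    assert nxt.generation == pop.generation + 1


def test_offspring_spread_uniformly_over_sires(desk_panel, desk_arch, desk_map):
    """With 25 sires and 10,000 offspring, per-sire counts are uniform
    (chi-square against the multinomial oracle)."""
    pop, cfg = _founders(desk_panel, desk_arch, n=100, seed=4)
    cfg = rs.BreedingConfig.desk(seed=4, n_individuals=10_000, n_sires=25)
    sires = rs.select_sires(pop, 25)
    nxt = rs.advance_generation(pop, sires, desk_map, desk_arch, cfg, np.random.default_rng(5))
    counts = np.array([(nxt.sire == s).sum() for s in sires])
    assert counts.sum() == 10_000
    assert stats.chisquare(counts).pvalue > 0.01


def test_mendelian_certainty_for_fixed_parents(desk_arch, desk_panel):
    """If both parents are homozygous for allele 1 at every site, every
    offspring has dosage 2 everywhere."""
    hap = [np.ones((4, n), dtype=np.uint8) for n in desk_panel.n_sites]
    panel = rs.HaplotypePanel(
        positions=desk_panel.positions, alleles=hap,
        chromosome_length_bp=desk_panel.chromosome_length_bp,
    )
    pop, cfg = _founders(panel, desk_arch, n=20, seed=6)
    m = rs.build_region_map(100, 1, panel.chromosome_length_bp, 2)
    nxt = rs.advance_generation(pop, pop.males[:3], m, desk_arch, cfg, np.random.default_rng(7))
    for c in range(2):
        assert (nxt.haplotypes[c].sum(axis=1) == 2).all()


def test_run_breeding_generation_labels_and_history_pairing(desk_panel, desk_map, desk_arch):
    """Generations run -(H-1)..0..F; the historical phase is bit-identical
    between the shift and no-shift arms under a shared seed."""
    base = rs.BreedingConfig.desk(seed=9)
    frame = rs.run_breeding(desk_panel, desk_map, desk_arch, base)
    assert list(frame.generation) == list(range(-9, 21))
    assert frame.loc[frame.generation == 0, "gain_std_units"].iloc[0] == 0.0

    shifted = rs.BreedingConfig.desk(seed=9, shift_at_generation_zero=True)
    frame_s = rs.run_breeding(desk_panel, desk_map, desk_arch, shifted)
    hist = frame[frame.generation <= 0].reset_index(drop=True)
    hist_s = frame_s[frame_s.generation <= 0].reset_index(drop=True)
    assert hist.equals(hist_s)
    # arms must diverge after the shift
    assert not frame[frame.generation > 0].equals(frame_s[frame_s.generation > 0])

    # no future generations -> historical summaries only
    short = rs.BreedingConfig.desk(seed=9, n_future_generations=0)
    assert len(rs.run_breeding(desk_panel, desk_map, desk_arch, short)) == 10


def test_run_breeding_is_deterministic(desk_panel, desk_map, desk_arch):
    cfg = rs.BreedingConfig.desk(seed=13, n_individuals=60, n_sires=5,
                                 n_historical_generations=3, n_future_generations=3)
    a = rs.run_breeding(desk_panel, desk_map, desk_arch, cfg)
    b = rs.run_breeding(desk_panel, desk_map, desk_arch, cfg)
    assert a.equals(b)


def test_pedigree_validity(desk_panel, desk_map, desk_arch):
    """Every non-founder's sire is a selected top-TBV male and its dam a
    previous-generation female."""
    cfg = rs.BreedingConfig.desk(seed=21, n_individuals=60, n_sires=5,
                                 n_historical_generations=4, n_future_generations=4)
    _, pops = rs.run_breeding(desk_panel, desk_map, desk_arch, cfg, keep_populations=True)
    for prev, curr in zip(pops, pops[1:]):
        expected_sires = set(rs.select_sires(prev, cfg.n_sires))
        assert set(np.unique(curr.sire)) <= expected_sires
        assert np.isin(curr.dam, prev.females).all()
        assert len(np.intersect1d(curr.ids, prev.ids)) == 0


def test_mean_tbv_nearly_monotone_under_selection(desk_panel, desk_map, desk_arch):
    """Truncation selection drives mean TBV up in >= 95% of generation steps
    across 10 desk replicates."""
    up = total = 0
    for seed in range(10):
        cfg = rs.BreedingConfig.desk(seed=seed, n_individuals=100, n_sires=5,
                                     n_historical_generations=5, n_future_generations=10)
        frame = rs.run_breeding(desk_panel, desk_map, desk_arch, cfg)
        steps = np.diff(frame.mean_tbv.values)
        up += (steps >= 0).sum()
        total += len(steps)
    assert up / total >= 0.95


def test_neutral_genic_variance_decays_at_drift_rate(desk_panel, desk_arch):
    """With selection switched off (all males are sires), genic variance
    decays like (1 - 1/(2Ne))^t with Ne = N for this mating design."""
    n, gens = 100, 25
    m = rs.build_region_map(100, 1, desk_panel.chromosome_length_bp, 2)
    ratios = []
    for seed in range(10):
        cfg = rs.BreedingConfig.desk(seed=seed, n_individuals=n, n_sires=n // 2,
                                     n_historical_generations=1 + gens,
                                     n_future_generations=0,
                                     base_generation=-gens)
        frame = rs.run_breeding(desk_panel, m, desk_arch, cfg)
        ratios.append(frame.genic_variance.iloc[-1] / frame.genic_variance.iloc[0])
    predicted = (1 - 1 / (2 * n)) ** gens
    se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
    assert abs(np.mean(ratios) - predicted) < 3 * se


def test_two_per_dam_scheme_runs(desk_panel, desk_map, desk_arch):
    cfg = rs.BreedingConfig.desk(seed=2, n_individuals=60, n_sires=5,
                                 n_historical_generations=3, n_future_generations=2,
                                 dam_scheme="two_per_dam")
    _, pops = rs.run_breeding(desk_panel, desk_map, desk_arch, cfg, keep_populations=True)
    for pop in pops[1:]:
        counts = np.unique(pop.dam, return_counts=True)[1]
        assert counts.max() == 2  # every dam has exactly two offspring


def test_invalid_breeding_configs():
    with pytest.raises(ConfigurationError):
        rs.BreedingConfig(n_individuals=101)
    with pytest.raises(ConfigurationError):
        rs.BreedingConfig(n_individuals=100, n_sires=51)
    with pytest.raises(ConfigurationError):
        rs.BreedingConfig(dam_scheme="harem")
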