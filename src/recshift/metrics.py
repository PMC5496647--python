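"""Response variables: standardized genetic gain, genetic and genic variance.

Per generation the simulator reports:

* **genetic gain** in base-generation standard deviations,
  (mean TBV_curr - mean TBV_base) / sd(TBV_base);
* **genetic variance** (realised additive variance)
  sigma_A^2 = a'a/(n-1) with *a* the mean-centred TBV vector — this reflects
  both allele frequencies and linkage disequilibrium;
* **genic variance** sigma_alpha^2 = 2 * sum_i p_i q_i alpha_i^2, the
  additive variance expected were all QTN independent and in Hardy–Weinberg
  equilibrium; fixed QTN contribute zero but remain in the architecture;
* mean expected heterozygosity 2pq at the QTN.

The default base generation is generation 0, the start of future breeding,
which is what all reported curves are standardised to.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DimensionError

__all__ = [
    "GenerationSummary",
    "genetic_gain",
    "genetic_variance",
    "genic_variance",
    "expected_heterozygosity",
    "summarize_generation",
    "summaries_to_frame",
]


@dataclass
class GenerationSummary:
    """Metrics for one generation of one simulation run."""

    generation: int
    mean_tbv: float
    gain_std_units: float
    genetic_variance: float
    genic_variance: float
    mean_heterozygosity: float


def genetic_gain(mean_curr: float, mean_base: float, sd_base: float) -> float:
    """Gain in units of the base-generation TBV standard deviation."""
    if sd_base <= 0:
        raise ConfigurationError(f"base-generation TBV sd must be > 0, got {sd_base}")
    return (mean_curr - mean_base) / sd_base


def genetic_variance(tbvs: np.ndarray) -> float:
    """Realised additive variance a'a/(n-1), a = mean-centred TBV vector."""
    tbvs = np.asarray(tbvs, dtype=float)
    n = tbvs.shape[0]
    if tbvs.ndim != 1 or n < 2:
        raise ConfigurationError("need a 1-D TBV vector with n >= 2")
    a = tbvs - tbvs.mean()
    return float(a @ a / (n - 1))


def genic_variance(freqs: np.ndarray, effects: np.ndarray) -> float:
    """2 * sum p q alpha^2 over QTN; zero for fixed QTN (p in {0, 1})."""
    p = np.asarray(freqs, dtype=float)
    alpha = np.asarray(effects, dtype=float)
    if p.shape != alpha.shape:
        raise DimensionError(f"frequency/effect length mismatch: {p.shape} vs {alpha.shape}")
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("allele frequencies must lie in [0, 1]")
    return float(2.0 * np.sum(p * (1.0 - p) * alpha**2))


def expected_heterozygosity(freqs: np.ndarray) -> float:
    """Mean 2pq over QTN; lies in [0, 0.5]."""
    p = np.asarray(freqs, dtype=float)
    return float(np.mean(2.0 * p * (1.0 - p)))


def summarize_generation(
    generation: int,
    tbvs: np.ndarray,
    qtn_freqs: np.ndarray,
    effects: np.ndarray,
    base_mean: float | None = None,
    base_sd: float | None = None,
) -> GenerationSummary:
    """Assemble all per-generation metrics.

    If the base statistics are not yet known (the base generation occurs
    mid-run), ``gain_std_units`` is NaN and is filled in afterwards.
    """
    mean = float(np.mean(tbvs))
    gain = np.nan
    if base_mean is not None and base_sd is not None:
        gain = genetic_gain(mean, base_mean, base_sd)
    return GenerationSummary(
        generation=generation,
        mean_tbv=mean,
        gain_std_units=gain,
        genetic_variance=genetic_variance(tbvs),
        genic_variance=genic_variance(qtn_freqs, effects),
        mean_heterozygosity=expected_heterozygosity(qtn_freqs),
    )


def summaries_to_frame(summaries: list[GenerationSummary]) -> pd.DataFrame:
    """Tidy one-row-per-generation DataFrame."""
    return pd.DataFrame([asdict(s) for s in summaries])
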