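"""Rate arithmetic and statistical utilities for the recombination screen.

Covers the per-plant conversion rate from screen counts, the per-meiosis
rate from progeny counts, the detection-threshold truncation correction
(the tall-plant cutoff misses the lower tail of the revertant height
distribution), a Bayesian discriminator between point mutation and gene
conversion as the source of a specific base reversion, mosaic-fraction
estimation from amplicon read counts, and small test utilities (Wilcoxon
signed-rank, segregation chi-square, two-proportion chi-square lives in
:mod:`mitorec.events`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TISSUES = ("flag_leaf", "basal_leaf", "root")


@dataclass(frozen=True)
class ScreenCounts:
    """Counts from a phenotypic screen of an F1 population.

    The per-plant gene-conversion rate normalises the event count by the
    population size, the two haplotypes at risk, and the two intragenic
    markers assayed.
    """

    n_plants: int
    n_gc_events: int
    n_co_events: int = 0
    n_haplotypes: int = 2
    n_markers: int = 2

    def __post_init__(self) -> None:
        if self.n_plants <= 0:
            raise ValueError("population size must be positive")
        if min(self.n_gc_events, self.n_co_events) < 0:
            raise ValueError("event counts must be non-negative")
        if self.n_gc_events + self.n_co_events > self.n_plants:
            raise ValueError("more events than screened plants")


@dataclass(frozen=True)
class TruncationResult:
    """Detection-threshold correction under a normal phenotype model."""

    z: float
    missed_fraction: float
    corrected_total: float


@dataclass(frozen=True)
class MutationPrior:
    """Prior pieces for the mutation-vs-conversion discrimination.

    ``mu`` is the point mutation rate per bp per generation; only one of
    the three possible base changes produces the specific observed
    substitution, hence ``specific_change_fraction`` defaults to 1/3.
    ``expected_mutants`` (the expected number of plants carrying the
    specific substitution by mutation alone) is recomputed from ``mu``
    unless overridden.
    """

    mu: float
    n_plants: float
    specific_change_fraction: float = 1.0 / 3.0
    expected_mutants: float | None = None

    def __post_init__(self) -> None:
        if self.mu < 0 or self.n_plants <= 0:
            raise ValueError("mu must be >= 0 and n_plants > 0")
        if self.expected_mutants is None:
            object.__setattr__(
                self,
                "expected_mutants",
                self.mu * self.specific_change_fraction * self.n_plants,
            )

    @property
    def site_rate(self) -> float:
        """Per-site per-generation probability of the specific change."""
        return self.mu * self.specific_change_fraction


@dataclass(frozen=True)
class MosaicSample:
    """Recombinant-cell fraction of one tissue sample from read counts."""

    sample_id: str
    tissue: str
    tiller: str
    n_recombinant: int
    n_nonrecombinant: int
    fraction_recombinant: float
    depth: int
    pass_depth: bool
    corrected_fraction: float | None = None


def per_plant_gc_rate(counts: ScreenCounts) -> float:
    """Gene-conversion rate per marker per haplotype per plant."""
    return counts.n_gc_events / counts.n_plants / counts.n_haplotypes / counts.n_markers


def meiotic_event_rate(
    n_events: int,
    n_individuals: int,
    gametes_per_individual: int = 2,
    transmission_prob: float = 0.25,
) -> float:
    """Per-meiosis event rate from events observed in progeny.

    Each individual derives from two gametes (hence two meioses) and a
    meiotic event is transmitted to any given gamete with probability 1/4,
    so the observed frequency is divided by both factors.
    """
    if n_individuals <= 0 or gametes_per_individual <= 0 or transmission_prob <= 0:
        raise ValueError("denominators must be positive")
    if n_events < 0:
        raise ValueError("event count must be non-negative")
    return n_events / n_individuals / gametes_per_individual / transmission_prob


def truncation_correction(
    mean: float, sd: float, cutoff: float, observed: int
) -> TruncationResult:
    """Correct an observed count for individuals missed below a cutoff.

    Assumes the selected phenotype (revertant height) is normal with the
    given mean and sd; the fraction below the cutoff is the standard normal
    lower tail at Z = (cutoff - mean)/sd and the corrected total is
    observed / (1 - missed).
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    z = (cutoff - mean) / sd
    missed = float(stats.norm.cdf(z))
    return TruncationResult(z=z, missed_fraction=missed, corrected_total=observed / (1.0 - missed))


def bayes_mutation_posterior(prior: MutationPrior, n_obs: int) -> tuple[float, float]:
    """Posterior odds that observed reversions are mutations, not conversions.

    With a flat prior over source, the probability that one observed
    specific substitution arose by point mutation is

        p_mut = r / (r + f_obs),   r = mu/3,
        f_obs = (n_obs - expected_mutants) / n_plants,

    and the probability that none of the ``n_obs`` observations is a
    mutation is (1 - p_mut)^n_obs.  Returns ``(p_mut, p_all_not_mutation)``.
    """
    if n_obs < 0:
        raise ValueError("n_obs must be non-negative")
    rate = prior.site_rate
    obs_freq = (n_obs - prior.expected_mutants) / prior.n_plants
    if obs_freq < 0:
        obs_freq = 0.0
    if rate == 0 and obs_freq == 0:
        raise ValueError("posterior undefined: both mutation rate and observed frequency are zero")
    p_mut = rate / (rate + obs_freq)
    return p_mut, (1.0 - p_mut) ** n_obs


def mosaic_fraction(
    counts: pd.DataFrame,
    min_depth: int = 1,
    error_rate: float | None = None,
) -> list[MosaicSample]:
    """Recombinant-cell fraction per tissue sample from diagnostic-site reads.

    ``counts`` needs columns sample_id, tissue, tiller, n_rec, n_nonrec
    (reads carrying the recombinant-type and nonrecombinant-type base at
    the diagnostic site).  Samples below ``min_depth`` are flagged rather
    than dropped.  If ``error_rate`` e is given, a symmetric base-error
    deconvolution f = (p - e)/(1 - 2e) (clipped to [0, 1]) is also
    reported.
    """
    required = {"sample_id", "tissue", "tiller", "n_rec", "n_nonrec"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    if error_rate is not None and not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    out: list[MosaicSample] = []
    for row in counts.itertuples(index=False):
        n_rec, n_nonrec = int(row.n_rec), int(row.n_nonrec)
        if n_rec < 0 or n_nonrec < 0:
            raise ValueError("read counts must be non-negative")
        depth = n_rec + n_nonrec
        if depth == 0:
            raise ValueError(f"zero read depth for sample {row.sample_id!r}")
        frac = n_rec / depth
        corrected = None
        if error_rate is not None:
            corrected = float(np.clip((frac - error_rate) / (1 - 2 * error_rate), 0.0, 1.0))
        out.append(
            MosaicSample(
                sample_id=str(row.sample_id),
                tissue=str(row.tissue),
                tiller=str(row.tiller),
                n_recombinant=n_rec,
                n_nonrecombinant=n_nonrec,
                fraction_recombinant=frac,
                depth=depth,
                pass_depth=depth >= min_depth,
                corrected_fraction=corrected,
            )
        )
    return out


def paired_rank_test(x, y) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples (exact for n <= 25).

    Identical samples (all differences zero) return ``(0.0, 1.0)``.
    Returns ``(statistic, p)`` for the two-sided alternative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 pairs")
    if np.all(x == y):
        return 0.0, 1.0
    method = "exact" if len(x) <= 25 else "auto"
    res = stats.wilcoxon(x, y, zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue)


def segregation_test(
    counts: tuple[int, int, int], expected_ratio: tuple[float, ...] = (1, 2, 1)
) -> tuple[float, float, int]:
    """Pearson chi-square of genotype counts against an expected ratio.

    Default ratio 1:2:1 is the Mendelian expectation for selfing a
    heterozygous carrier.  Returns ``(statistic, p, df)``.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.sum() <= 0:
        raise ValueError("total count must be positive")
    if len(obs) != len(expected_ratio):
        raise ValueError("counts and expected ratio have different lengths")
    ratio = np.asarray(expected_ratio, dtype=float)
    expected = obs.sum() * ratio / ratio.sum()
    stat, p = stats.chisquare(obs, f_exp=expected)
    return float(stat), float(p), len(obs) - 1


def standard_error(sd: float, n: int) -> float:
    """Standard error of a mean from the sample sd and size."""
    if sd < 0 or n <= 0:
        raise ValueError("sd must be >= 0 and n > 0")
    return sd / math.sqrt(n)
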