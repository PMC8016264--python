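"""Forward cell-lineage model of early plant development.

The zygote grows as a binary cell tree.  At each division every cell
independently acquires a recombination event with a per-division
probability; because conversion resolves on one chromatid, a new event
enters exactly one of the two daughters, while daughters of an
already-recombinant cell both inherit the changed genotype.  At the
root/shoot split (the division at which the founder pools are drawn) the
founders of the root meristem (RM) and shoot apical meristem (SAM) are
allocated uniformly at random without replacement among the cells then
present.

A screened phenotype (tall stature plus recombinant roots) requires a
minimum number of recombinant founders in each pool, so an event is
detectable only if it happened before the root/shoot split.  Inverting the
Monte-Carlo detection probability against the observed per-plant event
frequency calibrates the per-division event rate; in the small-rate regime
the detection probability is linear in the rate, which the calibrator
exploits for its final refinement.

There is no cell-lineage competition in this model, and the observed
fixation of recombinant cells in late leaves is deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "OntogenyConfig",
    "LineageOutcome",
    "DetectionEstimate",
    "CalibrationResult",
    "SITUATIONS",
    "simulate_lineage",
    "detection_probability",
    "calibrate_rate",
    "simulate_gamete_path",
]


@dataclass(frozen=True)
class OntogenyConfig:
    """Founder-cell configuration for early development.

    ``split_division`` is the division index at which the RM/SAM founders
    are drawn (``None`` auto-selects the earliest division with enough
    cells, e.g. the 4-cell stage for 2+2 founders).  ``n_divisions`` is the
    total zygote-to-gamete division count used by path-level quantities.
    """

    n_founders_rm: int
    n_founders_sam: int
    min_rec_rm: int = 1
    min_rec_sam: int = 1
    split_division: int | None = None
    n_divisions: int = 40
    rate_per_division: float | None = None

    def __post_init__(self) -> None:
        if min(self.n_founders_rm, self.n_founders_sam) < 1:
            raise ValueError("founder pools must contain at least one cell")
        if not (1 <= self.min_rec_rm <= self.n_founders_rm):
            raise ValueError("min_rec_rm must be in [1, n_founders_rm]")
        if not (1 <= self.min_rec_sam <= self.n_founders_sam):
            raise ValueError("min_rec_sam must be in [1, n_founders_sam]")
        split = self.resolved_split()
        if 2 ** split < self.n_founders_rm + self.n_founders_sam:
            raise ValueError(
                f"cannot allocate {self.n_founders_rm + self.n_founders_sam} "
                f"founders from {2 ** split} cells at division {split}"
            )

    def resolved_split(self) -> int:
        if self.split_division is not None:
            if self.split_division < 1:
                raise ValueError("split_division must be >= 1")
            return self.split_division
        total = self.n_founders_rm + self.n_founders_sam
        return max(1, math.ceil(math.log2(total)))


#: the four founder configurations considered viable for rice early
#: development: (RM founders (minimum recombinant), SAM founders (minimum))
SITUATIONS: dict[int, OntogenyConfig] = {
    1: OntogenyConfig(n_founders_rm=2, n_founders_sam=2, min_rec_rm=1, min_rec_sam=1),
    2: OntogenyConfig(n_founders_rm=3, n_founders_sam=2, min_rec_rm=2, min_rec_sam=1),
    3: OntogenyConfig(n_founders_rm=4, n_founders_sam=4, min_rec_rm=2, min_rec_sam=1),
    4: OntogenyConfig(n_founders_rm=4, n_founders_sam=4, min_rec_rm=3, min_rec_sam=1),
}


@dataclass(frozen=True)
class LineageOutcome:
    """Result of one simulated lineage up to the root/shoot split."""

    detected: bool
    rec_fraction_root: float
    rec_fraction_shoot: float
    n_rec_rm: int
    n_rec_sam: int
    transmitted_to_gamete: bool


@dataclass(frozen=True)
class DetectionEstimate:
    probability: float
    ci_low: float
    ci_high: float
    n_reps: int
    n_detected: int


@dataclass(frozen=True)
class CalibrationResult:
    rate: float
    ci_low: float
    ci_high: float
    detection_probability: float
    n_reps: int
    config: OntogenyConfig


def _simulate_batch(
    config: OntogenyConfig, rate: float, n_reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised tree growth; returns (detected, n_rec_rm, n_rec_sam)."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must be a probability")
    split = config.resolved_split()
    rec = np.zeros((n_reps, 1), dtype=bool)
    for _ in range(split):
        n_cells = rec.shape[1]
        daughters = np.repeat(rec, 2, axis=1)
        events = rng.random((n_reps, n_cells)) < rate
        which = rng.integers(0, 2, size=(n_reps, n_cells))
        # a new event enters exactly one daughter of a non-recombinant parent
        r, c = np.where(events & ~rec)
        daughters[r, 2 * c + which[r, c]] = True
        rec = daughters
    n_cells = rec.shape[1]
    total = config.n_founders_rm + config.n_founders_sam
    # uniform allocation without replacement of founder cells to RM then SAM
    order = rng.random((n_reps, n_cells)).argsort(axis=1)
    founders = order[:, :total]
    rec_founders = np.take_along_axis(rec, founders, axis=1)
    n_rec_rm = rec_founders[:, : config.n_founders_rm].sum(axis=1)
    n_rec_sam = rec_founders[:, config.n_founders_rm :].sum(axis=1)
    detected = (n_rec_rm >= config.min_rec_rm) & (n_rec_sam >= config.min_rec_sam)
    return detected, n_rec_rm, n_rec_sam


def simulate_lineage(
    config: OntogenyConfig, rate: float | None = None, seed: int | np.random.Generator = 0
) -> LineageOutcome:
    """Simulate one zygote lineage to the root/shoot split.

    An event carried by a founder is transmitted to a sampled gamete with
    probability 1/2 (it sits on one of the two homologues).
    """
    rng = np.random.default_rng(seed)
    if rate is None:
        rate = config.rate_per_division
    if rate is None:
        raise ValueError("no rate_per_division given")
    detected, n_rm, n_sam = _simulate_batch(config, rate, 1, rng)
    carried = bool(n_sam[0] > 0)
    return LineageOutcome(
        detected=bool(detected[0]),
        rec_fraction_root=float(n_rm[0] / config.n_founders_rm),
        rec_fraction_shoot=float(n_sam[0] / config.n_founders_sam),
        n_rec_rm=int(n_rm[0]),
        n_rec_sam=int(n_sam[0]),
        transmitted_to_gamete=carried and bool(rng.random() < 0.5),
    )


def detection_probability(
    config: OntogenyConfig,
    rate: float,
    n_reps: int = 100_000,
    seed: int | np.random.Generator = 0,
    confidence: float = 0.95,
) -> DetectionEstimate:
    """Monte-Carlo probability that a lineage shows the screened phenotype,
    with a Clopper-Pearson binomial CI."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    detected, _, _ = _simulate_batch(config, rate, n_reps, rng)
    k = int(detected.sum())
    ci = stats.binomtest(k, n_reps).proportion_ci(confidence_level=confidence)
    return DetectionEstimate(
        probability=k / n_reps,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_reps=n_reps,
        n_detected=k,
    )


def calibrate_rate(
    observed: float,
    config: OntogenyConfig,
    n_observed: int | None = None,
    tol: float | None = None,
    n_reps: int = 100_000,
    seed: int | np.random.Generator = 0,
    max_iter: int = 25,
    bracket: tuple[float, float] = (1e-9, 0.999),
) -> CalibrationResult:
    """Invert the detection probability to a per-division event rate.

    Bisection on the Monte-Carlo detection probability down to ``tol``
    (default: the MC standard error) followed by a linear-regime
    refinement rate = observed / (p_hat / rate_hat).  The CI combines the
    binomial CI of the final detection estimate with, when ``n_observed``
    (the screened population size behind ``observed``) is given, the
    Clopper-Pearson CI of the observed frequency itself.
    """
    if not 0 < observed < 1:
        raise ValueError("observed per-plant frequency must be in (0, 1); "
                         "a zero frequency is non-identifiable")
    rng = np.random.default_rng(seed)
    lo, hi = bracket
    p_hi = detection_probability(config, hi, n_reps, rng).probability
    if p_hi < observed:
        raise ValueError("observed frequency not bracketed: detection too rare even at max rate")
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)  # geometric bisection: rates span decades
        p_mid = detection_probability(config, mid, n_reps, rng).probability
        if p_mid < observed:
            lo = mid
        else:
            hi = mid
        if tol is not None and abs(p_mid - observed) < tol:
            break
        if hi / lo < 1.05:
            break
    rate = math.sqrt(lo * hi)
    est = detection_probability(config, rate, n_reps, rng)
    if est.probability == 0:
        raise ValueError("no detections at calibrated rate; increase n_reps")
    slope = est.probability / rate
    rate = observed / slope
    # slope CI from the proportion CI of the final evaluation
    slope_lo = slope * est.ci_low / est.probability
    slope_hi = slope * est.ci_high / est.probability
    if n_observed is not None:
        k = round(observed * n_observed)
        obs_ci = stats.binomtest(k, n_observed).proportion_ci(confidence_level=0.95)
        obs_lo, obs_hi = float(obs_ci.low), float(obs_ci.high)
    else:
        obs_lo = obs_hi = observed
    return CalibrationResult(
        rate=rate,
        ci_low=obs_lo / slope_hi,
        ci_high=obs_hi / slope_lo if slope_lo > 0 else math.inf,
        detection_probability=est.probability,
        n_reps=n_reps,
        config=replace(config, rate_per_division=rate),
    )


def simulate_gamete_path(
    n_divisions: int, rate: float, n_reps: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Events carried along one zygote-to-gamete cell path.

    Per division an event occurs in the tracked cell with probability
    ``rate`` and stays on the tracked path with probability 1/2, so the
    expected count is n * rate / 2.  Returns the per-replicate counts.
    """
    rng = np.random.default_rng(seed)
    hits = rng.random((n_reps, n_divisions)) < rate / 2.0
    return hits.sum(axis=1)
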