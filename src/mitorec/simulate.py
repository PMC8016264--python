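"""Synthetic-data generator: every input the pipeline consumes, with truth.

The generator emulates the structure of the field screen: a 15-marker map
spanning ~445 kb around the focal gene with the two intragenic diagnostic
markers 2.3 kb apart near the centre; an F1 population of all-heterozygous
vectors into which CO, NCO-GC and CO-GC events are planted at configurable
per-plant rates; amplicon read counts over a true mosaic fraction with a
symmetric base-error rate; and F2 progeny segregating 1:2:1 from a selfed
heterozygous carrier.

Planted-event geometry follows the footprint templates the classifier
recognises: a CO is a terminal homozygous run from a breakpoint drawn
uniformly over the surveyed span; an NCO-GC converts the markers covered by
a tract of sampled length dropped uniformly on the span; a CO-GC is a CO
whose homozygous region carries an embedded opposite-state tract kept
below the two-CO threshold.  Every plant's planted events are recorded as
ground truth so recovery can be scored exactly.

Default per-plant event rates are the screen frequencies observed in the
1.1-million-plant population (18 CO, 3 NCO-GC, 3 CO-GC); the default tract-
length distribution is a two-component log-normal mixture spanning the
~8 kb to ~250 kb range of called tracts — a stand-in, as the real tract-
length distribution is known only through a few dozen events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genotypes import H, MISSING, N, P, GenotypeVector, MarkerMap
from .tracts import midpoint_tract

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class TractLengthMixture:
    """Two-component log-normal tract-length mixture (bp)."""

    weights: tuple[float, float] = (0.7, 0.3)
    log_means: tuple[float, float] = (np.log(8_000.0), np.log(60_000.0))
    log_sds: tuple[float, float] = (0.5, 0.6)

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        n = 1 if size is None else size
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights) / sum(self.weights))
        draws = rng.lognormal(
            mean=np.asarray(self.log_means)[comp], sigma=np.asarray(self.log_sds)[comp]
        )
        return float(draws[0]) if size is None else draws


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic screen."""

    n_markers: int = 15
    span_bp: int = 445_000
    spacing: str = "uniform"  # uniform | field-like
    focal_distance_bp: int = 2_300
    rate_co: float = 18 / 1_100_000
    rate_nco_gc: float = 3 / 1_100_000
    rate_co_gc: float = 3 / 1_100_000
    tract_lengths: TractLengthMixture = field(default_factory=TractLengthMixture)
    cogc_tract_max_bp: float = 60_000.0
    long_threshold: float = 100_000.0
    read_depth: int = 100_000
    base_error_rate: float = 1e-3
    n_f2_per_plant: int = 43

    def __post_init__(self) -> None:
        if self.n_markers < 4:
            raise ValueError("need at least 4 markers")
        rates = (self.rate_co, self.rate_nco_gc, self.rate_co_gc)
        if any(r < 0 for r in rates) or sum(rates) > 1:
            raise ValueError("per-plant event rates must be >= 0 and sum to <= 1")
        if self.spacing not in ("uniform", "field-like"):
            raise ValueError(f"unknown spacing {self.spacing!r}")
        if self.read_depth < 1:
            raise ValueError("read depth must be >= 1")


@dataclass
class PlantedEvent:
    """Ground truth for one planted event."""

    event_class: str                     # CO | NCO_GC | CO_GC
    donor: str                           # to_N | to_P
    breakpoint_bp: float | None = None   # CO breakpoint (bp)
    co_side: str | None = None           # left | right (side turned homozygous)
    tract_start_bp: float | None = None  # true tract bounds (bp)
    tract_end_bp: float | None = None
    converted_markers: tuple[int, ...] = ()
    co_markers: tuple[int, ...] = ()


@dataclass
class TruthRecord:
    sample_id: str
    events: list[PlantedEvent]


class SyntheticPopulation:
    """A generated F1 population with per-plant ground truth.

    States are held as a dense (n_plants x n_markers) character array;
    plants without planted events are all-H.
    """

    def __init__(self, states: np.ndarray, sample_ids: Sequence[str],
                 truth: dict[str, TruthRecord], mmap: MarkerMap):
        self.states = states
        self.sample_ids = list(sample_ids)
        self.truth = truth
        self.mmap = mmap

    @property
    def n_plants(self) -> int:
        return self.states.shape[0]

    def vector(self, i: int) -> GenotypeVector:
        return GenotypeVector(self.sample_ids[i], tuple(self.states[i]))

    def event_plant_indices(self) -> list[int]:
        ids = {s: i for i, s in enumerate(self.sample_ids)}
        return sorted(ids[s] for s in self.truth)

    def non_h_plant_indices(self) -> np.ndarray:
        return np.nonzero((self.states != H).any(axis=1))[0]

    def write_genotypes(self, path: str | Path) -> None:
        from .genotypes import write_genotypes

        write_genotypes(
            (self.vector(i) for i in range(self.n_plants)), self.mmap, path
        )

    def write_truth(self, path: str | Path) -> None:
        payload = {
            s: [asdict(e) for e in rec.events] for s, rec in self.truth.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_marker_map(config: SyntheticConfig = SyntheticConfig(),
                   seed: int | np.random.Generator = 0) -> MarkerMap:
    """Generate a marker map over the configured span.

    ``uniform`` spacing places markers evenly; ``field-like`` draws
    log-normal gaps and forces one dense (<2 kb) and one sparse (>90 kb)
    interval so classifier edge cases are exercised.  In both modes the
    focal pair sits near the centre at the configured intragenic distance.
    """
    rng = _rng(seed)
    n, span = config.n_markers, config.span_bp
    f0 = n // 2
    f1 = f0 + 1
    if config.spacing == "uniform":
        pos = np.linspace(1, span + 1, n)
        pos[f1] = pos[f0] + config.focal_distance_bp
    else:
        gaps = rng.lognormal(mean=np.log(span / n), sigma=1.0, size=n - 1)
        gaps[f0] = 0.0  # focal gap fixed afterwards
        order = np.argsort(gaps)
        nonfocal = [i for i in order if i != f0]
        gaps[nonfocal[0]] = rng.uniform(500, 1_900)      # one dense interval
        gaps[nonfocal[-1]] = rng.uniform(91_000, 120_000)  # one sparse interval
        free = [i for i in range(n - 1) if i != f0]
        fixed = gaps[nonfocal[0]] + gaps[nonfocal[-1]] + config.focal_distance_bp
        scalable = [i for i in free if i not in (nonfocal[0], nonfocal[-1])]
        scale = (span - fixed) / gaps[scalable].sum()
        gaps[scalable] *= scale
        gaps[f0] = config.focal_distance_bp
        pos = np.concatenate([[1.0], 1.0 + np.cumsum(gaps)])
    positions = np.round(pos).astype(int)
    for i in range(1, n):
        if positions[i] <= positions[i - 1]:
            positions[i] = positions[i - 1] + 1
    allele_n = rng.choice(_BASES, size=n)
    allele_p = np.array(
        [rng.choice([b for b in _BASES if b != a]) for a in allele_n]
    )
    return MarkerMap(
        marker_id=tuple(f"M{i + 1}" for i in range(n)),
        chromosome="chr1",
        position=tuple(int(p) for p in positions),
        allele_n=tuple(allele_n),
        allele_p=tuple(allele_p),
        focal_markers=(f0, f1),
    )


def _markers_in(mmap: MarkerMap, lo: float, hi: float) -> np.ndarray:
    pos = np.asarray(mmap.position)
    return np.nonzero((pos >= lo) & (pos <= hi))[0]


def _plant_co(states: np.ndarray, mmap: MarkerMap, rng: np.random.Generator) -> PlantedEvent:
    pos = np.asarray(mmap.position)
    bp = rng.uniform(pos[0], pos[-1])
    donor = N if rng.random() < 0.5 else P
    side = "right" if rng.random() < 0.5 else "left"
    if side == "right":
        idx = np.nonzero(pos > bp)[0]
    else:
        idx = np.nonzero(pos < bp)[0]
    if idx.size == 0:  # breakpoint beyond outermost interval on that side
        idx = np.array([states.size - 1] if side == "right" else [0])
        bp = float(pos[idx[0]] - 0.5) if side == "right" else float(pos[idx[0]] + 0.5)
    states[idx] = donor
    return PlantedEvent(
        event_class="CO", donor=f"to_{donor}", breakpoint_bp=float(bp),
        co_side=side, co_markers=tuple(int(i) for i in idx),
    )


def _plant_nco_gc(states: np.ndarray, mmap: MarkerMap, config: SyntheticConfig,
                  rng: np.random.Generator) -> PlantedEvent:
    pos = np.asarray(mmap.position)
    length = float(config.tract_lengths.sample(rng))
    anchor = rng.uniform(pos[0], pos[-1])
    lo, hi = anchor, min(anchor + length, float(pos[-1]) + 1)
    donor = N if rng.random() < 0.5 else P
    idx = _markers_in(mmap, lo, hi)
    states[idx] = donor
    return PlantedEvent(
        event_class="NCO_GC", donor=f"to_{donor}", tract_start_bp=lo,
        tract_end_bp=hi, converted_markers=tuple(int(i) for i in idx),
    )


def _plant_co_gc(states: np.ndarray, mmap: MarkerMap, config: SyntheticConfig,
                 rng: np.random.Generator) -> PlantedEvent:
    """CO with an embedded opposite-state conversion tract.

    The CO turns markers b+1..end homozygous for the CO donor; the tract
    re-converts an interior sub-run, shrunk until its midpoint length stays
    below the two-CO threshold.
    """
    n = mmap.n_markers
    pos = np.asarray(mmap.position)
    co_donor = N if rng.random() < 0.5 else P
    tract_donor = P if co_donor == N else N
    # need >= 3 markers in the CO region: one flank, tract, one flank
    b = int(rng.integers(0, n - 3))  # last heterozygous marker index
    co_idx = np.arange(b + 1, n)
    states[co_idx] = co_donor
    bp = float(rng.uniform(pos[b], pos[b + 1]))
    # embedded tract: interior run of the CO region
    i = int(rng.integers(b + 2, n - 1))
    target = min(float(config.tract_lengths.sample(rng)), config.cogc_tract_max_bp)
    j = i
    while j + 1 <= n - 2 and pos[j + 1] - pos[i] <= target:
        j += 1
    while j > i and midpoint_tract((i, j), mmap).length >= config.long_threshold:
        j -= 1
    if midpoint_tract((i, j), mmap).length >= config.long_threshold:
        # single marker still too long (sparse map); plant it anyway, truth
        # records the geometry and the classifier will read two COs
        pass
    tract_idx = np.arange(i, j + 1)
    states[tract_idx] = tract_donor
    return PlantedEvent(
        event_class="CO_GC", donor=f"to_{tract_donor}", breakpoint_bp=bp,
        co_side="right", tract_start_bp=float(pos[i]), tract_end_bp=float(pos[j]),
        converted_markers=tuple(int(k) for k in tract_idx),
        co_markers=tuple(int(k) for k in co_idx),
    )


def gen_f1_population(
    n_plants: int,
    config: SyntheticConfig = SyntheticConfig(),
    seed: int | np.random.Generator = 0,
    mmap: MarkerMap | None = None,
) -> SyntheticPopulation:
    """Generate an F1 population with planted recombination events.

    Every plant starts all-H; each event class is planted independently
    with its per-plant rate.  Returns the population with ground truth for
    every plant that received at least one event.
    """
    rng = _rng(seed)
    if mmap is None:
        mmap = gen_marker_map(config, rng)
    states = np.full((n_plants, mmap.n_markers), H, dtype="U2")
    draws = rng.random((n_plants, 3))
    flags = draws < np.array([config.rate_co, config.rate_nco_gc, config.rate_co_gc])
    truth: dict[str, TruthRecord] = {}
    sample_ids = [f"S{i + 1}" for i in range(n_plants)]
    for i in np.nonzero(flags.any(axis=1))[0]:
        events: list[PlantedEvent] = []
        if flags[i, 0]:
            events.append(_plant_co(states[i], mmap, rng))
        if flags[i, 1]:
            events.append(_plant_nco_gc(states[i], mmap, config, rng))
        if flags[i, 2]:
            events.append(_plant_co_gc(states[i], mmap, config, rng))
        truth[sample_ids[i]] = TruthRecord(sample_id=sample_ids[i], events=events)
    return SyntheticPopulation(states, sample_ids, truth, mmap)


def gen_read_counts(
    true_fraction: float | Sequence[float],
    depth: int,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Binomial amplicon read counts at the diagnostic site.

    A read reports the recombinant base if it comes from a recombinant
    cell and is read correctly, or from a nonrecombinant cell and is
    miscalled: p = f(1-e) + (1-f)e.  Returns an array of shape (k, 2) with
    columns (n_recombinant, n_nonrecombinant).
    """
    rng = _rng(seed)
    f = np.atleast_1d(np.asarray(true_fraction, dtype=float))
    if np.any((f < 0) | (f > 1)):
        raise ValueError("true fractions must be in [0, 1]")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error rate must be in [0, 0.5)")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    p = f * (1 - error_rate) + (1 - f) * error_rate
    n_rec = rng.binomial(depth, p)
    return np.column_stack([n_rec, depth - n_rec])


F2_CLASSES = ("PdelPwt/PdelPwt", "PdelPwt/NwtPwt", "NwtPwt/NwtPwt")


def gen_f2(
    f1_restored_class: str,
    n_progeny: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """F2 genotype counts at the focal locus from selfing a restored F1.

    Only a heterozygous carrier of the restored haplotype (diagnostic
    class ``H8-P9``-like: one restored, one single-defect haplotype)
    segregates; its selfed progeny follow the Mendelian 1:2:1 over
    (defect/defect, defect/restored, restored/restored).
    """
    rng = _rng(seed)
    if not f1_restored_class.startswith("H"):
        raise ValueError(
            f"F1 class {f1_restored_class!r} is not a heterozygous restored "
            "carrier; 1:2:1 segregation applies to selfed H-class carriers"
        )
    if n_progeny < 1:
        raise ValueError("need at least one progeny")
    return rng.multinomial(n_progeny, [0.25, 0.5, 0.25])
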