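"""Segmentation of genotype vectors and classification of recombination events.

An F1 of the two-parent cross is heterozygous (``H``) at every informative
marker; mitotic recombination leaves characteristic footprints:

* a crossover (CO) with the LOH-producing spindle orientation makes every
  marker homozygous from the breakpoint to the chromosome end, so the
  vector shows ``H`` on one side and one homozygous state to the end;
* a noncrossover gene conversion (NCO-GC) converts a contiguous internal
  tract, so the vector shows ``H`` on both sides of a homozygous run;
* a CO with an associated conversion tract (CO-GC) shows a short homozygous
  tract of one parent embedded in, or abutting, the homozygous run of the
  other parent.

Because two independent COs within a short physical interval are suppressed
by crossover interference, a minority homozygous block is interpreted as a
conversion tract when its midpoint length is below ``long_threshold``
(default 100 kb) and as two adjacent COs otherwise.

The classifier is deterministic and depends only on the ordered block
sequence and the marker positions.  Patterns it cannot fit to a single
canonical type are decomposed into a minimal set of constituent events and
labelled ``OTHER``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .genotypes import H, HOMOZYGOUS, MISSING, GenotypeVector, MarkerMap
from .tracts import ConversionTract, midpoint_tract

CO = "CO"
NCO_GC = "NCO_GC"
CO_GC = "CO_GC"

OTHER = "OTHER"

#: pattern labels for canonical single events, keyed by gained state
_TRACT_TYPE = {"N": "Type1", "P": "Type2"}
_CO_TYPE = {"N": "Type4", "P": "Type5"}


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class StateBlock:
    """A maximal run of identically-called (non-missing) markers."""

    state: str
    first_marker: int
    last_marker: int

    def span(self, mmap: MarkerMap) -> int:
        """bp from first to last marker position."""
        return mmap.position[self.last_marker] - mmap.position[self.first_marker]


@dataclass
class RecombinationEvent:
    """A called CO / NCO-GC / CO-GC event.

    ``donor`` records which parental haplotype's alleles were gained
    (``to_N`` or ``to_P``); for a CO-GC it refers to the conversion tract.
    ``breakpoints`` are (left, right) marker-index pairs bounding each
    genotype transition between adjacent genotyped markers.
    """

    event_class: str
    pattern_type: str
    donor: str
    breakpoints: tuple[tuple[int, int], ...]
    tract: ConversionTract | None = None
    sample_id: str | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.event_class in (NCO_GC, CO_GC) and self.tract is None:
            raise ClassificationError(f"{self.event_class} event must carry a tract")
        if self.event_class == CO and self.tract is not None:
            raise ClassificationError("CO event cannot carry a tract")


@dataclass(frozen=True)
class EventSummary:
    """Event-class counts and the derived CO:NCO-GC statistics.

    ``co_to_ncogc_ratio`` counts CO-GC events on the CO side,
    (n_CO + n_CO_GC) / n_NCO_GC; ``co_associated_fraction`` is the share of
    conversion events that ride along with a CO,
    n_CO_GC / (n_CO_GC + n_NCO_GC).  Both are None when their denominator
    is zero.
    """

    n_co: int
    n_nco_gc: int
    n_co_gc: int
    co_to_ncogc_ratio: float | None
    co_associated_fraction: float | None


def segment(gv: GenotypeVector) -> list[StateBlock]:
    """Split a vector into maximal state blocks, skipping missing markers.

    Blocks tile the non-missing markers in order; a block may span interior
    missing markers when the calls on both sides agree.
    """
    blocks: list[StateBlock] = []
    for i, s in enumerate(gv.states):
        if s == MISSING:
            continue
        if blocks and blocks[-1].state == s:
            blocks[-1] = StateBlock(s, blocks[-1].first_marker, i)
        else:
            blocks.append(StateBlock(s, i, i))
    if not blocks:
        raise ClassificationError(f"sample {gv.sample_id!r}: all markers missing")
    return blocks


def _tract_for(block: StateBlock, mmap: MarkerMap, event_key: str | None) -> ConversionTract:
    return midpoint_tract((block.first_marker, block.last_marker), mmap, event_key=event_key)


def _tract_length(block: StateBlock, mmap: MarkerMap) -> float:
    return _tract_for(block, mmap, None).length


def _donor(state: str) -> str:
    return f"to_{state}"


def classify(
    blocks: Sequence[StateBlock],
    mmap: MarkerMap,
    long_threshold: float = 100_000,
    missing: frozenset[int] | Iterable[int] = frozenset(),
    sample_id: str | None = None,
) -> list[RecombinationEvent]:
    """Classify a block sequence into recombination events.

    Decision procedure over the ordered blocks:

    1. a single block is no event (an all-H vector is a nonrecombinant F1;
       uniform homozygosity offers no transition to call);
    2. a lone terminal homozygous block is one CO (terminal homozygosity
       cannot be distinguished from a tract running off the surveyed
       region);
    3. a lone internal homozygous block is one NCO-GC; a vector made solely
       of two or more such disjoint tracts is the two-conversion pattern
       (Type3);
    4. terminal homozygous blocks at both ends with heterozygosity between
       are two COs (Type6);
    5. within a run of adjacent homozygous blocks, a minority block whose
       midpoint length is strictly below ``long_threshold`` is a conversion
       tract associated with the CO that produced the surrounding
       homozygosity (CO-GC, embedded = Type7, abutting = Type8); at or
       above the threshold it is read as two adjacent COs;
    6. anything else is decomposed minimally and labelled OTHER.
    """
    missing = frozenset(missing)
    if not blocks:
        raise ClassificationError("empty block sequence")
    if len(blocks) == 1:
        return []

    # group maximal runs of consecutive homozygous blocks
    runs: list[list[int]] = []
    for i, b in enumerate(blocks):
        if b.state == H:
            continue
        if runs and runs[-1][-1] == i - 1:
            runs[-1].append(i)
        else:
            runs.append([i])

    events: list[RecombinationEvent] = []
    canonical_tract_runs = 0  # runs yielding one canonical internal NCO-GC
    for run in runs:
        left_h = run[0] > 0
        right_h = run[-1] < len(blocks) - 1
        run_blocks = [blocks[i] for i in run]
        new = _handle_run(run_blocks, left_h, right_h, blocks, run, mmap, long_threshold)
        if len(new) == 1 and new[0].event_class == NCO_GC and new[0].pattern_type != OTHER:
            canonical_tract_runs += 1
        events.extend(new)

    # Type3: the whole vector is two or more disjoint internal tracts
    if canonical_tract_runs >= 2 and all(
        e.event_class == NCO_GC and e.pattern_type in ("Type1", "Type2") for e in events
    ):
        for e in events:
            e.pattern_type = "Type3"

    # Type6: exactly two terminal COs, one at each end
    if (
        len(events) == 2
        and all(e.event_class == CO and e.pattern_type in ("Type4", "Type5") for e in events)
        and blocks[0].state != H
        and blocks[-1].state != H
        and len(runs) == 2
    ):
        for e in events:
            e.pattern_type = "Type6"

    for e in events:
        e.sample_id = sample_id
        if e.tract is not None and any(
            e.tract.first_converted <= m <= e.tract.last_converted for m in missing
        ):
            e.flags = tuple(sorted(set(e.flags) | {"low_confidence"}))
    return events


def _handle_run(
    run_blocks: list[StateBlock],
    left_h: bool,
    right_h: bool,
    blocks: Sequence[StateBlock],
    run: list[int],
    mmap: MarkerMap,
    thr: float,
) -> list[RecombinationEvent]:
    m = len(run_blocks)
    if m == 1:
        return _single_block(run_blocks[0], left_h, right_h, blocks, run, mmap)
    if m == 2:
        return _two_blocks(run_blocks, left_h, right_h, blocks, run, mmap, thr)
    if m == 3:
        # with two homozygous states a 3-block run is always X|Y|X
        return _embedded(run_blocks, left_h, right_h, blocks, run, mmap, thr)
    return _greedy(run_blocks, left_h, right_h, blocks, run, mmap)


def _left_breakpoint(blocks: Sequence[StateBlock], run: list[int]) -> tuple[int, int]:
    prev = blocks[run[0] - 1]
    return (prev.last_marker, blocks[run[0]].first_marker)


def _right_breakpoint(blocks: Sequence[StateBlock], run: list[int]) -> tuple[int, int]:
    nxt = blocks[run[-1] + 1]
    return (blocks[run[-1]].last_marker, nxt.first_marker)


def _single_block(
    b: StateBlock,
    left_h: bool,
    right_h: bool,
    blocks: Sequence[StateBlock],
    run: list[int],
    mmap: MarkerMap,
) -> list[RecombinationEvent]:
    if left_h and right_h:
        tract = _tract_for(b, mmap, None)
        return [
            RecombinationEvent(
                NCO_GC,
                _TRACT_TYPE[b.state],
                _donor(b.state),
                (_left_breakpoint(blocks, run), _right_breakpoint(blocks, run)),
                tract=tract,
            )
        ]
    if left_h or right_h:
        bp = _left_breakpoint(blocks, run) if left_h else _right_breakpoint(blocks, run)
        return [RecombinationEvent(CO, _CO_TYPE[b.state], _donor(b.state), (bp,))]
    # a single homozygous block with no heterozygous flank spans the whole
    # vector, which is the single-block case handled by the caller
    return []


def _two_blocks(
    run_blocks: list[StateBlock],
    left_h: bool,
    right_h: bool,
    blocks: Sequence[StateBlock],
    run: list[int],
    mmap: MarkerMap,
    thr: float,
) -> list[RecombinationEvent]:
    a, b = run_blocks
    adjacency_bp = (a.last_marker, b.first_marker)
    if not left_h and not right_h:
        # whole vector is X|Y: one CO plus a tract for the minority block,
        # or two adjacent COs when the minority is long
        la, lb = _tract_length(a, mmap), _tract_length(b, mmap)
        minority, majority = (a, b) if la <= lb else (b, a)
        if min(la, lb) < thr:
            tract = _tract_for(minority, mmap, None)
            return [
                RecombinationEvent(
                    CO_GC,
                    "Type8",
                    _donor(minority.state),
                    (adjacency_bp,),
                    tract=tract,
                    flags=("boundary_censored",),
                )
            ]
        return [
            RecombinationEvent(CO, OTHER, _donor(a.state), (adjacency_bp,), flags=("adjacent_co",)),
            RecombinationEvent(CO, OTHER, _donor(b.state), (adjacency_bp,), flags=("adjacent_co",)),
        ]
    if left_h and right_h:
        # both internal: two abutting conversion tracts of opposite donors
        return [
            RecombinationEvent(
                NCO_GC,
                OTHER,
                _donor(a.state),
                (_left_breakpoint(blocks, run), adjacency_bp),
                tract=_tract_for(a, mmap, None),
                flags=("adjacent_gc",),
            ),
            RecombinationEvent(
                NCO_GC,
                OTHER,
                _donor(b.state),
                (adjacency_bp, _right_breakpoint(blocks, run)),
                tract=_tract_for(b, mmap, None),
                flags=("adjacent_gc",),
            ),
        ]
    # one terminal, one internal: only the internal block can be a tract
    internal, terminal = (a, b) if left_h else (b, a)
    outer_bp = _left_breakpoint(blocks, run) if left_h else _right_breakpoint(blocks, run)
    li = _tract_length(internal, mmap)
    if li < thr:
        return [
            RecombinationEvent(
                CO_GC,
                "Type8",
                _donor(internal.state),
                (outer_bp, adjacency_bp),
                tract=_tract_for(internal, mmap, None),
            )
        ]
    return [
        RecombinationEvent(
            CO, OTHER, _donor(internal.state), (outer_bp,), flags=("adjacent_co",)
        ),
        RecombinationEvent(
            CO, OTHER, _donor(terminal.state), (adjacency_bp,), flags=("adjacent_co",)
        ),
    ]


def _embedded(
    run_blocks: list[StateBlock],
    left_h: bool,
    right_h: bool,
    blocks: Sequence[StateBlock],
    run: list[int],
    mmap: MarkerMap,
    thr: float,
) -> list[RecombinationEvent]:
    outer_l, mid, outer_r = run_blocks
    lmid = _tract_length(mid, mmap)
    left_adj = (outer_l.last_marker, mid.first_marker)
    right_adj = (mid.last_marker, outer_r.first_marker)
    merged = StateBlock(outer_l.state, outer_l.first_marker, outer_r.last_marker)
    if lmid < thr:
        tract = _tract_for(mid, mmap, None)
        if left_h and right_h:
            # fully internal: a nested pair of conversions (outer tract with
            # the minority re-converted inside it)
            outer_tract = _tract_for(merged, mmap, None)
            return [
                RecombinationEvent(
                    NCO_GC,
                    OTHER,
                    _donor(outer_l.state),
                    (_left_breakpoint(blocks, run), _right_breakpoint(blocks, run)),
                    tract=outer_tract,
                    flags=("nested",),
                ),
                RecombinationEvent(
                    NCO_GC,
                    OTHER,
                    _donor(mid.state),
                    (left_adj, right_adj),
                    tract=tract,
                    flags=("nested",),
                ),
            ]
        # surrounding homozygosity reaches an end: one CO with an embedded
        # conversion tract
        bps: list[tuple[int, int]] = []
        if left_h:
            bps.append(_left_breakpoint(blocks, run))
        if right_h:
            bps.append(_right_breakpoint(blocks, run))
        bps.extend([left_adj, right_adj])
        return [
            RecombinationEvent(
                CO_GC, "Type7", _donor(mid.state), tuple(bps), tract=tract
            )
        ]
    # long middle block: two adjacent COs flipping to the middle state and
    # back, plus whatever explains the merged surrounding run
    events = [
        RecombinationEvent(CO, OTHER, _donor(mid.state), (left_adj,), flags=("adjacent_co",)),
        RecombinationEvent(CO, OTHER, _donor(outer_r.state), (right_adj,), flags=("adjacent_co",)),
    ]
    outer_events = _single_block(merged, left_h, right_h, blocks, run, mmap)
    for e in outer_events:
        e.flags = tuple(sorted(set(e.flags) | {"complex",}))
    return events + outer_events


def _greedy(
    run_blocks: list[StateBlock],
    left_h: bool,
    right_h: bool,
    blocks: Sequence[StateBlock],
    run: list[int],
    mmap: MarkerMap,
) -> list[RecombinationEvent]:
    """Fallback minimal decomposition for runs of four or more alternating
    homozygous blocks: terminal blocks become COs, internal blocks become
    conversion tracts; everything is flagged and labelled OTHER."""
    events: list[RecombinationEvent] = []
    for k, b in enumerate(run_blocks):
        terminal = (k == 0 and not left_h) or (k == len(run_blocks) - 1 and not right_h)
        if terminal:
            if k == 0:
                bp = (b.last_marker, run_blocks[1].first_marker)
            else:
                bp = (run_blocks[-2].last_marker, b.first_marker)
            events.append(
                RecombinationEvent(
                    CO, OTHER, _donor(b.state), (bp,), flags=("complex_decomposition",)
                )
            )
        else:
            left_bp = (
                _left_breakpoint(blocks, run)
                if k == 0
                else (run_blocks[k - 1].last_marker, b.first_marker)
            )
            right_bp = (
                _right_breakpoint(blocks, run)
                if k == len(run_blocks) - 1
                else (b.last_marker, run_blocks[k + 1].first_marker)
            )
            events.append(
                RecombinationEvent(
                    NCO_GC,
                    OTHER,
                    _donor(b.state),
                    (left_bp, right_bp),
                    tract=_tract_for(b, mmap, None),
                    flags=("complex_decomposition",),
                )
            )
    return events


def call_events(
    gv: GenotypeVector,
    mmap: MarkerMap,
    long_threshold: float = 100_000,
) -> list[RecombinationEvent]:
    """Segment one individual's vector and classify its events."""
    blocks = segment(gv)
    return classify(
        blocks,
        mmap,
        long_threshold=long_threshold,
        missing=gv.missing_indices(),
        sample_id=gv.sample_id,
    )


def summarize(events: Iterable[RecombinationEvent]) -> EventSummary:
    """Count events by class across individuals and derive the CO:NCO-GC
    ratio and the CO-associated conversion fraction."""
    n_co = n_nco = n_cogc = 0
    for e in events:
        if e.event_class == CO:
            n_co += 1
        elif e.event_class == NCO_GC:
            n_nco += 1
        elif e.event_class == CO_GC:
            n_cogc += 1
        else:
            raise ClassificationError(f"unknown event class {e.event_class!r}")
    ratio = (n_co + n_cogc) / n_nco if n_nco > 0 else None
    frac = n_cogc / (n_cogc + n_nco) if (n_cogc + n_nco) > 0 else None
    return EventSummary(n_co, n_nco, n_cogc, ratio, frac)


def chisq_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """2x2 Pearson chi-square comparing two proportions, no continuity
    correction.  Returns (statistic, p)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    if min(a, b, c, d) < 0:
        raise ValueError("counts cannot exceed sample sizes")
    for margin in (a + b, c + d, a + c, b + d):
        if margin == 0:
            raise ValueError("chi-square undefined: zero margin")
    n = n1 + n2
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(stat), float(stats.chi2.sf(stat, df=1))


def events_to_frame(events: Iterable[RecombinationEvent], mmap: MarkerMap) -> pd.DataFrame:
    """Tabulate events (one row each) for TSV output."""
    rows = []
    for e in events:
        t = e.tract
        rows.append(
            {
                "sample_id": e.sample_id,
                "event_class": e.event_class,
                "pattern_type": e.pattern_type,
                "donor": e.donor,
                "left_bound_marker": e.breakpoints[0][0] if e.breakpoints else None,
                "right_bound_marker": e.breakpoints[-1][1] if e.breakpoints else None,
                "first_converted": t.first_converted if t else None,
                "last_converted": t.last_converted if t else None,
                "tract_length_bp": t.length if t else None,
                "n_markers_converted": t.n_markers_converted if t else None,
                "flags": ";".join(e.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "event_class", "pattern_type", "donor",
            "left_bound_marker", "right_bound_marker", "first_converted",
            "last_converted", "tract_length_bp", "n_markers_converted", "flags",
        ],
    )
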