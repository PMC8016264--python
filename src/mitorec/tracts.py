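"""Conversion-tract boundary and length estimation by the midpoint method.

A conversion tract is only interval-censored by the marker grid: we observe
which markers switched state, not where the tract really starts and ends.
The midpoint method places each boundary halfway between the outermost
converted marker and the nearest flanking non-converted marker.  Tracts that
reach the edge of the surveyed region have no flanking marker on that side;
the boundary is then anchored at the outermost converted marker itself,
which is conservative (it can only shorten the tract) and is flagged as
censored.

Two mean-tract statistics are supported.  With M tracts of total span S
arising from N events (some events deposit conversion in several disjoint
blocks, so M >= N), the mean per tract is S/M and the mean summed span per
event is S/N; the latter is never smaller.  Single-marker tracts, whose
called length is purely a function of local marker density, can optionally
be replaced by a fixed nominal length before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genotypes import MarkerMap


@dataclass
class ConversionTract:
    """A converted span with midpoint-method boundaries.

    ``first_converted``/``last_converted`` are 0-based marker indices;
    bounds are bp coordinates; ``length = right_bound - left_bound``.
    """

    first_converted: int
    last_converted: int
    left_bound: float
    right_bound: float
    length: float
    n_markers_converted: int
    single_marker: bool
    left_censored: bool = False
    right_censored: bool = False
    tract_id: str | None = None
    event_key: str | None = None

    def __post_init__(self) -> None:
        if self.left_bound >= self.right_bound:
            raise ValueError("tract bounds must satisfy left < right")
        if self.length <= 0:
            raise ValueError("tract length must be positive")


@dataclass(frozen=True)
class TractSummary:
    """Aggregate tract statistics: total span S over M tracts from N events."""

    total_span: float          # S, bp
    n_tracts: int              # M
    n_events: int              # N
    mean_per_tract: float      # S/M
    mean_per_event: float      # S/N
    mean: float                # the mean selected by `mode`
    excluded: tuple[str, ...]


def midpoint_tract(
    converted_run: Sequence[int] | tuple[int, int],
    mmap: MarkerMap,
    tract_id: str | None = None,
    event_key: str | None = None,
) -> ConversionTract:
    """Midpoint-method tract for a contiguous run of converted markers.

    ``converted_run`` is either an inclusive ``(first, last)`` index pair or
    a sequence of consecutive marker indices.
    """
    run = sorted(int(i) for i in converted_run)
    if not run:
        raise ValueError("converted run is empty")
    if len(run) == 2 and tuple(converted_run) == (run[0], run[1]):
        first, last = run[0], run[1]
    else:
        first, last = run[0], run[-1]
        if run != list(range(first, last + 1)):
            raise ValueError(f"converted run {run} is not contiguous in marker order")
    if first < 0 or last >= mmap.n_markers:
        raise ValueError("converted run outside marker map bounds")
    pos = mmap.position
    left_censored = first == 0
    right_censored = last == mmap.n_markers - 1
    left = float(pos[first]) if left_censored else (pos[first - 1] + pos[first]) / 2.0
    right = float(pos[last]) if right_censored else (pos[last] + pos[last + 1]) / 2.0
    n_conv = last - first + 1
    return ConversionTract(
        first_converted=first,
        last_converted=last,
        left_bound=left,
        right_bound=right,
        length=right - left,
        n_markers_converted=n_conv,
        single_marker=n_conv == 1,
        left_censored=left_censored,
        right_censored=right_censored,
        tract_id=tract_id,
        event_key=event_key,
    )


def mean_tract_length(
    tracts: Sequence[ConversionTract],
    mode: str = "per_tract",
    event_index: Sequence[object] | None = None,
    exclude: Iterable[object] = (),
    single_marker_length: float | None = None,
) -> TractSummary:
    """Mean tract statistics with optional exclusions and single-marker correction.

    Parameters
    ----------
    mode
        ``"per_tract"`` (S/M) or ``"per_event"`` (S/N).
    event_index
        Group key per tract (e.g. originating plant or event id).  Defaults
        to each tract's ``event_key``, falling back to its own index, so
        without grouping information per-event equals per-tract.
    exclude
        Tract ids (``tract_id``, falling back to positional index) to drop
        before averaging, e.g. a poorly resolved low-marker-density tract.
    single_marker_length
        If set, every single-marker tract contributes this length instead
        of its marker-density-dependent called length.
    """
    if mode not in ("per_tract", "per_event"):
        raise ValueError(f"unknown mode {mode!r}")
    excl = {str(e) for e in exclude}
    kept: list[tuple[ConversionTract, object]] = []
    dropped: list[str] = []
    for i, t in enumerate(tracts):
        tid = t.tract_id if t.tract_id is not None else str(i)
        if str(tid) in excl:
            dropped.append(str(tid))
            continue
        if event_index is not None:
            key = event_index[i]
        else:
            key = t.event_key if t.event_key is not None else f"__tract_{i}"
        kept.append((t, key))
    if not kept:
        raise ValueError("no tracts left after exclusions")
    lengths = [
        single_marker_length if (single_marker_length is not None and t.single_marker) else t.length
        for t, _ in kept
    ]
    total = float(sum(lengths))
    n_tracts = len(kept)
    n_events = len({key for _, key in kept})
    per_tract = total / n_tracts
    per_event = total / n_events
    return TractSummary(
        total_span=total,
        n_tracts=n_tracts,
        n_events=n_events,
        mean_per_tract=per_tract,
        mean_per_event=per_event,
        mean=per_tract if mode == "per_tract" else per_event,
        excluded=tuple(dropped),
    )


def tract_ratio(mitotic_mean: float, meiotic_mean: float) -> float:
    """Ratio of mitotic to meiotic mean tract length (mitotic:meiotic)."""
    if meiotic_mean <= 0:
        raise ValueError("meiotic mean tract length must be positive")
    return mitotic_mean / meiotic_mean
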