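"""Helper: build placeholder event lists with given class counts."""

from mitorec.events import CO, CO_GC, NCO_GC, RecombinationEvent
from mitorec.tracts import ConversionTract


def _event(event_class):
    tract = None
    if event_class in (NCO_GC, CO_GC):
        tract = ConversionTract(
            first_converted=1, last_converted=1, left_bound=0.0,
            right_bound=1.0, length=1.0, n_markers_converted=1,
            single_marker=True,
        )
    return RecombinationEvent(event_class, "Type1", "to_N", ((0, 1),), tract=tract)


def screen_events(n_co, n_nco_gc, n_co_gc):
    return (
        [_event(CO) for _ in range(n_co)]
        + [_event(NCO_GC) for _ in range(n_nco_gc)]
        + [_event(CO_GC) for _ in range(n_co_gc)]
    )
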