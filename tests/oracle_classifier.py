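"""Independent rule oracle for event classification.

A deliberately naive re-implementation of the classification rules working
directly on the raw state tuple (no block machinery, no event objects):
used to cross-check the production classifier by exhaustive enumeration.
Returns only the multiset of event classes.
"""

from itertools import groupby


def _midpoint_len(first, last, positions):
    n = len(positions)
    left = positions[first] if first == 0 else (positions[first - 1] + positions[first]) / 2
    right = positions[last] if last == n - 1 else (positions[last] + positions[last + 1]) / 2
    return right - left


def oracle_classes(states, positions, thr=100_000):
    """Sorted list of event classes called on a fully-genotyped vector."""
    runs = []
    i = 0
    for state, grp in groupby(states):
        k = len(list(grp))
        runs.append((state, i, i + k - 1))
        i += k
    if len(runs) == 1:
        return []

    # group consecutive homozygous runs
    groups, cur = [], []
    for ri, run in enumerate(runs):
        if run[0] == "H":
            if cur:
                groups.append(cur)
            cur = []
        else:
            cur.append((ri, run))
    if cur:
        groups.append(cur)

    out = []
    for grp in groups:
        first_ri, last_ri = grp[0][0], grp[-1][0]
        left_h = first_ri > 0
        right_h = last_ri < len(runs) - 1
        blocks = [run for _, run in grp]
        m = len(blocks)
        tlen = lambda b: _midpoint_len(b[1], b[2], positions)
        if m == 1:
            if left_h and right_h:
                out.append("NCO_GC")
            elif left_h or right_h:
                out.append("CO")
            # a lone homozygous run with no flank is the single-block case
        elif m == 2:
            a, b = blocks
            if left_h and right_h:
                out += ["NCO_GC", "NCO_GC"]
            elif not left_h and not right_h:
                if min(tlen(a), tlen(b)) < thr:
                    out.append("CO_GC")
                else:
                    out += ["CO", "CO"]
            else:
                internal = a if left_h else b
                if tlen(internal) < thr:
                    out.append("CO_GC")
                else:
                    out += ["CO", "CO"]
        elif m == 3:
            mid = blocks[1]
            if tlen(mid) < thr:
                if left_h and right_h:
                    out += ["NCO_GC", "NCO_GC"]
                else:
                    out.append("CO_GC")
            else:
                out += ["CO", "CO"]
                if left_h and right_h:
                    out.append("NCO_GC")
                elif left_h or right_h:
                    out.append("CO")
        else:
            for k in range(m):
                terminal = (k == 0 and not left_h) or (k == m - 1 and not right_h)
                out.append("CO" if terminal else "NCO_GC")
    return sorted(out)
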