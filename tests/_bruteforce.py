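"""Independent brute-force oracles for the motif census.

Deliberately naive implementations (explicit window scans, recursive path
enumeration) used only to validate the vectorized census code on small
random instances.
"""

from __future__ import annotations

import numpy as np


def brute_group_counts(labels, w: int, M: int, n_ens: int) -> dict[str, int]:
    """Window-by-window group census of a single 1-D label array."""
    labels = list(labels)
    out = {"fully_mixed": 0, "stimulus_driven": 0, "noise": 0, "any": 0}
    for s in range(len(labels) - w + 1):
        win = labels[s : s + w]
        ens = [x for x in win if x >= 1]
        if M <= n_ens and all(any(x == m for x in win) for m in range(1, M + 1)):
            out["fully_mixed"] += 1
        if len(ens) >= M:
            out["stimulus_driven"] += 1
        if sum(1 for x in win if x == -1) >= M:
            out["noise"] += 1
        if sum(1 for x in win if x != 0) >= M:
            out["any"] += 1
    return out


def brute_sequence_count(actives, lo: int, hi: int) -> int:
    """Recursive enumeration of spacing-respecting paths across steps.

    ``actives`` is a list of 1-D 0/1 arrays, one per time step; a path
    visits one active synapse per step with positional offsets in [lo, hi).
    """
    actives = [np.flatnonzero(a) for a in actives]

    def extend(step: int, pos: int) -> int:
        if step == len(actives):
            return 1
        total = 0
        for nxt in actives[step]:
            if lo <= nxt - pos < hi:
                total += extend(step + 1, int(nxt))
        return total

    return sum(extend(1, int(p)) for p in actives[0])
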