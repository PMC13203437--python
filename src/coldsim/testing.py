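"""Hand-built synthetic snapshots for exercising the spatial analysis.

These are deliberately artificial constructions (labelled synthetic), small
enough to verify the sanctuary algorithm's component and area behaviour by
inspection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import Snapshot

__all__ = ["sanctuary_toy_snapshot"]


def sanctuary_toy_snapshot(grid: int = 20) -> Snapshot:
    """A synthetic 20x20 snapshot with exactly one qualifying sanctuary.

    Layout: a background population of low-PD-L1 tumour cells under uniform
    engagement pressure, one 4-cell high-PD-L1 block with perfect trailing
    survival (qualifies: area >= 4), and one 3-cell high-PD-L1 run, equally
    protected, that the minimum-area filter must reject.  CTLs sit away from
    both blocks so the low-density criterion passes there.
    """
    L = W = grid
    rows = []
    # background tumour: a 10x10 block of low expressors
    for x in range(2, 12):
        for y in range(2, 12):
            rows.append((x, y, 1.0, 1.0))
    # qualifying 2x2 block, far corner
    four = [(15, 15), (15, 16), (16, 15), (16, 16)]
    for x, y in four:
        rows.append((x, y, 12.0, 12.0))
    # 3-cell horizontal run, separated from everything by > 1 cell
    three = [(15, 2), (15, 3), (15, 4)]
    for x, y in three:
        rows.append((x, y, 12.0, 12.0))
    tumour = pd.DataFrame(rows, columns=["x", "y", "e_basal", "e_total"])

    # CTLs concentrated on the background block -> high local density there
    ipos = [(x, y) for x in range(3, 11) for y in range(3, 11) if (x + y) % 2 == 0]
    immune = pd.DataFrame(ipos, columns=["x", "y"])

    faced = np.zeros((L, W), dtype=np.int64)
    survived = np.zeros((L, W), dtype=np.int64)
    # background: heavily engaged, everything killed eventually -> survival 0
    faced[2:12, 2:12] = 5
    # the high blocks: engaged and always survived
    for x, y in four + three:
        faced[x, y] = 5
        survived[x, y] = 5
    return Snapshot(
        step=100,
        tumour=tumour,
        immune=immune,
        conc=np.zeros((L, W)),
        faced=faced,
        survived=survived,
        window_filled=True,
    )
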