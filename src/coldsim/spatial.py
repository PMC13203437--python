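"""Spatial summary statistics: sanctuaries, immunoediting, seeding.

A *protective sanctuary* is an 8-connected lattice region (area >= 4 cells)
of tumour-occupied cells jointly satisfying, per snapshot:

1. local effective PD-L1 (mean over the toroidal 3x3 Moore window) at or
   above the snapshot 80th percentile over tumour-occupied cells;
2. local CTL density (3x3 window count / 9) below the snapshot mean CTL
   density; and
3. trailing survival fraction (engagements survived / faced in the 3x3
   window over the last 50 steps) at or above the snapshot 80th percentile
   over cells with at least one engagement.

Thresholds are percentile-calibrated per snapshot, which makes detection
invariant to monotone rescaling of the expression field and portable across
runs with different absolute calibrations.

The *immunoediting ratio* is the median effective PD-L1 of the surviving
population divided by the initial cohort median: the fold-enrichment of
resistant phenotypes.  *Seeding classification* identifies established
secondary colonies (distant-seeded lineages with >= 5 descendants placed in
a different grid quadrant than the primary cluster) and reports Wilson 95%
intervals on colony proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .model import ReplicateResult, Snapshot
from .stats import ProportionCI, wilson_interval

__all__ = [
    "SanctuaryReport",
    "SeedingReport",
    "detect_sanctuaries",
    "immunoediting_ratio",
    "classify_seeding",
]

_BOX3 = np.ones((3, 3))
_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class SanctuaryReport:
    """Detected sanctuaries in one snapshot."""

    step: int
    window_filled: bool
    count: int
    areas: tuple[int, ...]
    members: tuple[tuple[tuple[int, int], ...], ...]
    total_area: int
    tumour_fraction: float       # fraction of tumour cells inside sanctuaries
    pdl1_enrichment: float       # mean E_total inside / outside (NaN if undefined)


def _window_mean(arr: np.ndarray) -> np.ndarray:
    return ndimage.convolve(arr, _BOX3, mode="wrap")


def detect_sanctuaries(snapshot: Snapshot, grid_shape: tuple[int, int] | None = None) -> SanctuaryReport:
    """Apply the three-criterion sanctuary algorithm to one snapshot."""
    if grid_shape is None:
        grid_shape = snapshot.conc.shape
    L, W = grid_shape
    empty = SanctuaryReport(
        step=snapshot.step,
        window_filled=snapshot.window_filled,
        count=0,
        areas=(),
        members=(),
        total_area=0,
        tumour_fraction=0.0,
        pdl1_enrichment=float("nan"),
    )
    if not snapshot.window_filled or len(snapshot.tumour) == 0:
        return empty

    tum_occ = np.zeros((L, W), dtype=bool)
    e_total = np.zeros((L, W), dtype=float)
    tx = snapshot.tumour["x"].to_numpy()
    ty = snapshot.tumour["y"].to_numpy()
    tum_occ[tx, ty] = True
    e_total[tx, ty] = snapshot.tumour["e_total"].to_numpy()
    imm = np.zeros((L, W), dtype=float)
    if len(snapshot.immune):
        imm[snapshot.immune["x"].to_numpy(), snapshot.immune["y"].to_numpy()] = 1.0

    # (a) local mean effective PD-L1 over tumour cells in the 3x3 window
    nbr_count = _window_mean(tum_occ.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        local_pdl1 = np.where(nbr_count > 0, _window_mean(e_total) / nbr_count, 0.0)
    pdl1_thresh = np.percentile(local_pdl1[tum_occ], 80)

    # (b) local CTL density vs the snapshot mean density
    local_ctl = _window_mean(imm) / 9.0
    mean_density = imm.sum() / (L * W)

    # (c) trailing survival fraction over the same window
    faced = _window_mean(snapshot.faced.astype(float))
    survived = _window_mean(snapshot.survived.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        survival = np.where(faced > 0, survived / np.maximum(faced, 1e-300), 0.0)
    engaged = faced > 0
    if not np.any(engaged):
        return empty
    surv_thresh = np.percentile(survival[engaged], 80)

    passing = (
        tum_occ
        & (local_pdl1 >= pdl1_thresh)
        & (local_ctl < mean_density)
        & engaged
        & (survival >= surv_thresh)
    )
    labels, n_comp = ndimage.label(passing, structure=_EIGHT_CONN)
    # NOTE: scipy's label is not periodic; merge components touching across
    # the wrap so 8-connectivity is toroidal, matching the lattice topology.
    labels = _merge_wrapped(labels)

    members: list[tuple[tuple[int, int], ...]] = []
    areas: list[int] = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        pos = np.argwhere(labels == lab)
        if len(pos) >= 4:
            members.append(tuple((int(a), int(b)) for a, b in pos))
            areas.append(len(pos))
    if not members:
        return empty

    inside = np.zeros((L, W), dtype=bool)
    for comp in members:
        for a, b in comp:
            inside[a, b] = True
    outside = tum_occ & ~inside
    enrichment = (
        float(e_total[inside].mean() / e_total[outside].mean())
        if outside.any() and e_total[outside].mean() > 0
        else float("nan")
    )
    return SanctuaryReport(
        step=snapshot.step,
        window_filled=True,
        count=len(members),
        areas=tuple(areas),
        members=tuple(members),
        total_area=int(sum(areas)),
        tumour_fraction=float(inside.sum() / tum_occ.sum()),
        pdl1_enrichment=enrichment,
    )


def _merge_wrapped(labels: np.ndarray) -> np.ndarray:
    """Union labels of components that touch across the periodic boundary."""
    L, W = labels.shape
    parent = {int(l): int(l) for l in np.unique(labels) if l != 0}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for j in range(W):
        for dj in (-1, 0, 1):
            a, b = labels[L - 1, j], labels[0, (j + dj) % W]
            if a and b:
                union(int(a), int(b))
    for i in range(L):
        for di in (-1, 0, 1):
            a, b = labels[i, W - 1], labels[(i + di) % L, 0]
            if a and b:
                union(int(a), int(b))
    out = labels.copy()
    for l in parent:
        out[labels == l] = find(l)
    return out


def immunoediting_ratio(survivor_e_totals, initial_median: float) -> float:
    """Median survivor effective PD-L1 divided by the initial cohort median."""
    s = np.asarray(survivor_e_totals, dtype=float)
    if s.size == 0:
        raise ValueError("immunoediting ratio undefined for an extinct population")
    if not initial_median > 0:
        raise ValueError("initial median must be positive")
    return float(np.median(s) / initial_median)


@dataclass(frozen=True)
class SeedingReport:
    """Cross-replicate classification of distant-seeding colonies."""

    n_replicates: int
    n_colonised_replicates: int
    n_colonies: int
    n_high_pdl1_colonies: int
    colonised_ci: ProportionCI
    high_pdl1_ci: ProportionCI | None


def classify_seeding(
    results: list[ReplicateResult],
    high_threshold: float = 9.0,
    min_colony: int = 5,
) -> SeedingReport:
    """Identify established secondary colonies across replicates.

    A colony is the lineage of a distant-seeded founder placed in a grid
    quadrant different from the primary-cluster centroid quadrant at seeding
    time, with at least ``min_colony`` descendants alive at simulation end.
    The founder is high-PD-L1 if its effective expression exceeded
    ``high_threshold`` when shed.
    """
    n_colonised = 0
    n_colonies = 0
    n_high = 0
    for r in results:
        found = 0
        for ev in r.seeding_events:
            if ev.seed_quadrant == ev.primary_quadrant:
                continue
            if r.lineage_final_counts.get(ev.lineage_id, 0) < min_colony:
                continue
            found += 1
            n_colonies += 1
            if ev.founder_e_total > high_threshold:
                n_high += 1
        n_colonised += found > 0
    return SeedingReport(
        n_replicates=len(results),
        n_colonised_replicates=n_colonised,
        n_colonies=n_colonies,
        n_high_pdl1_colonies=n_high,
        colonised_ci=wilson_interval(n_colonised, len(results)),
        high_pdl1_ci=wilson_interval(n_high, n_colonies) if n_colonies else None,
    )
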