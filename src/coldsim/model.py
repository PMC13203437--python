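"""Discrete agent layer and the hybrid step scheduler.

The model runs on an L x W toroidal lattice.  Each lattice cell holds at
most one tumour cell and at most one CTL simultaneously; co-occupation of
one position by a tumour cell and a CTL is the geometric prerequisite for
an engagement, resolved the same step.

Per step, in deterministic phase order:

1. advance the IFN-gamma PDE one FTCS step using the secretion deposited by
   last step's engagements (adaptive arms only);
2. recompute every tumour cell's effective expression from the local field
   (adaptive arms; static arms keep E_total = E_basal);
3. tumour phase in shuffled order: each cell attempts division with
   probability ``p_prolif``; daughters go to a uniformly chosen empty Moore
   neighbour, or -- when fully contact-inhibited -- to a uniformly chosen
   empty position anywhere on the grid with probability ``p_seed`` (distant
   seeding, the metastasis proxy);
4. immune phase in shuffled order: each CTL moves (uniform over the 8 Moore
   neighbours plus stay; chemotactically biased toward the steepest local
   IFN-gamma with probability ``p_bias`` when a tumour cell is within the
   Chebyshev detection radius and a field exists) and resolves at most one
   engagement: the co-occupying tumour cell is killed with probability
   1 - p_evasion(E_total); every engagement deposits one secretion quantum;
   on an evaded engagement the CTL itself dies with probability
   ``p_exhaust`` (PD-1 ligation driving exhaustion/apoptosis);
5. summary statistics are recorded every ``record_every`` steps.

A replicate terminates at extinction (tumour count 0), carrying capacity
(tumour count = L*W), or the step horizon, whichever comes first.  Seeds
derive deterministically from (base_seed, arm_id, replicate_index) via a
cryptographic hash, so a replicate re-run with the same identity is
bit-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter

from .dose_response import HillParams, LogisticParams, hill_induction, kill_probability
from .field import FieldParams, FieldInstabilityError, check_stability, ftcs_step

__all__ = [
    "SimulationConfig",
    "TerminationClass",
    "SeedingEvent",
    "Snapshot",
    "ReplicateResult",
    "Simulation",
    "derive_seed",
    "run_replicate",
    "steps_to_hours",
]

SURVIVAL_WINDOW = 50  # steps of trailing engagement history per lattice cell

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """All tunable parameters of one simulation arm."""

    grid_l: int = 50
    grid_w: int = 50
    n_tumour0: int = 500
    n_immune0: int = 250
    p_prolif: float = 0.02
    p_seed: float = 0.001
    p_bias: float = 0.5
    p_exhaust: float = 0.3
    detect_radius: int = 3
    max_steps: int = 500
    record_every: int = 10
    minutes_per_step: float = 5.5

    # arm switches
    evasion_mode: str = "heterogeneous"  # heterogeneous | null | uniform_high
    uniform_high_tpm: float = 28.4
    adaptive_enabled: bool = False
    induction_ko: bool = False
    diffusion_ko: bool = False
    immune_disabled: bool = False

    logistic: LogisticParams = dc_field(default_factory=LogisticParams)
    hill: HillParams = dc_field(default_factory=HillParams)
    field: FieldParams = dc_field(default_factory=FieldParams)

    # seed scheme
    base_seed: int = 0
    arm_id: str = "adhoc"
    replicate_index: int = 0

    def __post_init__(self) -> None:
        cap = self.grid_l * self.grid_w
        if self.grid_l < 2 or self.grid_w < 2:
            raise ConfigError("grid must be at least 2x2")
        if not (0 <= self.n_tumour0 <= cap and 0 <= self.n_immune0 <= cap):
            raise ConfigError("initial agent counts must fit on the grid")
        for name in ("p_prolif", "p_seed", "p_bias", "p_exhaust"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v}")
        if self.evasion_mode not in ("heterogeneous", "null", "uniform_high"):
            raise ConfigError(f"unknown evasion_mode {self.evasion_mode!r}")
        if self.adaptive_enabled:
            eff = self.effective_field_params()
            rep = check_stability(eff)
            if not rep.stable:
                raise ConfigError(
                    "unstable PDE parameters: combined stability factor "
                    f"{rep.combined:.3f} (requires <= 1), CFL {rep.cfl_ratio:.3f} "
                    "(requires <= 0.25)"
                )

    def effective_field_params(self) -> FieldParams:
        """Field parameters after applying the diffusion-knockout switch."""
        if self.diffusion_ko:
            return replace(self.field, diff_coeff=0.0)
        return self.field

    def effective_hill_params(self) -> HillParams:
        """Hill parameters after applying the induction-knockout switch."""
        if self.induction_ko:
            return replace(self.hill, p_max=0.0)
        return self.hill


@dataclass(frozen=True)
class TerminationClass:
    """Why and when a replicate stopped."""

    kind: str  # max_steps_reached | extinction | carrying_capacity
    step: int


@dataclass(frozen=True)
class SeedingEvent:
    """One distant-seeding (metastasis proxy) event."""

    step: int
    x: int
    y: int
    lineage_id: int
    founder_e_total: float       # effective expression of the shedding clone
    founder_e_basal: float
    seed_quadrant: int
    primary_quadrant: int


@dataclass
class Snapshot:
    """State export for spatial analysis at one recorded step."""

    step: int
    tumour: pd.DataFrame          # columns x, y, e_basal, e_total
    immune: pd.DataFrame          # columns x, y
    conc: np.ndarray              # IFN-gamma field (L, W)
    faced: np.ndarray             # engagements faced per cell over the window
    survived: np.ndarray          # engagements survived per cell over the window
    window_filled: bool


@dataclass
class ReplicateResult:
    """Per-replicate output of :func:`run_replicate`."""

    arm_id: str
    replicate_index: int
    seed: int
    termination: TerminationClass
    records: pd.DataFrame
    survivor_e_basal: np.ndarray
    survivor_e_total: np.ndarray
    n_immune_final: int
    initial_median: float
    seeding_events: list[SeedingEvent]
    lineage_final_counts: dict[int, int]   # seeded lineages only
    snapshots: list[Snapshot]

    @property
    def final_tumour_count(self) -> int:
        return int(self.survivor_e_basal.size)


def derive_seed(base_seed: int, arm_id: str, replicate_index: int) -> int:
    """Stable 31-bit seed from the replicate identity.

    SHA-256 of ``"{base_seed}:{arm_id}:{replicate_index}"`` reduced mod 2^31;
    the contract (not the resulting random stream) is what independent
    implementations can agree on.
    """
    digest = hashlib.sha256(f"{base_seed}:{arm_id}:{replicate_index}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


def steps_to_hours(steps: int, config: SimulationConfig) -> float:
    """Convert simulation steps to hours of biological time."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    return steps * config.minutes_per_step / 60.0


def _central_cluster_positions(grid_l: int, grid_w: int) -> np.ndarray:
    """Row-major positions of the central compact region holding exactly
    ceil(L*W*0.25) lattice cells (the initial tumour cluster footprint)."""
    target = int(np.ceil(grid_l * grid_w * 0.25))
    side = int(np.ceil(np.sqrt(target)))
    side_l = min(side, grid_l)
    side_w = min(int(np.ceil(target / side_l)), grid_w)
    while side_l * side_w < target and side_l < grid_l:
        side_l += 1
    r0 = (grid_l - side_l) // 2
    c0 = (grid_w - side_w) // 2
    rows, cols = np.meshgrid(
        np.arange(r0, r0 + side_l), np.arange(c0, c0 + side_w), indexing="ij"
    )
    flat = np.stack([rows.ravel(), cols.ravel()], axis=1)
    return flat[:target]


class Simulation:
    """Mutable model state plus the step scheduler.

    Internally the agent populations live on dense per-position arrays
    (occupancy masks, expression fields, lineage tags), which keeps the
    per-step cost dominated by a few vectorised lattice operations plus a
    short Python loop over CTLs and dividing tumour cells.
    """

    def __init__(
        self,
        config: SimulationConfig,
        cohort,
        rng: np.random.Generator | None = None,
        snapshot_steps: Iterable[int] = (),
        track_engagement_window: bool | None = None,
    ) -> None:
        self.config = config
        self.cohort = cohort
        self.seed = derive_seed(config.base_seed, config.arm_id, config.replicate_index)
        self.rng = rng if rng is not None else np.random.default_rng(self.seed)
        self.snapshot_steps = set(int(s) for s in snapshot_steps)
        self.track_window = (
            bool(self.snapshot_steps)
            if track_engagement_window is None
            else track_engagement_window
        )

        L, W = config.grid_l, config.grid_w
        self.L, self.W = L, W
        self.tum_occ = np.zeros((L, W), dtype=bool)
        self.imm_occ = np.zeros((L, W), dtype=bool)
        self.e_basal = np.zeros((L, W), dtype=float)
        self.e_total = np.zeros((L, W), dtype=float)
        self.lineage = np.full((L, W), -1, dtype=np.int64)
        self.seeded = np.zeros((L, W), dtype=bool)
        self.conc = np.zeros((L, W), dtype=float)
        self.source_buffer = np.zeros((L, W), dtype=float)
        if self.track_window:
            self._ring_faced = np.zeros((SURVIVAL_WINDOW, L, W), dtype=np.uint16)
            self._ring_survived = np.zeros((SURVIVAL_WINDOW, L, W), dtype=np.uint16)
        self.step_index = 0
        self.termination: TerminationClass | None = None
        self.records: list[dict] = []
        self.seeding_events: list[SeedingEvent] = []
        self.snapshots: list[Snapshot] = []
        self._next_lineage = 0
        self._engagements_this_step = 0
        self._kills_this_step = 0

        self._initialise()

    # ------------------------------------------------------------------ setup

    def _initialise(self) -> None:
        cfg = self.config
        cluster = _central_cluster_positions(self.L, self.W)
        if cfg.n_tumour0 > len(cluster):
            raise ConfigError(
                f"{cfg.n_tumour0} tumour cells do not fit the central cluster "
                f"region of {len(cluster)} cells"
            )
        pick = self.rng.choice(len(cluster), size=cfg.n_tumour0, replace=False)
        tpos = cluster[pick]
        self.tum_occ[tpos[:, 0], tpos[:, 1]] = True
        if cfg.evasion_mode == "uniform_high":
            basal = np.full(cfg.n_tumour0, cfg.uniform_high_tpm)
        else:
            basal = self.cohort.sample(self.rng, cfg.n_tumour0)
        self.e_basal[tpos[:, 0], tpos[:, 1]] = basal
        self.e_total[tpos[:, 0], tpos[:, 1]] = basal
        self.lineage[tpos[:, 0], tpos[:, 1]] = np.arange(cfg.n_tumour0)
        self._next_lineage = cfg.n_tumour0

        free = np.argwhere(~self.tum_occ)
        if cfg.n_immune0 > len(free):
            raise ConfigError("not enough free positions for the immune population")
        ipick = self.rng.choice(len(free), size=cfg.n_immune0, replace=False)
        ipos = free[ipick]
        self.imm_occ[ipos[:, 0], ipos[:, 1]] = True

        self.initial_median = float(self.cohort.median)
        self._record()

    # ------------------------------------------------------------- main loop

    @property
    def tumour_count(self) -> int:
        return int(self.tum_occ.sum())

    @property
    def immune_count(self) -> int:
        return int(self.imm_occ.sum())

    def run(self) -> None:
        """Advance until a termination condition is met."""
        while self.termination is None:
            self.step()

    def step(self) -> None:
        if self.termination is not None:
            raise RuntimeError("simulation already terminated")
        cfg = self.config
        self.step_index += 1
        self._engagements_this_step = 0
        self._kills_this_step = 0
        if self.track_window:
            slot = self.step_index % SURVIVAL_WINDOW
            self._ring_faced[slot] = 0
            self._ring_survived[slot] = 0

        # (1) PDE advance with last step's accumulated sources
        if cfg.adaptive_enabled:
            self.conc = ftcs_step(self.conc, self.source_buffer, cfg.effective_field_params())
            self.source_buffer[:] = 0.0
            # (2) memoryless induction from the current field
            induced = hill_induction(self.conc, cfg.effective_hill_params())
            np.copyto(self.e_total, self.e_basal)
            self.e_total[self.tum_occ] += induced[self.tum_occ]

        # (3) tumour phase, shuffled
        self._tumour_phase()

        # (4) immune phase, shuffled
        if cfg.n_immune0 > 0 and not cfg.immune_disabled:
            self._immune_phase()

        # (5) record + termination
        count = self.tumour_count
        if count == 0:
            self.termination = TerminationClass("extinction", self.step_index)
        elif count == self.L * self.W:
            self.termination = TerminationClass("carrying_capacity", self.step_index)
        elif self.step_index >= cfg.max_steps:
            self.termination = TerminationClass("max_steps_reached", self.step_index)
        if (
            self.step_index % cfg.record_every == 0
            or self.termination is not None
        ):
            self._record()
        if self.step_index in self.snapshot_steps:
            self.snapshots.append(self.take_snapshot())

    # ------------------------------------------------------------ sub-phases

    def _tumour_phase(self) -> None:
        cfg, rng = self.config, self.rng
        occupied = np.flatnonzero(self.tum_occ.ravel())
        if occupied.size == 0:
            return
        order = rng.permutation(occupied.size)
        attempts = rng.random(occupied.size) < cfg.p_prolif
        idx = occupied[order][attempts[order]]
        if idx.size == 0:
            return
        L, W = self.L, self.W
        tum = self.tum_occ
        for flat in idx:
            x, y = divmod(int(flat), W)
            empties = [
                (nx, ny)
                for dx, dy in _MOORE
                if not tum[(nx := (x + dx) % L), (ny := (y + dy) % W)]
            ]
            if empties:
                nx, ny = empties[rng.integers(len(empties))]
                self._place_daughter(x, y, nx, ny, seeded=False)
            elif cfg.p_seed > 0 and rng.random() < cfg.p_seed:
                free = np.argwhere(~tum)
                if free.size:
                    nx, ny = free[rng.integers(len(free))]
                    self._place_daughter(x, y, int(nx), int(ny), seeded=True)

    def _place_daughter(self, px: int, py: int, nx: int, ny: int, seeded: bool) -> None:
        self.tum_occ[nx, ny] = True
        eb = self.e_basal[px, py]
        self.e_basal[nx, ny] = eb
        # daughters inherit basal expression only; induced expression is
        # recomputed from their own local field next step
        self.e_total[nx, ny] = eb
        if seeded:
            lid = self._next_lineage
            self._next_lineage += 1
            self.lineage[nx, ny] = lid
            self.seeded[nx, ny] = True
            primary = np.argwhere(self.tum_occ & ~self.seeded)
            cx, cy = primary.mean(axis=0)
            self.seeding_events.append(
                SeedingEvent(
                    step=self.step_index,
                    x=nx,
                    y=ny,
                    lineage_id=lid,
                    founder_e_total=float(self.e_total[px, py]),
                    founder_e_basal=float(eb),
                    seed_quadrant=self._quadrant(nx, ny),
                    primary_quadrant=self._quadrant(cx, cy),
                )
            )
        else:
            self.lineage[nx, ny] = self.lineage[px, py]
            self.seeded[nx, ny] = self.seeded[px, py]

    def _quadrant(self, x: float, y: float) -> int:
        return (2 if x >= self.L / 2 else 0) + (1 if y >= self.W / 2 else 0)

    def _immune_phase(self) -> None:
        cfg, rng = self.config, self.rng
        L, W = self.L, self.W
        ctls = np.argwhere(self.imm_occ)
        if ctls.size == 0:
            return
        rng.shuffle(ctls, axis=0)
        size = 2 * cfg.detect_radius + 1
        detect = maximum_filter(self.tum_occ.astype(np.uint8), size=size, mode="wrap") > 0
        use_field = cfg.adaptive_enabled
        kill_lut_mode = cfg.evasion_mode
        tum = self.tum_occ
        imm = self.imm_occ
        conc = self.conc
        for x, y in ctls:
            x, y = int(x), int(y)
            if not imm[x, y]:
                continue  # died earlier this phase (cannot happen; safety)
            tx, ty = x, y
            if use_field and detect[x, y] and rng.random() < cfg.p_bias:
                # chemotactic step: Moore neighbour with maximal local field
                best, cands = -1.0, []
                for dx, dy in _MOORE:
                    nx, ny = (x + dx) % L, (y + dy) % W
                    c = conc[nx, ny]
                    if c > best:
                        best, cands = c, [(nx, ny)]
                    elif c == best:
                        cands.append((nx, ny))
                tx, ty = cands[rng.integers(len(cands))] if len(cands) > 1 else cands[0]
            else:
                k = rng.integers(9)
                if k < 8:
                    dx, dy = _MOORE[k]
                    tx, ty = (x + dx) % L, (y + dy) % W
            if (tx, ty) != (x, y):
                if imm[tx, ty]:
                    tx, ty = x, y  # blocked by another CTL: stay
                else:
                    imm[x, y] = False
                    imm[tx, ty] = True
            # engagement upon co-occupation, at most one per CTL per step
            if tum[tx, ty]:
                self._resolve_engagement(tx, ty)

    def _resolve_engagement(self, x: int, y: int) -> None:
        cfg, rng = self.config, self.rng
        self._engagements_this_step += 1
        # secretion occurs on every engagement, applied in the next PDE phase
        if cfg.adaptive_enabled:
            self.source_buffer[x, y] += cfg.field.secretion
        if cfg.evasion_mode == "null":
            p_kill = 1.0
        else:
            p_kill = kill_probability(self.e_total[x, y], cfg.logistic)
        if self.track_window:
            self._ring_faced[self.step_index % SURVIVAL_WINDOW, x, y] += 1
        if rng.random() < p_kill:
            self._kills_this_step += 1
            self.tum_occ[x, y] = False
            self.e_basal[x, y] = 0.0
            self.e_total[x, y] = 0.0
            self.lineage[x, y] = -1
            self.seeded[x, y] = False
        else:
            if self.track_window:
                self._ring_survived[self.step_index % SURVIVAL_WINDOW, x, y] += 1
            if cfg.p_exhaust > 0 and rng.random() < cfg.p_exhaust:
                self.imm_occ[x, y] = False

    # ------------------------------------------------------------- recording

    def _record(self) -> None:
        occ = self.tum_occ
        n = int(occ.sum())
        rec = {
            "step": self.step_index,
            "tumour_count": n,
            "immune_count": self.immune_count,
            "mean_e_basal": float(self.e_basal[occ].mean()) if n else np.nan,
            "mean_e_total": float(self.e_total[occ].mean()) if n else np.nan,
            "median_e_total": float(np.median(self.e_total[occ])) if n else np.nan,
            "field_max": float(self.conc.max()),
            "engagements": self._engagements_this_step,
            "kills": self._kills_this_step,
        }
        self.records.append(rec)

    def take_snapshot(self) -> Snapshot:
        if not self.track_window:
            raise RuntimeError("engagement-window tracking disabled for this run")
        tpos = np.argwhere(self.tum_occ)
        ipos = np.argwhere(self.imm_occ)
        return Snapshot(
            step=self.step_index,
            tumour=pd.DataFrame(
                {
                    "x": tpos[:, 0],
                    "y": tpos[:, 1],
                    "e_basal": self.e_basal[tpos[:, 0], tpos[:, 1]],
                    "e_total": self.e_total[tpos[:, 0], tpos[:, 1]],
                }
            ),
            immune=pd.DataFrame({"x": ipos[:, 0], "y": ipos[:, 1]}),
            conc=self.conc.copy(),
            faced=self._ring_faced.sum(axis=0, dtype=np.int64),
            survived=self._ring_survived.sum(axis=0, dtype=np.int64),
            window_filled=self.step_index >= SURVIVAL_WINDOW,
        )

    def check_occupancy_invariants(self) -> None:
        """Debug assertion: per-type occupancy is consistent with the agent fields."""
        assert self.e_basal[~self.tum_occ].max(initial=0.0) == 0.0
        assert (self.lineage >= 0).sum() == self.tum_occ.sum()
        assert np.all(self.lineage[self.tum_occ] >= 0)

    # ---------------------------------------------------------------- result

    def result(self) -> ReplicateResult:
        if self.termination is None:
            raise RuntimeError("simulation has not terminated")
        occ = self.tum_occ
        seeded_ids = [ev.lineage_id for ev in self.seeding_events]
        lineage_counts = {
            lid: int(np.sum(self.lineage[occ] == lid)) for lid in seeded_ids
        }
        return ReplicateResult(
            arm_id=self.config.arm_id,
            replicate_index=self.config.replicate_index,
            seed=self.seed,
            termination=self.termination,
            records=pd.DataFrame(self.records),
            survivor_e_basal=self.e_basal[occ].copy(),
            survivor_e_total=self.e_total[occ].copy(),
            n_immune_final=self.immune_count,
            initial_median=self.initial_median,
            seeding_events=list(self.seeding_events),
            lineage_final_counts=lineage_counts,
            snapshots=list(self.snapshots),
        )


def run_replicate(
    config: SimulationConfig,
    cohort,
    arm_id: str | None = None,
    replicate_index: int | None = None,
    snapshot_steps: Iterable[int] = (),
) -> ReplicateResult:
    """Run one replicate to termination and return its result.

    ``arm_id`` / ``replicate_index`` override the identity fields of
    ``config`` for the deterministic seed scheme.
    """
    if arm_id is not None or replicate_index is not None:
        config = replace(
            config,
            arm_id=arm_id if arm_id is not None else config.arm_id,
            replicate_index=(
                replicate_index if replicate_index is not None else config.replicate_index
            ),
        )
    sim = Simulation(config, cohort, snapshot_steps=snapshot_steps)
    sim.run()
    return sim.result()
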