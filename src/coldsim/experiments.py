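"""Experiment arms and sensitivity sweeps.

Arm semantics
-------------
Phase II (static engine, no cytokine field, 500-step horizon):

* ``no_immunity``     -- no CTLs; unimpeded-growth baseline.
* ``null_evasion``    -- evasion forced to 0; CTL-efficiency control.
* ``uniform_high``    -- every cell at 28.4 TPM basal; evasion ceiling control.
* ``tcga_static``     -- basal heterogeneity sampled from the cohort.

Phase III (hybrid, field on):

* ``adaptive``        -- full IFN-gamma/PD-L1 feedback with chemotaxis.
* ``induction_ko``    -- P_max = 0: field and chemotaxis active, induction off.
* ``diffusion_ko``    -- D = 0: induction retained at engagement sites only.
* ``immune_disabled`` -- CTLs present but inert; maximum-growth control.

All primary comparisons default to 50 stochastic replicates per arm with the
deterministic (base_seed, arm_id, replicate_index) seed scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_response import LogisticParams
from .model import ReplicateResult, SimulationConfig, run_replicate
from .spatial import immunoediting_ratio

__all__ = [
    "ARM_NAMES",
    "ArmSpec",
    "ArmSummary",
    "SweepResult",
    "arm_config",
    "run_arm",
    "grid_scale_sweep",
    "logistic_sensitivity_heatmap",
    "effector_ratio_sweep",
]

ARM_NAMES = (
    "no_immunity",
    "null_evasion",
    "uniform_high",
    "tcga_static",
    "adaptive",
    "induction_ko",
    "diffusion_ko",
    "immune_disabled",
)

_PHASE_III = {"adaptive", "induction_ko", "diffusion_ko", "immune_disabled"}


def arm_config(name: str, base: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """Build the configuration for a named arm from a base configuration."""
    if name not in ARM_NAMES:
        raise ValueError(f"unknown arm {name!r}; expected one of {ARM_NAMES}")
    cfg = base if base is not None else SimulationConfig()
    changes: dict = {"arm_id": name}
    if name == "no_immunity":
        changes.update(n_immune0=0, adaptive_enabled=False)
    elif name == "null_evasion":
        changes.update(evasion_mode="null", adaptive_enabled=False)
    elif name == "uniform_high":
        changes.update(evasion_mode="uniform_high", adaptive_enabled=False)
    elif name == "tcga_static":
        changes.update(evasion_mode="heterogeneous", adaptive_enabled=False)
    elif name == "adaptive":
        changes.update(adaptive_enabled=True)
    elif name == "induction_ko":
        changes.update(adaptive_enabled=True, induction_ko=True)
    elif name == "diffusion_ko":
        changes.update(adaptive_enabled=True, diffusion_ko=True)
    elif name == "immune_disabled":
        changes.update(adaptive_enabled=True, immune_disabled=True)
    changes.update(overrides)
    return replace(cfg, **changes)


@dataclass(frozen=True)
class ArmSpec:
    """One experiment arm: name, config overrides, replicate budget."""

    name: str
    n_replicates: int = 50
    max_steps: int | None = None  # default: 500 everywhere (metrics are at t=500)
    overrides: Mapping = dc_field(default_factory=dict)

    def build_config(self, base: SimulationConfig | None = None) -> SimulationConfig:
        ov = dict(self.overrides)
        if self.max_steps is not None:
            ov["max_steps"] = self.max_steps
        return arm_config(self.name, base, **ov)


@dataclass
class ArmSummary:
    """Cross-replicate aggregate of one arm."""

    name: str
    n_replicates: int
    final_counts: np.ndarray
    mean_final: float
    sd_final: float
    termination_tally: dict[str, int]
    editing_ratios: np.ndarray        # per replicate; NaN where extinct
    mean_editing_ratio: float         # over replicates with survivors
    survivor_median_e_total: float    # pooled-replicate mean of per-replicate medians
    n_seeding_replicates: int
    replicates: list[ReplicateResult]


def run_arm(
    spec: ArmSpec,
    cohort,
    base: SimulationConfig | None = None,
    base_seed: int = 0,
    keep_replicates: bool = True,
) -> ArmSummary:
    """Run ``spec.n_replicates`` independent replicates and aggregate them."""
    cfg = spec.build_config(base)
    cfg = replace(cfg, base_seed=base_seed)
    results: list[ReplicateResult] = []
    for i in range(spec.n_replicates):
        results.append(run_replicate(replace(cfg, replicate_index=i), cohort))
    finals = np.array([r.final_tumour_count for r in results], dtype=float)
    tally: dict[str, int] = {}
    for r in results:
        tally[r.termination.kind] = tally.get(r.termination.kind, 0) + 1
    ratios = np.array(
        [
            immunoediting_ratio(r.survivor_e_total, r.initial_median)
            if r.final_tumour_count > 0
            else np.nan
            for r in results
        ]
    )
    medians = np.array(
        [
            float(np.median(r.survivor_e_total)) if r.final_tumour_count > 0 else np.nan
            for r in results
        ]
    )
    with np.errstate(invalid="ignore"):
        mean_ratio = float(np.nanmean(ratios)) if np.any(np.isfinite(ratios)) else float("nan")
        mean_median = float(np.nanmean(medians)) if np.any(np.isfinite(medians)) else float("nan")
    summary = ArmSummary(
        name=spec.name,
        n_replicates=spec.n_replicates,
        final_counts=finals,
        mean_final=float(finals.mean()),
        sd_final=float(finals.std(ddof=1)) if len(finals) > 1 else 0.0,
        termination_tally=tally,
        editing_ratios=ratios,
        mean_editing_ratio=mean_ratio,
        survivor_median_e_total=mean_median,
        n_seeding_replicates=sum(1 for r in results if r.seeding_events),
        replicates=results if keep_replicates else [],
    )
    return summary


@dataclass
class SweepResult:
    """Factorial sweep outcome table."""

    axes: dict[str, Sequence]
    table: pd.DataFrame
    n_replicates: int


def grid_scale_sweep(
    cohort,
    sizes: Sequence[tuple[int, int]] = ((30, 30), (50, 50), (100, 100)),
    density: float = 0.040,
    n_replicates: int = 20,
    base: SimulationConfig | None = None,
    base_seed: int = 0,
    max_steps: int = 1500,
    arm: str = "adaptive",
) -> SweepResult:
    """Grid-scale robustness protocol: constant initial density, constant
    baseline 2:1 tumour:immune ratio, run to carrying-capacity equilibrium.

    Reports final burden, capacity fraction, immunoediting ratio and the
    termination step per grid size.
    """
    rows = []
    for L, W in sizes:
        n_t = int(round(L * W * density))
        n_i = int(round(n_t * 0.5))
        cfg = arm_config(
            arm,
            base,
            grid_l=L,
            grid_w=W,
            n_tumour0=n_t,
            n_immune0=n_i,
            max_steps=max_steps,
            base_seed=base_seed,
            arm_id=f"gridsweep_{arm}_{L}x{W}",
        )
        for i in range(n_replicates):
            r = run_replicate(replace(cfg, replicate_index=i), cohort)
            rows.append(
                {
                    "grid_l": L,
                    "grid_w": W,
                    "replicate": i,
                    "final_burden": r.final_tumour_count,
                    "capacity_fraction": 100.0 * r.final_tumour_count / (L * W),
                    "editing_ratio": immunoediting_ratio(
                        r.survivor_e_total, r.initial_median
                    )
                    if r.final_tumour_count
                    else np.nan,
                    "termination_step": r.termination.step,
                    "termination": r.termination.kind,
                }
            )
    return SweepResult(
        axes={"sizes": list(sizes)}, table=pd.DataFrame(rows), n_replicates=n_replicates
    )


def logistic_sensitivity_heatmap(
    cohort,
    x0_values: Sequence[float],
    k_values: Sequence[float],
    steps: int = 300,
    n_replicates: int = 5,
    base: SimulationConfig | None = None,
    base_seed: int = 0,
    arm: str = "tcga_static",
) -> SweepResult:
    """Mean final tumour count after ``steps`` steps over an (x0, k) grid."""
    rows = []
    for x0 in x0_values:
        for k in k_values:
            cfg = arm_config(
                arm,
                base,
                logistic=LogisticParams(x0=float(x0), k=float(k)),
                max_steps=steps,
                base_seed=base_seed,
                arm_id=f"heatmap_{arm}_x0={x0}_k={k}",
            )
            finals = [
                run_replicate(replace(cfg, replicate_index=i), cohort).final_tumour_count
                for i in range(n_replicates)
            ]
            rows.append(
                {
                    "x0": float(x0),
                    "k": float(k),
                    "mean_final_count": float(np.mean(finals)),
                    "sd_final_count": float(np.std(finals, ddof=1)) if len(finals) > 1 else 0.0,
                }
            )
    return SweepResult(
        axes={"x0": list(x0_values), "k": list(k_values)},
        table=pd.DataFrame(rows),
        n_replicates=n_replicates,
    )


def effector_ratio_sweep(
    cohort,
    immune_counts: Sequence[int],
    arms: Iterable[str] = ("tcga_static", "adaptive"),
    n_replicates: int = 10,
    base: SimulationConfig | None = None,
    base_seed: int = 0,
    max_steps: int = 500,
) -> SweepResult:
    """Clearance fraction (replicates ending in extinction) per arm and CTL count."""
    rows = []
    for arm in arms:
        for n_i in immune_counts:
            if n_i == 0:
                rows.append(
                    {"arm": arm, "n_immune": 0, "clearance_fraction": 0.0, "n_extinct": 0}
                )
                continue
            cfg = arm_config(
                arm,
                base,
                n_immune0=int(n_i),
                max_steps=max_steps,
                base_seed=base_seed,
                arm_id=f"effector_{arm}_{n_i}",
            )
            extinct = 0
            for i in range(n_replicates):
                r = run_replicate(replace(cfg, replicate_index=i), cohort)
                extinct += r.termination.kind == "extinction"
            rows.append(
                {
                    "arm": arm,
                    "n_immune": int(n_i),
                    "clearance_fraction": extinct / n_replicates,
                    "n_extinct": extinct,
                }
            )
    return SweepResult(
        axes={"immune_counts": list(immune_counts), "arms": list(arms)},
        table=pd.DataFrame(rows),
        n_replicates=n_replicates,
    )
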