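"""Dose-response couplings of the evasion model.

Two functions link molecular state to behaviour:

* a logistic map from a tumour cell's total PD-L1 expression ``E`` (TPM) to
  its per-engagement immune-evasion probability,

      p_evasion(E) = 1 / (1 + exp(-k (E - x0))),

  with kill probability ``1 - p_evasion`` (the static engine); and

* a Hill function mapping local IFN-gamma concentration ``C`` (normalised
  units) to induced PD-L1 expression,

      E_induced(C) = P_max C^n / (K^n + C^n),

  the switch-like adaptive engine: induction stays low until ``C`` exceeds
  the half-saturation ``K``, then rapidly approaches the ceiling ``P_max``.

Effective expression is the memoryless sum ``E_total = E_basal + E_induced``;
it is recomputed from the current field every step (no hysteresis), so
induced resistance is fully reversible when the cytokine decays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LogisticParams",
    "HillParams",
    "ExpressionState",
    "evasion_probability",
    "kill_probability",
    "hill_induction",
    "effective_expression",
]


class ParameterError(ValueError):
    """A coupling parameter violates its admissible range."""


@dataclass(frozen=True)
class LogisticParams:
    """Midpoint ``x0`` (TPM) and steepness ``k`` (per TPM) of the evasion logistic."""

    x0: float = 3.0
    k: float = 1.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ParameterError(f"logistic steepness k must be > 0, got {self.k}")


@dataclass(frozen=True)
class HillParams:
    """Induction ceiling ``p_max`` (TPM), half-saturation ``half_sat`` (normalised
    concentration) and Hill coefficient ``coeff`` of the IFN-gamma -> PD-L1 coupling."""

    p_max: float = 15.0
    half_sat: float = 5.0
    coeff: float = 2.0

    def __post_init__(self) -> None:
        if self.p_max < 0:
            raise ParameterError(f"p_max must be >= 0, got {self.p_max}")
        if not self.half_sat > 0:
            raise ParameterError(f"half_sat must be > 0, got {self.half_sat}")
        if not self.coeff > 0:
            raise ParameterError(f"Hill coefficient must be > 0, got {self.coeff}")


@dataclass(frozen=True)
class ExpressionState:
    """Basal, induced and total PD-L1 expression of one tumour cell (TPM)."""

    e_basal: float
    e_induced: float

    @property
    def e_total(self) -> float:
        return self.e_basal + self.e_induced


def evasion_probability(e_total, params: LogisticParams = LogisticParams()):
    """Per-engagement evasion probability; strictly increasing in ``e_total``."""
    e = np.asarray(e_total, dtype=float)
    if np.any(e < 0):
        raise ParameterError("total expression must be non-negative")
    out = 1.0 / (1.0 + np.exp(-params.k * (e - params.x0)))
    return out if out.ndim else float(out)


def kill_probability(e_total, params: LogisticParams = LogisticParams()):
    """Complement of :func:`evasion_probability` (exact, by construction)."""
    e = np.asarray(e_total, dtype=float)
    if np.any(e < 0):
        raise ParameterError("total expression must be non-negative")
    # 1 - 1/(1+exp(-z)) = 1/(1+exp(z)); evaluate directly for accuracy at large E
    out = 1.0 / (1.0 + np.exp(params.k * (e - params.x0)))
    return out if out.ndim else float(out)


def hill_induction(c_local, params: HillParams = HillParams()):
    """Induced PD-L1 expression (TPM) at local concentration ``c_local``.

    Monotone non-decreasing, zero at zero, saturating at ``p_max``.  A
    negative concentration raises, because it signals instability in the
    upstream PDE solve rather than a meaningful input.
    """
    c = np.asarray(c_local, dtype=float)
    if np.any(c < 0):
        raise ParameterError("negative IFN-gamma concentration (PDE instability upstream?)")
    if params.p_max == 0:
        return np.zeros_like(c) if c.ndim else 0.0
    cn = np.power(c, params.coeff)
    out = params.p_max * cn / (params.half_sat**params.coeff + cn)
    return out if out.ndim else float(out)


def effective_expression(
    e_basal: float, c_local: float, params: HillParams = HillParams()
) -> ExpressionState:
    """Compose basal and Hill-induced expression into the cell's effective state."""
    if e_basal < 0:
        raise ParameterError("basal expression must be non-negative")
    return ExpressionState(e_basal=float(e_basal), e_induced=float(hill_induction(c_local, params)))
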