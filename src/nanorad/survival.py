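"""Multi-target radiation-survival model with repair saturation.

The model describes clonogenic survival of a cell whose genome is carried
in several identical copies ("units"). A single unit survives a dose
``D`` (kGy) with probability

.. math::

    S(D) = \\exp\\bigl(-\\alpha D\\,e^{-\\beta e^{-\\delta D}}\\bigr)

where ``alpha`` (kGy^-1) is the induction rate of lethal double-strand
breaks, ``beta`` (dimensionless) the repair capacity of the cell, and
``delta`` (kGy^-1) the rate at which radiation inactivates the repair
proteins themselves. A cell forms a colony if at least one of its
``n_units`` genome copies survives:

.. math::

    S_\\mathrm{cfu}(D) = 1 - (1 - S(D))^{n}

At low dose the repair term keeps survival near 1 (the "shoulder");
once ``delta * D`` is large repair is switched off and survival decays
as the bare exponential ``exp(-alpha * D)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SurvivalParams",
    "single_unit_survival",
    "cfu_survival",
    "approximate_survival",
    "dose_at_survival",
    "sensitization_enhancement_ratio",
    "amplification_at_dose",
]


@dataclass(frozen=True)
class SurvivalParams:
    """Parameter triple of the survival model plus the genome-unit count.

    Parameters
    ----------
    alpha : float
        Double-strand-break induction rate, kGy^-1. Must be > 0.
    beta : float
        Dimensionless repair capacity. Must be >= 0; ``beta = 0`` removes
        the shoulder and reduces the model to ``exp(-alpha * D)``.
    delta : float
        Repair-protein inactivation rate, kGy^-1. Must be >= 0.
    n_units : int
        Number of genome copies (the exponent of the multi-target term).
        Defaults to 4, the copy number of the *D. radiodurans* genome.
    """

    alpha: float
    beta: float = 0.0
    delta: float = 0.0
    n_units: int = 4

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be positive and finite, got {self.alpha}")
        if not (self.beta >= 0 and math.isfinite(self.beta)):
            raise ValueError(f"beta must be non-negative, got {self.beta}")
        if not (self.delta >= 0 and math.isfinite(self.delta)):
            raise ValueError(f"delta must be non-negative, got {self.delta}")
        if not (isinstance(self.n_units, (int, np.integer)) and self.n_units >= 1):
            raise ValueError(f"n_units must be an integer >= 1, got {self.n_units}")


def _check_dose(dose) -> np.ndarray:
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise ValueError("dose must be finite and >= 0 (kGy)")
    return d


def single_unit_survival(dose, params: SurvivalParams):
    """Survival probability of a single genome unit at ``dose`` kGy.

    Evaluates ``exp(-alpha * D * exp(-beta * exp(-delta * D)))``.
    Accepts scalars or arrays; returns the same shape. Equals 1 at D=0.
    """
    d = _check_dose(dose)
    exponent = params.alpha * d * np.exp(-params.beta * np.exp(-params.delta * d))
    out = np.exp(-exponent)
    return out.item() if np.isscalar(dose) or np.ndim(dose) == 0 else out


def cfu_survival(dose, params: SurvivalParams):
    """Colony-forming (whole-cell) survival: ``1 - (1 - S)^n_units``.

    The cell survives if any one of its genome copies does, so CFU
    survival always lies at or above the single-unit curve. Strictly
    decreasing in dose for ``alpha > 0``.
    """
    d = _check_dose(dose)
    s = params.alpha * d * np.exp(-params.beta * np.exp(-params.delta * d))
    # 1-(1-exp(-x))^n via expm1 for accuracy near x=0
    out = 1.0 - (-np.expm1(-s)) ** params.n_units
    return out.item() if np.isscalar(dose) or np.ndim(dose) == 0 else out


def approximate_survival(dose, params: SurvivalParams, order: str = "asymptotic"):
    """High-dose approximations of the single-unit survival curve.

    ``order="first_order"`` expands the inner repair exponential to first
    order: ``exp(-alpha*D*(1 - beta*exp(-delta*D)))``. ``order="asymptotic"``
    drops the repair term entirely: ``exp(-alpha*D)``. Both converge to the
    exact curve as ``delta * D`` grows.
    """
    d = _check_dose(dose)
    if order == "first_order":
        out = np.exp(-params.alpha * d * (1.0 - params.beta * np.exp(-params.delta * d)))
    elif order == "asymptotic":
        out = np.exp(-params.alpha * d)
    else:
        raise ValueError(f"unknown order {order!r}; use 'first_order' or 'asymptotic'")
    return out.item() if np.isscalar(dose) or np.ndim(dose) == 0 else out


def dose_at_survival(
    params: SurvivalParams,
    target: float,
    *,
    dose_cap: float = 100.0,
    xtol: float = 1e-6,
) -> float:
    """Dose (kGy) at which CFU survival equals ``target``.

    CFU survival is strictly decreasing in dose, so the root is unique;
    it is found by Brent's method on ``[0, dose_cap]``.

    Raises
    ------
    ValueError
        If ``target`` is outside (0, 1), or survival at ``dose_cap``
        still exceeds ``target`` (no bracket below the cap).
    """
    if not (0.0 < target < 1.0):
        raise ValueError(f"target survival must lie in (0, 1), got {target}")
    f = lambda d: cfu_survival(d, params) - target
    if f(dose_cap) > 0:
        raise ValueError(
            f"survival at the dose cap {dose_cap} kGy is still above {target}; "
            "raise dose_cap"
        )
    return float(brentq(f, 0.0, dose_cap, xtol=xtol))


def sensitization_enhancement_ratio(
    params_ref: SurvivalParams,
    params_test: SurvivalParams,
    level: float = 0.5,
    **kwargs,
) -> float:
    """Sensitization enhancement ratio at an iso-effect survival level.

    The SER is the ratio of doses producing the same CFU reduction
    without vs. with the sensitizer: ``D_ref(level) / D_test(level)``.
    ``level=0.5`` (50% CFU reduction) is the conventional choice. A
    ratio above 1 means the test condition is radio-sensitized.
    """
    return dose_at_survival(params_ref, level, **kwargs) / dose_at_survival(
        params_test, level, **kwargs
    )


def amplification_at_dose(survival_ref: float, survival_test: float) -> float:
    """Relative survival reduction at a fixed dose.

    ``(S_ref - S_test) / S_ref``: the fraction of otherwise-surviving
    cells killed by adding the sensitizer. Negative output (protection)
    is permitted and simply reported.
    """
    if not (0.0 < survival_ref <= 1.0):
        raise ValueError(f"reference survival must lie in (0, 1], got {survival_ref}")
    if not (0.0 <= survival_test <= 1.0):
        raise ValueError(f"test survival must lie in [0, 1], got {survival_test}")
    return (survival_ref - survival_test) / survival_ref
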