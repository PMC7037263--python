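"""The predicted Budyko-type curve: ET/P as a function of the aridity index.

The aridity index ``AI = ET0/P`` (potential over actual precipitation)
separates energy-limited (``AI < 1``) from water-limited (``AI > 1``)
ecosystems, with the classical Budyko bounds ``ET/P ≤ 1`` and
``ET/P ≤ AI``.  The percolation-optimization model predicts:

* energy-limited branch: ``ET/P = min(AI, c_h)`` with the humid base
  fraction ``c_h = 1.9/(1.9 + 1.15) ≈ 0.623``;
* water-limited branch (``AI ≥ 1``): vegetation covers a fraction
  ``P/ET0`` of the ground and transpires 0.813 of the precipitation it
  receives, bare ground evaporates everything it receives, so
  ``ET/P = 1 − c/AI`` with the arid run-off coefficient
  ``c = 1 − 0.813 = 0.187`` (also printed as 0.183);
* above a crossover aridity index of ~1.8 soils are typically still
  deepening (no steady state); depth then scales more weakly with
  the flux and the predicted ET jumps upward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .npp_optimizer import base_et_fraction, et_fraction_closed_form
from .percolation_core import CoefficientMode, PercolationConstants

__all__ = [
    "WaterBalanceInput",
    "BudykoCurveConfig",
    "BareEvaporation",
    "aridity_index",
    "arid_et_ratio",
    "bare_evaporation_fraction",
    "predicted_curve",
    "surface_runoff_fixed",
    "TOTAL_RUNOFF_FRACTION",
]

#: Complement of the humid base ET fraction: share of P leaving as run-off.
TOTAL_RUNOFF_FRACTION = 0.377

PHASES = ("in-phase", "out-of-phase", "non-seasonal")


@dataclass(frozen=True)
class WaterBalanceInput:
    """Per-basin fluxes and fractions, in one declared rate unit.

    ``phase`` records whether the precipitation maximum coincides with
    the irradiance maximum (tropics: in-phase; temperate: out-of-phase;
    maritime: non-seasonal); it is carried through to outputs but no
    quantitative phase correction is applied.
    """

    P: float
    ET0: float
    interception: float = 0.0
    f_sub: float = 0.6
    phase: str = "non-seasonal"
    dS_dt: float = 0.0
    units: str = "mm/yr"

    def __post_init__(self) -> None:
        if self.P < 0 or self.ET0 < 0:
            raise ValueError("P and ET0 must be >= 0")
        if not (0.0 <= self.f_sub <= 1.0):
            raise ValueError(f"f_sub must lie in [0, 1], got {self.f_sub!r}")
        if self.interception < 0 or self.interception > self.P:
            raise ValueError(
                f"interception must lie in [0, P], got {self.interception!r}"
            )
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")


@dataclass(frozen=True)
class BudykoCurveConfig:
    """Knobs of the predicted curve.

    ``arid_coefficient`` is the water-limited run-off share of
    vegetated-area precipitation: 0.187 as derived (1 − 0.813) or 0.183
    as printed alongside the model; ``crossover_AI`` locates the jump to
    the non-steady-soil branch; predictions of the bare-soil evaporation
    split are flagged unreliable below
    ``evap_fraction_validity_threshold``.
    """

    arid_coefficient: float = 0.187
    crossover_AI: float = 1.8
    evap_fraction_validity_threshold: float = 0.4
    enable_nonsteady_branch: bool = True
    mode: CoefficientMode = "printed"

    def __post_init__(self) -> None:
        if not (0.0 < self.arid_coefficient < 1.0):
            raise ValueError(
                f"arid_coefficient must lie in (0, 1), got {self.arid_coefficient!r}"
            )
        if self.crossover_AI <= 1.0:
            raise ValueError(
                f"crossover_AI must be > 1, got {self.crossover_AI!r}"
            )

    @classmethod
    def paper_fidelity(cls) -> "BudykoCurveConfig":
        """Preset using the printed arid coefficient 0.183."""
        return cls(arid_coefficient=0.183)


def aridity_index(inputs: WaterBalanceInput) -> float:
    """``AI = ET0/P``; +inf for a zero-precipitation basin."""
    if inputs.P == 0.0:
        return math.inf
    return inputs.ET0 / inputs.P


def surface_runoff_fixed(
    P: float, f_sub: float, total_runoff_frac: float = TOTAL_RUNOFF_FRACTION
) -> float:
    """Fixed-total-run-off surface component: ``Qsurf = (1−f_sub)·0.377·P``."""
    if not (0.0 <= f_sub <= 1.0):
        raise ValueError(f"f_sub must lie in [0, 1], got {f_sub!r}")
    return (1.0 - f_sub) * total_runoff_frac * P


def arid_et_ratio(AI: float, cfg: BudykoCurveConfig = BudykoCurveConfig()) -> float:
    """Water-limited branch: ``ET/P = 1 − c/AI``.

    Vegetation covers the fraction ``P/ET0 = 1/AI`` of the surface and
    runs off ``c`` of its precipitation; bare ground evaporates all of
    its share.
    """
    if AI < 1.0:
        raise ValueError(
            f"the water-limited branch requires AI >= 1, got {AI!r}"
        )
    return 1.0 - cfg.arid_coefficient / AI


class BareEvaporation(NamedTuple):
    """Bare-soil evaporation share of ET, with a validity flag."""

    fraction: float
    reliable: bool


def bare_evaporation_fraction(
    AI: float, cfg: BudykoCurveConfig = BudykoCurveConfig()
) -> BareEvaporation:
    """Share of ET due to bare-ground evaporation in the arid regime.

    ``(1 − 1/AI)/(1 − c/AI)``: the bare fraction of the surface times its
    (complete) evaporation, over total ET.  Identically 0 at ``AI = 1``,
    hence useful only where it yields fractions above the configured
    validity threshold (~0.4).
    """
    if AI < 1.0:
        raise ValueError(
            f"the water-limited branch requires AI >= 1, got {AI!r}"
        )
    frac = (1.0 - 1.0 / AI) / (1.0 - cfg.arid_coefficient / AI)
    return BareEvaporation(frac, frac >= cfg.evap_fraction_validity_threshold)


def _nonsteady_coefficient(cfg: BudykoCurveConfig, const: PercolationConstants) -> float:
    # Still-deepening soils: depth responds to the flux roughly as a square
    # root, so the depth exponent inside beta is halved (an interpretation;
    # no closed form is published for this branch).
    beta = (const.depth_power / 2.0) * (3.0 - const.df_3d)
    return 1.0 - et_fraction_closed_form(const.df_3d, beta)


def predicted_curve(
    ai_grid: Sequence[float] | np.ndarray,
    cfg: BudykoCurveConfig = BudykoCurveConfig(),
    const: PercolationConstants = PercolationConstants(),
) -> pd.DataFrame:
    """Evaluate the piecewise predicted curve on a sorted grid of AI values.

    Returns a table with columns ``ai``, ``et_over_p``, ``branch``
    (energy-limit | humid | arid | arid-nonsteady) and ``regime``
    (energy-limited | water-limited | crossover).  Both Budyko bounds
    are enforced by clamping; the branches are intentionally
    discontinuous at ``crossover_AI`` (upward jump).
    """
    ai = np.asarray(ai_grid, dtype=float)
    if ai.ndim != 1 or len(ai) == 0:
        raise ValueError("ai_grid must be a non-empty 1-D sequence")
    if np.any(ai <= 0):
        raise ValueError("all aridity indices must be > 0")
    if np.any(np.diff(ai) < 0):
        raise ValueError("ai_grid must be sorted ascending")

    c_h = base_et_fraction(cfg.mode, const.df_2d, const.depth_power)
    c_ns = _nonsteady_coefficient(cfg, const)

    rows = []
    for a in ai:
        if a < 1.0:
            etp = min(a, c_h)
            branch = "energy-limit" if a < c_h else "humid"
            regime = "energy-limited"
        else:
            regime = "crossover" if a == 1.0 else "water-limited"
            if cfg.enable_nonsteady_branch and a >= cfg.crossover_AI:
                etp = 1.0 - c_ns / a
                branch = "arid-nonsteady"
            else:
                etp = arid_et_ratio(a, cfg)
                branch = "arid"
        etp = min(etp, 1.0, a)  # Budyko bounds
        rows.append((a, etp, branch, regime))
    return pd.DataFrame(rows, columns=["ai", "et_over_p", "branch", "regime"])
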