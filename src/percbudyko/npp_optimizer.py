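"""NPP optimization over evapotranspiration and the closed-form partitions.

The ecosystem's net primary productivity is modelled as the product of
root mass, ``ET^df`` with ``df`` the root-system mass-fractal dimension,
and a soil-depth factor ``x^p`` with ``x`` the transport-limited
steady-state depth (``p = 1`` in the humid regime, ``p = 3−df = 0.5``
for arid 3D root systems).  Substituting the depth law

    NPP(ET) ∝ x0 · [Qsub / (Db·φ·D)]^depth_power·p · ET^df,   Qsub = P′ − ET − Qsurf

(with ``P′ = P − interception``) and maximizing over ET partitions the
precipitation reaching the ground.  When the denudation rate ``D`` is
held fixed the maximizer is the closed form

    ET* = df/(df + β) · (P′ − Qsurf),      β = depth_power · p,

which gives the headline fractions 1.9/(1.9+1.15) = 0.623 (humid) and
2.5/(2.5+0.575) = 0.813 (arid, vegetated area).  When ``D`` itself
responds to the fluxes, ``D = a·Qsub + b·Qsurf``, the optimum shifts;
for ``b ≫ a`` a second-order expansion is available.  Interception is
water that never reaches the ground: it is removed before the
optimization and added back to ET afterwards, giving

    ET = c·(P − Qsurf) + (1−c)·I_t,        c = 0.623.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .percolation_core import CoefficientMode, PercolationConstants, SoilSystem

__all__ = [
    "NPPModelParams",
    "PartitionResult",
    "BASE_ET_FRACTION_PRINTED",
    "npp_value",
    "optimize_et_numeric",
    "et_fraction_closed_form",
    "et_first_order",
    "et_second_order",
    "et_with_interception",
    "et_partition_selfconsistent",
    "base_et_fraction",
]

#: Humid-regime ET fraction as printed alongside the model: 1.9/(1.9+1.15)
#: rounded to three digits.
BASE_ET_FRACTION_PRINTED = 0.623


@dataclass(frozen=True)
class NPPModelParams:
    """Exponents of the NPP functional.

    ``df`` is the root mass-fractal dimension (2D percolation value 1.9
    for shallow-rooted humid ecosystems, 3D value 2.5 for arid ones);
    ``depth_power`` the soil-depth exponent; ``depth_factor_power`` the
    power of the depth factor in the NPP product (1 humid, ``3−df``
    arid).  ``A0`` is a reference area that cancels in the optimization.
    """

    df: float = 1.9
    depth_power: float = 1.15
    depth_factor_power: float = 1.0
    A0: float = 1.0

    def __post_init__(self) -> None:
        if not (1.0 < self.df <= 3.0):
            raise ValueError(f"df must lie in (1, 3], got {self.df!r}")
        if self.depth_power <= 0:
            raise ValueError(f"depth_power must be > 0, got {self.depth_power!r}")
        if self.depth_factor_power <= 0:
            raise ValueError(
                f"depth_factor_power must be > 0, got {self.depth_factor_power!r}"
            )
        if self.A0 <= 0:
            raise ValueError(f"A0 must be > 0, got {self.A0!r}")

    @property
    def beta(self) -> float:
        """Effective water-loss exponent ``depth_power · depth_factor_power``."""
        return self.depth_power * self.depth_factor_power

    @classmethod
    def humid(cls, const: PercolationConstants | None = None) -> "NPPModelParams":
        c = const or PercolationConstants()
        return cls(df=c.df_2d, depth_power=c.depth_power, depth_factor_power=1.0)

    @classmethod
    def arid(cls, const: PercolationConstants | None = None) -> "NPPModelParams":
        c = const or PercolationConstants()
        return cls(
            df=c.df_3d, depth_power=c.depth_power, depth_factor_power=3.0 - c.df_3d
        )


@dataclass(frozen=True)
class PartitionResult:
    """Closure-checked partition of precipitation.

    All fluxes share the units of ``P``.  Interception is folded into
    ET (it is evaporated water), so closure reads
    ``P = ET + Qsurf + Qsub`` exactly.
    """

    P: float
    ET: float
    interception: float
    Qsurf: float
    Qsub: float
    E: float = 0.0
    regime: str = "unspecified"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.P <= 0:
            raise ValueError(f"P must be > 0, got {self.P!r}")
        closure = self.ET + self.Qsurf + self.Qsub - self.P
        if abs(closure) > 1e-12 * self.P:
            raise ValueError(f"water balance does not close: residual {closure!r}")
        for name in ("ET", "interception", "Qsurf", "Qsub", "E"):
            v = getattr(self, name)
            if v < -1e-12 * self.P:
                raise ValueError(f"{name} must be >= 0, got {v!r}")

    @property
    def T(self) -> float:
        """Transpiration: ET net of interception and bare-soil evaporation."""
        return self.ET - self.interception - self.E

    @property
    def et_over_p(self) -> float:
        return self.ET / self.P

    @property
    def q_over_p(self) -> float:
        return (self.Qsurf + self.Qsub) / self.P


def _partition(
    P: float,
    ET: float,
    interception: float,
    Qsurf: float,
    *,
    E: float = 0.0,
    regime: str = "unspecified",
    flags: tuple[str, ...] = (),
) -> PartitionResult:
    Qsub = P - ET - Qsurf
    return PartitionResult(
        P=P,
        ET=ET,
        interception=interception,
        Qsurf=max(Qsurf, 0.0),
        Qsub=max(Qsub, 0.0) if abs(Qsub) < 1e-15 * P else Qsub,
        E=E,
        regime=regime,
        flags=flags,
    )


def _denudation(soil: SoilSystem, qsub: float, qsurf: float) -> float:
    if soil.denudation_mode == "constant":
        assert soil.D is not None
        return soil.D
    a = soil.a if soil.a is not None else 0.0
    b = soil.b if soil.b is not None else 0.0
    return a * qsub + b * qsurf


def npp_value(
    et: float,
    P: float,
    params: NPPModelParams,
    soil: SoilSystem,
    *,
    qsurf: float = 0.0,
    interception: float = 0.0,
    const: PercolationConstants = PercolationConstants(),
) -> float:
    """Evaluate the NPP functional at ground-level evapotranspiration ``et``.

    ``et`` is the ET of the soil column (transpiration + bare-soil
    evaporation), excluding interception; the feasible interval is
    ``[0, P − interception − qsurf]``.
    """
    p_ground = P - interception
    if not (0.0 <= et <= p_ground - qsurf + 1e-15 * P):
        raise ValueError(
            f"ET = {et!r} outside the feasible interval [0, {p_ground - qsurf!r}]"
        )
    qsub = max(p_ground - et - qsurf, 0.0)
    denud = _denudation(soil, qsub, qsurf)
    if denud <= 0.0:
        raise ValueError("denudation rate must be positive inside the NPP bracket")
    bracket = qsub / (const.Db * soil.porosity * denud)
    depth = soil.x0 * bracket**params.depth_power
    return depth**params.depth_factor_power * et**params.df / params.A0


def optimize_et_numeric(
    P: float,
    params: NPPModelParams,
    soil: SoilSystem,
    *,
    qsurf: float = 0.0,
    interception: float = 0.0,
    regime: str = "unspecified",
    xatol_frac: float = 1e-12,
    grid_points: int = 512,
) -> PartitionResult:
    """Maximize NPP over ET by bounded scalar search on the feasible interval.

    A coarse grid pre-scan brackets the maximum (guarding against flat
    or degenerate shapes) before Brent refinement to ``xatol_frac·P``.
    The returned result reports total ET (ground ET + interception).
    """
    p_ground = P - interception
    upper = p_ground - qsurf
    if upper <= 0.0:
        warnings.warn(
            "no water remains for the soil column (P - interception <= Qsurf); "
            "returning the all-run-off partition",
            RuntimeWarning,
            stacklevel=2,
        )
        return _partition(
            P, interception, interception, min(qsurf, P - interception),
            regime=regime, flags=("degenerate-interval",),
        )

    def neg(et: float) -> float:
        return -npp_value(
            et, P, params, soil, qsurf=qsurf, interception=interception
        )

    grid = np.linspace(0.0, upper, grid_points + 1)[1:-1]
    values = np.array([-neg(g) for g in grid])
    k = int(np.argmax(values))
    lo = grid[max(k - 1, 0)] if k > 0 else 0.0
    hi = grid[min(k + 1, len(grid) - 1)] if k < len(grid) - 1 else upper
    res = minimize_scalar(
        neg, bounds=(lo, hi), method="bounded",
        options={"xatol": xatol_frac * P},
    )
    et_ground = float(res.x)
    return _partition(
        P, et_ground + interception, interception, qsurf, regime=regime
    )


def et_fraction_closed_form(df: float, beta: float) -> float:
    """Maximizer of ``(1−f)^beta · f^df`` on (0, 1): ``f* = df/(df+beta)``.

    This is the ET share of the water available to the soil column in
    constant-denudation mode; (1.9, 1.15) → 0.623, (2.5, 0.575) → 0.813.
    """
    if df <= 0 or beta <= 0:
        raise ValueError(f"df and beta must be > 0, got df={df!r}, beta={beta!r}")
    return df / (df + beta)


def base_et_fraction(
    mode: CoefficientMode = "printed",
    df: float = 1.9,
    beta: float = 1.15,
) -> float:
    """Humid-regime ET fraction: printed constant 0.623 or df/(df+beta)."""
    if mode == "printed" and df == 1.9 and beta == 1.15:
        return BASE_ET_FRACTION_PRINTED
    return et_fraction_closed_form(df, beta)


def et_first_order(
    P: float,
    Qsurf: float,
    *,
    mode: CoefficientMode = "printed",
    df: float = 1.9,
    beta: float = 1.15,
) -> float:
    """First-order optimum with flux-proportional denudation, ``b ≫ a``.

    ``ET = c·(P − Qsurf)``; ``D ≈ b·Qsurf`` is then constant and the
    closed-form fraction applies to the water passing the surface.
    """
    if Qsurf > P:
        raise ValueError(f"Qsurf = {Qsurf!r} exceeds P = {P!r}")
    return base_et_fraction(mode, df, beta) * (P - Qsurf)


def et_second_order(P: float, Qsurf: float, a: float, b: float) -> float:
    """Two-term expansion of the optimum in the small ratio ``a/b``.

    Derived with the approximated exponents (df = 2, depth_power = 1):

        ET = (2/3)(P − Qsurf) + (2/27)·(P − Qsurf)²/Qsurf · (a/b).

    Valid only for ``b ≫ a``; for ``Qsurf = 0`` the correction term is
    singular and only the first term is returned (with a warning).
    """
    if b <= 0:
        raise ValueError(f"b must be > 0, got {b!r}")
    if a < 0:
        raise ValueError(f"a must be >= 0, got {a!r}")
    if Qsurf > P:
        raise ValueError(f"Qsurf = {Qsurf!r} exceeds P = {P!r}")
    first = (2.0 / 3.0) * (P - Qsurf)
    if Qsurf == 0.0:
        warnings.warn(
            "second-order term is singular at Qsurf = 0; returning first term only",
            RuntimeWarning,
            stacklevel=2,
        )
        return first
    return first + (2.0 / 27.0) * (P - Qsurf) ** 2 / Qsurf * (a / b)


def et_with_interception(
    P: float,
    interception: float,
    Qsurf: float,
    *,
    mode: CoefficientMode = "printed",
    df: float = 1.9,
    beta: float = 1.15,
    regime: str = "unspecified",
) -> PartitionResult:
    """Interception-extended first-order partition.

    Interception never reaches the soil, so the optimization applies to
    ``P′ = P − I_t`` and the intercepted water is added back to ET:

        ET = c·(P − I_t − Qsurf) + I_t = c·(P − Qsurf) + (1−c)·I_t.
    """
    if interception < 0 or Qsurf < 0:
        raise ValueError("interception and Qsurf must be >= 0")
    if interception + Qsurf > P:
        raise ValueError(
            f"infeasible: interception + Qsurf = {interception + Qsurf!r} > P = {P!r}"
        )
    c = base_et_fraction(mode, df, beta)
    et = c * (P - interception - Qsurf) + interception
    return _partition(P, et, interception, Qsurf, regime=regime)


def et_partition_selfconsistent(
    P: float,
    interception: float,
    f_sub: float,
    *,
    mode: CoefficientMode = "printed",
    df: float = 1.9,
    beta: float = 1.15,
    regime: str = "unspecified",
) -> PartitionResult:
    """Partition with surface run-off tied to total run-off self-consistently.

    Solves the fixed point ``Qsurf = (1 − f_sub)·(P − ET)`` jointly with
    ``ET = c·(P − I_t − Qsurf) + I_t`` (linear, solved in closed form).
    The default "table mode" elsewhere instead fixes
    ``Qsurf = (1 − f_sub)·0.377·P``.
    """
    if not (0.0 <= f_sub <= 1.0):
        raise ValueError(f"f_sub must lie in [0, 1], got {f_sub!r}")
    c = base_et_fraction(mode, df, beta)
    g = (1.0 - f_sub) * c
    # ET = c(P − I) − c(1−f_sub)(P − ET) + I  →  solve for ET
    et = (c * (P - interception) - g * P + interception) / (1.0 - g)
    qsurf = (1.0 - f_sub) * (P - et)
    return _partition(P, et, interception, qsurf, regime=regime)
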