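"""Universal percolation exponents and the soil-formation scaling laws.

Solute transported by advection through a 3D pore network near the
percolation threshold travels a Euclidean distance ``x`` in a time that
scales as ``t ∝ x^Db`` with the backbone exponent ``Db = 1.87``, rather
than linearly as in the advection--dispersion picture.  Because chemical
weathering in the field is transport-limited, the soil-production rate
inherits this scaling, ``Rs ∝ Qsub·(x/x0)^(−(Db−1))``, and setting
production equal to the denudation rate ``D`` yields a steady-state soil
depth

    x = x0 · [Qsub / (Db · φ · D)]^(1/(Db−1))

with ``x0`` the network (pore) scale, taken as the median particle
diameter d50, and ``φ`` the porosity.  This module houses those
exponents, the depth/rate/time-scale laws derived from them, and the
Damköhler regime rule that decides when the transport-limited picture
applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple

__all__ = [
    "PercolationConstants",
    "SoilSystem",
    "TimeScales",
    "M_PER_MYR_TO_MM_PER_YR",
    "steady_state_soil_depth",
    "soil_formation_rate",
    "transport_time",
    "position_at_time",
    "erosion_timescale",
    "weathering_regime",
    "time_scales",
]

#: 1 m/Myr expressed in mm/yr.
M_PER_MYR_TO_MM_PER_YR = 1e-3

CoefficientMode = Literal["printed", "exact"]


@dataclass(frozen=True)
class PercolationConstants:
    """Universal percolation exponents and the powers derived from them.

    Parameters
    ----------
    Db
        3D backbone exponent governing advective solute travel time,
        ``t ∝ x^Db``.
    d_opt
        2D optimal-path tortuosity exponent (root length vs radial
        extent, ``RL ∝ RRE^1.21``).
    df_2d, df_3d
        Mass-fractal dimensions of large percolation clusters in 2D and
        3D; used for root systems in humid and arid climates.
    depth_power
        Exponent of the steady-state depth law, ``1/(Db−1)``.  In
        ``"printed"`` mode this is the rounded value 1.15 so that
        published coefficients (0.623 etc.) are reproduced digit for
        digit; ``"exact"`` mode carries ``1/0.87 = 1.14942…``.
    rate_power
        Exponent of the soil-production law, ``Db − 1``.
    mode
        Which convention ``depth_power`` follows; recorded so outputs
        can state it.
    """

    Db: float = 1.87
    d_opt: float = 1.21
    df_2d: float = 1.9
    df_3d: float = 2.5
    depth_power: float = 1.15
    rate_power: float = 0.87
    mode: CoefficientMode = "printed"

    def __post_init__(self) -> None:
        for name in ("Db", "d_opt", "df_2d", "df_3d", "depth_power", "rate_power"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if not (self.df_2d < self.df_3d <= 3.0):
            raise ValueError(
                f"require df_2d < df_3d <= 3, got df_2d={self.df_2d}, df_3d={self.df_3d}"
            )
        # depth_power must invert rate_power; the printed values 1.15/0.87
        # only do so to ~5e-4, the exact mode to machine precision.
        tol = 1e-12 if self.mode == "exact" else 5e-3
        if abs(self.depth_power * (self.Db - 1.0) - 1.0) > tol:
            raise ValueError(
                "depth_power is inconsistent with 1/(Db-1) for mode "
                f"{self.mode!r}: {self.depth_power} vs {1.0 / (self.Db - 1.0)}"
            )

    @classmethod
    def printed(cls) -> "PercolationConstants":
        """Constants with the rounded printed powers (1.15, 0.87)."""
        return cls()

    @classmethod
    def exact(cls) -> "PercolationConstants":
        """Constants with ``depth_power = 1/(Db−1)`` to full precision."""
        return cls(depth_power=1.0 / 0.87, rate_power=0.87, mode="exact")


@dataclass(frozen=True)
class SoilSystem:
    """Pore-scale geometry and fluxes of one soil column / basin.

    ``Qsub`` and ``D`` (and the flux-proportional denudation
    coefficients ``a``, ``b``) must be supplied in one consistent unit
    system: the depth-law bracket ``Qsub/(Db·φ·D)`` is dimensionless
    only then.  ``units`` records the declared flux unit.

    ``D`` may be given directly (constant-denudation mode) or replaced
    by the flux-proportional model ``D = a·Qsub + b·Qsurf`` (set ``a``
    and ``b``, leave ``D`` as ``None``).
    """

    x0: float
    porosity: float
    Qsub: float = 0.0
    D: float | None = None
    a: float | None = None
    b: float | None = None
    units: str = "mm/yr"

    def __post_init__(self) -> None:
        if self.x0 <= 0:
            raise ValueError(f"x0 must be > 0, got {self.x0!r}")
        if not (0.0 < self.porosity < 1.0):
            raise ValueError(f"porosity must lie in (0, 1), got {self.porosity!r}")
        if self.Qsub < 0:
            raise ValueError(f"Qsub must be >= 0, got {self.Qsub!r}")
        if self.D is not None and self.D <= 0:
            raise ValueError(f"D must be > 0 when given, got {self.D!r}")
        if (self.a is not None) or (self.b is not None):
            a = self.a if self.a is not None else 0.0
            b = self.b if self.b is not None else 0.0
            if a < 0 or b < 0:
                raise ValueError("denudation coefficients a, b must be >= 0")
            if a == 0 and b == 0:
                raise ValueError("denudation coefficients a and b cannot both be 0")

    @property
    def denudation_mode(self) -> str:
        """``"constant"`` when D is fixed, ``"flux"`` for D = a·Qsub + b·Qsurf."""
        return "constant" if (self.a is None and self.b is None) else "flux"

    @property
    def t0(self) -> float:
        """Network-scale time ``x0·φ/Qsub`` (pore advection time)."""
        if self.Qsub <= 0:
            raise ValueError("t0 requires Qsub > 0")
        return self.x0 * self.porosity / self.Qsub


class TimeScales(NamedTuple):
    """Bundle of the characteristic times of one soil column."""

    t0: float
    t_x: float
    t_D: float
    Da_I: float | None = None


def steady_state_soil_depth(
    soil: SoilSystem,
    const: PercolationConstants = PercolationConstants(),
    *,
    include_transport_factor: bool = True,
) -> float:
    """Depth at which transport-limited soil production balances denudation.

    ``x = x0 · [Qsub/(Db·φ·D)]^depth_power``.  The ``1/Db`` factor in
    the bracket comes from differentiating ``x(t) ∝ t^(1/Db)``; the
    time-scale-matching convention omits it (set
    ``include_transport_factor=False``).
    """
    if soil.Qsub <= 0:
        raise ValueError(f"Qsub must be > 0 for a steady-state depth, got {soil.Qsub!r}")
    if soil.D is None or soil.D <= 0:
        raise ValueError("SoilSystem.D must be set and > 0 for the steady-state depth")
    factor = const.Db if include_transport_factor else 1.0
    bracket = soil.Qsub / (factor * soil.porosity * soil.D)
    return soil.x0 * bracket**const.depth_power


def soil_formation_rate(
    soil: SoilSystem,
    x: float,
    const: PercolationConstants = PercolationConstants(),
) -> float:
    """Soil-production rate at depth ``x``: ``(Qsub/(Db·φ))·(x/x0)^(−(Db−1))``.

    Decreases with depth because the solute front slows as ``t^(1/Db−1)``;
    equals the denudation rate exactly at the steady-state depth (an
    algebraic identity in ``"exact"`` coefficient mode).
    """
    if x < soil.x0:
        raise ValueError(
            f"x = {x!r} is below the network scale x0 = {soil.x0!r}; "
            "the scaling law is not defined there"
        )
    return (soil.Qsub / (const.Db * soil.porosity)) * (x / soil.x0) ** (-const.rate_power)


def transport_time(
    x: float,
    soil: SoilSystem,
    const: PercolationConstants = PercolationConstants(),
) -> float:
    """Time for the weathering (solute) front to reach depth ``x``.

    ``t_x = t0 · (x/x0)^Db`` with ``t0 = x0·φ/Qsub``.
    """
    if x < soil.x0:
        raise ValueError(
            f"x = {x!r} is below the network scale x0 = {soil.x0!r}; "
            "the scaling law is not defined there"
        )
    return soil.t0 * (x / soil.x0) ** const.Db


def position_at_time(
    t: float,
    soil: SoilSystem,
    const: PercolationConstants = PercolationConstants(),
) -> float:
    """Solute-front depth after time ``t``; inverse of :func:`transport_time`."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t!r}")
    return soil.x0 * (t / soil.t0) ** (1.0 / const.Db)


def erosion_timescale(x: float, D: float) -> float:
    """Erosional residence time of a soil column: ``t_D = x/D``.

    With ``D`` from ~1 m/Myr (arid continental interiors) to
    ~1000 m/Myr (tectonically active, wet mountains) this spans
    ~1 Myr down to ~1 kyr for a 1 m soil, and a couple of centuries for
    decimetre soils.
    """
    if D <= 0:
        raise ValueError(f"denudation rate D must be > 0, got {D!r}")
    if x < 0:
        raise ValueError(f"depth x must be >= 0, got {x!r}")
    return x / D


def weathering_regime(Da_I: float) -> str:
    """Classify weathering by the Damköhler ratio ``Da_I = τ_A/τ_R``.

    ``Da_I > 1`` (advection slower than reaction): transport-limited,
    the percolation scaling laws of this module apply.  ``Da_I < 1``:
    kinetics-limited — the formation rate is (to lowest order) constant
    and depth grows linearly in time.  ``Da_I`` is an external input
    here; computing it from mineral kinetics is out of scope.
    """
    if Da_I < 0:
        raise ValueError(f"Da_I must be >= 0, got {Da_I!r}")
    if math.isclose(Da_I, 1.0, rel_tol=0.0, abs_tol=0.0) or Da_I == 1.0:
        return "crossover"
    return "transport-limited" if Da_I > 1.0 else "kinetics-limited"


def time_scales(
    x: float,
    soil: SoilSystem,
    const: PercolationConstants = PercolationConstants(),
    *,
    D: float | None = None,
    Da_I: float | None = None,
) -> TimeScales:
    """Assemble ``(t0, t_x, t_D, Da_I)`` for a column of depth ``x``."""
    D_eff = D if D is not None else soil.D
    if D_eff is None:
        raise ValueError("a denudation rate D is required for t_D")
    return TimeScales(
        t0=soil.t0,
        t_x=transport_time(x, soil, const),
        t_D=erosion_timescale(x, D_eff),
        Da_I=Da_I,
    )
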