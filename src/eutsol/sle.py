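"""Solid–liquid-equilibrium solubility from fusion data.

The saturation condition for a crystalline solute is ln(γ·x) = −ΔG_fus/(R·T).
ΔG_fus(T) is evaluated by the Schröder–van Laar approximation with the heat
capacity difference neglected, ΔG_fus = ΔH_fus·(1 − T/T_m), which is isolated
behind :func:`gibbs_fusion` so alternative temperature dependences can be
swapped in.  Non-ideality enters only through a pluggable activity model
(``ln_gamma(x, composition, T)``); the solver is a damped fixed-point
iteration on ln x starting from the ideal solubility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, log
from typing import Callable, Protocol

from eutsol.data import SolventComposition
from eutsol.exceptions import DomainError, ValidationError

__all__ = [
    "R_J_PER_MOL_K",
    "FusionData",
    "EDARAVONE_FUSION",
    "ActivityModel",
    "ideal_activity",
    "margules",
    "SLEResult",
    "gibbs_fusion",
    "ideal_solubility",
    "solve_sle",
]

R_J_PER_MOL_K = 8.314


@dataclass(frozen=True)
class FusionData:
    """Melting temperature (K) and enthalpy of fusion (kJ/mol)."""

    T_m: float
    H_fus: float

    def __post_init__(self) -> None:
        if self.T_m <= 0 or self.H_fus <= 0:
            raise ValidationError("T_m and H_fus must be positive")


#: Fusion data of edaravone (melting point 403.15 K, ΔH_fus 29.91 kJ/mol).
EDARAVONE_FUSION = FusionData(T_m=403.15, H_fus=29.91)


class ActivityModel(Protocol):
    """Behavioral contract: ln γ of the solute at (x, composition, T)."""

    def __call__(
        self, x_solute: float, composition: SolventComposition | None, T: float
    ) -> float: ...


def ideal_activity(x_solute: float, composition=None, T: float = 298.15) -> float:
    """Ideal solution: ln γ ≡ 0."""
    return 0.0


def margules(A: float) -> ActivityModel:
    """One-parameter Margules model ln γ = A·(1 − x)²."""

    def _ln_gamma(x_solute: float, composition=None, T: float = 298.15) -> float:
        return A * (1.0 - x_solute) ** 2

    return _ln_gamma


@dataclass(frozen=True)
class SLEResult:
    """Converged (or not) saturation mole fraction with the iteration history."""

    x_sat: float
    iterations: int
    converged: bool
    trajectory: tuple[float, ...] = field(default_factory=tuple)


def gibbs_fusion(fusion: FusionData, T: float) -> float:
    """ΔG_fus(T) = ΔH_fus·(1 − T/T_m) in kJ/mol; zero at T_m, negative above."""
    if T <= 0:
        raise DomainError("temperature must be positive")
    return fusion.H_fus * (1.0 - T / fusion.T_m)


def ideal_solubility(fusion: FusionData, T: float) -> float:
    """Ideal saturation mole fraction exp(−max(0, ΔG_fus)/(R·T)).

    The clamp makes the solid cease to limit solubility above the melting
    point (x = 1 for T ≥ T_m).
    """
    dg_j = max(0.0, gibbs_fusion(fusion, T)) * 1000.0
    return exp(-dg_j / (R_J_PER_MOL_K * T))


def solve_sle(
    model: ActivityModel,
    fusion: FusionData,
    composition: SolventComposition | None = None,
    T: float = 298.15,
    tol: float = 1e-8,
    max_iter: int = 200,
    damping: float = 1.0,
) -> SLEResult:
    """Solve ln(γ(x)·x) = −ΔG_fus/(R·T) by damped fixed-point iteration.

    Iterates ln x_{i+1} = −ln γ(x_i) − max(0, ΔG_fus)/(R·T) from the ideal
    solubility, with an optional damping factor on the ln-x update for
    oscillating activity models.  Convergence is |Δ ln x| < tol; failure to
    converge within ``max_iter`` is flagged, not raised.
    """
    if tol <= 0:
        raise DomainError("tol must be positive")
    if max_iter < 1:
        raise DomainError("max_iter must be >= 1")
    if not 0.0 < damping <= 1.0:
        raise DomainError("damping must lie in (0, 1]")
    dg_term = max(0.0, gibbs_fusion(fusion, T)) * 1000.0 / (R_J_PER_MOL_K * T)
    x = ideal_solubility(fusion, T)
    ln_x = log(x)
    trajectory = [x]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        ln_x_new = -model(x, composition, T) - dg_term
        ln_x_new = ln_x + damping * (ln_x_new - ln_x)
        ln_x_new = min(ln_x_new, 0.0)  # clip to x <= 1
        step = abs(ln_x_new - ln_x)
        ln_x = ln_x_new
        x = exp(ln_x)
        trajectory.append(x)
        if step < tol:
            converged = True
            break
    return SLEResult(
        x_sat=x, iterations=iterations, converged=converged, trajectory=tuple(trajectory)
    )
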