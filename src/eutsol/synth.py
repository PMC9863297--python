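"""Seeded generators emulating the statistical structure of the study's inputs.

Three generators cover the three data shapes the analysis consumes:

* descriptor tables with a planted sparse linear relation to log-solubility
  plus Gaussian noise (emulating the 72-measurement modelling dataset);
* smooth σ-potential/profile curves as Gaussian bumps on the standard
  61-point σ grid;
* van't Hoff-like temperature-dependent saturation tables with the layout of
  the measured-solubility fixture, with multiplicative noise matching the
  roughly proportional standard deviations of the measurements.

All generators are pure functions of their arguments and an explicit integer
seed (a fresh ``numpy.random.default_rng`` per call; no global state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from eutsol.data import SolubilityRecord, SolventComposition, concentration_from_mole_fraction
from eutsol.exceptions import DomainError, ValidationError
from eutsol.sigma import DescriptorTable, SigmaCurve, default_grid

__all__ = [
    "PlantedModelSpec",
    "gen_descriptor_dataset",
    "gen_sigma_curve",
    "gen_solubility_table",
    "fit_vant_hoff",
]


@dataclass(frozen=True)
class PlantedModelSpec:
    """Recipe for a descriptor table with a known sparse linear response.

    Defaults emulate the modelling dataset of the study: n=72 samples, a
    six-descriptor true model, and noise sd 0.03 in log10 units (the scale of
    the reported trimmed mean absolute errors).
    """

    n_samples: int = 72
    n_descriptors: int = 10
    true_subset: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    true_coefficients: tuple[float, ...] = (0.17, 0.53, -1.21, 0.80, 0.36, 0.14)
    intercept: float = -1.1
    noise_sd: float = 0.03
    correlated_pairs: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.true_subset) != len(self.true_coefficients):
            raise ValidationError("one coefficient per planted descriptor required")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if any(i >= self.n_descriptors or i < 0 for i in self.true_subset):
            raise ValidationError("true_subset index out of range")


def gen_descriptor_dataset(spec: PlantedModelSpec) -> DescriptorTable:
    """Standardized Gaussian descriptors with a planted linear response.

    Descriptors are i.i.d. N(0, 1); requested inter-correlations are imposed
    by Cholesky mixing of the full target correlation matrix (an infeasible,
    non-positive-definite request is an error).  The response is
    intercept + Σ coef·descriptor + N(0, noise_sd).
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_descriptors
    corr = np.eye(p)
    for i, j, rho in spec.correlated_pairs:
        if not -1.0 < rho < 1.0:
            raise DomainError(f"correlation {rho} outside (-1, 1)")
        corr[i, j] = corr[j, i] = rho
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise DomainError("requested correlation matrix is not positive-definite") from exc
    X = rng.standard_normal((spec.n_samples, p)) @ chol.T
    y = spec.intercept + np.zeros(spec.n_samples)
    for idx, coef in zip(spec.true_subset, spec.true_coefficients):
        y = y + coef * X[:, idx]
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
    names = [f"d{i + 1}" for i in range(p)]
    ids = [f"s{i + 1:03d}" for i in range(spec.n_samples)]
    frame = pd.DataFrame(X, index=ids, columns=names)
    response = pd.Series(y, index=ids, name="log_xE")
    return DescriptorTable(frame=frame, response=response)


def gen_sigma_curve(
    kind: str = "potential",
    peak_params: Sequence[tuple[float, float, float]] = (),
    seed: int | None = None,
    noise_sd: float = 0.0,
    label: str = "synthetic",
) -> SigmaCurve:
    """Sum of Gaussian bumps (center, width, height) on the 61-point σ grid.

    Optional Gaussian noise (seeded) roughens the curve; profile curves are
    clipped to be nonnegative.
    """
    grid = default_grid()
    values = np.zeros_like(grid)
    for center, width, height in peak_params:
        if width <= 0:
            raise DomainError("peak width must be positive")
        values += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=grid.size)
    if kind == "profile":
        values = np.clip(values, 0.0, None)
    return SigmaCurve(kind=kind, sigma_grid=grid, values=values, label=label)


def gen_solubility_table(
    systems: Sequence[SolventComposition],
    T_list: Sequence[float],
    vant_hoff_params: Sequence[tuple[float, float]],
    noise_cv: float = 0.0,
    seed: int | None = None,
    density: float = 1.10,
) -> list[SolubilityRecord]:
    """Van't Hoff-like saturation records x_E = exp(a − b/T)·(1 + ε).

    ``vant_hoff_params`` supplies (a, b) per system; ε is Gaussian with the
    given coefficient of variation (multiplicative noise, matching the
    roughly proportional measurement scatter).  Concentrations are derived
    from the mole fraction at a nominal solution density.
    """
    if len(systems) != len(vant_hoff_params):
        raise ValidationError("one (a, b) pair per system required")
    if any(T <= 0 for T in T_list):
        raise DomainError("temperatures must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for comp, (a, b) in zip(systems, vant_hoff_params):
        for T in T_list:
            x = float(np.exp(a - b / T))
            if x >= 1.0:
                raise DomainError(
                    f"van't Hoff parameters (a={a}, b={b}) give x>=1 at T={T}"
                )
            if noise_cv > 0:
                x = x * (1.0 + float(rng.normal(0.0, noise_cv)))
                x = float(np.clip(x, 1e-12, 1.0 - 1e-12))
            records.append(
                SolubilityRecord(
                    composition=comp,
                    temperature=float(T),
                    x_E=x,
                    c_E=concentration_from_mole_fraction(x, density, comp),
                )
            )
    return records


def fit_vant_hoff(records: Sequence[SolubilityRecord]) -> tuple[float, float]:
    """Least-squares (a, b) of ln x = a − b/T over a record series."""
    if len(records) < 2:
        raise DomainError("van't Hoff fit needs >= 2 points")
    invT = np.array([1.0 / r.temperature for r in records])
    lnx = np.array([np.log(r.x_E) for r in records])
    slope, intercept = np.polyfit(invT, lnx, 1)
    return float(intercept), float(-slope)
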