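"""Tautomer populations and association thermodynamics.

Edaravone exists as keto, enol and amine tautomers whose relative Gibbs
energies (from quantum-chemistry calculations, ingested here as numbers)
determine Boltzmann populations.  Raw electronic energies can carry separate
electron-correlation, zero-point and basis-set-superposition corrections that
are toggled per context (gas vs bulk phase).

Association equilibria X + Y → XY are described by the activity-based
constant K_a = K_x·K_γ; ΔG_r^(a) = −RT ln K_a is concentration-independent
while ΔG_r^(x) = −RT ln K_x carries the composition dependence through K_γ.
Energies are in kcal/mol throughout (R = 1.9872·10⁻³ kcal/(mol·K)).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from eutsol.exceptions import AlignmentError, DomainError, ParseError

__all__ = [
    "R_KCAL_PER_MOL_K",
    "KCAL_PER_KJ",
    "kcal_to_kj",
    "kj_to_kcal",
    "SpeciesEnergy",
    "ReactionThermo",
    "corrected_energy",
    "load_species_csv",
    "boltzmann_populations",
    "population_curve",
    "gibbs_from_K",
    "K_from_gibbs",
    "decompose_Ka",
    "rank_complexes",
]

R_KCAL_PER_MOL_K = 1.9872e-3
KCAL_PER_KJ = 1.0 / 4.184


def kcal_to_kj(value: float) -> float:
    return value * 4.184


def kj_to_kcal(value: float) -> float:
    return value * KCAL_PER_KJ


@dataclass(frozen=True)
class SpeciesEnergy:
    """A species' relative free energy (kcal/mol) with optional corrections."""

    label: str
    G_base: float
    dE_corr: float = 0.0
    dE_zpe: float = 0.0
    dE_bsse: float = 0.0


@dataclass(frozen=True)
class ReactionThermo:
    """ΔG of an X + Y → XY association, activity- and concentration-based."""

    reaction: str
    dG_a: float
    dG_x: float
    T: float = 298.15


def corrected_energy(
    species: SpeciesEnergy,
    include: Iterable[str] = ("corr", "zpe", "bsse"),
) -> float:
    """G_base plus the corrections named in ``include`` ('corr', 'zpe', 'bsse')."""
    include = set(include)
    unknown = include - {"corr", "zpe", "bsse"}
    if unknown:
        raise DomainError(f"unknown correction(s): {sorted(unknown)}")
    total = species.G_base
    if "corr" in include:
        total += species.dE_corr
    if "zpe" in include:
        total += species.dE_zpe
    if "bsse" in include:
        total += species.dE_bsse
    return total


def load_species_csv(path: str | Path) -> list[SpeciesEnergy]:
    """Read species energies from `label,G_base_kcal,dE_corr,dE_zpe,dE_bsse`."""
    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot read species CSV {path}: {exc}") from exc
    if "label" not in frame.columns or "G_base_kcal" not in frame.columns:
        raise ParseError(f"{path}: needs at least columns label,G_base_kcal")
    out = []
    for _, row in frame.iterrows():
        out.append(
            SpeciesEnergy(
                label=str(row["label"]),
                G_base=float(row["G_base_kcal"]),
                dE_corr=float(row.get("dE_corr", 0.0) or 0.0),
                dE_zpe=float(row.get("dE_zpe", 0.0) or 0.0),
                dE_bsse=float(row.get("dE_bsse", 0.0) or 0.0),
            )
        )
    return out


def boltzmann_populations(energies: Sequence[float], T: float = 298.15) -> np.ndarray:
    """Boltzmann fractions p_t ∝ exp(−G_t/RT), computed shift-invariantly."""
    if len(energies) == 0:
        raise DomainError("need at least one species")
    if T <= 0:
        raise DomainError("temperature must be positive")
    g = np.asarray(energies, dtype=float)
    w = np.exp(-(g - g.min()) / (R_KCAL_PER_MOL_K * T))
    return w / w.sum()


def population_curve(
    energies_by_composition: Mapping[float, Mapping[str, float]],
    T: float = 298.15,
) -> pd.DataFrame:
    """Tautomer populations vs solvent composition x*_DES.

    ``energies_by_composition`` maps x*_DES to {tautomer label: corrected
    energy kcal/mol}; every composition must list the same labels.  Returns a
    DataFrame indexed by x*_DES with one column per tautomer; rows sum to 1.
    """
    if not energies_by_composition:
        raise DomainError("need at least one composition")
    keys = sorted(energies_by_composition)
    labels = list(energies_by_composition[keys[0]])
    rows = []
    for k in keys:
        entry = energies_by_composition[k]
        if set(entry) != set(labels):
            raise AlignmentError(
                f"tautomer labels at x*_DES={k} differ from {sorted(labels)}"
            )
        rows.append(boltzmann_populations([entry[lab] for lab in labels], T=T))
    return pd.DataFrame(rows, index=pd.Index(keys, name="x_star_des"), columns=labels)


def interpolate_energies(
    energies_by_composition: Mapping[float, Mapping[str, float]], x_star: float
) -> dict[str, float]:
    """Linear interpolation of per-tautomer energies between composition grid points."""
    keys = np.array(sorted(energies_by_composition))
    if not keys[0] <= x_star <= keys[-1]:
        raise DomainError(f"x*_DES={x_star} outside the tabulated range")
    labels = list(energies_by_composition[keys[0]])
    return {
        lab: float(
            np.interp(x_star, keys, [energies_by_composition[k][lab] for k in keys])
        )
        for lab in labels
    }


def gibbs_from_K(K: float, T: float = 298.15) -> float:
    """ΔG = −RT ln K in kcal/mol."""
    if K <= 0:
        raise DomainError("equilibrium constant must be positive")
    if T <= 0:
        raise DomainError("temperature must be positive")
    return -R_KCAL_PER_MOL_K * T * log(K)


def K_from_gibbs(dG: float, T: float = 298.15) -> float:
    """Inverse of :func:`gibbs_from_K`: K = exp(−ΔG/RT)."""
    if T <= 0:
        raise DomainError("temperature must be positive")
    return exp(-dG / (R_KCAL_PER_MOL_K * T))


def decompose_Ka(
    Ka: float, Kgamma: float, T: float = 298.15
) -> tuple[float, float, float]:
    """Split K_a = K_x·K_γ into (K_x, ΔG_a, ΔG_x).

    Satisfies ΔG_a = ΔG_x − RT ln K_γ by construction.
    """
    if Ka <= 0 or Kgamma <= 0:
        raise DomainError("Ka and Kgamma must be positive")
    Kx = Ka / Kgamma
    return Kx, gibbs_from_K(Ka, T), gibbs_from_K(Kx, T)


def rank_complexes(
    reactions: Sequence[ReactionThermo], by: str = "dG_a"
) -> list[ReactionThermo]:
    """Order associations by stability (most negative ΔG first; stable sort)."""
    if by not in ("dG_a", "dG_x"):
        raise DomainError("ranking key must be 'dG_a' or 'dG_x'")
    if not reactions:
        return []
    temps = {r.T for r in reactions}
    if len(temps) > 1:
        raise DomainError(f"mixed temperatures in ranking: {sorted(temps)}")
    return sorted(reactions, key=lambda r: getattr(r, by))
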