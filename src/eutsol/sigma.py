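"""σ-profile / σ-potential containers and descriptor reduction.

COSMO-RS characterizes molecules and mixtures by the screening charge
density σ (e/Å²) over the molecular surface: the σ-profile p(σ) is the
surface-area histogram and the σ-potential μ_s(σ) the solvent's affinity for
surface of polarity σ, conventionally tabulated on a 61-point uniform grid
over [−0.03, +0.03].  This module ingests such curves (as numbers — the
quantum-chemistry layer that produces them is out of scope) and reduces them
to the scalar descriptors used in solubility regression:

* ``spot1..spot6`` — means of μ_s(σ) over six 0.01-wide σ bins;
* HBA / HBD / HYD — integrals over the hydrogen-bond-acceptor (σ < −0.01),
  donor (σ > +0.01) and non-polar (|σ| ≤ 0.01) regions;
* relative misfit / hydrogen-bond / van-der-Waals energy fractions;
* the "inverse relative" curve, a pointwise difference between the
  solute-free solvent potential and the neat solute potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from eutsol.exceptions import AlignmentError, DomainError, ParseError, ValidationError

__all__ = [
    "SIGMA_MIN",
    "SIGMA_MAX",
    "N_GRID",
    "default_grid",
    "SigmaCurve",
    "EnergyContributions",
    "DescriptorTable",
    "read_sigma_file",
    "write_sigma_file",
    "spot_reduce",
    "region_measures",
    "energy_fractions",
    "inverse_relative_curve",
    "pot2inv",
    "assemble_table",
]

SIGMA_MIN = -0.03
SIGMA_MAX = 0.03
N_GRID = 61

SPOT_NAMES = tuple(f"spot{k}" for k in range(1, 7))
REGION_NAMES = ("HBA", "HBD", "HYD")
FRACTION_NAMES = ("dE_misfit", "dE_hb", "dE_vdw")


def default_grid() -> np.ndarray:
    """The standard 61-point uniform σ grid on [−0.03, +0.03] (e/Å²)."""
    return np.linspace(SIGMA_MIN, SIGMA_MAX, N_GRID)


@dataclass(frozen=True)
class SigmaCurve:
    """A σ-grid function: profile p(σ) (area, Å²) or potential μ_s(σ) (kcal/mol)."""

    kind: str
    sigma_grid: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("profile", "potential"):
            raise ValidationError(f"kind must be 'profile' or 'potential', got {self.kind!r}")
        grid = np.asarray(self.sigma_grid, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if grid.ndim != 1 or grid.shape != vals.shape:
            raise ValidationError("grid and values must be 1-D arrays of equal length")
        if grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValidationError("sigma grid must be strictly increasing with >= 2 points")
        if self.kind == "profile" and np.any(vals < 0):
            raise ValidationError("profile values must be nonnegative")
        object.__setattr__(self, "sigma_grid", grid)
        object.__setattr__(self, "values", vals)

    def __sub__(self, other: "SigmaCurve") -> "SigmaCurve":
        _check_same_grid(self, other)
        return SigmaCurve(
            kind=self.kind,
            sigma_grid=self.sigma_grid,
            values=self.values - other.values,
            label=f"{self.label}-{other.label}",
        )


@dataclass(frozen=True)
class EnergyContributions:
    """COSMO-RS interaction-energy split of a system (kcal/mol)."""

    E_misfit: float
    E_hb: float
    E_vdw: float
    E_total: float | None = None


def _check_same_grid(a: SigmaCurve, b: SigmaCurve) -> None:
    if a.sigma_grid.shape != b.sigma_grid.shape or not np.allclose(
        a.sigma_grid, b.sigma_grid, rtol=0, atol=1e-12
    ):
        raise AlignmentError("σ grids differ")


def _check_covers_range(curve: SigmaCurve) -> None:
    g = curve.sigma_grid
    if g[0] > SIGMA_MIN + 1e-12 or g[-1] < SIGMA_MAX - 1e-12:
        raise DomainError(
            f"grid [{g[0]}, {g[-1]}] does not cover [{SIGMA_MIN}, {SIGMA_MAX}]"
        )


# ---------------------------------------------------------------------------
# file I/O


def read_sigma_file(path: str | Path) -> SigmaCurve:
    """Read a two-column whitespace ``sigma value`` file.

    A comment line ``# kind: potential|profile`` declares the curve kind
    (default: potential).  Other ``#`` lines (COSMOtherm-style metadata) are
    ignored.
    """
    kind = "potential"
    grid, vals = [], []
    path = Path(path)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("kind:"):
                kind = body.split(":", 1)[1].strip().lower()
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"{path} line {lineno}: expected two columns")
        try:
            grid.append(float(parts[0]))
            vals.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path} line {lineno}: non-numeric entry") from exc
    if not grid:
        raise ParseError(f"{path}: no data lines")
    return SigmaCurve(kind=kind, sigma_grid=np.array(grid), values=np.array(vals),
                      label=path.stem)


def write_sigma_file(curve: SigmaCurve, path: str | Path) -> None:
    lines = [f"# kind: {curve.kind}", f"# label: {curve.label}"]
    lines += [f"{s: .6e} {v: .8e}" for s, v in zip(curve.sigma_grid, curve.values)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# reductions


def spot_reduce(curve: SigmaCurve) -> np.ndarray:
    """Six bin-mean descriptors spot1..spot6 of a σ-potential.

    Bin k averages μ(σ) over grid points with σ in
    [−0.03 + 0.01(k−1), −0.03 + 0.01k); bins are half-open with the last one
    closed, so boundary points belong to the right bin.
    """
    _check_covers_range(curve)
    g, v = curve.sigma_grid, curve.values
    edges = SIGMA_MIN + 0.01 * np.arange(7)
    spots = np.empty(6)
    for k in range(6):
        if k < 5:
            mask = (g >= edges[k] - 1e-15) & (g < edges[k + 1] - 1e-15)
        else:
            mask = (g >= edges[k] - 1e-15) & (g <= edges[k + 1] + 1e-15)
        if not mask.any():
            raise DomainError(f"no grid points in spot bin {k + 1}")
        spots[k] = v[mask].mean()
    return spots


def region_measures(curve: SigmaCurve) -> tuple[float, float, float]:
    """Trapezoidal integrals over the HBA, HBD and HYD σ regions.

    HBA: σ ∈ [−0.03, −0.01] (affinity for hydrogen-bond donors),
    HBD: σ ∈ [+0.01, +0.03], HYD: σ ∈ [−0.01, +0.01].  For a profile the
    result is surface area; for a potential a potential-weighted measure.
    """
    _check_covers_range(curve)
    g, v = curve.sigma_grid, curve.values

    def _integral(lo: float, hi: float) -> float:
        mask = (g >= lo - 1e-15) & (g <= hi + 1e-15)
        return float(np.trapezoid(v[mask], g[mask]))

    return _integral(-0.03, -0.01), _integral(0.01, 0.03), _integral(-0.01, 0.01)


def energy_fractions(
    e: EnergyContributions, signed: bool = False
) -> tuple[float, float, float]:
    """Relative misfit/HB/vdW contributions ΔE_j = E_j / Σ_j E_j.

    By default magnitudes are used so the fractions form a composition
    summing to 1; ``signed=True`` keeps the raw signs (fractions then still
    sum to 1 but need not lie in [0, 1]).
    """
    parts = np.array([e.E_misfit, e.E_hb, e.E_vdw], dtype=float)
    if not signed:
        parts = np.abs(parts)
    total = parts.sum()
    if abs(total) < 1e-300 or np.all(np.abs(parts) == 0):
        raise DomainError("all energy contributions are zero")
    frac = parts / total
    return float(frac[0]), float(frac[1]), float(frac[2])


def inverse_relative_curve(
    solute: SigmaCurve, solvent: SigmaCurve, convention: str = "solvent_minus_solute"
) -> SigmaCurve:
    """Pointwise difference between solvent and solute σ-potentials.

    The default convention is μ_solvent(σ) − μ_solute(σ); the opposite sign is
    available as ``convention='solute_minus_solvent'``.
    """
    _check_same_grid(solute, solvent)
    if convention == "solvent_minus_solute":
        vals = solvent.values - solute.values
    elif convention == "solute_minus_solvent":
        vals = solute.values - solvent.values
    else:
        raise DomainError(f"unknown convention {convention!r}")
    return SigmaCurve(
        kind="potential", sigma_grid=solute.sigma_grid, values=vals,
        label="inverse-relative",
    )


def pot2inv(
    solute: SigmaCurve, solvent: SigmaCurve, convention: str = "solvent_minus_solute"
) -> float:
    """spot2 of the inverse-relative curve (the σ ∈ [−0.02, −0.01) bin mean)."""
    return float(spot_reduce(inverse_relative_curve(solute, solvent, convention))[1])


# ---------------------------------------------------------------------------
# descriptor tables


@dataclass
class DescriptorTable:
    """Samples × named molecular descriptors, with an optional response.

    Wraps a :class:`pandas.DataFrame` indexed by sample id; ``response``
    holds log10 saturation mole fraction per sample when available.
    """

    frame: pd.DataFrame
    response: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            dupes = self.frame.columns[self.frame.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate descriptor names: {dupes}")
        if self.response is not None:
            if not self.frame.index.equals(self.response.index):
                raise ValidationError("response index does not match the sample index")

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path: str | Path, response_column: str = "log_xE") -> "DescriptorTable":
        """Read `sample_id, [log_xE,] descriptor...` CSV."""
        frame = pd.read_csv(path, index_col="sample_id")
        response = None
        if response_column in frame.columns:
            response = frame.pop(response_column)
        return cls(frame=frame, response=response)

    def to_csv(self, path: str | Path, response_column: str = "log_xE") -> None:
        out = self.frame.copy()
        if self.response is not None:
            out.insert(0, response_column, self.response)
        out.index.name = "sample_id"
        out.to_csv(path)


def assemble_table(
    sources: Mapping[object, Mapping],
    response: Mapping[object, float] | None = None,
) -> DescriptorTable:
    """Build a :class:`DescriptorTable` from per-sample ingredients.

    Each sample maps to a dict with optional keys:

    * ``"scalars"`` — {name: value} of externally supplied descriptors
      (total/misfit energies, chemical potential, affinity terms, ...);
    * ``"potential"`` — a σ-potential :class:`SigmaCurve`, reduced to
      spot1..6 and HBA/HBD/HYD;
    * ``"energies"`` — :class:`EnergyContributions`, reduced to relative
      fractions.

    All samples must supply the same descriptor set; columns are ordered
    deterministically (scalars in first-seen order, then spots, regions,
    fractions).
    """
    if not sources:
        raise ValidationError("no samples supplied")
    rows: dict = {}
    ref_names: list[str] | None = None
    for sid, src in sources.items():
        row: dict[str, float] = {}
        for name, value in dict(src.get("scalars", {})).items():
            if name in row:
                raise ValidationError(f"duplicate descriptor name {name!r}")
            row[name] = float(value)
        curve = src.get("potential")
        if curve is not None:
            for name, value in zip(SPOT_NAMES, spot_reduce(curve)):
                row[name] = float(value)
            for name, value in zip(REGION_NAMES, region_measures(curve)):
                row[name] = float(value)
        energies = src.get("energies")
        if energies is not None:
            for name, value in zip(FRACTION_NAMES, energy_fractions(energies)):
                row[name] = float(value)
        if ref_names is None:
            ref_names = list(row)
        elif list(row) != ref_names:
            raise ValidationError(
                f"sample {sid!r} supplies descriptors {sorted(row)} != {sorted(ref_names)}"
            )
        rows[sid] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")[ref_names]
    resp = None
    if response is not None:
        missing = [sid for sid in rows if sid not in response]
        if missing:
            raise ValidationError(f"response missing for samples {missing}")
        resp = pd.Series({sid: float(response[sid]) for sid in rows}, name="log_xE")
        resp = resp.loc[frame.index]
    return DescriptorTable(frame=frame, response=resp)
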