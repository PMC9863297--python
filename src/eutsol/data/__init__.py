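"""Measured saturation solubility records and comparative analytics.

The central objects are :class:`SolventComposition` (a solute-free solvent,
e.g. "ethaline 1:2" or a DES–water mixture), :class:`SolubilityRecord` (one
measured saturation point) and :class:`CalibrationCurve` (the UV-Vis
absorbance-vs-concentration line used to quantify the dissolved drug).

The packaged fixture ``table1_solubility.csv`` transcribes the measured
saturation mole fractions (stored at the printed ×10⁴ scale to avoid
transcription rounding) and mass concentrations of edaravone in glyceline
(choline chloride : glycerol) and ethaline (choline chloride : ethylene
glycol) at 1:1, 1:2 and 1:4 molar ratios and four temperatures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from eutsol.exceptions import (
    AlignmentError,
    DomainError,
    FitError,
    ParseError,
    ValidationError,
)

__all__ = [
    "MOLAR_MASS",
    "EDARAVONE_MOLAR_MASS",
    "SolventComposition",
    "SolubilityRecord",
    "CalibrationCurve",
    "table1_fixture_path",
    "load_solubility_csv",
    "load_table1",
    "mole_fraction_from_concentration",
    "concentration_from_mole_fraction",
    "solubility_ratio",
    "percent_gain",
    "mean_ratio_over_temperatures",
    "dose_volume",
    "fit_calibration",
    "invert_calibration",
    "comparison_report",
    "write_report_json",
]

#: Molar masses (g/mol) of the solvent species appearing in the study.
MOLAR_MASS: dict[str, float] = {
    "water": 18.015,
    "choline chloride": 139.62,
    "ethylene glycol": 62.07,
    "glycerol": 92.09,
}

#: Molar mass of edaravone (5-methyl-2-phenyl-4H-pyrazol-3-one), g/mol.
EDARAVONE_MOLAR_MASS: float = 174.20

_CSV_COLUMNS = [
    "des",
    "polyol",
    "chcl_ratio",
    "polyol_ratio",
    "x_star_des",
    "temperature_K",
    "xE_1e4",
    "cE_mg_per_mL",
    "sd_xE_1e4",
    "sd_cE",
]


@dataclass(frozen=True)
class SolventComposition:
    """A solute-free solvent given as (species, mole fraction, molar mass g/mol).

    ``x_star_des`` is the mole fraction of the DES in the solute-free aqueous
    mixture (1.0 for a neat DES).  Two bookkeeping conventions are supported
    through the factory :meth:`from_ratio`: the *molecular* model counts
    choline chloride as one neutral species, while the *ion-pair* model counts
    one ChCl·polyol pair as a single species and only the excess polyol
    separately.
    """

    components: tuple[tuple[str, float, float], ...]
    des_label: str = ""
    x_star_des: float = 1.0

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError("composition needs at least one component")
        total = 0.0
        for name, x, m in self.components:
            if x < 0:
                raise ValidationError(f"negative mole fraction for {name!r}")
            if m <= 0:
                raise ValidationError(f"nonpositive molar mass for {name!r}")
            total += x
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"component mole fractions sum to {total}, not 1")
        if not 0.0 <= self.x_star_des <= 1.0:
            raise ValidationError("x_star_des must lie in [0, 1]")

    @property
    def mean_molar_mass(self) -> float:
        """Mole-fraction-weighted solvent molar mass M̄ (g/mol)."""
        return sum(x * m for _, x, m in self.components)

    @classmethod
    def from_ratio(
        cls,
        polyol: str,
        chcl_ratio: float = 1.0,
        polyol_ratio: float = 2.0,
        x_star_des: float = 1.0,
        ion_pair: bool = False,
        label: str = "",
    ) -> "SolventComposition":
        """Build a ChCl:polyol DES, optionally diluted with water.

        ``x_star_des`` dilutes the DES with water on a solute-free basis: the
        DES (with its internal ChCl:polyol proportions) contributes
        ``x_star_des`` and water ``1 − x_star_des`` of the solvent moles.
        With ``ion_pair=True`` each ChCl is paired with one polyol molecule
        into a single species and only the excess polyol counts separately.
        """
        if polyol not in MOLAR_MASS:
            raise ValidationError(f"unknown polyol {polyol!r}")
        if chcl_ratio <= 0 or polyol_ratio <= 0:
            raise ValidationError("molar ratios must be positive")
        m_chcl = MOLAR_MASS["choline chloride"]
        m_pol = MOLAR_MASS[polyol]
        if ion_pair:
            if polyol_ratio < chcl_ratio:
                raise ValidationError("ion-pair model needs polyol excess >= ChCl")
            pair = (f"ChCl-{polyol} pair", chcl_ratio, m_chcl + m_pol)
            excess = polyol_ratio - chcl_ratio
            parts = [pair] + ([(polyol, excess, m_pol)] if excess > 0 else [])
        else:
            parts = [("choline chloride", chcl_ratio, m_chcl), (polyol, polyol_ratio, m_pol)]
        des_moles = sum(n for _, n, _ in parts)
        comps = [(name, x_star_des * n / des_moles, m) for name, n, m in parts]
        if x_star_des < 1.0:
            comps.append(("water", 1.0 - x_star_des, MOLAR_MASS["water"]))
        if not label:
            label = f"{'ETA' if polyol == 'ethylene glycol' else 'GLE'} {chcl_ratio:g}:{polyol_ratio:g}"
        return cls(tuple(comps), des_label=label, x_star_des=x_star_des)


@dataclass(frozen=True)
class SolubilityRecord:
    """One measured saturation point: composition, T (K), x_E, c_E (mg/mL)."""

    composition: SolventComposition
    temperature: float
    x_E: float
    c_E: float
    sd_x: float | None = None
    sd_c: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.x_E < 1.0:
            raise ValidationError(f"x_E={self.x_E} outside (0, 1)")
        if self.c_E <= 0:
            raise ValidationError(f"c_E={self.c_E} must be positive")
        if not 273.0 < self.temperature < 400.0:
            raise ValidationError(f"temperature {self.temperature} K outside (273, 400)")


@dataclass(frozen=True)
class CalibrationCurve:
    """Absorbance = slope·c + intercept with LOD/LOQ in concentration units."""

    slope: float
    intercept: float
    r2: float
    lod: float | None = None
    loq: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError("calibration slope must be positive")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValidationError("r2 outside [0, 1]")
        if self.lod is not None and self.loq is not None and not self.lod < self.loq:
            raise ValidationError("LOD must be below LOQ")


def table1_fixture_path() -> Path:
    """Path of the packaged saturation-solubility fixture CSV."""
    return Path(resources.files("eutsol.data") / "table1_solubility.csv")


def load_solubility_csv(path: str | Path, ion_pair: bool = False) -> list[SolubilityRecord]:
    """Read saturation records from the documented CSV schema.

    Columns: ``des,polyol,chcl_ratio,polyol_ratio,x_star_des,temperature_K,
    xE_1e4,cE_mg_per_mL,sd_xE_1e4,sd_cE``.  Mole fractions are stored at the
    ×10⁴ scale (column name flags it) and de-scaled on load.
    """
    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot read solubility CSV {path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records: list[SolubilityRecord] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        try:
            comp = SolventComposition.from_ratio(
                polyol=str(row["polyol"]),
                chcl_ratio=float(row["chcl_ratio"]),
                polyol_ratio=float(row["polyol_ratio"]),
                x_star_des=float(row["x_star_des"]),
                ion_pair=ion_pair,
                label=f"{row['des']} {row['chcl_ratio']:g}:{row['polyol_ratio']:g}",
            )
            records.append(
                SolubilityRecord(
                    composition=comp,
                    temperature=float(row["temperature_K"]),
                    x_E=float(row["xE_1e4"]) / 1e4,
                    c_E=float(row["cE_mg_per_mL"]),
                    sd_x=float(row["sd_xE_1e4"]) / 1e4 if pd.notna(row["sd_xE_1e4"]) else None,
                    sd_c=float(row["sd_cE"]) if pd.notna(row["sd_cE"]) else None,
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise ValidationError(f"{path} line {line}: {exc}") from exc
            raise ParseError(f"{path} line {line}: malformed row ({exc})") from exc
    return records


def load_table1(ion_pair: bool = False) -> list[SolubilityRecord]:
    """Load the packaged measured-solubility fixture (24 records)."""
    return load_solubility_csv(table1_fixture_path(), ion_pair=ion_pair)


# ---------------------------------------------------------------------------
# unit conversions


def mole_fraction_from_concentration(
    c_E: float,
    density: float,
    composition: SolventComposition,
    solute_molar_mass: float = EDARAVONE_MOLAR_MASS,
) -> float:
    """Convert a mass concentration (mg/mL) to solute mole fraction.

    On a 1 mL basis: n_E = c_E/M_E and n_solv = (1000·ρ − c_E)/M̄, where M̄ is
    the mole-fraction-weighted molar mass of the solute-free solvent.
    """
    if c_E < 0 or density <= 0 or solute_molar_mass <= 0:
        raise DomainError("c_E must be >= 0, density and molar mass positive")
    if density * 1000.0 <= c_E:
        raise DomainError("solution mass per mL must exceed the solute mass")
    n_solute = c_E / solute_molar_mass
    n_solvent = (1000.0 * density - c_E) / composition.mean_molar_mass
    return n_solute / (n_solute + n_solvent)


def concentration_from_mole_fraction(
    x_E: float,
    density: float,
    composition: SolventComposition,
    solute_molar_mass: float = EDARAVONE_MOLAR_MASS,
) -> float:
    """Exact algebraic inverse of :func:`mole_fraction_from_concentration`."""
    if not 0.0 <= x_E < 1.0:
        raise DomainError(f"x_E={x_E} must lie in [0, 1)")
    if density <= 0 or solute_molar_mass <= 0:
        raise DomainError("density and molar mass must be positive")
    m_bar = composition.mean_molar_mass
    # c = 1000 rho * x ME / (x ME + (1-x) Mbar)
    return 1000.0 * density * x_E * solute_molar_mass / (
        x_E * solute_molar_mass + (1.0 - x_E) * m_bar
    )


# ---------------------------------------------------------------------------
# comparative analytics


def _as_x(value: SolubilityRecord | float) -> float:
    return value.x_E if isinstance(value, SolubilityRecord) else float(value)


def solubility_ratio(
    numerator: SolubilityRecord | float, denominator: SolubilityRecord | float
) -> float:
    """Ratio of two saturation mole fractions x_num / x_den."""
    x_num, x_den = _as_x(numerator), _as_x(denominator)
    if x_num <= 0 or x_den <= 0:
        raise DomainError("solubility ratio needs positive mole fractions")
    return x_num / x_den


def percent_gain(a: SolubilityRecord | float, b: SolubilityRecord | float) -> float:
    """Relative solubility gain of ``a`` over ``b`` in percent: (x_a/x_b − 1)·100."""
    return (solubility_ratio(a, b) - 1.0) * 100.0


def mean_ratio_over_temperatures(
    series_a: Sequence[SolubilityRecord],
    series_b: Sequence[SolubilityRecord],
    atol: float = 1e-6,
) -> float:
    """Arithmetic mean of per-temperature solubility ratios x_a(T)/x_b(T)."""
    if len(series_a) != len(series_b) or not series_a:
        raise AlignmentError("series must be nonempty and of equal length")
    a = sorted(series_a, key=lambda r: r.temperature)
    b = sorted(series_b, key=lambda r: r.temperature)
    ratios = []
    for ra, rb in zip(a, b):
        if abs(ra.temperature - rb.temperature) > atol:
            raise AlignmentError(
                f"temperature mismatch: {ra.temperature} K vs {rb.temperature} K"
            )
        ratios.append(solubility_ratio(ra, rb))
    return sum(ratios) / len(ratios)


def dose_volume(dose_mg: float, c_E: float) -> float:
    """Solvent volume (mL) of a saturated solution holding ``dose_mg`` of drug."""
    if c_E <= 0:
        raise DomainError("concentration must be positive")
    if dose_mg < 0:
        raise DomainError("dose must be nonnegative")
    return dose_mg / c_E


# ---------------------------------------------------------------------------
# spectrophotometric calibration


def fit_calibration(
    concentrations: Sequence[float],
    absorbances: Sequence[float],
    sigma_blank: float | None = None,
    k_lod: float = 3.3,
    k_loq: float = 10.0,
) -> CalibrationCurve:
    """Ordinary least-squares calibration line with optional LOD/LOQ.

    LOD = k_lod·σ_blank/slope and LOQ = k_loq·σ_blank/slope; the multipliers
    default to the ICH convention (3.3 and 10) and are configurable.
    """
    if len(concentrations) != len(absorbances) or len(concentrations) < 3:
        raise FitError("calibration needs >= 3 paired points")
    if len(set(concentrations)) < 2:
        raise FitError("calibration concentrations are degenerate (zero variance)")
    res = stats.linregress(concentrations, absorbances)
    if res.slope <= 0:
        raise FitError("calibration slope is nonpositive")
    lod = loq = None
    if sigma_blank is not None:
        if sigma_blank <= 0:
            raise DomainError("sigma_blank must be positive")
        lod = k_lod * sigma_blank / res.slope
        loq = k_loq * sigma_blank / res.slope
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        lod=lod,
        loq=loq,
    )


def invert_calibration(curve: CalibrationCurve, absorbance: float) -> float:
    """Concentration (mg/mL) from a measured absorbance: (A − intercept)/slope."""
    return (absorbance - curve.intercept) / curve.slope


# ---------------------------------------------------------------------------
# report


def _pick(
    records: Iterable[SolubilityRecord], des: str, ratio: str, T: float
) -> SolubilityRecord:
    for r in records:
        if r.composition.des_label == f"{des} {ratio}" and abs(r.temperature - T) < 1e-6:
            return r
    raise AlignmentError(f"no record for {des} {ratio} at {T} K")


def comparison_report(
    records: Sequence[SolubilityRecord],
    reference_x: float | None = None,
    reference_label: str = "reference solvent",
    dose_mg: float = 60.0,
) -> dict:
    """Comparative analytics over a neat-DES solubility table.

    Produces, per DES: the best molar ratio at each temperature, the
    1:2-vs-1:1 percent gains, and dose volumes at the optimal composition;
    across DES: the mean ETA/GLE efficiency; and, when ``reference_x`` is
    given, ratios of each optimal composition to that reference solubility.
    """
    temps = sorted({r.temperature for r in records})
    des_labels = sorted({r.composition.des_label.split()[0] for r in records})
    report: dict = {"temperatures_K": temps, "per_des": {}}
    for des in des_labels:
        sub = [r for r in records if r.composition.des_label.startswith(des + " ")]
        best = {
            T: max((r for r in sub if r.temperature == T), key=lambda r: r.x_E) for T in temps
        }
        entry: dict = {
            "best_ratio_by_T": {
                T: best[T].composition.des_label.split(" ", 1)[1] for T in temps
            },
            "gain_1to2_vs_1to1_percent": {
                T: percent_gain(_pick(sub, des, "1:2", T), _pick(sub, des, "1:1", T))
                for T in temps
            },
            "dose_volume_mL_at_best": {
                T: dose_volume(dose_mg, best[T].c_E) for T in temps
            },
        }
        if reference_x is not None:
            entry[f"ratio_to_{reference_label}_at_{temps[0]:g}K"] = solubility_ratio(
                best[temps[0]].x_E, reference_x
            )
        report["per_des"][des] = entry
    if {"ETA", "GLE"} <= set(des_labels):
        eta = [r for r in records if r.composition.des_label == "ETA 1:2"]
        gle = [r for r in records if r.composition.des_label == "GLE 1:2"]
        report["mean_ETA_over_GLE_1to2"] = mean_ratio_over_temperatures(eta, gle)
    return report


def write_report_json(report: dict, path: str | Path) -> None:
    """Serialize a comparison report to JSON (string keys, 2-space indent)."""

    def _keys(obj):
        if isinstance(obj, dict):
            return {str(k): _keys(v) for k, v in obj.items()}
        return obj

    Path(path).write_text(json.dumps(_keys(report), indent=2) + "\n")
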