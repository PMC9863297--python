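# eutsol

Solubility analytics and QSPR modelling for poorly water-soluble drugs in
choline-chloride deep eutectic solvents (DES), built around the case of
edaravone — a BCS class IV neuroprotective agent — in ethaline
(choline chloride : ethylene glycol, "ETA"), glyceline
(choline chloride : glycerol, "GLE") and their aqueous mixtures.

The package is aimed at solubility/preformulation scientists who measure
saturation data in designed solvents and want to (i) run the comparative
arithmetic rigorously, (ii) place the measurements on a thermodynamic
footing, and (iii) build and validate small-dataset regression models from
COSMO-RS-style molecular descriptors. Quantum chemistry itself is out of
scope: σ-potentials, interaction energies and association free energies are
*ingested* as numbers, never computed here.

## What is implemented

**Data analytics** (`eutsol.data`) — saturation records
(composition, T, x_E, c_E), mole-fraction ↔ mg/mL conversion via solution
density, solubility ratios and percent gains, dose volumes, and the UV-Vis
calibration line with configurable LOD/LOQ multipliers. A packaged CSV
transcribes the measured table (2 DES × 3 ChCl:polyol ratios × 4
temperatures, 24 records).

**Solid–liquid equilibrium** (`eutsol.sle`) — the saturation condition
ln(γ·x_sat) = −ΔG_fus/(R·T) with ΔG_fus = ΔH_fus(1 − T/T_m)
(Schröder–van Laar, ΔC_p neglected), solved by damped fixed-point iteration
on ln x with a pluggable activity model; for edaravone T_m = 403.15 K,
ΔH_fus = 29.91 kJ/mol.

**Tautomers & associations** (`eutsol.tautomers`) — Boltzmann populations
p_t ∝ exp(−G_t/RT) of keto/enol/amine forms with toggleable
correlation/ZPE/BSSE corrections, and association bookkeeping
ΔG_r^(a) = −RT ln K_a with K_a = K_x·K_γ.

**σ-descriptors** (`eutsol.sigma`) — σ-profile/σ-potential containers on the
standard 61-point grid over σ ∈ [−0.03, +0.03] e/Å², reduced to the spot1–6
bin means, HBA/HBD/HYD region integrals, relative misfit/HB/vdW energy
fractions, and the inverse-relative-curve descriptor `pot2inv`.

**QSPR workflow** (`eutsol.qspr`) — standardization, pairwise R² > 0.5
correlation filtering, deterministic Kennard–Stone 80/20 splitting,
exhaustive best-subset OLS ranked by MAE95(test), validation metrics
(R²_adj, Q²_LOO, Q²_F1, Q²_F2, MAE95) and a Williams-type applicability
domain with h* = 3(k−1)/N. The published six-descriptor model

    log10(x_E) = 0.1722·EEtot + 0.5324·EEmisfit − 1.2071·μE
               + 0.7958·pot2inv + 0.3588·HBA + 0.1363·GrAB3 − 1.1069

(on standardized descriptors) ships as `published_edaravone_model()`.

**Synthetic data** (`eutsol.synth`) — seeded generators for descriptor
tables with planted sparse linear models, Gaussian-bump σ-curves, and
van't Hoff solubility tables with multiplicative noise.

## Worked example

```python
from eutsol import data, sle, qspr

records = data.load_table1()                      # 24 saturation records
gle = [r for r in records
       if r.composition.des_label == "GLE 1:2" and r.temperature == 298.15][0]
print(round(data.solubility_ratio(gle, 0.0688), 2))   # 1.53  vs dichloromethane
print(round(data.dose_volume(60.0, 302.96), 2))       # 0.2   mL of neat ETA per daily dose

print(round(sle.ideal_solubility(sle.EDARAVONE_FUSION, 298.15), 4))  # 0.0432

model = qspr.published_edaravone_model()
print(qspr.predict(model, {n: 0.0 for n in model.descriptor_names}))  # -1.1069
```

The first two numbers say that saturated glyceline 1:2 dissolves 1.53× more
edaravone (mole-fraction basis) than the best conventional solvent, and
that the 60 mg daily dose fits in 0.20 mL of saturated neat ethaline. The
ideal SLE solubility (0.0432) sits well below every measured value
(0.079–0.36 across the table), quantifying how strongly favourable the
drug–DES interactions are. The model prediction at the all-zero
standardized descriptor vector returns the intercept, i.e. the dataset-mean
log10 solubility.

The numbered scripts under `analysis/` run the full narrative —
comparative analytics, SLE curves, tautomer populations, descriptor
reduction and the planted-model recovery benchmark — and write their tables
to `results/`:

```bash
python analysis/01_solubility_comparisons.py
...
python analysis/05_qspr_recovery.py
```

## Layout

```
src/eutsol/        library (data, sle, tautomers, sigma, qspr, synth, cli)
analysis/          numbered narrative drivers writing to results/
tests/             pytest suite (unit, property and end-to-end)
scripts/           acceptance.py
docs/methods.md    models, assumptions, parameter choices, limitations
```

A thin CLI is also installed: `eutsol data ratios`, `eutsol data dose`,
`eutsol sle`, `eutsol tautomers`, `eutsol descriptors spots`,
`eutsol qspr fit/predict`, `eutsol synth descriptors`.
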