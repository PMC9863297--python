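# Methods

This note documents the models, conventions and numerical choices behind
`eutsol`, in the package's own words. It states no empirical result that the
tests and `scripts/acceptance.py` do not themselves compute.

## Solubility bookkeeping

A solvent is a list of (species, mole fraction, molar mass) on a solute-free
basis. Choline chloride is counted as **one neutral species** by default (the
"molecular" model); an `ion_pair=True` flag switches to counting one
ChCl·polyol pair as a single species with only the excess polyol separate,
because both conventions are in use for DES and they give different mean
molar masses and hence different mole fractions. Aqueous mixtures are
parameterized by x\*_DES, the DES mole fraction in the solute-free solvent.

Concentration ↔ mole-fraction conversion works on a 1 mL basis:
n_E = c_E/M_E, n_solv = (1000·ρ − c_E)/M̄ with M̄ the mole-fraction-weighted
solvent molar mass; the inverse is solved algebraically so the round trip is
exact to machine precision. Molar masses: edaravone 174.20, choline chloride
139.62, ethylene glycol 62.07, glycerol 92.09, water 18.015 g/mol.

The packaged measured table stores x_E at the printed ×10⁴ scale (column
`xE_1e4`) to avoid transcription rounding; ratios and gains are reported
unrounded and any presentation rounding is left to the caller, because the
source material mixes rounding and truncation (e.g. a dose volume of
60/191.06 = 0.314 mL appears in print as 0.32 mL — the package reports the
computed value).

Calibration LOD/LOQ use LOD = k_LOD·σ_blank/slope with k_LOD = 3.3 and
k_LOQ = 10 (ICH convention) by default. The multipliers are configurable
because published LOD/LOQ pairs in this field are often computed with
other factors (the pair quoted for the edaravone assay has ratio 3.0).

## Solid–liquid equilibrium

Saturation of a crystalline solute satisfies ln(γ·x_sat) = −ΔG_fus/(R·T).
The temperature dependence of ΔG_fus is not measurable from (T_m, ΔH_fus)
alone; the package adopts the Schröder–van Laar form
ΔG_fus(T) = ΔH_fus·(1 − T/T_m), i.e. ΔC_p = 0, and isolates it behind
`gibbs_fusion` so a ΔC_p-corrected form can be swapped in. A
max(0, ΔG_fus) clamp makes the solid cease to limit solubility above T_m
(x_sat → 1).

The solver iterates ln x_{i+1} = −ln γ(x_i) − max(0, ΔG_fus)/(R·T) from the
ideal solubility, with convergence metric |Δ ln x| < tol (default 1e-8,
max_iter 200) and an optional damping factor in (0, 1] for oscillating
activity models. For the one-parameter Margules family ln γ = A(1−x)² the
iteration map has contraction factor |2A·x(1−x)| ≤ |A|/2, so it converges
for |A| < 2; property tests therefore randomize A over [−1.5, 1.5] and
check the fixed point against an independent bisection oracle. COSMO-RS is
*not* reimplemented: all solvent dependence enters through the ln γ
contract. R = 8.314 J/(mol·K).

## Tautomers and associations

Populations are Boltzmann fractions of per-species free energies in
kcal/mol (R = 1.9872·10⁻³ kcal/(mol·K)), computed shift-invariantly by
subtracting the minimum energy before exponentiating. Which corrections
(electron correlation, ZPE, BSSE) enter a species' energy is a per-call
configuration because different combinations are appropriate in gas vs bulk
contexts. Composition-dependent energies are supplied as tables keyed by
x\*_DES and interpolated linearly; no published interpolation rule exists
for such curves, so the simplest one is used and named.

Association thermodynamics follow K_a = K_x·K_γ with
ΔG_r^(a) = −RT ln K_a and ΔG_r^(x) = −RT ln K_x, so
ΔG_a = ΔG_x − RT ln K_γ holds identically. Ranking of complexes is a stable
sort on ΔG (most negative first), preserving input order on ties.

## σ-curves and descriptors

Curves live on a strictly increasing σ grid; the standard grid is 61
uniform points on [−0.03, +0.03] e/Å² (the package standardizes on e/Å²,
the usual surface-charge-density unit). spot1..spot6 are bin means over six
0.01-wide bins; bins are half-open on the right with the last bin closed,
so grid points exactly on a 0.01 boundary belong to the right bin. Region
measures HBA (σ ∈ [−0.03, −0.01]), HBD ([+0.01, +0.03]) and HYD
([−0.01, +0.01]) are trapezoidal integrals over the grid points inside each
closed interval; adjacent regions share their boundary point, which
contributes half a trapezoid cell to each side.

Relative energy fractions ΔE_j = |E_j| / Σ|E_j| over j ∈ {misfit, HB, vdW}
use magnitudes by default so the three fractions form a composition summing
to 1 (interaction energies are typically all negative); a signed variant is
available behind a flag.

The inverse-relative curve is defined here as μ_solvent(σ) − μ_solute(σ)
(convention explicit and swappable, since the graphical source it emulates
does not pin the arithmetic down), and `pot2inv` is spot2 of that curve.
Descriptor tables are schema-driven — any mix of externally supplied
scalars, curve reductions and energy fractions — because the full candidate
descriptor list of the original analysis was never enumerated.

## QSPR workflow

* **Standardization** uses the sample (n−1) standard deviation; parameters
  are stored in the fitted model for prediction-time reuse.
* **Correlation filter** (pairwise R² > 0.5): iteratively drop the
  descriptor with the most above-threshold partners, ties broken by larger
  mean |r|, then by column order — a deterministic realization of "omit
  interrelated parameters".
* **Kennard–Stone split** (80/20 by default): maximal-distance pair first,
  then max-min additions, Euclidean metric in standardized space, ties to
  the lowest row index. The split is a pure function of row order.
* **Fitting** is OLS with intercept via `numpy.linalg.lstsq`; rank
  deficiency raises. Coefficient standard errors come from
  σ²(XᵀX)⁻¹ with σ² the residual mean square.
* **MAE95** is the trimmed mean absolute error discarding the
  ceil(0.05·n) largest absolute residuals (the ceiling rule of the
  small-dataset QSAR toolkits this metric comes from); the n = 1 case
  trims everything and is defined as 0 with a warning.
* **Q²_LOO** uses the hat-matrix PRESS identity e_i/(1 − h_ii), which is
  algebraically exact for OLS; tests verify equality with an explicit
  n-refit oracle to 1e-10.
* **Q²_F1 / Q²_F2** normalize the test-set residual sum by deviations from
  the training / test response mean respectively, so Q²_F2 ≤ Q²_F1 always.
* **Exhaustive search** enumerates all k-subsets (guarded by a combination
  cap), scores by MAE95(test), and breaks ties by descriptor-name tuple so
  the ranking is independent of evaluation and column order.
* **Applicability domain**: leverage h_i = x_iᵀ(XᵀX)⁻¹x_i with intercept
  column; the cutoff defaults to h* = 3(k−1)/N — the convention printed in
  the source analysis — with the textbook 3(k+1)/N selectable
  (`h_star_convention="standard"`). Outliers are |standardized residual| > 3,
  with the residual sd taken from the training fit (dof n−k−1).
* The response is log10 mole-fraction solubility throughout.

The published six-descriptor model is stored with its printed coefficients
and standard errors and `standardization=None` ("external"): its
standardization parameters belonged to the original 72-point descriptor
table, which was never published, so the model can only be evaluated on
already-standardized inputs. Its final term is stored as +0.1363·GrAB3 with
intercept −1.1069: under standardized descriptors the intercept equals the
mean response, and the measured solubilities (x ≈ 0.08–0.36) give mean
log10 x ≈ −1.1, fixing the sign split of the ambiguously typeset constant.

## Synthetic data

The generators define the study conditions for every statistical test:

* **Descriptor tables**: n = 72 samples (the size of the original modelling
  dataset), i.i.d. standard-normal descriptors with optional target
  correlations imposed by Cholesky mixing, a planted 6-descriptor linear
  model with coefficients of the magnitude pattern of the published
  equation, and Gaussian response noise of sd 0.03 in log10 units — the
  scale of the reported trimmed MAEs. The candidate pool is 10 descriptors,
  chosen as the package's benchmark size so that the exhaustive C(10,6) = 210
  enumeration over 100 replicates completes in well under two minutes on one
  CPU while still forcing the search to reject 204 wrong subsets per
  replicate.
* **σ-curves**: sums of Gaussian bumps on the 61-point grid, optionally
  roughened with seeded noise; profiles are clipped nonnegative.
* **Solubility tables**: van't Hoff form x = exp(a − b/T) with
  multiplicative Gaussian noise (coefficient of variation), matching the
  roughly proportional scatter of the measurements; concentrations are
  derived from the mole fraction at a nominal density of 1.10 g/mL.

All generators take an explicit integer seed and use a private
`numpy.random.default_rng`; there is no global random state.

What the generators deliberately do **not** emulate: real descriptor
distributions are neither Gaussian nor independent (they derive from shared
physics and are strongly temperature-structured), real noise is not exactly
multiplicative, and real candidate pools are larger (≈54) and heavily
inter-correlated before filtering. Passing the recovery benchmark therefore
demonstrates that the *workflow* is correct and well-posed at the study's
signal-to-noise ratio, not that any particular measured dataset will yield
a six-descriptor model of the published quality.

## Known limitations

* The headline validation statistics of the original analysis
  (R²_adj = 0.9987 etc.) are not reproducible anywhere, because the
  underlying 72-point descriptor table was never published; the package
  replaces them with property-level guarantees and planted-data recovery.
* ΔC_p of fusion is neglected; below-ambient extrapolation of SLE
  solubility inherits that bias.
* The ideal-solubility reference uses a single (T_m, ΔH_fus) pair; melting
  data for this drug scatter over ~3 K in the literature.
* The exhaustive search is exact but combinatorial; beyond the cap
  (default 5·10⁵ subsets) the user must filter descriptors first — there is
  deliberately no stochastic fallback, since reproducibility of the ranking
  is the point.
* `population_curve` assumes the same tautomer label set at every
  composition and linear interpolation between grid points.
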