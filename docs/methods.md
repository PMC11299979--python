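# Methods

This note records the models implemented in `tagfold`, the defaults they
ship with, the choices made where the underlying methodology admits more
than one convention, and what the synthetic-data tests do and do not
demonstrate about real data.

## Two-state equilibrium unfolding

Chemical denaturation is modelled with the linear extrapolation model:
ΔG([D]) = ΔG₀ − m[D], with the unfolded population
f_u = 1/(1 + exp(ΔG/RT)). The fit is Levenberg–Marquardt (lmfit) started
from several endpoint-derived guesses for the m-value and a signal-midpoint
guess for Cm; the lowest-RSS solution is kept (parameter tolerance 1e-10).
Curves flagged `normalized` are fitted with the bare two-parameter model
(ΔG₀, m); raw optical signals co-fit linear folded/unfolded baselines
(af + bf·[D], au + bu·[D]). The identity Cm = ΔG₀/m is exact by
construction (Cm is a derived property, never a free parameter).

* R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹; default temperature 298 K (experiments
  at 25 °C), configurable per fit.
* ΔΔG between constructs requires equal fit temperatures and propagates
  errors in quadrature.
* Thermal melts use an empirical four-parameter logistic
  (baselines, T_m, width). No van't Hoff enthalpy is extracted: the data
  these fits serve report a sigmoidal CD transition, not a calorimetric
  model, so T_m and an apparent width are the only defensible outputs.
* Parameter errors come from the fit covariance. For stable constructs
  whose Cm approaches the top of the denaturant axis (e.g. ΔG₀ ≈ 11–12
  kcal/mol with m ≈ 2 on a 0–6 M axis) single noisy curves carry leverage
  error of several tenths of a kcal/mol; recovery criteria are therefore
  defined on means over ≥10 replicate curves.

## Native-state proteolysis

Under the opening-limited (EX2-like) regime, k_obs = K_op·(k_cat/K_M)·[P].
Stages: (1) per-concentration first-order fit I(t) = A·e^(−k_obs·t) with A
bounded in [0.8, 1.2] around the no-protease control to stabilize sparse
time courses; (2) linear regression of k_obs on molar protease
concentration with a free intercept (background proteolysis) — only the
slope enters the energetics; (3)
ΔG_proteolysis = −RT ln(slope / 99,000 M⁻¹s⁻¹), referencing thermolysin's
specificity constant for fully unfolded chains. Concentrations supplied in
mg/mL are converted with a configurable molecular weight (thermolysin
default 34,600 g/mol). A rising time course raises an error rather than
returning a negative rate.

## Amide temperature coefficients

Per-residue ordinary least squares of the amide ¹H shift (ppm) on
temperature (K), slope reported in ppb/K together with the residual sum
of squares; residues with fewer than three observed temperatures are
skipped with a warning. Shifts are assumed pre-referenced (water/DSS
calibration happens upstream). Disorder-prone amides are flagged below the
(mean − SD) line, with a guard requiring the mean coefficient to be
negative — a positive mean indicates a sign-flipped input table.

Because low-identity homologues cannot be matched residue-by-residue,
cross-protein comparison is segment-wise: coefficients are averaged over a
named secondary-structure map and ΔTc_avg = mean(ref) − mean(query) is
reported per segment. The bundled default map is the canonical β-grasp
assignment on ubiquitin numbering (β1 2–7, β2 11–17, α1 23–34, β3 40–45,
β4 48–50, α2-loop 51–63, β5 66–71); it is a package default, not a
published table, and should be overridden per protein. Segment errors are
SEMs; comparison errors are quadrature sums; the highlight threshold is a
single line at (mean over segments of ΔTc_avg) + (mean error), which makes
the comparison antisymmetric under swapping the two proteins up to the
flag set.

## Model-free relaxation analysis

¹⁵N relaxation is interpreted with the Lipari–Szabo spectral density
J(ω) = (2/5)[S²τ_m/(1+(ωτ_m)²) + (1−S²)τ′/(1+(ωτ′)²)], 1/τ′ = 1/τ_m + 1/τ_e,
inside the standard dipolar + CSA expressions for R1, R2 and the
steady-state NOE, with R_ex added to R2. Fixed physical constants:
r(N–H) = 1.02 Å, Δσ(¹⁵N) = −160 ppm, isotropic tumbling, signed
gyromagnetic ratios (so NOE < 1 and can go negative for flexible
residues).

* τ_m is estimated by inverting the trimmed mean R2/R1 ratio of rigid
  residues (NOE > 0.65, with a 1.5×MAD filter on the ratio to exclude
  exchange-broadened outliers), then refined by minimizing the summed χ²
  of exchange-free (S², τ_e) fits of those residues over a bounded
  interval. Refining with exchange-free models is deliberate: allowing
  R_ex during τ_m refinement lets exchange absorb tumbling errors.
* Per residue, models M1 {S²}, M2 {S², τ_e}, M3 {S², R_ex},
  M4 {S², τ_e, R_ex} are fitted by bounded least squares (τ_e carried in
  ps internally so all parameters are O(1)–O(100); multi-start on τ_e).
  Selection is by AIC (χ² + 2k). The small-sample AICc correction is
  degenerate at a single field — three observables per residue leave
  n − k − 1 ≤ 0 for k ≥ 2 — so the plain AIC penalty is used; with
  multi-field data AICc would be preferable.
* Parameter errors come from the pseudo-inverse of JᵀJ at the optimum.

The hetNOE is I_sat/I_ref with the relative-error quadrature formula
(err/NOE)² = (err_ref/I_ref)² + (err_sat/I_sat)².

### Entropy meter

Order parameters map to backbone conformational entropy through a linear
"entropy meter" S_conf = s·(1−S²) + s₀, default
s = 0.0109 kcal mol⁻¹ K⁻¹ per unit (1−S²) — obtained by linearizing the
diffusion-in-a-cone closed form S_conf = R ln(π(3−√(1+8√S²))) around
S² ≈ 0.8 (the cone map itself is available as an alternative; it diverges
at S² = 1 and is clamped just below). Absolute entropies are not
meaningful on this scale; the package only ever reports differences
(−TΔS per segment), so the additive constant cancels and the slope sets
the overall scale. Published absolute −TΔS values for this system are
therefore reproducible in pattern but not in magnitude, which is a
property of the calibration literature, not of the fit.

## Trajectory plasticity metrics

* Native contacts: minimum heavy-atom distance between residues ≤ 7 Å in
  the reference, |i−j| ≥ 4 within a chain; cross-chain pairs are classed
  tag–substrate. α is the per-frame retained fraction.
* β-sheet hydrogen bonds: backbone N···O ≤ 3.5 Å, no angle term; η is
  counted per strand pair over the bonds present in the reference.
* Superposition: least-squares rotation (Kabsch, via
  `scipy.spatial.transform.Rotation.align_vectors`) on Cα, unweighted.
  RMSF is about the mean structure; RMSD is against the reference.
* Radii of gyration: mass-weighted; Rgyr excludes a user-supplied loop
  mask, Rog covers all atoms. No ordering between the two is asserted —
  they are different selections.
* Free-energy landscapes: 50×50 (default) 2D histogram of (RMSD, Rgyr),
  ΔG_i = −k_B T ln(N_i/N_0); the most populated bin is exactly 0 and
  empty bins are NaN-masked rather than zero.
* PCA: eigendecomposition of the Cα coordinate covariance of superposed
  frames; variances non-increasing and summing to the total positional
  variance; PC1 extreme-structure interpolation is exportable.
* Contact disruption: per-substrate-residue mean long-range native
  contact count, free minus conjugated, clipped at zero and max-normalized;
  tag occupancy is the fraction of frames with any tag atom within the
  cutoff, max-normalized.

## Synthetic data: what it emulates, and what it does not

The generators are the exact inverse problems of the fitters: two-state
populations mixed with linear baselines plus additive Gaussian noise on
normalized signals (σ defaults: 0.02 for melts, 0.03 for gel intensities);
first-order decays driven by K_op with a unit no-protease control; linear
shift drifts with a 283 K reference temperature; relaxation rates from
the forward model with relative Gaussian noise (reported errors
max(noise_frac, 0.5%) of each rate); and an idealized two-strand hairpin
toy (N/CA/O pseudo-atoms per residue, one inter-strand hydrogen bond per
column, ~24 native contacts at 20 residues) with rigid per-residue
Gaussian fluctuations and a contact-breaking schedule executed by
displacing strand-B residues in a fixed seeded order. Noise magnitudes are
package choices — instrument-level noise is not published for these
measurements.

Seeding: one seed per spec, with per-series child streams (SeedSequence
spawning), so enlarging a dataset never reshuffles earlier draws.

Consequences for interpretation: passing recovery tests shows the
estimators are unbiased and correctly scaled under the stated noise model.
It does not validate against baseline curvature, correlated noise,
anisotropic tumbling, non-two-state intermediates, or force-field realism
— the toy trajectory tests metric correctness (against brute-force
oracles), not dynamics. The scheduled contact loss has residue-level
granularity (one displaced residue breaks its 2–3 contacts at once), so a
schedule value is honored to within ~1/8 of the contact count on the
20-residue toy.

## Problem sizes

Recovery runs use 25-point chemical melts (0–6 M, 0.25 M steps), 76-point
thermal melts (20–95 °C, 1 °C), 4 protease concentrations × 8 time points,
8–10 residue relaxation sets, and 16–20 residue toy trajectories with
tens of frames — sizes representative of the corresponding bench
experiments, where a CD melt has dozens of points and a gel time course
has a handful of lanes.

## Known limitations

* Two-state only: no three-state or domain-coupled unfolding models, no
  global multi-wavelength fits.
* No EX1/EX2 discrimination in proteolysis; the opening-limited regime is
  assumed.
* Single-field model-free fitting (600 or 800 MHz); no anisotropic
  diffusion tensor, no extended two-timescale model, no reduced spectral
  density mapping.
* Temperature-coefficient models are strictly linear; curvature (minor
  state exchange) is not detected.
* The trajectory module analyzes coordinates; it does not run or steer
  MD, compute PMFs from steered ensembles, or estimate solvent-accessible
  surface areas.
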