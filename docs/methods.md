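# Methods

This note documents the models behind each stage of the measurement chain,
the synthetic data they are validated against, and the numerical and design
choices that were genuinely open.

## Synthetic cohort

The generator produces virtual 3 × 3 × 6 mm cortical bone specimens (axis 3,
the 6-mm edge, aligned with the osteons) whose ground truth carries the
statistical structure of the study population.

**Porosity.** Drawn from a log-normal truncated to [0.024, 0.40] with
median 0.093 and log-SD 0.8. The truncated log-normal reproduces the
right-skewed distribution of cortical porosity in elderly hips, in which a
single highly porous, partly trabecularised specimen occasionally appears;
that specimen is exactly the case the downstream normality gate and
exclusion rule exist for.

**Porosity → property links.** The functional porosity–modulus relationship
of the real specimens is not known; a power law is used as an explicit
stand-in:

* modulus `E3 = E0 (1 − p)^k` with `E0 = 23 GPa`, `k = 1.9`, spanning
  ≈ 8.7–21.9 GPa over the porosity range;
* strength `UCS = S0 (1 − p)^q` with `S0 = 160 MPa`, `q = 2.1`, spanning
  ≈ 55–152 MPa (median ≈ 128 MPa at median porosity);
* density as a two-phase mixture `ρ = ρ_tissue (1 − p) + ρ_fluid p` with
  `ρ_tissue = 2.0`, `ρ_fluid = 1.0 mg/mm³` (this spans 1.60–1.98 mg/mm³
  over the porosity range; real cohorts reach 1.4 mg/mm³, which would
  require a lower effective tissue density — the mixture constants are
  configurable);
* ash density `BMDA = 0.55 ρ_tissue (1 − p)` (ash fraction 0.55 of tissue
  mass, giving BMDA ≈ 1.0 mg/mm³ at median porosity);
* the full orthotropic tensor is a fixed reference tensor for femoral
  cortical bone scaled uniformly so its E3 equals the specimen's E3 —
  anisotropy ratios are therefore constant across the cohort.

All links are strictly monotone in porosity, so the rank correlation
between porosity and any mechanical ground truth is −1 before measurement
noise; measured correlations then reflect only the per-modality error
models.

Because every modality measures the *same* `E3_true`, the generator does
not emulate the systematic offsets seen between real quasi-static
compression and ultrasound moduli (bone is viscoelastic; ultrasound probes
a much higher strain rate). Viscoelastic constitutive fidelity beyond a
logarithmic hold-creep term is deliberately out of scope, so passing
round-trip tests demonstrate correctness of each analysis, not the
inter-modality biases of real data.

**Randomness.** One master seed; each specimen carries a child seed spawned
deterministically from it, and each modality generator draws from an
independent stream of the child (`SeedSequence`-based), so cohorts and
signals are bit-reproducible and adding a modality never perturbs another.

**Raw-signal models.**

* *Indentation*: loading follows Hertz `P = (4/3) E* √R h^{3/2}`; the 60-s
  hold adds logarithmic creep (default amplitude 0.1 μm, time constant
  5 s); unloading is elastic from the crept depth, i.e. a power law with
  `m = 3/2` and `h_f` equal to the accumulated creep. Additive Gaussian
  displacement noise (default 10 nm). The protocol mirrors the study:
  200 μN preload, 0.1 N/s to 10 N, 60 s hold, 0.3 N/s unload.
* *Compression*: a quadratic toe to 0.2 % strain, a linear region of slope
  exactly `E3_true`, parabolic hardening to the peak at `ucs_true`, linear
  post-peak softening; ten preconditioning cycles precede the ramp. Two
  LVDT channels = true displacement ± a load-proportional antisymmetric
  tilt plus independent noise (default 0.2 μm per channel).
* *Ultrasound*: a Gaussian-windowed 5 MHz tone truncated three envelope
  widths before its centre, inserted at `TOF = L₃ / √(C₃₃/ρ)`; noise floor
  1e-3 of the pulse amplitude; repositioning jitters the TOF by 0.5 %
  (relative) across the six repeats.
* *Resonance spectrum*: the package's own forward solver at the specimen's
  tensor, multiplicative frequency noise (0.3 %) and independent mode
  dropout (10 %) emulating peaks lost to damping.
* *Micro-CT*: straight axis-3-aligned cylindrical canals with diameters
  drawn around 29–44 μm, unioned on overlap, rasterised at 7 μm; bone at
  grey 200, pores at 50, Gaussian noise SD 10. The imaged block defaults
  to a 0.896 × 0.896 × 0.448 mm sub-region — the canal field is
  statistically uniform in the transverse plane, so a sub-region estimates
  porosity without bias while keeping volumes small; tests that probe
  accuracy at scale use 256³ voxels.

## Indentation analysis

Oliver–Pharr with the spherical contact-area rule `A = 2πR h_c`. The
"upper portion" of the unloading curve is the 50–95 % load band of P_max
(configurable): the upper cut avoids the creep shoulder at peak load, the
lower cut avoids final-contact artefacts. The power-law fit is bounded
nonlinear least squares in `(log α, m, h_f)` with `h_f` constrained below
the smallest depth in the window and initialised from a linear
extrapolation of the low-load tail; three exponent starts (1.5, 1.2, 1.8)
guard against local minima. Thermal drift can optionally be estimated from
the final 30 s of the hold and subtracted from unloading displacements.
Degenerate unloads are flagged "uninterpretable" (as happens on pore
strikes in real specimens) and excluded from the central-four grid mean.

On noiseless Hertz-generated curves this chain is exact by construction
(`E_r = E*` algebraically for `m = 3/2`, `h_f` elastic), so the 5 %
round-trip tolerance absorbs only fit and discretisation error.

## Compression analysis

Strain uses the mean of the two LVDT channels (antisymmetric platen-tilt
perturbations cancel exactly); stress = load / nominal cross-section.
Preconditioning is stripped by segment label when present, otherwise by
walking back from the load peak to the last point at the displacement
floor. The sliding-window modulus uses every recorded sample as a window
origin (exhaustive; curves are small and prefix sums make each window
O(1)); windows reaching past the stress peak are excluded so post-yield
softening never inflates the modulus. CAEM is reported in GPa with the
winning origin; UCS is the peak stress with its strain.

## Bulk-wave ultrasound

"First deviation from zero" is operationalised as the first sample whose
magnitude exceeds `k_σ = 5` times the noise SD of the leading 10 % of the
trace, refined by linear interpolation to the exact crossing; on a
noiseless trace it degenerates to the first nonzero sample. Couplant and
transducer delays are assumed calibrated out. The detector's mean error is
below half a sample period at the study's signal-to-noise ratio (verified
over 200 jittered traces). Velocities (not times) are averaged over the
six repeats; `c₃₃ = ρ v²` is reported in GPa.

## Resonant ultrasound spectroscopy

**Forward.** Rayleigh–Ritz with the product basis of normalised Legendre
polynomials of total degree ≤ N on the parallelepiped, stress-free
boundaries. The basis is L2-orthonormal, so the mass matrix is a scalar
multiple of the identity and the generalized eigenproblem reduces to a
single symmetric `eigvalsh`. The six zero-frequency rigid-body modes are
discarded. Eigenvalues are variational upper bounds, decreasing
monotonically in N (asserted per mode in the tests). At N = 12 the lowest
twelve modes of an isotropic cube agree with an independent trilinear-FEM
eigen-oracle (Richardson-extrapolated over 8³ and 12³ meshes) to better
than 0.05 %.

**Inverse.** The study-grade Bayesian machinery is reduced to a MAP point
estimate: minimise the sum of squared relative frequency residuals
(scaled by an assumed relative noise `data_sigma`, default 0.1 %) plus
Gaussian prior penalties on the nine constants. `data_sigma` is set below
the synthetic noise level deliberately: the data dominate the
well-identified diagonal constants while the prior still bounds the weakly
identified off-diagonal ones. Measured modes are paired to predicted modes
by a monotone assignment minimising total relative residual (dynamic
programme over a predicted list extended by six extra modes), which
tolerates undetected modes. Two robustness devices matter in practice:

1. *Scale alignment*: frequencies scale as √s under `C → sC`, so a single
   forward solve suffices to scan a scale factor that aligns the predicted
   comb with the measured one before the nine-parameter fit — without it,
   a prior mean a few percent off sends the fit into a shifted-assignment
   local minimum.
2. *Frozen-assignment outer loop*: each bounded least-squares pass runs at
   fixed pairing (smooth objective); the pairing is then recomputed and
   the fit repeated until stable (≤ 4 outer iterations).

Basis order N = 6 (252 basis functions) is the working default for
synthesis and inversion: generation and inversion share the same forward
model, so the round trip is unaffected by basis truncation, and a full
20-specimen study inverts in about a minute. N = 12 is used where absolute
forward accuracy is the point. Specimens whose measured porosity exceeds
0.35 are RUS-ineligible (the vibrational model assumes millimetre-scale
homogeneity; a trabecularised cortex violates it) and enter the cohort
table as missing values.

## Micro-CT porosity

Otsu's criterion on the in-mask histogram is the default threshold
(reproducible and parameter-free; the study names thresholding but not the
threshold). A bimodality guard rejects the split when the two classes are
separated by fewer than three pooled within-class standard deviations, so
a pore-free volume reports porosity 0 instead of a bisected noise
histogram. A fixed threshold and an optional minimum-component-size filter
(default off — no despeckling is part of the nominal method) are
available. Morphometry labels 6-connected components and reports the
equivalent circular diameter of each canal's mean transverse
cross-section.

## Densitometry

Volume is the product of per-axis means of four calliper repeats; wet mass
is the mean of eight balance readings; `ρ = mass/volume` and
`BMDA = ash mass/volume` in mg/mm³. Ash mass exceeding wet mass is
rejected as a measurement error.

## Contact mechanics

The Hertz closed form gives the half-space approach
`δ = (9P²/(16 R E*²))^{1/3}` with `1/E* = (1−ν²)/E + (1−ν_i²)/E_i`. For
the study constants (R = 3 mm, P = 10 N, bone 6 GPa/0.33, sapphire
420 GPa/0.24) δ = 7.53 μm and the contact radius is 0.15 mm.

The finite-geometry solver quantifies the sample-width effect: trilinear
hexahedral FEM on a quarter-symmetry graded tensor mesh (the contact
radius resolved by six elements by default, geometric cell growth 1.4
toward the far field), bone block bonded to a rigid base, lateral faces
free. Because the contact patch is two orders of magnitude smaller than
any simulated width, the Hertzian pressure distribution of the combined
contact is applied as a prescribed traction; the indenter displacement is
the pressure-weighted mean of `(u_z + r²/2R)` over the patch plus the
closed-form tip-side share. This estimate equals the Hertz approach
exactly in the half-space limit, and the solver reproduces it within ~1 %
on a 60 × 60 mm block. A frictionless base changes the result by < 0.1 %.

Computed displacements at study parameters: ≈ 7.34 μm for wide blocks
(30–60 mm) and ≈ 7.96 μm for the 3-mm specimen width — the narrow block is
strictly more compliant, which is the effect that depresses apparent
indentation moduli measured on small specimens. The reference
finite-element study reports 7.7 and 9.5 μm for the same nominal setup;
its wide-block value already exceeds the Hertz half-space bound and its
mesh, element type and base conditions are unreported, so the ≈ 20 %
narrow-case gap most plausibly reflects a soft discretisation or a
different boundary condition in that model. Our mesh-refinement study
(contact radius resolved by 6 → 9 elements, growth 1.4 → 1.3) moves the
narrow value by only 0.5 %, i.e. the solver is converged; the qualitative
ordering narrow > wide is asserted as the hard contract.

## Statistics

Shapiro–Wilk at α = 0.05 per measurement column gates the method: any
non-normal column selects Spearman (average ranks for ties) for the
full-cohort matrix, with Pearson permitted after the porosity-cutoff
(default 0.35) exclusion. Missing RUS values are handled by pairwise
deletion, so RUS correlations run on the gated-down n while other columns
keep the full cohort. p-values are two-sided with no multiple-testing
correction (matching the study's reporting); because the asymptotic
Spearman p-value is approximate at n ≤ 20, an exact permutation p-value is
available per pair (`exact_p=True`, seeded). The multiple regression
reports R = √R² carrying the sign of the porosity coefficient — the
study's signed-r convention for a porosity-dominated fit — plus
per-predictor p-values and a condition-number collinearity flag on the
standardised design.

## Problem sizes and runtimes

Defaults are chosen so a full study runs at desk scale on one core:
20 specimens end-to-end ≈ 30 s (RUS inversion at N = 6 dominating), a
single contact solve 10–40 s (20k–70k DOF), CT accuracy checks at 256³
voxels a few seconds each, and the whole validation suite a few minutes.

## Known limitations

* No osteonal microstructure, lacunar/nano-porosity, cement lines or
  anisotropic pore shapes — vascular porosity only, as straight cylinders.
* No viscoelastic modality offsets (see above); creep is a single
  logarithmic term.
* The RUS inversion is a MAP point estimate; posterior uncertainty on
  `C_ij` is not propagated into the cohort statistics.
* The contact solver prescribes the half-space contact pressure; it is
  accurate while the patch is small relative to the sample, and does not
  re-solve the contact inequality for extreme geometries.
* Indentation heterogeneity within a sample is modelled as independent
  per-indent modulus scatter, not as a spatial pore field under the tip.
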