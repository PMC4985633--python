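# Methods

This note documents the models implemented in `neutroshell`, the
assumptions and tunable parameters behind them, the numerical choices,
and what the synthetic-data tests do and do not establish.

## Scattering length densities

All SLDs derive from six hard-coded bound coherent scattering lengths
(Sears compilation): H −3.7390, D +6.671, C +6.6460, N +9.36, O +5.803,
S +2.847 fm.  Water SLD is linear in D₂O mole fraction between the pure
endpoints computed from the 25 °C densities 0.99707 (H₂O) and 1.1044
(D₂O) g/cm³: −0.558×10¹⁰ and +6.358×10¹⁰ cm⁻².  Densities are
configurable for other temperatures; scattering lengths are treated as
temperature-independent.

**Osmolyte solvents.** Ectoine is C₆H₁₀N₂O₂, M = 142.16 g/mol, with 2
exchangeable (amidinium N–H) hydrogens that take the solvent H/D ratio.
Solvent SLD uses volume-additive mixing: per litre, the osmolyte
contributes its scattering length at the given molarity and displaces
water by molarity × partial molar volume.  The partial molar volume is
not measurable from within this package's inputs; it is calibrated once
by least squares against the four published ectoine solvent SLDs
(2 M/3 M × H₂O/D₂O), giving **102.87 cm³/mol** (implied density
1.38 g/cm³, consistent with ectoine's crystal density ≈ 1.37).
Residuals of the calibrated model are ≤ 0.03×10¹⁰ cm⁻².  For
reproduction of the published analysis the solvent SLDs are taken
verbatim from the published table (`solvent_mode="table-1"`, the
default) so that no invented constant propagates; the calibrated
mixing model (`"computed"`) serves everything else.

**Proteins.** A composition records element counts, the number of
labile (solvent-exchangeable) H, molar mass, and partial specific
volume (default 0.75 cm³/g; particle volume M·v̄/N_A).  Non-labile H
carry deuterium at the labeling level; labile H at
exchange_fraction × solvent D₂O fraction, with exchange_fraction = 0.85
by default (folded proteins never exchange completely).  Deuteration is
assumed not to change the partial volume.

**The average-composition protein model.** When the exact sequence is
unknown the generic builder scales the Swiss-Prot average residue
(C 4.86, H 7.58, N 1.36, O 1.48, S 0.042 per residue).  The one
parameter that matters to the contrast analysis and that chemical
counting cannot fix reliably is the *effective* exchangeable-H count:
full chemical counting (backbone amides less proline plus side-chain
OH/NH/SH) gives ≈ 1.76 per residue, but buried and structurally
protected sites make the realised count smaller.  The default is
therefore **calibrated to the measured contrast-match point of the
protiated protein, 40 % D₂O**, giving 1.356 labile H per residue; the
chemical value is exported alongside for sensitivity checks.  The
deuterated labeling is pinned the same way, by its measured match-out
at 100 % D₂O (non-labile deuteration 0.765 — the expected level for
growth on protiated carbon source in 85 % D₂O).  Both calibration
targets are measured observables independent of the shell analysis.

Match points are located by bisection of protein SLD minus the water
SLD line over D₂O fraction ∈ [0, 1.05]; a composition that tracks the
solvent line everywhere is reported as degenerate (0) rather than an
arbitrary root.

## Guinier and Stuhrmann analysis

`GuinierModel` performs a weighted linear regression of ln I on Q²
(weights (I/σ)², i.e. 1/σ² on the log scale; unweighted when σ is
absent).  The window is iterated self-consistently: fit, recompute
R_g = √(−3·slope), move the high-Q edge to Q_max·R_g = bound, repeat.
The default bound is 1.3.  Note that the bound limits *approximation*
error, not fitting error: for a uniform sphere the Guinier estimate is
intrinsically biased +1.8 % at Q_max·R_g = 1.3 and +0.7 % at 0.8, so
recovery tests that demand better than 1 % accuracy on strongly curved
form factors fit at a bound of 0.8.  Parameter uncertainties come from
the regression covariance, inflated by reduced χ² when the data carry
uncertainties and the fit is poor.

`normalize_forward` divides I(0) by the number concentration
N = c·N_A/M, making forward intensities comparable across
concentrations; √(I(0)/N) equals the particle excess scattering length
(Δρ·V) on absolute scale.  `StuhrmannModel` fits the signed amplitudes
against solvent SLD; signs must come from computed contrasts (they are
not inferable from intensities), and the x-intercept is the particle's
contrast-match SLD.  The published absolute I(0)/N magnitudes embed an
instrument factor that the inputs do not itemize, so all downstream
analysis uses amplitude *ratios*, which are scale-free.

## Hydration-shell decomposition

The particle is protein plus a shell of pure water (no osmolyte),
**10 % denser than bulk** by default, so the shell SLD is
1.1 × the bulk-water SLD of the solvent's isotopic composition and its
contrast is that value minus the full (osmolyte-containing) solvent
SLD.  The shell-to-protein volume ratio X is solved from the amplitude
ratio between one H₂O-based and one D₂O-based condition of the same
labeled protein — the deuterated protein is the discriminating pair,
since its bare-protein contrast is large in H₂O and small in D₂O while
the shell contrast has opposite signs in the two solvents.  The solver
is a 0.005-step grid on X ∈ [0, 1] with bracketed bisection refinement
(robust near the pole where the denominator amplitude crosses zero;
grid points past a denominator sign change are excluded).  σ_X follows
from σ_R through the local slope dR/dX.

With X fixed, the fractional protein contribution
f₁ = (Δρ·V)_Prot / [(Δρ·V)_Prot + X·V_Prot·Δρ_Hyd] is computed per
condition (f₁ may exceed 1 when the shell term opposes the protein
term), and a weighted line fit of R_g² on f₁ (weights from
σ(R_g²) = 2 R_g σ_Rg) extrapolates to the protein radius at f₁ = 1 and
the shell radius at f₁ = 0, under the assumption that protein and
shell centres of mass coincide.  The self-consistency loop (X before
f₁) is executed once.

Shell geometry maps the protein to its sphere-equivalent radius
R = √(5/3)·R_Prot, solves (R+t)³ = (1+X)·R³ for the thickness t, and
evaluates the uniform-spherical-shell R_g² = (3/5)(R₂⁵−R₁⁵)/(R₂³−R₁³).
At X = 0.30 around a 25 Å-R_g protein this gives t ≈ 3.0 Å — one water
layer — and shell R_g ≈ 33.8 Å.

**Known limitation.**  On the published eight-condition table the
package reproduces the amplitude-ratio fit (X = 0.283 ± 0.016 against
the published 0.30 ± 0.05) and the protein radius (25.3 Å against
25 ± 1 Å), but the shell-radius extrapolation lands at 37.6 Å where
33 ± 1 Å was published.  The extrapolation to f₁ = 0 is far outside the
measured f₁ range (0.64–1.21 under the average-composition model) and
is acutely sensitive to the f₁ values, which depend on the exact
(unpublished) protein composition; every composition consistent with
the measured 40 %/100 % match points yields 35.5–38 Å under any
reasonable weighting.  The number is reported as computed.

## Elastic-scan dynamics

Per temperature (ramp data binned, default 5 K), ln I_el is regressed
on Q² inside the window 0.18–1.33 Å⁻², where the Gaussian approximation
holds for hydrated membrane samples; ⟨u²⟩ = −d·slope with the divisor
convention d = 6 (full 3-D MSD) or 3, always stated in reports and
never silently assumed.  A positive slope clamps the MSD at 0 with a
flag.  The resilience is ⟨k′⟩ = 2k_B/(d⟨u²⟩/dT) = 0.002761/(slope in
Å²/K) N/m, from a weighted regression of MSD on temperature; a
non-increasing MSD raises rather than returning a negative stiffness.
Because 1/slope is convex, ensembles of noisy replicates should be
summarised by the median resilience or by the pooled slope — the
arithmetic mean is biased high by roughly the squared coefficient of
variation of the slope (≈ +8 % at the test conditions of 2 % intensity
noise over a 38 K ramp).

## Liquids diffraction

g(r) = 1 + (2π²ρ₀r)⁻¹ ∫₀^Qmax Q[S(Q)−1]W(Q)sin(Qr)dQ by trapezoidal
quadrature on the measured grid, with the analytic limit at r → 0.  The
default window is Lorch, W(Q) = sin(πQ/Q_max)/(πQ/Q_max), which
suppresses truncation ripples by more than 3× at the cost of
deliberate peak broadening; plain truncation is selectable and is what
the round-trip fidelity tests use, since the Lorch path is lossy by
design.  Peak *positions* survive the window and are refined by
three-point quadratic interpolation; distances over the instrument
range 0.22–23.5 Å⁻¹ are recovered to within 0.02 Å in the test suite.
The default r grid is 0.01–10 Å, step 0.01 Å (solute–solute
correlations fall beyond the analysed r < 4 Å range).  ρ₀ can be
computed from composition — 1.5 mol/L of a 20-atom solute with 31
waters per solute gives 0.102 atoms/Å³ — or supplied directly.

Solute self-correlations are removed as
S′(Q) = S(Q) − Σ w·sinc(Qr)·exp(−γQ²/2) over a user-supplied pair
list; the packaged ectoine list is an idealized stand-in (textbook bond
lengths, nominal weights, γ = 0.005/0.01 Å² for bonded/geminal pairs)
and is labeled synthetic.

H-bond geometry uses the law of cosines on the measured distances: the
intramolecular D–O–D angle α from (d_OD, d_DD); the donor angle β
between O–D and O–O from (d_OD, d_OO, d_OD-inter); the H-bond angle θ
at D.  Degenerate (collinear) triangles are allowed; violations of the
triangle inequality raise.  Angles are kept in double precision and
rounded only in reports.  Note the printed distances are themselves
rounded to 2 decimals, so angles recomputed from them can differ from
published angle values by up to ~1°.

## Membrane diffraction

Bragg's law d = nλ/(2 sin θ) on indexed lamellar peaks (angles as
2θ in degrees, default λ = 4.75 Å); multi-order series are fitted as
sin θ_n = nλ/(2d) through the origin, with a mis-indexing warning when
sin θ residuals exceed 5×10⁻³.  Peak extraction from detector traces is
out of scope; inputs are peak lists.

## Synthetic data: what the tests show

Generators are deterministic given a seed and emit ground truth
sidecars.  Noise is multiplicative Gaussian (relative σ), matching
normalized-intensity data.  The SANS generator uses the exact
concentric-spheres amplitude (series-expanded at small QR for
stability); the contrast-series generator emulates the measured design
— two labelings × four ectoine solvents — with R_g² built from the same
parallel-axes identity the analysis inverts.  Defaults mirror the
study conditions: X = 0.30, R_Prot = 25 Å, 85 % exchange, 1.1 shell
density factor, 280–318 K ramps, 0.22–23.5 Å⁻¹ liquids Q range,
d = 82 Å lamellar stacks.

What passing recovery tests establish: the estimators invert their own
forward models without bias at the stated noise, windows behave as
documented, and the analysis chain is internally consistent.  What
they do not establish: robustness to instrument resolution smearing,
inter-particle interference, multiple scattering, inelastic
backgrounds, or composition errors in real samples — all of which are
assumed corrected or known before data enter this package.

## Problem sizes

The test suite and the reproduction script run in seconds: the
published-table chain is eight conditions and closed-form algebra; the
recovery ensembles use 50–100 replicates of 8-condition tables or
8-temperature × 30-point scans, chosen to make ensemble means/medians
stable to well under the tested tolerances.
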