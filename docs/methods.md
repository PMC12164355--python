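# Methods

This note documents the models implemented in `plasmoniso`, the conventions
and defaults behind them, what the synthetic-data generators do and do not
emulate, and the known limits of each approximation.

## 1. Optical constants and medium

Gold is described by its complex relative permittivity ε(λ). Two
interchangeable models ship with the package:

* **Embedded table** (default): Johnson–Christy-style single-crystal n, k
  values spanning ~285–1940 nm, interpolated linearly in wavelength.
  Evaluation reproduces table nodes exactly; the validity window exposed to
  callers is 300–900 nm.
* **Analytic Drude + two-Lorentz model**: a nine-parameter oscillator fit to
  the embedded table, weighted least squares on the relative deviation over
  400–800 nm. Maximum relative deviation from the table over that window is
  4.6% (asserted ≤ 5% in the tests). Useful when a smooth, differentiable
  ε(λ) is needed.

Both models are passive (Im ε ≥ 0 everywhere on 350–800 nm), metallic
(Re ε < 0 for λ ≥ 500 nm) and Drude-like (Re ε strictly decreasing over
600–900 nm).

The embedding medium is a lossless dielectric with refractive index n,
permeability 1, conductivity 0. The default n = 1.343 models the
aqueous/lipid environment of vesicle-templated assemblies. Source material
for this kind of simulation sometimes quotes the *permittivity* of the lipid
phase as 1.343; taken literally that would mean n ≈ 1.159, under which a
12-nm gold sphere would resonate near 505 nm, inconsistent with the
524–525-nm single-particle peaks those same simulations report. We therefore
interpret the number as a refractive index; both readings remain selectable
(`Medium(1.343)` vs `Medium.from_permittivity(1.343)`).

With the embedded table and n = 1.343, the Mie extinction of the 12-nm
sphere peaks at 521.3 nm. Published finite-element results for the same
system, using a commercial materials library, quote 525 nm; optical-constant
datasets for gold legitimately differ by a few nm in the position of this
peak, which is why the package's acceptance band for the single-particle
resonance is ±5 nm. No mean-free-path (size-dependent damping) correction is
applied by default; at r = 6 nm it mainly broadens the resonance without
moving its position appreciably.

## 2. Single-particle Mie theory

`mie_cross_sections` implements the Lorenz–Mie multipole series
(Bohren–Huffman formulation, logarithmic-derivative downward recurrence)
for σ_abs, σ_sca, σ_ext = σ_abs + σ_sca in nm². The series is truncated at
the size-adaptive Wiscombe order n_max = x + 4x^{1/3} + 2 (x = 2πn_m r/λ),
with a hard ceiling of 80 beyond which a convergence error is raised. For
the particles of interest (r ≤ 10 nm, x ≈ 0.1) the dipole term dominates;
the full series agrees with the radiatively corrected dipole-polarizability
formula within 5% at the peak for r ≤ 10 nm.

Peak positions are reported with sub-grid precision: a parabola through the
three samples around each discrete maximum. Default peak prominence is 2% of
the spectrum maximum; the default wavelength grid is 400–800 nm at 1 nm.

`incident_irradiance(E0, Z0)` returns I = E0²/(2Z0); with E0 = 10⁵ V/m and
Z0 = 376.73 Ω this is 1.33·10⁷ W/m², the plane-wave intensity used in the
electromagnetic solves.

## 3. Cluster geometries

`build_radial_geometry(sp)` realizes the 63-particle protocol: 21 collinear
trimers (3 spheres each, radius 6 nm by default) in the XY plane. Trimer
*i* (i = 0…20) uses the uniform surface gap {0.75·sp, sp, 1.25·sp}[i mod 3] —
seven subgroups per variant, so the subgroup-averaged spacing ⟨sp⟩ equals
the nominal sp exactly — and its axis is rotated by iπ/21. Because these
angles sample a half-turn uniformly *within each gap class* (Σ e^{2iθ} = 0
class-by-class), the ensemble extinction is polarization-isotropic in the
plane up to inter-subgroup coupling residue.

Subgroup centers follow a deterministic concentric-ring rule (no randomness;
geometries are reproducible bit-for-bit): one trimer at the origin, then
rings of radius j·d_min holding ⌊2πj⌋ trimers, with
d_min = 2(3r + 1.25·sp) + 20r. The 20-radius clearance keeps every
inter-subgroup surface distance far above the 4-radius independence
threshold and the residual Ex/Ey asymmetry below ~0.2% (asserted ≤ 1%).
The placement rule is a package convention: the physical requirement is only
that subgroups respond independently.

`build_chain_geometry(sp, r, n)` builds the 1D comparison system: n collinear
spheres along X with uniform gap sp. Chains are polarization-anisotropic by
construction and are solved for Ex and Ey separately (unpolarized = mean).

## 4. Coupled-dipole solver

Finite-element electromagnetics is replaced by the coupled-dipole
approximation (CDA): one induced point dipole per sphere,

&nbsp;&nbsp;p_i = α(λ) [E_inc(r_i) + Σ_{j≠i} G(r_i − r_j) p_j],

with the full retarded dipole–dipole dyadic G and the radiative-reaction
polarizability 1/α = 1/α_CM − (2i/3)k³, α_CM = r³(ε' − 1)/(ε' + 2),
ε' = ε_Au/ε_medium, k = 2πn_m/λ. A lattice-dispersion-style variant adding
the finite-size k²/r term is selectable. The 3N×3N complex system is solved
directly at every wavelength; σ_ext comes from the optical theorem, σ_abs
from per-dipole dissipation (with the radiative term removed), and
σ_sca = σ_ext − σ_abs. Far-field quadrature of the scattered Poynting flux
is used as an independent oracle in the tests (2% agreement on small
clusters).

**Fidelity limits.** Point dipoles are quantitatively reliable for surface
gaps ≳ 1 radius and qualitatively correct below; at gaps < 0.15 radii the
solver emits a `FidelityWarning`. In particular, CDA *underestimates*
near-field coupling at sub-nm gaps: where multipole-resolved solvers place
the coupled resonance of a 0.3-nm-gap trimer near 609 nm, CDA puts the
red-most ensemble peak near 560 nm. All sub-nm-gap spectral positions from
such solvers are therefore treated as qualitative anchors (directions of
shift, presence/absence of features), never as CDA targets. The trends CDA
does reproduce — monotone red shift with decreasing gap, emergence of the
isosbestic crossing, its monotone blue shift with increasing ⟨sp⟩, and its
independence of cluster shape (radial vs chain agree within 0.25 nm at equal
⟨sp⟩) — are the mechanisms the analysis relies on.

`field_enhancement_map` evaluates |E|/E₀ on user points as incident +
summed dipole fields, masking points inside spheres; by linearity the
enhancement is independent of E₀.

## 5. Isosbestic analysis

`find_isosbestic` locates sign changes of A(λ) − B(λ) inside the crossing
window (default 450–650 nm) and refines each root linearly between grid
points. With multiple crossings it returns the one nearest the primary peak
of the *uncoupled* spectrum (the physically shared pivot of both
populations) and reports the count. Identical spectra raise a
degenerate-input error; no crossing returns a distinguished "not found"
result rather than an error.

`isosbestic_from_family` applies this to consecutive pairs of a
concentration series and declares an isosbestic point present when all pairs
cross and the standard deviation of the crossing positions is ≤ 1.5 nm
(experimental λ_iso values carry ±1 nm; the family threshold is slightly
looser).

Experimental spectra are normalized by their value at 350 nm before
comparison (`read_spectrum(..., normalize_350=True)`), the standard
acquisition convention for these titrations.

**Sigmoid calibration.** `fit_sigmoid` fits
λ_iso = (λ_A − λ_B)/(1 + e^{(sp − sp₀)/k}) + λ_B by nonlinear least squares
(lmfit), parameterized as (λ_B, Δ = λ_A − λ_B > 0, sp₀, k > 0) so the
plateau ordering is enforced structurally; the covariance is mapped back to
(λ_A, λ_B, sp₀, k) with the constant Jacobian of that reparameterization.
Initialization: plateaus from the observed extremes, sp₀ from the abscissa
of the steepest numerical gradient, k from the quartile spread. One-flank
data (no resolved inflection) yields an ill-conditioned fit, surfaced as a
missing or very large sp₀ uncertainty rather than an error.

`invert_sigmoid` applies the closed-form inverse
⟨sp⟩ = sp₀ + k·ln[(λ_A − λ_B)/(λ_iso − λ_B) − 1], defined strictly on the
open interval (λ_B, λ_A) — out-of-range inputs raise, they are never
clamped. Uncertainty combines first-order propagation of σ_λ with the
calibration covariance. The inversion is strictly monotone: smaller spacings
always map to larger λ_iso. (Published EV examples quote 531 nm → 0.7 nm and
529 nm → 0.6 nm, an ordering that contradicts the monotone law those same
data establish; this package reproduces the sub-nm magnitudes but not that
inverted ordering.) Note also that spacing estimates from the isosbestic
channel and from Cryo-EM imaging are independent measurement channels that
need not coincide (0.3 vs 0.8 nm for the softest template); the package
never reconciles them silently.

**Aggregation index.** The AI is not given a formula in the source
literature, so the definition is a recorded configuration field of every
output. Default: ∫₆₀₀⁷⁰⁰ σ dλ / ∫₅₀₀⁶⁰⁰ σ dλ (band-integral ratio, = 1 for a
flat spectrum); alternative: σ(650)/σ(peak). Both increase monotonically
with the coupled fraction for fixed endpoints.

**Concentration regimes.** With template concentrations attached,
`classify_concentration_regime` computes the AI per spectrum and places the
regime boundary at the AI maximum: below it (nanoparticle excess,
"saturation") clusters are saturated and uniform and the isosbestic holds;
above it ("excess-template") cluster heterogeneity develops and the common
crossing is lost.

**Stiffness calibration.** `fit_stiffness_map` fits the same sigmoidal
family with stiffness as abscissa to ≥ 4 (stiffness, λ_iso) pairs after a
monotonicity check (decreasing beyond 1 nm of noise raises a calibration
error), and `invert_stiffness` inverts it with the same error propagation.

## 6. SAXS: sticky hard spheres

Internal momentum-transfer units are nm⁻¹; Å⁻¹ input is converted
(×10) exactly once and flagged.

**Form factor.** The Schulz (gamma) radius distribution with mean R and
polydispersity p = σ_R/R (Z = 1/p² − 1) admits a closed-form orientational
and size average of the sphere intensity: writing F(x) = sin x − x cos x,
⟨F(QR)²⟩ reduces to gamma moments ⟨Rⁿe^{2iQR}⟩ = ⟨Rⁿ⟩(1 − 2iQ/a)^{−(Z+1+n)}
(a = (Z+1)/R), evaluated exactly with complex arithmetic and normalized so
P(0) = 1. Numerical guards: a Taylor series (through Q⁶) replaces the
cancelling combination where the widest realized x is < 0.35, and
p < 10⁻³ switches to the monodisperse sphere formula (the moment route
loses precision for Z ≳ 10⁶). Validity: 0 ≤ p < 0.5. Accuracy against
adaptive quadrature over the Schulz density: ≤ 0.1% on 0.03–3 nm⁻¹.

**Structure factor.** Baxter's adhesive-sphere solution in the
Percus–Yevick closure, via the Wertheim–Baxter factorization
S(Q)⁻¹ = |Q̂(Q)|², Q̂(Q) = 1 − 2πρ∫₀^σ q(r)e^{iQr}dr with the closed-form
factor function q(r) = (a/2)(r² − σ²) + bσ(r − σ) + λσ²/12. The coupling λ
is the smaller root of (η/12)λ² − (τ + η/(1−η))λ + (1 + η/2)/(1−η)² = 0;
no real root means the (φ, τ) pair lies in the forbidden/percolated region
and a parameter-region error is raised. Implementation checks: the τ → ∞
limit matches the independent Percus–Yevick hard-sphere closed form to
0.1%; φ → 0 gives S ≡ 1 to 10⁻⁴; the analytic factor integral matches
numerical quadrature to machine precision. The hard-core diameter default
is σ_hc = 2R_core; φ is treated as an opaque fit parameter (whether it is a
local or global volume fraction is not specified by the protocol this
mirrors).

**Intensity model and fit.** I(Q) = scale·P(Q)·S(Q) + background — the
decoupling approximation (polydispersity in P only), matching common
practice for this model family; its error grows with p and φ and is
negligible at p ≈ 0.13 and φ ≲ 0.15. `fit_sticky_hard_sphere` fixes the
form factor (from a separate free-particle fit, per the standard protocol)
and fits (scale, background, φ, τ) by weighted least squares (1/dI², else
1/I), multi-starting from a coarse (φ, τ) grid because the χ² surface has
local minima under noise. The background is deliberately unbounded: pinning
it at zero destroys the covariance estimate whenever the true background is
≈ 0.

A caveat established while validating the estimator: the softest-template
reference state (φ = 0.0189, τ = 0.0634) lies very close to the
discriminant boundary of Baxter's quadratic. Noise-free recovery there is
exact, but under multiplicative noise the constrained maximum-likelihood
estimate occasionally rides the boundary, giving non-Gaussian errors.
Monte-Carlo coverage of the reported standard errors is therefore assessed
at the interior reference state (φ = 0.1515, τ = 0.5930), where 2σ joint
coverage is 92% over 200 replicates.

**Structure-factor extraction.** S(Q) = I_mix/(c·I_free) on the common
(coarser) grid after background subtraction, with c fixed so the mean of S
over the top decade of Q (Q ≥ Q_max/10, where intra-cluster interference has
decayed) is 1.

**Pair potential.** u₀/k_BT = ln(12τε), the perturbative identification of
the adhesive-sphere limit of a narrow square well of relative width ε. The
exact ε convention used by the original analysis is not published; the
package default ε = 0.02 reproduces the quoted softest-template well depth
(−4.186 vs −4.190 k_BT) and the full printed ordering across the five
reference samples, with deviations up to ~1 k_BT for intermediate rows —
consistent with per-sample ε values that were not published. When a surface
spacing is supplied, ε defaults to sp/(σ_hc + sp); both conventions are
explicit arguments.

## 7. Synthetic data: what it emulates, and what not

`generate_mixture_series` emulates a vesicle titration at fixed AuNP
concentration (default 4.4·10¹² /mL; templates 6·10¹⁰–3.2·10¹¹ /mL, eight
log-spaced points spanning number ratios ~74/1 → ~14/1). The coupled
fraction follows the saturation law f = min(1, c_template·N_sat/c_AuNP)
with N_sat = 14 nanoparticles per template (the maximal-clustering ratio of
the reference titration). Within the saturation regime the series is a
strict two-endpoint mixture family — an exact isosbestic by construction.
Above saturation (beyond a 5% tolerance band at the changeover) the coupled
endpoint is replaced per-spectrum by a heterogeneous variant whose red-band
shift shrinks with template excess and carries random jitter, so the common
crossing is lost, mirroring the high-concentration regime. Noise is additive
Gaussian in absorbance (instrument-like); noisy spectra may legitimately dip
below zero in the tails.

Endpoints come from either the coupled-dipole solver or (default) a
**parametric two-Lorentzian model**: the uncoupled endpoint is a Lorentzian
at 524 nm (HWHM 30 nm); the coupled endpoint retains 75% of that band plus a
broader red band (HWHM 45 nm) whose center μ(sp) follows a logistic
distance-coupling map anchored at 609 nm for sp = 0.3 nm and 553 nm for
sp = 0.8 nm. The red-band amplitude is solved from the crossing condition so
that the endpoints cross exactly at λ*(μ) = 524 + (30/196)(μ − 524) nm,
which places the crossings at the observed isosbestic anchors (537.0 nm for
the 0.3-nm class, 528.4 nm for the 0.8-nm class) and makes λ_iso(⟨sp⟩)
exactly sigmoidal with plateaus 541.4/524 nm, sp₀ = 0.55 nm, k = 0.2325 nm.
These constants were fixed once, from the anchors, before any test was run.

What the generators do **not** emulate: instrument baselines and stray-light
curvature, template (vesicle) scattering contributions, kinetic drift during
acquisition, cluster-size polydispersity within the saturation regime, and
inter-batch variability of particle size. Passing tests therefore establish
the correctness and statistical calibration of the *estimators* under the
stated generative model, not the absence of systematics in real spectra.

`generate_saxs_profile` produces scale·P·S + background with multiplicative
Gaussian noise (counting-statistics-like) and records the generating truth;
`generate_calibration_set` evaluates the spacing sigmoid (default truth
λ_A = 538, λ_B = 526, sp₀ = 0.7, k = 0.25) plus additive noise. All
generators are bit-reproducible from (scenario, seed).

## 8. Numerical conventions and problem sizes

* Wavelengths, lengths in nm; Q in nm⁻¹; cross sections nm²; stiffness N/m.
* Default wavelength grid 400–800 nm at 1 nm; crossing window 450–650 nm.
* Cluster solves in the test suite use 450–650 nm at 2 nm — the window that
  contains both plasmonic bands — so a full 63-particle spectrum solves in
  well under a second and the whole suite in about half a minute.
* Monte-Carlo suites use 200 replicates with consecutive integer seeds.
* SAXS grids: 200 (or 100 in replicate studies) log-spaced points on
  0.3–3 nm⁻¹, the window that excludes low-Q cluster-mass scattering.
* Linear solves are dense LAPACK; no iterative tolerances are involved.
  lmfit/least-squares fits use machine defaults; fits that converge without
  an estimable covariance are returned with the covariance marked absent.

## 9. Known limitations

* CDA at sub-nm gaps is qualitative (Section 4); no multipolar response,
  no substrate/membrane dielectric contrast, no nonlocal/quantum corrections.
* The decoupling approximation ties polydispersity to P(Q) only.
* The τ → u₀ conversion depends on an unpublished ε convention; values for
  intermediate samples carry that systematic.
* The stiffness map is calibrated on four anchor pairs spanning
  0.006–0.031 N/m; extrapolation beyond the plateaus is undefined by
  construction (the inverse raises out-of-range errors).
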