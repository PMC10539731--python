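# Methods

This note records the model conventions, numerical choices and limitations
behind `masfloquet`.  Everything quantitative stated here is computed by the
test suite or the example scripts; nothing is quoted from elsewhere.

## Spin systems and couplings

A system is a list of proton coordinates (Å), isotropic shifts (ppm) and a
Larmor frequency (Hz).  The dipolar anisotropy of a pair is

δ_pq = −2 (μ₀/4π) γ_p γ_q ħ / r³  (rad s⁻¹),

with CODATA constants γ_H = 2.6752218744×10⁸ rad s⁻¹ T⁻¹,
ħ = 1.054571817×10⁻³⁴ J s, μ₀/4π = 10⁻⁷.  With these constants the built-in
systems give δ₁₂/2π = −44 826.2 Hz (r = 1.75 Å) etc.; constant-set choices
move these values by a few parts in 10⁵ at most.  All internal angular
frequencies are rad s⁻¹; user-facing I/O is Hz and ppm, with
ω_p = 2π · shift_ppm · 10⁻⁶ · ν_Larmor.  A global sign flip of all shifts
only mirrors spectra and is not otherwise significant.

Coordinates are moved into a canonical crystallite frame: z along r₁→r₂,
the first non-collinear spin in the x–z plane.  Planar systems therefore
have all pair azimuths φ_pq ∈ {0°, 180°}, and the reference pair has
θ₁₂ = φ₁₂ = 0.  Spins closer than 0.5 Å are rejected (degenerate couplings
always indicate an input error at proton densities).

The built-in three-spin fixture prints δ₂₃/2π = −5734 Hz as implied by its
coordinates (r₂₃ = 3.47 Å); a rounded variant −5750 Hz circulates for the
same geometry but is not what the coordinates give.

## Rotations and Fourier coefficients

Euler convention: ZYZ, active.  A crystallite orientation (α, β, γ) maps
crystallite vectors to the rotor frame via R_z(γ) R_y(β) R_z(α), so (α, β)
are the azimuth/polar coordinates of the rotor axis on the crystallite
sphere — the two angles a powder scheme must cover — and γ is the rotor
phase at t = 0.  Eigenvalue-derived quantities (frequencies, moments,
widths) depend on γ only through the time origin of the effective
Hamiltonian; γ defaults to 0 and can be grid-sampled (`gamma_steps`) for
intensity-sensitive studies.  During development we verified that sampling
the wrong two angles of the ZYZ triple confines planar systems to a
degenerate slice of orientation space in which the second-order term
vanishes identically — the orientation-set quadrature tests (rank-2
spherical harmonics averaging to zero over (α, β)) guard this convention.

The time-dependent coupling is normalized by its static limit:
ω_pq(t) = (δ_pq/2)·(3 cos²Θ(t) − 1)/2 with Θ(t) the lab polar angle of the
internuclear vector, matching the operator form 2I_zI_z − I_xI_x − I_yI_y.
The five Fourier coefficients follow in closed form from the rotor-frame
polar angle β_r and azimuth γ_r of the pair vector:

ω^(0) = 0 (magic angle),
ω^(±1) = −(δ/2)(√2/2) sin β_r cos β_r e^{±iγ_r},
ω^(±2) = (δ/8) sin² β_r e^{±2iγ_r}.

An independent brute-force oracle (Cartesian rotation of the unit vector,
FFT over one rotor period) pins the normalization and phases to <10⁻¹⁰
relative error in the tests; the magic angle is stored to full double
precision and is not configurable.

## Effective Hamiltonians

Floquet/van Vleck series in the Fourier components (all in rad s⁻¹,
ω_r = 2πν_r):

- order 1: H^(0) (shifts only, since ω^(0) = 0);
- order 2: (1/2) Σ_{n≠0} [H^(n), H^(−n)]/(n ω_r) — hermitian, commutes with
  F_z (zero-quantum), vanishes for an isolated pair;
- order 3: (1/2) Σ_{n≠0} [H^(n), [H^(0), H^(−n)]]/(n ω_r)² +
  (1/3) Σ_{n,k≠0, k≠−n} [H^(n), [H^(k), H^(−k−n)]]/(n k ω_r²), with
  H^(m) = 0 for |m| > 2.

The k = −n exclusion in the double sum matters: those terms reduce to the
H^(0) cross commutator already counted in the first sum, and keeping them
(total weight 5/6 instead of 1/2) destroys the ω_r⁻³ convergence toward the
exact effective Hamiltonian.  The coefficients (1/2, 1/3) and the exclusion
were calibrated against the numerically exact propagator: with them the
eigenvalue residual after order 3 falls off at least as ω_r⁻³ (measured
slope ≈ −4 for these systems), without them it stalls at ω_r⁻².

The exact effective Hamiltonian is H̄ = (i/τ_r) ln U(τ_r).  U is the
time-ordered product of midpoint-sampled slice propagators (default 1000
slices per rotor period; the self-convergence test confirms the midpoint
rule's n⁻² defect).  The logarithm is evaluated through the complex Schur
form of the unitary — diagonal for a normal matrix — with eigenphases on
the principal branch, which guarantees hermiticity and eigenvalues in
(−ν_r/2, +ν_r/2]; a warning is raised if an eigenphase sits within 10⁻⁶·2π
of the branch cut, where the modulo-ν_r ambiguity becomes real.

### Comparing exact and Floquet Hamiltonians

The matrix logarithm of U(τ_r) equals the van Vleck effective Hamiltonian
conjugated by the periodic micromotion operator exp(−iΛ(0)), Λ = O(ω_r⁻¹).
Eigenvalues are invariant under that conjugation, so spectra, moments and
widths from the two routes agree order by order.  Operator-norm
comparisons, however, see the conjugation: at a generic orientation
‖H̄_exact − H̄_order3‖_F is dominated by the micromotion commutator and
falls only as ω_r⁻² (ω_r⁻¹ with shifts).  When the rotor axis lies in the
plane of a planar zero-shift system (α ∈ {0°, 180°}), all H^(n) carry a
common phase, the leading micromotion commutator drops out of the
difference, and the Frobenius residuals show the clean ω_r⁻² / ω_r⁻³
scaling of the series itself.  `effective_residual_scan` therefore defaults
to such an orientation for its Frobenius metric and also offers the
frame-invariant eigenvalue metric, which is the right diagnostic at
arbitrary orientations.

## Spectra and moments

Transitions: ω_ij = E_i − E_j with intensities
I_ij = Re[(σ₀)_ij d_ji], σ₀ = F_x, d = F⁻, i.e. the coefficient of
e^{−iω_ij t} in Tr[σ(t) d].  Written this way the total intensity is
Tr(σ₀ d) = N·2^N/4 regardless of the eigenbasis, so it is conserved across
order-1/2/3/exact constructions — a conjugated variant of the formula that
one sometimes sees breaks this invariance in complex eigenbases and is
rejected by the conservation test.  Imaginary residuals above 10⁻⁸ of the
total trigger a warning (they indicate operator-phase bugs).  Transitions
within 10⁻⁹ Hz are merged; frequencies are kept signed so the first moment
measures the signed center of gravity (M₁ = 0 for dipolar-only powders by
symmetry).

Moments over a region are intensity-weighted raw sums; the line width uses
the *central* second moment (M₂_raw − M₁²) so that spinning-frequency
dependent line shifts do not inflate widths; both raw and central values
are reported.  Whether the shift is subtracted before the Gaussian-FWHM
conversion is a genuine convention choice; for the dipolar-only scans both
give identical numbers.

Binned spectra are intensity-conserving histograms convolved with a
Lorentzian of the requested FWHM (the frequency-domain equivalent of
exponential line broadening).  The center band is (ref − ν_r/2,
ref + ν_r/2]; line regions default to the midpoint partition between
consecutive isotropic shifts intersected with the center band (gap-based
clustering is available; exact region extents are a convention whenever
lines overlap, and the midpoint rule is the documented default).

## Powder averaging

Orientations are deterministic and RNG-free: cos β uniform over [−1, 1],
α advancing by the golden angle (an equal-area ZCW-style set for arbitrary
counts; the classic construction fixes counts to Fibonacci numbers, and any
equal-area low-discrepancy set gives the same powder averages, which the
rank-2 quadrature tests verify).  Powder moments pool all transitions with
their weights before the moment sums — not averaging per-orientation
moments — so they agree with moments of the high-resolution binned powder
spectrum.  Powder-averaged observables are invariant under global rotation
of the input coordinates (tested) and converge to ~1% in FWHM by ~10³
orientations for three-spin systems.

## Scan drivers and problem sizes

Default grids mirror the studies the package is built around:
ν_r ∈ {20, 30, 50, 75, 100, 150, 200, 250} kHz, Larmor 1 GHz for shifted
systems.  Desk-scale defaults use 2000 orientations for line-width and
breadth scans, 5000 for the four-spin decomposition, and 500–1000 slices
per rotor period for exact propagators — the convergence tests (orientation
doubling, slice refinement) show these change the reported observables by
well under the effect sizes discussed.  "Breadth" (total extent of the
powder pattern) has no unique definition for a stick spectrum; it is
implemented as the full width of the lightly smoothed binned spectrum at
0.1% of its maximum amplitude (threshold configurable).  The measure is
validated by what it is used for: the breadth difference between order-3
and exact constructions recovers a log-log slope of −3 ± 0.05 against
spinning frequency (the fourth-order fingerprint), robust to doubling the
orientation count or the bin density.

The serine-phosphate mimic fixture (r₁₂ = 1.60 Å, r₁₃ = r₂₃ = 2.35 Å,
70° apex angles) uses representative CH₂/CαH proton shifts (4.4, 3.9,
4.8 ppm) at a 20 T field; the line-shift study probes the spinning-rate
dependence of the apparent shifts, which is insensitive to the absolute
ppm values chosen.

## Limitations

- Hilbert-space dimension grows as 2^N; the dense implementation is meant
  for N ≤ 5.  Five-spin decomposition weightings are not implemented.
- No CSA, J couplings, heteronuclei, RF irradiation, off-magic-angle or
  double rotation; no relaxation (the computed widths are the coherent
  contribution only — real proton lines add a nearly rate-independent
  incoherent term).
- Fourth-order terms are never constructed analytically; they are observed
  only through exact-vs-order-3 differences.
- Stick spectra are center-band by construction: the exact Hamiltonian's
  eigenvalues live in (−ν_r/2, ν_r/2], so spinning sidebands are outside
  the model.  At ν_r comparable to the largest coupling the folding of
  eigenvalues into the principal branch is a real ambiguity (warned about)
  and perturbative constructions extend beyond the band.
- These model systems isolate the coherent dipolar mechanism; passing the
  package's tests says nothing about susceptibility broadening, shift
  dispersion or dynamics in real samples.
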