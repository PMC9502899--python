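# Methods

This note records the model, the numerical choices, and the limits of what
the test suite establishes. Everything quantitative stated here is computed
by the package's tests or by `scripts/acceptance.py`.

## 1. Line-shape model

### FFCF and broadening function

One vibrational resonance is parameterized by the frequencies ω₀₁, ω₁₂ of
its |0⟩→|1⟩ and |1⟩→|2⟩ transitions, an amplitude weight, a transition
dipole direction, and the frequency fluctuation correlation function

ξ(t) = δ(t)/T₂\* + Δ₁² exp(−t/τ_c).

The δ-term is the motionally narrowed (homogeneous) dephasing channel; the
exponential is diffusive spectral sampling of the solvation environment.
Δ₁ is stored in cm⁻¹ exactly as fit tables print it and converted to rad/ps
(factor 2πc ≈ 0.18837) only inside the broadening function

g(t) = t/T₂\* + (Δω τ_c)² [e^(−t/τ_c) + t/τ_c − 1],

the closed-form double time-integral of ξ. The δ-term therefore enters as
the exact linear t/T₂\* contribution — no numerical delta function exists
anywhere. `tests/test_lineshape.py` verifies g against double quadrature of
ξ to 1e−8 relative tolerance.

### Lifetime broadening conventions

The response expression behind the published parameter tables is not
printed, so the population-lifetime contribution to coherence decay is an
exposed convention:

* 0–1 coherences decay with `lifetime_factor · γ₁` (default factor 1/2,
  the population-limited coherence convention); configurable.
* the diagonal ESA 1–2 coherence decays with (γ₁+γ₂)/2 scaled the same
  way;
* cross-peak ESA uses the same rate as the cross-peak bleach so that the
  two cancel *exactly* when x_ij → 0 (a structural requirement, since an
  uncoupled pair must produce no cross peak).

γ₁, γ₂ are held fixed during line-shape fits: in the underlying workflow
they are measured independently by pump-probe, and floating them against
the same line shapes that determine T₂\* invites degeneracy.

### Linear absorption numerics

The spectrum is the half-Fourier transform of Σᵢ wᵢ e^{i(ω−ω₀₁ᵢ)t − gᵢ(t)}
with trapezoid end-point weighting, evaluated by FFT. The time step is
chosen so the Nyquist range covers 4× the requested spectral span; the
record is zero-padded 4× and cubic-spline interpolated onto the user grid
(interpolation error ≪ 0.1 cm⁻¹ for carbonyl-band widths). Analytic limit
oracles: fast-modulation Lorentzian FWHM 2(Δω²τ_c + 1/T₂\* + γ₁/2) and
static Gaussian FWHM 2√(2 ln 2) Δ₁, both matched within 2%.

## 2. Absorptive 2DIR

Rephasing and non-rephasing pathways use the standard cumulant line-shape
factors in the six time-interval combinations of g; the homogeneous part
reduces exactly to a separable e^{−(t₁+t₃)/T₂\*} factor, which the engine
exploits. Amplitudes carry the resonance weight, the isotropic
orientational factor ((1+2cos²θ)/15 parallel, (2−cos²θ)/15 perpendicular,
1/9 magic — verified against a 10⁶-sample Monte-Carlo orientation
average), and e^(−γ₁ t₂) population decay during the waiting time.

Cross peaks between modes i and j use mixed broadening functions built
from the product Δ₁ᵢΔ₁ⱼ scaled by a correlation coefficient (default 1:
modes of one molecule share a solvation shell, so their fluctuations are
taken fully correlated; the homogeneous δ-channel is uncorrelated between
distinct modes). The cross ESA sits at ω₀₁ʲ + x_ij (red-shifted for the
normal negative x_ij). Cross-peak amplitudes scale as √(wᵢwⱼ), diagonal
peaks as wᵢ (weights are fourth-power dipole weights).

Numerics: t₁, t₃ grids of `SimConfig` (default 3.2 ps at 20 fs — the
carbonyl response has decayed by >4 e-folds there), cosine apodization
over the trailing 10%, zero-padding to 512 points, double FFT, both phases
folded to positive pump frequency, bicubic-spline readout onto the
requested grids. `SimConfig.fine()` (6 ps, 10 fs, 2048 points) serves
center-line-slope work, where CLS(t₂) fits recover τ_c within 10%
(criterion test) and the known CLS ≈ normalized-FFCF relation is the
oracle.

The impulsive limit is assumed throughout (no pulse-envelope convolution,
no coherent-artefact modelling); the experimental geometry enters only
through the polarization choice.

## 3. The joint fit

`FFCFSpectrumModel` fits n resonances to one linear spectrum plus any
number of same-polarization 2DIR maps:

* parameter vector: per-resonance ω₀₁, δ = ω₀₁ − ω₁₂ (δ ≥ 0 prevents sign
  flips), T₂\*, relative amplitude (first resonance fixed to 1); Δ₁ and
  τ_c shared across resonances when flagged (the default, mirroring the
  published parameterization);
* every data block is normalized to unit maximum; the block *amplitude* is
  profiled out analytically (variable projection) — normalizing the model
  by a noisy data maximum instead measurably biases every shape parameter;
* blocks are weighted 1/√(block size) so the linear spectrum and each map
  contribute equally (the exact weighting of the original protocol is
  unknown; this is a documented choice);
* optimizer: scipy bounded trust-region least squares, multi-start
  (default 5 starts; centers jittered ±5 cm⁻¹) with best-χ² selection,
  guarding against local minima from overlapping bands. Starting values
  default to band moments of the linear spectrum.
* uncertainties: 1σ from the covariance (JᵀJ)⁻¹·s² at convergence; weight
  uncertainties by the delta method through the normalization.

Fitting ≥4 resonances inside one carbonyl band triggers an
ill-conditioning warning (strong overlap makes the problem practically
degenerate — the reason the reference analysis uses three).

The model evaluation engine is the same code that generates synthetic
data, so round-trip tests are free of model error: noiseless round trips
recover all parameters within 0.5%, and 20-seed ensembles at 1% noise show
bias below the reported 1σ for every parameter.

## 4. VPT2

Force constants are reduced-normal-coordinate φ in cm⁻¹ (the common
quantum-chemistry printout convention), potential
V = ½Σωq² + (1/6)Σφ₃q³ + (1/24)Σφ₄q⁴. Standard VPT2 x-matrix expressions
are used with Coriolis terms omitted (solution-phase, non-rotating model).
Near-resonant denominators (|2ωᵢ−ω_k| or a ±ω combination below 50 cm⁻¹,
configurable) are deperturbed: the term is dropped, recorded on the
`XMatrix`, and warned about.

Oracles: (i) exact Morse eigenvalues — the Morse force field reproduces
x_ii = −ω_e x_e to machine precision; (ii) harmonic-basis variational
diagonalization (≤3 modes). Note the variational oracle diagonalizes the
*truncated* cubic+quartic potential, which departs from the parent Morse
potential beyond second order, so quantitative VPT2-vs-variational
agreement (5% of the shift) is asserted only in the weak-anharmonicity
regime (|φ| ≲ 0.02 min ω); at carbonyl-like Morse anharmonicity
(ω_e x_e = 10) the truncation itself contributes ~12%.

Anharmonic fundamentals: ν_i = scale·ωᵢ + 2x_ii + ½Σ_{j≠i}x_ij with the
harmonic scale factor (default 0.97) absorbing the systematic DFT
frequency overestimate; ω₁₂ = ν_i + 2x_ii.

## 5. Kinetics

Population: S(t) = Σaᵢe^(−t/τᵢ), bounded least squares, components sorted
by lifetime, warning when lifetimes are closer than 1.5×. At the reference
conditions (0–5 ps window, 20 fs steps, 2% noise) the Cramér–Rao bound on
the short lifetime of the 380/820 fs biexponential is ≈19% — single
realizations scatter accordingly, so tests and the acceptance script
evaluate the replicate mean (measured unbiased: 0.3796 ps over 300
replicates).

Anisotropy: r(t) = (S∥−S⊥)/(S∥+2S⊥), single-exponential fit with r₀ free
(finite-pulse effects), fit window from 0.1 ps (coherent-artefact
exclusion), truncated where the isotropic denominator falls below 2% of
its maximum. Residuals are weighted by the isotropic signal — the
propagated error of the ratio scales as its inverse, and without the
weighting near-zero-denominator points dominate and the estimator
collapses. A residual +8–10% skewness bias at 2% noise remains (measured
over 200 replicates: mean 5.5 ps for a true 5 ps); this is intrinsic to
fitting the ratio on a ~2 ps usable window and sits well inside the
5 ± 1 ps uncertainty the measurement itself carries.

## 6. Chiroptics

CD bands are unit-area Lorentzians on the wavenumber axis, weighted by
R·ν/ν₀; absorption bands by oscillator strength. All band-shape math runs
in wavenumbers (the natural axis for Kramers–Kronig) with nm conversion at
the edges; dipole gauge is the data producer's responsibility.

The KK transform is evaluated by the MacLaurin alternating-point
principal-value quadrature (points of opposite parity, doubled spacing —
O(h²), <1% RMS against the closed-form dispersive Lorentzian over ±5Γ).
**Sign convention:** the dispersion relation taken literally gives the
refractive-index sign (negative high-frequency wing for a positive band);
the implemented transform carries an overall minus so that a band with
positive rotational strength (μ–m angle < 90°) has a positive
high-frequency dispersion wing — the sign rule the structural assignment
rests on. The inverse transform is negated consistently (round trip <2%
RMS). Absolute scales default to 1: band positions and signs are the
modelling target, not molar amplitudes.

The band width Γ is a free input (the original analysis tuned it to the
measured ORD shape and does not print it); UV-VIS fixture tests use 5 nm
(3.5 nm for the more congested cis manifold).

## 7. Synthetic data: what a green test establishes

Generators add seeded i.i.d. Gaussian noise scaled to the signal maximum —
a detector-noise approximation. They reproduce none of: multiplicative or
correlated noise, baseline drift, pump scatter, finite pulse bandwidth, or
solvent background. Round-trip recovery therefore establishes estimator
correctness and conditioning *under the stated noise model*, not
robustness to real-instrument systematics. The built-in carbonyl-band
parameter set, kinetic constants (380/820 fs, τ_R = 5 ps; free-proline
340/1100 fs), mixing ratio 3:1 and conformer transition wavelengths are
the package's reference world; the electronic-transition dipole vectors
in the fixtures are synthetic stand-ins (only positions and sign logic are
modelled, and they are labelled as such).

## 8. Known limitations

* Single-exponential + δ FFCF only; no power-law or multi-timescale
  spectral diffusion.
* Cross-peak correlation is a single scalar coefficient, not a
  mode-resolved correlation matrix.
* No global fitting across polarizations (the reference analysis uses the
  parallel data set only).
* The anisotropy estimator's small-sample bias (above) is documented, not
  corrected; a joint S∥/S⊥ fit would remove it but changes the stated
  method.
* VPT2 deperturbation drops resonant terms instead of treating them
  variationally (no Fermi-resonance polyads).
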