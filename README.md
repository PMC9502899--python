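# kubospec

Kubo line-shape modelling of vibrational and chiroptical spectra of
metal–amino-acid complexes — built around the carbonyl band of
Cu(L-proline)₂ in water.

## The problem

The d⁹ configuration of Cu²⁺ makes its coordination sphere floppy
(Jahn–Teller distortion), so a simple complex like Cu(L-proline)₂ exists in
solution as a distribution of conformers (*cis*/*trans* N,O-arrangements)
and hydration states. Two optical diagnostics constrain that distribution:

* the **carbonyl stretching band near 1600 cm⁻¹**, whose inhomogeneous
  broadening and spectral diffusion are read out by linear IR and
  two-dimensional infrared (2DIR) spectroscopy, and
* the **visible d–d transitions**, whose circular dichroism (CD) and
  optical rotatory dispersion (ORD) are sensitive to the μ–m geometry of
  each conformer.

`kubospec` implements the modelling layer of that analysis as a reusable,
tested package: simulation and fitting of linear IR / 2DIR line shapes with
cumulant-expansion response functions, second-order vibrational
perturbation theory (VPT2) for anharmonic shifts, pump-probe kinetics, and
Lorentzian-band CD/ORD modelling via the Kramers–Kronig transform. Because
no experimental raw data is deposited, a synthetic-data module generates
every input with known ground truth.

## The model

Each vibrational resonance carries a frequency fluctuation correlation
function (FFCF)

    ξ(t) = δ(t)/T₂* + Δ₁² exp(−t/τ_c)

with pure dephasing time T₂* (ps), fluctuation amplitude Δ₁ (cm⁻¹) and
correlation time τ_c (ps). Its double time-integral, the line-broadening
function

    g(t) = t/T₂* + (Δω τ_c)² [e^(−t/τ_c) + t/τ_c − 1],   Δω = 2πc Δ₁,

drives both the linear absorption (half-Fourier transform of e^(−g(t))) and
the rephasing/non-rephasing third-order response functions whose sum gives
absorptive 2DIR spectra: negative ground-state-bleach/stimulated-emission
peaks at (ω₀₁, ω₀₁), positive excited-state absorption at (ω₀₁, ω₁₂), cross
peaks controlled by off-diagonal anharmonicities x_ij, and polarization
weights from the relative orientation of transition dipoles. VPT2 converts
cubic/quartic force constants φ into the anharmonicity matrix x (e.g.
x_ii = φ_iiii/16 − (5/48)φ_iii²/ω_i − …), linking quantum-chemical force
fields to the observed diagonal red-shift ω₀₁ − ω₁₂. Rotational strengths
R = **μ**·**m** set CD band signs; ORD follows by Kramers–Kronig.

## Worked example

Fit the built-in three-resonance carbonyl-band parameterization back from
noisy synthetic data (linear IR + 2DIR maps at t₂ = 0.9 and 2.0 ps):

```python
from kubospec.synthetic import carbonyl_band_dataset
from kubospec.fitting import FFCFSpectrumModel

linear, maps, truth = carbonyl_band_dataset(noise=0.01, seed=1)
gammas = [(r.ffcf.gamma1, r.ffcf.gamma2) for r in truth.resonances]
model = FFCFSpectrumModel(linear, maps, n_res=3, gammas=gammas)
res = model.fit(n_starts=5, seed=1)
print(res.summary())
```

```
Kubo FFCF line-shape fit
==============================================================================
resonances: 3   shared: Delta1, tau_c   converged: True
chi2 = 0.000278373   reduced chi2 = 1.33e-08
------------------------------------------------------------------------------
  omega01   omega12  weight  Delta1  T2*/ps   tau_c    g1    g2
   1595.1    1588.6   0.202    8.37   0.804   1.569  1.00  1.30
(    0.10)(    0.11)( 0.005)(  0.02)( 0.005)( 0.014)
   1604.1    1598.5   0.557    8.37   0.956   1.569  0.98  1.30
(    0.04)(    0.05)( 0.006)(  0.02)( 0.007)( 0.014)
   1620.9    1612.4   0.241    8.37   0.953   1.569  1.00  1.30
(    0.02)(    0.03)( 0.001)(  0.02)( 0.004)( 0.014)
```

The three rows are the fitted resonances (centers ω₀₁, overtone-shifted
ω₁₂, amplitude weights, shared spectral-diffusion parameters Δ₁ and τ_c,
per-resonance dephasing T₂*; bracketed numbers are 1σ uncertainties). The
dominant resonance at 1604.1 cm⁻¹ with weight 0.56 carries the
antisymmetric carbonyl stretch; the fitted FFCF says the band is
inhomogeneously broadened (Δ₁ ≈ 8.4 cm⁻¹) with ~1.6 ps frequency memory.

A command-line surface mirrors the workflow
(`kubospec gen-synthetic | simulate-linear | simulate-2dir | fit-2dir |
fit-decay | cd2ord | mix-species | run`).

## Acceptance script

`scripts/acceptance.py` recomputes the analysis end-to-end from scratch:
the three-resonance round-trip fit on freshly generated noisy data (fitted
ω₀₁, Δ₁, τ_c, T₂*, weight and ω₁₂ of the dominant resonance), the
replicate-mean biexponential population lifetime and rotational anisotropy
time from synthetic pump-probe traces, and the position of the linear
absorption maximum. Run it as

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(≈2 minutes on one CPU; all randomness derives from `--seed`).
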