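# Methods

## The measurement model

A birefringent retarder of retardance `λ0 = δn·d` placed between aligned
linear polarisers (a Lyot interferometer) transmits

    T(λ) = cos²(π λ0 / λ),

which is a pure cosine in optical frequency: with `Λ = 2π λ0 / c` and
`ν = c/λ`, `T(ν) ∝ 1 + cos(Λν)`. Varying the retardance tunes the
modulation frequency, so cheap polarisation optics realise a family of
cosine spectral modulation functions without custom dielectric coatings.

The package models two single-shot readout geometries.

**Mosaic-camera configuration** (the default): one input linear polariser,
two identical retarders with extraordinary axes at 45° and 0°, and a
division-of-focal-plane polarisation camera whose 2×2 superpixels analyse at
0°, 45°, 90° and 135°. For polarised input flux `I(ν)` the four sub-images
are

    I0   = ∫ I/2 (1 + cos Λν) dν      I90  = ∫ I/2 (1 − cos Λν) dν
    I45  = ∫ I/4 (3 − cos 2Λν) dν     I135 = ∫ I/4 (1 + cos 2Λν) dν

and the per-pixel spectral modulation vector (SMV) is

    V1 = (I0 − I90)/(I0 + I90) = ⟨cos Λν⟩
    V2 = (I45 − I135)/(I45 + I135) = ⟨sin² Λν⟩,

the normalised projections onto the modulation pair {cos Λν, sin² Λν}
(sin² is itself a shifted cosine at 2Λ, so the pair is orthogonal over full
periods). A monochromatic sweep of the SMV traces the parabola
`V2 = 1 − V1²` — the instrument's "rainbow response curve".

**Four-detector configuration**: a polarising beamsplitter feeds two
parallel Lyot arms with retardances λ0 and 2λ0; both outputs of each arm are
detected, so nothing is lost and the SMV pair is {cos Λν, cos 2Λν}.

Both channel models are verified against an independent Jones-calculus
oracle that propagates the field through explicit per-wavelength 2×2
retarder matrices and analyser projections; the two routes share no algebra
and agree to ~1e-12 relative.

### SMVs, mixing and unmixing

For modulation functions `P_k` bounded by [−1, 1], every SMV component of a
non-negative spectrum lies in [−1, 1], and the SMV of a sum of spectra is
the power-weighted mean of the component SMVs. That linearity is the basis
of the analysis module: polygonal gates in the (V1, V2) plane classify
pixels by spectral signature independent of brightness, and a pixel's SMV
can be decomposed exactly onto K ≤ 3 reference SMVs by solving
`Σ f_k R_k = V, Σ f_k = 1`. Non-negativity is imposed by clipping and
renormalising by default; a simplex-constrained NNLS variant is available.
The pseudocolour synthesis divides each component intensity
(`f_k × total`) by its mean over a user-declared white-reference region and
rescales jointly to [0, 1]; this white-balance recipe is this package's own
convention (the general idea — balancing against the illumination light —
admits several formulas).

## Numerical conventions

* **Quadrature.** All modulation integrals are defined in frequency and
  evaluated by the exact substitution ν = c/λ, so the quadrature runs as a
  trapezoid on the (typically uniform) wavelength grid; the Jacobian is
  absorbed by the substitution. On a uniform grid the trapezoid error for
  smooth band-limited spectra is at the 1e-15 level (Euler–Maclaurin
  boundary terms cancel); the Gaussian characteristic-function closed form
  `V1 = cos(Λν0)·e^{−Λ²σ²/2}` is reproduced to ~1e-16 at 0.1 nm sampling.
* **Validity masking.** The SMV ratio is undefined at zero power. Pixels
  with total intensity below `max(abs_threshold, rel_threshold × image max)`
  (defaults 0 and 1e-3) or with a vanishing ratio denominator are masked,
  never clamped or propagated as non-finite.
* **Demosaicking.** Superpixel extraction (each channel read from its one
  site per 2×2 block, half resolution) is the default and is the exact
  inverse of the mosaic interleave; interpolating demosaics are deliberately
  not implemented to keep the channel ratios bit-faithful.
* **Orthogonality reporting.** `check_orthogonality` returns window-*mean*
  inner products (the frequency integral divided by the window width) so
  entries are O(1) regardless of the Hz scale. Over an integer number of
  base periods the off-diagonals vanish (< 1e-15 observed); over the
  instrument's finite 450–650 nm band — about 0.23 of a base period at
  λ0 = 335 nm — orthogonality is only approximate, so the function reports
  the matrix with an `exact_window` flag rather than asserting zeros.
* **Retardance fit.** `fit_retardance` fits `V1(λ) = cos(2πλ0/λ)` by least
  squares. The cost is oscillatory in λ0, so a 1 nm grid scan over
  50–2000 nm seeds a Levenberg–Marquardt refinement; the reported standard
  error is the Gauss-Newton covariance at the optimum. On an ideal sweep the
  recovery is exact to < 1e-6 nm; a 3 nm-bandwidth sweep biases the estimate
  by ~0.1 nm (see bandwidth bias below).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| retardance λ0 | 335 nm | optical path difference of each retarder; a half-wave plate cut for 670 nm. Sets Λ = 2πλ0/c. Higher λ0 → finer spectral resolution, shorter unambiguous range. |
| wavelength grid | 450–650 nm @ 0.5 nm | the visible band the mosaic camera supports well |
| extinction ratio | ∞ (ideal) | analyser contrast; finite values mix each channel with its crossed partner `(ER·I∥ + I⊥)/(ER+1)`. Real mosaic sensors roll off towards ~100:1 at the red end. |
| mosaic layout | [[90, 45], [135, 0]]° | 2×2 superpixel assignment; the four angles are fixed, their geometric arrangement is configurable |
| photon_scale / read_noise_sd | None / 0 | sensor noise: Poisson counts at `photon_scale × intensity`, plus Gaussian read noise; seeded |
| validity rel_threshold | 1e-3 | fraction of the image maximum below which SMV pixels are masked |

Over 450–650 nm with λ0 = 335 nm the phase δ = 2πλ0/λ spans ≈ 3.24–4.68 rad,
so V1 = cos δ runs from −1 (at 670 nm, outside the band) up to −0.035 at the
450 nm edge; the V1 = 0 crossing of this retardance lies at 4λ0/3 ≈ 446.7 nm,
just blueward of the band. The in-band response curve therefore covers the
left half of the parabola, with V2 → 0.9988 (not exactly 1) at the blue edge.

### Finite-bandwidth bias

A narrowband line of frequency SD σν departs from the monochromatic
parabola at second order: `V2 − (1 − V1²) = −(Λσν)² sin² δ`. For a 3 nm
FWHM line this reaches −1.75e-4 at 450 nm and falls below 1e-5 beyond
~560 nm. The test suite asserts this closed form rather than treating the
deviation as error.

## What the synthetic scenes emulate — and what they do not

`make_two_fluorophore_scene` emulates a fluorescence field of view: disk or
ellipse blobs of two Gaussian-band emitters (means 540 and 600 nm, SD
15 nm) on a spatially uniform dim background (mean 500 nm, SD 40 nm at 5% of
the blob photon budget), with ground-truth labels and per-pixel photon
fractions. `make_absorption_scene` emulates transmitted-light histology: a
flat illuminant attenuated by Beer–Lambert absorption from three synthetic
Gaussian-band chromophores with smooth random optical-density fields, plus
an unstained strip for white balance. Both are pure functions of
(seed, parameters).

The emitter and chromophore spectra are stand-ins chosen for realistic band
positions and overlap, not reproductions of any measured fluorophore or
stain; real data additionally carry optical blur, sub-image registration
error, flat-field structure, analyser extinction roll-off with wavelength,
retarder dispersion (δn varying with λ) and sensor dark current, none of
which the generators include (finite extinction ratio is modelled, the rest
are out of scope). Passing tests therefore demonstrate correctness of the
modulation/estimation chain under the stated noise model — shot noise plus
read noise — not performance on hardware frames.

Default study conditions used by the deeper tests: 128×128 pixels, 10⁴
expected photons per blob pixel, five blobs per class. At that budget the
three SMV clusters are separated by ~0.3–0.4 in the SMV plane against
per-pixel noise SDs of ~0.01 (blobs) and ~0.05 (dim background), so square
gates of half-width 0.13 around the ground-truth centroids recover the class
map with ≳ 99% agreement; the acceptance threshold is 95%.

## Known limitations

* Retarder dispersion neglected: the phase is exactly δ = 2πλ0/λ.
  Real polymer/quartz retarders deviate at band edges.
* The wavelength → SMV map is only invertible within a monotonic sub-band;
  no phase unwrapping is attempted.
* SMV linearity holds for emission/transmission intensities; Beer–Lambert
  absorption is nonlinear in concentration, so unmixing of absorption
  scenes onto fixed-OD references is approximate (the tests assert dominant-
  component majority, not exact fractions).
* The two-shot variable-retarder variant, true sine/cosine phasor optics
  with achromatic quarter-wave plates, and polarisation-anisotropy readout
  are not modelled.
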