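# polspec

Simulation and analysis of **polarisation-based single-shot hyperspectral
imaging**. Instead of resolving a full spectrum per pixel, the instrument
passes light through birefringent retarders between polarisers (Lyot-type
interferometers), producing transmission functions that are cosines in
optical frequency, and reads the result with a polarisation-mosaic camera.
Each pixel then yields a compact **spectral modulation vector (SMV)**

    V_k = ∫ I(ν) P_k(ν) dν / ∫ I(ν) dν,

the normalised projection of its spectrum `I(ν)` onto orthogonal modulation
functions `P_k` — here the pair {cos Λν, sin² Λν} with `Λ = 2πλ0/c` set by
the retardance λ0. SMVs generalise the spectral phasor: they are bounded,
intensity-normalised, and mixtures combine linearly, so spectral
classification (polygon gating) and linear unmixing onto reference SMVs
work directly in the 2-D SMV plane at a fraction of a hyperspectral cube's
data volume.

The package is aimed at people designing or validating such instruments —
it contains the physics forward model (channel integrals, an independent
Jones-calculus oracle, a 2×2 polariser-mosaic sensor with Poisson/read
noise and finite extinction ratio), seeded synthetic fluorescence and
transmitted-light scenes, instrument-response calibration against a
narrowband sweep, and the SMV-space gating / unmixing / pseudocolour
analysis chain. No hardware is required.

## Worked example

```python
import numpy as np
import polspec as ps

grid   = ps.default_grid()        # 450-650 nm @ 0.5 nm
config = ps.InstrumentConfig()    # mosaic camera, retardance 335 nm
mods   = ps.ModulationSet()       # {cos, sin^2} modulation pair

# a 3 nm narrowband line at 550 nm through the forward model
line = ps.make_narrowband(550.0, 3.0, grid)
channels = ps.polarsens_channels(line, config)
print({k: round(float(v), 4) for k, v in channels.channels.items()})
# {'I0': 0.113, 'I90': 0.887, 'I45': 0.7004, 'I135': 0.2996}

v = ps.compute_smv(line, mods)
print(np.round(v, 4))             # [-0.7741  0.4007]
```

The four channel integrals sum in complementary pairs to the unit input
power, and the SMV sits on the instrument's theoretical response parabola
`V2 = 1 − V1²` to within the finite-bandwidth bias (−3.1e-5 here).

Calibrating the retardance from a simulated 41-point sweep:

```python
sweep  = np.linspace(450, 650, 41)
frames = [(lam, ps.polarsens_channels(ps.make_narrowband(lam, 3.0, grid), config))
          for lam in sweep]
fit = ps.fit_retardance(ps.measure_irf(frames))
print(fit.summary())
# Retardance calibration (V1 = cos(2*pi*lambda0/lambda))
#   points:          41
#   retardance (nm): 334.9548 +/- 0.0296
#   residual norm:   1.011e-02
```

The recovered retardance is 334.95 ± 0.03 nm against the true 335 nm; the
0.05 nm shortfall is the known 3 nm-bandwidth bias, not noise.

End-to-end classification of a seeded synthetic fluorescence scene
(two emitter classes plus dim background, 128×128, 10⁴ photons/pixel):

```python
scene = ps.make_two_fluorophore_scene(seed=21, photon_budget=1e4)
ch    = ps.render_scene(scene, config, "unpolarised")
raw   = ps.mosaic_and_noise(ch, config, photon_scale=1.0, seed=21)
img   = ps.smv_from_polarsens(ps.demosaic(raw))
gates = [ps.box_gate(name, tuple(ps.compute_smv(
            ps.Spectrum(scene.grid, scene.cube[scene.labels == t][0]), mods)), 0.13)
         for name, t in [("fluor_a", 1), ("fluor_b", 2), ("background", 0)]]
labels, legend = ps.classify(img, gates)
# pixel agreement with ground truth: 0.9974
```

The three spectral components form separated clusters in the SMV plane and
square gates around the ground-truth centroids reproduce the class map with
99.7% pixel agreement despite shot noise and the 50% input-polariser loss.

## Command line

```sh
polspec simulate --config run.json --outdir out   # scene + channels + mosaic TIFFs
polspec smv out/mosaic.tif --outdir out           # demosaic + SMV image
polspec irf --n-points 41 --outdir out            # sweep + retardance calibration
polspec analyse out/smv.tif --gates gates.json --refs refs.json --outdir out
polspec fixtures --seed 1                         # standard synthetic scenes
```

All rasters are TIFF with JSON sidecars; every run writes its resolved
configuration and seed next to the outputs.

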