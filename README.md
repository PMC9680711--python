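# sofikit

Super-resolution optical fluctuation imaging (SOFI) analysis in Python:
temporal moment/cumulant reconstruction of blinking-fluorophore movies,
Fourier interpolation onto finer pixel grids, temporal noise filtering,
local dynamic range compression (ldrc), photobleaching correction, and a
blinking-emitter movie simulator with ground truth.

## The problem and who this is for

Wide-field fluorescence microscopy is diffraction-limited, but fluorophores
that stochastically switch between a bright "on" and a dark "off" state
carry extra information in their temporal fluctuations. SOFI exploits it:
for a sample of N independently blinking emitters the camera signal at
pixel r is

    F(r, t) = Σₖ εₖ bₖ(t) U(r − rₖ),

with εₖ the on-state brightness, bₖ(t) ∈ {0, 1} the blinking trace and U
the point spread function (PSF). The n-th order temporal cumulant of the
fluctuation δF = F − ⟨F⟩ₜ, computed per pixel at zero time lag, is

    Cₙ(r) = Σₖ εₖⁿ ωₙ(ρₖ) Uⁿ(r − rₖ),

i.e. an image taken with the PSF raised to the n-th power — a Gaussian PSF
becomes √n-fold narrower — and "virtual" emitter brightnesses εₖⁿ ωₙ(ρₖ),
where ωₙ is the n-th cumulant of the Bernoulli blinking marginal with
on-time ratio ρₖ (ω₂ = ρ(1−ρ), ω₃ = ρ(1−ρ)(1−2ρ),
ω₄ = ρ(1−ρ)(1−6ρ+6ρ²)). Because ωₙ changes sign with ρ, high-order images
can contain adjacent positive and negative virtual emitters (cusp
artifacts), and naive reconstructions are distorted by photobleaching and
by the enormous dynamic range of n-th-power brightnesses. The package is
aimed at microscopists processing blinking-fluorophore movies (e.g.
Dronpa-labelled live cells) and at method developers who need a tested,
scriptable SOFI stack with a simulator for validation.

Cumulant images are built from centered moment images G₁…Gₙ with the
recursion

    Cumₙ = Gₙ − Σᵢ₌₁ⁿ⁻¹ C(n−1, i) · Cumₙ₋ᵢ · Gᵢ,

evaluated pixel-wise in ascending order (and invertible, moments from
cumulants). On top of this the package provides:

- **Fourier interpolation (FI)** — trigonometric upsampling of each frame
  onto a grid `factor·(n−1)+1` points per axis, built from an explicit
  inverse-DFT matrix evaluated at fractional coordinates (no zero-padding);
  exact on band-limited signals and at original grid points.
- **Temporal noise filtering** — pixel-wise Gaussian convolution along a
  series of per-block reconstruction images (unit-sum kernel, mirror
  boundary), suppressing block-to-block statistical noise without spatial
  blurring.
- **ldrc** — a 20×20 (configurable) window scans the image with stride 1;
  each window is linearly rescaled to the local [min, max] range of a
  reference image (the temporal mean or a 2nd-order image); overlapping
  rescalings are averaged. Compresses the dynamic range while preserving
  structure.
- **Bleaching correction (BC)** — the movie is split into blocks within
  which the smoothed total signal I(t) decays by the same fraction fbc;
  each block is reconstructed independently (centering removes the local
  trend) and the per-order images are averaged.
- **Simulator** — two-state Markov blinking with exact stationary marginal
  ρ, Gaussian PSF, optional exponential photobleaching and camera noise,
  returning the blink traces as ground truth; includes the reference scenes
  (51-emitter semicircle with ρ ramping 0.01→0.99, 3 close emitters,
  20×200-frame block series).

## Worked example

Simulate a single emitter blinking with on-time ratio ρ = 0.3 and recover
its virtual brightness from the cumulant images:

```python
import sofikit as sk

# one blinking emitter, rho = 0.3, eps = 100 photons/frame, sigma = 1.5 px
field = sk.EmitterField(positions=[(10.0, 10.0)], brightness=100.0, on_ratio=0.3)
movie, truth = sk.simulate_movie(field, sk.PsfModel(sigma=1.5),
                                 frames=20000, shape=(21, 21), seed=7)
print(f"empirical on-fraction: {truth.on_fraction()[0]:.4f}")

cums = sk.cumulants_from_moments(sk.calc_moments_set(movie, highest_order=4))
for n in (2, 3, 4):
    rho = 0.3
    omega = {2: rho*(1-rho), 3: rho*(1-rho)*(1-2*rho),
             4: rho*(1-rho)*(1-6*rho+6*rho**2)}[n]
    print(f"order {n}: peak {cums[n][10,10]:12.1f}   "
          f"predicted eps^n*omega_n = {100.0**n*omega:12.1f}")
```

```
empirical on-fraction: 0.2928
order 2: peak       2070.7   predicted eps^n*omega_n =       2100.0
order 3: peak      85809.0   predicted eps^n*omega_n =      84000.0
order 4: peak   -5019517.7   predicted eps^n*omega_n =   -5460000.0
```

The peak of each cumulant image matches εⁿωₙ(ρ)·Uⁿ(0) up to sampling error
(the trace ran at 29.28% on instead of exactly 30%); the 4th-order peak is
*negative* because ω₄ < 0 for 0.211 < ρ < 0.789 — the origin of cusp
artifacts in high-order SOFI.

The same operations are available from the shell:

```sh
sofi simulate --scene semicircle --frames 2000 --seed 1 --out scene.tiff
sofi cumulants scene.tiff --highest-order 4 --bleach-correction --fbc 0.04 --smooth-kernel 251
sofi finterp scene.tiff --factors 2 --factors 4 --frames 0 100
sofi sofi2 --blocks 'Block*.tiff' --order 6 --kernel-length 21 --sigma 2 --window 20 20
```

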