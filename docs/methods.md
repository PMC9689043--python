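# Methods

`lusim` simulates the two canonical lung-ultrasound artifacts — the
horizontal A-lines of a healthy, aerated lung surface and the vertical
B-lines associated with fluid-infiltrated subpleural tissue — from first
principles: a randomized tissue phantom, 2D linear acoustics, a swept
linear-array acquisition, and a standard B-mode imaging chain.

## Physical model

The imaged scene is a chest-wall muscle slab of width W = 50 mm and
thickness L = 10 mm, viewed from below by a linear array on the skin
face. Healthy aerated lung above the slab reflects essentially all
incident energy (its impedance is ~0.17 Mrayl against ~1.7 Mrayl for
muscle), so it is not meshed: the muscle/lung interface is imposed as a
pressure-release boundary (p = 0, reflection coefficient −1). The
transducer face and the domain bottom are sound-hard (zero normal
velocity); the lateral sides carry 5 mm perfectly-matched-layer (PML)
strips so the finite width does not reverberate.

Disease is modeled as an elliptical lung disease zone (LDZ) of
fluid-infiltrated tissue touching the pleural boundary: height 5 mm, and
length 10 mm (variant A), 4 mm (variant B) or 1 mm (the 4 MHz narrow
variant).

### Randomized inhomogeneous materials

Each tissue's sound speed and density fluctuate via a bounded random
field built as a sum of cosine modes

    f(x, y) = Σₘ aₘ cos(2π(kₓₘ x + k_yₘ y) + φₘ),

with radial spatial frequency uniform in [k_min, k_max], isotropic
directions, amplitudes uniform in (0, 1] and phases uniform in [0, 2π),
rescaled so max |f| = 1 (sign chosen to make the peak positive; the
ensemble is sign-symmetric). The default band takes k_max = 2 f₀ / c_water
— a correlation length of about half a wavelength at the center
frequency — which produces sub-wavelength scatterers; the band is
configuration, not physics, and is exposed as `FieldSpectrumParams`.

Material maps are affine in the field:

* LDZ: v = 1070 + 430 f m/s, ρ = 715 + 285 f kg/m³, spanning a 60 %-air
  mixture (640 m/s, 430 kg/m³) to pure water (1500 m/s, 1000 kg/m³).
* muscle: v = 1570 + G g m/s, ρ = 1090 + G g kg/m³, with the
  inhomogeneity level G ∈ {0, 5, 10} applied with the same numeric value
  to both quantities, as the model prescribes.

The muscle field g is drawn independently of the LDZ field f and its
x-wavenumbers are divided by an anisotropy ratio (default 4) so the
texture stretches horizontally like muscle fiber. Velocity and density
share one field per tissue, so impedance fluctuations are maximal —
the model's intent for strong multiple scattering in the LDZ.

## Wave solver

The first-order variable-density acoustic system

    ∂p/∂t = −ρc² ∇·u,   ∂u/∂t = −(1/ρ) ∇p

is integrated on a staggered grid (p at cell centers, u, v on edges) with
2nd-order leapfrog time stepping and 4th-order spatial differences in the
interior (2nd order in the cells adjoining boundaries). Density is
averaged harmonically onto edges. The lateral strips use a split-field
PML, polynomial grading of order 3, sized for 60 dB target round-trip
attenuation; damping is applied as an exponential factor per step.

Grid spacing resolves the slowest medium present (640 m/s with an LDZ,
1570 m/s without) at ≥ 10 points per wavelength of f₀ by default (8 at
desk scale). The internal time step subdivides the 0.02 µs output
interval to satisfy the CFL bound at cfl_number 0.5; output samples are
taken exactly on internal steps (no interpolation). The measured
stability edge sits at about 6/7 of the 2nd-order CFL bound, matching
the 4th-order stencil's coefficient sum, so 0.5 leaves a wide margin.

Sources are additive ("soft") pressure injections at the cells spanned by
a driven element, scaled by dt_internal/dt so results are invariant under
substepping; element recordings are the arithmetic mean of pressure over
the element's cells per output sample. Amplitudes are arbitrary units —
the chain is linear and all reported scores are ratios.

Solver correctness is pinned by oracle tests rather than by comparison to
any particular reference engine: point-to-point travel time against d/c,
normal-incidence reflection against (Z₂−Z₁)/(Z₂+Z₁) on a quasi-1D
two-layer column, sign inversion at the pressure-release top,
reciprocity, linearity, energy decay with absorbing strips, grid
convergence of arrival times, and a < −30 dB PML return.

## Acquisition

A 32-element array spans the 50 mm slab (pitch 1.5625 mm; element width
0.8 × pitch — element size and pitch are package choices, constrained
only by the 32 elements spanning the 50 mm slab). Transmissions use 5-element
subapertures stepping one element at a time: 28 scan lines, 28 × 32 = 896
traces of 2500 samples. The excitation is a Gaussian-windowed sine burst
(σ = 1.5/f₀ ≈ three cycles) and each aperture applies the focal delay law
B(i) = (max_j path_j − path_i)/c_ref with path_i = √(z_f² + x_i²),
z_f = 10 mm, c_ref = 1570 m/s: outer elements fire first and all wavelets
arrive at the focus simultaneously.

## Imaging

Each scan line is formed from its transmit subaperture's traces with
fixed-focus receive delay-and-sum (the mirror of the transmit law; no
dynamic focusing, no apodization, no time-gain compensation). Two chain
orders exist:

* `log_first` (display default): sign-preserving log amplification
  y = sign(x) log₁₀(1 + |x|/x_ref) with x_ref = dataset peak / 10³,
  then Hilbert envelope, then delay-and-sum of envelopes;
* `conventional`: delay-and-sum of raw RF, then Hilbert envelope.

Lines are laterally interpolated (endpoint-preserving linear, factor 4:
28 lines → 109 columns), peak-normalized, and displayed over a 50 dB
dynamic range. The depth axis is c_ref (t − t₀)/2 with t₀ the emission
reference (pulse envelope center + focal-law span); with it the pleural
band maps to the 10 mm slab thickness.

Quantitative artifact scoring always uses the conventional chain even
when the display uses the compressed one: measured on this simulator, the
log-first chain at the default compression washes the inside/outside
contrast of the vertical artifact down to near 1 and distorts
linear-intensity statistics, which makes it unsuitable as a measurement
domain (it remains faithful as a display).

## Artifact metrics

* **Echo train** — peaks of the envelope of a single element's RF above a
  threshold fraction (default 0.1) of the post-transmit maximum, with a
  dead time excluding the drive pulse. In a healthy slab the spacing
  matches the round trip 2L/c = 12.74 µs.
* **Reverberation bands** — prominent maxima of the laterally averaged
  linear image intensity (prominence ≥ 0.2 of the profile range, ≥ 4 mm
  apart, beyond a 4 mm dead zone), computed over columns away from the
  LDZ so a stripe cannot mask them. The first band is the pleural line.
* **B-line score** — inside/outside ratio of mean linear intensity below
  the pleural line, with the band rows (±2 mm) excluded. The bands are
  horizontal artifacts common to every column; what makes a B-line is the
  continuous inter-band fill, and excluding the bands isolates exactly
  that. The outside reference starts one half-aperture beyond the LDZ
  edge, clearing the imaging system's lateral spill. `bline_width` is
  the lateral extent of columns whose inter-band mean exceeds the
  midpoint between the inside and outside means.

All thresholds above are design targets of this package.

## Scales

`full` scale retains the complete setup (50 × 10 mm, 32 elements, 28
sweeps, 50 µs, 10 ppw); one image costs tens of minutes on one CPU.
`desk` scale preserves every mechanism — same equations, material ranges,
boundary conditions, pulse and focal law — in a 32 × 10 mm domain with 20
elements, 16 sweeps, 30 µs and 8 ppw, a few minutes per image. The desk
domain is deliberately wider than a minimal reduction: variant A's 10 mm
LDZ needs a reference corridor wider than the beam spill on both sides
for inside/outside scores to mean anything. Echo-train (A-line) runs keep
the 50 µs window even at desk scale because the third reverberation echo
arrives at ≈ 40 µs; they are cheap since a homogeneous slab allows the
coarse grid.

## What the synthetic phantoms do not capture

The generator emulates sub-wavelength random scattering in fluid-mixed
lung and fibrous muscle texture; it does not model ribs and their
shadows, frequency-dependent absorption, nonlinearity, elastic shear,
3D out-of-plane scattering, or physiological motion. Passing tests show
the artifact *mechanisms* (reverberation between face and pleura;
trapped multiple scattering acting as a persistent secondary source)
reproduce under controlled 2D conditions — not that the simulator
predicts clinical image appearance.

## Degenerate inputs and numerical choices

Zero-length LDZ degrades to a pure muscle slab (empty mask). An all-zero
RF dataset maps to a uniform image at the dynamic-range floor and the log
amplifier passes it through unchanged. Non-finite fields abort the solver
with the failing step index. Fractional-sample beamform shifts use linear
interpolation with zero fill; delays beyond the trace length simply
truncate. Tie-breaks in peak detection follow `scipy.signal.find_peaks`
ordering (first-in-depth wins for the pleural line).
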