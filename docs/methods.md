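# Methods

`sweptsa` implements constrained swept synthetic aperture (SSA) ultrasound
imaging end to end: it simulates interleaved plane-/diverging-wave channel
data from a small phased array translating laterally, estimates the
transducer trajectory from the data themselves, beamforms the synthesized
large aperture, and quantifies resolution and lesion detectability.  This
note records the models, the parameters that matter, and the numerical
choices made where the design was genuinely open.

## Acquisition model

The array is a P4-2v-style phased array: 64 elements, 0.3 mm pitch
(18.9 mm element-center extent, 19.2 mm footprint), 3 MHz center frequency,
80% fractional bandwidth, c = 1540 m/s.  Coordinates are right-handed with
lateral x along the element row (positive in the sweep direction) and axial
z into the medium; the array center at the first frame is the world origin.
Angles are radians; all internal quantities are SI.

Each repetition of the interleaved sequence contains an unsteered plane
wave (for tracking) followed by one or two diverging waves (for imaging),
260 µs apart, at a 500 Hz repetition rate.  Diverging waves use an
11-element subaperture with transmit f-number −0.75, i.e. a virtual point
source 2.475 mm behind the subaperture center; the `left_right` sequence
fires from the two array ends, extending the synthesized transmit aperture
by roughly a transducer length.  Sweep trajectories are `constant` (uniform
velocity) or `smoothstep` (cubic 3s² − 2s³ ease emulating a manual sweep
with zero end velocity).  Frame timestamps are the time of the frame's
first event; every event's pose is interpolated from the trajectory at its
own absolute time.

## Field simulator

A linear point-scatterer model replaces a full spatial-impulse-response
simulator.  Each scatterer contributes to each receive element an echo pulse
delayed by (transmit path + element distance)/c and scaled by the scatterer
reflectivity, 1/r receive spreading, and the element directivity (hard
baffle strip of width = pitch: sinc × cosine, the default).  The pulse is a
Gaussian-windowed sinusoid whose −6 dB (two-way) fractional bandwidth is
0.8.  The pulse is evaluated through a dense lookup table (step 1/(256 f0),
interpolation error below −80 dB) at the continuous arrival time and sampled
directly at the 20 MHz output rate, which is equivalent to ideal
band-limited recording: no delay quantization enters the data.  The model is
exactly linear in the scatterers and exactly translation-equivariant
(simulating pose +d equals shifting the world by −d), which is the physical
basis of both motion estimators and is enforced by property tests.

Plane-wave transmits are aperture-limited: a scatterer is insonified only
when its back-projection along the steering direction lands on the element
footprint, with a 2 mm smoothstep rolloff standing in for edge diffraction.
Without this, a plane-wave model would insonify a target from ±45° and the
compounded reference image could not show the aperture-limited resolution a
real small array produces.  Diverging transmits use the virtual-source
convention τ = (‖p − vs‖ − d_vs)/c (t = 0 when the wavefront crosses the
array plane); the same shared function drives simulation and beamforming, so
the two cannot drift apart.  Attenuation, nonlinearity and elevation
focusing are not modeled.

Speckle phantoms draw a Poisson number of uniformly distributed scatterers
with i.i.d. standard-normal reflectivities, at 15 scatterers per resolution
cell; the cell defaults to λ/2 axially × λz/D laterally evaluated at 60 mm
depth for the ~70 mm effective swept aperture (0.257 × 0.44 mm), times the
elevation slab height when a 3-D slab is requested.  Anechoic lesions are
carved out as spheres; point targets are appended 40 dB above the speckle
RMS.  Band-limited channel noise is white Gaussian noise band-passed to the
pulse band and scaled so the signal-to-noise power ratio inside the axial
window at the estimation depth matches the requested channel SNR.

## Motion estimation

Both estimators compare plane-wave frames, whose transmit field is (by
construction) translation invariant, so the scene's apparent motion is the
negative of the transducer motion.

**Speckle tracking** beamforms each plane-wave frame on a fixed
array-local Cartesian grid (lateral pixel λ/4 ≈ 0.13 mm, axial λ/8),
envelope-detects, and laterally correlates a 10 × 10 mm kernel at 20 mm
depth (zero-mean normalized cross-correlation) against the next frame over
a ±2.5 mm search.  **Channel correlation** skips beamforming entirely: for
integer element shifts k up to ±10 (±3 mm) it correlates the axially
windowed raw RF (same 10 mm window at 20 mm depth) of elements [k:] of one
frame against elements [:N−k] of the other, producing a correlation curve
sampled at the element pitch.

Sub-sample peaks are found by band-limited reconstructive interpolation: a
sinc-basis reconstruction of the sampled curve maximized by bounded scalar
search to 1e-4 sample.  A three-point parabolic fit is available as a
fallback for spatially aliased data, but is markedly worse here (~19 µm vs
~4 µm cyclic error for channel correlation).  A peak on the search boundary
raises an error instead of returning an unreliable estimate.

Pairwise estimates from every frame pair up to 10 frames apart are fused by
weighted least squares: each row of H is a position difference, Y the
observed displacement, and W the peak correlation coefficient (clipped to
[0, 1]).  The difference operator annihilates constants, so the printed
normal equations are singular; the gauge is fixed by anchoring frame 0 at
position 0 (SSA needs only relative positions).  A disconnected pair graph
is reported as an error naming the components.  Plane-frame estimates are
linearly interpolated to the diverging-event times.

### Numerical choices that proved load-bearing

Three implementation details, each chosen after measuring estimator bias on
simulated data, matter at the micrometer scale:

* **Tapered dynamic receive aperture.**  Tracking images use a dynamic
  f/1.5 receive aperture with a Tukey(0.5) taper.  A *hard* aperture edge —
  whether the moving dynamic-aperture edge or the static array end —
  imprints a pitch-periodic texture on the speckle (the 0.3 mm pitch
  slightly undersamples the λ/2 = 0.26 mm field) and biases sub-pitch
  tracking by 6–13 µm; a full *static* aperture instead makes the imaging
  operator laterally space-variant, which pulls every pair estimate toward
  zero by ~0.1% of the displacement and integrates to tens of µm of drift
  over a 50 mm sweep.  The tapered dynamic aperture removes both effects.
* **Tapered channel overlap.**  Channel correlation applies the same
  Tukey(0.5) window across the overlapped element subsets before
  correlating; the hard subaperture edge otherwise aliases the
  pitch-sampled coherence function (cyclic error up to ~6 µm, reduced to
  ~4 µm).
* **Baseband delay interpolation.**  The beamformer linearly interpolates
  the baseband-demodulated analytic signal and restores the carrier phase
  at the exact delay.  Interpolating the 3 MHz carrier directly at 20 MHz
  sampling leaves a delay-dependent ripple that biases speckle tracking by
  several µm.

The search region must also keep the correlation peak away from its
boundary: a peak within ~0.5 mm of the search edge is biased inward by the
truncated sinc reconstruction, so sweep-scale studies size the search as
the maximum multi-lag pair displacement plus a 2 mm margin.

## Beamforming

All beamforming is delay-and-sum on the analytic signal, so frames combine
coherently and the envelope is the pixel magnitude.  Plane-wave images form
in array-local coordinates; diverging frames acquired along the sweep are
focused in world coordinates at their (true or estimated) pose, with the
virtual source and elements translated together.  Fractional delays use the
baseband-linear interpolation above; samples outside the record contribute
zero.

SSA reconstruction resamples repetitions greedily to ≥0.5 mm spacing
(collapsing stationary segments), beamforms each retained diverging frame at
its own pose, coherently combines left/right transmissions, and weights
frames with a Tukey window (ratio 0.25, configurable) across the sweep
position axis to suppress the high spatial frequencies of the sparsely
synthesized transmit aperture.  The window is evaluated on the position span
padded by half a frame spacing so end frames keep nonzero weight; a
single-frame "sweep" degenerates to a scaled single-frame image.  The
effective-aperture diagnostic reports the average of the receive span
(sweep + footprint) and transmit span (sweep + distance between edge
virtual sources).

A reference image compounds steered plane waves (default −45°…45° at 1°)
from a single position.  The equivalent large-array benchmark simulates
full synthetic-aperture acquisition from a static 70 mm array (transmits
limited to the central 50 mm, every 2nd element: 0.6 mm transmit sampling,
comparable to the 0.5 mm SSA resampling).

## Metrics

Lateral PSF: envelope peak located near the nominal point position, lateral
slice through the peak depth, normalized to 0 dB; FWHM from the
half-amplitude (−6.02 dB) crossings by linear interpolation.  gCNR: 1 minus
the overlap of the two regions' envelope histograms on 256 equal-width bins
spanning the pooled min–max; it is bounded in [0, 1] and invariant to any
common affine rescaling of both regions (the bin edges are data-driven),
but not to general monotone transforms.  Lesion ROIs are an inner disk
1 mm inside the lesion radius and an annulus from 1 to 3 mm outside it.
Trajectory errors are summarized per frame (estimated − truth, both
anchored at frame 0) as bias, population sd, RMSE and max |error|.

## Study conditions and problem sizes

The study runners simulate everything they consume.  Scatterer slabs are
2-D (elevation collapsed — a config choice of the phantom builder) and span
only the depth band each study interrogates (13–27 mm around the 20 mm
tracking depth), at the full 15 scatterers per resolution cell; lateral
extent covers the sweep plus the insonified margin.  The 50 mm sweep study
runs at 0.2 mm repetition spacing (250 repetitions over 1 s) with the
tracking slab for plane frames and the point target at 100 mm for the
diverging frames — a valid decomposition because the model is linear and
the two scenes' echoes occupy disjoint record windows.  The sub-pitch study
uses 0.03 mm steps to one pitch over 10 speckle realizations; the
robustness study uses 0.1 mm steps to 5 mm (±7.5 mm speckle search), with
0 dB channel SNR for the noise arm and assumed sound speeds 1240–1840 m/s
(true 1540) for the sound-speed arm.  These sizes run the full acceptance
pipeline in roughly ten minutes on one CPU.

What passing these studies does and does not show: the generator reproduces
fully developed speckle, the aperture geometry, pulse bandwidth and
band-limited noise — the quantities that govern correlation-based tracking
and lateral resolution — but not elevation focusing, reverberation,
attenuation, phase aberration or tissue inhomogeneity, so the µm-level
error bounds demonstrated here are a best case relative to in vivo data
(the cited phantom experiments observe larger errors through real media).

## Known limitations

* The far-field point-element model slightly overestimates FWHM relative
  to a full aperture-integral simulator (e.g. the equivalent 70/50 mm
  array measures 0.78 mm against the 0.744 mm ideal-rect closed form).
* Motion is assumed purely lateral and in-plane; rotation and elevation
  motion are out of scope.
* Tracking from diverging-wave frames is not supported.
* gCNR values depend on binning; only orderings across conditions are
  asserted, not absolute values.
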