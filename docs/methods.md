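# Methods

`ringtomo` models a 3D breast-imaging workflow built around a 256-element
ring transducer (200 mm diameter, 3 MHz) that is lowered through the
water bath in 1.5 mm steps, acquiring a full-synthetic-aperture
pulse-echo dataset at each height. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic
studies do and do not demonstrate.

## Acquisition model

**Array and pulse.** Elements are idealized omnidirectional points spaced
equally on the ring (256 elements on a 200 mm circle give a 2.454 mm
center-to-center chord). The excitation is an `n_cycles`-period sinusoid
at the center frequency (default 5 cycles at 3 MHz, 1.67 µs). The default
simulation sampling rate is 24 MHz; the hardware preset of 11.9 MHz is
available but gives fewer than 4 samples per carrier cycle and is warned
about. Acquisition is full matrix: each element transmits in turn, all
elements record, producing an n×n×t tensor per layer.

**Born engine.** The workhorse simulator is a first-order (single
scattering) point-scatterer model: the phantom is rasterized to
sound-speed and density grids (0.3 mm step, matching the protocol's
stated grid resolution), reduced to interface voxels — voxels whose
impedance Z = ρc differs from a face neighbor and from the ambient
water — and each interface voxel re-emits the pulse with amplitude
R/(√(r_tx·r_rx) + ε), where R = (Z − Z̄_nbr)/(Z + Z̄_nbr) is the local
impedance contrast, the square-root factor is 2D cylindrical spreading,
and ε equals one grid step to regularize the on-top case. The direct
transmitter→receiver wave is added as a separately flagged component.
The engine is exactly linear in the scatterer cloud and reciprocal in
(tx, rx); both properties are asserted in tests.

**FDTD validator.** A small second-order finite-difference solver for
the 2D variable-speed wave equation (Cerjan-style exponential sponge of
20 cells, CFL limit c·dt/h ≤ 1/√2, grids capped at 300²) provides an
independent physics cross-check: echo arrival times for a weak inclusion
agree with the Born prediction within 2 samples. Note that 2D cylindrical
waves carry a genuine afterglow tail after the wavefront (the 2D Green's
function is not sharp), so "quiet after the direct arrival" is asserted
as a decaying tail with no late echo bump, not as numerical zero.

**Scanning.** A 3D phantom is scanned by geometric slicing: at each
layer height the spheres become circles of chord diameter
2√(r² − dz²), the slice is rasterized and acquired in 2D. This matches
a thin-beam acquisition idealization; out-of-plane scattering is not
modeled. Layers are generated lazily so that large-element-count scans
never hold more than one echo tensor in memory.

## Reconstruction

**Gating.** Samples earlier than the per-pair direct-arrival time
|tx − rx|/c + guard are zeroed (default guard 2 µs, just over the pulse
length). Echoes that arrive inside the guard window of a pair are lost
with it; with ≥128 elements the image is formed from the surviving
thousands of pairs.

**Beamforming.** Classical full-matrix delay-and-sum: the analytic
signal of every trace (frequency-domain quadrature) is summed at the
two-way time (|tx − p| + |p − rx|)/c_ref with linear interpolation in
time, and the pixel value is the magnitude of the complex sum,
normalized to [0, 1]. The beamforming speed is fixed at the water value
1500 m/s regardless of tissue properties, mirroring standard practice;
out-of-range delays contribute zero; images whose raw peak is below
10⁻¹²·n_pairs are left unnormalized (empty scene). An optional receive
sub-aperture (angular limit about the element opposite the transmitter)
and a coherence-weighting hook exist but are off by default.

## Preprocessing and segmentation

Tomograms are smoothed with a sampled Gaussian (σ in pixels, truncation
4σ, reflective borders; diffusion time t = 0.5σ²). Thresholding is
global: foreground where f ≥ T. T is chosen at the deepest interior
trough of the 5-bin-smoothed 256-bin histogram *between the two class
means identified by Otsu's criterion*; a trough must dip at least 10%
below both mode bins, otherwise the Otsu value itself is used and the
result is flagged. Anchoring the trough between the Otsu class means is
deliberate: the envelope histograms here are trimodal (no-signal pixels,
speckle-like clutter, bright boundaries), and an unanchored
"deepest trough between the two highest peaks" rule latches onto a dip
inside the background mode and floods the mask with clutter.

## Interlayer interpolation

Virtual slices are synthesized across the layer axis with the
cubic-convolution (Keys) kernel

    h3(z) = (a+2)|z|³ − (a+3)|z|² + 1      0 ≤ |z| < 1
            a|z|³ − 5a|z|² + 8a|z| − 4a    1 ≤ |z| < 2

with h3(0) = 1 and h3(1) = h3(2) = 0 for every a, so acquired slices are
reproduced exactly at integer layer positions. The default a = −0.5
reproduces constants and linear ramps exactly; the kernel is negative on
1 < |z| < 2 (e.g. h3(1.5, −0.5) = −0.0625). A factor-f densification of
n slices yields (n−1)·f + 1 layers at pitch/f spacing; boundary slices
are clamp-replicated.

## Surface and volume rendering

Isosurfaces are extracted with standard marching cubes (8-bit corner
index into the 256-case table, linear edge interpolation; the cell walk
is delegated to scikit-image). Vertex normals are the central-difference
gradient field, negated (pointing from high to low values, outward for
"inside ≥ c" solids) and trilinearly interpolated to the vertices.
Binary masks are pre-smoothed (σ = 1 voxel) and extracted at c = 0.5 to
avoid staircase meshes. When the iso value coincides exactly with grid
values the level is nudged by 10⁻⁶ of the data range: a corner-exact
surface would emit zero-area triangles and open the mesh (the nudge is
far below every geometric tolerance used). The conventional case table
is used without an asymptotic decider; rare ambiguous-saddle topology
errors are a known limitation.

Volume rendering is parallel-projection ray casting: equidistant samples
along each ray, trilinear value and gradient-magnitude interpolation
(gradient normalized by its 99th percentile), piecewise-linear transfer
functions for color and opacity, and front-to-back compositing with
early termination at accumulated opacity 0.99. Transfer-function opacity
is interpreted per millimeter of ray travel (each sample contributes
1 − (1 − α)^step), which makes images converge under step refinement
instead of depending on the sample count.

## Resolution metrics

Profiles are sampled bilinearly. Target diameters are estimated as the
distance between the inflection points flanking the profile peak, with
FWHM reported alongside. Inflections are located as the onset of the
significant convex lobe on each side (2% of that side's maximum positive
second derivative, after σ = 1-sample smoothing): for a Gaussian bump
this recovers the 2σ inflection distance to within a sample spacing,
and unlike a raw zero-crossing search it remains well defined on
profiles with straight flanks, where the second derivative is
numerically zero with noise-level sign flips.

Two targets are "resolved" when the profile along their joining line has
a local maximum within 35% of the line length of each end and the
interior minimum satisfies min/mean(peaks) ≤ 0.8. The criterion is
symmetric in the two probe points and is stated explicitly because the
field's usage is loose.

**Two-lesion separation d.** The separation swept in the resolution
study is interpreted as the center-to-center distance between the two
1 mm lesions. The package supports an edge-gap parameterization as well,
but simulation shows the full-ring aperture separates 1 mm lesions at
any positive edge gap (dip ratio 0.56 at a 1 mm gap), so an edge-gap
sweep terminating at 1 mm has no failure point; under the
center-to-center reading d = 1 mm means touching lesions (unresolved)
and d = 2 mm is resolved with a dip ratio of ~0.4 — the behavior a
two-point-resolution statement describes. This reading is the package's
documented choice.

## Reproduction studies and problem sizes

`ringtomo.studies` fixes the desk-scale conditions; all four studies run
in minutes on one core:

* two-lesion sweep: 128 elements, separations {6,5,4,3,2,1} mm, 16 mm
  image box at 0.15 mm pixels;
* multi-size detectability: 128 elements, lesions of 0.3/0.5/1.0 mm in
  water (the background disk is given water properties so container-wall
  echoes do not mask the micro-lesions), detection = local envelope
  maximum within 0.5 mm of the true center and ≥ 6 dB above the median
  envelope in a 2–4 mm annulus;
* model-2 3D pipeline: 128 elements, 5 layers at 1.5 mm pitch around the
  small spheres, segmentation + factor-5 densification, presence =
  foreground within 0.5 mm of the true center;
* model-1 gap sweep: 256 elements, 7 layers, gaps {4,3,2,1} mm,
  separation = distinct connected components nearest the two sphere
  centers in both reconstructed sections through the centers (the
  transverse and coronal planes — with the two centers differing only in
  x, these are the planes that contain both).

Lesion coordinates for the built-in phantoms are package choices (the
source models are specified only pictorially) and are fixed so every
study is deterministic; sphere centers lie on scan-layer planes so the
layered acquisition intersects each lesion. The breast solid is a
hemispheroid of 160 mm upper diameter and 48 mm height (the height spans
the 32-layer × 1.5 mm scan range).

## What the synthetic studies show — and what they do not

The Born engine is noiseless, single-scattering, attenuation-free and
in-plane only; phantom interfaces are clean circles and spheres. The
studies therefore probe the *geometry* of ring-array synthetic-aperture
imaging — aperture, pulse length, gating, layer pitch and the
segmentation/interpolation chain — under idealized contrast. They do not
demonstrate robustness to speckle from sub-resolution microstructure,
multiple scattering and aberration through heterogeneous tissue,
element directivity, or electronic noise; resolution figures obtained
here are accordingly optimistic relative to hardware experiments, whose
published numbers require the original channel data and are out of scope
here. An additive-Gaussian-noise hook with an explicit seed exists for
sensitivity experiments and is off in the reproduction presets.

## Numerical choices and degenerate inputs

* Echo deposition and delay lookups use linear interpolation between
  samples; the deposition is the adjoint of the lookup.
* Record windows may start at t0 > 0 (windowed recording); every stage
  consumes t0 metadata, and beamformed images are invariant under a
  whole-sample window shift.
* A record window too short for the farthest echo is an error that
  states the required minimum.
* Empty scatterer clouds are legal everywhere and produce all-zero
  datasets, all-zero tomograms (normalization skipped), empty masks and
  empty meshes; an iso value outside the volume range yields an empty
  mesh, not an error.
* Constant images cannot be thresholded (error); constant volumes have
  zero gradient and their normals are flagged undefined (zero vectors).
* DICOM series use deterministic UIDs derived from the series content,
  and HDF5 datasets disable timestamp tracking, so pipeline reruns are
  byte-identical and the manifest's SHA-256 checksums are reproducible.
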