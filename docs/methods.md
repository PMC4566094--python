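# Methods

`rhodoct` simulates and analyses depth-resolved rhodopsin imaging with
visible-light spectral-domain OCT (VIS-OCT). The measurement principle is
retinal densitometry: dark-adapted rhodopsin in the rod outer segments (OS)
absorbs a 520 nm probe (absorption peak 500 nm); photobleaching shifts the
peak to 380 nm and renders the pigment transparent at the probe. Because OCT
resolves depth, the absorption change appears both as reduced backscatter
from the OS band and as a double-pass shadow on every layer beneath it. No
in vivo data are used anywhere: a ground-truth phantom generates all inputs,
and every quantitative claim the tests make is a statement about this
synthetic model.

## Retina phantom

The retina is an ordered stack of constant-property layers (defaults:
RNFL 15 µm / reflectivity 0.85, OPL 20/0.50, ONL 75/0.10, IS 20/0.20,
OS 30/1.00 with rhodopsin, RPE 15/0.90, choroid 50/0.50, sclera 100/0.0).
The bright OS on a dim IS puts the dominant positive axial-gradient edge at
the IS/OS junction, as in real B-scans; the sclera is given zero backscatter
because in vivo measurements show no scleral contribution even though the
sclera is within the imaging range. Reflectivities are model choices on an
arbitrary linear scale; thicknesses are plausible for the adult rat.

Rhodopsin absorbance is `OD(λ, b) = OD_peak · [(1−b)·S_dark(λ) +
b·S_bleached(λ)]` with unit-peak Gaussian bands at 500 and 380 nm (common
FWHM 100 nm, approximating the α-band width) and `b` the local bleach
fraction. `OD_peak` defaults to 0.25 single-pass (decadic); the in vivo
value is not established, so this is a configuration choice placing the
simulated contrast in the regime where the light/light-vs-dark/light
separation claim is meaningful. Adaptation states: dark ⇒ b ≡ 0; light
(~800 lx for 15 s) ⇒ b ≡ 1, i.e. the light-adapted scan is treated as the
fully bleached reference — bleaching kinetics and rhodopsin regeneration
are not modelled; pattern ⇒ b = 1 inside a full-height vertical strip
(default 7.8° of a 39° scan width). Melanin in the RPE and choroid of
pigmented eyes is wavelength-flat with single-pass OD 1.0 per layer.
Geometry: 39°×39° field (55 µm/degree), axial curvature bowl (default peak
offset 30 µm at the field corners), optional optic-disc region where OS
reflectivity and rhodopsin OD are zero.

## Forward model

The noise-free expectation of an A-line is `I(z) = R(z) · 10^(−2·OD_above(z))`
where `OD_above` accumulates *fractionally* through each absorbing layer
(the probe crosses the absorber on the way in and out; partial traversal
attenuates partially). The profile is blurred axially with a Gaussian PSF of
13.7/1.4 µm FWHM in tissue (incoherent approximation, applied to intensity).
Speckle is fully developed: per-voxel intensity is `|a|²` for a circular
complex Gaussian amplitude with mean-square equal to the expectation
(exponential intensity, contrast 1). All volumes of one session share the
scatterer realization — the tissue does not move between scans — so the
dark/light ratio isolates absorption. Repeat-scan decorrelation enters
through two acquisition-keyed noise sources:

* per-A-line axial jitter, Normal(0, 0.3 px), applied by linear
  interpolation;
* an additive detection background, exponential with mean 0.02 in
  reflectivity units. This floor is what makes pigmentation matter in the
  *normalized* differential: melanin attenuates dark and light scans
  equally, so in a purely multiplicative model the relative differential
  below the RPE would be pigmentation-invariant; physically the choroidal
  signal of a pigmented eye (double-pass melanin OD ≥ 2) falls below the
  detection floor and its differential vanishes, which is what the model
  reproduces.

A coherent spectral path exists alongside the intensity path: interference
spectra are synthesized on a uniform *wavelength* grid (2048 pixels across
520 ± 3·9.3 nm, Gaussian envelope), with discrete boundary reflectors and a
Gaussian sensitivity falloff reaching 0.5 at half the imaging depth.
Reconstruction subtracts the reference spectrum, resamples to uniform
wavenumber (cubic spline), applies a Hann window (imaging default; the
window is omitted for resolution metrology, where the source envelope
itself is the window and the unwindowed PSF matches the Gaussian coherence
length (2 ln 2/π)·λ²/Δλ ≈ 12.8 µm within 5%), Fourier transforms, and
divides out the falloff with a 0.05 sensitivity floor. Axial resolution is
quoted, per OCT convention, as the FWHM of the linear-magnitude PSF; the
reconstructed profile is magnitude-squared, so the metrology takes the
square root first. Dispersion is not modelled.

## Segmentation, flattening, averaging

The IS/OS is detected per A-line as the argmax of the axial gradient of the
laterally smoothed volume (default uniform filter 3×9×3 in y, x, z) inside a
search band at [55%, 85%] of the occupied depth extent (pixels above 10% of
the per-A-line maximum), which excludes the hyper-reflective RNFL; the plain
gradient is used rather than an intensity-weighted gradient because the
latter localizes an ideal edge with a ~1 px deep bias. Ties take the
shallowest candidate. Detections whose gradient falls below 3% of the
A-line maximum are filled from the nearest valid neighbour; >20% invalid
A-lines abort with advice to supply a manual boundary CSV (columns
y, x, isos_z), the interoperability path for hand-traced segmentations.
A 5×5 lateral median filter suppresses speckle outliers (disable it on
noise-free data or very coarse grids, where it biases a curved boundary).

Flattening shifts each A-line by an integer offset so the IS/OS lands on a
common reference row; integer shifts preserve speckle statistics and make
the IS/OS-forward projection exactly shift-invariant. Vacated pixels are
zero-filled and masked; averaging across the B-scan stack is a masked
pixel-wise mean. Inter-B-scan alignment uses the IS/OS reference only — no
cross-correlation refinement is layered on top.

## Differential imaging and quantification

With `I1` dark- and `I2` light-adapted intensity, the differential is
`(I2−I1)/max(I2, floor)` (default; bounded above by 1 and matching the
percentage language used for the light/light comparison) or
`log10(I2/I1)` (densitometry convention). The floor defaults to 10⁻⁶ of
the brighter image maximum. On noise-free data the log-density differential
below the OS equals exactly twice the cumulative rhodopsin OD above — the
double-pass shadow — so `0.5·log10(light/dark)` of en face projections is a
per-pixel single-pass OD estimate (negative estimates clipped and flagged).
For unbiased OD recovery the projection band is placed *below* the OS
(boundary + 20 px ≈ OS thickness + PSF margin); a band containing the OS
itself mixes partially attenuated pixels and underestimates the OD. The en
face band otherwise runs from the IS/OS to the occupied bottom of the
volume (median over A-lines plus a 5 px margin) rather than to the deepest
pixel, so the additive background of hundreds of empty depth pixels does
not dilute the projection. ROI statistics use the population SD. Bleach
patterns are segmented by Otsu thresholding of the lightly smoothed (σ=2 px)
x-y differential, with a unimodality guard that returns an empty mask and a
warning; bleach dosimetry is `energy = passes · power / point_rate`.

A note on depth profiles: with constant-per-layer reflectivity the
noise-free differential below the IS/OS is a contiguous band spanning
OS→RPE→choroid rather than three separated peaks (there is no
hyporeflective gap between these layers in the phantom). The depth-structure
tests therefore assert band support — strong differential in all three
outer bands and none in the inner retina for the albino phantom, and a
choroid contribution <10% of the albino one for the pigmented phantom —
which is the structural content of the albino/pigmented comparison.

## Problem sizes and reproducibility

The headline separation experiment uses the full acquisition geometry
(512×128 A-lines, 1024 depth pixels at 2 µm, three volumes) and runs in
about a minute on one CPU; unit and property tests use reduced grids
(64–260 A-lines, 8–128 B-scans, 256 depth pixels) chosen so that each
statistical assertion retains comfortable margin (e.g. speckle-averaging
uses the full 128 B-scans its 1/√128 claim requires). All randomness flows
from a single integer seed through named Philox streams (scatterers;
jitter+background keyed by acquisition index), so every volume, experiment
and script output is bit-for-bit reproducible; artifact sidecars record the
phantom hash, seed and pipeline version.

## Known limitations

What the synthetic model deliberately omits: partial-bleach kinetics and
regeneration, cone pigments, photoreceptor waveguiding, lateral PSF and
ocular aberrations, dispersion, eye motion beyond axial jitter, vascular
shadows, and any absolute radiometric scale — recovered OD is relative to
the configured ground truth, not molecules per area. Passing tests show the
pipeline is correct under these assumptions; they do not show that a real
eye meets them.
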