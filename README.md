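# rhodoct

Depth-resolved rhodopsin imaging with visible-light OCT, end to end on
synthetic data.

Rhodopsin, the visual pigment of rod photoreceptors, absorbs strongly near
500 nm when dark-adapted and becomes transparent there after photobleaching
(its absorption peak shifts to 380 nm). A 520 nm spectral-domain OCT probe
therefore sees the dark-adapted outer segments — and everything beneath
them, through a double-pass shadow — dimmer than the light-adapted ones.
The normalized dark/light differential

&nbsp;&nbsp;&nbsp;&nbsp;D(x, y) = (I₂ − I₁) / I₂  (I₁ dark-, I₂ light-adapted)

computed on IS/OS-forward en face projections (lateral map) or on
speckle-averaged B-scans (depth-resolved map) is then a rhodopsin image, and
half the decadic log ratio of the projections, 0.5·log₁₀(I₂/I₁), estimates
the single-pass rhodopsin optical density per pixel. Because no public
in vivo datasets exist for this protocol, `rhodoct` pairs the analysis with
a ground-truth forward model — layered rat-retina phantom, Beer–Lambert
double-pass attenuation, fully developed speckle, axial motion jitter, raw
interference spectra — so every stage (reconstruction, IS/OS segmentation,
flattening/averaging, differential imaging, OD recovery, pattern-bleach
dosimetry) can be validated against known truth. It is intended for people
developing or teaching OCT densitometry pipelines.

## Worked example

```python
import numpy as np
from rhodoct import *

params = ScanParams(n_x=128, n_y=32, n_z=256, seed=0)
ph = build_phantom({"map_shape": (32, 128),
                    "disc_center_deg": (19.5, 19.5), "disc_radius_deg": 2.0})
dark  = apply_adaptation(ph, AdaptationState("dark"))
light = apply_adaptation(ph, AdaptationState("light"))

vd  = simulate_volume(dark,  params, acquisition=0)   # shared speckle,
vl1 = simulate_volume(light, params, acquisition=1)   # independent jitter
vl2 = simulate_volume(light, params, acquisition=2)

b    = detect_isos(vd)
band = b.band_extent_to_bottom()
ed, el1, el2 = (enface_projection(v, b, band) for v in (vd, vl1, vl2))

d_dl = differential_image(ed,  el1)    # dark vs light: rhodopsin contrast
d_ll = differential_image(el1, el2)    # light vs light: noise control
field = ~ph.disc_mask()
print(np.mean(np.abs(d_dl.value[field])))   # 0.5117
print(np.mean(np.abs(d_ll.value[field])))   # 0.0073

sub = BoundaryMap(isos_z=b.isos_z + 20)     # band below the outer segments
rho = estimate_rhodopsin_od(enface_projection(vd, sub, 25),
                            enface_projection(vl1, sub, 25))
print(np.median(rho.od_estimate[field]))    # 0.2092
```

The dark/light differential averages 0.51 — about half the backscattered
light is removed by rhodopsin absorption at the default single-pass OD of
0.25 — while two consecutive light-adapted scans differ by only 0.0073
(1.4% of the rhodopsin signal), confirming the contrast is molecular rather
than speckle or motion. The recovered median OD of 0.209 sits within 7% of
the ground-truth probe-wavelength OD of 0.223.

The same pipeline is scriptable from the shell:

```bash
rhodoct run --preset albino_map --out out/ --seed 1        # full experiment
rhodoct run --preset pattern_bleach --out out_pb/ --seed 1 # strip bleach + ROI table
rhodoct segment --volume out/volume_dark.tiff --out-boundary b.csv
rhodoct diff --dark out/volume_dark.tiff --light out/volume_light1.tiff \
             --boundary b.csv --plane xy --out d.csv --png d.png
```

`rhodoct run` writes volumes (multi-page float32 TIFF + YAML sidecars),
boundary CSVs, en face and differential images, a depth profile CSV, a
rhodopsin map and a provenance report.

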