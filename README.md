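# slvol — mobile structured-light food volume estimation

`slvol` implements the software stack of a smartphone-mounted structured-light
dietary scanner: a green laser module behind a diffraction grating projects an
11 × 11 dot matrix onto a plate of food, the phone's camera records a
360-degree orbit of the plate, and the software reconstructs a 3D point cloud
of the food and integrates its volume in cm³. Accurate portion-size volumes
matter to nutrition researchers and clinical dietitians (for example when
estimating carbohydrate intake for diabetic patients), where manual journals
reach only ~60 % accuracy.

The package is a full, tested re-implementation of that pipeline plus a
synthetic scene renderer, so every stage can be exercised end-to-end — with
known ground truth — without the physical laser rig.

## The measurement model

Depth comes from triangulation across the camera–projector baseline. For a
projected point P, camera centre O and laser origin L, the law of sines gives

    |PO| = |OL| · sin(∠PLO) / sin(∠LPO)

In practice the device avoids explicit angle measurement: it is calibrated
once by photographing the dot grid on a white plane at known distances
(10–60 cm in 1 cm steps). Each grid index (i, j) then owns a *trajectory* —
its pixel position as a function of depth, a near-straight segment whose
parameterisation is the depth cue. At scan time a detected dot's depth z_E is
read by projecting its sub-pixel centroid onto the calibrated trajectory, and
its world coordinates follow from the horizontal field of view θ:

    x_ratio = (x_C − x_d/2) / (x_d/2)
    x_E = tan(θ/2) · z_E · x_ratio + C_x
    y_E = (2/3) · tan(θ/2) · z_E · y_ratio + C_y

Dots are isolated by a three-mask cascade — an HSV gate (hue 90–180°,
saturation ≥ 90 %), a cosine-similarity mask against pure green (0, 255, 0),
and a BT.709 luminance mask (L = 0.2126 R + 0.7152 G + 0.0722 B) thresholded
after subtracting a morphological opening — combined by pixelwise AND.
Detected dots are indexed on the integer lattice relative to the brighter
centre dot, missing dots are imputed from their grid neighbours, the six most
stable frames (lowest high-pass accelerometer RMS) are fused by their poses,
and the volume is integrated as a prism sum over a Delaunay triangulation of
the footprint above the estimated support plane.

## Worked example

Everything below is synthetic and reproducible (fixed seeds). First render a
calibration stack and fit the model:

```bash
slvol synth --kind calibration --out stack --seed 1
# wrote 51 frames, manifest stack/manifest.csv
slvol calibrate --stack stack/manifest.csv --out model.json --report report.json
# calibrated 121 trajectories, depth range (10.0, 60.0)
```

`report.json` shows the resubstitution depth accuracy
(`"accuracy_pct": 100.0` on the training stack; on a noisy held-out stack it
stays above 98 %). Then scan a smooth convex item — an ellipsoid with
semi-axes 6 × 4.5 × 4 cm, a mango-sized analogue — and measure it:

```bash
slvol synth --kind scan --shape ellipsoid --axes 6,4.5,4 --out scan --seed 3
# wrote 6 frames, true volume 452.389 cm^3
slvol volume --scan scan --model model.json --out result.json --ply cloud.ply
# volume 485.963 cm^3 (6 frames, 393 points)
```

The estimate is 485.96 cm³ against a true 452.39 cm³ — a 7.4 % error, inside
the ~11 % level this class of device achieves on real food. `cloud.ply` holds
the fused point cloud (ASCII PLY, cm units) and `result.json` the volume, the
fitted bottom plane and per-frame diagnostics.

The same pipeline is available as a library (`slvol.detect_dots`,
`slvol.index_dots`, `slvol.build_calibration`, `slvol.measure_scan`, …); see
`docs/methods.md` for the model details and parameter meanings.

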