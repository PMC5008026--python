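# sblda — single-block linear detection for CT liver segmentation

`sblda` segments the liver in 2D abdominal CT slices with an
iteration-free, initialization-free edge pipeline, and ships the
evaluation metrics and a synthetic CT-phantom generator needed to test the
whole method without any patient data. It is aimed at medical-image
researchers who want a fast, fully reproducible baseline segmenter and a
desk-scale testbed for edge-based organ extraction.

## Method

A slice in Hounsfield units is windowed (width 400 HU, level 40 HU) onto a
strictly positive display scale [1, 256] and denoised with a 5×5 median
filter. For every pixel and each of the eight principal directions
θ ∈ {0°, 45°, …, 315°}, a candidate point sits one pixel away along θ and
two N×N blocks flank it at ⌊w/2⌋ pixels on either side. With V_c the
candidate intensity and C₁, C₂ the flanking block means, the ratio
parameter is

    R_c = (C1 + C2 − 2·V_c) / (2·V_c)

— a scale-free score that is large in magnitude when the candidate lies on
a dark interface between brighter structures (the fat planes that separate
abdominal organs). The per-pixel maximum of |R_c| over the eight
directions, thresholded at T, gives a binary confidence matrix of edge
evidence. Defaults are the operating point T = 0.85, w = 9, N = 3.

Postprocessing turns edge evidence into one liver mask: open with a 2 px
disk to drop speckle, keep the largest edge network, invert and erode so
closed contours become separate interior regions, intersect with the
body mask M (Otsu body extraction opened with a 20 px disk — this rejects
ring artifacts hugging the body outline), pick the largest region in the
left part of the image (the liver's anatomical position in radiological
display), and smooth the boundary (Gaussian σ = 2 px + 5 px median
reconnection).

Evaluation follows the usual liver-benchmark conventions: sensitivity,
specificity, accuracy, volumetric overlap error (VOE), signed relative
volume difference (SRVD), and average / RMS / maximum symmetric surface
distances (ASD, RMSD, MSD) in mm.

## Worked example

Generate a noise-free phantom, segment it, and score the result:

```
$ sblda phantom --seed 3 --out ph --noise-sigma 0
wrote phantom (seed 3) to ph
$ sblda segment ph/phantom.nii.gz --slice-index 0 --out-mask pred.png
wrote pred.png (13097 liver pixels)
$ sblda evaluate pred.png ph/truth.png --spacing 1 1
tp           13097
tn           51915
fp           0
fn           524
sensitivity  0.9615
specificity  1.0000
accuracy     0.9920
voe          3.8470
srvd         -3.8470
asd          1.1743
rmsd         1.1933
msd          2.0000
```

The segmenter recovered 13097 of the 13621 true liver pixels with no false
positives: a 3.85 % volumetric overlap error and a mean boundary error of
1.17 mm at unit pixel spacing, the residual being a thin under-segmented
shell where the detected boundary band intrudes into the liver edge. The
same pipeline is available from Python (`sblda.segment_liver`,
`sblda.generate_phantom`, `sblda.evaluate_masks`), and
`sblda sweep-threshold` reproduces the threshold-vs-accuracy curve on a
randomized phantom suite.

A YAML config (`--config`) can override any parameter
(`T`, `w`, `N`, `window_width`, `window_level`, `median_window`,
`outlier_radius`, `ring_radius`, `gaussian_sigma`, `reconnect_window`,
`directions`, `block_orientation`).

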