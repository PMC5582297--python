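# oftquant

Quantitative analysis of myocardial remodeling in the embryonic heart
outflow tract (OFT) under altered hemodynamic load, for researchers working
with labeled 3D electron-microscopy volumes and 10-plex TMT proteomics.

When the embryonic OFT is constricted by a suture band (severity measured
as band tightness `BT = 1 − Da/Db`, the relative reduction of the maximal
external diameter at the band site), cardiomyocyte ultrastructure and the
proteome remodel. `oftquant` provides the measurement machinery for both
arms of such a study:

**Morphometry of labeled voxel volumes** (classes: cytoplasm, myofibril,
mitochondria, nucleus, extracellular):

- cytoplasm by subtraction (`total − nucleus − extracellular`) and
  myofibril/mitochondrial volume fractions *of cytoplasm*;
- myofibril bundle orientation angles φ (xy/circumferential plane, angle to
  the x-axis) and θ (xz/radial plane, angle to the z-axis), folded into
  [0°, 90°] because a fibril axis is unsigned (5° ≡ 175°); distribution
  shape is summarized by the maximal fraction of bundles inside a sliding
  20° window;
- bundle thickness as the 3D length of annotated Z-lines;
- mitochondrial clustering: 26-connected components, single-linkage merging
  within a physical gap distance, top-k volume concentration, distance to
  the nucleus surface;
- two-sample pooled-variance Student's t-tests between control and banded
  groups.

**TMT proteomics**: PSM filters (|mass error| < 20 ppm, unique protein
mapping), reporter QC (trimmed mean of 8 > 500 after dropping the min and
max channel), per-protein channel summation, total-sum channel
normalization, signed fold changes (ratio 0.833 → −1.2), two-sample t-tests
on log2 intensities, Benjamini–Hochberg FDR, and directional pathway
activation scoring: one-sided Fisher overlap p plus the activation z-score

    z = (N₊ − N₋) / √N,

where N₊/N₋ count dysregulated pathway members whose fold-change sign
matches/opposes the literature activation direction. A pathway is called
activated when `z ≥ 2` and `p < 0.05`, inhibited when `z ≤ −2` and
`p < 0.05`.

A synthetic-data module generates labeled volumes (nucleus ellipsoid,
boundary extracellular shell, capsule-shaped bundles with von Mises
orientation sampling, Thomas-process mitochondrial clusters) and TMT PSM
tables (planted folds, lognormal noise, flagged contaminants) with complete
ground truth, so every stage is testable end to end.

## Worked example

```python
from oftquant.fibril_metrics import fold_angle, compute_orientation, concentration_statistic
from oftquant.synthetic_data import VolumeGenParams, generate_labeled_volume
from oftquant.volumetrics import compute_volume_fractions

print(fold_angle(175.0))                      # 5.0   (5° and 175° are the same orientation)
print(compute_orientation((0.0, 1.0, 0.0)))   # OrientationAngles(phi=90.0, theta=None)

vol, annotations, truth = generate_labeled_volume(VolumeGenParams(seed=1))
rep = compute_volume_fractions(vol)
print(round(rep.myo_fraction_of_cytoplasm, 3),
      round(rep.mito_fraction_of_cytoplasm, 3))  # 0.156 0.103

phis = [compute_orientation(a.axis_vector).phi for a in annotations]
print(round(concentration_statistic(phis, 20.0), 3))  # 1.0 (few bundles, tight preset)
```

`fold_angle(175.0) == 5.0` expresses the axial symmetry of fibril
orientation; `phi = 90°` marks a longitudinally aligned bundle. The volume
fractions are the generated sample's myofibril and mitochondrial shares of
its cytoplasm (planted targets 0.12 and 0.10; realized values are exact
recounts of the emitted voxel grid — bundle painting is granular, so the
myofibril share overshoots its target by up to one capsule).

A command-line interface covers the same ground
(`oftquant simulate-volume | simulate-tmt | morphometry | proteomics |
pathways | band-tightness | run-all`), driven by a single YAML config that
records every threshold; reruns with the same config and seed are
byte-identical.

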