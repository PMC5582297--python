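# Methods

## Scope and model

`oftquant` quantifies two readouts of embryonic outflow-tract myocardium
remodeling under increased hemodynamic load: the 3D arrangement of
myofibrils and mitochondria in labeled electron-microscopy volumes, and
differential protein abundance with pathway-activation scoring from
10-plex TMT data (5 control vs 5 banded channels). Band severity is
screened with the tightness index `BT = 1 − Da/Db` restricted to the
0.30–0.45 window (inclusive endpoints) within which the induced pressure
and shear changes are approximately constant.

## Morphometry

**Volume accounting.** A labeled volume assigns each voxel exactly one of
five classes. Cytoplasm is defined by subtraction — everything that is not
nucleus or extracellular — so embedded organelles count as cytoplasm, and
organelle content is reported as a fraction of cytoplasm rather than of
total volume. This removes the dependence on how much nuclear or
extracellular material the field of view happens to include. Fractions are
invariant to voxel size and axis order; physical volumes scale with the
voxel volume (nm³ → μm³).

**Orientation.** A bundle axis is an unsigned direction. Its angle in the
xy (circumferential) plane is measured from the x-axis, in the xz (radial)
plane from the z-axis; both are folded to [0°, 90°] via
`min(a mod 180, 180 − a mod 180)`, which is idempotent and identifies a
with 180 − a. A projection whose magnitude is below 10⁻⁶ of the vector
norm leaves the corresponding angle undefined rather than returning a
noise-driven value. Because absolute sample orientation in the resin block
is arbitrary, only distribution shape is compared between samples: the
concentration statistic is the maximum fraction of angles inside a closed
20°-wide window, scanned in 0.5° steps over [0, 70] (no wraparound —
folding already removes periodicity beyond 90°). For uniform angles it
approaches 20/90 ≈ 0.222; for a degenerate distribution it is 1.

**Thickness.** Bundle thickness is taken as the Z-line length — the 3D
Euclidean distance between annotated endpoint pairs, in nm — pooled over
all bundles of a sample and summarized by mean and quartiles. Whether
Z-lines should be measured in-slice (2D) instead is an open question for
real data; this package uses the 3D distance throughout.

**Mitochondrial clustering.** There is no canonical operational definition
of a mitochondrial "group", so clustering is parameterized explicitly:
26-connected components of the mitochondria mask (isotropic in label
space) are merged by single linkage whenever the minimum distance between
their surface-voxel centers, computed in physical nm so the fine slice
axis is honored, is ≤ `gap_nm` (default 200 nm, a free parameter that
should always be reported with the result; the surface metric is
voxel-center to voxel-center, not face to face). Cluster counts are
monotone non-increasing in the gap, so parameter sweeps are well behaved.
Reports include per-cluster volumes, the volume share of the largest k
clusters (default k = 3), and the mean distance from cluster centroids to
the nucleus surface via a Euclidean distance transform.

**Group comparison.** Control vs banded metrics are compared with a
two-sample pooled-variance Student's t-test, two-tailed, significance at
p < 0.05. If both groups are constant and equal, p = 1 by convention;
constant but unequal groups are an error at the statistics level (the
proteomics pipeline instead assigns p = 0 to perfectly separated noiseless
groups so that degenerate synthetic data flows through).

## Proteomics

The PSM-to-results chain applies, in order: identification filters
(absolute precursor mass error < 20 ppm and a unique protein mapping),
reporter QC (drop exactly one maximum and one minimum intensity — one
instance each on ties — and require the mean of the remaining eight to
exceed 500), per-protein per-channel summation with distinct-peptide
counts, and channel normalization by total-sum scaling (every channel
total is scaled to the grand-mean total). Normalization is a transparent
substitute for count-model normalizers (e.g. TMM) that is adequate for the
calibration claims made here; it is an explicit argument and can be
disabled when channels are already calibrated — the noiseless
fold-recovery checks run unnormalized, since a one-sided planted fold
necessarily perturbs channel totals and total-sum scaling would bias the
recovered fold by the planted signal's share of the channel total.

Differential abundance per protein: the banded/control ratio of mean
normalized intensities, reported in the signed-fold convention (ratio ≥ 1
→ +ratio, ratio < 1 → −1/ratio, so |fold| ≥ 1 and 0.833 → −1.2; the raw
ratio is also emitted since both conventions appear in practice); a
pooled t-test on log2 intensities; Benjamini–Hochberg step-up q-values
across all tested proteins. Proteins with a zero intensity in any channel
receive a pseudo-count of 1 on every channel before the log transform and
are flagged. The acceptance surface of this stage is *calibration on
synthetic data* — uniform null p-values and empirical FDR control at
q < 0.1 — not reproduction of any specific experimental protein list.

Pathway input filtering keeps proteins that are well measured and
nominally changed: fewer than two channels below 4,000 summed intensity,
at least two distinct peptides, and differential p < 0.1. Each pathway
then receives a one-sided Fisher's exact overlap p (hypergeometric tail
over the detected-protein universe; direction plays no role) and the
activation z-score `z = (N₊ − N₋)/√N` over direction-annotated
dysregulated members. Direction-unknown members are excluded from N by
default; a switch can include them in the denominator only, reflecting an
alternative reading of "detected dysregulated proteins in the pathway".
Calls: activated iff z ≥ +2 and p < 0.05, inhibited iff z ≤ −2 and
p < 0.05, otherwise indeterminate. No multiple-testing correction is
applied across pathways; the p < 0.05 screen is used as reported.

## Synthetic data generator

The generator emulates the study design, not image realism.

*Volumes* (default 64×64×48 voxels at 20×20×4 nm): a central nucleus
ellipsoid sized to its volume-fraction target; an extracellular shell of
the boundary-nearest voxels selected by exact count; capsule-shaped
myofibril bundles added until the myofibril share of cytoplasm reaches its
target (default 0.12; mitochondria 0.10 — the ~10–13% regime), each with
transverse Z-discs every `sarcomere_spacing` along the axis and Z-line
endpoint pairs spanning the bundle diameter; mitochondrial ellipsoid blobs
from a Thomas-type process whose parents sit on a ring around the nucleus
at equal azimuths (default 2–3 parents) with Gaussian offspring
dispersion. Painting precedence is nucleus > extracellular > myofibril >
mitochondria > cytoplasm, mirroring the exclusivity of manual
segmentation; targets unreachable within a bounded attempt budget raise an
explicit packing error. Bundle orientation angles are sampled from a von
Mises distribution on the doubled angle, halved and folded to [0, 90]
(κ = 0 is exactly uniform on [0, 90]; folding is idempotent under this
construction), and axis vectors are constructed so the analyzer's
orientation operations — which share no code with the sampler — recover
the sampled φ/θ. Bundle radius (120 ± 20 nm) and sarcomere spacing
(400 nm, compressed to fit desk-scale grids) are modeling assumptions, not
measured values; thickness claims are therefore recovery claims (planted
vs measured), never absolute.

*TMT experiments*: per-protein log2-normal baselines (mean 13, sd 1.5),
per-peptide ionization factors (log2 sd 0.5), Poisson-plus-one peptides
per protein (mean 3), optional per-channel scale factors to exercise
normalization, planted fold changes on a random protein subset (default
5% at 1.1–1.5×, random direction — the modest-effect regime typical of
this tissue), multiplicative lognormal noise with mean 1 and the requested
CV (exactly 1 at CV 0), and contaminant PSMs: high mass error (≥ 20 ppm),
multi-protein mappings, and rows rescaled below the intensity floor.
Ground-truth flags are *realized* — recomputed from the emitted values by
independent inline rules — so filter outputs can be compared to the clean
set exactly.

All randomness flows from one integer seed through fixed per-component
substreams; volume, annotation and table outputs are bit-identical under a
fixed seed, and pipeline output files (sorted-key JSON, fixed-order TSV,
no timestamps) are byte-identical across reruns.

## Problem sizes and numerical choices

Tests and examples run at deliberately small scale chosen as sufficient
for their statistical claims: 48×48×32 or 40×40×24 voxel grids for
recovery suites (30 volumes for fraction recovery, 20 for thickness, 40
seeds for cluster recovery at the default 64×64×48 grid, where the three
planted clusters are spatially resolvable), 400–1,000 proteins and 50
replicates for FDR calibration, 2,000 simulations for t-test null
calibration. Monte-Carlo tolerances follow binomial/oracle error at those
sizes (e.g. ±0.02 on the 0.222 uniform-concentration limit at n = 10,000).
Tie-breaks and degenerate inputs are handled explicitly: reporter QC drops
exactly one min/max instance; empty masks yield empty cluster reports;
empty PSM tables yield empty result files with a warning; zero axis
vectors, zero-length Z-lines, zero cytoplasm, non-positive ratios and
inconsistent contingency counts raise errors naming the offense.

## Limitations

The generator does not emulate EM texture, membrane-resolved cell
boundaries, partial-volume effects, or segmentation error, so passing
recovery tests demonstrates correctness of the measurement operations, not
robustness to annotation noise. The proteomics substitute (total-sum
scaling + log2 t-test) is calibrated on synthetic lognormal data and is
not a drop-in reimplementation of count-based differential tools; with
real reporter-ion data those tools may differ, particularly for
low-intensity proteins. Pathway scoring operates on user-supplied
definitions; it does not reproduce any proprietary knowledge base, its
indirect-relationship networks, or downstream-effect predictions.
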