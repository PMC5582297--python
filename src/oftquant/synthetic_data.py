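"""Synthetic labeled volumes and TMT experiments with known ground truth.

Every downstream stage of the pipeline is exercised against data whose
generative parameters are known, replacing the original segmented EM
volumes and mass-spectrometry runs:

* ``generate_labeled_volume`` paints a voxel grid with a nucleus ellipsoid,
  an extracellular boundary shell, capsule-shaped myofibril bundles whose
  axes follow folded von Mises orientation distributions, and
  mitochondrial blobs from a Thomas-type parent/offspring cluster process.
  Overlaps resolve by precedence nucleus > extracellular > myofibril >
  mitochondria > cytoplasm, mirroring the exclusivity of a manual
  segmentation.
* ``generate_tmt_experiment`` emits a peptide-spectrum-match table for a
  5 control + 5 banded channel design with per-protein baselines,
  per-peptide ionization factors, lognormal reporter noise, planted
  fold changes, and contaminant PSMs (high mass error, ambiguous protein
  mapping, low intensity) flagged in the ground truth.

All randomness derives from a single integer seed; per-component
substreams use fixed offsets, so outputs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fibril_metrics import BundleAnnotation
from .proteomics_quant import CHANNELS
from .volumetrics import CLASS_CODES, LabeledVolume


class PackingError(RuntimeError):
    """Raised when organelle volume targets cannot be reached in the grid."""


# --------------------------------------------------------------------------
# labeled-volume generation
# --------------------------------------------------------------------------

@dataclass
class VolumeGenParams:
    """Generative parameters for a labeled myocardium volume.

    Defaults emulate the imaged tissue: ~10-13% myofibril and mitochondrial
    cytoplasm fractions, 2-3 mitochondrial clusters, anisotropic voxels
    (fine slice axis).  Bundle radius and sarcomere spacing are modeling
    assumptions (no measured values exist for them here).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size: tuple[float, float, float] = (20.0, 20.0, 4.0)  # nm per axis
    nucleus_fraction: float = 0.15
    ecm_fraction: float = 0.10
    myo_fraction_target: float = 0.12
    mito_fraction_target: float = 0.10
    bundle_radius_mean_sd: tuple[float, float] = (120.0, 20.0)  # nm
    sarcomere_spacing: float = 400.0  # nm between Z-discs along the axis
    phi_mode: float = 10.0
    phi_kappa: float = 4.0
    theta_mode: float = 80.0
    theta_kappa: float = 4.0
    mito_cluster_count: int = 3
    mito_cluster_sd: float = 120.0  # nm dispersion of blobs about parents
    mito_blob_radius_nm: float = 90.0
    seed: int = 0
    max_attempts: int = 2000

    def __post_init__(self) -> None:
        fracs = (
            self.nucleus_fraction,
            self.ecm_fraction,
            self.myo_fraction_target,
            self.mito_fraction_target,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if sum(fracs) >= 1.0:
            raise ValueError("class fraction targets must sum to < 1")
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.phi_kappa < 0 or self.theta_kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not 0.0 <= self.phi_mode <= 90.0 or not 0.0 <= self.theta_mode <= 90.0:
            raise ValueError("orientation modes must lie in [0, 90] degrees")


@dataclass
class VolumeGroundTruth:
    class_counts: dict[str, int]
    bundle_axes: list[tuple[float, float, float]]
    bundle_phis: list[float]
    bundle_thetas: list[float]
    zline_lengths_nm: list[float]
    mito_parent_centers_nm: list[tuple[float, float, float]]


def sample_folded_angles(
    rng: np.random.Generator, mode_deg: float, kappa: float, n: int
) -> np.ndarray:
    """Sample folded axial angles in [0, 90] degrees.

    The raw planar angle (period 180 degrees) is drawn by sampling a von
    Mises variate on the doubled angle and halving, then folding into
    [0, 90] via min(a, 180 - a).  kappa = 0 gives the uniform distribution
    on [0, 90]; large kappa concentrates at the mode.  Folding is
    idempotent under this construction.
    """
    mu = math.radians(2.0 * mode_deg)
    doubled = rng.vonmises(mu, kappa, size=n) if kappa > 0 else rng.uniform(
        -math.pi, math.pi, size=n
    )
    raw = (np.degrees(doubled) % 360.0) / 2.0  # in [0, 180)
    return np.minimum(raw, 180.0 - raw)


def axis_from_angles(phi_deg: float, theta_deg: float) -> np.ndarray:
    """Unit axis vector realizing given folded phi (xy/x) and theta (xz/z).

    Constructed so that the orientation analyzer recovers the input angles:
    the xy projection makes angle phi with x, and the xz projection makes
    angle theta with z.
    """
    phi = math.radians(phi_deg)
    theta = math.radians(max(theta_deg, 1e-9))
    x, y = math.cos(phi), math.sin(phi)
    if x < 1e-12:  # phi = 90: purely longitudinal, theta degenerate
        v = np.array([0.0, 1.0, 0.0])
    else:
        z = x / math.tan(theta)
        v = np.array([x, y, z])
    return v / np.linalg.norm(v)


def _perp_unit(axis: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(np.dot(axis, ref))) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    p = np.cross(axis, ref)
    return p / np.linalg.norm(p)


def generate_labeled_volume(
    params: VolumeGenParams,
) -> tuple[LabeledVolume, list[BundleAnnotation], VolumeGroundTruth]:
    """Paint a labeled volume and return it with annotations + ground truth.

    Raises :class:`PackingError` when the myofibril or mitochondria volume
    target cannot be reached within the attempt budget.
    """
    nx, ny, nz = params.grid_shape
    sx, sy, sz = params.voxel_size
    extents = np.array([nx * sx, ny * sy, nz * sz])
    grid = np.zeros(params.grid_shape, dtype=np.uint8)

    X = ((np.arange(nx) + 0.5) * sx)[:, None, None]
    Y = ((np.arange(ny) + 0.5) * sy)[None, :, None]
    Z = ((np.arange(nz) + 0.5) * sz)[None, None, :]
    center = extents / 2.0

    # nucleus: ellipsoid at the grid center, semi-axes proportional to extents
    nucleus_semi = np.zeros(3)
    if params.nucleus_fraction > 0:
        r = (6.0 * params.nucleus_fraction / math.pi) ** (1.0 / 3.0)
        nucleus_semi = r * extents / 2.0
        ell = (
            ((X - center[0]) / nucleus_semi[0]) ** 2
            + ((Y - center[1]) / nucleus_semi[1]) ** 2
            + ((Z - center[2]) / nucleus_semi[2]) ** 2
        )
        grid[ell <= 1.0] = CLASS_CODES["nucleus"]

    # extracellular shell: the target count of voxels nearest the volume
    # boundary (stable argsort of physical distance-to-boundary, so the
    # realized fraction matches the target up to nucleus overlap)
    if params.ecm_fraction > 0:
        db = np.minimum.reduce(
            [
                np.broadcast_to(np.minimum(X, extents[0] - X), grid.shape),
                np.broadcast_to(np.minimum(Y, extents[1] - Y), grid.shape),
                np.broadcast_to(np.minimum(Z, extents[2] - Z), grid.shape),
            ]
        )
        k = int(round(params.ecm_fraction * grid.size))
        flat_idx = np.argsort(db.ravel(), kind="stable")[:k]
        shell = np.zeros(grid.size, dtype=bool)
        shell[flat_idx] = True
        shell = shell.reshape(grid.shape) & (grid == CLASS_CODES["cytoplasm"])
        grid[shell] = CLASS_CODES["extracellular"]

    total = grid.size
    cyto_capacity = int(
        total
        - (grid == CLASS_CODES["nucleus"]).sum()
        - (grid == CLASS_CODES["extracellular"]).sum()
    )

    # myofibril bundles: capsules with transverse Z-discs
    rng_bundle = np.random.default_rng([params.seed, 1])
    annotations: list[BundleAnnotation] = []
    axes_gt: list[tuple[float, float, float]] = []
    phis_gt: list[float] = []
    thetas_gt: list[float] = []
    zline_lengths: list[float] = []
    myo_target = int(round(params.myo_fraction_target * cyto_capacity))
    myo_count = 0
    attempts = 0
    half_len = 0.45 * float(extents.max())
    while myo_count < myo_target:
        attempts += 1
        if attempts > params.max_attempts:
            raise PackingError(
                f"myofibril target {myo_target} voxels unreachable: "
                f"{myo_count} painted after {attempts - 1} attempts"
            )
        phi = float(sample_folded_angles(rng_bundle, params.phi_mode, params.phi_kappa, 1)[0])
        theta = float(
            sample_folded_angles(rng_bundle, params.theta_mode, params.theta_kappa, 1)[0]
        )
        axis = axis_from_angles(phi, theta)
        c = rng_bundle.uniform(0.1, 0.9, size=3) * extents
        radius = max(
            40.0,
            rng_bundle.normal(params.bundle_radius_mean_sd[0], params.bundle_radius_mean_sd[1]),
        )
        dx, dy, dz = X - c[0], Y - c[1], Z - c[2]
        t = np.clip(dx * axis[0] + dy * axis[1] + dz * axis[2], -half_len, half_len)
        d2 = (dx - t * axis[0]) ** 2 + (dy - t * axis[1]) ** 2 + (dz - t * axis[2]) ** 2
        mask = (d2 <= radius**2) & (grid == CLASS_CODES["cytoplasm"])
        painted = int(mask.sum())
        if painted == 0:
            continue
        grid[mask] = CLASS_CODES["myofibril"]
        myo_count += painted

        n_side = int(half_len // params.sarcomere_spacing)
        offsets = np.arange(-n_side, n_side + 1) * params.sarcomere_spacing
        perp = _perp_unit(axis)
        zlines = []
        for off in offsets:
            p = c + off * axis
            zlines.append((tuple(p - radius * perp), tuple(p + radius * perp)))
            zline_lengths.append(2.0 * radius)
        bid = f"bundle_{len(annotations):03d}"
        annotations.append(
            BundleAnnotation(bundle_id=bid, axis_vector=tuple(axis), zlines=tuple(zlines))
        )
        axes_gt.append(tuple(float(a) for a in axis))
        phis_gt.append(phi)
        thetas_gt.append(theta)

    # mitochondria: Thomas-type cluster process, parents near nucleus poles
    rng_mito = np.random.default_rng([params.seed, 2])
    parents: list[np.ndarray] = []
    if params.mito_fraction_target > 0 and params.mito_cluster_count > 0:
        for k in range(params.mito_cluster_count):
            if params.nucleus_fraction > 0:
                # ring around the nucleus at equal azimuths: parents stay
                # well separated so planted cluster counts are recoverable
                alpha = 2.0 * math.pi * k / params.mito_cluster_count
                base = center + 1.5 * np.array(
                    [
                        nucleus_semi[0] * math.cos(alpha),
                        nucleus_semi[1] * math.sin(alpha),
                        0.0,
                    ]
                )
                jitter = rng_mito.normal(0.0, 0.03 * extents, size=3)
                parents.append(np.clip(base + jitter, 0.05 * extents, 0.95 * extents))
            else:
                parents.append(rng_mito.uniform(0.1, 0.9, size=3) * extents)
    mito_target = int(round(params.mito_fraction_target * cyto_capacity))
    mito_count = 0
    attempts = 0
    blob_r = params.mito_blob_radius_nm
    while mito_count < mito_target:
        attempts += 1
        if attempts > params.max_attempts:
            raise PackingError(
                f"mitochondria target {mito_target} voxels unreachable: "
                f"{mito_count} painted after {attempts - 1} attempts"
            )
        parent = parents[(attempts - 1) % len(parents)]
        c = parent + rng_mito.normal(0.0, params.mito_cluster_sd, size=3)
        semi = blob_r * rng_mito.uniform(0.7, 1.3, size=3)
        ell = (
            ((X - c[0]) / semi[0]) ** 2
            + ((Y - c[1]) / semi[1]) ** 2
            + ((Z - c[2]) / semi[2]) ** 2
        )
        mask = (ell <= 1.0) & (grid == CLASS_CODES["cytoplasm"])
        painted = int(mask.sum())
        if painted == 0:
            continue
        grid[mask] = CLASS_CODES["mitochondria"]
        mito_count += painted

    counts = {
        name: int((grid == code).sum()) for name, code in CLASS_CODES.items()
    }
    vol = LabeledVolume(class_grid=grid, voxel_size=params.voxel_size)
    gt = VolumeGroundTruth(
        class_counts=counts,
        bundle_axes=axes_gt,
        bundle_phis=phis_gt,
        bundle_thetas=thetas_gt,
        zline_lengths_nm=zline_lengths,
        mito_parent_centers_nm=[tuple(float(x) for x in p) for p in parents],
    )
    return vol, annotations, gt


# --------------------------------------------------------------------------
# TMT experiment generation
# --------------------------------------------------------------------------

@dataclass
class TmtGenParams:
    """Generative parameters for a 10-channel (5 control + 5 banded) TMT run."""

    n_proteins: int = 1000
    mean_peptides: float = 3.0  # mean peptides (PSMs) per protein, >= 1
    baseline_log2_mean: float = 13.0
    baseline_log2_sd: float = 1.5
    peptide_log2_sd: float = 0.5
    channel_scale_factors: tuple[float, ...] = (1.0,) * 10
    de_fraction: float = 0.05
    planted_fold_range: tuple[float, float] = (1.1, 1.5)
    noise_cv: float = 0.1
    frac_high_mass_error: float = 0.02
    frac_multi_protein: float = 0.02
    frac_low_intensity: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive (empty table otherwise)")
        if len(self.channel_scale_factors) != 10:
            raise ValueError("exactly 10 channel scale factors required")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        lo, hi = self.planted_fold_range
        if lo < 1.0 or hi < lo:
            raise ValueError("planted folds must be >= 1 with lo <= hi")
        if self.mean_peptides < 1.0:
            raise ValueError("mean_peptides must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass
class TmtGroundTruth:
    """Planted truth for a generated TMT experiment.

    ``true_signed_fold`` maps every protein to its planted banded/control
    fold under the signed convention (+1.0 for unchanged proteins).  PSM
    flags are *realized*: they record whether each emitted row actually
    violates the corresponding filter rule.
    """

    true_signed_fold: dict[str, float]
    de_proteins: set[str]
    psm_flags: pd.DataFrame  # columns: high_mass_error, multi_protein, low_intensity


def generate_tmt_experiment(
    params: TmtGenParams,
) -> tuple[pd.DataFrame, TmtGroundTruth]:
    """Generate a PSM table with planted differential abundance.

    Each PSM intensity is channel_scale x protein baseline x peptide
    factor x planted fold (banded channels of DE proteins) x lognormal
    noise with the requested CV (exactly 1 when noise_cv = 0).
    """
    rng = np.random.default_rng([params.seed, 3])
    n = params.n_proteins
    width = max(4, len(str(n)))
    proteins = np.array([f"P{i:0{width}d}" for i in range(1, n + 1)])

    baselines = 2.0 ** rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, n)
    n_de = int(round(params.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    lo, hi = params.planted_fold_range
    magnitudes = rng.uniform(lo, hi, size=n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    banded_multiplier = np.ones(n)
    signed_fold_true = np.ones(n)
    for j, idx in enumerate(de_idx):
        f = magnitudes[j]
        if signs[j] > 0:
            banded_multiplier[idx] = f
            signed_fold_true[idx] = f
        else:
            banded_multiplier[idx] = 1.0 / f
            signed_fold_true[idx] = -f

    pep_counts = 1 + rng.poisson(params.mean_peptides - 1.0, size=n)
    prot_of_psm = np.repeat(np.arange(n), pep_counts)
    n_psm = prot_of_psm.size
    pep_factor = 2.0 ** rng.normal(0.0, params.peptide_log2_sd, n_psm)

    scale = np.asarray(params.channel_scale_factors, dtype=float)
    fold_cols = np.ones((n_psm, 10))
    fold_cols[:, 5:] = banded_multiplier[prot_of_psm][:, None]
    base = baselines[prot_of_psm][:, None] * pep_factor[:, None]
    intens = base * scale[None, :] * fold_cols
    if params.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + params.noise_cv**2))
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=(n_psm, 10))
        intens = intens * noise

    mass_error = np.clip(rng.normal(0.0, 5.0, n_psm), -15.0, 15.0)
    protein_ids = proteins[prot_of_psm].astype(object)

    def _contaminate(frac: float) -> np.ndarray:
        m = int(round(frac * n_psm))
        return rng.choice(n_psm, size=m, replace=False) if m > 0 else np.array([], int)

    hi_me = _contaminate(params.frac_high_mass_error)
    mass_error[hi_me] = rng.uniform(25.0, 80.0, hi_me.size) * rng.choice(
        [-1.0, 1.0], hi_me.size
    )
    multi = _contaminate(params.frac_multi_protein)
    for i in multi:
        protein_ids[i] = f"{protein_ids[i]};CONT_{int(i):05d}"
    low = _contaminate(params.frac_low_intensity)
    if low.size:
        trimmed = np.sort(intens[low], axis=1)[:, 1:-1].mean(axis=1)
        target = rng.uniform(20.0, 400.0, low.size)
        intens[low] *= (target / trimmed)[:, None]

    psm_ids = [f"psm_{i:06d}" for i in range(n_psm)]
    peptide_ids = [f"pep_{i:06d}" for i in range(n_psm)]
    table = pd.DataFrame(
        {
            "psm_id": psm_ids,
            "peptide_id": peptide_ids,
            "protein_ids": [str(p) for p in protein_ids],
            "mass_error_ppm": mass_error,
        }
    )
    for j, ch in enumerate(CHANNELS):
        table[ch] = intens[:, j]

    realized_trimmed = np.sort(intens, axis=1)[:, 1:-1].mean(axis=1)
    flags = pd.DataFrame(
        {
            "psm_id": psm_ids,
            "high_mass_error": np.abs(mass_error) >= 20.0,
            "multi_protein": [";" in str(p) for p in protein_ids],
            "low_intensity": realized_trimmed <= 500.0,
        }
    ).set_index("psm_id")

    gt = TmtGroundTruth(
        true_signed_fold={p: float(f) for p, f in zip(proteins, signed_fold_true)},
        de_proteins={str(proteins[i]) for i in de_idx},
        psm_flags=flags,
    )
    return table, gt
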