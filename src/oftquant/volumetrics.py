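"""Organelle volume accounting on labeled voxel grids.

Cytoplasm is defined by subtraction: everything in the imaged volume that
is neither nucleus nor extracellular material, so organelles (myofibrils,
mitochondria) count as cytoplasm.  Myofibril and mitochondrial content is
reported as a fraction of cytoplasm rather than of total volume, which
removes the dependence on how much nuclear/extracellular material a given
field of view happens to contain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical label encoding shared by the generator and all readers.
CLASS_CODES: dict[str, int] = {
    "cytoplasm": 0,
    "myofibril": 1,
    "mitochondria": 2,
    "nucleus": 3,
    "extracellular": 4,
}


@dataclass
class LabeledVolume:
    """A 3D grid of integer class labels with anisotropic voxel size.

    ``class_grid`` is indexed (x, y, z); ``voxel_size`` gives nm per axis
    in the same order.
    """

    class_grid: np.ndarray
    voxel_size: tuple[float, float, float]
    class_codes: dict[str, int] = field(default_factory=lambda: dict(CLASS_CODES))

    def __post_init__(self) -> None:
        self.class_grid = np.asarray(self.class_grid)
        if self.class_grid.ndim != 3:
            raise ValueError("class grid must be 3D")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (nm)")

    @property
    def voxel_volume_nm3(self) -> float:
        sx, sy, sz = self.voxel_size
        return float(sx * sy * sz)

    def mask(self, class_name: str) -> np.ndarray:
        return self.class_grid == self.class_codes[class_name]

    def count(self, class_name: str) -> int:
        return int(self.mask(class_name).sum())


@dataclass(frozen=True)
class VolumeFractionReport:
    total_voxels: int
    nuclear_voxels: int
    ecm_voxels: int
    cytoplasm_voxels: int
    myo_voxels: int
    mito_voxels: int
    myo_fraction_of_cytoplasm: float
    mito_fraction_of_cytoplasm: float


def _check_known_codes(vol: LabeledVolume) -> None:
    known = set(vol.class_codes.values())
    present = set(int(c) for c in np.unique(vol.class_grid))
    unknown = present - known
    if unknown:
        raise ValueError(f"unknown class code(s) in grid: {sorted(unknown)}")


def compute_cytoplasm_volume(vol: LabeledVolume) -> tuple[int, float]:
    """Cytoplasm voxel count and physical volume (μm³) by subtraction.

    cytoplasm = total − nucleus − extracellular; organelles embedded in the
    cytoplasm are counted as cytoplasm.
    """
    _check_known_codes(vol)
    total = int(vol.class_grid.size)
    count = total - vol.count("nucleus") - vol.count("extracellular")
    volume_um3 = count * vol.voxel_volume_nm3 / 1e9
    return count, volume_um3


def compute_volume_fractions(vol: LabeledVolume) -> VolumeFractionReport:
    """Myofibril and mitochondrial volume fractions of the cytoplasm."""
    cyto, _ = compute_cytoplasm_volume(vol)
    if cyto == 0:
        raise ValueError("cytoplasm volume is zero; fractions undefined")
    myo = vol.count("myofibril")
    mito = vol.count("mitochondria")
    return VolumeFractionReport(
        total_voxels=int(vol.class_grid.size),
        nuclear_voxels=vol.count("nucleus"),
        ecm_voxels=vol.count("extracellular"),
        cytoplasm_voxels=cyto,
        myo_voxels=myo,
        mito_voxels=mito,
        myo_fraction_of_cytoplasm=myo / cyto,
        mito_fraction_of_cytoplasm=mito / cyto,
    )
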