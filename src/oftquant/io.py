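"""File formats: TIFF+YAML labeled volumes, TSV tables, JSON reports.

Volumes travel as multi-page 8-bit TIFF stacks (one page per z slice)
with a YAML sidecar recording the voxel size in nm per axis and the label
encoding.  Annotations, PSM tables, pathway definitions and diameter
tables are tab-separated text with a header row.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fibril_metrics import BundleAnnotation
from .pathway_scoring import PathwayDefinition
from .proteomics_quant import CHANNELS
from .volumetrics import CLASS_CODES, LabeledVolume

PSM_COLUMNS = ["peptide_id", "protein_ids", "mass_error_ppm", *CHANNELS]


def write_labeled_volume(vol: LabeledVolume, tiff_path: str | Path, yaml_path: str | Path) -> None:
    """Write a volume as a z-paged TIFF plus a YAML voxel-size sidecar."""
    pages = np.transpose(vol.class_grid.astype(np.uint8), (2, 1, 0))  # (z, y, x)
    tifffile.imwrite(str(tiff_path), pages)
    sidecar = {
        "voxel_size_nm": {
            "x": float(vol.voxel_size[0]),
            "y": float(vol.voxel_size[1]),
            "z": float(vol.voxel_size[2]),
        },
        "class_codes": {k: int(v) for k, v in vol.class_codes.items()},
    }
    Path(yaml_path).write_text(yaml.safe_dump(sidecar, sort_keys=True))


def read_labeled_volume(tiff_path: str | Path, yaml_path: str | Path) -> LabeledVolume:
    pages = tifffile.imread(str(tiff_path))
    if pages.ndim == 2:
        pages = pages[None]
    grid = np.transpose(pages, (2, 1, 0))  # back to (x, y, z)
    meta = yaml.safe_load(Path(yaml_path).read_text())
    vs = meta["voxel_size_nm"]
    codes = {str(k): int(v) for k, v in meta.get("class_codes", CLASS_CODES).items()}
    return LabeledVolume(
        class_grid=grid,
        voxel_size=(float(vs["x"]), float(vs["y"]), float(vs["z"])),
        class_codes=codes,
    )


_ANN_COLUMNS = [
    "bundle_id", "axis_x", "axis_y", "axis_z",
    "zline_x1", "zline_y1", "zline_z1", "zline_x2", "zline_y2", "zline_z2",
]


def write_annotations(annotations: Iterable[BundleAnnotation], path: str | Path) -> None:
    """One TSV row per Z-line; the bundle axis repeats on each of its rows."""
    rows = []
    for ann in annotations:
        ax, ay, az = ann.axis_vector
        for (p1, p2) in ann.zlines:
            rows.append([ann.bundle_id, ax, ay, az, *p1, *p2])
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[BundleAnnotation]:
    df = _read_tsv(path, _ANN_COLUMNS)
    out: list[BundleAnnotation] = []
    for bid, g in df.groupby("bundle_id", sort=True):
        axis = (float(g.iloc[0].axis_x), float(g.iloc[0].axis_y), float(g.iloc[0].axis_z))
        zlines = tuple(
            (
                (float(r.zline_x1), float(r.zline_y1), float(r.zline_z1)),
                (float(r.zline_x2), float(r.zline_y2), float(r.zline_z2)),
            )
            for r in g.itertuples()
        )
        out.append(BundleAnnotation(bundle_id=str(bid), axis_vector=axis, zlines=zlines))
    return out


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:  # pandas reports the offending line
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def write_psm_table(psms: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["psm_id", *PSM_COLUMNS] if c in psms.columns]
    psms[cols].to_csv(path, sep="\t", index=False)


def read_psm_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, PSM_COLUMNS)
    bad = df[CHANNELS].lt(0).any(axis=1)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # 1-based plus header row
        raise ValueError(f"{path}: negative reporter intensity at line {line}")
    return df


def write_pathways(definitions: Iterable[PathwayDefinition], path: str | Path) -> None:
    rows = [
        [d.pathway_id, prot, direction]
        for d in definitions
        for prot, direction in d.members.items()
    ]
    pd.DataFrame(rows, columns=["pathway_id", "protein_id", "direction"]).to_csv(
        path, sep="\t", index=False
    )


def read_pathways(path: str | Path) -> list[PathwayDefinition]:
    df = _read_tsv(path, ["pathway_id", "protein_id", "direction"])
    out = []
    for pid, g in df.groupby("pathway_id", sort=True):
        members = {str(r.protein_id): int(r.direction) for r in g.itertuples()}
        out.append(PathwayDefinition(pathway_id=str(pid), members=members))
    return out


def read_diameters(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["embryo_id", "d_before", "d_after"])
    return df


def to_jsonable(obj: Any) -> Any:
    """Recursively convert dataclasses / numpy scalars for JSON output."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    return obj


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(to_jsonable(obj), sort_keys=True, indent=2) + "\n")
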