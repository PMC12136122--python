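"""Readers and writers: TIFF/NIfTI volumes, CSV surface tables, en face maps,
flat key-value configs, and phantom ground truth sidecars.

Volumes are stored as multi-page TIFF with pages along z (or as NIfTI), with
spacing and laterality in a small YAML sidecar.  Surfaces go to CSV with one
row per A-line: ``x_index, y_index, ilm_z, nflgcl_z, iplinl_z`` (0-based
voxel indices, fractional depths).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import TruthScene
from .volume import EnFaceMap, ScanVolume, SurfaceSet

__all__ = [
    "save_scan", "load_scan",
    "surfaces_to_csv", "surfaces_from_csv",
    "map_to_tiff", "map_to_csv", "map_from_tiff",
    "save_truth", "load_truth",
    "flatten_config", "write_config", "read_config",
]


def save_scan(directory, name: str, vol: ScanVolume, fmt: str = "tiff") -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    if fmt == "tiff":
        # pages along z: (z, x, y)
        tifffile.imwrite(d / f"{name}_structure.tif",
                         np.moveaxis(vol.structure, -1, 0))
        tifffile.imwrite(d / f"{name}_flow.tif", np.moveaxis(vol.flow, -1, 0))
    elif fmt == "nifti":
        import nibabel as nib
        aff = np.diag([vol.lateral_spacing_mm, vol.lateral_spacing_mm,
                       vol.axial_spacing_um / 1000.0, 1.0])
        nib.save(nib.Nifti1Image(vol.structure, aff), d / f"{name}_structure.nii")
        nib.save(nib.Nifti1Image(vol.flow, aff), d / f"{name}_flow.nii")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    meta = {
        "lateral_spacing_mm": float(vol.lateral_spacing_mm),
        "axial_spacing_um": float(vol.axial_spacing_um),
        "laterality": vol.laterality,
        "format": fmt,
    }
    (d / f"{name}_meta.yaml").write_text(yaml.safe_dump(meta))


def load_scan(directory, name: str) -> ScanVolume:
    d = Path(directory)
    meta = yaml.safe_load((d / f"{name}_meta.yaml").read_text())
    if meta["format"] == "tiff":
        structure = np.moveaxis(tifffile.imread(d / f"{name}_structure.tif"), 0, -1)
        flow = np.moveaxis(tifffile.imread(d / f"{name}_flow.tif"), 0, -1)
    else:
        import nibabel as nib
        structure = np.asarray(nib.load(d / f"{name}_structure.nii").dataobj)
        flow = np.asarray(nib.load(d / f"{name}_flow.nii").dataobj)
    return ScanVolume(structure=structure, flow=flow,
                      lateral_spacing_mm=meta["lateral_spacing_mm"],
                      axial_spacing_um=meta["axial_spacing_um"],
                      laterality=meta["laterality"])


def surfaces_to_csv(path, s: SurfaceSet) -> None:
    nx, ny = s.shape
    xi, yi = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pd.DataFrame({
        "x_index": xi.ravel(), "y_index": yi.ravel(),
        "ilm_z": s.ilm_z.ravel(), "nflgcl_z": s.nflgcl_z.ravel(),
        "iplinl_z": s.iplinl_z.ravel(),
    }).to_csv(path, index=False)


def surfaces_from_csv(path) -> SurfaceSet:
    df = pd.read_csv(path)
    nx = int(df["x_index"].max()) + 1
    ny = int(df["y_index"].max()) + 1
    out = {}
    for col in ("ilm_z", "nflgcl_z", "iplinl_z"):
        arr = np.full((nx, ny), np.nan)
        arr[df["x_index"], df["y_index"]] = df[col]
        out[col] = arr
    return SurfaceSet(**out)


def map_to_tiff(path, emap: EnFaceMap) -> None:
    tifffile.imwrite(path, emap.values.astype(np.float32),
                     metadata={"kind": emap.kind,
                               "lateral_spacing_mm": emap.lateral_spacing_mm})


def map_from_tiff(path, kind: str, lateral_spacing_mm: float) -> EnFaceMap:
    return EnFaceMap(values=tifffile.imread(path), kind=kind,
                     lateral_spacing_mm=lateral_spacing_mm)


def map_to_csv(path, emap: EnFaceMap) -> None:
    pd.DataFrame(emap.values).to_csv(path, index=False, header=False)


def save_truth(directory, name: str, scene: TruthScene) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / f"{name}_labels.tif",
                     np.moveaxis(scene.plexus_label_volume, -1, 0))
    tifffile.imwrite(d / f"{name}_cleanflow.tif",
                     np.moveaxis(scene.clean_flow, -1, 0))
    pd.DataFrame([{
        "true_watershed_fraction": scene.true_watershed_fraction,
        "faz_center_x_px": scene.faz_center_px[0],
        "faz_center_y_px": scene.faz_center_px[1],
    }]).to_csv(d / f"{name}_truth.csv", index=False)


def load_truth(directory, name: str) -> TruthScene:
    d = Path(directory)
    labels = np.moveaxis(tifffile.imread(d / f"{name}_labels.tif"), 0, -1)
    clean = np.moveaxis(tifffile.imread(d / f"{name}_cleanflow.tif"), 0, -1)
    row = pd.read_csv(d / f"{name}_truth.csv").iloc[0]
    return TruthScene(plexus_label_volume=labels, clean_flow=clean,
                      true_watershed_fraction=float(row["true_watershed_fraction"]),
                      faz_center_px=(float(row["faz_center_x_px"]),
                                     float(row["faz_center_y_px"])))


def flatten_config(obj, prefix: str = "") -> dict:
    """Flatten a (possibly nested) config dataclass to dotted key-value pairs."""
    out = {}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        items = dataclasses.asdict(obj).items()
    elif isinstance(obj, dict):
        items = obj.items()
    else:
        return {prefix.rstrip("."): obj}
    for k, v in items:
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(flatten_config(v, prefix=key + "."))
        elif isinstance(v, (list, tuple)):
            out[key] = list(v)
        else:
            out[key] = v
    return out


def write_config(path, cfg) -> None:
    Path(path).write_text(yaml.safe_dump(flatten_config(cfg), sort_keys=True))


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
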