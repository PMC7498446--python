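"""Shared file dialects: NIfTI-1 volumes, JSON contour files, TSV tables.

All volumes are reoriented to the canonical right/anterior/superior axes on
load; a flip relative to the file's stored orientation is logged rather than
silently applied.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .volume import Volume3D

log = logging.getLogger("strokeatlas")

CONTOUR_FORMAT = "strokeatlas-contours"
CONTOUR_VERSION = (1, 0)


def write_volume(vol: Volume3D, path: str | Path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.data), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> Volume3D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path.name}: expected a 3D volume, got shape {img.shape}")
    canonical = nib.as_closest_canonical(img)
    if canonical.affine is not None and not np.allclose(canonical.affine, img.affine):
        log.info("reoriented %s to canonical RAS axes", path.name)
    affine = canonical.affine
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-4):
        raise ValueError(f"{path.name}: oblique affine not supported; resample first")
    spacing = tuple(np.abs(np.diag(rot)))
    origin = tuple(affine[:3, 3])
    data = np.asanyarray(canonical.dataobj).astype(float)
    return Volume3D(data, spacing, origin)


def write_contours(cs, path: str | Path) -> None:
    doc = {
        "format": CONTOUR_FORMAT,
        "version": list(CONTOUR_VERSION),
        "grid": {
            "shape": list(cs.grid_shape),
            "spacing": list(cs.grid_spacing),
            "origin": list(cs.grid_origin),
        },
        "slices": [
            {
                "slice_index": int(k),
                "polygons": [np.asarray(p).tolist() for p in polys],
            }
            for k, polys in sorted(cs.slices.items())
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_contours(path: str | Path):
    from .lesionseg import ContourSet

    doc = json.loads(Path(path).read_text())
    if doc.get("format") != CONTOUR_FORMAT:
        raise ValueError(f"not a {CONTOUR_FORMAT} file")
    major = int(doc.get("version", [0])[0])
    if major != CONTOUR_VERSION[0]:
        raise ValueError(f"unsupported contour format major version {major}")
    grid = doc["grid"]
    slices = {
        int(s["slice_index"]): [np.asarray(p, dtype=float) for p in s["polygons"]]
        for s in doc["slices"]
    }
    return ContourSet(
        slices=slices,
        grid_shape=tuple(grid["shape"]),
        grid_spacing=tuple(grid["spacing"]),
        grid_origin=tuple(grid["origin"]),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"table {Path(path).name} missing required columns: {missing}")
    return df


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))
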