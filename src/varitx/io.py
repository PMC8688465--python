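"""Readers and writers for the standard formats the pipeline touches.

NIfTI voxel maps (through nibabel, against a mask image), GMT gene-set
files, run manifests with motion-QC flags, and YAML/JSON configuration.
Voxel indexing is 0-based over the flattened mask in C (scanner-space
array) order; the same convention is used everywhere in the package.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .containers import GeneSetCollection

__all__ = [
    "read_map", "write_map", "mask_voxel_table",
    "read_gmt", "write_gmt",
    "read_manifest", "read_config", "write_provenance",
]

FD_THRESHOLD_MM = 0.2   # runs with mean FD at or above this fail QC


def _mask_array(mask_img: nib.Nifti1Image) -> np.ndarray:
    mask = np.asarray(mask_img.dataobj) > 0
    if mask.sum() == 0:
        raise ValueError("mask contains 0 voxels")
    return mask


def write_map(values: np.ndarray, mask_img: nib.Nifti1Image,
              path: str | Path) -> None:
    """Write a per-voxel vector as a 3-D NIfTI volume inside the mask."""
    mask = _mask_array(mask_img)
    values = np.asarray(values, dtype=np.float32)
    if values.size != int(mask.sum()):
        raise ValueError("value count does not match the mask voxel count")
    vol = np.zeros(mask.shape, dtype=np.float32)
    vol[mask] = values
    nib.save(nib.Nifti1Image(vol, mask_img.affine), str(path))


def read_map(path: str | Path, mask_img: nib.Nifti1Image) -> np.ndarray:
    """Read a NIfTI map as a voxel vector over the mask.

    Shape and affine must match the mask exactly; NaN outside the mask is
    ignored, NaN inside the mask is an error listing the voxels.
    """
    img = nib.load(str(path))
    mask = _mask_array(mask_img)
    if img.shape != mask.shape:
        raise ValueError(f"map shape {img.shape} does not match the mask "
                         f"{mask.shape}")
    if not np.allclose(img.affine, mask_img.affine):
        raise ValueError("map affine does not match the mask affine")
    values = np.asarray(img.dataobj, dtype=np.float32)[mask]
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValueError(f"NaN/inf inside the mask at voxels {bad[:10]}")
    return values


def mask_voxel_table(mask_img: nib.Nifti1Image) -> pd.DataFrame:
    """voxel_id <-> (i, j, k) and mm coordinates for the flattened mask."""
    mask = _mask_array(mask_img)
    ijk = np.argwhere(mask)
    mm = nib.affines.apply_affine(mask_img.affine, ijk)
    df = pd.DataFrame({"voxel_id": np.arange(len(ijk)),
                       "i": ijk[:, 0], "j": ijk[:, 1], "k": ijk[:, 2],
                       "x_mm": mm[:, 0], "y_mm": mm[:, 1], "z_mm": mm[:, 2]})
    return df


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, genes...).

    Duplicate genes within a set are collapsed with a warning; an empty
    set line is an error naming the line number.  The background is the
    union of all genes.
    """
    sets: dict[str, set] = {}
    background: dict[str, None] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not any(g.strip() for g in parts[2:]):
            raise ValueError(f"{path}: empty gene set on line {lineno}")
        name, genes = parts[0], [g for g in parts[2:] if g.strip()]
        if len(genes) != len(set(genes)):
            warnings.warn(f"set {name!r}: duplicate genes collapsed")
        sets[name] = set(genes)
        for g in genes:
            background.setdefault(g)
    return GeneSetCollection(sets=sets, background=list(background))


def write_gmt(collection: GeneSetCollection, path: str | Path,
              descriptions: dict | None = None) -> None:
    lines = []
    for name, members in collection.sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path,
                  fd_threshold: float = FD_THRESHOLD_MM) -> pd.DataFrame:
    """Run manifest TSV: subject, session, run, path[, mean_fd].

    Adds a ``qc_pass`` column (mean FD below the threshold; runs without
    an FD value pass).  Duplicate (subject, session, run) rows are an
    error.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"subject", "session", "run", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df.duplicated(["subject", "session", "run"]).any():
        raise ValueError("duplicate (subject, session, run) rows in manifest")
    if "mean_fd" in df.columns:
        df["qc_pass"] = df["mean_fd"].isna() | (df["mean_fd"] < fd_threshold)
    else:
        df["qc_pass"] = True
    return df


def read_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_provenance(record: dict, path: str | Path) -> None:
    import numpy
    import scipy

    from . import __version__

    record = dict(record)
    record["versions"] = {"varitx": __version__,
                          "numpy": numpy.__version__,
                          "scipy": scipy.__version__}
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True,
                                     default=str) + "\n")
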