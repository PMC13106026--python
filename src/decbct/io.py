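"""Persistence: NPZ sinogram containers, volumes with JSON sidecars, MetaImage.

Every artifact written by the pipeline carries provenance (config hash,
package version, per-stage seeds, timestamp) in its sidecar or NPZ metadata.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from .acquisition import ProjectionSet
from .decomposition import BasisSinogram
from .reconstruction import ReconGrid, Volume


def config_hash(config_dict: dict) -> str:
    """Stable hash of a configuration mapping (canonical YAML, sha256)."""
    text = yaml.safe_dump(config_dict, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def provenance(config_dict: dict | None = None, seeds: dict | None = None) -> dict:
    from . import __version__

    return {
        "package_version": __version__,
        "config_hash": config_hash(config_dict or {}),
        "seeds": seeds or {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


# -- sinograms ---------------------------------------------------------------


def save_projections(path, pset: ProjectionSet) -> None:
    np.savez_compressed(
        path,
        angles=pset.angles,
        line_integrals=pset.line_integrals,
        kvp=pset.kvp,
        mAs_per_pulse=pset.mAs_per_pulse,
        seed=-1 if pset.seed is None else pset.seed,
        meta=json.dumps(pset.meta, default=float),
    )


def load_projections(path) -> ProjectionSet:
    with np.load(path, allow_pickle=False) as z:
        seed = int(z["seed"])
        return ProjectionSet(
            angles=z["angles"],
            line_integrals=z["line_integrals"],
            kvp=float(z["kvp"]),
            mAs_per_pulse=float(z["mAs_per_pulse"]),
            seed=None if seed < 0 else seed,
            meta=json.loads(str(z["meta"])),
        )


def save_basis(path, basis: BasisSinogram) -> None:
    np.savez_compressed(
        path,
        t_al=basis.t_al,
        t_pmma=basis.t_pmma,
        angles=basis.angles,
        provenance=json.dumps(basis.provenance, default=str),
    )


def load_basis(path) -> BasisSinogram:
    with np.load(path, allow_pickle=False) as z:
        return BasisSinogram(
            t_al=z["t_al"],
            t_pmma=z["t_pmma"],
            angles=z["angles"],
            provenance=json.loads(str(z["provenance"])),
        )


# -- volumes -----------------------------------------------------------------


def save_volume(path, volume: Volume, sidecar: dict | None = None) -> None:
    """NPZ voxel data plus a JSON sidecar with grid, unit tag and provenance."""
    path = Path(path)
    np.savez_compressed(path, values=volume.values)
    meta = {
        "unit": volume.unit,
        "voxel_mm": volume.grid.voxel_mm,
        "dims": [volume.grid.nx, volume.grid.ny, volume.grid.nz],
        "slice_mm": volume.grid.slice_mm,
    }
    meta.update(sidecar or {})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=float))


def load_volume(path) -> Volume:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as z:
        values = z["values"]
    nx, ny, nz = meta["dims"]
    grid = ReconGrid(
        voxel_mm=meta["voxel_mm"], nx=nx, ny=ny, nz=nz, slice_mm=meta.get("slice_mm")
    )
    return Volume(values=values, grid=grid, unit=meta["unit"])


def write_mhd(path, volume: Volume) -> None:
    """Minimal MetaImage (MHD + RAW) writer for interoperability."""
    path = Path(path)
    raw = path.with_suffix(".raw")
    values = volume.values
    data = (values[None] if values.ndim == 2 else values).astype(np.float32)
    data.tofile(raw)
    nz, ny, nx = data.shape
    header = "\n".join(
        [
            "ObjectType = Image",
            "NDims = 3",
            "BinaryData = True",
            "BinaryDataByteOrderMSB = False",
            f"DimSize = {nx} {ny} {nz}",
            f"ElementSpacing = {volume.grid.voxel_mm} {volume.grid.voxel_mm} "
            f"{volume.grid.dz}",
            "ElementType = MET_FLOAT",
            f"ElementDataFile = {raw.name}",
            "",
        ]
    )
    path.write_text(header)
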