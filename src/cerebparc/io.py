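"""Readers and writers: NIfTI volumes, delimited matrices, sidecars.

Conventions stated in every sidecar: coordinates are voxel centers in
millimetres derived from the affine; voxel indices are 0-based, C-order
linearized over the grid axes; column order of a matrix file is the
ascending linear voxel index.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .bold import BoldSeries
from .errors import FormatError, InvalidArgumentError
from .geometry import VoxelGeometry
from .parcellation import Parcellation

__all__ = [
    "write_bold",
    "read_bold",
    "write_parcellation",
    "read_parcellation",
    "write_geometry_sidecar",
    "read_geometry_sidecar",
    "write_decomposition",
    "read_decomposition",
]

_SIDECAR_NOTE = (
    "coords are voxel centers in mm; voxel_id is the 0-based C-order "
    "linear index over grid axes; matrix columns follow ascending voxel_id"
)


def _affine(geometry: VoxelGeometry) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = geometry.spacing
    return aff


def write_geometry_sidecar(geometry: VoxelGeometry, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# grid_shape: {list(geometry.grid_shape)}\n")
        fh.write(f"# spacing: {list(geometry.spacing)}\n")
        fh.write(f"# hemisphere: {geometry.hemisphere}\n")
        fh.write(f"# note: {_SIDECAR_NOTE}\n")
        fh.write("voxel_id\tx\ty\tz\n")
        for vid, (x, y, z) in zip(geometry.voxel_ids, geometry.coords):
            fh.write(f"{int(vid)}\t{float(x)!r}\t{float(y)!r}\t{float(z)!r}\n")


def read_geometry_sidecar(path) -> VoxelGeometry:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    tab = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    required = {"voxel_id", "x", "y", "z"}
    if not required <= set(tab.columns):
        raise FormatError(f"{path}: sidecar must have columns {sorted(required)}")
    try:
        grid_shape = tuple(json.loads(meta["grid_shape"]))
        spacing = tuple(json.loads(meta["spacing"]))
    except (KeyError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: missing/invalid grid_shape or spacing header") from exc
    return VoxelGeometry(
        voxel_ids=tab["voxel_id"].to_numpy(),
        coords=tab[["x", "y", "z"]].to_numpy(),
        grid_shape=grid_shape,
        spacing=spacing,
        hemisphere=meta.get("hemisphere", "synthetic"),
    )


def write_bold(b: BoldSeries, path, geometry_path=None) -> None:
    """Write a subject as 4D NIfTI (+mask) or matrix TSV (+sidecar).

    Dispatch on extension: ``.nii``/``.nii.gz`` writes a 4D volume with
    the lattice affine and a companion ``*_mask.nii.gz``; ``.tsv``
    writes the T x V matrix with voxel ids as the header and a geometry
    sidecar at ``geometry_path`` (default: ``<stem>_geometry.tsv``).
    """
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        geom = b.geometry
        vol = np.zeros(geom.grid_shape + (b.n_timepoints,))
        flat = vol.reshape(-1, b.n_timepoints)
        flat[geom.voxel_ids] = b.data.T
        nib.save(nib.Nifti1Image(vol, _affine(geom)), str(path))
        mask = np.zeros(geom.grid_shape, dtype=np.uint8)
        mask.reshape(-1)[geom.voxel_ids] = 1
        stem = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
        nib.save(nib.Nifti1Image(mask, _affine(geom)), str(path.parent / f"{stem}_mask.nii.gz"))
    elif path.suffix == ".tsv":
        header = "\t".join(str(v) for v in b.geometry.voxel_ids)
        with open(path, "w") as fh:
            fh.write(f"# subject: {b.subject_id}\n")
            fh.write(f"# condition: {b.condition}\n")
            fh.write(f"# standardized: {b.standardized}\n")
            fh.write(header + "\n")
            for row in b.data:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")
        gpath = Path(geometry_path) if geometry_path else path.with_name(path.stem + "_geometry.tsv")
        write_geometry_sidecar(b.geometry, gpath)
    else:
        raise InvalidArgumentError(f"unsupported extension for {path}")


def read_bold(path, geometry_path=None, mask_path=None,
              subject_id: Optional[str] = None, condition: str = "synthetic") -> BoldSeries:
    """Read a subject written by :func:`write_bold`.

    Voxel order is the ascending C-order linear index, matching the
    writer's contract.
    """
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data4d = np.asarray(img.dataobj, dtype=np.float64)
        if data4d.ndim != 4:
            raise FormatError(f"{path}: expected a 4D volume, got shape {data4d.shape}")
        if mask_path is None:
            stem = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
            mask_path = path.parent / f"{stem}_mask.nii.gz"
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj) > 0
        if mask.shape != data4d.shape[:3]:
            raise FormatError(
                f"mask {mask_path} shape {mask.shape} does not match data "
                f"{path} spatial shape {data4d.shape[:3]}"
            )
        grid_shape = mask.shape
        voxel_ids = np.flatnonzero(mask.reshape(-1))
        aff = img.affine
        spacing = tuple(float(aff[i, i]) for i in range(3))
        idx = np.stack(np.unravel_index(voxel_ids, grid_shape), axis=1)
        coords = (aff[:3, :3] @ idx.T).T + aff[:3, 3]
        geom = VoxelGeometry(voxel_ids=voxel_ids, coords=coords,
                             grid_shape=grid_shape, spacing=spacing)
        data = data4d.reshape(-1, data4d.shape[3])[voxel_ids].T
        return BoldSeries(subject_id=subject_id or path.name, condition=condition,
                          data=data, geometry=geom)
    elif path.suffix == ".tsv":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
        tab = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        gpath = Path(geometry_path) if geometry_path else path.with_name(path.stem + "_geometry.tsv")
        geom = read_geometry_sidecar(gpath)
        order = np.argsort([int(c) for c in tab.columns])
        data = tab.to_numpy()[:, order]
        standardized = meta.get("standardized", "False") == "True"
        return BoldSeries(
            subject_id=subject_id or meta.get("subject", path.stem),
            condition=condition if condition != "synthetic" else meta.get("condition", "synthetic"),
            data=data,
            geometry=geom,
            standardized=standardized,
        )
    raise InvalidArgumentError(f"unsupported extension for {path}")


def write_parcellation(parc: Parcellation, path, legend_path=None) -> None:
    """Integer NIfTI label volume (0 = unassigned) plus a TSV legend."""
    if parc.geometry is None:
        raise InvalidArgumentError("parcellation has no geometry attached")
    if parc.labels.size == 0:
        raise InvalidArgumentError("empty parcellation")
    path = Path(path)
    geom = parc.geometry
    vol = np.zeros(geom.grid_shape, dtype=np.int16)
    vol.reshape(-1)[geom.voxel_ids] = parc.labels.astype(np.int16)
    nib.save(nib.Nifti1Image(vol, _affine(geom)), str(path))
    if legend_path is None:
        stem = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
        legend_path = path.parent / f"{stem}_legend.tsv"
    counts = parc.label_counts()
    with open(legend_path, "w") as fh:
        fh.write("label\tn_voxels\n")
        for lab in sorted(counts):
            fh.write(f"{lab}\t{counts[lab]}\n")
        fh.write(f"0\t{int((parc.labels == 0).sum())}\n")


def read_parcellation(path, geometry: VoxelGeometry) -> Parcellation:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj).astype(np.int64)
    if vol.shape != geometry.grid_shape:
        raise FormatError(
            f"{path}: label volume shape {vol.shape} does not match geometry "
            f"grid {geometry.grid_shape}"
        )
    labels = vol.reshape(-1)[geometry.voxel_ids]
    K = int(labels.max()) if labels.size else 0
    return Parcellation(labels=labels, geometry=geometry, K=K,
                        threshold=np.nan, provenance={"source": str(path)})


def write_decomposition(dec, outdir, extra_manifest: Optional[dict] = None) -> None:
    """Arrays as .npz plus a YAML manifest of provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savez(outdir / "decomposition.npz", dictionary=dec.dictionary,
             group_maps=dec.group_maps, objective_trace=dec.objective_trace)
    manifest = {
        "K": int(dec.K),
        "lambda": float(dec.lam),
        "seed": int(dec.seed),
        "n_iterations": int(len(dec.objective_trace)),
        "final_objective": float(dec.objective_trace[-1]),
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(outdir / "decomposition.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_decomposition(outdir):
    from .decomposition import GroupDecomposition

    outdir = Path(outdir)
    arrays = np.load(outdir / "decomposition.npz")
    with open(outdir / "decomposition.yaml") as fh:
        manifest = yaml.safe_load(fh)
    return GroupDecomposition(
        dictionary=arrays["dictionary"],
        group_maps=arrays["group_maps"],
        K=manifest["K"],
        lam=manifest["lambda"],
        objective_trace=arrays["objective_trace"],
        seed=manifest["seed"],
    )
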