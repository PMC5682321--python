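"""Readers and writers for the on-disk formats the pipeline speaks.

Time series travel as TSV (one row per voxel, columns = timepoints) with
a JSON sidecar carrying ROI metadata, or as NIfTI 4D volumes with an
integer-labelled ROI mask.  DWI gradient tables use the FSL dialect
(bvals: one row; bvecs: three rows of components).  Tract voxel sets are
CSVs with columns ``tract_name,x,y,z``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dti import GradientTable
from .granger import EdgeMatrix, GCWindowResult
from .simulate import TractGeometry
from .timeseries import ROITimeSeries

__all__ = [
    "write_roi_series",
    "read_roi_series",
    "read_roi_series_nifti",
    "write_edge_matrix",
    "read_edge_matrix",
    "write_gc_report",
    "read_fsl_gradients",
    "write_fsl_gradients",
    "write_scalar_map",
    "read_scalar_map",
    "read_tract_voxels",
    "write_tract_voxels",
]


# ---------------------------------------------------------------------------
# ROI time series
# ---------------------------------------------------------------------------


def write_roi_series(roi: ROITimeSeries, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (voxels x time) and ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    sidecar = prefix.with_suffix(".json")
    np.savetxt(tsv, roi.data, delimiter="\t")
    sidecar.write_text(
        json.dumps(
            {
                "roi_name": roi.roi_name,
                "voxel_ids": [list(v) for v in roi.voxel_ids],
                "tr_seconds": roi.tr_seconds,
            },
            indent=2,
        )
    )
    return tsv, sidecar


def read_roi_series(prefix: str | Path) -> ROITimeSeries:
    """Read a TSV + JSON sidecar pair written by :func:`write_roi_series`."""
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.atleast_2d(np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t"))
    return ROITimeSeries(
        roi_name=meta["roi_name"],
        voxel_ids=[tuple(v) for v in meta["voxel_ids"]],
        data=data,
        tr_seconds=float(meta.get("tr_seconds", 2.0)),
    )


def read_roi_series_nifti(
    image_path: str | Path,
    mask_path: str | Path,
    label_map: dict[int, str],
    tr_seconds: float | None = None,
) -> dict[str, ROITimeSeries]:
    """Extract ROI voxel series from a 4D NIfTI and integer-label mask.

    ``label_map`` maps mask integer labels to ROI names; voxel indices
    follow the mask array order, 0-based, with no world-space transform.
    """
    img = nib.load(str(image_path))
    mask = nib.load(str(mask_path))
    vol = np.asarray(img.dataobj, dtype=float)
    labels = np.asarray(mask.dataobj).astype(int)
    if vol.ndim != 4:
        raise ValueError("image must be a 4D volume")
    if labels.shape != vol.shape[:3]:
        raise ValueError("mask grid does not match image grid")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    out: dict[str, ROITimeSeries] = {}
    for label, name in label_map.items():
        coords = np.argwhere(labels == label)
        if coords.size == 0:
            raise ValueError(f"label {label} ({name}) absent from mask")
        data = vol[coords[:, 0], coords[:, 1], coords[:, 2], :]
        out[name] = ROITimeSeries(
            roi_name=name,
            voxel_ids=[tuple(int(c) for c in xyz) for xyz in coords],
            data=data,
            tr_seconds=tr_seconds,
        )
    return out


# ---------------------------------------------------------------------------
# edge matrices and GC reports
# ---------------------------------------------------------------------------


def write_edge_matrix(edges: EdgeMatrix, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(edges.gc, index=edges.roi_names, columns=edges.roi_names)
    frame.to_csv(path, sep="\t")
    return path


def read_edge_matrix(path: str | Path) -> EdgeMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return EdgeMatrix(roi_names=list(frame.index), gc=frame.values.astype(float))


def write_gc_report(
    details: dict[str, GCWindowResult], path: str | Path
) -> Path:
    """JSON report of per-edge windowed GC details (edge key ``SRC->TGT``)."""
    path = Path(path)
    payload = {edge: dataclasses.asdict(res) for edge, res in details.items()}
    path.write_text(json.dumps(payload, indent=2, default=float))
    return path


# ---------------------------------------------------------------------------
# DWI gradients, scalar maps, tract voxel sets
# ---------------------------------------------------------------------------


def read_fsl_gradients(bvals_path: str | Path, bvecs_path: str | Path) -> GradientTable:
    """FSL dialect: bvals one row; bvecs three rows of vector components."""
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return GradientTable(bvals=bvals, bvecs=bvecs)


def write_fsl_gradients(
    gtab: GradientTable, bvals_path: str | Path, bvecs_path: str | Path
) -> None:
    np.savetxt(bvals_path, gtab.bvals[None, :], fmt="%.1f")
    np.savetxt(bvecs_path, gtab.bvecs.T, fmt="%.8f")


def write_scalar_map(volume: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), np.eye(4)), str(path))
    return path


def read_scalar_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def read_tract_voxels(path: str | Path) -> dict[str, np.ndarray]:
    """CSV with columns tract_name,x,y,z -> {tract: (n, 3) int array}."""
    frame = pd.read_csv(path)
    required = {"tract_name", "x", "y", "z"}
    if not required.issubset(frame.columns):
        raise ValueError(f"tract CSV must have columns {sorted(required)}")
    return {
        name: grp[["x", "y", "z"]].to_numpy(dtype=int)
        for name, grp in frame.groupby("tract_name", sort=True)
    }


def write_tract_voxels(
    geometry: dict[str, TractGeometry] | dict[str, np.ndarray], path: str | Path
) -> Path:
    path = Path(path)
    rows = []
    for name, geom in geometry.items():
        voxels = geom.voxels if isinstance(geom, TractGeometry) else np.asarray(geom)
        for x, y, z in voxels:
            rows.append({"tract_name": name, "x": int(x), "y": int(y), "z": int(z)})
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
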