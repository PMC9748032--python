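"""Readers and writers: NIfTI masks, cohort tables, deterministic reports.

Readers validate and reject malformed input rather than silently coercing;
writers are byte-deterministic (sorted keys, floats at 6 significant digits)
so identical inputs always produce identical report files.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
import pathlib
import warnings

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ValidationError
from .grid import LesionMask, VoxelGrid

__all__ = [
    "read_mask",
    "write_mask",
    "read_roi_points",
    "read_roi_polygons",
    "read_cohort_table",
    "validate_cohort",
    "write_report",
    "load_table1",
    "load_table2",
]

COHORT_REQUIRED_COLUMNS = (
    "subject_id",
    "initial_score",
    "manual_tv_cc",
    "manual_tmd_cm",
    "auto_tv_cc",
    "auto_tmd_cm",
)


def read_mask(
    path,
    thickness_mm: float | None = None,
    gap_mm: float | None = None,
) -> LesionMask:
    """Read a binary lesion mask from a NIfTI file.

    Values > 0 are inside (masks may arrive as probability-like floats).
    The in-plane spacing and origin come from the header affine.  When
    ``thickness_mm``/``gap_mm`` are given they define the slice profile and
    override the header z-spacing semantics (clinical exports often store
    centre spacing without gap information); otherwise the header z-spacing
    is taken as slice thickness with zero gap.

    An all-zero volume is returned with a warning; measurement operations
    will refuse it.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise FormatError(f"could not read NIfTI mask {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {data.shape}")
    occ = data > 0

    dx, dy, dz_header = (float(v) for v in nib.affines.voxel_sizes(img.affine))
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if (thickness_mm is None) != (gap_mm is None):
        raise ValidationError("provide both thickness_mm and gap_mm, or neither")
    if thickness_mm is not None:
        thickness, gap = float(thickness_mm), float(gap_mm)
    else:
        thickness, gap = dz_header, 0.0
    grid = VoxelGrid(
        nx=occ.shape[0], ny=occ.shape[1], nz=occ.shape[2],
        dx=dx, dy=dy, slice_thickness=thickness, slice_gap=gap, origin=origin,
    )
    if not occ.any():
        warnings.warn(f"mask {path} contains no inside voxels", stacklevel=2)
    return LesionMask(grid, occ)


def write_mask(mask: LesionMask, path) -> None:
    """Write a lesion mask as uint8 NIfTI with slice-centre z-spacing."""
    g = mask.grid
    affine = np.diag([g.dx, g.dy, g.dz, 1.0])
    affine[:3, 3] = g.origin
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), affine)
    img.to_filename(str(path))


def read_roi_points(path, grid: VoxelGrid) -> LesionMask:
    """Read per-slice ROI voxel lists from CSV (columns: slice_index, i, j).

    Each row marks voxel (i, j) of slice ``slice_index`` as inside.  Indices
    must lie within the supplied grid.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse ROI CSV {path}: {exc}") from exc
    required = ("slice_index", "i", "j")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"ROI CSV is missing columns: {missing}")
    if len(table) == 0:
        raise EmptyInputError(f"ROI CSV {path} lists no voxels")
    idx = table[list(required)].to_numpy()
    if not np.issubdtype(idx.dtype, np.integer):
        if not np.allclose(idx, np.round(idx)):
            raise ValidationError("ROI CSV indices must be integers")
        idx = np.round(idx).astype(int)
    k, i, j = idx[:, 0], idx[:, 1], idx[:, 2]
    if ((i < 0) | (i >= grid.nx) | (j < 0) | (j >= grid.ny)
            | (k < 0) | (k >= grid.nz)).any():
        raise ValidationError("ROI CSV indices fall outside the voxel grid")
    occ = np.zeros(grid.shape, dtype=bool)
    occ[i, j, k] = True
    return LesionMask(grid, occ)


def read_roi_polygons(path, grid: VoxelGrid) -> LesionMask:
    """Read per-slice ROI polygons from JSON.

    Dialect: ``{"slices": [{"slice_index": k, "polygon": [[i, j], ...]},
    ...]}`` with vertices in voxel-index units; each polygon is rasterized
    (voxel centres inside or on the outline are inside).  Multiple entries
    for one slice union.
    """
    from skimage.draw import polygon as _raster_polygon

    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"could not parse ROI JSON {path}: {exc}") from exc
    entries = payload.get("slices") if isinstance(payload, dict) else None
    if not entries:
        raise ValidationError('ROI JSON must contain a non-empty "slices" list')
    occ = np.zeros(grid.shape, dtype=bool)
    for entry in entries:
        try:
            k = int(entry["slice_index"])
            verts = np.asarray(entry["polygon"], dtype=float)
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"malformed ROI JSON entry {entry!r}") from exc
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValidationError("each polygon needs >= 3 [i, j] vertices")
        if not (0 <= k < grid.nz):
            raise ValidationError(f"slice_index {k} outside the grid")
        rr, cc = _raster_polygon(verts[:, 0], verts[:, 1],
                                 shape=(grid.nx, grid.ny))
        occ[rr, cc, k] = True
    if not occ.any():
        raise EmptyInputError(f"ROI JSON {path} rasterizes to an empty mask")
    return LesionMask(grid, occ)


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the documented cohort-table schema; returns a typed copy."""
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table is missing columns: {missing}")
    table = table.copy()
    if len(table) == 0:
        table["initial_score"] = table["initial_score"].astype(int)
        return table
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject_id values: {dupes}")
    try:
        table["initial_score"] = table["initial_score"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"initial_score must be integer: {exc}") from exc
    bad = ~table["initial_score"].isin((3, 4, 5))
    if bad.any():
        raise ValidationError(
            f"initial_score outside {{3,4,5}}: {sorted(table.loc[bad, 'initial_score'].unique())}"
        )
    for col in COHORT_REQUIRED_COLUMNS[2:]:
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any():
            raise ValidationError(f"column {col} must be non-negative numbers")
        table[col] = vals
    if "rescored_score" in table.columns:
        resc = pd.to_numeric(table["rescored_score"], errors="coerce")
        known = resc.dropna()
        if not known.isin((3, 4, 5)).all():
            raise ValidationError("rescored_score outside {3,4,5}")
    return table


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (documented header, one row per subject)."""
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse cohort CSV {path}: {exc}") from exc
    return validate_cohort(table)


def _six_sig(x: float) -> float:
    return float(f"{x:.6g}")


def _canonical(obj):
    """Recursively convert a report to a deterministic JSON-ready form."""
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _canonical(obj.tolist())
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        return _six_sig(float(obj))
    return obj


def _flatten(obj, prefix=""):
    if isinstance(obj, dict):
        for k, v in obj.items():
            yield from _flatten(v, f"{prefix}{k}.")
    elif isinstance(obj, list):
        for i, v in enumerate(obj):
            yield from _flatten(v, f"{prefix}{i}.")
    else:
        yield prefix.rstrip("."), obj


def write_report(report: dict, path, fmt: str = "json") -> None:
    """Write a measurement/rescoring/statistics report deterministically.

    JSON: sorted keys, floats at 6 significant digits, trailing newline.
    CSV: flattened dotted keys, sorted, two columns (key, value).
    """
    if not isinstance(report, dict) or len(report) == 0:
        raise EmptyInputError("report must be a non-empty mapping")
    if fmt not in ("json", "csv"):
        raise ValidationError(f"unknown report format {fmt!r} (use 'json' or 'csv')")
    canon = _canonical(report)
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        text = json.dumps(canon, sort_keys=True, indent=2) + "\n"
        path.write_text(text)
    else:
        rows = sorted(_flatten(canon))
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["key", "value"])
            for key, value in rows:
                writer.writerow([key, value])


def _data_path(name: str):
    return importlib.resources.files("lesionfit3d").joinpath("data", name)


def load_table2() -> pd.DataFrame:
    """Packaged fixture: the 15 published subjects whose score changed.

    Section A: 4 initially score-3 subjects; section B: 11 initially score-4
    subjects; columns follow the cohort-table schema plus ``section`` and the
    published ``rescored_score``.
    """
    with importlib.resources.as_file(_data_path("table2.csv")) as p:
        return validate_cohort(pd.read_csv(p))


def load_table1() -> pd.DataFrame:
    """Packaged fixture: per-score mean/SD of TV (cc) and TMD (cm), both methods."""
    with importlib.resources.as_file(_data_path("table1.csv")) as p:
        return pd.read_csv(p, index_col="score")
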