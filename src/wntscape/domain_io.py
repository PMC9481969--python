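"""Reading and writing catalogues, volumes, tables and networks.

Volume formats are NIfTI-1 (``.nii``/``.nii.gz``, via nibabel) and
multi-page TIFF (via tifffile).  A catalogue is indexed by a manifest:
either a CSV with header ``label,family,stage,file`` (special family
values ``embryo`` and ``anatomy`` mark the foreground mask and the label
volume) or an equivalent JSON document that additionally records voxel
size, origin and the anatomy name table.  :func:`write_catalog` emits the
JSON form, since CSV cannot carry grid metadata for TIFF volumes.

Input masks are binarized with the fixed rule ``value > 0 -> True``;
greyscale thresholding of raw signal is out of scope.  The native Woolz
(.wlz) format of the deposited atlas data is not parsed — convert to
NIfTI or TIFF first (see README).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import TYPE_CHECKING

import nibabel as nib
import numpy as np
import tifffile

from .domains import AnatomyLabels, BinaryDomain, DomainCatalog, VoxelGrid
from .errors import GridCompatibilityError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .volumetrics import PairwiseTable

AXIS_ORDER = "plane,row,column"

_EMBRYO_FAMILY = "embryo"
_ANATOMY_FAMILY = "anatomy"


# ---------------------------------------------------------------------------
# single volumes


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    """Read one volume; return (array, voxel_size_um or None).

    NIfTI headers carry voxel size; TIFF files do not (the manifest does).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise ValidationError(f"{path}: expected a 3D volume, got shape {data.shape}")
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return data, zooms
    if suffixes.endswith((".tif", ".tiff")):
        data = tifffile.imread(str(path))
        if data.ndim != 3:
            raise ValidationError(f"{path}: expected a 3D volume, got shape {data.shape}")
        return np.asarray(data), None
    raise ValidationError(f"unsupported volume format: {path}")


def write_volume(
    array: np.ndarray,
    path: str | Path,
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> None:
    """Write one volume; NIfTI records the voxel size in its header."""
    path = Path(path)
    array = np.asarray(array)
    if array.dtype == np.bool_:
        array = array.astype(np.uint8)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(voxel_size_um) + [1.0])
        img = nib.Nifti1Image(array, affine)
        img.header.set_zooms(voxel_size_um)
        nib.save(img, str(path))
    elif suffixes.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), array)
    else:
        raise ValidationError(f"unsupported volume format: {path}")


# ---------------------------------------------------------------------------
# catalogues


def read_catalog(manifest_path: str | Path) -> DomainCatalog:
    """Read a catalogue from a CSV or JSON manifest.

    All listed volumes must decode to the same shape; the first volume
    fixes the grid.  Masks are binarized with ``value > 0``.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise IOError(f"manifest not found: {manifest_path}")
    if manifest_path.suffix.lower() == ".json":
        return _read_json_manifest(manifest_path)
    return _read_csv_manifest(manifest_path)


def _read_rows(
    rows: list[dict],
    base: Path,
    voxel_size_um: tuple[float, float, float] | None,
    origin_um: tuple[float, float, float],
    anatomy_names: dict[int, str] | None,
) -> DomainCatalog:
    grid: VoxelGrid | None = None
    domains: list[BinaryDomain] = []
    embryo: BinaryDomain | None = None
    anatomy_volume: np.ndarray | None = None

    for row in rows:
        label = str(row["label"])
        family = str(row["family"])
        stage = str(row.get("stage", ""))
        file_entry = str(row["file"])
        fpath = Path(file_entry)
        if not fpath.is_absolute():
            fpath = base / fpath
        try:
            data, zooms = read_volume(fpath)
        except IOError as exc:
            raise IOError(
                f"manifest row (label={label!r}, family={family!r}, stage={stage!r}): {exc}"
            ) from exc
        if grid is None:
            vsize = voxel_size_um or zooms or (1.0, 1.0, 1.0)
            grid = VoxelGrid(shape=data.shape, voxel_size_um=vsize, origin_um=origin_um)
        elif data.shape != grid.shape:
            raise GridCompatibilityError(
                f"volume for {label!r} has shape {data.shape}, "
                f"but the catalogue grid is {grid.shape}"
            )
        if family == _ANATOMY_FAMILY:
            anatomy_volume = np.asarray(data)
        elif family == _EMBRYO_FAMILY:
            embryo = BinaryDomain(grid, data > 0, label=label, family="other", stage=stage)
        else:
            domains.append(BinaryDomain(grid, data > 0, label=label, family=family, stage=stage))

    if grid is None:
        raise ValidationError("manifest lists no volumes")

    anatomy = None
    if anatomy_volume is not None:
        names = anatomy_names
        if names is None:
            names = {
                int(v): f"label_{int(v)}" for v in np.unique(anatomy_volume) if v != 0
            }
        anatomy = AnatomyLabels(volume=anatomy_volume, names=names)
    return DomainCatalog(grid=grid, domains=domains, embryo_mask=embryo, anatomy=anatomy)


def _read_csv_manifest(path: Path) -> DomainCatalog:
    with open(path, newline="") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        required = {"label", "family", "stage", "file"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(
                f"CSV manifest must have header columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        rows = list(reader)
    return _read_rows(rows, path.parent, None, (0.0, 0.0, 0.0), None)


def _read_json_manifest(path: Path) -> DomainCatalog:
    with open(path) as fh:
        doc = json.load(fh)
    rows = [dict(r) for r in doc.get("domains", [])]
    if doc.get("embryo_mask"):
        entry = doc["embryo_mask"]
        if isinstance(entry, str):
            entry = {"label": "embryo", "file": entry}
        rows.append({**entry, "family": _EMBRYO_FAMILY, "label": entry.get("label", "embryo")})
    anatomy_names = None
    if doc.get("anatomy"):
        entry = doc["anatomy"]
        rows.append(
            {"label": entry.get("label", "anatomy"), "family": _ANATOMY_FAMILY,
             "file": entry["file"]}
        )
        if "names" in entry:
            anatomy_names = {int(k): str(v) for k, v in entry["names"].items()}
    vsize = doc.get("voxel_size_um")
    vsize = tuple(float(v) for v in vsize) if vsize else None
    origin = tuple(float(v) for v in doc.get("origin_um", (0.0, 0.0, 0.0)))
    return _read_rows(rows, path.parent, vsize, origin, anatomy_names)


def _safe_name(*parts: str) -> str:
    keep = []
    for p in parts:
        if p:
            keep.append("".join(c if (c.isalnum() or c in "-_.") else "_" for c in p))
    return "__".join(keep)


def write_catalog(
    catalog: DomainCatalog, out_dir: str | Path, format: str = "nifti"
) -> Path:
    """Write one volume file per domain plus a JSON manifest; return its path."""
    if format not in ("nifti", "tiff"):
        raise ValidationError(f"format must be 'nifti' or 'tiff', got {format!r}")
    ext = ".nii.gz" if format == "nifti" else ".tif"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vsize = catalog.grid.voxel_size_um

    doc: dict = {
        "axis_order": AXIS_ORDER,
        "shape": list(catalog.grid.shape),
        "voxel_size_um": list(vsize),
        "origin_um": list(catalog.grid.origin_um),
        "domains": [],
    }
    for dom in catalog.domains:
        fname = _safe_name(dom.family, dom.stage, dom.label) + ext
        write_volume(dom.mask, out_dir / fname, vsize)
        doc["domains"].append(
            {"label": dom.label, "family": dom.family, "stage": dom.stage, "file": fname}
        )
    if catalog.embryo_mask is not None:
        fname = _safe_name("embryo", catalog.embryo_mask.label) + ext
        write_volume(catalog.embryo_mask.mask, out_dir / fname, vsize)
        doc["embryo_mask"] = {"label": catalog.embryo_mask.label, "file": fname}
    if catalog.anatomy is not None:
        fname = "anatomy" + ext
        write_volume(catalog.anatomy.volume.astype(np.int16), out_dir / fname, vsize)
        doc["anatomy"] = {
            "file": fname,
            "names": {str(k): v for k, v in catalog.anatomy.names.items()},
        }

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path


# ---------------------------------------------------------------------------
# tables


def export_table(table: "PairwiseTable", path: str | Path) -> None:
    """Write a pairwise table as CSV.

    Leading ``#`` comment lines record the normalisation mode and the
    per-label total volumes (voxels), so absolute volumes can be
    recovered from any normalised table.  Values are written at full
    float precision (round-trip exact).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# mode: {table.mode}\n")
        vols = ",".join(f"{lab}={int(v)}" for lab, v in zip(table.labels, table.volumes))
        fh.write(f"# volumes_voxels: {vols}\n")
        writer = csv.writer(fh)
        writer.writerow(["label", *table.labels])
        for lab, row in zip(table.labels, table.values):
            writer.writerow([lab, *(repr(float(v)) for v in row)])


def read_table(path: str | Path) -> "PairwiseTable":
    """Read back a CSV written by :func:`export_table`."""
    from .volumetrics import PairwiseTable

    path = Path(path)
    mode = None
    volumes: dict[str, int] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# mode:"):
                mode = line.split(":", 1)[1].strip()
            elif line.startswith("# volumes_voxels:"):
                body = line.split(":", 1)[1].strip()
                if body:
                    for item in body.split(","):
                        k, v = item.split("=")
                        volumes[k] = int(v)
            elif not line.startswith("#"):
                data_lines.append(line)
    if mode is None:
        raise ValidationError(f"{path}: missing '# mode:' header")
    reader = csv.reader(data_lines)
    header = next(reader)
    labels = header[1:]
    values = []
    for row in reader:
        if not row:
            continue
        values.append([float(v) for v in row[1:]])
    return PairwiseTable(
        labels=labels,
        values=np.array(values, dtype=float),
        mode=mode,
        volumes=np.array([volumes.get(lab, 0) for lab in labels], dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# networks


def write_network(network, path: str | Path) -> None:
    """Export a similarity network as GraphML (node attrs: family, stage,
    volume_voxels; edge attr: ji)."""
    import networkx as nx

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(network.graph, str(path))
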