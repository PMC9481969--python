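"""Occupancy maps, regions of high occupancy (ROHOs) and derived territories.

The *occupancy* of a voxel is the number of gene-family members whose
mapped domain includes it: the per-voxel sum of the family's binary
masks.  Thresholding the occupancy volume at a family/stage-specific
level t and taking connected components yields the regions of high
occupancy.  The defaults ship the published thresholds — Wnt 5+ at E9.5
and E11.5, 4+ at E10.5, Fzd 4+ at all stages, occupancy peaks at Wnt ≥ 7
and Fzd ≥ 6 — all configurable.

A region's *gene set* is every gene whose domain intersects at least one
voxel of the region (the intersect-any-voxel rule).  Unique-gene
territories are the occupancy = 1 voxels attributed to the single gene
expressed there; the zero-expression territory is the embryo-mask voxels
with occupancy 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .domains import BinaryDomain, DomainCatalog, VoxelGrid
from .errors import (
    EmptySelectionError,
    GridCompatibilityError,
    ParameterError,
    ThresholdError,
)

#: Published ROHO occupancy thresholds per family and stage.
DEFAULT_ROHO_THRESHOLDS: dict[str, dict[str, int]] = {
    "Wnt": {"E9.5": 5, "E10.5": 4, "E11.5": 5},
    "Fzd": {"E9.5": 4, "E10.5": 4, "E11.5": 4},
}

#: Published occupancy-peak thresholds per family.
DEFAULT_PEAK_THRESHOLDS: dict[str, int] = {"Wnt": 7, "Fzd": 6}

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class OccupancyMap:
    """Integer volume counting co-expressed family members per voxel."""

    grid: VoxelGrid
    counts: np.ndarray
    family: str | None
    stage: str | None
    n_genes: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != self.grid.shape:
            raise GridCompatibilityError(
                f"occupancy counts shape {counts.shape} != grid shape {self.grid.shape}"
            )
        self.counts = counts.astype(np.int32)

    @property
    def max_occupancy(self) -> int:
        return int(self.counts.max(initial=0))


@dataclass
class LabelledRegions:
    """Connected components of an occupancy threshold set.

    ``labels`` assigns 1..n_regions in decreasing voxel-count order (ties
    broken by lexicographic bounding-box origin); 0 is background.
    """

    occupancy: OccupancyMap
    threshold: int
    connectivity: int
    min_voxels: int
    labels: np.ndarray
    n_regions: int

    @property
    def grid(self) -> VoxelGrid:
        return self.occupancy.grid

    def region_mask(self, region_id: int) -> np.ndarray:
        if not 1 <= region_id <= self.n_regions:
            raise ParameterError(f"region id {region_id} out of range 1..{self.n_regions}")
        return self.labels == region_id


@dataclass
class ROHORecord:
    """One labelled high-occupancy component with its gene set and peaks."""

    id: int
    family: str | None
    stage: str | None
    threshold: int
    voxel_count: int
    volume_um3: float
    bounding_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    centroid: tuple[float, float, float]
    peak_occupancy: int
    gene_set: set[str] = field(default_factory=set)
    gene_overlap_voxels: dict[str, int] = field(default_factory=dict)


def occupancy_map(
    catalog: DomainCatalog,
    family: str | None = None,
    stage: str | None = None,
) -> OccupancyMap:
    """Per-voxel count of expressed family members (sum of binary masks)."""
    domains = catalog.select(family=family, stage=stage)
    if not domains:
        raise EmptySelectionError(f"no domains match family={family!r}, stage={stage!r}")
    counts = np.zeros(catalog.grid.shape, dtype=np.int32)
    for dom in domains:
        catalog.grid.require_compatible(dom.grid)
        counts += dom.mask
    return OccupancyMap(
        grid=catalog.grid, counts=counts, family=family, stage=stage, n_genes=len(domains)
    )


def threshold_regions(
    occ: OccupancyMap,
    t: int,
    connectivity: int = 26,
    min_voxels: int = 5,
) -> LabelledRegions:
    """Connected components of {v : occupancy(v) >= t}.

    Components smaller than ``min_voxels`` are discarded (single-voxel
    noise suppression; the subtraction-based territories are sensitive to
    per-gene binarization noise).  Labels are renumbered 1..n in
    decreasing size, ties broken by bounding-box origin.
    """
    if t < 1:
        raise ThresholdError(f"threshold must be >= 1, got {t}")
    if t > occ.n_genes:
        raise ThresholdError(
            f"threshold {t} exceeds the number of summed domains ({occ.n_genes})"
        )
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ParameterError(f"connectivity must be one of 6, 18, 26, got {connectivity}")
    if min_voxels < 1:
        raise ParameterError(f"min_voxels must be >= 1, got {min_voxels}")

    above = occ.counts >= t
    raw_labels, n_raw = ndimage.label(above, structure=_CONNECTIVITY_STRUCTS[connectivity])
    labels = np.zeros_like(raw_labels)
    order: list[tuple[int, tuple, int]] = []
    if n_raw:
        sizes = np.bincount(raw_labels.ravel())  # sizes[0] is background
        slices = ndimage.find_objects(raw_labels)
        for rid in range(1, n_raw + 1):
            if sizes[rid] < min_voxels:
                continue
            sl = slices[rid - 1]
            origin = tuple(s.start for s in sl)
            order.append((int(sizes[rid]), origin, rid))
        order.sort(key=lambda item: (-item[0], item[1]))
        for new_id, (_, _, rid) in enumerate(order, start=1):
            labels[raw_labels == rid] = new_id
    return LabelledRegions(
        occupancy=occ,
        threshold=t,
        connectivity=connectivity,
        min_voxels=min_voxels,
        labels=labels,
        n_regions=len(order),
    )


def roho_gene_sets(
    regions: LabelledRegions,
    catalog: DomainCatalog,
    family: str | None = "__occ__",
    stage: str | None = "__occ__",
) -> list[ROHORecord]:
    """One record per region with gene set, overlap counts and peak occupancy.

    A gene joins the region's gene set iff its domain intersects *any*
    voxel of the region.  By default genes are drawn from the same
    family/stage filter the occupancy map was built with; pass explicit
    filters (including None for "all") to widen the query.
    """
    catalog.grid.require_compatible(regions.grid)
    if family == "__occ__":
        family = regions.occupancy.family
    if stage == "__occ__":
        stage = regions.occupancy.stage
    domains = catalog.select(family=family, stage=stage)
    counts = regions.occupancy.counts
    vox_um3 = regions.grid.voxel_volume_um3

    records: list[ROHORecord] = []
    slices = ndimage.find_objects(regions.labels)
    for rid in range(1, regions.n_regions + 1):
        sl = slices[rid - 1]
        local = regions.labels[sl] == rid
        voxel_count = int(local.sum())
        bbox = tuple((int(s.start), int(s.stop)) for s in sl)
        offs = np.array([s.start for s in sl], dtype=float)
        centroid = tuple(float(c) for c in (np.array(ndimage.center_of_mass(local)) + offs))
        peak = int(counts[sl][local].max())
        overlaps: dict[str, int] = {}
        for dom in domains:
            overlaps[dom.label] = int(np.logical_and(dom.mask[sl], local).sum())
        records.append(
            ROHORecord(
                id=rid,
                family=family,
                stage=stage,
                threshold=regions.threshold,
                voxel_count=voxel_count,
                volume_um3=voxel_count * vox_um3,
                bounding_box=bbox,
                centroid=centroid,
                peak_occupancy=peak,
                gene_set={g for g, n in overlaps.items() if n >= 1},
                gene_overlap_voxels=overlaps,
            )
        )
    return records


def roho_table(records: list[ROHORecord]) -> pd.DataFrame:
    """Flatten ROHO records into a per-region table (one row per region)."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "family": r.family,
                "stage": r.stage,
                "threshold": r.threshold,
                "voxels": r.voxel_count,
                "volume_um3": r.volume_um3,
                "centroid_plane": r.centroid[0],
                "centroid_row": r.centroid[1],
                "centroid_col": r.centroid[2],
                "peak_occupancy": r.peak_occupancy,
                "n_genes": len(r.gene_set),
                "gene_set": ";".join(sorted(r.gene_set)),
            }
        )
    return pd.DataFrame(rows)


def occupancy_peaks(occ: OccupancyMap, peak_t: int) -> BinaryDomain:
    """Mask of voxels at or above the peak threshold (e.g. Wnt ≥ 7, Fzd ≥ 6)."""
    if peak_t < 1:
        raise ParameterError(f"peak threshold must be >= 1, got {peak_t}")
    return BinaryDomain(
        grid=occ.grid,
        mask=occ.counts >= peak_t,
        label=f"peaks_ge{peak_t}",
        family=occ.family or "other",
        stage=occ.stage or "",
    )


def unique_gene_domains(
    catalog: DomainCatalog,
    family: str | None = None,
    stage: str | None = None,
) -> tuple[dict[str, BinaryDomain], pd.DataFrame]:
    """Per-gene single-occupancy territories and their contribution table.

    unique_g = domain_g ∩ {occupancy = 1}.  The table reports, per gene,
    the unique voxel count, its fraction of the combined single-gene
    territory, and its fraction of the gene's own domain — the two
    percentages used to quantify how much one gene dominates the unique
    territory.
    """
    domains = catalog.select(family=family, stage=stage)
    if len(domains) < 2:
        raise EmptySelectionError(
            f"unique-gene analysis needs >= 2 domains (family={family!r}, stage={stage!r})"
        )
    occ = occupancy_map(catalog, family=family, stage=stage)
    single = occ.counts == 1
    total_single = int(single.sum())

    uniques: dict[str, BinaryDomain] = {}
    rows = []
    for dom in domains:
        umask = np.logical_and(dom.mask, single)
        uvox = int(umask.sum())
        uniques[dom.label] = dom.with_mask(umask, label=f"{dom.label}_unique")
        rows.append(
            {
                "label": dom.label,
                "unique_voxels": uvox,
                "unique_um3": uvox * catalog.grid.voxel_volume_um3,
                "frac_of_single_gene_domain": (uvox / total_single) if total_single else 0.0,
                "frac_of_gene_domain": (uvox / dom.volume_voxels) if dom.volume_voxels else 0.0,
            }
        )
    return uniques, pd.DataFrame(rows).set_index("label")


def zero_expression_domain(
    catalog: DomainCatalog,
    family: str | None = None,
    stage: str | None = None,
) -> BinaryDomain:
    """Embryo-mask voxels where no family member is detected (occupancy 0)."""
    if catalog.embryo_mask is None:
        raise ParameterError("zero-expression territory requires an embryo mask")
    occ = occupancy_map(catalog, family=family, stage=stage)
    mask = np.logical_and(catalog.embryo_mask.mask, occ.counts == 0)
    return BinaryDomain(
        grid=catalog.grid,
        mask=mask,
        label=f"zero_{family or 'all'}",
        family=family or "other",
        stage=stage or "",
    )


def combine(domains: list[BinaryDomain], op: str = "union") -> BinaryDomain:
    """Voxelwise set algebra over domains: union, intersection or subtract.

    ``subtract`` treats the first domain as minuend and removes the union
    of the rest.
    """
    if not domains:
        raise ParameterError("combine needs at least one domain")
    if op not in ("union", "intersection", "subtract"):
        raise ParameterError(f"op must be union/intersection/subtract, got {op!r}")
    grid = domains[0].grid
    for dom in domains[1:]:
        grid.require_compatible(dom.grid)
    if op == "union":
        mask = np.zeros(grid.shape, dtype=bool)
        for dom in domains:
            mask |= dom.mask
    elif op == "intersection":
        mask = np.ones(grid.shape, dtype=bool)
        for dom in domains:
            mask &= dom.mask
    else:
        mask = domains[0].mask.copy()
        for dom in domains[1:]:
            mask &= ~dom.mask
    label = f"{op}({','.join(d.label for d in domains)})"
    return BinaryDomain(
        grid=grid, mask=mask, label=label,
        family=domains[0].family, stage=domains[0].stage,
    )
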