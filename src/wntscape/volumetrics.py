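"""Volumes, intersections, Jaccard similarity and normalised pairwise tables.

The pairwise pattern-similarity statistic throughout is the Jaccard
index, JI(A, B) = |A ∩ B| / |A ∪ B| over voxel sets.  Intersection
tables count voxels in common and can be normalised by the test-pattern
volume (row normalised, entry(i, j) = |i ∩ j| / |i|) or the target
pattern volume (column normalised, the transpose convention).  Voxel
counts convert to real-space µm³ via the grid's voxel volume.

All statistics are computed over the full grid: mapped domains lie
inside the embryo by construction.  Pass ``restrict_to_embryo=True`` to
first intersect every mask with the embryo foreground; a change in any
count is logged, which flags stray voxels outside the mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domains import BinaryDomain, DomainCatalog
from .errors import (
    EmptySelectionError,
    ParameterError,
    UndefinedStatisticError,
)

logger = logging.getLogger(__name__)

TABLE_MODES = ("intersection_voxels", "row_normalised", "column_normalised", "jaccard")


@dataclass
class PairwiseTable:
    """A square gene x gene table of intersection or similarity values.

    ``volumes`` carries per-label voxel counts so normalised tables can be
    converted back to absolute values.
    """

    labels: list[str]
    values: np.ndarray
    mode: str
    volumes: np.ndarray
    family: str | None = None
    stage: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in TABLE_MODES:
            raise ParameterError(f"unknown table mode {self.mode!r}; use one of {TABLE_MODES}")
        self.values = np.asarray(self.values, dtype=float)
        self.volumes = np.asarray(self.volumes)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ParameterError(
                f"table values must be {n}x{n} for {n} labels, got {self.values.shape}"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def volume(domain: BinaryDomain) -> tuple[int, float]:
    """Domain volume as (voxel count, real-space µm³)."""
    voxels = domain.volume_voxels
    return voxels, voxels * domain.grid.voxel_volume_um3


def intersection_voxels(a: BinaryDomain, b: BinaryDomain) -> int:
    """Number of voxels in common between two domains."""
    a.grid.require_compatible(b.grid)
    return int(np.logical_and(a.mask, b.mask).sum())


def jaccard(a: BinaryDomain, b: BinaryDomain) -> float:
    """JI = |A ∩ B| / |A ∪ B|; two empty domains give 0 (logged)."""
    a.grid.require_compatible(b.grid)
    inter = int(np.logical_and(a.mask, b.mask).sum())
    union = int(a.mask.sum()) + int(b.mask.sum()) - inter
    if union == 0:
        logger.info("jaccard of two empty domains (%s, %s) defined as 0", a.label, b.label)
        return 0.0
    return inter / union


def _select_masks(
    catalog: DomainCatalog,
    family: str | None,
    stage: str | None,
    restrict_to_embryo: bool,
) -> list[BinaryDomain]:
    domains = catalog.select(family=family, stage=stage)
    if not domains:
        raise EmptySelectionError(f"no domains match family={family!r}, stage={stage!r}")
    if restrict_to_embryo:
        if catalog.embryo_mask is None:
            raise ParameterError("restrict_to_embryo requires an embryo mask")
        emb = catalog.embryo_mask.mask
        clipped = []
        for d in domains:
            new = np.logical_and(d.mask, emb)
            if int(new.sum()) != d.volume_voxels:
                logger.warning(
                    "domain %s has %d voxels outside the embryo mask (clipped)",
                    d.label,
                    d.volume_voxels - int(new.sum()),
                )
            clipped.append(d.with_mask(new))
        domains = clipped
    return domains


def pairwise_table(
    catalog: DomainCatalog,
    family: str | None = None,
    stage: str | None = None,
    mode: str = "jaccard",
    restrict_to_embryo: bool = False,
) -> PairwiseTable:
    """Square pairwise table over the filtered domains, in the given mode.

    Zero-volume rows/denominators yield 0 entries (kept finite, logged by
    :func:`jaccard`'s convention).
    """
    if mode not in TABLE_MODES:
        raise ParameterError(f"unknown table mode {mode!r}; use one of {TABLE_MODES}")
    domains = _select_masks(catalog, family, stage, restrict_to_embryo)
    labels = [d.label for d in domains]
    flat = np.stack([d.mask.ravel() for d in domains]).astype(np.int64)
    inter = flat @ flat.T  # inter[i, i] == |domain_i|
    vols = np.diag(inter).copy()

    if mode == "intersection_voxels":
        values = inter.astype(float)
    elif mode == "row_normalised":
        denom = np.where(vols > 0, vols, 1)[:, None]
        values = np.where(vols[:, None] > 0, inter / denom, 0.0)
    elif mode == "column_normalised":
        denom = np.where(vols > 0, vols, 1)[None, :]
        values = np.where(vols[None, :] > 0, inter / denom, 0.0)
    else:  # jaccard
        union = vols[:, None] + vols[None, :] - inter
        values = np.where(union > 0, inter / np.where(union > 0, union, 1), 0.0)

    return PairwiseTable(
        labels=labels, values=values, mode=mode, volumes=vols, family=family, stage=stage
    )


def anatomy_proportions(
    catalog: DomainCatalog,
    family: str | None = None,
    stage: str | None = None,
) -> pd.DataFrame:
    """Fraction of each anatomical structure occupied by each expression domain.

    Rows are gene labels; columns are structure names plus a
    ``whole_embryo`` column computed against the embryo mask.  A
    zero-voxel structure yields fraction 0 with a logged warning.
    """
    if catalog.anatomy is None:
        raise ParameterError("catalogue has no anatomy label volume")
    domains = catalog.select(family=family, stage=stage)
    if not domains:
        raise EmptySelectionError(f"no domains match family={family!r}, stage={stage!r}")

    structures: list[tuple[str, np.ndarray]] = []
    if catalog.embryo_mask is not None:
        structures.append(("whole_embryo", catalog.embryo_mask.mask))
    for value in catalog.anatomy.present_labels():
        structures.append((catalog.anatomy.names[value], catalog.anatomy.volume == value))

    rows = {}
    for dom in domains:
        fractions = []
        for name, struct in structures:
            denom = int(struct.sum())
            if denom == 0:
                logger.warning("structure %s has zero voxels; fraction reported as 0", name)
                fractions.append(0.0)
            else:
                fractions.append(int(np.logical_and(dom.mask, struct).sum()) / denom)
        rows[dom.label] = fractions
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[name for name, _ in structures]
    )


def coverage_outside(a: BinaryDomain, others: list[BinaryDomain]) -> float:
    """Fraction of ``a`` lying outside the union of ``others``.

    The statistic behind claims like "half of one gene's domain lies
    outside any receptor domain".  Undefined (error) for empty ``a``.
    """
    if a.volume_voxels == 0:
        raise UndefinedStatisticError(f"coverage_outside undefined for empty domain {a.label!r}")
    covered = np.zeros(a.grid.shape, dtype=bool)
    for other in others:
        a.grid.require_compatible(other.grid)
        covered |= other.mask
    outside = np.logical_and(a.mask, ~covered)
    return int(outside.sum()) / a.volume_voxels
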