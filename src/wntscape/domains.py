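"""Core spatial types: voxel grids, binary expression domains, catalogues.

All volumes in a catalogue live on one shared :class:`VoxelGrid`.  Arrays
are indexed ``(plane, row, column)`` with index origin 0; this axis
convention is recorded in written manifests so external viewers can
reorient.  A :class:`BinaryDomain` is one gene's (or reporter's) mapped
expression territory as a boolean volume; a :class:`DomainCatalog` is the
per-stage integrated dataset: every domain co-registered to one grid,
plus the embryo foreground mask and an optional anatomy label volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridCompatibilityError, ValidationError

#: Canonical family tags.  ``family`` is a free string, but these are the
#: values the analysis modules and the phantom generator use.
FAMILIES = ("Wnt", "Fzd", "TcfLef", "Sfrp", "other", "reporter")

#: Canonical embryonic-day stage tags (Theiler stages 15, 17, 19).
STAGES = ("E9.5", "E10.5", "E11.5")


@dataclass(frozen=True)
class VoxelGrid:
    """Shared discrete geometry all masks of a catalogue must agree on.

    Parameters
    ----------
    shape
        Volume shape as ``(planes, rows, columns)``; every entry >= 1.
    voxel_size_um
        Physical voxel edge lengths in micrometres per axis; all > 0.
        Anisotropic voxels are supported.
    origin_um
        Real-space position of voxel (0, 0, 0), in micrometres.
    """

    shape: tuple[int, int, int]
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vsize = tuple(float(v) for v in self.voxel_size_um)
        origin = tuple(float(o) for o in self.origin_um)
        if len(shape) != 3 or len(vsize) != 3 or len(origin) != 3:
            raise ValidationError("grid shape, voxel size and origin must be triples")
        if any(s < 1 for s in shape):
            raise ValidationError(f"every grid axis must have >= 1 voxel, got {shape}")
        if any(v <= 0 for v in vsize):
            raise ValidationError(f"voxel sizes must be positive, got {vsize}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size_um", vsize)
        object.__setattr__(self, "origin_um", origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_um3(self) -> float:
        """Real-space volume of one voxel in cubic micrometres."""
        return float(np.prod(self.voxel_size_um))

    def compatible(self, other: "VoxelGrid") -> bool:
        """Two grids are compatible iff shape and voxel size match elementwise."""
        return self.shape == other.shape and self.voxel_size_um == other.voxel_size_um

    def require_compatible(self, other: "VoxelGrid") -> None:
        if not self.compatible(other):
            raise GridCompatibilityError(
                f"incompatible grids: shape {self.shape} / voxel {self.voxel_size_um} "
                f"vs shape {other.shape} / voxel {other.voxel_size_um}"
            )


@dataclass
class BinaryDomain:
    """One mapped expression pattern: a boolean volume plus metadata.

    A zero-volume domain is legal (a gene may not be detected at a stage).
    """

    grid: VoxelGrid
    mask: np.ndarray
    label: str
    family: str = "other"
    stage: str = ""

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.dtype != np.bool_:
            mask = mask > 0
        if mask.shape != self.grid.shape:
            raise GridCompatibilityError(
                f"mask shape {mask.shape} does not match grid shape {self.grid.shape} "
                f"for domain {self.label!r}"
            )
        self.mask = mask

    @property
    def volume_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_um3(self) -> float:
        return self.volume_voxels * self.grid.voxel_volume_um3

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.family, self.stage, self.label)

    def with_mask(self, mask: np.ndarray, label: str | None = None) -> "BinaryDomain":
        """New domain on the same grid with a replaced mask (and optional label)."""
        return BinaryDomain(
            grid=self.grid,
            mask=mask,
            label=self.label if label is None else label,
            family=self.family,
            stage=self.stage,
        )


@dataclass
class AnatomyLabels:
    """Anatomy label volume: non-negative integer labels plus a name table.

    Label 0 is background and needs no name; every non-zero label present
    in the volume must have a name-table entry.
    """

    volume: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vol = np.asarray(self.volume)
        if not np.issubdtype(vol.dtype, np.integer):
            if not np.allclose(vol, np.round(vol)):
                raise ValidationError("anatomy volume must contain integer labels")
            vol = np.round(vol).astype(np.int32)
        if vol.min() < 0:
            raise ValidationError("anatomy labels must be non-negative")
        self.volume = vol
        self.names = {int(k): str(v) for k, v in self.names.items()}

    def present_labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.volume) if v != 0]

    def validate_names(self) -> None:
        missing = [v for v in self.present_labels() if v not in self.names]
        if missing:
            raise ValidationError(f"anatomy labels without a name-table entry: {missing}")


@dataclass
class DomainCatalog:
    """The per-stage integrated dataset: all domains on one reference grid."""

    grid: VoxelGrid
    domains: list[BinaryDomain]
    embryo_mask: BinaryDomain | None = None
    anatomy: AnatomyLabels | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for dom in self.domains:
            self.grid.require_compatible(dom.grid)
            if dom.key in seen:
                raise ValidationError(
                    f"duplicate domain (family={dom.family!r}, stage={dom.stage!r}, "
                    f"label={dom.label!r})"
                )
            seen.add(dom.key)
        if self.embryo_mask is not None:
            self.grid.require_compatible(self.embryo_mask.grid)
        if self.anatomy is not None:
            if self.anatomy.volume.shape != self.grid.shape:
                raise GridCompatibilityError(
                    f"anatomy volume shape {self.anatomy.volume.shape} does not match "
                    f"grid shape {self.grid.shape}"
                )
            self.anatomy.validate_names()

    def select(self, family: str | None = None, stage: str | None = None) -> list[BinaryDomain]:
        """Domains matching the family/stage filters (None matches anything)."""
        return [
            d
            for d in self.domains
            if (family is None or d.family == family) and (stage is None or d.stage == stage)
        ]

    def get(self, label: str, family: str | None = None, stage: str | None = None) -> BinaryDomain:
        hits = [d for d in self.select(family, stage) if d.label == label]
        if not hits:
            raise KeyError(f"no domain labelled {label!r} (family={family}, stage={stage})")
        if len(hits) > 1:
            raise KeyError(f"label {label!r} is ambiguous without family/stage filters")
        return hits[0]

    @property
    def families(self) -> list[str]:
        out: list[str] = []
        for d in self.domains:
            if d.family not in out:
                out.append(d.family)
        return out

    @property
    def stages(self) -> list[str]:
        out: list[str] = []
        for d in self.domains:
            if d.stage not in out:
                out.append(d.stage)
        return out
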