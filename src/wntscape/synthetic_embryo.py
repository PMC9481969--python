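"""Synthetic embryo phantoms with planted, recoverable structure.

The generator emulates the statistical structure of a mapped gene-family
catalogue: an ellipsoidal embryo foreground, K localised multi-gene
hotspots (spheres shared by several family members, so the hotspot is a
planted region of high occupancy), per-gene private spheres, optional
per-voxel speckle noise, paralogue pairs built to hit an exact Jaccard
index, and a reporter domain derived from hotspot territories.  Every
planted feature is recorded in :class:`PhantomTruth` so recovery tests
can compare detected against planted structure.

Spheres are Euclidean balls in voxel units (anisotropy is ignored during
generation).  Under ``strict_recovery`` geometry — hotspot separation
greater than twice the sum of hotspot and private radii, and private
spheres kept clear of hotspots and of each other — the planted hotspots
are guaranteed to appear as disjoint connected components of the
thresholded occupancy map, with exactly the planted gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .domains import BinaryDomain, DomainCatalog, VoxelGrid
from .errors import ConfigurationError, ParameterError, PlacementError, ValidationError

_RETRY_BUDGET = 1000


@dataclass
class PhantomConfig:
    """Parameters of one synthetic catalogue.

    Defaults mirror the real catalogue's composition: 19 Wnt-like and 10
    Fzd-like genes on one grid, five hotspots each shared by five genes
    of a family, two private spheres per gene, no speckle.
    """

    grid: VoxelGrid = field(default_factory=lambda: VoxelGrid(shape=(40, 56, 40)))
    n_genes_per_family: dict[str, int] = field(
        default_factory=lambda: {"Wnt": 19, "Fzd": 10}
    )
    n_hotspots: int = 5
    hotspot_radius_vox: float = 3.0
    min_hotspot_separation_vox: float = 14.0
    genes_per_hotspot: int = 5
    n_private_blobs: int = 2
    private_radius_vox: float = 2.0
    speckle_rate: float = 0.0
    stage: str = "E10.5"
    seed: int = 0
    strict_recovery: bool = False

    def validate(self) -> None:
        if self.n_hotspots < 0:
            raise ValidationError("n_hotspots must be >= 0")
        if self.hotspot_radius_vox <= 0 or self.private_radius_vox <= 0:
            raise ValidationError("sphere radii must be positive")
        if not 0 <= self.speckle_rate < 1:
            raise ValidationError("speckle_rate must be in [0, 1)")
        if self.genes_per_hotspot < 1:
            raise ValidationError("genes_per_hotspot must be >= 1")
        if self.n_private_blobs < 0:
            raise ValidationError("n_private_blobs must be >= 0")
        if any(n < 0 for n in self.n_genes_per_family.values()):
            raise ValidationError("gene counts must be non-negative")
        if self.strict_recovery:
            bound = 2 * (self.hotspot_radius_vox + self.private_radius_vox)
            if self.min_hotspot_separation_vox <= bound:
                raise ValidationError(
                    "strict_recovery requires min_hotspot_separation_vox > "
                    f"2*(hotspot_radius + private_radius) = {bound}, "
                    f"got {self.min_hotspot_separation_vox}"
                )


@dataclass
class PhantomTruth:
    """Everything the generator planted, for recovery tests."""

    hotspot_centers: list[tuple[int, int, int]]
    hotspot_radius_vox: float
    #: family -> one gene-label set per hotspot
    hotspot_gene_sets: dict[str, list[set[str]]]
    #: label -> voxels planted (sum of per-sphere counts, each clipped to
    #: the embryo mask; equals the measured mask volume when spheres are
    #: disjoint)
    planted_volumes: dict[str, int]
    paralogue_targets: dict[tuple[str, str], float] = field(default_factory=dict)


def _ball_mask(
    shape: tuple[int, int, int], center: tuple[float, float, float], radius: float
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Local bounding slices + boolean ball within them."""
    lo = [max(0, int(np.floor(c - radius))) for c in center]
    hi = [min(s, int(np.ceil(c + radius)) + 1) for s, c in zip(shape, center)]
    slices = tuple(slice(a, b) for a, b in zip(lo, hi))
    axes = np.ogrid[slices]
    dist2 = sum((ax - c) ** 2 for ax, c in zip(axes, center))
    return slices, dist2 <= radius**2


def _stamp_ball(
    out: np.ndarray,
    center: tuple[float, float, float],
    radius: float,
    clip: np.ndarray,
) -> int:
    """OR a mask-clipped ball into ``out``; return the ball's own clipped count."""
    slices, ball = _ball_mask(out.shape, center, radius)
    ball = np.logical_and(ball, clip[slices])
    out[slices] |= ball
    return int(ball.sum())


def make_embryo_mask(grid: VoxelGrid, seed: int) -> BinaryDomain:
    """A single connected filled ellipsoid occupying 20-60% of the grid.

    Semi-axes are drawn as 85-95% of each half-extent and the centre is
    jittered by up to 2% of the extent, keeping the continuous volume
    fraction within roughly 0.32-0.45 so the discrete fraction stays
    inside the contract on any legal grid.
    """
    if any(s < 4 for s in grid.shape):
        raise ConfigurationError(
            f"grid {grid.shape} too small for an embryo ellipsoid (need >= 4 voxels per axis)"
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    shape = np.array(grid.shape, dtype=float)
    center = (shape - 1) / 2 + rng.uniform(-0.02, 0.02, size=3) * shape
    semi = rng.uniform(0.85, 0.95, size=3) * shape / 2
    axes = np.ogrid[tuple(slice(0, s) for s in grid.shape)]
    inside = sum(((ax - c) / a) ** 2 for ax, c, a in zip(axes, center, semi)) <= 1.0
    return BinaryDomain(grid=grid, mask=inside, label="embryo", family="other", stage="")


def _place_separated(
    rng: np.random.Generator,
    candidates: np.ndarray,
    n: int,
    min_separation: float,
    existing: list[np.ndarray],
    what: str,
) -> list[np.ndarray]:
    """Rejection-sample n points from candidate voxels at the given pairwise
    separation from ``existing`` and from each other."""
    placed: list[np.ndarray] = []
    for i in range(n):
        for _ in range(_RETRY_BUDGET):
            pt = candidates[rng.integers(len(candidates))].astype(float)
            others = existing + placed
            if all(np.linalg.norm(pt - o) >= min_separation for o in others):
                placed.append(pt)
                break
        else:
            raise PlacementError(
                f"could not place {what} {i + 1}/{n} at separation "
                f"{min_separation} after {_RETRY_BUDGET} tries ({i} placed)"
            )
    return placed


def generate_catalog(config: PhantomConfig) -> tuple[DomainCatalog, PhantomTruth]:
    """Generate a phantom catalogue plus its ground truth.

    Each gene's domain is the union of the spheres at its assigned
    hotspots, its private spheres, and optional speckle voxels, all
    clipped to the embryo mask.  Hotspot centres are shared across
    families; each family with at least ``genes_per_hotspot`` members
    contributes that many genes to every hotspot (smaller families
    contribute all their members), so family-filtered occupancy analysis
    sees the planted plateaus.  Deterministic given the seed: one seed
    sequence per catalogue, per-gene child streams derived in label order.
    """
    config.validate()
    grid = config.grid
    embryo = make_embryo_mask(grid, config.seed)
    emb = embryo.mask
    candidates = np.argwhere(emb)

    root = np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    master = np.random.default_rng(root)

    centers = _place_separated(
        master, candidates, config.n_hotspots,
        config.min_hotspot_separation_vox, [], "hotspot",
    )

    labels_by_family: dict[str, list[str]] = {
        fam: [f"{fam}{i + 1}" for i in range(n)]
        for fam, n in config.n_genes_per_family.items()
    }

    # per-family hotspot gene sets, drawn from the master stream
    hotspot_sets: dict[str, list[set[str]]] = {}
    for fam, labels in labels_by_family.items():
        k = min(config.genes_per_hotspot, len(labels))
        sets = []
        for _ in centers:
            chosen = master.choice(len(labels), size=k, replace=False) if k else []
            sets.append({labels[i] for i in sorted(chosen)})
        hotspot_sets[fam] = sets

    all_labels = [lab for labels in labels_by_family.values() for lab in labels]
    child_seeds = dict(zip(all_labels, root.spawn(len(all_labels))))

    # strict geometry: privates stay clear of hotspots and of each other
    private_clearance = config.hotspot_radius_vox + config.private_radius_vox + 1.0
    placed_privates: list[np.ndarray] = []

    domains: list[BinaryDomain] = []
    planted: dict[str, int] = {}
    for fam, labels in labels_by_family.items():
        for lab in labels:
            rng = np.random.default_rng(child_seeds[lab])
            mask = np.zeros(grid.shape, dtype=bool)
            vol = 0
            for center, geneset in zip(centers, hotspot_sets[fam]):
                if lab in geneset:
                    vol += _stamp_ball(mask, tuple(center), config.hotspot_radius_vox, emb)
            if config.n_private_blobs:
                if config.strict_recovery:
                    pair_sep = 2 * config.private_radius_vox + 1.0
                    pts = []
                    for i in range(config.n_private_blobs):
                        for _ in range(_RETRY_BUDGET):
                            pt = candidates[rng.integers(len(candidates))].astype(float)
                            clear_of_hotspots = all(
                                np.linalg.norm(pt - c) >= private_clearance for c in centers
                            )
                            clear_of_privates = all(
                                np.linalg.norm(pt - o) >= pair_sep
                                for o in placed_privates + pts
                            )
                            if clear_of_hotspots and clear_of_privates:
                                pts.append(pt)
                                break
                        else:
                            raise PlacementError(
                                f"could not place private sphere {i + 1} for {lab} "
                                f"after {_RETRY_BUDGET} tries"
                            )
                    placed_privates.extend(pts)
                else:
                    pts = [
                        candidates[rng.integers(len(candidates))].astype(float)
                        for _ in range(config.n_private_blobs)
                    ]
                for pt in pts:
                    vol += _stamp_ball(mask, tuple(pt), config.private_radius_vox, emb)
            if config.speckle_rate > 0:
                flips = rng.random(len(candidates)) < config.speckle_rate
                idx = candidates[flips]
                mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
            planted[lab] = vol
            domains.append(
                BinaryDomain(grid=grid, mask=mask, label=lab, family=fam, stage=config.stage)
            )

    catalog = DomainCatalog(grid=grid, domains=domains, embryo_mask=embryo)
    truth = PhantomTruth(
        hotspot_centers=[tuple(int(v) for v in c) for c in centers],
        hotspot_radius_vox=config.hotspot_radius_vox,
        hotspot_gene_sets=hotspot_sets,
        planted_volumes=planted,
    )
    return catalog, truth


def generate_paralogue_pair(
    core_vox: int,
    private_a_vox: int,
    private_b_vox: int,
    embryo_mask: BinaryDomain,
    seed: int = 0,
    label_a: str = "paralog_a",
    label_b: str = "paralog_b",
    family: str = "Wnt",
    stage: str = "",
) -> tuple[BinaryDomain, BinaryDomain]:
    """Two domains with an exact target Jaccard index.

    Core and private voxel sets are drawn without replacement from the
    embryo-mask voxels, so A = core ∪ private_a and B = core ∪ private_b
    with the three sets pairwise disjoint and
    JI(A, B) = core / (core + private_a + private_b) exactly.
    """
    if min(core_vox, private_a_vox, private_b_vox) < 0:
        raise ParameterError("voxel counts must be non-negative")
    total = core_vox + private_a_vox + private_b_vox
    flat = np.flatnonzero(embryo_mask.mask)
    if total > len(flat):
        raise PlacementError(
            f"embryo mask has {len(flat)} voxels; cannot place {total} disjoint voxels"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat, size=total, replace=False)
    core = chosen[:core_vox]
    priv_a = chosen[core_vox : core_vox + private_a_vox]
    priv_b = chosen[core_vox + private_a_vox :]

    grid = embryo_mask.grid
    mask_a = np.zeros(grid.n_voxels, dtype=bool)
    mask_b = np.zeros(grid.n_voxels, dtype=bool)
    mask_a[core] = True
    mask_a[priv_a] = True
    mask_b[core] = True
    mask_b[priv_b] = True
    a = BinaryDomain(grid, mask_a.reshape(grid.shape), label_a, family, stage)
    b = BinaryDomain(grid, mask_b.reshape(grid.shape), label_b, family, stage)
    return a, b


def generate_reporter(
    truth: PhantomTruth,
    subset: list[int],
    dilation_vox: int,
    embryo_mask: BinaryDomain,
    stage: str = "",
) -> BinaryDomain:
    """Reporter domain: union of the chosen hotspots' spheres, dilated,
    clipped to the embryo mask.

    Emulates a pathway read-out concentrated on co-expression hotspots.
    """
    if dilation_vox < 0:
        raise ParameterError("dilation must be >= 0")
    n = len(truth.hotspot_centers)
    for idx in subset:
        if not 0 <= idx < n:
            raise ParameterError(f"hotspot index {idx} out of range 0..{n - 1}")
    grid = embryo_mask.grid
    mask = np.zeros(grid.shape, dtype=bool)
    for idx in subset:
        _stamp_ball(mask, truth.hotspot_centers[idx], truth.hotspot_radius_vox,
                    np.ones(grid.shape, dtype=bool))
    if dilation_vox:
        mask = ndimage.binary_dilation(
            mask, structure=ndimage.generate_binary_structure(3, 1),
            iterations=dilation_vox,
        )
    mask &= embryo_mask.mask
    return BinaryDomain(grid, mask, label="TcfLef-GFP", family="reporter", stage=stage)
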