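import numpy as np
import pytest

from wntscape import AnatomyLabels, BinaryDomain, DomainCatalog, VoxelGrid


def random_catalog(
    seed: int,
    shape=(8, 8, 8),
    n_genes: int | None = None,
    family: str = "Wnt",
    stage: str = "E10.5",
    density: float = 0.3,
    with_embryo: bool = True,
    with_anatomy: bool = False,
    clip_to_embryo: bool = False,
) -> DomainCatalog:
    """A catalogue of random binary masks for oracle comparisons."""
    rng = np.random.default_rng(seed)
    if n_genes is None:
        n_genes = int(rng.integers(5, 11))
    grid = VoxelGrid(shape=shape)
    embryo = None
    embryo_mask = np.ones(shape, dtype=bool)
    if with_embryo:
        embryo_mask = rng.random(shape) < 0.7
        embryo_mask[tuple(s // 2 for s in shape)] = True  # never fully empty
        embryo = BinaryDomain(grid, embryo_mask, label="embryo")
    domains = []
    for i in range(n_genes):
        mask = rng.random(shape) < density
        if clip_to_embryo:
            mask &= embryo_mask
        domains.append(BinaryDomain(grid, mask, label=f"g{i + 1}", family=family, stage=stage))
    anatomy = None
    if with_anatomy:
        volume = rng.integers(0, 4, size=shape)
        anatomy = AnatomyLabels(
            volume=volume, names={v: f"structure_{v}" for v in (1, 2, 3)}
        )
    return DomainCatalog(grid=grid, domains=domains, embryo_mask=embryo, anatomy=anatomy)


@pytest.fixture
def small_grid() -> VoxelGrid:
    return VoxelGrid(shape=(8, 8, 8))


@pytest.fixture
def catalog8():
    return random_catalog(seed=42, n_genes=6)
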