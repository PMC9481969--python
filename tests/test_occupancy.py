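import numpy as np
import pytest

from wntscape import (
    BinaryDomain,
    DomainCatalog,
    VoxelGrid,
    combine,
    generate_catalog,
    occupancy_map,
    occupancy_peaks,
    roho_gene_sets,
    threshold_regions,
    unique_gene_domains,
    zero_expression_domain,
)
from wntscape.errors import (
    EmptySelectionError,
    GridCompatibilityError,
    ParameterError,
    ThresholdError,
)

import oracles
from conftest import random_catalog
from test_synthetic_embryo import small_strict_config

GRID8 = VoxelGrid(shape=(8, 8, 8))


def dom(mask, label, family="Wnt", stage="E10.5"):
    return BinaryDomain(GRID8, mask, label=label, family=family, stage=stage)


def catalog_of(masks, embryo=None):
    domains = [dom(m, f"g{i + 1}") for i, m in enumerate(masks)]
    emb = None
    if embryo is not None:
        emb = BinaryDomain(GRID8, embryo, label="embryo")
    return DomainCatalog(grid=GRID8, domains=domains, embryo_mask=emb)


class TestOccupancyMap:
    def test_shared_voxel_counts_all_genes(self):
        masks = [np.zeros((8, 8, 8), bool) for _ in range(3)]
        for m in masks:
            m[4, 4, 4] = True
        occ = occupancy_map(catalog_of(masks))
        assert occ.counts[4, 4, 4] == 3

    def test_all_empty_masks_give_zero_map(self):
        occ = occupancy_map(catalog_of([np.zeros((8, 8, 8), bool)] * 2))
        assert occ.max_occupancy == 0

    def test_empty_selection_raises(self, catalog8):
        with pytest.raises(EmptySelectionError):
            occupancy_map(catalog8, family="Sfrp")

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_per_voxel_loop_oracle(self, seed):
        cat = random_catalog(seed=seed, n_genes=6)
        occ = occupancy_map(cat)
        expected = oracles.o_occupancy([d.mask for d in cat.domains])
        assert np.array_equal(occ.counts, expected)

    def test_conservation_of_total_counts(self, catalog8):
        occ = occupancy_map(catalog8)
        assert occ.counts.sum() == sum(d.volume_voxels for d in catalog8.domains)


class TestThresholdRegions:
    def two_plateau_occupancy(self):
        masks = [np.zeros((8, 8, 8), bool) for _ in range(2)]
        for m in masks:
            m[1:3, 1:3, 1:3] = True  # plateau A: 8 voxels, occupancy 2
            m[5:8, 5:8, 5:8] = True  # plateau B: 27 voxels, occupancy 2
        return occupancy_map(catalog_of(masks))

    def test_separated_plateaus_become_two_regions(self):
        regions = threshold_regions(self.two_plateau_occupancy(), 2, min_voxels=1)
        assert regions.n_regions == 2

    def test_labels_ordered_by_decreasing_size(self):
        regions = threshold_regions(self.two_plateau_occupancy(), 2, min_voxels=1)
        sizes = [int((regions.labels == i).sum()) for i in (1, 2)]
        assert sizes == [27, 8]

    def test_threshold_above_max_occupancy_gives_no_regions(self):
        occ = self.two_plateau_occupancy()
        # t=2 is max occupancy here; n_genes is also 2 so t=2 is the ceiling
        assert threshold_regions(occ, 2, min_voxels=100).n_regions == 0

    def test_threshold_above_gene_count_rejected(self):
        with pytest.raises(ThresholdError):
            threshold_regions(self.two_plateau_occupancy(), 3)

    def test_min_voxels_filters_small_components(self):
        occ = self.two_plateau_occupancy()
        regions = threshold_regions(occ, 2, min_voxels=10)
        assert regions.n_regions == 1
        assert int((regions.labels == 1).sum()) == 27

    def test_every_region_voxel_meets_threshold(self, catalog8):
        occ = occupancy_map(catalog8)
        regions = threshold_regions(occ, 2, min_voxels=1)
        assert np.all(occ.counts[regions.labels > 0] >= 2)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_regions_nest_under_increasing_threshold(self, seed):
        cat = random_catalog(seed=seed, n_genes=6, density=0.4)
        occ = occupancy_map(cat)
        for t in range(1, occ.max_occupancy):
            lo = threshold_regions(occ, t, min_voxels=1)
            hi = threshold_regions(occ, t + 1, min_voxels=1)
            for rid in range(1, hi.n_regions + 1):
                parents = np.unique(lo.labels[hi.labels == rid])
                assert len(parents) == 1 and parents[0] > 0

    def test_connectivity_changes_component_count(self):
        # two voxels touching only at a corner: one 26-component, two 6-components
        mask = np.zeros((8, 8, 8), bool)
        mask[2, 2, 2] = True
        mask[3, 3, 3] = True
        occ = occupancy_map(catalog_of([mask]))
        assert threshold_regions(occ, 1, connectivity=26, min_voxels=1).n_regions == 1
        assert threshold_regions(occ, 1, connectivity=6, min_voxels=1).n_regions == 2


class TestRohoGeneSets:
    def test_single_voxel_intersection_joins_gene_set(self):
        core = np.zeros((8, 8, 8), bool)
        core[2:5, 2:5, 2:5] = True
        toucher = np.zeros((8, 8, 8), bool)
        toucher[4, 4, 4] = True  # exactly one voxel inside the region
        outsider = np.zeros((8, 8, 8), bool)
        outsider[7, 7, 7] = True
        cat = catalog_of([core, core, toucher, outsider])
        occ = occupancy_map(cat)
        regions = threshold_regions(occ, 2, min_voxels=1)
        records = roho_gene_sets(regions, cat)
        assert len(records) == 1
        assert records[0].gene_set == {"g1", "g2", "g3"}
        assert records[0].gene_overlap_voxels["g3"] == 1
        assert records[0].gene_overlap_voxels["g4"] == 0

    def test_gene_set_size_at_least_threshold(self, catalog8):
        occ = occupancy_map(catalog8)
        regions = threshold_regions(occ, 2, min_voxels=1)
        for record in roho_gene_sets(regions, catalog8):
            assert len(record.gene_set) >= 2

    def test_strict_phantom_recovers_planted_gene_sets(self):
        cat, truth = generate_catalog(small_strict_config(seed=21))
        occ = occupancy_map(cat, family="Wnt", stage="E10.5")
        regions = threshold_regions(occ, 5)
        records = roho_gene_sets(regions, cat)
        assert regions.n_regions == len(truth.hotspot_centers)
        got = sorted(sorted(r.gene_set) for r in records)
        want = sorted(sorted(s) for s in truth.hotspot_gene_sets["Wnt"])
        assert got == want
        assert all(r.peak_occupancy == 5 for r in records)


class TestOccupancyPeaks:
    def test_threshold_one_equals_union(self, catalog8):
        occ = occupancy_map(catalog8)
        union = combine(catalog8.domains, "union")
        assert np.array_equal(occupancy_peaks(occ, 1).mask, union.mask)

    def test_above_gene_count_is_empty(self, catalog8):
        occ = occupancy_map(catalog8)
        assert occupancy_peaks(occ, occ.n_genes + 1).volume_voxels == 0

    def test_peaks_nest(self, catalog8):
        occ = occupancy_map(catalog8)
        for t in range(1, occ.n_genes):
            hi = occupancy_peaks(occ, t + 1).mask
            lo = occupancy_peaks(occ, t).mask
            assert not np.any(hi & ~lo)


class TestUniqueAndZero:
    def test_identical_domains_have_no_unique_voxels(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:5] = True
        uniques, table = unique_gene_domains(catalog_of([mask, mask.copy()]))
        assert all(u.volume_voxels == 0 for u in uniques.values())
        assert table["unique_voxels"].sum() == 0

    def test_exclusive_blob_counted_exactly(self):
        shared = np.zeros((8, 8, 8), bool)
        shared[0:2] = True
        exclusive = shared.copy()
        exclusive[5, :5, :5] = True  # 25 exclusive voxels (plus shared overlap)
        uniques, table = unique_gene_domains(catalog_of([shared, exclusive]))
        assert table.loc["g2", "unique_voxels"] == 25
        assert uniques["g2"].volume_voxels == 25

    def test_unique_volumes_partition_single_occupancy(self, catalog8):
        occ = occupancy_map(catalog8)
        _, table = unique_gene_domains(catalog8)
        assert table["unique_voxels"].sum() == int((occ.counts == 1).sum())

    def test_contribution_fractions_match_oracle(self):
        cat = random_catalog(seed=8, n_genes=5)
        _, table = unique_gene_domains(cat)
        expected = oracles.o_unique_voxels([d.mask for d in cat.domains])
        total = sum(expected)
        for d, exp in zip(cat.domains, expected):
            assert table.loc[d.label, "unique_voxels"] == exp
            assert table.loc[d.label, "frac_of_single_gene_domain"] == (
                exp / total if total else 0.0
            )
            assert table.loc[d.label, "frac_of_gene_domain"] == (
                exp / d.volume_voxels if d.volume_voxels else 0.0
            )

    def test_zero_domain_when_family_covers_embryo(self):
        embryo = np.zeros((8, 8, 8), bool)
        embryo[2:6] = True
        zero = zero_expression_domain(catalog_of([embryo.copy()], embryo=embryo))
        assert zero.volume_voxels == 0

    def test_zero_domain_equals_embryo_when_nothing_expressed(self):
        embryo = np.zeros((8, 8, 8), bool)
        embryo[2:6] = True
        empty = np.zeros((8, 8, 8), bool)
        zero = zero_expression_domain(catalog_of([empty, empty.copy()], embryo=embryo))
        assert np.array_equal(zero.mask, embryo)

    def test_partition_identity_with_clipped_domains(self):
        cat = random_catalog(seed=6, n_genes=5, clip_to_embryo=True)
        occ = occupancy_map(cat)
        zero = zero_expression_domain(cat)
        emb = cat.embryo_mask.mask
        one = int(((occ.counts == 1) & emb).sum())
        multi = int(((occ.counts >= 2) & emb).sum())
        assert zero.volume_voxels + one + multi == cat.embryo_mask.volume_voxels


class TestCombine:
    def test_union_with_empty_is_identity(self):
        a = np.zeros((8, 8, 8), bool)
        a[1:4] = True
        out = combine([dom(a, "a"), dom(np.zeros((8, 8, 8), bool), "e")], "union")
        assert np.array_equal(out.mask, a)

    def test_self_subtraction_is_empty(self):
        a = np.zeros((8, 8, 8), bool)
        a[1:4] = True
        assert combine([dom(a, "a"), dom(a, "a2")], "subtract").volume_voxels == 0

    def test_de_morgan_on_random_masks(self):
        rng = np.random.default_rng(17)
        embryo = rng.random((8, 8, 8)) < 0.7
        a = (rng.random((8, 8, 8)) < 0.4) & embryo
        b = (rng.random((8, 8, 8)) < 0.4) & embryo
        emb_dom = dom(embryo, "emb")
        # embryo \ (a ∪ b) == (embryo \ a) ∩ (embryo \ b)
        lhs = combine([emb_dom, combine([dom(a, "a"), dom(b, "b")], "union")], "subtract")
        rhs = combine(
            [combine([emb_dom, dom(a, "a")], "subtract"),
             combine([emb_dom, dom(b, "b")], "subtract")],
            "intersection",
        )
        assert np.array_equal(lhs.mask, rhs.mask)

    def test_incompatible_grids_rejected(self):
        other = VoxelGrid(shape=(8, 8, 4))
        with pytest.raises(GridCompatibilityError):
            combine(
                [dom(np.zeros((8, 8, 8), bool), "a"),
                 BinaryDomain(other, np.zeros((8, 8, 4), bool), "b")],
                "union",
            )

    def test_unknown_op_rejected(self):
        with pytest.raises(ParameterError):
            combine([dom(np.zeros((8, 8, 8), bool), "a")], "xor")
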