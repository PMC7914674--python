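"""Synthetic spectra generator: catalog fidelity, determinism, structure."""

import numpy as np
import pytest

from nirgan import (
    WavenumberGrid,
    reference_catalog,
    sample_archetypes,
    derive_manufacturer_profiles,
    generate_dataset,
    profile_curve,
)


class TestReferenceCatalog:
    def test_totals(self, table_catalog):
        assert table_catalog.total == 1721
        assert table_catalog.k == 29
        assert table_catalog.counts.max() == 135
        assert table_catalog.counts.min() == 21

    def test_counts_and_grouping(self, table_catalog):
        expected = (94, 48, 67, 21, 48, 64, 27, 35, 48, 24, 68, 97, 97, 97,
                    59, 94, 58, 135, 49, 39, 45, 36, 39, 94, 56, 29, 27, 89, 37)
        assert tuple(table_catalog.counts) == expected
        drugs = table_catalog.drug_ids
        assert set(drugs[:14]) == {1}
        assert set(drugs[14:19]) == {2}
        assert set(drugs[19:24]) == {3}
        assert set(drugs[24:29]) == {4}


class TestArchetypes:
    def test_deterministic_under_seed(self, small_grid):
        a = sample_archetypes(4, small_grid, rng_seed=1)
        b = sample_archetypes(4, small_grid, rng_seed=1)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.peak_centers, y.peak_centers)
            np.testing.assert_array_equal(x.peak_heights, y.peak_heights)

    def test_peak_centers_within_grid(self, small_grid):
        (a,) = sample_archetypes(1, small_grid, rng_seed=3)
        assert np.all(a.peak_centers >= small_grid.start)
        assert np.all(a.peak_centers <= small_grid.end)

    def test_pairwise_separability(self, small_grid):
        arch = sample_archetypes(4, small_grid, rng_seed=5)
        for i, a in enumerate(arch):
            for j, b in enumerate(arch):
                if i == j:
                    continue
                d = np.abs(a.peak_centers[:, None] - b.peak_centers[None, :]).min(axis=1)
                assert np.any(d > a.peak_widths)

    def test_different_seeds_differ(self, small_grid):
        draws = [sample_archetypes(1, small_grid, rng_seed=s)[0] for s in range(20)]
        centers = {tuple(np.round(a.peak_centers, 6)) for a in draws}
        assert len(centers) == 20

    def test_invalid_count_rejected(self, small_grid):
        with pytest.raises(ValueError):
            sample_archetypes(0, small_grid, rng_seed=1)


class TestManufacturerProfiles:
    def test_zero_effect_collapses_within_drug(self, small_grid, tiny_catalog):
        arch = sample_archetypes(2, small_grid, rng_seed=2)
        profiles = derive_manufacturer_profiles(arch, tiny_catalog, 0.0, rng_seed=4)
        curves = [profile_curve(p, small_grid) for p in profiles]
        np.testing.assert_array_equal(curves[0], curves[1])  # same drug 1
        np.testing.assert_array_equal(curves[3], curves[4])  # same drug 2

    def test_deterministic(self, small_grid, tiny_catalog):
        arch = sample_archetypes(2, small_grid, rng_seed=2)
        p1 = derive_manufacturer_profiles(arch, tiny_catalog, 0.05, rng_seed=4)
        p2 = derive_manufacturer_profiles(arch, tiny_catalog, 0.05, rng_seed=4)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.height_deltas, b.height_deltas)

    def test_within_drug_more_similar_than_across(self, small_grid, table_catalog):
        arch = sample_archetypes(4, small_grid, rng_seed=2)
        profiles = derive_manufacturer_profiles(arch, table_catalog, 0.03, rng_seed=4)
        curves = np.stack([profile_curve(p, small_grid) for p in profiles])
        curves = curves / np.linalg.norm(curves, axis=1, keepdims=True)
        cos = curves @ curves.T
        drugs = table_catalog.drug_ids
        same = (drugs[:, None] == drugs[None, :]) & ~np.eye(29, dtype=bool)
        diff = drugs[:, None] != drugs[None, :]
        assert cos[same].mean() > cos[diff].mean()

    def test_archetype_count_mismatch(self, small_grid, tiny_catalog):
        arch = sample_archetypes(3, small_grid, rng_seed=2)
        with pytest.raises(ValueError):
            derive_manufacturer_profiles(arch, tiny_catalog, 0.05, rng_seed=4)


class TestGenerateDataset:
    def test_counts_match_catalog_exactly(self, tiny_dataset, tiny_catalog):
        for class_id, _, n in tiny_catalog.classes:
            assert (tiny_dataset.class_ids == class_id).sum() == n

    def test_reference_catalog_yields_1721(self, small_grid, table_catalog):
        arch = sample_archetypes(4, small_grid, rng_seed=1)
        profiles = derive_manufacturer_profiles(arch, table_catalog, 0.03, rng_seed=2)
        ds = generate_dataset(profiles, table_catalog, 0.01, small_grid, rng_seed=3)
        assert len(ds) == 1721

    def test_zero_noise_gives_identical_class_spectra(self, small_grid, tiny_catalog):
        arch = sample_archetypes(2, small_grid, rng_seed=2)
        profiles = derive_manufacturer_profiles(arch, tiny_catalog, 0.05, rng_seed=4)
        ds = generate_dataset(profiles, tiny_catalog, 0.0, small_grid, rng_seed=5)
        rows = ds.X[ds.class_ids == 1]
        assert np.all(rows == rows[0])

    def test_seed_reproducibility(self, small_grid, tiny_catalog):
        arch = sample_archetypes(2, small_grid, rng_seed=2)
        profiles = derive_manufacturer_profiles(arch, tiny_catalog, 0.05, rng_seed=4)
        d1 = generate_dataset(profiles, tiny_catalog, 0.02, small_grid, rng_seed=6,
                              scatter_sd=0.05)
        d2 = generate_dataset(profiles, tiny_catalog, 0.02, small_grid, rng_seed=6,
                              scatter_sd=0.05)
        np.testing.assert_array_equal(d1.X, d2.X)

    def test_noise_sd_recovered(self, small_grid, tiny_catalog):
        """Monte-Carlo: per-channel sd over repeated draws matches noise_sd."""
        arch = sample_archetypes(2, small_grid, rng_seed=2)
        profiles = derive_manufacturer_profiles(arch, tiny_catalog, 0.0, rng_seed=4)
        noise_sd = 0.05
        draws = np.stack([
            generate_dataset(profiles, tiny_catalog, noise_sd, small_grid, rng_seed=s).X[0]
            for s in range(300)
        ])
        est = draws.std(axis=0).mean()
        assert abs(est - noise_sd) / noise_sd < 0.10
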