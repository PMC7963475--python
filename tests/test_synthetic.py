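"""Synthetic world generator: determinism, masks, planted structure."""

import numpy as np
import pytest

from nichedomains import (
    ArchetypeSpec,
    WorldConfig,
    apply_geographic_restriction,
    build_coarse_climate,
    generate_climate_world,
    generate_species_pool,
    well_separated_archetypes,
)
from nichedomains.errors import ConfigurationError


def small_world(seed=0, **kw):
    return generate_climate_world(
        WorldConfig(fine_shape=(60, 60), land_fraction=0.9, seed=seed, **kw)
    )


def test_shapes_and_coarse_grid_bookkeeping():
    world = generate_climate_world(WorldConfig(fine_shape=(120, 120), aggregation_factor=6))
    assert world.energy_fine.shape == (120, 120)
    assert world.config.coarse_shape == (20, 20)


def test_same_seed_gives_bit_identical_rasters():
    cfg = WorldConfig(fine_shape=(60, 60), seed=7)
    a, b = generate_climate_world(cfg), generate_climate_world(cfg)
    np.testing.assert_array_equal(a.energy_fine, b.energy_fine)
    np.testing.assert_array_equal(a.water_fine, b.water_fine)
    np.testing.assert_array_equal(a.land_mask, b.land_mask)


def test_values_respect_configured_ranges_and_land_mask():
    world = small_world(3)
    (elo, ehi), (wlo, whi) = world.config.energy_range, world.config.water_range
    e, w = world.energy_fine, world.water_fine
    assert np.isnan(e[~world.land_mask]).all()
    assert (e[world.land_mask] >= elo).all() and (e[world.land_mask] <= ehi).all()
    assert (w[world.land_mask] >= wlo).all() and (w[world.land_mask] <= whi).all()
    frac = world.land_mask.mean()
    assert abs(frac - world.config.land_fraction) < 0.05


def test_invalid_configs_are_rejected():
    with pytest.raises(ConfigurationError):
        WorldConfig(fine_shape=(121, 120), aggregation_factor=6)
    with pytest.raises(ConfigurationError):
        WorldConfig(land_fraction=0.0)
    with pytest.raises(ConfigurationError):
        WorldConfig(energy_range=(5.0, 5.0))
    with pytest.raises(ConfigurationError):
        ArchetypeSpec(center=(1, 1), breadth=(0.0, 1.0), n_species=3)


def test_species_occupy_land_cells_with_defined_climate():
    world = small_world(1)
    arch = well_separated_archetypes(world, n_species=8)
    presence, labels = generate_species_pool(world, arch, seed=2)
    coarse = build_coarse_climate(
        world.energy_fine, world.water_fine, world.land_mask, 6
    )
    land_flat = np.flatnonzero(coarse.land.ravel())
    for sp, cells in presence.cells.items():
        assert np.isin(cells, land_flat).all()
        assert len(cells) >= 5
        assert sp in labels


def test_degenerate_breadth_collapses_to_nearest_climate_cells():
    world = small_world(4)
    coarse = build_coarse_climate(
        world.energy_fine, world.water_fine, world.land_mask, 6
    )
    e, w = coarse.energy[coarse.land], coarse.water[coarse.land]
    center = (float(np.median(e)), float(np.median(w)))
    arch = [ArchetypeSpec(center=center, breadth=(1e-9, 1e-9), n_species=3, range_cells=30)]
    presence, _ = generate_species_pool(world, arch, min_range_cells=1, seed=0)
    # all species share the one cell whose climate is nearest the center
    sizes = {len(c) for c in presence.cells.values()}
    assert sizes == {1}
    occupied = {int(c[0]) for c in presence.cells.values()}
    assert len(occupied) == 1


def test_planted_archetypes_have_blockwise_similar_profiles():
    """Within-archetype niche profiles are more alike than between."""
    from nichedomains import assign_bins, build_bin_grid, niche_profiles

    world = small_world(5)
    arch = well_separated_archetypes(world, n_species=10)
    presence, labels = generate_species_pool(world, arch, seed=1)
    coarse = build_coarse_climate(
        world.energy_fine, world.water_fine, world.land_mask, 6
    )
    grid = build_bin_grid(coarse, 8)
    prof = niche_profiles(presence, assign_bins(coarse, grid), grid)
    W = prof.weights / np.linalg.norm(prof.weights, axis=0, keepdims=True)
    cos = W.T @ W
    lab = np.array([labels[sp] for sp in prof.species_ids])
    same = lab[:, None] == lab[None, :]
    off_diag = ~np.eye(len(lab), dtype=bool)
    within = cos[same & off_diag].mean()
    between = cos[~same].mean()
    assert within > between


def test_restriction_identity_at_rho_one():
    world = small_world(6)
    presence, _ = generate_species_pool(
        world, well_separated_archetypes(world, n_species=5), seed=3
    )
    assert apply_geographic_restriction(presence, 1.0, seed=9) is presence


def test_restriction_halves_range_sizes_within_one_cell():
    world = small_world(6)
    presence, _ = generate_species_pool(
        world, well_separated_archetypes(world, n_species=5), seed=3
    )
    restricted = apply_geographic_restriction(presence, 0.5, seed=9, min_range_cells=1)
    for sp in presence.cells:
        assert abs(len(restricted.cells[sp]) - 0.5 * len(presence.cells[sp])) <= 1
        assert np.isin(restricted.cells[sp], presence.cells[sp]).all()


def test_restriction_drops_species_when_min_range_unreachable():
    world = small_world(6)
    presence, _ = generate_species_pool(
        world, well_separated_archetypes(world, n_species=4, range_cells=12), seed=3
    )
    victim = presence.species_ids[0]
    rhos = {sp: (0.05 if sp == victim else 1.0) for sp in presence.cells}
    with pytest.warns(UserWarning, match="dropped"):
        restricted = apply_geographic_restriction(presence, rhos, seed=9, min_range_cells=5)
    assert victim not in restricted.cells
    assert restricted.n_species == presence.n_species - 1
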