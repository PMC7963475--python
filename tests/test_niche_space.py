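"""Climate aggregation, quantile binning, and niche profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichedomains import (
    BinGrid,
    PresenceMatrix,
    aggregate_to_coarse,
    assign_bins,
    build_coarse_climate,
    filter_small_ranges,
    niche_profiles,
    quantile_edges,
)
from nichedomains.errors import ConfigurationError, DataError
from nichedomains.niche_space import select_from_gain_curve


# --- aggregation ---------------------------------------------------------

def test_block_mean_of_constants_and_masked_values():
    fine = np.full((6, 6), 7.5)
    coarse, counts = aggregate_to_coarse(fine, np.ones((6, 6), bool), 6)
    assert coarse[0, 0] == 7.5 and counts[0, 0] == 36

    fine = np.zeros((6, 6))
    mask = np.zeros((6, 6), bool)
    fine[0, :3] = [1, 2, 3]
    mask[0, :3] = True
    coarse, counts = aggregate_to_coarse(fine, mask, 6)
    assert coarse[0, 0] == pytest.approx(2.0)
    assert counts[0, 0] == 3

    coarse, counts = aggregate_to_coarse(np.ones((6, 6)), np.zeros((6, 6), bool), 6)
    assert np.isnan(coarse[0, 0]) and counts[0, 0] == 0


def test_non_divisible_shapes_rejected():
    with pytest.raises(ConfigurationError):
        aggregate_to_coarse(np.ones((7, 6)), np.ones((7, 6), bool), 6)


def test_aggregation_is_mean_preserving():
    rng = np.random.default_rng(0)
    fine = rng.uniform(0, 10, (24, 30))
    mask = rng.random((24, 30)) < 0.7
    coarse, counts = aggregate_to_coarse(fine, mask, 6)
    land = counts > 0
    weighted = (coarse[land] * counts[land]).sum() / counts[land].sum()
    assert weighted == pytest.approx(fine[mask].mean(), abs=1e-9)


# --- quantile edges ------------------------------------------------------

def test_median_of_1_to_100_by_linear_interpolation():
    edges = quantile_edges(np.arange(1.0, 101.0), 2)
    np.testing.assert_allclose(edges, [1.0, 50.5, 100.0])


def test_skewed_values_give_equal_occupancy_intervals():
    rng = np.random.default_rng(1)
    vals = rng.lognormal(0, 1, 500)
    d = 10
    edges = quantile_edges(vals, d)
    grid = BinGrid(energy_edges=edges, water_edges=np.array([0.0, 1.0]))
    idx = grid.axis_index(vals, "energy")
    counts = np.bincount(idx, minlength=d)
    assert np.all(np.abs(counts - len(vals) / d) <= 1)


def test_duplicate_edges_collapse_to_fewer_divisions():
    edges = quantile_edges(np.array([5.0, 5.0, 5.0, 7.0]), 4)
    assert np.all(np.diff(edges) > 0)
    assert len(edges) - 1 < 4


def test_degenerate_inputs_rejected():
    with pytest.raises(ConfigurationError):
        quantile_edges(np.arange(10.0), 1)
    with pytest.raises(DataError):
        quantile_edges(np.full(10, 3.0), 4)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.lists(st.floats(0, 1e4, allow_nan=False), min_size=40, max_size=200),
    st.integers(2, 8),
)
def test_quantile_interval_occupancy_property(values, d):
    # the equal-occupancy contract applies to tie-free axes
    vals = np.unique(np.asarray(values))
    if len(vals) < 2 * d:
        return
    edges = quantile_edges(vals, d)
    if len(edges) - 1 < d:
        return
    idx = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, d - 1)
    counts = np.bincount(idx, minlength=d)
    assert np.all(np.abs(counts - len(vals) / d) <= 1)


# --- bin assignment ------------------------------------------------------

@pytest.fixture()
def toy_grid():
    return BinGrid(
        energy_edges=np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
        water_edges=np.array([0.0, 10.0, 20.0]),
    )


def test_half_open_intervals_with_closed_last(toy_grid):
    # value on a lower edge belongs to that interval
    assert toy_grid.assign([3.0], [10.0])[0] == toy_grid.flat_bin(3, 1)
    # the maximum value falls in the last interval, not overflow
    assert toy_grid.assign([4.0], [20.0])[0] == toy_grid.flat_bin(3, 1)


def test_out_of_range_values_clamp_to_end_bins(toy_grid):
    assert toy_grid.assign([-5.0], [25.0])[0] == toy_grid.flat_bin(0, 1)


def test_bin_partition_is_exhaustive_and_disjoint():
    rng = np.random.default_rng(2)
    fine_e = rng.uniform(0, 100, (30, 30))
    fine_w = rng.uniform(0, 100, (30, 30))
    mask = rng.random((30, 30)) < 0.8
    coarse = build_coarse_climate(fine_e, fine_w, mask, 6)
    from nichedomains import build_bin_grid

    grid = build_bin_grid(coarse, 3)
    bins = assign_bins(coarse, grid)
    n_land = int(coarse.land.sum())
    assigned = bins[bins >= 0]
    assert len(assigned) == n_land
    assert int(np.bincount(assigned).sum()) == n_land


# --- filtering & profiles ------------------------------------------------

def make_presence(sizes: dict[str, int], grid_shape=(10, 10)) -> PresenceMatrix:
    cells = {
        sp: np.arange(n, dtype=int) for sp, n in sizes.items()
    }
    return PresenceMatrix(grid_shape=grid_shape, cells=cells)


def test_five_cell_threshold_keeps_five_drops_four():
    presence = make_presence({"four": 4, "five": 5})
    kept, removed = filter_small_ranges(presence, 5)
    assert "five" in kept.cells and "four" not in kept.cells
    assert removed == {"four": 4}


def test_filter_counts_on_graded_pool_and_identity_at_one():
    presence = make_presence({f"s{n}": n for n in range(1, 11)})
    kept, removed = filter_small_ranges(presence, 5)
    assert len(removed) == 4
    kept1, removed1 = filter_small_ranges(presence, 1)
    assert removed1 == {} and kept1.n_species == 10


def test_empty_filter_result_is_an_error():
    with pytest.raises(DataError, match="no species survive filter"):
        filter_small_ranges(make_presence({"a": 2, "b": 3}), 5)


def test_profile_weights_are_cell_count_proportions():
    # 4 cells: 2 in bin A, 1 in bin B, 1 in bin C
    bin_raster = np.full((10, 10), -1)
    bin_raster.ravel()[[0, 1]] = 4
    bin_raster.ravel()[2] = 7
    bin_raster.ravel()[3] = 9
    presence = make_presence({"sp": 4})
    prof = niche_profiles(presence, bin_raster)
    w = dict(zip(prof.bin_ids, prof.weights[:, 0]))
    assert w == {4: 0.5, 7: 0.25, 9: 0.25}
    assert prof.weights.sum() == pytest.approx(1.0)


def test_single_bin_species_gets_weight_one():
    bin_raster = np.full((10, 10), 3)
    prof = niche_profiles(make_presence({"sp": 6}), bin_raster)
    assert prof.bin_ids == [3]
    assert prof.weights[0, 0] == 1.0


def test_total_profile_weight_equals_species_count():
    rng = np.random.default_rng(3)
    bin_raster = rng.integers(0, 12, (10, 10))
    sizes = {f"s{i}": int(rng.integers(3, 30)) for i in range(15)}
    prof = niche_profiles(make_presence(sizes), bin_raster)
    assert prof.weights.sum() == pytest.approx(len(sizes), abs=1e-9)
    np.testing.assert_allclose(prof.weights.sum(axis=0), 1.0, atol=1e-9)


# --- division selection --------------------------------------------------

def test_gain_curve_elbow_rule_on_worked_example():
    curve = pd.DataFrame(
        {"d": [5, 10, 15, 20, 25], "gain_bits": [1.0, 2.0, 2.9, 2.95, 2.96]}
    )
    assert select_from_gain_curve(curve) == 15


def test_single_candidate_returned_unchanged():
    curve = pd.DataFrame({"d": [9], "gain_bits": [1.2]})
    assert select_from_gain_curve(curve) == 9
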