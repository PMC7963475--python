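"""Region maps, AMI, specificity statistics, geographical signal."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichedomains import (
    PresenceMatrix,
    actual_specificity,
    adjusted_mutual_information,
    bin_specificity,
    geographical_signal,
    project_specificity,
    region_map,
)
from nichedomains.errors import ConfigurationError, DataError
from nichedomains.geography import (
    expected_mutual_information,
    mutual_information,
    _contingency,
)


# --- region map ---------------------------------------------------------

def test_region_map_projects_bin_domains_and_conserves_cells(micro_network):
    net, part = micro_network
    rng = np.random.default_rng(0)
    bins = rng.choice([1, 2, 3], size=(6, 6))
    bins[0, :3] = -1  # sea
    regions = region_map(bins, part, net)
    land = bins >= 0
    assert (regions.labels[~land] == -1).all()
    # cell count per region equals the sum over its bins
    inv = {v: k for k, v in regions.legend.items()}
    n_d1 = int((bins == 1).sum())
    n_d2 = int(((bins == 2) | (bins == 3)).sum())
    assert (regions.labels == inv["0"]).sum() == n_d1
    assert (regions.labels == inv["1"]).sum() == n_d2


def test_single_bin_world_is_one_uniform_region(micro_network):
    net, part = micro_network
    bins = np.full((4, 4), 2)
    regions = region_map(bins, part, net)
    assert len(np.unique(regions.labels)) == 1


# --- AMI ----------------------------------------------------------------

def test_identical_partitions_score_one():
    rng = np.random.default_rng(1)
    labels = rng.integers(0, 5, 100)
    assert adjusted_mutual_information(labels, labels.copy()) == pytest.approx(1.0, abs=1e-12)


def test_ami_matches_sklearn_reference():
    sk = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(2)
    for _ in range(5):
        a = rng.integers(0, 4, 120)
        b = rng.integers(0, 6, 120)
        ours = adjusted_mutual_information(a, b)
        ref = sk.adjusted_mutual_info_score(a, b)
        assert ours == pytest.approx(ref, abs=1e-9)


def test_expected_mi_matches_exhaustive_permutation_enumeration():
    """E[MI] equals the mean MI over all label permutations (<= 8 cells)."""
    a = np.array([0, 0, 0, 1, 1, 1, 2, 2])
    b = np.array([0, 0, 1, 1, 2, 2, 2, 0])
    analytic = expected_mutual_information(_contingency(a, b))
    mis = [
        mutual_information(_contingency(a, np.array(p)))
        for p in itertools.permutations(b)
    ]
    assert analytic == pytest.approx(float(np.mean(mis)), abs=1e-9)


def test_ami_symmetry_and_label_renaming_invariance():
    rng = np.random.default_rng(3)
    a = rng.integers(0, 4, 80)
    b = rng.integers(0, 3, 80)
    assert adjusted_mutual_information(a, b) == pytest.approx(
        adjusted_mutual_information(b, a), abs=1e-12
    )
    relabeled = (b + 7) * 3  # injective relabeling
    assert adjusted_mutual_information(a, relabeled) == pytest.approx(
        adjusted_mutual_information(a, b), abs=1e-12
    )


def test_nodata_cells_excluded_pairwise():
    a = np.array([0.0, 0, 1, 1, np.nan, 2])
    b = np.array([5.0, 5, 6, 6, 7, -1])
    # only the first four cells are shared; they agree perfectly
    assert adjusted_mutual_information(a, b) == pytest.approx(1.0)


def test_single_shared_cell_is_an_error():
    with pytest.raises(DataError):
        adjusted_mutual_information(np.array([1.0, np.nan]), np.array([1.0, 2.0]))


def test_degenerate_single_label_partitions():
    ones = np.ones(10)
    assert adjusted_mutual_information(ones, ones) == 1.0
    mixed = np.array([0] * 5 + [1] * 5)
    assert adjusted_mutual_information(ones, mixed) == 0.0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_ami_symmetric_on_random_labelings(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 60))
    a = rng.integers(0, 5, n)
    b = rng.integers(0, 5, n)
    assert adjusted_mutual_information(a, b) == pytest.approx(
        adjusted_mutual_information(b, a), abs=1e-12
    )


# --- specificity (hand-worked micro network) ----------------------------

def test_bin_specificity_hand_values(micro_network):
    net, part = micro_network
    spec = bin_specificity(net, part)
    assert spec[1] == pytest.approx(1.0, abs=1e-12)
    assert spec[2] == pytest.approx(1 / 3, abs=1e-12)
    assert spec[3] == pytest.approx(1.0, abs=1e-12)


def test_specificity_conservation(micro_network):
    """Same-domain plus cross-domain weight fractions sum to one per bin."""
    net, part = micro_network
    spec = bin_specificity(net, part)
    for b, ws in net.weights_by_bin().items():
        dom = part.paths[f"bin_{b}"]
        total = sum(w for _, w in ws)
        cross = sum(w for sp, w in ws if part.paths[sp] != dom) / total
        assert spec[b] + cross == pytest.approx(1.0, abs=1e-12)


def test_projection_copies_bin_values_without_smoothing(micro_network):
    net, part = micro_network
    spec = bin_specificity(net, part)
    bins = np.array([[1, 2], [3, -1]])
    s_p = project_specificity(bins, spec)
    assert s_p[0, 0] == spec[1]
    assert s_p[0, 1] == spec[2]
    assert s_p[1, 0] == spec[3]
    assert np.isnan(s_p[1, 1])
    # histogram equals bin specificities weighted by cell counts
    vals = s_p[~np.isnan(s_p)]
    assert sorted(vals) == sorted(spec[b] for b in (1, 2, 3))


def test_actual_specificity_hand_values(micro_network):
    net, part = micro_network
    bins = np.array([[2]])
    pres = PresenceMatrix(grid_shape=(1, 1), cells={"s2": np.array([0]), "s3": np.array([0])})
    s_a, _ = actual_specificity(net, part, pres, bins)
    assert s_a[0, 0] == pytest.approx(1 / 3, abs=1e-12)

    pres_only_s3 = PresenceMatrix(grid_shape=(1, 1), cells={"s3": np.array([0])})
    s_a, _ = actual_specificity(net, part, pres_only_s3, bins)
    assert s_a[0, 0] == pytest.approx(1.0, abs=1e-12)


def test_cells_without_species_are_excluded(micro_network):
    net, part = micro_network
    bins = np.array([[2, 3]])
    pres = PresenceMatrix(grid_shape=(1, 2), cells={"s3": np.array([0])})
    s_a, n_excl = actual_specificity(net, part, pres, bins)
    assert n_excl == 1
    assert np.isnan(s_a[0, 1])


def test_inconsistent_presence_raises(micro_network):
    net, part = micro_network
    bins = np.array([[3]])  # s1 has no weight in bin 3
    pres = PresenceMatrix(grid_shape=(1, 1), cells={"s1": np.array([0])})
    with pytest.raises(DataError, match="zero weight"):
        actual_specificity(net, part, pres, bins)


# --- geographical signal ------------------------------------------------

def test_signal_zero_when_actual_equals_projected():
    s = np.array([[0.2, 0.8], [np.nan, 0.5]])
    assert geographical_signal(s, s.copy()) == 0.0


def test_signal_is_mean_absolute_difference():
    s_a = np.array([0.5, 0.9])
    s_p = np.array([0.7, 0.5])
    assert geographical_signal(s_a, s_p) == pytest.approx(0.3)


def test_signal_requires_aligned_usable_cells():
    with pytest.raises(ConfigurationError):
        geographical_signal(np.zeros(3), np.zeros(4))
    with pytest.raises(DataError):
        geographical_signal(np.array([np.nan]), np.array([0.5]))
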