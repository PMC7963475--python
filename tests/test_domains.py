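"""Domain detection, bootstrap resampling, and support statistics."""

import numpy as np
import pandas as pd
import pytest

from nichedomains import (
    BipartiteNicheNetwork,
    HierarchicalPartition,
    PresenceMatrix,
    bootstrap_networks,
    detect_domains,
    domain_support,
    major_domains,
    one_module_code_length,
)
from nichedomains.domains import resample_cell_mean
from nichedomains.errors import ConfigurationError, DataError
from nichedomains.niche_space import BinGrid


def biclique_pair() -> BipartiteNicheNetwork:
    """Two disconnected 2-bin x 3-species bicliques."""
    links = []
    for b in (0, 1):
        for s in (0, 1, 2):
            links.append((b, s, 0.5))
    for b in (2, 3):
        for s in (3, 4, 5):
            links.append((b, s, 0.5))
    return BipartiteNicheNetwork(
        bin_ids=[0, 1, 2, 3],
        species_ids=[f"sp{i}" for i in range(6)],
        links=links,
    )


def test_disconnected_bicliques_found_as_two_domains():
    net = biclique_pair()
    part = detect_domains(net, n_runs=20, seed=0)
    mods = part.finest_modules()
    assert len(mods) == 2
    assert frozenset(["bin_0", "bin_1", "sp0", "sp1", "sp2"]) in mods.values()
    assert part.code_length <= one_module_code_length(net) + 1e-12


def test_detection_deterministic_given_seed():
    net = biclique_pair()
    a = detect_domains(net, n_runs=25, seed=3)
    b = detect_domains(net, n_runs=25, seed=3)
    assert a.paths == b.paths and a.code_length == b.code_length


def test_nonpositive_run_count_rejected():
    with pytest.raises(ConfigurationError):
        detect_domains(biclique_pair(), n_runs=0)


def test_found_code_length_beats_planted_partition(planted_run):
    """The search should at least match the planted ground truth."""
    from nichedomains import read_pajek
    from nichedomains.mapequation import hierarchical_code_length
    from nichedomains.network import bin_node_name

    net = read_pajek(planted_run.out / "network.net")
    g = net.to_graph()
    names = net.node_names
    # planted partition: species by archetype, bins by majority weight
    w_by_bin = net.weights_by_bin()
    planted_paths = {}
    for b, ws in w_by_bin.items():
        votes: dict[int, float] = {}
        for sp, w in ws:
            votes[planted_run.planted[sp]] = votes.get(planted_run.planted[sp], 0.0) + w
        planted_paths[bin_node_name(b)] = (max(votes, key=votes.get),)
    for sp in net.species_ids:
        planted_paths[sp] = (planted_run.planted[sp],)
    L_planted = hierarchical_code_length(g, [planted_paths[n] for n in names])
    assert planted_run.partition.code_length <= L_planted + 1e-9


# --- bootstrap ----------------------------------------------------------


def grid_1d() -> BinGrid:
    return BinGrid(
        energy_edges=np.array([0.0, 5.0, 10.0]),
        water_edges=np.array([0.0, 5.0, 10.0]),
    )


def test_single_pixel_cells_resample_to_themselves():
    presence = PresenceMatrix(
        grid_shape=(2, 2),
        cells={"sp": np.array([0, 1])},
        fine_values={0: np.array([[1.0, 1.0]]), 1: np.array([[7.0, 7.0]])},
    )
    nets = list(bootstrap_networks(presence, grid_1d(), B=5, seed=0))
    for net in nets:
        assert sorted(net.bin_ids) == [0, 3]
        assert all(w == 0.5 for _, _, w in net.links)


def test_bootstrap_profiles_still_sum_to_one():
    rng = np.random.default_rng(0)
    fine = {
        c: rng.uniform(0, 10, (9, 2)) for c in range(6)
    }
    presence = PresenceMatrix(
        grid_shape=(2, 3),
        cells={"a": np.array([0, 1, 2]), "b": np.array([2, 3, 4, 5])},
        fine_values=fine,
    )
    for net in bootstrap_networks(presence, grid_1d(), B=10, seed=1):
        per_species = {}
        for _, s, w in net.links:
            per_species[s] = per_species.get(s, 0.0) + w
        assert all(abs(v - 1.0) < 1e-9 for v in per_species.values())


def test_missing_fine_values_is_an_error():
    presence = PresenceMatrix(grid_shape=(2, 2), cells={"sp": np.array([0])})
    with pytest.raises(DataError, match="fine climate"):
        next(iter(bootstrap_networks(presence, grid_1d(), B=1, seed=0)))


def test_resampled_cell_mean_variance_matches_analytic_se():
    """Var of the bootstrap cell mean ~ within-cell pixel variance / n."""
    rng = np.random.default_rng(42)
    vals = rng.normal([5.0, 2.0], [2.0, 0.5], size=(25, 2))
    draws = np.array([resample_cell_mean(rng, vals) for _ in range(4000)])
    expected = vals.var(axis=0) / len(vals)
    np.testing.assert_allclose(draws.var(axis=0), expected, rtol=0.15)


# --- support ------------------------------------------------------------


def flat_partition(assignment: dict[str, int]) -> HierarchicalPartition:
    return HierarchicalPartition(
        paths={k: (v,) for k, v in assignment.items()}, code_length=1.0
    )


def test_identical_bootstrap_partitions_give_full_support():
    obs = flat_partition({"bin_0": 0, "a": 0, "bin_1": 1, "b": 1})
    table = domain_support(obs, [obs] * 8)
    assert set(table.support.values()) == {1.0}
    assert table.B == 8


def test_partial_recovery_counts_matching_fraction():
    obs = flat_partition({"bin_0": 0, "a": 0, "b": 0, "c": 0})
    hit = flat_partition({"bin_0": 0, "a": 0, "b": 0, "c": 1})  # jaccard 3/4
    miss = flat_partition({"bin_0": 0, "a": 1, "b": 2, "c": 3})  # best jaccard 1/4
    table = domain_support(obs, [hit] * 7 + [miss] * 3)
    assert table.support[(0,)] == pytest.approx(0.7)


def test_jaccard_threshold_is_strict():
    obs = flat_partition({"a": 0, "b": 0, "c": 1, "d": 1})
    half = flat_partition({"a": 0, "b": 1, "c": 0, "d": 1})
    # every module overlaps each observed domain by exactly jaccard 1/3
    table = domain_support(obs, [half], jaccard_threshold=1 / 3)
    assert set(table.support.values()) == {0.0}


def test_major_domain_threshold_at_fifty_species():
    sp49 = [f"x{i}" for i in range(49)]
    sp50 = [f"y{i}" for i in range(50)]
    paths = {s: (0,) for s in sp49}
    paths.update({s: (1,) for s in sp50})
    paths["bin_0"] = (0,)
    paths["bin_1"] = (1,)
    part = HierarchicalPartition(paths=paths, code_length=1.0)
    df = major_domains(part, sp49 + sp50, min_species=50).set_index("domain")
    assert not df.loc["0", "major"]
    assert df.loc["1", "major"]
    assert df.n_species.sum() == 99
    df_all = major_domains(part, sp49 + sp50, min_species=1)
    assert df_all.major.all()
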