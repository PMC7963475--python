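"""Shared fixtures: hand-built micro network and the three synthetic studies.

The heavy fixtures are session-scoped so the planted-recovery run, the
niche-overlap sweep and the geographic-restriction sweep are each
computed once and shared by the unit and acceptance tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from nichedomains import (
    BipartiteNicheNetwork,
    HierarchicalPartition,
    RunConfig,
    WorldConfig,
    apply_geographic_restriction,
    assign_bins,
    bin_specificity,
    bootstrap_networks,
    build_bin_grid,
    build_coarse_climate,
    build_network,
    detect_domains,
    domain_support,
    filter_small_ranges,
    generate_climate_world,
    generate_species_pool,
    niche_profiles,
    run_pipeline,
    signal_report,
    well_separated_archetypes,
)
from nichedomains.pipeline import _read_partition, stage_seed


@pytest.fixture()
def micro_network() -> tuple[BipartiteNicheNetwork, HierarchicalPartition]:
    """Three species, three bins, two hand-assigned domains.

    s1: all weight in b1; s2: half b1, half b2; s3: quarter b2, rest b3.
    Domain D1 = {b1, s1, s2}, D2 = {b2, b3, s3}.
    """
    net = BipartiteNicheNetwork(
        bin_ids=[1, 2, 3],
        species_ids=["s1", "s2", "s3"],
        links=[(0, 0, 1.0), (0, 1, 0.5), (1, 1, 0.5), (1, 2, 0.25), (2, 2, 0.75)],
    )
    part = HierarchicalPartition(
        paths={
            "bin_1": (0,),
            "s1": (0,),
            "s2": (0,),
            "bin_2": (1,),
            "bin_3": (1,),
            "s3": (1,),
        },
        code_length=float("nan"),
    )
    return net, part


@dataclass
class PlantedRun:
    """Artifacts of the reference planted-domain pipeline run."""

    out: Path
    config: RunConfig
    partition: HierarchicalPartition
    planted: dict[str, int]
    support: pd.DataFrame
    signal: dict


@pytest.fixture(scope="session")
def planted_run(tmp_path_factory) -> PlantedRun:
    """Full pipeline on a world with 4 well-separated archetypes.

    60 species per archetype, 12 quantile divisions per axis, 50
    detection restarts, 20 bootstrap replicates.
    """
    out = tmp_path_factory.mktemp("planted")
    cfg = RunConfig(
        seed=1,
        out_dir=str(out),
        n_species_per_archetype=60,
        d=12,
        n_runs=50,
        B=20,
        boot_n_runs=20,
    )
    run_pipeline(cfg)
    part = _read_partition(out)
    labels = pd.read_csv(out / "planted_labels.csv", dtype={"species_id": str})
    planted = dict(zip(labels.species_id, labels.archetype))
    support = pd.read_csv(out / "support.csv")
    with open(out / "signal_report.json") as fh:
        signal = json.load(fh)
    return PlantedRun(
        out=out, config=cfg, partition=part, planted=planted,
        support=support, signal=signal,
    )


def _matched_domain_support(partition, planted, support_table, species_in_net):
    """Support of the finest module holding the majority of each archetype."""
    sup = {
        tuple(int(x) for x in str(r.domain).split(":")): r.support
        for r in support_table.itertuples()
    }
    by_arch: dict[int, list] = {}
    for sp, arch in planted.items():
        if sp in species_in_net:
            by_arch.setdefault(arch, []).append(partition.paths[sp])
    out = {}
    for arch, paths in by_arch.items():
        vals, counts = np.unique([":".join(map(str, p)) for p in paths], return_counts=True)
        out[arch] = sup[tuple(int(x) for x in vals[np.argmax(counts)].split(":"))]
    return out


@dataclass
class SweepLevel:
    breadth_frac: float
    mean_bin_specificity: float
    matched_support: dict[int, float]
    domain_pairs: list[tuple[float, float]]  # (mean S_P, support) per bin-bearing domain


@pytest.fixture(scope="session")
def breadth_sweep() -> list[SweepLevel]:
    """Niche-overlap sweep: same world, archetype breadth increasing.

    25 species per archetype, 10 divisions; breadth fractions span the
    regime where the four planted domains persist (beyond ~0.14 the
    optimizer correctly merges them and specificity is trivially 1).
    """
    seed = 2
    levels = []
    for bf in (0.03, 0.06, 0.09, 0.12):
        world = generate_climate_world(WorldConfig(seed=stage_seed(seed, "simulate")))
        arch = well_separated_archetypes(world, n_species=25, breadth_frac=bf)
        presence, planted = generate_species_pool(
            world, arch, seed=stage_seed(seed, "simulate") + 1
        )
        coarse = build_coarse_climate(
            world.energy_fine, world.water_fine, world.land_mask, 6
        )
        presence, _ = filter_small_ranges(presence)
        grid = build_bin_grid(coarse, 10)
        bins = assign_bins(coarse, grid)
        net = build_network(niche_profiles(presence, bins, grid))
        part = detect_domains(net, n_runs=30, seed=stage_seed(seed, "domains"))
        spec = bin_specificity(net, part)
        boots = [
            detect_domains(b, n_runs=10, seed=100 + i)
            for i, b in enumerate(bootstrap_networks(presence, grid, B=10, seed=7))
        ]
        sup = domain_support(part, boots)
        matched = _matched_domain_support(
            part, planted, sup.to_frame(), set(net.species_ids)
        )
        pairs = []
        for path, nodes in part.finest_modules().items():
            dbins = [int(n[4:]) for n in nodes if n.startswith("bin_")]
            if dbins:
                pairs.append(
                    (float(np.mean([spec[b] for b in dbins])), sup.support[path])
                )
        levels.append(
            SweepLevel(
                breadth_frac=bf,
                mean_bin_specificity=float(np.mean(list(spec.values()))),
                matched_support=matched,
                domain_pairs=pairs,
            )
        )
    return levels


@pytest.fixture(scope="session")
def rho_sweep() -> dict[float, list[float]]:
    """Geographic-restriction sweep: G per rho over 3 matched worlds.

    Fragmented climate (autocorrelation scale 3) so each domain's
    climate occurs in disjoint patches; 40 species per archetype with
    80-cell ranges.  Returns rho -> list of G values (one per world).
    """
    out: dict[float, list[float]] = {1.0: [], 0.6: [], 0.3: []}
    for seed in (3, 11, 42):
        sim = stage_seed(seed, "simulate")
        for rho in out:
            world = generate_climate_world(
                WorldConfig(seed=sim, autocorr_scale=3.0)
            )
            arch = well_separated_archetypes(
                world, n_species=40, breadth_frac=0.05, range_cells=80
            )
            presence, _ = generate_species_pool(world, arch, seed=sim + 1)
            if rho < 1.0:
                presence = apply_geographic_restriction(presence, rho, seed=sim + 2)
            coarse = build_coarse_climate(
                world.energy_fine, world.water_fine, world.land_mask, 6
            )
            presence, _ = filter_small_ranges(presence)
            grid = build_bin_grid(coarse, 12)
            bins = assign_bins(coarse, grid)
            net = build_network(niche_profiles(presence, bins, grid))
            part = detect_domains(net, n_runs=40, seed=stage_seed(seed, "domains"))
            out[rho].append(signal_report(net, part, presence, bins).G)
    return out
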