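"""Niche-domain detection and bootstrap significance clustering.

Domains are modules of the bipartite species-bin network found by
minimizing the map-equation code length with a multi-restart search
(:mod:`nichedomains.mapequation`).  Robustness is quantified by
non-parametric bootstrap: within every occupied coarse cell the fine
climate pixels are resampled with replacement, cell means recomputed,
cells re-binned with the original edges, and the resulting bootstrap
networks re-clustered.  A domain's support is the fraction of bootstrap
partitions containing a module with Jaccard similarity above threshold
(default 0.5) to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .mapequation import (
    HierarchicalPartition,
    detect_partition,
    one_level_code_length,
)
from .network import BipartiteNicheNetwork, build_network
from .niche_space import BinGrid, NicheProfileSet
from .presence import PresenceMatrix

log = logging.getLogger(__name__)

__all__ = [
    "SupportTable",
    "detect_domains",
    "one_module_code_length",
    "bootstrap_networks",
    "domain_support",
    "major_domains",
]


def one_module_code_length(network: BipartiteNicheNetwork) -> float:
    """Code length of the trivial all-in-one-module description."""
    return one_level_code_length(network.to_graph())


def detect_domains(
    network: BipartiteNicheNetwork,
    n_runs: int = 1000,
    seed: int = 0,
    hierarchical: bool = True,
) -> HierarchicalPartition:
    """Minimum-code-length joint partition of bins and species.

    Runs the stochastic search ``n_runs`` times and keeps the best
    partition; with ``hierarchical=True`` modules are recursively offered
    sub-splits that are kept only when they shorten the description.
    Deterministic given (seed, n_runs).  The finest-level modules are the
    niche domains reported downstream.
    """
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    return detect_partition(
        network.to_graph(),
        network.node_names,
        n_runs=n_runs,
        seed=seed,
        hierarchical=hierarchical,
    )


def resample_cell_mean(rng: np.random.Generator, fine_vals: np.ndarray) -> np.ndarray:
    """Bootstrap a cell's climate: mean of n pixels drawn with replacement.

    Pixels are drawn jointly for both axes, preserving within-cell
    covariance; the resampled mean has standard error ~ pixel SD / sqrt(n).
    """
    n = len(fine_vals)
    idx = rng.integers(0, n, n)
    return fine_vals[idx].mean(axis=0)


def bootstrap_networks(
    presence: PresenceMatrix,
    grid: BinGrid,
    B: int = 100,
    seed: int = 0,
) -> Iterator[BipartiteNicheNetwork]:
    """Lazily yield B bootstrap networks.

    Per replicate, per species, per occupied coarse cell: draw n fine
    pixels with replacement from the cell's n land pixels (jointly for
    both climate axes, preserving within-cell covariance), average them,
    and re-assign the cell to a bin with the ORIGINAL global edges.
    Profiles and the network are rebuilt from the resampled bins.
    Deterministic given ``seed``.
    """
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    for c in presence.occupied_cells():
        if int(c) not in presence.fine_values:
            raise DataError(f"occupied cell {int(c)} lacks fine climate values")
    streams = np.random.SeedSequence(seed).spawn(B)
    species = sorted(presence.cells)
    for ss in streams:
        rng = np.random.default_rng(ss)
        bin_lists: list[dict[int, float]] = []
        used: set[int] = set()
        for sp in species:
            cc = presence.cells[sp]
            counts: dict[int, int] = {}
            for c in cc:
                e_mean, w_mean = resample_cell_mean(rng, presence.fine_values[int(c)])
                b = int(grid.assign(np.array([e_mean]), np.array([w_mean]))[0])
                counts[b] = counts.get(b, 0) + 1
            prof = {b: k / len(cc) for b, k in counts.items()}
            bin_lists.append(prof)
            used.update(prof)
        bin_ids = sorted(used)
        brow = {b: i for i, b in enumerate(bin_ids)}
        w = np.zeros((len(bin_ids), len(species)))
        for j, prof in enumerate(bin_lists):
            for b, p in prof.items():
                w[brow[b], j] = p
        yield build_network(
            NicheProfileSet(
                species_ids=species, bin_ids=bin_ids, weights=w, grid=grid
            )
        )


@dataclass
class SupportTable:
    """Bootstrap support per observed finest domain."""

    support: dict[tuple[int, ...], float]
    B: int
    jaccard_threshold: float
    domain_sizes: dict[tuple[int, ...], int]

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ConfigurationError("B must be >= 1")
        for d, s in self.support.items():
            if not (0.0 <= s <= 1.0):
                raise DataError(f"support of domain {d} outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "domain": [_path_str(d) for d in self.support],
                "n_nodes": [self.domain_sizes[d] for d in self.support],
                "support": list(self.support.values()),
                "B": self.B,
                "jaccard_threshold": self.jaccard_threshold,
            }
        )


def _path_str(path: tuple[int, ...]) -> str:
    return ":".join(str(p) for p in path)


def _jaccard(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


def domain_support(
    observed: HierarchicalPartition,
    bootstrap_partitions: list[HierarchicalPartition],
    jaccard_threshold: float = 0.5,
    node_kind: str = "union",
    bin_names: set[str] | None = None,
) -> SupportTable:
    """Fraction of bootstrap partitions recovering each observed domain.

    A bootstrap partition recovers a domain when at least one of its
    finest modules has Jaccard similarity STRICTLY greater than
    ``jaccard_threshold`` to the domain's node set.  The node set is the
    union of the domain's bins and species by default; ``node_kind =
    'species'`` restricts the comparison to species nodes (requires
    ``bin_names``).  Nodes absent from a bootstrap network count as
    absent from all its modules.
    """
    if not bootstrap_partitions:
        raise ConfigurationError("at least one bootstrap partition required")
    if node_kind not in ("union", "species"):
        raise ConfigurationError("node_kind must be 'union' or 'species'")
    if node_kind == "species" and bin_names is None:
        raise ConfigurationError("species-only support needs bin_names")

    def select(nodes: frozenset[str]) -> frozenset[str]:
        if node_kind == "union":
            return nodes
        return frozenset(n for n in nodes if n not in bin_names)

    obs_modules = {
        path: select(nodes) for path, nodes in observed.finest_modules().items()
    }
    for path, nodes in obs_modules.items():
        if not nodes:
            raise DataError(f"observed domain {path} is empty")
    boot_module_sets = [
        [select(m) for m in bp.finest_modules().values()]
        for bp in bootstrap_partitions
    ]
    support = {}
    for path, nodes in obs_modules.items():
        hits = sum(
            1
            for mods in boot_module_sets
            if any(_jaccard(nodes, m) > jaccard_threshold for m in mods)
        )
        support[path] = hits / len(bootstrap_partitions)
    sizes = {p: len(n) for p, n in observed.finest_modules().items()}
    return SupportTable(
        support=support,
        B=len(bootstrap_partitions),
        jaccard_threshold=jaccard_threshold,
        domain_sizes=sizes,
    )


def major_domains(
    partition: HierarchicalPartition,
    species_ids: list[str],
    min_species: int = 50,
) -> pd.DataFrame:
    """Flag finest domains holding at least ``min_species`` species.

    Domains below the threshold are too species-poor to interpret as
    stable climate regions and are reported as minor.
    """
    species = set(species_ids)
    rows = []
    for path, nodes in sorted(partition.finest_modules().items()):
        n_sp = sum(1 for n in nodes if n in species)
        rows.append(
            {
                "domain": _path_str(path),
                "n_species": n_sp,
                "n_bins": len(nodes) - n_sp,
                "major": n_sp >= min_species,
            }
        )
    return pd.DataFrame(rows)
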