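"""The weighted bipartite species-bin network and its Pajek exchange format.

Climatic bins and species form the two disjoint node sets; the link
weight between bin i and species j is w_ij, the proportion of species
j's occupied cells with the climate of bin i.  Per-species link weights
therefore sum to 1 and the total link weight equals the number of
species.

Networks are exchanged as bipartite Pajek (.net) files — the format the
standard map-equation tooling consumes — with bin nodes listed first and
the partition boundary in the ``*Vertices n n_bins`` header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .mapequation import Graph
from .niche_space import BinGrid, NicheProfileSet

log = logging.getLogger(__name__)

__all__ = ["BipartiteNicheNetwork", "build_network", "write_pajek", "read_pajek"]


def bin_node_name(bin_id: int) -> str:
    return f"bin_{bin_id}"


@dataclass
class BipartiteNicheNetwork:
    """Weighted bipartite network of climatic bins and species.

    ``links`` holds (bin position, species position, weight) triples with
    positions indexing ``bin_ids`` / ``species_ids``; all weights are
    strictly positive.
    """

    bin_ids: list[int]
    species_ids: list[str]
    links: list[tuple[int, int, float]]
    grid: BinGrid | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        nb, ns = len(self.bin_ids), len(self.species_ids)
        for b, s, w in self.links:
            if not (0 <= b < nb and 0 <= s < ns):
                raise DataError(f"link ({b},{s}) outside node sets")
            if w <= 0:
                raise DataError(f"non-positive link weight on ({b},{s})")

    @property
    def n_bins(self) -> int:
        return len(self.bin_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_bins + self.n_species

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.links))

    @property
    def node_names(self) -> list[str]:
        return [bin_node_name(b) for b in self.bin_ids] + list(self.species_ids)

    def bin_names(self) -> set[str]:
        return {bin_node_name(b) for b in self.bin_ids}

    def species_degree(self, species_id: str) -> int:
        j = self.species_ids.index(species_id)
        return sum(1 for _, s, _ in self.links if s == j)

    def to_graph(self) -> Graph:
        nb = self.n_bins
        return Graph.from_edges(
            self.n_nodes, [(b, nb + s, w) for b, s, w in self.links]
        )

    def weights_by_bin(self) -> dict[int, list[tuple[str, float]]]:
        """bin id -> [(species id, w_ij), ...]."""
        out: dict[int, list[tuple[str, float]]] = {b: [] for b in self.bin_ids}
        for b, s, w in self.links:
            out[self.bin_ids[b]].append((self.species_ids[s], w))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteNicheNetwork):
            return NotImplemented
        return (
            self.bin_ids == other.bin_ids
            and self.species_ids == other.species_ids
            and sorted(self.links) == sorted(other.links)
        )


def build_network(profiles: NicheProfileSet) -> BipartiteNicheNetwork:
    """One link per positive w_ij; isolated bins are dropped (logged)."""
    if profiles.n_species == 0:
        raise DataError("empty profile set")
    row_tot = profiles.weights.sum(axis=1)
    keep = row_tot > 0
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropped %d isolated bin nodes", dropped)
    bin_ids = [b for b, k in zip(profiles.bin_ids, keep) if k]
    w = profiles.weights[keep]
    bi, sj = np.nonzero(w)
    links = [(int(i), int(j), float(w[i, j])) for i, j in zip(bi, sj)]
    return BipartiteNicheNetwork(
        bin_ids=bin_ids,
        species_ids=list(profiles.species_ids),
        links=links,
        grid=profiles.grid,
    )


def write_pajek(network: BipartiteNicheNetwork, path) -> None:
    """Bipartite Pajek: bins first, species second, undirected weighted edges.

    Weights are written with ``repr`` (shortest round-trip float), so a
    write/read cycle reproduces the network bit-exactly.
    """
    names = network.node_names
    nb = network.n_bins
    with open(path, "w") as fh:
        fh.write(f"% bipartite species-bin network; first {nb} vertices are bins\n")
        fh.write(f"*Vertices {len(names)} {nb}\n")
        for i, name in enumerate(names, 1):
            fh.write(f'{i} "{name}"\n')
        fh.write("*Edges\n")
        for b, s, w in sorted(network.links):
            fh.write(f"{b + 1} {nb + s + 1} {w!r}\n")


def read_pajek(path) -> BipartiteNicheNetwork:
    """Read and validate a bipartite Pajek file written by :func:`write_pajek`."""
    n = nb = None
    names: list[str] = []
    links: list[tuple[int, int, float]] = []
    mode = "head"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                parts = line.split()
                if len(parts) < 3:
                    raise DataError(
                        f"{path}:{lineno}: *Vertices needs total and bipartite counts"
                    )
                n, nb = int(parts[1]), int(parts[2])
                mode = "vertices"
                continue
            if low.startswith("*edges") or low.startswith("*arcs"):
                mode = "edges"
                continue
            if mode == "vertices":
                idx, _, rest = line.partition(" ")
                if int(idx) != len(names) + 1:
                    raise DataError(f"{path}:{lineno}: vertices out of order")
                names.append(rest.strip().strip('"'))
            elif mode == "edges":
                parts = line.split()
                if len(parts) != 3:
                    raise DataError(f"{path}:{lineno}: edge line needs 'u v w'")
                u, v, w = int(parts[0]), int(parts[1]), float(parts[2])
                if not (1 <= u <= len(names) and 1 <= v <= len(names)):
                    raise DataError(f"{path}:{lineno}: edge names undeclared vertex")
                if u > v:
                    u, v = v, u
                if not (u <= nb < v):
                    raise DataError(
                        f"{path}:{lineno}: edge ({u},{v}) violates bipartiteness "
                        f"(boundary at {nb})"
                    )
                links.append((u - 1, v - nb - 1, w))
            else:
                raise DataError(f"{path}:{lineno}: content before *Vertices")
    if n is None or len(names) != n:
        raise DataError(f"{path}: vertex count mismatch")
    bin_ids = []
    for name in names[:nb]:
        if not name.startswith("bin_"):
            raise DataError(f"{path}: first-mode vertex {name!r} is not a bin node")
        bin_ids.append(int(name[4:]))
    return BipartiteNicheNetwork(
        bin_ids=bin_ids, species_ids=names[nb:], links=links
    )


def write_node_table(network: BipartiteNicheNetwork, path) -> None:
    """Sidecar CSV with node kinds, labels, and bin climate intervals."""
    rows = []
    for i, b in enumerate(network.bin_ids, 1):
        e_iv = w_iv = (np.nan, np.nan)
        if network.grid is not None:
            e_iv, w_iv = network.grid.bin_interval(b)
        rows.append(
            {
                "node_id": i,
                "kind": "bin",
                "label": bin_node_name(b),
                "energy_lo": e_iv[0],
                "energy_hi": e_iv[1],
                "water_lo": w_iv[0],
                "water_hi": w_iv[1],
            }
        )
    for j, sp in enumerate(network.species_ids, 1):
        rows.append(
            {
                "node_id": network.n_bins + j,
                "kind": "species",
                "label": sp,
                "energy_lo": np.nan,
                "energy_hi": np.nan,
                "water_lo": np.nan,
                "water_hi": np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
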