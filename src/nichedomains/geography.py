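"""Geographic projection of niche domains and the specificity statistics.

A niche domain's climatic region is the set of coarse cells whose
climate falls in the domain's bins.  Three statistics characterize the
match between climate and species distributions:

* bin specificity  S_i = sum of w_ij to same-domain species / sum of all
  w_ij — low values mark climatic transition zones;
* projected vs actual specificity — a cell inherits its bin's
  specificity (projected, S^P), or recomputes it from the species
  actually present in the cell (actual, S^A);
* the geographical signal  G = mean |S^A - S^P| over cells — 0 when each
  domain's species fill its whole climatic region, approaching 1 when
  species occupy only scattered portions of it.

Regionalizations (ours, a reference classification, another taxon's)
are compared with adjusted mutual information under the permutation
model, so chance agreement scores ~0 and identity scores 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ConfigurationError, DataError
from .mapequation import HierarchicalPartition
from .network import BipartiteNicheNetwork, bin_node_name
from .presence import PresenceMatrix

log = logging.getLogger(__name__)

__all__ = [
    "RegionMap",
    "SignalReport",
    "region_map",
    "adjusted_mutual_information",
    "expected_mutual_information",
    "bin_specificity",
    "project_specificity",
    "actual_specificity",
    "geographical_signal",
    "domain_summary",
]

UNCLASSIFIED = -2  # bins dropped as isolated carry no domain


@dataclass
class RegionMap:
    """Coarse raster of domain labels; -1 = no climate, -2 = unclassified."""

    labels: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels[self.labels >= 0]).tolist())
        if not present.issubset(self.legend):
            raise DataError("legend does not cover all labels")

    def legend_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": list(self.legend), "domain": list(self.legend.values())}
        )


def _bin_domains(
    network: BipartiteNicheNetwork, partition: HierarchicalPartition
) -> dict[int, tuple[int, ...]]:
    out = {}
    for b in network.bin_ids:
        name = bin_node_name(b)
        if name in partition.paths:
            out[b] = partition.paths[name]
    return out


def region_map(
    bin_raster: np.ndarray,
    partition: HierarchicalPartition,
    network: BipartiteNicheNetwork,
) -> RegionMap:
    """Label every climate-bearing cell with its bin's finest domain.

    Bins absent from the network (no species occurrences) get the
    designated unclassified label.
    """
    bin_dom = _bin_domains(network, partition)
    domains = sorted(set(bin_dom.values()))
    dom_label = {d: i for i, d in enumerate(domains)}
    legend = {i: ":".join(map(str, d)) for d, i in dom_label.items()}
    labels = np.full(bin_raster.shape, -1, dtype=int)
    land = bin_raster >= 0
    flat = bin_raster[land]
    mapped = np.array(
        [dom_label[bin_dom[b]] if b in bin_dom else UNCLASSIFIED for b in flat]
    )
    labels[land] = mapped
    n_unclass = int((mapped == UNCLASSIFIED).sum())
    if n_unclass:
        log.info("%d cells fall in bins with no species (unclassified)", n_unclass)
    return RegionMap(labels=labels, legend=legend)


# ---------------------------------------------------------------------------
# adjusted mutual information


def _contingency(a: np.ndarray, b: np.ndarray):
    av, ai = np.unique(a, return_inverse=True)
    bv, bi = np.unique(b, return_inverse=True)
    table = np.zeros((len(av), len(bv)), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def expected_mutual_information(table: np.ndarray) -> float:
    """E[MI] of two labelings under the permutation (hypergeometric) model.

    Sums, for every (row, column) pair, the mutual-information
    contribution of each feasible joint count weighted by its
    hypergeometric probability.  Natural-log units.
    """
    n = int(table.sum())
    a = table.sum(axis=1).astype(np.int64)
    b = table.sum(axis=0).astype(np.int64)
    lg = gammaln
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                log_p = (
                    lg(ai + 1)
                    + lg(bj + 1)
                    + lg(n - ai + 1)
                    + lg(n - bj + 1)
                    - lg(n + 1)
                    - lg(nij + 1)
                    - lg(ai - nij + 1)
                    - lg(bj - nij + 1)
                    - lg(n - ai - bj + nij + 1)
                )
                emi += (nij / n) * np.log(n * nij / (ai * bj)) * np.exp(log_p)
    return float(emi)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(table: np.ndarray) -> float:
    n = table.sum()
    a = table.sum(axis=1, keepdims=True)
    b = table.sum(axis=0, keepdims=True)
    nz = table > 0
    t = table[nz].astype(float)
    outer = (a @ b)[nz].astype(float)
    return float((t / n * np.log(n * t / outer)).sum())


def adjusted_mutual_information(
    labels_a: np.ndarray, labels_b: np.ndarray, average: str = "mean"
) -> float:
    """Chance-corrected similarity of two labelings of the same cells.

    AMI = (MI - E[MI]) / (norm(H_a, H_b) - E[MI]) with E[MI] under the
    permutation model; ``average='mean'`` normalizes by the mean of the
    two entropies (the common convention), ``'max'`` by their maximum.
    Cells that are nodata (< 0 or NaN) in either labeling are excluded
    pairwise.  Identical partitions score 1; two single-label partitions
    are identical by construction and also score 1.
    """
    a = np.asarray(labels_a, dtype=float).ravel()
    b = np.asarray(labels_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ConfigurationError("labelings must cover the same cells")
    valid = ~(np.isnan(a) | np.isnan(b)) & (a >= 0) & (b >= 0)
    if valid.sum() < 2:
        raise DataError("need at least two shared labeled cells")
    a, b = a[valid].astype(int), b[valid].astype(int)
    table = _contingency(a, b)
    if table.shape == (1, 1):
        return 1.0
    ha, hb = _entropy(table.sum(axis=1)), _entropy(table.sum(axis=0))
    if average == "mean":
        norm = 0.5 * (ha + hb)
    elif average == "max":
        norm = max(ha, hb)
    else:
        raise ConfigurationError("average must be 'mean' or 'max'")
    mi = mutual_information(table)
    emi = expected_mutual_information(table)
    denom = norm - emi
    if abs(denom) < 1e-15:
        return 1.0 if abs(mi - emi) < 1e-15 else 0.0
    return float((mi - emi) / denom)


# ---------------------------------------------------------------------------
# specificity (Eq. 1 family) and the geographical signal


def bin_specificity(
    network: BipartiteNicheNetwork, partition: HierarchicalPartition
) -> dict[int, float]:
    """Share of each bin's link weight going to species of its own domain.

    S_i = sum_{j in D} w_ij / sum_j w_ij for bin i in domain D; equals 1
    when the bin connects only to species of its own domain, and drops
    toward 0 in climatic transition zones.
    """
    for name in network.node_names:
        if name not in partition.paths:
            raise DataError(f"node {name} missing from partition")
    spec = {}
    for b, weights in network.weights_by_bin().items():
        dom = partition.paths[bin_node_name(b)]
        total = sum(w for _, w in weights)
        if total <= 0:
            raise DataError(f"bin {b} has zero total link weight")
        same = sum(w for sp, w in weights if partition.paths[sp] == dom)
        spec[b] = same / total
    return spec


def project_specificity(
    bin_raster: np.ndarray, specificity: dict[int, float]
) -> np.ndarray:
    """S^P raster: every cell of bin i carries S_i verbatim (no smoothing)."""
    out = np.full(bin_raster.shape, np.nan)
    land = bin_raster >= 0
    out[land] = [specificity.get(int(b), np.nan) for b in bin_raster[land]]
    return out


def actual_specificity(
    network: BipartiteNicheNetwork,
    partition: HierarchicalPartition,
    presence: PresenceMatrix,
    bin_raster: np.ndarray,
) -> tuple[np.ndarray, int]:
    """S^A raster from the species pool actually present in each cell.

    For cell q with bin i in domain D:
    S^A_q = sum_{j in D present in q} w_ij / sum_{j present in q} w_ij.
    Cells with no species present are NaN and counted as excluded.
    """
    w_by_bin = {
        b: dict(ws) for b, ws in network.weights_by_bin().items()
    }
    bin_dom = _bin_domains(network, partition)
    sp_dom = {sp: partition.paths[sp] for sp in network.species_ids}
    cell_sp = presence.cell_species_index()
    out = np.full(bin_raster.shape, np.nan)
    flat_bins = bin_raster.ravel()
    n_excluded = 0
    for c in np.flatnonzero(flat_bins >= 0):
        b = int(flat_bins[c])
        if b not in bin_dom:
            n_excluded += 1
            continue
        present = cell_sp.get(int(c), [])
        if not present:
            n_excluded += 1
            continue
        weights = w_by_bin[b]
        num = den = 0.0
        for sp in present:
            if sp not in sp_dom:
                raise DataError(
                    f"species {sp} present in cell {int(c)} but absent from network"
                )
            w = weights.get(sp, 0.0)
            if w <= 0.0:
                raise DataError(
                    f"species {sp} present in cell {int(c)} has zero weight in "
                    f"bin {b}; presence and profiles are inconsistent"
                )
            den += w
            if sp_dom[sp] == bin_dom[b]:
                num += w
        out.ravel()[c] = num / den
    return out, n_excluded


def geographical_signal(s_actual: np.ndarray, s_projected: np.ndarray) -> float:
    """G = mean over usable cells of |S^A - S^P|, in [0, 1]."""
    if s_actual.shape != s_projected.shape:
        raise ConfigurationError("specificity rasters must align")
    both = ~(np.isnan(s_actual) | np.isnan(s_projected))
    if not both.any():
        raise DataError("zero usable cells for the geographical signal")
    return float(np.abs(s_actual[both] - s_projected[both]).mean())


@dataclass
class SignalReport:
    """Projected/actual specificity rasters and the scalar signal G."""

    s_projected: np.ndarray
    s_actual: np.ndarray
    G: float
    n_cells_used: int
    n_cells_excluded: int

    def __post_init__(self) -> None:
        for arr in (self.s_projected, self.s_actual):
            vals = arr[~np.isnan(arr)]
            if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
                raise DataError("specificity values must lie in [0, 1]")
        if not (0.0 <= self.G <= 1.0):
            raise DataError("G must lie in [0, 1]")


def signal_report(
    network: BipartiteNicheNetwork,
    partition: HierarchicalPartition,
    presence: PresenceMatrix,
    bin_raster: np.ndarray,
) -> SignalReport:
    """Convenience wrapper computing S^P, S^A and G in one pass."""
    spec = bin_specificity(network, partition)
    s_p = project_specificity(bin_raster, spec)
    s_a, n_excl = actual_specificity(network, partition, presence, bin_raster)
    both = ~(np.isnan(s_a) | np.isnan(s_p))
    return SignalReport(
        s_projected=s_p,
        s_actual=s_a,
        G=geographical_signal(s_a, s_p),
        n_cells_used=int(both.sum()),
        n_cells_excluded=n_excl,
    )


def domain_summary(
    network: BipartiteNicheNetwork,
    partition: HierarchicalPartition,
    regions: RegionMap,
    specificity: dict[int, float],
    support=None,
) -> pd.DataFrame:
    """Per-domain table (species, bins, cells, mean S^P, bootstrap support).

    This is the export a downstream mixed-model analysis of support
    vs specificity would consume.
    """
    species = set(network.species_ids)
    label_of = {d: l for l, d in ((l, tuple(map(int, d.split(":")))) for l, d in regions.legend.items())}
    rows = []
    for path, nodes in sorted(partition.finest_modules().items()):
        bins = [int(n[4:]) for n in nodes if n not in species]
        n_cells = (
            int((regions.labels == label_of[path]).sum()) if path in label_of else 0
        )
        cell_weighted = [
            specificity[b]
            for b in bins
            if b in specificity
        ]
        rows.append(
            {
                "domain": ":".join(map(str, path)),
                "n_species": len(nodes) - len(bins),
                "n_bins": len(bins),
                "n_cells": n_cells,
                "mean_S_P": float(np.mean(cell_weighted)) if cell_weighted else np.nan,
                "bootstrap_support": (
                    support.support.get(path, np.nan) if support is not None else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
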