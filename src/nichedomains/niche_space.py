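"""The two-dimensional climate space and species niche profiles.

Fine climate rasters are aggregated to the coarse analysis grid by
block-averaging land pixels.  Each axis (energy, water) is then divided
into quantile bins computed from the distribution of coarse land-cell
values across the whole world, so bins hold roughly equal numbers of
cells and resolution concentrates where climates are common.  A species'
niche profile is the proportion of its occupied cells falling in each
two-dimensional climate bin — the link weights w_ij of the bipartite
species-bin network downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .presence import PresenceMatrix

log = logging.getLogger(__name__)

__all__ = [
    "CoarseClimate",
    "BinGrid",
    "NicheProfileSet",
    "aggregate_to_coarse",
    "build_coarse_climate",
    "quantile_edges",
    "build_bin_grid",
    "assign_bins",
    "filter_small_ranges",
    "niche_profiles",
    "select_divisions",
]


@dataclass
class CoarseClimate:
    """Block-averaged climate on the coarse grid (NaN where no land)."""

    energy: np.ndarray
    water: np.ndarray
    land_pixel_counts: np.ndarray
    factor: int

    @property
    def land(self) -> np.ndarray:
        return self.land_pixel_counts > 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.energy.shape

    def land_values(self, axis: str) -> np.ndarray:
        arr = self.energy if axis == "energy" else self.water
        return arr[self.land]


def aggregate_to_coarse(
    fine_raster: np.ndarray, land_mask: np.ndarray, factor: int
) -> tuple[np.ndarray, np.ndarray]:
    """Masked block mean: each coarse cell averages its fine land pixels.

    Returns (coarse means with NaN for all-sea blocks, land-pixel counts).
    The aggregation is mean-preserving: the count-weighted mean of coarse
    values equals the mean over fine land pixels.
    """
    if fine_raster.shape != land_mask.shape:
        raise ConfigurationError("raster and mask shapes differ")
    r, c = fine_raster.shape
    if factor < 1 or r % factor or c % factor:
        raise ConfigurationError(
            f"raster shape {fine_raster.shape} not divisible by factor {factor}"
        )
    R, C = r // factor, c // factor
    filled = np.where(land_mask, fine_raster, 0.0)
    sums = filled.reshape(R, factor, C, factor).sum(axis=(1, 3))
    counts = land_mask.reshape(R, factor, C, factor).sum(axis=(1, 3))
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def build_coarse_climate(
    energy_fine: np.ndarray,
    water_fine: np.ndarray,
    land_mask: np.ndarray,
    factor: int,
) -> CoarseClimate:
    e, counts = aggregate_to_coarse(energy_fine, land_mask, factor)
    w, _ = aggregate_to_coarse(water_fine, land_mask, factor)
    return CoarseClimate(energy=e, water=w, land_pixel_counts=counts, factor=factor)


def quantile_edges(values: np.ndarray, d: int) -> np.ndarray:
    """Quantile break points at k/d, k = 0..d (linear interpolation).

    Consecutive duplicate edges are collapsed, so the effective number of
    divisions can fall below ``d`` on heavily tied data (logged).
    """
    if d < 2:
        raise ConfigurationError("number of divisions must be >= 2")
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise DataError("no values to compute quantiles from")
    if np.ptp(vals) == 0.0:
        raise DataError("degenerate axis: all values identical")
    # linear-interpolation quantiles with exact integer positions: an edge at
    # k/d sits at sorted position k*(n-1)/d, computed with integer arithmetic
    # so edges on order statistics carry no floating-point jitter
    x = np.sort(vals)
    n = len(x)
    edges = np.empty(d + 1)
    for k in range(d + 1):
        i, rem = divmod(k * (n - 1), d)
        edges[k] = x[i] if rem == 0 else x[i] + (rem / d) * (x[i + 1] - x[i])
    keep = np.concatenate([[True], np.diff(edges) > 0])
    collapsed = edges[keep]
    if len(collapsed) < d + 1:
        log.info(
            "collapsed %d duplicate quantile edges (effective divisions %d < %d)",
            d + 1 - len(collapsed),
            len(collapsed) - 1,
            d,
        )
    return collapsed


@dataclass
class BinGrid:
    """Cartesian product of per-axis quantile intervals.

    Intervals are half-open [edge_k, edge_{k+1}) with the last interval
    closed; a flat bin id is ``e_idx * d_w + w_idx``.
    """

    energy_edges: np.ndarray
    water_edges: np.ndarray

    def __post_init__(self) -> None:
        for edges in (self.energy_edges, self.water_edges):
            if len(edges) < 2 or np.any(np.diff(edges) <= 0):
                raise ConfigurationError("edges must be strictly increasing")

    @property
    def d_energy(self) -> int:
        return len(self.energy_edges) - 1

    @property
    def d_water(self) -> int:
        return len(self.water_edges) - 1

    @property
    def n_bins(self) -> int:
        return self.d_energy * self.d_water

    def axis_index(self, values: np.ndarray, axis: str) -> np.ndarray:
        edges = self.energy_edges if axis == "energy" else self.water_edges
        idx = np.searchsorted(edges, values, side="right") - 1
        n_clamped = int(np.sum((idx < 0) | (idx > len(edges) - 2)))
        # values at the top edge belong to the last (closed) interval;
        # values outside the edges (foreign datasets) clamp to end bins
        out_of_range = int(
            np.sum((values < edges[0]) | (values > edges[-1]))
        )
        if out_of_range:
            log.info("%d %s values outside edges clamped to end bins", out_of_range, axis)
        del n_clamped
        return np.clip(idx, 0, len(edges) - 2)

    def flat_bin(self, e_idx: np.ndarray, w_idx: np.ndarray) -> np.ndarray:
        return e_idx * self.d_water + w_idx

    def assign(self, energy: np.ndarray, water: np.ndarray) -> np.ndarray:
        return self.flat_bin(
            self.axis_index(np.asarray(energy), "energy"),
            self.axis_index(np.asarray(water), "water"),
        )

    def bin_interval(self, bin_id: int):
        e_idx, w_idx = divmod(int(bin_id), self.d_water)
        return (
            (self.energy_edges[e_idx], self.energy_edges[e_idx + 1]),
            (self.water_edges[w_idx], self.water_edges[w_idx + 1]),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for axis, edges in (("energy", self.energy_edges), ("water", self.water_edges)):
            for k, e in enumerate(edges):
                rows.append({"axis": axis, "k": k, "edge": e})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinGrid":
        e = df[df.axis == "energy"].sort_values("k").edge.to_numpy()
        w = df[df.axis == "water"].sort_values("k").edge.to_numpy()
        return cls(energy_edges=e, water_edges=w)


def build_bin_grid(coarse: CoarseClimate, d: int, d_water: int | None = None) -> BinGrid:
    """Quantile bin grid from the global coarse land-cell climate.

    Both axes get the same division count by default; ``d_water`` allows
    a per-axis count.
    """
    return BinGrid(
        energy_edges=quantile_edges(coarse.land_values("energy"), d),
        water_edges=quantile_edges(coarse.land_values("water"), d_water or d),
    )


def assign_bins(coarse: CoarseClimate, grid: BinGrid) -> np.ndarray:
    """Flat bin id per coarse cell; -1 where there is no climate (sea)."""
    out = np.full(coarse.shape, -1, dtype=int)
    land = coarse.land
    out[land] = grid.assign(coarse.energy[land], coarse.water[land])
    return out


def filter_small_ranges(
    presence: PresenceMatrix, min_cells: int = 5
) -> tuple[PresenceMatrix, dict[str, int]]:
    """Drop species occupying fewer than ``min_cells`` coarse cells.

    Narrow-ranging species carry too few cells for a stable realized
    niche estimate.  Returns the filtered presence and a report of the
    removed species with their range sizes.
    """
    removed = {
        sp: len(cc) for sp, cc in presence.cells.items() if len(cc) < min_cells
    }
    kept = [sp for sp in presence.cells if sp not in removed]
    if not kept:
        raise DataError("no species survive filter")
    if removed:
        log.info("filtered %d species below %d cells", len(removed), min_cells)
    return presence.subset(kept), removed


@dataclass
class NicheProfileSet:
    """w_ij link weights: per species, share of occupied cells per bin.

    ``weights`` is (n_bins, n_species); rows are indexed by ``bin_ids``
    (flat bin ids actually carrying weight), columns by ``species_ids``.
    Every species column sums to 1.
    """

    species_ids: list[str]
    bin_ids: list[int]
    weights: np.ndarray
    grid: BinGrid | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.weights.shape != (len(self.bin_ids), len(self.species_ids)):
            raise ConfigurationError("weight matrix shape mismatch")
        col = self.weights.sum(axis=0)
        if self.species_ids and not np.allclose(col, 1.0, atol=1e-9):
            raise DataError("species profile rows must sum to 1")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def to_frame(self) -> pd.DataFrame:
        bi, sj = np.nonzero(self.weights)
        return pd.DataFrame(
            {
                "bin_id": [self.bin_ids[i] for i in bi],
                "species_id": [self.species_ids[j] for j in sj],
                "weight": self.weights[bi, sj],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, grid: BinGrid | None = None) -> "NicheProfileSet":
        species = sorted(df.species_id.astype(str).unique())
        bins = sorted(int(b) for b in df.bin_id.unique())
        w = np.zeros((len(bins), len(species)))
        brow = {b: i for i, b in enumerate(bins)}
        scol = {s: j for j, s in enumerate(species)}
        for r in df.itertuples():
            w[brow[int(r.bin_id)], scol[str(r.species_id)]] = r.weight
        return cls(species_ids=species, bin_ids=bins, weights=w, grid=grid)


def niche_profiles(
    presence: PresenceMatrix, bin_raster: np.ndarray, grid: BinGrid | None = None
) -> NicheProfileSet:
    """Species niche profiles: proportion of occupied cells per climate bin."""
    flat_bins = bin_raster.ravel()
    species = sorted(presence.cells)
    per_species: list[dict[int, float]] = []
    used_bins: set[int] = set()
    for sp in species:
        cc = presence.cells[sp]
        if len(cc) == 0:
            raise DataError(f"species {sp} occupies zero cells; filter upstream")
        bins = flat_bins[cc]
        if np.any(bins < 0):
            raise DataError(f"species {sp} occupies cells with no climate")
        vals, counts = np.unique(bins, return_counts=True)
        prof = {int(b): c / len(cc) for b, c in zip(vals, counts)}
        per_species.append(prof)
        used_bins.update(prof)
    bin_ids = sorted(used_bins)
    brow = {b: i for i, b in enumerate(bin_ids)}
    w = np.zeros((len(bin_ids), len(species)))
    for j, prof in enumerate(per_species):
        for b, p in prof.items():
            w[brow[b], j] = p
    return NicheProfileSet(species_ids=species, bin_ids=bin_ids, weights=w, grid=grid)


def select_divisions(
    presence: PresenceMatrix,
    coarse: CoarseClimate,
    d_candidates: list[int] | None = None,
    n_runs: int = 20,
    seed: int = 0,
    rel_tol: float = 0.02,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of per-axis divisions by the compression-gain elbow.

    For each candidate d the species-bin network is built and clustered;
    the gain is the one-module code length minus the optimized code
    length (bits of compression won by the partition).  The selected d*
    is the largest candidate whose marginal gain over the previous
    candidate is at least ``rel_tol`` of the cumulative gain at that
    candidate — i.e. trailing candidates adding only negligible
    compression are discarded.  Returns (d*, the full gain curve).
    """
    from .domains import detect_domains, one_module_code_length
    from .network import build_network

    if not d_candidates:
        raise ConfigurationError("empty candidate list")
    d_candidates = sorted(d_candidates)
    gains = []
    for i, d in enumerate(d_candidates):
        grid = build_bin_grid(coarse, d)
        bins = assign_bins(coarse, grid)
        profiles = niche_profiles(presence, bins, grid)
        net = build_network(profiles)
        part = detect_domains(
            net, n_runs=n_runs, seed=seed + i, hierarchical=False
        )
        gains.append(one_module_code_length(net) - part.code_length)
    curve = pd.DataFrame({"d": d_candidates, "gain_bits": gains})
    curve["marginal_gain"] = curve.gain_bits.diff()
    d_star = select_from_gain_curve(curve, rel_tol)
    return d_star, curve


def select_from_gain_curve(curve: pd.DataFrame, rel_tol: float = 0.02) -> int:
    """Elbow rule on a (d, gain_bits) curve; see :func:`select_divisions`."""
    if len(curve) == 1:
        return int(curve.d.iloc[0])
    d_star = int(curve.d.iloc[0])
    for i in range(1, len(curve)):
        marginal = curve.gain_bits.iloc[i] - curve.gain_bits.iloc[i - 1]
        if curve.gain_bits.iloc[i] > 0 and marginal >= rel_tol * curve.gain_bits.iloc[i]:
            d_star = int(curve.d.iloc[i])
    return d_star
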