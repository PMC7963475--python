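"""Synthetic climate worlds and species pools with planted niche domains.

This module manufactures the ground truth the rest of the package is
tested against: a masked world grid with two spatially autocorrelated
climate fields (an energy surrogate such as potential evapotranspiration
and a water surrogate such as annual precipitation), and a pool of
species whose occupied cells concentrate around planted climate
archetypes.  Each archetype plays the role of a niche domain: a point in
climate space plus a breadth (niche width, which controls how much
neighbouring archetypes overlap) and a geographic-restriction parameter
rho (which fraction of a species' climatically suitable range it
actually occupies — the lever that creates a geographical signal).

Climate fields are white noise convolved with a Gaussian kernel and
affinely rescaled into the configured value ranges; the energy axis
additionally carries a north-south gradient, mimicking the latitudinal
organisation of real energy input.  Species ranges are sampled without
replacement over coarse cells with probability proportional to a
Gaussian suitability kernel evaluated at each cell's (energy, water).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DataError
from .presence import PresenceMatrix

log = logging.getLogger(__name__)

__all__ = [
    "WorldConfig",
    "ArchetypeSpec",
    "SyntheticWorld",
    "generate_climate_world",
    "generate_species_pool",
    "apply_geographic_restriction",
    "well_separated_archetypes",
    "saturate_presence_by_bins",
]


@dataclass(frozen=True)
class WorldConfig:
    """Geometry and climate statistics of a synthetic world.

    The fine grid emulates a high-resolution climate raster; coarse
    analysis cells are exact ``aggregation_factor``-sized blocks of fine
    pixels, so block aggregation is unambiguous.  Ranges are in nominal
    climate units (defaults roughly follow global annual potential
    evapotranspiration and precipitation, in mm/yr).
    """

    fine_shape: tuple[int, int] = (120, 120)
    aggregation_factor: int = 6
    land_fraction: float = 0.85
    energy_range: tuple[float, float] = (100.0, 1800.0)
    water_range: tuple[float, float] = (0.0, 3000.0)
    autocorr_scale: float = 6.0
    gradient_weight: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        r, c = self.fine_shape
        f = self.aggregation_factor
        if f < 2:
            raise ConfigurationError("aggregation_factor must be >= 2")
        if r % f or c % f:
            raise ConfigurationError(
                f"fine_shape {self.fine_shape} not divisible by factor {f}"
            )
        if not (0.0 < self.land_fraction <= 1.0):
            raise ConfigurationError("land_fraction must be in (0, 1]")
        for lo, hi in (self.energy_range, self.water_range):
            if not hi > lo:
                raise ConfigurationError("climate ranges must have max > min")
        if self.autocorr_scale <= 0:
            raise ConfigurationError("autocorr_scale must be positive")

    @property
    def coarse_shape(self) -> tuple[int, int]:
        f = self.aggregation_factor
        return (self.fine_shape[0] // f, self.fine_shape[1] // f)


@dataclass(frozen=True)
class ArchetypeSpec:
    """A planted niche domain.

    ``center`` is the archetype's climatic optimum (energy, water);
    ``breadth`` the per-axis standard deviation of the Gaussian
    suitability kernel; ``occupancy_rho`` the fraction of each species'
    suitable range it keeps after geographic restriction (1 = no
    restriction); ``range_cells`` the target occupied-cell count per
    species (actual sizes are drawn uniformly within +-50%).
    """

    center: tuple[float, float]
    breadth: tuple[float, float]
    n_species: int
    occupancy_rho: float = 1.0
    range_cells: int = 40

    def __post_init__(self) -> None:
        if min(self.breadth) <= 0:
            raise ConfigurationError("breadth must be positive")
        if self.n_species < 1:
            raise ConfigurationError("n_species must be >= 1")
        if not (0.0 < self.occupancy_rho <= 1.0):
            raise ConfigurationError("occupancy_rho must be in (0, 1]")
        if self.range_cells < 1:
            raise ConfigurationError("range_cells must be >= 1")


@dataclass
class SyntheticWorld:
    """A generated world: climate rasters, land mask, species, truth labels."""

    config: WorldConfig
    energy_fine: np.ndarray
    water_fine: np.ndarray
    land_mask: np.ndarray
    presence: PresenceMatrix | None = None
    planted_labels: dict[str, int] = field(default_factory=dict)


def _smooth_field(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(noise, sigma=scale, mode="reflect")
    lo, hi = sm.min(), sm.max()
    return (sm - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def _rescale(field01: np.ndarray, rng_pair: tuple[float, float]) -> np.ndarray:
    lo, hi = rng_pair
    return lo + field01 * (hi - lo)


def generate_climate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate the climate part of a synthetic world (no species yet).

    Deterministic given ``config.seed``.  Both rasters lie within their
    configured ranges; climate is defined exactly on land pixels (NaN at
    sea).  The land mask is obtained by thresholding an independent
    smoothed field at the land_fraction quantile, which yields one or a
    few contiguous land blocks.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.fine_shape

    if config.land_fraction >= 1.0:
        land = np.ones(shape, dtype=bool)
    else:
        land_field = _smooth_field(rng, shape, config.autocorr_scale * 2.0)
        thr = np.quantile(land_field, 1.0 - config.land_fraction)
        land = land_field >= thr
    if not land.any():
        raise ConfigurationError("land_fraction yields zero land pixels")

    energy01 = _smooth_field(rng, shape, config.autocorr_scale)
    grad = np.linspace(1.0, 0.0, shape[0])[:, None] * np.ones(shape)
    g = config.gradient_weight
    energy01 = g * grad + (1.0 - g) * energy01
    lo, hi = energy01.min(), energy01.max()
    energy01 = (energy01 - lo) / (hi - lo)
    water01 = _smooth_field(rng, shape, config.autocorr_scale)

    energy = _rescale(energy01, config.energy_range)
    water = _rescale(water01, config.water_range)
    energy[~land] = np.nan
    water[~land] = np.nan

    # at least one coarse cell must contain land
    f = config.aggregation_factor
    R, C = config.coarse_shape
    coarse_land = land.reshape(R, f, C, f).any(axis=(1, 3))
    if not coarse_land.any():
        raise ConfigurationError("land_fraction yields zero coarse land cells")

    return SyntheticWorld(
        config=config, energy_fine=energy, water_fine=water, land_mask=land
    )


def _coarse_cell_climate(world: SyntheticWorld):
    """Flat indices of coarse land cells with their mean (energy, water)."""
    f = world.config.aggregation_factor
    R, C = world.config.coarse_shape

    def block_mean(fine):
        filled = np.where(world.land_mask, fine, 0.0)
        sums = filled.reshape(R, f, C, f).sum(axis=(1, 3))
        counts = world.land_mask.reshape(R, f, C, f).sum(axis=(1, 3))
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan), counts

    e_coarse, counts = block_mean(world.energy_fine)
    w_coarse, _ = block_mean(world.water_fine)
    flat = np.flatnonzero(counts.ravel() > 0)
    return flat, e_coarse.ravel()[flat], w_coarse.ravel()[flat]


def generate_species_pool(
    world: SyntheticWorld,
    archetypes: list[ArchetypeSpec],
    min_range_cells: int = 5,
    seed: int = 0,
) -> tuple[PresenceMatrix, dict[str, int]]:
    """Sample species ranges around planted archetypes.

    Each species draws a target range size, then samples that many coarse
    land cells without replacement with probability proportional to its
    archetype's Gaussian suitability at the cell's (energy, water).
    Species that cannot reach ``min_range_cells`` suitable cells are
    dropped with a warning.  Deterministic given ``seed``.
    """
    if not archetypes:
        raise ConfigurationError("at least one archetype required")
    rng = np.random.default_rng(seed)
    cells_flat, e_vals, w_vals = _coarse_cell_climate(world)

    cells: dict[str, np.ndarray] = {}
    labels: dict[str, int] = {}
    for k, arch in enumerate(archetypes):
        (ce, cw), (be, bw) = arch.center, arch.breadth
        logk = -0.5 * (((e_vals - ce) / be) ** 2 + ((w_vals - cw) / bw) ** 2)
        kern = np.exp(logk - logk.max())
        kern[kern < 1e-300] = 0.0
        if not np.isfinite(kern).all() or kern.sum() <= 0:
            raise DataError(f"archetype {k} has zero suitable cells")
        n_suitable = int((kern > 0).sum())
        prob = kern / kern.sum()
        lo = max(min_range_cells, arch.range_cells // 2)
        hi = max(lo, (3 * arch.range_cells) // 2)
        for s in range(arch.n_species):
            name = f"a{k}_s{s:03d}"
            target = int(rng.integers(lo, hi + 1))
            size = min(target, n_suitable)
            if size < min_range_cells:
                warnings.warn(
                    f"species {name}: only {size} suitable cells "
                    f"(< min_range_cells={min_range_cells}); dropped"
                )
                log.warning("dropped species %s (%d suitable cells)", name, size)
                continue
            chosen = rng.choice(cells_flat, size=size, replace=False, p=prob)
            cells[name] = np.sort(chosen.astype(int))
            labels[name] = k

    if not cells:
        raise DataError("no species generated (all below min_range_cells)")

    presence = PresenceMatrix(grid_shape=world.config.coarse_shape, cells=cells)
    _attach_world_fine_values(presence, world)
    world.presence = presence
    world.planted_labels = labels
    return presence, labels


def _attach_world_fine_values(presence: PresenceMatrix, world: SyntheticWorld) -> None:
    from .presence import attach_fine_values

    attach_fine_values(
        presence,
        world.energy_fine,
        world.water_fine,
        world.land_mask,
        world.config.aggregation_factor,
    )


def apply_geographic_restriction(
    presence: PresenceMatrix,
    rho_per_species: float | dict[str, float],
    seed: int = 0,
    min_range_cells: int = 5,
) -> PresenceMatrix:
    """Restrict each species to a geographically compact part of its range.

    For rho < 1 a species keeps the ``round(rho * n)`` occupied cells
    nearest (Euclidean, grid units) to a randomly chosen anchor cell of
    its range — a compact patch of the climatically suitable geography.
    rho = 1 is the identity.  Species falling below ``min_range_cells``
    are dropped with a warning.
    """
    rhos = (
        {sp: float(rho_per_species) for sp in presence.cells}
        if np.isscalar(rho_per_species)
        else dict(rho_per_species)
    )
    for sp, rho in rhos.items():
        if not (0.0 < rho <= 1.0):
            raise ConfigurationError(f"rho for {sp} must be in (0, 1]")
    if all(r == 1.0 for r in rhos.values()):
        return presence

    rng = np.random.default_rng(seed)
    C = presence.grid_shape[1]
    new_cells: dict[str, np.ndarray] = {}
    for sp, cc in presence.cells.items():
        rho = rhos.get(sp, 1.0)
        if rho == 1.0:
            new_cells[sp] = cc
            continue
        n_keep = int(round(rho * len(cc)))
        if n_keep < min_range_cells:
            warnings.warn(
                f"species {sp}: rho={rho} leaves {n_keep} cells "
                f"(< min_range_cells={min_range_cells}); dropped"
            )
            continue
        anchor = int(rng.choice(cc))
        ar, ac = divmod(anchor, C)
        rr, cc_col = np.divmod(cc, C)
        d2 = (rr - ar) ** 2 + (cc_col - ac) ** 2
        order = np.lexsort((cc, d2))
        new_cells[sp] = np.sort(cc[order[:n_keep]])
    if not new_cells:
        raise DataError("no species survive geographic restriction")
    return PresenceMatrix(
        grid_shape=presence.grid_shape,
        cells=new_cells,
        fine_values=presence.fine_values,
    )


def well_separated_archetypes(
    world: SyntheticWorld,
    n_species: int = 60,
    breadth_frac: float = 0.05,
    occupancy_rho: float = 1.0,
    range_cells: int = 40,
) -> list[ArchetypeSpec]:
    """Four archetypes at the corners of the realized climate spread.

    Centers sit at the (0.2, 0.8) per-axis quantile combinations of the
    coarse land-cell climate; breadths are ``breadth_frac`` of each
    axis's realized spread.  At the default breadth the four kernels are
    separated by far more than six standard deviations, which makes the
    planted domains unambiguous.
    """
    _, e_vals, w_vals = _coarse_cell_climate(world)
    e_lo, e_hi = np.quantile(e_vals, [0.2, 0.8])
    w_lo, w_hi = np.quantile(w_vals, [0.2, 0.8])
    be = breadth_frac * (e_vals.max() - e_vals.min())
    bw = breadth_frac * (w_vals.max() - w_vals.min())
    return [
        ArchetypeSpec(
            center=(ce, cw),
            breadth=(be, bw),
            n_species=n_species,
            occupancy_rho=occupancy_rho,
            range_cells=range_cells,
        )
        for ce in (e_lo, e_hi)
        for cw in (w_lo, w_hi)
    ]


def saturate_presence_by_bins(
    presence: PresenceMatrix, bin_raster: np.ndarray
) -> PresenceMatrix:
    """Extend every species to all cells of every climatic bin it touches.

    After saturation each cell's species pool reproduces its bin's
    species pool exactly, so the actual specificity equals the projected
    specificity everywhere and the geographical signal vanishes — the
    zero-signal reference configuration.
    """
    flat_bins = bin_raster.ravel()
    cells_of_bin: dict[int, np.ndarray] = {
        int(b): np.flatnonzero(flat_bins == b)
        for b in np.unique(flat_bins[flat_bins >= 0])
    }
    new_cells = {}
    for sp, cc in presence.cells.items():
        bins = np.unique(flat_bins[cc])
        bins = bins[bins >= 0]
        new_cells[sp] = np.unique(
            np.concatenate([cells_of_bin[int(b)] for b in bins])
        )
    return PresenceMatrix(
        grid_shape=presence.grid_shape,
        cells=new_cells,
        fine_values=presence.fine_values,
    )
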