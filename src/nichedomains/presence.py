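"""Species presence on the coarse analysis grid.

A :class:`PresenceMatrix` records, for each species, the set of occupied
coarse grid cells (range-map semantics: a cell is occupied or not, no
abundance), plus the fine-pixel climate values inside each coarse cell.
The fine values are what the bootstrap resamples: each occupied cell's
climate is the mean of its fine land pixels, and resampling those pixels
with replacement propagates within-cell climate variability into the
species' niche profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class PresenceMatrix:
    """Species x coarse-cell occupancy with per-cell fine climate values.

    ``cells[species]`` holds sorted flat coarse-cell indices;
    ``fine_values[cell]`` is an (n_pixels, 2) array of (energy, water)
    values of the cell's fine land pixels, shared across species.
    """

    grid_shape: tuple[int, int]
    cells: dict[str, np.ndarray]
    fine_values: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def species_ids(self) -> list[str]:
        return list(self.cells)

    @property
    def n_species(self) -> int:
        return len(self.cells)

    def range_size(self, species: str) -> int:
        return len(self.cells[species])

    def occupied_cells(self) -> np.ndarray:
        if not self.cells:
            return np.array([], dtype=int)
        return np.unique(np.concatenate(list(self.cells.values())))

    def cell_species_index(self) -> dict[int, list[str]]:
        """Inverted index: flat cell -> species present there."""
        index: dict[int, list[str]] = {}
        for sp, cc in self.cells.items():
            for c in cc:
                index.setdefault(int(c), []).append(sp)
        return index

    def subset(self, species: list[str]) -> "PresenceMatrix":
        return PresenceMatrix(
            grid_shape=self.grid_shape,
            cells={sp: self.cells[sp] for sp in species},
            fine_values=self.fine_values,
        )

    def to_csv(self, path) -> None:
        rows, cols, sps = [], [], []
        C = self.grid_shape[1]
        for sp, cc in self.cells.items():
            for c in cc:
                sps.append(sp)
                rows.append(int(c) // C)
                cols.append(int(c) % C)
        pd.DataFrame(
            {"species_id": sps, "cell_row": rows, "cell_col": cols}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid_shape: tuple[int, int]) -> "PresenceMatrix":
        df = pd.read_csv(path, dtype={"species_id": str})
        need = {"species_id", "cell_row", "cell_col"}
        if not need.issubset(df.columns):
            raise DataError(f"{path}: expected columns {sorted(need)}")
        R, C = grid_shape
        if ((df.cell_row < 0) | (df.cell_row >= R)).any() or (
            (df.cell_col < 0) | (df.cell_col >= C)
        ).any():
            raise DataError(f"{path}: cell index outside grid {grid_shape}")
        flat = df.cell_row.to_numpy() * C + df.cell_col.to_numpy()
        cells = {
            str(sp): np.unique(flat[df.species_id.to_numpy() == sp])
            for sp in df.species_id.unique()
        }
        return cls(grid_shape=grid_shape, cells=cells)


def attach_fine_values(
    presence: PresenceMatrix,
    energy_fine: np.ndarray,
    water_fine: np.ndarray,
    land_mask: np.ndarray,
    factor: int,
) -> PresenceMatrix:
    """Populate ``fine_values`` for every occupied cell from fine rasters."""
    R, C = presence.grid_shape
    if energy_fine.shape != (R * factor, C * factor):
        raise DataError(
            f"fine raster shape {energy_fine.shape} incompatible with "
            f"coarse grid {presence.grid_shape} at factor {factor}"
        )
    for c in presence.occupied_cells():
        r, col = divmod(int(c), C)
        sl = (slice(r * factor, (r + 1) * factor), slice(col * factor, (col + 1) * factor))
        m = land_mask[sl]
        if not m.any():
            raise DataError(f"occupied cell {int(c)} has no fine land pixels")
        presence.fine_values[int(c)] = np.column_stack(
            [energy_fine[sl][m], water_fine[sl][m]]
        )
    return presence
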