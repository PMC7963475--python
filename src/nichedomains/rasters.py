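"""Plain-text raster I/O (ESRI ASCII grid).

All gridded artifacts (climate fields, bin assignments, region maps,
specificity surfaces) are exchanged as single-band ESRI ASCII grids: a
six-line header followed by whitespace-separated rows, top row first.
NaN cells are written as the declared NODATA value.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError

_NODATA = -9999.0


def write_ascii_grid(path, array: np.ndarray, cellsize: float = 1.0) -> None:
    arr = np.asarray(array, dtype=float)
    if arr.ndim != 2:
        raise ValueError("raster must be two-dimensional")
    out = np.where(np.isnan(arr), _NODATA, arr)
    with open(path, "w") as fh:
        fh.write(f"ncols {arr.shape[1]}\n")
        fh.write(f"nrows {arr.shape[0]}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cellsize!r}\n")
        fh.write(f"NODATA_value {_NODATA!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> np.ndarray:
    """Read an ASCII grid; NODATA cells come back as NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(header) < 6 and not _is_number(parts[0]):
                if len(parts) != 2:
                    raise DataError(f"{path}:{lineno}: malformed header line")
                header[parts[0].lower()] = float(parts[1])
            else:
                try:
                    rows.append([float(v) for v in parts])
                except ValueError as exc:
                    raise DataError(f"{path}:{lineno}: {exc}") from None
    for key in ("ncols", "nrows", "nodata_value"):
        if key not in header:
            raise DataError(f"{path}: missing header field {key}")
    arr = np.array(rows, dtype=float)
    expect = (int(header["nrows"]), int(header["ncols"]))
    if arr.shape != expect:
        raise DataError(f"{path}: data shape {arr.shape} != header {expect}")
    arr[arr == header["nodata_value"]] = np.nan
    return arr


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
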