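"""The 16-cell area-of-interest (AOI) grid over normalized gaze coordinates.

Gaze direction is expressed as a coordinate pair (x, y), each in [-1, 1],
relative to the phone camera: x runs from -1 (leftward gaze) to +1
(rightward), y from -1 (downward) to +1 (upward), and (0, 0) is gaze
straight into the camera.  The square is partitioned into a 4x4 grid of
equal cells.  A cell is named by its row letter then column letter, each in
A..D: row A is the top band (y near +1), column A the left band (x near -1).
Labels are ordered alphabetically and encoded as integers AA=0 ... DD=15.

Boundary convention: cells are half-open, closed at the top/left edge, and
the outer boundary of the square is closed, so every point of [-1,1]^2 maps
to exactly one cell.
"""

from __future__ import annotations

import numpy as np

#: Grid side length (4 rows x 4 columns = 16 AOIs).
GRID_SIZE = 4

_ROW_LETTERS = "ABCD"
_COL_LETTERS = "ABCD"

#: All 16 AOI labels in alphabetical order: AA, AB, ..., DD.
AOI_LABELS: tuple[str, ...] = tuple(
    r + c for r in _ROW_LETTERS for c in _COL_LETTERS
)

#: Number of AOIs.
N_AOI = len(AOI_LABELS)

#: Alphabetical integer code of each label (AA=0 ... DD=15).
AOI_CODES: dict[str, int] = {lab: i for i, lab in enumerate(AOI_LABELS)}

#: Width of one cell in normalized coordinates.
CELL_SIZE = 2.0 / GRID_SIZE


def label_to_code(label: str) -> int:
    """Return the alphabetical integer code of an AOI label (AA=0 ... DD=15)."""
    try:
        return AOI_CODES[label]
    except KeyError:
        raise ValueError(f"unknown AOI label: {label!r}") from None


def code_to_label(code: int) -> str:
    """Return the AOI label for an integer code in 0..15."""
    if not 0 <= int(code) < N_AOI:
        raise ValueError(f"AOI code out of range 0..15: {code}")
    return AOI_LABELS[int(code)]


def _check_range(x: np.ndarray, y: np.ndarray) -> None:
    if np.any((x < -1.0) | (x > 1.0)) or np.any((y < -1.0) | (y > 1.0)):
        raise ValueError("gaze coordinates must lie in [-1, 1]")


def assign_aoi_codes(x, y) -> np.ndarray:
    """Vectorized AOI assignment: coordinates -> integer codes (AA=0..DD=15).

    Column index = min(floor((x+1)/0.5), 3), left to right; row index =
    min(floor((1-y)/0.5), 3), top to bottom (row A is upward gaze).  The
    clip closes the outer boundary so x=1 / y=-1 fall in column/row D.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_range(x, y)
    col = np.minimum(np.floor((x + 1.0) / CELL_SIZE).astype(int), GRID_SIZE - 1)
    row = np.minimum(np.floor((1.0 - y) / CELL_SIZE).astype(int), GRID_SIZE - 1)
    return row * GRID_SIZE + col


def assign_aoi(x: float, y: float) -> str:
    """Map a single gaze coordinate pair in [-1,1]^2 to its AOI label."""
    code = assign_aoi_codes(np.asarray([x]), np.asarray([y]))[0]
    return AOI_LABELS[code]


def cell_bounds(label_or_code) -> tuple[float, float, float, float]:
    """Return (x_min, x_max, y_min, y_max) of an AOI cell.

    Bounds are the closed rectangle of the cell; interior points of the
    rectangle always map back to this AOI under :func:`assign_aoi`.
    """
    code = (
        label_to_code(label_or_code)
        if isinstance(label_or_code, str)
        else int(label_or_code)
    )
    if not 0 <= code < N_AOI:
        raise ValueError(f"AOI code out of range 0..15: {code}")
    row, col = divmod(code, GRID_SIZE)
    x_min = -1.0 + col * CELL_SIZE
    y_max = 1.0 - row * CELL_SIZE
    return x_min, x_min + CELL_SIZE, y_max - CELL_SIZE, y_max


#: The four central AOIs closest to the camera (gaze near (0, 0)).
CENTRAL_AOIS = ("BB", "BC", "CB", "CC")
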