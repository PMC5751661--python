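"""Freeman chain-code boundary tracing for binary lesion masks.

Coordinates are 0-based ``(row, col)`` with the row index increasing
downward, as in any raster image.  The eight Freeman directions are numbered
counter-clockwise in conventional x/y axes (x = col, y = -row):

    code   0     1     2     3     4     5     6     7
    move   E    NE     N    NW     W    SW     S    SE
    (dr,dc) (0,+1) (-1,+1) (-1,0) (-1,-1) (0,-1) (+1,-1) (+1,0) (+1,+1)

Because the row axis points down, a contour that is counter-clockwise in
x/y axes appears clockwise on screen.

The tracer is Moore-neighbor boundary following with Jacob's stopping
criterion, started from the scan-order-minimal (topmost, then leftmost)
foreground pixel.  Masks are expected to hold a single 8-connected,
hole-free foreground component; :func:`preprocess_mask` enforces that.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "FREEMAN_OFFSETS",
    "ChainContour",
    "EmptyMaskError",
    "DegenerateContourError",
    "as_binary",
    "preprocess_mask",
    "find_start_pixel",
    "trace_chain_code",
    "reconstruct_from_codes",
]

#: (drow, dcol) displacement for each Freeman code 0..7.
FREEMAN_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)

_OFFSET_TO_CODE = {off: code for code, off in enumerate(FREEMAN_OFFSETS)}

#: 8-connectivity structuring element.
_STRUCT8 = np.ones((3, 3), dtype=bool)


class EmptyMaskError(ValueError):
    """Raised when a mask contains no foreground pixel."""


class DegenerateContourError(ValueError):
    """Raised when the traced component is a single pixel."""


@dataclass
class ChainContour:
    """A closed lesion boundary as a Freeman chain code.

    Attributes
    ----------
    start
        ``(row, col)`` of the first boundary pixel (scan-order minimal).
    codes
        Freeman direction codes of the successive moves; applying them from
        ``start`` returns to ``start``.
    points
        The boundary pixels implied by ``start`` + ``codes``; the closing
        ``start`` pixel is repeated as the last element.
    """

    start: tuple[int, int]
    codes: list[int]
    points: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if any(not (0 <= c <= 7) for c in self.codes):
            raise ValueError("Freeman codes must lie in 0..7")
        if self.points and reconstruct_from_codes(self.start, self.codes) != self.points:
            raise ValueError("points do not match start + codes")

    def __len__(self) -> int:
        return len(self.codes)

    def point_array(self, closed: bool = True) -> np.ndarray:
        pts = self.points if closed else self.points[:-1]
        return np.asarray(pts, dtype=float)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"start": list(self.start), "codes": [int(c) for c in self.codes]}
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "ChainContour":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        obj = json.loads(text)
        start = tuple(int(v) for v in obj["start"])
        codes = [int(c) for c in obj["codes"]]
        return cls(start=start, codes=codes, points=reconstruct_from_codes(start, codes))


def as_binary(mask: np.ndarray) -> np.ndarray:
    """Validate and convert a mask to a uint8 array of {0, 1}."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask values must be exactly 0 or 1")
    return arr.astype(np.uint8)


def preprocess_mask(mask: np.ndarray) -> np.ndarray:
    """Keep the largest 8-connected foreground component and fill its holes.

    The contraction stage assumes a single simply-connected lesion, so this
    is run before tracing unless explicitly disabled.
    """
    arr = as_binary(mask)
    labels, n = ndimage.label(arr, structure=_STRUCT8)
    if n == 0:
        raise EmptyMaskError("no foreground pixels in mask")
    if n > 1:
        sizes = ndimage.sum_labels(arr, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        arr = (labels == keep).astype(np.uint8)
    return ndimage.binary_fill_holes(arr).astype(np.uint8)


def find_start_pixel(mask: np.ndarray) -> tuple[int, int]:
    """Scan-order-minimal foreground pixel (topmost row, then leftmost col)."""
    arr = as_binary(mask)
    rows, cols = np.nonzero(arr)
    if rows.size == 0:
        raise EmptyMaskError("no foreground pixels in mask")
    i = np.lexsort((cols, rows))[0]
    return int(rows[i]), int(cols[i])


def _foreground(arr: np.ndarray, r: int, c: int) -> bool:
    h, w = arr.shape
    return 0 <= r < h and 0 <= c < w and bool(arr[r, c])


def trace_chain_code(mask: np.ndarray, preprocess: bool = True) -> ChainContour:
    """Trace the outer boundary of the lesion as a Freeman chain code.

    Parameters
    ----------
    mask
        Binary lesion mask.
    preprocess
        When True (default) the mask is reduced to its largest hole-free
        component first.  When False and several components exist, the one
        containing the scan-order start pixel is traced and a warning is
        emitted.
    """
    arr = preprocess_mask(mask) if preprocess else as_binary(mask)
    if not preprocess:
        _, n = ndimage.label(arr, structure=_STRUCT8)
        if n == 0:
            raise EmptyMaskError("no foreground pixels in mask")
        if n > 1:
            warnings.warn(
                "mask has multiple components; tracing the one containing the "
                "start pixel",
                stacklevel=2,
            )
    start = find_start_pixel(arr)

    has_neighbor = any(
        _foreground(arr, start[0] + dr, start[1] + dc) for dr, dc in FREEMAN_OFFSETS
    )
    if not has_neighbor:
        raise DegenerateContourError("single-pixel component has no contour")

    # Moore-neighbor following.  State = (current pixel, direction from the
    # current pixel to its backtrack/background neighbor).  The start pixel is
    # topmost-leftmost, so its west neighbor is guaranteed background.
    b_dir0 = 4  # west
    cur, b_dir = start, b_dir0
    points = [start]
    codes: list[int] = []
    # Jacob's criterion: stop on revisiting the start pixel with an already
    # seen backtrack direction (the walk state has recurred, so the boundary
    # cycle is closed).  The artificial initial state can be transient, in
    # which case the pre-cycle prefix is trimmed.
    start_visits: dict[int, int] = {b_dir0: 0}
    max_steps = 8 * int(arr.sum()) + 16  # safety bound; never hit in practice
    for _ in range(max_steps):
        move = None
        for k in range(1, 9):
            # Scan the Moore neighborhood clockwise on screen, starting just
            # past the backtrack neighbor (decreasing Freeman code).
            d = (b_dir - k) % 8
            dr, dc = FREEMAN_OFFSETS[d]
            if _foreground(arr, cur[0] + dr, cur[1] + dc):
                move = (d, k)
                break
        assert move is not None  # has_neighbor guarantees one
        d, k = move
        prev_bg_dir = (b_dir - (k - 1)) % 8  # last background neighbor scanned
        bg_pixel = (cur[0] + FREEMAN_OFFSETS[prev_bg_dir][0],
                    cur[1] + FREEMAN_OFFSETS[prev_bg_dir][1])
        nxt = (cur[0] + FREEMAN_OFFSETS[d][0], cur[1] + FREEMAN_OFFSETS[d][1])
        if d % 2 == 1:
            # A diagonal move cuts an inner corner.  The neighbor scanned just
            # before d (at (d+1) mod 8) is background; if the other flanking
            # 4-neighbor is foreground it is a boundary pixel (its background
            # contact is diagonal) that the walk would otherwise skip — route
            # through it with two 4-connected moves.
            flank_dir = (d - 1) % 8
            flank = (
                cur[0] + FREEMAN_OFFSETS[flank_dir][0],
                cur[1] + FREEMAN_OFFSETS[flank_dir][1],
            )
            if _foreground(arr, *flank):
                codes.append(flank_dir)
                points.append(flank)
                codes.append(_OFFSET_TO_CODE[(nxt[0] - flank[0], nxt[1] - flank[1])])
                points.append(nxt)
            else:
                codes.append(d)
                points.append(nxt)
        else:
            codes.append(d)
            points.append(nxt)
        # Direction from the new pixel back to the last background neighbor
        # (always an 8-neighbor of the new pixel).
        b_dir = _OFFSET_TO_CODE[(bg_pixel[0] - nxt[0], bg_pixel[1] - nxt[1])]
        cur = nxt
        if cur == start:
            if b_dir in start_visits:
                i = start_visits[b_dir]
                points, codes = points[i:], codes[i:]
                break
            start_visits[b_dir] = len(points) - 1
    else:  # pragma: no cover - defensive
        raise RuntimeError("boundary tracing did not terminate")
    return ChainContour(start=start, codes=codes, points=points)


def reconstruct_from_codes(
    start: tuple[int, int], codes
) -> list[tuple[int, int]]:
    """Apply Freeman *codes* cumulatively from *start*.

    Returns ``len(codes) + 1`` points; if the codes close the walk, the first
    and last point coincide.
    """
    r, c = int(start[0]), int(start[1])
    points = [(r, c)]
    for code in codes:
        code = int(code)
        if not 0 <= code <= 7:
            raise ValueError(f"Freeman code out of range: {code}")
        dr, dc = FREEMAN_OFFSETS[code]
        r, c = r + dr, c + dc
        points.append((r, c))
    return points
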