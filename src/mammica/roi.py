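"""Region-of-interest extraction from chain-coded ground-truth boundaries.

Ground-truth abnormality outlines arrive as *chain codes*: a start pixel plus a
sequence of 8-connected direction digits tracing a closed freehand curve.  Each
outline is turned into the smallest square patch that contains it; outlines too
close to the image border to admit a centred square are discarded.  Normal
tissue patches are sampled uniformly at random from mass-free images, with
sides drawn from the size range observed for masses.  All patches are brought
to a common side (32 or 64 px) by bilinear interpolation before feature
extraction.

Direction convention (row, col), row increasing downward, 0-based::

    7 0 1
    6 . 2       0=N, 1=NE, 2=E, 3=SE, 4=S, 5=SW, 6=W, 7=NW
    5 4 3
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS",
    "ChainCodeRegion",
    "BoundingSquare",
    "ROIPatch",
    "Overlay",
    "OverlayError",
    "trace",
    "parse_overlay",
    "write_overlay",
    "smallest_square",
    "extract_roi",
    "sample_normal_rois",
    "resize_bilinear",
]

#: unit steps (drow, dcol) for chain-code digits 0-7
DIRECTIONS: dict[int, tuple[int, int]] = {
    0: (-1, 0),
    1: (-1, 1),
    2: (0, 1),
    3: (1, 1),
    4: (1, 0),
    5: (1, -1),
    6: (0, -1),
    7: (-1, -1),
}

MASS_LABELS = ("benign", "malignant")


class OverlayError(ValueError):
    """Malformed overlay file or chain-code region."""


@dataclass(frozen=True)
class ChainCodeRegion:
    """Closed freehand boundary: start pixel plus 8-connected direction codes."""

    start: tuple[int, int]
    codes: tuple[int, ...]
    label: str = "malignant"

    def __post_init__(self) -> None:
        if self.label not in MASS_LABELS:
            raise OverlayError(f"unknown region label {self.label!r}")
        if any(c < 0 or c > 7 for c in self.codes):
            raise OverlayError("chain codes must be digits 0-7")


@dataclass(frozen=True)
class BoundingSquare:
    """Axis-aligned square patch location: top-left corner and side length."""

    top: int
    left: int
    side: int


@dataclass
class ROIPatch:
    """Square grayscale patch with class label and breast-density grade."""

    pixels: np.ndarray
    label: str  # malignant | benign | normal
    density: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("ROI patch must be a square 2-D array")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    @property
    def is_mass(self) -> bool:
        return self.label in MASS_LABELS


@dataclass
class Overlay:
    """Parsed overlay file: host image dimensions plus its regions."""

    image_shape: tuple[int, int]
    regions: list[ChainCodeRegion] = field(default_factory=list)


def trace(
    region: ChainCodeRegion, image_shape: tuple[int, int] | None = None
) -> list[tuple[int, int]]:
    """Walk the chain code and return the ordered boundary pixels.

    The returned list has one pixel per code, starting at ``region.start``;
    the final step must land back on the start (closed curve).

    Raises
    ------
    OverlayError
        If the curve is open, has fewer than 2 steps, or leaves
        ``image_shape`` bounds.
    """
    if len(region.codes) < 2:
        raise OverlayError("open curve: need at least 2 chain codes to close")
    r, c = region.start
    pixels = [(r, c)]
    for k, code in enumerate(region.codes):
        dr, dc = DIRECTIONS[code]
        r, c = r + dr, c + dc
        if image_shape is not None:
            h, w = image_shape
            if not (0 <= r < h and 0 <= c < w):
                raise OverlayError(
                    f"chain code step {k} leaves image bounds at ({r}, {c})"
                )
        pixels.append((r, c))
    if pixels[-1] != region.start:
        raise OverlayError(
            f"open curve: path ends at {pixels[-1]}, started at {region.start}"
        )
    return pixels[:-1]  # closed loop; drop the repeated start


def write_overlay(overlay: Overlay) -> str:
    """Serialize an overlay to its text dialect (inverse of parse_overlay)."""
    h, w = overlay.image_shape
    lines = [f"IMAGE {h} {w}"]
    for reg in overlay.regions:
        lines.append(f"REGION {reg.label}")
        lines.append(f"START {reg.start[0]} {reg.start[1]}")
        lines.append("CODES " + " ".join(str(c) for c in reg.codes))
        lines.append("END")
    return "\n".join(lines) + "\n"


def parse_overlay(source: str | Path | io.TextIOBase) -> Overlay:
    """Parse an overlay text file into its chain-code regions.

    Dialect: line 1 ``IMAGE <H> <W>``; then per region the four lines
    ``REGION <label>``, ``START <row> <col>``, ``CODES <digits 0-7>``, ``END``.
    Every region is validated: codes are digits, the curve closes, and the
    traced path stays inside the declared image dimensions.  Errors name the
    offending line.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    elif isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith((".txt", ".overlay"))):
        text = Path(source).read_text()
    else:
        text = str(source)

    lines = text.splitlines()
    if not lines or not lines[0].startswith("IMAGE"):
        raise OverlayError("line 1: expected 'IMAGE <H> <W>' header")
    try:
        _, hs, ws = lines[0].split()
        shape = (int(hs), int(ws))
    except ValueError as exc:
        raise OverlayError(f"line 1: malformed IMAGE header {lines[0]!r}") from exc

    overlay = Overlay(image_shape=shape)
    i = 1
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("REGION"):
            raise OverlayError(f"line {i + 1}: expected 'REGION <label>', got {line!r}")
        label = line.split(maxsplit=1)[1].strip() if " " in line else ""
        if label not in MASS_LABELS:
            raise OverlayError(f"line {i + 1}: unknown region label {label!r}")
        try:
            start_line = lines[i + 1].split()
            codes_line = lines[i + 2].split()
            end_line = lines[i + 3].strip()
        except IndexError as exc:
            raise OverlayError(f"line {i + 1}: truncated region block") from exc
        if start_line[0] != "START" or len(start_line) != 3:
            raise OverlayError(f"line {i + 2}: expected 'START <row> <col>'")
        start = (int(start_line[1]), int(start_line[2]))
        h, w = shape
        if not (0 <= start[0] < h and 0 <= start[1] < w):
            raise OverlayError(
                f"line {i + 2}: start {start} outside declared image {shape}"
            )
        if codes_line[0] != "CODES":
            raise OverlayError(f"line {i + 3}: expected 'CODES <digits>'")
        try:
            codes = tuple(int(tok) for tok in codes_line[1:])
        except ValueError as exc:
            raise OverlayError(f"line {i + 3}: non-integer chain code") from exc
        if any(c < 0 or c > 7 for c in codes):
            raise OverlayError(f"line {i + 3}: chain codes must be digits 0-7")
        if end_line != "END":
            raise OverlayError(f"line {i + 4}: expected 'END'")
        region = ChainCodeRegion(start=start, codes=codes, label=label)
        try:
            trace(region, image_shape=shape)  # validates closure and bounds
        except OverlayError as exc:
            raise OverlayError(f"line {i + 1}: {exc}") from exc
        overlay.regions.append(region)
        i += 4
    return overlay


def smallest_square(
    region: ChainCodeRegion, image_shape: tuple[int, int]
) -> BoundingSquare | None:
    """Smallest enclosing square for a traced boundary, or None if discarded.

    The square side equals the larger extent of the boundary's axis-aligned
    bounding box.  Along the longer axis the square coincides with the box;
    along the shorter axis it is centred on the box centre (integer rounding
    pads one pixel less on the low side when the padding is odd).  If the
    centred square does not fit inside the image it is *discarded* — the patch
    is never shifted or cropped to rescue it.
    """
    pixels = trace(region, image_shape=image_shape)
    rows = [p[0] for p in pixels]
    cols = [p[1] for p in pixels]
    rmin, rmax = min(rows), max(rows)
    cmin, cmax = min(cols), max(cols)
    h_ext = rmax - rmin + 1
    w_ext = cmax - cmin + 1
    side = max(h_ext, w_ext)
    top = rmin - (side - h_ext) // 2
    left = cmin - (side - w_ext) // 2
    H, W = image_shape
    if top < 0 or left < 0 or top + side > H or left + side > W:
        return None
    return BoundingSquare(top=top, left=left, side=side)


def extract_roi(
    image: np.ndarray,
    region: ChainCodeRegion,
    density: int,
    source_id: str = "",
) -> ROIPatch | None:
    """Cut the smallest-square patch for a region; None if discarded."""
    sq = smallest_square(region, image.shape)
    if sq is None:
        return None
    patch = image[sq.top : sq.top + sq.side, sq.left : sq.left + sq.side]
    return ROIPatch(
        pixels=np.array(patch, dtype=float),
        label=region.label,
        density=density,
        source_id=source_id,
    )


def sample_normal_rois(
    image: np.ndarray,
    n: int,
    size_range: tuple[int, int],
    rng: np.random.Generator,
    density: int = 1,
    source_id: str = "",
    min_mean: float = 0.05,
    max_attempts: int = 100,
) -> list[ROIPatch]:
    """Sample ``n`` random square normal-tissue patches from one image.

    Sides are uniform integers on ``size_range`` (inclusive) and positions
    uniform over valid placements.  Patches whose mean intensity falls below
    ``min_mean`` (empty background) are redrawn, up to ``max_attempts`` times
    each; the last draw is kept if all attempts fail.
    """
    H, W = image.shape
    lo, hi = size_range
    if lo < 2 or hi < lo:
        raise ValueError(f"invalid size range {size_range}")
    if hi > min(H, W):
        raise ValueError(f"max patch size {hi} exceeds image {image.shape}")
    patches: list[ROIPatch] = []
    for k in range(n):
        for _ in range(max_attempts):
            side = int(rng.integers(lo, hi + 1))
            top = int(rng.integers(0, H - side + 1))
            left = int(rng.integers(0, W - side + 1))
            pix = image[top : top + side, left : left + side]
            if pix.mean() >= min_mean:
                break
        patches.append(
            ROIPatch(
                pixels=np.array(pix, dtype=float),
                label="normal",
                density=density,
                source_id=f"{source_id}:n{k}" if source_id else f"n{k}",
            )
        )
    return patches


def resize_bilinear(
    patch: ROIPatch | np.ndarray, target_side: int, allow_any_side: bool = False
) -> ROIPatch | np.ndarray:
    """Resize a square patch to ``target_side`` with bilinear interpolation.

    Uses a corner-aligned sampling grid (source corners map to target
    corners), so interpolated values stay inside the source intensity range
    and resizing to the same side is the identity.  ``target_side`` is
    restricted to the study sizes {32, 64} unless ``allow_any_side``.
    """
    if target_side not in (32, 64) and not allow_any_side:
        raise ValueError("target side must be 32 or 64 (set allow_any_side to override)")
    arr = patch.pixels if isinstance(patch, ROIPatch) else np.asarray(patch, dtype=float)
    s = arr.shape[0]
    if s < 2:
        raise ValueError("source patch must be at least 2x2")
    if s == target_side:
        out = np.array(arr, dtype=float)
    else:
        # corner-aligned grid: target index i samples source coord i*(s-1)/(t-1)
        coords = np.linspace(0.0, s - 1.0, target_side)
        rr, cc = np.meshgrid(coords, coords, indexing="ij")
        out = ndimage.map_coordinates(
            arr, [rr.ravel(), cc.ravel()], order=1, mode="nearest"
        ).reshape(target_side, target_side)
    if isinstance(patch, ROIPatch):
        return ROIPatch(
            pixels=out, label=patch.label, density=patch.density, source_id=patch.source_id
        )
    return out
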