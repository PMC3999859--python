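"""Camera-based liquid-level sensing.

A buoyant green float rides on the liquid surface of the reservoir; a camera
frames the vessel and the level is read off the float position.  The
detection pipeline is deliberately simple enough to run on a very small
computer:

1. split the frame into red/green/blue channels and form the *green excess*
   ``max(G - R, 0)`` per pixel (green objects light up; white, grey, red and
   blue content cancels);
2. threshold the green-excess image to black and white;
3. label connected components and take the largest white region;
4. report the region centroid's height from the bottom of the image, and map
   it to a volume through a monotone pixel-height -> mL calibration table.

A synthetic scene generator renders vessel + float + optional clutter frames
with known ground truth, so the pipeline is testable without any camera.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from PIL import Image
from skimage import measure


class VisionError(Exception):
    pass


#: Defaults for the pipeline (the threshold is a convention of this
#: implementation; the minimum area rejects isolated noise specks).
DEFAULT_THRESHOLD = 60
DEFAULT_CONNECTIVITY = 8
DEFAULT_MIN_AREA = 20


@dataclass(frozen=True)
class FloatObservation:
    """Result of one level measurement."""

    found: bool
    centroid_row: int | None = None
    centroid_col: int | None = None
    height_from_bottom: int | None = None
    area: int | None = None
    volume_ml: float | None = None

    def to_dict(self) -> dict:
        return {
            "found": self.found,
            "centroid_row": self.centroid_row,
            "centroid_col": self.centroid_col,
            "height_from_bottom": self.height_from_bottom,
            "area": self.area,
            "volume_ml": self.volume_ml,
        }


class LevelCalibration:
    """Monotone (pixel height, volume mL) table for a vessel.

    Needs at least two points, strictly increasing in both coordinates
    (a pear-shaped flask makes the mapping nonlinear -- more points, better
    fit).  Lookup is piecewise-linear, clamped at the table ends.
    """

    def __init__(self, points: Sequence[tuple[float, float]]):
        if len(points) < 2:
            raise VisionError("calibration needs at least two points")
        hs = [p[0] for p in points]
        vs = [p[1] for p in points]
        if any(b <= a for a, b in zip(hs, hs[1:])) or any(
            b <= a for a, b in zip(vs, vs[1:])
        ):
            raise VisionError("calibration must be strictly increasing")
        self.heights = np.asarray(hs, dtype=float)
        self.volumes = np.asarray(vs, dtype=float)

    def volume(self, height_px: float) -> float:
        return float(np.interp(height_px, self.heights, self.volumes))

    @classmethod
    def from_csv(cls, path: str) -> "LevelCalibration":
        """Load a two-column CSV: height_px, volume_mL (header optional)."""
        rows: list[tuple[float, float]] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.strip().split(",")
                if len(parts) < 2:
                    continue
                try:
                    rows.append((float(parts[0]), float(parts[1])))
                except ValueError:
                    continue  # header
        return cls(rows)


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def _check_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise VisionError("frame must be an (H, W, 3) RGB array")
    if frame.shape[0] < 1 or frame.shape[1] < 1:
        raise VisionError("frame must be at least 1x1")
    return frame


def green_excess(frame: np.ndarray) -> np.ndarray:
    """Per-pixel ``max(G - R, 0)`` as a uint8 grid."""
    frame = _check_frame(frame)
    g = frame[:, :, 1].astype(np.int16)
    r = frame[:, :, 0].astype(np.int16)
    return np.clip(g - r, 0, 255).astype(np.uint8)


def binarize(grid: np.ndarray, threshold: int = DEFAULT_THRESHOLD) -> np.ndarray:
    """White where ``value > threshold`` (strict), else black."""
    if not 0 <= threshold <= 255:
        raise VisionError("threshold must be in [0, 255]")
    return np.asarray(grid) > threshold


@dataclass(frozen=True)
class Region:
    area: int
    centroid_row: int
    centroid_col: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def largest_region(
    binary: np.ndarray,
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_area: int = DEFAULT_MIN_AREA,
) -> Region | None:
    """Largest connected white region, or ``None`` if there is none.

    Area ties are broken by topmost- then leftmost-centroid.  Regions below
    ``min_area`` pixels are ignored as noise.  Centroids are arithmetic means
    of member pixel coordinates, rounded half-up.
    """
    if connectivity not in (4, 8):
        raise VisionError("connectivity must be 4 or 8")
    labels = measure.label(np.asarray(binary, dtype=bool), connectivity=1 if connectivity == 4 else 2)
    if labels.max() == 0:
        return None
    best: tuple[float, float, float] | None = None  # (-area, crow, ccol)
    best_region: Region | None = None
    for prop in measure.regionprops(labels):
        if prop.area < min_area:
            continue
        crow, ccol = prop.centroid
        key = (-float(prop.area), crow, ccol)
        if best is None or key < best:
            best = key
            best_region = Region(
                area=int(prop.area),
                centroid_row=_round_half_up(crow),
                centroid_col=_round_half_up(ccol),
            )
    return best_region


def measure_level(
    frame: np.ndarray,
    threshold: int = DEFAULT_THRESHOLD,
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_area: int = DEFAULT_MIN_AREA,
    calibration: LevelCalibration | None = None,
) -> FloatObservation:
    """Full pipeline: green excess -> threshold -> largest region -> height.

    ``height_from_bottom`` is ``H - centroid_row`` in pixels; with a
    calibration the corresponding volume in mL is attached.
    """
    frame = _check_frame(frame)
    region = largest_region(binarize(green_excess(frame), threshold), connectivity, min_area)
    if region is None:
        return FloatObservation(found=False)
    height = frame.shape[0] - region.centroid_row
    volume = calibration.volume(height) if calibration is not None else None
    return FloatObservation(
        found=True,
        centroid_row=region.centroid_row,
        centroid_col=region.centroid_col,
        height_from_bottom=height,
        area=region.area,
        volume_ml=volume,
    )


# ---------------------------------------------------------------------------
# Synthetic scene generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneTruth:
    """Ground truth emitted with each synthetic frame."""

    centroid_row: int
    centroid_col: int
    height_from_bottom: int
    float_radius: int


def synth_frame(
    level: float,
    height: int = 120,
    width: int = 80,
    float_color: tuple[int, int, int] = (20, 200, 40),
    float_radius: tuple[int, int] = (5, 8),
    clutter: int = 0,
    noise: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, SceneTruth]:
    """Render a vessel scene with a green float riding at ``level``.

    ``level`` in [0, 1] places the float's centre between the vessel bottom
    (0) and top (1).  ``clutter`` adds that many red/blue rectangles;
    ``noise`` is the fraction of pixels flipped to white salt.  The same seed
    always yields byte-identical frames.  Returns the frame and its
    :class:`SceneTruth`.
    """
    if not 0.0 <= level <= 1.0:
        raise VisionError("level must be in [0, 1]")
    rng = np.random.default_rng(seed)
    frame = np.full((height, width, 3), (170, 170, 175), dtype=np.uint8)  # grey bench

    # vessel interior: dark glass over a slightly lighter liquid fill
    top, bottom = 10, height - 11
    left, right = width // 4, width - width // 4
    frame[top : bottom + 1, left : right + 1] = (120, 120, 130)
    ry, rx = float_radius
    row = int(round(bottom - level * (bottom - top)))
    row = min(max(row, top + ry), bottom - ry) if bottom - ry >= top + ry else row
    liquid_top = min(row + ry, bottom)
    frame[liquid_top : bottom + 1, left : right + 1] = (90, 95, 140)  # liquid

    # clutter first, so the float wins any overlap
    for _ in range(clutter):
        ch, cw = int(rng.integers(4, 14)), int(rng.integers(4, 14))
        r0 = int(rng.integers(0, height - ch))
        c0 = int(rng.integers(0, width - cw))
        color = (200, 30, 30) if rng.random() < 0.5 else (30, 40, 210)
        frame[r0 : r0 + ch, c0 : c0 + cw] = color

    # green float ellipse at the level
    col = (left + right) // 2
    yy, xx = np.mgrid[0:height, 0:width]
    mask = ((yy - row) / ry) ** 2 + ((xx - col) / rx) ** 2 <= 1.0
    frame[mask] = float_color

    if noise > 0:
        salt = rng.random((height, width)) < noise
        frame[salt] = (255, 255, 255)
        frame[mask & salt] = float_color  # float stays visible

    rows, cols = np.nonzero(mask)
    truth = SceneTruth(
        centroid_row=_round_half_up(float(rows.mean())),
        centroid_col=_round_half_up(float(cols.mean())),
        height_from_bottom=height - _round_half_up(float(rows.mean())),
        float_radius=max(ry, rx),
    )
    return frame, truth


# ---------------------------------------------------------------------------
# Frame I/O
# ---------------------------------------------------------------------------

def read_frame(path: str) -> np.ndarray:
    """Load a PNG or PPM frame as an (H, W, 3) uint8 array."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def write_frame(path: str, frame: np.ndarray) -> None:
    """Write a frame as PNG or binary PPM (P6), chosen by extension."""
    frame = _check_frame(frame).astype(np.uint8)
    img = Image.fromarray(frame, mode="RGB")
    img.save(path)
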