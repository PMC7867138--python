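"""Video frames and the ground line.

Image coordinates follow the raster convention: origin top-left, rows
increase downward, columns increase rightward.  Sub-pixel positions are
real-valued ``(column, row)`` pairs.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

# ITU-R 601 luma weights, as used by skimage.color.rgb2gray.
_LUMA = np.array([0.2125, 0.7154, 0.0721])

#: Ground lines steeper than this trigger a validation warning: the walkway
#: is expected to be nearly horizontal in a properly aligned recording.
MAX_GROUND_SLOPE = 0.2


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Convert an image array to a 2-D uint8 grayscale grid."""
    arr = np.asarray(pixels)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr[:, :, :3] @ _LUMA
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return arr


@dataclass(frozen=True)
class VideoFrame:
    """One grayscale image of a sequence.

    Parameters
    ----------
    index : int
        Non-negative frame number, unique within a sequence.
    pixels : ndarray
        2-D uint8 intensity grid (colour input is converted on load).
    """

    index: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("frame index must be non-negative")
        px = to_grayscale(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a non-empty 2-D grid")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GroundPlane:
    """The walkway surface as an image-space line through two points.

    Points are ``(column, row)``.  The line may not be vertical; slopes
    steeper than :data:`MAX_GROUND_SLOPE` produce a warning because they
    suggest a mis-aligned camera.
    """

    p1: tuple[float, float]
    p2: tuple[float, float]
    slope: float = field(init=False)
    intercept: float = field(init=False)

    def __post_init__(self) -> None:
        (c1, r1), (c2, r2) = self.p1, self.p2
        if c1 == c2:
            raise ValueError("ground line may not be vertical (equal columns)")
        slope = (r2 - r1) / (c2 - c1)
        if abs(slope) > MAX_GROUND_SLOPE:
            warnings.warn(
                f"ground line slope {slope:.3f} exceeds {MAX_GROUND_SLOPE}; "
                "walkway should be near-horizontal",
                stacklevel=2,
            )
        object.__setattr__(self, "slope", slope)
        object.__setattr__(self, "intercept", r1 - slope * c1)

    def row_at(self, column):
        """Row of the ground line at ``column`` (vectorized)."""
        return self.slope * np.asarray(column, dtype=float) + self.intercept

    def mirrored(self, width: int) -> "GroundPlane":
        """The same line in a horizontally mirrored image of ``width``."""
        (c1, r1), (c2, r2) = self.p1, self.p2
        return GroundPlane((width - 1 - c1, r1), (width - 1 - c2, r2))


_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(path: Path) -> tuple:
    nums = _NUM_RE.findall(path.stem)
    return (int(nums[-1]) if nums else 0, path.name)


def load_frames(source: str | Path) -> list[VideoFrame]:
    """Load a frame sequence from a directory of images or a video file.

    A directory is scanned for PNG/JPEG files and sorted by the numeric
    index embedded in the file name.  Video files are decoded through
    imageio when an ffmpeg plugin is available.
    """
    import imageio.v3 as iio

    source = Path(source)
    if source.is_dir():
        paths = sorted(
            (p for p in source.iterdir()
             if p.suffix.lower() in {".png", ".jpg", ".jpeg"}),
            key=_numeric_key,
        )
        if not paths:
            raise FileNotFoundError(f"no image files found in {source}")
        return [VideoFrame(i, iio.imread(p)) for i, p in enumerate(paths)]
    if not source.exists():
        raise FileNotFoundError(source)
    try:
        return [VideoFrame(i, im) for i, im in enumerate(iio.imiter(source))]
    except Exception as exc:  # pragma: no cover - depends on codecs present
        raise RuntimeError(
            f"could not decode video {source}; install an imageio ffmpeg "
            "plugin or supply a directory of PNG frames"
        ) from exc
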