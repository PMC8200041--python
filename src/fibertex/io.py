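"""Image stack I/O, physical cropping and coverage gating.

SHG acquisitions arrive as single-channel multi-page TIFF stacks of 16-bit
photon counts (one file per detection channel).  Analysis operates on square
physical crops — 45 x 45 um regions of the 180 x 180 um field — and crops
with insufficient collagen coverage are discarded before feature extraction,
because sparse regions distort texture and spectral statistics.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "Channel",
    "SHGField",
    "Crop",
    "FormatError",
    "read_stack",
    "write_stack",
    "crop_rois",
    "gate_by_coverage",
    "read_label_table",
]


class FormatError(ValueError):
    """Raised for unreadable or non-conforming image files."""


class Channel(str, enum.Enum):
    FORWARD = "F"
    BACKWARD = "B"


@dataclass
class SHGField:
    """One optical section of one channel: a 2D raster of photon counts."""

    pixels: np.ndarray
    channel: Channel
    pixel_size_um: float
    stack_id: str = ""
    z_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("SHGField pixels must be a 2D array")
        if np.issubdtype(self.pixels.dtype, np.integer) and self.pixels.min() < 0:
            raise ValueError("photon counts must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def fov_um(self) -> float:
        return self.pixels.shape[0] * self.pixel_size_um


@dataclass
class Crop:
    """A square sub-region of a parent field, indexed 0-based, half-open."""

    pixels: np.ndarray
    stack_id: str
    z_index: int
    origin: Tuple[int, int]  # (row0, col0)
    size_px: int
    pixel_size_um: float
    channel: Channel
    label: Optional[str] = None
    coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if self.coverage is not None and not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must lie in [0, 1]")


def read_stack(
    path: str | Path,
    channel: Channel | str | None = None,
    pixel_size_um: float | None = None,
) -> List[SHGField]:
    """Read a single-channel multi-page TIFF into one SHGField per page.

    The channel is taken from the filename convention ``*_F.tif`` /
    ``*_B.tif`` when not given explicitly.  Pixel size must come from TIFF
    resolution metadata or the ``pixel_size_um`` argument (sidecar config).
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
            if pixel_size_um is None:
                res = tif.pages[0].tags.get("XResolution")
                # (1, 1) is the writer default, i.e. no real resolution info
                if res is not None and res.value[0] > 0 and res.value != (1, 1):
                    num, den = res.value
                    pixel_size_um = den / num  # resolution stored as px per um
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc

    for page in pages:
        if page.ndim != 2:
            raise FormatError(f"{path}: expected single-channel grayscale pages, got shape {page.shape}")
    if pixel_size_um is None:
        raise FormatError(f"{path}: pixel size missing from metadata; supply pixel_size_um")

    if channel is None:
        stem = path.stem.upper()
        if stem.endswith("_F"):
            channel = Channel.FORWARD
        elif stem.endswith("_B"):
            channel = Channel.BACKWARD
        else:
            raise FormatError(
                f"{path}: channel not deducible from filename (expected *_F or *_B); pass channel="
            )
    channel = Channel(channel)
    stack_id = path.stem.rsplit("_", 1)[0] if path.stem.upper().endswith(("_F", "_B")) else path.stem
    return [
        SHGField(pixels=page, channel=channel, pixel_size_um=float(pixel_size_um),
                 stack_id=stack_id, z_index=z)
        for z, page in enumerate(pages)
    ]


def write_stack(path: str | Path, fields: Sequence[SHGField]) -> None:
    """Write fields as a 16-bit grayscale multi-page TIFF with resolution tags."""
    if not fields:
        raise ValueError("no fields to write")
    px = fields[0].pixel_size_um
    data = np.stack([np.asarray(f.pixels, dtype=np.uint16) for f in fields])
    tifffile.imwrite(Path(path), data, resolution=(1.0 / px, 1.0 / px))


def crop_rois(field: SHGField, crop_um: float) -> List[Crop]:
    """Tile a field into non-overlapping square crops of physical size crop_um.

    The pixel size of a crop is ``round(crop_um / pixel_size_um)`` with
    round-half-even; partial tiles at the edges are discarded (padding would
    bias texture and spectral statistics).
    """
    n = field.pixels.shape[0]
    size_px = int(np.round(crop_um / field.pixel_size_um))
    if size_px <= 0 or size_px > min(field.pixels.shape):
        raise ValueError(
            f"crop of {crop_um} um ({size_px} px) does not fit a "
            f"{field.pixels.shape} field at {field.pixel_size_um} um/px"
        )
    crops = []
    for r0 in range(0, field.pixels.shape[0] - size_px + 1, size_px):
        for c0 in range(0, field.pixels.shape[1] - size_px + 1, size_px):
            crops.append(
                Crop(
                    pixels=field.pixels[r0 : r0 + size_px, c0 : c0 + size_px],
                    stack_id=field.stack_id,
                    z_index=field.z_index,
                    origin=(r0, c0),
                    size_px=size_px,
                    pixel_size_um=field.pixel_size_um,
                    channel=field.channel,
                )
            )
    return crops


def gate_by_coverage(crops: Iterable[Crop], min_coverage: float = 0.70) -> List[Crop]:
    """Keep crops whose collagen coverage is at least ``min_coverage``.

    Coverage must already be attached (see
    :func:`fibertex.fibers.packing_coefficient`); regions below ~70% coverage
    degrade the texture and spectral readouts and are excluded upstream of
    classification.
    """
    crops = list(crops)
    kept = []
    for c in crops:
        if c.coverage is None:
            from .fibers import packing_coefficient

            c.coverage = packing_coefficient(c.pixels)
        if c.coverage >= min_coverage:
            kept.append(c)
    logger.info("coverage gate %.2f: retained %d / %d crops", min_coverage, len(kept), len(crops))
    if crops and not kept:
        warnings.warn("coverage gate retained no crops", stacklevel=2)
    return kept


def read_label_table(path: str | Path) -> Dict[Tuple[str, int, int], str]:
    """Read the (stack_id, row0, col0) -> tissue class mapping TSV.

    This external table stands in for the pathologist's mapping of lesion
    regions onto the unstained SHG slides.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"stack_id", "row0", "col0", "label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"label table {path} missing columns: {sorted(missing)}")
    return {
        (str(r.stack_id), int(r.row0), int(r.col0)): str(r.label)
        for r in df.itertuples(index=False)
    }
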