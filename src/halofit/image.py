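"""Plate images to per-track chromatograms.

A developed plate photographed under UV illumination is reduced to one
intensity profile per sample track: the image is converted to an 8-bit grey
scale, grey values are averaged across the central 50 % of the application
band, and the resulting profile is smoothed with a Savitzky-Golay filter
before any peak work. Positions along the development direction can be
mapped to retention factors (Rf).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from scipy.signal import savgol_filter

from .errors import GeometryError, InputError, ParameterError

#: ITU-R BT.601 luminance weights used for colour-to-grey conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Savitzky-Golay defaults used for all chromatograms.
SAVGOL_POLYORDER = 2
SAVGOL_WINDOW = 111


@dataclass(frozen=True)
class GreyImage:
    """8-bit single-channel plate image."""

    pixels: np.ndarray  # (height, width) uint8
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ParameterError("grey image must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ParameterError("grey intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class TrackGeometry:
    """Positions needed to locate one sample track on the plate image.

    ``application_y`` is the Y pixel row of the application origin and
    ``front_y`` the row of the solvent front; development runs from the
    former to the latter (either direction in image coordinates).
    """

    track_center_x: float
    application_band_width: float
    application_y: float
    front_y: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.application_band_width <= 0:
            raise ParameterError("application_band_width must be > 0")
        if self.front_y == self.application_y:
            raise GeometryError("zero development distance (front_y == application_y)")


@dataclass
class Chromatogram:
    """Ordered (position, intensity) profile along one sample track.

    Positions are 0-based sample coordinates starting at the application
    origin and increasing toward the solvent front; an optional
    ``mm_per_position`` calibration maps them to millimetres.
    """

    positions: np.ndarray
    intensities: np.ndarray
    smoothed: bool = False
    track: TrackGeometry | None = None
    label: str = ""
    mm_per_position: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape or self.positions.ndim != 1:
            raise ParameterError("positions and intensities must be equal-length 1-D arrays")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ParameterError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ParameterError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "intensity": self.intensities, "track": self.label}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Chromatogram":
        df = pd.read_csv(path)
        label = str(df["track"].iloc[0]) if "track" in df and len(df) else ""
        return cls(
            positions=df["position"].to_numpy(float),
            intensities=df["intensity"].to_numpy(float),
            label=label,
        )


def load_grey_image(path: str | Path) -> GreyImage:
    """Load a raster image (PNG/TIFF/JPEG) as an 8-bit grey image.

    Colour images are reduced with the fixed ITU-R BT.601 luminance weights
    0.299 R + 0.587 G + 0.114 B, rounded to the nearest integer.
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            arr = np.asarray(img)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise InputError(f"cannot read image file: {path}") from exc
    return GreyImage(pixels=_to_grey(arr), source_path=str(path))


def _to_grey(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        grey = arr.astype(float)
    elif arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(float)
        grey = rgb @ np.asarray(LUMA_WEIGHTS)
    else:
        raise InputError(f"unsupported image shape {arr.shape}")
    return np.clip(np.round(grey), 0, 255).astype(np.uint8)


def extract_track_profile(image: GreyImage, track: TrackGeometry) -> Chromatogram:
    """Average grey values over the central 50 % of the application band.

    For every image row between the application origin and the solvent front
    (inclusive, ordered so that position increases with migration), the
    intensity is the arithmetic mean of the columns within a quarter
    band-width of the track centre — i.e. the central half of the band,
    which is an odd pixel count for integral centres.
    """
    half = track.application_band_width / 4.0
    if track.track_center_x - half < -0.5 or track.track_center_x + half > image.width - 0.5:
        raise GeometryError("averaging band exceeds image bounds")
    cols = np.arange(image.width)
    sel = np.abs(cols - track.track_center_x) <= half + 1e-9
    if not sel.any():
        raise GeometryError("averaging band selects no pixel columns")
    lo, hi = sorted((int(track.application_y), int(track.front_y)))
    if lo < 0 or hi >= image.height:
        raise GeometryError("track rows exceed image bounds")
    rows = np.arange(lo, hi + 1)
    if track.front_y < track.application_y:
        rows = rows[::-1]
    profile = image.pixels[np.ix_(rows, cols[sel])].mean(axis=1)
    return Chromatogram(
        positions=np.arange(len(rows), dtype=float),
        intensities=profile,
        smoothed=False,
        track=track,
        label=track.label,
    )


def smooth(
    chrom: Chromatogram,
    polyorder: int = SAVGOL_POLYORDER,
    window_length: int = SAVGOL_WINDOW,
) -> Chromatogram:
    """Savitzky-Golay filtered copy of a chromatogram.

    Defaults (polyorder 2, window 111) suppress pixel noise without
    over-smoothing typical plate signals.
    """
    n = len(chrom)
    if window_length % 2 != 1 or window_length <= polyorder:
        raise ParameterError("window_length must be odd and greater than polyorder")
    if window_length > n:
        raise ParameterError(
            f"window_length {window_length} exceeds profile length {n}; "
            "shorten the window or extract a longer track"
        )
    return replace(
        chrom,
        intensities=savgol_filter(chrom.intensities, window_length, polyorder),
        smoothed=True,
    )


def rf_of_position(position: float, track: TrackGeometry) -> float:
    """Retention factor of a plate-axis position.

    Rf = (position − application origin) / (solvent front − application
    origin). Values outside [0, 1] indicate a position outside the developed
    region and are returned unclipped.
    """
    rise = track.front_y - track.application_y
    if rise == 0:
        raise GeometryError("zero development distance")
    return (position - track.application_y) / rise
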