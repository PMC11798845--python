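"""Cine clips, ROI rasterization, flash detection, and time-intensity curves.

A contrast-enhanced ultrasound (CEUS) flash-replenishment acquisition is a
multi-frame grayscale cine: a steady-state contrast plateau, a high-power
destruction ("flash") window that clears microbubbles from the imaging
plane, and a replenishment phase in which contrast refills the
microvasculature.  This module handles the imaging-side plumbing: reading
and writing clips (multi-page TIFF plus a plain-text sidecar), turning ROI
specifications into pixel masks, locating the end of the destruction
window, and averaging a clip over a mask into a time-intensity curve (TIC).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from .errors import FlashDetectionError, FormatError, GeometryError, InputError

__all__ = [
    "CineClip",
    "RoiSpec",
    "TimeIntensityCurve",
    "load_cine",
    "save_cine",
    "rasterize_roi",
    "detect_flash",
    "extract_tic",
    "circular_mask",
    "elliptical_mask",
]

#: canonical ROI labels used throughout the package
ROI_LABELS = ("whole_brain", "central_thalamic", "peripheral_parenchyma")


@dataclass
class CineClip:
    """A cine acquisition: T frames of H x W nonnegative intensities.

    Parameters
    ----------
    frames
        Array of shape (T, H, W), arbitrary intensity units (au).
    frame_interval_s
        Time between consecutive frames, seconds.
    pixel_spacing_mm
        Isotropic pixel pitch, millimetres.
    flash_end_index
        Index of the first frame at or after the end of the destruction
        window, if known from the acquisition protocol.
    clip_id
        Free-form provenance identifier.
    """

    frames: np.ndarray
    frame_interval_s: float
    pixel_spacing_mm: float
    flash_end_index: int | None = None
    clip_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise FormatError("cine must be a (T, H, W) stack with T >= 2")
        if self.frames.shape[1] < 1 or self.frames.shape[2] < 1:
            raise FormatError("cine frames must be non-empty")
        if np.any(self.frames < 0):
            raise FormatError("cine intensities must be nonnegative")
        if not (self.frame_interval_s > 0):
            raise FormatError("frame_interval_s must be positive")
        if not (self.pixel_spacing_mm > 0):
            raise FormatError("pixel_spacing_mm must be positive")
        if self.flash_end_index is not None:
            idx = int(self.flash_end_index)
            if not 0 <= idx < self.frames.shape[0]:
                raise FormatError("flash_end_index out of range")
            self.flash_end_index = idx

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) grid shape."""
        return self.frames.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        """Frame acquisition times, t = 0 at the first frame."""
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class RoiSpec:
    """A region of interest: a circle in physical units or an explicit mask.

    Circles are given by ``center_mm`` (row, column, measured from the image
    origin) and ``diameter_mm``.  Explicit masks bypass rasterization and
    are used unchanged.
    """

    label: str
    center_mm: tuple[float, float] | None = None
    diameter_mm: float | None = None
    mask: np.ndarray | None = None
    clip_id: str = ""

    def __post_init__(self) -> None:
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if not self.mask.any():
                raise GeometryError("explicit ROI mask is empty")
        elif self.center_mm is not None and self.diameter_mm is not None:
            if not (self.diameter_mm > 0):
                raise GeometryError("circle diameter must be positive")
        else:
            raise GeometryError("RoiSpec needs either a circle or a mask")


@dataclass
class TimeIntensityCurve:
    """ROI-mean contrast intensity versus time for one acquisition."""

    times_s: np.ndarray
    intensities_au: np.ndarray
    roi_label: str = ""
    replicate: int = 0
    animal_id: str = ""
    group: str = ""
    day: int | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities_au = np.asarray(self.intensities_au, dtype=float)
        if self.times_s.shape != self.intensities_au.shape:
            raise InputError("times and intensities must have equal length")
        if self.times_s.ndim != 1 or self.times_s.size < 2:
            raise InputError("a TIC needs at least two samples")
        if np.any(np.diff(self.times_s) <= 0):
            raise InputError("TIC times must be strictly increasing")
        if np.any(self.intensities_au < 0):
            raise InputError("TIC intensities must be nonnegative")

    def to_csv(self, path: str | os.PathLike) -> None:
        arr = np.column_stack([self.times_s, self.intensities_au])
        np.savetxt(path, arr, delimiter=",", header="time_s,intensity_au", comments="")


# --- container I/O ---------------------------------------------------------

_SIDECAR_SUFFIX = ".meta"
_REQUIRED_KEYS = ("frame_interval_s", "pixel_spacing_mm")


def _sidecar_path(path: str | os.PathLike) -> str:
    return os.fspath(path) + _SIDECAR_SUFFIX


def save_cine(clip: CineClip, path: str | os.PathLike) -> None:
    """Write a clip as a multi-page TIFF plus a plain-text key=value sidecar.

    Pages are written in the clip's own floating-point precision so the
    round trip is bit-exact.
    """
    frames = clip.frames
    if frames.dtype not in (np.float32, np.float64):
        frames = frames.astype(np.float32)
    tifffile.imwrite(os.fspath(path), frames)
    lines = [
        f"frame_interval_s={clip.frame_interval_s!r}",
        f"pixel_spacing_mm={clip.pixel_spacing_mm!r}",
        f"clip_id={clip.clip_id}",
    ]
    if clip.flash_end_index is not None:
        lines.append(f"flash_end_index={clip.flash_end_index}")
    with open(_sidecar_path(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_cine(path: str | os.PathLike) -> CineClip:
    """Read a clip written by :func:`save_cine`.

    Raises
    ------
    FormatError
        If the sidecar is missing or lacks a required key.
    """
    sidecar = _sidecar_path(path)
    if not os.path.exists(sidecar):
        raise FormatError(f"missing sidecar metadata file: {sidecar}")
    meta: dict[str, str] = {}
    with open(sidecar) as fh:
        for line in fh:
            line = line.strip()
            if line and "=" in line:
                key, _, value = line.partition("=")
                meta[key.strip()] = value.strip()
    for key in _REQUIRED_KEYS:
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} is missing required key {key!r}")
    frames = tifffile.imread(os.fspath(path))
    if frames.ndim == 2:  # single page: invalid, but let CineClip report it
        frames = frames[None]
    flash = meta.get("flash_end_index")
    return CineClip(
        frames=frames,
        frame_interval_s=float(meta["frame_interval_s"]),
        pixel_spacing_mm=float(meta["pixel_spacing_mm"]),
        flash_end_index=int(flash) if flash is not None else None,
        clip_id=meta.get("clip_id", ""),
    )


# --- ROI rasterization -----------------------------------------------------


def circular_mask(
    shape: tuple[int, int],
    center_mm: tuple[float, float],
    diameter_mm: float,
    pixel_spacing_mm: float,
) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within ``diameter_mm / 2``.

    Pixel (i, j) has its center at ((i + 0.5), (j + 0.5)) * spacing; the
    inclusion rule is center-in-circle.
    """
    h, w = shape
    radius = diameter_mm / 2.0
    cr, cc = center_mm
    if (
        cr - radius < 0
        or cc - radius < 0
        or cr + radius > h * pixel_spacing_mm
        or cc + radius > w * pixel_spacing_mm
    ):
        raise GeometryError("circle extends outside the image grid")
    rows = (np.arange(h) + 0.5) * pixel_spacing_mm
    cols = (np.arange(w) + 0.5) * pixel_spacing_mm
    dist2 = (rows[:, None] - cr) ** 2 + (cols[None, :] - cc) ** 2
    mask = dist2 <= radius**2
    if not mask.any():
        raise GeometryError("circle contains no pixel centers")
    return mask


def elliptical_mask(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    semi_axes_px: tuple[float, float],
) -> np.ndarray:
    """Boolean elliptical mask in pixel coordinates (used for whole-brain ROIs)."""
    h, w = shape
    cr, cc = center_px
    ar, ac = semi_axes_px
    if ar <= 0 or ac <= 0:
        raise GeometryError("ellipse semi-axes must be positive")
    rows = np.arange(h) + 0.5
    cols = np.arange(w) + 0.5
    val = ((rows[:, None] - cr) / ar) ** 2 + ((cols[None, :] - cc) / ac) ** 2
    mask = val <= 1.0
    if not mask.any():
        raise GeometryError("ellipse contains no pixel centers")
    return mask


def rasterize_roi(spec: RoiSpec, clip: CineClip) -> np.ndarray:
    """Turn an ROI specification into a boolean mask on the clip's grid."""
    if spec.mask is not None:
        if spec.mask.shape != clip.shape:
            raise GeometryError(
                f"mask shape {spec.mask.shape} does not match clip grid {clip.shape}"
            )
        return spec.mask
    return circular_mask(clip.shape, spec.center_mm, spec.diameter_mm, clip.pixel_spacing_mm)


# --- flash detection -------------------------------------------------------


def detect_flash(clip: CineClip, drop_fraction: float = 0.5) -> int:
    """Locate the end of the microbubble destruction window.

    If the clip metadata carries ``flash_end_index`` it is returned as-is.
    Otherwise the whole-frame mean intensity is scanned for its global
    minimum; the flash end is the last frame of the minimal run (intensity
    is lowest throughout destruction and starts rising at replenishment
    onset).  The minimum must fall below ``drop_fraction`` of the mean
    intensity of the frames preceding it, otherwise no destruction event is
    considered present.

    Raises
    ------
    FlashDetectionError
        If no frame satisfies the drop criterion; supply
        ``flash_end_index`` explicitly in that case.
    """
    if clip.flash_end_index is not None:
        return clip.flash_end_index
    if clip.n_frames < 5:
        raise InputError("flash detection needs at least 5 frames")
    means = clip.frames.reshape(clip.n_frames, -1).mean(axis=1)
    gmin = float(means.min())
    tol = 1e-9 * max(float(means.max()) - gmin, 1.0)
    minimal = np.flatnonzero(means <= gmin + tol)
    first, last = int(minimal[0]), int(minimal[-1])
    if first == 0:
        raise FlashDetectionError(
            "no pre-flash baseline before the intensity minimum; "
            "specify flash_end_index explicitly"
        )
    pre_mean = float(means[:first].mean())
    if not gmin < drop_fraction * pre_mean:
        raise FlashDetectionError(
            "no destruction window found (no frame below "
            f"{drop_fraction:.0%} of the preceding mean); "
            "specify flash_end_index explicitly"
        )
    if last >= clip.n_frames - 1:
        raise FlashDetectionError("post-flash segment is empty")
    return last


# --- TIC extraction --------------------------------------------------------


def extract_tic(
    clip: CineClip,
    mask: np.ndarray,
    roi_label: str = "",
    replicate: int = 0,
    animal_id: str = "",
    group: str = "",
    day: int | None = None,
) -> TimeIntensityCurve:
    """ROI-mean time-intensity curve: arithmetic mean over mask pixels per frame."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != clip.shape:
        raise GeometryError("mask shape does not match clip grid")
    if not mask.any():
        raise GeometryError("empty ROI mask")
    intensities = clip.frames[:, mask].mean(axis=1)
    return TimeIntensityCurve(
        times_s=clip.times_s,
        intensities_au=intensities,
        roi_label=roi_label,
        replicate=replicate,
        animal_id=animal_id,
        group=group,
        day=day,
    )
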