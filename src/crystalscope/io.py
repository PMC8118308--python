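"""Image, hyperspectral-cube and spectrum I/O plus the geometric conventions
shared by the whole package.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)``; the row index increases
  downward. Pixel *centers* sit on the integer lattice, so the pixel at
  ``(r, c)`` occupies the square ``[r - 0.5, r + 0.5] x [c - 0.5, c + 0.5]``.
* Physical lengths are ``pixels * pixel_size_um`` (micrometres).
* Hyperspectral cubes are ``(row, col, channel)`` arrays bound to a uniform
  :class:`WavenumberAxis`; on disk they are multi-page grayscale TIFFs (one
  page per wavenumber, ascending) with a JSON sidecar carrying the axis and
  the pixel size.
* Spectra interchange as two-column CSV with the header
  ``wavenumber_cm1,intensity``.
* Intensities are kept as read — no rescaling or normalization happens at
  I/O time; normalization is an explicit spectral operation.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "ChannelLabel",
    "IntensityImage",
    "WavenumberAxis",
    "HyperspectralCube",
    "Roi",
    "RoiShape",
    "Spectrum",
    "read_image",
    "write_image",
    "read_cube",
    "write_cube",
    "read_spectrum",
    "write_spectrum",
    "roi_pixels",
]


class ChannelLabel(str, Enum):
    """Imaging modality that produced a single-channel frame."""

    SHG = "SHG"
    SRS = "SRS"
    CARS = "CARS"
    REFLECTANCE = "REFLECTANCE"
    OTHER = "OTHER"


MIN_IMAGE_DIM = 8


@dataclass
class IntensityImage:
    """A single-channel 2-D frame with a physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities (any real dtype;
        integers are converted to float64 without rescaling).
    pixel_size_um
        Physical edge length of one pixel, micrometres (> 0).
    channel_label
        Modality tag; purely descriptive.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_label: ChannelLabel = ChannelLabel.OTHER

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={arr.ndim}")
        if arr.shape[0] < MIN_IMAGE_DIM or arr.shape[1] < MIN_IMAGE_DIM:
            raise ValueError(
                f"image too small: shape {arr.shape}, need >= {MIN_IMAGE_DIM} in both dimensions"
            )
        arr = arr.astype(np.float64, copy=False)
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite values")
        if arr.min() < 0:
            raise ValueError("image contains negative intensities")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        self.pixels = arr
        self.channel_label = ChannelLabel(self.channel_label)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def area_mm2(self) -> float:
        """Physical area of the full frame in mm^2."""
        n = self.pixels.size
        return n * (self.pixel_size_um * 1e-3) ** 2


@dataclass(frozen=True)
class WavenumberAxis:
    """Uniform wavenumber axis: ``start + k*step`` for ``k = 0..n-1``.

    The channel count is ``floor((stop - start)/step) + 1``, so an axis of
    2825-3075 cm^-1 at 5 cm^-1 steps has 51 channels.
    """

    start_cm1: float
    stop_cm1: float
    step_cm1: float

    def __post_init__(self) -> None:
        if not self.step_cm1 > 0:
            raise ValueError(f"step_cm1 must be > 0, got {self.step_cm1}")
        if not self.start_cm1 < self.stop_cm1:
            raise ValueError(
                f"start_cm1 ({self.start_cm1}) must be < stop_cm1 ({self.stop_cm1})"
            )

    @property
    def n_channels(self) -> int:
        return int(math.floor((self.stop_cm1 - self.start_cm1) / self.step_cm1 + 1e-9)) + 1

    def values(self) -> np.ndarray:
        return self.start_cm1 + self.step_cm1 * np.arange(self.n_channels)

    def to_dict(self) -> dict:
        return {
            "start_cm1": self.start_cm1,
            "stop_cm1": self.stop_cm1,
            "step_cm1": self.step_cm1,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WavenumberAxis":
        return cls(
            start_cm1=float(d["start_cm1"]),
            stop_cm1=float(d["stop_cm1"]),
            step_cm1=float(d["step_cm1"]),
        )


@dataclass
class HyperspectralCube:
    """(row, col, channel) stack where every pixel carries a vibrational
    spectrum on a shared :class:`WavenumberAxis`."""

    data: np.ndarray
    axis: WavenumberAxis
    pixel_size_um: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"cube must be 3-D (row, col, channel), got ndim={arr.ndim}")
        if arr.shape[2] != self.axis.n_channels:
            raise ValueError(
                f"channel dimension ({arr.shape[2]}) does not match axis channel count "
                f"({self.axis.n_channels})"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("cube contains non-finite values")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        self.data = arr

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]  # type: ignore[return-value]

    def pixel_spectrum(self, row: int, col: int, label: str = "") -> "Spectrum":
        return Spectrum(self.axis.values(), self.data[row, col, :].copy(), label=label)


@dataclass
class Spectrum:
    """Intensity versus wavenumber trace."""

    wavenumbers_cm1: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers_cm1, dtype=np.float64)
        y = np.asarray(self.intensities, dtype=np.float64)
        if w.ndim != 1 or y.ndim != 1 or w.size != y.size:
            raise ValueError("wavenumbers and intensities must be 1-D vectors of equal length")
        if w.size >= 2 and not np.all(np.diff(w) > 0):
            raise ValueError("wavenumbers must be strictly ascending")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        self.wavenumbers_cm1 = w
        self.intensities = y

    def __len__(self) -> int:
        return self.wavenumbers_cm1.size


class RoiShape(str, Enum):
    DISK = "DISK"
    ELLIPSE = "ELLIPSE"
    POLYGON = "POLYGON"
    MASK = "MASK"


@dataclass
class Roi:
    """Region of interest over an image grid.

    ``DISK``: center=(row, col), radius r — pixels whose centers lie within
    Euclidean distance r of the center.
    ``ELLIPSE``: center=(row, col), radii=(r_row, r_col).
    ``POLYGON``: vertices as (row, col) pairs; pixels whose centers fall
    inside the polygon (matplotlib-free scanline fill via skimage).
    ``MASK``: explicit boolean grid of the full image shape.
    """

    shape: RoiShape
    center: tuple[float, float] | None = None
    radius: float | None = None
    radii: tuple[float, float] | None = None
    vertices: Sequence[tuple[float, float]] | None = None
    mask: np.ndarray | None = None
    name: str = ""

    def to_dict(self) -> dict:
        d: dict = {"shape": self.shape.value, "name": self.name}
        if self.center is not None:
            d["center"] = list(self.center)
        if self.radius is not None:
            d["radius"] = self.radius
        if self.radii is not None:
            d["radii"] = list(self.radii)
        if self.vertices is not None:
            d["vertices"] = [list(v) for v in self.vertices]
        if self.mask is not None:
            d["mask"] = np.asarray(self.mask, dtype=bool).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Roi":
        return cls(
            shape=RoiShape(d["shape"]),
            center=tuple(d["center"]) if "center" in d else None,
            radius=d.get("radius"),
            radii=tuple(d["radii"]) if "radii" in d else None,
            vertices=[tuple(v) for v in d["vertices"]] if "vertices" in d else None,
            mask=np.asarray(d["mask"], dtype=bool) if "mask" in d else None,
            name=d.get("name", ""),
        )


def roi_pixels(roi: Roi, image_shape: tuple[int, int]) -> np.ndarray:
    """Resolve an ROI to its pixel set.

    Returns
    -------
    ndarray of shape (n, 2)
        Sorted (row, col) integer coordinates. Deterministic: sorted
        lexicographically by row then column.

    Raises
    ------
    ValueError
        If the ROI resolves to an empty pixel set or reaches outside the
        image bounds.
    """
    nrow, ncol = image_shape
    if roi.shape is RoiShape.MASK:
        if roi.mask is None:
            raise ValueError("MASK ROI requires an explicit boolean grid")
        m = np.asarray(roi.mask, dtype=bool)
        if m.shape != tuple(image_shape):
            raise ValueError(f"mask shape {m.shape} does not match image shape {tuple(image_shape)}")
        coords = np.argwhere(m)
    elif roi.shape is RoiShape.DISK:
        if roi.center is None or roi.radius is None:
            raise ValueError("DISK ROI requires center and radius")
        cr, cc = roi.center
        r = float(roi.radius)
        lo_r, hi_r = int(math.floor(cr - r)), int(math.ceil(cr + r))
        lo_c, hi_c = int(math.floor(cc - r)), int(math.ceil(cc + r))
        rr, ccg = np.mgrid[lo_r : hi_r + 1, lo_c : hi_c + 1]
        inside = (rr - cr) ** 2 + (ccg - cc) ** 2 <= r**2 + 1e-12
        coords = np.stack([rr[inside], ccg[inside]], axis=1)
    elif roi.shape is RoiShape.ELLIPSE:
        if roi.center is None or roi.radii is None:
            raise ValueError("ELLIPSE ROI requires center and radii")
        cr, cc = roi.center
        ar, ac = roi.radii
        if ar <= 0 or ac <= 0:
            raise ValueError("ellipse radii must be > 0")
        lo_r, hi_r = int(math.floor(cr - ar)), int(math.ceil(cr + ar))
        lo_c, hi_c = int(math.floor(cc - ac)), int(math.ceil(cc + ac))
        rr, ccg = np.mgrid[lo_r : hi_r + 1, lo_c : hi_c + 1]
        inside = ((rr - cr) / ar) ** 2 + ((ccg - cc) / ac) ** 2 <= 1 + 1e-12
        coords = np.stack([rr[inside], ccg[inside]], axis=1)
    elif roi.shape is RoiShape.POLYGON:
        if roi.vertices is None or len(roi.vertices) < 3:
            raise ValueError("POLYGON ROI requires >= 3 vertices")
        from skimage.draw import polygon as sk_polygon

        verts = np.asarray(roi.vertices, dtype=float)
        rr, cc = sk_polygon(verts[:, 0], verts[:, 1])
        coords = np.stack([rr, cc], axis=1)
        vmin = verts.min(axis=0)
        vmax = verts.max(axis=0)
        if vmin[0] < -0.5 or vmin[1] < -0.5 or vmax[0] > nrow - 0.5 or vmax[1] > ncol - 0.5:
            raise ValueError("polygon extends outside the image bounds")
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown ROI shape {roi.shape}")

    if coords.size == 0:
        raise ValueError("ROI resolves to an empty pixel set")
    if (
        coords[:, 0].min() < 0
        or coords[:, 1].min() < 0
        or coords[:, 0].max() >= nrow
        or coords[:, 1].max() >= ncol
    ):
        raise ValueError("ROI reaches outside the image bounds")
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    return coords[order]


# ---------------------------------------------------------------------------
# TIFF images
# ---------------------------------------------------------------------------

def read_image(
    path: str | Path,
    pixel_size_um: float,
    channel_label: ChannelLabel | str = ChannelLabel.OTHER,
) -> IntensityImage:
    """Read a single-page grayscale TIFF as an :class:`IntensityImage`.

    Integer pixel types are converted to float64 without rescaling. Color
    (multi-sample) or multi-page inputs are rejected.
    """
    with tifffile.TiffFile(str(path)) as tf:
        n_pages = len(tf.pages)
        if n_pages != 1:
            raise ValueError(
                f"expected single-channel single-page TIFF, got {n_pages} pages in {path}"
            )
        arr = tf.pages[0].asarray()
    if arr.ndim == 3:
        raise ValueError(
            f"expected single-channel image, got {arr.shape[-1]} samples per pixel in {path}"
        )
    return IntensityImage(arr, pixel_size_um=pixel_size_um, channel_label=channel_label)


def write_image(path: str | Path, image: IntensityImage | np.ndarray, dtype=None) -> None:
    """Write a 2-D image as a single-page grayscale TIFF.

    ``dtype`` may force an integer on-disk type (values are cast, not
    rescaled); by default float32 is used for real data and the native type
    for integer arrays.
    """
    arr = image.pixels if isinstance(image, IntensityImage) else np.asarray(image)
    if dtype is not None:
        arr = arr.astype(dtype)
    elif arr.dtype.kind == "f":
        arr = arr.astype(np.float32)
    tifffile.imwrite(str(path), arr, photometric="minisblack")


# ---------------------------------------------------------------------------
# Hyperspectral cubes
# ---------------------------------------------------------------------------

def read_cube(path: str | Path, sidecar_path: str | Path) -> HyperspectralCube:
    """Read a multi-page TIFF plus JSON sidecar as a hyperspectral cube.

    Page ``k`` maps to wavenumber ``start + k*step``; the page count must
    equal the sidecar axis's channel count.
    """
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    axis = WavenumberAxis.from_dict(meta)
    pixel_size_um = float(meta["pixel_size_um"])
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None, ...]
    n_pages = stack.shape[0]
    if n_pages != axis.n_channels:
        raise ValueError(
            f"page count ({n_pages}) does not match axis channel count ({axis.n_channels})"
        )
    data = np.moveaxis(stack, 0, 2)
    return HyperspectralCube(data, axis=axis, pixel_size_um=pixel_size_um)


def write_cube(path: str | Path, sidecar_path: str | Path, cube: HyperspectralCube) -> None:
    """Write a cube as a multi-page float32 TIFF plus JSON sidecar."""
    stack = np.moveaxis(cube.data, 2, 0).astype(np.float32)
    tifffile.imwrite(str(path), stack, photometric="minisblack")
    meta = cube.axis.to_dict()
    meta["pixel_size_um"] = cube.pixel_size_um
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=2)


# ---------------------------------------------------------------------------
# Spectra (CSV)
# ---------------------------------------------------------------------------

CSV_HEADER = ("wavenumber_cm1", "intensity")


def read_spectrum(path: str | Path, label: str | None = None) -> Spectrum:
    """Read a two-column ``wavenumber_cm1,intensity`` CSV spectrum."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip() for h in header] != list(CSV_HEADER):
            raise ValueError(
                f"unexpected CSV header {header!r}; expected {','.join(CSV_HEADER)!r}"
            )
        rows = [(float(w), float(y)) for w, y in reader]
    if not rows:
        raise ValueError(f"no data rows in {path}")
    arr = np.asarray(rows, dtype=np.float64)
    return Spectrum(arr[:, 0], arr[:, 1], label=label if label is not None else path.stem)


def write_spectrum(path: str | Path, spectrum: Spectrum) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for w, y in zip(spectrum.wavenumbers_cm1, spectrum.intensities):
            writer.writerow([repr(float(w)), repr(float(y))])
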