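"""Synthetic SHG needle fields, hyperspectral cubes and reflectance sections
with exact ground truth.

These generators emulate the three kinds of frames the analysis pipeline
consumes:

* 512x512 SHG fields of bright needle-shaped cholesterol crystals on a dark
  background, rendered as anti-aliased rotated rectangles;
* hyperspectral stimulated-Raman cubes over the CH-stretch window
  (2825-3075 cm^-1 at 5 cm^-1 steps) whose pixels are linear mixtures of
  parametric reference spectra (free cholesterol, cholesteryl esters,
  protein) plus Gaussian noise;
* reflectance sections with a dim plaque body carrying bright crystal
  specks over a known area fraction.

Every generator is a pure function of its parameters including the seed, and
ground truth is returned alongside the rendered data so that segmentation,
unmixing and burden estimates can be scored exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .io import HyperspectralCube, IntensityImage, ChannelLabel, Spectrum, WavenumberAxis

__all__ = [
    "Species",
    "SceneClass",
    "DEFAULT_BAND_TABLE",
    "CH_STRETCH_AXIS",
    "FINGERPRINT_AXIS",
    "LengthDistribution",
    "NeedleFieldParams",
    "NeedleGroundTruth",
    "NeedleTruth",
    "SpectralScene",
    "synth_reference_spectrum",
    "generate_needle_field",
    "generate_cube",
    "generate_reflectance_section",
]


class Species(str, Enum):
    """Reference species for spectral unmixing."""

    CHOLESTEROL_MONOHYDRATE = "CHOLESTEROL_MONOHYDRATE"
    CHOLESTERYL_OLEATE = "CHOLESTERYL_OLEATE"
    CHOLESTERYL_LINOLEATE = "CHOLESTERYL_LINOLEATE"
    PROTEIN = "PROTEIN"


class SceneClass(str, Enum):
    BACKGROUND = "BACKGROUND"
    PROTEIN = "PROTEIN"
    AMORPHOUS_LIPID = "AMORPHOUS_LIPID"
    CE_CRYSTAL_LINOLEATE = "CE_CRYSTAL_LINOLEATE"
    CE_CRYSTAL_OLEATE = "CE_CRYSTAL_OLEATE"
    FC_CRYSTAL = "FC_CRYSTAL"


# Gaussian band model per species: (center_cm1, fwhm_cm1, relative_amplitude).
#
# CH-stretch anchors: the CH2 symmetric stretch near 2845-2850 cm^-1 that
# carries lipid SRS contrast, the =C-H stretch near 3010 cm^-1 diagnostic of
# unsaturated acyl chains (stronger for linoleate, two C=C, than oleate,
# one), and the protein CH3 envelope around 2930-2960 cm^-1. Fingerprint
# anchors: the ester carbonyl at 1740 cm^-1 present in cholesteryl esters but
# absent in cholesterol monohydrate, the sterol C=C near 1674 cm^-1, and the
# protein amide I near 1655 cm^-1. Widths and relative amplitudes are
# package defaults chosen to reproduce those qualitative orderings.
DEFAULT_BAND_TABLE: dict[Species, list[tuple[float, float, float]]] = {
    Species.CHOLESTEROL_MONOHYDRATE: [
        (2850.0, 35.0, 1.0),
        (2880.0, 40.0, 0.7),
        (2935.0, 45.0, 0.45),
        (1674.0, 25.0, 0.3),
    ],
    Species.CHOLESTERYL_OLEATE: [
        (2845.0, 35.0, 1.0),
        (2885.0, 40.0, 0.6),
        (3005.0, 25.0, 0.15),
        (1740.0, 20.0, 0.5),
    ],
    Species.CHOLESTERYL_LINOLEATE: [
        (2845.0, 35.0, 1.0),
        (2885.0, 40.0, 0.6),
        (3010.0, 25.0, 0.35),
        (1740.0, 20.0, 0.5),
    ],
    Species.PROTEIN: [
        (2930.0, 50.0, 1.0),
        (2960.0, 40.0, 0.5),
        (1655.0, 45.0, 0.8),
    ],
}

#: CH-stretch acquisition axis used for SRS hyperspectral stacks.
CH_STRETCH_AXIS = WavenumberAxis(2825.0, 3075.0, 5.0)
#: Fingerprint axis used for conventional Raman point spectra.
FINGERPRINT_AXIS = WavenumberAxis(1600.0, 1800.0, 2.0)

# Per-pixel composition of each scene class in reference-species weights.
CLASS_WEIGHTS: dict[SceneClass, dict[Species, float]] = {
    SceneClass.BACKGROUND: {},
    SceneClass.PROTEIN: {Species.PROTEIN: 1.0},
    # Droplet-like CH2-rich lipid: ester mixture dominated by oleate.
    SceneClass.AMORPHOUS_LIPID: {
        Species.CHOLESTERYL_OLEATE: 0.8,
        Species.CHOLESTERYL_LINOLEATE: 0.2,
    },
    SceneClass.CE_CRYSTAL_LINOLEATE: {Species.CHOLESTERYL_LINOLEATE: 1.0},
    SceneClass.CE_CRYSTAL_OLEATE: {Species.CHOLESTERYL_OLEATE: 1.0},
    SceneClass.FC_CRYSTAL: {Species.CHOLESTEROL_MONOHYDRATE: 1.0},
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def synth_reference_spectrum(
    species: Species | str,
    axis: WavenumberAxis,
    band_table: dict[Species, list[tuple[float, float, float]]] | None = None,
) -> Spectrum:
    """Evaluate a species' Gaussian band model on ``axis``, peak-normalized.

    The spectrum is the sum of Gaussian bands ``amp * exp(-(w-c)^2/2s^2)``
    with ``s = fwhm / (2 sqrt(2 ln 2))``, scaled so its maximum on the axis
    is exactly 1.

    Raises
    ------
    ValueError
        For a species absent from the band table, or if no band has any
        support on the axis (the spectrum would be identically ~0).
    """
    band_table = DEFAULT_BAND_TABLE if band_table is None else band_table
    species = Species(species)
    if species not in band_table:
        raise ValueError(f"unknown species {species!r}; band table has {sorted(band_table)}")
    w = axis.values()
    y = np.zeros_like(w)
    for center, fwhm, amp in band_table[species]:
        sigma = fwhm * _FWHM_TO_SIGMA
        y += amp * np.exp(-0.5 * ((w - center) / sigma) ** 2)
    peak = y.max()
    if peak < 1e-12:
        raise ValueError(
            f"{species.value} has no band with support on axis "
            f"[{axis.start_cm1}, {axis.stop_cm1}] cm^-1"
        )
    return Spectrum(w, y / peak, label=species.value)


# ---------------------------------------------------------------------------
# SHG needle fields
# ---------------------------------------------------------------------------


class LengthDistribution(str, Enum):
    LOGNORMAL = "LOGNORMAL"
    GAMMA = "GAMMA"
    FIXED = "FIXED"


@dataclass
class NeedleFieldParams:
    """Parameters of a synthetic SHG needle field.

    ``length_params`` depends on the family: FIXED -> (length_um,);
    GAMMA -> (shape, scale_um); LOGNORMAL -> (mean_log, sd_log) of
    log(length_um).
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.5
    n_needles: int = 40
    length_family: LengthDistribution = LengthDistribution.FIXED
    length_params: tuple[float, ...] = (20.0,)
    width_px: float = 3.0
    intensity_amplitude: float = 100.0
    background_level: float = 10.0
    noise_sd: float = 0.0
    allow_overlap: bool = False
    n_forced_crossing_pairs: int = 0
    crossing_angle_deg: tuple[float, float] = (18.0, 22.0)
    min_length_um: float = 2.0
    max_length_um: float | None = None
    margin_px: int = 4
    clearance_px: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_needles < 0 or self.n_forced_crossing_pairs < 0:
            raise ValueError("needle counts must be >= 0")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")
        if self.intensity_amplitude <= 0:
            raise ValueError("intensity_amplitude must be > 0")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background_level and noise_sd must be >= 0")
        self.length_family = LengthDistribution(self.length_family)


@dataclass
class NeedleTruth:
    """Ground truth for one rendered needle."""

    center: tuple[float, float]
    orientation_deg: float
    true_length_um: float
    true_width_px: float
    pixels: np.ndarray  # (n, 2) int coordinates with coverage > 0.5


@dataclass
class NeedleGroundTruth:
    needles: list[NeedleTruth]
    crossing_pairs: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "needles": [
                {
                    "center": list(n.center),
                    "orientation_deg": n.orientation_deg,
                    "true_length_um": n.true_length_um,
                    "true_width_px": n.true_width_px,
                    "pixels": np.asarray(n.pixels).tolist(),
                }
                for n in self.needles
            ],
            "crossing_pairs": [list(p) for p in self.crossing_pairs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeedleGroundTruth":
        return cls(
            needles=[
                NeedleTruth(
                    center=tuple(n["center"]),
                    orientation_deg=n["orientation_deg"],
                    true_length_um=n["true_length_um"],
                    true_width_px=n["true_width_px"],
                    pixels=np.asarray(n["pixels"], dtype=int),
                )
                for n in d["needles"]
            ],
            crossing_pairs=[tuple(p) for p in d["crossing_pairs"]],
        )


def _needle_coverage_patch(
    shape: tuple[int, int],
    center: tuple[float, float],
    theta_deg: float,
    length_px: float,
    width_px: float,
) -> tuple[slice, slice, np.ndarray]:
    """Anti-aliased coverage of a rotated rectangle, on its bounding patch.

    Coverage per pixel is the separable product of clipped axis distances —
    an area-weighting approximation exact for axis-aligned edges and within
    a fraction of a pixel for rotated ones.
    """
    th = math.radians(theta_deg)
    d = np.array([math.sin(th), math.cos(th)])  # unit vector (drow, dcol)
    nvec = np.array([-d[1], d[0]])
    half_diag = 0.5 * math.hypot(length_px, width_px) + 1.5
    r0 = max(0, int(math.floor(center[0] - half_diag)))
    r1 = min(shape[0], int(math.ceil(center[0] + half_diag)) + 1)
    c0 = max(0, int(math.floor(center[1] - half_diag)))
    c1 = min(shape[1], int(math.ceil(center[1] + half_diag)) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - center[0]
    dc = cc - center[1]
    dpar = np.abs(dr * d[0] + dc * d[1])
    dperp = np.abs(dr * nvec[0] + dc * nvec[1])
    cov = np.clip(length_px / 2 - dpar + 0.5, 0.0, 1.0) * np.clip(
        width_px / 2 - dperp + 0.5, 0.0, 1.0
    )
    return slice(r0, r1), slice(c0, c1), cov


def _draw_length_um(rng: np.random.Generator, params: NeedleFieldParams) -> float:
    fam, p = params.length_family, params.length_params
    if fam is LengthDistribution.FIXED:
        length = p[0]
    elif fam is LengthDistribution.GAMMA:
        length = rng.gamma(shape=p[0], scale=p[1])
    else:
        length = math.exp(rng.normal(p[0], p[1]))
    lo = params.min_length_um
    hi = params.max_length_um if params.max_length_um is not None else math.inf
    return float(min(max(length, lo), hi))


def generate_needle_field(
    params: NeedleFieldParams,
) -> tuple[IntensityImage, NeedleGroundTruth]:
    """Render a needle field and its exact ground truth.

    Needles are anti-aliased rotated rectangles at ``intensity_amplitude``
    over ``background_level`` with additive Gaussian noise. When
    ``allow_overlap`` is false, independent needles are placed with a
    ``clearance_px`` pixel buffer between them (rejection sampling; a
    placement failure after bounded retries raises). Forced crossing pairs
    are two needles intersecting near their midpoints at a shallow relative
    angle drawn from ``crossing_angle_deg``.

    The ground-truth pixel set of a needle is the set of pixels with
    rendering coverage > 0.5, i.e. exactly the pixels recovered by
    thresholding the noiseless image at background + amplitude/2.
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.image_shape)
    img = np.full(shape, float(params.background_level))
    occupancy = np.zeros(shape, dtype=bool)
    needles: list[NeedleTruth] = []
    crossing_pairs: list[tuple[int, int]] = []

    from scipy import ndimage as ndi

    def try_place(length_px: float, width_px: float, forced: tuple | None = None, partner_cov=None):
        max_retries = 300
        for _ in range(max_retries):
            if forced is None:
                theta = rng.uniform(0.0, 180.0)
                half = 0.5 * math.hypot(length_px, width_px)
                lo = params.margin_px + half
                if lo >= shape[0] - lo or lo >= shape[1] - lo:
                    raise ValueError("needle too long for the image at the required margin")
                center = (rng.uniform(lo, shape[0] - lo), rng.uniform(lo, shape[1] - lo))
            else:
                center, theta = forced
                half = 0.5 * math.hypot(length_px, width_px)
                if not (
                    half + 1 < center[0] < shape[0] - half - 1
                    and half + 1 < center[1] < shape[1] - half - 1
                ):
                    return None
            rs, cs, cov = _needle_coverage_patch(shape, center, theta, length_px, width_px)
            core = cov > 0.5
            if not params.allow_overlap:
                # clearance against previously placed needles
                grown = ndi.binary_dilation(core, iterations=params.clearance_px)
                occ = occupancy[rs, cs]
                if partner_cov is not None:
                    occ = occ & ~partner_cov[rs, cs]
                if np.any(grown & occ):
                    if forced is not None:
                        return None
                    continue
            return center, theta, rs, cs, cov, core
        raise ValueError(
            f"could not place a needle of {length_px:.0f} px without overlap after "
            f"{max_retries} retries; reduce n_needles or allow_overlap"
        )

    def commit(center, theta, rs, cs, cov, core, length_um, width_px) -> int:
        img[rs, cs] += params.intensity_amplitude * cov
        occupancy[rs, cs] |= core
        offset = np.argwhere(core)
        offset[:, 0] += rs.start
        offset[:, 1] += cs.start
        needles.append(
            NeedleTruth(
                center=(float(center[0]), float(center[1])),
                orientation_deg=float(theta % 180.0),
                true_length_um=float(length_um),
                true_width_px=float(width_px),
                pixels=offset,
            )
        )
        return len(needles) - 1

    # independent needles
    for _ in range(params.n_needles):
        length_um = _draw_length_um(rng, params)
        length_px = length_um / params.pixel_size_um
        placed = try_place(length_px, params.width_px)
        commit(*placed, length_um, params.width_px)

    # forced crossing pairs: partner intersects the first needle near both
    # midpoints at a shallow relative angle
    for _ in range(params.n_forced_crossing_pairs):
        for _attempt in range(300):
            length_um_a = _draw_length_um(rng, params)
            length_px_a = length_um_a / params.pixel_size_um
            placed_a = try_place(length_px_a, params.width_px)
            center_a, theta_a = placed_a[0], placed_a[1]
            cov_a_full = np.zeros(shape)
            cov_a_full[placed_a[2], placed_a[3]] = placed_a[4]
            core_a_full = np.zeros(shape, dtype=bool)
            core_a_full[placed_a[2], placed_a[3]] = placed_a[5]

            length_um_b = _draw_length_um(rng, params)
            length_px_b = length_um_b / params.pixel_size_um
            dtheta = rng.uniform(*params.crossing_angle_deg) * rng.choice([-1.0, 1.0])
            # shift the partner's midpoint slightly along needle A
            t = rng.uniform(-0.1, 0.1) * length_px_a
            tha = math.radians(theta_a)
            center_b = (center_a[0] + t * math.sin(tha), center_a[1] + t * math.cos(tha))
            placed_b = try_place(
                length_px_b,
                params.width_px,
                forced=(center_b, theta_a + dtheta),
                partner_cov=core_a_full,
            )
            if placed_b is None:
                continue
            ia = commit(*placed_a, length_um_a, params.width_px)
            ib = commit(*placed_b, length_um_b, params.width_px)
            crossing_pairs.append((ia, ib))
            break
        else:
            raise ValueError("could not place a forced crossing pair; scene too crowded")

    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=shape)
    img = np.clip(img, 0.0, None)

    image = IntensityImage(img, pixel_size_um=params.pixel_size_um, channel_label=ChannelLabel.SHG)
    return image, NeedleGroundTruth(needles=needles, crossing_pairs=crossing_pairs)


# ---------------------------------------------------------------------------
# Hyperspectral cubes
# ---------------------------------------------------------------------------


@dataclass
class SpectralScene:
    """Per-pixel composition of a synthetic hyperspectral field.

    Either ``class_map`` (one SceneClass per pixel) or ``mixture_map``
    (per-pixel non-negative weights over ``species_order`` summing to 1 —
    all-zero rows mean background) defines the composition.
    """

    class_map: np.ndarray | None = None
    mixture_map: np.ndarray | None = None
    species_order: tuple[Species, ...] = tuple(Species)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.class_map is None) == (self.mixture_map is None):
            raise ValueError("provide exactly one of class_map or mixture_map")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mixture_map is not None:
            m = np.asarray(self.mixture_map, dtype=np.float64)
            if m.ndim != 3 or m.shape[2] != len(self.species_order):
                raise ValueError("mixture_map must be (row, col, n_species)")
            if m.min() < -1e-12:
                raise ValueError("mixture weights must be non-negative")
            sums = m.sum(axis=2)
            bad = np.abs(sums - 1.0) > 1e-9
            if np.any(bad & (sums > 1e-12)):
                raise ValueError("mixture weights must sum to 1 (or 0 for background)")
            self.mixture_map = m

    @property
    def spatial_shape(self) -> tuple[int, int]:
        src = self.class_map if self.class_map is not None else self.mixture_map
        return src.shape[:2]  # type: ignore[union-attr]


def generate_cube(
    scene: SpectralScene,
    axis: WavenumberAxis,
    band_table: dict[Species, list[tuple[float, float, float]]] | None = None,
    pixel_size_um: float = 0.5,
) -> tuple[HyperspectralCube, SpectralScene]:
    """Render a scene into a hyperspectral cube.

    Each pixel's spectrum is the weighted sum of the peak-normalized
    reference spectra of its class (or mixture weights) plus i.i.d. Gaussian
    noise of sd ``scene.noise_sd``. The scene itself is returned as ground
    truth.
    """
    band_table = DEFAULT_BAND_TABLE if band_table is None else band_table
    refs = {
        sp: synth_reference_spectrum(sp, axis, band_table).intensities
        for sp in scene.species_order
    }
    nchan = axis.n_channels
    shape = scene.spatial_shape
    data = np.zeros(shape + (nchan,), dtype=np.float64)

    if scene.class_map is not None:
        cmap = np.asarray(scene.class_map)
        for cls in np.unique(cmap):
            cls_enum = SceneClass(cls)
            if cls_enum not in CLASS_WEIGHTS:
                raise ValueError(f"scene class {cls_enum} has no species mapping")
            weights = CLASS_WEIGHTS[cls_enum]
            if not weights:
                continue
            spec = np.zeros(nchan)
            for sp, wgt in weights.items():
                spec += wgt * refs[sp]
            data[cmap == cls] = spec
    else:
        m = scene.mixture_map
        basis = np.stack([refs[sp] for sp in scene.species_order], axis=0)  # (s, chan)
        data = np.tensordot(m, basis, axes=([2], [0]))

    if scene.noise_sd > 0:
        rng = np.random.default_rng(scene.seed)
        data = data + rng.normal(0.0, scene.noise_sd, size=data.shape)

    cube = HyperspectralCube(data, axis=axis, pixel_size_um=pixel_size_um)
    return cube, scene


# ---------------------------------------------------------------------------
# Reflectance sections
# ---------------------------------------------------------------------------


def generate_reflectance_section(
    shape: tuple[int, int],
    plaque_ellipse: tuple[float, float, float, float],
    crystal_fraction: float,
    seed: int = 0,
    plaque_level: float = 0.25,
    exterior_level: float = 0.05,
    crystal_level: float = 1.0,
    noise_sd: float = 0.01,
) -> tuple[IntensityImage, np.ndarray, np.ndarray]:
    """Render a reflectance section with known crystal burden.

    Parameters
    ----------
    plaque_ellipse
        (center_row, center_col, radius_row, radius_col) of the plaque body;
        must lie inside the image.
    crystal_fraction
        Target fraction of plaque pixels covered by bright crystal specks.
        Met exactly up to quantization: the speck pixel count is
        ``round(fraction * n_plaque)``.

    Returns
    -------
    (image, plaque_mask, crystal_mask)
        Crystal specks are grown as small clusters from random seeds inside
        the plaque until the pixel budget is met, so
        ``crystal_mask ⊆ plaque_mask`` holds by construction.
    """
    if not 0.0 <= crystal_fraction <= 1.0:
        raise ValueError(f"crystal_fraction must be in [0, 1], got {crystal_fraction}")
    cr, cc, ar, ac = plaque_ellipse
    if cr - ar < 0 or cc - ac < 0 or cr + ar > shape[0] - 1 or cc + ac > shape[1] - 1:
        raise ValueError("plaque ellipse extends outside the image")
    rr, ccg = np.mgrid[0 : shape[0], 0 : shape[1]]
    plaque_mask = ((rr - cr) / ar) ** 2 + ((ccg - cc) / ac) ** 2 <= 1.0

    rng = np.random.default_rng(seed)
    n_plaque = int(plaque_mask.sum())
    budget = int(round(crystal_fraction * n_plaque))
    crystal_mask = np.zeros(shape, dtype=bool)
    plaque_coords = np.argwhere(plaque_mask)
    placed = 0
    while placed < budget:
        seed_px = plaque_coords[rng.integers(len(plaque_coords))]
        blob_r = rng.integers(1, 4)  # speck radius 1-3 px
        r0, c0 = seed_px
        rr2, cc2 = np.mgrid[
            max(0, r0 - blob_r) : min(shape[0], r0 + blob_r + 1),
            max(0, c0 - blob_r) : min(shape[1], c0 + blob_r + 1),
        ]
        blob = (rr2 - r0) ** 2 + (cc2 - c0) ** 2 <= blob_r**2
        cand = np.stack([rr2[blob], cc2[blob]], axis=1)
        for r, c in cand:
            if placed >= budget:
                break
            if plaque_mask[r, c] and not crystal_mask[r, c]:
                crystal_mask[r, c] = True
                placed += 1

    img = np.full(shape, exterior_level)
    img[plaque_mask] = plaque_level
    img[crystal_mask] = crystal_level
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(img, 0.0, None)
    image = IntensityImage(img, pixel_size_um=1.0, channel_label=ChannelLabel.REFLECTANCE)
    return image, plaque_mask, crystal_mask
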