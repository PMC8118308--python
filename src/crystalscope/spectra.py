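"""ROI spectral analysis of hyperspectral cubes: extraction, smoothing,
reference decomposition and composition calling.

The workflow mirrors how crystal composition is read out from vibrational
micro-spectroscopy: extract the mean spectrum of a region of interest,
compare it against reference spectra of cholesterol monohydrate, cholesteryl
oleate, cholesteryl linoleate and protein by non-negative least squares, and
flag the diagnostic bands — the =C-H stretch near 3010 cm^-1 (unsaturated
acyl chains, stronger in linoleate than oleate) on CH-stretch axes, and the
ester carbonyl near 1740 cm^-1 (present in cholesteryl esters, absent in
free cholesterol) on fingerprint axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import nnls
from scipy.signal import find_peaks, peak_prominences, savgol_filter

from .io import HyperspectralCube, Roi, Spectrum, WavenumberAxis, read_spectrum, roi_pixels
from .synth import DEFAULT_BAND_TABLE, Species, synth_reference_spectrum

__all__ = [
    "DominantClass",
    "BandWindow",
    "ReferenceLibrary",
    "CompositionConfig",
    "CompositionCall",
    "extract_roi_spectrum",
    "smooth_spectrum",
    "decompose_spectrum",
    "detect_band",
    "classify_composition",
]


class DominantClass(str, Enum):
    CE_DOMINANT = "CE_DOMINANT"
    FREE_CHOLESTEROL = "FREE_CHOLESTEROL"
    PROTEIN = "PROTEIN"
    AMORPHOUS_LIPID = "AMORPHOUS_LIPID"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class BandWindow:
    """Diagnostic band search window."""

    center_cm1: float
    half_width_cm1: float = 20.0
    min_prominence: float = 0.12  # fraction of the spectrum dynamic range


UNSATURATION_WINDOW = BandWindow(3010.0, 20.0, 0.12)
ESTER_WINDOW = BandWindow(1740.0, 20.0, 0.12)

CE_SPECIES = (Species.CHOLESTERYL_OLEATE, Species.CHOLESTERYL_LINOLEATE)


@dataclass
class ReferenceLibrary:
    """Named reference spectra on one common axis, peak-normalized."""

    entries: dict[Species, Spectrum]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("reference library is empty")
        axes = [e.wavenumbers_cm1 for e in self.entries.values()]
        for a in axes[1:]:
            if a.shape != axes[0].shape or not np.allclose(a, axes[0]):
                raise ValueError("all library entries must share one wavenumber axis")
        for sp, e in self.entries.items():
            peak = e.intensities.max()
            if peak <= 0:
                raise ValueError(f"library entry {sp} has non-positive peak")
            if abs(peak - 1.0) > 1e-9:
                self.entries[sp] = Spectrum(e.wavenumbers_cm1, e.intensities / peak, e.label)

    @property
    def wavenumbers_cm1(self) -> np.ndarray:
        return next(iter(self.entries.values())).wavenumbers_cm1

    @property
    def species(self) -> list[Species]:
        return list(self.entries)

    def matrix(self) -> np.ndarray:
        """(n_channels, n_species) design matrix."""
        return np.stack([self.entries[sp].intensities for sp in self.entries], axis=1)

    @classmethod
    def from_band_model(
        cls,
        axis: WavenumberAxis,
        band_table: dict | None = None,
        species: tuple[Species, ...] = tuple(Species),
    ) -> "ReferenceLibrary":
        band_table = DEFAULT_BAND_TABLE if band_table is None else band_table
        return cls({sp: synth_reference_spectrum(sp, axis, band_table) for sp in species})

    @classmethod
    def from_directory(cls, path: str | Path) -> "ReferenceLibrary":
        """Load one ``<SPECIES>.csv`` spectrum per species from a directory."""
        path = Path(path)
        entries: dict[Species, Spectrum] = {}
        for sp in Species:
            f = path / f"{sp.value}.csv"
            if f.exists():
                entries[sp] = read_spectrum(f, label=sp.value)
        if not entries:
            raise ValueError(f"no reference spectra found under {path}")
        return cls(entries)


@dataclass
class CompositionConfig:
    """Composition-calling thresholds.

    ce_fraction_min
        Pooled oleate+linoleate fraction above which a spectrum is called
        CE-dominated.
    residual_max
        Relative RMS residual below which an unclassified mixture is called
        amorphous lipid rather than indeterminate.
    """

    ce_fraction_min: float = 0.5
    residual_max: float = 0.1
    unsaturation_window: BandWindow = UNSATURATION_WINDOW
    ester_window: BandWindow = ESTER_WINDOW


@dataclass
class CompositionCall:
    coefficients: dict[Species, float]
    fractions: dict[Species, float]
    residual_rms: float
    unsaturation_band_present: bool | None
    ester_band_present: bool | None
    dominant_class: DominantClass

    def to_dict(self) -> dict:
        return {
            "coefficients": {k.value: v for k, v in self.coefficients.items()},
            "fractions": {k.value: v for k, v in self.fractions.items()},
            "residual_rms": self.residual_rms,
            "unsaturation_band_present": self.unsaturation_band_present,
            "ester_band_present": self.ester_band_present,
            "dominant_class": self.dominant_class.value,
        }


def extract_roi_spectrum(cube: HyperspectralCube, roi: Roi, label: str | None = None) -> Spectrum:
    """Per-channel mean intensity over the ROI pixel set."""
    coords = roi_pixels(roi, cube.spatial_shape)
    vals = cube.data[coords[:, 0], coords[:, 1], :]
    return Spectrum(
        cube.axis.values(),
        vals.mean(axis=0),
        label=label if label is not None else roi.name,
    )


def smooth_spectrum(spectrum: Spectrum, resample_step_cm1: float = 1.0) -> Spectrum:
    """Cubic-spline interpolation onto a finer axis.

    The interpolant passes exactly through the original samples and
    reproduces polynomials up to degree 3 (natural-spline boundary effects
    aside, a not-a-knot spline is used).

    Raises
    ------
    ValueError
        If fewer than 4 points, or the requested step is not finer than the
        original sampling.
    """
    w = spectrum.wavenumbers_cm1
    if len(w) < 4:
        raise ValueError("smoothing requires at least 4 spectral points")
    orig_step = np.min(np.diff(w))
    if resample_step_cm1 >= orig_step:
        raise ValueError(
            f"resample step ({resample_step_cm1}) must be finer than the original "
            f"sampling ({orig_step})"
        )
    spline = CubicSpline(w, spectrum.intensities)  # not-a-knot
    n = int(np.floor((w[-1] - w[0]) / resample_step_cm1)) + 1
    fine = w[0] + resample_step_cm1 * np.arange(n)
    return Spectrum(fine, spline(fine), label=spectrum.label)


def _preprocess(intensities: np.ndarray) -> np.ndarray:
    """Baseline-subtract (spectrum minimum) and peak-normalize."""
    y = intensities - intensities.min()
    peak = y.max()
    if peak <= 0:
        raise ValueError("flat spectrum cannot be normalized")
    return y / peak


def decompose_spectrum(
    spectrum: Spectrum, library: ReferenceLibrary
) -> tuple[dict[Species, float], float]:
    """Non-negative least-squares fit of the spectrum in the reference basis.

    The spectrum is baseline-subtracted (minimum) and peak-normalized before
    fitting, so the result is invariant to positive scaling of the input.

    Returns
    -------
    (coefficients, residual_rms)
        Conic-combination coefficients per species and the root-mean-square
        of the fit residual (on the normalized scale).
    """
    w = spectrum.wavenumbers_cm1
    lw = library.wavenumbers_cm1
    if w.shape != lw.shape or not np.allclose(w, lw):
        raise ValueError("spectrum and library must share one wavenumber axis")
    y = _preprocess(spectrum.intensities)
    A = library.matrix()
    coef, rnorm = nnls(A, y)
    residual_rms = rnorm / np.sqrt(len(y))
    return dict(zip(library.species, coef)), float(residual_rms)


def detect_band(
    spectrum: Spectrum,
    window: BandWindow,
    resample_step_cm1: float = 1.0,
    denoise_window: int = 7,
) -> tuple[bool, float | None, float]:
    """Detect a local maximum inside a diagnostic window.

    The sampled trace is lightly denoised (Savitzky-Golay, quadratic, over
    ``denoise_window`` samples) so that channel noise does not masquerade as
    a band, then spline-resampled to ``resample_step_cm1``; local maxima are
    located over the full trace (endpoints are never peaks), and the band is
    present iff a peak inside the window has topographic prominence >=
    ``window.min_prominence`` times the spectrum's dynamic range.

    Returns
    -------
    (present, peak_cm1, prominence)
        Position and prominence of the best in-window peak; ``peak_cm1`` is
        None when no in-window local maximum exists.
    """
    w = spectrum.wavenumbers_cm1
    lo, hi = window.center_cm1 - window.half_width_cm1, window.center_cm1 + window.half_width_cm1
    if lo < w[0] or hi > w[-1]:
        raise ValueError(
            f"band window [{lo}, {hi}] cm^-1 outside the spectrum axis [{w[0]}, {w[-1]}]"
        )
    if denoise_window >= 5 and len(w) >= denoise_window:
        spectrum = Spectrum(
            w, savgol_filter(spectrum.intensities, denoise_window, 2), spectrum.label
        )
    step = np.min(np.diff(w))
    if step > resample_step_cm1 and len(w) >= 4:
        spectrum = smooth_spectrum(spectrum, resample_step_cm1)
        w = spectrum.wavenumbers_cm1
    y = spectrum.intensities
    peaks, _ = find_peaks(y)
    if len(peaks) == 0:
        return False, None, 0.0
    in_window = peaks[(w[peaks] >= lo) & (w[peaks] <= hi)]
    if len(in_window) == 0:
        return False, None, 0.0
    prominences = peak_prominences(y, in_window)[0]
    best = int(np.argmax(prominences))
    scale = y.max() - y.min()
    prom = float(prominences[best]) / scale if scale > 0 else 0.0
    present = bool(prom >= window.min_prominence)
    return present, float(w[in_window[best]]), prom


def _axis_kind(w: np.ndarray, config: CompositionConfig) -> str:
    """CH-stretch, fingerprint, or neither (error)."""
    uw = config.unsaturation_window
    ew = config.ester_window
    covers_unsat = w[0] <= uw.center_cm1 - uw.half_width_cm1 and w[-1] >= uw.center_cm1 + uw.half_width_cm1
    covers_ester = w[0] <= ew.center_cm1 - ew.half_width_cm1 and w[-1] >= ew.center_cm1 + ew.half_width_cm1
    if covers_unsat and w[0] >= 2000:
        return "ch_stretch"
    if covers_ester:
        return "fingerprint"
    raise ValueError(
        "spectrum axis covers neither the CH-stretch (3010 cm^-1) nor the "
        "fingerprint (1740 cm^-1) diagnostic region"
    )


def classify_composition(
    spectrum: Spectrum,
    library: ReferenceLibrary,
    config: CompositionConfig | None = None,
) -> CompositionCall:
    """Decompose a spectrum and call its dominant composition class.

    Rules, in order: CE_DOMINANT if the pooled cholesteryl-ester fraction
    (oleate + linoleate) exceeds ``ce_fraction_min``; FREE_CHOLESTEROL if
    the cholesterol-monohydrate fraction exceeds 0.5; PROTEIN if the
    protein fraction exceeds 0.5; otherwise AMORPHOUS_LIPID when the fit
    residual is small, else INDETERMINATE. The unsaturation (3010 cm^-1)
    flag is attached on CH-stretch axes and the ester (1740 cm^-1) flag on
    fingerprint axes; the other flag is None.
    """
    config = config or CompositionConfig()
    kind = _axis_kind(spectrum.wavenumbers_cm1, config)
    coefficients, residual_rms = decompose_spectrum(spectrum, library)
    total = sum(coefficients.values())
    if total > 0:
        fractions = {sp: c / total for sp, c in coefficients.items()}
    else:
        fractions = {sp: 0.0 for sp in coefficients}

    ce_fraction = sum(fractions.get(sp, 0.0) for sp in CE_SPECIES)
    if total > 0 and ce_fraction > config.ce_fraction_min:
        dominant = DominantClass.CE_DOMINANT
    elif fractions.get(Species.CHOLESTEROL_MONOHYDRATE, 0.0) > 0.5:
        dominant = DominantClass.FREE_CHOLESTEROL
    elif fractions.get(Species.PROTEIN, 0.0) > 0.5:
        dominant = DominantClass.PROTEIN
    elif residual_rms < config.residual_max and total > 0:
        dominant = DominantClass.AMORPHOUS_LIPID
    else:
        dominant = DominantClass.INDETERMINATE

    unsat = ester = None
    if kind == "ch_stretch":
        unsat = detect_band(spectrum, config.unsaturation_window)[0]
    else:
        ester = detect_band(spectrum, config.ester_window)[0]

    return CompositionCall(
        coefficients=coefficients,
        fractions=fractions,
        residual_rms=residual_rms,
        unsaturation_band_present=unsat,
        ester_band_present=ester,
        dominant_class=dominant,
    )
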