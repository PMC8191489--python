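"""Excitation-emission matrix (EEM) fluorometry for rhodamine WT (RWT).

The quantitation chain mirrors standard aqueous-fluorescence practice:

1. *Background correction*: subtract the mean intensity of a low-signal
   rectangle of the EEM from the whole spectrum.
2. *Raman normalisation*: divide by the integrated water-Raman scatter
   peak of a pure-water blank, putting intensities in Raman Units (RU)
   so different instrument sessions are comparable.
3. *Calibration*: fit intensity-vs-concentration for standards of known
   RWT concentration; the three grid points with the highest response
   per ppb (near the RWT maximum at excitation/emission 558/582 nm)
   become the quantitation peaks, and the per-pixel response map becomes
   the reference spectral pattern.
4. *Quantitation*: mean intensity at the three peaks, through the
   inverse calibration line, floored at zero.
5. *Pattern detection*: an EEM "shows RWT" when its centred correlation
   with the reference pattern over the signal region clears a threshold
   and each quantitation peak is a local maximum.

Unit state moves strictly raw -> background_corrected -> raman_units.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

UNIT_STATES = ("raw", "background_corrected", "raman_units")

#: wavelength (nm) of maximum RWT fluorescence, excitation/emission
RWT_PEAK_EX_NM = 558.0
RWT_PEAK_EM_NM = 582.0


class UnitStateError(RuntimeError):
    """Raised when an EEM is in the wrong processing state for an operation."""


@dataclass
class EEM:
    """Fluorescence intensity on an excitation x emission wavelength grid."""

    excitation_nm: np.ndarray
    emission_nm: np.ndarray
    intensity: np.ndarray
    unit_state: str = "raw"

    def __post_init__(self) -> None:
        self.excitation_nm = np.asarray(self.excitation_nm, dtype=float)
        self.emission_nm = np.asarray(self.emission_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        for grid, name in ((self.excitation_nm, "excitation"), (self.emission_nm, "emission")):
            if grid.ndim != 1 or len(grid) < 2:
                raise ValueError(f"{name} grid must be 1-D with >= 2 points")
            if np.any(np.diff(grid) <= 0):
                raise ValueError(f"{name} grid must be strictly increasing")
        if self.intensity.shape != (len(self.excitation_nm), len(self.emission_nm)):
            raise ValueError("intensity must be (n_excitation, n_emission)")
        if self.unit_state not in UNIT_STATES:
            raise ValueError(f"unknown unit_state {self.unit_state!r}")

    def same_grids(self, other: "EEM") -> bool:
        return (
            self.excitation_nm.shape == other.excitation_nm.shape
            and self.emission_nm.shape == other.emission_nm.shape
            and np.allclose(self.excitation_nm, other.excitation_nm)
            and np.allclose(self.emission_nm, other.emission_nm)
        )

    def index_of(self, ex_nm: float, em_nm: float) -> tuple:
        """Indices of the grid point nearest (ex_nm, em_nm)."""
        i = int(np.argmin(np.abs(self.excitation_nm - ex_nm)))
        j = int(np.argmin(np.abs(self.emission_nm - em_nm)))
        return i, j

    def with_intensity(self, intensity: np.ndarray, unit_state: str) -> "EEM":
        return EEM(self.excitation_nm.copy(), self.emission_nm.copy(), intensity, unit_state)


def acquisition_grids(
    ex_start: float = 425.0,
    ex_stop: float = 625.0,
    ex_step: float = 5.0,
    em_start: float = 248.0,
    em_stop: float = 827.0,
    em_step: float = 4.5,
):
    """The spectrometer acquisition grids used for aerosol samples:
    excitation 425-625 nm at 5 nm steps, emission 248-~824 nm at 4.5 nm."""
    ex = np.arange(ex_start, ex_stop + 0.5 * ex_step, ex_step)
    em = np.arange(em_start, em_stop + 1e-9, em_step)
    return ex, em


@dataclass(frozen=True)
class WavelengthRect:
    """An (excitation x emission) wavelength rectangle, inclusive bounds in nm."""

    ex_min: float
    ex_max: float
    em_min: float
    em_max: float

    def mask(self, eem: EEM) -> np.ndarray:
        ex_ok = (eem.excitation_nm >= self.ex_min) & (eem.excitation_nm <= self.ex_max)
        em_ok = (eem.emission_nm >= self.em_min) & (eem.emission_nm <= self.em_max)
        return np.outer(ex_ok, em_ok)


#: default background-correction region: the low-signal corner at highest
#: excitation / shortest emission, far from both the RWT peak and the
#: water-Raman ridge.  Configurable; instrument-specific in practice.
DEFAULT_BACKGROUND_RECT = WavelengthRect(600.0, 625.0, 248.0, 300.0)

#: window in which quantitation peaks are searched, bracketing the RWT
#: fluorescence maximum so noise spikes elsewhere cannot be selected
DEFAULT_PEAK_WINDOW = WavelengthRect(533.0, 583.0, 552.0, 612.0)

#: region over which the spectral-pattern correlation is evaluated; kept
#: clear of the water-Raman ridge (emission ~614 nm and longer only for
#: excitation below ~528 nm, outside this rectangle)
DEFAULT_SIGNAL_REGION = WavelengthRect(533.0, 608.0, 537.0, 627.0)


@dataclass(frozen=True)
class RamanBand:
    """Excitation line and emission band of the water-Raman scatter peak.

    The common convention is excitation 350 nm with emission integrated
    over 380-420 nm; when the acquisition grid does not reach 350 nm the
    band must be moved onto the grid (the Raman ridge follows a constant
    ~3400 cm^-1 shift, so any on-grid excitation line works).
    """

    excitation_nm: float = 350.0
    emission_min_nm: float = 380.0
    emission_max_nm: float = 420.0


def raman_shifted_emission(excitation_nm, shift_cm1: float = 3400.0):
    """Emission wavelength (nm) of the water-Raman peak for a given
    excitation line, at the given Stokes shift in cm^-1."""
    ex = np.asarray(excitation_nm, dtype=float)
    return 1.0 / (1.0 / ex - shift_cm1 * 1e-7)


# ---------------------------------------------------------------------------
# processing steps


def background_correct(eem: EEM, rect: WavelengthRect = DEFAULT_BACKGROUND_RECT) -> EEM:
    """Subtract the mean intensity inside ``rect`` from the whole spectrum.

    Idempotent for a fixed rectangle: after the first pass the rectangle
    mean is zero, so a second pass changes nothing.
    """
    if eem.unit_state not in ("raw", "background_corrected"):
        raise UnitStateError("background correction applies before Raman normalisation")
    mask = rect.mask(eem)
    if not mask.any():
        raise ValueError("background rectangle lies outside the EEM grids")
    corrected = eem.intensity - eem.intensity[mask].mean()
    return eem.with_intensity(corrected, "background_corrected")


def raman_area(reference: EEM, band: RamanBand) -> float:
    """Integrated water-Raman peak of a pure-water reference scan
    (trapezoidal over the emission band at the band's excitation line)."""
    i = int(np.argmin(np.abs(reference.excitation_nm - band.excitation_nm)))
    if abs(reference.excitation_nm[i] - band.excitation_nm) > 5.0:
        raise ValueError(
            f"Raman excitation line {band.excitation_nm} nm is not on the grid "
            f"(nearest {reference.excitation_nm[i]} nm)"
        )
    sel = (reference.emission_nm >= band.emission_min_nm) & (
        reference.emission_nm <= band.emission_max_nm
    )
    if sel.sum() < 2:
        raise ValueError("Raman emission band covers fewer than two grid points")
    area = float(np.trapezoid(reference.intensity[i, sel], reference.emission_nm[sel]))
    if area <= 0:
        raise ValueError("non-positive Raman peak area: invalid water reference")
    return area


def raman_normalize(eem: EEM, water_reference: EEM, band: RamanBand = RamanBand()) -> EEM:
    """Divide intensities by the water-Raman peak area of the reference,
    yielding Raman Units (RU)."""
    if eem.unit_state != "background_corrected":
        raise UnitStateError("Raman normalisation requires a background-corrected EEM")
    if not eem.same_grids(water_reference):
        raise ValueError("sample and water reference must share wavelength grids")
    area = raman_area(water_reference, band)
    return eem.with_intensity(eem.intensity / area, "raman_units")


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationModel:
    """Linear RWT calibration plus the reference spectral pattern.

    ``reference_pattern`` is the per-pixel fluorescence response per ppb
    (unit L2 norm), i.e. the shape of pure RWT after background
    correction; constant offsets (background, Raman ridge) cancel out of
    the per-pixel regression that produces it.
    """

    peak_pairs: list  # three (excitation_nm, emission_nm) tuples
    slope: float  # RU per ppb
    intercept: float  # RU
    fit_r2: float
    background_rect: WavelengthRect
    raman_band: RamanBand
    signal_region: WavelengthRect
    excitation_nm: np.ndarray
    emission_nm: np.ndarray
    reference_pattern: np.ndarray

    def __post_init__(self) -> None:
        if len(self.peak_pairs) != 3:
            raise ValueError("exactly three quantitation peak pairs are required")
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    @property
    def peak_indices(self) -> list:
        ref = EEM(self.excitation_nm, self.emission_nm, self.reference_pattern, "raman_units")
        return [ref.index_of(ex, em) for ex, em in self.peak_pairs]

    def to_yaml(self, path) -> None:
        doc = {
            "peak_pairs": [[float(a), float(b)] for a, b in self.peak_pairs],
            "slope": float(self.slope),
            "intercept": float(self.intercept),
            "fit_r2": float(self.fit_r2),
            "background_rect": list(
                (self.background_rect.ex_min, self.background_rect.ex_max,
                 self.background_rect.em_min, self.background_rect.em_max)
            ),
            "raman_band": [self.raman_band.excitation_nm,
                           self.raman_band.emission_min_nm,
                           self.raman_band.emission_max_nm],
            "signal_region": list(
                (self.signal_region.ex_min, self.signal_region.ex_max,
                 self.signal_region.em_min, self.signal_region.em_max)
            ),
            "excitation_nm": [float(v) for v in self.excitation_nm],
            "emission_nm": [float(v) for v in self.emission_nm],
            "reference_pattern": [[float(f"{v:.6g}") for v in row]
                                  for row in self.reference_pattern],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            peak_pairs=[tuple(p) for p in doc["peak_pairs"]],
            slope=doc["slope"],
            intercept=doc["intercept"],
            fit_r2=doc["fit_r2"],
            background_rect=WavelengthRect(*doc["background_rect"]),
            raman_band=RamanBand(*doc["raman_band"]),
            signal_region=WavelengthRect(*doc["signal_region"]),
            excitation_nm=np.asarray(doc["excitation_nm"], dtype=float),
            emission_nm=np.asarray(doc["emission_nm"], dtype=float),
            reference_pattern=np.asarray(doc["reference_pattern"], dtype=float),
        )


def fit_calibration(
    standards,
    peak_window: WavelengthRect = DEFAULT_PEAK_WINDOW,
    signal_region: WavelengthRect = DEFAULT_SIGNAL_REGION,
    background_rect: WavelengthRect = DEFAULT_BACKGROUND_RECT,
    raman_band: RamanBand = RamanBand(),
) -> CalibrationModel:
    """Fit the calibration line from ``standards`` = [(ppb, EEM), ...].

    Standards must already be in Raman Units.  The per-pixel least-squares
    response map (RU per ppb) supplies both the reference pattern and the
    peak ranking; the three best pixels inside ``peak_window`` become the
    quantitation peaks; mean-of-three-peaks intensity vs concentration is
    fit by ordinary least squares.
    """
    if len(standards) < 3:
        raise ValueError("at least three calibration standards are required")
    concs = np.array([c for c, _ in standards], dtype=float)
    if np.ptp(concs) <= 0:
        raise ValueError("calibration standards must span a positive concentration range")
    eems = [e for _, e in standards]
    first = eems[0]
    for e in eems:
        if e.unit_state != "raman_units":
            raise UnitStateError("standards must be processed to Raman Units")
        if not e.same_grids(first):
            raise ValueError("all standards must share wavelength grids")

    cube = np.stack([e.intensity for e in eems])  # (n, nex, nem)
    dc = concs - concs.mean()
    # per-pixel OLS slope of intensity vs concentration
    slope_map = np.tensordot(dc, cube - cube.mean(axis=0), axes=(0, 0)) / (dc @ dc)

    window = peak_window.mask(first)
    ranked = np.argsort(np.where(window, slope_map, -np.inf), axis=None)[::-1][:3]
    peak_idx = [np.unravel_index(k, slope_map.shape) for k in ranked]
    peak_pairs = [
        (float(first.excitation_nm[i]), float(first.emission_nm[j])) for i, j in peak_idx
    ]

    response = cube[:, [i for i, _ in peak_idx], [j for _, j in peak_idx]].mean(axis=1)
    fit = stats.linregress(concs, response)
    if fit.slope <= 0:
        raise ValueError("calibration slope is non-positive; check standards")

    norm = np.linalg.norm(slope_map)
    pattern = slope_map / norm if norm > 0 else slope_map
    return CalibrationModel(
        peak_pairs=peak_pairs,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        fit_r2=float(fit.rvalue**2),
        background_rect=background_rect,
        raman_band=raman_band,
        signal_region=signal_region,
        excitation_nm=first.excitation_nm.copy(),
        emission_nm=first.emission_nm.copy(),
        reference_pattern=pattern,
    )


def quantify(eem: EEM, cal: CalibrationModel) -> float:
    """RWT concentration (ppb) in the liquid, from the mean intensity at
    the three quantitation peaks through the inverse calibration line;
    floored at zero."""
    if eem.unit_state != "raman_units":
        raise UnitStateError("quantitation requires an EEM in Raman Units")
    mean3 = float(np.mean([eem.intensity[i, j] for i, j in cal.peak_indices]))
    return max(0.0, (mean3 - cal.intercept) / cal.slope)


def detect_pattern(
    eem: EEM,
    cal: CalibrationModel,
    threshold: float = 0.9,
    neighborhood: int = 2,
) -> bool:
    """True iff the EEM shows the RWT fluorescence pattern.

    Two scale-free requirements: (a) centred Pearson correlation with the
    reference pattern over the signal region >= ``threshold``; (b) each
    quantitation peak dominates its (2*neighborhood+1)^2 pixel
    neighbourhood.  The three peaks are adjacent pixels on the same
    fluorescence ridge, so each is compared against the non-peak pixels
    of its neighbourhood only.  A flat EEM is never a detection.
    """
    if eem.unit_state == "raw":
        raise UnitStateError("pattern detection requires a processed EEM")
    mask = cal.signal_region.mask(eem)
    a = eem.intensity[mask]
    b = cal.reference_pattern[mask]
    if a.std() == 0 or b.std() == 0:
        return False
    r = float(np.corrcoef(a, b)[0, 1])
    if not r >= threshold:
        return False
    n = neighborhood
    peak_set = set(cal.peak_indices)
    for i, j in cal.peak_indices:
        center = eem.intensity[i, j]
        for ii in range(max(0, i - n), min(eem.intensity.shape[0], i + n + 1)):
            for jj in range(max(0, j - n), min(eem.intensity.shape[1], j + n + 1)):
                if (ii, jj) not in peak_set and eem.intensity[ii, jj] > center:
                    return False
    return True


# ---------------------------------------------------------------------------
# long-format CSV I/O


def write_eem_csv(eem: EEM, path) -> None:
    ex, em = np.meshgrid(eem.excitation_nm, eem.emission_nm, indexing="ij")
    pd.DataFrame(
        {
            "excitation_nm": ex.ravel(),
            "emission_nm": em.ravel(),
            "intensity": eem.intensity.ravel(),
        }
    ).to_csv(path, index=False)


def read_eem_csv(path, unit_state: str = "raw") -> EEM:
    df = pd.read_csv(path)
    wide = df.pivot_table(index="excitation_nm", columns="emission_nm", values="intensity")
    wide = wide.sort_index().sort_index(axis=1)
    return EEM(
        wide.index.to_numpy(float), wide.columns.to_numpy(float), wide.to_numpy(), unit_state
    )
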