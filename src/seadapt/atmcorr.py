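"""Empirical atmospheric correction against in situ radiometry.

The chain turns shipboard radiometry at a set of stations into per-band
calibration lines for a multispectral image:

1. diffuse attenuation K(λ) from upwelling radiance at two depths
   (K = −(1/z)·ln(L(0.65)/L(0.21)) with z = 0.44 m);
2. Beer's-law propagation of L(0.21, λ) to just beneath the surface;
3. water-leaving radiance via a scalar air–water transmittance factor
   (default 0.543) and remote-sensing reflectance Rrs = Lw(0+)/Es(0+);
4. band averaging of the hyperspectral Rrs through the sensor's spectral
   response functions;
5. ordinary least squares per band: in situ = gain·image + offset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .msio import MultispectralScene

#: Default air-water interface factor relating Lu(0−) to Lw(0+):
#: t/n² with t ≈ 0.98 and n ≈ 1.34 for seawater.
DEFAULT_TRANSMITTANCE = 0.543

#: Depth separation of the two radiance sensors (m).
SENSOR_DEPTH_GAP = 0.65 - 0.21


@dataclass
class RadiometricStation:
    """Radiometry measured at one station on a common wavelength grid (nm)."""

    wavelengths: np.ndarray
    Es0plus: np.ndarray
    Lu065: np.ndarray
    Lu021: np.ndarray
    Eu021: np.ndarray | None = None  # carried through, unused by the formulas
    location: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        arrays = [self.wavelengths, self.Es0plus, self.Lu065, self.Lu021]
        lengths = {len(np.asarray(a)) for a in arrays}
        if len(lengths) != 1:
            raise ValidationError("all station spectra must share the wavelength grid")
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.Es0plus = np.asarray(self.Es0plus, dtype=np.float64)
        self.Lu065 = np.asarray(self.Lu065, dtype=np.float64)
        self.Lu021 = np.asarray(self.Lu021, dtype=np.float64)
        if self.Eu021 is not None:
            self.Eu021 = np.asarray(self.Eu021, dtype=np.float64)

    @classmethod
    def from_csv(cls, path: str | Path, location: tuple[float, float] | None = None
                 ) -> "RadiometricStation":
        """Read one station file with columns wavelength, Es0plus, Lu065,
        Lu021 and optionally Eu021."""
        df = pd.read_csv(path)
        required = ("wavelength", "Es0plus", "Lu065", "Lu021")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing columns {missing}")
        return cls(
            df["wavelength"].to_numpy(), df["Es0plus"].to_numpy(),
            df["Lu065"].to_numpy(), df["Lu021"].to_numpy(),
            df["Eu021"].to_numpy() if "Eu021" in df.columns else None,
            location,
        )


@dataclass
class SpectralResponse:
    """Per-band relative spectral response curves on wavelength grids (nm)."""

    band_names: tuple[str, ...]
    grids: list[np.ndarray]    # per band: wavelengths
    weights: list[np.ndarray]  # per band: non-negative weights

    def __post_init__(self) -> None:
        if len(self.grids) != len(self.band_names) or len(self.weights) != len(self.band_names):
            raise ValidationError("one grid and one weight vector per band required")
        for name, g, w in zip(self.band_names, self.grids, self.weights):
            w = np.asarray(w, dtype=np.float64)
            if (w < 0).any() or w.sum() <= 0:
                raise ValidationError(f"band '{name}': weights must be non-negative with positive sum")

    @property
    def n_bands(self) -> int:
        return len(self.band_names)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralResponse":
        """Read a wide CSV: a ``wavelength`` column plus one column per band."""
        df = pd.read_csv(path)
        if "wavelength" not in df.columns:
            raise ValidationError(f"{path}: needs a 'wavelength' column")
        bands = tuple(c for c in df.columns if c != "wavelength")
        grid = df["wavelength"].to_numpy(dtype=np.float64)
        return cls(bands, [grid] * len(bands), [df[b].to_numpy(dtype=np.float64) for b in bands])

    @classmethod
    def boxcars(cls, band_names, edges) -> "SpectralResponse":
        """Idealized flat responses over [lo, hi] nm intervals."""
        grids, weights = [], []
        for lo, hi in edges:
            g = np.linspace(lo, hi, 21)
            grids.append(g)
            weights.append(np.ones_like(g))
        return cls(tuple(band_names), grids, weights)


@dataclass
class BandCalibration:
    """Per-band linear calibration: in situ = gain·image + offset."""

    band_names: tuple[str, ...]
    gain: np.ndarray
    offset: np.ndarray
    r_squared: np.ndarray
    n_stations: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "band_names": list(self.band_names),
            "gain": self.gain.tolist(), "offset": self.offset.tolist(),
            "r_squared": self.r_squared.tolist(), "n_stations": self.n_stations,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BandCalibration":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["band_names"]), np.array(d["gain"]), np.array(d["offset"]),
                   np.array(d["r_squared"]), d["n_stations"])


def diffuse_attenuation(Lu065: np.ndarray, Lu021: np.ndarray,
                        z: float = SENSOR_DEPTH_GAP) -> np.ndarray:
    """Upwelling diffuse attenuation K(λ) = −(1/z)·ln(Lu(0.65)/Lu(0.21)), 1/m.

    Negative K (radiance increasing with depth) is physically odd but
    numerically defined; it is returned with a warning.
    """
    Lu065 = np.asarray(Lu065, dtype=np.float64)
    Lu021 = np.asarray(Lu021, dtype=np.float64)
    if z <= 0:
        raise ValidationError("sensor depth gap z must be positive")
    if (Lu065 <= 0).any() or (Lu021 <= 0).any():
        raise ValidationError("radiances must be positive for the attenuation log-ratio")
    K = -np.log(Lu065 / Lu021) / z
    if (K < 0).any():
        warnings.warn("negative attenuation coefficient (Lu(0.65) > Lu(0.21)) at some wavelengths",
                      stacklevel=2)
    return K


def propagate_to_surface(Lu021: np.ndarray, K: np.ndarray, depth: float = 0.21) -> np.ndarray:
    """Beer's law from 0.21 m to just beneath the surface:
    Lu(0−) = Lu(0.21)·exp(K·depth)."""
    if depth < 0:
        raise ValidationError("depth must be non-negative")
    return np.asarray(Lu021, dtype=np.float64) * np.exp(np.asarray(K, dtype=np.float64) * depth)


def water_leaving_radiance(Lu0minus: np.ndarray,
                           transmittance_factor: float = DEFAULT_TRANSMITTANCE) -> np.ndarray:
    """Lw(0+) = t·Lu(0−) with the scalar interface transmittance factor."""
    if transmittance_factor <= 0:
        raise ValidationError("transmittance factor must be positive")
    return transmittance_factor * np.asarray(Lu0minus, dtype=np.float64)


def remote_sensing_reflectance(Lw0plus: np.ndarray, Es0plus: np.ndarray) -> np.ndarray:
    """Rrs(λ) = Lw(0+, λ)/Es(0+, λ), sr⁻¹."""
    Es = np.asarray(Es0plus, dtype=np.float64)
    if (Es <= 0).any():
        raise ValidationError("downwelling irradiance must be positive")
    return np.asarray(Lw0plus, dtype=np.float64) / Es


def station_rrs(station: RadiometricStation,
                transmittance_factor: float = DEFAULT_TRANSMITTANCE) -> np.ndarray:
    """Full per-station chain: attenuation → surface propagation → Rrs(λ)."""
    K = diffuse_attenuation(station.Lu065, station.Lu021)
    Lu0m = propagate_to_surface(station.Lu021, K)
    return remote_sensing_reflectance(water_leaving_radiance(Lu0m, transmittance_factor),
                                      station.Es0plus)


def band_average(wavelengths: np.ndarray, spectrum: np.ndarray,
                 response: SpectralResponse) -> np.ndarray:
    """Response-weighted trapezoidal mean of a spectrum per band:
    ∫w·s dλ / ∫w dλ on the response grid.

    Response wavelengths outside the spectrum's range get zero weight (with a
    warning); a band whose support is entirely outside raises.
    """
    wavelengths = np.asarray(wavelengths, dtype=np.float64)
    spectrum = np.asarray(spectrum, dtype=np.float64)
    out = np.empty(response.n_bands)
    lo, hi = wavelengths.min(), wavelengths.max()
    for i, (name, grid, w) in enumerate(
            zip(response.band_names, response.grids, response.weights)):
        grid = np.asarray(grid, dtype=np.float64)
        w = np.asarray(w, dtype=np.float64).copy()
        outside = (grid < lo) | (grid > hi)
        if outside.any() and w[outside].sum() > 0:
            warnings.warn(f"band '{name}': response extends beyond the measured spectrum; "
                          "outside weights set to 0", stacklevel=2)
            w[outside] = 0.0
        denom = np.trapezoid(w, grid) if len(grid) > 1 else w.sum()
        if denom <= 0:
            raise ValidationError(f"band '{name}': no overlap between response and spectrum")
        s = np.interp(grid, wavelengths, spectrum)
        num = np.trapezoid(w * s, grid) if len(grid) > 1 else (w * s).sum()
        out[i] = num / denom
    return out


def fit_band_calibration(insitu_band_values: np.ndarray, image_band_values: np.ndarray,
                         band_names: tuple[str, ...] | None = None) -> BandCalibration:
    """Ordinary least squares per band: in situ = gain·image + offset."""
    insitu = np.atleast_2d(np.asarray(insitu_band_values, dtype=np.float64))
    image = np.atleast_2d(np.asarray(image_band_values, dtype=np.float64))
    if insitu.shape != image.shape:
        raise ValidationError("in situ and image tables must have matching S×B shapes")
    s, b = insitu.shape
    if s < 2:
        raise ValidationError("at least 2 stations are needed for a linear fit")
    band_names = band_names or tuple(f"band_{i + 1}" for i in range(b))
    gain = np.empty(b)
    offset = np.empty(b)
    r2 = np.empty(b)
    for i in range(b):
        x, y = image[:, i], insitu[:, i]
        if np.ptp(x) == 0:
            raise ValidationError(f"band '{band_names[i]}': image values are constant, fit is degenerate")
        res = stats.linregress(x, y)
        gain[i], offset[i], r2[i] = res.slope, res.intercept, res.rvalue**2
    return BandCalibration(band_names, gain, offset, r2, s)


def apply_calibration(scene: MultispectralScene, cal: BandCalibration) -> MultispectralScene:
    """Map every pixel through its band's calibration line; nodata preserved."""
    if scene.n_bands != len(cal.gain):
        raise ValidationError(f"scene has {scene.n_bands} bands, calibration has {len(cal.gain)}")
    pixels = scene.pixels * cal.gain + cal.offset
    return MultispectralScene(pixels, scene.band_names, scene.nodata_mask.copy(), scene.geo)
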