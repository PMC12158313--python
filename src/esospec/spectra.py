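"""Impedance ↔ complex permittivity conversion for a two-electrode sensor.

A sweep measured through the thoracic plexus arrives as resistance R and
reactance X per frequency bin (``Z = R + jX``).  With the electrode geometry
(surface ``S``, separation ``d``) the sweep is converted bin-wise to the
complex relative permittivity ``ε* = ε′ − jε″`` of the probed medium via the
vacuum capacitance ``C0 = ε0·S/d``:

    ε′(f) = −X / ((R² + X²) · 2πf · C0)
    ε″(f) =  R / ((R² + X²) · 2πf · C0)

which is the component form of ``ε* = 1/(jωC0·Z)``.  The ionic conductivity
follows from the loss factor, ``σ = ε0·ε″·2πf``, and the permittivity modulus
is ``|ε*| = √(ε′² + ε″²)``.  The exact analytic inverse ``Z = 1/(jωC0·ε*)``
is provided for round-trip testing and forward simulation.

Conversion is strictly bin-wise: no interpolation or resampling happens here.
The reactance keeps its measured sign; capacitive loads have X < 0, which
makes ε′ positive through the leading minus sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

#: Vacuum permittivity, F/m (CODATA).  Fixed, not user-configurable.
EPSILON_0 = 8.8541878128e-12

#: Minimum number of frequency bins for a usable sweep.
MIN_BINS = 8


class MeasurementState(IntEnum):
    """The four per-subject recordings of the study protocol."""

    EMPTY = 0   #: empty esophagus
    WATER = 1   #: drinking water
    JUICE = 2   #: drinking orange juice
    BRINE = 3   #: drinking 1% w/w saline


class GeometryError(ValueError):
    """Invalid sensor geometry (non-positive surface or separation)."""


class SpectrumError(ValueError):
    """A spectrum violates its structural invariants."""


class DegenerateImpedanceError(SpectrumError):
    """R = X = 0 at some bin: the permittivity there is undefined."""


class DegeneratePermittivityError(SpectrumError):
    """ε′ = ε″ = 0 at some bin: the impedance there is undefined."""


@dataclass(frozen=True)
class SensorGeometry:
    """Two-electrode sensor geometry.

    Parameters
    ----------
    surface : float
        Electrode surface area, m².
    separation : float
        Inter-electrode distance ``d``, m (measured per participant).
    """

    surface: float
    separation: float

    def __post_init__(self) -> None:
        if not (self.surface > 0):
            raise GeometryError(f"electrode surface must be > 0, got {self.surface}")
        if not (self.separation > 0):
            raise GeometryError(f"electrode separation must be > 0, got {self.separation}")

    @property
    def vacuum_capacitance(self) -> float:
        """Capacitance of the empty geometry, ``C0 = ε0·S/d`` (F)."""
        return EPSILON_0 * self.surface / self.separation


def vacuum_capacitance(geometry: SensorGeometry) -> float:
    """Return the vacuum capacitance ``C0 = ε0·S/d`` of *geometry* (F)."""
    return geometry.vacuum_capacitance


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise SpectrumError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise SpectrumError(f"{name} contains non-finite values")
    return arr


def _check_frequencies(frequencies: np.ndarray) -> None:
    if frequencies.size < MIN_BINS:
        raise SpectrumError(
            f"need at least {MIN_BINS} frequency bins, got {frequencies.size}"
        )
    if np.any(frequencies <= 0):
        raise SpectrumError("frequencies must all be > 0")
    if np.any(np.diff(frequencies) <= 0):
        raise SpectrumError("frequencies must be strictly increasing")


@dataclass
class ImpedanceSpectrum:
    """A measured impedance sweep: ``Z(f) = R(f) + jX(f)``.

    Arrays are equal-length, with strictly increasing positive frequencies
    and a non-degenerate impedance (R² + X² > 0) at every bin.
    """

    frequencies: np.ndarray
    resistance: np.ndarray
    reactance: np.ndarray
    subject_id: str = ""
    state: MeasurementState = MeasurementState.EMPTY

    def __post_init__(self) -> None:
        self.frequencies = _as_float_array(self.frequencies, "frequencies")
        self.resistance = _as_float_array(self.resistance, "resistance")
        self.reactance = _as_float_array(self.reactance, "reactance")
        self.state = MeasurementState(self.state)
        if not (self.frequencies.size == self.resistance.size == self.reactance.size):
            raise SpectrumError("frequencies, resistance and reactance must have equal length")
        _check_frequencies(self.frequencies)
        mag2 = self.resistance**2 + self.reactance**2
        if np.any(mag2 == 0):
            bin_ = int(np.flatnonzero(mag2 == 0)[0])
            raise DegenerateImpedanceError(f"R = X = 0 at bin {bin_}")

    def __len__(self) -> int:
        return int(self.frequencies.size)


@dataclass
class PermittivitySpectrum:
    """Complex permittivity on a frequency grid.

    ``eps_real`` is the dielectric constant ε′, ``eps_imag`` the loss factor
    ε″, ``conductivity`` the ionic conductivity σ (S/m) and ``modulus`` the
    permittivity modulus |ε*|; all dimensionless except σ.
    """

    frequencies: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray
    conductivity: np.ndarray = field(default=None)  # type: ignore[assignment]
    modulus: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: str = ""
    state: MeasurementState = MeasurementState.EMPTY

    def __post_init__(self) -> None:
        self.frequencies = _as_float_array(self.frequencies, "frequencies")
        self.eps_real = _as_float_array(self.eps_real, "eps_real")
        self.eps_imag = _as_float_array(self.eps_imag, "eps_imag")
        self.state = MeasurementState(self.state)
        if not (self.frequencies.size == self.eps_real.size == self.eps_imag.size):
            raise SpectrumError("frequencies, eps_real and eps_imag must have equal length")
        _check_frequencies(self.frequencies)
        if self.conductivity is None:
            self.conductivity = ionic_conductivity(self)
        else:
            self.conductivity = _as_float_array(self.conductivity, "conductivity")
        if self.modulus is None:
            self.modulus = permittivity_modulus(self)
        else:
            self.modulus = _as_float_array(self.modulus, "modulus")

    def __len__(self) -> int:
        return int(self.frequencies.size)


def ionic_conductivity(perm: PermittivitySpectrum) -> np.ndarray:
    """Ionic conductivity per bin, ``σ = ε0·ε″·2πf`` (S/m)."""
    return EPSILON_0 * perm.eps_imag * 2.0 * np.pi * perm.frequencies


def permittivity_modulus(perm: PermittivitySpectrum) -> np.ndarray:
    """Permittivity modulus per bin, ``|ε*| = √(ε′² + ε″²)``."""
    return np.hypot(perm.eps_real, perm.eps_imag)


def impedance_to_permittivity(
    spectrum: ImpedanceSpectrum, geometry: SensorGeometry
) -> PermittivitySpectrum:
    """Convert a measured impedance sweep to complex permittivity.

    Applies, bin by bin,

        ε′ = −X / ((R² + X²)·2πf·C0),   ε″ = R / ((R² + X²)·2πf·C0)

    and fills σ and |ε*| from the converted components.  Metadata
    (subject id, measurement state) is propagated unchanged.
    """
    r, x, f = spectrum.resistance, spectrum.reactance, spectrum.frequencies
    mag2 = r**2 + x**2
    if np.any(mag2 == 0):
        bin_ = int(np.flatnonzero(mag2 == 0)[0])
        raise DegenerateImpedanceError(f"R = X = 0 at bin {bin_}")
    c0 = geometry.vacuum_capacitance
    denom = mag2 * 2.0 * np.pi * f * c0
    return PermittivitySpectrum(
        frequencies=f.copy(),
        eps_real=-x / denom,
        eps_imag=r / denom,
        subject_id=spectrum.subject_id,
        state=spectrum.state,
    )


def permittivity_to_impedance(
    perm: PermittivitySpectrum, geometry: SensorGeometry
) -> ImpedanceSpectrum:
    """Exact analytic inverse of :func:`impedance_to_permittivity`.

    From ``Z = 1/(jωC0·ε*)`` with ``ε* = ε′ − jε″``:

        R =  ε″ / (ωC0·(ε′² + ε″²)),   X = −ε′ / (ωC0·(ε′² + ε″²)).
    """
    ep, epp, f = perm.eps_real, perm.eps_imag, perm.frequencies
    mag2 = ep**2 + epp**2
    if np.any(mag2 == 0):
        bin_ = int(np.flatnonzero(mag2 == 0)[0])
        raise DegeneratePermittivityError(f"ε′ = ε″ = 0 at bin {bin_}")
    c0 = geometry.vacuum_capacitance
    denom = mag2 * 2.0 * np.pi * f * c0
    return ImpedanceSpectrum(
        frequencies=f.copy(),
        resistance=epp / denom,
        reactance=-ep / denom,
        subject_id=perm.subject_id,
        state=perm.state,
    )


def alpha_band_conductivity(perm: PermittivitySpectrum, f_max: float = 1000.0) -> float:
    """Geometric-mean ionic conductivity over the α band (bins with f ≤ *f_max*).

    The α dispersion sits in the Hz–kHz range, where σ is dominated by the
    mobile-ion dc term; the geometric mean over that band is a robust scalar
    summary used for liquid-state comparisons.
    """
    mask = perm.frequencies <= f_max
    if not np.any(mask):
        raise SpectrumError(f"no bins at or below {f_max} Hz")
    sigma = perm.conductivity[mask]
    if np.any(sigma <= 0):
        raise SpectrumError("non-positive conductivity in the α band")
    return float(10.0 ** np.mean(np.log10(sigma)))
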