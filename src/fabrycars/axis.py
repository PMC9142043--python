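"""Wavenumber axis of a CARS hyperspectral sweep.

In coherent anti-Stokes Raman scattering (CARS) the probed Raman shift is
set by the detuning between a tunable pump beam and a fixed Stokes beam:
``shift = 1e7/lambda_pump - 1e7/lambda_stokes`` with wavelengths in nm and
the shift in cm^-1.  Sweeping the pump from 804.0 nm to 826.4 nm in 0.7 nm
steps against a 1064 nm Stokes beam yields 33 channels covering the
CH-stretch window 2702.2-3039.3 cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectralAxis", "raman_shift", "build_axis"]

#: nm-grid termination tolerance so e.g. 804.0 + 32*0.7 == 826.4 is included
#: despite binary-float rounding.
GRID_TOL_NM = 1e-6

#: round-trip tolerance (cm^-1) between stored wavenumbers and the pump grid.
AXIS_CONSISTENCY_TOL = 0.05


def raman_shift(pump_nm: float, stokes_nm: float) -> float:
    """Raman shift (cm^-1) probed by a pump/Stokes wavelength pair (nm).

    May be negative if the pump is redder than the Stokes beam.
    """
    if pump_nm <= 0 or stokes_nm <= 0:
        raise ValueError(
            f"wavelengths must be positive, got pump={pump_nm}, stokes={stokes_nm}"
        )
    return 1e7 / pump_nm - 1e7 / stokes_nm


@dataclass(frozen=True)
class SpectralAxis:
    """Pump-wavelength grid and the derived wavenumber axis.

    Channels are ordered by increasing pump wavelength, hence strictly
    decreasing wavenumber (acquisition order).
    """

    stokes_nm: float
    pump_nm: np.ndarray
    wavenumbers_cm1: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        pump = np.asarray(self.pump_nm, dtype=float)
        object.__setattr__(self, "pump_nm", pump)
        if self.wavenumbers_cm1 is None:
            wn = np.array([raman_shift(p, self.stokes_nm) for p in pump])
        else:
            wn = np.asarray(self.wavenumbers_cm1, dtype=float)
        object.__setattr__(self, "wavenumbers_cm1", wn)
        self.validate()

    def validate(self) -> None:
        if self.pump_nm.ndim != 1 or len(self.pump_nm) < 1:
            raise ValueError("pump_nm must be a non-empty 1-D sequence")
        if len(self.pump_nm) != len(self.wavenumbers_cm1):
            raise ValueError("pump_nm and wavenumbers_cm1 lengths differ")
        expected = np.array([raman_shift(p, self.stokes_nm) for p in self.pump_nm])
        if np.max(np.abs(expected - self.wavenumbers_cm1)) > AXIS_CONSISTENCY_TOL:
            raise ValueError("wavenumbers inconsistent with pump/Stokes geometry")
        if len(self.pump_nm) > 1:
            dp = np.diff(self.pump_nm)
            if np.all(dp > 0) and not np.all(np.diff(self.wavenumbers_cm1) < 0):
                raise ValueError("increasing pump grid must give decreasing wavenumbers")

    def __len__(self) -> int:
        return len(self.pump_nm)

    @property
    def n_channels(self) -> int:
        return len(self.pump_nm)

    def nearest_channel(self, wavenumber_cm1: float) -> int:
        """Index of the channel whose wavenumber is closest to the query."""
        return int(np.argmin(np.abs(self.wavenumbers_cm1 - wavenumber_cm1)))

    def to_dict(self) -> dict:
        return {
            "stokes_nm": float(self.stokes_nm),
            "pump_nm": [float(p) for p in self.pump_nm],
            "wavenumbers_cm1": [float(w) for w in self.wavenumbers_cm1],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralAxis":
        return cls(
            stokes_nm=d["stokes_nm"],
            pump_nm=np.asarray(d["pump_nm"], dtype=float),
            wavenumbers_cm1=np.asarray(d["wavenumbers_cm1"], dtype=float),
        )


def build_axis(
    start_nm: float = 804.0,
    stop_nm: float = 826.4,
    step_nm: float = 0.7,
    stokes_nm: float = 1064.0,
) -> SpectralAxis:
    """Build the axis for a pump sweep ``start, start+step, ... <= stop``.

    The grid terminates at the largest pump value not exceeding
    ``stop_nm + 1e-6`` so that endpoints reached exactly (up to float
    rounding) are included; the defaults reproduce the 33-channel
    CH-stretch acquisition window.
    """
    if step_nm <= 0:
        raise ValueError(f"step_nm must be positive, got {step_nm}")
    if start_nm > stop_nm:
        raise ValueError(f"start_nm={start_nm} exceeds stop_nm={stop_nm}")
    n = int(np.floor((stop_nm - start_nm) / step_nm + GRID_TOL_NM)) + 1
    pump = start_nm + step_nm * np.arange(n)
    return SpectralAxis(stokes_nm=stokes_nm, pump_nm=pump)
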