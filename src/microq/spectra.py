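"""Single-event lineal-energy spectra.

The stochastic quantity lineal energy, ``y`` (keV/µm), is the energy a
single radiation track deposits in a microscopic site divided by the
site's mean chord length.  A radiation field is characterized by the
frequency-weighted probability density ``f(y)`` of single-event lineal
energies, or equivalently by the dose-weighted density

    d(y) = y f(y) / ∫ y f(y) dy ,

both normalized so that their integral over ``y`` is unity.  This module
provides the spectrum container, the f↔d transforms, moment summaries
(the frequency-mean ``ȳ_F`` and dose-mean ``ȳ_D`` lineal energies),
rebinning, TSV round-trip I/O, and a triangular chord-length surrogate
generator for mono-energetic ion beams.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "InvalidSpectrumError",
    "LinealEnergySpectrum",
    "IonBeamSpec",
    "frequency_to_dose",
    "dose_to_frequency",
    "mean_lineal_energy",
    "triangular_spectrum",
    "rebin",
    "read_spectrum",
    "write_spectrum",
]

logger = logging.getLogger(__name__)

NORMALIZATION_TOL = 1e-9

Representation = Literal["frequency", "dose"]


class InvalidSpectrumError(ValueError):
    """Raised when array contents cannot form a valid spectrum."""


@dataclass(frozen=True)
class IonBeamSpec:
    """A mono-energetic ion beam characterized by its LET.

    Parameters
    ----------
    label
        Ion name, e.g. ``"Si"``.
    let
        Linear energy transfer in keV/µm; must be positive.
    energy
        Nominal beam energy in MeV/n.  Metadata only; the triangular
        surrogate spectrum depends on the beam solely through its LET.
    """

    label: str
    let: float
    energy: float | None = None

    def __post_init__(self) -> None:
        if not self.let > 0:
            raise ValueError(f"LET must be positive, got {self.let}")


@dataclass(frozen=True)
class LinealEnergySpectrum:
    """A discretized single-event lineal-energy density.

    ``y_grid`` holds strictly increasing positive lineal energies
    (keV/µm) and ``density`` the aligned non-negative density values.
    ``representation`` records whether the density is the
    frequency-weighted ``f(y)`` or the dose-weighted ``d(y)``.  The
    density is renormalized at construction so its trapezoid integral
    over the grid equals one.
    """

    y_grid: np.ndarray
    density: np.ndarray
    representation: Representation = "frequency"
    label: str = ""
    site_diameter_um: float | None = None  # metadata only

    def __post_init__(self) -> None:
        y = np.asarray(self.y_grid, dtype=float)
        rho = np.asarray(self.density, dtype=float)
        if y.ndim != 1 or rho.shape != y.shape:
            raise InvalidSpectrumError("y_grid and density must be equal-length 1-D arrays")
        if y.size < 2:
            raise InvalidSpectrumError("spectrum needs at least two grid points")
        if np.any(~np.isfinite(y)) or np.any(~np.isfinite(rho)):
            raise InvalidSpectrumError("non-finite values in spectrum")
        if np.any(y <= 0) or np.any(np.diff(y) <= 0):
            raise InvalidSpectrumError("y_grid must be strictly increasing and positive")
        if np.any(rho < 0):
            raise InvalidSpectrumError("density values must be non-negative")
        total = np.trapezoid(rho, y)
        if total <= 0:
            raise InvalidSpectrumError("density must have positive total integral")
        if self.representation not in ("frequency", "dose"):
            raise InvalidSpectrumError(f"unknown representation {self.representation!r}")
        object.__setattr__(self, "y_grid", y)
        object.__setattr__(self, "density", rho / total)

    @property
    def norm(self) -> float:
        """Trapezoid integral of the stored density (one by construction)."""
        return float(np.trapezoid(self.density, self.y_grid))

    def mean(self, weighting: Representation | None = None) -> float:
        """First moment; see :func:`mean_lineal_energy`."""
        return mean_lineal_energy(self, weighting or self.representation)


def frequency_to_dose(spec: LinealEnergySpectrum) -> LinealEnergySpectrum:
    """Transform a frequency-weighted spectrum to dose weighting.

    Computes ``d(y) = y f(y) / ∫ y f(y) dy`` on the spectrum's own grid.
    A dose-weighted input is returned unchanged.
    """
    if spec.representation == "dose":
        return spec
    weighted = spec.y_grid * spec.density
    total = np.trapezoid(weighted, spec.y_grid)
    if total <= 0:
        raise InvalidSpectrumError("∫ y f(y) dy vanishes; cannot dose-weight")
    return replace(spec, density=weighted / total, representation="dose")


def dose_to_frequency(spec: LinealEnergySpectrum) -> LinealEnergySpectrum:
    """Inverse of :func:`frequency_to_dose`: ``f(y) ∝ d(y)/y``.

    Well defined because the grid excludes y = 0; the round trip
    f → d → f is the identity to floating-point accuracy.
    """
    if spec.representation == "frequency":
        return spec
    weighted = spec.density / spec.y_grid
    total = np.trapezoid(weighted, spec.y_grid)
    return replace(spec, density=weighted / total, representation="frequency")


def mean_lineal_energy(
    spec: LinealEnergySpectrum, weighting: Representation = "dose"
) -> float:
    """Frequency-mean ``ȳ_F`` or dose-mean ``ȳ_D`` lineal energy (keV/µm).

    The spectrum is converted internally to the requested weighting and
    the first moment taken by the trapezoid rule on the stored grid.
    """
    if weighting == "frequency":
        spec = dose_to_frequency(spec)
    elif weighting == "dose":
        spec = frequency_to_dose(spec)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return float(np.trapezoid(spec.y_grid * spec.density, spec.y_grid))


def triangular_spectrum(
    beam: IonBeamSpec, n_bins: int = 512
) -> LinealEnergySpectrum:
    """Triangular chord-length surrogate spectrum for a mono-energetic beam.

    For a track of constant LET crossing a spherical site, the chord-length
    distribution makes the single-event lineal energy triangular:

        f(y) = 2 y / y_max²  on (0, y_max],   y_max = (3/2) · LET.

    This is the unique triangular form whose frequency mean equals the LET
    (the sphere mean-chord identity ȳ_F = LET) and whose dose mean is
    ȳ_D = (9/8) · LET.  The grid is linear from ``y_max/n_bins`` to
    ``y_max`` (never exactly zero, keeping the d→f transform defined).

    Parameters
    ----------
    beam
        Beam with positive LET in keV/µm.
    n_bins
        Number of grid points, at least 16.  At the default 512 the
        discretized dose mean matches (9/8)·LET to better than 1e-5
        relative; coarse grids are allowed but less accurate.
    """
    if n_bins < 16:
        raise ValueError(f"n_bins must be at least 16, got {n_bins}")
    y_max = 1.5 * beam.let
    y = np.linspace(y_max / n_bins, y_max, n_bins)
    f = 2.0 * y / y_max**2
    return LinealEnergySpectrum(y, f, representation="frequency", label=beam.label)


def rebin(spec: LinealEnergySpectrum, new_grid: np.ndarray) -> LinealEnergySpectrum:
    """Interpolate a spectrum onto a new grid and renormalize.

    Linear interpolation with zero density outside the original support.
    When ``new_grid`` refines the old one the total integral (hence all
    moments) is preserved to high accuracy; coarse target grids lose
    resolution and a 2–3 point grid triggers a logged warning.
    """
    new_grid = np.asarray(new_grid, dtype=float)
    if new_grid.ndim != 1 or new_grid.size < 2:
        raise ValueError("new_grid must be a 1-D array with at least two points")
    if np.any(new_grid <= 0) or np.any(np.diff(new_grid) <= 0):
        raise ValueError("new_grid must be strictly increasing and positive")
    lo, hi = spec.y_grid[0], spec.y_grid[-1]
    if new_grid[-1] < lo or new_grid[0] > hi:
        raise ValueError(
            f"new_grid [{new_grid[0]:g}, {new_grid[-1]:g}] does not overlap "
            f"spectrum support [{lo:g}, {hi:g}]"
        )
    if new_grid.size <= 3:
        logger.warning(
            "rebinning %s onto a %d-point grid; moments will be inaccurate",
            spec.label or "spectrum",
            new_grid.size,
        )
    rho = np.interp(new_grid, spec.y_grid, spec.density, left=0.0, right=0.0)
    return replace(spec, y_grid=new_grid, density=rho)


# ---------------------------------------------------------------------------
# TSV round trip.  Header comments carry representation / units / label;
# the body is two numeric columns (y, density), delimiter-tolerant on read.

def write_spectrum(spec: LinealEnergySpectrum, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# representation: {spec.representation}",
        "# units_y: keV/um",
        f"# label: {spec.label}",
    ]
    # 17 significant digits: adjacent grid points one ulp apart must stay distinct
    lines += [f"{y:.17g}\t{rho:.17g}" for y, rho in zip(spec.y_grid, spec.density)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_spectrum(path: str | Path) -> LinealEnergySpectrum:
    path = Path(path)
    representation: Representation = "frequency"
    label = ""
    ys: list[float] = []
    rhos: list[float] = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key, value = key.strip().lower(), value.strip()
                if key == "representation":
                    if value not in ("frequency", "dose"):
                        raise InvalidSpectrumError(
                            f"unknown representation {value!r} in {path}"
                        )
                    representation = value  # type: ignore[assignment]
                elif key == "label":
                    label = value
            continue
        fields = re.split(r"[,\s]+", line)
        if len(fields) < 2:
            raise InvalidSpectrumError(f"malformed spectrum line in {path}: {raw!r}")
        ys.append(float(fields[0]))
        rhos.append(float(fields[1]))
    if not ys:
        raise InvalidSpectrumError(f"no data rows in {path}")
    return LinealEnergySpectrum(
        np.array(ys), np.array(rhos), representation=representation, label=label
    )
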