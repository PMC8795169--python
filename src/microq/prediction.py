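"""Apply fitted weighting functions to environment spectra.

Given a dose-weighted lineal-energy spectrum d(y) measured or calculated
for a radiation environment (free space, a planetary surface, a mixed
beam), this module folds it with biological weighting functions to
produce relative-effect metrics, folds it with a quality-factor
weighting Q(y) to produce the mean quality factor

    Q̄ = ∫ Q(y) d(y) dy ,

and converts absorbed dose to dose equivalent, H = D × Q̄ (Sv).

Weightings may be parametric (:class:`~microq.unfolding.QualityFunction`)
or tabulated two-column curves, so a published consensus Q(y) can be
applied directly once one exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .spectra import LinealEnergySpectrum, frequency_to_dose
from .unfolding import QualityFunction, fold

__all__ = [
    "TabulatedWeighting",
    "EnvironmentPrediction",
    "predict_environment",
    "mean_quality_factor",
    "dose_equivalent",
    "read_weighting",
]


@dataclass(frozen=True)
class TabulatedWeighting:
    """A weighting function given as (y, value) pairs, linearly interpolated.

    No extrapolation: evaluating outside [y[0], y[-1]] is a domain error,
    so a weighting must cover the full support of any spectrum it is
    folded with.
    """

    y: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if y.ndim != 1 or v.shape != y.shape or y.size < 2:
            raise ValueError("tabulated weighting needs matching 1-D arrays, >= 2 points")
        if np.any(np.diff(y) <= 0):
            raise ValueError("tabulation grid must be strictly increasing")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "values", v)

    def __call__(self, y) -> np.ndarray | float:
        arr = np.asarray(y, dtype=float)
        if np.any(arr < self.y[0] - 1e-12) or np.any(arr > self.y[-1] + 1e-12):
            raise ValueError(
                f"weighting tabulated on [{self.y[0]:g}, {self.y[-1]:g}] keV/µm is "
                f"undefined over part of the requested range "
                f"[{arr.min():g}, {arr.max():g}]"
            )
        out = np.interp(arr, self.y, self.values)
        return float(out) if np.isscalar(y) else out


@dataclass(frozen=True)
class EnvironmentPrediction:
    """Folded metrics (and optionally Q̄, D, H) for one environment."""

    label: str
    e_te: float
    e_nte: float
    q_bar: float | None = None
    dose_gy: float | None = None
    dose_equivalent_sv: float | None = None


def mean_quality_factor(
    weighting: QualityFunction | TabulatedWeighting, spectrum: LinealEnergySpectrum
) -> float:
    """Spectrum-averaged quality factor ∫ Q(y) d(y) dy (trapezoid rule)."""
    if spectrum.representation == "frequency":
        spectrum = frequency_to_dose(spectrum)
    q = weighting(spectrum.y_grid)
    return float(np.trapezoid(np.asarray(q) * spectrum.density, spectrum.y_grid))


def dose_equivalent(dose_gy: float, q_bar: float) -> float:
    """Dose equivalent H = D × Q̄ in Sieverts."""
    if dose_gy < 0:
        raise ValueError("absorbed dose must be non-negative")
    if q_bar <= 0:
        raise ValueError("mean quality factor must be positive")
    return dose_gy * q_bar


def predict_environment(
    qf_te: QualityFunction,
    qf_nte: QualityFunction,
    spectrum: LinealEnergySpectrum,
    dose_gy: float | None = None,
    q_weighting: QualityFunction | TabulatedWeighting | None = None,
    label: str | None = None,
) -> EnvironmentPrediction:
    """Fold the TE and NTE weighting functions with an environment spectrum.

    Optionally also computes Q̄ from ``q_weighting`` and, if ``dose_gy``
    is given, the dose equivalent H = D × Q̄.
    """
    if spectrum.representation == "frequency":
        spectrum = frequency_to_dose(spectrum)
    e_te = fold(qf_te, spectrum)
    e_nte = fold(qf_nte, spectrum)
    q_bar = mean_quality_factor(q_weighting, spectrum) if q_weighting is not None else None
    h = None
    if dose_gy is not None and q_bar is not None:
        h = dose_equivalent(dose_gy, q_bar)
    return EnvironmentPrediction(
        label=label if label is not None else spectrum.label,
        e_te=e_te,
        e_nte=e_nte,
        q_bar=q_bar,
        dose_gy=dose_gy,
        dose_equivalent_sv=h,
    )


def read_weighting(path: str | Path) -> QualityFunction | TabulatedWeighting:
    """Read a weighting function file.

    Either three whitespace-separated numbers (k1 k2 k3, possibly on
    ``k1: ...`` keyed lines) for the parametric form, or a two-column
    (y, value) tabulation; ``#`` lines are comments.
    """
    path = Path(path)
    rows: list[list[float]] = []
    keyed: dict[str, float] = {}
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" in line:
            key, _, value = line.partition(":")
            keyed[key.strip().lower()] = float(value)
            continue
        rows.append([float(tok) for tok in line.replace(",", " ").split()])
    if keyed:
        return QualityFunction(keyed["k1"], keyed["k2"], keyed["k3"])
    if len(rows) == 1 and len(rows[0]) == 3:
        return QualityFunction(*rows[0])
    if rows and all(len(r) == 2 for r in rows):
        arr = np.array(rows)
        return TabulatedWeighting(arr[:, 0], arr[:, 1], label=path.stem)
    raise ValueError(f"unrecognized weighting-function format in {path}")
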