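"""Biological weighting-function parameterization, folding, and unfolding.

The endpoint-specific biological weighting function is parameterized as

    q(y) = exp[ k1 (y/100)^k2 - k3 (y/100)^(1+k2) ],

a three-parameter form that is unity at y = 0, rises smoothly with
lineal energy, and peaks then flattens at high y (energy-deposition
saturation).  Folding q against a dose-weighted single-event spectrum
d_i(y),

    E_i = ∫ q(y) d_i(y) dy ,

predicts the relative low-dose effect metric of radiation type i (the
gamma-normalizing constant of the underlying Fredholm relation is fixed
to one, so only the shape of q is meaningful).  Unfolding inverts this:
given observed metrics with 95% CI widths for several radiation types,
the CI-weighted least-squares objective

    F = Σ_i (E_pred,i - E_obs,i)² / CI_i²

is minimized over (k1, k2, k3) ∈ [0, 10]³ by a multistart constrained
local search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml
from scipy.optimize import minimize

from .spectra import LinealEnergySpectrum, frequency_to_dose, read_spectrum

__all__ = [
    "QualityFunction",
    "UnfoldingProblem",
    "UnfoldingResult",
    "UnfoldingFailureError",
    "q_eval",
    "peak_location",
    "fold",
    "objective",
    "unfold",
    "goodness_of_fit",
    "refine_grid",
    "read_problem",
    "write_problem",
    "format_unfolding_report",
]

logger = logging.getLogger(__name__)

K_BOUNDS = (0.0, 10.0)
Y_SCALE = 100.0  # keV/µm; the y/100 scaling inside q


class UnfoldingFailureError(RuntimeError):
    """All multistart attempts failed; carries the per-restart log."""

    def __init__(self, message: str, restart_log: list | None = None):
        super().__init__(message)
        self.restart_log = restart_log or []


@dataclass(frozen=True)
class QualityFunction:
    """The three-parameter weighting function q(y).

    k1 controls the initial rise, k2 its steepness in (y/100), and k3
    the saturation that bends the curve back down; all are confined to
    [0, 10], which is what keeps fitted curves free of sharp spikes.
    ``q(0) = 1`` by construction.
    """

    k1: float
    k2: float
    k3: float
    effect_channel: Literal["TE", "NTE"] | None = None
    site_diameter_um: float | None = None  # metadata

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3"):
            v = getattr(self, name)
            if not (K_BOUNDS[0] <= v <= K_BOUNDS[1]):
                raise ValueError(f"{name}={v} outside bounds {K_BOUNDS}")

    def __call__(self, y) -> np.ndarray | float:
        return q_eval(self, y)

    @property
    def k(self) -> tuple[float, float, float]:
        return (self.k1, self.k2, self.k3)


def q_eval(qf: QualityFunction, y) -> np.ndarray | float:
    """Evaluate q(y) = exp[k1 u^k2 - k3 u^(1+k2)] with u = y/100."""
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0):
        raise ValueError("lineal energy must be non-negative")
    u = arr / Y_SCALE
    # q(0)=1 is the defining normalization; pin it explicitly so the k2=0
    # edge (where u**k2 would jump to 1 at u=0) cannot break it.
    u_safe = np.where(u > 0, u, 1.0)
    rise = np.where(u > 0, np.power(u_safe, qf.k2), 0.0)
    sat = np.where(u > 0, np.power(u_safe, 1.0 + qf.k2), 0.0)
    # cap the exponent at 700 (just under float overflow) so extreme corners
    # of the k-box yield a huge-but-finite objective instead of inf/nan
    val = np.exp(np.minimum(qf.k1 * rise - qf.k3 * sat, 700.0))
    return float(val) if np.isscalar(y) else val


def peak_location(qf: QualityFunction) -> float:
    """Lineal energy y* of the interior maximum of q.

    Setting d(log q)/dy = 0 gives y* = 100 · k1 k2 / (k3 (1 + k2)).
    Raises if k2 or k3 vanishes (monotone or flat q: no interior peak).
    """
    if qf.k2 <= 0 or qf.k3 <= 0 or qf.k1 <= 0:
        raise ValueError(
            "no interior peak: requires k1, k2, k3 all positive "
            f"(got k1={qf.k1}, k2={qf.k2}, k3={qf.k3})"
        )
    return Y_SCALE * qf.k1 * qf.k2 / (qf.k3 * (1.0 + qf.k2))


def fold(qf: QualityFunction, spectrum: LinealEnergySpectrum) -> float:
    """Predicted effect metric ∫ q(y) d(y) dy by the trapezoid rule.

    A frequency-weighted spectrum is converted to dose weighting first
    (with a logged notice); the integral uses the spectrum's own grid.
    """
    if spectrum.representation == "frequency":
        logger.info("fold received a frequency-weighted spectrum; converting to dose weighting")
        spectrum = frequency_to_dose(spectrum)
    return float(np.trapezoid(q_eval(qf, spectrum.y_grid) * spectrum.density, spectrum.y_grid))


@dataclass(frozen=True)
class UnfoldingProblem:
    """Observed metrics, their CI widths, and dose spectra per radiation type."""

    labels: tuple[str, ...]
    spectra: tuple[LinealEnergySpectrum, ...]
    observed: np.ndarray
    ci_widths: np.ndarray
    effect_channel: Literal["TE", "NTE"] | None = None

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float)
        widths = np.asarray(self.ci_widths, dtype=float)
        n = len(self.labels)
        if not (len(self.spectra) == obs.size == widths.size == n):
            raise ValueError("labels, spectra, observed, ci_widths must have equal length")
        if n < 3:
            raise ValueError(f"need at least 3 radiation types to constrain 3 parameters, got {n}")
        if np.any(widths <= 0):
            raise ValueError("CI widths must be positive (they weight the objective)")
        spectra = tuple(
            frequency_to_dose(sp) if sp.representation == "frequency" else sp
            for sp in self.spectra
        )
        object.__setattr__(self, "spectra", spectra)
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "ci_widths", widths)

    def predictions(self, qf: QualityFunction) -> np.ndarray:
        return np.array([fold(qf, sp) for sp in self.spectra])


@dataclass
class UnfoldingResult:
    """Best-fit weighting function plus multistart diagnostics."""

    best: QualityFunction
    objective_value: float
    predicted: np.ndarray
    r2: float
    rmse: float
    restarts: list[tuple[float, tuple[float, float, float]]] = field(default_factory=list)
    # (objective, (k1,k2,k3)) per restart, sorted ascending by objective


def objective(k: Sequence[float], problem: UnfoldingProblem) -> float:
    """CI-weighted sum of squared prediction errors F(k1,k2,k3)."""
    qf = QualityFunction(*k, effect_channel=problem.effect_channel)
    resid = (problem.predictions(qf) - problem.observed) / problem.ci_widths
    resid = np.clip(resid, -1e150, 1e150)  # keeps the sum finite at wild k
    return float(np.dot(resid, resid))


def unfold(
    problem: UnfoldingProblem,
    n_restarts: int = 300,
    seed: int = 20220127,
    x0: Sequence[float] | None = None,
) -> UnfoldingResult:
    """Estimate (k1, k2, k3) by multistart constrained minimization of F.

    ``n_restarts`` local searches (SLSQP within the [0, 10]³ box) start
    from uniform-random points drawn from a generator seeded with
    ``seed``; pass ``x0`` to replace the first random start with a
    chosen point.  The minimal-objective solution is returned, with all
    restart optima retained (sorted) for multimodality diagnostics;
    ties within 1e-8 go to the first-found solution.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be at least 1")
    rng = np.random.default_rng(seed)
    starts = rng.uniform(K_BOUNDS[0], K_BOUNDS[1], size=(n_restarts, 3))
    if x0 is not None:
        starts[0] = np.asarray(x0, dtype=float)
    bounds = [K_BOUNDS] * 3
    restart_log: list[tuple[float, tuple[float, float, float]]] = []
    errors: list[str] = []
    best_f, best_k = np.inf, None
    for start in starts:
        try:
            res = minimize(
                objective,
                start,
                args=(problem,),
                method="SLSQP",
                bounds=bounds,
                options={"maxiter": 200, "ftol": 1e-10},
            )
        except (ValueError, FloatingPointError) as exc:
            errors.append(str(exc))
            continue
        k_opt = tuple(np.clip(res.x, K_BOUNDS[0], K_BOUNDS[1]))
        f_opt = objective(k_opt, problem)
        restart_log.append((f_opt, k_opt))
        if f_opt < best_f - 1e-8:
            best_f, best_k = f_opt, k_opt
    if best_k is None:
        raise UnfoldingFailureError("all restarts failed", restart_log=errors)
    restart_log.sort(key=lambda t: t[0])
    qf = QualityFunction(*best_k, effect_channel=problem.effect_channel)
    predicted = problem.predictions(qf)
    r2, rmse = _r2_rmse(predicted, problem.observed)
    return UnfoldingResult(
        best=qf,
        objective_value=best_f,
        predicted=predicted,
        r2=r2,
        rmse=rmse,
        restarts=restart_log,
    )


def _r2_rmse(predicted: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    resid = predicted - observed
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R² undefined: observed metrics have zero variance")
    return 1.0 - ss_res / ss_tot, float(np.sqrt(np.mean(resid**2)))


def goodness_of_fit(result: UnfoldingResult, problem: UnfoldingProblem) -> tuple[float, float]:
    """Unweighted R² (about the mean observed metric) and RMSE."""
    if len(problem.labels) < 2:
        raise ValueError("R² undefined for a single radiation type")
    return _r2_rmse(result.predicted, problem.observed)


def refine_grid(spectrum: LinealEnergySpectrum, factor: int = 4) -> LinealEnergySpectrum:
    """Utility for fold-convergence checks: linearly refine the grid ``factor``×."""
    from .spectra import rebin

    y = spectrum.y_grid
    fine = np.unique(np.concatenate([
        np.linspace(a, b, factor + 1) for a, b in zip(y[:-1], y[1:])
    ]))
    return rebin(spectrum, fine)


# ---------------------------------------------------------------------------
# Problem-bundle config I/O (YAML: per radiation type a spectrum file path,
# observed metric, and CI bounds).


def read_problem(path: str | Path, effect_channel: str | None = None) -> UnfoldingProblem:
    path = Path(path)
    cfg = yaml.safe_load(path.read_text(encoding="utf-8"))
    channel = effect_channel or cfg.get("effect_channel")
    rows = cfg["radiation_types"]
    labels, spectra, observed, widths = [], [], [], []
    for row in rows:
        labels.append(str(row["label"]))
        spec_path = Path(row["spectrum"])
        if not spec_path.is_absolute():
            spec_path = path.parent / spec_path
        spectra.append(read_spectrum(spec_path))
        observed.append(float(row["observed"]))
        if "ci_width" in row:
            widths.append(float(row["ci_width"]))
        else:
            widths.append(float(row["ci_upper"]) - float(row["ci_lower"]))
    return UnfoldingProblem(
        labels=tuple(labels),
        spectra=tuple(spectra),
        observed=np.array(observed),
        ci_widths=np.array(widths),
        effect_channel=channel,
    )


def write_problem(problem: UnfoldingProblem, path: str | Path, spectrum_dir: str | Path | None = None) -> None:
    from .spectra import write_spectrum

    path = Path(path)
    spec_dir = Path(spectrum_dir) if spectrum_dir else path.parent
    spec_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for lb, sp, obs, w in zip(problem.labels, problem.spectra, problem.observed, problem.ci_widths):
        fname = f"spectrum_{lb}.tsv"
        write_spectrum(sp, spec_dir / fname)
        rel = (spec_dir / fname).relative_to(path.parent) if spec_dir != path.parent else Path(fname)
        rows.append({"label": lb, "spectrum": str(rel), "observed": float(obs), "ci_width": float(w)})
    cfg = {"effect_channel": problem.effect_channel, "radiation_types": rows}
    path.write_text(yaml.safe_dump(cfg, sort_keys=False), encoding="utf-8")


def format_unfolding_report(result: UnfoldingResult, problem: UnfoldingProblem) -> str:
    lines = [
        f"channel: {problem.effect_channel or '-'}",
        f"k1 = {result.best.k1:.3f}   k2 = {result.best.k2:.3f}   k3 = {result.best.k3:.3f}",
        f"objective F = {result.objective_value:.6g}",
        f"R^2 = {result.r2:.3f}   RMSE = {result.rmse:.3f}",
        "",
        f"{'radiation':<10}{'observed':>10}{'predicted':>11}{'CI width':>10}",
    ]
    for lb, obs, pred, w in zip(problem.labels, problem.observed, result.predicted, problem.ci_widths):
        lines.append(f"{lb:<10}{obs:>10.2f}{pred:>11.2f}{w:>10.2f}")
    return "\n".join(lines)
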