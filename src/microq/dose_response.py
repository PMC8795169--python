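"""TE+NTE tumor dose-response model and low-dose relative-effect metrics.

Tumor yield (tumors per mouse) after a dose ``D`` of radiation type
``i`` is modeled as the sum of a background yield, a linear
targeted-effect (TE) term, and a saturating non-targeted-effect (NTE)
term:

    M(D) = B + T_i D + N_i (1 - exp(-s D))

with the background ``B`` and the NTE saturation rate ``s`` shared
across all radiation types, and a gamma-ray reference group supplying
``T_γ`` and ``N_γ``.  Per-mouse tumor counts are treated as Poisson with
mean ``M(D)``; the model is fitted by maximum likelihood under the
constraints that all parameters are non-negative and that the ion TE
slopes satisfy ``T_i ≥ T_γ`` (implemented as ``T_i = T_γ + δ_i`` with
``δ_i ≥ 0``).

The fitted slopes and plateaus yield the low-dose relative-effect
metrics ``E_TE,i = T_i / T_γ`` and ``E_NTE,i = N_i / N_γ``, which are
the observables unfolded against lineal-energy spectra elsewhere in the
package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .reference import DOSE_RESPONSE_PARAMS, GAMMA_LABEL, NTE_RATE_S, NTE_RATE_S_CI, IonRecord

__all__ = [
    "TumorYieldDataset",
    "DoseResponseFit",
    "EffectMetricSet",
    "FitFailureError",
    "fit",
    "model_yield",
    "confidence_intervals",
    "effect_metrics",
    "reference_fit",
    "read_tumor_dataset",
    "write_tumor_dataset",
    "format_fit_report",
]

logger = logging.getLogger(__name__)

CONTROL_LABEL = "control"
_CHI2_95_DF1 = float(chi2.ppf(0.95, 1))  # 3.841...
_S_UPPER = 500.0  # Gy^-1; beyond this NTE saturation is instantaneous at any study dose


class FitFailureError(RuntimeError):
    """Optimization failed to converge; carries the best point found."""

    def __init__(self, message: str, best: "DoseResponseFit | None" = None):
        super().__init__(message)
        self.best = best


class TumorYieldDataset:
    """Per-mouse tumor counts grouped by radiation type and dose.

    One record per mouse: ``(radiation_label, dose_gy, tumor_count)``.
    Doses are stored in Gy.  Rows at zero dose act as shared controls
    regardless of label (the model reduces to the background there).
    """

    def __init__(self, records: pd.DataFrame | Iterable[tuple[str, float, int]]):
        if isinstance(records, pd.DataFrame):
            df = records.copy()
        else:
            df = pd.DataFrame(records, columns=["radiation_label", "dose_gy", "tumor_count"])
        required = {"radiation_label", "dose_gy", "tumor_count"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        df = df[["radiation_label", "dose_gy", "tumor_count"]].reset_index(drop=True)
        df["radiation_label"] = df["radiation_label"].astype(str)
        df["dose_gy"] = df["dose_gy"].astype(float)
        if (df["dose_gy"] < 0).any():
            raise ValueError("doses must be non-negative")
        counts = df["tumor_count"].to_numpy()
        if np.any(counts < 0) or np.any(counts != np.asarray(counts, dtype=int)):
            raise ValueError("tumor counts must be non-negative integers")
        df["tumor_count"] = df["tumor_count"].astype(int)
        self.records = df

    # -- structure ----------------------------------------------------------
    @property
    def fitted_labels(self) -> list[str]:
        """Labels with at least one positive dose, gamma first."""
        mask = self.records["dose_gy"] > 0
        labels = sorted(self.records.loc[mask, "radiation_label"].unique())
        if GAMMA_LABEL in labels:
            labels.remove(GAMMA_LABEL)
            labels.insert(0, GAMMA_LABEL)
        return labels

    @property
    def ion_labels(self) -> list[str]:
        return [lb for lb in self.fitted_labels if lb != GAMMA_LABEL]

    @property
    def has_gamma(self) -> bool:
        return GAMMA_LABEL in self.fitted_labels

    @property
    def has_controls(self) -> bool:
        return bool((self.records["dose_gy"] == 0).any())

    def group_table(self) -> pd.DataFrame:
        """Sufficient statistics per (label, dose): mouse count and tumor sum."""
        g = (
            self.records.groupby(["radiation_label", "dose_gy"])["tumor_count"]
            .agg(n="size", total="sum", mean="mean")
            .reset_index()
        )
        return g

    def subset(self, labels: Sequence[str], keep_controls: bool = True) -> "TumorYieldDataset":
        mask = self.records["radiation_label"].isin(labels)
        if keep_controls:
            mask |= self.records["dose_gy"] == 0
        return TumorYieldDataset(self.records.loc[mask])

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class DoseResponseFit:
    """Maximum-likelihood parameters of the TE+NTE model.

    ``T`` and ``N`` map radiation label to the TE slope (Gy⁻¹) and NTE
    plateau (unitless); ``B`` (tumors/mouse) and ``s`` (Gy⁻¹) are shared.
    CI dictionaries are populated by :func:`confidence_intervals` (or
    carried over from published values for reference fits).
    """

    B: float
    s: float
    T: dict[str, float]
    N: dict[str, float]
    loglik: float = np.nan
    converged: bool = True
    B_ci: tuple[float, float] | None = None
    s_ci: tuple[float, float] | None = None
    T_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    N_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_restarts: int = 0
    restart_logliks: list[float] = field(default_factory=list)
    bootstrap_replicates: pd.DataFrame | None = None

    def labels(self) -> list[str]:
        return list(self.T)


@dataclass(frozen=True)
class EffectMetricSet:
    """Per-ion relative low-dose effect metrics with 95% CIs.

    ``te[label]`` holds ``E_TE = T_i/T_γ`` and ``nte[label]`` holds
    ``E_NTE = N_i/N_γ`` as (value, lower, upper) records; the CI width
    (upper − lower) is what weights the unfolding objective.
    """

    te: dict[str, IonRecord]
    nte: dict[str, IonRecord]


def model_yield(fitted: DoseResponseFit, radiation_label: str, dose_gy: float | np.ndarray):
    """Expected tumor yield ``B + T D + N (1 - exp(-s D))`` for one group."""
    dose = np.asarray(dose_gy, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    if radiation_label == CONTROL_LABEL:
        out = np.full_like(dose, fitted.B)
        return float(out) if np.isscalar(dose_gy) else out
    try:
        T = fitted.T[radiation_label]
        N = fitted.N[radiation_label]
    except KeyError:
        raise KeyError(f"unknown radiation label {radiation_label!r}; have {fitted.labels()}")
    out = fitted.B + T * dose + N * (1.0 - np.exp(-fitted.s * dose))
    return float(out) if np.isscalar(dose_gy) else out


# ---------------------------------------------------------------------------
# Likelihood machinery.  The free vector is
#   theta = [B, s, T_gamma, N_gamma, delta_1.., N_1..]
# over the ion labels in dataset order, with T_i = T_gamma + delta_i.


class _Problem:
    def __init__(self, dataset: TumorYieldDataset):
        if not dataset.has_gamma:
            raise ValueError("dataset must contain a gamma-labelled reference group")
        if not dataset.has_controls:
            raise ValueError("dataset must contain a zero-dose control group")
        g = dataset.group_table()
        for lb in dataset.fitted_labels:
            ndose = g.loc[(g.radiation_label == lb) & (g.dose_gy > 0), "dose_gy"].nunique()
            if ndose < 2:
                raise ValueError(f"group {lb!r} has fewer than 2 distinct positive doses")
        self.ions = dataset.ion_labels
        self.n_params = 4 + 2 * len(self.ions)
        pos = g[g.dose_gy > 0]
        self.D = pos["dose_gy"].to_numpy()
        self.n = pos["n"].to_numpy(dtype=float)
        self.S = pos["total"].to_numpy(dtype=float)
        labels = pos["radiation_label"].to_numpy()
        self.is_gamma = labels == GAMMA_LABEL
        self.ion_index = np.array(
            [self.ions.index(lb) if lb != GAMMA_LABEL else -1 for lb in labels]
        )
        zero = g[g.dose_gy == 0]
        self.n0 = float(zero["n"].sum())
        self.S0 = float(zero["total"].sum())
        # constant term of the Poisson log-likelihood (log factorials) omitted

    def names(self) -> list[str]:
        return (
            ["B", "s", f"T_{GAMMA_LABEL}", f"N_{GAMMA_LABEL}"]
            + [f"delta_{lb}" for lb in self.ions]
            + [f"N_{lb}" for lb in self.ions]
        )

    def bounds(self) -> list[tuple[float, float | None]]:
        b: list[tuple[float, float | None]] = [(1e-8, None), (0.0, _S_UPPER), (0.0, None), (0.0, None)]
        b += [(0.0, None)] * len(self.ions)
        b += [(0.0, None)] * len(self.ions)
        return b

    def unpack(self, theta: np.ndarray):
        k = len(self.ions)
        B, s, Tg, Ng = theta[0], theta[1], theta[2], theta[3]
        delta = theta[4 : 4 + k]
        N_ion = theta[4 + k : 4 + 2 * k]
        return B, s, Tg, Ng, delta, N_ion

    def _per_cell(self, ion_values: np.ndarray, gamma_value: float) -> np.ndarray:
        if ion_values.size == 0:
            return np.full(self.D.shape, gamma_value)
        idx = np.maximum(self.ion_index, 0)  # gamma cells masked out below
        return np.where(self.is_gamma, gamma_value, ion_values[idx])

    def mean(self, theta: np.ndarray) -> np.ndarray:
        B, s, Tg, Ng, delta, N_ion = self.unpack(theta)
        T_cell = self._per_cell(Tg + delta, Tg)
        N_cell = self._per_cell(N_ion, Ng)
        return B + T_cell * self.D + N_cell * (1.0 - np.exp(-s * self.D))

    def negloglik_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        B, s, Tg, Ng, delta, N_ion = self.unpack(theta)
        k = len(self.ions)
        expsd = np.exp(-s * self.D)
        sat = 1.0 - expsd
        M = self.mean(theta)
        M = np.maximum(M, 1e-12)
        ll = float(np.sum(self.S * np.log(M) - self.n * M))
        ll += self.S0 * np.log(max(B, 1e-12)) - self.n0 * B
        g_cell = self.S / M - self.n  # d ll / d M_c
        grad = np.zeros_like(theta)
        grad[0] = np.sum(g_cell) + (self.S0 / max(B, 1e-12) - self.n0)
        N_cell = self._per_cell(N_ion, Ng)
        grad[1] = np.sum(g_cell * N_cell * self.D * expsd)
        grad[2] = np.sum(g_cell * self.D)  # T_gamma enters every positive-dose cell
        grad[3] = np.sum(g_cell * sat * self.is_gamma)
        for j in range(k):
            mask = self.ion_index == j
            grad[4 + j] = np.sum(g_cell[mask] * self.D[mask])
            grad[4 + k + j] = np.sum(g_cell[mask] * sat[mask])
        return -ll, -grad

    # -- initial points ------------------------------------------------------
    def smart_init(self) -> np.ndarray:
        B0 = max(self.S0 / max(self.n0, 1.0), 0.05)
        theta = np.zeros(self.n_params)
        theta[0] = B0
        theta[1] = 30.0
        means = self.S / np.maximum(self.n, 1.0)
        gm = self.is_gamma
        Tg0 = 1.0
        if gm.any():
            excess = np.maximum(means[gm] - B0, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                slopes = excess / self.D[gm]
            Tg0 = float(np.clip(np.nanmedian(slopes), 0.01, 50.0))
        theta[2] = Tg0
        theta[3] = 0.5
        k = len(self.ions)
        for j in range(k):
            mask = self.ion_index == j
            excess = np.maximum(means[mask] - B0, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                slopes = excess / self.D[mask]
            sl = float(np.clip(np.nanmedian(slopes), 0.01, 50.0))
            theta[4 + j] = max(sl - Tg0, 0.0)
            theta[4 + k + j] = min(float(np.min(excess)) if mask.any() else 0.5, 10.0)
        return theta

    def random_init(self, rng: np.random.Generator) -> np.ndarray:
        k = len(self.ions)
        theta = np.empty(self.n_params)
        theta[0] = rng.uniform(0.05, 6.0)
        theta[1] = rng.uniform(1.0, 100.0)
        theta[2] = rng.uniform(0.0, 15.0)
        theta[3] = rng.uniform(0.0, 5.0)
        theta[4 : 4 + k] = rng.uniform(0.0, 10.0, size=k)
        theta[4 + k :] = rng.uniform(0.0, 5.0, size=k)
        return theta


def _optimize(problem: _Problem, x0: np.ndarray, bounds=None, fixed: dict[int, float] | None = None):
    """L-BFGS-B on the negative log-likelihood, optionally pinning coordinates."""
    bounds = list(bounds if bounds is not None else problem.bounds())
    x0 = np.asarray(x0, dtype=float).copy()
    if fixed:
        for idx, val in fixed.items():
            bounds[idx] = (val, val)
            x0[idx] = val
    for i, (lo, hi) in enumerate(bounds):
        x0[i] = np.clip(x0[i], lo, hi if hi is not None else np.inf)
    res = minimize(
        problem.negloglik_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    return res


def fit(
    dataset: TumorYieldDataset,
    n_restarts: int = 50,
    seed: int = 20220127,
    compute_ci: bool = False,
) -> DoseResponseFit:
    """Fit the TE+NTE model jointly across radiation types.

    Maximizes the Poisson log-likelihood of the per-mouse counts with
    shared ``B`` and ``s``, the gamma group as reference, and the ion
    constraint ``T_i ≥ T_γ``.  The optimizer is run from one
    moment-based starting point plus ``n_restarts`` random ones and the
    best optimum kept; the multistart is deterministic given ``seed``.

    Set ``compute_ci=True`` to attach profile-likelihood 95% CIs for all
    parameters (see :func:`confidence_intervals`).
    """
    problem = _Problem(dataset)
    rng = np.random.default_rng(seed)
    starts = [problem.smart_init()] + [problem.random_init(rng) for _ in range(n_restarts)]
    best = None
    logliks = []
    for x0 in starts:
        try:
            res = _optimize(problem, x0)
        except (ValueError, FloatingPointError):  # pathological start
            continue
        logliks.append(-res.fun)
        if best is None or res.fun < best.fun - 0.0:
            best = res
    if best is None:
        raise FitFailureError("all optimizer restarts failed")
    result = _result_from_theta(problem, best.x, -best.fun)
    result.converged = bool(best.success or np.max(np.abs(best.jac)) < 1e-3)
    result.n_restarts = len(starts)
    result.restart_logliks = sorted(logliks, reverse=True)
    if not result.converged:
        raise FitFailureError("dose-response fit did not converge", best=result)
    if compute_ci:
        confidence_intervals(result, dataset)
    return result


def _result_from_theta(problem: _Problem, theta: np.ndarray, loglik: float) -> DoseResponseFit:
    B, s, Tg, Ng, delta, N_ion = problem.unpack(theta)
    T = {GAMMA_LABEL: float(Tg)}
    N = {GAMMA_LABEL: float(Ng)}
    for j, lb in enumerate(problem.ions):
        T[lb] = float(Tg + delta[j])
        N[lb] = float(N_ion[j])
    return DoseResponseFit(B=float(B), s=float(s), T=T, N=N, loglik=float(loglik))


# ---------------------------------------------------------------------------
# Confidence intervals


def _theta_from_result(problem: _Problem, fitted: DoseResponseFit) -> np.ndarray:
    k = len(problem.ions)
    theta = np.empty(problem.n_params)
    theta[0], theta[1] = fitted.B, fitted.s
    theta[2], theta[3] = fitted.T[GAMMA_LABEL], fitted.N[GAMMA_LABEL]
    for j, lb in enumerate(problem.ions):
        theta[4 + j] = max(fitted.T[lb] - fitted.T[GAMMA_LABEL], 0.0)
        theta[4 + k + j] = fitted.N[lb]
    return theta


def _profile_value(problem: _Problem, theta_hat: np.ndarray, name: str, value: float) -> float:
    """Profile log-likelihood: fix one *natural* parameter, maximize the rest.

    Natural parameters are B, s, T_<label>, N_<label>.  Fixing an ion
    slope T_i at ``value`` caps T_γ at ``value`` (the constraint
    T_i ≥ T_γ) and substitutes δ_i = value − T_γ inside the objective.
    """
    k = len(problem.ions)
    bounds = problem.bounds()
    if name == "B":
        fixed = {0: value}
    elif name == "s":
        fixed = {1: value}
    elif name == f"T_{GAMMA_LABEL}":
        fixed = {2: value}
    elif name == f"N_{GAMMA_LABEL}":
        fixed = {3: value}
    elif name.startswith("N_"):
        lb = name[2:]
        fixed = {4 + k + problem.ions.index(lb): value}
    elif name.startswith("T_"):
        lb = name[2:]
        j = problem.ions.index(lb)

        # reduced problem: delta_j is dependent (= value - T_gamma)
        class _Reduced:
            def negloglik_grad(_self, theta):
                th = theta.copy()
                th[4 + j] = max(value - th[2], 0.0)
                f, g = problem.negloglik_grad(th)
                # d delta_j / d T_gamma = -1 folds the delta_j gradient into T_gamma
                g = g.copy()
                g[2] -= g[4 + j]
                g[4 + j] = 0.0
                return f, g

        rbounds = list(bounds)
        rbounds[2] = (0.0, value)
        rbounds[4 + j] = (0.0, 0.0)
        x0 = theta_hat.copy()
        x0[2] = min(x0[2], value)
        res = minimize(
            _Reduced().negloglik_grad, np.clip(x0, [b[0] for b in rbounds],
                                               [b[1] if b[1] is not None else np.inf for b in rbounds]),
            jac=True, method="L-BFGS-B", bounds=rbounds,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        return -res.fun
    else:
        raise KeyError(f"unknown parameter {name!r}")
    res = _optimize(problem, theta_hat, fixed=fixed)
    return -res.fun


def _natural_value(fitted: DoseResponseFit, name: str) -> float:
    if name == "B":
        return fitted.B
    if name == "s":
        return fitted.s
    if name.startswith("T_"):
        return fitted.T[name[2:]]
    if name.startswith("N_"):
        return fitted.N[name[2:]]
    raise KeyError(name)


def _profile_bound(
    problem: _Problem,
    theta_hat: np.ndarray,
    ll_hat: float,
    name: str,
    mle: float,
    side: int,
    cutoff: float,
) -> float:
    """Walk outward from the MLE until the profile deviance crosses the cutoff,
    then bisect.  ``side`` is -1 for the lower bound, +1 for the upper."""

    def deviance(v: float) -> float:
        return 2.0 * (ll_hat - _profile_value(problem, theta_hat, name, v))

    lower_limit = 0.0
    step = max(0.25 * abs(mle), 0.05)
    v_in, d_in = mle, 0.0
    v = mle
    for _ in range(60):
        v = v + side * step
        if side < 0 and v <= lower_limit:
            v = lower_limit
        d = deviance(v)
        if d >= cutoff:
            break
        v_in, d_in = v, d
        if side < 0 and v == lower_limit:
            return lower_limit  # boundary inside the confidence region
        step *= 1.6
    else:
        warnings.warn(f"profile for {name} appears flat; CI bound unreliable")
        return v
    v_out, d_out = v, d
    for _ in range(40):  # bisection on the monotone deviance
        mid = 0.5 * (v_in + v_out)
        d_mid = deviance(mid)
        if d_mid < cutoff:
            v_in, d_in = mid, d_mid
        else:
            v_out, d_out = mid, d_mid
        if abs(v_out - v_in) < 1e-4 * max(1.0, abs(mle)):
            break
    return 0.5 * (v_in + v_out)


def confidence_intervals(
    fitted: DoseResponseFit,
    dataset: TumorYieldDataset,
    method: Literal["profile", "bootstrap"] = "profile",
    parameters: Sequence[str] | None = None,
    n_boot: int = 200,
    seed: int = 20220127,
) -> dict[str, tuple[float, float]]:
    """95% confidence intervals for the dose-response parameters.

    ``method="profile"`` (default) inverts the profile-likelihood-ratio
    test at the χ²(1) 95% cutoff (3.84); bounds that run into a
    parameter constraint are reported at the constraint.
    ``method="bootstrap"`` case-resamples mice within each (label, dose)
    group and takes percentile intervals over ``n_boot`` refits.

    ``parameters`` restricts the computation to named natural parameters
    ("B", "s", "T_Si", "N_gamma", ...); default is all of them.  The CIs
    are stored on ``fitted`` and also returned as a dict.
    """
    problem = _Problem(dataset)
    names = (
        list(parameters)
        if parameters is not None
        else ["B", "s"] + [f"T_{lb}" for lb in fitted.labels()] + [f"N_{lb}" for lb in fitted.labels()]
    )
    out: dict[str, tuple[float, float]] = {}
    if method == "profile":
        theta_hat = _theta_from_result(problem, fitted)
        ll_hat = fitted.loglik
        for name in names:
            mle = _natural_value(fitted, name)
            lo = _profile_bound(problem, theta_hat, ll_hat, name, mle, -1, _CHI2_95_DF1)
            hi = _profile_bound(problem, theta_hat, ll_hat, name, mle, +1, _CHI2_95_DF1)
            out[name] = (min(lo, mle), max(hi, mle))
    elif method == "bootstrap":
        if n_boot <= 0:
            raise ValueError("bootstrap requires at least one resample")
        rng = np.random.default_rng(seed)
        rows = []
        for b in range(n_boot):
            parts = []
            for _, g in dataset.records.groupby(["radiation_label", "dose_gy"]):
                parts.append(g.iloc[rng.integers(0, len(g), size=len(g))])
            resampled = pd.concat(parts, ignore_index=True)
            try:
                refit = fit(TumorYieldDataset(resampled), n_restarts=2,
                            seed=int(rng.integers(2**31)))
            except FitFailureError:
                continue
            row = {"B": refit.B, "s": refit.s}
            row.update({f"T_{lb}": refit.T[lb] for lb in refit.labels()})
            row.update({f"N_{lb}": refit.N[lb] for lb in refit.labels()})
            rows.append(row)
        if not rows:
            raise FitFailureError("all bootstrap refits failed")
        reps = pd.DataFrame(rows)
        fitted.bootstrap_replicates = reps
        for name in names:
            lo, hi = np.percentile(reps[name].dropna(), [2.5, 97.5])
            out[name] = (float(lo), float(hi))
    else:
        raise ValueError(f"unknown CI method {method!r}")

    for name, ci in out.items():
        if name == "B":
            fitted.B_ci = ci
        elif name == "s":
            fitted.s_ci = ci
        elif name.startswith("T_"):
            fitted.T_ci[name[2:]] = ci
        elif name.startswith("N_"):
            fitted.N_ci[name[2:]] = ci
    return out


# ---------------------------------------------------------------------------
# Effect metrics


def _ratio_record(num: float, den: float, num_ci, den_ci) -> IonRecord:
    value = num / den
    if num_ci is None or den_ci is None:
        return IonRecord(value, np.nan, np.nan)
    # delta method on the ratio, independence assumed; SE from CI width
    se_n = (num_ci[1] - num_ci[0]) / 3.92
    se_d = (den_ci[1] - den_ci[0]) / 3.92
    se = abs(value) * np.sqrt((se_n / num) ** 2 + (se_d / den) ** 2)
    return IonRecord(value, value - 1.96 * se, value + 1.96 * se)


def effect_metrics(
    fitted: DoseResponseFit,
    method: Literal["delta", "bootstrap"] = "delta",
) -> EffectMetricSet:
    """Relative low-dose effect metrics ``E_TE = T_i/T_γ``, ``E_NTE = N_i/N_γ``.

    CIs come from bootstrap ratio percentiles when the fit carries
    bootstrap replicates and ``method="bootstrap"``; otherwise from a
    delta-method propagation of the parameter CI widths.  Metrics for
    the gamma reference are identically one and omitted.
    """
    Tg, Ng = fitted.T[GAMMA_LABEL], fitted.N[GAMMA_LABEL]
    if Tg <= 0 or Ng <= 0:
        raise ZeroDivisionError(
            f"gamma reference parameters must be positive (T_γ={Tg}, N_γ={Ng})"
        )
    te: dict[str, IonRecord] = {}
    nte: dict[str, IonRecord] = {}
    ions = [lb for lb in fitted.labels() if lb != GAMMA_LABEL]
    if method == "bootstrap":
        reps = fitted.bootstrap_replicates
        if reps is None:
            raise ValueError("fit has no bootstrap replicates; run confidence_intervals(method='bootstrap')")
        for lb in ions:
            r_te = (reps[f"T_{lb}"] / reps[f"T_{GAMMA_LABEL}"]).replace([np.inf, -np.inf], np.nan).dropna()
            r_nte = (reps[f"N_{lb}"] / reps[f"N_{GAMMA_LABEL}"]).replace([np.inf, -np.inf], np.nan).dropna()
            te[lb] = IonRecord(fitted.T[lb] / Tg, *np.percentile(r_te, [2.5, 97.5]))
            nte[lb] = IonRecord(fitted.N[lb] / Ng, *np.percentile(r_nte, [2.5, 97.5]))
    else:
        for lb in ions:
            if fitted.T[lb] == Tg:
                # slope pinned at the gamma reference: the ratio is exactly one
                te[lb] = IonRecord(1.0, 1.0, 1.0) if not fitted.T_ci else _ratio_record(
                    fitted.T[lb], Tg, fitted.T_ci.get(lb), fitted.T_ci.get(GAMMA_LABEL)
                )
                te[lb] = IonRecord(1.0, te[lb].lo, te[lb].hi)
            else:
                te[lb] = _ratio_record(fitted.T[lb], Tg, fitted.T_ci.get(lb), fitted.T_ci.get(GAMMA_LABEL))
            nte[lb] = _ratio_record(fitted.N[lb], Ng, fitted.N_ci.get(lb), fitted.N_ci.get(GAMMA_LABEL))
    return EffectMetricSet(te=te, nte=nte)


def reference_fit(background: float = 3.0) -> DoseResponseFit:
    """A :class:`DoseResponseFit` populated with the published best-fit
    parameters of the APC1638N/+ intestinal-tumor study.

    The study's background yield is not published; ``background`` defaults
    to 3.0 tumors/mouse, a typical spontaneous yield for this strain.
    Used as simulation truth and for metric computations from published
    values.
    """
    T = {lb: rec["T"].value for lb, rec in DOSE_RESPONSE_PARAMS.items()}
    N = {lb: rec["N"].value for lb, rec in DOSE_RESPONSE_PARAMS.items()}
    T_ci = {lb: (rec["T"].lo, rec["T"].hi) for lb, rec in DOSE_RESPONSE_PARAMS.items()}
    N_ci = {lb: (rec["N"].lo, rec["N"].hi) for lb, rec in DOSE_RESPONSE_PARAMS.items()}
    return DoseResponseFit(
        B=background, s=NTE_RATE_S, T=T, N=N,
        s_ci=NTE_RATE_S_CI, T_ci=T_ci, N_ci=N_ci,
    )


# ---------------------------------------------------------------------------
# I/O and reporting


def read_tumor_dataset(path: str | Path) -> TumorYieldDataset:
    """Read a per-mouse TSV with columns radiation_label, dose_cGy, tumor_count."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "dose_cGy" in df.columns:
        df["dose_gy"] = df["dose_cGy"].astype(float) / 100.0
        df = df.drop(columns=["dose_cGy"])
    return TumorYieldDataset(df)


def write_tumor_dataset(dataset: TumorYieldDataset, path: str | Path) -> None:
    out = dataset.records.copy()
    out["dose_cGy"] = (out.pop("dose_gy") * 100.0).round(6)
    out[["radiation_label", "dose_cGy", "tumor_count"]].to_csv(path, sep="\t", index=False)


def format_fit_report(fitted: DoseResponseFit) -> str:
    """Parameter table (one row per radiation type) as plain text."""

    def ci_str(ci):
        return f"({ci[0]:.2f}, {ci[1]:.2f})" if ci else "(-, -)"

    lines = [
        f"Background B = {fitted.B:.3f} tumors/mouse  95% CI {ci_str(fitted.B_ci)}",
        f"NTE rate s   = {fitted.s:.1f} Gy^-1         95% CI {ci_str(fitted.s_ci)}",
        f"log-likelihood = {fitted.loglik:.3f}",
        "",
        f"{'radiation':<10}{'T (Gy^-1)':>10}{'95% CI':>16}{'N':>8}{'95% CI':>16}",
    ]
    for lb in fitted.labels():
        lines.append(
            f"{lb:<10}{fitted.T[lb]:>10.2f}{ci_str(fitted.T_ci.get(lb)):>16}"
            f"{fitted.N[lb]:>8.2f}{ci_str(fitted.N_ci.get(lb)):>16}"
        )
    return "\n".join(lines)
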