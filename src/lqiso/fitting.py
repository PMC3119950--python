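"""Weighted least-squares fitting of LQ and ELQ models to dose-survival data.

Clonogenic survival points rarely come with published error bars; the working
assumption here is that the standard deviation of a point is proportional to
its value, so weighted least squares with weights 1/sd_i^2 in linear survival
space is equivalent to relative least squares. Fitting in log-survival space
(where the proportional-SD assumption makes the log-residual SD constant) is
available as an option.

The ELQ fit follows a two-stage rule: an unconstrained fit over (alpha, beta,
gamma) first; if the fitted alpha comes out negative, the fit is repeated with
alpha fixed to zero and flagged. If gamma runs beyond a divergence ceiling the
data carry no evidence of high-dose linearity and the result is reported as
the LQ limit (gamma unbounded).

Percentage parameter uncertainties come from the Gauss-Newton covariance at
the optimum, scaled by the reduced chi-square.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .models import (
    GAMMA_UNBOUNDED,
    ELQParameters,
    LQParameters,
    elq_log_survival,
    lq_log_survival,
)

__all__ = [
    "SurvivalDataset",
    "FitResult",
    "fit_lq",
    "fit_elq",
    "compute_wssr",
    "parameter_uncertainty",
    "alpha_beta_ratio_uncertainty",
    "GAMMA_CEILING",
]

#: gamma values above this (per Gy) are reported as the LQ limit.
GAMMA_CEILING = 1e4

# Convergence tolerances, fixed so fits are deterministic.
_FTOL = 1e-10
_XTOL = 1e-10
_GTOL = 1e-12

_BETA_FLOOR = 1e-12


class InsufficientDataError(ValueError):
    """Fewer data points than the fit can support."""


class FitFailureError(RuntimeError):
    """The optimizer did not converge; carries solver diagnostics."""


@dataclass(frozen=True)
class SurvivalDataset:
    """One cell line's dose-response: strictly increasing doses (Gy),
    surviving fractions in (0, 1], and optional per-point SDs.

    When ``sd`` is absent, the effective SD is ``sd_scale`` times the
    surviving fraction (proportional-SD assumption, default constant 1)."""

    label: str
    dose: np.ndarray
    surviving_fraction: np.ndarray
    sd: np.ndarray | None = None
    sd_scale: float = 1.0

    def __post_init__(self):
        d = np.asarray(self.dose, dtype=float)
        s = np.asarray(self.surviving_fraction, dtype=float)
        object.__setattr__(self, "dose", d)
        object.__setattr__(self, "surviving_fraction", s)
        if d.ndim != 1 or s.shape != d.shape:
            raise ValueError("dose and surviving_fraction must be 1-D and equal length")
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("doses must be nonnegative and strictly increasing")
        if np.any(s <= 0) or np.any(s > 1):
            raise ValueError("surviving fractions must lie in (0, 1]")
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            object.__setattr__(self, "sd", sd)
            if sd.shape != d.shape or np.any(sd < 0):
                raise ValueError("sd must match dose shape and be nonnegative")
        if not self.sd_scale > 0:
            raise ValueError("sd_scale must be > 0")

    def __len__(self) -> int:
        return self.dose.size

    @property
    def effective_sd(self) -> np.ndarray:
        if self.sd is not None:
            return self.sd
        return self.sd_scale * self.surviving_fraction

    # -- delimited-text I/O (CSV, header row, '#' comments) -----------------

    def to_csv(self, path) -> None:
        cols = ["dose_Gy", "surviving_fraction"] + (["sd"] if self.sd is not None else [])
        lines = [f"# dataset: {self.label}", ",".join(cols)]
        for i in range(len(self)):
            row = [repr(float(self.dose[i])), repr(float(self.surviving_fraction[i]))]
            if self.sd is not None:
                row.append(repr(float(self.sd[i])))
            lines.append(",".join(row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path, label: str | None = None) -> "SurvivalDataset":
        path = Path(path)
        header = None
        rows = []
        file_label = label or path.stem
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line[1:].strip().startswith("dataset:") and label is None:
                    file_label = line.split("dataset:", 1)[1].strip()
                continue
            fields = [f.strip() for f in line.split(",")]
            if header is None:
                header = fields
                if header[:2] != ["dose_Gy", "surviving_fraction"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header 'dose_Gy,surviving_fraction[,sd]'"
                    )
                continue
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        if header is None or not rows:
            raise ValueError(f"{path}: no data rows")
        arr = np.array(rows, dtype=float)
        sd = arr[:, 2] if arr.shape[1] >= 3 else None
        return cls(label=file_label, dose=arr[:, 0], surviving_fraction=arr[:, 1], sd=sd)


@dataclass
class FitResult:
    """Outcome of a weighted LQ or ELQ fit.

    ``pct_uncertainty`` maps each *free* parameter name to 100*SE/estimate;
    parameters fixed by a constraint carry no entry. ``covariance`` is the
    scaled Gauss-Newton covariance over the free parameters (row order =
    ``free_names``); it is None when the curvature is singular, in which case
    the corresponding percentages are ``math.inf``."""

    model_kind: str  # "LQ" | "ELQ"
    parameters: LQParameters | ELQParameters
    wssr: float
    pct_uncertainty: dict[str, float]
    n_points: int
    alpha_fixed_to_zero: bool = False
    gamma_unbounded: bool = False
    fit_space: str = "linear"
    free_names: tuple[str, ...] = ()
    covariance: np.ndarray | None = None

    def to_dict(self) -> dict:
        p = self.parameters
        params = {"alpha": p.alpha, "beta": p.beta}
        if isinstance(p, ELQParameters):
            params["gamma"] = None if p.gamma_unbounded else p.gamma
        return {
            "model_kind": self.model_kind,
            "parameters": params,
            "wssr": self.wssr,
            "pct_uncertainty": dict(self.pct_uncertainty),
            "n_points": self.n_points,
            "alpha_fixed_to_zero": self.alpha_fixed_to_zero,
            "gamma_unbounded": self.gamma_unbounded,
            "fit_space": self.fit_space,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# residuals and objective


def _residual_fn(data: SurvivalDataset, log_survival: Callable, fit_space: str):
    """Weighted residual vector in the configured fit space.

    linear: (S_model - S_obs)/sd_i ; log: (lnS_model - lnS_obs)/(sd_i/S_obs_i),
    the delta-method SD of ln S under the proportional-SD assumption."""
    d = data.dose
    obs = data.surviving_fraction
    sd = data.effective_sd
    if np.any(sd == 0):
        raise ZeroDivisionError("degenerate weight: sd = 0 at some point")
    if fit_space == "linear":
        def resid(theta):
            return (np.exp(log_survival(theta, d)) - obs) / sd
    elif fit_space == "log":
        log_obs = np.log(obs)
        log_sd = sd / obs
        def resid(theta):
            return (log_survival(theta, d) - log_obs) / log_sd
    else:
        raise ValueError(f"unknown fit_space {fit_space!r} (use 'linear' or 'log')")
    return resid


def compute_wssr(
    data: SurvivalDataset,
    survival: Callable[[np.ndarray], np.ndarray],
    fit_space: str = "linear",
) -> float:
    """Weighted sum of squared residuals of a survival function against data.

    sum_i ((obs_i - fit_i)/sd_i)^2 in linear space, the log-space analogue
    otherwise. Zero iff the model interpolates every point."""
    sd = data.effective_sd
    if np.any(sd == 0):
        raise ZeroDivisionError("degenerate weight: sd = 0 at some point")
    fit_vals = np.asarray(survival(data.dose), dtype=float)
    obs = data.surviving_fraction
    if fit_space == "linear":
        r = (fit_vals - obs) / sd
    elif fit_space == "log":
        r = (np.log(fit_vals) - np.log(obs)) / (sd / obs)
    else:
        raise ValueError(f"unknown fit_space {fit_space!r} (use 'linear' or 'log')")
    return float(np.sum(r**2))


# ---------------------------------------------------------------------------
# uncertainty machinery


def _jacobian(resid, theta, rel_step=1e-7):
    """Central-difference Jacobian of the residual vector (2-3 params)."""
    theta = np.asarray(theta, dtype=float)
    r0 = resid(theta)
    J = np.empty((r0.size, theta.size))
    for j in range(theta.size):
        h = rel_step * max(abs(theta[j]), 1e-8)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        J[:, j] = (resid(tp) - resid(tm)) / (2 * h)
    return J


def _covariance(J, wssr, n, p, scale_by_reduced_chisq=True):
    """Gauss-Newton covariance inv(J'J), optionally scaled by WSSR/(n-p)."""
    JtJ = J.T @ J
    try:
        cov = np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        return None
    if np.any(~np.isfinite(cov)):
        return None
    if scale_by_reduced_chisq and n > p:
        cov = cov * (wssr / (n - p))
    return cov


def _pct_from_cov(cov, theta, names):
    if cov is None:
        return {n: math.inf for n in names}
    out = {}
    for j, n in enumerate(names):
        var = cov[j, j]
        if var < 0 or theta[j] == 0:
            out[n] = math.inf
        else:
            out[n] = 100.0 * math.sqrt(var) / abs(theta[j])
    return out


def parameter_uncertainty(
    fit: FitResult,
    data: SurvivalDataset,
    scale_by_reduced_chisq: bool = True,
) -> dict[str, float]:
    """Recompute percentage uncertainties (100*SE/estimate) for a converged fit.

    The covariance is the Gauss-Newton curvature of the weighted objective at
    the optimum; by default it is scaled by the reduced chi-square WSSR/(n-p)
    so that a perfect (noiseless) fit reports ~0. With scaling disabled the
    standard errors track the supplied SDs directly (doubling every sd doubles
    each SE). A singular curvature yields inf, not an exception."""
    theta, names, log_surv = _pack_fit(fit)
    resid = _residual_fn(data, log_surv, fit.fit_space)
    J = _jacobian(resid, theta)
    cov = _covariance(J, fit.wssr, len(data), len(theta), scale_by_reduced_chisq)
    return _pct_from_cov(cov, theta, names)


def _pack_fit(fit: FitResult):
    """Free-parameter vector, names and a theta-based log-survival evaluator."""
    p = fit.parameters
    if fit.model_kind == "LQ":
        return (
            np.array([p.alpha, p.beta]),
            ("alpha", "beta"),
            lambda th, d: -th[0] * d - th[1] * d**2,
        )
    if fit.gamma_unbounded:
        return (
            np.array([p.alpha, p.beta]),
            ("alpha", "beta"),
            lambda th, d: -th[0] * d - th[1] * d**2,
        )
    if fit.alpha_fixed_to_zero:
        return (
            np.array([p.beta, p.gamma]),
            ("beta", "gamma"),
            lambda th, d: _elq_log_surv_theta(0.0, th[0], th[1], d),
        )
    return (
        np.array([p.alpha, p.beta, p.gamma]),
        ("alpha", "beta", "gamma"),
        lambda th, d: _elq_log_surv_theta(th[0], th[1], th[2], d),
    )


def alpha_beta_ratio_uncertainty(fit: FitResult, assume_independent: bool = True):
    """(alpha/beta, percentage uncertainty) by first-order error propagation.

    With independence assumed, pct = sqrt(pct_alpha^2 + pct_beta^2); otherwise
    the retained covariance supplies the cross term."""
    p = fit.parameters
    ratio = p.alpha / p.beta
    pa = fit.pct_uncertainty.get("alpha")
    pb = fit.pct_uncertainty.get("beta")
    if pa is None or pb is None:
        return ratio, math.inf
    if assume_independent or fit.covariance is None:
        return ratio, math.hypot(pa, pb)
    names = list(fit.free_names)
    ia, ib = names.index("alpha"), names.index("beta")
    cov_term = 2.0 * fit.covariance[ia, ib] / (p.alpha * p.beta) * 100.0**2
    return ratio, math.sqrt(max(pa**2 + pb**2 - cov_term, 0.0))


# ---------------------------------------------------------------------------
# fitting


def _elq_log_surv_theta(a, b, g, d):
    k = g * g / (2.0 * b)
    return -(a + g) * d + k * -np.expm1(-2.0 * b * d / g)


def _run_ls(resid, x0, bounds):
    sol = least_squares(
        resid, x0, bounds=bounds, method="trf", ftol=_FTOL, xtol=_XTOL, gtol=_GTOL
    )
    if not sol.success:
        raise FitFailureError(f"least_squares failed: {sol.message} (status {sol.status})")
    return sol


def _lq_start(data: SurvivalDataset):
    """Initial (alpha, beta) from the linearisation -lnS/d = alpha + beta*d."""
    d, s = data.dose, data.surviving_fraction
    mask = d > 0
    y = -np.log(s[mask]) / d[mask]
    beta, alpha = np.polyfit(d[mask], y, 1)
    return max(alpha, 0.0), max(beta, 1e-4)


def fit_lq(data: SurvivalDataset, fit_space: str = "linear") -> FitResult:
    """Weighted LQ fit with alpha constrained >= 0 and beta > 0.

    Minimises sum_i w_i r_i^2 with w_i = 1/sd_i^2 in the configured fit space.
    Needs at least 4 points (parameters + 2)."""
    if len(data) < 4:
        raise InsufficientDataError(f"LQ fit needs >= 4 points, got {len(data)}")
    resid = _residual_fn(data, lambda th, d: -th[0] * d - th[1] * d**2, fit_space)
    a0, b0 = _lq_start(data)
    sol = _run_ls(resid, [a0, b0], ([0.0, _BETA_FLOOR], [np.inf, np.inf]))
    wssr = float(2 * sol.cost)
    theta = sol.x
    cov = _covariance(sol.jac, wssr, len(data), 2)
    names = ("alpha", "beta")
    return FitResult(
        model_kind="LQ",
        parameters=LQParameters(float(theta[0]), float(theta[1])),
        wssr=wssr,
        pct_uncertainty=_pct_from_cov(cov, theta, names),
        n_points=len(data),
        fit_space=fit_space,
        free_names=names,
        covariance=cov,
    )


# deterministic multistart recipe for the ELQ stage-1 fit: each entry maps the
# LQ seed (a, b) to a (alpha, beta, gamma) start; the large-gamma start makes
# the nesting property (ELQ WSSR <= LQ WSSR) hold by construction.
_ELQ_STARTS: Sequence[Callable] = (
    lambda a, b: (a, b, 1e3),
    lambda a, b: (a, b, 1.0),
    lambda a, b: (0.0, 2.0 * b, 1.0),
    lambda a, b: (0.0, 2.0 * b, 0.5),
    lambda a, b: (a / 2.0, 1.5 * b, 2.0),
)

_GAMMA_SEARCH_UPPER = 1e7  # optimizer bound; results past GAMMA_CEILING -> LQ limit


def fit_elq(
    data: SurvivalDataset,
    fit_space: str = "linear",
    gamma_ceiling: float = GAMMA_CEILING,
) -> FitResult:
    """Weighted ELQ fit with the negative-alpha refit rule.

    Stage 1 fits (alpha, beta, gamma) with alpha unconstrained, multistarted
    from five deterministic initial points (ties broken by lowest WSSR, then
    lowest gamma). If the best alpha is negative, the fit is repeated with
    alpha fixed to 0 and flagged. The data carry no evidence of a high-dose
    linear tail when the gamma estimate runs beyond ``gamma_ceiling`` or when
    the ELQ objective fails to improve on the nested LQ fit (the cost surface
    is flat in gamma); either way the result is the LQ-limit fit with gamma
    unbounded, which also guarantees the nesting property
    ELQ WSSR <= LQ WSSR. Needs at least 5 points."""
    if len(data) < 5:
        raise InsufficientDataError(f"ELQ fit needs >= 5 points, got {len(data)}")
    lq = fit_lq(data, fit_space=fit_space)
    a0, b0 = lq.parameters.alpha, lq.parameters.beta

    resid3 = _residual_fn(
        data, lambda th, d: _elq_log_surv_theta(th[0], th[1], th[2], d), fit_space
    )
    lo = [-np.inf, _BETA_FLOOR, 1e-6]
    hi = [np.inf, np.inf, _GAMMA_SEARCH_UPPER]
    best = None
    for make in _ELQ_STARTS:
        x0 = np.clip(make(a0, b0), lo, hi)
        try:
            sol = _run_ls(resid3, x0, (lo, hi))
        except FitFailureError:
            continue
        key = (2 * sol.cost, sol.x[2])
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        raise FitFailureError("all ELQ starts failed to converge")
    sol = best[1]

    alpha_fixed = False
    if sol.x[0] < 0:
        alpha_fixed = True
        resid2 = _residual_fn(
            data, lambda th, d: _elq_log_surv_theta(0.0, th[0], th[1], d), fit_space
        )
        sol = _run_ls(
            resid2,
            [max(sol.x[1], _BETA_FLOOR), min(max(sol.x[2], 1e-6), _GAMMA_SEARCH_UPPER)],
            ([_BETA_FLOOR, 1e-6], [np.inf, _GAMMA_SEARCH_UPPER]),
        )
        theta = np.array([sol.x[0], sol.x[1]])
        names = ("beta", "gamma")
        params = ELQParameters(0.0, float(theta[0]), float(theta[1]))
    else:
        theta = sol.x
        names = ("alpha", "beta", "gamma")
        params = ELQParameters(float(theta[0]), float(theta[1]), float(theta[2]))

    wssr_cand = float(2 * sol.cost)
    # relative improvement of the ELQ over the nested LQ; non-positive or
    # negligible improvement means gamma is unidentified on this dataset
    improvement = (lq.wssr - wssr_cand) / max(lq.wssr, 1e-300)
    if params.gamma > gamma_ceiling or improvement < 1e-6:
        # LQ limit: report the constrained LQ fit with gamma unbounded
        return FitResult(
            model_kind="ELQ",
            parameters=ELQParameters(a0, b0, GAMMA_UNBOUNDED),
            wssr=lq.wssr,
            pct_uncertainty=dict(lq.pct_uncertainty),
            n_points=len(data),
            alpha_fixed_to_zero=False,
            gamma_unbounded=True,
            fit_space=fit_space,
            free_names=lq.free_names,
            covariance=lq.covariance,
        )

    wssr = float(2 * sol.cost)
    cov = _covariance(sol.jac, wssr, len(data), len(theta))
    return FitResult(
        model_kind="ELQ",
        parameters=params,
        wssr=wssr,
        pct_uncertainty=_pct_from_cov(cov, theta, names),
        n_points=len(data),
        alpha_fixed_to_zero=alpha_fixed,
        gamma_unbounded=False,
        fit_space=fit_space,
        free_names=names,
        covariance=cov,
    )
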