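"""Isoeffect calculations for fractionated radiotherapy schedules.

An isoeffect is the set of schedules (fraction number n, total dose D) that
produce the same effect E = -ln(total survival), assuming complete repair of
sublethal damage between fractions and no repopulation during treatment.

For the LQ model the effect of n fractions of d = D/n is

    E = alpha*D + beta*D**2/n

which inverts in closed form (the positive quadratic root). For the ELQ,

    E = (alpha+gamma)*D - n*gamma^2/(2*beta)*(1 - exp(-2*beta*D/(n*gamma)))

is implicit in D and is solved by bracketed root finding; the effect is
strictly increasing in D, so the root is unique.

``anchored_lq_isoeffect_dose`` supports the common clinical shortcut of
specifying only an alpha/beta ratio: an LQ isoeffect anchored to a reference
schedule depends on alpha and beta only through their ratio (the BED-style
cancellation D*(1 + d/(alpha/beta)) = const), so no absolute scale is needed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .fitting import FitResult
from .models import ELQParameters, LQParameters, elq_log_survival, lq_log_survival

__all__ = [
    "Schedule",
    "IsoeffectCurve",
    "parse_schedule",
    "lq_effect",
    "elq_effect",
    "effect",
    "lq_isoeffect_dose",
    "elq_isoeffect_dose",
    "isoeffect_dose",
    "isoeffect_curve",
    "fraction_ratio",
    "isoeffect_uncertainty_band",
    "anchored_lq_isoeffect_dose",
    "lq_approximation_report",
]

_ROOT_XTOL = 1e-12
_ROOT_RTOL = 1e-12


@dataclass(frozen=True)
class Schedule:
    """n fractions of dose_per_fraction Gy; n may be a positive real when
    schedules are treated continuously."""

    n: float
    dose_per_fraction: float

    def __post_init__(self):
        if not self.n >= 1:
            raise ValueError("fraction number n must be >= 1")
        if not self.dose_per_fraction > 0:
            raise ValueError("dose per fraction must be > 0")

    @property
    def total_dose(self) -> float:
        return self.n * self.dose_per_fraction

    def __str__(self) -> str:
        return f"{self.n:g}x{self.dose_per_fraction:g}"


def parse_schedule(text: str) -> Schedule:
    """Parse 'NxD' (e.g. '40x2', '3x15'), dose in Gy."""
    try:
        n_str, d_str = text.lower().split("x")
        return Schedule(float(n_str), float(d_str))
    except (ValueError, TypeError):
        raise ValueError(f"cannot parse schedule {text!r}; expected 'NxD' like '40x2'")


def lq_effect(params: LQParameters, schedule: Schedule) -> float:
    """E = alpha*D + beta*D^2/n for n fractions totalling D Gy."""
    D, n = schedule.total_dose, schedule.n
    return params.alpha * D + params.beta * D * D / n


def elq_effect(params: ELQParameters, schedule: Schedule) -> float:
    """ELQ effect of a fractionated schedule: n times the per-fraction effect.

    Equals -n * elq_log_survival(d = D/n); delegates to the LQ effect when
    gamma is unbounded."""
    if params.gamma_unbounded:
        return lq_effect(params.as_lq(), schedule)
    return -schedule.n * elq_log_survival(params, schedule.dose_per_fraction)


def effect(params, schedule: Schedule) -> float:
    """Model-dispatching effect of a schedule."""
    if isinstance(params, ELQParameters):
        return elq_effect(params, schedule)
    return lq_effect(params, schedule)


def lq_isoeffect_dose(params: LQParameters, E: float, n: float) -> float:
    """Total dose D in n fractions achieving effect E under the LQ model.

    Positive root of beta*D^2/n + alpha*D - E = 0, written in the
    cancellation-free form 2E/(alpha + sqrt(alpha^2 + 4*beta*E/n)), which is
    exact for alpha = 0 as well (pure quadratic branch sqrt(n*E/beta))."""
    if not E > 0:
        raise ValueError("effect E must be > 0")
    if not n >= 1:
        raise ValueError("fraction number n must be >= 1")
    a, b = params.alpha, params.beta
    return 2.0 * E / (a + math.sqrt(a * a + 4.0 * b * E / n))


def elq_isoeffect_dose(params: ELQParameters, E: float, n: float) -> float:
    """Total dose D in n fractions achieving effect E under the ELQ model.

    Solved by Brent's method on the strictly increasing effect-in-D map. The
    analytic bracket is [E/(alpha+gamma), E/(alpha+gamma) + n*gamma^2 /
    (2*beta*(alpha+gamma))]: dropping the repair term overestimates the
    effect (lower bound), and the high-dose asymptote offset bounds how much
    extra dose the repair term can absorb (upper bound). A geometric
    expansion covers any residual non-straddling from rounding."""
    if not E > 0:
        raise ValueError("effect E must be > 0")
    if not n >= 1:
        raise ValueError("fraction number n must be >= 1")
    if params.gamma_unbounded:
        return lq_isoeffect_dose(params.as_lq(), E, n)

    def f(D):
        return elq_effect(params, Schedule(n, D / n)) - E

    slope = params.alpha + params.gamma
    lo = E / slope
    hi = lo + n * params.gamma**2 / (2.0 * params.beta * slope)
    # widen defensively; f(lo) <= 0 <= f(hi) analytically but allow rounding
    for _ in range(60):
        if f(lo) <= 0:
            break
        lo *= 0.5
    for _ in range(60):
        if f(hi) >= 0:
            break
        hi *= 2.0
    if not (f(lo) <= 0 <= f(hi)):
        raise RuntimeError(
            f"isoeffect bracket failed for {params} at E={E}, n={n}: "
            f"f({lo})={f(lo)}, f({hi})={f(hi)}"
        )
    return float(brentq(f, lo, hi, xtol=_ROOT_XTOL, rtol=_ROOT_RTOL))


def isoeffect_dose(params, E: float, n: float) -> float:
    """Model-dispatching inverse: total dose achieving effect E in n fractions."""
    if isinstance(params, ELQParameters):
        return elq_isoeffect_dose(params, E, n)
    return lq_isoeffect_dose(params, E, n)


@dataclass(frozen=True)
class IsoeffectCurve:
    """Isoeffect curve: (n, D) pairs all achieving the reference schedule's
    effect under one model."""

    reference: Schedule
    effect: float
    model_kind: str
    n: np.ndarray
    total_dose: np.ndarray

    @property
    def points(self):
        return list(zip(self.n.tolist(), self.total_dose.tolist()))

    def dose_at(self, n: float) -> float:
        idx = np.nonzero(np.isclose(self.n, n))[0]
        if idx.size == 0:
            raise KeyError(f"n={n} not on curve")
        return float(self.total_dose[idx[0]])


def isoeffect_curve(params, reference: Schedule, n_range=None) -> IsoeffectCurve:
    """Isoeffect curve through a reference schedule over a range of fraction
    numbers (default n = 1..50). The curve passes exactly through the
    reference point by construction."""
    if n_range is None:
        n_range = np.arange(1, 51)
    n_arr = np.asarray(n_range, dtype=float)
    E = effect(params, reference)
    doses = np.array([isoeffect_dose(params, E, n) for n in n_arr])
    kind = "ELQ" if isinstance(params, ELQParameters) else "LQ"
    return IsoeffectCurve(reference, E, kind, n_arr, doses)


def fraction_ratio(lq: LQParameters, elq: ELQParameters, dose_per_fraction: float) -> float:
    """n_ELQ/n_LQ: how many more fractions at a given dose per fraction the
    ELQ model requires for the effect the LQ model predicts, i.e.
    ln S_LQ(d) / ln S_ELQ(d)."""
    ls_lq = lq_log_survival(lq, dose_per_fraction)
    ls_elq = elq_log_survival(elq, dose_per_fraction)
    if ls_lq == 0 or ls_elq == 0:
        raise ValueError("log survival is zero at this dose; ratio undefined")
    return ls_lq / ls_elq


# ---------------------------------------------------------------------------
# uncertainty band


def _perturbed_params(fit: FitResult, signs) -> tuple:
    """Parameters displaced by +/- 1 SE per free parameter; clipped to the
    model's bounds when a perturbation would violate them."""
    p = fit.parameters
    vals = {"alpha": p.alpha, "beta": p.beta}
    if isinstance(p, ELQParameters):
        vals["gamma"] = p.gamma
    clipped = False
    for name, s in zip(fit.free_names, signs):
        pct = fit.pct_uncertainty.get(name, 0.0)
        if not math.isfinite(pct):
            continue
        se = abs(vals[name]) * pct / 100.0
        vals[name] = vals[name] + s * se
    floor = {"alpha": 0.0, "beta": 1e-12, "gamma": 1e-9}
    for name in vals:
        lo = floor[name]
        if vals[name] < lo:
            vals[name] = lo
            clipped = True
    if isinstance(p, ELQParameters):
        return ELQParameters(vals["alpha"], vals["beta"], vals["gamma"]), clipped
    return LQParameters(vals["alpha"], vals["beta"]), clipped


def isoeffect_uncertainty_band(fit: FitResult, reference: Schedule, n_range=None):
    """Per-n (D_low, D_high) isoeffect band from +/- 1-SE corner evaluation.

    Every corner of the free-parameter hypercube re-derives the reference
    effect from the reference schedule before inverting, so each corner's
    curve still passes through the reference point; the band is the pointwise
    min/max over corners and the nominal curve, hence contains the nominal
    curve by construction. Corners violating parameter bounds are clipped and
    flagged. Returns (n, D_low, D_high, any_clipped)."""
    if n_range is None:
        n_range = np.arange(1, 51)
    n_arr = np.asarray(n_range, dtype=float)
    nominal = isoeffect_curve(fit.parameters, reference, n_arr)
    lows = nominal.total_dose.copy()
    highs = nominal.total_dose.copy()
    any_clipped = False
    k = len(fit.free_names)
    for signs in itertools.product((-1.0, 1.0), repeat=k):
        params, clipped = _perturbed_params(fit, signs)
        any_clipped = any_clipped or clipped
        curve = isoeffect_curve(params, reference, n_arr)
        lows = np.minimum(lows, curve.total_dose)
        highs = np.maximum(highs, curve.total_dose)
    return n_arr, lows, highs, any_clipped


# ---------------------------------------------------------------------------
# alpha/beta-ratio-only LQ curves and the approximation report


def anchored_lq_isoeffect_dose(alpha_beta: float, reference: Schedule, n: float) -> float:
    """LQ isoeffect dose specified only by an alpha/beta ratio, anchored to a
    reference schedule.

    The anchored LQ curve solves D*(1 + (D/n)/(alpha/beta)) = BED_ref with
    BED_ref = D_ref*(1 + d_ref/(alpha/beta)); absolute alpha cancels."""
    if not alpha_beta > 0:
        raise ValueError("alpha/beta ratio must be > 0")
    bed = reference.total_dose * (1.0 + reference.dose_per_fraction / alpha_beta)
    # D^2/(n*ab) + D - bed = 0, positive root in cancellation-free form
    return 2.0 * bed / (1.0 + math.sqrt(1.0 + 4.0 * bed / (n * alpha_beta)))


@dataclass(frozen=True)
class ApproximationResult:
    """Agreement of one candidate alpha/beta LQ curve with the ELQ curve."""

    alpha_beta: float
    n_start: float | None  # maximal contiguous agreement interval, None if empty
    n_end: float | None
    max_abs_diff_gy: float
    diffs: np.ndarray  # signed D_LQ - D_ELQ per n


def lq_approximation_report(
    elq: ELQParameters,
    alpha_beta_candidates,
    reference: Schedule,
    n_range=None,
    tolerance_gy: float = 1.0,
) -> list[ApproximationResult]:
    """For each candidate alpha/beta, the maximal contiguous fraction-number
    interval on which the anchored LQ isoeffect curve agrees with the ELQ
    curve to within ``tolerance_gy``. An empty interval is reported as
    (None, None), not an error."""
    if n_range is None:
        n_range = np.arange(1, 51)
    n_arr = np.asarray(n_range, dtype=float)
    elq_curve = isoeffect_curve(elq, reference, n_arr)
    out = []
    for ab in alpha_beta_candidates:
        d_lq = np.array([anchored_lq_isoeffect_dose(ab, reference, n) for n in n_arr])
        diffs = d_lq - elq_curve.total_dose
        ok = np.abs(diffs) <= tolerance_gy
        best = (0, None, None)  # (length, start, end)
        i = 0
        while i < ok.size:
            if ok[i]:
                j = i
                while j + 1 < ok.size and ok[j + 1]:
                    j += 1
                if j - i + 1 > best[0]:
                    best = (j - i + 1, n_arr[i], n_arr[j])
                i = j + 1
            else:
                i += 1
        out.append(
            ApproximationResult(
                alpha_beta=float(ab),
                n_start=best[1],
                n_end=best[2],
                max_abs_diff_gy=float(np.max(np.abs(diffs))),
                diffs=diffs,
            )
        )
    return out
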