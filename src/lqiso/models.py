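"""Cell-survival models: linear-quadratic (LQ) and extended linear-quadratic (ELQ).

The LQ model describes clonogenic log survival after an acute dose ``d`` as

    ln S = -alpha*d - beta*d**2

with ``alpha`` (per Gy) the low-dose linear killing coefficient and ``beta``
(per Gy^2) the quadratic coefficient. The ELQ generalises it with a third
parameter ``gamma`` (per Gy):

    ln S = -(alpha + gamma)*d + gamma**2/(2*beta) * (1 - exp(-2*beta*d/gamma))

so that the high-dose log-survival becomes linear with slope ``-(alpha+gamma)``
and extrapolation number ``gamma**2/(2*beta)``, while the low-dose behaviour is
still ``-alpha*d - beta*d**2``. The ELQ contains the dose-protraction-modified
LQ as a special case: for a constant dose rate ``R`` and first-order sublethal
damage repair at rate ``lam``, choosing ``gamma = 2*beta*R/lam`` reproduces the
Lea-Catcheside-protracted LQ exactly. As ``gamma -> inf`` the ELQ collapses to
the plain LQ, which is represented here by the sentinel ``GAMMA_UNBOUNDED``.

Units are fixed: dose in Gy, time in hours (``dose_rate`` and ``repair_rate``
must share the time unit; no conversion is performed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GAMMA_UNBOUNDED",
    "LQParameters",
    "ELQParameters",
    "ProtractionSpec",
    "lq_log_survival",
    "elq_log_survival",
    "protraction_factor",
    "gamma_from_protraction",
    "elq_low_dose_series",
    "elq_high_dose_asymptote",
]

#: Sentinel for an unbounded (infinite) gamma, i.e. the exact LQ limit of the
#: ELQ. IEEE infinity compares exactly and needs no magnitude convention.
GAMMA_UNBOUNDED: float = math.inf

# Below this value of lambda*T the Lea-Catcheside factor is evaluated by
# Taylor series to avoid catastrophic cancellation in (exp(-x) + x - 1)/x^2.
_G_SERIES_SWITCHOVER = 1e-4


def _as_dose(dose):
    """Validate a nonnegative dose (scalar or array), return float array."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be nonnegative (Gy)")
    return d


def _maybe_scalar(value, template):
    """Return a Python float when the input was scalar."""
    if np.ndim(template) == 0:
        return float(value)
    return value


@dataclass(frozen=True)
class LQParameters:
    """Two-parameter LQ model: ``alpha`` per Gy, ``beta`` per Gy^2."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.alpha >= 0 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha}")
        if not (self.beta > 0 and math.isfinite(self.beta)):
            raise ValueError(f"beta must be finite and > 0, got {self.beta}")

    @property
    def alpha_beta_ratio(self) -> float:
        """alpha/beta in Gy — the dose at which linear and quadratic killing are equal."""
        return self.alpha / self.beta


@dataclass(frozen=True)
class ELQParameters:
    """Three-parameter ELQ model.

    ``alpha`` is the low-dose slope (per Gy), ``beta`` the low-dose quadratic
    coefficient (per Gy^2) and ``alpha + gamma`` the high-dose slope (per Gy).
    ``gamma`` may be ``GAMMA_UNBOUNDED`` (``math.inf``), in which case every
    evaluation delegates to the LQ model with the same (alpha, beta).
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        if not (self.alpha >= 0 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha}")
        if not (self.beta > 0 and math.isfinite(self.beta)):
            raise ValueError(f"beta must be finite and > 0, got {self.beta}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0 (or math.inf), got {self.gamma}")

    @property
    def gamma_unbounded(self) -> bool:
        return math.isinf(self.gamma)

    @property
    def alpha_beta_ratio(self) -> float:
        return self.alpha / self.beta

    @property
    def extrapolation_number(self) -> float:
        """gamma^2/(2*beta): intercept of the back-extrapolated high-dose line (ln units)."""
        return self.gamma**2 / (2.0 * self.beta)

    def as_lq(self) -> LQParameters:
        """The (alpha, beta) projection, exact when gamma is unbounded."""
        return LQParameters(self.alpha, self.beta)


@dataclass(frozen=True)
class ProtractionSpec:
    """Constant-dose-rate exposure: ``dose_rate`` R (Gy/h), ``repair_rate``
    lambda (1/h), and ``delta`` (per Gy), a dose-rate-independent term.
    ``delta = 0`` recovers the pure protracted-LQ correspondence
    gamma = 2*beta*R/lambda. ``dose_rate`` may be ``math.inf`` (acute limit)."""

    dose_rate: float
    repair_rate: float
    delta: float = 0.0

    def __post_init__(self):
        if not self.dose_rate > 0:
            raise ValueError("dose_rate must be > 0")
        if not (self.repair_rate > 0 and math.isfinite(self.repair_rate)):
            raise ValueError("repair_rate must be finite and > 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


def lq_log_survival(params: LQParameters, dose):
    """LQ log survival ln S = -alpha*d - beta*d**2. Strictly decreasing in dose."""
    d = _as_dose(dose)
    return _maybe_scalar(-params.alpha * d - params.beta * d**2, dose)


def elq_log_survival(params: ELQParameters, dose):
    """ELQ log survival.

    ln S = -(alpha+gamma)*d + gamma^2/(2 beta) * (1 - exp(-2 beta d / gamma))

    With ``gamma`` unbounded this is exactly the LQ evaluation.
    """
    if params.gamma_unbounded:
        return lq_log_survival(params.as_lq(), dose)
    d = _as_dose(dose)
    a, b, g = params.alpha, params.beta, params.gamma
    k = g * g / (2.0 * b)
    out = -(a + g) * d + k * -np.expm1(-2.0 * b * d / g)
    return _maybe_scalar(out, dose)


def protraction_factor(lambda_T):
    """Lea-Catcheside dose-protraction factor for constant dose rate.

    G(x) = (2/x^2) * (exp(-x) + x - 1) with x = lambda*T, the product of the
    repair rate and the treatment time. G is 1 in the acute limit x -> 0,
    strictly decreasing, and ~ 2/x for large x. Small arguments are evaluated
    by Taylor series (1 - x/3 + x^2/12 - x^3/60) to avoid cancellation.
    """
    x = np.asarray(lambda_T, dtype=float)
    if np.any(x < 0):
        raise ValueError("lambda_T must be nonnegative")
    small = x < _G_SERIES_SWITCHOVER
    xs = np.where(small, 1.0, x)
    # expm1 keeps (e^-x - 1) + x accurate where the terms nearly cancel
    exact = 2.0 * (np.expm1(-xs) + xs) / xs**2
    series = 1.0 - x / 3.0 + x**2 / 12.0 - x**3 / 60.0
    return _maybe_scalar(np.where(small, series, exact), lambda_T)


def gamma_from_protraction(beta: float, spec: ProtractionSpec) -> float:
    """Map a protraction specification to the ELQ gamma: 2*beta/(delta + lambda/R).

    With ``delta = 0`` this is the protracted-LQ correspondence 2*beta*R/lambda.
    An infinite dose rate with ``delta = 0`` gives ``GAMMA_UNBOUNDED`` (the LQ
    limit); with ``delta > 0`` gamma stays finite at 2*beta/delta.
    """
    denom = spec.delta + spec.repair_rate / spec.dose_rate
    if denom == 0.0:
        return GAMMA_UNBOUNDED
    return 2.0 * beta / denom


def elq_low_dose_series(params: ELQParameters, dose):
    """Third-order small-dose expansion of the ELQ log survival.

    ln S ~ -alpha*d - beta*d^2 + (2*beta^2/(3*gamma))*d^3, obtained by
    expanding the exponential in the exact form; the remainder is O(d^4).
    With gamma unbounded the cubic term vanishes and the LQ form is returned.
    """
    d = _as_dose(dose)
    a, b = params.alpha, params.beta
    out = -a * d - b * d**2
    if not params.gamma_unbounded:
        out = out + (2.0 * b * b / (3.0 * params.gamma)) * d**3
    return _maybe_scalar(out, dose)


def elq_high_dose_asymptote(params: ELQParameters, dose):
    """High-dose linear asymptote ln S ~ -(alpha+gamma)*d + gamma^2/(2*beta).

    The exact ELQ approaches this line exponentially fast as d grows; the
    intercept gamma^2/(2*beta) is the (log) extrapolation number. Requires a
    finite gamma (the LQ has no linear asymptote).
    """
    if params.gamma_unbounded:
        raise ValueError("high-dose asymptote undefined for unbounded gamma (LQ limit)")
    d = _as_dose(dose)
    out = -(params.alpha + params.gamma) * d + params.extrapolation_number
    return _maybe_scalar(out, dose)
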