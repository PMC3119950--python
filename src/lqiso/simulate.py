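"""Synthetic dose-survival datasets with proportional noise.

The real digitized datasets behind the four published cell-line fits are not
available, so the generator emulates their statistical structure: a
monotonically spaced dose grid (~0.5-15 Gy, denser at low dose), surviving
fractions drawn around the LQ/ELQ model value with a standard deviation
proportional to the value (multiplicative noise, coefficient of variation
``noise_cv``). The default distribution is lognormal, parameterised so its
mean equals the model value and its CV equals ``noise_cv`` (positive support
by construction); a mean/SD-matched truncated normal is available as an
option. Draws are clipped to (0, 1] and a flag is raised when clipping
affects more than 1% of points.

Reproducibility: a master seed deterministically derives one substream per
dose value (keyed on the dose, not its grid position), so extending the dose
grid never reshuffles draws at existing doses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .fitting import SurvivalDataset
from .models import ELQParameters, LQParameters, elq_log_survival, lq_log_survival
from .reference import LITERATURE_FITS

__all__ = ["GeneratorConfig", "generate_dataset", "default_dose_grid", "fixture_library"]


def default_dose_grid(max_dose: float = 15.0, n_points: int = 12) -> np.ndarray:
    """Dose grid emulating a clonogenic-assay design: geometric-ish spacing
    from 0.5 Gy, denser at low dose where survival changes fastest."""
    return np.round(np.geomspace(0.5, max_dose, n_points), 3)


@dataclass(frozen=True)
class GeneratorConfig:
    """Recipe for one synthetic dataset.

    ``noise_cv`` is the coefficient of variation of the multiplicative noise
    (0 gives exact model values); ``replicates`` repeats every dose with an
    independent draw, mimicking repeated platings. The fixed ``seed`` makes
    output bit-identical across runs."""

    label: str
    params: LQParameters | ELQParameters
    dose_grid: np.ndarray = field(default_factory=default_dose_grid)
    noise_cv: float = 0.05
    replicates: int = 1
    seed: int = 0
    distribution: str = "lognormal"  # or "truncnorm"
    dose_rate_gy_per_min: float | None = None  # metadata only

    def __post_init__(self):
        grid = np.asarray(self.dose_grid, dtype=float)
        object.__setattr__(self, "dose_grid", grid)
        if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("dose grid must be nonnegative and strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.distribution not in ("lognormal", "truncnorm"):
            raise ValueError(f"unknown distribution {self.distribution!r}")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def _dose_rng(seed: int, dose: float) -> np.random.Generator:
    # substream keyed on the dose value so grids are extensible
    key = int(round(dose * 1e6)) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _model_survival(params, dose):
    if isinstance(params, ELQParameters):
        return np.exp(elq_log_survival(params, dose))
    return np.exp(lq_log_survival(params, dose))


def _draw(rng, mean, cv, distribution, size):
    if cv == 0:
        return np.full(size, mean)
    if distribution == "lognormal":
        sigma2 = math.log1p(cv * cv)
        mu = math.log(mean) - sigma2 / 2.0
        return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)
    # truncated-at-zero normal, mean/SD matched before truncation
    draws = rng.normal(loc=mean, scale=cv * mean, size=size)
    return np.abs(draws)  # reflection keeps support positive


def generate_dataset(config: GeneratorConfig) -> SurvivalDataset:
    """Draw one synthetic SurvivalDataset.

    The surviving fraction at each dose has mean equal to the model value and
    SD = noise_cv * model value; the dataset's sd column is set to
    noise_cv * observed value, matching how error bars would be assigned in
    practice. With ``noise_cv = 0`` the sd column is omitted (the fitting
    layer then applies the proportional-SD default)."""
    doses, values = [], []
    n_clipped = 0
    n_total = 0
    for d in config.dose_grid:
        mean = float(_model_survival(config.params, d))
        rng = _dose_rng(config.seed, d)
        draws = _draw(rng, mean, config.noise_cv, config.distribution, config.replicates)
        n_total += draws.size
        n_clipped += int(np.sum(draws > 1.0))
        draws = np.clip(draws, 1e-12, 1.0)
        for v in draws:
            doses.append(d)
            values.append(float(v))
    if n_total and n_clipped / n_total > 0.01:
        warnings.warn(
            f"noise_cv={config.noise_cv} clipped {n_clipped}/{n_total} draws above 1",
            RuntimeWarning,
        )
    dose_arr = np.asarray(doses)
    sf_arr = np.asarray(values)
    sd_factor = config.noise_cv
    if config.replicates > 1:
        # collapse replicates to per-dose means so doses stay strictly
        # increasing; the SD of a k-replicate mean shrinks by sqrt(k)
        uniq = np.unique(dose_arr)
        sf_arr = np.array([sf_arr[dose_arr == u].mean() for u in uniq])
        dose_arr = uniq
        sd_factor = config.noise_cv / math.sqrt(config.replicates)
    sd = None if config.noise_cv == 0 else sd_factor * sf_arr
    return SurvivalDataset(
        label=config.label, dose=dose_arr, surviving_fraction=sf_arr, sd=sd
    )


def fixture_library() -> dict[str, GeneratorConfig]:
    """Named generator configurations for the four published cell lines.

    True parameters are the published ELQ fits (CHO is the LQ limit, gamma
    unbounded; PC3/NCIH841/CP3 have alpha = 0 exactly); metadata records the
    published measurement dose rates."""
    return {
        name: GeneratorConfig(
            label=name,
            params=fit.elq,
            dose_rate_gy_per_min=fit.dose_rate_gy_per_min,
        )
        for name, fit in LITERATURE_FITS.items()
    }
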