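"""Simplified cohort-component population generator.

Stands in for an official national population projection: six variant
parameterizations spanning low/high fertility (G), life expectancy (L) and
net migration (W).  Each projection year the population is aged forward
under Gompertz-Makeham survival whose level is tuned so that period life
expectancy moves linearly toward the variant's 2040 target, newborns are
added from a fertility rate applied to women of childbearing age, and net
migration is spread over a fixed triangular age profile peaking at age 25.

The generator is deterministic; the ``seed`` argument is accepted for API
symmetry with the other generators and reserved for future stochastic
variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from ..grids import AGES, N_AGES, N_SEXES, N_YEARS, SEXES, YEARS
from ..interpolation import spline_ages

__all__ = [
    "DemographicVariantParams",
    "PopulationProjection",
    "VARIANTS",
    "default_base_population",
    "generate_population",
    "mortality_curves",
    "mortality_surface",
]

# Period life expectancy at birth in the base year (tuning anchor).
LIFE_EXPECTANCY_BASE = {"male": 77.5, "female": 82.6}

# Gompertz-Makeham shape; only the senescent level b is tuned per year.
_GM_THETA = 0.1
_GM_MAKEHAM = {"male": 3.0e-4, "female": 2.0e-4}

_MALE_BIRTH_SHARE = 0.5122  # ~105 boys per 100 girls
_FERTILE_AGES = slice(15, 50)
_FERTILE_SPAN = 35.0


@dataclass(frozen=True)
class DemographicVariantParams:
    """One fertility / life-expectancy / migration assumption triple."""

    variant_id: str
    fertility: float  # children per woman
    life_expectancy_2040: dict[str, float]  # years at birth per sex
    net_migration: float  # persons per year (may be negative)

    def __post_init__(self):
        if self.fertility < 0:
            # zero is admitted as a limit case (no births)
            raise ValueError("fertility must be non-negative")
        for sex in SEXES:
            le = self.life_expectancy_2040[sex]
            if not 40 < le < 110:
                raise ValueError(f"life_expectancy_2040[{sex}]={le} outside (40, 110)")
        if not np.isfinite(self.net_migration):
            raise ValueError("net_migration must be finite")


#: Six variants: the G2L2W2 baseline plus single-knob departures.
VARIANTS: dict[str, DemographicVariantParams] = {
    p.variant_id: p
    for p in (
        DemographicVariantParams("G2L2W2", 1.55, {"male": 84.0, "female": 88.0}, 290_000.0),
        DemographicVariantParams("G2L2W1", 1.55, {"male": 84.0, "female": 88.0}, 150_000.0),
        DemographicVariantParams("G2L2W3", 1.55, {"male": 84.0, "female": 88.0}, 400_000.0),
        DemographicVariantParams("G2L1W2", 1.55, {"male": 82.5, "female": 86.5}, 290_000.0),
        DemographicVariantParams("G2L3W2", 1.55, {"male": 85.5, "female": 89.5}, 290_000.0),
        DemographicVariantParams("G1L2W2", 1.40, {"male": 84.0, "female": 88.0}, 290_000.0),
    )
}


@dataclass(frozen=True)
class PopulationProjection:
    """Person counts on the full (sex, age, year) grid."""

    counts: np.ndarray
    variant_id: str = ""

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (N_SEXES, N_AGES, N_YEARS):
            raise ValueError(f"expected shape {(N_SEXES, N_AGES, N_YEARS)}, got {c.shape}")
        if not np.isfinite(c).all():
            raise ValueError("non-finite population counts")
        if (c < 0).any():
            raise ValueError("negative population counts")
        object.__setattr__(self, "counts", c)

    @property
    def base_year_counts(self) -> np.ndarray:
        return self.counts[:, :, 0]


# ---------------------------------------------------------------------------
# mortality level tuning


def _gm_rates(ages: np.ndarray, b: float, sex: str) -> np.ndarray:
    return _GM_MAKEHAM[sex] + b * np.exp(_GM_THETA * ages)


def _life_expectancy(b: float, sex: str) -> float:
    ages = np.arange(0, 121, dtype=float)
    m = _gm_rates(ages, b, sex)
    surv = np.exp(-np.concatenate(([0.0], np.cumsum(m))))
    return float(np.trapezoid(surv, np.arange(0, 122, dtype=float)))


@lru_cache(maxsize=None)
def _solve_gm_level(target_le: float, sex: str) -> float:
    return brentq(lambda b: _life_expectancy(b, sex) - target_le, 1e-8, 5e-3, xtol=1e-14)


def mortality_curves(params: DemographicVariantParams, year: int) -> np.ndarray:
    """(sex, age) general-mortality rates for one projection year.

    The Gompertz-Makeham level is solved so that period life expectancy at
    birth interpolates linearly between the base-year anchor and the
    variant's 2040 target.
    """
    frac = (year - YEARS[0]) / (YEARS[-1] - YEARS[0])
    out = np.empty((N_SEXES, N_AGES))
    for s, sex in enumerate(SEXES):
        le = LIFE_EXPECTANCY_BASE[sex] + frac * (
            params.life_expectancy_2040[sex] - LIFE_EXPECTANCY_BASE[sex]
        )
        b = _solve_gm_level(round(le, 9), sex)
        out[s] = _gm_rates(AGES.astype(float), b, sex)
    return out


def mortality_surface(params: DemographicVariantParams) -> np.ndarray:
    """Full (sex, age, year) general-mortality surface for a variant."""
    return np.stack([mortality_curves(params, int(y)) for y in YEARS], axis=2)


# ---------------------------------------------------------------------------
# base pyramid


def default_base_population(total: float = 81.75e6) -> np.ndarray:
    """Plausible 2010-style age pyramid, shape (sex, age), scaled to ``total``.

    Built from spline-interpolated anchor counts (mid-life bulge, tapering
    old ages) and an age-declining male share.
    """
    anchors = [
        (0, 665), (5, 700), (10, 770), (15, 830), (20, 975), (25, 990),
        (30, 970), (35, 950), (40, 1250), (45, 1400), (50, 1270), (55, 1100),
        (60, 980), (65, 900), (70, 1050), (75, 850), (80, 540), (85, 320),
        (90, 130), (95, 35), (100, 6),
    ]
    both = spline_ages(anchors, lower=0.0)
    both *= total / both.sum()
    share_anchors = [
        (0, 0.512), (20, 0.510), (40, 0.505), (60, 0.490), (70, 0.470),
        (80, 0.420), (90, 0.330), (100, 0.250),
    ]
    male_share = spline_ages(share_anchors, lower=0.0, upper=1.0)
    return np.stack([both * male_share, both * (1.0 - male_share)])


def _migration_profile() -> np.ndarray:
    # triangular over ages 0..50 peaking at 25
    w = np.maximum(0.0, 1.0 - np.abs(AGES - 25) / 25.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# projection


def generate_population(
    params: DemographicVariantParams,
    base_counts: np.ndarray,
    seed: int = 2010,
    *,
    mortality_override: np.ndarray | None = None,
) -> PopulationProjection:
    """Cohort-component projection of ``base_counts`` through 2040.

    Parameters
    ----------
    params
        Variant knobs (fertility, 2040 life expectancy, net migration).
    base_counts
        Base-year person counts, shape (sex, age) covering ages 0..100.
    seed
        Accepted for determinism contract symmetry; the generator itself is
        deterministic.
    mortality_override
        Optional (sex, age) rate grid applied in every year in place of the
        tuned Gompertz-Makeham schedule (used for limit-case testing).
    """
    base = np.asarray(base_counts, dtype=float)
    if base.shape != (N_SEXES, N_AGES):
        raise ValueError(f"base_counts must have shape {(N_SEXES, N_AGES)} (ages 0..100)")
    if not np.isfinite(base).all():
        raise ValueError("non-finite base counts")
    if (base < 0).any():
        raise ValueError("negative base counts")

    profile = _migration_profile()
    counts = np.empty((N_SEXES, N_AGES, N_YEARS))
    counts[:, :, 0] = base
    for yi in range(1, N_YEARS):
        if mortality_override is not None:
            m = np.asarray(mortality_override, dtype=float)
        else:
            m = mortality_curves(params, int(YEARS[yi - 1]))
        surv = np.exp(-m)
        prev = counts[:, :, yi - 1]
        nxt = np.zeros_like(prev)
        nxt[:, 1:] = prev[:, :-1] * surv[:, :-1]
        nxt[:, -1] += prev[:, -1] * surv[:, -1]  # age 100 is absorbing
        women = prev[1, _FERTILE_AGES].sum()
        births = params.fertility * women / _FERTILE_SPAN
        nxt[0, 0] = births * _MALE_BIRTH_SHARE
        nxt[1, 0] = births * (1.0 - _MALE_BIRTH_SHARE)
        nxt += 0.5 * params.net_migration * profile[None, :]
        counts[:, :, yi] = np.maximum(nxt, 0.0)
    return PopulationProjection(counts, variant_id=params.variant_id)
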