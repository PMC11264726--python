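"""Synthetic age- and sex-specific epidemiological inputs.

Prevalence shapes follow the broad strokes of diagnosed diabetes in an
industrialised population: type 1 rises through childhood to a low adult
plateau, type 2 climbs logistically with age; incidence mirrors those
shapes; the mortality rate ratio of ill versus healthy declines with age.
Levels are calibrated so the population-weighted base-year prevalence hits
configurable targets (defaults: 0.3% type 1, 7% type 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..grids import AGES, N_AGES, N_SEXES, SEXES, TYPES
from .demography import VARIANTS, default_base_population, mortality_curves

__all__ = ["EpiConfig", "EpiInputs", "generate_epi_inputs"]


@dataclass(frozen=True)
class EpiConfig:
    """Shape and level knobs for the epidemiological generator."""

    # population-weighted base-year prevalence targets
    target_prev_t1: float = 0.003
    target_prev_t2: float = 0.07
    # type 2 prevalence: logistic rise with age
    t2_prev_midpoint: float = 65.0
    t2_prev_scale: float = 12.0
    # type 1 prevalence: linear rise to a plateau at this age
    t1_prev_plateau_age: float = 15.0
    # male-to-female shape multipliers (levels recalibrated jointly)
    male_factor_t1: float = 1.05
    male_factor_t2: float = 1.10
    # incidence levels (per person-year)
    t2_inc_floor: float = 5.0e-4
    t2_inc_max: float = 0.018
    t2_inc_midpoint: float = 62.0
    t2_inc_scale: float = 10.0
    t1_inc_peak: float = 3.0e-4
    t1_inc_peak_age: float = 12.0
    t1_inc_width: float = 15.0
    # MRR = 1 + amplitude * exp(-age / decay)
    mrr_amplitude: dict[str, float] = field(
        default_factory=lambda: {"T1": 5.5, "T2": 3.0}
    )
    mrr_decay: dict[str, float] = field(default_factory=lambda: {"T1": 45.0, "T2": 40.0})
    # optional multiplicative lognormal jitter on prevalence and incidence
    jitter_sd: float = 0.0


@dataclass(frozen=True)
class EpiInputs:
    """Base-year epidemiological grids, all shaped (sex, age)."""

    prevalence0: dict[str, np.ndarray]  # per type, proportions
    incidence: dict[str, np.ndarray]  # per type, per person-year
    mortality_general: np.ndarray  # per person-year
    mrr: dict[str, np.ndarray]  # per type, dimensionless

    def __post_init__(self):
        for d in TYPES:
            for grid, lo_ok in (
                (self.prevalence0[d], True),
                (self.incidence[d], True),
                (self.mrr[d], True),
            ):
                g = np.asarray(grid, dtype=float)
                if g.shape != (N_SEXES, N_AGES):
                    raise ValueError(f"bad grid shape {g.shape}")
                if not np.isfinite(g).all() or (g < 0).any():
                    raise ValueError("epi grids must be finite and non-negative")
            if (np.asarray(self.prevalence0[d]) > 1).any():
                raise ValueError("prevalence above 1")
        m = np.asarray(self.mortality_general, dtype=float)
        if m.shape != (N_SEXES, N_AGES) or not np.isfinite(m).all() or (m < 0).any():
            raise ValueError("bad general mortality grid")

    def weighted_prevalence(self, pop_base: np.ndarray, diabetes_type: str) -> float:
        """Population-weighted prevalence of one type against a (sex, age) pyramid."""
        w = np.asarray(pop_base, dtype=float)
        return float((self.prevalence0[diabetes_type] * w).sum() / w.sum())


def _logistic(a: np.ndarray, midpoint: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(a - midpoint) / scale))


def generate_epi_inputs(
    config: EpiConfig | None = None,
    seed: int = 2010,
    population: np.ndarray | None = None,
) -> EpiInputs:
    """Generate calibrated base-year epidemiological inputs.

    ``population`` is the (sex, age) pyramid used for calibration weighting;
    defaults to :func:`default_base_population`.  Deterministic given
    ``(config, seed)``; ``seed`` only matters when ``config.jitter_sd > 0``.
    """
    cfg = config or EpiConfig()
    pop = default_base_population() if population is None else np.asarray(population, float)
    if pop.shape != (N_SEXES, N_AGES):
        raise ValueError(f"population must have shape {(N_SEXES, N_AGES)}")
    a = AGES.astype(float)

    shapes = {
        "T1": np.minimum(a / cfg.t1_prev_plateau_age, 1.0),
        "T2": _logistic(a, cfg.t2_prev_midpoint, cfg.t2_prev_scale),
    }
    male_factor = {"T1": cfg.male_factor_t1, "T2": cfg.male_factor_t2}
    targets = {"T1": cfg.target_prev_t1, "T2": cfg.target_prev_t2}

    rng = np.random.default_rng(seed)
    prevalence0: dict[str, np.ndarray] = {}
    for d in TYPES:
        shape = np.stack([shapes[d] * male_factor[d], shapes[d]])
        if cfg.jitter_sd > 0:
            noise = np.exp(rng.normal(0.0, cfg.jitter_sd, shape.shape) - cfg.jitter_sd**2 / 2)
            shape = shape * noise
        level = targets[d] * pop.sum() / (shape * pop).sum()
        prev = level * shape
        if (prev > 1).any():
            raise ValueError(f"configured shapes produce prevalence > 1 for {d}")
        prevalence0[d] = prev

    inc_t2 = cfg.t2_inc_floor + cfg.t2_inc_max * _logistic(a, cfg.t2_inc_midpoint, cfg.t2_inc_scale)
    inc_t1 = cfg.t1_inc_peak * np.exp(-(((a - cfg.t1_inc_peak_age) / cfg.t1_inc_width) ** 2))
    incidence = {
        "T1": np.stack([inc_t1 * male_factor["T1"], inc_t1]),
        "T2": np.stack([inc_t2 * male_factor["T2"], inc_t2]),
    }
    if cfg.jitter_sd > 0:
        for d in TYPES:
            noise = np.exp(
                rng.normal(0.0, cfg.jitter_sd, incidence[d].shape) - cfg.jitter_sd**2 / 2
            )
            incidence[d] = incidence[d] * noise

    mrr = {}
    for d in TYPES:
        curve = 1.0 + cfg.mrr_amplitude[d] * np.exp(-a / cfg.mrr_decay[d])
        mrr[d] = np.stack([curve, curve])

    mortality_general = mortality_curves(VARIANTS["G2L2W2"], 2010)
    return EpiInputs(prevalence0, incidence, mortality_general, mrr)
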