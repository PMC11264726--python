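"""Illness-death-model prevalence projection.

The three-state model healthy -> ill -> dead (no remission) implies a
transport equation for the age- and time-specific prevalence p(a, t):

    dp/dt + dp/da = (1 - p) * ( i(a,t) - p * (m1(a,t) - m0(a,t)) )

where i is the incidence rate, m1 and m0 are the mortality rates of the ill
and healthy.  Only the general-population mortality m and the mortality rate
ratio MRR = m1/m0 are observed, so the state-specific rates are recovered
from the mixture identity m = p*m1 + (1-p)*m0:

    m0 = m / (1 + p*(MRR - 1)),      m1 = MRR * m0.

The equation is integrated along characteristics (age and calendar time
advancing together) with classical Runge-Kutta.  A stochastic
microsimulation of the same three-state process serves as an independent
validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import AGES, BASE_YEAR, N_AGES, N_SEXES, N_YEARS, SEXES, TYPES, YEARS

__all__ = [
    "RateSurface",
    "PrevalenceSurface",
    "TrendSpec",
    "apply_trend",
    "solve_idm_pde",
    "microsim_oracle",
    "constant_prevalence_surface",
    "case_counts",
]


# ---------------------------------------------------------------------------
# rate surfaces


@dataclass(frozen=True)
class RateSurface:
    """Dense rate grid over (sex, age, year), shape (2, 101, 31)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_SEXES, N_AGES, N_YEARS):
            raise ValueError(f"expected shape {(N_SEXES, N_AGES, N_YEARS)}, got {v.shape}")
        if np.isnan(v).any():
            raise ValueError("NaN in rate surface")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_base(cls, base: np.ndarray) -> "RateSurface":
        """Constant-in-time surface from a (sex, age) base-year grid."""
        base = np.asarray(base, dtype=float)
        if base.shape != (N_SEXES, N_AGES):
            raise ValueError(f"expected shape {(N_SEXES, N_AGES)}, got {base.shape}")
        return cls(np.repeat(base[:, :, None], N_YEARS, axis=2))

    def at(self, sex_idx: int, ages: np.ndarray, t: float) -> np.ndarray:
        """Bilinear evaluation at fractional ages and time t (clamped to grid)."""
        t = min(max(t, YEARS[0]), YEARS[-1])
        j = min(int(t - YEARS[0]), N_YEARS - 2)
        w = t - YEARS[j]
        col = (1.0 - w) * self.values[sex_idx, :, j] + w * self.values[sex_idx, :, j + 1]
        a = np.clip(ages, 0.0, 100.0)
        return np.interp(a, AGES.astype(float), col)


@dataclass(frozen=True)
class TrendSpec:
    """Proportional annual changes applied to incidence and MRR."""

    annual_change_incidence: float = 0.0
    annual_change_mrr: float = 0.0
    reference_year: int = BASE_YEAR

    def __post_init__(self):
        for name in ("annual_change_incidence", "annual_change_mrr"):
            if 1.0 + getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must exceed -1")


def apply_trend(
    base: np.ndarray,
    trend: float,
    reference_year: int = BASE_YEAR,
    *,
    floor: float | None = None,
) -> RateSurface:
    """Geometric calendar-time trend from a base-year (sex, age) grid.

    value(a, s, t) = value(a, s, ref) * (1 + trend)^(t - ref), optionally
    floored (used to keep a declining MRR from crossing below 1).
    """
    if 1.0 + trend <= 0.0:
        raise ValueError("trend must exceed -1")
    base = np.asarray(base, dtype=float)
    if base.shape != (N_SEXES, N_AGES):
        raise ValueError(f"expected shape {(N_SEXES, N_AGES)}, got {base.shape}")
    mult = (1.0 + trend) ** (YEARS - reference_year).astype(float)
    surf = base[:, :, None] * mult[None, None, :]
    if floor is not None:
        surf = np.maximum(surf, floor)
    return RateSurface(surf)


# ---------------------------------------------------------------------------
# PDE solver


@dataclass
class PrevalenceSurface:
    """Prevalence p(a, s, d, t): per-type arrays of shape (2, 101, 31)."""

    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for d, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (N_SEXES, N_AGES, N_YEARS):
                raise ValueError(f"type {d}: bad shape {v.shape}")
            if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
                raise ValueError(f"type {d}: prevalence outside [0, 1]")
            self.values[d] = np.clip(v, 0.0, 1.0)


def _excess_mortality(p, m, mrr):
    # m1 - m0 with m0 = m / (1 + p*(mrr-1)), m1 = mrr*m0
    return m * (mrr - 1.0) / (1.0 + p * (mrr - 1.0))


def solve_idm_pde(
    p0: np.ndarray,
    incidence: RateSurface,
    mortality_general: RateSurface,
    mrr: RateSurface,
    step: float = 0.25,
) -> np.ndarray:
    """Integrate the illness-death PDE for one sex-pair of surfaces.

    Parameters
    ----------
    p0
        Initial prevalence cross-section at the base year, shape (2, 101).
    incidence, mortality_general, mrr
        Rate surfaces on the common (sex, age, year) grid.
    step
        Characteristic step in years; must divide 1 evenly (1, 0.5, 0.25, ...).

    Returns
    -------
    Prevalence array of shape (2, 101, 31), clipped to [0, 1].  The base-year
    slice equals ``p0`` exactly; the age-0 boundary is 0 after the base year.
    """
    if not (0 < step <= 1):
        raise ValueError("step must be in (0, 1]")
    n_sub = round(1.0 / step)
    if abs(n_sub * step - 1.0) > 1e-9:
        raise ValueError("step must divide one year evenly")
    h = 1.0 / n_sub

    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (N_SEXES, N_AGES):
        raise ValueError(f"p0 must have shape {(N_SEXES, N_AGES)}")
    if np.isnan(p0).any():
        raise ValueError("NaN in initial prevalence")

    grid = np.arange(0.0, 100.0 + h / 2, h)  # fine age grid
    out = np.empty((N_SEXES, N_AGES, N_YEARS))
    for s in range(N_SEXES):
        p = np.interp(grid, AGES.astype(float), p0[s])
        out[s, :, 0] = p0[s]

        def rhs(pp, a, t):
            i = incidence.at(s, a, t)
            m = mortality_general.at(s, a, t)
            r = mrr.at(s, a, t)
            return (1.0 - pp) * (i - pp * _excess_mortality(pp, m, r))

        for k in range(30 * n_sub):
            t = BASE_YEAR + k * h
            a = grid
            k1 = rhs(p, a, t)
            k2 = rhs(p + 0.5 * h * k1, a + 0.5 * h, t + 0.5 * h)
            k3 = rhs(p + 0.5 * h * k2, a + 0.5 * h, t + 0.5 * h)
            k4 = rhs(p + h * k3, a + h, t + h)
            adv = p + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            p = np.empty_like(p)
            p[1:] = adv[:-1]  # characteristics move one cell up in age
            p[0] = 0.0  # newborn boundary
            np.clip(p, 0.0, 1.0, out=p)
            if (k + 1) % n_sub == 0:
                out[s, :, (k + 1) // n_sub] = p[::n_sub]
    return out


def constant_prevalence_surface(p0: np.ndarray) -> np.ndarray:
    """Hold the base-year cross-section fixed in every projection year."""
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (N_SEXES, N_AGES):
        raise ValueError(f"p0 must have shape {(N_SEXES, N_AGES)}")
    return np.repeat(p0[:, :, None], N_YEARS, axis=2)


# ---------------------------------------------------------------------------
# microsimulation oracle


def microsim_oracle(
    incidence: RateSurface,
    mortality_general: RateSurface,
    mrr: RateSurface,
    n: int,
    seed: int,
    probes: list[tuple[int, int]],
    *,
    sex_idx: int = 0,
    p0: np.ndarray | None = None,
    dt: float = 0.05,
    from_birth: bool = False,
) -> list[tuple[float, float]]:
    """Stochastic three-state cohort simulation at requested (age, year) probes.

    Each probe (a, t) simulates one cohort of ``n`` individuals forward in
    time steps ``dt`` (<= 0.1 year) using the same m0/m1 mortality partition
    as the PDE, with the partition prevalence taken self-consistently from
    the surviving cohort.  By default the cohort enters where the PDE's
    domain starts — age 0 in year t-a if born after the base year, else age
    a-(t-base) in the base year, optionally seeded ill with probability
    ``p0`` at the entry age — which makes the estimates directly comparable
    to the PDE solution.  With ``from_birth=True`` every cohort starts
    healthy at age 0 in year t-a (rate lookups before the grid are clamped
    to its edge).

    Returns ``(p_hat, se)`` per probe: prevalence among survivors and its
    binomial standard error.
    """
    if n < 1000:
        raise ValueError("n must be at least 1000")
    if not 0 < dt <= 0.1:
        raise ValueError("dt must be in (0, 0.1]")
    rng = np.random.default_rng(seed)
    results = []
    for a_probe, t_probe in probes:
        if from_birth:
            a0 = 0.0
            t0 = float(t_probe) - float(a_probe)
        else:
            back = t_probe - BASE_YEAR
            a0 = max(0.0, float(a_probe) - back)
            t0 = float(t_probe) - (float(a_probe) - a0)
        if p0 is not None and t0 == BASE_YEAR:
            start_prev = float(np.interp(a0, AGES.astype(float), np.asarray(p0, float)))
        else:
            start_prev = 0.0
        ill = rng.random(n) < start_prev
        alive = np.ones(n, dtype=bool)
        n_steps = round((float(a_probe) - a0) / dt)
        one = np.ones(1)
        for k in range(n_steps):
            a = a0 + k * dt
            t = t0 + k * dt
            i = float(incidence.at(sex_idx, one * a, t)[0])
            m = float(mortality_general.at(sex_idx, one * a, t)[0])
            r = float(mrr.at(sex_idx, one * a, t)[0])
            n_alive = int(alive.sum())
            if n_alive == 0:
                break
            p_now = float((ill & alive).sum()) / n_alive
            m0 = m / (1.0 + p_now * (r - 1.0))
            m1 = r * m0
            u = rng.random(n)
            # deaths
            die_h = alive & ~ill & (u < 1.0 - np.exp(-m0 * dt))
            die_i = alive & ill & (u < 1.0 - np.exp(-m1 * dt))
            alive &= ~(die_h | die_i)
            # incident cases among surviving healthy
            v = rng.random(n)
            new_ill = alive & ~ill & (v < 1.0 - np.exp(-i * dt))
            ill |= new_ill
        n_alive = int(alive.sum())
        if n_alive == 0:
            results.append((float("nan"), float("nan")))
            continue
        p_hat = float((ill & alive).sum()) / n_alive
        se = float(np.sqrt(max(p_hat * (1.0 - p_hat), 1e-12) / n_alive))
        results.append((p_hat, se))
    return results


# ---------------------------------------------------------------------------
# case counts


def case_counts(prev: PrevalenceSurface, pop_counts: np.ndarray) -> dict[str, np.ndarray]:
    """Case numbers count(a,s,d,t) = p(a,s,d,t) * N(a,s,t) per diabetes type."""
    pop_counts = np.asarray(pop_counts, dtype=float)
    if pop_counts.shape != (N_SEXES, N_AGES, N_YEARS):
        raise ValueError("population grid mismatch")
    return {d: prev.values[d] * pop_counts for d in prev.values}
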