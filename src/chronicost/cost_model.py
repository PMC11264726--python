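"""Per capita cost baselines, excess-cost growth, totals, cost ratios,
attributable cost fractions and national extrapolation.

The baseline profile is derived from the aggregated claims table: per
(diagnosis, sex, age group) the six expenditure fields are summed and
divided by the stratum member count, then linearly interpolated between
group midpoints to single years of age.  Excess costs (ill minus healthy
per capita) are the only component subject to the annual growth rate; the
per capita costs of people without the disease stay at their base-year
level throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import BASE_YEAR, DIAGNOSES, N_AGES, N_SEXES, N_YEARS, SEXES, TYPES, YEARS
from .interpolation import linear_by_age_group
from .prevalence_projection import PrevalenceSurface
from .synthetic_data.costs import AggregatedCostTable

__all__ = [
    "PerCapitaCostProfile",
    "baseline_per_capita",
    "project_per_capita",
    "per_capita_surfaces",
    "total_costs",
    "total_excess_costs",
    "cost_ratio",
    "compute_pac",
    "aggregate_pac",
    "extrapolate_national",
]

#: floor (in euro) applied to the no-disease per capita curve before ratio
#: computation, to avoid division blow-ups in degenerate synthetic strata
RATIO_FLOOR_EUR = 1.0


@dataclass(frozen=True)
class PerCapitaCostProfile:
    """Base-year per capita cost curves c_d(sex, age) per diagnosis group.

    ``aggregate`` holds the all-ages average per person per (diagnosis, sex)
    — total stratum euro sums divided by total members, the headline
    published figures.
    """

    curves: dict[str, np.ndarray]  # diagnosis -> (sex, age)
    aggregate: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        for d in DIAGNOSES:
            c = np.asarray(self.curves[d], dtype=float)
            if c.shape != (N_SEXES, N_AGES):
                raise ValueError(f"curve {d}: bad shape {c.shape}")
            if (c < 0).any() or not np.isfinite(c).all():
                raise ValueError(f"curve {d}: costs must be finite and non-negative")

    def excess(self, diabetes_type: str) -> np.ndarray:
        """Excess per capita cost e_d = c_d - c_none, shape (sex, age)."""
        return self.curves[diabetes_type] - self.curves["none"]


def baseline_per_capita(table: AggregatedCostTable) -> PerCapitaCostProfile:
    """Base-year per capita cost profile from the aggregated claims table.

    Per (diagnosis, sex, age group): sum the six expenditure fields and
    divide by the member count; empty strata get per capita 0 with a
    warning.  Group values are then linearly interpolated between group
    midpoints to single ages 0..100.
    """
    df = table.frame
    if (df["total_cost_eur"] < 0).any() or (df["member_count"] < 0).any():
        raise ValueError("negative entries in cost table")
    grouped = (
        df.groupby(["diagnosis", "sex", "age_group_lo", "age_group_hi"])
        .agg(total=("total_cost_eur", "sum"), members=("member_count", "first"))
        .reset_index()
    )
    n_empty = int((grouped["members"] == 0).sum())
    if n_empty:
        warnings.warn(
            f"{n_empty} stratum/strata with zero members; per capita set to 0",
            UserWarning,
            stacklevel=2,
        )
    grouped["per_capita"] = np.where(
        grouped["members"] > 0, grouped["total"] / grouped["members"].where(grouped["members"] > 0), 0.0
    )

    curves: dict[str, np.ndarray] = {}
    aggregate: dict[tuple[str, str], float] = {}
    for d in DIAGNOSES:
        per_sex = []
        for sex in SEXES:
            sub = grouped[(grouped["diagnosis"] == d) & (grouped["sex"] == sex)].sort_values(
                "age_group_lo"
            )
            rows = list(zip(sub["age_group_lo"], sub["age_group_hi"], sub["per_capita"]))
            per_sex.append(linear_by_age_group(rows, lower=0.0))
            m = sub["members"].sum()
            aggregate[(d, sex)] = float(sub["total"].sum() / m) if m > 0 else 0.0
        curves[d] = np.stack(per_sex)
    return PerCapitaCostProfile(curves, aggregate)


def project_per_capita(
    profile: PerCapitaCostProfile, growth: float, year: int
) -> dict[str, np.ndarray]:
    """Per capita costs at ``year``: c_d = c_none + e_d * (1+growth)^(year-base).

    Growth compounds geometrically per calendar year from the base year and
    applies to the excess only; the no-disease curve is constant in time.
    """
    if growth <= -1:
        raise ValueError("growth must exceed -1")
    if year < BASE_YEAR:
        raise ValueError(f"year must be >= {BASE_YEAR}")
    factor = (1.0 + growth) ** (year - BASE_YEAR)
    out = {"none": profile.curves["none"].copy()}
    for d in TYPES:
        out[d] = profile.curves["none"] + profile.excess(d) * factor
    return out


def per_capita_surfaces(profile: PerCapitaCostProfile, growth: float) -> dict[str, np.ndarray]:
    """Full (sex, age, year) per capita surfaces for all diagnosis groups."""
    if growth <= -1:
        raise ValueError("growth must exceed -1")
    factors = (1.0 + growth) ** (YEARS - BASE_YEAR).astype(float)
    none = np.repeat(profile.curves["none"][:, :, None], N_YEARS, axis=2)
    out = {"none": none}
    for d in TYPES:
        out[d] = none + profile.excess(d)[:, :, None] * factors[None, None, :]
    return out


def _check_grid(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape != (N_SEXES, N_AGES, N_YEARS):
        raise ValueError(f"{name}: grid mismatch, got shape {arr.shape}")
    return arr


def total_costs(
    prev: PrevalenceSurface, pop_counts: np.ndarray, percap: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Total annual euro costs per diagnosis group, shape (sex, year).

    total_d(s, t) = sum_a N(a,s,t) * p_d(a,s,t) * c_d(a,s,t); the "none"
    entry prices the disease-free share 1 - p_T1 - p_T2 at c_none.
    """
    n = _check_grid(pop_counts, "population")
    out = {}
    p_all = np.zeros_like(n)
    for d in TYPES:
        c = _check_grid(percap[d], f"percap[{d}]")
        out[d] = (n * prev.values[d] * c).sum(axis=1)
        p_all = p_all + prev.values[d]
    c_none = _check_grid(percap["none"], "percap[none]")
    out["none"] = (n * np.clip(1.0 - p_all, 0.0, 1.0) * c_none).sum(axis=1)
    return out


def total_excess_costs(
    prev: PrevalenceSurface, pop_counts: np.ndarray, excess: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Total annual excess euro costs per type, shape (sex, year)."""
    n = _check_grid(pop_counts, "population")
    return {
        d: (n * prev.values[d] * _check_grid(excess[d], f"excess[{d}]")).sum(axis=1)
        for d in TYPES
    }


def cost_ratio(percap_d: np.ndarray, percap_none: np.ndarray) -> np.ndarray:
    """Elementwise per capita cost ratio R = c_d / c_none.

    Both sides are floored at RATIO_FLOOR_EUR so the ratio stays positive
    and finite even in degenerate (empty-stratum) synthetic strata; a zero
    cost after flooring is impossible, but non-finite input is rejected.
    """
    cd = np.asarray(percap_d, dtype=float)
    cn = np.asarray(percap_none, dtype=float)
    if not (np.isfinite(cd).all() and np.isfinite(cn).all()):
        raise ValueError("non-finite per capita costs")
    if cn.ndim == 2 and cd.ndim == 3:
        cn = cn[:, :, None]
    return np.maximum(cd, RATIO_FLOOR_EUR) / np.maximum(cn, RATIO_FLOOR_EUR)


def compute_pac(prev_d: np.ndarray, ratio: np.ndarray) -> np.ndarray:
    """Attributable cost fraction PAC = p(R-1) / (1 + p(R-1)).

    Clipped at 0 where R < 1 (protective strata); always < 1.
    """
    p = np.asarray(prev_d, dtype=float)
    r = np.asarray(ratio, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("prevalence outside [0, 1]")
    if (r <= 0).any():
        raise ValueError("cost ratio must be positive")
    x = p * (r - 1.0)
    return np.clip(x / (1.0 + x), 0.0, None)


def aggregate_pac(
    prev: PrevalenceSurface,
    pop_counts: np.ndarray,
    percap: dict[str, np.ndarray],
    diabetes_type: str,
) -> np.ndarray:
    """Cost-weighted aggregate attributable fraction per year, shape (year,).

    Equals total excess costs of the type divided by the total cost of the
    whole population when only this type's excess is counted:

        PAC_d(t) = E_d(t) / ( sum_a,s N*c_none + E_d(t) )

    which is identical to weighting the stratum-level PAC by stratum total
    costs.
    """
    n = _check_grid(pop_counts, "population")
    c_none = _check_grid(percap["none"], "percap[none]")
    c_d = _check_grid(percap[diabetes_type], f"percap[{diabetes_type}]")
    p_d = prev.values[diabetes_type]
    excess = (n * p_d * (c_d - c_none)).sum(axis=(0, 1))
    total = (n * c_none).sum(axis=(0, 1)) + excess
    if np.any(total <= 0):
        raise ValueError("zero total cost")
    return excess / total


def extrapolate_national(
    agg_pac: np.ndarray | float,
    sample_total_cost: np.ndarray | float,
    sample_fraction: float,
) -> dict[str, np.ndarray]:
    """National attributable euro from sample totals and attributable fraction.

    national_total = sample_total_cost / sample_fraction;
    attributable   = national_total * aggregate PAC.
    """
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    national = np.asarray(sample_total_cost, dtype=float) / sample_fraction
    attributable = national * np.asarray(agg_pac, dtype=float)
    return {"national_total": national, "attributable": attributable}


def totals_frame(
    totals: dict[str, np.ndarray],
    excess: dict[str, np.ndarray],
    counts: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Tidy per-(year, type, sex) results table."""
    rows = []
    for d in TYPES:
        for si, sex in enumerate(SEXES):
            for yi, year in enumerate(YEARS):
                n_cases = counts[d][si, :, yi].sum()
                tot = totals[d][si, yi]
                rows.append(
                    {
                        "year": int(year),
                        "type": d,
                        "sex": sex,
                        "total_cost_eur": tot,
                        "total_excess_eur": excess[d][si, yi],
                        "cases": n_cases,
                        "per_capita_eur": tot / n_cases if n_cases > 0 else 0.0,
                    }
                )
    return pd.DataFrame(rows)
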