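"""Synthetic claims-style aggregated cost table.

Emulates an aggregated claims extract from a random sample of the insured
population: total annual costs by expenditure field x diagnosis x sex x
five-year age group, plus member counts per (diagnosis, sex, age group)
stratum shared across the six fields.

Member counts are the sampled share of the base-year population in each
stratum; costs are members x a per capita schedule x fixed field shares,
with optional seeded lognormal noise.  The per capita schedules are scaled
per (diagnosis, sex) so that the member-weighted average — exactly what the
downstream baseline computation recovers — equals configurable targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..grids import (
    AGE_GROUPS,
    DIAGNOSES,
    EXPENDITURE_FIELDS,
    N_AGE_GROUPS,
    SEXES,
)
from .demography import PopulationProjection
from .epidemiology import EpiInputs

__all__ = ["CostConfig", "AggregatedCostTable", "generate_cost_table"]

COLUMNS = (
    "field",
    "diagnosis",
    "sex",
    "age_group_lo",
    "age_group_hi",
    "total_cost_eur",
    "member_count",
)

_DEFAULT_TARGETS = {
    ("T1", "male"): 4285.0,
    ("T1", "female"): 4889.0,
    ("T2", "male"): 3868.0,
    ("T2", "female"): 3889.0,
    ("none", "male"): 2360.0,
    ("none", "female"): 2316.0,
}

_DEFAULT_FIELD_SHARES = {
    "physicians": 0.17,
    "dentists": 0.04,
    "pharmacies": 0.17,
    "hospitals": 0.36,
    "sick_benefits": 0.06,
    "others": 0.20,
}

# per capita age tilt: schedule shape = 1 + tilt * (age/100 - 0.5);
# negative tilt = child-heavy costs (type 1), positive = old-age-heavy.
_DEFAULT_TILTS = {"T1": -0.8, "T2": 0.8, "none": 1.2}


@dataclass(frozen=True)
class CostConfig:
    sample_fraction: float = 0.068
    noise_sd: float = 0.01
    per_capita_targets: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_TARGETS)
    )
    field_shares: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FIELD_SHARES)
    )
    age_tilts: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_TILTS))

    def __post_init__(self):
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if set(self.field_shares) != set(EXPENDITURE_FIELDS):
            raise ValueError("field_shares must cover exactly the six expenditure fields")
        if abs(sum(self.field_shares.values()) - 1.0) > 1e-9:
            raise ValueError("field_shares must sum to 1")


@dataclass(frozen=True)
class AggregatedCostTable:
    """Claims-style aggregate: one row per (field, diagnosis, sex, age group)."""

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        n_expected = len(EXPENDITURE_FIELDS) * len(DIAGNOSES) * len(SEXES) * N_AGE_GROUPS
        if len(df) != n_expected:
            raise ValueError(f"expected {n_expected} rows, got {len(df)}")
        if (df["total_cost_eur"] < 0).any():
            raise ValueError("negative total_cost_eur")
        if (df["member_count"] < 0).any():
            raise ValueError("negative member_count")
        # member counts must be shared across the six fields of a stratum
        per_stratum = df.groupby(["diagnosis", "sex", "age_group_lo"])["member_count"].nunique()
        if (per_stratum != 1).any():
            raise ValueError("member_count differs across fields within a stratum")

    def stratum_members(self) -> pd.DataFrame:
        """One row per (diagnosis, sex, age group) with its member count."""
        return (
            self.frame.groupby(["diagnosis", "sex", "age_group_lo", "age_group_hi"])[
                "member_count"
            ]
            .first()
            .reset_index()
        )


def generate_cost_table(
    config: CostConfig | None = None,
    epi: EpiInputs | None = None,
    pop: PopulationProjection | None = None,
    seed: int = 2010,
) -> AggregatedCostTable:
    """Generate the aggregated cost table for the base year.

    Deterministic given ``(config, epi, pop, seed)``; two different seeds
    produce different tables whenever ``config.noise_sd > 0``.
    """
    cfg = config or CostConfig()
    if epi is None or pop is None:
        raise ValueError("epi inputs and population projection are required")

    n_base = pop.base_year_counts  # (sex, age)
    p = {
        "T1": epi.prevalence0["T1"],
        "T2": epi.prevalence0["T2"],
    }
    p["none"] = np.clip(1.0 - p["T1"] - p["T2"], 0.0, 1.0)

    rng = np.random.default_rng(seed)
    rows = []
    for diagnosis in DIAGNOSES:
        tilt = cfg.age_tilts.get(diagnosis, 0.0)
        for si, sex in enumerate(SEXES):
            members = np.zeros(N_AGE_GROUPS)
            shape = np.zeros(N_AGE_GROUPS)
            for gi, (lo, hi) in enumerate(AGE_GROUPS):
                ages = [a for a in range(lo, hi + 1) if a <= 100]
                if ages:
                    members[gi] = round(
                        cfg.sample_fraction * (n_base[si, ages] * p[diagnosis][si, ages]).sum()
                    )
                mid = (lo + hi) / 2.0
                shape[gi] = max(1.0 + tilt * (mid / 100.0 - 0.5), 0.05)
            target = cfg.per_capita_targets[(diagnosis, sex)]
            weighted = (members * shape).sum()
            scale = target * members.sum() / weighted if weighted > 0 else 0.0
            per_capita = scale * shape
            for gi, (lo, hi) in enumerate(AGE_GROUPS):
                for fld in EXPENDITURE_FIELDS:
                    base_cost = members[gi] * per_capita[gi] * cfg.field_shares[fld]
                    if cfg.noise_sd > 0 and base_cost > 0:
                        z = rng.normal(0.0, cfg.noise_sd)
                        base_cost *= np.exp(z - cfg.noise_sd**2 / 2)
                    rows.append(
                        (fld, diagnosis, sex, lo, hi, float(base_cost), int(members[gi]))
                    )
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    return AggregatedCostTable(frame)
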