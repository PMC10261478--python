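"""Goldberg cut-off screening for energy misreporters.

A participant's reported energy intake (EI) is compared with their
estimated basal metabolic rate (BMR).  Under plausible reporting the
EI:BMR ratio should scatter around the physical activity level (PAL);
the Goldberg band widens that expectation by the combined uncertainty of
a short food record, the BMR estimate and the PAL measure:

    S = sqrt(cv_wEI^2 / n_days + cv_wB^2 + cv_tP^2)
    lower, upper = PAL * exp(-/+ z * S / 100)

Participants whose ratio falls below the band are flagged as
under-reporters, above as over-reporters; the analysis set is the
participants flagged plausible.
"""

from __future__ import annotations

import enum
import math
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConfigError
from .knowledge_base import (
    AnalysisConfig,
    BmrCoefficient,
    GoldbergConfig,
    Participant,
    Sex,
)
from .nutrient_engine import NutrientProfile


class MisreportStatus(str, enum.Enum):
    plausible = "plausible"
    under = "under"
    over = "over"


class MisreportFlag(BaseModel):
    model_config = ConfigDict(frozen=True)

    participant_id: str
    ei_bmr_ratio: float
    lower_bound: float
    upper_bound: float
    status: MisreportStatus

    @model_validator(mode="after")
    def _consistent(self) -> "MisreportFlag":
        if self.lower_bound > self.upper_bound:
            raise ValueError("lower bound exceeds upper bound")
        expected = (
            MisreportStatus.under
            if self.ei_bmr_ratio < self.lower_bound
            else MisreportStatus.over
            if self.ei_bmr_ratio > self.upper_bound
            else MisreportStatus.plausible
        )
        if self.status is not expected:
            raise ValueError("status inconsistent with ratio and bounds")
        return self


def bmr_mj(
    sex: Sex,
    age: float,
    weight_kg: float,
    coefficients: Sequence[BmrCoefficient],
) -> float:
    """Basal metabolic rate (MJ/day) from the configured linear table."""
    for c in coefficients:
        if c.sex == sex and c.age_min <= age < c.age_max:
            return c.slope_mj_per_kg * weight_kg + c.intercept_mj
    raise ConfigError(f"no BMR coefficient row for sex={sex.value}, age={age}")


def goldberg_bounds(
    pal: float, cfg: GoldbergConfig | None = None
) -> tuple[float, float]:
    """Plausibility band for the EI:BMR ratio around the individual PAL."""
    cfg = cfg or GoldbergConfig()
    if pal <= 0:
        raise ValueError("PAL must be positive")
    s = math.sqrt(cfg.cv_wei**2 / cfg.n_days + cfg.cv_wb**2 + cfg.cv_tp**2)
    half_width = cfg.z * s / 100.0
    return pal * math.exp(-half_width), pal * math.exp(half_width)


def flag_misreporter(
    participant_id: str,
    energy_intake_mj: float,
    bmr: float,
    bounds: tuple[float, float],
) -> MisreportFlag:
    """Classify one participant's mean daily EI against the Goldberg band."""
    if bmr <= 0:
        raise ValueError("BMR must be positive")
    lower, upper = bounds
    ratio = energy_intake_mj / bmr
    status = (
        MisreportStatus.under
        if ratio < lower
        else MisreportStatus.over
        if ratio > upper
        else MisreportStatus.plausible
    )
    return MisreportFlag(
        participant_id=participant_id,
        ei_bmr_ratio=ratio,
        lower_bound=lower,
        upper_bound=upper,
        status=status,
    )


def flag_cohort(
    participants: Mapping[str, Participant],
    profiles: Mapping[str, NutrientProfile],
    cfg: AnalysisConfig | None = None,
) -> list[MisreportFlag]:
    """Goldberg screening of every participant that has a nutrient profile.

    EI is the profile's mean daily total energy (alcohol included),
    converted from kJ to MJ; BMR comes from the configured coefficient
    table; the band uses the participant's own questionnaire PAL.
    """
    cfg = cfg or AnalysisConfig()
    flags = []
    for pid in sorted(profiles):
        if pid not in participants:
            raise ConfigError(f"profile for unknown participant '{pid}'")
        part = participants[pid]
        bmr = bmr_mj(part.sex, part.age, part.weight_kg, cfg.bmr_coefficients)
        bounds = goldberg_bounds(part.pal, cfg.goldberg)
        ei_mj = profiles[pid].energy_kj / 1000.0
        flags.append(flag_misreporter(pid, ei_mj, bmr, bounds))
    return flags


def flags_frame(flags: Iterable[MisreportFlag]) -> pd.DataFrame:
    out = pd.DataFrame(
        [
            {
                "participant_id": f.participant_id,
                "ei_bmr_ratio": f.ei_bmr_ratio,
                "lower_bound": f.lower_bound,
                "upper_bound": f.upper_bound,
                "status": f.status.value,
            }
            for f in flags
        ]
    ).set_index("participant_id")
    return out


def analysis_set(flags: Iterable[MisreportFlag]) -> list[str]:
    """Participant ids retained after exclusion of misreporters."""
    return [
        f.participant_id for f in flags if f.status is MisreportStatus.plausible
    ]
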