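"""EI:BMR misreporting screen.

Reported energy intakes that are physiologically implausible bias diet
quality scores, so before any scoring-based analysis each participant's
basal metabolic rate (BMR) is estimated from the Schofield (1985)
weight-only equations and the ratio of mean daily energy intake to BMR
(EI:BMR) is computed. Following the statistical principle behind the
Goldberg cut-off — values outside the 95% limits of the EI:BMR distribution
are implausible — the top and bottom 2.5% of the distribution are excluded.

The 2.5% trim is operationalised by rank: with N participants,
``k = floor(0.025 * N)`` are removed from each tail. This rank rule, rather
than percentile interpolation, is the only simple reading consistent with
removing exactly 12 of 272 participants; ties are broken by participant id
so the screen is deterministic and order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ValidationError

#: Schofield (1985) weight-only coefficients, MJ/day: (slope, intercept) by
#: sex and age band. Bands: [18, 30), [30, 60], (60, inf).
SCHOFIELD_COEFFICIENTS: dict[str, dict[str, tuple[float, float]]] = {
    "man": {
        "18-30": (0.063, 2.896),
        "30-60": (0.048, 3.653),
        "60+": (0.049, 2.459),
    },
    "woman": {
        "18-30": (0.062, 2.036),
        "30-60": (0.034, 3.538),
        "60+": (0.038, 2.755),
    },
}

DEFAULT_TAIL_FRACTION = 0.025


@dataclass(frozen=True)
class ParticipantProfile:
    """Demographics needed by the screen (plus optional covariates elsewhere)."""

    participant_id: str
    scoring_sex: str  # "woman" | "man"
    age_years: float
    weight_kg: float

    def __post_init__(self) -> None:
        if self.scoring_sex not in ("woman", "man"):
            raise ValidationError(
                f"participant {self.participant_id!r}: scoring_sex must be "
                f"'woman' or 'man'"
            )
        if not (0 < self.age_years < 120):
            raise ValidationError(
                f"participant {self.participant_id!r}: age_years out of range"
            )
        if not (20 < self.weight_kg < 400):
            raise ValidationError(
                f"participant {self.participant_id!r}: weight_kg out of range"
            )


@dataclass(frozen=True)
class PlausibilityResult:
    """Screen outcome for one participant."""

    participant_id: str
    bmr_mj_per_day: float
    ei_bmr_ratio: float
    excluded: bool
    reason: str  # "none" | "low_tail" | "high_tail"


def _age_band(age_years: float) -> str:
    # edge 30 -> 30-60 band; edge 60 -> 30-60 band (<=60 inclusive)
    if age_years < 30:
        return "18-30"
    if age_years <= 60:
        return "30-60"
    return "60+"


def schofield_bmr(sex: str, age_years: float, weight_kg: float) -> float:
    """Basal metabolic rate (MJ/day) from the weight-only Schofield equations.

    The study population is adults (18-65), so ages below 18 are rejected
    rather than silently mapped to the adolescent coefficient set.
    """
    if sex not in SCHOFIELD_COEFFICIENTS:
        raise ValidationError(f"sex must be 'woman' or 'man', got {sex!r}")
    if not math.isfinite(weight_kg) or weight_kg <= 0:
        raise ValidationError("weight_kg must be finite and > 0")
    if not math.isfinite(age_years) or age_years < 18:
        raise ValidationError("schofield_bmr covers adults only (age >= 18)")
    slope, intercept = SCHOFIELD_COEFFICIENTS[sex][_age_band(age_years)]
    return slope * weight_kg + intercept


def ei_bmr_ratio(mean_energy_kj_per_day: float, bmr_mj_per_day: float) -> float:
    """Dimensionless ratio of reported energy intake (kJ/day) to BMR (MJ/day)."""
    if not math.isfinite(bmr_mj_per_day) or bmr_mj_per_day <= 0:
        raise ValidationError("bmr_mj_per_day must be finite and > 0")
    if not math.isfinite(mean_energy_kj_per_day) or mean_energy_kj_per_day < 0:
        raise ValidationError("mean_energy_kj_per_day must be finite and >= 0")
    return (mean_energy_kj_per_day / 1000.0) / bmr_mj_per_day


def tail_exclusion(
    ratios: Sequence[tuple[str, float]],
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
    bmr_by_participant: Optional[Mapping[str, float]] = None,
) -> list[PlausibilityResult]:
    """Exclude the ``floor(tail_fraction * N)`` smallest and largest EI:BMR ratios.

    Ties are broken by participant id (lexicographic) so the excluded set is
    deterministic and invariant to input order. Results are returned sorted
    by participant id.
    """
    if not ratios:
        raise ValidationError("tail_exclusion requires at least one participant")
    if not (0 <= tail_fraction < 0.5):
        raise ValidationError("tail_fraction must be in [0, 0.5)")
    for pid, r in ratios:
        if not math.isfinite(r):
            raise ValidationError(f"participant {pid!r}: non-finite EI:BMR ratio")

    n = len(ratios)
    k = math.floor(tail_fraction * n)
    order = sorted(ratios, key=lambda t: (t[1], t[0]))
    low = {pid for pid, _ in order[:k]}
    high = {pid for pid, _ in order[n - k:]} if k else set()

    bmrs = bmr_by_participant or {}
    results = []
    for pid, r in sorted(ratios, key=lambda t: t[0]):
        if pid in low:
            reason = "low_tail"
        elif pid in high:
            reason = "high_tail"
        else:
            reason = "none"
        results.append(
            PlausibilityResult(
                participant_id=pid,
                bmr_mj_per_day=float(bmrs.get(pid, math.nan)),
                ei_bmr_ratio=r,
                excluded=reason != "none",
                reason=reason,
            )
        )
    return results


def screen_cohort(
    energy_by_participant: Mapping[str, float],
    profiles: Iterable[ParticipantProfile],
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
) -> list[PlausibilityResult]:
    """Full screen: Schofield BMR, EI:BMR ratio, then the 2.5% tail trim.

    ``energy_by_participant`` maps participant id to mean daily energy
    intake (kJ/day); only participants present in both inputs are screened
    (the day-count filter upstream defines the denominator).
    """
    profs = {p.participant_id: p for p in profiles}
    ratios = []
    bmrs = {}
    for pid in sorted(energy_by_participant):
        if pid not in profs:
            raise ValidationError(f"no profile for participant {pid!r}")
        p = profs[pid]
        bmr = schofield_bmr(p.scoring_sex, p.age_years, p.weight_kg)
        bmrs[pid] = bmr
        ratios.append((pid, ei_bmr_ratio(energy_by_participant[pid], bmr)))
    return tail_exclusion(ratios, tail_fraction, bmr_by_participant=bmrs)


def results_to_frame(results: Sequence[PlausibilityResult]) -> pd.DataFrame:
    """CSV layout: participant_id, bmr_mj_per_day, ei_bmr_ratio, excluded, reason."""
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "bmr_mj_per_day": r.bmr_mj_per_day,
                "ei_bmr_ratio": r.ei_bmr_ratio,
                "excluded": r.excluded,
                "reason": r.reason,
            }
            for r in results
        ]
    )


def load_profiles(path: str) -> list[ParticipantProfile]:
    """Read a participant CSV; extra covariate columns are ignored here
    (construct_validity consumes them from the same file)."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = ["participant_id", "scoring_sex", "age_years", "weight_kg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        from .errors import SchemaError

        raise SchemaError(f"participant table missing required column(s): {missing}")
    return [
        ParticipantProfile(
            participant_id=str(r.participant_id),
            scoring_sex=str(r.scoring_sex),
            age_years=float(r.age_years),
            weight_kg=float(r.weight_kg),
        )
        for r in df.itertuples(index=False)
    ]
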