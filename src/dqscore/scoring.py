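"""The 11-component Diet Quality Score (DQS) band scorer.

The DQS measures alignment of mean daily intake with the Australian Dietary
Guidelines-2013. Eleven components are scored and summed to a 0-100 total:

===================  ==========  ======  =====================================
component            framework    max    unit scored
===================  ==========  ======  =====================================
fruit                adequacy      10    serves/day
vegetable            adequacy      10    serves/day
fruit_variety        adequacy       5    unique types/day
vegetable_variety    adequacy       5    unique types/day
milk_alt             adequacy      10    serves/day
water                adequacy      10    cups/day (gendered bands)
meat_alt             optimal       10    serves/day (gendered bands)
grain                optimal       10    serves/day
discretionary_food   moderation    10    serves/day (600 kJ = 1 serve)
ssb                  moderation    10    serves/day (600 kJ = 1 serve)
alcohol              moderation    10    serves/day (600 kJ = 1 serve)
===================  ==========  ======  =====================================

Adequacy components increase with intake up to a recommended amount;
optimal-range components (grain, meat and alternatives) are maximal only at
the recommended upper serve value and drop to zero beyond it; moderation
components decrease with intake, with zero consumption scoring maximum.

Scoring is banded: each component's published score table is transcribed as
an ordered list of intervals. The transcription convention is left-closed /
right-open ("``>=a`` to ``<b``"); the optimal-range peaks (grain 6.0 serves,
meat 2.5 serves for women / 3.0 for men) and moderation zeros are singleton
bands matched within an absolute tolerance of 1e-9. A continuous
piecewise-linear ``proportional`` mode is available for sensitivity analysis
but the banded tables are the published framework and the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError
from .intake import DailyIntakeSummary

INF = math.inf

#: Absolute tolerance for singleton-band membership.
SINGLETON_TOL = 1e-9

COMPONENTS = (
    "fruit",
    "vegetable",
    "fruit_variety",
    "vegetable_variety",
    "milk_alt",
    "water",
    "meat_alt",
    "grain",
    "discretionary_food",
    "ssb",
    "alcohol",
)

FRAMEWORKS = ("adequacy", "optimal_range", "moderation")

SEXES = ("woman", "man")


@dataclass(frozen=True)
class ScoreBand:
    """One interval of a component's score table."""

    lower: float
    upper: float
    lower_closed: bool
    upper_closed: bool
    points: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ConfigurationError("band lower bound exceeds upper bound")
        if self.points < 0:
            raise ConfigurationError("band points must be >= 0")

    @property
    def is_singleton(self) -> bool:
        return self.lower == self.upper

    def contains(self, value: float, tol: float = SINGLETON_TOL) -> bool:
        if self.is_singleton:
            return abs(value - self.lower) <= tol
        lo_ok = value >= self.lower if self.lower_closed else value > self.lower
        hi_ok = value <= self.upper if self.upper_closed else value < self.upper
        return lo_ok and hi_ok


@dataclass(frozen=True)
class ComponentRule:
    """A component's full scoring rule: framework, bands (per sex if gendered)."""

    component: str
    framework: str
    max_points: float
    gendered: bool = False
    bands: tuple[ScoreBand, ...] = ()
    bands_by_sex: Mapping[str, tuple[ScoreBand, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.framework not in FRAMEWORKS:
            raise ConfigurationError(f"unknown framework {self.framework!r}")
        for bands in self._all_band_sets():
            peak = max(b.points for b in bands)
            if not math.isclose(peak, self.max_points):
                raise ConfigurationError(
                    f"{self.component}: max band points {peak} != max_points "
                    f"{self.max_points}"
                )

    def _all_band_sets(self) -> list[tuple[ScoreBand, ...]]:
        if self.gendered:
            return [tuple(v) for v in self.bands_by_sex.values()]
        return [self.bands]

    def bands_for(self, sex: Optional[str] = None) -> tuple[ScoreBand, ...]:
        if self.gendered:
            if sex is None:
                raise ConfigurationError(
                    f"component {self.component!r} is gendered; scoring_sex required"
                )
            if sex not in self.bands_by_sex:
                raise ConfigurationError(
                    f"component {self.component!r}: no bands for sex {sex!r}"
                )
            return tuple(self.bands_by_sex[sex])
        return self.bands


@dataclass(frozen=True)
class DQSResult:
    """Eleven component scores and their 0-100 total for one participant."""

    participant_id: str
    component_points: Mapping[str, float]
    total: float

    def as_dict(self) -> dict[str, float]:
        d: dict[str, object] = {"participant_id": self.participant_id}
        d.update({c: self.component_points[c] for c in COMPONENTS})
        d["total"] = self.total
        return d


def _bands(spec: Sequence[tuple[float, float, bool, bool, float]]) -> tuple[ScoreBand, ...]:
    return tuple(ScoreBand(*row) for row in spec)


def _steps(edges: Sequence[float], points: Sequence[float]) -> tuple[ScoreBand, ...]:
    """[e0,e1)->p0, [e1,e2)->p1, ..., [e_last, inf)->p_last."""
    bands = []
    for i, p in enumerate(points):
        hi = edges[i + 1] if i + 1 < len(edges) else INF
        bands.append(ScoreBand(edges[i], hi, True, False, p))
    return tuple(bands)


def _optimal(
    edges: Sequence[float], points: Sequence[float], peak: float
) -> tuple[ScoreBand, ...]:
    """Rising step bands, a singleton 10-point peak, then zero above it."""
    bands = list(_steps(edges, points[:-1]))
    # replace the open tail of the last composite band so it stops at the peak
    last = bands[-1]
    bands[-1] = replace(last, upper=peak, upper_closed=False)
    bands.append(ScoreBand(peak, peak, True, True, points[-1]))
    bands.append(ScoreBand(peak, INF, False, False, 0.0))
    return tuple(bands)


def _moderation(edges: Sequence[float], points: Sequence[float]) -> tuple[ScoreBand, ...]:
    """Singleton zero at max points, then decreasing bands: (0,e1)->p1, [e1,e2)->p2, ..."""
    bands = [ScoreBand(0.0, 0.0, True, True, points[0])]
    lo, lo_closed = 0.0, False
    for i, p in enumerate(points[1:]):
        hi = edges[i + 1] if i + 1 < len(edges) else INF
        bands.append(ScoreBand(lo, hi, lo_closed, False, p))
        lo, lo_closed = hi, True
    return tuple(bands)


def canonical_rules(widen_optimal_peak: bool = False) -> dict[str, ComponentRule]:
    """The published DQS band tables, transcribed exactly.

    With ``widen_optimal_peak`` the optimal-range singleton peaks (grain 6.0;
    meat 2.5 women / 3.0 men) are widened so the whole final composite band
    up to and including the peak earns maximum points; off by default, which
    reproduces the tables as printed.
    """
    rules: dict[str, ComponentRule] = {}

    rules["fruit"] = ComponentRule(
        "fruit", "adequacy", 10,
        bands=_steps([0, 0.5, 1, 1.5, 2], [0, 2.5, 5, 7.5, 10]),
    )
    rules["vegetable"] = ComponentRule(
        "vegetable", "adequacy", 10,
        bands=_steps([0, 1, 2, 3, 4, 5], [0, 2, 4, 6, 8, 10]),
    )
    for comp in ("fruit_variety", "vegetable_variety"):
        rules[comp] = ComponentRule(
            comp, "adequacy", 5,
            bands=_steps([0, 1, 2, 3, 4, 5], [0, 1, 2, 3, 4, 5]),
        )
    rules["milk_alt"] = ComponentRule(
        "milk_alt", "adequacy", 10,
        bands=_steps([0, 0.5, 1, 1.5, 2, 2.5], [0, 2, 4, 6, 8, 10]),
    )
    rules["water"] = ComponentRule(
        "water", "adequacy", 10, gendered=True,
        bands_by_sex={
            "woman": _steps([0, 1, 3, 5, 8], [0, 2, 6, 8, 10]),
            "man": _steps([0, 1, 3, 5, 10], [0, 2, 6, 8, 10]),
        },
    )
    rules["meat_alt"] = ComponentRule(
        "meat_alt", "optimal_range", 10, gendered=True,
        bands_by_sex={
            "woman": _optimal([0, 0.5, 1, 1.5, 2], [0, 2, 4, 6, 8, 10], peak=2.5),
            "man": _optimal([0, 1, 1.5, 2, 2.5], [0, 2, 4, 6, 8, 10], peak=3.0),
        },
    )
    rules["grain"] = ComponentRule(
        "grain", "optimal_range", 10,
        bands=_optimal([0, 1, 2, 3, 4, 5], [0, 1, 2, 5, 6, 8, 10], peak=6.0),
    )
    rules["discretionary_food"] = ComponentRule(
        "discretionary_food", "moderation", 10,
        bands=_moderation([0, 0.75, 1.75, 2.75], [10, 8, 4, 2, 0]),
    )
    for comp in ("ssb", "alcohol"):
        rules[comp] = ComponentRule(
            comp, "moderation", 10,
            bands=_moderation([0, 0.5, 1.25, 2], [10, 8, 4, 2, 0]),
        )

    if widen_optimal_peak:
        rules["grain"] = _widen_peak(rules["grain"])
        rules["meat_alt"] = _widen_peak(rules["meat_alt"])
    return rules


def _widen_peak(rule: ComponentRule) -> ComponentRule:
    def widen(bands: tuple[ScoreBand, ...]) -> tuple[ScoreBand, ...]:
        peak = next(b for b in bands if b.is_singleton)
        out = []
        for b in bands:
            if b.is_singleton:
                continue
            if b.upper == peak.lower and not b.upper_closed:
                out.append(replace(b, upper_closed=True, points=peak.points))
            else:
                out.append(b)
        return tuple(out)

    if rule.gendered:
        return replace(
            rule, bands_by_sex={s: widen(b) for s, b in rule.bands_by_sex.items()}
        )
    return replace(rule, bands=widen(rule.bands))


def score_component(
    rule: ComponentRule,
    value: float,
    sex: Optional[str] = None,
    proportional: bool = False,
) -> float:
    """Points for one component at the given mean daily intake.

    Singleton bands (the optimal-range peaks and the moderation zeros) win
    within their 1e-9 tolerance before ordinary interval membership is
    consulted, so 6.0 +/- 1e-12 grain serves still earns the peak.
    """
    if not math.isfinite(value) or value < 0:
        raise ValidationError(
            f"component {rule.component!r}: intake value must be finite and >= 0"
        )
    bands = rule.bands_for(sex)
    if proportional:
        return _score_proportional(rule, bands, value)
    for band in bands:
        if band.is_singleton and band.contains(value):
            return band.points
    for band in bands:
        if not band.is_singleton and band.contains(value):
            return band.points
    raise ConfigurationError(
        f"component {rule.component!r}: no band covers value {value!r}"
    )


def _score_proportional(
    rule: ComponentRule, bands: tuple[ScoreBand, ...], value: float
) -> float:
    """Continuous sensitivity-analysis mode: linear interpolation between
    band lower edges, clipped at the extreme bands' points; optimal-range
    intakes above the peak still score 0 (the published cliff is kept)."""
    best: dict[float, float] = {}
    for b in bands:
        if math.isfinite(b.lower):
            best[b.lower] = max(best.get(b.lower, 0.0), b.points)
    nodes = sorted(best.items())
    if rule.framework == "optimal_range":
        peak = next(b for b in bands if b.is_singleton or b.points == rule.max_points)
        if value > peak.lower + SINGLETON_TOL:
            return 0.0
    xs = [n[0] for n in nodes]
    ps = [n[1] for n in nodes]
    if value <= xs[0]:
        return ps[0]
    if value >= xs[-1]:
        return ps[-1]
    for i in range(len(xs) - 1):
        if xs[i] <= value <= xs[i + 1]:
            w = (value - xs[i]) / (xs[i + 1] - xs[i])
            return ps[i] + w * (ps[i + 1] - ps[i])
    return ps[-1]


#: Which DailyIntakeSummary field feeds each component.
_SUMMARY_FIELD = {
    "fruit": lambda s: s.serves["fruit"],
    "vegetable": lambda s: s.serves["vegetable"],
    "fruit_variety": lambda s: s.fruit_variety_per_day,
    "vegetable_variety": lambda s: s.vegetable_variety_per_day,
    "milk_alt": lambda s: s.serves["milk_alt"],
    "water": lambda s: s.water_cups_per_day,
    "meat_alt": lambda s: s.serves["meat_alt"],
    "grain": lambda s: s.serves["grain"],
    "discretionary_food": lambda s: s.serves["discretionary_food"],
    "ssb": lambda s: s.serves["ssb"],
    "alcohol": lambda s: s.serves["alcohol"],
}


def score_participant(
    summary: DailyIntakeSummary,
    sex: str,
    rules: Optional[Mapping[str, ComponentRule]] = None,
    proportional: bool = False,
) -> DQSResult:
    """Apply all 11 component rules to a participant's mean daily intakes."""
    if rules is None:
        rules = canonical_rules()
    points: dict[str, float] = {}
    for comp in COMPONENTS:
        if comp not in rules:
            raise ConfigurationError(f"missing rule for component {comp!r}")
        try:
            value = _SUMMARY_FIELD[comp](summary)
        except KeyError as exc:
            raise ValidationError(
                f"summary for {summary.participant_id!r} lacks the "
                f"{comp!r} dimension"
            ) from exc
        points[comp] = score_component(rules[comp], value, sex=sex, proportional=proportional)
    return DQSResult(
        participant_id=summary.participant_id,
        component_points=points,
        total=sum(points.values()),
    )


def score_cohort(
    summaries: Sequence[DailyIntakeSummary],
    sex_by_participant: Mapping[str, str],
    rules: Optional[Mapping[str, ComponentRule]] = None,
    proportional: bool = False,
) -> list[DQSResult]:
    results = []
    for s in summaries:
        if s.participant_id not in sex_by_participant:
            raise ConfigurationError(
                f"no scoring_sex recorded for participant {s.participant_id!r}"
            )
        results.append(
            score_participant(s, sex_by_participant[s.participant_id], rules, proportional)
        )
    return results


def results_to_frame(results: Sequence[DQSResult]) -> pd.DataFrame:
    """One CSV row per participant: id, 11 component columns, total."""
    return pd.DataFrame([r.as_dict() for r in results])


# -- rule (de)serialisation ---------------------------------------------------

def _band_to_list(b: ScoreBand) -> list:
    lo = "-inf" if b.lower == -INF else b.lower
    hi = "inf" if b.upper == INF else b.upper
    return [lo, hi, b.lower_closed, b.upper_closed, b.points]


def _band_from_list(row: Sequence) -> ScoreBand:
    lo, hi, lc, uc, pts = row
    lo = -INF if lo in ("-inf", "-Infinity") else float(lo)
    hi = INF if hi in ("inf", "Infinity") else float(hi)
    return ScoreBand(lo, hi, bool(lc), bool(uc), float(pts))


def rules_to_yaml(rules: Mapping[str, ComponentRule], path: str | Path) -> None:
    """Write a band-table config (YAML) that :func:`rules_from_yaml` reads back."""
    doc = []
    for comp in COMPONENTS:
        r = rules[comp]
        entry: dict[str, object] = {
            "component": r.component,
            "framework": r.framework,
            "max_points": r.max_points,
            "gendered": r.gendered,
        }
        if r.gendered:
            entry["bands_by_sex"] = {
                s: [_band_to_list(b) for b in bs] for s, bs in r.bands_by_sex.items()
            }
        else:
            entry["bands"] = [_band_to_list(b) for b in r.bands]
        doc.append(entry)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def rules_from_yaml(path: str | Path) -> dict[str, ComponentRule]:
    doc = yaml.safe_load(Path(path).read_text())
    rules: dict[str, ComponentRule] = {}
    for entry in doc:
        comp = entry["component"]
        if entry.get("gendered"):
            rules[comp] = ComponentRule(
                comp,
                entry["framework"],
                float(entry["max_points"]),
                gendered=True,
                bands_by_sex={
                    s: tuple(_band_from_list(b) for b in bs)
                    for s, bs in entry["bands_by_sex"].items()
                },
            )
        else:
            rules[comp] = ComponentRule(
                comp,
                entry["framework"],
                float(entry["max_points"]),
                bands=tuple(_band_from_list(b) for b in entry["bands"]),
            )
    missing = [c for c in COMPONENTS if c not in rules]
    if missing:
        raise ConfigurationError(f"rule config missing component(s): {missing}")
    return rules
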