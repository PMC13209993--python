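"""End-to-end pipeline: load -> day filter -> aggregate -> screen -> score -> validate.

Exclusions are applied in a fixed order matching the study's participant
flow: first participants with fewer than the minimum number of recorded
days are removed, then the EI:BMR tail screen runs on the remaining sample
(so the screen's percentile denominator is the post-day-filter count), and
only the surviving participants are scored and analysed.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import intake, plausibility, scoring, validity
from .composition import load_composition_table
from .errors import DQSError
from .validity import PredictorSpec

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    composition_path: str
    intake_path: str
    participants_path: str
    out_dir: str
    min_days: int = 2
    tail_fraction: float = plausibility.DEFAULT_TAIL_FRACTION
    rules_path: Optional[str] = None  # band-table YAML override
    proportional: bool = False
    comparator_column: Optional[str] = None  # external comparator score in participants CSV
    predictors: Sequence[PredictorSpec] = field(default_factory=tuple)
    collinearity_threshold: float = 0.8
    seed: int = 0


@dataclass
class FlowReport:
    """Participant counts at each exclusion stage."""

    initial: int
    after_day_filter: int
    after_screen: int

    def as_dict(self) -> dict[str, int]:
        return {
            "initial": self.initial,
            "after_day_filter": self.after_day_filter,
            "after_screen": self.after_screen,
        }


def run_pipeline(config: RunConfig) -> FlowReport:
    """Execute the full flow, writing all artifacts under ``config.out_dir``.

    Outputs: summaries.csv, plausibility.csv, scores.csv, tertiles.csv,
    associations.csv, model.csv (when predictors are declared), flow.json.
    Any stage error removes partial outputs and re-raises.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out, written)
    except DQSError:
        for p in written:
            if p.exists():
                p.unlink()
        raise


def _write(df: pd.DataFrame, path: Path, written: list[Path]) -> None:
    df.to_csv(path, index=False)
    written.append(path)


def _run(config: RunConfig, out: Path, written: list[Path]) -> FlowReport:
    composition = load_composition_table(config.composition_path)
    events = intake.load_intake_events(config.intake_path)
    profiles = plausibility.load_profiles(config.participants_path)
    profile_df = pd.read_csv(config.participants_path, dtype={"participant_id": str})
    logger.info("loaded %d composition items, %d events, %d profiles",
                len(composition), len(events), len(profiles))

    initial = len({e.participant_id for e in events})
    summaries, excluded_days = intake.summarise_cohort(events, composition, config.min_days)
    logger.info("day filter: %d -> %d (removed %d with <%d recorded days)",
                initial, len(summaries), len(excluded_days), config.min_days)
    _write(intake.summaries_to_frame(summaries), out / "summaries.csv", written)

    energy = {s.participant_id: s.mean_energy_kj_per_day for s in summaries}
    screen = plausibility.screen_cohort(energy, profiles, config.tail_fraction)
    _write(plausibility.results_to_frame(screen), out / "plausibility.csv", written)
    kept = {r.participant_id for r in screen if not r.excluded}
    logger.info("EI:BMR screen: %d -> %d", len(summaries), len(kept))

    rules = (scoring.rules_from_yaml(config.rules_path)
             if config.rules_path else scoring.canonical_rules())
    sex_by_pid = {p.participant_id: p.scoring_sex for p in profiles}
    scored_summaries = [s for s in summaries if s.participant_id in kept]
    results = scoring.score_cohort(scored_summaries, sex_by_pid, rules,
                                   proportional=config.proportional)
    scores_df = scoring.results_to_frame(results)
    _write(scores_df, out / "scores.csv", written)

    dqs = pd.Series(scores_df["total"].to_numpy(), index=scores_df["participant_id"])
    tert_dqs = validity.assign_tertiles(dqs)
    tert_frame = pd.DataFrame(
        [{"participant_id": t.participant_id, "tertile_dqs": t.tertile} for t in tert_dqs]
    )

    prof_indexed = profile_df.set_index("participant_id").loc[list(dqs.index)]
    comparator = None
    if config.comparator_column and config.comparator_column in prof_indexed.columns:
        comparator = prof_indexed[config.comparator_column].astype(float)

    if comparator is not None:
        tert_comp = validity.assign_tertiles(comparator)
        tert_frame["tertile_comparator"] = [t.tertile for t in tert_comp]
        outcome = validity.lowest_in_both(tert_dqs, tert_comp)
    else:
        outcome = pd.Series(
            {t.participant_id: int(t.tertile == 1) for t in tert_dqs}, dtype=int
        )
    tert_frame["lowest_tertile_outcome"] = outcome.reindex(
        tert_frame["participant_id"]).to_numpy()
    _write(tert_frame, out / "tertiles.csv", written)

    assoc_rows = []
    if comparator is not None:
        cmp_result = validity.compare_indices(dqs.to_numpy(), comparator.to_numpy())
        assoc_rows.append({
            "analysis": "index_comparison", "covariate": config.comparator_column,
            "statistic": cmp_result.mean_difference, "p": cmp_result.p_value,
            "extra": f"rho={cmp_result.spearman_rho:.3f}",
        })
    for col, kind in (("age_years", "continuous"), ("bmi", "continuous"),
                      ("total_cholesterol", "continuous"),
                      ("scoring_sex", "binary"),
                      ("ipaq_category", "multi"), ("attention_to_diet", "multi")):
        if col not in prof_indexed.columns:
            continue
        try:
            a = validity.bivariate_association(dqs.to_numpy(), prof_indexed[col], kind)
        except DQSError as exc:
            logger.warning("skipping association with %s: %s", col, exc)
            continue
        assoc_rows.append({"analysis": f"dqs_vs_{kind}", "covariate": col,
                           "statistic": a.statistic, "p": a.p_value, "extra": f"n={a.n}"})
    _write(
        pd.DataFrame(assoc_rows, columns=["analysis", "covariate", "statistic", "p", "extra"]),
        out / "associations.csv", written)

    if config.predictors:
        numeric = [p.name for p in config.predictors if p.kind == "continuous"]
        keep_predictors = list(config.predictors)
        if len(numeric) >= 2:
            report = validity.collinearity_screen(
                prof_indexed, numeric, threshold=config.collinearity_threshold,
                priority=numeric)
            dropped = {d for d, _, _ in report.dropped}
            if dropped:
                logger.info("collinearity screen dropped %s", sorted(dropped))
            keep_predictors = [p for p in config.predictors if p.name not in dropped]
        model = validity.fit_lowest_tertile_model(outcome, prof_indexed.reset_index(),
                                                  keep_predictors)
        mdf = validity.model_result_to_frame(model)
        _write(mdf, out / "model.csv", written)
        (out / "model_summary.json").write_text(json.dumps({
            "nagelkerke_r2": model.nagelkerke_r2,
            "classification_rate": model.classification_rate,
            "n": model.n,
            "reference_levels": dict(model.reference_levels),
        }, indent=2))
        written.append(out / "model_summary.json")

    flow = FlowReport(initial=initial, after_day_filter=len(summaries),
                      after_screen=len(kept))
    (out / "flow.json").write_text(json.dumps(flow.as_dict(), indent=2))
    written.append(out / "flow.json")
    logger.info("flow: %d -> %d -> %d", flow.initial, flow.after_day_filter,
                flow.after_screen)
    return flow
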