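"""Construct-validity statistics for diet quality scores.

A new diet quality index is validated by showing it behaves the way diet
quality is known to behave: agreement with an established comparator index,
expected bivariate associations with sociodemographic and clinical
covariates, and a multivariable model of membership in the lowest diet
quality tertile. This module implements that battery:

* paired comparison of two indices (paired t mean difference + Spearman);
* bivariate associations (Spearman for continuous covariates, two-sample t
  for binary ones, one-way ANOVA for multi-level ones);
* tertile assignment by average rank (lowest / middle / highest score);
* a binary "lowest tertile under both indices" outcome;
* multivariable binary logistic regression with Wald odds-ratio CIs,
  Nagelkerke pseudo-R^2 and a 0.5-threshold classification rate;
* a pairwise-correlation multicollinearity screen.

Missing values are never imputed: each analysis uses complete cases only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    ConfigurationError,
    ConvergenceError,
    InsufficientDataError,
    ValidationError,
)


@dataclass(frozen=True)
class IndexComparison:
    """Agreement between two paired diet quality indices."""

    n: int
    mean_difference: float  # mean(index_a - index_b)
    ci_low: float
    ci_high: float
    t_statistic: float
    p_value: float
    spearman_rho: float
    spearman_p: float


def compare_indices(
    index_a: Sequence[float], index_b: Sequence[float], ci_level: float = 0.95
) -> IndexComparison:
    """Paired t-test on the mean difference (a - b) plus Spearman correlation."""
    a = np.asarray(index_a, dtype=float)
    b = np.asarray(index_b, dtype=float)
    if a.shape != b.shape:
        raise AlignmentError("index vectors must be paired (same length)")
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    n = a.size
    if n < 3:
        raise InsufficientDataError("need at least 3 complete pairs")
    d = a - b
    mean_d = float(d.mean())
    se = float(d.std(ddof=1) / math.sqrt(n))
    if se == 0.0:
        t_stat, p = 0.0, 1.0
        ci_low = ci_high = mean_d
    else:
        t_stat = mean_d / se
        p = float(2 * stats.t.sf(abs(t_stat), df=n - 1))
        tcrit = float(stats.t.ppf(0.5 + ci_level / 2, df=n - 1))
        ci_low, ci_high = mean_d - tcrit * se, mean_d + tcrit * se
    rho, rho_p = stats.spearmanr(a, b)
    return IndexComparison(
        n=n,
        mean_difference=mean_d,
        ci_low=ci_low,
        ci_high=ci_high,
        t_statistic=float(t_stat),
        p_value=p,
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
    )


@dataclass(frozen=True)
class Association:
    """One bivariate score-covariate association."""

    kind: str  # "continuous" | "binary" | "multi"
    statistic: float  # rho, t or F
    p_value: float
    n: int


def bivariate_association(
    scores: Sequence[float],
    covariate: Sequence,
    kind: str,
    equal_var: bool = True,
) -> Association:
    """Score vs covariate: Spearman (continuous), t-test (binary) or ANOVA (multi).

    ``equal_var=False`` switches the two-group comparison to Welch's t.
    Complete cases only; a group with fewer than 2 members raises.
    """
    # positional pairing: strip any incoming pandas indexes
    s = pd.Series(np.asarray(scores, dtype=float))
    c = pd.Series(list(covariate))
    if len(s) != len(c):
        raise AlignmentError("scores and covariate must have equal length")
    mask = s.notna() & c.notna()
    s, c = s[mask], c[mask]
    if len(s) < 3:
        raise InsufficientDataError("need at least 3 complete cases")

    if kind == "continuous":
        rho, p = stats.spearmanr(s, c.astype(float))
        return Association("continuous", float(rho), float(p), len(s))

    groups = [s[c == level].to_numpy() for level in pd.unique(c)]
    if any(len(g) < 2 for g in groups):
        raise InsufficientDataError("every group needs at least 2 observations")
    if kind == "binary":
        if len(groups) != 2:
            raise ValidationError(f"binary covariate has {len(groups)} levels")
        t, p = stats.ttest_ind(groups[0], groups[1], equal_var=equal_var)
        return Association("binary", float(t), float(p), len(s))
    if kind == "multi":
        if len(groups) < 3:
            raise ValidationError("multi-level covariate needs >= 3 levels")
        f, p = stats.f_oneway(*groups)
        return Association("multi", float(f), float(p), len(s))
    raise ValidationError(f"unknown association kind {kind!r}")


@dataclass(frozen=True)
class TertileAssignment:
    participant_id: str
    tertile: int  # 1 = lowest score


def assign_tertiles(
    scores: Mapping[str, float] | pd.Series,
) -> list[TertileAssignment]:
    """Rank-based tertiles: average ranks, cut at n/3 and 2n/3.

    All members of a tie group share an average rank and therefore a
    tertile, so boundary ties never straddle a cut. A fully degenerate
    (all-equal) distribution is assigned tertile 1 with a warning.
    """
    s = pd.Series(scores, dtype=float)
    n = len(s)
    if n < 3:
        raise InsufficientDataError("need at least 3 scores for tertiles")
    if s.isna().any():
        raise ValidationError("scores must be complete for tertile assignment")
    if s.nunique() == 1:
        warnings.warn(
            "degenerate score distribution: all scores equal; assigning tertile 1",
            stacklevel=2,
        )
        return [TertileAssignment(str(pid), 1) for pid in s.index]
    ranks = stats.rankdata(s.to_numpy(), method="average")
    out = []
    for pid, rank in zip(s.index, ranks):
        if rank <= n / 3:
            t = 1
        elif rank <= 2 * n / 3:
            t = 2
        else:
            t = 3
        out.append(TertileAssignment(str(pid), t))
    return out


def lowest_in_both(
    tertiles_a: Sequence[TertileAssignment],
    tertiles_b: Sequence[TertileAssignment],
) -> pd.Series:
    """Binary outcome: 1 iff the participant is in tertile 1 under both indices."""
    a = {t.participant_id: t.tertile for t in tertiles_a}
    b = {t.participant_id: t.tertile for t in tertiles_b}
    if set(a) != set(b):
        raise AlignmentError("tertile assignments cover different participants")
    return pd.Series(
        {pid: int(a[pid] == 1 and b[pid] == 1) for pid in sorted(a)}, dtype=int
    )


@dataclass(frozen=True)
class PredictorSpec:
    """Declaration of one model predictor.

    ``levels``/``reference`` apply to categoricals; ``priority`` (lower =
    keep first) resolves which of a collinear group is retained.
    """

    name: str
    kind: str  # "continuous" | "categorical"
    levels: tuple[str, ...] = ()
    reference: Optional[str] = None
    priority: int = 100


@dataclass(frozen=True)
class TermResult:
    term: str  # predictor name, or "name=level" for a dummy
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class LogisticModelResult:
    terms: tuple[TermResult, ...]
    nagelkerke_r2: float
    classification_rate: float
    n: int
    reference_levels: Mapping[str, str] = field(default_factory=dict)
    coefficients: Mapping[str, float] = field(default_factory=dict)


def _design_matrix(
    profile: pd.DataFrame, predictors: Sequence[PredictorSpec]
) -> tuple[pd.DataFrame, dict[str, str]]:
    cols = {}
    refs = {}
    for spec in predictors:
        if spec.name not in profile.columns:
            raise ConfigurationError(f"predictor {spec.name!r} not in profile table")
        col = profile[spec.name]
        if spec.kind == "continuous":
            cols[spec.name] = col.astype(float)
        elif spec.kind == "categorical":
            levels = list(spec.levels) or sorted(col.dropna().astype(str).unique())
            ref = spec.reference if spec.reference is not None else levels[0]
            if ref not in levels:
                raise ConfigurationError(
                    f"reference level {ref!r} not among levels of {spec.name!r}"
                )
            refs[spec.name] = ref
            observed = set(col.dropna().astype(str))
            unknown = observed - set(levels)
            if unknown:
                raise ValidationError(
                    f"predictor {spec.name!r}: undeclared level(s) {sorted(unknown)}"
                )
            for level in levels:
                if level == ref:
                    continue
                cols[f"{spec.name}={level}"] = (
                    col.astype(str).eq(level).astype(float).where(col.notna())
                )
        else:
            raise ConfigurationError(f"unknown predictor kind {spec.kind!r}")
    return pd.DataFrame(cols, index=profile.index), refs


def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Rescaled Cox-Snell pseudo-R^2, bounded in [0, 1]."""
    cs = 1.0 - math.exp((2.0 / n) * (ll_null - ll_model))
    max_cs = 1.0 - math.exp((2.0 / n) * ll_null)
    if max_cs <= 0:
        return 0.0
    return min(max(cs / max_cs, 0.0), 1.0)


def fit_lowest_tertile_model(
    outcome: pd.Series,
    profile: pd.DataFrame,
    predictors: Sequence[PredictorSpec],
    ci_level: float = 0.95,
) -> LogisticModelResult:
    """Maximum-likelihood binary logistic regression of the poor-diet outcome.

    Categorical predictors are dummy-coded against their declared reference
    levels; Wald confidence intervals are exponentiated to the odds-ratio
    scale. Complete cases only.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = pd.Series(outcome).astype(float)
    if profile.index.name == "participant_id" or "participant_id" in profile.columns:
        prof = profile.set_index("participant_id") if "participant_id" in profile.columns else profile
        prof.index = prof.index.astype(str)
        y.index = y.index.astype(str)
        prof = prof.loc[prof.index.intersection(y.index)]
    else:
        prof = profile
    X, refs = _design_matrix(prof, predictors)
    data = X.copy()
    data["__y"] = y.reindex(X.index) if not X.index.equals(y.index) else y
    data = data.dropna()
    if data.empty or data["__y"].nunique() < 2:
        raise ValidationError("outcome must contain both classes after complete-case filtering")
    yv = data.pop("__y").to_numpy()
    Xv = sm.add_constant(data, has_constant="add")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(yv, Xv).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        big = [c for c, v in fit.params.items() if c != "const" and abs(v) > 15]
        raise ConvergenceError(
            "logistic fit did not converge"
            + (f"; quasi-complete separation suspected in {big}" if big else "")
        )

    z = float(stats.norm.ppf(0.5 + ci_level / 2))
    terms = []
    for name in data.columns:
        beta = float(fit.params[name])
        se = float(fit.bse[name])
        terms.append(
            TermResult(
                term=name,
                odds_ratio=math.exp(beta),
                ci_low=math.exp(beta - z * se),
                ci_high=math.exp(beta + z * se),
                p_value=float(fit.pvalues[name]),
            )
        )
    n = len(yv)
    r2 = nagelkerke_r2(float(fit.llf), float(fit.llnull), n)
    predicted = (fit.predict(Xv) >= 0.5).astype(int)
    rate = float((predicted == yv).mean())
    return LogisticModelResult(
        terms=tuple(terms),
        nagelkerke_r2=r2,
        classification_rate=rate,
        n=n,
        reference_levels=refs,
        coefficients={c: float(v) for c, v in fit.params.items()},
    )


@dataclass(frozen=True)
class CollinearityReport:
    retained: tuple[str, ...]
    dropped: tuple[tuple[str, str, float], ...]  # (dropped, kept_representative, r)


def collinearity_screen(
    profile: pd.DataFrame,
    predictors: Sequence[str],
    threshold: float = 0.8,
    priority: Optional[Sequence[str]] = None,
) -> CollinearityReport:
    """Group numeric predictors whose pairwise |r| exceeds ``threshold``;
    retain one representative per group by priority order (default: the
    order the predictors were declared in)."""
    if len(predictors) < 2:
        raise ConfigurationError("collinearity screen needs >= 2 candidate predictors")
    missing = [p for p in predictors if p not in profile.columns]
    if missing:
        raise ConfigurationError(f"predictor(s) not in profile table: {missing}")
    order = list(priority) if priority is not None else list(predictors)
    rank = {name: order.index(name) if name in order else len(order) for name in predictors}

    corr = profile[list(predictors)].astype(float).corr(method="pearson").abs()
    # union-find over the high-correlation graph
    parent = {p: p for p in predictors}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs: dict[tuple[str, str], float] = {}
    for i, a in enumerate(predictors):
        for b in list(predictors)[i + 1:]:
            r = float(corr.loc[a, b])
            if not math.isnan(r) and r > threshold:
                pairs[(a, b)] = r
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    groups: dict[str, list[str]] = {}
    for p in predictors:
        groups.setdefault(find(p), []).append(p)

    retained, dropped = [], []
    for members in groups.values():
        keep = min(members, key=lambda m: (rank[m], m))
        retained.append(keep)
        for m in members:
            if m != keep:
                r = pairs.get((keep, m)) or pairs.get((m, keep)) or float(corr.loc[keep, m])
                dropped.append((m, keep, float(r)))
    retained.sort(key=lambda m: (rank[m], m))
    dropped.sort()
    return CollinearityReport(retained=tuple(retained), dropped=tuple(dropped))


def model_result_to_frame(result: LogisticModelResult) -> pd.DataFrame:
    """One row per term: term, OR, CI_low, CI_high, p."""
    return pd.DataFrame(
        [
            {
                "term": t.term,
                "OR": t.odds_ratio,
                "CI_low": t.ci_low,
                "CI_high": t.ci_high,
                "p": t.p_value,
            }
            for t in result.terms
        ]
    )
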