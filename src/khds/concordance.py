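"""Cohort summaries, discrimination tables, and score-vs-SATS concordance.

This is the pipeline stage that turns a scored cohort into the study's
report tables:

* a descriptive cohort summary (age, sex, admission and 24-h death rates);
* a discrimination table — per score variant, the c statistic for 24-h
  mortality and for hospital admission on that variant's complete-case
  subset, with the default score *recomputed on the same subset* as the
  reference (the full-cohort reference would not be comparable), plus the
  SATS urgency rank itself treated as a 4-level ordinal score;
* the score-points x SATS-urgency cross-tabulation and the acuity
  discordance derived from it: patients the score rates higher than their
  SATS ranking (high points but non-urgent presentation) and lower
  (urgent-or-above presentation but low points);
* outcome breakdowns by score level and within the higher-discordant group.

A published cross-tabulation of 7,500 ranked presentations ships as a
packaged fixture (:func:`reference_crosstab`) so the concordance arithmetic
can be exercised without any cohort data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    PatientRecord,
    ScoreVariant,
    analysis_set,
    compute_khds,
    has_sats_ranking,
    variant_complete,
)
from .reporting import percentage, round_half_up
from .sats import UrgencyLevel, rank_patient, urgency_from_token
from .stats import (
    DegenerateComparisonError,
    ROCResult,
    UndefinedDiscriminationError,
    c_statistic,
    compare_c_statistics,
)

N_POINTS = 4  # score levels 0..3
_LEVELS = list(UrgencyLevel)


@dataclass(frozen=True)
class CrossTab:
    """Score points (rows, 0-3) x SATS urgency (columns) patient counts."""

    counts: np.ndarray  # shape (4, 4), int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (N_POINTS, len(_LEVELS)):
            raise ValueError(f"counts must be 4x4, got {c.shape}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def score_totals(self) -> np.ndarray:
        """Marginal over urgency: patients per score level."""
        return self.counts.sum(axis=1)

    def urgency_totals(self) -> np.ndarray:
        """Marginal over score: patients per urgency level."""
        return self.counts.sum(axis=0)

    def urgency_total(self, level: UrgencyLevel) -> int:
        return int(self.counts[:, int(level)].sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts,
            index=pd.Index(range(N_POINTS), name="points"),
            columns=[str(u) for u in _LEVELS],
        )
        df["total"] = self.score_totals()
        df.loc["total"] = list(self.urgency_totals()) + [self.total]
        return df


@dataclass(frozen=True)
class DiscordanceConfig:
    """How score-vs-SATS discordance is counted.

    high_score_cut: minimum points treated as a high (urgent-grade) score.
    lower_levels: SATS levels forming the lower-discordance denominator;
    emergent may be added, which on the published table changes nothing
    since no emergent patient scored below the cut.
    """

    high_score_cut: int = 2
    lower_levels: tuple[UrgencyLevel, ...] = (
        UrgencyLevel.URGENT,
        UrgencyLevel.VERY_URGENT,
    )

    def __post_init__(self) -> None:
        if not (0 <= self.high_score_cut <= N_POINTS):
            raise ValueError("high_score_cut must be in 0..4")
        if UrgencyLevel.NON_URGENT in self.lower_levels:
            raise ValueError("lower_levels cannot include non_urgent")


@dataclass(frozen=True)
class DiscordanceSummary:
    """Acuity disagreement between the score and the SATS ranking.

    Percentages are rounded half-up to one decimal and always recompute
    from the stored counts.
    """

    n_higher: int
    non_urgent_total: int
    pct_higher: float
    n_lower: int
    lower_denominator: int
    pct_lower: float


@dataclass(frozen=True)
class CohortSummary:
    n: int
    mean_age: float
    sd_age: float
    median_age: float
    iqr_age: tuple[float, float]
    n_male: int
    pct_male: float
    n_admitted: int
    pct_admitted: float
    n_died_24h: int
    pct_died_24h: float


@dataclass(frozen=True)
class DiscordantOutcomes:
    """Outcomes within the higher-acuity discordant group (high score,
    non-urgent SATS ranking)."""

    n_group: int
    n_admitted: int
    pct_admitted: float | None
    n_died_24h: int
    n_died_later: int
    pct_died_of_admitted: float | None


def reference_crosstab() -> CrossTab:
    """The packaged published cross-tabulation of 7,500 ranked patients."""
    path = resources.files("khds.data").joinpath("table3_counts.csv")
    counts = np.zeros((N_POINTS, len(_LEVELS)), dtype=int)
    with path.open() as fh:
        for row in csv.DictReader(fh):
            counts[int(row["points"]), int(urgency_from_token(row["urgency"]))] = int(
                row["count"]
            )
    return CrossTab(counts=counts)


def crosstab_khds_sats(
    records: Sequence[PatientRecord],
    variant: ScoreVariant = ScoreVariant.KHDS_SAT,
) -> CrossTab:
    """Cross-tabulate score points against SATS urgency.

    Records missing a score component for the variant, or carrying no SATS
    presentation codes (never ranked), are excluded; the exclusion count is
    reported on the result.
    """
    counts = np.zeros((N_POINTS, len(_LEVELS)), dtype=int)
    excluded = 0
    for rec in records:
        if not variant_complete(rec, variant) or not has_sats_ranking(rec):
            excluded += 1
            continue
        s = compute_khds(rec, variant).points
        u = rank_patient(rec.presentations)
        counts[s, int(u)] += 1
    return CrossTab(counts=counts, n_excluded=excluded)


def acuity_discordance(
    crosstab: CrossTab, config: DiscordanceConfig | None = None
) -> DiscordanceSummary:
    """Count patients rated higher / lower by the score than by SATS.

    higher: points >= cut among non-urgent-ranked patients, as a share of
    the non-urgent total.  lower: points < cut among patients at the
    configured urgent-or-above levels, as a share of those levels' total.
    """
    cfg = config or DiscordanceConfig()
    cut = cfg.high_score_cut
    nu = int(UrgencyLevel.NON_URGENT)
    n_higher = int(crosstab.counts[cut:, nu].sum())
    non_urgent_total = crosstab.urgency_total(UrgencyLevel.NON_URGENT)
    lower_cols = [int(u) for u in cfg.lower_levels]
    n_lower = int(crosstab.counts[:cut, lower_cols].sum())
    lower_denom = int(crosstab.counts[:, lower_cols].sum())
    if non_urgent_total == 0 or lower_denom == 0:
        raise ValueError("empty denominator group: discordance percentage undefined")
    return DiscordanceSummary(
        n_higher=n_higher,
        non_urgent_total=non_urgent_total,
        pct_higher=percentage(n_higher, non_urgent_total),
        n_lower=n_lower,
        lower_denominator=lower_denom,
        pct_lower=percentage(n_lower, lower_denom),
    )


def discordant_outcomes(
    records: Sequence[PatientRecord],
    variant: ScoreVariant = ScoreVariant.KHDS_SAT,
    config: DiscordanceConfig | None = None,
) -> DiscordantOutcomes:
    """Outcomes of the higher-acuity discordant patients (points >= cut,
    SATS non-urgent): admissions, 24-h deaths, and later in-hospital deaths.

    pct_died_of_admitted pools deaths at any time in hospital over the
    admitted members of the group; it is None when nobody was admitted.
    """
    cfg = config or DiscordanceConfig()
    group = [
        r
        for r in records
        if variant_complete(r, variant)
        and has_sats_ranking(r)
        and rank_patient(r.presentations) is UrgencyLevel.NON_URGENT
        and compute_khds(r, variant).points >= cfg.high_score_cut
    ]
    n_group = len(group)
    n_admitted = sum(r.admitted for r in group)
    n_died_24h = sum(r.died_within_24h for r in group)
    n_died_later = sum(r.died_in_hospital and not r.died_within_24h for r in group)
    return DiscordantOutcomes(
        n_group=n_group,
        n_admitted=n_admitted,
        pct_admitted=percentage(n_admitted, n_group) if n_group else None,
        n_died_24h=n_died_24h,
        n_died_later=n_died_later,
        pct_died_of_admitted=(
            percentage(n_died_24h + n_died_later, n_admitted) if n_admitted else None
        ),
    )


def cohort_summary(records: Sequence[PatientRecord]) -> CohortSummary:
    """Descriptive summary: age (mean/SD, median, IQR), sex, admissions,
    24-h deaths.

    Quantiles use the q(n+1) plotting position (Excel's exclusive /
    type-6 convention): for three ages the IQR spans the smallest to the
    largest.  SD is the sample standard deviation (0 for a single record).
    """
    if not records:
        raise ValueError("empty cohort")
    ages = np.array([r.age for r in records], dtype=float)
    n = len(records)
    q25, q50, q75 = np.percentile(ages, [25, 50, 75], method="weibull")
    n_male = sum(r.sex.value == "male" for r in records)
    n_admitted = sum(r.admitted for r in records)
    n_died = sum(r.died_within_24h for r in records)
    return CohortSummary(
        n=n,
        mean_age=float(ages.mean()),
        sd_age=float(ages.std(ddof=1)) if n > 1 else 0.0,
        median_age=float(q50),
        iqr_age=(float(q25), float(q75)),
        n_male=n_male,
        pct_male=percentage(n_male, n),
        n_admitted=n_admitted,
        pct_admitted=percentage(n_admitted, n),
        n_died_24h=n_died,
        pct_died_24h=percentage(n_died, n),
    )


def analysis_sets_summary(
    records: Sequence[PatientRecord],
) -> dict[str, CohortSummary]:
    """Cohort summaries per analysis set: each variant's complete-case
    subset plus the SATS-ranked sub-cohort (sets shrink where a component
    was introduced later)."""
    sets: dict[str, list[PatientRecord]] = {
        ScoreVariant.KHDS_SAT.name: analysis_set(records, ScoreVariant.KHDS_SAT),
        ScoreVariant.KHDS_MONTHS.name: analysis_set(records, ScoreVariant.KHDS_MONTHS),
        SATS_ROW: [r for r in records if has_sats_ranking(r)],
        ScoreVariant.KHDS_RESP.name: analysis_set(records, ScoreVariant.KHDS_RESP),
    }
    return {name: cohort_summary(subset) for name, subset in sets.items() if subset}


def summary_frame(summaries: dict[str, CohortSummary]) -> pd.DataFrame:
    """Tabulate per-analysis-set summaries (columns = analysis sets)."""
    rows = {}
    for name, s in summaries.items():
        rows[name] = {
            "n": s.n,
            "mean_age": round_half_up(s.mean_age, 1),
            "sd_age": round_half_up(s.sd_age, 1),
            "median_age": round_half_up(s.median_age, 1),
            "iqr_age_low": round_half_up(s.iqr_age[0], 1),
            "iqr_age_high": round_half_up(s.iqr_age[1], 1),
            "n_male": s.n_male,
            "pct_male": s.pct_male,
            "n_admitted": s.n_admitted,
            "pct_admitted": s.pct_admitted,
            "n_died_24h": s.n_died_24h,
            "pct_died_24h": s.pct_died_24h,
        }
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Discrimination table
# ---------------------------------------------------------------------------

_OUTCOME_GETTERS = {
    "death_24h": lambda r: r.died_within_24h,
    "admitted": lambda r: r.admitted,
}

SATS_ROW = "SATS"  # label of the urgency-rank-as-score row


def _scores_for(
    records: Sequence[PatientRecord], variant: ScoreVariant
) -> tuple[list[PatientRecord], np.ndarray]:
    subset = [r for r in records if variant_complete(r, variant)]
    return subset, np.array([compute_khds(r, variant).points for r in subset])


def _sats_scores(records: Sequence[PatientRecord]) -> tuple[list[PatientRecord], np.ndarray]:
    subset = [r for r in records if has_sats_ranking(r)]
    return subset, np.array([int(rank_patient(r.presentations)) for r in subset])


def roc_for_variant(
    records: Sequence[PatientRecord], variant: ScoreVariant, outcome: str
) -> ROCResult:
    """c statistic of one score variant on its complete-case subset."""
    subset, scores = _scores_for(records, variant)
    y = np.array([_OUTCOME_GETTERS[outcome](r) for r in subset])
    return c_statistic(scores, y)


def discrimination_table(
    records: Sequence[PatientRecord],
    variants: Sequence[ScoreVariant] = (
        ScoreVariant.KHDS_RESP,
        ScoreVariant.KHDS_MONTHS,
    ),
    outcomes: Sequence[str] = ("death_24h", "admitted"),
    reference: ScoreVariant = ScoreVariant.KHDS_SAT,
    include_sats: bool = True,
) -> pd.DataFrame:
    """Per-outcome discrimination of each score variant vs the reference.

    For every non-reference row the reference c statistic is *recomputed on
    that row's complete-case subset* before comparison — a variant measured
    on a late-starting sub-cohort is only comparable to the reference on
    the same patients.  The SATS row uses the urgency rank 0-3 as an
    ordinal score over the ranked sub-cohort.  Comparison p-values are
    one-tailed independent-z by default.

    Rows whose subset lacks an outcome class are flagged non-computable
    (NaN statistics, note says why).
    """
    rows = []
    for outcome in outcomes:
        get = _OUTCOME_GETTERS[outcome]  # validates the outcome name

        ref_subset, ref_scores = _scores_for(records, reference)
        ref_y = np.array([get(r) for r in ref_subset]) if ref_subset else np.array([])
        ref_computable = ref_y.size > 0 and ref_y.any() and not ref_y.all()
        if ref_computable:
            ref_roc = c_statistic(ref_scores, ref_y)
            rows.append(
                {
                    "outcome": outcome,
                    "score": reference.name,
                    "n": ref_roc.n_pos + ref_roc.n_neg,
                    "auc": ref_roc.auc,
                    "se": ref_roc.se,
                    "ref_auc": np.nan,
                    "ref_se": np.nan,
                    "p": np.nan,
                    "note": "reference",
                }
            )
        else:
            rows.append(
                {
                    "outcome": outcome,
                    "score": reference.name,
                    "n": len(ref_subset),
                    "auc": np.nan,
                    "se": np.nan,
                    "ref_auc": np.nan,
                    "ref_se": np.nan,
                    "p": np.nan,
                    "note": "non-computable: outcome class absent",
                }
            )

        comparisons: list[tuple[str, list[PatientRecord], np.ndarray]] = []
        for variant in variants:
            if variant is reference:
                continue
            subset, scores = _scores_for(records, variant)
            comparisons.append((variant.name, subset, scores))
        if include_sats:
            comparisons.append((SATS_ROW, *_sats_scores(records)))

        for label, subset, scores in comparisons:
            y = np.array([get(r) for r in subset]) if subset else np.array([])
            if y.size == 0 or y.all() or not y.any():
                rows.append(
                    {
                        "outcome": outcome,
                        "score": label,
                        "n": len(subset),
                        "auc": np.nan,
                        "se": np.nan,
                        "ref_auc": np.nan,
                        "ref_se": np.nan,
                        "p": np.nan,
                        "note": "non-computable: outcome class absent",
                    }
                )
                continue
            roc = c_statistic(scores, y)
            # reference recomputed on this row's subset
            ids = {id(r) for r in subset}
            ref_sub = [r for r in ref_subset if id(r) in ids]
            ref_sub_scores = np.array(
                [compute_khds(r, reference).points for r in ref_sub]
            )
            try:
                ref_on_subset = c_statistic(ref_sub_scores, [get(r) for r in ref_sub])
                cmp = compare_c_statistics(roc, ref_on_subset)
            except (UndefinedDiscriminationError, DegenerateComparisonError) as exc:
                rows.append(
                    {
                        "outcome": outcome,
                        "score": label,
                        "n": len(subset),
                        "auc": roc.auc,
                        "se": roc.se,
                        "ref_auc": np.nan,
                        "ref_se": np.nan,
                        "p": np.nan,
                        "note": f"non-computable comparison: {exc}",
                    }
                )
                continue
            rows.append(
                {
                    "outcome": outcome,
                    "score": label,
                    "n": len(subset),
                    "auc": roc.auc,
                    "se": roc.se,
                    "ref_auc": ref_on_subset.auc,
                    "ref_se": ref_on_subset.se,
                    "p": cmp.p,
                    "note": "",
                }
            )
    return pd.DataFrame(rows)


def breakdown_by_score(
    records: Sequence[PatientRecord],
    variant: ScoreVariant = ScoreVariant.KHDS_SAT,
) -> pd.DataFrame:
    """Outcome counts per score level (0-3): n, admissions, deaths within
    24 h, later in-hospital deaths.  Complete-case for the variant."""
    counts = {
        s: {"n": 0, "n_admitted": 0, "n_died_24h": 0, "n_died_later": 0}
        for s in range(N_POINTS)
    }
    for rec in records:
        if not variant_complete(rec, variant):
            continue
        s = compute_khds(rec, variant).points
        counts[s]["n"] += 1
        counts[s]["n_admitted"] += rec.admitted
        counts[s]["n_died_24h"] += rec.died_within_24h
        counts[s]["n_died_later"] += rec.died_in_hospital and not rec.died_within_24h
    df = pd.DataFrame.from_dict(counts, orient="index")
    df.index.name = "points"
    return df


def admissions_below_cut(breakdown: pd.DataFrame, cut: int = 2) -> tuple[int, float]:
    """(count, %) of all admissions that scored below the cut."""
    below = int(breakdown.loc[: cut - 1, "n_admitted"].sum())
    total = int(breakdown["n_admitted"].sum())
    return below, percentage(below, total)


def deaths_at_or_above(breakdown: pd.DataFrame, cut: int = 3) -> tuple[int, float]:
    """(count, %) of 24-h deaths that scored at or above the cut."""
    high = int(breakdown.loc[cut:, "n_died_24h"].sum())
    total = int(breakdown["n_died_24h"].sum())
    return high, percentage(high, total)
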