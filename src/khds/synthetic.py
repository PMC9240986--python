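"""Seedable synthetic-cohort generator.

Real patient-level triage data of this kind is rarely deposited, so the
pipeline is exercised on simulated cohorts whose *marginal* structure is
calibrated to a published 14,585-patient emergency/outpatient cohort:
score-class prevalences, admission and 24-h death probabilities conditional
on the score, the joint distribution of score points and SATS urgency over
the ranked sub-population, age/sex demographics, and arrival-time load by
6-hour block.

Generation is score-class-first: each patient draws a score class (0-3),
then a uniformly chosen component pattern of that size, then component
values consistent with the pattern (SpO2 and respiratory rate from the
matching ranges, mental-status flags, a months-backwards result that
disagrees with the subjective assessment at a small configurable rate),
then a SATS urgency conditional on the score, and finally outcomes.
Only joint structure the calibration targets imply is modelled; vital-sign
physiology, repeat attendance and time-of-day acuity effects are not.

Sub-cohort structure: only a fraction of patients carry a respiratory
rate, a months-backwards result, or a SATS ranking (mirroring staggered
introduction of those assessments); the fractions default to the published
sub-cohort sizes.  Unranked patients carry an empty presentation list;
ranked non-urgent patients carry the explicit ``non_urgent`` pseudo-code.

Determinism: one root seed spawns independent per-stage child streams, so
the same seed always yields a byte-identical cohort and adding a stage
never reshuffles earlier draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import truncnorm

from .cohort import Gait, PatientRecord, Sex
from .sats import NON_URGENT_CODE, UrgencyLevel, codes_at

# --- published calibration counts -----------------------------------------
_N_DEFAULT = 14_585
_SCORE_COUNTS = (14_585 - 1490 - 1805 - 653, 1490, 1805, 653)  # points 0..3
_N_ADMITTED = 1804
_N_ADMITTED_BELOW_2 = 96
_DEATHS24_BY_SCORE = (0, 0, 2, 37)
_N_LATE_DEATHS = 134
_P_ADMIT_SCORE3 = 0.95  # free parameter: the 2-vs-3 admission split
# ranked sub-population: points (rows 0..3) x urgency (non/urgent/very/emergent)
_SATS_COUNTS = (
    (5430, 0, 0, 0),
    (728, 2, 5, 0),
    (689, 127, 206, 15),
    (79, 27, 184, 8),
)
_N_RANKED = 7500
_N_RESP = 4368
_N_MONTHS = 11_481
# arrival load by 6-h block (00-06, 06-12, 12-18, 18-24); day blocks carry
# 13,316 of 14,585 arrivals, the small-hours block 297
_ARRIVAL_BLOCK_COUNTS = (297, 6658, 6658, 972)

_MENTAL, _MOBILITY, _RESP = 1, 2, 4  # component bitmask
_MASKS_BY_POINTS = ((0,), (1, 2, 4), (3, 5, 6), (7,))


@dataclass(frozen=True)
class GeneratorConfig:
    """Calibration of the synthetic cohort; defaults via :func:`default_config`.

    Probability vectors are indexed by score points 0-3.  ``sats_joint`` is
    the (points x urgency) joint distribution of the ranked sub-population;
    urgency is drawn conditional on each patient's points, so the points
    marginal always follows ``score_class_probs``.
    """

    n: int
    score_class_probs: tuple[float, float, float, float]
    p_admit_by_score: tuple[float, float, float, float]
    p_death24_by_score: tuple[float, float, float, float]
    p_late_death_given_admitted_by_score: tuple[float, float, float, float]
    sats_joint: tuple[tuple[float, ...], ...]
    months_disagreement: float = 0.05
    p_resp_rate_available: float = _N_RESP / _N_DEFAULT
    p_months_available: float = _N_MONTHS / _N_DEFAULT
    p_sats_available: float = _N_RANKED / _N_DEFAULT
    spo2_low: tuple[int, int] = (88, 93)
    spo2_normal: tuple[int, int] = (94, 99)
    rr_normal: tuple[int, int] = (12, 23)
    rr_high: tuple[int, int] = (24, 40)
    age_mean: float = 44.0
    age_sd: float = 19.9
    age_min: int = 12
    p_male: float = 0.392
    arrival_block_weights: tuple[float, float, float, float] = tuple(
        c / _N_DEFAULT for c in _ARRIVAL_BLOCK_COUNTS
    )
    study_start: str = "2020-11-23"
    study_days: int = 342
    # geometric day-of-death parameter for post-24h in-hospital deaths;
    # 0.21 puts ~69% of late deaths within 5 days
    late_death_day_geom_p: float = 0.21
    # confine score-2 24-h deaths to the {mental, mobility} component
    # pattern (rate rescaled to preserve the marginal), so no decedent has
    # a stable gait or a normal mental status
    deaths_require_mental_and_mobility: bool = True
    seed: int = 0

    def validate(self) -> None:
        def _check_probs(name: str, v: Sequence[float]) -> None:
            a = np.asarray(v, dtype=float)
            if (a < 0).any() or (a > 1).any():
                raise ValueError(f"{name} must lie in [0, 1]")

        sc = np.asarray(self.score_class_probs, dtype=float)
        if sc.shape != (4,) or (sc < 0).any() or not np.isclose(sc.sum(), 1.0):
            raise ValueError("score_class_probs must be a normalized 4-vector")
        for name in (
            "p_admit_by_score",
            "p_death24_by_score",
            "p_late_death_given_admitted_by_score",
        ):
            _check_probs(name, getattr(self, name))
        if np.any(
            np.asarray(self.p_death24_by_score) > np.asarray(self.p_admit_by_score)
        ):
            raise ValueError(
                "p_death24_by_score must be <= p_admit_by_score (deaths are admissions)"
            )
        sj = np.asarray(self.sats_joint, dtype=float)
        if sj.shape != (4, 4) or (sj < 0).any() or not np.isclose(sj.sum(), 1.0):
            raise ValueError("sats_joint must be a normalized 4x4 matrix")
        for name in (
            "months_disagreement",
            "p_resp_rate_available",
            "p_months_available",
            "p_sats_available",
            "p_male",
        ):
            _check_probs(name, [getattr(self, name)])
        bw = np.asarray(self.arrival_block_weights, dtype=float)
        if bw.shape != (4,) or (bw < 0).any() or not np.isclose(bw.sum(), 1.0):
            raise ValueError("arrival_block_weights must be a normalized 4-vector")
        if not (0 < self.late_death_day_geom_p <= 1):
            raise ValueError("late_death_day_geom_p must be in (0, 1]")
        if self.n < 0:
            raise ValueError("n must be >= 0")

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        raw = json.loads(text)
        def _tup(v):
            return tuple(tuple(x) if isinstance(x, list) else x for x in v)
        for key in (
            "score_class_probs",
            "p_admit_by_score",
            "p_death24_by_score",
            "p_late_death_given_admitted_by_score",
            "sats_joint",
            "spo2_low",
            "spo2_normal",
            "rr_normal",
            "rr_high",
            "arrival_block_weights",
        ):
            if key in raw:
                raw[key] = _tup(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def default_config(n: int = _N_DEFAULT, seed: int = 0) -> GeneratorConfig:
    """The default calibration.

    * score-class shares from the published prevalences (10.2% one point,
      12.4% two, 4.5% three);
    * 24-h death rates 0, 0, 2/1805, 37/653 by score;
    * admission probabilities solved so the expected cohort admission rate
      is 12.4% with 96 admissions below two points: p(3) fixed at 0.95 (a
      documented free choice), p(2) solved for the remaining 1,708 expected
      admissions at >= 2 points, p(0) = p(1) spread over the 12,127
      low-score patients;
    * late in-hospital death probability uniform over scores (134/1,804);
    * SATS joint distribution = the published ranked cross-tab / 7,500.
    """
    n0, n1, n2, n3 = _SCORE_COUNTS
    total = sum(_SCORE_COUNTS)
    p_admit_low = _N_ADMITTED_BELOW_2 / (n0 + n1)
    p_admit_2 = (_N_ADMITTED - _N_ADMITTED_BELOW_2 - _P_ADMIT_SCORE3 * n3) / n2
    p_late = _N_LATE_DEATHS / _N_ADMITTED
    sats_total = sum(sum(row) for row in _SATS_COUNTS)
    cfg = GeneratorConfig(
        n=n,
        score_class_probs=tuple(c / total for c in _SCORE_COUNTS),
        p_admit_by_score=(p_admit_low, p_admit_low, p_admit_2, _P_ADMIT_SCORE3),
        p_death24_by_score=tuple(
            d / c for d, c in zip(_DEATHS24_BY_SCORE, _SCORE_COUNTS)
        ),
        p_late_death_given_admitted_by_score=(p_late,) * 4,
        sats_joint=tuple(tuple(c / sats_total for c in row) for row in _SATS_COUNTS),
        seed=seed,
    )
    cfg.validate()
    return cfg


_GAITS_IMPAIRED = (Gait.UNSTEADY, Gait.USES_AID, Gait.NEEDS_HELP, Gait.BEDRIDDEN)
_BLOCK_STARTS = (0, 6, 12, 18)

_truncnorm_cache: dict[tuple[float, float, float], tuple[float, float]] = {}


def _truncnorm_parent_params(
    mean: float, sd: float, lower: float
) -> tuple[float, float]:
    """Parent normal (loc, scale) whose truncation at ``lower`` has the
    requested mean and SD — naive truncation of N(mean, sd) would bias the
    realized moments (e.g. to ~46/18 for 44/19.9 floored at 12)."""
    key = (mean, sd, lower)
    if key not in _truncnorm_cache:

        def moments(params: np.ndarray) -> list[float]:
            loc, scale = params
            scale = abs(scale)
            a = (lower - loc) / scale
            m, v = truncnorm.stats(a, np.inf, loc=loc, scale=scale, moments="mv")
            return [float(m) - mean, float(np.sqrt(v)) - sd]

        sol = optimize.fsolve(moments, x0=[mean, sd], full_output=False)
        _truncnorm_cache[key] = (float(sol[0]), float(abs(sol[1])))
    return _truncnorm_cache[key]


def generate_cohort(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> list[PatientRecord]:
    """Simulate a cohort of eligible presentations.

    ``seed`` overrides ``config.seed``; the same (config, seed) pair always
    yields an identical cohort.
    """
    cfg = config or default_config()
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    (
        ss_score,
        ss_comp,
        ss_vitals,
        ss_months,
        ss_sats,
        ss_outcome,
        ss_demo,
        ss_arrival,
    ) = root.spawn(8)
    n = cfg.n
    if n == 0:
        return []

    rng_score = np.random.default_rng(ss_score)
    rng_comp = np.random.default_rng(ss_comp)
    rng_vitals = np.random.default_rng(ss_vitals)
    rng_months = np.random.default_rng(ss_months)
    rng_sats = np.random.default_rng(ss_sats)
    rng_outcome = np.random.default_rng(ss_outcome)
    rng_demo = np.random.default_rng(ss_demo)
    rng_arrival = np.random.default_rng(ss_arrival)

    points = rng_score.choice(4, size=n, p=np.asarray(cfg.score_class_probs))

    # component pattern: uniform over subsets of size = points
    masks = np.zeros(n, dtype=int)
    for k in (1, 2):
        idx = np.flatnonzero(points == k)
        choices = np.asarray(_MASKS_BY_POINTS[k])
        masks[idx] = choices[rng_comp.integers(0, len(choices), size=idx.size)]
    masks[points == 3] = 7
    mental_pos = (masks & _MENTAL) > 0
    mobility_pos = (masks & _MOBILITY) > 0
    resp_pos = (masks & _RESP) > 0

    # mental flags: abnormal status fails one uniformly chosen flag
    failing_flag = rng_comp.integers(0, 4, size=n)
    # gait: impaired category uniform over the four impaired levels
    impaired_gait = rng_comp.integers(0, 4, size=n)

    # vitals consistent with the respiratory component
    spo2 = np.where(
        resp_pos,
        rng_vitals.integers(cfg.spo2_low[0], cfg.spo2_low[1] + 1, size=n),
        rng_vitals.integers(cfg.spo2_normal[0], cfg.spo2_normal[1] + 1, size=n),
    ).astype(float)
    rr = np.where(
        resp_pos,
        rng_vitals.integers(cfg.rr_high[0], cfg.rr_high[1] + 1, size=n),
        rng_vitals.integers(cfg.rr_normal[0], cfg.rr_normal[1] + 1, size=n),
    ).astype(float)
    rr_avail = rng_vitals.random(n) < cfg.p_resp_rate_available

    # months-backwards result: agrees with subjective status except at the
    # configured disagreement rate
    months_pass = ~mental_pos
    flip = rng_months.random(n) < cfg.months_disagreement
    months_pass = np.where(flip, ~months_pass, months_pass)
    months_avail = rng_months.random(n) < cfg.p_months_available

    # SATS urgency conditional on points
    sj = np.asarray(cfg.sats_joint, dtype=float)
    urgency = np.zeros(n, dtype=int)
    for s in range(4):
        idx = np.flatnonzero(points == s)
        row = sj[s]
        if row.sum() == 0:
            continue  # leaves NON_URGENT
        urgency[idx] = rng_sats.choice(4, size=idx.size, p=row / row.sum())
    sats_avail = rng_sats.random(n) < cfg.p_sats_available
    # one presentation code per ranked patient, uniform within the level
    code_pick = rng_sats.random(n)

    p_admit = np.asarray(cfg.p_admit_by_score)[points]
    admitted = rng_outcome.random(n) < p_admit
    p_death = np.asarray(cfg.p_death24_by_score)[points].copy()
    if cfg.deaths_require_mental_and_mobility:
        # at-risk pattern among score-2 patients is {mental, mobility};
        # uniform allocation makes that a third of them, so triple the rate
        at_risk2 = (points == 2) & (masks == (_MENTAL | _MOBILITY))
        p_death = np.where(points == 2, 0.0, p_death)
        p_death[at_risk2] = min(cfg.p_death24_by_score[2] * len(_MASKS_BY_POINTS[2]), 1.0)
    died24 = rng_outcome.random(n) < p_death
    admitted |= died24  # every death is an admission
    p_late = np.asarray(cfg.p_late_death_given_admitted_by_score)[points]
    died_late = admitted & ~died24 & (rng_outcome.random(n) < p_late)
    late_days = rng_outcome.geometric(cfg.late_death_day_geom_p, size=n)

    # demographics: age truncated-normal at age_min; the parent normal's
    # parameters are solved so the *truncated* law has the target moments
    loc, scale = _truncnorm_parent_params(cfg.age_mean, cfg.age_sd, cfg.age_min)
    a = (cfg.age_min - loc) / scale
    ages = truncnorm.ppf(rng_demo.random(n), a, np.inf, loc=loc, scale=scale)
    ages = np.maximum(np.rint(ages).astype(int), cfg.age_min)
    male = rng_demo.random(n) < cfg.p_male

    block = rng_arrival.choice(4, size=n, p=np.asarray(cfg.arrival_block_weights))
    day = rng_arrival.integers(0, cfg.study_days + 1, size=n)
    sec_in_block = rng_arrival.integers(0, 6 * 3600, size=n)
    start = datetime.fromisoformat(cfg.study_start)

    level_codes = {lvl: codes_at(lvl) for lvl in UrgencyLevel if lvl != UrgencyLevel.NON_URGENT}

    records: list[PatientRecord] = []
    for i in range(n):
        flags = [True, True, True, True]
        if mental_pos[i]:
            flags[failing_flag[i]] = False
        gait = (
            _GAITS_IMPAIRED[impaired_gait[i]]
            if mobility_pos[i]
            else Gait.STABLE_INDEPENDENT
        )
        if sats_avail[i]:
            lvl = UrgencyLevel(int(urgency[i]))
            if lvl is UrgencyLevel.NON_URGENT:
                presentations = (NON_URGENT_CODE,)
            else:
                codes = level_codes[lvl]
                presentations = (codes[int(code_pick[i] * len(codes))],)
        else:
            presentations = ()
        if died24[i]:
            day_of_death: int | None = 0
        elif died_late[i]:
            day_of_death = int(late_days[i])
        else:
            day_of_death = None
        arrival = start + timedelta(
            days=int(day[i]),
            hours=_BLOCK_STARTS[block[i]],
            seconds=int(sec_in_block[i]),
        )
        records.append(
            PatientRecord(
                patient_id=f"P{i:06d}",
                age=int(ages[i]),
                sex=Sex.MALE if male[i] else Sex.FEMALE,
                arrival=arrival,
                pregnant=False,
                alert=flags[0],
                attentive=flags[1],
                calm=flags[2],
                coherent=flags[3],
                months_backwards_pass=bool(months_pass[i]) if months_avail[i] else None,
                gait=gait,
                spo2=float(spo2[i]),
                resp_rate=float(rr[i]) if rr_avail[i] else None,
                presentations=presentations,
                admitted=bool(admitted[i]),
                died_within_24h=bool(died24[i]),
                died_in_hospital=bool(died24[i] or died_late[i]),
                day_of_death=day_of_death,
            )
        )
    return records
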