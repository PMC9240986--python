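"""Cross-tabulation, acuity discordance, summaries and report arithmetic."""

import numpy as np
import pytest

from khds.cohort import Gait, ScoreVariant
from khds.concordance import (
    CrossTab,
    DiscordanceConfig,
    acuity_discordance,
    admissions_below_cut,
    analysis_sets_summary,
    breakdown_by_score,
    cohort_summary,
    crosstab_khds_sats,
    deaths_at_or_above,
    discordant_outcomes,
    discrimination_table,
    reference_crosstab,
)
from khds.reporting import percentage, round_half_up
from khds.sats import UrgencyLevel
from conftest import make_record


class TestReferenceCrossTab:
    """The packaged published cross-tab of 7,500 ranked presentations."""

    def test_row_and_column_totals_match_the_published_table(self):
        ct = reference_crosstab()
        assert ct.total == 7500
        # urgency totals: non-urgent, urgent, very urgent, emergent
        assert ct.urgency_totals().tolist() == [6926, 156, 395, 23]
        # score totals across points 0-3
        assert ct.score_totals().tolist() == [5430, 735, 1037, 298]

    def test_discordance_reproduces_published_percentages(self):
        summary = acuity_discordance(reference_crosstab())
        assert summary.n_higher == 768
        assert summary.pct_higher == 11.1
        assert summary.n_lower == 7
        assert summary.lower_denominator == 551
        assert summary.pct_lower == 1.3

    def test_including_emergent_changes_nothing_here(self):
        # no emergent patient scored below the cut in the published table
        cfg = DiscordanceConfig(
            lower_levels=(
                UrgencyLevel.URGENT,
                UrgencyLevel.VERY_URGENT,
                UrgencyLevel.EMERGENT,
            )
        )
        summary = acuity_discordance(reference_crosstab(), cfg)
        assert summary.n_lower == 7
        assert summary.lower_denominator == 551 + 23


class TestAcuityDiscordanceEdges:
    def test_cut_zero_empties_the_lower_side(self):
        s = acuity_discordance(reference_crosstab(), DiscordanceConfig(high_score_cut=0))
        assert s.n_lower == 0
        assert s.n_higher == s.non_urgent_total

    def test_cut_four_empties_the_higher_side(self):
        s = acuity_discordance(reference_crosstab(), DiscordanceConfig(high_score_cut=4))
        assert s.n_higher == 0

    def test_all_non_urgent_mass_at_zero_points(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 100
        counts[1, 1] = 1
        assert acuity_discordance(CrossTab(counts)).n_higher == 0

    def test_empty_denominator_rejected(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[2, 0] = 10  # non-urgent only: urgent+very-urgent denominator empty
        with pytest.raises(ValueError):
            acuity_discordance(CrossTab(counts))

    def test_percentages_recompute_from_counts(self):
        s = acuity_discordance(reference_crosstab())
        assert s.pct_higher == percentage(s.n_higher, s.non_urgent_total)
        assert s.pct_lower == percentage(s.n_lower, s.lower_denominator)


class TestCrossTabFromRecords:
    def test_single_record_single_cell(self):
        rec = make_record(
            coherent=False,
            gait=Gait.BEDRIDDEN,
            spo2=88.0,
            presentations=("hypoglycaemia",),
        )
        ct = crosstab_khds_sats([rec])
        assert ct.total == 1
        assert ct.counts[3, int(UrgencyLevel.EMERGENT)] == 1

    def test_unranked_and_incomplete_records_are_excluded(self):
        ranked = make_record(presentations=("vomiting",))
        unranked = make_record(patient_id="P2")
        no_spo2 = make_record(patient_id="P3", spo2=None, presentations=("vomiting",))
        ct = crosstab_khds_sats([ranked, unranked, no_spo2])
        assert ct.total == 1
        assert ct.n_excluded == 2

    def test_marginals_match_score_and_urgency_distributions(self, default_cohort):
        ct = crosstab_khds_sats(default_cohort)
        assert ct.total + ct.n_excluded == len(default_cohort)
        assert ct.score_totals().sum() == ct.total
        assert ct.urgency_totals().sum() == ct.total


class TestCohortSummary:
    def test_single_record(self):
        s = cohort_summary([make_record(age=40)])
        assert s.mean_age == 40.0
        assert s.sd_age == 0.0

    def test_three_age_quantile_convention(self):
        s = cohort_summary(
            [make_record(age=28), make_record(age=40), make_record(age=59)]
        )
        assert s.median_age == 40.0
        assert s.iqr_age == (28.0, 59.0)

    def test_sex_percentage(self):
        from khds.cohort import Sex

        records = [
            make_record(patient_id=f"P{i}", sex=Sex.MALE if i < 2 else Sex.FEMALE)
            for i in range(5)
        ]
        s = cohort_summary(records)
        assert s.n_male == 2
        assert s.pct_male == 40.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])

    def test_analysis_sets_shrink_with_component_availability(self, default_cohort):
        summaries = analysis_sets_summary(default_cohort)
        assert summaries["KHDS_SAT"].n == len(default_cohort)
        assert summaries["KHDS_RESP"].n < summaries["KHDS_MONTHS"].n < summaries["KHDS_SAT"].n


class TestDiscriminationTable:
    def test_reference_vs_itself_is_null(self, default_cohort):
        df = discrimination_table(
            default_cohort, variants=(ScoreVariant.KHDS_SAT,), include_sats=False
        )
        assert (df["note"] == "reference").all()

    def test_reference_recomputed_on_subset(self, default_cohort):
        df = discrimination_table(default_cohort, outcomes=("admitted",))
        ref_row = df[df["note"] == "reference"].iloc[0]
        resp_row = df[df["score"] == "KHDS_RESP"].iloc[0]
        # the rate variant is measured on a sub-cohort: the reference AUC
        # recomputed there differs from its full-cohort value
        assert resp_row["n"] < ref_row["n"]
        assert resp_row["ref_auc"] != pytest.approx(ref_row["auc"], abs=1e-6)

    def test_sats_row_uses_urgency_rank_as_score(self, default_cohort):
        from khds.cohort import has_sats_ranking
        from khds.sats import rank_patient
        from khds.stats import c_statistic

        df = discrimination_table(default_cohort, outcomes=("admitted",))
        sats_row = df[df["score"] == "SATS"].iloc[0]
        ranked = [r for r in default_cohort if has_sats_ranking(r)]
        expected = c_statistic(
            [int(rank_patient(r.presentations)) for r in ranked],
            [r.admitted for r in ranked],
        )
        assert sats_row["auc"] == pytest.approx(expected.auc)
        assert sats_row["n"] == len(ranked)

    def test_absent_outcome_class_flagged(self):
        records = [make_record(patient_id=f"P{i}") for i in range(10)]  # nobody admitted
        df = discrimination_table(records, outcomes=("admitted",), include_sats=False)
        assert (df["note"] == "non-computable: outcome class absent").any() or df[
            "auc"
        ].isna().all()


class TestBreakdownAndWorkedRatios:
    def test_planted_cohort_recounted_exactly(self):
        records = []
        for i in range(37):  # deaths at three points
            records.append(
                make_record(
                    patient_id=f"D3_{i}", coherent=False, gait=Gait.BEDRIDDEN,
                    spo2=88.0, admitted=True, died_within_24h=True,
                    died_in_hospital=True, day_of_death=0,
                )
            )
        for i in range(2):  # deaths at two points
            records.append(
                make_record(
                    patient_id=f"D2_{i}", coherent=False, gait=Gait.BEDRIDDEN,
                    spo2=97.0, admitted=True, died_within_24h=True,
                    died_in_hospital=True, day_of_death=0,
                )
            )
        records.append(make_record(patient_id="W", spo2=97.0))
        df = breakdown_by_score(records)
        assert df.loc[3, "n_died_24h"] == 37
        assert df.loc[2, "n_died_24h"] == 2
        n_high, pct = deaths_at_or_above(df, cut=3)
        assert n_high == 37
        assert pct == 94.9  # rounds to the published 95%
        assert round_half_up(pct, 0) == 95.0

    def test_no_deaths_gives_zero_rows(self, well_record):
        df = breakdown_by_score([well_record])
        assert df["n_died_24h"].sum() == 0
        assert df["n_died_later"].sum() == 0

    def test_published_worked_ratios(self):
        # the report layer's half-up one-decimal rounding on published counts
        assert percentage(39, 1804) == 2.2  # 24-h deaths per admission
        assert percentage(96, 1804) == 5.3  # admissions below two points
        assert percentage(37, 39) == 94.9  # decedents with the saturation point
        assert percentage(3 + 22, 407) == 6.1  # in-hospital deaths of admitted discordants
        assert percentage(407, 768) == 53.0  # admitted share of higher-discordants

    def test_admissions_below_cut_counts(self):
        records = [
            make_record(patient_id="A", admitted=True, spo2=97.0),  # 0 points
            make_record(patient_id="B", admitted=True, spo2=88.0, gait=Gait.UNSTEADY),  # 2
        ]
        df = breakdown_by_score(records)
        below, pct = admissions_below_cut(df, cut=2)
        assert (below, pct) == (1, 50.0)


class TestDiscordantOutcomes:
    def test_planted_discordant_group(self):
        records = []
        # 4 high-score non-urgent patients: 2 admitted, 1 of them died late
        for i, (adm, died_late) in enumerate([(True, True), (True, False), (False, False), (False, False)]):
            records.append(
                make_record(
                    patient_id=f"G{i}", gait=Gait.NEEDS_HELP, spo2=90.0,
                    presentations=("non_urgent",), admitted=adm,
                    died_in_hospital=died_late, day_of_death=3 if died_late else None,
                )
            )
        # an urgent-ranked patient must not enter the group
        records.append(
            make_record(patient_id="U", gait=Gait.NEEDS_HELP, spo2=90.0,
                        presentations=("vomiting",)),
        )
        out = discordant_outcomes(records)
        assert out.n_group == 4
        assert out.n_admitted == 2
        assert out.pct_admitted == 50.0
        assert out.n_died_24h == 0
        assert out.n_died_later == 1
        assert out.pct_died_of_admitted == 50.0

    def test_group_without_admissions_has_no_percentage(self):
        rec = make_record(gait=Gait.NEEDS_HELP, spo2=90.0, presentations=("non_urgent",))
        out = discordant_outcomes([rec])
        assert out.pct_died_of_admitted is None

    def test_synthetic_cohort_recount_matches_enumeration(self, default_cohort):
        from khds.cohort import compute_khds, has_sats_ranking
        from khds.sats import rank_patient

        out = discordant_outcomes(default_cohort)
        group = [
            r
            for r in default_cohort
            if has_sats_ranking(r)
            and rank_patient(r.presentations) is UrgencyLevel.NON_URGENT
            and compute_khds(r).points >= 2
        ]
        assert out.n_group == len(group)
        assert out.n_admitted == sum(r.admitted for r in group)
        assert out.n_died_24h == sum(r.died_within_24h for r in group)
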