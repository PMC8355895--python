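"""Two-tier funnel state tracking and summarization."""

import numpy as np
import pytest

import iemscreen as im
from iemscreen.screening_pipeline import PipelineError


def make_panel(cutoffs, specimen_id, overrides=None, tier="primary"):
    schema = cutoffs.schema()
    values = {}
    for m in im.primary_markers(schema):
        lo, hi = cutoffs[m]
        values[m] = float(np.sqrt(max(lo, hi / 100) * hi))
    values.update(overrides or {})
    return im.AnalytePanel(specimen_id, values, tier=tier)


class TestPrimaryScreen:
    def test_low_c0_specimen_is_primary_positive(self, cutoffs, patterns):
        panels = [make_panel(cutoffs, "a", {"C0": 2.83})]
        recs = im.run_primary_screen(panels, cutoffs, patterns)
        assert recs[0].primary_positive

    def test_all_normal_panel_is_screen_negative(self, cutoffs, patterns):
        recs = im.run_primary_screen([make_panel(cutoffs, "a")], cutoffs, patterns)
        assert not recs[0].primary_positive
        assert recs[0].final_state == "screen_negative"

    def test_counts_one_abnormal_among_three(self, cutoffs, patterns):
        panels = [
            make_panel(cutoffs, "a"),
            make_panel(cutoffs, "b", {"Phe": 400.0}),
            make_panel(cutoffs, "c"),
        ]
        recs = im.run_primary_screen(panels, cutoffs, patterns)
        assert sum(r.primary_positive for r in recs) == 1

    def test_duplicate_specimen_rejected(self, cutoffs, patterns):
        panels = [make_panel(cutoffs, "a"), make_panel(cutoffs, "a")]
        with pytest.raises(PipelineError, match="duplicate"):
            im.run_primary_screen(panels, cutoffs, patterns)

    def test_recall_tier_panel_rejected_at_primary(self, cutoffs, patterns):
        with pytest.raises(PipelineError):
            im.run_primary_screen(
                [make_panel(cutoffs, "a", tier="recall")], cutoffs, patterns
            )

    def test_pattern_trigger_requires_full_signature(self, cutoffs, patterns):
        # Phe high alone: positive under any_abnormal_marker, not under
        # any_pattern_match (PKU needs Phe/Tyr high as well)
        panels = [make_panel(cutoffs, "a", {"Phe": 400.0, "Tyr": 250.0})]
        by_marker = im.run_primary_screen(panels, cutoffs, patterns, "any_abnormal_marker")
        assert by_marker[0].primary_positive
        panels = [make_panel(cutoffs, "a", {"Phe": 400.0, "Tyr": 250.0})]
        by_pattern = im.run_primary_screen(panels, cutoffs, patterns, "any_pattern_match")
        assert not by_pattern[0].primary_positive


class TestRecallAndConfirm:
    def _positive_records(self, cutoffs, patterns, n=3):
        panels = [make_panel(cutoffs, f"s{i}", {"C0": 2.0}) for i in range(n)]
        return im.run_primary_screen(panels, cutoffs, patterns)

    def test_lost_specimens_are_lost_to_followup(self, cutoffs, patterns):
        recs = self._positive_records(cutoffs, patterns)
        recall = [make_panel(cutoffs, "s0", {"C0": 2.5}, tier="recall"),
                  make_panel(cutoffs, "s1", tier="recall")]
        recs = im.apply_recall(recs, recall, {"s2"}, cutoffs, patterns)
        states = {r.specimen_id: r.final_state for r in recs}
        assert states["s2"] == "lost_to_followup"
        assert states["s1"] == "recall_negative"
        assert states["s0"] == "recall_positive_unconfirmed"

    def test_recall_for_negative_specimen_rejected(self, cutoffs, patterns):
        recs = im.run_primary_screen([make_panel(cutoffs, "neg")], cutoffs, patterns)
        with pytest.raises(PipelineError):
            im.apply_recall(
                recs, [make_panel(cutoffs, "neg", tier="recall")], set(), cutoffs, patterns
            )

    def test_unaccounted_positive_rejected(self, cutoffs, patterns):
        recs = self._positive_records(cutoffs, patterns)
        with pytest.raises(PipelineError, match="neither"):
            im.apply_recall(recs, [], set(), cutoffs, patterns)

    def test_empty_diagnoses_confirms_nothing(self, cutoffs, patterns):
        recs = self._positive_records(cutoffs, patterns, n=1)
        recall = [make_panel(cutoffs, "s0", {"C0": 2.5}, tier="recall")]
        recs = im.apply_recall(recs, recall, set(), cutoffs, patterns)
        recs = im.confirm(recs, {})
        assert im.summarize(recs).n_confirmed == 0

    def test_diagnosis_for_recall_negative_rejected(self, cutoffs, patterns):
        recs = self._positive_records(cutoffs, patterns, n=1)
        recall = [make_panel(cutoffs, "s0", tier="recall")]  # normal at recall
        recs = im.apply_recall(recs, recall, set(), cutoffs, patterns)
        with pytest.raises(PipelineError):
            im.confirm(recs, {"s0": "PCD"})

    def test_confirmed_state_and_spectrum(self, cutoffs, patterns):
        recs = self._positive_records(cutoffs, patterns, n=2)
        recall = [make_panel(cutoffs, f"s{i}", {"C0": 2.5}, tier="recall") for i in range(2)]
        recs = im.apply_recall(recs, recall, set(), cutoffs, patterns)
        recs = im.confirm(recs, {"s0": "PCD"})
        assert recs[0].final_state == "confirmed"
        summary = im.summarize(recs, patterns)
        assert summary.per_disorder == {"PCD": 1}
        assert summary.per_category == {"FAMD": 1}


class TestSummary:
    def test_funnel_monotonicity_enforced(self):
        with pytest.raises(PipelineError, match="monotone"):
            im.CohortSummary(
                n_screened=10, n_primary_positive=5, n_recalled=6,
                n_recall_positive=2, n_confirmed=1,
            )

    def test_spectrum_counts_must_sum_to_confirmed(self):
        with pytest.raises(PipelineError):
            im.CohortSummary(
                n_screened=10, n_primary_positive=5, n_recalled=4,
                n_recall_positive=3, n_confirmed=2, per_disorder={"PCD": 3},
            )

    def test_no_loss_perfect_persistence_keeps_funnel_flat(self, cutoffs, patterns):
        cfg = im.SimulationConfig(n_newborns=300, seed=5, loss_rate=0.0,
                                  fp_persistence=1.0, tp_persistence=1.0)
        cohort = im.simulate_cohort(cfg, cutoffs, patterns)
        _, summary = im.screen_cohort(cohort, cutoffs, patterns)
        assert summary.n_recalled == summary.n_primary_positive
        assert summary.n_recall_positive == summary.n_primary_positive

    def test_published_funnel_replay(self, published_counts, patterns):
        """The printed funnel counts reproduce the printed rates exactly."""
        c = published_counts["newborn"]
        summary = im.CohortSummary.from_counts(
            c["n_screened"], c["n_primary_positive"], c["n_recalled"], c["n_confirmed"],
        )
        report = im.funnel_report(summary)
        assert report["primary_positive_rate"] == "2.2%"
        assert report["recall_rate"] == "92.3%"
        assert report["ppv"] == "1.3%"
        assert report["incidence"] == "1/3,733"

    def test_spectrum_table_shape(self, published_counts, patterns):
        c = published_counts["newborn"]
        per_disorder = {
            row["disorder"]: row["cases"] for row in c["spectrum"] if row["disorder"]
        }
        summary = im.CohortSummary.from_counts(
            c["n_screened"], c["n_primary_positive"], c["n_recalled"], c["n_confirmed"],
            per_disorder=per_disorder,
            category_map={p.disorder_id: p.category for p in patterns},
        )
        table = im.spectrum_table(summary)
        famd = table[(table["category"] == "FAMD") & (table["disorder"] == "")]
        assert famd["cases"].item() == 15
        assert famd["incidence"].item() == "1/7,466"
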