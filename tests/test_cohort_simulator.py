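"""Healthy-marker model, affected draws and whole-cohort simulation."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import iemscreen as im
from iemscreen.cohort_simulator import _PanelSampler, ConfigurationError


class TestHealthyModel:
    def test_closed_form_tail_mass(self, cutoffs):
        model = im.fit_healthy_model(cutoffs, 0.05)
        for marker in ("C0", "Phe", "C5:1"):  # incl. a zero-lower-bound marker
            assert model.tail_mass(marker) == pytest.approx(0.05, abs=1e-10)

    def test_monte_carlo_out_of_range_fraction(self, cutoffs):
        model = im.fit_healthy_model(cutoffs, 0.05)
        rng = np.random.default_rng(3)
        x = model.sample("C0", 100_000, rng)
        frac = float(((x < 9.0) | (x > 55.0)).mean())
        se = math.sqrt(0.05 * 0.95 / 100_000)
        assert abs(frac - 0.05) < 3 * se

    def test_quadrature_recovers_alpha_for_phe(self, cutoffs):
        """Numeric integration of the fitted log-normal density over (24, 116)."""
        model = im.fit_healthy_model(cutoffs, 0.05)
        j = model.index("Phe")
        dist = stats.lognorm(s=model.sigma[j], scale=math.exp(model.mu[j]))
        inside, _ = integrate.quad(dist.pdf, 24.0, 116.0)
        assert 1.0 - inside == pytest.approx(0.05, abs=1e-6)

    def test_alpha_zero_degenerates_to_midpoint(self, cutoffs):
        model = im.fit_healthy_model(cutoffs, 0.0)
        rng = np.random.default_rng(0)
        x = model.sample("C0", 1000, rng)
        assert np.allclose(x, math.sqrt(9.0 * 55.0))

    def test_in_range_sampling_respects_bounds(self, cutoffs):
        model = im.fit_healthy_model(cutoffs, 0.05)
        rng = np.random.default_rng(1)
        for _ in range(200):
            x = model.sample_in_range(rng)
            assert np.all(x >= model.lower) and np.all(x <= model.upper)

    def test_tail_sampling_leaves_range(self, cutoffs):
        model = im.fit_healthy_model(cutoffs, 0.05)
        rng = np.random.default_rng(2)
        j = model.index("C0")
        assert all(model.sample_tail(j, "low", rng) < 9.0 for _ in range(50))
        assert all(model.sample_tail(j, "high", rng) > 55.0 for _ in range(50))


@pytest.fixture(scope="module")
def model(cutoffs):
    return im.fit_healthy_model(cutoffs, 0.05)


class TestAffectedPanels:
    def test_pku_draws_inside_printed_range(self, cutoffs, patterns, model):
        rng = np.random.default_rng(4)
        for _ in range(100):
            p = im.sample_affected_panel("PKU", patterns, model, rng, cutoffs=cutoffs)
            assert 201 <= p.values["Phe"] <= 1000.5
            assert p.truth_label == "PKU"

    def test_pcd_draws_flag_low_c0(self, cutoffs, patterns, model):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = im.sample_affected_panel("PCD", patterns, model, rng, cutoffs=cutoffs)
            assert 0.74 <= p.values["C0"] <= 5.45
            fl = im.flag_analyte_panel(p, cutoffs)
            assert ("C0", "low") in fl.abnormal

    def test_iva_draws_always_match_iva(self, cutoffs, patterns, model):
        """The printed IVA range lies wholly above the cut-off: 1,000/1,000 match."""
        rng = np.random.default_rng(6)
        sampler = _PanelSampler(cutoffs, patterns, model)
        hits = 0
        for _ in range(1000):
            x = sampler.affected("IVA", rng)
            panel = sampler.to_panel(x, "t", "primary", "newborn", "IVA")
            fl = im.flag_analyte_panel(panel, cutoffs)
            report = im.match_disorders(fl, patterns, mode="all_markers")
            hits += "IVA" in report.candidate_ids
        assert hits == 1000

    def test_ratio_signatures_back_solved(self, cutoffs, patterns, model):
        # SCADD requires C4/C2 within the printed range; the denominator C2 is
        # adjusted whenever the independent draws miss it
        rng = np.random.default_rng(7)
        sampler = _PanelSampler(cutoffs, patterns, model)
        for _ in range(100):
            x = sampler.affected("SCADD", rng)
            ratio = x[model.index("C4")] / x[model.index("C2")]
            assert 0.069 <= ratio <= 0.114 + 1e-12

    def test_unknown_disorder_rejected(self, cutoffs, patterns, model):
        rng = np.random.default_rng(8)
        with pytest.raises(ConfigurationError):
            im.sample_affected_panel("NOPE", patterns, model, rng, cutoffs=cutoffs)


class TestCohortSimulation:
    def test_seed_determinism(self, cutoffs, patterns):
        cfg = im.SimulationConfig(n_newborns=200, seed=9)
        a = im.simulate_cohort(cfg, cutoffs, patterns)
        b = im.simulate_cohort(cfg, cutoffs, patterns)
        assert a.truth == b.truth and a.lost_ids == b.lost_ids
        for pa, pb in zip(a.primary_panels + a.recall_panels,
                          b.primary_panels + b.recall_panels):
            assert pa.specimen_id == pb.specimen_id and pa.values == pb.values

    def test_different_seeds_differ(self, cutoffs, patterns):
        a = im.simulate_cohort(im.SimulationConfig(n_newborns=50, seed=1), cutoffs, patterns)
        b = im.simulate_cohort(im.SimulationConfig(n_newborns=50, seed=2), cutoffs, patterns)
        assert any(
            pa.values != pb.values for pa, pb in zip(a.primary_panels, b.primary_panels)
        )

    def test_recall_only_for_primary_positives(self, cutoffs, patterns):
        cfg = im.SimulationConfig(n_newborns=500, seed=10)
        cohort = im.simulate_cohort(cfg, cutoffs, patterns)
        records = im.run_primary_screen(cohort.primary_panels, cutoffs, patterns)
        positive = {r.specimen_id for r in records if r.primary_positive}
        assert {p.specimen_id for p in cohort.recall_panels} <= positive
        assert cohort.lost_ids <= positive

    def test_sensitivity_recovers_seeded_spectrum_exactly(self, cutoffs, patterns):
        """tp_persistence 1 and no loss: every affected specimen is confirmed."""
        prevalence = {"PCD": 0.02, "PKU": 0.01, "IVA": 0.01, "MMA": 0.005}
        cfg = im.SimulationConfig(
            n_newborns=800, seed=11, prevalence=prevalence, alpha=0.02,
            loss_rate=0.0, tp_persistence=1.0,
        )
        cohort = im.simulate_cohort(cfg, cutoffs, patterns)
        assert cohort.truth  # at least one affected seeded at these prevalences
        _, summary = im.screen_cohort(cohort, cutoffs, patterns)
        seeded = {}
        for d in cohort.truth.values():
            seeded[d] = seeded.get(d, 0) + 1
        assert summary.per_disorder == seeded
        assert summary.n_confirmed == len(cohort.truth)

    def test_prevalence_recovery_within_three_binomial_sd(self, cutoffs, patterns):
        prevalence = {"PCD": 0.03, "PKU": 0.02}
        n = 2000
        cfg = im.SimulationConfig(
            n_newborns=n, seed=12, prevalence=prevalence, alpha=0.02, loss_rate=0.0,
        )
        cohort = im.simulate_cohort(cfg, cutoffs, patterns)
        _, summary = im.screen_cohort(cohort, cutoffs, patterns)
        for d, p in prevalence.items():
            sd = math.sqrt(n * p * (1 - p))
            assert abs(summary.per_disorder.get(d, 0) - n * p) <= 3 * sd

    def test_unknown_prevalence_disorder_rejected(self, cutoffs, patterns):
        with pytest.raises(ConfigurationError):
            im.simulate_cohort(
                im.SimulationConfig(n_newborns=10, seed=0, prevalence={"XX": 0.1}),
                cutoffs, patterns,
            )

    def test_default_config_matches_published_conditions(self):
        cfg = im.SimulationConfig(seed=0)
        assert sum(cfg.prevalence.values()) == pytest.approx(30 / 111986)
        assert cfg.loss_rate == pytest.approx(1 - 2275 / 2464)
        # alpha solved so expected positive rate is the published 2.2%
        p = sum(cfg.prevalence.values())
        assert cfg.alpha_for("newborn") == pytest.approx((0.022 - p) / (1 - p))

    def test_high_risk_cohort_generated_with_own_prevalence(self, cutoffs, patterns):
        cfg = im.SimulationConfig(
            n_newborns=0, n_high_risk=300, seed=13, alpha=0.02,
            prevalence_high_risk={"CTLN2": 0.02, "OTC": 0.01},
        )
        cohort = im.simulate_cohort(cfg, cutoffs, patterns)
        assert all(p.cohort == "high_risk" for p in cohort.primary_panels)
        assert set(cohort.truth.values()) <= {"CTLN2", "OTC"}
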