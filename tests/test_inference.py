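"""Estimator tests: polyandry rate and interval, competition-intensity
summaries, the quasi-Poisson fitness regression, drive-parameter recovery
and the selection gradient, on constructed tables and simulated data."""

import numpy as np
import pandas as pd
import pytest

import tdrive as td
from tdrive.drive import WT, WW
from tdrive.inference import (
    FitError,
    competition_intensity,
    estimate_behavioural_polyandry,
    estimate_competitiveness,
    estimate_drive_strength,
    estimate_polyandry,
    female_summaries,
    fit_male_fitness,
    selection_gradient,
)


class TestEstimatePolyandry:
    def test_rate_and_interval_on_constructed_counts(self, litters_factory):
        specs = []
        for i in range(10):
            sires = [(WW, "A"), (WW, "B")] if i < 3 else [(WW, "A"), (WW, "A")]
            specs.append((f"L{i}", f"F{i}", WW, sires))
        specs.append(("Lx", "Fx", WW, [(WW, "A")]))  # singleton excluded
        est = estimate_polyandry(litters_factory(specs))
        assert est.n == 10 and est.k_multisire == 3
        assert est.rate == pytest.approx(0.3)
        assert est.ci_low <= est.rate <= est.ci_high
        assert est.ci_method == "wilson"

    def test_zero_multisire(self, litters_factory):
        est = estimate_polyandry(
            litters_factory([(f"L{i}", f"F{i}", WW, [(WW, "A"), (WW, "A")]) for i in range(10)])
        )
        assert est.rate == 0.0 and est.ci_low == 0.0

    def test_interval_shrinks_with_sample_size(self, litters_factory):
        def width(n):
            specs = [
                (f"L{i}", f"F{i}", WW, [(WW, "A"), (WW, "B" if i % 2 else "A")])
                for i in range(n)
            ]
            e = estimate_polyandry(litters_factory(specs))
            return e.ci_high - e.ci_low

        assert width(400) < width(100) < width(25)

    def test_no_eligible_litters(self, litters_factory):
        with pytest.raises(ValueError):
            estimate_polyandry(litters_factory([("L1", "F1", WW, [(WW, "A")])]))


class TestCompetitionIntensity:
    def test_co_sire_means(self, litters_factory):
        table = litters_factory(
            [
                ("L1", "F1", WW, [(WW, "M1"), (WW, "M1")]),  # M1 alone
                ("L2", "F2", WW, [(WW, "M1"), (WW, "M2"), (WW, "M3")]),  # 3 sires
            ]
        )
        out = competition_intensity(table).set_index("male_id")
        assert out.loc["M1", "mean_competitors"] == pytest.approx(1.0)  # (0 + 2)/2
        assert out.loc["M1", "n_offspring"] == 3 and out.loc["M1", "n_litters"] == 2
        assert out.loc["M2", "mean_competitors"] == pytest.approx(2.0)

    def test_uncontested_male(self, litters_factory):
        table = litters_factory([("L1", "F1", WW, [(WW, "M1")] * 4)])
        out = competition_intensity(table).set_index("male_id")
        assert out.loc["M1", "mean_competitors"] == 0.0
        assert out.loc["M1", "harmonic_competitors"] == 0.0
        assert out.loc["M1", "n_offspring"] == 4 and out.loc["M1", "n_litters"] == 1

    def test_harmonic_summary_with_zeros(self, litters_factory):
        # litters with 1 and 3 sires: harmonic of (1, 3) minus 1
        table = litters_factory(
            [
                ("L1", "F1", WW, [(WW, "M1"), (WW, "M1")]),
                ("L2", "F2", WW, [(WW, "M1"), (WW, "M2"), (WW, "M3")]),
            ]
        )
        out = competition_intensity(table).set_index("male_id")
        assert out.loc["M1", "harmonic_competitors"] == pytest.approx(2 / (1 + 1 / 3) - 1)

    def test_offspring_totals_conserved(self, small_sim):
        out = competition_intensity(small_sim.litters)
        assert out["n_offspring"].sum() == len(small_sim.litters)

    def test_monandry_population_has_no_competitors(self):
        res = td.simulate(td.SimConfig(n_founders=40, n_t_founders=10, n_generations=2, n_adults=80, P=0.0, seed=5))
        out = competition_intensity(res.litters)
        assert (out["mean_competitors"] == 0.0).all()


class TestMaleFitnessModel:
    def test_degenerate_designs_rejected(self):
        base = pd.DataFrame(
            {
                "male_id": [f"M{i}" for i in range(12)],
                "genotype": [WT if i % 2 else WW for i in range(12)],
                "n_offspring": [5] * 12,
                "n_litters": [2] * 12,
                "mean_competitors": [1.0] * 12,
            }
        )
        with pytest.raises(FitError, match="competitors|n_litters"):
            fit_male_fitness(base)
        single = base.assign(genotype=WW)
        with pytest.raises(FitError):
            fit_male_fitness(single)
        with pytest.raises(FitError):
            fit_male_fitness(base.head(5))

    def test_competition_slopes_on_study_data(self, study_sim):
        males = competition_intensity(study_sim.litters, study_sim.pedigree)
        res = fit_male_fitness(males, select=False)
        slope_ww = res.params["competitors"]
        interaction = res.params["genotype_WT:competitors"]
        # success declines with rivals for both genotypes, and faster for
        # drive carriers (share c < 1/2 in contested litters)
        assert slope_ww < 0
        assert slope_ww + interaction < slope_ww
        assert interaction < 0
        assert set(res.deviance_fractions) == {"competition", "genotype", "interaction"}
        assert all(0.0 <= v <= 1.0 for v in res.deviance_fractions.values())

    def test_selection_table_and_summary(self, study_sim):
        males = competition_intensity(study_sim.litters, study_sim.pedigree)
        res = fit_male_fitness(males)
        assert res.selection_table["qAIC"].is_monotonic_increasing
        assert res.dispersion > 0
        text = res.summary()
        assert "qAIC" in text and "dispersion" in text


class TestDriveStrength:
    def test_direct_proportion(self, litters_factory):
        specs = []
        for i in range(50):
            pups = [(WT, f"S{i}"), (WT, f"S{i}")] if i < 45 else [(WW, f"S{i}"), (WT, f"S{i}")]
            specs.append((f"L{i}", f"F{i}", WW, pups))
        ped = pd.DataFrame(
            {"id": [f"S{i}" for i in range(50)], "dam": "", "sire": "", "sex": "M", "genotype": WT, "cohort": 0}
        )
        est = estimate_drive_strength(litters_factory(specs), ped)
        assert est.estimate == pytest.approx((45 * 2 + 5) / 100)
        assert est.n == 100

    def test_recovery_from_simulation(self, study_sim):
        est = estimate_drive_strength(study_sim.litters, study_sim.pedigree)
        assert est.n > 500
        se = np.sqrt(0.9 * 0.1 / est.n)
        assert est.estimate == pytest.approx(0.9, abs=2 * se)

    def test_error_without_eligible_crosses(self, litters_factory):
        table = litters_factory([("L1", "F1", WW, [(WW, "S1"), (WW, "S1")])])
        ped = pd.DataFrame({"id": ["S1"], "dam": "", "sire": "", "sex": "M", "genotype": WW, "cohort": 0})
        with pytest.raises(ValueError):
            estimate_drive_strength(table, ped)


class TestCompetitiveness:
    def test_symmetric_null(self):
        cfg = td.SimConfig(
            n_founders=300, n_t_founders=90, n_generations=3, n_adults=900,
            P=0.7, c=0.5, d=0.9, seed=29,
        )
        res = td.simulate(cfg)
        est = estimate_competitiveness(res.litters, matings=res.matings)
        se = np.sqrt(0.25 / est.n)
        assert est.estimate == pytest.approx(0.5, abs=2 * se)
        assert not est.conditional

    def test_recovery_from_study_simulation(self, study_sim):
        est = estimate_competitiveness(study_sim.litters, matings=study_sim.matings)
        assert est.n > 1000
        se = np.sqrt(0.113 * 0.887 / est.n)
        assert est.estimate == pytest.approx(0.113, abs=2 * se)

    def test_conditional_mode_is_flagged_and_overstates(self, study_sim):
        est = estimate_competitiveness(study_sim.litters, pedigree=study_sim.pedigree)
        assert est.conditional
        # conditioning on both males siring discards all-or-nothing litters,
        # inflating the share
        assert est.estimate > 0.113

    def test_error_without_mixed_litters(self, litters_factory):
        table = litters_factory([("L1", "F1", WW, [(WW, "A"), (WW, "B")])])
        ped = pd.DataFrame({"id": ["A", "B"], "dam": "", "sire": "", "sex": "M", "genotype": WW, "cohort": 0})
        with pytest.raises(ValueError):
            estimate_competitiveness(table, pedigree=ped)


class TestBehaviouralPolyandry:
    def test_known_misclassification_recovered(self, litters_factory):
        # all litters size 3, no carriers: m-bar = 2 * 0.5^3 = 0.25
        specs = []
        for i in range(40):
            sires = [(WW, "A"), (WW, "B"), (WW, "A")] if i < 12 else [(WW, "A")] * 3
            specs.append((f"L{i}", f"F{i}", WW, sires))
        est, corr = estimate_behavioural_polyandry(litters_factory(specs), c=0.113, wt_freq=0.0)
        assert corr.single_sire_prob == pytest.approx(0.25)
        assert corr.behavioural_rate == pytest.approx(0.3 / 0.75)

    def test_per_cohort_frequencies_required_for_all_cohorts(self, small_sim):
        with pytest.raises(ValueError, match="cohort"):
            estimate_behavioural_polyandry(small_sim.litters, c=0.113, wt_freq={0: 0.1})


class TestSelectionGradient:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        poly = rng.uniform(0, 1, 40)
        females = pd.DataFrame(
            {
                "female_id": [f"F{i}" for i in range(40)],
                "genotype": WW,
                "polyandry": poly,
                "n_offspring": 2 + 4 * poly,
            }
        )
        res = selection_gradient(females)
        assert res.gradient > 0
        assert res.se == pytest.approx(0.0, abs=1e-8)

    def test_planted_genotype_specific_slopes(self):
        rng = np.random.default_rng(1)
        n = 200
        geno = np.where(rng.random(n) < 0.5, WT, WW)
        poly = rng.uniform(0, 1, n)
        base = 5 + np.where(geno == WT, 5.0, 0.0) * poly + rng.normal(0, 0.3, n)
        females = pd.DataFrame(
            {"female_id": [f"F{i}" for i in range(n)], "genotype": geno, "polyandry": poly, "n_offspring": base}
        )
        res = selection_gradient(females)
        assert res.contrast is not None
        assert res.contrast / res.contrast_se > 2
        assert res.per_genotype[WT][0] > res.per_genotype[WW][0]

    def test_identical_polyandry_rejected(self):
        females = pd.DataFrame(
            {"female_id": [f"F{i}" for i in range(12)], "genotype": WW, "polyandry": 0.5, "n_offspring": 3}
        )
        with pytest.raises(FitError):
            selection_gradient(females)

    def test_female_summaries_structure(self, litters_factory):
        table = litters_factory(
            [
                ("L1", "F1", WT, [(WW, "A"), (WW, "B")]),
                ("L2", "F1", WT, [(WW, "A"), (WW, "A"), (WW, "A")]),
                ("L3", "F2", WW, [(WW, "A")]),  # singleton: F2 dropped
            ]
        )
        fem = female_summaries(table).set_index("female_id")
        assert list(fem.index) == ["F1"]
        assert fem.loc["F1", "polyandry"] == pytest.approx(0.5)
        assert fem.loc["F1", "n_offspring"] == 5
        assert fem.loc["F1", "mean_litter_size"] == pytest.approx(2.5)
        assert fem.loc["F1", "genotype"] == WT
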