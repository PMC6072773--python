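"""Scenario orchestration, efficacy scoring, dose studies."""
import numpy as np
import pytest

from aaqsp import induction as ind
from aaqsp import network as net
from aaqsp import pbpk, scoring
from aaqsp.synthetic import toy_one_compartment_drug


def profile_from(values_pge2, values_ltb4, times=None):
    times = times if times is not None else np.arange(len(values_pge2), dtype=float)
    conc = np.vstack([values_pge2, values_ltb4])
    return net.MediatorProfile(
        times=times, concentrations=conc, species_names=["PGE2", "wLTB4"]
    )


class TestDesArithmetic:
    def test_treated_equals_control_gives_zero(self):
        c = profile_from([10.0, 10.0], [4.0, 4.0])
        t = profile_from([10.0, 10.0], [4.0, 4.0])
        assert scoring.compute_des(c, t, 1.0) == 0.0

    def test_half_pge2_only_gives_quarter(self):
        """PGE2 10 -> 5 and wLTB4 4 -> 4: DES = (0.5 + 0)/2 = 0.25."""
        c = profile_from([10.0, 10.0], [4.0, 4.0])
        t = profile_from([5.0, 5.0], [4.0, 4.0])
        assert scoring.compute_des(c, t, 1.0) == pytest.approx(0.25)

    def test_complete_suppression_gives_one(self):
        c = profile_from([10.0, 10.0], [4.0, 4.0])
        t = profile_from([0.0, 0.0], [0.0, 0.0])
        assert scoring.compute_des(c, t, 1.0) == pytest.approx(1.0)

    def test_zero_control_mediator_is_an_error(self):
        c = profile_from([0.0, 0.0], [4.0, 4.0])
        t = profile_from([0.0, 0.0], [4.0, 4.0])
        with pytest.raises(ZeroDivisionError):
            scoring.compute_des(c, t, 1.0)

    def test_mismatched_grids_rejected(self):
        c = profile_from([10.0, 10.0], [4.0, 4.0])
        t = profile_from([10.0, 10.0, 10.0], [4.0, 4.0, 4.0])
        with pytest.raises(ValueError):
            scoring.compute_des(c, t, 1.0)


class TestScenarioRegistry:
    def test_eleven_unique_scenarios(self, scenarios):
        assert sorted(scenarios) == list(range(1, 12))

    def test_registry_matches_treatment_table(self, scenarios):
        drugs = {i: sorted(d.name for d in s.drugs) for i, s in scenarios.items()}
        assert drugs[1] == ["celecoxib"]
        assert drugs[2] == ["diclofenac"]
        assert drugs[5] == ["licofelone"]
        assert drugs[6] == ["celecoxib", "zileuton"]
        assert drugs[7] == ["diclofenac", "zileuton"]
        for i in (3, 4, 10, 11):
            assert scenarios[i].rif_pretreatment is not None
        # the clinical DDI comparisons use their own dose levels and
        # pre-treatment regimens
        assert scenarios[10].drugs[0].dose_mg == 100
        assert scenarios[10].rif_pretreatment.dose_mg == 450
        assert scenarios[10].rif_pretreatment.days == 6
        assert scenarios[11].drugs[0].dose_mg == 200
        assert scenarios[11].rif_pretreatment.dose_mg == 600
        assert scenarios[11].rif_pretreatment.days == 5

    def test_every_scenario_drug_has_a_target(self, scenarios):
        targets = scoring.load_targets()
        for s in scenarios.values():
            assert any(d.name in targets for d in s.drugs)


class TestScenarioRuns:
    def test_huge_ki_gives_near_zero_des(self, runner, scenarios):
        res = runner.run_scenario(scenarios[2], ki_override=1e9)
        assert np.max(np.abs(res.des)) < 1e-3

    def test_des_bounded_above_by_one(self, runner, scenarios):
        res = runner.run_scenario(scenarios[6])
        assert np.all(res.des <= 1.0)

    def test_des_early_and_late_read_from_same_trajectory(
        self, runner, scenarios
    ):
        res = runner.run_scenario(scenarios[1])
        assert res.des_early == pytest.approx(
            float(np.interp(30.0, res.times, res.des))
        )
        assert res.des_late == pytest.approx(
            float(np.interp(360.0, res.times, res.des))
        )

    def test_paired_control_is_shared_and_deterministic(self, runner, scenarios):
        r1 = runner.run_scenario(scenarios[1])
        r2 = runner.run_scenario(scenarios[2])
        assert np.array_equal(
            r1.control.concentrations, r2.control.concentrations
        )

    def test_cotreatment_at_least_as_effective_as_components(
        self, runner, scenarios
    ):
        """Celecoxib+zileuton scores at least as high as either single agent
        shortly after dosing (verified numerically on the surrogate)."""
        co = runner.run_scenario(scenarios[6])
        cel = runner.run_scenario(scenarios[1])
        zlt_scenario = scoring.Scenario(
            id=99, name="zileuton alone",
            drugs=[scoring.ScenarioDrug(name="zileuton", dose_mg=600)],
        )
        zlt = runner.run_scenario(zlt_scenario)
        assert co.des_early >= max(cel.des_early, zlt.des_early) - 1e-6
        assert co.des_late >= max(cel.des_late, zlt.des_late) - 1e-6

    def test_rifampicin_pretreatment_reduces_efficacy(self, runner, scenarios):
        plain = runner.run_scenario(scenarios[1])
        ddi = runner.run_scenario(scenarios[3])
        assert ddi.des_late < plain.des_late


class TestDoseStudies:
    def test_final_grid_point_equals_plain_run(self, runner, scenarios):
        rows = runner.dose_escalation(scenarios[2], [0.5, 1.0])
        plain = runner.run_scenario(scenarios[2])
        assert rows[-1]["DES_6h"] == pytest.approx(plain.des_late, abs=1e-12)

    def test_vanishing_dose_gives_vanishing_des(self, runner, scenarios):
        rows = runner.dose_escalation(scenarios[1], [1e-6])
        assert abs(rows[0]["DES_6h"]) < 1e-4

    def test_des_monotone_in_dose_on_surrogate(self, runner, scenarios):
        """Single COX-2 inhibitor: DES at 6 h non-decreasing across the dose
        grid (checked numerically)."""
        rows = runner.dose_escalation(scenarios[1], [0.1, 0.3, 1.0])
        vals = [r["DES_6h"] for r in rows]
        assert vals == sorted(vals)

    def test_unsorted_or_out_of_range_grid_rejected(self, runner, scenarios):
        with pytest.raises(ValueError):
            runner.dose_escalation(scenarios[1], [0.5, 0.1])
        with pytest.raises(ValueError):
            runner.dose_escalation(scenarios[1], [0.0, 1.0])


class TestDoseAdjustment:
    def test_identity_when_induction_disabled(self, scenarios):
        """With CYP induction switched off the DDI scenario coincides with
        the reference and the search returns multiplier 1."""
        runner = scoring.ScenarioRunner(induction_enabled=False)
        out = runner.dose_adjustment_search(scenarios[4], scenarios[2])
        assert out["multiplier"] == 1.0
        assert out["multiplier_rounded"] == 1.0

    def test_doubled_clearance_needs_doubled_dose(self):
        """Toy one-compartment drug, linear PD regime: doubling the
        clearance via a constant activity fold is compensated by ~2x dose.

        Absorption-limited (flip-flop) kinetics, ka << ke, makes the
        concentration at any post-transient time proportional to dose/CL,
        so the closed-form answer is exactly 2; the search must recover it
        by simulation."""
        phys = pbpk.Physiology(
            body_weight=73.0, hematocrit=0.45,
            compartments=[
                pbpk.Compartment(name="venous_plasma", volume=40.0),
                pbpk.Compartment(name="blood_cells", volume=2.0),
                pbpk.Compartment(name="gut_lumen", volume=1.0),
            ],
            enzyme_expression={"CYPX": {"venous_plasma": 1.0}},
        )
        drug = pbpk.DrugSpec(
            name="toydrug", molecular_weight=300.0, fraction_unbound_plasma=1.0,
            absorption=pbpk.Absorption(ka=0.002),
            processes=[pbpk.AdmeProcess(
                kind="metabolism", enzyme_or_transporter="CYPX",
                site="venous_plasma",
                kinetics=pbpk.Kinetics(kcat=8e5, km=1e6), terminal=True,
            )],
        )
        runner = scoring.ScenarioRunner(
            physiology=phys,
            targets={"toydrug": [{"enzyme": "COX-2", "ki": 1.0}]},
        )
        runner._drug_cache["toydrug"] = drug
        ref = scoring.Scenario(
            id=98, name="toy ref",
            drugs=[scoring.ScenarioDrug(name="toydrug", dose_mg=10.0)],
        )
        ddi = scoring.Scenario(
            id=97, name="toy ddi",
            drugs=[scoring.ScenarioDrug(name="toydrug", dose_mg=10.0)],
            rif_pretreatment=scoring.RifPretreatment(),
        )
        grid = np.linspace(0.0, 360.0, 37)
        runner.induction_folds = lambda pre, horizon: ind.ActivityFold(
            times=grid, folds={"CYPX": np.full_like(grid, 2.0)}
        )
        out = runner.dose_adjustment_search(ddi, ref, t_min=180.0)
        assert out["multiplier"] == pytest.approx(2.0, rel=0.10)
        assert out["multiplier_rounded"] == 2.0

    def test_no_solution_reported_when_bracket_fails(self, runner, scenarios):
        """An unreachable reference efficacy yields an explicit no-solution
        report with the achieved DES range."""
        impossible_ref = scoring.Scenario(
            id=96, name="unreachable",
            drugs=[scoring.ScenarioDrug(name="zileuton", dose_mg=600),
                   scoring.ScenarioDrug(name="celecoxib", dose_mg=400)],
        )
        narrow = scoring.Scenario(
            id=95, name="weak",
            drugs=[scoring.ScenarioDrug(name="diclofenac", dose_mg=1.0)],
        )
        with pytest.raises(RuntimeError, match="achieved DES range"):
            runner.dose_adjustment_search(
                narrow, impossible_ref, bracket=(1.0, 1.5), t_min=120.0
            )
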