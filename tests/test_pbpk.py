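"""Whole-body PBPK engine: closed-form oracles, conservation, linearity."""
import numpy as np
import pytest

from aaqsp import pbpk
from aaqsp.synthetic import toy_one_compartment_drug, toy_physiology


def _sim(model, route, mg, span_min, **kw):
    return pbpk.simulate(
        model, [pbpk.DoseEvent(route=route, amount=mg)], span_min, **kw
    )


class TestOneCompartmentClosedForms:
    def test_iv_bolus_matches_monoexponential(self, toy_iv_setup):
        """100 mg iv into V=10 L with k=0.1/h: C0 = 10 mg/L and
        AUCinf = C0/k = 100 mg*h/L."""
        _phys, drug, model = toy_iv_setup
        prof = _sim(model, "intravenous", 100.0, 72 * 60)
        c0_mg_l = prof.total(drug.name, "venous_plasma")[0] * drug.molecular_weight / 1e3
        assert c0_mg_l == pytest.approx(10.0, rel=1e-9)
        m = pbpk.pk_metrics(prof, drug.name)
        assert m.cmax == pytest.approx(10_000.0, rel=1e-9)  # ng/ml
        assert m.auc_inf == pytest.approx(100_000.0, rel=1e-3)  # ng*h/ml
        # dense grid against the analytic solution
        k = 0.1 / 60.0
        expected = 33.3333333333 * np.exp(-k * prof.times)
        got = prof.total(drug.name, "venous_plasma")
        assert np.max(np.abs(got - expected) / expected[0]) < 1e-6

    def test_auc_monoexponential_within_0p1_percent(self, toy_iv_setup):
        _phys, drug, model = toy_iv_setup
        prof = _sim(model, "intravenous", 50.0, 96 * 60)
        m = pbpk.pk_metrics(prof, drug.name)
        c0 = prof.total(drug.name, "venous_plasma")[0] * drug.molecular_weight
        assert m.auc_inf == pytest.approx(c0 / 0.1, rel=1e-3)

    def test_oral_large_ka_approaches_iv_cmax(self):
        """With ka >> k the oral profile converges to the iv bolus."""
        phys = toy_physiology(volume=10.0, with_gut=True)
        ke = 0.1 / 60.0
        iv_model = pbpk.build_model(
            phys, toy_one_compartment_drug(ke_per_min=ke)
        )
        iv = pbpk.pk_metrics(_sim(iv_model, "intravenous", 100.0, 48 * 60), "toydrug")
        oral_model = pbpk.build_model(
            phys, toy_one_compartment_drug(ke_per_min=ke, ka_per_min=50.0)
        )
        oral = pbpk.pk_metrics(_sim(oral_model, "oral", 100.0, 48 * 60), "toydrug")
        assert oral.cmax == pytest.approx(iv.cmax, rel=0.02)
        assert oral.auc_inf == pytest.approx(iv.auc_inf, rel=0.01)

    def test_dose_linearity(self, toy_iv_setup):
        """Purely first-order model: doubling the dose doubles Cmax and AUC
        and leaves Tmax unchanged."""
        _phys, drug, model = toy_iv_setup
        m1 = pbpk.pk_metrics(_sim(model, "intravenous", 50.0, 48 * 60), drug.name)
        m2 = pbpk.pk_metrics(_sim(model, "intravenous", 100.0, 48 * 60), drug.name)
        assert m2.cmax == pytest.approx(2 * m1.cmax, rel=1e-9)
        assert m2.auc_inf == pytest.approx(2 * m1.auc_inf, rel=1e-6)
        assert m2.tmax == m1.tmax


class TestConservationAndStructure:
    def test_mass_conserved_without_elimination(self):
        """Distribution-only model (no processes): dosed moles stay in the
        system exactly."""
        phys = pbpk.packaged_physiology()
        drug = pbpk.DrugSpec(
            name="inert", molecular_weight=300.0, fraction_unbound_plasma=0.5,
            partition_coefficients={"periphery": 2.0},
        )
        model = pbpk.build_model(phys, drug)
        prof = _sim(model, "intravenous", 10.0, 12 * 60)
        assert prof.mass_balance_error() < 1e-9

    @pytest.mark.parametrize(
        "name,dose",
        [("diclofenac", 50.0), ("celecoxib", 100.0), ("zileuton", 600.0),
         ("licofelone", 200.0), ("rifampicin", 600.0)],
    )
    def test_mass_balance_all_packaged_drugs(self, physiology, name, dose):
        model = pbpk.build_model(physiology, pbpk.packaged_drug(name))
        prof = _sim(model, "oral", dose, 6 * 60)
        assert prof.mass_balance_error() < 1e-6

    def test_total_adme_process_count_is_32(self):
        """The five packaged drug models implement 32 ADME processes in
        total (transports, metabolic reactions, clearances)."""
        total = sum(
            pbpk.packaged_drug(n).n_processes() for n in pbpk.packaged_drug_names()
        )
        assert total == 32

    def test_metabolite_chain_bookkeeping(self, physiology):
        """parent -> M1 -> M2: the state covers 3 compounds x all wells and
        cumulative formed M1+M2 equals the parent moles metabolized (flux
        accumulator oracle)."""
        drug = pbpk.DrugSpec(
            name="parent", molecular_weight=300.0, fraction_unbound_plasma=0.5,
            processes=[pbpk.AdmeProcess(
                kind="metabolism", enzyme_or_transporter="CYP3A4", site="liver",
                kinetics=pbpk.Kinetics(kcat=50.0, km=10.0), product="m1",
            )],
            metabolites=[pbpk.DrugSpec(
                name="m1", molecular_weight=316.0, fraction_unbound_plasma=0.5,
                processes=[pbpk.AdmeProcess(
                    kind="metabolism", enzyme_or_transporter="CYP2C9",
                    site="liver", kinetics=pbpk.Kinetics(kcat=20.0, km=10.0),
                    product="m2",
                )],
                metabolites=[pbpk.DrugSpec(
                    name="m2", molecular_weight=330.0,
                    fraction_unbound_plasma=0.5,
                )],
            )],
        )
        model = pbpk.build_model(physiology, drug)
        assert [c.name for c in model.compounds] == ["parent", "m1", "m2"]
        assert model.n_amount_states == 3 * len(model.wells)
        prof = _sim(model, "intravenous", 10.0, 12 * 60)
        n_wells = len(model.wells)
        amounts = prof.amounts[: model.n_amount_states].reshape(3, n_wells, -1)
        m1_plus_m2 = amounts[1].sum(axis=0) + amounts[2].sum(axis=0)
        parent_metabolized = prof.formed(0)  # cumulative flux parent -> m1
        assert np.allclose(m1_plus_m2, parent_metabolized, rtol=1e-6, atol=1e-9)
        # second accumulator: m1 -> m2
        assert np.allclose(amounts[2].sum(axis=0), prof.formed(1),
                           rtol=1e-6, atol=1e-9)
        assert prof.mass_balance_error() < 1e-9

    def test_unbound_never_exceeds_total(self, physiology):
        model = pbpk.build_model(physiology, pbpk.packaged_drug("diclofenac"))
        prof = _sim(model, "oral", 50.0, 6 * 60)
        for well in ("venous_plasma", "blood_cells", "liver_intracellular"):
            assert np.all(
                prof.unbound("diclofenac", well)
                <= prof.total("diclofenac", well) + 1e-15
            )

    def test_unknown_process_site_raises_naming_offender(self, physiology):
        drug = pbpk.DrugSpec(
            name="bad", molecular_weight=300.0, fraction_unbound_plasma=0.5,
            processes=[pbpk.AdmeProcess(
                kind="clearance_renal", site="spleen",
                kinetics=pbpk.Kinetics(rate=0.1),
            )],
        )
        with pytest.raises(pbpk.ConfigurationError, match="spleen"):
            pbpk.build_model(physiology, drug)

    def test_config_validation_rejects_bad_values(self):
        with pytest.raises(ValueError):
            pbpk.Kinetics(km=-1.0)
        with pytest.raises(ValueError):
            pbpk.Physiology(
                body_weight=73, hematocrit=1.2,
                compartments=[pbpk.Compartment(name="venous_plasma", volume=3.0)],
            )
        with pytest.raises(ValueError, match="sum"):
            pbpk.Subcompartments(vascular=0.5, interstitial=0.5, intracellular=0.5)
        with pytest.raises(ValueError, match="product|terminal"):
            pbpk.AdmeProcess(
                kind="metabolism", enzyme_or_transporter="CYP3A4", site="liver",
                kinetics=pbpk.Kinetics(kcat=1.0, km=1.0),
            )

    def test_repeat_dosing_accumulates(self, toy_iv_setup):
        _phys, drug, model = toy_iv_setup
        doses = [pbpk.DoseEvent(
            route="intravenous", amount=10.0, time=0.0,
            repeat=pbpk.DoseRepeat(interval=360.0, count=3),
        )]
        prof = pbpk.simulate(model, doses, 3 * 360.0)
        conc = prof.total(drug.name, "venous_plasma")
        # trough before each re-dose is above the previous pre-dose level
        assert conc[720] > conc[360] > 0
        assert prof.mass_balance_error() < 1e-9


class TestInductionHook:
    def _metabolized_toy(self):
        phys = pbpk.Physiology(
            body_weight=73.0, hematocrit=0.45,
            compartments=[pbpk.Compartment(name="venous_plasma", volume=10.0)],
            enzyme_expression={"CYPX": {"venous_plasma": 1.0}},
        )
        drug = pbpk.DrugSpec(
            name="toydrug", molecular_weight=300.0, fraction_unbound_plasma=1.0,
            processes=[pbpk.AdmeProcess(
                kind="metabolism", enzyme_or_transporter="CYPX",
                site="venous_plasma",
                kinetics=pbpk.Kinetics(kcat=1e4, km=1e6), terminal=True,
            )],
        )
        return pbpk.build_model(phys, drug)

    def test_identity_fold_leaves_profiles_unchanged(self):
        model = self._metabolized_toy()
        base = _sim(model, "intravenous", 100.0, 24 * 60)
        induced = pbpk.apply_cyp_induction(model, {"CYPX": lambda t: 1.0})
        prof = _sim(induced, "intravenous", 100.0, 24 * 60)
        assert np.array_equal(
            base.total("toydrug", "venous_plasma"),
            prof.total("toydrug", "venous_plasma"),
        )

    def test_constant_fold_two_halves_auc(self):
        """Doubling the only clearance enzyme's activity halves AUCinf in a
        linear one-compartment model (closed form AUC = D/CL)."""
        model = self._metabolized_toy()
        m1 = pbpk.pk_metrics(_sim(model, "intravenous", 100.0, 72 * 60), "toydrug")
        induced = pbpk.apply_cyp_induction(model, {"CYPX": lambda t: 2.0})
        m2 = pbpk.pk_metrics(_sim(induced, "intravenous", 100.0, 72 * 60), "toydrug")
        assert m2.auc_inf == pytest.approx(m1.auc_inf / 2.0, rel=1e-3)

    def test_fold_below_one_rejected(self):
        model = self._metabolized_toy()
        with pytest.raises(ValueError, match="below 1"):
            pbpk.apply_cyp_induction(model, {"CYPX": lambda t: 0.5})

    def test_induced_diclofenac_exposure_decreases(self, physiology):
        """Time-varying CYP2C9/3A4 folds can only lower Cmax and AUC (higher
        clearance never raises exposure)."""
        model = pbpk.build_model(physiology, pbpk.packaged_drug("diclofenac"))
        base = pbpk.pk_metrics(_sim(model, "oral", 50.0, 12 * 60), "diclofenac")
        folds = {
            "CYP2C9": lambda t: 1.3 + 0.1 * np.exp(-t / 600.0),
            "CYP3A4": lambda t: 2.0 + 0.5 * np.exp(-t / 600.0),
        }
        induced = pbpk.apply_cyp_induction(model, folds)
        ddi = pbpk.pk_metrics(_sim(induced, "oral", 50.0, 12 * 60), "diclofenac")
        assert ddi.auc_inf < base.auc_inf
        assert ddi.cmax < base.cmax


class TestPkMetricsEdgeCases:
    def test_extrapolation_refused_for_non_decaying_profile(self, physiology):
        """A profile still rising at the end of the window must not be
        extrapolated; AUC to the last point is flagged instead."""
        model = pbpk.build_model(physiology, pbpk.packaged_drug("celecoxib"))
        prof = _sim(model, "oral", 100.0, 90)  # still absorbing at 1.5 h
        m = pbpk.pk_metrics(prof, "celecoxib")
        assert m.extrapolation_refused
        assert m.extrapolated_fraction == 0.0
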