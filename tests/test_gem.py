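"""Tests of network IO, objective construction, sampling and the
fold-change conditioning rules."""

import math

import numpy as np
import pandas as pd
import pytest
from cobra import Metabolite, Model, Reaction
from hypothesis import given, settings, strategies as st

from cofactorkit import gem
from cofactorkit.gem import (
    FoldChangeRecord,
    GEMValidationError,
    InfeasibleModelError,
    ReferenceState,
    apply_fold_change_constraints,
    apply_reversibility_bounds,
    build_fao_objective,
    compare_states,
    load_network,
    sample_fluxes,
    save_network,
    set_atp_maintenance,
    set_objective,
    turnover_flux,
)
from cofactorkit.toynet import supplementation_records, toy_manifest


def _mini_model(*reactions) -> Model:
    """Assemble a model from (id, {met: coef}, lb, ub, subsystem) tuples."""
    m = Model("mini")
    mets = {}
    for rid, stoich, lb, ub, sub in reactions:
        r = Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.subsystem = sub
        coeffs = {}
        for mid, c in stoich.items():
            if mid not in mets:
                mets[mid] = Metabolite(mid, compartment=mid.rsplit("_", 1)[1])
            coeffs[mets[mid]] = c
        r.add_metabolites(coeffs)
        m.add_reactions([r])
    return m


class TestNetworkIO:
    @pytest.mark.parametrize("fmt", ["xml", "json"])
    def test_write_then_load_round_trip(self, toy_model_pristine, tmp_path, fmt):
        path = str(tmp_path / f"toy.{fmt}")
        save_network(toy_model_pristine, path)
        loaded = load_network(path)
        assert len(loaded.reactions) == len(toy_model_pristine.reactions)
        assert len(loaded.metabolites) == len(toy_model_pristine.metabolites)
        for rxn in toy_model_pristine.reactions:
            other = loaded.reactions.get_by_id(rxn.id)
            assert other.bounds == rxn.bounds
            assert {m.id: c for m, c in other.metabolites.items()} == {
                m.id: c for m, c in rxn.metabolites.items()
            }

    def test_unknown_extension_rejected(self, tmp_path):
        with pytest.raises(GEMValidationError):
            load_network(str(tmp_path / "model.txt"))

    def test_reversibility_bounds_policy(self):
        m = _mini_model(
            ("FWD", {"a_c": -1, "b_c": 1}, 0, 5, ""),
            ("REV", {"b_c": -1, "a_c": 1}, -5, 5, ""),
            ("EX_a_c", {"a_c": -1}, -1, 1, ""),
            ("EX_b_c", {"b_c": -1}, -1, 1, ""),
        )
        apply_reversibility_bounds(m)
        assert m.reactions.FWD.bounds == (0.0, math.inf)
        assert m.reactions.REV.bounds == (-math.inf, math.inf)
        assert m.reactions.EX_a_c.bounds == (-1, 1)  # exchanges untouched


class TestATPMaintenance:
    def test_hepatic_resting_expenditure_bound(self, toy_model):
        """15 kcal/liver/h at 51.77 kJ/mol ATP gives ~1,212 mmol/h."""
        lb = set_atp_maintenance(toy_model, 15.0, 51.77)
        assert lb == pytest.approx(1212.4, rel=2e-4)
        assert toy_model.reactions.ATPM.lower_bound == lb

    def test_zero_energy_zero_bound_and_proportionality(self, toy_model):
        assert set_atp_maintenance(toy_model, 0.0) == 0.0
        one = set_atp_maintenance(toy_model, 1.0)
        assert set_atp_maintenance(toy_model, 2.0) == pytest.approx(2 * one)

    def test_missing_reaction_raises(self, toy_model):
        with pytest.raises(GEMValidationError):
            set_atp_maintenance(toy_model, 15.0, reaction_id="NOPE")


class TestFAOObjective:
    def test_weights_count_produced_cofactors_only(self):
        m = _mini_model(
            # mitochondrial beta-oxidation step: 1 FADH2 + 1 NADH -> weight 2
            ("BOX", {"fa_m": -1, "fad_m": -1, "nad_m": -1,
                     "fadh2_m": 1, "nadh_m": 1, "ac_m": 2}, 0, 10,
             "Fatty acid oxidation"),
            # cytosolic lookalike: excluded by compartment
            ("BOXC", {"fa_c": -1, "nad_c": -1, "nadh_c": 1, "ac_c": 2}, 0, 10,
             "Fatty acid oxidation"),
            # consumes NADH: contributes nothing
            ("RED", {"nadh_m": -1, "x_m": -1, "nad_m": 1, "fadh2_m": 1}, 0, 10,
             "Fatty acid oxidation"),
        )
        weights = build_fao_objective(m)
        assert weights == {"BOX": 2.0, "RED": 1.0}

    def test_toy_network_weight_equals_produced_fadh2_plus_nadh(self, toy_model):
        weights = build_fao_objective(toy_model)
        assert weights == {"FAOX": 14.0}  # 7 FADH2 + 7 NADH per palmitate

    def test_empty_selection_raises_with_criteria(self, toy_model):
        with pytest.raises(GEMValidationError, match="subsystem"):
            build_fao_objective(toy_model, fao_subsystem="Nope")


class TestSampling:
    def test_single_free_flux_mean_near_interval_midpoint(self):
        """A one-dimensional flux free on [0, 10] samples around 5."""
        m = _mini_model(
            ("EX_in_c", {"a_c": -1}, -10, 0, ""),
            ("CONV", {"a_c": -1, "b_c": 1}, 0, 10, ""),
            ("EX_out_c", {"b_c": -1}, 0, 10, ""),
        )
        m.objective = "CONV"
        samples = sample_fluxes(m, n=1000, seed=7, objective_fraction=None)
        sd = samples["CONV"].std(ddof=1)
        assert abs(samples["CONV"].mean() - 5.0) < max(3 * sd / np.sqrt(1000), 0.5)

    def test_samples_satisfy_steady_state_and_bounds(self, toy_model):
        weights = build_fao_objective(toy_model)
        set_objective(toy_model, weights)
        samples = sample_fluxes(toy_model, n=200, seed=3)
        s_matrix = pd.DataFrame(
            {r.id: {m.id: c for m, c in r.metabolites.items()}
             for r in toy_model.reactions}
        ).fillna(0.0)
        v = samples[s_matrix.columns].to_numpy()
        imbalance = v @ s_matrix.to_numpy().T
        scale = max(np.abs(v).max(), 1.0)
        assert np.abs(imbalance).max() / scale < 1e-6
        for rxn in toy_model.reactions:
            col = samples[rxn.id]
            assert (col >= rxn.lower_bound - 1e-7).all()
            assert (col <= rxn.upper_bound + 1e-7).all()

    def test_two_pathway_samples_inside_vertex_hull(self):
        """Split pathway: enumerated vertices of {v1,v2>=0, v1<=5, v2<=5,
        v1+v2<=8} bound the sampled means."""
        m = _mini_model(
            ("EX_in_c", {"a_c": -1}, -8, 0, ""),
            ("P1", {"a_c": -1, "b_c": 1}, 0, 5, ""),
            ("P2", {"a_c": -1, "b_c": 1}, 0, 5, ""),
            ("EX_out_c", {"b_c": -1}, 0, 8, ""),
        )
        m.objective = "EX_out_c"
        samples = sample_fluxes(m, n=500, seed=1, objective_fraction=None)
        v1, v2 = samples["P1"], samples["P2"]
        assert ((v1 >= -1e-9) & (v1 <= 5 + 1e-9)).all()
        assert ((v2 >= -1e-9) & (v2 <= 5 + 1e-9)).all()
        assert (v1 + v2 <= 8 + 1e-7).all()

    def test_seed_determinism(self, toy_model):
        weights = build_fao_objective(toy_model)
        set_objective(toy_model, weights)
        a = sample_fluxes(toy_model, n=50, seed=5)
        b = sample_fluxes(toy_model, n=50, seed=5)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_fixed_flux_reaction_mean_is_exact(self):
        # CONV is pinned at 3 while a second, independent branch keeps
        # the flux polytope full-dimensional for the sampler
        m = _mini_model(
            ("EX_in_c", {"a_c": -1}, -10, 0, ""),
            ("CONV", {"a_c": -1, "b_c": 1}, 3, 3, ""),
            ("EX_out_c", {"b_c": -1}, 0, 10, ""),
            ("EX_in2_c", {"x_c": -1}, -10, 0, ""),
            ("CONV2", {"x_c": -1, "y_c": 1}, 0, 10, ""),
            ("CONV3", {"x_c": -1, "y_c": 1}, 0, 10, ""),
            ("EX_out2_c", {"y_c": -1}, 0, 10, ""),
        )
        m.objective = "CONV"
        ref = gem.compute_reference(m, n=100, seed=2, objective_fraction=None)
        assert ref.fluxes["CONV"] == pytest.approx(3.0, abs=1e-6)

    def test_monte_carlo_error_shrinks_with_sample_count(self):
        """Standard error of the mean scales ~1/sqrt(n) (factor-1.5 slack)."""
        m = _mini_model(
            ("EX_in_c", {"a_c": -1}, -10, 0, ""),
            ("CONV", {"a_c": -1, "b_c": 1}, 0, 10, ""),
            ("EX_out_c", {"b_c": -1}, 0, 10, ""),
        )
        m.objective = "CONV"

        def spread(n):
            means = [
                sample_fluxes(m, n=n, seed=s, objective_fraction=None)["CONV"].mean()
                for s in range(8)
            ]
            return np.std(means, ddof=1)

        s_small, s_large = spread(50), spread(200)
        assert s_large < s_small  # 4x samples must not widen the spread
        assert s_large > s_small / (2.0 * 1.5)  # and shrinks ~sqrt(4)=2x

    def test_infeasible_model_raises(self):
        m = _mini_model(
            ("EX_in_c", {"a_c": -1}, 0, 0, ""),
            ("CONV", {"a_c": -1, "b_c": 1}, 1, 10, ""),
            ("EX_out_c", {"b_c": -1}, 0, 10, ""),
        )
        m.objective = "CONV"
        with pytest.raises(InfeasibleModelError):
            sample_fluxes(m, n=10, seed=0)


def _ref(mapping) -> ReferenceState:
    return ReferenceState(fluxes=pd.Series(mapping), n_samples=1, seed=0)


def _uptake_model(lb=-10.0, ub=10.0) -> Model:
    return _mini_model(
        ("EX_a_c", {"a_c": -1}, lb, ub, ""),
        ("SINK", {"a_c": -1}, -1000, 1000, ""),
    )


class TestFoldChangeRules:
    def test_uptake_plasma_decreased_doubles_ceiling(self):
        """Uptaken metabolite whose plasma halves: uptake moves to
        [v, 2v] (consumption increased)."""
        m = _uptake_model()
        cond = apply_fold_change_constraints(
            m, _ref({"EX_a_c": -1.0}), [FoldChangeRecord("a_c", 2.0, "decreased")]
        )
        assert cond.reactions.EX_a_c.bounds == (-2.0, -1.0)

    def test_secretion_plasma_decreased_halves_floor(self):
        """Secreted metabolite whose plasma halves: secretion in [v/2, v]."""
        m = _uptake_model()
        cond = apply_fold_change_constraints(
            m, _ref({"EX_a_c": 1.0}), [FoldChangeRecord("a_c", 2.0, "decreased")]
        )
        assert cond.reactions.EX_a_c.bounds == (0.5, 1.0)

    def test_mirror_cases_plasma_increased(self):
        m = _uptake_model()
        up = apply_fold_change_constraints(
            m, _ref({"EX_a_c": -1.0}), [FoldChangeRecord("a_c", 2.0, "increased")]
        )
        assert up.reactions.EX_a_c.bounds == (-1.0, -0.5)
        sec = apply_fold_change_constraints(
            m, _ref({"EX_a_c": 1.0}), [FoldChangeRecord("a_c", 2.0, "increased")]
        )
        assert sec.reactions.EX_a_c.bounds == (1.0, 2.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        v=st.floats(0.01, 50.0),
        f=st.floats(1.0, 10.0),
        direction=st.sampled_from(["increased", "decreased"]),
        uptake=st.booleans(),
    )
    def test_bounds_always_bracket_reference_magnitude(self, v, f, direction, uptake):
        m = _uptake_model(lb=-100, ub=100)
        ref_flux = -v if uptake else v
        cond = apply_fold_change_constraints(
            m, _ref({"EX_a_c": ref_flux}), [FoldChangeRecord("a_c", f, direction)]
        )
        lb, ub = cond.reactions.EX_a_c.bounds
        lo, hi = sorted((abs(lb), abs(ub)))
        assert lo <= v * (1 + 1e-12) and hi >= v * (1 - 1e-12)
        if f == 1.0:
            assert lo == pytest.approx(v) and hi == pytest.approx(v)

    def test_fold_change_one_is_identity_on_bounds(self):
        m = _uptake_model()
        for direction in ("increased", "decreased"):
            cond = apply_fold_change_constraints(
                m, _ref({"EX_a_c": -0.7}), [FoldChangeRecord("a_c", 1.0, direction)]
            )
            assert cond.reactions.EX_a_c.bounds == (-0.7, -0.7)

    def test_zero_reference_flux_degenerates_with_warning(self):
        m = _uptake_model()
        with pytest.warns(UserWarning, match="degenerate"):
            cond = apply_fold_change_constraints(
                m, _ref({"EX_a_c": 0.0}), [FoldChangeRecord("a_c", 2.0, "decreased")],
                epsilon=1e-3, default_exchange_bound=1000.0,
            )
        lb, ub = cond.reactions.EX_a_c.bounds
        assert (lb, ub) == (-1.0, 0.0)  # uptake direction, magnitude <= eps*default

    def test_record_without_exchange_raises(self):
        m = _mini_model(
            ("T", {"a_c": -1, "b_c": 1}, -10, 10, ""),
            ("EX_b_c", {"b_c": -1}, -10, 10, ""),
        )
        with pytest.raises(GEMValidationError):
            apply_fold_change_constraints(
                m, _ref({"T": 1.0}), [FoldChangeRecord("a_c", 2.0, "decreased")]
            )

    def test_invalid_record_values_rejected(self):
        with pytest.raises(GEMValidationError):
            FoldChangeRecord("a_c", 0.5, "decreased")
        with pytest.raises(GEMValidationError):
            FoldChangeRecord("a_c", 2.0, "sideways")

    def test_infeasible_record_combination_reported(self):
        m = _mini_model(
            ("EX_a_c", {"a_c": -1}, -10, 10, ""),
            ("EX_b_c", {"b_c": -1}, 0, 0.1, ""),
            ("CONV", {"a_c": -1, "b_c": 1}, 0, 10, ""),
        )
        # force uptake of a to [5, 10] while b secretion stays capped at 0.1
        with pytest.raises(InfeasibleModelError):
            apply_fold_change_constraints(
                m, _ref({"EX_a_c": -5.0}), [FoldChangeRecord("a_c", 2.0, "decreased")]
            )


class TestTurnover:
    def test_single_compartment_production_equals_turnover(self):
        m = _mini_model(
            ("EX_a_c", {"a_c": -1}, -10, 10, ""),
            ("MAKE", {"x_c": -1, "a_c": 1}, 0, 10, ""),
            ("EX_x_c", {"x_c": -1}, -10, 10, ""),
        )
        fluxes = pd.Series({"EX_a_c": 2.0, "MAKE": 2.0, "EX_x_c": -2.0})
        assert turnover_flux(fluxes, m, "a") == pytest.approx(2.0)

    def test_two_compartments_add(self):
        m = _mini_model(
            ("EX_a_c", {"a_c": -1}, -10, 10, ""),
            ("Tcm", {"a_c": -1, "a_m": 1}, -10, 10, ""),
            ("SINKm", {"a_m": -1}, 0, 10, ""),
        )
        fluxes = pd.Series({"EX_a_c": -2.0, "Tcm": 2.0, "SINKm": 2.0})
        assert turnover_flux(fluxes, m, "a") == pytest.approx(4.0)
        assert turnover_flux(fluxes, m, "a", halved=False) == pytest.approx(8.0)

    def test_toy_network_matches_manual_enumeration(self, toy_model_pristine):
        rng = np.random.default_rng(0)
        fluxes = pd.Series(
            {r.id: rng.uniform(-1, 1) for r in toy_model_pristine.reactions}
        )
        expected = 0.0
        for mid in ("carn_e", "carn_c", "carn_m"):
            met = toy_model_pristine.metabolites.get_by_id(mid)
            expected += 0.5 * sum(
                abs(r.metabolites[met] * fluxes[r.id]) for r in met.reactions
            )
        assert turnover_flux(fluxes, toy_model_pristine, "carn") == pytest.approx(
            expected
        )

    def test_unknown_metabolite_raises(self, toy_model_pristine):
        with pytest.raises(GEMValidationError):
            turnover_flux(pd.Series(dtype=float), toy_model_pristine, "unobtainium")


class TestCompareStates:
    def test_identical_states_all_ratios_one(self):
        ref = _ref({"A": 1.0, "B": 2.0})
        report = compare_states(ref, ref, {"p1": ["A"], "p2": ["B"]})
        assert (report["ratio"] == 1.0).all()
        assert (report["direction"] == "unchanged").all()

    def test_pathway_aggregate_is_member_sum(self):
        ref = _ref({"A": 1.0, "B": 2.0})
        per = _ref({"A": 2.0, "B": 4.0})
        report = compare_states(ref, per, {"both": ["A", "B"]})
        assert report.loc[0, "reference_flux"] == 3.0
        assert report.loc[0, "personalized_flux"] == 6.0
        assert report.loc[0, "direction"] == "increased"

    def test_report_covers_study_pathways(self, toy_reference):
        model, reference = toy_reference
        report = compare_states(reference, reference, toy_manifest()["pathways"])
        assert set(report["pathway"]) == {
            "fatty_acid_oxidation", "glutathione_synthesis", "bcaa_oxidation",
            "glycolysis", "lipoprotein_secretion",
        }
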