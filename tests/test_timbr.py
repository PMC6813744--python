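import numpy as np
import pandas as pd
import pytest

from toxpipe import timbr
from toxpipe.model_io import parse_gpr
from toxpipe.synthetic_data import generate_toy_model
from toxpipe.timbr import TimbrError


class TestGPREvaluation:
    @pytest.mark.parametrize("rule,fc,expected", [
        ("g1 and g2", {"g1": 1.2, "g2": -0.4}, -0.4),
        ("g1 or g2", {"g1": 1.2, "g2": -0.4}, 1.2),
        ("g1 and (g2 or g3)", {"g2": 0.5}, 0.0),
        ("g1", {"g1": -2.0}, -2.0),
        ("g1 or (g2 and g3)", {"g2": 3.0, "g3": 1.0}, 1.0),
    ])
    def test_signed_min_max_semantics(self, rule, fc, expected):
        assert timbr.evaluate_gpr(parse_gpr(rule), fc) == pytest.approx(expected)

    def test_empty_gpr_is_zero(self):
        assert timbr.evaluate_gpr(None, {"g1": 5.0}) == 0.0

    def test_reaction_mapping_covers_all_reactions(self, chain_model):
        delta = timbr.reaction_log2fc(chain_model, {"g1": 1.5})
        assert delta == {"EX_A": 0.0, "R_AB": 1.5, "EX_B": 0.0}


class TestWeights:
    def test_zero_delta_gives_baseline(self):
        w = timbr.compute_weights({"r1": 0.0})
        assert w.w_control[0] == w.w_treatment[0] == 1.0

    def test_plus_two_delta_scale_half(self):
        w = timbr.compute_weights({"r1": 2.0}, scale=0.5)
        assert w.w_treatment[0] == pytest.approx(0.5)
        assert w.w_control[0] == pytest.approx(2.0)

    def test_product_invariant(self):
        rng = np.random.default_rng(0)
        delta = {f"r{i}": float(d) for i, d in enumerate(rng.normal(size=20))}
        w = timbr.compute_weights(delta, scale=0.7, baseline=1.0)
        assert np.allclose(w.w_control * w.w_treatment, 1.0)
        assert (w.w_control > 0).all() and (w.w_treatment > 0).all()

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            timbr.compute_weights({"r": 0.0}, scale=0.0)


class TestMaxProduction:
    def test_chain_vmax_is_uptake_bound(self, chain_model):
        assert timbr.max_production(chain_model, "B") == pytest.approx(10.0)

    def test_blocked_metabolite_vmax_zero(self, chain_model):
        blocked = chain_model
        blocked.reaction("R_AB").ub = 0.0  # sever the only path
        assert timbr.max_production(blocked, "B") == pytest.approx(0.0)

    def test_vmax_ignores_weights(self, chain_model):
        # weights are not an argument: recompute after changing nothing else
        a = timbr.max_production(chain_model, "B")
        b = timbr.max_production(chain_model, "B")
        assert a == b

    def test_cobra_oracle_agreement(self):
        """Independent FBA (cobra) reproduces v_max on a generated model."""
        cobra = pytest.importorskip("cobra")
        model = generate_toy_model(5, 3, [f"g{i}" for i in range(12)], seed=1)
        cm = cobra.Model("toy")
        mets = {m.id: cobra.Metabolite(m.id, compartment="c")
                for m in model.metabolites}
        for r in model.reactions:
            rxn = cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
            cm.add_reactions([rxn])
            rxn.add_metabolites({mets[k]: v for k, v in r.stoich.items()})
        for m in model.metabolites:
            if m.exchangeable:
                ex = model.exchange_for(m.id)
                cm.objective = ex
                sol = cm.optimize(objective_sense="maximize")
                assert timbr.max_production(model, m.id) == pytest.approx(
                    sol.objective_value, abs=1e-6)


class TestNetworkDemand:
    def test_chain_demand_hand_lp(self, chain_model):
        """Three reactions each carry flux 10 at unit weights: X = 30."""
        d = timbr.network_demand(chain_model, np.ones(3), "B", opt_fraction=1.0)
        assert d.X == pytest.approx(30.0)
        assert d.v_max == pytest.approx(10.0)

    def test_opt_fraction_scales_requirement(self, chain_model):
        d = timbr.network_demand(chain_model, np.ones(3), "B", opt_fraction=0.5)
        assert d.X == pytest.approx(15.0)
        assert d.v_opt == pytest.approx(5.0)

    def test_feasibility_of_returned_flux(self, chain_model):
        d = timbr.network_demand(chain_model, np.ones(3), "B", opt_fraction=0.9)
        S = chain_model.stoichiometric_matrix()
        lb, ub = chain_model.bounds()
        assert np.allclose(S @ d.flux, 0, atol=1e-8)
        assert (d.flux >= lb - 1e-8).all() and (d.flux <= ub + 1e-8).all()
        j = [r.id for r in chain_model.reactions].index("EX_B")
        assert d.flux[j] >= d.v_opt - 1e-8

    def test_parallel_paths_route_through_cheap_reaction(self, parallel_model):
        # reactions: EX_A, R1 (w=1), R2 (w=4), EX_B
        w = np.array([1.0, 1.0, 4.0, 1.0])
        d = timbr.network_demand(parallel_model, w, "B", opt_fraction=1.0)
        idx = {r.id: i for i, r in enumerate(parallel_model.reactions)}
        assert d.flux[idx["R1"]] == pytest.approx(10.0)
        assert d.flux[idx["R2"]] == pytest.approx(0.0)
        # vertex enumeration of the 2-path toy: all-R1 costs 30, all-R2 costs 60
        assert d.X == pytest.approx(30.0)

    def test_demand_nondecreasing_in_any_single_weight(self, parallel_model):
        w = np.ones(4)
        base = timbr.network_demand(parallel_model, w, "B", opt_fraction=1.0).X
        for i in range(4):
            w2 = w.copy()
            w2[i] *= 3.0
            bumped = timbr.network_demand(parallel_model, w2, "B",
                                          opt_fraction=1.0).X
            assert bumped >= base - 1e-9

    def test_infeasible_requirement_names_metabolite(self, chain_model):
        chain_model.reaction("R_AB").ub = 1.0  # cannot reach 0.9 * vmax...
        # vmax recomputes to 1.0, so force a stale larger vmax explicitly
        with pytest.raises(TimbrError, match="B"):
            timbr.network_demand(chain_model, np.ones(3), "B",
                                 opt_fraction=1.0, v_max=10.0)

    def test_enumeration_oracle_small_model(self):
        """Demand matches brute-force enumeration over a flux grid on a
        3-reaction chain where the optimum is an LP vertex."""
        from toxpipe.model_io import MetabolicModel, Metabolite, Reaction

        model = MetabolicModel(
            metabolites=[Metabolite("A", "A", False),
                         Metabolite("B", "B", True)],
            reactions=[
                Reaction("EX_A", "up", -10.0, 0.0, "", {"A": -1.0}),
                Reaction("R", "conv", 0.0, 1000.0, "", {"A": -1.0, "B": 1.0}),
                Reaction("EX_B", "out", 0.0, 1000.0, "", {"B": -1.0}),
            ])
        w = np.array([2.0, 1.0, 3.0])
        d = timbr.network_demand(model, w, "B", opt_fraction=1.0)
        # chain forces |v| = (t, t, t) with t >= v_opt = 10; cost = 6t minimized at t=10
        assert d.X == pytest.approx(60.0)


class TestScores:
    def test_production_score_symmetry_and_arithmetic(self):
        assert timbr.production_score(20.0, 20.0) == 0.0
        assert timbr.production_score(60.0, 20.0) == pytest.approx(0.5)
        assert timbr.production_score(20.0, 60.0) == pytest.approx(-0.5)

    def test_zero_total_demand_scores_zero(self):
        assert timbr.production_score(0.0, 0.0) == 0.0

    def test_two_point_z(self):
        out = timbr.z_scores_and_call({"m1": 0.5, "m2": -0.5})
        assert dict(zip(out.metabolite, out.x_s)) == {"m1": 1.0, "m2": -1.0}
        assert dict(zip(out.metabolite, out.call)) == {
            "m1": "increased", "m2": "decreased"}

    def test_degenerate_all_equal_unchanged(self):
        out = timbr.z_scores_and_call({"m1": 0.3, "m2": 0.3, "m3": 0.3})
        assert (out.call == "unchanged").all()

    def test_z_exactly_at_cutoff_is_unchanged(self):
        # construct raw scores with one z exactly 0.1
        out = timbr.z_scores_and_call({"m1": 0.5, "m2": -0.5}, cutoff=1.0)
        assert (out.call == "unchanged").all()

    def test_population_z_moments(self):
        rng = np.random.default_rng(1)
        raw = {f"m{i}": float(v) for i, v in enumerate(rng.normal(size=30))}
        out = timbr.z_scores_and_call(raw)
        z = out.x_s.to_numpy()
        assert abs(z.mean()) < 1e-9
        assert abs((z ** 2).sum() - len(z)) < 1e-9


class TestConditionScores:
    def test_weight_null_identity(self):
        model = generate_toy_model(5, 4, [f"g{i}" for i in range(15)], seed=2)
        out = timbr.condition_scores(model, {})
        assert np.allclose(out.x_raw, 0.0)
        assert (out.call == "unchanged").all()
        assert np.allclose(out.x_control, out.x_treatment)

    def test_directional_sanity_planted_upregulation(self, chain_model):
        """Up-regulating the sole path's gene lowers treatment demand."""
        from toxpipe.model_io import MetabolicModel, Metabolite, Reaction

        # two products so the z-transform has >= 2 metabolites
        model = MetabolicModel(
            metabolites=[Metabolite("A", "A", False),
                         Metabolite("B", "B", True),
                         Metabolite("C", "C", True)],
            reactions=[
                Reaction("EX_A", "up", -10.0, 0.0, "", {"A": -1.0}),
                Reaction("R_AB", "a2b", 0.0, 1000.0, "gB",
                         {"A": -1.0, "B": 1.0}),
                Reaction("R_AC", "a2c", 0.0, 1000.0, "gC",
                         {"A": -1.0, "C": 1.0}),
                Reaction("EX_B", "outB", 0.0, 1000.0, "", {"B": -1.0}),
                Reaction("EX_C", "outC", 0.0, 1000.0, "", {"C": -1.0}),
            ])
        out = timbr.condition_scores(model, {"gB": 2.0})
        row = out[out.metabolite == "B"].iloc[0]
        assert row.x_treatment < row.x_control
        assert row.x_raw > 0
        assert row.call == "increased"

    def test_bounds_profile_applied(self, chain_model):
        timbr.apply_bounds_profile(chain_model, {"EX_A": (-5.0, 0.0)})
        assert timbr.max_production(chain_model, "B") == pytest.approx(5.0)

    def test_bounds_profile_rejects_internal_reaction(self, chain_model):
        with pytest.raises(TimbrError, match="non-exchange"):
            timbr.apply_bounds_profile(chain_model, {"R_AB": (0.0, 1.0)})
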