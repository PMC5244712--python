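"""FBA/FVA/calibration/essentiality against independent small-LP oracles."""

import cobra
import numpy as np
import pytest

from trichodfba import fba
from trichodfba.constraints import apply_celltype
from trichodfba.fba import CalibrationError, calibrate_maintenance, essentiality

from lp_oracle import brute_force_lp, cobra_lp_arrays


def _model_from_spec(reactions, objective):
    """reactions: list of (id, {met: coeff}, lb, ub)."""
    m = cobra.Model("fixture")
    mets = {}
    for _, stoich, _, _ in reactions:
        for mid in stoich:
            mets.setdefault(mid, cobra.Metabolite(mid, compartment="c"))
    m.add_metabolites(list(mets.values()))
    for rid, stoich, lb, ub in reactions:
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.add_metabolites({mets[k]: v for k, v in stoich.items()})
        m.add_reactions([r])
    m.objective = objective
    return m


# three <= 10-reaction fixtures with nontrivial optima
FIXTURES = {
    "branched": (
        [
            ("EX_A", {"A": -1}, -10, 0),
            ("A2B", {"A": -1, "B": 1}, 0, 1000),
            ("A2C", {"A": -1, "C": 2}, 0, 3),
            ("B_OUT", {"B": -1}, 0, 4),
            ("C_OUT", {"C": -1}, 0, 1000),
        ],
        "C_OUT",
    ),
    "coupled": (
        [
            ("EX_S", {"S": -1}, -5, 0),
            ("EX_E", {"E": -1}, -2, 0),
            ("CONV", {"S": -1, "E": -1, "P": 1}, 0, 1000),
            ("ALT", {"S": -2, "P": 1}, 0, 1),
            ("P_OUT", {"P": -1}, 0, 1000),
        ],
        "P_OUT",
    ),
    "reversible": (
        [
            ("EX_A", {"A": -1}, -4, 4),
            ("AB", {"A": -1, "B": 1}, -1000, 1000),
            ("EX_B", {"B": -1}, -1, 3),
        ],
        "EX_B",
    ),
}


class TestSolveFBAAgainstVertexEnumeration:
    @pytest.mark.parametrize("name", sorted(FIXTURES))
    def test_optimum_matches_brute_force(self, name):
        reactions, objective = FIXTURES[name]
        model = _model_from_spec(reactions, objective)
        sol = fba.solve_fba(model)
        c, S, lb, ub = cobra_lp_arrays(model)
        expected, _ = brute_force_lp(c, S, lb, ub)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(expected, abs=1e-6)

    def test_no_energy_means_zero_growth(self, toy_bundle):
        model, _, pa = toy_bundle
        sub = apply_celltype(model, pa)
        sub.reactions.EX_photon.bounds = (0.0, 0.0)
        sub.reactions.EN_ATP.lower_bound = 0.0
        # without photons neither carbon fixation nor export is possible
        sub.reactions.EX_co2.bounds = (-0.927, 0.0)
        sol = fba.solve_fba(sub)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_status_is_propagated(self):
        model = _model_from_spec(
            [("EX_A", {"A": -1}, 0, 0), ("SINK", {"A": -1}, 2, 5)], "SINK"
        )
        sol = fba.solve_fba(model)
        assert sol.status == "infeasible"
        assert sol.objective_value is None

    def test_steady_state_residual(self, toy_bundle):
        model, _, pa = toy_bundle
        sub = apply_celltype(model, pa)
        sol = fba.solve_fba(sub)
        assert sol.steady_state_residual(sub) <= 1e-9


class TestFVA:
    def test_fixed_bound_reaction_has_zero_width(self, toy_bundle):
        model, dz, _ = toy_bundle
        sub = apply_celltype(model, dz)
        fva = fba.run_fva(sub, reactions=["NIT"])
        assert fva.loc["NIT", "maximum"] - fva.loc["NIT", "minimum"] == pytest.approx(
            0.0, abs=1e-9
        )

    def test_envelope_property(self, toy_bundle):
        # pinning any reaction at its FVA extreme preserves the optimum
        model, _, pa = toy_bundle
        sub = apply_celltype(model, pa)
        opt = fba.solve_fba(sub).objective_value
        fva = fba.run_fva(sub, reactions=["PSI", "RESP"], fraction_of_optimum=1.0)
        for rxn_id in ("PSI", "RESP"):
            for extreme in ("minimum", "maximum"):
                with sub as ctx:
                    val = fva.loc[rxn_id, extreme]
                    ctx.reactions.get_by_id(rxn_id).bounds = (val, val)
                    pinned = fba.solve_fba(ctx).objective_value
                assert pinned == pytest.approx(opt, rel=1e-5, abs=1e-8)

    def test_photoautotroph_carbon_fixation_excludes_zero(self, toy_bundle):
        model, _, pa = toy_bundle
        sub = apply_celltype(model, pa)
        fva = fba.run_fva(sub, reactions=["CBB"])
        assert fva.loc["CBB", "minimum"] > 0.5

    def test_diazotroph_central_carbon_admits_zero_except_fixation(
        self, toy_bundle
    ):
        model, dz, _ = toy_bundle
        sub = apply_celltype(model, dz)
        fva = fba.run_fva(sub, reactions=["RESP", "OPP", "GLYCSYN", "NIT"])
        for rxn_id in ("RESP", "OPP", "GLYCSYN"):
            assert fva.loc[rxn_id, "minimum"] <= 1e-9
        assert fva.loc["NIT", "minimum"] > 0.1


class TestCalibration:
    def test_linear_tradeoff_has_analytic_intercept(self):
        # growth = 10 - maintenance: bisection must land on the line
        model = _model_from_spec(
            [
                ("EX_S", {"S": -1}, -10, 0),
                ("GROW", {"S": -1}, 0, 1000),
                ("EN_ATP", {"S": -1}, 0, 1000),
            ],
            "GROW",
        )
        m = calibrate_maintenance(model, target_growth=4.0, bracket=(0.0, 10.0))
        assert m == pytest.approx(6.0, abs=1e-5)

    def test_toy_round_trip(self, toy_bundle):
        model, _, pa = toy_bundle
        sub = apply_celltype(model, pa)
        sub.reactions.EN_ATP.lower_bound = 0.0
        m = calibrate_maintenance(sub, target_growth=0.0146)
        sub.reactions.EN_ATP.lower_bound = m
        sol = fba.solve_fba(sub)
        assert sol.objective_value == pytest.approx(0.0146, abs=1e-6)

    def test_unreachable_target_reports_range(self, toy_bundle):
        model, _, pa = toy_bundle
        sub = apply_celltype(model, pa)
        with pytest.raises(CalibrationError, match="achievable range"):
            calibrate_maintenance(sub, target_growth=5.0)


class TestEssentiality:
    def test_gene_mode_on_photoautotroph(self, toy_bundle):
        model, _, pa = toy_bundle
        sub = apply_celltype(model, pa)
        result = essentiality(sub, mode="gene")
        wild_type = result.attrs["wild_type_growth"]
        # complex member of carbon fixation is lethal for a carbon fixer
        assert result.loc["tg_rbcL", "classification"] == "essential"
        # glycogen degradation is idle in the photoautotroph
        assert result.loc["tg_glgP", "classification"] == "neutral"
        # isozymes: knocking out one respiratory gene keeps the other
        assert result.loc["tg_cox1", "growth"] == pytest.approx(
            wild_type, rel=1e-6
        )
        assert (result["growth"] <= wild_type + 1e-9).all()

    def test_reaction_mode_nitrogenase_is_lethal_for_diazotroph(
        self, toy_bundle
    ):
        model, dz, _ = toy_bundle
        sub = apply_celltype(model, dz)
        result = essentiality(sub, mode="reaction")
        assert result.loc["NIT", "growth"] == pytest.approx(0.0, abs=1e-9)
        assert result.loc["NIT", "classification"] == "essential"

    def test_fva_nonzero_implies_not_neutral(self, toy_bundle):
        # a reaction whose interval at the optimum excludes zero cannot be
        # neutral to remove
        model, _, pa = toy_bundle
        sub = apply_celltype(model, pa)
        fva = fba.run_fva(sub, reactions=["CBB"], fraction_of_optimum=1.0)
        assert fva.loc["CBB", "minimum"] > 0
        result = essentiality(sub, mode="reaction")
        assert result.loc["CBB", "classification"] in (
            "essential", "growth-reducing",
        )

    def test_mode_validation(self, toy_model):
        with pytest.raises(ValueError, match="mode"):
            essentiality(toy_model, mode="plasmid")
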