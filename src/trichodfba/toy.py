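"""Reduced two-phenotype network with a known-ground-truth equilibrium.

The toy model compresses the division of labour in a *Trichodesmium*
trichome into <= 20 elementally balanced reactions:

* photon capture split into PSII (linear electron flow: water photolysis to
  reducing equivalents + O2) and PSI (lumped cyclic photophosphorylation:
  photon-driven ATP synthesis),
* RuBisCO-like carbon fixation (CO2 + 2 NADPH + ATP -> fixed carbon CH2O),
* a 6-carbon glycogen currency (polymerisation / free degradation),
* respiration and an oxidative-PP-like NADPH regeneration from fixed carbon,
* nitrogenase (N2 + 16 ATP + reductant carbon -> 2 ammonium),
* a lumped biomass reaction with the organism's carbon mass share and
  growth-associated maintenance, plus a maintenance ATP hydrolysis.

Costs follow the full reconstruction's energetics: one glycogen costs
``atp_per_glycogen`` (~64) ATP to make, one ammonium costs ``atp_per_nh4``
(8; 16 per N2) at the nitrogenase.  Every reaction balances C/H/O/N (the
nicotinamide pool uses an abstract element R), so the structural validators
pass cleanly, and the population equilibrium has a brute-force oracle:
:func:`analytic_equilibrium` scans the diazotroph fraction and solves the
coupled two-cell-type LP at stationarity with scipy's HiGHS solver —
independently of the cobra/GLPK path used by FBA and the dFBA simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import cobra
from scipy.optimize import linprog
from scipy.sparse import block_diag, csr_matrix

from . import constraints as ct
from .core import set_reaction_category, stoichiometric_matrix

__all__ = [
    "ToyNetworkParams",
    "make_toy_model",
    "toy_constraint_sets",
    "analytic_equilibrium",
    "EquilibriumSolution",
]


@dataclass
class ToyNetworkParams:
    """Tunable stoichiometry of the reduced network.

    Units: ATP/NADPH/carbon in mmol (g DW)-1 h-1 flux space; biomass carbon
    and nitrogen in mmol per g DW (45.8 % carbon by mass and a Redfield-like
    C:N of ~6.3 reproduce the measured elemental make-up).
    """

    atp_per_glycogen: float = 64.0      # total ATP to build one glycogen unit
    glycogen_poly_atp: float = 4.0      # of which: polymerisation of 6 CH2O
    atp_per_nh4: float = 8.0            # nitrogenase ATP per NH4+ (16 per N2)
    biomass_c: float = 38.1             # mmol C per g DW  (45.8 % C by mass)
    biomass_n: float = 6.05             # mmol N per g DW  (C:N ~ 6.3)
    gam: float = 544.0                  # growth-associated ATP, mmol per g DW
    atp_per_photon: float = 1.0         # PSI ATP yield per photon
    nadph_per_photon: float = 1.0       # PSII NADPH yield per photon
    resp_atp_per_c: float = 5.0         # respiratory ATP per fixed carbon
    photon_budget: float = 80.0         # uE, shared by PSI + PSII
    carbon_uptake_cap: float = 0.927    # mmol C (g DW)-1 h-1, both phenotypes
    maintenance: dict[str, float] = field(
        default_factory=lambda: {
            "diazotroph": ct.MAINTENANCE_DZ,
            "photoautotroph": ct.MAINTENANCE_PA,
        }
    )
    nitrogenase_flux: float = ct.NITROGENASE_FLUX_DEFAULT

    def __post_init__(self) -> None:
        positive = {
            "atp_per_glycogen": self.atp_per_glycogen,
            "atp_per_nh4": self.atp_per_nh4,
            "biomass_c": self.biomass_c,
            "biomass_n": self.biomass_n,
            "atp_per_photon": self.atp_per_photon,
            "nadph_per_photon": self.nadph_per_photon,
            "resp_atp_per_c": self.resp_atp_per_c,
            "photon_budget": self.photon_budget,
            "carbon_uptake_cap": self.carbon_uptake_cap,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.glycogen_poly_atp < 0 or self.glycogen_poly_atp >= self.atp_per_glycogen:
            raise ValueError("glycogen_poly_atp must lie in [0, atp_per_glycogen)")

    @property
    def fix_atp_per_c(self) -> float:
        """ATP per fixed carbon implied by the glycogen cost split."""
        return (self.atp_per_glycogen - self.glycogen_poly_atp) / 6.0


def _met(mid, name, formula, compartment="c", charge=0):
    return cobra.Metabolite(mid, name=name, formula=formula,
                            compartment=compartment, charge=charge)


def make_toy_model(
    params: ToyNetworkParams | None = None,
) -> tuple[cobra.Model, ct.CellTypeConstraintSet, ct.CellTypeConstraintSet]:
    """Build the toy model and its two cell-type constraint sets."""
    p = params or ToyNetworkParams()
    model = cobra.Model("toy_trichome")

    # biomass elemental formula follows from its precursors so the reaction
    # balances exactly: biomass_c CH2O + biomass_n NH3
    bm_h = 2 * p.biomass_c + 3 * p.biomass_n
    mets = {
        "photon_c": _met("photon_c", "photon", "R0"),        # massless
        "atp_c": _met("atp_c", "ATP", "C10H16N5O13P3"),
        "adp_c": _met("adp_c", "ADP", "C10H15N5O10P2"),
        "pi_c": _met("pi_c", "phosphate", "H3O4P"),
        "nadp_c": _met("nadp_c", "NADP", "R"),
        "nadph_c": _met("nadph_c", "NADPH", "RH2"),
        "h2o_c": _met("h2o_c", "water", "H2O"),
        "co2_c": _met("co2_c", "carbon dioxide", "CO2"),
        "o2_c": _met("o2_c", "dioxygen", "O2"),
        "fixedc_c": _met("fixedc_c", "fixed carbon (CH2O unit)", "CH2O"),
        "glyc_c": _met("glyc_c", "glycogen (glucose unit)", "C6H12O6"),
        "glyc_e": _met("glyc_e", "glycogen (medium)", "C6H12O6", "e"),
        "nh4_c": _met("nh4_c", "ammonium", "H3N"),
        "nh4_e": _met("nh4_e", "ammonium (medium)", "H3N", "e"),
        "n2_c": _met("n2_c", "dinitrogen", "N2"),
        "biomass_c": _met(
            "biomass_c", "biomass",
            f"C{p.biomass_c:g}H{bm_h:g}N{p.biomass_n:g}O{p.biomass_c:g}",
        ),
    }
    model.add_metabolites(list(mets.values()))

    def rxn(rid, name, stoich, lb, ub, category, gpr="", confidence=2):
        r = cobra.Reaction(rid, name=name, lower_bound=lb, upper_bound=ub)
        r.add_metabolites({mets[m]: c for m, c in stoich.items()})
        set_reaction_category(r, category, confidence)
        if gpr:
            r.gene_reaction_rule = gpr
        return r

    y = p.atp_per_photon
    z = p.nadph_per_photon
    a = p.fix_atp_per_c
    k = p.resp_atp_per_c
    reactions = [
        # --- energy capture -------------------------------------------------
        rxn("PSII", "photosystem II (linear electron flow)",
            {"photon_c": -1, "h2o_c": -z, "nadp_c": -z,
             "nadph_c": z, "o2_c": 0.5 * z},
            0, 1000, "metabolic", gpr="tg_psbA"),
        rxn("PSI", "photosystem I (cyclic photophosphorylation)",
            {"photon_c": -1, "adp_c": -y, "pi_c": -y,
             "atp_c": y, "h2o_c": y},
            0, 1000, "metabolic", gpr="tg_psaA"),
        # --- carbon ---------------------------------------------------------
        rxn("CBB", "carbon fixation (RuBisCO, lumped CBB)",
            {"co2_c": -1, "nadph_c": -2, "atp_c": -a, "h2o_c": -a + 1,
             "fixedc_c": 1, "nadp_c": 2, "adp_c": a, "pi_c": a},
            0, 1000, "metabolic", gpr="tg_rbcL and tg_rbcS"),
        rxn("GLYCSYN", "glycogen polymerisation",
            {"fixedc_c": -6, "atp_c": -p.glycogen_poly_atp,
             "h2o_c": -p.glycogen_poly_atp, "glyc_c": 1,
             "adp_c": p.glycogen_poly_atp, "pi_c": p.glycogen_poly_atp},
            0, 1000, "metabolic", gpr="tg_glgA"),
        rxn("GLYCDEG", "glycogen degradation",
            {"glyc_c": -1, "fixedc_c": 6},
            0, 1000, "metabolic", gpr="tg_glgP"),
        rxn("RESP", "respiration",
            {"fixedc_c": -1, "o2_c": -1, "adp_c": -k, "pi_c": -k,
             "co2_c": 1, "atp_c": k, "h2o_c": k + 1},
            0, 1000, "metabolic", gpr="tg_cox1 or tg_cyd1"),
        rxn("OPP", "NADPH regeneration (oxidative PP, lumped)",
            {"fixedc_c": -1, "h2o_c": -1, "nadp_c": -2,
             "co2_c": 1, "nadph_c": 2},
            0, 1000, "metabolic", gpr="tg_zwf"),
        # --- nitrogen ---------------------------------------------------------
        # 16 ATP per N2; electrons from 1.5 CH2O (4 e- each = 6 e- per N2)
        rxn("NIT", "nitrogenase (lumped N2 fixation)",
            {"n2_c": -1, "fixedc_c": -1.5, "h2o_c": -1.5 - 2 * p.atp_per_nh4,
             "atp_c": -2 * p.atp_per_nh4,
             "nh4_c": 2, "co2_c": 1.5,
             "adp_c": 2 * p.atp_per_nh4, "pi_c": 2 * p.atp_per_nh4},
            0, 1000, "metabolic", gpr="tg_nifH and tg_nifD"),
        # --- biomass and maintenance ----------------------------------------
        rxn("BIOMASS", "biomass formation",
            {"fixedc_c": -p.biomass_c, "nh4_c": -p.biomass_n,
             "atp_c": -p.gam, "h2o_c": -p.gam,
             "adp_c": p.gam, "pi_c": p.gam, "biomass_c": 1},
            0, 1000, "biomass", confidence=1),
        rxn("EN_ATP", "maintenance ATP hydrolysis",
            {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
            0, 1000, "metabolic", confidence=1),
        # --- transport --------------------------------------------------------
        rxn("T_glyc", "glycogen transport", {"glyc_e": -1, "glyc_c": 1},
            -1000, 1000, "transport", gpr="tg_glcP", confidence=4),
        rxn("T_nh4", "ammonium transport", {"nh4_e": -1, "nh4_c": 1},
            -1000, 1000, "transport", gpr="tg_amt1", confidence=4),
        # --- exchanges --------------------------------------------------------
        rxn("EX_photon", "photon exchange", {"photon_c": -1}, -1000, 0, "exchange"),
        rxn("EX_co2", "CO2 exchange", {"co2_c": -1}, -1000, 1000, "exchange"),
        rxn("EX_o2", "O2 exchange", {"o2_c": -1}, -1000, 1000, "exchange"),
        rxn("EX_h2o", "water exchange", {"h2o_c": -1}, -1000, 1000, "exchange"),
        rxn("EX_glyc", "glycogen exchange", {"glyc_e": -1}, -1000, 1000, "exchange"),
        rxn("EX_nh4", "ammonium exchange", {"nh4_e": -1}, -1000, 1000, "exchange"),
        rxn("EX_n2", "dinitrogen exchange", {"n2_c": -1}, -1000, 1000, "exchange"),
        rxn("DM_biomass", "biomass drain", {"biomass_c": -1}, 0, 1000, "exchange"),
    ]
    model.add_reactions(reactions)
    model.objective = "BIOMASS"
    dz, pa = toy_constraint_sets(p)
    return model, dz, pa


def toy_constraint_sets(
    params: ToyNetworkParams | None = None,
) -> tuple[ct.CellTypeConstraintSet, ct.CellTypeConstraintSet]:
    """The diazotroph and photoautotroph bound sets for the toy model."""
    p = params or ToyNetworkParams()
    # water stays freely exchangeable; O2 is taken up by the (respiring)
    # diazotroph and evolved by the photoautotroph
    dz = ct.diazotroph_constraints(
        glycogen_exchange="EX_glyc",
        carbon_uptake=-p.carbon_uptake_cap / 6.0,   # cap in glucose units
        nitrogenase_flux=p.nitrogenase_flux,
        maintenance_atp=p.maintenance["diazotroph"],
        uptake_only=frozenset({"EX_n2", "EX_o2"}),
        export_only=frozenset({"EX_nh4", "EX_co2"}),
    )
    pa = ct.photoautotroph_constraints(
        co2_exchange="EX_co2",
        carbon_uptake=-p.carbon_uptake_cap,
        maintenance_atp=p.maintenance["photoautotroph"],
        uptake_only=frozenset({"EX_nh4"}),
        export_only=frozenset({"EX_glyc", "EX_n2", "EX_o2"}),
    )
    return dz, pa


# ---------------------------------------------------------------------------
# brute-force equilibrium oracle
# ---------------------------------------------------------------------------

@dataclass
class EquilibriumSolution:
    """Oracle result: best diazotroph fraction and population growth rate."""

    f_dz: float | None
    growth_rate: float | None          # total population growth, h-1
    scan: np.ndarray                   # columns (f, growth); NaN = infeasible

    @property
    def viable(self) -> bool:
        return self.f_dz is not None


def _celltype_lp_blocks(model: cobra.Model, spec: ct.CellTypeConstraintSet,
                        release_fixed: bool):
    """S matrix and bound arrays for one phenotype, dFBA-style if requested."""
    if release_fixed:
        # population-level semantics: fixed carbon/nitrogenase equalities
        # become inequality caps / free rates, mirroring the simulator
        from dataclasses import replace
        spec = replace(
            spec,
            carbon_uptake_fixed=False,
            nitrogenase_flux=None if spec.name == "diazotroph" else spec.nitrogenase_flux,
        )
    sub = ct.apply_celltype(model, spec, copy=True)
    S = stoichiometric_matrix(sub)
    lb = np.array([r.lower_bound for r in sub.reactions])
    ub = np.array([r.upper_bound for r in sub.reactions])
    idx = {r.id: j for j, r in enumerate(sub.reactions)}
    return S, lb, ub, idx


def _solve_joint(S_dz, lb_dz, ub_dz, idx_dz, S_pa, lb_pa, ub_pa, idx_pa,
                 f: float, glycogen_ex: str = "EX_glyc", nh4_ex: str = "EX_nh4",
                 biomass_rxn: str = "BIOMASS"):
    """Max total growth at fixed composition f with shared-metabolite closure.

    Variables are the per-gDW flux vectors of both phenotypes; coupling
    constraints enforce glycogen supply = demand and ammonium supply >=
    demand per unit total biomass; the objective is
    f * mu_DZ + (1 - f) * mu_PA.
    """
    n_dz, n_pa = S_dz.shape[1], S_pa.shape[1]
    A_eq = block_diag((csr_matrix(S_dz), csr_matrix(S_pa))).tolil()
    b_eq = np.zeros(A_eq.shape[0])

    glyc = np.zeros(n_dz + n_pa)
    glyc[idx_dz[glycogen_ex]] = f
    glyc[n_dz + idx_pa[glycogen_ex]] = 1.0 - f
    A_eq = A_eq.tocsr()
    from scipy.sparse import vstack
    A_eq = vstack([A_eq, csr_matrix(glyc)])
    b_eq = np.append(b_eq, 0.0)

    nh4 = np.zeros(n_dz + n_pa)
    nh4[idx_dz[nh4_ex]] = -f
    nh4[n_dz + idx_pa[nh4_ex]] = -(1.0 - f)
    A_ub = csr_matrix(nh4)          # -(net nh4 out) <= 0
    b_ub = np.zeros(1)

    c = np.zeros(n_dz + n_pa)
    c[idx_dz[biomass_rxn]] = -f
    c[n_dz + idx_pa[biomass_rxn]] = -(1.0 - f)

    bounds = list(zip(np.append(lb_dz, lb_pa), np.append(ub_dz, ub_pa)))
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if not res.success:
        return None
    return -res.fun


def analytic_equilibrium(
    params: ToyNetworkParams | None = None,
    coarse_step: float = 0.005,
    fine_step: float = 1e-4,
    f_bounds: tuple[float, float] = (1e-4, 1.0 - 1e-4),
) -> EquilibriumSolution:
    """Brute-force scan for the growth-maximising diazotroph fraction.

    For each candidate fraction f the coupled two-phenotype LP is solved at
    stationarity (glycogen supply = demand, ammonium supply >= demand) and
    the total growth recorded; a coarse scan is refined at ``fine_step``
    around its peak so the grid error stays far below the 2 % tolerance the
    dynamic simulation is held to.
    """
    p = params or ToyNetworkParams()
    model, dz_spec, pa_spec = make_toy_model(p)
    blocks_dz = _celltype_lp_blocks(model, dz_spec, release_fixed=True)
    blocks_pa = _celltype_lp_blocks(model, pa_spec, release_fixed=True)

    def growth(f: float):
        return _solve_joint(*blocks_dz, *blocks_pa, f=f)

    coarse = np.arange(f_bounds[0], f_bounds[1] + coarse_step, coarse_step)
    coarse_vals = np.array([g if (g := growth(f)) is not None else np.nan
                            for f in coarse])
    if np.all(~np.isfinite(coarse_vals)) or np.nanmax(coarse_vals) <= 0:
        scan = np.column_stack([coarse, coarse_vals])
        return EquilibriumSolution(f_dz=None, growth_rate=None, scan=scan)

    f_best = coarse[np.nanargmax(coarse_vals)]
    lo = max(f_bounds[0], f_best - coarse_step)
    hi = min(f_bounds[1], f_best + coarse_step)
    fine = np.arange(lo, hi + fine_step, fine_step)
    fine_vals = np.array([g if (g := growth(f)) is not None else np.nan
                          for f in fine])
    j = np.nanargmax(fine_vals)
    scan = np.column_stack(
        [np.concatenate([coarse, fine]), np.concatenate([coarse_vals, fine_vals])]
    )
    return EquilibriumSolution(
        f_dz=float(fine[j]), growth_rate=float(fine_vals[j]), scan=scan
    )
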