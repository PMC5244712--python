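"""Two-phenotype population dynamic FBA with deficiency-driven differentiation.

The trichome is modeled as a well-mixed batch reactor holding two biomass
pools — diazotrophs (DZ) and photoautotrophs (PA) — that exchange a
6-carbon glycogen currency (PA -> DZ) and ammonium (DZ -> PA) through the
medium.  Each time step of length ``dt``:

1. the PA submodel maximizes growth, with its glycogen export forced to
   cover the diazotrophs' previous-step consumption scaled by the predictive
   factor (mu_DZ dt + 1) and the DZ:PA biomass ratio, and its ammonium
   uptake capped by what the medium holds;
2. the DZ submodel maximizes ammonium export (the shared-metabolite
   objective; a growth objective is selectable), with glycogen uptake capped
   both by the population carbon constraint |v_CO2_PA| / (6 f_DZ) and by
   availability;
3. biomass integrates batch-reactor style, X_f' = X_0 exp(mu dt);
4. the step's biomass increment is reallocated between cell types in
   proportion to metabolite shortage: for each deficient shared metabolite,
   a differentiation pool X_delta = sum_gamma alpha * sigma_gamma *
   dX'_gamma is drawn from its consumers and dealt to its producers by
   their production shares; with no deficiency the entire surplus stays
   with (is allocated to) the photoautotrophs;
5. the medium updates by net production minus consumption, exactly.

A population may borrow a shared metabolite from an arbitrary environmental
cache during the first ``grace`` steps, but only while a live producer cell
type for it exists; after ``grace`` consecutive zero-growth steps the
population is declared dead.  Shortage is measured against *demand*: the
consumer's flux re-solved with the availability cap relaxed, so a binding
uptake bound registers as deficiency even though realized consumption can
never exceed supply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import cobra

from . import constraints as ct

__all__ = [
    "DFBAConfig",
    "PopulationState",
    "AllocationRecord",
    "StepRecord",
    "SimulationTrace",
    "MetricsResult",
    "build_dfba_submodels",
    "required_glycogen_supply",
    "diazotroph_glycogen_cap",
    "allocate_differentiation",
    "simulate_population",
    "compute_metrics",
    "run_ensemble",
    "nitrogen_source_scenario",
    "NITROGEN_SOURCES",
]

DZ = "diazotroph"
PA = "photoautotroph"

#: carbons per glycogen (glucose) unit
GLYCOGEN_CARBONS = 6.0


@dataclass
class DFBAConfig:
    """Run settings for the population simulation."""

    horizon: float = 400.0          # h
    dt: float = 1.0                 # h
    grace: int = 3                  # steps with access to the substrate cache
    initial_biomass: float = 4e-5   # g DW L-1 total inoculum
    dz_objective: str = "nh4_export"        # or "biomass"
    allocation_semantics: str = "prose"     # or "literal"
    #: re-extract full flux vectors and record max |S.v| per step (slower)
    validate_steady_state: bool = False
    zero_growth_tol: float = 1e-9
    lp_tol: float = 1e-9
    glycogen_exchange: str = "EX_glyc"
    ammonium_exchange: str = "EX_nh4"
    co2_exchange: str = "EX_co2"
    biomass_reaction: str = "BIOMASS"
    nitrogenase_reaction: str = "NIT"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.horizon < self.dt:
            raise ValueError("horizon shorter than one step")
        if self.dz_objective not in ("nh4_export", "biomass"):
            raise ValueError("dz_objective must be 'nh4_export' or 'biomass'")
        if self.allocation_semantics not in ("prose", "literal"):
            raise ValueError("allocation_semantics must be 'prose' or 'literal'")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon / self.dt))


@dataclass
class PopulationState:
    """Biomasses, medium concentrations and composition at one time point."""

    t: float                            # h
    X: dict[str, float]                 # cell type -> g DW L-1
    C: dict[str, float]                 # metabolite -> mmol L-1

    @property
    def total_biomass(self) -> float:
        return sum(self.X.values())

    @property
    def f(self) -> dict[str, float]:
        tot = self.total_biomass
        if tot <= 0:
            return {k: 0.0 for k in self.X}
        return {k: v / tot for k, v in self.X.items()}

    @property
    def f_dz(self) -> float:
        return self.f.get(DZ, 0.0)


@dataclass
class AllocationRecord:
    """One step's differentiation accounting.

    ``per_metabolite`` maps a shared metabolite to its totals (consumed /
    produced over the step, signed), the portion coefficients sigma on both
    roles, the clamped allocation coefficient alpha and the pool drawn for
    it; ``pool`` is the total differentiation pool, ``transfers`` the net
    biomass moved per cell type (summing to zero).
    """

    per_metabolite: dict[str, dict]
    pool: float
    transfers: dict[str, float]
    surplus_to: str | None = None       # cell type receiving surplus, if any


@dataclass
class StepRecord:
    """Everything one dFBA step computed."""

    t: float
    mu: dict[str, float]                # self growth rate per type, h-1
    mu_effective: dict[str, float]      # allocation-inclusive rate, h-1
    fluxes: dict[str, dict[str, float]]  # cell type -> reaction -> flux
    demand_fluxes: dict[str, dict[str, float]]
    produced: dict[str, float]          # metabolite -> mmol L-1 added
    consumed: dict[str, float]          # metabolite -> mmol L-1 removed (>= 0)
    borrowed: dict[str, float]          # cache draw during grace, mmol L-1
    allocation: AllocationRecord | None
    infeasible: dict[str, bool]
    dead_step: bool
    max_residual: float = float("nan")  # max |S.v| over the step's LP solves


@dataclass
class SimulationTrace:
    """Ordered states and step records over the simulated horizon."""

    states: list[PopulationState]
    records: list[StepRecord]
    status: str                          # "completed" | "died"
    death_time: float | None = None
    config: DFBAConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.states):
            rec = self.records[i - 1] if i > 0 else None
            rows.append(
                {
                    "t": s.t,
                    "X_DZ": s.X.get(DZ, 0.0),
                    "X_PA": s.X.get(PA, 0.0),
                    "f_DZ": s.f_dz,
                    "C_glycogen": s.C.get("glycogen", 0.0),
                    "C_NH4": s.C.get("nh4", 0.0),
                    "mu_t": np.nan if rec is None else
                    math.log(max(s.total_biomass, 1e-300) /
                             max(self.states[i - 1].total_biomass, 1e-300))
                    / (s.t - self.states[i - 1].t),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class MetricsResult:
    """Growth and nitrogen-yield summary of a trace."""

    mu_t: np.ndarray                     # per-step growth rate, h-1
    mu_total: float                      # ln(sum X_f / sum X_0) / T, h-1
    doubling_time: float                 # ln 2 / mu_total, h
    nitrogen_release_fraction: float     # accumulated medium NH4 / NH4 produced
    equilibrium_f_dz: float              # final-window mean diazotroph fraction
    status: str
    nitrogenase_flux: float = float("nan")   # final-window DZ N2 fixation
    co2_uptake: float = float("nan")         # final-window PA CO2 uptake (abs)


# ---------------------------------------------------------------------------
# submodels and step arithmetic
# ---------------------------------------------------------------------------

def build_dfba_submodels(
    model: cobra.Model,
    dz_spec: ct.CellTypeConstraintSet,
    pa_spec: ct.CellTypeConstraintSet,
) -> dict[str, cobra.Model]:
    """Phenotype submodels with the strict rate equalities released.

    Population-level runs release the fixed carbon-uptake equalities to
    inequality caps at the measured rates (the partner's demand, not a
    pinned flux, then drives the exchange) and free the nitrogenase rate.
    """
    out = {}
    for name, spec in ((DZ, dz_spec), (PA, pa_spec)):
        relaxed = replace(
            spec,
            carbon_uptake_fixed=False,
            nitrogenase_flux=None if name == DZ else spec.nitrogenase_flux,
        )
        out[name] = ct.apply_celltype(model, relaxed, copy=True)
    return out


def required_glycogen_supply(
    prev_dz_glycogen_uptake: float,
    mu_dz: float,
    biomass_ratio: float,
    dt: float = 1.0,
) -> float:
    """Predictive forced PA glycogen export, per gDW PA per h.

    Last step's diazotroph consumption |v| is scaled by the predictive
    factor (mu_DZ dt + 1) and the DZ:PA biomass ratio X_DZ / X_PA.
    """
    mu = max(mu_dz, 0.0)
    return (mu * dt + 1.0) * abs(min(prev_dz_glycogen_uptake, 0.0)) * biomass_ratio


def diazotroph_glycogen_cap(v_co2_pa: float, f_dz: float) -> float:
    """Population carbon cap on DZ glycogen uptake, glucose units (>= 0).

    One sixth of the photoautotroph CO2 uptake magnitude divided by the
    diazotroph biomass fraction.
    """
    if f_dz <= 0:
        return 0.0
    return abs(min(v_co2_pa, 0.0)) / (GLYCOGEN_CARBONS * f_dz)


def _solve(
    model: cobra.Model, wanted: tuple[str, ...], S=None
) -> tuple[float | None, dict, float]:
    """Solve; return (objective, fluxes-of-wanted, max |S.v|) or (None, zeros, nan).

    With ``S`` given the full flux vector is extracted and the steady-state
    residual computed; otherwise only the watched fluxes are read back.
    """
    if S is not None:
        sol = model.optimize(raise_error=False)
        if sol.status != "optimal":
            return None, {r: 0.0 for r in wanted}, float("nan")
        v = sol.fluxes.to_numpy()
        resid = float(np.abs(S @ v).max())
        return (float(sol.objective_value),
                {r: float(sol.fluxes[r]) for r in wanted}, resid)
    value = model.slim_optimize(error_value=np.nan)
    if np.isnan(value):
        return None, {r: 0.0 for r in wanted}, float("nan")
    return (float(value),
            {r: float(model.reactions.get_by_id(r).flux) for r in wanted},
            float("nan"))


# ---------------------------------------------------------------------------
# allocation (the differentiation rule)
# ---------------------------------------------------------------------------

def allocate_differentiation(
    increments: dict[str, float],
    final_prime: dict[str, float],
    consumer_fluxes: dict[str, dict[str, float]],
    producer_fluxes: dict[str, dict[str, float]],
    dt: float = 1.0,
    semantics: str = "prose",
    surplus_to: str = PA,
) -> tuple[AllocationRecord, dict[str, float]]:
    """Redistribute the step's biomass increment according to shortage.

    ``increments`` are the uncorrected per-type increments dX' (>= 0);
    ``final_prime`` the uncorrected end-of-step biomasses X_f'.  For each
    shared metabolite, ``consumer_fluxes[m]`` maps consumer cell types to
    their (demand) uptake flux (< 0) and ``producer_fluxes[m]`` maps
    producers to export flux (> 0), both in mmol (g DW)-1 h-1.

    Totals per role are C^T = sum v * X_f' * dt (signed).  When production
    falls short of demand the allocation coefficient
    alpha = (C_prod^T + C_cons^T) / C_cons^T (clamped to [0, 1]) sets the
    fraction of the consumers' increment entering the differentiation pool,
    drawn by consumption shares sigma_gamma and dealt to the producers by
    production shares sigma_pi (``semantics='prose'``); ``'literal'``
    follows the printed role indices and deals the pool back to the
    consumer side.  If no metabolite is deficient the entire increment of
    every cell type is allocated to ``surplus_to``.  Biomass is conserved
    exactly: transfers sum to zero and no cell loses more than it gained.
    """
    if any(dx < -1e-12 for dx in increments.values()):
        raise ValueError("allocation redistributes gains; increments must be >= 0")

    per_met: dict[str, dict] = {}
    transfers = {k: 0.0 for k in increments}
    any_deficiency = False

    metabolites = set(consumer_fluxes) | set(producer_fluxes)
    for m in sorted(metabolites):
        cons = consumer_fluxes.get(m, {})
        prod = producer_fluxes.get(m, {})
        c_tot = sum(min(v, 0.0) * final_prime.get(g, 0.0) * dt for g, v in cons.items())
        p_tot = sum(max(v, 0.0) * final_prime.get(g, 0.0) * dt for g, v in prod.items())
        entry: dict = {
            "consumed_total": c_tot,
            "produced_total": p_tot,
            "alpha": 0.0,
            "sigma_consumers": {},
            "sigma_producers": {},
            "pool": 0.0,
        }
        if c_tot >= 0.0 or abs(c_tot) < 1e-300:
            per_met[m] = entry       # no consumption: nothing to correct
            continue
        sigma_c = {
            g: (min(v, 0.0) * final_prime.get(g, 0.0) * dt) / c_tot
            for g, v in cons.items()
        }
        if p_tot > 0:
            sigma_p = {
                g: (max(v, 0.0) * final_prime.get(g, 0.0) * dt) / p_tot
                for g, v in prod.items()
            }
        else:
            n = max(len(prod), 1)
            sigma_p = {g: 1.0 / n for g in prod}
        alpha = (p_tot + c_tot) / c_tot        # = 1 - prod/|cons|, signed totals
        alpha = min(max(alpha, 0.0), 1.0)
        entry.update(alpha=alpha, sigma_consumers=sigma_c, sigma_producers=sigma_p)
        if alpha > 0.0:
            any_deficiency = True
            pool = sum(alpha * sigma_c[g] * increments.get(g, 0.0) for g in sigma_c)
            entry["pool"] = pool
            if pool > 0:
                # the pool is always drawn from the consumers; 'literal'
                # follows the printed role indices and deals it back to the
                # consumer side instead of the producers
                sources = sigma_c
                targets = sigma_p if semantics == "prose" else sigma_c
                for g, s in sources.items():
                    transfers[g] = transfers.get(g, 0.0) - alpha * s * increments.get(g, 0.0)
                for g, s in targets.items():
                    transfers[g] = transfers.get(g, 0.0) + s * pool
        per_met[m] = entry

    final = {}
    surplus_target = None
    if not any_deficiency:
        surplus_target = surplus_to
        total_increment = sum(increments.values())
        for g in increments:
            base = final_prime.get(g, 0.0) - increments.get(g, 0.0)  # X_0
            final[g] = base + (total_increment if g == surplus_to else 0.0)
    else:
        for g in increments:
            final[g] = final_prime.get(g, 0.0) + transfers.get(g, 0.0)

    record = AllocationRecord(
        per_metabolite=per_met,
        pool=sum(e["pool"] for e in per_met.values()),
        transfers=transfers if any_deficiency else {
            g: final[g] - final_prime.get(g, 0.0) for g in increments
        },
        surplus_to=surplus_target,
    )
    return record, final


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def simulate_population(
    submodels: dict[str, cobra.Model],
    initial: PopulationState | None = None,
    config: DFBAConfig | None = None,
    pa_nh4_replete: bool = False,
    nitrogen_replete: bool = False,
) -> SimulationTrace:
    """Run the sequential PA -> DZ population simulation.

    ``submodels`` come from :func:`build_dfba_submodels` (they are mutated
    in place during the run; pass copies to reuse them).  ``initial``
    defaults to an equal-parts inoculum of ``config.initial_biomass`` with
    an empty medium.  ``nitrogen_replete`` marks runs where an external
    nitrogen source is supplied in excess: nitrogen can then never be
    deficient (no differentiation towards diazotrophs) and photoautotroph
    ammonium consumption is drawn from the replete reservoir rather than
    the tracked medium pool.
    """
    cfg = config or DFBAConfig()
    if initial is None:
        half = cfg.initial_biomass / 2.0
        initial = PopulationState(t=0.0, X={DZ: half, PA: half},
                                  C={"glycogen": 0.0, "nh4": 0.0})
    if any(x < 0 for x in initial.X.values()):
        raise ValueError("initial biomasses must be non-negative")

    pa_m = submodels[PA]
    dz_m = submodels[DZ]
    pa_m.objective = cfg.biomass_reaction
    dz_m.objective = (cfg.ammonium_exchange if cfg.dz_objective == "nh4_export"
                      else cfg.biomass_reaction)
    dz_m.objective_direction = "max"
    pa_m.objective_direction = "max"

    pa_watch = (cfg.biomass_reaction, cfg.co2_exchange, cfg.glycogen_exchange,
                cfg.ammonium_exchange)
    dz_watch = (cfg.biomass_reaction, cfg.glycogen_exchange, cfg.ammonium_exchange,
                cfg.nitrogenase_reaction)

    # standing physiological caps of the submodels; step bounds only tighten
    dz_gly_cap = abs(dz_m.reactions.get_by_id(cfg.glycogen_exchange).lower_bound)
    pa_nh4_cap = abs(pa_m.reactions.get_by_id(cfg.ammonium_exchange).lower_bound)

    S_dz = S_pa = None
    if cfg.validate_steady_state:
        from .core import stoichiometric_matrix
        S_dz = stoichiometric_matrix(dz_m)
        S_pa = stoichiometric_matrix(pa_m)

    state = PopulationState(t=initial.t, X=dict(initial.X), C=dict(initial.C))
    states = [state]
    records: list[StepRecord] = []
    status = "completed"
    death_time = None
    consecutive_dead = 0

    prev_dz_gly = 0.0        # last step's DZ glycogen uptake flux (<= 0)
    prev_mu_dz_eff = 0.0

    for n in range(1, cfg.n_steps + 1):
        t0, dt = state.t, cfg.dt
        X_dz, X_pa = state.X.get(DZ, 0.0), state.X.get(PA, 0.0)
        total0 = X_dz + X_pa
        f_dz = X_dz / total0 if total0 > 0 else 0.0
        in_grace = n <= cfg.grace

        fluxes = {DZ: {r: 0.0 for r in dz_watch}, PA: {r: 0.0 for r in pa_watch}}
        demand = {DZ: {}, PA: {}}
        infeasible = {DZ: False, PA: False}
        mu = {DZ: 0.0, PA: 0.0}
        residuals = []

        # ------------------------------------------------------ PA step
        if X_pa > 0:
            ex_gly = pa_m.reactions.get_by_id(cfg.glycogen_exchange)
            ex_nh4 = pa_m.reactions.get_by_id(cfg.ammonium_exchange)
            required = required_glycogen_supply(
                prev_dz_gly, prev_mu_dz_eff, X_dz / X_pa, dt
            )
            ex_gly.bounds = (min(required, 1000.0), 1000.0)

            if pa_nh4_replete:
                avail_nh4 = 1000.0
            else:
                avail_nh4 = state.C.get("nh4", 0.0) / (X_pa * dt)
                if in_grace and X_dz > 0:        # borrow: live producer exists
                    avail_nh4 = 1000.0
            # demand solve: availability cap and the forced-export burden are
            # both relaxed, so demand measures the phenotype's potential when
            # its partner is not limiting (upper bounds untouched so scenario
            # submodels may re-secrete surplus ammonium)
            nh4_ub = ex_nh4.upper_bound
            ex_nh4.bounds = (-pa_nh4_cap, nh4_ub)
            ex_gly.bounds = (0.0, 1000.0)
            obj, dem, res = _solve(pa_m, pa_watch, S_pa)
            demand[PA] = dem
            residuals.append(res)
            # actual solve
            ex_gly.bounds = (min(required, 1000.0), 1000.0)
            ex_nh4.bounds = (-min(avail_nh4, pa_nh4_cap), nh4_ub)
            obj, got, res = _solve(pa_m, pa_watch, S_pa)
            residuals.append(res)
            if obj is None:
                infeasible[PA] = True
            else:
                mu[PA] = max(obj, 0.0)
                fluxes[PA] = got
        v_co2_pa = fluxes[PA].get(cfg.co2_exchange, 0.0)
        v_gly_pa = max(fluxes[PA].get(cfg.glycogen_exchange, 0.0), 0.0)
        v_nh4_pa_raw = fluxes[PA].get(cfg.ammonium_exchange, 0.0)
        v_nh4_pa = min(v_nh4_pa_raw, 0.0)

        # ------------------------------------------------------ DZ step
        if X_dz > 0:
            ex_gly = dz_m.reactions.get_by_id(cfg.glycogen_exchange)
            cap5 = diazotroph_glycogen_cap(v_co2_pa, f_dz)
            avail_gly = (state.C.get("glycogen", 0.0) + v_gly_pa * X_pa * dt) / (
                X_dz * dt
            )
            if in_grace and X_pa > 0:
                avail_gly = 1000.0
            # demand solve: availability relaxed; the population carbon cap
            # and the standing physiological cap are kept
            ex_gly.bounds = (-min(cap5, dz_gly_cap), 0.0)
            obj, dem, res = _solve(dz_m, dz_watch, S_dz)
            demand[DZ] = dem
            residuals.append(res)
            # actual solve
            ex_gly.bounds = (-min(cap5, avail_gly, dz_gly_cap), 0.0)
            obj, got, res = _solve(dz_m, dz_watch, S_dz)
            residuals.append(res)
            if obj is None:
                infeasible[DZ] = True
            else:
                fluxes[DZ] = got
                mu[DZ] = max(got.get(cfg.biomass_reaction, 0.0), 0.0)
        v_gly_dz = min(fluxes[DZ].get(cfg.glycogen_exchange, 0.0), 0.0)
        v_nh4_dz = max(fluxes[DZ].get(cfg.ammonium_exchange, 0.0), 0.0)

        # ------------------------------------------- batch growth + allocation
        increments = {
            DZ: X_dz * (math.exp(mu[DZ] * dt) - 1.0),
            PA: X_pa * (math.exp(mu[PA] * dt) - 1.0),
        }
        final_prime = {DZ: X_dz + increments[DZ], PA: X_pa + increments[PA]}

        consumer_fluxes = {
            "glycogen": {DZ: min(demand[DZ].get(cfg.glycogen_exchange, v_gly_dz), 0.0)},
            "nh4": {PA: 0.0 if nitrogen_replete
                    else min(demand[PA].get(cfg.ammonium_exchange, v_nh4_pa), 0.0)},
        }
        producer_fluxes = {
            "glycogen": {PA: v_gly_pa},
            "nh4": {DZ: v_nh4_dz},
        }
        allocation, X_final = allocate_differentiation(
            increments, final_prime, consumer_fluxes, producer_fluxes,
            dt=dt, semantics=cfg.allocation_semantics,
        )

        # ------------------------------------------------------ medium update
        produced = {
            "glycogen": v_gly_pa * X_pa * dt,
            "nh4": v_nh4_dz * X_dz * dt + max(v_nh4_pa_raw, 0.0) * X_pa * dt,
        }
        consumed = {
            "glycogen": -v_gly_dz * X_dz * dt,
            # with ammonium itself supplied replete, PA draws on that
            # reservoir rather than the tracked medium pool
            "nh4": 0.0 if pa_nh4_replete else -v_nh4_pa * X_pa * dt,
        }
        C_new = {}
        borrowed = {}
        for m in ("glycogen", "nh4"):
            c = state.C.get(m, 0.0) + produced[m] - consumed[m]
            if c < 0:
                if in_grace or c > -1e-9:
                    borrowed[m] = -c          # drawn from the arbitrary cache
                    c = 0.0
                else:
                    raise RuntimeError(
                        f"medium concentration of {m} went negative ({c:.3g}) "
                        "outside the grace period"
                    )
            C_new[m] = c

        total_growth = sum(increments.values())
        dead_step = total_growth <= cfg.zero_growth_tol * max(total0, 1e-12)

        state = PopulationState(t=t0 + dt, X=X_final, C=C_new)
        mu_eff = {
            g: (math.log(X_final[g] / states[-1].X.get(g, 0.0)) / dt
                if X_final[g] > 0 and states[-1].X.get(g, 0.0) > 0 else 0.0)
            for g in (DZ, PA)
        }
        records.append(
            StepRecord(
                t=state.t, mu=mu, mu_effective=mu_eff, fluxes=fluxes,
                demand_fluxes=demand, produced=produced, consumed=consumed,
                borrowed=borrowed, allocation=allocation,
                infeasible=infeasible, dead_step=dead_step,
                max_residual=(float(np.nanmax(residuals))
                              if residuals and not all(np.isnan(residuals))
                              else float("nan")),
            )
        )
        states.append(state)

        prev_dz_gly = v_gly_dz
        prev_mu_dz_eff = max(mu_eff[DZ], 0.0)

        consecutive_dead = consecutive_dead + 1 if dead_step else 0
        if consecutive_dead >= cfg.grace:
            status = "died"
            death_time = state.t
            break

    return SimulationTrace(states=states, records=records, status=status,
                           death_time=death_time, config=cfg)


# ---------------------------------------------------------------------------
# metrics, ensemble, nitrogen-source scenarios
# ---------------------------------------------------------------------------

def compute_metrics(trace: SimulationTrace, window_fraction: float = 0.1) -> MetricsResult:
    """Growth-rate and nitrogen-yield metrics of a finished trace."""
    if not trace.states:
        raise ValueError("empty trace")
    X0 = trace.states[0].total_biomass
    Xf = trace.states[-1].total_biomass
    T = trace.states[-1].t - trace.states[0].t
    if X0 <= 0 or T <= 0:
        return MetricsResult(
            mu_t=np.array([]), mu_total=0.0, doubling_time=float("inf"),
            nitrogen_release_fraction=0.0, equilibrium_f_dz=0.0, status="died",
        )
    totals = np.array([s.total_biomass for s in trace.states])
    dts = np.diff([s.t for s in trace.states])
    with np.errstate(divide="ignore"):
        mu_t = np.log(totals[1:] / totals[:-1]) / dts
    mu_total = math.log(Xf / X0) / T

    produced_nh4 = sum(r.produced.get("nh4", 0.0) for r in trace.records)
    delta_c = trace.states[-1].C.get("nh4", 0.0) - trace.states[0].C.get("nh4", 0.0)
    y = delta_c / produced_nh4 if produced_nh4 > 0 else 0.0
    y = min(max(y, 0.0), 1.0)

    n_window = max(int(len(trace.states) * window_fraction), min(10, len(trace.states)))
    window = trace.states[-n_window:]
    eq_f = float(np.mean([s.f_dz for s in window]))
    rec_window = trace.records[-n_window:]
    cfg = trace.config or DFBAConfig()
    nit = float(np.mean([r.fluxes[DZ].get(cfg.nitrogenase_reaction, 0.0)
                         for r in rec_window])) if rec_window else float("nan")
    co2 = float(np.mean([abs(r.fluxes[PA].get(cfg.co2_exchange, 0.0))
                         for r in rec_window])) if rec_window else float("nan")
    return MetricsResult(
        mu_t=mu_t, mu_total=mu_total,
        doubling_time=math.log(2) / mu_total if mu_total > 0 else float("inf"),
        nitrogen_release_fraction=y, equilibrium_f_dz=eq_f, status=trace.status,
        nitrogenase_flux=nit, co2_uptake=co2,
    )


def run_ensemble(
    model: cobra.Model,
    dz_spec: ct.CellTypeConstraintSet,
    pa_spec: ct.CellTypeConstraintSet,
    n: int = 1000,
    config: DFBAConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated simulations from randomized inocula.

    Initial biomasses of both cell types are drawn independently and
    uniformly on (0, initial_biomass]; the initial fraction is the ratio of
    the two draws.  Returns one row per iteration with the inoculum, the
    terminal status and the growth/nitrogen metrics.
    """
    cfg = config or DFBAConfig()
    rng = np.random.default_rng(seed)
    submodels = build_dfba_submodels(model, dz_spec, pa_spec)
    rows = []
    for i in range(n):
        x_dz, x_pa = rng.uniform(0.0, cfg.initial_biomass, size=2)
        init = PopulationState(t=0.0, X={DZ: x_dz, PA: x_pa},
                               C={"glycogen": 0.0, "nh4": 0.0})
        trace = simulate_population(submodels, init, cfg)
        metrics = compute_metrics(trace)
        rows.append(
            {
                "iteration": i,
                "X0_DZ": x_dz,
                "X0_PA": x_pa,
                "f0_DZ": x_dz / (x_dz + x_pa),
                "status": trace.status,
                "mu_total": metrics.mu_total if trace.status == "completed" else 0.0,
                "nitrogen_release_fraction": (
                    metrics.nitrogen_release_fraction
                    if trace.status == "completed" else 0.0
                ),
                "equilibrium_f_dz": metrics.equilibrium_f_dz,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class NitrogenSource:
    """An alternative nitrogen source opened into the medium in excess."""

    name: str
    exchange: str | None            # pre-existing exchange id, if any
    formula: str | None             # for a temporarily added species
    degradation: dict[str, float] | None  # lumped catabolism (metabolite: coeff)
    transport_atp: float = 0.0      # ATP per mol moved across the membrane


NITROGEN_SOURCES: dict[str, NitrogenSource] = {
    "N2": NitrogenSource("N2", exchange=None, formula=None, degradation=None),
    "NH4": NitrogenSource("NH4", exchange="EX_nh4", formula=None, degradation=None),
    "urea": NitrogenSource(
        "urea", exchange=None, formula="CH4N2O",
        degradation={"h2o_c": -1.0, "nh4_c": 2.0, "co2_c": 1.0},
        transport_atp=2.0,          # ATP-dependent active transport
    ),
    "glutamate": NitrogenSource(
        "glutamate", exchange=None, formula="C5H9NO4",
        degradation={"h2o_c": -2.0, "nh4_c": 1.0, "fixedc_c": 5.0, "o2_c": 0.5},
        transport_atp=1.0,
    ),
    "glutamine": NitrogenSource(
        "glutamine", exchange=None, formula="C5H10N2O3",
        degradation={"h2o_c": -3.0, "nh4_c": 2.0, "fixedc_c": 5.0, "o2_c": 0.5},
        transport_atp=0.5,
    ),
}


def _install_source(sub: cobra.Model, source: NitrogenSource) -> None:
    """Open (adding species/transport if needed) one nitrogen source."""
    if source.exchange is not None:
        sub.reactions.get_by_id(source.exchange).lower_bound = -1000.0
        return
    sid = source.name.lower()
    ext = cobra.Metabolite(f"{sid}_e", name=f"{source.name} (medium)",
                           formula=source.formula, compartment="e")
    cyt = cobra.Metabolite(f"{sid}_c", name=source.name,
                           formula=source.formula, compartment="c")
    ex = cobra.Reaction(f"EX_{sid}", lower_bound=-1000.0, upper_bound=0.0)
    ex.add_metabolites({ext: -1.0})
    ex.notes["category"] = "exchange"
    tr = cobra.Reaction(f"T_{sid}", lower_bound=0.0, upper_bound=1000.0)
    tr_mets = {ext: -1.0, cyt: 1.0}
    if source.transport_atp:
        a = source.transport_atp
        for mid, coeff in (("atp_c", -a), ("h2o_c", -a), ("adp_c", a), ("pi_c", a)):
            tr_mets[sub.metabolites.get_by_id(mid)] = tr_mets.get(
                sub.metabolites.get_by_id(mid), 0.0) + coeff
    tr.add_metabolites(tr_mets)
    tr.notes["category"] = "transport"
    deg = cobra.Reaction(f"DEG_{sid}", lower_bound=0.0, upper_bound=1000.0)
    deg_mets: dict = {cyt: -1.0}
    for mid, coeff in source.degradation.items():
        deg_mets[sub.metabolites.get_by_id(mid)] = coeff
    deg.add_metabolites(deg_mets)
    deg.notes["category"] = "metabolic"
    sub.add_reactions([ex, tr, deg])


def nitrogen_source_scenario(
    model: cobra.Model,
    dz_spec: ct.CellTypeConstraintSet,
    pa_spec: ct.CellTypeConstraintSet,
    source: str,
    config: DFBAConfig | None = None,
    initial: PopulationState | None = None,
    open_uptake: bool = True,
) -> tuple[SimulationTrace, MetricsResult]:
    """Population run with an alternative nitrogen source in excess.

    The source's exchange is opened replete for both phenotypes (adding a
    diffusion-style transporter — ATP-dependent for urea — and a lumped
    catabolic reaction when the species is not in the model); surplus
    ammonium from catabolism may be re-secreted by the photoautotroph.
    With ``open_uptake=False`` the source bound stays closed and the run
    reduces to the baseline.
    """
    if source not in NITROGEN_SOURCES:
        raise KeyError(
            f"unknown nitrogen source {source!r}; options: {sorted(NITROGEN_SOURCES)}"
        )
    cfg = config or DFBAConfig()
    src = NITROGEN_SOURCES[source]
    submodels = build_dfba_submodels(model, dz_spec, pa_spec)
    pa_replete = False
    n_replete = source != "N2" and open_uptake
    if source != "N2" and open_uptake:
        if src.exchange is not None and src.exchange not in model.reactions:
            raise KeyError(f"source exchange {src.exchange!r} absent from model")
        # the source feeds the growing photoautotrophs; diazotrophs
        # down-regulate fixation under replete fixed nitrogen
        _install_source(submodels[PA], src)
        if source == "NH4":
            pa_replete = True
        else:
            # deaminating cells may re-secrete surplus ammonium
            submodels[PA].reactions.get_by_id(cfg.ammonium_exchange).upper_bound = 1000.0
    trace = simulate_population(submodels, initial, cfg, pa_nh4_replete=pa_replete,
                                nitrogen_replete=n_replete)
    return trace, compute_metrics(trace)
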