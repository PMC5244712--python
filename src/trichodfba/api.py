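"""Model/Results façade over the two-cell-type trichome analysis.

:class:`TrichomeModel` bundles a metabolic reconstruction with the two
phenotype constraint sets; :meth:`TrichomeModel.fit` runs the standard
analysis pipeline — per-phenotype FBA (optionally calibrating maintenance
ATP against a measured growth rate), nutrient-unlimited reference optima,
and the population dynamic FBA searched to its equilibrium composition —
and returns a :class:`TrichomeResults` carrying the estimates with a
``summary()`` table.  Simulation and plotting hang off these two objects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import cobra
import pandas as pd

from . import constraints as ct
from . import dfba as dyn
from . import fba
from .core import load_model
from .toy import ToyNetworkParams, make_toy_model

__all__ = ["TrichomeModel", "TrichomeResults"]

DZ, PA = dyn.DZ, dyn.PA


@dataclass
class TrichomeResults:
    """Fitted estimates of the two-cell-type trichome analysis."""

    celltype_growth: dict[str, float]        # constrained FBA optimum, h-1
    independent_growth: dict[str, float | None]  # nutrient-unlimited optimum
    maintenance: dict[str, float]            # mmol ATP (g DW)-1 h-1
    calibrated: bool
    target_growth: float | None
    equilibrium_f_dz: float
    mu_total: float                          # h-1, equilibrium-start run
    doubling_time: float                     # h
    nitrogen_release_fraction: float
    nitrogenase_flux: float                  # mmol N2 (g DW)-1 h-1, eq. window
    co2_uptake: float                        # mmol CO2 (g DW)-1 h-1, eq. window
    trace_search: dyn.SimulationTrace        # equal-parts inoculum run
    trace_equilibrium: dyn.SimulationTrace   # equilibrium inoculum re-run
    model: "TrichomeModel" = None

    def summary(self) -> str:
        """Human-readable results table."""
        def fmt(x, nd=4):
            if x is None:
                return "n/a"
            return f"{x:.{nd}g}"

        lines = [
            "        Two-Cell-Type Trichome Model Results",
            "=" * 58,
            f"{'':34s}{'Diazotroph':>11s}{'Photoauto.':>12s}",
            f"{'FBA growth rate (h^-1)':34s}"
            f"{fmt(self.celltype_growth.get(DZ)):>11s}"
            f"{fmt(self.celltype_growth.get(PA)):>12s}",
            f"{'maintenance ATP (mmol/gDW/h)':34s}"
            f"{fmt(self.maintenance.get(DZ)):>11s}"
            f"{fmt(self.maintenance.get(PA)):>12s}",
            f"{'independent optimum (h^-1)':34s}"
            f"{fmt(self.independent_growth.get(DZ)):>11s}"
            f"{fmt(self.independent_growth.get(PA)):>12s}",
            "-" * 58,
            "Population dynamic FBA (equilibrium inoculum)",
            f"{'equilibrium diazotroph fraction':40s}{self.equilibrium_f_dz:>10.4f}",
            f"{'total growth rate (h^-1)':40s}{self.mu_total:>10.4g}",
            f"{'doubling time (h)':40s}{self.doubling_time:>10.4g}",
            f"{'fixed nitrogen released':40s}"
            f"{100 * self.nitrogen_release_fraction:>9.1f}%",
            f"{'nitrogenase flux (mmol N2/gDW/h)':40s}{self.nitrogenase_flux:>10.4g}",
            f"{'CO2 uptake (mmol/gDW/h)':40s}{self.co2_uptake:>10.4g}",
            "=" * 58,
        ]
        if self.calibrated:
            lines.insert(
                -1,
                f"maintenance calibrated to growth {self.target_growth:g} h^-1",
            )
        return "\n".join(lines)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "growth_dz": self.celltype_growth.get(DZ),
                "growth_pa": self.celltype_growth.get(PA),
                "maintenance_dz": self.maintenance.get(DZ),
                "maintenance_pa": self.maintenance.get(PA),
                "independent_dz": self.independent_growth.get(DZ),
                "independent_pa": self.independent_growth.get(PA),
                "equilibrium_f_dz": self.equilibrium_f_dz,
                "mu_total": self.mu_total,
                "doubling_time": self.doubling_time,
                "nitrogen_release_fraction": self.nitrogen_release_fraction,
                "nitrogenase_flux": self.nitrogenase_flux,
                "co2_uptake": self.co2_uptake,
            }
        )

    def plot_population(self, trace: dyn.SimulationTrace | None = None, ax=None):
        """Cell-type fractions and medium concentrations over time."""
        import matplotlib.pyplot as plt

        trace = trace or self.trace_search
        frame = trace.to_frame()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(frame["t"], frame["f_DZ"], label="diazotroph fraction")
        ax.plot(frame["t"], 1 - frame["f_DZ"], label="photoautotroph fraction")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("fraction of biomass")
        ax.legend()
        return ax


class TrichomeModel:
    """A metabolic reconstruction plus its two phenotype constraint sets.

    Parameters
    ----------
    model:
        The shared genome-scale (or reduced) reconstruction.
    dz_spec, pa_spec:
        Bound-override sets defining the diazotroph and photoautotroph.
    config:
        Population-simulation settings (horizon, step, grace, inoculum).
    """

    def __init__(
        self,
        model: cobra.Model,
        dz_spec: ct.CellTypeConstraintSet,
        pa_spec: ct.CellTypeConstraintSet,
        config: dyn.DFBAConfig | None = None,
    ) -> None:
        self.model = model
        self.specs = {DZ: dz_spec, PA: pa_spec}
        self.config = config or dyn.DFBAConfig()

    # ------------------------------------------------------------ builders
    @classmethod
    def from_toy(
        cls,
        params: ToyNetworkParams | None = None,
        config: dyn.DFBAConfig | None = None,
    ) -> "TrichomeModel":
        """The reduced two-phenotype network with its default constraint sets."""
        model, dz_spec, pa_spec = make_toy_model(params)
        obj = cls(model, dz_spec, pa_spec, config)
        obj.toy_params = params or ToyNetworkParams()
        return obj

    @classmethod
    def from_files(
        cls,
        source,
        dz_spec: ct.CellTypeConstraintSet,
        pa_spec: ct.CellTypeConstraintSet,
        config: dyn.DFBAConfig | None = None,
    ) -> "TrichomeModel":
        """Load the reconstruction from SBML or a tabular listing directory."""
        return cls(load_model(source), dz_spec, pa_spec, config)

    # ------------------------------------------------------------ pieces
    def celltype_model(self, name: str, unconstrained: bool = False) -> cobra.Model:
        spec = self.specs[name]
        if unconstrained:
            spec = ct.unconstrained_variant(spec)
        return ct.apply_celltype(self.model, spec, copy=True)

    def submodels(self) -> dict[str, cobra.Model]:
        return dyn.build_dfba_submodels(self.model, self.specs[DZ], self.specs[PA])

    def simulate(
        self,
        f_dz: float = 0.5,
        total_biomass: float | None = None,
        config: dyn.DFBAConfig | None = None,
    ) -> dyn.SimulationTrace:
        """Population run from a given inoculum composition."""
        cfg = config or self.config
        total = total_biomass if total_biomass is not None else cfg.initial_biomass
        init = dyn.PopulationState(
            t=0.0,
            X={DZ: f_dz * total, PA: (1.0 - f_dz) * total},
            C={"glycogen": 0.0, "nh4": 0.0},
        )
        return dyn.simulate_population(self.submodels(), init, cfg)

    # ------------------------------------------------------------ fit
    def fit(
        self,
        target_growth: float | None = None,
        search_f_dz: float = 0.5,
    ) -> TrichomeResults:
        """Run the full analysis; calibrates maintenance when a target is given.

        With ``target_growth`` the maintenance ATP lower bound of each
        phenotype is bisected until its constrained FBA growth matches the
        target, and the calibrated values are used for everything downstream.
        The equilibrium composition is found by simulating from an
        equal-parts inoculum and re-simulating from the discovered
        equilibrium fraction.
        """
        maintenance = {}
        for name in (DZ, PA):
            spec = self.specs[name]
            if target_growth is not None:
                sub = ct.apply_celltype(self.model, replace(spec, maintenance_atp=0.0))
                m = fba.calibrate_maintenance(
                    sub, target_growth, maintenance_id=spec.maintenance_id
                )
                self.specs[name] = replace(spec, maintenance_atp=m)
            maintenance[name] = self.specs[name].maintenance_atp

        celltype_growth = {}
        independent_growth = {}
        for name in (DZ, PA):
            sol = fba.solve_fba(self.celltype_model(name))
            celltype_growth[name] = sol.objective_value if sol.optimal else 0.0
            sol_u = fba.solve_fba(self.celltype_model(name, unconstrained=True))
            independent_growth[name] = sol_u.objective_value if sol_u.optimal else None

        trace_search = self.simulate(f_dz=search_f_dz)
        m_search = dyn.compute_metrics(trace_search)
        f_eq = m_search.equilibrium_f_dz

        trace_eq = self.simulate(f_dz=f_eq)
        metrics = dyn.compute_metrics(trace_eq)

        return TrichomeResults(
            celltype_growth=celltype_growth,
            independent_growth=independent_growth,
            maintenance=maintenance,
            calibrated=target_growth is not None,
            target_growth=target_growth,
            equilibrium_f_dz=metrics.equilibrium_f_dz,
            mu_total=metrics.mu_total,
            doubling_time=metrics.doubling_time,
            nitrogen_release_fraction=metrics.nitrogen_release_fraction,
            nitrogenase_flux=metrics.nitrogenase_flux,
            co2_uptake=metrics.co2_uptake,
            trace_search=trace_search,
            trace_equilibrium=trace_eq,
            model=self,
        )

    # ------------------------------------------------------------ extras
    def ensemble(self, n: int = 1000, seed: int = 0,
                 config: dyn.DFBAConfig | None = None) -> pd.DataFrame:
        return dyn.run_ensemble(self.model, self.specs[DZ], self.specs[PA],
                                n=n, config=config or self.config, seed=seed)

    def nitrogen_source(self, source: str,
                        f_dz: float | None = None,
                        config: dyn.DFBAConfig | None = None):
        cfg = config or self.config
        initial = None
        if f_dz is not None:
            total = cfg.initial_biomass
            initial = dyn.PopulationState(
                t=0.0, X={DZ: f_dz * total, PA: (1 - f_dz) * total},
                C={"glycogen": 0.0, "nh4": 0.0},
            )
        return dyn.nitrogen_source_scenario(
            self.model, self.specs[DZ], self.specs[PA], source,
            config=cfg, initial=initial,
        )
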