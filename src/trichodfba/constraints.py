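"""Cell-type constraint sets: diazotroph and photoautotroph submodels.

A *Trichodesmium* trichome contains one genome but two metabolic phenotypes,
each defined purely by flux-bound overrides on the shared reconstruction:

* **diazotroph** (DZ): Photosystem II off, nitrogenase on (fixed flux),
  glycogen/N2/O2 available for uptake, ammonium and CO2 export-only;
* **photoautotroph** (PA): nitrogenase off, CO2 uptake fixed at the measured
  rate, ammonium uptake-only, glycogen/N2 export-only.

Both share an 80 uE photon budget split between the photosystems, a
replete-seawater uptake set fixed at [-1000, 0], and a non-growth-associated
maintenance ATP hydrolysis (EN_ATP) imposed as a lower bound.  The sign
convention is uptake negative, secretion positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import cobra

__all__ = [
    "CellTypeConstraintSet",
    "diazotroph_constraints",
    "photoautotroph_constraints",
    "apply_celltype",
    "unconstrained_variant",
    "PHOTON_BUDGET",
]

#: total photon supply per cell, uE == mmol photons (g DW)-1 h-1
PHOTON_BUDGET = 80.0

#: literature nitrogenase flux, mmol (g DW)-1 h-1 (an alternative fitted
#: value of 0.206 is reported alongside and selectable via the dataclass)
NITROGENASE_FLUX_DEFAULT = 0.132
NITROGENASE_FLUX_ALT = 0.206

#: measured CO2 uptake, mmol (g DW)-1 h-1 (uptake-negative)
CO2_UPTAKE = -0.927

#: calibrated maintenance energies, mmol ATP (g DW)-1 h-1
MAINTENANCE_PA = 64.3
MAINTENANCE_DZ = 67.2


@dataclass
class CellTypeConstraintSet:
    """Bound overrides that turn the shared model into one phenotype.

    ``fixed_fluxes`` pins reactions to exact values (lb == ub); ``None``
    values in the optional fields mean "leave the model's bound alone".
    Exchange-id sets: ``uptake_only`` -> [-1000, 0], ``export_only`` ->
    [0, 1000], ``seawater`` -> [-1000, 0] (replete medium).
    """

    name: str                                   # "diazotroph" | "photoautotroph"
    carbon_exchange: str                        # exchange id of the carbon carrier
    carbon_uptake: float | None                 # uptake flux (negative) or None
    nitrogenase_id: str
    nitrogenase_flux: float | None              # fixed value; None = free >= 0
    psii_id: str
    psii_bound: float | None                    # upper bound on PSII; None = open
    photon_exchanges: tuple[str, ...]
    photon_budget: float = PHOTON_BUDGET
    maintenance_id: str = "EN_ATP"
    maintenance_atp: float = 0.0
    uptake_only: frozenset[str] = frozenset()
    export_only: frozenset[str] = frozenset()
    seawater: frozenset[str] = frozenset()
    fixed_fluxes: dict[str, float] = field(default_factory=dict)
    objective: str = "BIOMASS"
    #: True pins carbon uptake as an equality (lb == ub); False keeps it an
    #: inequality cap [carbon_uptake, 0]
    carbon_uptake_fixed: bool = True

    def __post_init__(self) -> None:
        if self.name not in ("diazotroph", "photoautotroph"):
            raise ValueError("name must be 'diazotroph' or 'photoautotroph'")
        if self.photon_budget < 0:
            raise ValueError("photon budget must be non-negative")


def diazotroph_constraints(
    *,
    glycogen_exchange: str = "EX_glyc",
    carbon_uptake: float | None = None,
    nitrogenase_id: str = "NIT",
    nitrogenase_flux: float | None = NITROGENASE_FLUX_DEFAULT,
    psii_id: str = "PSII",
    photon_exchanges: tuple[str, ...] = ("EX_photon",),
    maintenance_atp: float = MAINTENANCE_DZ,
    maintenance_id: str = "EN_ATP",
    uptake_only: frozenset[str] = frozenset(),
    export_only: frozenset[str] = frozenset(),
    seawater: frozenset[str] = frozenset(),
    objective: str = "BIOMASS",
) -> CellTypeConstraintSet:
    """Diazotroph bounds: PSII = 0, nitrogenase fixed, glycogen-fed."""
    return CellTypeConstraintSet(
        name="diazotroph",
        carbon_exchange=glycogen_exchange,
        carbon_uptake=carbon_uptake,
        nitrogenase_id=nitrogenase_id,
        nitrogenase_flux=nitrogenase_flux,
        psii_id=psii_id,
        psii_bound=0.0,
        photon_exchanges=photon_exchanges,
        maintenance_atp=maintenance_atp,
        maintenance_id=maintenance_id,
        uptake_only=uptake_only,
        export_only=export_only,
        seawater=seawater,
        objective=objective,
    )


def photoautotroph_constraints(
    *,
    co2_exchange: str = "EX_co2",
    carbon_uptake: float | None = CO2_UPTAKE,
    nitrogenase_id: str = "NIT",
    psii_id: str = "PSII",
    photon_exchanges: tuple[str, ...] = ("EX_photon",),
    maintenance_atp: float = MAINTENANCE_PA,
    maintenance_id: str = "EN_ATP",
    uptake_only: frozenset[str] = frozenset(),
    export_only: frozenset[str] = frozenset(),
    seawater: frozenset[str] = frozenset(),
    objective: str = "BIOMASS",
) -> CellTypeConstraintSet:
    """Photoautotroph bounds: nitrogenase = 0, CO2 uptake fixed."""
    return CellTypeConstraintSet(
        name="photoautotroph",
        carbon_exchange=co2_exchange,
        carbon_uptake=carbon_uptake,
        nitrogenase_id=nitrogenase_id,
        nitrogenase_flux=0.0,
        psii_id=psii_id,
        psii_bound=None,
        photon_exchanges=photon_exchanges,
        maintenance_atp=maintenance_atp,
        maintenance_id=maintenance_id,
        uptake_only=uptake_only,
        export_only=export_only,
        seawater=seawater,
        objective=objective,
    )


def _get_reaction(model: cobra.Model, rxn_id: str) -> cobra.Reaction:
    try:
        return model.reactions.get_by_id(rxn_id)
    except KeyError as exc:
        raise KeyError(f"constraint set references absent reaction {rxn_id!r}") from exc


def apply_celltype(
    model: cobra.Model, spec: CellTypeConstraintSet, copy: bool = True
) -> cobra.Model:
    """Apply a phenotype's bound overrides; idempotent.

    Seawater exchanges open to uptake, the uptake-only/export-only sets are
    clamped to half-lines, PSII/nitrogenase/carbon fixes are installed,
    maintenance becomes a lower bound on EN_ATP, and the photon supply is
    capped at the shared budget.  With a single photon exchange the cap is
    its lower bound; with separate PSI/PSII photon exchanges a joint solver
    constraint ``sum(uptake) >= -budget`` implements the shared budget.
    """
    if copy:
        model = model.copy()

    for ex in spec.seawater:
        _get_reaction(model, ex).bounds = (-1000.0, 0.0)
    for ex in spec.uptake_only:
        _get_reaction(model, ex).bounds = (-1000.0, 0.0)
    for ex in spec.export_only:
        _get_reaction(model, ex).bounds = (0.0, 1000.0)

    if spec.psii_bound is not None:
        _get_reaction(model, spec.psii_id).bounds = (0.0, spec.psii_bound)

    nit = _get_reaction(model, spec.nitrogenase_id)
    if spec.nitrogenase_flux is None:
        nit.bounds = (0.0, 1000.0)
    else:
        nit.bounds = (spec.nitrogenase_flux, spec.nitrogenase_flux)

    carbon = _get_reaction(model, spec.carbon_exchange)
    if spec.carbon_uptake is None:
        carbon.bounds = (-1000.0, 0.0)
    else:
        if spec.carbon_uptake > 0:
            raise ValueError("carbon uptake must be given uptake-negative")
        if spec.carbon_uptake_fixed:
            carbon.bounds = (spec.carbon_uptake, spec.carbon_uptake)
        else:
            carbon.bounds = (spec.carbon_uptake, 0.0)

    maint = _get_reaction(model, spec.maintenance_id)
    if spec.maintenance_atp > maint.upper_bound:
        raise ValueError(
            f"maintenance lower bound {spec.maintenance_atp} exceeds upper bound "
            f"{maint.upper_bound} of {spec.maintenance_id}"
        )
    maint.lower_bound = spec.maintenance_atp

    for rxn_id, value in spec.fixed_fluxes.items():
        _get_reaction(model, rxn_id).bounds = (value, value)

    photons = [_get_reaction(model, ex) for ex in spec.photon_exchanges]
    if len(photons) == 1:
        photons[0].bounds = (-spec.photon_budget, 0.0)
    else:
        for rxn in photons:
            rxn.bounds = (-spec.photon_budget, 0.0)
        name = "photon_budget"
        if name in model.constraints:
            model.remove_cons_vars([model.constraints[name]])
        joint = model.problem.Constraint(
            sum(r.flux_expression for r in photons),
            lb=-spec.photon_budget, ub=0.0, name=name,
        )
        model.add_cons_vars([joint])

    if spec.objective in model.reactions:
        model.objective = spec.objective
    model.id = f"{model.id}__{spec.name}" if not model.id.endswith(spec.name) else model.id
    return model


def unconstrained_variant(spec: CellTypeConstraintSet) -> CellTypeConstraintSet:
    """Nutrient-unlimited copy of a phenotype.

    The partner-supplied substrate (glycogen for the diazotroph, ammonium
    for the photoautotroph) is opened to [-1000, 0] and the fixed-rate
    carbon/nitrogenase equalities are released to inequality bounds; applying
    it to an already-unconstrained set is a no-op.
    """
    if spec.name == "diazotroph":
        # the partner-supplied glycogen opens fully; nitrogenase becomes free
        return replace(spec, carbon_uptake=None, nitrogenase_flux=None)
    # ammonium is already uptake-only at [-1000, 0]; the CO2 equality is
    # released to an inequality cap at the measured rate
    return replace(spec, carbon_uptake_fixed=False, nitrogenase_flux=0.0)
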