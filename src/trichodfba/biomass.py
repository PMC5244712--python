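"""Build the biomass formation equation from macromolecular composition.

The organism's dry weight is decomposed into macromolecule pools (protein,
carbohydrate, DNA, RNA, lipid, pigments, cyanophycin, a soluble pool).  Each
pool is produced by a lumped condensation reaction from its monomers; the
pool's molar mass follows from the monomer profile minus condensation water,
and the biomass coefficient of pool *m* is

    coefficient_m  [mmol (g DW)-1]  =  mass_fraction_m / molar_mass_m

with mass fractions measured in g (g DW)-1 and molar masses in g mmol-1.
Pools assayed as subsets of another pool (phycoerythrin and cyanophycin
within protein; phycocyanin and chlorophyll within lipid) are subtracted
from their parent's mass before conversion so nothing is counted twice.

The assembled biomass reaction consumes every pool at its coefficient plus a
growth-associated maintenance (GAM) ATP hydrolysis of 544 mmol ATP (g DW)-1,
and produces 1 g DW of biomass.

Macromolecule species use the residue-unit convention standard in
genome-scale reconstructions: "1 mmol of protein" means 1 mmol of condensed
residues, whose molar mass is the profile-weighted mean residue mass.  Mass
fractions are used as printed by default (columns need not close to 1 g/g);
``normalize=True`` rescales them to unit total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra

__all__ = [
    "WATER_MASS",
    "AMINO_ACID_MASS",
    "NUCLEOTIDE_MASS",
    "DEOXYNUCLEOTIDE_MASS",
    "MONOMER_MASS",
    "BiomassComposition",
    "BiomassEquation",
    "default_composition",
    "build_macromolecule_reactions",
    "composition_to_coefficients",
    "assemble_biomass_reaction",
]

#: average molar mass of water, g/mol
WATER_MASS = 18.015

#: free (un-condensed) average molar masses, g/mol
AMINO_ACID_MASS = {
    "ala": 89.09, "arg": 174.20, "asn": 132.12, "asp": 133.10,
    "cys": 121.16, "gln": 146.15, "glu": 147.13, "gly": 75.07,
    "his": 155.16, "ile": 131.17, "leu": 131.17, "lys": 146.19,
    "met": 149.21, "phe": 165.19, "pro": 115.13, "ser": 105.09,
    "thr": 119.12, "trp": 204.23, "tyr": 181.19, "val": 117.15,
}
NUCLEOTIDE_MASS = {"amp": 347.22, "gmp": 363.22, "cmp": 323.20, "ump": 324.18}
DEOXYNUCLEOTIDE_MASS = {"damp": 331.22, "dgmp": 347.22, "dcmp": 307.20, "dtmp": 322.21}

#: one flat lookup used by the condensation builder
MONOMER_MASS: dict[str, float] = {
    **AMINO_ACID_MASS,
    **NUCLEOTIDE_MASS,
    **DEOXYNUCLEOTIDE_MASS,
    "glucose": 180.16,
    # lumped monomers for pools measured as single species
    "soluble_unit": 300.0,
    "pigment_unit": 893.5,        # chlorophyll a
    "phycobilin_unit": 586.7,     # open-chain tetrapyrrole chromophore
    "lipid_unit": 750.0,          # mean acyl-glycerolipid
}

_PROFILE_TOL = 1e-6


@dataclass
class BiomassComposition:
    """Measured macromolecular composition of the biomass.

    ``mass_fraction`` is g per g DW per macromolecule; ``subset_of`` marks
    pools assayed inside another pool; the monomer profiles are mole
    fractions summing to one.
    """

    mass_fraction: dict[str, float]
    subset_of: dict[str, str] = field(default_factory=dict)
    amino_acid_fractions: dict[str, float] = field(default_factory=dict)
    fatty_acid_fractions: dict[str, float] = field(default_factory=dict)
    lipid_subclass_ratios: dict[str, float] = field(default_factory=dict)
    #: explicit monomer profile per macromolecule (overrides the defaults)
    monomer_profiles: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, frac in self.mass_fraction.items():
            if frac < 0:
                raise ValueError(f"negative mass fraction for {name!r}")
        for label, profile in self._profiles():
            total = sum(profile.values())
            if profile and abs(total - 1.0) > 1e-3:
                raise ValueError(f"{label} profile sums to {total:.4f}, not 1")

    def _profiles(self):
        yield "amino acid", self.amino_acid_fractions
        yield "fatty acid", self.fatty_acid_fractions
        yield "lipid subclass", self.lipid_subclass_ratios
        for name, prof in self.monomer_profiles.items():
            yield name, prof

    def effective_mass_fraction(self, normalize: bool = False) -> dict[str, float]:
        """Mass fractions with subset pools subtracted from their parents."""
        eff = dict(self.mass_fraction)
        for child, parent in self.subset_of.items():
            if child not in eff:
                continue
            if parent not in eff:
                raise ValueError(f"{child!r} is a subset of unknown pool {parent!r}")
            eff[parent] -= eff[child]
            if eff[parent] < 0:
                raise ValueError(
                    f"subset {child!r} exceeds its parent {parent!r} mass fraction"
                )
        if normalize:
            total = sum(eff.values())
            eff = {k: v / total for k, v in eff.items()}
        return eff


@dataclass
class BiomassEquation:
    """Stoichiometric coefficients of the biomass formation reaction."""

    coefficients: dict[str, float]          # macromolecule -> mmol (g DW)-1
    gam: float = 544.0                      # mmol ATP (g DW)-1

    def __post_init__(self) -> None:
        for name, coeff in self.coefficients.items():
            if coeff < 0:
                raise ValueError(f"negative biomass coefficient for {name!r}")


# Mass fractions as printed for the N2-grown (default) and KNO3-grown columns.
_MASS_FRACTION = {
    "N2": {
        "protein": 0.289,
        "phycoerythrin": 1.54e-2,
        "cyanophycin": 3.80e-2,
        "carbohydrate": 0.265,
        "rna": 9.18e-2,
        "dna": 4.28e-2,
        "lipid": 0.137,
        "phycocyanin": 2.60e-2,
        "chlorophyll": 8.91e-3,
        "soluble_pool": 2.86e-2,
    },
    "KNO3": {
        "protein": 0.438,
        "phycoerythrin": 3.67e-2,
        "cyanophycin": 9.33e-2,
        "carbohydrate": 0.351,
        "rna": 6.51e-2,
        "dna": 2.40e-2,
        "lipid": 7.40e-2,
        "phycocyanin": 3.67e-2,
        "chlorophyll": 0.424e-3,
        "soluble_pool": 2.86e-2,
    },
}

_SUBSET_OF = {
    "phycoerythrin": "protein",
    "cyanophycin": "protein",
    "phycocyanin": "lipid",
    "chlorophyll": "lipid",
}

# Representative monomer profiles.  The measured amino-acid and fatty-acid
# distributions appear only in a supplement that does not accompany the text,
# so these are synthetic stand-ins: a typical cyanobacterial amino-acid usage
# and a 16:0/16:1/18:1-dominated acyl profile.
_SYNTHETIC_AA_PROFILE = {
    "ala": 0.105, "arg": 0.05, "asn": 0.04, "asp": 0.055, "cys": 0.01,
    "gln": 0.04, "glu": 0.075, "gly": 0.09, "his": 0.02, "ile": 0.055,
    "leu": 0.09, "lys": 0.05, "met": 0.02, "phe": 0.04, "pro": 0.045,
    "ser": 0.055, "thr": 0.055, "trp": 0.01, "tyr": 0.03, "val": 0.065,
}
_SYNTHETIC_FA_PROFILE = {"16:0": 0.45, "16:1": 0.25, "18:0": 0.05, "18:1": 0.25}

_DEFAULT_PROFILES = {
    "protein": _SYNTHETIC_AA_PROFILE,
    "carbohydrate": {"glucose": 1.0},
    "rna": {"amp": 0.25, "gmp": 0.3, "cmp": 0.25, "ump": 0.2},
    "dna": {"damp": 0.33, "dgmp": 0.17, "dcmp": 0.17, "dtmp": 0.33},
    "cyanophycin": {"arg": 0.5, "asp": 0.5},  # polymerised Arg:Asp 1:1
    "lipid": {"lipid_unit": 1.0},
    "phycoerythrin": {"phycobilin_unit": 1.0},
    "phycocyanin": {"phycobilin_unit": 1.0},
    "chlorophyll": {"pigment_unit": 1.0},
    "soluble_pool": {"soluble_unit": 1.0},
}


def default_composition(nitrogen_source: str = "N2") -> BiomassComposition:
    """The measured composition table for the chosen nitrogen source.

    The N2-grown column is the model's default average biomass; the
    KNO3-grown column is selectable.
    """
    if nitrogen_source not in _MASS_FRACTION:
        raise ValueError(f"nitrogen_source must be one of {sorted(_MASS_FRACTION)}")
    return BiomassComposition(
        mass_fraction=dict(_MASS_FRACTION[nitrogen_source]),
        subset_of=dict(_SUBSET_OF),
        amino_acid_fractions=dict(_SYNTHETIC_AA_PROFILE),
        fatty_acid_fractions=dict(_SYNTHETIC_FA_PROFILE),
        lipid_subclass_ratios={"SQDG": 0.25, "MGDG": 0.35, "DGDG": 0.25, "PGP": 0.15},
        monomer_profiles={k: dict(v) for k, v in _DEFAULT_PROFILES.items()},
    )


def _residue_mass(profile: dict[str, float]) -> float:
    """Profile-weighted mean residue (condensed monomer) mass in g/mmol."""
    mass = 0.0
    for monomer, frac in profile.items():
        if monomer not in MONOMER_MASS:
            raise KeyError(f"unknown monomer mass for {monomer!r}")
        mass += frac * (MONOMER_MASS[monomer] - WATER_MASS)
    # g/mol -> g/mmol
    return mass / 1000.0


def build_macromolecule_reactions(
    composition: BiomassComposition,
) -> tuple[list[cobra.Reaction], dict[str, float]]:
    """One condensation reaction per macromolecule pool, plus molar masses.

    Each reaction consumes monomers in the profile's mole fractions and
    releases one water per condensed bond, producing 1 (m)mol of residue
    units of the pool; the returned molar masses are in g mmol-1.
    """
    reactions: list[cobra.Reaction] = []
    molar_masses: dict[str, float] = {}
    cache: dict[str, cobra.Metabolite] = {}

    def species(met_id: str, **kw) -> cobra.Metabolite:
        if met_id not in cache:
            cache[met_id] = cobra.Metabolite(met_id, compartment="c", **kw)
        return cache[met_id]

    for pool in composition.mass_fraction:
        profile = composition.monomer_profiles.get(
            pool, _DEFAULT_PROFILES.get(pool)
        )
        if profile is None:
            raise KeyError(f"no monomer profile for macromolecule {pool!r}")
        molar_masses[pool] = _residue_mass(profile)
        rxn = cobra.Reaction(f"MACRO_{pool}", name=f"{pool} condensation",
                             lower_bound=0.0, upper_bound=1000.0)
        mets: dict[cobra.Metabolite, float] = {
            species(f"{pool}_c", name=pool): 1.0,
            species("h2o_c", name="water", formula="H2O"): 1.0,
        }
        for monomer, frac in profile.items():
            if frac == 0:
                continue
            mets[species(f"{monomer}_c", name=monomer)] = -frac
        rxn.add_metabolites(mets)
        rxn.notes["category"] = "macromolecule"
        reactions.append(rxn)
    return reactions, molar_masses


def composition_to_coefficients(
    composition: BiomassComposition,
    molar_masses: dict[str, float],
    gam: float = 544.0,
    normalize: bool = False,
) -> BiomassEquation:
    """Convert (subset-adjusted) mass fractions to mmol (g DW)-1 coefficients."""
    effective = composition.effective_mass_fraction(normalize=normalize)
    coefficients = {}
    for pool, frac in effective.items():
        if pool not in molar_masses:
            raise KeyError(f"no molar mass for macromolecule {pool!r}")
        coefficients[pool] = frac / molar_masses[pool] if frac else 0.0
    return BiomassEquation(coefficients=coefficients, gam=gam)


def assemble_biomass_reaction(
    equation: BiomassEquation, model: cobra.Model | None = None
) -> cobra.Reaction:
    """The single biomass formation reaction: pools + GAM ATP -> 1 g DW.

    When ``model`` is given, macromolecule/cofactor species are looked up in
    it (raising if absent); otherwise detached species are created.
    """
    if not equation.coefficients:
        raise ValueError("empty biomass equation")

    def species(met_id: str, **kw) -> cobra.Metabolite:
        if model is not None:
            try:
                return model.metabolites.get_by_id(met_id)
            except KeyError as exc:
                raise KeyError(f"species {met_id!r} missing from model") from exc
        return cobra.Metabolite(met_id, compartment="c", **kw)

    rxn = cobra.Reaction("BIOMASS", name="biomass formation",
                         lower_bound=0.0, upper_bound=1000.0)
    mets: dict[cobra.Metabolite, float] = {}
    for pool, coeff in equation.coefficients.items():
        if coeff:
            mets[species(f"{pool}_c", name=pool)] = -coeff
    gam = equation.gam
    mets[species("atp_c", name="ATP")] = -gam
    mets[species("h2o_c", name="water", formula="H2O")] = -gam
    mets[species("adp_c", name="ADP")] = gam
    mets[species("pi_c", name="phosphate")] = gam
    mets[species("biomass_c", name="biomass")] = 1.0
    rxn.add_metabolites(mets)
    rxn.notes["category"] = "biomass"
    if model is not None:
        model.add_reactions([rxn])
    return rxn
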