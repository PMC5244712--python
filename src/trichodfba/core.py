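"""Load, represent and validate the genome-scale metabolic model.

The in-memory container is a :class:`cobra.Model`; this module adds the
bookkeeping the reconstruction carries on top of plain stoichiometry:

* a reaction *category* (``biomass``, ``macromolecule``, ``exchange``,
  ``transport`` or ``metabolic``) stored in ``Reaction.notes["category"]``,
* a curation *confidence* score (1, 2 or 4; transporters are proteomics-backed
  fours) in ``Reaction.notes["confidence"]``,

and the structural checks run on the finished reconstruction: category
statistics, element/charge balancing, directional dead-end detection and the
closed-exchange futile-cycle (type III loop) screen.

Models can be read from SBML (level 3 / FBC, via cobrapy) or from a delimited
tabular dialect mirroring the supplement's reaction and metabolite listings.
The tabular dialect is two tab-separated files in one directory:

``metabolites.tsv``
    columns ``id, name, formula, charge, compartment``
``reactions.tsv``
    columns ``id, name, equation, lower_bound, upper_bound, gpr, category,
    confidence`` where ``equation`` uses metabolite ids, e.g.
    ``2 A_c + B_c --> C_e`` or ``A_c <=> B_c``.

Flux bounds use the reconstruction's literal +/-1000 mmol (g DW)-1 h-1
sentinel for "unbounded"; it is never replaced by infinity so listings
round-trip bit-stably.  The sign convention for exchanges is uptake negative,
secretion positive.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import cobra
import pandas as pd
from cobra.util.array import create_stoichiometric_matrix

__all__ = [
    "CATEGORIES",
    "BOUND_SENTINEL",
    "ModelStatistics",
    "BalanceViolation",
    "DeadEndReport",
    "load_model",
    "load_tabular",
    "write_tabular",
    "reaction_category",
    "set_reaction_category",
    "model_statistics",
    "check_balances",
    "find_dead_ends",
    "detect_futile_cycles",
    "stoichiometric_matrix",
]

CATEGORIES = ("biomass", "macromolecule", "exchange", "transport", "metabolic")

#: literal "unbounded" sentinel used throughout the reconstruction
BOUND_SENTINEL = 1000.0

_ARROWS = ("<=>", "<->", "-->", "->", "<--", "<-")


class ModelParseError(ValueError):
    """Raised when a tabular listing cannot be interpreted."""


@dataclass
class ModelStatistics:
    """Reaction counts by category plus gene and metabolite totals."""

    reactions: dict[str, int]
    n_reactions: int
    n_genes: int
    n_metabolites: int

    def as_dict(self) -> dict:
        d = dict(self.reactions)
        d.update(
            total_reactions=self.n_reactions,
            genes=self.n_genes,
            metabolites=self.n_metabolites,
        )
        return d


@dataclass
class BalanceViolation:
    """A reaction failing element or charge conservation.

    ``imbalance`` maps element symbol (or ``"charge"``) to the net excess on
    the product side; ``uncheckable`` marks reactions touching a metabolite
    with no formula, which are *not* claimed unbalanced.
    """

    reaction_id: str
    imbalance: dict[str, float] = field(default_factory=dict)
    uncheckable: bool = False


@dataclass
class DeadEndReport:
    """Directional dead-end metabolites and the reactions they strand."""

    metabolites: set[str]
    stranded_reactions: set[str]

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_stranded(self) -> int:
        return len(self.stranded_reactions)


# ---------------------------------------------------------------------------
# categories
# ---------------------------------------------------------------------------

def reaction_category(reaction: cobra.Reaction) -> str:
    """Return the curated category, inferring one when the note is absent.

    Inference (for models read from bare SBML): boundary reactions are
    ``exchange``; reactions spanning two compartments are ``transport``;
    anything whose id starts with ``BIOMASS``/``biomass`` is ``biomass``;
    the rest are ``metabolic``.
    """
    cat = reaction.notes.get("category")
    if cat in CATEGORIES:
        return cat
    if reaction.boundary:
        return "exchange"
    if reaction.id.lower().startswith("biomass"):
        return "biomass"
    if len({m.compartment for m in reaction.metabolites}) > 1:
        return "transport"
    return "metabolic"


def set_reaction_category(reaction: cobra.Reaction, category: str,
                          confidence: int | None = None) -> None:
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    reaction.notes["category"] = category
    if confidence is not None:
        reaction.notes["confidence"] = int(confidence)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def _split_terms(side: str, rxn_id: str) -> list[tuple[float, str]]:
    terms = []
    for chunk in side.split("+"):
        chunk = chunk.strip()
        if not chunk:
            continue
        m = re.match(r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S+)$", chunk)
        if m is None:
            raise ModelParseError(f"reaction {rxn_id!r}: cannot parse term {chunk!r}")
        coeff = float(m.group(1)) if m.group(1) else 1.0
        terms.append((coeff, m.group(2)))
    return terms


def parse_equation(equation: str, rxn_id: str = "?") -> tuple[dict[str, float], bool]:
    """Parse ``2 A + B --> C`` into ({A: -2, B: -1, C: 1}, reversible)."""
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise ModelParseError(f"reaction {rxn_id!r}: no arrow in equation {equation!r}")
    left, right = equation.split(arrow, 1)
    if arrow in ("<--", "<-"):
        left, right = right, left
    stoich: dict[str, float] = {}
    for sign, side in ((-1.0, left), (1.0, right)):
        for coeff, met in _split_terms(side, rxn_id):
            stoich[met] = stoich.get(met, 0.0) + sign * coeff
    return stoich, arrow in ("<=>", "<->")


def format_equation(reaction: cobra.Reaction) -> str:
    def side(items):
        parts = []
        for met, coeff in sorted(items, key=lambda kv: kv[0].id):
            c = abs(coeff)
            parts.append(met.id if c == 1 else f"{c:g} {met.id}")
        return " + ".join(parts)

    subs = [(m, c) for m, c in reaction.metabolites.items() if c < 0]
    prods = [(m, c) for m, c in reaction.metabolites.items() if c > 0]
    arrow = "<=>" if reaction.reversibility or reaction.lower_bound < 0 else "-->"
    return f"{side(subs)} {arrow} {side(prods)}".strip()


def load_tabular(directory: str | Path, model_id: str | None = None) -> cobra.Model:
    """Build a model from ``metabolites.tsv`` + ``reactions.tsv``."""
    directory = Path(directory)
    met_path = directory / "metabolites.tsv"
    rxn_path = directory / "reactions.tsv"
    for p in (met_path, rxn_path):
        if not p.exists():
            raise ModelParseError(f"missing listing {p}")
    mets = pd.read_csv(met_path, sep="\t", dtype=str).fillna("")
    rxns = pd.read_csv(rxn_path, sep="\t", dtype=str).fillna("")

    model = cobra.Model(model_id or directory.name)
    metabolites = {}
    for row in mets.itertuples(index=False):
        if row.id in metabolites:
            raise ModelParseError(f"duplicate metabolite id {row.id!r}")
        met = cobra.Metabolite(
            row.id,
            name=row.name or row.id,
            formula=row.formula or None,
            charge=int(row.charge) if row.charge not in ("", "None") else None,
            compartment=row.compartment or "c",
        )
        metabolites[row.id] = met
    model.add_metabolites(list(metabolites.values()))

    seen = set()
    reactions = []
    for row in rxns.itertuples(index=False):
        if row.id in seen:
            raise ModelParseError(f"duplicate reaction id {row.id!r}")
        seen.add(row.id)
        stoich, _ = parse_equation(row.equation, row.id)
        unknown = [m for m in stoich if m not in metabolites]
        if unknown:
            raise ModelParseError(
                f"reaction {row.id!r} references undeclared metabolite(s) {unknown}"
            )
        rxn = cobra.Reaction(
            row.id,
            name=row.name or row.id,
            lower_bound=float(row.lower_bound),
            upper_bound=float(row.upper_bound),
        )
        rxn.add_metabolites({metabolites[m]: c for m, c in stoich.items()})
        if getattr(row, "gpr", ""):
            rxn.gene_reaction_rule = row.gpr
        category = getattr(row, "category", "") or None
        if category:
            set_reaction_category(rxn, category)
        conf = getattr(row, "confidence", "")
        if conf not in ("", "None"):
            rxn.notes["confidence"] = int(float(conf))
        reactions.append(rxn)
    model.add_reactions(reactions)
    return model


def write_tabular(model: cobra.Model, directory: str | Path) -> None:
    """Write the two-file listing that :func:`load_tabular` reads back."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mets = pd.DataFrame(
        {
            "id": [m.id for m in model.metabolites],
            "name": [m.name for m in model.metabolites],
            "formula": [m.formula or "" for m in model.metabolites],
            "charge": [m.charge if m.charge is not None else "" for m in model.metabolites],
            "compartment": [m.compartment for m in model.metabolites],
        }
    )
    rxns = pd.DataFrame(
        {
            "id": [r.id for r in model.reactions],
            "name": [r.name for r in model.reactions],
            "equation": [format_equation(r) for r in model.reactions],
            "lower_bound": [r.lower_bound for r in model.reactions],
            "upper_bound": [r.upper_bound for r in model.reactions],
            "gpr": [r.gene_reaction_rule for r in model.reactions],
            "category": [reaction_category(r) for r in model.reactions],
            "confidence": [r.notes.get("confidence", "") for r in model.reactions],
        }
    )
    mets.to_csv(directory / "metabolites.tsv", sep="\t", index=False)
    rxns.to_csv(directory / "reactions.tsv", sep="\t", index=False)


def load_model(source: str | Path) -> cobra.Model:
    """Load a model from SBML (``.xml``/``.sbml``) or a tabular listing directory."""
    source = Path(source)
    if source.is_dir():
        return load_tabular(source)
    if source.suffix.lower() in (".xml", ".sbml"):
        model = cobra.io.read_sbml_model(str(source))
        for rxn in model.reactions:
            # cobra round-trips notes as strings; normalise the two we own
            if "confidence" in rxn.notes:
                try:
                    rxn.notes["confidence"] = int(float(rxn.notes["confidence"]))
                except (TypeError, ValueError):
                    pass
        return model
    raise ModelParseError(f"cannot tell model format of {source}")


def stoichiometric_matrix(model: cobra.Model):
    """Sparse stoichiometric matrix S (metabolites x reactions)."""
    return create_stoichiometric_matrix(model, array_type="lil").tocsr()


# ---------------------------------------------------------------------------
# structural statistics and checks
# ---------------------------------------------------------------------------

def model_statistics(model: cobra.Model) -> ModelStatistics:
    counts = {c: 0 for c in CATEGORIES}
    for rxn in model.reactions:
        counts[reaction_category(rxn)] += 1
    return ModelStatistics(
        reactions=counts,
        n_reactions=len(model.reactions),
        n_genes=len(model.genes),
        n_metabolites=len(model.metabolites),
    )


#: categories whose reactions are intentionally unbalanced (lumped or boundary)
BALANCE_EXEMPT = frozenset({"biomass", "macromolecule", "exchange"})


def check_balances(model: cobra.Model, tolerance: float = 1e-6) -> list[BalanceViolation]:
    """Element/charge conservation on mechanistic reactions.

    Biomass, macromolecule-condensation and exchange reactions are excluded:
    only mechanistic chemistry is expected to balance.  A reaction involving
    a metabolite without a formula is flagged ``uncheckable``.
    """
    violations = []
    for rxn in model.reactions:
        if reaction_category(rxn) in BALANCE_EXEMPT or rxn.boundary:
            continue
        if any(not met.formula for met in rxn.metabolites):
            violations.append(BalanceViolation(rxn.id, uncheckable=True))
            continue
        imbalance = rxn.check_mass_balance()
        imbalance = {k if isinstance(k, str) else "charge": v
                     for k, v in imbalance.items() if abs(v) > tolerance}
        if imbalance:
            violations.append(BalanceViolation(rxn.id, imbalance=imbalance))
    return violations


def find_dead_ends(model: cobra.Model) -> DeadEndReport:
    """Directional dead-end metabolites and the reactions they strand.

    A metabolite is a dead end iff, across all reactions and respecting the
    bound-allowed directions, it can only ever be produced or only ever be
    consumed.  Any reaction touching a dead-end metabolite cannot carry
    steady-state flux through it and is reported as stranded.
    """
    dead = set()
    for met in model.metabolites:
        producible = consumable = False
        for rxn in met.reactions:
            coeff = rxn.metabolites[met]
            if (coeff > 0 and rxn.upper_bound > 0) or (coeff < 0 and rxn.lower_bound < 0):
                producible = True
            if (coeff < 0 and rxn.upper_bound > 0) or (coeff > 0 and rxn.lower_bound < 0):
                consumable = True
            if producible and consumable:
                break
        if not (producible and consumable):
            dead.add(met.id)
    stranded = {
        rxn.id
        for met_id in dead
        for rxn in model.metabolites.get_by_id(met_id).reactions
    }
    return DeadEndReport(metabolites=dead, stranded_reactions=stranded)


def detect_futile_cycles(model: cobra.Model, tolerance: float = 1e-6,
                         reactions: Iterable[str] | None = None) -> list[str]:
    """Reactions able to carry flux with every exchange closed (type III loops).

    All boundary reactions are fixed to zero and flux variability of the
    internal reactions is evaluated with a zero objective requirement; any
    reaction whose [min, max] interval has width above ``tolerance`` sits on
    a thermodynamically infeasible internal loop.  An infeasible closed model
    (possible only through inconsistent fixed bounds) yields a warning and an
    empty result, since the all-zero flux vector is otherwise always feasible.
    """
    from cobra.flux_analysis import flux_variability_analysis

    closed = model.copy()
    for rxn in closed.boundary:
        rxn.bounds = (0.0, 0.0)
    closed.objective = closed.problem.Objective(0)
    internal = [r for r in closed.reactions if not r.boundary]
    if reactions is not None:
        wanted = set(reactions)
        internal = [r for r in internal if r.id in wanted]
    try:
        fva = flux_variability_analysis(
            closed, reaction_list=internal, fraction_of_optimum=0.0, processes=1
        )
    except Exception as exc:  # infeasible closed model: bad fixed bounds
        warnings.warn(
            f"closed-exchange model infeasible ({exc}); check fixed nonzero bounds",
            stacklevel=2,
        )
        return []
    width = fva["maximum"] - fva["minimum"]
    return sorted(width.index[width > tolerance])
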