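"""Fe(III)-reduction geochemistry and reaction bioenergetics.

Two jobs live here.  First, bookkeeping of the enrichment Fe chemistry:
percent of total Fe(III) reduced (100 * Fe2+ / FeTOT) and the >10%
selection rule with per-mineral / per-carbon tallies.  Second,
activity-corrected reaction energetics for the redox couples relevant to
iron-oxide enrichments (acetate or lactate oxidation coupled to goethite
reduction, lactate oxidation coupled to sulfate reduction):

    yield = -(dG0 + R T ln Q) / |nu_basis|        [kJ per mole of donor]

with dG0 assembled from standard formation energies, activities equated
to molar concentrations, H+ at 10^-pH, and solids/water at unit
activity.  The sign convention reports thermodynamically favorable
reactions as positive energy yields.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "R_KJ",
    "SpeciesData",
    "ThermoTable",
    "ReactionSpec",
    "ConditionSet",
    "BalanceReport",
    "EnrichmentRecord",
    "UnbalancedReactionError",
    "REACTIONS",
    "CONDITIONS",
    "percent_reduced",
    "select_reduced",
    "validate_reaction",
    "delta_g_prime",
    "records_to_frame",
    "read_enrichment_table",
    "write_enrichment_table",
]

#: Gas constant, kJ mol^-1 K^-1.
R_KJ = 8.31446e-3

MINERALS = ("ferrihydrite", "goethite", "hematite")
CARBONS = ("acetate", "lactate", "glucose", "mixed")


class UnbalancedReactionError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesData:
    name: str
    elements: dict
    charge: int
    phase: str  # aq | s | l | conv
    dgf: float  # kJ/mol, 25 C
    provenance: str = ""


class ThermoTable:
    """Species -> formation energy / composition lookup."""

    def __init__(self, species: dict[str, SpeciesData]):
        self.species = dict(species)
        for required in ("H+", "H2O"):
            if required not in self.species:
                raise ValueError(f"thermo table must define {required}")

    def __getitem__(self, name: str) -> SpeciesData:
        try:
            return self.species[name]
        except KeyError:
            raise KeyError(f"species {name!r} missing from thermo table") from None

    def __contains__(self, name: str) -> bool:
        return name in self.species

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThermoTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "ThermoTable":
        species = {
            name: SpeciesData(
                name=name,
                elements=dict(entry.get("elements", {})),
                charge=int(entry.get("charge", 0)),
                phase=str(entry.get("phase", "aq")),
                dgf=float(entry["dgf"]),
                provenance=str(entry.get("provenance", "")),
            )
            for name, entry in raw["species"].items()
        }
        return cls(species)

    @classmethod
    def default(cls) -> "ThermoTable":
        ref = resources.files("trflptools.data").joinpath("thermo_table.yaml")
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


@dataclass(frozen=True)
class ReactionSpec:
    """Signed stoichiometry over species names: products positive,
    reactants negative.  `basis` names the electron donor the per-mole
    yield is normalized to."""

    name: str
    stoichiometry: dict
    basis: str
    electrons: int | None = None

    def __post_init__(self):
        if self.basis not in self.stoichiometry:
            raise ValueError(f"basis species {self.basis!r} not in stoichiometry")

    def scaled(self, factor: float) -> "ReactionSpec":
        return ReactionSpec(
            self.name,
            {sp: c * factor for sp, c in self.stoichiometry.items()},
            self.basis,
            self.electrons,
        )


@dataclass
class ConditionSet:
    """In-situ conditions: pH, temperature, and molar concentrations of
    the aqueous species (solids and water are at unit activity)."""

    pH: float
    temperature: float = 298.15
    concentrations: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError("pH outside [0, 14]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        for name, c in self.concentrations.items():
            if c <= 0:
                raise ValueError(f"concentration of {name} must be positive")

    def activity(self, sp: SpeciesData) -> float:
        if sp.name == "H+":
            return 10.0 ** (-self.pH)
        if sp.phase in ("s", "l", "conv"):
            return 1.0
        try:
            return self.concentrations[sp.name]
        except KeyError:
            raise KeyError(
                f"no concentration given for aqueous species {sp.name!r}"
            ) from None


@dataclass(frozen=True)
class BalanceReport:
    element_residuals: dict
    charge_residual: float
    degenerate: bool = False

    @property
    def balanced(self) -> bool:
        tol = 1e-9
        return abs(self.charge_residual) < tol and all(
            abs(v) < tol for v in self.element_residuals.values()
        )


def validate_reaction(rxn: ReactionSpec, table: ThermoTable | None = None) -> BalanceReport:
    """Element/charge bookkeeping; residuals are products minus reactants."""
    table = table or ThermoTable.default()
    elements: Counter = Counter()
    charge = 0.0
    for name, coeff in rxn.stoichiometry.items():
        sp = table[name]
        for el, n in sp.elements.items():
            elements[el] += coeff * n
        charge += coeff * sp.charge
    residuals = {el: v for el, v in elements.items() if abs(v) > 1e-9}
    return BalanceReport(
        element_residuals=residuals,
        charge_residual=charge if abs(charge) > 1e-9 else 0.0,
        degenerate=not any(c != 0 for c in rxn.stoichiometry.values()),
    )


def delta_g_prime(
    rxn: ReactionSpec,
    table: ThermoTable | None = None,
    cond: ConditionSet | None = None,
) -> float:
    """Activity-corrected energy yield, kJ per mole of basis species.

    yield = -(dG0 + R T ln Q) / |nu_basis|; positive values are
    thermodynamically favorable.
    """
    table = table or ThermoTable.default()
    if cond is None:
        raise ValueError("a ConditionSet is required")
    report = validate_reaction(rxn, table)
    if not report.balanced:
        raise UnbalancedReactionError(
            f"reaction {rxn.name!r} unbalanced: elements {report.element_residuals}, "
            f"charge {report.charge_residual}"
        )
    dg0 = sum(coeff * table[name].dgf for name, coeff in rxn.stoichiometry.items())
    ln_q = sum(
        coeff * math.log(cond.activity(table[name]))
        for name, coeff in rxn.stoichiometry.items()
        if table[name].phase == "aq"
    )
    dg = dg0 + R_KJ * cond.temperature * ln_q
    nu_basis = abs(rxn.stoichiometry[rxn.basis])
    if nu_basis == 0:
        raise ValueError("basis species has zero stoichiometric coefficient")
    return -dg / nu_basis


# ---------------------------------------------------------------------------
# Built-in reactions and enrichment conditions

REACTIONS = {
    # acetate- + 8 FeOOH + 15 H+ -> 2 HCO3- + 8 Fe2+ + 12 H2O
    "acetate_goethite": ReactionSpec(
        "acetate_goethite",
        {
            "acetate-": -1, "goethite": -8, "H+": -15,
            "HCO3-": 2, "Fe2+": 8, "H2O": 12,
        },
        basis="acetate-",
        electrons=8,
    ),
    # lactate- + 4 FeOOH + 7 H+ -> acetate- + HCO3- + 4 Fe2+ + 6 H2O
    "lactate_goethite": ReactionSpec(
        "lactate_goethite",
        {
            "lactate-": -1, "goethite": -4, "H+": -7,
            "acetate-": 1, "HCO3-": 1, "Fe2+": 4, "H2O": 6,
        },
        basis="lactate-",
        electrons=4,
    ),
    # lactate- + 1/2 SO42- -> acetate- + HCO3- + 1/2 HS- + 1/2 H+
    "lactate_sulfate": ReactionSpec(
        "lactate_sulfate",
        {
            "lactate-": -1, "SO42-": -0.5,
            "acetate-": 1, "HCO3-": 1, "HS-": 0.5, "H+": 0.5,
        },
        basis="lactate-",
        electrons=4,
    ),
    # half reactions (electron bookkeeping species at unit activity)
    "lactate_oxidation_half": ReactionSpec(
        "lactate_oxidation_half",
        {
            "lactate-": -1, "H2O": -2,
            "acetate-": 1, "HCO3-": 1, "H+": 5, "e-": 4,
        },
        basis="lactate-",
        electrons=4,
    ),
    "goethite_reduction_half": ReactionSpec(
        "goethite_reduction_half",
        {
            "goethite": -1, "H+": -3, "e-": -1,
            "Fe2+": 1, "H2O": 2,
        },
        basis="goethite",
        electrons=1,
    ),
}

#: The enrichment-medium conditions the reaction energies are quoted at.
CONDITIONS = {
    "acetate_enrichment": ConditionSet(
        pH=7.3,
        concentrations={"acetate-": 10e-3, "Fe2+": 5e-6, "HCO3-": 10e-3},
    ),
    "lactate_enrichment": ConditionSet(
        pH=7.3,
        concentrations={
            "lactate-": 10e-3, "acetate-": 1e-6, "Fe2+": 5e-6,
            "HCO3-": 10e-3, "SO42-": 200e-6, "HS-": 1e-6,
        },
    ),
}


# ---------------------------------------------------------------------------
# Enrichment Fe chemistry

@dataclass
class EnrichmentRecord:
    """One enrichment culture: condition plus measured Fe chemistry.
    `target_percent` carries the generator's pre-noise ground truth when
    the record is synthetic; it is None for real data."""

    sample_id: str
    mineral: str
    carbon: str
    dilution_exponent: int
    fe2_mM: float
    fetot_mM: float
    target_percent: float | None = None

    def __post_init__(self):
        if not 0 <= self.fe2_mM <= self.fetot_mM:
            raise ValueError("need 0 <= Fe(II) <= FeTOT")

    @property
    def percent_reduced(self) -> float:
        return percent_reduced(self.fe2_mM, self.fetot_mM)


def percent_reduced(fe2: float, fetot: float) -> float:
    """Percent of total Fe(III) reduced, 100 * Fe2+ / FeTOT."""
    if fetot <= 0:
        raise ValueError("FeTOT must be positive")
    if not 0 <= fe2 <= fetot:
        raise ValueError("need 0 <= Fe(II) <= FeTOT")
    return 100.0 * fe2 / fetot


def records_to_frame(records) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "mineral": r.mineral,
            "carbon": r.carbon,
            "dilution_exponent": r.dilution_exponent,
            "fe2_mM": r.fe2_mM,
            "fetot_mM": r.fetot_mM,
            "percent_reduced": r.percent_reduced,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def select_reduced(records, threshold: float = 10.0):
    """Apply the strict > threshold selection rule.

    Returns (selected records, tallies) where tallies is a DataFrame of
    counts and selection fractions per mineral and per carbon source.
    """
    records = list(records)
    selected = [r for r in records if r.percent_reduced > threshold]
    rows = []
    for factor, levels in (("mineral", MINERALS), ("carbon", CARBONS)):
        for level in levels:
            total = sum(1 for r in records if getattr(r, factor) == level)
            if total == 0:
                continue
            n_sel = sum(1 for r in selected if getattr(r, factor) == level)
            rows.append(
                {
                    "factor": factor,
                    "level": level,
                    "n_total": total,
                    "n_selected": n_sel,
                    "fraction_selected": n_sel / total,
                    "share_of_selected": (n_sel / len(selected)) if selected else 0.0,
                }
            )
    return selected, pd.DataFrame(rows)


def write_enrichment_table(records, path: str | Path, comment: str = "") -> None:
    df = records_to_frame(records)[
        ["sample_id", "mineral", "carbon", "dilution_exponent", "fe2_mM", "fetot_mM"]
    ]
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_enrichment_table(path: str | Path) -> list[EnrichmentRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        EnrichmentRecord(
            str(row.sample_id), str(row.mineral), str(row.carbon),
            int(row.dilution_exponent), float(row.fe2_mM), float(row.fetot_mM),
        )
        for row in df.itertuples()
    ]
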