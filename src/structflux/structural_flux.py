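"""Efficiency-weighted structural fluxes for a chosen biological objective.

Given the elementary modes of a network, each mode i is scored by how
efficiently it converts substrate mass into the objective:

* normalised yield of reaction k in mode i:
  ``e_i^k = c_i^k / sum_s c_{s,i} * MW_s`` where the sum runs over the
  substrate-uptake reactions and MW is the molecular weight of the
  imported substrate (g/mol).  The molecular-weight weighting makes
  yields comparable across chemically different substrates (glucose,
  lactate, amino acids, proteins, free fatty acids, ...).
* efficiency: ``eps_i = e_i^objective / sum_k |e_i^k|`` — the objective
  yield divided by the total flux investment of the mode.  Modes that do
  not produce the objective (zero or negative yield), or that take up no
  substrate at all, get efficiency zero.
* structural flux of reaction k:
  ``aSF_k = sum_i eps_i * |e_i^k| / sum_i eps_i`` — the efficiency-
  weighted mean absolute participation of the reaction over all modes.
* normalised structural flux: ``aStruF_k = aSF_k / aSF_TotalSub`` where
  aSF_TotalSub sums aSF over the substrate-uptake reactions.  This makes
  values comparable across networks of different size, e.g. between an
  unconstrained network and one restricted by gene expression.

All quantities are homogeneous of degree zero in each mode's scaling, so
they do not depend on how the elementary modes are normalised.  They are
computed in exact rational arithmetic and exposed as Fractions; convert
with ``float`` at the boundary.
"""

from __future__ import annotations

import configparser
import io
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

from structflux.em_core import ElementaryMode, ModeSet
from structflux.model_io import MetabolicModel

__all__ = [
    "ObjectiveSpec",
    "EfficiencyResult",
    "StructuralFluxTable",
    "ScanResult",
    "ObjectiveUnreachableError",
    "DEFAULT_OBJECTIVE_NAMES",
    "normalized_yields",
    "efficiency",
    "structural_fluxes",
    "objective_scan",
    "read_objective_registry",
]

#: Biological objectives shipped by default for a kidney-type organ model:
#: exchange or synthesis processes the tissue may plausibly maximise.
#: The registry config maps each name used for a given model to the
#: concrete reaction id; names absent from a model's registry are ignored.
DEFAULT_OBJECTIVE_NAMES = (
    "ammonia_excretion",
    "growth",
    "atp_maintenance",
    "glucose_production",
    "urea_excretion",
    "protein_uptake",
    "protein_breakdown",
    "lactate_uptake",
    "free_fatty_acid_uptake",
    "lysine_transport",
    "phenylalanine_transport",
)


class ObjectiveUnreachableError(RuntimeError):
    """No active mode produces the objective (all efficiencies zero)."""

    def __init__(self, objective_name: str):
        super().__init__(f"objective unreachable: {objective_name}")
        self.objective_name = objective_name


@dataclass(frozen=True)
class ObjectiveSpec:
    """A named biological objective tied to one model reaction whose
    normalised yield defines the numerator of the efficiency."""

    name: str
    objective_reaction: str

    def validate(self, model: MetabolicModel) -> None:
        if self.objective_reaction not in model.reversible:
            raise KeyError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )


@dataclass
class EfficiencyResult:
    """Per-mode yields and efficiency for one objective."""

    mode: ElementaryMode
    yields: dict[str, Fraction] | None  # None iff no substrate taken up
    substrate_weight: Fraction  # sum_s c_{s,i} * MW_s (the denominator)
    objective_yield: Fraction
    efficiency: Fraction

    @property
    def no_substrate(self) -> bool:
        return self.yields is None


@dataclass
class StructuralFluxTable:
    """Per-reaction structural fluxes for one objective and one active
    mode set (the scenario)."""

    objective: str
    scenario: str
    asf: dict[str, Fraction]
    asf_total_sub: Fraction
    astruf: dict[str, Fraction] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["reaction_id\taSF\taStruF\tobjective\tscenario"]
        for rxn, value in self.asf.items():
            lines.append(
                f"{rxn}\t{float(value):.12g}\t{float(self.astruf[rxn]):.12g}"
                f"\t{self.objective}\t{self.scenario}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "StructuralFluxTable":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        if header[:3] != ["reaction_id", "aSF", "aStruF"]:
            raise ValueError("not a structural flux table")
        asf: dict[str, Fraction] = {}
        astruf: dict[str, Fraction] = {}
        objective = scenario = ""
        for ln in lines[1:]:
            rxn, a, s, objective, scenario = ln.split("\t")
            asf[rxn] = Fraction(a)
            astruf[rxn] = Fraction(s)
        # recover the substrate total from any nonzero pair (aSF / aStruF)
        asf_total = next(
            (asf[r] / v for r, v in astruf.items() if v != 0), Fraction(0)
        )
        return cls(
            objective=objective,
            scenario=scenario,
            asf=asf,
            asf_total_sub=asf_total,
            astruf=astruf,
        )


def normalized_yields(
    mode: ElementaryMode, model: MetabolicModel
) -> tuple[dict[str, Fraction] | None, Fraction]:
    """Molecular-weight normalised yields of every reaction in a mode.

    Returns ``(yields, substrate_weight)``.  ``yields`` maps each support
    reaction to ``c^k / substrate_weight``; it is None (with weight 0)
    for modes that take up no substrate, e.g. internal futile cycles.
    A substrate reaction running in reverse (substrate produced rather
    than consumed) contributes nothing to the denominator.
    """
    if not model.substrates:
        raise ValueError("model declares no substrates with molecular weights")
    weight = Fraction(0)
    for rxn, mw in model.substrates.items():
        c = mode.coefficient(rxn)
        if c > 0:
            weight += c * mw
    if weight == 0:
        return None, Fraction(0)
    yields = {r: c / weight for r, c in mode.coefficients}
    return yields, weight


def efficiency(
    mode: ElementaryMode, model: MetabolicModel, objective: ObjectiveSpec
) -> EfficiencyResult:
    """Efficiency of one mode: objective yield over total flux investment.

    Zero for modes that take up no substrate or whose objective yield is
    zero or negative (the objective reaction absent or running backward).
    Invariant under rescaling of the mode's coefficients.
    """
    objective.validate(model)
    yields, weight = normalized_yields(mode, model)
    if yields is None:
        return EfficiencyResult(mode, None, weight, Fraction(0), Fraction(0))
    e_obj = yields.get(objective.objective_reaction, Fraction(0))
    if e_obj <= 0:
        return EfficiencyResult(mode, yields, weight, e_obj, Fraction(0))
    investment = sum(abs(v) for v in yields.values())
    return EfficiencyResult(mode, yields, weight, e_obj, e_obj / investment)


def structural_fluxes(
    modes: ModeSet | Iterable[ElementaryMode],
    model: MetabolicModel,
    objective: ObjectiveSpec,
    scenario: str = "all-modes",
) -> StructuralFluxTable:
    """Efficiency-weighted structural fluxes over an active mode set.

    Raises :class:`ObjectiveUnreachableError` when no active mode has a
    positive efficiency for the objective, and ValueError when the
    substrate-uptake structural flux is zero (aStruF undefined).
    """
    mode_list = list(modes.modes if isinstance(modes, ModeSet) else modes)
    results = [efficiency(m, model, objective) for m in mode_list]
    total_eps = sum(r.efficiency for r in results)
    if total_eps == 0:
        raise ObjectiveUnreachableError(objective.name)
    asf: dict[str, Fraction] = {r: Fraction(0) for r in model.reaction_ids}
    for res in results:
        if res.efficiency == 0 or res.yields is None:
            continue
        for rxn, e in res.yields.items():
            asf[rxn] += res.efficiency * abs(e)
    for rxn in asf:
        asf[rxn] /= total_eps
    asf_total_sub = sum(asf[s] for s in model.substrates)
    if asf_total_sub == 0:
        raise ValueError(
            "total substrate structural flux is zero; aStruF undefined"
        )
    astruf = {r: v / asf_total_sub for r, v in asf.items()}
    return StructuralFluxTable(
        objective=objective.name,
        scenario=scenario,
        asf=asf,
        asf_total_sub=asf_total_sub,
        astruf=astruf,
    )


@dataclass
class ScanResult:
    """Outcome of scoring one active mode set against many objectives."""

    tables: dict[str, StructuralFluxTable]
    unreachable: list[str]


def objective_scan(
    modes: ModeSet,
    model: MetabolicModel,
    objectives: Sequence[ObjectiveSpec],
    scenario: str = "all-modes",
) -> ScanResult:
    """One structural-flux table per reachable objective; objectives with
    no efficiency-positive mode are reported in ``unreachable`` rather
    than silently dropped."""
    if not objectives:
        raise ValueError("objective list is empty")
    tables: dict[str, StructuralFluxTable] = {}
    unreachable: list[str] = []
    for objective in objectives:
        try:
            tables[objective.name] = structural_fluxes(
                modes, model, objective, scenario=scenario
            )
        except ObjectiveUnreachableError:
            unreachable.append(objective.name)
    return ScanResult(tables=tables, unreachable=unreachable)


def read_objective_registry(text: str) -> list[ObjectiveSpec]:
    """Read an objective registry config: an ``[objectives]`` section
    mapping objective name -> model reaction id."""
    parser = configparser.ConfigParser()
    parser.optionxform = str
    parser.read_file(io.StringIO(text))
    if not parser.has_section("objectives"):
        raise ValueError("objective registry lacks an [objectives] section")
    return [
        ObjectiveSpec(name=name, objective_reaction=rxn.strip())
        for name, rxn in parser.items("objectives")
    ]
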