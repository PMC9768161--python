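"""Read, validate and write stoichiometric models in METATOOL text format.

A model is a signed, exact-rational stoichiometric table over declared
reactions and metabolites, split into reversible/irreversible reactions and
internal/external metabolites.  Coefficients are stored as
:class:`fractions.Fraction` so that downstream elementary-mode support
tests are exact and independent of float round-off.

METATOOL cannot carry substrate molecular weights, exchange-reaction
mappings or gene-reaction links, so those ride in sidecar files:

* a key-value config with ``[substrates]`` (uptake reaction -> MW in g/mol)
  and ``[exchange_map]`` (exchange reaction -> measured metabolite name);
* a two-column tab-separated gene map with header ``reaction<TAB>gene``.
"""

from __future__ import annotations

import configparser
import io
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

__all__ = [
    "MetabolicModel",
    "MetatoolParseError",
    "ModelValidationError",
    "ValidationReport",
    "ReversibleSplit",
    "parse_metatool",
    "write_metatool",
    "validate_model",
    "split_reversible",
    "read_sidecar_config",
    "read_gene_map",
    "load_model",
]

SECTION_HEADERS = ("-ENZREV", "-ENZIRREV", "-METINT", "-METEXT", "-CAT")


class MetatoolParseError(ValueError):
    """Raised when a METATOOL document violates the format contract."""


class ModelValidationError(ValueError):
    """Raised when a model violates its structural invariants."""


@dataclass
class MetabolicModel:
    """Stoichiometric network with exact-rational coefficients.

    Attributes
    ----------
    reaction_ids:
        Ordered, unique reaction identifiers.
    reversible:
        Reaction id -> bool.
    metabolite_ids:
        Ordered, unique metabolite identifiers.
    is_internal:
        Metabolite id -> bool (internal metabolites are balanced at steady
        state; external ones are sources/sinks).
    stoich:
        Sparse ``(metabolite, reaction) -> Fraction`` with nonzero entries
        only; substrates on the left of a reaction equation are negative.
    substrates:
        Uptake-exchange reaction id -> molecular weight of the imported
        substrate (g/mol, > 0).  Drives yield normalisation.
    gene_map:
        Reaction id -> set of gene symbols (possibly empty), many-to-many.
    exchange_map:
        Model exchange-reaction id -> measured-metabolite name, used to
        pair predictions with arteriovenous measurements.
    """

    reaction_ids: list[str]
    reversible: dict[str, bool]
    metabolite_ids: list[str]
    is_internal: dict[str, bool]
    stoich: dict[tuple[str, str], Fraction]
    substrates: dict[str, Fraction] = field(default_factory=dict)
    gene_map: dict[str, frozenset[str]] = field(default_factory=dict)
    exchange_map: dict[str, str] = field(default_factory=dict)

    # -- derived views -------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def internal_metabolites(self) -> list[str]:
        return [m for m in self.metabolite_ids if self.is_internal[m]]

    @property
    def external_metabolites(self) -> list[str]:
        return [m for m in self.metabolite_ids if not self.is_internal[m]]

    def coefficient(self, metabolite: str, reaction: str) -> Fraction:
        return self.stoich.get((metabolite, reaction), Fraction(0))

    def internal_matrix(self) -> list[list[Fraction]]:
        """Internal stoichiometric submatrix, rows = internal metabolites
        in declaration order, columns = reactions in declaration order."""
        rows = []
        for met in self.internal_metabolites:
            rows.append([self.coefficient(met, rxn) for rxn in self.reaction_ids])
        return rows

    def reactions_of_metabolite(self, metabolite: str) -> list[str]:
        return [r for r in self.reaction_ids if (metabolite, r) in self.stoich]

    def reactions_of_gene(self, gene: str) -> set[str]:
        """Reactions associated with a gene symbol (case-insensitive)."""
        g = gene.lower()
        return {
            rxn
            for rxn, genes in self.gene_map.items()
            if any(s.lower() == g for s in genes)
        }

    # -- invariants ----------------------------------------------------

    def check_invariants(self) -> None:
        """Raise :class:`ModelValidationError` on the first violation."""
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise ModelValidationError("duplicate reaction identifiers")
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise ModelValidationError("duplicate metabolite identifiers")
        rxn_set = set(self.reaction_ids)
        met_set = set(self.metabolite_ids)
        for (met, rxn), coeff in self.stoich.items():
            if met not in met_set:
                raise ModelValidationError(f"stoichiometry references undeclared metabolite {met!r}")
            if rxn not in rxn_set:
                raise ModelValidationError(f"stoichiometry references undeclared reaction {rxn!r}")
            if coeff == 0:
                raise ModelValidationError(f"explicit zero coefficient for ({met!r}, {rxn!r})")
        for rxn in self.substrates:
            if rxn not in rxn_set:
                raise ModelValidationError(f"substrate MW declared for undeclared reaction {rxn!r}")
            if not any(
                (met, rxn) in self.stoich
                for met in self.metabolite_ids
                if not self.is_internal[met]
            ):
                raise ModelValidationError(
                    f"substrate reaction {rxn!r} touches no external metabolite"
                )
        for rxn, mw in self.substrates.items():
            if mw <= 0:
                raise ModelValidationError(f"non-positive molecular weight for {rxn!r}")


# ---------------------------------------------------------------------------
# METATOOL parsing
# ---------------------------------------------------------------------------

_COEFF_NAME_RE = re.compile(r"^(\d+(?:\.\d+)?(?:/\d+)?)([A-Za-z_].*)$")
_NUMBER_RE = re.compile(r"^\d+(?:\.\d+)?(?:/\d+)?$")


def _parse_coefficient(text: str) -> Fraction:
    # decimals are expanded exactly: "1.5" -> 3/2
    return Fraction(text)


def _parse_term(term: str, lineno: int) -> tuple[Fraction, str]:
    """One side-term of a CAT equation: "2 A", "2A", "3/2 A" or "A"."""
    term = term.strip()
    if not term:
        raise MetatoolParseError(f"line {lineno}: empty term in equation")
    tokens = term.split()
    if len(tokens) >= 2 and _NUMBER_RE.match(tokens[0]):
        return _parse_coefficient(tokens[0]), " ".join(tokens[1:])
    if len(tokens) == 1:
        m = _COEFF_NAME_RE.match(tokens[0])
        if m:
            return _parse_coefficient(m.group(1)), m.group(2)
        return Fraction(1), tokens[0]
    raise MetatoolParseError(f"line {lineno}: cannot parse term {term!r}")


def parse_metatool(text: str) -> MetabolicModel:
    """Parse a METATOOL-format document into a :class:`MetabolicModel`.

    The five section headers ``-ENZREV``, ``-ENZIRREV``, ``-METINT``,
    ``-METEXT`` and ``-CAT`` may appear in any order; all five must be
    present.  Blank lines and ``#`` comments are ignored.  Left-hand-side
    coefficients are stored negative, right-hand-side positive; a
    metabolite appearing on both sides is stored with its net coefficient.
    """
    sections: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        stripped = line.strip()
        if not stripped:
            continue
        if stripped in SECTION_HEADERS:
            if stripped in sections:
                raise MetatoolParseError(f"line {lineno}: duplicate section {stripped}")
            sections[stripped] = []
            current = stripped
            continue
        if current is None:
            raise MetatoolParseError(f"line {lineno}: content before any section header")
        sections[current].append((lineno, stripped))

    missing = [h for h in SECTION_HEADERS if h not in sections]
    if missing:
        raise MetatoolParseError(f"missing section header(s): {', '.join(missing)}")

    def _ids(header: str) -> list[str]:
        out: list[str] = []
        for _, line in sections[header]:
            out.extend(line.split())
        return out

    rev_ids = _ids("-ENZREV")
    irr_ids = _ids("-ENZIRREV")
    met_int = _ids("-METINT")
    met_ext = _ids("-METEXT")

    reaction_ids = rev_ids + irr_ids
    seen: set[str] = set()
    for rid in reaction_ids:
        if rid in seen:
            raise MetatoolParseError(f"duplicate reaction id {rid!r}")
        seen.add(rid)
    metabolite_ids = met_int + met_ext
    seen_m: set[str] = set()
    for mid in metabolite_ids:
        if mid in seen_m:
            raise MetatoolParseError(f"duplicate metabolite id {mid!r}")
        seen_m.add(mid)

    reversible = {r: True for r in rev_ids}
    reversible.update({r: False for r in irr_ids})
    is_internal = {m: True for m in met_int}
    is_internal.update({m: False for m in met_ext})

    stoich: dict[tuple[str, str], Fraction] = {}
    rxn_set = set(reaction_ids)
    met_set = set(metabolite_ids)
    cat_seen: set[str] = set()
    for lineno, line in sections["-CAT"]:
        if ":" not in line:
            raise MetatoolParseError(f"line {lineno}: CAT line lacks ':' separator")
        rxn_id, _, equation = line.partition(":")
        rxn_id = rxn_id.strip()
        if rxn_id not in rxn_set:
            raise MetatoolParseError(f"line {lineno}: undeclared reaction {rxn_id!r}")
        if rxn_id in cat_seen:
            raise MetatoolParseError(f"line {lineno}: duplicate CAT line for {rxn_id!r}")
        cat_seen.add(rxn_id)
        if "=" not in equation:
            raise MetatoolParseError(f"line {lineno}: equation lacks '=' separator")
        lhs, _, rhs = equation.partition("=")
        for side_text, sign in ((lhs, -1), (rhs, +1)):
            side_text = side_text.strip()
            if not side_text:
                continue
            for term in side_text.split("+"):
                coeff, name = _parse_term(term, lineno)
                if name not in met_set:
                    raise MetatoolParseError(f"line {lineno}: undeclared metabolite {name!r}")
                key = (name, rxn_id)
                new = stoich.get(key, Fraction(0)) + sign * coeff
                if new == 0:
                    stoich.pop(key, None)
                else:
                    stoich[key] = new

    model = MetabolicModel(
        reaction_ids=reaction_ids,
        reversible=reversible,
        metabolite_ids=metabolite_ids,
        is_internal=is_internal,
        stoich=stoich,
    )
    model.check_invariants()
    return model


def _format_coefficient(coeff: Fraction) -> str:
    if coeff.denominator == 1:
        return str(coeff.numerator)
    return f"{coeff.numerator}/{coeff.denominator}"


def write_metatool(model: MetabolicModel) -> str:
    """Serialise a model to canonical METATOOL text.

    The output always uses the "coeff<SPACE>name" spelling, omits unit
    coefficients, and orders sections ENZREV, ENZIRREV, METINT, METEXT,
    CAT.  ``parse_metatool(write_metatool(m))`` reproduces ``m`` exactly.
    """
    model.check_invariants()
    lines: list[str] = []
    lines.append("-ENZREV")
    lines.append(" ".join(r for r in model.reaction_ids if model.reversible[r]))
    lines.append("")
    lines.append("-ENZIRREV")
    lines.append(" ".join(r for r in model.reaction_ids if not model.reversible[r]))
    lines.append("")
    lines.append("-METINT")
    lines.append(" ".join(model.internal_metabolites))
    lines.append("")
    lines.append("-METEXT")
    lines.append(" ".join(model.external_metabolites))
    lines.append("")
    lines.append("-CAT")
    for rxn in model.reaction_ids:
        lhs_terms = []
        rhs_terms = []
        for met in model.metabolite_ids:
            coeff = model.coefficient(met, rxn)
            if coeff == 0:
                continue
            mag = abs(coeff)
            term = met if mag == 1 else f"{_format_coefficient(mag)} {met}"
            (lhs_terms if coeff < 0 else rhs_terms).append(term)
        if not lhs_terms and not rhs_terms:
            continue
        lines.append(f"{rxn} : {' + '.join(lhs_terms)} = {' + '.join(rhs_terms)}")
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Structural diagnostics that are suspicious but not fatal."""

    dead_end_metabolites: list[str] = field(default_factory=list)
    zero_stoichiometry_reactions: list[str] = field(default_factory=list)
    bad_substrate_reactions: list[str] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (
            self.dead_end_metabolites
            or self.zero_stoichiometry_reactions
            or self.bad_substrate_reactions
        )

    def as_text(self) -> str:
        if self.is_clean:
            return "model OK: no structural issues found\n"
        out = []
        for met in self.dead_end_metabolites:
            out.append(f"dead-end internal metabolite: {met}")
        for rxn in self.zero_stoichiometry_reactions:
            out.append(f"reaction with all-zero stoichiometry: {rxn}")
        for rxn in self.bad_substrate_reactions:
            out.append(f"substrate reaction consuming no external metabolite: {rxn}")
        return "\n".join(out) + "\n"


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Report dead-end internal metabolites (fewer than two reactions),
    reactions with empty stoichiometry, and substrate declarations on
    reactions that do not consume an external metabolite."""
    report = ValidationReport()
    for met in model.internal_metabolites:
        if len(model.reactions_of_metabolite(met)) < 2:
            report.dead_end_metabolites.append(met)
    used = {rxn for (_, rxn) in model.stoich}
    for rxn in model.reaction_ids:
        if rxn not in used:
            report.zero_stoichiometry_reactions.append(rxn)
    for rxn in model.substrates:
        consumes_external = any(
            model.coefficient(met, rxn) < 0
            for met in model.external_metabolites
        )
        if not consumes_external:
            report.bad_substrate_reactions.append(rxn)
    return report


# ---------------------------------------------------------------------------
# Reversible splitting
# ---------------------------------------------------------------------------

REVERSE_SUFFIX = "__rev"


@dataclass
class ReversibleSplit:
    """Back-mapping from a reversible-split model to the original.

    ``direction`` maps each expanded reaction id to ``(original_id, sign)``
    where sign is +1 for the forward copy and -1 for the reverse copy.
    """

    original: MetabolicModel
    expanded: MetabolicModel
    direction: dict[str, tuple[str, int]]

    def recombine(self, expanded_vector: Mapping[str, Fraction]) -> dict[str, Fraction]:
        """Collapse a nonnegative expanded-space vector into a signed
        original-space vector.

        A vector with simultaneous flux through both directions of the
        same reversible reaction is not a meaningful single mode and is
        rejected.
        """
        out: dict[str, Fraction] = {}
        for exp_id, value in expanded_vector.items():
            if value == 0:
                continue
            if value < 0:
                raise ValueError(f"expanded-space value for {exp_id!r} is negative")
            orig, sign = self.direction[exp_id]
            if orig in out:
                raise ValueError(
                    f"vector uses both directions of reversible reaction {orig!r}"
                )
            out[orig] = sign * value
        return out


def split_reversible(model: MetabolicModel) -> ReversibleSplit:
    """Expand each reversible reaction into forward and reverse
    irreversible copies (reverse stoichiometry negated)."""
    reaction_ids: list[str] = []
    reversible: dict[str, bool] = {}
    stoich: dict[tuple[str, str], Fraction] = {}
    direction: dict[str, tuple[str, int]] = {}
    for rxn in model.reaction_ids:
        reaction_ids.append(rxn)
        reversible[rxn] = False
        direction[rxn] = (rxn, +1)
        for met in model.metabolite_ids:
            coeff = model.coefficient(met, rxn)
            if coeff != 0:
                stoich[(met, rxn)] = coeff
        if model.reversible[rxn]:
            rev_id = rxn + REVERSE_SUFFIX
            reaction_ids.append(rev_id)
            reversible[rev_id] = False
            direction[rev_id] = (rxn, -1)
            for met in model.metabolite_ids:
                coeff = model.coefficient(met, rxn)
                if coeff != 0:
                    stoich[(met, rev_id)] = -coeff
    expanded = MetabolicModel(
        reaction_ids=reaction_ids,
        reversible=reversible,
        metabolite_ids=list(model.metabolite_ids),
        is_internal=dict(model.is_internal),
        stoich=stoich,
    )
    return ReversibleSplit(original=model, expanded=expanded, direction=direction)


# ---------------------------------------------------------------------------
# Sidecar files
# ---------------------------------------------------------------------------


def read_sidecar_config(text: str) -> tuple[dict[str, Fraction], dict[str, str]]:
    """Read the sidecar config carrying substrate molecular weights and the
    exchange map.

    Format: INI-style with a ``[substrates]`` section (reaction id = MW in
    g/mol) and an ``[exchange_map]`` section (reaction id = metabolite
    name).  Either section may be absent.
    """
    parser = configparser.ConfigParser()
    parser.optionxform = str  # reaction ids are case-sensitive
    parser.read_file(io.StringIO(text))
    substrates: dict[str, Fraction] = {}
    if parser.has_section("substrates"):
        for rxn, mw in parser.items("substrates"):
            value = Fraction(mw)
            if value <= 0:
                raise ModelValidationError(f"molecular weight for {rxn!r} must be > 0")
            substrates[rxn] = value
    exchange_map: dict[str, str] = {}
    if parser.has_section("exchange_map"):
        for rxn, name in parser.items("exchange_map"):
            exchange_map[rxn] = name.strip()
    return substrates, exchange_map


def read_gene_map(text: str) -> dict[str, frozenset[str]]:
    """Read a two-column tab-separated gene map with header
    ``reaction<TAB>gene``; many-to-many."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return {}
    header = lines[0].split("\t")
    if [h.strip().lower() for h in header[:2]] != ["reaction", "gene"]:
        raise ModelValidationError(
            "gene map must start with header 'reaction<TAB>gene'"
        )
    mapping: dict[str, set[str]] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ModelValidationError(f"malformed gene-map line: {ln!r}")
        rxn, gene = parts[0].strip(), parts[1].strip()
        mapping.setdefault(rxn, set()).add(gene)
    return {rxn: frozenset(genes) for rxn, genes in mapping.items()}


def load_model(
    model_text: str,
    sidecar_text: str | None = None,
    gene_map_text: str | None = None,
) -> MetabolicModel:
    """Parse a METATOOL document and attach optional sidecar data."""
    model = parse_metatool(model_text)
    if sidecar_text is not None:
        substrates, exchange_map = read_sidecar_config(sidecar_text)
        model.substrates = substrates
        model.exchange_map = exchange_map
    if gene_map_text is not None:
        gene_map = read_gene_map(gene_map_text)
        unknown = set(gene_map) - set(model.reaction_ids)
        if unknown:
            raise ModelValidationError(
                f"gene map references undeclared reactions: {sorted(unknown)}"
            )
        model.gene_map = gene_map
    model.check_invariants()
    return model
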