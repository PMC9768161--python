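"""Synthetic inputs for every pipeline stage.

Toy network families with analytically known elementary-mode counts
(chain, diamond/fan, double-diamond, cycle+chain) plus seeded
random-sparse networks for property testing against the brute-force
oracle; synthetic arteriovenous measurement sets constructed so that the
organ-balance arithmetic recovers a prescribed flux pattern plus Gaussian
concentration noise; and synthetic differential-expression tables with a
known upregulated subset.  Everything is deterministic given its seed and
is written in the same formats the real pipeline reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from structflux.evaluation import exchange_sign
from structflux.expression_constrain import ExpressionTable
from structflux.model_io import MetabolicModel
from structflux.organ_flux import AnimalMeasurement
from structflux.structural_flux import StructuralFluxTable

__all__ = [
    "ToySpec",
    "make_toy_network",
    "make_synthetic_measurements",
    "make_synthetic_expression",
    "predicted_exchange_pattern",
    "DEFAULT_SUBSTRATE_MW",
]

#: Toy substrate molecular weight (g/mol); a round number keeps the
#: worked-example arithmetic exact by hand.
DEFAULT_SUBSTRATE_MW = Fraction(100)

FAMILIES = ("chain", "diamond", "fan", "double-diamond", "cycle-chain", "random-sparse")


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a toy network.

    ``size`` is the chain length for ``chain``, the branch count for
    ``fan``, and the target pre-split reaction count for
    ``random-sparse``; it is ignored by the fixed families.  Random
    generation caps the post-split reaction count at
    ``max_split_reactions`` so the brute-force oracle stays applicable.
    """

    family: str
    size: int = 3
    fraction_reversible: float = 0.0
    seed: int = 0
    max_split_reactions: int = 12

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; pick from {FAMILIES}")
        if self.size < 1:
            raise ValueError("size must be >= 1")
        if not 0 <= self.fraction_reversible <= 1:
            raise ValueError("fraction_reversible must lie in [0, 1]")


def _build(
    reactions: list[tuple[str, bool, dict[str, Fraction]]],
    internal: list[str],
    external: list[str],
    substrates: dict[str, Fraction],
    exchange_map: dict[str, str],
) -> MetabolicModel:
    stoich: dict[tuple[str, str], Fraction] = {}
    for rid, _, coeffs in reactions:
        for met, c in coeffs.items():
            stoich[(met, rid)] = c
    model = MetabolicModel(
        reaction_ids=[r for r, _, _ in reactions],
        reversible={r: rev for r, rev, _ in reactions},
        metabolite_ids=internal + external,
        is_internal={**{m: True for m in internal}, **{m: False for m in external}},
        stoich=stoich,
        substrates=substrates,
        exchange_map=exchange_map,
        gene_map={r: frozenset({f"g_{r}"}) for r, _, _ in reactions},
    )
    model.check_invariants()
    return model


def _chain(n: int) -> tuple[MetabolicModel, int]:
    """Sext -> M1 -> ... -> M_{n-1} -> Pext: a single path, 1 EM."""
    one = Fraction(1)
    internal = [f"M{i}" for i in range(1, n)]
    reactions = []
    mets = ["Sext"] + internal + ["Pext"]
    for i in range(n):
        rid = "up" if i == 0 else ("ex" if i == n - 1 else f"r{i}")
        reactions.append((rid, False, {mets[i]: -one, mets[i + 1]: one}))
    model = _build(
        reactions,
        internal,
        ["Sext", "Pext"],
        substrates={"up": DEFAULT_SUBSTRATE_MW},
        exchange_map={"up": "substrate", reactions[-1][0]: "product"},
    )
    return model, 1


def _fan(k: int) -> tuple[MetabolicModel, int]:
    """One uptake feeding k parallel branch pairs; exactly k EMs."""
    one = Fraction(1)
    internal = ["A"] + [f"B{j}" for j in range(1, k + 1)]
    external = ["Sext"] + [f"P{j}ext" for j in range(1, k + 1)]
    reactions = [("up", False, {"Sext": -one, "A": one})]
    exchange_map = {"up": "substrate"}
    for j in range(1, k + 1):
        reactions.append((f"v{j}", False, {"A": -one, f"B{j}": one}))
        reactions.append((f"e{j}", False, {f"B{j}": -one, f"P{j}ext": one}))
        exchange_map[f"e{j}"] = f"product_{j}"
    model = _build(
        reactions, internal, external,
        substrates={"up": DEFAULT_SUBSTRATE_MW},
        exchange_map=exchange_map,
    )
    return model, k


def _double_diamond() -> tuple[MetabolicModel, int]:
    """Two diamonds in series (2 x 2 path choices): 4 EMs."""
    one = Fraction(1)
    internal = ["A", "B1", "B2", "C", "D1", "D2", "E"]
    external = ["Sext", "Pext"]
    reactions = [
        ("up", False, {"Sext": -one, "A": one}),
        ("a1", False, {"A": -one, "B1": one}),
        ("a2", False, {"A": -one, "B2": one}),
        ("b1", False, {"B1": -one, "C": one}),
        ("b2", False, {"B2": -one, "C": one}),
        ("c1", False, {"C": -one, "D1": one}),
        ("c2", False, {"C": -one, "D2": one}),
        ("d1", False, {"D1": -one, "E": one}),
        ("d2", False, {"D2": -one, "E": one}),
        ("ex", False, {"E": -one, "Pext": one}),
    ]
    model = _build(
        reactions, internal, external,
        substrates={"up": DEFAULT_SUBSTRATE_MW},
        exchange_map={"up": "substrate", "ex": "product"},
    )
    return model, 4


def _cycle_chain() -> tuple[MetabolicModel, int]:
    """A substrate-to-product path plus an internal futile cycle: 2 EMs,
    one of which takes up no substrate."""
    one = Fraction(1)
    internal = ["A", "B", "C"]
    external = ["Sext", "Pext"]
    reactions = [
        ("up", False, {"Sext": -one, "A": one}),
        ("r1", False, {"A": -one, "B": one}),
        ("ex", False, {"B": -one, "Pext": one}),
        ("c1", False, {"B": -one, "C": one}),
        ("c2", False, {"C": -one, "A": one}),
    ]
    model = _build(
        reactions, internal, external,
        substrates={"up": DEFAULT_SUBSTRATE_MW},
        exchange_map={"up": "substrate", "ex": "product"},
    )
    return model, 2


def _random_sparse(spec: ToySpec) -> MetabolicModel:
    """Seeded random sparse network; no claimed EM count (the brute-force
    oracle decides).  All internal metabolites are guaranteed to touch at
    least two reactions so the model validates cleanly."""
    rng = np.random.default_rng(spec.seed)
    one = Fraction(1)
    n_int = int(rng.integers(2, 5))
    internal = [f"M{i}" for i in range(n_int)]
    external = ["Xext"]
    reactions: list[tuple[str, bool, dict[str, Fraction]]] = [
        ("up", False, {"Xext": -one, "M0": one})
    ]
    substrates = {"up": DEFAULT_SUBSTRATE_MW}
    exchange_map = {"up": "substrate"}
    n_internal_rxns = max(1, min(spec.size - 2, 6))
    for idx in range(n_internal_rxns):
        i, j = rng.choice(n_int, size=2, replace=False)
        coeff = Fraction(int(rng.choice([1, 1, 1, 2])))
        coeffs = {f"M{i}": -coeff, f"M{j}": one}
        if n_int > 2 and rng.random() < 0.2:
            k = int(rng.integers(0, n_int))
            if k != i and f"M{k}" not in coeffs:
                coeffs[f"M{k}"] = one
        reactions.append((f"t{idx}", False, coeffs))
    # exports: terminal metabolite always, then patch dead ends
    external.append("Yext")
    reactions.append(("ex", False, {f"M{n_int - 1}": -one, "Yext": one}))
    exchange_map["ex"] = "product"
    counts: dict[str, int] = {m: 0 for m in internal}
    for _, _, coeffs in reactions:
        for met in coeffs:
            if met in counts:
                counts[met] += 1
    patch = 0
    for met, c in sorted(counts.items()):
        if c < 2:
            ext = f"Z{patch}ext"
            external.append(ext)
            reactions.append((f"ex_{met}", False, {met: -one, ext: one}))
            exchange_map[f"ex_{met}"] = f"sink_{met}"
            patch += 1
    # sprinkle reversibility within the post-split budget
    budget = spec.max_split_reactions - len(reactions)
    rev_flags = [False] * len(reactions)
    if spec.fraction_reversible > 0 and budget > 0:
        order = rng.permutation(len(reactions))
        for idx in order:
            if budget == 0:
                break
            rid = reactions[idx][0]
            if rid == "up":
                continue  # keep the substrate uptake irreversible
            if rng.random() < spec.fraction_reversible:
                rev_flags[idx] = True
                budget -= 1
    reactions = [
        (rid, rev, coeffs)
        for (rid, _, coeffs), rev in zip(reactions, rev_flags)
    ]
    return _build(reactions, internal, external, substrates, exchange_map)


def make_toy_network(spec: ToySpec) -> tuple[MetabolicModel, int | None]:
    """Build a toy network; the second element is the analytically known
    EM count for deterministic families and None for random-sparse."""
    if spec.family == "chain":
        return _chain(spec.size)
    if spec.family in ("diamond", "fan"):
        k = 2 if spec.family == "diamond" else spec.size
        return _fan(k)
    if spec.family == "double-diamond":
        return _double_diamond()
    if spec.family == "cycle-chain":
        return _cycle_chain()
    return _random_sparse(spec), None


# ---------------------------------------------------------------------------
# Synthetic measurements and expression
# ---------------------------------------------------------------------------


def predicted_exchange_pattern(
    table: StructuralFluxTable, model: MetabolicModel
) -> dict[str, float]:
    """Release-positive predicted exchange value per mapped metabolite."""
    return {
        met: exchange_sign(model, rxn) * float(table.astruf[rxn])
        for rxn, met in model.exchange_map.items()
        if rxn in table.astruf
    }


def make_synthetic_measurements(
    model: MetabolicModel,
    true_pattern: Mapping[str, float],
    noise_sd: float,
    n_animals: int,
    seed: int,
    group: str = "SYN",
    body_weight_g: float = 300.0,
    plasma_flow: float = 3.0,
    arterial_baseline: float = 500.0,
) -> list[AnimalMeasurement]:
    """Arteriovenous measurement sets that invert to a known flux pattern.

    Venous concentrations are constructed so that the organ-balance
    formula returns ``true_pattern[met]`` exactly at zero noise; Gaussian
    noise of standard deviation ``noise_sd`` (in flux units) is applied
    to the venous concentrations, i.e. upstream of the same arithmetic
    the real pipeline uses.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_animals < 1:
        raise ValueError("need at least one animal")
    rng = np.random.default_rng(seed)
    conv = body_weight_g / (100.0 * plasma_flow)  # flux -> concentration
    animals = []
    mets = list(true_pattern)
    for i in range(n_animals):
        arterial = {m: arterial_baseline for m in mets}
        noise = rng.normal(0.0, noise_sd, size=len(mets)) if noise_sd > 0 else np.zeros(len(mets))
        venous = {
            m: arterial_baseline + (true_pattern[m] + noise[j]) * conv
            for j, m in enumerate(mets)
        }
        animals.append(
            AnimalMeasurement(
                animal=f"{group}{i + 1}",
                group=group,
                body_weight_g=body_weight_g,
                arterial=arterial,
                venous=venous,
                urine={},
                urine_flow=0.0,
                plasma_flow=plasma_flow,
                hematocrit=0.45,
            )
        )
    return animals


def make_synthetic_expression(
    genes: Sequence[str],
    upregulated_subset: Sequence[str],
    effect_log2fc: float = 2.0,
    seed: int = 0,
    alpha: float = 0.05,
) -> ExpressionTable:
    """Expression table whose upregulated set is recovered exactly by the
    significance filter: the chosen subset gets the stated positive
    log2 fold change and adjusted P below alpha; all other genes get a
    near-zero fold change and adjusted P at or above alpha."""
    up = set(upregulated_subset)
    if not up <= set(genes):
        raise ValueError("upregulated subset must be a subset of genes")
    if effect_log2fc <= 0:
        raise ValueError("effect_log2fc must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for g in genes:
        if g in up:
            rows.append(
                {
                    "gene": g,
                    "log2fc": effect_log2fc * float(rng.uniform(0.8, 1.2)),
                    "padj": float(rng.uniform(1e-6, alpha * 0.5)),
                }
            )
        else:
            rows.append(
                {
                    "gene": g,
                    "log2fc": float(rng.normal(0.0, 0.05)),
                    "padj": float(rng.uniform(alpha, 1.0)),
                }
            )
    return ExpressionTable(data=pd.DataFrame(rows), alpha=alpha)
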