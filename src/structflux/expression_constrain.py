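"""Restrict the active elementary-mode set with upregulated genes.

In the unconstrained (healthy) condition every mode may contribute.  In a
perturbed condition the assumption is that only the pathways carrying at
least one significantly upregulated gene are active: for each upregulated
gene, the mode set is restricted to modes whose support intersects the
gene's reaction set, and structural fluxes are recomputed on that subset
under the same objective.  Each gene gives its own scenario; comparing a
scenario's normalised structural fluxes against the unconstrained baseline
yields per-reaction relative flux changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from structflux.em_core import ModeSet
from structflux.model_io import MetabolicModel
from structflux.structural_flux import (
    ObjectiveSpec,
    ObjectiveUnreachableError,
    StructuralFluxTable,
    structural_fluxes,
)

__all__ = [
    "ExpressionTable",
    "GeneScenario",
    "UnmappedGeneError",
    "select_upregulated",
    "restrict_modes",
    "per_gene_predictions",
    "relative_change",
    "NEW_FLUX",
]

#: Sentinel for a reaction with zero baseline flux but positive constrained
#: flux: the relative change is not a finite percentage.
NEW_FLUX = float("inf")


class UnmappedGeneError(KeyError):
    """Gene has no reaction in the model's gene map."""

    def __init__(self, gene: str):
        super().__init__(f"unmapped gene: {gene}")
        self.gene = gene


@dataclass
class ExpressionTable:
    """Differential-expression results: one row per gene with its log2
    fold change and multiple-testing adjusted P value."""

    data: pd.DataFrame  # columns: gene, log2fc, padj
    alpha: float = 0.05

    def __post_init__(self) -> None:
        required = {"gene", "log2fc", "padj"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"expression table missing columns: {sorted(missing)}")
        if self.data["gene"].duplicated().any():
            dups = self.data.loc[self.data["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        padj = self.data["padj"]
        if ((padj < 0) | (padj > 1)).any():
            raise ValueError("adjusted P values must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_tsv(cls, text: str, alpha: float = 0.05) -> "ExpressionTable":
        import io

        df = pd.read_csv(io.StringIO(text), sep="\t")
        return cls(data=df, alpha=alpha)

    def to_tsv(self) -> str:
        return self.data.to_csv(sep="\t", index=False)


def select_upregulated(expr: ExpressionTable) -> list[str]:
    """Genes with log2 fold change > 0 and adjusted P below alpha,
    in deterministic (alphabetical) order."""
    mask = (expr.data["log2fc"] > 0) & (expr.data["padj"] < expr.alpha)
    return sorted(expr.data.loc[mask, "gene"].astype(str))


def restrict_modes(modes: ModeSet, model: MetabolicModel, gene: str) -> ModeSet:
    """Modes whose support contains at least one reaction associated with
    ``gene`` (case-insensitive symbol match); order preserved."""
    reactions = model.reactions_of_gene(gene)
    if not reactions:
        raise UnmappedGeneError(gene)
    kept = [m for m in modes.modes if m.support & reactions]
    return ModeSet(model=model, modes=kept)


@dataclass
class GeneScenario:
    """Structural-flux prediction under one upregulated gene's restriction."""

    gene: str
    restricted: ModeSet
    table: StructuralFluxTable | None  # None iff flagged
    flag: str | None = None  # "empty-mode-set" | "objective unreachable"

    @property
    def ok(self) -> bool:
        return self.table is not None


def per_gene_predictions(
    modes: ModeSet,
    model: MetabolicModel,
    objective: ObjectiveSpec,
    genes: Sequence[str],
) -> list[GeneScenario]:
    """One scenario per upregulated gene, each restricting the active mode
    set independently.  Scenarios whose restricted set is empty or whose
    objective becomes unreachable are flagged, not dropped."""
    if not genes:
        raise ValueError("gene list is empty")
    scenarios: list[GeneScenario] = []
    for gene in genes:
        restricted = restrict_modes(modes, model, gene)
        if restricted.count == 0:
            scenarios.append(
                GeneScenario(gene, restricted, None, flag="empty-mode-set")
            )
            continue
        try:
            table = structural_fluxes(
                restricted, model, objective, scenario=f"gene:{gene}"
            )
        except ObjectiveUnreachableError:
            scenarios.append(
                GeneScenario(gene, restricted, None, flag="objective unreachable")
            )
            continue
        scenarios.append(GeneScenario(gene, restricted, table))
    return scenarios


def relative_change(
    constrained: StructuralFluxTable, baseline: StructuralFluxTable
) -> dict[str, float]:
    """Per-reaction percent change of normalised structural flux relative
    to the unconstrained baseline.

    ``100 * (aStruF_constrained - aStruF_baseline) / aStruF_baseline``;
    reactions at zero in both tables give 0%, reactions appearing only in
    the constrained table are flagged with :data:`NEW_FLUX` (infinity)
    rather than an arbitrary number.
    """
    if set(constrained.astruf) != set(baseline.astruf):
        raise ValueError("tables cover different reaction sets")
    if constrained.objective != baseline.objective:
        raise ValueError(
            "tables were computed for different objectives: "
            f"{constrained.objective!r} vs {baseline.objective!r}"
        )
    out: dict[str, float] = {}
    for rxn, base in baseline.astruf.items():
        cons = constrained.astruf[rxn]
        if base == 0:
            out[rxn] = 0.0 if cons == 0 else NEW_FLUX
        else:
            out[rxn] = float(100 * (cons - base) / base)
    return out
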