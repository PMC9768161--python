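"""Compare predicted structural fluxes against measured organ fluxes.

Predicted normalised structural fluxes are unitless; measured
arteriovenous fluxes are in nmol (100 g bw)^-1 min^-1.  The Pearson
correlation coefficient is invariant under positive affine rescaling of
either vector, so the two can be compared directly once both are on the
release-positive sign convention.  Scenarios (objectives, or
objective+gene restrictions) are ranked by r; Stouffer's method combines
one-sided P values across related tests with a direction sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from structflux.model_io import MetabolicModel
from structflux.structural_flux import StructuralFluxTable

__all__ = [
    "AlignedPairs",
    "CorrelationReport",
    "align_fluxes",
    "exchange_sign",
    "pearson",
    "stouffer_combined_p",
    "rank_scenarios",
    "evaluate_predictions",
]


@dataclass
class AlignedPairs:
    """Predicted/measured value pairs on a shared metabolite set, both
    release-positive; metabolites missing on either side are listed in
    ``excluded`` with a reason, never silently dropped."""

    metabolites: list[str]
    predicted: np.ndarray
    measured: np.ndarray
    excluded: list[tuple[str, str]] = field(default_factory=list)


def exchange_sign(model: MetabolicModel, reaction_id: str) -> int:
    """Release-positive sign of an exchange reaction: +1 if the reaction
    produces its external metabolite(s) (release into the circulation),
    -1 if it consumes them (uptake)."""
    total = sum(
        model.coefficient(met, reaction_id) for met in model.external_metabolites
    )
    if total == 0:
        raise ValueError(
            f"reaction {reaction_id!r} has no net external stoichiometry; "
            "cannot orient it as an exchange"
        )
    return 1 if total > 0 else -1


def align_fluxes(
    pred: StructuralFluxTable,
    measured: Mapping[str, float],
    model: MetabolicModel,
) -> AlignedPairs:
    """Pair predicted exchange values with measured per-metabolite fluxes.

    The model's ``exchange_map`` links exchange-reaction ids to measured
    metabolite names.  Predicted values are the normalised structural
    fluxes of the mapped reactions, negated for uptake reactions so both
    vectors follow the release-positive convention.  Requires at least
    three shared metabolites.
    """
    if not model.exchange_map:
        raise ValueError("model has an empty exchange map")
    metabolites: list[str] = []
    pred_vals: list[float] = []
    meas_vals: list[float] = []
    excluded: list[tuple[str, str]] = []
    for rxn, met in model.exchange_map.items():
        if rxn not in pred.astruf:
            excluded.append((met, f"no prediction for reaction {rxn}"))
            continue
        if met not in measured:
            excluded.append((met, "no measurement"))
            continue
        metabolites.append(met)
        pred_vals.append(exchange_sign(model, rxn) * float(pred.astruf[rxn]))
        meas_vals.append(float(measured[met]))
    if len(metabolites) < 3:
        raise ValueError(
            f"only {len(metabolites)} shared metabolites; need at least 3"
        )
    return AlignedPairs(
        metabolites=metabolites,
        predicted=np.asarray(pred_vals, dtype=float),
        measured=np.asarray(meas_vals, dtype=float),
        excluded=excluded,
    )


def pearson(pairs: AlignedPairs) -> tuple[float, float, int]:
    """Product-moment correlation with two-sided P from the t transform
    on n-2 degrees of freedom.  Degenerate (constant) vectors are an
    error rather than a NaN."""
    x, y = pairs.predicted, pairs.measured
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate correlation: constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def stouffer_combined_p(
    p_values: Sequence[float],
    directions: Sequence[int] | None = None,
    epsilon: float = 1e-15,
) -> float:
    """Stouffer's combined one-sided P.

    Each one-sided p is converted to a z score, multiplied by its
    direction sign (+1/-1), summed and divided by sqrt(k); the combined
    P is the upper-tail probability of the resulting Z.  P values at the
    boundary (0 or 1) are clamped to ``epsilon`` with a warning.
    """
    if len(p_values) == 0:
        raise ValueError("no P values to combine")
    if directions is None:
        directions = [1] * len(p_values)
    if len(directions) != len(p_values):
        raise ValueError("directions and p_values must have equal length")
    z_sum = 0.0
    for p, d in zip(p_values, directions):
        if not 0 < p < 1:
            warnings.warn(
                f"P value {p} outside (0,1); clamping", RuntimeWarning, stacklevel=2
            )
            p = min(max(p, epsilon), 1 - epsilon)
        z_sum += d * stats.norm.isf(p)
    z = z_sum / np.sqrt(len(p_values))
    return float(stats.norm.sf(z))


@dataclass
class CorrelationReport:
    """Per-scenario evaluation result with the two-tier significance
    flag: '*' for P < 0.05, '**' for 0.05 <= P < 0.1."""

    scenario: str
    n: int
    r: float
    p: float
    flag: str = ""
    rank: int | None = None

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")
        if not self.flag:
            if self.p < 0.05:
                self.flag = "*"
            elif self.p < 0.1:
                self.flag = "**"


def rank_scenarios(reports: Sequence[CorrelationReport]) -> list[CorrelationReport]:
    """Order scenarios by descending r; ties break alphabetically on the
    scenario name for determinism.  Ranks are 1-based."""
    if not reports:
        raise ValueError("no reports to rank")
    ordered = sorted(reports, key=lambda rep: (-rep.r, rep.scenario))
    out = []
    for i, rep in enumerate(ordered, start=1):
        out.append(
            CorrelationReport(
                scenario=rep.scenario, n=rep.n, r=rep.r, p=rep.p,
                flag=rep.flag, rank=i,
            )
        )
    return out


def evaluate_predictions(
    tables: Mapping[str, StructuralFluxTable],
    measured: Mapping[str, float],
    model: MetabolicModel,
) -> list[CorrelationReport]:
    """Align, correlate and rank a collection of scenario predictions
    against one measured flux vector (typically group means)."""
    reports = []
    for name, table in tables.items():
        pairs = align_fluxes(table, measured, model)
        r, p, n = pearson(pairs)
        reports.append(CorrelationReport(scenario=name, n=n, r=r, p=p))
    return rank_scenarios(reports)


def report_to_tsv(reports: Sequence[CorrelationReport]) -> str:
    lines = ["scenario\tn\tr\tp\tflag\trank"]
    for rep in reports:
        lines.append(
            f"{rep.scenario}\t{rep.n}\t{rep.r:.6g}\t{rep.p:.6g}"
            f"\t{rep.flag}\t{rep.rank if rep.rank is not None else ''}"
        )
    return "\n".join(lines) + "\n"
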