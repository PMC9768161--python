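"""Arteriovenous organ-balance fluxes from per-animal measurements.

Net exchange of a metabolite across the organ is plasma flow times the
venous-minus-arterial concentration difference, normalised to 100 g body
weight.  The sign convention is release-positive: positive values mean the
organ adds the substrate to the circulation, negative values mean uptake.
Plasma flow is measured by constant infusion of para-aminohippuric acid
(PAH) and Fick's principle: the urinary PAH excretion rate divided by the
arteriovenous PAH concentration difference.  Total ammoniagenesis is the
renal venous ammonia efflux plus urinary ammonia excretion.

Units: concentrations nmol ml^-1, flows ml min^-1, body weight g, fluxes
nmol (100 g bw)^-1 min^-1.  Flows and fluxes refer to both kidneys.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from structflux.evaluation import stouffer_combined_p

__all__ = [
    "AnimalMeasurement",
    "MeasuredFluxTable",
    "GroupSummary",
    "renal_plasma_flow_pah",
    "exchange_flux",
    "urinary_excretion",
    "total_ammoniagenesis",
    "compute_fluxes",
    "group_summary",
    "read_animal_table",
    "AMMONIA",
]

AMMONIA = "ammonia"

ANIMAL_TABLE_COLUMNS = [
    "animal",
    "group",
    "bw_g",
    "metabolite",
    "art_conc",
    "ven_conc",
    "urine_conc",
    "urine_flow",
    "plasma_flow",
    "hematocrit",
]


@dataclass
class AnimalMeasurement:
    """Raw measurements for one animal.

    ``plasma_flow`` may be given directly or derived from PAH
    concentrations via :func:`renal_plasma_flow_pah`.  Hematocrit is
    carried for completeness; the default organ-balance formulas operate
    on plasma quantities and do not use it.
    """

    animal: str
    group: str
    body_weight_g: float
    arterial: dict[str, float]  # metabolite -> nmol ml^-1
    venous: dict[str, float]
    urine: dict[str, float] = field(default_factory=dict)
    urine_flow: float = 0.0  # ml min^-1
    plasma_flow: float | None = None  # ml min^-1, both kidneys
    hematocrit: float = 0.0

    def __post_init__(self) -> None:
        if self.body_weight_g <= 0:
            raise ValueError("body weight must be > 0")
        if self.urine_flow < 0:
            raise ValueError("urine flow must be >= 0")
        if self.plasma_flow is not None and self.plasma_flow < 0:
            raise ValueError("plasma flow must be >= 0")
        if not 0 <= self.hematocrit < 1:
            raise ValueError("hematocrit must lie in [0, 1)")


def renal_plasma_flow_pah(
    urinary_pah_rate: float, arterial_pah: float, venous_pah: float
) -> float:
    """Effective renal plasma flow (ml min^-1) from PAH clearance.

    Fick's principle: everything that left the plasma appeared in urine,
    so flow = urinary excretion rate / arteriovenous concentration
    difference.  Requires net extraction (arterial > venous).
    """
    if urinary_pah_rate == 0:
        return 0.0
    diff = arterial_pah - venous_pah
    if diff <= 0:
        raise ValueError(
            "no PAH extraction: arterial concentration must exceed venous"
        )
    return urinary_pah_rate / diff


def exchange_flux(
    arterial: float, venous: float, plasma_flow: float, body_weight_g: float
) -> float:
    """Net organ exchange flux, release-positive.

    ``(venous - arterial) * plasma_flow * 100 / body_weight`` in
    nmol (100 g bw)^-1 min^-1.
    """
    if plasma_flow < 0:
        raise ValueError("plasma flow must be >= 0")
    if body_weight_g <= 0:
        raise ValueError("body weight must be > 0")
    return (venous - arterial) * plasma_flow * 100.0 / body_weight_g


def urinary_excretion(
    urine_conc: float, urine_flow: float, body_weight_g: float
) -> float:
    """Urinary excretion rate in nmol (100 g bw)^-1 min^-1."""
    if urine_conc < 0 or urine_flow < 0:
        raise ValueError("urine concentration and flow must be >= 0")
    if body_weight_g <= 0:
        raise ValueError("body weight must be > 0")
    return urine_conc * urine_flow * 100.0 / body_weight_g


def total_ammoniagenesis(
    renal_flux: float, urinary_rate: float
) -> tuple[float, float | None]:
    """Total ammonia production: renal venous efflux plus urinary
    excretion.  Returns ``(total, percent_urinary)``; the percentage is
    None (undefined) when the total is not positive."""
    if urinary_rate < 0:
        raise ValueError("urinary excretion rate must be >= 0")
    total = renal_flux + urinary_rate
    if total > 0:
        return total, 100.0 * urinary_rate / total
    return total, None


@dataclass
class MeasuredFluxTable:
    """Release-positive exchange fluxes per (animal, metabolite), with a
    per-animal ammonia summary when ammonia was measured."""

    fluxes: pd.DataFrame  # columns: animal, group, metabolite, flux
    ammonia: pd.DataFrame | None = None
    # ammonia columns: animal, group, renal_flux, urinary_excretion,
    #                  total_ammoniagenesis, percent_urinary

    def group_means(self) -> pd.DataFrame:
        """Per-group per-metabolite mean flux (index group, metabolite)."""
        return (
            self.fluxes.groupby(["group", "metabolite"])["flux"]
            .mean()
            .to_frame()
        )

    def metabolite_means(self, group: str) -> dict[str, float]:
        sub = self.fluxes[self.fluxes["group"] == group]
        return sub.groupby("metabolite")["flux"].mean().to_dict()

    def to_tsv(self) -> str:
        out = self.fluxes.to_csv(sep="\t", index=False)
        return out


def compute_fluxes(
    animals: list[AnimalMeasurement], ammonia_metabolite: str = AMMONIA
) -> MeasuredFluxTable:
    """Exchange fluxes for every animal and metabolite, plus the ammonia
    balance (renal flux, urinary excretion, total, percent urinary) for
    animals where ammonia was measured in plasma."""
    rows = []
    ammonia_rows = []
    for a in animals:
        if a.plasma_flow is None:
            raise ValueError(f"animal {a.animal}: plasma flow is missing")
        for met in a.arterial:
            if met not in a.venous:
                continue
            flux = exchange_flux(
                a.arterial[met], a.venous[met], a.plasma_flow, a.body_weight_g
            )
            rows.append(
                {"animal": a.animal, "group": a.group, "metabolite": met, "flux": flux}
            )
        if ammonia_metabolite in a.arterial and ammonia_metabolite in a.venous:
            renal = exchange_flux(
                a.arterial[ammonia_metabolite],
                a.venous[ammonia_metabolite],
                a.plasma_flow,
                a.body_weight_g,
            )
            urinary = urinary_excretion(
                a.urine.get(ammonia_metabolite, 0.0), a.urine_flow, a.body_weight_g
            )
            total, pct = total_ammoniagenesis(renal, urinary)
            ammonia_rows.append(
                {
                    "animal": a.animal,
                    "group": a.group,
                    "renal_flux": renal,
                    "urinary_excretion": urinary,
                    "total_ammoniagenesis": total,
                    "percent_urinary": pct if pct is not None else np.nan,
                }
            )
    fluxes = pd.DataFrame(rows, columns=["animal", "group", "metabolite", "flux"])
    ammonia = pd.DataFrame(ammonia_rows) if ammonia_rows else None
    return MeasuredFluxTable(fluxes=fluxes, ammonia=ammonia)


def read_animal_table(text: str) -> list[AnimalMeasurement]:
    """Read the per-animal tab-separated table (one row per animal and
    metabolite, columns as in :data:`ANIMAL_TABLE_COLUMNS`)."""
    df = pd.read_csv(io.StringIO(text), sep="\t")
    missing = set(ANIMAL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"animal table missing columns: {sorted(missing)}")
    animals: list[AnimalMeasurement] = []
    for (animal, group), sub in df.groupby(["animal", "group"], sort=True):
        first = sub.iloc[0]
        animals.append(
            AnimalMeasurement(
                animal=str(animal),
                group=str(group),
                body_weight_g=float(first["bw_g"]),
                arterial={
                    str(r["metabolite"]): float(r["art_conc"])
                    for _, r in sub.iterrows()
                },
                venous={
                    str(r["metabolite"]): float(r["ven_conc"])
                    for _, r in sub.iterrows()
                },
                urine={
                    str(r["metabolite"]): float(r["urine_conc"])
                    for _, r in sub.iterrows()
                    if not math.isnan(float(r["urine_conc"]))
                },
                urine_flow=float(first["urine_flow"]),
                plasma_flow=float(first["plasma_flow"]),
                hematocrit=float(first["hematocrit"]),
            )
        )
    return animals


@dataclass
class GroupSummary:
    """Descriptive statistics and two-group comparisons of measured
    fluxes: mean +/- SEM and median (range) per group and metabolite, a
    nonparametric (Mann-Whitney) P per metabolite when two groups are
    present, and a direction-aware Stouffer-combined P across
    metabolites."""

    summary: pd.DataFrame  # index (group, metabolite)
    per_metabolite_p: dict[str, float]
    combined_p: float | None


def group_summary(table: MeasuredFluxTable) -> GroupSummary:
    df = table.fluxes
    if df.empty:
        raise ValueError("measured flux table is empty")
    summary = (
        df.groupby(["group", "metabolite"])["flux"]
        .agg(
            n="count",
            mean="mean",
            sem=lambda x: float(stats.sem(x)) if len(x) > 1 else 0.0,
            median="median",
            min="min",
            max="max",
        )
        .sort_index()
    )
    groups = sorted(df["group"].unique())
    per_metabolite_p: dict[str, float] = {}
    combined: float | None = None
    if len(groups) == 2:
        g0, g1 = groups
        p_values, directions = [], []
        for met in sorted(df["metabolite"].unique()):
            x = df[(df["group"] == g0) & (df["metabolite"] == met)]["flux"]
            y = df[(df["group"] == g1) & (df["metabolite"] == met)]["flux"]
            if len(x) == 0 or len(y) == 0:
                continue
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            per_metabolite_p[met] = float(res.pvalue)
            p_values.append(float(res.pvalue))
            directions.append(1 if y.mean() >= x.mean() else -1)
        if p_values:
            combined = stouffer_combined_p(p_values, directions)
    return GroupSummary(
        summary=summary, per_metabolite_p=per_metabolite_p, combined_p=combined
    )
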