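import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from structflux.organ_flux import (
    AnimalMeasurement,
    compute_fluxes,
    exchange_flux,
    group_summary,
    read_animal_table,
    renal_plasma_flow_pah,
    total_ammoniagenesis,
    urinary_excretion,
)

finite = st.floats(min_value=-1e3, max_value=1e3, allow_nan=False)
positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


def test_pah_flow_direct_division():
    assert renal_plasma_flow_pah(300.0, 150.0, 50.0) == pytest.approx(3.0)
    assert renal_plasma_flow_pah(0.0, 150.0, 50.0) == 0.0


def test_pah_flow_requires_extraction():
    with pytest.raises(ValueError, match="extraction"):
        renal_plasma_flow_pah(300.0, 50.0, 150.0)


def test_exchange_flux_sign_convention():
    assert exchange_flux(100.0, 110.0, 3.0, 300.0) == pytest.approx(10.0)  # release
    assert exchange_flux(100.0, 100.0, 3.0, 300.0) == 0.0
    assert exchange_flux(110.0, 100.0, 3.0, 300.0) == pytest.approx(-10.0)  # uptake


@settings(deadline=None, max_examples=50, derandomize=True)
@given(a=finite, v=finite, flow=positive, bw=positive)
def test_exchange_flux_antisymmetric_in_av_swap(a, v, flow, bw):
    assert exchange_flux(a, v, flow, bw) == pytest.approx(
        -exchange_flux(v, a, flow, bw), abs=1e-9
    )


@settings(deadline=None, max_examples=50, derandomize=True)
@given(a=finite, v=finite, flow=positive, bw=positive,
       lam=st.floats(min_value=0.1, max_value=10))
def test_rate_operations_homogeneity(a, v, flow, bw, lam):
    """Degree 1 in flow and concentrations, degree -1 in body weight."""
    base = exchange_flux(a, v, flow, bw)
    assert exchange_flux(a, v, lam * flow, bw) == pytest.approx(lam * base, rel=1e-9, abs=1e-9)
    assert exchange_flux(lam * a, lam * v, flow, bw) == pytest.approx(lam * base, rel=1e-9, abs=1e-9)
    assert exchange_flux(a, v, flow, lam * bw) == pytest.approx(base / lam, rel=1e-9, abs=1e-9)
    u = urinary_excretion(abs(a), flow, bw)
    assert urinary_excretion(abs(a), lam * flow, bw) == pytest.approx(lam * u, rel=1e-9, abs=1e-9)


def test_urinary_excretion_arithmetic():
    assert urinary_excretion(1000.0, 0.009, 300.0) == pytest.approx(3.0)
    assert urinary_excretion(1000.0, 0.0, 300.0) == 0.0
    assert urinary_excretion(0.0, 0.009, 300.0) == 0.0


def test_total_ammoniagenesis_and_percent():
    total, pct = total_ammoniagenesis(3.0, 7.0)
    assert total == pytest.approx(10.0)
    assert pct == pytest.approx(70.0)
    assert total_ammoniagenesis(5.0, 0.0) == (5.0, 0.0)
    assert total_ammoniagenesis(0.0, 5.0)[1] == pytest.approx(100.0)
    assert total_ammoniagenesis(-6.0, 5.0)[1] is None  # undefined


def test_total_exceeds_components_when_release_positive():
    total, _ = total_ammoniagenesis(3.0, 7.0)
    assert total >= 3.0 and total >= 7.0


def _fixture_animals():
    animals = []
    rng = np.random.default_rng(7)
    for group, offset in (("AL", 0.0), ("HD", 20.0)):
        for i in range(3):
            art = {"ammonia": 100.0, "glutamine": 400.0}
            ven = {
                "ammonia": 100.0 + 5.0 + offset + rng.normal(0, 1),
                "glutamine": 400.0 - 10.0 - offset + rng.normal(0, 1),
            }
            animals.append(
                AnimalMeasurement(
                    animal=f"{group}{i}",
                    group=group,
                    body_weight_g=300.0,
                    arterial=art,
                    venous=ven,
                    urine={"ammonia": 1000.0},
                    urine_flow=0.009,
                    plasma_flow=3.0,
                    hematocrit=0.45,
                )
            )
    return animals


def test_compute_fluxes_matches_direct_recomputation():
    animals = _fixture_animals()
    table = compute_fluxes(animals)
    for a in animals:
        for met in ("ammonia", "glutamine"):
            row = table.fluxes[
                (table.fluxes["animal"] == a.animal)
                & (table.fluxes["metabolite"] == met)
            ]
            expected = (a.venous[met] - a.arterial[met]) * 3.0 * 100.0 / 300.0
            assert row["flux"].iloc[0] == pytest.approx(expected)
    # ammonia summary: total = renal + urinary
    amm = table.ammonia.set_index("animal")
    for a in animals:
        renal = (a.venous["ammonia"] - a.arterial["ammonia"]) * 3.0 * 100.0 / 300.0
        urinary = 1000.0 * 0.009 * 100.0 / 300.0
        assert amm.loc[a.animal, "total_ammoniagenesis"] == pytest.approx(
            renal + urinary
        )


def test_group_summary_matches_independent_computation():
    table = compute_fluxes(_fixture_animals())
    gs = group_summary(table)
    sub = table.fluxes[
        (table.fluxes["group"] == "AL") & (table.fluxes["metabolite"] == "ammonia")
    ]["flux"].to_numpy()
    row = gs.summary.loc[("AL", "ammonia")]
    assert row["mean"] == pytest.approx(sub.mean())
    assert row["sem"] == pytest.approx(sub.std(ddof=1) / np.sqrt(len(sub)))
    assert row["median"] == pytest.approx(np.median(sub))
    assert (row["min"], row["max"]) == (sub.min(), sub.max())
    assert set(gs.per_metabolite_p) == {"ammonia", "glutamine"}
    assert 0 < gs.combined_p < 1


def test_group_summary_order_invariant():
    animals = _fixture_animals()
    a = group_summary(compute_fluxes(animals))
    b = group_summary(compute_fluxes(list(reversed(animals))))
    assert a.summary.equals(b.summary)
    assert a.combined_p == pytest.approx(b.combined_p)


def test_group_summary_single_group_has_no_between_group_stats():
    animals = [x for x in _fixture_animals() if x.group == "AL"]
    gs = group_summary(compute_fluxes(animals))
    assert gs.per_metabolite_p == {}
    assert gs.combined_p is None


def test_animal_measurement_validation():
    with pytest.raises(ValueError, match="body weight"):
        AnimalMeasurement("a", "AL", 0.0, {}, {})
    with pytest.raises(ValueError, match="hematocrit"):
        AnimalMeasurement("a", "AL", 300.0, {}, {}, hematocrit=1.2)


def test_read_animal_table_round_trip():
    text = (
        "animal\tgroup\tbw_g\tmetabolite\tart_conc\tven_conc\turine_conc"
        "\turine_flow\tplasma_flow\thematocrit\n"
        "r1\tAL\t300\tammonia\t100\t110\t1000\t0.009\t3.0\t0.45\n"
        "r1\tAL\t300\tglutamine\t400\t390\t\t0.009\t3.0\t0.45\n"
    )
    animals = read_animal_table(text)
    assert len(animals) == 1
    a = animals[0]
    assert a.arterial == {"ammonia": 100.0, "glutamine": 400.0}
    assert a.urine == {"ammonia": 1000.0}
    table = compute_fluxes(animals)
    assert table.fluxes.shape[0] == 2
    amm = table.ammonia.iloc[0]
    assert amm["renal_flux"] == pytest.approx(10.0)
    assert amm["urinary_excretion"] == pytest.approx(3.0)
    assert amm["total_ammoniagenesis"] == pytest.approx(13.0)
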