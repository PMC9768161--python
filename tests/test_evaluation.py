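import math

import numpy as np
import pytest

from structflux.em_core import enumerate_elementary_modes
from structflux.evaluation import (
    AlignedPairs,
    CorrelationReport,
    align_fluxes,
    evaluate_predictions,
    exchange_sign,
    pearson,
    rank_scenarios,
    stouffer_combined_p,
)
from structflux.structural_flux import ObjectiveSpec, objective_scan, structural_fluxes


def _pairs(x, y):
    return AlignedPairs(
        metabolites=[f"m{i}" for i in range(len(x))],
        predicted=np.asarray(x, float),
        measured=np.asarray(y, float),
    )


def test_exchange_sign_orientation(diamond):
    assert exchange_sign(diamond, "up") == -1  # consumes Sext: uptake
    assert exchange_sign(diamond, "e1") == 1  # produces P1ext: release


def test_align_fluxes_pairs_and_exclusions(diamond, b_export_objective):
    modes = enumerate_elementary_modes(diamond)
    table = structural_fluxes(modes, diamond, b_export_objective)
    measured = {"substrate": -5.0, "product_1": 5.0, "product_2": 0.5}
    pairs = align_fluxes(table, measured, diamond)
    assert sorted(pairs.metabolites) == ["product_1", "product_2", "substrate"]
    by_met = dict(zip(pairs.metabolites, pairs.predicted))
    assert by_met["substrate"] == pytest.approx(-1.0)  # negated uptake
    assert by_met["product_1"] == pytest.approx(1.0)
    assert pairs.excluded == []
    # missing measurement is listed, not silently dropped
    pairs2 = align_fluxes(
        table, {"substrate": -5.0, "product_1": 5.0, "product_2": 0.5, "ghost": 1.0},
        diamond,
    )
    assert pairs2.excluded == []
    del measured["product_2"]
    with pytest.raises(ValueError, match="shared metabolites"):
        align_fluxes(table, measured, diamond)


def test_align_reports_missing_measurement(fan4):
    modes = enumerate_elementary_modes(fan4)
    table = structural_fluxes(modes, fan4, ObjectiveSpec("export_1", "e1"))
    measured = {"substrate": -5.0, "product_1": 5.0, "product_2": 0.1, "product_3": 0.2}
    pairs = align_fluxes(table, measured, fan4)
    assert ("product_4", "no measurement") in pairs.excluded
    assert len(pairs.metabolites) == 4


def test_pearson_perfect_correlations():
    r, p, n = pearson(_pairs([1, 2, 3, 4], [10, 20, 30, 40]))
    assert r == pytest.approx(1.0)
    r, _, _ = pearson(_pairs([1, 2, 3, 4], [-1, -2, -3, -4]))
    assert r == pytest.approx(-1.0)


def test_pearson_matches_textbook_formula():
    x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
    y = np.array([2.0, 3.0, 3.5, 6.0, 9.0])
    r, p, n = pearson(_pairs(x, y))
    # independent closed-form evaluation
    sx, sy = x - x.mean(), y - y.mean()
    r_ref = (sx * sy).sum() / math.sqrt((sx**2).sum() * (sy**2).sum())
    t = r_ref * math.sqrt((n - 2) / (1 - r_ref**2))
    from scipy.stats import t as tdist

    p_ref = 2 * tdist.sf(abs(t), n - 2)
    assert r == pytest.approx(r_ref, abs=1e-12)
    assert p == pytest.approx(p_ref, rel=1e-9)


def test_pearson_rejects_degenerate_input():
    with pytest.raises(ValueError, match="degenerate"):
        pearson(_pairs([1, 1, 1, 1], [1, 2, 3, 4]))
    with pytest.raises(ValueError, match="at least 3"):
        pearson(_pairs([1, 2], [1, 2]))


def test_stouffer_single_p_is_identity():
    assert stouffer_combined_p([0.07]) == pytest.approx(0.07, abs=1e-12)


def test_stouffer_same_direction_reinforces():
    assert stouffer_combined_p([0.1] * 4) < 0.1


def test_stouffer_matches_independent_normal_formula():
    from scipy.stats import norm

    ps = [0.03, 0.2, 0.08]
    dirs = [1, 1, -1]
    z = sum(d * norm.isf(p) for p, d in zip(ps, dirs)) / math.sqrt(3)
    # independent route via the error function
    expected = 0.5 * math.erfc(z / math.sqrt(2))
    assert stouffer_combined_p(ps, dirs) == pytest.approx(expected, rel=1e-12)


def test_stouffer_four_subthreshold_tests_combine_strongly():
    """Four concordant tests, each individually weak (P < 0.2), combine
    to P = 0.0025 when each one-sided P is ~0.0802."""
    from scipy.stats import norm

    p_each = float(norm.sf(norm.isf(0.0025) / 2))
    assert p_each < 0.2
    assert stouffer_combined_p([p_each] * 4) == pytest.approx(0.0025, rel=1e-9)


def test_stouffer_clamps_boundary_p_with_warning():
    with pytest.warns(RuntimeWarning, match="clamping"):
        p = stouffer_combined_p([0.0, 0.5])
    assert 0 <= p <= 1


def test_rank_scenarios_order_and_ties():
    reports = [
        CorrelationReport("b", 5, 0.5, 0.2),
        CorrelationReport("a", 5, 0.8, 0.01),
        CorrelationReport("c", 5, -0.2, 0.7),
    ]
    ranked = rank_scenarios(reports)
    assert [r.scenario for r in ranked] == ["a", "b", "c"]
    assert [r.rank for r in ranked] == [1, 2, 3]
    assert ranked[0].flag == "*"
    tie = rank_scenarios(
        [CorrelationReport("zeta", 5, 0.5, 0.2), CorrelationReport("alpha", 5, 0.5, 0.2)]
    )
    assert [r.scenario for r in tie] == ["alpha", "zeta"]


def test_rank_is_permutation_invariant():
    reports = [
        CorrelationReport(s, 5, r, 0.5)
        for s, r in [("a", 0.1), ("b", 0.9), ("c", 0.4)]
    ]
    a = rank_scenarios(reports)
    b = rank_scenarios(list(reversed(reports)))
    assert [x.scenario for x in a] == [x.scenario for x in b]


def test_significance_flags_follow_two_tier_rule():
    assert CorrelationReport("s", 5, 0.9, 0.01).flag == "*"
    assert CorrelationReport("s", 5, 0.9, 0.07).flag == "**"
    assert CorrelationReport("s", 5, 0.9, 0.5).flag == ""


def test_identity_fixture_evaluates_to_top_rank(fan4):
    """Predictions correlated against their own exchange pattern give
    r = 1 for the generating objective and first rank."""
    from structflux.synthgen import predicted_exchange_pattern

    modes = enumerate_elementary_modes(fan4)
    objectives = [ObjectiveSpec(f"export_{j}", f"e{j}") for j in range(1, 5)]
    scan = objective_scan(modes, fan4, objectives)
    measured = predicted_exchange_pattern(scan.tables["export_2"], fan4)
    reports = evaluate_predictions(scan.tables, measured, fan4)
    assert reports[0].scenario == "export_2"
    assert reports[0].r == pytest.approx(1.0)
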