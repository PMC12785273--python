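"""Directional mitigation indicators, rank scores, and coverage summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiqsar.datasets import RegulatorModule
from epiqsar.ranking import (
    MODULES,
    ModulePrediction,
    build_profile,
    mitigation_indicator,
    rank_library,
    rank_score,
    summarize_module_coverage,
)

DOWN = (RegulatorModule.MIR34A, RegulatorModule.DNMT3A, RegulatorModule.HDAC)
UP = (RegulatorModule.MIR125B, RegulatorModule.MIR135A)


@pytest.mark.parametrize("module", MODULES, ids=lambda m: m.value)
@pytest.mark.parametrize("label", [0, 1])
def test_directional_truth_table(module, label):
    expected = int(label == 0) if module in DOWN else int(label == 1)
    assert mitigation_indicator(module, label) == expected


def test_rank_score_extremes_and_resveratrol_profile():
    assert rank_score({m: 1 for m in MODULES}) == 1.0
    assert rank_score({m: 0 for m in MODULES}) == 0.0
    profile = {
        RegulatorModule.MIR34A: 1,
        RegulatorModule.DNMT3A: 1,
        RegulatorModule.HDAC: 1,
        RegulatorModule.MIR125B: 1,
        RegulatorModule.MIR135A: 0,
    }
    assert rank_score(profile) == pytest.approx(0.8)


def test_rank_score_missing_module_named():
    with pytest.raises(ValueError, match="MIR135A"):
        rank_score({m: 1 for m in MODULES if m is not RegulatorModule.MIR135A})


@settings(max_examples=50, deadline=None)
@given(
    st.tuples(*[st.integers(0, 1) for _ in MODULES]),
    st.sampled_from(list(MODULES)),
)
def test_flipping_one_module_shifts_score_by_point_two(bits, flipped):
    indicators = dict(zip(MODULES, bits))
    before = rank_score(indicators)
    indicators[flipped] = 1 - indicators[flipped]
    after = rank_score(indicators)
    assert abs(after - before) == pytest.approx(0.2)


def _predictions(cid, labels, in_domain=None):
    in_domain = in_domain or {}
    return [
        ModulePrediction(
            compound_id=cid, module=m, predicted_label=labels[m],
            in_domain=in_domain.get(m, True),
        )
        for m in MODULES
    ]


def test_out_of_domain_module_contributes_zero_with_flag():
    labels = {m: m.favorable_label for m in MODULES}  # all favorable
    profile = build_profile(
        _predictions("c1", labels, in_domain={RegulatorModule.HDAC: False})
    )
    assert profile.indicators[RegulatorModule.HDAC] == 0
    assert profile.out_of_domain == {RegulatorModule.HDAC}
    assert profile.rank_score == pytest.approx(0.8)


def test_rank_library_orders_and_breaks_ties_by_id():
    all_fav = {m: m.favorable_label for m in MODULES}
    none_fav = {m: 1 - m.favorable_label for m in MODULES}
    preds = (
        _predictions("zeta", all_fav)
        + _predictions("beta", none_fav)
        + _predictions("alpha", none_fav)
    )
    table = rank_library(preds)
    assert [p.compound_id for p in table.profiles] == ["zeta", "alpha", "beta"]


def test_rank_library_matches_bruteforce_sort():
    rng = np.random.default_rng(3)
    preds = []
    expected = []
    for i in range(50):
        cid = f"c{i:02d}"
        labels = {m: int(rng.integers(0, 2)) for m in MODULES}
        preds += _predictions(cid, labels)
        score = sum(mitigation_indicator(m, labels[m]) for m in MODULES) / 5
        expected.append((cid, score))
    expected.sort(key=lambda t: (-t[1], t[0]))
    table = rank_library(preds)
    assert [(p.compound_id, p.rank_score) for p in table.profiles] == expected


def test_rank_library_incomplete_matrix_errors():
    preds = _predictions("c1", {m: 0 for m in MODULES})[:-1]
    with pytest.raises(ValueError, match="MIR135A"):
        rank_library(preds)


def test_coverage_percentages():
    preds = []
    # 10 compounds; 4 with favorable HDAC; one compound favorable for two miRs
    for i in range(10):
        labels = {m: 1 - m.favorable_label for m in MODULES}
        if i < 4:
            labels[RegulatorModule.HDAC] = RegulatorModule.HDAC.favorable_label
        if i == 0:
            labels[RegulatorModule.MIR34A] = 0
            labels[RegulatorModule.MIR125B] = 1
        preds += _predictions(f"c{i}", labels)
    coverage = summarize_module_coverage(rank_library(preds))
    assert coverage["HDAC"] == 40.00
    assert coverage["MIR34A"] == 10.00
    assert coverage["MIR125B"] == 10.00
    # double-hit compound counted once in the microRNA umbrella
    assert coverage["microRNA"] == 10.00


def test_coverage_all_zero_and_union_bounds():
    none_fav = {m: 1 - m.favorable_label for m in MODULES}
    preds = [p for i in range(5) for p in _predictions(f"c{i}", none_fav)]
    coverage = summarize_module_coverage(rank_library(preds))
    assert all(v == 0.0 for v in coverage.values())

    rng = np.random.default_rng(9)
    preds = [
        p
        for i in range(40)
        for p in _predictions(f"r{i}", {m: int(rng.integers(0, 2)) for m in MODULES})
    ]
    coverage = summarize_module_coverage(rank_library(preds))
    mir = [coverage["MIR34A"], coverage["MIR125B"], coverage["MIR135A"]]
    assert max(mir) <= coverage["microRNA"] <= min(100.0, sum(mir)) + 0.01


def test_coverage_empty_table_errors():
    from epiqsar.ranking import RankTable

    with pytest.raises(ValueError):
        summarize_module_coverage(RankTable(profiles=[]))
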