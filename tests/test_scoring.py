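"""Tariff scoring: rule arithmetic, pass-through, additivity, oracle."""

import datetime as dt

import numpy as np
import pytest

import labequity as le
from labequity.scoring import (
    Contribution,
    Rule,
    ScoringError,
    UNITS_PREFIX,
    WorkloadSchema,
    illustrative_schema,
    score_case,
    score_table,
    totals,
)

SURGICAL_TARIFF = WorkloadSchema(
    metric_names=("L4E", "cases"),
    rules=(
        Rule(
            name="surgical",
            match={"case_class": "surgical"},
            contributions={
                "L4E": Contribution(base=1.0, per_block=0.5),
                "cases": Contribution(base=1.0),
            },
        ),
        Rule(
            name="cytology",
            match={"case_class": "cytology"},
            contributions={
                "L4E": Contribution(base=0.5, per_specimen=0.25),
                "cases": Contribution(base=1.0),
            },
        ),
    ),
    unmatched_policy="zero",
)


def _case(cls="surgical", blocks=0, spec=1, pre=None, cid="X1", anc=None):
    return le.CaseRecord(
        case_id=cid,
        pathologist_id="P",
        signout_date=dt.date(2018, 5, 7),
        site="AH",
        organization="alpha_org",
        case_class=cls,
        specimen_count=spec,
        block_count=blocks,
        ancillary_counts=anc or {},
        precomputed_units=pre,
    )


def test_rule_arithmetic_base_plus_blocks():
    # surgical: 1 base + 0.5/block, 4 blocks -> 3.0
    assert score_case(_case(blocks=4), SURGICAL_TARIFF)["L4E"] == pytest.approx(3.0)


def test_precomputed_units_win_over_rules():
    v = score_case(_case(blocks=4, pre={"L4E": 2.5}), SURGICAL_TARIFF)
    assert v["L4E"] == 2.5
    assert v["cases"] == 1.0  # non-precomputed metric still scored by rules


def test_counting_metric_scores_one_per_case():
    cases = [_case(cid=f"C{i}", cls="cytology", spec=i) for i in range(1, 101)]
    scored, _ = score_table(cases, SURGICAL_TARIFF)
    assert totals(scored, SURGICAL_TARIFF)["cases"] == pytest.approx(100.0)


def test_empty_table_scores_zero_totals():
    scored, _ = score_table([], SURGICAL_TARIFF)
    assert totals(scored, SURGICAL_TARIFF) == {"L4E": 0.0, "cases": 0.0}


def test_first_match_semantics_rule_order_significant():
    overlapping = WorkloadSchema(
        metric_names=("L4E",),
        rules=(
            Rule("small", {"case_class": "surgical", "specimen_max": 2},
                 {"L4E": Contribution(base=1.0)}),
            Rule("any-surgical", {"case_class": "surgical"},
                 {"L4E": Contribution(base=9.0)}),
        ),
        unmatched_policy="zero",
    )
    assert score_case(_case(spec=1), overlapping)["L4E"] == 1.0
    assert score_case(_case(spec=5), overlapping)["L4E"] == 9.0


def test_unmatched_policy_error_names_case():
    strict = WorkloadSchema(
        metric_names=("L4E",),
        rules=(Rule("surg", {"case_class": "surgical"}, {"L4E": Contribution(base=1)}),),
        unmatched_policy="error",
    )
    with pytest.raises(ScoringError, match="X9"):
        score_table([_case(), _case(cls="cytology", cid="X9")], strict)


def test_unmatched_policy_zero_counts_warning():
    scored, report = score_table([_case(cls="review", cid="R1")], SURGICAL_TARIFF)
    assert report.n_unmatched == 1
    assert scored[UNITS_PREFIX + "L4E"].iloc[0] == 0.0


def _random_cases(rng, n=50):
    classes = ["surgical", "cytology", "review"]
    return [
        _case(
            cls=classes[rng.integers(0, 3)],
            blocks=int(rng.integers(0, 12)),
            spec=int(rng.integers(1, 7)),
            cid=f"R{i}",
            anc={"ihc": int(rng.integers(0, 4))},
        )
        for i in range(n)
    ]


def _oracle_case_units(case, schema):
    """Independent per-case scorer: plain ifs, no shared code path."""
    out = {m: 0.0 for m in schema.metric_names}
    for rule in schema.rules:
        ok = True
        if "case_class" in rule.match and case.case_class != rule.match["case_class"]:
            ok = False
        if "specimen_min" in rule.match and case.specimen_count < rule.match["specimen_min"]:
            ok = False
        if "specimen_max" in rule.match and case.specimen_count > rule.match["specimen_max"]:
            ok = False
        if not ok:
            continue
        for metric, c in rule.contributions.items():
            v = c.base + c.per_specimen * case.specimen_count + c.per_block * case.block_count
            for name, w in c.per_ancillary.items():
                v += w * case.ancillary_counts.get(name, 0)
            out[metric] = v
        break
    return out


def test_totals_match_brute_force_oracle():
    rng = np.random.default_rng(42)
    tariff = WorkloadSchema(
        metric_names=("L4E", "fees"),
        rules=(
            Rule("surg-small", {"case_class": "surgical", "specimen_max": 3},
                 {"L4E": Contribution(1.0, 0.1, 0.5, {"ihc": 0.4}), "fees": Contribution(20.0)}),
            Rule("surg", {"case_class": "surgical"},
                 {"L4E": Contribution(2.0, 0.0, 0.5), "fees": Contribution(30.0, 12.0)}),
            Rule("cyto", {"case_class": "cytology"},
                 {"L4E": Contribution(0.6, 0.2, 0.0), "fees": Contribution(12.0)}),
            Rule("review", {"case_class": "review"}, {"L4E": Contribution(1.5)}),
        ),
        unmatched_policy="zero",
    )
    cases = _random_cases(rng)
    scored, _ = score_table(cases, tariff)
    got = totals(scored, tariff)
    expected = {m: 0.0 for m in tariff.metric_names}
    for case in cases:
        for m, v in _oracle_case_units(case, tariff).items():
            expected[m] += v
    for m in tariff.metric_names:
        assert got[m] == pytest.approx(expected[m], rel=1e-9)


def test_additivity_and_permutation_invariance():
    rng = np.random.default_rng(7)
    cases = _random_cases(rng, n=40)
    whole, _ = score_table(cases, SURGICAL_TARIFF)
    a, _ = score_table(cases[:17], SURGICAL_TARIFF)
    b, _ = score_table(cases[17:], SURGICAL_TARIFF)
    perm = [cases[i] for i in rng.permutation(40)]
    shuffled, _ = score_table(perm, SURGICAL_TARIFF)
    for m in SURGICAL_TARIFF.metric_names:
        t = totals(whole, SURGICAL_TARIFF)[m]
        assert t == pytest.approx(
            totals(a, SURGICAL_TARIFF)[m] + totals(b, SURGICAL_TARIFF)[m], rel=1e-9
        )
        assert t == pytest.approx(totals(shuffled, SURGICAL_TARIFF)[m], rel=1e-9)


def test_block_monotonicity():
    """Adding a block never decreases any metric under nonnegative tariffs."""
    for blocks in range(0, 10):
        lo = score_case(_case(blocks=blocks), SURGICAL_TARIFF)
        hi = score_case(_case(blocks=blocks + 1), SURGICAL_TARIFF)
        for m in SURGICAL_TARIFF.metric_names:
            assert hi[m] >= lo[m]


def test_illustrative_schema_loads_and_scores(toy_cases):
    schema = illustrative_schema()
    scored, report = score_table(toy_cases, schema)
    assert report.n_unmatched == 0
    assert (scored[UNITS_PREFIX + "cases"] == 1.0).all()
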