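import math

import numpy as np
import pandas as pd
import pytest

from snpbarcode import (
    Barcode,
    Cohort,
    CohortEvaluator,
    FactorDefinition,
    decode_particle,
    evaluate_barcode,
    format_barcode,
    match_subject,
)
from snpbarcode.barcode import EXCLUDED, EXPOSED, UNEXPOSED

from conftest import build_row_cohort


class TestDecodeParticle:
    def test_status_example(self):
        factors = [
            FactorDefinition(f"f{i}", "environment", {0: "a", 1: "b", 2: "c"})
            for i in range(5)
        ]
        barcode = decode_particle([0, 1, 0, 0, 1, 1, 1, 0, 0, 0], factors)
        # factors 1, 3, 4 selected in statuses 1, 3, 2 -> level codes 0, 2, 1
        assert barcode.selections == (("f0", 0), ("f2", 2), ("f3", 1))

    def test_all_zero_decodes_empty(self):
        factors = [FactorDefinition("f", "snp", {1: "x", 2: "y"})]
        assert decode_particle([0, 0], factors).order == 0

    def test_invalid_status_leaves_factor_unselected(self):
        factors = [FactorDefinition("f", "environment", {0: "no", 1: "yes"})]
        # status 3 would select level 2, outside valid codes {0,1}
        assert decode_particle([1, 1], factors).order == 0

    def test_every_bit_pattern_decodes(self, panel):
        rng = np.random.default_rng(3)
        for _ in range(50):
            bits = rng.integers(0, 2, size=2 * len(panel))
            barcode = decode_particle(bits, panel)
            for name, code in barcode.selections:
                assert code in next(f for f in panel if f.name == name).valid_codes

    def test_wrong_length_rejected(self, panel):
        with pytest.raises(ValueError):
            decode_particle([0, 1], panel)


class TestMatchSubject:
    barcode = Barcode((("age", 2), ("rs887844", 1)))

    @pytest.mark.parametrize(
        "values, expected",
        [
            ({"age": 2.0, "rs887844": 1.0}, EXPOSED),
            ({"age": 1.0, "rs887844": 1.0}, UNEXPOSED),
            ({"age": 2.0, "rs887844": math.nan}, EXCLUDED),
            ({"age": math.nan, "rs887844": 2.0}, EXCLUDED),
        ],
    )
    def test_trichotomy_cases(self, values, expected):
        assert match_subject(values, self.barcode) == expected

    def test_exactly_one_outcome(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            values = {
                "age": rng.choice([1.0, 2.0, math.nan]),
                "rs887844": rng.choice([1.0, 2.0, math.nan]),
            }
            assert match_subject(values, self.barcode) in (EXPOSED, UNEXPOSED, EXCLUDED)

    def test_unknown_factor_is_error(self):
        with pytest.raises(KeyError):
            match_subject({"age": 2.0}, self.barcode)

    def test_empty_barcode_rejected(self):
        with pytest.raises(ValueError):
            match_subject({"age": 2.0}, Barcode(()))


class TestEvaluateBarcode:
    def test_reproduces_five_factor_tables(self, five_factor_cohort, printed_rows):
        row = printed_rows["five_factor"]
        ev = evaluate_barcode(five_factor_cohort, row["barcode"])
        assert ev.table_cvn.cells == (53, 7, 189, 257)
        assert ev.table_pvn.cells == (9, 7, 61, 257)
        assert round(ev.est_cvn.or_value, 2) == 10.30
        assert round(ev.est_pvn.or_value, 2) == 5.42
        assert round(ev.delta, 2) == 4.88
        assert ev.delta == pytest.approx(ev.est_cvn.or_value - ev.est_pvn.or_value)

    def test_reproduces_two_factor_opmd_row(self, panel, printed_rows):
        row = printed_rows["age_rs4411227"]
        cohort = build_row_cohort(row, panel)
        ev = evaluate_barcode(cohort, row["barcode"])
        assert ev.table_pvn.cells == (11, 12, 59, 252)
        assert round(ev.est_pvn.or_value, 2) == 3.92

    def test_group_accounting(self, five_factor_cohort, printed_rows):
        ev = evaluate_barcode(five_factor_cohort, printed_rows["five_factor"]["barcode"])
        sizes = five_factor_cohort.group_sizes
        assert ev.table_cvn.d_e + ev.table_cvn.d_n + ev.n_excluded["cancer"] == sizes["cancer"]
        assert ev.table_cvn.h_e + ev.table_cvn.h_n + ev.n_excluded["control"] == sizes["control"]
        assert ev.table_pvn.d_e + ev.table_pvn.d_n + ev.n_excluded["opmd"] == sizes["opmd"]

    def test_independent_exposure_gives_unit_ors(self):
        age = FactorDefinition("age", "environment", {1: "a", 2: "b"})
        frame = pd.DataFrame({"age": [1, 2] * 60})
        groups = np.array(["control", "opmd", "cancer"]).repeat(40)
        cohort = Cohort.from_arrays(frame, groups, factors=[age])
        ev = evaluate_barcode(cohort, Barcode((("age", 2),)))
        assert ev.est_cvn.or_value == pytest.approx(1.0)
        assert ev.est_pvn.or_value == pytest.approx(1.0)
        assert ev.delta == pytest.approx(0.0)

    def test_fully_excluded_group_is_undefined(self):
        age = FactorDefinition("age", "environment", {1: "a", 2: "b"})
        frame = pd.DataFrame({"age": [1.0, 2.0, math.nan, math.nan]})
        groups = np.array(["control", "cancer", "opmd", "opmd"])
        cohort = Cohort.from_arrays(frame, groups, factors=[age])
        ev = evaluate_barcode(cohort, Barcode((("age", 2),)))
        assert not ev.defined
        assert ev.fitness == -math.inf

    def test_monotone_refinement_never_gains_exposed(self, five_factor_cohort, printed_rows):
        full = printed_rows["five_factor"]["barcode"]
        prefix = None
        previous = math.inf
        for name, code in full.selections:
            prefix = Barcode((*(prefix.selections if prefix else ()), (name, code)))
            ev = evaluate_barcode(five_factor_cohort, prefix)
            exposed = ev.table_cvn.d_e + ev.table_cvn.h_e
            assert exposed <= previous
            previous = exposed


class TestEvaluatorCache:
    def test_identical_barcode_returns_identical_object(self, five_factor_cohort, printed_rows):
        evaluator = CohortEvaluator(five_factor_cohort)
        barcode = printed_rows["five_factor"]["barcode"]
        first = evaluator.evaluate(barcode)
        second = evaluator.evaluate(Barcode(barcode.selections))
        assert first is second
        assert evaluator.n_evaluations == 1


class TestFormatBarcode:
    def test_schema_order_labels(self, panel):
        names = [f.name for f in panel]
        barcode = Barcode((("rs887844", 1), ("age", 2)))
        assert format_barcode(barcode, names) == "2-1"  # age precedes the SNP

    def test_level_zero_rendered(self):
        assert format_barcode(Barcode((("age", 2), ("alcohol", 0)))) == "2-0"

    def test_empty_barcode_symbol(self):
        assert format_barcode(Barcode(())) == "∅"
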