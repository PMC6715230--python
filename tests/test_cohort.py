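import math
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from snpbarcode import (
    Cohort,
    DataError,
    FactorDefinition,
    SchemaError,
    hwe_by_group,
    hwe_test,
    read_cohort,
    summarize_cohort,
    write_cohort,
)

AGE = FactorDefinition("age", "environment", {1: "<=50", 2: ">50"})
RS = FactorDefinition("rs887844", "snp", {1: "A/G", 2: "G/G"})
SCHEMA = [AGE, RS]


def write(tmp_path, text):
    path = tmp_path / "cohort.csv"
    path.write_text(textwrap.dedent(text))
    return path


class TestReadCohort:
    def test_minimal_valid_file(self, tmp_path):
        path = write(
            tmp_path,
            """\
            subject_id,group,age,rs887844
            s1,control,1,2
            s2,opmd,2,1
            s3,cancer,2,2
            """,
        )
        cohort = read_cohort(path, SCHEMA)
        assert cohort.n_subjects == 3
        assert cohort.group_sizes == {"control": 1, "opmd": 1, "cancer": 1}

    def test_tab_delimited_autodetected(self, tmp_path):
        path = write(
            tmp_path,
            "subject_id\tgroup\tage\trs887844\ns1\tcontrol\t1\t2\n",
        )
        assert read_cohort(path, SCHEMA).n_subjects == 1

    def test_out_of_domain_code_names_subject(self, tmp_path):
        path = write(
            tmp_path,
            """\
            subject_id,group,age,rs887844
            s1,control,1,2
            s2,cancer,3,1
            """,
        )
        with pytest.raises(DataError, match="s2"):
            read_cohort(path, SCHEMA)

    @pytest.mark.parametrize("token", ["NA", "", "-"])
    def test_missing_tokens_stored_as_missing(self, tmp_path, token):
        path = write(
            tmp_path,
            f"subject_id,group,age,rs887844\ns1,control,{token},2\n",
        )
        cohort = read_cohort(path, SCHEMA)
        assert math.isnan(cohort.values("age")[0])

    def test_missing_column_is_schema_error(self, tmp_path):
        path = write(tmp_path, "subject_id,group,age\ns1,control,1\n")
        with pytest.raises(SchemaError, match="rs887844"):
            read_cohort(path, SCHEMA)

    def test_unknown_group_is_data_error(self, tmp_path):
        path = write(
            tmp_path, "subject_id,group,age,rs887844\ns1,patient,1,2\n"
        )
        with pytest.raises(DataError, match="patient"):
            read_cohort(path, SCHEMA)

    def test_roundtrip_preserves_codes_and_missing(self, tmp_path):
        path = write(
            tmp_path,
            """\
            subject_id,group,age,rs887844
            s1,control,1,NA
            s2,opmd,2,1
            s3,cancer,NA,2
            """,
        )
        cohort = read_cohort(path, SCHEMA)
        out = tmp_path / "out.csv"
        write_cohort(cohort, out)
        again = read_cohort(out, SCHEMA)
        pd.testing.assert_frame_equal(cohort.data, again.data)


class TestSummarize:
    @pytest.fixture()
    def study_age_cohort(self):
        # Age distribution of the three groups in the study population.
        codes, groups = [], []
        for group, (n1, n2) in {
            "cancer": (114, 128),
            "opmd": (31, 39),
            "control": (206, 58),
        }.items():
            codes += [1] * n1 + [2] * n2
            groups += [group] * (n1 + n2)
        return Cohort.from_arrays(
            pd.DataFrame({"age": codes}), np.array(groups), factors=[AGE]
        )

    def test_published_percentages(self, study_age_cohort):
        summary = summarize_cohort(study_age_cohort)
        over50 = summary[summary["level"] == 2].iloc[0]
        assert round(over50["pct_cancer"], 2) == 52.89
        assert round(over50["pct_control"], 2) == 21.97
        assert over50["n_cancer"] == 128 and over50["n_control"] == 58

    def test_percentages_sum_to_100(self, study_age_cohort):
        summary = summarize_cohort(study_age_cohort)
        for g in ("control", "opmd", "cancer"):
            assert summary[f"pct_{g}"].sum() == pytest.approx(100.0)

    def test_group_difference_p_value(self, study_age_cohort):
        summary = summarize_cohort(study_age_cohort)
        assert summary["p_value"].iloc[0] < 0.001  # strong age imbalance

    def test_single_observed_level_gives_undefined_p(self):
        cohort = Cohort.from_arrays(
            pd.DataFrame({"age": [1, 1, 1]}),
            np.array(["control", "opmd", "cancer"]),
            factors=[AGE],
        )
        summary = summarize_cohort(cohort)
        assert math.isnan(summary["p_value"].iloc[0])
        assert summary[summary["level"] == 1]["pct_control"].iloc[0] == 100.0


class TestHardyWeinberg:
    def test_exact_proportions_give_zero(self):
        stat, p = hwe_test(25, 50, 25)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_monomorphic_sample_fits_exactly(self):
        stat, p = hwe_test(0, 0, 100)
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_deviation(self):
        # counts (30,40,30): p=q=1/2, expected (25,50,25),
        # chi2 = 25/25 + 100/50 + 25/25 = 4
        stat, _ = hwe_test(30, 40, 30)
        assert stat == pytest.approx(4.0)

    @given(
        st.integers(min_value=0, max_value=300),
        st.integers(min_value=1, max_value=300),
        st.integers(min_value=0, max_value=300),
    )
    def test_symmetric_in_homozygotes(self, a, h, b):
        assert hwe_test(a, h, b)[0] == pytest.approx(hwe_test(b, h, a)[0])

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)

    def test_two_class_snp_reported_not_applicable(self, panel):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {
                "rs707718": rng.integers(0, 3, size=90),
                "rs887844": rng.integers(1, 3, size=90),
            }
        )
        groups = np.array(["control", "opmd", "cancer"]).repeat(30)
        factors = [f for f in panel if f.name in ("rs707718", "rs887844")]
        cohort = Cohort.from_arrays(frame, groups, factors=factors)
        table = hwe_by_group(cohort)
        three_class = table[table["snp"] == "rs707718"]
        two_class = table[table["snp"] == "rs887844"]
        assert three_class["applicable"].all()
        assert np.isfinite(three_class["chi2"]).all()
        assert not two_class["applicable"].any()
        assert two_class["chi2"].isna().all()
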