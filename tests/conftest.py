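import numpy as np
import pytest

from snpbarcode import Barcode, cohort_from_counts, study_factor_panel

# Published contingency cells for named barcode models (inputs for
# reconstruction tests): per row, the barcode, the exposed counts and the
# "other" counts per group.
PRINTED_ROWS = {
    "age_rs887844": {
        "barcode": Barcode((("age", 2), ("rs887844", 1))),
        "exposed": {"cancer": 70, "opmd": 18, "control": 15},
        "other": {"cancer": 172, "opmd": 52, "control": 249},
        "or_cvn": 6.76,
        "ci_cvn": (3.74, 12.19),
    },
    "age_rs4411227": {
        "barcode": Barcode((("age", 2), ("rs4411227", 1))),
        "exposed": {"cancer": 40, "opmd": 11, "control": 12},
        "other": {"cancer": 202, "opmd": 59, "control": 252},
        "or_cvn": 4.16,
        "or_pvn": 3.92,
        "ci_pvn": (1.65, 9.31),
    },
    "age_rs12256889": {
        "barcode": Barcode((("age", 2), ("rs12256889", 1))),
        "exposed": {"cancer": 126, "opmd": 37, "control": 57},
        "other": {"cancer": 116, "opmd": 33, "control": 207},
        "or_cvn": 3.94,
        "or_pvn": 4.07,
    },
    "age_race": {
        "barcode": Barcode((("age", 2), ("race", 1))),
        "exposed": {"cancer": 110, "opmd": 30, "control": 46},
        "other": {"cancer": 132, "opmd": 40, "control": 218},
        "or_cvn": 3.95,
        "or_pvn": 3.55,
        "delta": 0.40,
    },
    "age_alcohol0": {
        "barcode": Barcode((("age", 2), ("alcohol", 0))),
        "exposed": {"cancer": 56, "opmd": 16, "control": 22},
        "other": {"cancer": 186, "opmd": 54, "control": 242},
        "or_cvn": 3.31,
        "or_pvn": 3.26,
    },
    "three_factor": {
        "barcode": Barcode((("age", 2), ("race", 1), ("rs887844", 1))),
        "exposed": {"cancer": 63, "opmd": 14, "control": 11},
        "other": {"cancer": 179, "opmd": 56, "control": 253},
        "or_cvn": 8.09,
        "or_pvn": 5.75,
        "ci_cvn": (4.15, 15.80),
    },
    "four_factor": {
        "barcode": Barcode(
            (("age", 2), ("race", 1), ("betel_quid", 1), ("rs887844", 1))
        ),
        "exposed": {"cancer": 53, "opmd": 10, "control": 7},
        "other": {"cancer": 189, "opmd": 60, "control": 257},
        "or_cvn": 10.30,
        "or_pvn": 6.12,
    },
    "five_factor": {
        "barcode": Barcode(
            (("age", 2), ("race", 1), ("betel_quid", 1), ("rs887844", 1), ("rs12256889", 1))
        ),
        "exposed": {"cancer": 53, "opmd": 9, "control": 7},
        "other": {"cancer": 189, "opmd": 61, "control": 257},
        "or_cvn": 10.30,
        "or_pvn": 5.42,
        "ci_cvn": (4.58, 23.15),
        "ci_pvn": (1.94, 15.12),
        "delta": 4.88,
    },
}


@pytest.fixture(scope="session")
def panel():
    """The study's 14 factor definitions."""
    return [spec.definition for spec in study_factor_panel()]


@pytest.fixture(scope="session")
def printed_rows():
    return PRINTED_ROWS


def build_row_cohort(row, panel):
    """Minimal cohort reproducing one printed row's cells."""
    return cohort_from_counts([(row["barcode"], row["exposed"], row["other"])], panel)


@pytest.fixture(scope="session")
def five_factor_cohort(panel):
    return build_row_cohort(PRINTED_ROWS["five_factor"], panel)
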