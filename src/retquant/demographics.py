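"""Printed donor demographics of the study cohort.

The per-donor ages and sexes below are the values printed in the study's
demographics table (9 AD donors, 12 controls; two control ages unknown).
They serve as a small real-data input for the rank-sum machinery: the
group mean ages and the AD-vs-control age comparison are *computed* from
these entries, not hard-coded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import rank_sum_test

__all__ = ["donor_table", "age_summary"]

_DONORS = [
    # (donor_id, group, age, sex, preparation)
    ("A1", "AD", 89, "M", "cross-section"),
    ("A2", "AD", 82, "F", "cross-section"),
    ("A3", "AD", 55, "F", "cross-section"),
    ("A4", "AD", 84, "M", "cross-section"),
    ("A5", "AD", 83, "M", "cross-section"),
    ("A6", "AD", 70, "M", "punch"),
    ("A7", "AD", 80, "M", "punch"),
    ("A8", "AD", 76, "F", "punch"),
    ("A9", "AD", 80, "M", "cross-section"),
    ("C1", "control", 80, "M", "cross-section"),
    ("C2", "control", 80, None, "cross-section"),
    ("C3", "control", 72, "F", "cross-section"),
    ("C4", "control", 75, "M", "cross-section"),
    ("C5", "control", 75, "M", "cross-section"),
    ("C6", "control", 79, "M", "cross-section"),
    ("C7", "control", 75, "M", "cross-section"),
    ("C8", "control", 70, "M", "punch"),
    ("C9", "control", 68, "M", "punch"),
    ("C10", "control", 74, "M", "punch"),
    ("C11", "control", None, None, "cross-section"),
    ("C12", "control", None, None, "cross-section"),
]


def donor_table() -> pd.DataFrame:
    """The printed donor roster as a DataFrame (missing entries NaN)."""
    return pd.DataFrame(
        _DONORS, columns=["donor_id", "group", "age", "sex", "preparation"]
    ).astype({"age": "float64"})


def age_summary() -> dict:
    """Group mean ages and the two-sided rank-sum p for the age contrast.

    Means are over the donors with a printed age (9 AD, 10 control).
    """
    df = donor_table().dropna(subset=["age"])
    ad = df.loc[df["group"] == "AD", "age"].to_numpy()
    ctl = df.loc[df["group"] == "control", "age"].to_numpy()
    w, p = rank_sum_test(ad, ctl)
    return {
        "ad_mean_age": float(np.mean(ad)),
        "control_mean_age": float(np.mean(ctl)),
        "n_ad": int(ad.size),
        "n_control": int(ctl.size),
        "rank_sum_W": w,
        "p_value": p,
    }
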