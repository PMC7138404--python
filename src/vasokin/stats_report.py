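"""Control-normalised z-scores, two-group tests and cohort report tables.

Each experimental specimen is normalised to the control group of its own
study arm: z = (x - mean(controls)) / sd(controls), with the sample (n-1)
standard deviation since control groups are small (4-5 animals).  Control
specimens are z-scored against their own group summary, so by construction
their z-scores have mean 0 and (sample) SD 1.  Group differences use the
two-sided Mann-Whitney U test (exact null for small groups) or Welch's
t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def zscore_to_control(values, control_values, *, ddof: int = 1) -> np.ndarray:
    """z-scores of ``values`` against the control group mean and SD."""
    control = np.asarray(control_values, dtype=float)
    if control.size < 2:
        raise ValueError("need >=2 control specimens")
    sd = control.std(ddof=ddof)
    if sd == 0:
        raise ValueError("control group SD is zero")
    return (np.asarray(values, dtype=float) - control.mean()) / sd


def group_compare(a, b, test: str = "mann_whitney") -> dict:
    """Two-sided comparison of two groups.

    ``test="mann_whitney"`` uses the exact U null distribution for groups of
    up to 8 observations without ties (normal approximation with tie
    correction otherwise, flagged in the output); ``test="t"`` is Welch's
    unequal-variance t-test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >=2 observations")
    if test == "t":
        res = sps.ttest_ind(a, b, equal_var=False)
        return {"test": "welch_t", "statistic": float(res.statistic),
                "p_value": float(res.pvalue), "exact": False}
    if test != "mann_whitney":
        raise ValueError("test must be 'mann_whitney' or 't'")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    small = max(a.size, b.size) <= 8
    method = "exact" if (small and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"test": "mann_whitney", "statistic": float(res.statistic),
            "p_value": float(res.pvalue), "exact": method == "exact",
            "ties": ties}


def cohort_table(values: pd.DataFrame, *, group_col: str = "group",
                 control_label: str = "control",
                 arm_col: str | None = None,
                 id_col: str = "specimen") -> pd.DataFrame:
    """Tidy long-format cohort table with control-normalised z-scores.

    ``values`` is long-format with one row per (specimen, parameter):
    columns ``id_col``, ``group_col``, ``parameter``, ``value`` and
    optionally ``arm_col`` (e.g. short-term vs long-term arm).  z-scores are
    computed per parameter against the control group of the same arm.
    """
    required = {id_col, group_col, "parameter", "value"}
    missing = required - set(values.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = values.copy()
    keys = ["parameter"] + ([arm_col] if arm_col else [])
    out = []
    for _, sub in df.groupby(keys, dropna=False):
        ctrl = sub.loc[sub[group_col] == control_label, "value"].to_numpy()
        sub = sub.copy()
        sub["z_score"] = zscore_to_control(sub["value"].to_numpy(), ctrl)
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def compare_groups_table(table: pd.DataFrame, *, group_col: str = "group",
                         control_label: str = "control",
                         test: str = "mann_whitney") -> pd.DataFrame:
    """Per-parameter two-group tests of every treated group vs control."""
    rows = []
    for param, sub in table.groupby("parameter"):
        ctrl = sub.loc[sub[group_col] == control_label, "value"].to_numpy()
        for grp in sub[group_col].unique():
            if grp == control_label:
                continue
            trt = sub.loc[sub[group_col] == grp, "value"].to_numpy()
            res = group_compare(trt, ctrl, test=test)
            rows.append({"parameter": param, "group": grp, **res,
                         "significant": res["p_value"] < 0.05})
    return pd.DataFrame(rows)
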