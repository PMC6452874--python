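"""Expression-noise and association statistics for cell populations.

Cell-to-cell variability in protein abundance (expression noise) is
summarised by the coefficient of variation, CV = 100 * sigma / mu, per
strain, medium and fluorescence compartment.  Group comparisons use the
two-sided Wilcoxon rank-sum (Mann-Whitney) test — exact by enumeration
for small samples, normal approximation with tie correction otherwise.
Across environments, the association between selection-coefficient
magnitude and apparent free protein is summarised by a Pearson
correlation.
"""

from __future__ import annotations

import itertools
import warnings
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "coefficient_of_variation",
    "rank_sum_test",
    "correlate_abs_s_vs_free",
    "noise_report",
]

#: largest combined sample size for which the rank-sum null is enumerated
EXACT_ENUMERATION_LIMIT = 20


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 * sample standard deviation / mean.

    Requires n >= 2 and a positive mean (the ratio is meaningless for
    centred or negative-mean data).  Scale-invariant: CV(c*x) = CV(x)
    for c > 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return 100.0 * x.std(ddof=1) / mean


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments.

    Handles ties via midranks: for every way of assigning the pooled
    values to the first group, the Mann-Whitney U is computed from the
    pooled midranks, and the p-value is the null fraction of assignments
    at least as far from the mean U as observed.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1, n2 = a.size, b.size
    mu = n1 * n2 / 2.0
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    dev_obs = abs(u_obs - mu)
    hits = 0
    total = comb(n1 + n2, n1)
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev_obs - 1e-9:
            hits += 1
    return hits / total


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration of the permutation null (tie-aware) for combined
    n <= 20; normal approximation with tie correction for larger
    samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if a.size + b.size <= EXACT_ENUMERATION_LIMIT:
        return _exact_rank_sum_p(a, b)
    return float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic").pvalue)


def correlate_abs_s_vs_free(env_table) -> float:
    """Pearson r of per-environment mean |S| against mean free-protein fraction.

    ``env_table`` is a DataFrame with columns ``mean_abs_S`` and
    ``mean_f_free`` (or any two-column array-like in that order), one
    row per environment, at least three environments.  Zero variance in
    either column leaves the correlation undefined: NaN is returned with
    a warning.
    """
    if isinstance(env_table, pd.DataFrame):
        x = env_table["mean_abs_S"].to_numpy(dtype=float)
        y = env_table["mean_f_free"].to_numpy(dtype=float)
    else:
        arr = np.asarray(env_table, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if x.size < 3:
        raise ValueError("need >= 3 environments for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in one column: correlation undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


_COMPARTMENT_COLS = {"total": "f_total", "foci": "f_foci", "cyto": "f_cyto"}


def noise_report(cells: pd.DataFrame, group_cols=("strain",)) -> tuple:
    """Noise summary per group and compartment, with pairwise tests.

    For each group (e.g. strain x medium) three compartments are
    summarised: ``total`` over all cells, and ``foci``/``cyto`` over the
    foci-containing subset only (cells with f_foci > 0), matching how
    deposit-level variability is quantified; groups without any
    foci-containing cell simply lack those rows.  Groups with n < 2 are
    flagged and their CV omitted.

    Returns ``(summary, tests)``: a tidy table of n/mean/sd/CV rows and
    a table of two-sided rank-sum p-values comparing every pair of
    groups within each compartment.  P-values are reported unadjusted
    (no multiple-testing correction).
    """
    group_cols = list(group_cols)
    cells = cells.sort_values(group_cols + ["cell_id"] if "cell_id" in cells else group_cols)
    rows = []
    samples = {}
    for key, grp in cells.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        label = "/".join(str(k) for k in key)
        for comp, col in _COMPARTMENT_COLS.items():
            sub = grp if comp == "total" else grp[grp["f_foci"] > 0]
            if comp != "total" and len(sub) == 0:
                continue
            vals = sub[col].to_numpy(dtype=float)
            row = {"group": label, "compartment": comp, "n": vals.size,
                   "mean": vals.mean() if vals.size else np.nan,
                   "sd": vals.std(ddof=1) if vals.size >= 2 else np.nan,
                   "cv_percent": np.nan, "flag": ""}
            if vals.size < 2:
                row["flag"] = "n<2: CV omitted"
            elif vals.mean() <= 0:
                row["flag"] = "non-positive mean: CV omitted"
            else:
                row["cv_percent"] = coefficient_of_variation(vals)
            rows.append(row)
            samples[(label, comp)] = vals
    summary = pd.DataFrame(rows)

    test_rows = []
    by_comp: dict[str, list] = {}
    for (label, comp), vals in samples.items():
        by_comp.setdefault(comp, []).append((label, vals))
    for comp, entries in by_comp.items():
        for (la, va), (lb, vb) in itertools.combinations(entries, 2):
            if va.size == 0 or vb.size == 0:
                continue
            test_rows.append({
                "compartment": comp, "group_a": la, "group_b": lb,
                "p_value": rank_sum_test(va, vb), "adjusted": False,
            })
    tests = pd.DataFrame(test_rows,
                         columns=["compartment", "group_a", "group_b",
                                  "p_value", "adjusted"])
    return summary, tests
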