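"""Per-position over/under-representation statistics.

For each reference position i with cancer count c_i and non-cancer count
n_i (class totals C and N):

* observed frequency  f_obs_cancer = c_i / C (same for non-cancer),
* expected frequency  f_exp = (c_i + n_i) / (C + N),
* representation ratio r_cancer = f_obs_cancer / f_exp; r > 1 means
  cancer mutations are over-represented at the position (and non-cancer
  mutations under-represented, since the two ratios sit on opposite
  sides of 1),
* significance from a Pearson chi-square test on the 2x2 table
  [[c_i, C - c_i], [n_i, N - n_i]] with one degree of freedom. Yates
  continuity correction is ON by default (the 2x2 default of R's
  chisq.test); positions with any expected cell below 5 are flagged but
  kept.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError
from .hotspots import PositionCounts
from .model import CANCER, NONCANCER

LABEL_OVER_CANCER = "over_cancer"
LABEL_OVER_NONCANCER = "over_noncancer"
LABEL_NOT_SIGNIFICANT = "not_significant"
LABEL_UNDEFINED = "undefined"


def observed_frequency(count_at_position: int, class_total: int) -> float:
    """count / class total; NaN (never a division error) for an empty class."""
    if class_total < 0 or count_at_position < 0:
        raise ConfigError("counts must be nonnegative")
    if class_total == 0:
        return math.nan
    return count_at_position / class_total


def representation_ratio(
    c_i: int, n_i: int, C: int, N: int
) -> tuple[float, float]:
    """(ratio_cancer, ratio_noncancer) = observed / expected frequency.

    NaN marks undefined entries (empty class or unmutated position).
    """
    if C + N <= 0 or c_i + n_i <= 0:
        return (math.nan, math.nan)
    f_exp = (c_i + n_i) / (C + N)
    ratio_cancer = (c_i / C) / f_exp if C > 0 else math.nan
    ratio_noncancer = (n_i / N) / f_exp if N > 0 else math.nan
    return (ratio_cancer, ratio_noncancer)


class ChiSquareResult(NamedTuple):
    chi2: float
    p_value: float
    min_expected: float


def chi_square_position(
    c_i: int, n_i: int, C: int, N: int, yates: bool = True
) -> ChiSquareResult:
    """Pearson chi-square on [[c_i, C-c_i], [n_i, N-n_i]], 1 dof.

    Degenerate cases: an unmutated position (c_i + n_i = 0) is undefined
    (NaN); a table with an empty complementary margin carries no
    information against the null and returns chi2 = 0, p = 1 exactly.
    """
    if not (0 <= c_i <= C):
        raise ConfigError(f"c_i={c_i} outside [0, C={C}]")
    if not (0 <= n_i <= N):
        raise ConfigError(f"n_i={n_i} outside [0, N={N}]")
    if C <= 0 or N <= 0:
        raise ConfigError("both class totals must be positive")
    if c_i + n_i == 0:
        return ChiSquareResult(math.nan, math.nan, math.nan)
    table = np.array([[c_i, C - c_i], [n_i, N - n_i]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    min_expected = float(expected.min())
    if np.any(expected == 0):
        return ChiSquareResult(0.0, 1.0, min_expected)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=yates)
    return ChiSquareResult(float(chi2), float(p), min_expected)


def classify_positions(
    counts: PositionCounts,
    alpha: float = 0.05,
    yates: bool = True,
    bh: bool = False,
) -> pd.DataFrame:
    """Full per-position statistics table.

    One row per position with c_i + n_i > 0: counts, observed/expected
    frequencies, representation ratios, chi-square, p-value, a
    small-expected-cell flag and the over/under label (over_cancer when
    p < alpha and ratio_cancer > 1, over_noncancer when p < alpha and
    ratio_cancer < 1, else not_significant). ``bh`` additionally applies
    a Benjamini-Hochberg adjustment before labeling (an extension beyond
    the raw-p convention; OFF by default).
    """
    if not (0 < alpha < 1):
        raise ConfigError(f"alpha: must be in (0, 1), got {alpha}")
    C = counts.total(CANCER)
    N = counts.total(NONCANCER)
    rows = []
    for pos in counts.positions:
        c_i = counts.get(pos, CANCER)
        n_i = counts.get(pos, NONCANCER)
        if c_i + n_i == 0:
            continue
        f_obs_c = observed_frequency(c_i, C)
        f_obs_n = observed_frequency(n_i, N)
        f_exp = (c_i + n_i) / (C + N) if C + N > 0 else math.nan
        ratio_c, ratio_n = representation_ratio(c_i, n_i, C, N)
        if C > 0 and N > 0:
            chi2, p, min_expected = chi_square_position(c_i, n_i, C, N, yates=yates)
        else:
            chi2, p, min_expected = math.nan, math.nan, math.nan
        rows.append(
            {
                "position": pos,
                "cancer": c_i,
                "non_cancer": n_i,
                "benign": counts.get(pos, "benign"),
                "f_obs_cancer": f_obs_c,
                "f_obs_noncancer": f_obs_n,
                "f_exp": f_exp,
                "ratio_cancer": ratio_c,
                "ratio_noncancer": ratio_n,
                "chi2": chi2,
                "p_value": p,
                "small_expected": bool(min_expected < 5) if not math.isnan(min_expected) else True,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "position", "cancer", "non_cancer", "benign",
            "f_obs_cancer", "f_obs_noncancer", "f_exp",
            "ratio_cancer", "ratio_noncancer", "chi2", "p_value",
            "small_expected",
        ],
    )
    if df.empty:
        df["p_adjusted"] = []
        df["label"] = []
        return df
    if bh:
        df["p_adjusted"] = _benjamini_hochberg(df["p_value"].to_numpy())
    else:
        df["p_adjusted"] = df["p_value"]
    labels = []
    for _, row in df.iterrows():
        p = row["p_adjusted"]
        ratio = row["ratio_cancer"]
        if math.isnan(p) or math.isnan(ratio):
            labels.append(LABEL_UNDEFINED)
        elif p < alpha and ratio > 1:
            labels.append(LABEL_OVER_CANCER)
        elif p < alpha and ratio < 1:
            labels.append(LABEL_OVER_NONCANCER)
        else:
            labels.append(LABEL_NOT_SIGNIFICANT)
    df["label"] = labels
    return df


def _benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Step-up BH adjustment (NaNs passed through)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    m = pm.size
    if m == 0:
        return out
    order = np.argsort(pm)
    ranked = pm[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(ranked, 1.0)
    out[mask] = adjusted
    return out
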