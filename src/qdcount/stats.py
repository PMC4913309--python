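"""Population-level scoring of single-cell drug response.

Given per-cell measurements from an untreated population ``X`` (size ``M``)
and a drug-treated population ``Y`` (size ``N``), the central statistic is
the *index of drug insensitivity*

    index(X, Y) = P(X < Y) + 0.5 P(X = Y)
               ≈ (1 / (M N)) Σ_i Σ_j [ δ(x_i < y_j) + 0.5 δ(x_i = y_j) ]

i.e. the probability that a randomly drawn treated cell has a higher signal
than a randomly drawn untreated cell, ties split evenly (the common-language
effect size of the Mann-Whitney test). An index of 0.5 means the treatment
left the population distribution unchanged (maximal insensitivity); an index
near 0 means essentially every treated cell fell below every untreated cell
(complete inhibition).

The index is computed by midranks in O((M+N) log(M+N)) and is exactly equal
to the pairwise double sum. The companion rank-sum test supplies p-values,
Holm-Šidák (default) adjustment handles multi-drug panels, and two auxiliary
effect measures mirror common reporting: the mean phosphoresponse in units
of the untreated standard deviation, and signal-to-noise against an isotype
control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PopulationSample",
    "ComparisonResult",
    "index_of_insensitivity",
    "ranksum_test",
    "adjust_pvalues",
    "mean_phosphoresponse",
    "signal_to_noise",
    "compare_conditions",
    "flag_outliers",
]


@dataclass(frozen=True)
class PopulationSample:
    """A labelled vector of per-cell measurements (counts or intensities)."""

    condition: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("PopulationSample requires a non-empty 1-D value vector")
        if not np.all(np.isfinite(vals)):
            raise ValueError("PopulationSample values must be finite")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ComparisonResult:
    """Untreated-vs-treated scoring for one drug/condition."""

    condition: str
    M: int
    N: int
    index_of_insensitivity: float
    rank_sum_U: float
    p_value: float
    p_adjusted: float
    mean_phosphoresponse: float


def _as_values(sample) -> np.ndarray:
    if isinstance(sample, PopulationSample):
        vals = sample.values
    else:
        vals = np.asarray(sample, dtype=float)
    if vals.ndim != 1 or vals.size == 0:
        raise ValueError("sample must be a non-empty 1-D array of measurements")
    if not np.all(np.isfinite(vals)):
        raise ValueError("sample values must be finite")
    return vals


def _rank_sum_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Number of (x_i, y_j) pairs with x_i < y_j, ties counted 1/2, via midranks."""
    m, n = x.size, y.size
    ranks = sps.rankdata(np.concatenate([x, y]), method="average")
    r_y = float(ranks[m:].sum())
    # Midranks make this identical to the pairwise sum, including tie halves.
    return r_y - n * (n + 1) / 2.0


def index_of_insensitivity(x, y) -> float:
    """Probability that a treated cell out-measures an untreated cell.

    Parameters
    ----------
    x : array-like or PopulationSample
        Untreated per-cell values (size M).
    y : array-like or PopulationSample
        Treated per-cell values (size N).

    Returns
    -------
    float in [0, 1]; 0.5 under identical distributions, smaller values the
    more completely treatment suppressed the signal.
    """
    xv, yv = _as_values(x), _as_values(y)
    u = _rank_sum_statistic(xv, yv)
    return u / (xv.size * yv.size)


_ALTERNATIVES = {"two_sided": "two-sided", "treated_lower": "less"}


def ranksum_test(x, y, alternative: str = "two_sided") -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) test of untreated X vs treated Y.

    Returns ``(U, p)`` where ``U = M·N × index_of_insensitivity(x, y)`` — the
    count of (x, y) pairs with the treated value larger, ties counted half.
    Exact enumeration is used for small tie-free samples (M·N ≤ 64);
    otherwise the normal approximation with tie-corrected variance and
    continuity correction. ``alternative`` is ``"two_sided"`` or
    ``"treated_lower"`` (treated population shifted down).
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    xv, yv = _as_values(x), _as_values(y)
    m, n = xv.size, yv.size
    u = _rank_sum_statistic(xv, yv)

    combined = np.concatenate([xv, yv])
    if np.all(combined == combined[0]):
        warnings.warn("all observations tied; rank-sum p-value is 1", stacklevel=2)
        return u, 1.0

    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (m * n <= 64 and not has_ties) else "asymptotic"
    # mannwhitneyu's statistic for (y, x) is exactly our pair count u.
    res = sps.mannwhitneyu(
        yv, xv, alternative=_ALTERNATIVES[alternative], method=method, use_continuity=True
    )
    return u, float(min(res.pvalue, 1.0))


_ADJUST_METHODS = {"holm_sidak": "holm-sidak", "holm": "holm", "bonferroni": "bonferroni"}


def adjust_pvalues(p_values: Sequence[float], method: str = "holm_sidak") -> np.ndarray:
    """Adjust a family of p-values for multiple comparisons.

    Default is the step-down Holm-Šidák procedure:
    sorted ascending, adjusted_i = max_{j ≤ i} 1 − (1 − p_(j))^(m − j + 1),
    clipped to [0, 1] and mapped back to input order.
    """
    if method not in _ADJUST_METHODS:
        raise ValueError(f"method must be one of {sorted(_ADJUST_METHODS)}")
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method=_ADJUST_METHODS[method])
    return np.clip(p_adj, 0.0, 1.0)


def mean_phosphoresponse(x, y) -> float:
    """Treated-minus-untreated mean shift in units of the untreated SD.

    ``(mean(Y) − mean(X)) / sd(X)`` with the sample SD (denominator M−1).
    Negative values indicate inhibition.
    """
    xv, yv = _as_values(x), _as_values(y)
    if xv.size < 2:
        raise ValueError("untreated sample needs at least 2 cells to estimate sigma")
    sd = float(np.std(xv, ddof=1))
    if sd == 0.0:
        raise ValueError("untreated sample has zero standard deviation")
    return float((np.mean(yv) - np.mean(xv)) / sd)


def signal_to_noise(signal, isotype_control) -> float:
    """Mean signal level divided by the mean isotype-control (noise floor) level."""
    sv, cv = _as_values(signal), _as_values(isotype_control)
    c_mean = float(np.mean(cv))
    if c_mean <= 0:
        raise ValueError("isotype control mean must be positive for an S/N ratio")
    return float(np.mean(sv)) / c_mean


def flag_outliers(values, untreated) -> np.ndarray:
    """Boolean flags for treated cells at or above the untreated mean.

    Marks candidate drug-insensitive single cells: treated cells whose value
    is ≥ the untreated population mean.
    """
    vv = _as_values(values)
    uv = _as_values(untreated)
    return vv >= float(np.mean(uv))


def compare_conditions(
    table: pd.DataFrame,
    value_col: str = "qd_count",
    condition_col: str = "condition",
    untreated_label: str = "untreated",
    alternative: str = "two_sided",
    adjust_method: str = "holm_sidak",
) -> pd.DataFrame:
    """Score every treated condition in a per-cell table against the untreated one.

    The adjustment family is the set of treated conditions present in the
    table (one drug panel). Returns one row per treated condition with
    columns condition, M, N, index, U, p, p_adj, mean_phosphoresponse.
    """
    if untreated_label not in set(table[condition_col]):
        raise ValueError(f"untreated reference condition {untreated_label!r} missing")
    x = table.loc[table[condition_col] == untreated_label, value_col].to_numpy(float)
    rows = []
    conditions = [c for c in pd.unique(table[condition_col]) if c != untreated_label]
    for cond in conditions:
        y = table.loc[table[condition_col] == cond, value_col].to_numpy(float)
        u, p = ranksum_test(x, y, alternative=alternative)
        rows.append(
            {
                "condition": cond,
                "M": x.size,
                "N": y.size,
                "index_of_insensitivity": index_of_insensitivity(x, y),
                "rank_sum_U": u,
                "p_value": p,
                "mean_phosphoresponse": mean_phosphoresponse(x, y),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = adjust_pvalues(out["p_value"].to_numpy(), method=adjust_method)
        out = out[
            [
                "condition",
                "M",
                "N",
                "index_of_insensitivity",
                "rank_sum_U",
                "p_value",
                "p_adjusted",
                "mean_phosphoresponse",
            ]
        ]
    return out
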