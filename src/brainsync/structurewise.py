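"""Structure-wise group comparisons of AP-binned traces.

For every brain region the AP bins act as repeated-measure blocks and the
experimental groups as conditions; the per-block condition value is the
group-mean count in that bin.  A Friedman rank test decides whether the
groups differ, Wilcoxon signed-rank post hocs with one-step Bonferroni
correction localize the pairwise differences, and a signed sum-of-differences
metric summarizes effect direction and size.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import wilcoxon_exact

__all__ = [
    "FriedmanResult",
    "DeltaSummary",
    "friedman_statistic",
    "friedman_compare",
    "posthoc_pairwise",
    "sum_of_delta",
    "compare_all_regions",
]


@dataclass(frozen=True)
class FriedmanResult:
    region_id: int
    hemisphere: str
    chi2: float
    df: int
    p: float
    n_blocks: int
    testable: bool


@dataclass(frozen=True)
class DeltaSummary:
    region_id: int
    hemisphere: str
    sum_delta: float


def friedman_statistic(values: np.ndarray) -> tuple[float, int, float]:
    """Tie-corrected Friedman chi-square on a blocks x conditions matrix.

    Ranks are assigned within each block with midranks for ties.  The
    statistic is

        chi2 = (k - 1) * sum_j (R_j - n(k+1)/2)^2 / (A - C)

    with A the sum of squared ranks and C = n k (k+1)^2 / 4; without ties
    this reduces to the classical 12/(nk(k+1)) form.  If every block is
    entirely tied (A == C) the statistic is 0 and p = 1.

    Returns (chi2, df, p) with df = k - 1.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D blocks x conditions matrix")
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 1:
        raise ValueError("need at least 1 block")
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    a_term = float((ranks**2).sum())
    c_term = n * k * (k + 1) ** 2 / 4.0
    df = k - 1
    denom = a_term - c_term
    if denom <= 0:
        return 0.0, df, 1.0
    chi2 = (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum()) / denom
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def _group_mean_matrix(traces_by_group: dict[str, np.ndarray]) -> np.ndarray:
    """Stack group-mean traces into a blocks(bins) x conditions(groups) matrix."""
    names = sorted(traces_by_group)
    means = []
    n_bins = None
    for name in names:
        arr = np.asarray(traces_by_group[name], dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"group {name!r}: expected samples x bins array")
        if n_bins is None:
            n_bins = arr.shape[1]
        elif arr.shape[1] != n_bins:
            raise ValueError("groups do not share a bin grid")
        means.append(arr.mean(axis=0))
    return np.column_stack(means)


def friedman_compare(
    traces_by_group: dict[str, np.ndarray],
    region_id: int = 0,
    hemisphere: str = "",
    min_blocks: int = 3,
) -> FriedmanResult:
    """Friedman test across groups for one region.

    ``traces_by_group`` maps group name -> (samples x bins) count array on a
    shared bin grid.  Regions with fewer than ``min_blocks`` bins are flagged
    untestable (NaN statistic/p) rather than tested.
    """
    if len(traces_by_group) < 2:
        raise ValueError("need at least 2 groups")
    mat = _group_mean_matrix(traces_by_group)
    k = mat.shape[1]
    if mat.shape[0] < min_blocks:
        return FriedmanResult(
            region_id, hemisphere, np.nan, k - 1, np.nan, mat.shape[0], False
        )
    chi2, df, p = friedman_statistic(mat)
    return FriedmanResult(region_id, hemisphere, chi2, df, p, mat.shape[0], True)


def posthoc_pairwise(
    traces_by_group: dict[str, np.ndarray],
) -> dict[tuple[str, str], float]:
    """Bonferroni-adjusted pairwise Wilcoxon tests on bin-matched group means.

    For every unordered group pair a two-sided Wilcoxon signed-rank test is
    run on the per-bin group-mean values (bins are the pairing unit) and the
    raw p is multiplied by the number of pairs, capped at 1.  Identical
    traces give an adjusted p of 1.  Intended to be applied only when the
    Friedman test is significant; the gating is the caller's concern.
    """
    names = sorted(traces_by_group)
    pairs = list(combinations(names, 2))
    n_pairs = len(pairs)
    means = {
        name: np.asarray(traces_by_group[name], dtype=float).mean(axis=0)
        for name in names
    }
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        try:
            res = wilcoxon_exact(means[a], means[b])
            p_adj = min(1.0, res.p * n_pairs)
        except ValueError:  # all differences zero
            p_adj = 1.0
        out[(a, b)] = p_adj
    return out


def sum_of_delta(
    group_a: np.ndarray,
    group_b: np.ndarray,
    region_id: int = 0,
    hemisphere: str = "",
) -> DeltaSummary:
    """Signed effect metric: all-pairs per-bin differences, averaged, summed.

    Computes, for all |A| x |B| sample pairs, the per-bin difference A - B,
    averages over pairs per bin, and sums over bins.  Algebraically equal to
    sum_bins(mean(A) - mean(B)); both routes are evaluated and cross-checked.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be samples x bins arrays on one grid")
    pair_diffs = a[:, None, :] - b[None, :, :]
    via_pairs = float(pair_diffs.mean(axis=(0, 1)).sum())
    via_means = float((a.mean(axis=0) - b.mean(axis=0)).sum())
    if not np.isclose(via_pairs, via_means, rtol=1e-9, atol=1e-7):
        raise AssertionError("sum_of_delta identity violated")  # pragma: no cover
    return DeltaSummary(region_id, hemisphere, via_pairs)


def compare_all_regions(
    traces: np.ndarray,
    group_of_sample: np.ndarray,
    region_ids: np.ndarray,
    hemispheres: np.ndarray,
    delta_pair: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Friedman + gated post hocs + sum-of-delta over a cohort array.

    ``traces`` is (samples x regions x bins); ``group_of_sample`` labels each
    sample.  If ``delta_pair`` = (A, B) is given the sum-of-delta column is
    A - B, otherwise it is omitted.
    """
    groups = sorted(set(group_of_sample.tolist()))
    rows = []
    for ri in range(traces.shape[1]):
        by_group = {
            g: traces[np.asarray(group_of_sample) == g, ri, :] for g in groups
        }
        fr = friedman_compare(
            by_group, region_id=int(region_ids[ri]), hemisphere=str(hemispheres[ri])
        )
        row: dict = {
            "region_id": fr.region_id,
            "hemisphere": fr.hemisphere,
            "chi2": fr.chi2,
            "df": fr.df,
            "p": fr.p,
            "n_blocks": fr.n_blocks,
            "testable": fr.testable,
        }
        if fr.testable and fr.p < alpha:
            for (a, b), p_adj in posthoc_pairwise(by_group).items():
                row[f"p_adj[{a}|{b}]"] = p_adj
        if delta_pair is not None:
            ga, gb = delta_pair
            row["sum_delta"] = sum_of_delta(
                by_group[ga], by_group[gb], fr.region_id, fr.hemisphere
            ).sum_delta
        rows.append(row)
    return pd.DataFrame(rows)
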