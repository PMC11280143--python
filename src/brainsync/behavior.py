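"""Behavior-time aggregation and exact paired nonparametric tests.

Frame-level behavior labels (one boolean per video frame per behavior class)
are summed into per-session durations, and paired ctrl/TBS durations are
compared with a two-tailed Wilcoxon signed-rank test whose p-value is exact:
the null distribution of the statistic is obtained from all 2^n sign
assignments of the ranked absolute differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WilcoxonResult",
    "total_time",
    "wilcoxon_exact",
    "behavior_table_tests",
    "signed_rank_counts",
]

#: behavior classes used throughout the synthetic tables
BEHAVIOR_CLASSES = (
    "nose_to_nose",
    "side_by_side",
    "side_reverse_side",
    "nose_to_tail",
    "nose_to_body",
    "following",
    "sniffing",
    "huddle",
    "lookaround",
    "climbing",
)

EXPECTED_SESSION_FRAMES = 18_000  # 10-minute session at 30 fps


@dataclass(frozen=True)
class WilcoxonResult:
    """Outcome of a two-tailed Wilcoxon signed-rank test.

    ``w`` is the smaller of the positive/negative signed-rank sums; ``p`` is
    the two-tailed p-value.  ``exact`` records whether the full enumeration
    null was used (it is not when |differences| are tied, in which case a
    midrank normal approximation is applied and flagged here).
    """

    behavior: str
    n_pairs: int
    w: float
    p: float
    exact: bool


def total_time(
    frame_labels: pd.DataFrame,
    fps: float = 30.0,
    expected_frames: int | None = EXPECTED_SESSION_FRAMES,
) -> pd.DataFrame:
    """Sum labeled frames into seconds per (mouse, behavior, condition).

    Parameters
    ----------
    frame_labels
        Long table with columns ``mouse_id``, ``behavior``, ``condition``,
        ``frame_index``, ``label`` (boolean / 0-1).
    fps
        Frames per second of the recording.
    expected_frames
        If given, a warning is emitted for sessions whose frame count
        differs from this value (not fatal).

    Returns
    -------
    DataFrame with columns ``mouse_id``, ``behavior``, ``condition``,
    ``seconds``.
    """
    required = {"mouse_id", "behavior", "condition", "frame_index", "label"}
    missing = required - set(frame_labels.columns)
    if missing:
        raise ValueError(f"frame_labels missing columns: {sorted(missing)}")

    if expected_frames is not None:
        session_sizes = frame_labels.groupby(
            ["mouse_id", "behavior", "condition"], sort=False
        )["frame_index"].nunique()
        odd = session_sizes[session_sizes != expected_frames]
        if len(odd):
            warnings.warn(
                f"{len(odd)} session(s) do not have {expected_frames} frames",
                stacklevel=2,
            )

    out = (
        frame_labels.assign(label=lambda d: d["label"].astype(bool))
        .groupby(["mouse_id", "behavior", "condition"], sort=True)["label"]
        .sum()
        .rename("seconds")
        .astype(float)
        / float(fps)
    )
    return out.reset_index()


def signed_rank_counts(n: int) -> np.ndarray:
    """Number of subsets of {1..n} with each possible rank sum.

    Returns an integer array ``c`` of length n(n+1)/2 + 1 where ``c[s]`` is
    the number of sign assignments whose positive-rank sum equals ``s``.
    Computed by dynamic programming over the generating polynomial
    prod_{k=1..n} (1 + x^k); identical to enumerating all 2^n assignments.
    """
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for k in range(1, n + 1):
        counts[k:] += counts[: total + 1 - k].copy()
    return counts


def _exact_min_rank_sum_p(w_obs: float, n: int) -> float:
    # P(min(W+, W-) <= w_obs) over all 2^n equiprobable sign assignments
    counts = signed_rank_counts(n)
    total = n * (n + 1) // 2
    s = np.arange(total + 1)
    hit = (s <= w_obs) | (s >= total - w_obs)
    return float(counts[hit].sum()) / float(2**n)


def wilcoxon_exact(
    paired_a: np.ndarray,
    paired_b: np.ndarray,
    behavior: str = "",
    max_exact_n: int = 25,
) -> WilcoxonResult:
    """Two-tailed Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped before ranking (classical convention).
    With no ties among |differences| and n <= ``max_exact_n`` the p-value is
    exact: p = P(min(W+, W-) <= W_observed) under the enumeration null.
    Otherwise midranks are used and a tie-corrected normal approximation is
    applied (``exact=False`` in the result).

    Raises
    ------
    ValueError
        If the inputs differ in length or all differences are zero
        (untestable).
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero: untestable")

    absd = np.abs(d)
    ranks = stats.rankdata(absd)  # midranks
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)

    has_ties = np.unique(absd).size < n
    if not has_ties and n <= max_exact_n:
        p = _exact_min_rank_sum_p(w, n)
        return WilcoxonResult(behavior, n, w, p, exact=True)

    # midrank normal approximation with tie correction
    mean = n * (n + 1) / 4.0
    tie_counts = np.unique(absd, return_counts=True)[1]
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise ValueError("degenerate variance in signed-rank approximation")
    z = (w_pos - mean) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = min(1.0, p)
    return WilcoxonResult(behavior, n, w, p, exact=False)


def behavior_table_tests(
    table: pd.DataFrame,
    condition_a: str = "ctrl",
    condition_b: str = "TBS",
) -> pd.DataFrame:
    """Run the paired test per behavior on a durations table.

    ``table`` must have columns ``mouse_id``, ``behavior``, ``condition``,
    ``seconds`` with one row per (mouse, behavior, condition).  Behaviors
    whose differences are all zero are reported with NaN p and flagged
    untestable.
    """
    rows = []
    for behavior, sub in table.groupby("behavior", sort=True):
        wide = sub.pivot(index="mouse_id", columns="condition", values="seconds")
        if condition_a not in wide or condition_b not in wide:
            raise ValueError(
                f"behavior {behavior!r} lacks condition "
                f"{condition_a!r} or {condition_b!r}"
            )
        a = wide[condition_a].to_numpy()
        bvals = wide[condition_b].to_numpy()
        try:
            res = wilcoxon_exact(a, bvals, behavior=behavior)
            rows.append(
                {
                    "behavior": behavior,
                    "n_pairs": res.n_pairs,
                    "W": res.w,
                    "p": res.p,
                    "exact": res.exact,
                    "testable": True,
                }
            )
        except ValueError:
            rows.append(
                {
                    "behavior": behavior,
                    "n_pairs": 0,
                    "W": np.nan,
                    "p": np.nan,
                    "exact": False,
                    "testable": False,
                }
            )
    return pd.DataFrame(rows)
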