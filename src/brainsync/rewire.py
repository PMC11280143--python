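"""Rewiring / activity-modulation correlation classifier.

For each candidate region, all pairwise genotype difference traces of the
axon label (one trace per mutant/wild-type sample pair) and the second-order
stimulation difference traces of the activity marker are reduced to mean
traces; their Pearson correlation is classified as positive, negative, or
none against a bin-reshuffled null using three criteria:

1. r beyond the 95th (positive) / 5th (negative) percentile of the shuffled
   r distribution;
2. |r| > 0.1 with matching sign;
3. the product of the two trace "tendencies" (signed sums of scaled bins
   exceeding the shuffled 99th-percentile magnitude threshold) has matching
   sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DeltaTraceSet",
    "NullDistributions",
    "CorrClassification",
    "delta_traces",
    "ddcfos",
    "correlate_region",
    "reshuffle_null",
    "tendency",
    "classify",
    "classify_region",
]


@dataclass(frozen=True)
class DeltaTraceSet:
    """All pairwise difference traces for one region plus their mean."""

    region_id: int
    hemisphere: str
    pair_traces: np.ndarray  # (n_pairs, n_bins)
    mean_trace: np.ndarray  # (n_bins,)


@dataclass(frozen=True)
class NullDistributions:
    r_shuffled: np.ndarray  # (n_shuffles,)
    tendency_threshold_ochief: float
    tendency_threshold_ddcfos: float
    scale_ochief: float
    scale_ddcfos: float
    degenerate: bool


@dataclass(frozen=True)
class CorrClassification:
    region_id: int
    r: float
    r_null_quantiles: tuple[float, float]  # (5th, 95th) percentile
    tendency_ochief: float
    tendency_ddcfos: float
    label: str  # "positive" | "negative" | "none"
    extras: dict = field(default_factory=dict)


def delta_traces(
    group_a: np.ndarray,
    group_b: np.ndarray,
    region_id: int = 0,
    hemisphere: str = "",
) -> DeltaTraceSet:
    """All ordered (A_i - B_j) traces on a shared bin grid, plus the mean."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be samples x bins arrays on one grid")
    pairs = (a[:, None, :] - b[None, :, :]).reshape(-1, a.shape[1])
    return DeltaTraceSet(region_id, hemisphere, pairs, pairs.mean(axis=0))


def ddcfos(mut_deltas: DeltaTraceSet, wt_deltas: DeltaTraceSet) -> DeltaTraceSet:
    """Second-order differences: every mutant delta minus every WT delta."""
    m = mut_deltas.pair_traces
    w = wt_deltas.pair_traces
    if m.shape[1] != w.shape[1]:
        raise ValueError("delta trace sets are not on a shared bin grid")
    pairs = (m[:, None, :] - w[None, :, :]).reshape(-1, m.shape[1])
    return DeltaTraceSet(
        mut_deltas.region_id, mut_deltas.hemisphere, pairs, pairs.mean(axis=0)
    )


def correlate_region(mean_x: np.ndarray, mean_y: np.ndarray) -> float:
    """Pearson r between two mean traces; NaN when either is constant."""
    x = np.asarray(mean_x, dtype=float)
    y = np.asarray(mean_y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 overlapping finite bins")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _family_permutations(
    rng: np.random.Generator, n_shuffles: int, n_traces: int, n_bins: int
) -> np.ndarray:
    # independent bin permutation per trace per shuffle
    return np.argsort(rng.random((n_shuffles, n_traces, n_bins)), axis=-1)


def _shuffled_means(traces: np.ndarray, perms: np.ndarray) -> np.ndarray:
    # traces: (T, B); perms: (S, T, B) -> (S, B) means over shuffled traces
    shuffled = np.take_along_axis(traces[None, :, :], perms, axis=2)
    return shuffled.mean(axis=1)


def _scale_of(mean_trace: np.ndarray) -> float:
    s = float(np.max(np.abs(mean_trace)))
    return s if s > 0 else 1.0


def reshuffle_null(
    dochief_pairs: np.ndarray,
    wt_dcfos_pairs: np.ndarray,
    mut_dcfos_pairs: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    tendency_pct: float = 99.0,
) -> NullDistributions:
    """Bin-reshuffled null for the mean-trace correlation and tendencies.

    For the correlation null, each shuffle draws one AP-bin permutation per
    trace family (the three families are reshuffled independently of one
    another), which permutes the family mean traces; the Pearson r of each
    shuffled mean pair forms ``r_shuffled``.  The second-order mean is the
    mutant delta mean minus the WT delta mean, which equals the mean over
    all second-order pairs.

    For the tendency thresholds, each shuffle instead permutes every
    pairwise difference trace of the population independently (a common
    permutation would leave the mean trace's value set — hence its
    percentiles — unchanged); the threshold of a family is the
    across-shuffle mean of the ``tendency_pct`` percentile of the |scaled|
    shuffled mean trace, where scaling divides by the max |mean trace| of
    the unshuffled family.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    do = np.asarray(dochief_pairs, dtype=float)
    wt = np.asarray(wt_dcfos_pairs, dtype=float)
    mu = np.asarray(mut_dcfos_pairs, dtype=float)
    n_bins = do.shape[1]
    if wt.shape[1] != n_bins or mu.shape[1] != n_bins:
        raise ValueError("trace families are not on a shared bin grid")

    mean_do = do.mean(axis=0)
    mean_dd = mu.mean(axis=0) - wt.mean(axis=0)
    scale_do = _scale_of(mean_do)
    scale_dd = _scale_of(mean_dd)
    degenerate = np.ptp(mean_do) == 0.0 or np.ptp(mean_dd) == 0.0
    if degenerate:
        warnings.warn("constant mean trace: degenerate reshuffling null", stacklevel=2)

    # correlation null: one permutation per family per shuffle, applied to
    # the family mean traces
    perm = np.argsort(rng.random((3, n_shuffles, n_bins)), axis=-1)
    p_do = mean_do[perm[0]]
    p_dd = (mu.mean(axis=0))[perm[1]] - (wt.mean(axis=0))[perm[2]]

    # vectorized Pearson r per shuffle
    xc = p_do - p_do.mean(axis=1, keepdims=True)
    yc = p_dd - p_dd.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_shuffled = (xc * yc).sum(axis=1) / denom
    r_shuffled = r_shuffled[np.isfinite(r_shuffled)]

    # tendency null: independent permutation per trace per shuffle; traces
    # are put in canonical (lexicographic) order first so the result does
    # not depend on sample ordering
    do_c, wt_c, mu_c = (a[np.lexsort(a.T[::-1])] for a in (do, wt, mu))
    s_do = _shuffled_means(do_c, _family_permutations(rng, n_shuffles, *do.shape))
    s_wt = _shuffled_means(wt_c, _family_permutations(rng, n_shuffles, *wt.shape))
    s_mu = _shuffled_means(mu_c, _family_permutations(rng, n_shuffles, *mu.shape))
    s_dd = s_mu - s_wt
    thr_do = float(
        np.mean(np.percentile(np.abs(s_do) / scale_do, tendency_pct, axis=1))
    )
    thr_dd = float(
        np.mean(np.percentile(np.abs(s_dd) / scale_dd, tendency_pct, axis=1))
    )
    return NullDistributions(r_shuffled, thr_do, thr_dd, scale_do, scale_dd, degenerate)


def tendency(mean_trace: np.ndarray, scale: float, threshold: float) -> float:
    """Signed sum of scaled bins whose magnitude exceeds the null threshold.

    Returns 0.0 when no bin exceeds the threshold (which forces the
    classification to "none" through the sign-product criterion).
    """
    scaled = np.asarray(mean_trace, dtype=float) / scale
    over = np.abs(scaled) > threshold
    if not over.any():
        return 0.0
    return float(scaled[over].sum())


def classify(
    r: float,
    null: NullDistributions,
    tendency_ochief: float,
    tendency_ddcfos: float,
    r_cut: float = 0.1,
    null_pct: float = 95.0,
    region_id: int = 0,
) -> CorrClassification:
    """Apply the three-criterion rule to one region's correlation."""
    if null.r_shuffled.size == 0 or not np.isfinite(r):
        lo, hi = np.nan, np.nan
        label = "none"
    else:
        lo = float(np.percentile(null.r_shuffled, 100.0 - null_pct))
        hi = float(np.percentile(null.r_shuffled, null_pct))
        product = tendency_ochief * tendency_ddcfos
        if r > hi and r > r_cut and product > 0:
            label = "positive"
        elif r < lo and r < -r_cut and product < 0:
            label = "negative"
        else:
            label = "none"
    return CorrClassification(
        region_id=region_id,
        r=float(r),
        r_null_quantiles=(lo, hi),
        tendency_ochief=tendency_ochief,
        tendency_ddcfos=tendency_ddcfos,
        label=label,
    )


def classify_region(
    ochief_mut: np.ndarray,
    ochief_wt: np.ndarray,
    cfos_wt_tbs: np.ndarray,
    cfos_wt_ctrl: np.ndarray,
    cfos_mut_tbs: np.ndarray,
    cfos_mut_ctrl: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    r_cut: float = 0.1,
    null_pct: float = 95.0,
    tendency_pct: float = 99.0,
    region_id: int = 0,
    hemisphere: str = "",
) -> CorrClassification:
    """End-to-end classification of one region from raw group traces."""
    d_ochief = delta_traces(ochief_mut, ochief_wt, region_id, hemisphere)
    d_wt = delta_traces(cfos_wt_tbs, cfos_wt_ctrl, region_id, hemisphere)
    d_mut = delta_traces(cfos_mut_tbs, cfos_mut_ctrl, region_id, hemisphere)
    dd = ddcfos(d_mut, d_wt)
    r = correlate_region(d_ochief.mean_trace, dd.mean_trace)
    null = reshuffle_null(
        d_ochief.pair_traces,
        d_wt.pair_traces,
        d_mut.pair_traces,
        n_shuffles=n_shuffles,
        seed=seed,
        tendency_pct=tendency_pct,
    )
    t_o = tendency(d_ochief.mean_trace, null.scale_ochief, null.tendency_threshold_ochief)
    t_d = tendency(dd.mean_trace, null.scale_ddcfos, null.tendency_threshold_ddcfos)
    out = classify(
        r, null, t_o, t_d, r_cut=r_cut, null_pct=null_pct, region_id=region_id
    )
    out.extras["sum_dochief"] = float(d_ochief.mean_trace.sum())
    out.extras["hemisphere"] = hemisphere
    return out
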