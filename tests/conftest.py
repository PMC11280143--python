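"""Shared fixtures: small synthetic atlases and cohorts, oracle helpers."""

from itertools import permutations

import numpy as np
import pytest

from brainsync import synthdata as sd


@pytest.fixture(scope="session")
def small_atlas():
    return sd.make_atlas(8, 2000.0, seed=0)


@pytest.fixture(scope="session")
def null_cohort(small_atlas):
    """No planted effects at all."""
    return sd.simulate_cohort(small_atlas, sd.CohortDesign(n_per_group=7), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


# ------------------------------------------------------------- oracles
# These stay independent of the package implementations they check.


def wilcoxon_bruteforce_p(diffs: np.ndarray) -> tuple[float, float]:
    """Enumerate all 2^n sign assignments; p = P(min(W+, W-) <= W_obs)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    order = np.argsort(np.abs(d))
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    w_pos = ranks[d > 0].sum()
    w_obs = min(w_pos, ranks.sum() - w_pos)
    signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(bool)
    w_plus = np.where(signs, ranks, 0.0).sum(axis=1)
    w_min = np.minimum(w_plus, ranks.sum() - w_plus)
    return float(w_obs), float(np.mean(w_min <= w_obs))


def kendall_enumeration_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p over all n! orderings (untied data)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    perms = np.array(list(permutations(range(n))))
    iu = np.triu_indices(n, 1)
    sx = np.sign(x[iu[0]] - x[iu[1]])
    sy_all = np.sign(y[perms][:, iu[0]] - y[perms][:, iu[1]])
    d = (sx[None, :] * sy_all).sum(axis=1)
    d_obs = float((sx * np.sign(y[iu[0]] - y[iu[1]])).sum())
    return float(np.mean(np.abs(d) >= abs(d_obs)))


def friedman_rank_oracle(mat: np.ndarray) -> tuple[float, int, float]:
    """Friedman chi-square by explicit comparison-count midranks."""
    from scipy.stats import chi2 as chi2_dist

    mat = np.asarray(mat, dtype=float)
    n, k = mat.shape
    ranks = np.zeros_like(mat)
    for b in range(n):
        for j in range(k):
            less = np.sum(mat[b] < mat[b, j])
            equal = np.sum(mat[b] == mat[b, j])  # includes self
            ranks[b, j] = less + (equal + 1) / 2.0
    col = ranks.sum(axis=0)
    a_term = (ranks**2).sum()
    c_term = n * k * (k + 1) ** 2 / 4.0
    if a_term - c_term <= 0:
        return 0.0, k - 1, 1.0
    chi2 = (k - 1) * ((col - n * (k + 1) / 2.0) ** 2).sum() / (a_term - c_term)
    return float(chi2), k - 1, float(chi2_dist.sf(chi2, k - 1))
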