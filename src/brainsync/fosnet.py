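"""Interregional activity-correlation networks.

One network per experimental group: pairwise two-sided Kendall tau-b across
samples on per-region activity densities, gated at p < 0.05 (nonsignificant
entries set to exactly 0), then graph construction, degree centrality and
participation coefficient, threshold-stability sweeps, area-level summaries,
and subnetwork extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrMatrix",
    "correlation_matrix",
    "build_graph",
    "node_metrics",
    "stability_sweep",
    "area_summary",
    "negative_fraction",
    "extract_subnetwork",
    "DMN_CORE_ACRONYMS",
]

#: core default-mode-network region acronyms (prefrontal, somatomotor, medial)
DMN_CORE_ACRONYMS = (
    "ACAd", "ACAv", "PL", "ILA", "ORBl", "ORBm", "ORBvl",
    "SSp-tr", "SSp-ll", "MOs",
    "VISa", "VISam", "RSPagl", "RSPd", "RSPv",
)


@dataclass(frozen=True)
class CorrMatrix:
    """Significance-gated symmetric correlation matrix for one group."""

    group: str
    regions: list
    r: np.ndarray  # zeros where not significant; zero diagonal
    p: np.ndarray  # two-sided p-values (diagonal = 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.regions, columns=self.regions)


def _kendall(x: np.ndarray, y: np.ndarray, exact_n_max: int) -> tuple[float, float]:
    n = x.size
    no_ties = np.unique(x).size == n and np.unique(y).size == n
    method = "exact" if (no_ties and n < exact_n_max) else "asymptotic"
    res = stats.kendalltau(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def correlation_matrix(
    density: pd.DataFrame,
    group: str = "",
    p_max: float = 0.05,
    exact_n_max: int = 10,
) -> CorrMatrix:
    """Gated Kendall tau-b matrix from a samples x regions density table.

    Exact two-sided p-values are used for small sample counts without ties
    (full permutation null); the tie-corrected normal approximation is used
    otherwise.  Entries with p >= ``p_max`` are set to exactly 0, as is the
    diagonal.  Regions that are constant across samples get all-zero entries
    with a warning.
    """
    if density.shape[0] < 4:
        raise ValueError("need at least 4 samples per group")
    regions = list(density.columns)
    x = density.to_numpy(dtype=float)
    n_reg = len(regions)
    r = np.zeros((n_reg, n_reg))
    p = np.ones((n_reg, n_reg))
    constant = [regions[j] for j in range(n_reg) if np.ptp(x[:, j]) == 0.0]
    if constant:
        warnings.warn(
            f"constant regions (all entries gated to 0): {constant}", stacklevel=2
        )
    for i in range(n_reg):
        for j in range(i + 1, n_reg):
            if np.ptp(x[:, i]) == 0.0 or np.ptp(x[:, j]) == 0.0:
                continue
            tau, pv = _kendall(x[:, i], x[:, j], exact_n_max)
            p[i, j] = p[j, i] = pv
            if pv < p_max:
                r[i, j] = r[j, i] = tau
    return CorrMatrix(group, regions, r, p)


def build_graph(
    matrix: CorrMatrix, r_abs_min: float = 0.0, p_max: float = 0.05
) -> nx.Graph:
    """Weighted graph with an edge iff |r| >= r_abs_min and p < p_max."""
    g = nx.Graph()
    g.add_nodes_from(matrix.regions)
    n = len(matrix.regions)
    for i in range(n):
        for j in range(i + 1, n):
            rij = matrix.r[i, j]
            if rij != 0.0 and abs(rij) >= r_abs_min and matrix.p[i, j] < p_max:
                g.add_edge(matrix.regions[i], matrix.regions[j], weight=float(rij))
    return g


def node_metrics(graph: nx.Graph, partition: dict) -> pd.DataFrame:
    """Degree centrality and participation coefficient per node.

    DC = degree / (N - 1).  PC_i = 1 - sum_m (k_im / k_i)^2 over the
    communities m of ``partition`` using binary degrees; an isolated node has
    DC = PC = 0.
    """
    missing = [v for v in graph.nodes if v not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    n = graph.number_of_nodes()
    rows = []
    for v in graph.nodes:
        k = graph.degree(v)
        dc = k / (n - 1) if n > 1 else 0.0
        if k == 0:
            pc = 0.0
        else:
            per_comm: dict = {}
            for u in graph.neighbors(v):
                per_comm[partition[u]] = per_comm.get(partition[u], 0) + 1
            pc = 1.0 - sum((km / k) ** 2 for km in per_comm.values())
        rows.append({"region": v, "DC": dc, "PC": pc})
    return pd.DataFrame(rows).set_index("region")


def stability_sweep(
    matrix: CorrMatrix,
    r_grid: np.ndarray,
    p_grid: np.ndarray,
) -> pd.DataFrame:
    """Mean graph-degree DC over an (|r|, p) threshold grid.

    Mean DC is computed from the degree of the thresholded graph (not the
    gated matrix), one row per (r_abs_min, p_max) pair.
    """
    rows = []
    n = len(matrix.regions)
    for r_min in np.asarray(r_grid, dtype=float):
        for pm in np.asarray(p_grid, dtype=float):
            g = build_graph(matrix, r_abs_min=r_min, p_max=pm)
            mean_dc = (
                np.mean([d for _, d in g.degree()]) / (n - 1) if n > 1 else 0.0
            )
            rows.append({"r_abs_min": r_min, "p_max": pm, "mean_DC": float(mean_dc)})
    return pd.DataFrame(rows)


def area_summary(
    matrix: CorrMatrix,
    region_to_area: dict,
    include_gated_zeros: bool = True,
) -> pd.DataFrame:
    """Mean correlation within and between parent brain areas.

    By default gated-to-zero entries participate in the means with value 0
    ("no correlation"); pass ``include_gated_zeros=False`` to average over
    significant entries only.  A within-area mean is missing (NaN) for areas
    with fewer than 2 regions.
    """
    areas = sorted({region_to_area[r] for r in matrix.regions})
    idx_of_area = {
        a: [i for i, reg in enumerate(matrix.regions) if region_to_area[reg] == a]
        for a in areas
    }
    rows = []
    for ai, a in enumerate(areas):
        for b in areas[ai:]:
            ia, ib = idx_of_area[a], idx_of_area[b]
            if a == b:
                if len(ia) < 2:
                    rows.append({"area_a": a, "area_b": b, "mean_r": np.nan})
                    continue
                sub = matrix.r[np.ix_(ia, ia)]
                iu = np.triu_indices(len(ia), k=1)
                vals = sub[iu]
                pvals = matrix.p[np.ix_(ia, ia)][iu]
            else:
                vals = matrix.r[np.ix_(ia, ib)].ravel()
                pvals = matrix.p[np.ix_(ia, ib)].ravel()
            if not include_gated_zeros:
                keep = pvals < 0.05
                vals = vals[keep]
            mean_r = float(vals.mean()) if vals.size else np.nan
            rows.append({"area_a": a, "area_b": b, "mean_r": mean_r})
    return pd.DataFrame(rows)


def negative_fraction(matrix: CorrMatrix, p_max: float = 0.05) -> float:
    """Fraction of significant upper-triangle entries with r < 0."""
    iu = np.triu_indices(len(matrix.regions), k=1)
    sig = matrix.p[iu] < p_max
    if not sig.any():
        return 0.0
    return float((matrix.r[iu][sig] < 0.0).mean())


def extract_subnetwork(matrix: CorrMatrix, regions: list) -> CorrMatrix:
    """Row/column restriction of a gated matrix to the listed regions.

    Regions absent from the matrix are reported via a warning; an empty
    intersection is an error.
    """
    present = [r for r in regions if r in matrix.regions]
    absent = [r for r in regions if r not in matrix.regions]
    if absent:
        warnings.warn(f"regions not in matrix (skipped): {absent}", stacklevel=2)
    if not present:
        raise ValueError("no requested region is present in the matrix")
    idx = [matrix.regions.index(r) for r in present]
    return CorrMatrix(
        matrix.group,
        present,
        matrix.r[np.ix_(idx, idx)].copy(),
        matrix.p[np.ix_(idx, idx)].copy(),
    )
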