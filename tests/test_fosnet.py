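import networkx as nx
import numpy as np
import pandas as pd
import pytest

from brainsync import fosnet as fn
from conftest import kendall_enumeration_p


def _matrix_from(r, p=None, regions=None):
    n = r.shape[0]
    regions = regions or list(range(n))
    if p is None:
        p = np.where(r != 0, 0.001, 1.0)
        np.fill_diagonal(p, 1.0)
    return fn.CorrMatrix("g", regions, r, p)


class TestCorrelationMatrix:
    def test_concordant_pair_n7_exact_p(self, rng):
        x = np.arange(7.0)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.normal(size=7)})
        mat = fn.correlation_matrix(df)
        i, j = mat.regions.index("a"), mat.regions.index("b")
        assert mat.r[i, j] == pytest.approx(1.0)
        assert mat.p[i, j] == pytest.approx(2 / 5040, rel=1e-9)

    def test_n4_single_discordance_gated(self):
        # tau from one discordant pair at n=4 is not significant
        df = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 4.0, 3.0]}
        )
        mat = fn.correlation_matrix(df)
        assert mat.p[0, 1] >= 0.05
        assert mat.r[0, 1] == 0.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 8))
            df = pd.DataFrame(
                {
                    "a": rng.permutation(n).astype(float),
                    "b": rng.permutation(n).astype(float),
                    "c": rng.permutation(n).astype(float),
                    "d": rng.permutation(n).astype(float),
                }
            )
            mat = fn.correlation_matrix(df)
            cols = list(df.columns)
            for i in range(4):
                for j in range(i + 1, 4):
                    p_oracle = kendall_enumeration_p(
                        df[cols[i]].to_numpy(), df[cols[j]].to_numpy()
                    )
                    assert mat.p[i, j] == pytest.approx(p_oracle, abs=1e-12)

    def test_symmetry_zero_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(8, 5)))
        mat = fn.correlation_matrix(df)
        assert np.array_equal(mat.r, mat.r.T)
        assert np.all(np.diag(mat.r) == 0.0)
        assert np.all(np.abs(mat.r) <= 1.0)
        assert np.all(mat.r[mat.p >= 0.05] == 0.0)

    def test_constant_region_warns(self, rng):
        df = pd.DataFrame({"a": np.ones(6), "b": rng.normal(size=6)})
        with pytest.warns(UserWarning, match="constant"):
            mat = fn.correlation_matrix(df)
        assert np.all(mat.r[0] == 0.0)

    def test_needs_four_samples(self, rng):
        with pytest.raises(ValueError):
            fn.correlation_matrix(pd.DataFrame(rng.normal(size=(3, 4))))


class TestGraphAndMetrics:
    def test_all_zero_matrix_edgeless(self):
        mat = _matrix_from(np.zeros((4, 4)), p=np.ones((4, 4)))
        assert fn.build_graph(mat).number_of_edges() == 0

    def test_raising_threshold_monotone(self, rng):
        r = rng.uniform(-1, 1, (10, 10))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0.0)
        mat = _matrix_from(r)
        prev = None
        for r_min in [0.0, 0.3, 0.6, 0.9]:
            edges = set(fn.build_graph(mat, r_abs_min=r_min).edges())
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_hand_built_adjacency(self):
        r = np.zeros((3, 3))
        r[0, 1] = r[1, 0] = 0.8
        r[1, 2] = r[2, 1] = -0.5
        mat = _matrix_from(r, regions=["x", "y", "z"])
        g = fn.build_graph(mat)
        assert set(g.edges()) == {("x", "y"), ("y", "z")}
        assert g["x"]["y"]["weight"] == pytest.approx(0.8)

    def test_complete_graph_dc_one(self):
        g = nx.complete_graph(6)
        met = fn.node_metrics(g, {v: 0 for v in g})
        assert np.allclose(met["DC"], 1.0)

    def test_pc_zero_within_own_community(self):
        g = nx.complete_graph(4)
        met = fn.node_metrics(g, {v: 0 for v in g})
        assert np.allclose(met["PC"], 0.0)

    def test_pc_half_for_two_two_split(self):
        g = nx.Graph()
        g.add_edges_from([("v", a) for a in "abcd"])
        partition = {"v": 0, "a": 1, "b": 1, "c": 2, "d": 2}
        met = fn.node_metrics(g, partition)
        assert met.loc["v", "PC"] == pytest.approx(0.5)

    def test_isolated_node_zeros(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        met = fn.node_metrics(g, {"a": 0, "b": 0})
        assert met.loc["a", "DC"] == 0.0
        assert met.loc["a", "PC"] == 0.0


class TestSweepAndSummaries:
    def test_mean_dc_nonincreasing_in_r(self, rng):
        r = rng.uniform(-1, 1, (12, 12))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0.0)
        mat = _matrix_from(r)
        sweep = fn.stability_sweep(mat, np.linspace(0, 1, 6), [0.05])
        dc = sweep.sort_values("r_abs_min")["mean_DC"].to_numpy()
        assert np.all(np.diff(dc) <= 1e-12)

    def test_ungated_point_matches_plain_graph(self, rng):
        r = rng.uniform(0, 1, (8, 8))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0.0)
        mat = _matrix_from(r)
        sweep = fn.stability_sweep(mat, [0.0], [1.0])
        g = fn.build_graph(mat, 0.0, 1.0)
        expect = np.mean([d for _, d in g.degree()]) / 7
        assert sweep["mean_DC"].iloc[0] == pytest.approx(expect)

    def test_block_diagonal_between_zero(self):
        r = np.zeros((4, 4))
        r[0, 1] = r[1, 0] = 0.5
        r[2, 3] = r[3, 2] = 0.5
        mat = _matrix_from(r)
        out = fn.area_summary(mat, {0: "A", 1: "A", 2: "B", 3: "B"})
        between = out[(out.area_a == "A") & (out.area_b == "B")]
        assert between["mean_r"].iloc[0] == 0.0

    def test_uniform_matrix_all_means_equal(self):
        r = np.full((6, 6), 0.5)
        np.fill_diagonal(r, 0.0)
        mat = _matrix_from(r)
        out = fn.area_summary(mat, {i: "A" if i < 3 else "B" for i in range(6)})
        assert np.allclose(out["mean_r"], 0.5)

    def test_single_region_area_missing_within(self):
        r = np.zeros((3, 3))
        mat = _matrix_from(r, p=np.ones((3, 3)))
        out = fn.area_summary(mat, {0: "A", 1: "B", 2: "B"})
        within_a = out[(out.area_a == "A") & (out.area_b == "A")]
        assert np.isnan(within_a["mean_r"].iloc[0])

    def test_negative_fraction(self):
        r = np.zeros((21, 21))
        p = np.ones((21, 21))
        k = 0
        iu = list(zip(*np.triu_indices(21, 1)))
        for i, j in iu[:200]:
            val = -0.5 if k < 3 else 0.5
            r[i, j] = r[j, i] = val
            p[i, j] = p[j, i] = 0.01
            k += 1
        mat = _matrix_from(r, p=p)
        assert fn.negative_fraction(mat) == pytest.approx(3 / 200)
        none = _matrix_from(np.zeros((4, 4)), p=np.ones((4, 4)))
        assert fn.negative_fraction(none) == 0.0

    def test_extract_subnetwork(self, rng):
        r = rng.uniform(-1, 1, (6, 6))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0.0)
        mat = _matrix_from(r, regions=list("abcdef"))
        sub = fn.extract_subnetwork(mat, ["b", "d", "f"])
        assert sub.regions == ["b", "d", "f"]
        assert sub.r[0, 1] == mat.r[1, 3]
        with pytest.warns(UserWarning, match="skipped"):
            sub2 = fn.extract_subnetwork(mat, ["a", "zz"])
        assert sub2.regions == ["a"]
        with pytest.raises(ValueError):
            fn.extract_subnetwork(mat, ["zz"])

    def test_planted_communities_within_above_between(self, small_atlas):
        from brainsync import synthdata as sd

        contra = [r.region_id for r in small_atlas.regions if r.hemisphere == "contra"]
        comms = {"C1": contra[:4], "C2": contra[4:]}
        wins = 0
        for seed in range(8):
            design = sd.CohortDesign(
                n_per_group={"WT_ctrl": 8, "WT_TBS": 3, "Tbr1het_ctrl": 3, "Tbr1het_TBS": 3},
                communities=comms,
                loadings={"C1": 0.9, "C2": 0.9},
            )
            c = sd.simulate_cohort(small_atlas, design, seed=seed)
            grp = c.sample_mask("WT", "ctrl")
            dens = c.density().loc[np.array(c.sample_ids)[grp], contra]
            mat = fn.correlation_matrix(dens)
            out = fn.area_summary(
                mat, {rid: ("C1" if rid in comms["C1"] else "C2") for rid in contra}
            )
            within = out[out.area_a == out.area_b]["mean_r"].mean()
            between = out[out.area_a != out.area_b]["mean_r"].mean()
            wins += within > between
        assert wins >= 7
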