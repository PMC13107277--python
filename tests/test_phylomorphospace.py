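"""BM ancestral states (vs a dense GLS oracle) and the projection contract."""

import numpy as np
import pandas as pd
import pytest

from morphodisparse import (
    ancestral_states_bm,
    project_phylomorphospace,
    read_newick,
    render_phylomorphospace,
    tip_labels,
)
from morphodisparse.errors import NameMismatchError, ZeroBranchLengthError
from morphodisparse.phylomorphospace import assign_node_ids

from conftest import random_binary_newick


def gls_oracle(tree, tip_values):
    """Dense normal-equation solve of the weighted squared-change objective.

    Minimizes sum over branches of (x_child - x_parent)^2 / length with tip
    values fixed: builds the full graph Laplacian over internal nodes and
    solves it with a dense linear solver.  Independent of the two-pass
    production algorithm.
    """
    ids = assign_node_ids(tree)
    internal = [ids[id(n)] for n in tree.preorder_node_iter() if not n.is_leaf()]
    index = {nid: i for i, nid in enumerate(internal)}
    n = len(internal)
    a = np.zeros((n, n))
    b = np.zeros(n)
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            w = 1.0 / child.edge.length
            pi = index[ids[id(node)]]
            if child.is_leaf():
                a[pi, pi] += w
                b[pi] += w * tip_values[child.taxon.label]
            else:
                ci = index[ids[id(child)]]
                a[pi, pi] += w
                a[ci, ci] += w
                a[pi, ci] -= w
                a[ci, pi] -= w
    sol = np.linalg.solve(a, b)
    return {nid: sol[i] for nid, i in index.items()}


class TestAncestralStates:
    def test_two_tip_symmetric(self):
        tree = read_newick("(A:1,B:1);")
        anc = ancestral_states_bm(tree, {"A": 2.0, "B": 6.0})
        assert anc.estimates[anc.root_id] == pytest.approx(4.0)

    def test_two_tip_inverse_length_weights(self):
        """Closed-form GLS: lengths 1 and 3, tips 0 and 4 ->
        root = (0/1 + 4/3)/(1 + 1/3) = 1."""
        tree = read_newick("(A:1,B:3);")
        anc = ancestral_states_bm(tree, {"A": 0.0, "B": 4.0})
        assert anc.estimates[anc.root_id] == pytest.approx(1.0, abs=1e-12)

    def test_star_tree_root_is_mean(self):
        tree = read_newick("(A:2,B:2,C:2,D:2);")
        vals = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 6.0}
        anc = ancestral_states_bm(tree, vals)
        assert anc.estimates[anc.root_id] == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dense_gls_oracle(self, seed):
        """Two-pass production algorithm vs the dense Laplacian solve on
        random binary trees with up to 8 tips."""
        rng = np.random.default_rng(seed)
        n_tips = int(rng.integers(3, 9))
        tree = read_newick(random_binary_newick(n_tips, rng))
        vals = {t: float(rng.normal(0, 3)) for t in tip_labels(tree)}
        anc = ancestral_states_bm(tree, vals)
        oracle = gls_oracle(tree, vals)
        for nid, expected in oracle.items():
            assert anc.estimates[nid] == pytest.approx(expected, abs=1e-8)

    def test_polytomy_handled(self):
        tree = read_newick("((A:1,B:1,C:1):1,(D:1,E:1):1);")
        vals = dict(zip("ABCDE", [1.0, 2.0, 3.0, 10.0, 20.0]))
        anc = ancestral_states_bm(tree, vals)
        oracle = gls_oracle(tree, vals)
        for nid, expected in oracle.items():
            assert anc.estimates[nid] == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_translation_and_scale_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        tree = read_newick(random_binary_newick(6, rng))
        vals = {t: float(rng.normal()) for t in tip_labels(tree)}
        a, b = 2.5, -7.0
        anc = ancestral_states_bm(tree, vals)
        anc_t = ancestral_states_bm(tree, {k: a * v + b for k, v in vals.items()})
        for nid in anc.estimates:
            assert anc_t.estimates[nid] == pytest.approx(
                a * anc.estimates[nid] + b, abs=1e-10)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_estimates_are_convex_combinations_of_tips(self, seed):
        """Each node's weight vector over tips (solved via indicator tip
        values on the oracle) is non-negative and sums to 1."""
        rng = np.random.default_rng(seed)
        tree = read_newick(random_binary_newick(6, rng))
        tips = tip_labels(tree)
        weights = {}
        for tip in tips:
            indicator = {t: float(t == tip) for t in tips}
            sol = gls_oracle(tree, indicator)
            for nid, w in sol.items():
                weights.setdefault(nid, []).append(w)
        for nid, ws in weights.items():
            ws = np.asarray(ws)
            assert (ws >= -1e-10).all()
            assert ws.sum() == pytest.approx(1.0, abs=1e-10)

    def test_root_within_tip_range(self):
        rng = np.random.default_rng(10)
        tree = read_newick(random_binary_newick(7, rng))
        vals = {t: float(rng.normal(5, 2)) for t in tip_labels(tree)}
        anc = ancestral_states_bm(tree, vals)
        assert min(vals.values()) <= anc.estimates[anc.root_id] <= max(vals.values())

    def test_pruning_irrelevance(self):
        """Grafting a tip whose value equals the estimate at its attachment
        point leaves the other estimates unchanged."""
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        vals = {"A": 1.0, "B": 3.0, "C": 5.0, "D": 9.0}
        anc = ancestral_states_bm(tree, vals)
        # tree2 splits the (A,B)-clade branch and hangs E off the midpoint;
        # the self-consistent E value (fixed point of "E = estimate at its
        # attachment node") is the interpolated state of the E-free tree
        tree2 = read_newick("(((A:1,B:1):0.5,E:0.7):0.5,(C:1,D:1):1);")
        e_val = anc.estimates["node1"]  # start from the (A,B) ancestor state
        anc2 = None
        for _ in range(50):
            anc2 = ancestral_states_bm(tree2, {**vals, "E": e_val})
            new_val = anc2.estimates["node1"]  # E's attachment node
            if abs(new_val - e_val) < 1e-14:
                break
            e_val = new_val
        anc2 = ancestral_states_bm(tree2, {**vals, "E": e_val})
        for nid in ("node0",):
            assert anc2.estimates[nid] == pytest.approx(anc.estimates[nid], abs=1e-8)

    def test_zero_branch_policy(self):
        tree = read_newick("((A:0,B:1):1,C:1);")
        with pytest.raises(ZeroBranchLengthError):
            ancestral_states_bm(tree, {"A": 1.0, "B": 2.0, "C": 3.0},
                                epsilon_policy=False)
        anc = ancestral_states_bm(tree, {"A": 1.0, "B": 2.0, "C": 3.0})
        assert np.isfinite(list(anc.estimates.values())).all()


def scores_frame(tree, rng):
    tips = tip_labels(tree)
    return pd.DataFrame({
        "PC1": rng.normal(size=len(tips)),
        "PC2": rng.normal(size=len(tips)),
        "region": ["madagascar"] * len(tips),
    }, index=tips)


class TestProjection:
    def test_tips_carry_input_scores(self):
        rng = np.random.default_rng(0)
        tree = read_newick(random_binary_newick(5, rng))
        scores = scores_frame(tree, rng)
        proj = project_phylomorphospace(tree, scores)
        tips = proj.tips.set_index("id")
        for tip in scores.index:
            assert tips.loc[tip, "PC1"] == scores.loc[tip, "PC1"]
            assert tips.loc[tip, "PC2"] == scores.loc[tip, "PC2"]

    def test_binary_tree_combinatorics(self):
        rng = np.random.default_rng(1)
        tree = read_newick(random_binary_newick(8, rng))
        proj = project_phylomorphospace(tree, scores_frame(tree, rng))
        assert len(proj.tips) == 8
        assert len(proj.nodes) == 7
        assert len(proj.edges) == 14

    def test_star_tree_root_is_mean_of_scores(self):
        tree = read_newick("(A:1,B:1,C:1,D:1);")
        rng = np.random.default_rng(2)
        scores = scores_frame(tree, rng)
        proj = project_phylomorphospace(tree, scores)
        root = proj.nodes.set_index("id").loc["node0"]
        assert root["PC1"] == pytest.approx(scores["PC1"].mean())
        assert root["PC2"] == pytest.approx(scores["PC2"].mean())

    def test_name_mismatch_raises(self):
        rng = np.random.default_rng(3)
        tree = read_newick(random_binary_newick(4, rng))
        scores = scores_frame(tree, rng).iloc[:-1]
        with pytest.raises(NameMismatchError):
            project_phylomorphospace(tree, scores)


class TestRender:
    def test_writes_csvs_and_round_trips(self, tmp_path):
        rng = np.random.default_rng(4)
        tree = read_newick(random_binary_newick(4, rng))
        proj = project_phylomorphospace(tree, scores_frame(tree, rng))
        paths = render_phylomorphospace(proj, str(tmp_path / "pm"),
                                        write_image=False)
        coords = pd.read_csv(paths["coordinates"])
        assert set(coords["type"]) == {"tip", "node"}
        assert len(coords) == 4 + 3
        edges = pd.read_csv(paths["edges"])
        assert len(edges) == 6
        # re-exported coordinates are identical
        paths2 = render_phylomorphospace(proj, str(tmp_path / "pm2"),
                                         write_image=False)
        coords2 = pd.read_csv(paths2["coordinates"])
        pd.testing.assert_frame_equal(coords, coords2)
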