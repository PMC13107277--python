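"""Phylomorphospace: tree branches drawn through PC space.

Species centroids are projected onto the first two PC axes and internal
tree nodes are placed at their maximum-likelihood ancestral states under
Brownian motion, computed independently per axis.  Under BM the ML node
states are the values minimizing the branch-length-weighted sum of squared
changes, sum over branches of (delta state)^2 / branch length; they are
computed here with the classic two-pass (post-order contraction, pre-order
finalization) algorithm, which handles polytomies natively and runs in
linear time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .errors import NameMismatchError, ZeroBranchLengthError
from .io_core import tip_labels

logger = logging.getLogger(__name__)


@dataclass
class AncestralStates:
    """ML point estimates (and variances) of node states under BM.

    ``estimates`` maps node id -> value; tips appear with their observed
    values so a single mapping covers the whole tree.  ``variances`` holds,
    per internal node, the effective branch length of the node after the
    post-order contraction — proportional to the conditional variance of
    the estimate under unit-rate BM.
    """

    estimates: dict[str, float]
    variances: dict[str, float]
    root_id: str


def _effective_lengths(tree: dendropy.Tree, epsilon_policy: bool = True):
    """Branch lengths with zero-length branches replaced by a small epsilon.

    GLS weights are 1/length, so zero-length branches are replaced by
    1e-8 x tree height (with a logged warning) unless ``epsilon_policy`` is
    disabled, in which case they raise.
    """
    height = tree.max_distance_from_root()
    if height is None or height <= 0:
        height = 1.0
    eps = 1e-8 * height
    lengths: dict[int, float] = {}
    n_zero = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length
        if bl is None or bl <= 0:
            if not epsilon_policy:
                raise ZeroBranchLengthError(
                    f"zero/missing branch length at node {id(node)}"
                )
            n_zero += 1
            bl = eps
        lengths[id(node)] = float(bl)
    if n_zero:
        logger.warning("replaced %d zero-length branch(es) by epsilon %.3g",
                       n_zero, eps)
    return lengths


def assign_node_ids(tree: dendropy.Tree) -> dict[int, str]:
    """Stable node ids: tips use their taxon labels, internal nodes get
    ``node0, node1, ...`` in preorder (root is always ``node0``)."""
    ids: dict[int, str] = {}
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            ids[id(node)] = node.taxon.label
        else:
            ids[id(node)] = f"node{counter}"
            counter += 1
    return ids


def ancestral_states_bm(tree: dendropy.Tree, tip_values: dict[str, float],
                        epsilon_policy: bool = True) -> AncestralStates:
    """ML ancestral states for one continuous trait under Brownian motion.

    Post-order pass: each node is contracted to a pseudo-observation with
    value equal to the inverse-branch-length weighted mean of its children
    and an effective branch length of own length + 1 / sum(1/child effective
    lengths).  Pre-order pass: each internal node's final estimate combines
    its downpass value with the finalized parent estimate, again with
    inverse-length weights.  This is the exact GLS solution; polytomies
    need no special handling.
    """
    tips = set(tip_labels(tree))
    missing = tips - set(tip_values)
    if missing:
        raise NameMismatchError(f"tip(s) without a value: {sorted(missing)}")
    lengths = _effective_lengths(tree, epsilon_policy=epsilon_policy)
    ids = assign_node_ids(tree)

    down_value: dict[int, float] = {}
    down_weight: dict[int, float] = {}   # 1 / effective length below+branch
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            v = float(tip_values[node.taxon.label])
            eff = lengths[id(node)]
        else:
            wsum = sum(down_weight[id(c)] for c in node.child_nodes())
            v = sum(down_weight[id(c)] * down_value[id(c)]
                    for c in node.child_nodes()) / wsum
            if node is tree.seed_node:
                eff = np.inf
            else:
                eff = lengths[id(node)] + 1.0 / wsum
        down_value[id(node)] = v
        down_weight[id(node)] = 1.0 / eff if np.isfinite(eff) else 0.0

    estimates: dict[str, float] = {}
    variances: dict[str, float] = {}
    final: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        nid = ids[id(node)]
        if node.is_leaf():
            final[id(node)] = float(tip_values[node.taxon.label])
            estimates[nid] = final[id(node)]
            continue
        wsum_children = sum(down_weight[id(c)] for c in node.child_nodes())
        num = sum(down_weight[id(c)] * down_value[id(c)]
                  for c in node.child_nodes())
        if node is tree.seed_node:
            est = num / wsum_children
            var = 1.0 / wsum_children
        else:
            w_up = 1.0 / lengths[id(node)]
            est = (num + w_up * final[id(node.parent_node)]) / (wsum_children + w_up)
            var = 1.0 / (wsum_children + w_up)
        final[id(node)] = est
        estimates[nid] = float(est)
        variances[nid] = float(var)
    root_id = ids[id(tree.seed_node)]
    return AncestralStates(estimates, variances, root_id)


@dataclass
class PhylomorphospaceProjection:
    """Tip and node coordinates plus the tree's edge list.

    ``tips``/``nodes`` are DataFrames with columns id, PC1, PC2 (tips also
    carry region); ``edges`` lists (parent id, child id) pairs covering
    every branch of the tree.
    """

    tips: pd.DataFrame
    nodes: pd.DataFrame
    edges: list[tuple[str, str]]

    def coordinates_frame(self) -> pd.DataFrame:
        t = self.tips.assign(type="tip")
        n = self.nodes.assign(type="node", region="")
        cols = ["id", "type", "PC1", "PC2", "region"]
        return pd.concat([t[cols], n[cols]], ignore_index=True)

    def edges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["parent", "child"])


def project_phylomorphospace(tree: dendropy.Tree, centroid_scores: pd.DataFrame,
                             ) -> PhylomorphospaceProjection:
    """Place tips at their centroid PC scores and internal nodes at BM
    ancestral states, per axis independently.

    ``centroid_scores`` is indexed by species, with columns PC1 and PC2 and
    optionally ``region``; its species set must equal the tree's tips.
    """
    tips = set(tip_labels(tree))
    species = set(centroid_scores.index.astype(str))
    if tips != species:
        raise NameMismatchError(
            f"tree-only: {sorted(tips - species)}; table-only: {sorted(species - tips)}"
        )
    anc = {
        axis: ancestral_states_bm(tree, centroid_scores[axis].to_dict())
        for axis in ("PC1", "PC2")
    }
    ids = assign_node_ids(tree)
    tip_rows, node_rows, edges = [], [], []
    for node in tree.preorder_node_iter():
        nid = ids[id(node)]
        for child in node.child_nodes():
            edges.append((nid, ids[id(child)]))
        if node.is_leaf():
            row = {"id": nid,
                   "PC1": float(centroid_scores.loc[nid, "PC1"]),
                   "PC2": float(centroid_scores.loc[nid, "PC2"]),
                   "region": str(centroid_scores.loc[nid, "region"])
                   if "region" in centroid_scores.columns else ""}
            tip_rows.append(row)
        else:
            node_rows.append({"id": nid,
                              "PC1": anc["PC1"].estimates[nid],
                              "PC2": anc["PC2"].estimates[nid]})
    return PhylomorphospaceProjection(
        pd.DataFrame(tip_rows), pd.DataFrame(node_rows), edges
    )


def render_phylomorphospace(projection: PhylomorphospaceProjection,
                            out_prefix: str,
                            write_image: bool = True) -> dict[str, str]:
    """Write coordinate and edge CSVs (always) and a PNG (best effort).

    Returns the paths written, keyed ``coordinates``, ``edges`` and
    (when produced) ``image``.
    """
    if projection.tips.empty:
        raise ValueError("empty projection: nothing to render")
    coords_path = f"{out_prefix}_coordinates.csv"
    edges_path = f"{out_prefix}_edges.csv"
    projection.coordinates_frame().to_csv(coords_path, index=False)
    projection.edges_frame().to_csv(edges_path, index=False)
    written = {"coordinates": coords_path, "edges": edges_path}
    if write_image:
        try:
            written["image"] = _draw(projection, f"{out_prefix}.png")
        except Exception as exc:  # rendering is best-effort only
            logger.warning("figure rendering failed: %s", exc)
    return written


def _draw(projection: PhylomorphospaceProjection, path: str) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = {r.id: (r.PC1, r.PC2) for r in projection.tips.itertuples()}
    pos.update({r.id: (r.PC1, r.PC2) for r in projection.nodes.itertuples()})
    fig, ax = plt.subplots(figsize=(7, 6))
    for parent, child in projection.edges:
        (x0, y0), (x1, y1) = pos[parent], pos[child]
        ax.plot([x0, x1], [y0, y1], color="0.4", lw=0.8, zorder=1)
    regions = projection.tips["region"].unique()
    for region, color in zip(regions, ("#1b9e77", "#d95f02", "#7570b3", "#e7298a")):
        sel = projection.tips[projection.tips["region"] == region]
        ax.scatter(sel["PC1"], sel["PC2"], s=45, color=color, zorder=3,
                   label=region or "tips")
    ax.scatter(projection.nodes["PC1"], projection.nodes["PC2"], s=12,
               color="black", zorder=2, label="ancestral nodes")
    for r in projection.tips.itertuples():
        ax.annotate(r.id, (r.PC1, r.PC2), fontsize=6,
                    textcoords="offset points", xytext=(3, 3))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
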