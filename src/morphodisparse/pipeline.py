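"""End-to-end orchestration: the analysis bundle behind the CLI.

`analyze_table` runs the whole morphospace/disparity chain on one
measurement table — z-scoring, individual and centroid PCA, per-region
distance matrices and neighbor summaries, and the dispersion permutation
test — and returns everything in a single result object that the CLI (and
the acceptance script) serialize to CSV/JSON.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from . import __version__
from .disparity import (
    DispersionResult,
    DistanceMatrix,
    NeighborSummary,
    distance_matrix,
    neighbor_summary,
    permutation_test,
)
from .io_core import MeasurementTable, align_tree_table, prune_to_species
from .morphospace import (
    CentroidSet,
    PCAResult,
    centroid_pca,
    pca,
    species_centroids,
    zscale,
)
from .phylomorphospace import (
    PhylomorphospaceProjection,
    project_phylomorphospace,
    render_phylomorphospace,
)


@dataclass
class AnalysisBundle:
    """All statistics produced by one analysis run."""

    pca_individual: PCAResult
    pca_centroid: PCAResult
    centroids: CentroidSet
    distances: DistanceMatrix
    region_distances: dict[str, DistanceMatrix]
    region_summaries: dict[str, NeighborSummary]
    dispersion: DispersionResult

    def summary_dict(self) -> dict:
        """Flat summary of the headline statistics (percentages in %)."""
        out = {
            "n_species": len(self.centroids.species),
            "pc1_percent_individual": 100 * float(self.pca_individual.variance_proportions[0]),
            "pc2_percent_individual": 100 * float(self.pca_individual.variance_proportions[1]),
            "pc1_percent_centroid": 100 * float(self.pca_centroid.variance_proportions[0]),
            "pc2_percent_centroid": 100 * float(self.pca_centroid.variance_proportions[1]),
            "observed_mean_dispersion": self.dispersion.observed_mean_dispersion,
            "dispersion_F": self.dispersion.f_statistic,
            "permutation_p": self.dispersion.p_value,
            "n_reps": self.dispersion.n_reps,
        }
        for region, summ in self.region_summaries.items():
            for key, val in summ.to_dict().items():
                out[f"{key}_{region}"] = val
        return out


def analyze_table(table: MeasurementTable, n_reps: int = 1000, seed: int = 0,
                  rescale_centroids: bool = False,
                  smoothing: bool = False) -> AnalysisBundle:
    """Run the full disparity analysis on a measurement table.

    The dispersion permutation test operates on the species centroids
    partitioned by region, with ``n_reps`` joint row/column permutations of
    the centroid distance matrix.
    """
    scaled = zscale(table)
    result_ind = pca(scaled)
    cents = species_centroids(scaled, table.species, table.species_region_map())
    result_cent = centroid_pca(cents, rescale=rescale_centroids)
    dm = distance_matrix(cents)
    regions = sorted(set(cents.regions))
    region_dms, region_summ = {}, {}
    for region in regions:
        members = [sp for sp, r in zip(cents.species, cents.regions) if r == region]
        if len(members) >= 2:
            sub = dm.subset(members)
            region_dms[region] = sub
            region_summ[region] = neighbor_summary(sub)
    groups = dict(zip(cents.species, cents.regions))
    disp = permutation_test(dm, groups, n_reps=n_reps, seed=seed,
                            smoothing=smoothing)
    return AnalysisBundle(result_ind, result_cent, cents, dm,
                          region_dms, region_summ, disp)


def phylo_projection(tree: dendropy.Tree, table: MeasurementTable,
                     rescale_centroids: bool = False,
                     policy: str = "strict") -> PhylomorphospaceProjection:
    """Prune/match the tree to the table and project the centroid PCA
    scores (PC1/PC2) with BM ancestral states at internal nodes."""
    key = align_tree_table(tree, table, policy=policy)
    work = tree
    if key.unmatched_tips:
        keep = [t for t in key.tip_to_species]
        work = prune_to_species(tree, keep)
    scaled = zscale(table)
    cents = species_centroids(scaled, table.species, table.species_region_map())
    result = centroid_pca(cents, rescale=rescale_centroids)
    scores = result.scores_frame()[["PC1", "PC2"]].copy()
    scores["region"] = cents.regions
    # index scores by tip label so the projection matches the tree
    species_to_tip = {sp: tip for tip, sp in key.tip_to_species.items()}
    scores = scores.loc[[sp for sp in scores.index if sp in species_to_tip]]
    scores.index = [species_to_tip[sp] for sp in scores.index]
    return project_phylomorphospace(work, scores)


def reproduce_statistics(measurements_csv, tree_newick=None, n_reps: int = 1000,
                         seed: int = 0) -> dict:
    """One-call reproduction of the headline statistics from input files.

    Reads a measurement CSV (and optionally a Newick tree), runs the full
    deterministic pipeline and returns the flat statistics summary:
    individual and centroid PCA variance percentages, per-region neighbor
    distances, observed mean dispersion, dispersion F and the permutation
    p-value.  Point estimates are fully deterministic; only the permutation
    p depends on ``seed``/``n_reps``.
    """
    from .io_core import read_measurements, read_newick

    table = read_measurements(measurements_csv)
    bundle = analyze_table(table, n_reps=n_reps, seed=seed)
    summary = bundle.summary_dict()
    summary["n_specimens"] = table.n_specimens
    if tree_newick is not None:
        tree = read_newick(tree_newick)
        projection = phylo_projection(tree, table)
        summary["n_projection_nodes"] = len(projection.nodes)
    return summary


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_bundle(bundle: AnalysisBundle, out_dir: str, seed: int,
                 config: dict | None = None) -> dict[str, str]:
    """Serialize an analysis bundle to a directory of CSV/JSON artifacts."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def save_csv(name, frame, **kw):
        path = os.path.join(out_dir, name)
        frame.to_csv(path, **kw)
        paths[name] = path

    save_csv("pca_individual_scores.csv", bundle.pca_individual.scores_frame(),
             index_label="specimen_id")
    save_csv("pca_individual_loadings.csv", bundle.pca_individual.loadings_frame(),
             index_label="variable")
    save_csv("pca_individual_eigenvalues.csv",
             bundle.pca_individual.eigenvalue_table(), index=False)
    save_csv("pca_centroid_scores.csv", bundle.pca_centroid.scores_frame(),
             index_label="species")
    save_csv("pca_centroid_eigenvalues.csv",
             bundle.pca_centroid.eigenvalue_table(), index=False)
    save_csv("centroids.csv", bundle.centroids.frame(), index_label="species")
    save_csv("distance_matrix.csv", bundle.distances.frame(), index_label="species")
    for region, dm in bundle.region_distances.items():
        save_csv(f"distance_matrix_{region}.csv", dm.frame(), index_label="species")
    summary_rows = [{"region": region, **summ.to_dict()}
                    for region, summ in bundle.region_summaries.items()]
    save_csv("neighbor_summary.csv", pd.DataFrame(summary_rows), index=False)

    disp_path = os.path.join(out_dir, "dispersion.json")
    with open(disp_path, "w", encoding="utf-8") as fh:
        json.dump(bundle.dispersion.to_dict(), fh, indent=2, sort_keys=True)
    paths["dispersion.json"] = disp_path

    manifest = {
        "package": "morphodisparse",
        "version": __version__,
        "seed": seed,
        "config": config or {},
        "config_hash": _config_hash({"seed": seed, **(config or {})}),
        "summary": bundle.summary_dict(),
    }
    man_path = os.path.join(out_dir, "manifest.json")
    with open(man_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest.json"] = man_path
    return paths


def write_projection(projection: PhylomorphospaceProjection, out_dir: str,
                     write_image: bool = True) -> dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    return render_phylomorphospace(
        projection, os.path.join(out_dir, "phylomorphospace"),
        write_image=write_image,
    )
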