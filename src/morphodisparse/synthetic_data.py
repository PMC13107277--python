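"""Synthetic trees and measurement tables with the structure the analysis assumes.

The generator emulates a pair of same-aged sister radiations: two
monophyletic clades (12 + 9 species by default) splitting 9.06 time units
ago, species mean phenotypes evolving on the tree by Brownian motion, and
within-species measurement noise at caliper scale.  The trait model is a
one-factor structure: a scalar "size" factor evolving by BM loads on all
seven variables through a unit loading vector, while independent per-variable
"shape" BMs add residual structure; with the default rates the shared size
factor dominates and the individual-level correlation PCA concentrates
~93% of the variance on PC1, matching the regime of real long-fingered-bat
wing measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .errors import InvalidConfigError, TargetOutOfRangeError
from .io_core import (
    MEASUREMENT_COLUMNS,
    MeasurementTable,
    read_newick,
)
from .morphospace import pca, zscale

#: Default per-species specimen counts (total 206): 12 island-clade species
#: and 9 continental-clade species, mirroring a realistic museum series.
DEFAULT_COUNTS_CLADE_A: tuple[int, ...] = (9, 8, 11, 10, 9, 20, 6, 13, 9, 10, 6, 5)
DEFAULT_COUNTS_CLADE_B: tuple[int, ...] = (19, 5, 6, 6, 5, 10, 20, 9, 10)

#: Baseline (root) species mean for the seven measurements, mm.  Ordered as
#: MEASUREMENT_COLUMNS: tibia, D2 metacarpal, D3 metacarpal, D3 phalanx 1,
#: D3 phalanx 2, D4 metacarpal, D5 metacarpal — typical of a mid-sized
#: clutter-edge insectivorous bat.
DEFAULT_BASELINE: tuple[float, ...] = (16.0, 38.0, 42.0, 13.0, 30.0, 40.0, 38.0)


@dataclass
class SimulationConfig:
    """Parameters of the two-clade trait simulation.

    Rates are per unit time (the tree is in the same units as
    ``split_depth``); ``within_sd`` is the within-species SD per variable in
    mm.  ``loading_vector`` is the unit-norm direction of the shared size
    factor (default: equal loadings, 1/sqrt(7)).
    """

    n_clade_a: int = 12
    n_clade_b: int = 9
    split_depth: float = 9.06
    crown_fraction: float = 0.75
    tree_mode: str = "two_clade_yule"
    sigma_size: float = 2.1
    sigma_shape: float = 0.05
    loading_vector: tuple[float, ...] | None = None
    within_sd: float = 0.5
    n_per_species: tuple[int, ...] | None = None
    baseline_mean: tuple[float, ...] = DEFAULT_BASELINE
    region_a: str = "madagascar"
    region_b: str = "continental"
    seed: int = 0

    def validate(self) -> None:
        if self.n_clade_a < 1 or self.n_clade_b < 1:
            raise InvalidConfigError("each clade needs at least one species")
        if self.split_depth <= 0 or not (0 < self.crown_fraction <= 1):
            raise InvalidConfigError("split_depth > 0 and 0 < crown_fraction <= 1 required")
        if self.tree_mode not in ("two_clade_yule", "yule"):
            raise InvalidConfigError(f"unknown tree_mode {self.tree_mode!r}")
        if min(self.sigma_size, self.sigma_shape, self.within_sd) < 0:
            raise InvalidConfigError("rates and SDs must be >= 0")
        lv = self.loadings()
        if abs(np.linalg.norm(lv) - 1.0) > 1e-8:
            raise InvalidConfigError("loading_vector must have unit norm")
        counts = self.counts()
        if len(counts) != self.n_clade_a + self.n_clade_b:
            raise InvalidConfigError("n_per_species length must equal total species")
        if any(c < 1 for c in counts):
            raise InvalidConfigError("n_per_species entries must be >= 1")
        if len(self.baseline_mean) != len(MEASUREMENT_COLUMNS):
            raise InvalidConfigError("baseline_mean must have 7 entries")

    def loadings(self) -> np.ndarray:
        if self.loading_vector is None:
            p = len(MEASUREMENT_COLUMNS)
            return np.full(p, 1.0 / np.sqrt(p))
        return np.asarray(self.loading_vector, dtype=float)

    def counts(self) -> tuple[int, ...]:
        if self.n_per_species is not None:
            return tuple(self.n_per_species)
        if (self.n_clade_a, self.n_clade_b) == (12, 9):
            return DEFAULT_COUNTS_CLADE_A + DEFAULT_COUNTS_CLADE_B
        return tuple([10] * (self.n_clade_a + self.n_clade_b))

    def species_names(self) -> list[str]:
        a = [f"sp_A{i + 1:02d}" for i in range(self.n_clade_a)]
        b = [f"sp_B{i + 1:02d}" for i in range(self.n_clade_b)]
        return a + b

    def region_map(self) -> dict[str, str]:
        names = self.species_names()
        return {n: (self.region_a if n.startswith("sp_A") else self.region_b)
                for n in names}

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("name", "birth", "children", "end")

    def __init__(self, birth: float):
        self.name = None
        self.birth = birth
        self.children: list["_Lineage"] = []
        self.end = None


def _yule_subtree(n_tips: int, names: list[str], height: float,
                  rng: np.random.Generator) -> str:
    """Newick (no trailing ';') of a pure-birth tree with crown height ``height``."""
    if n_tips == 1:
        return f"{names[0]}:{height:.10f}"
    root = _Lineage(0.0)
    left, right = _Lineage(0.0), _Lineage(0.0)
    root.children = [left, right]
    active, t = [left, right], 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        parent = active[rng.integers(len(active))]
        parent.end = t
        kids = [_Lineage(t), _Lineage(t)]
        parent.children = kids
        active.remove(parent)
        active.extend(kids)
    t += rng.exponential(1.0 / n_tips)  # run to the next (uncounted) event
    for i, leaf in enumerate(active):
        leaf.end = t
        leaf.name = names[i]
    scale = height / t

    def emit(node: _Lineage) -> str:
        bl = (node.end - node.birth) * scale
        if not node.children:
            return f"{node.name}:{bl:.10f}"
        inner = ",".join(emit(c) for c in node.children)
        return f"({inner}):{bl:.10f}"

    inner = ",".join(emit(c) for c in root.children)
    return f"({inner}):0.0"


def simulate_tree(cfg: SimulationConfig, rng: np.random.Generator | None = None
                  ) -> dendropy.Tree:
    """Ultrametric two-clade tree: root at ``split_depth``, each clade grown
    by a pure-birth process and rescaled so its crown sits at
    ``crown_fraction * split_depth`` before present."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    names = cfg.species_names()
    names_a, names_b = names[: cfg.n_clade_a], names[cfg.n_clade_a:]
    crown = cfg.crown_fraction * cfg.split_depth
    stem = cfg.split_depth - crown
    if cfg.tree_mode == "yule":
        sub = _yule_subtree(len(names), names, cfg.split_depth, rng)
        body, _ = sub.rsplit(":", 1)
        return read_newick(f"{body};")

    def clade(sub_names):
        if len(sub_names) == 1:
            return f"{sub_names[0]}:{cfg.split_depth:.10f}"
        sub = _yule_subtree(len(sub_names), sub_names, crown, rng)
        body, _ = sub.rsplit(":", 1)
        return f"{body}:{stem:.10f}"

    newick = f"({clade(names_a)},{clade(names_b)});"
    return read_newick(newick)


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------

def _bm_on_tree(tree: dendropy.Tree, sigma: float, n_traits: int,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Independent BM realizations per trait; returns tip label -> values."""
    values: dict[int, np.ndarray] = {id(tree.seed_node): np.zeros(n_traits)}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            bl = max(node.edge.length or 0.0, 0.0)
            step = rng.normal(0.0, sigma * np.sqrt(bl), size=n_traits)
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


def simulate_species_means(tree: dendropy.Tree, cfg: SimulationConfig,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Species mean vectors: baseline + size_s * loadings + shape_s.

    ``size`` is a scalar BM with rate ``sigma_size``; each of the seven
    shape coordinates is an independent BM with rate ``sigma_shape``.
    Returns a species x 7 DataFrame in mm.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    size = _bm_on_tree(tree, cfg.sigma_size, 1, rng)
    shape = _bm_on_tree(tree, cfg.sigma_shape, len(MEASUREMENT_COLUMNS), rng)
    base = np.asarray(cfg.baseline_mean, dtype=float)
    lv = cfg.loadings()
    rows = {sp: base + size[sp][0] * lv + shape[sp] for sp in size}
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(MEASUREMENT_COLUMNS))
    order = [n for n in cfg.species_names() if n in frame.index]
    return frame.loc[order] if len(order) == len(frame) else frame


def simulate_individuals(means: pd.DataFrame, cfg: SimulationConfig,
                         rng: np.random.Generator | None = None) -> MeasurementTable:
    """Specimen table: species mean + iid Gaussian noise, rounded to 0.01 mm."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    counts = dict(zip(cfg.species_names(), cfg.counts()))
    if set(means.index) != set(counts):
        raise InvalidConfigError("means index does not match configured species")
    region = cfg.region_map()
    records = []
    for sp in means.index:
        mu = means.loc[sp].to_numpy(dtype=float)
        noise = rng.normal(0.0, cfg.within_sd, size=(counts[sp], len(mu)))
        # caliper floor: lengths are recorded at 0.01 mm, never <= 0
        vals = np.maximum(np.round(mu + noise, 2), 0.01)
        for i in range(counts[sp]):
            rec = {"specimen_id": f"{sp}_{i + 1:03d}", "species": sp,
                   "region": region[sp]}
            rec.update(dict(zip(MEASUREMENT_COLUMNS, vals[i])))
            records.append(rec)
    return MeasurementTable.from_frame(pd.DataFrame.from_records(records))


def simulate_dataset(cfg: SimulationConfig
                     ) -> tuple[dendropy.Tree, MeasurementTable, pd.DataFrame]:
    """Full simulation: tree, specimen table and the true species means.

    Each stage draws from an independent child stream of ``cfg.seed`` so
    the whole dataset is bit-reproducible."""
    cfg.validate()
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(cfg.seed).spawn(3)]
    tree = simulate_tree(cfg, streams[0])
    means = simulate_species_means(tree, cfg, streams[1])
    table = simulate_individuals(means, cfg, streams[2])
    return tree, table, means


# ---------------------------------------------------------------------------
# size-dominance tuning
# ---------------------------------------------------------------------------

def realized_pc1_share(cfg: SimulationConfig) -> float:
    """PC1 variance proportion of the individual-level correlation PCA for
    one simulated dataset."""
    _, table, _ = simulate_dataset(cfg)
    return float(pca(zscale(table)).variance_proportions[0])


def tune_size_dominance(target_pc1_share: float, cfg: SimulationConfig,
                        n_seeds: int = 3, n_iter: int = 18,
                        ) -> SimulationConfig:
    """Find the sigma_size/sigma_shape ratio whose realized PC1 share
    matches ``target_pc1_share``, by bisection on the log-ratio.

    The PC1 share of the correlation PCA is monotone non-decreasing in the
    size/shape rate ratio (more shared-factor variance concentrates the
    leading eigenvalue), which justifies the bisection.  The share is
    measured as the mean over ``n_seeds`` simulated datasets on a fixed
    seed schedule derived from ``cfg.seed``.
    """
    p = len(MEASUREMENT_COLUMNS)
    if not (1.0 / p < target_pc1_share < 1.0):
        raise TargetOutOfRangeError(
            f"target must lie in (1/{p}, 1), got {target_pc1_share}")
    cfg.validate()
    if cfg.sigma_shape <= 0:
        raise TargetOutOfRangeError("tuning needs sigma_shape > 0")
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(cfg.seed).spawn(n_seeds)]

    def share_at(log_ratio: float) -> float:
        ratio = 10.0 ** log_ratio
        shares = []
        for s in seeds:
            trial = SimulationConfig(**{**cfg.to_dict(),
                                        "sigma_size": cfg.sigma_shape * ratio,
                                        "seed": s})
            shares.append(realized_pc1_share(trial))
        return float(np.mean(shares))

    lo, hi = -2.0, 4.0
    if share_at(lo) > target_pc1_share:
        lo = -4.0
    for _ in range(n_iter):
        mid = (lo + hi) / 2
        if share_at(mid) < target_pc1_share:
            lo = mid
        else:
            hi = mid
    ratio = 10.0 ** ((lo + hi) / 2)
    return SimulationConfig(**{**cfg.to_dict(),
                               "sigma_size": cfg.sigma_shape * ratio})
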