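"""Readers, writers and reconciliation for measurement tables and trees.

The measurement table holds specimen-level records of seven linear wing/limb
lengths (tibia plus six wing-bone elements), in millimetres, together with a
species label and a biogeographic region.  Trees are time-calibrated,
species-level phylogenies carried as :class:`dendropy.Tree` objects; this
module wraps parsing, pruning and name reconciliation so downstream analysis
code never touches raw Newick.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    AmbiguousRegionError,
    DuplicateSpecimenIdError,
    EmptyTableError,
    MissingBranchLengthError,
    MissingColumnError,
    NewickParseError,
    NonPositiveMeasurementError,
    TooFewTipsError,
    UnknownTipError,
    UnmatchedNamesError,
)

logger = logging.getLogger(__name__)

#: The seven linear measurements, in canonical order: tibia length, digit-2
#: metacarpal, digit-3 metacarpal, digit-3 phalanx 1, digit-3 phalanx 2,
#: digit-4 metacarpal, digit-5 metacarpal.  All in mm, 0.01 mm precision.
MEASUREMENT_COLUMNS: tuple[str, ...] = (
    "Tib", "D2M", "D3M", "D3P1", "D3P2", "D4M", "D5M",
)

ID_COLUMN = "specimen_id"
SPECIES_COLUMN = "species"
REGION_COLUMN = "region"


@dataclass
class MeasurementTable:
    """Validated specimen-level measurement records.

    ``data`` has columns ``specimen_id``, ``species``, ``region`` and the
    seven measurement columns, one row per specimen.  Construction via
    :func:`read_measurements` or :meth:`from_frame` guarantees the
    invariants (unique ids, positive measurements, one region per species).
    """

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, mode: str = "strict") -> "MeasurementTable":
        return cls(_validate_frame(frame, mode=mode))

    @property
    def n_specimens(self) -> int:
        return len(self.data)

    @property
    def species(self) -> pd.Series:
        return self.data[SPECIES_COLUMN]

    @property
    def regions(self) -> pd.Series:
        return self.data[REGION_COLUMN]

    def species_region_map(self) -> dict[str, str]:
        """Mapping species label -> region (validated to be unambiguous)."""
        return (
            self.data.groupby(SPECIES_COLUMN, sort=False)[REGION_COLUMN]
            .first()
            .to_dict()
        )

    def measurement_matrix(self) -> np.ndarray:
        """(n_specimens, 7) float array in canonical column order."""
        return self.data[list(MEASUREMENT_COLUMNS)].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        cols = [ID_COLUMN, SPECIES_COLUMN, REGION_COLUMN, *MEASUREMENT_COLUMNS]
        self.data[cols].to_csv(path, index=False)


def _validate_frame(frame: pd.DataFrame, mode: str = "strict") -> pd.DataFrame:
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    required = [ID_COLUMN, SPECIES_COLUMN, REGION_COLUMN, *MEASUREMENT_COLUMNS]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise MissingColumnError(f"missing column(s): {', '.join(missing)}")

    out = frame[required].copy()
    out[ID_COLUMN] = out[ID_COLUMN].astype(str)
    out[SPECIES_COLUMN] = out[SPECIES_COLUMN].astype(str).str.strip()
    out[REGION_COLUMN] = out[REGION_COLUMN].astype(str).str.strip()
    for col in MEASUREMENT_COLUMNS:
        out[col] = pd.to_numeric(out[col], errors="coerce")

    meas = out[list(MEASUREMENT_COLUMNS)]
    bad = meas.isna().any(axis=1) | (meas <= 0).any(axis=1)
    if bad.any():
        if mode == "strict":
            offenders = out.loc[bad, ID_COLUMN].tolist()
            raise NonPositiveMeasurementError(
                f"{int(bad.sum())} row(s) with missing or non-positive "
                f"measurements: {offenders[:10]}"
            )
        logger.warning("dropping %d row(s) with missing/non-positive measurements",
                       int(bad.sum()))
        out = out.loc[~bad]

    if out.empty:
        raise EmptyTableError("no valid specimen rows")
    if (out[SPECIES_COLUMN] == "").any():
        raise EmptyTableError("empty species label(s) present")

    dupes = out[ID_COLUMN][out[ID_COLUMN].duplicated()].unique()
    if len(dupes):
        raise DuplicateSpecimenIdError(f"duplicate specimen ids: {list(dupes)[:10]}")

    ambiguous = (
        out.groupby(SPECIES_COLUMN)[REGION_COLUMN].nunique()
    )
    ambiguous = ambiguous[ambiguous > 1]
    if len(ambiguous):
        raise AmbiguousRegionError(
            f"species mapped to multiple regions: {list(ambiguous.index)}"
        )
    return out.reset_index(drop=True)


def read_measurements(path, schema: dict[str, str] | None = None,
                      mode: str = "strict") -> MeasurementTable:
    """Read a specimen measurement CSV.

    Parameters
    ----------
    path:
        Comma-separated UTF-8 file with a header row.
    schema:
        Optional map from canonical names (``specimen_id``, ``species``,
        ``region``, ``Tib`` ... ``D5M``) to the column names actually used
        in the file.
    mode:
        ``"strict"`` rejects any row with a missing or non-positive
        measurement; ``"lenient"`` drops such rows with a logged count.
    """
    frame = pd.read_csv(path)
    if schema:
        rename = {actual: canonical for canonical, actual in schema.items()}
        frame = frame.rename(columns=rename)
    return MeasurementTable.from_frame(frame, mode=mode)


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_newick(source: str | os.PathLike, require_branch_lengths: bool = True,
                default_branch_length: float | None = None) -> dendropy.Tree:
    """Parse a Newick tree from a path or a literal Newick string.

    Every non-root node must carry a branch length unless
    ``default_branch_length`` is supplied.  Zero-length branches are
    accepted; downstream consumers decide how to treat them.
    """
    text = None
    if isinstance(source, (str, bytes)) and "(" in str(source):
        text = str(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"could not parse Newick input: {exc}") from exc
    if len(tree.leaf_nodes()) < 2:
        raise NewickParseError("tree has fewer than two tips")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            if default_branch_length is not None:
                node.edge.length = default_branch_length
            elif require_branch_lengths:
                raise MissingBranchLengthError(
                    f"node {node_label(node)!r} has no branch length"
                )
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize a tree to Newick; write to ``path`` when given."""
    text = tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or "<internal>"


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path lengths, by tip label."""
    depths = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node is not tree.seed_node:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


def prune_to_species(tree: dendropy.Tree, keep) -> dendropy.Tree:
    """Prune a tree down to ``keep``, collapsing unifurcations.

    Degree-2 internal nodes created by tip removal are collapsed by summing
    their two incident branch lengths, and a dangling root stem is dropped,
    so root-to-tip depths of retained tips are preserved up to the removed
    stem.  The input tree is not modified.
    """
    keep = set(keep)
    labels = set(tip_labels(tree))
    unknown = keep - labels
    if unknown:
        raise UnknownTipError(f"tip(s) not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise TooFewTipsError(f"need at least 2 tips to retain, got {len(keep)}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(keep))
    # drop the stem dendropy leaves above the new root
    pruned.seed_node.edge.length = None
    return pruned


# ---------------------------------------------------------------------------
# Tree <-> table reconciliation
# ---------------------------------------------------------------------------

_GENUS_PREFIXES = ("miniopterus", "m.", "m")


def normalize_species_name(name: str, genus_aliases=_GENUS_PREFIXES) -> str:
    """Canonical form used to match tree tips against table species labels.

    Lower-cases, trims, collapses internal whitespace to underscores, and
    strips a leading genus token ("Miniopterus", "M.", "M") so e.g.
    ``"M_gleni"``, ``"M. gleni"`` and ``"Miniopterus gleni"`` all map to
    ``"gleni"`` while labels like ``"Clade 4"`` become ``"clade_4"``.
    """
    s = re.sub(r"\s+", "_", name.strip().lower())
    parts = s.split("_", 1)
    if len(parts) == 2 and parts[0] in genus_aliases:
        s = parts[1]
    return s


@dataclass
class SpeciesKey:
    """Reconciliation result between tree tips and table species labels."""

    tip_to_species: dict[str, str]
    unmatched_tips: list[str] = field(default_factory=list)
    unmatched_species: list[str] = field(default_factory=list)

    @property
    def matched(self) -> bool:
        return not self.unmatched_tips and not self.unmatched_species

    def to_dict(self) -> dict:
        return {
            "tip_to_species": dict(self.tip_to_species),
            "unmatched_tips": list(self.unmatched_tips),
            "unmatched_species": list(self.unmatched_species),
        }


def align_tree_table(tree: dendropy.Tree, table: MeasurementTable,
                     policy: str = "strict") -> SpeciesKey:
    """Match tree tip labels to table species labels after normalization.

    ``policy="strict"`` raises :class:`UnmatchedNamesError` when any name on
    either side has no partner; ``policy="drop_unmatched"`` returns the
    partial bijection together with the two drop lists.
    """
    if policy not in ("strict", "drop_unmatched"):
        raise ValueError(f"unknown policy {policy!r}")
    tips = tip_labels(tree)
    species = list(dict.fromkeys(table.species))
    norm_tips = {normalize_species_name(t): t for t in tips}
    norm_species = {normalize_species_name(s): s for s in species}
    if len(norm_tips) != len(tips):
        raise UnmatchedNamesError(tips, [])  # tips collide after normalization
    common = norm_tips.keys() & norm_species.keys()
    key = SpeciesKey(
        tip_to_species={norm_tips[k]: norm_species[k] for k in sorted(common)},
        unmatched_tips=sorted(norm_tips[k] for k in norm_tips.keys() - common),
        unmatched_species=sorted(norm_species[k] for k in norm_species.keys() - common),
    )
    if policy == "strict" and not key.matched:
        raise UnmatchedNamesError(key.unmatched_tips, key.unmatched_species)
    return key
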