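"""Shared fixtures: small measurement frames, toy trees, random-tree makers."""

import numpy as np
import pandas as pd
import pytest

from morphodisparse import MEASUREMENT_COLUMNS, MeasurementTable, read_newick


def make_frame(rows):
    """Build a measurement DataFrame from (id, species, region, 7 values) tuples."""
    records = []
    for sid, sp, region, vals in rows:
        rec = {"specimen_id": sid, "species": sp, "region": region}
        rec.update(dict(zip(MEASUREMENT_COLUMNS, vals)))
        records.append(rec)
    return pd.DataFrame.from_records(records)


@pytest.fixture
def tiny_table():
    """Two species, two regions, four specimens with hand-picked values."""
    rng = np.random.default_rng(7)
    rows = []
    for i, (sp, region) in enumerate([("alpha", "madagascar"), ("alpha", "madagascar"),
                                      ("beta", "continental"), ("beta", "continental")]):
        vals = 30 + 5 * i + rng.normal(0, 0.3, 7)
        rows.append((f"s{i}", sp, region, np.round(vals, 2)))
    return MeasurementTable.from_frame(make_frame(rows))


@pytest.fixture
def gaussian_table():
    """30 specimens, 6 species, strong shared size factor."""
    rng = np.random.default_rng(11)
    rows = []
    base = np.array([16.0, 38.0, 42.0, 13.0, 30.0, 40.0, 38.0])
    for s in range(6):
        size = rng.normal(0, 3)
        region = "madagascar" if s < 3 else "continental"
        for i in range(5):
            vals = base + size * np.ones(7) + rng.normal(0, 0.5, 7)
            rows.append((f"sp{s}_{i}", f"sp{s}", region, np.round(vals, 2)))
    return MeasurementTable.from_frame(make_frame(rows))


@pytest.fixture
def three_tip_tree():
    return read_newick("((A:1,B:1):0.5,C:1.5);")


def random_binary_newick(n_tips, rng, min_bl=0.1, max_bl=2.0):
    """Random binary tree shape with uniform random branch lengths."""
    nodes = [f"t{i}" for i in range(n_tips)]

    def bl():
        return rng.uniform(min_bl, max_bl)

    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]}:{bl():.6f},{nodes[j]}:{bl():.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]}:{bl():.6f},{nodes[1]}:{bl():.6f});"
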