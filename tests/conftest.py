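import itertools

import numpy as np
import pandas as pd
import pytest

from ricetf.io import ExpressionMatrix, Scale
from ricetf.synthetic import make_characterized_fixture


@pytest.fixture(scope="session")
def characterized():
    """The packaged 92-record characterized fixture (set, trees, matrix)."""
    return make_characterized_fixture()


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples (2 groups x 2 replicates), log2 intensities."""
    meta = pd.DataFrame(
        {
            "sample_id": ["root_r1", "root_r2", "seed_r1", "seed_r2"],
            "platform": ["affymetrix"] * 4,
            "category": ["anatomy"] * 4,
            "group": ["root", "root", "seed", "seed"],
            "replicate_index": [1, 2, 1, 2],
        }
    ).set_index("sample_id")
    values = pd.DataFrame(
        [[2.0, 4.0, 1.0, 1.0], [5.0, 5.0, 5.0, 5.0], [0.0, 0.0, 8.0, 10.0]],
        index=pd.Index(["g1", "g2", "g3"], name="locus_id"),
        columns=meta.index,
    )
    return ExpressionMatrix(values, meta, Scale.LOG2_INTENSITY)


def random_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary tree with random branch lengths.

    Returns (newick, exact leaf-pair distances) where the distances are
    accumulated during construction, independently of any newick parser.
    """
    nodes = []
    for i in range(n_leaves):
        label = f"L{i:02d}"
        nodes.append((label, {label: 0.0}))
    dist: dict[tuple[str, str], float] = {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (nwk_a, da) = nodes.pop(j)
        (nwk_b, db) = nodes.pop(i)
        ba, bb = rng.uniform(0.1, 2.0, size=2).round(3)
        for x, dx in da.items():
            for y, dy in db.items():
                d = dx + ba + dy + bb
                dist[(x, y)] = d
                dist[(y, x)] = d
        merged = {x: d + ba for x, d in da.items()}
        merged.update({y: d + bb for y, d in db.items()})
        nodes.append((f"({nwk_a}:{ba},{nwk_b}:{bb})", merged))
    return nodes[0][0] + ";", dist
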