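"""Gene-family trees and closest-paralog extraction.

Family trees (maximum-likelihood trees built upstream) arrive as newick text;
each leaf is a gene locus.  A characterized gene's closest paralog is the
leaf at minimum patristic distance (sum of branch lengths on the connecting
path).  A gene alone in its family tree — a clade of a single member — is a
singleton with no expected redundancy partner.  An optional distance cap lets
callers treat distant nearest leaves as singletons too.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import dendropy

__all__ = [
    "GeneFamilyTree",
    "ParalogAssignment",
    "parse_newick",
    "patristic_distance",
    "closest_paralog",
    "read_trees",
    "assign_paralogs",
]


@dataclass(frozen=True)
class ParalogAssignment:
    locus_id: str
    partner: str | None
    patristic_distance: float | None
    singleton: bool

    def __post_init__(self) -> None:
        assert self.singleton == (self.partner is None)


class GeneFamilyTree:
    """A rooted gene-family tree with unique leaf labels.

    Edges without a branch length are given length 1.0, turning a cladogram
    into topological distance; the root edge is 0.
    """

    def __init__(self, tree: dendropy.Tree, family_name: str = "") -> None:
        self._tree = tree
        self.family_name = family_name
        labels = [
            leaf.taxon.label if leaf.taxon else (leaf.label or "")
            for leaf in tree.leaf_node_iter()
        ]
        if any(not l for l in labels):
            raise ValueError("tree contains an unlabeled leaf")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        self.leaves = sorted(labels)
        for edge in tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0 if edge.head_node is tree.seed_node else 1.0
            elif edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        self._dist: dict[tuple[str, str], float] | None = None

    def __len__(self) -> int:
        return len(self.leaves)

    def _distances(self) -> dict[tuple[str, str], float]:
        if self._dist is None:
            pdm = self._tree.phylogenetic_distance_matrix()
            self._dist = {}
            for t1 in self._tree.taxon_namespace:
                for t2 in self._tree.taxon_namespace:
                    self._dist[(t1.label, t2.label)] = float(
                        pdm.patristic_distance(t1, t2)
                    )
        return self._dist

    def distance(self, leaf_a: str, leaf_b: str) -> float:
        for leaf in (leaf_a, leaf_b):
            if leaf not in self.leaves:
                raise KeyError(f"leaf {leaf!r} not in tree")
        if leaf_a == leaf_b:
            return 0.0
        return self._distances()[(leaf_a, leaf_b)]

    def as_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()


def parse_newick(text: str, family_name: str = "") -> GeneFamilyTree:
    """Parse newick text (branch lengths and internal labels optional)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"newick parse error: {exc}") from exc
    if not family_name and tree.seed_node.label:
        family_name = tree.seed_node.label
    return GeneFamilyTree(tree, family_name)


def patristic_distance(tree: GeneFamilyTree, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    return tree.distance(leaf_a, leaf_b)


def closest_paralog(
    tree: GeneFamilyTree,
    locus: str,
    max_distance: float | None = None,
) -> ParalogAssignment:
    """Nearest leaf by patristic distance, or a singleton call.

    Ties are broken by the lexicographically smallest partner locus id.  With
    ``max_distance`` set, a nearest leaf farther than the cap is ignored and
    the locus reported as singleton.
    """
    if locus not in tree.leaves:
        raise KeyError(f"locus {locus!r} not in tree")
    others = [l for l in tree.leaves if l != locus]
    if not others:
        return ParalogAssignment(locus, None, None, True)
    partner = min(others, key=lambda l: (tree.distance(locus, l), l))
    d = tree.distance(locus, partner)
    if max_distance is not None and d > max_distance:
        return ParalogAssignment(locus, None, None, True)
    return ParalogAssignment(locus, partner, d, False)


def read_trees(path: str | Path) -> list[GeneFamilyTree]:
    """Read one or more newick trees from a file (one tree per statement).

    A tree's family name is taken from its root label when present.
    """
    text = Path(path).read_text()
    trees = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if chunk:
            trees.append(parse_newick(chunk + ";"))
    return trees


def assign_paralogs(
    trees: Iterable[GeneFamilyTree],
    loci: Iterable[str] | None = None,
    max_distance: float | None = None,
) -> list[ParalogAssignment]:
    """Closest-paralog assignment for every requested locus across trees."""
    wanted = set(loci) if loci is not None else None
    out = []
    for tree in trees:
        for leaf in tree.leaves:
            if wanted is None or leaf in wanted:
                out.append(closest_paralog(tree, leaf, max_distance))
    return out
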