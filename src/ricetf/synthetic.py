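"""Synthetic inputs with planted ground truth for every pipeline stage.

Real meta-expression data are assembled from hundreds of public microarray
and RNA-Seq experiments; none of that is needed to exercise the pipeline.
This module generates:

* expression matrices with planted tissue-specific, ubiquitous and
  background genes (log2 scale, Gaussian noise, truth table returned);
* paralog expression vectors whose *empirical* Pearson correlation hits a
  requested target exactly (orthogonalized-residual construction);
* replicate log2 fold-change blocks with planted responsive genes;
* the packaged characterized-gene fixture: 92 records (39 singleton-clade,
  14 without unique probes, 39 analyzable pairs) whose pair vectors realize
  a reference correlation histogram of 4/11/11/10/3 across the bins
  [-0.25,0], (0,0.25], (0.25,0.5], (0.5,0.75], (0.75,1], including the three
  reference pair values -0.09, 0.24 and 0.92.  Record identities and family
  trees are versioned text data shipped with the package; the expression
  vectors are synthesized deterministically at load time.

Every generator takes an explicit seed and owns its random generator; none
touches global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, Scale
from .phylo import GeneFamilyTree, parse_newick
from .redundancy import CharacterizedRecord, CharacterizedSet, pearson

__all__ = [
    "GeneratorSpec",
    "make_expression_matrix",
    "make_correlated_pair",
    "make_fc_block",
    "make_characterized_fixture",
    "ANATOMY_GROUPS",
]

#: tissue classes of the anatomical meta-expression analysis
ANATOMY_GROUPS = ("vegetative", "root", "sam_panicle", "anther_pollen", "seed")


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for a planted expression matrix.

    ``groups`` maps each group label to its replicate count; ``planted`` is a
    list of (class, count, effect_size) with class in {'tissue_specific',
    'ubiquitous'}.  Background genes sit at ``baseline`` on the log2 scale
    with Gaussian noise of sd ``noise_sd``; tissue-specific genes are silent
    (level ~0, i.e. not expressed) outside exactly one group (assigned
    round-robin) and at their effect size inside it, the one-hot pattern of
    a truly tissue-restricted transcript; ubiquitous genes sit flat at
    baseline + ubiquitous_lift everywhere.
    """

    n_genes: int = 1000
    groups: tuple[tuple[str, int], ...] = tuple((g, 3) for g in ANATOMY_GROUPS)
    planted: tuple[tuple[str, int, float], ...] = (
        ("tissue_specific", 50, 8.0),
        ("ubiquitous", 50, 0.0),
    )
    noise_sd: float = 0.5
    baseline: float = 4.0
    ubiquitous_lift: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.noise_sd < 0:
            raise ValueError("degenerate generator spec")
        if sum(c for _, c, _ in self.planted) > self.n_genes:
            raise ValueError("planted counts exceed n_genes")
        for cls, _, _ in self.planted:
            if cls not in {"tissue_specific", "ubiquitous"}:
                raise ValueError(f"unknown planted class {cls!r}")


def _meta_frame(groups: tuple[tuple[str, int], ...], category: str) -> pd.DataFrame:
    rows = []
    for g, n_rep in groups:
        for j in range(1, n_rep + 1):
            rows.append(
                {
                    "sample_id": f"{g}_r{j}",
                    "platform": "affymetrix",
                    "category": category,
                    "group": g,
                    "replicate_index": j,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def make_expression_matrix(
    spec: GeneratorSpec | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Planted log2-intensity matrix plus its truth table.

    The truth table has one row per planted gene: locus_id, class, group
    (the elevated tissue; empty for ubiquitous genes).
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    group_labels = [g for g, _ in spec.groups]
    meta = _meta_frame(spec.groups, "anatomy")
    n_samples = len(meta)
    loci = [f"GEN{i:05d}" for i in range(spec.n_genes)]
    values = spec.baseline + rng.normal(0.0, spec.noise_sd, (spec.n_genes, n_samples))

    truth_rows = []
    i = 0
    for cls, count, effect in spec.planted:
        for j in range(count):
            locus = loci[i]
            if cls == "tissue_specific":
                g = group_labels[j % len(group_labels)]
                cols = meta["group"] == g
                values[i, :] -= spec.baseline  # silent outside the tissue
                values[i, cols.to_numpy()] += effect
                truth_rows.append({"locus_id": locus, "class": cls, "group": g})
            else:
                values[i, :] += spec.ubiquitous_lift
                truth_rows.append({"locus_id": locus, "class": cls, "group": ""})
            i += 1
    frame = pd.DataFrame(values, index=pd.Index(loci, name="locus_id"),
                         columns=meta.index)
    matrix = ExpressionMatrix(frame, meta, Scale.LOG2_INTENSITY)
    truth = pd.DataFrame(truth_rows, columns=["locus_id", "class", "group"])
    return matrix, truth


def make_correlated_pair(
    target_pcc: float,
    n_samples: int = 40,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two vectors whose empirical Pearson correlation equals the target.

    Draws x ~ N(0,1), orthogonalizes an independent residual against the
    centered x, and mixes y = r*u + sqrt(1-r^2)*w from the resulting unit
    vectors, so the sample correlation is ``target_pcc`` to floating-point
    accuracy (|r_emp - r| <= 1e-9), not merely in expectation.
    """
    if not -1.0 < target_pcc < 1.0:
        raise ValueError("target PCC must lie strictly inside (-1, 1)")
    if n_samples < 3:
        raise ValueError("need at least 3 samples for orthogonalization")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n_samples)
    e = rng.normal(size=n_samples)
    xc = x - x.mean()
    u = xc / np.linalg.norm(xc)
    ec = e - e.mean()
    w = ec - (ec @ u) * u
    norm_w = np.linalg.norm(w)
    if norm_w == 0:
        raise ValueError("degenerate draw: residual parallel to x")
    w /= norm_w
    y = target_pcc * u + np.sqrt(1.0 - target_pcc**2) * w
    return x, y


def make_fc_block(
    n_genes: int = 1000,
    conditions: tuple[str, ...] = ("drought", "salinity", "cold"),
    n_replicates: int = 3,
    responsive_fraction: float = 0.05,
    effect: float = 3.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Replicate log2 fold-change block with planted responsive genes.

    Null genes draw log2FC ~ N(0, noise_sd) in every replicate; each
    condition plants ``responsive_fraction`` of genes at N(effect, noise_sd).
    Returns (fc matrix with one column per condition replicate, experiment ->
    condition mapping, truth table of planted locus/condition rows).
    """
    if n_genes < 1 or n_replicates < 2 or not 0 <= responsive_fraction <= 1:
        raise ValueError("degenerate fold-change block spec")
    rng = np.random.default_rng(seed)
    loci = [f"GEN{i:05d}" for i in range(n_genes)]
    n_resp = int(round(responsive_fraction * n_genes))
    cols = {}
    groups = {}
    truth_rows = []
    planted: dict[str, np.ndarray] = {}
    for ci, cond in enumerate(conditions):
        # distinct planted sets per condition, chosen deterministically
        idx = rng.permutation(n_genes)[:n_resp]
        planted[cond] = idx
        for locus_i in sorted(idx):
            truth_rows.append({"locus_id": loci[locus_i], "condition": cond})
        for j in range(1, n_replicates + 1):
            col = f"{cond}_e{j}"
            vals = rng.normal(0.0, noise_sd, n_genes)
            vals[idx] += effect
            cols[col] = vals
            groups[col] = cond
    fc = pd.DataFrame(cols, index=pd.Index(loci, name="locus_id"))
    truth = pd.DataFrame(truth_rows, columns=["locus_id", "condition"])
    return fc, groups, truth


def make_coexpression_block(
    n_planted: int = 80,
    n_background: int = 200,
    n_samples: int = 60,
    pcc_range: tuple[float, float] = (0.80, 0.99),
    seed: int = 7,
) -> tuple[pd.DataFrame, str]:
    """Log2 matrix with a query gene and a block of planted co-expressed genes.

    Every planted gene's vector comes from :func:`make_correlated_pair` with
    the same seed, so all planted genes share the query vector and hit their
    (evenly spaced) target correlations in ``pcc_range`` exactly; background
    genes are independent noise.  Returns (matrix, query locus id).
    """
    rng = np.random.default_rng(seed)
    targets = np.linspace(pcc_range[0], pcc_range[1], n_planted)
    rows = {}
    query = "QUERY00000"
    for i, r in enumerate(targets):
        x, y = make_correlated_pair(float(r), n_samples, seed=seed)
        if i == 0:
            rows[query] = 7.0 + 1.5 * x
        rows[f"COEX{i:05d}"] = 7.0 + 1.5 * y
    for i in range(n_background):
        rows[f"BG{i:05d}"] = 7.0 + 1.5 * rng.normal(size=n_samples)
    frame = pd.DataFrame(rows).T
    frame.index.name = "locus_id"
    frame.columns = [f"s{j:03d}" for j in range(n_samples)]
    return frame, query


# ---------------------------------------------------------------------------
# characterized-gene fixture
# ---------------------------------------------------------------------------

def _fixture_dir() -> Path:
    return Path(str(resources.files("ricetf") / "data"))


def load_fixture_records() -> pd.DataFrame:
    """The versioned fixture record table (synthetic stand-in identities)."""
    path = _fixture_dir() / "characterized_records.tsv"
    return pd.read_csv(path, sep="\t", dtype=str)


def load_fixture_trees() -> dict[str, GeneFamilyTree]:
    """Family trees of the fixture, keyed by family name (newick root label)."""
    text = (_fixture_dir() / "characterized_trees.nwk").read_text()
    trees = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if chunk:
            t = parse_newick(chunk + ";")
            trees[t.family_name] = t
    return trees


def make_characterized_fixture(
    n_samples: int = 40,
    base_seed: int = 2019,
) -> tuple[CharacterizedSet, dict[str, GeneFamilyTree], ExpressionMatrix]:
    """Build the 92-record characterized fixture.

    Loads the versioned record table and family trees, then synthesizes an
    anatomical meta-expression matrix in which every analyzable pair's two
    vectors realize the record's target correlation exactly (via
    :func:`make_correlated_pair`; an affine map to a log2-intensity-like
    range preserves the correlation).  Each record's ``pair_pcc`` is the
    correlation *computed* from those vectors, so downstream summaries rest
    on measured values.

    Returns (CharacterizedSet, family trees, ExpressionMatrix).
    """
    records_df = load_fixture_records()
    trees = load_fixture_trees()
    groups = tuple((f"t{j:02d}", n_samples // 8) for j in range(1, 9))
    if sum(n for _, n in groups) != n_samples:
        groups = (("t01", n_samples),)
    meta = _meta_frame(groups, "anatomy")

    records: list[CharacterizedRecord] = []
    vectors: dict[str, np.ndarray] = {}
    pair_i = 0
    for row in records_df.itertuples(index=False):
        category = row.category
        if category == "singleton":
            records.append(
                CharacterizedRecord(row.locus_id, True, row.family, True)
            )
        elif category == "no_probe":
            records.append(
                CharacterizedRecord(
                    row.locus_id, False, row.family, False, partner=row.partner_id
                )
            )
        elif category == "pair":
            target = float(row.target_pcc)
            x, y = make_correlated_pair(target, n_samples, seed=base_seed + pair_i)
            # affine map into a log2-intensity-like range; PCC is unchanged
            vectors[row.locus_id] = 7.0 + 1.5 * x
            vectors[row.partner_id] = 7.0 + 1.5 * y
            measured = pearson(vectors[row.locus_id], vectors[row.partner_id])
            records.append(
                CharacterizedRecord(
                    row.locus_id,
                    True,
                    row.family,
                    False,
                    partner=row.partner_id,
                    pair_pcc=measured,
                )
            )
            pair_i += 1
        else:
            raise ValueError(f"unknown fixture category {category!r}")

    frame = pd.DataFrame(
        vectors, index=meta.index
    ).T
    frame.index.name = "locus_id"
    matrix = ExpressionMatrix(frame, meta, Scale.LOG2_INTENSITY)
    return CharacterizedSet(records), trees, matrix
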