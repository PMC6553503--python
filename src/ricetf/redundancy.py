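"""Paralog expression collinearity and functional-dominance calling.

Whether a characterized gene's phenotype reflects a dominant (non-redundant)
role can be screened from expression alone: a gene whose anatomical
meta-expression profile correlates weakly with its closest paralog's
(Pearson r < 0.5) is unlikely to be buffered by that paralog.  This module
computes pairwise Pearson correlations, calls dominance against the 0.5
threshold, bins pair correlations for the characteristic histogram, and
aggregates a characterized-gene set into a dominance summary in which
singleton-clade genes (no close paralog at all) count as predominant and
genes without a unique probe are excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "ParalogPair",
    "CharacterizedRecord",
    "CharacterizedSet",
    "DominanceSummary",
    "pearson",
    "classify_dominance",
    "bin_pcc",
    "summarize_characterized",
    "ParalogDominanceClassifier",
    "DEFAULT_BIN_EDGES",
]

PREDOMINANT = "predominant"
POTENTIALLY_REDUNDANT = "potentially_redundant"
UNTESTABLE = "untestable"

#: histogram bin edges; bins are right-closed: [-0.25, 0], (0, 0.25], ...
DEFAULT_BIN_EDGES = (-0.25, 0.00, 0.25, 0.50, 0.75, 1.00)


@dataclass(frozen=True)
class ParalogPair:
    locus_a: str
    locus_b: str
    pcc: float | None
    call: str
    reason: str | None = None  # no_probe | zero_variance


@dataclass(frozen=True)
class CharacterizedRecord:
    """One characterized gene in the worked-example accounting."""

    locus_id: str
    has_unique_probe: bool
    family: str
    is_singleton: bool
    partner: str | None = None
    pair_pcc: float | None = None

    def __post_init__(self) -> None:
        if self.is_singleton and self.pair_pcc is not None:
            raise ValueError(
                f"singleton record {self.locus_id} must not carry a pair PCC"
            )


@dataclass
class CharacterizedSet:
    records: list[CharacterizedRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def analyzable(self) -> list[CharacterizedRecord]:
        """Non-singleton records with a unique probe (testable pairs)."""
        return [
            r for r in self.records if not r.is_singleton and r.has_unique_probe
        ]


@dataclass(frozen=True)
class DominanceSummary:
    n_selected: int
    n_singleton: int
    n_no_probe: int
    n_pairs_tested: int
    histogram: tuple[int, ...]
    n_predominant_paired: int
    n_predominant_total: int
    pct_predominant: float

    def __post_init__(self) -> None:
        assert self.n_selected == (
            self.n_singleton + self.n_no_probe + self.n_pairs_tested
        )
        assert self.n_predominant_total == (
            self.n_singleton + self.n_predominant_paired
        )
        denom = self.n_selected - self.n_no_probe
        assert abs(
            self.pct_predominant - round(100.0 * self.n_predominant_total / denom, 1)
        ) < 1e-9


def pearson(x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray) -> float:
    """Product-moment correlation of two expression vectors (n >= 3).

    Raises on zero variance; batch callers should catch and mark the pair
    untestable instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def classify_dominance(pcc: float, threshold: float = 0.5) -> str:
    """Strictly-below-threshold correlation implies a predominant role."""
    if not -1.0 - 1e-12 <= pcc <= 1.0 + 1e-12:
        raise ValueError(f"PCC {pcc} outside [-1, 1]")
    return PREDOMINANT if pcc < threshold else POTENTIALLY_REDUNDANT


def bin_pcc(
    pcc_values: Iterable[float],
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> tuple[int, ...]:
    """Histogram counts over right-closed bins [e0,e1], (e1,e2], ...

    Right-closed bins keep 0.50 in the third default bin, so predominance
    (PCC < 0.5, midpoint-valued data) corresponds to the first three bins.
    """
    edges = np.asarray(edges, dtype=float)
    counts = np.zeros(edges.size - 1, dtype=int)
    for v in pcc_values:
        if v < edges[0] or v > edges[-1]:
            raise ValueError(f"PCC {v} outside histogram range "
                             f"[{edges[0]}, {edges[-1]}]")
        idx = int(np.searchsorted(edges, v, side="left")) - 1
        counts[max(idx, 0)] += 1
    return tuple(int(c) for c in counts)


def summarize_characterized(
    cset: CharacterizedSet,
    threshold: float = 0.5,
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> DominanceSummary:
    """Aggregate a characterized set into the dominance accounting.

    Records without a unique probe are removed from the denominator;
    singleton-clade genes count as predominant outright; each analyzable
    pair is called by ``classify_dominance`` on its PCC.  The percentage is
    rounded to one decimal for reporting.
    """
    n_selected = len(cset)
    n_singleton = sum(r.is_singleton for r in cset.records)
    no_probe = [r for r in cset.records if not r.is_singleton and not r.has_unique_probe]
    n_no_probe = len(no_probe)
    pairs = cset.analyzable()
    missing = [r.locus_id for r in pairs if r.pair_pcc is None]
    if missing:
        raise ValueError(f"analyzable records lack a pair PCC: {missing}")
    pccs = [r.pair_pcc for r in pairs]
    n_predominant_paired = sum(
        classify_dominance(p, threshold) == PREDOMINANT for p in pccs
    )
    n_predominant_total = n_singleton + n_predominant_paired
    denom = n_selected - n_no_probe
    return DominanceSummary(
        n_selected=n_selected,
        n_singleton=n_singleton,
        n_no_probe=n_no_probe,
        n_pairs_tested=len(pairs),
        histogram=bin_pcc(pccs, edges),
        n_predominant_paired=n_predominant_paired,
        n_predominant_total=n_predominant_total,
        pct_predominant=round(100.0 * n_predominant_total / denom, 1),
    )


class ParalogDominanceClassifier(BaseEstimator):
    """PCC-based dominance calls for paralog pairs over an expression matrix.

    ``fit`` stores a genes-by-samples log2 matrix (typically the anatomical
    meta-expression profile); ``predict`` takes (locus_a, locus_b) pairs and
    returns per-pair calls.  Pairs with a member absent from the matrix are
    untestable with reason ``no_probe``; zero-variance members give reason
    ``zero_variance``.

    Parameters
    ----------
    threshold : float
        Dominance cutoff on the pair correlation (strict <, default 0.5).

    Attributes
    ----------
    matrix_ : pandas.DataFrame   the fitted expression matrix
    pairs_ : list of ParalogPair  set by ``fit_predict``-style usage
    """

    def __init__(self, threshold: float = 0.5) -> None:
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None) -> "ParalogDominanceClassifier":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a genes-by-samples DataFrame")
        self.matrix_ = X
        return self

    def predict(
        self, pairs: Iterable[tuple[str, str]]
    ) -> list[ParalogPair]:
        out = []
        for a, b in pairs:
            if a not in self.matrix_.index or b not in self.matrix_.index:
                out.append(ParalogPair(a, b, None, UNTESTABLE, "no_probe"))
                continue
            try:
                r = pearson(self.matrix_.loc[a], self.matrix_.loc[b])
            except ValueError:
                out.append(ParalogPair(a, b, None, UNTESTABLE, "zero_variance"))
                continue
            out.append(ParalogPair(a, b, r, classify_dominance(r, self.threshold)))
        self.pairs_ = out
        return out
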