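"""Tissue-specificity classification of expression profiles.

Genes are scored with the Tau index on their per-tissue mean profile:

    tau = sum_i (1 - x_i / x_max) / (n - 1),   x_i >= 0

tau = 0 for a perfectly uniform profile (broad expression) and 1 when
expression is confined to a single tissue.  A low cutoff (tau < 0.15 by
default) defines ubiquitously expressed genes; a permissive high cutoff
(tau > 0.6) screens tissue-preferential candidates, which are then refined by
K-means clustering (Euclidean distance on max-normalized profiles) so each
candidate inherits its cluster's dominant tissue label.  Because related
tissues (e.g. leaf and flag leaf) blur single-gene scores, a Sprent-style
pairwise outlier test on two correlated tissues can rescue additional
tissue-preferential genes: it fits the major axis of the two-tissue scatter
and flags genes whose perpendicular residual is an outlier under a normal
model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

__all__ = [
    "SpecificityConfig",
    "SpecificityCall",
    "tau",
    "classify_by_tau",
    "kmeans_refine",
    "sprent_outliers",
    "assign_labels",
    "TissueSpecificityClassifier",
]

UBIQUITOUS = "ubiquitous"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class SpecificityConfig:
    """Thresholds and clustering settings for specificity calling."""

    ubiquitous_cutoff: float = 0.15
    preferential_cutoff: float = 0.6
    kmeans_k: int = 5
    kmeans_seed: int = 7
    kmeans_restarts: int = 10
    sprent_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.ubiquitous_cutoff < self.preferential_cutoff <= 1):
            raise ValueError(
                "require 0 <= ubiquitous_cutoff < preferential_cutoff <= 1"
            )


@dataclass(frozen=True)
class SpecificityCall:
    """Final per-gene specificity label with provenance.

    ``label`` is 'ubiquitous', 'unclassified' or 'preferential:<group>';
    ``method`` records which screen produced the label.
    """

    locus_id: str
    tau: float
    label: str
    method: str  # tau_only | kmeans_refined | sprent
    cluster_id: int | None = None


def tau(profile: Sequence[float] | np.ndarray) -> float:
    """Tissue-specificity index of a non-negative per-group profile.

    Returns 0 iff all values are equal and 1 iff exactly one value is
    nonzero.  Invariant to positive rescaling and to group order.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a vector of length >= 2")
    if (x < 0).any():
        raise ValueError("profile values must be >= 0")
    xmax = x.max()
    if xmax == 0:
        raise ValueError("tau undefined for an all-zero profile")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def tau_profiles(profiles: pd.DataFrame, min_shift: bool = True) -> pd.Series:
    """Tau per row of a genes-by-groups profile table.

    Log2 profiles may contain negative entries, which Tau does not accept;
    with ``min_shift`` a row whose minimum is negative is shifted to minimum
    0 before the index is computed.  Rows that are already non-negative are
    left alone — shifting them too would make Tau blind to the profile's
    absolute level and score flat noisy profiles as specific.
    """
    arr = profiles.to_numpy(dtype=float)
    if min_shift:
        mins = arr.min(axis=1, keepdims=True)
        arr = np.where(mins < 0, arr - mins, arr)
    return pd.Series(
        [tau(row) for row in arr], index=profiles.index, name="tau", dtype=float
    )


def classify_by_tau(
    tau_values: pd.Series | Mapping[str, float],
    config: SpecificityConfig | None = None,
) -> pd.DataFrame:
    """Screen genes into ubiquitous / preferential-candidate / unclassified.

    tau < ubiquitous_cutoff marks broad expression; tau > preferential_cutoff
    marks candidates for the tissue-preferential refinement step.
    """
    config = config or SpecificityConfig()
    s = pd.Series(dict(tau_values)) if not isinstance(tau_values, pd.Series) else tau_values
    cls = pd.Series(UNCLASSIFIED, index=s.index, dtype=object)
    cls[s < config.ubiquitous_cutoff] = UBIQUITOUS
    cls[s > config.preferential_cutoff] = "candidate"
    return pd.DataFrame({"tau": s, "tau_class": cls})


def kmeans_refine(
    profiles: pd.DataFrame,
    config: SpecificityConfig | None = None,
) -> tuple[dict[str, int], dict[int, str]]:
    """Cluster candidate profiles and label each cluster by its top tissue.

    Profiles are row-normalized to unit maximum, then clustered with Lloyd's
    K-means (Euclidean distance, ``kmeans_restarts`` initializations, fixed
    seed).  A cluster's label is the group at which its centroid peaks.
    Returns (locus -> cluster_id, cluster_id -> group label).
    """
    config = config or SpecificityConfig()
    k = config.kmeans_k
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the {len(profiles)} candidate genes")
    arr = profiles.to_numpy(dtype=float)
    arr = arr - arr.min(axis=1, keepdims=True)
    rowmax = arr.max(axis=1, keepdims=True)
    rowmax[rowmax == 0] = 1.0
    arr = arr / rowmax
    km = KMeans(
        n_clusters=k,
        n_init=config.kmeans_restarts,
        random_state=config.kmeans_seed,
        algorithm="lloyd",
    ).fit(arr)
    assignment = {
        locus: int(c) for locus, c in zip(profiles.index, km.labels_)
    }
    cluster_label = {
        c: profiles.columns[int(np.argmax(km.cluster_centers_[c]))]
        for c in range(k)
    }
    return assignment, cluster_label


def sprent_outliers(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    alpha: float = 0.05,
) -> np.ndarray:
    """Flag genes whose expression departs from the two-tissue major axis.

    For per-gene log2 means in tissues A (``x``) and B (``y``), fits the
    major axis (first principal axis through the centroid) of the scatter,
    computes each gene's signed perpendicular residual, standardizes the
    residuals, and flags genes with two-sided normal-theory p < ``alpha``.
    Positive displacement toward higher A yields 'toward_A'.

    Returns an array over genes with values 'toward_A', 'toward_B' or 'none'.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 10:
        raise ValueError("need at least 10 genes to fit the major axis")
    pts = np.column_stack([x, y])
    centered = pts - pts.mean(axis=0)
    cov = np.cov(centered, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, np.argmax(eigvals)]
    perp = np.array([axis[1], -axis[0]])
    if perp[0] < 0 or (perp[0] == 0 and perp[1] < 0):
        perp = -perp  # orient so positive residual means displaced toward A
    resid = centered @ perp
    sd = resid.std(ddof=1)
    scale = np.sqrt((centered**2).sum() / x.size)
    if sd <= 1e-10 * max(scale, 1.0):
        raise ValueError("zero residual variance: no scatter around the axis")
    z = resid / sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    flags = np.full(x.size, "none", dtype=object)
    flags[(p < alpha) & (z > 0)] = "toward_A"
    flags[(p < alpha) & (z < 0)] = "toward_B"
    return flags


def assign_labels(
    tau_table: pd.DataFrame,
    kmeans_assignment: Mapping[str, int] | None = None,
    cluster_labels: Mapping[int, str] | None = None,
    sprent_flags: Mapping[str, str] | None = None,
) -> list[SpecificityCall]:
    """Combine the three screens into one label per gene.

    Precedence: ubiquitous (tau) > K-means-refined preferential label >
    Sprent-rescued preferential label > unclassified.  ``sprent_flags`` maps
    locus -> group toward which the gene is displaced.
    """
    kmeans_assignment = kmeans_assignment or {}
    cluster_labels = cluster_labels or {}
    sprent_flags = sprent_flags or {}
    if tau_table.index.duplicated().any():
        raise ValueError("duplicate loci in tau table: conflicting calls")
    calls: list[SpecificityCall] = []
    for locus, row in tau_table.iterrows():
        t = float(row["tau"])
        if row["tau_class"] == UBIQUITOUS:
            calls.append(SpecificityCall(locus, t, UBIQUITOUS, "tau_only"))
        elif row["tau_class"] == "candidate" and locus in kmeans_assignment:
            c = kmeans_assignment[locus]
            calls.append(
                SpecificityCall(
                    locus, t, f"preferential:{cluster_labels[c]}", "kmeans_refined", c
                )
            )
        elif locus in sprent_flags:
            calls.append(
                SpecificityCall(locus, t, f"preferential:{sprent_flags[locus]}", "sprent")
            )
        else:
            calls.append(SpecificityCall(locus, t, UNCLASSIFIED, "tau_only"))
    return calls


def calls_to_frame(calls: Iterable[SpecificityCall]) -> pd.DataFrame:
    rows = [
        {
            "locus_id": c.locus_id,
            "tau": c.tau,
            "label": c.label,
            "method": c.method,
            "cluster_id": c.cluster_id,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)


class TissueSpecificityClassifier(BaseEstimator):
    """Tau + K-means (+ optional Sprent rescue) specificity caller.

    A scikit-learn-style estimator over a genes-by-groups table of per-group
    mean log2 expression.  ``fit`` computes Tau for every gene, screens
    ubiquitous genes and preferential candidates, refines candidates by
    K-means, and optionally rescues genes from correlated tissue pairs with
    the Sprent-style outlier test.

    Parameters
    ----------
    ubiquitous_cutoff, preferential_cutoff : float
        Tau screening thresholds (defaults 0.15 and 0.6).
    n_clusters : int
        K for the refinement clustering (default 5 tissue classes).
    n_restarts, random_state : int
        K-means initializations and seed.
    sprent_pairs : list of (group, group) or None
        Correlated tissue pairs to test with the outlier rescue.
    sprent_alpha : float
        Two-sided significance level of the rescue test.

    Attributes
    ----------
    tau_ : pandas.Series           per-gene Tau scores
    calls_ : list of SpecificityCall
    labels_ : pandas.Series        per-gene final label
    """

    def __init__(
        self,
        ubiquitous_cutoff: float = 0.15,
        preferential_cutoff: float = 0.6,
        n_clusters: int = 5,
        n_restarts: int = 10,
        random_state: int = 7,
        sprent_pairs: list[tuple[str, str]] | None = None,
        sprent_alpha: float = 0.05,
    ) -> None:
        self.ubiquitous_cutoff = ubiquitous_cutoff
        self.preferential_cutoff = preferential_cutoff
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.sprent_pairs = sprent_pairs
        self.sprent_alpha = sprent_alpha

    def _config(self) -> SpecificityConfig:
        return SpecificityConfig(
            ubiquitous_cutoff=self.ubiquitous_cutoff,
            preferential_cutoff=self.preferential_cutoff,
            kmeans_k=self.n_clusters,
            kmeans_seed=self.random_state,
            kmeans_restarts=self.n_restarts,
            sprent_alpha=self.sprent_alpha,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "TissueSpecificityClassifier":
        """Fit on a genes-by-groups profile table (log2 per-group means)."""
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a genes-by-groups DataFrame")
        config = self._config()
        self.tau_ = tau_profiles(X)
        table = classify_by_tau(self.tau_, config)
        candidates = table.index[table["tau_class"] == "candidate"]
        assignment: dict[str, int] = {}
        cluster_labels: dict[int, str] = {}
        if len(candidates) >= config.kmeans_k and config.kmeans_k > 0:
            assignment, cluster_labels = kmeans_refine(X.loc[candidates], config)
        flags: dict[str, str] = {}
        for a, b in self.sprent_pairs or []:
            fl = sprent_outliers(X[a], X[b], alpha=config.sprent_alpha)
            for locus, f in zip(X.index, fl):
                if f == "toward_A":
                    flags.setdefault(locus, a)
                elif f == "toward_B":
                    flags.setdefault(locus, b)
        self.calls_ = assign_labels(table, assignment, cluster_labels, flags)
        self.labels_ = pd.Series(
            {c.locus_id: c.label for c in self.calls_}, name="label"
        ).loc[X.index]
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Labels for (new) profiles; refit-free tau-only classification."""
        config = self._config()
        t = tau_profiles(X)
        table = classify_by_tau(t, config)
        return table["tau_class"].replace({"candidate": UNCLASSIFIED})

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.Series:
        return self.fit(X).labels_
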