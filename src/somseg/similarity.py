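"""Slide-similarity engine: tumor-content filtering, K-means representative
selection, mean pairwise similarity, the similarity matrix, and expert matching.

Similarity between two slides is the mean of all pairwise similarities between
their representative sets — the k feature vectors closest to the K-means
centroids of each slide's tumor-patch embeddings (k x k comparisons, 25 with
the default k = 5). Cosine similarity is the default metric; L1/L2 distances
are supported as negated values so "most similar = arg-max" holds uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import json
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .core_io import LabelMask, Patch
from .encoding import FeatureSet

Metric = Literal["cosine", "neg_L1", "neg_L2"]


@dataclass(frozen=True)
class SimilarityConfig:
    """Knobs of the similarity engine.

    tumor_content_threshold: strict lower bound on a patch's tumor-area
        fraction for retention (default 0.60 — "more than 60%").
    k_representatives: K-means cluster count / representative-set size.
    metric: cosine (default), neg_L1 or neg_L2.
    """

    tumor_content_threshold: float = 0.60
    k_representatives: int = 5
    metric: Metric = "cosine"
    kmeans_seed: int = 0
    kmeans_restarts: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.tumor_content_threshold < 1:
            raise ValueError("tumor_content_threshold must be in (0, 1)")
        if self.k_representatives < 1:
            raise ValueError("k_representatives must be >= 1")
        if self.metric not in ("cosine", "neg_L1", "neg_L2"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class RepresentativeSet:
    """The k_eff centroid-nearest member vectors summarizing one slide."""

    slide_id: str
    vectors: np.ndarray  # k_eff x d, each row a verbatim member of the FeatureSet
    source_refs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] == 0:
            raise ValueError("representative set must be a non-empty k x d matrix")

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass
class SimilarityMatrix:
    """Query x annotated grid of mean-pairwise-similarity values."""

    annotated_ids: list[str]
    query_ids: list[str]
    values: np.ndarray  # |queries| x |annotated|
    metric: str = "cosine"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.query_ids), len(self.annotated_ids)):
            raise ValueError("similarity grid shape does not match id lists")

    def row(self, query_id: str) -> dict[str, float]:
        try:
            qi = self.query_ids.index(query_id)
        except ValueError:
            raise KeyError(f"unknown query slide {query_id!r}") from None
        return dict(zip(self.annotated_ids, self.values[qi]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.query_ids, columns=self.annotated_ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="query_id")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "metric": self.metric,
                    "annotated_ids": self.annotated_ids,
                    "query_ids": self.query_ids,
                    "values": self.values.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SimilarityMatrix":
        d = json.loads(Path(path).read_text())
        return cls(d["annotated_ids"], d["query_ids"], np.asarray(d["values"]), d["metric"])


def tumor_fraction(mask_patch: LabelMask | np.ndarray, tumor_codes: set[int]) -> float:
    """Fraction of patch pixels carrying a tumor code (ignore pixels count in
    the denominator)."""
    codes = mask_patch.codes if isinstance(mask_patch, LabelMask) else np.asarray(mask_patch)
    if codes.size == 0:
        raise ValueError("empty mask crop")
    return float(np.isin(codes, list(tumor_codes)).mean())


def filter_tumor_patches(
    patches: Sequence[Patch],
    tumor_codes: set[int],
    cfg: SimilarityConfig | None = None,
) -> list[Patch]:
    """Retain exactly the patches with tumor fraction strictly above the
    threshold; order preserved. Patches must carry masks (manual annotations
    or tumor-locator predictions)."""
    cfg = cfg or SimilarityConfig()
    out = []
    for p in patches:
        if p.mask is None:
            raise ValueError(f"patch at {p.origin} of slide {p.slide_id} has no mask")
        if tumor_fraction(p.mask, tumor_codes) > cfg.tumor_content_threshold:
            out.append(p)
    return out


#: below this sample count the clustering is solved exactly by enumeration
_EXACT_KMEANS_MAX_N = 10


def _rgs_strings(n: int, k: int):
    """Restricted growth strings of length n using exactly k labels — one
    canonical representative per set partition into k nonempty parts."""
    a = np.zeros(n, dtype=int)

    def rec(i: int, m: int):
        if i == n:
            if m == k:
                yield a.copy()
            return
        # pruning: remaining positions must be able to reach k labels
        for v in range(min(m + 1, k)):
            a[i] = v
            if k - max(m, v + 1) <= n - i - 1:
                yield from rec(i + 1, max(m, v + 1))

    yield from rec(1, 1) if n > 0 else iter(())


def _exact_min_sse(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Globally optimal k-partition by enumeration (tiny n only)."""
    n = X.shape[0]
    best_sse, best_labels = np.inf, None
    for labels in _rgs_strings(n, k):
        sse = 0.0
        for c in range(k):
            member = X[labels == c]
            sse += float(((member - member.mean(axis=0)) ** 2).sum())
        if sse < best_sse - 1e-12:
            best_sse, best_labels = sse, labels
    centers = np.stack([X[best_labels == c].mean(axis=0) for c in range(k)])
    return centers, best_labels


def select_representatives(
    features: FeatureSet, cfg: SimilarityConfig | None = None
) -> RepresentativeSet:
    """Cluster the slide's embeddings into k groups and return, per cluster,
    the member vector closest to the centroid (ties -> lowest row index).

    k_eff = min(k, number of distinct vectors): a slide with fewer than k
    distinct tumor embeddings collapses to fewer representatives rather than
    erroring (the low-tumor-content failure mode). For tiny inputs
    (n <= 10) the minimum-SSE partition is found exactly by enumeration;
    larger inputs use Lloyd's algorithm with k-means++ and restarts, which at
    realistic patch counts converges to the same objective in practice.
    """
    cfg = cfg or SimilarityConfig()
    if len(features) == 0:
        raise ValueError(f"slide {features.slide_id}: insufficient tumor patches")
    X = features.vectors
    n_distinct = np.unique(X, axis=0).shape[0]
    k_eff = min(cfg.k_representatives, n_distinct)
    if k_eff == 1:
        centers = X.mean(axis=0, keepdims=True)
        labels = np.zeros(X.shape[0], dtype=int)
    elif X.shape[0] <= _EXACT_KMEANS_MAX_N:
        centers, labels = _exact_min_sse(X, k_eff)
    else:
        km = KMeans(
            n_clusters=k_eff,
            init="k-means++",
            n_init=cfg.kmeans_restarts,
            tol=1e-6,
            random_state=cfg.kmeans_seed,
        ).fit(X)
        centers, labels = km.cluster_centers_, km.labels_
    rows, refs = [], []
    for c in range(k_eff):
        members = np.flatnonzero(labels == c)
        d = np.linalg.norm(X[members] - centers[c], axis=1)
        best = members[int(np.argmin(d))]  # argmin takes the lowest index on ties
        rows.append(best)
        refs.append(features.patch_refs[best])
    return RepresentativeSet(features.slide_id, X[rows], refs)


def _metric_value(u: np.ndarray, v: np.ndarray, metric: Metric, who: str) -> float:
    if metric == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            raise ValueError(f"zero-norm feature vector in {who}; cosine undefined")
        return float(u @ v / (nu * nv))
    if metric == "neg_L1":
        return float(-np.abs(u - v).sum())
    return float(-np.linalg.norm(u - v))


def pair_count(a: RepresentativeSet, b: RepresentativeSet) -> int:
    """Number of pairwise comparisons behind one similarity value (k_a * k_b)."""
    return len(a) * len(b)


def pairwise_mean_similarity(
    a: RepresentativeSet, b: RepresentativeSet, metric: Metric = "cosine"
) -> float:
    """Mean of metric(u, v) over the full |a| x |b| grid of representative pairs."""
    vals = [
        _metric_value(u, v, metric, f"{a.slide_id} vs {b.slide_id}")
        for u in a.vectors
        for v in b.vectors
    ]
    return float(np.mean(vals))


def build_similarity_matrix(
    annotated: Sequence[RepresentativeSet],
    queries: Sequence[RepresentativeSet],
    metric: Metric = "cosine",
) -> SimilarityMatrix:
    if not annotated or not queries:
        raise ValueError("annotated and query lists must be non-empty")
    a_ids = [r.slide_id for r in annotated]
    q_ids = [r.slide_id for r in queries]
    if len(set(a_ids)) != len(a_ids) or len(set(q_ids)) != len(q_ids):
        raise ValueError("duplicate slide ids")
    values = np.array(
        [[pairwise_mean_similarity(q, a, metric) for a in annotated] for q in queries]
    )
    return SimilarityMatrix(a_ids, q_ids, values, metric)


def match_expert(matrix: SimilarityMatrix, query_id: str) -> str:
    """Annotated slide with the highest similarity to the query; ties broken
    by lexicographically smallest annotated id."""
    row = matrix.row(query_id)
    best = max(row.values())
    return min(aid for aid, v in row.items() if v == best)


def matching_table(matrix: SimilarityMatrix) -> pd.DataFrame:
    """Per-query matched expert and similarity, as a DataFrame (CSV-exportable)."""
    rows = []
    for q in matrix.query_ids:
        m = match_expert(matrix, q)
        rows.append({"query_id": q, "matched_id": m, "similarity": matrix.row(q)[m]})
    return pd.DataFrame(rows)


class ExpertMatcher(BaseEstimator):
    """Nearest-annotated-slide matcher over representative sets.

    sklearn-style: ``fit`` ingests the annotated slides' representative sets,
    ``predict`` returns the matched annotated slide id per query set.
    """

    def __init__(self, metric: Metric = "cosine"):
        self.metric = metric

    def fit(self, annotated: Sequence[RepresentativeSet], y=None) -> "ExpertMatcher":
        if not annotated:
            raise ValueError("need at least one annotated representative set")
        ids = [r.slide_id for r in annotated]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate slide ids")
        self.annotated_ = list(annotated)
        self.annotated_ids_ = ids
        return self

    def transform(self, queries: Sequence[RepresentativeSet]) -> SimilarityMatrix:
        return build_similarity_matrix(self.annotated_, queries, self.metric)

    def predict(self, queries: Sequence[RepresentativeSet]) -> list[str]:
        matrix = self.transform(queries)
        return [match_expert(matrix, q) for q in matrix.query_ids]
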