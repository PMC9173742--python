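"""Ensemble low-dimensional embedding and clustering of input-region profiles.

A single nonlinear embedding of z-scored fractional counts is stochastic
(seed-dependent), so region relationships are summarized over an ensemble:
each of ``n_embeddings`` seeded UMAP runs yields a 2-D point set, pairwise
Euclidean distances are normalized by the maximum distance within that
embedding, and the matrices are averaged element-wise.  Hierarchical
clustering on the aggregated matrix then groups regions with similar
patterns of variation across brains.  A nearest-neighbor mixing score with a
permutation null formalizes the visual "datasets mix vs segregate" judgment
when comparing two cohorts.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .catalog import RegionCatalog
from .quantify import FractionMatrix, fraction_matrix
from .synthetic import Cohort

__all__ = [
    "ZScoreMatrix",
    "AggregatedDistanceMatrix",
    "ClusterAssignment",
    "zscore_regions",
    "embed_ensemble",
    "normalized_pairwise_distance",
    "aggregate_distances",
    "cluster_regions",
    "mixing_score",
    "compare_datasets",
    "DATASET_COMPARISON_SUBSETS",
]


@dataclass
class ZScoreMatrix:
    """Regions x brains matrix of standardized fractional counts.

    Each row (region) has sample mean 0 and sample SD 1 across brains unless
    the region's counts were constant, in which case the row is all zeros and
    listed in ``constant_regions``.
    """

    values: pd.DataFrame  # index = regions, columns = brain ids
    constant_regions: list[str] = field(default_factory=list)

    @property
    def region_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def brain_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class AggregatedDistanceMatrix:
    """Regions x regions mean of max-normalized pairwise embedding distances."""

    values: pd.DataFrame
    n_embeddings: int
    seeds: list[int]

    def validate(self) -> None:
        a = self.values.to_numpy()
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("aggregated distance matrix must be symmetric")
        if not np.allclose(np.diag(a), 0.0):
            raise ValueError("aggregated distance matrix must have zero diagonal")
        if a.min() < -1e-12 or a.max() > 1.0 + 1e-12:
            raise ValueError("aggregated distances must lie in [0, 1]")


@dataclass
class ClusterAssignment:
    labels: pd.Series  # index = regions, values = cluster ids
    k: int
    linkage: str
    silhouette: float


def zscore_regions(fractions: FractionMatrix) -> ZScoreMatrix:
    """Standardize each region's fractional counts across brains (sample SD).

    The fraction matrix is transposed so regions become the points to embed.
    Constant regions cannot be standardized; their rows are set to zero and a
    warning is emitted.
    """
    values = fractions.values
    if values.shape[0] < 2:
        raise ValueError("z-scoring requires at least two brains")
    z = values.T.copy().astype(float)
    means = z.mean(axis=1)
    sds = z.std(axis=1, ddof=1)
    constant = sds[sds == 0.0].index.tolist()
    if constant:
        warnings.warn(
            f"{len(constant)} region(s) constant across brains; z-rows set to 0",
            stacklevel=2,
        )
    safe = sds.replace(0.0, 1.0)
    z = z.sub(means, axis=0).div(safe, axis=0)
    z.loc[constant] = 0.0
    return ZScoreMatrix(values=z, constant_regions=constant)


def embed_ensemble(
    data: np.ndarray | pd.DataFrame,
    n_embeddings: int = 20,
    n_neighbors: int = 10,
    min_dist: float = 0.1,
    metric: str = "euclidean",
    seeds: Optional[Sequence[int]] = None,
) -> list[np.ndarray]:
    """One seeded 2-D UMAP embedding of the rows of ``data`` per seed.

    Seeds default to ``0..n_embeddings-1`` and must be distinct so the
    ensemble actually samples embedding variability.
    """
    import umap  # deferred: numba compilation is slow to import

    X = np.asarray(data, dtype=float)
    if seeds is None:
        seeds = list(range(n_embeddings))
    seeds = [int(s) for s in seeds]
    if len(seeds) != n_embeddings:
        raise ValueError("need exactly one seed per embedding")
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    if n_embeddings < 1:
        raise ValueError("n_embeddings must be >= 1")
    if X.shape[0] <= n_neighbors:
        raise ValueError(
            f"n_neighbors={n_neighbors} must be smaller than the "
            f"number of points ({X.shape[0]})"
        )
    out = []
    for seed in seeds:
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric=metric,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.append(np.asarray(reducer.fit_transform(X), dtype=float))
    return out


def normalized_pairwise_distance(points: np.ndarray) -> np.ndarray:
    """Euclidean distances divided by the maximum pairwise distance.

    The largest entry is exactly 1 and the diagonal is 0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least two points")
    d = pdist(pts)
    dmax = d.max()
    if dmax == 0.0:
        raise ValueError("all points coincide; normalization undefined")
    return squareform(d / dmax)


def aggregate_distances(
    matrices: Sequence[np.ndarray],
    region_names: Optional[Sequence[str]] = None,
    seeds: Optional[Sequence[int]] = None,
) -> AggregatedDistanceMatrix:
    """Element-wise mean of normalized distance matrices across the ensemble."""
    mats = [np.asarray(m, dtype=float) for m in matrices]
    if not mats:
        raise ValueError("no matrices to aggregate")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("distance matrices must share shape and ordering")
    mean = np.mean(mats, axis=0)
    if region_names is None:
        region_names = [str(i) for i in range(shape[0])]
    values = pd.DataFrame(mean, index=list(region_names), columns=list(region_names))
    agg = AggregatedDistanceMatrix(
        values=values,
        n_embeddings=len(mats),
        seeds=list(seeds) if seeds is not None else list(range(len(mats))),
    )
    agg.validate()
    return agg


def cluster_regions(
    agg: AggregatedDistanceMatrix,
    k: Optional[int] = None,
    linkage: str = "average",
    k_range: Sequence[int] = range(2, 7),
) -> ClusterAssignment:
    """Agglomerative clustering on the aggregated distance matrix.

    With ``k=None`` the cluster count is chosen from ``k_range`` by maximum
    mean silhouette on the aggregated distances.
    """
    agg.validate()
    D = agg.values.to_numpy()
    n = D.shape[0]
    names = agg.values.index

    def fit(k_):
        model = AgglomerativeClustering(
            n_clusters=k_, metric="precomputed", linkage=linkage
        )
        return model.fit_predict(D)

    if k is not None:
        if not 1 <= k <= n:
            raise ValueError("k must be between 1 and the number of regions")
        if k == 1:
            labels = np.zeros(n, dtype=int)
            sil = np.nan
        else:
            labels = fit(k)
            sil = float(silhouette_score(D, labels, metric="precomputed"))
        return ClusterAssignment(
            labels=pd.Series(labels, index=names), k=k, linkage=linkage,
            silhouette=sil,
        )
    best = None
    for k_ in k_range:
        if k_ >= n:
            continue
        labels = fit(k_)
        sil = float(silhouette_score(D, labels, metric="precomputed"))
        if best is None or sil > best[0]:
            best = (sil, k_, labels)
    if best is None:
        raise ValueError("no feasible k in k_range")
    sil, k_, labels = best
    return ClusterAssignment(
        labels=pd.Series(labels, index=names), k=k_, linkage=linkage,
        silhouette=sil,
    )


def mixing_score(points: np.ndarray, labels: Sequence,
                 k_nn: int = 5) -> tuple[float, float]:
    """Mean same-dataset fraction among each point's k nearest neighbors.

    Returns ``(score, chance)`` where ``chance`` is the expected same-label
    fraction under random mixing.  The score approaches ``chance`` when the
    two datasets are interchangeable and 1 when they segregate.
    """
    pts = np.asarray(points, dtype=float)
    lab = np.asarray(labels)
    uniq, counts = np.unique(lab, return_counts=True)
    if len(uniq) != 2:
        raise ValueError("mixing score requires exactly two dataset labels")
    if (counts < k_nn + 1).any():
        raise ValueError("each dataset needs more than k_nn points")
    nn = NearestNeighbors(n_neighbors=k_nn + 1).fit(pts)
    _, idx = nn.kneighbors(pts)
    neighbor_labels = lab[idx[:, 1:]]  # drop self
    same = (neighbor_labels == lab[:, None]).mean()
    n = len(lab)
    chance = float(sum(c / n * (c - 1) / (n - 1) for c in counts))
    return float(same), chance


DATASET_COMPARISON_SUBSETS = ("excluded", "questionable", "long_range")


def _subset_regions(catalog: RegionCatalog, subset: str) -> list[str]:
    """Region groups for cross-dataset comparison.

    ``excluded``: sites dropped by earlier whole-brain studies (the VTA
    subnuclei plus SNc, SNr, RPC, IPN); ``questionable``: the remaining local
    midbrain/hindbrain sites; ``long_range``: sites quantified by both.
    """
    excluded = {r.name for r in catalog.vta_subnuclei()} | {
        "SNc", "SNr", "RPC", "IPN"
    }
    if subset == "excluded":
        return [r.name for r in catalog if r.name in excluded]
    if subset == "questionable":
        return [r.name for r in catalog.local() if r.name not in excluded]
    if subset == "long_range":
        return [r.name for r in catalog.long_range()]
    raise ValueError(f"unknown subset {subset!r}")


def compare_datasets(
    cohort_a: Cohort,
    cohort_b: Cohort,
    catalog: RegionCatalog,
    subset: str = "long_range",
    n_embeddings: int = 20,
    k_nn: int = 5,
    n_permutations: int = 200,
    seed: int = 0,
    n_neighbors: Optional[int] = None,
) -> dict:
    """Mixing report for two cohorts over a region subset.

    Brains are the points: fractional counts are restricted to the subset
    regions and renormalized, jointly z-scored per region, embedded as an
    ensemble, and scored with the nearest-neighbor mixing statistic.  The
    permutation p-value is the probability of a mixing score at least as
    large under shuffled cohort labels.
    """
    regions = _subset_regions(catalog, subset)
    if not regions:
        raise ValueError(f"subset {subset!r} selects no regions")
    # brain ids may collide across cohorts; relabel for the joint matrix
    relabeled = [
        dataclasses.replace(b, brain_id=f"{tag}:{b.brain_id}")
        for tag, cohort in (("a", cohort_a), ("b", cohort_b))
        for b in cohort
    ]
    joint = Cohort(brains=relabeled)
    fm = fraction_matrix(joint, catalog)
    sub = fm.values[regions]
    sub = sub.div(sub.sum(axis=1), axis=0)  # renormalize within subset
    z = zscore_regions(FractionMatrix(values=sub, denominator="all_inputs"))
    X = z.values.to_numpy().T  # brains x regions
    labels = np.array(
        ["a"] * len(cohort_a.brains) + ["b"] * len(cohort_b.brains)
    )
    if n_neighbors is None:
        n_neighbors = min(10, X.shape[0] - 1)
    embeddings = embed_ensemble(
        X, n_embeddings=n_embeddings, n_neighbors=n_neighbors,
        seeds=[seed * 1000 + i for i in range(n_embeddings)],
    )
    scores, chances = zip(
        *(mixing_score(pts, labels, k_nn=k_nn) for pts in embeddings)
    )
    observed = float(np.mean(scores))
    chance = float(np.mean(chances))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(labels)
        null[i] = np.mean(
            [mixing_score(pts, perm, k_nn=k_nn)[0] for pts in embeddings]
        )
    p_value = float((1 + (null >= observed - 1e-12).sum()) / (1 + n_permutations))
    return {
        "subset": subset,
        "regions": regions,
        "mixing_score": observed,
        "chance": chance,
        "permutation_p": p_value,
        "n_permutations": n_permutations,
        "n_embeddings": n_embeddings,
        "k_nn": k_nn,
    }
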