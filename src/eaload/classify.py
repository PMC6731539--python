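"""Classify bursts by spike load with a self-organizing map (SOM).

Bursts with >= 5 spikes are described by three weighted features —
log(number of spikes) x 2, log(median inter-spike interval) x 2, and the
SD of inter-spike intervals x 1 — z-scored across the training set before
weighting. A batch-trained SOM maps the feature space onto a hexagonal
grid of prototype nodes. The node combining the highest spike count with
the lowest median ISI (H*) anchors a spike-load index in [0, 1]
(1 = H*, 0 = the farthest node). Ward clustering of the node prototypes
with the Thorndike elbow criterion yields burst categories (canonically
three: low-, medium-, high-load). Every burst inherits the category and
load index of its best-matching node; bursts with < 5 spikes are assigned
to the low-load category without an index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .bursts import Burst

FEATURE_WEIGHTS = np.array([2.0, 2.0, 1.0])
MIN_SPIKES_FOR_SOM = 5

CATEGORIES = ("low-load", "medium-load", "high-load")


@dataclass(frozen=True)
class FeatureParams:
    """z-score parameters (per-feature mean/SD over the training set)."""

    mean: np.ndarray
    sd: np.ndarray
    weights: np.ndarray = field(default_factory=lambda: FEATURE_WEIGHTS.copy())


def raw_features(burst: Burst) -> np.ndarray:
    """[log n_spikes, log median ISI, sample SD of ISIs] for one burst."""
    if burst.n_spikes < MIN_SPIKES_FOR_SOM:
        raise ValueError(
            f"features are defined for bursts with >= {MIN_SPIKES_FOR_SOM} "
            f"spikes, got {burst.n_spikes}"
        )
    isis = burst.isis
    return np.array([
        np.log(burst.n_spikes),
        np.log(np.median(isis)),
        isis.std(ddof=1),
    ])


def extract_features(
    bursts: Sequence[Burst],
) -> tuple[np.ndarray, FeatureParams]:
    """Weighted z-scored feature matrix for the SOM training set.

    z-scores are computed across the pooled training bursts first, then
    the weights (2, 2, 1) are applied — weighting before z-scoring would
    cancel out.
    """
    raw = np.array([raw_features(b) for b in bursts])
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("degenerate training set: a feature has zero variance")
    params = FeatureParams(mean=mean, sd=sd)
    return (raw - mean) / sd * params.weights, params


def transform_features(bursts: Sequence[Burst], params: FeatureParams) -> np.ndarray:
    raw = np.array([raw_features(b) for b in bursts])
    return (raw - params.mean) / params.sd * params.weights


# ---------------------------------------------------------------------------
# batch SOM
# ---------------------------------------------------------------------------

def hex_positions(rows: int, cols: int) -> np.ndarray:
    """Planar coordinates of a hexagonal grid (odd rows shifted by 1/2)."""
    pos = np.empty((rows * cols, 2))
    for r in range(rows):
        for c in range(cols):
            pos[r * cols + c] = (c + 0.5 * (r % 2), r * np.sqrt(3) / 2)
    return pos


@dataclass
class SomModel:
    """Trained SOM with load index and categories attached to its nodes."""

    rows: int
    cols: int
    prototypes: np.ndarray            # (rows*cols, n_features)
    params: FeatureParams
    seed: int
    qe_trace: list[float] = field(default_factory=list)
    hstar_node: int | None = None
    load_index: np.ndarray | None = None   # per node, in [0, 1]
    node_category: np.ndarray | None = None  # per node, strings
    n_categories: int | None = None
    linkage_matrix: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def bmu(self, features: np.ndarray) -> np.ndarray:
        """Best-matching node per feature vector (smallest Euclidean
        prototype distance; ties break to the lowest node index)."""
        d = cdist(np.atleast_2d(features), self.prototypes)
        return d.argmin(axis=1)

    # -- serialization (JSON keeps float64 round-trip exact) ---------------
    def to_json(self) -> str:
        payload = {
            "rows": self.rows,
            "cols": self.cols,
            "prototypes": self.prototypes.tolist(),
            "mean": self.params.mean.tolist(),
            "sd": self.params.sd.tolist(),
            "weights": self.params.weights.tolist(),
            "seed": self.seed,
            "qe_trace": self.qe_trace,
            "hstar_node": self.hstar_node,
            "load_index": None if self.load_index is None else self.load_index.tolist(),
            "node_category": None if self.node_category is None else list(self.node_category),
            "n_categories": self.n_categories,
            "linkage_matrix": None if self.linkage_matrix is None else self.linkage_matrix.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SomModel":
        d = json.loads(text)
        return cls(
            rows=d["rows"],
            cols=d["cols"],
            prototypes=np.asarray(d["prototypes"], dtype=float),
            params=FeatureParams(
                mean=np.asarray(d["mean"], dtype=float),
                sd=np.asarray(d["sd"], dtype=float),
                weights=np.asarray(d["weights"], dtype=float),
            ),
            seed=d["seed"],
            qe_trace=list(d["qe_trace"]),
            hstar_node=d["hstar_node"],
            load_index=None if d["load_index"] is None else np.asarray(d["load_index"]),
            node_category=None if d["node_category"] is None else np.asarray(d["node_category"]),
            n_categories=d["n_categories"],
            linkage_matrix=None if d["linkage_matrix"] is None
            else np.asarray(d["linkage_matrix"], dtype=float),
        )


def _linear_init(x: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Lay prototypes on the plane of the first two principal components,
    scaled by the component SDs (deterministic batch-SOM initialization)."""
    mean = x.mean(axis=0)
    centered = x - mean
    # grid coordinates normalized to [-1, 1] per axis
    g = pos - pos.mean(axis=0)
    span = g.max(axis=0) - g.min(axis=0)
    span[span == 0] = 1.0
    g = 2.0 * g / span
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    protos = np.tile(mean, (pos.shape[0], 1))
    n = max(x.shape[0] - 1, 1)
    for axis in range(min(2, vt.shape[0])):
        sd = s[axis] / np.sqrt(n)
        protos += np.outer(g[:, axis], sd * vt[axis])
    return protos


def train_som(
    features: np.ndarray,
    rows: int = 12,
    cols: int = 8,
    epochs: int = 30,
    seed: int = 0,
    params: FeatureParams | None = None,
) -> SomModel:
    """Batch-train a SOM on (already weighted, z-scored) feature vectors.

    Each epoch assigns every vector to its best-matching node and replaces
    every prototype by the neighborhood-weighted mean of the data, with a
    Gaussian neighborhood whose radius shrinks linearly from half the grid
    diagonal to 0.5. Prototypes are linearly initialized on the plane of
    the first two principal components (the standard batch-SOM
    initialization), so training is deterministic; ``seed`` is recorded
    for provenance and used only if stochastic extensions are enabled.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.size == 0:
        raise ValueError("empty feature table")
    n_nodes = rows * cols
    if x.shape[0] < n_nodes:
        warnings.warn(
            f"fewer training vectors ({x.shape[0]}) than nodes ({n_nodes}); "
            "the map will be underdetermined"
        )
    pos = hex_positions(rows, cols)
    prototypes = _linear_init(x, pos)
    grid_d2 = cdist(pos, pos) ** 2
    sigma0 = max(np.sqrt(grid_d2.max()) / 2.0, 0.5)

    model = SomModel(
        rows=rows, cols=cols, prototypes=prototypes,
        params=params if params is not None
        else FeatureParams(mean=np.zeros(x.shape[1]), sd=np.ones(x.shape[1])),
        seed=seed,
    )
    for epoch in range(epochs):
        d = cdist(x, prototypes)
        bmus = d.argmin(axis=1)
        model.qe_trace.append(float(d[np.arange(x.shape[0]), bmus].mean()))
        sigma = sigma0 + (0.5 - sigma0) * epoch / max(epochs - 1, 1)
        h = np.exp(-grid_d2 / (2.0 * sigma**2))  # (node, node)
        # per-node data sums, then neighborhood-smoothed batch update
        sums = np.zeros_like(prototypes)
        np.add.at(sums, bmus, x)
        counts = np.bincount(bmus, minlength=n_nodes).astype(float)
        num = h @ sums
        den = h @ counts
        nz = den > 0
        prototypes[nz] = num[nz] / den[nz, None]
    model.prototypes = prototypes
    return model


# ---------------------------------------------------------------------------
# load index, categories
# ---------------------------------------------------------------------------

def identify_hstar(model: SomModel) -> int:
    """Node representing the highest spike count and lowest median ISI.

    Chosen as the prototype maximizing (weighted-z log n_spikes) minus
    (weighted-z log median ISI)."""
    return int(np.argmax(model.prototypes[:, 0] - model.prototypes[:, 1]))


def compute_load_index(model: SomModel) -> np.ndarray:
    """Spike-load index per node: 1 - d/d_max of the distance to H*.

    H* scores exactly 1; the farthest node scores exactly 0.
    """
    hstar = identify_hstar(model)
    d = np.linalg.norm(model.prototypes - model.prototypes[hstar], axis=1)
    dmax = d.max()
    model.hstar_node = hstar
    model.load_index = 1.0 - d / dmax if dmax > 0 else np.ones_like(d)
    return model.load_index


def thorndike_k(
    heights: np.ndarray, k_max: int | None = None, flat_fraction: float = 0.2
) -> int:
    """Elbow of the last-merge distance vs number-of-categories curve.

    ``heights[k-1]`` is the distance of the last merge performed when
    stopping at k categories (decreasing in k). The elbow is read as the
    smallest k from which the curve stays flat: every further drop
    (from j to j+1 categories, j >= k) is below ``flat_fraction`` of the
    largest drop. Returns 1 for a curve that is flat from the start.
    """
    n = heights.size
    if n < 2 or heights[0] == 0:
        return 1
    k_max = n if k_max is None else min(k_max, n)
    drops = -np.diff(heights)  # drops[k-1] = drop from k to k+1 categories
    biggest = drops.max()
    if biggest <= 0:
        return 1
    for k in range(2, k_max):
        if np.all(drops[k - 1:] <= flat_fraction * biggest):
            return k
    return k_max


def cluster_nodes(model: SomModel, k: int | None = None) -> SomModel:
    """Ward-cluster the node prototypes into load categories.

    The number of categories defaults to the Thorndike elbow of the
    dendrogram (``k`` overrides it). Categories are labeled by the mean
    spike-load index of their nodes: the highest-index group is
    "high-load", the lowest "low-load", anything between "medium-load".
    """
    if model.load_index is None:
        compute_load_index(model)
    z = linkage(model.prototypes, method="ward")
    model.linkage_matrix = z
    n = model.n_nodes
    # heights[k-1] = distance of the merge that reduced k+1 -> k clusters,
    # i.e. the last merge performed when stopping at k categories
    heights = np.array([z[n - 1 - k, 2] for k in range(1, n)])
    if k is None:
        if np.allclose(z[:, 2], 0):
            warnings.warn("all node prototypes identical; using one category")
            k = 1
        else:
            k = thorndike_k(heights)
    if k > n:
        raise ValueError(f"requested {k} categories for {n} nodes")
    assignments = fcluster(z, t=k, criterion="maxclust")
    mean_load = np.array([
        model.load_index[assignments == c].mean() for c in range(1, k + 1)
    ])
    order = np.argsort(mean_load)  # ascending load
    labels = np.empty(k, dtype=object)
    for rank, c in enumerate(order):
        if rank == 0:
            labels[c] = "low-load"
        elif rank == k - 1:
            labels[c] = "high-load"
        else:
            labels[c] = "medium-load"
    if k == 1:
        labels[0] = "low-load"
    model.node_category = np.array([labels[a - 1] for a in assignments], dtype=object)
    model.n_categories = k
    return model


# ---------------------------------------------------------------------------
# re-mapping to bursts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifiedBurst:
    """A burst with its load category (and, if SOM-classified, index/node)."""

    burst: Burst
    category: str
    load_index: float | None = None
    node: int | None = None


def assign_bursts(model: SomModel, bursts: Sequence[Burst]) -> list[ClassifiedBurst]:
    """Map every burst to a category.

    Bursts with >= 5 spikes inherit category and spike-load index from
    their best-matching node; smaller bursts go to the low-load category
    with no index (their feature variability is too high to place on the
    map, and their rates track low-load rates).
    """
    if model.node_category is None or model.load_index is None:
        raise ValueError("model must be clustered before assignment")
    out: list[ClassifiedBurst] = []
    big = [b for b in bursts if b.n_spikes >= MIN_SPIKES_FOR_SOM]
    nodes = model.bmu(transform_features(big, model.params)) if big else np.array([], int)
    it = iter(nodes)
    for b in bursts:
        if b.n_spikes < MIN_SPIKES_FOR_SOM:
            out.append(ClassifiedBurst(burst=b, category="low-load"))
        else:
            node = int(next(it))
            out.append(ClassifiedBurst(
                burst=b,
                category=str(model.node_category[node]),
                load_index=float(model.load_index[node]),
                node=node,
            ))
    return out
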