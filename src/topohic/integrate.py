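"""Multi-view sample-similarity integration.

Feature matrices (samples x genomic positions) are filtered, converted to
distances (squared Euclidean for continuous views, Jaccard for binary call
views), turned into adaptive-bandwidth Gaussian affinities, fused by
cross-network diffusion, and clustered. Consensus NMF and a feature-network
concordance computation provide the quantitative clustering surfaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .errors import ValidationError

__all__ = [
    "FusionConfig",
    "FusedNetwork",
    "filter_features",
    "distance_continuous",
    "distance_binary",
    "affinity",
    "snf_fuse",
    "fused_distance",
    "embed_2d",
    "spectral_cluster",
    "nmi",
    "concordance_network",
    "nmf_consensus",
]


@dataclass
class FusionConfig:
    K: int = 20                # affinity / sparse-kernel neighbors
    sigma: float = 0.3         # kernel width multiplier
    T: int = 16                # diffusion iterations
    C: int = 2                 # clusters for the concordance computation
    variance_keep: float = 0.40
    max_missing: float = 0.05

    def __post_init__(self):
        if self.T < 1:
            raise ValidationError("T must be >= 1")
        if not 0 < self.variance_keep <= 1:
            raise ValidationError("variance_keep must lie in (0, 1]")

    def clamped_k(self, n_samples: int) -> int:
        """K must stay below n; small test cohorts clamp to n - 2 with a warning."""
        if self.K < n_samples:
            return self.K
        k = max(1, n_samples - 2)
        warnings.warn(
            f"K={self.K} >= n_samples={n_samples}; clamping to {k}", stacklevel=2)
        return k


@dataclass
class FusedNetwork:
    fused: np.ndarray                       # P-bar
    per_view_affinity: list[np.ndarray]     # W_v
    per_view_full_kernel: list[np.ndarray]  # P_v at input
    per_view_sparse_kernel: list[np.ndarray]


def filter_features(matrix: np.ndarray, config: FusionConfig) -> np.ndarray:
    """Drop columns with >= max_missing missing samples, keep the top
    variance_keep fraction by variance (ties at the cutoff kept), then
    mean-impute what is left."""
    matrix = np.asarray(matrix, dtype=float)
    n_samples = matrix.shape[0]
    missing_frac = np.mean(np.isnan(matrix), axis=0)
    cols = np.flatnonzero(missing_frac < config.max_missing)
    if cols.size == 0:
        raise ValidationError("no columns survive the missingness filter")
    sub = matrix[:, cols]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        variances = np.nanvar(sub, axis=0)
    n_keep = int(np.floor(config.variance_keep * cols.size))
    if n_keep == 0:
        raise ValidationError("variance filter would drop every column")
    cutoff = np.sort(variances)[::-1][n_keep - 1]
    keep = variances >= cutoff  # ties at the cutoff kept
    sub = sub[:, keep]
    # column-mean imputation of remaining missing values
    col_means = np.nanmean(sub, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(sub))
    sub = sub.copy()
    sub[nan_r, nan_c] = col_means[nan_c]
    if np.isnan(sub).any():
        raise ValidationError("columns with all values missing survived filtering")
    return sub


def distance_continuous(matrix: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance between sample rows."""
    x = np.asarray(matrix, dtype=float)
    sq = np.sum(x ** 2, axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * x @ x.T
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def distance_binary(matrix: np.ndarray) -> np.ndarray:
    """Jaccard distance between binary call vectors; two empty sets -> 0."""
    x = np.asarray(matrix)
    if not np.isin(x, (0, 1)).all():
        raise ValidationError("binary feature matrix may contain only 0/1")
    inter = (x @ x.T).astype(float)
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return d


def affinity(distances: np.ndarray, config: FusionConfig) -> np.ndarray:
    """Adaptive Gaussian-density kernel affinity.

    eps_st = (mu_s + mu_t + D_st) / 3 with mu the mean distance to the K
    nearest neighbors; W_st = normal density of D_st at scale sigma * eps_st.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    k = config.clamped_k(n)
    if k >= n:
        raise ValidationError("K must be smaller than the number of samples")
    off = d + np.diag(np.full(n, np.inf))
    knn = np.sort(off, axis=1)[:, :k]
    mu = knn.mean(axis=1)
    eps = (mu[:, None] + mu[None, :] + d) / 3.0
    if np.any(eps == 0):
        raise ValidationError("degenerate distances: zero kernel bandwidth")
    scale = config.sigma * eps
    w = np.exp(-d ** 2 / (2.0 * scale ** 2)) / (scale * np.sqrt(2.0 * np.pi))
    return (w + w.T) / 2.0


def _full_kernel(w: np.ndarray) -> np.ndarray:
    """Row-normalized kernel: off-diagonal mass 1/2, diagonal 1/2."""
    p = np.array(w, dtype=float)
    np.fill_diagonal(p, 0.0)
    rows = p.sum(axis=1)
    rows[rows == 0] = 1.0
    p = p / (2.0 * rows[:, None])
    np.fill_diagonal(p, 0.5)
    return p


def _sparse_kernel(w: np.ndarray, k: int) -> np.ndarray:
    s = np.zeros_like(w, dtype=float)
    n = w.shape[0]
    off = np.array(w, dtype=float)
    np.fill_diagonal(off, -np.inf)
    for i in range(n):
        nn = np.argpartition(off[i], -k)[-k:]
        total = w[i, nn].sum()
        if total > 0:
            s[i, nn] = w[i, nn] / total
    return s


def snf_fuse(affinities: list[np.ndarray], config: FusionConfig) -> FusedNetwork:
    """Similarity-network fusion by iterated cross-diffusion."""
    if not affinities:
        raise ValidationError("need at least one affinity matrix")
    n = affinities[0].shape[0]
    for w in affinities:
        if w.shape != (n, n):
            raise ValidationError("affinity matrices must share one sample set")
    k = config.clamped_k(n)
    full = [_full_kernel(w) for w in affinities]
    sparse = [_sparse_kernel(w, k) for w in affinities]
    m = len(affinities)
    if m == 1:
        return FusedNetwork(full[0], list(affinities), full, sparse)
    p = [f.copy() for f in full]
    for _ in range(config.T):
        nxt = []
        for v in range(m):
            others = sum(p[u] for u in range(m) if u != v) / (m - 1)
            q = sparse[v] @ others @ sparse[v].T
            q = (q + q.T) / 2.0
            nxt.append(_full_kernel(q))
        p = nxt
    fused = sum(p) / m
    fused = _full_kernel((fused + fused.T) / 2.0)
    return FusedNetwork(fused, list(affinities), full, sparse)


def fused_distance(fused: np.ndarray) -> np.ndarray:
    """distance = 0.5 - similarity off the diagonal; 0 on it.

    The row-normalized kernel is symmetrized first so the distance matrix is
    exactly symmetric.
    """
    p = np.asarray(fused, dtype=float)
    d = 0.5 - (p + p.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 0.5)


def embed_2d(distances: np.ndarray, seed: int = 0,
             n_neighbors: int | None = None) -> np.ndarray:
    """2-D neighborhood-preserving embedding of a precomputed distance matrix.

    Backed by UMAP when available, else classical MDS; the embedding is a
    visualization surface only -- quantitative results use distances directly.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n == 1:
        return np.zeros((1, 2))
    try:
        import umap  # deferred: heavy import, optional backend

        nn = min(n - 1, 15 if n_neighbors is None else n_neighbors)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = umap.UMAP(n_components=2, metric="precomputed",
                              n_neighbors=nn, random_state=seed)
            return np.asarray(model.fit_transform(d))
    except ImportError:
        from sklearn.manifold import MDS

        model = MDS(n_components=2, dissimilarity="precomputed",
                    random_state=seed, normalized_stress="auto")
        return np.asarray(model.fit_transform(d))


def spectral_cluster(w: np.ndarray, c: int, seed: int = 0) -> np.ndarray:
    """Normalized-cut spectral clustering of a symmetric affinity matrix."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if c > n:
        raise ValidationError("more clusters than samples")
    deg = w.sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    sym = d_inv_sqrt[:, None] * w * d_inv_sqrt[None, :]
    evals, evecs = np.linalg.eigh((sym + sym.T) / 2.0)
    n_comp = int(np.sum(evals > 1.0 - 1e-9))
    if n_comp > c:
        warnings.warn(f"affinity graph has ~{n_comp} components for C={c}",
                      stacklevel=2)
    u = evecs[:, -c:]
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    u = u / norms
    km = KMeans(n_clusters=c, random_state=seed, n_init=20)
    return km.fit_predict(u)


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information I(a;b)/sqrt(H(a) H(b)) in [0, 1]."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size:
        raise ValidationError("label vectors must have equal length")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    ha = -np.sum(pa[pa > 0] * np.log(pa[pa > 0]))
    hb = -np.sum(pb[pb > 0] * np.log(pb[pb > 0]))
    if ha == 0 and hb == 0:
        return 1.0
    if ha == 0 or hb == 0:
        return 0.0
    nz = joint > 0
    mi = np.sum(joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz]))
    return float(max(0.0, min(1.0, mi / np.sqrt(ha * hb))))


def concordance_network(view_affinities: dict[str, np.ndarray],
                        fused: np.ndarray, config: FusionConfig,
                        seed: int = 0) -> tuple[dict, dict]:
    """NMI concordance of each network's C-way clustering with every other.

    Returns (concordance, distance) keyed by frozenset pairs plus per-network
    labels under key "_labels"; distance = 1 - concordance.
    """
    networks = dict(view_affinities)
    networks["fused"] = fused
    if len(networks) < 2:
        raise ValidationError("need at least two networks")
    labels = {name: spectral_cluster(w, config.C, seed=seed)
              for name, w in networks.items()}
    names = list(networks)
    conc, dist = {}, {}
    for i, u in enumerate(names):
        for v in names[i:]:
            value = nmi(labels[u], labels[v])
            conc[(u, v)] = conc[(v, u)] = value
            dist[(u, v)] = dist[(v, u)] = 1.0 - value
    conc["_labels"] = labels
    return conc, dist


def _nmf_once(v: np.ndarray, k: int, rng: np.random.Generator,
              n_iter: int = 500, floor: float = 1e-9) -> np.ndarray:
    """One multiplicative-update Frobenius NMF of v (features x samples);
    returns per-sample labels = argmax over the k rows of H."""
    f, n = v.shape
    scale = np.sqrt(v.mean() / k) if v.mean() > 0 else 1.0
    w = rng.uniform(floor, 1.0, size=(f, k)) * scale
    h = rng.uniform(floor, 1.0, size=(k, n)) * scale
    for _ in range(n_iter):
        h *= (w.T @ v) / np.maximum(w.T @ w @ h, floor)
        h = np.maximum(h, floor)
        w *= (v @ h.T) / np.maximum(w @ (h @ h.T), floor)
        w = np.maximum(w, floor)
    return np.argmax(h, axis=0)


def nmf_consensus(matrix: np.ndarray, k: int = 3, n_runs: int = 30,
                  seed: int = 0, n_iter: int = 500) -> dict:
    """Consensus NMF clustering of a samples x features matrix.

    The matrix is shifted non-negative by its global minimum; each run's
    sample labels come from argmax of H; the co-clustering fraction matrix is
    cut by average-linkage hierarchical clustering at k, and silhouettes are
    computed on (1 - consensus).
    """
    from sklearn.metrics import silhouette_samples

    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    if k > n:
        raise ValidationError("k exceeds the number of samples")
    v = (x - np.nanmin(x)).T  # features x samples, non-negative
    if np.isnan(v).any():
        raise ValidationError("NMF input contains missing values; filter first")
    if (v < 0).any():
        raise ValidationError("negative entries after non-negative shift")
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    consensus = np.zeros((n, n))
    for ss in seeds:
        labels = _nmf_once(v, k, np.random.default_rng(ss), n_iter=n_iter)
        consensus += labels[:, None] == labels[None, :]
    consensus /= n_runs
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    final = fcluster(z, t=k, criterion="maxclust") - 1
    if len(np.unique(final)) > 1:
        sil = silhouette_samples(dist, final, metric="precomputed")
    else:
        sil = np.zeros(n)
    return {"labels": final, "consensus": consensus, "silhouettes": sil}
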