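"""Conformational-motif analysis of per-lipid g3 fingerprints.

Each lipid's intramolecular structure is fingerprinted with the
radial-angular three-particle correlation function g3: for every selection
atom B, its nearest selection neighbour A defines a reference direction,
and every other selection atom C within a radial cutoff deposits weight at
(r_BC, cos theta_ABC).  The resulting 2D histograms (201 radial bins over
(0, 15 A], 101 angular bins over cos theta in [-1, 1], frame-averaged,
normalised to unit mass) are compared pairwise with the structural
similarity index (SSIM), embedded in 2D with t-SNE on 1 - SSIM
dissimilarities, clustered with HDBSCAN, and validated with an independent
PCA embedding.  Clusters are mapped onto a four-motif taxonomy (closed vs
splayed tails x ordered vs disordered chains) from two documented scores:
the trans/gauche second-shell peak ratio and the inter-tail packing band
mass at 4 < r < 6 A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .core import TrajectoryData

__all__ = [
    "G3Histogram",
    "SimilarityMatrix",
    "ClusterResult",
    "G3_CUTOFF",
    "G3_BINS",
    "TRANS_WINDOW",
    "GAUCHE_WINDOW",
    "PACKING_WINDOW",
    "compute_g3",
    "compute_g3_all",
    "ssim_score",
    "build_similarity_matrix",
    "embed_and_cluster",
    "characterize_clusters",
    "MotifClusterer",
]

G3_CUTOFF = 15.0  # A
G3_BINS = (201, 101)  # radial x angular

# Integration windows (r_min, r_max, cos_min, cos_max) fixed from the ideal
# rotamer geometry of a 1.53 A / 111 deg chain: the third-bond neighbour on
# the nearest-neighbour side sits at (3.88 A, cos 0.93) for a trans dihedral
# and at (2.99 A, cos 0.54) for gauche.
TRANS_WINDOW = (3.60, 4.15, 0.85, 1.00)
GAUCHE_WINDOW = (2.80, 3.20, 0.35, 0.75)
#: inter-tail packing band: increased density at 4 < r < 6 A indicates
#: atoms of the other tail packed against the central one
PACKING_WINDOW = (4.0, 6.0, -1.0, 1.0)

# Motif-assignment thresholds on (trans/gauche ratio, packing band mass).
# Calibrated once as geometric midpoints between the cluster-mean scores of
# the four pure-motif reference ensembles; documented in the methods note.
TG_ORDERED_THRESHOLD = 3.3
PACKING_CLOSED_THRESHOLD = 0.13
TG_TIGHT_THRESHOLD = 19.0


@dataclass
class G3Histogram:
    """Frame-averaged radial-angular three-particle histogram of one lipid."""

    values: np.ndarray  # (201, 101), unit total mass
    cutoff: float = G3_CUTOFF
    lipid_id: int = -1

    def __post_init__(self):
        if self.values.shape != G3_BINS:
            raise ValueError(f"g3 grid must be {G3_BINS}, got {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("g3 densities must be non-negative")

    @property
    def r_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.cutoff, G3_BINS[0] + 1)

    @property
    def cos_edges(self) -> np.ndarray:
        return np.linspace(-1.0, 1.0, G3_BINS[1] + 1)


@dataclass
class SimilarityMatrix:
    values: np.ndarray  # (n, n), symmetric, unit diagonal, scores in [-1, 1]

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")

    def to_dissimilarity(self) -> np.ndarray:
        return np.clip(1.0 - self.values, 0.0, None)


@dataclass
class ClusterResult:
    embedding: np.ndarray  # (n, 2) t-SNE
    labels: np.ndarray  # (n,) cluster ids, noise = -1
    pca_embedding: np.ndarray  # (n, 2)
    motif_map: dict | None = None  # cluster id -> motif id
    fractions: dict | None = None  # system -> {label: percent}
    cluster_scores: dict | None = None  # cluster id -> (tg_ratio, packing)
    mean_histograms: dict | None = None  # cluster id -> (201, 101)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels >= 0]))

    def motif_labels(self) -> np.ndarray:
        """Per-lipid motif ids (-1 for noise); requires characterisation."""
        if self.motif_map is None:
            raise ValueError("run characterize_clusters first")
        out = np.full(len(self.labels), -1)
        for cid, mid in self.motif_map.items():
            out[self.labels == cid] = mid
        return out


def _g3_accumulate(points: np.ndarray, cutoff: float, hist: np.ndarray):
    """Deposit one frame's triplets of one lipid into ``hist`` (in place)."""
    n_r, n_a = hist.shape
    d = points[None, :, :] - points[:, None, :]  # d[b, c] = C - B
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, np.inf)
    # nearest neighbour per central atom; ties resolved to the lowest index
    a_idx = np.argmin(r, axis=1)
    ba = d[np.arange(len(points)), a_idx]
    ba = ba / np.linalg.norm(ba, axis=-1, keepdims=True)
    cos = np.einsum("bj,bcj->bc", ba, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = cos / r
    mask = np.isfinite(r) & (r <= cutoff)
    rr = r[mask]
    cc = np.clip(cos[mask], -1.0, 1.0)
    ri = np.minimum((rr / cutoff * n_r).astype(np.intp), n_r - 1)
    ci = np.minimum(((cc + 1.0) / 2.0 * n_a).astype(np.intp), n_a - 1)
    np.add.at(hist, (ri, ci), 1.0)


def compute_g3(
    traj: TrajectoryData,
    lipid_id: int,
    selection: tuple[str, ...] | None = None,
    cutoff: float = G3_CUTOFF,
    frames: slice | None = None,
) -> G3Histogram:
    """g3 fingerprint of one lipid, averaged over the analysis frames.

    ``selection`` defaults to the topology's g3 selection (lipid-acid
    carbons, excluding the carbonyl carbon).  All three triplet members
    B, A, C come from the same lipid (intramolecular structure in
    isolation); C ranges over every selection atom except B itself, so the
    nearest neighbour contributes the first peak at one bond length near
    cos theta = 1.
    """
    names = selection or traj.topology.g3_selection
    if len(names) < 3:
        raise ValueError("g3 selection needs at least 3 atoms")
    idx = traj.topology.indices_of(names) + lipid_id * traj.topology.atoms_per_lipid
    fr = frames or slice(None)
    hist = np.zeros(G3_BINS)
    frame_ids = range(*fr.indices(traj.n_frames))
    for f in frame_ids:
        _g3_accumulate(traj.coords[f, idx].astype(float), cutoff, hist)
    total = hist.sum()
    if total > 0:
        hist /= total
    return G3Histogram(values=hist, cutoff=cutoff, lipid_id=lipid_id)


def compute_g3_all(
    traj: TrajectoryData,
    selection: tuple[str, ...] | None = None,
    cutoff: float = G3_CUTOFF,
    frames: slice | None = None,
    dtype=np.float32,
) -> np.ndarray:
    """g3 fingerprints of every lipid, shape (n_lipids, 201, 101)."""
    out = np.empty((traj.n_lipids,) + G3_BINS, dtype=dtype)
    for lid in range(traj.n_lipids):
        out[lid] = compute_g3(traj, lid, selection, cutoff, frames).values
    return out


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------

_SSIM_K1, _SSIM_K2 = 0.01, 0.03


def _ssim_map(x, y, mu_x, mu_y, xx, yy, win: int, data_range: float):
    """Mean SSIM from precomputed first/second moment maps (uniform window).

    Border windows (half the window width) are cropped before averaging, so
    only boundary-independent filter output is used.  Inputs may carry a
    leading batch axis on the ``y`` side.
    """
    size = (win, win) if x.ndim == 2 else (1, win, win)
    pad = (win - 1) // 2
    xy = uniform_filter(x * y, size=size)
    c1 = (_SSIM_K1 * data_range) ** 2
    c2 = (_SSIM_K2 * data_range) ** 2
    # sample-variance correction used by the reference implementation
    npix = win * win
    corr = npix / (npix - 1)
    mxy = mu_x * mu_y
    cov = xy
    cov -= mxy
    cov *= 2 * corr  # 2*cov
    var = xx + yy
    var -= mu_x * mu_x
    var -= mu_y * mu_y
    var *= corr  # var_x + var_y
    num = 2 * mxy + c1
    num *= cov + c2
    den = mu_x * mu_x + mu_y * mu_y + c1
    den *= var + c2
    s = num
    s /= den
    if s.ndim == 2:
        return float(s[pad:-pad, pad:-pad].mean(dtype=np.float64))
    return s[:, pad:-pad, pad:-pad].mean(axis=(1, 2), dtype=np.float64)


def ssim_score(
    h1: G3Histogram | np.ndarray,
    h2: G3Histogram | np.ndarray,
    window: int = 7,
    data_range: float | None = None,
) -> float:
    """Structural similarity index of two equally shaped 2D histograms.

    Mean local SSIM over sliding uniform windows with the standard
    luminance/contrast/structure terms; symmetric in its arguments and 1
    for identical inputs.  ``data_range`` defaults to the joint value
    range of the pair.
    """
    x = h1.values if isinstance(h1, G3Histogram) else np.asarray(h1)
    y = h2.values if isinstance(h2, G3Histogram) else np.asarray(h2)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if window % 2 != 1:
        raise ValueError("window size must be odd")
    x = x.astype(np.float64)
    y = y.astype(np.float64)
    if data_range is None:
        lo = min(x.min(), y.min())
        hi = max(x.max(), y.max())
        data_range = hi - lo
        if data_range == 0:
            return 1.0
    size = (window, window)
    mu_x = uniform_filter(x, size=size)
    mu_y = uniform_filter(y, size=size)
    xx = uniform_filter(x * x, size=size)
    yy = uniform_filter(y * y, size=size)
    return _ssim_map(x, y, mu_x, mu_y, xx, yy, window, data_range)


def build_similarity_matrix(
    histograms: np.ndarray | list,
    window: int = 7,
    data_range: float | None = None,
    batch: int = 512,
) -> SimilarityMatrix:
    """Pairwise SSIM matrix of g3 histograms (each pair computed once).

    ``data_range`` defaults to the global value range of the whole set so
    scores are mutually comparable.  First/second-moment maps are
    precomputed per histogram and pair products are filtered in batches.
    """
    if isinstance(histograms, list):
        histograms = np.stack(
            [h.values if isinstance(h, G3Histogram) else h for h in histograms]
        )
    X = histograms.astype(np.float32)
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 histograms")
    if data_range is None:
        data_range = float(X.max() - X.min())
        if data_range == 0:
            return SimilarityMatrix(np.ones((n, n)))
    size = (1, window, window)
    mu = uniform_filter(X, size=size)
    sq = uniform_filter(X * X, size=size)
    out = np.ones((n, n))
    for i in range(n - 1):
        for j0 in range(i + 1, n, batch):
            j1 = min(j0 + batch, n)
            s = _ssim_map(
                X[i][None], X[j0:j1], mu[i][None], mu[j0:j1], sq[i][None], sq[j0:j1],
                window, data_range,
            )
            out[i, j0:j1] = s
            out[j0:j1, i] = s
    return SimilarityMatrix(out)


# ---------------------------------------------------------------------------
# embedding + clustering
# ---------------------------------------------------------------------------

def embed_and_cluster(
    matrix: SimilarityMatrix,
    perplexity: float = 100.0,
    early_exaggeration: float = 4.0,
    min_cluster_size: int = 50,
    seed: int = 0,
) -> ClusterResult:
    """t-SNE embedding of 1 - SSIM dissimilarities, HDBSCAN clustering,
    and an independent PCA embedding for validation.

    t-SNE is randomly initialised under ``seed``; HDBSCAN runs on the 2D
    embedding with the given minimum cluster size and labels outliers -1.
    """
    from sklearn.cluster import HDBSCAN
    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE

    D = matrix.to_dissimilarity()
    n = len(D)
    if n <= 3 * perplexity:
        raise ValueError(
            f"n={n} samples is too small for perplexity={perplexity}; "
            "lower the perplexity (need n > 3*perplexity)"
        )
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        perplexity=perplexity,
        early_exaggeration=early_exaggeration,
        random_state=seed,
    )
    emb = tsne.fit_transform(D)
    if n < min_cluster_size:
        # no cluster can satisfy the minimum size: everything is noise
        labels = np.full(n, -1)
    else:
        # allow_single_cluster so a homogeneous ensemble reports one
        # population instead of all-noise; multi-population structure still
        # yields the hierarchy leaves
        labels = (
            HDBSCAN(min_cluster_size=min_cluster_size, allow_single_cluster=True, copy=True)
            .fit(emb)
            .labels_
        )
    pca = PCA(n_components=2, random_state=seed).fit_transform(D)
    return ClusterResult(embedding=emb, labels=labels, pca_embedding=pca)


def _window_mass(h: np.ndarray, window: tuple[float, float, float, float],
                 cutoff: float = G3_CUTOFF) -> float:
    r_lo, r_hi, c_lo, c_hi = window
    n_r, n_a = h.shape
    r_edges = np.linspace(0.0, cutoff, n_r + 1)
    c_edges = np.linspace(-1.0, 1.0, n_a + 1)
    ri = (r_edges[:-1] >= r_lo) & (r_edges[1:] <= r_hi)
    ci = (c_edges[:-1] >= c_lo) & (c_edges[1:] <= c_hi)
    return float(h[np.ix_(ri, ci)].sum())


def conformation_scores(h: np.ndarray, cutoff: float = G3_CUTOFF) -> tuple[float, float]:
    """(trans/gauche peak ratio, inter-tail packing band mass) of a g3 map."""
    trans = _window_mass(h, TRANS_WINDOW, cutoff)
    gauche = _window_mass(h, GAUCHE_WINDOW, cutoff)
    packing = _window_mass(h, PACKING_WINDOW, cutoff)
    return trans / max(gauche, 1e-12), packing


def _assign_motif(tg_ratio: float, packing: float) -> int:
    """Four-quadrant taxonomy: closed/splayed x ordered/disordered.

    0 closed-ordered, 1 tightly-closed-ordered (highest order among closed),
    2 splayed-disordered, 3 splayed-ordered.  Disorder dominates the split
    (fluid tails have low trans/gauche ratios regardless of splay); among
    ordered clusters the inter-tail packing band separates closed from
    splayed, and the highest trans/gauche ratios mark the tight motif.
    """
    if tg_ratio <= TG_ORDERED_THRESHOLD:
        return 2
    if packing >= PACKING_CLOSED_THRESHOLD:
        return 1 if tg_ratio > TG_TIGHT_THRESHOLD else 0
    return 3


def characterize_clusters(
    result: ClusterResult,
    histograms: np.ndarray,
    system_ids: np.ndarray | None = None,
    cutoff: float = G3_CUTOFF,
) -> ClusterResult:
    """Average g3 per cluster, trans/gauche and packing scores, motif ids,
    and per-system label fractions (percentages over motifs + noise).

    Modifies and returns ``result``.
    """
    labels = result.labels
    cluster_ids = sorted(set(labels[labels >= 0]))
    if not cluster_ids:
        raise ValueError("all points are noise; nothing to characterise")
    if isinstance(histograms, list):
        histograms = np.stack(
            [h.values if isinstance(h, G3Histogram) else h for h in histograms]
        )
    means, scores, motif_map = {}, {}, {}
    for cid in cluster_ids:
        m = histograms[labels == cid].mean(axis=0).astype(float)
        means[cid] = m
        scores[cid] = conformation_scores(m, cutoff)
        motif_map[cid] = _assign_motif(*scores[cid])
    sys_ids = np.zeros(len(labels), dtype=int) if system_ids is None else np.asarray(system_ids)
    fractions = {}
    for s in np.unique(sys_ids):
        mask = sys_ids == s
        total = mask.sum()
        frac = {}
        for cid in cluster_ids:
            mid = motif_map[cid]
            frac[mid] = frac.get(mid, 0.0) + 100.0 * np.sum(labels[mask] == cid) / total
        frac["noise"] = 100.0 * np.sum(labels[mask] < 0) / total
        fractions[int(s)] = frac
    result.mean_histograms = means
    result.cluster_scores = scores
    result.motif_map = motif_map
    result.fractions = fractions
    return result


class MotifClusterer:
    """sklearn-style estimator for the g3 -> SSIM -> t-SNE -> HDBSCAN stage.

    fit(X) takes an (n, 201, 101) stack of g3 histograms; fitted attributes
    are ``labels_``, ``embedding_``, ``pca_embedding_``, ``motif_map_`` and
    ``similarity_`` (the SSIM matrix).
    """

    def __init__(self, perplexity=100.0, early_exaggeration=4.0,
                 min_cluster_size=50, ssim_window=7, random_state=0):
        self.perplexity = perplexity
        self.early_exaggeration = early_exaggeration
        self.min_cluster_size = min_cluster_size
        self.ssim_window = ssim_window
        self.random_state = random_state

    def get_params(self, deep=True):
        return {
            "perplexity": self.perplexity,
            "early_exaggeration": self.early_exaggeration,
            "min_cluster_size": self.min_cluster_size,
            "ssim_window": self.ssim_window,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None, system_ids=None):
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("X must be an (n, n_r, n_a) histogram stack")
        sim = build_similarity_matrix(X, window=self.ssim_window)
        res = embed_and_cluster(
            sim,
            perplexity=self.perplexity,
            early_exaggeration=self.early_exaggeration,
            min_cluster_size=self.min_cluster_size,
            seed=self.random_state,
        )
        characterize_clusters(res, X, system_ids=system_ids)
        self.similarity_ = sim
        self.result_ = res
        self.labels_ = res.labels
        self.embedding_ = res.embedding
        self.pca_embedding_ = res.pca_embedding
        self.motif_map_ = res.motif_map
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_
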